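"""Curve-fitter tests: noiseless round trips, invariances, degenerate inputs."""

import numpy as np
import pytest

from ktau import (
    HillCurve,
    OperationalModel,
    PlateauAssociation,
    PlateauDecay,
    RiseFall,
    TimeCourse,
)
from ktau.fitting import FitConvergenceError
from ktau.kinetics import RiseFallParams, risefall_response
from ktau.qc import invert_downward, preprocess
from ktau.simulate import builtin_fixtures, generate_risefall_plate


def association_curve(t, y0, plateau, k, x0):
    out = np.full_like(t, y0)
    m = t >= x0
    out[m] = y0 + (plateau - y0) * (1 - np.exp(-k * (t[m] - x0)))
    return out


def upward_tc(t, y, **kw):
    return TimeCourse(times=t, values=y, direction="upward", **kw)


T = np.arange(0, 21.0, 0.15)
TRUE = dict(y0=0.01, plateau=0.45, k=0.92, x0=1.05)


class TestPlateauAssociation:
    def test_noiseless_round_trip(self):
        y = association_curve(T, **TRUE)
        res = PlateauAssociation(upward_tc(T, y)).fit()
        for name, truth in TRUE.items():
            assert res.params[name] == pytest.approx(truth, rel=1e-4, abs=1e-6)
        assert res.rsquared > 0.999999

    def test_time_shift_invariance(self):
        """Shifting all times by delta shifts the fitted x0 by delta and
        leaves the other parameters unchanged."""
        y = association_curve(T, **TRUE)
        base = PlateauAssociation(upward_tc(T, y)).fit()
        delta = 2.5
        shifted = PlateauAssociation(upward_tc(T + delta, y)).fit()
        assert shifted.params["x0"] - base.params["x0"] == pytest.approx(
            delta, abs=1e-6
        )
        for name in ("y0", "plateau", "k"):
            assert shifted.params[name] == pytest.approx(
                base.params[name], rel=1e-6, abs=1e-9
            )

    def test_constant_trace_flagged_unidentifiable(self):
        y = np.full_like(T, 0.3)
        res = PlateauAssociation(upward_tc(T, y)).fit()
        assert res.params["plateau"] == pytest.approx(res.params["y0"], abs=1e-6)
        assert not res.identifiable

    def test_downward_trace_rejected(self):
        tc = TimeCourse(times=T, values=1 - association_curve(T, **TRUE),
                        direction="downward")
        with pytest.raises(ValueError, match="invert"):
            PlateauAssociation(tc)

    def test_too_few_post_onset_points(self):
        t = np.linspace(0, 10, 10)
        y = np.where(t < 9.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="post-onset"):
            PlateauAssociation(upward_tc(t, y))

    def test_replicates_fit_as_separate_points(self):
        """Two replicates offset symmetrically fit to their pointwise middle,
        which pre-averaging would also give -- but the residuals see 2n points."""
        y = association_curve(T, **TRUE)
        tc1 = upward_tc(T, y + 0.01)
        tc2 = upward_tc(T, y - 0.01)
        res = PlateauAssociation([tc1, tc2]).fit()
        assert res.nobs == 2 * len(T)
        assert res.params["plateau"] == pytest.approx(TRUE["plateau"], rel=1e-3)


class TestPlateauDecay:
    def test_noiseless_round_trip(self):
        y0, plateau, k, x0 = 1.0, 0.56, 0.92, 1.05
        m = T >= x0
        y = np.full_like(T, y0)
        y[m] = plateau + (y0 - plateau) * np.exp(-k * (T[m] - x0))
        tc = TimeCourse(times=T, values=y, direction="downward")
        res = PlateauDecay(tc).fit()
        assert res.params["k"] == pytest.approx(k, rel=1e-4)
        assert res.params["plateau"] == pytest.approx(plateau, rel=1e-4)

    def test_matches_inverted_association_fit(self):
        """Fitting a downward trace with the decay form gives the same rate as
        fitting its inversion with the association form."""
        fx = builtin_fixtures()
        from ktau.simulate import generate_arrestin_plate

        traces = generate_arrestin_plate(fx["angii-arrestin-saturating"])
        from ktau.qc import delta_f_over_f

        tcs_down = [delta_f_over_f(tr) for tr in traces]
        tcs_up = [invert_downward(tc) for tc in tcs_down]
        k_down = PlateauDecay(tcs_down).fit()
        k_up = PlateauAssociation(tcs_up).fit()
        se = max(k_down.se["k"], k_up.se["k"])
        assert abs(k_down.params["k"] - k_up.params["k"]) < max(se, 1e-8)

    def test_flat_trace_unidentifiable(self):
        y = np.full_like(T, 1.0)
        res = PlateauDecay(TimeCourse(times=T, values=y, direction="downward")).fit()
        assert not res.identifiable


class TestRiseFall:
    def test_noiseless_round_trip(self):
        p = RiseFallParams(c=1.7, k1=2.0, k2=0.2, baseline=0.05)
        x0 = 1.05
        y = np.where(T < x0, p.baseline,
                     risefall_response(np.clip(T - x0, 0, None), p))
        res = RiseFall(upward_tc(T, y)).fit()
        assert res.params["c"] == pytest.approx(1.7, rel=1e-4)
        assert res.params["k1"] == pytest.approx(2.0, rel=1e-4)
        assert res.params["k2"] == pytest.approx(0.2, rel=1e-4)
        assert res.params["k1"] >= res.params["k2"]

    def test_drift_recovery(self):
        """A slight negative drift is recovered within 50% at 3% noise."""
        fx = builtin_fixtures()
        traces = generate_risefall_plate(fx["angii-calcium"])
        tcs = [preprocess(tr) for tr in traces]
        res = RiseFall(tcs, with_drift=True).fit()
        assert res.params["drift"] == pytest.approx(-0.002, rel=0.5)

    def test_dag_ktau_recovery_at_noise(self):
        """The DAG-like initial rate C (1.7 NFU/min) is recovered within 10%
        from noisy synthetic traces."""
        fx = builtin_fixtures()
        traces = generate_risefall_plate(fx["angii-dag"])
        tcs = [preprocess(tr) for tr in traces]
        res = RiseFall(tcs).fit()
        assert res.params["c"] == pytest.approx(1.7, rel=0.10)

    def test_degenerate_equal_rates_branch(self):
        k = 1.0
        y = np.where(T < 1.05, 0.0, 1.5 * np.clip(T - 1.05, 0, None)
                     * np.exp(-k * np.clip(T - 1.05, 0, None)))
        res = RiseFall(upward_tc(T, y)).fit()
        assert res.params["k1"] == pytest.approx(res.params["k2"], rel=1e-3)
        assert res.params["c"] == pytest.approx(1.5, rel=1e-2)


class TestHillCurve:
    CONC = np.array([1e-8, 3.2e-8, 1e-7, 3.2e-7, 1e-6, 3.2e-6, 1e-5, 3.2e-5])

    @staticmethod
    def sigmoid(conc, top, bottom, log_l50, hill):
        return bottom + (top - bottom) / (
            1 + 10 ** ((log_l50 - np.log10(conc)) * hill)
        )

    def test_noiseless_round_trip(self):
        y = self.sigmoid(self.CONC, 0.41, 0.0, -6.92, 1.0)
        res = HillCurve(self.CONC, y, fix_bottom_at_zero=True).fit()
        assert res.params["top"] == pytest.approx(0.41, rel=1e-4)
        assert res.params["log_l50"] == pytest.approx(-6.92, abs=1e-4)
        assert res.params["hill"] == pytest.approx(1.0, rel=1e-4)

    def test_midpoint_definition(self):
        res = HillCurve(
            self.CONC, self.sigmoid(self.CONC, 0.41, 0.0, -6.92, 1.0),
            fix_bottom_at_zero=True,
        ).fit()
        at_l50 = res.predict(np.array([res.l50]))[0]
        assert at_l50 == pytest.approx(0.41 / 2, rel=1e-6)

    def test_noisy_l50_recovery(self):
        """log L50 recovered within 0.1 log units at 3% noise, 3 replicates."""
        rng = np.random.default_rng(11)
        conc = np.repeat(self.CONC, 3)
        y = self.sigmoid(conc, 0.41, 0.0, -6.92, 1.0)
        y = y * (1 + 0.03 * rng.standard_normal(y.shape))
        res = HillCurve(conc, y, fix_bottom_at_zero=True).fit()
        assert abs(res.params["log_l50"] + 6.92) < 0.1

    def test_constant_response_refused(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            HillCurve(self.CONC, np.full(8, 0.3))

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            HillCurve(np.array([1e-8, 1e-7, 1e-6]), np.array([0.1, 0.2, 0.3]))


class TestOperationalModel:
    CONC = TestHillCurve.CONC

    @staticmethod
    def operational(conc, e_m, tau, k_a, n=1.0):
        rho = conc**n / (k_a**n + conc**n)
        return e_m * rho * tau / (1 + rho * tau)

    def test_saturation_limits(self):
        # tau -> infinity approaches Em; tau = 1 gives Em/2 at saturation
        y_inf = self.operational(1e-2, 0.259, 1e6, 1.2e-6)
        assert y_inf == pytest.approx(0.259, rel=1e-4)
        y_tau1 = self.operational(1.0, 0.259, 1.0, 1.2e-6)
        assert y_tau1 == pytest.approx(0.259 / 2, rel=1e-4)

    def test_noiseless_round_trip(self):
        y = self.operational(self.CONC, 0.259, 1.8, 1.2e-6)
        res = OperationalModel(self.CONC, y, e_m=0.259).fit()
        assert res.params["tau"] == pytest.approx(1.8, rel=1e-4)
        assert res.k_a == pytest.approx(1.2e-6, rel=1e-3)

    def test_tau_recovery_at_noise(self):
        """tau recovered within 15% at 3% noise (1-min parameter set:
        Em 0.259, tau 1.8, K_A 1,200 nM)."""
        rng = np.random.default_rng(5)
        conc = np.repeat(self.CONC, 3)
        y = self.operational(conc, 0.259, 1.8, 1.2e-6)
        y = y * (1 + 0.03 * rng.standard_normal(y.shape))
        res = OperationalModel(conc, y, e_m=0.259).fit()
        assert res.params["tau"] == pytest.approx(1.8, rel=0.15)

    def test_warns_when_em_at_or_below_response(self):
        y = self.operational(self.CONC, 0.259, 50.0, 1.2e-6)
        res = OperationalModel(self.CONC, y, e_m=0.25).fit()
        assert res.warnings


class TestGoodnessOfFit:
    def test_r2_above_095_at_study_noise(self, angii_dose_response_fits):
        """At the study's data quality (CV <= 5%), R^2 exceeds 0.95 for every
        effective concentration's association fit."""
        for res in angii_dose_response_fits[3:]:  # concentrations >= K_A scale
            assert res.rsquared > 0.95
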