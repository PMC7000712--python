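"""Preprocessing and plate-QC tests: DeltaF/F, inversion, %CV, Z', endpoints."""

from collections import defaultdict
from dataclasses import replace

import numpy as np
import pytest

from ktau import (
    PlateauAssociation,
    RawTrace,
    TimeCourse,
    delta_f_over_f,
    endpoint_dose_response,
    generate_arrestin_plate,
    invert_downward,
    percent_cv,
    z_prime,
)
from ktau.qc import NO_WINDOW, preprocess
from ktau.simulate import ANGII_ARRESTIN, LigandSpec, builtin_fixtures


def raw(values, times=None, addition=1.0, **kw):
    values = np.asarray(values, float)
    if times is None:
        times = np.arange(len(values)) * 0.2
    return RawTrace(times=times, raw_fluorescence=values, addition_time=addition, **kw)


def flat_tc(values, direction="upward"):
    t = np.arange(len(values)) * 0.2
    return TimeCourse(times=t, values=np.asarray(values, float), direction=direction)


class TestDeltaFOverF:
    def test_flat_trace_normalizes_to_one(self):
        tr = raw(np.full(20, 812.0))
        assert np.allclose(delta_f_over_f(tr).values, 1.0)

    def test_hand_division(self):
        vals = np.concatenate([np.full(6, 1000.0), np.full(10, 560.0)])
        tc = delta_f_over_f(raw(vals))
        assert tc.values[-1] == pytest.approx(0.56)

    def test_scale_invariance(self):
        vals = np.concatenate([np.full(6, 1000.0), np.linspace(1000, 500, 10)])
        a = delta_f_over_f(raw(vals)).values
        b = delta_f_over_f(raw(37.5 * vals)).values
        assert np.allclose(a, b)

    def test_nonpositive_baseline_refused(self):
        vals = np.concatenate([np.full(6, 0.0), np.full(10, 5.0)])
        with pytest.raises(ValueError, match="baseline"):
            delta_f_over_f(raw(vals))


class TestInversion:
    def test_values_and_direction(self):
        tc = flat_tc([1.0] * 5 + [0.56] * 5, direction="downward")
        inv = invert_downward(tc)
        assert inv.direction == "upward"
        assert inv.values[0] == pytest.approx(0.0)
        assert inv.values[-1] == pytest.approx(0.44)

    def test_double_inversion_identity(self):
        tc = flat_tc(np.linspace(1, 0.5, 10), direction="downward")
        back = invert_downward(invert_downward(tc))
        assert np.allclose(back.values, tc.values)
        assert back.direction == tc.direction

    def test_preprocess_recovers_generating_curve(self):
        """DeltaF/F + inversion undoes the generator's forward mapping: the
        noiseless preprocessed trace equals the recruitment model exactly."""
        from ktau.kinetics import arrestin_response

        fx = builtin_fixtures()
        sc = replace(fx["angii-arrestin-saturating"], noise_cv=0.0,
                     jitter_sd_min=0.0, replicates=1)
        tr = generate_arrestin_plate(sc)[0]
        tc = preprocess(tr)
        t_post = np.clip(tc.times - sc.baseline_min, 0, None)
        expected = arrestin_response(t_post, 3.2e-5, ANGII_ARRESTIN)
        assert np.allclose(tc.values, expected, atol=1e-12)


class TestPercentCV:
    def test_identical_replicates(self):
        tcs = [flat_tc(np.linspace(1, 2, 10)) for _ in range(3)]
        assert np.allclose(percent_cv(tcs).to_numpy(), 0.0)

    def test_hand_value_duplicates(self):
        # replicates {0.9, 1.1}: sample sd 0.1414, mean 1.0 -> 14.14%
        tcs = [flat_tc([0.9] * 10), flat_tc([1.1] * 10)]
        assert percent_cv(tcs).iloc[0] == pytest.approx(14.142, abs=0.01)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            percent_cv([flat_tc([1.0] * 10)])


class TestZPrime:
    def two_groups(self, sd_pos, sd_neg, sep=1.0, n=3, npts=10):
        rng = np.random.default_rng(0)
        pos = [flat_tc(np.full(npts, 1.0 + sep) + 0) for _ in range(n)]
        neg = [flat_tc(np.full(npts, 1.0)) for _ in range(n)]
        # inject exact spreads deterministically: +/- sd around the mean
        pos = [flat_tc(np.full(npts, 1.0 + sep + s)) for s in (-sd_pos, 0, sd_pos)]
        neg = [flat_tc(np.full(npts, 1.0 + s)) for s in (-sd_neg, 0, sd_neg)]
        return pos, neg

    def test_upper_bound_at_zero_variance(self):
        pos, neg = self.two_groups(0.0, 0.0)
        assert np.allclose(z_prime(pos, neg).to_numpy(), 1.0)

    def test_boundary_zero(self):
        # sd = separation/6 in each group gives Z' = 0 (sample sd of
        # {-s, 0, s} is s; 1 - 3(s + s)/sep with s = sep/6)
        pos, neg = self.two_groups(1.0 / 6.0, 1.0 / 6.0, sep=1.0)
        assert np.allclose(z_prime(pos, neg).to_numpy(), 0.0, atol=1e-12)

    def test_no_separation_sentinel(self):
        pos, neg = self.two_groups(0.1, 0.1, sep=0.0)
        assert np.all(z_prime(pos, neg).to_numpy() == NO_WINDOW)

    def test_monotone_in_spread(self):
        z_small = z_prime(*self.two_groups(0.02, 0.02)).iloc[0]
        z_big = z_prime(*self.two_groups(0.1, 0.1)).iloc[0]
        assert z_big < z_small <= 1.0

    def test_plateau_window_beats_rise_phase(self):
        """On synthetic saturating wells, Z' is high and stable on the plateau
        and lower on the rise phase, mirroring the screening-window profile."""
        fx = builtin_fixtures()
        sc = replace(fx["angii-arrestin-saturating"], replicates=4)
        pos = [preprocess(tr) for tr in generate_arrestin_plate(sc)]
        neg_sc = replace(sc, ligands=(LigandSpec("vehicle",
                         replace(ANGII_ARRESTIN, k_tau=0.0)),), seed=77)
        neg = [preprocess(tr) for tr in generate_arrestin_plate(neg_sc)]
        z = z_prime(pos, neg)
        rise = z[(z.index > 1.2) & (z.index < 1.8)].median()
        plateau = z[z.index > 10].median()
        assert plateau > 0.5
        assert rise < plateau


class TestEndpointDoseResponse:
    def test_ec50_decreases_over_time(self, angii_dose_response_fits):
        """Endpoint EC50 falls from 1 min to 20 min after addition, while the
        kinetic k_tau underlying the data is time-invariant."""
        e1 = endpoint_dose_response(angii_dose_response_fits, 1.0)
        e20 = endpoint_dose_response(angii_dose_response_fits, 20.0)
        assert e1.ec50 > e20.ec50
        assert e20.e_max > e1.e_max

    def test_early_ec50_tracks_affinity(self, angii_dose_response_fits):
        """At a time on the linear (initial-rate) portion, the endpoint EC50
        approximates the true K_A (120 nM) within 2-fold."""
        e1 = endpoint_dose_response(angii_dose_response_fits, 1.0)
        assert 60e-9 < e1.ec50 < 240e-9

    def test_partial_rate_ligand_narrative(self):
        """A half-rate ligand looks partial at 1 min but near-full at the
        plateau endpoint."""
        fx = builtin_fixtures()
        half = replace(
            ANGII_ARRESTIN,
            k_tau=0.5 * ANGII_ARRESTIN.k_tau,
            c_scale=0.5 * ANGII_ARRESTIN.c_scale,
        )
        sc = replace(fx["angii-arrestin"],
                     ligands=(LigandSpec("halfrate", half),), seed=31)
        groups = defaultdict(list)
        for tr in generate_arrestin_plate(sc):
            groups[tr.conc].append(preprocess(tr))
        fits = [PlateauAssociation(tcs).fit() for _, tcs in sorted(groups.items())]
        full_1 = endpoint_dose_response([f for f in fits], 1.0)

        ref_fits = []
        ref_groups = defaultdict(list)
        for tr in generate_arrestin_plate(fx["angii-arrestin"]):
            ref_groups[tr.conc].append(preprocess(tr))
        ref_fits = [PlateauAssociation(tcs).fit()
                    for _, tcs in sorted(ref_groups.items())]
        ref_1 = endpoint_dose_response(ref_fits, 1.0)
        ref_20 = endpoint_dose_response(ref_fits, 20.0)
        half_20 = endpoint_dose_response(fits, 20.0)
        assert full_1.e_max / ref_1.e_max < 0.75  # partial on the rise phase
        assert half_20.e_max / ref_20.e_max > 0.85  # near-full at the plateau
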