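"""Nonlinear least-squares models for biosensor time courses and dose-response data.

Each model follows the statsmodels convention: construct from data, call
``fit()``, get a Results object carrying parameter estimates, asymptotic
standard errors (Jacobian-based covariance), R^2 and a ``summary()`` table.

All time-course equations share the piecewise-baseline structure used by
plate-reader workflows: the signal is flat at the pre-stimulus baseline until
the onset time ``x0`` (free in every fit, to absorb well-to-well differences
in ligand-addition timing) and follows the kinetic equation afterwards.
Fits are unweighted; technical replicates enter as separate points and are
never pre-averaged.

Initial guesses are deterministic and data-driven (no user tuning):
baseline from pre-onset points, plateau from the last 10% of points, rate from
the time-to-half-change, onset from the largest absolute first difference;
biexponential rates are seeded at fixed splits around the single-exponential
rate (a small deterministic multi-start; lowest SSR wins).
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import lmfit
import numpy as np

from .datatypes import TimeCourse
from .kinetics import RATE_DEGENERACY_RTOL

__all__ = [
    "FitConvergenceError",
    "CurveResults",
    "PlateauAssociation",
    "PlateauDecay",
    "RiseFall",
    "HillCurve",
    "OperationalModel",
    "GlobalRecruitment",
]

#: convergence tolerances shared by all fitters
XTOL = 1e-8
MAX_NFEV = 10_000


class FitConvergenceError(RuntimeError):
    """Raised when the optimizer fails to converge; carries solver diagnostics."""


def _coerce_points(data, require_direction: str | None = None):
    """Accept a TimeCourse, a sequence of TimeCourses (replicates fit as
    separate points), or a (times, values) pair; return flat point arrays
    plus metadata from the first trace."""
    meta = {"ligand": "", "conc": None, "replicate": None}
    if isinstance(data, TimeCourse):
        data = [data]
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], TimeCourse):
        for tc in data:
            if require_direction and tc.direction != require_direction:
                raise ValueError(
                    f"expected a {require_direction} trace, got {tc.direction} "
                    "(apply invert_downward first)"
                )
        t = np.concatenate([tc.times for tc in data])
        y = np.concatenate([tc.values for tc in data])
        order = np.argsort(t, kind="stable")
        meta = {
            "ligand": data[0].ligand,
            "conc": data[0].conc,
            "replicate": data[0].replicate,
        }
        return t[order], y[order], meta
    t, y = data
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    order = np.argsort(t, kind="stable")
    return t[order], y[order], meta


def _minimize(residual, params) -> lmfit.minimizer.MinimizerResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lmfit warns on near-singular covariances
        res = lmfit.minimize(
            residual,
            params,
            method="least_squares",
            xtol=XTOL,
            ftol=XTOL,
            gtol=XTOL,
            max_nfev=MAX_NFEV,
        )
    if not res.success:
        raise FitConvergenceError(
            f"fit did not converge: {res.message} (nfev={res.nfev})"
        )
    return res


def _rsquared(y, resid) -> float:
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _guess_profile(t, y) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-averaged, lightly smoothed profile used only for initial
    guesses (never for fitting; replicates are always fit as separate points)."""
    tu, inv = np.unique(t, return_inverse=True)
    ym = np.bincount(inv, weights=y) / np.bincount(inv)
    if ym.size >= 5:
        kernel = np.ones(3) / 3.0
        ym = np.convolve(np.pad(ym, 1, mode="edge"), kernel, mode="valid")
    return tu, ym


def _guess_onset(t, y) -> float:
    """Onset guess: time of the largest absolute first difference of the
    replicate-averaged smoothed profile."""
    tu, ym = _guess_profile(t, y)
    d = np.abs(np.diff(ym))
    if np.all(d == 0):
        return float(tu[0])
    return float(tu[int(np.argmax(d))])


class CurveResults:
    """Base fitted-parameter record.

    Attributes
    ----------
    params : dict
        Point estimates by parameter name.
    se : dict
        Asymptotic standard errors (NaN when not estimable, e.g. at a bound
        or for an unidentifiable parameter).
    rsquared : float
        Unweighted coefficient of determination.
    cov : pandas-free covariance matrix aligned with ``param_names``.
    """

    def __init__(self, model, mres: lmfit.minimizer.MinimizerResult, t, y):
        self.model = model
        self._mres = mres
        self.nobs = len(y)
        self.nfev = mres.nfev
        self.param_names = list(mres.var_names)
        self.params = {name: float(p.value) for name, p in mres.params.items()}
        self.se = {
            name: (float(p.stderr) if p.stderr is not None else np.nan)
            for name, p in mres.params.items()
        }
        self.cov = getattr(mres, "covar", None)
        self.rsquared = _rsquared(y, mres.residual)
        self.ligand = model.ligand
        self.conc = model.conc

    # spec alias
    @property
    def r2(self) -> float:
        return self.rsquared

    def cov_pair(self, a: str, b: str) -> float:
        """Estimated covariance of two fitted parameters (0 if unavailable)."""
        if self.cov is None:
            return 0.0
        try:
            ia, ib = self.param_names.index(a), self.param_names.index(b)
        except ValueError:
            return 0.0
        return float(self.cov[ia, ib])

    def predict(self, t):
        """Evaluate the fitted curve at times ``t`` (minutes)."""
        return self.model._evaluate(np.asarray(t, dtype=float), self.params)

    def __getattr__(self, name):
        params = self.__dict__.get("params", {})
        if name in params:
            return params[name]
        raise AttributeError(name)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit",
            f"  n points: {self.nobs}   R^2: {self.rsquared:.5f}   nfev: {self.nfev}",
            f"  {'param':>10}  {'value':>12}  {'std err':>12}",
        ]
        for name in self.params:
            lines.append(
                f"  {name:>10}  {self.params[name]:>12.6g}  {self.se[name]:>12.4g}"
            )
        return "\n".join(lines)


class ExpFitResults(CurveResults):
    """Single-exponential (association or decay) fit: y0, plateau, k, x0."""

    @property
    def identifiable(self) -> bool:
        """False when the rate constant carries no information (flat trace):
        its standard error is missing or exceeds the estimate itself."""
        se_k = self.se.get("k", np.nan)
        return bool(np.isfinite(se_k) and se_k <= abs(self.params["k"]))

    @property
    def amplitude(self) -> float:
        return self.params["plateau"] - self.params["y0"]


class RiseFallResults(CurveResults):
    """Biexponential fit: baseline, c, k1, k2, x0 (+ drift). k1 >= k2 enforced."""

    degenerate: bool = False

    @property
    def identifiable(self) -> bool:
        se_c = self.se.get("c", np.nan)
        return bool(np.isfinite(se_c) and se_c <= abs(self.params["c"]) or
                    self.params["c"] == 0.0)


class SigmoidResults(CurveResults):
    """Variable-slope log-logistic fit: top, bottom, log_l50, hill."""

    @property
    def l50(self) -> float:
        """Midpoint concentration (molar)."""
        return float(10.0 ** self.params["log_l50"])

    @property
    def l50_se(self) -> float:
        se = self.se.get("log_l50", np.nan)
        return float(math.log(10.0) * self.l50 * se)


class OperationalResults(CurveResults):
    """Operational-model fit: tau, k_a (via pK_A), n; Em held fixed."""

    def __init__(self, model, mres, t, y, fit_warnings):
        super().__init__(model, mres, t, y)
        self.e_m = model.e_m
        self.warnings = list(fit_warnings)

    @property
    def k_a(self) -> float:
        return float(10.0 ** -self.params["p_k_a"])

    @property
    def k_a_se(self) -> float:
        return float(math.log(10.0) * self.k_a * self.se.get("p_k_a", np.nan))


class GlobalResults(CurveResults):
    """Global recruitment fit: k_tau, c_scale, k_off, pK_A, n (+ per-trace x0)."""

    def __init__(self, model, mres, t, y, fit_warnings):
        super().__init__(model, mres, t, y)
        self.warnings = list(fit_warnings)

    @property
    def k_a(self) -> float:
        return float(10.0 ** -self.params["p_k_a"])

    def predict(self, t, trace_index: int = 0):
        return self.model._evaluate_trace(
            np.asarray(t, dtype=float), self.params, trace_index
        )


class _TimeCourseModel:
    """Shared machinery for piecewise-baseline time-course fits."""

    results_class = CurveResults
    require_direction: str | None = None
    min_post_onset = 6

    def __init__(self, data):
        self.t, self.y, meta = _coerce_points(data, self.require_direction)
        self.ligand = meta["ligand"]
        self.conc = meta["conc"]
        self._tg, self._yg = _guess_profile(self.t, self.y)
        self.x0_guess = _guess_onset(self.t, self.y)
        n_post = int(np.sum(self.t > self.x0_guess))
        if n_post < self.min_post_onset:
            raise ValueError(
                f"need >= {self.min_post_onset} post-onset points, found {n_post}"
            )

    # subclasses: _build_params(), _evaluate(t, params)
    def _residual(self, params):
        vals = {name: params[name].value for name in params}
        return self._evaluate(self.t, vals) - self.y

    def fit(self):
        params = self._build_params()
        mres = _minimize(self._residual, params)
        return self.results_class(self, mres, self.t, self.y)

    # --- guess helpers -------------------------------------------------
    def _segment_means(self):
        """(baseline guess, plateau guess) from pre-onset / last-10% points."""
        pre = self._yg[self._tg <= self.x0_guess]
        y0 = float(np.mean(pre)) if pre.size else float(self._yg[0])
        n_tail = max(1, len(self._yg) // 10)
        plateau = float(np.mean(self._yg[-n_tail:]))
        return y0, plateau

    def _rate_guess(self, y0, target) -> float:
        """k from the time-to-half-change toward ``target`` after onset."""
        half = 0.5 * (y0 + target)
        post = self._tg > self.x0_guess
        tp, yp = self._tg[post], self._yg[post]
        toward = np.abs(yp - target) <= np.abs(half - target)
        dt = float(np.median(np.diff(self._tg))) or 1.0
        if not np.any(toward):
            t_half = self._tg[-1]
        else:
            t_half = float(tp[np.argmax(toward)])
        return math.log(2.0) / max(t_half - self.x0_guess, dt)


class PlateauAssociation(_TimeCourseModel):
    """'Plateau followed by one phase association' for upward responses.

    y = y0 for x < x0, else y0 + (plateau - y0) * (1 - e^(-k (x - x0)))

    Used for arrestin-recruitment traces after DeltaF/F normalization and
    inversion (1 - DeltaF/F).  Downward traces must be inverted first.
    """

    results_class = ExpFitResults
    require_direction = "upward"

    def _build_params(self):
        y0, plateau = self._segment_means()
        k0 = self._rate_guess(y0, plateau)
        p = lmfit.Parameters()
        p.add("y0", value=y0)
        p.add("plateau", value=plateau)
        p.add("k", value=k0, min=1e-6)
        p.add("x0", value=self.x0_guess, min=float(self.t[0]), max=float(self.t[-1]))
        return p

    @staticmethod
    def _evaluate(t, v):
        out = np.full_like(t, v["y0"], dtype=float)
        m = t >= v["x0"]
        out[m] = v["y0"] + (v["plateau"] - v["y0"]) * -np.expm1(
            -v["k"] * (t[m] - v["x0"])
        )
        return out


class PlateauDecay(PlateauAssociation):
    """'Plateau followed by one phase decay' for downward responses.

    y = y0 for x < x0, else plateau + (y0 - plateau) * e^(-k (x - x0))

    The association and decay parameterizations are related by inversion of
    the trace; fitting a downward trace here and its inverted counterpart with
    :class:`PlateauAssociation` yields the same rate constant.
    """

    results_class = ExpFitResults
    require_direction = "downward"

    @staticmethod
    def _evaluate(t, v):
        out = np.full_like(t, v["y0"], dtype=float)
        m = t >= v["x0"]
        out[m] = v["plateau"] + (v["y0"] - v["plateau"]) * np.exp(
            -v["k"] * (t[m] - v["x0"])
        )
        return out


class RiseFall(_TimeCourseModel):
    """Rise-and-fall biexponential for transient (DAG/Ca2+-like) responses.

    y = baseline + drift*x                                  for x < x0
    y = baseline + drift*x + C/(K1-K2)(e^(-K2 dx) - e^(-K1 dx)),  dx = x - x0

    ``with_drift`` enables the linear-drift variant used when the late plateau
    sits below the pre-stimulus baseline.  The equation is symmetric under
    exchange of (K1, K2), so the ordering K1 >= K2 is enforced after
    convergence by relabeling.  If the fit lands on the K1 = K2 degeneracy it
    is re-run on the analytic limit branch C * dx * e^(-K dx).
    """

    results_class = RiseFallResults
    require_direction = "upward"

    def __init__(self, data, with_drift: bool = False):
        super().__init__(data)
        self.with_drift = bool(with_drift)

    def _build_params(self, degenerate: bool = False, split: float = 4.0):
        baseline, _ = self._segment_means()
        post = self._tg > self.x0_guess
        if np.any(post):
            peak = float(np.max(self._yg[post]))
        else:
            peak = float(np.max(self._yg))
        amp = max(peak - baseline, 1e-6)
        ks = self._rate_guess(baseline, peak)
        p = lmfit.Parameters()
        p.add("baseline", value=baseline)
        p.add("x0", value=self.x0_guess, min=float(self.t[0]), max=float(self.t[-1]))
        p.add("drift", value=0.0, vary=self.with_drift)
        if degenerate:
            p.add("c", value=amp * ks * math.e, min=0.0)
            p.add("k", value=ks, min=1e-6)
        else:
            k1, k2 = split * ks, ks / split
            p.add("c", value=1.2 * amp * k1, min=0.0)
            p.add("k1", value=k1, min=1e-6)
            p.add("k2", value=k2, min=1e-6)
        return p

    @staticmethod
    def _core(dx, v):
        if "k" in v:  # degenerate branch
            return v["c"] * dx * np.exp(-v["k"] * dx)
        return v["c"] / (v["k1"] - v["k2"]) * (
            np.exp(-v["k2"] * dx) - np.exp(-v["k1"] * dx)
        )

    @classmethod
    def _evaluate(cls, t, v):
        out = np.full_like(t, v["baseline"], dtype=float) + v.get("drift", 0.0) * t
        m = t >= v["x0"]
        out[m] += cls._core(t[m] - v["x0"], v)
        return out

    #: fixed multi-start splits for the k1/k2 seeds around the
    #: single-exponential rate; the lowest-SSR converged fit wins
    START_SPLITS = (4.0, 2.0, 8.0)

    def fit(self):
        mres = None
        for split in self.START_SPLITS:
            try:
                cand = _minimize(self._residual, self._build_params(split=split))
            except FitConvergenceError:
                continue
            if mres is None or cand.chisqr < mres.chisqr:
                mres = cand
        if mres is None:
            raise FitConvergenceError("rise-and-fall fit failed from every start")
        k1, k2 = mres.params["k1"].value, mres.params["k2"].value
        if abs(k1 - k2) < RATE_DEGENERACY_RTOL * max(k1, k2):
            res = self._fit_degenerate()
            return res
        if k1 < k2:  # relabel: the curve is invariant under the exchange
            for a, b in (("k1", "k2"),):
                pa, pb = mres.params[a], mres.params[b]
                pa.value, pb.value = pb.value, pa.value
                pa.stderr, pb.stderr = pb.stderr, pa.stderr
        return self.results_class(self, mres, self.t, self.y)

    def _fit_degenerate(self):
        params = self._build_params(degenerate=True)
        mres = _minimize(self._residual_degenerate, params)
        res = self.results_class(self, mres, self.t, self.y)
        res.degenerate = True
        k = res.params.pop("k")
        se_k = res.se.pop("k")
        res.params["k1"] = res.params["k2"] = k
        res.se["k1"] = res.se["k2"] = se_k
        return res

    def _residual_degenerate(self, params):
        vals = {name: params[name].value for name in params}
        return self._evaluate(self.t, vals) - self.y


class HillCurve:
    """'Log(agonist) vs. response -- Variable slope' sigmoid model.

    y = Bottom + (Top - Bottom) / (1 + 10^((logL50 - log10[A]) * HillSlope))

    ``fix_bottom_at_zero`` constrains Bottom to 0, as used for the k-tau
    analysis where the Plateau x k_obs product is zero at zero occupancy.
    The midpoint is reported as L50 rather than EC50 because for the
    Plateau x k_obs plot it estimates the ligand dissociation constant K_A,
    not a potency.
    """

    results_class = SigmoidResults
    ligand = ""
    conc = None

    def __init__(self, conc, response, fix_bottom_at_zero: bool = False):
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape or conc.ndim != 1:
            raise ValueError("conc and response must be 1-D arrays of equal length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0 (molar) for the log fit")
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if np.ptp(response) == 0:
            raise ValueError("all responses equal: sigmoid unidentifiable")
        self.x = np.log10(conc)
        self.y = response
        self.fix_bottom = bool(fix_bottom_at_zero)
        self.t = self.x  # for CurveResults bookkeeping

    @staticmethod
    def _evaluate_x(x, v):
        return v["bottom"] + (v["top"] - v["bottom"]) / (
            1.0 + 10.0 ** ((v["log_l50"] - x) * v["hill"])
        )

    def _evaluate(self, conc, v):
        return self._evaluate_x(np.log10(np.asarray(conc, dtype=float)), v)

    def _residual(self, params):
        vals = {name: params[name].value for name in params}
        return self._evaluate_x(self.x, vals) - self.y

    def fit(self) -> SigmoidResults:
        top0 = float(np.max(self.y))
        bottom0 = 0.0 if self.fix_bottom else float(np.min(self.y))
        half = 0.5 * (top0 + bottom0)
        x50 = float(self.x[np.argmin(np.abs(self.y - half))])
        p = lmfit.Parameters()
        p.add("bottom", value=bottom0, vary=not self.fix_bottom)
        p.add("top", value=top0)
        p.add("log_l50", value=x50)
        p.add("hill", value=1.0)
        mres = _minimize(self._residual, p)
        return self.results_class(self, mres, self.x, self.y)


class OperationalModel:
    """Operational model of agonism with the system maximum Em held fixed.

    y = Em * rho_A * tau / (1 + rho_A * tau),
    rho_A = [A]^n / (K_A^n + [A]^n)

    Em is supplied externally (conventionally the reference agonist's fitted
    Top at the same time point).  Fits the transducer ratio tau, the agonist
    dissociation constant K_A (via pK_A) and the binding slope n.  A maximal
    observed response at or above Em inflates tau; a warning is attached.
    """

    results_class = OperationalResults
    ligand = ""
    conc = None

    def __init__(self, conc, response, e_m: float):
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape or conc.ndim != 1:
            raise ValueError("conc and response must be 1-D arrays of equal length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0 (molar)")
        if not e_m > 0:
            raise ValueError("e_m must be > 0")
        self.concs = conc
        self.y = response
        self.e_m = float(e_m)
        self.t = conc

    def _evaluate(self, conc, v):
        conc = np.asarray(conc, dtype=float)
        k_a = 10.0 ** -v["p_k_a"]
        cn = np.power(conc, v["n"])
        rho = cn / (k_a ** v["n"] + cn)
        return self.e_m * rho * v["tau"] / (1.0 + rho * v["tau"])

    def _residual(self, params):
        vals = {name: params[name].value for name in params}
        return self._evaluate(self.concs, vals) - self.y

    def fit(self) -> OperationalResults:
        fit_warnings = []
        ymax = float(np.max(self.y))
        if ymax >= self.e_m:
            fit_warnings.append(
                "maximal response >= Em within the data: tau is poorly bounded above"
            )
            tau0 = 10.0
        else:
            tau0 = max(ymax / (self.e_m - ymax), 0.05)
        half = 0.5 * ymax
        ec50 = float(self.concs[np.argmin(np.abs(self.y - half))])
        k_a0 = ec50 * (1.0 + tau0)
        p = lmfit.Parameters()
        p.add("tau", value=tau0, min=1e-6)
        p.add("p_k_a", value=-math.log10(k_a0), min=0.0, max=15.0)
        p.add("n", value=1.0, min=0.1, max=10.0)
        mres = _minimize(self._residual, p)
        return self.results_class(self, mres, self.concs, self.y, fit_warnings)


class GlobalRecruitment:
    """Global fit of the recruitment model to time courses at many concentrations.

    Simultaneously fits (k_tau, c_scale, k_off, pK_A, n) plus one free onset
    time per trace to the concentration-indexed family

        y_i(t) = y0 + rho_n(c_i) k_tau / k_obs(c_i) * (1 - e^(-k_obs(c_i)(t-x0_i)))
        k_obs(c) = rho_n(c) * c_scale + k_off
        rho_n(c) = c^n / (K_A^n + c^n)

    Requires >= 3 distinct concentrations of a single ligand (one
    concentration carries no leverage on K_A or c_scale).  When the fitted
    k_off and c_scale are strongly anti-correlated (|corr| > 0.95) an
    identifiability warning is attached to the results.
    """

    results_class = GlobalResults

    def __init__(self, timecourses: Sequence[TimeCourse]):
        tcs = list(timecourses)
        if not tcs:
            raise ValueError("no time courses given")
        ligands = {tc.ligand for tc in tcs}
        if len(ligands) > 1:
            raise ValueError(f"global fit requires a single ligand, got {ligands}")
        concs = sorted({tc.conc for tc in tcs})
        if len(concs) < 3:
            raise ValueError(
                "global fit needs >= 3 distinct concentrations "
                f"(got {len(concs)}: insufficient concentration leverage)"
            )
        for tc in tcs:
            if tc.direction != "upward":
                raise ValueError("all traces must be upward (invert_downward first)")
        self.traces = tcs
        self.ligand = tcs[0].ligand
        self.conc = None

    def _evaluate_trace(self, t, v, i):
        tc = self.traces[i]
        k_a = 10.0 ** -v["p_k_a"]
        cn = tc.conc ** v["n"]
        rho = cn / (k_a ** v["n"] + cn) if tc.conc > 0 else 0.0
        kobs = rho * v["c_scale"] + v["k_off"]
        x0 = v[f"x0_{i}"]
        out = np.full_like(t, v["y0"], dtype=float)
        m = t >= x0
        if kobs > 0:
            out[m] += rho * v["k_tau"] / kobs * -np.expm1(-kobs * (t[m] - x0))
        else:
            out[m] += rho * v["k_tau"] * (t[m] - x0)
        return out

    def _residual(self, params):
        v = {name: params[name].value for name in params}
        return np.concatenate(
            [
                self._evaluate_trace(tc.times, v, i) - tc.values
                for i, tc in enumerate(self.traces)
            ]
        )

    def fit(self) -> GlobalResults:
        # seed from per-trace single-exponential guesses at the top concentration
        top_conc = max(tc.conc for tc in self.traces)
        top = [tc for tc in self.traces if tc.conc == top_conc]
        plateau0 = float(np.mean([np.mean(tc.values[-max(1, len(tc.values) // 10):])
                                  for tc in top]))
        x0g = [_guess_onset(tc.times, tc.values) for tc in self.traces]
        span = float(np.mean([tc.times[-1] - x for tc, x in zip(top, x0g)]))
        k0 = max(5.0 * math.log(2.0) / span, 0.05)
        p = lmfit.Parameters()
        p.add("k_tau", value=max(plateau0, 1e-3) * k0, min=0.0)
        p.add("c_scale", value=k0, min=1e-6)
        p.add("k_off", value=0.0, min=0.0)
        mid_conc = sorted({tc.conc for tc in self.traces})[len({tc.conc for tc in self.traces}) // 2]
        p.add("p_k_a", value=-math.log10(mid_conc), min=0.0, max=15.0)
        p.add("n", value=1.0, min=0.1, max=10.0)
        p.add("y0", value=0.0)
        for i, tc in enumerate(self.traces):
            p.add(
                f"x0_{i}",
                value=x0g[i],
                min=float(tc.times[0]),
                max=float(tc.times[-1]),
            )
        mres = _minimize(self._residual, p)
        fit_warnings = []
        names = list(mres.var_names)
        covar = getattr(mres, "covar", None)
        if covar is not None and "k_off" in names and "c_scale" in names:
            ia, ib = names.index("k_off"), names.index("c_scale")
            denom = math.sqrt(abs(covar[ia, ia] * covar[ib, ib])) or np.nan
            if np.isfinite(denom) and denom > 0:
                corr = covar[ia, ib] / denom
                if abs(corr) > 0.95:
                    fit_warnings.append(
                        f"k_off and c_scale are strongly correlated (r={corr:.3f}): "
                        "they are not separately identifiable from these data"
                    )
        y_all = np.concatenate([tc.values for tc in self.traces])
        return self.results_class(self, mres, None, y_all, fit_warnings)
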