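"""The k-tau measurement workflows.

k_tau, the initial rate of recruitment/signaling by the agonist-occupied
receptor, equals Plateau x k_obs of the association-exponential fit at a
maximally-effective agonist concentration.  Three routes are provided:

* concentration-response: fit every concentration, plot Plateau x k_obs
  against [A], fit the variable-slope sigmoid with Bottom fixed at 0; k_tau is
  the Top and the ligand dissociation constant K_A is the L50;
* single concentration: Plateau x k_obs at one saturating concentration;
* global: fit the concentration-indexed recruitment model to all traces at
  once, returning k_tau, c_scale, k_off, K_A and the slope together.

For rise-and-fall (G-protein) responses the fitted initial-rate constant C is
itself k_tau.  Efficacy is conventionally reported as percent of a reference
full agonist (mean k_tau of the ligand over mean k_tau of the reference).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datatypes import TimeCourse
from .fitting import (
    ExpFitResults,
    GlobalRecruitment,
    HillCurve,
    RiseFallResults,
)

__all__ = [
    "KtauEstimate",
    "NormalizedKtau",
    "SaturationWarning",
    "ktau_dose_response",
    "ktau_single_conc",
    "ktau_risefall",
    "ktau_global",
    "half_life",
    "normalize_to_reference",
]

#: single-concentration saturation rule: conc must exceed this multiple of K_A
SATURATION_FOLD = 100.0


class SaturationWarning(UserWarning):
    """The concentration used for a single-concentration k-tau estimate may
    not be saturating; Plateau x k_obs then underestimates k_tau by rho_A."""


class IdentifiabilityWarning(UserWarning):
    """A fitted quantity is weakly constrained by the data."""


@dataclass(frozen=True)
class KtauEstimate:
    """A k-tau estimate with provenance.

    k_tau / se are in NFU per minute.  k_a (molar) and p_k_a are present only
    for methods with concentration leverage (dose_response, global).
    """

    k_tau: float
    se: float
    method: str
    ligand: str = ""
    k_a: float | None = None
    p_k_a: float | None = None
    pathway: str = ""
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.k_tau < 0:
            raise ValueError("k_tau must be >= 0")
        if self.k_a is not None:
            pk = -math.log10(self.k_a)
            if self.p_k_a is None:
                object.__setattr__(self, "p_k_a", pk)
            elif abs(self.p_k_a - pk) > 1e-9:
                raise ValueError("p_k_a inconsistent with k_a")


@dataclass(frozen=True)
class NormalizedKtau:
    """k-tau expressed as percent of a reference agonist on one pathway."""

    ligand: str
    pathway: str
    percent_of_reference: float
    reference: str


def _product_se(a, se_a, b, se_b, cov_ab=0.0) -> float:
    """First-order se of a*b with optional covariance."""
    var = (b * se_a) ** 2 + (a * se_b) ** 2 + 2.0 * a * b * cov_ab
    return math.sqrt(max(var, 0.0))


def ktau_dose_response(
    fits: Sequence[ExpFitResults],
    concs: Sequence[float] | None = None,
    ligand: str | None = None,
    pathway: str = "",
) -> KtauEstimate:
    """k-tau from the Plateau x k_obs concentration-response curve.

    Each fit's Plateau x k_obs equals rho_A * k_tau; plotted against
    concentration it traces a sigmoid whose Top is k_tau and whose L50 is K_A.
    Fits carry their concentration metadata when built from TimeCourses;
    otherwise pass ``concs`` explicitly.

    Warns (and reports the largest product as a lower bound) when the sigmoid
    top is weakly constrained, i.e. the tested range does not saturate.
    """
    fits = list(fits)
    if concs is None:
        concs = [f.conc for f in fits]
        if any(c is None for c in concs):
            raise ValueError("fits carry no concentration metadata; pass concs")
    if len(fits) != len(concs):
        raise ValueError("fits and concs length mismatch")
    if len({c for c in concs}) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    products = np.array([f.params["plateau"] * f.params["k"] for f in fits])
    if np.ptp(products) == 0:
        raise ValueError(
            "Plateau x k_obs identical across concentrations: sigmoid degenerate"
        )
    res = HillCurve(np.asarray(concs, float), products, fix_bottom_at_zero=True).fit()
    notes = []
    top, se_top = res.params["top"], res.se["top"]
    if not np.isfinite(se_top) or se_top > 0.5 * abs(top):
        warnings.warn(
            "sigmoid top weakly constrained (no saturation in tested range); "
            "k_tau is effectively a lower bound",
            IdentifiabilityWarning,
            stacklevel=2,
        )
        notes.append("lower bound: top weakly constrained")
    return KtauEstimate(
        k_tau=max(top, 0.0),
        se=se_top if np.isfinite(se_top) else float("nan"),
        method="dose_response",
        ligand=fits[0].ligand if ligand is None else ligand,
        k_a=res.l50,
        pathway=pathway,
        notes=tuple(notes),
    )


def ktau_single_conc(
    fit: ExpFitResults,
    conc: float | None = None,
    k_a_hint: float | None = None,
    pathway: str = "",
) -> KtauEstimate:
    """k-tau = Plateau x k_obs at a single saturating concentration.

    The standard error propagates both parameter uncertainties to first
    order, using their fitted covariance.  If ``k_a_hint`` is supplied and
    the concentration is below ``SATURATION_FOLD`` times it, a
    :class:`SaturationWarning` is issued and noted on the estimate.
    """
    if conc is None:
        conc = fit.conc
    notes = []
    if k_a_hint is not None and conc is not None and conc < SATURATION_FOLD * k_a_hint:
        warnings.warn(
            f"conc {conc:g} M < {SATURATION_FOLD:g} x K_A hint {k_a_hint:g} M: "
            "Plateau x k_obs underestimates k_tau by the occupancy factor",
            SaturationWarning,
            stacklevel=2,
        )
        notes.append("saturation warning: conc < 100 x K_A")
    plateau, k = fit.params["plateau"], fit.params["k"]
    se = _product_se(
        plateau, fit.se["plateau"], k, fit.se["k"], fit.cov_pair("plateau", "k")
    )
    return KtauEstimate(
        k_tau=max(plateau * k, 0.0),
        se=se,
        method="single_conc",
        ligand=fit.ligand,
        pathway=pathway,
        notes=tuple(notes),
    )


def ktau_risefall(fit: RiseFallResults, pathway: str = "") -> KtauEstimate:
    """k-tau for a rise-and-fall response: the fitted initial-rate constant C."""
    return KtauEstimate(
        k_tau=max(fit.params["c"], 0.0),
        se=fit.se["c"],
        method="risefall",
        ligand=fit.ligand,
        pathway=pathway,
    )


def ktau_global(
    timecourses: Sequence[TimeCourse], pathway: str = ""
) -> tuple[KtauEstimate, "GlobalResults"]:
    """k-tau from the global concentration-indexed recruitment fit.

    Returns the estimate together with the full results object (which also
    carries c_scale, k_off, the slope and any identifiability warnings).
    """
    res = GlobalRecruitment(timecourses).fit()
    for msg in res.warnings:
        warnings.warn(msg, IdentifiabilityWarning, stacklevel=2)
    est = KtauEstimate(
        k_tau=max(res.params["k_tau"], 0.0),
        se=res.se["k_tau"],
        method="global",
        ligand=res.ligand,
        k_a=res.k_a,
        pathway=pathway,
        notes=tuple(res.warnings),
    )
    return est, res


def half_life(k: float) -> float:
    """Half-time in seconds from a rate constant in 1/min: 60 * ln2 / k."""
    if not k > 0:
        raise ValueError("k must be > 0 (1/min)")
    return 60.0 * math.log(2.0) / k


def normalize_to_reference(
    estimates: Iterable[KtauEstimate], reference: str
) -> list[NormalizedKtau]:
    """Percent-of-reference efficacy: 100 * mean k_tau(ligand) / mean k_tau(ref).

    Estimates are averaged per ligand (e.g. across experiments) before
    division, so the reference ligand itself maps to exactly 100.  Rounding is
    left to the display layer.
    """
    by_ligand: dict[str, list[KtauEstimate]] = {}
    pathway = ""
    for est in estimates:
        by_ligand.setdefault(est.ligand, []).append(est)
        pathway = pathway or est.pathway
    if reference not in by_ligand:
        raise ValueError(f"reference ligand {reference!r} not among estimates")
    ref_mean = float(np.mean([e.k_tau for e in by_ligand[reference]]))
    if not ref_mean > 0:
        raise ValueError("reference k_tau must be > 0")
    return [
        NormalizedKtau(
            ligand=lig,
            pathway=pathway,
            percent_of_reference=100.0 * float(np.mean([e.k_tau for e in ests])) / ref_mean,
            reference=reference,
        )
        for lig, ests in by_ligand.items()
    ]
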