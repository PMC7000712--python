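"""Kinetic biased-agonism quantification via k-tau ratios.

Bias between two pathways is the ratio of reference-normalized k-tau values:
divide the ligand's percent-of-reference efficacy on pathway A by that on
pathway B.  The reference agonist's ratio is 1 by construction, and because
each pathway is normalized to the same reference within that pathway, the
ratio is invariant to sensor brightness/gain differences between pathways --
the property that makes cross-sensor comparison meaningful.

Responses below the detection limit of a sensor are carried as an explicit
``BELOW_DETECTION`` marker, never as zero, so ratios against them are flagged
("no measurable response") rather than reported as infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pipeline import KtauEstimate

__all__ = ["BELOW_DETECTION", "BiasTable", "bias_ratio", "build_bias_table"]


class _BelowDetection:
    """Sentinel for a pathway response below the sensor's detection limit."""

    def __repr__(self):
        return "BELOW_DETECTION"


BELOW_DETECTION = _BelowDetection()


def bias_ratio(norm_a: float, norm_b) -> float:
    """Ratio of two percent-of-reference k-tau values (pathway A over B).

    Returns NaN (flagged upstream as "no measurable response") when the
    denominator is below detection or zero.
    """
    if norm_b is BELOW_DETECTION or norm_b is None:
        return float("nan")
    if norm_b == 0:
        return float("nan")
    if norm_b < 0:
        raise ValueError("normalized k_tau must be >= 0")
    return float(norm_a) / float(norm_b)


@dataclass(frozen=True)
class BiasTable:
    """Per-ligand normalized k-tau by pathway plus pathway-pair k-tau ratios.

    ``normalized``: {(ligand, pathway): percent or BELOW_DETECTION}
    ``ratios``:     {(ligand, (pathway_a, pathway_b)): ratio (NaN if flagged)}
    ``ratio_se``:   first-order propagated uncertainty of each ratio
    ``flags``:      {(ligand, pair): reason} for undefined ratios
    """

    reference: str
    normalized: dict
    ratios: dict
    ratio_se: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per ligand, normalized columns then ratios."""
        ligands = sorted({lig for lig, _ in self.normalized},
                         key=lambda l: (l != self.reference, l))
        pathways = sorted({p for _, p in self.normalized})
        rows = []
        for lig in ligands:
            row = {"ligand": lig}
            for p in pathways:
                v = self.normalized.get((lig, p))
                row[f"ktau_pct_{p}"] = (
                    np.nan if v is BELOW_DETECTION or v is None else v
                )
            for (l2, pair), r in self.ratios.items():
                if l2 == lig:
                    row[f"ratio_{pair[0]}_over_{pair[1]}"] = r
            rows.append(row)
        return pd.DataFrame(rows)


def _mean_and_se(ests: Sequence[KtauEstimate]) -> tuple[float, float]:
    vals = [e.k_tau for e in ests]
    ses = [e.se for e in ests]
    mean = float(np.mean(vals))
    se = float(np.sqrt(np.nansum(np.square(ses))) / len(ses))
    return mean, se


def build_bias_table(
    estimates: Mapping[tuple[str, str], object],
    reference: str,
    pathway_pairs: Sequence[tuple[str, str]],
) -> BiasTable:
    """Build the kinetic bias table from k-tau estimates per (ligand, pathway).

    ``estimates`` maps (ligand, pathway) to a KtauEstimate, a sequence of them
    (averaged, as for replicate experiments), or ``BELOW_DETECTION``.  The
    reference agonist must be measured on every pathway involved; pathways in
    which it is missing are refused.  Ratio uncertainty is first-order
    propagation of the four standard errors involved.
    """
    pathways = {p for _, p in estimates}
    for pair in pathway_pairs:
        for p in pair:
            if p not in pathways:
                raise ValueError(f"pathway {p!r} has no estimates")
            if (reference, p) not in estimates or estimates[(reference, p)] is BELOW_DETECTION:
                raise ValueError(
                    f"reference {reference!r} not measured in pathway {p!r}"
                )

    # per-pathway normalization to the reference (percent + relative se)
    normalized: dict = {}
    rel_se: dict = {}
    for p in pathways:
        ref_ests = estimates[(reference, p)]
        if isinstance(ref_ests, KtauEstimate):
            ref_ests = [ref_ests]
        ref_mean, ref_se = _mean_and_se(ref_ests)
        if not ref_mean > 0:
            raise ValueError(f"reference k_tau must be > 0 in pathway {p!r}")
        for (lig, p2), val in estimates.items():
            if p2 != p:
                continue
            if val is BELOW_DETECTION:
                normalized[(lig, p)] = BELOW_DETECTION
                continue
            ests = [val] if isinstance(val, KtauEstimate) else list(val)
            mean, se = _mean_and_se(ests)
            pct = 100.0 * mean / ref_mean
            normalized[(lig, p)] = pct
            var = 0.0
            if mean > 0:
                var = (se / mean) ** 2 + (ref_se / ref_mean) ** 2
            rel_se[(lig, p)] = math.sqrt(var)

    ratios: dict = {}
    ratio_se: dict = {}
    flags: dict = {}
    ligands = {lig for lig, _ in estimates}
    for lig in ligands:
        for pair in pathway_pairs:
            pa, pb = pair
            na = normalized.get((lig, pa))
            nb = normalized.get((lig, pb))
            if na is None or nb is None:
                continue
            if nb is BELOW_DETECTION:
                ratios[(lig, pair)] = float("nan")
                flags[(lig, pair)] = f"no measurable response in {pb!r}"
                continue
            if na is BELOW_DETECTION:
                ratios[(lig, pair)] = float("nan")
                flags[(lig, pair)] = f"no measurable response in {pa!r}"
                continue
            r = bias_ratio(na, nb)
            ratios[(lig, pair)] = r
            if np.isnan(r):
                flags[(lig, pair)] = f"no measurable response in {pb!r}"
            else:
                rel = math.hypot(rel_se.get((lig, pa), 0.0), rel_se.get((lig, pb), 0.0))
                ratio_se[(lig, pair)] = r * rel
    return BiasTable(
        reference=reference,
        normalized=normalized,
        ratios=ratios,
        ratio_se=ratio_se,
        flags=flags,
    )
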