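"""Seeded generator of synthetic plate-reader experiments with known ground truth.

The generator emulates what a fluorescence plate reader records in a
biosensor kinetics experiment: a flat pre-addition baseline read at a short
fixed interval (9 s by default), ligand addition with slight well-to-well
timing jitter, then the sensor response -- an association-exponential
recruitment signal or a rise-and-fall biexponential signal -- mapped onto the
sensor's DeltaF/F span by a gain factor, on top of multiplicative Gaussian
read noise with a constant coefficient of variation.

For a downward sensor the raw signal is F0 * (1 - gain * s(t)); for an upward
sensor F0 * (1 + gain * s(t)), where s is the model response in normalized
fluorescence units.  With gain = 1 a saturating recruitment plateau of
~0.44 NFU maps to a DeltaF/F trough of ~0.56, the span observed for
AT1-receptor arrestin traces.

What the generator does NOT emulate: photobleaching, channel bleed-through,
well-edge effects, or any nonlinearity between complex occupancy and
fluorescence quench (the mapping is assumed linear).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Union

import numpy as np

from .datatypes import RawTrace
from .kinetics import (
    ArrestinModelParams,
    OccupancyParams,
    RiseFallParams,
    arrestin_response,
    occupancy,
    risefall_response,
)

__all__ = [
    "LigandSpec",
    "GeneratorScenario",
    "generate_arrestin_plate",
    "generate_risefall_plate",
    "builtin_fixtures",
    "scenario_to_dict",
    "scenario_from_dict",
]

ModelParams = Union[ArrestinModelParams, RiseFallParams]


@dataclass(frozen=True)
class LigandSpec:
    """A ligand and the ground-truth parameters generating its wells.

    For rise-and-fall ligands, ``occupancy`` (optional) scales the initial
    rate C by fractional receptor occupancy at sub-saturating concentrations.
    """

    name: str
    params: ModelParams
    occupancy_params: OccupancyParams | None = None


@dataclass(frozen=True)
class GeneratorScenario:
    """Conditions of a synthetic plate-reader experiment.

    Defaults mirror the study conditions: 9-s read interval, ~1-min baseline
    (7 pre-addition reads), 20-min post-addition window, 3-s addition-time
    jitter, 3% multiplicative read noise, a downward sensor with unit gain,
    and technical duplicates.
    """

    ligands: tuple[LigandSpec, ...]
    concentrations: tuple[float, ...]
    seed: int
    time_step_s: float = 9.0
    duration_min: float = 20.0
    baseline_min: float = 1.05
    jitter_sd_min: float = 0.05
    noise_cv: float = 0.03
    additive_sd: float = 0.0
    direction: str = "downward"
    gain: float = 1.0
    f0: float = 1000.0
    replicates: int = 2
    channel: str = "green"

    def __post_init__(self):
        if not 0.0 <= self.noise_cv <= 0.10:
            raise ValueError("noise_cv must be within [0, 0.10]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        n_baseline = int(np.floor(self.baseline_min / (self.time_step_s / 60.0)))
        if n_baseline < 5:
            raise ValueError("baseline must cover >= 5 pre-addition reads")

    @property
    def time_grid_min(self) -> np.ndarray:
        step = self.time_step_s / 60.0
        n = int(np.floor((self.baseline_min + self.duration_min) / step)) + 1
        return np.arange(n) * step


def _signal(spec: LigandSpec, conc: float, t_post: np.ndarray) -> np.ndarray:
    if isinstance(spec.params, ArrestinModelParams):
        return np.asarray(arrestin_response(t_post, conc, spec.params))
    p = spec.params
    if spec.occupancy_params is not None:
        rho = occupancy(conc, spec.occupancy_params)
        p = replace(p, c=p.c * float(rho))
    return np.asarray(risefall_response(t_post, p)) - p.baseline - p.drift * t_post


def _generate(scenario: GeneratorScenario, kind: str,
              seed: int | None = None) -> list[RawTrace]:
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    times = scenario.time_grid_min
    traces: list[RawTrace] = []
    sign = -1.0 if scenario.direction == "downward" else 1.0
    for spec in scenario.ligands:
        want = ArrestinModelParams if kind == "arrestin" else RiseFallParams
        if not isinstance(spec.params, want):
            raise ValueError(
                f"ligand {spec.name!r} has {type(spec.params).__name__}, "
                f"expected {want.__name__}"
            )
        for conc in scenario.concentrations:
            for rep in range(scenario.replicates):
                jitter = rng.normal(0.0, scenario.jitter_sd_min)
                jitter = float(np.clip(jitter, -2.5 * scenario.jitter_sd_min,
                                       2.5 * scenario.jitter_sd_min))
                x0 = scenario.baseline_min + jitter
                t_post = np.clip(times - x0, 0.0, None)
                s = _signal(spec, conc, t_post)
                if isinstance(spec.params, RiseFallParams):
                    drift = spec.params.drift * np.clip(times - x0, 0.0, None)
                    s = s + drift
                f = scenario.f0 * (1.0 + sign * scenario.gain * s)
                noisy = f * (1.0 + scenario.noise_cv * rng.standard_normal(f.shape))
                if scenario.additive_sd > 0:
                    noisy = noisy + scenario.additive_sd * rng.standard_normal(f.shape)
                traces.append(
                    RawTrace(
                        times=times,
                        raw_fluorescence=noisy,
                        addition_time=scenario.baseline_min,
                        well=f"{spec.name}:{conc:.3g}:{rep}",
                        ligand=spec.name,
                        conc=float(conc),
                        replicate=rep,
                        channel=scenario.channel,
                        direction=scenario.direction,  # type: ignore[arg-type]
                    )
                )
    return traces


def generate_arrestin_plate(scenario: GeneratorScenario,
                            seed: int | None = None) -> list[RawTrace]:
    """Generate raw recruitment traces (association-exponential forward model).

    Deterministic for a fixed seed; ``seed`` overrides the scenario's.
    """
    return _generate(scenario, "arrestin", seed)


def generate_risefall_plate(scenario: GeneratorScenario,
                            seed: int | None = None) -> list[RawTrace]:
    """Generate raw rise-and-fall traces (DAG/Ca2+-like biexponential model)."""
    return _generate(scenario, "risefall", seed)


# ---------------------------------------------------------------------------
# Built-in fixtures: named scenarios with documented ground truth.
# Arrestin parameters follow the AT1-receptor peptide series: the saturating
# k_obs is set from the printed half-times (k_obs = ln2 / t_half), with a
# small arrestin off-rate (k_off = 0.02 / min) so c_scale = k_obs_sat - k_off.
# ---------------------------------------------------------------------------

HALF_LOG_SERIES = (1e-8, 3.2e-8, 1e-7, 3.2e-7, 1e-6, 3.2e-6, 1e-5, 3.2e-5)
SATURATING_CONC = 3.2e-5  # 32 uM

#: small default arrestin-receptor off-rate (1/min); the studied receptors
#: show stable plateaus, implying slow dissociation on the assay timescale
DEFAULT_K_OFF = 0.02


def _arrestin_params(k_tau: float, t_half_s: float, k_a: float,
                     k_off: float = DEFAULT_K_OFF) -> ArrestinModelParams:
    kobs_sat = 60.0 * math.log(2.0) / t_half_s
    return ArrestinModelParams(
        k_tau=k_tau,
        k_off=k_off,
        c_scale=kobs_sat - k_off,
        occupancy=OccupancyParams(k_a=k_a, n=1.0),
    )


ANGII_ARRESTIN = _arrestin_params(k_tau=0.41, t_half_s=45.0, k_a=120e-9)
SII_ARRESTIN = _arrestin_params(k_tau=0.20, t_half_s=84.0, k_a=1100e-9)
TRV055_ARRESTIN = _arrestin_params(k_tau=0.38, t_half_s=45.0, k_a=130e-9)

ANGII_DAG = RiseFallParams(c=1.7, k1=2.0, k2=0.15)
ANGII_CALCIUM = RiseFallParams(c=2.2, k1=3.0, k2=0.5, drift=-0.002)


def builtin_fixtures() -> dict[str, GeneratorScenario]:
    """Named scenarios with documented ground truth.

    * ``angii-arrestin``: full dose-response (10 nM - 32 uM, half-log) with the
      AngII arrestin parameters (k_tau 0.41 NFU/min, K_A 120 nM, saturating
      t_half 45 s), n = 3 replicates, 3% noise.
    * ``angii-arrestin-saturating``: 32 uM only -- the single-concentration
      k_tau workflow.
    * ``sii-arrestin``: half-rate, ~9-fold weaker-affinity partial agonist
      (k_tau 0.20, K_A 1,100 nM, t_half 84 s).
    * ``trv055-arrestin``: near-full agonist (k_tau 0.38, K_A 130 nM).
    * ``angii-dag`` / ``angii-calcium``: rise-and-fall pathways at the
      saturating concentration (C = 1.7 and 2.2 NFU/min; the calcium channel
      uses an upward sensor with a slight negative drift).
    * ``bias-arrestin`` / ``bias-gprotein``: a two-pathway pair with a known
      bias factor of 3 (test ligand at 90% of reference on arrestin, 30% on
      the DAG-kinetics G-protein pathway).
    """
    f: dict[str, GeneratorScenario] = {}
    f["angii-arrestin"] = GeneratorScenario(
        ligands=(LigandSpec("AngII", ANGII_ARRESTIN),),
        concentrations=HALF_LOG_SERIES,
        replicates=3,
        seed=20200204,
    )
    f["angii-arrestin-saturating"] = replace(
        f["angii-arrestin"], concentrations=(SATURATING_CONC,)
    )
    f["sii-arrestin"] = GeneratorScenario(
        ligands=(LigandSpec("SII", SII_ARRESTIN),),
        concentrations=HALF_LOG_SERIES,
        replicates=3,
        seed=20200205,
    )
    f["trv055-arrestin"] = GeneratorScenario(
        ligands=(LigandSpec("TRV055", TRV055_ARRESTIN),),
        concentrations=HALF_LOG_SERIES,
        replicates=3,
        seed=20200206,
    )
    f["angii-dag"] = GeneratorScenario(
        ligands=(LigandSpec("AngII", ANGII_DAG),),
        concentrations=(SATURATING_CONC,),
        replicates=3,
        direction="downward",
        channel="red",
        seed=20200207,
    )
    f["angii-calcium"] = GeneratorScenario(
        ligands=(LigandSpec("AngII", ANGII_CALCIUM),),
        concentrations=(SATURATING_CONC,),
        replicates=3,
        direction="upward",
        channel="red",
        seed=20200208,
    )
    bias_arr = replace(ANGII_ARRESTIN, k_tau=0.9 * ANGII_ARRESTIN.k_tau)
    bias_gq = replace(ANGII_DAG, c=0.3 * ANGII_DAG.c)
    f["bias-arrestin"] = GeneratorScenario(
        ligands=(LigandSpec("AngII", ANGII_ARRESTIN),
                 LigandSpec("TRVX", bias_arr)),
        concentrations=(SATURATING_CONC,),
        replicates=3,
        seed=20200209,
    )
    f["bias-gprotein"] = GeneratorScenario(
        ligands=(LigandSpec("AngII", ANGII_DAG),
                 LigandSpec("TRVX", bias_gq)),
        concentrations=(SATURATING_CONC,),
        replicates=3,
        direction="downward",
        channel="red",
        seed=20200210,
    )
    return f


# --- scenario config serialization ----------------------------------------

def _params_to_dict(params: ModelParams) -> dict:
    if isinstance(params, ArrestinModelParams):
        return {
            "model": "arrestin",
            "k_tau": params.k_tau,
            "k_off": params.k_off,
            "c_scale": params.c_scale,
            "k_a": params.occupancy.k_a,
            "n": params.occupancy.n,
            "scenario": params.scenario,
        }
    return {
        "model": "risefall",
        "c": params.c,
        "k1": params.k1,
        "k2": params.k2,
        "baseline": params.baseline,
        "drift": params.drift,
    }


def _params_from_dict(d: dict) -> ModelParams:
    d = dict(d)
    kind = d.pop("model")
    if kind == "arrestin":
        return ArrestinModelParams(
            k_tau=d["k_tau"], k_off=d["k_off"], c_scale=d["c_scale"],
            occupancy=OccupancyParams(k_a=d["k_a"], n=d.get("n", 1.0)),
            scenario=d.get("scenario", "receptor_excess"),
        )
    if kind == "risefall":
        return RiseFallParams(**d)
    raise ValueError(f"unknown model kind {kind!r}")


def scenario_to_dict(scenario: GeneratorScenario) -> dict:
    """Structured key-value form of a scenario, suitable for a JSON config."""
    d = {
        f.name: getattr(scenario, f.name)
        for f in fields(scenario)
        if f.name not in ("ligands", "concentrations")
    }
    d["concentrations"] = list(scenario.concentrations)
    d["ligands"] = [
        {
            "name": spec.name,
            "params": _params_to_dict(spec.params),
            **(
                {"occupancy": {"k_a": spec.occupancy_params.k_a,
                               "n": spec.occupancy_params.n}}
                if spec.occupancy_params is not None else {}
            ),
        }
        for spec in scenario.ligands
    ]
    return d


def scenario_from_dict(d: dict) -> GeneratorScenario:
    """Inverse of :func:`scenario_to_dict`."""
    d = dict(d)
    ligands = tuple(
        LigandSpec(
            name=item["name"],
            params=_params_from_dict(item["params"]),
            occupancy_params=(
                OccupancyParams(**item["occupancy"]) if "occupancy" in item else None
            ),
        )
        for item in d.pop("ligands")
    )
    concentrations = tuple(d.pop("concentrations"))
    return GeneratorScenario(ligands=ligands, concentrations=concentrations, **d)
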