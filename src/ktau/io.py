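"""Plate-file reading/writing and structured result serialization.

Plate files are long-format delimited text, one row per (time, well)
observation.  Times are stored in seconds (plate readers report seconds) and
converted to minutes on read; concentrations are molar.

Required columns:
    time_s, well, ligand, conc_molar, replicate, channel, direction, fluorescence
Optional:
    addition_time_s (defaults to 60 s when absent)

Results files are JSON documents that round-trip the package's record types
losslessly and carry the tool version, the input checksum and the seed, so a
pipeline run is fully reproducible from (input, config, seed, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import BELOW_DETECTION, BiasTable
from .datatypes import RawTrace
from .pipeline import KtauEstimate, NormalizedKtau
from .qc import EndpointDR

__all__ = [
    "PLATE_COLUMNS",
    "read_plate",
    "write_plate",
    "write_results",
    "read_results",
    "file_checksum",
    "PlateFormatError",
]

PLATE_COLUMNS = [
    "time_s",
    "well",
    "ligand",
    "conc_molar",
    "replicate",
    "channel",
    "direction",
    "fluorescence",
]
DEFAULT_ADDITION_TIME_S = 60.0


class PlateFormatError(ValueError):
    """A plate file violates the schema; the message lists the offending rows."""


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_plate(traces: list[RawTrace], path) -> None:
    """Write traces as a long-format plate CSV (times in seconds)."""
    rows = []
    for tr in traces:
        for t, f in zip(tr.times, tr.raw_fluorescence):
            rows.append(
                {
                    "time_s": t * 60.0,
                    "well": tr.well,
                    "ligand": tr.ligand,
                    "conc_molar": tr.conc,
                    "replicate": tr.replicate,
                    "channel": tr.channel,
                    "direction": tr.direction,
                    "fluorescence": f,
                    "addition_time_s": tr.addition_time * 60.0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate(path) -> list[RawTrace]:
    """Read and validate a plate file; returns traces grouped by well.

    Malformed content (missing columns, non-numeric cells, non-monotone or
    duplicate times within a well) raises :class:`PlateFormatError` naming the
    offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing required column(s): {', '.join(missing)}")
    problems = []
    for col in ("time_s", "conc_molar", "fluorescence"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad[:20]:
            problems.append(f"row {i + 1}: non-numeric {col} ({df[col][i]!r})")
        bad_na = df.index[df[col].isna()]
        for i in bad_na[:20]:
            problems.append(f"row {i + 1}: missing {col}")
        df[col] = coerced
    if problems:
        raise PlateFormatError("malformed plate file:\n  " + "\n  ".join(problems))
    if "addition_time_s" not in df.columns:
        df["addition_time_s"] = DEFAULT_ADDITION_TIME_S

    traces = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.reset_index()
        t = grp["time_s"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            rows = ", ".join(str(grp["index"][i] + 1) for i in dup[:10])
            raise PlateFormatError(f"duplicate (time, well) in well {well!r}: rows {rows}")
        if np.any(np.diff(t) < 0):
            raise PlateFormatError(
                f"times not increasing within well {well!r} "
                "(plate files must be sorted per well)"
            )
        first = grp.iloc[0]
        traces.append(
            RawTrace(
                times=t / 60.0,
                raw_fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                addition_time=float(first["addition_time_s"]) / 60.0,
                well=str(well),
                ligand=str(first["ligand"]),
                conc=float(first["conc_molar"]),
                replicate=int(first["replicate"]),
                channel=str(first["channel"]),
                direction=str(first["direction"]),  # type: ignore[arg-type]
            )
        )
    return traces


# --- structured results ----------------------------------------------------

_RECORD_TYPES = {
    "KtauEstimate": KtauEstimate,
    "NormalizedKtau": NormalizedKtau,
    "EndpointDR": EndpointDR,
}


def _encode(obj):
    if obj is BELOW_DETECTION:
        return {"__type__": "below_detection"}
    if isinstance(obj, BiasTable):
        return {
            "__type__": "BiasTable",
            "reference": obj.reference,
            "normalized": [
                [lig, p, _encode(v)] for (lig, p), v in obj.normalized.items()
            ],
            "ratios": [
                [lig, list(pair), _encode(v)] for (lig, pair), v in obj.ratios.items()
            ],
            "ratio_se": [
                [lig, list(pair), _encode(v)] for (lig, pair), v in obj.ratio_se.items()
            ],
            "flags": [
                [lig, list(pair), v] for (lig, pair), v in obj.flags.items()
            ],
        }
    if isinstance(obj, EndpointDR):
        d = dataclasses.asdict(obj)
        d.pop("fit", None)
        return {"__type__": "EndpointDR", **_encode(d)}
    if dataclasses.is_dataclass(obj) and type(obj).__name__ in _RECORD_TYPES:
        return {"__type__": type(obj).__name__, **_encode(dataclasses.asdict(obj))}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return {"__type__": "float", "repr": repr(obj)}
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        tag = obj.get("__type__")
        if tag == "below_detection":
            return BELOW_DETECTION
        if tag == "float":
            return float(obj["repr"])
        if tag == "BiasTable":
            return BiasTable(
                reference=obj["reference"],
                normalized={(l, p): _decode(v) for l, p, v in obj["normalized"]},
                ratios={(l, tuple(pr)): _decode(v) for l, pr, v in obj["ratios"]},
                ratio_se={(l, tuple(pr)): _decode(v) for l, pr, v in obj["ratio_se"]},
                flags={(l, tuple(pr)): v for l, pr, v in obj["flags"]},
            )
        if tag in _RECORD_TYPES:
            fields = {k: _decode(v) for k, v in obj.items() if k != "__type__"}
            if tag == "KtauEstimate" and isinstance(fields.get("notes"), list):
                fields["notes"] = tuple(fields["notes"])
            if tag == "EndpointDR":
                fields.pop("fit", None)
            return _RECORD_TYPES[tag](**fields)
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_results(path, results: dict, seed: int | None = None,
                  input_path=None) -> None:
    """Serialize a results tree (records, tables, scalars) with provenance."""
    from . import __version__

    envelope = {
        "tool": "ktau",
        "version": __version__,
        "seed": seed,
        "input_checksum": file_checksum(input_path) if input_path else None,
        "results": _encode(results),
    }
    Path(path).write_text(json.dumps(envelope, indent=2, allow_nan=False) + "\n")


def read_results(path) -> dict:
    """Read a results file back; record types are reconstructed losslessly."""
    envelope = json.loads(Path(path).read_text())
    envelope["results"] = _decode(envelope["results"])
    return envelope
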