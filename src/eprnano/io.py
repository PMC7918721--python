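"""File I/O: two-column ASCII spectra with JSON sidecars, and JSON
serialization of solution clouds, GHOST results and comparison tables.

Spectrum dialect: two whitespace- or comma-separated numeric columns
(field [mT], intensity), '#'-prefixed header lines ignored. Instrument
settings travel in a ``<name>.json`` sidecar next to the data file. All
artifact writers are deterministic (sorted keys, fixed float repr, no
timestamps) so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .fitting import FitBounds, FitSolution, SolutionCloud
from .ghost import GhostGroup, GhostResult
from .spin_model import (
    DomainParams,
    SpectrometerSettings,
    Spectrum,
    ValidationError,
)

__all__ = [
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "sidecar_path",
    "cloud_to_dict",
    "cloud_from_dict",
    "save_cloud",
    "load_cloud",
    "ghost_result_to_dict",
    "save_ghost_result",
    "save_json",
]

SCHEMA_VERSION = 1


class SpectrumParseError(ValueError):
    """Raised with a line number when a spectrum file cannot be parsed."""


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def read_spectrum(path: str | Path, dialect: str = "auto") -> Spectrum:
    """Read a two-column ASCII spectrum (+ optional JSON sidecar).

    ``dialect``: "ascii2col" (whitespace), "csv" (comma) or "auto".
    """
    path = Path(path)
    if dialect not in ("auto", "ascii2col", "csv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    field = []
    intensity = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "csv" or (dialect == "auto" and "," in line):
                parts = [p for p in line.split(",") if p.strip()]
            else:
                parts = line.split()
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                field.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric value ({exc})") from None
    if len(field) < 128:
        raise SpectrumParseError(
            f"{path}: only {len(field)} data rows (need >= 128)")
    field_arr = np.array(field)
    if not np.all(np.diff(field_arr) > 0):
        bad = int(np.argmin(np.diff(field_arr) > 0)) + 2
        raise SpectrumParseError(
            f"{path}: field not strictly increasing near data row {bad}")
    settings = SpectrometerSettings()
    provenance = {"source": str(path)}
    sc = sidecar_path(path)
    if sc.exists() and sc != path:
        meta = json.loads(sc.read_text())
        settings_kw = {k: meta[k] for k in (
            "microwave_frequency", "center_field", "sweep_width", "n_points",
            "modulation_amplitude", "temperature") if k in meta}
        settings = SpectrometerSettings(**settings_kw)
        provenance.update(meta.get("provenance", {}))
    return Spectrum(field=field_arr, intensity=np.array(intensity),
                    settings=settings, provenance=provenance)


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   dialect: str = "ascii2col") -> None:
    """Write the ASCII dialect plus the JSON settings sidecar."""
    path = Path(path)
    sep = {"ascii2col": "  ", "csv": ","}.get(dialect)
    if sep is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    lines = ["# field_mT{0}intensity".format(sep if dialect == "csv" else "  ")]
    for b, y in zip(spectrum.field, spectrum.intensity):
        lines.append(f"{float(b)!r}{sep}{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")
    meta = asdict(spectrum.settings)
    meta["provenance"] = _jsonable(spectrum.provenance)
    save_json(meta, sidecar_path(path))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_json(data: dict, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, no timestamps)."""
    Path(path).write_text(
        json.dumps(_jsonable(data), indent=1, sort_keys=True) + "\n")


def cloud_to_dict(cloud: SolutionCloud) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "spectrum_id": cloud.spectrum_id,
        "k": cloud.k,
        "bounds": cloud.bounds.to_dict(),
        "solutions": [
            {"chi2": s.chi2, "seed": s.seed, "n_evals": s.n_evals,
             "domains": [[d.S, d.tau_c, d.pA, d.pg, d.W, d.d]
                         for d in s.domains]}
            for s in cloud.solutions
        ],
    }


def cloud_from_dict(data: dict) -> SolutionCloud:
    solutions = [
        FitSolution(
            domains=[DomainParams(S=r[0], tau_c=r[1], pA=r[2], pg=r[3],
                                  W=r[4], d=r[5]) for r in s["domains"]],
            chi2=s["chi2"], seed=s["seed"], n_evals=s["n_evals"])
        for s in data["solutions"]
    ]
    return SolutionCloud(solutions=solutions,
                         spectrum_id=data.get("spectrum_id", ""),
                         bounds=FitBounds.from_dict(data["bounds"]),
                         k=data.get("k", 0))


def save_cloud(cloud: SolutionCloud, path: str | Path) -> None:
    save_json(cloud_to_dict(cloud), path)


def load_cloud(path: str | Path) -> SolutionCloud:
    return cloud_from_dict(json.loads(Path(path).read_text()))


def _group_to_dict(g: GhostGroup) -> dict:
    return {"label": g.label, "n_members": g.n_members, "mean": g.mean,
            "stderr": _jsonable(g.stderr),
            "proportion_pct": g.proportion_pct,
            "member_indices": g.member_indices,
            "hulls": _jsonable(g.hulls),
            "errors_defined": g.errors_defined}


def ghost_result_to_dict(result: GhostResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "config": result.config.to_dict(),
        "n_runs_total": result.n_runs_total,
        "n_runs_kept": result.n_runs_kept,
        "n_points_retained": len(result.points),
        "groups": [_group_to_dict(g) for g in result.groups],
    }


def save_ghost_result(result: GhostResult, path: str | Path) -> None:
    save_json(ghost_result_to_dict(result), path)
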