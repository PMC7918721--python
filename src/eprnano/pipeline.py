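"""Declarative pipeline configuration and orchestration.

A :class:`PipelineConfig` fully determines one analysis: the input
spectrum (a file or a synthetic preset), the fit scale, the condensation
thresholds and the output directory. ``run_pipeline`` executes
generate/read -> multi-run HEO -> GHOST -> (optionally) condition
comparison, writing deterministic JSON/CSV artifacts stamped with the
config hash and package version.

Seed fan-out: one global ``seed`` S determines every stage —
noise generation uses S, the HEO multi-run uses base seed S * 1000, and
replicate r of a condition uses S + r (its fit then S*1000 + r*10000).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .fitting import FitBounds, HeoConfig
from .ghost import AXIS_PAIRS, GhostConfig
from .io import (
    ghost_result_to_dict,
    read_spectrum,
    save_cloud,
    save_json,
    write_spectrum,
)
from .model import SpectralModel
from .spin_model import ValidationError
from .stats import ConditionResult, compare_conditions
from .synthetic import NoiseModel, generate, make_preset

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Validated, file-round-trippable pipeline configuration."""

    seed: int = 0
    k: int = Field(default=3, ge=1, le=5)
    n_runs: int = Field(default=200, ge=1)
    out_dir: str = "eprnano_out"
    # input: either a spectrum file or a synthetic preset
    spectrum: str | None = None
    preset: str | None = None
    snr: float = Field(default=50.0, gt=0)
    # stage parameter overrides (validated on construction below)
    heo: dict = Field(default_factory=dict)
    ghost: dict = Field(default_factory=dict)
    bounds: dict = Field(default_factory=dict)
    # optional condition comparison: replicate spectrum files per side
    condition_spectra: list[str] = Field(default_factory=list)
    control_spectra: list[str] = Field(default_factory=list)
    render_diagrams: bool = True

    @field_validator("heo")
    @classmethod
    def _check_heo(cls, v: dict) -> dict:
        HeoConfig(**v)
        return v

    @field_validator("ghost")
    @classmethod
    def _check_ghost(cls, v: dict) -> dict:
        GhostConfig(**v)
        return v

    @field_validator("bounds")
    @classmethod
    def _check_bounds(cls, v: dict) -> dict:
        FitBounds(**{k: tuple(val) for k, val in v.items()})
        return v

    def heo_config(self) -> HeoConfig:
        return HeoConfig(**self.heo)

    def ghost_config(self) -> GhostConfig:
        return GhostConfig(**self.ghost)

    def fit_bounds(self) -> FitBounds:
        return FitBounds(**{k: tuple(v) for k, v in self.bounds.items()})

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (output locations and
        rendering toggles excluded)."""
        data = self.model_dump(exclude={"out_dir", "render_diagrams"})
        blob = json.dumps(data, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return PipelineConfig(**data)


def _input_spectrum(config: PipelineConfig, seed: int, out_dir: Path):
    if config.spectrum:
        return read_spectrum(config.spectrum)
    if config.preset:
        preset = make_preset(config.preset)
        spec = generate(preset, NoiseModel(snr=config.snr, seed=seed))
        write_spectrum(spec, out_dir / "input_spectrum.txt")
        return spec
    raise ValidationError("config needs either 'spectrum' or 'preset'")


def _analyze_one(spectrum, config: PipelineConfig, base_seed: int):
    model = SpectralModel(spectrum, k=config.k, bounds=config.fit_bounds(),
                          config=config.heo_config())
    t0 = time.perf_counter()
    results = model.fit_multirun(n_runs=config.n_runs, base_seed=base_seed)
    log.info("multi-run fit: %d runs in %.1f s", config.n_runs,
             time.perf_counter() - t0)
    condensed = results.condense(config.ghost_config())
    log.info("GHOST: kept %d/%d runs, %d points, %d groups",
             condensed.result.n_runs_kept, condensed.result.n_runs_total,
             len(condensed.result.points), condensed.n_groups)
    return results, condensed


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis; returns artifact paths.

    Deterministic given the config (timestamps are logged, never
    written into artifacts).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "version": __version__}
    artifacts: dict[str, str] = {}

    def emit(name: str, data: dict) -> None:
        path = out_dir / name
        save_json({**data, "stamp": stamp}, path)
        artifacts[name] = str(path)

    try:
        spectrum = _input_spectrum(config, config.seed, out_dir)
        results, condensed = _analyze_one(spectrum, config,
                                          config.seed * 1000)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit+ghost' failed: {exc}") from exc
    save_cloud(results.cloud, out_dir / "cloud.json")
    artifacts["cloud.json"] = str(out_dir / "cloud.json")
    emit("groups.json", ghost_result_to_dict(condensed.result))
    for pair in AXIS_PAIRS:
        dia = condensed.diagram(pair)
        rows = np.column_stack([dia.x, dia.y, dia.colors])
        name = f"diagram_{pair.replace('-', '_')}.csv"
        header = f"{pair.split('-')[0]},{pair.split('-')[1]},r,g,b"
        np.savetxt(out_dir / name, rows, delimiter=",", header=header,
                   comments="")
        artifacts[name] = str(out_dir / name)
        if config.render_diagrams:
            import matplotlib
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt
            ax = condensed.plot_diagram(pair)
            png = out_dir / f"diagram_{pair.replace('-', '_')}.png"
            ax.figure.savefig(png, dpi=120)
            plt.close(ax.figure)
            artifacts[png.name] = str(png)

    if config.condition_spectra and config.control_spectra:
        try:
            table = _comparison(config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'compare' failed: {exc}") from exc
        path = out_dir / "comparison.csv"
        table.to_csv(path, index=False)
        artifacts["comparison.csv"] = str(path)
    return artifacts


def _comparison(config: PipelineConfig):
    sides = []
    for label, files in (("condition", config.condition_spectra),
                         ("control", config.control_spectra)):
        reps = []
        for r, path in enumerate(files):
            spec = read_spectrum(path)
            _, condensed = _analyze_one(
                spec, config, config.seed * 1000 + (r + 1) * 10000)
            reps.append(ConditionResult(condition=label, replicate=r,
                                        groups=condensed.groups))
        sides.append(reps)
    return compare_conditions(sides[0], sides[1])
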