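"""Model/Results front end for the fit-and-condense pipeline.

Usage parallels the statsmodels idiom: build a :class:`SpectralModel`
from a measured (or synthetic) spectrum, call :meth:`SpectralModel.fit`
for a single HEO run or :meth:`SpectralModel.fit_multirun` for the
full multi-run analysis, then :meth:`MultiRunResults.condense` for the
GHOST domain groups and ``summary()`` for a report table.

    >>> model = SpectralModel(spectrum, k=3)
    >>> results = model.fit_multirun(n_runs=200, base_seed=1)
    >>> ghost = results.condense()
    >>> print(ghost.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import DEFAULT_KAPPA
from .fitting import (
    FitBounds,
    FitSolution,
    HeoConfig,
    SolutionCloud,
    heo_run,
    multi_run,
)
from .ghost import GhostConfig, GhostResult, condense, make_diagram
from .spin_model import (
    DomainParams,
    MagneticTensors,
    Spectrum,
    simulate_spectrum,
)

__all__ = ["SpectralModel", "SingleRunResults", "MultiRunResults",
           "CondensedResults"]


class SpectralModel:
    """K-component nitroxide lineshape model bound to one spectrum.

    Parameters
    ----------
    spectrum : Spectrum
        The measured first-derivative spectrum.
    k : int
        Number of domain components (default 3).
    bounds, tensors, config : optional
        Search bounds, rigid-limit magnetic tensors, and HEO
        hyperparameters; package defaults if omitted.
    """

    def __init__(self, spectrum: Spectrum, k: int = 3,
                 bounds: FitBounds | None = None,
                 tensors: MagneticTensors | None = None,
                 config: HeoConfig | None = None,
                 kappa: float = DEFAULT_KAPPA):
        self.spectrum = spectrum
        self.k = k
        self.bounds = bounds or FitBounds()
        self.tensors = tensors or MagneticTensors()
        self.config = config or HeoConfig()
        self.kappa = kappa

    @classmethod
    def from_file(cls, path, **kw) -> "SpectralModel":
        from .io import read_spectrum
        return cls(read_spectrum(path), **kw)

    def simulate(self, domains: list[DomainParams],
                 n_theta: int = 64) -> Spectrum:
        """Forward spectrum for explicit domain parameters."""
        return simulate_spectrum(domains, self.tensors,
                                 self.spectrum.settings, n_theta=n_theta,
                                 kappa=self.kappa)

    def fit(self, seed: int = 0) -> "SingleRunResults":
        """One seeded HEO run (GA + simplex)."""
        sol = heo_run(self.spectrum, k=self.k, bounds=self.bounds, seed=seed,
                      config=self.config, tensors=self.tensors,
                      kappa=self.kappa)
        return SingleRunResults(self, sol)

    def fit_multirun(self, n_runs: int = 200,
                     base_seed: int = 0) -> "MultiRunResults":
        """The full multi-run HEO analysis (default 200 runs)."""
        cloud = multi_run(self.spectrum, k=self.k, bounds=self.bounds,
                          n_runs=n_runs, base_seed=base_seed,
                          config=self.config, tensors=self.tensors,
                          kappa=self.kappa,
                          spectrum_id=str(self.spectrum.provenance.get(
                              "preset", "")))
        return MultiRunResults(self, cloud)


class SingleRunResults:
    """Estimates of one HEO run."""

    def __init__(self, model: SpectralModel, solution: FitSolution):
        self.model = model
        self.solution = solution
        self.chi2 = solution.chi2

    @property
    def domains(self) -> list[DomainParams]:
        return self.solution.domains

    def fitted_spectrum(self) -> Spectrum:
        return self.model.simulate(self.domains)

    def summary(self) -> pd.DataFrame:
        rows = [{"component": i + 1, "S": d.S, "tau_c_ns": d.tau_c,
                 "pA": d.pA, "pg": d.pg, "W_mT": d.W, "d": d.d}
                for i, d in enumerate(self.domains)]
        return pd.DataFrame(rows)


class MultiRunResults:
    """Solution cloud of a multi-run HEO fit."""

    def __init__(self, model: SpectralModel, cloud: SolutionCloud):
        self.model = model
        self.cloud = cloud

    @property
    def n_runs(self) -> int:
        return len(self.cloud)

    def best(self) -> SingleRunResults:
        idx = int(np.argmin(self.cloud.chi2_values()))
        return SingleRunResults(self.model, self.cloud.solutions[idx])

    def condense(self, config: GhostConfig | None = None) -> "CondensedResults":
        """GHOST condensation of the cloud into domain groups."""
        return CondensedResults(self, condense(self.cloud, config))

    def save(self, path) -> None:
        from .io import save_cloud
        save_cloud(self.cloud, path)


class CondensedResults:
    """GHOST domain groups with summaries, diagrams and plotting."""

    def __init__(self, multirun: MultiRunResults, result: GhostResult):
        self.multirun = multirun
        self.result = result

    @property
    def groups(self):
        return self.result.groups

    @property
    def n_groups(self) -> int:
        return len(self.result.groups)

    def group_by_rank(self, rank: int):
        """1-based domain label (1 = highest order parameter)."""
        return self.result.groups[rank - 1]

    def diagram(self, axis_pair: str = "S-tau_c"):
        return make_diagram(self.result.points, axis_pair)

    def summary(self) -> pd.DataFrame:
        """One row per domain group: means, standard errors, proportion."""
        rows = []
        for g in self.result.groups:
            rows.append({
                "domain": g.label, "n_members": g.n_members,
                "S": g.mean["S"], "S_se": g.stderr["S"],
                "tau_c_ns": g.mean["tau_c"], "tau_c_se": g.stderr["tau_c"],
                "pA": g.mean["pA"], "pA_se": g.stderr["pA"],
                "W_mT": g.mean["W"], "W_se": g.stderr["W"],
                "proportion_pct": g.proportion_pct,
            })
        return pd.DataFrame(rows)

    def plot_diagram(self, axis_pair: str = "S-tau_c", ax=None):
        from .plotting import plot_ghost_diagram
        return plot_ghost_diagram(self, axis_pair=axis_pair, ax=ax)

    def save(self, path) -> None:
        from .io import save_ghost_result
        save_ghost_result(self.result, path)
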