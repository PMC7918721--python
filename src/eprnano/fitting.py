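"""Hybrid evolutionary optimization (HEO) of multi-component spectra.

A real-coded genetic algorithm performs the global search over the
K x (S, tau_c, pA, pg, W) parameter space and Nelder-Mead downhill
simplex refines the best individual. Because the lineshape model is
strongly multimodal in the component assignment, a single run is only one
draw from the solution distribution; the intended usage is
:func:`multi_run`, whose solution cloud is condensed by the GHOST
procedure (:mod:`eprnano.ghost`).

Three implementation choices matter for convergence and are documented in
docs/methods.md:

* the spectrum is linear in the proportions d, so d is solved exactly by
  non-negative least squares at every objective evaluation (variable
  projection) and renormalized to sum(d) = 1, instead of being searched;
* every genome keeps its components sorted by descending S (canonical
  ordering), which removes the K! label symmetry that otherwise makes
  crossover destructive;
* after the simplex refinement, "split" moves re-start the simplex from
  candidates in which the largest-proportion component is split in two,
  the standard escape from merged-component local minima of mixture fits.

The global phase runs on a decimated field grid; the final refinement and
the reported chi-square always use the full grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
from scipy.optimize import minimize, nnls

from . import _kernels
from .constants import DEFAULT_KAPPA
from .spin_model import (
    DomainParams,
    MagneticTensors,
    Spectrum,
    ValidationError,
    _CONE_CA,
    _CONE_W,
    _CONE_X,
    _powder_nodes,
)

__all__ = [
    "FitBounds",
    "HeoConfig",
    "FitSolution",
    "SolutionCloud",
    "chi_square",
    "estimate_noise_sd",
    "heo_run",
    "multi_run",
]

log = logging.getLogger(__name__)

PARAM_NAMES = ("S", "tau_c", "pA", "pg", "W", "d")

#: relative floor on the estimated noise sd (units of the normalized
#: amplitude); keeps chi-square finite on noise-free synthetic spectra
NOISE_SD_FLOOR = 1e-4


@dataclass(frozen=True)
class FitBounds:
    """Per-parameter box bounds of the search space.

    Defaults: S in [0,1], tau_c in [0.05, 5] ns, pA in [0.85, 1.15],
    pg in [0.999, 1.001] (g shifts are tiny at X-band), W in [0, 0.5] mT,
    d in [0, 1].
    """

    S: tuple[float, float] = (0.0, 1.0)
    tau_c: tuple[float, float] = (0.05, 5.0)
    pA: tuple[float, float] = (0.85, 1.15)
    pg: tuple[float, float] = (0.999, 1.001)
    W: tuple[float, float] = (0.0, 0.5)
    d: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"bounds for {name}: need lower < upper")

    @property
    def lower(self) -> np.ndarray:
        """Lower bounds in (S, tau_c, pA, pg, W, d) order."""
        return np.array([getattr(self, n)[0] for n in PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in PARAM_NAMES])

    def to_dict(self) -> dict:
        return {n: list(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "FitBounds":
        return cls(**{k: tuple(v) for k, v in d.items()})


@dataclass(frozen=True)
class HeoConfig:
    """GA + simplex hyperparameters (see module docstring).

    ``ga_stride``/``nm_stride`` decimate the field grid during the global
    and intermediate phases (1 = full resolution). ``chi2_floor`` is the
    goodness-of-fit level below which a noise-free fit is considered
    converged (diagnostic only).
    """

    population: int = 36
    generations: int = 60
    tournament: int = 3
    crossover_prob: float = 0.9
    blend_alpha: float = 0.5
    row_swap_prob: float = 0.5
    mutation_prob: float = 0.2
    mutation_sd_frac: float = 0.05
    elitism: int = 2
    immigrant_fraction: float = 0.25
    immigrant_every: int = 10
    ga_stride: int = 4
    nm_stride: int = 2
    nm_maxfev_mid: int = 2500
    nm_maxfev_fine: int = 800
    split_deltas: tuple[float, ...] = (0.07, 0.12)
    split_maxfev: int = 1200
    #: (dS, tau factor) restart kicks applied to the lowest-S component
    nudge_moves: tuple[tuple[float, float], ...] = ((0.12, 0.4), (-0.12, 2.5))
    chi2_floor: float = 10.0

    def __post_init__(self) -> None:
        if self.population < 4 or self.generations < 1:
            raise ValidationError("population >= 4 and generations >= 1 required")
        if self.ga_stride < 1 or self.nm_stride < 1:
            raise ValidationError("grid strides must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def fast(cls) -> "HeoConfig":
        """Reduced-effort profile for quick exploratory fits and tests."""
        return cls(population=24, generations=30, nm_maxfev_mid=1200,
                   nm_maxfev_fine=400, split_maxfev=800)


@dataclass
class FitSolution:
    """One HEO run's best K-component parameter set."""

    domains: list[DomainParams]
    chi2: float
    seed: int
    n_evals: int

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValidationError("chi2 must be >= 0")
        total = sum(d.d for d in self.domains)
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"solution proportions sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        """(K, 6) array of (S, tau_c, pA, pg, W, d) rows."""
        return np.array([[d.S, d.tau_c, d.pA, d.pg, d.W, d.d]
                         for d in self.domains])


@dataclass
class SolutionCloud:
    """All solutions of a multi-run HEO fit of one spectrum."""

    solutions: list[FitSolution]
    spectrum_id: str = ""
    bounds: FitBounds = dc_field(default_factory=FitBounds)
    k: int = 0

    def __post_init__(self) -> None:
        if self.solutions:
            ks = {len(s.domains) for s in self.solutions}
            if len(ks) != 1:
                raise ValidationError(f"mixed component counts in cloud: {ks}")
            if not self.k:
                self.k = ks.pop()

    def chi2_values(self) -> np.ndarray:
        return np.array([s.chi2 for s in self.solutions])

    def __len__(self) -> int:
        return len(self.solutions)


def estimate_noise_sd(spectrum: Spectrum, tail_fraction: float = 0.05) -> float:
    """Noise sd from the outer ``tail_fraction`` of field points.

    The sweep edges of a well-centred spectrum carry no signal; the sd of
    the mean-subtracted edge intensities estimates the additive noise.
    """
    n = spectrum.intensity.size
    m = max(int(round(0.5 * tail_fraction * n)), 4)
    tails = np.concatenate([spectrum.intensity[:m], spectrum.intensity[-m:]])
    return float(np.std(tails - tails.mean()))


def chi_square(simulated: Spectrum, measured: Spectrum,
               noise_sd: float | None = None) -> float:
    """Noise-weighted sum of squared residuals between two spectra.

    The spectra must share one field grid and be on a common amplitude
    scale (the fit normalizes both to unit maximum absolute amplitude
    before calling this). If ``noise_sd`` is omitted it is estimated from
    the outer field points of the measured spectrum.
    """
    if simulated.field.shape != measured.field.shape or \
            not np.allclose(simulated.field, measured.field):
        raise ValidationError("spectra are not on a common field grid")
    if noise_sd is None:
        noise_sd = max(estimate_noise_sd(measured), NOISE_SD_FLOOR)
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    r = (simulated.intensity - measured.intensity) / noise_sd
    return float(r @ r)


class _VarProObjective:
    """chi-square of a flattened (K*5) shape-parameter vector against a
    unit-amplitude measured spectrum, with proportions d projected out by
    non-negative least squares at every call."""

    GENES = 5  # S, tau_c, pA, pg, W

    def __init__(self, measured: Spectrum, k: int, bounds: FitBounds,
                 tensors: MagneticTensors, kappa: float, n_theta: int,
                 stride: int = 1):
        peak = np.max(np.abs(measured.intensity))
        if peak <= 0:
            raise ValidationError("measured spectrum has zero amplitude")
        y_full = measured.intensity / peak
        noise = estimate_noise_sd(
            Spectrum(measured.field, y_full, measured.settings))
        self.noise_sd = max(noise, NOISE_SD_FLOOR)
        self.field = np.ascontiguousarray(measured.field[::stride])
        self.y = np.ascontiguousarray(y_full[::stride])
        self.k = k
        self.lower5 = bounds.lower[: self.GENES]
        self.upper5 = bounds.upper[: self.GENES]
        self.tensors = tensors
        self.kappa = kappa
        self.freq = measured.settings.microwave_frequency
        self.u, self.wu = _powder_nodes(n_theta)
        self._b0 = np.empty((n_theta, 3))
        self._gam = np.empty((n_theta, 3))
        self._tmp = np.empty_like(self.field)
        self._c = np.empty((k, self.field.size))
        self._span = self.field[-1] - self.field[0]
        self.n_evals = 0

    def clip(self, x: np.ndarray) -> np.ndarray:
        p = x.reshape(self.k, self.GENES).copy()
        np.clip(p, self.lower5, self.upper5, out=p)
        return p

    def components(self, p: np.ndarray) -> np.ndarray | None:
        """(K, n) matrix of unit-area component derivatives, or None."""
        t = self.tensors
        for k in range(self.k):
            s, tau_c, p_a, p_g, w_res = p[k]
            apar = p_a * (t.a_iso + (2.0 / 3.0) * s * t.delta_A)
            aperp = p_a * (t.a_iso - (1.0 / 3.0) * s * t.delta_A)
            gpar = p_g * (t.g_iso + (2.0 / 3.0) * s * t.delta_g)
            gperp = p_g * (t.g_iso - (1.0 / 3.0) * s * t.delta_g)
            cos_t0 = min(0.5 * (np.sqrt(1.0 + 8.0 * s) - 1.0), 1.0)
            area, a_l, a_r = _kernels.component_derivative(
                self.field, self.u, self.wu, apar, aperp, gpar, gperp,
                p_a * t.A_zz, p_a * 0.5 * (t.A_xx + t.A_yy),
                p_g * t.g_zz, p_g * 0.5 * (t.g_xx + t.g_yy),
                cos_t0, tau_c, w_res, self.kappa, self.freq,
                _CONE_X, _CONE_W, _CONE_CA, self._b0, self._gam, self._tmp)
            slope = (a_r - a_l) / self._span
            area_c = area - 0.5 * (a_l + a_r) * self._span
            if area_c <= 0 or not np.isfinite(area_c):
                return None
            self._c[k] = (self._tmp - slope) / area_c
        return self._c

    def chi2_and_d(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        self.n_evals += 1
        c = self.components(self.clip(x))
        if c is None or not np.isfinite(c).all():
            return 1e12, np.full(self.k, 1.0 / self.k)
        w, resid = nnls(c.T, self.y)
        total = w.sum()
        d = w / total if total > 1e-12 else np.full(self.k, 1.0 / self.k)
        return float((resid / self.noise_sd) ** 2), d

    def __call__(self, x: np.ndarray) -> float:
        return self.chi2_and_d(x)[0]


def _canonical(pop: np.ndarray, k: int) -> np.ndarray:
    """Sort each genome's components by descending S (removes label symmetry)."""
    q = pop.reshape(-1, k, _VarProObjective.GENES)
    order = np.argsort(-q[:, :, 0], axis=1)
    return np.take_along_axis(q, order[:, :, None], axis=1).reshape(pop.shape)


def _ga_phase(obj: _VarProObjective, k: int, config: HeoConfig,
              rng: np.random.Generator) -> np.ndarray:
    n_genes = _VarProObjective.GENES * k
    lo = np.tile(obj.lower5, k)
    hi = np.tile(obj.upper5, k)
    width = hi - lo
    mut_sd = config.mutation_sd_frac * width
    pop = _canonical(lo + rng.random((config.population, n_genes)) * width, k)
    fitness = np.array([obj(ind) for ind in pop])
    n_children = config.population - config.elitism
    for gen in range(config.generations):
        order = np.argsort(fitness)
        elite = pop[order[: config.elitism]].copy()
        elite_fit = fitness[order[: config.elitism]].copy()
        idx = rng.integers(0, config.population,
                           size=(n_children, 2, config.tournament))
        winners = idx[np.arange(n_children)[:, None], [0, 1],
                      np.argmin(fitness[idx], axis=2)]
        pa = pop[winners[:, 0]]
        pb = pop[winners[:, 1]]
        # structured crossover: whole-component swap or BLX-alpha blend
        rows = rng.random((n_children, k)) < 0.5
        swap = np.where(np.repeat(rows, _VarProObjective.GENES, axis=1), pa, pb)
        cmin = np.minimum(pa, pb)
        cmax = np.maximum(pa, pb)
        span = cmax - cmin
        blend = cmin - config.blend_alpha * span + \
            rng.random((n_children, n_genes)) * \
            span * (1.0 + 2.0 * config.blend_alpha)
        use_swap = rng.random(n_children) < config.row_swap_prob
        children = np.where(use_swap[:, None], swap, blend)
        do_cx = rng.random(n_children) < config.crossover_prob
        children = np.where(do_cx[:, None], children, pa)
        do_mut = rng.random((n_children, n_genes)) < config.mutation_prob
        children = children + do_mut * \
            rng.normal(0.0, 1.0, (n_children, n_genes)) * mut_sd
        np.clip(children, lo, hi, out=children)
        children = _canonical(children, k)
        child_fit = np.array([obj(c) for c in children])
        pop = np.vstack([elite, children])
        fitness = np.concatenate([elite_fit, child_fit])
        # random immigrants keep the population from collapsing early
        if config.immigrant_fraction > 0 and config.immigrant_every > 0 and \
                (gen + 1) % config.immigrant_every == 0 and \
                gen < config.generations - 5:
            n_imm = int(config.immigrant_fraction * config.population)
            worst = np.argsort(fitness)[-n_imm:]
            pop[worst] = _canonical(
                lo + rng.random((n_imm, n_genes)) * width, k)
            fitness[worst] = [obj(i) for i in pop[worst]]
    return pop[int(np.argmin(fitness))]


def _nm(obj: _VarProObjective, x0: np.ndarray, k: int, maxfev: int,
        xatol: float = 1e-6, fatol: float = 1e-8) -> np.ndarray:
    bounds = list(zip(np.tile(obj.lower5, k), np.tile(obj.upper5, k)))
    res = minimize(obj, x0, method="Nelder-Mead", bounds=bounds,
                   options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol,
                            "adaptive": True})
    return res.x


def _split_candidates(p: np.ndarray, d: np.ndarray, k: int,
                      deltas: tuple[float, ...]) -> list[np.ndarray]:
    """Restart candidates splitting the largest-d component in two."""
    if k < 2:
        return []
    cands = []
    for delta in deltas:
        big = int(np.argmax(d))
        small = int(np.argmin(d))
        q = p.copy()
        q[small] = p[big].copy()
        q[big, 0] = min(p[big, 0] + delta, 1.0)
        q[small, 0] = max(p[big, 0] - delta, 0.0)
        q[big, 1] = min(p[big, 1] * 1.4, 5.0)
        q[small, 1] = max(p[big, 1] * 0.6, 0.05)
        cands.append(_canonical(q.ravel()[None], k)[0])
    return cands


def _nudge_candidates(p: np.ndarray, k: int,
                      moves: tuple[tuple[float, float], ...]) -> list[np.ndarray]:
    """Restart candidates kicking the lowest-S component (escapes the
    common minimum where the most disordered component collapses to the
    S = 0 bound with a compensating correlation time)."""
    low = int(np.argmin(p[:, 0]))
    cands = []
    for d_s, tau_f in moves:
        q = p.copy()
        q[low, 0] = float(np.clip(p[low, 0] + d_s, 0.0, 1.0))
        q[low, 1] = float(np.clip(p[low, 1] * tau_f, 0.05, 5.0))
        cands.append(_canonical(q.ravel()[None], k)[0])
    return cands


def heo_run(measured: Spectrum, k: int = 3,
            bounds: FitBounds | None = None,
            seed: int = 0,
            config: HeoConfig | None = None,
            tensors: MagneticTensors | None = None,
            kappa: float = DEFAULT_KAPPA,
            n_theta: int = 32) -> FitSolution:
    """One seeded HEO run: GA global search + Nelder-Mead refinement.

    Component labels within the returned solution carry no meaning (the
    domains are sorted by descending S for readability only); label
    assignment across runs is the job of GHOST condensation.

    ``n_theta`` is the powder-quadrature size of the fit model; 32 nodes
    reproduce the 64-node reference spectra to ~1e-9 of peak, so the
    default favours speed at no accuracy cost.
    """
    if k < 1:
        raise ValidationError(f"component count k={k} must be >= 1")
    bounds = bounds or FitBounds()
    config = config or HeoConfig()
    tensors = tensors or MagneticTensors()

    def make_obj(stride: int) -> _VarProObjective:
        return _VarProObjective(measured, k, bounds, tensors, kappa,
                                n_theta, stride=stride)

    obj_ga = make_obj(config.ga_stride)
    obj_mid = make_obj(config.nm_stride) if config.nm_stride != config.ga_stride \
        else obj_ga
    obj_fine = make_obj(1) if config.nm_stride != 1 else obj_mid

    rng = np.random.default_rng(seed)
    x = _ga_phase(obj_ga, k, config, rng)
    if not np.isfinite(obj_ga(x)) or obj_ga(x) >= 1e12:
        raise RuntimeError(
            f"HEO run (seed={seed}) aborted: GA produced no finite model")
    x = _nm(obj_mid, x, k, config.nm_maxfev_mid)
    x = _nm(obj_fine, x, k, config.nm_maxfev_fine, xatol=1e-7, fatol=1e-9)
    chi2, d = obj_fine.chi2_and_d(x)

    def try_candidates(x, chi2, cands):
        for cand in cands:
            x2 = _nm(obj_mid, cand, k, config.split_maxfev)
            chi2_2, _ = obj_fine.chi2_and_d(x2)
            if chi2_2 < chi2:
                x2 = _nm(obj_mid, x2, k, config.nm_maxfev_mid)
                x2 = _nm(obj_fine, x2, k, config.nm_maxfev_fine,
                         xatol=1e-7, fatol=1e-9)
                chi2_2, _ = obj_fine.chi2_and_d(x2)
                if chi2_2 < chi2:
                    x, chi2 = x2, chi2_2
        return x, chi2

    # restart moves: escape merged-component, then collapsed-component minima
    x, chi2 = try_candidates(
        x, chi2, _split_candidates(obj_fine.clip(x), d, k, config.split_deltas))
    x, chi2 = try_candidates(
        x, chi2, _nudge_candidates(obj_fine.clip(x), k, config.nudge_moves))
    p = obj_fine.clip(x)
    chi2, d = obj_fine.chi2_and_d(x)
    order = np.argsort(-p[:, 0])
    domains = [DomainParams(S=p[i, 0], tau_c=p[i, 1], pA=p[i, 2], pg=p[i, 3],
                            W=p[i, 4], d=d[i]) for i in order]
    n_evals = obj_ga.n_evals + obj_mid.n_evals + obj_fine.n_evals
    return FitSolution(domains=domains, chi2=chi2, seed=seed, n_evals=n_evals)


def multi_run(measured: Spectrum, k: int = 3,
              bounds: FitBounds | None = None,
              n_runs: int = 200, base_seed: int = 0,
              config: HeoConfig | None = None,
              tensors: MagneticTensors | None = None,
              kappa: float = DEFAULT_KAPPA,
              n_theta: int = 32,
              spectrum_id: str = "") -> SolutionCloud:
    """``n_runs`` independent HEO runs with seeds base_seed .. base_seed+n-1.

    Every run's solution enters the cloud; goodness-of-fit filtering is
    deferred to GHOST condensation.
    """
    if n_runs < 1:
        raise ValidationError(f"n_runs={n_runs} must be >= 1")
    bounds = bounds or FitBounds()
    solutions = []
    for i in range(n_runs):
        try:
            solutions.append(heo_run(measured, k=k, bounds=bounds,
                                     seed=base_seed + i, config=config,
                                     tensors=tensors, kappa=kappa,
                                     n_theta=n_theta))
        except Exception as exc:  # noqa: BLE001 - annotate run index
            raise RuntimeError(f"HEO run {i} (seed={base_seed + i}) failed: "
                               f"{exc}") from exc
        if (i + 1) % 25 == 0:
            log.info("multi_run: %d/%d runs done", i + 1, n_runs)
    return SolutionCloud(solutions=solutions, spectrum_id=spectrum_id,
                         bounds=bounds, k=k)
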