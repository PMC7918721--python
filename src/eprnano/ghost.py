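"""GHOST condensation of a multi-run HEO solution cloud.

Many independent fit runs of one spectrum produce a cloud of candidate
parameter sets. GHOST condenses the cloud into discrete domain groups:

1. :func:`filter_solutions` — keep the best-fitting fraction of runs,
   explode each kept run into one point per fitted component in the
   normalized (S, tau_c, W, pA) parameter space, and drop low-density
   points (fewer than ``min_neighbors`` within ``density_radius``);
2. :func:`detect_groups` — slice the order-parameter axis into
   overlapping windows, link points that fall in a common slice and lie
   within ``density_radius`` of each other in the (tau_c, W, pA)
   subspace, and merge linked clusters across slices into connected
   components;
3. :func:`group_summary` — per-group parameter means, standard errors
   from the member covariance matrix, and spin-population proportions
   (mean fitted d, renormalized to 100% across groups).

Groups are labelled by descending mean order parameter: domain 1 is the
most ordered. :func:`condense` chains the three steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
from scipy.spatial import cKDTree, ConvexHull, QhullError

from .fitting import FitBounds, SolutionCloud
from .spin_model import ValidationError

__all__ = [
    "NoCondensableSolutionsError",
    "GhostConfig",
    "CloudPoints",
    "GhostGroup",
    "GhostDiagram",
    "GhostResult",
    "filter_solutions",
    "detect_groups",
    "group_summary",
    "make_diagram",
    "condense",
    "AXIS_PAIRS",
]

#: geometric coordinates of a solution point, in normalization order
POINT_PARAMS = ("S", "tau_c", "W", "pA")

AXIS_PAIRS = ("S-tau_c", "S-W", "S-pA")


class NoCondensableSolutionsError(RuntimeError):
    """All solution points were removed by the fit/density filters."""


@dataclass(frozen=True)
class GhostConfig:
    """Filtering and slicing thresholds of the condensation.

    All distances are Euclidean in bound-normalized coordinates.
    """

    fit_keep_fraction: float = 0.5
    density_radius: float = 0.05
    min_neighbors: int = 5
    slice_width: float = 0.05
    slice_step: float = 0.025

    def __post_init__(self) -> None:
        if not 0 < self.fit_keep_fraction <= 1:
            raise ValidationError("fit_keep_fraction must be in (0, 1]")
        if self.density_radius <= 0 or self.slice_width <= 0 or \
                self.slice_step <= 0:
            raise ValidationError("radii and slice sizes must be positive")
        if self.min_neighbors < 0:
            raise ValidationError("min_neighbors must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CloudPoints:
    """Retained per-component solution points of a filtered cloud.

    values holds original units in POINT_PARAMS order plus d and pg;
    normalized holds (S, tau_c, W, pA) scaled to [0, 1] by the fit bounds.
    """

    values: np.ndarray  # (n, 6): S, tau_c, W, pA, d, pg
    normalized: np.ndarray  # (n, 4): S, tau_c, W, pA
    run_index: np.ndarray  # (n,)
    chi2: np.ndarray  # (n,)
    bounds: FitBounds

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class GhostGroup:
    """One condensed domain group."""

    label: int  # 1 = highest mean order parameter
    n_members: int
    mean: dict  # parameter -> mean over members (S, tau_c, W, pA, d)
    stderr: dict  # parameter -> standard error (NaN if undefined)
    proportion_pct: float  # renormalized across groups, sums to 100
    member_indices: list[int]
    hulls: dict = dc_field(default_factory=dict)  # axis pair -> vertex list
    errors_defined: bool = True


@dataclass
class GhostDiagram:
    """2D projection of the retained cloud with RGB-encoded extra axes.

    Colors are (tau_c, W, pA) normalized to the fit bounds (red, green,
    blue respectively).
    """

    axis_pair: str
    x: np.ndarray
    y: np.ndarray
    colors: np.ndarray  # (n, 3) in [0, 1]


@dataclass
class GhostResult:
    """Full condensation output: retained points, groups and diagrams."""

    points: CloudPoints
    groups: list[GhostGroup]
    config: GhostConfig
    n_runs_total: int
    n_runs_kept: int

    def proportions(self) -> dict[int, float]:
        return {g.label: g.proportion_pct for g in self.groups}


def _normalize_columns(values: np.ndarray, bounds: FitBounds) -> np.ndarray:
    lo = np.array([getattr(bounds, p)[0] for p in POINT_PARAMS])
    hi = np.array([getattr(bounds, p)[1] for p in POINT_PARAMS])
    return (values[:, :4] - lo) / (hi - lo)


def filter_solutions(cloud: SolutionCloud,
                     fit_keep_fraction: float = 0.5,
                     density_radius: float = 0.05,
                     min_neighbors: int = 5) -> CloudPoints:
    """Goodness-of-fit and density filtering of the solution cloud.

    Keeps the best ``fit_keep_fraction`` of runs by chi-square, explodes
    each kept run into K points (one per fitted component), normalizes
    the (S, tau_c, W, pA) coordinates to the fit bounds and removes
    points with fewer than ``min_neighbors`` other points within
    ``density_radius``.
    """
    if len(cloud) == 0:
        raise ValidationError("empty solution cloud")
    chi2 = cloud.chi2_values()
    n_keep = max(1, int(np.ceil(fit_keep_fraction * len(cloud))))
    kept_runs = np.sort(np.argsort(chi2, kind="stable")[:n_keep])
    rows = []
    run_idx = []
    chi2_col = []
    for r in kept_runs:
        for dom in cloud.solutions[r].domains:
            rows.append([dom.S, dom.tau_c, dom.W, dom.pA, dom.d, dom.pg])
            run_idx.append(r)
            chi2_col.append(chi2[r])
    values = np.array(rows)
    normalized = _normalize_columns(values, cloud.bounds)
    tree = cKDTree(normalized)
    counts = tree.query_ball_point(normalized, r=density_radius,
                                   return_length=True) - 1  # exclude self
    dense = counts >= min_neighbors
    if not dense.any():
        raise NoCondensableSolutionsError(
            f"no condensable solutions: all {len(values)} points fall below "
            f"{min_neighbors} neighbors within radius {density_radius}")
    return CloudPoints(values=values[dense],
                       normalized=normalized[dense],
                       run_index=np.array(run_idx)[dense],
                       chi2=np.array(chi2_col)[dense],
                       bounds=cloud.bounds)


def _union(parent: np.ndarray, a: int, b: int) -> None:
    ra, rb = _find(parent, a), _find(parent, b)
    if ra != rb:
        parent[max(ra, rb)] = min(ra, rb)


def _find(parent: np.ndarray, a: int) -> int:
    while parent[a] != a:
        parent[a] = parent[parent[a]]
        a = parent[a]
    return a


def detect_groups(points: CloudPoints,
                  slice_width: float = 0.05,
                  slice_step: float = 0.025,
                  density_radius: float = 0.05) -> list[list[int]]:
    """Slice-wise group detection along the order-parameter axis.

    Overlapping slices of normalized S are scanned; within each slice,
    points closer than ``density_radius`` in the (tau_c, W, pA) subspace
    are linked, and clusters sharing points across slices are merged.
    Returns member-index lists ordered by descending mean S (group 1 =
    most ordered domain). Consumes no randomness and is invariant to
    point order.
    """
    n = len(points)
    if n == 0:
        raise ValidationError("no retained points")
    s = points.normalized[:, 0]
    sub = points.normalized[:, 1:]
    parent = np.arange(n)
    start = 0.0
    s_max = float(s.max())
    while True:
        in_slice = np.where((s >= start) & (s <= start + slice_width))[0]
        if in_slice.size > 1:
            tree = cKDTree(sub[in_slice])
            for i_loc, j_loc in tree.query_pairs(r=density_radius):
                _union(parent, int(in_slice[i_loc]), int(in_slice[j_loc]))
        if start > s_max:
            break
        start += slice_step
    roots = np.array([_find(parent, i) for i in range(n)])
    groups = [np.where(roots == r)[0].tolist() for r in np.unique(roots)]
    groups.sort(key=lambda m: -float(np.mean(points.values[m, 0])))
    return groups


def group_summary(members: list[int], points: CloudPoints, label: int,
                  proportion_norm: float = 1.0) -> GhostGroup:
    """Mean parameters, covariance-based standard errors and proportion.

    ``proportion_norm`` is the sum of mean-d over all groups, used to
    renormalize the proportions to 100%. Singleton groups report means
    with undefined (NaN) errors.
    """
    if not members:
        raise ValidationError("empty member set")
    vals = points.values[members]  # S, tau_c, W, pA, d, pg
    names = ("S", "tau_c", "W", "pA", "d")
    mean = {p: float(vals[:, i].mean()) for i, p in enumerate(names)}
    n = len(members)
    if n >= 2:
        cov = np.cov(vals[:, :5], rowvar=False)
        se = np.sqrt(np.diag(cov) / n)
        stderr = {p: float(se[i]) for i, p in enumerate(names)}
        defined = True
    else:
        stderr = {p: float("nan") for p in names}
        defined = False
    hulls = {}
    for pair in AXIS_PAIRS:
        other = pair.split("-")[1]
        cols = {"tau_c": 1, "W": 2, "pA": 3}[other]
        pts2 = vals[:, [0, cols]]
        try:
            hull = ConvexHull(pts2)
            hulls[pair] = pts2[hull.vertices].tolist()
        except (QhullError, ValueError):
            hulls[pair] = pts2.tolist()  # degenerate: fewer than 3 / collinear
    proportion = 100.0 * mean["d"] / proportion_norm if proportion_norm > 0 \
        else float("nan")
    return GhostGroup(label=label, n_members=n, mean=mean, stderr=stderr,
                      proportion_pct=proportion,
                      member_indices=list(map(int, members)),
                      hulls=hulls, errors_defined=defined)


def make_diagram(points: CloudPoints, axis_pair: str) -> GhostDiagram:
    """GHOST diagram data for one 2D projection.

    Coordinates are in original units; the per-point RGB color encodes
    the bound-normalized (tau_c, W, pA) values.
    """
    if axis_pair not in AXIS_PAIRS:
        raise ValidationError(
            f"unknown axis pair {axis_pair!r}; choose from {AXIS_PAIRS}")
    ycol = {"S-tau_c": 1, "S-W": 2, "S-pA": 3}[axis_pair]
    colors = np.clip(points.normalized[:, [1, 2, 3]], 0.0, 1.0)
    return GhostDiagram(axis_pair=axis_pair,
                        x=points.values[:, 0].copy(),
                        y=points.values[:, ycol].copy(),
                        colors=colors)


def condense(cloud: SolutionCloud,
             config: GhostConfig | None = None) -> GhostResult:
    """Full GHOST condensation: filter, group, summarize."""
    config = config or GhostConfig()
    points = filter_solutions(cloud,
                              fit_keep_fraction=config.fit_keep_fraction,
                              density_radius=config.density_radius,
                              min_neighbors=config.min_neighbors)
    member_lists = detect_groups(points,
                                 slice_width=config.slice_width,
                                 slice_step=config.slice_step,
                                 density_radius=config.density_radius)
    totals = [float(np.mean(points.values[m, 4])) for m in member_lists]
    norm = sum(totals)
    groups = [group_summary(m, points, label=i + 1, proportion_norm=norm)
              for i, m in enumerate(member_lists)]
    n_keep = max(1, int(np.ceil(config.fit_keep_fraction * len(cloud))))
    return GhostResult(points=points, groups=groups, config=config,
                       n_runs_total=len(cloud), n_runs_kept=n_keep)
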