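"""GHOST condensation on synthetic solution clouds (no fitting involved)."""

import numpy as np
import pytest

from eprnano import (
    DomainParams,
    FitBounds,
    FitSolution,
    GhostConfig,
    SolutionCloud,
    ValidationError,
    condense,
    detect_groups,
    filter_solutions,
    group_summary,
    make_diagram,
)
from eprnano.ghost import NoCondensableSolutionsError, CloudPoints

from _oracles import epsilon_graph_components

BOUNDS = FitBounds()


def _solution(domains, chi2=1.0, seed=0):
    return FitSolution(domains=[DomainParams(**d) for d in domains],
                       chi2=chi2, seed=seed, n_evals=1)


def _denorm(s, tau, w, pa):
    """Build original-unit values from normalized coordinates."""
    return dict(
        S=s * 1.0,
        tau_c=0.05 + tau * (5.0 - 0.05),
        W=w * 0.5,
        pA=0.85 + pa * (1.15 - 0.85),
    )


def _cloud_from_normalized(coords, chi2=None, k=1, d=None):
    """coords: (n, 4) normalized (S, tau_c, W, pA); one domain per run."""
    coords = np.asarray(coords)
    sols = []
    for i, row in enumerate(coords):
        p = _denorm(*row)
        sols.append(_solution([dict(d=1.0, **p)],
                              chi2=1.0 if chi2 is None else chi2[i], seed=i))
    return SolutionCloud(solutions=sols, bounds=BOUNDS, k=1)


def _gaussian_cluster_cloud(centers, n_per, sd, rng, d_means=None):
    """K-domain cloud: run j gets one domain per cluster center."""
    k = len(centers)
    sols = []
    for j in range(n_per):
        doms = []
        weights = d_means if d_means is not None else [1.0 / k] * k
        total = sum(weights)
        for c, w in zip(centers, weights):
            coords = np.clip(np.asarray(c) + rng.normal(0, sd, 4), 0.001, 0.999)
            doms.append(dict(d=w / total, **_denorm(*coords)))
        sols.append(_solution(doms, chi2=1.0 + 0.01 * j, seed=j))
    return SolutionCloud(solutions=sols, bounds=BOUNDS, k=k)


class TestFilterSolutions:
    def test_identical_solutions_all_retained(self):
        cloud = _cloud_from_normalized([[0.5, 0.3, 0.2, 0.5]] * 20)
        pts = filter_solutions(cloud, fit_keep_fraction=1.0)
        assert len(pts) == 20

    def test_bad_fit_removed_by_chi2_filter(self):
        coords = [[0.5, 0.3, 0.2, 0.5]] * 20
        chi2 = [1.0] * 19 + [1000.0]
        cloud = _cloud_from_normalized(coords, chi2=chi2)
        pts = filter_solutions(cloud, fit_keep_fraction=0.5)
        assert len(pts) == 10
        assert np.all(pts.chi2 < 1000)

    def test_isolated_point_removed_by_density_filter(self):
        rng = np.random.default_rng(5)
        cluster = 0.5 + rng.normal(0, 0.01, (100, 4))
        isolated = np.array([[0.95, 0.9, 0.9, 0.9]])  # far from the cluster
        coords = np.vstack([cluster, isolated])
        cloud = _cloud_from_normalized(coords)
        pts = filter_solutions(cloud, fit_keep_fraction=1.0,
                               density_radius=0.05, min_neighbors=5)
        assert len(pts) == 100
        # brute-force check that the removed point was indeed isolated
        dists = np.linalg.norm(coords[:-1] - coords[-1], axis=1)
        assert np.sum(dists <= 0.05) == 0

    def test_all_filtered_raises(self):
        rng = np.random.default_rng(6)
        coords = rng.random((10, 4))  # 10 scattered points, no neighbors
        cloud = _cloud_from_normalized(coords)
        with pytest.raises(NoCondensableSolutionsError):
            filter_solutions(cloud, fit_keep_fraction=1.0,
                             density_radius=0.01, min_neighbors=5)

    def test_points_per_kept_run_equals_k(self, three_domains):
        sols = [FitSolution(domains=three_domains, chi2=1.0, seed=i,
                            n_evals=1) for i in range(20)]
        cloud = SolutionCloud(solutions=sols, bounds=BOUNDS, k=3)
        pts = filter_solutions(cloud, fit_keep_fraction=0.5)
        assert len(pts) == 10 * 3


class TestDetectGroups:
    def _points(self, coords):
        coords = np.asarray(coords, dtype=float)
        values = np.column_stack([
            coords[:, 0],
            0.05 + coords[:, 1] * 4.95,
            coords[:, 2] * 0.5,
            0.85 + coords[:, 3] * 0.3,
            np.full(len(coords), 1.0 / max(len(coords), 1)),
            np.ones(len(coords)),
        ])
        return CloudPoints(values=values, normalized=coords,
                           run_index=np.arange(len(coords)),
                           chi2=np.ones(len(coords)), bounds=BOUNDS)

    def test_three_planted_clusters_give_three_groups(self):
        rng = np.random.default_rng(7)
        centers = [(0.62, 0.5, 0.24, 0.47), (0.37, 0.16, 0.2, 0.5),
                   (0.12, 0.09, 0.16, 0.57)]
        coords = np.vstack([
            np.clip(c + rng.normal(0, 0.008, (30, 4)), 0, 1)
            for c in centers])
        groups = detect_groups(self._points(coords))
        assert len(groups) == 3
        # ordered by descending mean S
        means = [np.mean(coords[m, 0]) for m in groups]
        assert means == sorted(means, reverse=True)

    def test_single_cluster_gives_one_group(self):
        rng = np.random.default_rng(8)
        coords = np.clip(0.4 + rng.normal(0, 0.01, (40, 4)), 0, 1)
        assert len(detect_groups(self._points(coords))) == 1

    def test_matches_epsilon_graph_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            n = int(rng.integers(40, 120))
            # mixture of a few loose blobs to exercise merges and splits
            centers = rng.random((int(rng.integers(2, 6)), 4))
            coords = np.clip(np.vstack([
                c + rng.normal(0, 0.04, (n // len(centers) + 1, 4))
                for c in centers])[:n], 0, 1)
            pts = self._points(coords)
            got = detect_groups(pts, slice_width=0.05, slice_step=0.025,
                                density_radius=0.05)
            want = epsilon_graph_components(coords[:, 0], coords[:, 1:],
                                            slice_width=0.05,
                                            slice_step=0.025, radius=0.05)
            got_sets = sorted(tuple(sorted(m)) for m in got)
            want_sets = sorted(tuple(sorted(m)) for m in want)
            assert got_sets == want_sets

    def test_invariant_to_point_order(self):
        rng = np.random.default_rng(10)
        coords = np.vstack([
            np.clip((0.3, 0.3, 0.3, 0.3) + rng.normal(0, 0.01, (20, 4)), 0, 1),
            np.clip((0.7, 0.7, 0.7, 0.7) + rng.normal(0, 0.01, (20, 4)), 0, 1)])
        base = detect_groups(self._points(coords))
        perm = rng.permutation(len(coords))
        shuffled = detect_groups(self._points(coords[perm]))
        base_sets = sorted(tuple(sorted(m)) for m in base)
        mapped = sorted(tuple(sorted(perm[m2] for m2 in m)) for m in shuffled)
        assert base_sets == mapped

    def test_gaussian_cluster_recovery_rate(self):
        """Three clusters separated by >= 5 sd are recovered in >= 95 of
        100 seeded replicates."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            sd = 0.01
            centers = [(0.65, 0.5, 0.3, 0.5), (0.4, 0.25, 0.25, 0.45),
                       (0.15, 0.1, 0.2, 0.55)]  # separations >> 5 sd
            coords = np.vstack([
                np.clip(c + rng.normal(0, sd, (25, 4)), 0, 1)
                for c in centers])
            if len(detect_groups(self._points(coords))) == 3:
                hits += 1
        assert hits >= 95


class TestGroupSummary:
    def test_identical_members_zero_se(self):
        pts = TestDetectGroups()._points([[0.5, 0.3, 0.2, 0.5]] * 8)
        g = group_summary(list(range(8)), pts, label=1)
        assert g.stderr["S"] == 0.0
        assert g.errors_defined

    def test_singleton_errors_undefined(self):
        pts = TestDetectGroups()._points([[0.5, 0.3, 0.2, 0.5]])
        g = group_summary([0], pts, label=1)
        assert not g.errors_defined
        assert np.isnan(g.stderr["S"])
        assert g.mean["S"] == pytest.approx(0.5)

    def test_proportions_renormalized(self):
        rng = np.random.default_rng(11)
        cloud = _gaussian_cluster_cloud(
            [(0.6, 0.5, 0.3, 0.5), (0.2, 0.2, 0.2, 0.5)],
            n_per=30, sd=0.005, rng=rng, d_means=[0.6, 0.4])
        res = condense(cloud, GhostConfig(fit_keep_fraction=1.0))
        assert len(res.groups) == 2
        props = [g.proportion_pct for g in res.groups]
        assert sum(props) == pytest.approx(100.0, abs=0.1)
        assert props[0] == pytest.approx(60.0, abs=1.0)
        assert props[1] == pytest.approx(40.0, abs=1.0)

    def test_group_means_near_planted_centroids(self):
        rng = np.random.default_rng(12)
        centers = [(0.62, 0.5, 0.24, 0.47), (0.37, 0.16, 0.2, 0.5),
                   (0.12, 0.09, 0.16, 0.57)]
        cloud = _gaussian_cluster_cloud(centers, n_per=40, sd=0.008, rng=rng)
        res = condense(cloud, GhostConfig(fit_keep_fraction=1.0))
        assert len(res.groups) == 3
        for g, c in zip(res.groups, centers):
            assert g.mean["S"] == pytest.approx(c[0], abs=3 * 0.008)

    def test_membership_is_partition(self):
        rng = np.random.default_rng(13)
        cloud = _gaussian_cluster_cloud(
            [(0.6, 0.5, 0.3, 0.5), (0.2, 0.2, 0.2, 0.5)],
            n_per=25, sd=0.01, rng=rng)
        res = condense(cloud, GhostConfig(fit_keep_fraction=1.0))
        all_members = sorted(i for g in res.groups for i in g.member_indices)
        assert all_members == list(range(len(res.points)))


class TestDiagram:
    def test_corner_colors(self):
        # upper bound of tau_c, lower bounds of W and pA -> pure red
        pts = TestDetectGroups()._points([[0.5, 1.0, 0.0, 0.0]])
        dia = make_diagram(pts, "S-tau_c")
        np.testing.assert_allclose(dia.colors[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_deterministic_and_complete(self):
        rng = np.random.default_rng(14)
        coords = rng.random((25, 4))
        pts = TestDetectGroups()._points(coords)
        d1 = make_diagram(pts, "S-W")
        d2 = make_diagram(pts, "S-W")
        assert len(d1.x) == 25
        np.testing.assert_array_equal(d1.x, d2.x)
        np.testing.assert_array_equal(d1.colors, d2.colors)

    def test_unknown_axis_pair_rejected(self):
        pts = TestDetectGroups()._points([[0.5, 0.5, 0.5, 0.5]])
        with pytest.raises(ValidationError):
            make_diagram(pts, "tau_c-W")

    def test_rendered_diagram_has_points_and_group_markers(self):
        import matplotlib
        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt
        from eprnano.plotting import plot_ghost_diagram
        rng = np.random.default_rng(15)
        cloud = _gaussian_cluster_cloud(
            [(0.6, 0.5, 0.3, 0.5), (0.2, 0.2, 0.2, 0.5)],
            n_per=25, sd=0.01, rng=rng)
        res = condense(cloud, GhostConfig(fit_keep_fraction=1.0))
        ax = plot_ghost_diagram(res, axis_pair="S-tau_c")
        assert len(ax.collections) == 1  # the point scatter
        assert ax.get_xlabel().startswith("order parameter")
        plt.close(ax.figure)
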