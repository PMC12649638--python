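"""Network construction, Ward.D2 clustering, tree cut, eigengenes, kME."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from polypnet import coexpression as cx
from polypnet import synthetic_data as sim
from conftest import make_expression


def naive_pearson(x, y):
    """Two-pass textbook Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestFilterGenes:
    def test_identity_when_nothing_filters(self, rng):
        expr = make_expression(rng.standard_normal((8, 6)), samples=list("abcdef"))
        out = cx.filter_genes(expr, min_mean=None, top_n=8)
        pd.testing.assert_frame_equal(out, expr)

    def test_top_by_variance_matches_bruteforce(self, rng):
        expr = make_expression(rng.standard_normal((10, 6)) * rng.uniform(0.1, 3, (10, 1)),
                               samples=list("abcdef"))
        out = cx.filter_genes(expr, min_mean=None, top_n=3)
        expected = set(expr.var(axis=1, ddof=1).sort_values(ascending=False).index[:3])
        assert set(out.index) == expected
        assert list(out.index) == [g for g in expr.index if g in expected]  # order kept

    def test_constant_gene_loses_to_any_varying_gene(self, rng):
        values = np.vstack([np.ones(6), rng.standard_normal((4, 6))])
        expr = make_expression(values, samples=list("abcdef"))
        out = cx.filter_genes(expr, min_mean=None, top_n=4)
        assert "g1" not in out.index

    def test_mean_floor_and_errors(self, rng):
        values = rng.standard_normal((6, 4)) + np.array([[10], [10], [10], [0], [0], [0]])
        expr = make_expression(values, samples=list("abcd"))
        out = cx.filter_genes(expr, min_mean=5.0, top_n=3)
        assert len(out) == 3
        with pytest.raises(ValueError):
            cx.filter_genes(expr, min_mean=99.0, top_n=10)
        with pytest.warns(UserWarning, match="keeping all"):
            cx.filter_genes(expr, min_mean=None, top_n=100)


class TestCorrelationAndDistance:
    def test_self_and_anticorrelated(self, rng):
        x = rng.standard_normal(8)
        expr = make_expression(np.vstack([x, -x, rng.standard_normal(8)]),
                               samples=[f"s{i}" for i in range(8)])
        R, D = cx.correlation_and_distance(expr)
        assert R.iloc[0, 0] == 1.0 and D.iloc[0, 0] == 0.0
        assert R.iloc[0, 1] == pytest.approx(-1.0)
        assert D.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)  # unsigned network
        assert ((D.to_numpy() >= 0) & (D.to_numpy() <= 1)).all()

    def test_matches_naive_two_pass_pearson(self, rng):
        expr = make_expression(rng.standard_normal((4, 10)),
                               samples=[f"s{i}" for i in range(10)])
        R, _D = cx.correlation_and_distance(expr)
        for i in range(4):
            for j in range(4):
                assert R.iloc[i, j] == pytest.approx(
                    naive_pearson(expr.iloc[i], expr.iloc[j]), abs=1e-12
                )

    def test_zero_variance_gene_named(self, rng):
        values = np.vstack([np.ones(6), rng.standard_normal((2, 6))])
        expr = make_expression(values, samples=list("abcdef"))
        with pytest.raises(ValueError, match="g1"):
            cx.correlation_and_distance(expr)


def naive_ward_reference(D):
    """Deliberately simple O(n^3) Lance--Williams Ward.D2 reference.

    Scans every active pair at every step (lowest-index pair on ties) and
    applies the squared-distance update with explicit loops.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    d2 = {(i, j): D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    clusters = {i: [i] for i in range(n)}
    ids = {i: i for i in range(n)}
    merges = []
    next_id = n
    for _step in range(n - 1):
        keys = sorted(clusters)
        best, best_pair = np.inf, None
        for a_pos, a in enumerate(keys):
            for b in keys[a_pos + 1:]:
                val = d2[(a, b)] if (a, b) in d2 else d2[(b, a)]
                if val < best:
                    best, best_pair = val, (a, b)
        i, j = best_pair
        ni, nj = len(clusters[i]), len(clusters[j])
        merges.append(
            (min(ids[i], ids[j]), max(ids[i], ids[j]), np.sqrt(max(best, 0.0)), ni + nj)
        )
        for k in keys:
            if k in (i, j):
                continue
            nk = len(clusters[k])
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            d2[(min(i, k), max(i, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * best
            ) / (ni + nj + nk)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        ids[i] = next_id
        next_id += 1
    return np.array(merges)


def random_distance_matrix(rng, n):
    pts = rng.standard_normal((n, 3))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    return D


class TestWardLinkage:
    def test_two_leaves(self):
        link = cx.ward_linkage(np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert link.merges.shape == (1, 4)
        assert link.merges[0, 2] == pytest.approx(0.4)
        assert link.merges[0, 3] == 2

    def test_matches_naive_reference_on_small_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            D = random_distance_matrix(rng, n)
            link = cx.ward_linkage(D)
            ref = naive_ward_reference(D)
            assert np.allclose(link.merges, ref, atol=1e-9)

    def test_matches_scipy_ward(self, rng):
        # independent C implementation of the same Ward.D2 recurrence
        for _ in range(20):
            n = int(rng.integers(4, 15))
            D = random_distance_matrix(rng, n)
            link = cx.ward_linkage(D)
            ref = scipy_linkage(squareform(D, checks=False), method="ward")
            mine = np.column_stack([
                np.minimum(link.merges[:, 0], link.merges[:, 1]),
                np.maximum(link.merges[:, 0], link.merges[:, 1]),
                link.merges[:, 2], link.merges[:, 3],
            ])
            theirs = np.column_stack([
                np.minimum(ref[:, 0], ref[:, 1]),
                np.maximum(ref[:, 0], ref[:, 1]),
                ref[:, 2], ref[:, 3],
            ])
            assert np.allclose(mine, theirs, atol=1e-9)

    def test_uniform_distances_follow_tie_rule(self):
        D = np.ones((5, 5)) - np.eye(5)
        link1 = cx.ward_linkage(D)
        link2 = cx.ward_linkage(D)
        assert np.array_equal(link1.merges, link2.merges)
        # first merge is the lowest-index pair
        assert tuple(link1.merges[0, :2]) == (0.0, 1.0)

    def test_heights_monotone(self, rng):
        D = random_distance_matrix(rng, 30)
        link = cx.ward_linkage(D)
        assert (np.diff(link.heights) >= -1e-9).all()

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            cx.ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            cx.ward_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative
        with pytest.raises(ValueError):
            cx.ward_linkage(np.array([[1.0, 0.5], [0.5, 0.0]]))  # diag


class TestCutDendrogram:
    def test_cut_above_root_single_module(self, rng):
        D = random_distance_matrix(rng, 12)
        link = cx.ward_linkage(D)
        labels = cx.cut_dendrogram(link, cut_height=link.heights[-1] * 10, min_size=2)
        # refinement may split, but every gene is assigned
        assert (labels > 0).all()
        labels_coarse = cx.cut_dendrogram(
            link, cut_height=link.heights[-1] * 10, min_size=12
        )
        assert (labels_coarse == 1).all()

    def test_cut_below_every_merge_all_grey(self, rng):
        D = random_distance_matrix(rng, 10) + 1.0
        np.fill_diagonal(D, 0.0)
        link = cx.ward_linkage(D)
        labels = cx.cut_dendrogram(link, cut_height=link.heights.min() / 2, min_size=2)
        assert (labels == 0).all()

    def test_recovers_two_planted_noiseless_modules(self, zero_noise_two_modules):
        expr, _groups, truth = zero_noise_two_modules
        _R, D = cx.correlation_and_distance(expr)
        link = cx.ward_linkage(D)
        labels = cx.cut_dendrogram(link, min_size=10)
        assert set(labels) == {1, 2}
        # size-rank labelling: module 1 is the larger planted module
        assert np.array_equal(labels, truth.gene_module)

    def test_invalid_cut_parameters(self, rng):
        link = cx.ward_linkage(random_distance_matrix(rng, 5))
        with pytest.raises(ValueError):
            cx.cut_dendrogram(link, cut_height=-1.0)
        with pytest.raises(ValueError):
            cx.cut_dendrogram(link, min_size=1)


class TestModuleEigengene:
    def test_identical_genes_module(self, rng):
        profile = rng.standard_normal(10)
        expr = make_expression(np.tile(profile, (6, 1)) * rng.uniform(0.5, 2, (6, 1)))
        labels = np.ones(6, dtype=int)
        table = cx.module_eigengene(expr, labels)
        assert table.variance_explained.loc[1] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(table.eigengenes.loc[1].to_numpy(), z, atol=1e-9)

    def test_sign_convention_under_global_flip(self, small_sim):
        _cfg, expr, _groups, truth = small_sim
        labels = truth.gene_module
        table = cx.module_eigengene(expr, labels)
        flipped = cx.module_eigengene(-expr, labels)
        for m in table.eigengenes.index:
            r = np.corrcoef(table.eigengenes.loc[m], flipped.eigengenes.loc[m])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_variance_explained_matches_squared_loading(self):
        cfg = sim.SimConfig(
            n_genes=120, module_sizes=(100,), n_per_group=100,
            loading_range=(0.9, 0.9), trait_effect=0.0,
            driven_module_index=0, seed=21,
        )
        expr, _groups, truth = sim.simulate_expression(cfg)
        table = cx.module_eigengene(expr, truth.gene_module)
        assert table.variance_explained.loc[1] == pytest.approx(0.81, abs=0.05)

    def test_single_gene_module_warns(self, rng):
        expr = make_expression(rng.standard_normal((3, 8)),
                               samples=[f"s{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="single gene"):
            table = cx.module_eigengene(expr, np.array([1, 2, 2]))
        assert table.variance_explained.loc[1] == 1.0


class TestMergeModules:
    def test_identical_planted_modules_merge(self, rng):
        latent = rng.standard_normal(10)
        noise = 0.05 * rng.standard_normal((40, 10))
        expr = make_expression(latent + noise)
        labels = np.repeat([1, 2], 20)
        merged = cx.merge_modules(expr, labels)
        assert set(merged) == {1}

    def test_independent_modules_stay_separate(self):
        cfg = sim.SimConfig(
            n_genes=60, module_sizes=(30, 30), n_per_group=100,
            loading_range=(0.9, 0.9), trait_effect=0.0,
            driven_module_index=0, seed=8,
        )
        expr, _groups, truth = sim.simulate_expression(cfg)
        merged = cx.merge_modules(expr, truth.gene_module)
        assert set(merged) == {1, 2}

    def test_postcondition_no_pair_above_threshold(self, small_sim):
        _cfg, expr, _groups, truth = small_sim
        merged = cx.merge_modules(expr, truth.gene_module, r_threshold=0.75)
        modules = [m for m in np.unique(merged) if m != 0]
        if len(modules) > 1:
            table = cx.module_eigengene(expr, merged)
            corr = np.corrcoef(table.eigengenes.to_numpy())
            iu = np.triu_indices(len(modules), k=1)
            assert corr[iu].max() <= 0.75


class TestKme:
    def test_gene_equal_to_eigengene(self, rng):
        profile = rng.standard_normal(12)
        expr = make_expression(
            np.vstack([profile, profile * 2 + 3, rng.standard_normal(12)]),
            samples=[f"s{i}" for i in range(12)],
        )
        labels = np.array([1, 1, 0])
        table = cx.module_eigengene(expr, labels)
        k = cx.kme(expr, table.eigengenes)
        assert k.loc["g1", 1] == pytest.approx(1.0, abs=1e-9)
        # Pearson invariance: affinely rescaled gene has identical kME
        assert k.loc["g2", 1] == pytest.approx(k.loc["g1", 1], abs=1e-9)

    def test_own_module_kme_tracks_planted_loading(self):
        cfg = sim.SimConfig(
            n_genes=80, module_sizes=(60,), n_per_group=250,
            loading_range=(0.8, 0.8), trait_effect=0.0,
            driven_module_index=0, seed=13,
        )
        expr, _groups, truth = sim.simulate_expression(cfg)
        table = cx.module_eigengene(expr, truth.gene_module)
        k = cx.kme(expr, table.eigengenes)
        own = k[1].to_numpy()[truth.gene_module == 1]
        assert own.mean() == pytest.approx(0.8, abs=0.05)
        assert np.allclose(own, 0.8, atol=0.1)

    def test_zero_variance_gene_rejected(self, rng):
        expr = make_expression(np.vstack([np.ones(8), rng.standard_normal((2, 8))]),
                               samples=[f"s{i}" for i in range(8)])
        table = cx.module_eigengene(expr.iloc[1:], np.array([1, 1]))
        with pytest.raises(ValueError, match="g1"):
            cx.kme(expr, table.eigengenes)


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, small_sim):
        _cfg, expr, _groups, truth = small_sim
        table = cx.module_eigengene(expr, truth.gene_module)
        traits = pd.DataFrame({"me_copy": table.eigengenes.loc[1]})
        out = cx.module_trait(table.eigengenes, traits)
        row = out[(out["module"] == 1) & (out["trait"] == "me_copy")].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["p_value"] < 1e-12
        assert row["significant"]

    def test_single_pair_q_equals_p(self, rng):
        e = pd.DataFrame(rng.standard_normal((1, 10)), index=pd.Index([1], name="module"),
                         columns=[f"s{i}" for i in range(10)])
        traits = pd.DataFrame({"t": rng.standard_normal(10)},
                              index=[f"s{i}" for i in range(10)])
        out = cx.module_trait(e, traits)
        assert out["q_value"].iloc[0] == pytest.approx(out["p_value"].iloc[0])

    def test_p_matches_t_transform(self, rng):
        from scipy import stats as sps
        e = pd.DataFrame(rng.standard_normal((1, 12)), index=pd.Index([1], name="module"),
                         columns=[f"s{i}" for i in range(12)])
        traits = pd.DataFrame({"t": rng.standard_normal(12)}, index=e.columns)
        out = cx.module_trait(e, traits).iloc[0]
        r, n = out["pearson_r"], 12
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        assert out["p_value"] == pytest.approx(2 * sps.t.sf(abs(t), n - 2), rel=1e-9)

    def test_constant_trait_rejected(self, small_sim):
        _cfg, expr, _groups, truth = small_sim
        table = cx.module_eigengene(expr, truth.gene_module)
        traits = pd.DataFrame({"flat": np.ones(expr.shape[1])}, index=expr.columns)
        with pytest.raises(ValueError, match="flat"):
            cx.module_trait(table.eigengenes, traits)


class TestExportNetwork:
    def test_threshold_one_gives_no_edges(self, small_sim):
        _cfg, expr, _groups, truth = small_sim
        R, _D = cx.correlation_and_distance(expr)
        table = cx.module_eigengene(expr, truth.gene_module)
        k = cx.kme(expr, table.eigengenes)
        _nodes, edges = cx.export_network(R, truth.gene_module, k, edge_min_abs_r=1.0)
        assert edges.empty

    def test_zero_noise_complete_within_module_graph(self, zero_noise_two_modules):
        expr, _groups, truth = zero_noise_two_modules
        R, _D = cx.correlation_and_distance(expr)
        table = cx.module_eigengene(expr, truth.gene_module)
        k = cx.kme(expr, table.eigengenes)
        nodes, edges = cx.export_network(R, truth.gene_module, k, edge_min_abs_r=0.99)
        sizes = [int((truth.gene_module == m).sum()) for m in (1, 2)]
        expected = sum(s * (s - 1) // 2 for s in sizes)
        assert len(edges) == expected
        assert len(nodes) == sum(sizes)
        assert np.allclose(nodes["kme"], 1.0, atol=1e-9)

    def test_edge_count_matches_hand_enumeration(self, rng):
        expr = make_expression(rng.standard_normal((5, 10)))
        labels = np.array([1, 1, 1, 1, 1])
        R, _D = cx.correlation_and_distance(expr)
        table = cx.module_eigengene(expr, labels)
        k = cx.kme(expr, table.eigengenes)
        threshold = 0.3
        _nodes, edges = cx.export_network(R, labels, k, edge_min_abs_r=threshold)
        hand = sum(
            1
            for i in range(5)
            for j in range(i + 1, 5)
            if abs(R.iloc[i, j]) >= threshold
        )
        assert len(edges) == hand


def test_pipeline_determinism_on_identical_inputs(small_sim):
    """Same expression + parameters give byte-identical module tables."""
    _cfg, expr, _groups, _truth = small_sim

    def run():
        _R, D = cx.correlation_and_distance(expr)
        link = cx.ward_linkage(D)
        raw = cx.cut_dendrogram(link, min_size=10)
        return cx.merge_modules(expr, raw)

    assert np.array_equal(run(), run())
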