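"""Signed network construction, TOM, module detection, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest

from t2dbrain.network import (
    NetworkConfig,
    detect_modules,
    gs_mm,
    hub_genes,
    kme_filter,
    merge_modules,
    module_eigengene,
    module_trait_stats,
    pick_soft_threshold,
    residualize,
    run_network,
    signed_adjacency,
    tom_similarity,
)


@pytest.fixture(scope="module")
def planted_expression():
    """5 modules x 40 genes + 100 noise genes, 60 samples, strong factors."""
    rng = np.random.default_rng(42)
    n, gpm, n_mod = 60, 40, 5
    factors = rng.normal(size=(n_mod, n))
    rows, labels = [], []
    for m in range(n_mod):
        load = rng.uniform(0.8, 1.2, gpm)
        rows.append(load[:, None] * factors[m][None, :] + rng.normal(0, 0.5, (gpm, n)))
        labels += [m + 1] * gpm
    rows.append(rng.normal(size=(100, n)))
    labels += [0] * 100
    X = pd.DataFrame(np.vstack(rows),
                     index=[f"G{i:04d}" for i in range(len(labels))],
                     columns=[f"S{j}" for j in range(n)])
    return X, np.array(labels), factors


class TestResidualize:
    def test_intercept_only_centers_rows(self, rng):
        Y = rng.normal(size=(5, 12))
        R = residualize(Y, np.ones((12, 1)))
        assert np.allclose(R, Y - Y.mean(axis=1, keepdims=True))

    def test_linear_gene_vanishes(self, rng):
        age = rng.uniform(30, 70, 20)
        Y = np.vstack([3 * age + 1, rng.normal(size=20)])
        R = residualize(Y, np.column_stack([np.ones(20), age]))
        assert np.abs(R[0]).max() < 1e-9

    def test_residuals_orthogonal_to_design(self, rng):
        X = np.column_stack([np.ones(15), rng.normal(size=(15, 3))])
        Y = rng.normal(size=(8, 15))
        R = residualize(Y, X)
        assert np.abs(R @ X).max() < 1e-9

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=12)
        X = np.column_stack([np.ones(12), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=(3, 12)), X)


class TestAdjacency:
    def test_endpoints_of_signed_map(self):
        x = np.arange(10.0)
        X = np.vstack([x, x, -x])
        A = signed_adjacency(X, beta=1)
        assert A[0, 1] == pytest.approx(1.0)  # cor +1
        assert A[0, 2] == pytest.approx(0.0)  # cor -1

    def test_power_arithmetic(self):
        # cor 0.6 -> ((1+0.6)/2)^2 = 0.64
        assert ((1 + 0.6) / 2) ** 2 == pytest.approx(0.64)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 30))
        A1 = signed_adjacency(X, beta=1)
        A2 = signed_adjacency(X, beta=2)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(A2[off], A1[off] ** 2)

    def test_symmetric_bounded(self, rng):
        A = signed_adjacency(rng.normal(size=(20, 15)), beta=6)
        assert np.allclose(A, A.T)
        assert A.min() >= 0 and A.max() <= 1
        assert (np.diag(A) == 0).all()

    def test_rejects_beta_below_one(self, rng):
        with pytest.raises(ValueError):
            signed_adjacency(rng.normal(size=(3, 5)), beta=0.5)


class TestTOM:
    @staticmethod
    def _oracle(A):
        n = A.shape[0]
        k = A.sum(axis=1)
        T = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
        return T

    def test_zero_adjacency(self):
        A = np.zeros((4, 4))
        T = tom_similarity(A)
        assert (T[~np.eye(4, dtype=bool)] == 0).all()
        assert (np.diag(T) == 1).all()

    def test_complete_triangle_hand_value(self):
        A = np.ones((3, 3)) - np.eye(3)
        T = tom_similarity(A)
        # TOM_12 = (1 + 1) / (2 + 1 - 1) = 1
        assert T[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self, rng):
        C = rng.uniform(size=(30, 30))
        A = (C + C.T) / 2
        np.fill_diagonal(A, 0.0)
        T = tom_similarity(A)
        assert np.abs(T - self._oracle(A)).max() < 1e-12
        assert T.min() >= 0 and T.max() <= 1 + 1e-12


class TestSoftThreshold:
    def test_deterministic_and_bounded(self, planted_expression):
        X, _, _ = planted_expression
        b1, t1 = pick_soft_threshold(X, powers=range(1, 13))
        b2, t2 = pick_soft_threshold(X, powers=range(1, 13))
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)
        ok = t1["sft_rsq"].dropna()
        assert ((ok >= -1) & (ok <= 1)).all()

    def test_noise_falls_back_with_warning(self, rng, caplog):
        X = rng.normal(size=(120, 40))
        import logging

        with caplog.at_level(logging.WARNING, logger="t2dbrain.network"):
            beta, _ = pick_soft_threshold(X, powers=range(1, 8), rsq_cut=0.999)
        assert any("falling back" in r.message for r in caplog.records)
        assert 1 <= beta <= 7


class TestModules:
    def test_planted_modules_recovered(self, planted_expression):
        from sklearn.metrics import adjusted_rand_score

        X, truth, _ = planted_expression
        A = signed_adjacency(X, 6)
        tom = tom_similarity(A)
        labels = detect_modules(1 - tom, min_module_size=30)
        labels = kme_filter(X, labels, 0.7, 30)
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_zero_dissimilarity_pairs_co_assigned(self, planted_expression):
        # duplicate each gene at dissimilarity exactly 0: the pair must land
        # in the same module (average linkage merges zero-distance pairs first)
        X, _, _ = planted_expression
        A = signed_adjacency(X.iloc[:100], 6)
        D = 1 - tom_similarity(A)
        n = D.shape[0]
        Dd = np.zeros((2 * n, 2 * n))
        Dd[:n, :n] = Dd[n:, n:] = Dd[:n, n:] = Dd[n:, :n] = D
        np.fill_diagonal(Dd, 0.0)  # D[i, n+i] = D[i, i] = 0 by construction
        labels = detect_modules(Dd, min_module_size=20)
        assert (labels[:n] == labels[n:]).all()

    def test_noise_mostly_unassigned(self, rng):
        X = rng.normal(size=(200, 50))
        A = signed_adjacency(X, 6)
        labels = detect_modules(1 - tom_similarity(A), min_module_size=40)
        assert (labels == 0).mean() >= 0.9

    def test_gene_order_invariance(self, planted_expression):
        X, _, _ = planted_expression
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(X))
        A = signed_adjacency(X, 6)
        l0 = detect_modules(1 - tom_similarity(A), 30)
        Ap = signed_adjacency(X.iloc[perm], 6)
        lp = detect_modules(1 - tom_similarity(Ap), 30)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(l0[perm], lp) == pytest.approx(1.0)


class TestEigengene:
    def test_identical_genes_recover_common_profile(self):
        rng = np.random.default_rng(3)
        prof = rng.normal(size=25)
        X = np.tile(prof, (6, 1))
        ME = module_eigengene(X, np.ones(6, dtype=int))
        r = np.corrcoef(ME["ME1"], prof)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign anchored to members

    def test_global_sign_flip_invariant(self, planted_expression):
        X, truth, _ = planted_expression
        ME1 = module_eigengene(X.to_numpy(), truth)
        ME2 = module_eigengene(-X.to_numpy(), truth)
        for c in ME1.columns:
            assert np.allclose(ME1[c], -ME2[c]) or np.allclose(ME1[c], ME2[c])
            # anchored: correlation with members positive in both
        assert np.allclose(np.abs(ME1.to_numpy()), np.abs(ME2.to_numpy()))

    def test_pca_optimality(self, planted_expression):
        X, truth, _ = planted_expression
        Xa = X.to_numpy()
        ME = module_eigengene(Xa, truth)
        m = 1
        sub = Xa[truth == m]
        sub = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        me = ME[f"ME{m}"].to_numpy()

        def var_explained(v):
            v = (v - v.mean()) / v.std()
            return float(np.sum((sub @ v / len(v)) ** 2))

        best_gene = max(var_explained(g) for g in sub)
        assert var_explained(me) >= best_gene - 1e-9


class TestMergeAndFilter:
    def test_same_factor_modules_merge(self, rng):
        f = rng.normal(size=40)
        X = np.vstack([f + rng.normal(0, 0.3, (30, 40)),
                       f + rng.normal(0, 0.3, (30, 40))])
        labels = np.array([1] * 30 + [2] * 30)
        merged = merge_modules(X, labels, 0.15)
        assert len(set(merged) - {0}) == 1

    def test_orthogonal_factors_do_not_merge(self, planted_expression):
        X, truth, _ = planted_expression
        merged = merge_modules(X.to_numpy(), truth, 0.15)
        assert len(set(merged) - {0}) == 5

    def test_merge_idempotent(self, planted_expression):
        X, truth, _ = planted_expression
        once = merge_modules(X.to_numpy(), truth, 0.15)
        twice = merge_modules(X.to_numpy(), once, 0.15)
        assert (once == twice).all()

    def test_kme_filter_removes_noise_gene(self, planted_expression, rng):
        X, truth, _ = planted_expression
        Xa = np.vstack([X.to_numpy(), rng.normal(size=(1, X.shape[1]))])
        labels = np.append(truth, 1)  # noise gene claimed by module 1
        out = kme_filter(Xa, labels, min_kme=0.7, min_module_size=10)
        assert out[-1] == 0
        # core planted genes retained
        assert (out[:40] == 1).mean() > 0.9

    def test_min_kme_zero_keeps_labels(self, planted_expression):
        X, truth, _ = planted_expression
        out = kme_filter(X.to_numpy(), truth, min_kme=0.0, min_module_size=2)
        assert (out == truth).all()


class TestTraitStats:
    def test_zero_correlation_p_one(self):
        ME = pd.DataFrame({"ME1": [1.0, -1.0, 1.0, -1.0]})
        stats_tab = module_trait_stats(ME, [1, 1, 0, 0])
        assert stats_tab.loc["ME1", "r"] == pytest.approx(0.0)
        assert stats_tab.loc["ME1", "p"] == pytest.approx(1.0)

    def test_closed_form_t_inversion(self):
        # r = 0.374 at n = 27 sits almost exactly at p = 0.05
        from scipy import stats as ss

        n, r = 27, 0.374
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * ss.t.sf(t, n - 2)
        assert p == pytest.approx(0.05, abs=0.006)
        rng = np.random.default_rng(0)
        me = rng.normal(size=n)
        status = rng.integers(0, 2, n)
        tab = module_trait_stats(pd.DataFrame({"ME1": me}), status)
        rr = tab.loc["ME1", "r"]
        tt = rr * np.sqrt((n - 2) / (1 - rr**2))
        assert tab.loc["ME1", "p"] == pytest.approx(2 * ss.t.sf(abs(tt), n - 2))


class TestGsMm:
    def test_bounds_and_null_center(self, planted_expression, rng):
        X, truth, _ = planted_expression
        ME = module_eigengene(X.to_numpy(), truth)
        status = rng.integers(0, 2, X.shape[1])
        gs, mm, corr = gs_mm(X, truth, ME, status)
        assert gs.abs().max() <= 1
        assert mm.abs().to_numpy().max() <= 1
        assert abs(gs.mean()) < 0.1  # permuted/random status: GS centred at 0

    def test_status_driven_module_couples_gs_mm(self):
        rng = np.random.default_rng(7)
        n = 80
        status = np.array([1] * 40 + [0] * 40)
        f = status * 1.5 + rng.normal(size=n)
        load = rng.uniform(0.4, 1.2, 50)
        X = load[:, None] * f[None, :] + rng.normal(0, 1.0, (50, n))
        labels = np.ones(50, dtype=int)
        ME = module_eigengene(X, labels)
        gs, mm, corr = gs_mm(X, labels, ME, status)
        assert corr.loc[1, "cor_gs_mm"] > 0
        assert corr.loc[1, "p"] < 0.05


class TestHubs:
    def test_star_topology_center_is_top_hub(self):
        rng = np.random.default_rng(5)
        hubsig = rng.normal(size=100)
        X = np.vstack([hubsig] +
                      [0.5 * hubsig + rng.normal(0, 1.2, 100) for _ in range(9)])
        A = signed_adjacency(X, 2)
        labels = np.ones(10, dtype=int)
        ids = [f"g{i}" for i in range(10)]
        out = hub_genes(A, labels, 1, gene_ids=ids, top_edges=9, top_fraction=0.1)
        assert out.iloc[0]["gene_id"] == "g0"

    def test_ceiling_arithmetic(self, planted_expression):
        X, truth, _ = planted_expression
        A = signed_adjacency(X.to_numpy(), 6)
        out = hub_genes(A, truth, 1, top_edges=500, top_fraction=0.05)
        assert out["is_hub"].sum() == int(np.ceil(0.05 * (truth == 1).sum()))

    def test_top_edges_saturation(self, planted_expression):
        X, truth, _ = planted_expression
        A = signed_adjacency(X.to_numpy(), 6)
        n_edges = 40 * 39 // 2
        a = hub_genes(A, truth, 1, top_edges=n_edges, top_fraction=0.05)
        b = hub_genes(A, truth, 1, top_edges=n_edges * 10, top_fraction=0.05)
        assert set(a.loc[a["is_hub"], "gene_id"]) == set(b.loc[b["is_hub"], "gene_id"])

    def test_tiny_module_rejected(self, planted_expression):
        X, truth, _ = planted_expression
        A = signed_adjacency(X.to_numpy(), 6)
        with pytest.raises(ValueError):
            hub_genes(A, np.where(truth == 1, 0, truth), 1)


def test_full_stage_with_config_validation(planted_expression):
    X, truth, _ = planted_expression
    with pytest.raises(ValueError):
        NetworkConfig(merge_cut_height=1.5).validate()
    rng = np.random.default_rng(9)
    status = rng.integers(0, 2, X.shape[1])
    res = run_network(X, status, NetworkConfig(min_module_size=30))
    assert res.module_labels.max() >= 4
    assert set(res.eigengenes.columns) == {f"ME{m}" for m in
                                           sorted(set(res.module_labels) - {0})}
    assert (res.eigengenes.std(ddof=1) - 1).abs().max() < 1e-8


def test_edge_export_tsv_and_graphml(tmp_path, planted_expression):
    import networkx as nx

    from t2dbrain.network import export_top_edges

    X, truth, _ = planted_expression
    A = signed_adjacency(X.to_numpy(), 6)
    ids = X.index.to_numpy()
    tsv = tmp_path / "edges.tsv"
    gml = tmp_path / "edges.graphml"
    export_top_edges(A, truth, 1, ids, tsv, gml, top_edges=50)
    edges = pd.read_csv(tsv, sep="\t")
    assert len(edges) == 50
    assert (edges["weight"].diff().dropna() <= 1e-12).all()  # descending
    g = nx.read_graphml(gml)
    assert g.number_of_edges() == 50
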