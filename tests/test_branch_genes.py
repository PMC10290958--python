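"""Branch test: BH oracle, nested-model properties, relabeling symmetry,
power/calibration on planted data, kinetic clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from fatetrace.branch_genes import (avg_logfc, bh_qvalues, fit_branch_test,
                                    filter_branch_genes, kinetic_clusters,
                                    natural_spline_basis)
from fatetrace.divergence import smooth_branch_curves
from fatetrace.io_qc import normalize_log
from fatetrace.synthetic import SimConfig, simulate_bifurcation


def bh_oracle(p):
    """Direct evaluation: q_i = min over tail of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(tail))
    return q


class TestBH:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_oracle(self, p):
        np.testing.assert_allclose(bh_qvalues(np.array(p)), bh_oracle(p),
                                   atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=100)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_q_geq_p(self, rng):
        p = rng.uniform(size=50)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)


class TestSplineBasis:
    def test_shape_and_rank(self, rng):
        x = rng.uniform(0, 100, 200)
        B = natural_spline_basis(x, df=3)
        assert B.shape == (200, 3)
        X = np.column_stack([np.ones(200), B])
        assert np.linalg.matrix_rank(X) == 4

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.ones(10), df=3)


def synthetic_expr(meta, fn_u, fn_l, noise=0.0, seed=0):
    """Direct log-space expression builder for closed-form tests."""
    rng = np.random.default_rng(seed)
    t = meta.pseudotime_stretched.to_numpy()
    branch = meta.branch.to_numpy()
    y = np.where(branch == "U", fn_u(t), fn_l(t)).astype(float)
    if noise:
        y = y + rng.normal(0, noise, len(y))
    return y[:, None], np.array(["G0"], dtype=object), \
        meta.cell_id.to_numpy()


def ul_meta(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "branch": rng.choice(["U", "L"], size=n),
        "pseudotime_stretched": rng.uniform(0, 100, n),
    })


class TestAvgLogFC:
    def test_identical_branches_zero(self):
        # paired design: same pseudotimes in both branches, identical
        # curves -> branch means coincide exactly
        t = np.linspace(0, 100, 50)
        meta = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(100)],
            "branch": ["U"] * 50 + ["L"] * 50,
            "pseudotime_stretched": np.concatenate([t, t]),
        })
        expr = synthetic_expr(meta, lambda t: 0.01 * t, lambda t: 0.01 * t)
        assert avg_logfc(expr, meta)["G0"] == pytest.approx(0.0)

    def test_swap_antisymmetry(self):
        meta = ul_meta(seed=1)
        expr = synthetic_expr(meta, lambda t: 1 + 0.02 * t, lambda t: 0.5,
                              noise=0.1, seed=2)
        lfc = avg_logfc(expr, meta)["G0"]
        swapped = meta.assign(branch=meta.branch.map({"U": "L", "L": "U"}))
        lfc_sw = avg_logfc(expr, swapped)["G0"]
        assert lfc_sw == pytest.approx(-lfc)

    def test_planted_ramp_closed_form(self):
        # ramp from t*=0 with full-strength shift delta at t=100:
        # expected avg logFC = delta * mean(t_U) / 100 computed exactly
        # from the same cells (independent arithmetic oracle)
        meta = ul_meta(n=2000, seed=3)
        delta = 0.8
        expr = synthetic_expr(meta, lambda t: delta * t / 100.0,
                              lambda t: 0.0)
        t_u = meta.loc[meta.branch == "U", "pseudotime_stretched"]
        expected = delta * t_u.mean() / 100.0
        assert avg_logfc(expr, meta)["G0"] == pytest.approx(expected)

    def test_empty_branch_raises(self):
        meta = ul_meta().assign(branch="U")
        expr = synthetic_expr(meta, lambda t: t, lambda t: t)
        with pytest.raises(ValueError, match="non-empty"):
            avg_logfc(expr, meta)


class TestFitBranchTest:
    def test_lr_nonnegative_and_p_valid(self, planted_norm):
        nm, meta, _ = planted_norm
        res = fit_branch_test(nm, meta)
        assert (res.lr >= 0).all()
        assert res.p.between(0, 1).all()
        assert res.q.between(0, 1).all()

    def test_zero_variance_gene_p1(self):
        meta = ul_meta(n=100)
        y = np.zeros((100, 2))
        y[:, 1] = np.arange(100.0)
        res = fit_branch_test((y, np.array(["flat", "var"]),
                               meta.cell_id.to_numpy()), meta)
        assert res.set_index("gene_id").loc["flat", "p"] == 1.0

    def test_relabel_invariance_except_lfc_sign(self, planted_norm):
        nm, meta, _ = planted_norm
        res = fit_branch_test(nm, meta)
        swapped = meta.assign(branch=meta.branch.map(
            {"U": "L", "L": "U", "P": "P"}))
        res_sw = fit_branch_test(nm, swapped)
        np.testing.assert_allclose(res.lr, res_sw.lr, atol=1e-8)
        np.testing.assert_allclose(res.avg_logfc, -res_sw.avg_logfc,
                                   atol=1e-10)

    def test_planted_effect_detected(self, planted_norm):
        nm, meta, truth = planted_norm
        res = fit_branch_test(nm, meta).set_index("gene_id")
        planted = truth.branch_gene_ids()
        assert (res.loc[planted, "q"] < 0.05).mean() >= 0.9

    def test_null_calibration(self, null_sim):
        cm, meta, _ = null_sim
        nm = normalize_log(cm)
        res = fit_branch_test(nm, meta)
        n = len(res)
        bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
        assert (res.q < 0.05).mean() <= bound

    def test_nb_family_smoke(self, planted):
        cm, meta, truth = planted
        nm = normalize_log(cm)
        genes = list(truth.branch_gene_ids()[:3]) + \
            list(truth.genes.loc[~truth.genes.is_branch_gene,
                                 "gene_id"][:3])
        idx = [list(cm.gene_ids).index(g) for g in genes]
        sub_nm = (nm.values[:, idx], np.array(genes), nm.cell_ids)
        sub_counts = (cm.values.toarray()[:, idx], np.array(genes),
                      cm.cell_ids)
        res = fit_branch_test(sub_nm, meta, family="nb", counts=sub_counts)
        res = res.set_index("gene_id")
        assert (res.loc[genes[:3], "p"] < 0.05).all()
        assert res.p.between(0, 1).all()


class TestFilter:
    def test_strict_boundaries(self):
        res = pd.DataFrame({
            "gene_id": ["keep", "lfc_at_bound", "q_at_bound"],
            "q": [0.04, 0.04, 0.05],
            "avg_logfc": [0.31, 0.30, 0.31],
        })
        assert filter_branch_genes(res) == ["keep"]

    def test_recall_on_planted(self, planted_norm):
        nm, meta, truth = planted_norm
        res = fit_branch_test(nm, meta)
        kept = set(filter_branch_genes(res))
        planted = set(truth.branch_gene_ids())
        assert len(kept & planted) / len(planted) >= 0.9


@pytest.fixture(scope="module")
def archetype_curves():
    cfg = SimConfig(n_cells=1500, n_genes=400, frac_branch_genes=0.3,
                    divergence_times=(10.0,), effect_size=2.0,
                    nb_dispersion=0.1, branch_gene_boost=8.0,
                    split_time=20.0, seed=21)
    cm, meta, truth = simulate_bifurcation(cfg)
    nm = normalize_log(cm)
    bg = truth.genes[truth.genes.is_branch_gene]
    curves = smooth_branch_curves(nm, meta, genes=bg.gene_id.tolist())
    return curves, bg


class TestKineticClusters:

    def test_recovers_planted_archetypes(self, archetype_curves):
        curves, bg = archetype_curves
        labels = kinetic_clusters(curves, bg.gene_id.tolist(), k=6)
        truth_arch = bg.set_index("gene_id").loc[labels.index, "archetype"]
        assert adjusted_rand_score(truth_arch, labels) >= 0.8

    def test_duplicate_curve_same_cluster(self, archetype_curves):
        curves, bg = archetype_curves
        genes = bg.gene_id.tolist()

        class Dup:
            def get(self, gid):
                real = gid[4:] if str(gid).startswith("dup:") else gid
                return curves.get(real)

        labels = kinetic_clusters(Dup(), genes + [f"dup:{genes[0]}"], k=6)
        assert labels[genes[0]] == labels[f"dup:{genes[0]}"]

    def test_k1_degenerate(self, archetype_curves):
        curves, bg = archetype_curves
        labels = kinetic_clusters(curves, bg.gene_id.tolist()[:10], k=1)
        assert set(labels) == {1}

    def test_too_few_genes_raises(self, archetype_curves):
        curves, bg = archetype_curves
        with pytest.raises(ValueError, match="at least"):
            kinetic_clusters(curves, bg.gene_id.tolist()[:3], k=6)
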