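"""Model-wise interpretation: exact first/second-order scores, decoy FDR,
selection, overlaps and genetic correlation."""

import numpy as np
import pytest
from scipy import stats

import linaprs as lp
from linaprs.interpret import (ImportanceTable, estimate_fdr, fdr_curve,
                               interaction_importance, model_importance,
                               multiway_overlap, select_at_fdr)

from conftest import make_constant_attention


def _table(real_scores, decoy_scores, trait="t0"):
    scores = np.concatenate([real_scores, decoy_scores])[None, :]
    m = len(real_scores) + len(decoy_scores)
    return ImportanceTable(
        scores=scores,
        snp_ids=np.array([f"s{i}" for i in range(m)], dtype=object),
        is_decoy=np.array([False] * len(real_scores) + [True] * len(decoy_scores)),
        chromosomes=np.array(["1"] * m, dtype=object),
        trait_names=np.array([trait], dtype=object),
        n_subjects_used=1,
    )


class TestModelImportance:
    def test_constant_attention_closed_form(self):
        cfg = lp.MTLModelConfig(n_snps=3, n_traits=2, hidden_sizes=(3, 2, 2))
        a0 = np.array([0.5, -2.0, 1.5])
        model = make_constant_attention(lp.init_model(cfg, seed=0), a0)
        X = np.random.default_rng(0).integers(0, 3, size=(20, 3)).astype(float)
        table = model_importance(model, X)
        np.testing.assert_allclose(table.scores, np.abs(model.K * a0), rtol=1e-12)

    def test_zero_coefficient_row_gives_zero_scores(self, tiny_model):
        tiny_model.K[0, :] = 0.0
        X = np.random.default_rng(1).integers(0, 3, size=(10, 20)).astype(float)
        table = model_importance(tiny_model, X)
        assert (table.scores[0] == 0).all()
        assert (table.scores[1] != 0).any()

    def test_matches_brute_force_subject_loop(self, ):
        cfg = lp.MTLModelConfig(n_snps=5, n_traits=2, hidden_sizes=(4, 3, 3))
        model = lp.init_model(cfg, seed=2)
        X = np.random.default_rng(2).integers(0, 3, size=(15, 5)).astype(float)
        table = model_importance(model, X)
        # brute force: per-subject instance coefficients, then signed mean
        expected = np.zeros((2, 5))
        for x in X:
            A = model.attention(x[None])[0]
            for t in range(2):
                for j in range(5):
                    expected[t, j] += model.K[t, j] * A[j]
        expected = np.abs(expected / len(X))
        np.testing.assert_allclose(table.scores, expected, rtol=1e-10)

    def test_abs_mean_aggregation_bounds_signed_mean(self, tiny_model):
        X = np.random.default_rng(3).integers(0, 3, size=(10, 20)).astype(float)
        signed = model_importance(tiny_model, X, aggregation="signed_mean").scores
        absolute = model_importance(tiny_model, X, aggregation="abs_mean").scores
        assert (absolute >= signed - 1e-12).all()

    def test_train_mode_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            model_importance(tiny_model, np.zeros((2, 20)), mode="train")

    def test_sex_chromosomes_dropped(self, tiny_model):
        X = np.random.default_rng(4).integers(0, 3, size=(6, 20)).astype(float)
        chroms = np.array(["1"] * 10 + ["X"] * 5 + ["22"] * 4 + ["Y"], dtype=object)
        table = model_importance(tiny_model, X, chromosomes=chroms)
        assert table.scores.shape[1] == 14
        assert set(table.chromosomes) <= {"1", "22"}


class TestJacobian:
    def test_constant_attention_has_zero_jacobian(self):
        cfg = lp.MTLModelConfig(n_snps=4, n_traits=1, hidden_sizes=(3, 2, 2))
        model = make_constant_attention(lp.init_model(cfg, seed=0), np.ones(4))
        J = lp.attention_jacobian(model, np.array([1.0, 0.0, 2.0, 1.0]))
        assert np.allclose(J, 0.0)

    def test_pure_linear_network_recovers_matrix(self):
        # strictly positive pre-activations keep every leaky-ReLU in its
        # identity regime, so the eval map is the product of the Dense maps
        cfg = lp.MTLModelConfig(n_snps=2, n_traits=1, hidden_sizes=(2, 2, 2))
        model = lp.init_model(cfg, seed=0)
        from linaprs._nn import BatchNorm, Dense
        Ws = []
        for layer in model.net.layers:
            if isinstance(layer, Dense):
                layer.W[...] = np.abs(np.random.default_rng(len(Ws)).normal(size=layer.W.shape))
                layer.b[...] = 5.0  # keeps hidden pre-activations positive
                Ws.append(layer.W)
            elif isinstance(layer, BatchNorm):
                layer.running_var[...] = 1.0 - layer.eps
        x = np.array([0.5, 1.0])
        J = lp.attention_jacobian(model, x)
        expected = (Ws[0] @ Ws[1] @ Ws[2] @ Ws[3]).T
        np.testing.assert_allclose(J, expected, rtol=1e-10)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(7)
        for seed in range(3):
            cfg = lp.MTLModelConfig(n_snps=6, n_traits=1, hidden_sizes=(5, 4, 3))
            model = lp.init_model(cfg, seed=seed)
            x = rng.normal(size=6)
            J = lp.attention_jacobian(model, x)
            h = 1e-4
            Jfd = np.zeros((6, 6))
            for k in range(6):
                xp, xm = x.copy(), x.copy()
                xp[k] += h
                xm[k] -= h
                Jfd[:, k] = (model.attention(xp[None])[0] - model.attention(xm[None])[0]) / (2 * h)
            assert np.abs(J - Jfd).max() <= 1e-4


class TestInteractions:
    def test_constant_attention_has_no_interactions(self):
        cfg = lp.MTLModelConfig(n_snps=4, n_traits=2, hidden_sizes=(3, 2, 2))
        model = make_constant_attention(lp.init_model(cfg, seed=0), np.ones(4))
        H = lp.interaction_scores(model, np.array([1.0, 2.0, 0.0, 1.0]), 0).matrix
        assert np.allclose(H, 0.0)  # purely linear model

    def test_symmetry_by_construction(self, tiny_model):
        x = np.random.default_rng(8).normal(size=20)
        H = lp.interaction_scores(tiny_model, x, 1).matrix
        np.testing.assert_allclose(H, H.T)

    def test_matches_finite_difference_hessian(self):
        rng = np.random.default_rng(9)
        for seed in range(3):
            cfg = lp.MTLModelConfig(n_snps=5, n_traits=2, hidden_sizes=(4, 3, 3))
            model = lp.init_model(cfg, seed=seed + 10)
            x = rng.normal(size=5)
            H = lp.interaction_scores(model, x, 0).matrix
            Hfd = _fd_hessian(lambda v: model.scores(v[None])[0, 0], x, 1e-4)
            scale = max(np.abs(Hfd).max(), 1e-9)
            assert np.abs(H - Hfd).max() / scale <= 1e-5

    def test_model_wise_interaction_importance_nonnegative(self, tiny_model):
        X = np.random.default_rng(10).normal(size=(4, 20))
        M = interaction_importance(tiny_model, X, 0)
        assert (M >= 0).all() and np.allclose(M, M.T)


def _fd_hessian(f, x, h):
    """Central second differences; exact (to rounding) for the piecewise-
    quadratic pre-sigmoid output away from activation kinks."""
    m = len(x)
    H = np.zeros((m, m))
    for k in range(m):
        for l in range(m):
            if k == l:
                xp, xm = x.copy(), x.copy()
                xp[k] += h
                xm[k] -= h
                H[k, k] = (f(xp) - 2 * f(x) + f(xm)) / (h * h)
            else:
                vals = 0.0
                for sk, sl, sign in ((h, h, 1), (h, -h, -1), (-h, h, -1), (-h, -h, 1)):
                    xx = x.copy()
                    xx[k] += sk
                    xx[l] += sl
                    vals += sign * f(xx)
                H[k, l] = vals / (4 * h * h)
    return H


class TestFDR:
    def test_published_count_ratio_rounds_to_five_percent(self):
        # 3091 decoys vs 59,350 reals above the 5%-FDR threshold
        assert estimate_fdr(3091, 59350) == pytest.approx(0.0521, abs=5e-4)
        assert round(100 * estimate_fdr(3091, 59350)) == 5
        table = _table(np.concatenate([np.full(59350, 1.0), np.full(100, 0.1)]),
                       np.concatenate([np.full(3091, 1.0), np.full(56359, 0.1)]))
        curve = fdr_curve(table, "t0")
        at_top = np.where(curve.thresholds == 1.0)[0][0]
        assert curve.n_real_above[at_top] == 59350
        assert curve.n_decoy_above[at_top] == 3091
        assert round(100 * curve.fdr_estimate[at_top]) == 5

    def test_zero_decoys_above_gives_zero_fdr(self):
        table = _table([0.9, 0.8, 0.7] + [0.1] * 45, [0.2] * 48)
        curve = fdr_curve(table, "t0")
        assert curve.fdr_estimate[0] == 0.0  # top threshold: 0 decoys / reals

    def test_all_equal_scores_degenerate(self):
        table = _table([0.5] * 10, [0.5] * 4)
        curve = fdr_curve(table, "t0")
        assert len(curve.thresholds) == 1
        assert curve.fdr_estimate[0] == pytest.approx(4 / 10)

    def test_counts_non_increasing_in_threshold(self, tiny_model, tiny_cohort):
        _, geno, _, _ = tiny_cohort
        aug = lp.make_decoys(geno, seed=0)
        X = aug.genotypes[:50].astype(float)
        cfg = lp.MTLModelConfig(n_snps=aug.n_snps, n_traits=2, hidden_sizes=(8, 6, 4))
        model = lp.init_model(cfg, seed=0)
        table = model_importance(model, X, is_decoy=aug.is_decoy)
        curve = fdr_curve(table, 0)
        # thresholds descend, inclusive counts ascend along the array
        assert (np.diff(curve.thresholds) < 0).all()
        assert (np.diff(curve.n_real_above) >= 0).all()
        assert (np.diff(curve.n_decoy_above) >= 0).all()

    def test_no_decoys_errors_toward_make_decoys(self):
        table = ImportanceTable(
            scores=np.array([[0.1, 0.2]]),
            snp_ids=np.array(["a", "b"], dtype=object),
            is_decoy=np.array([False, False]),
            chromosomes=np.array(["1", "1"], dtype=object),
            trait_names=np.array(["t0"], dtype=object),
            n_subjects_used=1,
        )
        with pytest.raises(ValueError, match="make_decoys"):
            fdr_curve(table, "t0")


class TestSelection:
    @staticmethod
    def _brute_force_select(real, decoy, target):
        """Independent oracle: exhaustive scan over every distinct score as an
        inclusive threshold; take the smallest feasible one."""
        scores = np.concatenate([real, decoy])
        feasible = []
        for t in np.unique(scores):
            n_r = int((np.asarray(real) >= t).sum())
            n_d = int((np.asarray(decoy) >= t).sum())
            if n_r > 0 and n_d / n_r <= target:
                feasible.append(t)
        if not feasible:
            return None, set()
        thr = min(feasible)
        return thr, {f"s{i}" for i, s in enumerate(real) if s >= thr}

    @pytest.mark.parametrize("target", [0.5, 0.4, 0.2, 0.05])
    def test_matches_exhaustive_threshold_scan(self, target):
        real = [0.9, 0.8, 0.7, 0.2]
        decoy = [0.75, 0.1, 0.05, 0.01]
        table = _table(real, decoy)
        curve = fdr_curve(table, "t0")
        sel, thr = select_at_fdr(curve, table, "t0", target_fdr=target)
        exp_thr, exp_sel = self._brute_force_select(real, decoy, target)
        if exp_thr is None:
            assert sel == []
        else:
            assert thr == pytest.approx(exp_thr)
            assert set(sel) == exp_sel

    def test_selected_set_meets_target_at_its_threshold(self):
        # the inclusive-tie convention: 1 decoy / 3 reals = 0.33 at 0.7
        table = _table([0.9, 0.8, 0.7, 0.2], [0.75, 0.1, 0.05, 0.01])
        curve = fdr_curve(table, "t0")
        i = np.where(curve.thresholds == 0.7)[0][0]
        assert curve.n_decoy_above[i] == 1 and curve.n_real_above[i] == 3
        assert curve.fdr_estimate[i] == pytest.approx(1 / 3)

    def test_vacuous_target_selects_all_reals(self):
        table = _table([0.9, 0.5, 0.2], [0.8, 0.4, 0.1])
        curve = fdr_curve(table, "t0")
        sel, _ = select_at_fdr(curve, table, "t0", target_fdr=1.0)
        assert set(sel) == {"s0", "s1", "s2"}

    def test_adversarial_decoys_give_empty_set(self):
        table = _table([0.3, 0.2, 0.1], [0.9, 0.8, 0.7])
        curve = fdr_curve(table, "t0")
        sel, thr = select_at_fdr(curve, table, "t0", target_fdr=0.05)
        assert sel == [] and thr == np.inf


class TestOverlapAndCorrelation:
    def test_pairwise_counts(self):
        mat = lp.overlap_table({"a": ["x", "y", "z"], "b": ["y", "z", "w"]})
        assert mat.loc["a", "b"] == 2 and mat.loc["b", "a"] == 2
        assert mat.loc["a", "a"] == 3

    def test_identical_sets_full_overlap(self):
        mat = lp.overlap_table({"a": ["x", "y"], "b": ["x", "y"]})
        assert mat.loc["a", "b"] == 2

    def test_three_way_matches_brute_force(self):
        rng = np.random.default_rng(0)
        universe = [f"s{i}" for i in range(1000)]
        sets = {f"t{k}": list(rng.choice(universe, size=sz, replace=False))
                for k, sz in enumerate((25, 36, 48))}
        expected = len(set(sets["t0"]) & set(sets["t1"]) & set(sets["t2"]))
        assert multiway_overlap(sets, ["t0", "t1", "t2"]) == expected

    def _two_trait_table(self, sa, sb):
        m = len(sa)
        return ImportanceTable(
            scores=np.vstack([sa, sb]),
            snp_ids=np.array([f"s{i}" for i in range(m)], dtype=object),
            is_decoy=np.zeros(m, dtype=bool),
            chromosomes=np.array(["1"] * m, dtype=object),
            trait_names=np.array(["a", "b"], dtype=object),
            n_subjects_used=1,
        )

    def test_identical_scores_correlate_perfectly(self):
        s = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        table = self._two_trait_table(s, s)
        sets = {"a": ["s0", "s1", "s2"], "b": ["s2", "s3", "s4"]}
        assert lp.genetic_correlation(table, sets, "a", "b") == pytest.approx(1.0)

    def test_reversed_ranks_correlate_negatively(self):
        s = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        table = self._two_trait_table(s, s[::-1])
        sets = {"a": list(table.snp_ids), "b": list(table.snp_ids)}
        assert lp.genetic_correlation(table, sets, "a", "b") == pytest.approx(-1.0)

    def test_hand_example_matches_rank_then_pearson(self):
        sa = np.array([0.9, 0.1, 0.5, 0.5, 0.3, 0.8])
        sb = np.array([0.2, 0.7, 0.6, 0.1, 0.3, 0.9])
        table = self._two_trait_table(sa, sb)
        sets = {"a": list(table.snp_ids), "b": []}
        rho = lp.genetic_correlation(table, sets, "a", "b")
        ra = stats.rankdata(sa)  # mid-rank ties
        rb = stats.rankdata(sb)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_tiny_union_undefined(self):
        table = self._two_trait_table(np.array([0.1]), np.array([0.2]))
        with pytest.raises(ValueError):
            lp.genetic_correlation(table, {"a": ["s0"], "b": ["s0"]}, "a", "b")
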