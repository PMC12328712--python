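import numpy as np
import pytest

from cellmkl import (
    GroupedDesign,
    LabelVector,
    RunConfig,
    compute_metrics,
    cross_validate,
    fit_group_lasso,
    lambda_endpoints,
    lambda_grid,
    lambda_max,
    make_dataset,
    predict_scores,
)
from cellmkl.model import rebalance_train, stratified_split
from oracles import group_lasso_bcd, objective_value, random_grouped_problem, rank_auroc


def make_design(rng, n=60, n_groups=3, width=4, signal=True):
    Z, y, blocks = random_grouped_problem(rng, n, n_groups, width, signal)
    return GroupedDesign(Z, blocks), y


class TestFitGroupLasso:
    def test_zero_solution_at_and_above_lambda_max(self, rng):
        design, y = make_design(rng)
        lmax = lambda_max(design, y)
        fit = fit_group_lasso(design, y, 1.01 * lmax)
        assert np.all(fit.beta == 0.0)
        assert all(e == 0.0 for e in fit.eta.values())
        # just below λ_max something activates
        fit2 = fit_group_lasso(design, y, 0.95 * lmax)
        assert any(e > 0 for e in fit2.eta.values())

    def test_orthonormal_single_group_closed_form(self, rng):
        """With Z̃ᵀZ̃ = I the solution is the block soft-threshold of Z̃ᵀỹ."""
        n, p = 40, 4
        raw = rng.normal(size=(n, p))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = np.where(rng.random(n) > 0.5, 1, -1)
        y[:2] = [1, -1]
        design = GroupedDesign(q, {"G": slice(0, p)})
        c = (q - q.mean(0)).T @ (y - y.mean())
        cn = np.linalg.norm(c)
        for lam in (0.25 * cn, 0.5 * cn, 0.9 * cn):
            fit = fit_group_lasso(design, y, lam, tol=1e-12, max_iter=20000)
            expected = (1 - lam / cn) * c
            np.testing.assert_allclose(fit.beta, expected, atol=1e-6)
            assert fit.eta["G"] == pytest.approx(cn - lam, abs=1e-6)

    def test_matches_independent_bcd_oracle(self, rng):
        """FISTA solution ties an exact block-coordinate-descent oracle."""
        for _ in range(5):
            n_groups = int(rng.integers(3, 7))
            design, y = make_design(rng, n=60, n_groups=n_groups)
            lmax = lambda_max(design, y)
            lam = 0.3 * lmax
            fit = fit_group_lasso(design, y, lam, tol=1e-12, max_iter=30000)
            beta_o = group_lasso_bcd(design.Z, y, design.blocks, lam)
            obj_f = objective_value(design.Z, y, design.blocks, fit.beta, lam)
            obj_o = objective_value(design.Z, y, design.blocks, beta_o, lam)
            assert abs(obj_f - obj_o) <= 1e-6 * max(abs(obj_o), 1e-12)

    def test_objective_trace_non_increasing(self, rng):
        design, y = make_design(rng, n=80, n_groups=4)
        fit = fit_group_lasso(design, y, 0.2 * lambda_max(design, y))
        diffs = np.diff(fit.objective_trace)
        assert (diffs <= 1e-9).all()

    def test_eta_equals_block_norms(self, rng):
        design, y = make_design(rng)
        fit = fit_group_lasso(design, y, 0.3 * lambda_max(design, y))
        for g, sl in design.blocks.items():
            assert fit.eta[g] == pytest.approx(np.linalg.norm(fit.beta[sl]))

    def test_single_class_labels_rejected(self, rng):
        design, _ = make_design(rng)
        with pytest.raises(ValueError, match="single class"):
            fit_group_lasso(design, np.ones(design.Z.shape[0]), 1.0)


class TestLambdaProtocol:
    def test_endpoints_bracket_activity(self, rng):
        design, y = make_design(rng, n=100, n_groups=4)
        lam_all, lam_one = lambda_endpoints(design, y)
        assert lam_all < lam_one
        fit_one = fit_group_lasso(design, y, lam_one)
        fit_all = fit_group_lasso(design, y, lam_all)
        assert len(fit_one.active_groups) == 1
        assert len(fit_all.active_groups) == len(design.blocks)

    def test_lam_one_selects_the_signal_group(self, rng):
        """All signal in one group: it must be the last survivor, and a
        dense λ sweep agrees on the first group to activate."""
        n, w = 120, 5
        Z = rng.normal(size=(n, 2 * w))
        coef = np.zeros(2 * w)
        coef[:w] = rng.normal(size=w) + 1
        y = np.where(Z @ coef > 0, 1, -1)
        design = GroupedDesign(Z, {"signal": slice(0, w), "noise": slice(w, 2 * w)})
        lam_all, lam_one = lambda_endpoints(design, y)
        fit = fit_group_lasso(design, y, lam_one)
        assert fit.active_groups == ["signal"]
        lmax = lambda_max(design, y)
        for lam in np.linspace(lam_one, lmax * 0.999, 25):
            active = fit_group_lasso(design, y, lam).active_groups
            assert active in ([], ["signal"])

    def test_grid_shape_and_spacing(self):
        grid = lambda_grid(0.1, 1.0)
        assert len(grid) == 10
        assert grid[0] == pytest.approx(0.1) and grid[-1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diff(grid), 0.1, atol=1e-12)
        assert all(b > a for a, b in zip(grid, grid[1:]))
        with pytest.raises(ValueError, match="lam_all < lam_one"):
            lambda_grid(1.0, 0.5)

    def test_active_count_monotone_in_lambda(self, small_run):
        """More regularization keeps fewer groups (≤1 transient violation)."""
        w = small_run.weights
        for _, rep in w.groupby("replicate"):
            counts = rep.groupby("lam_index")["active"].sum().sort_index()
            increases = np.diff(counts.to_numpy())
            assert (increases[increases > 0].sum()) <= 1


class TestCrossValidate:
    def _mats(self, ds):
        return {"RNA": ds.rna}, {"RNA": ds.gene_sets}

    def test_single_value_grid_returned_unchanged(self):
        ds = make_dataset(n_cells=80, n_groups=4, group_size=5, seed=2)
        mats, grp = self._mats(ds)
        got = cross_validate(mats, grp, ds.labels, [0.7], RunConfig(D=10), seed=1)
        assert got == 0.7

    def test_cv_choice_near_grid_optimum(self, small_dataset, small_run):
        """Test AUROC at the CV λ tracks the best grid λ.

        The one-standard-error rule gives up at most ~1 fold-SE of
        validation AUROC for sparsity; on this 150-cell fixture the fold
        SE is ~0.03, hence the 0.05 band."""
        m = small_run.metrics
        best = m[m.is_cv_best].groupby("replicate")["auroc"].first()
        grid_max = m.groupby("replicate")["auroc"].max()
        assert (best.mean()) >= grid_max.mean() - 0.05

    def test_saturated_scores_resolve_to_sparser_lambda(self):
        """When every λ performs identically the larger λ must win."""
        ds = make_dataset(n_cells=80, n_groups=4, group_size=5, effect=0.0, seed=3)
        mats, grp = self._mats(ds)
        # λ's far above λ_max: all-zero models, identical 0.5 AUROC
        got = cross_validate(mats, grp, ds.labels, [1e6, 2e6], RunConfig(D=10), seed=1)
        assert got == 2e6


class TestPredictAndMetrics:
    def test_zero_model_scores_intercept_and_half_auroc(self, rng):
        design, y = make_design(rng)
        fit = fit_group_lasso(design, y, 1.5 * lambda_max(design, y))
        scores = predict_scores(fit, design)
        np.testing.assert_allclose(scores, fit.intercept)
        assert compute_metrics(scores, y).auroc == pytest.approx(0.5)

    def test_separable_training_data_perfect_auroc(self, rng):
        Z = rng.normal(size=(300, 12))
        w = rng.normal(size=12)
        margin = Z @ w
        keep = np.abs(margin) > 1.0  # wide-margin separable subset
        Z, margin = Z[keep][:80], margin[keep][:80]
        y = np.where(margin > 0, 1, -1)
        design = GroupedDesign(Z, {f"G{i}": slice(4 * i, 4 * i + 4) for i in range(3)})
        fit = fit_group_lasso(design, y, 0.01 * lambda_max(design, y), tol=1e-10)
        assert compute_metrics(predict_scores(fit, design), y).auroc == 1.0

    def test_row_permutation_equivariance(self, rng):
        design, y = make_design(rng)
        fit = fit_group_lasso(design, y, 0.3 * lambda_max(design, y))
        perm = rng.permutation(design.Z.shape[0])
        permuted = GroupedDesign(design.Z[perm], dict(design.blocks))
        np.testing.assert_allclose(predict_scores(fit, permuted),
                                   predict_scores(fit, design)[perm])

    def test_perfect_scores_give_unit_metrics(self):
        y = np.array([1, -1, 1, -1])
        ms = compute_metrics(y.astype(float), y)
        assert (ms.auroc, ms.f1, ms.gmean, ms.precision, ms.recall) == (1, 1, 1, 1, 1)

    def test_hand_enumerated_auroc(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        y = np.array([1, -1, 1, -1])
        ms = compute_metrics(scores, y)
        assert ms.auroc == pytest.approx(0.75)
        assert ms.auroc == pytest.approx(rank_auroc(scores, y))

    def test_anticorrelated_scores_mirror_auroc(self, rng):
        y = np.where(rng.random(30) > 0.5, 1, -1)
        y[:2] = [1, -1]
        scores = rng.normal(size=30)
        a = compute_metrics(scores, y).auroc
        b = compute_metrics(-scores, y).auroc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics(np.array([0.1, 0.2]), np.array([1, 1]))


class TestSplitsAndRebalance:
    def test_stratified_split_preserves_class_fractions(self, rng):
        y = np.array([1] * 30 + [-1] * 70)
        tr, te = stratified_split(y, 0.8, rng)
        assert len(tr) == 80 and len(te) == 20
        assert (y[tr] == 1).sum() == 24 and (y[te] == 1).sum() == 6
        assert set(tr) | set(te) == set(range(100))
        assert not set(tr) & set(te)

    def test_rebalance_subsamples_negatives_only(self, rng):
        y = np.array([1] * 20 + [-1] * 80)
        tr = np.arange(100)
        out = rebalance_train(tr, y, ratio=0.5, rng=rng)
        assert (y[out] == 1).sum() == 20  # positives untouched
        assert (y[out] == -1).sum() == 10


class TestRunExperiment:
    def test_rerun_is_deterministic(self, small_dataset):
        from cellmkl import run_experiment

        ds = small_dataset
        kwargs = dict(config=RunConfig(D=16), n_replicates=2, seed=77)
        a = run_experiment(ds.matrices(), {"RNA": ds.gene_sets}, ds.labels, **kwargs)
        b = run_experiment(ds.matrices(), {"RNA": ds.gene_sets}, ds.labels, **kwargs)
        assert a.metrics.equals(b.metrics)
        assert a.weights.equals(b.weights)

    def test_imbalance_sweep_emits_per_ratio_rows(self):
        from cellmkl import run_experiment

        ds = make_dataset(n_cells=150, n_groups=4, group_size=6, n_informative=1,
                          effect=2.0, imbalance=2.0, seed=8)
        rows = []
        for ratio in (0.5, 1.0):
            s = run_experiment(ds.matrices(), {"RNA": ds.gene_sets}, ds.labels,
                               config=RunConfig(D=12), n_replicates=2, seed=5,
                               rebalance=ratio)
            assert not s.metrics.empty and not s.failures
            n_pos = (ds.labels.y == 1).sum()
            # training size reflects the subsampled negatives
            expect_train = int(round(0.8 * n_pos)) + int(round(ratio * round(0.8 * n_pos)))
            assert abs(s.metrics["n_train"].iloc[0] - expect_train) <= 2
            rows.append(s.best_metrics().assign(ratio=ratio))
        assert len(rows) == 2

    def test_mutating_heldout_cells_leaves_model_bit_identical(self, small_dataset):
        """No-leakage audit: the fitted weights and λ protocol depend only
        on training cells."""
        from cellmkl import run_experiment

        ds = small_dataset
        y = ds.labels.y
        root = np.random.SeedSequence(123)
        rep = root.spawn(1)[0]
        tr, te = stratified_split(y, 0.8, np.random.default_rng(rep))

        corrupted = ds.rna.values.toarray().copy()
        corrupted[te] = np.random.default_rng(0).poisson(30.0, size=corrupted[te].shape)
        from dataclasses import replace

        mats_b = {"RNA": replace(ds.rna, values=corrupted)}
        kwargs = dict(config=RunConfig(D=16), n_replicates=1, seed=123)
        a = run_experiment(ds.matrices(), {"RNA": ds.gene_sets}, ds.labels, **kwargs)
        b = run_experiment(mats_b, {"RNA": ds.gene_sets}, ds.labels, **kwargs)
        assert a.weights.equals(b.weights)  # η's bit-identical
        assert a.metrics["lam"].equals(b.metrics["lam"])  # λ grid bit-identical
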