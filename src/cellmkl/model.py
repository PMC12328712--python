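"""Group-lasso classification over concatenated per-group RFF blocks.

The classifier solves

    minimize_β  (1/2) ‖ỹ − Z̃β‖₂² + λ Σ_g ‖β_g‖₂

where Z is the column-wise concatenation of the per-group RFF maps Z_g
(one block of 2D columns per feature group, across modalities), ỹ is the
centered ±1 label vector and Z̃ the column-centered design — centering is
equivalent to an unpenalized intercept, which is recovered afterwards.
The group penalty zeroes entire blocks, so a group's fitted weight
η_g = ‖β_g‖₂ is 0 exactly when its kernel is excluded; nonzero η_g
quantifies the group's contribution.

Solver: FISTA (accelerated proximal gradient) with the block
soft-threshold prox, step 1/L from a power-iteration estimate of ‖Z̃‖₂²,
and momentum restart whenever the objective would increase, so the
recorded objective trace is non-increasing.

The λ grid follows a fixed protocol: find the largest λ selecting
exactly one group and the largest λ selecting all groups, then take the
eight linearly spaced values between them (ten values total).  λ is tuned
by stratified 4-fold cross-validation on AUROC, ties broken toward the
larger (sparser) λ.  The evaluation harness repeats a stratified 80/20
train/test split with fresh widths, bases and centering per replicate,
records η for every group at every grid λ, and test metrics throughout.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core_io import CellByFeatureMatrix, FeatureGrouping, LabelVector
from .kernels import (
    KernelConfig,
    compute_z,
    default_D,
    default_kernel,
    estimate_width,
    sample_frequencies,
)
from .preprocess import preprocess_pair

logger = logging.getLogger("cellmkl")

MODALITY_ORDER = ("RNA", "GAS", "ATAC")


# ---------------------------------------------------------------------------
# Design and fit containers
# ---------------------------------------------------------------------------

@dataclass
class GroupedDesign:
    """N × (Σ_g 2D_g) design with named contiguous column blocks."""

    Z: np.ndarray
    blocks: dict  # group_name -> slice
    modality_of_group: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        cols = sorted((s.start, s.stop) for s in self.blocks.values())
        pos = 0
        for start, stop in cols:
            if start != pos:
                raise ValueError("blocks must partition the design columns contiguously")
            pos = stop
        if pos != self.Z.shape[1]:
            raise ValueError("blocks do not cover all design columns")

    @property
    def group_names(self):
        return list(self.blocks)


@dataclass
class GroupLassoFit:
    beta: np.ndarray
    intercept: float
    lam: float
    eta: dict
    objective_trace: list
    converged: bool
    n_iter: int
    blocks: dict = field(default_factory=dict)

    @property
    def active_groups(self):
        return [g for g, e in self.eta.items() if e > 0]


@dataclass
class MetricSet:
    auroc: float
    f1: float
    precision: float
    recall: float
    gmean: float

    def as_dict(self):
        return {
            "auroc": self.auroc,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "gmean": self.gmean,
        }


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

class CenteredProblem:
    """Column-centered design + centered labels, reused along a λ path."""

    def __init__(self, Z, y, blocks):
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValueError("labels must be -1/+1")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.col_means = Z.mean(axis=0)
        self.Zc = Z - self.col_means
        self.y_mean = y.mean()
        self.yc = y - self.y_mean
        self.blocks = dict(blocks)
        self._block_slices = list(self.blocks.values())
        self.L = self._lipschitz()

    def _lipschitz(self):
        """Largest eigenvalue of Z̃ᵀZ̃ by power iteration (1% safety margin)."""
        rng = np.random.default_rng(0)
        b = rng.normal(size=self.Zc.shape[1])
        b /= np.linalg.norm(b)
        lam = 0.0
        for _ in range(100):
            b = self.Zc.T @ (self.Zc @ b)
            nb = np.linalg.norm(b)
            if nb == 0:
                return 1.0
            b /= nb
            if abs(nb - lam) <= 1e-6 * nb:
                lam = nb
                break
            lam = nb
        return 1.01 * lam

    def lambda_max(self):
        """Smallest λ at which β ≡ 0: max_g ‖Z̃_gᵀỹ‖₂ (KKT condition)."""
        g = self.Zc.T @ self.yc
        return max(float(np.linalg.norm(g[sl])) for sl in self._block_slices)

    def objective(self, beta):
        r = self.yc - self.Zc @ beta
        return 0.5 * float(r @ r)

    def full_objective(self, beta, lam):
        pen = sum(float(np.linalg.norm(beta[sl])) for sl in self._block_slices)
        return self.objective(beta) + lam * pen

    def _prox(self, v, thresh):
        out = v.copy()
        for sl in self._block_slices:
            nrm = np.linalg.norm(v[sl])
            if nrm <= thresh:
                out[sl] = 0.0
            else:
                out[sl] *= 1.0 - thresh / nrm
        return out

    def fit(self, lam, beta0=None, tol=1e-6, max_iter=5000):
        if lam < 0:
            raise ValueError("lam must be >= 0")
        m = self.Zc.shape[1]
        beta = np.zeros(m) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        step = 1.0 / self.L
        thresh = lam * step
        v = beta.copy()
        t = 1.0
        obj = self.full_objective(beta, lam)
        trace = [obj]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            grad = self.Zc.T @ (self.Zc @ v - self.yc)
            beta_new = self._prox(v - step * grad, thresh)
            obj_new = self.full_objective(beta_new, lam)
            if obj_new > obj:
                # momentum overshoot: restart from the last iterate (plain
                # proximal step, guaranteed non-increasing at step 1/L)
                t = 1.0
                grad = self.Zc.T @ (self.Zc @ beta - self.yc)
                beta_new = self._prox(beta - step * grad, thresh)
                obj_new = self.full_objective(beta_new, lam)
            t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
            v = beta_new + ((t - 1.0) / t_new) * (beta_new - beta)
            beta = beta_new
            t = t_new
            trace.append(obj_new)
            if abs(obj - obj_new) <= tol * max(obj, 1e-12):
                converged = True
                obj = obj_new
                break
            obj = obj_new
        if not converged:
            logger.warning("group lasso did not converge in %d iterations (lam=%.4g)", max_iter, lam)
        eta = {g: float(np.linalg.norm(beta[sl])) for g, sl in self.blocks.items()}
        intercept = float(self.y_mean - self.col_means @ beta)
        return GroupLassoFit(beta, intercept, lam, eta, trace, converged, it, dict(self.blocks))

    def fit_path(self, lams, tol=1e-6, max_iter=5000):
        """Fit a decreasing-λ path with warm starts; returns {lam: fit}."""
        fits = {}
        beta = None
        for lam in sorted(set(float(l) for l in lams), reverse=True):
            fit = self.fit(lam, beta0=beta, tol=tol, max_iter=max_iter)
            fits[lam] = fit
            beta = fit.beta
        return fits


def fit_group_lasso(design, y, lam, tol=1e-6, max_iter=5000, beta0=None):
    """Fit the group-lasso objective at one λ (see module docstring)."""
    y = y.y if isinstance(y, LabelVector) else np.asarray(y)
    problem = CenteredProblem(design.Z, y, design.blocks)
    return problem.fit(lam, beta0=beta0, tol=tol, max_iter=max_iter)


def predict_scores(fit, design):
    """Decision values Zβ + b; classify as sign(score), 0 → positive."""
    if list(design.blocks) != list(fit.blocks):
        raise ValueError("design blocks do not match the fitted model's blocks")
    return design.Z @ fit.beta + fit.intercept


def predict_classes(fit, design):
    return np.where(predict_scores(fit, design) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# λ protocol
# ---------------------------------------------------------------------------

def lambda_max(design, y):
    y = y.y if isinstance(y, LabelVector) else np.asarray(y)
    return CenteredProblem(design.Z, y, design.blocks).lambda_max()


def _n_active(problem, lam, cache, tol, max_iter):
    if lam not in cache:
        warm = None
        higher = [l for l in cache if l > lam]
        if higher:
            warm = cache[min(higher)].beta
        cache[lam] = problem.fit(lam, beta0=warm, tol=tol, max_iter=max_iter)
    return len(cache[lam].active_groups)


def lambda_endpoints(design, y, tol=1e-6, max_iter=5000, floor_factor=1e-4):
    """Find (lam_all, lam_one): the λ's selecting all groups and one group.

    lam_one: largest λ at which exactly one group is active, located by a
    geometric descent below λ_max and bisection to 1% relative width.
    lam_all: largest λ at which every group is active, by geometric
    decrease (factor 0.7) from lam_one, floored at 1e-4·λ_max — if some
    group never activates the floor is returned with a warning.
    """
    y = y.y if isinstance(y, LabelVector) else np.asarray(y)
    problem = CenteredProblem(design.Z, y, design.blocks)
    n_groups = len(problem.blocks)
    if n_groups < 2:
        raise ValueError("lambda endpoints require at least 2 groups")
    lmax = problem.lambda_max()
    cache = {}

    hi = lmax  # zero groups active at λ_max
    lo = 0.9 * lmax
    while _n_active(problem, lo, cache, tol, max_iter) < 1:
        hi = lo
        lo *= 0.9
        if lo < floor_factor * lmax:
            raise RuntimeError("no λ activates any group; degenerate design")
    while (hi - lo) > 0.01 * lo:
        mid = 0.5 * (hi + lo)
        if _n_active(problem, mid, cache, tol, max_iter) >= 1:
            lo = mid
        else:
            hi = mid
    # two groups can activate within the 1% bracket; keep narrowing toward
    # λ_max until exactly one survives (bounded for exact ties)
    while _n_active(problem, lo, cache, tol, max_iter) != 1 and (hi - lo) > 1e-8 * lo:
        mid = 0.5 * (hi + lo)
        if _n_active(problem, mid, cache, tol, max_iter) >= 1:
            lo = mid
        else:
            hi = mid
    lam_one = lo
    if _n_active(problem, lam_one, cache, tol, max_iter) != 1:
        logger.warning(
            "exactly-one-group λ not attainable (%d groups active at %.4g)",
            _n_active(problem, lam_one, cache, tol, max_iter), lam_one,
        )

    floor = floor_factor * lmax
    lam = 0.7 * lam_one
    while _n_active(problem, lam, cache, tol, max_iter) < n_groups and lam > floor:
        lam *= 0.7
    if _n_active(problem, lam, cache, tol, max_iter) < n_groups:
        logger.warning(
            "not all groups activate above the search floor %.4g; returning the floor", floor
        )
        lam = floor
    lam_all = lam
    return lam_all, lam_one


def lambda_grid(lam_all, lam_one, n_interior=8):
    """n_interior + 2 strictly increasing λ values from lam_all to lam_one."""
    if not lam_all < lam_one:
        raise ValueError(f"need lam_all < lam_one, got {lam_all} >= {lam_one}")
    return list(np.linspace(lam_all, lam_one, n_interior + 2))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(scores, labels):
    """AUROC (rank-based, tie-corrected), F1/precision/recall at the sign
    threshold, and G-mean = sqrt(sensitivity · specificity)."""
    y = labels.y if isinstance(labels, LabelVector) else np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute metrics")
    auroc = float(roc_auc_score(y, scores))
    pred = np.where(scores >= 0, 1, -1)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == -1)).sum())
    fn = int(((pred == -1) & (y == 1)).sum())
    tn = int(((pred == -1) & (y == -1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    gmean = math.sqrt(recall * specificity)
    return MetricSet(auroc, f1, precision, recall, gmean)


# ---------------------------------------------------------------------------
# Experiment configuration and harness
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved settings for one experiment.

    ``D="auto"`` means ceil(sqrt(N_train)·ln ln N_train) per replicate; a
    fixed integer (e.g. 100 for very many groups) overrides it.
    ``preprocess``/``kernel`` may name a scheme per modality; unset
    modalities use the defaults (RNA/GAS: lognorm_z + gaussian; ATAC:
    binary + laplacian, or gaussian under tfidf).
    """

    preprocess: dict = field(default_factory=dict)
    kernel: dict = field(default_factory=dict)
    D: object = "auto"
    width_n_cells: int = 2000
    width_n_features: int = 200
    n_interior: int = 8
    cv_folds: int = 4
    tol: float = 1e-6
    max_iter: int = 5000

    def scheme_for(self, modality):
        defaults = {"RNA": "lognorm_z", "GAS": "lognorm_z", "ATAC": "binary"}
        return self.preprocess.get(modality, defaults[modality])

    def kernel_for(self, modality):
        return self.kernel.get(modality, default_kernel(modality, self.scheme_for(modality)))

    def as_dict(self):
        return {
            "preprocess": {m: self.scheme_for(m) for m in MODALITY_ORDER},
            "kernel": {m: self.kernel_for(m) for m in MODALITY_ORDER},
            "D": self.D,
            "width_n_cells": self.width_n_cells,
            "width_n_features": self.width_n_features,
            "n_interior": self.n_interior,
            "cv_folds": self.cv_folds,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }


@dataclass
class RunSummary:
    """Per-replicate, per-λ records of metrics and group weights."""

    metrics: pd.DataFrame
    weights: pd.DataFrame
    config: dict
    failures: list = field(default_factory=list)

    @property
    def n_replicates(self):
        return self.metrics["replicate"].nunique() if not self.metrics.empty else 0

    @property
    def lam_indices(self):
        return sorted(self.metrics["lam_index"].unique())

    def best_metrics(self):
        """Test metrics at the CV-chosen λ, one row per replicate."""
        return self.metrics[self.metrics["is_cv_best"]].reset_index(drop=True)


def stratified_split(y, train_frac, rng):
    """Class-stratified train/test indices (shuffled within class)."""
    y = np.asarray(y)
    train, test = [], []
    for cls in (-1, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 cells; cannot stratify")
        idx = rng.permutation(idx)
        n_tr = int(round(train_frac * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.append(idx[:n_tr])
        test.append(idx[n_tr:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def rebalance_train(train_idx, y, ratio, rng):
    """Subsample the negative (reference) class in TRAINING to a target
    negative:positive ratio; test cells are never touched."""
    y = np.asarray(y)
    pos = train_idx[y[train_idx] == 1]
    neg = train_idx[y[train_idx] == -1]
    target_neg = int(round(ratio * len(pos)))
    if target_neg < 2:
        raise ValueError(f"rebalance ratio {ratio} leaves fewer than 2 negative cells")
    if target_neg >= len(neg):
        return train_idx
    keep = rng.choice(neg, size=target_neg, replace=False)
    return np.sort(np.concatenate([pos, keep]))


def _group_columns(matrix, grouping):
    """Per group: (sorted member ids, column indices into the matrix)."""
    col = matrix.column_index()
    out = {}
    for name, members in grouping.groups.items():
        feats = sorted(members)
        out[name] = (feats, np.array([col[f] for f in feats], dtype=int))
    return out


def _build_replicate_design(train_vals, test_vals, group_cols, kernel_by_mod, D,
                            config, seed_seq):
    """Estimate widths, sample bases and build train/test designs.

    ``train_vals``/``test_vals``: modality → preprocessed dense/sparse
    matrix.  One basis per group, seeded from ``seed_seq`` in fixed
    (modality, group) order; test cells use the train width and basis.
    """
    blocks, mod_of = {}, {}
    z_train, z_test = [], []
    pos = 0
    order = [m for m in MODALITY_ORDER if m in group_cols]
    for mod in order:
        kern = kernel_by_mod[mod]
        xtr = train_vals[mod]
        xte = test_vals.get(mod) if test_vals else None
        for name, (feats, cols) in group_cols[mod].items():
            key = (mod, name)  # gene-set-derived groups share names across modalities
            xg_tr = xtr[:, cols]
            # seeds keyed by a stable digest of (modality, group) so a
            # group's basis does not depend on which other groups exist
            # (ablations leave the survivors' kernels untouched)
            width_seed, basis_seed = _group_seeds(seed_seq, mod, name)
            s = estimate_width(
                xg_tr, kern, n_cells=config.width_n_cells,
                n_features=config.width_n_features, seed=width_seed,
            )
            basis = sample_frequencies(
                KernelConfig(kern, s, D, seed=basis_seed), len(cols), feats
            )
            z_train.append(compute_z(xg_tr, basis))
            if xte is not None:
                z_test.append(compute_z(xte[:, cols], basis))
            blocks[key] = slice(pos, pos + 2 * D)
            mod_of[key] = mod
            pos += 2 * D
    design_train = GroupedDesign(np.hstack(z_train), blocks, mod_of)
    design_test = GroupedDesign(np.hstack(z_test), dict(blocks), dict(mod_of)) if z_test else None
    return design_train, design_test


def _group_seeds(seed_seq, mod, name):
    key = (zlib.crc32(mod.encode()), zlib.crc32(name.encode()))
    return (
        np.random.SeedSequence(entropy=seed_seq.entropy,
                               spawn_key=seed_seq.spawn_key + key + (0,)),
        np.random.SeedSequence(entropy=seed_seq.entropy,
                               spawn_key=seed_seq.spawn_key + key + (1,)),
    )


def cross_validate(mats_train, groupings, y_train, grid, config, k=4, seed=0):
    """Stratified k-fold tuning of λ by mean validation AUROC.

    Widths, bases, preprocessing statistics and centering are all refit on
    each fold's training portion, so no validation information leaks into
    the model.  Ties are broken toward the larger λ (the sparser model).

    ``mats_train``: modality → raw (untransformed) CellByFeatureMatrix of
    training cells; ``grid``: λ values to score.
    """
    if len(grid) == 0:
        raise ValueError("empty λ grid")
    y_train = y_train.y if isinstance(y_train, LabelVector) else np.asarray(y_train)
    if len(grid) == 1:
        return float(grid[0])
    group_cols = {m: _group_columns(mats_train[m], groupings[m]) for m in mats_train}
    kernel_by_mod = {m: config.kernel_for(m) for m in mats_train}
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    fold_seeds = root.spawn(k)
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(root.generate_state(1)[0] % (2**31)))
    lams = sorted(float(l) for l in grid)
    scores = np.zeros((k, len(lams)))
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y_train)), y_train)):
        if len(np.unique(y_train[va])) < 2 or len(np.unique(y_train[tr])) < 2:
            raise ValueError("a CV fold lost a class; too few cells per class for k folds")
        train_vals, val_vals = {}, {}
        for mod, mat in mats_train.items():
            mtr = mat.subset_cells(tr)
            mva = mat.subset_cells(va)
            ptr, pva = preprocess_pair(mtr, mva, config.scheme_for(mod))
            train_vals[mod] = ptr.values
            val_vals[mod] = pva.values
        D = config.D if isinstance(config.D, int) else default_D(len(tr))
        d_tr, d_va = _build_replicate_design(
            train_vals, val_vals, group_cols, kernel_by_mod, D, config, fold_seeds[fold]
        )
        problem = CenteredProblem(d_tr.Z, y_train[tr], d_tr.blocks)
        fits = problem.fit_path(lams, tol=config.tol, max_iter=config.max_iter)
        for j, lam in enumerate(lams):
            s = predict_scores(fits[lam], d_va)
            scores[fold, j] = roc_auc_score(y_train[va], s)
    mean_scores = scores.mean(axis=0)
    j_max = int(np.argmax(mean_scores))
    # one-standard-error rule: the largest (sparsest) λ whose mean AUROC is
    # within 1 SE of the maximum; exact ties therefore also resolve upward
    se = scores[:, j_max].std(ddof=1) / math.sqrt(k) if k > 1 else 0.0
    candidates = [j for j in range(len(lams)) if mean_scores[j] >= mean_scores[j_max] - se]
    return lams[max(candidates)]


def run_experiment(mats, groupings, labels, config=None, n_replicates=100,
                   train_frac=0.8, seed=0, rebalance=None):
    """Replicated stratified 80/20 evaluation of the full pipeline.

    Per replicate: stratified split (optionally subsampling the negative
    class in training to ``rebalance`` × the positive count); per-modality
    preprocessing fit on training cells; per-group width estimation, basis
    sampling and Z construction on train, with test cells transformed by
    the train basis; λ endpoints + 10-value grid; 4-fold CV for λ; fits
    recorded at every grid λ (for interpretation) and test metrics at each,
    with the CV winner flagged.  A failing replicate is logged and skipped,
    not fatal.

    ``mats``: modality → CellByFeatureMatrix (raw counts), sharing cell
    order; ``groupings``: modality → FeatureGrouping.
    """
    config = config or RunConfig()
    if isinstance(labels, LabelVector):
        labels.check_both_classes()
        y = labels.y
    else:
        y = np.asarray(labels)
    n = len(y)
    for mod, mat in mats.items():
        if mat.n_cells != n:
            raise ValueError(f"{mod} matrix has {mat.n_cells} cells but {n} labels")
    groupings = {m: groupings[m].intersect_with(mats[m].feature_ids) for m in mats}
    group_cols = {m: _group_columns(mats[m], groupings[m]) for m in mats}
    kernel_by_mod = {m: config.kernel_for(m) for m in mats}

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_replicates)
    metric_rows, weight_rows, failures = [], [], []
    for r in range(n_replicates):
        try:
            m_rows, w_rows = _run_one_replicate(
                r, rep_seeds[r], mats, group_cols, kernel_by_mod, y,
                config, train_frac, rebalance,
            )
            metric_rows.extend(m_rows)
            weight_rows.extend(w_rows)
        except Exception as exc:  # noqa: BLE001 — a replicate failure must not kill the run
            logger.error("replicate %d failed: %s", r, exc)
            failures.append({"replicate": r, "error": str(exc)})
    metrics = pd.DataFrame(
        metric_rows,
        columns=["replicate", "lam_index", "lam", "auroc", "f1", "precision",
                 "recall", "gmean", "is_cv_best", "n_train", "n_test"],
    )
    weights = pd.DataFrame(
        weight_rows, columns=["replicate", "lam_index", "lam", "group", "modality", "eta", "active"]
    )
    cfg = config.as_dict()
    cfg.update({
        "n_replicates": n_replicates,
        "train_frac": train_frac,
        "seed": _seed_repr(root),
        "rebalance": rebalance,
        "modalities": sorted(mats),
        "n_groups": {m: len(groupings[m]) for m in mats},
    })
    return RunSummary(metrics, weights, cfg, failures)


def _seed_repr(seq):
    e = seq.entropy
    return int(e) if np.isscalar(e) else [int(x) for x in e]


def _run_one_replicate(r, rep_seed, mats, group_cols, kernel_by_mod, y,
                       config, train_frac, rebalance):
    rng = np.random.default_rng(rep_seed)
    train_idx, test_idx = stratified_split(y, train_frac, rng)
    if rebalance is not None:
        train_idx = rebalance_train(train_idx, y, rebalance, rng)
    y_tr, y_te = y[train_idx], y[test_idx]

    train_vals, test_vals, mats_train = {}, {}, {}
    for mod, mat in mats.items():
        mtr = mat.subset_cells(train_idx)
        mte = mat.subset_cells(test_idx)
        mats_train[mod] = mtr
        ptr, pte = preprocess_pair(mtr, mte, config.scheme_for(mod))
        train_vals[mod] = ptr.values
        test_vals[mod] = pte.values
    D = config.D if isinstance(config.D, int) else default_D(len(train_idx))

    design_seed, cv_seed = rep_seed.spawn(2)
    d_tr, d_te = _build_replicate_design(
        train_vals, test_vals, group_cols, kernel_by_mod, D, config, design_seed
    )
    lam_all, lam_one = lambda_endpoints(d_tr, y_tr, tol=config.tol, max_iter=config.max_iter)
    grid = lambda_grid(lam_all, lam_one, config.n_interior)
    lam_best = cross_validate(
        mats_train, {m: FeatureGrouping(mats_train[m].modality,
                                        {g: set(f) for g, (f, _) in group_cols[m].items()})
                     for m in mats_train},
        y_tr, grid, config, k=config.cv_folds, seed=cv_seed,
    )
    problem = CenteredProblem(d_tr.Z, y_tr, d_tr.blocks)
    fits = problem.fit_path(grid, tol=config.tol, max_iter=config.max_iter)

    metric_rows, weight_rows = [], []
    for j, lam in enumerate(sorted(grid)):
        fit = fits[lam]
        mset = compute_metrics(predict_scores(fit, d_te), y_te)
        metric_rows.append({
            "replicate": r, "lam_index": j, "lam": lam, **mset.as_dict(),
            "is_cv_best": bool(np.isclose(lam, lam_best)),
            "n_train": len(train_idx), "n_test": len(test_idx),
        })
        for (mod, g), e in fit.eta.items():
            weight_rows.append({
                "replicate": r, "lam_index": j, "lam": lam, "group": g,
                "modality": mod, "eta": e, "active": e > 0,
            })
    return metric_rows, weight_rows
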