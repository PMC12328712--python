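"""Model interpretation: group weights, ablations and robustness checks.

The replicated runs yield, for every (replicate, λ, group), a kernel
weight η_g = ‖β_g‖₂.  Interpretation summarizes these as selection
frequencies (fraction of replicates with η_g > 0) and mean weights,
averaged over the λ grid for robustness to the sparsity level; a
dot-plot table retains the top groups per modality with min-max scaled
values.  Two experiment protocols probe whether the prior knowledge in
the groupings matters: leave-group-out ablation (rerun with groups
removed, rank-sum tests on the surviving weights, paired signed-rank
test on AUROC), and grouping perturbation (replacing a fraction of each
group's members with random outside features, or appending permuted
noise columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import FeatureGrouping
from .model import RunSummary, run_experiment

logger = logging.getLogger("cellmkl")

CORRUPTION_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
NOISE_LEVELS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)


# ---------------------------------------------------------------------------
# Selection frequency and dot plots
# ---------------------------------------------------------------------------

def selection_frequency(summary):
    """Fraction of replicates in which each group is selected, per λ and
    averaged (unweighted) over the λ grid.

    Returns (per_lambda, per_group): a tidy frame with columns
    group/modality/lam_index/frequency, and a frame with the λ-averaged
    frequency and mean weight per group.
    """
    w = summary.weights
    if w.empty:
        raise ValueError("run summary holds no group weight records")
    per_lambda = (
        w.groupby(["group", "modality", "lam_index"], sort=False)["active"]
        .mean()
        .rename("frequency")
        .reset_index()
    )
    per_group = (
        per_lambda.groupby(["group", "modality"], sort=False)["frequency"]
        .mean()
        .rename("mean_frequency")
        .reset_index()
    )
    mean_eta = (
        w.groupby(["group", "modality"], sort=False)["eta"].mean().rename("mean_eta").reset_index()
    )
    per_group = per_group.merge(mean_eta, on=["group", "modality"])
    return per_lambda, per_group


def _minmax(values):
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        logger.warning("degenerate min-max range; scaled values set to 0 by convention")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def dotplot_table(summary, top_k=8):
    """Plot-ready table of the top ``top_k`` groups per modality.

    Groups are ranked within each modality by λ-averaged selection
    frequency; mean weights and frequencies are min-max scaled within the
    modality (so sparse and dense solutions are comparable).  In the
    intended display, point size encodes scaled frequency and opacity the
    scaled weight.
    """
    _, per_group = selection_frequency(summary)
    out = []
    for modality, sub in per_group.groupby("modality", sort=False):
        sub = sub.sort_values(["mean_frequency", "mean_eta", "group"],
                              ascending=[False, False, True]).head(top_k).copy()
        sub["scaled_frequency"] = _minmax(sub["mean_frequency"])
        sub["scaled_eta"] = _minmax(sub["mean_eta"])
        sub["rank"] = np.arange(1, len(sub) + 1)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def plot_dotplot(table, path):
    """Render the dot-plot table (optional; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 0.4 * len(table) + 1.5))
    colors = {"RNA": "tab:blue", "ATAC": "tab:orange", "GAS": "tab:green"}
    for i, row in table.iterrows():
        ax.scatter(
            row["scaled_frequency"], i,
            s=60 + 240 * row["scaled_frequency"],
            alpha=max(0.15, row["scaled_eta"]),
            color=colors.get(row["modality"], "grey"),
        )
    ax.set_yticks(range(len(table)))
    ax.set_yticklabels(table["group"])
    ax.set_xlabel("scaled selection frequency")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    baseline: RunSummary
    ablated: RunSummary
    group_stats: pd.DataFrame
    auroc_stats: dict = field(default_factory=dict)


def _eta_by_replicate(summary):
    """Per (group, replicate) λ-averaged η."""
    return summary.weights.groupby(["group", "replicate"])["eta"].mean()


def ablate_groups(mats, groupings, labels, groups_to_remove, config=None,
                  n_replicates=20, train_frac=0.8, seed=0, rebalance=None,
                  baseline=None):
    """Leave-group-out ablation with the same replicate seeds as baseline.

    Removes ``groups_to_remove`` from the groupings, reruns the full
    experiment, and for every surviving group reports the change in mean
    weight (ablated − baseline) with a two-sided Wilcoxon rank-sum test on
    the per-replicate λ-averaged weights (BH-corrected across groups).
    AUROC at the CV-chosen λ is compared with a one-sided paired
    signed-rank test of whether ablation worsened performance.
    """
    groups_to_remove = list(groups_to_remove)
    all_names = {g for fg in groupings.values() for g in fg.names}
    unknown = [g for g in groups_to_remove if g not in all_names]
    if unknown:
        raise ValueError(f"groups not present in any grouping: {unknown}")
    reduced = {}
    for mod, fg in groupings.items():
        kept = {g: m for g, m in fg.groups.items() if g not in groups_to_remove}
        if kept:
            reduced[mod] = FeatureGrouping(fg.modality, kept)
    n_left = sum(len(fg) for fg in reduced.values())
    if n_left < 2:
        raise ValueError("ablation must leave at least 2 groups")
    reduced_mats = {m: mats[m] for m in reduced}

    if baseline is None:
        baseline = run_experiment(mats, groupings, labels, config=config,
                                  n_replicates=n_replicates, train_frac=train_frac,
                                  seed=seed, rebalance=rebalance)
    ablated = run_experiment(reduced_mats, reduced, labels, config=config,
                             n_replicates=n_replicates, train_frac=train_frac,
                             seed=seed, rebalance=rebalance)

    eta_base = _eta_by_replicate(baseline)
    eta_abl = _eta_by_replicate(ablated)
    rows = []
    for g in sorted({g for g, _ in eta_abl.index}):
        b = eta_base.xs(g, level="group").to_numpy()
        a = eta_abl.xs(g, level="group").to_numpy()
        if np.allclose(a, 0) and np.allclose(b, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ranksums(a, b)
        rows.append({
            "group": g,
            "mean_eta_baseline": float(b.mean()),
            "mean_eta_ablated": float(a.mean()),
            "delta_eta": float(a.mean() - b.mean()),
            "statistic": float(stat),
            "p_value": float(p),
        })
    group_stats = pd.DataFrame(rows)
    if not group_stats.empty:
        group_stats["p_adj"] = multipletests(group_stats["p_value"], method="fdr_bh")[1]
        group_stats["neg_log10_p"] = -np.log10(np.maximum(group_stats["p_adj"], 1e-300))

    auroc_b = baseline.best_metrics().set_index("replicate")["auroc"]
    auroc_a = ablated.best_metrics().set_index("replicate")["auroc"]
    common = auroc_b.index.intersection(auroc_a.index)
    diffs = auroc_b.loc[common].to_numpy() - auroc_a.loc[common].to_numpy()
    if np.allclose(diffs, 0):
        w_p = 1.0
    else:
        # one-sided: baseline AUROC > ablated AUROC (ablation hurt)
        _, w_p = stats.wilcoxon(diffs, alternative="greater")
    auroc_stats = {
        "mean_auroc_baseline": float(auroc_b.loc[common].mean()),
        "mean_auroc_ablated": float(auroc_a.loc[common].mean()),
        "delta_auroc": float(-diffs.mean()),
        "p_value_worsened": float(w_p),
    }
    return AblationResult(baseline, ablated, group_stats, auroc_stats)


# ---------------------------------------------------------------------------
# Grouping perturbations
# ---------------------------------------------------------------------------

def corrupt_grouping(grouping, fraction, universe, seed=0):
    """Replace floor(fraction·|G|) of each group's members with random
    features drawn from outside the group (size preserved).

    ``fraction`` 0 returns an identical grouping; 1.0 yields groups
    disjoint from their original membership when the universe allows.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    universe = set(map(str, universe))
    if fraction == 0.0:
        return FeatureGrouping(grouping.modality, dict(grouping.groups))
    rng = np.random.default_rng(seed)
    out = {}
    for name, members in grouping.groups.items():
        members = sorted(members)
        n_replace = int(np.floor(fraction * len(members)))
        outside = sorted(universe - set(members))
        if n_replace > len(outside):
            raise ValueError(
                f"group {name!r}: cannot replace {n_replace} members; only "
                f"{len(outside)} features outside the group"
            )
        drop = set(rng.choice(members, size=n_replace, replace=False)) if n_replace else set()
        add = rng.choice(outside, size=n_replace, replace=False) if n_replace else []
        out[name] = (set(members) - drop) | set(map(str, add))
    return FeatureGrouping(grouping.modality, out)


def add_noise_features(grouping, matrix, level, seed=0):
    """Append round(level·|G|) permuted-copy noise features to each group.

    Each noise feature is a cell-wise permutation of a randomly chosen
    existing feature's column (source sampled with replacement), so the
    marginal value distribution is preserved while any association with
    the phenotype is destroyed.  New columns are appended to the matrix
    with unique ids and added to their group only.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if level == 0:
        return FeatureGrouping(grouping.modality, dict(grouping.groups)), matrix
    rng = np.random.default_rng(seed)
    dense = matrix.dense()
    n_cells = dense.shape[0]
    col = matrix.column_index()
    new_cols, new_ids = [], []
    new_groups = {}
    for name, members in grouping.groups.items():
        members = sorted(members)
        n_new = int(round(level * len(members)))
        ids = []
        for i in range(n_new):
            src = members[rng.integers(len(members))]
            perm = rng.permutation(n_cells)
            new_cols.append(dense[perm, col[src]])
            fid = f"noise_{name}_{i}"
            ids.append(fid)
        new_ids.extend(ids)
        new_groups[name] = set(members) | set(ids)
    if sp.issparse(matrix.values):
        values = sp.hstack([matrix.values, sp.csr_matrix(np.column_stack(new_cols))]).tocsr()
    else:
        values = np.hstack([dense, np.column_stack(new_cols)])
    out_matrix = replace(matrix, values=values,
                         feature_ids=list(matrix.feature_ids) + new_ids)
    return FeatureGrouping(grouping.modality, new_groups), out_matrix


def perturbation_experiment(mats, groupings, labels, mode, levels=None,
                            config=None, n_replicates=10, train_frac=0.8, seed=0):
    """Run the grouping-perturbation protocol across severity levels.

    ``mode``: "corrupt" (member replacement at fractions 0…1) or "noise"
    (permuted-feature padding at 0…8× group size).  Perturbations are
    applied once per level with a level-specific seed; the evaluation
    seeds are shared across levels so differences reflect the perturbation.
    Only single-modality groupings are perturbed here (the protocol is
    defined per grouping); pass one modality in ``mats``/``groupings``.

    Returns a tidy DataFrame with per-level mean/sd AUROC at the CV λ,
    and the per-level summaries.
    """
    if mode not in ("corrupt", "noise"):
        raise ValueError("mode must be 'corrupt' or 'noise'")
    if len(mats) != 1:
        raise ValueError("perturbation protocol operates on a single modality")
    if levels is None:
        levels = CORRUPTION_LEVELS if mode == "corrupt" else NOISE_LEVELS
    (modality, matrix), = mats.items()
    grouping = groupings[modality].intersect_with(matrix.feature_ids)
    root = np.random.SeedSequence(seed)
    pert_seeds = root.spawn(len(levels))
    rows, summaries = [], {}
    for i, level in enumerate(levels):
        if mode == "corrupt":
            g = corrupt_grouping(grouping, level, matrix.feature_ids, seed=pert_seeds[i])
            m = matrix
        else:
            g, m = add_noise_features(grouping, matrix, level, seed=pert_seeds[i])
        summary = run_experiment({modality: m}, {modality: g}, labels, config=config,
                                 n_replicates=n_replicates, train_frac=train_frac,
                                 seed=seed)
        best = summary.best_metrics()
        rows.append({
            "mode": mode, "level": level,
            "mean_auroc": float(best["auroc"].mean()),
            "sd_auroc": float(best["auroc"].std(ddof=1)) if len(best) > 1 else 0.0,
            "n_replicates": len(best),
        })
        summaries[level] = summary
    return pd.DataFrame(rows), summaries
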