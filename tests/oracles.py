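"""Independent oracles used by the test suite.

These deliberately share no code with the implementation paths they
check: the group-lasso oracle is exact block-coordinate descent with
per-group SVD subproblems solved by 1-D root finding (the implementation
uses accelerated proximal gradient), and the interval oracle is a
quadratic all-pairs scan.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def group_lasso_bcd(Z, y, blocks, lam, n_sweeps=2000, tol=1e-13):
    """Exact block coordinate descent for
    min (1/2)||yc - Zc b||^2 + lam * sum_g ||b_g||, on centered data.

    Each group subproblem min_b (1/2)||r - A b||^2 + lam ||b|| is solved
    exactly: b = 0 iff ||A^T r|| <= lam, else via SVD A = U S V^T the
    optimality condition reduces to a scalar root in t = ||b||:
        sum_i d_i^2 t^2 / (s_i^2 t + lam)^2 = t^2,  d = V^T A^T r.
    """
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    slices = list(blocks.values())
    svds = [np.linalg.svd(Zc[:, sl], full_matrices=False) for sl in slices]
    beta = np.zeros(Z.shape[1])
    resid = yc - Zc @ beta
    for _ in range(n_sweeps):
        max_delta = 0.0
        for sl, (U, S, Vt) in zip(slices, svds):
            A = Zc[:, sl]
            r = resid + A @ beta[sl]
            c = A.T @ r
            cn = np.linalg.norm(c)
            if cn <= lam:
                b_new = np.zeros(sl.stop - sl.start)
            else:
                d = Vt @ c

                def phi(t):
                    return np.sum(d**2 * t**2 / (S**2 * t + lam) ** 2) - t**2

                hi = cn / max(S.min() ** 2, 1e-12) + cn / max(lam, 1e-12) + 1.0
                while phi(hi) > 0:
                    hi *= 2.0
                t = brentq(phi, 1e-14, hi, xtol=1e-15, rtol=1e-14)
                a = d * t / (S**2 * t + lam)
                b_new = Vt.T @ a
            max_delta = max(max_delta, float(np.max(np.abs(b_new - beta[sl]))))
            resid = r - A @ b_new
            beta[sl] = b_new
        if max_delta < tol:
            break
    return beta


def objective_value(Z, y, blocks, beta, lam):
    Zc = np.asarray(Z, float) - np.asarray(Z, float).mean(axis=0)
    yc = np.asarray(y, float) - np.asarray(y, float).mean()
    r = yc - Zc @ beta
    pen = sum(np.linalg.norm(beta[sl]) for sl in blocks.values())
    return 0.5 * float(r @ r) + lam * pen


def brute_force_peak_gene_overlap(peaks, genes, window_bp):
    """All-pairs half-open overlap of peaks with windowed gene bodies."""
    mapping = {}
    for row in genes.itertuples(index=False):
        hits = set()
        for pk in peaks:
            if (
                pk.chrom == row.chrom
                and pk.start < row.end + window_bp
                and pk.end > row.start - window_bp
            ):
                hits.add(pk.label)
        mapping[str(row.gene_id)] = hits
    return mapping


def rank_auroc(scores, y):
    """Mann-Whitney AUROC by pair enumeration with half-credit ties."""
    scores = np.asarray(scores, float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_grouped_problem(rng, n=60, n_groups=4, block_width=4, signal=True):
    """Random dense design with named contiguous blocks and ±1 labels."""
    m = n_groups * block_width
    Z = rng.normal(size=(n, m))
    blocks = {
        f"G{i}": slice(i * block_width, (i + 1) * block_width)
        for i in range(n_groups)
    }
    if signal:
        w = np.zeros(m)
        w[: block_width] = rng.normal(size=block_width)
        y = np.where(Z @ w + 0.5 * rng.normal(size=n) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
    else:
        y = rng.choice([-1, 1], size=n)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
    return Z, y, blocks
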