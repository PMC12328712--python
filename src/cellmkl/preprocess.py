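"""Modality-appropriate transformations applied before kernel construction.

RNA (and gene-activity) counts default to per-cell log-normalization
followed by per-feature z-scoring; ATAC peak counts default to
binarization, with TF-IDF as the alternative.  Every transform is
deterministic and leakage-free: statistics estimated on training cells
(IDF, feature mean/sd) are applied unchanged to held-out cells.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import scipy.sparse as sp

from .core_io import CellByFeatureMatrix

logger = logging.getLogger("cellmkl")

RNA_SCHEMES = ("lognorm_z", "raw")
ATAC_SCHEMES = ("binary", "tfidf")


def _values(x):
    return x.values if isinstance(x, CellByFeatureMatrix) else x


def _rewrap(x, values):
    if isinstance(x, CellByFeatureMatrix):
        return replace(x, values=values)
    return values


def _check_nonnegative(v, op):
    data = v.data if sp.issparse(v) else np.asarray(v)
    if data.size and data.min() < 0:
        raise ValueError(f"{op} requires non-negative input values")


def tfidf_idf(x):
    """Per-feature inverse document frequency over cells.

    idf_f = ln((1 + N) / (1 + nnz_f) + 1) where N is the number of cells
    and nnz_f the number of cells in which feature f is detected (> 0).
    Rare peaks (open in few cells) get the largest weights.
    """
    v = _values(x)
    _check_nonnegative(v, "tfidf")
    n = v.shape[0]
    if sp.issparse(v):
        nnz = np.asarray((v > 0).sum(axis=0)).ravel()
    else:
        nnz = (np.asarray(v) > 0).sum(axis=0)
    return np.log((1.0 + n) / (1.0 + nnz) + 1.0)


def tfidf_transform(x, idf=None):
    """TF-IDF reweighting: out[c, f] = x[c, f] * idf_f.

    Pass ``idf`` computed on training cells to transform held-out cells
    without leakage; with ``idf=None`` the IDF is computed from ``x``
    itself.  The sparsity pattern is preserved exactly (zeros stay zero).
    """
    v = _values(x)
    _check_nonnegative(v, "tfidf")
    if idf is None:
        idf = tfidf_idf(v)
    idf = np.asarray(idf, dtype=float)
    if idf.shape != (v.shape[1],):
        raise ValueError(f"idf length {idf.shape} does not match {v.shape[1]} features")
    if sp.issparse(v):
        out = v @ sp.diags(idf)
        out = sp.csr_matrix(out)
    else:
        out = np.asarray(v, dtype=float) * idf
    return _rewrap(x, out)


def binarize(x):
    """0/1 presence-absence encoding; idempotent, sparsity preserved."""
    v = _values(x)
    _check_nonnegative(v, "binarize")
    if sp.issparse(v):
        out = v.copy()
        out.data = (out.data > 0).astype(float)
        out.eliminate_zeros()
    else:
        out = (np.asarray(v) > 0).astype(float)
    return _rewrap(x, out)


def log_normalize(x, scale_total=1e4):
    """Scale each cell to a fixed total count, then ln(1 + .).

    Cells with zero total counts are left at zero (warned): dividing by a
    zero library size is undefined and such cells carry no information.
    """
    v = _values(x)
    _check_nonnegative(v, "log_normalize")
    if sp.issparse(v):
        totals = np.asarray(v.sum(axis=1)).ravel()
    else:
        totals = np.asarray(v).sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cell(s) with zero total counts left at zero", int(zero.sum()))
    factors = np.where(zero, 0.0, scale_total / np.where(zero, 1.0, totals))
    if sp.issparse(v):
        out = sp.diags(factors) @ v
        out = sp.csr_matrix(out)
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(np.asarray(v, dtype=float) * factors[:, None])
    return _rewrap(x, out)


def standardize_per_feature(x_train, x_test=None):
    """Z-score each feature using TRAIN statistics (population sd, ddof=0).

    Constant features are set to 0 in both splits.  Output is dense — a
    z-scored matrix has no useful sparsity.  Returns the transformed train
    matrix, or a (train, test) pair when a test matrix is given.
    """
    vtr = _values(x_train)
    if vtr.shape[0] == 0:
        raise ValueError("training matrix is empty")
    dtr = vtr.toarray() if sp.issparse(vtr) else np.asarray(vtr, dtype=float)
    mean = dtr.mean(axis=0)
    sd = dtr.std(axis=0, ddof=0)
    keep = sd > 0
    safe_sd = np.where(keep, sd, 1.0)

    def apply(dense):
        z = (dense - mean) / safe_sd
        z[:, ~keep] = 0.0
        return z

    out_train = _rewrap(x_train, apply(dtr))
    if x_test is None:
        return out_train
    vte = _values(x_test)
    dte = vte.toarray() if sp.issparse(vte) else np.asarray(vte, dtype=float)
    if dte.shape[1] != dtr.shape[1]:
        raise ValueError("train and test have different feature counts")
    return out_train, _rewrap(x_test, apply(dte))


def preprocess_pair(x_train, x_test, scheme):
    """Apply a named preprocessing scheme to a train/test split, leakage-free.

    Schemes: ``lognorm_z`` (log-normalize then z-score on train stats),
    ``raw`` (identity), ``binary``, ``tfidf`` (IDF from training cells).
    """
    if scheme == "raw":
        return x_train, x_test
    if scheme == "lognorm_z":
        tr = log_normalize(x_train)
        te = log_normalize(x_test) if x_test is not None else None
        if te is None:
            return standardize_per_feature(tr), None
        return standardize_per_feature(tr, te)
    if scheme == "binary":
        return binarize(x_train), (binarize(x_test) if x_test is not None else None)
    if scheme == "tfidf":
        idf = tfidf_idf(x_train)
        tr = tfidf_transform(x_train, idf)
        te = tfidf_transform(x_test, idf) if x_test is not None else None
        return tr, te
    raise ValueError(f"unknown preprocessing scheme {scheme!r}")
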