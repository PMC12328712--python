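"""Domain types and readers/writers for the formats the tool touches.

Data flows through four containers: a cells × features matrix per modality,
a ±1 label vector, genomic intervals (peaks, gene bodies, TF binding
regions), and named feature groupings (gene sets, peak sets).  Coordinates
follow the BED convention (0-based, half-open) everywhere.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("cellmkl")

MODALITIES = ("RNA", "ATAC", "GAS")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CellByFeatureMatrix:
    """Cells × features count/value matrix for one modality.

    ``values`` may be dense ``ndarray`` or any scipy sparse matrix (stored
    as CSR).  Feature ids must be unique within the modality: duplicate ids
    silently merged into one column would corrupt groupings downstream, so
    they are rejected at construction.
    """

    values: object
    cell_ids: list
    feature_ids: list
    modality: str

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValueError("matrix must be 2-dimensional")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(f"{n} rows but {len(self.cell_ids)} cell ids")
        if p != len(self.feature_ids):
            raise ValueError(f"{p} columns but {len(self.feature_ids)} feature ids")
        seen: set = set()
        dups = sorted({f for f in self.feature_ids if f in seen or seen.add(f)})
        if dups:
            raise ValueError(f"duplicate feature ids in {self.modality}: {dups[:10]}")
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("matrix contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_cells(self):
        return self.values.shape[0]

    def column_index(self):
        """feature id -> column position."""
        return {f: j for j, f in enumerate(self.feature_ids)}

    def subset_features(self, feature_ids):
        idx = self.column_index()
        cols = [idx[f] for f in feature_ids]
        return replace(self, values=self.values[:, cols], feature_ids=list(feature_ids))

    def subset_cells(self, rows):
        rows = np.asarray(rows)
        return replace(
            self,
            values=self.values[rows],
            cell_ids=[self.cell_ids[i] for i in rows],
        )

    def dense(self):
        return self.values.toarray() if sp.issparse(self.values) else self.values


@dataclass
class LabelVector:
    """Per-cell binary phenotype labels encoded ±1.

    The positive class is the one *named by the user*, never inferred from
    ordering, so that AUROC/precision/recall have a fixed direction.
    """

    y: np.ndarray
    positive_class_name: str = "positive"
    negative_class_name: str = "negative"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        bad = set(np.unique(self.y)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be -1/+1, found {sorted(bad)}")

    @classmethod
    def from_strings(cls, labels, positive_class):
        labels = [str(x) for x in labels]
        classes = sorted(set(labels))
        if positive_class not in classes:
            raise ValueError(f"positive class {positive_class!r} not among labels {classes}")
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, found {classes}")
        negative = next(c for c in classes if c != positive_class)
        y = np.where(np.asarray(labels) == positive_class, 1, -1)
        return cls(y, positive_class, negative)

    def __len__(self):
        return len(self.y)

    def check_both_classes(self):
        if not ((self.y == 1).any() and (self.y == -1).any()):
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval, optionally named/stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other, slop=0):
        """≥1 bp intersection with `other` extended by `slop` on both sides."""
        return (
            self.chrom == other.chrom
            and self.start < other.end + slop
            and self.end > other.start - slop
        )

    @property
    def label(self):
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class FeatureGrouping:
    """Named groups of feature ids for one modality (gene sets, peak sets).

    Groups may overlap — shared features across groups are a property of
    real pathway collections and are preserved as-is.
    """

    modality: str
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.groups = {str(k): set(map(str, v)) for k, v in self.groups.items()}

    @property
    def names(self):
        return list(self.groups)

    def __len__(self):
        return len(self.groups)

    def intersect_with(self, feature_ids):
        """Restrict members to features present in a matrix; drop emptied groups.

        Raises if nothing survives — running with no groups is always a
        configuration error (wrong id namespace, wrong file).
        """
        universe = set(map(str, feature_ids))
        kept, dropped = {}, []
        for name, members in self.groups.items():
            inter = members & universe
            if inter:
                kept[name] = inter
            else:
                dropped.append(name)
        if dropped:
            logger.warning("dropping %d empty group(s) after intersection: %s",
                           len(dropped), dropped[:5])
        if not kept:
            raise ValueError("no group retains any feature after intersection with the matrix")
        return FeatureGrouping(self.modality, kept)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _find_sidecar(directory, candidates):
    for c in candidates:
        p = os.path.join(directory, c)
        if os.path.exists(p):
            return p
    return None


def read_matrix(path, format=None, modality="RNA"):
    """Read a cells × features matrix from mtx (+sidecar TSVs), h5ad, or CSV.

    MatrixMarket files are commonly stored features × cells (the 10x
    convention); orientation is detected from the sidecar barcode/feature
    counts and the matrix transposed to cells × features when needed.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = {".mtx": "mtx", ".h5ad": "h5ad", ".csv": "csv"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}; pass format=")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        non_numeric = df.columns[~df.dtypes.apply(lambda d: np.issubdtype(d, np.number))]
        if len(non_numeric):
            raise ValueError(f"non-numeric columns in CSV: {list(non_numeric)}")
        return CellByFeatureMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns), modality)

    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        return CellByFeatureMatrix(
            adata.X, list(adata.obs_names), list(adata.var_names), modality
        )

    if format == "mtx":
        directory = os.path.dirname(os.path.abspath(path))
        feat_path = _find_sidecar(directory, ["features.tsv", "genes.tsv", "peaks.tsv"])
        bc_path = _find_sidecar(directory, ["barcodes.tsv"])
        if feat_path is None or bc_path is None:
            raise FileNotFoundError(
                f"mtx sidecars not found next to {path}: need features.tsv (or genes.tsv/peaks.tsv) and barcodes.tsv"
            )
        features = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
        m = sp.csr_matrix(scipy.io.mmread(path))
        if m.shape == (len(barcodes), len(features)):
            pass
        elif m.shape == (len(features), len(barcodes)):
            m = m.T.tocsr()
        else:
            raise ValueError(
                f"matrix shape {m.shape} matches neither (cells={len(barcodes)}, features={len(features)}) "
                "orientation"
            )
        return CellByFeatureMatrix(m, barcodes, features, modality)

    raise ValueError(f"unknown format {format!r}")


def write_matrix_mtx(matrix, directory):
    """Write features × cells mtx + features.tsv/barcodes.tsv (10x-style)."""
    os.makedirs(directory, exist_ok=True)
    m = matrix.values if sp.issparse(matrix.values) else sp.csr_matrix(matrix.values)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), m.T.tocoo())
    pd.Series(matrix.feature_ids).to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(matrix.cell_ids).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    return os.path.join(directory, "matrix.mtx")


def read_labels(path, positive_class):
    """Read a TSV of cell labels: either one column, or cell_id<TAB>label."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    labels = df.iloc[:, -1].tolist()
    lv = LabelVector.from_strings(labels, positive_class)
    return lv


def read_gmt(path):
    """Parse a GMT gene-set file: name, description, members... per line.

    Overlapping membership between sets is allowed and preserved; duplicate
    set *names* are an error.
    """
    groups = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, _desc, *members = parts
            if name in groups:
                raise ValueError(f"{path}:{lineno}: duplicate group name {name!r}")
            groups[name] = set(m for m in members if m)
    if not groups:
        raise ValueError(f"{path}: empty GMT file")
    return FeatureGrouping("RNA", groups)


def write_gmt(grouping, path, description="cellmkl"):
    with open(path, "w") as fh:
        for name, members in grouping.groups.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_bed(path):
    """Parse a BED file into intervals (file order preserved).

    Columns: chrom, start, end[, name[, score[, strand]]].  Comment lines
    (#, track, browser) are skipped.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: unparsable coordinates: {e}") from None
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return intervals


def write_bed(intervals, path):
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t.\t{iv.strand}\n")


def read_gene_annotation(path):
    """Read a gene annotation BED (chrom, start, end, gene_id, score, strand)
    into a DataFrame with columns gene_id/chrom/start/end/strand."""
    ivs = read_bed(path)
    rows = []
    for iv in ivs:
        if iv.name is None:
            raise ValueError(f"{path}: gene annotation requires a name (4th) column")
        rows.append((iv.name, iv.chrom, iv.start, iv.end, iv.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# Run summary output
# ---------------------------------------------------------------------------

def write_run_summary(summary, directory):
    """Write a run summary as two tidy CSVs + one JSON.

    metrics.csv: one row per (replicate, λ); group_weights.csv: one row per
    (replicate, λ, group); config.json: resolved configuration and seeds so
    the run can be reproduced bit-exactly.
    """
    if summary.metrics.empty:
        raise ValueError("run summary has no replicates; nothing to write")
    os.makedirs(directory, exist_ok=True)
    metrics_path = os.path.join(directory, "metrics.csv")
    weights_path = os.path.join(directory, "group_weights.csv")
    config_path = os.path.join(directory, "config.json")
    summary.metrics.to_csv(metrics_path, index=False, float_format="%.10g")
    summary.weights.to_csv(weights_path, index=False, float_format="%.10g")
    with open(config_path, "w") as fh:
        json.dump(summary.config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return {"metrics": metrics_path, "weights": weights_path, "config": config_path}
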