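"""Construct ATAC peak groupings from prior knowledge.

Three routes from annotation to peak groups:

* gene sets → peaks: each dataset peak is assigned to every gene whose
  body, extended by a window (default 5 kb) on both sides, it overlaps;
  a gene set's peak group is the union over member genes.
* TF binding sets: peaks overlapping a transcription factor's published
  binding regions form that TF's group; when several studies cover the
  same TF the one annotating the most regions is kept, and TFs whose best
  source has fewer than 500 regions are dropped before any overlap.
* gene activity scores: per-cell sums of peak counts over gene body plus
  promoter, a pseudo-expression proxy for ATAC-only datasets.

All overlap arithmetic is 0-based half-open with a ≥1 bp intersection
rule; there is no fractional-overlap threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CellByFeatureMatrix, FeatureGrouping, GenomicInterval

logger = logging.getLogger("cellmkl")


def normalize_chrom_names(intervals, style):
    """Rename chromosomes to a uniform style: 'chr' (chr1) or 'plain' (1).

    Never applied implicitly — mixing naming schemes silently would make
    every overlap empty, so callers opt in via config.
    """
    if style not in ("chr", "plain"):
        raise ValueError("style must be 'chr' or 'plain'")
    out = []
    for iv in intervals:
        c = iv.chrom
        if style == "chr" and not c.startswith("chr"):
            c = "chr" + c
        elif style == "plain" and c.startswith("chr"):
            c = c[3:]
        out.append(GenomicInterval(c, iv.start, iv.end, iv.strand, iv.name))
    return out


def _interval_arrays(intervals):
    """Split intervals into per-chromosome start/end/index arrays."""
    by_chrom = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    out = {}
    for chrom, triples in by_chrom.items():
        a = np.asarray(triples)
        out[chrom] = (a[:, 0], a[:, 1], a[:, 2])
    return out


def _overlap_hits(query_start, query_end, starts, ends):
    """Boolean mask of intervals overlapping [query_start, query_end)."""
    return (starts < query_end) & (ends > query_start)


def map_peaks_to_genes(peaks, genes, window_bp=5000):
    """Assign peaks to genes whose extended body they overlap.

    A peak p maps to gene g iff interval(p) intersects
    [gene_start - window_bp, gene_end + window_bp) by at least 1 bp; a
    peak may map to several genes and genes with no peaks map to the
    empty set.

    Parameters
    ----------
    peaks : list of GenomicInterval (``name`` used as peak id)
    genes : DataFrame with columns gene_id, chrom, start, end
    window_bp : extension on both sides of the gene body, default 5000
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    genes = pd.DataFrame(genes)
    if genes.empty:
        raise ValueError("empty gene annotation table")
    peak_arrays = _interval_arrays(peaks)
    mapping = {}
    for row in genes.itertuples(index=False):
        hits = set()
        if row.chrom in peak_arrays:
            starts, ends, idx = peak_arrays[row.chrom]
            mask = _overlap_hits(row.start - window_bp, row.end + window_bp, starts, ends)
            hits = {peaks[i].label for i in idx[mask]}
        mapping[str(row.gene_id)] = hits
    return mapping


def gene_sets_to_peak_groups(grouping_rna, gene_to_peaks):
    """Translate gene sets into peak groups via a peak→gene mapping.

    Each output group is the set union of the peaks of its member genes.
    Groups whose genes collectively have no peaks are dropped with a
    warning; if every group empties out that is an error (wrong gene
    namespace or annotation).
    """
    out, dropped = {}, []
    for name, gene_ids in grouping_rna.groups.items():
        peaks = set()
        for g in gene_ids:
            peaks |= gene_to_peaks.get(g, set())
        if peaks:
            out[name] = peaks
        else:
            dropped.append(name)
    if dropped:
        logger.warning("%d gene set(s) map to no peaks and are dropped: %s",
                       len(dropped), dropped[:5])
    if not out:
        raise ValueError("all gene sets map to zero peaks; check id namespace and annotation")
    return FeatureGrouping("ATAC", out)


def tf_peak_groups(dataset_peaks, tf_sets, min_peaks=500, study_selector="most_peaks"):
    """Group dataset peaks by overlap with published TF binding regions.

    ``tf_sets`` maps tf_name → list of intervals (single source) or
    tf_name → {study_id: list of intervals} (multiple candidate sources).
    Per TF the source annotating the most regions is retained
    (``most_peaks``); TFs whose retained source has fewer than
    ``min_peaks`` regions are removed before any overlap with the dataset.
    """
    if study_selector != "most_peaks":
        raise ValueError(f"unknown study selector {study_selector!r}")
    if not tf_sets:
        raise ValueError("empty TF set collection")
    peak_arrays = _interval_arrays(dataset_peaks)
    groups = {}
    for tf, sources in tf_sets.items():
        if isinstance(sources, dict):
            if not sources:
                continue
            study = max(sources, key=lambda s: len(sources[s]))
            intervals = sources[study]
        else:
            intervals = sources
        if len(intervals) < min_peaks:
            logger.info("TF %s dropped: best source has %d < %d regions", tf, len(intervals), min_peaks)
            continue
        hits = set()
        for iv in intervals:
            if iv.chrom in peak_arrays:
                starts, ends, idx = peak_arrays[iv.chrom]
                mask = _overlap_hits(iv.start, iv.end, starts, ends)
                hits.update(dataset_peaks[i].label for i in idx[mask])
        if hits:
            groups[tf] = hits
    if not groups:
        raise ValueError("no TF group retained any dataset peak")
    return FeatureGrouping("ATAC", groups)


def gene_activity_score(atac, genes, promoter_bp=2000):
    """Per-cell, per-gene sum of ATAC counts over gene body ∪ promoter.

    The promoter is ``promoter_bp`` upstream of the TSS on the annotated
    strand ('+': upstream of start; '-': upstream of end), so the scored
    region is contiguous with the gene body.  Input must be raw counts.

    Returns a cells × genes matrix with modality GAS.
    """
    if not isinstance(atac, CellByFeatureMatrix):
        raise TypeError("atac must be a CellByFeatureMatrix")
    genes = pd.DataFrame(genes)
    if genes.empty:
        raise ValueError("empty gene annotation table")
    peak_ivs = []
    for fid in atac.feature_ids:
        iv = _parse_peak_id(fid)
        peak_ivs.append(iv)
    peak_arrays = _interval_arrays(peak_ivs)

    gene_ids = [str(g) for g in genes["gene_id"]]
    rows_cols = ([], [])  # peak index, gene index
    for j, row in enumerate(genes.itertuples(index=False)):
        strand = getattr(row, "strand", ".")
        if promoter_bp > 0 and strand not in ("+", "-"):
            raise ValueError(
                f"gene {row.gene_id}: strand required to place a promoter (promoter_bp={promoter_bp})"
            )
        start = row.start - (promoter_bp if strand == "+" else 0)
        end = row.end + (promoter_bp if strand == "-" else 0)
        start = max(start, 0)
        if row.chrom in peak_arrays:
            starts, ends, idx = peak_arrays[row.chrom]
            mask = _overlap_hits(start, end, starts, ends)
            for i in idx[mask]:
                rows_cols[0].append(i)
                rows_cols[1].append(j)
    n_peaks, n_genes = len(peak_ivs), len(gene_ids)
    indicator = sp.csr_matrix(
        (np.ones(len(rows_cols[0])), rows_cols), shape=(n_peaks, n_genes)
    )
    values = atac.values @ indicator
    if sp.issparse(values):
        values = sp.csr_matrix(values)
    return CellByFeatureMatrix(values, atac.cell_ids, gene_ids, "GAS")


def _parse_peak_id(fid):
    """Parse a peak id like 'chr1:100-200' (or chr1-100-200 / chr1_100_200)."""
    for seps in ((":", "-"), ("-", "-"), ("_", "_")):
        try:
            chrom, rest = fid.split(seps[0], 1)
            start, end = rest.rsplit(seps[1], 1) if seps[0] == seps[1] else rest.split(seps[1], 1)
            return GenomicInterval(chrom, int(start), int(end), name=fid)
        except (ValueError, TypeError):
            continue
    raise ValueError(f"cannot parse peak coordinates from feature id {fid!r}")
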