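"""Synthetic multiome-like fixtures with known ground truth.

The generator emulates the statistical structure the classifier assumes:
two cell classes whose difference is concentrated in a few informative
feature groups among many.  RNA counts are negative-binomial with
gene-level base means drawn log-normally and a class log-fold shift on
the member genes of informative groups; ATAC peaks are Bernoulli
presence/absence on a toy genome with real gene annotations, so the
peak→gene mapping, gene-set→peak-group construction, and gene activity
scoring are all exercised end-to-end.  Every dataset carries a truth
record (informative group names, per-modality assignment, generator
parameters) so tests are self-describing.

What this does NOT emulate: batch effects, doublets, ambient
contamination, sequencing-depth confounds — conclusions about those
require real data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    CellByFeatureMatrix,
    FeatureGrouping,
    GenomicInterval,
    LabelVector,
    write_bed,
    write_gmt,
    write_matrix_mtx,
)

MODALITY_PLANS = ("rna", "atac", "both", "complementary")


@dataclass
class ToyGenome:
    """Toy gene annotation + peak set with construction-time truth."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    peaks: list  # GenomicInterval with names
    gene_to_peaks: dict  # gene_id -> set of peak names (by construction)

    @property
    def peak_ids(self):
        return [p.label for p in self.peaks]


def make_toy_genome(n_chroms=2, n_genes=20, seed=0, peaks_per_gene=2,
                    n_intergenic_peaks=10, window_bp=5000):
    """Lay out non-overlapping genes and peaks with a known peak→gene map.

    Genes are spaced so their ±window neighborhoods never overlap; each
    gene receives ``peaks_per_gene`` peaks inside its window, and
    ``n_intergenic_peaks`` decoys are placed strictly farther than the
    window from every gene.  The emitted ``gene_to_peaks`` truth is the
    placement record, independent of any overlap code.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    genes, peaks, truth = [], [], {}
    genes_per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0)
                       for c in range(n_chroms)]
    gi = 0
    gap = 3 * window_bp  # guarantees disjoint ±window neighborhoods
    for c, n_on_chrom in enumerate(genes_per_chrom):
        chrom = f"chr{c + 1}"
        pos = window_bp + 1000
        for _ in range(n_on_chrom):
            length = int(rng.integers(2000, 8001))
            start, end = pos, pos + length
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gi:04d}"
            genes.append((gene_id, chrom, start, end, strand))
            truth[gene_id] = set()
            for _ in range(peaks_per_gene):
                while True:  # resample on the (rare) name collision
                    width = int(rng.integers(200, 601))
                    lo = start - window_bp + 1
                    hi = end + window_bp - width - 1
                    p_start = int(rng.integers(lo, hi))
                    name = f"{chrom}:{p_start}-{p_start + width}"
                    if name not in truth[gene_id]:
                        break
                pk = GenomicInterval(chrom, p_start, p_start + width, name=name)
                peaks.append(pk)
                truth[gene_id].add(pk.label)
            pos = end + gap
            gi += 1
        # decoy peaks in the tail of the chromosome, > window from all genes
        share = n_intergenic_peaks // n_chroms + (1 if c < n_intergenic_peaks % n_chroms else 0)
        decoy_pos = pos + 2 * window_bp
        for _ in range(share):
            width = int(rng.integers(200, 601))
            pk = GenomicInterval(chrom, decoy_pos, decoy_pos + width,
                                 name=f"{chrom}:{decoy_pos}-{decoy_pos + width}")
            peaks.append(pk)
            decoy_pos += width + 2 * window_bp
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    return ToyGenome(genes_df, peaks, truth)


@dataclass
class SyntheticDataset:
    rna: CellByFeatureMatrix | None
    atac: CellByFeatureMatrix | None
    labels: LabelVector
    gene_sets: FeatureGrouping
    genome: ToyGenome | None
    truth: dict = field(default_factory=dict)

    def matrices(self):
        out = {}
        if self.rna is not None:
            out["RNA"] = self.rna
        if self.atac is not None:
            out["ATAC"] = self.atac
        return out


def make_dataset(n_cells=600, n_groups=20, group_size=25, n_informative=3,
                 effect=2.0, modality_plan="rna", imbalance=1.0, seed=0,
                 dispersion=0.5, base_mean_median=2.0, base_mean_sigma=1.0,
                 n_shared_features=0, background_frac=15.0, peaks_per_gene=2,
                 n_intergenic_peaks=20, atac_base_lo=0.05, atac_base_hi=0.25,
                 window_bp=5000):
    """Generate a two-class dataset with group-structured signal.

    Parameters
    ----------
    effect : float
        Group-aggregate class effect size.  Each informative gene's NB
        mean is shifted by a log-fold change of effect/sqrt(group_size),
        and each informative peak's accessibility probability by
        min(0.4, effect/sqrt(group_size · peaks_per_gene)), so the
        aggregated discriminability a group kernel carries is on the
        scale of ``effect`` regardless of group size: the class signal
        is a property of the group, with individually modest features,
        which is the regime the method is designed for.  ``effect=0``
        is an exact null.
    modality_plan : {"rna", "atac", "both", "complementary"}
        Which modalities carry data; ``complementary`` places disjoint
        halves of the informative groups in RNA and ATAC so neither
        modality alone sees all the signal.
    imbalance : float
        Negative:positive cell-count ratio (1.0 = balanced).
    dispersion : float
        NB dispersion α (var = μ + αμ²); default 0.5, recorded in truth.
    base_mean_median, base_mean_sigma : float
        Gene base means are lognormal(ln(median), sigma): a median of 2
        counts/cell with 1 ln-unit spread, typical of the moderately
        expressed genes curated pathway collections are biased toward.
    n_shared_features : int
        Extra cross-memberships per group, mimicking overlapping pathway
        collections (members borrowed from the next group).
    background_frac : float
        Ungrouped null genes added to the RNA matrix, as a multiple of
        the grouped gene count.  Pathway collections cover a minority of
        the transcriptome, and grouping-perturbation protocols draw
        replacement features from the whole matrix, so a background is
        part of realistic study conditions.
    """
    if modality_plan not in MODALITY_PLANS:
        raise ValueError(f"modality_plan must be one of {MODALITY_PLANS}")
    if n_informative > n_groups:
        raise ValueError("n_informative cannot exceed n_groups")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)

    n_pos = int(round(n_cells / (1.0 + imbalance)))
    n_neg = n_cells - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"imbalance {imbalance} leaves a class with < 2 of {n_cells} cells")
    y = np.concatenate([np.ones(n_pos, int), -np.ones(n_neg, int)])
    y = y[rng.permutation(n_cells)]
    labels = LabelVector(y, "case", "control")
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    n_genes = n_groups * group_size
    n_background = int(round(background_frac * n_genes))
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    background_ids = [f"bg{i:04d}" for i in range(n_background)]
    group_names = [f"GROUP_{i:02d}" for i in range(n_groups)]
    groups = {}
    for i, name in enumerate(group_names):
        members = set(gene_ids[i * group_size:(i + 1) * group_size])
        for k in range(n_shared_features):
            members.add(gene_ids[((i + 1) * group_size + k) % n_genes])
        groups[name] = members
    gene_sets = FeatureGrouping("RNA", groups)
    informative = group_names[:n_informative]

    # which modality carries each informative group's signal
    if modality_plan == "complementary":
        half = max(1, n_informative // 2)
        rna_inf = informative[:half]
        atac_inf = informative[half:]
    elif modality_plan == "rna":
        rna_inf, atac_inf = informative, []
    elif modality_plan == "atac":
        rna_inf, atac_inf = [], informative
    else:  # both
        rna_inf, atac_inf = informative, informative

    rna_inf_genes = sorted(set().union(*(groups[g] for g in rna_inf)) if rna_inf else set())
    atac_inf_genes = sorted(set().union(*(groups[g] for g in atac_inf)) if atac_inf else set())

    rna = genome = atac = None
    rna_base = None
    gene_lfc = effect / np.sqrt(group_size)
    peak_shift = min(0.4, effect / np.sqrt(group_size * peaks_per_gene))
    if modality_plan in ("rna", "both", "complementary"):
        rna, rna_base = _simulate_rna(rng, y, gene_ids + background_ids,
                                      rna_inf_genes, gene_lfc, dispersion,
                                      base_mean_median, base_mean_sigma, cell_ids)
    if modality_plan in ("atac", "both", "complementary"):
        genome = make_toy_genome(
            n_chroms=2, n_genes=n_genes, seed=rng.integers(2**31),
            peaks_per_gene=peaks_per_gene, n_intergenic_peaks=n_intergenic_peaks,
            window_bp=window_bp,
        )
        atac, atac_base = _simulate_atac(rng, y, genome, atac_inf_genes, peak_shift,
                                         atac_base_lo, atac_base_hi, cell_ids)

    truth = {
        "informative_groups": informative,
        "rna_informative_groups": rna_inf,
        "atac_informative_groups": atac_inf,
        "rna_informative_genes": rna_inf_genes,
        "atac_informative_genes": atac_inf_genes,
        "effect": effect,
        "gene_log_fold_change": float(gene_lfc),
        "peak_probability_shift": float(peak_shift),
        "dispersion": dispersion,
        "base_mean_sigma": base_mean_sigma,
        "modality_plan": modality_plan,
        "imbalance": imbalance,
        "n_cells": n_cells,
        "n_groups": n_groups,
        "group_size": group_size,
        "n_background_genes": n_background,
        "seed": int(seed) if np.isscalar(seed) else str(seed),
    }
    if rna is not None:
        truth["rna_base_means"] = {g: float(m) for g, m in zip(rna.feature_ids, rna_base)}
    if atac is not None:
        truth["atac_base_probs"] = {p: float(b) for p, b in zip(atac.feature_ids, atac_base)}
    return SyntheticDataset(rna, atac, labels, gene_sets, genome, truth)


def _simulate_rna(rng, y, gene_ids, informative_genes, log_fold_change,
                  dispersion, base_mean_median, base_mean_sigma, cell_ids):
    """NB counts: var = μ + αμ², sampled as NB(r = 1/α, p = r/(r+μ))."""
    n_cells, n_genes = len(y), len(gene_ids)
    base = rng.lognormal(mean=np.log(base_mean_median), sigma=base_mean_sigma,
                         size=n_genes)
    mu = np.tile(base, (n_cells, 1))
    inf_idx = [gene_ids.index(g) for g in informative_genes]
    if inf_idx:
        mu[np.ix_(y == 1, inf_idx)] *= np.exp(log_fold_change)
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    values = sp.csr_matrix(counts.astype(float))
    return CellByFeatureMatrix(values, cell_ids, gene_ids, "RNA"), base


def _simulate_atac(rng, y, genome, informative_genes, shift, base_lo, base_hi,
                   cell_ids):
    """Bernoulli peak accessibility with a probability shift on the peaks
    of informative genes (chosen so the gene-set→peak-group pipeline
    carries the signal end-to-end)."""
    peak_ids = genome.peak_ids
    n_cells, n_peaks = len(y), len(peak_ids)
    base = rng.uniform(base_lo, base_hi, size=n_peaks)
    informative_peaks = set()
    for g in informative_genes:
        informative_peaks |= genome.gene_to_peaks.get(g, set())
    inf_idx = [i for i, p in enumerate(peak_ids) if p in informative_peaks]
    prob = np.tile(base, (n_cells, 1))
    if inf_idx:
        prob[np.ix_(y == 1, inf_idx)] = np.minimum(base[inf_idx] + shift, 0.95)
    counts = (rng.random((n_cells, n_peaks)) < prob).astype(float)
    return CellByFeatureMatrix(sp.csr_matrix(counts), cell_ids, peak_ids, "ATAC"), base


def derive_atac_grouping(dataset, window_bp=5000):
    """Build the ATAC peak grouping from the dataset's gene sets through
    the peak→gene mapping pipeline (the same route real data takes)."""
    from .grouping import gene_sets_to_peak_groups, map_peaks_to_genes

    if dataset.genome is None:
        raise ValueError("dataset has no ATAC modality")
    g2p = map_peaks_to_genes(dataset.genome.peaks, dataset.genome.genes, window_bp)
    return gene_sets_to_peak_groups(dataset.gene_sets, g2p)


def save_dataset(dataset, directory):
    """Write the dataset as plain-text artifacts: 10x-style mtx + TSVs,
    labels.tsv, sets.gmt, genes.bed, peaks.bed, truth.json."""
    os.makedirs(directory, exist_ok=True)
    if dataset.rna is not None:
        write_matrix_mtx(dataset.rna, os.path.join(directory, "rna"))
    if dataset.atac is not None:
        write_matrix_mtx(dataset.atac, os.path.join(directory, "atac"))
    some = dataset.rna or dataset.atac
    labels_df = pd.DataFrame({
        "cell_id": some.cell_ids,
        "label": np.where(dataset.labels.y == 1,
                          dataset.labels.positive_class_name,
                          dataset.labels.negative_class_name),
    })
    labels_df.to_csv(os.path.join(directory, "labels.tsv"), sep="\t",
                     header=False, index=False)
    write_gmt(dataset.gene_sets, os.path.join(directory, "sets.gmt"))
    if dataset.genome is not None:
        write_bed(dataset.genome.peaks, os.path.join(directory, "peaks.bed"))
        gene_ivs = [GenomicInterval(r.chrom, r.start, r.end, r.strand, r.gene_id)
                    for r in dataset.genome.genes.itertuples(index=False)]
        write_bed(gene_ivs, os.path.join(directory, "genes.bed"))
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory
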