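# cellmkl

Interpretable classification of single cells from RNA and/or ATAC
profiles, with the answer expressed in the currency biologists use:
**which pathways and which regulatory programs separate the classes**.

Standard high-accuracy classifiers for single-cell data are opaque;
interpretable linear models underfit. `cellmkl` takes a middle road:
multiple kernel learning, with **one kernel per prior-knowledge feature
group** — pathway gene sets (e.g. MSigDB Hallmark) for scRNA-seq,
transcription-factor binding peak sets or gene-set-derived peak groups
for scATAC-seq — made scalable by **random Fourier features** and made
sparse and interpretable by a **group lasso**.

For cells (x_i, y_i), y_i ∈ {−1, +1}, and feature groups G_1 … G_P, each
group's shift-invariant kernel k_g (Gaussian for RNA, Laplacian for
binary ATAC) is approximated by a random feature map
Z_g = √(1/D)[cos(XW_g) | sin(XW_g)] with frequencies W_g drawn from the
kernel's spectral density, and the blocks are concatenated into one
design for

  min_β (1/2)‖ỹ − Z̃β‖² + λ Σ_g ‖β_g‖₂ .

The group penalty selects or zeroes whole kernels: η_g = ‖β_g‖₂ is the
learned importance of pathway/TF group g.  λ is tuned by stratified
4-fold cross-validation over a 10-value grid spanning
"one group selected" to "all groups selected", inside an outer loop of
repeated stratified 80/20 train/test splits; selection frequencies and
weights across replicates are the interpretation output.  See
`docs/methods.md` for the full model description.

Supported inputs: MatrixMarket `.mtx` (+ `features.tsv`/`barcodes.tsv`,
either orientation), `.h5ad`, CSV; GMT gene sets; BED peak/gene/TF
annotations; TSV labels.  Utilities cover TF-IDF and binarization for
ATAC, log-normalization for RNA, 5 kb peak→gene mapping, TF peak-set
grouping (largest study per TF, ≥500-peak filter), and gene activity
scores.  A synthetic-data module generates multiome-like data with
planted informative groups so every stage is testable offline.

## Worked example

```python
import cellmkl as mkl

# 300 cells, 8 gene groups of 10; groups 0 and 1 carry the class signal
ds = mkl.make_dataset(n_cells=300, n_groups=8, group_size=10,
                      n_informative=2, effect=2.0, seed=0)
summary = mkl.run_experiment(ds.matrices(), {"RNA": ds.gene_sets},
                             ds.labels, n_replicates=5, seed=0)
best = summary.best_metrics()
print(f"mean held-out AUROC at the CV lambda: {best['auroc'].mean():.3f}")
_, per_group = mkl.selection_frequency(summary)
print(per_group.sort_values('mean_frequency', ascending=False).head(4).to_string(index=False))
```

prints

```
mean held-out AUROC at the CV lambda: 0.947
   group modality  mean_frequency  mean_eta
GROUP_01      RNA            0.94  0.871715
GROUP_00      RNA            0.78  0.850784
GROUP_02      RNA            0.14  0.040074
GROUP_05      RNA            0.12  0.039843
```

Held-out cells are classified with AUROC 0.95, and the two planted
groups (GROUP_00, GROUP_01) dominate both selection frequency (how often
a group's kernel is kept across replicate splits, averaged over the λ
grid) and mean weight η — the uninformative groups trail far behind.

## Command line

```bash
cellmkl simulate --out sim/ --n-cells 600
cellmkl run --rna sim/rna/matrix.mtx --labels sim/labels.tsv \
            --positive-class case --gmt sim/sets.gmt --out run/ \
            --replicates 20 --seed 1
cellmkl interpret --summary run/ --out interp/          # dot-plot tables
cellmkl ablate  ... --remove GROUP_00                   # leave-group-out
cellmkl perturb ... --mode corrupt                      # robustness curves
```

Every run writes `resolved_config.json` (all defaults and seeds);
re-running with the same resolved config reproduces outputs
byte-for-byte.

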