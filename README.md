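# annosom

Automated annotation and differential abundance analysis for
**over-clustered cytometry data**.

Modern mass- and spectral-flow cytometry pipelines cluster millions of cells
into hundreds or thousands of SOM-style clusters, which then have to be
merged into biologically meaningful cell populations. That merging step is
usually manual: an analyst inspects each marker's per-cluster median
expression, decides where "negative" ends and "positive" begins, and sorts
clusters into a gating hierarchy (T cells → CD8 T cells → central-memory
CD8 T cells, …). `annosom` automates the computational part of that
workflow for anyone working downstream of FlowSOM/GigaSOM-style clustering:

1. **Threshold estimation** (`annosom.thresholds`). Per-marker cluster
   medians are typically bimodal. For each marker the low/high boundary is
   estimated two ways — an *exact* 1D two-means split (all `n−1` contiguous
   splits of the sorted vector are scored; no random initialisation) and a
   two-component Gaussian mixture fitted by EM whose threshold is the
   density crossing `w₁ φ(x; μ₁, σ₁) = w₂ φ(x; μ₂, σ₂)` between the
   component means. Each candidate partition `x ≤ t` vs `x > t` is scored by
   its mean silhouette width `s = (b − a)/max(a, b)`, and the better method
   wins. Sarle's bimodality coefficient
   `BC = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3)))` is reported per marker;
   values above 5/9 ≈ 0.555 (the uniform distribution's asymptotic value)
   flag a usable bimodal split. Thresholds can be overridden manually and
   saved/reloaded as CSV.
2. **Tree annotation** (`annosom.tree`). Phenotypes form a hierarchy rooted
   at "unassigned". Each node is a set of positive/negative marker
   constraints; a cluster is filtered top-down into the first child whose
   constraints it satisfies against the current thresholds (strictly above
   threshold = positive). A node's full definition is the cumulative
   constraint set along its branch. Changing any threshold recomputes the
   whole assignment deterministically. Clusters left behind at an internal
   node become a `<name>_remaining` population.
3. **Differential abundance** (`annosom.abundance`). Cluster counts are
   summed per terminal phenotype and sample, converted to within-sample
   proportions, and every phenotype is compared between each pair of
   conditions with a two-sided Wilcoxon rank-sum test (exact enumeration up
   to 25 tie-free samples), with Bonferroni / Holm / Hochberg /
   Benjamini–Hochberg adjustment.
4. **Synthetic data** (`annosom.simulate`). A ground-truth generator emits
   complete projects (expression, frequency, metadata, counts + generating
   tree) with bimodal marker modes and Dirichlet-multinomial per-sample
   counts carrying a configurable fold-change, so the entire pipeline is
   testable without any real dataset.

## Worked example

```bash
annosom simulate --outdir demo --seed 7
annosom thresholds --expression demo/expression.csv --out demo/thresholds.csv
annosom annotate --expression demo/expression.csv \
    --thresholds demo/thresholds.csv --tree demo/annotation.csv \
    --out-labels demo/labels.csv
annosom da --labels demo/labels.csv --counts demo/counts.csv \
    --metadata demo/metadata.csv --adjust hochberg --out demo/da.csv
```

The simulated project has 200 clusters over a 10-marker panel, six ground
truth populations, 8 control + 8 case samples of 100 000 cells, and a
two-fold abundance increase of B cells in the case arm. `demo/da.csv` then
contains (one row per phenotype × condition pair):

```
phenotype,group_a,group_b,n_a,n_b,statistic,p_raw,p_adjusted
B cells,case,control,8,8,64.0,0.0001554001554001554,0.0001554001554001554
CD4 T cells,case,control,8,8,19.0,0.19487179487179485,0.19487179487179485
CD8 T cells,case,control,8,8,18.0,0.1605283605283605,0.1605283605283605
NK cells,case,control,8,8,4.0,0.0018648018648018648,0.0018648018648018648
T cells_remaining,case,control,8,8,14.0,0.06495726495726495,0.06495726495726495
unassigned,case,control,8,8,15.0,0.08289640988222398,0.08289640988222398
```

`statistic` is the Mann–Whitney U of the first (case) group: 64 = 8·8 means
every case sample has a higher B-cell proportion than every control sample,
giving the smallest possible exact p (0.00016). The spiked phenotype is the
clear top hit; the mild counter-shifts in other populations (e.g. NK cells
at U = 4) are the arithmetic consequence of proportions summing to one. The same workflow is
available as library calls (`simulate_project`, `estimate_thresholds`,
`recompute`, `terminal_labels`, `run_da`); every CSV written by one step is
a documented, reloadable interface.

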