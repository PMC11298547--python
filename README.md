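# tanypsa

Pseudospatial analysis of gradient-organized ependymal cell populations.

The wall of the third ventricle is lined by a continuum of ependymoglial
cells — typical ependymal cells dorsally, then α1-, α2-, β1- and β2-tanycytes
toward the ventral tip — whose gene expression changes gradually along the
dorso-ventral axis rather than in discrete steps. `tanypsa` is a library for
dissecting such gradients from single-cell UMI counts:

- **Pseudospace**: order cells on a 1-D axis *s* ∈ [0, 1] (rank-normalized
  principal axis, anchored so ependymal markers sit at *s* = 0 and β2 markers
  at *s* = 1) and fit per-gene cubic B-spline profiles *f<sub>g</sub>(s)* on a
  shared grid.
- **Marker classification** (specific vs. shared): correlate every gene with
  binary indicator vectors of all 30 population subsets; keep positive
  correlations with BH-adjusted *p* < 0.01 and assign each gene the subset
  maximizing *score = r · w̄*, where *w̄* is the subset's mean expression.
  Singleton winners are specific markers; the {ependymal, β2} subset captures
  U-shaped profiles high at both axis ends.
- **Unsupervised segmentation**: cluster standardized profiles into patterns
  (k-means, silhouette-selected k, patterns with ≤ 50 genes dropped), mark
  on–off switches as threshold-gated zero crossings (gates ±0.1 … ±0.5), and
  sum them into transition scores whose peaks are the "split regions"
  separating populations.
- **Differential pseudospatial analysis (DPSA)**: compare each gene's fed
  profile with its fasting profile (Pearson *r* + center-of-mass displacement
  Δc) and call dorso→ventral (Δc > δ) or ventro→dorsal (Δc < −δ) shifts.
- **Pseudobulk differential expression**: split each (population, condition)
  stratum into four equal pseudo-replicates, sum counts, and test with a
  negative-binomial Wald test (median-of-ratios size factors, trended
  moment dispersions); classify genes along fed → 12 h → 24 h fasting into
  temporal trajectory families I/D/T with shape sub-indices (I1 … T6).
- **Cell–cell communication**: per ligand–receptor pair, score = mean ligand
  expression over sender cells × receptor summary over receiver cells
  (geometric mean of subunit means), per pseudo-replicate; one-way ANOVA
  across conditions, DeltaScores, and per-category up/down summaries.
- **Synthetic data**: a generator that plants all of the above — populations
  on axis intervals, specific/gradient/U-shape/shifted gene programs, NB
  noise, library-size variation, and LR rewiring — so every stage is testable
  against known ground truth.

## Worked example

```python
import tanypsa as tp
from tanypsa.pipeline import default_anchor_genes
from scipy.stats import spearmanr

adata, truth = tp.generate_dataset(tp.default_config(seed=1))
filtered, report = tp.qc_filter(adata)          # mito MAD + min-genes filters
norm = tp.normalize(filtered)                   # log1p(count/total * 1e4)

ps = tp.order_cells(norm, default_anchor_genes(norm))
print(spearmanr(ps.s, norm.obs["true_s"]).statistic)   # 0.971

design = tp.make_design(norm)
table = tp.assign_markers(tp.correlate_memberships(norm, design), norm, design)
spec = norm.var.index[norm.var["program"] == "specific"]
print((table.reindex(spec)["subset"] == norm.var.loc[spec, "subset"]).mean())  # 1.0
```

The Spearman ρ of 0.971 says the inferred axis reproduces the planted cell
ordering almost perfectly; the 1.0 is the fraction of planted
population-specific genes assigned exactly their own population. Running
`python examples/04_dpsa_shifts.py` prints the DPSA recovery of planted
profile shifts (100% of +0.2-shifted genes called dorso→ventral, mean
recovered displacement +0.201), and `examples/06_communication_scores.py`
shows the planted LR rewiring: secreted-signaling scores fall at 24 h
fasting while ECM-receptor scores rise.

Each script in `examples/` is a short narrative for one capability. A thin
CLI mirrors the stages (`tanypsa simulate | qc | pseudospace | markers |
patterns | dpsa | de | trajectories | ccc | run-all`).

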