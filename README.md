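# rots

Reproducibility-optimized differential expression testing for two-group
RNA-seq count data.

Instead of fixing a test statistic in advance, the method selects one from a
family of modified t-statistics

```
d(g) = |mean1(g) - mean2(g)| / (a1 + a2 * s_g)
```

(`a1 >= 0`, `a2 in {0, 1}`, `s_g` the pooled two-group standard error) by
maximizing a z-type reproducibility score: the average overlap of the top-k
gene lists across pairs of within-group bootstrap datasets, standardized
against the overlap under random permutation of the group labels and the
bootstrap SD. The scan runs over a dense `a1` lattice and top-list sizes `k`
from 5 to the number of genes. Significance at the selected statistic is
assessed with a permutation FDR. As a rule of thumb, an optimized z-score
below 2 means the data or the statistic are insufficient for reliable
detection (the run warns but still completes).

The package also provides:

- **TMM scaling + log-CPM transformation** (`rots.normalize`) — the
  preprocessing the statistic expects; factors are computed from
  within-sample count proportions and are invariant to rescaling any column.
- **A negative-binomial spike-in-style simulator** (`rots.simulate`) — known
  fold-change truth (preset: 92 controls at fold changes 0.5/0.67/1/4, 23 of
  them null, five replicates per group) embedded in a null background, with
  NB noise (`var = mu + phi * mu^2`) and unequal library sizes.
- **An evaluation harness** (`rots.evaluate`) — ROC AUC (rank formulation,
  ties count 1/2) and confusion counts at an FDR cutoff.

## Command line

```sh
# simulate a spike-in style benchmark (writes counts/design/truth tables)
rots simulate --genes 1000 --n 5 --preset spikein --seed 1 --out sim

# run the full test
rots run --counts sim.counts.tsv --design sim.design.tsv \
         --out fit --b 1000 --seed 1
# -> fit.results.tsv (gene_id, statistic, logfc, fdr)
#    fit.summary.tsv (alpha1, alpha2, k_opt, R_opt, Z_opt, B, P, seed, ...)

# score the results against the simulation truth
rots evaluate --results fit.results.tsv --truth sim.truth.tsv --fdr-cutoff 0.05
```

Useful `run` flags: `--no-normalize` (skip TMM for pre-normalized input),
`--prior-count` (log-CPM pseudo-count), `--p-perms` (FDR permutations,
default `--b`), `--alpha-grid FILE` / `--k-grid FILE` (custom lattices).
Input matrices are plain delimited text (tab or comma, auto-detected), genes
in rows, first row a sample header, first column gene ids; designs are
two-column files (sample id, group label) without a header.

Every run is fully deterministic given `--seed`.

## Python API

```python
import rots

counts = rots.read_counts("sim.counts.tsv")
design = rots.read_design("sim.design.tsv")
fit = rots.run_rots(counts, design, B=1000, seed=1)
print(fit.alpha, fit.k_opt, fit.Z_opt)
rots.write_results(fit, "fit.results.tsv")
```

Lower-level pieces (`d_stat`, `make_bootstrap_pairs`, `reproducibility_curves`,
`optimize`, `estimate_fdr`, ...) are exposed for custom pipelines.

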