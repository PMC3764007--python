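# spcn — sparse partial correlation networks

`spcn` infers sparse undirected networks of *direct* associations from a
samples × variables signal matrix (e.g. per-promoter histone-modification,
chromatin-accessibility, and expression levels). The pipeline:

1. **Rank transform** — every column is replaced by its ranks (midranks for
   ties), so results are invariant to strictly monotone marginal transforms
   and robust to outliers and multimodal marginals.
2. **Partial correlation matrix (PCM)** — the correlation matrix is inverted,
   normalized to unit diagonal, and negated:
   `P_ij = -W_ij / sqrt(W_ii W_jj)` with `W = C⁻¹`.
3. **Significance** — Fisher-z per entry, `z = atanh(r)·sqrt(n − k − 3)` with
   `k = p − 2` control variables, two-sided normal p-values, Benjamini–
   Hochberg q-values over all p(p−1)/2 tests.
4. **Cross-validated sparsification** — with very large n *every* entry is
   significant, so per fold (10-fold CV) a q-threshold sweep is scored by the
   mean OLS test-prediction error using each variable's co-variables only;
   the sparsest threshold whose error stays within 10% of the min–max error
   range is selected. Edges kept in ≥ 7/10 folds form the mask applied to the
   full-data PCM. Optionally one special node (e.g. `mRNA`) is completed up
   to degree 4 with its lowest-q remaining edges.
5. **Downstream** — explaining-away effect matrices (partial vs marginal
   correlation, strongest single explainer per pair), top-n overlap curves
   between conditions with hypergeometric / Monte-Carlo nulls, and consensus
   networks across conditions with support counts and sign-conflict flags.

A synthetic-data module generates samples from sparse Gaussian graphical
models with known edge sets, optionally distorted through strictly monotone
(lognormal / bimodal-mixture) marginal transforms that leave ranks — and
hence the entire pipeline output — unchanged.

## CLI

```sh
# simulate a known GGM and sample a matrix from it
spcn simulate --p 23 --edges 40 --n 12000 --seed 1 --out sim.tsv --truth truth.tsv

# partial correlations + p/q-value matrices
spcn pcm --input sim.tsv --out-prefix pcm

# sparse network (edge list TSV + GraphML + CV curves + run metadata JSON)
spcn network --input sim.tsv --folds 10 --min-support 7 --tolerance 0.10 \
             --seed 1 --out-prefix run1
# add --special-node mRNA to complete that node's degree up to 4

# explaining-away effect table (optional --plot heatmap.png)
spcn effects --input sim.tsv --out effects.tsv

# top-n overlap between two or more conditions' ranked pair lists
spcn overlap --inputs cond1.tsv --inputs cond2.tsv --out overlap.tsv

# consensus network across conditions
spcn consensus --inputs run1.graphml --inputs run2.graphml --min-conditions 2 \
               --out consensus.graphml
```

Input matrices are TSV: header row of variable names, first column of
sample/region ids; gzip is transparent. `normalize_counts` converts raw read
counts to reads/bp (fixed 4000 bp window for ChIP-style columns, per-row
transcript lengths for mRNA columns).

## Python API

```python
import spcn

truth = spcn.random_sparse_precision(p=23, n_edges=40, min_abs_partial=0.1, seed=1)
X = spcn.sample_ggm(truth, n=12000, seed=2)
net = spcn.build_spcn(X, n_folds=10, min_support=7, tolerance=0.10, seed=3)
net.to_network()          # edge list with weights, q-values, support, provenance
spcn.effect_matrix(X)     # explaining-away analysis
```

## Tests and acceptance report

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the property-based acceptance checks (oracle
equivalence of the two partial-correlation routes, BH vs brute force,
Fisher-z calibration, synthetic edge recovery, rank invariance, overlap
enumeration checks, …) from scratch and prints a PASS/FAIL summary to
stderr. No numeric headline targets are reproducible at desk scale (they
require external multi-GB genomics datasets), so the JSON target object it
writes is empty by design.

## Notes

- The rank transform is applied once, before fold splitting; the mild
  train/test leakage through shared ranks is a deliberate simplification.
- The Fisher-z degrees-of-freedom offset (`n − k − 3`) is configurable via
  `df_offset`.
- Null overlap lists are sampled without replacement by default (a ranked
  top-n list has distinct pairs); `--with-replacement` reproduces the
  alternative null.
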