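# stance-st

Detection of **spatially variable genes (SVGs)** and **cell-type-specific
spatially variable genes (ctSVGs)** in spatial transcriptomics, with results
that are provably invariant to how the tissue section happened to be
oriented on the slide.

## The problem

A gene is spatially variable when its expression forms a non-random pattern
across tissue locations. Much of that variation is driven by where
different cell types sit, so a gene can be spatially patterned *within* one
cell type yet look flat overall (and vice versa). Methods that model
cell-type spatial effects as fixed functions of the coordinates give
different answers when the section is rotated — an arbitrary artifact of
sample preparation. This package instead puts the cell-type spatial effects
in the *covariance*: for one gene's normalized expression `y` over `n`
spots with coordinates `s`, cell-type proportions `Π = (π_1 … π_K)` and
covariates `X`,

```
y = X β + π_1 ⊙ γ_1(s) + … + π_K ⊙ γ_K(s) + ε,
γ_k ~ N(0, τ_k K),    ε ~ N(0, σ²_ε I),
```

so `Cov(y) = Σ_k τ_k Σ_k + σ²_ε I` with `Σ_k = diag(π_k) K diag(π_k)` and
`K` a Gaussian (or Laplacian / Matérn-3/2) kernel of the pairwise spot
distances. Because `K` depends only on distances, every test below is
exactly rotation- and translation-invariant.

Testing proceeds in two stages:

1. **Overall test** (`H0: τ_1 = … = τ_K = 0`) — a variance-component score
   test `Q = ½ yᵀP̂ (Σ_k Σ_k) P̂ y` against a moment-matched scaled
   chi-square (an exact weighted-chi-square inversion is available for
   verification), aggregated across a bandwidth grid by the Cauchy
   combination rule and screened by Benjamini–Yekutieli FDR. Genes passing
   are *unified-type SVGs* (utSVGs): the union of SVGs and ctSVGs.
2. **Individual tests** (`H0: τ_k = 0`, one cell type at a time, utSVGs
   only) — same score-test machinery, but the null model keeps the other
   `K−1` components, fitted by constrained REML.

A per-gene **variance decomposition** additionally reports the share of
variance attributable to each cell type's spatial effect (the data behind
stacked variance bar plots), and a **synthetic-data module** generates the
cell-level point-process study designs used for validation.

## Worked example

```python
import numpy as np
from stance import TwoStageSVGTest, VarianceComponents, filter_dataset, normalize_counts
from stance.simulate import SimulationConfig, simulate_dataset

# a synthetic tissue: 4000 cells, one spatially-variable domain, 3 cell
# types (10/30/60%), 400 spots after grid aggregation
ds, cells = simulate_dataset(SimulationConfig(design="sim2", dispersion=1.5, seed=2))
ds = normalize_counts(filter_dataset(ds, min_spot_total=10, min_expr_frac=0.1))

est = TwoStageSVGTest(alpha=0.05, n_bandwidths=1).fit(ds)
print(f"{len(est.utsvg_gene_ids_)} utSVGs of {ds.n_genes} genes at BY-FDR 0.05")
print("ctSVGs per cell type:", (est.individual_p_adj_ <= 0.05).sum(axis=0))

dec = VarianceComponents().fit(ds, genes=est.utsvg_gene_ids_[:3])
print(dec.to_frame().round(3).to_string(index=False))
```

Output:

```
637 utSVGs of 1000 genes at BY-FDR 0.05
ctSVGs per cell type: [ 24 127 214]
gene_id  tau_type_1  tau_type_2  tau_type_3  sigma2  prop_type_1  prop_type_2  prop_type_3  prop_error
 gene_1       9.670       0.437       0.000   1.710        0.106        0.025        0.000       0.869
 gene_2       2.172       0.930       0.027   1.852        0.023        0.052        0.005       0.919
 gene_3      11.910       0.174       0.000   1.771        0.124        0.009        0.009       0.857
```

In this design genes 0–299 are cell-type marker genes (here: 2-fold
elevated in type 1 everywhere), genes 300–899 carry true within-cell-type
spatial patterns (200 per type), and the rest are noise. The first three
utSVGs are type-1 markers: a uniform within-type elevation is
indistinguishable from a constant draw of the type-1 spatial effect, so
the model flags them and the decomposition attributes ~10–12% of their
variance to cell type 1 — the same behavior that makes the method useful
for surfacing cell-type marker genes in real tissue. Power for genuine
ctSVGs rises with the proportion of the carrying cell type (60% ≫ 10%),
which is why type 3 yields by far the most ctSVG calls.

A command-line interface mirrors the library:

```bash
stance simulate --design sim2 --dispersion 1.5 --seed 2 --out sim/
stance two-stage --counts sim/counts.tsv --coords sim/coords.csv \
    --composition sim/composition.csv --min-spot-total 10 --min-expr-frac 0.1 \
    --alpha 0.05 --out results/
```

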