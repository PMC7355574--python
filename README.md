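# sigselect

Sparse, stable gene-signature discovery from qPCR expression panels.

Targeted real-time PCR panels measure a few dozen genes in small patient
cohorts (often 12–30 samples per group, e.g. hematopoietic CD34+ cells from
different graft sources before and after transplantation). The question is
rarely "which single gene differs" but "which small, reproducible *set* of
genes separates the two groups". `sigselect` implements that workflow end to
end:

1. **Relative quantification** — raw cycle thresholds to 2^−ΔΔCt values
   against a housekeeping gene and a calibrator reference.
2. **Univariate screening** — per-gene two-sided Mann–Whitney tests with
   significance tiers and BH adjustment.
3. **Signature selection** — a linear classifier `f(x) = β·x` whose weights
   minimize

   ```
   (1/n)‖Y − Xβ‖² + τ‖β‖₁ + λ‖β‖²
   ```

   (elastic-net-type: the ℓ1 weight τ forces exact zeros, the ℓ2 weight λ
   lets correlated genes enter together), embedded in **nested K-fold
   cross-validation**: inner folds pick (τ*, λ*), outer folds provide
   unbiased held-out predictions and one gene list each. Genes selected in
   ≥50% of outer folds form the signature, ranked by that frequency.
4. **Performance metrics** — accuracy and the Matthews Correlation
   Coefficient, MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
   pooled over held-out predictions.
5. **Enrichment** — exact hypergeometric over-representation of the
   signature against GMT gene-set collections.
6. **Synthetic benchmarks** — a seeded generator of panel-shaped two-class
   datasets with planted effects, correlated gene blocks and Ct-scale
   noise, so the whole pipeline is testable with known ground truth.

## Worked example

`examples/03_signature_discovery.py`:

```python
from sigselect import CVConfiguration, SyntheticSpec, generate, run_nested_cv

ds = generate(SyntheticSpec(n_per_class=(12, 15), planted_genes=6, seed=3))
fold_results, signature = run_nested_cv(
    ds.expression, ds.spec.class_names, CVConfiguration(seed=3)
)
```

prints (≈20 s):

```
signature (6 genes at >=50% fold frequency):
  G008 * 100.0%  down
  G016 * 100.0%  down
  G022 * 100.0%  down
  G017 *  60.0%  up
  G070 *  60.0%  down
  G073 *  60.0%  up
pooled accuracy: 100.0%
pooled MCC:      1.00
```

All six genes carrying a true planted effect (`*`) are recovered; the
frequency column is the share of outer folds whose sparse model used the
gene, and accuracy/MCC are computed only on held-out outer-fold
predictions. The other `examples/` scripts walk through quantification,
univariate screening and enrichment the same way.

A thin CLI covers the two shell-level tasks:

```bash
sigselect simulate --spec spec.yaml --out data/
sigselect select --matrix data/expression.csv --labels data/annotation.csv \
    --classes groupA,groupB --out sigdir/
```

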