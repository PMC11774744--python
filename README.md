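# chemosig

Chemoresistance biomarker screening and prognostic gene-signature
discovery for expression data.

Tumor cultures (patient-derived organoids, cell lines) can be profiled
for both transcriptome and drug sensitivity (IC50). `chemosig`
implements the computational chain that turns such panels into
survival-predicting classifiers for patient cohorts:

1. **IC50 estimation** — four-parameter log-logistic fits
   `f(x) = c + (d − c)/(1 + (x/e)^b)` to viability data; relative
   (inflection `e`) or absolute (`f(x) = 0.5`) IC50.
2. **Correlation screening** — per dataset, Spearman ρ of every gene
   against IC50; a gene is a hit when `|ρ| > 0.3` and `p < 0.05`.
3. **Co-directional intersection** — keep genes significant with the
   *same sign in every dataset*; reproducibility across independent
   panels is the false-positive control. Cross-drug overlaps and sign
   contradictions are reported.
4. **Signature search** — gated forward beam search over logistic
   regressions: grow gene sets up to 12 genes, requiring the new gene
   `p < 0.15` and all retained genes `p < 0.05` (Wald), pruning each step
   to the top 50% by repeated stratified 3-fold CV ROC-AUC; select the
   model with the best CV AUC among those with train and test AUC above a
   threshold (0.85, falling back to 0.75).
5. **Survival evaluation** — patients are labelled by the 5-year rule
   (event within 5 y → unfavorable; event-free past 5 y → favorable;
   otherwise uncertain); predicted groups are compared with Kaplan-Meier
   curves, the log-rank test, and a multivariate Cox proportional-hazards
   model (HR with 95% CI, Efron or Breslow ties).

A synthetic-data module generates in-vitro panels with genes planted at a
target Spearman ρ against IC50, patient cohorts with a planted logistic
signature and right-censored survival, and noisy dose-response plates —
so the entire chain is testable offline. See `docs/methods.md` for the
models, defaults, and limitations.

## Worked example

```python
import chemosig as cs

# three synthetic in-vitro panels sharing 10 genes truly correlated
# (|rho| = 0.7) with log-IC50, among 500 nulls
spec = cs.PanelSpec(seed=1)
sets = []
for expr, resp in cs.simulate_invitro_panel(spec):
    norm = cs.size_factor_log_transform(expr)
    res = cs.spearman_screen(norm, resp.ic50_series("drugX"))
    sets.append(cs.filter_significant(res))
hits = cs.codirectional_intersection(sets, drug="drugX")
print(sorted(hits.positive_genes), sorted(hits.negative_genes))

# a 160-patient cohort with a 5-gene planted signature in a 60-gene pool
expr, cohort = cs.simulate_cohort(cs.CohortSpec(seed=1))
registry, sel, train, test = cs.discover_signature(
    expr, cohort, config=cs.SearchConfig(seed=1))
m = sel.model
print(m.genes)
print(f"train {m.train_auc:.3f}  cv {m.cv_auc:.3f}  test {m.test_auc:.3f}")

labels, prob = cs.classify(m, expr)
report = cs.evaluate_predictions(cohort, labels, cohort.covariates)
print(f"HR {report['cox'].hazard_ratio('predicted_unfavorable'):.1f}  "
      f"log-rank p {report['logrank']['p']:.2e}")
```

Output:

```
['PLT01', 'PLT02', 'PLT03', 'PLT05'] ['PLT06', 'PLT07', 'PLT08', 'PLT09', 'PLT10']
('SIG4', 'SIG3', 'SIG5', 'SIG1', 'SIG2', 'N045', 'N012', 'N027', 'N011', 'N055', 'N036', 'N054')
train 0.964  cv 0.899  test 0.860
HR 12.1  log-rank p 3.25e-19
```

Nine of the ten planted correlation biomarkers survive the
co-directional intersection with zero null contamination (a ρ = 0.7 gene
at n = 30 clears the per-dataset filter with probability ≈ 0.99, so an
occasional planted gene narrowly misses in one panel); the beam search
finds a 12-gene signature containing all five planted prognostic genes,
generalizing to held-out patients (test AUC 0.86); the
predicted-unfavorable group has a 12-fold higher hazard of death,
adjusted for age and sex.

There is also a CLI (`chemosig simulate|fit-dr|screen|intersect|search|
evaluate`) operating on TSV/JSON files; run `chemosig --help`.

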