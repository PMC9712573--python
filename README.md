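# tikd

Diagnostic-yield analysis for targeted gene-panel screens of hereditary
tubulointerstitial kidney disease (ADTKD, MITKD, nephronophthisis and
Alport-spectrum disease) in adult CKD registries.

Hereditary tubulointerstitial kidney diseases show no pathognomonic
clinical or histologic sign — just progressive CKD with interstitial
fibrosis — so they are systematically under-diagnosed. One way to find
them is to pre-select registry members whose leading diagnosis and age at
inclusion make an inherited cause plausible, sequence a small targeted
panel (29 genes: the five classic ADTKD genes *MUC1*, *UMOD*, *REN*,
*HNF1B*, *SEC61A1*; three differential-diagnosis genes; *COL4A3/4/5*; 17
nephronophthisis genes; plus the mitochondrial genome), and ask whether
the resulting diagnostic yield beats what unselected exome sequencing
achieves. This package implements the complete statistical workflow of
such a screen, for genetic epidemiologists and clinical bioinformaticians:

- **Cohort funnel** (`tikd.filtering`): nine-category selection with
  per-category inclusive age cutoffs (≤50 y default, ≤40 y for the
  glomerulonephritis-adjacent categories, none for "hereditary
  disorders"), six exclusion conditions, deduplication of
  (individual, category) entries, and DNA-quality/identity QC gates.
- **Variant classification** (`tikd.acmg`): the categorical ACMG/AMP
  2015 combining rules and, in parallel, the Bayesian posterior of
  pathogenicity. Evidence criteria act as exponents on a shared odds
  scale — combined odds `O^(n_PVS + n_PS/2 + n_PM/4 + n_PP/8 − n_BS/2 −
  n_BP/8)` with `O = 350` — converted against a prior `π = 0.10` via
  `P = O·π / ((O−1)·π + 1)`. Variants whose posterior reaches the
  pathogenic tier (≥ 0.99) while the rules stop at class 4 are flagged
  *discordant*.
- **Yield and enrichment** (`tikd.stats`): diagnostic yield (unique
  individuals with ≥ 1 class-4/5 variant), exact binomial per-category
  enrichment against the pooled individual×category baseline with
  Bonferroni correction, gene×category matrices, biopsy/suspicion
  cross-tabulations, rank-based group comparison of kidney-function
  values, fold-enrichment and prevalence interpolation.
- **Resampling comparison** (`tikd.resampling`): a null for the panel
  yield built by drawing cohort-sized subsets without replacement from a
  reference exome cohort and applying a panel-detectability predicate
  (gene on panel ∧ small nuclear variant); per-replicate detectable
  counts follow the hypergeometric law, which serves as the test oracle.
- **Synthetic data** (`tikd.cohort`): generators for registries with the
  assumed structure (category mix, truncated age models, log-normal
  creatinine/ACR calibrated to median CKD-EPI eGFR ≈ 55.5 mL/min/1.73 m²
  and median ACR ≈ 182 mg/g, planted variant spectra) and for the
  reference cohort from its printed summary counts, with CKD-EPI (2009,
  race term omitted) and IDMS-MDRD eGFR equations.

A packaged table transcribing the screen's published per-variant report
(36 class-4/5 variants in six genes, 34 unique carriers of a 271-member
cohort) drives the fixture-based statistics.

## Worked example

```python
from tikd import load_table1_fixture, diagnostic_yield, build_yield_report

variants = load_table1_fixture()
frac, ids = diagnostic_yield(variants, 271)
print(f"{len(ids)}/271 = {100*frac:.1f}%")      # -> 34/271 = 12.5%

report = build_yield_report(variants, 271)
k, n, p = report.per_category["hereditary disorders"]
print(k, n, f"p={p:.2g}")                        # -> 10 17 p=1.4e-05
```

The overall yield is 12.5%: 34 of 271 pre-selected individuals carry at
least one likely pathogenic or pathogenic variant (11.1% — 30/271 —
counting only small nuclear variants, the footprint comparable to exome
studies). The "hereditary disorders" category is significantly enriched
over the pooled 39/292 baseline (exact binomial p ≈ 1.4×10⁻⁵, below the
Bonferroni threshold 0.05/9 ≈ 0.0056), "gout" nominally so (p ≈ 0.023).

Narrative scripts in `examples/` cover each capability:

```bash
python examples/classify_variants.py      # dual-route ACMG classification
python examples/cohort_funnel.py          # synthetic registry + selection funnel
python examples/fixture_yield.py          # yield, enrichment, biopsy overlaps
python examples/resampling_comparison.py  # resampling null vs reference cohort
```

A thin CLI wraps the same calls (`tikd --help`: `simulate-cohort`,
`simulate-reference`, `filter`, `classify`, `yield`, `enrich`,
`resample`, `run`).

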