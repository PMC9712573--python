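# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical conventions chosen where the design was open.

## Selection funnel

Registry members carry one or two of nine closed, case-sensitive
leading-diagnosis labels. A (member, category) pair is selected iff the
member's age at inclusion does not exceed the category's cutoff
(inclusive ≤, per the clinical definition of the criteria) and the member
carries none of the six exclusion conditions (postrenal, primary
glomerular, systemic disease, post-AKI, polycystic, single kidney).
Defaults: 50 years for most categories, 40 for "IgA nephropathy",
"chronic glomerulonephritis" and "analgesic nephropathy", no cutoff for
"hereditary disorders". Each pair is evaluated independently; a member
enters the cohort if at least one pair passes. Entries are deduplicated
to unique individuals, then two QC gates run in a fixed priority order
(DNA quality, then genomic fingerprint, then declared-vs-inferred sex) so
every exclusion carries exactly one reason; the underlying registry data
pools the two identity failures, so the funnel report also exposes the
pooled count. Selection is idempotent and permutation-invariant (output
sorted by id, category).

The individual×category *combination* count over the final cohort — cohort
size plus one per extra label — is the denominator for all per-category
statistics, not the individual count. The modeled cohort has 271
individuals, 21 double-labeled, hence 292 combinations, of which 39
belong to diagnosed individuals.

## Variant classification

Two classifiers run in parallel on identical evidence profiles
(non-negative counts of PVS/PS/PM/PP and BA/BS/BP criteria):

**Categorical.** The 2015 ACMG/AMP combining rules, evaluated in the
order: BA1 short-circuits to class 1; mixed pathogenic+benign evidence is
conflicting and yields class 3; otherwise the pathogenic rule table (class
5), the likely-pathogenic table (class 4), the benign (class 1) and
likely-benign (class 2) tables; else class 3 (VUS). The test suite checks
the implementation against an independent data-driven enumeration of the
rule table, exhaustively for all profiles with per-criterion counts ≤ 4.

**Bayesian.** Combined odds of pathogenicity
`O_c = O^(n_PVS/1 + n_PS/2 + n_PM/4 + n_PP/8 − n_BS/2 − n_BP/8)` with
`O = 350`, transformed against prior `π` by
`P = O_c·π / ((O_c−1)·π + 1)`. Defaults `π = 0.10`, `O = 350` — the
constants under which the posterior reproduces the values conventionally
printed alongside each class (0.90 for the modal likely-pathogenic
combination 2 PM + 2 PP, exact value 0.89991; 0.97 for PS + 2 PM, exact
0.97493; ≥ 0.995 printing as 1.00 for class-5 combinations). Both
constants are configuration. Posterior tiers: ≥ 0.99 pathogenic, ≥ 0.90
likely pathogenic, ≤ 0.001 benign, ≤ 0.10 likely benign, else VUS. BA1 is
categorical-only and carries no odds.

A variant is *discordant* when its posterior reaches the pathogenic tier
but the combining rules stop at class 4 — possible because the rule table
requires at least one strong criterion for class 5 while the odds scale
lets moderate/supporting criteria accumulate without bound (e.g. 3 PM +
4 PP → odds 350^1.25 ≈ 1514, posterior 0.994).

Display rounding: posteriors are reported at two decimals with half-even
rounding, which reproduces every conventionally printed boundary value;
truncation is selectable but turns 0.89991 into 0.89. Full precision is
always retained internally.

## Yield and enrichment

Diagnostic yield counts unique individuals with ≥ 1 class-4/5 variant;
VUS are excluded; dual-diagnosis individuals count once. The
exome-comparison mode restricts to small nuclear variants (SNV/indel on
autosomes/gonosomes), the footprint an exome study that calls neither
CNVs nor mitochondrial variants shares with the panel.

Per-category enrichment: exact binomial test of k diagnosed combinations
out of n category combinations against the pooled baseline (39/292 on
the packaged table), two-sided by the minimum-likelihood convention. For
upper-tail enrichments at these parameters no lower-tail outcome
qualifies, so the two-sided p equals the upper tail (asserted in tests).
Multiple testing: Bonferroni at α/9 with α = 0.05 (≈ 0.0056), α
configurable.

Group comparison of kidney-function values (diagnosed vs undiagnosed) is
the two-sided Mann–Whitney rank-sum test. The groups are independent and
of unequal size (34 vs 237), so a paired signed-rank statistic is not
applicable; this is a deliberate, documented choice of the appropriate
independent-samples rank test. Degenerate all-tied input returns p = 1.

The gene×category matrix counts unique (individual, category, gene)
triples; its total exceeds the combination count exactly by the
dual-diagnosis surplus (41 = 39 + 2 on the packaged table). The packaged
per-category combination totals list the six published counts (94, 71,
48, 23, 17, 9); the remaining 30 combinations are split 12/2/16 across
"chronic glomerulonephritis"/"analgesic nephropathy"/"others" as an
approximate allocation — only statistics of those three categories depend
on it, and none of the reported significances do.

## Resampling null

The reference exome cohort is materialized from printed summary counts:
3315 members, diagnostic fraction 9.3% (308 members), exactly 108
collagen-IV carriers and 12 ADTKD small-variant carriers, allocated
deterministically and order-shuffled with the seed, so counts are exact
rather than in expectation. The full population — diagnostic and
non-diagnostic members alike — is the sampling frame: only that reading
puts the null on the yield scale. The count of *other* panel-detectable
carriers (nephronophthisis-group genes) is not a published number; the
default of 22 is a configuration choice on the order of the
nephronophthisis diagnoses such a cohort reports, and the collagen-IV
fraction p below is sensitive to it.

Each replicate draws 271 members without replacement and applies the
detectability predicate (diagnostic ∧ gene ∈ panel ∧ type ∈ detectable
set). Because a member's contribution depends only on its class, member
draws are collapsed to one multivariate hypergeometric draw over the
class counts (detectable collagen-IV / detectable other / rest) — exactly
equivalent, and the hypergeometric closed forms (mean nK/N, variance
nK/N·(1−K/N)·(N−n)/(N−1)) are the module's primary oracle, checked within
3 Monte-Carlo standard errors at 10,000 replicates.

Empirical p uses the add-one convention, (r+1)/(R+1), so it is never
exactly zero and the smallest reportable value at 10,000 replicates is
1/10001 ≈ 10⁻⁴ (displayed "< 0.0001"). The two-sided variant is twice the
smaller add-one tail, capped at 1. For the collagen-IV fraction null,
replicates with zero detectable draws have an undefined fraction and are
excluded, with their count reported. Under the defaults the observed
panel yield 30/271 yields empirical p = 1/10001 and the observed
collagen-IV share 26/30 a two-sided p ≈ 0.42–0.43.

## Synthetic registry generator

The generator models the *post-database-filter* stage (default 303
members) rather than the full >5000-member registry: the screen's data
only parameterize the selected funnel, and the full registry enters the
analysis solely through the prevalence-interpolation denominator (5217).
Features:

- **Categories**: one label per member from the combination-proportion
  mix; with probability 0.077 a second, uniformly chosen distinct label
  (the aggregate dual-label rate is the only published quantity; pairwise
  structure is not modeled).
- **Ages**: scaled Beta(a, b) on each category's admissible range
  (concentration 6, shapes solving for the target median — 43 y for
  50-cutoff categories, 35 y for 40-cutoff, 45 y on 18–69 for
  "hereditary disorders"), so generated members honor their cutoff. Only
  median and range of the real age distributions are known; the Beta
  family is a modeling convenience.
- **Creatinine**: log-normal per sex, medians 1.53 (male) / 1.23
  (female) mg/dL, σ = 0.32 — calibrated once so the selected-cohort
  median CKD-EPI eGFR is ≈ 55.5 mL/min/1.73 m²; the same parameters give
  an MDRD median ≈ 50 without further tuning. CKD-EPI 2009 omits the
  race multiplier (ethnically homogeneous modeled registry, and current
  practice); MDRD uses the IDMS-traceable 175 coefficient, consistent
  with MDRD reading below CKD-EPI at these creatinine levels.
- **ACR**: log-normal, median 182.1 mg/g, σ = 1.30 (reproducing the
  extreme mean ≪ SD right skew of albuminuria in tubulointerstitial
  disease). The true measurement distribution is unknown beyond
  median/SD; log-normal is a convenience choice.
- **QC**: DNA-quality failure 5.3%, identity mismatch 5.6% (split evenly
  between fingerprint and inferred-sex failures) — the funnel rates of
  the modeled screen. Residual exclusion-condition rates default to 0.5%
  each, small because the modeled stage is post-database-filter.
- **Planted variants**: a configurable spectrum (default 36 variants:
  COL4A5 16 with 9 founder-hotspot copies and 1 CNV, COL4A4 8 with 2
  indels, COL4A3 4, HNF1B 4 with 2 CNVs, UMOD 3, MT-TF 1 homoplasmic)
  placed on members that survive selection and QC, with exactly
  `total − dual_diagnosis_count` unique carriers; dual-diagnosis members
  carry variants in two different genes. Classes/posteriors follow the
  spectrum's typical pattern (hotspot/CNV class 5, other SNVs class 4 at
  posterior 0.90).

What the generator does **not** emulate: sequencing reads, coverage,
genotype likelihoods or call errors; family structure/relatedness;
correlation between kidney-function values and either age or diagnostic
status; the VNTR/CNV calling problem itself (variant types are labels).
Passing tests therefore demonstrate the statistical pipeline on data with
the assumed marginal structure, not robustness to real-data artifacts.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds; identical
(config, seed) reproduces byte-identical cohorts, variant tables and null
distributions. Defaults used throughout: 10,000 resampling replicates of
271 draws (seconds on one CPU), 1000-replicate calibration checks for the
generator medians, exhaustive rule-table enumeration to per-criterion
count 4 (31,250 profiles). The acceptance script derives its two stream
seeds from the single `--seed` argument.

## Known limitations

- The categorical classifier implements the written 2015 rule table
  verbatim; later ClinGen refinements (criterion strength modulation,
  e.g. PVS1_moderate) are representable only by adjusting counts.
- The collagen-IV fraction null's p depends on the unpublished gene
  composition of the reference cohort's panel-detectable carriers; the
  default reproduces a two-sided p ≈ 0.43 but is explicitly a
  configuration, not an estimate.
- HGVS strings are opaque labels; no syntactic validation or liftover.
- The funnel's inferred sex is an input field; computing it from
  coverage is out of scope.
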