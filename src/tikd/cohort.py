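"""Synthetic registry and reference-cohort generators.

Everything downstream of DNA extraction — funnel filtering, variant
classification, yield and enrichment statistics, resampling — can be
exercised on synthetic data with the statistical structure the analysis
assumes:

* :func:`generate_cohort` emulates the post-database-filter stage of a
  CKD registry: ~300 members each carrying one or two of the nine
  leading-diagnosis labels, ages honoring the per-category selection
  cutoffs, a male-skewed sex ratio, log-normal serum creatinine and
  albumin-creatinine ratio (both right-skewed in real registries), sparse
  residual exclusion conditions, and quality-control failure flags.

* :func:`generate_planted_variants` plants a configurable spectrum of
  class-4/5 variants (gene counts, founder-hotspot recurrence,
  dual-diagnosis overlaps) onto members that survive selection and QC.

* :func:`generate_reference_cohort` builds a synthetic stand-in for a
  published exome-sequenced CKD cohort from its printed summary counts
  (total size, diagnostic fraction, per-gene-bucket carrier counts),
  with deterministic count allocation and a seeded shuffle so the printed
  counts are matched exactly rather than in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .filtering import FilterCriteria, IndividualRecord, apply_qc, dedupe, select_entries
from .gfr import egfr_ckdepi, egfr_mdrd
from .stats import COL4A5_HOTSPOT, VariantRecord
from .vocab import (
    CATEGORY_LABELS,
    COL4A_GENES,
    DEFAULT_PANEL_GENES,
    EXCLUSION_FLAGS,
    MITO_GENES,
    NPHP_GENES,
)

__all__ = [
    "AgeModel",
    "LogNormalModel",
    "VariantSpectrum",
    "CohortConfig",
    "ReferenceCohortConfig",
    "generate_cohort",
    "generate_planted_variants",
    "generate_reference_cohort",
]


@dataclass(frozen=True)
class AgeModel:
    """Truncated skewed age distribution for one category.

    Ages are drawn as ``min + (max - min) * Beta(a, b)`` with the Beta
    shapes chosen (total concentration 6) so the distribution median lands
    on ``median`` — the registry publishes only median and range, so any
    unimodal right-capped shape on the stated support is equally defensible.
    """

    min: float
    max: float
    median: float

    def beta_shapes(self) -> tuple[float, float]:
        m = (self.median - self.min) / (self.max - self.min)
        total = 6.0
        a = m * (total - 2.0 / 3.0) + 1.0 / 3.0
        return a, total - a

    def validate(self, name: str) -> None:
        if not (self.min < self.median < self.max):
            raise ConfigError(f"{name}: need min < median < max, got {self}")
        if self.min < 18:
            raise ConfigError(f"{name}: adult registry, min age must be >= 18")


@dataclass(frozen=True)
class LogNormalModel:
    """Log-normal with parameters given as (median, sigma of log)."""

    median: float
    sigma: float

    def validate(self, name: str) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ConfigError(f"{name}: median and sigma must be positive, got {self}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.exp(np.log(self.median) + self.sigma * rng.standard_normal(size))


@dataclass(frozen=True)
class VariantSpectrum:
    """Planted diagnostic-variant spectrum.

    ``gene_counts`` gives class-4/5 variant counts per gene;
    ``hotspot_count`` of the COL4A5 variants are copies of the recurrent
    founder allele; ``dual_diagnosis_count`` individuals carry two variants
    in different genes; ``cnv_counts``/``indel_counts`` carve out CNV and
    indel rows from the per-gene totals (the remainder are SNVs;
    mitochondrial genes always yield mito_SNV).
    """

    gene_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "COL4A5": 16, "COL4A4": 8, "COL4A3": 4, "HNF1B": 4, "UMOD": 3, "MT-TF": 1,
        }
    )
    hotspot_count: int = 9
    dual_diagnosis_count: int = 2
    cnv_counts: Mapping[str, int] = field(
        default_factory=lambda: {"COL4A5": 1, "HNF1B": 2}
    )
    indel_counts: Mapping[str, int] = field(default_factory=lambda: {"COL4A4": 2})

    @property
    def total(self) -> int:
        return sum(self.gene_counts.values())

    def validate(self) -> None:
        allowed = set(DEFAULT_PANEL_GENES) | set(MITO_GENES)
        for gene, count in self.gene_counts.items():
            if gene not in allowed:
                raise ConfigError(f"variant_spectrum: gene {gene!r} not on the panel")
            if count < 0:
                raise ConfigError(f"variant_spectrum: negative count for {gene}")
        if self.hotspot_count > self.gene_counts.get("COL4A5", 0):
            raise ConfigError("variant_spectrum: hotspot_count exceeds COL4A5 count")
        if self.dual_diagnosis_count >= self.total and self.total > 0:
            raise ConfigError("variant_spectrum: dual_diagnosis_count too large")
        for name, mapping in (("cnv_counts", self.cnv_counts), ("indel_counts", self.indel_counts)):
            for gene, count in mapping.items():
                if count > self.gene_counts.get(gene, 0):
                    raise ConfigError(f"variant_spectrum: {name}[{gene}] exceeds gene count")


def _default_prevalence() -> dict[str, float]:
    # Individual x category combination proportions of the modeled cohort.
    return {
        "nephrosclerosis": 94 / 292,
        "IgA nephropathy": 71 / 292,
        "unknown": 48 / 292,
        "interstitial nephritis": 23 / 292,
        "hereditary disorders": 17 / 292,
        "gout": 9 / 292,
        "chronic glomerulonephritis": 12 / 292,
        "analgesic nephropathy": 2 / 292,
        "others": 16 / 292,
    }


def _default_age_models() -> dict[str, AgeModel]:
    models: dict[str, AgeModel] = {}
    for label in CATEGORY_LABELS:
        if label == "hereditary disorders":
            models[label] = AgeModel(18, 69, 45)
        elif label in ("IgA nephropathy", "chronic glomerulonephritis", "analgesic nephropathy"):
            models[label] = AgeModel(18, 40, 35)
        else:
            models[label] = AgeModel(18, 50, 43)
    return models


@dataclass
class CohortConfig:
    """Configuration of the synthetic registry generator.

    Defaults emulate the structure of the modeled screening cohort at the
    post-database-filter stage: ~303 members, category mix matching the
    published combination breakdown, a 7.7% dual-label rate, sex ratio
    1.40, creatinine calibrated to a median CKD-EPI eGFR of ~55.5
    mL/min/1.73 m², ACR median ~182 mg/g with a long right tail, a ~5.3%
    DNA-quality failure rate and ~5.6% identity-mismatch rate, and a 46%
    prior-biopsy rate.
    """

    n_total: int = 303
    category_prevalence: Mapping[str, float] = field(default_factory=_default_prevalence)
    dual_category_rate: float = 0.077
    sex_ratio: float = 1.40
    age_model: Mapping[str, AgeModel] = field(default_factory=_default_age_models)
    creatinine_model: Mapping[str, LogNormalModel] = field(
        default_factory=lambda: {
            "male": LogNormalModel(1.53, 0.32),
            "female": LogNormalModel(1.23, 0.32),
        }
    )
    acr_model: LogNormalModel = LogNormalModel(182.1, 1.30)
    exclusion_flag_rates: Mapping[str, float] = field(
        default_factory=lambda: {flag: 0.005 for flag in EXCLUSION_FLAGS}
    )
    qc_fail_rates: Mapping[str, float] = field(
        default_factory=lambda: {"dna_quality": 0.053, "identity_mismatch": 0.056}
    )
    variant_spectrum: VariantSpectrum = field(default_factory=VariantSpectrum)
    biopsy_rate: float = 0.461

    def validate(self) -> None:
        if self.n_total < 0:
            raise ConfigError(f"n_total must be non-negative, got {self.n_total}")
        if set(self.category_prevalence) != set(CATEGORY_LABELS):
            raise ConfigError(
                "category_prevalence keys must be exactly the nine category labels"
            )
        for label, p in self.category_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"category_prevalence[{label!r}] must be in [0,1], got {p}")
        total = sum(self.category_prevalence.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigError(f"category_prevalence must sum to 1, sums to {total:.4f}")
        for name, p in (
            ("dual_category_rate", self.dual_category_rate),
            ("biopsy_rate", self.biopsy_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        if self.sex_ratio <= 0:
            raise ConfigError(f"sex_ratio must be positive, got {self.sex_ratio}")
        if set(self.age_model) != set(CATEGORY_LABELS):
            raise ConfigError("age_model must provide a model for each category")
        for label, model in self.age_model.items():
            model.validate(f"age_model[{label!r}]")
        for sex in ("male", "female"):
            if sex not in self.creatinine_model:
                raise ConfigError(f"creatinine_model missing entry for {sex!r}")
            self.creatinine_model[sex].validate(f"creatinine_model[{sex!r}]")
        self.acr_model.validate("acr_model")
        for mapping_name, mapping in (
            ("exclusion_flag_rates", self.exclusion_flag_rates),
            ("qc_fail_rates", self.qc_fail_rates),
        ):
            for key, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{mapping_name}[{key!r}] must be in [0,1], got {p}")
        for flag in self.exclusion_flag_rates:
            if flag not in EXCLUSION_FLAGS:
                raise ConfigError(f"exclusion_flag_rates: unknown flag {flag!r}")
        for key in self.qc_fail_rates:
            if key not in ("dna_quality", "identity_mismatch"):
                raise ConfigError(f"qc_fail_rates: unknown key {key!r}")
        self.variant_spectrum.validate()


def generate_cohort(config: CohortConfig, seed: int) -> list[IndividualRecord]:
    """Generate ``config.n_total`` synthetic registry members.

    Deterministic: identical (config, seed) yields identical records. Every
    member carries one category label, or two distinct labels with
    probability ``dual_category_rate``; the age is drawn from the model of
    the member's most age-restrictive label so multi-label members remain
    selectable under both labels.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_total
    labels = list(CATEGORY_LABELS)
    p = np.array([config.category_prevalence[l] for l in labels])
    p = p / p.sum()

    primary = rng.choice(len(labels), size=n, p=p)
    dual = rng.random(n) < config.dual_category_rate
    offsets = rng.integers(1, len(labels), size=n)
    secondary = (primary + offsets) % len(labels)
    male = rng.random(n) < config.sex_ratio / (1.0 + config.sex_ratio)

    # age from the most restrictive (smallest max) label of each member
    ages = np.empty(n)
    eff_label = np.empty(n, dtype=int)
    maxima = np.array([config.age_model[l].max for l in labels])
    for i in range(n):
        cats = [primary[i], secondary[i]] if dual[i] else [primary[i]]
        eff_label[i] = min(cats, key=lambda c: maxima[c])
    for j, label in enumerate(labels):
        idx = eff_label == j
        if not idx.any():
            continue
        model = config.age_model[label]
        a, b = model.beta_shapes()
        ages[idx] = model.min + (model.max - model.min) * rng.beta(a, b, idx.sum())

    creat = np.empty(n)
    creat[male] = config.creatinine_model["male"].sample(rng, int(male.sum()))
    creat[~male] = config.creatinine_model["female"].sample(rng, int((~male).sum()))
    acr = config.acr_model.sample(rng, n)

    flag_draws = {
        flag: rng.random(n) < rate for flag, rate in config.exclusion_flag_rates.items()
    }
    dna_ok = rng.random(n) >= config.qc_fail_rates.get("dna_quality", 0.0)
    identity_bad = rng.random(n) < config.qc_fail_rates.get("identity_mismatch", 0.0)
    identity_kind = rng.random(n) < 0.5  # fingerprint vs inferred-sex mismatch
    biopsy = rng.random(n) < config.biopsy_rate

    records: list[IndividualRecord] = []
    for i in range(n):
        cats = (labels[primary[i]], labels[secondary[i]]) if dual[i] else (labels[primary[i]],)
        sex = "male" if male[i] else "female"
        fingerprint = not (identity_bad[i] and identity_kind[i])
        if identity_bad[i] and not identity_kind[i]:
            inferred = "female" if sex == "male" else "male"
        else:
            inferred = sex
        age = float(ages[i])
        records.append(
            IndividualRecord(
                id=f"SYN_{i + 1:06d}",
                age=round(age, 1),
                sex_declared=sex,
                sex_inferred=inferred,
                categories=cats,
                exclusion_flags=tuple(f for f in EXCLUSION_FLAGS if flag_draws[f][i]),
                creatinine=round(float(creat[i]), 2),
                egfr_ckdepi=round(egfr_ckdepi(round(float(creat[i]), 2), round(age, 1), sex), 1),
                egfr_mdrd=round(egfr_mdrd(round(float(creat[i]), 2), round(age, 1), sex), 1),
                acr=round(float(acr[i]), 1),
                biopsy=bool(biopsy[i]),
                hereditary_suspected="hereditary disorders" in cats,
                dna_quality_ok=bool(dna_ok[i]),
                fingerprint_match=fingerprint,
            )
        )
    return records


def _selected_ids(cohort: list[IndividualRecord], criteria: FilterCriteria) -> list[str]:
    result = apply_qc(dedupe(select_entries(cohort, criteria)), cohort)
    return sorted(result.final_ids)


def generate_planted_variants(
    cohort: list[IndividualRecord],
    config: CohortConfig,
    seed: int,
    criteria: FilterCriteria | None = None,
) -> list[VariantRecord]:
    """Plant the configured class-4/5 variant spectrum onto the cohort.

    Carriers are drawn from members that survive selection and QC, so the
    planted spectrum is visible to downstream yield statistics. Exactly
    ``spectrum.total - dual_diagnosis_count`` unique carriers result;
    dual-diagnosis members receive their second variant in a different gene.
    """
    config.validate()
    spectrum = config.variant_spectrum
    criteria = criteria or FilterCriteria()
    rng = np.random.default_rng(seed)
    eligible = _selected_ids(cohort, criteria)
    n_carriers = spectrum.total - spectrum.dual_diagnosis_count
    if n_carriers > len(eligible):
        raise ConfigError(
            f"variant_spectrum: {n_carriers} carriers requested but only"
            f" {len(eligible)} selectable members available"
        )
    by_id = {r.id: r for r in cohort}
    hotspot_gene, hotspot_hgvs = COL4A5_HOTSPOT

    # Build one slot per planted variant: (gene, type, hotspot flag).
    slots: list[tuple[str, str, bool]] = []
    for gene in sorted(spectrum.gene_counts):
        count = spectrum.gene_counts[gene]
        n_cnv = spectrum.cnv_counts.get(gene, 0)
        n_indel = spectrum.indel_counts.get(gene, 0)
        n_hot = spectrum.hotspot_count if gene == hotspot_gene else 0
        for k in range(count):
            if gene in MITO_GENES:
                vtype = "mito_SNV"
            elif k < n_cnv:
                vtype = "CNV"
            elif k < n_cnv + n_indel:
                vtype = "indel"
            else:
                vtype = "SNV"
            hot = gene == hotspot_gene and vtype == "SNV" and (count - k) <= n_hot
            slots.append((gene, vtype, hot))
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    carrier_ids = list(rng.choice(eligible, size=n_carriers, replace=False))
    assigned: dict[str, set[str]] = {}
    variants: list[VariantRecord] = []
    queue = list(carrier_ids)
    for gene, vtype, hot in slots:
        holder = None
        if queue:
            holder = queue.pop()
        else:  # dual-diagnosis slot: reuse a carrier without this gene
            candidates = [c for c in carrier_ids if gene not in assigned.get(c, set())]
            holder = candidates[int(rng.integers(len(candidates)))]
        assigned.setdefault(holder, set()).add(gene)
        record = by_id[holder]
        selected_cats = tuple(
            c for c in record.categories if criteria.passes(record, c)
        )
        if hot:
            hgvs_c, hgvs_p = hotspot_hgvs, "p.(Gly624Asp)"
            acmg_class, post = 5, 1.0
        elif vtype == "CNV":
            hgvs_c = f"g.(?_{int(rng.integers(10**6, 10**8))})_({int(rng.integers(10**6, 10**8))}_?)del"
            hgvs_p, acmg_class, post = "p.0?", 5, None
        elif vtype == "indel":
            pos = int(rng.integers(100, 5000))
            hgvs_c, hgvs_p = f"c.{pos}_{pos + 1}del", "p.(fs)"
            acmg_class, post = 5, 1.0
        elif vtype == "mito_SNV":
            hgvs_c, hgvs_p = "g.616T>C", "p.?"
            acmg_class, post = 5, 0.99
        else:
            pos = int(rng.integers(100, 5000))
            hgvs_c, hgvs_p = f"c.{pos}G>A", "p.(Gly%dAsp)" % (pos // 3)
            acmg_class, post = 4, 0.90
        if vtype == "mito_SNV":
            chrom, zygo = "mitochondrial", "homoplasmic"
        elif gene == "COL4A5":
            chrom = "gonosome"
            zygo = "hemizygous" if record.sex_declared == "male" else "heterozygous"
        else:
            chrom, zygo = "autosome", "heterozygous"
        variants.append(
            VariantRecord(
                individual_id=holder,
                gene=gene,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                variant_type=vtype,
                chromosome_class=chrom,
                zygosity=zygo,
                acmg_class=acmg_class,
                posterior=post,
                categories=selected_cats or record.categories,
                biopsy=record.biopsy,
                hereditary_suspected=record.hereditary_suspected,
            )
        )
    variants.sort(key=lambda v: (v.individual_id, v.gene, v.hgvs_c))
    return variants


# --- reference exome cohort -------------------------------------------------

#: Gene cycles used to label bucket members with concrete symbols.
_BUCKET_GENES: dict[str, tuple[str, ...]] = {
    "COL4A": COL4A_GENES,
    "ADTKD": ("UMOD", "HNF1B", "REN", "SEC61A1"),
    "other_panel": NPHP_GENES,
    "non_panel": ("PKD1", "PKD2", "PKHD1", "NPHS1", "NPHS2", "TTC21B_NP"),
}


@dataclass
class ReferenceCohortConfig:
    """Printed summary counts of the reference exome cohort.

    ``gene_distribution`` maps carrier buckets to exact counts: the
    collagen-IV bucket and the ADTKD small-variant bucket are published
    counts; ``other_panel`` — diagnostic carriers in the remaining panel
    genes (nephronophthisis group) — is a configuration parameter, not a
    published fact. All remaining diagnostic members fall in non-panel
    genes. ``cnv_mito_fraction`` marks that share of non-panel diagnostic
    members as CNV findings (0 for an exome study that called only small
    variants).
    """

    n_total: int = 3315
    diagnostic_fraction: float = 0.093
    gene_distribution: Mapping[str, int] = field(
        default_factory=lambda: {"COL4A": 108, "ADTKD": 12, "other_panel": 22}
    )
    cnv_mito_fraction: float = 0.0

    @property
    def n_diagnostic(self) -> int:
        return int(round(self.n_total * self.diagnostic_fraction))

    def validate(self) -> None:
        if self.n_total < 0:
            raise ConfigError(f"n_total must be non-negative, got {self.n_total}")
        if not 0.0 <= self.diagnostic_fraction <= 1.0:
            raise ConfigError(
                f"diagnostic_fraction must be in [0,1], got {self.diagnostic_fraction}"
            )
        if not 0.0 <= self.cnv_mito_fraction <= 1.0:
            raise ConfigError(
                f"cnv_mito_fraction must be in [0,1], got {self.cnv_mito_fraction}"
            )
        for bucket, count in self.gene_distribution.items():
            if bucket not in _BUCKET_GENES or bucket == "non_panel":
                raise ConfigError(f"gene_distribution: unknown bucket {bucket!r}")
            if count < 0:
                raise ConfigError(f"gene_distribution[{bucket!r}] must be non-negative")
        if sum(self.gene_distribution.values()) > self.n_diagnostic:
            raise ConfigError(
                "gene_distribution: bucket counts exceed the diagnostic member count"
                f" ({sum(self.gene_distribution.values())} > {self.n_diagnostic})"
            )


def generate_reference_cohort(
    config: ReferenceCohortConfig, seed: int
) -> pd.DataFrame:
    """Materialize the reference cohort as one row per member.

    Columns: ``member_id``, ``diagnostic``, ``bucket``, ``gene``,
    ``variant_type``. Counts are allocated deterministically (each bucket
    gets exactly its configured count; genes cycle within a bucket) and
    row order is then shuffled with the seed, so printed counts are exact
    while draws remain random.
    """
    config.validate()
    rows: list[tuple[bool, str, str, str]] = []
    for bucket in ("COL4A", "ADTKD", "other_panel"):
        count = config.gene_distribution.get(bucket, 0)
        genes = _BUCKET_GENES[bucket]
        for k in range(count):
            rows.append((True, bucket, genes[k % len(genes)], "SNV"))
    n_non_panel = config.n_diagnostic - len(rows)
    n_cnv = int(round(config.n_diagnostic * config.cnv_mito_fraction))
    genes = _BUCKET_GENES["non_panel"]
    for k in range(n_non_panel):
        vtype = "CNV" if k < n_cnv else "SNV"
        rows.append((True, "non_panel", genes[k % len(genes)], vtype))
    while len(rows) < config.n_total:
        rows.append((False, "none", "none", "none"))
    frame = pd.DataFrame(rows, columns=["diagnostic", "bucket", "gene", "variant_type"])
    rng = np.random.default_rng(seed)
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    frame.insert(0, "member_id", [f"REF_{i + 1:06d}" for i in range(len(frame))])
    return frame
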