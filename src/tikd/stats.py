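"""Diagnostic yield, category enrichment and descriptive statistics.

The central quantity is the *diagnostic yield*: the fraction of sequenced
individuals carrying at least one class-4/5 (likely pathogenic or
pathogenic) variant, with dual-diagnosis individuals counted once. A
comparison mode restricts the yield to small nuclear variants (SNV/indel
on autosomes and gonosomes), the detectability footprint shared with
exome-based reference studies that call neither CNVs nor mitochondrial
variants.

Category enrichment is tested per leading-diagnosis category with an exact
binomial test against the pooled baseline rate over all individual x
category combinations, Bonferroni-corrected over the nine categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError
from .vocab import CATEGORY_LABELS, CHROMOSOME_CLASSES, COL4A_GENES, VARIANT_TYPES

__all__ = [
    "VariantRecord",
    "YieldReport",
    "diagnostic_yield",
    "binomial_enrichment",
    "bonferroni_threshold",
    "gene_category_matrix",
    "biopsy_crosstab",
    "group_compare",
    "fold_enrichment",
    "interpolate_prevalence",
    "structure_report",
    "build_yield_report",
    "STUDY_CATEGORY_COMBINATIONS",
    "COL4A5_HOTSPOT",
]

#: Individual x category combination totals of the screened cohort
#: (271 individuals, 21 of them double-labeled, 292 combinations). The six
#: largest counts are the published cohort breakdown; the split of the
#: remaining 30 combinations across the three smallest categories is an
#: approximate allocation and only affects statistics of those categories.
STUDY_CATEGORY_COMBINATIONS: dict[str, int] = {
    "nephrosclerosis": 94,
    "IgA nephropathy": 71,
    "unknown": 48,
    "interstitial nephritis": 23,
    "hereditary disorders": 17,
    "gout": 9,
    "chronic glomerulonephritis": 12,
    "analgesic nephropathy": 2,
    "others": 16,
}

#: The recurrent European founder allele in COL4A5 (glycine substitution in
#: the collagenous domain), the single most frequent diagnostic variant.
COL4A5_HOTSPOT: tuple[str, str] = ("COL4A5", "c.1871G>A")


@dataclass
class VariantRecord:
    """One diagnostic or candidate variant carried by one individual."""

    individual_id: str
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    variant_type: str = "SNV"
    chromosome_class: str = "autosome"
    zygosity: str = "unknown"
    acmg_class: int = 3
    posterior: float | None = None
    categories: tuple[str, ...] = ()
    biopsy: bool = False
    hereditary_suspected: bool = False

    def __post_init__(self) -> None:
        self.categories = tuple(self.categories)
        if self.variant_type not in VARIANT_TYPES:
            raise DataError(
                f"variant {self.gene} {self.hgvs_c}: unknown variant_type {self.variant_type!r}"
            )
        if self.chromosome_class not in CHROMOSOME_CLASSES:
            raise DataError(
                f"variant {self.gene} {self.hgvs_c}: unknown chromosome_class"
                f" {self.chromosome_class!r}"
            )
        if (self.variant_type == "mito_SNV") != (self.chromosome_class == "mitochondrial"):
            raise DataError(
                f"variant {self.gene} {self.hgvs_c}: variant_type mito_SNV must pair"
                " with chromosome_class mitochondrial"
            )
        if not 1 <= int(self.acmg_class) <= 5:
            raise DataError(f"variant {self.gene} {self.hgvs_c}: acmg_class out of range")

    @property
    def diagnostic(self) -> bool:
        """Class 4/5 counts toward yield; class 3 (VUS) does not."""
        return self.acmg_class >= 4


def _diagnostic_subset(
    variants: Iterable[VariantRecord], include_types: set[str] | None
) -> list[VariantRecord]:
    out = []
    for v in variants:
        if not v.diagnostic:
            continue
        if include_types is not None and v.variant_type not in include_types:
            continue
        out.append(v)
    return out


def diagnostic_yield(
    variants: Iterable[VariantRecord],
    n_cohort: int,
    include_types: set[str] | None = None,
    known_ids: set[str] | None = None,
) -> tuple[float, set[str]]:
    """Diagnostic yield fraction and the set of diagnosed individuals.

    Counts unique individuals with >= 1 class-4/5 variant whose type is in
    ``include_types`` (all types when ``None``); individuals with multiple
    diagnostic variants count once. Duplicate rows for the same
    (individual, variant) do not inflate the count.
    """
    if n_cohort <= 0:
        raise ConfigError(f"n_cohort must be positive, got {n_cohort}")
    ids: set[str] = set()
    for v in _diagnostic_subset(variants, include_types):
        if known_ids is not None and v.individual_id not in known_ids:
            raise DataError(f"variant references unknown individual {v.individual_id!r}")
        ids.add(v.individual_id)
    return len(ids) / n_cohort, ids


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p value for k successes in n trials at p0.

    Uses the minimum-likelihood two-sided convention (sum of outcome
    probabilities no larger than that of the observed count); for upper-tail
    enrichments where no lower-tail outcome qualifies this coincides with
    the one-sided upper tail.
    """
    if not 0 < p0 < 1:
        raise ConfigError(f"p0 must lie strictly in (0, 1), got {p0}")
    if not 0 <= k <= n:
        raise ConfigError(f"need 0 <= k <= n, got k={k}, n={n}")
    return sps.binomtest(k, n, p0, alternative="two-sided").pvalue


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise ConfigError(f"m must be >= 1, got {m}")
    return alpha / m


def gene_category_matrix(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Count unique (individual, category, diagnostic gene) combinations.

    Splitting the per-category combinations additionally by gene yields a
    gene x category matrix whose total exceeds the individual x category
    combination count exactly by the surplus from dual-diagnosis
    individuals (two genes, same categories).
    """
    triples: set[tuple[str, str, str]] = set()
    for v in variants:
        if not v.diagnostic:
            continue
        for c in v.categories:
            triples.add((v.individual_id, c, v.gene))
    if not triples:
        return pd.DataFrame(0, index=[], columns=list(CATEGORY_LABELS))
    genes = sorted({g for _, _, g in triples})
    table = pd.DataFrame(0, index=genes, columns=list(CATEGORY_LABELS))
    for _, c, g in triples:
        table.loc[g, c] += 1
    return table


def _per_individual_flags(
    variants: Iterable[VariantRecord],
) -> pd.DataFrame:
    rows: dict[str, dict] = {}
    for v in variants:
        if not v.diagnostic:
            continue
        entry = rows.setdefault(
            v.individual_id,
            {"biopsy": False, "suspected": False, "col4a": False, "genes": set()},
        )
        entry["biopsy"] = entry["biopsy"] or v.biopsy
        entry["suspected"] = entry["suspected"] or v.hereditary_suspected
        entry["col4a"] = entry["col4a"] or v.gene in COL4A_GENES
        entry["genes"].add(v.gene)
    return pd.DataFrame.from_dict(rows, orient="index")


def biopsy_crosstab(
    variants: Iterable[VariantRecord],
    cohort: Sequence | None = None,
) -> dict:
    """Overlap counts of {genetic diagnosis, prior biopsy, hereditary suspicion}.

    Always reports the diagnosed-individual cells and the derived fractions
    (biopsied among diagnosed, biopsied among collagen-IV diagnosed,
    biopsied diagnosed without prior hereditary suspicion). When the full
    cohort is supplied, the remaining four cells over undiagnosed
    individuals complete the eight-cell overlap.
    """
    flags = _per_individual_flags(variants)
    cells: dict[str, int] = {}
    if len(flags) == 0:
        flags = pd.DataFrame(columns=["biopsy", "suspected", "col4a", "genes"])
    for biopsy in (True, False):
        for suspected in (True, False):
            key = (
                f"diagnosis&{'biopsy' if biopsy else 'no_biopsy'}"
                f"&{'suspicion' if suspected else 'no_suspicion'}"
            )
            cells[key] = int(
                ((flags.get("biopsy", pd.Series(dtype=bool)) == biopsy)
                 & (flags.get("suspected", pd.Series(dtype=bool)) == suspected)).sum()
            )
    if cohort is not None:
        diagnosed = set(flags.index)
        for record in cohort:
            if record.id in diagnosed:
                continue
            key = (
                f"no_diagnosis&{'biopsy' if record.biopsy else 'no_biopsy'}"
                f"&{'suspicion' if record.hereditary_suspected else 'no_suspicion'}"
            )
            cells[key] = cells.get(key, 0) + 1
    n_diag = len(flags)
    n_biopsied = int(flags["biopsy"].sum()) if n_diag else 0
    col4a = flags[flags["col4a"]] if n_diag else flags
    n_col4a = len(col4a)
    n_col4a_biopsied = int(col4a["biopsy"].sum()) if n_col4a else 0
    biopsied_no_susp = (
        int((flags["biopsy"] & ~flags["suspected"]).sum()) if n_diag else 0
    )
    return {
        "cells": cells,
        "diagnosed": n_diag,
        "biopsied_diagnosed": n_biopsied,
        "biopsied_diagnosed_pct": 100.0 * n_biopsied / n_diag if n_diag else float("nan"),
        "col4a_diagnosed": n_col4a,
        "biopsied_col4a_diagnosed": n_col4a_biopsied,
        "biopsied_col4a_diagnosed_pct": (
            100.0 * n_col4a_biopsied / n_col4a if n_col4a else float("nan")
        ),
        "biopsied_diagnosed_without_suspicion": biopsied_no_susp,
        "biopsied_diagnosed_with_suspicion": n_biopsied - biopsied_no_susp,
    }


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided rank-based comparison of two independent groups.

    Implemented as the Mann-Whitney rank-sum test: the groups compared here
    (diagnosed vs undiagnosed individuals) are independent and of unequal
    size, so a paired signed-rank statistic is not applicable. Degenerate
    inputs where every value is tied return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("group_compare requires two non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fold_enrichment(k1: int, n1: int, k2: int, n2: int) -> float:
    """Rate ratio (k1/n1)/(k2/n2); NaN when the comparison rate is zero."""
    if n1 <= 0 or n2 <= 0:
        raise ConfigError("fold_enrichment requires positive denominators")
    rate2 = k2 / n2
    if rate2 == 0:
        return float("nan")
    return (k1 / n1) / rate2


def interpolate_prevalence(k: int, n_full_cohort: int) -> float:
    """Percentage prevalence 100*k/n when a yield is projected onto the
    full registry under the assumption of complete enrichment by the
    selection criteria."""
    if n_full_cohort <= 0:
        raise ConfigError("n_full_cohort must be positive")
    return 100.0 * k / n_full_cohort


def structure_report(variants: Sequence[VariantRecord]) -> dict:
    """Descriptive structure of a diagnostic-variant table.

    Reports per-gene variant counts, the founder-hotspot share, the
    collagen-IV share among non-CNV variants, and the collagen-IV share of
    small-nuclear-variant diagnoses.
    """
    diag = [v for v in variants if v.diagnostic]
    hotspot_gene, hotspot_hgvs = COL4A5_HOTSPOT
    gene_counts: dict[str, int] = {}
    for v in diag:
        gene_counts[v.gene] = gene_counts.get(v.gene, 0) + 1
    n_hotspot = sum(1 for v in diag if v.gene == hotspot_gene and v.hgvs_c == hotspot_hgvs)
    n_col4a5 = gene_counts.get(hotspot_gene, 0)
    n_col4a_rows = sum(gene_counts.get(g, 0) for g in COL4A_GENES)
    non_cnv = [v for v in diag if v.variant_type != "CNV"]
    n_col4a_non_cnv = sum(1 for v in non_cnv if v.gene in COL4A_GENES)
    small = {"SNV", "indel"}
    small_ids = {v.individual_id for v in diag if v.variant_type in small}
    col4a_small_ids = {
        v.individual_id for v in diag if v.variant_type in small and v.gene in COL4A_GENES
    }
    return {
        "n_variants": len(diag),
        "gene_counts": gene_counts,
        "hotspot_count": n_hotspot,
        "hotspot_share_of_col4a5_pct": (
            100.0 * n_hotspot / n_col4a5 if n_col4a5 else float("nan")
        ),
        "hotspot_share_of_col4a_pct": (
            100.0 * n_hotspot / n_col4a_rows if n_col4a_rows else float("nan")
        ),
        "col4a_share_of_non_cnv_pct": (
            100.0 * n_col4a_non_cnv / len(non_cnv) if non_cnv else float("nan")
        ),
        "n_non_cnv": len(non_cnv),
        "col4a_non_cnv": n_col4a_non_cnv,
        "small_variant_individuals": len(small_ids),
        "col4a_small_variant_individuals": len(col4a_small_ids),
        "col4a_share_of_small_variant_individuals_pct": (
            100.0 * len(col4a_small_ids) / len(small_ids) if small_ids else float("nan")
        ),
    }


@dataclass
class YieldReport:
    """Yield and enrichment summary over one cohort and variant table."""

    n_cohort: int
    diagnostic_ids: set[str]
    yield_fraction: float
    per_category: dict[str, tuple[int, int, float]]
    baseline_rate: float
    bonferroni_alpha: float
    gene_category_counts: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_cohort": self.n_cohort,
            "n_diagnosed": len(self.diagnostic_ids),
            "yield_pct": round(100.0 * self.yield_fraction, 1),
            "baseline_rate": self.baseline_rate,
            "bonferroni_alpha": self.bonferroni_alpha,
            "per_category": {
                label: {"k": k, "n": n, "p": p}
                for label, (k, n, p) in self.per_category.items()
            },
            "significant_after_correction": [
                label
                for label, (_, _, p) in self.per_category.items()
                if p < self.bonferroni_alpha
            ],
            "gene_category_total": int(self.gene_category_counts.values.sum()),
        }


def build_yield_report(
    variants: Sequence[VariantRecord],
    n_cohort: int,
    category_totals: Mapping[str, int] | None = None,
    alpha: float = 0.05,
) -> YieldReport:
    """Assemble yield, per-category enrichment and the gene x category matrix.

    ``category_totals`` gives the number of individual x category
    combinations per category in the analyzed cohort (the enrichment
    denominators); the packaged study totals are used when omitted. The
    baseline rate is pooled over all combinations, and each category is
    tested with the exact binomial test against it.
    """
    totals = dict(category_totals or STUDY_CATEGORY_COMBINATIONS)
    unknown = set(totals) - set(CATEGORY_LABELS)
    if unknown:
        raise ConfigError(f"category_totals: unknown labels {sorted(unknown)}")
    yield_fraction, ids = diagnostic_yield(variants, n_cohort)
    pairs: set[tuple[str, str]] = set()
    for v in variants:
        if v.diagnostic:
            for c in v.categories:
                pairs.add((v.individual_id, c))
    k_by_cat = {label: 0 for label in totals}
    for _, c in pairs:
        if c in k_by_cat:
            k_by_cat[c] += 1
    n_comb = sum(totals.values())
    k_total = len(pairs)
    baseline = k_total / n_comb
    per_category = {
        label: (k_by_cat[label], totals[label], binomial_enrichment(k_by_cat[label], totals[label], baseline))
        for label in totals
        if totals[label] > 0
    }
    return YieldReport(
        n_cohort=n_cohort,
        diagnostic_ids=ids,
        yield_fraction=yield_fraction,
        per_category=per_category,
        baseline_rate=baseline,
        bonferroni_alpha=bonferroni_threshold(alpha, len(totals)),
        gene_category_counts=gene_category_matrix(variants),
    )
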