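"""The cohort selection funnel.

Registry members are selected into the sequencing cohort by a
category-and-age query: each of the nine leading-diagnosis categories has
an optional maximum age at inclusion (50 years for most, 40 for the
glomerulonephritis-adjacent categories where an older onset points away
from an inherited tubulointerstitial cause, none for "hereditary
disorders"), and members carrying any of six exclusion conditions are
dropped outright. The resulting (individual, category) *entries* are
deduplicated to unique individuals — a member may enter under two
categories — and then pass DNA-quality and identity (genomic fingerprint /
inferred sex) quality gates.

The entry/individual distinction matters downstream: per-category
enrichment tests use individual x category combinations, not individuals,
as their denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigError, DataError
from .vocab import CATEGORY_LABELS, EXCLUSION_FLAGS

__all__ = [
    "IndividualRecord",
    "FilterCriteria",
    "SelectionResult",
    "select_entries",
    "dedupe",
    "apply_qc",
    "expand_combinations",
    "funnel_report",
]


@dataclass
class IndividualRecord:
    """One registry member with the fields the funnel and statistics need."""

    id: str
    age: float
    sex_declared: str
    categories: tuple[str, ...]
    sex_inferred: str = "unknown"
    exclusion_flags: tuple[str, ...] = ()
    creatinine: float | None = None
    egfr_ckdepi: float | None = None
    egfr_mdrd: float | None = None
    acr: float | None = None
    biopsy: bool = False
    hereditary_suspected: bool = False
    dna_quality_ok: bool = True
    fingerprint_match: bool = True

    def __post_init__(self) -> None:
        self.categories = tuple(self.categories)
        self.exclusion_flags = tuple(self.exclusion_flags)
        for c in self.categories:
            if c not in CATEGORY_LABELS:
                raise DataError(f"record {self.id}: unknown category label {c!r}")
        for f in self.exclusion_flags:
            if f not in EXCLUSION_FLAGS:
                raise DataError(f"record {self.id}: unknown exclusion flag {f!r}")


def _default_age_cutoffs() -> dict[str, Optional[float]]:
    cutoffs: dict[str, Optional[float]] = {label: 50.0 for label in CATEGORY_LABELS}
    for label in ("IgA nephropathy", "chronic glomerulonephritis", "analgesic nephropathy"):
        cutoffs[label] = 40.0
    cutoffs["hereditary disorders"] = None
    return cutoffs


@dataclass
class FilterCriteria:
    """Per-category inclusive age cutoffs plus the exclusion conditions."""

    age_cutoff_by_category: Mapping[str, Optional[float]] = field(
        default_factory=_default_age_cutoffs
    )
    excluded_conditions: tuple[str, ...] = EXCLUSION_FLAGS

    def __post_init__(self) -> None:
        if set(self.age_cutoff_by_category) != set(CATEGORY_LABELS):
            missing = set(CATEGORY_LABELS) - set(self.age_cutoff_by_category)
            extra = set(self.age_cutoff_by_category) - set(CATEGORY_LABELS)
            raise ConfigError(
                f"age_cutoff_by_category keys must be exactly the nine category labels"
                f" (missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        for f in self.excluded_conditions:
            if f not in EXCLUSION_FLAGS:
                raise ConfigError(f"excluded_conditions: unknown flag {f!r}")

    def passes(self, record: IndividualRecord, category: str) -> bool:
        """Whether one (individual, category) pair satisfies the criteria."""
        if category not in record.categories:
            return False
        if set(record.exclusion_flags) & set(self.excluded_conditions):
            return False
        cutoff = self.age_cutoff_by_category[category]
        return cutoff is None or record.age <= cutoff


@dataclass
class SelectionResult:
    """The funnel state: entries, unique individuals, QC removals."""

    entries: list[tuple[str, str]] = field(default_factory=list)
    unique_ids: set[str] = field(default_factory=set)
    qc_excluded: dict[str, str] = field(default_factory=dict)
    final_ids: set[str] = field(default_factory=set)


def select_entries(
    cohort: Iterable[IndividualRecord], criteria: FilterCriteria | None = None
) -> list[tuple[str, str]]:
    """Emit every (id, category) pair passing the category/age/exclusion query.

    Each pair is evaluated independently; an individual with two labels may
    contribute zero, one or two entries. Output is sorted by id then
    category so the result is stable under input permutation.
    """
    criteria = criteria or FilterCriteria()
    pairs: set[tuple[str, str]] = set()
    for record in cohort:
        if not record.categories:
            raise DataError(f"record {record.id}: no category label")
        for category in record.categories:
            if criteria.passes(record, category):
                pairs.add((record.id, category))
    return sorted(pairs)


def dedupe(entries: Sequence[tuple[str, str]]) -> SelectionResult:
    """Collapse entries to unique individuals, preserving entry multiplicity."""
    result = SelectionResult(entries=list(entries))
    result.unique_ids = {ind for ind, _ in entries}
    return result


def apply_qc(
    result: SelectionResult, cohort: Iterable[IndividualRecord]
) -> SelectionResult:
    """Apply the DNA-quality and identity gates to the unique individuals.

    Reasons are prioritized (dna_quality > fingerprint > sex_mismatch) so
    every excluded id carries exactly one reason.
    """
    by_id = {r.id: r for r in cohort}
    for ind in sorted(result.unique_ids):
        record = by_id.get(ind)
        if record is None:
            raise DataError(f"selection references unknown individual {ind!r}")
        if not record.dna_quality_ok:
            result.qc_excluded[ind] = "dna_quality"
        elif not record.fingerprint_match:
            result.qc_excluded[ind] = "fingerprint"
        elif (
            record.sex_inferred != "unknown"
            and record.sex_declared != record.sex_inferred
        ):
            result.qc_excluded[ind] = "sex_mismatch"
    result.final_ids = result.unique_ids - set(result.qc_excluded)
    return result


def expand_combinations(result: SelectionResult) -> int:
    """Count (individual, category) combinations among the final cohort.

    This is the denominator of the per-category enrichment tests: the sum
    over final individuals of their selected category count, i.e. cohort
    size plus the number of extra labels carried by multi-label members.
    """
    ids = result.final_ids if result.final_ids or result.qc_excluded else result.unique_ids
    return sum(1 for ind, _ in result.entries if ind in ids)


def funnel_report(result: SelectionResult) -> dict:
    """Stage counts of the selection funnel, JSON-serializable."""
    reasons = list(result.qc_excluded.values())
    n_quality = reasons.count("dna_quality")
    n_identity = reasons.count("fingerprint") + reasons.count("sex_mismatch")
    return {
        "entries": len(result.entries),
        "unique_individuals": len(result.unique_ids),
        "excluded_dna_quality": n_quality,
        "after_dna_quality": len(result.unique_ids) - n_quality,
        "excluded_identity": n_identity,
        "final_individuals": len(result.final_ids),
        "final_combinations": expand_combinations(result),
        "dual_label_individuals": expand_combinations(result) - len(result.final_ids),
    }
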