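"""Category/age selection, deduplication, QC gates and combination counts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tikd.errors import ConfigError, DataError
from tikd.filtering import (
    FilterCriteria,
    IndividualRecord,
    SelectionResult,
    apply_qc,
    dedupe,
    expand_combinations,
    funnel_report,
    select_entries,
)


def _rec(id="a", age=45.0, categories=("nephrosclerosis",), **kw):
    return IndividualRecord(id=id, age=age, sex_declared="male", categories=categories, **kw)


@pytest.mark.parametrize(
    "age,category,flags,selected",
    [
        (45, "nephrosclerosis", (), True),      # within the 50-year cutoff
        (50, "nephrosclerosis", (), True),      # cutoff is inclusive
        (51, "nephrosclerosis", (), False),
        (45, "IgA nephropathy", (), False),     # 40-year cutoff category
        (40, "IgA nephropathy", (), True),
        (70, "hereditary disorders", (), True), # no age cutoff
        (30, "gout", ("polycystic",), False),   # exclusion condition wins
        (30, "unknown", ("single_kidney",), False),
    ],
)
def test_selection_rules(age, category, flags, selected):
    entries = select_entries(
        [_rec(age=age, categories=(category,), exclusion_flags=flags)]
    )
    assert (("a", category) in entries) == selected


def test_pairs_evaluated_independently():
    """A dual-label member enters under every label whose cutoff it meets."""
    rec = _rec(age=45, categories=("nephrosclerosis", "IgA nephropathy"))
    assert select_entries([rec]) == [("a", "nephrosclerosis")]


def test_selection_order_stable_and_idempotent():
    records = [
        _rec(id="b", age=30, categories=("gout",)),
        _rec(id="a", age=35, categories=("unknown", "gout")),
    ]
    forward = select_entries(records)
    assert forward == select_entries(records[::-1])
    assert forward == sorted(forward)


def test_unknown_category_rejected():
    with pytest.raises(DataError):
        IndividualRecord(id="x", age=40, sex_declared="male", categories=("IGA",))


def test_criteria_requires_all_nine_labels():
    with pytest.raises(ConfigError):
        FilterCriteria(age_cutoff_by_category={"gout": 50.0})


def test_dedupe():
    result = dedupe([("a", "gout"), ("a", "unknown"), ("b", "gout")])
    assert result.unique_ids == {"a", "b"}
    assert len(result.entries) == 3
    assert dedupe([]).unique_ids == set()


def test_qc_reasons_prioritized():
    records = [
        _rec(id="q", dna_quality_ok=False, fingerprint_match=False),
        _rec(id="f", fingerprint_match=False),
        _rec(id="s", sex_inferred="female"),
        _rec(id="ok", sex_inferred="male"),
    ]
    result = apply_qc(dedupe(select_entries(records)), records)
    assert result.qc_excluded == {"q": "dna_quality", "f": "fingerprint", "s": "sex_mismatch"}
    assert result.final_ids == {"ok"}


def test_qc_all_passing_keeps_everyone():
    records = [_rec(id=f"i{k}") for k in range(5)]
    result = apply_qc(dedupe(select_entries(records)), records)
    assert result.final_ids == result.unique_ids


def test_funnel_counts_303_287_271(funnel_cohort):
    """16 planted DNA-quality failures then 16 identity mismatches reduce
    303 selected individuals to a final cohort of 271."""
    result = apply_qc(dedupe(select_entries(funnel_cohort)), funnel_cohort)
    report = funnel_report(result)
    assert report["unique_individuals"] == 303
    assert report["excluded_dna_quality"] == 16
    assert report["after_dna_quality"] == 287
    assert report["excluded_identity"] == 16
    assert report["final_individuals"] == 271
    # funnel conservation
    assert len(result.unique_ids) == len(result.qc_excluded) + len(result.final_ids)


def test_expand_combinations():
    # 3 individuals, one of them dual-label -> 4 combinations
    entries = [("a", "gout"), ("a", "unknown"), ("b", "gout"), ("c", "others")]
    result = dedupe(entries)
    assert expand_combinations(result) == 4
    # single individual, three labels
    assert expand_combinations(dedupe([("z", "gout"), ("z", "unknown"), ("z", "others")])) == 3
    # after QC, only final individuals count
    result.qc_excluded = {"c": "dna_quality"}
    result.final_ids = {"a", "b"}
    assert expand_combinations(result) == 3


@settings(derandomize=True, max_examples=50)
@given(
    ages=st.lists(st.floats(18, 80), min_size=1, max_size=12),
    perm_seed=st.integers(0, 1000),
)
def test_selection_permutation_invariant(ages, perm_seed):
    import random

    records = [
        _rec(id=f"p{k}", age=a, categories=("interstitial nephritis",))
        for k, a in enumerate(ages)
    ]
    shuffled = records[:]
    random.Random(perm_seed).shuffle(shuffled)
    assert select_entries(records) == select_entries(shuffled)


def test_every_final_individual_satisfies_criteria(default_cohort):
    """Post-hoc re-check: all selected pairs pass their category cutoff and
    no final individual carries an excluded condition."""
    criteria = FilterCriteria()
    result = apply_qc(dedupe(select_entries(default_cohort)), default_cohort)
    by_id = {r.id: r for r in default_cohort}
    for ind, cat in result.entries:
        assert criteria.passes(by_id[ind], cat)
    for ind in result.final_ids:
        assert not set(by_id[ind].exclusion_flags)
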