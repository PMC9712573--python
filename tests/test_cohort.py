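"""Synthetic registry and reference-cohort generators."""

import numpy as np
import pytest

from tikd.cohort import (
    CohortConfig,
    ReferenceCohortConfig,
    VariantSpectrum,
    generate_cohort,
    generate_planted_variants,
    generate_reference_cohort,
)
from tikd.errors import ConfigError
from tikd.filtering import apply_qc, dedupe, select_entries
from tikd.io import write_cohort_csv


def _selected(cohort):
    return apply_qc(dedupe(select_entries(cohort)), cohort)


def test_empty_cohort():
    assert generate_cohort(CohortConfig(n_total=0), seed=1) == []


def test_determinism_bit_identical(tmp_path, default_cohort):
    again = generate_cohort(CohortConfig(), seed=1)
    assert again == default_cohort
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(default_cohort, a)
    write_cohort_csv(again, b)
    assert a.read_bytes() == b.read_bytes()
    assert generate_cohort(CohortConfig(), seed=2) != default_cohort


def test_every_member_labeled_and_adult(default_cohort):
    assert len(default_cohort) == 303
    for rec in default_cohort:
        assert len(rec.categories) >= 1
        assert rec.age >= 18


def test_dual_label_rate_among_selected(default_cohort):
    """Dual-label share of the final cohort ~ 7.7% (the modeled study's
    21/271), within Monte-Carlo tolerance at this cohort size."""
    result = _selected(default_cohort)
    per_id = {}
    for ind, _ in result.entries:
        if ind in result.final_ids:
            per_id[ind] = per_id.get(ind, 0) + 1
    dual = sum(1 for v in per_id.values() if v >= 2)
    assert abs(dual / len(result.final_ids) - 0.077) < 0.045


def test_invalid_probability_names_field():
    config = CohortConfig(dual_category_rate=1.5)
    with pytest.raises(ConfigError, match="dual_category_rate"):
        config.validate()
    prevalence = dict(CohortConfig().category_prevalence)
    prevalence["gout"] = -0.1
    with pytest.raises(ConfigError, match="category_prevalence"):
        CohortConfig(category_prevalence=prevalence).validate()


def test_selected_cohort_calibration():
    """Pooled over 1000 generated registries, the selected-cohort median
    CKD-EPI eGFR lies within +-2 of 55.5 and median ACR within +-15% of
    182.1 — the kidney-function targets the generator is built to emulate."""
    config = CohortConfig()
    egfr, acr = [], []
    for seed in range(1000):
        cohort = generate_cohort(config, seed=seed)
        final = _selected(cohort).final_ids
        for rec in cohort:
            if rec.id in final:
                egfr.append(rec.egfr_ckdepi)
                acr.append(rec.acr)
    assert len(egfr) > 200_000
    assert abs(np.median(egfr) - 55.5) < 2.0
    assert abs(np.median(acr) - 182.1) / 182.1 < 0.15


def test_planted_variant_bookkeeping(default_cohort):
    """Unique carriers = spectrum total - dual-diagnosis overlaps; all
    carriers survive selection and QC; per-gene counts honored."""
    config = CohortConfig()
    variants = generate_planted_variants(default_cohort, config, seed=2)
    spectrum = config.variant_spectrum
    assert len(variants) == spectrum.total == 36
    carriers = {v.individual_id for v in variants}
    assert len(carriers) == spectrum.total - spectrum.dual_diagnosis_count == 34
    final = _selected(default_cohort).final_ids
    assert carriers <= final
    per_gene = {}
    for v in variants:
        per_gene[v.gene] = per_gene.get(v.gene, 0) + 1
    assert per_gene == dict(spectrum.gene_counts)
    hotspot = [v for v in variants if v.gene == "COL4A5" and v.hgvs_c == "c.1871G>A"]
    assert len(hotspot) == spectrum.hotspot_count
    # dual-diagnosis carriers hold variants in two different genes
    genes_by_carrier = {}
    for v in variants:
        genes_by_carrier.setdefault(v.individual_id, set()).add(v.gene)
    assert sum(1 for g in genes_by_carrier.values() if len(g) == 2) == 2


def test_planted_variants_deterministic(default_cohort):
    config = CohortConfig()
    a = generate_planted_variants(default_cohort, config, seed=7)
    b = generate_planted_variants(default_cohort, config, seed=7)
    assert a == b


def test_reference_cohort_counts_exact():
    """Bucket counts are allocated deterministically: 108 collagen-IV, 12
    ADTKD small-variant carriers, diagnostic total = round(3315 * 0.093)."""
    config = ReferenceCohortConfig()
    ref = generate_reference_cohort(config, seed=3)
    assert len(ref) == 3315
    counts = ref["bucket"].value_counts()
    assert counts["COL4A"] == 108
    assert counts["ADTKD"] == 12
    assert int(ref["diagnostic"].sum()) == config.n_diagnostic == 308
    # deterministic under the seed, shuffled but identical
    again = generate_reference_cohort(config, seed=3)
    assert ref.equals(again)
    assert not ref.equals(generate_reference_cohort(config, seed=4))


def test_reference_cohort_degenerate_and_invalid():
    empty = generate_reference_cohort(
        ReferenceCohortConfig(n_total=10, diagnostic_fraction=0.0, gene_distribution={}),
        seed=0,
    )
    assert len(empty) == 10 and not empty["diagnostic"].any()
    bad = ReferenceCohortConfig(n_total=100, gene_distribution={"COL4A": 500})
    with pytest.raises(ConfigError, match="gene_distribution"):
        bad.validate()


def test_spectrum_validation():
    with pytest.raises(ConfigError, match="hotspot"):
        VariantSpectrum(hotspot_count=99).validate()
    with pytest.raises(ConfigError, match="panel"):
        VariantSpectrum(gene_counts={"NOTAGENE": 1}).validate()
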