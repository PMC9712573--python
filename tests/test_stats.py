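"""Yield, enrichment, descriptive and comparative statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from tikd.errors import ConfigError, DataError
from tikd.stats import (
    VariantRecord,
    binomial_enrichment,
    biopsy_crosstab,
    bonferroni_threshold,
    diagnostic_yield,
    fold_enrichment,
    gene_category_matrix,
    group_compare,
    interpolate_prevalence,
)


def _var(ind, gene="UMOD", vtype="SNV", acmg=5, cats=("gout",), **kw):
    chrom = "mitochondrial" if vtype == "mito_SNV" else "autosome"
    return VariantRecord(
        individual_id=ind, gene=gene, variant_type=vtype,
        chromosome_class=chrom, acmg_class=acmg, categories=cats, **kw
    )


class TestDiagnosticYield:
    def test_counts_unique_individuals_once(self):
        variants = [
            _var("a"), _var("a", gene="HNF1B"),  # dual diagnosis
            _var("b", acmg=4), _var("c", acmg=3),  # VUS excluded
        ]
        frac, ids = diagnostic_yield(variants, 10)
        assert ids == {"a", "b"} and frac == pytest.approx(0.2)

    def test_type_filter(self):
        variants = [_var("a", vtype="CNV"), _var("b", vtype="mito_SNV", gene="MT-TF"), _var("c")]
        frac, ids = diagnostic_yield(variants, 10, include_types={"SNV", "indel"})
        assert ids == {"c"}

    def test_empty_and_invariances(self):
        assert diagnostic_yield([], 5) == (0.0, set())
        variants = [_var("a"), _var("b", acmg=4)]
        base = diagnostic_yield(variants, 7)
        assert diagnostic_yield(variants[::-1], 7) == base
        assert diagnostic_yield(variants + [variants[0]], 7) == base  # duplicate row

    def test_unknown_individual_rejected(self):
        with pytest.raises(DataError):
            diagnostic_yield([_var("ghost")], 5, known_ids={"a"})


class TestBinomial:
    def test_matches_direct_summation_oracle(self):
        """Minimum-likelihood two-sided p equals summing every outcome whose
        probability does not exceed the observed one's."""
        for k, n, p0 in [(10, 17, 39 / 292), (4, 9, 39 / 292), (3, 20, 0.5), (0, 7, 0.3), (7, 7, 0.9)]:
            pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
            oracle = pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()
            assert binomial_enrichment(k, n, p0) == pytest.approx(oracle, abs=1e-12)

    def test_upper_tail_coincidence(self):
        """For the enrichment settings used here no lower-tail outcome
        qualifies, so the two-sided p equals the upper tail."""
        for k, n in [(10, 17), (4, 9)]:
            upper = sps.binom.sf(k - 1, n, 39 / 292)
            assert binomial_enrichment(k, n, 39 / 292) == pytest.approx(upper, rel=1e-9)

    def test_degenerate_and_domain(self):
        assert binomial_enrichment(5, 5, 0.999999) == pytest.approx(1.0, abs=1e-4)
        with pytest.raises(ConfigError):
            binomial_enrichment(1, 2, 0.0)
        with pytest.raises(ConfigError):
            binomial_enrichment(3, 2, 0.5)


def test_bonferroni():
    assert bonferroni_threshold(0.05, 9) == pytest.approx(0.00556, abs=5e-5)
    assert bonferroni_threshold(0.05, 1) == 0.05
    thresholds = [bonferroni_threshold(0.05, m) for m in range(1, 10)]
    assert thresholds == sorted(thresholds, reverse=True)
    with pytest.raises(ConfigError):
        bonferroni_threshold(0.05, 0)


def test_gene_category_matrix_small():
    variants = [
        _var("a", gene="COL4A5", cats=("gout",)),
        _var("a", gene="COL4A3", cats=("gout",)),       # second gene -> +1
        _var("b", gene="UMOD", cats=("gout", "unknown")),  # two categories
        _var("b", gene="UMOD", cats=("gout",)),            # duplicate triple
    ]
    table = gene_category_matrix(variants)
    assert int(table.values.sum()) == 4
    assert table.loc["UMOD", "gout"] == 1 and table.loc["UMOD", "unknown"] == 1


def test_biopsy_crosstab_small():
    variants = [
        _var("a", biopsy=True, hereditary_suspected=True),
        _var("b", gene="COL4A4", biopsy=True),
        _var("c", gene="COL4A5", biopsy=False),
    ]
    out = biopsy_crosstab(variants)
    assert out["diagnosed"] == 3
    assert out["biopsied_diagnosed"] == 2
    assert out["biopsied_diagnosed_without_suspicion"] == 1
    assert out["col4a_diagnosed"] == 2 and out["biopsied_col4a_diagnosed"] == 1
    assert out["cells"]["diagnosis&biopsy&suspicion"] == 1


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        assert group_compare([1.0, 1.0], [1.0])[1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            group_compare([], [1.0])

    def test_power_under_planted_shift(self):
        """ACR shifted up ~3.5x in a 27-member subgroup (the collagen-IV
        carrier effect scale) is detected at p<0.05 in >=95% of replicates
        against 237 unshifted members."""
        rng = np.random.default_rng(0)
        hits = 0
        reps = 100
        for _ in range(reps):
            base = np.exp(np.log(182.1) + 1.30 * rng.standard_normal(237))
            shifted = 3.5 * np.exp(np.log(182.1) + 1.30 * rng.standard_normal(27))
            if group_compare(shifted, base)[1] < 0.05:
                hits += 1
        assert hits / reps >= 0.95

    def test_null_p_uniform(self):
        """With both groups from one distribution the p values are uniform
        (Kolmogorov-Smirnov check over 1000 replicates)."""
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(1000):
            a = rng.standard_normal(27)
            b = rng.standard_normal(237)
            pvals.append(group_compare(a, b)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_fold_enrichment():
    assert fold_enrichment(5, 271, 12, 3315) == pytest.approx(5.1, abs=0.05)
    assert fold_enrichment(3, 10, 6, 20) == 1.0
    assert fold_enrichment(7, 271, 7, 271) == 1.0
    assert np.isnan(fold_enrichment(1, 10, 0, 10))
    with pytest.raises(ConfigError):
        fold_enrichment(1, 0, 1, 1)


def test_interpolate_prevalence():
    assert round(interpolate_prevalence(7, 5217), 2) == 0.13
    assert interpolate_prevalence(0, 100) == 0.0
    assert interpolate_prevalence(50, 50) == 100.0


def test_mito_type_consistency_enforced():
    with pytest.raises(DataError):
        VariantRecord(individual_id="a", gene="MT-TF", variant_type="mito_SNV",
                      chromosome_class="autosome", acmg_class=5)
    with pytest.raises(DataError):
        VariantRecord(individual_id="a", gene="UMOD", variant_type="SNV",
                      chromosome_class="mitochondrial", acmg_class=5)
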