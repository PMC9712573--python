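"""Categorical ACMG combining rules and the odds-based posterior."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tikd.acmg import (
    BayesParams,
    EvidenceProfile,
    categorical_class,
    classify,
    combined_odds,
    format_posterior,
    parse_evidence,
    posterior,
)
from tikd.errors import ConfigError, DataError

# --- independent rule-table oracle -----------------------------------------
# Minimum-count combinations of the published 2015 combining rules, written
# as data so the oracle shares no control flow with the implementation.
_PATHOGENIC_MINIMA = [
    # (pvs, ps, pm, pp)
    (1, 1, 0, 0), (1, 0, 2, 0), (1, 0, 1, 1), (1, 0, 0, 2),
    (0, 2, 0, 0),
    (0, 1, 3, 0), (0, 1, 2, 2), (0, 1, 1, 4),
]
_LIKELY_PATHOGENIC_MINIMA = [
    (1, 0, 1, 0),
    (0, 1, 1, 0), (0, 1, 0, 2),
    (0, 0, 3, 0), (0, 0, 2, 2), (0, 0, 1, 4),
]


def oracle_class(p: EvidenceProfile) -> int:
    if p.ba >= 1:
        return 1
    counts = (p.pvs, p.ps, p.pm, p.pp)
    if any(c > 0 for c in counts) and (p.bs > 0 or p.bp > 0):
        return 3
    if any(all(c >= m for c, m in zip(counts, minima)) for minima in _PATHOGENIC_MINIMA):
        return 5
    if any(all(c >= m for c, m in zip(counts, minima)) for minima in _LIKELY_PATHOGENIC_MINIMA):
        return 4
    if p.bs >= 2:
        return 1
    if (p.bs >= 1 and p.bp >= 1) or p.bp >= 2:
        return 2
    return 3


def test_exhaustive_agreement_with_rule_table():
    """Implementation matches the data-driven rule table for all profiles
    with per-criterion counts up to 4 (BA binary)."""
    rng4 = range(5)
    for pvs, ps, pm, pp, ba, bs, bp in itertools.product(
        rng4, rng4, rng4, rng4, (0, 1), rng4, rng4
    ):
        profile = EvidenceProfile(pvs, ps, pm, pp, ba, bs, bp)
        assert categorical_class(profile) == oracle_class(profile), profile


@pytest.mark.parametrize(
    "profile,expected",
    [
        (EvidenceProfile(ps=1, pm=2), 4),
        (EvidenceProfile(pvs=1, ps=1), 5),
        (EvidenceProfile(pm=1, pp=1), 3),
        (EvidenceProfile(ba=1, pvs=1), 1),  # stand-alone benign short-circuit
        (EvidenceProfile(bs=2), 1),
        (EvidenceProfile(bs=1, bp=1), 2),
        (EvidenceProfile(ps=1, bp=1), 3),  # conflicting evidence
        (EvidenceProfile(), 3),
    ],
)
def test_categorical_examples(profile, expected):
    assert categorical_class(profile) == expected


def test_combined_odds_values():
    assert combined_odds(EvidenceProfile()) == pytest.approx(1.0)
    assert combined_odds(EvidenceProfile(pvs=1)) == pytest.approx(350.0)
    assert combined_odds(EvidenceProfile(pm=2, pp=2)) == pytest.approx(80.92, abs=0.01)


def test_odds_multiplicative_over_concatenation():
    a = EvidenceProfile(ps=1, pp=2)
    b = EvidenceProfile(pm=2, bs=1)
    combined = EvidenceProfile(ps=1, pp=2, pm=2, bs=1)
    assert combined_odds(combined) == pytest.approx(
        combined_odds(a) * combined_odds(b), rel=1e-12
    )


def test_posterior_identity_and_examples():
    assert posterior(1.0, 0.10) == pytest.approx(0.10)
    modal = posterior(combined_odds(EvidenceProfile(pm=2, pp=2)), 0.10)
    assert round(modal, 2) == 0.90
    strong = posterior(combined_odds(EvidenceProfile(ps=1, pm=2)), 0.10)
    assert strong == pytest.approx(0.9749, abs=5e-4)
    assert format_posterior(strong) == "0.97"
    assert format_posterior(strong, convention="truncate") == "0.97"
    vstrong = posterior(combined_odds(EvidenceProfile(pvs=1, pm=2)), 0.10)
    assert vstrong >= 0.99 and format_posterior(vstrong) == "1.00"


def test_classify_discordant_flag():
    """Moderate+supporting pile-ups reach pathogenic posterior but only
    class 4 categorically."""
    result = classify(EvidenceProfile(pm=3, pp=4))
    assert result.categorical_class == 4
    assert result.posterior >= 0.99
    assert result.discordant

    empty = classify(EvidenceProfile())
    assert empty.categorical_class == 3
    assert empty.posterior == pytest.approx(0.10)
    assert not empty.discordant


_profiles = st.builds(
    EvidenceProfile,
    pvs=st.integers(0, 2), ps=st.integers(0, 3), pm=st.integers(0, 4),
    pp=st.integers(0, 4), ba=st.integers(0, 1), bs=st.integers(0, 3),
    bp=st.integers(0, 4),
)


@settings(derandomize=True, max_examples=200)
@given(profile=_profiles, which=st.sampled_from(["pvs", "ps", "pm", "pp", "bs", "bp"]))
def test_posterior_monotone_in_evidence(profile, which):
    """Adding a pathogenic criterion never lowers the posterior; a benign
    criterion never raises it; the posterior stays inside (0, 1)."""
    base = posterior(combined_odds(profile), 0.10)
    assert 0.0 < base < 1.0
    bumped = EvidenceProfile(**{
        f: getattr(profile, f) + (1 if f == which else 0)
        for f in ("pvs", "ps", "pm", "pp", "ba", "bs", "bp")
    })
    after = posterior(combined_odds(bumped), 0.10)
    if which in ("pvs", "ps", "pm", "pp"):
        assert after >= base
    else:
        assert after <= base


def test_parse_evidence_tokens():
    profile = parse_evidence("PS1;PM2;PP3")
    assert (profile.ps, profile.pm, profile.pp) == (1, 1, 1)
    assert parse_evidence("PVS1, PM2 PM4 BP7") == EvidenceProfile(pvs=1, pm=2, bp=1)
    assert parse_evidence("") == EvidenceProfile()
    with pytest.raises(DataError):
        parse_evidence("PX9")


def test_invalid_params_rejected():
    with pytest.raises(ConfigError):
        BayesParams(prior=0.0)
    with pytest.raises(ConfigError):
        BayesParams(odds_pvst=1.0)
    with pytest.raises(ConfigError):
        EvidenceProfile(ba=2)
    with pytest.raises(ConfigError):
        EvidenceProfile(pm=-1)
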