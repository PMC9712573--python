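"""ACMG/AMP five-tier variant classification and its Bayesian counterpart.

Two classifiers run in parallel on the same evidence profile:

* the categorical 2015 ACMG/AMP combining rules, which map counts of
  pathogenic criteria (PVS very strong, PS strong, PM moderate, PP
  supporting) and benign criteria (BA stand-alone, BS strong, BP
  supporting) onto the five classes (1 benign ... 5 pathogenic); and

* the odds-of-pathogenicity framework, which treats each criterion as an
  exponent step on a shared odds scale — a very strong criterion carries
  odds O, a strong criterion O^(1/2), moderate O^(1/4), supporting
  O^(1/8), with benign criteria contributing the negated exponents — and
  converts the combined odds into a posterior probability of pathogenicity
  against a prior.

With the default prior of 0.10 and O = 350 the posterior reproduces the
values conventionally printed next to each class: the modal likely
pathogenic combination (2 PM + 2 PP) gives 0.90, and class-5 combinations
give values rounding to 1.00. Some evidence combinations (e.g. 3 PM +
4 PP) reach posterior >= 0.99 — numerically "pathogenic" — yet the
categorical rules cap them at likely pathogenic because no strong
criterion is present; such variants are flagged ``discordant``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .errors import ConfigError, DataError

__all__ = [
    "EvidenceProfile",
    "BayesParams",
    "ClassificationResult",
    "parse_evidence",
    "combined_odds",
    "posterior",
    "categorical_class",
    "classify",
]


@dataclass(frozen=True)
class EvidenceProfile:
    """Counts of satisfied ACMG evidence criteria for one variant."""

    pvs: int = 0
    ps: int = 0
    pm: int = 0
    pp: int = 0
    ba: int = 0
    bs: int = 0
    bp: int = 0

    def __post_init__(self) -> None:
        for name in ("pvs", "ps", "pm", "pp", "ba", "bs", "bp"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if self.ba > 1:
            raise ConfigError(f"ba is a stand-alone criterion, count must be 0 or 1, got {self.ba}")

    @property
    def has_pathogenic(self) -> bool:
        return (self.pvs + self.ps + self.pm + self.pp) > 0

    @property
    def has_benign(self) -> bool:
        return (self.ba + self.bs + self.bp) > 0


@dataclass(frozen=True)
class BayesParams:
    """Constants of the odds-of-pathogenicity posterior.

    ``odds_pvst`` is the odds assigned to one very strong criterion; the
    exponent denominators halve the log-odds per step down in strength
    (very strong 1, strong 2, moderate 4, supporting 8). Benign criteria
    use the negated exponents. BA1 is categorical-only and carries no odds.
    """

    prior: float = 0.10
    odds_pvst: float = 350.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ConfigError(f"prior must be in (0, 1), got {self.prior}")
        if not self.odds_pvst > 1.0:
            raise ConfigError(f"odds_pvst must exceed 1, got {self.odds_pvst}")


@dataclass(frozen=True)
class ClassificationResult:
    categorical_class: int
    posterior: float
    bayes_tier: str
    discordant: bool


_TOKEN_RE = re.compile(r"[;,\s]+")
# order matters: PVS before PS, BA/BS/BP before bare prefixes
_PREFIXES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")


def parse_evidence(tokens: str) -> EvidenceProfile:
    """Parse a criterion-token string like ``"PS1;PM2;PP3"`` into counts.

    Tokens are separated by semicolons, commas or whitespace; each token is
    matched by its criterion-family prefix (the trailing index digit is not
    interpreted). Unknown tokens raise :class:`DataError`.
    """
    counts = {p: 0 for p in _PREFIXES}
    for token in _TOKEN_RE.split(tokens.strip()):
        if not token:
            continue
        for prefix in _PREFIXES:
            if token.upper().startswith(prefix):
                counts[prefix] += 1
                break
        else:
            raise DataError(f"unknown ACMG evidence token {token!r}")
    return EvidenceProfile(
        pvs=counts["PVS"], ps=counts["PS"], pm=counts["PM"], pp=counts["PP"],
        ba=counts["BA"], bs=counts["BS"], bp=counts["BP"],
    )


def combined_odds(profile: EvidenceProfile, params: BayesParams = BayesParams()) -> float:
    """Combined odds of pathogenicity for an evidence profile.

    odds = O^(pvs + ps/2 + pm/4 + pp/8 - bs/2 - bp/8); multiplicative over
    concatenated profiles, identity 1.0 on the empty profile.
    """
    exponent = (
        profile.pvs
        + profile.ps / 2.0
        + profile.pm / 4.0
        + profile.pp / 8.0
        - profile.bs / 2.0
        - profile.bp / 8.0
    )
    return params.odds_pvst ** exponent


def posterior(odds: float, prior: float = 0.10) -> float:
    """Posterior probability of pathogenicity from combined odds and prior.

    posterior = odds * prior / ((odds - 1) * prior + 1); equals the prior
    at odds 1 and is strictly increasing in odds.
    """
    if not odds > 0:
        raise DataError(f"odds must be positive, got {odds}")
    return odds * prior / ((odds - 1.0) * prior + 1.0)


def _pathogenic_rule(p: EvidenceProfile) -> bool:
    if p.pvs >= 1 and (
        p.ps >= 1 or p.pm >= 2 or (p.pm == 1 and p.pp == 1) or p.pp >= 2
    ):
        return True
    if p.ps >= 2:
        return True
    if p.ps == 1 and (
        p.pm >= 3 or (p.pm == 2 and p.pp >= 2) or (p.pm == 1 and p.pp >= 4)
    ):
        return True
    return False


def _likely_pathogenic_rule(p: EvidenceProfile) -> bool:
    if p.pvs >= 1 and p.pm == 1:
        return True
    if p.ps == 1 and 1 <= p.pm <= 2:
        return True
    if p.ps == 1 and p.pp >= 2:
        return True
    if p.pm >= 3:
        return True
    if p.pm == 2 and p.pp >= 2:
        return True
    if p.pm == 1 and p.pp >= 4:
        return True
    return False


def categorical_class(profile: EvidenceProfile) -> int:
    """Categorical ACMG class 1-5 from the 2015 combining rules.

    BA1 short-circuits to class 1 before any rule evaluation. Mixed
    pathogenic and benign evidence is treated as conflicting and yields
    class 3, while the parallel posterior still combines both signs.
    """
    if profile.ba >= 1:
        return 1
    if profile.has_pathogenic and profile.has_benign:
        return 3
    if _pathogenic_rule(profile):
        return 5
    if _likely_pathogenic_rule(profile):
        return 4
    if profile.bs >= 2:
        return 1
    if (profile.bs == 1 and profile.bp >= 1) or profile.bp >= 2:
        return 2
    return 3


#: Posterior cut points for the Bayesian five tiers.
BAYES_TIERS = (
    (0.99, "pathogenic"),
    (0.90, "likely_pathogenic"),
)


def bayes_tier(post: float) -> str:
    if post >= 0.99:
        return "pathogenic"
    if post >= 0.90:
        return "likely_pathogenic"
    if post <= 0.001:
        return "benign"
    if post <= 0.10:
        return "likely_benign"
    return "VUS"


def classify(profile: EvidenceProfile, params: BayesParams = BayesParams()) -> ClassificationResult:
    """Run the categorical and Bayesian classifiers and flag disagreement.

    ``discordant`` is set when the posterior reaches the pathogenic tier
    (>= 0.99) while the combining rules stop at class 4 — combinations of
    moderate/supporting criteria can accumulate pathogenic-level odds that
    the rule table, which requires a strong criterion for class 5, cannot
    express.
    """
    cat = categorical_class(profile)
    post = posterior(combined_odds(profile, params), params.prior)
    tier = bayes_tier(post)
    discordant = tier == "pathogenic" and cat == 4
    return ClassificationResult(
        categorical_class=cat, posterior=post, bayes_tier=tier, discordant=discordant
    )


def format_posterior(post: float, decimals: int = 2, convention: str = "round") -> str:
    """Render a posterior for reports.

    ``convention`` is ``"round"`` (half-even to ``decimals``; the default,
    since it reproduces the conventional printed per-variant values — the
    modal likely-pathogenic posterior 0.89991 prints as 0.90 and class-5
    posteriors >= 0.995 print as 1.00, neither of which truncation gives)
    or ``"truncate"``. Full precision is always retained internally.
    """
    if convention == "truncate":
        factor = 10 ** decimals
        return f"{math.floor(post * factor) / factor:.{decimals}f}"
    if convention == "round":
        return f"{post:.{decimals}f}"
    raise ConfigError(f"convention must be 'truncate' or 'round', got {convention!r}")
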