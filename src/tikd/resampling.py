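"""Resampling null distributions against a reference exome cohort.

The panel yield is benchmarked against a large published exome-sequenced
CKD reference cohort by simulation: repeatedly draw a panel-cohort-sized
subset (default 271) without replacement from the reference members
(default 3315), apply the *panel-detectability* predicate to each drawn
member — a member counts only if it is diagnostic, its gene is on the
panel, and its variant type is within the detectable set — and record the
detectable fraction. The observed panel yield is then ranked within this
null (add-one empirical p). A second null records, per replicate, the
fraction of detectable draws falling in the collagen-IV gene group, to
test whether the panel cohort is unusually collagen-IV-heavy.

Because each member's contribution depends only on its class (detectable
collagen-IV / detectable other / non-detectable), drawing members without
replacement is collapsed to a multivariate hypergeometric draw over the
class counts — exactly equivalent member-level sampling, and the
hypergeometric law provides the closed-form moment oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .vocab import COL4A_GENES, DEFAULT_PANEL_GENES

__all__ = [
    "PanelDefinition",
    "NullDistribution",
    "is_panel_detectable",
    "simulate_null_yield",
    "simulate_col4a_fraction",
    "empirical_p",
]

#: Variant types an exome-comparison analysis shares with the panel:
#: small variants on autosomes and gonosomes only.
COMPARISON_DETECTABLE_TYPES: frozenset[str] = frozenset({"SNV", "indel"})


@dataclass(frozen=True)
class PanelDefinition:
    """The gene panel and the variant types counted as detectable."""

    genes: frozenset[str] = frozenset(DEFAULT_PANEL_GENES)
    detectable_types: frozenset[str] = COMPARISON_DETECTABLE_TYPES

    def __post_init__(self) -> None:
        required = set(COL4A_GENES) | {"MUC1", "UMOD", "REN", "HNF1B", "SEC61A1"}
        missing = required - set(self.genes)
        if missing:
            raise ConfigError(
                f"genes: panel must contain the collagen-IV and ADTKD core genes,"
                f" missing {sorted(missing)}"
            )


@dataclass
class NullDistribution:
    """Per-replicate statistics of a resampling null and the ranked observation."""

    reps: int
    n_draw: int
    statistics: np.ndarray
    observed: float | None = None
    empirical_p: float | None = None
    seed: int | None = None
    n_excluded: int = 0
    direction: str = "greater"

    def summary(self) -> dict:
        out = {
            "reps": self.reps,
            "n_draw": self.n_draw,
            "mean": float(np.mean(self.statistics)),
            "sd": float(np.std(self.statistics, ddof=1)),
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "direction": self.direction,
            "seed": self.seed,
            "replicates_excluded": self.n_excluded,
        }
        if self.empirical_p is not None and self.empirical_p <= 1.0 / self.reps:
            out["empirical_p_display"] = f"< {1.0 / self.reps:g}"
        return out


def is_panel_detectable(member, panel: PanelDefinition) -> bool:
    """Whether one reference-cohort member's finding is detectable by the panel.

    ``member`` is any object or mapping with ``diagnostic``, ``gene`` and
    ``variant_type`` fields. Non-diagnostic members are never detectable.
    """
    if isinstance(member, dict):
        diagnostic = member["diagnostic"]
        gene = member["gene"]
        vtype = member["variant_type"]
    else:
        diagnostic, gene, vtype = member.diagnostic, member.gene, member.variant_type
    return bool(diagnostic) and gene in panel.genes and vtype in panel.detectable_types


def _class_counts(reference: pd.DataFrame, panel: PanelDefinition) -> tuple[int, int, int]:
    """Counts of (detectable collagen-IV, detectable other, non-detectable)."""
    det = (
        reference["diagnostic"].astype(bool)
        & reference["gene"].isin(panel.genes)
        & reference["variant_type"].isin(panel.detectable_types)
    )
    col4 = reference["gene"].isin(COL4A_GENES)
    n_det_col4 = int((det & col4).sum())
    n_det_other = int((det & ~col4).sum())
    return n_det_col4, n_det_other, len(reference) - n_det_col4 - n_det_other


def _draws(
    reference: pd.DataFrame,
    panel: PanelDefinition,
    n_draw: int,
    reps: int,
    seed: int,
) -> np.ndarray:
    if n_draw > len(reference):
        raise ConfigError(
            f"n_draw={n_draw} exceeds the reference population of {len(reference)}"
        )
    if reps < 1:
        raise ConfigError(f"reps must be >= 1, got {reps}")
    counts = _class_counts(reference, panel)
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, n_draw, size=reps)


def simulate_null_yield(
    reference: pd.DataFrame,
    panel: PanelDefinition,
    n_draw: int = 271,
    reps: int = 10_000,
    seed: int = 0,
    observed: float | None = None,
) -> NullDistribution:
    """Null distribution of the panel-detectable yield under random subsetting.

    Each replicate draws ``n_draw`` reference members without replacement
    and records the fraction passing the panel-detectability predicate.
    Deterministic for fixed (reference, panel, n_draw, reps, seed).
    """
    draws = _draws(reference, panel, n_draw, reps, seed)
    stats = (draws[:, 0] + draws[:, 1]) / n_draw
    null = NullDistribution(
        reps=reps, n_draw=n_draw, statistics=stats, observed=observed, seed=seed
    )
    if observed is not None:
        null.empirical_p = empirical_p(null, observed, "greater")
        null.direction = "greater"
    return null


def simulate_col4a_fraction(
    reference: pd.DataFrame,
    panel: PanelDefinition,
    n_draw: int = 271,
    reps: int = 10_000,
    seed: int = 0,
    observed: float | None = None,
) -> NullDistribution:
    """Null distribution of the collagen-IV fraction among detectable draws.

    Replicates with zero detectable members have an undefined fraction;
    they are dropped from the statistics and their count reported in
    ``n_excluded``.
    """
    draws = _draws(reference, panel, n_draw, reps, seed)
    det = draws[:, 0] + draws[:, 1]
    ok = det > 0
    stats = draws[ok, 0] / det[ok]
    null = NullDistribution(
        reps=reps,
        n_draw=n_draw,
        statistics=stats,
        observed=observed,
        seed=seed,
        n_excluded=int((~ok).sum()),
        direction="two_sided",
    )
    if observed is not None:
        null.empirical_p = empirical_p(null, observed, "two_sided")
    return null


def empirical_p(
    null: NullDistribution | Sequence[float],
    observed: float,
    direction: str = "greater",
) -> float:
    """Add-one empirical p value of an observation within a simulated null.

    ``greater``: (#{replicates >= observed} + 1) / (reps + 1), never exactly
    zero, so the smallest reportable value at R replicates is 1/(R+1).
    ``two_sided``: twice the smaller of the two add-one tail probabilities,
    capped at 1.
    """
    stats = np.asarray(
        null.statistics if isinstance(null, NullDistribution) else null, dtype=float
    )
    if stats.size == 0:
        raise DataError("empirical_p: the null distribution is empty")
    r = stats.size
    upper = (np.sum(stats >= observed) + 1) / (r + 1)
    if direction == "greater":
        return float(upper)
    if direction == "two_sided":
        lower = (np.sum(stats <= observed) + 1) / (r + 1)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ConfigError(f"direction must be 'greater' or 'two_sided', got {direction!r}")
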