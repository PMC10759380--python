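"""Six-domain confidence rating for network meta-analysis comparisons.

Each comparison is judged on within-study bias, reporting bias,
intransitivity, imprecision, heterogeneity, and incoherence, each receiving
no / some / major concerns; the overall grade starts at 'high' and is
downgraded one step per 'some concerns' domain and two per 'major concerns'
domain on the high / moderate / low / very-low ladder.  Trial-level
judgements (risk of bias, intransitivity level) are summarized per comparison
by the weighted-average rule over the contribution matrix.  Imprecision and
heterogeneity are judged by how the confidence interval — and, for
heterogeneity, the prediction interval — sit relative to an equivalence range
of plus/minus one minimal clinically important difference (MCID); for binary
outcomes any increase in risk is treated as relevant, so the range collapses
to the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

from .datamodel import ComparisonKey, ValidationError


class ConcernLevel(IntEnum):
    no_concerns = 0
    some_concerns = 1
    major_concerns = 2

    def __str__(self) -> str:
        return self.name


DOMAINS = (
    "within_study_bias", "reporting_bias", "intransitivity",
    "imprecision", "heterogeneity", "incoherence",
)

GRADES = ("high", "moderate", "low", "very_low")


class JudgementGapError(ValueError):
    """A contributing trial lacks the judgement needed for a weighted rule."""


@dataclass(frozen=True)
class MCIDConfig:
    """Equivalence-range half-widths: minimal clinically important
    differences on the Constant and DASH scales; binary outcomes treat any
    risk increase as clinically relevant (range = the null value)."""

    cs_mcid: float = 5.4
    dash_mcid: float = 8.1
    binary_rule: bool = True

    def __post_init__(self) -> None:
        if self.cs_mcid <= 0 or self.dash_mcid <= 0:
            raise ValidationError("MCIDs must be > 0")

    def range_for(self, outcome: str) -> tuple[float, float]:
        if outcome == "CS":
            return (-self.cs_mcid, self.cs_mcid)
        if outcome == "DASH":
            return (-self.dash_mcid, self.dash_mcid)
        return (0.0, 0.0)  # binary: any increase is relevant


@dataclass
class DomainJudgement:
    level: ConcernLevel | None      # None = not applicable
    rationale: str = ""

    @property
    def applicable(self) -> bool:
        return self.level is not None


@dataclass
class ConfidenceRating:
    pair: ComparisonKey
    judgements: dict[str, DomainJudgement]
    overall: str

    def __post_init__(self) -> None:
        if set(self.judgements) != set(DOMAINS):
            raise ValidationError(f"expected exactly the six domains {DOMAINS}")


# ---------------------------------------------------------------------------
# Weighted-average summarization of trial-level judgements

_LEVEL_SCORE = {"low": 1.0, "moderate": 2.0, "high": 3.0}


def rate_weighted_domain(
    contribution_row: Mapping[str, float],
    trial_levels: Mapping[str, str],
    some_threshold: float = 1.5,
    major_threshold: float = 2.5,
) -> ConcernLevel:
    """Contribution-weighted average of trial levels (low=1, moderate=2,
    high=3): below ``some_threshold`` -> no concerns, below
    ``major_threshold`` -> some, else major."""
    total, weighted = 0.0, 0.0
    for trial_id, pct in contribution_row.items():
        if pct <= 0:
            continue
        if trial_id not in trial_levels:
            raise JudgementGapError(f"no judgement for contributing trial {trial_id!r}")
        level = trial_levels[trial_id]
        if level not in _LEVEL_SCORE:
            raise JudgementGapError(f"trial {trial_id!r}: unknown level {level!r}")
        weighted += pct * _LEVEL_SCORE[level]
        total += pct
    if total <= 0:
        raise JudgementGapError("contribution row has no positive entries")
    w = weighted / total
    if w < some_threshold:
        return ConcernLevel.no_concerns
    if w < major_threshold:
        return ConcernLevel.some_concerns
    return ConcernLevel.major_concerns


# ---------------------------------------------------------------------------
# Reporting bias

@dataclass(frozen=True)
class ReportingBiasIndicators:
    """Network-level reporting-bias warning signs: grey literature and
    unpublished data not searched; evidence base is a few positive early
    findings; comparisons studied mainly in industry-funded trials; prior
    documented evidence of reporting bias."""

    missing_grey_literature: bool = False
    small_positive_early: bool = False
    industry_funded: bool = False
    documented_bias: bool = False

    def any(self) -> bool:
        return (
            self.missing_grey_literature or self.small_positive_early
            or self.industry_funded or self.documented_bias
        )


def rate_reporting_bias(
    indicators: ReportingBiasIndicators,
    contributing_trials: Sequence,
    trigger_level: ConcernLevel = ConcernLevel.some_concerns,
) -> tuple[ConcernLevel, str]:
    """Any triggered indicator, any unregistered contributing trial, or any
    registered trial with planned-vs-reported outcome discrepancies raises
    the level to ``trigger_level`` (default: some concerns)."""
    reasons = []
    if indicators.any():
        reasons.append("network-level reporting-bias indicator triggered")
    for t in contributing_trials:
        if not t.registered:
            reasons.append(f"trial {t.trial_id} has no pre-dating registration")
        elif t.outcome_discrepancy:
            reasons.append(f"trial {t.trial_id} has planned-vs-reported outcome discrepancy")
    if reasons:
        return trigger_level, "; ".join(reasons)
    return ConcernLevel.no_concerns, "all trials registered, no discrepancies, no indicators"


# ---------------------------------------------------------------------------
# Imprecision / heterogeneity via the equivalence range

def _crossings(lo: float, hi: float, eq_range: tuple[float, float]) -> int:
    """How many equivalence-range boundaries the interval crosses.

    A degenerate range (binary outcomes) is a single boundary at the null;
    crossing it counts as two — any straddle of the null is a conclusion
    change there.
    """
    lo_b, hi_b = eq_range
    if lo_b == hi_b:
        return 2 if lo < lo_b < hi else 0
    return int(lo < lo_b < hi) + int(lo < hi_b < hi)


def rate_imprecision(
    ci_low: float, ci_high: float, eq_range: tuple[float, float]
) -> tuple[ConcernLevel, str]:
    """CI entirely inside or entirely beyond the equivalence range implies a
    firm conclusion (no concerns); crossing one boundary blurs it (some);
    crossing both — or the null, for binary outcomes — is uninformative
    (major)."""
    k = _crossings(ci_low, ci_high, eq_range)
    level = [ConcernLevel.no_concerns, ConcernLevel.some_concerns, ConcernLevel.major_concerns][k]
    return level, (
        f"95% CI [{ci_low:.2f}, {ci_high:.2f}] crosses {k} boundary(ies) of "
        f"the equivalence range [{eq_range[0]:.2f}, {eq_range[1]:.2f}]"
    )


def rate_heterogeneity(
    ci: tuple[float, float],
    prediction_interval: tuple[float, float],
    eq_range: tuple[float, float],
) -> tuple[ConcernLevel, str]:
    """Concern grows with how many additional equivalence-range boundaries
    the prediction interval crosses beyond those the CI already crosses."""
    extra = max(0, _crossings(*prediction_interval, eq_range) - _crossings(*ci, eq_range))
    level = [ConcernLevel.no_concerns, ConcernLevel.some_concerns,
             ConcernLevel.major_concerns][min(extra, 2)]
    return level, (
        f"prediction interval [{prediction_interval[0]:.2f}, {prediction_interval[1]:.2f}] "
        f"crosses {extra} boundary(ies) beyond the 95% CI"
    )


# ---------------------------------------------------------------------------
# Incoherence

def rate_incoherence(
    side_p: float | None,
    side_difference: float | None,
    global_flagged: bool | None,
    eq_range: tuple[float, float],
    threshold: float = 0.10,
) -> tuple[ConcernLevel | None, str]:
    """SIDE drives the rating where applicable: a flagged split is a major
    concern when the direct-indirect difference exceeds the equivalence
    half-width (conclusion-changing), otherwise some concern.  Without SIDE,
    a flagged global test gives some concern; with neither test applicable
    the domain is not applicable (None)."""
    if side_p is not None:
        if side_p < threshold:
            half = (eq_range[1] - eq_range[0]) / 2.0
            if side_difference is not None and abs(side_difference) > half:
                return ConcernLevel.major_concerns, (
                    f"SIDE p={side_p:.2f} with conclusion-changing direct-indirect difference"
                )
            return ConcernLevel.some_concerns, f"SIDE p={side_p:.2f} below {threshold}"
        return ConcernLevel.no_concerns, f"SIDE p={side_p:.2f}"
    if global_flagged is None:
        return None, "cannot assess: no closed loop provides indirect evidence"
    if global_flagged:
        return ConcernLevel.some_concerns, "global design-by-treatment test flagged"
    return ConcernLevel.no_concerns, "global design-by-treatment test not flagged"


# ---------------------------------------------------------------------------
# Ladder and summaries

def rate_overall(judgements: Mapping[str, DomainJudgement]) -> str:
    """Downgrade ladder: start 'high', one step per some-concerns domain, two
    per major-concerns; not-applicable domains do not downgrade; floor at
    'very_low'."""
    if set(judgements) != set(DOMAINS):
        raise ValidationError(f"expected exactly the six domains {DOMAINS}")
    steps = sum(int(j.level) for j in judgements.values() if j.applicable)
    return GRADES[min(steps, len(GRADES) - 1)]


def build_rating(pair: ComparisonKey, judgements: dict[str, DomainJudgement]) -> ConfidenceRating:
    return ConfidenceRating(pair=pair, judgements=judgements, overall=rate_overall(judgements))


def summarize_downgrades(ratings: Sequence[ConfidenceRating]) -> dict[str, float | None]:
    """Per domain, the percentage of comparisons downgraded (level at least
    some concerns), integer-rounded half-up; None where the domain was not
    applicable for every comparison."""
    out: dict[str, float | None] = {}
    for d in DOMAINS:
        applicable = [r for r in ratings if r.judgements[d].applicable]
        if not applicable:
            out[d] = None
            continue
        downgraded = sum(
            1 for r in applicable
            if r.judgements[d].level >= ConcernLevel.some_concerns
        )
        pct = 100.0 * downgraded / len(ratings)
        out[d] = float(int(pct + 0.5))
    return out


__all__ = [
    "ConcernLevel", "DOMAINS", "GRADES", "DomainJudgement", "ConfidenceRating",
    "MCIDConfig", "ReportingBiasIndicators", "JudgementGapError",
    "rate_weighted_domain", "rate_reporting_bias", "rate_imprecision",
    "rate_heterogeneity", "rate_incoherence", "rate_overall", "build_rating",
    "summarize_downgrades",
]
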