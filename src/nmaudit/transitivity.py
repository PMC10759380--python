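"""Quantitative transitivity assessment.

Indirect comparisons are only valid if effect modifiers (here: age, gender,
plus analyst-supplied qualitative modifiers such as fracture morphology or
surgical indication) are balanced across the comparisons of a network.  This
module pools each comparison's modifier distribution over its trials, takes
differences against a designated reference comparison, and applies predefined
cutoffs: an absolute mean-age difference above 5 years flags intransitivity
outright (no significance test — trial age SDs are typically unreported), and
a proportion-of-females difference flags only when it exceeds 0.20 in
absolute terms AND Fisher's exact test is significant.  Sensitivity cutoffs
(10 years / 0.30) are supported.  Per-trial intransitivity levels (low /
moderate / high) count the distinct flagged modifiers on the trial's
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from scipy import stats

from .datamodel import ComparisonKey, TrialRecord, ValidationError
from .effects import combined_mean, combined_sd


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TransitivityConfig:
    age_cutoff: float = 5.0           # years
    female_cutoff: float = 0.20       # absolute proportion difference
    sensitivity_age_cutoff: float = 10.0
    sensitivity_female_cutoff: float = 0.30
    alpha: float = 0.05               # Fisher screening level
    reference: ComparisonKey = ComparisonKey("HA", "NOP")

    def __post_init__(self) -> None:
        for name in ("age_cutoff", "female_cutoff",
                     "sensitivity_age_cutoff", "sensitivity_female_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    def sensitivity(self) -> "TransitivityConfig":
        """The same config with the sensitivity cutoffs promoted to primary."""
        return replace(
            self,
            age_cutoff=self.sensitivity_age_cutoff,
            female_cutoff=self.sensitivity_female_cutoff,
        )


@dataclass(frozen=True)
class QualitativeFlag:
    """An analyst judgement that a comparison lacks transitivity on a
    modifier that cannot be compared numerically."""

    pair: ComparisonKey
    modifier: str           # e.g. fracture_morphology, comorbidity, indication
    rationale: str
    source: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValidationError("qualitative flag requires a rationale")


@dataclass
class ComparisonModifierSummary:
    pair: ComparisonKey
    n_trials: int
    n_participants: int
    pooled_age: float | None
    pooled_age_sd: float | None
    females: int | None
    female_pct: float | None
    age_diff: float | None = None
    female_diff: float | None = None   # percentage points
    fisher_p: float | None = None
    flags: set[str] = field(default_factory=set)
    is_reference: bool = False


def reconstruct_females(trial: TrialRecord, female_pct: float) -> int:
    """Round half-up a reported percentage to a count (Fisher needs counts)."""
    import math

    return int(math.floor(female_pct / 100.0 * trial.total_n + 0.5))


def pool_modifiers(
    trials_by_edge: dict[ComparisonKey, Sequence[TrialRecord]],
) -> list[ComparisonModifierSummary]:
    """Pool mean age (participant-weighted combined mean) and female
    proportion per comparison.  Trials missing a modifier are excluded from
    that modifier's pooling with a warning; the combined age SD is reported
    only when every trial on the edge has one."""
    out = []
    for pair in sorted(trials_by_edge, key=str):
        trials = list(trials_by_edge[pair])
        n_participants = sum(t.total_n for t in trials)
        with_age = [t for t in trials if t.mean_age is not None]
        if len(with_age) < len(trials):
            warnings.warn(f"{pair}: {len(trials) - len(with_age)} trial(s) missing mean age")
        pooled_age = (
            combined_mean([(t.total_n, t.mean_age) for t in with_age]) if with_age else None
        )
        pooled_age_sd = None
        if with_age and all(t.sd_age is not None for t in with_age):
            pooled_age_sd = combined_sd(
                [(t.total_n, t.mean_age, t.sd_age) for t in with_age]
            )
        with_f = [t for t in trials if t.females is not None]
        if len(with_f) < len(trials):
            warnings.warn(f"{pair}: {len(trials) - len(with_f)} trial(s) missing female count")
        females = sum(t.females for t in with_f) if with_f else None
        f_total = sum(t.total_n for t in with_f)
        female_pct = 100.0 * females / f_total if with_f else None
        out.append(
            ComparisonModifierSummary(
                pair=pair, n_trials=len(trials), n_participants=n_participants,
                pooled_age=pooled_age, pooled_age_sd=pooled_age_sd,
                females=females, female_pct=female_pct,
            )
        )
    return out


def fisher_female_p(
    females_a: int, total_a: int, females_b: int, total_b: int
) -> float:
    """Two-sided Fisher's exact p for the 2x2 females/males table (the
    sum-of-tables-no-more-probable-than-observed convention)."""
    table = [[females_a, total_a - females_a], [females_b, total_b - females_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def compare_to_reference(
    summaries: Sequence[ComparisonModifierSummary],
    config: TransitivityConfig = TransitivityConfig(),
    qualitative: Sequence[QualitativeFlag] = (),
) -> list[ComparisonModifierSummary]:
    """Attach differences versus the reference comparison, Fisher screening,
    and intransitivity flags to each summary.

    Age flag: ``|pooled_age - reference age| > age_cutoff`` (absolute rule).
    Gender flag: Fisher p < alpha AND ``|difference| > 100 * female_cutoff``
    percentage points.  Qualitative flags are attached verbatim.
    """
    ref = next((s for s in summaries if s.pair == config.reference), None)
    if ref is None:
        raise ConfigurationError(
            f"reference comparison {config.reference} not present in the network"
        )
    qual_by_pair: dict[ComparisonKey, set[str]] = {}
    for qf in qualitative:
        qual_by_pair.setdefault(qf.pair, set()).add(qf.modifier)

    ref_total = ref.n_participants
    out = []
    for s in summaries:
        s = replace_summary(s)
        s.is_reference = s.pair == config.reference
        if s.pair in qual_by_pair:
            s.flags.add("qualitative")
        if s.is_reference:
            s.age_diff = 0.0
            s.female_diff = 0.0
            s.fisher_p = 1.0
            out.append(s)
            continue
        if s.pooled_age is not None and ref.pooled_age is not None:
            s.age_diff = s.pooled_age - ref.pooled_age
            if abs(s.age_diff) > config.age_cutoff:
                s.flags.add("age")
        if s.female_pct is not None and ref.female_pct is not None:
            s.female_diff = s.female_pct - ref.female_pct
            s.fisher_p = fisher_female_p(
                s.females, s.n_participants, ref.females, ref_total
            )
            if s.fisher_p < config.alpha and abs(s.female_diff) > 100.0 * config.female_cutoff:
                s.flags.add("gender")
        out.append(s)
    return out


def replace_summary(s: ComparisonModifierSummary) -> ComparisonModifierSummary:
    return ComparisonModifierSummary(
        pair=s.pair, n_trials=s.n_trials, n_participants=s.n_participants,
        pooled_age=s.pooled_age, pooled_age_sd=s.pooled_age_sd,
        females=s.females, female_pct=s.female_pct,
    )


def classify_trial_intransitivity(
    trial: TrialRecord, summaries: Sequence[ComparisonModifierSummary]
) -> str:
    """Per-trial intransitivity level: count the distinct flagged modifiers
    (age, gender, qualitative) over the comparisons the trial informs —
    0 modifiers -> low, 1 -> moderate, >= 2 -> high."""
    pairs = set(trial.comparisons())
    modifiers: set[str] = set()
    for s in summaries:
        if s.pair in pairs:
            modifiers |= s.flags
    return "low" if not modifiers else ("moderate" if len(modifiers) == 1 else "high")


__all__ = [
    "TransitivityConfig", "QualitativeFlag", "ComparisonModifierSummary",
    "ConfigurationError",
    "pool_modifiers", "compare_to_reference", "classify_trial_intransitivity",
    "fisher_female_p", "reconstruct_females",
]
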