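"""Contrast-level effect measures and pairwise pooling.

Arm-level summaries become within-trial contrasts (mean differences in score
points for continuous outcomes, log odds ratios for binary), which are then
pooled per comparison by inverse-variance weighting, with a DerSimonian–Laird
between-trial variance under the random-effects model.  The module also holds
the combined-group mean/SD formulas used by the transitivity assessment and
the mean-SD imputation used as a sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datamodel import ArmRecord, ComparisonKey, TrialRecord, ValidationError


class MissingSDError(ValueError):
    """A continuous arm lacks an SD (impute or drop before contrasting)."""


class NoEvidenceError(ValueError):
    """No contrasts supplied for the requested pooling."""


@dataclass(frozen=True)
class Contrast:
    """A within-trial relative effect of ``pair.b`` versus ``pair.a``.

    Orientation is fixed by the canonical (sorted) order of the pair: the
    estimate is second-listed minus first-listed (continuous) or the log odds
    ratio of second versus first (binary).  ``oriented(b, a)`` gives the
    sign-flipped view.
    """

    trial_id: str
    pair: ComparisonKey
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"contrast {self.trial_id} {self.pair}: se must be > 0")

    def oriented(self, first: str, second: str) -> float:
        """Estimate of ``second`` relative to ``first``."""
        if (first, second) == self.pair.pair:
            return self.estimate
        if (second, first) == self.pair.pair:
            return -self.estimate
        raise KeyError(f"{first}:{second} does not match contrast pair {self.pair}")


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    i2: float
    q: float
    k: int


def _continuous_contrast(a1: ArmRecord, a2: ArmRecord) -> tuple[float, float]:
    for a in (a1, a2):
        if a.sd is None:
            raise MissingSDError(
                f"arm {a.intervention}: mean reported without an SD; impute or exclude"
            )
    est = a2.mean - a1.mean
    se = math.sqrt(a1.sd**2 / a1.n + a2.sd**2 / a2.n)
    return est, se


def _binary_contrast(a1: ArmRecord, a2: ArmRecord) -> tuple[float, float]:
    e1, f1 = a1.events, a1.n - a1.events
    e2, f2 = a2.events, a2.n - a2.events
    if (e1 == 0 and e2 == 0) or (f1 == 0 and f2 == 0):
        raise ValidationError(
            "degenerate 2x2 table: no events (or no non-events) in either arm"
        )
    cells = [e1, f1, e2, f2]
    if any(c == 0 for c in cells):
        # 0.5 continuity correction on all four cells when any cell is zero
        e1, f1, e2, f2 = (c + 0.5 for c in cells)
    est = math.log((e2 / f2) / (e1 / f1))
    se = math.sqrt(1 / e1 + 1 / f1 + 1 / e2 + 1 / f2)
    return est, se


def contrast_from_arms(
    arm1: ArmRecord,
    arm2: ArmRecord,
    outcome_type: str,
    trial_id: str = "",
) -> Contrast:
    """Contrast of arm2's intervention versus arm1's, in canonical pair order.

    Continuous: mean difference with SE ``sqrt(sd1^2/n1 + sd2^2/n2)``.
    Binary: log odds ratio; a 0.5 continuity correction is added to all four
    cells iff any cell is zero.
    """
    pair = ComparisonKey(arm1.intervention, arm2.intervention)
    if pair.pair != (arm1.intervention, arm2.intervention):
        arm1, arm2 = arm2, arm1  # canonical orientation
    if outcome_type == "continuous":
        est, se = _continuous_contrast(arm1, arm2)
    elif outcome_type == "binary":
        est, se = _binary_contrast(arm1, arm2)
    else:
        raise ValidationError(f"unknown outcome_type {outcome_type!r}")
    return Contrast(trial_id=trial_id, pair=pair, estimate=est, se=se)


def _arm_variance(arm: ArmRecord, outcome_type: str) -> float:
    """Sampling variance an arm contributes to any contrast it enters."""
    if outcome_type == "continuous":
        if arm.sd is None:
            raise MissingSDError(f"arm {arm.intervention}: SD absent")
        return arm.sd**2 / arm.n
    e, f = arm.events, arm.n - arm.events
    if e == 0 or f == 0:
        e, f = e + 0.5, f + 0.5
    return 1 / e + 1 / f


def contrasts_from_trial(trial: TrialRecord, outcome_type: str) -> list[Contrast]:
    """All C(m, 2) contrasts of an m-arm trial.  The full pairwise set is
    emitted deliberately: from its SEs the network fit reconstructs the exact
    within-trial covariance (shared-arm covariance = shared-arm variance)."""
    arms = sorted(trial.arms, key=lambda a: a.intervention)
    return [
        contrast_from_arms(arms[i], arms[j], outcome_type, trial_id=trial.trial_id)
        for i in range(len(arms))
        for j in range(i + 1, len(arms))
    ]


def trial_arm_variances(trial: TrialRecord, outcome_type: str) -> dict[str, float]:
    """Per-arm sampling variances, keyed by intervention code."""
    return {a.intervention: _arm_variance(a, outcome_type) for a in trial.arms}


def pool_pairwise(contrasts: Sequence[Contrast], model: str = "random") -> PooledEstimate:
    """Inverse-variance pooling of contrasts sharing one comparison.

    ``model='common'`` is the fixed-effect estimate; ``model='random'`` adds
    a DerSimonian–Laird tau^2 to every within-trial variance.  With a single
    contrast both models return it unchanged (tau2 = 0, I^2 = 0).
    """
    if not contrasts:
        raise NoEvidenceError("no contrasts to pool")
    pairs = {c.pair for c in contrasts}
    if len(pairs) != 1:
        raise ValidationError(f"contrasts span multiple comparisons: {sorted(map(str, pairs))}")

    y = np.array([c.estimate for c in contrasts])
    v = np.array([c.se**2 for c in contrasts])
    w = 1 / v
    est_c = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - est_c) ** 2))
    k = len(y)
    df = k - 1
    if df > 0:
        c_factor = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c_factor) if c_factor > 0 else 0.0
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    else:
        tau2, i2 = 0.0, 0.0

    if model == "random":
        w_star = 1 / (v + tau2)
        est = float(np.sum(w_star * y) / np.sum(w_star))
        se = float(math.sqrt(1 / np.sum(w_star)))
    elif model == "common":
        est, se = est_c, float(math.sqrt(1 / np.sum(w)))
    else:
        raise ValidationError(f"unknown model {model!r}")

    half = 1.959963984540054 * se
    return PooledEstimate(
        estimate=est, se=se, ci_low=est - half, ci_high=est + half,
        tau2=tau2, i2=i2, q=q, k=k,
    )


def combined_mean(groups: Iterable[tuple[float, float]]) -> float:
    """Sample-size weighted combined mean over (n, mean) groups."""
    groups = list(groups)
    if not groups:
        raise NoEvidenceError("no groups to combine")
    n_tot = sum(n for n, _ in groups)
    return sum(n * m for n, m in groups) / n_tot


def combined_sd(groups: Iterable[tuple[float, float, float | None]]) -> float:
    """Combined-group SD over (n, mean, sd) groups: pooled within-group
    variance plus the between-group spread of means, on N - 1 degrees of
    freedom — the SD one would compute from the concatenated raw samples."""
    groups = list(groups)
    if not groups:
        raise NoEvidenceError("no groups to combine")
    for _, _, s in groups:
        if s is None:
            raise MissingSDError("a group SD is absent; combined SD undefined")
    n_tot = sum(n for n, _, _ in groups)
    grand = combined_mean([(n, m) for n, m, _ in groups])
    within = sum((n - 1) * s**2 for n, _, s in groups)
    between = sum(n * (m - grand) ** 2 for n, m, _ in groups)
    return math.sqrt((within + between) / (n_tot - 1))


class CannotImputeError(ValueError):
    """No reported SDs anywhere in the network to average."""


def impute_sd(trials: Sequence[TrialRecord], outcome: str | None = None) -> list[TrialRecord]:
    """Replace every absent arm SD by the unweighted mean of all reported
    arm-level SDs in the network; reported SDs untouched, imputed arms
    flagged.  Mirrors the mean-SD imputation sensitivity analysis."""
    reported = [
        a.sd for t in trials for a in t.arms
        if a.mean is not None and a.sd is not None
    ]
    needs = any(a.mean is not None and a.sd is None for t in trials for a in t.arms)
    if needs and not reported:
        raise CannotImputeError("no reported SDs available to impute from")
    if not needs:
        return list(trials)
    fill = float(np.mean(reported))
    out = []
    for t in trials:
        new_arms = [
            replace(a, sd=fill, sd_imputed=True)
            if (a.mean is not None and a.sd is None) else a
            for a in t.arms
        ]
        out.append(replace(t, arms=new_arms))
    return out


__all__ = [
    "Contrast", "PooledEstimate",
    "MissingSDError", "NoEvidenceError", "CannotImputeError",
    "contrast_from_arms", "contrasts_from_trial", "trial_arm_variances",
    "pool_pairwise", "combined_mean", "combined_sd", "impute_sd",
]
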