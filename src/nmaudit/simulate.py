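"""Synthetic trial networks with known truth.

Every pipeline stage is testable against networks generated here: true
relative effects obey consistency by construction, optional per-design
offsets inject incoherence into chosen loops, a between-trial SD adds
heterogeneity, and per-intervention modifier models (age, sex) let modifier
imbalance — the mechanism behind intransitivity — propagate into the
generated trial records.  Continuous outcomes are simulated on the 0-100
Constant-score scale; binary outcomes through a logit link on the baseline
risk.  A single global seed spawns one independent substream per trial, so a
fixed seed yields byte-identical output.

``fixture_like_paper`` builds networks whose topology, trial counts,
participant totals, pooled ages, and female percentages match the three
audited shoulder-fracture networks; outcome values are synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    ArmRecord, ComparisonKey, NetworkSpec, TrialRecord, ValidationError,
)


@dataclass(frozen=True)
class ModifierModel:
    """Per-intervention distribution of trial-level effect modifiers."""

    age_mean: float = 75.0     # years
    age_sd: float = 8.0        # years, between-participant
    female_p: float = 0.85     # probability a participant is female


@dataclass
class SimConfig:
    interventions: list[str]
    true_effects: dict[str, float]           # vs interventions[0]; score pts or log OR
    edges: list[tuple[ComparisonKey, int, int]]   # (pair, n_trials, per-arm n)
    tau: float = 0.0                         # between-trial SD of true contrasts
    incoherence_offsets: dict[ComparisonKey, float] = field(default_factory=dict)
    modifier_model: dict[str, ModifierModel] = field(default_factory=dict)
    sd_missing_prob: float = 0.0
    outcome: str = "CS"
    outcome_type: str = "continuous"
    arm_sd: float = 12.0                     # within-arm outcome SD (score points)
    baseline_mean: float = 60.0              # reference-arm Constant score
    baseline_risk: float = 0.20              # reference-arm event risk (binary)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if not 0 <= self.sd_missing_prob <= 1:
            raise ValidationError("sd_missing_prob must be in [0, 1]")
        known = set(self.interventions)
        for pair, _, _ in self.edges:
            if not set(pair.pair) <= known:
                raise ValidationError(f"edge {pair} uses codes outside {sorted(known)}")
        edge_pairs = {pair for pair, _, _ in self.edges}
        for pair in self.incoherence_offsets:
            if pair not in edge_pairs:
                raise ValidationError(f"incoherence offset on non-existent design {pair}")
        for code in self.interventions:
            self.true_effects.setdefault(code, 0.0)
            self.modifier_model.setdefault(code, ModifierModel())


@dataclass
class SimTruth:
    """Ground truth retained for scoring parameter recovery."""

    true_effects: dict[str, float]
    per_trial_contrast: dict[str, float]     # realized true contrast (b vs a)
    offsets: dict[ComparisonKey, float]
    tau: float


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _simulate_arm_outcome(
    rng: np.random.Generator, cfg: SimConfig, true_mean: float, n: int, missing_sd: bool
) -> dict:
    obs_mean = float(np.clip(rng.normal(true_mean, cfg.arm_sd / math.sqrt(n)), 0.0, 100.0))
    obs_sd = float(cfg.arm_sd * math.sqrt(rng.chisquare(n - 1) / (n - 1)))
    return {"mean": round(obs_mean, 2), "sd": None if missing_sd else round(obs_sd, 2)}


def generate_network(config: SimConfig) -> tuple[list[TrialRecord], SimTruth]:
    """Simulate one trial network from the configured truth."""
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(sum(k for _, k, _ in config.edges))
    trials: list[TrialRecord] = []
    per_trial_contrast: dict[str, float] = {}
    s = 0
    for pair, n_trials, per_arm_n in config.edges:
        a, b = pair.pair
        base = config.true_effects[b] - config.true_effects[a]
        base += config.incoherence_offsets.get(pair, 0.0)
        for j in range(n_trials):
            rng = np.random.default_rng(streams[s])
            s += 1
            trial_id = f"{pair.a}-{pair.b}-{j + 1}"
            d_true = base + (rng.normal(0.0, config.tau) if config.tau > 0 else 0.0)
            per_trial_contrast[trial_id] = d_true
            arms = []
            if config.outcome_type == "continuous":
                mu_a = rng.normal(config.baseline_mean, 5.0)
                means = {a: mu_a, b: mu_a + d_true}
                for code in (a, b):
                    missing = rng.random() < config.sd_missing_prob
                    payload = _simulate_arm_outcome(rng, config, means[code], per_arm_n, missing)
                    arms.append(ArmRecord(intervention=code, n=per_arm_n, **payload))
            else:
                p_a = config.baseline_risk
                risks = {a: p_a, b: _expit(_logit(p_a) + d_true)}
                for code in (a, b):
                    events = int(rng.binomial(per_arm_n, risks[code]))
                    arms.append(ArmRecord(intervention=code, n=per_arm_n, events=events))
            # trial-level modifiers from the mixture of arm-specific models
            ages, females = [], 0
            for arm in arms:
                mm = config.modifier_model[arm.intervention]
                ages.append(rng.normal(mm.age_mean, mm.age_sd / math.sqrt(arm.n)))
                females += int(rng.binomial(arm.n, mm.female_p))
            total_n = sum(arm.n for arm in arms)
            mean_age = sum(age * arm.n for age, arm in zip(ages, arms)) / total_n
            trials.append(
                TrialRecord(
                    trial_id=trial_id, arms=arms,
                    mean_age=round(float(mean_age), 1),
                    sd_age=round(
                        float(np.mean([config.modifier_model[x.intervention].age_sd
                                       for x in arms])), 1),
                    females=min(females, total_n),
                    registered=True, outcome_discrepancy=False, rob="low",
                    outcome=config.outcome,
                )
            )
    truth = SimTruth(
        true_effects=dict(config.true_effects),
        per_trial_contrast=per_trial_contrast,
        offsets=dict(config.incoherence_offsets),
        tau=config.tau,
    )
    return trials, truth


# ---------------------------------------------------------------------------
# Fixtures shaped like the three audited networks
#
# Per edge: (comparison, n_trials, total participants, pooled mean age,
# female %).  These marginals match the published quantitative transitivity
# table of the audit; outcome values are synthetic.

_FIXTURE_EDGES: dict[str, list[tuple[str, int, int, float, float]]] = {
    "davey": [
        ("HA:NOP", 2, 105, 77.4, 90.0),
        ("HA:LCP", 1, 32, 71.6, 84.0),
        ("IMN:LCP", 3, 184, 65.0, 72.0),
        ("LCP:NOP", 3, 197, 73.0, 87.0),
        ("LCP:RSA", 1, 124, 75.2, 90.0),
        ("HA:RSA", 1, 61, 74.0, 85.0),
        ("NOP:RSA", 1, 59, 83.5, 86.0),
    ],
    "du": [
        ("HA:NOP", 2, 105, 77.4, 90.0),
        ("HA:ORIF", 1, 32, 71.6, 84.0),
        ("NOP:ORIF", 3, 149, 73.5, 85.0),
        ("HA:RSA", 1, 61, 74.0, 85.0),
    ],
    "orman": [
        ("HA:NOP", 2, 105, 77.4, 90.0),
        ("HA:ORIF", 2, 92, 68.0, 64.0),
        ("NOP:ORIF", 3, 149, 73.5, 85.0),
        ("HA:RSA", 1, 61, 74.0, 85.0),
    ],
}

#: Edges whose (single) trial reported its continuous outcome without an SD
#: — the situation that, in the audited reviews, forced that trial out of
#: the continuous-outcome networks and broke the only closed loop.
_FIXTURE_MISSING_SD: dict[str, set[str]] = {
    "davey": set(),
    "du": {"HA:ORIF"},
    "orman": {"HA:ORIF"},
}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fixture_like_paper(which: str, outcome: str = "CS") -> NetworkSpec:
    """A synthetic network whose topology, trial counts, participant totals,
    pooled ages, and female percentages match one of the three audited
    networks ('davey', 'du', 'orman').  Outcome payloads are synthetic but
    deterministic.  For continuous outcomes the historical missing-SD trial
    is reproduced (its arms carry means without SDs)."""
    if which not in _FIXTURE_EDGES:
        raise ValidationError(f"unknown fixture {which!r}; choose from {sorted(_FIXTURE_EDGES)}")
    outcome_type = "binary" if outcome == "additional_surgery" else "continuous"
    trials: list[TrialRecord] = []
    counter = 0
    for pair_s, k, total, age, fpct in _FIXTURE_EDGES[which]:
        pair = ComparisonKey.parse(pair_s)
        # the historical missing-SD situation affected a single trial
        edge_missing_sd = outcome_type == "continuous" and str(pair) in {
            str(ComparisonKey.parse(p)) for p in _FIXTURE_MISSING_SD[which]
        }
        # split participants over trials, then over two arms, preserving totals
        base, rem = divmod(total, k)
        trial_ns = [base + (1 if i < rem else 0) for i in range(k)]
        females_left = _round_half_up(fpct * total / 100.0)
        for j, t_n in enumerate(trial_ns):
            counter += 1
            f = min(_round_half_up(fpct * t_n / 100.0), females_left, t_n)
            if j == k - 1:
                f = min(females_left, t_n)
            females_left -= f
            n1 = t_n // 2
            n2 = t_n - n1
            missing_sd = edge_missing_sd and j == 0
            arms = []
            for code, n_arm, bump in ((pair.a, n1, 0.0), (pair.b, n2, 3.0)):
                if outcome_type == "continuous":
                    arms.append(ArmRecord(
                        intervention=code, n=max(n_arm, 1),
                        mean=round(60.0 + bump + 0.7 * counter, 1),
                        sd=None if missing_sd else 12.0,
                    ))
                else:
                    arms.append(ArmRecord(
                        intervention=code, n=max(n_arm, 1),
                        events=max(1, _round_half_up(0.15 * n_arm)),
                    ))
            trials.append(TrialRecord(
                trial_id=f"{which}-{pair.a}-{pair.b}-{j + 1}",
                arms=arms, mean_age=age, sd_age=None, females=f,
                total_n=t_n, fracture_parts="3-4-part",
                registered=(counter % 3 == 0),
                outcome_discrepancy=(counter % 3 == 0 and counter % 2 == 0),
                rob="high" if counter % 2 else "moderate",
                outcome=outcome,
            ))
    return NetworkSpec(
        trials=trials, outcome=outcome, outcome_type=outcome_type,
        reference_comparison=ComparisonKey("HA", "NOP"), label=which,
    )


__all__ = [
    "ModifierModel", "SimConfig", "SimTruth",
    "generate_network", "fixture_like_paper",
]
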