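"""End-to-end reliability audit of a trial network.

For each outcome the pipeline builds the evidence graph, fits the
frequentist network meta-analysis, runs the incoherence tests, assesses
transitivity against the reference comparison, and rates six-domain
confidence for every comparison, finishing with the per-domain downgrade
summary.  Stage order matters: coherence and transitivity both feed the
confidence domains.  Missing-SD trials are dropped from continuous outcomes
unless mean-SD imputation is enabled; every exclusion and every convention in
effect is echoed into the report's provenance block, so a reader can see
exactly which analytic choices produced each number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .datamodel import (
    ComparisonKey, NetworkSpec, TrialRecord,
    build_network, edge_trials, has_closed_loop,
)
from .effects import MissingSDError, contrasts_from_trial, impute_sd
from .nma import (
    ConnectivityError, NetworkFit, comparison_contributions, contribution_matrix,
    fit_network, league_table,
)
from .coherence import CoherenceReport, coherence_report, DEFAULT_THRESHOLD
from .transitivity import (
    ComparisonModifierSummary, QualitativeFlag, TransitivityConfig,
    classify_trial_intransitivity, compare_to_reference, pool_modifiers,
)
from .confidence import (
    ConcernLevel, ConfidenceRating, DomainJudgement, MCIDConfig,
    ReportingBiasIndicators, build_rating, rate_heterogeneity, rate_imprecision,
    rate_incoherence, rate_reporting_bias, rate_weighted_domain,
    summarize_downgrades,
)


@dataclass
class AuditConfig:
    transitivity: TransitivityConfig = field(default_factory=TransitivityConfig)
    mcid: MCIDConfig = field(default_factory=MCIDConfig)
    model: str = "random"
    coherence_threshold: float = DEFAULT_THRESHOLD
    reporting_indicators: ReportingBiasIndicators = field(
        default_factory=lambda: ReportingBiasIndicators(missing_grey_literature=True)
    )
    qualitative_flags: tuple[QualitativeFlag, ...] = ()
    exclude_trials: tuple[str, ...] = ()      # e.g. duplicate publications
    impute_missing_sd: bool = False
    use_sensitivity_cutoffs: bool = False
    seed: int = 0


@dataclass
class OutcomeReport:
    outcome: str
    outcome_type: str
    nodes: list[str]
    trials_used: list[str]
    trials_dropped: dict[str, str]            # trial_id -> reason
    has_closed_loop: bool
    fit: NetworkFit | None
    coherence: CoherenceReport | None
    transitivity: list[ComparisonModifierSummary]
    trial_intransitivity: dict[str, str]
    ratings: list[ConfidenceRating]
    downgrade_summary: dict[str, float | None]
    errors: dict[str, str] = field(default_factory=dict)  # stage -> message


@dataclass
class AuditReport:
    label: str
    outcomes: dict[str, OutcomeReport]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "outcomes": {k: _outcome_dict(v) for k, v in self.outcomes.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _outcome_dict(r: OutcomeReport) -> dict:
    fit = r.fit
    return {
        "outcome": r.outcome,
        "nodes": r.nodes,
        "trials_used": r.trials_used,
        "trials_dropped": r.trials_dropped,
        "has_closed_loop": r.has_closed_loop,
        "model": fit.model if fit else None,
        "tau2": round(fit.tau2, 6) if fit else None,
        "i2": round(fit.i2, 4) if fit else None,
        "q": {
            "total": [round(fit.q_total, 4), fit.df_total],
            "heterogeneity": [round(fit.q_heterogeneity, 4), fit.df_heterogeneity],
            "inconsistency": [round(fit.q_inconsistency, 4), fit.df_inconsistency],
        } if fit else None,
        "coherence": _coherence_dict(r.coherence),
        "transitivity": [_summary_dict(s) for s in r.transitivity],
        "trial_intransitivity": r.trial_intransitivity,
        "ratings": [_rating_dict(x) for x in r.ratings],
        "downgrade_summary": r.downgrade_summary,
        "errors": r.errors,
    }


def _coherence_dict(c: CoherenceReport | None) -> dict | None:
    if c is None:
        return None
    return {
        "threshold": c.threshold,
        "side": {
            str(pair): (None if res is None else {
                "p": round(res.p, 4), "z": round(res.z, 4),
                "difference": round(res.difference, 4), "flagged": res.flagged,
            })
            for pair, res in sorted(c.side.items(), key=lambda kv: str(kv[0]))
        },
        "global": {
            "q": round(c.global_test.q, 4), "df": c.global_test.df,
            "p": None if c.global_test.p is None else round(c.global_test.p, 4),
            "flagged": c.global_test.flagged,
            "applicable": c.global_test.applicable,
        },
    }


def _summary_dict(s: ComparisonModifierSummary) -> dict:
    rnd = lambda x, k=1: None if x is None else round(x, k)
    return {
        "comparison": str(s.pair), "n_trials": s.n_trials,
        "n_participants": s.n_participants,
        "pooled_age": rnd(s.pooled_age), "pooled_age_sd": rnd(s.pooled_age_sd),
        "female_pct": rnd(s.female_pct, 0), "age_diff": rnd(s.age_diff),
        "female_diff": rnd(s.female_diff, 0),
        "fisher_p": rnd(s.fisher_p, 4),
        "flags": sorted(s.flags), "reference": s.is_reference,
    }


def _rating_dict(r: ConfidenceRating) -> dict:
    return {
        "comparison": str(r.pair),
        "overall": r.overall,
        "domains": {
            d: {
                "level": None if j.level is None else str(j.level),
                "rationale": j.rationale,
            }
            for d, j in r.judgements.items()
        },
    }


# ---------------------------------------------------------------------------

def _select_trials(
    trials: Sequence[TrialRecord], outcome: str, outcome_type: str, config: AuditConfig
) -> tuple[list[TrialRecord], list[TrialRecord], dict[str, str]]:
    """Split into (trials for transitivity, trials for estimation, dropped).

    Transitivity is judged on every included trial reporting the outcome —
    modifier data do not depend on a usable SD — whereas estimation,
    coherence, and confidence require complete outcome payloads, so
    missing-SD trials are dropped there unless imputation is enabled.
    """
    dropped: dict[str, str] = {}
    kept: list[TrialRecord] = []
    for t in trials:
        if t.trial_id in config.exclude_trials:
            dropped[t.trial_id] = "excluded by configuration (e.g. duplicate publication)"
            continue
        if t.outcome is not None and t.outcome != outcome:
            continue
        want_binary = outcome_type == "binary"
        if want_binary and not all(a.is_binary for a in t.arms):
            dropped[t.trial_id] = f"no event data for {outcome}"
            continue
        if not want_binary and not all(a.is_continuous for a in t.arms):
            dropped[t.trial_id] = f"no continuous data for {outcome}"
            continue
        kept.append(t)
    analysable = list(kept)
    if outcome_type == "continuous":
        if config.impute_missing_sd:
            analysable = impute_sd(kept, outcome)
        else:
            analysable = []
            for t in kept:
                if any(a.mean is not None and a.sd is None for a in t.arms):
                    dropped[t.trial_id] = "continuous outcome reported without an SD"
                else:
                    analysable.append(t)
    return kept, analysable, dropped


def audit_outcome(spec: NetworkSpec, config: AuditConfig) -> OutcomeReport:
    """Run the full audit for one outcome network."""
    all_trials, trials, dropped = _select_trials(
        spec.trials, spec.outcome, spec.outcome_type, config
    )
    errors: dict[str, str] = {}
    tconfig = config.transitivity
    if config.use_sensitivity_cutoffs:
        tconfig = tconfig.sensitivity()

    if not all_trials:
        return OutcomeReport(
            outcome=spec.outcome, outcome_type=spec.outcome_type, nodes=[],
            trials_used=[], trials_dropped=dropped, has_closed_loop=False,
            fit=None, coherence=None, transitivity=[], trial_intransitivity={},
            ratings=[], downgrade_summary={}, errors={"network": "no usable trials"},
        )

    # the analysis graph (what estimation and coherence can use)
    loop = bool(trials) and has_closed_loop(build_network(trials))
    # transitivity is assessed over every included trial for the outcome
    by_edge: dict[ComparisonKey, list[TrialRecord]] = {}
    for t in all_trials:
        for pair in t.comparisons():
            by_edge.setdefault(pair, []).append(t)

    # --- transitivity ------------------------------------------------------
    summaries = pool_modifiers(by_edge)
    try:
        summaries = compare_to_reference(summaries, tconfig, config.qualitative_flags)
    except Exception as exc:  # reference missing etc.: keep unflagged summaries
        errors["transitivity"] = str(exc)
    trial_levels = {
        t.trial_id: classify_trial_intransitivity(t, summaries) for t in all_trials
    }

    # --- network fit and coherence ----------------------------------------
    fit: NetworkFit | None = None
    coh: CoherenceReport | None = None
    try:
        if not trials:
            raise ConnectivityError("no trials with complete outcome data")
        contrasts = [c for t in trials for c in contrasts_from_trial(t, spec.outcome_type)]
        fit_nodes = {a.intervention for t in trials for a in t.arms}
        reference = (
            spec.reference_comparison.b
            if spec.reference_comparison.b in fit_nodes else None
        )
        fit = fit_network(contrasts, model=config.model, reference=reference,
                          outcome=spec.outcome)
        coh = coherence_report(fit, threshold=config.coherence_threshold)
    except (ConnectivityError, MissingSDError, ValueError) as exc:
        errors["nma"] = str(exc)

    # --- confidence --------------------------------------------------------
    ratings: list[ConfidenceRating] = []
    if fit is not None:
        eq_range = config.mcid.range_for(spec.outcome)
        rob_levels = {t.trial_id: t.rob for t in trials}
        trial_lookup = {t.trial_id: t for t in trials}
        for a, b in _all_pairs(fit.nodes):
            pair = ComparisonKey(a, b)
            row = comparison_contributions(fit, pair)
            contributing = [trial_lookup[tid] for tid, pct in row.items() if pct > 0]
            j: dict[str, DomainJudgement] = {}
            j["within_study_bias"] = DomainJudgement(
                rate_weighted_domain(row, rob_levels),
                "contribution-weighted risk-of-bias average",
            )
            level, why = rate_reporting_bias(config.reporting_indicators, contributing)
            j["reporting_bias"] = DomainJudgement(level, why)
            j["intransitivity"] = DomainJudgement(
                rate_weighted_domain(row, trial_levels),
                "contribution-weighted trial intransitivity average",
            )
            est, se, lo, hi = fit.estimate_ci(a, b)
            level, why = rate_imprecision(lo, hi, eq_range)
            j["imprecision"] = DomainJudgement(level, why)
            level, why = rate_heterogeneity(
                (lo, hi), fit.prediction_interval(a, b), eq_range
            )
            j["heterogeneity"] = DomainJudgement(level, why)
            side = coh.side.get(pair) if coh else None
            global_flag = (
                None if (coh is None or not coh.global_test.applicable)
                else coh.global_test.flagged
            )
            level, why = rate_incoherence(
                None if side is None else side.p,
                None if side is None else side.difference,
                global_flag, eq_range, threshold=config.coherence_threshold,
            )
            j["incoherence"] = DomainJudgement(level, why)
            ratings.append(build_rating(pair, j))

    return OutcomeReport(
        outcome=spec.outcome, outcome_type=spec.outcome_type,
        nodes=sorted({a.intervention for t in all_trials for a in t.arms}),
        trials_used=[t.trial_id for t in trials],
        trials_dropped=dropped, has_closed_loop=loop, fit=fit, coherence=coh,
        transitivity=summaries, trial_intransitivity=trial_levels,
        ratings=ratings, downgrade_summary=summarize_downgrades(ratings),
        errors=errors,
    )


def _all_pairs(nodes: Sequence[str]) -> list[tuple[str, str]]:
    return [(nodes[i], nodes[j]) for i in range(len(nodes)) for j in range(i + 1, len(nodes))]


def run_audit(specs: Sequence[NetworkSpec], config: AuditConfig | None = None,
              label: str = "") -> AuditReport:
    """Audit one network per outcome and assemble the full report with a
    provenance block recording every analytic convention in effect."""
    config = config or AuditConfig()
    outcomes = {spec.outcome: audit_outcome(spec, config) for spec in specs}
    tcfg = config.transitivity.sensitivity() if config.use_sensitivity_cutoffs \
        else config.transitivity
    provenance = {
        "package": f"nmaudit {__version__}",
        "model": config.model,
        "coherence_threshold": config.coherence_threshold,
        "age_cutoff_years": tcfg.age_cutoff,
        "female_cutoff_proportion": tcfg.female_cutoff,
        "fisher_alpha": tcfg.alpha,
        "reference_comparison": str(tcfg.reference),
        "mcid": {"CS": config.mcid.cs_mcid, "DASH": config.mcid.dash_mcid,
                 "binary_any_increase": config.mcid.binary_rule},
        "impute_missing_sd": config.impute_missing_sd,
        "sensitivity_cutoffs": config.use_sensitivity_cutoffs,
        "excluded_trials": list(config.exclude_trials),
        "conventions": [
            "binary effect measure: log odds ratio, 0.5 continuity correction on any zero cell",
            "network tau2: method-of-moments (DerSimonian-Laird generalization), one per network",
            "multi-arm trials: exact shared-arm covariance in the GLS weights",
            "node splitting: multi-arm trials with the split pair count as direct only",
            "contribution: stream decomposition of hat-matrix evidence flow",
            "weighted-average rule thresholds: 1.5 / 2.5",
            "age flag: absolute cutoff only; gender flag: Fisher p < alpha AND cutoff",
        ],
        "seed": config.seed,
    }
    return AuditReport(label=label, outcomes=outcomes, provenance=provenance)


@dataclass
class SensitivityDiff:
    variant: str
    changes: list[str]


def run_sensitivity(
    specs: Sequence[NetworkSpec], config: AuditConfig | None = None, label: str = ""
) -> tuple[AuditReport, dict[str, tuple[AuditReport, SensitivityDiff]]]:
    """Primary audit plus each enabled sensitivity variant, with a diff of
    every flag, level, and grade that changed."""
    config = config or AuditConfig()
    variants: dict[str, AuditConfig] = {}
    if not config.use_sensitivity_cutoffs:
        variants["alt_cutoffs"] = dataclasses.replace(config, use_sensitivity_cutoffs=True)
    if not config.impute_missing_sd:
        variants["impute_sd"] = dataclasses.replace(config, impute_missing_sd=True)
    if not variants:
        raise ValueError("no sensitivity variant to run: all toggles already enabled")
    primary = run_audit(specs, config, label=label)
    out: dict[str, tuple[AuditReport, SensitivityDiff]] = {}
    for name, vconfig in variants.items():
        report = run_audit(specs, vconfig, label=f"{label}:{name}")
        out[name] = (report, _diff_reports(primary, report, name))
    return primary, out


def _diff_reports(a: AuditReport, b: AuditReport, variant: str) -> SensitivityDiff:
    changes: list[str] = []
    for outcome in a.outcomes:
        ra, rb = a.outcomes[outcome], b.outcomes.get(outcome)
        if rb is None:
            continue
        flags_a = {str(s.pair): sorted(s.flags) for s in ra.transitivity}
        flags_b = {str(s.pair): sorted(s.flags) for s in rb.transitivity}
        for pair in sorted(set(flags_a) | set(flags_b)):
            if flags_a.get(pair) != flags_b.get(pair):
                changes.append(
                    f"{outcome} {pair}: transitivity flags {flags_a.get(pair)} -> "
                    f"{flags_b.get(pair)}"
                )
        grades_a = {str(r.pair): r.overall for r in ra.ratings}
        grades_b = {str(r.pair): r.overall for r in rb.ratings}
        for pair in sorted(set(grades_a) | set(grades_b)):
            if grades_a.get(pair) != grades_b.get(pair):
                changes.append(
                    f"{outcome} {pair}: overall {grades_a.get(pair)} -> {grades_b.get(pair)}"
                )
        for tid in sorted(set(ra.trial_intransitivity) | set(rb.trial_intransitivity)):
            la, lb = ra.trial_intransitivity.get(tid), rb.trial_intransitivity.get(tid)
            if la != lb:
                changes.append(f"{outcome} trial {tid}: intransitivity {la} -> {lb}")
    return SensitivityDiff(variant=variant, changes=changes)


# ---------------------------------------------------------------------------
# Table exports

def transitivity_table(report: OutcomeReport) -> pd.DataFrame:
    """Per-comparison pooled-modifier table (the quantitative transitivity
    analogue): comparison, trials, participants, pooled age (SD), age
    difference, female %, female difference with significance marker."""
    rows = []
    for s in report.transitivity:
        sig = ""
        if s.fisher_p is not None and not s.is_reference:
            sig = "*" if s.fisher_p < 0.001 else "ns"
        rows.append({
            "comparison": str(s.pair),
            "rcts": s.n_trials,
            "participants": s.n_participants,
            "mean_age": None if s.pooled_age is None else round(s.pooled_age, 1),
            "age_sd": None if s.pooled_age_sd is None else round(s.pooled_age_sd, 1),
            "age_diff": "reference" if s.is_reference else (
                None if s.age_diff is None else round(s.age_diff, 1)),
            "female_pct": None if s.female_pct is None else int(s.female_pct + 0.5),
            "female_diff": "reference" if s.is_reference else (
                None if s.female_diff is None else f"{int(round(s.female_diff))} ({sig})"),
            "flags": ",".join(sorted(s.flags)),
        })
    return pd.DataFrame(rows)


def downgrade_table(reports: Mapping[str, OutcomeReport]) -> pd.DataFrame:
    """Per-outcome downgrade percentages per domain (NA where a domain was
    inapplicable for every comparison)."""
    rows = []
    for outcome, r in reports.items():
        row = {"outcome": outcome, "studies": len(r.trials_used),
               "comparisons": len(r.ratings)}
        for d, v in r.downgrade_summary.items():
            row[d] = "NA" if v is None else int(v)
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "AuditConfig", "AuditReport", "OutcomeReport", "SensitivityDiff",
    "run_audit", "run_sensitivity", "audit_outcome",
    "transitivity_table", "downgrade_table",
]
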