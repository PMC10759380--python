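"""Domain types for trial networks of randomized comparisons.

The package audits networks of randomized trials comparing treatments for
proximal humerus fractures (nonoperative care, plating, nailing, arthroplasty).
Everything downstream — network estimation, incoherence tests, transitivity
checks, confidence ratings — consumes the types defined here: arm-level trial
records, unordered comparison keys, and a network specification that binds a
set of trials to one outcome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

#: Controlled vocabulary of intervention codes: nonoperative treatment,
#: locking compression plate, intramedullary nail, hemi-arthroplasty,
#: reverse shoulder arthroplasty, tension band, open reduction internal
#: fixation.
INTERVENTIONS = frozenset({"NOP", "LCP", "IMN", "HA", "RSA", "TB", "ORIF"})

#: Remap used by the audited reviews that pool plate and tension-band
#: fixation under a generic ORIF node.
ORIF_REMAP: Mapping[str, str] = {"LCP": "ORIF", "TB": "ORIF"}

OUTCOMES = ("CS", "DASH", "additional_surgery")
ROB_LEVELS = ("low", "moderate", "high")


class SchemaError(ValueError):
    """Input violates the trial-arm schema (unknown code, bad column)."""


class DesignError(ValueError):
    """A trial's arms are structurally invalid (e.g. duplicate interventions)."""


class ValidationError(ValueError):
    """A record violates a numeric invariant (e.g. events > n)."""


class EmptyNetworkError(ValueError):
    """No trials available to build a network from."""


def validate_code(code: str) -> str:
    """Enforce the controlled vocabulary (applied at the file boundary)."""
    if code not in INTERVENTIONS:
        raise SchemaError(
            f"unknown intervention code {code!r}; expected one of {sorted(INTERVENTIONS)}"
        )
    return code


def _check_token(code: str) -> str:
    """Core types accept any well-formed token, so simulated networks may use
    abstract codes; vocabulary membership is checked by the loaders."""
    if not code or not code.replace("_", "").replace("-", "").isalnum():
        raise SchemaError(f"malformed intervention token {code!r}")
    return code


def apply_remap(code: str, remap: Mapping[str, str] | None) -> str:
    """Collapse a source code through the (functional) remapping table."""
    if remap is None:
        return code
    return validate_code(remap.get(code, code))


@dataclass(frozen=True)
class ComparisonKey:
    """Unordered pair of intervention codes; HA:NOP equals NOP:HA."""

    a: str
    b: str

    def __post_init__(self) -> None:
        _check_token(self.a)
        _check_token(self.b)
        if self.a == self.b:
            raise DesignError(f"comparison requires two distinct codes, got {self.a!r} twice")
        # canonical order so the pair hashes/compares orientation-free
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @classmethod
    def parse(cls, text: str) -> "ComparisonKey":
        """Parse 'HA:NOP' style notation."""
        left, _, right = text.partition(":")
        return cls(left.strip(), right.strip())

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)

    def __str__(self) -> str:
        return f"{self.a}:{self.b}"

    def __iter__(self):
        return iter((self.a, self.b))


@dataclass
class ArmRecord:
    """One randomized arm: the intervention, its size, and its outcome payload.

    Continuous outcomes carry ``mean``/``sd`` (score points); ``sd`` may be
    absent (the missing-SD case handled by :func:`nmaudit.effects.impute_sd`).
    Binary outcomes carry an ``events`` count. Exactly one payload kind per
    outcome.
    """

    intervention: str
    n: int
    mean: float | None = None
    sd: float | None = None
    events: int | None = None
    sd_imputed: bool = False

    def __post_init__(self) -> None:
        _check_token(self.intervention)
        if self.n < 1:
            raise ValidationError(f"arm n must be >= 1, got {self.n}")
        if self.events is not None:
            if self.mean is not None or self.sd is not None:
                raise ValidationError(
                    f"arm {self.intervention}: carries both event and mean payloads"
                )
            if not 0 <= self.events <= self.n:
                raise ValidationError(
                    f"arm {self.intervention}: events={self.events} outside [0, n={self.n}]"
                )
        if self.sd is not None:
            if self.mean is None:
                raise ValidationError(f"arm {self.intervention}: sd present without mean")
            if self.sd < 0:
                raise ValidationError(f"arm {self.intervention}: sd must be >= 0")

    @property
    def is_continuous(self) -> bool:
        return self.mean is not None

    @property
    def is_binary(self) -> bool:
        return self.events is not None


@dataclass
class TrialRecord:
    """One randomized trial: >= 2 arms with distinct interventions, plus
    trial-level effect-modifier data and registration metadata."""

    trial_id: str
    arms: list[ArmRecord]
    mean_age: float | None = None
    sd_age: float | None = None
    females: int | None = None
    total_n: int | None = None
    fracture_parts: str | None = None
    registered: bool = False
    outcome_discrepancy: bool = False
    rob: str = "high"
    outcome: str | None = None

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise DesignError(f"trial {self.trial_id}: needs >= 2 arms, has {len(self.arms)}")
        codes = [a.intervention for a in self.arms]
        if len(set(codes)) != len(codes):
            raise DesignError(
                f"trial {self.trial_id}: arms map to duplicate intervention codes {codes}; "
                "cannot form a within-trial contrast"
            )
        if self.total_n is None:
            self.total_n = sum(a.n for a in self.arms)
        if self.females is not None and self.females > self.total_n:
            raise ValidationError(
                f"trial {self.trial_id}: females={self.females} > total_n={self.total_n}"
            )
        if self.rob not in ROB_LEVELS:
            raise ValidationError(f"trial {self.trial_id}: rob={self.rob!r} not in {ROB_LEVELS}")

    @property
    def design(self) -> tuple[str, ...]:
        """The trial's design: its sorted set of intervention codes."""
        return tuple(sorted(a.intervention for a in self.arms))

    def comparisons(self) -> list[ComparisonKey]:
        """All arm-pair comparisons the trial informs."""
        codes = sorted(a.intervention for a in self.arms)
        return [
            ComparisonKey(codes[i], codes[j])
            for i in range(len(codes))
            for j in range(i + 1, len(codes))
        ]

    def arm(self, intervention: str) -> ArmRecord:
        for a in self.arms:
            if a.intervention == intervention:
                return a
        raise KeyError(f"trial {self.trial_id} has no {intervention} arm")


@dataclass
class NetworkSpec:
    """A set of trials bound to one outcome and a reference comparison."""

    trials: list[TrialRecord]
    outcome: str
    outcome_type: str
    reference_comparison: ComparisonKey
    label: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"outcome {self.outcome!r} not in {OUTCOMES}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValidationError("outcome_type must be 'continuous' or 'binary'")


# ---------------------------------------------------------------------------
# Readers / writers

CSV_COLUMNS = [
    "trial_id", "intervention", "n", "mean", "sd", "events",
    "mean_age", "sd_age", "females", "fracture_parts",
    "registered", "outcome_discrepancy", "rob", "outcome",
]


def _opt_float(cell: str) -> float | None:
    return float(cell) if cell.strip() else None


def _opt_int(cell: str) -> int | None:
    return int(float(cell)) if cell.strip() else None


def _bool(cell: str) -> bool:
    return cell.strip().lower() in ("1", "true", "yes", "y")


def load_trials(path: str | Path, remap: Mapping[str, str] | None = None) -> list[TrialRecord]:
    """Read trial records from a delimited trial-arm table (one row per arm).

    ``remap`` collapses intervention codes (e.g. ``{"LCP": "ORIF"}``) before
    validation; two arms of one trial collapsing to the same code is a
    :class:`DesignError` because the within-trial contrast vanishes.
    """
    rows_by_trial: dict[tuple[str, str], list[dict[str, str]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = {"trial_id", "intervention", "n"} - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"trial-arm file missing columns: {sorted(missing)}")
        for row in reader:
            # one record per (trial, outcome): a trial reporting several
            # outcomes appears once per outcome with its own arm payloads
            key = (row["trial_id"], (row.get("outcome") or "").strip())
            rows_by_trial.setdefault(key, []).append(row)

    trials = []
    for (trial_id, _outcome), rows in rows_by_trial.items():
        arms = [
            ArmRecord(
                intervention=apply_remap(validate_code(r["intervention"].strip()), remap),
                n=int(r["n"]),
                mean=_opt_float(r.get("mean", "") or ""),
                sd=_opt_float(r.get("sd", "") or ""),
                events=_opt_int(r.get("events", "") or ""),
            )
            for r in rows
        ]
        head = rows[0]
        trials.append(
            TrialRecord(
                trial_id=trial_id,
                arms=arms,
                mean_age=_opt_float(head.get("mean_age", "") or ""),
                sd_age=_opt_float(head.get("sd_age", "") or ""),
                females=_opt_int(head.get("females", "") or ""),
                fracture_parts=(head.get("fracture_parts") or "").strip() or None,
                registered=_bool(head.get("registered", "") or ""),
                outcome_discrepancy=_bool(head.get("outcome_discrepancy", "") or ""),
                rob=(head.get("rob") or "high").strip() or "high",
                outcome=(head.get("outcome") or "").strip() or None,
            )
        )
    return trials


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write trial records back to the trial-arm schema (round-trips load_trials)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for t in trials:
            for a in t.arms:
                writer.writerow([
                    t.trial_id, a.intervention, a.n,
                    "" if a.mean is None else repr(a.mean),
                    "" if a.sd is None else repr(a.sd),
                    "" if a.events is None else a.events,
                    "" if t.mean_age is None else repr(t.mean_age),
                    "" if t.sd_age is None else repr(t.sd_age),
                    "" if t.females is None else t.females,
                    t.fracture_parts or "",
                    "true" if t.registered else "false",
                    "true" if t.outcome_discrepancy else "false",
                    t.rob,
                    t.outcome or "",
                ])


def load_remap(path: str | Path) -> dict[str, str]:
    """Read a two-column source_code,target_code remap table."""
    remap: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("source_code", "source"):
                continue
            src, dst = row[0].strip(), row[1].strip()
            if src in remap and remap[src] != dst:
                raise SchemaError(f"remap maps {src!r} to both {remap[src]!r} and {dst!r}")
            remap[src] = validate_code(dst)
    return remap


# ---------------------------------------------------------------------------
# Graph construction

def build_network(trials: Sequence[TrialRecord]) -> nx.MultiGraph:
    """Build the evidence graph: nodes are interventions, one edge per trial
    per arm-pair (so edge multiplicity counts the trials informing a
    comparison, and an m-arm trial contributes C(m, 2) edges)."""
    if not trials:
        raise EmptyNetworkError("no trials to build a network from")
    g = nx.MultiGraph()
    for t in trials:
        for a in t.arms:
            g.add_node(a.intervention)
        for key in t.comparisons():
            g.add_edge(key.a, key.b, trial_id=t.trial_id, key_pair=key)
    return g


def edge_trials(graph: nx.MultiGraph) -> dict[ComparisonKey, list[str]]:
    """Trials informing each comparison (edge) of the network."""
    out: dict[ComparisonKey, list[str]] = {}
    for u, v, data in graph.edges(data=True):
        out.setdefault(ComparisonKey(u, v), []).append(data["trial_id"])
    return out


def has_closed_loop(graph: nx.MultiGraph) -> bool:
    """True iff the network contains a cycle through >= 3 distinct
    interventions, i.e. a loop along which direct and indirect evidence can
    disagree.  Parallel edges (independent trials on the same comparison) do
    not count: with only two treatments there is no indirect route.
    """
    simple = nx.Graph(graph)
    try:
        nx.find_cycle(simple)
        return True
    except nx.NetworkXNoCycle:
        return False


__all__ = [
    "INTERVENTIONS", "ORIF_REMAP", "OUTCOMES", "ROB_LEVELS",
    "SchemaError", "DesignError", "ValidationError", "EmptyNetworkError",
    "ComparisonKey", "ArmRecord", "TrialRecord", "NetworkSpec",
    "load_trials", "write_trials", "load_remap",
    "build_network", "edge_trials", "has_closed_loop",
    "apply_remap", "validate_code",
]
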