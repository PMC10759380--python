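"""Incoherence assessment: node-splitting and the global design-by-treatment
interaction test.

Separating Indirect from Direct Evidence (SIDE) removes a comparison's direct
trials from the network, refits, and z-tests the direct pooled estimate
against the indirect network estimate.  It needs both kinds of evidence, so
it is not applicable on loop-free networks — there the only recourse is the
global design-by-treatment interaction chi-square built from the Q
decomposition of the consistency fit.  Both tests have low power, so the
decision threshold defaults to p < 0.10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .datamodel import ComparisonKey
from .effects import Contrast, PooledEstimate, pool_pairwise
from .nma import ConnectivityError, NetworkFit, fit_network

DEFAULT_THRESHOLD = 0.10


class NotApplicableError(ValueError):
    """The requested test cannot be computed on this network topology."""


@dataclass(frozen=True)
class SideResult:
    pair: ComparisonKey
    direct: PooledEstimate
    indirect_estimate: float
    indirect_se: float
    difference: float
    z: float
    p: float
    flagged: bool


@dataclass(frozen=True)
class DesignByTreatmentResult:
    q: float
    df: int
    p: float | None
    flagged: bool

    @property
    def applicable(self) -> bool:
        return self.df > 0


@dataclass
class CoherenceReport:
    """Per-comparison SIDE results plus the global interaction test."""

    side: dict[ComparisonKey, SideResult | None]  # None = not applicable
    global_test: DesignByTreatmentResult
    threshold: float = DEFAULT_THRESHOLD

    @property
    def any_flag(self) -> bool:
        return self.global_test.flagged or any(
            r is not None and r.flagged for r in self.side.values()
        )

    def flagged_pairs(self) -> list[ComparisonKey]:
        return sorted(
            (p for p, r in self.side.items() if r is not None and r.flagged), key=str
        )


def _split_contrasts(
    contrasts: list[Contrast], pair: ComparisonKey
) -> tuple[list[Contrast], list[Contrast]]:
    """Partition into (direct, indirect-network) sets for node-splitting.

    A trial containing both interventions of the split pair — including any
    multi-arm trial — contributes to the direct side only and is removed from
    the indirect network entirely.
    """
    trial_pairs: dict[str, set[ComparisonKey]] = {}
    for c in contrasts:
        trial_pairs.setdefault(c.trial_id, set()).add(c.pair)
    direct_trials = {tid for tid, pairs in trial_pairs.items() if pair in pairs}
    direct = [c for c in contrasts if c.trial_id in direct_trials and c.pair == pair]
    indirect = [c for c in contrasts if c.trial_id not in direct_trials]
    return direct, indirect


def side_split(
    fit: NetworkFit,
    pair: ComparisonKey,
    threshold: float = DEFAULT_THRESHOLD,
) -> SideResult:
    """Node-splitting for one comparison: direct pooled vs indirect network
    estimate, compared by a two-sided z-test.

    Raises :class:`NotApplicableError` when the comparison has only direct or
    only indirect evidence (e.g. every edge of a loop-free network).
    """
    direct_cs, indirect_cs = _split_contrasts(fit.contrasts, pair)
    if not direct_cs:
        raise NotApplicableError(f"{pair}: no direct evidence; SIDE undefined")
    g = nx.Graph((c.pair.a, c.pair.b) for c in indirect_cs)
    if not (g.has_node(pair.a) and g.has_node(pair.b) and nx.has_path(g, pair.a, pair.b)):
        raise NotApplicableError(
            f"{pair}: no indirect path once direct evidence is removed; SIDE undefined"
        )
    direct = pool_pairwise(direct_cs, model=fit.model)
    # the indirect network only needs the component joining the split pair
    comp = nx.node_connected_component(g, pair.a)
    indirect_cs = [c for c in indirect_cs if c.pair.a in comp and c.pair.b in comp]
    sub = fit_network(indirect_cs, model=fit.model, outcome=fit.outcome)
    ind_est, ind_se = sub.estimate(pair.a, pair.b)
    diff = direct.estimate - ind_est
    z = diff / math.sqrt(direct.se**2 + ind_se**2)
    p = float(2 * stats.norm.sf(abs(z)))
    return SideResult(
        pair=pair, direct=direct, indirect_estimate=ind_est, indirect_se=ind_se,
        difference=diff, z=z, p=p, flagged=p < threshold,
    )


def design_by_treatment(
    fit: NetworkFit, threshold: float = DEFAULT_THRESHOLD
) -> DesignByTreatmentResult:
    """Global incoherence test: the between-design component of the
    consistency-model Q against chi-square with (designs - basic parameters)
    degrees of freedom.  Loop-free (tree) networks have df = 0 and the test
    is reported as not applicable."""
    df = fit.df_inconsistency
    if df <= 0:
        return DesignByTreatmentResult(q=fit.q_inconsistency, df=max(df, 0), p=None, flagged=False)
    p = float(stats.chi2.sf(fit.q_inconsistency, df))
    return DesignByTreatmentResult(q=fit.q_inconsistency, df=df, p=p, flagged=p < threshold)


def coherence_report(fit: NetworkFit, threshold: float = DEFAULT_THRESHOLD) -> CoherenceReport:
    """SIDE on every eligible comparison plus the global test; comparisons
    without both kinds of evidence are marked not applicable."""
    side: dict[ComparisonKey, SideResult | None] = {}
    for pair in fit.edges():
        try:
            side[pair] = side_split(fit, pair, threshold=threshold)
        except (NotApplicableError, ConnectivityError):
            side[pair] = None
    return CoherenceReport(
        side=side, global_test=design_by_treatment(fit, threshold), threshold=threshold
    )


__all__ = [
    "SideResult", "DesignByTreatmentResult", "CoherenceReport", "NotApplicableError",
    "side_split", "design_by_treatment", "coherence_report", "DEFAULT_THRESHOLD",
]
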