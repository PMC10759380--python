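"""Frequentist contrast-based network meta-analysis.

The estimator is weighted least squares on the edge-incidence design of the
evidence graph: every trial contributes its spanning set of contrasts against
a within-trial baseline arm, weighted by the inverse of the exact within-trial
covariance (the covariance between two contrasts sharing an arm equals that
arm's sampling variance, reconstructed from the trial's full pairwise SEs).
Under the consistency model the basic parameters are each intervention's
effect versus a reference node, and every relative effect is a difference of
basic parameters, so the consistency equations hold exactly by construction.

Heterogeneity is a single network tau^2 estimated by a method-of-moments
generalization of DerSimonian–Laird; the total Q of the consistency fit is
decomposed into a within-design (heterogeneity) part and a between-design
(inconsistency) part, the latter feeding the design-by-treatment interaction
test.  Per-comparison evidence flow is read off the hat matrix and decomposed
into source-to-sink streams to obtain the percentage contribution of each
trial to each network comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import ComparisonKey, ValidationError
from .effects import Contrast, PooledEstimate

Z975 = 1.959963984540054


class ConnectivityError(ValueError):
    """The evidence graph is disconnected for the requested outcome."""


class UnderdeterminedError(ValueError):
    """Fewer independent contrasts than basic parameters."""


@dataclass
class _TrialBlock:
    """One trial's spanning contrasts and their exact covariance."""

    trial_id: str
    baseline: str
    others: list[str]          # non-baseline arms, spanning contrast order
    y: np.ndarray              # estimates, other minus baseline
    cov: np.ndarray            # within-trial covariance of the spanning set
    edge_pairs: list[ComparisonKey]


def _build_blocks(contrasts: Sequence[Contrast]) -> list[_TrialBlock]:
    by_trial: dict[str, list[Contrast]] = {}
    for c in contrasts:
        by_trial.setdefault(c.trial_id, []).append(c)
    blocks = []
    for tid, cs in by_trial.items():
        nodes = sorted({code for c in cs for code in c.pair})
        m = len(nodes)
        if len(cs) != m * (m - 1) // 2:
            raise ValidationError(
                f"trial {tid}: expected the full set of {m*(m-1)//2} pairwise "
                f"contrasts over arms {nodes}, got {len(cs)}"
            )
        lookup = {c.pair: c for c in cs}
        baseline, others = nodes[0], nodes[1:]
        y = np.array([lookup[ComparisonKey(baseline, o)].oriented(baseline, o) for o in others])
        if m == 2:
            cov = np.array([[lookup[ComparisonKey(baseline, others[0])].se ** 2]])
        else:
            # solve v_a + v_b = se_ab^2 for the per-arm variances
            idx = {node: i for i, node in enumerate(nodes)}
            rows, rhs = [], []
            for c in cs:
                row = np.zeros(m)
                row[idx[c.pair.a]] = 1.0
                row[idx[c.pair.b]] = 1.0
                rows.append(row)
                rhs.append(c.se**2)
            v_arm, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
            v_arm = np.maximum(v_arm, 1e-12)
            cov = np.full((m - 1, m - 1), v_arm[0])
            for i, o in enumerate(others):
                cov[i, i] = v_arm[0] + v_arm[idx[o]]
        blocks.append(
            _TrialBlock(
                trial_id=tid, baseline=baseline, others=others, y=y, cov=cov,
                edge_pairs=[ComparisonKey(baseline, o) for o in others],
            )
        )
    return blocks


def _design_matrix(blocks: Sequence[_TrialBlock], nodes: list[str], reference: str) -> np.ndarray:
    cols = [n for n in nodes if n != reference]
    col_idx = {n: i for i, n in enumerate(cols)}
    rows = []
    for b in blocks:
        for o in b.others:
            row = np.zeros(len(cols))
            if o != reference:
                row[col_idx[o]] += 1.0
            if b.baseline != reference:
                row[col_idx[b.baseline]] -= 1.0
            rows.append(row)
    return np.vstack(rows)


def _block_diag(mats: Sequence[np.ndarray]) -> np.ndarray:
    n = sum(m.shape[0] for m in mats)
    out = np.zeros((n, n))
    i = 0
    for m in mats:
        k = m.shape[0]
        out[i : i + k, i : i + k] = m
        i += k
    return out


def _re_structure(blocks: Sequence[_TrialBlock]) -> np.ndarray:
    """Random-effects structure: tau^2 on the diagonal, tau^2/2 between
    contrasts of the same multi-arm trial (heterogeneity on every pairwise
    contrast of the trial, consistent across its arms)."""
    mats = []
    for b in blocks:
        k = len(b.others)
        mats.append((np.eye(k) + np.ones((k, k))) / 2.0 if k > 1 else np.eye(1))
    return _block_diag(mats)


@dataclass
class NetworkFit:
    """A fitted consistency model for one outcome network."""

    outcome: str
    model: str
    reference: str
    nodes: list[str]
    basic: dict[str, float]            # effect vs reference; reference -> 0
    vcov: pd.DataFrame                 # covariance of basic estimates (non-ref nodes)
    tau2: float
    i2: float
    q_total: float
    df_total: int
    q_heterogeneity: float
    df_heterogeneity: int
    q_inconsistency: float
    df_inconsistency: int
    contrasts: list[Contrast] = field(repr=False, default_factory=list)
    direct_proportion: dict[ComparisonKey, float] = field(default_factory=dict)
    _blocks: list[_TrialBlock] = field(repr=False, default_factory=list)
    _xtwx_pinv: np.ndarray | None = field(repr=False, default=None)
    _w: np.ndarray | None = field(repr=False, default=None)
    _x: np.ndarray | None = field(repr=False, default=None)

    def estimate(self, first: str, second: str) -> tuple[float, float]:
        """Network estimate and SE of ``second`` versus ``first``."""
        est = self.basic[second] - self.basic[first]
        var = 0.0
        cols = self.vcov.columns
        v = self.vcov.to_numpy()
        x = np.zeros(len(cols))
        if second != self.reference:
            x[cols.get_loc(second)] += 1.0
        if first != self.reference:
            x[cols.get_loc(first)] -= 1.0
        var = float(x @ v @ x)
        return est, math.sqrt(max(var, 0.0))

    def estimate_ci(self, first: str, second: str) -> tuple[float, float, float, float]:
        est, se = self.estimate(first, second)
        return est, se, est - Z975 * se, est + Z975 * se

    def prediction_interval(self, first: str, second: str) -> tuple[float, float]:
        """Approximate 95% prediction interval for a future trial's effect."""
        est, se = self.estimate(first, second)
        half = Z975 * math.sqrt(se**2 + self.tau2)
        return est - half, est + half

    def edges(self) -> list[ComparisonKey]:
        return sorted({c.pair for c in self.contrasts}, key=str)


def _graph_of(contrasts: Sequence[Contrast]) -> nx.Graph:
    g = nx.Graph()
    for c in contrasts:
        g.add_edge(c.pair.a, c.pair.b)
    return g


def fit_network(
    contrasts: Sequence[Contrast],
    model: str = "random",
    reference: str | None = None,
    outcome: str = "",
) -> NetworkFit:
    """Fit the consistency model to a set of within-trial contrasts.

    Multi-arm trials must supply their full pairwise contrast set (as
    :func:`nmaudit.effects.contrasts_from_trial` does); the spanning subset
    enters the fit with its exact covariance so correlated contrasts are not
    double-counted.  A single-edge network reduces exactly to inverse-variance
    pairwise pooling.
    """
    if model not in ("common", "random"):
        raise ValidationError(f"unknown model {model!r}")
    if not contrasts:
        raise ValidationError("no contrasts to fit")
    g = _graph_of(contrasts)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ConnectivityError(f"evidence graph is disconnected: components {comps}")
    nodes = sorted(g.nodes)
    reference = reference or nodes[0]
    if reference not in nodes:
        raise ValidationError(f"reference {reference!r} not in network nodes {nodes}")

    blocks = _build_blocks(contrasts)
    y = np.concatenate([b.y for b in blocks])
    V = _block_diag([b.cov for b in blocks])
    X = _design_matrix(blocks, nodes, reference)
    n_params = len(nodes) - 1
    if len(y) < n_params:
        raise UnderdeterminedError(
            f"{len(y)} independent contrasts cannot identify {n_params} basic parameters"
        )

    def _gls(Vmat: np.ndarray):
        W = np.linalg.inv(Vmat)
        xtwx = X.T @ W @ X
        xtwx_pinv = np.linalg.pinv(xtwx)
        theta = xtwx_pinv @ X.T @ W @ y
        resid = y - X @ theta
        q = float(resid @ W @ resid)
        return W, xtwx_pinv, theta, q

    W0, pinv0, theta0, q_total = _gls(V)
    df_total = len(y) - n_params

    # method-of-moments network tau^2 (common-effects weights)
    P = _re_structure(blocks)
    if df_total > 0:
        trace_wp = float(np.trace(W0 @ P))
        trace_corr = float(np.trace(pinv0 @ (X.T @ W0 @ P @ W0 @ X)))
        c_factor = trace_wp - trace_corr
        tau2 = max(0.0, (q_total - df_total) / c_factor) if c_factor > 0 else 0.0
    else:
        tau2 = 0.0
    i2 = max(0.0, 1.0 - df_total / q_total) if q_total > df_total > 0 else 0.0

    if model == "random" and tau2 > 0:
        W, xtwx_pinv, theta, _ = _gls(V + tau2 * P)
    else:
        W, xtwx_pinv, theta = W0, pinv0, theta0

    q_het, df_het = _q_heterogeneity(blocks)
    q_inc = max(0.0, q_total - q_het)
    df_inc = df_total - df_het

    cols = [n for n in nodes if n != reference]
    basic = {reference: 0.0}
    basic.update({n: float(t) for n, t in zip(cols, theta)})
    vcov = pd.DataFrame(xtwx_pinv, index=cols, columns=cols)

    fit = NetworkFit(
        outcome=outcome, model=model, reference=reference, nodes=nodes,
        basic=basic, vcov=vcov, tau2=float(tau2), i2=float(i2),
        q_total=q_total, df_total=df_total,
        q_heterogeneity=q_het, df_heterogeneity=df_het,
        q_inconsistency=q_inc, df_inconsistency=df_inc,
        contrasts=list(contrasts),
        _blocks=blocks, _xtwx_pinv=xtwx_pinv, _w=W, _x=X,
    )
    fit.direct_proportion = {
        pair: _edge_flows(fit, pair.a, pair.b).get(pair, 0.0) for pair in fit.edges()
    }
    return fit


def _q_heterogeneity(blocks: Sequence[_TrialBlock]) -> tuple[float, int]:
    """Within-design Q: residual heterogeneity after giving every design
    (treatment set) its own free effect vector."""
    by_design: dict[tuple, list[_TrialBlock]] = {}
    for b in blocks:
        key = tuple([b.baseline] + b.others)
        by_design.setdefault(key, []).append(b)
    q, df = 0.0, 0
    for design, members in by_design.items():
        if len(members) < 2:
            continue
        winvs = [np.linalg.inv(b.cov) for b in members]
        pooled_prec = sum(winvs)
        pooled = np.linalg.solve(pooled_prec, sum(wi @ b.y for wi, b in zip(winvs, members)))
        for wi, b in zip(winvs, members):
            r = b.y - pooled
            q += float(r @ wi @ r)
        df += (len(members) - 1) * (len(design) - 1)
    return q, df


# ---------------------------------------------------------------------------
# League table

def league_table(fit: NetworkFit) -> pd.DataFrame:
    """All ordered-pair network estimates with 95% CIs (anti-symmetric)."""
    rows = []
    for first, second in combinations(fit.nodes, 2):
        for a, b in ((first, second), (second, first)):
            est, se, lo, hi = fit.estimate_ci(a, b)
            rows.append({
                "first": a, "second": b, "estimate": est, "se": se,
                "ci_low": lo, "ci_high": hi,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evidence flow and per-trial contribution

def _hat_row(fit: NetworkFit, first: str, second: str) -> np.ndarray:
    """Row of the hat matrix mapping observed contrasts to the network
    estimate of second-vs-first."""
    cols = fit.vcov.columns
    x = np.zeros(len(cols))
    if second != fit.reference:
        x[cols.get_loc(second)] += 1.0
    if first != fit.reference:
        x[cols.get_loc(first)] -= 1.0
    return x @ fit._xtwx_pinv @ fit._x.T @ fit._w


def _edge_flows(fit: NetworkFit, first: str, second: str) -> dict[ComparisonKey, float]:
    """Aggregate the hat row into per-edge evidence flow magnitudes via the
    stream (path) decomposition of the unit first->second flow it defines."""
    h = _hat_row(fit, first, second)
    # net signed flow per oriented edge
    flow: dict[tuple[str, str], float] = {}
    i = 0
    for b in fit._blocks:
        for o in b.others:
            coef = h[i]
            i += 1
            key = (b.baseline, o)
            flow[key] = flow.get(key, 0.0) + coef
    dg = nx.DiGraph()
    for (u, v), f in flow.items():
        if abs(f) < 1e-12:
            continue
        a, b_ = (u, v) if f > 0 else (v, u)
        dg.add_edge(a, b_, flow=dg.get_edge_data(a, b_, {}).get("flow", 0.0) + abs(f))
    contrib: dict[ComparisonKey, float] = {}
    total = 0.0
    # peel off source-to-sink streams; each stream spreads its flow equally
    # over the edges it traverses
    while True:
        try:
            path = nx.shortest_path(dg, first, second)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            break
        edges = list(zip(path[:-1], path[1:]))
        phi = min(dg[u][v]["flow"] for u, v in edges)
        share = phi / len(edges)
        for u, v in edges:
            contrib[ComparisonKey(u, v)] = contrib.get(ComparisonKey(u, v), 0.0) + share
            dg[u][v]["flow"] -= phi
            if dg[u][v]["flow"] <= 1e-12:
                dg.remove_edge(u, v)
        total += phi
    if total > 0:
        contrib = {k: v / total for k, v in contrib.items()}
    return contrib


def comparison_contributions(fit: NetworkFit, pair: ComparisonKey) -> dict[str, float]:
    """Percentage contribution of each trial to one network comparison
    (direct or indirect).  The comparison's hat-matrix row is decomposed into
    evidence streams; each edge's share is then split over the trials on that
    edge proportionally to their inverse-variance weights.  Sums to 100."""
    trial_ids = sorted({c.trial_id for c in fit.contrasts})
    edge_weights: dict[ComparisonKey, dict[str, float]] = {}
    for c in fit.contrasts:
        d = edge_weights.setdefault(c.pair, {})
        d[c.trial_id] = d.get(c.trial_id, 0.0) + 1.0 / c.se**2
    flows = _edge_flows(fit, pair.a, pair.b)
    row = dict.fromkeys(trial_ids, 0.0)
    for edge, share in flows.items():
        weights = edge_weights.get(edge, {})
        wsum = sum(weights.values())
        for tid, w in weights.items():
            row[tid] += 100.0 * share * w / wsum
    total = sum(row.values())
    if total > 0:
        row = {k: 100.0 * v / total for k, v in row.items()}
    return row


def contribution_matrix(fit: NetworkFit) -> pd.DataFrame:
    """Percentage contribution of each trial (columns) to each network
    comparison (rows); rows sum to 100.  See
    :func:`comparison_contributions` for the decomposition."""
    trial_ids = sorted({c.trial_id for c in fit.contrasts})
    rows = {str(pair): comparison_contributions(fit, pair) for pair in fit.edges()}
    return pd.DataFrame.from_dict(rows, orient="index")[trial_ids]


__all__ = [
    "NetworkFit", "ConnectivityError", "UnderdeterminedError",
    "fit_network", "league_table", "contribution_matrix",
    "comparison_contributions",
]
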