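# Methods

This note documents the statistical model behind `nmaudit`, the conventions
chosen where the methodology literature leaves room, and what the synthetic
networks do and do not establish about real data.

## Estimation model

The engine fits the *consistency model* of a contrast-based network
meta-analysis. Every trial contributes its within-trial contrasts
(mean differences in score points for continuous outcomes; log odds ratios
for binary, with a 0.5 continuity correction added to all four cells of a
2×2 table iff any cell is zero). For an m-arm trial the full set of
C(m, 2) pairwise contrasts is formed, and the spanning subset against the
trial's baseline arm enters the fit with its exact covariance: the
covariance between two contrasts sharing an arm equals that arm's sampling
variance, reconstructed from the pairwise SEs by solving
v_a + v_b = se²_ab. This avoids both double counting and the approximate
"variance adjustment" heuristics sometimes used for multi-arm trials.

With y the stacked contrasts, X the edge-incidence design over basic
parameters (each intervention's effect versus a reference node), and V the
block-diagonal within-trial covariance, the estimator is generalized least
squares, θ̂ = (XᵀV⁻¹X)⁺ XᵀV⁻¹y, using the Moore–Penrose pseudoinverse.
Consistency relations (θ_AC = θ_AB + θ_BC) hold exactly by construction.
A single-edge network reduces algebraically to inverse-variance pairwise
pooling; the test suite verifies the general case against an exact-rational
symbolic GLS oracle.

### Heterogeneity

One network-level τ² is estimated by a method-of-moments generalization of
DerSimonian–Laird: with common-effects weights W, residual Q, and P the
random-effects structure (τ² on each contrast, τ²/2 between contrasts of one
multi-arm trial),

    τ̂² = max(0, (Q − df) / [tr(WP) − tr((XᵀWX)⁻ XᵀWPWX)]),

which collapses to the classical DL estimator on a single edge. The random
model refits with V + τ²P. I² = max(0, 1 − df/Q). A single τ² (rather than
per-comparison) is the standard choice and the only identifiable one in
sparse networks with 1–3 trials per edge.

### Q decomposition and the design-by-treatment test

Q_total from the consistency fit splits into a within-design part
(each design — the treatment set of a trial — given its own free effect) and
a between-design remainder: Q_total = Q_het + Q_inc, with
df_inc = Σ_designs (m_d − 1) − (n_nodes − 1). Q_inc against χ²(df_inc) is the
global design-by-treatment interaction test. Tree networks have df_inc = 0:
the test is reported *not applicable*, never "coherent".

### Node splitting (SIDE)

For a comparison with both kinds of evidence, the direct side pools its
trials by inverse variance; the indirect side refits the network with every
trial containing both split interventions removed (multi-arm trials count as
direct only — the dominant convention, which keeps the two sides
independent enough for the z-test). The indirect estimate comes from an
actual refit rather than algebraic subtraction; the two agree exactly in
single-loop networks (tested) and the refit remains exact in multi-loop
ones. Both tests use a 0.10 threshold by default, configurable; the low
power of these tests means a non-flag is never evidence *for* coherence.

### Evidence flow and contributions

The hat-matrix row of any comparison aggregates to a unit evidence flow from
one intervention to the other. The flow is decomposed into source-to-sink
streams (shortest paths peeled off in order), each stream spreading its flow
equally over the edges it traverses; each edge's share is then divided over
the trials on that edge proportionally to their inverse-variance weights and
normalized to percentages. Rows sum to 100 and a trial with no path to a
comparison contributes exactly 0. Other decompositions exist; this one is
recorded in the report provenance so downstream judgements are auditable.

## Transitivity rules

Pooled mean age per comparison is the participant-weighted combined mean
(Σnm/Σn); the pooled SD companion formula (within- plus between-group
components over N − 1) is available but typically unusable because trials
rarely report age SDs — which is exactly why the age rule is an absolute
cutoff rather than a t-test: |Δage vs reference| > 5 years flags
intransitivity (10 years in sensitivity mode). The female-proportion rule
requires both statistical evidence and magnitude: Fisher's exact p < 0.05
*and* an absolute difference > 0.20 (0.30 in sensitivity mode). The
two-sided Fisher p sums all tables no more probable than the observed one.
When a trial reports only a percentage, the count is reconstructed by
half-up rounding (Fisher needs integers). Qualitative modifiers (fracture
morphology, surgical indication, comorbidity) cannot be compared numerically
across heterogeneous classifications; they enter as analyst-supplied
structured flags. Per-trial intransitivity counts distinct flagged modifiers
on the trial's comparisons: 0 → low, 1 → moderate, ≥2 → high.

## Confidence rating

Six domains per comparison, each no/some/major concerns:

* **within-study bias, intransitivity** — contribution-weighted average of
  trial levels (low = 1, moderate = 2, high = 3) with thresholds 1.5/2.5.
  The rule itself is standard; the cut points are this package's choice and
  are exposed in configuration.
* **reporting bias** — any of four network-level indicators, any
  unregistered contributing trial, or any registered trial with
  planned-vs-reported outcome discrepancies triggers "some concerns" by
  default (the mapping is configurable).
* **imprecision** — the 95% CI against the equivalence range ±MCID
  (Constant score 5.4, DASH 8.1; binary outcomes collapse the range to the
  null since any risk increase is taken as relevant): 0 boundaries crossed →
  no concerns, 1 → some, 2 (or a null straddle for binary) → major.
* **heterogeneity** — the same comparison for the 95% prediction interval
  est ± 1.96√(se² + τ²), counting boundaries crossed *beyond* the CI.
* **incoherence** — SIDE where applicable (flag → major if the
  direct−indirect difference exceeds the MCID half-width, else some);
  otherwise the global test (flag → some); with no closed loop the domain is
  *not applicable* and excluded from the ladder.

The boundary-crossing codifications for imprecision and heterogeneity are
declared approximations of web-tool behaviour that is not published as an
algorithm; every judgement carries a rationale string for audit. Overall
grade: start high, −1 step per some-concerns domain, −2 per major, floored
at very-low; not-applicable domains never downgrade.

## Synthetic networks

The generator draws, per trial, a true contrast = consistency value +
per-design incoherence offset + N(0, τ²); continuous arms observe means with
SE sd/√n on a 0–100 score scale (within-arm SD 12 points by default, the
order of magnitude of shoulder-score SDs) and SDs via the χ² sampling
distribution; binary arms draw events binomially through a logit link on a
default baseline risk of 0.20. Trial-level modifiers come from
per-intervention models (default: mean age 75, SD 8, 85% female — elderly,
predominantly female fracture populations), so configured age/sex imbalance
between interventions propagates into the transitivity assessment exactly
the way real effect-modifier imbalance would. One global seed spawns a
substream per trial, so output is byte-identical for a fixed seed.

The published-shaped fixtures reproduce the *marginals* of the three audited
networks — topology, trials per edge, participant totals, pooled ages,
female percentages, including the historical trial whose continuous outcome
lacked an SD (dropping it breaks the only closed loop of one network) — but
their outcome payloads are synthetic. Passing tests therefore demonstrate
that the machinery reproduces the published transitivity table, flag sets,
and coherence applicability from matching inputs; they do not reproduce
published node-splitting p-values or downgrade percentages, which depend on
unpublished trial-level outcome data and are treated as external benchmarks
only.

## Problem sizes and numerical choices

Simulation studies use triangles (1 trial/edge, 50/arm) for incoherence
calibration — 1000 replicates for type-I error, 200 for power at an offset
of ten direct-contrast SEs — and 6-edge 4-node networks (2 trials/edge,
50/arm, τ = 0.5) over 500 replicates for CI coverage. These sizes give
binomial noise comfortably inside the asserted bands while keeping the whole
suite under a minute. GLS agreement with the symbolic oracle is asserted at
1e-8 (the oracle rationalizes floating-point inputs at denominator 10⁶);
flow decomposition clips residual flows below 1e-12 and renormalizes rows;
τ² estimates are truncated at 0; degenerate 2×2 tables (no events anywhere)
are rejected rather than corrected.

## Known limitations

* Effect measures are mean difference and (log) odds ratio; standardized
  mean differences and risk ratios are not implemented (a config hook exists
  for the binary measure).
* Back-calculating SDs from non-parametric p-values is deliberately
  unsupported; the mean-SD imputation sensitivity path is the only recovery
  route for missing SDs.
* The weighted-average thresholds and the imprecision/heterogeneity
  boundary rules are codifications of under-specified practice; conclusions
  that hinge on a judgement near a threshold deserve a sensitivity look.
* Bayesian estimation and ranking metrics (e.g. SUCRA) are out of scope:
  the audit chain is frequentist end to end.
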