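"""Simulate a coherent network with known truth and recover its parameters.

A 4-node network with between-trial heterogeneity (tau = 0.5 score points)
is generated and refitted; the printed table compares the random-effects
network estimates with the simulated truth.
"""

from nmaudit import (
    ComparisonKey, SimConfig, contrasts_from_trial, fit_network, generate_network,
)

truth = {"B": 2.0, "C": 5.0, "D": -3.0}
cfg = SimConfig(
    interventions=["A", "B", "C", "D"],
    true_effects=dict(truth),
    edges=[(ComparisonKey(a, b), 2, 100) for a, b in
           [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]],
    tau=0.5,
    seed=123,
)
trials, sim_truth = generate_network(cfg)
contrasts = [c for t in trials for c in contrasts_from_trial(t, "continuous")]
fit = fit_network(contrasts, model="random", reference="A")

print(f"network tau^2 = {fit.tau2:.3f} (simulated tau = {cfg.tau})")
print("node   truth   estimate   95% CI")
for node, true_val in truth.items():
    est, se, lo, hi = fit.estimate_ci("A", node)
    print(f"  {node}   {true_val:+.1f}    {est:+.2f}    [{lo:+.2f}, {hi:+.2f}]")
print("\nEach interval should usually cover its truth column; across many")
print("seeds the coverage sits near the nominal 95%.")
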