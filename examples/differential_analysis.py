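"""Differential analysis with permutation contrast scores + GZ cutoff.

With 2 experimental and 1 background replicates, each feature's three
pooled values admit three ways to assign two of them to a
pseudo-experimental group; the two non-identity assignments act as the
feature's own negative controls. The max contrast score is positive only
when the real assignment shows the strongest absolute mean difference, and
the GZ cutoff (1/h correction, h=2 here) bounds the FDR.
"""

from contrastfdr import SimulationConfig, evaluate_fdp_power, generate_dataset, run_analysis

config = SimulationConfig(d=2000, design=(2, 1), family="poisson",
                          background="heterogeneous", mode="differential",
                          pi1=0.1, effect=3.0, seed=7)
pair, truth = generate_dataset(config)

result = run_analysis(pair, mode="differential", q=0.1)
fdp, power = evaluate_fdp_power(result.discoveries, truth)

print(f"route: {result.config.score} contrast score + {result.config.procedure} "
      f"cutoff with h = {result.plan.h} permutation classes")
print(f"cutoff: {result.cutoff:.4f}; discoveries: {result.result.n_discoveries}")
print(f"realized FDP: {fdp:.4f} (target q = 0.1); power: {power:.3f}")
# Differential analysis detects changes in either direction; with so few
# replicates p-value-based tests are uncalibrated, but the permutation
# contrast scores retain finite-sample FDR control.
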