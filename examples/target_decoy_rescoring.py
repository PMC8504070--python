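"""Target-decoy rescoring of per-feature q-values (proteomics-style).

Each feature (e.g. a mass spectrum) carries a q-value for its best target
match and one for its best decoy match. The -log10 q-value pair forms a
1vs1 enrichment problem: decoys act as per-feature negative controls, and
the BC cutoff turns the score gap into an FDR-controlled discovery list.
"""

import numpy as np

from contrastfdr import rescore_paired_qvalues

rng = np.random.default_rng(3)
d = 500
decoy_q = rng.uniform(0.005, 1.0, size=d)  # decoys: noise matches
target_q = rng.uniform(0.005, 1.0, size=d)
true_ids = np.arange(150)
target_q[true_ids] = rng.uniform(1e-6, 0.01, size=true_ids.size)  # real peptides

result = rescore_paired_qvalues(target_q, decoy_q, q=0.05)
false = np.setdiff1d(result.discoveries, true_ids)

print(f"cutoff on -log10 q-value difference: {result.cutoff:.3f}")
print(f"discoveries: {result.result.n_discoveries} of {d} spectra")
print(f"false discoveries among them: {false.size} "
      f"(realized FDP {false.size / max(result.result.n_discoveries, 1):.4f}, target 0.05)")
# 150 spectra carry genuine identifications; the rescoring recovers most of
# them while keeping the realized false discovery proportion near the target.
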