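"""Reproducibility R, Jaccard, and precision/recall/F between call sets.

R = 1/2 (n_a/N_a + n_b/N_b) averages the fraction of each set found in the
other; restricting both sets to the HRR gives the upper bound of
reproducibility, unrestricted calls the lower bound.
"""

from hrrforge.metrics import (
    avg_jaccard,
    depth_filter,
    jaccard,
    precision_recall_f,
    reproducibility,
)
from hrrforge.model import match_callsets
from hrrforge.simulate import SimulationConfig, simulate_study

config = SimulationConfig(
    genome=(("chr1", 200_000),),
    n_sites=500,
    labs=("lab1",),
    aligners=("alnA",),
    callers=("c1", "c2"),
    caller_fn=(0.03, 0.08),
    aligner_fn=(0.0,),
    seed=9,
)
data = simulate_study(config)
sample = config.samples[0]
sets = [cs for cs in data.callsets if cs.sample == sample]

# technical replicates of the same pipeline, depth-filtered at DP >= 8
reps = [depth_filter(cs, min_dp=8, max_dp="auto")
        for cs in sets if cs.labels.caller == "c1"]
a, b, c = reps[:3]
m = match_callsets(a, b)
print(f"replicates r1 vs r2: N_a={m.counts.N_a} N_b={m.counts.N_b} "
      f"n_a={m.counts.n_a}")
print(f"  technical R      : {reproducibility(m.counts):.4f}")
print(f"  pairwise Jaccard : {jaccard(a, b):.4f}")
print(f"  average Jaccard over the triplicate: {avg_jaccard(a, b, c):.4f}")

# a noisier caller benchmarked against the cleaner one as a stand-in truth
noisy = next(cs for cs in sets if cs.labels.caller == "c2")
p, r, f = precision_recall_f(match_callsets(noisy, a).counts)
print(f"caller c2 vs c1  : precision={p:.4f} recall={r:.4f} F={f:.4f}")
# Jaccard <= R always; the gap widens as the two sets diverge.
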