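"""Per-dataset length summaries and the accompanying hypothesis tests.

Draws synthetic callsets from the built-in profiles (each anchored at a
published five-number length summary), prints their six-number summaries,
and demonstrates the exact statistics: a rank-sum comparison of two length
samples and a binomial test of an inheritance-mode proportion against a
background.
"""

import numpy as np

from invkit import binomial_test, length_summary, wilcoxon_rank_sum
from invkit.simulate import BUILTIN_PROFILES, builtin_profile, make_callset, make_genome

genome = make_genome(2, 250_000_000, seed=0)
print(f"{'dataset':10s} {'n':>6s} {'q1_kb':>8s} {'median':>8s} {'mean':>9s} {'q3_kb':>8s}")
samples = {}
for name in BUILTIN_PROFILES:
    cs, _ = make_callset(builtin_profile(name, n_calls=2000), seed=42, genome=genome)
    s = length_summary(cs)
    samples[name] = [c.length / 1000 for c in cs.calls]
    print(f"{name:10s} {s.n:6d} {s.q1:8.3f} {s.median:8.2f} {s.mean:9.1f} {s.q3:8.2f}")

res = wilcoxon_rank_sum(samples["onekgp"][:500], samples["ebert"][:400])
print(
    f"\nRank-sum test, short-read-like vs long-read-like lengths: "
    f"W = {res.statistic:.0f}, p = {res.p_value:.3g} ({res.method})"
)

# 52 AR genes among 120 phenotype-linked genes hit, background AR share 40%
res = binomial_test(52, 120, 0.40)
print(
    f"Binomial test of 52/120 AR genes vs a 40% background: p = {res.p_value:.3f}"
)
print(
    "\nThe heavy right tails (means far above medians) mirror the published"
    "\ncallsets; the rank-sum p-value shows the short-read-like profile calls"
    "\nsystematically smaller events than the assembly-based one."
)
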