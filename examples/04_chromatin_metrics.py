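"""Measure chromatin features around binding-site anchors: NFR width from
flanking nucleosome maxima, MNase footprint protection, and the Pol II
roadblock index, then compare groups statistically."""

import numpy as np

from divorseq import aggregate_profile, group_compare, nfr_width
from divorseq.chromatin import Anchor, mnase_protection_ratio, roadblock_index
from divorseq.simulate import simulate_profiles

rng = np.random.default_rng(1)
n = 12
anchors = [Anchor("chrS", 2000 + 3000 * i, "+-"[i % 2]) for i in range(n)]
# first half emulates long-residence sites (wide NFR, strong protection,
# roadblock), second half short-residence sites
half = n // 2
sim = simulate_profiles(
    anchors,
    nfr_half_widths=[154] * half + [136] * half,
    roadblock_indices=[3.0] * half + [1.2] * half,
    protection_depths=list(rng.uniform(2.5, 3.5, half))
    + list(rng.uniform(1.1, 1.5, half)),
    seed=1,
)

long_prof = aggregate_profile(sim.occupancy, anchors[:half], flank=500)
short_prof = aggregate_profile(sim.occupancy, anchors[half:], flank=500)
print(f"NFR width, long-residence group : {nfr_width(long_prof)} bp")
print(f"NFR width, short-residence group: {nfr_width(short_prof)} bp")

ratios = [
    mnase_protection_ratio(sim.mnase_before, sim.mnase_after, a) for a in anchors
]
groups = ["long"] * half + ["short"] * half
test = group_compare(ratios, groups, test="wilcoxon")
print(f"protection ratios (long) : {np.round(ratios[:half], 2)}")
print(f"protection ratios (short): {np.round(ratios[half:], 2)}")
print(f"wilcoxon rank-sum p      : {test.p_value:.4g}")

calls = [roadblock_index(sim.polII, a).is_roadblock for a in anchors]
print(f"roadblock calls (index > 2): {sum(calls)}/{n} sites")
# Wider NFRs, deeper MNase protection and roadblock behaviour all mark
# the group built to mimic stably bound (long-residence) sites.
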