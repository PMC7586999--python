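"""Fit the exponential decay model to one site's depletion time course.

Simulates a binding site with a known off-rate at experiment-like depth
(three replicates, Poisson counting noise), fits the model and prints the
estimates next to the truth.
"""

from divorseq import fit_decay, round_sig
from divorseq.simulate import NoiseModel, simulate_timecourse

KOFF_TRUE = 0.12   # 1/min -> mean residence time 1/0.12 = 8.3 min
Y0_TRUE = 800.0    # normalized binding before depletion
YF_TRUE = 80.0     # plateau the site decays to

tc = simulate_timecourse(
    "demo_site", KOFF_TRUE, Y0_TRUE, YF_TRUE,
    noise=NoiseModel(kind="poisson", seed=1),
)
fit = fit_decay(tc)

print(f"true k_off        : {KOFF_TRUE:.3f} /min")
print(f"fitted k_off      : {fit.koff:.3f} /min")
print(f"mean residence    : {round_sig(fit.residence_time_min, 2)} min (1 / k_off)")
print(f"y0 -> yf          : {fit.y0:.0f} -> {fit.yf:.0f} (normalized binding)")
print(f"pseudo-R^2        : {fit.r2:.3f}")
# The fitted rate should sit within a few percent of the truth; the
# pseudo-R^2 says how much of the binding decrease the model explains.
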