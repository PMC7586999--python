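# Methods

This note documents the models, conventions and numerical choices behind
`divorseq`, the assumptions they carry, and what the synthetic-data tests
do and do not demonstrate about real data.

## Decay model and fitting

Binding at each site after nuclear depletion is modelled as first-order
dissociation to a site-specific floor:

    y(t) = y_f + (y_0 − y_f) · exp(−k_off · t)

- `y_0` (normalized binding units): level before depletion (t = 0).
- `y_f` (same units): asymptotic level. A shared or zero floor would bias
  rates because sites decay to different backgrounds; `y_f` is therefore
  free per site. Negative fitted `y_f` is allowed (normalized signal is
  nonnegative, so a negative floor flags an extrapolation artefact rather
  than being clipped — clipping would bias `k_off` upward).
- `k_off` (min⁻¹): the off-rate; mean residence time is `1/k_off`,
  half-life `ln 2 / k_off`.

The loss is the sum of squared residuals over **all replicate
observations jointly** (no pre-averaging): one fit per site, replicates
weighting the fit by their scatter. The rate is parameterized as
`log k_off` so positivity is structural, and optimization uses
Levenberg–Marquardt (`scipy.optimize.least_squares`). Self-start values:
`y_f` from the smallest time-point mean (floored at 0), `y_0` from the
t = 0 mean, and `log k_off` from the slope of a log-linear regression of
the floor-subtracted means on time (90 % of the floor is subtracted so
exact-model data keeps a positive log argument). Because the SSE surface
can hold a fast-rate local optimum when the decay amplitude is small, the
fit restarts from the self-start rate shifted by −3, −1.5 and +1.5 log
units and keeps the lowest SSE. Non-convergence (or non-finite
parameters) marks the fit `converged = False`; such sites are excluded
from quartile assignment by the pipeline.

Goodness of fit is a pseudo-R², `1 − SS_res / SS_tot`, computed by
default on the same observations that entered the loss; a switch
(`r2_on="means"`) computes it on time-point means instead, which removes
replicate scatter from SS_tot and is therefore systematically higher.
The default keeps R² consistent with the quantity being minimized.

The default sampling grid is 0, 2.5, 5, 7.5, 10, 15, 20, 30, 45, 60,
90 min — eleven points across a 90-minute depletion, denser early where
fast sites (residence times of a few minutes) carry their information.
Only the count and span are anchored to the experimental design; the grid
is configurable everywhere.

Residence-time quartiles sort converged fits by residence time
descending and split them into four groups, larger groups first (191
sites give 48/48/48/47); boundary ties break on site id so assignment is
deterministic. Confidence intervals on `k_off` (profile likelihood,
bootstrap) are deliberately out of scope.

## Quantification and normalization

Each paired-end fragment contributes a weight-1 boxcar of 101 bp centred
on its midpoint, so coverage at a base counts fragment midpoints within
±50 bp. Tracks are scaled to a common depth (default 10⁶ fragments),
then site binding is the summed coverage over summit ± 50 bp (101 bases,
clipped at chromosome ends).

Comparability across the time course comes from background
normalization: during depletion the in-peak fraction of the library
shrinks, so per-peak sums are divided by each sample's background read
fraction — reads whose fragment midpoints fall outside **every** called
peak (the full unfiltered set, not the filtered one), divided by total
reads. Midpoint containment is used because it matches the coverage
construction; the fraction is computed from deduplicated fragment
counts. This equalizes background levels between samples while
preserving within-sample ratios exactly.

Replicate outliers are flagged by a per-time-point MAD rule: a sample
whose median absolute deviation around the per-peak cross-replicate
median is strictly more than 6× the median MAD of the other replicates
at that time point is excluded from all fitting. The threshold mirrors
the magnitude of deviation that motivated discarding a sample in the
original experiments; single-replicate time points are skipped with a
warning since the comparison is undefined.

## Motif scanning and site selection

PFM columns are normalized to frequencies and multiplied by 1000 to give
additive column scores (matchPWM-style; no log-odds, no background
model). A window matches when its score reaches ≥ 85 % of the maximum
attainable score; both strands are scanned, minus-strand windows scored
on the reverse complement. `N` bases score the column minimum
(worst-case), so N-containing windows rarely pass.

The motif **midpoint** of a length-L motif is position `L // 2` in motif
orientation (0-based; for even L, the base just 3′ of centre) — stated
explicitly because every downstream offset (−8 bp cross-linking base,
−37 bp roadblock window) hangs off it. The −8 position is 8 bp 5′ of the
midpoint on the motif strand; for minus-strand matches that is genomic
midpoint + 8, complemented. An `N` at −8 fails the G/C test because
cross-linkability cannot be asserted.

Filters: fold enrichment ≥ 4; ≥ 1 motif match with its midpoint within
summit ± 100 bp (the bound applies to the midpoint, not the motif span);
**every** match at the peak must carry G/C at −8 (one bad motif drops
the peak, since cross-linking any motif with A/T at −8 is inefficient);
summit outside user-supplied telomere intervals (no numeric telomere
definition is imposed; default none). Membership of the final set is
order-independent — each filter is a pure predicate — while drop-reason
bookkeeping charges each peak to the first failing filter in the order
FE → motif → −8 → telomere.

The per-position enrichment test between quartile base compositions
(e.g. thymine at −1) is a two-sided Fisher exact test on the 2×2 base ×
group table; the test choice is this package's default for small count
tables and is noted in the function's docstring.

## Chromatin metrics

All profiles share one convention: anchors are best motif matches,
offsets are motif-oriented (negative = 5′ of the midpoint on the motif
strand). Minus-strand anchors reverse their windows, and stranded Pol II
pairs additionally swap plus/minus sub-tracks before reversal, so
"sense" is always the motif direction.

- **MNase protection ratio**: mean per-base cut density over the
  footprint [−8, +8] (17 bases) after depletion over before; > 1 means
  the factor shielded its footprint. Sites with zero cuts in either
  condition are excluded (ratio undefined).
- **NFR width**: distance between the −1 and +1 nucleosome midpoints.
  When external dyad annotations are supplied they take precedence;
  otherwise the occupancy profile is smoothed with a 31 bp centred
  moving average and the −1 (+1) nucleosome is the local maximum nearest
  the anchor at offset < −30 (> +30) with prominence ≥ 10 % of the
  profile maximum. The smoothing width, exclusion zone and prominence
  are package choices (config keys), tuned for ~147 bp nucleosome bumps;
  published analyses typically read dyads from an annotation, hence the
  precedence rule.
- **Roadblock index**: mean sense-strand Pol II over the closed window
  [−42, −32] ("−37 ± 5 bp") divided by the mean over [−300, −100]
  (incoming transcription). A site is a roadblock when the index is
  strictly > 2. Zero upstream signal leaves the index undefined and the
  site excluded with a reason.
- Profiles store per-offset SEM; plotting conventions differ on whether
  bands show ±1 or ±2 SEM, so renderers take a multiplier (default 1).

Group comparisons: one-way ANOVA with Tukey-HSD-adjusted pairwise
contrasts (statsmodels), two-tailed t-test, or Wilcoxon rank-sum
(Mann–Whitney U, exact for small tie-free samples).

## Transcription dynamics

Nascent-transcript counts are normalized by median-of-totals after
removing rRNA genes (totals computed post-filter, following the order of
operations in the normalization's definition). Differential-expression
results are **consumed, not computed** — a negative-binomial model on raw
counts belongs upstream; a fallback (per-gene two-sided t-test on log
counts vs t = 0 with Benjamini–Hochberg adjustment) exists only so
synthetic end-to-end runs are self-contained and is labelled
non-equivalent. A gene is depletion-responsive when |fold change| > 1.5
with adjusted p < 0.01 at **both** 20 and 30 min (strict inequalities);
response strength at 20 min sub-labels genes (> 2× strong, 1.5–2× weak).
Sites link to genes when the summit lies in the 500 bp promoter upstream
of the TSS (TSS excluded; nearest summit wins). Synthesis decay uses the
identical model and fitter as binding; genes without a reliable fit are
reported as unfittable rather than forced.

## Synthetic data: what it emulates and what it does not

The generators define the conditions under which the method is tested:
off-rates uniform on 0.030–0.24 min⁻¹ (the observed range), initial
binding 300–1500 normalized units with floors at 5–15 % of `y_0`,
three replicates, Poisson counting noise (fragment counting is a
counting process; a mean-preserving log-normal option emulates
replicate-level variability), and uniform background fragments (default
0.3 per bp). Site categories are planted to fail each filter — weak
enrichment, no motif, A/T at −8, telomeric — and flanking sequence is
re-randomized until each peak region contains exactly its planted
matches, so filter outcomes are forced by construction. Chromatin tracks
are built geometrically: Gaussian nucleosome bumps at ± the NFR
half-width (σ = 45 bp), uniform MNase cut density with the footprint
divided by the protection depth, and a rectangular Pol II stall component
sized so the roadblock index equals its target exactly.

Passing tests on these inputs demonstrate that the estimators invert the
generative model they were designed for — correct coordinate arithmetic,
unbiased rate recovery at realistic depth, exact metric round trips. They
do **not** demonstrate robustness to features real data has and the
generator lacks: non-uniform and structured background, copy-number and
mappability artefacts, crosslinking efficiency differences between
sites, overlapping peaks, nucleosome phasing heterogeneity, or
depletion kinetics that are not instantaneous. Real-scale headline
numbers (a 948-peak cascade, hundreds of fitted sites from deposited
sequencing runs) require the published datasets and are documented as an
optional full-data mode, not part of the test suite.

## Problem sizes and determinism

The shipped tests and the acceptance script run entirely on synthetic
data at deliberately modest sizes — 200 sites for noisy-recovery checks,
30 sites through the fragment-level pipeline, 60³ grids for the
fit-vs-grid oracle — sizes at which every check is exact or tightly
bounded while the whole suite runs in well under a minute of compute per
module. All randomness flows through seeded `numpy` generators; rerunning
any generator or pipeline with the same seed is bit-identical.
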