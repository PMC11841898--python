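# Methods

`msatcall` re-implements, headlessly, the computational engine of a
capillary-electrophoresis microsatellite genotyper: ABIF/FSA parsing,
peak delineation, crosstalk flagging, DNA-ladder sizing with a quality
score, bin management with inter-run offset correction, and
stutter/adenylation-aware allele calling. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Chromatogram model and peak delineation

A chromatogram is 4 or 5 integer fluorescence traces sampled per scan,
plus run metadata. Peaks are delineated on the raw trace — no smoothing
is applied — by a two-part criterion: an apex must clear an absolute
fluorescence level (`peak.min_height`, default 20 units) *and* exceed
both flanking minima by at least `peak.min_prominence_ratio` (default
0.5) times its own level. Peak bounds are the flanking minima; plateau
apexes resolve to the plateau midpoint.

When whole chromatograms are processed (`detect_all_channels`), the
absolute threshold for each channel is raised to the channel's noise
ceiling, estimated robustly as median + 8·σ with σ from the median
absolute deviation. Background in fragment-analysis data is a roughly
constant baseline plus sensor noise; the median/MAD pair captures both
while ignoring the sparse peaks. Without this, any non-zero baseline
floods detection with noise bumps that then poison the median-height
ladder filter.

Baseline subtraction interpolates linearly between each peak's start and
end anchor points and is zero between peaks, so both anchors land at
level zero. Two modes: *relative-elevation* subtracts the local baseline
(apex keeps its elevation); *absolute-height* additionally rescales the
in-peak signal so the apex keeps its original value. Signals with no
detectable peaks are returned unchanged; negative outputs clamp to 0.

Crosstalk (spectral pull-up) is flagged, never subtracted. A peak is
flagged when a co-located peak on another channel (apexes within
`crosstalk.apex_tolerance` = 3 scans) dominates it in intensity
(height ratio ≤ `crosstalk.height_ratio_max` = 0.2), their windows
correlate in shape (Pearson r ≥ `crosstalk.shape_similarity_min` = 0.9),
and the candidate source is the most intense peak at that position. A
saturated source is ranked by the width of its clipped region, since its
height no longer reflects DNA quantity. The tallest co-located peak is
never flagged; flagged peaks are excluded from ladder assignment and
allele calling but remain available for manual assignment.

## Ladder assignment

Fragment mobility is a smooth, monotone, non-linear function of length,
so the local slope Δscan/Δsize between consecutive ladder fragments
varies slowly. The matcher maximises, over all monotone peak↔size
matchings,

    B·k − Σ |log slope(i,i+1) − log slope(i−1,i)|

a bonus B per matched fragment (default 0.5) minus the total variation
of the log-slope along the matching. Spurious peaks and missing
fragments break the slope progression and stay unassigned. Because the
penalty couples only adjacent matching edges, a dynamic program over
edges (consecutive matched pairs) finds the exact optimum; it is
vectorised per middle pair and runs in milliseconds at ladder scale
(≤ ~20 peaks, ≤ ~40 sizes). Matchings must be strictly increasing in
scan and in size; co-eluting peaks cannot both be ladder fragments.

Before matching, crosstalk-flagged peaks are dropped and peaks of
unusual height removed (outside [0.1, 10] × median height): ladder
fragments are loaded at comparable molarity, so a far-off height is an
artifact.

A refinement pass then fits the sizing polynomial to the matched pairs
and re-matches peaks to sizes within a ±2 bp residual window
(alignment DP: maximise matches, tie-break on total deviation). The
window can orphan correct matches at the extremes of strongly curved
mobility maps, where polynomial lack-of-fit is largest, so any original
match whose peak and size both remain free is restored when it keeps the
matching monotone.

## Sizing fit and quality score

Sizing is ordinary least squares: standard size as response, apex scan
as explanatory variable, polynomial degree 1–3. The normal equations are
solved by Cholesky decomposition after centring and scaling scans to
[−1, 1] — degree-3 normal equations on raw scan numbers (~10⁴) are
hopelessly ill-conditioned — and coefficients are reported in raw scan
units. Fewer than degree+1 points or duplicate scans are errors.

Sizing quality in [0, 1]:

    score = max(0, 1 − max(ΔR²/ΔS) · 10/3 − (n_s − n_p)/10)

where ΔR and ΔS are the residual and scan differences of adjacent
assigned peaks, n_s the number of sizes in the standard and n_p the
number assigned. A single mis-assignment produces a residual jump that
drives the first term, usually to zero; unassigned sizes are penalised
mildly (they reflect electrophoresis problems the software cannot fix).
Fits with fewer than two assignments score 0, as the adjacent-pair term
is undefined and such a ladder is unusable.

The GeneScan-brand ladders (350, 400HD, 500, 600) ship as built-ins;
custom standards load and save as 2-column text.

## Bins and the offset correction

Markers carry a dye channel, ploidy (1 or 2), repeat-motif length and an
allele size range; bins are disjoint bp intervals naming expected allele
sizes. Automatic bin sets place bins of a given width at
anchor + k·spacing for every k whose *centre* lies in the marker range —
edge bins may overhang by half their width, matching the convention that
a 1-bp bin centred on the boundary is legitimate. Names are the centre
rounded to the nearest integer, ties half-up.

Estimated sizes drift slightly between sequencer runs. Instead of moving
bins, estimated sizes are corrected by y = a + b·x. Moving the bin-set
range [s, e] to [s′, e′] determines the parameters exactly:
b = (e′−s′)/(e−s), a = s′ − s·b. Identity is (a=0, b=1); the correction
is monotone for b > 0 and attaches to (sample set, marker) pairs. With
no GUI, the move is expressed numerically (`--bin-shift`, `--bin-scale`,
or the four boundary values).

## Allele calling

Stutter (slippage products at whole-repeat offsets, decaying in height)
and partial adenylation (+A products splitting an allele into two peaks
1 bp apart) multiply the peaks of one allele. In-range, non-crosstalk
peaks are grouped by seeded absorption in decreasing intensity order:
each unassigned peak seeds a cluster and transitively absorbs

* shorter peaks at ≈ k·motif (within `calling.stutter_tol` = 0.5 bp)
  whose height is below 0.5× the absorbing member's — real stutter
  rarely exceeds ~30% per step, while the two alleles of a heterozygote
  also sit whole repeats apart but are near-balanced, and must not
  merge;
* peaks within `calling.adenylation_tol` = 0.5 bp of 1 bp on either
  side, not taller than the member.

A purely distance-based transitive closure was rejected: it merges every
heterozygote whose alleles differ by whole repeat units, i.e. almost all
of them. The height conditions encode the biology of the two processes.

The most intense member of each cluster is the allele; intensity is apex
height, except that saturated peaks outrank all unsaturated ones and
order among themselves by clipped width. Ties go to the longer fragment
(full adenylation is the +1 product). The most intense cluster always
yields an allele — peak-quality assessment is left to the user. For
diploid markers a second cluster becomes the second allele when its
relative height is ≥ `calling.het_min_ratio` = 0.25; otherwise, and for
all further clusters, principals at ≥ `calling.secondary_ratio` = 0.2 of
the weakest allele are kept as additional fragments (optional,
`calling.detect_additional`) and the rest discarded. Allele count never
exceeds ploidy; one detected allele at a diploid marker is reported
homozygous (duplicated on export). Alleles are named after the
containing bin, else "?". Genuinely 1-bp-apart alleles merged as an
adenylation pair are re-examined by a batch cross-check: when other
genotypes in the same batch carry x and x+1 as distinct alleles and the
merged pair is near-balanced (ratio ≥ 0.7), the cluster is split and the
genotype re-called. Heterozygotes with > 60 bp allele spread receive no
special handling beyond a logged warning when a large additional
fragment sits that far above the called allele.

For ratio thresholds a saturated peak always passes as numerator and
contributes its clipped height as denominator; clipped heights are lower
bounds, so this errs toward keeping the weaker peak.

## Synthetic data generator

The generator emulates exactly the phenomena above: Gaussian peaks
(σ = 4 scans) placed by a monotone cubic size→scan mobility map
(default ≈ 18 scans/bp, giving realistic 1-bp resolution), ladder peaks
at the standard's sizes (800 units), allele peaks with stutter series
(0.3 per step, 3 steps) and adenylation splits (60% +A; the allele's
nominal size is the fully adenylated product), cross-channel bleed (5%),
constant baseline (30 units), Gaussian noise (σ = 10), and clipping at a
saturation limit with flat tops. Random mobility maps integrate a
positive random quadratic derivative, so they are monotone by
construction. Between-run drift is affine in size space, matching the
correction model. Heterozygote heights share a per-locus amplification
base with a per-allele balance factor in [0.7, 1.0] — real het peaks are
near-balanced, and independent heights would make a minor allele
indistinguishable from strong stutter. Alleles are drawn on the motif
grid with a motif-length margin inside the marker range so the +A
product of a boundary allele stays in range. Everything is a
deterministic function of the seed.

A peak-level variant (`random_genotype_peaks`) skips trace synthesis and
emits already-sized peaks (with spurious, crosstalk-flagged and
saturated cases) for high-volume calling tests.

Deliberately not modelled: peak skew/tailing, dye-specific spectra and
mobility shifts, size-dependent signal decay, plate edge effects, and
stutter on the +1 repeat side. Passing tests therefore demonstrate the
contracts of detection, sizing, correction and calling under controlled,
well-formed signals — not performance on degraded real-world runs.

## Problem sizes used in the test suite

Unit tests run on single chromatograms or peak lists. The end-to-end
recovery suite uses 100 seeded two-sample plates (800 genotypes) under
the generator's default conditions; the ploidy-cap suite uses 10,000
peak-level scenarios; the ladder-matcher suite compares the production
DP against an independently implemented suffix recursion on 100 seeded
ladders of 16 sizes with up to 2 spurious and 1 missing peak; round-trip
suites use 200 randomized cases per format.

## Known limitations

* The ABIF writer emits only the tags this package reads; files from
  real instruments carry many more, which the reader ignores.
* The saturation tag layout is not publicly documented; this package
  writes/reads per-channel int32 scan-index lists and otherwise detects
  flat-topped plateaus (≥ 3 scans within 1 unit of a channel maximum
  ≥ 30000).
* The GeneMapper panel importer is best-effort: name, dye and range are
  mapped; ploidy and motif default to diploid/dinucleotide with a
  warning.
* Offset parameters are supplied numerically; automatic peak↔bin offset
  estimation is out of scope.
* Polyploid genotypes are not called; additional fragments are the
  mechanism for inspecting extra peaks.
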