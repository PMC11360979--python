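# Methods

This note documents the models, defaults and numerical choices behind
`dabquant`, and what the synthetic validation does and does not establish
about real tissue.

## Stain model and separation

Brightfield attenuation is modelled as base-10 Beer–Lambert:
`rgb = 255·10^(−M·c)` with `M` the 3×3 matrix of unit-norm stain OD
spectra (columns: hematoxylin, DAB, residual) and `c` the per-pixel
concentration vector. The inverse `OD = −log10((v+1)/255)` uses a +1 offset
on integer images to guard the logarithm; OD is clamped at zero. Float
images (the pre-quantization forward model) are inverted without the
offset, which makes compose-then-deconvolve the exact identity — the
round-trip test asserts agreement to 1e-6 on noiseless float renders.
8-bit quantization limits the corresponding uint8 round-trip to ~1e-3 OD;
that is a property of the image format, not of the unmixing.

Default spectra are the classical H-DAB reference vectors,
H ≈ (0.650, 0.704, 0.286) and DAB ≈ (0.269, 0.568, 0.778), normalized.
The residual channel is the per-channel complement
`r_c = sqrt(max(0, 1 − h_c² − d_c²))`, normalized — the construction used
by the classical colour-deconvolution plugins. We prefer it to the cross
product because it keeps every matrix entry nonnegative (a cross product of
these two vectors has a negative green component), while remaining
config-overridable for labs with calibrated vectors. The matrix is rejected
if any column is not unit norm or the condition number exceeds 1e6.

Negative concentrations after inversion are clamped to zero and the
pixel-channel fraction is reported. On noiseless renders this fraction is
zero. With the default OD noise (SD 0.02) most of the white background
clamps tiny negatives — the OD clamp makes recovered background OD
one-sided, and the mixed-sign rows of `M⁻¹` turn that into small negative
concentrations on roughly a third of background pixel-channels. The
reported fraction is therefore a format-level bookkeeping number at
nonzero noise; magnitudes involved are ≤ a few times the noise SD.

## Cell detection

Detection channel is the hematoxylin + DAB concentration sum: strongly
DAB-positive cells can mask the hematoxylin counterstain and must still
count as cells. The pipeline is

1. Gaussian smooth (σ = 1.5 µm), threshold at 0.1 OD, fill holes, drop
   objects below 16 µm².
2. Watershed splitting of merged nuclei. Markers are multi-scale
   Laplacian-of-Gaussian peaks of the unsmoothed detection channel — a
   matched filter for disc-shaped nuclei whose scale range brackets the
   expected nucleus radius (default 3.5 µm). Morphological seeding
   (distance-transform peaks) was measured at 85–93% nucleus recovery on
   default-condition renders because thresholding inflates every nucleus by
   about one smoothing σ and fills the waist between neighbours; the
   matched filter recovers 97–99%. Splitting is applied to every object,
   not only those above the maximum area: with the generator's minimum
   centre distance (0.8× the radius sum ≈ 5.6 µm), merged pairs are far
   smaller than any reasonable maximum-area gate. The [16, 250] µm² band
   filters segments after splitting.
3. Per-cell intensity. Mean DAB OD (and mean hematoxylin OD) are taken
   over the segment core — the segment minus the ~1 σ low-OD halo
   introduced by thresholding the smoothed image. Without this the halo
   dilutes a 0.6 OD nucleus to ~0.24, uncomfortably close to the 0.2
   positivity threshold; with it, label agreement against ground truth is
   ~100% at default noise. Centroids come from the segment for isolated
   nuclei (sub-pixel, symmetric) and from the seed for split nuclei (the
   halo of a merged blob biases piece centroids).
4. Positivity: `positive ⇔ mean DAB OD > τ`, strict inequality, τ = 0.2 OD
   by default. The threshold is deliberately a free parameter — scoring
   protocols of this kind declare it rather than derive it — and the whole
   validation suite runs at the default.

Cells touching the image border are retained; window membership is decided
later from centroids, so discarding them here would bias window counts.

## Peak / subpeak windows

"Most affected region" is operationalized as the square window of area
0.1 mm² maximizing the **positive-cell count** (equivalently positives/mm²
at fixed area). Percent-positive alone would favour near-empty windows.
Ties prefer the higher positive percentage, then the smallest (y, x)
origin, which makes the search deterministic. The search runs on a grid
with stride side/10 (≈ 31.6 µm) plus flush-to-edge positions; against an
exhaustive 1-µm-stride oracle the grid peak scores ≥ 95% of the optimum on
average over random fixtures (a single missed cell costs ~7% when the
optimum holds ~15 cells, so per-fixture equality is not a meaningful bar).
The subpeak is the best window with zero area overlap with the peak;
windows are half-open, so each centroid belongs to exactly one window of a
tiling and edge-to-edge windows do not double count.

Geometry caveat: an image of ≥ 4× the window area can still fail to host a
disjoint subpeak if the peak lands centrally; guaranteed feasibility for
every peak position needs an extent of ≥ 3× the window side (~949 µm) in
one axis. The default simulated image (2048 px at 0.5 µm/px = 1024 µm)
satisfies this; the search raises an explicit error otherwise. Real
protocols additionally ask the window to span all epithelial layers; the
synthetic scenes have no layers, so that instruction is not modelled.

Empty windows report a *missing* percent-positive (propagated through
means) and 0 positives/mm²; the density denominator is always the nominal
window area.

## Cohort statistics

Three analysis modes: both windows pooled (2 values/subject), peak only,
and the per-subject mean of the two. Summaries report mean, median, 25th
and 75th percentiles by linear interpolation between order statistics,
IQR = P75 − P25 exactly as computed, and sample SD (n−1). Published tables
of this kind occasionally print an IQR a point or two off its quartiles
(rounding order); the engine's definition is declared rather than
reverse-engineered.

Group comparison is the two-tailed Mann–Whitney U from midranks: exact
permutation null when the combined sample is ≤ 16 without ties, otherwise
the tie-corrected normal approximation with continuity correction.
Identical samples return p = 1. No multiple-testing correction is applied;
raw p-values are reported, as is conventional for this table layout. The
implementation is cross-checked in the tests against an independent
enumeration over all rank assignments for every nA, nB ≤ 8, and its
empirical type-I error at the 5% level is 4.8% over 10,000 null cohorts of
sizes 15 and 21 with rounding-induced ties (seed 1; the acceptance script
recomputes this number).

## Synthetic cohort generator

Per subject, the positive fraction `f` is Beta-distributed across subjects
(moment-matched to the group mean/SD; infeasible SDs raise an error) and
the total cell density `d` is Gamma (moment-matched). Within a section,
negatives are homogeneous Poisson with intensity `d·(1−f)`; positives are
a Thomas cluster process with total intensity `d·f`: Poisson parents
(default 2/mm²) on the image dilated by 3σ, Poisson offspring per parent
(mean `f·d/κ`), Gaussian scatter σ = 60 µm, offspring outside the image
dropped. Nuclei closer than 0.8× the sum of their radii are rejected and
redrawn around their parent a bounded number of times; exhaustion raises
an error naming the density. Nucleus radii are normal (3.5 ± 0.5 µm,
floored at 0.5 µm). Rendering stamps each nucleus as a flat disc of
hematoxylin 0.7 OD plus DAB 0.6 OD (positives) or 0.05 OD (negatives),
overlaps taking the per-stain maximum, then applies the forward model with
additive Gaussian OD noise (SD 0.02, i.e. multiplicative in transmitted
intensity) and quantizes to 8 bits.

Default group structure mirrors a three-group esophagitis cohort
(HV n=15, GERD n=21, EoE n=20) with positive-fraction means/SDs
0.38/0.31, 0.59/0.28 and 0.63/0.29. Total cell density defaults to
Gamma(600, 200)/mm² for every group: the published tables report only
positive densities inside peak windows, never total density, and the
clustering defaults concentrate positives ~20-fold at hotspot cores, so
densities much above ~600/mm² make cores confluent — at which point nuclei
are no longer individually resolvable by *any* detector, contradicting the
generator's purpose of producing watershed-splittable scenes. The price of
that separability is that absolute positives/mm² values run roughly 2×
below the published tables; the group ordering and effect structure are
preserved.

Two deliberate properties of peak-window scoring follow from the model and
matter when interpreting recovery experiments:

- **Hotspot enrichment.** On clustered positives the peak window measures
  the hotspot, so its percent-positive is far above the subject's global
  `f` — that is the point of peak scoring in patchy disease, not an error.
  Measurement-chain recovery is therefore validated on the generator's
  *unclustered limit* (`patchiness: null`, positives homogeneous), where
  the window fraction is an unbiased image of `f` up to max-selection bias.
- **Max-selection bias.** Even on homogeneous scenes, picking the maximum
  window inflates the measured fraction by roughly +3–4 percentage points
  at ~150 cells/window; the ±8-point recovery band accommodates this.

Determinism: one master seed derives per-subject seeds via
`SeedSequence.spawn`; identical parameters reproduce bit-identical images,
manifests and tables. Blinding shuffles the manifest with a seeded
permutation, strips subject and group identity, and stores the inverse key
separately; per-subject measurements are provably identical in blinded and
unblinded order.

## Problem sizes used by the test suite

Cohort-level tests and the recovery experiments run at 960×960 px and
1 µm/px (0.92 mm², the smallest extent that guarantees a disjoint subpeak
for every peak position), with 56-subject cohorts over 10 master seeds;
unit fixtures use 448 µm scenes with a demo-sized 0.01 mm² window. These
sizes are the package's validation choices; the generator's defaults
(2048×2048 at 0.5 µm/px) remain the simulated "scanner" format.

## What passing tests do not show

The generator emulates the *statistical* structure the pipeline assumes —
group-wise fractions and densities, spatial clustering, stain mixing,
OD-space noise. It does not emulate epithelial architecture (layers,
basal-zone gradients), dilated intercellular spaces, cytoplasmic or
membranous stain localization, stain-vector variability between batches,
out-of-focus regions or scanner artifacts. Recovery results therefore
validate the computational chain, not the biological fidelity of any
particular antibody readout; on real slides the positivity threshold τ,
the stain vectors and the nuclear threshold must be set against control
tissue.

## Known limitations

- Hotspot cores at high `f·d` saturate against the overlap rule; the
  sampler then fails loudly rather than silently flattening the cluster.
- The percent-positive of peak windows is not an estimator of the global
  positive fraction on clustered tissue (by design; see above).
- Exact Mann–Whitney p-values are only used for small tie-free samples;
  image-derived percentages tie frequently, so cohort-scale comparisons
  use the corrected normal approximation.
- The clamped-negative fraction is strict pixel-channel accounting and is
  dominated by sub-noise background clamps at nonzero noise.
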