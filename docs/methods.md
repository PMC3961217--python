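# Methods

## The screen model

The package analyses (and simulates) an arrayed high-content screen: each
384-well plate carries library wells — one pre-miR per well, each miRNA in
quadruplicate — plus control wells present on every plate: scrambled
oligonucleotide with senescence induced (SCR), scrambled without induction
(SCR_uninduced, a staining/technical control), and three siRNA controls
(BMI1i and JMJD3i, which enhance induction of the p16 marker, and p16i,
which suppresses it). Each well is imaged in six fields of roughly 100
cells; the readout per field is the percentage of cells positive for the
senescence marker, and the well value is the unweighted mean of its six
field percentages (not the pooled-cell percentage — with unequal cell
counts the two differ, and the unweighted mean is the contract throughout).

## Synthetic-data generator

The generator's defaults are the screen's study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_library_mirnas` | 471 | arrayed pre-miR library size |
| `replicates_per_mirna` | 4 | quadruplicate wells, consecutive layout |
| `wells_per_plate` | 384 | 16 × 24 plates, row-major well names |
| `images_per_well` | 6 | fields per well |
| `cells_per_image_mean` | 100 | Poisson mean cell count per field |
| `baseline_positive_fraction` | 0.30 | induced, untreated positive fraction |
| `uninduced_positive_fraction` | 0.02 | SCR_uninduced positive fraction |
| `up_hit_fold` | 2.25 | planted up-hit multiplier |
| `down_hit_fold_range` | (5, 10) | planted down-hits divide by a uniform draw |
| `hit_fraction` | 23/471 | fraction of non-null miRNAs |
| `up_hit_share` | 16/23 | up-hits among the non-null miRNAs |
| `plate_noise_sd` | 0.15 | per-plate shift, logit scale |
| `well_noise_sd` | 0.10 | per-well shift, logit scale |
| `control_wells_per_role` | 8 | control wells per role per plate |

Cell counts are Poisson around the nominal ~100 cells per field — the
simplest count model consistent with an "approximately" specification.
A well's probability that a cell is marker-positive is
`clamp(baseline × effect, 0, 1)` pushed through logit-additive plate and
well noise; the logit parameterisation keeps fractions in range and
produces the plate-to-plate variation that motivates per-plate Z-scores.
With zero noise the probability reduces to the clamped product exactly,
which is what the closed-form tests use. Uninduced scrambled wells use
`uninduced_positive_fraction` regardless of any effect.

Marker intensity is a two-component log-normal mixture (negative component
centred at 40 a.u. with log-SD 0.2, positive at 600 a.u.; nuclear channel
log-normal around 500 a.u.). The components are far enough apart that a
mean + 3·SD threshold calibrated on uninduced-control cells misclassifies
a negligible fraction of cells, which is deliberate: the screen statistics,
not the classifier, are the object under study.

Control-effect multipliers are not printed anywhere for the original
screen, so the generator fixes them once as plausible partial-knockdown
phenotypes: BMI1i 1.7×, JMJD3i 1.5×, p16i 0.25× on the positive fraction,
SCR 1.0×. They bracket the planted hit magnitudes: an up-hit at ×2.25 must
clear the strongest positive control (×1.7), and down-hits at ÷5–10 fall
below the p16i control (×0.25, i.e. below ÷4), so the control-anchored
rule can in principle recover every planted hit. Down-hit folds are drawn
uniformly over the 5–10 range because the design brief gives a range, not
a value.

Rendered images place each nucleus as an isotropic Gaussian blob
(σ = 3 px) on a 100 a.u. background with 5 a.u. read noise, centroids
drawn by dart throwing with a hard 12 px minimum separation (≥ 4σ, so
blobs never merge) and a 12 px border margin. Channel 1 amplitude is the
cell's nuclear intensity, channel 2 its marker intensity; images are
written as 16-bit TIFF. The generator does not model optics (PSF tails,
illumination gradients, saturation), cell morphology, confluency or
mitotic figures — so passing segmentation tests certify the readout
contract on separable nuclei, not robustness to crowded real micrographs.

For scale, the screen-wide generator (`simulate_screen_cells`) draws all
~1.3 million cells of a full screen vectorised and without centroids;
`simulate_well` adds positions when wells are to be rendered.

## Screen statistics

Per-well Z-scores standardise against the well's own plate using the
sample SD (ddof = 1). The normalisation set defaults to the plate's
*library wells only*: the plate average is meant to estimate the typical
induced response, and the deliberately strong control wells (and the
uninduced technical control) would otherwise drag it. Including controls
is a flag; uninduced wells are never included. A zero-variance
normalisation set raises an error naming the plate.

Replicates are aggregated after standardisation (sample Z = mean of well
Zs), because the Z is defined per well; the sample percent is the mean of
well percents, and the fold change is the ratio of the sample mean to the
mean of each contributing well's own plate average.

Hit calls are control-anchored, not p-value based (hence no multiple-
testing correction): up-hit ⇔ sample Z strictly greater than the maximum
of the BMI1i and JMJD3i per-plate mean Zs over the sample's plates;
down-hit ⇔ sample Z strictly below the p16i per-plate mean Z (minimum over
plates). Ties are never hits. A pooled mode anchors on screen-wide mean
control Zs instead; per-plate is the default because controls are laid out
per plate precisely to absorb plate effects.

One distributional note: the mean of k independent per-well Zs has SD
≈ 1/√k, so sample Zs from quadruplicates are normal with SD ≈ 0.5, not
standard normal. Calibration checks therefore test normality with fitted
location and scale, and the null hit-rate expectation is computed from
normal theory at the realised control thresholds and the realised sample-Z
scale.

## Image quantification

Segmentation is a global Otsu threshold on the nuclear channel, connected
components, and an area filter (defaults 15–2000 px); a distance-transform
watershed split is available behind a flag but off by default, because the
generator enforces nucleus separation. Centroids are 0-based (row, col)
pixel coordinates. Positivity is a per-cell binary call: marker-channel
region mean strictly above a threshold. The threshold rule — mean + k·SD
(k = 3) of marker intensities pooled over uninduced scrambled-control
cells — is this package's own calibration contract; when quantifying
images it is calibrated on *measured* region intensities from rendered
control wells, so the table route and the image route each get a threshold
in their own intensity space. An empty image yields a missing value (never
0%), and missing fields are excluded from the well mean.

## Seed-site scanning

The seed is nucleotides 2–8 of the mature strand (RNA or DNA input,
normalised U→T). On the UTR sense strand a site is an occurrence of the
reverse complement of seed positions 2–7 (the 6-mer core), typed by its
flanks: a match opposite position 8 immediately 5′ of the core, and/or a
genomic adenosine immediately 3′ of it (the base opposite miRNA position
1, required to be A regardless of the miRNA's first base). Each core is
reported once under the strongest type it supports (8mer > 7mer-m8 >
7mer-A1 > 6mer); overlapping cores are all reported; windows containing N
never match. Coordinates are 0-based half-open over the full matched
pattern. Only exact seed matching is implemented — no context scoring,
conservation, accessibility or 3′-supplementary pairing — and the scanner
is region-agnostic: it scans whatever FASTA it is given (3′UTRs by
convention, but nothing in the logic assumes it). The default minimum
site type for target-gene sets is 6mer; stricter minima only shrink the
set.

The UTR generator writes the exact site string at each planted position,
adjusts the single flanking base where needed so the site types exactly as
requested, and (in clean-background mode) re-draws any background window
that accidentally contains the core, so planted truth is the complete site
list. Seeds whose site strings contain the core at a non-canonical offset
(periodic seeds) are rejected rather than silently producing ambiguous
truth.

## Expression analysis

2^−ΔΔCt assumes amplification efficiency exactly 2; technical replicates
are averaged on the Ct scale; a missing cell of the condition × role
design is an error naming the cell. The qPCR generator inverts the
estimator (treated target Ct shifted by −log2(ratio)) and adds Gaussian
noise per Ct; with noise the estimator is slightly biased upward
(log-normal mean), about +1% at Ct noise 0.1, well inside the 5%
round-trip tolerance.

The DE stage is a gene-level stand-in for a full RNA-seq pipeline: log2
values, Welch two-sample t-test, BH adjustment across all tested genes,
significant ⇔ q strictly below the threshold. The default threshold is
q < 0.05; a much more lenient cut-off (up to 0.5) remains selectable
rather than silently normalised away. Zero-variance genes follow a
documented rule (p = 1 if the group means are equal, else the smallest
positive double) instead of propagating NaNs. At the generator's default
biological dispersion (log2-SD 0.15) and n = 3 per group the Welch test
has modest power for 2-fold changes — deliberately realistic; recovery
round-trip studies state a low dispersion (0.05) so planted effects are
recovered with near-certainty and the set logic, not test power, is what
is being checked. In the DE/overlap round trip the non-target planted
genes are given strong, signed effects so that sporadic false positives
among null genes cannot perturb the target intersections being asserted.

## Problem sizes and numerical choices

Simulation studies run at the screen's native scale: 471 miRNAs ×
quadruplicates across six 384-well plates (~1.3 M cells, a few seconds
vectorised); 10 such screens for null calibration; 50 rendered wells
(300 fields) for segmentation fidelity; 1,000 random 500-nt UTRs for the
scanner/oracle comparison; 1,000 simulated assays for the noisy ΔΔCt
check. All randomness flows through `numpy.random.Generator` seeded from
explicit integers; a fixed configuration and seed reproduce byte-identical
outputs. Logit noise clips probabilities to [1e-9, 1 − 1e-9] before
transforming; 16-bit image rendering rounds and clips to [0, 65535].

## Known limitations

- The positivity threshold rule (mean + 3·SD of uninduced controls) is a
  package convention, not a reconstruction of any commercial analyzer's
  criterion.
- The hit rule inherits the control-anchored design's property that hit
  thresholds are themselves noisy estimates; with eight control wells per
  role per plate this noise is small but not zero.
- Down-hits near the weak end of the 5–10× range sit close to the p16i
  control threshold by construction; recovery there depends on the chosen
  control effect sizes.
- The generators model none of: spatial plate artefacts (edge effects,
  gradients), optical crosstalk between channels, cell-cycle or
  senescence biology, read-count noise for RNA-seq, or qPCR efficiency
  departures from 2.
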