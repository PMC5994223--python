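# Methods

## Probe design

A single-pair probe consists of a junction-spanning oligo and an immediately
adjacent partner, each 18–25 nt. The designer enumerates every placement in
which the spanning oligo extends at least `min_overhang` (default 4) nt into
each exon flanking the junction and the partner abuts it with zero gap on
either side; both adjacent-upstream and adjacent-downstream placements are
reported. Each oligo must satisfy a GC-content bound (default [0.30, 0.70] —
a design heuristic, not a physical model; override via `gc_range`). All
coordinates are 0-based half-open in transcript space; records store the
sense-strand target with the junction marked `/` (`-` accepted on input),
and the `antisense` flag records that the synthesized oligos are the reverse
complements. The overhang is exposed as a parameter rather than fixed
because commercial probes show variable junction offsets within the spanning
oligo.

Specificity screening is exact-substring search of the spanning oligo in
every isoform transcript of the gene model. A probe is *specific* iff every
isoform containing the oligo sequence actually carries the targeted junction
(same consecutive exon pair). No thermodynamic mismatch or hybridization
energy model is applied: single-base mismatch tolerance of the chemistry is
outside scope, and exon ids are treated as opaque labels (numbering
conventions differ between references).

The bundled ErbB4-like gene model (`pairfish.minigene`) combines the
published junction-flanking target fragments of ten probes with
deterministic synthetic filler inside each exon; it is a synthetic stand-in
for the full transcripts, adequate for junction-probe design because only
junction-proximal sequence matters there. Exon sizes follow the real gene
where known (JMa 75 nt, JMb 45 nt, CYT-1 cassette 48 nt).

## Field simulator

Each synthetic field has two 16-bit channels. The nuclear channel contains
`n_nuclei` soft-edged disks (radius uniform in `nucleus_radius_px`,
rejection-sampled so that disks never overlap and keep ≥ 2 px clearance)
plus additive Gaussian read noise. The signal channel contains dots rendered
as isotropic 2-D Gaussians (σ = `psf_sigma_px`, default 1.2 px — the
standard idealization of a diffraction-limited punctum) on the same baseline
and noise; peak values are clipped to the dtype range without wrap-around.
Poisson shot noise is not modelled; at the default dot amplitudes the read
noise dominates the detection margin.

Expression: each cell expresses with probability `positive_fraction`
(default 0.20, the regime in which roughly a fifth of nuclei are labelled);
expressing cells draw a dot count from Poisson (default mean 5) or
gamma-Poisson. Dots are placed uniformly in an annulus of
[0.2, 1.2] × nucleus radius around the owner's centroid. This tight
perinuclear placement reflects thin-section 2-D projections, where
cytoplasmic signal overlaps and closely rings the nuclear profile; a wider
annulus in a dense field would place dots genuinely closer to neighbouring
nuclei, making any closest-nucleus rule mis-attribute them. Dot centers
keep a minimum spacing (default 7 px): the chromogenic precipitates are
discrete resolvable objects at this pixel size, and unresolvable proximity
is modelled explicitly by the clump artifact instead — with probability
`clump_prob` (default 0.02) an expressing cell's dots collapse onto one
center with sub-pixel jitter, mimicking the signal accumulations produced by
enzymatic dye conversion on abundant targets.

Background (nonspecific) dots arrive as a Poisson process at
`background_dot_rate_per_mm2` (default 150/mm², ≈ 4 isolated dots per
default 512² field at 0.325 µm/px) uniformly over the field, rendered
identically to real dots — nonspecific binding is indistinguishable
punctum-by-punctum, which is exactly why quantification needs a
knock-out-calibrated floor. Negative-control mode forces
`positive_fraction = 0`, leaving only this background; pooled over fields
its per-cell histogram is concentrated at 1 dot/cell. All draws come from
one `numpy` generator seeded by `SimParams.seed`: identical parameters give
bit-identical images and ground truth.

What passing tests on this generator do *not* show: robustness to uneven
illumination, tissue autofluorescence texture, z-stack effects, nucleus
shape irregularity, or chromatic offsets between channels — none of which
are simulated.

## Quantification

*Segmentation*: Gaussian smoothing (σ = 2 px) → Otsu global threshold →
hole filling → watershed on the distance transform seeded at local maxima
(min peak separation 7 px) → area filter (60–5000 px). Deterministic; a
blank channel yields zero nuclei with a warning.

*Calibration*: the intensity threshold is `KO mean + k·SD` (k = 3 default)
over all pooled negative-control signal pixels; a percentile mode (99.9th by
default) is available as an alternative. Whole-image statistics are the
default (computing over detected-object pixels only is offered via the
percentile mode); with wild-type images supplied the mean detected dot
diameter is recorded (single-pixel specks excluded), and in `wt-derived`
mode the size threshold becomes `floor(wt_mean_diameter × fraction)`.
Calibration without at least one KO image is an error — the negative control
defines background.

*Detection*: binarize strictly above the threshold, 8-connected components,
retain components with equivalent-circle diameter `2·sqrt(area/π)` ≥ the
size threshold (default 3 px). Equivalent diameter is used because the
puncta are near-circular and it is robust to ragged boundaries. Optional
declumping splits components larger than `max_single_dot_area_px` by
watershed seeded at local intensity maxima and re-tests each fragment; it is
off by default (a fused clump then counts as one dot, matching the
conservative reading of clumped signal).

*Assignment*: a dot's distance to a nucleus is 0 if its rounded centroid
pixel lies inside the mask, else the Euclidean distance from the sub-pixel
centroid to the nearest mask pixel (centroid-to-boundary rather than
centroid-to-centroid, because the signal is cytoplasmic and nucleus sizes
vary). The accelerated implementation (k-d tree over mask pixels) is exact
and is tested against an exhaustive per-pixel search. Dots farther than
`max_distance_px` (default 30 px ≈ one cell diameter) from every nucleus
stay unassigned — an unlimited radius would attach far-field background dots
to cells. Exact ties go to the lowest label.

*Region metrics*: dots/area uses all detected dots over the full frame area
(tissue-masked area is a caller-side alternative); a cell is positive iff
its count ≥ `positive_min_dots` (default 1 — the knock-out background then
sets the empirical floor, and a stricter cutoff of 2 is one configuration
flag away); % positive and the mean over positive cells are NaN, not 0, when
undefined; the dots-per-positive-cell histogram has unit bins with an
open-ended last bin.

Under the default study conditions (200 nuclei/field, 20% positive, mean 5
dots/cell) the pipeline recovers the positive fraction to within ~2
percentage points and mean dots per positive cell to within ~10% relative;
the residual bias is dominated by background dots being counted as small
positive cells and by clumped cells counting as one dot.

## Statistics

One-way ANOVA is the classical fixed-effects decomposition. The
from-summary path computes SS-between from the n-weighted group means and
MS-within by pooling `n·sem²` per group weighted by n−1; because the
decomposition depends on data only through per-group (mean, SD, n), it is
exactly the raw-data ANOVA for any data reproducing the summaries. For
testing, raw vectors with prescribed (mean, SEM, n) are reconstructed as m
points at mean±d (plus one at the mean for odd n) with
`d = sd·sqrt((n−1)/(2m))`, which reproduces the ddof-1 SD exactly.

Tukey HSD uses `q = |Δmean| / sqrt(MS_within/n_h)` with the harmonic mean
`n_h` of the pair's sizes (Tukey–Kramer; it reduces to plain Tukey for
balanced designs) and the studentized range distribution with k groups and
the ANOVA's within-group df (scipy's numerically integrated CDF; checked
against the published critical value q(0.05; 3, 9) ≈ 3.95 and against
statsmodels on raw data). Degenerate inputs (all variances zero) yield F = 0
with p = 1 and a warning rather than an exception; p-values are clamped away
from exact 0.

Two-way ANOVA with interaction runs on a complete crossed design via an OLS
fit; missing cells are an error (no imputation). When applied to
genotype × dots-per-cell-bin histograms, the bins are counts from the same
cells and therefore not independent observations; the test is reported as
specified, and this caveat is deliberately flagged rather than "fixed".
Optional Tukey comparisons of the first factor within each level of the
second use the pooled residual MS.

Relative isoform abundance takes paired per-animal measurements for two
probes (dots/area by default — which upstream metric feeds the percentages
is a configuration choice, exposed rather than hard-coded) and reports
per-animal `100·a/(a+b)` with group mean ± SEM; animals with zero total are
excluded with a warning.

## Numerical and scale choices

Tests and the acceptance script scale simulations to what desk hardware
verifies comfortably: oracle checks run on twenty 256² fields (~40 nuclei
each), recovery and negative-control checks on 512² fields with 200 nuclei
(12–20 seeds), and the isoform-abundance readout pools two 512² sections per
probe per animal so the simulated truth itself stays near the nominal 85/15
split. The detection-oracle regime uses psf σ = 3 px with SNR 5 and dot
spacing of 5σ: below ~σ = 2.5 the supra-threshold footprint of an SNR-5 dot
fluctuates around the 3 px diameter floor (the size filter would reject
valid dots), and at spacing of exactly 4σ read noise can occasionally bridge
two footprints into one component, so the guaranteed-exact regime sits
strictly inside those boundaries.

## Known limitations

- Intensity calibration assumes KO background statistics transfer to the
  sample sections (same staining batch/exposure); no per-image flat-field or
  batch correction is provided.
- Dots/area normalizes to full frame area, not tissue area.
- The specificity screen is exact-match only; near-matches that could
  cross-hybridize are not flagged.
- 2-D only: no z-stacks, no optical-section aggregation.
- The two-way ANOVA on histogram bins inherits the independence caveat
  above.
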