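# Methods

## Stain model and deconvolution

Brightfield H-DAB immunohistochemistry is modeled with the Beer–Lambert
law: per RGB channel, `OD = −log10(max(I, 1) / I₀)` with incident
intensity `I₀ = 255` by default and an intensity floor of 1 so fully dark
pixels map to a finite OD of `log10(255) ≈ 2.41`. Optical densities of
co-localized stains add, so a pixel's OD vector is a linear mixture of
per-stain absorption vectors. Unmixing (Ruifrok–Johnston color
deconvolution) is an exact 3×3 inversion per pixel.

The absorption basis defaults to the widely used H-DAB preset —
hematoxylin `(0.650, 0.704, 0.286)`, DAB `(0.269, 0.568, 0.778)`, both
unit-normalized, residual = their unit cross product — and is configurable
(`[stains]` in the TOML config) because stain vectors vary between
scanners and staining batches. Stain-vector *estimation* from the image
(e.g. Macenko) is out of scope.

Concentration maps are re-rendered to 8-bit pseudo-transmittance channels,
`value = round(255 · 10^(−c))`, before thresholding. The named automatic
thresholds are 256-bin histogram methods and historically operate on such
8-bit per-stain channels; thresholding the float concentration field
directly would change their semantics.

## Automatic thresholds

* **Otsu** (hematoxylin → stroma): the split `{≤ t, > t}` maximizing
  between-class variance; ties go to the smallest `t`; a single-bin
  histogram returns that bin. Verified against an exhaustive 256-split
  search.
* **Tsai moments** (DAB → tumor): the binary two-level distribution
  `(p₀ at z₀, 1−p₀ at z₁)` preserving the histogram's first three
  gray-level moments is solved in closed form; the threshold is the
  smallest gray level whose cumulative fraction reaches `p₀`. A tolerance
  of `1e-7` decides exact ties (e.g. two-spike histograms where `p₀`
  equals a cumulative step to within round-off); it sits well above the
  numerical error of the moment algebra (~1e-9) and below the smallest
  possible cumulative step for realistic pixel counts (≥ ~1e-6).
  Verified against an independent linear-solve/polynomial-root
  implementation of the same moment equations.

Both channels are median filtered first (disc footprint, default radius
2 px, scipy's edge-duplicating reflection at borders). Radius 0 disables
the filter.

**Stain-positivity floor.** An automatic threshold always splits the
histogram *somewhere*; on a channel containing no genuine stain it
degenerates to a near-white split and would label the entire field as
stained. The effective threshold is therefore capped at the
pseudo-transmittance of `min_stain_od` (default 0.1 OD, i.e. channel
value 203): pixels lighter than that are never counted as stain-positive.
For genuinely stained channels (DAB-positive pixels sit near value 26 at
1.0 OD) the cap is far above the automatic threshold and has no effect;
its purpose is to make EpCAM-negative cores come out with an *empty*
tumor mask so the negativity flag fires.

## Masks, overlap, QC

Stain-positive is dark: a mask is `channel ≤ t`. Stroma overlapping the
tumor mask is removed before the ratio; default is pixel-wise subtraction
(`overlap_mode = "pixel"`), with an alternative that drops every
8-connected stroma component touching tumor (`"component"`), matching a
stricter reading of "non-overlapping regions". Pixel mode is the default
because it is conservative and insensitive to how components happen to
merge.

QC flags per core:

* **four_sides_pass** — tumor pixels present in all four edge bands, each
  `ceil(border_fraction · dimension)` wide (default 5%). This
  operationalizes the visual-scoring rule that tumor must be visible on
  the north, south, east and west sides of the field; 5% is the smallest
  band that is robust to the 8-bit/median-filter erosion of single-pixel
  contacts.
* **epcam_negative** — tumor-mask area fraction strictly below
  `min_tumor_fraction` (default 1%). Such cores are reported but not
  auto-scored; in practice they go to manual review.
* **empty_stroma** — stroma mask empty after overlap exclusion (TSR
  undefined).

A core is informative iff it passes all three. `TSR = tumor px /
stroma px`, kept at double precision internally and rounded to 4 decimals
in CSV output (published values are typically printed at 2 decimals, but
ranking and cut-off decisions should not be quantized).

## Patient aggregation and dichotomization

Per patient, min and max TSR over informative cores (a single informative
core contributes both); patients with none are excluded with an explicit
signal and counted in the run summary. Dichotomization uses a
configurable statistic (default **max**, the headline choice in the TSR
literature for these cohorts) against a cut-off (default 1.0); the
boundary belongs to the high class (`statistic ≥ cutoff → high`). Since
the intended design is two cores per patient, `mean`/`median` statistics
are computed as the midpoint of the stored min and max; with more than
two informative cores they are approximations.

## Cohort statistics

* Proportions: percentage per category, rounded to 2 decimals.
* Pearson chi-square without continuity correction (errors out on a zero
  expected count, directing the user to Fisher); Fisher's exact test with
  the two-sided probability-mass rule (sum of all tables with the observed
  margins no more probable than the observed one), p = 1 on a degenerate
  margin. Both delegate to scipy behind this module's interface.
* Kaplan–Meier product-limit estimator and Mantel–Cox log-rank test
  (chi-square with 1 df) via lifelines. Records without a follow-up time
  are excluded. Tests hold the machinery to independent oracles: exact
  enumeration for Fisher, hand product-limit arithmetic for KM, a direct
  O−E/V accumulation and a 10,000-relabeling permutation null for the
  log-rank test.
* Cox regression is deliberately not reimplemented; the `survival` CLI can
  report a hazard ratio from an off-the-shelf proportional-hazards fit,
  outside the tested core.

## Synthetic data

**What it emulates.** `make_layout` places elliptical tumor "glands", each
with a central blank lumen (lumen = 25% of gland area by default), on a
stroma background; four glands are pinned to the border midpoints so
layouts satisfy the four-sides rule by construction, the rest are placed
uniformly at random. A shared gland scale factor is found by bisection
until the realized tumor/stroma pixel ratio is within 5% of the target
(feasible targets 0.02–50 on canvases ≥ 64×64). Blank lumina are included
on purpose: gland architecture creates unstained holes that inflate
visual stroma estimates, and the pipeline must not count them as stroma.

`render_ihc` applies the forward Beer–Lambert model with class-wise
concentrations — tumor: 1.0 OD DAB + 0.2 OD hematoxylin counterstain;
stroma: 0.7 OD hematoxylin; lumen: blank — plus additive Gaussian noise
in OD space (default sd 0.05 OD, multiplicative in intensity), then
quantizes to 8-bit RGB. Noiseless renders are bit-for-bit reproducible;
noisy renders are reproducible per seed.

**What it does not emulate.** Nuclei-level texture, stain-vector drift,
scanner color profiles, focal blur, tissue folds, necrosis, and
non-elliptical gland morphology. Passing recovery tests therefore show
the *algorithmic* chain (deconvolution → thresholds → overlap → ratio) is
correct under its own stain model with realistic geometry and noise; they
do not certify accuracy on any particular scanner's slides, for which the
stain vectors and QC parameters may need site-specific configuration.

**Cohort simulator.** Per-core TSRs are log-normal with defaults
`μ = ln(1.06)`, `σ = √(2·ln(2.89/1.06)) ≈ 1.417`, i.e. a TSR distribution
with median 1.06 and mean 2.89 as reported for an automated-scoring pilot
cohort; under max-of-two-cores dichotomization this yields ≈ 23% low-TSR
patients, matching the validation cohort's split. Event times are
exponential; `baseline_event_rate` (default 0.09) is the probability that
a *low*-TSR patient recurs before the follow-up horizon (default 120
months), and the high-TSR hazard is `hazard_ratio` (default 2.75, the
published multivariate estimate) times larger, giving ≈ 17–20% events
overall. Times beyond the horizon are censored at the horizon.

## Numerical choices and degenerate inputs

* OD base 10; background `I₀ = 255`; intensity floor 1.
* Empty stroma → TSR undefined (signalled, not NaN-propagated).
* Zero informative cores → explicit exclusion error.
* Otsu/moments on single-bin histograms return that bin.
* Log-rank with zero events raises rather than returning 0/0; simulation
  studies count such replicates as non-rejections.
* Simulation sizes used by the test suite and acceptance script: 256×256
  canvases, 3 seeds × 5 target ratios for recovery; 1,000 null replicates
  at n = 50 for calibration; 200 replicates at n = 209 for power. These
  give Monte-Carlo standard errors comfortably inside the asserted bands
  (e.g. ±0.007 on the type-I error).

## Known limitations

* Stroma is defined purely as hematoxylin-positive, non-tumor pixels; no
  attempt is made to exclude benign glands, nerves or vessels.
* The four-sides rule is a band-occupancy surrogate for a rule originally
  defined for human scoring; band width 5% is a convention, not a fit.
* EpCAM-negative cores are flagged, never auto-scored.
* Whole-slide pyramidal formats, 16-bit and multispectral input are out of
  scope; inputs are 8-bit RGB TIFF/PNG fields of view.
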