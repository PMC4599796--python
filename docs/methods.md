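# Methods

## The readout and its assumptions

A follicle encapsulated in a fibrin–alginate bead degrades the fibrin
around itself in proportion to its proteolytic (hence secretory, hence
health) state. The package quantifies the optically cleared zone in a
single calibrated brightfield micrograph per well and turns it into a
health call. The chain assumes:

- one bead, one follicle per image, with the bead at least mostly in
  frame;
- cleared fibrin images *brighter* than intact fibrin (standard
  brightfield contrast; an `invert` flag covers the opposite acquisition
  convention);
- an evenly exposed background — a single global threshold is meaningless
  under strong illumination gradients, so images whose background
  coefficient of variation exceeds 10% (configurable) are refused rather
  than silently flat-fielded;
- day-6 imaging for classification (configurable `analysis_day`): by then
  live and dead phenotypes separate clearly while antrum formation is
  still ahead.

## Segmentation and measurement

**Threshold.** Otsu's between-class variance criterion over all integer
levels of the declared bit depth. The implementation is a vectorised
histogram scan that returns the *midpoint of the maximal criterion
plateau*, so a clean two-level image yields a threshold midway between the
levels instead of hugging the lower one; on noisy images it coincides with
the standard library implementation (tested against scikit-image).

**Bead geometry.** The bead is the single large dark component (fibrin
plus follicle). Its convex-hull boundary is circle-fit by trimmed
algebraic least squares (Kasa fit, iteratively dropping radial residuals
above max(1.5 px, 75th percentile)). For an intact fibrin annulus the fit
is exact; when edge truncation bites a gap into the annulus the hull's
chord across the gap is rejected as outliers, keeping the fit sub-pixel
where a centroid/equivalent-radius estimate errs by up to 10% in radius
and tens of pixels in centre. Zero large dark components raises "bead not
found", two raises "multiple beads", and a component touching three or
more image borders raises "bead clipped" unless explicitly allowed.

**Follicle.** The follicle is the intact-labelled hole enclosed by the
cleared component, nearest the bead centre (minimum 9 px to skip specks).
With no clearance at all (dead phenotype) the interior is near-uniformly
dark and the follicle class is far too small for a histogram split;
instead the image is Gaussian-smoothed (σ = 2 px) and pixels robustly
below the fibrin level (median − 4 × 1.4826 MAD of the smoothed interior)
form the candidate blob. A manual seed point can override the search.

**Degradation area.** Degraded pixels inside the bead circle are labelled
(8-connectivity) and the component enclosing the follicle is selected —
identified by overlap with a thin disc just outside the follicle body,
falling back to "filled interior contains the follicle centroid". The two
rules agree on clean geometry; the overlap rule also survives clearances
cut open at the bead edge. `raw_area` counts the component's pixels;
`corrected_area` fills the component's holes, restoring the follicle
footprint — for concentric geometry this equals the filled clearance
disc, which is why the synthetic truth stores exactly that quantity.
Areas are pixel counts × (µm/px)².

**Truncation.** The flag is set when any component pixel lies within
`margin` (default 3 px) of the fitted bead circle. For ideal circles this
is equivalent to the analytic predicate
dist(centres) + r_degradation ≥ r_bead − margin, and the synthetic grid
test holds the pixel-level flag to 100% agreement with that predicate.

## Classification

Controls (≥ 2 non-truncated control wells, refit per plate by default)
give cutoff = mean − 1.5·SD (sample SD, floored at 0). Calls: truncated →
"?" unconditionally; otherwise area below/above the cutoff with relative
tolerance ε = 10⁻⁶ → "X"/"√", inside the ε-band → "?" (the "equal to the
cutoff" case, unreachable in floats without a tolerance).

A property worth stating plainly: the cutoff sits 1.5 SD inside the
healthy distribution *by construction*, so ≈ 6.7% of genuinely healthy
follicles fall below it (one-sided normal tail at z = −1.5; the design's
known false-flag rate, close to the conventional 5%). Tests therefore
verify that the classifier reproduces the cutoff rule exactly, not that
it recovers generative live/dead labels — no threshold rule of this form
can exceed ≈ 93% specificity on the healthy class.

The group-level comparison is Welch's unequal-variance *t*
(one-sided, treatment < control, for toxicity; a two-sided mode for
diameter/area comparisons), delegated to scipy and cross-checked in tests
against the closed-form statistic and Welch–Satterthwaite df.

## Condition-level statistics

Percentages follow the screening convention: %survival over all cultured
follicles; %antrum over survivors; MII/GV/MI/DG over follicles matured
(undefined cells are NaN, rendered "–"). SEM uses the experiment
replicate as its unit when replicate labels exist, else the per-follicle
binomial SEM with a warning. Kaplan–Meier estimation is backed by
lifelines behind the module surface; deaths are interval-observed (2-day
imaging) and assigned to the first day seen dead, survivors are
right-censored at their last observation, so with no earlier censoring
S(final) equals the empirical survival fraction exactly. IC50 defaults to
the *tested* dose with survival nearest 50% (ties to the lower dose),
because a screen identifies a tested concentration; log-linear
interpolation between the bracketing doses is an explicit alternative
that warns and falls back when no bracket exists.

## Synthetic ground truth

The generator rasterises the four-level geometry (background 230,
clearance 200, fibrin 60, follicle 40 in 8-bit), adds fibrin speckle
(SD 5), Gaussian noise (SD 8) and an optional linear illumination ramp.
Defaults, chosen once as the simulated study conditions: 512×512 px at
2 µm/px; bead radius 200 px; follicle radius 31 px (124 µm diameter — a
two-layered secondary follicle); live clearance radius 155 px, i.e.
≈ 3×10⁵ µm² of cleared area, the day-6 healthy scale. Per-follicle
day-6 areas in simulated experiments follow N(3.0×10⁵, 0.3×10⁵) µm² when
alive and N(0.3×10⁵, 0.2×10⁵) µm² (floored at 0) when dead; the default
experiment design mirrors the validation screen (control ≈ 70% survival;
doses 200, 10, 1, 0.1 nM at 0%, 0.01 nM at 35%, 0.005 nM at 48%; group
sizes 52–92). A single master seed fans out to per-follicle substreams
(seed + index, mod 2³¹), so any subset regenerates identically.

What the generator does *not* model — and hence what passing tests do not
establish about real micrographs: point-spread blur and defocus, partial
or graded degradation fronts, non-circular clearances, debris, vignetting
beyond a linear ramp, and follicle morphology (the "dark and dense"
appearance graded by eye at 20×). Results on synthetic images certify the
measurement chain on idealised geometry; real-data performance rests on
the same assumptions the original manual protocol makes.

## Numerical choices and edge cases

- Coordinates are (row, col), origin top-left, 0-based; all areas
  computed in px² then scaled.
- Plateau tie-break in the threshold scan: midpoint of the maximal
  contiguous plateau (tolerance 10⁻¹² relative).
- Degenerate images (constant intensity) refuse with "no separable
  classes"; an empty dose map, empty record set, or < 2 usable controls
  refuse likewise rather than guessing.
- Zero-variance controls give cutoff = mean; negative raw cutoffs floor
  at 0 (areas cannot be negative), in which case nothing can be called
  "X" and a zero area is "?" (at the cutoff).
- Synthetic plates space control clearance radii *evenly* (0.75–0.85 of
  the bead radius): the extreme of n evenly spaced values lies ≈ 1.34
  sample SDs from their mean, safely above the 1.5-SD cutoff, which makes
  the expected √/X/? grid deterministic rather than seed-dependent.
- Batch runs are deterministic end to end: identical inputs and config
  produce byte-identical CSV/JSON outputs.

## Problem sizes used in checks

Automated checks run at desk scale: 100 micrographs for area recovery, a
10×10 geometry grid for truncation, 20 paired cases for manual/automated
equivalence, 200 simulated follicles for classifier fidelity, 100 for the
Kaplan–Meier simulation, and a 14-well plate for the end-to-end run —
sizes at which the binomial/analytic tolerances quoted in the tests are
meaningful. Biological headline numbers from live cultures (control
survival rates, diameters, maturation rates) are inputs to simulations
here, not quantities the package can re-derive.

## Known limitations

- One follicle per bead; clustered or twin follicles are out of scope
  ("multiple beads" / nearest-candidate behaviour is the only guard).
- No antrum detection from images and no morphology grading; those remain
  the manual "?"-review path.
- The truncated-area case is flagged, never extrapolated; truncated
  controls are excluded from cutoff fitting.
- No multiple-testing correction across wells, and no 4-parameter
  logistic dose–response fit — the screen's IC50 is a tested-dose pick,
  with interpolation only as an explicit opt-in.
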