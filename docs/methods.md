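# Methods

## The measurement problem

An excimer-laser eye tracker samples the pupil center (PC) during
photo-ablation and prints a summary plot: each sampled PC offset inside a
6 × 6 mm tracking square (3 mm each side of the fixation crosshair) is
marked by a small blue square, marks overlap freely, and time ordering is
not preserved. The plot is therefore a purely spatial record of fixation
behaviour. `fixscore` measures it with three morphometric parameters and a
fixed linear score:

* **SA** — number of mark pixels (union area of the possibly overlapping
  squares), in px² at the reference resolution;
* **SP** — summed boundary-edge perimeter of the connected mark clusters,
  in px;
* **ACD** — area-weighted mean Euclidean distance of cluster centroids from
  the tracking-square center, in px: clusters with more mark pixels pull the
  average harder;
* **FIS** = 0.005·SA + 0.027·SP + 0.213·ACD + 4.458, banded on a 0–90 scale
  as normal (≤ 12), borderline (13–36), case (37–90). The coefficients were
  calibrated on a clinical cohort against the HADS anxiety sub-score and are
  held as named configuration constants (`FISCoefficients`), not literals,
  so a different device can be recalibrated without code change.

The HADS anxiety sub-score sums seven items, each answered 0–3, and bands as
normal (≤ 7), borderline (8–10), case (11–21).

## Image pathway

**Mark detection** is a configurable hue/saturation/value band (default:
hue 0.55–0.78, saturation ≥ 0.5, value ≥ 0.2 — saturated blue). The device's
exact mark RGB is not published, so the band is a config object; gridlines,
the crosshair and axis ink fall outside the band, and any matching pixel
outside the tracking square is discarded. An all-background plot is valid
(a perfectly stable eye): it yields an empty mask with a warning flag, and
by convention (SA, SP, ACD) = (0, 0, 0), so FIS equals the intercept 4.458
(normal) — the most conservative reading.

**Units.** SA/SP/ACD are pixel quantities, and the device's native plot
resolution is not published, so all measurements are made at a fixed
reference scale (default 50 px/mm); images at other resolutions are
resampled to it (nearest neighbour, preserving the color band) before
measurement. Clinical magnitudes (SA in the hundreds to thousands, ACD in
the tens) are consistent with pixel units at roughly this scale.

**Clusters** are connected components of the mask, 8-connected by default
(diagonally touching marks read as one island; 4-connectivity is a flag).
Per cluster: pixel area; boundary-edge perimeter (the number of pixel edges
separating mark from non-mark — exactly 4s for an s×s square, which keeps
synthetic fixtures analytic; a polygonal arc-length perimeter would not
have this property and the source convention is unspecified); centroid as
the unweighted mean of member pixel coordinates; and its Euclidean distance
to the crosshair. Clusters partition the mask, so cluster areas always sum
to SA.

**Numerical reproducibility.** Centroids are computed from the raw pixel
coordinate arrays (bounding-box local mean plus integer offset) and the
SA/SP/ACD aggregations use exact, order-independent summation
(`math.fsum`), so the measured triple is reproducible bit-for-bit from the
pixel set alone regardless of labeling order. This is what makes the
oracle-equivalence tests exact rather than approximate.

Coordinates are image row/column with origin top-left internally; report
output converts centroid offsets to the device convention (x
temporal/nasal by eye side, y positive up) only at the presentation layer.

## Synthetic cohorts

Real plots are sensitive clinical data, so the generator is first-class,
tested code, and its defaults define the study conditions used everywhere.

Per subject, dwell positions are drawn as independent isotropic Gaussian
scatter — the plot discards time ordering, so only the spatial distribution
matters — and each dwell is rendered as a 5 px blue square; rendering is the
exact inverse of detection on mark pixels. The model is hierarchical:

* class level: median dwell scatter (5.5 / 8.0 / 11.5 px for normal /
  borderline / case), mean decentration bias ((−8, −6) / (−15, −11) /
  (−23, −18) px, nasal-and-up for a right eye, x mirrored for left eyes),
  and dwell-count ranges (49–170 / 69–240 / 101–348);
* subject level: a lognormal multiplier on the scatter (σ = 0.12 on the log
  scale) and Gaussian jitter on the bias (SD 3.5 / 4.0 / 4.5 px).

The subject level matters: without it every subject collapses onto its
class expectation and single parameters separate classes unrealistically
well, whereas clinical cohorts show wide within-class interquartile ranges.
Dwell counts are deliberately high — clinical plots are confluent (summed
perimeters far below what isolated marks would give), so marks must merge
into a few islands — and deliberately wide, which makes dwell count the
dominant source of between-subject area variability and decorrelates SA
from SP within class; bias jitter supplies an independent
centroid-deviation axis. With these defaults a 200-per-class cohort lands
its SA/SP/ACD medians near (630, 170, 11) / (1100, 330, 20) /
(2000, 630, 31) — the clinical order of magnitude — and reproduces the
qualitative cohort structure: FIS medians strictly increasing with class,
the FIS macro AUC at least that of every single parameter, Spearman
r(FIS, HADS) ≈ 0.88, and average-map support growing across classes.

Metadata is drawn per class to mirror the clinical orderings: HADS items
uniform over 7-item vectors conditioned on the class's sub-score band
(rejection sampling, hence exactly uniform); cooperation VAS around class
means 2.3 / 4.1 / 5.3; heart rate at five intra-operative time points
(baseline, start, flap, ablation, end) with the ablation peak most
pronounced in the case class; treatment breaks Poisson with class-increasing
rates. Eye laterality alternates right/left.

What the generator does **not** emulate: saccade dynamics, microsaccades,
cyclotorsion, tracker latency, anisotropic or multimodal dwell clouds, and
any coupling between refractive error and fixation. Passing tests therefore
demonstrate correctness of the measurement and evaluation machinery on
plots with the clinical plots' gross spatial statistics — not clinical
validity of the score on real eyes.

An **analytic oracle** computes (SA, SP, ACD) by exact pixel enumeration of
the square-union geometry directly from the ground-truth coordinates,
using `scipy.ndimage` labeling — a separate implementation from the image
pathway's `skimage` labeling and with no rendering or color detection
involved. Tests assert bit-exact agreement between the two routes on whole
seeded cohorts.

## Evaluation pipeline

Mirrors the validation design used for the clinical score:

* **Split**: stratified random 70/30 train/test, seeded; the original split
  is unrecoverable, so the seed is logged with every run.
* **Classifiers**: one soft-margin linear SVM per parameter per class pair,
  on the standardized scalar feature (a 1-D maximum margin is a threshold
  rule; the kernel is configurable but linear is the honest model for a
  monotone scalar).
* **ROC/AUC**: AUC as the tie-corrected normalized Mann–Whitney statistic
  (midranks; a constant score gives 0.5); standard errors by the
  Hanley–McNeil formula via the AUC's equivalence to the Wilcoxon statistic,
  with Q1 = A/(2−A) and Q2 = 2A²/(1+A). One-vs-one multiclass: per class
  pair, AUC reported for each positive class, macro-mean over pairs. With a
  single shared monotone score the two directions of a pair coincide; both
  rows are kept for layout compatibility with per-class-calibrated
  classifiers.
* **DeLong comparison** of two correlated AUCs on the same subjects:
  structural components V10 (per positive, mean concordance kernel against
  all negatives; kernel 1 / ½ / 0 for greater/tie/less) and V01 (symmetric);
  component covariance matrices give Var(ΔAUC); z = ΔAUC/SE with a
  two-sided normal p-value (no sidedness is standard for this table) and a
  symmetric 95% CI on |ΔAUC|. Identical scores (zero variance) are flagged
  degenerate with p = 1 rather than raising. The estimator coincides with
  the grouped leave-one-out jackknife, which the tests verify to machine
  precision, alongside a stratified-bootstrap cross-check.
* **Youden cutoff**: exhaustive scan over midpoints of adjacent distinct
  scores plus ±∞ sentinels; predict positive strictly above the threshold;
  ties in J break toward the lower threshold. Applied to raw FIS for the
  normal-vs-borderline and borderline-vs-case pairs.
* **Spearman matrix**: tie-corrected rank correlations for all numeric
  columns, with a significance-filtered variant (entries with p > 0.05
  masked). A constant column's correlations are undefined and masked, not
  an error.

## Average maps

The class-wise average PC-position map is the per-pixel mean of the binary
mark masks of all subjects in a class (optionally per eye side): the value
at a pixel is the fraction of subjects whose PC was recorded there, and the
map's area-weighted centroid offset summarizes systematic decentration.
Plain frequency averaging is the primary estimator; projecting the mask
stack onto its top-k principal components before averaging is available as
an explicitly secondary, denoised interpretation (the role of PCA in the
original figure is under-specified). Full-rank reconstruction reproduces
the plain average; reconstruction error is non-increasing in k.

## Numerical and design choices

* FIS scale value: round half up, then clip to [0, 90]; no rounding rule is
  published and half-up matches the integer band phrasing.
* Class boundaries on real-valued FIS: ≤ 12 / ≤ 36 (the inequality form);
  consistent with the integer bands 0–12 / 13–36 / 37–90.
* The clinical table reports a FIS minimum of 0.00 although the formula's
  minimum is its intercept 4.458; the package keeps the formula and applies
  no rescaling. Similarly, the published FIS class medians are not
  reproducible by evaluating the formula at the published SA/SP/ACD class
  medians; the synthetic defaults therefore target the parameter medians'
  order of magnitude and the qualitative orderings, not the printed FIS
  medians.
* Degenerate inputs: empty plots score the intercept and are flagged; a
  single-class training partition, a missing class, mixed mask geometries
  and k ≥ n in the PCA route raise with explicit messages.
* Problem sizes: the test suite and the acceptance script use 200 subjects
  per class (the default study conditions) for cohort statistics and ~200
  subjects for bit-exact recovery checks — large enough that every
  qualitative ordering holds with margin across seeds at roughly half a
  minute of compute.

## Known limitations

* The FIS coefficients are fixed to the published calibration; refitting on
  new data is out of scope (and impossible without the clinical cohort).
* The pixel↔mm scale behind the published parameter magnitudes is inferred,
  not documented; absolute SA/SP/ACD values depend on the reference
  resolution choice, though all orderings and the FIS bands' behaviour on
  synthetic data do not.
* Proprietary PDF treatment reports are not parsed; the supported interface
  is a raster plot plus a CSV sidecar with grid geometry.
* Cyclotorsion and temporal fixation dynamics are invisible in the plots
  and therefore out of scope.
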