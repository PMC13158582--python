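# Methods

## The localization model

A detection-grid record says only "tag *i* was heard by station *j* with
RSSI *r*". Localization proceeds in three fixed rules:

* **Noise floor.** Records with r ≤ −90 dBm are discarded as noise
  (boundary inclusive: −90 itself is dropped).
* **Band assignment.** r ≥ −82 dBm → inner band (0–15 m disc around the
  station); −90 < r < −82 dBm → outer band (15–35 m annulus). The two
  bands partition all surviving records.
* **Placement.** Each fix is drawn uniformly over the *area* of its band:
  radius r = √(r₀² + u·(r₁² − r₀²)) with u ~ U(0,1), angle uniform on
  [0, 2π). Uniform-over-area is the non-informative choice for a disc or
  annulus; the radius is drawn before the angle, and that stream layout is
  part of the reproducibility contract (one `numpy` Generator per pipeline
  run, seed recorded in outputs).

Distance-band thresholds come from field calibration of the deployed
hardware and are configurable (`LocalizationConfig`): floor −90 dBm,
band threshold −82 dBm, radii 15/35 m.

Activity windows operate per night (a "night" is keyed by the calendar
date of its evening). The effective window is
[max(21:00, sunset + 2 h), min(05:00, sunrise − 3 h)], closed at both
ends; sunset/sunrise instants are supplied per night in a sun table
rather than computed from an ephemeris. The detection percentage is the
share of calendar minutes inside that window containing ≥ 1 fix; using
the trimmed window (not the full schedule) as the denominator is a
configurable choice — the trimmed window is what the UDs are actually
estimated from.

## UD estimation

The estimator is a reference-function autocorrelation-adjusted KDE:

1. Fit two stationary position models per individual by exact maximum
   likelihood, each axis Gaussian and independent: IID (4 parameters) and
   OU with a shared timescale τ (5 parameters: τ, per-axis mean and
   stationary variance). The OU likelihood uses the exact transition
   density with decay e^(−Δt/τ), so multi-night gaps contribute almost
   nothing to the dependence structure; given τ, the mean (generalized
   least squares) and variance are profiled in closed form, and the
   1-D search over log τ runs a 49-point grid scan followed by bounded
   refinement — the profile can be multimodal for periodic or
   noise-dominated motion, where a local optimizer alone is unreliable.
2. Select by AIC (ties favor IID).
3. Effective sample size: n_eff = n for IID; n_eff = clamp(T/τ̂, 1, n)
   for OU, with T the summed within-night monitored time (sessions are
   split at gaps > 4 h).
4. Per-axis bandwidth h_i = σ̂_i · n_eff^(−1/6) (the 2-D Gaussian
   reference rule with the autocorrelation-discounted sample size);
   Gaussian KDE on a raster covering the fix bounding box padded by three
   bandwidths, renormalized to integrate to exactly 1. In the IID limit
   this is classic reference-bandwidth KDE.

Isopleths are greedy: cells sorted by density (descending, ties broken by
row-major index) accumulate until the target mass q is reached. q = 0.95
defines the home range, q = 0.50 the core area; areas are cell counts ×
cell area, reported in hectares. By construction the q₁ mask nests inside
the q₂ mask for q₁ < q₂.

Numerical choices:

* Default cell size 5 m (the 15/35 m placement radii and 65 m station
  spacing make this a safe resolution); a cell size exceeding the
  bandwidth is rejected as undersampling. Raster origins snap outward to
  the global cell lattice so rasters from different individuals align
  without resampling.
* Coincident timestamps are legal (one beacon slot heard by two stations
  yields two fixes, both kept — there is no principled fusion rule and
  the estimator tolerates the extra autocorrelated points); the OU
  likelihood floors Δt at 1 s to keep the transition density
  non-singular.
* Individuals qualify for a UD with ≥ 30 fixes on ≥ 2 nights; the
  `min_nights` parameter relaxes this for single-session reference
  tracks (the walking experiment).

Two behaviors of this estimator are worth knowing. First, smoothing
inflates area: for an IID Gaussian sample the expected 95% isopleth area
is ≈ 5.991·π·(σ̂² + h²), i.e. a factor (1 + n_eff^(−1/3)) above the
analytic 5.991·π·σ² — about +4.6% at n = 10⁴. Second, there is no
measurement-error component in the movement model, so the independent
band-placement noise added to every fix reads as near-instant
decorrelation: on placed fixes τ̂ collapses toward zero, n_eff ≈ n, and
the estimator effectively reduces to reference-bandwidth KDE. That is
consistent (the placed fixes *are* nearly independent given the
trajectory) but it means the autocorrelation adjustment mostly matters
for smooth inputs — GPS tracks, or proximity data with placement
disabled. Velocity-correlated (OUF) models, error-aware likelihoods and
weighted KDE for irregular sampling are deliberately out of scope.

## Overlap

BA = Σ √(ud_a·ud_b)·c² and UDOI = A_overlap · Σ (ud_a·ud_b)·c² on a
common raster (union extent, shared lattice; mass embedded without
resampling). A_overlap is the area where both densities are positive. By
default both indices are *conditional*: each UD is truncated to its own
level-q isopleth and renormalized first, and the supports of the
truncated UDs define A_overlap. The unconditional variant is available
via a flag; the conditional form is the default because home-range-level
questions ("how much of their 95% ranges do two bats share?") are posed
on the conditioned distributions. BA ∈ [0, 1] by Cauchy–Schwarz; UDOI is
1 for identical uniform use and exceeds 1 when both individuals
concentrate in the same cells. Inputs must integrate to 1 (tolerance
10⁻⁴) or the indices refuse to compute.

Dyads are all unordered pairs of eligible individuals within a tagging
batch, labeled mother–daughter or non-related from a kinship table;
pairs absent from the table default to non-related (unlisted pairs can
include sisters and aunt–niece pairs, which the pedigree classification
groups with non-related). Site fidelity compares one individual's UDs
across monitoring periods with BA, labeled within-year or between-year.

## Inference

The kinship contrast is a grouped permutation test: the statistic is
mean(kin UDOI) − mean(non-kin UDOI) over dyad rows; the null permutes
dyad-level labels, keeping repeated samplings of one dyad together
(approximating a dyad-identity random effect); the one-sided p-value is
(1 + #{null ≥ observed})/(1 + n_perm), n_perm = 10,000 by default.
Permutation p-values are discrete and conservative — exact mixed-model
machinery (Tweedie GLMMs with dispersion submodels, LMMs with
Satterthwaite degrees of freedom) is intentionally not reimplemented
here; the permutation test is this package's distribution-free analogue
and is labeled as such in outputs.

Method comparison (proximity vs GPS on the same track) reports per-track
area overestimation 100·(prox − gps)/gps (2 decimals), column means ±
SD, between-method BA, and a paired t-test on the area differences with
n − 1 df (identical columns return t = 0 by convention rather than NaN).
The detection-percentage diagnostic is a Spearman rank correlation
between per-individual detection percentage and UD area — a strong
correlation would mean UD size merely tracks time spent inside the grid.

## The simulator

What it emulates:

* **Grid**: a near-square lattice (65 stations → 8×8 + 1) at 65 m
  spacing; optional isotropic Gaussian jitter (per-axis SD 9.33 m
  reproduces the ~11.7 m mean between-season relocation observed in the
  field).
* **Movement**: exact-discretization OU per axis with stationary
  initialization. Defaults: τ = 600 s, σ = 40 m per axis — the
  Gaussian-equivalent of the ~3.1 ha mean home range observed in the
  field; colony centers are drawn over the grid extent extended one
  spacing outward, because the grid covers only the core of the
  colony's area and real individuals spend part of each night
  undetected beyond it. Mother–daughter centers differ by a 30 m
  per-axis Gaussian displacement, emulating maternal inheritance of
  foraging grounds.
* **Radio**: log-distance path loss RSSI(d) = P₀ − 10γ·log₁₀(max(d, 1 m))
  with P₀ and γ solved from two calibration anchors (−82 dBm at 15 m,
  −90 dBm at 40 m ⇒ P₀ ≈ −59.91 dBm, γ ≈ 1.878) plus Gaussian shadowing
  noise (default SD 3 dB, a typical outdoor BLE value). Detection is
  certain to 40 m, decays linearly, and ceases at 65 m — the observed
  beacon-dropoff pattern; the falloff *shape* between those ranges is a
  modeling choice, not a measured curve.
* **Walks**: piecewise-linear loops through waypoints at 1.2 m/s, 45 min
  at 2-s cadence, observed by GPS (truth + 4 m isotropic noise) and by
  the grid; the first and last 10 min are trimmed so tracks do not all
  overlap at the shared start/end point. The built-in validation
  scenario draws an irregular pentagon (radii 40–80 m) well inside the
  grid, sized so reference areas land in the ~1–4 ha range of the real
  accuracy-experiment tracks.

What it does not emulate: multipath and vegetation attenuation, antenna
anisotropy, battery/memory/gateway behavior, roosting and social
dynamics, non-stationary (drifting or multi-modal) home ranges. Passing
validation on simulated data therefore demonstrates the pipeline's
statistical correctness under its own assumptions — not that any given
field deployment meets those assumptions.

## Problem sizes

The test suite and the reproduction script use 20-replicate batteries
for stochastic checks (20 walks for the accuracy validation, 20 eight-
hour OU tracks for parameter recovery), n = 10⁴ draws for distributional
checks, and a six-bat, two-night colony for the end-to-end study; these
sizes give stable medians and counts while keeping a full run in tens of
seconds on one CPU.

## Known limitations

* No measurement-error model in the movement fit (see above): τ̂ from
  placed proximity fixes is not interpretable as a movement timescale.
* Isopleth areas inherit KDE smoothing inflation, ~(1 + n_eff^(−1/3));
  no debiasing is applied.
* The grid truncates UDs: activity outside detection range contributes
  nothing, so absolute areas are conservative for individuals whose
  ranges extend beyond the grid (the simulator reproduces this).
* Detection percentage, fix counts and overlap distributions in the
  colony scenario vary considerably between seeds at realistic colony
  sizes (n = 6–12 individuals); single-seed values are descriptive, not
  calibrated estimates.
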