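# Methods

`walkscape` reimplements, as a tested pipeline, a trip-level analysis of
how the urban environment a pedestrian walks through relates to what
they report feeling afterwards and to what their body does along the
way. The unit of analysis is the individual walking trip; trips are
nested within participants. This note records the models, the
parameters that matter, what the synthetic study emulates, and the
numerical choices made where the design was genuinely open.

## Pipeline model

A trip enters the analysis as three synchronized records: a GPS fix
stream (1 fix/s), a wearable session (interbeat intervals in ms; skin
conductance in µS at 4 Hz; skin temperature in °C), and four post-trip
semantic-differential ratings (Trip Feeling Environment 0–5;
Unwell–Well, Agitated–Calm and Tired–Awake 1–6). Environmental layers
live on a flat-topped hexagonal grid of 25 m vertex-to-vertex diameter
(NDVI in [−1, 1], Lden noise in dB(A), slope), as point sets (POIs by
category; street-level images with per-class pixel proportions) and as
a daily weather table.

### GPS stage

Fixes are ordered by timestamp per trip; any fix strictly more than
500 m (Haversine, R = 6 371 000 m) from the previously *retained* fix
is dropped in a single sequential pass. A simplified stop detector then
splits the stream: fixes are "moving" when a 5-s rolling mean speed
lies in [0.5, 3.0] m/s (the ceiling flags non-walking locomotion);
stationary stretches of ≥ 120 s split candidate trips, shorter pauses
are absorbed; candidates shorter than 120 s (matching the
physiological-session floor) are discarded. Each validated trip becomes
a LineString in a local equirectangular metric frame and receives a
25-m round-capped buffer. Exposure statistics are computed over all
grid cells intersecting the buffer, unweighted, with the population-SD
convention (the SD of a single cell is 0); POI counts use the closed
region (boundary points count) with absent categories reported as 0;
image class proportions are unweighted means over images inside the
buffer; weather joins by exact calendar date. Hexagon vertices are
constructed on an integer half-step lattice so that shared edges are
bitwise identical and edge intersection queries are exact.

### Physiological stage

Sessions pass quality control iff duration ≥ 120 s AND the IBI array is
non-empty AND sensor contact holds (mean skin temperature ≥ 30 °C OR
mean raw EDA ≥ 0.05 µS); every rejection carries its first failing
gate. HRV metrics are computed in consecutive 10-s windows (RMSSD,
pNN50 with a strict > 50 ms rule, mean HR = 60000 / mean IBI; windows
with fewer than two intervals are skipped) and summarized per trip.
The LF/HF ratio interpolates the IBI series onto an even 4-Hz tachogram
(cubic), estimates the spectrum by Welch's method and integrates
0.04–0.15 Hz against 0.15–0.40 Hz.

EDA is smoothed with a Savitzky–Golay filter (window 1 s, order 3) and
split into tonic + phasic with a zero-phase fourth-order Butterworth
low-pass at 0.015 Hz (tonic) and its exact complement (phasic), so the
additive decomposition holds to machine precision and a constant input
has zero phasic response. These defaults were chosen by measurement on
the analytic test pulse (linear rise 2 s to 1 µS, exponential decay
τ = 3 s): a first-order filter at a higher cutoff cannot keep both the
pulse shape error within a few percent and the leak of 0.005-Hz tonic
drift below 5%; the steeper, lower filter achieves ~3% amplitude error,
< 0.1 s rise error, ~0.1–0.25 s recovery error and 1.5% drift leak. All
filter parameters are configurable.

SCRs are scored on the phasic component: candidate peaks require
prominence ≥ 0.01 µS and a width of ≥ 2 samples; the onset level is the
preceding local minimum; onset *time* is refined by the tangent method
(maximal rising slope extrapolated to the onset level), peak time and
height by quadratic sub-sample interpolation; amplitude is peak minus
onset level; recovery time runs from the peak until the signal has
declined by 63% of the amplitude (the exponential time-constant
convention, configurable to the complementary reading), linearly
interpolated between samples and missing when the next event or the
record end arrives first; events with rise time < 0.5 s (unresolvable
at 4 Hz) are discarded as noise. The trip summary fills exactly 27
indicators: mean/SD of RMSSD, pNN50 and mean HR; min/max BPM; LF/HF;
mean/min/max/SD SCR amplitude; mean/SD rise time in seconds and in
samples; mean/SD recovery time; SCR count and rate per minute; mean/SD
tonic level; mean/min/max/SD skin temperature. The canonical list is
the package's own reconstruction: the source tables name a subset
(amplitude statistics, rise time in "npoints", LF/HF, mean BPM) and the
count 27, but never the full enumeration; the two count fields
(scr_count, scr_rate_per_min) complete the schema.

**Known limitation.** The full chain (smoothing corner loss, high-pass
absorption, 4-Hz sampling, trough-to-peak scoring) attenuates SCR
amplitudes by ~5–7% multiplicatively under realistic pulse trains.
Regression slopes of amplitude summaries on exposures inherit that
factor; parameter-recovery tests at tight tolerances sit close to their
bounds for this reason, and the attenuation should be kept in mind when
comparing absolute amplitude effects across processing pipelines.

### Inference stage

All predictors are z-scored over pooled trips (population SD); missing
POI values become 0 *before* standardization; zero-variance columns are
dropped with a warning. Mixed models are linear with a participant
random intercept, fitted by REML (statsmodels MixedLM; the default BFGS
optimizer with a Powell fallback — L-BFGS was observed to park the
variance component at the boundary on well-conditioned data) and
reported with Wald p-values. H1 fits the four rating outcomes on the
jointly-entered greenery/openness/micro-infrastructure/POI/slope set.
H2 fits five thematic blocks (noise; temperature; technical
infrastructure = curbs, poles; functional POIs; visual elements = cars,
pedestrians) against each of the 27 indicators — 135 models — and
retains associations with p < 0.05 and |β| > 0.1 (an optional
Benjamini–Hochberg flag adjusts the significance side). The noise
block defaults to mean Lden with the maximum-Lden variant supported,
since the source is ambiguous between the two. H3 runs K-means
(fixed seed, 10 restarts) on the standardized environmental features;
k comes from an elbow rule implemented as the maximal second difference
of **log** within-cluster sum of squares over k = 2…8 — on the raw
scale the k = 1→2 drop dominates and the rule degenerates to the
smallest k, so the scale-invariant form is used. Cluster labels are
canonically reordered by descending mean noise exposure. Outcome
differences across clusters use Kruskal–Wallis tests with tie
correction (ratings are discrete; ties are certain).

## Synthetic study

The generator emulates the structure of a naturalistic two-week
urban-walking protocol: 90 participants × ~25 trips (defaults) inside a 2.0 × 1.2 km
synthetic city divided into four contiguous archetype strips —
low-density quiet, green open, mixed-use, dense/noisy commercial — each
with its own NDVI, Lden, POI-rate and streetscape profile. On top of
the strip profiles every layer varies continuously within zones via
smooth Gaussian fields (white noise on a 200-m lattice, bilinearly
interpolated; each layer's field is mostly independent with a weak
shared component). This within-zone structure is what makes the
jointly-entered H1 predictors statistically identifiable — a scene
whose exposures vary only between four archetypes is rank-4 collinear
and no joint model can attribute effects — while the field amplitudes
are kept small enough that the four archetypes remain well-separated
for clustering recovery. An `archetype_separation` dial scales all
between-zone contrasts; at 0 the archetypes are identical and
typology-recovery ARI collapses to ~0, which the tests assert.

Trips are constant-cadence (1 fix/s) heading-jitter walks at
0.8–1.8 m/s, reflected at the boundary of their start zone so each
trip's exposure stays within one archetype (this is what gives the
trip-level typology a ground truth). Defects are injected at
configurable rates: a single fix displaced 700 m (teleport) and a
stationary dwell long enough to split the trip; the expected
post-cleaning segmentation is stored for oracle tests.

Ground-truth effects enter exactly where the estimators look:

* **Ratings** — rating = clip-and-round(grand mean + Σ β·z(exposure) +
  participant intercept N(0, 0.5²) + residual N(0, 1²)). Default betas
  sit in the 0.05–0.2 standardized band typical of trip-level
  urban-wellbeing effects (curbs +0.078/+0.092/+0.099 on the three 1–6
  scales, mean NDVI +0.126/+0.129, max NDVI −0.094, sky −0.115,
  water −0.073, tourism +0.127).
  Rounding and clipping attenuate slopes by a few percent at these
  scales.
* **Physiology** — each trip's SCR pulse amplitudes are shifted by
  β µS per 1 SD of the exposure (defaults: max temperature 0.16,
  mean Lden 0.18) plus a per-trip N(0, 0.08 µS) offset. The base
  amplitude range (0.5–1.1 µS) deliberately exceeds the largest
  configured shift so the positivity floor never censors the injection.
* **IBI** — a stationary lag-1 autoregressive series (φ = 0.9) around
  800 ms whose innovation SD is solved analytically from the target
  RMSSD (σ_ε = RMSSD·√((1+φ)/2)), giving closed-form control of the
  extracted metric.
* **SCR pulses** — linear rise (2 s) to a drawn amplitude, exponential
  decay (τ = 3 s), Poisson-timed with a refractory interval of
  rise + 4τ so successive events stay analytically separable
  (trough-to-peak amplitudes remain meaningful).

Everything is deterministic under the config seed (sub-streams are
derived with `SeedSequence`).

### What the generator does not emulate

Real street networks and route choice (walks are reflected random
walks); movement artifacts, beat-detection errors and sensor dropout
beyond the QC gates; circadian and activity-driven physiology;
spatially autocorrelated residuals in the ratings; day-to-day
within-participant correlation beyond the random intercept; seasonally
confounded exposure (weather varies by date, space by zone, and the
two are independent by construction). Passing tests therefore
demonstrate that the pipeline recovers known structure of this kind,
not that the substantive findings of any particular city transfer.

## Numerical choices and degenerate inputs

* 500-m exclusion is strictly greater-than, applied against the last
  retained fix (single-pass determinism).
* Stop-detection parameters (0.5 m/s, 120 s dwell, 120 s minimum,
  3 m/s ceiling) are declared defaults, not values inferred from data.
* SD of a single observation is 0 by convention at every trip-level
  summary, avoiding silent missingness.
* Empty SCR lists yield 0 counts and missing (NaN) amplitude/time
  fields; HF power of 0 yields a missing LF/HF.
* Degenerate extents (area below 1 km²), single-point routes,
  non-positive radii, non-positive intervals and non-monotone
  timestamps are rejected with explicit errors.
* K-means ties are handled by a fixed seed and 10 restarts; report
  labels are ordered by descending noise so runs are comparable.
* Problem sizes in the test-suite recovery checks (240–540 trips for
  typology and rating recovery; 90 × 25 for the mixed-model recovery
  simulation and the acceptance script's full pipeline) were chosen as
  the smallest sizes at which the corresponding statistical property is
  stable across seeds.
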