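# Methods

## Scope and units

`ivtrack` starts at tracked positions; it never touches pixel data. All
positions are micrometres, all times minutes, all speeds µm/min, and the
arrest coefficient is a percentage (0–100). These are the units in which
intravital lymphocyte motility is conventionally reported.

## Metric definitions and conventions

**Instantaneous speed** is the Euclidean displacement between consecutive
recorded positions divided by the actual elapsed time. Steps that span a
tolerated tracking gap are excluded from speed-based statistics: their
displacement is an average over the missing interval, not an instantaneous
step, and including it (or interpolating across the hole) would fabricate
slow steps and inflate arrest coefficients. Gap steps do remain in the
path length, where the straight-line distance is a defensible lower bound
and keeps the straightness invariant (net ≤ path) intact.

**Arrest coefficient** counts steps with speed *strictly* below the
threshold (default 3 µm/min); a step at exactly the threshold is motile.
With uniform frame sampling, step counting and dwell-time weighting
coincide, so the step fraction equals the fraction of time arrested.
Tracks split at a disallowed gap are treated as independent segments
(each with its `source_id` recorded) rather than pooled back into one
record: a pooled record would mix a per-cell arrest fraction with
per-segment straightness and an ill-defined net displacement across the
untracked hole.

**Straightness** is net displacement over path length. A zero-length path
has no direction: the ratio is reported as missing (NaN), never 0 or 1.

**MSD** uses the overlapping-interval estimator: MSD(nΔt) is the mean of
|r(i+n) − r(i)|² over all start indices i (the DiPer convention), with the
interval count recorded per lag. The default maximum lag is half the track
length because long-lag estimates are dominated by a handful of highly
correlated intervals. The cohort MSD averages per-track curves with equal
weight — matching per-cell plotting and preventing a few long tracks from
dominating — and truncates lags supported by fewer than a configurable
number of tracks (default 5). The alternative (pooling intervals across
tracks) weights long tracks quadratically and was rejected.

## Preprocessing

3-D tracks are analysed as 2-D projections. In a thin (40–60 µm) moving
tissue volume sampled at 7-µm z-steps, the axial coordinate is the least
reliable one and projection avoids tracking artefacts, at the cost of
slightly underestimating the speed of motile cells (a conservative bias
shared by the metrics' usual usage).

Tissue drift (peristalsis, breathing) is estimated per frame transition as
the componentwise **median** of the frame-to-frame displacement over all
cells present at both frames, then the cumulative series is subtracted
from every position. The median is the key choice: with a majority of
arrested cells it recovers the bulk motion exactly and is robust to the
motile minority; with an entirely motile cohort it still works because
individual headings are isotropic. No image registration is needed. The
estimator is idempotent (re-estimation after correction returns zero
drift to numerical precision) and only XY is corrected. Drift correction
is an explicit, optional, logged pipeline stage (on by default).

Tracks with holes longer than `max_gap` frames (default 1) are split;
segments and whole tracks shorter than `min_track_duration` (default
10 min) are discarded, because arrest coefficients on very short tracks
are high-variance. Kept/split/discarded counts are always reported.

## The two-state persistent-random-walk simulator

The generator emulates what an intravital two-photon recording of villus
lymphocytes delivers, not the underlying biology of chemokine signalling.
Each cell is a two-state Markov chain evaluated every 0.1 min — well below
the 1-min frame interval, because stop-and-go dynamics are not resolved at
60-s sampling:

- **arrested**: isotropic Gaussian XY jitter (σ_arrest per fine step)
  around the current position, plus small axial jitter;
- **patrolling**: a persistent random walk — heading θ diffuses with
  standard deviation σ_turn per fine step while the cell advances at
  v_run. The heading decorrelation time is ≈ fine_step/σ_turn², so σ_turn
  sets the straightness of patrolling tracks.

Switching probabilities p_AP (arrested→patrolling) and p_PA are per fine
step; the stationary arrested fraction is p_PA/(p_AP+p_PA), and initial
states are drawn from it. Positions reflect at the walls of a
150 × 50 × 50 µm box (villus lamina propria scale; the exact size is
cosmetic for cohort statistics and is configurable). All cells of a
simulated field share a sinusoidal XY drift with ~5-min period and 1 µm/min
peak speed, standing in for peristaltic motion and exercising the
drift-correction stage. The trajectory is then subsampled to the frame
interval and every recorded coordinate is perturbed by Gaussian
localization noise (default σ = 0.3 µm) — this noise floor is what keeps a
perfectly parked cell's measured speed near σ√π/Δt ≈ 0.5 µm/min rather
than zero, as in real spot-detection data.

Default acquisition settings (30-min recordings, 1-min frames, 0.3 µm
noise) follow the imaging protocol the package targets; cohort sizes used
for calibration and verification are n = 500 tracks.

### What the generator does not emulate

Real movies have heterogeneous cell populations, segmentation and
track-linking errors (identity switches, missed detections beyond simple
holes), spatially structured drift, anisotropic confinement by crypts and
epithelium, and chemokine-field mechanics. Passing tests therefore show
that the *pipeline* measures what the generative model produces under
acquisition-like distortion — they do not validate biological conclusions
on real data.

### Regime presets and calibration

Per-condition presets were fixed by `calibrate_regime`: a grid search over
(p_AP, p_PA, v_run, σ_arrest, σ_turn) scoring the summed relative error of
the cohort mean speed, arrest coefficient and straightness computed by the
*full* pipeline (drift on, corrected) at n = 500. The selected parameters
are frozen in the source with their achieved statistics; calibration
declares failure if no grid point lands within 20% on every target. The
patrolling regimes (`flagellin`, `rag2_steady`) have no published numeric
targets beyond direction (faster, less arrested, less confined than steady
state); they are parameterized only to be clearly separated from the
arrested regimes. Intuition for the levers: the arrested fraction sets the
arrest coefficient almost directly (arrested-state steps stay far below
the 3 µm/min threshold, run steps far above); mean speed then follows from
v_run and the jitter amplitudes; straightness is controlled by σ_turn and
by how many tracks contain a run bout — a never-running 30-step jitter
track has straightness ≈ 1/√30 ≈ 0.18, which is exactly the confined
steady-state value.

## Statistics

Group comparisons treat the track/cell as the statistical unit. The
Mann–Whitney U test uses the exact null distribution when the smaller
sample has ≤ 8 observations and the pooled data are tie-free, otherwise
the normal approximation with tie and continuity corrections; the method
used is always reported (both routes are provided by scipy; the exact path
is verified against full enumeration in the test suite). One-way ANOVA
reports F with its degrees of freedom and returns an explicit undefined
result (NaN) when all groups are constant with equal means. P values are
unadjusted by default, matching per-panel pairwise reporting conventions;
Holm adjustment is available behind a flag. Per-animal aggregation is out
of scope.

## Numerical choices and degenerate inputs

- Time-grid checks use a 10⁻⁶ min tolerance; step multiples of the frame
  interval are established by rounding.
- The canonical writer emits full-precision floats (`repr`), making
  write→read round trips the identity to well below 10⁻⁹ µm.
- Reflection at confinement walls mirrors the position and flips the
  in-plane heading component; with 0.1-min fine steps a single mirroring
  pass is always sufficient at the speeds simulated.
- Degenerate limits are exact: p_AP = 0 with zero jitter and zero noise
  yields a bitwise-stationary track; p_PA = 0 with zero turning yields a
  ballistic track with straightness 1 and MSD(nΔt) = (v·nΔt)².
- Empty cohorts, single-point tracks, zero-length paths and empty time
  bins are all explicit error or missing-value paths, never silent zeros.

## Known limitations

- The spot/wavy classifier is a deterministic threshold surrogate
  (net displacement < 10 µm, or arrest ≥ 80%) for what is, in practice, a
  visual call; only the direction of its regime dependence is asserted,
  not exact published fractions.
- Drift correction assumes a rigid in-plane bulk motion; rotational or
  spatially varying tissue deformation is not modelled or corrected.
- MSD-based diffusion coefficients are not bias-corrected for
  localization noise (the noise floor appears as a constant offset).
- The Imaris-style reader covers the common position-per-row CSV layout;
  proprietary binary scene files and TrackMate XML are out of scope.
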