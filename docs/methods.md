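# Methods

`goalreplay` reimplements, as a tested library, the analysis stack of a
rodent spatial-learning experiment: a rat alternates between goal-seeking
and random-foraging trials in a 2 m × 2 m open arena whose floor carries a
6 × 6 grid of reward wells; large CA1 ensembles are recorded throughout.
The package quantifies behaviour, detects sharp-wave ripples and theta
cycles in the LFP, maps place fields, decodes position from ensemble
spiking, scores theta sequences, tests ripple content for trajectory
replay against Monte-Carlo nulls, and tracks the trial-resolved emergence
of goal representation in ripples.  Because such recordings are not
publicly distributable, the package includes a synthetic session
generator with full ground truth; every recovery claim below is made
against that ground truth.

## The Bayesian decoder

Position is discretised into 2 cm bins.  Given per-unit rate maps
λ_i(b) and spike counts n_i in a window of length τ, the posterior under
independent-Poisson spiking and a uniform spatial prior is

    P(b | n) ∝ ∏_i λ_i(b)^{n_i} · exp(−τ Σ_i λ_i(b)).

Computation is in log space; rates are floored at ε = 0.01 Hz so a bin
where a firing unit's estimated map is exactly zero is penalised but not
impossible.  Windows containing no spikes are *flagged undefined* and
skipped rather than assigned a uniform posterior: a uniform frame would
corrupt the step-distance criteria of trajectory analyses.  The decoder
is memoryless (no transition prior), matching the study design it
follows.  Only place cells — excitatory units whose map peak exceeds
1 Hz — enter the encoding model.

Behavioural-timescale accuracy uses non-overlapping 250 ms windows;
decoding error is the Euclidean distance from the posterior-weighted mean
to the rat's position.

## Rate maps and spatial statistics

Maps are smoothed (Gaussian, SD 4 cm) occupancy-normalised histograms of
spikes emitted while the rat moved faster than 5 cm/s, on the 2 cm grid.
Spike-count and occupancy histograms are smoothed separately and then
divided.  Bins with less than `min_occupancy` = 5 ms of smoothed
occupancy are flagged unvisited (NaN): dividing a smoothed count by a
smoothing *tail* of the occupancy otherwise produces arbitrarily large
spurious rates, which a decoder will happily chase.  Place fields are
4-connected components above 20 % of the map maximum with at least 20
bins.  Spatial information is the Skaggs bits-per-spike form
I = Σ_b p_b (λ_b/λ̄) log2(λ_b/λ̄).  Goal / goal-adjacent / goal-distant
classes are assigned by which well is nearest the unit's maximal-rate
bin (the eight grid neighbours of the goal well are "adjacent").

## Ripples and theta

Ripple detection: 150–250 Hz band-pass (zero-phase Butterworth, order
4), |Hilbert| envelope smoothed with SD 12.5 ms, averaged across
channels; events are local peaks above mean + 3 SD during immobility
(< 5 cm/s), with boundaries at the surrounding mean-crossings and
overlapping events merged.  The threshold statistics are computed over
the whole session by default (configurable to immobility only).

Theta: 6–12 Hz band; power is the 300 ms-smoothed envelope z-scored over
the session, consumed only during movement (> 10 cm/s).  Phase is the
analytic-signal angle shifted so filtered-signal troughs are 0°; the
signal is reflect-padded before the Hilbert transform to suppress edge
distortion.  Cycles are delimited at successive 60° crossings and kept
only when mean speed exceeds 10 cm/s.

## Theta sequences

Each cycle is decoded either in a single whole-cycle window or in 24
wrapped phase windows of 60° advanced in 15°.  Each window's posterior is
translated so the rat sits at the origin, rotated so the reference
direction (movement heading, or rat-to-goal bearing) points along +x
(bilinear interpolation; mass conserved to ≲ 1 %), and collapsed over the
perpendicular axis, giving a phase × relative-position matrix.

The forward-encoding portion comprises windows whose centre phase lies in
the wrapped interval [240°, 60°+360°).  The forward slope is the
mass-weighted least-squares slope of relative position against phase (in
cycles), reported in cm/cycle.  One numerical choice matters here: the
three wrapped windows that span the cycle boundary mix the sawtooth
discontinuity of phase precession — content jumps from farthest-ahead
back to farthest-behind — and systematically bias any slope fit toward
zero, so they are excluded from the regression (they remain in the
matrix, and the quadrant score uses all windows).  In an idealised
recovery experiment this exclusion moves mean recovered slope from ~64 %
to ~84 % of the injected sweep; the residual attenuation reflects
posterior background mass and is inherent to weighted-mean readouts.

The quadrant score splits the phase axis at the cycle midpoint and the
position axis at zero: (early-behind + late-ahead − early-ahead −
late-behind) / total mass.  The rate-matched control removes spikes
uniformly at random from each cycle down to the Learning-phase mean
count, re-scores, and averages over repetitions (default 1000).

## Replay significance

Each ripple is decoded in 20 ms windows advanced in 5 ms; the weighted
mean per defined frame forms the decoded path.  A trajectory-encoding
event requires ≥ 15 consecutive defined frames with every inter-frame
step < 30 cm and start-to-end displacement > 40 cm.  Criteria-passing
events are tested against two nulls — permuting unit labels among
participating units, and independently circularly rotating every unit's
map in x and y — each re-decoded with the same frame boundaries and
zero-spike policy and scored by the same binary criteria;
p = (n + 1)/(r + 1) with r = 1000, and an event is a replay only when
both p < 0.05.  The shuffle decoding runs in single-precision BLAS
batches; posteriors there feed only the binary criteria, which are
insensitive to float32 error.

For goal-representation statistics the posterior mass of the well
partition the rat occupies is zeroed in every frame and *not*
renormalised, so all quantities are shares of the original posterior; a
ripple encodes the Goal when the mean per-frame mass inside a
30 cm × 30 cm goal-centred box exceeds 0.075 (a raw-sum mode is also
provided; with ~20 frames per event a raw sum against 0.075 would be
nearly always exceeded, so the per-frame mean is the default).
Trial-resolved representation uses a 4-trial running window and flags
the Goal well when the one-sided maximum Grubbs test (α = 0.05, t-based
critical value with Bonferroni α/n) identifies it as the outlier among
the 36 well values.

## The synthetic session generator

The generator emulates the statistical structure every stage assumes,
with one integer seed driving fixed per-subsystem substreams.

* **Behaviour** — trials alternate goal-seeking / random-foraging
  starting with goal-seeking; no Random well repeats within 15 trials.
  Paths are waypoint walks whose lateral excursions scale with a
  tortuosity parameter; goal-trial tortuosity decays across the first 6
  goal trials (1.2 → 0.15) so goal navigation improves and plateaus,
  while random-foraging stays tortuous (0.9).  Each reached well is
  followed by a 2.5 s immobile reward dwell (sub-1 cm/s jitter);
  inter-trial intervals and dwell lengths are free parameters.
* **Tuning** — excitatory units (90 %) carry single 2D Gaussian fields,
  peaks uniform on [1, 30] Hz, widths 7–12 cm SD, centres on a jittered
  grid ("stratified": statistically uniform but without the large voids
  of an iid scatter, which leave stretches of the arena undecodable).
  Inhibitory units fire spatially uniformly at 10–25 Hz.
* **Spiking** — inhomogeneous Poisson with intensity tuning × per-trial
  gain × theta modulation during movement.  The gain ramps 1.0 → 1.6
  over six trials and then plateaus (the Learning→Retrieval signature);
  theta amplitude follows the same shape.  Modulation (depth 0.7) peaks
  at the theta trough, the CA1 convention.  Phase precession shifts each
  unit's effective tuning centre along the heading by
  sweep × (cycle fraction − ½), sweep 16 cm/cycle, producing decodable
  theta sequences.  During immobility units fire at 0.3 Hz, except
  inside scheduled ripple windows, where the spontaneous rate is
  suppressed and content spiking takes over.
* **LFP** — movement-gated theta sinusoid (amplitude per trial) plus
  white noise plus Gaussian-windowed 200 Hz packets at scheduled ripple
  times (events scheduled during movement are rejected with a warning).
  Default rate 1250 Hz.
* **Ripple content** — events sit inside reward dwells (3 per dwell).
  Smooth events *reactivate segments of the rat's own past trajectory*
  (decimated at equal arc increments so waypoints follow the experienced
  path), an explicit model of replay-as-reactivation; goal-encoding
  events reuse a past approach that terminates at the Goal well.  Jump
  events teleport between previously visited locations; stationary
  events hold the current position.  A smooth event is only scheduled
  once enough territory has been experienced; otherwise it is demoted to
  stationary content.  Content spiking assigns each cell with a field on
  the path (tuning ≥ 1 Hz) its tuning-weighted share of a fixed
  population rate (default 800 Hz), over a broad co-active background
  (1.5 Hz per excitatory unit) — sharp-wave bursts recruit cells beyond
  the replayed path, and the identity-shuffle null only has statistical
  power because of them.  Goal content appears only from the configured
  emergence trial (default index 7) onward; non-goal content is kept
  ≥ 30 cm from the Goal well.

### The high-SNR replay battery

Sensitivity and specificity of the replay pipeline are characterised on
a dedicated configuration (`replay_battery_config`): 200 units, 60
trials (dense coverage → stable maps), fields 6–10 cm SD, content rate
2000 Hz with 2.5 Hz background, smooth events 115–125 ms so each can
hold a full 15-frame run.  In this regime ≥ 90 % of injected smooth
trajectories classify as replay at r = 1000 and essentially no jump
events do.  Typical sessions (the defaults) carry weaker content and
lower detection rates, as real sessions would.

### What the generator does not model

Bursting and refractoriness, multiple fields per cell, directional or
speed-modulated tuning, theta asymmetry and gamma, spike-sorting noise,
electrode drift, and EMG artefacts.  Passing recovery tests therefore
demonstrates correctness of the *analysis* under the stated generative
assumptions, not performance on real tetrode data.

## Problem sizes used by the test-suite and acceptance script

Recovery checks run at desk scale: ~10-minute 120-unit sessions for
decoding accuracy, a 200-unit battery session for replay significance
(50 + 50 events in the test suite, 30 + 30 in the acceptance script),
200 cycles for theta-slope recovery, 10,000 null simulations for Grubbs
calibration, and 16-trial sessions for the goal-emergence end-to-end
runs.  These sizes were chosen so each claim is statistically meaningful
at interactive runtimes.

## Known limitations

* The weighted-mean path readout shrinks decoded positions toward the
  posterior centroid; slope estimates carry a corresponding attenuation
  (documented above) that the acceptance band accommodates.
* The cell-identity null is weak for events whose participants all carry
  fields on the decoded corridor; its power in the battery comes from
  the co-active background ensemble.
* Grubbs' test assumes approximate normality of the 36 well values; the
  calibration test verifies the type-I rate only under that null.
* The generator's per-trial gain is shared by all excitatory units;
  cell-type- or class-specific learning effects are not modelled.
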