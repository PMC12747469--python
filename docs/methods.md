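# Methods

## Scope and shape

The package re-expresses a parallel, message-passing real-time decoding
system as a single-process, deterministic replay over file-backed streams.
Module boundaries mirror the live system's process decomposition (LFP/ripple
path, per-group encoders, decoder, coordinating event handler), so the
replay loop in `session.py` is an ordered interleaving of exactly the same
stage calls a multi-process port would make. What is deliberately *not*
reproduced: network acquisition, inter-process messaging, GUI, hardware
reward delivery, and wall-clock latency benchmarking — latency enters only
as the budget arithmetic `lfp_deadline_us` (1/fs per LFP sample).

## State-space model

Position is a distribution over `n_bins` half-open 5 cm bins on a segmented
track. Each decoder step covers the half-open window

    (t_curr − Δt_delay − Δt,  t_curr − Δt_delay]

so spikes have Δt_delay (default 30 ms) to arrive and have their joint mark
intensity estimated before the bin that contains them is evaluated; the
windows tile time exactly, and a spike can never be counted in two bins.
Defaults Δt = 6 ms, Δt_delay = 30 ms. The decoder clock is driven by LFP
timestamps: a step fires each time LFP time crosses the next Δt boundary.

The likelihood is accumulated in log space and exponentiated after
subtracting the maximum. Raw per-bin products of `λΔ` factors underflow
float64 once tens of groups and spikes are involved; the posterior is
invariant to the common rescaling, which the tests assert explicitly. If
every bin's evidence is exactly zero the update falls back to the prior
with a warning rather than producing NaNs.

Transition models are materialized row-stochastic matrices: `uniform`
(the non-informative choice used for content detection — the posterior then
equals the normalized likelihood at every step), `identity`, and a
discretized Gaussian `random_walk` (sd in bins) for smoothing applications.
Rows are renormalized after edge truncation.

## Encoding model

* Learning stores raw (mark, bin) pairs; no computation happens until a
  query. Only spikes concurrent with running (speed ≥ `vel_thresh`,
  default 4 cm/s, boxcar-smoothed over 0.25 s) are stored, and occupancy
  accumulates camera-frame dwell over the same movement frames.
* Kernel density: product Gaussian over mark dimensions with a single
  bandwidth σ (default 20, ADC amplitude units). The weighted histogram is
  divided by the stored count so that μ_i (stored spikes ÷ encoding
  movement time) carries the rate scale; the normalizer is a design choice
  — any constant cancels in the posterior, but this one makes λ and Λ
  honest rates in spikes/s.
* Occupancy π(x) is the normalized movement-frame histogram, smoothed with
  a Gaussian of sd 1 bin (mode `constant`, no wrap) and floored additively
  at 1e−12 before division, so briefly-visited bins do not blow up the
  intensities and unvisited bins stay effectively excluded.
* `freeze()` fixes the stored set (idempotent; queries before and after
  freezing on the same stored set are identical — verified by test). A
  group that stored nothing is excluded from the likelihood product, which
  is the mathematically correct limit (its factor is the empty product).

## Ripple detection

Causal Butterworth IIR stages with state carried across chunks, so any
chunking of the stream is sample-identical to whole-trace filtering:
order-2 band-pass 150–250 Hz, square, order-2 low-pass (default 50 Hz).
The power proxy is z-scored against a mean/sd estimated over the first
`baseline_window_s` (default 10 s) and then frozen (an optional slow EMA is
available). Events open at z ≥ `z_threshold` (default 3) and close below
`z_end_threshold` (default 0 — return to baseline power, which the live
system leaves undefined). Channels are independent; an n-of-m consensus
helper exists but is off by default.

The power proxy z-scores the smoothed *square* of the band signal, as the
processing chain is described, not its square root.

A note on thresholds and false positives: the envelope of narrowband-
filtered noise has few effective degrees of freedom, so its z-score tail is
approximately exponential — over minutes of stationary 1/f background the
maximum z reaches ~9–11 regardless of realization. A z = 3 threshold on
such a trace therefore *must* fire occasionally (as it does on real
baseline LFP). The burst-injection fixtures consequently run the detector
at z = 25, placed between the analytic noise ceiling and the injected-burst
response (z > 400 for 6× RMS bursts), so that recall, onset accuracy and
the absence of spurious events measure detector correctness rather than
noise extremes. The default threshold for real use remains 3.

## Event detection

Every posterior update in task 2, the most recent `dt_event` (36 ms = 6
posteriors at Δt = 6 ms) are averaged and renormalized. A representation
event requires, jointly: target fraction strictly > 0.40, off-target
fraction strictly < 0.20 (strict, as the rule is stated), animal within
17 cm of the central-box segments (2D clamped point-to-segment distance),
and ≥ 2 electrode groups with spatially specific activity in the window. A
group counts as spatially specific if it emitted a spike whose joint mark
intensity places > 50% of its mass within the target/off-target arm
segments — the live system requires "spatially specific" tetrodes without
defining the term, so this operationalization is configurable. A 3 s
refractory period (matching the reward-collection window) suppresses
retriggering; without one, a sustained representation would trigger every
6 ms.

## Synthetic sessions

The generator emulates the statistical structure the decoder assumes, not
biophysics:

* **Track**: two 75 cm arms plus a two-segment 55 cm central box, 205 cm =
  41 five-cm bins. Segments are ordered and oriented along the running path
  so the global bin index is monotone in path position — |bin difference| ×
  5 cm *is* distance along the track, which makes the error metric
  junction-free. The animal alternates arm visits at constant speed
  (25 cm/s) with pauses at the tips (1 s) and the central box (2 s).
* **Spiking**: each of the 8 × 3 units is an inhomogeneous Poisson process
  (Lewis–Shedler thinning against the peak rate) with a Gaussian tuning
  curve over path position; field centers are evenly spaced with jitter so
  the track is covered. Defaults: peak 80 Hz, field sd 8 cm, baseline 1 Hz.
  A "unit" here is a place-modulated multiunit amplitude cluster, not a
  sorted single cell — clusterless decoding consumes every threshold
  crossing, and 6 ms bins are only informative if the population emits
  ~1 spike per bin, the regime the original 40+-tetrode sessions operated
  in. Marks are the cluster center (uniform in [100, 350]⁴ ADC, minimum
  pairwise separation 100 = 5× the mark noise sd 20 within a group) plus
  isotropic Gaussian noise, matching the σ = 20 kernel bandwidth.
* **LFP**: unit-RMS 1/f-shaped Gaussian noise at 1,500 Hz plus 80 ms
  200 Hz bursts under a fast-attack Tukey(0.25) envelope at 6× RMS peak
  amplitude. The Tukey attack (10 ms) keeps "burst onset" well defined at
  the 20 ms accuracy scale; in vivo ripples likewise start abruptly. The
  first 15 s are injection-free so the detector's baseline window is clean.

What passing fixtures do **not** show about real data: no theta phase
precession, bursting, replay sequences with internal structure, electrode
drift, overlapping/unstable mark clusters, chewing or movement artifacts in
the LFP, or behaviourally realistic occupancy biases. A "hard" direction
for robustness work is simply lowering `cluster_separation` toward the mark
noise sd.

## Sizes, numerics, determinism

* Default synthetic session: 10 min (5 min encoding / 5 min decoding),
  chosen so a full replay plus offline summary completes in about a minute
  on one CPU while leaving ~37,000 movement-period decoding bins for the
  error statistics.
* Posterior normalization is asserted to |Σ−1| < 1e−9 after every step;
  KDE agreement with the brute-force oracle is required to 1e−10 relative;
  the chained filter matches an independently coded reference to 1e−10
  absolute.
* Tie-breaks: the offline MAP takes the lowest bin index and flags exactly
  uniform rows; merged streams order equal timestamps LFP → position →
  spikes (the LFP drives the clock, so it must advance first).
* All randomness flows through one seeded `numpy` generator per fixture;
  replaying the same inputs and configuration yields byte-identical record
  files (hash-verified in tests). Binary records are little-endian
  `struct`-packed payloads behind a 4-byte record id, with a JSON sidecar
  carrying the schemas so files are self-describing.

## Open-ended choices made here

* The record fields `cred_int_post`, `cred_int_lk` and `state_labels` that
  a live deployment logs are not computed — their definition is not
  specified anywhere; the record schema is extensible where they would go.
* The spike-collection delay and bin size are independent free parameters;
  their sum (36 ms with the defaults) is the effective spike incorporation
  latency.
* Task-state transitions are scheduled by time. Visit-count scheduling
  would need behavioural bookkeeping that adds nothing to the decoding
  path; the boundary is a config scalar.
* The decoder steps across the whole session so the bin lattice tiles the
  full LFP span; before the models freeze the likelihood is uniform (there
  is no model yet) and posteriors simply follow the prior. Event
  evaluation runs only after the freeze.
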