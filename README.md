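# replaydecoder

Streaming-replay implementation of an online **clusterless state-space
decoder** for hippocampal position, with sharp-wave-ripple (SWR) detection
from LFP and closed-loop-style detection of **remote spatial
representations** (decoded content away from the animal's actual location).
It is written for systems-neuroscience users who want to prototype, test and
characterize a real-time decoding pipeline deterministically from files —
the same stages a live closed-loop rig runs, replayed sample by sample from
CSV/HDF5 instead of a network stream.

## The model

Position is decoded from *unsorted* threshold-crossing spikes. Each spike on
electrode group *i* (e.g. a tetrode) carries a mark **m** — a vector of
waveform features, typically per-channel peak amplitudes. The decoder keeps
a posterior over linearized track bins *x* and updates it every time bin
Δt (6 ms by default) with the recursive Bayesian filter

    p(x_k | ΔN_k, {m}) ∝ p(x_k) · p(ΔN_k, {m} | x_k),
    p(x_k) = Σ_{x_{k-1}} p(x_k | x_{k-1}) p(x_{k-1} | data)

with a row-stochastic transition model (uniform / identity / Gaussian
random walk). The clusterless likelihood multiplies over electrode groups
and over each group's spikes in the bin:

    p(ΔN_k, {m} | x) ∝ Π_i [ Π_j λ_i(x, m_j) Δ ] · exp(−Λ_i(x) Δ)

where a spikeless group contributes only its no-spike factor
exp(−Λ_i(x) Δ). The intensities come from a stored-sample encoding model:

    λ_i(x, m) = μ_i · p_i(x, m) / π(x)        (joint mark intensity)
    Λ_i(x)    = μ_i · p_i(x) / π(x)           (ground process intensity)

During learning nothing is fitted — each (mark, position-bin) pair is
stored. At decode time p(x, m) is estimated on the fly with a Gaussian
kernel in mark space (bandwidth σ, default 20 ADC units): every stored mark
gets weight w_o = exp(−a_o²/2σ²)/(σ√2π) with a_o² the squared Euclidean
mark distance, and the weighted histogram of stored position bins, divided
by the stored count, is the density. π(x) is the movement-period occupancy,
p_i(x) the stored-spike position histogram, μ_i the group's mean rate.

Around the decoder:

* **Ripple detector** — causal band-pass (150–250 Hz) of each LFP channel,
  power via a causal low-pass of the squared band signal, z-scored against
  a frozen baseline; events open at z ≥ threshold (typically ≥ 3) and close
  on return to the end threshold.
* **Event detector** — every posterior update, the trailing 36 ms of
  posteriors is averaged and renormalized; a remote representation fires
  when >40% of that mass is in the target region, <20% in the off-target
  region, the animal is within 17 cm of the central box, and ≥2 electrode
  groups showed spatially specific spiking in the window.
* **Synthetic sessions** — a seeded generator produces a two-arm-maze
  trajectory (205 cm, 41 five-cm bins), place-modulated Poisson spiking
  with Gaussian mark clusters, and 1/f LFP with ripple-band bursts at known
  times, so every stage can be validated against ground truth.

## Worked example

```bash
decode simulate --out-dir demo --seed 3 --duration 120 --task1-end 60
```

then replay it through the full pipeline:

```python
import numpy as np
from replaydecoder import SessionConfig, run_session, decode_offline
from replaydecoder.ripples import RippleConfig

cfg = SessionConfig(
    spikes_path="demo/spikes.csv", lfp_path="demo/lfp.csv",
    position_path="demo/position.csv", output_path="demo/records.bin",
    task1_end_s=60.0,
    ripple=RippleConfig(z_threshold=25.0),  # separable threshold for fixtures
)
report = run_session(cfg)
print("spikes encoded (task 1, movement):", report.spikes_encoded)
print("spikes decoded (task 2):          ", report.spikes_decoded)
print("posterior records:                ", report.n_posterior_records)
print("ripples detected:                 ", report.n_ripples)

truth = np.load("demo/truth.npz")
df = decode_offline("demo/records.bin", truth["frame_times_s"], truth["frame_bin"])
t2 = df[df.task_state == 2]
moving = t2[np.interp(t2.bin_timestamp_r / 30000,
                      truth["frame_times_s"], truth["frame_speed"]) >= 4.0]
print("median decoding error (movement): %.1f cm" % moving.error_cm.median())
```

which prints:

```
spikes encoded (task 1, movement): 9074
spikes decoded (task 2):           12050
posterior records:                 19994
ripples detected:                  10
median decoding error (movement): 10.0 cm
```

The first minute (task 1) movement-period spikes build the encoding models;
at the task boundary the models freeze and every subsequent 6 ms bin yields
a normalized posterior over the 41 bins, written to `records.bin` together
with likelihoods, ripple events and any representation events. All 10
injected ripple bursts are recovered, and the median movement-period
decoding error is two position bins (10 cm) with 8 tetrode groups.

`decode ripples --lfp demo/lfp.csv --z-threshold 25` runs the SWR detector
standalone; `decode records-to-csv --in demo/records.bin` converts the
binary log to labeled CSVs; `decode config --defaults` prints the full
session YAML schema.

## Layout

| module | role |
| --- | --- |
| `types`, `sources`, `records` | sample objects, replayable CSV/HDF5 sources with merge, binary results log |
| `linearization` | 2D→1D track projection, bin grid, running speed |
| `encoder` | stored-sample encoding model, kernel density, intensities |
| `decoder` | time-bin windows, clusterless likelihood, forward filter |
| `ripples` | causal SWR detection chain |
| `events` | remote-representation gating |
| `simulate` | ground-truthed synthetic sessions |
| `session`, `config`, `cli` | single-process replay loop, YAML config, `decode` CLI |

See `docs/methods.md` for the modelling choices, parameter defaults and
what the synthetic fixtures do and do not establish.
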