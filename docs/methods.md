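# Methods

This note documents the models, parameter choices and numerical decisions
behind `flyssvep`, and what the synthetic test bed does and does not
establish about real recordings.

## Stimulus model

Trials are 20 s trains of 200 events at F1 = 10 Hz with a 50% duty cycle
(50 ms flashes), separated by 3 s pauses. Sequence positions are 1-based,
so "every fifth event" means positions 5, 10, …, 200; each trial therefore
opens with four carriers before the first deviant. Deviant trial types:

* **phasic** — deviants at exactly the nominal positions (2 Hz).
* **jittering** — each nominal position p is displaced by
  `round(N(0, jitter_sd))` with `jitter_sd = 1.0` position by default (the
  distribution is specified as normal and centred; its width is a free
  parameter here). Offsets that would put a deviant at or before the
  previously accepted deviant, or before position 1, are redrawn (up to 100
  times, then the nominal position is kept); deviants displaced past the
  end of the trial are dropped. Under this rule the realized gap between
  deviants is modal at 4 carriers with 3 and 5 next most likely, and the
  mean gap converges near 3.99 (the generator's Monte-Carlo check bounds it
  in [3.8, 4.1]).

Counterbalancing assigns each color the deviant role in an equal number of
trials (±1 when the count is odd, the extra trial's color randomized);
trial order is shuffled by the seeded generator.

## Forward LFP model

The simulator is a statistical forward model, not a biophysical one. Each
stimulus event adds an evoked kernel to every channel:

```
lfp[c, t] = pink(c, t) + line(c, t) + Σ_events  profile(c) · gain(event, c) · k_color(t − onset)
```

* **Kernel** `k` — biphasic difference-of-exponentials: a fast positive
  lobe (rise 4 ms, decay 12 ms) minus a 0.2-weighted slower rebound (rise
  10 ms, decay 25 ms), onset latency 20 ms, support 75 ms, normalized to
  unit peak-trough and scaled per color (green 1.0, blue 0.9 a.u.). The
  total span (95 ms) stays inside one 100 ms inter-stimulus interval, so
  successive responses never overlap and the noise-free peak-trough of an
  epoch equals the configured amplitude exactly — the basis of the
  truth-recovery tests. The rebound weight was chosen so the kernel keeps
  substantial net area (low-frequency content), which places the oddball
  train's low-frequency spectral peak at the 2 Hz fundamental rather than
  its harmonics.
* **Channel profile** — signed saturating taper `sign(d)·tanh(|d|/4)`
  where `d = reversal_channel − channel`: positive inboard, negative
  outboard, exactly zero at the reversal channel (default channel 12,
  within the 11–14 range typical of good insertions). Zero amplitude at
  the reference channel also makes re-referencing exact for the evoked
  component.
* **Gain table** — multiplicative gains indexed by (region group, role,
  state). Defaults encode the qualitative findings the simulator must
  reproduce, as configuration rather than as claims: carrier gain 1.0 in
  every region and state; deviant gains 0.75 / 0.85 / 0.95 in
  central / intermediate / peripheral; the central deviant gain is further
  multiplied by 0.6 during deep sleep. Carrier responses additionally carry
  an order-dependent modulation outside the central region (green carriers
  1–4 after a deviant: ×[1.20, 1.08, 1.00, 0.92]; blue: ×[0.80, 0.92, 1.00,
  1.08]) — a color-change effect with opposite sign per color, absent
  centrally. This modulation both provides the carrier-order contrast with
  a recoverable effect and gives the 5-event oddball cycle a smooth
  amplitude envelope whose fundamental dominates the F2 line at 2 Hz.
* **Noise** — per-channel 1/f (pink) background (SD 0.05 a.u.) mixed
  half-and-half with a steeper shared component across channels
  (synchronized slow activity), plus 50 Hz line noise (amplitude 0.02,
  harmonics at half amplitude below Nyquist, random phase per channel).
  The evoked/background ratio reflects the strong SSVEPs of this
  preparation; it is configurable.

Sampling rate: the `SimConfig` default is 1 kHz and the pipeline default
200 Hz (the long-recording analysis rate); the model is band-limited well
below 100 Hz, so simulating at the 24 kHz acquisition rate adds cost
without changing any analysis quantity. All randomness derives from one
master seed via per-component substreams; identical config + seed gives
bitwise-identical recordings.

## Behavior model

Wake and sleep bouts alternate (starting awake), with lognormal durations
(σ = 0.5) whose medians target 11.2 min (wake) and 12.8 min (sleep) —
the values observed under continuous visual stimulation. Sleep draws are
truncated above 5.5 min so every generated sleep bout is scorable under
the 5 min immobility criterion; wake draws above 1 min. Generated medians
converge within 5% of the targets over a few hundred bouts; the residual
upward bias from truncation stays inside that band. Movement is rectified
Gaussian noise (mean ≈ 0.8) during wake and sensor noise (0.005) during
sleep. "Deep" sleep is flagged for all sleep-bout samples except the
bout's first and last minute — the mid-bout period when rhythmic proboscis
extensions concentrate — and the gain table reads this flag.

Proboscis activity: rhythmic spells (4–8 extensions of 0.4 s at 1.5 s
intervals, amplitude 1.0) are placed as a Poisson process at 0.8/min in
deep sleep, 0.15/min in light sleep and 0.08/min in wake; singular 2.5 s
"reaches" (amplitude 0.8) occur at 0.3/min during wake only.

## Analysis decisions

* **Epoch window** [0, 100) ms post-onset — one inter-stimulus interval,
  guaranteeing non-overlapping epochs; amplitude is the unsigned max−min
  in the window (the trough may precede the peak).
* **Reversal detection** — per-channel average ERPs over 0–100 ms (up to
  2000 events); the dominant deflection is the signed extremum of the
  average waveform; candidate channels are those adjacent to a sign flip,
  and the one with the smallest peak-trough amplitude wins, ties breaking
  to the lower channel number. No sign flip anywhere raises an error,
  mirroring the exclusion of insertions without a visual response.
* **Line-noise removal** — 1 Hz-wide IIR notches at 50 Hz and each
  harmonic strictly below Nyquist (at 200 Hz only 50 Hz itself),
  zero-phase filtered. Narrow notches leave the 2 and 10 Hz analysis bands
  untouched (< 1% change).
* **Pipeline order is fixed** (downsample → notch → reversal detection →
  re-reference → regions) and re-running on preprocessed data is refused.
  Only the first 6 h of longer recordings are analyzed by default.
* **Normalization pool** — all events of a color within the analyzed span,
  per fly and channel, roles pooled. Computed in float64 so the
  mean-equals-one identity holds to machine precision even on float32
  recordings.
* **Mid-minute centering** — for a bout with M whole minutes, the middle
  minute starts at minute `floor((M−1)/2)` (so a 21 min bout's mid-sleep
  is minute 11, and a 5 min bout's five windows tile it exactly). Windows
  are placed first/last before middle and overlapping middles dropped,
  which can only trigger if the sleep criterion is configured below 5 min.
* **Wake segments** come from the wake bout immediately preceding each
  sleep bout; wake bouts under 2 min contribute none.
* **PE classification thresholds** (extension threshold 0.3, merge gap
  0.1 s, spell gap 5 s, ≥ 3 events per spell, reach > 1.5 s) are
  configuration defaults; the original video-based classifier is out of
  scope, and the pipeline consumes a 1-D extension-distance trace.
  Inter-extension sampling windows carry a 50 ms guard margin and must be
  at least one stimulus period long.
* **Spectra** — single-taper (boxcar) periodogram per 20 s trial span
  (0.05 Hz native resolution), each normalized to unit total power, then
  averaged across trials. The event-onset grid is sample-aligned by
  rounding, which at 200 Hz is exact for 10 Hz trains.
* **Statistics** — per-fly group means only; one-way ANOVA
  (`scipy.stats.f_oneway`) with Bonferroni multiplication over the
  pairwise family within each contrast. With two groups the omnibus F
  equals t² of the pooled-variance t-test (cross-checked in the tests).
  Zero within-group variance falls back to exact-equality handling with a
  logged warning.

## What the synthetic test bed shows — and does not

Passing tests establish that the pipeline recovers what the forward model
encodes: the configured reversal channel (≥ 95% of seeds at default
noise), truth bout boundaries to one scoring bin on noise-free traces,
noise-free amplitudes to < 1e−6 relative error, F1/F2 spectral peaks at
10 and 2 Hz, and the direction of the state-dependence result — no carrier
wake/sleep difference, a significant central deviant sleep decrement —
over 8 simulated flies. They do not establish effect sizes in real flies:
the gain values are placeholders chosen for parameter-recovery testing,
the noise model omits movement artifacts, electrode drift and
non-stationarity, the bout model omits circadian structure, and the
proboscis model omits grooming and feeding movements. Analyses of real
recordings exercise the same code paths via the truth-free container mode.

## Problem sizes used in the shipped checks

Tests and the acceptance script run on deliberately small simulations
chosen as the smallest sizes at which each property is stable: 20 trials
(~7.7 min) for spectra, 60 s recordings for reversal recovery across 20
seeds, 2 h of behavior for bout round-trips, and 5 pipeline replicates of
8 flies × 48 min at 200 Hz for the state-dependence recovery. Larger runs
only tighten the same statistics.
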