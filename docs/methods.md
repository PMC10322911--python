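# Methods

This note documents the models, the numerical choices behind them, what
the synthetic data do and do not emulate, and the known limitations of
the detection benchmark.

## Synthetic LFP sessions

A session is two channels at 500 Hz (or 20 kHz for the raw path): a
hippocampal *ripple channel* and a neocortical *noise reference*.

**Sleep architecture.** An alternating-renewal chain NREM → REM → WAKE →
NREM with exponential dwell times (benchmark means 480 / 60 / 90 s,
starting in NREM, giving ≈75% NREM over 30 min). States with zero dwell
mean drop out of the cycle, so a single-state recording is a valid
degenerate configuration. The session begins in NREM because thresholds
are calibrated on the opening 60 s of a rest recording.

**Background.** Gaussian 1/f^α noise (α = 1, flat below 1 Hz), broadband
SD 40 µV, scaled per state by 1.0 (NREM), 0.8 (REM), 1.2 (WAKE). The
state scaling is deliberate: it makes a fixed online threshold
calibrated in NREM misbehave in WAKE, as thresholds do across real state
changes.

**Ripples.** Poisson events within NREM epochs only (benchmark rate
0.35/s of NREM), with a 100 ms minimum peak separation so ground-truth
events never overlap. Each event is a Hanning-windowed sinusoid (centre
frequency uniform on 160–230 Hz, duration uniform on 30–90 ms, random
phase) riding on a negative half-cosine sharp wave 1.5× as long. The
envelope peak amplitude is expressed in units of the SD of the
band-pass-filtered (150–250 Hz) NREM background on the ripple channel —
the baseline ripple-band RMS — so that "a 5 SD ripple" means the same
thing across seeds and threshold multipliers transfer. Amplitudes are
log-normal with median 5 SD and σ_ln = (ln 5 − ln 3)/z₀.₉₀ ≈ 0.3986,
placing 10% of events below 3 SD (clipped to [1.5, 40] SD).

**Artifacts.** Brief broadband transients (Hanning-enveloped white
noise, 4–10 ms, amplitude 8 SD) added to *both* channels at 0.05/s.
Their duration is deliberately below the 20 ms event floor — electrical
transients are fast — so the post hoc duration limits exclude them,
while the online path rejects them through the noise-channel veto. The
opening 60 s are kept artifact-free: experimenters calibrate on a
curated quiet baseline.

**What the generator does not emulate.** Theta/spindle rhythms, EMG
contamination, electrode drift, non-Gaussian heavy-tailed background,
ripple frequency chirps, and any coupling between behavior and
electrophysiology. Passing tests show the pipeline's internal
consistency under a controlled signal model, not performance on real
recordings — see "Benchmark limitations" below.

## Online detection

Forward-only 4th-order Butterworth band-passes (150–250 Hz ripple,
80–500 Hz noise reference; at the 500 Hz online rate any edge at or
above Nyquist is clamped to 0.95×Nyquist = 237.5 Hz, since a filter edge
at Nyquist is ill-defined), followed by a trailing 10 ms sliding RMS.
Thresholds are `mean + k·SD` of the baseline RMS trace (default k = 4
on both channels; the first 0.5 s of the trace is dropped as filter
settle). Each supra-threshold ripple-RMS excursion produces exactly one
log entry decided at its first sample: LOCKED_OUT within 250 ms of the
previous FIRED trigger (the lockout must cover the 100 ms stimulation
train), VETOED if the noise-reference RMS is concurrently
supra-threshold (point-sample veto, no retroactive cancellation — the
simplest causal reading), otherwise FIRED. Trigger time = crossing time
+ 10 ms processing latency. Streaming is chunked with filter and RMS
state carried across boundaries, so truncating the input can never
change already-emitted triggers; a whole-vector batch oracle in the test
suite must reproduce the trigger indices exactly.

MFB stimulation is fourteen 1 ms, 100 µA pulses at 140 Hz per trigger
(nominal 100 ms span); the VHC protocol is a single 0.5 ms pulse
(5–15 V). `render_stimulus_artifact` adds saturating square transients
on both channels so the post hoc path can be exercised under
stimulation contamination.

## Post hoc detection

Raw 20 kHz data are decimated ×40 with a polyphase anti-aliasing FIR.
The 500 Hz trace is band-passed with a zero-phase (forward–backward)
Butterworth, and ripple power is taken as the squared magnitude of the
analytic (Hilbert) envelope smoothed by a centred 10 ms moving average.
The raw squared signal is *not* usable here: with the ripple band
abutting Nyquist at 500 Hz, squaring aliases the 2f component down to
25–180 Hz beats that repeatedly dip below the boundary criterion and
fragment genuine events into sub-20 ms pieces; the analytic envelope has
no 2f term. (`normalized_squared` still provides the plain
square-and-z-score transform.)

The power trace is z-scored against *background* moments estimated by
iterative clipping: samples above `mean + 2·peak_z·SD` are excluded and
the moments re-estimated to convergence. Clipping well above the peak
criterion leaves the null mass untouched (the iteration is stable) while
removing the event tail, whose log-normal amplitudes would otherwise
inflate the SD ~2.5× and make "3 SD" drift with event density. Events
are local maxima with z ≥ 3 whose edges are walked outward to the
nearest sub-2-SD sample, at most 150 ms away; overlapping candidates are
merged (optionally also those within `merge_gap_s`, default off, since
gap-merging chains background excursions); events outside 20–200 ms
(inclusive) are dropped. With stimulation trains supplied, ±10 ms around
every pulse is blanked: excluded from the moments and barred from
hosting peaks or event extent. Filter ring just outside a blanked window
can still leave residual events beside large artifacts — a fixed
blanking width cannot remove energy the filter has already smeared.

Two further practical properties of this operating point, measured by
the test suite: on event-free Gaussian noise the 3/2-SD envelope
criterion emits ≈0.13 false events/s (spurious 20–30 ms power
excursions; in laboratory practice these are what manual curation
removes), and ≥95% of ≥5 SD ground-truth events are recovered on the
benchmark. When a recording mixes sleep states, a per-sample validity
mask (the NREM mask, in the benchmark) restricts both the moments and
the event peaks: a single z-scale across states with different
background variance would otherwise flood the gold standard with WAKE
power fluctuations.

## Scoring

A FIRED trigger matches a reference event if its trigger time lies in
`[onset, offset + 50 ms]` (the trigger necessarily fires after onset,
and processing latency can push it just past a short event's offset).
Assignment is greedy nearest-onset, one-to-one, ties to the earlier
event. PD/FPD/MD percentages share the union denominator
`n_PD + n_FPD + n_MD`, so they sum to 100 exactly. Benchmark scoring
restricts both triggers and the gold standard to NREM epochs using
simulator ground-truth labels, standing in for the sleep scoring and
curation of conventional analysis. Latencies (trigger − event onset) are
histogrammed at 1 ms over at least [0, 50] ms; negative latencies are
counted and flagged, never dropped.

## Behavior

Per-tone freezing is `clip(test_cs · exp(−rate·(session−1)) + ε, 0, 100)`
with truncated-Gaussian per-tone noise (the per-tone noise model is a
modelling choice; only session-level structure is constrained by the
protocol of 20 tones/day in 5-tone blocks, ≤7 days). The packaged
fixture uses decay rates NS 0.30, OL 0.32, CL 0.60 per session (CL = 2×
NS), test CS+ ~ N(70, 10) clipped to [40, 95], tone noise SD 5, nine
animals per group, and fear-recovery increments at the renewal / remote /
reinstatement probes of 25/20/25 (NS), 25/18/22 (OL), 5/3/8 (CL)
percentage points — chosen once to straddle the remission criterion and
reproduce the qualitative group ordering (faster CL extinction, little
CL recovery). Remission is the first day whose first-block reduction is
*strictly* below 20% of the test CS+ level; later sessions are ignored
(training stopped at remission); animals not remitting within 7 days are
censored at 7. Note an edge case: a zero-noise decay at rate ln(5)/2
lands exactly on 20% on day 3, where the strict inequality makes the
outcome a floating-point coin flip — calibrations should avoid the exact
boundary.

## Benchmark operating point and limitations

On the pinned 10-seed benchmark the pipeline measures PD 54.4%,
FPD 9.3%, MD 36.3% (union partition), modal trigger latency 24 ms
(envelope 15–27 ms for high-SNR events), and 97% recovery of ≥5 SD
events by the post hoc detector. Reported closed-loop systems of this
design achieve PD ≈ 80% with FPD ≈ 8% and MD ≈ 12% on real recordings.
The gap is a property of the synthetic signal model, not of either
detector implementation, and is worth stating precisely:

- In Gaussian 1/f background, ripple-band power fluctuates with heavy
  (Gamma-like) tails, so a gold standard operating at 3 SD peak / 2 SD
  boundary necessarily detects ≈0.13 background excursions per second
  alongside true events near the 3 SD amplitude floor.
- The online path is a point-sample threshold on a trailing 10 ms RMS:
  it has no duration selectivity, and its calibration baseline contains
  ripples, which inflate the RMS-trace SD and put the k = 4 threshold
  near a 4.3 SD amplitude floor. Lowering k closes the sensitivity gap
  but fires on every short background excursion the offline duration
  floor rejects (k = 3 triples the trigger count), so no k aligns the
  two detectors on this background.
- On real hippocampal LFP the inter-event ripple band is far quieter
  than Gaussian-matched noise, and the published gold standards are
  manually curated; both effects collapse the floor mismatch that
  dominates MD here.

The remaining regime properties — the partition summing to 100, the
latency envelope, the veto rejecting shared artifacts, stimulation
protocol structure, streaming/batch equality, and all behavior metrics —
are reproduced and tested. Problem sizes throughout (30 min sessions,
10 LFP seeds, 20 behavior replicates) were chosen as the smallest runs
that make the stochastic summaries stable to ~1 percentage point.
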