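# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `nirsdoc`, and what the synthetic cohorts do and do not
establish about real recordings.

## Study paradigm and montage

Each simulated subject completes two runs, one per auditory condition —
subject's own name (SON, passive) and motor imagery (MI, active). A run is
60 s of baseline followed by 8 blocks of 30 s task + 40 s recovery (620 s);
runs are separated by 60 s and their order is randomised per subject
(`run_order: fixed` forces SON first). Event times are seconds from
recording start, and all windows are half-open `[start, end)` on the sample
grid with onsets snapped to the nearest sample, so every derived number is
exactly reproducible.

The montage has 3 sources and 2 detectors over the left prefrontal cortex
wired into 5 channels at 3 cm separation. Which 5 of the 6 possible
source-detector pairs are wired is a free choice; the default pairs D1 with
all three sources and D2 with S2 and S3, with schematic coordinates placed
so each wired pair is exactly 3 cm apart. The pairing is recorded in the
montage object and in every written recording, so an alternative layout is a
data edit, not a code change.

## Hemodynamic model

The evoked response is a unit-peak single-gamma kernel
g(t) ∝ (t/p)^k · e^{k(1−t/p)} with peak latency p = 6 s, shape k = 4 and an
optional undershoot (a second gamma at 2p scaled by the undershoot ratio,
default 0.1); the combined kernel is rescaled in time and amplitude so it
still peaks at exactly p with value 1. The block regressor (boxcar ⊛ kernel)
is normalised to unit peak, so a profile amplitude *is* the evoked peak in
µM. Group × condition amplitudes encode the qualitative phenomenology the
assessment relies on:

| group | SON HbO | SON HbR | MI HbO | MI HbR |
|-------|---------|---------|--------|--------|
| HC    | −0.50   | −0.10   | −0.30  | −0.06  |
| MCS   | +0.40   | +0.08   | +0.20  | +0.04  |
| VS    | +0.80   | +0.16   | +0.30  | +0.06  |

i.e. amp(VS) > amp(MCS) > 0 > amp(HC) for SON on both chromophores, a more
strongly negative HC response to SON than to MI, and small positive patient
MI responses. No physical amplitudes are published for this paradigm, so
these are free parameters chosen once; all quantitative claims rest on sign
and ordering recovery, never on absolute µM values. HbR amplitudes are
simulated independently (not forced to a fixed fraction of HbO) at 20 % of
the HbO amplitude — small enough that CBSI (below) attenuates but never
sign-flips the evoked response.

## Noise and artifacts

Per channel and chromophore, independently: cardiac (1.1 Hz, 0.4 µM),
respiratory (0.25 Hz, 0.3 µM) and Mayer-wave (0.1 Hz, 0.2 µM) sinusoids with
random phases, a random-walk drift (0.05 µM·√s⁻¹ increments) and white noise
(1.0 µM per sample). Each sinusoid's frequency is jittered ±10 % per
channel: real physiological rhythms drift, and an exactly 0.1 Hz Mayer wave
would be phase-locked to the 70 s block period (7.0 cycles), making every
epoch of a run see the same nuisance value and invalidating the independence
that pooled rank tests assume. HbR receives the same noise structure at 50 %
amplitude.

Motion artifacts share event times across channels and chromophores, as a
head movement would: spikes (one-sample rise, exponential decay τ = 0.5 s,
0.3 per minute) and persistent steps (0.05 per minute), both at 20 µM with
random sign, appearing on HbR at 50 % of the HbO amplitude — the common-mode
geometry CBSI exploits. White-noise amplitude was set so the single-epoch
feature SNR is ≈ 1: single trials are ambiguous and 8-block averaging is
what makes response signs clearly recoverable, which is the reason the
paradigm block-averages at all.

## Preprocessing conventions

- **I₀ definition.** I₀ is the *geometric* mean of intensity over the
  reference window (whole series by default, first 60 s selectable), i.e.
  the arithmetic mean of log-intensity, which makes ΔOD average exactly to
  zero over that window. An explicit I₀ can be passed instead, e.g. to
  invert a forward simulation exactly (round-trip error < 1e-9 relative).
- **Extinction coefficients** ship as an editable table
  (cm⁻¹·µM⁻¹, decadic, standard compiled hemoglobin spectra at 760/830 nm);
  no result depends on the specific values, only on forward/inverse
  consistency. DPF defaults to 6.0 at both wavelengths; d to 3 cm.
- **Filtering** uses a 3rd-order Butterworth band-pass (0.01–0.2 Hz) run
  forward and backward. Initial conditions follow Gustafsson's method
  rather than signal-extension padding: with a 0.01 Hz high-pass edge,
  padded two-pass filtering leaks minute-scale edge transients an order of
  magnitude above the stopband floor, while the Gustafsson solution keeps a
  600 s 1.1 Hz tone below 1 % residual RMS and passband tones within
  0.1 dB.
- **CBSI** is applied per full recording, before z-scoring, and can be
  disabled (`--no-cbsi`). Strict CBSI forces HbR′ = −HbO′/α, which is
  mathematically incompatible with same-sign HbO/HbR group averages; the
  switch lets users reproduce either reading of the processing chain. Under
  the default noise model (α ≈ 2) CBSI attenuates the same-sign evoked
  signal by roughly a factor 4 but preserves its sign and group ordering.
  On a *noise-free* subject, CBSI cancels the perfectly proportional
  HbO/HbR signal exactly, so noise-free sign-recovery checks run with CBSI
  disabled.
- **Trial rejection** happens at the epoch level, after z-scoring. Epochs
  are scored as max(|z|)/5 and max(|Δz|)/3 against a *robust* scale — the
  Gaussian-consistent MAD of the channel's pooled epochs — because a large
  motion transient inflates the plain standard deviation enough to mask
  itself (a single filtered 20 µM step caps its own classical z at ≈ 7, two
  steps at ≈ 5). With the robust scale, uncorrected steps are rejected
  essentially always while ≈ 2 % of artifact-free trials are lost. A trial
  is dropped for a channel when either chromophore trips the threshold. The
  thresholds are declared stand-ins for a qualitative clinical criterion
  ("serious artifacts that could not be corrected") and are configurable.
- **z-scoring** is per channel and chromophore over the full recording, and
  precedes segmentation.

## Features and statistics

The mean concentration is the arithmetic mean of the baseline-corrected
block curve over [2, 20) s; the fitting slope is the OLS slope over
[5, 15) s. On the 10 Hz grid the baseline window [−3, 0) contains samples
−3.0 … −0.1 s, so e.g. a unit time-ramp epoch is shifted by +1.55 s (the
grid mean), not the continuous-limit 1.5 — the half-open grid convention is
applied consistently everywhere rather than per-case.

Features can be computed per retained epoch (default) or on the
block-averaged curve; whether a clinical analysis pools epochs × channels or
uses one value per subject changes the effective sample size enormously, so
every test result carries its mode label and no equivalence between modes is
implied. The Mann-Whitney U test uses midranks, the tie-corrected normal
approximation without continuity correction (Z < 0 when the first sample
ranks lower), and an exact enumerated p-value for small tie-free samples;
Kruskal-Wallis uses the χ²_{k−1} reference with tie correction, defining
H = 0, p = 1 when all pooled values are identical. No multiple-testing
correction is applied by default (a Benjamini-Hochberg helper is provided,
off by default). The KS normality screen estimates the reference normal's
parameters from the sample, which makes it conservative — it errs toward
keeping the rank tests.

## Verification scale and determinism

The acceptance checks run at desk scale on one CPU: the type-I error of the
full chain (simulate → preprocess → features → Mann-Whitney) is estimated
from 70 null cohorts of 11 subjects (> 1000 contrasts, observed rate ≈ 0.05
within [0.03, 0.07]), and phenomenology recovery from 20 cohorts at the
clinical group sizes n = {15, 4, 14}. One master seed drives everything;
per-subject streams derive deterministically from (seed, subject index), so
identical configurations reproduce outputs byte for byte.

## What the synthetic cohorts do not show

The generator emulates block-locked gamma-kernel responses with stationary
sinusoidal/random-walk nuisance and idealised spike/step artifacts. It does
not model photon transport, anatomical variability, scalp coupling changes,
serial autocorrelation of real hemodynamics, systemic physiology coupled to
the task (e.g. stimulus-locked blood-pressure responses), or non-stationary
artifact bursts. Passing tests therefore establish the *correctness of the
pipeline's operations and statistics under the stated model*, not the
clinical sensitivity or specificity of the assessment; the headline patient
statistics of the motivating study were computed on unreleased clinical
recordings and are not reproducible at desk scale.
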