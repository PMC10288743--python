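"""Seeded synthetic cohorts of block-design prefrontal fNIRS recordings.

The generator emulates the study conditions of the auditory assessment
paradigm: per subject, two runs (one per condition — the subject's own name,
SON, and motor imagery, MI), each consisting of 60 s baseline followed by
8 blocks of 30 s task + 40 s recovery, with runs separated by 60 s and run
order randomised per subject.

Ground-truth hemodynamics are a unit-peak gamma-kernel block response scaled
by signed group × condition amplitudes: healthy controls carry the
"inverted" (negative) response on both chromophores, patients carry positive
responses, larger in the vegetative-state (VS) than the minimally-conscious
(MCS) group for SON.  Physiological nuisance (cardiac, respiratory,
Mayer-wave sinusoids with random phases, random-walk drift, white noise) and
motion artifacts (exponentially decaying spikes and persistent steps, shared
across channels as a head movement would be) are added on top, and the
result is pushed through the forward modified Beer-Lambert law to raw
dual-wavelength optical intensities.

Everything is drawn from seeded generators: identical specs (including the
seed) produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from nirsdoc.io_formats import (
    CONDITIONS,
    EventSchedule,
    HbTimeSeries,
    Montage,
    OpticalRecording,
    ValidationError,
    default_montage,
    write_events,
    write_recording,
)
from nirsdoc.preprocess import PreprocessConfig, extinction_matrix


@dataclass
class ResponseProfile:
    """Evoked-response shape for one group × condition cell.

    ``amp_hbo`` / ``amp_hbr`` are the signed evoked peak amplitudes in µM
    (the block regressor has unit peak, so the amplitude *is* the peak).
    A negative amplitude encodes the inverted response pattern.
    """

    group: str
    condition: str
    amp_hbo: float
    amp_hbr: float
    hrf_peak_s: float = 6.0
    hrf_undershoot_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.hrf_peak_s <= 0:
            raise ValidationError("hrf_peak_s must be positive")
        if not (0 <= self.hrf_undershoot_ratio < 1):
            raise ValidationError("hrf_undershoot_ratio must lie in [0, 1)")
        if not np.isfinite([self.amp_hbo, self.amp_hbr]).all():
            raise ValidationError("amplitudes must be finite")


@dataclass
class NoiseSpec:
    """Amplitudes (µM) and rates of the simulated nuisance components.

    Sinusoidal terms get an independent random phase per channel and
    chromophore; motion artifacts share their event times across channels
    (a head movement moves every optode) and appear on HbR scaled by
    ``artifact_hbr_ratio`` with the same sign, which is the geometry CBSI
    exploits.  Defaults put the single-epoch feature SNR near 1 so that
    8-block averaging is what makes the response signs clearly recoverable.
    """

    cardiac_freq_hz: float = 1.1
    cardiac_amp: float = 0.4
    respiratory_freq_hz: float = 0.25
    respiratory_amp: float = 0.3
    mayer_freq_hz: float = 0.1
    mayer_amp: float = 0.2
    drift_scale: float = 0.05  # µM per √s random-walk increment scale
    white_sd: float = 1.0
    artifact_spike_rate_per_min: float = 0.3
    artifact_step_rate_per_min: float = 0.05
    artifact_amp: float = 20.0
    artifact_tau_s: float = 0.5
    artifact_hbr_ratio: float = 0.5
    hbr_noise_ratio: float = 0.5
    #: relative jitter of each sinusoid's frequency, drawn per channel; real
    #: cardiac/respiratory/Mayer rhythms drift rather than phase-locking to
    #: the 70 s block period
    freq_jitter: float = 0.1

    def validate(self, fs: float) -> None:
        for name in ("cardiac", "respiratory", "mayer"):
            f = getattr(self, f"{name}_freq_hz")
            if not 0 <= f < fs / 2:
                raise ValidationError(f"{name} frequency {f:g} Hz violates Nyquist ({fs / 2:g})")
        for name in (
            "cardiac_amp", "respiratory_amp", "mayer_amp", "drift_scale", "white_sd",
            "artifact_spike_rate_per_min", "artifact_step_rate_per_min", "artifact_amp",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def silent(self) -> "NoiseSpec":
        """A copy with every noise and artifact amplitude set to zero."""
        return replace(
            self, cardiac_amp=0.0, respiratory_amp=0.0, mayer_amp=0.0,
            drift_scale=0.0, white_sd=0.0,
            artifact_spike_rate_per_min=0.0, artifact_step_rate_per_min=0.0,
            artifact_amp=0.0,
        )


@dataclass
class ParadigmSpec:
    baseline_s: float = 60.0
    n_blocks: int = 8
    task_s: float = 30.0
    recovery_s: float = 40.0
    inter_run_gap_s: float = 60.0
    run_order: str = "random"  # random | fixed (SON first)

    @property
    def run_length_s(self) -> float:
        return self.baseline_s + self.n_blocks * (self.task_s + self.recovery_s)

    @property
    def total_duration_s(self) -> float:
        return 2 * self.run_length_s + self.inter_run_gap_s


def default_profiles() -> dict[tuple[str, str], ResponseProfile]:
    """Group × condition amplitudes encoding the reported phenomenology.

    For SON the evoked amplitude goes from negative (HC) through moderate
    positive (MCS) to largest positive (VS) on both chromophores; the HC
    response is more strongly negative for SON than for MI, and patient MI
    responses are small positive.
    """
    table = [
        ("HC", "SON", -0.5, -0.10),
        ("HC", "MI", -0.3, -0.06),
        ("MCS", "SON", 0.4, 0.08),
        ("MCS", "MI", 0.2, 0.04),
        ("VS", "SON", 0.8, 0.16),
        ("VS", "MI", 0.3, 0.06),
    ]
    return {
        (g, c): ResponseProfile(group=g, condition=c, amp_hbo=o, amp_hbr=r)
        for g, c, o, r in table
    }


@dataclass
class CohortSpec:
    """Full description of a simulated cohort; the seed is part of the spec."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 15, "MCS": 4, "VS": 14}
    )
    profiles: dict[tuple[str, str], ResponseProfile] = field(default_factory=default_profiles)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    mbll: PreprocessConfig = field(default_factory=PreprocessConfig)
    i0: float = 1.0
    sampling_rate_hz: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValidationError("subject counts must be non-negative")
        for group, n in self.n_per_group.items():
            if n == 0:
                continue
            for cond in CONDITIONS:
                if (group, cond) not in self.profiles:
                    raise ValidationError(f"no response profile for {group} × {cond}")
        self.noise.validate(self.sampling_rate_hz)


# ---------------------------------------------------------------------------
# paradigm and response kernel
# ---------------------------------------------------------------------------


def build_paradigm(
    paradigm: ParadigmSpec | None = None,
    rng: np.random.Generator | None = None,
) -> EventSchedule:
    """Two-run block schedule: 60 s baseline + 8 × (30 s task, 40 s recovery)
    per condition, runs separated by 60 s, order random unless fixed."""
    paradigm = paradigm or ParadigmSpec()
    order = list(CONDITIONS)
    if paradigm.run_order == "random":
        rng = rng if rng is not None else np.random.default_rng()
        if rng.random() < 0.5:
            order = order[::-1]
    elif paradigm.run_order != "fixed":
        raise ValidationError(f"unknown run_order {paradigm.run_order!r}")
    blocks = []
    start = 0.0
    for cond in order:
        for k in range(paradigm.n_blocks):
            onset = start + paradigm.baseline_s + k * (paradigm.task_s + paradigm.recovery_s)
            blocks.append((cond, onset, paradigm.task_s))
        start += paradigm.run_length_s + paradigm.inter_run_gap_s
    return EventSchedule.from_blocks(blocks)


def gamma_hrf(
    t: np.ndarray | float,
    peak_s: float = 6.0,
    undershoot_ratio: float = 0.0,
    shape: float = 4.0,
) -> np.ndarray | float:
    """Unit-peak single-gamma response kernel with optional late undershoot.

    The base kernel is (t/p)^k · exp(k (1 − t/p)), which peaks at exactly
    ``p`` with value 1; the undershoot subtracts ``undershoot_ratio`` times
    a second gamma peaking at 2p.  The combination is rescaled in time and
    amplitude so the delivered kernel still peaks at ``peak_s`` with value 1
    and is 0 at t = 0.
    """
    if peak_s <= 0:
        raise ValidationError("peak_s must be positive")
    if not (0 <= undershoot_ratio < 1):
        raise ValidationError("undershoot_ratio must lie in [0, 1)")

    def _gamma(u: np.ndarray, p: float) -> np.ndarray:
        u = np.maximum(u, 0.0)
        return (u / p) ** shape * np.exp(shape * (1.0 - u / p))

    def _raw(u: np.ndarray) -> np.ndarray:
        k = _gamma(u, peak_s)
        if undershoot_ratio > 0:
            k = k - undershoot_ratio * _gamma(u, 2.0 * peak_s)
        return k

    if undershoot_ratio > 0:
        grid = np.linspace(0.0, 4.0 * peak_s, 40001)
        vals = _raw(grid)
        i = int(np.argmax(vals))
        t_star, peak = float(grid[i]), float(vals[i])
    else:
        t_star, peak = peak_s, 1.0

    t_arr = np.asarray(t, dtype=float)
    out = _raw(t_arr * (t_star / peak_s)) / peak
    return out if out.ndim else float(out)


@dataclass
class GroundTruth:
    """Injected signal parameters for one simulated subject."""

    subject_id: str
    group: str
    amplitudes: dict[tuple[str, str], float]  # (condition, chromophore) -> µM
    spike_times_s: list[float]
    step_times_s: list[float]


# ---------------------------------------------------------------------------
# hemodynamic simulation
# ---------------------------------------------------------------------------


def _block_regressor(
    schedule: EventSchedule,
    condition: str,
    profile: ResponseProfile,
    n: int,
    fs: float,
) -> np.ndarray:
    """Boxcar train ⊛ kernel, normalised so a single block has unit peak."""
    kernel_t = np.arange(0.0, 10.0 * profile.hrf_peak_s, 1.0 / fs)
    kernel = np.asarray(
        gamma_hrf(kernel_t, profile.hrf_peak_s, profile.hrf_undershoot_ratio)
    )
    rows = schedule.frame[schedule.frame["condition"] == condition]
    train = np.zeros(n)
    single_peak = None
    for onset, duration in zip(rows["onset_s"], rows["duration_s"]):
        i0 = int(round(onset * fs))
        i1 = min(n, i0 + int(round(duration * fs)))
        if i0 < n:
            train[i0:i1] = 1.0
        if single_peak is None:
            box = np.ones(int(round(duration * fs)))
            single_peak = float(np.max(np.convolve(box, kernel))) / fs
    if single_peak is None or single_peak == 0:
        return np.zeros(n)
    return np.convolve(train, kernel)[:n] / fs / single_peak


def simulate_hb(
    schedule: EventSchedule,
    profiles: dict[tuple[str, str], ResponseProfile],
    noise: NoiseSpec,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    group: str,
    channels: list[str],
    subject_id: str = "sim",
) -> tuple[HbTimeSeries, GroundTruth]:
    """Simulate clean-units (µM) ΔHbO/ΔHbR plus the injected ground truth.

    Evoked = Σ_conditions amplitude × unit-peak block regressor; nuisance
    sinusoids, drift and white noise are drawn independently per channel and
    chromophore; motion spikes and steps share event times across channels.
    """
    noise.validate(fs)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    n_ch = len(channels)

    evoked_o = np.zeros(n)
    evoked_r = np.zeros(n)
    amplitudes: dict[tuple[str, str], float] = {}
    for cond in schedule.conditions:
        if (group, cond) not in profiles:
            raise ValidationError(f"no profile for scheduled condition {group} × {cond}")
        prof = profiles[(group, cond)]
        reg = _block_regressor(schedule, cond, prof, n, fs)
        evoked_o += prof.amp_hbo * reg
        evoked_r += prof.amp_hbr * reg
        amplitudes[(cond, "HbO")] = prof.amp_hbo
        amplitudes[(cond, "HbR")] = prof.amp_hbr

    hbo = np.tile(evoked_o, (n_ch, 1))
    hbr = np.tile(evoked_r, (n_ch, 1))

    sinusoids = (
        (noise.cardiac_freq_hz, noise.cardiac_amp),
        (noise.respiratory_freq_hz, noise.respiratory_amp),
        (noise.mayer_freq_hz, noise.mayer_amp),
    )
    for target, ratio in ((hbo, 1.0), (hbr, noise.hbr_noise_ratio)):
        for freq, amp in sinusoids:
            if amp > 0:
                phases = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
                freqs = freq * (
                    1.0 + noise.freq_jitter * rng.uniform(-1, 1, size=(n_ch, 1))
                )
                target += ratio * amp * np.sin(2 * np.pi * freqs * t[None, :] + phases)
        if noise.drift_scale > 0:
            steps = rng.normal(0.0, noise.drift_scale / np.sqrt(fs), size=(n_ch, n))
            target += ratio * np.cumsum(steps, axis=1)
        if noise.white_sd > 0:
            target += ratio * rng.normal(0.0, noise.white_sd, size=(n_ch, n))

    # motion artifacts: shared event times across channels and chromophores
    minutes = duration_s / 60.0
    spike_times: list[float] = []
    step_times: list[float] = []
    if noise.artifact_amp > 0:
        n_spikes = rng.poisson(noise.artifact_spike_rate_per_min * minutes)
        n_steps = rng.poisson(noise.artifact_step_rate_per_min * minutes)
        for _ in range(n_spikes):
            t0 = float(rng.uniform(0, duration_s))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            i0 = int(round(t0 * fs))
            if i0 >= n:
                continue
            shape = np.exp(-(t[i0:] - t[i0]) / noise.artifact_tau_s)
            hbo[:, i0:] += sign * noise.artifact_amp * shape
            hbr[:, i0:] += sign * noise.artifact_amp * noise.artifact_hbr_ratio * shape
            spike_times.append(t0)
        for _ in range(n_steps):
            t0 = float(rng.uniform(0, duration_s))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            i0 = int(round(t0 * fs))
            if i0 >= n:
                continue
            hbo[:, i0:] += sign * noise.artifact_amp
            hbr[:, i0:] += sign * noise.artifact_amp * noise.artifact_hbr_ratio
            step_times.append(t0)

    hb = HbTimeSeries(
        subject_id=subject_id,
        group=group,
        sampling_rate_hz=fs,
        channels=list(channels),
        hbo=hbo,
        hbr=hbr,
        units="uM",
    )
    hb.log("simulate", seed_stream="per-subject", n_spikes=len(spike_times),
           n_steps=len(step_times))
    truth = GroundTruth(
        subject_id=subject_id,
        group=group,
        amplitudes=amplitudes,
        spike_times_s=sorted(spike_times),
        step_times_s=sorted(step_times),
    )
    return hb, truth


# ---------------------------------------------------------------------------
# forward Beer-Lambert model
# ---------------------------------------------------------------------------


def forward_mbll(
    hb: HbTimeSeries,
    config: PreprocessConfig | None = None,
    i0: np.ndarray | float = 1.0,
    montage: Montage | None = None,
    wavelengths: tuple[float, float] = (760.0, 830.0),
) -> OpticalRecording:
    """Map µM concentration changes to raw intensities, I = I0·10^(−ΔOD)."""
    if hb.units != "uM":
        raise ValidationError("forward model expects concentration units (uM)")
    config = config or PreprocessConfig()
    a = extinction_matrix(config, wavelengths)  # raises if singular
    conc = np.stack([hb.hbo, hb.hbr], axis=1)  # (ch, 2, t)
    od = np.einsum("ij,cjt->cit", a, conc)
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=float), od.shape[:2])[..., None]
    intensity = i0_arr * 10.0 ** (-od)
    if montage is None:
        montage = default_montage()
    return OpticalRecording(
        subject_id=hb.subject_id,
        group=hb.group,
        intensity=intensity,
        montage=montage,
        sampling_rate_hz=hb.sampling_rate_hz,
        wavelengths_nm=wavelengths,
        t0_s=hb.t0_s,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    subject_id: str
    group: str
    seed_key: int
    recording: OpticalRecording
    schedule: EventSchedule
    ground_truth: GroundTruth


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectData]
    manifest: pd.DataFrame


def subject_rng(master_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-subject stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Simulate one recording per subject plus a tidy ground-truth manifest."""
    spec = spec or CohortSpec()
    spec.validate()
    montage = default_montage()
    channels = montage.channel_labels
    fs = spec.sampling_rate_hz
    duration = spec.paradigm.total_duration_s

    subjects: list[SubjectData] = []
    rows = []
    index = 0
    for group in ("HC", "MCS", "VS"):
        for k in range(spec.n_per_group.get(group, 0)):
            rng = subject_rng(spec.seed, index)
            subject_id = f"{group}{k + 1:02d}"
            schedule = build_paradigm(spec.paradigm, rng)
            hb, truth = simulate_hb(
                schedule, spec.profiles, spec.noise, duration, fs, rng,
                group=group, channels=channels, subject_id=subject_id,
            )
            rec = forward_mbll(hb, spec.mbll, i0=spec.i0, montage=montage)
            subjects.append(SubjectData(subject_id, group, index, rec, schedule, truth))
            row = {
                "subject_id": subject_id,
                "group": group,
                "seed_key": index,
                "first_condition": schedule.frame["condition"].iloc[0],
                "n_spikes": len(truth.spike_times_s),
                "n_steps": len(truth.step_times_s),
            }
            for (cond, chrom), amp in truth.amplitudes.items():
                row[f"amp_{chrom.lower()}_{cond.lower()}"] = amp
            rows.append(row)
            index += 1
    manifest = pd.DataFrame(rows)
    return Cohort(spec=spec, subjects=subjects, manifest=manifest)


def write_cohort(cohort: Cohort, outdir) -> pd.DataFrame:
    """Write recordings, schedules and the manifest as TSV; returns manifest
    augmented with file paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    manifest = cohort.manifest.copy()
    rec_paths, evt_paths = [], []
    for subj in cohort.subjects:
        # paths are stored relative to the cohort directory so the manifest
        # is byte-reproducible regardless of where the cohort lives
        rec_name = f"{subj.subject_id}_intensity.tsv"
        evt_name = f"{subj.subject_id}_events.tsv"
        write_recording(subj.recording, os.path.join(outdir, rec_name))
        write_events(subj.schedule, os.path.join(outdir, evt_name))
        rec_paths.append(rec_name)
        evt_paths.append(evt_name)
    manifest["recording_path"] = rec_paths
    manifest["events_path"] = evt_paths
    manifest.to_csv(os.path.join(outdir, "manifest.tsv"), sep="\t", index=False)
    return manifest
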