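"""Raw intensity to cleaned, normalised hemoglobin concentration series.

The processing chain is the standard prefrontal fNIRS sequence:

1. optical density:      ΔOD(t, λ) = −log10( I(t, λ) / I0(λ) )
2. Beer-Lambert inversion (modified Beer-Lambert law, MBLL):
       ΔOD(λ) = d · DPF(λ) · [ ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR ]
   solved per channel and sample as a 2×2 linear system over the two
   wavelengths, giving ΔHbO / ΔHbR in µM
3. zero-phase band-pass 0.01–0.2 Hz (cardiac / respiratory suppression)
4. correlation-based signal improvement (CBSI) motion correction
5. full-recording per-channel z-score normalisation

Epoch-level trial rejection (:func:`artifact_score`) is applied downstream,
on the z-scored epochs, by :mod:`nirsdoc.epochs_features`.

Every step appends to the ``processing_log`` of the produced
:class:`~nirsdoc.io_formats.HbTimeSeries`, so the applied order is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import butter, filtfilt

from nirsdoc.io_formats import HbTimeSeries, OpticalRecording, ValidationError

#: Molar extinction coefficients in cm⁻¹·µM⁻¹ (decadic, so they compose with
#: the base-10 optical density above).  Values follow the standard compiled
#: hemoglobin spectra used throughout the fNIRS literature.
DEFAULT_EXTINCTION: dict[float, dict[str, float]] = {
    760.0: {"HbO": 5.8600e-4, "HbR": 1.5485e-3},
    830.0: {"HbO": 9.7400e-4, "HbR": 6.9304e-4},
}


@dataclass
class RejectionConfig:
    """Epoch rejection thresholds applied to z-scored epochs."""

    max_abs_z: float = 5.0
    max_jump_z: float = 3.0


@dataclass
class PreprocessConfig:
    """Parameters of the intensity → z-scored concentration chain.

    ``i0_definition`` selects the reference intensity I0 per channel and
    wavelength: ``"mean"`` uses the geometric mean over the whole series,
    ``"baseline60"`` the geometric mean over the first 60 s.  The geometric
    mean makes ΔOD average exactly to zero over the defining window.
    """

    i0_definition: str = "mean"  # mean | baseline60
    extinction: dict[float, dict[str, float]] = field(
        default_factory=lambda: {w: dict(v) for w, v in DEFAULT_EXTINCTION.items()}
    )
    dpf: dict[float, float] = field(default_factory=lambda: {760.0: 6.0, 830.0: 6.0})
    d_cm: float = 3.0
    band_hz: tuple[float, float] = (0.01, 0.2)
    filter_order: int = 3
    cbsi_enabled: bool = True
    rejection: RejectionConfig = field(default_factory=RejectionConfig)

    def validate(self, fs: float | None = None) -> None:
        low, high = self.band_hz
        if not 0 < low < high:
            raise ValidationError("band edges must satisfy 0 < low < high")
        if fs is not None and high >= fs / 2:
            raise ValidationError("band upper edge must lie below Nyquist")
        if self.d_cm <= 0:
            raise ValidationError("d_cm must be positive")
        if any(v <= 0 for v in self.dpf.values()):
            raise ValidationError("DPF values must be positive")


def extinction_matrix(
    config: PreprocessConfig, wavelengths: tuple[float, float]
) -> np.ndarray:
    """Pathlength-scaled 2×2 system matrix A with ΔOD = A @ [ΔHbO, ΔHbR]."""
    rows = []
    for wl in wavelengths:
        if wl not in config.extinction:
            raise ValidationError(f"no extinction coefficients for {wl:g} nm")
        eps = config.extinction[wl]
        dpf = config.dpf.get(wl)
        if dpf is None:
            raise ValidationError(f"no DPF for {wl:g} nm")
        rows.append([config.d_cm * dpf * eps["HbO"], config.d_cm * dpf * eps["HbR"]])
    a = np.asarray(rows)
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(f"extinction system is singular (condition number {cond:.3g})")
    return a


# ---------------------------------------------------------------------------
# stage 1: optical density
# ---------------------------------------------------------------------------


def intensity_to_od(
    rec: OpticalRecording,
    i0_definition: str = "mean",
    i0: np.ndarray | float | None = None,
) -> np.ndarray:
    """Convert raw intensity to optical-density change ΔOD = −log10(I/I0).

    ``i0`` may be given explicitly (scalar or (channel, wavelength) array),
    e.g. to invert a forward simulation exactly; otherwise I0 is the
    geometric mean of the intensity over the window named by
    ``i0_definition``, which makes ΔOD average to zero over that window.
    """
    rec.validate()  # raises on non-positive intensity, naming the sample
    log_i = np.log10(rec.intensity)
    if i0 is not None:
        log_i0 = np.log10(np.broadcast_to(np.asarray(i0, dtype=float),
                                          rec.intensity.shape[:2]))[..., None]
    elif i0_definition == "mean":
        log_i0 = log_i.mean(axis=2, keepdims=True)
    elif i0_definition == "baseline60":
        n = max(1, int(round(60.0 * rec.sampling_rate_hz)))
        log_i0 = log_i[:, :, :n].mean(axis=2, keepdims=True)
    else:
        raise ValueError(f"unknown i0_definition {i0_definition!r}")
    return -(log_i - log_i0)


# ---------------------------------------------------------------------------
# stage 2: MBLL inversion
# ---------------------------------------------------------------------------


def od_to_hb(
    od: np.ndarray,
    config: PreprocessConfig,
    wavelengths: tuple[float, float],
    *,
    subject_id: str = "",
    group: str = "HC",
    sampling_rate_hz: float = 10.0,
    channels: list[str] | None = None,
    t0_s: float = 0.0,
) -> HbTimeSeries:
    """Solve the 2×2 Beer-Lambert system per channel and sample (units µM)."""
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[1] != 2:
        raise ValidationError("od must be (channel, wavelength=2, time)")
    a = extinction_matrix(config, wavelengths)
    # concentrations = A^{-1} @ od, applied across channels and samples
    conc = np.einsum("ij,cjt->cit", np.linalg.inv(a), od)
    n_ch = od.shape[0]
    hb = HbTimeSeries(
        subject_id=subject_id,
        group=group,
        sampling_rate_hz=sampling_rate_hz,
        channels=channels if channels is not None else [f"ch{i}" for i in range(n_ch)],
        hbo=conc[:, 0, :],
        hbr=conc[:, 1, :],
        units="uM",
        t0_s=t0_s,
    )
    hb.log("mbll", d_cm=config.d_cm, dpf={f"{w:g}": v for w, v in config.dpf.items()},
           wavelengths_nm=list(wavelengths))
    return hb


# ---------------------------------------------------------------------------
# stage 3: band-pass
# ---------------------------------------------------------------------------


def bandpass(hb: HbTimeSeries, config: PreprocessConfig) -> HbTimeSeries:
    """Zero-phase Butterworth band-pass of both chromophores.

    The filter is applied forward and backward (squared magnitude response,
    zero phase) with Gustafsson initial conditions, which remove the edge
    transients a padded two-pass filter would otherwise leak into the first
    and last minutes of a recording.
    """
    config.validate(fs=hb.sampling_rate_hz)
    low, high = config.band_hz
    n = hb.n_samples
    if n <= 3 * (2 * config.filter_order + 1):
        raise ValidationError(f"series of {n} samples too short for filtering")
    b, a = butter(config.filter_order, [low, high], btype="band", fs=hb.sampling_rate_hz)
    out = hb.copy_with(
        hbo=filtfilt(b, a, hb.hbo, axis=1, method="gust"),
        hbr=filtfilt(b, a, hb.hbr, axis=1, method="gust"),
    )
    out.log("bandpass", band_hz=list(config.band_hz), order=config.filter_order,
            design="butterworth", zero_phase=True)
    return out


# ---------------------------------------------------------------------------
# stage 4: CBSI motion correction
# ---------------------------------------------------------------------------


def cbsi_correct(hb: HbTimeSeries) -> HbTimeSeries:
    """Correlation-based signal improvement, channel by channel.

    Assumes true HbO and HbR are anti-correlated while motion moves both the
    same way.  With α = std(HbO)/std(HbR):

        HbO' = (HbO − α·HbR) / 2,   HbR' = −HbO'/α

    so the corrected pair is exactly anti-correlated, and any component
    injected identically (after α-scaling) into both chromophores cancels.
    """
    sd_o = hb.hbo.std(axis=1)
    sd_r = hb.hbr.std(axis=1)
    zero = np.argwhere(sd_r == 0)
    if zero.size:
        raise ValidationError(
            f"CBSI undefined: zero-variance HbR on channel {hb.channels[int(zero[0][0])]}"
        )
    alpha = (sd_o / sd_r)[:, None]
    hbo_c = (hb.hbo - alpha * hb.hbr) / 2.0
    hbr_c = -hbo_c / alpha
    out = hb.copy_with(hbo=hbo_c, hbr=hbr_c)
    out.log("cbsi", alpha=[float(x) for x in alpha[:, 0]])
    return out


# ---------------------------------------------------------------------------
# epoch / series artifact scoring (used by epochs_features for rejection)
# ---------------------------------------------------------------------------


def artifact_score(
    series: np.ndarray,
    rejection: RejectionConfig | None = None,
    scale: float | None = None,
) -> tuple[float, bool]:
    """Score a 1-D epoch or series for uncorrectable motion residue.

    The input is assumed to be in z units; pass ``scale`` to normalise raw
    data first.  The score is the larger of max|z| / max_abs_z and
    max|Δz| / max_jump_z; a score above 1 marks the trial for rejection.
    Returns ``(score, reject)``.
    """
    rejection = rejection or RejectionConfig()
    z = np.asarray(series, dtype=float).ravel()
    if scale is not None:
        if scale <= 0:
            raise ValidationError("scale must be positive")
        z = z / scale
    if z.size == 0:
        return 0.0, False
    amp_ratio = float(np.abs(z).max() / rejection.max_abs_z)
    jump_ratio = 0.0
    if z.size > 1:
        jump_ratio = float(np.abs(np.diff(z)).max() / rejection.max_jump_z)
    score = max(amp_ratio, jump_ratio)
    return score, score > 1.0


# ---------------------------------------------------------------------------
# stage 5: z-score normalisation
# ---------------------------------------------------------------------------


def zscore(hb: HbTimeSeries) -> HbTimeSeries:
    """Per-channel, per-chromophore z-score over the full recording."""
    def _z(arr: np.ndarray, name: str) -> np.ndarray:
        sd = arr.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            ch = int(np.argwhere(sd[:, 0] == 0)[0][0])
            raise ValidationError(f"zero variance in {name} on channel {hb.channels[ch]}")
        return (arr - arr.mean(axis=1, keepdims=True)) / sd

    out = hb.copy_with(_z(hb.hbo, "hbo"), _z(hb.hbr, "hbr"), units="z")
    out.log("zscore", scope="full-recording per channel per chromophore")
    return out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def preprocess_recording(
    rec: OpticalRecording,
    config: PreprocessConfig | None = None,
    i0: np.ndarray | float | None = None,
) -> HbTimeSeries:
    """Run OD → MBLL → band-pass → CBSI (optional) → z-score on a recording."""
    config = config or PreprocessConfig()
    config.validate(fs=rec.sampling_rate_hz)
    od = intensity_to_od(rec, config.i0_definition, i0=i0)
    hb = od_to_hb(
        od,
        config,
        rec.wavelengths_nm,
        subject_id=rec.subject_id,
        group=rec.group,
        sampling_rate_hz=rec.sampling_rate_hz,
        channels=rec.montage.channel_labels,
        t0_s=rec.t0_s,
    )
    hb.processing_log.insert(
        0, {"stage": "od", "i0_definition": config.i0_definition if i0 is None else "explicit"}
    )
    hb = bandpass(hb, config)
    if config.cbsi_enabled:
        hb = cbsi_correct(hb)
    return zscore(hb)
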