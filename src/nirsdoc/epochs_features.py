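"""Stimulus-locked epoching, baseline correction and scalar response features.

Window conventions (seconds relative to block onset, all half-open
``[start, end)`` on the sample grid, onsets snapped to the nearest sample):

* segment window  (−5, +45):  extracted epoch
* analysis window (−3, +40):  span of the reported response curve
* baseline        (−3, 0):    mean subtracted per epoch
* mean window     (2, 20):    arithmetic-mean concentration feature
* slope window    (5, 15):    ordinary-least-squares fitting-slope feature

Both features are linear in the curve, and adding a constant shifts the mean
feature by that constant while leaving the slope unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from nirsdoc.io_formats import BLOCK_AVG, CHROMOPHORES, EventSchedule, HbTimeSeries, \
    ValidationError
from nirsdoc.preprocess import RejectionConfig, artifact_score


@dataclass
class EpochWindows:
    segment: tuple[float, float] = (-5.0, 45.0)
    analysis: tuple[float, float] = (-3.0, 40.0)
    baseline: tuple[float, float] = (-3.0, 0.0)
    mean_window: tuple[float, float] = (2.0, 20.0)
    slope_window: tuple[float, float] = (5.0, 15.0)

    def __post_init__(self) -> None:
        def inside(inner: tuple[float, float], outer: tuple[float, float]) -> bool:
            return outer[0] <= inner[0] and inner[1] <= outer[1]

        if not inside(self.analysis, self.segment):
            raise ValidationError("analysis window must lie inside the segment window")
        for name in ("baseline", "mean_window", "slope_window"):
            if not inside(getattr(self, name), self.analysis):
                raise ValidationError(f"{name} must lie inside the analysis window")


def window_mask(times_s: np.ndarray, window: tuple[float, float], fs: float) -> np.ndarray:
    """Half-open [start, end) membership on the sample grid, robust to float
    round-off by comparing integer sample indices."""
    idx = np.round(np.asarray(times_s) * fs).astype(int)
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    return (idx >= lo) & (idx < hi)


@dataclass
class EpochSet:
    """Epochs for one (condition, channel, chromophore) cell of a subject.

    ``epochs`` is (n_epochs, n_samples) on the segment-window grid;
    ``valid`` marks epochs fully inside the recording, ``retained`` those
    additionally surviving artifact rejection.
    """

    subject_id: str
    group: str
    condition: str
    channel: str
    chromophore: str
    epochs: np.ndarray
    times_s: np.ndarray  # relative to onset, shared by all epochs
    onsets_s: np.ndarray
    sampling_rate_hz: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.epochs), dtype=bool)
        if self.retained is None:
            self.retained = self.valid.copy()

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


def segment(
    hb: HbTimeSeries,
    schedule: EventSchedule,
    windows: EpochWindows | None = None,
) -> dict[tuple[str, str, str], EpochSet]:
    """Cut stimulus-locked epochs for every condition × channel × chromophore.

    Epochs whose segment window extends past either end of the recording are
    kept in place but flagged invalid rather than silently truncated.
    """
    windows = windows or EpochWindows()
    fs = hb.sampling_rate_hz
    start_off = int(round(windows.segment[0] * fs))
    n_len = int(round((windows.segment[1] - windows.segment[0]) * fs))
    times = (start_off + np.arange(n_len)) / fs

    out: dict[tuple[str, str, str], EpochSet] = {}
    arrays = {"HbO": hb.hbo, "HbR": hb.hbr}
    for condition in schedule.conditions:
        onsets = schedule.onsets(condition)
        starts = np.round(onsets * fs).astype(int) + start_off
        valid = (starts >= 0) & (starts + n_len <= hb.n_samples)
        for ci, channel in enumerate(hb.channels):
            for chrom in CHROMOPHORES:
                data = np.full((len(onsets), n_len), np.nan)
                for k, s in enumerate(starts):
                    if valid[k]:
                        data[k] = arrays[chrom][ci, s:s + n_len]
                out[(condition, channel, chrom)] = EpochSet(
                    subject_id=hb.subject_id,
                    group=hb.group,
                    condition=condition,
                    channel=channel,
                    chromophore=chrom,
                    epochs=data,
                    times_s=times,
                    onsets_s=np.asarray(onsets, dtype=float),
                    sampling_rate_hz=fs,
                    valid=valid.copy(),
                )
    return out


def _robust_scale(samples: np.ndarray) -> float:
    """Gaussian-consistent MAD scale; artifact excursions barely move it,
    unlike the plain standard deviation they would otherwise inflate."""
    x = samples[np.isfinite(samples)]
    if x.size == 0:
        return 1.0
    mad = np.median(np.abs(x - np.median(x)))
    if mad > 0:
        return float(1.4826 * mad)
    sd = x.std()
    return float(sd) if sd > 0 else 1.0


def reject_epochs(
    epoch_sets: dict[tuple[str, str, str], EpochSet],
    rejection: RejectionConfig | None = None,
) -> dict[tuple[str, str, str], EpochSet]:
    """Flag trials with uncorrectable motion residue.

    Each epoch is scored in robust z units: the scale is the
    Gaussian-consistent MAD of the channel × chromophore data pooled across
    all its epochs, so a large motion transient cannot mask itself by
    inflating its own reference scale.  A trial is rejected for a channel
    when either chromophore scores above threshold, since motion moves both
    together.
    """
    rejection = rejection or RejectionConfig()
    out = {key: replace(es, epochs=es.epochs.copy(), retained=es.retained.copy())
           for key, es in epoch_sets.items()}
    scales: dict[tuple[str, str], float] = {}
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for (_, channel, chrom), es in out.items():
        pooled.setdefault((channel, chrom), []).append(es.epochs[es.valid])
    for key, chunks in pooled.items():
        scales[key] = _robust_scale(np.concatenate([c.ravel() for c in chunks])
                                    if chunks else np.empty(0))
    cells: dict[tuple[str, str], list[EpochSet]] = {}
    for (cond, channel, _), es in out.items():
        cells.setdefault((cond, channel), []).append(es)
    for pair in cells.values():
        n_ep = pair[0].n_epochs
        keep = np.ones(n_ep, dtype=bool)
        for es in pair:
            scale = scales[(es.channel, es.chromophore)]
            for k in range(n_ep):
                if not es.valid[k]:
                    keep[k] = False
                    continue
                _, reject = artifact_score(es.epochs[k], rejection, scale=scale)
                if reject:
                    keep[k] = False
        for es in pair:
            es.retained = es.valid & keep
    return out


def baseline_correct(epoch_set: EpochSet, windows: EpochWindows | None = None) -> EpochSet:
    """Subtract the per-epoch mean of the baseline window; idempotent."""
    windows = windows or EpochWindows()
    mask = window_mask(epoch_set.times_s, windows.baseline, epoch_set.sampling_rate_hz)
    if not mask.any():
        raise ValidationError("baseline window contains no samples")
    epochs = epoch_set.epochs.copy()
    valid = epoch_set.valid.copy()
    retained = epoch_set.retained.copy()
    for k in range(len(epochs)):
        base = epochs[k, mask]
        if np.isnan(base).all():
            valid[k] = False
            retained[k] = False
            continue
        epochs[k] = epochs[k] - np.nanmean(base)
    return replace(epoch_set, epochs=epochs, valid=valid, retained=retained,
                   baseline_corrected=True)


def block_average(epoch_set: EpochSet) -> tuple[np.ndarray | None, int]:
    """Pointwise mean over retained epochs; ``(None, 0)`` when none remain."""
    keep = epoch_set.retained & epoch_set.valid
    n = int(keep.sum())
    if n == 0:
        return None, 0
    return epoch_set.epochs[keep].mean(axis=0), n


def mean_feature(
    curve: np.ndarray,
    times_s: np.ndarray,
    windows: EpochWindows | None = None,
    fs: float = 10.0,
) -> float:
    """Arithmetic mean of the curve over the mean window [2, 20) s."""
    windows = windows or EpochWindows()
    mask = window_mask(times_s, windows.mean_window, fs)
    if not mask.any() or np.isnan(curve[mask]).any():
        return float("nan")
    return float(np.mean(curve[mask]))


def slope_feature(
    curve: np.ndarray,
    times_s: np.ndarray,
    windows: EpochWindows | None = None,
    fs: float = 10.0,
) -> float:
    """OLS slope of the curve against time over the slope window [5, 15) s."""
    windows = windows or EpochWindows()
    mask = window_mask(times_s, windows.slope_window, fs)
    if mask.sum() < 3:
        raise ValidationError("slope window covers fewer than 3 samples")
    y = curve[mask]
    if np.isnan(y).any():
        return float("nan")
    t = times_s[mask]
    tc = t - t.mean()
    return float(np.sum(tc * (y - y.mean())) / np.sum(tc * tc))


def subject_features(
    hb: HbTimeSeries,
    schedule: EventSchedule,
    windows: EpochWindows | None = None,
    rejection: RejectionConfig | None = None,
    mode: str = "per-epoch",
) -> pd.DataFrame:
    """Segment, reject, baseline-correct and featurise one subject.

    ``mode="per-epoch"`` yields one row per retained-or-flagged trial;
    ``mode="block-avg"`` yields one row per cell with the features of the
    block-averaged curve.  Rejected trials stay in the table with missing
    features and ``retained=False``, never silently as zeros.
    """
    if mode not in ("per-epoch", "block-avg"):
        raise ValueError(f"unknown feature mode {mode!r}")
    windows = windows or EpochWindows()
    sets = segment(hb, schedule, windows)
    sets = reject_epochs(sets, rejection)
    rows = []
    for (condition, channel, chrom), es in sets.items():
        es = baseline_correct(es, windows)
        common = {
            "subject_id": es.subject_id,
            "group": es.group,
            "condition": condition,
            "channel": channel,
            "chromophore": chrom,
        }
        if mode == "per-epoch":
            for k in range(es.n_epochs):
                ok = bool(es.retained[k] and es.valid[k])
                rows.append({
                    **common,
                    "epoch_index": k,
                    "mean_conc": mean_feature(es.epochs[k], es.times_s, windows,
                                              es.sampling_rate_hz) if ok else float("nan"),
                    "slope": slope_feature(es.epochs[k], es.times_s, windows,
                                           es.sampling_rate_hz) if ok else float("nan"),
                    "retained": ok,
                    "n_retained": int((es.retained & es.valid).sum()),
                })
        else:
            curve, n_ret = block_average(es)
            ok = curve is not None
            rows.append({
                **common,
                "epoch_index": BLOCK_AVG,
                "mean_conc": mean_feature(curve, es.times_s, windows,
                                          es.sampling_rate_hz) if ok else float("nan"),
                "slope": slope_feature(curve, es.times_s, windows,
                                       es.sampling_rate_hz) if ok else float("nan"),
                "retained": ok,
                "n_retained": n_ret,
            })
    return pd.DataFrame(rows)


def build_feature_table(subject_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject feature tables into one tidy cohort table."""
    if not subject_tables:
        return pd.DataFrame(columns=[
            "subject_id", "group", "condition", "channel", "chromophore",
            "epoch_index", "mean_conc", "slope", "retained", "n_retained",
        ])
    return pd.concat(subject_tables, ignore_index=True)


def block_average_curves(
    hb: HbTimeSeries,
    schedule: EventSchedule,
    windows: EpochWindows | None = None,
    rejection: RejectionConfig | None = None,
) -> pd.DataFrame:
    """Long-format block-averaged curves (for plotting and export)."""
    windows = windows or EpochWindows()
    sets = reject_epochs(segment(hb, schedule, windows), rejection)
    rows = []
    for (condition, channel, chrom), es in sets.items():
        es = baseline_correct(es, windows)
        curve, n_ret = block_average(es)
        if curve is None:
            continue
        mask = window_mask(es.times_s, windows.analysis, es.sampling_rate_hz)
        for tt, vv in zip(es.times_s[mask], curve[mask]):
            rows.append({
                "subject_id": es.subject_id, "group": es.group,
                "condition": condition, "channel": channel, "chromophore": chrom,
                "time_s": tt, "value": vv, "n_retained": n_ret,
            })
    return pd.DataFrame(rows)
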