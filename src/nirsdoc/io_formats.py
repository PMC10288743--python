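"""Typed containers for fNIRS recordings, events, features and test results.

All on-disk formats are plain text (tab-separated values with ``#``-prefixed
JSON metadata lines) except for an optional HDF5 container laid out in the
style of SNIRF (data block + probe block).  The TSV dialect is the canonical
format: it round-trips every numeric field at double precision and is
trivially inspectable.

Time conventions: event times are seconds from recording start (sample 0),
and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("HC", "MCS", "VS")
CONDITIONS = ("SON", "MI")
CHROMOPHORES = ("HbO", "HbR")

#: sentinel epoch index for features computed on the block-averaged curve
BLOCK_AVG = "block-avg"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Montage:
    """Optode layout: labelled 2-D scalp positions and source-detector pairs.

    Coordinates are schematic (cm in a flattened scalp plane); the physical
    source-detector separation used by the Beer-Lambert inversion is carried
    explicitly per channel in :attr:`separation_cm`.
    """

    sources: dict[str, tuple[float, float]]
    detectors: dict[str, tuple[float, float]]
    channels: list[tuple[str, str]]
    separation_cm: list[float]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.channels:
            raise ValidationError("montage has no channels")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("duplicate source-detector pairs in montage")
        if len(self.separation_cm) != len(self.channels):
            raise ValidationError("separation_cm must have one entry per channel")
        for (src, det), sep in zip(self.channels, self.separation_cm):
            if src not in self.sources:
                raise ValidationError(f"channel references unknown source {src!r}")
            if det not in self.detectors:
                raise ValidationError(f"channel references unknown detector {det!r}")
            if not sep > 0:
                raise ValidationError(f"non-positive separation for channel {src}-{det}")

    @property
    def channel_labels(self) -> list[str]:
        return [f"{s}-{d}" for s, d in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def to_dict(self) -> dict:
        return {
            "sources": {k: list(v) for k, v in self.sources.items()},
            "detectors": {k: list(v) for k, v in self.detectors.items()},
            "channels": [list(c) for c in self.channels],
            "separation_cm": list(self.separation_cm),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Montage":
        return cls(
            sources={k: tuple(v) for k, v in d["sources"].items()},
            detectors={k: tuple(v) for k, v in d["detectors"].items()},
            channels=[tuple(c) for c in d["channels"]],
            separation_cm=[float(s) for s in d["separation_cm"]],
        )


def default_montage() -> Montage:
    """Prefrontal 3-source / 2-detector montage with five 3 cm channels.

    Five of the six possible source-detector pairings are wired: detector D1
    sits at the centre of an arc of the three sources, detector D2 closes the
    layout against S2 and S3.  The schematic coordinates are chosen so every
    wired pair is exactly 3 cm apart, matching the physical separation used
    for the pathlength term of the Beer-Lambert inversion.
    """
    sources = {"S1": (-3.0, 0.0), "S2": (0.0, 3.0), "S3": (3.0, 0.0)}
    detectors = {"D1": (0.0, 0.0), "D2": (3.0, 3.0)}
    channels = [("S1", "D1"), ("S2", "D1"), ("S3", "D1"), ("S2", "D2"), ("S3", "D2")]
    return Montage(sources, detectors, channels, [3.0] * 5)


@dataclass
class OpticalRecording:
    """Raw dual-wavelength optical intensity, indexed (channel, wavelength, time).

    Intensities are strictly positive arbitrary units; the optical-density
    conversion takes their logarithm.
    """

    subject_id: str
    group: str
    intensity: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    montage: Montage
    sampling_rate_hz: float = 10.0
    wavelengths_nm: tuple[float, float] = (760.0, 830.0)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if len(set(self.wavelengths_nm)) != len(self.wavelengths_nm):
            raise ValidationError("wavelengths must be distinct")
        if self.intensity.ndim != 3:
            raise ValidationError("intensity must be (channel, wavelength, time)")
        n_ch, n_wl, _ = self.intensity.shape
        if n_ch != self.montage.n_channels:
            raise ValidationError(
                f"intensity has {n_ch} channels but montage defines {self.montage.n_channels}"
            )
        if n_wl != len(self.wavelengths_nm):
            raise ValidationError("intensity wavelength axis does not match wavelengths_nm")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity contains non-finite values")
        bad = np.argwhere(self.intensity <= 0)
        if bad.size:
            ch, wl, t = bad[0]
            label = self.montage.channel_labels[ch]
            raise ValidationError(
                f"non-positive intensity at channel {label}, "
                f"wavelength {self.wavelengths_nm[wl]:g} nm, sample {t}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz


class EventSchedule:
    """Ordered task blocks (condition, onset, duration), half-open in seconds."""

    def __init__(self, frame: pd.DataFrame, task_s: float | None = None,
                 tol_s: float = 0.1) -> None:
        required = {"onset_s", "duration_s", "condition"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"event table missing columns: {sorted(missing)}")
        frame = frame[["onset_s", "duration_s", "condition"]].copy()
        frame["onset_s"] = frame["onset_s"].astype(float)
        frame["duration_s"] = frame["duration_s"].astype(float)
        frame["condition"] = frame["condition"].astype(str)

        unknown = set(frame["condition"]) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown condition labels: {sorted(unknown)}")
        if (frame["onset_s"] < 0).any():
            raise ValidationError("negative block onset")
        if (frame["duration_s"] <= 0).any():
            raise ValidationError("non-positive block duration")

        if not frame["onset_s"].is_monotonic_increasing:
            logger.warning("event rows were not sorted by onset; sorting")
            frame = frame.sort_values("onset_s", kind="stable")
        frame = frame.reset_index(drop=True)

        ends = frame["onset_s"] + frame["duration_s"]
        overlap = frame["onset_s"].values[1:] < ends.values[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            raise ValidationError(
                f"blocks {i} and {i + 1} overlap "
                f"({ends.iloc[i]:g} s > {frame['onset_s'].iloc[i + 1]:g} s)"
            )
        if task_s is not None:
            off = np.abs(frame["duration_s"].values - task_s)
            if (off > tol_s).any():
                raise ValidationError(
                    f"block durations deviate from task period {task_s:g} s by more "
                    f"than {tol_s:g} s"
                )
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventSchedule) and self.frame.equals(other.frame)

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if c in set(self.frame["condition"])]

    def onsets(self, condition: str) -> np.ndarray:
        return self.frame.loc[self.frame["condition"] == condition, "onset_s"].values

    @property
    def end_s(self) -> float:
        return float((self.frame["onset_s"] + self.frame["duration_s"]).max())

    @classmethod
    def from_blocks(cls, blocks: Iterable[tuple[str, float, float]]) -> "EventSchedule":
        """Build from ``(condition, onset_s, duration_s)`` triples."""
        rows = [{"condition": c, "onset_s": o, "duration_s": d} for c, o, d in blocks]
        return cls(pd.DataFrame(rows))


@dataclass
class HbTimeSeries:
    """Per-channel ΔHbO / ΔHbR concentration time series.

    ``units`` is ``"uM"`` after Beer-Lambert inversion and ``"z"`` after
    z-score normalisation.  ``processing_log`` records every applied
    operation with its parameters, in application order.
    """

    subject_id: str
    group: str
    sampling_rate_hz: float
    channels: list[str]
    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    units: str = "uM"
    processing_log: list[dict] = field(default_factory=list)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.units not in ("uM", "z"):
            raise ValidationError(f"units must be 'uM' or 'z', got {self.units!r}")
        if self.hbo.shape != self.hbr.shape:
            raise ValidationError("hbo and hbr must share shape")
        if self.hbo.ndim != 2 or self.hbo.shape[0] != len(self.channels):
            raise ValidationError("hb arrays must be (n_channels, n_samples)")
        if self.units == "z" and self.hbo.shape[1] > 1:
            for name, arr in (("hbo", self.hbo), ("hbr", self.hbr)):
                mu = np.abs(arr.mean(axis=1)).max()
                sd = np.abs(arr.std(axis=1) - 1).max()
                if mu > 1e-6 or sd > 1e-6:
                    raise ValidationError(
                        f"z-units {name} violates mean 0 / std 1 (|mean| {mu:.2e}, "
                        f"|std-1| {sd:.2e})"
                    )

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def log(self, stage: str, **params) -> None:
        self.processing_log.append({"stage": stage, **params})

    def copy_with(self, hbo: np.ndarray, hbr: np.ndarray,
                  units: str | None = None) -> "HbTimeSeries":
        return HbTimeSeries(
            subject_id=self.subject_id,
            group=self.group,
            sampling_rate_hz=self.sampling_rate_hz,
            channels=list(self.channels),
            hbo=hbo,
            hbr=hbr,
            units=self.units if units is None else units,
            processing_log=[dict(e) for e in self.processing_log],
            t0_s=self.t0_s,
        )


@dataclass
class TestResult:
    """One nonparametric comparison.

    ``z_value`` is present only for the Mann-Whitney U test (the normal
    approximation the field reports); Kruskal-Wallis carries H and
    Kolmogorov-Smirnov carries D in ``statistic``.
    """

    __test__ = False  # keep pytest from collecting this despite the name

    test: str  # MWU | KW | KS
    groups: dict[str, int]
    statistic: float
    p_value: float
    z_value: float | None = None
    tie_corrected: bool = False
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.test not in ("MWU", "KW", "KS"):
            raise ValidationError(f"unknown test {self.test!r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")
        if any(n < 1 for n in self.groups.values()):
            raise ValidationError("group sizes must be >= 1")
        if (self.test == "MWU") != (self.z_value is not None):
            raise ValidationError("z_value must be present iff test is MWU")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "groups": dict(self.groups),
            "statistic": float(self.statistic),
            "z_value": None if self.z_value is None else float(self.z_value),
            "p_value": float(self.p_value),
            "tie_corrected": bool(self.tie_corrected),
            "context": dict(self.context),
        }

    def report(self) -> str:
        """Two-decimal statistic / three-decimal p, full precision retained."""
        stat = f"Z = {self.z_value:.2f}" if self.test == "MWU" else (
            f"H = {self.statistic:.2f}" if self.test == "KW" else f"D = {self.statistic:.2f}"
        )
        return f"{self.test}: {stat}, p = {self.p_value:.3f}"


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _meta_lines(meta: Mapping) -> list[str]:
    return [f"# {key}\t{json.dumps(val)}" for key, val in meta.items()]


def _read_meta(path) -> tuple[dict, int]:
    meta: dict = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            try:
                key, val = line[1:].strip().split("\t", 1)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed metadata line {n_meta}") from exc
            meta[key] = json.loads(val)
    return meta, n_meta


def write_recording(rec: OpticalRecording, path, dialect: str = "tsv") -> str:
    """Write a recording; returns the path.  Lossless at double precision."""
    rec.validate()
    if dialect == "tsv":
        return _write_recording_tsv(rec, path)
    if dialect == "snirf":
        return _write_recording_snirf(rec, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path, dialect: str = "tsv") -> OpticalRecording:
    if dialect == "tsv":
        return _read_recording_tsv(path)
    if dialect == "snirf":
        return _read_recording_snirf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_recording_tsv(rec: OpticalRecording, path) -> str:
    labels = rec.montage.channel_labels
    cols = ["time_s"] + [
        f"{lab}@{wl:g}" for lab in labels for wl in rec.wavelengths_nm
    ]
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "wavelengths_nm": list(rec.wavelengths_nm),
        "t0_s": rec.t0_s,
        "montage": rec.montage.to_dict(),
    }
    n_ch, n_wl, n_t = rec.intensity.shape
    data = np.empty((n_t, 1 + n_ch * n_wl))
    data[:, 0] = rec.times_s
    data[:, 1:] = rec.intensity.reshape(n_ch * n_wl, n_t).T
    with open(path, "w") as fh:
        fh.write("\n".join(_meta_lines(meta)) + "\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, data, fmt=_FLOAT_FMT, delimiter="\t")
    return str(path)


def _read_recording_tsv(path) -> OpticalRecording:
    meta, n_meta = _read_meta(path)
    for key in ("subject_id", "group", "sampling_rate_hz", "wavelengths_nm", "montage"):
        if key not in meta:
            raise FormatError(f"{path}: missing metadata key {key!r}")
    montage = Montage.from_dict(meta["montage"])
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    try:
        table = pd.read_csv(path, sep="\t", skiprows=n_meta)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse data table: {exc}") from exc
    expected = ["time_s"] + [
        f"{lab}@{wl:g}" for lab in montage.channel_labels for wl in wavelengths
    ]
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = table[expected].isna()
    if bad.values.any():
        row = int(np.argwhere(bad.values)[0][0])
        raise FormatError(
            f"{path}: malformed value at data line {row + 1} "
            f"(file line {n_meta + 2 + row})"
        )
    n_t = len(table)
    n_ch, n_wl = montage.n_channels, len(wavelengths)
    intensity = table[expected[1:]].values.T.reshape(n_ch, n_wl, n_t)
    return OpticalRecording(
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        intensity=intensity,
        montage=montage,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        wavelengths_nm=wavelengths,
        t0_s=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# SNIRF-style HDF5 container (optional dialect)
# ---------------------------------------------------------------------------


def _write_recording_snirf(rec: OpticalRecording, path) -> str:
    import h5py

    n_ch, n_wl, n_t = rec.intensity.shape
    with h5py.File(path, "w") as f:
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # SNIRF layout: time x measurement columns, one per channel x wavelength
        data.create_dataset(
            "dataTimeSeries", data=rec.intensity.reshape(n_ch * n_wl, n_t).T
        )
        data.create_dataset("time", data=rec.times_s)
        for i in range(n_ch * n_wl):
            ch, wl = divmod(i, n_wl)
            ml = data.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=wl + 1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("group", data=rec.group)
        meta.create_dataset("sampling_rate_hz", data=rec.sampling_rate_hz)
        meta.create_dataset("t0_s", data=rec.t0_s)
        meta.create_dataset("montage_json", data=json.dumps(rec.montage.to_dict()))
    return str(path)


def _read_recording_snirf(path) -> OpticalRecording:
    import h5py

    with h5py.File(path, "r") as f:
        try:
            nirs = f["nirs"]
            series = np.asarray(nirs["data1/dataTimeSeries"])
            wavelengths = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
            meta = nirs["metaDataTags"]
            montage = Montage.from_dict(json.loads(meta["montage_json"][()].decode()))
            subject_id = meta["SubjectID"][()].decode()
            group = meta["group"][()].decode()
            fs = float(meta["sampling_rate_hz"][()])
            t0 = float(meta["t0_s"][()])
        except KeyError as exc:
            raise FormatError(f"{path}: missing SNIRF block {exc}") from exc
    n_ch, n_wl = montage.n_channels, len(wavelengths)
    intensity = series.T.reshape(n_ch, n_wl, -1)
    return OpticalRecording(
        subject_id=subject_id,
        group=group,
        intensity=intensity,
        montage=montage,
        sampling_rate_hz=fs,
        wavelengths_nm=wavelengths,
        t0_s=t0,
    )


def write_hb_series(hb: HbTimeSeries, path) -> str:
    """Write a cleaned concentration series (columns HbO@ch / HbR@ch)."""
    meta = {
        "subject_id": hb.subject_id,
        "group": hb.group,
        "sampling_rate_hz": hb.sampling_rate_hz,
        "channels": list(hb.channels),
        "units": hb.units,
        "t0_s": hb.t0_s,
        "processing_log": hb.processing_log,
    }
    cols = ["time_s"] + [f"HbO@{c}" for c in hb.channels] + [f"HbR@{c}" for c in hb.channels]
    data = np.column_stack([hb.times_s, hb.hbo.T, hb.hbr.T])
    with open(path, "w") as fh:
        fh.write("\n".join(_meta_lines(meta)) + "\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, data, fmt=_FLOAT_FMT, delimiter="\t")
    return str(path)


def read_hb_series(path) -> HbTimeSeries:
    meta, n_meta = _read_meta(path)
    channels = [str(c) for c in meta["channels"]]
    table = pd.read_csv(path, sep="\t", skiprows=n_meta)
    hbo = table[[f"HbO@{c}" for c in channels]].values.T
    hbr = table[[f"HbR@{c}" for c in channels]].values.T
    return HbTimeSeries(
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channels=channels,
        hbo=hbo,
        hbr=hbr,
        units=str(meta["units"]),
        processing_log=list(meta.get("processing_log", [])),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# events / features / results
# ---------------------------------------------------------------------------


def write_events(schedule: EventSchedule, path) -> str:
    frame = schedule.frame[["onset_s", "duration_s", "condition"]]
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return str(path)


def read_events(path) -> EventSchedule:
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse event table: {exc}") from exc
    return EventSchedule(frame)


def write_features(table: pd.DataFrame, path) -> str:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return str(path)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_test_results(results: Sequence[TestResult], path) -> str:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
    return str(path)


def read_test_results(path) -> list[TestResult]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        TestResult(
            test=r["test"],
            groups={k: int(v) for k, v in r["groups"].items()},
            statistic=r["statistic"],
            p_value=r["p_value"],
            z_value=r["z_value"],
            tie_corrected=r["tie_corrected"],
            context=r.get("context", {}),
        )
        for r in raw
    ]
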