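"""Config-driven orchestration: simulate → preprocess → features → stats → plot.

A single YAML file (see :func:`default_config_dict`) drives the whole chain;
one master seed makes every output reproducible, with per-subject streams
derived deterministically.  Each stage can be run individually and resumes
from the files a previous stage left in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

import nirsdoc
from nirsdoc import epochs_features, group_stats, io_formats, preprocess, synthetic_data
from nirsdoc.epochs_features import EpochWindows
from nirsdoc.io_formats import ValidationError
from nirsdoc.preprocess import PreprocessConfig, RejectionConfig
from nirsdoc.synthetic_data import CohortSpec, NoiseSpec, ParadigmSpec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration violates its schema."""


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    windows: EpochWindows = field(default_factory=EpochWindows)
    feature_mode: str = "per-epoch"
    alpha: float = 0.05
    outdir: str = "nirsdoc_output"

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError(f"stats.alpha must lie in (0, 1), got {self.alpha}")
        if self.feature_mode not in ("per-epoch", "block-avg"):
            raise ConfigError(f"features.mode must be per-epoch or block-avg, "
                              f"got {self.feature_mode!r}")
        self.generator.seed = int(self.seed)
        self.generator.validate()
        self.preprocess.validate()


def default_config_dict() -> dict:
    """Fully materialised default configuration (what 'default' means)."""
    return config_to_dict(PipelineConfig())


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Materialise every effective setting of a configuration."""
    noise = asdict(cfg.generator.noise)
    return {
        "seed": cfg.seed,
        "generator": {
            "n_per_group": dict(cfg.generator.n_per_group),
            "sampling_rate_hz": cfg.generator.sampling_rate_hz,
            "noise": noise,
            "paradigm": asdict(cfg.generator.paradigm),
            "profiles": [asdict(p) for p in cfg.generator.profiles.values()],
        },
        "preprocess": {
            "i0_definition": cfg.preprocess.i0_definition,
            "dpf": {f"{k:g}": v for k, v in cfg.preprocess.dpf.items()},
            "extinction": {f"{k:g}": dict(v) for k, v in cfg.preprocess.extinction.items()},
            "d_cm": cfg.preprocess.d_cm,
            "band_hz": list(cfg.preprocess.band_hz),
            "filter_order": cfg.preprocess.filter_order,
            "cbsi_enabled": cfg.preprocess.cbsi_enabled,
            "rejection": asdict(cfg.preprocess.rejection),
        },
        "windows": {k: list(v) for k, v in asdict(cfg.windows).items()},
        "features": {"mode": cfg.feature_mode},
        "stats": {"alpha": cfg.alpha},
        "output": {"directory": cfg.outdir},
    }


def _take(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def config_from_dict(raw: dict) -> PipelineConfig:
    """Parse and validate a configuration mapping (the YAML schema)."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _take(raw, {"seed", "generator", "preprocess", "windows", "features",
                "stats", "output"}, "top level")
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", 0))

    gen = raw.get("generator", {}) or {}
    _take(gen, {"n_per_group", "sampling_rate_hz", "noise", "paradigm", "profiles"},
          "generator")
    spec = CohortSpec(seed=cfg.seed)
    if "n_per_group" in gen:
        spec.n_per_group = {str(k): int(v) for k, v in gen["n_per_group"].items()}
    if "sampling_rate_hz" in gen:
        spec.sampling_rate_hz = float(gen["sampling_rate_hz"])
    if "noise" in gen:
        _take(gen["noise"], set(asdict(NoiseSpec())), "generator.noise")
        spec.noise = replace(NoiseSpec(), **gen["noise"])
    if "paradigm" in gen:
        _take(gen["paradigm"], set(asdict(ParadigmSpec())), "generator.paradigm")
        spec.paradigm = replace(ParadigmSpec(), **gen["paradigm"])
    if "profiles" in gen:
        profiles = {}
        for p in gen["profiles"]:
            prof = synthetic_data.ResponseProfile(**p)
            profiles[(prof.group, prof.condition)] = prof
        spec.profiles = profiles
    cfg.generator = spec

    pp = raw.get("preprocess", {}) or {}
    _take(pp, {"i0_definition", "dpf", "extinction", "d_cm", "band_hz",
               "filter_order", "cbsi_enabled", "rejection"}, "preprocess")
    pcfg = PreprocessConfig()
    if "i0_definition" in pp:
        pcfg.i0_definition = str(pp["i0_definition"])
    if "dpf" in pp:
        pcfg.dpf = {float(k): float(v) for k, v in pp["dpf"].items()}
    if "extinction" in pp:
        pcfg.extinction = {
            float(k): {str(c): float(e) for c, e in v.items()}
            for k, v in pp["extinction"].items()
        }
    if "d_cm" in pp:
        pcfg.d_cm = float(pp["d_cm"])
    if "band_hz" in pp:
        pcfg.band_hz = tuple(float(v) for v in pp["band_hz"])
    if "filter_order" in pp:
        pcfg.filter_order = int(pp["filter_order"])
    if "cbsi_enabled" in pp:
        pcfg.cbsi_enabled = bool(pp["cbsi_enabled"])
    if "rejection" in pp:
        _take(pp["rejection"], {"max_abs_z", "max_jump_z"}, "preprocess.rejection")
        pcfg.rejection = RejectionConfig(**pp["rejection"])
    cfg.preprocess = pcfg
    cfg.generator.mbll = pcfg  # forward model shares the inversion constants

    win = raw.get("windows", {}) or {}
    _take(win, {"segment", "analysis", "baseline", "mean_window", "slope_window"},
          "windows")
    try:
        cfg.windows = EpochWindows(**{k: tuple(v) for k, v in win.items()})
    except ValidationError as exc:
        raise ConfigError(f"windows: {exc}") from exc

    feats = raw.get("features", {}) or {}
    _take(feats, {"mode"}, "features")
    cfg.feature_mode = str(feats.get("mode", "per-epoch"))

    st = raw.get("stats", {}) or {}
    _take(st, {"alpha"}, "stats")
    cfg.alpha = float(st.get("alpha", 0.05))

    out = raw.get("output", {}) or {}
    _take(out, {"directory"}, "output")
    cfg.outdir = str(out.get("directory", "nirsdoc_output"))

    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_simulate(cfg: PipelineConfig, outdir: str) -> pd.DataFrame:
    cohort_dir = os.path.join(outdir, "cohort")
    cohort = synthetic_data.generate_cohort(cfg.generator)
    manifest = synthetic_data.write_cohort(cohort, cohort_dir)
    logger.info("simulate: wrote %d recordings to %s", len(manifest), cohort_dir)
    return manifest


def _load_manifest(outdir: str) -> pd.DataFrame:
    path = os.path.join(outdir, "cohort", "manifest.tsv")
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"{path} not found — run the simulate stage first (nirsdoc simulate)"
        )
    manifest = pd.read_csv(path, sep="\t")
    cohort_dir = os.path.join(outdir, "cohort")
    for col in ("recording_path", "events_path"):
        manifest[col] = [
            p if os.path.isabs(p) else os.path.join(cohort_dir, p)
            for p in manifest[col]
        ]
    return manifest


def stage_preprocess(cfg: PipelineConfig, outdir: str) -> list[str]:
    manifest = _load_manifest(outdir)
    clean_dir = os.path.join(outdir, "clean")
    os.makedirs(clean_dir, exist_ok=True)
    paths = []
    for _, row in manifest.iterrows():
        rec = io_formats.read_recording(row["recording_path"])
        hb = preprocess.preprocess_recording(rec, cfg.preprocess)
        path = os.path.join(clean_dir, f"{row['subject_id']}_hb.tsv")
        io_formats.write_hb_series(hb, path)
        paths.append(path)
        logger.info("preprocess: %s -> %s (%d channels)", row["subject_id"], path,
                    len(hb.channels))
    return paths


def stage_features(cfg: PipelineConfig, outdir: str) -> pd.DataFrame:
    manifest = _load_manifest(outdir)
    clean_dir = os.path.join(outdir, "clean")
    tables = []
    curves = []
    for _, row in manifest.iterrows():
        hb_path = os.path.join(clean_dir, f"{row['subject_id']}_hb.tsv")
        if not os.path.exists(hb_path):
            raise FileNotFoundError(
                f"{hb_path} not found — run the preprocess stage first"
            )
        hb = io_formats.read_hb_series(hb_path)
        schedule = io_formats.read_events(row["events_path"])
        table = epochs_features.subject_features(
            hb, schedule, cfg.windows, cfg.preprocess.rejection, cfg.feature_mode
        )
        tables.append(table)
        curves.append(epochs_features.block_average_curves(
            hb, schedule, cfg.windows, cfg.preprocess.rejection
        ))
        n_rej = int((~table["retained"]).sum())
        logger.info("features: %s — %d rows, %d flagged", row["subject_id"],
                    len(table), n_rej)
    features = epochs_features.build_feature_table(tables)
    io_formats.write_features(features, os.path.join(outdir, "features.tsv"))
    pd.concat(curves, ignore_index=True).to_csv(
        os.path.join(outdir, "block_average_curves.tsv"), sep="\t", index=False,
        float_format="%.17g",
    )
    return features


def stage_stats(cfg: PipelineConfig, outdir: str) -> list[io_formats.TestResult]:
    feat_path = os.path.join(outdir, "features.tsv")
    if not os.path.exists(feat_path):
        raise FileNotFoundError(f"{feat_path} not found — run the features stage first")
    features = io_formats.read_features(feat_path)
    retained = features[features["retained"]]
    results = group_stats.run_comparisons(retained, mode=cfg.feature_mode)
    io_formats.write_test_results(results, os.path.join(outdir, "test_results.json"))
    summary = group_stats.summarize(retained)
    summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False,
                   float_format="%.17g")
    for res in results:
        logger.info("stats: %s — %s", res.context.get("contrast"), res.report())
    return results


def plot_group_curves(curves: pd.DataFrame, outdir: str,
                      filename: str = "group_curves.png") -> str:
    """One panel per group × condition: group-mean HbO / HbR ± SEM."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = ["HC", "MCS", "VS"]
    conditions = ["SON", "MI"]
    fig, axes = plt.subplots(len(groups), len(conditions),
                             figsize=(9, 9), sharex=True, sharey=True)
    for gi, group in enumerate(groups):
        for ci, condition in enumerate(conditions):
            ax = axes[gi, ci]
            cell = curves[(curves["group"] == group) & (curves["condition"] == condition)]
            if cell.empty:
                ax.text(0.5, 0.5, "no data", ha="center", va="center",
                        transform=ax.transAxes)
            else:
                for chrom, color in (("HbO", "crimson"), ("HbR", "royalblue")):
                    sub = cell[cell["chromophore"] == chrom]
                    # average over subjects and channels at each time point
                    g = sub.groupby("time_s")["value"]
                    mean, sem = g.mean(), g.sem()
                    ax.plot(mean.index, mean.values, color=color, label=chrom)
                    ax.fill_between(mean.index, mean - sem, mean + sem,
                                    color=color, alpha=0.25, linewidth=0)
                ax.axvspan(0, 30, color="0.9", zorder=0)
                ax.axhline(0.0, color="0.5", linewidth=0.5)
            ax.set_title(f"{group} — {condition}")
            if gi == len(groups) - 1:
                ax.set_xlabel("time from onset (s)")
            if ci == 0:
                ax.set_ylabel("Δconcentration (z)")
    axes[0, 0].legend(loc="upper right", frameon=False)
    fig.tight_layout()
    path = os.path.join(outdir, filename)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def stage_plot(cfg: PipelineConfig, outdir: str) -> str:
    path = os.path.join(outdir, "block_average_curves.tsv")
    if not os.path.exists(path):
        raise FileNotFoundError(f"{path} not found — run the features stage first")
    curves = pd.read_csv(path, sep="\t")
    out = plot_group_curves(curves, outdir)
    logger.info("plot: wrote %s", out)
    return out


def run_all(cfg: PipelineConfig, outdir: str | None = None) -> str:
    """Run every stage and write a provenance manifest; returns the outdir."""
    cfg.validate()
    outdir = outdir or cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "pipeline.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("nirsdoc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        stage_simulate(cfg, outdir)
        stage_preprocess(cfg, outdir)
        stage_features(cfg, outdir)
        stage_stats(cfg, outdir)
        stage_plot(cfg, outdir)
        manifest = {
            "config": config_to_dict(cfg),
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "versions": {
                "nirsdoc": nirsdoc.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
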