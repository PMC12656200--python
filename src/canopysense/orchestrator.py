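"""End-to-end campaign pipeline: frames + logs + anchors -> fused table -> model.

Wires the stages together: RGB frames to cover metrics, thermal frames to
water-stress indices (with ambient temperature interpolated from the E-nose
log), GPS densification and geofencing, per-tree aggregation of every
stream, feature scaling and splitting, ANN training, and PCA/correlation
statistics.  Each run writes its outputs, a log, and the resolved
configuration into an append-only run directory; partial failures (frames
with no canopy, trees never entered) are logged, not fatal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ann, features, geosync, imaging_rgb, imaging_thermal, sensors_io, stats

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one campaign run.

    All paths are resolved relative to ``base_dir`` when that is set; every
    numeric knob mirrors the stage defaults.
    """

    rgb_frames: Optional[str] = None
    rgb_srt: Optional[str] = None
    thermal_frames: Optional[str] = None
    thermal_srt: Optional[str] = None
    enose_log: Optional[str] = None
    anchors: Optional[str] = None
    track: Optional[str] = None  # SRT or CSV; defaults to the E-nose GPS fixes
    weather: Optional[str] = None
    base_dir: Optional[str] = None

    threshold: Optional[int] = None  # manual blue-histogram threshold
    grid_rows: int = 5
    grid_cols: int = 5
    large_gap_fraction: float = 0.75
    k: float = 0.5
    sky_cutoff: float = 0.0
    p_wet: float = 5.0
    p_dry: float = 95.0
    thermal_gain: float = 1.0
    thermal_offset: float = 0.0
    rate_hz: float = 10.0
    max_radius_m: float = 15.0
    seed: int = 0
    n_hidden: int = 20
    max_epochs: int = 200

    def resolve(self, name: str) -> Optional[Path]:
        value = getattr(self, name)
        if value is None:
            return None
        p = Path(value)
        if not p.is_absolute() and self.base_dir:
            p = Path(self.base_dir) / p
        return p

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if cfg.base_dir is None:
            cfg.base_dir = str(Path(path).parent)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _setup_run_logger(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("canopysense").addHandler(handler)
    return handler


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full campaign flow; returns a dict of output paths/tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logger(out_dir)
    results: dict = {"out_dir": out_dir}
    try:
        config.to_yaml(out_dir / "resolved_config.yaml")

        # --- E-nose stream (needed early: ambient temperature for CTD)
        enose_df = None
        if config.resolve("enose_log"):
            samples = sensors_io.read_enose_log(config.resolve("enose_log"))
            enose_df = sensors_io.enose_frame(samples)
            log.info("E-nose: %d samples", len(enose_df))

        # --- RGB stage
        rgb_df = None
        if config.resolve("rgb_frames"):
            rgb_df = imaging_rgb.process_directory(
                config.resolve("rgb_frames"),
                threshold=config.threshold,
                grid_rows=config.grid_rows,
                grid_cols=config.grid_cols,
                large_gap_fraction=config.large_gap_fraction,
                k=config.k,
            )
            if config.resolve("rgb_srt"):
                rgb_track = sensors_io.parse_srt(config.resolve("rgb_srt"))
                if len(rgb_track) != len(rgb_df):
                    raise ValueError(
                        f"RGB SRT has {len(rgb_track)} blocks for {len(rgb_df)} frames"
                    )
                rgb_df.insert(1, "time", rgb_track.times)
            rgb_df.to_csv(out_dir / "rgb_metrics.csv", index=False)
            log.info("RGB: %d frames processed", len(rgb_df))
            results["rgb"] = rgb_df

        # --- thermal stage
        thermal_df = None
        if config.resolve("thermal_frames"):
            calib = imaging_thermal.ThermalCalibration(
                gain=config.thermal_gain, offset=config.thermal_offset
            )
            timestamps = None
            if config.resolve("thermal_srt"):
                timestamps = sensors_io.parse_srt(config.resolve("thermal_srt")).times
            frames = imaging_thermal.read_thermal_frames(
                config.resolve("thermal_frames"), calib, timestamps
            )
            rows = []
            for fr in frames:
                t_avg = np.nan
                if enose_df is not None and fr.timestamp is not None:
                    t_avg = float(
                        np.interp(fr.timestamp, enose_df["time"], enose_df["temp_C"])
                    )
                try:
                    ws = imaging_thermal.water_status_for_frame(
                        fr, t_avg, config.sky_cutoff, config.p_wet, config.p_dry
                    )
                except imaging_thermal.EmptyCanopyError:
                    log.warning("thermal frame %s: no canopy, skipped", fr.frame_id)
                    continue
                rows.append(
                    {
                        "frame_id": fr.frame_id,
                        "time": fr.timestamp,
                        "t_canopy": ws.t_canopy,
                        "t_wet": ws.t_wet,
                        "t_dry": ws.t_dry,
                        "raw_index": ws.raw_index,
                        "twsi": ws.twsi,
                        "ig": ws.ig,
                        "ctd": ws.ctd,
                    }
                )
            thermal_df = pd.DataFrame(rows)
            thermal_df.to_csv(out_dir / "thermal_metrics.csv", index=False)
            log.info("thermal: %d frames kept", len(thermal_df))
            results["thermal"] = thermal_df

        # --- geofencing and fusion
        per_tree = None
        if config.resolve("anchors"):
            anchors = geosync.read_anchors_csv(config.resolve("anchors"))
            track_path = config.resolve("track")
            if track_path is not None:
                track = sensors_io.parse_srt(track_path)
            elif enose_df is not None:
                samples = sensors_io.read_enose_log(config.resolve("enose_log"))
                track = geosync.GeoTrack(
                    times=np.array([s.timestamp for s in samples]),
                    lats=np.array([s.latitude for s in samples]),
                    lons=np.array([s.longitude for s in samples]),
                    alts=np.array([s.altitude for s in samples]),
                )
            else:
                raise ValueError("anchors given but no track or E-nose GPS available")
            dense = geosync.densify_track(track, config.rate_hz)
            regions = geosync.build_geofences(anchors, config.max_radius_m)
            intervals = geosync.region_intervals(dense, regions)
            log.info(
                "geosync: %d/%d trees entered", len({iv.tree_id for iv in intervals}),
                len(anchors),
            )
            merged: dict[str, geosync.TreeRecord] = {}
            streams = []
            if rgb_df is not None and "time" in rgb_df.columns:
                streams.append(rgb_df[["time", "lai", "laie"]])
            if thermal_df is not None and len(thermal_df):
                streams.append(thermal_df[["time", "twsi", "ig", "ctd", "raw_index"]])
            if enose_df is not None:
                streams.append(enose_df)
            for stream in streams:
                for rec in geosync.aggregate_by_interval(stream, intervals):
                    tgt = merged.setdefault(
                        rec.tree_id,
                        geosync.TreeRecord(rec.tree_id, rec.entry_time, rec.exit_time),
                    )
                    tgt.means.update(rec.means)
                    tgt.counts.update(rec.counts)
            per_tree = geosync.records_to_frame(
                sorted(merged.values(), key=lambda r: r.entry_time)
            )
            if len(per_tree):
                per_tree = per_tree.rename(columns={"temp_C": "temp_C", "rh_pct": "rh_pct"})
            per_tree.to_csv(out_dir / "per_tree.csv", index=False)
            results["per_tree"] = per_tree

        # --- ANN on the fused table
        if per_tree is not None and len(per_tree) >= features.MIN_ROWS:
            needed = set(features.INPUT_ORDER[:8]) | {"temp_C", "rh_pct"} | set(
                features.TARGET_ORDER
            )
            if needed <= set(per_tree.columns):
                dataset = features.build_dataset(per_tree)
                if len(dataset) >= features.MIN_ROWS:
                    dataset = features.split_dataset(dataset, config.seed)
                    features.save_dataset(
                        dataset, out_dir / "scaled.csv", out_dir / "split_manifest.csv"
                    )
                    model = ann.init_network(
                        n_hidden=config.n_hidden, seed=config.seed
                    )
                    model, report = ann.train_lm(
                        model, dataset, max_epochs=config.max_epochs
                    )
                    ann.save_model(model, out_dir / "model.json")
                    (out_dir / "fit_report.json").write_text(
                        json.dumps(dataclasses.asdict(report), indent=1)
                    )
                    results["fit_report"] = report
                else:
                    log.warning("too few complete rows for ANN training; skipped")
            else:
                log.warning("per-tree table lacks ANN columns; training skipped")
        elif per_tree is not None:
            log.warning(
                "only %d per-tree rows (< %d); ANN training skipped",
                len(per_tree), features.MIN_ROWS,
            )

        # --- statistics on the fused table
        if per_tree is not None and len(per_tree) >= 3:
            numeric = per_tree.select_dtypes("number").drop(
                columns=["entry_time", "exit_time"], errors="ignore"
            )
            numeric = numeric[[c for c in numeric.columns if not c.startswith("n_")]]
            numeric = numeric.dropna(axis=1, how="any")
            varying = numeric.loc[:, numeric.std(ddof=1) > 0]
            if varying.shape[1] >= 2:
                pca_res = stats.pca(varying)
                stats.export_pca(pca_res, out_dir / "stats")
                corr = stats.pearson_matrix(varying)
                stats.export_correlation(corr, out_dir / "stats_correlation.csv")
                results["pca"] = pca_res
                results["correlation"] = corr
            else:
                log.warning("fewer than 2 varying columns; statistics skipped")
    finally:
        logging.getLogger("canopysense").removeHandler(handler)
        handler.close()
    return results
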