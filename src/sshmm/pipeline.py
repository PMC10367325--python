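"""Orchestration: files in, prepared datasets, experiment series out.

Binds the stages together: read raw GPS tracks (CSV), regularize and
segment them, compute movement metrics, align sensor summaries onto fix
intervals and fuse them into known states, then run the supervision
sweep. Everything on disk is plain text (RFC-4180 CSV, UTF-8, JSON) and
every result file carries provenance (config, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import evaluation, hmm
from .sensor_fusion import UNKNOWN, fuse_track
from .simulate import SimConfig, SimOutput, simulate_dataset
from .track_prep import (
    MoveSeries,
    RawTrack,
    RegularTrack,
    compute_move_metrics,
    regularize,
)

__all__ = [
    "RunConfig",
    "read_tracks",
    "write_tracks",
    "PreparedDataset",
    "prepare_dataset",
    "write_sim_output",
    "read_sim_output",
    "run_experiment",
]

log = logging.getLogger("sshmm")

SENSOR_COLS = ["prop_wet", "prop_on_water", "prop_flapping", "dives_acc", "dives_tdr"]

DEFAULT_ALIASES = {
    "trip_id": ["trip_id", "trip", "tag-local-identifier", "individual-local-identifier"],
    "timestamp": ["timestamp", "time", "t"],
    "x": ["x", "lon", "longitude", "location-long"],
    "y": ["y", "lat", "latitude", "location-lat"],
}


@dataclass
class RunConfig:
    """Declarative settings for one experiment run."""

    tracks_path: str | None = None
    sensors_path: str | None = None
    truth_path: str | None = None
    out_dir: str = "results"
    interval_s: float = 300.0
    max_gap_s: float = 1200.0
    crs_mode: str = "planar_m"
    fusion_eps: float = 0.0
    n_restarts: int = 10
    maxiter: int = 300
    seed: int = 0
    n_folds: int = 10
    test_frac: float = 0.10
    fractions: list[float] = field(default_factory=lambda: [0.0, 0.05])
    thresholds: list[float] = field(default_factory=lambda: [0.90])
    simulate: SimConfig | None = None

    def __post_init__(self) -> None:
        self.fractions = sorted(self.fractions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_jsonable()
        return d


def _resolve_columns(df: pd.DataFrame, aliases: dict | None) -> dict[str, str]:
    aliases = aliases or DEFAULT_ALIASES
    resolved = {}
    lower = {c.lower(): c for c in df.columns}
    for canon, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                resolved[canon] = lower[name.lower()]
                break
        else:
            raise ValueError(f"missing required column {canon!r} (tried {names})")
    return resolved


def read_tracks(path: str | Path, aliases: dict | None = None) -> list[RawTrack]:
    """Read raw GPS fixes from CSV into per-trip records.

    Timestamps may be epoch seconds or ISO-8601. Malformed rows are
    dropped and counted in the parse report (logged at WARNING).
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        warnings.warn(f"{path}: no rows")
        return []
    cols = _resolve_columns(df, aliases)
    n_raw = len(df)
    ts = pd.to_numeric(df[cols["timestamp"]], errors="coerce")
    if ts.isna().any():
        parsed = pd.to_datetime(
            df[cols["timestamp"]], errors="coerce", utc=True, format="mixed"
        )
        epoch = parsed.map(lambda d: d.timestamp() if pd.notna(d) else np.nan)
        ts = ts.fillna(epoch)
    df = df.assign(
        _t=ts,
        _x=pd.to_numeric(df[cols["x"]], errors="coerce"),
        _y=pd.to_numeric(df[cols["y"]], errors="coerce"),
    )
    bad = df[["_t", "_x", "_y"]].isna().any(axis=1)
    if bad.any():
        log.warning("%s: dropped %d malformed rows of %d", path, int(bad.sum()), n_raw)
    df = df[~bad]
    tracks = []
    for trip_id, g in df.groupby(cols["trip_id"], sort=False):
        g = g.sort_values("_t")
        if g["_t"].duplicated().any():
            log.warning("trip %s: dropped duplicate timestamps", trip_id)
            g = g[~g["_t"].duplicated()]
        tracks.append(
            RawTrack(str(trip_id), g["_t"].to_numpy(), g["_x"].to_numpy(), g["_y"].to_numpy())
        )
    return tracks


def write_tracks(tracks: list[RawTrack], path: str | Path) -> None:
    rows = [
        pd.DataFrame({"trip_id": t.trip_id, "timestamp": t.times, "x": t.x, "y": t.y})
        for t in tracks
    ]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


@dataclass
class PreparedDataset:
    """Regularized tracks + movement metrics + known states, HMM-ready.

    ``frame`` has one row per regularized fix in flat (trip, segment,
    time) order — the same order as ``obs`` flattens to. ``known`` is the
    per-fix label vector (-1 unknown); ``true_state`` is -1 where truth
    is unavailable (real data, or fixes interpolated across a gap in the
    truth grid).
    """

    frame: pd.DataFrame
    obs: hmm.Observations
    known: np.ndarray
    true_state: np.ndarray
    regular_tracks: list[RegularTrack]
    moves: list[MoveSeries]

    @property
    def n_fixes(self) -> int:
        return len(self.frame)

    @property
    def known_idx(self) -> np.ndarray:
        return np.flatnonzero(self.known >= 0)


def prepare_dataset(
    tracks: list[RawTrack],
    sensors: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    interval_s: float = 300.0,
    max_gap_s: float = 1200.0,
    crs_mode: str = "planar_m",
    fusion_eps: float = 0.0,
) -> PreparedDataset:
    """Regularize, compute metrics, align sensors, fuse known states.

    ``sensors``/``truth`` are keyed by (trip_id, timestamp) on the
    original fix grid; they join onto regularized fixes by time, so
    fixes re-interpolated inside short gaps inherit the sensor summary
    recorded for that interval (devices keep logging through GPS
    dropouts).
    """
    frames, regs, moves = [], [], []
    for raw in tracks:
        reg = regularize(raw, interval_s=interval_s, max_gap_s=max_gap_s)
        reg.crs_mode = crs_mode
        if reg.n_fixes == 0:
            continue
        mv = compute_move_metrics(reg)
        seg_rows = []
        for si, seg in enumerate(reg.segments):
            seg_rows.append(
                pd.DataFrame(
                    {
                        "trip_id": raw.trip_id,
                        "segment_id": f"{raw.trip_id}:{si}",
                        "timestamp": seg.times,
                        "x": seg.x,
                        "y": seg.y,
                        "interpolated": seg.interpolated.astype(int),
                    }
                )
            )
        df = pd.concat(seg_rows, ignore_index=True)
        df["step"] = mv.step
        df["angle"] = mv.angle
        frames.append(df)
        regs.append(reg)
        moves.append(mv)
    if not frames:
        raise ValueError("no usable tracks")
    frame = pd.concat(frames, ignore_index=True)

    if sensors is not None:
        sens = frame[["trip_id", "timestamp"]].merge(
            sensors, on=["trip_id", "timestamp"], how="left"
        )
        pos = 0
        fused_parts = []
        for reg in regs:
            n = reg.n_fixes
            fused_parts.append(fuse_track(reg, sens.iloc[pos : pos + n][SENSOR_COLS].reset_index(drop=True), eps=fusion_eps))
            pos += n
        fused = pd.concat(fused_parts, ignore_index=True)
        frame = pd.concat([frame, sens[SENSOR_COLS], fused], axis=1)
        known = fused["label"].to_numpy()
    else:
        known = np.full(len(frame), UNKNOWN, dtype=int)
        frame["label"] = known
        frame["label_name"] = "UNKNOWN"

    if truth is not None:
        tr = frame[["trip_id", "timestamp"]].merge(
            truth[["trip_id", "timestamp", "true_state"]],
            on=["trip_id", "timestamp"],
            how="left",
        )
        true_state = tr["true_state"].fillna(-1).astype(int).to_numpy()
    else:
        true_state = np.full(len(frame), -1, dtype=int)
    frame["true_state"] = true_state

    obs = hmm.Observations.from_move_series(moves, known_flat=known)
    return PreparedDataset(frame, obs, known, true_state, regs, moves)


def write_sim_output(sim: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": out / "tracks.csv",
        "sensors": out / "sensors.csv",
        "truth": out / "truth.csv",
        "config": out / "sim_config.json",
    }
    write_tracks(sim.tracks, paths["tracks"])
    sim.sensors.to_csv(paths["sensors"], index=False)
    sim.truth.to_csv(paths["truth"], index=False)
    paths["config"].write_text(json.dumps(_provenance(sim.config.to_jsonable()), indent=2))
    return paths


def read_sim_output(out_dir: str | Path) -> tuple[list[RawTrack], pd.DataFrame, pd.DataFrame]:
    out = Path(out_dir)
    tracks = read_tracks(out / "tracks.csv")
    sensors = pd.read_csv(out / "sensors.csv")
    truth = pd.read_csv(out / "truth.csv")
    return tracks, sensors, truth


def _provenance(payload: dict) -> dict:
    blob = json.dumps(payload, sort_keys=True).encode()
    return {
        "sshmm_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": payload,
    }


def run_experiment(config: RunConfig) -> pd.DataFrame:
    """Execute prepare -> fuse -> sweep and write artifacts to disk.

    With ``config.simulate`` set, the inputs are generated first and
    written alongside the results for provenance; otherwise they are
    read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("experiment seed=%d out=%s", config.seed, out)
    if config.simulate is not None:
        sim = simulate_dataset(config.simulate)
        write_sim_output(sim, out / "inputs")
        tracks, sensors, truth = sim.tracks, sim.sensors, sim.truth
    else:
        if config.tracks_path is None:
            raise ValueError("tracks_path required when not simulating")
        tracks = read_tracks(config.tracks_path)
        sensors = pd.read_csv(config.sensors_path) if config.sensors_path else None
        truth = pd.read_csv(config.truth_path) if config.truth_path else None

    prep = prepare_dataset(
        tracks,
        sensors,
        truth,
        interval_s=config.interval_s,
        max_gap_s=config.max_gap_s,
        crs_mode=config.crs_mode,
        fusion_eps=config.fusion_eps,
    )
    prep.frame.to_csv(out / "prepared.csv", index=False)
    known_idx = prep.known_idx
    log.info(
        "prepared %d fixes, %d known (%.1f%%)",
        prep.n_fixes, len(known_idx), 100.0 * len(known_idx) / prep.n_fixes,
    )
    plan = evaluation.make_folds(
        known_idx, n_folds=config.n_folds, test_frac=config.test_frac, seed=config.seed
    )
    # clip requested fractions at the feasible ceiling
    ceiling = min(len(p) for p in plan.train_pool_idx) / prep.n_fixes
    fractions = [f for f in config.fractions if f <= ceiling]
    if len(fractions) < len(config.fractions):
        log.info("fractions clipped at feasible ceiling %.3f", ceiling)
    sweep = evaluation.supervision_sweep(
        prep.obs,
        prep.known,
        fractions,
        plan,
        thresholds=config.thresholds,
        n_restarts=config.n_restarts,
        seed=config.seed,
        maxiter=config.maxiter,
    )
    sweep.to_csv(out / "sweep.csv", index=False)
    summary = sweep.attrs.get("summary")
    summary_payload = _provenance(config.to_jsonable())
    if summary is not None and len(summary):
        flat = summary.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        summary_payload["summary"] = json.loads(flat.reset_index().to_json(orient="records"))
    (out / "summary.json").write_text(json.dumps(summary_payload, indent=2))
    return sweep
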