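"""Fusing auxiliary biologging sensors into known behavioural states.

Three sensor streams carry direct behavioural information that GPS
movement metrics alone do not: a salt-water immersion (wet-dry) logger,
a tri-axial accelerometer summarized into proportions of time on-water /
flapping plus detected dives, and a time-depth recorder (TDR) giving dive
counts. Each GPS fix interval [t, t+1) receives a summary of the streams
falling inside it (forward matching, consistent with the forward step /
turning-angle convention), and a rule set turns summaries into a *known
state* used to semi-supervise the HMM:

* FORAGE — at least one dive in the accelerometer or TDR stream;
* REST   — the interval is 100% wet, or over 50% on-water, with no dive
  detected in any available dive stream;
* TRAVEL — the interval is 0% wet, or 100% flapping, with no dive
  detected in any available dive stream.

Evidence for both REST and TRAVEL at once (e.g. accelerometer says
on-water while immersion says dry) is incoherent; such fixes stay UNKNOWN
with a conflict flag rather than receiving an arbitrary label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .track_prep import RegularTrack

__all__ = [
    "REST",
    "FORAGE",
    "TRAVEL",
    "UNKNOWN",
    "LABEL_NAMES",
    "SensorSummary",
    "KnownState",
    "align_forward",
    "assign_known_state",
    "fuse_track",
]

# canonical state codes, ordered by expected step length (rest shortest)
REST, FORAGE, TRAVEL = 0, 1, 2
UNKNOWN = -1
LABEL_NAMES = {REST: "REST", FORAGE: "FORAGE", TRAVEL: "TRAVEL", UNKNOWN: "UNKNOWN"}


@dataclass
class SensorSummary:
    """Per-interval sensor summary; ``None`` marks a missing stream."""

    prop_wet: float | None = None
    prop_on_water: float | None = None
    prop_flapping: float | None = None
    dives_acc: int | None = None
    dives_tdr: int | None = None

    def __post_init__(self) -> None:
        for name in ("prop_wet", "prop_on_water", "prop_flapping"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("dives_acc", "dives_tdr"):
            v = getattr(self, name)
            if v is not None and (v < 0 or v != int(v)):
                raise ValueError(f"{name}={v} not a non-negative integer")


@dataclass
class KnownState:
    label: int
    evidence: frozenset = field(default_factory=frozenset)
    conflict: bool = False


def assign_known_state(s: SensorSummary, eps: float = 0.0) -> KnownState:
    """Apply the fusion rules to one interval summary.

    A dive in either stream dominates everything else. The REST/TRAVEL
    rules require every *available* dive stream to read zero; if both dive
    streams are missing they may still fire on immersion/activity evidence
    alone. ``eps`` loosens the exact 100%/0% comparisons for float safety
    (default exact).
    """
    dives = [d for d in (s.dives_acc, s.dives_tdr) if d is not None]
    if any(d >= 1 for d in dives):
        ev = set()
        if s.dives_acc is not None and s.dives_acc >= 1:
            ev.add("dive_acc")
        if s.dives_tdr is not None and s.dives_tdr >= 1:
            ev.add("dive_tdr")
        return KnownState(FORAGE, frozenset(ev))

    # all available dive streams are zero (or none available)
    rest_ev, travel_ev = set(), set()
    if s.prop_wet is not None and s.prop_wet >= 1.0 - eps:
        rest_ev.add("wet_100")
    if s.prop_on_water is not None and s.prop_on_water > 0.5:
        rest_ev.add("on_water_gt50")
    if s.prop_wet is not None and s.prop_wet <= eps:
        travel_ev.add("wet_0")
    if s.prop_flapping is not None and s.prop_flapping >= 1.0 - eps:
        travel_ev.add("flapping_100")

    if rest_ev and travel_ev:
        return KnownState(UNKNOWN, frozenset(rest_ev | travel_ev), conflict=True)
    if rest_ev:
        return KnownState(REST, frozenset(rest_ev))
    if travel_ev:
        return KnownState(TRAVEL, frozenset(travel_ev))
    return KnownState(UNKNOWN)


def align_forward(
    stream: pd.DataFrame, grid_times: np.ndarray, interval_s: float = 300.0
) -> pd.DataFrame:
    """Summarize raw timestamped sensor records forward onto fix intervals.

    ``stream`` has columns ``stream_type`` (one of ``wet``, ``on_water``,
    ``flapping``, ``dive_acc``, ``dive_tdr``), ``timestamp`` (s) and
    ``value``. The summary at grid time *t* aggregates records with
    timestamps in [t, t+interval): binary/proportion streams by
    time-weighted mean (records are treated as left-aligned samples of a
    piecewise-constant signal), dive streams by event count. Intervals
    with no records get NaN (missing).
    """
    grid_times = np.asarray(grid_times, dtype=float)
    out = pd.DataFrame(
        {
            "timestamp": grid_times,
            "prop_wet": np.nan,
            "prop_on_water": np.nan,
            "prop_flapping": np.nan,
            "dives_acc": np.nan,
            "dives_tdr": np.nan,
        }
    )
    if len(stream) == 0:
        warnings.warn("empty sensor stream: all summaries missing")
        return out
    tmin, tmax = stream["timestamp"].min(), stream["timestamp"].max()
    if tmax < grid_times.min() or tmin >= grid_times.max() + interval_s:
        warnings.warn("sensor stream entirely outside track time range")
        return out

    prop_cols = {"wet": "prop_wet", "on_water": "prop_on_water", "flapping": "prop_flapping"}
    count_cols = {"dive_acc": "dives_acc", "dive_tdr": "dives_tdr"}
    for stype, g in stream.groupby("stream_type"):
        ts = g["timestamp"].to_numpy(dtype=float)
        vals = g["value"].to_numpy(dtype=float)
        order = np.argsort(ts, kind="stable")
        ts, vals = ts[order], vals[order]
        idx = np.searchsorted(grid_times, ts, side="right") - 1
        in_interval = (idx >= 0) & (ts < grid_times[np.clip(idx, 0, None)] + interval_s)
        if stype in count_cols:
            # a dive belongs to the interval containing its start time
            counts = np.bincount(idx[in_interval], minlength=len(grid_times))
            out[count_cols[stype]] = counts.astype(float)
        elif stype in prop_cols:
            col = np.full(len(grid_times), np.nan)
            for i in np.unique(idx[in_interval]):
                sel = in_interval & (idx == i)
                st, sv = ts[sel], vals[sel]
                # piecewise-constant: each sample holds until the next
                # record or the interval end
                edges = np.append(st, grid_times[i] + interval_s)
                w = np.diff(edges)
                col[i] = float(np.average(sv, weights=w)) if w.sum() > 0 else float(sv.mean())
            out[prop_cols[stype]] = col
        else:
            raise ValueError(f"unknown stream_type {stype!r}")
    return out


def _row_to_summary(row: pd.Series) -> SensorSummary:
    def f(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

    d_acc, d_tdr = f(row.get("dives_acc")), f(row.get("dives_tdr"))
    return SensorSummary(
        prop_wet=f(row.get("prop_wet")),
        prop_on_water=f(row.get("prop_on_water")),
        prop_flapping=f(row.get("prop_flapping")),
        dives_acc=None if d_acc is None else int(d_acc),
        dives_tdr=None if d_tdr is None else int(d_tdr),
    )


def fuse_track(
    track: RegularTrack, summaries: pd.DataFrame, eps: float = 0.0
) -> pd.DataFrame:
    """Assign a known state to every fix of a regularized track.

    ``summaries`` must have one row per fix (same order as the track's
    concatenated segments). Returns a DataFrame with ``label`` (state code,
    -1 unknown), ``label_name``, ``evidence`` and ``conflict`` columns,
    with per-label counts attached under ``df.attrs['counts']``.
    """
    n = track.n_fixes
    if len(summaries) != n:
        raise ValueError(f"{len(summaries)} summaries for {n} fixes")
    labels = np.empty(n, dtype=int)
    conflicts = np.zeros(n, dtype=bool)
    evidence = []
    for i, (_, row) in enumerate(summaries.iterrows()):
        ks = assign_known_state(_row_to_summary(row), eps=eps)
        labels[i] = ks.label
        conflicts[i] = ks.conflict
        evidence.append(",".join(sorted(ks.evidence)))
    out = pd.DataFrame(
        {
            "label": labels,
            "label_name": [LABEL_NAMES[v] for v in labels],
            "evidence": evidence,
            "conflict": conflicts,
        }
    )
    out.attrs["counts"] = {
        LABEL_NAMES[k]: int((labels == k).sum()) for k in (REST, FORAGE, TRAVEL)
    }
    out.attrs["n_conflict"] = int(conflicts.sum())
    return out
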