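"""Cardiac output, heart rate and stroke volume from pulsatile flow traces.

A transit-time flow probe around the ventral aorta records pulsatile blood
flow (ml min^-1).  Probes are bench-calibrated gravimetrically: water is
pumped at known rates, and a linear map recorded -> true flow corrects the
in-vivo signal.  For every respirometry measure cycle,

* CO  = calibrated mean flow over the window / body mass (ml min^-1 kg^-1),
* fH  = pulse frequency from peak detection, (n_beats - 1) / span * 60,
* SV  = CO / fH (ml kg^-1).

Resting values are means over the cycles that defined SMR; maximum values are
taken at the MMR cycle; scope = maximum - resting and may legitimately be
negative (post-chase heart rate can fall below the resting rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ProbeCalibration",
    "BeatDetection",
    "CardiacSample",
    "calibrate_probe",
    "detect_beats",
    "cardiac_during_cycle",
    "summarize_cardiac",
    "timecourse_extract",
    "POST_CHASE_GRID_MIN",
]

#: minutes after exercise at which time-course values are collected
POST_CHASE_GRID_MIN = (0, 10, 20, 30, 60, 120, 300, 600, 900)


@dataclass
class ProbeCalibration:
    """Linear map recorded -> true flow (true = gain * recorded + offset)."""

    gain: float
    offset: float
    r2: float
    n_points: int

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("calibration gain must be positive")

    def apply(self, recorded):
        return self.gain * np.asarray(recorded, dtype=float) + self.offset

    def invert(self, true):
        return (np.asarray(true, dtype=float) - self.offset) / self.gain


IDENTITY_CALIBRATION = ProbeCalibration(gain=1.0, offset=0.0, r2=1.0, n_points=0)


@dataclass
class BeatDetection:
    beat_times_s: np.ndarray
    fh: float | None  # beats min^-1; None when < 2 beats found
    n_beats: int


@dataclass
class CardiacSample:
    window_start_s: float
    window_end_s: float
    co: float  # ml min^-1 kg^-1
    fh: float | None
    sv: float | None
    n_beats: int


def calibrate_probe(true_flow, recorded_flow) -> ProbeCalibration:
    """Least-squares linear calibration from gravimetric bench points."""
    x = np.asarray(recorded_flow, dtype=float)
    y = np.asarray(true_flow, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 paired calibration points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all recorded flows equal")
    gain, offset = np.polyfit(x, y, 1)
    resid = y - (gain * x + offset)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ProbeCalibration(gain=float(gain), offset=float(offset), r2=r2, n_points=len(x))


def detect_beats(
    time_s,
    flow,
    expected_max_fh: float = 120.0,
    prominence_frac: float = 0.25,
    min_prominence: float = 0.5,
) -> BeatDetection:
    """Peak detection on a flow window.

    Minimum inter-peak distance is half the period of ``expected_max_fh``;
    required prominence is ``prominence_frac`` of the window amplitude with an
    absolute floor ``min_prominence`` (ml min^-1) so a flat trace yields no
    beats.  fH = (n_beats - 1) / span * 60; with fewer than 2 beats fH is
    undefined (None).
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(flow, dtype=float)
    if len(t) < 2:
        return BeatDetection(np.array([]), None, 0)
    dt = float(np.median(np.diff(t)))
    min_dist = max(1, int(round(0.5 * (60.0 / expected_max_fh) / dt)))
    prominence = max(prominence_frac * float(np.ptp(f)), min_prominence)
    peaks, _ = find_peaks(f, distance=min_dist, prominence=prominence)
    beats = t[peaks]
    if len(beats) < 2:
        return BeatDetection(beats, None, len(beats))
    span = beats[-1] - beats[0]
    fh = (len(beats) - 1) / span * 60.0 if span > 0 else None
    return BeatDetection(beats, fh, len(beats))


def cardiac_during_cycle(
    flow_trace: pd.DataFrame,
    window: tuple[float, float],
    calibration: ProbeCalibration = IDENTITY_CALIBRATION,
    body_mass_kg: float = 1.0,
    expected_max_fh: float = 120.0,
) -> CardiacSample:
    """CO / fH / SV for one respirometry measure window.

    CO is the calibrated mean flow over the window divided by body mass; when
    fH is undefined SV is null but CO is still reported.
    """
    s, e = window
    t = flow_trace["time_s"].to_numpy()
    f = flow_trace["flow_ml_min"].to_numpy(dtype=float)
    mask = (t >= s) & (t < e)
    if not mask.any():
        raise ValueError(f"flow trace does not overlap window [{s}, {e}]")
    fw = calibration.apply(f[mask])
    co = float(np.mean(fw)) / body_mass_kg
    det = detect_beats(t[mask], fw, expected_max_fh=expected_max_fh)
    sv = co / det.fh if det.fh else None
    return CardiacSample(
        window_start_s=float(s), window_end_s=float(e),
        co=co, fh=det.fh, sv=sv, n_beats=det.n_beats,
    )


def summarize_cardiac(
    samples: pd.DataFrame,
    smr_cycle_ids,
    mmr_cycle_id,
) -> dict[str, float | None]:
    """Resting / maximum / scope for CO, fH and SV.

    ``samples`` is indexed (or keyed via a ``cycle`` column) by respirometry
    cycle; resting values average the cycles that defined SMR, maximum values
    are read at the MMR cycle.  Scope may be negative.
    """
    df = samples.set_index("cycle") if "cycle" in samples.columns else samples
    missing = [c for c in smr_cycle_ids if c not in df.index]
    if mmr_cycle_id not in df.index:
        missing.append(mmr_cycle_id)
    if missing:
        raise ValueError(f"no cardiac sample co-timed with cycle(s) {missing}")
    rest = df.loc[list(smr_cycle_ids)]
    peak = df.loc[mmr_cycle_id]
    out: dict[str, float | None] = {}
    for var in ("co", "fh", "sv"):
        r = float(rest[var].mean())
        m = peak[var]
        m = None if m is None or (isinstance(m, float) and np.isnan(m)) else float(m)
        out[f"{var}_rest"] = r
        out[f"{var}_max"] = m
        out[f"{var}_scope"] = (m - r) if m is not None and np.isfinite(r) else None
    return out


def timecourse_extract(
    times_s,
    values,
    chase_time_s: float,
    grid_min=POST_CHASE_GRID_MIN,
    max_distance_min: float = 30.0,
) -> pd.DataFrame:
    """Values at the standard post-exercise time grid.

    For each target (minutes after the chase) the temporally closest
    available sample is taken and its offset recorded; targets with no sample
    within ``max_distance_min`` yield null.
    """
    t_min = (np.asarray(times_s, dtype=float) - chase_time_s) / 60.0
    v = np.asarray(values, dtype=float)
    rows = []
    for g in grid_min:
        if len(t_min) == 0:
            rows.append({"target_min": g, "value": np.nan, "offset_min": np.nan})
            continue
        i = int(np.argmin(np.abs(t_min - g)))
        off = t_min[i] - g
        if abs(off) > max_distance_min:
            rows.append({"target_min": g, "value": np.nan, "offset_min": np.nan})
        else:
            rows.append({"target_min": g, "value": v[i], "offset_min": off})
    return pd.DataFrame(rows)
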