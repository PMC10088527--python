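"""Intermittent-flow respirometry: air-saturation traces -> quality-filtered MO2.

An intermittent-flow respirometer alternates *flush* phases (oxygenated water
pumped through the chamber) with sealed *measure* phases.  During a sealed
phase the percentage air saturation declines linearly at a rate set by the
fish's oxygen uptake plus microbial background respiration.  Each measure
phase yields one MO2 sample via

    MO2 = (|alpha_a| * V_n - |alpha_b| * V_t) * beta / 100 * 3600 / M

where ``alpha_a`` is the fitted saturation slope with the fish present
(% s^-1), ``alpha_b`` the background slope from a fish-free run, ``beta`` the
O2 solubility (mg O2 l^-1 at 100% air saturation), ``V_t`` the respirometer
volume (l), ``V_n = V_t - M`` the net water volume (body mass in kg read as
litres of displaced water) and ``M`` the body mass (kg).  The result is in
mg O2 h^-1 kg^-1.

Quality control follows standard practice: the first 30-60 s of each sealed
phase are discarded (mixing transient), slopes are ordinary least squares,
and a slope is accepted only when R^2 > 0.90 (strict).  Every cycle appears
in the audit exactly once, either accepted or rejected with a reason code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeasureCycle",
    "SlopeFit",
    "MO2Sample",
    "make_schedule",
    "segment_cycles",
    "fit_slope",
    "filter_slopes",
    "oxygen_solubility",
    "compute_mo2",
    "background_correction_schedule",
    "process_trace",
]

# Rejection reason codes (audit invariant: one reason per rejected cycle).
REASON_LOW_R2 = "low_r2"
REASON_TOO_FEW_SAMPLES = "too_few_samples"
REASON_STRADDLES_CHASE = "straddles_chase"


@dataclass
class MeasureCycle:
    """Samples of one sealed measurement phase."""

    index: int
    start_s: float
    end_s: float
    phase: str  # "pre_chase" | "post_chase"
    time_s: np.ndarray
    sat: np.ndarray

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class SlopeFit:
    """OLS slope of % air saturation vs time for one measure cycle."""

    cycle: int
    alpha: float  # % s^-1 (negative when O2 is being consumed)
    r2: float  # NaN when undefined (zero variance in saturation)
    n_points: int
    excluded_head_s: float
    phase: str = "pre_chase"
    midpoint_s: float = 0.0


@dataclass
class MO2Sample:
    time_s: float
    mo2: float  # mg O2 h^-1 kg^-1
    beta: float
    vt: float
    vn: float
    body_mass: float
    flagged_negative: bool = False


def make_schedule(
    total_s: float,
    flush_s: float,
    measure_s: float,
    start_s: float = 0.0,
    phase: str = "pre_chase",
) -> pd.DataFrame:
    """Periodic flush/measure schedule as a table of sealed windows.

    Each cycle is ``flush_s`` of flushing followed by ``measure_s`` sealed;
    only complete cycles fitting inside ``[start_s, start_s + total_s)`` are
    emitted.
    """
    if flush_s <= 0 or measure_s <= 0:
        raise ValueError("flush and measure durations must be positive")
    rows = []
    t = start_s
    i = 0
    while t + flush_s + measure_s <= start_s + total_s + 1e-9:
        rows.append(
            {
                "cycle": i,
                "flush_start_s": t,
                "measure_start_s": t + flush_s,
                "measure_end_s": t + flush_s + measure_s,
                "phase": phase,
            }
        )
        t += flush_s + measure_s
        i += 1
    return pd.DataFrame(rows, columns=["cycle", "flush_start_s", "measure_start_s", "measure_end_s", "phase"])


def segment_cycles(
    trace: pd.DataFrame,
    schedule: pd.DataFrame,
    chase_time_s: float | None = None,
) -> tuple[list[MeasureCycle], list[dict]]:
    """Assign trace samples to sealed measure windows.

    Returns (cycles, excluded) where ``excluded`` logs any cycle dropped
    because its sealed window straddles the chase marker (the fish is out of
    the respirometer during the chase, so such a window cannot be a
    measurement).  Flush-phase samples are discarded by construction.
    """
    required = {"measure_start_s", "measure_end_s"}
    if not required.issubset(schedule.columns):
        raise ValueError(f"schedule must contain columns {sorted(required)}")
    t = np.asarray(trace["time_s"], dtype=float)
    v = np.asarray(trace["sat"], dtype=float)
    if len(t) == 0:
        return [], []
    span = (t[0], t[-1])
    if len(schedule) and (schedule["measure_start_s"].min() > span[1] or schedule["measure_end_s"].max() < span[0]):
        warnings.warn("schedule does not overlap trace span", stacklevel=2)
    cycles: list[MeasureCycle] = []
    excluded: list[dict] = []
    for row in schedule.itertuples(index=False):
        s, e = float(row.measure_start_s), float(row.measure_end_s)
        if chase_time_s is not None and s < chase_time_s < e:
            excluded.append({"cycle": int(row.cycle), "reason": REASON_STRADDLES_CHASE})
            continue
        mask = (t >= s) & (t < e)
        phase = getattr(row, "phase", "pre_chase")
        cycles.append(MeasureCycle(int(row.cycle), s, e, str(phase), t[mask], v[mask]))
    return cycles, excluded


def fit_slope(cycle: MeasureCycle, head_exclusion_s: float = 45.0, min_points: int = 10) -> SlopeFit:
    """OLS slope (% s^-1) and R^2 after trimming the mixing transient.

    ``head_exclusion_s`` must lie in [30, 60] per the acceptance rule that the
    first 30-60 s of each sealed phase are non-linear.  With fewer than
    ``min_points`` samples remaining a ``ValueError`` is raised; callers doing
    batch processing catch it and audit the cycle as ``too_few_samples``.
    """
    if not 30.0 <= head_exclusion_s <= 60.0:
        raise ValueError("head_exclusion_s must be within [30, 60] s")
    keep = cycle.time_s >= cycle.start_s + head_exclusion_s
    t = cycle.time_s[keep]
    y = cycle.sat[keep]
    if len(t) < min_points:
        raise ValueError(f"cycle {cycle.index}: {len(t)} samples after head exclusion (< {min_points})")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = np.nan if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return SlopeFit(
        cycle=cycle.index,
        alpha=float(slope),
        r2=float(r2),
        n_points=int(len(t)),
        excluded_head_s=head_exclusion_s,
        phase=cycle.phase,
        midpoint_s=0.5 * (t[0] + t[-1]),
    )


def filter_slopes(fits: list[SlopeFit], r2_min: float = 0.90) -> tuple[list[SlopeFit], list[tuple[SlopeFit, str]]]:
    """Strict R^2 acceptance: keep fits with R^2 > r2_min.

    Ties at exactly ``r2_min`` and undefined (NaN) R^2 are rejected.  Rejected
    fits are retained alongside their reason for the audit trail.
    """
    accepted, rejected = [], []
    for f in fits:
        if np.isfinite(f.r2) and f.r2 > r2_min:
            accepted.append(f)
        else:
            rejected.append((f, REASON_LOW_R2))
    if fits and not accepted:
        warnings.warn("all slopes rejected by R^2 filter", stacklevel=2)
    return accepted, rejected


# Benson & Krause (1984) unit-standard-atmosphere fit for dissolved O2 at
# 100% air saturation, with the salinity correction term; mg O2 l^-1.
def oxygen_solubility(temperature_c: float, salinity_ppt: float = 0.0) -> float:
    """O2 solubility beta (mg O2 l^-1 at 100% air saturation).

    Valid for -2 <= T <= 40 degC and 0 <= S <= 40 ppt; monotonically
    decreasing in both temperature and salinity.
    """
    if not -2.0 <= temperature_c <= 40.0:
        raise ValueError(f"temperature {temperature_c} degC outside [-2, 40]")
    if not 0.0 <= salinity_ppt <= 40.0:
        raise ValueError(f"salinity {salinity_ppt} ppt outside [0, 40]")
    tk = temperature_c + 273.15
    ln_do = (
        -139.34411
        + 1.575701e5 / tk
        - 6.642308e7 / tk**2
        + 1.2438e10 / tk**3
        - 8.621949e11 / tk**4
        - salinity_ppt * (0.017674 - 10.754 / tk + 2140.7 / tk**2)
    )
    return float(np.exp(ln_do))


def compute_mo2(
    fit: SlopeFit,
    background_alpha: float,
    beta: float,
    vt: float,
    body_mass: float,
) -> MO2Sample:
    """Background-corrected oxygen uptake for one accepted cycle.

    Negative results (background slope exceeding the fish slope) are flagged,
    never silently clipped.
    """
    if vt <= body_mass:
        raise ValueError("respirometer volume must exceed body mass (as litres)")
    vn = vt - body_mass
    mo2 = (abs(fit.alpha) * vn - abs(background_alpha) * vt) * beta / 100.0 * 3600.0 / body_mass
    return MO2Sample(
        time_s=fit.midpoint_s,
        mo2=float(mo2),
        beta=beta,
        vt=vt,
        vn=vn,
        body_mass=body_mass,
        flagged_negative=bool(mo2 < 0),
    )


def background_correction_schedule(
    background_runs: dict[str, float] | list[float],
    mode: str = "constant",
    trace_span_s: float | None = None,
    start_alpha: float = 0.0,
    missing: str = "error",
):
    """Background slope alpha_b(t) for a series.

    The measurement protocol determines background microbial respiration once,
    at the end of each experimental series; the default therefore applies that
    end-point value as a constant to every cycle.  ``mode='ramp'`` instead
    interpolates linearly from ``start_alpha`` at t=0 to the end-run value at
    ``trace_span_s`` (for users who assume background grows during a run).

    ``background_runs`` is either a single-respirometer list of fitted slopes
    (the last entry is the end run) or a mapping respirometer -> slope.
    Returns a callable alpha_b(t_seconds) for the single-respirometer form, or
    a dict of callables for the mapping form.  A respirometer with no run is
    handled per ``missing``: ``'error'`` raises, ``'zero'`` warns and uses 0.
    """
    def _make(end_alpha: float):
        if mode == "constant":
            return lambda t: end_alpha
        if mode == "ramp":
            if trace_span_s is None or trace_span_s <= 0:
                raise ValueError("ramp mode requires a positive trace_span_s")
            return lambda t: start_alpha + (end_alpha - start_alpha) * np.clip(t / trace_span_s, 0.0, 1.0)
        raise ValueError(f"unknown background mode {mode!r}")

    if isinstance(background_runs, dict):
        out = {}
        for resp, alpha in background_runs.items():
            if alpha is None:
                if missing == "zero":
                    warnings.warn(f"no background run for respirometer {resp}; using 0", stacklevel=2)
                    alpha = 0.0
                else:
                    raise ValueError(f"missing background run for respirometer {resp}")
            out[resp] = _make(float(alpha))
        return out
    if len(background_runs) == 0:
        raise ValueError("at least one background run is required")
    return _make(float(background_runs[-1]))


def process_trace(
    trace: pd.DataFrame,
    schedule: pd.DataFrame,
    *,
    beta: float,
    vt: float,
    body_mass: float,
    background_alpha=0.0,
    chase_time_s: float | None = None,
    r2_min: float = 0.90,
    head_exclusion_s: float = 45.0,
    min_points: int = 10,
) -> pd.DataFrame:
    """Full trace -> audited MO2 series.

    Returns one row per scheduled cycle with columns ``time_s, mo2, phase,
    accepted, reason, alpha, r2, cycle``; rejected cycles carry NaN mo2 and a
    single reason code.  ``background_alpha`` may be a constant or a callable
    alpha_b(t).
    """
    bg = background_alpha if callable(background_alpha) else (lambda t: background_alpha)
    cycles, excluded = segment_cycles(trace, schedule, chase_time_s=chase_time_s)
    rows = []
    for exc in excluded:
        rows.append(
            {"cycle": exc["cycle"], "time_s": np.nan, "mo2": np.nan, "phase": "excluded",
             "accepted": False, "reason": exc["reason"], "alpha": np.nan, "r2": np.nan}
        )
    fits, failed = [], []
    for c in cycles:
        try:
            fits.append(fit_slope(c, head_exclusion_s=head_exclusion_s, min_points=min_points))
        except ValueError:
            failed.append(c)
    for c in failed:
        rows.append(
            {"cycle": c.index, "time_s": c.midpoint_s, "mo2": np.nan, "phase": c.phase,
             "accepted": False, "reason": REASON_TOO_FEW_SAMPLES, "alpha": np.nan, "r2": np.nan}
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        accepted, rejected = filter_slopes(fits, r2_min=r2_min)
    for f, reason in rejected:
        rows.append(
            {"cycle": f.cycle, "time_s": f.midpoint_s, "mo2": np.nan, "phase": f.phase,
             "accepted": False, "reason": reason, "alpha": f.alpha, "r2": f.r2}
        )
    for f in accepted:
        sample = compute_mo2(f, float(bg(f.midpoint_s)), beta, vt, body_mass)
        rows.append(
            {"cycle": f.cycle, "time_s": f.midpoint_s, "mo2": sample.mo2, "phase": f.phase,
             "accepted": True,
             "reason": "negative_mo2_flag" if sample.flagged_negative else "",
             "alpha": f.alpha, "r2": f.r2}
        )
    out = pd.DataFrame(rows).sort_values("cycle").reset_index(drop=True)
    return out
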