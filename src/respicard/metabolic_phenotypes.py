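"""SMR, MMR, aerobic scope and EPOC from an audited MO2 series.

Definitions follow standard fish-respirometry practice:

* SMR: mean of the lowest 20% of accepted pre-chase MO2 samples, after a
  one-pass mean +/- 2 s.d. outlier screen within that lowest-20% subset.
* MMR: highest single accepted post-chase sample (earliest on ties).
* Aerobic scope: MMR - SMR.
* EPOC: trapezoidal integral of MO2 above SMR+10% from the chase until the
  first time the (activity-smoothed) series reaches SMR+10%; a fish whose
  series never reaches that threshold is flagged unrecovered and carries no
  EPOC magnitude/duration.

All MO2 values in mg O2 h^-1 kg^-1; EPOC in mg O2 kg^-1; times in hours
relative to the chase unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SmrEstimate",
    "MmrEstimate",
    "EpocResult",
    "MetabolicPhenotype",
    "estimate_smr",
    "estimate_mmr",
    "smooth_activity",
    "compute_epoc",
    "phenotype_from_series",
]


@dataclass
class SmrEstimate:
    smr: float
    n_samples: int  # samples retained after the outlier screen
    sample_ids: list  # cycle ids of retained samples (for cardiac alignment)


@dataclass
class MmrEstimate:
    mmr: float
    time_s: float
    cycle: int


@dataclass
class EpocResult:
    recovered: bool
    epoc: float | None  # mg O2 kg^-1
    duration_h: float | None
    rate: float | None  # mg O2 kg^-1 h^-1


@dataclass
class MetabolicPhenotype:
    smr: float
    mmr: float | None
    aerobic_scope: float | None
    epoc: float | None
    epoc_duration_h: float | None
    epoc_rate: float | None
    recovered: bool
    n_smr_samples: int


def estimate_smr(
    values,
    cycle_ids=None,
    min_samples: int = 10,
    screen_on_subset: bool = True,
) -> SmrEstimate:
    """Lowest-20% SMR with mean +/- 2 s.d. outlier exclusion.

    ``values`` are accepted pre-chase MO2 samples.  The lowest
    ``ceil(0.2 * n)`` are taken; within that subset (or, with
    ``screen_on_subset=False``, using the full window's mean/s.d.) values
    outside mean +/- 2 s.d. are removed in a single pass and SMR is the mean
    of the remainder.
    """
    v = np.asarray(values, dtype=float)
    if cycle_ids is None:
        cycle_ids = np.arange(len(v))
    ids = np.asarray(cycle_ids)
    if len(v) < min_samples:
        raise ValueError(f"need >= {min_samples} pre-chase samples, got {len(v)}")
    k = math.ceil(0.2 * len(v))
    order = np.argsort(v, kind="stable")[:k]
    sub = v[order]
    if screen_on_subset:
        mu, sd = sub.mean(), sub.std(ddof=1) if len(sub) > 1 else 0.0
    else:
        mu, sd = v.mean(), v.std(ddof=1)
    keep = np.abs(sub - mu) <= 2.0 * sd if sd > 0 else np.ones(len(sub), dtype=bool)
    if not keep.any():
        raise ValueError("all lowest-20% samples excluded by the outlier screen")
    return SmrEstimate(
        smr=float(sub[keep].mean()),
        n_samples=int(keep.sum()),
        sample_ids=list(ids[order][keep]),
    )


def estimate_mmr(values, times_s, cycle_ids=None) -> MmrEstimate:
    """Highest accepted post-chase sample; ties resolve to the earliest."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if len(v) == 0:
        raise ValueError("no accepted post-chase samples")
    if cycle_ids is None:
        cycle_ids = np.arange(len(v))
    order = np.argsort(t, kind="stable")
    v, t, ids = v[order], t[order], np.asarray(cycle_ids)[order]
    i = int(np.argmax(v))  # argmax returns the first (earliest) maximum
    return MmrEstimate(mmr=float(v[i]), time_s=float(t[i]), cycle=int(ids[i]))


def smooth_activity(
    values,
    times_h=None,
    threshold: float = 0.05,
    unsmoothed_head_h: float = 0.0,
    chase_time_h: float = 0.0,
):
    """Suppress transient activity-driven MO2 elevations.

    Scanning forward: when a sample rises by at least ``threshold``
    (fractional) above the running value, it is replaced by the pre-spike
    value and held there until a raw sample returns to within ``threshold``
    of that held value.  Samples within ``unsmoothed_head_h`` hours after the
    chase pass through unmodified (used for ligated fish, whose genuine
    post-chase impairment must not be edited away).  Never increases any
    sample.
    """
    v = np.asarray(values, dtype=float)
    out = v.copy()
    if len(v) < 2:
        return out
    if times_h is None:
        times_h = np.arange(len(v), dtype=float)
    t = np.asarray(times_h, dtype=float)
    head_end = chase_time_h + unsmoothed_head_h
    held = None
    for i in range(1, len(v)):
        if t[i] < head_end:
            held = None
            continue
        if held is not None:
            if v[i] <= (1.0 + threshold) * held:
                out[i] = v[i]
                held = None
            else:
                out[i] = held
        elif v[i] >= (1.0 + threshold) * out[i - 1]:
            held = out[i - 1]
            out[i] = held
    return out


def compute_epoc(
    times_h,
    values,
    smr: float,
    recovery_margin: float = 0.10,
    chase_time_h: float = 0.0,
    anchor_start: bool = True,
) -> EpocResult:
    """EPOC magnitude, duration and repayment rate.

    ``times_h``/``values`` are the (smoothed) post-chase series; times in
    hours.  The recovery threshold is ``(1 + recovery_margin) * smr``.
    Duration is the first time the series reaches the threshold, linearly
    interpolated between the straddling samples; EPOC is the trapezoidal
    integral of ``max(MO2 - threshold, 0)`` from the chase to that time
    (``anchor_start`` extends the first sample's value back to the chase
    instant).  A series that never reaches the threshold yields
    ``recovered=False`` with null magnitude/duration — a valid, flagged
    outcome, not an error.
    """
    if smr <= 0:
        raise ValueError("smr must be positive")
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    post = t >= chase_time_h
    t, v = t[post] - chase_time_h, v[post]
    if len(t) == 0:
        raise ValueError("post-chase series is empty")
    th = (1.0 + recovery_margin) * smr
    below = np.flatnonzero(v <= th)
    if len(below) == 0:
        return EpocResult(recovered=False, epoc=None, duration_h=None, rate=None)
    i = below[0]
    if i == 0:
        return EpocResult(recovered=True, epoc=0.0, duration_h=0.0, rate=None)
    # linear interpolation of the threshold crossing
    t_rec = t[i - 1] + (t[i] - t[i - 1]) * (v[i - 1] - th) / (v[i - 1] - v[i])
    tt = list(t[:i]) + [t_rec]
    vv = list(v[:i]) + [th]
    if anchor_start and tt[0] > 0.0:
        tt = [0.0] + tt
        vv = [vv[0]] + vv
    excess = np.maximum(np.asarray(vv) - th, 0.0)
    epoc = float(np.trapezoid(excess, np.asarray(tt)))
    duration = float(t_rec)
    rate = epoc / duration if duration > 0 else None
    return EpocResult(recovered=True, epoc=epoc, duration_h=duration, rate=rate)


def phenotype_from_series(
    series: pd.DataFrame,
    chase_time_s: float | None,
    ligated: bool = False,
    smooth_threshold: float = 0.05,
    unsmoothed_head_h: float = 2.0,
    recovery_margin: float = 0.10,
    min_smr_samples: int = 10,
) -> tuple[MetabolicPhenotype, SmrEstimate, MmrEstimate | None]:
    """Full metabolic phenotype from an audited MO2 series.

    ``series`` is the respirometry output (columns ``time_s, mo2, phase,
    accepted, cycle``).  The unsmoothed head after the chase is applied only
    to ligated fish, whose early post-chase depression is physiology rather
    than activity.
    """
    acc = series[series["accepted"] & np.isfinite(series["mo2"])]
    pre = acc[acc["phase"] == "pre_chase"]
    smr_est = estimate_smr(pre["mo2"].to_numpy(), pre["cycle"].to_numpy(), min_samples=min_smr_samples)

    if chase_time_s is None:
        pheno = MetabolicPhenotype(
            smr=smr_est.smr, mmr=None, aerobic_scope=None, epoc=None,
            epoc_duration_h=None, epoc_rate=None, recovered=True,
            n_smr_samples=smr_est.n_samples,
        )
        return pheno, smr_est, None

    post = acc[acc["phase"] == "post_chase"]
    mmr_est = estimate_mmr(post["mo2"].to_numpy(), post["time_s"].to_numpy(), post["cycle"].to_numpy())

    t_h = (post["time_s"].to_numpy() - chase_time_s) / 3600.0
    smoothed = smooth_activity(
        post["mo2"].to_numpy(), t_h,
        threshold=smooth_threshold,
        unsmoothed_head_h=unsmoothed_head_h if ligated else 0.0,
        chase_time_h=0.0,
    )
    epoc = compute_epoc(t_h, smoothed, smr_est.smr, recovery_margin=recovery_margin)

    pheno = MetabolicPhenotype(
        smr=smr_est.smr,
        mmr=mmr_est.mmr,
        aerobic_scope=mmr_est.mmr - smr_est.smr,
        epoc=epoc.epoc,
        epoc_duration_h=epoc.duration_h,
        epoc_rate=epoc.rate,
        recovered=epoc.recovered,
        n_smr_samples=smr_est.n_samples,
    )
    return pheno, smr_est, mmr_est
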