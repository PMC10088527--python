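"""End-to-end analysis: simulated (or loaded) study -> per-fish phenotypes,
cardiac summaries and the group-level report."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cardiac as cardiac_mod
from . import metabolic_phenotypes as pheno_mod
from . import respirometry as resp_mod
from . import stats_report
from .cardiac import IDENTITY_CALIBRATION, ProbeCalibration
from .synthetic_data import FishData, SimulatedStudy

__all__ = ["FishAnalysis", "StudyAnalysis", "analyze_fish", "analyze_study", "fit_background_runs"]


@dataclass
class FishAnalysis:
    fish_id: int
    mo2_series: pd.DataFrame
    phenotype: pheno_mod.MetabolicPhenotype
    smr_estimate: pheno_mod.SmrEstimate
    mmr_estimate: pheno_mod.MmrEstimate | None
    cardiac_samples: pd.DataFrame | None
    cardiac_summary: dict | None


@dataclass
class StudyAnalysis:
    fish: list[FishAnalysis]
    phenotypes: pd.DataFrame
    cardiac: pd.DataFrame | None
    metadata: pd.DataFrame

    def report(self, **kwargs) -> dict:
        return stats_report.build_report(self.phenotypes, self.cardiac, **kwargs)


def fit_background_runs(study: SimulatedStudy, r2_min: float = 0.0) -> dict[str, float]:
    """End-run background slope (alpha_b, % s^-1) per respirometer.

    Background declines are shallow, so no R^2 gate is applied by default;
    the fitted slope of the last background cycle is used, per the
    end-of-series correction convention.
    """
    out = {}
    for resp, trace in study.background_runs.items():
        cycles, _ = resp_mod.segment_cycles(trace, study.background_schedule)
        fits = [resp_mod.fit_slope(c) for c in cycles]
        fits = [f for f in fits if np.isfinite(f.alpha)]
        out[resp] = float(np.mean([f.alpha for f in fits])) if fits else 0.0
    return out


def analyze_fish(
    fish: FishData,
    beta: float,
    background_alpha: float = 0.0,
    calibration: ProbeCalibration = IDENTITY_CALIBRATION,
    r2_min: float = 0.90,
    head_exclusion_s: float = 45.0,
    min_smr_samples: int = 10,
) -> FishAnalysis:
    series = resp_mod.process_trace(
        fish.airsat,
        fish.schedule,
        beta=beta,
        vt=fish.meta["respirometer_volume_l"],
        body_mass=fish.body_mass_kg,
        background_alpha=background_alpha,
        chase_time_s=fish.chase_time_s,
        r2_min=r2_min,
        head_exclusion_s=head_exclusion_s,
    )
    pheno, smr_est, mmr_est = pheno_mod.phenotype_from_series(
        series,
        chase_time_s=fish.chase_time_s,
        ligated=fish.surgery_group == "ligated",
        min_smr_samples=min_smr_samples,
    )

    card_samples = None
    card_summary = None
    if fish.flow is not None and mmr_est is not None:
        rows = []
        accepted = series[series["accepted"]]
        windows = fish.schedule.set_index("cycle")
        for cyc in accepted["cycle"]:
            w = windows.loc[cyc]
            try:
                cs = cardiac_mod.cardiac_during_cycle(
                    fish.flow,
                    (float(w["measure_start_s"]), float(w["measure_end_s"])),
                    calibration=calibration,
                    body_mass_kg=fish.body_mass_kg,
                )
            except ValueError:
                continue
            rows.append({
                "cycle": int(cyc), "window_start_s": cs.window_start_s,
                "window_end_s": cs.window_end_s, "co": cs.co, "fh": cs.fh,
                "sv": cs.sv, "n_beats": cs.n_beats,
            })
        card_samples = pd.DataFrame(rows)
        try:
            card_summary = cardiac_mod.summarize_cardiac(
                card_samples, smr_est.sample_ids, mmr_est.cycle
            )
        except ValueError as err:
            warnings.warn(f"fish {fish.fish_id}: {err}", stacklevel=2)

    return FishAnalysis(
        fish_id=fish.fish_id,
        mo2_series=series,
        phenotype=pheno,
        smr_estimate=smr_est,
        mmr_estimate=mmr_est,
        cardiac_samples=card_samples,
        cardiac_summary=card_summary,
    )


def analyze_study(
    study: SimulatedStudy,
    calibration: ProbeCalibration = IDENTITY_CALIBRATION,
    r2_min: float = 0.90,
    min_smr_samples: int = 10,
) -> StudyAnalysis:
    """Run the full pipeline over every fish of a study."""
    from .respirometry import oxygen_solubility

    d = study.design
    beta = {
        "fresh": oxygen_solubility(d.temperature_c, d.salinity_fresh_ppt),
        "sea": oxygen_solubility(d.temperature_c, d.salinity_sea_ppt),
    }
    background = fit_background_runs(study)
    analyses = []
    ph_rows = []
    card_rows = []
    for fish in study.fish:
        try:
            fa = analyze_fish(
                fish,
                beta=beta[fish.salinity_group],
                background_alpha=background.get(fish.respirometer, 0.0),
                calibration=calibration,
                r2_min=r2_min,
                min_smr_samples=min_smr_samples,
            )
        except ValueError as err:
            warnings.warn(f"fish {fish.fish_id} dropped from analysis: {err}", stacklevel=2)
            continue
        analyses.append(fa)
        p = fa.phenotype
        ph_rows.append({
            "fish_id": fish.fish_id,
            "salinity_group": fish.salinity_group,
            "surgery_group": fish.surgery_group,
            "smr": p.smr, "mmr": p.mmr, "aerobic_scope": p.aerobic_scope,
            "epoc": p.epoc, "epoc_duration_h": p.epoc_duration_h,
            "epoc_rate": p.epoc_rate, "recovered": p.recovered,
            "n_smr_samples": p.n_smr_samples,
        })
        if fa.cardiac_summary is not None:
            card_rows.append({
                "fish_id": fish.fish_id,
                "salinity_group": fish.salinity_group,
                "surgery_group": fish.surgery_group,
                **fa.cardiac_summary,
            })
    phenotypes = pd.DataFrame(ph_rows)
    cardiac_df = pd.DataFrame(card_rows) if card_rows else None
    return StudyAnalysis(
        fish=analyses,
        phenotypes=phenotypes,
        cardiac=cardiac_df,
        metadata=study.metadata,
    )
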