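"""Biometric and haematological indices with exclusion rules.

Indices follow the conventional definitions: condition factor
100*mass/length^3 (g, cm), splenosomatic index and relative ventricle mass as
percent of body mass, relative compact mass as percent of dry ventricular
mass, and MCHC as [Hb] (g l^-1) divided by Hct (%) — reported in g l^-1 per
% Hct without further unit conversion.  Anaemic fish (Hct < 20, strict) are
excluded from analysis, with every removal logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FishRecord",
    "condition_factor",
    "organ_indices",
    "mchc",
    "apply_exclusions",
    "add_index_columns",
    "HCT_ANAEMIA_THRESHOLD",
]

HCT_ANAEMIA_THRESHOLD = 20.0
RULE_ANAEMIC = "hct_below_20"


@dataclass
class FishRecord:
    fish_id: int
    body_mass_g: float
    fork_length_cm: float
    spleen_mass_g: float
    ventricle_wet_mass_g: float
    ventricle_dry_mass_g: float
    compact_dry_mass_g: float
    hb_g_l: float
    hct_pct: float
    salinity_group: str = "fresh"
    surgery_group: str = "sham"

    def __post_init__(self):
        for name in ("body_mass_g", "fork_length_cm", "spleen_mass_g",
                     "ventricle_wet_mass_g", "ventricle_dry_mass_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.hct_pct < 100.0:
            raise ValueError("hct_pct must lie in (0, 100)")
        if self.compact_dry_mass_g > self.ventricle_dry_mass_g + 1e-12:
            raise ValueError("compact dry mass cannot exceed ventricular dry mass")


def condition_factor(body_mass_g: float, fork_length_cm: float) -> float:
    """Fulton condition factor, 100 * mass / length^3."""
    if body_mass_g <= 0 or fork_length_cm <= 0:
        raise ValueError("mass and length must be positive")
    return 100.0 * body_mass_g / fork_length_cm**3


def mchc(hb_g_l: float, hct_pct: float) -> float:
    """Mean corpuscular haemoglobin concentration, [Hb]/Hct (g l^-1 per % Hct)."""
    if hct_pct <= 0:
        raise ValueError("hct must be positive")
    return hb_g_l / hct_pct


def organ_indices(record: FishRecord | dict) -> dict[str, float]:
    """Splenosomatic index, relative ventricle mass, relative compact mass, MCHC.

    All mass ratios are on the x100 (percent) scale.
    """
    r = record if isinstance(record, dict) else record.__dict__
    if r["body_mass_g"] <= 0 or r["ventricle_dry_mass_g"] <= 0:
        raise ValueError("denominators must be positive")
    return {
        "condition_factor": condition_factor(r["body_mass_g"], r["fork_length_cm"]),
        "splenosomatic_index": r["spleen_mass_g"] / r["body_mass_g"] * 100.0,
        "relative_ventricle_mass": r["ventricle_wet_mass_g"] / r["body_mass_g"] * 100.0,
        "relative_compact_mass": r["compact_dry_mass_g"] / r["ventricle_dry_mass_g"] * 100.0,
        "mchc": mchc(r["hb_g_l"], r["hct_pct"]),
    }


def apply_exclusions(records: pd.DataFrame, hct_threshold: float = HCT_ANAEMIA_THRESHOLD):
    """Remove anaemic fish (Hct strictly below the threshold).

    Returns ``(kept, audit)`` where audit holds one entry per removed record
    with the rule id; Hct exactly at the threshold is retained.
    """
    if len(records) == 0:
        return records.copy(), []
    anaemic = records["hct_pct"] < hct_threshold
    audit = [
        {"fish_id": row.fish_id, "rule": RULE_ANAEMIC, "hct_pct": float(row.hct_pct)}
        for row in records[anaemic].itertuples(index=False)
    ]
    return records[~anaemic].reset_index(drop=True), audit


def add_index_columns(metadata: pd.DataFrame) -> pd.DataFrame:
    """Metadata table with the derived index columns appended."""
    out = metadata.copy()
    out["condition_factor"] = 100.0 * out["body_mass_g"] / out["fork_length_cm"] ** 3
    out["splenosomatic_index"] = out["spleen_mass_g"] / out["body_mass_g"] * 100.0
    out["relative_ventricle_mass"] = out["ventricle_wet_mass_g"] / out["body_mass_g"] * 100.0
    out["relative_compact_mass"] = out["compact_dry_mass_g"] / out["ventricle_dry_mass_g"] * 100.0
    out["mchc"] = out["hb_g_l"] / out["hct_pct"]
    return out
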