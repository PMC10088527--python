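"""Published group-level results used as inputs.

The study's raw recordings were never deposited, so the printed group means
(mean, s.e.m., n per 2x2 cell: salinity {fresh, sea} x surgery {sham,
ligated}) are the only quantitative anchor available.  They serve two roles:

* calibration of the synthetic-study generator's default cell means, and
* inputs to the percent-effect recomputations (``stats_report.percent_effect``
  and ``relative_difference_ratio``).

Units: metabolic variables mg O2 h^-1 kg^-1; cardiac output ml min^-1 kg^-1;
heart rate beats min^-1; stroke volume ml kg^-1; EPOC mg O2 kg^-1.
"""

from __future__ import annotations

CELLS = ("fresh_sham", "fresh_ligated", "sea_sham", "sea_ligated")

#: (mean, sem) per cell.  ``None`` where the value was not printed.
GROUP_MEANS: dict[str, dict[str, tuple[float, float] | None]] = {
    "mmr": {
        "fresh_sham": (274.3, 9.61),
        "fresh_ligated": (227.2, 10.2),
        "sea_sham": (259.9, 13.0),
        "sea_ligated": (175.3, 2.8),
    },
    "aerobic_scope": {
        "fresh_sham": (222.4, 10.5),
        "fresh_ligated": (184.0, 9.4),
        "sea_sham": (200.6, 13.7),
        "sea_ligated": (118.3, 5.4),
    },
    # Sham SMR cells were not printed directly; derived as MMR - AS per cell.
    "smr": {
        "fresh_sham": (274.3 - 222.4, None),
        "fresh_ligated": (43.2, 3.8),
        "sea_sham": (259.9 - 200.6, None),
        "sea_ligated": (57.0, 4.0),
    },
    "co_max": {
        "fresh_sham": (27.1, 2.5),
        "fresh_ligated": (19.6, 2.0),
        "sea_sham": (26.9, 1.4),
        "sea_ligated": (16.6, 2.4),
    },
    "co_scope": {
        "fresh_sham": (14.4, 2.0),
        "fresh_ligated": (6.9, 1.4),
        "sea_sham": (12.5, 1.2),
        "sea_ligated": (6.1, 0.9),
    },
    "fh_rest": {
        "fresh_sham": (44.0, 2.0),
        "fresh_ligated": (50.0, 2.0),
        "sea_sham": (57.0, 2.0),
        "sea_ligated": (58.0, 2.0),
    },
    "fh_scope": {
        "fresh_sham": (16.0, 2.0),
        "fresh_ligated": None,
        "sea_sham": (-4.0, 3.0),
        "sea_ligated": None,
    },
    "sv_max": {
        "fresh_sham": None,
        "fresh_ligated": None,
        "sea_sham": (0.51, 0.02),
        "sea_ligated": (0.34, 0.06),
    },
}

#: EPOC was printed per salinity only (overall effect of seawater acclimation).
EPOC_BY_SALINITY: dict[str, tuple[float, float]] = {
    "fresh": (608.0, 65.7),
    "sea": (397.3, 32.0),
}

#: Nominal per-cell sample size implied by the F_{1,32} denominators (N=36).
N_PER_CELL = 9

#: Fraction of fish that never reached SMR+10% within the 15 h window.
NON_RECOVERY_FRACTION = {"sham": 0.06, "ligated": 0.44}


def cell_mean(variable: str, cell: str) -> float:
    entry = GROUP_MEANS[variable][cell]
    if entry is None:
        raise KeyError(f"no printed mean for {variable}/{cell}")
    return entry[0]
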