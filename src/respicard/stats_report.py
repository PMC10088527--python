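"""Group-level statistics and study report.

The design is a 2x2 factorial: salinity (fresh/sea) x surgery
(sham/coronary-ligated).  Each response is analysed by two-way ANOVA (Type II
sums of squares, robust to the mildly unbalanced cells left by per-variable
exclusions); when a main effect is significant, the simple main effect of
that factor is evaluated at each level of the other with Bonferroni
correction.  Some responses are transformed before ANOVA to stabilise
variance (log for resting CO and SV scope, square root for maximum fH,
square for maximum SV); results are reported on the original scale.

Percent effects quoted in the study abstract are recomputed from the printed
group means: percent_effect gives the percent reduction of a treatment mean
relative to its reference, and relative_difference_ratio expresses how much
larger the (sham - ligated) difference is in one salinity than the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "EffectTable",
    "TRANSFORMS",
    "two_way_anova",
    "simple_main_effects",
    "percent_effect",
    "relative_difference_ratio",
    "group_summary",
    "timecourse_mixed_anova",
    "build_report",
    "save_report",
    "load_report",
]

ALPHA = 0.05

#: variance-stabilising transforms per response, applied before ANOVA
TRANSFORMS: dict[str, str] = {
    "co_rest": "log",
    "sv_scope": "log",
    "fh_max": "sqrt",
    "sv_max": "square",
}

_TRANSFORM_FUNCS = {
    "none": lambda x: x,
    "log": np.log,
    "sqrt": np.sqrt,
    "square": np.square,
}


@dataclass
class GroupSummary:
    variable: str
    cells: dict[str, dict[str, float]]  # cell -> {n, mean, sem}


@dataclass
class EffectTable:
    variable: str
    transformation: str
    effects: dict[str, dict[str, float]]  # term -> {F, df_num, df_den, p}
    simple_effects: list[dict] = field(default_factory=list)


def _validate_cells(df: pd.DataFrame, response: str, factor_a: str, factor_b: str):
    counts = df.groupby([factor_a, factor_b], observed=True)[response].count()
    levels_a = df[factor_a].unique()
    levels_b = df[factor_b].unique()
    for a in levels_a:
        for b in levels_b:
            n = counts.get((a, b), 0)
            if n == 0:
                raise ValueError(f"empty cell ({a}, {b}) for response {response!r}")


def two_way_anova(
    df: pd.DataFrame,
    response: str,
    factor_a: str = "salinity_group",
    factor_b: str = "surgery_group",
    transformation: str | None = None,
) -> EffectTable:
    """Two-way factorial ANOVA with interaction (Type II sums of squares).

    ``transformation`` defaults to the registry entry for the response
    (``TRANSFORMS``), or none.  Rows with missing response are dropped, so
    degrees of freedom reflect per-variable n.
    """
    data = df[[response, factor_a, factor_b]].dropna()
    if transformation is None:
        transformation = TRANSFORMS.get(response, "none")
    _validate_cells(data, response, factor_a, factor_b)
    data = data.assign(_y=_TRANSFORM_FUNCS[transformation](data[response].astype(float)))
    model = smf.ols(f"_y ~ C({factor_a}) * C({factor_b})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = float(table.loc["Residual", "df"])
    effects = {}
    names = {f"C({factor_a})": factor_a, f"C({factor_b})": factor_b,
             f"C({factor_a}):C({factor_b})": "interaction"}
    for row_name, term in names.items():
        effects[term] = {
            "F": float(table.loc[row_name, "F"]),
            "df_num": float(table.loc[row_name, "df"]),
            "df_den": df_den,
            "p": float(table.loc[row_name, "PR(>F)"]),
        }
    return EffectTable(variable=response, transformation=transformation, effects=effects)


def simple_main_effects(
    df: pd.DataFrame,
    response: str,
    factor: str,
    within: str,
    transformation: str | None = None,
    alpha: float = ALPHA,
) -> list[dict]:
    """Simple main effect of ``factor`` at each level of ``within``.

    One contrast per level of ``within``; the Bonferroni divisor equals the
    number of levels tested, so the adjusted significance threshold is
    ``alpha / k`` (reported, alongside Bonferroni-adjusted p-values).
    """
    data = df[[response, factor, within]].dropna()
    if transformation is None:
        transformation = TRANSFORMS.get(response, "none")
    y = _TRANSFORM_FUNCS[transformation](data[response].astype(float))
    data = data.assign(_y=y)
    levels = list(pd.unique(data[within]))
    k = len(levels)
    out = []
    for lev in levels:
        sub = data[data[within] == lev]
        groups = [g["_y"].to_numpy() for _, g in sub.groupby(factor, observed=True)]
        if len(groups) < 2 or min(len(g) for g in groups) < 2:
            out.append({"level": lev, "F": np.nan, "p": np.nan,
                        "p_adjusted": np.nan, "alpha_adjusted": alpha / k,
                        "significant": False})
            continue
        f, p = sps.f_oneway(*groups)
        out.append({
            "level": lev,
            "F": float(f),
            "p": float(p),
            "p_adjusted": float(min(1.0, p * k)),
            "alpha_adjusted": alpha / k,
            "significant": bool(p < alpha / k),
        })
    return out


def percent_effect(mean_reference: float, mean_treatment: float, round_to_int: bool = True):
    """Percent reduction of the treatment mean relative to the reference.

    100 * (reference - treatment) / reference, rounded to the nearest integer
    for parity with how such effects are quoted in reports.
    """
    if mean_reference == 0:
        raise ValueError("reference mean must be non-zero")
    pct = 100.0 * (mean_reference - mean_treatment) / mean_reference
    return int(round(pct)) if round_to_int else pct


def relative_difference_ratio(diff_numerator_pair, diff_denominator_pair, round_to_int: bool = True):
    """How much larger one group difference is than another, in percent.

    100 * ((a1 - a2) / (b1 - b2) - 1) for pairs (a1, a2) and (b1, b2); e.g.
    the ligation-induced loss of aerobic scope in sea water relative to the
    same loss in fresh water.
    """
    a1, a2 = diff_numerator_pair
    b1, b2 = diff_denominator_pair
    if b1 - b2 == 0:
        raise ValueError("denominator difference must be non-zero")
    pct = 100.0 * ((a1 - a2) / (b1 - b2) - 1.0)
    return int(round(pct)) if round_to_int else pct


def group_summary(df: pd.DataFrame, variable: str,
                  factor_a: str = "salinity_group",
                  factor_b: str = "surgery_group") -> GroupSummary:
    """Per-cell n, mean and s.e.m. (s.d./sqrt(n)) for one variable."""
    cells = {}
    for (a, b), g in df.groupby([factor_a, factor_b], observed=True):
        v = g[variable].dropna().astype(float)
        n = len(v)
        cells[f"{a}_{b}"] = {
            "n": n,
            "mean": float(v.mean()) if n else np.nan,
            "sem": float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        }
    return GroupSummary(variable=variable, cells=cells)


def timecourse_mixed_anova(
    long_df: pd.DataFrame,
    response: str = "value",
    subject: str = "fish_id",
    time: str = "target_min",
    factor_a: str = "salinity_group",
    factor_b: str = "surgery_group",
):
    """Mixed-model analysis of the post-exercise time course.

    Thin wrapper over a standard linear mixed model (random intercept per
    fish, full between x within fixed-effect structure).  Returns the fitted
    statsmodels result plus per-time-point simple main effects of surgery
    with Bonferroni correction (the asterisk logic of a recovery figure).
    """
    data = long_df.dropna(subset=[response]).copy()
    data[time] = data[time].astype(float)
    model = smf.mixedlm(
        f"{response} ~ C({factor_a}) * C({factor_b}) * C({time})",
        data=data,
        groups=data[subject],
    )
    fit = model.fit(reml=True, method="lbfgs")
    times = sorted(data[time].unique())
    k = len(times)
    per_time = []
    for tp in times:
        sub = data[data[time] == tp]
        groups = [g[response].to_numpy() for _, g in sub.groupby(factor_b, observed=True)]
        if len(groups) == 2 and min(map(len, groups)) >= 2:
            f, p = sps.f_oneway(*groups)
            per_time.append({"time": tp, "F": float(f), "p": float(p),
                             "significant": bool(p < ALPHA / k)})
        else:
            per_time.append({"time": tp, "F": np.nan, "p": np.nan, "significant": False})
    return fit, per_time


def build_report(
    phenotypes: pd.DataFrame,
    cardiac: pd.DataFrame | None = None,
    variables: list[str] | None = None,
    timecourse: pd.DataFrame | None = None,
) -> dict:
    """Assemble the machine-readable study report.

    ``phenotypes`` must hold one row per fish (``fish_id``, group factors,
    metabolic variables); ``cardiac`` likewise for CO/fH/SV summaries.  Fish
    ids present in one table but not the other raise an error listing the
    orphans.  EPOC summaries include only recovered fish; per-variable n is
    carried explicitly and the number of unrecovered (excluded) fish is
    footnoted per group.
    """
    tables = phenotypes
    if cardiac is not None:
        orphans = set(phenotypes["fish_id"]).symmetric_difference(cardiac["fish_id"])
        if orphans:
            raise ValueError(f"fish ids not shared across tables: {sorted(orphans)}")
        tables = phenotypes.merge(
            cardiac.drop(columns=["salinity_group", "surgery_group"], errors="ignore"),
            on="fish_id",
        )
    if variables is None:
        skip = {"fish_id", "salinity_group", "surgery_group", "recovered", "n_smr_samples"}
        variables = [c for c in tables.columns
                     if c not in skip and pd.api.types.is_numeric_dtype(tables[c])]

    report: dict = {"group_summaries": {}, "effects": {}, "epoc_exclusions": {}, "n_fish": int(len(phenotypes))}
    epoc_vars = {"epoc", "epoc_duration_h", "epoc_rate"}
    for var in variables:
        sub = tables
        if var in epoc_vars and "recovered" in tables.columns:
            sub = tables[tables["recovered"].astype(bool)]
        gs = group_summary(sub, var)
        report["group_summaries"][var] = gs.cells
        try:
            et = two_way_anova(sub, var)
        except ValueError:
            continue
        entry = {"transformation": et.transformation, "anova": et.effects, "simple_effects": {}}
        for term, factor, within in (
            ("salinity_group", "salinity_group", "surgery_group"),
            ("surgery_group", "surgery_group", "salinity_group"),
        ):
            if et.effects[term]["p"] < ALPHA:
                entry["simple_effects"][factor] = simple_main_effects(sub, var, factor, within)
        report["effects"][var] = entry
    if "recovered" in tables.columns:
        for (a, b), g in tables.groupby(["salinity_group", "surgery_group"], observed=True):
            n_un = int((~g["recovered"].astype(bool)).sum())
            report["epoc_exclusions"][f"{a}_{b}"] = {
                "n_group": int(len(g)),
                "n_unrecovered": n_un,
                "footnote": (f"{n_un} fish never reached SMR+10% and are excluded "
                             f"from EPOC summaries") if n_un else "",
            }
    if timecourse is not None:
        report["timecourse"] = timecourse.to_dict(orient="records")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def save_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return path


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
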