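"""Factorial statistics, percent effects and the study report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from respicard import stats_report as sr


def balanced_frame(cell_means, n=6, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for (a, b), mu in cell_means.items():
        for _ in range(n):
            rows.append({"fish_id": i, "salinity_group": a, "surgery_group": b,
                         "y": mu + rng.normal(0, sd)})
            i += 1
    return pd.DataFrame(rows)


def brute_force_balanced_anova(df):
    """Textbook sums-of-squares decomposition for a balanced 2x2 design."""
    y = df["y"].to_numpy()
    grand = y.mean()
    n = len(df) // 4
    cells = df.groupby(["salinity_group", "surgery_group"])["y"].mean()
    a_means = df.groupby("salinity_group")["y"].mean()
    b_means = df.groupby("surgery_group")["y"].mean()
    ss_a = 2 * n * sum((m - grand) ** 2 for m in a_means)
    ss_b = 2 * n * sum((m - grand) ** 2 for m in b_means)
    ss_cells = n * sum((m - grand) ** 2 for m in cells)
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g["y"] - g["y"].mean()) ** 2).sum()
        for _, g in df.groupby(["salinity_group", "surgery_group"])
    )
    df_err = len(df) - 4
    ms_err = ss_err / df_err
    return {
        "salinity_group": ss_a / ms_err,
        "surgery_group": ss_b / ms_err,
        "interaction": ss_ab / ms_err,
    }


class TestTwoWayAnova:
    def test_matches_brute_force_on_balanced_random_data(self):
        means = {("fresh", "sham"): 10.0, ("fresh", "ligated"): 12.0,
                 ("sea", "sham"): 9.0, ("sea", "ligated"): 15.0}
        df = balanced_frame(means, n=8, sd=2.0, seed=42)
        table = sr.two_way_anova(df, "y")
        oracle = brute_force_balanced_anova(df)
        for term in ("salinity_group", "surgery_group", "interaction"):
            assert table.effects[term]["F"] == pytest.approx(oracle[term], rel=1e-9)
        assert table.effects["salinity_group"]["df_den"] == len(df) - 4

    def test_null_case_small_f(self):
        means = {(a, b): 10.0 for a in ("fresh", "sea") for b in ("sham", "ligated")}
        df = balanced_frame(means, n=10, sd=1.0, seed=7)
        table = sr.two_way_anova(df, "y")
        for term in table.effects.values():
            assert term["p"] > 0.01

    def test_additive_shifts_have_zero_interaction_ss(self):
        # deterministic additive cell means, within-cell noise only
        means = {("fresh", "sham"): 10.0, ("fresh", "ligated"): 13.0,
                 ("sea", "sham"): 14.0, ("sea", "ligated"): 17.0}
        rng = np.random.default_rng(1)
        rows = []
        noise = rng.normal(0, 1.0, 6)  # identical noise replicated across cells
        i = 0
        for (a, b), mu in means.items():
            for e in noise:
                rows.append({"salinity_group": a, "surgery_group": b, "y": mu + e})
                i += 1
        df = pd.DataFrame(rows)
        table = sr.two_way_anova(df, "y")
        assert table.effects["interaction"]["F"] == pytest.approx(0.0, abs=1e-18)

    def test_empty_cell_error_names_cell(self):
        df = balanced_frame({("fresh", "sham"): 10.0, ("fresh", "ligated"): 11.0,
                             ("sea", "sham"): 10.0, ("sea", "ligated"): 11.0}, n=3)
        df = df[~((df.salinity_group == "sea") & (df.surgery_group == "ligated"))]
        with pytest.raises(ValueError, match="sea.*ligated"):
            sr.two_way_anova(df, "y")

    def test_transformation_registry_applied(self):
        means = {(a, b): 50.0 for a in ("fresh", "sea") for b in ("sham", "ligated")}
        df = balanced_frame(means, n=4, sd=2.0, seed=3).rename(columns={"y": "fh_max"})
        table = sr.two_way_anova(df, "fh_max")
        assert table.transformation == "sqrt"


class TestSimpleMainEffects:
    def test_bonferroni_alpha_two_levels(self):
        df = balanced_frame({("fresh", "sham"): 10.0, ("fresh", "ligated"): 10.0,
                             ("sea", "sham"): 10.0, ("sea", "ligated"): 10.0}, n=5)
        out = sr.simple_main_effects(df, "y", "surgery_group", "salinity_group")
        assert len(out) == 2
        for c in out:
            assert c["alpha_adjusted"] == pytest.approx(0.025)
            assert not c["significant"]

    def test_effect_only_in_sea_water_detected_with_power(self):
        # designed effect (2 s.d.) present only in sea water; over replicates
        # the sea-level contrast must be detected with power >= 0.8 while the
        # fresh-level contrast stays at its nominal error rate
        hits_sea, hits_fresh = 0, 0
        reps = 200
        for rep in range(reps):
            means = {("fresh", "sham"): 10.0, ("fresh", "ligated"): 10.0,
                     ("sea", "sham"): 10.0, ("sea", "ligated"): 12.0}
            df = balanced_frame(means, n=9, sd=1.0, seed=1000 + rep)
            out = {c["level"]: c for c in sr.simple_main_effects(
                df, "y", "surgery_group", "salinity_group")}
            hits_sea += out["sea"]["significant"]
            hits_fresh += out["fresh"]["significant"]
        assert hits_sea / reps >= 0.8
        assert hits_fresh / reps < 0.15


class TestPercentEffects:
    def test_printed_worked_examples(self):
        assert sr.percent_effect(259.9, 175.3) == 33
        assert sr.percent_effect(200.6, 118.3) == 41

    def test_equal_means_zero(self):
        assert sr.percent_effect(100.0, 100.0) == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1.0, 1e4), st.floats(0.0, 1.0))
    def test_exact_identity(self, x, p):
        assert sr.percent_effect(x, x * (1 - p), round_to_int=False) == pytest.approx(100 * p, abs=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            sr.percent_effect(0.0, 1.0)


class TestRelativeDifferenceRatio:
    def test_aerobic_scope_ratio(self):
        assert sr.relative_difference_ratio((200.6, 118.3), (222.4, 184.0)) == 114

    def test_identical_pairs_zero(self):
        assert sr.relative_difference_ratio((5.0, 3.0), (7.0, 5.0)) == 0

    def test_hand_arithmetic(self):
        got = sr.relative_difference_ratio((10.0, 4.0), (8.0, 5.0), round_to_int=False)
        assert got == pytest.approx(100.0 * (6.0 / 3.0 - 1.0))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            sr.relative_difference_ratio((1.0, 0.0), (2.0, 2.0))


class TestGroupSummaryAndReport:
    def _phenotypes(self, n=5, seed=0, unrecovered_ligated=0):
        rng = np.random.default_rng(seed)
        rows = []
        i = 0
        for a in ("fresh", "sea"):
            for b in ("sham", "ligated"):
                k_unrec = unrecovered_ligated if b == "ligated" else 0
                for j in range(n):
                    rec = j >= k_unrec
                    rows.append({
                        "fish_id": i, "salinity_group": a, "surgery_group": b,
                        "smr": 50 + rng.normal(0, 3),
                        "mmr": 250 + rng.normal(0, 10),
                        "aerobic_scope": 200 + rng.normal(0, 10),
                        "epoc": (500 + rng.normal(0, 30)) if rec else np.nan,
                        "epoc_duration_h": 8.0 if rec else np.nan,
                        "epoc_rate": 60.0 if rec else np.nan,
                        "recovered": rec,
                        "n_smr_samples": 6,
                    })
                    i += 1
        return pd.DataFrame(rows)

    def test_sem_definition(self):
        df = self._phenotypes()
        gs = sr.group_summary(df, "smr")
        cell = df[(df.salinity_group == "fresh") & (df.surgery_group == "sham")]["smr"]
        assert gs.cells["fresh_sham"]["sem"] == pytest.approx(
            cell.std(ddof=1) / np.sqrt(len(cell)))
        assert gs.cells["fresh_sham"]["n"] == len(cell)

    def test_null_study_report_has_no_significant_contrasts(self):
        report = sr.build_report(self._phenotypes(n=6, seed=5))
        for entry in report["effects"].values():
            for contrasts in entry["simple_effects"].values():
                pass  # simple effects only appear for significant omnibus terms
        # with null effects very few variables should even trigger simple effects
        n_triggered = sum(bool(e["simple_effects"]) for e in report["effects"].values())
        assert n_triggered <= 2

    def test_unrecovered_fish_excluded_from_epoc_with_footnote(self):
        report = sr.build_report(self._phenotypes(n=5, unrecovered_ligated=2))
        assert report["group_summaries"]["epoc"]["fresh_ligated"]["n"] == 3
        assert report["group_summaries"]["smr"]["fresh_ligated"]["n"] == 5
        foot = report["epoc_exclusions"]["fresh_ligated"]
        assert foot["n_unrecovered"] == 2 and "SMR+10%" in foot["footnote"]

    def test_orphan_ids_error(self):
        ph = self._phenotypes()
        card = ph[["fish_id", "salinity_group", "surgery_group"]].copy()
        card["co_rest"] = 12.0
        card = card[card.fish_id != 3]
        with pytest.raises(ValueError, match="3"):
            sr.build_report(ph, card)

    def test_report_json_round_trip(self, tmp_path):
        report = sr.build_report(self._phenotypes(n=5, unrecovered_ligated=1))
        path = sr.save_report(report, tmp_path / "report.json")
        loaded = sr.load_report(path)
        assert loaded["group_summaries"]["smr"].keys() == report["group_summaries"]["smr"].keys()
        got = loaded["group_summaries"]["mmr"]["sea_sham"]["mean"]
        assert got == pytest.approx(report["group_summaries"]["mmr"]["sea_sham"]["mean"])
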