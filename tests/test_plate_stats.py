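"""Survival rates, protection scores, QC, Z-scores, hits, pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from neuroscreen import plate_stats as ps
from neuroscreen.plate_stats import (
    AssayWindowError,
    PlateLayout,
    ProtectionResult,
    WellCounts,
    call_hits,
    pool_counts,
    pooling_sd_analysis,
    protection_score,
    qc_filter,
    score_screen,
    survival_rate,
    zscore_map,
)
from neuroscreen.synthetic_data import simulate_well_counts


class TestPlateLayout:
    def test_inner_wells_exclude_outer_ring(self):
        wells = PlateLayout.inner_wells()
        assert len(wells) == 60
        assert "A1" not in wells and "H12" not in wells and "B2" in wells

    def test_duplicate_wells_rejected(self):
        df = pd.DataFrame(
            {"well": ["B2", "B2"], "condition": ["untreated"] * 2,
             "compound": ["untreated"] * 2, "replicate": ["1", "1"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            PlateLayout(df)

    def test_build_parses_compound_names(self):
        layout = PlateLayout.build({"B2": "compound+NMDA:drugX"})
        assert layout.table["compound"].iloc[0] == "drugX"

    def test_csv_round_trip(self, tmp_path):
        layout = PlateLayout.build(
            {w: ps.UNTREATED for w in PlateLayout.inner_wells()[:4]}
        )
        layout.to_csv(tmp_path / "layout.csv")
        back = PlateLayout.from_csv(tmp_path / "layout.csv")
        pd.testing.assert_frame_equal(layout.table, back.table)


class TestSurvivalRate:
    def test_all_live(self):
        assert survival_rate(WellCounts("B2", 3000, 0)) == 1.0

    def test_none_live(self):
        assert survival_rate(0, 100) == 0.0

    def test_untreated_mean_viability_arithmetic(self):
        # 2271 live of 3000 cells: the 75.7% anchor
        assert survival_rate(2271, 3000) == pytest.approx(0.757)

    def test_zero_total_is_an_error_not_a_qc_fail(self):
        with pytest.raises(ZeroDivisionError):
            survival_rate(0, 0)


class TestPoolCounts:
    WELLS = [WellCounts("a", 10, 0), WellCounts("b", 0, 10),
             WellCounts("c", 5, 5), WellCounts("d", 8, 2),
             WellCounts("e", 1, 9)]

    def test_k1_is_identity(self):
        pooled = pool_counts(self.WELLS, 1)
        assert list(pooled["n_live"]) == [10, 0, 5, 8, 1]

    def test_pooled_survival_is_count_weighted_mean(self):
        pooled = pool_counts(self.WELLS[:2], 2)
        assert len(pooled) == 1
        assert pooled["n_live"][0] / pooled["n_total"][0] == 0.5

    def test_leftovers_dropped_and_totals_conserved(self):
        pooled = pool_counts(self.WELLS, 2)
        assert len(pooled) == 2  # fifth well dropped
        assert pooled["n_total"].sum() == 40

    def test_k_larger_than_wells_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            pool_counts(self.WELLS, 6)


class TestProtectionScore:
    def test_full_rescue_is_100(self):
        assert protection_score(0.757, 0.2, 0.757) == pytest.approx(100.0)

    def test_no_effect_is_0(self):
        assert protection_score(0.2, 0.2, 0.757) == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        assert protection_score(0.60, 0.40, 0.757) == pytest.approx(
            56.02240896358543
        )

    def test_collapsed_window_raises(self):
        with pytest.raises(AssayWindowError, match="window"):
            protection_score(0.5, 0.4, 0.4)

    def test_scores_outside_0_100_not_clipped(self):
        assert protection_score(0.1, 0.2, 0.757) < 0.0
        assert protection_score(0.9, 0.2, 0.757) > 100.0

    @given(
        s_c=st.floats(0, 1),
        s_v=st.floats(0, 0.49),
        s_u=st.floats(0.51, 1),
    )
    def test_affine_in_compound_survival(self, s_c, s_v, s_u):
        slope = 100.0 / (s_u - s_v)
        base = protection_score(s_c, s_v, s_u)
        eps = 0.01
        shifted = protection_score(s_c + eps, s_v, s_u)
        assert shifted - base == pytest.approx(slope * eps, rel=1e-6, abs=1e-6)


class TestQCFilter:
    def test_strictly_below_threshold_fails(self):
        out = qc_filter({"a": 90, "b": 1000, "c": 1010}, screen_average=1000)
        a = out.set_index("compound")
        assert not a.loc["a", "qc_pass"]
        assert "low cell count" in a.loc["a", "qc_reason"]

    def test_exactly_at_threshold_passes(self):
        out = qc_filter({"a": 100, "b": 1000}, screen_average=1000)
        assert out.set_index("compound").loc["a", "qc_pass"]  # strict <

    def test_manual_exclusion_reported_with_reason(self):
        out = qc_filter(
            {"Mitoxantrone": 5000, "other": 5000},
            manual_exclusions={"Mitoxantrone": "interference"},
        )
        row = out.set_index("compound").loc["Mitoxantrone"]
        assert not row["qc_pass"] and row["qc_reason"] == "interference"


class TestZScoreMap:
    def _frame(self):
        rng = np.random.default_rng(0)
        wells = PlateLayout.inner_wells()[:20]
        cond = ["untreated"] * 10 + ["vehicle+NMDA"] * 10
        vals = np.r_[rng.normal(0.75, 0.1, 10), rng.normal(0.2, 0.05, 10)]
        return pd.DataFrame({"well": wells, "condition": cond, "value": vals})

    def test_group_mean_zero_sd_one(self):
        z = zscore_map(self._frame())
        for _, grp in z.groupby("condition"):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["z"].std(ddof=1) == pytest.approx(1.0)

    def test_value_at_group_mean_maps_to_zero(self):
        df = pd.DataFrame(
            {"well": ["B2", "B3", "B4"], "condition": ["u"] * 3,
             "value": [1.0, 2.0, 3.0]}
        )
        assert zscore_map(df)["z"][1] == pytest.approx(0.0)

    def test_groups_do_not_contaminate_each_other(self):
        # two groups with very different means: within-group Z stays small
        z = zscore_map(self._frame())
        assert z["z"].abs().max() < 4.0
        # pooling the groups would give |Z| ~ 2+ for every well
        pooled_z = (z["value"] - z["value"].mean()) / z["value"].std(ddof=1)
        assert pooled_z.abs().min() > 0.5

    def test_zero_sd_raises(self):
        df = pd.DataFrame(
            {"well": ["B2", "B3"], "condition": ["u"] * 2, "value": [1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="zero within-group SD"):
            zscore_map(df)

    def test_singleton_group_raises(self):
        df = pd.DataFrame({"well": ["B2"], "condition": ["u"], "value": [1.0]})
        with pytest.raises(ValueError, match="< 2 wells"):
            zscore_map(df)


class TestCallHits:
    def _result(self, score):
        return ProtectionResult(
            compound="x", s_compound=0.5, s_vehicle=0.2, s_untreated=0.757,
            score=score, pooled_n_total=9000, qc_pass=score is not None,
        )

    def test_strict_threshold(self):
        assert call_hits([self._result(50.0)]) == []
        hits = call_hits([self._result(50.1)])
        assert len(hits) == 1

    def test_moderately_protective_is_not_a_hit(self):
        # the strongest natural-product score class (32.2%) stays below 50%
        assert call_hits([self._result(32.2)]) == []

    def test_qc_failed_compound_never_hits(self):
        r = self._result(None)
        r.qc_pass = False
        assert call_hits([r]) == []


class TestPoolingSD:
    def test_identical_wells_sd_zero(self):
        wells = [WellCounts(f"w{i}", 80, 20) for i in range(30)]
        out = pooling_sd_analysis(wells)
        assert np.allclose(out["sd"], 0.0, atol=1e-12)

    def test_sd_decreases_with_pooling_under_overdispersion(self):
        sds = np.zeros(4)
        for seed in range(10):
            counts = simulate_well_counts(
                {f"w{i}": 0.243 for i in range(30)},
                n_cells_per_well=1000, well_sd=0.12, seed=seed,
            )
            sds += pooling_sd_analysis(counts)["sd"].to_numpy()
        sds /= 10
        assert np.all(np.diff(sds) < 0)


class TestScoreScreen:
    def _screen(self):
        wells, conds = [], {}
        i = 0
        for name, p in [("untreated", None), ("vehicle+NMDA", None)]:
            for _ in range(3):
                conds[f"W{i:02d}"] = name
                i += 1
        for drug in ("drugA", "drugB"):
            for _ in range(3):
                conds[f"W{i:02d}"] = f"compound+NMDA:{drug}"
                i += 1
        layout = PlateLayout.build(conds)
        p_death = {"untreated": 0.243, "vehicle+NMDA": 0.8,
                   "compound+NMDA:drugA": 0.41, "compound+NMDA:drugB": 0.79}
        counts = simulate_well_counts(
            {w: p_death[conds[w]] for w in conds}, n_cells_per_well=1000, seed=5
        )
        return counts, layout

    def test_scores_and_hits(self):
        counts, layout = self._screen()
        results = score_screen(counts, layout)
        byname = {r.compound: r for r in results}
        assert byname["drugA"].hit and byname["drugA"].score > 50
        assert not byname["drugB"].hit and abs(byname["drugB"].score) < 15

    def test_missing_anchor_condition_raises(self):
        counts, layout = self._screen()
        no_vehicle = PlateLayout(
            layout.table[layout.table["condition"] != "vehicle+NMDA"]
        )
        with pytest.raises(ValueError, match="vehicle"):
            score_screen(
                counts[counts["well"].isin(no_vehicle.wells)], no_vehicle
            )

    def test_wells_without_counts_raise(self):
        counts, layout = self._screen()
        with pytest.raises(ValueError, match="without counts"):
            score_screen(counts.iloc[:-2], layout)
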