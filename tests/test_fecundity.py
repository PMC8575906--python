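"""Fecundity measures, de novo influx, batch numbers and sensitivity."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ovodyn import fecundity as fe


def females_frame(rows):
    """rows: (female_id, year, TL, W, OW, prespawning)"""
    return pd.DataFrame(
        [
            {
                "female_id": fid,
                "capture_date": dt.date(year, 5, 15),
                "total_length_cm": tl,
                "body_weight_g": w,
                "ovary_weight_g": ow,
                "maturity_stage": 6,
                "prespawning_flag": flag,
            }
            for fid, year, tl, w, ow, flag in rows
        ]
    )


def opd_frame(entries):
    """entries: (female_id, phase, opd_per_g)"""
    return pd.DataFrame(
        [
            {"female_id": fid, "phase": ph, "V_V": 0.01, "k_mean": 1.0,
             "cOD_v_um": 200.0, "opd_log10": np.log10(v) if v > 0 else -np.inf,
             "opd_per_g": v, "rho_o": 1.047}
            for fid, ph, v in entries
        ]
    )


def orc_frame(pairs):
    return pd.DataFrame(
        [{"female_id": fid, "n_pvo": 1, "n_dev": 1, "OR": 1.0, "ORC": orc} for fid, orc in pairs]
    )


class TestFecundityTable:
    def test_counts_and_relative_measures(self):
        females = females_frame([("F1", 2019, 35.0, 500.0, 50.0, False)])
        fec = fe.fecundity_table(opd_frame([("F1", "PVO4c", 1000.0)]), females)
        row = fec.iloc[0]
        assert row["NO"] == pytest.approx(50_000.0)
        assert row["RF"] == pytest.approx(100.0)
        assert row["RF_TL"] == pytest.approx(100 * 50_000 / 35**3.13)

    def test_zero_density_zero_everything(self):
        females = females_frame([("F1", 2019, 35.0, 500.0, 50.0, False)])
        fec = fe.fecundity_table(opd_frame([("F1", "CA", 0.0)]), females)
        assert (fec[["NO", "RF", "RF_TL"]].iloc[0] == 0).all()

    def test_conservation_across_phases(self):
        # sum of phase counts equals ovary weight times summed densities
        females = females_frame([("F1", 2019, 35.0, 500.0, 42.0, False)])
        entries = [("F1", p, v) for p, v in [("PVO2", 3e4), ("PVO4c", 2e3), ("VO1", 500.0)]]
        fec = fe.fecundity_table(opd_frame(entries), females)
        assert fec["NO"].sum() == pytest.approx(42.0 * (3e4 + 2e3 + 500.0))

    def test_missing_female_join_is_error(self):
        females = females_frame([("F1", 2019, 35.0, 500.0, 50.0, False)])
        with pytest.raises(KeyError):
            fe.fecundity_table(opd_frame([("F2", "CA", 10.0)]), females)


class TestRfByOrc:
    def test_cell_means_and_intervals(self):
        females = females_frame(
            [("F1", 2019, 35, 500, 50, True), ("F2", 2019, 35, 500, 50, True), ("F3", 2019, 35, 500, 50, False)]
        )
        opd = opd_frame([("F1", "PVO4c", 1000.0), ("F2", "PVO4c", 2000.0), ("F3", "PVO4c", 500.0)])
        orc = orc_frame([("F1", 0), ("F2", 0), ("F3", 4)])
        grid = fe.rf_by_orc(fe.fecundity_table(opd, females), orc, females)
        cell0 = grid[(grid.ORC == 0) & (grid.phase == "PVO4c")].iloc[0]
        assert cell0["mean_RF"] == pytest.approx(150.0)
        assert cell0["ci_defined"]
        cell4 = grid[(grid.ORC == 4) & (grid.phase == "PVO4c")].iloc[0]
        assert cell4["n"] == 1 and not cell4["ci_defined"]

    def test_constant_cell_has_zero_width(self):
        females = females_frame([("F1", 2019, 35, 500, 50, True), ("F2", 2019, 35, 500, 50, True)])
        opd = opd_frame([("F1", "CA", 800.0), ("F2", "CA", 800.0)])
        grid = fe.rf_by_orc(fe.fecundity_table(opd, females), orc_frame([("F1", 0), ("F2", 0)]), females)
        cell = grid.iloc[0]
        assert cell["ci_low"] == cell["ci_high"] == cell["mean_RF"]

    def test_empty_join_rejected(self):
        females = females_frame([("F1", 2019, 35, 500, 50, False)])
        fec = fe.fecundity_table(opd_frame([("F1", "CA", 10.0)]), females)
        with pytest.raises(ValueError, match="empty join"):
            fe.rf_by_orc(fec, orc_frame([("F9", 1)]), females)


class TestInflux:
    def summary(self, mean0, mean4):
        return pd.DataFrame(
            [
                {"phase": "PVO4c", "ORC": 0, "year": 2019, "mean_RF": mean0, "se": 5.0,
                 "ci_low": mean0 - 10, "ci_high": mean0 + 10, "n": 20, "ci_defined": True},
                {"phase": "PVO4c", "ORC": 4, "year": 2019, "mean_RF": mean4, "se": 2.0,
                 "ci_low": mean4 - 4, "ci_high": mean4 + 4, "n": 20, "ci_defined": True},
            ]
        )

    def test_subtraction(self):
        influx, se = fe.denovo_influx(self.summary(200.0, 40.0))
        assert influx == pytest.approx(160.0)
        assert se == pytest.approx(np.hypot(5.0, 2.0))

    def test_equal_means_zero(self):
        assert fe.denovo_influx(self.summary(80.0, 80.0))[0] == 0.0

    def test_negative_influx_warned_not_clamped(self):
        with pytest.warns(RuntimeWarning, match="negative"):
            influx, _ = fe.denovo_influx(self.summary(40.0, 200.0))
        assert influx == pytest.approx(-160.0)

    def test_missing_cell_is_error(self):
        with pytest.raises(ValueError, match="cannot quantify influx"):
            fe.denovo_influx(self.summary(200.0, 40.0).iloc[[0]])


class TestBatches:
    def test_worked_example(self):
        total, ests = fe.total_potential_and_batches(528.0, 160.0, [40.0])
        assert total == 688.0
        assert ests[0].n_batches == 17
        assert ests[0].ratio == pytest.approx(17.2)

    def test_alternative_batch_fecundities(self):
        _, ests = fe.total_potential_and_batches(528.0, 160.0, [30.0, 34.0])
        assert [e.n_batches for e in ests] == [23, 20]

    def test_single_batch_identity(self):
        total, ests = fe.total_potential_and_batches(40.0, 0.0, [40.0])
        assert total == 40.0 and ests[0].n_batches == 1

    def test_unit_consistency(self):
        # per-kg bookkeeping gives the same batch count as per-g
        _, per_g = fe.total_potential_and_batches(528.0, 160.0, [40.0])
        _, per_kg = fe.total_potential_and_batches(528_000.0, 160_000.0, [40_000.0])
        assert per_g[0].n_batches == per_kg[0].n_batches
        assert per_g[0].ratio == pytest.approx(per_kg[0].ratio)

    def test_bad_batch_fecundity(self):
        with pytest.raises(ValueError):
            fe.total_potential_and_batches(528.0, 160.0, [0.0])


class TestThresholdSensitivity:
    def build(self, phase_rf, orc=2):
        females = females_frame([("F1", 2019, 35.0, 500.0, 50.0, False)])
        opd = opd_frame([("F1", p, rf * 500.0 / 50.0) for p, rf in phase_rf.items()])
        fec = fe.fecundity_table(opd, females)
        return fec, orc_frame([("F1", orc)]), females

    def test_worked_reduction(self):
        fec, orc, females = self.build({"PVO4a": 10, "PVO4b": 10, "PVO4c": 30, "CA": 50})
        out = fe.threshold_sensitivity(fec, orc, females)
        assert out["mean_pct_reduction"].iloc[0] == pytest.approx(20.0)

    def test_no_small_pvo_means_no_reduction(self):
        fec, orc, females = self.build({"PVO4a": 0, "PVO4b": 0, "PVO4c": 30, "CA": 50})
        out = fe.threshold_sensitivity(fec, orc, females)
        assert out["mean_pct_reduction"].iloc[0] == pytest.approx(0.0)

    def test_revised_only_female_drops_out(self):
        fec, orc, females = self.build({"PVO4a": 10, "PVO4b": 0, "PVO4c": 0, "CA": 0})
        with pytest.raises(ValueError, match="no paired females"):
            fe.threshold_sensitivity(fec, orc, females)

    def test_outside_orc_range_excluded(self):
        fec, orc, females = self.build({"PVO4a": 10, "PVO4c": 30}, orc=4)
        with pytest.raises(ValueError, match="ORC range"):
            fe.threshold_sensitivity(fec, orc, females)


class TestStandardIndividual:
    def test_single_female_equals_own_sum(self):
        females = females_frame([("F1", 2019, 35.0, 500.0, 50.0, False)])
        opd = opd_frame([("F1", "PVO4c", 1000.0), ("F1", "CA", 500.0)])
        fec = fe.fecundity_table(opd, females)
        out = fe.standard_individual(fec, orc_frame([("F1", 1)]), females)
        assert out["total_RF"].iloc[0] == pytest.approx(fec["RF"].sum())

    def test_duplicate_females_idempotent(self):
        females = females_frame(
            [("F1", 2019, 35.0, 500.0, 50.0, False), ("F2", 2019, 35.0, 500.0, 50.0, False)]
        )
        opd = opd_frame(
            [("F1", "PVO4c", 1000.0), ("F1", "CA", 500.0), ("F2", "PVO4c", 1000.0), ("F2", "CA", 500.0)]
        )
        fec = fe.fecundity_table(opd, females)
        both = fe.standard_individual(fec, orc_frame([("F1", 1), ("F2", 1)]), females)
        one = fe.standard_individual(
            fec[fec.female_id == "F1"], orc_frame([("F1", 1)]), females
        )
        assert both["total_RF"].iloc[0] == pytest.approx(one["total_RF"].iloc[0])

    def test_contributions_sum_to_total(self):
        females = females_frame(
            [("F1", 2019, 35.0, 500.0, 50.0, False), ("F2", 2019, 33.0, 420.0, 40.0, False)]
        )
        opd = opd_frame(
            [("F1", "PVO4c", 900.0), ("F1", "VO1", 300.0), ("F2", "PVO4c", 700.0), ("F2", "VO1", 100.0)]
        )
        fec = fe.fecundity_table(opd, females)
        out = fe.standard_individual(fec, orc_frame([("F1", 2), ("F2", 2)]), females)
        grouped = out.groupby(["year", "ORC"])
        for _, grp in grouped:
            assert grp["mean_RF_contribution"].sum() == pytest.approx(grp["total_RF"].iloc[0])


class TestStructurePrevalence:
    def frame(self, vvs):
        rows = []
        for fid, vv in vvs.items():
            rows.append({"female_id": fid, "phase": "ATR_PVO", "V_V": vv, "k_mean": np.nan,
                         "cOD_v_um": np.nan, "opd_log10": np.nan, "opd_per_g": np.nan, "rho_o": 1.047})
        return pd.DataFrame(rows)

    def test_absent_structure_zero_prevalence(self):
        females = females_frame([("F1", 2019, 35, 500, 50, False), ("F2", 2019, 35, 500, 50, False)])
        out = fe.structure_prevalence(
            self.frame({"F1": 0.0, "F2": 0.0}), orc_frame([("F1", 1), ("F2", 1)]), females
        )
        row = out[out.structure == "ATR_PVO"].iloc[0]
        assert row["prevalence_pct"] == 0.0 and row["mean_V_V"] == 0.0

    def test_uniform_8pct_case(self):
        females = females_frame([("F1", 2019, 35, 500, 50, False), ("F2", 2019, 35, 500, 50, False)])
        out = fe.structure_prevalence(
            self.frame({"F1": 0.08, "F2": 0.08}), orc_frame([("F1", 3), ("F2", 3)]), females
        )
        row = out.iloc[0]
        assert row["prevalence_pct"] == 100.0
        assert row["mean_V_V"] == pytest.approx(0.08)

    def test_prevalence_invariant_to_duplication(self):
        females = females_frame(
            [("F1", 2019, 35, 500, 50, False), ("F2", 2019, 35, 500, 50, False),
             ("F3", 2019, 35, 500, 50, False), ("F4", 2019, 35, 500, 50, False)]
        )
        single = fe.structure_prevalence(
            self.frame({"F1": 0.08, "F2": 0.0}), orc_frame([("F1", 2), ("F2", 2)]), females
        )
        doubled = fe.structure_prevalence(
            self.frame({"F1": 0.08, "F2": 0.0, "F3": 0.08, "F4": 0.0}),
            orc_frame([("F1", 2), ("F2", 2), ("F3", 2), ("F4", 2)]),
            females,
        )
        assert single["prevalence_pct"].iloc[0] == doubled["prevalence_pct"].iloc[0] == 50.0
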