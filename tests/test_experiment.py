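import numpy as np
import pandas as pd
import pytest

from syconpump import experiment as ex


def flux_table(rows):
    return pd.DataFrame(
        rows, columns=["sponge", "replicate", "distance_mm", "time_s", "osculum_area_mm2"]
    )


class TestExcurrentFlow:
    def test_single_replicate(self):
        t = flux_table([("S1", 1, 10.0, 2.0, 1.0)])
        f = ex.excurrent_flow(t)
        assert f.jet_speed_mm_s == pytest.approx(5.0)
        assert f.flow_mm3_s == pytest.approx(5.0)
        assert f.flow_um3_s == pytest.approx(5e9)

    def test_equal_speed_replicates(self):
        t = flux_table([("S1", 1, 10.0, 2.0, 1.0), ("S1", 2, 20.0, 4.0, 1.0)])
        assert ex.excurrent_flow(t).flow_mm3_s == pytest.approx(5.0)

    def test_zero_area(self):
        t = flux_table([("S1", 1, 10.0, 2.0, 0.0)])
        assert ex.excurrent_flow(t).flow_mm3_s == 0.0

    def test_nonpositive_time_rejected(self):
        t = flux_table([("S1", 1, 10.0, -2.0, 1.0)])
        with pytest.raises(ex.MeasurementError):
            ex.excurrent_flow(t)


class TestPerUnitRates:
    def test_per_choanocyte_rate(self):
        r = ex.per_unit_rates(1151.0 * 1000, 1000)
        assert r.Q_ost == pytest.approx(1151.0)
        assert round(r.Q_ch) == 48
        assert r.in_leucon_range

    def test_out_of_range_flag(self):
        r = ex.per_unit_rates(10.0 * 24, 24)
        assert not r.in_leucon_range

    def test_zero_counts_rejected(self):
        with pytest.raises(ex.MeasurementError):
            ex.per_unit_rates(1000.0, 0)


class TestBeadCalibration:
    def test_basic_arithmetic(self):
        conc = ex.bead_calibrated_concentration({"LNA": 2000}, 500, 100.0)
        assert conc["LNA"] == pytest.approx(400.0)

    def test_ratio_invariance(self):
        a = ex.bead_calibrated_concentration({"LNA": 2000}, 500, 100.0)
        b = ex.bead_calibrated_concentration({"LNA": 4000}, 1000, 100.0)
        assert a["LNA"] == pytest.approx(b["LNA"])

    def test_zero_events(self):
        assert ex.bead_calibrated_concentration({"Euk": 0}, 500, 100.0)["Euk"] == 0.0

    def test_zero_beads_rejected(self):
        with pytest.raises(ex.MeasurementError):
            ex.bead_calibrated_concentration({"Euk": 10}, 0, 100.0)


class TestRetentionEfficiency:
    @pytest.mark.parametrize(
        "cin,cex,expected", [(100, 40, 60.0), (100, 0, 100.0), (50, 50, 0.0),
                             (100, 150, -50.0)]
    )
    def test_formula(self, cin, cex, expected):
        assert ex.retention_efficiency(cin, cex) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert ex.retention_efficiency(3.0, 1.2) == pytest.approx(
            ex.retention_efficiency(3000.0, 1200.0)
        )

    def test_nonpositive_inhaled_rejected(self):
        with pytest.raises(ex.MeasurementError):
            ex.retention_efficiency(0.0, 10.0)


class TestBoxStats:
    def test_order_statistics(self):
        s = ex.box_stats([50, 55, 60, 65, 70])
        assert s.median == 60 and s.q1 == 55 and s.q3 == 65
        assert s.whisker_lo == 50 and s.whisker_hi == 70
        assert s.outliers == ()

    def test_degenerate_sample(self):
        s = ex.box_stats([60.0] * 5)
        assert s.q1 == s.q3 == s.median == 60.0
        assert s.outliers == ()

    def test_far_point_is_outlier(self):
        vals = [50, 55, 60, 65, 70]
        iqr = 10
        far = 60 + 10 * iqr
        s = ex.box_stats(vals + [far])
        assert far in s.outliers

    def test_whiskers_never_exceed_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(60, 15, size=rng.integers(4, 40))
            s = ex.box_stats(x)
            assert x.min() <= s.whisker_lo <= s.whisker_hi <= x.max()
            inside = (x >= s.whisker_lo) & (x <= s.whisker_hi)
            assert inside.sum() + len(s.outliers) == len(x)


class TestPairRetention:
    def make_table(self):
        rows = []
        for flow, counts in (("in", (100, 1000, 2000)), ("ex", (2, 20, 800))):
            rows.append(
                {"sponge": "S1", "pair": 1, "flow": flow, "beads": 500,
                 "bead_stock": 100.0, "Euk": counts[0], "HNA": counts[1],
                 "LNA": counts[2]}
            )
        return pd.DataFrame(rows)

    def test_hand_computed(self):
        rets = ex.pair_retention(self.make_table())
        assert rets.loc[0, "Euk"] == pytest.approx(98.0)
        assert rets.loc[0, "HNA"] == pytest.approx(98.0)
        assert rets.loc[0, "LNA"] == pytest.approx(60.0)

    def test_missing_column_named(self):
        bad = self.make_table().drop(columns=["beads"])
        with pytest.raises(ex.MeasurementError, match="beads"):
            ex.pair_retention(bad)

    def test_unpaired_sample_rejected(self):
        t = self.make_table()
        with pytest.raises(ex.MeasurementError):
            ex.pair_retention(t[t["flow"] == "in"])
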