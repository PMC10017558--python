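import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcatcalib.calibration import (
    CalibrationError,
    ConversionTable,
    Factor,
    apply_conversion,
    average_tables,
    conversion_factor,
    correct_measurement,
    estimate_factors,
    round_half_up,
)
from pcatcalib.measurement import PCATMeasurement


def make_measurement(vessel, kvp, pcat, recon="IR", window=(-190.0, -30.0)):
    return PCATMeasurement(
        vessel_id=vessel, kvp=kvp, recon=recon, adipose_voxel_count=1000,
        pcat_ma_hu=pcat, window=window, voi_size_voxels=1400,
    )


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(1.2665, 3, 1.267), (0.9465, 3, 0.947), (1.080, 3, 1.080),
         (0.0255, 3, 0.026), (0.0235, 3, 0.024), (58.3333, 1, 58.3),
         (-1.2665, 3, -1.267)],
    )
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


class TestFactorArithmetic:
    def test_identity_at_reference(self):
        assert conversion_factor(-100.0, -100.0) == 1.0

    @pytest.mark.parametrize(
        "pcat_i,pcat_ref,expected",
        [(-126.7, -100.0, 1.267), (-94.7, -100.0, 0.947)],
    )
    def test_ratio(self, pcat_i, pcat_ref, expected):
        assert conversion_factor(pcat_i, pcat_ref) == pytest.approx(expected)

    def test_zero_reference_errors(self):
        with pytest.raises(CalibrationError):
            conversion_factor(-100.0, 0.0)

    def test_positive_values_warn(self):
        with pytest.warns(UserWarning, match="adipose"):
            conversion_factor(50.0, -100.0)

    def test_apply_identity_and_example(self):
        assert apply_conversion(-80.0, 1.0) == -80.0
        assert apply_conversion(-95.025, 1.267) == pytest.approx(-75.0)

    def test_apply_nonpositive_factor_errors(self):
        with pytest.raises(CalibrationError):
            apply_conversion(-80.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(-200.0, -31.0),
        b=st.floats(-200.0, -31.0),
        x=st.floats(-500.0, -1.0),
    )
    def test_round_trip_is_algebraic_inverse(self, a, b, x):
        k = conversion_factor(a, b)
        assert apply_conversion(x * k, k) == pytest.approx(x, rel=1e-12)


class TestEstimateFactors:
    def test_single_vessel_ratios(self):
        ms = [
            make_measurement("V1", kvp, pcat)
            for kvp, pcat in [(80, -95.03), (100, -81.0), (120, -75.0), (140, -71.0)]
        ]
        table = estimate_factors(ms)
        rounded = table.rounded()
        assert rounded[80] == (1.267, 0.0)
        assert rounded[100] == (1.080, 0.0)
        assert rounded[120] == (1.0, 0.0)
        assert rounded[140] == (0.947, 0.0)

    def test_identical_pcat_all_kvp_gives_unit_factors(self):
        ms = [
            make_measurement(v, kvp, -80.0)
            for v in ("V1", "V2", "V3")
            for kvp in (80, 100, 120, 140)
        ]
        table = estimate_factors(ms)
        assert all(f.k == pytest.approx(1.0) for f in table.factors.values())

    def test_reference_entry_is_exactly_one(self):
        ms = [make_measurement("V1", k, p) for k, p in [(80, -90.0), (120, -75.0)]]
        table = estimate_factors(ms)
        assert table.factors[120] == Factor(1.0, 0.0)

    def test_missing_reference_errors(self):
        ms = [make_measurement("V1", 80, -90.0), make_measurement("V1", 100, -80.0)]
        with pytest.raises(CalibrationError, match="reference"):
            estimate_factors(ms)

    def test_absent_recon_filter_errors(self):
        ms = [make_measurement("V1", 120, -75.0, recon="FBP")]
        with pytest.raises(CalibrationError, match="IR"):
            estimate_factors(ms, recon_filter="IR")

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        pcat = {
            v: {k: float(-rng.uniform(60, 110)) for k in (80, 100, 120, 140)}
            for v in ("V1", "V2", "V3", "V4")
        }
        def table_for(c):
            ms = [
                make_measurement(v, k, c * p, window=(-600.0, -1.0))
                for v, per in pcat.items()
                for k, p in per.items()
            ]
            return estimate_factors(ms, sd_method="sample")
        base = table_for(1.0)
        scaled = table_for(2.5)
        for kvp in (80, 100, 140):
            assert scaled.factors[kvp].k == pytest.approx(base.factors[kvp].k, rel=1e-12)
            assert scaled.factors[kvp].sd == pytest.approx(base.factors[kvp].sd, rel=1e-9)

    @pytest.mark.parametrize("method", ["propagation", "sample", "bootstrap"])
    def test_sd_methods_agree_in_order_of_magnitude(self, method):
        rng = np.random.default_rng(17)
        ms = []
        for v in range(8):
            base = -75.0 + rng.normal(0, 3)
            for kvp, r in [(80, 1.27), (100, 1.08), (120, 1.0), (140, 0.95)]:
                ms.append(make_measurement(f"V{v}", kvp, base * r + rng.normal(0, 0.5)))
        table = estimate_factors(ms, sd_method=method)
        sd = table.factors[80].sd
        assert 0.0 < sd < 0.1

    def test_incomplete_vessels_dropped_listwise(self):
        ms = [
            make_measurement("V1", k, p)
            for k, p in [(80, -95.0), (100, -81.0), (120, -75.0), (140, -71.0)]
        ]
        ms.append(make_measurement("V2", 120, -70.0))  # incomplete vessel
        table = estimate_factors(ms)
        assert table.source == ("V1",)


class TestAverageTables:
    @staticmethod
    def printed_scanner_tables():
        a = ConversionTable(
            120,
            {80: Factor(1.292, 0.086), 100: Factor(1.049, 0.088),
             120: Factor(1.0, 0.0), 140: Factor(0.923, 0.030)},
            scanner_label="wide-detector-256",
        )
        b = ConversionTable(
            120,
            {80: Factor(1.241, 0.017), 100: Factor(1.111, 0.042),
             120: Factor(1.0, 0.0), 140: Factor(0.970, 0.022)},
            scanner_label="dual-source",
        )
        return [a, b]

    def test_two_scanner_average_matches_published_row(self):
        avg = average_tables(self.printed_scanner_tables())
        rounded = avg.rounded()
        assert rounded[80] == (1.267, 0.026)
        assert rounded[100] == (1.080, 0.031)
        assert rounded[120] == (1.0, 0.0)
        assert rounded[140] == (0.947, 0.024)

    def test_identical_tables_average_to_themselves_sd_zero(self):
        t = self.printed_scanner_tables()[0]
        avg = average_tables([t, t, t])
        for kvp in (80, 100, 140):
            assert avg.factors[kvp].k == pytest.approx(t.factors[kvp].k)
            assert avg.factors[kvp].sd == 0.0

    def test_mismatched_kvp_sets_rejected(self):
        a = ConversionTable(120, {80: Factor(1.2), 120: Factor(1.0)})
        b = ConversionTable(120, {100: Factor(1.1), 120: Factor(1.0)})
        with pytest.raises(CalibrationError, match="mismatch"):
            average_tables([a, b])

    def test_single_table_rejected(self):
        with pytest.raises(CalibrationError):
            average_tables([self.printed_scanner_tables()[0]])


class TestCorrectMeasurement:
    def test_reference_measurement_unchanged(self):
        table = ConversionTable(120, {80: Factor(1.267), 120: Factor(1.0)})
        m = make_measurement("V1", 120, -75.0)
        out = correct_measurement(m, table)
        assert out.pcat_ma_hu == -75.0
        assert out.kvp == 120

    def test_published_factor_recovers_reference_value(self):
        table = ConversionTable(120, {80: Factor(1.267), 120: Factor(1.0)})
        m = make_measurement("V1", 80, -95.025)
        out = correct_measurement(m, table)
        assert out.pcat_ma_hu == pytest.approx(-75.0, abs=0.1)
        assert out.kvp == 120
        assert out.corrected_from_kvp == 80

    def test_missing_kvp_errors(self):
        table = ConversionTable(120, {120: Factor(1.0)})
        with pytest.raises(CalibrationError, match="missing"):
            correct_measurement(make_measurement("V1", 80, -95.0), table)

    def test_refit_on_corrected_data_gives_unit_factors(self):
        rng = np.random.default_rng(2)
        ms = []
        for v in range(6):
            base = -75.0 + rng.normal(0, 3)
            for kvp, r in [(80, 1.267), (100, 1.080), (120, 1.0), (140, 0.947)]:
                ms.append(make_measurement(f"V{v}", kvp, base * r + rng.normal(0, 0.3)))
        table = estimate_factors(ms, sd_method="sample")
        corrected = [correct_measurement(m, table) for m in ms]
        # corrected measurements all live at the reference kVp label; rebuild
        # per-vessel series using their origin kVp to re-estimate
        for m in corrected:
            m.kvp = m.corrected_from_kvp if m.corrected_from_kvp else 120
        refit = estimate_factors(corrected, sd_method="sample")
        for kvp in (80, 100, 140):
            f = refit.factors[kvp]
            assert abs(f.k - 1.0) < max(2 * table.factors[kvp].sd, 0.02)


class TestTableIO:
    def test_csv_and_json_round_trip(self, tmp_path):
        table = ConversionTable(
            120,
            {80: Factor(1.2921234, 0.0861), 100: Factor(1.0494, 0.0885),
             120: Factor(1.0, 0.0), 140: Factor(0.9228, 0.0301)},
            scanner_label="wide-detector-256",
            source=("V1", "V2"),
        )
        table.to_csv(tmp_path / "t.csv")
        back_csv = ConversionTable.from_csv(tmp_path / "t.csv")
        table.to_json(tmp_path / "t.json")
        back_json = ConversionTable.from_json(tmp_path / "t.json")
        for back in (back_csv, back_json):
            assert back.reference_kvp == 120
            for kvp, f in table.factors.items():
                assert back.factors[kvp].k == pytest.approx(f.k, abs=1e-8)
                assert back.factors[kvp].sd == pytest.approx(f.sd, abs=1e-8)
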