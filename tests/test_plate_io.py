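import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbscreen import plate_io
from hbscreen.plate_io import (
    DoseSeries,
    PlateParseError,
    control_stats,
    extract_dose_series,
    parse_well,
    percent_inhibition,
    read_plate_map,
    read_raw_plate,
    well_name,
)


def _map_df(rows):
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "content_type", "compound_id",
                       "concentration_molar", "model_id"]
    )


def _basic_map():
    rows = [("P1", "A01", "compound", "X", 1e-7, "M1")]
    rows += [("P1", f"B{i:02d}", "neg_control", "", np.nan, "M1") for i in (1, 2)]
    rows += [("P1", f"C{i:02d}", "pos_control", "", np.nan, "M1") for i in (1, 2)]
    return _map_df(rows)


class TestWellAddressing:
    @pytest.mark.parametrize(
        "well,rc", [("A01", (0, 0)), ("P24", (15, 23)), ("h12", (7, 11))]
    )
    def test_parse_roundtrip(self, well, rc):
        assert parse_well(well) == rc
        assert parse_well(well_name(*rc)) == rc

    @pytest.mark.parametrize("bad", ["Q01", "A25", "A0x", "1A", ""])
    def test_malformed_addresses_rejected(self, bad):
        with pytest.raises(PlateParseError):
            parse_well(bad)


class TestReadPlateMap:
    def test_compound_well_accepted_with_zero_based_indices(self):
        pm = read_plate_map(_basic_map())
        w = pm.wells.loc["A01"]
        assert (w["row"], w["col"]) == (0, 0)
        assert w["compound_id"] == "X"
        assert w["concentration_molar"] == 1e-7

    def test_duplicate_well_names_offender(self):
        df = pd.concat([_basic_map(), _basic_map().iloc[:1]], ignore_index=True)
        with pytest.raises(PlateParseError, match="A01"):
            read_plate_map(df)

    @pytest.mark.parametrize("conc", [0.0, -1e-9])
    def test_nonpositive_concentration_rejected(self, conc):
        df = _basic_map()
        df.loc[0, "concentration_molar"] = conc
        with pytest.raises(PlateParseError):
            read_plate_map(df)

    def test_two_models_on_one_plate_rejected(self):
        df = _basic_map()
        df.loc[0, "model_id"] = "M2"
        with pytest.raises(PlateParseError):
            read_plate_map(df)


class TestReadRawPlate:
    def test_complete_plate(self):
        wells = [well_name(r, c) for r in range(16) for c in range(24)]
        df = pd.DataFrame({"plate_id": "P1", "well": wells, "signal": 1000.0})
        rp = read_raw_plate(df)
        assert len(rp.signals) == 384

    def test_missing_well_reported(self):
        pm = read_plate_map(_basic_map())
        df = pd.DataFrame(
            {"plate_id": "P1", "well": ["A01", "B01", "B02", "C01"], "signal": 1.0}
        )
        with pytest.raises(PlateParseError, match="C02"):
            read_raw_plate(df, pm)

    @pytest.mark.parametrize("sig", [-5, "abc", np.inf])
    def test_bad_signals_rejected(self, sig):
        df = pd.DataFrame({"plate_id": "P1", "well": ["A01"], "signal": [sig]})
        with pytest.raises(PlateParseError):
            read_raw_plate(df)


class TestControlStatsAndInhibition:
    def _plate(self, neg, pos, compound_signal=5200.0):
        pm = read_plate_map(_basic_map())
        sig = {"A01": compound_signal, "B01": neg[0], "B02": neg[1],
               "C01": pos[0], "C02": pos[1]}
        rp = read_raw_plate(
            pd.DataFrame({"plate_id": "P1", "well": list(sig), "signal": list(sig.values())})
        )
        return pm, rp

    def test_identical_controls(self):
        pm, rp = self._plate((10000, 10000), (400, 400))
        cs = control_stats(pm, rp)
        assert (cs.mu_neg, cs.sd_neg, cs.mu_pos) == (10000, 0, 400)

    def test_sample_sd(self):
        pm, rp = self._plate((9000, 11000), (400, 400))
        cs = control_stats(pm, rp)
        assert cs.mu_neg == 10000
        assert cs.sd_neg == pytest.approx(1414.2, abs=0.1)  # sample SD, ddof=1

    def test_missing_pos_controls_error(self):
        df = _basic_map()
        df = df[df["content_type"] != "pos_control"]
        pm = read_plate_map(df)
        rp = read_raw_plate(
            pd.DataFrame({"plate_id": "P1", "well": ["A01", "B01", "B02"], "signal": 1.0})
        )
        with pytest.raises(ValueError, match="pos_control"):
            control_stats(pm, rp)

    @pytest.mark.parametrize(
        "signal,expected", [(10000.0, 0.0), (400.0, 100.0), (5200.0, 50.0)]
    )
    def test_percent_inhibition_control_axis(self, signal, expected):
        pm, rp = self._plate((10000, 10000), (400, 400), compound_signal=signal)
        pi = percent_inhibition(pm, rp)
        assert len(pi) == 1  # control wells excluded
        assert pi["pi"].iloc[0] == pytest.approx(expected)

    def test_degenerate_controls_error(self):
        pm, rp = self._plate((400, 400), (400, 400))
        with pytest.raises(ValueError, match="degenerate"):
            percent_inhibition(pm, rp)

    @settings(deadline=None, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_affine_invariance_under_signal_rescaling(self, k):
        pm, rp1 = self._plate((10000, 9000), (400, 500), compound_signal=5200.0)
        rp2 = plate_io.RawPlate(plate_id="P1", signals=rp1.signals * k)
        pi1 = percent_inhibition(pm, rp1)["pi"].iloc[0]
        pi2 = percent_inhibition(pm, rp2)["pi"].iloc[0]
        assert pi2 == pytest.approx(pi1, rel=1e-9)


class TestExtractDoseSeries:
    def _pi_table(self, rows):
        return pd.DataFrame(
            rows, columns=["plate_id", "well", "compound_id",
                           "concentration_molar", "model_id", "pi"]
        )

    def test_five_doses_one_series(self):
        rows = [("P1", f"A{i+1:02d}", "X", 10.0 ** (-9 + i), "M1", 10.0 * i)
                for i in range(5)]
        (s,) = extract_dose_series(self._pi_table(rows))
        assert len(s.x) == 5
        assert np.all(np.diff(s.x) > 0)

    def test_replicates_averaged_on_pi_scale(self):
        rows = [
            ("P1", "A01", "X", 1e-8, "M1", 40.0),
            ("P1", "A02", "X", 1e-8, "M1", 60.0),
            ("P1", "A03", "X", 1e-7, "M1", 80.0),
        ]
        (s,) = extract_dose_series(self._pi_table(rows))
        assert s.pi[0] == pytest.approx(50.0)

    def test_compound_on_two_models_gives_two_series(self):
        rows = [("P1", "A01", "X", 1e-8, "M1", 10.0), ("P1", "A02", "X", 1e-7, "M1", 20.0),
                ("P2", "A01", "X", 1e-8, "M2", 10.0), ("P2", "A02", "X", 1e-7, "M2", 20.0)]
        series = extract_dose_series(self._pi_table(rows))
        assert {s.model_id for s in series} == {"M1", "M2"}

    def test_single_dose_series_skipped_with_warning(self):
        rows = [("P1", "A01", "X", 1e-8, "M1", 40.0)]
        with pytest.warns(UserWarning, match="skipped"):
            assert extract_dose_series(self._pi_table(rows)) == []


def test_plate_table_roundtrip_lossless(fixture_screen):
    maps, raws, _ = fixture_screen
    pm, rp = maps[0], raws[0]
    pm2 = read_plate_map(plate_io.write_plate_map(pm))
    rp2 = read_raw_plate(plate_io.write_raw_plate(rp))
    pd.testing.assert_frame_equal(pm.wells, pm2.wells)
    pd.testing.assert_series_equal(rp.signals, rp2.signals)
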