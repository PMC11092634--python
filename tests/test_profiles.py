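import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paintbench import profiles as pf


class TestParseFeatureName:
    @pytest.mark.parametrize(
        "raw, compartment, group, stains",
        [
            ("Nuclei_Intensity_MeanIntensity_RNA", "Nuclei", "Intensity", ("RNA",)),
            ("Cells_Correlation_Costes_DNA_RNA", "Cells", "Correlation", ("DNA", "RNA")),
            ("Cytoplasm_AreaShape_Area", "Cytoplasm", "AreaShape", ()),
            ("Cells_Neighbors_NumberOfNeighbors", "Cells", "Neighbors", ()),
            ("Nuclei_Intensity_MeanIntensity_Hoechst", "Nuclei", "Intensity", ("DNA",)),
            ("Cells_Intensity_MeanIntensity_Phalloidin", "Cells", "Intensity", ("AGP",)),
        ],
    )
    def test_token_parsing(self, raw, compartment, group, stains):
        key = pf.parse_feature_name(raw)
        assert (key.compartment, key.group, key.stains) == (compartment, group, stains)

    def test_costes_flagged(self):
        assert pf.parse_feature_name("Cells_Correlation_Costes_DNA_RNA").is_costes
        assert not pf.parse_feature_name("Cells_Correlation_Overlap_DNA_RNA").is_costes

    def test_unknown_compartment_raises(self):
        with pytest.raises(ValueError, match="Golgi"):
            pf.parse_feature_name("Golgi_Intensity_MeanIntensity_DNA")

    def test_unknown_channel_token_warns(self, caplog):
        with caplog.at_level("WARNING"):
            key = pf.parse_feature_name("Nuclei_Intensity_MeanIntensity_FITC")
        assert key.stains == ()
        assert any("FITC" in r.message or "channel" in r.message for r in caplog.records)


class TestCleanFeatures:
    def test_all_missing_column_dropped_before_cells(self, tiny_cells):
        cells = tiny_cells.copy()
        cells["Nuclei_Intensity_MeanIntensity_DNA"] = np.nan
        out = pf.clean_features(cells)
        assert "Nuclei_Intensity_MeanIntensity_DNA" not in out.columns
        assert len(out) == len(cells)  # no cell dropped for the dead column

    def test_costes_column_dropped_not_cells(self, tiny_cells):
        # Costes feature missing in ~half the cells: the column goes, cells stay
        out = pf.clean_features(tiny_cells)
        assert "Cells_Correlation_Costes_DNA_RNA" not in out.columns
        assert len(out) == len(tiny_cells)

    def test_sparse_missing_drops_single_cell(self, tiny_cells):
        cells = tiny_cells.copy()
        cells.loc[0, "Cells_AreaShape_Area"] = np.nan
        out = pf.clean_features(cells)
        assert "Cells_AreaShape_Area" in out.columns
        assert len(out) == len(cells) - 1

    def test_idempotent(self, tiny_cells):
        once = pf.clean_features(tiny_cells)
        twice = pf.clean_features(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_nothing_left_raises(self, tiny_cells):
        cells = tiny_cells.copy()
        feats = pf.feature_columns(cells)
        cells[feats] = np.nan
        with pytest.raises(ValueError):
            pf.clean_features(cells)


def _counts_frame(vehicle_mean, dose_mean, n=4):
    rows = []
    for i in range(n):
        rows.append(("P1", f"A{i:02d}", "DMSO", 0.0, "DMSO", i + 1, vehicle_mean))
        rows.append(("P1", f"B{i:02d}", "X", 25.0, "DMSO", i + 1, dose_mean))
    return pd.DataFrame(
        rows,
        columns=[*pf.METADATA_COLUMNS, "cell_count"],
    )


class TestFlagCytotoxic:
    def test_below_quarter_flagged(self):
        flags = pf.flag_cytotoxic(_counts_frame(400, 99))
        assert flags == {("X", 25.0)}

    def test_exact_quarter_retained(self):
        # rule is strictly less-than: a dose at exactly 25% survives
        flags = pf.flag_cytotoxic(_counts_frame(400, 100))
        assert flags == set()

    def test_zero_vehicle_mean_raises(self):
        with pytest.raises(ValueError, match="vehicle mean"):
            pf.flag_cytotoxic(_counts_frame(0, 100))

    def test_missing_vehicle_wells_raise(self):
        counts = _counts_frame(400, 99)
        counts = counts[counts["Metadata_Concentration"] > 0]
        with pytest.raises(ValueError, match="vehicle"):
            pf.flag_cytotoxic(counts)


class TestRobustize:
    def _table(self, control_values, treated_value=4.4826):
        rows = []
        for i, v in enumerate(control_values):
            rows.append(("P1", "A01", "DMSO", 0.0, "DMSO", 1, v))
        rows.append(("P1", "B01", "X", 1.0, "DMSO", 1, treated_value))
        df = pd.DataFrame(
            rows, columns=[*pf.METADATA_COLUMNS, "Nuclei_Intensity_MeanIntensity_DNA"]
        )
        return df

    def test_center_maps_to_zero_and_scaled_mad(self):
        # controls {1..5}: median 3, MAD*1.4826 = 1.4826; x=4.4826 -> 1.0
        cells = self._table([1.0, 2.0, 3.0, 4.0, 5.0])
        params = pf.fit_normalization(cells)
        out = pf.robustize(cells, params)
        col = out["Nuclei_Intensity_MeanIntensity_DNA"]
        controls = out[out["Metadata_Concentration"] == 0][
            "Nuclei_Intensity_MeanIntensity_DNA"
        ]
        assert controls.iloc[2] == pytest.approx(0.0)
        assert col.iloc[-1] == pytest.approx(1.0, rel=1e-12)

    def test_constant_control_feature_dropped(self, caplog):
        cells = self._table([2.0, 2.0, 2.0, 2.0])
        with caplog.at_level("WARNING"):
            params = pf.fit_normalization(cells)
        assert params.dropped == ["Nuclei_Intensity_MeanIntensity_DNA"]

    def test_unknown_plate_raises(self):
        cells = self._table([1.0, 2.0, 3.0])
        params = pf.fit_normalization(cells)
        other = cells.copy()
        other["Metadata_Plate"] = "P2"
        with pytest.raises(ValueError, match="P2"):
            pf.robustize(other, params)


class TestGlog:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, math.log(0.5)), (1.5, math.log((1.5 + math.sqrt(3.25)) / 2))],
    )
    def test_closed_form(self, x, expected):
        assert pf.glog_transform(x, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_offset_raises(self):
        with pytest.raises(ValueError):
            pf.glog_transform(1.0, 0.0)

    @given(
        x1=st.floats(-1e6, 1e6), x2=st.floats(-1e6, 1e6),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_monotone(self, x1, x2, c):
        lo, hi = sorted((x1, x2))
        glo, ghi = pf.glog_transform(lo, c), pf.glog_transform(hi, c)
        assert glo <= ghi
        if hi - lo > 1e-6 * max(1.0, abs(lo), abs(hi)):
            assert glo < ghi


class TestAggregateWells:
    def test_median_is_robust_and_even_count(self, tiny_cells):
        cells = pf.clean_features(tiny_cells)
        cells.loc[cells.index[:3], "Cells_AreaShape_Area"] = [1.0, 2.0, 100.0]
        prof = pf.aggregate_wells(cells)
        assert len(prof) == 3
        # {1,2,100,40,50} -> median 40 (robust to the outlier)
        assert set(prof.columns) >= {"cell_count", "Cells_AreaShape_Area"}
        even = pf.aggregate_wells(cells[cells["ObjectNumber"] <= 4])
        well = even[even["Metadata_Well"] == "B01"]
        # values {10,20,30,40} -> 25.0
        assert well["Cells_AreaShape_Area"].iloc[0] == pytest.approx(25.0)

    def test_cytotoxic_wells_excluded(self, tiny_cells):
        cells = pf.clean_features(tiny_cells)
        prof = pf.aggregate_wells(cells, cytotoxic={("X", 1.0)})
        assert (prof["Metadata_Chemical"] != "X").all()


class TestPipelineInvariants:
    def test_vehicle_medians_near_zero_without_glog(self, planted_plate):
        cells, _, _, _ = planted_plate
        prof, _ = pf.preprocess(cells, glog_offset=None)
        veh = prof[prof["Metadata_Concentration"] == 0]
        feats = [c for c in pf.feature_columns(prof) if c != "cell_count"]
        med = veh[feats].median()
        assert (med.abs() < 0.2).mean() > 0.95
        assert med.abs().median() < 0.1

    def test_row_order_invariance(self, tiny_cells):
        cells = pf.clean_features(tiny_cells)
        params = pf.fit_normalization(cells)
        shuffled = cells.sample(frac=1.0, random_state=0)
        a = pf.aggregate_wells(pf.robustize(cells, params))
        b = pf.aggregate_wells(pf.robustize(shuffled, params))
        pd.testing.assert_frame_equal(a, b)

    def test_plate_offsets_removed(self, small_catalog):
        # same chemistry on two plates with very different additive offsets:
        # robustize should superimpose the vehicle profiles
        from paintbench.simulate import (
            EffectSpec, PlateDesign, Treatment, generate_plate_set,
        )

        design = PlateDesign(
            treatments=[Treatment("A"), Treatment("B")],
            plates=("P1", "P2"),
            features=small_catalog[:20],
        )
        effects = EffectSpec(plate_shift_sd=5.0)
        cells, _ = generate_plate_set(design, effects, seed=3)
        prof, _ = pf.preprocess(cells, glog_offset=None)
        veh = prof[prof["Metadata_Concentration"] == 0]
        feats = [c for c in pf.feature_columns(prof) if c != "cell_count"]
        by_plate = veh.groupby("Metadata_Plate")[feats].median()
        assert float((by_plate.iloc[0] - by_plate.iloc[1]).abs().max()) < 1.5
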