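"""Single-cell feature tests: segmentation, CD69, ORR, aggregation, QC."""

import numpy as np
import pandas as pd
import pytest

from lymphomi import (
    aggregate_cell_features,
    apply_qc_filters,
    assign_cd69,
    label_activation,
    normalize_orr,
    redox_ratio,
    segment_cells,
)
from lymphomi.features import assign_cd69_labels, segment_cd69
from lymphomi.fitting import FitImageResult


def make_fit_result(shape, **const_maps):
    """Uniform FitImageResult over a boolean footprint (kw `footprint`)."""
    footprint = const_maps.pop("footprint")
    defaults = dict(
        tau1=0.4, tau2=2.5, a1=0.7, a1_raw=0.7, a2_raw=0.3, C=0.0,
        tau_m=1.03, chi2=1.0, photons=500.0,
    )
    defaults.update(const_maps)
    arrays = {}
    for name, val in defaults.items():
        arr = np.full(shape, np.nan, dtype=np.float32)
        arr[footprint] = val
        arrays[name] = arr
    return FitImageResult(
        **arrays,
        bin_factor=np.where(footprint, 0, -1).astype(np.int16),
        converged=footprint.copy(),
    )


class TestSegmentation:
    def test_recovers_simulated_masks(self, small_field):
        """Mean IoU against the simulator's ground-truth cell masks."""
        cells, nuclei, cyto = segment_cells(small_field.nadh.intensity())
        truth = small_field.cell_mask
        ious = []
        for lab in range(1, truth.max() + 1):
            tm = truth == lab
            overlap_ids = np.unique(cells[tm])
            overlap_ids = overlap_ids[overlap_ids > 0]
            if overlap_ids.size == 0:
                ious.append(0.0)
                continue
            best = max(overlap_ids, key=lambda i: ((cells == i) & tm).sum())
            sm = cells == best
            ious.append((tm & sm).sum() / (tm | sm).sum())
        assert np.mean(ious) >= 0.8
        assert np.all((cyto > 0) == ((cells > 0) & (nuclei == 0)))

    def test_blank_image_yields_no_cells(self):
        cells, nuclei, cyto = segment_cells(np.zeros((32, 32)))
        assert cells.max() == 0 and nuclei.max() == 0 and cyto.max() == 0

    def test_two_blobs_become_two_labels(self):
        img = np.zeros((64, 64))
        img[8:20, 8:20] = 500.0
        img[40:52, 40:52] = 500.0
        cells, _, _ = segment_cells(img)
        assert cells.max() == 2


class TestCD69:
    def _masks(self, overlap_px):
        # CD69 component: a 4x25 rectangle, exactly 100 px
        cd69 = np.zeros((40, 40), bool)
        cd69[0:4, 0:25] = True
        cell = np.zeros((40, 40), bool)
        flat_idx = np.nonzero(cd69)
        cell[flat_idx[0][:overlap_px], flat_idx[1][:overlap_px]] = True
        cell[30:35, 30:35] = True  # bulk of the cell elsewhere
        assert cd69.sum() == 100 and (cd69 & cell).sum() == overlap_px
        return cd69, cell

    def test_80_percent_overlap_is_positive(self):
        cd69, cell = self._masks(80)
        assert assign_cd69(cd69, cell) is True

    def test_74_percent_overlap_is_negative(self):
        cd69, cell = self._masks(74)
        assert assign_cd69(cd69, cell) is False

    def test_no_touching_component_is_negative(self):
        cd69 = np.zeros((20, 20), bool)
        cd69[0:3, 0:3] = True
        cell = np.zeros((20, 20), bool)
        cell[10:15, 10:15] = True
        assert assign_cd69(cd69, cell) is False

    def test_empty_cell_mask_rejected(self):
        with pytest.raises(ValueError):
            assign_cd69(np.ones((5, 5), bool), np.zeros((5, 5), bool))

    def test_simulated_cd69_recovered_from_marker_image(self, small_field):
        mask = segment_cd69(small_field.cd69_image)
        flags = assign_cd69_labels(mask, small_field.cell_mask)
        truth = small_field.ground_truth.set_index("cell_id")["cd69_positive"]
        agreement = np.mean([flags[i] == truth[i] for i in truth.index])
        assert agreement >= 0.9


class TestLabelsAndRatios:
    @pytest.mark.parametrize(
        "condition, cd69, expected",
        [
            ("control", False, "quiescent"),
            ("stimulated", True, "activated"),
            ("control", True, "unlabeled"),
            ("stimulated", False, "unlabeled"),
        ],
    )
    def test_activation_labeling(self, condition, cd69, expected):
        assert label_activation(condition, cd69) == expected

    @pytest.mark.parametrize(
        "nadh, fad, expected", [(100, 100, 0.5), (300, 0, 1.0), (300, 100, 0.75)]
    )
    def test_redox_ratio(self, nadh, fad, expected):
        assert redox_ratio(nadh, fad) == pytest.approx(expected)

    def test_redox_ratio_zero_rejected(self):
        with pytest.raises(ValueError):
            redox_ratio(0.0, 0.0)


class TestNormalizeORR:
    def _table(self):
        return pd.DataFrame(
            {
                "batch_id": ["d1"] * 4 + ["d2"] * 4,
                "condition": ["control", "control", "stimulated", "stimulated"] * 2,
                "activation": ["quiescent", "quiescent", "activated", "activated"] * 2,
                "orr": [0.4, 0.6, 0.6, 0.7, 0.2, 0.3, 0.5, 0.6],
            }
        )

    def test_batchwise_normalization_is_independent(self):
        out = normalize_orr(self._table())
        # d1 control mean 0.5; d2 control mean 0.25
        np.testing.assert_allclose(
            out["orr_norm"], [0.8, 1.2, 1.2, 1.4, 0.8, 1.2, 2.0, 2.4]
        )

    def test_control_cells_average_to_one_per_batch(self):
        out = normalize_orr(self._table())
        ctrl = out[out.activation == "quiescent"]
        for _, grp in ctrl.groupby("batch_id"):
            assert grp["orr_norm"].mean() == pytest.approx(1.0)

    def test_batch_without_controls_is_an_error_naming_it(self):
        t = self._table()
        t.loc[t.batch_id == "d2", "activation"] = "activated"
        with pytest.raises(ValueError, match="d2"):
            normalize_orr(t)


class TestAggregation:
    def test_uniform_cell_equals_pixel_values(self):
        shape = (16, 16)
        cell = np.zeros(shape, np.uint16)
        cell[4:10, 4:10] = 1
        nucleus = np.zeros(shape, np.uint16)
        nucleus[6:8, 6:8] = 1
        foot = cell > 0
        nadh_fit = make_fit_result(shape, footprint=foot)
        fad_fit = make_fit_result(shape, footprint=foot, tau1=0.3, tau2=2.0, a1=0.6,
                                  tau_m=0.98)
        intensity = np.where(foot, 400.0, 0.0)
        table = aggregate_cell_features(
            nadh_fit, fad_fit, intensity, intensity, cell, nucleus,
            condition="control",
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row.nadh_tm == pytest.approx(1.03)
        assert row.nadh_a1 == pytest.approx(70.0)
        assert row.fad_a1 == pytest.approx(60.0)
        assert row.orr == pytest.approx(0.5)
        assert row.area_px == 36
        assert row.photons == pytest.approx(400.0 * 32)  # cytoplasm = 36 - 4 px

    def test_mean_of_two_pixel_populations(self):
        shape = (8, 8)
        cell = np.zeros(shape, np.uint16)
        cell[2:4, 2:6] = 1
        foot = cell > 0
        fit = make_fit_result(shape, footprint=foot)
        fit.a1[2, 2:6] = 0.6
        fit.a1[3, 2:6] = 0.8
        table = aggregate_cell_features(
            fit, fit, np.ones(shape), np.ones(shape), cell,
            np.zeros(shape, np.uint16), condition="control",
        )
        assert table.iloc[0].nadh_a1 == pytest.approx(70.0)

    def test_chi2_rule_applies_per_pixel_before_averaging(self):
        shape = (8, 8)
        cell = np.zeros(shape, np.uint16)
        cell[2:4, 2:6] = 1
        foot = cell > 0
        fit = make_fit_result(shape, footprint=foot)
        fit.chi2[2, 2:6] = 5.0  # these pixels fail chi2 <= 1.3
        fit.a1[2, 2:6] = 0.99  # and would skew the mean if included
        table = aggregate_cell_features(
            fit, fit, np.ones(shape), np.ones(shape), cell,
            np.zeros(shape, np.uint16), condition="control",
        )
        assert table.iloc[0].nadh_a1 == pytest.approx(70.0)
        assert table.iloc[0].n_valid_pixels == 4


class TestQCFilters:
    def _fixture(self):
        base = dict(
            nadh_tm=1.0, photons=50_000.0, area_px=300, chi2_mean=1.0
        )
        rows = [dict(base, cell_id=i) for i in range(1, 11)]
        rows[3]["photons"] = 4999.0  # photon rule
        rows[5]["area_px"] = 249  # area rule
        rows[7]["chi2_mean"] = 1.8  # chi2 rule
        return pd.DataFrame(rows)

    def test_one_violation_each_rule(self):
        kept, counts = apply_qc_filters(self._fixture())
        assert len(kept) == 7
        assert counts == {"photons": 1, "area": 1, "chi2": 1}

    def test_boundary_values_are_exclusive(self):
        t = self._fixture().iloc[:1].copy()
        t["photons"] = 5000.0
        t["area_px"] = 250
        kept, _ = apply_qc_filters(t)
        assert len(kept) == 1

    def test_tightening_thresholds_is_monotone(self, rng):
        t = pd.DataFrame(
            {
                "cell_id": np.arange(200),
                "nadh_tm": 1.0,
                "photons": rng.uniform(1000, 20000, 200),
                "area_px": rng.integers(100, 600, 200),
                "chi2_mean": rng.uniform(0.5, 2.0, 200),
            }
        )
        prev = len(t) + 1
        for mp, ma, mc in [(2000, 150, 1.8), (5000, 250, 1.3), (9000, 400, 1.0)]:
            kept, _ = apply_qc_filters(t, mp, ma, mc)
            assert len(kept) <= prev
            prev = len(kept)

    def test_pixelless_cells_count_as_chi2_exclusions(self):
        t = self._fixture()
        t["n_valid_pixels"] = 10
        t.loc[7, "n_valid_pixels"] = 0
        t.loc[7, "chi2_mean"] = 1.0
        kept, counts = apply_qc_filters(t)
        assert counts["chi2"] == 1 and len(kept) == 7
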