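"""Feature extraction checked against an independent dense-matrix oracle.

The oracle rebuilds the full dense GLRLM of one ROI and evaluates every
feature with explicit double loops over (gray level, run length); the
package's keyed-reduction path must agree to 1e-12 relative.
"""

import numpy as np
import pytest
from conftest import dense_from_entries

from glrlmtex.errors import CompletenessError, DivisionDomainError
from glrlmtex.features import (
    EMPHASIS_POWERS,
    FEATURE_NAMES,
    assemble_feature_maps,
    extract_all_features,
    roi_denominators,
    weighted_feature,
)
from glrlmtex.fixtures import synth_checkerboard, synth_constant, synth_random
from glrlmtex.glrlm_batch import glrlm_all_rois_batch
from glrlmtex.image_model import DIRECTIONS, ROISpec


def dense_features(dense, n_pixels, level_offset):
    """Brute-force double-loop evaluation of all 11 features on one dense matrix."""
    out = {}
    s = dense.sum()
    for name, (a, b) in EMPHASIS_POWERS.items():
        total = 0.0
        for gray in range(dense.shape[0]):
            for run in range(1, dense.shape[1]):
                if dense[gray, run]:
                    total += (gray + level_offset) ** a * run**b * dense[gray, run]
        out[name] = total / s
    out["GLN"] = sum(row.sum() ** 2 for row in dense) / s
    out["RLN"] = sum(dense[:, j].sum() ** 2 for j in range(dense.shape[1])) / s
    out["RP"] = s / n_pixels
    return out


class TestWorkedExampleFeatures:
    """The known horizontal GLRLM of the 5x5 worked ROI, as exact fractions."""

    @pytest.fixture()
    def h0_batch(self, worked, spec55):
        return glrlm_all_rois_batch(worked.image, spec55, DIRECTIONS["H0"])

    def test_denominator_is_total_run_count(self, h0_batch):
        _, s = roi_denominators(h0_batch)
        assert s.tolist() == [22.0]

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("SRE", 19.75 / 22),
            ("LRE", 31 / 22),
            ("GLN", 100 / 22),
            ("RLN", 370 / 22),
            ("RP", 22 / 25),
            ("HGRE", 451832 / 22),  # levels 1,43,114,129,256 under offset 1
        ],
    )
    def test_exact_fraction_values(self, h0_batch, spec55, name, expected):
        table = extract_all_features(h0_batch, spec55)
        assert table.values[name][0] == pytest.approx(expected, rel=1e-12)

    def test_all_eleven_against_dense_oracle(self, h0_batch, worked, spec55):
        dense = dense_from_entries(worked.expected["H0"])
        expected = dense_features(dense, 25, level_offset=1)
        table = extract_all_features(h0_batch, spec55)
        for name in FEATURE_NAMES:
            assert table.values[name][0] == pytest.approx(expected[name], rel=1e-12)


class TestDenseOracleAgreement:
    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("offset", [1, 2])
    def test_keyed_reductions_match_dense_loops(self, seed, offset, direction):
        img = synth_random(10, 12, 8, seed)
        spec = ROISpec(4, 5, level_offset=offset)
        batch = glrlm_all_rois_batch(img, spec, direction)
        table = extract_all_features(batch, spec)
        for pos, roi_index in enumerate(table.roi_index):
            dense = dense_from_entries(batch.entries_for_roi(int(roi_index)))
            expected = dense_features(dense, spec.n_pixels, offset)
            for name in FEATURE_NAMES:
                assert table.values[name][pos] == pytest.approx(
                    expected[name], rel=1e-12
                ), (name, roi_index)


class TestClosedForms:
    def test_constant_roi_horizontal(self):
        """w x h constant window: h runs of length w."""
        w, h, v = 5, 3, 6
        batch = glrlm_all_rois_batch(synth_constant(h, w, v), ROISpec(w, h), DIRECTIONS["H0"])
        t = extract_all_features(batch)
        assert t.values["SRE"][0] == pytest.approx(1 / w**2)
        assert t.values["LRE"][0] == pytest.approx(w**2)
        assert t.values["RP"][0] == pytest.approx(1 / w)
        assert t.values["GLN"][0] == pytest.approx(h)
        assert t.values["RLN"][0] == pytest.approx(h)
        assert t.values["LGRE"][0] == pytest.approx(1 / (v + 1) ** 2)
        assert t.values["HGRE"][0] == pytest.approx((v + 1) ** 2)

    @pytest.mark.parametrize("name", ["H0", "V90"])
    def test_checkerboard_unit_runs_along_axes(self, name):
        """Axis-adjacent checkerboard cells always differ, so every run has
        length 1 (diagonal lines are constant-valued and behave differently)."""
        batch = glrlm_all_rois_batch(
            synth_checkerboard(6, 6, 0, 1), ROISpec(4, 4), DIRECTIONS[name]
        )
        t = extract_all_features(batch)
        for fname in ("RP", "SRE", "LRE"):
            assert np.all(t.values[fname] == 1.0)
        assert np.all(t.values["RLN"] == 16)

    def test_even_checkerboard_gln(self):
        batch = glrlm_all_rois_batch(
            synth_checkerboard(4, 4, 2, 5), ROISpec(4, 4), DIRECTIONS["H0"]
        )
        t = extract_all_features(batch)
        assert t.values["GLN"][0] == pytest.approx(8)  # (N/2)^2 * 2 / N


class TestFeatureInvariants:
    @pytest.fixture()
    def random_table(self):
        img = synth_random(12, 12, 8, seed=11)
        spec = ROISpec(5, 5)
        batch = glrlm_all_rois_batch(img, spec, DIRECTIONS["AD45"])
        return extract_all_features(batch, spec), batch

    def test_bounded_emphasis_features(self, random_table):
        t, _ = random_table
        for name in ("SRE", "LGRE", "SRLGE", "RP"):
            assert np.all(t.values[name] > 0) and np.all(t.values[name] <= 1)
        assert np.all(t.values["LRE"] >= 1)

    def test_sre_lre_bracket_unity(self, random_table):
        t, _ = random_table
        assert np.all(t.values["SRE"] <= 1) and np.all(t.values["LRE"] >= 1)

    def test_nonuniformities_bounded_by_run_total(self, random_table):
        t, batch = random_table
        _, s = roi_denominators(batch)
        for name in ("GLN", "RLN"):
            assert np.all(t.values[name] <= s + 1e-9)
            assert np.all(t.values[name] >= 1)

    def test_exactly_eleven_features_per_roi(self, random_table):
        t, _ = random_table
        df = t.to_frame()
        assert list(df.columns) == ["roi_index"] + list(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 11

    def test_zero_intensity_with_zero_offset_raises(self):
        img = synth_checkerboard(4, 4, 0, 3)
        spec = ROISpec(2, 2, level_offset=0)
        batch = glrlm_all_rois_batch(img, spec, DIRECTIONS["H0"])
        _, s = roi_denominators(batch)
        with pytest.raises(DivisionDomainError):
            weighted_feature(batch, -2, 0, s)
        # non-inverse gray weights remain well defined
        assert np.all(weighted_feature(batch, 2, 0, s) >= 0)


class TestFeatureMaps:
    def test_single_roi_gives_one_by_one_maps(self, worked, spec55):
        batch = glrlm_all_rois_batch(worked.image, spec55, DIRECTIONS["H0"])
        maps = assemble_feature_maps(extract_all_features(batch), (5, 5), spec55)
        assert all(m.shape == (1, 1) for m in maps.maps.values())

    def test_constant_image_rp_map(self):
        img = synth_constant(8, 8, 3)
        spec = ROISpec(4, 4)
        batch = glrlm_all_rois_batch(img, spec, DIRECTIONS["H0"])
        maps = assemble_feature_maps(extract_all_features(batch), (8, 8), spec)
        assert maps.maps["RP"].shape == (5, 5)
        assert np.allclose(maps.maps["RP"], 0.25)

    def test_cells_ordered_by_roi_position(self):
        img = synth_random(2, 3, 4, seed=0)
        spec = ROISpec(2, 2)
        batch = glrlm_all_rois_batch(img, spec, DIRECTIONS["H0"])
        table = extract_all_features(batch)
        maps = assemble_feature_maps(table, (2, 3), spec)
        assert maps.maps["RP"].shape == (1, 2)
        assert maps.maps["RP"][0].tolist() == table.values["RP"].tolist()

    def test_missing_rois_rejected(self, worked, spec55):
        batch = glrlm_all_rois_batch(worked.image, spec55, DIRECTIONS["H0"])
        table = extract_all_features(batch)
        with pytest.raises(CompletenessError):
            assemble_feature_maps(table, (6, 6), spec55)

    def test_log_transform_only_on_request(self):
        img = synth_random(6, 6, 8, seed=3)
        spec = ROISpec(3, 3)
        batch = glrlm_all_rois_batch(img, spec, DIRECTIONS["H0"])
        table = extract_all_features(batch)
        plain = assemble_feature_maps(table, (6, 6), spec)
        logged = assemble_feature_maps(table, (6, 6), spec, log_transform=["LGRE"])
        assert np.allclose(np.log(plain.maps["LGRE"]), logged.maps["LGRE"])
        assert np.allclose(plain.maps["SRE"], logged.maps["SRE"])
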