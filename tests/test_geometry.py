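"""ETDRS ring geometry: chord rule, column weights, ring aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octloc.geometry import (
    ColumnRingWeights,
    ScanGeometry,
    column_ring_weights,
    columns_to_rings,
    ring_stripes,
)


def rasterize_ring_weights(geom: ScanGeometry, slice_index: int, n_samples: int = 10_000) -> np.ndarray:
    """Independent oracle: dense lateral sampling of the concentric discs."""
    d = geom.slice_positions_mm[slice_index]
    radii = np.array(geom.ring_radii_mm)
    edges = geom.column_edges_mm
    w = np.zeros((geom.n_columns, len(radii)))
    for c in range(geom.n_columns):
        xs = np.linspace(edges[c], edges[c + 1], n_samples, endpoint=False)
        r = np.sqrt((xs - geom.fovea_lateral_mm) ** 2 + d**2)
        ring_idx = np.searchsorted(radii, r, side="left")
        for j in range(len(radii)):
            w[c, j] = np.mean(ring_idx == j)
    return w


class TestRingStripes:
    def test_foveal_slice_has_symmetric_stripes(self, centered_geometry):
        layout = ring_stripes(centered_geometry, 0)
        # d=0: half-widths equal the radii 0.5 / 1.5 / 3.0 around x_f = 3
        assert layout.stripes[0] == ((2.5, 3.5),)
        assert layout.stripes[1] == ((1.5, 2.5), (3.5, 4.5))
        assert layout.stripes[2] == ((0.0, 1.5), (4.5, 6.0))

    def test_chord_rule_at_2mm(self, centered_geometry):
        layout = ring_stripes(centered_geometry, 2)  # d = 2.0
        assert layout.stripes[0] == ()
        assert layout.stripes[1] == ()
        (a, b), = layout.stripes[2]
        half = np.sqrt(9.0 - 4.0)
        assert a == pytest.approx(3.0 - half, abs=1e-9)
        assert b == pytest.approx(3.0 + half, abs=1e-9)

    def test_chord_rule_at_1mm(self, centered_geometry):
        layout = ring_stripes(centered_geometry, 1)  # d = 1.0
        assert layout.stripes[0] == ()
        (a, b), = layout.stripes[1]
        assert b - a == pytest.approx(2 * np.sqrt(1.25), abs=1e-9)
        left, right = layout.stripes[2]
        assert left[0] == pytest.approx(3.0 - np.sqrt(8.0), abs=1e-9)
        assert left[1] == pytest.approx(3.0 - np.sqrt(1.25), abs=1e-9)
        assert right == pytest.approx((3.0 + np.sqrt(1.25), 3.0 + np.sqrt(8.0)), abs=1e-9)

    def test_out_of_range_slice_raises(self, centered_geometry):
        with pytest.raises(IndexError):
            ring_stripes(centered_geometry, 99)

    def test_distant_slice_has_no_stripes(self, centered_geometry):
        layout = ring_stripes(centered_geometry, 3)  # d = 3.5 >= 3.0
        assert all(s == () for s in layout.stripes)


class TestColumnRingWeights:
    def test_column_inside_central_disc(self, centered_geometry):
        w = column_ring_weights(centered_geometry, 0).w
        # column 7 covers [2.625, 3.0) mm, wholly inside the 1 mm ring
        assert w[7] == pytest.approx([1.0, 0.0, 0.0])

    def test_column_split_between_rings(self, centered_geometry):
        w = column_ring_weights(centered_geometry, 0).w
        # column 6 covers [2.25, 2.625): 0.125 mm inside ring 1 of 0.375 mm
        assert w[6] == pytest.approx([1 / 3, 2 / 3, 0.0])

    def test_distant_slice_all_zero(self, centered_geometry):
        w = column_ring_weights(centered_geometry, 3).w
        assert np.all(w == 0)

    @pytest.mark.parametrize("slice_index", [0, 1, 2])
    def test_against_rasterization_oracle(self, centered_geometry, slice_index):
        w = column_ring_weights(centered_geometry, slice_index).w
        ref = rasterize_ring_weights(centered_geometry, slice_index)
        assert np.abs(w - ref).max() < 1e-3

    def test_random_geometries_against_oracle(self, rng):
        for _ in range(25):
            n_cols = int(rng.integers(4, 24))
            width = float(rng.uniform(4.0, 9.0))
            n_slices = 5
            positions = tuple(rng.uniform(-3.2, 3.2, size=n_slices))
            fovea = float(rng.uniform(0.3, 0.7) * width)
            geom = ScanGeometry(
                scan_width_mm=width,
                slice_positions_mm=positions,
                fovea_lateral_mm=fovea,
                n_columns=n_cols,
            )
            s = int(rng.integers(0, n_slices))
            w = column_ring_weights(geom, s).w
            ref = rasterize_ring_weights(geom, s)
            assert np.abs(w - ref).max() < 1e-3

    def test_weight_conservation_inside_outer_disc(self, centered_geometry):
        # sum over rings = fraction of the column inside the 6 mm disc
        for s in range(3):
            w = column_ring_weights(centered_geometry, s).w
            ref = rasterize_ring_weights(centered_geometry, s)
            assert np.abs(w.sum(axis=1) - ref.sum(axis=1)).max() < 1e-3
            assert np.all(w.sum(axis=1) <= 1 + 1e-9)

    def test_mirror_symmetry_of_weights(self, centered_geometry):
        for s in range(4):
            w = column_ring_weights(centered_geometry, s).w
            assert np.allclose(w, w[::-1], atol=1e-12)


class TestColumnsToRings:
    def test_zero_probs_give_zero_rings(self, centered_geometry):
        w = column_ring_weights(centered_geometry, 0)
        rp = columns_to_rings(w, np.zeros((16, 2)))
        assert np.all(rp.probabilities[rp.valid] == 0)
        assert rp.valid.all()

    def test_single_hot_column_passes_through(self, centered_geometry):
        w = column_ring_weights(centered_geometry, 0)
        probs = np.zeros((16, 2))
        probs[7, 0] = 0.9  # column 7 fully inside ring 1
        rp = columns_to_rings(w, probs)
        assert rp.probabilities[0, 0] == pytest.approx(0.9)

    def test_weighted_max_rule(self):
        w = ColumnRingWeights(w=np.array([[0.5], [1.0]]), slice_index=0)
        rp = columns_to_rings(w, np.array([[1.0], [0.4]]))
        assert rp.probabilities[0, 0] == pytest.approx(0.5)

    def test_invalid_ring_is_nan(self, centered_geometry):
        w = column_ring_weights(centered_geometry, 2)  # d=2: rings 1,2 absent
        rp = columns_to_rings(w, np.full((16, 2), 0.7))
        assert not rp.valid[0] and not rp.valid[1] and rp.valid[2]
        assert np.isnan(rp.probabilities[0, 0])

    def test_rejects_probabilities_outside_unit_interval(self, centered_geometry):
        w = column_ring_weights(centered_geometry, 0)
        with pytest.raises(ValueError):
            columns_to_rings(w, np.full((16, 2), 1.5))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_mirror_symmetry_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        geom = ScanGeometry(scan_width_mm=6.0, slice_positions_mm=(float(rng.uniform(-3, 3)),), n_columns=16)
        w = column_ring_weights(geom, 0)
        probs = rng.uniform(0, 1, size=(16, 2))
        rp = columns_to_rings(w, probs)
        flipped = columns_to_rings(w, probs[::-1])
        assert np.allclose(
            np.nan_to_num(rp.probabilities), np.nan_to_num(flipped.probabilities), atol=1e-12
        )
        # raising one column probability never lowers any ring probability
        c = int(rng.integers(0, 16))
        probs2 = probs.copy()
        probs2[c] = np.minimum(1.0, probs2[c] + rng.uniform(0, 1 - probs2[c].max()))
        rp2 = columns_to_rings(w, probs2)
        assert np.all(np.nan_to_num(rp2.probabilities) >= np.nan_to_num(rp.probabilities) - 1e-12)


class TestGeometryIO:
    def test_yaml_roundtrip(self, tmp_path, centered_geometry):
        path = tmp_path / "geom.yaml"
        centered_geometry.to_file(path)
        back = ScanGeometry.from_file(path)
        assert back == centered_geometry

    def test_implicit_centered_positions(self):
        geom = ScanGeometry.from_mapping(
            {"scan_width_mm": 6.0, "n_slices": 5, "slice_spacing_um": 500.0, "centered": True}
        )
        assert geom.slice_positions_mm == (-1.0, -0.5, 0.0, 0.5, 1.0)

    def test_invalid_ring_diameters_rejected(self):
        with pytest.raises(ValueError):
            ScanGeometry(scan_width_mm=6.0, slice_positions_mm=(0.0,), ring_diameters_mm=(3.0, 1.0))
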