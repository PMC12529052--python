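"""Synthetic leaf generator: determinism, placement statistics, geometry."""

import numpy as np
import pytest

import stomagrid as sg
from stomagrid.synthetic import _plantable_rows, exclusion_raster


def small_spec(**kw):
    base = dict(width_mm=2.0, height_mm=2.0, seed=0)
    base.update(kw)
    return sg.SyntheticLeafSpec(**base)


class TestGenerate:
    def test_zero_density_gives_empty_truth(self):
        img, truth = sg.generate_leaf_image(
            small_spec(base_density_mm2=0.0, tip_density_mm2=0.0)
        )
        assert len(truth) == 0
        # no dark ellipses: the only sub-background structure is veins/border
        assert img.pixels.shape == small_spec().shape

    def test_seeded_determinism(self):
        spec = small_spec(seed=5)
        img1, t1 = sg.generate_leaf_image(spec)
        img2, t2 = sg.generate_leaf_image(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1.records.equals(t2.records)
        assert np.array_equal(t1.exclusion, t2.exclusion)

    def test_different_seed_differs(self):
        img1, _ = sg.generate_leaf_image(small_spec(seed=1))
        img2, _ = sg.generate_leaf_image(small_spec(seed=2))
        assert not np.array_equal(img1.pixels, img2.pixels)

    def test_image_shape_and_dtype(self):
        spec = small_spec()
        img, _ = sg.generate_leaf_image(spec)
        assert img.pixels.shape == spec.shape
        assert img.pixels.dtype == np.uint16
        assert img.pixels.max() <= 65535
        img8, _ = sg.generate_leaf_image(small_spec(bit_depth=8))
        assert img8.pixels.dtype == np.uint8

    def test_centroids_inside_bounds_and_outside_exclusion(self):
        spec = small_spec(base_density_mm2=80, tip_density_mm2=80, seed=3)
        img, truth = sg.generate_leaf_image(spec)
        xy = truth.centroids_um
        assert len(xy) > 0
        assert (xy[:, 0] > 0).all() and (xy[:, 0] < img.width_um).all()
        assert (xy[:, 1] > 0).all() and (xy[:, 1] < img.height_um).all()
        px = spec.pixel_size_um
        on_excl = truth.exclusion[
            (xy[:, 1] / px).astype(int), (xy[:, 0] / px).astype(int)
        ]
        assert not on_excl.any()

    def test_no_two_stomata_overlap(self):
        spec = small_spec(base_density_mm2=90, tip_density_mm2=90, seed=4)
        _, truth = sg.generate_leaf_image(spec)
        df = truth.records
        for _, row_df in df.groupby("row_index"):
            x = np.sort(row_df.centroid_x_um.to_numpy())
            assert (np.diff(x) >= spec.stoma_major_um).all()
        # different rows are separated by at least one file spacing > minor axis
        ys = np.sort(df.centroid_y_um.unique())
        if len(ys) > 1:
            assert np.diff(ys).min() >= spec.file_spacing_um - 1e-9

    def test_poisson_count_oracle_over_seeds(self):
        """Mean rendered count over 20 seeds matches the analytic expectation
        within 4 Poisson standard deviations of the total."""
        total_expected = 0.0
        total_observed = 0
        for seed in range(20):
            spec = small_spec(base_density_mm2=70, tip_density_mm2=70, seed=seed)
            _, truth = sg.generate_leaf_image(spec)
            total_observed += len(truth)
            total_expected += sg.expected_count_field(spec).sum()
        assert abs(total_observed - total_expected) < 4 * np.sqrt(total_expected)

    def test_cellwise_counts_match_expectation(self):
        """Per-cell mean over 30 seeds within 3 standard errors of the
        analytic count field (hard-core renewal variance <= Poisson)."""
        spec0 = small_spec(base_density_mm2=60, tip_density_mm2=90)
        expected = sg.expected_count_field(spec0)
        nseeds = 30
        counts = np.zeros_like(expected)
        cell_um = 1000.0
        for seed in range(nseeds):
            _, truth = sg.generate_leaf_image(small_spec(
                base_density_mm2=60, tip_density_mm2=90, seed=100 + seed))
            xy = truth.centroids_um
            cx = np.minimum((xy[:, 0] / cell_um).astype(int), expected.shape[1] - 1)
            cy = np.minimum((xy[:, 1] / cell_um).astype(int), expected.shape[0] - 1)
            np.add.at(counts, (cy, cx), 1)
        mean = counts / nseeds
        se = np.sqrt(np.maximum(expected, 1e-9) / nseeds)
        cells = expected > 5  # cells with real placement mass
        assert cells.any()
        assert (np.abs(mean - expected)[cells] <= 3 * se[cells]).all()


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(width_mm=0.0),
            dict(stoma_intensity_frac=1.0),
            dict(base_density_mm2=-5.0),
            dict(stoma_major_um=3000.0, width_mm=2.0),
            dict(file_spacing_um=10.0),
            dict(base_density_mm2=500.0, tip_density_mm2=500.0),  # infeasible spacing
            dict(base_density_mm2=0.0, tip_density_mm2=60.0),  # gradient touching zero
        ],
    )
    def test_degenerate_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_spec(**kw).validate()

    def test_detectable_area_gate(self):
        with pytest.raises(ValueError, match="detectable"):
            small_spec(stoma_major_um=30.0, stoma_minor_um=15.0).validate(detectable=True)
        small_spec(stoma_major_um=30.0, stoma_minor_um=15.0).validate(detectable=False)


class TestExpectedFields:
    def test_flat_gradient_constant_field(self):
        spec = small_spec(base_density_mm2=60, tip_density_mm2=60)
        field = sg.expected_density_field(spec)
        assert np.allclose(field[field > 0], 60.0)

    def test_linear_midpoint(self):
        spec = sg.SyntheticLeafSpec(
            width_mm=4.0, height_mm=2.0, base_density_mm2=40, tip_density_mm2=62, seed=0
        )
        field = sg.expected_density_field(spec)
        # mid-leaf (x = 2 mm) lies between the two central cell columns
        mid = 0.5 * (field[0, 1] + field[0, 2])
        assert mid == pytest.approx(51.0)

    def test_count_field_matches_monte_carlo(self):
        """sum(expected counts) ~ mean rendered count over 50 seeds."""
        spec0 = small_spec(base_density_mm2=50, tip_density_mm2=80)
        expected_total = sg.expected_count_field(spec0).sum()
        counts = [
            len(sg.generate_leaf_image(small_spec(
                base_density_mm2=50, tip_density_mm2=80, seed=s))[1])
            for s in range(50)
        ]
        se = np.sqrt(expected_total / len(counts))
        assert abs(np.mean(counts) - expected_total) < 4 * se

    def test_count_field_consistent_with_density_field(self):
        """Counts integrate density over the plantable row geometry."""
        spec = small_spec(base_density_mm2=70, tip_density_mm2=70)
        cf = sg.expected_count_field(spec)
        n_rows = len(_plantable_rows(spec))
        # total = d * (rows * spacing * usable length) in mm^2
        from stomagrid.synthetic import _row_x_extent

        x_lo, x_hi = _row_x_extent(spec)
        plantable_mm2 = n_rows * spec.file_spacing_um * (x_hi - x_lo) / 1e6
        assert cf.sum() == pytest.approx(70.0 * plantable_mm2, rel=1e-9)


class TestExclusionRaster:
    def test_border_and_veins_marked(self):
        spec = small_spec()
        excl = exclusion_raster(spec)
        assert excl[0, 0] and excl[-1, -1]  # border frame
        H = excl.shape[0]
        assert excl[H // 2, excl.shape[1] // 2] or excl.any(axis=1).sum() > 2 * int(
            spec.border_um / spec.pixel_size_um
        )

    def test_ground_truth_io_roundtrip(self, tmp_path, small_leaf):
        _, _, truth = small_leaf
        p = tmp_path / "truth.csv"
        truth.to_csv(p)
        import pandas as pd

        back = pd.read_csv(p)
        assert len(back) == len(truth)
        assert np.allclose(back.centroid_x_um, truth.records.centroid_x_um)
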