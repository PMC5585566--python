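import numpy as np
import pytest

from octeb.phantom import (
    BoundaryTrace,
    PhantomSpec,
    add_speckle,
    generate_boundaries,
    make_phantom,
    rasterize_ground_truth,
    render_bscan,
)


class TestSpecValidation:
    def test_rejects_non_increasing_depths(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PhantomSpec(mean_depths=(50.0, 40.0), layer_intensities=(0.1, 0.5, 0.9))

    def test_rejects_wrong_intensity_count(self):
        with pytest.raises(ValueError, match="n_boundaries \\+ 1"):
            PhantomSpec(mean_depths=(40.0, 80.0), layer_intensities=(0.1, 0.5))

    def test_rejects_infeasible_min_gap(self):
        with pytest.raises(ValueError, match="min_gap"):
            PhantomSpec(
                mean_depths=(40.0, 44.0),
                layer_intensities=(0.1, 0.5, 0.9),
                min_gap=10.0,
            )

    def test_rejects_depths_outside_image(self):
        with pytest.raises(ValueError, match="within"):
            PhantomSpec(height=100, mean_depths=(20.0, 120.0),
                        layer_intensities=(0.1, 0.5, 0.9))


class TestGenerateBoundaries:
    def test_zero_amplitude_gives_constant_traces(self):
        spec = PhantomSpec(undulation_amplitude=0.0)
        for trace, depth in zip(generate_boundaries(spec), spec.mean_depths):
            assert np.all(trace.rows == depth)

    def test_deterministic_given_seed(self):
        spec = PhantomSpec(seed=11)
        a = generate_boundaries(spec)
        b = generate_boundaries(spec)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.rows, tb.rows)

    def test_min_gap_respected_per_column(self):
        spec = PhantomSpec(
            height=200,
            mean_depths=(20.0, 50.0, 80.0, 110.0, 140.0, 170.0),
            undulation_amplitude=5.0,
            min_gap=10.0,
            seed=4,
        )
        rows = np.stack([t.rows for t in generate_boundaries(spec)])
        gaps = np.diff(rows, axis=0)
        assert gaps.min() >= 10.0 - 1e-9

    def test_amplitude_bound(self):
        spec = PhantomSpec(undulation_amplitude=4.0, seed=2)
        for trace, depth in zip(generate_boundaries(spec), spec.mean_depths):
            # projection can move a trace, but the raw perturbation is bounded
            assert np.max(np.abs(trace.rows - depth)) <= 4.0 + spec.min_gap


class TestRenderBscan:
    def test_single_boundary_definition(self):
        trace = BoundaryTrace("b", np.full(7, 10.0))
        img = render_bscan([trace], [0.8, 0.2], (20, 7))
        assert np.all(img[:10] == 0.8)
        assert np.all(img[10:] == 0.2)

    def test_zero_boundaries_constant(self):
        img = render_bscan([], [0.5], (5, 9))
        assert np.all(img == 0.5)

    def test_six_boundaries_seven_values(self):
        spec = PhantomSpec(seed=1)
        traces = generate_boundaries(spec)
        img = render_bscan(traces, spec.layer_intensities, (spec.height, spec.width))
        assert len(np.unique(img)) == 7

    def test_intensity_count_error(self):
        trace = BoundaryTrace("b", np.full(5, 10.0))
        with pytest.raises(ValueError, match="length 2"):
            render_bscan([trace], [0.8, 0.2, 0.1], (20, 5))


class TestAddSpeckle:
    def test_large_looks_limit(self):
        img = np.full((50, 50), 0.4)
        out = add_speckle(img, looks=1e6, seed=0)
        assert np.max(np.abs(out - img)) < 0.01

    def test_zero_image_stays_zero(self):
        out = add_speckle(np.zeros((10, 10)), looks=4, seed=0)
        assert np.all(out == 0)

    def test_gamma_moments(self):
        # unit-mean gamma with L looks: mean preserved, variance I^2 / L
        img = np.full((250, 400), 0.5)
        out = add_speckle(img, looks=4, seed=123)
        n = out.size
        se_mean = 0.25 / np.sqrt(n)
        assert abs(out.mean() - 0.5) < 3 * se_mean
        # Var(s^2) ~ (mu4 - sigma^4)/n for the scaled gamma
        mu4 = (3 / 16 + 6 / 64) * 0.5**4
        se_var = np.sqrt((mu4 - 0.0625**2) / n)
        assert abs(out.var(ddof=1) - 0.25 / 4) < 3 * se_var

    def test_invalid_looks(self):
        with pytest.raises(ValueError):
            add_speckle(np.zeros((2, 2)), looks=0, seed=0)


class TestRasterize:
    def test_single_constant_trace(self):
        gt = rasterize_ground_truth([BoundaryTrace("b", np.full(5, 10.0))], (20, 5))
        rows, cols = np.nonzero(gt.edge_mask)
        assert rows.tolist() == [10] * 5
        assert gt.edge_mask.sum() == 5

    def test_roi_is_inclusive_band(self):
        traces = [BoundaryTrace("a", np.full(4, 10.0)), BoundaryTrace("b", np.full(4, 20.0))]
        gt = rasterize_ground_truth(traces, (30, 4))
        assert np.all(gt.roi_mask.sum(axis=0) == 11)

    def test_half_up_rounding(self):
        gt = rasterize_ground_truth([BoundaryTrace("b", np.full(3, 10.5))], (20, 3))
        assert set(np.nonzero(gt.edge_mask)[0]) == {11}

    def test_crossing_error_names_column(self):
        traces = [
            BoundaryTrace("a", np.array([5.0, 5.0, 12.0])),
            BoundaryTrace("b", np.array([10.0, 10.0, 10.0])),
        ]
        with pytest.raises(ValueError, match="column 2"):
            rasterize_ground_truth(traces, (20, 3))


class TestPhantomInvariants:
    @pytest.mark.parametrize("seed", [0, 5])
    def test_edge_pixel_count(self, seed):
        spec = PhantomSpec(seed=seed)
        _, gt = make_phantom(spec)
        assert gt.edge_mask.sum() == spec.n_boundaries * spec.width
        # exactly one edge pixel per trace per column
        assert np.all(gt.edge_mask.sum(axis=0) == spec.n_boundaries)

    def test_roi_column_heights(self):
        spec = PhantomSpec(seed=8)
        _, gt = make_phantom(spec)
        ilm = gt.traces[0].rounded()
        rpe = gt.traces[-1].rounded()
        assert np.all(gt.roi_mask.sum(axis=0) == rpe - ilm + 1)

    def test_render_rasterize_consistency(self):
        """Every ground-truth edge pixel sits where its column's intensity
        changes (or at the first row of the band)."""
        spec = PhantomSpec(seed=9)
        traces = generate_boundaries(spec)
        clean = render_bscan(traces, spec.layer_intensities, (spec.height, spec.width))
        gt = rasterize_ground_truth(traces, (spec.height, spec.width))
        rows, cols = np.nonzero(gt.edge_mask)
        assert np.all(rows > 0)
        assert np.all(clean[rows, cols] != clean[rows - 1, cols])
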