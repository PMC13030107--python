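"""Generator tests: templates, sampled spectra, scenes and mosaicking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluorocold import msfa_cube, synthetic_data
from fluorocold.synthetic_data import (
    SceneSpec,
    SpectrumModel,
    class_template,
    default_wavelengths,
    mosaic,
    render_scene,
    sample_spectra,
)


class TestClassTemplate:
    @pytest.mark.parametrize("amplitudes", [(3.0, 2.0, 1.0), (5.0, 1.2, 0.3), (2.0, 1.9, 1.8)])
    def test_amplitude_ordering_forces_pointwise_ordering(self, amplitudes):
        model = SpectrumModel(class_amplitudes=amplitudes)
        t0, t1, t2 = (class_template(model, c) for c in (0, 1, 2))
        assert np.all(t0 >= t1) and np.all(t1 >= t2)

    def test_flat_gaussian_limit_is_twice_amplitude(self):
        model = SpectrumModel(peak_widths=(1e7, 1e7))
        for label in (0, 1, 2):
            expected = model.class_amplitudes[label] * 2
            assert class_template(model, label) == pytest.approx(expected, rel=1e-6)

    def test_single_peak_argmax_matches_exhaustive_scan(self):
        # both peaks collapsed onto 679 nm act as a single narrow peak
        model = SpectrumModel(peak_centers=(679.0, 679.0), peak_widths=(10.0, 10.0))
        template = class_template(model, 0)
        best, best_val = 0, -np.inf
        for i in range(25):  # brute-force argmax oracle
            if template[i] > best_val:
                best, best_val = i, template[i]
        assert int(np.argmax(template)) == best
        assert best == int(np.argmin(np.abs(model.wavelengths - 679.0)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            class_template(SpectrumModel(), 3)

    def test_amplitudes_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            SpectrumModel(class_amplitudes=(1.0, 2.0, 3.0))


class TestSampleSpectra:
    def test_zero_noise_reproduces_templates_exactly(self):
        model = SpectrumModel(noise_sd=0.0, sample_cv=0.0)
        ds = sample_spectra(model, n_per_class=4)
        for c in (0, 1, 2):
            assert np.array_equal(ds.X[ds.y == c], np.tile(class_template(model, c), (4, 1)))

    def test_same_seed_is_bit_identical(self):
        a = sample_spectra(SpectrumModel(seed=5), 20)
        b = sample_spectra(SpectrumModel(seed=5), 20)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_class_means_converge_to_analytic_mean(self):
        """Law of large numbers at n=1000 under the default noise model.

        The analytic mean of the zero-clipped process is computed
        independently by quadrature: conditional on the log-normal factor f,
        E[max(0, f*t + e)] = mu*Phi(mu/sigma) + sigma*phi(mu/sigma) with
        mu = f*t, integrated over f by Gauss-Hermite.  Away from zero this
        reduces to the template itself (mean-1 factor, mean-0 noise); near
        zero, clipping adds a small positive bias the oracle accounts for.
        Every band mean must sit within 2% of the template's peak intensity.
        """
        from scipy.stats import norm

        model = SpectrumModel(seed=3)
        ds = sample_spectra(model, n_per_class=1000)
        sigma2 = np.log1p(model.sample_cv**2)
        nodes, weights = np.polynomial.hermite_e.hermegauss(40)
        factors = np.exp(-sigma2 / 2 + np.sqrt(sigma2) * nodes)
        weights = weights / weights.sum()
        s = model.noise_sd
        for c in (0, 1, 2):
            template = class_template(model, c)
            mu = factors[:, None] * template[None, :]
            clipped_mean = (weights[:, None] * (
                mu * norm.cdf(mu / s) + s * norm.pdf(mu / s))).sum(axis=0)
            gap = np.abs(ds.X[ds.y == c].mean(axis=0) - clipped_mean)
            assert gap.max() <= 0.02 * template.max()


class TestRenderScene:
    def test_full_frame_polygon_labels_everything(self):
        spec = SceneSpec(8, 9, [(np.array([[0, 0], [0, 9], [8, 9], [8, 0]]), 0)])
        _, labels = render_scene(spec, SpectrumModel())
        assert np.all(labels == 0)

    def test_empty_scene_is_all_background(self):
        cube, labels = render_scene(SceneSpec(5, 6), SpectrumModel())
        assert np.all(labels == -1)
        assert np.all(cube.values == SceneSpec(5, 6).background_level)

    def test_rectangle_pixel_counts_match_scanline_oracle(self):
        r1 = np.array([[1.5, 1.5], [1.5, 6.5], [4.5, 6.5], [4.5, 1.5]])
        r2 = np.array([[6.5, 2.5], [6.5, 9.5], [9.5, 9.5], [9.5, 2.5]])
        spec = SceneSpec(12, 12, [(r1, 0), (r2, 2)])
        _, labels = render_scene(spec, SpectrumModel(noise_sd=0, sample_cv=0))

        def rasterize(poly, h, w):  # independent per-pixel crossing-count fill
            count = 0
            for rr in range(h):
                for cc in range(w):
                    hits = 0
                    n = len(poly)
                    for k in range(n):
                        y1, x1 = poly[k]
                        y2, x2 = poly[(k + 1) % n]
                        if (y1 > rr) != (y2 > rr):
                            if cc < x1 + (rr - y1) / (y2 - y1) * (x2 - x1):
                                hits += 1
                    count += hits % 2
            return count

        assert (labels == 0).sum() == rasterize(r1, 12, 12)
        assert (labels == 2).sum() == rasterize(r2, 12, 12)

    def test_overlapping_polygons_rejected(self):
        tri = np.array([[1, 1], [1, 8], [8, 4]])
        spec = SceneSpec(10, 10, [(tri, 0), (tri + 0.5, 1)])
        with pytest.raises(ValueError, match="overlap"):
            render_scene(spec, SpectrumModel())

    def test_saturation_fraction_forces_sensor_max(self):
        spec = SceneSpec(10, 10, saturation_fraction=0.25)
        cube, _ = render_scene(spec, SpectrumModel())
        n_sat = (cube.values == 2**16 - 1).all(axis=2).sum()
        assert n_sat == 25


class TestMosaic:
    def test_single_cell_cube_fills_tile_in_layout_order(self):
        cube = msfa_cube.Hypercube(
            np.arange(25, dtype=float).reshape(1, 1, 25), default_wavelengths()
        )
        frame = mosaic(cube, offsets=(0, 0))
        assert frame.shape == (5, 5)
        assert np.array_equal(frame.values, np.arange(25.0).reshape(5, 5))

    def test_frame_indices_match_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        cube = msfa_cube.Hypercube(rng.uniform(0, 100, (4, 3, 25)), default_wavelengths())
        layout = msfa_cube.default_layout()
        frame = mosaic(cube, offsets=(2, 1))
        for i in range(4):
            for j in range(3):
                for b in range(25):
                    r, c = layout[b]
                    assert frame.values[1 + 5 * i + r, 2 + 5 * j + c] == cube.values[i, j, b]

    def test_non_bijective_layout_rejected(self):
        layout = msfa_cube.default_layout()
        layout[1] = layout[0]
        cube = msfa_cube.Hypercube(np.zeros((2, 2, 25)), default_wavelengths())
        with pytest.raises(ValueError, match="bijection"):
            mosaic(cube, layout=layout)

    @settings(max_examples=25, deadline=None)
    @given(
        rows=st.integers(1, 6), cols=st.integers(1, 6),
        ox=st.integers(0, 4), oy=st.integers(0, 4),
        seed=st.integers(0, 1000),
    )
    def test_mosaic_demosaic_round_trip_is_exact(self, rows, cols, ox, oy, seed):
        rng = np.random.default_rng(seed)
        cube = msfa_cube.Hypercube(
            rng.uniform(0, 1000, (rows, cols, 25)), default_wavelengths()
        )
        frame = mosaic(cube, offsets=(ox, oy))
        back = msfa_cube.demosaic(frame, offset_x=ox, offset_y=oy)
        assert np.array_equal(back.values, cube.values)
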