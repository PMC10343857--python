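"""2D-COS math: dynamic spectra, Hilbert–Noda, map symmetries, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ir2dcos import (
    Band,
    PerturbationParams,
    Spectrum,
    TwoDCosTransformer,
    asynchronous_map,
    build_perturbation_series,
    compute_all,
    hilbert_noda,
    integrative_map,
    make_dynamic,
    synchronous_map,
)


def _sync_oracle(dyn: np.ndarray) -> np.ndarray:
    """Explicit double loop over wavenumber pairs (reference for Eq.-form)."""
    n, g = dyn.shape
    out = np.empty((g, g))
    for a in range(g):
        for b in range(g):
            out[a, b] = sum(dyn[i, a] * dyn[i, b] for i in range(n)) / (n - 1)
    return out


def _async_oracle(dyn: np.ndarray) -> np.ndarray:
    n, g = dyn.shape
    nod = hilbert_noda(n)
    out = np.empty((g, g))
    for a in range(g):
        for b in range(g):
            out[a, b] = sum(
                dyn[j, a] * nod[j, k] * dyn[k, b]
                for j in range(n) for k in range(n)
            ) / (n - 1)
    return out


class TestPerturbationSeries:
    def test_vanishing_amplitude_limit(self):
        s = Spectrum(np.array([4.0, 3.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        series = build_perturbation_series(s, PerturbationParams(amplitude=1e-12))
        np.testing.assert_allclose(series, np.tile(s.intensities, (16, 1)), atol=1e-9)

    def test_flat_unit_spectrum_hand_values(self):
        s = Spectrum(np.array([4.0, 3.0, 2.0, 1.0]), np.ones(4))
        series = build_perturbation_series(
            s, PerturbationParams(n_steps=4, amplitude=0.1, cycles=1.0)
        )
        expected = 1.0 + 0.1 * np.sin([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        for col in range(4):
            np.testing.assert_allclose(series[:, col], expected, atol=1e-12)

    def test_zero_phase_gradient_gives_proportional_columns(self):
        s = Spectrum(np.array([4.0, 3.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        series = build_perturbation_series(s, PerturbationParams(phase_gradient=0.0))
        ratio = series / series[:, :1]
        np.testing.assert_allclose(ratio, np.tile(ratio[0], (16, 1)), atol=1e-12)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            PerturbationParams(n_steps=1)


class TestMakeDynamic:
    def test_constant_series_gives_zero(self):
        d = make_dynamic(np.full((5, 3), 2.5))
        np.testing.assert_array_equal(d.values, 0.0)

    def test_two_step_example(self):
        d = make_dynamic(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(d.values.ravel(), [-1.0, 1.0])
        assert d.reference[0] == 2.0

    def test_columns_mean_center(self, rng):
        d = make_dynamic(rng.normal(size=(9, 14)))
        np.testing.assert_allclose(d.values.mean(axis=0), 0.0, atol=1e-12)


class TestHilbertNoda:
    def test_n3_exact_values(self):
        expected = np.array([
            [0.0, 1 / np.pi, 1 / (2 * np.pi)],
            [-1 / np.pi, 0.0, 1 / np.pi],
            [-1 / (2 * np.pi), -1 / np.pi, 0.0],
        ])
        np.testing.assert_allclose(hilbert_noda(3), expected, atol=1e-15)

    def test_n2_exact_values(self):
        np.testing.assert_allclose(
            hilbert_noda(2), [[0.0, 1 / np.pi], [-1 / np.pi, 0.0]], atol=1e-15
        )

    @pytest.mark.parametrize("n", [2, 5, 16, 64])
    def test_antisymmetric(self, n):
        m = hilbert_noda(n)
        np.testing.assert_array_equal(m + m.T, np.zeros((n, n)))

    def test_n1_rejected(self):
        with pytest.raises(ValueError):
            hilbert_noda(1)


class TestMaps:
    def test_single_variable_two_steps(self):
        d = make_dynamic(np.array([[1.0], [3.0]]))  # dynamic (-1, +1)
        assert synchronous_map(d)[0, 0] == pytest.approx(2.0)

    def test_sync_matches_loop_oracle(self, rng):
        d = make_dynamic(rng.normal(size=(5, 6)))
        np.testing.assert_allclose(synchronous_map(d), _sync_oracle(d.values),
                                   atol=1e-10)

    def test_async_matches_loop_oracle(self, rng):
        d = make_dynamic(rng.normal(size=(5, 6)))
        np.testing.assert_allclose(asynchronous_map(d), _async_oracle(d.values),
                                   atol=1e-10)

    def test_symmetry_suite_on_random_inputs(self, rng):
        """Sync symmetric PSD, async antisymmetric zero-diagonal, I = -I^T."""
        for _ in range(50):
            n = int(rng.integers(3, 12))
            g = int(rng.integers(2, 9))
            d = make_dynamic(rng.normal(size=(n, g)))
            sync = synchronous_map(d)
            asyn = asynchronous_map(d)
            integ = integrative_map(sync, asyn)
            np.testing.assert_allclose(sync, sync.T, atol=1e-10)
            assert np.all(np.diag(sync) >= 0)
            assert np.min(np.linalg.eigvalsh(sync)) >= -1e-10
            np.testing.assert_allclose(asyn, -asyn.T, atol=1e-10)
            np.testing.assert_allclose(np.diag(asyn), 0.0, atol=1e-10)
            np.testing.assert_allclose(integ, -integ.T, atol=1e-10)

    def test_integrative_hand_example(self):
        sync = np.array([[1.0, 2.0], [2.0, 4.0]])
        asyn = np.array([[0.0, 3.0], [-3.0, 0.0]])
        np.testing.assert_array_equal(
            integrative_map(sync, asyn), [[0.0, 6.0], [-6.0, 0.0]]
        )

    def test_zero_async_gives_zero_integrative(self, rng):
        sync = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(integrative_map(sync, np.zeros((4, 4))), 0.0)

    def test_sinusoid_phase_law(self):
        """Cross-peaks of two pure sinusoids follow the cos/sin phase law.

        Sync cross-peaks equal A1*A2*cos(dphi)/2 (up to the n/(n-1)
        sampling factor); async cross-peaks are proportional to
        A1*A2*sin(dphi), the proportionality constant being the discrete
        Hilbert–Noda kernel's gain at the perturbation frequency.
        """
        n = 64
        t = 2 * np.pi * np.arange(n) / n
        a1, a2 = 1.3, 0.8
        offsets = [0.0, np.pi / 4, np.pi / 2]
        sync, asyn = {}, {}
        for dphi in offsets:
            d = make_dynamic(np.stack([a1 * np.sin(t), a2 * np.sin(t + dphi)], axis=1))
            sync[dphi] = synchronous_map(d)[0, 1]
            asyn[dphi] = asynchronous_map(d)[0, 1]
        scale = n / (n - 1) / 2  # discrete sum over whole cycles
        for dphi in offsets:
            assert sync[dphi] == pytest.approx(
                a1 * a2 * np.cos(dphi) * scale, abs=0.02 * a1 * a2
            )
        # async gain estimated at quadrature, where |async| is maximal
        # and sync vanishes
        gain = asyn[np.pi / 2]
        assert abs(sync[np.pi / 2]) < 0.02 * a1 * a2
        assert abs(asyn[0.0]) < 0.02 * abs(gain)
        for dphi in offsets:
            assert asyn[dphi] == pytest.approx(
                gain * np.sin(dphi), abs=0.02 * abs(gain)
            )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    series=arrays(
        np.float64,
        st.tuples(st.integers(2, 10), st.integers(1, 8)),
        elements=st.floats(-10, 10, allow_nan=False),
    )
)
def test_map_algebra_holds_for_arbitrary_series(series):
    """Property: any perturbation series yields a symmetric PSD sync map
    and an antisymmetric zero-diagonal async map."""
    d = make_dynamic(series)
    sync = synchronous_map(d)
    asyn = asynchronous_map(d)
    scale = max(1.0, np.abs(sync).max())
    np.testing.assert_allclose(sync, sync.T, atol=1e-10 * scale)
    assert np.min(np.linalg.eigvalsh(sync)) >= -1e-9 * scale
    np.testing.assert_allclose(asyn, -asyn.T, atol=1e-10 * scale)
    np.testing.assert_allclose(np.diag(asyn), 0.0, atol=1e-10 * scale)


class TestComputeAll:
    def _spectrum(self):
        grid = 1800.0 - 8.0 * np.arange(60)
        y = np.exp(-0.5 * ((grid - 1500.0) / 40.0) ** 2)
        return Spectrum(grid, y)

    def test_band_grid_carried_through(self):
        maps = compute_all(self._spectrum(), Band(1700.0, 1300.0))
        side = maps.wavenumbers.size
        assert maps.sync.shape == maps.async_.shape == maps.integrative.shape \
            == (side, side)
        assert maps.wavenumbers.min() >= 1300.0

    def test_amplitude_homogeneity(self):
        """Doubling amplitude scales sync/async by 4 and integrative by 16."""
        s = self._spectrum()
        p1 = PerturbationParams(amplitude=0.02, phase_gradient=0.01)
        p2 = PerturbationParams(amplitude=0.04, phase_gradient=0.01)
        m1 = compute_all(s, None, p1)
        m2 = compute_all(s, None, p2)
        np.testing.assert_allclose(m2.sync, 4 * m1.sync, rtol=1e-9)
        np.testing.assert_allclose(m2.async_, 4 * m1.async_, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(m2.integrative, 16 * m1.integrative,
                                   rtol=1e-9, atol=1e-18)

    def test_deterministic(self):
        s = self._spectrum()
        p = PerturbationParams(phase_gradient=0.005)
        m1, m2 = compute_all(s, None, p), compute_all(s, None, p)
        np.testing.assert_array_equal(m1.sync, m2.sync)
        np.testing.assert_array_equal(m1.async_, m2.async_)

    def test_transformer_matches_compute_all(self, small_dataset):
        tf = TwoDCosTransformer(map_type="sync", phase_gradient=0.005)
        tf.fit(small_dataset.spectra, wavenumbers=small_dataset.wavenumbers)
        maps = tf.transform(small_dataset.spectra[:2])
        for i in range(2):
            ref = compute_all(small_dataset[i], None,
                              PerturbationParams(phase_gradient=0.005))
            np.testing.assert_allclose(maps[i], ref.sync, atol=1e-12)
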