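"""Generalized two-dimensional correlation spectroscopy (2D-COS).

A perturbation applied to a sample produces an ordered series of spectra
:math:`y(v, t_1), \\dots, y(v, t_n)`.  Subtracting the per-wavenumber mean
reference :math:`\\bar y(v)` gives the *dynamic spectra*
:math:`\\tilde y(v, t_i) = y(v, t_i) - \\bar y(v)`.  Correlating dynamic
intensity changes between every pair of wavenumbers yields two square
maps over the grid:

- synchronous map
  :math:`\\Phi(v_1, v_2) = \\frac{1}{n-1} \\sum_i \\tilde y(v_1, t_i)\\,
  \\tilde y(v_2, t_i)` — in-phase covariation; symmetric, non-negative
  diagonal (auto-peaks), positive semidefinite;
- asynchronous map
  :math:`\\Psi(v_1, v_2) = \\frac{1}{n-1}\\, \\tilde y(v_1)^T N \\tilde
  y(v_2)` with the Hilbert–Noda matrix :math:`N_{jk} = 0` for
  :math:`j = k` and :math:`1/(\\pi(k-j))` otherwise — out-of-phase
  (quadrature) covariation; antisymmetric with zero diagonal.

The *integrative* map is the elementwise product :math:`I = \\Phi \\cdot
\\Psi` and is therefore antisymmetric as well.

For a static 1-D spectrum (a single measurement, as in routine FT-IR
fingerprinting) the perturbation series is produced synthetically: the
spectrum is modulated by a sinusoid across ``n_steps`` equally spaced
perturbation steps.  With a wavenumber-dependent phase the modulation is
no longer in phase everywhere and the asynchronous map becomes nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import Band, Spectrum
from .spectra import extract_band

__all__ = [
    "PerturbationParams",
    "DynamicSpectra",
    "CorrelationMaps",
    "build_perturbation_series",
    "make_dynamic",
    "hilbert_noda",
    "synchronous_map",
    "asynchronous_map",
    "integrative_map",
    "compute_all",
    "TwoDCosTransformer",
]


@dataclass(frozen=True)
class PerturbationParams:
    """Sinusoidal perturbation applied to a static spectrum.

    Parameters
    ----------
    n_steps
        Number of equally spaced perturbation steps (rows of the series).
    amplitude
        Relative modulation depth (dimensionless); 0.05 = +/-5%.
    cycles
        Perturbation periods spanned across the ``n_steps`` steps.
    phase_gradient
        Phase advance per cm^-1 across the grid (rad/cm^-1).  Zero means
        every wavenumber is modulated in phase, which makes the
        asynchronous map identically zero; a nonzero gradient is required
        for a non-degenerate asynchronous map.
    additive
        If True the sinusoid is added to the spectrum instead of
        modulating it multiplicatively.
    """

    n_steps: int = 16
    amplitude: float = 0.05
    cycles: float = 1.0
    phase_gradient: float = 0.0
    additive: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.cycles <= 0:
            raise ValueError("cycles must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DynamicSpectra:
    """Mean-centred perturbation series: rows are steps, columns wavenumbers."""

    wavenumbers: np.ndarray
    values: np.ndarray          # n_steps x n_grid, column means == 0
    reference: np.ndarray       # the subtracted mean spectrum

    @property
    def n_steps(self) -> int:
        return int(self.values.shape[0])


@dataclass
class CorrelationMaps:
    """The three square correlation maps over one wavenumber grid."""

    wavenumbers: np.ndarray
    sync: np.ndarray
    async_: np.ndarray
    integrative: np.ndarray

    def by_type(self, map_type: str) -> np.ndarray:
        key = {"sync": "sync", "async": "async_", "integrative": "integrative"}
        if map_type not in key:
            raise ValueError(f"unknown map type {map_type!r}")
        return getattr(self, key[map_type])


def build_perturbation_series(s: Spectrum, params: PerturbationParams) -> np.ndarray:
    """Expand a static spectrum into an n_steps x n_grid perturbation series.

    Row ``i`` (0-based) at grid point ``v`` is
    ``s(v) * (1 + a * sin(2*pi*cycles*i/n + g*(v - v_ref)))`` in the
    default multiplicative mode, with ``v_ref`` the first grid point.
    Deterministic; no randomness involved.
    """
    w = s.wavenumbers
    y = s.intensities
    i = np.arange(params.n_steps)[:, None]
    phase = (
        2.0 * np.pi * params.cycles * i / params.n_steps
        + params.phase_gradient * (w - w[0])[None, :]
    )
    wave = params.amplitude * np.sin(phase)
    if params.additive:
        return y[None, :] + wave
    return y[None, :] * (1.0 + wave)


def make_dynamic(series: np.ndarray, wavenumbers: np.ndarray | None = None) -> DynamicSpectra:
    """Subtract each wavenumber's mean over steps (the reference spectrum)."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    reference = series.mean(axis=0)
    if wavenumbers is None:
        wavenumbers = np.arange(series.shape[1], dtype=float)
    return DynamicSpectra(
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        values=series - reference[None, :],
        reference=reference,
    )


def hilbert_noda(n: int) -> np.ndarray:
    """The n x n Hilbert–Noda matrix: 0 on the diagonal, 1/(pi*(k-j)) off it.

    Antisymmetric; acts as a discrete Hilbert transform across the
    perturbation steps, shifting each Fourier component by 90 degrees.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    j = np.arange(n)
    diff = j[None, :] - j[:, None]          # k - j
    with np.errstate(divide="ignore"):
        m = 1.0 / (np.pi * diff)
    np.fill_diagonal(m, 0.0)
    return m


def synchronous_map(d: DynamicSpectra) -> np.ndarray:
    """Synchronous correlation: (1/(n-1)) * Y^T Y over the step axis."""
    n = d.n_steps
    if n < 2:
        raise ValueError("synchronous map needs at least 2 perturbation steps")
    return d.values.T @ d.values / (n - 1)


def asynchronous_map(d: DynamicSpectra) -> np.ndarray:
    """Asynchronous correlation: (1/(n-1)) * Y^T N Y with N Hilbert–Noda."""
    n = d.n_steps
    if n < 2:
        raise ValueError("asynchronous map needs at least 2 perturbation steps")
    return d.values.T @ hilbert_noda(n) @ d.values / (n - 1)


def integrative_map(sync: np.ndarray, async_: np.ndarray) -> np.ndarray:
    """Integrative correlation: elementwise product of sync and async maps."""
    sync = np.asarray(sync, dtype=float)
    async_ = np.asarray(async_, dtype=float)
    if sync.shape != async_.shape:
        raise ValueError("sync and async maps must have the same shape")
    return sync * async_


def compute_all(
    s: Spectrum,
    band: Band | None = None,
    params: PerturbationParams | None = None,
) -> CorrelationMaps:
    """Band-extract, perturb, mean-centre and compute all three maps."""
    params = params or PerturbationParams()
    if band is not None:
        s = extract_band(s, band)
    series = build_perturbation_series(s, params)
    d = make_dynamic(series, s.wavenumbers)
    sync = synchronous_map(d)
    async_ = asynchronous_map(d)
    return CorrelationMaps(
        wavenumbers=s.wavenumbers.copy(),
        sync=sync,
        async_=async_,
        integrative=integrative_map(sync, async_),
    )


class TwoDCosTransformer(BaseEstimator, TransformerMixin):
    """Transform a samples x wavenumbers matrix into per-sample 2D-COS maps.

    scikit-learn style: stateless apart from recording the grid at fit
    time.  ``transform`` returns an array of shape
    ``(n_samples, n_grid, n_grid)`` holding the requested map type for
    every sample, each sample's spectrum seeding its own perturbation
    series.
    """

    def __init__(
        self,
        map_type: str = "sync",
        n_steps: int = 16,
        amplitude: float = 0.05,
        cycles: float = 1.0,
        phase_gradient: float = 0.0,
        additive: bool = False,
    ):
        self.map_type = map_type
        self.n_steps = n_steps
        self.amplitude = amplitude
        self.cycles = cycles
        self.phase_gradient = phase_gradient
        self.additive = additive

    def _params(self) -> PerturbationParams:
        return PerturbationParams(
            n_steps=self.n_steps,
            amplitude=self.amplitude,
            cycles=self.cycles,
            phase_gradient=self.phase_gradient,
            additive=self.additive,
        )

    def fit(self, X, y=None, wavenumbers: np.ndarray | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.map_type not in ("sync", "async", "integrative"):
            raise ValueError(f"unknown map type {self.map_type!r}")
        self._params()  # validates
        self.n_features_in_ = X.shape[1]
        self.wavenumbers_ = (
            np.asarray(wavenumbers, dtype=float)
            if wavenumbers is not None
            else np.arange(X.shape[1], dtype=float)
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "wavenumbers_"):
            raise RuntimeError("TwoDCosTransformer is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        params = self._params()
        n, g = X.shape
        out = np.empty((n, g, g))
        w = self.wavenumbers_
        # phase matrix is sample-independent; precompute the modulation
        i = np.arange(params.n_steps)[:, None]
        phase = (
            2.0 * np.pi * params.cycles * i / params.n_steps
            + params.phase_gradient * (w - w[0])[None, :]
        )
        wave = params.amplitude * np.sin(phase)
        noda = hilbert_noda(params.n_steps)
        for k in range(n):
            series = X[k][None, :] + wave if params.additive else X[k][None, :] * (1.0 + wave)
            dyn = series - series.mean(axis=0, keepdims=True)
            if self.map_type == "sync":
                out[k] = dyn.T @ dyn / (params.n_steps - 1)
            elif self.map_type == "async":
                out[k] = dyn.T @ noda @ dyn / (params.n_steps - 1)
            else:
                s = dyn.T @ dyn / (params.n_steps - 1)
                a = dyn.T @ noda @ dyn / (params.n_steps - 1)
                out[k] = s * a
        return out
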