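"""Synthetic multi-class FT-IR absorbance spectra.

Real powdered-herb FT-IR fingerprints of closely related species share
their peak positions (the underlying chemistry — O-H/C-H stretches, ester
C=O, lignin ring modes, saccharide C-OH — is common) and differ mainly in
relative peak intensities.  The generator emulates exactly that regime:
every class places peaks at the same ten characteristic wavenumbers and
classes are distinguished by reproducible per-peak amplitude multipliers.
On top of the class template each sample receives multiplicative amplitude
jitter, a small linear baseline drift and i.i.d. Gaussian noise.

All randomness flows from explicit integer seeds; there is no global RNG
state, and identical arguments yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .containers import LabeledSpectrumSet, Spectrum

__all__ = [
    "CHARACTERISTIC_WAVENUMBERS",
    "DEFAULT_GRID",
    "PeakSpec",
    "ClassRecipe",
    "default_recipes",
    "generate_spectrum",
    "generate_dataset",
    "make_grid",
]

#: The ten characteristic absorption maxima (cm^-1) used as shared peak
#: centres: O-H stretch, methylene asym./sym. stretches, ester C=O,
#: terpenoid C-C, lignin ring skeleton (x2), methylene deformation,
#: saccharide C-OH and C-H bending.
CHARACTERISTIC_WAVENUMBERS: tuple[float, ...] = (
    3292.0, 2922.0, 2849.0, 1732.0, 1610.0, 1510.0, 1422.0, 1371.0, 1030.0, 920.0,
)

#: Default acquisition window: 4010 -> 365 cm^-1 at 4 cm^-1 resolution
#: (the noisy tail below 365 cm^-1 is excluded).
DEFAULT_GRID: dict = {"start": 4010.0, "stop": 365.0, "step": 4.0}

# Half-widths (cm^-1) loosely matching condensed-phase IR band widths:
# broad O-H, medium C-H stretches, narrower fingerprint modes.
_DEFAULT_WIDTHS: tuple[float, ...] = (
    120.0, 35.0, 30.0, 20.0, 25.0, 18.0, 18.0, 16.0, 40.0, 25.0,
)
# Base amplitudes (a.u.) before class multipliers.
_DEFAULT_AMPLITUDES: tuple[float, ...] = (
    0.55, 0.40, 0.30, 0.35, 0.45, 0.30, 0.28, 0.25, 0.60, 0.20,
)

#: Between-class spread: sd of the lognormal per-peak amplitude multiplier.
DEFAULT_CLASS_SPREAD = 0.35
#: Within-class spread: sd of per-sample lognormal amplitude jitter.
DEFAULT_SAMPLE_JITTER = 0.08
#: Additive noise sd in absorbance units.
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class PeakSpec:
    """One absorption peak: centre and half-width in cm^-1, amplitude in a.u."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"peak width must be positive, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"peak amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate the unit-free peak profile on a wavenumber grid."""
        x = (np.asarray(grid, dtype=float) - self.center) / self.width
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * x * x)
        return self.amplitude / (1.0 + x * x)


@dataclass
class ClassRecipe:
    """Everything needed to synthesize one class's spectra.

    ``sample_jitter`` is the sd of the per-sample lognormal amplitude
    multiplier (within-class variation); ``center_jitter_sd`` optionally
    wobbles peak positions per sample and is off by default because
    closely related species share peak positions.
    """

    label: str
    peaks: list[PeakSpec] = field(default_factory=list)
    baseline_slope: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    sample_jitter: float = DEFAULT_SAMPLE_JITTER
    center_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a class recipe needs at least one peak")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def to_dict(self) -> dict:
        return asdict(self)


def make_grid(start: float = DEFAULT_GRID["start"],
              stop: float = DEFAULT_GRID["stop"],
              step: float = DEFAULT_GRID["step"]) -> np.ndarray:
    """Descending wavenumber grid from ``start`` down to ``stop``.

    Endpoints are inclusive when they fall on the step lattice; a final
    partial step is dropped, matching instrument convention.  The default
    window yields 912 points (4010, 4006, ..., 366).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start <= stop:
        raise ValueError("grid is stored descending; need start > stop")
    n = int(np.floor((start - stop) / step)) + 1
    return start - step * np.arange(n)


def default_recipes(
    n_classes: int,
    seed: int,
    class_spread: float = DEFAULT_CLASS_SPREAD,
    noise_sd: float = DEFAULT_NOISE_SD,
    sample_jitter: float = DEFAULT_SAMPLE_JITTER,
    shape: str = "gaussian",
) -> list[ClassRecipe]:
    """Build ``n_classes`` recipes sharing the ten characteristic centres.

    Peak positions are identical across classes; each class gets its own
    reproducible lognormal amplitude multiplier per peak, with
    ``class_spread`` controlling how far classes sit apart.  Labels are
    ``"A"``, ``"B"``, ...

    Parameters
    ----------
    n_classes
        Number of classes, 1..26.
    seed
        Seeds the multiplier draw; same (n_classes, seed) gives
        identical recipes.
    class_spread
        Sd of log-amplitude multipliers between classes (the
        separability dial; 0 makes all classes identical up to noise).
    """
    if not 1 <= n_classes <= 26:
        raise ValueError(f"n_classes must be in 1..26, got {n_classes}")
    if class_spread < 0:
        raise ValueError("class_spread must be >= 0")
    rng = np.random.default_rng(seed)
    labels = [chr(ord("A") + i) for i in range(n_classes)]
    recipes = []
    for label in labels:
        mult = np.exp(rng.normal(0.0, class_spread, size=len(CHARACTERISTIC_WAVENUMBERS)))
        peaks = [
            PeakSpec(center=c, width=w, amplitude=a * m, shape=shape)
            for c, w, a, m in zip(
                CHARACTERISTIC_WAVENUMBERS, _DEFAULT_WIDTHS, _DEFAULT_AMPLITUDES, mult
            )
        ]
        # gentle, class-specific baseline tilt (a.u. per cm^-1)
        slope = rng.normal(0.0, 2e-6)
        recipes.append(
            ClassRecipe(
                label=label,
                peaks=peaks,
                baseline_slope=slope,
                noise_sd=noise_sd,
                sample_jitter=sample_jitter,
            )
        )
    return recipes


def generate_spectrum(recipe: ClassRecipe, grid: np.ndarray, seed: int) -> Spectrum:
    """Synthesize one spectrum: peak sum + linear baseline + Gaussian noise.

    The per-sample amplitude jitter and optional centre jitter also draw
    from ``seed``, so a seed fully determines the sample.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    rng = np.random.default_rng(seed)
    jitter = (
        np.exp(rng.normal(0.0, recipe.sample_jitter, size=len(recipe.peaks)))
        if recipe.sample_jitter > 0
        else np.ones(len(recipe.peaks))
    )
    centers = (
        rng.normal(0.0, recipe.center_jitter_sd, size=len(recipe.peaks))
        if recipe.center_jitter_sd > 0
        else np.zeros(len(recipe.peaks))
    )
    y = np.zeros_like(grid)
    for peak, j, dc in zip(recipe.peaks, jitter, centers):
        shifted = PeakSpec(peak.center + dc, peak.width, peak.amplitude * j, peak.shape)
        y += shifted.profile(grid)
    y += recipe.baseline_slope * (grid - grid.mean())
    if recipe.noise_sd > 0:
        y += rng.normal(0.0, recipe.noise_sd, size=grid.size)
    return Spectrum(grid, y, recipe.label)


def generate_dataset(
    n_classes: int = 7,
    n_per_class: int = 25,
    grid_spec: dict | None = None,
    seed: int = 0,
    recipes: Sequence[ClassRecipe] | None = None,
    class_spread: float = DEFAULT_CLASS_SPREAD,
    noise_sd: float = DEFAULT_NOISE_SD,
    sample_jitter: float = DEFAULT_SAMPLE_JITTER,
) -> LabeledSpectrumSet:
    """Generate ``n_classes x n_per_class`` labelled spectra.

    Uses :func:`default_recipes` unless explicit ``recipes`` are given
    (then ``n_classes`` must match).  Per-sample seeds are spawned
    deterministically from ``seed``.
    """
    if n_classes <= 0 or n_per_class <= 0:
        raise ValueError("n_classes and n_per_class must be positive")
    gs = dict(DEFAULT_GRID)
    if grid_spec:
        gs.update(grid_spec)
    grid = make_grid(gs["start"], gs["stop"], gs["step"])
    if recipes is None:
        recipes = default_recipes(
            n_classes, seed,
            class_spread=class_spread, noise_sd=noise_sd, sample_jitter=sample_jitter,
        )
    elif len(recipes) != n_classes:
        raise ValueError(f"{len(recipes)} recipes for n_classes={n_classes}")
    seed_rng = np.random.default_rng(seed + 1)
    sample_seeds = seed_rng.integers(0, 2**31 - 1, size=n_classes * n_per_class)
    spectra = np.empty((n_classes * n_per_class, grid.size))
    labels = []
    k = 0
    for recipe in recipes:
        for _ in range(n_per_class):
            spectra[k] = generate_spectrum(recipe, grid, int(sample_seeds[k])).intensities
            labels.append(recipe.label)
            k += 1
    return LabeledSpectrumSet(grid, spectra, labels)
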