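"""Reading, normalizing, averaging and band-extracting 1-D spectra.

Feature bands: redundant full-range spectra dilute the class signal, so
downstream modelling works on four characteristic windows of the
mid-IR fingerprint — the O-H stretch region (3500-3000 cm^-1), the
methylene stretches (3000-2750), the carbonyl/aromatic fingerprint
(1750-1100) and the low-wavenumber saccharide region (1100-400) — plus
the full acquisition window.  Band bounds are inclusive on both ends.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import Band, FormatError, LabeledSpectrumSet, Spectrum

__all__ = [
    "BAND_PRESETS",
    "read_spectra",
    "normalize",
    "normalize_set",
    "average_spectra",
    "extract_band",
    "extract_band_set",
    "concat_bands",
]

#: Named feature-band presets addressable from the CLI and config.
BAND_PRESETS: dict[str, Band] = {
    "bandA": Band(3500.0, 3000.0, "bandA"),
    "bandB": Band(3000.0, 2750.0, "bandB"),
    "bandC": Band(1750.0, 1100.0, "bandC"),
    "bandD": Band(1100.0, 400.0, "bandD"),
    "full": Band(4010.0, 365.0, "full"),
}


def read_spectra(path: str | Path, dialect: str = "wide_table") -> LabeledSpectrumSet:
    """Read a labelled spectra table (wide-table dialect).

    The grid is re-sorted descending if the file stores it ascending;
    format problems raise :class:`FormatError` naming the offending row.
    """
    if dialect != "wide_table":
        raise ValueError(f"unknown dialect {dialect!r}")
    s = LabeledSpectrumSet.from_csv(path)
    if s.wavenumbers.size >= 2:
        d = np.diff(s.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise FormatError(f"{path}: wavenumber header is not monotonic")
        if d[0] > 0:  # stored ascending; flip to descending convention
            s = LabeledSpectrumSet(
                s.wavenumbers[::-1].copy(), s.spectra[:, ::-1].copy(), s.labels
            )
    return s


def normalize(s: Spectrum, method: str = "minmax") -> Spectrum:
    """Normalize a spectrum.

    ``minmax`` rescales to [0, 1]; ``vector`` scales to unit Euclidean
    norm (preserving pairwise cosine similarity between spectra).
    """
    y = s.intensities
    if method == "minmax":
        lo, hi = float(y.min()), float(y.max())
        if hi == lo:
            raise ValueError("minmax normalization undefined for a constant spectrum")
        y = (y - lo) / (hi - lo)
    elif method == "vector":
        n = float(np.linalg.norm(y))
        if n == 0:
            raise ValueError("vector normalization undefined for an all-zero spectrum")
        y = y / n
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return Spectrum(s.wavenumbers, y, s.label)


def normalize_set(s: LabeledSpectrumSet, method: str = "minmax") -> LabeledSpectrumSet:
    """Apply :func:`normalize` to every sample in a set."""
    rows = [normalize(sp, method).intensities for sp in s]
    return LabeledSpectrumSet(s.wavenumbers, np.vstack(rows), list(s.labels))


def average_spectra(s: LabeledSpectrumSet, by_label: bool = True) -> LabeledSpectrumSet:
    """Pointwise mean spectra, per label or globally."""
    if not by_label:
        return LabeledSpectrumSet(
            s.wavenumbers, s.spectra.mean(axis=0, keepdims=True), ["mean"]
        )
    labels = s.classes
    rows = []
    for lab in labels:
        mask = np.array([l == lab for l in s.labels])
        rows.append(s.spectra[mask].mean(axis=0))
    return LabeledSpectrumSet(s.wavenumbers, np.vstack(rows), labels)


def extract_band(s: Spectrum, band: Band) -> Spectrum:
    """Restrict a spectrum to a band (inclusive bounds); order preserved."""
    mask = band.contains(s.wavenumbers)
    if not mask.any():
        raise ValueError(
            f"band {band.name or (band.high, band.low)} does not intersect the grid"
        )
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], s.label)


def extract_band_set(s: LabeledSpectrumSet, band: Band) -> LabeledSpectrumSet:
    """Band-restrict every sample of a set on the shared grid."""
    mask = band.contains(s.wavenumbers)
    if not mask.any():
        raise ValueError(
            f"band {band.name or (band.high, band.low)} does not intersect the grid"
        )
    return LabeledSpectrumSet(s.wavenumbers[mask], s.spectra[:, mask], list(s.labels))


def concat_bands(s: LabeledSpectrumSet, bands: list[Band]) -> LabeledSpectrumSet:
    """Concatenate several band extractions into one fused feature vector.

    The fused 'grid' is the concatenation of the band grids (it is no
    longer monotonic overall, only per segment); used for the
    fused-feature-band variant where all four windows feed one map.
    """
    masks = [band.contains(s.wavenumbers) for band in bands]
    for band, m in zip(bands, masks):
        if not m.any():
            raise ValueError(f"band {band.name} does not intersect the grid")
    w = np.concatenate([s.wavenumbers[m] for m in masks])
    x = np.concatenate([s.spectra[:, m] for m in masks], axis=1)
    return LabeledSpectrumSet(w, x, list(s.labels))
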