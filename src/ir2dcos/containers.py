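"""Core in-memory containers for 1-D IR spectra.

A :class:`Spectrum` is a single wavenumber-indexed absorbance trace; a
:class:`LabeledSpectrumSet` is a collection of spectra that share one
wavenumber grid, each carrying a class label.  Sets round-trip through a
wide delimited-text table (first column ``label``, one column per grid
point, header row of wavenumbers) so that every pipeline stage can be
driven from plain files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "Band", "LabeledSpectrumSet", "FormatError"]


class FormatError(ValueError):
    """Raised when a spectra file does not parse under the declared dialect."""


@dataclass(frozen=True)
class Band:
    """A contiguous wavenumber window, bounds inclusive on both ends."""

    high: float
    low: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError(
                f"band bounds must satisfy high > low, got {self.high} <= {self.low}"
            )

    def contains(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points falling inside the band."""
        w = np.asarray(wavenumbers, dtype=float)
        return (w >= self.low) & (w <= self.high)


@dataclass
class Spectrum:
    """One absorbance spectrum on a strictly monotonic wavenumber grid."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotonic")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass
class LabeledSpectrumSet:
    """Samples x grid-points absorbance matrix with one label per sample."""

    wavenumbers: np.ndarray
    spectra: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.labels = [str(l) for l in self.labels]
        if self.spectra.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} columns but grid has "
                f"{self.wavenumbers.size} points"
            )
        if len(self.labels) != self.spectra.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.spectra.shape[0]} spectra"
            )

    @property
    def n_samples(self) -> int:
        return int(self.spectra.shape[0])

    @property
    def classes(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l)
        return list(seen)

    def __len__(self) -> int:
        return self.n_samples

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.spectra[i], self.labels[i])

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(self.n_samples):
            yield self[i]

    def subset(self, indices: Sequence[int]) -> "LabeledSpectrumSet":
        idx = np.asarray(indices, dtype=int)
        return LabeledSpectrumSet(
            self.wavenumbers,
            self.spectra[idx],
            [self.labels[i] for i in idx],
        )

    # ------------------------------------------------------------------
    # wide-table text I/O
    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path, metadata: dict | None = None) -> Path:
        """Write the set as a wide table; optionally a JSON sidecar of params.

        Floats are written with shortest round-tripping repr, so a
        write/read cycle reproduces intensities bit-for-bit.
        """
        path = Path(path)
        df = pd.DataFrame(self.spectra,
                          columns=[repr(float(w)) for w in self.wavenumbers])
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)
        if metadata is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledSpectrumSet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            df = pd.read_csv(path, dtype={"label": str},
                             float_precision="round_trip")
        except pd.errors.ParserError as e:  # ragged rows
            raise FormatError(f"{path}: malformed table ({e})") from e
        if "label" not in df.columns or df.shape[1] < 3:
            raise FormatError(
                f"{path}: expected a 'label' column plus >=2 wavenumber columns"
            )
        try:
            wavenumbers = np.array([float(c) for c in df.columns[1:]])
        except ValueError as e:
            raise FormatError(f"{path}: non-numeric wavenumber header ({e})") from e
        values = df.iloc[:, 1:]
        numeric = values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & ~values.isna()
        if bad.to_numpy().any():
            row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
            raise FormatError(f"{path}: non-numeric cell in data row {row}")
        if numeric.isna().to_numpy().any():
            row = int(np.argwhere(numeric.isna().to_numpy().any(axis=1))[0][0])
            raise FormatError(f"{path}: missing value in data row {row}")
        return cls(wavenumbers, numeric.to_numpy(dtype=float), df["label"].tolist())
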