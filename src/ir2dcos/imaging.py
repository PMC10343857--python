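"""Rendering correlation maps into fixed-size RGB raster images.

Maps are drawn as pure data pixels — no axes, ticks or text — so the
classifier never sees typography.  The default scaling is symmetric
about zero (``symmetric_max``): the interval ``[-max|m|, +max|m|]`` is
mapped onto a diverging palette, putting zero at the palette midpoint
and making the rendering invariant to an overall scale factor of the
map.  Resampling to the target pixel size is bilinear, which commutes
with matrix transposition, so a symmetric synchronous map renders to an
image equal to its own transpose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.ndimage import map_coordinates
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["RenderConfig", "render_map", "save_image", "load_image",
           "render_dataset", "MapImageRenderer"]


@dataclass(frozen=True)
class RenderConfig:
    """How a correlation matrix becomes pixels."""

    size: int = 224
    colormap: str = "coolwarm"
    scaling: str = "symmetric_max"      # or "percentile"
    style: str = "heatmap"              # or "filled_contour"
    contour_levels: int = 10
    percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if self.scaling not in ("symmetric_max", "percentile"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.style not in ("heatmap", "filled_contour"):
            raise ValueError(f"unknown style {self.style!r}")
        if self.style == "filled_contour" and self.contour_levels < 2:
            raise ValueError("contour_levels must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


def _resample(m: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resample a square matrix to size x size."""
    n = m.shape[0]
    if n == size:
        return m.astype(float)
    # sample at positions mapping pixel centres onto matrix coordinates
    coords = np.linspace(0, n - 1, size)
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    return map_coordinates(m.astype(float), [rr, cc], order=1, mode="nearest")


def render_map(m: np.ndarray, cfg: RenderConfig | None = None) -> np.ndarray:
    """Render a square correlation matrix to an RGB uint8 image array.

    Deterministic: the same matrix and config always give the same
    bytes.  A zero matrix maps uniformly to the palette midpoint.
    """
    cfg = cfg or RenderConfig()
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if cfg.scaling == "symmetric_max":
        vmax = float(np.max(np.abs(m)))
    else:
        vmax = float(np.percentile(np.abs(m), cfg.percentile))
    if vmax == 0.0:
        vmax = 1.0  # zero matrix -> palette midpoint everywhere
    scaled = np.clip(m / vmax, -1.0, 1.0)
    resized = np.clip(_resample(scaled, cfg.size), -1.0, 1.0)
    unit = (resized + 1.0) / 2.0
    if cfg.style == "filled_contour":
        # quantize into contour_levels filled bands
        levels = cfg.contour_levels
        unit = np.floor(unit * levels) / max(levels - 1, 1)
        unit = np.clip(unit, 0.0, 1.0)
    cmap = colormaps[cfg.colormap]
    rgba = cmap(unit)
    return (rgba[..., :3] * 255.0).round().astype(np.uint8)


def save_image(img: np.ndarray, path: str | Path, force: bool = False) -> Path:
    """Write an RGB array as PNG (lossless). Refuses to overwrite unless forced."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode="RGB").save(path, format="PNG")
    return path


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG back into an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


class MapImageRenderer(BaseEstimator, TransformerMixin):
    """Vector-to-pixels stage: stack of maps -> stack of RGB images.

    ``transform`` maps ``(n, g, g)`` correlation matrices to
    ``(n, size, size, 3)`` uint8 images, each rendered independently.
    """

    def __init__(self, size: int = 224, colormap: str = "coolwarm",
                 scaling: str = "symmetric_max", style: str = "heatmap",
                 contour_levels: int = 10):
        self.size = size
        self.colormap = colormap
        self.scaling = scaling
        self.style = style
        self.contour_levels = contour_levels

    def _cfg(self) -> RenderConfig:
        return RenderConfig(size=self.size, colormap=self.colormap,
                            scaling=self.scaling, style=self.style,
                            contour_levels=self.contour_levels)

    def fit(self, X=None, y=None):
        self._cfg()  # validates
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._cfg()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        out = np.empty((X.shape[0], cfg.size, cfg.size, 3), dtype=np.uint8)
        for i in range(X.shape[0]):
            out[i] = render_map(X[i], cfg)
        return out


def render_dataset(
    maps: np.ndarray,
    labels: list[str],
    sample_ids: list[str],
    out_dir: str | Path,
    map_type: str,
    set_name: str,
    cfg: RenderConfig | None = None,
    force: bool = False,
    manifest_extra: dict | None = None,
) -> dict:
    """Render a stack of maps to ``<out>/<set>/<label>/<id>_<maptype>.png``.

    Returns (and writes) a manifest mapping each file to its sample,
    label, map type and set.
    """
    cfg = cfg or RenderConfig()
    out_dir = Path(out_dir)
    entries = []
    for m, label, sid in zip(maps, labels, sample_ids):
        img = render_map(m, cfg)
        rel = Path(set_name) / label / f"{sid}_{map_type}.png"
        save_image(img, out_dir / rel, force=force)
        entries.append({"file": str(rel), "sample": sid, "label": label,
                        "map_type": map_type, "set": set_name})
    manifest = {"render_config": cfg.to_dict(), "entries": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = out_dir / f"manifest_{set_name}_{map_type}.json"
    mpath.parent.mkdir(parents=True, exist_ok=True)
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
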