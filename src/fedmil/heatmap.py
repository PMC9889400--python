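"""Attention heatmaps on the patch grid of a slide.

Attention weights are min-max normalised to [0, 1] over the bag's
patches and rasterised onto the (row, col) patch grid; cells with no
patch are marked missing (NaN) and rendered transparent.  When every
weight is equal the normalisation is undefined and all cells are set to
0.5 (neutral mid-colormap).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mil import AttentionWeights
from .synthetic import FeatureBag

__all__ = ["HeatmapGrid", "normalize_attention", "export_heatmap"]


@dataclass
class HeatmapGrid:
    """Normalised attention raster; NaN marks cells without a patch."""

    raster: np.ndarray  # (rows, cols) float with NaN for missing cells

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.raster)


def normalize_attention(alpha: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; an all-equal vector maps to 0.5."""
    alpha = np.asarray(alpha, dtype=float)
    lo, hi = alpha.min(), alpha.max()
    if hi - lo == 0:
        return np.full_like(alpha, 0.5)
    return (alpha - lo) / (hi - lo)


def export_heatmap(
    bag: FeatureBag,
    alpha: AttentionWeights | np.ndarray,
    csv_path: Path | str | None = None,
    png_path: Path | str | None = None,
    cmap: str = "jet",
) -> HeatmapGrid:
    """Build (and optionally write) the attention heatmap for one slide.

    The CSV lists (row, col, alpha_raw, alpha_norm) per patch; the PNG
    renders alpha_norm through a fixed colormap with missing cells
    transparent.
    """
    a = alpha.alpha if isinstance(alpha, AttentionWeights) else np.asarray(alpha, dtype=float)
    if bag.grid_coords is None:
        raise ValueError(f"slide {bag.slide_id} has no patch grid coordinates")
    coords = np.asarray(bag.grid_coords)
    if a.shape != (coords.shape[0],):
        raise ValueError("attention length must equal the number of patches")
    if len({(int(r), int(c)) for r, c in coords}) != len(coords):
        raise ValueError(f"slide {bag.slide_id} has duplicate grid cells")

    norm = normalize_attention(a)
    raster = np.full((coords[:, 0].max() + 1, coords[:, 1].max() + 1), np.nan)
    raster[coords[:, 0], coords[:, 1]] = norm

    if csv_path is not None:
        pd.DataFrame(
            {"row": coords[:, 0], "col": coords[:, 1], "alpha_raw": a, "alpha_norm": norm}
        ).to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        colormap = plt.get_cmap(cmap).copy()
        colormap.set_bad(alpha=0.0)
        rgba = colormap(np.ma.masked_invalid(raster))
        plt.imsave(png_path, rgba)
    return HeatmapGrid(raster=raster)
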