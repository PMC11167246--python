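"""Visual representations: grayscale images of counting arrays and
relevance heat maps of classifier feature importances.

The image representation normalizes a counting array by its own maximum
and maps 0 to white and 1 to black, one pixel per cell, so repeating
structural motifs become visible stripes. A relevance heat map un-flattens
a feature-importance vector back into array coordinates (element × level
rows, backbone-carbon columns) and renders it with a sequential colormap,
showing which backbone positions and elements drive a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoder import CountingArray, DatasetLayout, unflatten

__all__ = ["GrayscaleImage", "RelevanceMap", "array_to_image", "render_relevance_heatmap"]


@dataclass
class GrayscaleImage:
    """Normalized intensities in [0, 1]; 0 renders white, 1 renders black."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_pil(self, zoom: int = 1):
        """8-bit PIL image; pixel = round(255 * (1 - value)), zoom repeats pixels."""
        from PIL import Image

        if zoom < 1:
            raise ValueError(f"zoom must be >= 1, got {zoom}")
        arr = np.kron(self.values, np.ones((zoom, zoom)))
        pixels = np.round(255.0 * (1.0 - arr)).astype(np.uint8)
        return Image.fromarray(pixels, mode="L")

    def save(self, path: str | Path, zoom: int = 1) -> None:
        self.to_pil(zoom=zoom).save(Path(path), format="PNG")


@dataclass
class RelevanceMap:
    """Feature importances in counting-array coordinates."""

    values: np.ndarray  # (n_rows, max_carbons), non-negative
    layout: DatasetLayout

    def row_labels(self) -> list[str]:
        return [
            f"{elem}_L{level}"
            for level in range(1, self.layout.levels + 1)
            for elem in self.layout.alphabet.symbols
        ]

    def row_totals(self) -> dict[str, float]:
        """Aggregate importance per (element, level) row, for ranking."""
        return {lab: float(v) for lab, v in zip(self.row_labels(), self.values.sum(axis=1))}


def array_to_image(array: CountingArray, global_max: float | None = None) -> GrayscaleImage:
    """Convert a counting array to its grayscale image.

    Each cell is divided by the array's maximum entry (per-molecule
    normalization; pass global_max for data-set-wide comparability).
    An all-zero array has no signal and maps to all white.
    """
    values = np.asarray(array.values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot render an empty counting array")
    peak = float(global_max) if global_max is not None else float(values.max())
    if peak <= 0:
        return GrayscaleImage(np.zeros_like(values))
    return GrayscaleImage(values / peak)


def render_relevance_heatmap(
    importances: np.ndarray,
    layout: DatasetLayout,
    out_path: str | Path | None = None,
    title: str = "Relevance heat map",
) -> RelevanceMap:
    """Un-flatten an importance vector and render it as a heat map.

    Writes PNG to out_path (and a CSV of the map next to it) when given;
    always returns the RelevanceMap. Raises ValueError stating both
    lengths if the vector does not match the layout.
    """
    importances = np.asarray(importances, dtype=float)
    if importances.size != layout.vector_length:
        raise ValueError(
            f"importance vector has length {importances.size} but the layout "
            f"expects {layout.vector_length}"
        )
    rmap = RelevanceMap(values=unflatten(importances, layout), layout=layout)
    if out_path is not None:
        out_path = Path(out_path)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_rows, n_cols = rmap.values.shape
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.12 * n_cols + 1.5), max(3.0, 0.25 * n_rows + 1.0))
        )
        im = ax.imshow(rmap.values, aspect="auto", cmap="viridis", interpolation="nearest")
        ax.set_xlabel("backbone carbon position")
        ax.set_ylabel("element × level")
        ax.set_yticks(range(n_rows), labels=rmap.row_labels(), fontsize=6)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="importance")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)

        import pandas as pd

        csv_path = out_path.with_suffix(".csv")
        pd.DataFrame(
            rmap.values,
            index=rmap.row_labels(),
            columns=[f"C{j}" for j in range(rmap.values.shape[1])],
        ).to_csv(csv_path)
    return rmap
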