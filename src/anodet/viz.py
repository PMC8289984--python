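"""Error-map overlays and ranked score galleries.

Overlays show the original image on the left and the error map, colormapped
and alpha-blended onto the grayscale original, on the right.  Blending
strength at each pixel is the overlay opacity scaled by the normalized error,
so a zero error map leaves the original untouched.  Display normalization
defaults to the 99th percentile of the map (robust to single hot pixels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

from .data_io import ImageRecord
from .exceptions import EmptyResultError, ShapeError
from .scoring import AnomalyScore

NORM_GLOBAL_MAX = "global_max"
NORM_PERCENTILE = "percentile"


@dataclass(frozen=True)
class OverlaySpec:
    colormap: str = "magma"
    opacity: float = 0.6
    normalization: str = NORM_PERCENTILE
    percentile: float = 99.0

    def __post_init__(self):
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must be in [0, 1]")
        if self.normalization not in (NORM_GLOBAL_MAX, NORM_PERCENTILE):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _to_gray01(pixels: np.ndarray) -> np.ndarray:
    return (np.clip(pixels, -1.0, 1.0) + 1.0) / 2.0


def _normalize_map(error_map: np.ndarray, spec: OverlaySpec) -> np.ndarray:
    if spec.normalization == NORM_GLOBAL_MAX:
        scale = float(error_map.max())
    else:
        scale = float(np.percentile(error_map, spec.percentile))
    if scale <= 0:
        return np.zeros_like(error_map, dtype=np.float64)
    return np.clip(error_map / scale, 0.0, 1.0)


def overlay_error_map(image: ImageRecord, error_map: np.ndarray,
                      spec: OverlaySpec = OverlaySpec()) -> np.ndarray:
    """Side-by-side panel (original | overlay) as an H x 2W x 3 float RGB array."""
    if image.pixels is None or image.pixels.shape != error_map.shape:
        raise ShapeError("image and error map must have identical shapes")
    gray = _to_gray01(image.pixels)
    gray_rgb = np.repeat(gray[:, :, None], 3, axis=2)
    norm = _normalize_map(np.asarray(error_map, dtype=np.float64), spec)
    cmap = matplotlib.colormaps[spec.colormap]
    colored = cmap(norm)[:, :, :3]
    alpha = (spec.opacity * norm)[:, :, None]
    right = (1.0 - alpha) * gray_rgb + alpha * colored
    return np.concatenate([gray_rgb, right], axis=1)


def ranked_gallery(scores: list[AnomalyScore], images, k: int,
                   order: str = "highest", record_filter=None):
    """Top/bottom-k records by score.

    Returns (ranked records, ranked scores, grid) where grid is a single-row
    montage of the grayscale images in rank order.  Ties are broken by id;
    an optional predicate on ImageRecord filters before ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if order not in ("highest", "lowest"):
        raise ValueError(f"order must be 'highest' or 'lowest', got {order!r}")
    by_id = {r.id: r for r in images}
    pairs = [(s, by_id[s.image_id]) for s in scores if s.image_id in by_id]
    if record_filter is not None:
        pairs = [(s, r) for s, r in pairs if record_filter(r)]
    if not pairs:
        raise EmptyResultError("no records remain after filtering")
    reverse = order == "highest"
    pairs.sort(key=lambda p: ((-p[0].value if reverse else p[0].value),
                              p[0].image_id))
    pairs = pairs[:k]
    ranked_scores = [s for s, _ in pairs]
    ranked = [r for _, r in pairs]
    grid = np.concatenate([_to_gray01(r.pixels) for r in ranked], axis=1)
    return ranked, ranked_scores, grid


def save_rgb_png(array: np.ndarray, path) -> Path:
    """Write a float [0,1] RGB (or grayscale) array as an 8-bit PNG."""
    import imageio.v3 as iio

    path = Path(path)
    data = np.clip(array, 0.0, 1.0)
    iio.imwrite(path, np.round(data * 255).astype(np.uint8))
    return path


def plot_roc_curves(results: dict[str, "object"], path) -> Path:
    """Plot labeled ROC curves (one per positives definition / method) to PNG."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in results.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUROC {roc.auroc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
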