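"""Model interpretation for count regressors.

Two complementary views of what drives the predicted count:

* **Occlusion sensitivity**: slide a small background-colored box over the
  image (default 10×10, stride 5 — about one leaf width), re-predict at each
  position, and record ``prediction − ground truth``.  Painting the box with
  the background color removes structure rather than adding an artificial
  object.  Positive cells mean the occlusion *raised* the count (e.g. the box
  severed a leaf near its base, splitting it in two); negative cells mean it
  lowered the count (e.g. the box erased a leaf tip).
* **Grad-CAM**: gradients of the scalar output w.r.t. the final convolutional
  feature map, spatially averaged into per-channel weights; the rectified
  weighted channel sum is min-max normalized to [0, 1] and upsampled to input
  resolution.  A logistic "emphasis" sharpens the boundary between hot and
  cold regions for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

WHITE = (255, 255, 255)
BLACK = (0, 0, 0)


@dataclass
class Heatmap:
    """Real-valued spatial grid with provenance metadata.

    ``values`` has one cell per window position (occlusion) or per feature-map
    cell (Grad-CAM); ``input_size`` and, for occlusion maps, ``window`` /
    ``stride`` map cells back to input pixels.
    """

    values: np.ndarray
    kind: Literal["occlusion", "gradcam", "gradcam_emphasized"]
    input_size: int
    window: int | None = None
    stride: int | None = None
    baseline_prediction: float | None = None
    ground_truth: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("heatmap values must be finite")

    def cell_to_pixel(self, row: int, col: int) -> tuple[int, int]:
        """Top-left input pixel of a grid cell."""
        if self.kind == "occlusion":
            return row * self.stride, col * self.stride
        scale = self.input_size / self.values.shape[0]
        return int(row * scale), int(col * scale)

    def to_pixel_grid(self) -> np.ndarray:
        """Nearest-neighbor upsample of the cell grid to input resolution."""
        n = self.input_size
        rows = np.minimum(
            (np.arange(n) * self.values.shape[0]) // n, self.values.shape[0] - 1
        )
        cols = np.minimum(
            (np.arange(n) * self.values.shape[1]) // n, self.values.shape[1] - 1
        )
        return self.values[np.ix_(rows, cols)]


def occlusion_heatmap(
    model,
    image: np.ndarray,
    ground_truth: int,
    window: int = 10,
    stride: int = 5,
    window_color: tuple[int, int, int] = WHITE,
    chunk: int = 64,
) -> Heatmap:
    """Prediction shift map under a sliding background-colored occluder.

    Cell (i, j) holds ``predict(image with window painted at (i·stride,
    j·stride)) − ground_truth``.  Grid side = ``⌊(S − window)/stride⌋ + 1``.
    ``model`` needs only ``predict``/``predict_batch``; a stub works.
    """
    image = np.asarray(image)
    s = image.shape[0]
    if image.ndim != 3 or image.shape[:2] != (s, s):
        raise ValueError(f"expected a square HxWx3 image, got {image.shape}")
    if window > s:
        raise ValueError(f"window {window} larger than image side {s}")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    side = (s - window) // stride + 1
    starts = [i * stride for i in range(side)]
    baseline = float(model.predict(image))

    color = np.asarray(window_color, dtype=np.uint8)
    values = np.empty((side, side), dtype=np.float64)
    positions = [(r, c) for r in starts for c in starts]
    batch = np.empty((min(chunk, len(positions)), s, s, 3), dtype=np.uint8)
    preds = np.empty(len(positions))
    for base in range(0, len(positions), chunk):
        group = positions[base : base + chunk]
        for k, (r, c) in enumerate(group):
            batch[k] = image
            batch[k, r : r + window, c : c + window] = color
        preds[base : base + len(group)] = model.predict_batch(batch[: len(group)])
    for idx, (r, c) in enumerate(positions):
        values[r // stride, c // stride] = preds[idx] - ground_truth

    return Heatmap(
        values=values,
        kind="occlusion",
        input_size=s,
        window=window,
        stride=stride,
        baseline_prediction=baseline,
        ground_truth=int(ground_truth),
    )


def grad_cam(model, image: np.ndarray) -> Heatmap:
    """Gradient-weighted activation map of the final convolutional layer.

    Channel weights are the spatial means of ∂output/∂feature-map; the
    weighted channel sum is rectified (negatives zeroed) and min-max
    normalized to [0, 1] (an all-equal map normalizes to all zeros).
    """
    for attr in ("feature_map", "feature_gradients"):
        if not hasattr(model, attr):
            raise TypeError(f"model does not expose {attr}; cannot run Grad-CAM")
    image = np.asarray(image)
    fmap = model.feature_map(image)  # C,H,W
    grads = model.feature_gradients(image)
    alpha = grads.mean(axis=(1, 2))  # per-channel weight
    cam = np.maximum((alpha[:, None, None] * fmap).sum(axis=0), 0.0)
    lo, hi = float(cam.min()), float(cam.max())
    cam = (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)
    return Heatmap(
        values=cam,
        kind="gradcam",
        input_size=int(image.shape[0]),
        baseline_prediction=float(model.predict(image)),
    )


def emphasize(heatmap: Heatmap, steepness: float = 10.0) -> Heatmap:
    """Logistic sharpening of a normalized Grad-CAM map about 0.5."""
    if heatmap.kind != "gradcam":
        raise ValueError(f"emphasize expects a gradcam heatmap, got {heatmap.kind!r}")
    values = 1.0 / (1.0 + np.exp(-steepness * (heatmap.values - 0.5)))
    return Heatmap(
        values=values,
        kind="gradcam_emphasized",
        input_size=heatmap.input_size,
        baseline_prediction=heatmap.baseline_prediction,
    )


def render_overlay(
    heatmap: Heatmap,
    image: np.ndarray,
    colormap_name: str = "jet",
    alpha: float = 0.5,
) -> np.ndarray:
    """Colorize the heatmap (warm = high) and alpha-blend onto the image."""
    import matplotlib

    image = np.asarray(image)
    if image.shape[0] != heatmap.input_size or image.shape[1] != heatmap.input_size:
        raise ValueError(
            f"image extent {image.shape[:2]} does not match heatmap input_size "
            f"{heatmap.input_size}"
        )
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    grid = heatmap.to_pixel_grid()
    lo, hi = float(grid.min()), float(grid.max())
    norm = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)
    colors = (matplotlib.colormaps[colormap_name](norm)[:, :, :3] * 255).astype(np.float64)
    blended = (1.0 - alpha) * image.astype(np.float64) + alpha * colors
    return blended.round().astype(np.uint8)
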