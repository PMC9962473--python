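"""Plant extraction from raw greenhouse-style images.

The scene (imaging rig, pot) occupies most pixels and is shared by every
image, so the plant is isolated by differencing against an *averaged*
background: averaging over many plant-free captures cancels the per-image
illumination jitter that defeats single-image subtraction.  The absolute
difference is converted to grayscale, binarized with Otsu's threshold, and the
largest connected component — the plant — is cropped out of the original
image and resized to the network input resolution (default 299 px square,
aspect preserved, white padded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from PIL import Image

#: ITU-R 601 luma weights used for every RGB→gray conversion in the package.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class ConstantImageError(ValueError):
    """Otsu thresholding is undefined on an image with a single gray level."""


class NoPlantError(ValueError):
    """The pipeline found no plausible plant component in the image."""


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box ``[row_min, row_max) × [col_min, col_max)``."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min


@dataclass
class ComponentRecord:
    label: int
    area_px: int
    bbox: BoundingBox


@dataclass
class ComponentTable:
    """Connected-component labeling result: label map plus per-label records."""

    label_map: np.ndarray
    components: list[ComponentRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)


def _check_rgb(image: np.ndarray, name: str = "image") -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"{name} must be HxWx3, got shape {image.shape}")
    return image


def average_background(backgrounds: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel, per-channel arithmetic mean of plant-free images, rounded half-up."""
    if len(backgrounds) == 0:
        raise ValueError("need at least one background image")
    first = _check_rgb(backgrounds[0], "backgrounds[0]")
    acc = np.zeros(first.shape, dtype=np.float64)
    for i, bg in enumerate(backgrounds):
        bg = _check_rgb(bg, f"backgrounds[{i}]")
        if bg.shape != first.shape:
            raise ValueError(
                f"backgrounds[{i}] shape {bg.shape} != backgrounds[0] shape {first.shape}"
            )
        acc += bg
    return np.floor(acc / len(backgrounds) + 0.5).astype(np.uint8)


def difference_image(
    original: np.ndarray,
    background: np.ndarray,
    mode: Literal["abs", "signed_clip"] = "abs",
) -> np.ndarray:
    """Per-pixel, per-channel difference between an image and the average background.

    ``abs`` (default) is robust to either contrast polarity; ``signed_clip``
    keeps only pixels darker than the background (clipped at zero).
    """
    original = _check_rgb(original, "original")
    background = _check_rgb(background, "background")
    if original.shape != background.shape:
        raise ValueError(f"shape mismatch {original.shape} vs {background.shape}")
    diff = original.astype(np.int16) - background.astype(np.int16)
    if mode == "abs":
        return np.abs(diff).astype(np.uint8)
    if mode == "signed_clip":
        return np.clip(-diff, 0, 255).astype(np.uint8)
    raise ValueError(f"unknown difference mode {mode!r}")


def to_gray(image: np.ndarray) -> np.ndarray:
    """RGB→gray with ITU-R 601 luma weights, rounded half-up to [0, 255]."""
    image = _check_rgb(image)
    gray = image.astype(np.float64) @ np.asarray(GRAY_WEIGHTS)
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over the 256-level histogram.

    Returns the integer ``t`` maximizing the between-class variance of the
    partition ``{v <= t} / {v > t}``; the smallest maximizer wins ties.
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ConstantImageError("image has a single gray level; Otsu is undefined")
    omega = np.cumsum(hist) / total  # class-0 probability up to and incl. t
    mu = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def otsu_binarize(
    gray: np.ndarray, foreground_polarity: Literal["bright", "dark"] = "bright"
) -> tuple[np.ndarray, int]:
    """Binarize with Otsu's threshold; foreground is the bright or dark class."""
    t = otsu_threshold(gray)
    if foreground_polarity == "bright":
        mask = np.asarray(gray) > t
    elif foreground_polarity == "dark":
        mask = np.asarray(gray) <= t
    else:
        raise ValueError(f"unknown polarity {foreground_polarity!r}")
    return mask.astype(np.uint8), t


def connected_components(mask: np.ndarray, connectivity: int = 8) -> ComponentTable:
    """Label connected foreground regions (4- or 8-neighborhood)."""
    from scipy import ndimage

    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = np.ones((3, 3), bool) if connectivity == 8 else None
    label_map, n = ndimage.label(np.asarray(mask) != 0, structure=structure)
    records = []
    if n:
        areas = np.bincount(label_map.ravel(), minlength=n + 1)
        slices = ndimage.find_objects(label_map)
        for lab, sl in enumerate(slices, start=1):
            records.append(
                ComponentRecord(
                    label=lab,
                    area_px=int(areas[lab]),
                    bbox=BoundingBox(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                )
            )
    return ComponentTable(label_map=label_map, components=records)


def largest_component_bbox(components: ComponentTable) -> BoundingBox:
    """Bounding box of the maximum-area component (smallest label on ties)."""
    if len(components) == 0:
        raise NoPlantError("no foreground components")
    best = max(components.components, key=lambda c: (c.area_px, -c.label))
    return best.bbox


def _resize_rgb(image: np.ndarray, size_hw: tuple[int, int], interpolation: str) -> np.ndarray:
    resample = {"bilinear": Image.BILINEAR, "nearest": Image.NEAREST}[interpolation]
    out = Image.fromarray(image).resize((size_hw[1], size_hw[0]), resample=resample)
    return np.asarray(out)


def crop_resize(
    image: np.ndarray,
    box: BoundingBox,
    out_size: int = 299,
    interpolation: Literal["bilinear", "nearest"] = "bilinear",
    pad_value: int = 255,
) -> np.ndarray:
    """Crop to ``box``, scale the longer side to ``out_size`` and pad to square.

    Aspect ratio is preserved; the shorter side is centered on a white
    (``pad_value``) square canvas.  Output is ``out_size × out_size × 3``.
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if not (0 <= box.row_min < box.row_max <= h and 0 <= box.col_min < box.col_max <= w):
        raise ValueError(f"box {box} outside image of shape {(h, w)}")
    crop = image[box.row_min : box.row_max, box.col_min : box.col_max]
    ch, cw = crop.shape[:2]
    if ch >= cw:
        new_h, new_w = out_size, max(1, round(cw * out_size / ch))
    else:
        new_h, new_w = max(1, round(ch * out_size / cw)), out_size
    resized = _resize_rgb(crop, (new_h, new_w), interpolation)
    out = np.full((out_size, out_size, 3), pad_value, dtype=np.uint8)
    r0 = (out_size - new_h) // 2
    c0 = (out_size - new_w) // 2
    out[r0 : r0 + new_h, c0 : c0 + new_w] = resized
    return out


@dataclass
class PreprocessConfig:
    out_size: int = 299
    connectivity: int = 8
    difference_mode: Literal["abs", "signed_clip"] = "abs"
    foreground_polarity: Literal["bright", "dark"] = "bright"
    min_plant_area: int = 100  # px; below this the frame is declared plant-free
    min_plant_contrast: float = 25.0  # mean difference-gray a plant must reach
    interpolation: Literal["bilinear", "nearest"] = "bilinear"


def preprocess_pipeline(
    original: np.ndarray,
    avg_background: np.ndarray,
    config: PreprocessConfig | None = None,
    return_intermediates: bool = False,
):
    """Full plant-extraction chain: difference → gray → Otsu → components → crop.

    The difference image is bright where the plant is (regardless of plant
    polarity in the original), so Otsu foreground is the *bright* class here.
    Raises :class:`NoPlantError` when the largest component is smaller than
    ``config.min_plant_area`` (e.g. a plant-free frame).
    """
    config = config or PreprocessConfig()
    diff = difference_image(original, avg_background, mode=config.difference_mode)
    gray = to_gray(diff)
    mask, threshold = otsu_binarize(gray, config.foreground_polarity)
    table = connected_components(mask, config.connectivity)
    if len(table) == 0:
        raise NoPlantError("binary image has no foreground")
    best = max(table.components, key=lambda c: (c.area_px, -c.label))
    if best.area_px < config.min_plant_area:
        raise NoPlantError(
            f"largest component has {best.area_px} px < min_plant_area "
            f"{config.min_plant_area}; no plant found"
        )
    # a real plant differs strongly from the averaged background; a component
    # made of residual illumination jitter does not
    contrast = float(gray[table.label_map == best.label].mean())
    if contrast < config.min_plant_contrast:
        raise NoPlantError(
            f"largest component mean difference intensity {contrast:.1f} < "
            f"min_plant_contrast {config.min_plant_contrast}; no plant found"
        )
    box = best.bbox
    out = crop_resize(original, box, config.out_size, config.interpolation)
    if not return_intermediates:
        return out
    return out, {
        "difference": diff,
        "gray": gray,
        "binary": mask,
        "threshold": threshold,
        "components": table,
        "bbox": box,
    }
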