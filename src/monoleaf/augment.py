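"""Geometric training-set augmentation.

Twelve label-preserving operations: the original image plus eleven
transforms.  The first six (identity, vertical/horizontal compression,
vertical flip, and vertical flip followed by either compression) produce
images a greenhouse camera could plausibly capture; the other six (horizontal
flip, 180° rotation, and the four 90°-rotation variants) are non-realistic
but still preserve the leaf count.  Compressed or rotated results smaller
than the working square are centered on white padding.  Augmentation applies
to training rows only; validation and test rows pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

REALISTIC_OPS = (
    "identity",
    "compress_v",
    "compress_h",
    "flip_v",
    "flip_v_compress_v",
    "flip_v_compress_h",
)
NON_REALISTIC_OPS = (
    "flip_h",
    "rot180",
    "rot90cw",
    "rot90cw_flip_v",
    "rot90ccw",
    "rot90ccw_flip_v",
)
ALL_OPS = REALISTIC_OPS + NON_REALISTIC_OPS

WHITE = 255


@dataclass(frozen=True)
class AugmentationOp:
    name: str

    def __post_init__(self):
        if self.name not in ALL_OPS:
            raise ValueError(f"unknown augmentation op {self.name!r}")

    @property
    def realistic(self) -> bool:
        return self.name in REALISTIC_OPS


def _compress(image: np.ndarray, factor: float, axis: int) -> np.ndarray:
    """Scale one axis by ``factor`` (bilinear) and center on white padding."""
    h, w = image.shape[:2]
    new_h = max(1, round(h * factor)) if axis == 0 else h
    new_w = max(1, round(w * factor)) if axis == 1 else w
    small = np.asarray(
        Image.fromarray(image).resize((new_w, new_h), resample=Image.BILINEAR)
    )
    out = np.full((h, w, 3), WHITE, dtype=np.uint8)
    r0, c0 = (h - new_h) // 2, (w - new_w) // 2
    out[r0 : r0 + new_h, c0 : c0 + new_w] = small
    return out


def _flip_v(im):  # reverse rows: top <-> bottom
    return im[::-1, :, :]


def _flip_h(im):  # reverse columns: left <-> right
    return im[:, ::-1, :]


def apply_transform(
    image: np.ndarray, op: AugmentationOp | str, compress_factor: float = 0.5
) -> np.ndarray:
    """Apply one augmentation op to a square RGB image (same output shape)."""
    if isinstance(op, str):
        op = AugmentationOp(op)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square HxWx3 image, got shape {image.shape}")
    if not (0 < compress_factor <= 1):
        raise ValueError(f"compress_factor must be in (0, 1], got {compress_factor}")
    name = op.name
    if name == "identity":
        return image.copy()
    if name == "compress_v":
        return _compress(image, compress_factor, axis=0)
    if name == "compress_h":
        return _compress(image, compress_factor, axis=1)
    if name == "flip_v":
        return np.ascontiguousarray(_flip_v(image))
    if name == "flip_v_compress_v":
        return _compress(np.ascontiguousarray(_flip_v(image)), compress_factor, axis=0)
    if name == "flip_v_compress_h":
        return _compress(np.ascontiguousarray(_flip_v(image)), compress_factor, axis=1)
    if name == "flip_h":
        return np.ascontiguousarray(_flip_h(image))
    if name == "rot180":
        return np.ascontiguousarray(image[::-1, ::-1, :])
    if name == "rot90cw":
        return np.ascontiguousarray(np.rot90(image, k=-1))
    if name == "rot90cw_flip_v":
        return np.ascontiguousarray(_flip_v(np.rot90(image, k=-1)))
    if name == "rot90ccw":
        return np.ascontiguousarray(np.rot90(image, k=1))
    if name == "rot90ccw_flip_v":
        return np.ascontiguousarray(_flip_v(np.rot90(image, k=1)))
    raise AssertionError(name)


def expand_training_set(
    manifest: pd.DataFrame, ops: Iterable[AugmentationOp | str]
) -> pd.DataFrame:
    """Replace each train row by one row per op; val/test rows pass through.

    Every augmented row keeps its source row's ``leaf_count``.  ``ops`` must
    include ``identity``, otherwise the original training images would be
    dropped from the expanded set.
    """
    ops = [AugmentationOp(o) if isinstance(o, str) else o for o in ops]
    names = [o.name for o in ops]
    if not names:
        raise ValueError("ops must be non-empty")
    if "identity" not in names:
        raise ValueError("ops must include 'identity' (originals would be dropped)")

    rows = []
    for _, row in manifest.iterrows():
        if row["split"] != "train":
            out = row.copy()
            if "augmentation" not in out.index:
                out["augmentation"] = "identity"
            rows.append(out)
            continue
        for name in names:
            out = row.copy()
            out["augmentation"] = name
            if name != "identity":
                out["image_id"] = f"{row['image_id']}__{name}"
                stem, dot, ext = str(row["path"]).rpartition(".")
                out["path"] = f"{stem}__{name}{dot}{ext}" if dot else f"{row['path']}__{name}"
            rows.append(out)
    return pd.DataFrame(rows).reset_index(drop=True)


def materialize_augmented(
    manifest: pd.DataFrame,
    source_root: str,
    out_root: str,
    compress_factor: float = 0.5,
) -> None:
    """Materialize every augmented row's image file under ``out_root``."""
    import os
    import shutil

    for _, row in manifest.iterrows():
        name = str(row.get("augmentation", "identity"))
        dst = os.path.join(out_root, str(row["path"]))
        os.makedirs(os.path.dirname(dst), exist_ok=True)
        if name == "identity":
            src = os.path.join(source_root, str(row["path"]))
            if os.path.abspath(src) != os.path.abspath(dst):
                shutil.copyfile(src, dst)
            continue
        src_rel = str(row["path"]).replace(f"__{name}", "")
        image = np.asarray(Image.open(os.path.join(source_root, src_rel)).convert("RGB"))
        Image.fromarray(apply_transform(image, name, compress_factor)).save(dst)
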