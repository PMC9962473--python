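"""Procedural generator of monocot-plant images with known leaf counts.

Greenhouse leaf-counting imagery is rarely redistributable, so the pipeline is
exercised on procedurally rendered plants instead: a static equipment-like
background (rails, poles, a panel, a dark pot) with per-image illumination
jitter, a vertical stem, and ``leaf_count`` curved leaf strokes attached
alternately along the stem.  Leaves are quadratic Bézier strokes that taper to
a ~2 px tip, so they thin to clean one-pixel skeletons.  The renderer keeps
per-leaf ground-truth masks internally, which lets tests verify occlusion
flags, skeleton endpoint counts and heatmap geometry against known geometry.

Everything is deterministic: the same spec (including seed) renders the same
bytes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .manifest import write_manifest

#: RNG stream tags: background jitter vs plant geometry vs distractor blobs.
_STREAM_JITTER, _STREAM_PLANT, _STREAM_BLOBS = 0, 1, 2

#: Seed of the *static* scene structure, shared by every render.
_STRUCTURE_SEED = 20230189


class GeometryError(ValueError):
    """Requested plant geometry cannot be drawn on the canvas."""


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Generative parameters for one rendered plant.

    Parameters
    ----------
    leaf_count:
        Number of leaf strokes to draw (>= 1); this is the regression label.
    stem_height_frac:
        Stem height as a fraction of image height, in (0, 1].
    leaf_length_range:
        Min/max leaf stroke length in pixels.  ``None`` derives a range from
        the canvas height (18%–33%).
    leaf_width_px:
        Stroke width at the leaf base; tips taper to ~2 px.
    curvature:
        Dimensionless bend of the leaf arc (0 = straight).
    occlusion:
        Force at least one pair of leaf strokes to intersect.
    illumination_jitter:
        Half-range of the uniform per-image brightness offset (gray levels).
    noise_blob_count:
        Number of small dark distractor blobs (grass/soil analogues) added to
        plant images only.
    canvas_size:
        (height, width) in pixels.
    seed:
        RNG seed; identical specs render bit-identical images.
    contrast_margin:
        Minimum gray-level gap between the plant and the mean background.
    """

    leaf_count: int = 4
    stem_height_frac: float = 0.55
    leaf_length_range: tuple[int, int] | None = None
    leaf_width_px: int = 7
    curvature: float = 0.35
    occlusion: bool = False
    illumination_jitter: float = 6.0
    noise_blob_count: int = 3
    canvas_size: tuple[int, int] = (512, 512)
    seed: int = 0
    contrast_margin: int = 60

    def __post_init__(self):
        if self.leaf_count < 1:
            raise ValueError(f"leaf_count must be >= 1, got {self.leaf_count}")
        h, w = self.canvas_size
        if h < 1 or w < 1:
            raise ValueError(f"canvas_size must be positive, got {self.canvas_size}")
        if not (0 < self.stem_height_frac <= 1):
            raise ValueError("stem_height_frac must be in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    def lengths(self) -> tuple[int, int]:
        if self.leaf_length_range is not None:
            return self.leaf_length_range
        h = self.canvas_size[0]
        return (max(8, int(0.18 * h)), max(10, int(0.33 * h)))


@dataclass
class PlantRender:
    """A rendered plant plus the internal ground truth the label came from."""

    image: np.ndarray  # HxWx3 uint8
    leaf_count: int
    plant_mask: np.ndarray  # bool, stem + leaves (the pixels a segmenter should find)
    stem_mask: np.ndarray
    leaf_masks: list[np.ndarray]
    blob_mask: np.ndarray
    tip_points: list[tuple[int, int]]  # (row, col) of each leaf tip
    attach_points: list[tuple[int, int]]
    spec: SyntheticPlantSpec = field(repr=False)


# ---------------------------------------------------------------------------
# low-level raster helpers


def _disk_indices(r: int, c: int, radius: int, h: int, w: int):
    rr, cc = np.ogrid[
        max(r - radius, 0) : min(r + radius + 1, h),
        max(c - radius, 0) : min(c + radius + 1, w),
    ]
    sel = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    return rr, cc, sel


def _stroke(mask: np.ndarray, points: np.ndarray, radii: np.ndarray) -> None:
    """Paint disks of varying radius along a polyline into a bool mask."""
    h, w = mask.shape
    for (r, c), rad in zip(points, radii):
        ri, ci = int(round(r)), int(round(c))
        if ri + rad < 0 or ri - rad >= h or ci + rad < 0 or ci - rad >= w:
            continue
        rr, cc, sel = _disk_indices(ri, ci, int(rad), h, w)
        region = mask[rr.ravel()[0] : rr.ravel()[-1] + 1, cc.ravel()[0] : cc.ravel()[-1] + 1]
        region[sel] = True


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


# ---------------------------------------------------------------------------
# background


def render_background(spec: SyntheticPlantSpec) -> np.ndarray:
    """Render the plant-free scene: equipment structure, pot, illumination jitter.

    The structure (rails, poles, panel, pot, low-frequency texture) is static
    across all specs; only the brightness offset varies with ``spec.seed``.
    """
    h, w = spec.canvas_size
    rs = np.random.default_rng(_STRUCTURE_SEED)
    base = np.full((h, w, 3), 178.0)

    # smooth low-amplitude texture so the background is not flat
    tex = gaussian_filter(rs.normal(0.0, 1.0, size=(h, w)), sigma=max(2, h // 64))
    if tex.std() > 0:
        tex = tex / tex.std() * 5.0
    base += tex[:, :, None]

    # vertical poles and a horizontal rail, as on a greenhouse imaging rig
    for frac in (0.12, 0.88):
        c0 = int(frac * w)
        base[:, max(0, c0 - w // 90) : c0 + max(1, w // 90), :] = 128.0
    r0 = int(0.14 * h)
    base[max(0, r0 - h // 120) : r0 + max(2, h // 100), :, :] = 118.0
    # a matte panel in the upper-left quadrant
    base[int(0.05 * h) : int(0.12 * h), int(0.2 * w) : int(0.45 * w), :] = 152.0

    # dark pot at the bottom center (part of the scene, present in every image)
    pot_top, pot_bot = int(0.80 * h), int(0.93 * h)
    half = max(2, int(0.09 * w))
    for r in range(pot_top, pot_bot):
        # slight taper toward the bottom
        shrink = int(0.25 * half * (r - pot_top) / max(1, pot_bot - pot_top))
        base[r, w // 2 - half + shrink : w // 2 + half - shrink] = (52.0, 40.0, 32.0)

    jitter = 0.0
    if spec.illumination_jitter > 0:
        jitter = spec.rng(_STREAM_JITTER).uniform(
            -spec.illumination_jitter, spec.illumination_jitter
        )
    return np.clip(base + jitter, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# plant


def _leaf_geometry(rng, attach, side, spec: SyntheticPlantSpec):
    """Sample one leaf's Bézier control points; returns (p0, p1, p2)."""
    lo, hi = spec.lengths()
    length = rng.uniform(lo, hi)
    phi = math.radians(rng.uniform(35.0, 65.0))  # angle from vertical
    ar, ac = attach
    tip = (ar - length * math.cos(phi), ac + side * length * math.sin(phi))
    mid = ((ar + tip[0]) / 2.0, (ac + tip[1]) / 2.0)
    # perpendicular to the chord, bending the arc upward
    d = (tip[0] - ar, tip[1] - ac)
    norm = math.hypot(*d) or 1.0
    perp = (-d[1] / norm, d[0] / norm)
    bend = spec.curvature * length * (1 if side < 0 else -1)
    p1 = (mid[0] + bend * perp[0], mid[1] + bend * perp[1])
    return (ar, ac), p1, tip


def _draw_leaf(spec: SyntheticPlantSpec, p0, p1, p2) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = spec.canvas_size
    n = max(16, int(2.5 * math.hypot(p2[0] - p0[0], p2[1] - p0[1])))
    pts = _bezier(p0, p1, p2, n)
    inside = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    if not inside.any():
        raise GeometryError("leaf stroke lies entirely outside the canvas")
    # taper from the base half-width down to a ~2 px tip
    t = np.linspace(0.0, 1.0, n)
    radii = np.maximum(1, np.round(spec.leaf_width_px / 2.0 * (1.0 - 0.75 * t))).astype(int)
    mask = np.zeros((h, w), dtype=bool)
    _stroke(mask, pts, radii)
    tip = (int(round(pts[-1, 0])), int(round(pts[-1, 1])))
    return mask, tip


def render_plant(spec: SyntheticPlantSpec) -> tuple[np.ndarray, int]:
    """Render a plant image; returns ``(image, leaf_count)``."""
    r = render_plant_detailed(spec)
    return r.image, r.leaf_count


def render_plant_detailed(spec: SyntheticPlantSpec) -> PlantRender:
    """Render a plant image and keep the per-leaf ground-truth masks.

    The stem rises from the pot top; leaves attach alternately left/right at
    evenly spaced heights.  With ``occlusion=True`` the topmost two leaves are
    re-aimed (deterministically) until two strokes intersect.
    """
    h, w = spec.canvas_size
    background = render_background(spec)
    rng = spec.rng(_STREAM_PLANT)

    pot_top = int(0.80 * h)
    stem_base = (pot_top + max(1, h // 100), w // 2 + int(rng.integers(-w // 50, w // 50 + 1)))
    stem_top = max(int(0.04 * h), int(stem_base[0] - spec.stem_height_frac * h))
    stem_w = max(1, round(h / 340))

    stem_mask = np.zeros((h, w), dtype=bool)
    rows = np.arange(stem_top, stem_base[0])
    cols = np.clip(stem_base[1] + np.zeros_like(rows), 0, w - 1)
    _stroke(stem_mask, np.stack([rows, cols], axis=1), np.full(len(rows), stem_w))

    # attachment heights: from just above the pot up to just below the stem top
    lo_r = stem_base[0] - int(0.08 * h)
    hi_r = stem_top + int(0.03 * h)
    attach_rows = np.linspace(lo_r, hi_r, spec.leaf_count).round().astype(int)
    first_side = int(rng.choice((-1, 1)))
    sides = [first_side * (-1) ** i for i in range(spec.leaf_count)]

    leaf_masks: list[np.ndarray] = []
    tips: list[tuple[int, int]] = []
    attaches: list[tuple[int, int]] = []
    for i in range(spec.leaf_count):
        attach = (int(attach_rows[i]), stem_base[1])
        p0, p1, p2 = _leaf_geometry(rng, attach, sides[i], spec)
        mask, tip = _draw_leaf(spec, p0, p1, p2)
        leaf_masks.append(mask)
        tips.append(tip)
        attaches.append(attach)

    if spec.occlusion and spec.leaf_count >= 2:
        # re-aim the top leaf across its neighbour until the strokes intersect
        j, k = spec.leaf_count - 1, spec.leaf_count - 2
        tries = 0
        while not (leaf_masks[j] & leaf_masks[k]).any():
            if tries >= 40:
                raise GeometryError("could not realize the requested occlusion")
            attach = attaches[j]
            p0, p1, p2 = _leaf_geometry(rng, attach, sides[k], spec)
            # pull the tip toward the neighbour's midpoint so the strokes cross
            target = ((attaches[k][0] + tips[k][0]) / 2.0, (attaches[k][1] + tips[k][1]) / 2.0)
            p2 = (0.3 * p2[0] + 0.7 * (2 * target[0] - attach[0]),
                  0.3 * p2[1] + 0.7 * (2 * target[1] - attach[1]))
            leaf_masks[j], tips[j] = _draw_leaf(spec, p0, p1, p2)
            tries += 1

    plant_mask = stem_mask.copy()
    for m in leaf_masks:
        plant_mask |= m

    # plant paint: dark green, scaled so its luma sits contrast_margin below
    # the mean background level
    bg_mean = float(background.mean())
    target = max(12.0, bg_mean - spec.contrast_margin)
    base_rgb = np.array([45.0, 92.0, 38.0])
    luma = float(base_rgb @ [0.299, 0.587, 0.114])
    scale = min(2.5, target / luma)
    image = background.astype(np.float64)
    leaf_rgb = np.clip(base_rgb * scale, 0, 255)
    stem_rgb = np.clip(np.array([55.0, 100.0, 45.0]) * scale, 0, 255)
    for m, tint in zip(leaf_masks, rng.uniform(-8, 8, size=spec.leaf_count)):
        image[m] = np.clip(leaf_rgb + tint, 0, 255)
    image[stem_mask & ~np.logical_or.reduce(leaf_masks)] = stem_rgb

    # distractor blobs (grass/soil analogues) off the plant
    blob_rng = spec.rng(_STREAM_BLOBS)
    blob_mask = np.zeros((h, w), dtype=bool)
    placed = 0
    attempts = 0
    while placed < spec.noise_blob_count and attempts < 200:
        attempts += 1
        br = int(blob_rng.integers(int(0.05 * h), int(0.95 * h)))
        bc = int(blob_rng.integers(int(0.05 * w), int(0.95 * w)))
        rad = int(blob_rng.integers(2, max(3, h // 128) + 1))
        rr, cc, sel = _disk_indices(br, bc, rad + 6, h, w)
        near = np.zeros((h, w), dtype=bool)
        near[rr.ravel()[0] : rr.ravel()[-1] + 1, cc.ravel()[0] : cc.ravel()[-1] + 1][sel] = True
        if (near & plant_mask).any():
            continue
        rr, cc, sel = _disk_indices(br, bc, rad, h, w)
        region = blob_mask[rr.ravel()[0] : rr.ravel()[-1] + 1, cc.ravel()[0] : cc.ravel()[-1] + 1]
        region[sel] = True
        placed += 1
    image[blob_mask] = (95.0, 84.0, 70.0)

    return PlantRender(
        image=image.round().astype(np.uint8),
        leaf_count=spec.leaf_count,
        plant_mask=plant_mask,
        stem_mask=stem_mask,
        leaf_masks=leaf_masks,
        blob_mask=blob_mask,
        tip_points=tips,
        attach_points=attaches,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# dataset


def _split_sizes(n: int, fracs: tuple[float, float, float]) -> list[int]:
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fracs}")
    floors = [int(math.floor(n * f)) for f in fracs]
    remainder = n - sum(floors)
    # largest-remainder apportionment
    residues = sorted(
        range(3), key=lambda i: (n * fracs[i]) - math.floor(n * fracs[i]), reverse=True
    )
    for i in range(remainder):
        floors[residues[i % 3]] += 1
    for size, frac in zip(floors, fracs):
        if frac > 0 and size == 0:
            raise ValueError(f"n={n} too small for split fractions {fracs}")
    return floors


def make_dataset(
    out_dir: str | os.PathLike,
    n: int,
    leaf_range: tuple[int, int] = (2, 8),
    occluded_fraction: float = 0.0,
    split_fracs: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    canvas_size: tuple[int, int] = (512, 512),
    n_backgrounds: int = 50,
    species: str = "sorghum",
    spec_overrides: dict | None = None,
):
    """Generate a dataset on disk: plant PNGs, background PNGs, manifest CSV.

    Leaf counts are drawn uniformly from ``leaf_range`` (inclusive); exactly
    ``floor(occluded_fraction * n)`` images are rendered with a forced leaf
    crossing.  Returns ``(manifest, manifest_path, background_paths)``.
    """
    import pandas as pd

    if leaf_range[0] < 1 or leaf_range[1] < leaf_range[0]:
        raise ValueError(f"invalid leaf_range {leaf_range}")
    sizes = _split_sizes(n, split_fracs)
    rng = np.random.default_rng(seed)

    counts = rng.integers(leaf_range[0], leaf_range[1] + 1, size=n)
    n_occluded = int(math.floor(occluded_fraction * n))
    occluded = np.zeros(n, dtype=bool)
    occluded[rng.permutation(n)[:n_occluded]] = True
    splits = np.array(
        ["train"] * sizes[0] + ["val"] * sizes[1] + ["test"] * sizes[2], dtype=object
    )[rng.permutation(n)]

    out_dir = os.fspath(out_dir)
    img_dir = os.path.join(out_dir, "images")
    bg_dir = os.path.join(out_dir, "backgrounds")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(bg_dir, exist_ok=True)

    rows = []
    renders = []
    for i in range(n):
        spec = SyntheticPlantSpec(
            leaf_count=int(counts[i]),
            occlusion=bool(occluded[i]),
            canvas_size=canvas_size,
            seed=int((seed * 1_000_003 + i) % 2**31),
            **(spec_overrides or {}),
        )
        render = render_plant_detailed(spec)
        name = f"plant_{i:05d}.png"
        Image.fromarray(render.image).save(os.path.join(img_dir, name))
        renders.append(render)
        rows.append(
            dict(
                image_id=f"plant_{i:05d}",
                path=os.path.join("images", name),
                leaf_count=int(counts[i]),
                split=str(splits[i]),
                species=species,
                view_angle_deg=0,
                occluded=bool(occluded[i]),
            )
        )

    bg_paths = []
    base_spec = SyntheticPlantSpec(canvas_size=canvas_size, **(spec_overrides or {}))
    for i in range(max(n_backgrounds, 0)):
        spec = replace(base_spec, seed=int((seed * 1_000_003 + n + i) % 2**31))
        name = f"background_{i:05d}.png"
        path = os.path.join(bg_dir, name)
        Image.fromarray(render_background(spec)).save(path)
        bg_paths.append(path)

    manifest = pd.DataFrame(rows)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    write_manifest(manifest, manifest_path)
    return manifest, manifest_path, bg_paths
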