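"""Dataset manifest I/O.

A manifest is a CSV binding image files to integer leaf-count labels and
train/val/test splits.  Columns::

    image_id,path,leaf_count,split,species,view_angle_deg,occluded[,augmentation]

``path`` is stored relative to the manifest file.  The optional
``augmentation`` column records which geometric transform produced the row
("identity" for originals); non-identity values are only legal on train rows.
"""

from __future__ import annotations

import os

import pandas as pd

MANIFEST_COLUMNS = [
    "image_id",
    "path",
    "leaf_count",
    "split",
    "species",
    "view_angle_deg",
    "occluded",
]
OPTIONAL_COLUMNS = ["augmentation"]
VALID_SPLITS = {"train", "val", "test"}

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class ManifestError(ValueError):
    """A manifest violates its schema; the message names the row and field."""


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ManifestError(f"row {row}: field 'occluded' has non-boolean value {value!r}")


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a manifest frame, returning a clean copy."""
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"missing columns: {', '.join(missing)}")
    df = df.copy()
    counts = []
    for row, value in enumerate(df["leaf_count"]):
        try:
            as_float = float(value)
            as_int = int(as_float)
            if as_int != as_float:
                raise ValueError
        except (TypeError, ValueError):
            raise ManifestError(
                f"row {row}: field 'leaf_count' is not an integer: {value!r}"
            ) from None
        if as_int < 1:
            raise ManifestError(f"row {row}: field 'leaf_count' must be >= 1, got {as_int}")
        counts.append(as_int)
    df["leaf_count"] = pd.array(counts, dtype="int64")
    for row, value in enumerate(df["split"]):
        if str(value) not in VALID_SPLITS:
            raise ManifestError(f"row {row}: field 'split' has unknown value {value!r}")
    df["occluded"] = [_parse_bool(v, i) for i, v in enumerate(df["occluded"])]
    df["view_angle_deg"] = pd.to_numeric(df["view_angle_deg"])
    if "augmentation" in df.columns:
        bad = df[(df["augmentation"] != "identity") & (df["split"] != "train")]
        if len(bad):
            row = int(bad.index[0])
            raise ManifestError(
                f"row {row}: field 'augmentation' is {bad['augmentation'].iloc[0]!r} "
                "on a non-train row"
            )
    return df.reset_index(drop=True)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a manifest CSV."""
    df = pd.read_csv(path, dtype={"path": str, "split": str, "species": str})
    return validate_manifest(df)


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Validate and write a manifest CSV (round-trips with :func:`read_manifest`)."""
    df = validate_manifest(df)
    cols = MANIFEST_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def resolve_image_path(manifest_path: str | os.PathLike, rel_path: str) -> str:
    """Resolve a manifest-relative image path against the manifest location."""
    base = os.path.dirname(os.path.abspath(os.fspath(manifest_path)))
    return os.path.normpath(os.path.join(base, rel_path))
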