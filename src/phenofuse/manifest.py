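"""Dataset manifest handling.

A manifest is a pandas DataFrame with one row per image file. It drives every
pipeline stage: segmentation appends rows, augmentation adds derived rows,
splitting assigns partitions, feature extraction aligns its output rows to it.

Columns
-------
path : str
    Image file path, unique within a manifest.
class : str
    Line / cultivar label.
organ : str
    ``"pod"`` or ``"seed"``.
scan_id : str
    Identifier of the source scanner image.
object_index : int
    Index of the object within its scan (-1 for whole-scan rows).
area_px : int
    Foreground pixel count of the segmented object (0 if unknown).
split : str
    One of ``train``, ``val``, ``test``, ``unassigned``.
is_augmented : bool
    True for rows produced by the augmentation stage.
source_path : str
    For augmented rows, the path of the original image; empty otherwise.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataError

MANIFEST_COLUMNS = [
    "path",
    "class",
    "organ",
    "scan_id",
    "object_index",
    "area_px",
    "split",
    "is_augmented",
    "source_path",
]

SPLITS = ("train", "val", "test", "unassigned")
ORGANS = ("pod", "seed")


def new_manifest(rows: list[dict] | None = None) -> pd.DataFrame:
    """Create an empty (or pre-filled) manifest with the canonical schema."""
    df = pd.DataFrame(rows or [], columns=MANIFEST_COLUMNS)
    return _coerce(df)


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["object_index"] = df["object_index"].fillna(-1).astype(int)
    df["area_px"] = df["area_px"].fillna(0).astype(int)
    df["split"] = df["split"].fillna("unassigned").astype(str)
    df["is_augmented"] = df["is_augmented"].fillna(False).astype(bool)
    df["source_path"] = df["source_path"].fillna("").astype(str)
    for col in ("path", "class", "organ", "scan_id"):
        df[col] = df[col].astype(str)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    """Check schema, path uniqueness and augmentation provenance."""
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"manifest is missing columns: {sorted(missing)}")
    if df["path"].duplicated().any():
        dup = df.loc[df["path"].duplicated(), "path"].iloc[0]
        raise DataError(f"duplicate manifest path: {dup}")
    bad_split = set(df["split"]) - set(SPLITS)
    if bad_split:
        raise DataError(f"unknown split values: {sorted(bad_split)}")
    aug = df[df["is_augmented"]]
    if len(aug):
        originals = set(df.loc[~df["is_augmented"], "path"])
        orphans = set(aug["source_path"]) - originals
        if orphans:
            raise DataError(f"augmented rows reference missing sources: {sorted(orphans)[:3]}")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"path": str, "class": str, "organ": str, "scan_id": str},
                     keep_default_na=False, na_values=[])
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "source_path" else (False if col == "is_augmented" else
                                                       ("unassigned" if col == "split" else 0))
    df["is_augmented"] = df["is_augmented"].astype(str).str.lower().isin(["true", "1"])
    return _coerce(df[MANIFEST_COLUMNS])


def write_manifest(df: pd.DataFrame, path) -> None:
    validate_manifest(df)
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def append_rows(df: pd.DataFrame, rows: list[dict]) -> pd.DataFrame:
    """Append rows (dicts with manifest keys) and return a new manifest."""
    if not rows:
        return df
    return _coerce(pd.concat([df, pd.DataFrame(rows)], ignore_index=True))
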