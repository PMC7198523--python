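"""Reading and writing the localization-table CSV dialect.

One row per single-molecule localization, ThunderSTORM-style: ``frame``,
``x_nm``, ``y_nm`` are mandatory; ``photons``, ``width_px``, ``bg``,
``channel``, ``track_id`` and the ground-truth columns ``true_x``,
``true_y``, ``true_z`` are optional.  Unknown extra columns are preserved.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MANDATORY_COLUMNS = ("frame", "x_nm", "y_nm")
OPTIONAL_COLUMNS = (
    "photons",
    "width_px",
    "bg",
    "channel",
    "track_id",
    "true_x",
    "true_y",
    "true_z",
)


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization CSV, validating the mandatory columns.

    A zero-row file with a valid header is returned as an empty table.
    Non-numeric coordinates raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"localization file not found: {path}")
    table = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"localization table {path} is missing mandatory column(s): "
            + ", ".join(missing)
        )
    for col in ("x_nm", "y_nm"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        if coerced.isna().sum() > table[col].isna().sum():
            raise ValueError(f"non-numeric values in coordinate column {col!r}")
        table[col] = coerced
    return table


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table to CSV (no index column)."""
    table.to_csv(path, index=False)


def read_image_stack(path: str | Path):
    """Read a multi-page TIFF image stack as a (frames, y, x) float array."""
    import tifffile

    return tifffile.imread(path).astype(float)


def write_image_stack(stack, path: str | Path) -> None:
    """Write a (frames, y, x) array as a multi-page float32 TIFF."""
    import numpy as np
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype="float32"))
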