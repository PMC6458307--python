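"""Localization-table I/O and ROI selection.

The pipeline's lingua franca is a pandas DataFrame with one row per detected
blink and canonical columns::

    id           int      unique row id
    frame        int      0-based acquisition frame
    x, y         float    position in nm
    uncertainty  float    localization precision in nm (>= 0)
    intensity    float    photon count (optional information, 0 if unknown)
    channel      str      free-form channel label, e.g. "647" / "488"
    is_fiducial  bool     True for fiducial-bead localizations
    molecule_id  Int64    ground-truth emitter id (synthetic data), <NA> if unknown

On disk the table is a ThunderSTORM-compatible CSV whose header uses the
unit-annotated tokens ``x [nm]``, ``y [nm]``, ``uncertainty [nm]`` and
``intensity [photon]``.  Unknown extra columns are preserved untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import Region

COLUMNS = [
    "id",
    "frame",
    "x",
    "y",
    "uncertainty",
    "intensity",
    "channel",
    "is_fiducial",
    "molecule_id",
]

# canonical column -> CSV header token
_CSV_NAMES = {
    "id": "id",
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "uncertainty": "uncertainty [nm]",
    "intensity": "intensity [photon]",
    "channel": "channel",
    "is_fiducial": "is_fiducial",
    "molecule_id": "molecule_id",
}
_FROM_CSV = {v: k for k, v in _CSV_NAMES.items()}
_REQUIRED = ("frame", "x [nm]", "y [nm]")
_NUMERIC = ("id", "frame", "x", "y", "uncertainty", "intensity", "molecule_id")


class FormatError(ValueError):
    """The file is not a recognizable localization table."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the row number."""


def empty_table() -> pd.DataFrame:
    """A zero-row table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "id": pd.Series(dtype=np.int64),
            "frame": pd.Series(dtype=np.int64),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "uncertainty": pd.Series(dtype=float),
            "intensity": pd.Series(dtype=float),
            "channel": pd.Series(dtype=object),
            "is_fiducial": pd.Series(dtype=bool),
            "molecule_id": pd.Series(dtype="Int64"),
        }
    )


def make_table(
    x,
    y,
    frame=0,
    uncertainty=0.0,
    intensity=0.0,
    channel="647",
    is_fiducial=False,
    molecule_id=None,
) -> pd.DataFrame:
    """Build a canonical table from arrays (scalars are broadcast)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = len(x)

    def _col(v, dtype):
        arr = np.broadcast_to(np.asarray(v), (n,)).astype(dtype)
        return arr.copy()

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "frame": _col(frame, np.int64),
            "x": x,
            "y": _col(y, float),
            "uncertainty": _col(uncertainty, float),
            "intensity": _col(intensity, float),
            "channel": _col(channel, object),
            "is_fiducial": _col(is_fiducial, bool),
        }
    )
    if molecule_id is None:
        df["molecule_id"] = pd.array([pd.NA] * n, dtype="Int64")
    else:
        df["molecule_id"] = pd.array(
            np.broadcast_to(np.asarray(molecule_id), (n,)), dtype="Int64"
        )
    return df


def reindex_ids(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a fresh contiguous ``id`` column and row index."""
    out = table.reset_index(drop=True).copy()
    out["id"] = np.arange(len(out), dtype=np.int64)
    return out


def concat_tables(*tables: pd.DataFrame) -> pd.DataFrame:
    parts = [t for t in tables if len(t)]
    if not parts:
        return empty_table()
    return reindex_ids(pd.concat(parts, ignore_index=True))


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a table as ThunderSTORM-style CSV.

    Column order is fixed and nm values are printed with 2 decimals (well
    below localization uncertainty), so two writes of the same table are
    byte-identical.
    """
    df = table.copy()
    extra = [c for c in df.columns if c not in COLUMNS]
    df = df[[c for c in COLUMNS if c in df.columns] + extra]
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        name = _CSV_NAMES.get(col, col)
        if col in ("x", "y", "uncertainty", "intensity"):
            out[name] = df[col].map(lambda v: f"{v:.2f}")
        elif col == "is_fiducial":
            out[name] = df[col].map(lambda v: "1" if v else "0")
        elif col == "molecule_id":
            out[name] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
        else:
            out[name] = df[col].astype(str)
    out.to_csv(path, index=False, lineterminator="\n")


def read_localizations(path) -> pd.DataFrame:
    """Read a ThunderSTORM-style CSV into the canonical table.

    Raises
    ------
    FormatError
        If a mandatory column (frame, x [nm], y [nm]) is missing.
    ParseError
        If a numeric cell cannot be parsed; names the 1-based data row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for req in _REQUIRED:
        if req not in raw.columns:
            raise FormatError(f"missing required column {req!r}")

    df = pd.DataFrame(index=raw.index)
    extra_cols = {}
    for name in raw.columns:
        col = _FROM_CSV.get(name)
        if col is None:
            extra_cols[name] = raw[name]
            continue
        s = raw[name]
        if col in _NUMERIC:
            blank = s.str.strip() == ""
            num = pd.to_numeric(s.where(~blank), errors="coerce")
            bad = num.isna() & ~blank
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise ParseError(
                    f"non-numeric value {s[bad.idxmax()]!r} in column "
                    f"{name!r}, data row {row}"
                )
            df[col] = num
        elif col == "is_fiducial":
            df[col] = s.isin(("1", "True", "true", "TRUE"))
        else:
            df[col] = s
    n = len(df)
    if "id" not in df:
        df["id"] = np.arange(n, dtype=np.int64)
    if "uncertainty" not in df:
        df["uncertainty"] = 0.0
    if "intensity" not in df:
        df["intensity"] = 0.0
    if "channel" not in df:
        df["channel"] = "647"
    if "is_fiducial" not in df:
        df["is_fiducial"] = False
    if "molecule_id" not in df:
        df["molecule_id"] = pd.array([pd.NA] * n, dtype="Int64")
    else:
        df["molecule_id"] = df["molecule_id"].round().astype("Int64")

    df["id"] = df["id"].astype(np.int64)
    df["frame"] = df["frame"].astype(np.int64)
    for c in ("x", "y", "uncertainty", "intensity"):
        df[c] = df[c].astype(float)
    df = df[COLUMNS]
    for name, s in extra_cols.items():
        df[name] = s
    return df


def select_center_roi(
    table: pd.DataFrame,
    roi_size: float = 3000.0,
    center: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, Region]:
    """Select a square analysis window (default 3 x 3 um) from a table.

    The window is centered on the centroid of the non-fiducial localizations
    (or on an explicit ``center`` override) and then, when the data's extent
    fits inside the window, nudged minimally so that no localization is cut
    off at the boundary; this makes repeated selection at the same size
    idempotent.  Returned coordinates are re-expressed relative to the
    window origin.
    """
    if len(table) == 0:
        raise ValueError("cannot select an ROI from an empty table")
    pts = table.loc[~table["is_fiducial"], ["x", "y"]].to_numpy(dtype=float)
    if len(pts) == 0:
        pts = table[["x", "y"]].to_numpy(dtype=float)
    if center is None:
        cx, cy = pts.mean(axis=0)
    else:
        cx, cy = center

    def _origin(c: float, vals: np.ndarray) -> float:
        o = c - roi_size / 2.0
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo < roi_size - 1e-6:  # window can cover everything: do so
            # the 1e-6 nm margin keeps the half-open upper bound robust to
            # floating-point cancellation at window scale
            o = min(o, lo)
            o = max(o, hi - roi_size + 1e-6)
        return o

    region = Region(
        _origin(cx, pts[:, 0]), _origin(cy, pts[:, 1]), roi_size, roi_size
    )
    inside = region.contains(table[["x", "y"]].to_numpy(dtype=float))
    out = table.loc[inside].copy()
    out["x"] = out["x"] - region.x0
    out["y"] = out["y"] - region.y0
    out = out.reset_index(drop=True)
    return out, Region(0.0, 0.0, roi_size, roi_size)
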