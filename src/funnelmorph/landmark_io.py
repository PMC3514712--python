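"""Reading and writing landmark configurations and specimen metadata.

Two file families are supported: the classic morphometric TPS record format
(``LM=``/``LM3=`` blocks with an ``ID=`` line) and plain CSV in either a wide
layout (one row per specimen, columns ``<landmark>_x`` ...) or a long layout
(one row per landmark with ``specimen_id, landmark, x, y[, z]`` columns).
Metadata (sex, group, predictor measurements) lives in a separate CSV keyed by
``specimen_id`` and is attached with strict one-to-one matching — missing
landmarks or unmatched specimens are errors, never silently dropped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "LandmarkFormatError",
    "read_tps",
    "write_tps",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_metadata_csv",
    "attach_metadata",
]

#: columns with reserved meaning in metadata tables; everything else numeric
RESERVED_METADATA_COLUMNS = ("specimen_id", "sex", "group")


class LandmarkFormatError(ValueError):
    """A landmark or metadata file violates its format contract."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's landmark coordinates.

    Attributes
    ----------
    specimen_id : str
        Unique specimen label.
    coords : (k, d) ndarray
        Landmark coordinates in the digitizer's units (mm assumed), d in {2, 3}.
    landmark_names : tuple of str
        Ordered landmark labels, one per row of ``coords``.
    """

    specimen_id: str
    coords: np.ndarray
    landmark_names: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "landmark_names", tuple(self.landmark_names))
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError(
                f"coords must be (k, 2) or (k, 3); got shape {coords.shape}"
            )
        k = coords.shape[0]
        if k < 3:
            raise ValueError(f"need at least 3 landmarks, got {k}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinates")
        if len(self.landmark_names) != k:
            raise ValueError(
                f"specimen {self.specimen_id!r}: {len(self.landmark_names)} landmark "
                f"names for {k} landmarks"
            )
        if len(set(self.landmark_names)) != k:
            raise ValueError(f"specimen {self.specimen_id!r}: duplicate landmark names")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class LandmarkDataset:
    """A set of same-landmark configurations plus a specimen metadata table.

    ``metadata`` always has a ``specimen_id`` column matching the
    configurations one-to-one, in the same order.
    """

    configurations: list[LandmarkConfiguration]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset needs at least one configuration")
        ref = self.configurations[0]
        for c in self.configurations[1:]:
            if c.landmark_names != ref.landmark_names:
                raise ValueError(
                    f"specimen {c.specimen_id!r} has landmark names differing from "
                    f"{ref.specimen_id!r}"
                )
            if c.d != ref.d:
                raise ValueError("mixed 2D/3D configurations in one dataset")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        if self.metadata is None:
            self.metadata = pd.DataFrame({"specimen_id": ids})
        if list(self.metadata["specimen_id"]) != ids:
            raise ValueError("metadata rows must match configuration order")

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def d(self) -> int:
        return self.configurations[0].d

    @property
    def landmark_names(self) -> tuple[str, ...]:
        return self.configurations[0].landmark_names

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an (n, k, d) array."""
        return np.stack([c.coords for c in self.configurations])


# ---------------------------------------------------------------------------
# TPS record format
# ---------------------------------------------------------------------------

def read_tps(path) -> LandmarkDataset:
    """Read a TPS landmark file (``LM=`` 2D / ``LM3=`` 3D records).

    Each record is an ``LM=``/``LM3=`` count line, that many whitespace-
    separated coordinate lines, then key lines of which ``ID=`` is required
    and ``SCALE=`` (applied multiplicatively to the coordinates) is honoured;
    ``IMAGE=`` and ``CURVES=`` are ignored.  Landmark names are not part of
    the format and are synthesised as ``lm01 ...``; attach real names via CSV
    or by rebuilding configurations.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    records: list[dict] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        upper = line.upper()
        if not (upper.startswith("LM=") or upper.startswith("LM3=")):
            raise LandmarkFormatError(
                f"{path}: expected LM=/LM3= record start, got {line!r}"
            )
        d = 3 if upper.startswith("LM3=") else 2
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise LandmarkFormatError(f"{path}: bad landmark count in {line!r}") from exc
        coords = []
        while len(coords) < k and i < len(lines):
            row = lines[i].strip()
            if "=" in row:  # ran into the next key line early
                break
            i += 1
            if not row:
                continue
            parts = row.split()
            if len(parts) != d:
                raise LandmarkFormatError(
                    f"{path}: record {len(records) + 1}: coordinate line {row!r} "
                    f"has {len(parts)} values, expected {d}"
                )
            coords.append([float(p) for p in parts])
        if len(coords) != k:
            raise LandmarkFormatError(
                f"{path}: record {len(records) + 1}: declared {k} landmarks but "
                f"found {len(coords)} coordinate lines"
            )
        spec_id = None
        scale = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            up = row.upper()
            if up.startswith(("LM=", "LM3=")):
                break
            i += 1
            if up.startswith("ID="):
                spec_id = row.split("=", 1)[1].strip()
            elif up.startswith("SCALE="):
                scale = float(row.split("=", 1)[1])
            # IMAGE=, CURVES= and other keys: ignored
        if spec_id is None:
            raise LandmarkFormatError(
                f"{path}: record {len(records) + 1}: missing ID= line"
            )
        arr = np.array(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        records.append({"id": spec_id, "coords": arr, "d": d})

    if not records:
        raise LandmarkFormatError(f"{path}: no landmark records found")
    dims = {r["d"] for r in records}
    if len(dims) > 1:
        raise LandmarkFormatError(f"{path}: mixed 2D and 3D records")
    k = records[0]["coords"].shape[0]
    for r in records:
        if r["coords"].shape[0] != k:
            raise LandmarkFormatError(
                f"{path}: record {r['id']!r} has {r['coords'].shape[0]} landmarks, "
                f"expected {k}"
            )
    names = tuple(f"lm{j + 1:02d}" for j in range(k))
    configs = [
        LandmarkConfiguration(r["id"], r["coords"], names) for r in records
    ]
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset as TPS records (coordinates to 6 decimal places)."""
    key = "LM3" if dataset.d == 3 else "LM"
    buf = io.StringIO()
    for c in dataset.configurations:
        buf.write(f"{key}={c.k}\n")
        for row in c.coords:
            buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write(f"ID={c.specimen_id}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# CSV layouts
# ---------------------------------------------------------------------------

def read_landmark_csv(path, layout: str = "wide") -> LandmarkDataset:
    """Read landmarks from CSV.

    ``layout='wide'``: one row per specimen, a ``specimen_id`` column and
    coordinate columns ``<name>_x, <name>_y[, <name>_z]``.
    ``layout='long'``: columns ``specimen_id, landmark, x, y[, z]``; landmark
    ordering is taken from the first specimen's row order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "wide":
        return _from_wide(df, path)
    if layout == "long":
        return _from_long(df, path)
    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def _from_wide(df: pd.DataFrame, path) -> LandmarkDataset:
    if "specimen_id" not in df.columns:
        raise LandmarkFormatError(f"{path}: wide layout needs a specimen_id column")
    coord_cols = [c for c in df.columns if c != "specimen_id"]
    names: list[str] = []
    for c in coord_cols:
        if "_" not in c or c.rsplit("_", 1)[1] not in ("x", "y", "z"):
            raise LandmarkFormatError(
                f"{path}: column {c!r} is not of the form <landmark>_x/y/z"
            )
        base = c.rsplit("_", 1)[0]
        if base not in names:
            names.append(base)
    axes = ["x", "y", "z"] if any(c.endswith("_z") for c in coord_cols) else ["x", "y"]
    configs = []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"])
        coords = np.empty((len(names), len(axes)))
        for li, name in enumerate(names):
            for ai, ax in enumerate(axes):
                col = f"{name}_{ax}"
                if col not in df.columns or pd.isna(row[col]):
                    raise LandmarkFormatError(
                        f"{path}: specimen {sid!r}: missing coordinate "
                        f"{ax!r} for landmark {name!r}"
                    )
                coords[li, ai] = float(row[col])
        configs.append(LandmarkConfiguration(sid, coords, tuple(names)))
    return LandmarkDataset(configs)


def _from_long(df: pd.DataFrame, path) -> LandmarkDataset:
    needed = {"specimen_id", "landmark", "x", "y"}
    if not needed.issubset(df.columns):
        raise LandmarkFormatError(
            f"{path}: long layout needs columns {sorted(needed)}"
        )
    axes = ["x", "y", "z"] if "z" in df.columns else ["x", "y"]
    first = str(df["specimen_id"].iloc[0])
    names = [str(v) for v in df.loc[df["specimen_id"].astype(str) == first, "landmark"]]
    if len(set(names)) != len(names):
        raise LandmarkFormatError(f"{path}: specimen {first!r}: duplicate landmarks")
    configs = []
    for sid, grp in df.groupby(df["specimen_id"].astype(str), sort=False):
        got = {str(r["landmark"]): r for _, r in grp.iterrows()}
        missing = [n for n in names if n not in got]
        if missing or len(got) != len(names):
            extra = sorted(set(got) - set(names))
            raise LandmarkFormatError(
                f"{path}: specimen {sid!r}: missing landmarks {missing}, "
                f"unexpected {extra}"
            )
        coords = np.empty((len(names), len(axes)))
        for li, name in enumerate(names):
            for ai, ax in enumerate(axes):
                val = got[name][ax]
                if pd.isna(val):
                    raise LandmarkFormatError(
                        f"{path}: specimen {sid!r}: missing coordinate {ax!r} "
                        f"for landmark {name!r}"
                    )
                coords[li, ai] = float(val)
        configs.append(LandmarkConfiguration(str(sid), coords, tuple(names)))
    return LandmarkDataset(configs)


def write_landmark_csv(dataset: LandmarkDataset, path, layout: str = "wide") -> None:
    """Write landmarks as CSV in the given layout, full float precision."""
    axes = ["x", "y", "z"][: dataset.d]
    if layout == "wide":
        cols: dict[str, list] = {"specimen_id": dataset.specimen_ids}
        for li, name in enumerate(dataset.landmark_names):
            for ai, ax in enumerate(axes):
                cols[f"{name}_{ax}"] = [
                    repr(float(c.coords[li, ai])) for c in dataset.configurations
                ]
        pd.DataFrame(cols).to_csv(path, index=False)
    elif layout == "long":
        rows = []
        for c in dataset.configurations:
            for li, name in enumerate(c.landmark_names):
                rows.append(
                    {"specimen_id": c.specimen_id, "landmark": name}
                    | {ax: repr(float(c.coords[li, ai])) for ai, ax in enumerate(axes)}
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata_csv(path) -> pd.DataFrame:
    """Read a metadata table; requires specimen_id, sex and group columns."""
    df = pd.read_csv(path, dtype={"specimen_id": str}, float_precision="round_trip")
    missing = [c for c in RESERVED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkFormatError(f"{path}: metadata missing columns {missing}")
    return df


def attach_metadata(dataset: LandmarkDataset, table: pd.DataFrame) -> LandmarkDataset:
    """Join a metadata table onto a dataset with strict one-to-one matching.

    Every configuration must match exactly one table row; unmatched or
    duplicated specimen ids raise.  Non-reserved columns are validated as
    numeric predictors.  Returns a new dataset with metadata rows reordered
    to configuration order.
    """
    if "specimen_id" not in table.columns:
        raise ValueError("metadata table needs a specimen_id column")
    table = table.copy()
    table["specimen_id"] = table["specimen_id"].astype(str)
    ids = dataset.specimen_ids
    counts = table["specimen_id"].value_counts()
    dupes = sorted(counts[counts > 1].index)
    if dupes:
        raise ValueError(f"duplicate specimen ids in metadata: {dupes}")
    missing = sorted(set(ids) - set(table["specimen_id"]))
    if missing:
        raise ValueError(f"specimens missing from metadata: {missing}")
    extra = sorted(set(table["specimen_id"]) - set(ids))
    if extra:
        raise ValueError(f"metadata rows without configurations: {extra}")
    for col in table.columns:
        if col in RESERVED_METADATA_COLUMNS:
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table[col].notna() & coerced.isna()
        if bad.any():
            raise ValueError(
                f"predictor column {col!r} has non-numeric values "
                f"(e.g. {table.loc[bad, col].iloc[0]!r})"
            )
        table[col] = coerced
    ordered = table.set_index("specimen_id").loc[ids].reset_index()
    return replace(dataset, metadata=ordered)
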