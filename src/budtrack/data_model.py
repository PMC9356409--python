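"""Core domain types and I/O for label movies and cell-cycle annotation tables.

A *label movie* is an ordered stack of 2D integer-labelled frames (0 =
background), one frame per time point, as produced by any segmentation
pipeline.  A *annotation table* stores the per-(frame, cell) cell-cycle state
of a budding-yeast pedigree: stage (``G1`` or ``S/G2/M``), generation number,
the mother/bud relationship and the reciprocal partner ID, plus emergence and
division frame indices.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; frame indices are 0-based.
* Missing relative/emergence/division values are encoded as ``-1``.
* ``pixel_size_um`` defaults to 1.0 so geometric outputs are in pixel units;
  femtolitre conversion is ``voxels * pixel_size_um**3`` (isotropy assumed).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

G1 = "G1"
S_G2_M = "S/G2/M"
STAGES = (G1, S_G2_M)
MOTHER = "mother"
BUD = "bud"

#: Canonical annotation-CSV column order (the cell-cycle output schema).
ANNOT_COLUMNS = [
    "frame_i",
    "Cell_ID",
    "cell_cycle_stage",
    "generation_num",
    "relative_ID",
    "relationship",
    "emerg_frame_i",
    "division_frame_i",
    "is_history_known",
]
#: Optional flag columns appended after the canonical set when present.
OPTIONAL_COLUMNS = ["is_cell_excluded", "is_cell_dead"]

_INT_COLUMNS = [
    "frame_i",
    "Cell_ID",
    "generation_num",
    "relative_ID",
    "emerg_frame_i",
    "division_frame_i",
]


class FormatError(ValueError):
    """Raised for non-integer pixel data or a malformed annotation CSV."""


class ShapeError(ValueError):
    """Raised when frames of one movie disagree in shape."""


class AnnotationValidationError(ValueError):
    """Raised when an annotation table violates its invariants.

    The ``violations`` attribute carries the full list of
    :class:`Violation` descriptors.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations)
        super().__init__(f"annotation table invalid: {msg}")


@dataclass(frozen=True)
class Violation:
    """One violated table invariant at (frame_i, Cell_ID)."""

    frame_i: int
    cell_id: int
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] frame {self.frame_i}, cell {self.cell_id}: {self.message}"


@dataclass
class LabelFrame:
    """A single 2D integer-labelled frame; 0 is background."""

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ShapeError(f"label frame must be 2D, got {self.pixels.ndim}D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError(f"label frame must be integer-valued, got dtype {self.pixels.dtype}")
        if self.pixels.size and self.pixels.min() < 0:
            raise FormatError("label frame contains negative labels")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the frame."""
        lab = np.unique(self.pixels)
        return lab[lab > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.pixels == label

    def copy(self) -> "LabelFrame":
        return LabelFrame(self.pixels.copy(), self.frame_index)


@dataclass
class LabelMovie:
    """Ordered stack of label frames sharing one grid."""

    stack: np.ndarray  # (T, H, W) integer array
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim == 2:
            self.stack = self.stack[None]
        if self.stack.ndim != 3:
            raise ShapeError(f"label movie must be (T, H, W), got shape {self.stack.shape}")
        if not np.issubdtype(self.stack.dtype, np.integer):
            raise FormatError(f"label movie must be integer-valued, got dtype {self.stack.dtype}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def from_frames(cls, frames: Sequence[LabelFrame | np.ndarray], pixel_size_um: float = 1.0) -> "LabelMovie":
        arrs = [f.pixels if isinstance(f, LabelFrame) else np.asarray(f) for f in frames]
        if not arrs:
            raise ValueError("movie needs at least one frame")
        shape0 = arrs[0].shape
        for i, a in enumerate(arrs):
            if a.shape != shape0:
                raise ShapeError(f"frame {i} has shape {a.shape}, expected {shape0}")
        return cls(np.stack(arrs), pixel_size_um)

    def __len__(self) -> int:
        return self.stack.shape[0]

    def __getitem__(self, i: int) -> LabelFrame:
        return LabelFrame(self.stack[i], frame_index=i)

    def __iter__(self) -> Iterator[LabelFrame]:
        for i in range(len(self)):
            yield self[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    def max_label(self) -> int:
        return int(self.stack.max(initial=0))

    def copy(self) -> "LabelMovie":
        return LabelMovie(self.stack.copy(), self.pixel_size_um)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_label_movie(path: str | Path, pixel_size_um: float = 1.0) -> LabelMovie:
    """Read a label movie from a multi-page TIFF or a directory of TIFFs.

    Per-frame TIFFs in a directory are ordered lexicographically. Pixel data
    must be integer; float-valued images raise :class:`FormatError`.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ShapeError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"label TIFF must contain integer labels, got dtype {arr.dtype}")
    return LabelMovie(arr, pixel_size_um=pixel_size_um)


def write_label_movie(movie: LabelMovie, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF (atomic: temp file + rename)."""
    _atomic_binary_write(
        Path(path), lambda f: tifffile.imwrite(f, movie.stack, photometric="minisblack")
    )


def read_intensity_movie(path: str | Path) -> np.ndarray:
    """Read an intensity-channel stack as a (T, H, W) float array."""
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ShapeError(f"intensity stack must be (T, H, W), got {arr.shape}")
    return arr


def _atomic_binary_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Per-(frame, cell) cell-cycle records backed by a pandas DataFrame.

    One row per (frame_i, Cell_ID); columns are :data:`ANNOT_COLUMNS` plus,
    optionally, :data:`OPTIONAL_COLUMNS`.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ANNOT_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ANNOT_COLUMNS:
            if col not in df.columns:
                if col == "cell_cycle_stage":
                    df[col] = pd.Series(dtype=object)
                elif col == "relationship":
                    df[col] = pd.Series(dtype=object)
                elif col == "is_history_known":
                    df[col] = pd.Series(dtype=bool)
                else:
                    df[col] = pd.Series(dtype=np.int64)
        for col in _INT_COLUMNS:
            df[col] = df[col].astype(np.int64)
        df["is_history_known"] = df["is_history_known"].astype(bool)
        ordered = ANNOT_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
        self.df = df[ordered].reset_index(drop=True)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_rows(cls, rows: Sequence[dict]) -> "AnnotationTable":
        return cls(pd.DataFrame(list(rows)))

    def copy(self) -> "AnnotationTable":
        return AnnotationTable(self.df.copy())

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        a = self.sorted().df.reset_index(drop=True)
        b = other.sorted().df.reset_index(drop=True)
        return a.equals(b)

    def sorted(self) -> "AnnotationTable":
        return AnnotationTable(self.df.sort_values(["frame_i", "Cell_ID"], kind="stable"))

    # -- row access -----------------------------------------------------------

    def get(self, frame_i: int, cell_id: int) -> pd.Series | None:
        sel = self.df[(self.df["frame_i"] == frame_i) & (self.df["Cell_ID"] == cell_id)]
        if sel.empty:
            return None
        return sel.iloc[0]

    def set_values(self, frame_i: int, cell_id: int, **values) -> None:
        mask = (self.df["frame_i"] == frame_i) & (self.df["Cell_ID"] == cell_id)
        if not mask.any():
            raise KeyError(f"no row for frame {frame_i}, cell {cell_id}")
        for k, v in values.items():
            self.df.loc[mask, k] = v

    def add_row(self, **values) -> None:
        row = {c: values.get(c) for c in ANNOT_COLUMNS}
        for c in OPTIONAL_COLUMNS:
            if c in self.df.columns or c in values:
                row[c] = values.get(c, False)
        missing = [c for c, v in row.items() if v is None]
        if missing:
            raise ValueError(f"add_row missing fields: {missing}")
        self.df = pd.concat([self.df, pd.DataFrame([row])], ignore_index=True)
        self.__post_init__()

    def cell_frames(self, cell_id: int) -> np.ndarray:
        """Sorted frame indices at which cell_id has a row."""
        return np.sort(self.df.loc[self.df["Cell_ID"] == cell_id, "frame_i"].to_numpy())

    def frames(self) -> np.ndarray:
        return np.sort(self.df["frame_i"].unique())


def validate_annotation_table(table: AnnotationTable) -> list[Violation]:
    """Check every table invariant; violations are returned, never raised.

    Rules checked (rule tag in parentheses):

    * at most one row per (frame_i, Cell_ID)               (duplicate_row)
    * stage is G1 or S/G2/M, relationship mother or bud    (bad_enum)
    * bud rows are in S/G2/M with a real relative_ID       (bud_state)
    * a bud's generation_num is 0 before its first division (bud_generation)
    * an S/G2/M mother has exactly one reciprocating bud
      row at the same frame                                 (one_bud)
    * presence is contiguous from emergence to last frame,
      unless the cell is flagged excluded                   (continuity)
    """
    v: list[Violation] = []
    df = table.df

    dup = df.duplicated(subset=["frame_i", "Cell_ID"], keep=False)
    for (fr, cid), _ in df[dup].groupby(["frame_i", "Cell_ID"]):
        v.append(Violation(int(fr), int(cid), "duplicate_row", "more than one row for this (frame, cell)"))

    for _, row in df.iterrows():
        fr, cid = int(row["frame_i"]), int(row["Cell_ID"])
        if row["cell_cycle_stage"] not in STAGES:
            v.append(Violation(fr, cid, "bad_enum", f"unknown stage {row['cell_cycle_stage']!r}"))
            continue
        if row["relationship"] not in (MOTHER, BUD):
            v.append(Violation(fr, cid, "bad_enum", f"unknown relationship {row['relationship']!r}"))
            continue
        if row["relationship"] == BUD:
            if row["cell_cycle_stage"] != S_G2_M:
                v.append(Violation(fr, cid, "bud_state", "bud must be in S/G2/M"))
            if row["relative_ID"] == -1:
                v.append(Violation(fr, cid, "bud_state", "bud must have a mother (relative_ID != -1)"))
            if row["generation_num"] != 0:
                v.append(Violation(fr, cid, "bud_generation", "bud generation_num must be 0 before division"))

    # one-bud rule: mothers in S/G2/M need exactly one reciprocating bud row
    for fr, sub in df.groupby("frame_i"):
        buds = sub[sub["relationship"] == BUD]
        mothers = sub[(sub["relationship"] == MOTHER) & (sub["cell_cycle_stage"] == S_G2_M)]
        for _, m in mothers.iterrows():
            mid = int(m["Cell_ID"])
            pointing = buds[buds["relative_ID"] == mid]
            if len(pointing) != 1 or int(m["relative_ID"]) not in pointing["Cell_ID"].astype(int).tolist():
                v.append(
                    Violation(
                        int(fr),
                        mid,
                        "one_bud",
                        f"S/G2/M mother must have exactly one reciprocating bud, found {len(pointing)}",
                    )
                )

    # continuity: presence contiguous from emergence (or first appearance)
    excluded = set()
    if "is_cell_excluded" in df.columns:
        excluded = set(df.loc[df["is_cell_excluded"].astype(bool), "Cell_ID"].astype(int))
    for cid, sub in df.groupby("Cell_ID"):
        cid = int(cid)
        if cid in excluded:
            continue
        frames = np.sort(sub["frame_i"].unique())
        emerg = int(sub["emerg_frame_i"].iloc[0])
        start = emerg if emerg >= 0 else int(frames[0])
        expected = np.arange(start, frames[-1] + 1)
        if frames[0] > start or len(frames) != len(expected) or not np.array_equal(frames, expected):
            v.append(
                Violation(
                    int(frames[0]),
                    cid,
                    "continuity",
                    f"cell must be present at every frame in [{start}, {frames[-1]}]",
                )
            )
    return v


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    """Write the table as a sorted CSV; raises if the table is invalid.

    Booleans are written as ``True``/``False`` and missing links as ``-1`` so
    that a read-back reproduces the table field-for-field.
    """
    violations = validate_annotation_table(table)
    if violations:
        raise AnnotationValidationError(violations)
    out = table.sorted().df
    path = Path(path)
    _atomic_binary_write(path, lambda f: out.to_csv(f, index=False))


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read an annotation CSV written by :func:`write_annotations`."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation CSV missing columns: {missing}")
    for col in ("is_history_known", *OPTIONAL_COLUMNS):
        if col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
            df[col] = df[col].astype(bool)
    return AnnotationTable(df)
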