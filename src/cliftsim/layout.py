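"""Spot-grid layout: pitch/density arithmetic and array-layout files.

Spots sit on a square lattice of centre-to-centre ``pitch`` μm.  The packing
density is ``floor(10^8 / pitch²)`` spots per cm² — the formula that
reproduces the measured series 150 μm → 4,444; 100 μm → 10,000;
75 μm → 17,777.  Heat spreading in the thick self-adhesive foil limits the
pitch to ~100 μm; the 5 μm spin-coated film reaches 75 μm.

Coordinates: origin at the top-left of the usable area, x rightward,
y downward, 0-based row/col internally, 1-based in exported files (GAL
convention).  Unassigned lattice positions are explicit "empty" records so
that quantification sees the full lattice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("cliftsim")

__all__ = [
    "SpotGrid",
    "SlideGeometry",
    "CapacityError",
    "EMPTY",
    "density",
    "grid_for",
    "min_pitch_for",
    "write_gal",
    "read_gal",
    "write_layout_tsv",
]

#: id marking an unassigned lattice position
EMPTY = "empty"

#: lowest practical pitch (μm) per donor-stack kind
MIN_PITCH_UM = {"thick-foil": 100.0, "thin-film": 75.0}


class CapacityError(ValueError):
    """Library does not fit the slide geometry at the requested pitch."""


@dataclass(frozen=True)
class SlideGeometry:
    """Usable patterning area (mm) and optional reference markers (μm)."""

    width_mm: float = 20.0
    height_mm: float = 20.0
    reference_markers: tuple = ()

    def __post_init__(self) -> None:
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ValueError("usable area must be positive")
        for x, y in self.reference_markers:
            if not (0 <= x <= self.width_mm * 1000 and 0 <= y <= self.height_mm * 1000):
                raise ValueError(f"marker ({x}, {y}) μm outside the slide")


@dataclass(frozen=True)
class SpotGrid:
    """Square spot lattice with row-major peptide assignments.

    ``assignments`` maps row-major spot index → peptide id; missing indices
    are empty.  Spot centre of (row, col) is origin + (col·pitch, row·pitch).
    """

    pitch_um: float
    rows: int
    cols: int
    origin_um: tuple = (0.0, 0.0)
    assignments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pitch_um > 0:
            raise ValueError("pitch must be > 0")
        if self.rows < 0 or self.cols < 0:
            raise ValueError("rows/cols must be >= 0")
        if self.assignments and max(self.assignments) >= self.rows * self.cols:
            raise ValueError("assignment index outside the grid")

    @property
    def n_spots(self) -> int:
        return self.rows * self.cols

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)

    def spot_id(self, index: int) -> str:
        return self.assignments.get(index, EMPTY)

    def centre_um(self, index: int) -> tuple[float, float]:
        """(x, y) μm of a row-major spot index."""
        r, c = divmod(index, self.cols)
        return (self.origin_um[0] + c * self.pitch_um,
                self.origin_um[1] + r * self.pitch_um)

    def to_frame(self) -> pd.DataFrame:
        """Full-lattice table: spot_index, row, col, x_um, y_um, peptide_id."""
        records = []
        for i in range(self.n_spots):
            r, c = divmod(i, self.cols)
            x, y = self.centre_um(i)
            records.append((i, r, c, x, y, self.spot_id(i)))
        return pd.DataFrame(
            records,
            columns=["spot_index", "row", "col", "x_um", "y_um", "peptide_id"],
        )


def density(pitch_um: float) -> int:
    """Spots per cm² at a given pitch: floor(10^8 / pitch²)."""
    if not pitch_um > 0:
        raise ValueError("pitch must be > 0")
    return int(1e8 // (pitch_um * pitch_um))


def min_pitch_for(stack_kind: str) -> float:
    """Lowest practical pitch (μm) for a donor-stack kind
    ('thick-foil' or 'thin-film')."""
    try:
        return MIN_PITCH_UM[stack_kind]
    except KeyError:
        raise ValueError(
            f"unknown stack kind {stack_kind!r}; expected one of "
            f"{sorted(MIN_PITCH_UM)}"
        ) from None


def grid_for(
    peptide_ids: list[str] | int,
    geometry: SlideGeometry,
    pitch_um: float,
    *,
    stack_kind: str | None = None,
) -> SpotGrid:
    """Row-major grid assigning the library to the slide at the given pitch.

    Accepts either the ids themselves or a bare count (ids become ``pep{i}``).
    Raises :class:`CapacityError` (stating the maximum) if the library does
    not fit; logs a warning if the pitch is below the stack kind's minimum.
    """
    if isinstance(peptide_ids, int):
        peptide_ids = [f"pep{i}" for i in range(peptide_ids)]
    if stack_kind is not None and pitch_um < min_pitch_for(stack_kind):
        logger.warning(
            "pitch %.4g μm is below the %s minimum of %.4g μm",
            pitch_um, stack_kind, min_pitch_for(stack_kind),
        )
    max_cols = int(geometry.width_mm * 1000 // pitch_um)
    max_rows = int(geometry.height_mm * 1000 // pitch_um)
    capacity = max_rows * max_cols
    n = len(peptide_ids)
    if n > capacity:
        raise CapacityError(
            f"{n} peptides exceed the capacity of {capacity} spots "
            f"({max_rows}×{max_cols} at {pitch_um:g} μm pitch)"
        )
    if n == 0:
        return SpotGrid(pitch_um, 0, 0)
    cols = min(n, max_cols)
    rows = math.ceil(n / cols)
    return SpotGrid(
        pitch_um, rows, cols,
        assignments={i: pid for i, pid in enumerate(peptide_ids)},
    )


# ---------------------------------------------------------------------------
# GAL (GenePix Array List) and TSV export
# ---------------------------------------------------------------------------

def write_gal(grid: SpotGrid, path: str | Path, *, spot_diameter_um: float = 110.0) -> None:
    """Write a single-block GAL file (ATF 1.0 framing, GenePix conventions).

    Every lattice position is written; empty spots carry Name/ID ``empty``.
    """
    header = [
        '"Type=GenePix ArrayList V1.0"',
        '"BlockCount=1"',
        '"BlockType=0"',
        f'"Block1={grid.origin_um[0]:g}, {grid.origin_um[1]:g}, '
        f'{spot_diameter_um:g}, {grid.cols}, {grid.pitch_um:g}, '
        f'{grid.rows}, {grid.pitch_um:g}"',
    ]
    lines = ["ATF\t1.0", f"{len(header)}\t5"]
    lines += header
    lines.append("Block\tColumn\tRow\tName\tID")
    for i in range(grid.n_spots):
        r, c = divmod(i, grid.cols)
        pid = grid.spot_id(i)
        lines.append(f"1\t{c + 1}\t{r + 1}\t{pid}\t{pid}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path: str | Path) -> SpotGrid:
    """Read a single-block GAL written by :func:`write_gal` (exact
    round-trip of positions and ids)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise ValueError(f"{path}: not an ATF/GAL file")
    n_header = int(lines[1].split("\t")[0])
    block = None
    for rec in lines[2 : 2 + n_header]:
        rec = rec.strip().strip('"')
        if rec.startswith("Block1="):
            block = [float(v) for v in rec.split("=", 1)[1].split(",")]
    if block is None:
        raise ValueError(f"{path}: missing Block1 geometry record")
    ox, oy, _dia, cols, col_pitch, rows, row_pitch = block
    if col_pitch != row_pitch:
        raise ValueError(f"{path}: only square lattices are supported")
    cols, rows = int(cols), int(rows)
    assignments: dict[int, str] = {}
    for line in lines[3 + n_header:]:
        if not line.strip():
            continue
        _b, c, r, name, _id = line.split("\t")
        if name != EMPTY:
            assignments[(int(r) - 1) * cols + (int(c) - 1)] = name
    return SpotGrid(col_pitch, rows, cols, (ox, oy), assignments)


def write_layout_tsv(grid: SpotGrid, path: str | Path, *, header: str | None = None) -> None:
    """Plain-TSV fallback: spot_index, row, col, x_um, y_um, peptide_id."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        grid.to_frame().to_csv(fh, sep="\t", index=False)
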