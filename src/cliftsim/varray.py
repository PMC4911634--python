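"""Virtual fluorescence readout: coupling yields, rendering, quantification.

The observable on a stained array is fluorescence from probes bound to
full-length product.  With single-coupling efficiency ε per layer, capping
removes truncations from further elongation, so the full-length fraction of
an n-layer peptide is the product of per-layer yields; double coupling lifts
the per-layer yield to 1−(1−ε)².  At effective yields ≥0.99 a 9-mer retains
≥94% of a 3-mer's full-length fraction — the regime in which probe series of
increasing length show no appreciable intensity drop.

Rendering emulates a 5 μm/pixel 16-bit scanner image: Gaussian spot profiles
on the lattice, amplitude proportional to the per-spot signal, plus additive
background noise from a seeded generator.  Quantification mirrors scanner
software: fixed-radius foreground circle (default pitch/3), local background
annulus median, background-subtracted mean, and CV across replicate spots
sharing a peptide id.  Deposited monomer is assumed in excess of surface
sites, so signal defaults to the full-length fraction alone; an optional
knob couples it to deposited mass for sub-threshold studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .layout import EMPTY, SpotGrid
from .library import PeptideSequence

logger = logging.getLogger("cliftsim")

__all__ = [
    "CouplingModel",
    "VirtualImage",
    "full_length_fraction",
    "spot_signals",
    "render",
    "quantify",
    "write_tiff",
    "read_tiff",
]


@dataclass(frozen=True)
class CouplingModel:
    """Per-layer coupling statistics.

    epsilon: single-coupling efficiency in [0, 1]; double_coupling repeats
    the patterning+coupling pass; capping removes uncoupled sites from later
    layers (without it truncations would still elongate — not modelled).
    """

    epsilon: float = 0.95
    double_coupling: bool = True
    capping: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")

    @property
    def effective_yield(self) -> float:
        """Per-layer yield: 1−(1−ε)² with double coupling, else ε."""
        if self.double_coupling:
            return 1.0 - (1.0 - self.epsilon) ** 2
        return self.epsilon


def full_length_fraction(seq: PeptideSequence, m: CouplingModel) -> float:
    """Fraction of surface sites carrying the full-length product: the
    product of per-layer effective yields over the sequence's layers."""
    return m.effective_yield ** len(seq)


def spot_signals(
    grid: SpotGrid,
    library: Sequence[PeptideSequence],
    m: CouplingModel = CouplingModel(),
    *,
    deposited_mass_pg: Mapping[str, float] | None = None,
    mass_scale_pg: float = 500.0,
) -> np.ndarray:
    """Relative signal per lattice spot (row-major), 0 for empty spots.

    Signal = full-length fraction; if ``deposited_mass_pg`` maps peptide ids
    to per-pass deposit masses, the signal is additionally scaled by
    min(mass/mass_scale_pg, 1) — a saturating coupling of signal to deposit
    for sub-threshold studies.
    """
    by_id = {s.id: s for s in library}
    out = np.zeros(grid.n_spots)
    for i in range(grid.n_spots):
        pid = grid.spot_id(i)
        if pid == EMPTY:
            continue
        if pid not in by_id:
            raise KeyError(f"spot {i}: peptide id {pid!r} not in library")
        sig = full_length_fraction(by_id[pid], m)
        if deposited_mass_pg is not None:
            sig *= min(deposited_mass_pg.get(pid, mass_scale_pg) / mass_scale_pg, 1.0)
        out[i] = sig
    return out


@dataclass(frozen=True)
class VirtualImage:
    """Rendering parameters for the synthetic scanner image."""

    pixel_size_um: float = 5.0
    background: float = 500.0
    noise_sd: float = 0.0
    sigma_spot_um: float = 25.0
    margin_um: float | None = None      # default: one pitch

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0 or not self.sigma_spot_um > 0:
            raise ValueError("pixel size and spot σ must be > 0")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise must be >= 0")


def render(
    grid: SpotGrid,
    amounts: np.ndarray,
    img: VirtualImage = VirtualImage(),
    seed: int = 0,
    *,
    amplitude: float = 30000.0,
) -> np.ndarray:
    """Synthetic 16-bit fluorescence image of the array.

    Each spot is a Gaussian profile of spread ``sigma_spot_um`` centred on
    its lattice position, peak height ``amplitude × amounts[i] / max``
    ... precisely: amplitude is the peak of a unit signal, so pixel values
    are linear in ``amounts``.  Additive Gaussian background noise is drawn
    from a generator seeded with ``seed`` (deterministic).  Warns when the
    spot σ exceeds pitch/2 (overlapping profiles).
    """
    amounts = np.asarray(amounts, dtype=float)
    if amounts.shape != (grid.n_spots,):
        raise ValueError(f"need {grid.n_spots} amounts, got {amounts.shape}")
    if np.any(amounts < 0):
        raise ValueError("amounts must be non-negative")
    if img.sigma_spot_um > grid.pitch_um / 2:
        logger.warning(
            "spot σ %.4g μm exceeds pitch/2 (%.4g μm): profiles overlap",
            img.sigma_spot_um, grid.pitch_um / 2,
        )
    margin = grid.pitch_um if img.margin_um is None else img.margin_um
    px = img.pixel_size_um
    width_um = (grid.cols - 1) * grid.pitch_um + 2 * margin if grid.cols else 2 * margin
    height_um = (grid.rows - 1) * grid.pitch_um + 2 * margin if grid.rows else 2 * margin
    nx, ny = int(math.ceil(width_um / px)), int(math.ceil(height_um / px))
    yy, xx = np.mgrid[0:ny, 0:nx]
    xs = (xx + 0.5) * px
    ys = (yy + 0.5) * px
    field = np.full((ny, nx), img.background, dtype=float)
    two_s2 = 2.0 * img.sigma_spot_um**2
    for i in range(grid.n_spots):
        if amounts[i] == 0:
            continue
        r, c = divmod(i, grid.cols)
        cx = margin + c * grid.pitch_um
        cy = margin + r * grid.pitch_um
        field += (amplitude * amounts[i]) * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / two_s2
        )
    if img.noise_sd > 0:
        rng = np.random.default_rng(seed)
        field += rng.normal(0.0, img.noise_sd, size=field.shape)
    return np.clip(np.round(field), 0, 65535).astype(np.uint16)


def quantify(
    image: np.ndarray,
    grid: SpotGrid,
    radius_um: float | None = None,
    *,
    pixel_size_um: float = 5.0,
    margin_um: float | None = None,
) -> pd.DataFrame:
    """Scanner-style quantification of a rendered (or real) array image.

    Per spot: mean over a circle of ``radius_um`` (default pitch/3) minus the
    median of a local background annulus (1.5–2.5 radii); replicate CV =
    sd/mean of background-subtracted signals over spots sharing a peptide id.
    Raises if any foreground circle falls outside the image.

    Returns columns: spot, row, col, id, mean_fg, median_bg, signal,
    cv_group.
    """
    radius = grid.pitch_um / 3.0 if radius_um is None else radius_um
    margin = grid.pitch_um if margin_um is None else margin_um
    ny, nx = image.shape
    px = pixel_size_um
    yy, xx = np.mgrid[0:ny, 0:nx]
    xs = (xx + 0.5) * px
    ys = (yy + 0.5) * px
    rows = []
    img_f = image.astype(float)
    for i in range(grid.n_spots):
        r, c = divmod(i, grid.cols)
        cx = margin + c * grid.pitch_um
        cy = margin + r * grid.pitch_um
        if cx - radius < 0 or cy - radius < 0 or cx + radius > nx * px or cy + radius > ny * px:
            raise ValueError(
                f"spot {i} circle (centre {cx:g},{cy:g} μm, r={radius:g} μm) "
                "outside the image"
            )
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        fg = d2 <= radius**2
        annulus = (d2 > (1.5 * radius) ** 2) & (d2 <= (2.5 * radius) ** 2)
        mean_fg = float(img_f[fg].mean())
        median_bg = float(np.median(img_f[annulus])) if annulus.any() else 0.0
        rows.append(
            {
                "spot": i, "row": r, "col": c, "id": grid.spot_id(i),
                "mean_fg": mean_fg, "median_bg": median_bg,
                "signal": mean_fg - median_bg,
            }
        )
    df = pd.DataFrame(rows)
    cv = (
        df[df["id"] != EMPTY]
        .groupby("id")["signal"]
        .agg(lambda s: s.std(ddof=1) / s.mean() if len(s) > 1 and s.mean() != 0 else 0.0)
    )
    df["cv_group"] = df["id"].map(cv).fillna(0.0)
    return df


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint16))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))
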