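"""Two-layer stacked deposition and in-situ activation design.

Non-activated Fmoc amino acids couple only after conversion to active esters.
The trick is to deposit the activation reagents (DIC carbodiimide + HOBt
racemization suppressor, embedded in matrix) first, then a second spot of the
free-acid building block on top; heat-induced melting mixes the two deposits
and the building block is activated in situ while diffusing through the
melted reagent layer.  Crossed energy gradients (rows = first material,
columns = second) map out the stoichiometry space in one experiment.

Per-spot amounts come from the thermal module's energy→thickness→mass
calibration; molar ratios follow from each recipe's solid mass fractions
(solvent evaporates during spin-coating and is excluded) and the component
formula weights.  Mixing on melting is treated as complete within a spot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .thermal import DepositionCalibration, deposited_mass, deposited_thickness

__all__ = [
    "TransferLayerRecipe",
    "StackedSpot",
    "GradientPattern",
    "RecipeError",
    "MOLAR_MASSES",
    "DIC_HOBT_RECIPE",
    "FMOC_GLY_OH_RECIPE",
    "gradient_design",
    "stoichiometry",
    "molar_ratio",
    "write_pattern_tsv",
]


class RecipeError(ValueError):
    """Inconsistent recipe or missing molar mass."""


#: standard formula weights (g·mol⁻¹) of the in-situ activation components;
#: editable/extendable by the caller.  The DIC mass is printed with a comma
#: decimal ("7,25 mg") in the source recipe and is read as 7.25 mg.
MOLAR_MASSES: dict[str, float] = {
    "Fmoc-Gly-OH": 297.3,
    "DIC": 126.2,
    "HOBt": 135.1,
}


@dataclass(frozen=True)
class TransferLayerRecipe:
    """Spin-coated transfer-layer composition.

    ``components`` lists (name, mg) of every solid, including the matrix
    polymer; solvents are excluded (they evaporate during spin-coating, so
    only solids are transferred).  Mass fractions are over total solids.
    """

    name: str
    components: tuple          # ((name, mg), …)
    solvent_ml: float = 1.0
    matrix: str = "matrix"

    def __post_init__(self) -> None:
        comps = tuple((n, float(mg)) for n, mg in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise RecipeError(f"{self.name}: recipe needs components")
        for n, mg in comps:
            if not mg > 0:
                raise RecipeError(f"{self.name}: mass of {n!r} must be > 0")
        if self.matrix not in dict(comps):
            raise RecipeError(f"{self.name}: matrix {self.matrix!r} not listed")

    @property
    def total_solids_mg(self) -> float:
        return sum(mg for _, mg in self.components)

    def mass_fraction(self, component: str) -> float:
        """Solid mass fraction of one component (fractions sum to 1)."""
        comps = dict(self.components)
        if component not in comps:
            raise RecipeError(f"{self.name}: no component {component!r}")
        return comps[component] / self.total_solids_mg

    @property
    def actives(self) -> list[str]:
        """Non-matrix components (the chemically relevant ones)."""
        return [n for n, _ in self.components if n != self.matrix]


#: activation-reagent donor: 3.75 mg HOBt + 7.25 mg DIC in 139 mg matrix
DIC_HOBT_RECIPE = TransferLayerRecipe(
    "DIC/HOBt", (("HOBt", 3.75), ("matrix", 139.0), ("DIC", 7.25))
)
#: non-activated building-block donor: 15 mg Fmoc-Gly-OH in 135 mg matrix
FMOC_GLY_OH_RECIPE = TransferLayerRecipe(
    "Fmoc-Gly-OH", (("Fmoc-Gly-OH", 15.0), ("matrix", 135.0))
)


@dataclass(frozen=True)
class StackedSpot:
    """One grid position with its ordered deposits (first = bottom)."""

    position: tuple            # (row, col)
    deposits: tuple            # ((recipe, energy_uJ, mass_pg), …)

    def mass_of(self, recipe_name: str) -> float:
        """Total deposited mass (pg) contributed by one recipe."""
        return sum(m for r, _e, m in self.deposits if r.name == recipe_name)


@dataclass(frozen=True)
class GradientPattern:
    """Crossed two-material gradient: rows sweep the first material's energy,
    columns the second's."""

    recipe_rows: TransferLayerRecipe
    recipe_cols: TransferLayerRecipe
    energies_rows: tuple
    energies_cols: tuple
    spots: tuple               # rows × cols of StackedSpot

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.energies_rows), len(self.energies_cols))


def gradient_design(
    recipe1: TransferLayerRecipe,
    recipe2: TransferLayerRecipe,
    energies_rows: Sequence[float],
    energies_cols: Sequence[float],
    cal: DepositionCalibration = DepositionCalibration(),
) -> GradientPattern:
    """Design the two-step gradient: spot (i, j) stacks ``recipe1`` deposited
    at ``energies_rows[i]`` under ``recipe2`` at ``energies_cols[j]``.

    Per-spot masses come from the deposition calibration; energies in the
    burn regime raise immediately.  With monotone energy lists the deposited
    amounts are monotone along the corresponding axis.  A single zero column
    energy reduces the second layer to the one-layer control.
    """
    if not energies_rows or not energies_cols:
        raise RecipeError("energy lists must be non-empty")
    # precompute masses (also validates against the burn regime)
    m_rows = [deposited_mass(deposited_thickness(e, cal), cal) for e in energies_rows]
    m_cols = [deposited_mass(deposited_thickness(e, cal), cal) for e in energies_cols]
    spots = tuple(
        tuple(
            StackedSpot(
                position=(i, j),
                deposits=(
                    (recipe1, float(er), m_rows[i]),
                    (recipe2, float(ec), m_cols[j]),
                ),
            )
            for j, ec in enumerate(energies_cols)
        )
        for i, er in enumerate(energies_rows)
    )
    return GradientPattern(
        recipe1, recipe2, tuple(map(float, energies_rows)),
        tuple(map(float, energies_cols)), spots,
    )


def stoichiometry(
    spot: StackedSpot, molar_masses: Mapping[str, float] = MOLAR_MASSES
) -> dict[str, float]:
    """Moles (pmol) of every non-matrix component deposited at a spot.

    moles = deposit mass (pg) × mass fraction / molar mass (g·mol⁻¹); with
    mass in pg the result is in pmol.  Ratios between components are
    invariant under uniform scaling of the deposit masses.
    """
    moles: dict[str, float] = {}
    for recipe, _e, mass_pg in spot.deposits:
        for name in recipe.actives:
            if name not in molar_masses:
                raise RecipeError(f"no molar mass for component {name!r}")
            moles[name] = moles.get(name, 0.0) + (
                mass_pg * recipe.mass_fraction(name) / molar_masses[name]
            )
    return moles


def molar_ratio(
    spot: StackedSpot,
    numerator: str,
    denominator: str,
    molar_masses: Mapping[str, float] = MOLAR_MASSES,
) -> float:
    """Activator:building-block style molar ratio at one spot."""
    moles = stoichiometry(spot, molar_masses)
    if moles.get(denominator, 0.0) == 0.0:
        raise RecipeError(f"no {denominator!r} deposited; ratio undefined")
    return moles[numerator] / moles[denominator]


def write_pattern_tsv(
    pattern: GradientPattern,
    path: str | Path,
    *,
    molar_masses: Mapping[str, float] = MOLAR_MASSES,
    header: str | None = None,
) -> None:
    """Export: spot, row, col, per-layer material and mass, molar ratios of
    every active pair (first recipe's actives over the second's)."""
    rows = []
    r1, r2 = pattern.recipe_rows, pattern.recipe_cols
    for i, row in enumerate(pattern.spots):
        for j, spot in enumerate(row):
            rec = {
                "spot": i * pattern.shape[1] + j,
                "row": i,
                "col": j,
                "layer1_material": r1.name,
                "layer1_mass_pg": spot.deposits[0][2],
                "layer2_material": r2.name,
                "layer2_mass_pg": spot.deposits[1][2],
            }
            moles = stoichiometry(spot, molar_masses)
            for a in r1.actives:
                for b in r2.actives:
                    col = f"ratio_{a}_per_{b}"
                    rec[col] = (
                        moles[a] / moles[b] if moles.get(b, 0.0) else float("nan")
                    )
            rows.append(rec)
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
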