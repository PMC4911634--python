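"""Donor-job scheduling, process-time and reagent-consumption model.

One synthesis layer elongates every peptide by one monomer.  Structuring the
layer means lasing all spots that take a given building block from that
block's donor slide, exchanging donors between jobs (~40 s per exchange), and
— with double coupling — repeating the whole pattern a second time before
Fmoc deprotection.  The scan head's per-spot cycle is the pulse plus fixed
delays (laser-on 300 μs, laser-off 310 μs, jump delay 200 μs, 100 μs jump),
5.91 ms at the defaults and budgeted at <10 ms.

Wet chemistry bounds the layer: coupling 60 min at 90 °C after each
patterning pass, an acetone wash, then capping, DMF washes, piperidine
deprotection and final washes.  A full double-coupling layer for 100,000
spots with 20 donors stays under 5 h.

Reagent consumption is frugal: a donor slide takes ~15 mg of amino acid
(8 mg for biotin) and can be reused up to 20 times, so slides per block =
ceil(patterning passes / reuse limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .library import PeptideSequence, layer_blocks

__all__ = [
    "ProcessTimings",
    "DonorRecipe",
    "LayerSchedule",
    "SynthesisPlan",
    "SchedulingError",
    "per_spot_cycle_time",
    "schedule_layer",
    "layer_time",
    "consumption",
    "plan_synthesis",
    "default_recipe",
]


class SchedulingError(ValueError):
    """Missing donor/recipe or inconsistent plan inputs."""


@dataclass(frozen=True)
class ProcessTimings:
    """Machine and wet-chemistry timing constants.

    Scan-head delays are in μs, the pulse in ms, donor exchange in s and wet
    steps in minutes, matching how each is controlled on the instrument.
    ``per_spot_budget_ms`` is the conservative per-spot allowance used for
    planning; it must not be undercut by the computed cycle time.
    """

    pulse_ms: float = 5.0
    laser_on_delay_us: float = 300.0
    laser_off_delay_us: float = 310.0
    jump_delay_us: float = 200.0
    jump_us: float = 100.0
    per_spot_budget_ms: float = 10.0
    donor_exchange_s: float = 40.0
    coupling_min: float = 60.0
    coupling_temp_C: float = 90.0
    acetone_wash_min: float = 15.0
    capping_min: float = 30.0
    dmf_wash_min: float = 5.0          # applied twice after capping and after deprotection
    piperidine_min: float = 20.0
    final_acetone_min: float = 2.0     # applied twice
    double_coupling: bool = True

    def __post_init__(self) -> None:
        for f in (
            "pulse_ms", "laser_on_delay_us", "laser_off_delay_us",
            "jump_delay_us", "jump_us", "per_spot_budget_ms",
            "donor_exchange_s", "coupling_min", "acetone_wash_min",
            "capping_min", "dmf_wash_min", "piperidine_min",
            "final_acetone_min",
        ):
            if getattr(self, f) < 0:
                raise SchedulingError(f"{f} must be >= 0")
        if self.per_spot_budget_ms < per_spot_cycle_time(self):
            raise SchedulingError(
                f"per-spot budget {self.per_spot_budget_ms} ms below the "
                f"computed cycle time {per_spot_cycle_time(self):.3f} ms"
            )

    @property
    def n_passes(self) -> int:
        """Patterning+coupling passes per layer (2 with double coupling)."""
        return 2 if self.double_coupling else 1


def per_spot_cycle_time(t: ProcessTimings) -> float:
    """Scan-head cycle per spot in ms: pulse + on/off delays + jump delay +
    jump.  5.91 ms at the defaults."""
    return t.pulse_ms + (
        t.laser_on_delay_us + t.laser_off_delay_us + t.jump_delay_us + t.jump_us
    ) / 1000.0


@dataclass(frozen=True)
class DonorRecipe:
    """Per-block donor-slide recipe and reuse policy."""

    block: str
    block_mg_per_slide: float = 15.0
    resin_mg_per_slide: float = 135.0
    solvent_ml: float = 1.0
    reuse_limit: int = 20

    def __post_init__(self) -> None:
        if not (self.block_mg_per_slide > 0 and self.resin_mg_per_slide > 0):
            raise SchedulingError("recipe masses must be > 0")
        if self.reuse_limit < 1:
            raise SchedulingError("reuse_limit must be >= 1")


def default_recipe(block: str) -> DonorRecipe:
    """Standard recipe: 15 mg block + 135 mg resin per slide (8 + 68 for
    biotin, which dissolves poorly in DCM), reusable 20 times."""
    if block == "biotin":
        return DonorRecipe(block, block_mg_per_slide=8.0, resin_mg_per_slide=68.0)
    return DonorRecipe(block)


@dataclass(frozen=True)
class LayerSchedule:
    """One patterning pass of one layer: donor jobs plus derived times."""

    layer: int
    jobs: tuple            # ((block, (spot indices…)), …) ascending by block
    lasing_s: float        # Σ spots × per-spot cycle time
    budget_lasing_s: float  # Σ spots × per-spot budget
    exchange_s: float      # distinct donors × exchange time

    @property
    def n_spots(self) -> int:
        return sum(len(spots) for _, spots in self.jobs)

    @property
    def n_exchanges(self) -> int:
        return len(self.jobs)

    @property
    def structuring_s(self) -> float:
        """Lasing plus donor exchanges for one pass."""
        return self.lasing_s + self.exchange_s


def schedule_layer(
    spot_blocks: Mapping[int, str],
    t: ProcessTimings = ProcessTimings(),
    *,
    layer: int = 1,
    donors: Iterable[str] | None = None,
) -> LayerSchedule:
    """Group a layer's spots into per-donor jobs and derive pass times.

    ``spot_blocks`` maps spot index → building-block token for this layer.
    One donor exchange per distinct donor per pass; jobs in ascending donor
    order.  If ``donors`` is given, every required block must be in it.
    """
    by_block: dict[str, list[int]] = {}
    for spot, block in spot_blocks.items():
        by_block.setdefault(block, []).append(spot)
    if donors is not None:
        missing = sorted(set(by_block) - set(donors))
        if missing:
            raise SchedulingError(
                f"layer {layer}: no donor slide for block(s) {missing}"
            )
    jobs = tuple(
        (block, tuple(sorted(spots))) for block, spots in sorted(by_block.items())
    )
    n_spots = sum(len(s) for _, s in jobs)
    return LayerSchedule(
        layer=layer,
        jobs=jobs,
        lasing_s=n_spots * per_spot_cycle_time(t) / 1000.0,
        budget_lasing_s=n_spots * t.per_spot_budget_ms / 1000.0,
        exchange_s=len(jobs) * t.donor_exchange_s,
    )


def layer_time(
    schedule: LayerSchedule,
    t: ProcessTimings = ProcessTimings(),
    *,
    use_budget: bool = False,
) -> float:
    """Total duration (s) of one full synthesis layer.

    Per patterning pass (×2 with double coupling): structuring + coupling +
    acetone wash.  Then once per layer: capping, 2× DMF wash, piperidine
    deprotection, 2× DMF wash, 2× final acetone wash.
    """
    structuring = (
        schedule.budget_lasing_s if use_budget else schedule.lasing_s
    ) + schedule.exchange_s
    per_pass = structuring + 60.0 * (t.coupling_min + t.acetone_wash_min)
    fixed = 60.0 * (
        t.capping_min
        + 2 * t.dmf_wash_min
        + t.piperidine_min
        + 2 * t.dmf_wash_min
        + 2 * t.final_acetone_min
    )
    return t.n_passes * per_pass + fixed


def consumption(
    layer_schedules: Sequence[LayerSchedule],
    t: ProcessTimings = ProcessTimings(),
    recipes: Mapping[str, DonorRecipe] | None = None,
) -> dict[str, dict[str, float]]:
    """Reagent ledger: per block, patterning passes (double coupling counts
    twice), donor slides needed = ceil(passes / reuse limit), and block mass.

    ``recipes`` defaults to :func:`default_recipe` per block; an explicit
    mapping missing a used block raises :class:`SchedulingError`.
    """
    passes: dict[str, int] = {}
    for sched in layer_schedules:
        for block, spots in sched.jobs:
            if spots:
                passes[block] = passes.get(block, 0) + t.n_passes
    ledger: dict[str, dict[str, float]] = {}
    for block, n in sorted(passes.items()):
        if recipes is None:
            recipe = default_recipe(block)
        elif block in recipes:
            recipe = recipes[block]
        else:
            raise SchedulingError(f"no donor recipe for block {block!r}")
        slides = math.ceil(n / recipe.reuse_limit)
        ledger[block] = {
            "passes": float(n),
            "slides": float(slides),
            "block_mg": slides * recipe.block_mg_per_slide,
            "resin_mg": slides * recipe.resin_mg_per_slide,
        }
    return ledger


@dataclass(frozen=True)
class SynthesisPlan:
    """Full multi-layer plan: per-layer schedules, durations and consumption."""

    layers: tuple                 # LayerSchedule per layer
    timings: ProcessTimings
    ledger: dict = field(default_factory=dict)

    @property
    def layer_times_s(self) -> list[float]:
        return [layer_time(s, self.timings) for s in self.layers]

    @property
    def total_time_s(self) -> float:
        return sum(self.layer_times_s)

    @property
    def total_slides(self) -> float:
        return sum(v["slides"] for v in self.ledger.values())


def plan_synthesis(
    library: Sequence[PeptideSequence],
    assignments: Mapping[int, str],
    t: ProcessTimings = ProcessTimings(),
    recipes: Mapping[str, DonorRecipe] | None = None,
) -> SynthesisPlan:
    """Plan the whole synthesis of ``library`` on a spot grid.

    ``assignments`` maps spot index → peptide id (as in
    :attr:`cliftsim.layout.SpotGrid.assignments`).  Layer ℓ of each spot takes
    the ℓ-th residue (synthesis order) of its peptide; shorter peptides drop
    out of later layers.
    """
    by_id = {seq.id: seq for seq in library}
    missing = sorted({pid for pid in assignments.values() if pid not in by_id})
    if missing:
        raise SchedulingError(f"assigned peptide id(s) not in library: {missing}")
    n_layers = max((len(s) for s in library), default=0)
    schedules = []
    for layer in range(1, n_layers + 1):
        spot_blocks = {
            spot: by_id[pid].residues[layer - 1].token
            for spot, pid in assignments.items()
            if len(by_id[pid]) >= layer
        }
        schedules.append(schedule_layer(spot_blocks, t, layer=layer))
    schedules = tuple(schedules)
    return SynthesisPlan(schedules, t, consumption(schedules, t, recipes))
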