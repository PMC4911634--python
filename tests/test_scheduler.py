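"""Donor scheduling, process-time model and reagent consumption."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from cliftsim.library import FLAG, HA, layer_blocks, permutation_variants
from cliftsim.scheduler import (
    DonorRecipe,
    ProcessTimings,
    SchedulingError,
    consumption,
    default_recipe,
    layer_time,
    per_spot_cycle_time,
    plan_synthesis,
    schedule_layer,
)

ZERO_WET = dict(
    coupling_min=0.0, acetone_wash_min=0.0, capping_min=0.0,
    dmf_wash_min=0.0, piperidine_min=0.0, final_acetone_min=0.0,
)


def test_per_spot_cycle_time_defaults():
    """5 ms pulse + 300/310/200 μs delays + 100 μs jump = 5.91 ms < 10 ms."""
    t = ProcessTimings()
    assert per_spot_cycle_time(t) == pytest.approx(5.91)
    assert per_spot_cycle_time(t) <= t.per_spot_budget_ms


def test_cycle_time_without_overheads():
    t = ProcessTimings(laser_on_delay_us=0, laser_off_delay_us=0,
                       jump_delay_us=0, jump_us=0)
    assert per_spot_cycle_time(t) == pytest.approx(5.0)


def test_budget_below_cycle_time_rejected():
    with pytest.raises(SchedulingError, match="budget"):
        ProcessTimings(per_spot_budget_ms=5.0)


def test_schedule_10000_spots_20_donors():
    """20 exchanges at 40 s → 800 s; 10,000 spots stay within 100 s at the
    10 ms budget; structuring fits 15 min."""
    t = ProcessTimings()
    sched = schedule_layer({i: f"b{i % 20}" for i in range(10000)}, t)
    assert sched.n_exchanges == 20
    assert sched.exchange_s == pytest.approx(800.0)
    assert sched.budget_lasing_s == pytest.approx(100.0)
    assert sched.lasing_s <= sched.budget_lasing_s
    assert sched.budget_lasing_s + sched.exchange_s <= 15 * 60


def test_schedule_empty_layer():
    sched = schedule_layer({})
    assert sched.n_spots == 0 and sched.n_exchanges == 0
    assert sched.lasing_s == 0.0 and sched.exchange_s == 0.0


def test_schedule_differing_layer_of_scan():
    variants = permutation_variants(HA, FLAG)
    ids = {i: v for i, v in enumerate(variants)}
    layer = 1  # display position 9 (Ala/Lys) → differing layer
    spot_blocks = {i: v.residues[layer - 1].token for i, v in ids.items()}
    sched = schedule_layer(spot_blocks)
    assert sched.n_exchanges == 2
    assert len(layer_blocks(variants)[layer]) == 2


def test_schedule_missing_donor_names_block():
    with pytest.raises(SchedulingError, match="Gly"):
        schedule_layer({0: "Ala", 1: "Gly"}, donors=["Ala"])


def test_jobs_deterministic_and_order_invariant():
    spots = {i: f"b{i % 5}" for i in range(100)}
    shuffled = dict(random.Random(0).sample(list(spots.items()), len(spots)))
    a, b = schedule_layer(spots), schedule_layer(shuffled)
    assert a.jobs == b.jobs
    assert layer_time(a) == layer_time(b)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(n=st.integers(0, 5000), k=st.integers(1, 30))
def test_lasing_linear_in_spots_exchanges_in_donors(n, k):
    t = ProcessTimings()
    sched = schedule_layer({i: f"b{i % k}" for i in range(n)}, t)
    assert sched.lasing_s == pytest.approx(n * per_spot_cycle_time(t) / 1000)
    assert sched.exchange_s == pytest.approx(min(n, k) * t.donor_exchange_s)
    assert sched.budget_lasing_s >= sched.lasing_s


def test_full_double_coupling_layer_under_5h():
    t = ProcessTimings()
    sched = schedule_layer({i: f"b{i % 20}" for i in range(100000)}, t)
    assert layer_time(sched, t) <= 5 * 3600
    assert layer_time(sched, t, use_budget=True) >= layer_time(sched, t)


def test_layer_time_zero_wet_single_coupling():
    t = ProcessTimings(double_coupling=False, **ZERO_WET)
    sched = schedule_layer({i: "Ala" for i in range(100)}, t)
    assert layer_time(sched, t) == pytest.approx(sched.structuring_s)


def test_double_vs_single_coupling_decomposition():
    """They differ by exactly one structuring pass + one coupling + one wash."""
    td = ProcessTimings(double_coupling=True)
    ts = ProcessTimings(double_coupling=False)
    sched = schedule_layer({i: f"b{i % 3}" for i in range(500)}, td)
    delta = layer_time(sched, td) - layer_time(sched, ts)
    expected = sched.structuring_s + 60 * (td.coupling_min + td.acetone_wash_min)
    assert delta == pytest.approx(expected)


# -- consumption --------------------------------------------------------------

def test_consumption_ceiling_arithmetic():
    """25 passes at reuse 20 → 2 slides → 30 mg of a 15 mg/slide block."""
    t = ProcessTimings(double_coupling=False)
    scheds = [schedule_layer({0: "Ala"}, t, layer=l) for l in range(1, 26)]
    ledger = consumption(scheds, t)
    assert ledger["Ala"] == {
        "passes": 25.0, "slides": 2.0, "block_mg": 30.0, "resin_mg": 270.0,
    }


def test_consumption_biotin_once():
    t = ProcessTimings(double_coupling=False)
    ledger = consumption([schedule_layer({0: "biotin"}, t)], t)
    assert ledger["biotin"]["slides"] == 1.0
    assert ledger["biotin"]["block_mg"] == pytest.approx(8.0)


def test_consumption_unused_block_absent_and_missing_recipe_errors():
    t = ProcessTimings(double_coupling=False)
    scheds = [schedule_layer({0: "Ala"}, t)]
    assert "Gly" not in consumption(scheds, t)
    with pytest.raises(SchedulingError, match="Ala"):
        consumption(scheds, t, recipes={"Gly": default_recipe("Gly")})


def test_default_recipes():
    assert default_recipe("Ala").block_mg_per_slide == 15.0
    assert default_recipe("biotin").block_mg_per_slide == 8.0
    with pytest.raises(SchedulingError):
        DonorRecipe("Ala", reuse_limit=0)


# -- full plan ----------------------------------------------------------------

def test_plan_synthesis_ha_flag_scan(ha_flag_variants):
    assignments = {i: v.id for i, v in enumerate(ha_flag_variants)}
    plan = plan_synthesis(ha_flag_variants, assignments)
    assert len(plan.layers) == 9
    # differing layers need 2 donors, conserved layers 1
    per_layer = {s.layer: s.n_exchanges for s in plan.layers}
    assert sorted(per_layer.values()) == [1, 1, 1, 2, 2, 2, 2, 2, 2]
    # double coupling: every used block patterns twice per layer
    assert plan.ledger["Val"]["passes"] == 2.0
    assert plan.total_time_s == pytest.approx(sum(plan.layer_times_s))
    with pytest.raises(SchedulingError, match="not in library"):
        plan_synthesis(ha_flag_variants, {0: "nope"})
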