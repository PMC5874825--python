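"""Random dimer search: generation, filtering, ranking, selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist
from scipy.stats import chisquare

from solvagg.cluster_search import (CandidateConfiguration, SelectionRule,
                                    boltzmann_rank, contact_filter,
                                    evaluate_energies,
                                    exhaustive_toy_minimum,
                                    generate_candidates,
                                    select_for_refinement, toy_dimer_oracle)
from solvagg.constants import R_KCAL
from solvagg.synthetic import (Fragment, ToyPotential, toy_potential_for,
                               water_fragment)

WATER = water_fragment()


def _single_site(element="O"):
    return Fragment(np.zeros((1, 3)), (element,), ("X",), ("other",),
                    "water")


def _pair_potential(eps=0.21, sigma=2.96):
    return ToyPotential(epsilon=[eps, eps], sigma=[sigma, sigma],
                        charge=[0.0, 0.0], molecule=[0, 1])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def test_zero_candidates():
    assert generate_candidates(WATER, WATER, cube_side=10.0, n=0) == []


def test_generation_deterministic_under_seed():
    a = generate_candidates(WATER, WATER, cube_side=10.0, n=50, seed=3)
    b = generate_candidates(WATER, WATER, cube_side=10.0, n=50, seed=3)
    for ca, cb in zip(a, b):
        assert np.array_equal(ca.mobile_coords, cb.mobile_coords)


def test_com_positions_uniform_per_axis():
    """χ² uniformity test on each axis of 10⁴ accepted placements."""
    cands = generate_candidates(_single_site(), _single_site(),
                                cube_side=30.0, n=10_000, seed=5)
    t = np.array([c.translation for c in cands])
    for axis in range(3):
        counts, _ = np.histogram(t[:, axis], bins=10, range=(-15, 15))
        assert chisquare(counts).pvalue > 0.01


def test_placements_respect_overlap_floor():
    cands = generate_candidates(WATER, WATER, cube_side=6.0, n=300, seed=1)
    for c in cands:
        assert cdist(c.mobile_coords, c.central_coords).min() >= 1.5


# ---------------------------------------------------------------------------
# Contact filter
# ---------------------------------------------------------------------------

def _candidate_at(distance):
    central = np.zeros((1, 3))
    mobile = np.array([[distance, 0.0, 0.0]])
    return CandidateConfiguration(central, mobile, mobile[0], np.eye(3), 0)


def test_contact_filter_boundary():
    kept = contact_filter([_candidate_at(3.9), _candidate_at(4.1)])
    assert len(kept) == 1
    assert kept[0].mobile_coords[0, 0] == 3.9


def test_contact_filter_matches_brute_force():
    cands = generate_candidates(WATER, WATER, cube_side=14.0, n=500, seed=9)
    kept = contact_filter(cands, cutoff=4.0)
    expected = []
    for c in cands:
        hit = False
        for pm in c.mobile_coords:
            for pc in c.central_coords:
                if np.linalg.norm(pm - pc) <= 4.0:
                    hit = True
        if hit:
            expected.append(c)
    assert kept == expected


def test_contact_filter_limits():
    cands = generate_candidates(WATER, WATER, cube_side=12.0, n=100, seed=2)
    assert contact_filter(cands, cutoff=math.inf) == cands
    assert contact_filter(cands, cutoff=0.0) == []


# ---------------------------------------------------------------------------
# Energies and ranking
# ---------------------------------------------------------------------------

def test_evaluate_preserves_order_and_flags_failures():
    cands = generate_candidates(WATER, WATER, cube_side=10.0, n=10, seed=0)
    calls = []

    def flaky(c):
        calls.append(c.index)
        if c.index == 3:
            raise RuntimeError("oracle died")
        return float(c.index)

    out = evaluate_energies(cands, flaky)
    assert [c.index for c in out] == list(range(10)) == calls
    assert out[3].failed and out[3].energy is None
    ranked = boltzmann_rank(out, T=300.0)
    assert all(c.index != 3 for c in ranked)


def test_equal_energies_uniform_weights():
    cands = generate_candidates(WATER, WATER, cube_side=10.0, n=4, seed=1)
    evaluate_energies(cands, lambda c: -7.5)
    ranked = boltzmann_rank(cands)
    assert [c.weight for c in ranked] == pytest.approx([0.25] * 4)
    # stable tie-break: input order preserved
    assert [c.index for c in ranked] == [0, 1, 2, 3]


def test_two_level_closed_form():
    T = 298.0
    cands = generate_candidates(WATER, WATER, cube_side=10.0, n=2, seed=1)
    energies = [0.0, R_KCAL * T * math.log(2)]
    evaluate_energies(cands, lambda c: energies[c.index])
    ranked = boltzmann_rank(cands, T=T)
    assert ranked[0].weight == pytest.approx(2 / 3, abs=1e-12)
    assert ranked[1].weight == pytest.approx(1 / 3, abs=1e-12)


def test_weights_match_longdouble_reference(rng):
    T = 298.0
    e = rng.uniform(-30, 10, 50)
    cands = generate_candidates(WATER, WATER, cube_side=10.0, n=50, seed=4)
    evaluate_energies(cands, lambda c: e[c.index])
    ranked = boltzmann_rank(cands, T=T)
    el = np.asarray(e, dtype=np.longdouble)
    ref = np.exp(-el / (np.longdouble(R_KCAL) * T))
    ref = (ref / ref.sum()).astype(float)
    for c in ranked:
        assert abs(c.weight - ref[c.index]) < 1e-12


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
       st.floats(-100, 100))
def test_weights_normalized_and_shift_invariant(energies, shift):
    cands = [CandidateConfiguration(np.zeros((1, 3)),
                                    np.ones((1, 3)) * 5, np.zeros(3),
                                    np.eye(3), i, energy=e)
             for i, e in enumerate(energies)]
    ranked = boltzmann_rank(cands, T=300.0)
    assert sum(c.weight for c in ranked) == pytest.approx(1.0, abs=1e-9)
    w0 = {c.index: c.weight for c in ranked}
    for c in cands:
        c.energy += shift
    ranked2 = boltzmann_rank(cands, T=300.0)
    for c in ranked2:
        assert c.weight == pytest.approx(w0[c.index], abs=1e-9)


def test_temperature_limits(rng):
    e = rng.uniform(-10, 10, 8)
    cands = [CandidateConfiguration(np.zeros((1, 3)), np.ones((1, 3)) * 5,
                                    np.zeros(3), np.eye(3), i, energy=ei)
             for i, ei in enumerate(e)]
    cold = boltzmann_rank(cands, T=1e-3)
    assert cold[0].index == int(np.argmin(e))
    assert cold[0].weight == pytest.approx(1.0)
    hot = boltzmann_rank(cands, T=1e9)
    assert [c.weight for c in hot] == pytest.approx([1 / 8] * 8, abs=1e-6)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _ranked_with_energies(energies, T=298.0):
    cands = [CandidateConfiguration(np.zeros((1, 3)), np.ones((1, 3)) * 5,
                                    np.zeros(3), np.eye(3), i, energy=e)
             for i, e in enumerate(energies)]
    return boltzmann_rank(cands, T=T)


def test_empty_selection_when_nothing_qualifies():
    # many near-degenerate states → every f_i < 0.01, window band empty
    ranked = _ranked_with_energies(np.linspace(0, 0.5, 200))
    sel = select_for_refinement(ranked, SelectionRule(seed=0))
    assert sel == []


def test_single_dominant_candidate_always_selected():
    ranked = _ranked_with_energies([0.0])
    sel = select_for_refinement(ranked, SelectionRule(seed=0))
    assert len(sel) == 1 and sel[0].weight == pytest.approx(1.0)


def test_selection_matches_reference_set_builder(rng):
    energies = np.concatenate([rng.uniform(0, 2.5, 60),
                               rng.uniform(3, 15, 120),
                               rng.uniform(16, 30, 20)])
    ranked = _ranked_with_energies(energies)
    rule = SelectionRule(seed=77)
    sel = select_for_refinement(ranked, rule)

    # independent rebuild of the selection set, same sampling protocol
    ref_rng = np.random.default_rng(77)
    e0 = min(c.energy for c in ranked)
    by_weight = [c for c in ranked if c.weight >= 0.01]
    window = [c for c in ranked if 3.0 <= c.energy - e0 <= 15.0]
    k = int(ref_rng.integers(10, 16))
    take = (window if len(window) <= k
            else [window[j] for j in ref_rng.choice(len(window), size=k,
                                                    replace=False)])
    expected = {c.index for c in by_weight} | {c.index for c in take}
    assert {c.index for c in sel} == expected


def test_window_smaller_than_count_taken_whole():
    energies = [0.0, 5.0, 7.0, 40.0, 45.0]
    ranked = _ranked_with_energies(energies)
    sel = select_for_refinement(ranked, SelectionRule(seed=1))
    picked = {round(c.energy, 1) for c in sel}
    assert {5.0, 7.0} <= picked          # whole window
    assert 0.0 in picked                 # dominant weight
    assert not {40.0, 45.0} & picked     # outside both criteria


# ---------------------------------------------------------------------------
# Exhaustive oracle and end-to-end search
# ---------------------------------------------------------------------------

def test_exhaustive_two_site_lj_minimum():
    pot = _pair_potential()
    best, e = exhaustive_toy_minimum(_single_site(), _single_site(), pot,
                                     cube_side=8.0, grid_spacing=0.25)
    r = np.linalg.norm(best.mobile_coords[0])
    assert abs(r - 2 ** (1 / 6) * 2.96) <= 0.25 * math.sqrt(3)
    assert e == pytest.approx(-0.21, abs=0.02)


def test_exhaustive_single_placement_grid():
    # central: two atoms straddling the origin; a zero-size grid admits
    # exactly one placement (mobile COM at the central COM)
    pot = ToyPotential(epsilon=[0.2, 0.2, 0.2], sigma=[3.0, 3.0, 3.0],
                       charge=[0.0] * 3, molecule=[0, 0, 1])
    central = Fragment(np.array([[-5.0, 0, 0], [5.0, 0, 0]]),
                       ("O", "O"), ("X", "X"), ("other",) * 2, "water")
    mobile = _single_site()
    best, e = exhaustive_toy_minimum(central, mobile, pot, cube_side=0.0,
                                     grid_spacing=1.0)
    assert best is not None
    assert np.allclose(best.translation, 0.0)
    assert np.allclose(best.mobile_coords, [[0.0, 0.0, 0.0]])


def test_random_search_reaches_exhaustive_minimum():
    """≥ 95% of seeds find the grid-enumerated minimum (toy LJ dimer)."""
    pot = _pair_potential()
    central, mobile = _single_site(), _single_site()
    _, e_grid = exhaustive_toy_minimum(central, mobile, pot, cube_side=7.0,
                                       grid_spacing=0.25)
    hits = 0
    for seed in range(20):
        cands = generate_candidates(central, mobile, cube_side=8.0, n=2000,
                                    seed=seed)
        kept = contact_filter(cands)
        evaluate_energies(kept, toy_dimer_oracle(pot))
        ranked = boltzmann_rank(kept)
        if ranked[0].energy <= e_grid + 0.02:
            hits += 1
    assert hits >= 19
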