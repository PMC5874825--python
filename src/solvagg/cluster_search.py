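"""Random rigid-body search for low-lying dimer structures.

Five-step protocol: (1) scatter a mobile fragment uniformly (position in
a cube centered on the central unit's COM, orientation uniform over
rotations); (2) keep candidates with at least one mobile atom within
4 Å of the central unit; (3) score each survivor with a pluggable energy
oracle; (4) rank by Boltzmann factor fᵢ = exp(−(Eᵢ−E₀)/RT)/Σⱼexp(−(Eⱼ−E₀)/RT)
and select the fᵢ ≥ 0.01 set plus a seeded random draw of 10–15
structures from the 3 ≤ Eᵢ−E₀ ≤ 15 kcal/mol window; step (5), geometry
refinement, is the caller's concern (the oracle is pluggable precisely
so a quantum-chemistry driver could stand behind it).

A brute-force grid/orientation enumerator over the same toy landscape is
provided as the independent check of the stochastic search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (CLOSEST_APPROACH, CONTACT_CUTOFF,
                        DEFAULT_TEMPERATURE, R_KCAL)
from .synthetic import (Fragment, ToyPotential, place_fragment,
                        random_rotation_matrix, toy_energy)

__all__ = [
    "CandidateConfiguration",
    "SelectionRule",
    "generate_candidates",
    "contact_filter",
    "evaluate_energies",
    "boltzmann_rank",
    "select_for_refinement",
    "exhaustive_toy_minimum",
    "toy_dimer_oracle",
]


@dataclass
class CandidateConfiguration:
    """One placed dimer candidate: geometries plus the placement
    transform, with energy and Boltzmann factor filled in downstream."""

    central_coords: np.ndarray
    mobile_coords: np.ndarray
    translation: np.ndarray
    rotation: np.ndarray
    index: int
    energy: float | None = None
    weight: float | None = None
    failed: bool = False

    @property
    def coordinates(self) -> np.ndarray:
        return np.vstack([self.central_coords, self.mobile_coords])


@dataclass
class SelectionRule:
    """Step-4 selection: keep every candidate with fᵢ ≥ ``f_threshold``
    plus a seeded uniform sample from the ``window`` energy band above
    the minimum; the sample size is drawn once per run from
    ``window_count_range`` (inclusive)."""

    f_threshold: float = 0.01
    window: tuple[float, float] = (3.0, 15.0)
    window_count_range: tuple[int, int] = (10, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_threshold <= 1):
            raise ValueError("f_threshold must be in (0, 1]")
        if not self.window[0] < self.window[1]:
            raise ValueError("window lower bound must be below the upper")


def generate_candidates(central: Fragment, mobile: Fragment,
                        cube_side: float, n: int, seed: int = 0,
                        max_retries: int = 1000
                        ) -> list[CandidateConfiguration]:
    """Scatter ``n`` rigid placements of ``mobile`` in a cube of side
    ``cube_side`` centered on the central fragment's COM.

    Placements violating the 1.5 Å closest-approach floor are redrawn
    (unphysical fused geometries would poison any energy oracle); the
    accepted COM distribution remains uniform over the allowed region.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if cube_side <= 2 * mobile.radius:
        raise ValueError("cube side must exceed the mobile fragment "
                         "diameter")
    rng = np.random.default_rng(seed)
    central_xyz = central.coords - central.com  # central COM at origin
    out: list[CandidateConfiguration] = []
    for i in range(n):
        for _ in range(max_retries):
            t = rng.uniform(-0.5, 0.5, 3) * cube_side
            rot = random_rotation_matrix(rng)
            placed = (mobile.coords - mobile.com) @ rot.T + t
            if cdist(placed, central_xyz).min() >= CLOSEST_APPROACH:
                out.append(CandidateConfiguration(
                    central_coords=central_xyz, mobile_coords=placed,
                    translation=t, rotation=rot, index=i))
                break
        else:
            raise RuntimeError(
                "cube too small: could not place the mobile fragment "
                f"clear of the central unit in {max_retries} tries")
    return out


def contact_filter(candidates: list[CandidateConfiguration],
                   cutoff: float = CONTACT_CUTOFF
                   ) -> list[CandidateConfiguration]:
    """Keep candidates with ≥ 1 mobile atom within ``cutoff`` of ≥ 1
    central-unit atom."""
    return [c for c in candidates
            if cdist(c.mobile_coords, c.central_coords).min() <= cutoff]


def evaluate_energies(candidates: list[CandidateConfiguration],
                      oracle) -> list[CandidateConfiguration]:
    """Fill ``energy`` on every candidate via ``oracle(candidate) →
    kcal/mol``; oracle failures flag the candidate (excluded from
    ranking) instead of aborting the run.  Order is preserved."""
    for c in candidates:
        try:
            c.energy = float(oracle(c))
            c.failed = False
        except Exception:
            c.energy = None
            c.failed = True
    return candidates


def boltzmann_rank(candidates: list[CandidateConfiguration],
                   T: float = DEFAULT_TEMPERATURE
                   ) -> list[CandidateConfiguration]:
    """Attach Boltzmann factors relative to the best candidate and sort
    by descending weight (stable: ties keep input order)."""
    ok = [c for c in candidates if not c.failed and c.energy is not None]
    if not ok:
        raise ValueError("no evaluated candidates to rank")
    e = np.array([c.energy for c in ok])
    w = np.exp(-(e - e.min()) / (R_KCAL * T))
    w /= w.sum()
    for c, wi in zip(ok, w):
        c.weight = float(wi)
    return sorted(ok, key=lambda c: -c.weight)


def select_for_refinement(ranked: list[CandidateConfiguration],
                          rule: SelectionRule
                          ) -> list[CandidateConfiguration]:
    """Union of the high-weight set (fᵢ ≥ threshold) and a seeded
    without-replacement sample from the energy window above the minimum;
    if the window holds fewer members than the drawn count, all are
    taken."""
    if not ranked:
        return []
    rng = np.random.default_rng(rule.seed)
    e0 = min(c.energy for c in ranked)
    keep = {id(c): c for c in ranked if c.weight >= rule.f_threshold}
    lo, hi = rule.window
    window = [c for c in ranked if lo <= c.energy - e0 <= hi]
    k_lo, k_hi = rule.window_count_range
    k = int(rng.integers(k_lo, k_hi + 1))
    if window:
        take = (window if len(window) <= k else
                [window[j] for j in rng.choice(len(window), size=k,
                                               replace=False)])
        for c in take:
            keep[id(c)] = c
    # deterministic output order: by rank (descending weight)
    order = {id(c): i for i, c in enumerate(ranked)}
    return sorted(keep.values(), key=lambda c: order[id(c)])


def toy_dimer_oracle(potential: ToyPotential):
    """Energy oracle closure evaluating the packaged toy potential on a
    candidate's stacked coordinates."""
    def oracle(candidate: CandidateConfiguration) -> float:
        return toy_energy(candidate.coordinates, potential)
    return oracle


def exhaustive_toy_minimum(central: Fragment, mobile: Fragment,
                           potential: ToyPotential, cube_side: float,
                           grid_spacing: float,
                           orientations: list[np.ndarray] | None = None
                           ) -> tuple[CandidateConfiguration | None, float]:
    """Brute-force enumeration over a COM grid × orientation set,
    returning the global toy-energy minimum on that grid.

    Intended as the slow, independent oracle for the stochastic search
    on small fragments.  If no grid point admits a bound (negative
    energy) placement the best grid configuration is still returned; a
    ``(None, inf)`` result means every grid point violated the
    closest-approach floor.
    """
    if orientations is None:
        orientations = [np.eye(3)]
    central_xyz = central.coords - central.com
    half = cube_side / 2.0
    axis = np.arange(-half, half + 1e-9, grid_spacing)
    best: CandidateConfiguration | None = None
    best_e = math.inf
    mobile_local = mobile.coords - mobile.com
    for rot in orientations:
        rotated = mobile_local @ rot.T
        for ix in axis:
            for iy in axis:
                for iz in axis:
                    t = np.array([ix, iy, iz])
                    placed = rotated + t
                    if cdist(placed, central_xyz).min() < CLOSEST_APPROACH:
                        continue
                    e = toy_energy(np.vstack([central_xyz, placed]),
                                   potential)
                    if e < best_e:
                        best_e = e
                        best = CandidateConfiguration(
                            central_coords=central_xyz,
                            mobile_coords=placed, translation=t,
                            rotation=rot, index=-1, energy=e)
    return best, best_e
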