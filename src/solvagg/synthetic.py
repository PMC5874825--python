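"""Synthetic input generators with exact, geometry-level ground truth.

Everything the analysis pipeline consumes can be produced here: a single
solute in a periodic water box with controllable hydrogen-bond contact
statistics, mixed nonionic/zwitterionic solution boxes with planted
molecular-pair contacts, isomer-energy ensembles with closed-form Boltzmann
statistics, and rigid molecular fragments plus a deterministic site-site
Lennard-Jones + Coulomb energy function for the cluster search.

Frames are drawn i.i.d. — there is no dynamics and no temporal
correlation.  Planted features are constructed geometrically (a contact is
*placed* at a distance inside the criterion, not sampled from a force
field), so the ground truth each generator records is exact rather than
estimated.  All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (CLOSEST_APPROACH, CONTACT_CUTOFF, COULOMB_K,
                        DEFAULT_TEMPERATURE, HBOND_CUTOFF, R_KCAL)
from .thermo import IsomerEnsemble
from .topology import (Frame, SiteTopology, Trajectory,
                       minimum_image_distance, pair_distance_matrix)

__all__ = [
    "Fragment",
    "PlantedMixtureSpec",
    "PlantedMixture",
    "PlantedIsomerEnsemble",
    "ToyPotential",
    "water_fragment",
    "solute_fragment",
    "assemble_topology",
    "random_rotation_matrix",
    "place_fragment",
    "make_solvated_solute",
    "make_planted_mixture",
    "make_isomer_ensemble",
    "make_ideal_gas",
    "toy_energy",
    "toy_potential_for",
    "InfeasibleDensityError",
]

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


class InfeasibleDensityError(RuntimeError):
    """Raised when random placement cannot satisfy the closest-approach
    floor within the retry budget (box too small for the requested
    contents)."""


# ---------------------------------------------------------------------------
# Rigid fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A rigid molecular fragment in a local frame (Å)."""

    coords: np.ndarray
    elements: tuple[str, ...]
    labels: tuple[str, ...]
    groups: tuple[str, ...]
    species: str

    @property
    def masses(self) -> np.ndarray:
        return np.array([_MASS[e] for e in self.elements])

    @property
    def com(self) -> np.ndarray:
        m = self.masses
        return (m[:, None] * self.coords).sum(axis=0) / m.sum()

    @property
    def radius(self) -> float:
        """Largest atom distance from the COM."""
        return float(np.linalg.norm(self.coords - self.com, axis=1).max())


def water_fragment() -> Fragment:
    """Rigid three-site water (O–H 1.0 Å, H–O–H 109.47°)."""
    a = math.radians(109.47)
    coords = np.array([[0.0, 0.0, 0.0],
                       [1.0, 0.0, 0.0],
                       [math.cos(a), math.sin(a), 0.0]])
    return Fragment(coords, ("O", "H", "H"), ("Ow", "Hw", "Hw"),
                    ("water",) * 3, "water")


def _rot2d(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def solute_fragment(species: str) -> Fragment:
    """Idealized rigid meta-aminobenzoic-acid tautomer.

    A planar C₆H₄ ring (C–C 1.39 Å) carries a carboxyl group at ring
    position 0 and an amino group at the meta position (ring atom 2).
    The nonionic form has –COOH and –NH₂; the zwitterion has –COO⁻ (two
    equivalent C–O bonds, no acidic H) and –NH₃⁺.  Bond lengths are
    standard textbook values; only the group topology and overall size
    matter to the analyses built on top.
    """
    if species not in ("nonionic", "zwitterionic"):
        raise ValueError("species must be 'nonionic' or 'zwitterionic'")
    coords, elements, labels, groups = [], [], [], []

    ring_r = 1.39
    ring_dirs = [np.array([math.cos(math.radians(60 * k)),
                           math.sin(math.radians(60 * k)), 0.0])
                 for k in range(6)]
    for k, u in enumerate(ring_dirs):
        coords.append(ring_r * u)
        elements.append("C")
        labels.append("Cr")
        groups.append("ring")
    for k in (1, 3, 4, 5):  # positions 0 and 2 carry substituents
        coords.append((ring_r + 1.08) * ring_dirs[k])
        elements.append("H")
        labels.append("Hr")
        groups.append("ring")

    # carboxyl on ring atom 0
    u0 = ring_dirs[0]
    cc = coords[0] + 1.50 * u0
    coords.append(cc); elements.append("C"); labels.append("Cc")
    groups.append("carboxyl")
    if species == "nonionic":
        o1 = cc + 1.23 * _rot2d(u0, 60.0)
        o2 = cc + 1.36 * _rot2d(u0, -60.0)
        hc = o2 + 0.97 * _rot2d(u0, -10.0)
        for p, e, l in ((o1, "O", "Om"), (o2, "O", "Om"), (hc, "H", "Hc")):
            coords.append(p); elements.append(e); labels.append(l)
            groups.append("carboxyl")
    else:  # carboxylate: two equivalent C–O bonds, no Hc
        for sign in (60.0, -60.0):
            coords.append(cc + 1.25 * _rot2d(u0, sign))
            elements.append("O"); labels.append("Om")
            groups.append("carboxyl")

    # amino on ring atom 2 (meta to the carboxyl)
    u2 = ring_dirs[2]
    nm = coords[2] + 1.40 * u2
    coords.append(nm); elements.append("N"); labels.append("Nm")
    groups.append("amino")
    if species == "nonionic":  # planar –NH2
        for ang in (55.0, -55.0):
            coords.append(nm + 1.01 * _rot2d(u2, ang))
            elements.append("H"); labels.append("Ha")
            groups.append("amino")
    else:  # –NH3+: three H at tetrahedral angles from the N–C bond
        v1 = np.array([-u2[1], u2[0], 0.0])
        v2 = np.array([0.0, 0.0, 1.0])
        ca, sa = math.cos(math.radians(70.5)), math.sin(math.radians(70.5))
        for phi in (90.0, 210.0, 330.0):
            w = (math.cos(math.radians(phi)) * v1
                 + math.sin(math.radians(phi)) * v2)
            coords.append(nm + 1.03 * (ca * u2 + sa * w))
            elements.append("H"); labels.append("Ha")
            groups.append("amino")

    xyz = np.array(coords)
    xyz = xyz - xyz.mean(axis=0)
    return Fragment(xyz, tuple(elements), tuple(labels), tuple(groups),
                    species)


def assemble_topology(fragments: list[Fragment]) -> SiteTopology:
    """Stack fragments into one topology, molecule ids in list order."""
    elements: list[str] = []
    labels: list[str] = []
    groups: list[str] = []
    molecule: list[int] = []
    species: dict[int, str] = {}
    for i, fr in enumerate(fragments):
        elements.extend(fr.elements)
        labels.extend(fr.labels)
        groups.extend(fr.groups)
        molecule.extend([i] * len(fr.elements))
        species[i] = fr.species
    masses = np.array([_MASS[e] for e in elements])
    return SiteTopology(elements, masses, labels,
                        np.array(molecule), groups, species)


# ---------------------------------------------------------------------------
# Rigid-body placement
# ---------------------------------------------------------------------------

def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix drawn uniformly over SO(3) via a unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def place_fragment(fragment: Fragment, rotation: np.ndarray,
                   com: np.ndarray) -> np.ndarray:
    """Rigidly rotate a fragment about its COM and move the COM to ``com``."""
    return (fragment.coords - fragment.com) @ rotation.T + com


def _min_cross_distance(xa: np.ndarray, xb: np.ndarray,
                        box: np.ndarray) -> float:
    return float(pair_distance_matrix(xa, xb, box).min())


# ---------------------------------------------------------------------------
# Solvated single solute with planted H-bond contacts
# ---------------------------------------------------------------------------

def make_solvated_solute(n_waters: int = 210,
                         box: float | np.ndarray = 18.6,
                         donor_contact_prob: float | dict[str, float] = 0.0,
                         n_frames: int = 50,
                         seed: int = 0,
                         species: str = "nonionic",
                         contact_labels: tuple[str, ...] = ("Om", "Nm"),
                         max_retries: int = 200) -> Trajectory:
    """One rigid solute in a periodic box of rigid waters.

    Every solute atom whose label is in ``contact_labels`` (the H-bond
    acceptor sites O_m and N_m by default) is a *contact site*: per frame
    and per site, with the requested probability a water is placed with
    one hydrogen at 1.7–2.4 Å from the site; otherwise every water
    hydrogen is kept ≥ 2.6 Å away.  The 2.5 Å H-bond existence criterion
    therefore fires on exactly the planted Bernoulli draws.  Remaining
    waters are uniform in the box subject to the 1.5 Å closest-approach
    floor.

    ``donor_contact_prob`` may be a scalar (applied to every contact
    site) or a mapping from site label to probability.
    """
    box = np.full(3, box, dtype=float) if np.isscalar(box) else np.asarray(box)
    rng = np.random.default_rng(seed)
    solute = solute_fragment(species)
    wat = water_fragment()
    top = assemble_topology([solute] + [wat] * n_waters)

    site_local = [i for i, l in enumerate(solute.labels)
                  if l in contact_labels]
    if np.isscalar(donor_contact_prob):
        probs = [float(donor_contact_prob)] * len(site_local)
    else:
        probs = [float(donor_contact_prob.get(solute.labels[i], 0.0))
                 for i in site_local]

    frames = []
    for f in range(n_frames):
        for attempt in range(max_retries):
            coords = _solvated_frame(rng, solute, wat, n_waters, box,
                                     site_local, probs, max_retries)
            if coords is not None:
                break
        else:
            raise InfeasibleDensityError(
                f"could not build frame {f}: box too dense for {n_waters} "
                "waters under the closest-approach floor")
        frames.append(Frame(coords, box.copy(), time=float(f)))
    return Trajectory(frames, top)


def _solvated_frame(rng, solute, wat, n_waters, box, site_local, probs,
                    max_retries):
    sol = place_fragment(solute, random_rotation_matrix(rng), box / 2.0)
    placed = [sol]
    sites = sol[site_local]
    flags = [rng.random() < p for p in probs]

    n_planted = 0
    for k, (site, flag) in enumerate(zip(sites, flags)):
        if not flag:
            continue
        ok = False
        for _ in range(max_retries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            d = rng.uniform(1.7, 2.4)
            w = _water_with_h_at(wat, site + d * u, u, rng)
            if _contact_water_ok(w, placed, sites, k, box):
                placed.append(w)
                n_planted += 1
                ok = True
                break
        if not ok:
            return None
    for _ in range(n_waters - n_planted):
        ok = False
        for _ in range(max_retries):
            com = rng.uniform(0, 1, 3) * box
            w = place_fragment(wat, random_rotation_matrix(rng), com)
            if _bulk_water_ok(w, placed, sites, box):
                placed.append(w)
                ok = True
                break
        if not ok:
            return None
    return np.vstack(placed)


def _water_with_h_at(wat, h_pos, u, rng):
    """Water oriented so its first hydrogen sits at ``h_pos`` with the
    O–H bond along ``u`` (O outward), random roll about the bond."""
    oh = wat.coords[1] - wat.coords[0]
    roll = random_rotation_matrix(rng)  # randomize, then align the bond
    c = wat.coords @ roll.T
    oh_r = c[1] - c[0]
    rot = _align(oh_r / np.linalg.norm(oh_r), -u)
    c = c @ rot.T
    return c - c[1] + h_pos


def _align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:
        # opposite vectors: rotate pi about any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, p)
        v /= np.linalg.norm(v)
        return 2 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _contact_water_ok(w, placed, sites, target_idx, box):
    for other in placed:
        if _min_cross_distance(w, other, box) < CLOSEST_APPROACH:
            return False
    # hydrogens (atoms 1, 2) must not graze any *other* site
    for j, site in enumerate(sites):
        hs = w[1:] if j != target_idx else w[2:]
        if len(hs) and minimum_image_distance(hs, site, box).min() < 2.6:
            return False
    return True


def _bulk_water_ok(w, placed, sites, box):
    for other in placed:
        if _min_cross_distance(w, other, box) < CLOSEST_APPROACH:
            return False
    if len(sites):
        d = pair_distance_matrix(w[1:], np.asarray(sites), box)
        if d.min() < 2.6:
            return False
    return True


# ---------------------------------------------------------------------------
# Ideal gas (for RDF limit tests)
# ---------------------------------------------------------------------------

def make_ideal_gas(n_atoms: int, box: float, n_frames: int,
                   seed: int = 0) -> Trajectory:
    """Uniform, non-interacting point particles: g(r) ≡ 1 in expectation."""
    rng = np.random.default_rng(seed)
    boxv = np.full(3, box, dtype=float)
    top = SiteTopology(
        elements=["O"] * n_atoms,
        masses=np.full(n_atoms, _MASS["O"]),
        labels=["X"] * n_atoms,
        molecule=np.arange(n_atoms),
        group=["other"] * n_atoms,
        species={i: "water" for i in range(n_atoms)},
    )
    frames = [Frame(rng.uniform(0, 1, (n_atoms, 3)) * boxv, boxv, float(f))
              for f in range(n_frames)]
    return Trajectory(frames, top)


# ---------------------------------------------------------------------------
# Mixed-species boxes with planted pair contacts
# ---------------------------------------------------------------------------

PAIR_CLASSES = ("nn", "zz", "mixed")


@dataclass
class PlantedMixtureSpec:
    """Recipe for a mixed nonionic/zwitterionic box with known contact
    statistics.

    ``pair_frequencies`` gives the expected number of simultaneous
    molecular contacts per frame for each pair class (``nn`` =
    nonionic–nonionic, ``zz`` = zwitterionic–zwitterionic, ``mixed``).
    Counts are realised per frame as ``floor(f) + Bernoulli(frac(f))`` so
    the mean is exactly the requested frequency.
    """

    n_nonionic: int = 10
    n_zwitterionic: int = 10
    box: float = 50.0
    n_frames: int = 200
    pair_frequencies: dict[str, float] = field(
        default_factory=lambda: {"nn": 2.0, "zz": 3.0, "mixed": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonionic < 0 or self.n_zwitterionic < 0:
            raise ValueError("molecule counts must be non-negative")
        freqs = {c: float(self.pair_frequencies.get(c, 0.0))
                 for c in PAIR_CLASSES}
        if any(v < 0 for v in freqs.values()):
            raise ValueError("pair frequencies must be non-negative")
        self.pair_frequencies = freqs
        nA, nZ = self.n_nonionic, self.n_zwitterionic
        caps = {"nn": nA * (nA - 1) // 2, "zz": nZ * (nZ - 1) // 2,
                "mixed": nA * nZ}
        for c in PAIR_CLASSES:
            if freqs[c] > caps[c]:
                raise ValueError(f"pair frequency {c}={freqs[c]} infeasible "
                                 f"for the molecule counts (max {caps[c]})")
        # planted pairs are vertex-disjoint, which needs headroom beyond
        # the combinatorial cap
        need_A = 2 * (math.floor(freqs["nn"]) + 1) + math.floor(freqs["mixed"]) + 1
        need_Z = 2 * (math.floor(freqs["zz"]) + 1) + math.floor(freqs["mixed"]) + 1
        if freqs["nn"] + freqs["mixed"] > 0 and nA < need_A:
            raise ValueError(f"need ≥ {need_A} nonionic molecules for "
                             "disjoint planted pairs")
        if freqs["zz"] + freqs["mixed"] > 0 and nZ < need_Z:
            raise ValueError(f"need ≥ {need_Z} zwitterionic molecules for "
                             "disjoint planted pairs")


@dataclass
class PlantedMixture:
    """Generator output: the trajectory plus the exact per-frame planted
    contact counts per pair class."""

    trajectory: Trajectory
    planted_counts: dict[str, np.ndarray]
    spec: PlantedMixtureSpec


def make_planted_mixture(spec: PlantedMixtureSpec,
                         max_retries: int = 200) -> PlantedMixture:
    """Build a mixed box whose per-frame molecular contact counts
    (minimum interatomic distance ≤ 4.0 Å) are known exactly.

    Contacted pairs are placed with their minimum interatomic distance in
    [3.2, 3.9] Å; every other molecule pair is kept > 4.5 Å apart, so the
    4.0 Å criterion recovers the planted counts with no ambiguity.  The
    generator verifies each frame by brute force before accepting it.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.full(3, spec.box, dtype=float)
    frags = ([solute_fragment("nonionic")] * spec.n_nonionic
             + [solute_fragment("zwitterionic")] * spec.n_zwitterionic)
    top = assemble_topology(frags)
    mols_A = list(range(spec.n_nonionic))
    mols_Z = list(range(spec.n_nonionic,
                        spec.n_nonionic + spec.n_zwitterionic))

    counts = {c: np.empty(spec.n_frames, dtype=int) for c in PAIR_CLASSES}
    frames = []
    for f in range(spec.n_frames):
        drawn = {}
        for c in PAIR_CLASSES:
            freq = spec.pair_frequencies[c]
            base = math.floor(freq)
            drawn[c] = base + int(rng.random() < freq - base)
        for attempt in range(max_retries):
            coords = _mixture_frame(rng, frags, mols_A, mols_Z, drawn, box,
                                    max_retries)
            if coords is None:
                continue
            if _verify_counts(coords, top, box) == drawn:
                break
        else:
            raise InfeasibleDensityError(
                f"could not realise planted contacts in frame {f}")
        for c in PAIR_CLASSES:
            counts[c][f] = drawn[c]
        frames.append(Frame(coords, box.copy(), time=float(f)))
    return PlantedMixture(Trajectory(frames, top), counts, spec)


def _choose_pairs(rng, drawn, mols_A, mols_Z):
    """Vertex-disjoint (hub, mobile) molecule pairs per class."""
    avail_A, avail_Z = list(mols_A), list(mols_Z)
    pairs = []
    for c, pool_h, pool_m in (("nn", avail_A, avail_A),
                              ("zz", avail_Z, avail_Z),
                              ("mixed", avail_A, avail_Z)):
        for _ in range(drawn[c]):
            if not pool_h or not pool_m or (pool_h is pool_m
                                            and len(pool_h) < 2):
                return None
            h = pool_h.pop(int(rng.integers(len(pool_h))))
            m = pool_m.pop(int(rng.integers(len(pool_m))))
            pairs.append((h, m))
    free = avail_A + avail_Z
    return pairs, free


def _mixture_frame(rng, frags, mols_A, mols_Z, drawn, box, max_retries):
    chosen = _choose_pairs(rng, drawn, mols_A, mols_Z)
    if chosen is None:
        return None
    pairs, free = chosen
    n = len(frags)
    coords = [None] * n
    max_r = max(fr.radius for fr in frags)
    sep = 2 * max_r + CONTACT_CUTOFF + 2.5  # COM spacing for non-contacts

    anchors = [h for h, _ in pairs] + free
    coms = []
    for mol in anchors:
        for _ in range(max_retries):
            com = rng.uniform(0, 1, 3) * box
            if all(minimum_image_distance(com, c, box) >= sep for c in coms):
                coms.append(com)
                break
        else:
            return None
        coords[mol] = place_fragment(frags[mol], random_rotation_matrix(rng),
                                     com)

    for h, m in pairs:
        target = rng.uniform(3.3, 3.8)
        ok = False
        for _ in range(max_retries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rot = random_rotation_matrix(rng)
            placed = _place_at_min_distance(frags[m], rot, coords[h],
                                            coms_anchor=_com(coords[h],
                                                             frags[h]),
                                            u=u, target=target, box=box)
            if placed is None:
                continue
            if _mobile_clear(placed, coords, h, box):
                coords[m] = placed
                ok = True
                break
        if not ok:
            return None
    return np.vstack(coords)


def _com(xyz, frag):
    m = frag.masses
    return (m[:, None] * xyz).sum(axis=0) / m.sum()


def _place_at_min_distance(frag, rot, hub_xyz, coms_anchor, u, target, box):
    """Bisect the COM offset along ``u`` until the minimum interatomic
    distance to the hub molecule equals ``target`` (within 0.01 Å)."""
    local = (frag.coords - frag.com) @ rot.T

    def min_d(t):
        return _min_cross_distance(local + coms_anchor + t * u, hub_xyz, box)

    lo, hi = 0.5, 25.0
    if min_d(lo) > target or min_d(hi) < target:
        return None
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if min_d(mid) < target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    d = min_d(t)
    if not (3.2 <= d <= 3.9) or d < CLOSEST_APPROACH:
        return None
    return local + coms_anchor + t * u


def _mobile_clear(placed, coords, hub, box):
    for j, other in enumerate(coords):
        if other is None or j == hub:
            continue
        if _min_cross_distance(placed, other, box) <= 4.5:
            return False
    return True


def _verify_counts(coords, top, box):
    """Brute-force molecular pair contact counts by class."""
    out = {c: 0 for c in PAIR_CLASSES}
    mols = top.solute_molecules()
    for a_i, m1 in enumerate(mols):
        x1 = coords[top.atoms_of(m1)]
        for m2 in mols[a_i + 1:]:
            x2 = coords[top.atoms_of(m2)]
            if _min_cross_distance(x1, x2, box) <= CONTACT_CUTOFF:
                s = {top.species[m1], top.species[m2]}
                if s == {"nonionic"}:
                    out["nn"] += 1
                elif s == {"zwitterionic"}:
                    out["zz"] += 1
                else:
                    out["mixed"] += 1
    return out


# ---------------------------------------------------------------------------
# Isomer ensembles with closed-form Boltzmann statistics
# ---------------------------------------------------------------------------

@dataclass
class PlantedIsomerEnsemble:
    """An isomer ensemble bundled with its independently evaluated
    Boltzmann weights and ensemble-average energy (long-double
    arithmetic, no shift trick)."""

    ensemble: IsomerEnsemble
    weights: np.ndarray
    average: float


def make_isomer_ensemble(n: int, energy_spacing: float = 1.0,
                         seed: int = 0,
                         temperature: float = DEFAULT_TEMPERATURE
                         ) -> PlantedIsomerEnsemble:
    """Isomer energies on an exact arithmetic ladder.

    Energies are ``base + i·energy_spacing`` (kcal/mol) with the minimum
    at index 0; the seed randomises only the base, which Boltzmann
    weights are invariant to.  The reference weights and average are
    evaluated in extended precision directly from the defining ratio of
    exponentials.
    """
    if n < 1:
        raise ValueError("need at least one isomer")
    rng = np.random.default_rng(seed)
    base = rng.uniform(-120.0, -80.0)
    energies = base + energy_spacing * np.arange(n, dtype=float)

    e = np.asarray(energies, dtype=np.longdouble)
    w = np.exp(-e / (np.longdouble(R_KCAL) * np.longdouble(temperature)))
    w = w / w.sum()
    avg = float((w * e).sum())
    ens = IsomerEnsemble(free_energies=energies, temperature=temperature)
    return PlantedIsomerEnsemble(ens, w.astype(float), avg)


# ---------------------------------------------------------------------------
# Toy site-site energy oracle
# ---------------------------------------------------------------------------

#: Packaged per-element toy Lennard-Jones parameters (ε kcal/mol, σ Å).
#: Fixed so that oracle energies are stable across package versions.
TOY_SITE_PARAMS: dict[str, tuple[float, float]] = {
    "H": (0.0157, 2.65),
    "C": (0.0860, 3.40),
    "N": (0.1700, 3.25),
    "O": (0.2100, 2.96),
}


@dataclass
class ToyPotential:
    """Per-site LJ + Coulomb parameters and the site → molecule map."""

    epsilon: np.ndarray
    sigma: np.ndarray
    charge: np.ndarray
    molecule: np.ndarray
    coulomb_k: float = COULOMB_K

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        self.molecule = np.asarray(self.molecule, dtype=int)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if not (len(self.epsilon) == len(self.sigma) == len(self.charge)
                == len(self.molecule)):
            raise ValueError("per-site parameter arrays differ in length")


def toy_potential_for(fragments: list[Fragment],
                      charges: np.ndarray | None = None) -> ToyPotential:
    """Build a :class:`ToyPotential` for stacked fragments from the
    packaged per-element parameters (charges default to zero)."""
    eps, sig, mol = [], [], []
    for i, fr in enumerate(fragments):
        for e in fr.elements:
            p = TOY_SITE_PARAMS[e]
            eps.append(p[0])
            sig.append(p[1])
            mol.append(i)
    q = np.zeros(len(eps)) if charges is None else np.asarray(charges)
    return ToyPotential(np.array(eps), np.array(sig), q, np.array(mol))


def toy_energy(coordinates: np.ndarray, potential: ToyPotential) -> float:
    """Pairwise LJ + Coulomb energy over *intermolecular* site pairs.

    ``4ε[(σ/r)¹² − (σ/r)⁶] + k·qᵢqⱼ/r`` with Lorentz–Berthelot combining
    rules.  Deterministic; raises on coincident interacting sites.
    """
    x = np.asarray(coordinates, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two sites")
    if x.shape[0] != len(potential.molecule):
        raise ValueError("coordinates and potential size mismatch")
    ii, jj = np.triu_indices(x.shape[0], k=1)
    inter = potential.molecule[ii] != potential.molecule[jj]
    ii, jj = ii[inter], jj[inter]
    if ii.size == 0:
        return 0.0
    r = np.linalg.norm(x[ii] - x[jj], axis=1)
    if np.any(r < 1e-9):
        raise ValueError("coincident interacting sites (singular energy)")
    sig = 0.5 * (potential.sigma[ii] + potential.sigma[jj])
    eps = np.sqrt(potential.epsilon[ii] * potential.epsilon[jj])
    sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coul = potential.coulomb_k * potential.charge[ii] * potential.charge[jj] / r
    return float(lj.sum() + coul.sum())
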