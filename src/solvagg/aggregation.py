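"""Aggregation statistics for mixed nonionic/zwitterionic solutions.

Three views of solute–solute association in a trajectory:

* **molecular pair counting** — two solute molecules form a pair in a
  frame when their minimum interatomic minimum-image distance is within
  4.0 Å; pairs are classified by the species of their members
  (nonionic–nonionic, zwitterionic–zwitterionic, mixed);
* **three-body reduction** — each solute collapses to the mass-weighted
  COMs of its amino, aromatic-ring and carboxyl groups, labelled A/B/C
  for the nonionic form and A*/B*/C* for the zwitterion;
* **pairwise interaction matrix (PIM)** — the 6×6 symmetric matrix of
  time-averaged intermolecular site-pair contacts (group-COM distance
  strictly below the cutoff), optionally percent-normalised over its 21
  upper-triangle elements.

Intramolecular site pairs are never counted: within one molecule the
A–B and B–C distances are always inside the cutoff and would otherwise
swamp the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CONTACT_CUTOFF
from .topology import (SiteTopology, Trajectory, center_of_mass,
                       minimum_image_distance, pair_distance_matrix)

__all__ = [
    "PairCountSeries",
    "ThreeBodyFrame",
    "PIMatrix",
    "PIM_LABELS",
    "GROUP_ORDER",
    "count_species_pairs",
    "reduce_three_body",
    "pairwise_interaction_matrix",
]

#: Row/column order of the pairwise interaction matrix.
PIM_LABELS = ("A*", "B*", "C*", "A", "B", "C")

#: Site order within one molecule: amino, ring, carboxyl.
GROUP_ORDER = ("amino", "ring", "carboxyl")

_SITE_LABELS = {
    "nonionic": ("A", "B", "C"),
    "zwitterionic": ("A*", "B*", "C*"),
}


@dataclass
class PairCountSeries:
    """Per-frame molecular pair counts by species class."""

    times: np.ndarray
    nn: np.ndarray
    zz: np.ndarray
    mixed: np.ndarray
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "nn": self.nn,
                             "zz": self.zz, "mixed": self.mixed})


@dataclass
class ThreeBodyFrame:
    """Group-COM sites for every solute molecule in one frame.

    ``sites`` has shape (n_solutes, 3, 3): per molecule the amino, ring
    and carboxyl COMs in that fixed order.
    """

    sites: np.ndarray
    site_labels: list[tuple[str, str, str]]
    molecules: list[int]
    box: np.ndarray
    time: float


@dataclass
class PIMatrix:
    """Symmetric 6×6 contact matrix over (A*, B*, C*, A, B, C).

    ``raw`` holds time-averaged pair counts; ``percent`` the
    percent-normalised values (upper triangle sums to 100), or None when
    no contact was ever observed (``undefined`` is then True).
    """

    raw: np.ndarray
    percent: np.ndarray | None
    cutoff: float
    undefined: bool = False

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        m = self.percent if percent else self.raw
        if m is None:
            raise ValueError("percentages undefined: no contacts observed")
        return pd.DataFrame(m, index=PIM_LABELS, columns=PIM_LABELS)


def count_species_pairs(traj: Trajectory,
                        cutoff: float = CONTACT_CUTOFF) -> PairCountSeries:
    """Count, per frame, solute molecule pairs whose minimum interatomic
    minimum-image distance is ≤ cutoff, classified by species."""
    top = traj.topology
    mols = top.solute_molecules()
    if not mols:
        raise ValueError("no solute molecules in topology")
    idx = [top.atoms_of(m) for m in mols]
    spec = [top.species[m] for m in mols]

    n_frames = len(traj.frames)
    nn = np.zeros(n_frames, dtype=int)
    zz = np.zeros(n_frames, dtype=int)
    mixed = np.zeros(n_frames, dtype=int)
    times = np.array([fr.time for fr in traj.frames])
    for k, fr in enumerate(traj.frames):
        x = fr.coordinates
        for a in range(len(mols)):
            for b in range(a + 1, len(mols)):
                d = pair_distance_matrix(x[idx[a]], x[idx[b]], fr.box)
                if d.min() <= cutoff:
                    pair = {spec[a], spec[b]}
                    if pair == {"nonionic"}:
                        nn[k] += 1
                    elif pair == {"zwitterionic"}:
                        zz[k] += 1
                    else:
                        mixed[k] += 1
    return PairCountSeries(times=times, nn=nn, zz=zz, mixed=mixed,
                           cutoff=cutoff)


def reduce_three_body(traj: Trajectory) -> list[ThreeBodyFrame]:
    """Collapse each solute molecule to its amino/ring/carboxyl group
    COMs, carrying the species through as A/B/C vs A*/B*/C* labels."""
    top = traj.topology
    mols = top.solute_molecules()
    if not mols:
        raise ValueError("no solute molecules in topology")

    group_idx: list[list[np.ndarray]] = []
    labels: list[tuple[str, str, str]] = []
    for m in mols:
        atoms = top.atoms_of(m)
        per_group = []
        for g in GROUP_ORDER:
            sel = atoms[[top.group[a] == g for a in atoms]]
            if sel.size == 0:
                raise ValueError(f"molecule {m} has no '{g}' group atoms")
            per_group.append(sel)
        group_idx.append(per_group)
        labels.append(_SITE_LABELS[top.species[m]])

    out = []
    for fr in traj.frames:
        sites = np.empty((len(mols), 3, 3))
        for i, per_group in enumerate(group_idx):
            for j, sel in enumerate(per_group):
                sites[i, j] = center_of_mass(fr.coordinates[sel],
                                             top.masses[sel], fr.box)
        out.append(ThreeBodyFrame(sites=sites, site_labels=labels,
                                  molecules=list(mols), box=fr.box,
                                  time=fr.time))
    return out


def pairwise_interaction_matrix(frames: list[ThreeBodyFrame],
                                cutoff: float = CONTACT_CUTOFF) -> PIMatrix:
    """Time-averaged 6×6 matrix of intermolecular site-pair contacts.

    Per frame, every unordered pair of sites on *different* molecules
    with minimum-image COM distance strictly below the cutoff
    increments the element for its label pair; counts are averaged over
    frames and percent-normalised by the grand total over the 21
    upper-triangle elements (counts pooled over frames first, then
    normalised).  The measure-zero boundary r = cutoff counts as no
    contact.
    """
    if not frames:
        raise ValueError("need at least one three-body frame")
    pos = {l: i for i, l in enumerate(PIM_LABELS)}
    raw = np.zeros((6, 6))
    for fb in frames:
        n_mol = fb.sites.shape[0]
        for a in range(n_mol):
            for b in range(a + 1, n_mol):
                d = pair_distance_matrix(fb.sites[a], fb.sites[b], fb.box)
                for i in range(3):
                    for j in range(3):
                        if d[i, j] < cutoff:
                            ia = pos[fb.site_labels[a][i]]
                            jb = pos[fb.site_labels[b][j]]
                            lo, hi = min(ia, jb), max(ia, jb)
                            raw[lo, hi] += 1.0
    raw /= len(frames)
    raw = raw + np.triu(raw, k=1).T  # symmetrise
    total = np.triu(raw).sum()
    if total == 0:
        return PIMatrix(raw=raw, percent=None, cutoff=cutoff, undefined=True)
    return PIMatrix(raw=raw, percent=raw / total * 100.0, cutoff=cutoff)
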