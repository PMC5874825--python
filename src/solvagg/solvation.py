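"""Solvation-structure metrics: RDFs, coordination numbers, peak ratios,
hydrogen-bond time series and hydration-shell statistics.

The radial distribution function g_αβ(r) is the probability, relative to
an ideal gas at the partner density, of finding a β atom at distance r
from an α atom.  The running coordination number is the standard
shell-volume-weighted integral

    n(r) = 4π (N/V) ∫₀ʳ g(r′) r′² dr′,

accumulated by the trapezoidal rule.  The amplitude ratio g_max/g_min of
the first peak to its following minimum serves as a proxy for
hydrogen-bond strength, and a distance criterion of 2.5 Å on X···H pairs
defines H-bond existence frame by frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import HBOND_CUTOFF
from .topology import (Trajectory, center_of_mass, pair_distance_matrix)

__all__ = [
    "RDFProfile",
    "PeakMetrics",
    "HydrationShellStats",
    "NoPeakError",
    "compute_rdf",
    "running_coordination_number",
    "first_peak_metrics",
    "peak_ratio",
    "hbond_series",
    "hydration_shell_distribution",
]


class NoPeakError(ValueError):
    """Raised when a profile has no first-peak/first-minimum structure."""


@dataclass
class RDFProfile:
    """Binned pair correlation with enough context to integrate it.

    ``density`` is the frame-averaged partner density N_b/V (Å⁻³) used by
    the coordination-number integral.
    """

    r: np.ndarray
    g: np.ndarray
    density: float
    labels: tuple[str, str] = ("a", "b")
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r.size != self.g.size:
            raise ValueError("r and g must be the same length")
        dr = np.diff(self.r)
        if self.r.size > 1 and (np.any(dr <= 0)
                                or not np.allclose(dr, dr[0], rtol=1e-6)):
            raise ValueError("bin centers must be uniform and increasing")
        if np.any(self.g < -1e-12):
            raise ValueError("g(r) must be non-negative")


@dataclass
class PeakMetrics:
    """First-peak maximum/minimum positions and amplitudes, and the
    coordination number at the first minimum."""

    r_max: float
    g_max: float
    r_min: float
    g_min: float
    n_w: float

    def __post_init__(self) -> None:
        if not self.r_min > self.r_max:
            raise ValueError("first minimum must lie beyond the maximum")
        if self.g_min < 0 or self.g_max < self.g_min:
            raise ValueError("require g_max ≥ g_min ≥ 0")

    @property
    def ratio(self) -> float:
        return peak_ratio(self)


@dataclass
class HydrationShellStats:
    """Per-frame hydration-shell occupancies and summary statistics."""

    counts: np.ndarray
    distribution: np.ndarray  # P(count = k) for k = 0..max
    mean: float
    mad: float  # mean absolute deviation about the mean


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def compute_rdf(traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray,
                bin_width: float = 0.02, r_cut: float | None = None,
                labels: tuple[str, str] = ("a", "b")) -> RDFProfile:
    """Frame-averaged radial distribution function between two atom
    selections under periodic boundary conditions.

    Selections must be disjoint at the atom level, or identical, in
    which case the self-RDF (pairs within the selection, i ≠ j) is
    computed.  Normalisation uses the frame-wise box volume, so NPT-like
    trajectories with varying boxes are handled.  ``r_cut`` defaults to
    half the smallest box edge and may not exceed it (minimum-image
    aliasing).
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty selection")
    shared = np.intersect1d(sel_a, sel_b)
    self_rdf = shared.size > 0
    if self_rdf and (sel_a.size != sel_b.size
                     or not np.array_equal(np.sort(sel_a), np.sort(sel_b))):
        raise ValueError("selections must be disjoint or identical "
                         "(identical → self-RDF)")

    min_edge = min(float(fr.box.min()) for fr in traj.frames)
    if r_cut is None:
        r_cut = min_edge / 2.0
    if r_cut > min_edge / 2.0 + 1e-9:
        raise ValueError(f"r_cut {r_cut} exceeds half the smallest box edge "
                         f"({min_edge / 2.0:.3f} Å): histogram would alias")

    n_bins = int(round(r_cut / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    counts = np.zeros(n_bins)
    expected = np.zeros(n_bins)
    dens_sum = 0.0
    for fr in traj.frames:
        d = pair_distance_matrix(fr.coordinates[sel_a],
                                 fr.coordinates[sel_b], fr.box)
        if self_rdf:
            iu = np.triu_indices(sel_a.size, k=1)
            dist = d[iu]
            n_ordered = sel_a.size * (sel_a.size - 1) / 2.0
        else:
            dist = d.ravel()
            n_ordered = sel_a.size * sel_b.size
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        expected += n_ordered * shell_vol / fr.volume
        dens_sum += sel_b.size / fr.volume

    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(r=centers, g=g, density=dens_sum / len(traj.frames),
                      labels=labels, counts=counts)


def running_coordination_number(rdf: RDFProfile) -> np.ndarray:
    """n(r) = 4π ρ ∫₀ʳ g(r′) r′² dr′ on the profile's bin centers
    (trapezoidal accumulation from r = 0; non-decreasing)."""
    integrand = rdf.g * rdf.r ** 2
    # include the implicit (0, 0) point so the first bin contributes
    r = np.concatenate(([0.0], rdf.r))
    y = np.concatenate(([0.0], integrand))
    n = 4.0 * math.pi * rdf.density * cumulative_trapezoid(y, r)
    return n


# ---------------------------------------------------------------------------
# Peak metrics
# ---------------------------------------------------------------------------

def _smooth3(g: np.ndarray) -> np.ndarray:
    pad = np.concatenate(([g[0]], g, [g[-1]]))
    return (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0


def first_peak_metrics(rdf: RDFProfile, search_from: float = 1.2,
                       smooth: bool = False) -> PeakMetrics:
    """Locate the first peak beyond ``search_from`` and its following
    minimum; ties break toward smaller r.

    The coordination number n_w is read from the running-coordination
    integral at the first-minimum position.  Raises :class:`NoPeakError`
    on profiles with no maximum-then-minimum structure.
    """
    g = _smooth3(rdf.g) if smooth else rdf.g
    r = rdf.r
    start = int(np.searchsorted(r, search_from))
    if start >= r.size - 2:
        raise NoPeakError("search window beyond the profile range")

    i_max = _first_turn(g, start, find_max=True)
    if i_max is None:
        raise NoPeakError("no first peak: profile has no local maximum "
                          f"beyond {search_from} Å")
    i_min = _first_turn(g, i_max + 1, find_max=False)
    if i_min is None:
        raise NoPeakError("no first-shell minimum after the first peak")

    n_curve = running_coordination_number(rdf)
    return PeakMetrics(r_max=float(r[i_max]), g_max=float(g[i_max]),
                       r_min=float(r[i_min]), g_min=float(g[i_min]),
                       n_w=float(n_curve[i_min]))


def _first_turn(g: np.ndarray, start: int, find_max: bool) -> int | None:
    """Index of the first local extremum at or after ``start``; plateaus
    resolve to their first (smallest-r) point."""
    y = g if find_max else -g
    n = y.size
    for i in range(max(start, 1), n - 1):
        if y[i - 1] < y[i] and y[i] >= y[i + 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                return i
    return None


def peak_ratio(metrics: PeakMetrics) -> float:
    """g_max/g_min, the H-bond-strength proxy.  A vanishing g_min yields
    the infinite-ratio sentinel ``math.inf`` rather than a number."""
    if metrics.g_min == 0:
        return math.inf
    return metrics.g_max / metrics.g_min


# ---------------------------------------------------------------------------
# Hydrogen-bond existence series
# ---------------------------------------------------------------------------

def hbond_series(traj: Trajectory, site_x: np.ndarray, site_h: np.ndarray,
                 cutoff: float = HBOND_CUTOFF) -> np.ndarray:
    """Per-frame boolean: is any X···H minimum-image distance ≤ cutoff?"""
    site_x = np.asarray(site_x, dtype=int)
    site_h = np.asarray(site_h, dtype=int)
    if site_x.size == 0 or site_h.size == 0:
        raise ValueError("empty selection")
    out = np.empty(len(traj.frames), dtype=bool)
    for k, fr in enumerate(traj.frames):
        d = pair_distance_matrix(fr.coordinates[site_x],
                                 fr.coordinates[site_h], fr.box)
        out[k] = bool(d.min() <= cutoff)
    return out


# ---------------------------------------------------------------------------
# Hydration shell
# ---------------------------------------------------------------------------

def hydration_shell_distribution(traj: Trajectory, solute: int,
                                 shell_radius: float) -> HydrationShellStats:
    """Distribution of the number of water COMs within ``shell_radius``
    of the solute COM (minimum image), with mean and mean absolute
    deviation about the mean."""
    if shell_radius <= 0:
        raise ValueError("shell_radius must be positive")
    top = traj.topology
    waters = top.water_molecules()
    if not waters:
        raise ValueError("topology contains no water molecules")
    sol_idx = top.atoms_of(solute)
    wat_idx = [top.atoms_of(m) for m in waters]

    counts = np.empty(len(traj.frames), dtype=int)
    for k, fr in enumerate(traj.frames):
        x = fr.coordinates
        com_s = center_of_mass(x[sol_idx], top.masses[sol_idx], fr.box)
        coms_w = np.array([center_of_mass(x[idx], top.masses[idx], fr.box)
                           for idx in wat_idx])
        d = np.linalg.norm(
            (coms_w - com_s) - fr.box * np.round((coms_w - com_s) / fr.box),
            axis=1)
        counts[k] = int((d <= shell_radius).sum())

    dist = np.bincount(counts) / counts.size
    mean = float(counts.mean())
    mad = float(np.abs(counts - mean).mean())
    return HydrationShellStats(counts=counts, distribution=dist,
                               mean=mean, mad=mad)
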