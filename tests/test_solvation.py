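"""RDFs, coordination numbers, peak metrics, H-bonds, hydration shells."""

import math

import numpy as np
import pytest
from _profiles import profile_through

from solvagg.solvation import (HydrationShellStats, NoPeakError, RDFProfile,
                               compute_rdf, first_peak_metrics, hbond_series,
                               hydration_shell_distribution, peak_ratio,
                               running_coordination_number)
from solvagg.synthetic import make_ideal_gas, solute_fragment, water_fragment
from solvagg.topology import Frame, SiteTopology, Trajectory


def _point_topology(n, species="water"):
    return SiteTopology(elements=["O"] * n, masses=np.full(n, 15.999),
                        labels=["X"] * n, molecule=np.arange(n),
                        group=["other"] * n,
                        species={i: species for i in range(n)})


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def test_ideal_gas_rdf_is_unity_within_mc_error():
    traj = make_ideal_gas(40, 20.0, 300, seed=1)
    sel = np.arange(40)
    rdf = compute_rdf(traj, sel, sel, bin_width=0.25, r_cut=9.0)
    # Poisson error per bin from the accumulated pair counts
    expected = rdf.counts / np.where(rdf.g > 0, rdf.g, 1.0)
    for k in range(rdf.r.size):
        if rdf.counts[k] < 5:  # tiny-count bins carry no information
            continue
        se = math.sqrt(rdf.counts[k]) / expected[k]
        assert abs(rdf.g[k] - 1.0) <= 3 * se


def test_single_pair_bin_value_matches_shell_normalization():
    """One a–b pair at 3.00 Å in a 20 Å box: g in the occupied bin is
    1/(ρ_b · V_shell)."""
    top = _point_topology(2)
    box = np.full(3, 20.0)
    coords = np.array([[5.0, 5.0, 5.0], [8.0, 5.0, 5.0]])
    traj = Trajectory([Frame(coords, box)], top)
    bw = 0.2
    rdf = compute_rdf(traj, np.array([0]), np.array([1]), bin_width=bw,
                      r_cut=9.0)
    k = int(3.0 / bw)  # bin [3.0, 3.2) holds the pair
    v_shell = 4 / 3 * math.pi * ((3.0 + bw) ** 3 - 3.0 ** 3)
    rho_b = 1.0 / box.prod()
    assert rdf.g[k] == pytest.approx(1.0 / (rho_b * v_shell), rel=1e-9)
    assert rdf.g[np.arange(rdf.g.size) != k].sum() == 0.0


def test_rdf_counts_match_brute_force_histogram(rng):
    top = _point_topology(50)
    box = np.array([12.0, 13.0, 14.0])
    coords = rng.uniform(0, 12, (50, 3))
    traj = Trajectory([Frame(coords, box)], top)
    sel_a = np.arange(20)
    sel_b = np.arange(20, 50)
    bw = 0.3
    rdf = compute_rdf(traj, sel_a, sel_b, bin_width=bw, r_cut=6.0)
    brute = np.zeros_like(rdf.counts)
    for i in sel_a:
        for j in sel_b:
            d = coords[i] - coords[j]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d)
            if r < rdf.counts.size * bw:
                brute[int(r / bw)] += 1
    assert np.array_equal(rdf.counts, brute)


def test_rcut_beyond_half_box_rejected():
    traj = make_ideal_gas(5, 10.0, 1, seed=0)
    with pytest.raises(ValueError, match="half"):
        compute_rdf(traj, np.arange(5), np.arange(5), bin_width=0.1,
                    r_cut=6.0)


# ---------------------------------------------------------------------------
# Running coordination number
# ---------------------------------------------------------------------------

def test_ncurve_zero_for_zero_g():
    prof = RDFProfile(r=np.arange(1, 100) * 0.05,
                      g=np.zeros(99), density=0.03)
    assert np.all(running_coordination_number(prof) == 0)


def test_ncurve_uniform_g_closed_form():
    rho = 0.0334
    r = np.arange(1, 400) * 0.02
    prof = RDFProfile(r=r, g=np.ones_like(r), density=rho)
    n = running_coordination_number(prof)
    closed = 4 / 3 * math.pi * r ** 3 * rho
    assert np.allclose(n, closed, rtol=5e-4, atol=1e-4)


def test_ncurve_plateau_counts_planted_partners():
    """Five partners inside the first shell, empty gap beyond → n(r)
    plateaus at 5."""
    n_part = 5
    top = _point_topology(1 + n_part)
    box = np.full(3, 30.0)
    rng = np.random.default_rng(0)
    frames = []
    for f in range(20):
        center = np.full(3, 15.0)
        coords = [center]
        for _ in range(n_part):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords.append(center + rng.uniform(2.0, 2.8) * u)
        frames.append(Frame(np.array(coords), box, time=float(f)))
    traj = Trajectory(frames, top)
    rdf = compute_rdf(traj, np.array([0]), np.arange(1, 1 + n_part),
                      bin_width=0.05, r_cut=8.0)
    n = running_coordination_number(rdf)
    gap = (rdf.r > 3.5) & (rdf.r < 7.5)
    assert np.allclose(n[gap], n_part, atol=0.05)


# ---------------------------------------------------------------------------
# Peak metrics and ratios
# ---------------------------------------------------------------------------

def test_first_peak_metrics_constructed_curve():
    prof = profile_through(1.79, 0.81, 2.50, 0.09)
    pk = first_peak_metrics(prof, search_from=1.2)
    assert pk.r_max == pytest.approx(1.79)
    assert pk.g_max == pytest.approx(0.81)
    assert pk.r_min == pytest.approx(2.50)
    assert pk.g_min == pytest.approx(0.09)


def test_monotone_profile_has_no_peak():
    r = np.arange(1, 200) * 0.02
    prof = RDFProfile(r=r, g=np.exp(-r), density=0.03)
    with pytest.raises(NoPeakError):
        first_peak_metrics(prof, search_from=1.2)


def test_peak_detection_matches_grid_scan_oracle(rng):
    """Random smooth rise–fall–rise profiles: compare against an
    exhaustive argmax/argmin scan."""
    for _ in range(100):
        r_max = rng.uniform(1.5, 2.2)
        r_min = rng.uniform(2.4, 3.2)
        g_max = rng.uniform(0.5, 3.0)
        g_min = rng.uniform(0.01, 0.4 * g_max)
        prof = profile_through(round(r_max, 2), g_max, round(r_min, 2),
                               g_min)
        pk = first_peak_metrics(prof, search_from=1.2)
        sl = prof.r >= 1.2
        i_max_oracle = np.argmax(prof.g[sl])
        i_min_oracle = i_max_oracle + np.argmin(prof.g[sl][i_max_oracle:])
        assert pk.r_max == pytest.approx(prof.r[sl][i_max_oracle])
        assert pk.r_min == pytest.approx(prof.r[sl][i_min_oracle])


@pytest.mark.parametrize("gmax,gmin,expected", [
    (0.81, 0.09, 9.00),
    (2.38, 0.17, 14.00),
    (1.0, 1.0, 1.0),
])
def test_peak_ratio_values(gmax, gmin, expected):
    from solvagg.solvation import PeakMetrics
    pk = PeakMetrics(r_max=1.79, g_max=gmax, r_min=2.50, g_min=gmin,
                     n_w=1.0)
    assert peak_ratio(pk) == pytest.approx(expected, abs=1e-9)


def test_peak_ratio_zero_minimum_is_infinite_sentinel():
    prof = profile_through(1.79, 0.8, 2.50, 0.0, g_end=0.3)
    pk = first_peak_metrics(prof)
    assert peak_ratio(pk) == math.inf


def test_peak_ratio_scale_invariance():
    p1 = profile_through(1.79, 0.81, 2.50, 0.09)
    p2 = RDFProfile(r=p1.r, g=3.7 * p1.g, density=p1.density)
    r1 = peak_ratio(first_peak_metrics(p1))
    r2 = peak_ratio(first_peak_metrics(p2))
    assert r1 == pytest.approx(r2, rel=1e-12)


# ---------------------------------------------------------------------------
# H-bond series
# ---------------------------------------------------------------------------

def _fixed_pair_traj(dist):
    top = _point_topology(2)
    box = np.full(3, 20.0)
    coords = np.array([[1.0, 1.0, 1.0], [1.0 + dist, 1.0, 1.0]])
    frames = [Frame(coords, box, time=float(k)) for k in range(5)]
    return Trajectory(frames, top)


def test_hbond_series_thresholds():
    a, b = np.array([0]), np.array([1])
    assert hbond_series(_fixed_pair_traj(2.0), a, b).all()
    assert not hbond_series(_fixed_pair_traj(3.0), a, b).any()


def test_hbond_series_monotone_in_cutoff():
    traj = _fixed_pair_traj(2.5)
    a, b = np.array([0]), np.array([1])
    small = hbond_series(traj, a, b, cutoff=1e-6)
    huge = hbond_series(traj, a, b, cutoff=1e6)
    assert not small.any() and huge.all()


# ---------------------------------------------------------------------------
# Hydration shell
# ---------------------------------------------------------------------------

def _shell_topology(n_waters):
    solute = solute_fragment("nonionic")
    top_frags = [solute] + [None] * 0
    elements = list(solute.elements) + ["O"] * n_waters
    masses = np.concatenate([solute.masses, np.full(n_waters, 15.999)])
    labels = list(solute.labels) + ["Ow"] * n_waters
    molecule = np.concatenate([np.zeros(len(solute.elements), dtype=int),
                               np.arange(1, n_waters + 1)])
    group = list(solute.groups) + ["water"] * n_waters
    species = {0: "nonionic"}
    species.update({i: "water" for i in range(1, n_waters + 1)})
    return SiteTopology(elements, masses, labels, molecule, group, species), \
        solute


def _shell_frame(top, solute, counts_inside, n_waters, box, rng, t):
    center = box / 2
    coords = [solute.coords - solute.com + center]
    for i in range(n_waters):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rng.uniform(4.5, 5.8) if i < counts_inside else \
            rng.uniform(8.0, 12.0)
        coords.append((center + r * u)[None, :])
    return Frame(np.vstack(coords), box, time=t)


def test_alternating_counts_mean_and_mad():
    """Frames alternating 3 and 5 shell waters → mean 4, MAD 1."""
    rng = np.random.default_rng(2)
    box = np.full(3, 40.0)
    top, solute = _shell_topology(8)
    frames = [_shell_frame(top, solute, 3 if k % 2 else 5, 8, box, rng,
                           float(k)) for k in range(10)]
    stats = hydration_shell_distribution(Trajectory(frames, top), 0,
                                         shell_radius=6.0)
    assert stats.mean == pytest.approx(4.0)
    assert stats.mad == pytest.approx(1.0)
    assert stats.distribution.sum() == pytest.approx(1.0)


def test_empty_shell_distribution():
    rng = np.random.default_rng(3)
    box = np.full(3, 40.0)
    top, solute = _shell_topology(5)
    frames = [_shell_frame(top, solute, 0, 5, box, rng, float(k))
              for k in range(4)]
    stats = hydration_shell_distribution(Trajectory(frames, top), 0,
                                         shell_radius=3.0)
    assert stats.mean == 0.0 and stats.mad == 0.0
    assert stats.distribution[0] == pytest.approx(1.0)


def test_poisson_planted_counts_recovered():
    """Occupancies drawn Poisson(λ=24) are reproduced exactly per frame
    and the mean lands within 3 SE of λ."""
    lam, n_frames, n_waters = 24, 100, 45
    rng = np.random.default_rng(8)
    ks = np.minimum(rng.poisson(lam, n_frames), n_waters)
    box = np.full(3, 40.0)
    top, solute = _shell_topology(n_waters)
    frames = [_shell_frame(top, solute, int(k), n_waters, box, rng,
                           float(i)) for i, k in enumerate(ks)]
    stats = hydration_shell_distribution(Trajectory(frames, top), 0,
                                         shell_radius=6.0)
    assert np.array_equal(stats.counts, ks)
    assert abs(stats.mean - lam) <= 3 * math.sqrt(lam / n_frames)


def test_shell_mean_consistent_with_com_rdf_integral(solvated_traj):
    """The shell occupancy mean equals the COM–COM running coordination
    number at the shell radius (quadrature-level agreement)."""
    from solvagg.topology import center_of_mass
    traj = solvated_traj
    top = traj.topology
    waters = top.water_molecules()
    shell_radius = 4.6
    stats = hydration_shell_distribution(traj, 0, shell_radius)

    # build a COM pseudo-trajectory: one site per molecule
    n = 1 + len(waters)
    ptop = _point_topology(n)
    sol_idx = top.atoms_of(0)
    frames = []
    for fr in traj.frames:
        pts = [center_of_mass(fr.coordinates[sol_idx], top.masses[sol_idx],
                              fr.box)]
        for m in waters:
            idx = top.atoms_of(m)
            pts.append(center_of_mass(fr.coordinates[idx], top.masses[idx],
                                      fr.box))
        frames.append(Frame(np.array(pts), fr.box, time=fr.time))
    ptraj = Trajectory(frames, ptop)
    rdf = compute_rdf(ptraj, np.array([0]), np.arange(1, n), bin_width=0.05)
    n_curve = running_coordination_number(rdf)
    k = int(np.searchsorted(rdf.r, shell_radius))
    assert n_curve[k] == pytest.approx(stats.mean, abs=0.15)
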