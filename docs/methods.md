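# Methods

This note documents the models, conventions and defaults behind
`solvagg`, and what the synthetic generators do and do not emulate.

## Geometry and periodic boundaries

Only orthorhombic cells are supported; triclinic input is rejected with
an explicit error. Under that restriction the minimum-image convention
reduces to a per-axis nearest-integer wrap, which is exact, and every
distance-based criterion in the package (H-bonds, contact filters, pair
counts, PIM) uses it. Group centres of mass are computed after
unwrapping the group's atoms to the periodic image nearest its first
atom; this prevents split-molecule artifacts for molecules straddling a
box face and is our convention — trajectories are not assumed to be
pre-unwrapped. Coordinates are Å internally; GRO files are nm on disk
and are converted on read/write. GRO frames are written with four
decimals (the high-precision variant of the format) so that write→read
round-trips preserve coordinates to 10⁻³ Å; extended XYZ uses six
decimals.

## Solvation metrics

g(r) is normalised per frame against the ideal-gas expectation using
the frame's own box volume, so constant-pressure trajectories with
fluctuating cells are handled. Defaults: bin width 0.02 Å; the cutoff
defaults to half the smallest box edge and may not exceed it.

The running coordination number is the standard shell-volume-weighted
integral n(r) = 4π(N/V)∫₀ʳ g(r′) r′² dr′, accumulated by the
trapezoidal rule with an implicit (0, 0) anchor point. (An often-seen
shorthand drops the r′² factor from the printed formula; the integral
is only dimensionally meaningful, and only reproduces plateau heights,
with it.)

First-peak detection scans the raw binned profile for the first local
maximum beyond `search_from` (default 1.2 Å, which excludes
covalent-distance artifacts) and the first subsequent local minimum;
plateaus resolve to their smallest-r point, matching the "first peak"
reading. An optional 3-bin moving average (off by default) is available
for noisy profiles. A monotone profile raises an explicit no-peak error
rather than returning a boundary value. The amplitude ratio
g_max/g_min is reported as an H-bond-strength proxy; a vanishing
minimum yields an infinite-ratio sentinel (`math.inf`), never a silent
division error. n_w is read off the n(r) curve at the first minimum.

Hydration-shell statistics count water COMs within a shell radius of
the solute COM. The mean absolute deviation is taken about the mean
(the conventional reading when no centre is specified). Because the
occupancy count is an integral quantity, its mean equals the COM–COM
running coordination number at the shell radius up to binning error —
this consistency is enforced in the tests. Coordination numbers of
multi-atom groups can be read per site (e.g. per carboxylate oxygen) or
per group by selecting the corresponding atoms; both views are exposed
through selections rather than baked in.

## Synthetic data: what is and is not emulated

Generators produce i.i.d. frames — there is no dynamics, no temporal
correlation and no Boltzmann sampling of configurations. Planted
features are constructed geometrically, which makes the ground truth
exact rather than estimated:

* **Solvated solute** (default: one solute in 210 waters, cubic box
  18.6 Å, matching a ~0.26 mol·L⁻¹ single-solute study box): per frame
  and per acceptor site (O_m, N_m), a Bernoulli draw decides whether a
  water hydrogen is placed 1.7–2.4 Å from the site; otherwise all water
  hydrogens are kept ≥ 2.6 Å away. The 2.5 Å existence criterion
  therefore fires exactly on the planted draws. Remaining waters are
  uniform subject to a 1.5 Å closest-approach floor (random sequential
  insertion with bounded retries; infeasible densities raise an error).
* **Planted mixture** (default: 10 + 10 solutes in a 50 Å box,
  mirroring equal-amounts mixed solutions): per frame, the per-class
  contact count is floor(f) + Bernoulli(frac(f)), so the mean equals
  the requested frequency exactly — a capped Poisson would be biased at
  these molecule counts. Contacted pairs are vertex-disjoint and placed
  with minimum interatomic distance in [3.2, 3.9] Å (bisection along a
  random direction); all other molecule pairs are kept > 4.5 Å apart,
  and every accepted frame is re-verified by brute force. Disjointness
  requires a little headroom in the molecule counts beyond the
  combinatorial bound; the spec validator enforces it. Water is not
  included — every statistic taken from these boxes is
  solute–solute only.
* **Isomer ensembles**: energies on an exact ladder base + i·spacing
  (minimum at index 0); the seed randomises only the base, to which
  Boltzmann weights are invariant. Reference weights and averages are
  evaluated in long-double precision directly from the defining
  ratio of exponentials, independent of the shifted-exponential
  implementation they are used to test.
* **Toy energy oracle**: pairwise 12-6 Lennard-Jones plus Coulomb over
  intermolecular site pairs, Lorentz–Berthelot combining, parameters
  fixed per element in a packaged table so oracle energies are stable
  across versions. It stands in for any electronic-structure scorer
  behind the same call signature; it is a real (if crude) interaction
  model, not a physical water/solute force field.

Consequently, passing tests demonstrate the *analysis machinery* —
normalisations, criteria, counting, ranking, averaging — on data whose
truth is known exactly. They do not validate force fields, sampling
quality or any physical prediction about real solutions.

The packaged solute fragments are idealized planar tautomers (ring C–C
1.39 Å, standard substituent bond lengths; carboxyl/carboxylate and
amine/ammonium variants). Only the group topology (one amino, one ring,
one carboxyl group per solute) and rough size matter to the analyses.

## Cluster search

Mobile-fragment COMs are uniform in a cube centred on the central
unit's COM (COM-centring is our choice); orientations are uniform over
SO(3) via random unit quaternions. Placements violating a 1.5 Å
hard-sphere floor are redrawn. The contact filter keeps candidates with
any mobile atom within 4.0 Å of the central unit. Ranking uses
f_i ∝ exp(−(E_i−E₀)/RT) at T = 298 K by default, computed on shifted
energies (exact, overflow-safe); ties keep input order. Selection takes
the union of {f_i ≥ 0.01} and a seeded without-replacement sample from
the 3–15 kcal·mol⁻¹ window, with the sample size drawn once per run
from {10,…,15} (the protocol states a range, not a number). Default
candidate counts are 10³–10⁴ in the pipeline configuration: the toy
landscape is smooth and cheap, and the tests show that 2 × 10³
candidates already locate the grid-enumerated minimum for ≥ 95% of
seeds; production searches against an expensive oracle would raise the
knob. Dimers only — no trimer/tetramer growth protocol.

For a molecule-level dimer the "at least one atom of each mobile
molecule" contact condition coincides with "any mobile atom"; the
multi-molecule generalisation is left open deliberately.

## Thermodynamics

R = 1.98720425 × 10⁻³ kcal·mol⁻¹·K⁻¹ throughout. The standard-state
correction RT·ln(R̃T) uses R̃ = 0.082 carried as a plain constant with
unit K⁻¹ (so R̃T is a pure number); dimensionally this is the gas
constant in L·atm·mol⁻¹·K⁻¹ — numerically identical, documented rather
than "fixed". Both free-energy routes are pure bookkeeping over
user-supplied component tables (TSV, one row per species/isomer,
columns named as the `FreeEnergyComponents` fields); the electronic-
structure numbers themselves are inputs, not something this package can
produce. Boltzmann weights are always computed on minimum-shifted
energies; the shift cancels exactly.

## Aggregation statistics

Two deliberately different contact criteria coexist: molecular pair
counting uses the minimum *interatomic* distance ≤ 4.0 Å (a molecule-
level criterion), while the PIM uses group-COM distances strictly
below 4.0 Å (the pairwise interaction function is defined on the
three-body sites; the measure-zero boundary counts as no contact).
Intramolecular site pairs are never counted — within one molecule the
A–B and B–C distances are always inside the cutoff and would swamp the
matrix. Unordered pairs are counted once. Percent normalisation pools
counts over frames first, then divides by the grand total over the 21
upper-triangle elements (pooled-then-normalised; the alternative,
per-frame normalisation before averaging, differs when frame totals
fluctuate and is not what a time-averaged contact census means here).
A trajectory with no contacts at all returns the raw zero matrix with
percentages flagged undefined instead of dividing by zero. The
`--last-ns` selector restricts any analysis to the final stretch of a
trajectory, mirroring the common practice of discarding equilibration.

## Numerical choices and degenerate inputs

* Peak/minimum ties break toward smaller r.
* Empty selections, empty ensembles, zero total mass, missing boxes,
  r_cut beyond half the box, mixed thermodynamic routes and malformed
  trajectory frames all raise explicit errors naming the offender.
* All stochastic stages take an integer seed and are bit-reproducible;
  the pipeline writes the seed into every summary and derives per-stage
  seeds by fixed small offsets.
* Problem sizes in the shipped configuration (tens to hundreds of
  frames, 10–210 molecules, 2 × 10³ search candidates) were chosen so
  statistical assertions have 3-standard-error headroom while the whole
  suite stays interactive.

## Known limitations

* Orthorhombic boxes only; no angular H-bond criterion (distance only);
  no bond perception — group membership always comes from the topology
  sidecar.
* Synthetic frames are statistically independent; autocorrelation-aware
  error bars are out of scope.
* The toy oracle's absolute energies are not comparable to any
  electronic-structure scale; only the search/ranking/selection
  machinery around it is.
* No cluster-size distributions, percolation analysis or free-energy
  estimates from pair populations.
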