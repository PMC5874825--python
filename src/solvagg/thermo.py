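"""Association free energies and Boltzmann ensemble averaging.

Two bookkeeping routes assemble the liquid-phase free energy G* of a
species from externally supplied components (the components themselves
come from quantum chemistry and are inputs here, read from TSV tables):

* **gas route** — gas-phase electronic energy + gas-phase
  vibrational/rotational/translational free energy + solvation free
  energy + the 1 atm → 1 mol·L⁻¹ standard-state correction RT·ln(R̃T);
* **solution route** — liquid-phase total energy (electronic expectation
  value + bulk-electrostatic polarisation + cavitation/dispersion/
  structural terms) + liquid-phase VRT free energy.

The association free energy of A + B → AB is then G*(AB) − G*(A) − G*(B)
on a single route, and multi-isomer species are collapsed first with the
Boltzmann ensemble average ⟨G⟩ = Σᵢ fᵢ G(Xᵢ), fᵢ ∝ exp(−G(Xᵢ)/RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, R_KCAL, RTILDE

__all__ = [
    "FreeEnergyComponents",
    "IsomerEnsemble",
    "AssociationResult",
    "standard_state_correction",
    "free_energy_gas_route",
    "free_energy_solution_route",
    "association_free_energy",
    "boltzmann_weights",
    "boltzmann_average",
    "read_component_table",
    "association_report",
]

GAS_FIELDS = ("E_e_gas", "dG_VRT_gas", "dG_solv")
SOLUTION_FIELDS = ("E_e_soln", "dG_EP", "G_CDS", "dG_VRT_soln")


@dataclass
class FreeEnergyComponents:
    """Per-species free-energy components (kcal/mol) for one route.

    Exactly the fields of the declared route must be set:
    ``gas`` → E_e_gas, dG_VRT_gas, dG_solv (the standard-state correction
    is added automatically); ``solution`` → E_e_soln, dG_EP, G_CDS,
    dG_VRT_soln.
    """

    route: str
    E_e_gas: float | None = None
    dG_VRT_gas: float | None = None
    dG_solv: float | None = None
    E_e_soln: float | None = None
    dG_EP: float | None = None
    G_CDS: float | None = None
    dG_VRT_soln: float | None = None
    temperature: float = DEFAULT_TEMPERATURE
    rtilde: float = RTILDE

    def __post_init__(self) -> None:
        if self.route not in ("gas", "solution"):
            raise ValueError("route must be 'gas' or 'solution'")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        fields = GAS_FIELDS if self.route == "gas" else SOLUTION_FIELDS
        for f in fields:
            if getattr(self, f) is None:
                raise ValueError(f"route '{self.route}' requires field {f!r}")


@dataclass
class IsomerEnsemble:
    """Free energies (or energies) of the low-lying isomers of one
    species, with lazily computed Boltzmann weights."""

    free_energies: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.free_energies = np.atleast_1d(
            np.asarray(self.free_energies, dtype=float))
        if self.free_energies.size < 1:
            raise ValueError("ensemble needs at least one isomer")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def weights(self) -> np.ndarray:
        return boltzmann_weights(self.free_energies, self.temperature)


@dataclass
class AssociationResult:
    """Dimerisation energetics for one reaction A + B → AB (kcal/mol)."""

    reaction: str
    route: str
    dG_ass: float
    dE_e_gas: float | None = None
    dG_ass_standard: float | None = None


def standard_state_correction(T: float = DEFAULT_TEMPERATURE,
                              rtilde: float = RTILDE) -> float:
    """RT·ln(R̃T): free-energy change of an ideal gas from 1 atm to
    1 mol·L⁻¹ (≈ 1.89 kcal/mol at 298 K with R̃ = 0.082)."""
    if T <= 0 or rtilde <= 0:
        raise ValueError("T and R̃ must be positive")
    return R_KCAL * T * math.log(rtilde * T)


def free_energy_gas_route(c: FreeEnergyComponents) -> float:
    """G* from separate gas-phase and solvation calculations."""
    if c.route != "gas":
        raise ValueError("components are not on the gas route")
    return (c.E_e_gas + c.dG_VRT_gas + c.dG_solv
            + standard_state_correction(c.temperature, c.rtilde))


def free_energy_solution_route(c: FreeEnergyComponents) -> float:
    """G* from a liquid-phase-optimised calculation."""
    if c.route != "solution":
        raise ValueError("components are not on the solution route")
    return (c.E_e_soln + c.dG_EP + c.G_CDS) + c.dG_VRT_soln


def free_energy(c: FreeEnergyComponents) -> float:
    return (free_energy_gas_route(c) if c.route == "gas"
            else free_energy_solution_route(c))


def association_free_energy(g_ab: float, g_a: float, g_b: float) -> float:
    """ΔG*_ass = G*(AB) − G*(A) − G*(B); all inputs must share one route
    and temperature (the caller's responsibility when passing bare
    floats; enforced when passing components via :func:`associate`)."""
    return g_ab - g_a - g_b


def associate(ab: FreeEnergyComponents, a: FreeEnergyComponents,
              b: FreeEnergyComponents, reaction: str = "A + B -> AB"
              ) -> AssociationResult:
    """Route- and temperature-checked association free energy."""
    if not (ab.route == a.route == b.route):
        raise ValueError("mixed routes in association")
    if not (ab.temperature == a.temperature == b.temperature):
        raise ValueError("mixed temperatures in association")
    dg = association_free_energy(free_energy(ab), free_energy(a),
                                 free_energy(b))
    de = (ab.E_e_gas - a.E_e_gas - b.E_e_gas
          if ab.route == "gas" else None)
    return AssociationResult(reaction=reaction, route=ab.route, dG_ass=dg,
                             dE_e_gas=de)


def boltzmann_weights(energies: np.ndarray, T: float) -> np.ndarray:
    """Normalised exp(−(Eᵢ−E₀)/RT); the shift by the minimum is exact and
    avoids overflow for deep energies."""
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    if e.size == 0:
        raise ValueError("empty energy list")
    if T <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(e - e.min()) / (R_KCAL * T))
    return w / w.sum()


def boltzmann_average(ensemble: IsomerEnsemble) -> float:
    """⟨G⟩ = Σᵢ fᵢ G(Xᵢ) over the ensemble's isomers."""
    w = ensemble.weights
    return float((w * ensemble.free_energies).sum())


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_COLUMN_FIELDS = ("E_e_gas", "dG_VRT_gas", "dG_solv", "E_e_soln", "dG_EP",
                  "G_CDS", "dG_VRT_soln")


def read_component_table(path: str | Path,
                         temperature: float = DEFAULT_TEMPERATURE
                         ) -> dict[str, list[FreeEnergyComponents]]:
    """Read a TSV of per-species (optionally per-isomer) components.

    Required columns: ``species``, ``route``; then the component columns
    named exactly as the :class:`FreeEnergyComponents` fields.  Several
    rows per species form its isomer ensemble.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("species", "route"):
        if col not in df.columns:
            raise ValueError(f"component table lacks column {col!r}")
    out: dict[str, list[FreeEnergyComponents]] = {}
    for _, row in df.iterrows():
        kwargs = {f: float(row[f]) for f in _COLUMN_FIELDS
                  if f in df.columns and pd.notna(row[f])}
        comp = FreeEnergyComponents(route=str(row["route"]),
                                    temperature=temperature, **kwargs)
        out.setdefault(str(row["species"]), []).append(comp)
    return out


def association_report(results: list[AssociationResult]) -> pd.DataFrame:
    """Summary table: one reaction per row, dimerisation energetics in
    kcal/mol."""
    return pd.DataFrame([
        {"reaction": r.reaction, "route": r.route,
         "dE_e_gas": r.dE_e_gas, "dG_ass_std": r.dG_ass_standard,
         "dG_ass": r.dG_ass}
        for r in results
    ])
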