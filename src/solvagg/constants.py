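"""Physical constants and shared defaults.

Energies are kcal/mol, distances Å, times ps, temperatures K throughout the
package; GRO files are the single exception (nm on disk, converted on read).
"""

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.98720425e-3

#: Default temperature for Boltzmann weighting and thermochemistry (K).
DEFAULT_TEMPERATURE = 298.0

#: Inverse-concentration factor R̃ entering the 1 atm → 1 mol·L⁻¹
#: standard-state correction RT·ln(R̃T).  Dimensionally this is the gas
#: constant in L·atm·mol⁻¹·K⁻¹ (0.082057), conventionally quoted as K⁻¹ so
#: that R̃T is a pure number at T in kelvin; the two readings are
#: numerically identical here.
RTILDE = 0.082

#: Distance criterion for an intermolecular hydrogen bond (Å).
HBOND_CUTOFF = 2.5

#: Distance criterion for a heavy-atom / group-COM contact (Å), used by the
#: cluster-search filter, molecular pair counting and the pairwise
#: interaction matrix.
CONTACT_CUTOFF = 4.0

#: Hard floor on interatomic distances in generated geometries (Å).
CLOSEST_APPROACH = 1.5

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻² (for the toy site-site potential).
COULOMB_K = 332.0637
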