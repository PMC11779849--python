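"""Physical constants and unit conversions used across the pipeline.

Conventions: coordinates in Å and trajectory time in ps; AFM separations in
nm and forces in pN; FRAP time in s.  All conversions live here so the rest
of the package never multiplies by raw powers of ten.
"""

#: Boltzmann constant in pN·nm·K⁻¹ (1.380649e-23 J/K expressed in pN·nm).
KB_PN_NM = 0.0138065

#: Avogadro constant, mol⁻¹.
AVOGADRO = 6.02214076e23

#: One kJ·mol⁻¹·nm⁻¹ expressed in pN (1e3 J / N_A / 1e-9 m, in units of 1e-12 N).
KJ_MOL_NM_TO_PN = 1e3 / AVOGADRO / 1e-9 * 1e12

PS_PER_NS = 1000.0
ANGSTROM_PER_NM = 10.0


def thermal_energy(temperature_k: float) -> float:
    """k_B·T in pN·nm at the given absolute temperature."""
    return KB_PN_NM * temperature_k


def kj_mol_nm_to_pn(f: float) -> float:
    """Convert a molar force gradient (kJ·mol⁻¹·nm⁻¹) to piconewtons."""
    return f * KJ_MOL_NM_TO_PN


def ps_to_ns(t_ps: float) -> float:
    return t_ps / PS_PER_NS


def ns_to_ps(t_ns: float) -> float:
    return t_ns * PS_PER_NS
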