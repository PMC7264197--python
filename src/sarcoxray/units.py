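"""Unit conventions and conversions used throughout the package.

Conventions (kept in one place so no module hand-rolls its own factors):

* axial reciprocal coordinates and axial spacings: Å⁻¹ and Å
  (actin monomer repeat ~27.3 Å, layer-line pitches ~51-59 Å);
* radial reciprocal coordinates: nm⁻¹, lattice spacings: nm
  (d1,0 of the hexagonal myofilament lattice ~36 nm);
* reciprocal coordinate q = 1/d (no 2π factor), matching how fiber
  diffraction spacings are quoted;
* specific force: mN/mm²; per-filament force: pN.
"""

from __future__ import annotations

#: hc in keV·Å — converts photon energy to wavelength.
HC_KEV_ANGSTROM = 12.3984

#: 1 Å⁻¹ expressed in nm⁻¹.
INV_ANGSTROM_TO_INV_NM = 10.0

#: 1 mN/mm² expressed in pN/nm² (10⁹ pN per mN, 10¹² nm² per mm²).
MN_PER_MM2_TO_PN_PER_NM2 = 1.0e-3


def wavelength_angstrom(photon_energy_kev: float) -> float:
    """X-ray wavelength λ (Å) for a photon energy in keV: λ = 12.3984/E."""
    if photon_energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_ANGSTROM / photon_energy_kev


def inv_nm_to_inv_angstrom(q_inv_nm: float) -> float:
    return q_inv_nm / INV_ANGSTROM_TO_INV_NM


def inv_angstrom_to_inv_nm(q_inv_a: float) -> float:
    return q_inv_a * INV_ANGSTROM_TO_INV_NM


def spacing_angstrom(q_inv_a: float) -> float:
    """d = 1/q with q in Å⁻¹."""
    return 1.0 / q_inv_a


def spacing_nm(q_inv_nm: float) -> float:
    """d = 1/q with q in nm⁻¹."""
    return 1.0 / q_inv_nm
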