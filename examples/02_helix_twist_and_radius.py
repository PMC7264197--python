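"""Actin helix parameters, twist change and filament radius.

Measures a wild-type pattern and a perturbed one whose long (left-handed)
pitch is reduced 0.43%, then derives the monomer rise h, subunits per
turn n, the twist change Δn/n, and the filament radius from the ALL6
radial first maximum under both Bessel-constant conventions.
"""

import sarcoxray as sx
from sarcoxray import reflections as refl, structure as struct

geom = sx.default_geometry()


def measure(spec):
    corrected, dsum = sx.subtract_background(sx.quadrant_fold(sx.simulate_pattern(spec, geom)))
    return refl.measure_pattern(corrected, diffuse_sum=dsum)


wt = measure(sx.PatternSpec())
mut = measure(sx.PatternSpec(helix=struct.HelixParams(59.15 * 0.9957, 50.70, radius_nm=5.2)))

helices = {}
for label, rs in [("WT", wt), ("mutant", mut)]:
    h = struct.helix_from_layerlines(rs["ALL6"].axial_spacing_a, rs["ALL7"].axial_spacing_a)
    helices[label] = h
    print(f"{label}: d6={h.d6_a:.3f} Å  d7={h.d7_a:.3f} Å  "
          f"rise h={h.h_a:.3f} Å  n={h.n_subunits_per_turn:.5f} subunits/turn")

twist = struct.twist_change(helices["WT"], helices["mutant"])
print(f"twist change dn/n = {100 * twist:+.3f}%  "
      "(negative dn/n: fewer subunits per turn, i.e. a more tightly wound helix)")

r1 = wt["ALL6"].radial_position_inv_nm
print(f"ALL6 radial first maximum: r = {r1:.5f} 1/nm")
print(f"filament radius R = {struct.actin_radius(r1):.3f} nm (1.85 convention), "
      f"{struct.actin_radius(r1, struct.BESSEL_J1_FIRST_MAX_EXACT):.3f} nm (exact J1 argmax)")
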