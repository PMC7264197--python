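"""Muscle-mechanics curve fits on generated traces.

Draws force-frequency, force-pCa, force-redevelopment (k_tr) and
slack-test data from their ground-truth models with realistic noise,
fits each, and compares the recovered parameters with the truth.
"""

import sarcoxray as sx
from sarcoxray import mechanics as mech

spec = sx.MechSpec(noise_sd={"force_frequency": 5.0, "force_pca": 2.0,
                             "ktr": 1.0, "slack": 0.001}, seed=42)

hill = mech.fit_force_frequency(sx.simulate_force_frequency(spec))
print(f"force-frequency: F50 = {hill.f50_hz:.2f} Hz (truth 45), "
      f"nH = {hill.nh:.2f} (truth 3), Fmax = {hill.fmax:.1f} mN (truth 400)")

pca = mech.fit_force_pca(sx.simulate_force_pca(spec))
print(f"force-pCa: pCa50 = {pca.pca50:.3f} (truth 5.9), nH = {pca.nh:.2f} (truth 5)")

ktr = mech.fit_ktr(sx.simulate_ktr_trace(spec))
print(f"k_tr: fast rate = {ktr.ktr_per_s:.2f} 1/s (truth 20), "
      f"slow rate = {ktr.k_per_s:.2f} 1/s (truth 2)")

vel = mech.unloaded_velocity(sx.simulate_slack_test(spec))
print(f"slack test: unloaded velocity = {vel.velocity_lengths_per_s:.3f} lengths/s "
      f"(truth 2.0), activation delay = {1e3 * vel.intercept_s:.2f} ms")

# normalization: an 11 mg EDL at optimal length 13 mm
geom = mech.MuscleGeometry(mass_mg=11.0, l0_mm=13.0, muscle_type="EDL")
area = mech.pcsa(geom)
print(f"PCSA = {area:.3f} mm²; 400 mN tetanus → specific force "
      f"{mech.specific_force(400.0, area):.1f} mN/mm²")

# does one force-frequency curve fit two shifted datasets?
a = sx.simulate_force_frequency(sx.MechSpec(noise_sd={"force_frequency": 5.0}, seed=1))
b = sx.simulate_force_frequency(
    sx.MechSpec(hill=sx.HillSpec(f50_hz=60.0), noise_sd={"force_frequency": 5.0}, seed=2))
res = mech.compare_curves_ftest([a, b], model="hill_ff")
print(f"one-curve-fits-all F-test: F = {res['F']:.1f} "
      f"(df {res['dfn']},{res['dfd']}), p = {res['p']:.2e} → separate curves needed")
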