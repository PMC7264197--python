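# sarcoxray

Analysis of small-angle X-ray fiber-diffraction patterns from intact
striated muscle, together with the standard muscle-mechanics curve fits —
the measurement chain used to characterize thin-filament structure in
myopathy models (e.g. nebulin-based nemaline myopathy) against wild-type
muscle.

**Who it is for.** Muscle physiologists and structural biologists who
record 2D detector images (Pilatus-style 32-bit TIFF) of resting and
tetanized muscle and force traces from intact-muscle or skinned-fiber
rigs, and who want a scripted, reproducible version of the usual
reduction steps: frame averaging, quadrant folding, background
subtraction with a summed-diffuse normalization standard, projection
traces, centroid spacings, Gaussian reflection intensities, equatorial
lattice analysis, and the structural quantities derived from them.

## What it computes

Given detector geometry (sample-detector distance, 172 µm pixels, 12 keV
beam), pixels map to reciprocal space by the exact Bragg relation
d = λ/(2 sin θ), θ = ½·atan(x/SDD).  From folded, background-subtracted
patterns the package measures:

* **meridionals** — the 27 Å actin monomer repeat (M13) and troponin TN3,
  via axial projection over 0 ≤ R ≤ 0.053 nm⁻¹ and peak centroids;
* **actin layer lines** ALL6 (~59 Å, left-handed one-start helix), ALL7
  (~51 Å, right-handed) and the tropomyosin-sensitive ALL2, with
  Gaussian-fitted intensities normalized by the summed diffuse
  background;
* **equator** — d₁,₀ (and d₁,₁ = d₁,₀/√3) of the hexagonal filament
  lattice.

Derived quantities follow the standard helix geometry.  With one-start
pitches d₆ > d₇ and monomer rise h,

    1/d₆ + 1/d₇ = 1/h,      n = 1 + d₆/d₇   (subunits per turn)

so layer-line spacings give h and n, and the twist change between
conditions is Δn/n.  The filament radius comes from the ALL6 radial
first maximum r through the J₁ Bessel profile, R = 1.85/(2πr) (the exact
argmax 1.84118 is available by option).  Thin-filament stiffness is
κ = F/(ε·1000) pN/nm/µm from the per-filament force F (specific force ×
myofibrillar fraction × unit-cell area 2·d₁,₀²/√3 per two thin filaments)
and the M13 strain ε.  The expected specific-force deficit budget adds a
lattice term, 100·(1 − (s_ref/s_test)²) with s = (2/3)·d₁,₀, to the
myofibrillar fractional-area difference in percentage points.

Mechanics fits: the force-frequency sigmoid
F = Fmin + (Fmax−Fmin)/(1+(F50/f)^nH), the force-pCa Hill relation
(pCa50, nH), the two-phase force redevelopment
F = Fss·((1−e^(−k_tr·t)) + (1−e^(−k·t))) + c, slack-test unloaded
shortening velocity, tetanus half-rise/half-relaxation times, active
stiffness, PCSA normalization (mass/(1.056·fiber length)), and the
extra-sum-of-squares F-test for "does one curve fit all datasets?".

A seeded synthetic-data generator renders forward-modelled patterns
(Gaussian equatorials and meridionals, |J_n(2πRr)|² layer-line profiles,
exponential diffuse background, Poisson noise) and mechanics traces from
the closed-form models, so the whole chain is testable without any
detector data.

## Worked example

```bash
python examples/02_helix_twist_and_radius.py
```

prints (wild-type canonical 13/6 helix vs a pattern with the long pitch
reduced 0.43%):

```
WT: d6=59.150 Å  d7=50.700 Å  rise h=27.300 Å  n=2.16667 subunits/turn
mutant: d6=58.896 Å  d7=50.700 Å  rise h=27.246 Å  n=2.16165 subunits/turn
twist change dn/n = -0.231%  (negative dn/n: fewer subunits per turn, i.e. a more tightly wound helix)
ALL6 radial first maximum: r = 0.05628 1/nm
filament radius R = 5.232 nm (1.85 convention), 5.207 nm (exact J1 argmax)
```

The measured pitches reproduce the generator truth to ~10⁻⁵ relative; the
Δn/n of −0.231% is what the imposed −0.43% pitch change predicts in
closed form; the radius recovers the simulated 5.2 nm within 0.2% under
the matching convention.  `examples/03_deficit_budget.py` shows the
additive force-deficit bookkeeping (12.9% lattice + 3.5 pp myofibrillar
= 16.4%), and `examples/05_end_to_end_pipeline.py` runs the full
config-driven comparison.

A thin CLI wraps the same stages:

```bash
sarcoxray run --config my_run.yaml --out-dir out/
sarcoxray analyze-pattern --tiff pattern.tiff --geom geom.yaml --out set1
sarcoxray mech-fit --kind force-frequency --table ff.csv --out fit.json
```

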