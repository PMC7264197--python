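"""Seeded forward models: synthetic diffraction patterns and mechanics traces.

The pattern generator renders, on the detector pixel grid, the thin-
filament reflections analysed downstream:

* equatorial 1,0 and 1,1 reflections of the hexagonal filament lattice at
  radial positions 1/d10 and √3/d10 (d11 = d10/√3);
* the 27 Å actin meridional (M13, the monomer axial repeat) and the
  troponin third-order meridional (TN3), as Gaussians on the meridian
  (Bessel order 0);
* actin layer lines ALL6 (~59 Å, left-handed one-start helix), ALL7
  (~51 Å, right-handed) and the tropomyosin-sensitive ALL2, with radial
  intensity |J_n(2πRr)|² (n = 1 for the one-start helices, n = 2 by
  default for ALL2) broadened by a Gaussian kernel;
* an isotropic exponentially decaying diffuse background;
* optional Poisson counting noise from one named RNG stream per image.

Patterns are mirror-symmetric about both the meridian and the equator by
construction.  With noise off the generator is fully deterministic; with
noise on, identical spec + seed reproduce the image bit-for-bit.

The mechanics generators draw force-frequency, force-pCa, k_tr, slack-test
and tetanus data from the closed-form models that the fitting module
estimates, plus seeded Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import jv

from .geometry import DetectorGeometry, DetectorImage
from .structure import HelixParams

REFLECTION_NAMES = ("E10", "E11", "M13", "ALL2", "ALL6", "ALL7", "TN3")

#: canonical 13/6 actin helix (13 subunits in 6 left-handed turns,
#: crossover repeat c = 354.9 Å): one-start pitches 59.15/50.70 Å,
#: rise 27.30 Å, n = 13/6 subunits per turn.
CANONICAL_HELIX = HelixParams(d6_a=59.15, d7_a=50.70, radius_nm=5.2)


def default_geometry(shape: tuple[int, int] = (512, 512),
                     sdd_mm: float = 900.0) -> DetectorGeometry:
    """Compact test geometry: half-integer-centered raster, 12 keV, 172 µm px.

    At 900 mm the 27 Å meridional falls ~198 px from the center of a
    512×512 raster, so every analysed reflection is on the detector.
    """
    nrow, ncol = shape
    return DetectorGeometry(
        sample_detector_distance_mm=sdd_mm,
        pixel_size_um=172.0,
        beam_center=((nrow - 1) / 2.0, (ncol - 1) / 2.0),
        photon_energy_kev=12.0,
        image_shape=shape,
    )


def _default_amplitudes() -> dict[str, float]:
    return {
        "E10": 4000.0,
        "E11": 2000.0,
        "M13": 1500.0,
        "ALL2": 600.0,
        "ALL6": 1200.0,
        "ALL7": 800.0,
        "TN3": 900.0,
    }


@dataclass
class PatternSpec:
    """Ground truth for one synthetic fiber-diffraction pattern.

    Amplitudes are peak counts per reflection; widths are Gaussian σ in
    reciprocal units (axial Å⁻¹, radial nm⁻¹).  ``d_m13_a`` defaults to
    the helix monomer rise (constructive consistency
    1/d6 + 1/d7 = 1/d_m13) but may be overridden, e.g. to impose an
    active-state axial strain.
    """

    helix: HelixParams = field(default_factory=lambda: replace(CANONICAL_HELIX))
    d10_nm: float = 36.0
    amplitudes: dict[str, float] = field(default_factory=_default_amplitudes)
    d_m13_a: float | None = None
    d_all2_a: float = 180.0
    d_tn3_a: float = 127.5
    all2_bessel_order: int = 2
    axial_sigma_inv_a: float = 2.0e-4
    radial_sigma_inv_nm: float = 2.5e-3
    layerline_broadening_inv_nm: float = 2.0e-3
    layerline_r_cutoff_inv_nm: float = 0.15
    bg_level: float = 50.0
    bg_decay_inv_nm: float = 0.25
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, amp in self.amplitudes.items():
            if name not in REFLECTION_NAMES:
                raise ValueError(f"unknown reflection {name!r}")
            if amp < 0:
                raise ValueError(f"amplitude of {name} must be non-negative")
        if self.axial_sigma_inv_a <= 0 or self.radial_sigma_inv_nm <= 0:
            raise ValueError("peak widths must be positive")
        if self.d10_nm <= 0 or self.d_all2_a <= 0 or self.d_tn3_a <= 0:
            raise ValueError("spacings must be positive")
        if self.helix.radius_nm is None or self.helix.radius_nm <= 0:
            raise ValueError("helix radius must be positive for pattern simulation")

    @property
    def m13_spacing_a(self) -> float:
        return self.d_m13_a if self.d_m13_a is not None else self.helix.h_a


def _broadened_bessel_profile(order: int, radius_nm: float, sigma_inv_nm: float,
                              r_cutoff: float, dr: float) -> tuple[np.ndarray, np.ndarray]:
    """|J_n(2πRr)|² on a fine uniform grid, Gaussian-broadened, max-normalized."""
    fine = dr / 4.0
    pad = 5.0 * sigma_inv_nm
    rg = np.arange(0.0, r_cutoff + pad, fine)
    prof = jv(order, 2.0 * np.pi * radius_nm * rg) ** 2
    if sigma_inv_nm > 0:
        half = int(np.ceil(4.0 * sigma_inv_nm / fine))
        kx = np.arange(-half, half + 1) * fine
        kern = np.exp(-0.5 * (kx / sigma_inv_nm) ** 2)
        kern /= kern.sum()
        # reflect at r=0 so the profile stays even across the meridian
        ext = np.concatenate([prof[half:0:-1], prof])
        prof = np.convolve(ext, kern, mode="same")[half:]
    peak = prof.max()
    if peak > 0:
        prof = prof / peak
    return rg, prof


def simulate_pattern(spec: PatternSpec, geom: DetectorGeometry,
                     state: str = "rest") -> DetectorImage:
    """Render a synthetic diffraction pattern on the detector grid."""
    r_nm, z_a = geom.reciprocal_grids()
    ra, za = np.abs(r_nm), np.abs(z_a)
    sz = spec.axial_sigma_inv_a
    sr = spec.radial_sigma_inv_nm

    q_nm = np.hypot(ra, 10.0 * za)
    intensity = spec.bg_level * np.exp(-q_nm / spec.bg_decay_inv_nm)

    amps = spec.amplitudes

    # equatorial lattice reflections (Gaussian in both directions)
    r10 = 1.0 / spec.d10_nm
    for name, rpos in (("E10", r10), ("E11", np.sqrt(3.0) * r10)):
        a = amps.get(name, 0.0)
        if a > 0:
            intensity += a * np.exp(-0.5 * ((ra - rpos) / sr) ** 2) \
                           * np.exp(-0.5 * (za / sz) ** 2)

    # meridional reflections (Bessel order 0 → Gaussian about the meridian)
    for name, d_a in (("M13", spec.m13_spacing_a), ("TN3", spec.d_tn3_a)):
        a = amps.get(name, 0.0)
        if a > 0:
            zpos = 1.0 / d_a
            intensity += a * np.exp(-0.5 * ((za - zpos) / sz) ** 2) \
                           * np.exp(-0.5 * (ra / sr) ** 2)

    # actin layer lines: axial Gaussian × broadened |J_n(2πRr)|²
    radius = float(spec.helix.radius_nm)  # type: ignore[arg-type]
    dr_px = abs(r_nm[0, 1] - r_nm[0, 0]) if geom.image_shape[1] > 1 else 1e-3
    layerlines = (
        ("ALL6", 1.0 / spec.helix.d6_a, 1),
        ("ALL7", 1.0 / spec.helix.d7_a, 1),
        ("ALL2", 1.0 / spec.d_all2_a, spec.all2_bessel_order),
    )
    for name, zpos, order in layerlines:
        a = amps.get(name, 0.0)
        if a <= 0:
            continue
        rg, prof = _broadened_bessel_profile(
            order, radius, spec.layerline_broadening_inv_nm,
            spec.layerline_r_cutoff_inv_nm, dr_px)
        radial = np.interp(ra, rg, prof, right=0.0)
        radial[ra > spec.layerline_r_cutoff_inv_nm] = 0.0
        intensity += a * radial * np.exp(-0.5 * ((za - zpos) / sz) ** 2)

    meta = {"state": state, "spec_seed": spec.seed, "poisson_noise": spec.poisson_noise}
    if spec.poisson_noise:
        rng = np.random.default_rng([spec.seed, 0 if state == "rest" else 1])
        intensity = rng.poisson(np.clip(intensity, 0.0, None)).astype(float)
    return DetectorImage(counts=intensity, geometry=geom, meta=meta)


def simulate_pair(
    spec: PatternSpec,
    geom: DetectorGeometry,
    strain_m13: float = 0.0,
    delta_d6: float = 0.0,
    delta_d7: float = 0.0,
    delta_radius: float = 0.0,
    intensity_scale: Mapping[str, float] | None = None,
) -> tuple[DetectorImage, DetectorImage]:
    """Render a rest/active pattern pair.

    The active image is regenerated with the M13 axial spacing scaled by
    (1 + strain), the layer-line pitches and filament radius scaled by
    their fractional deltas, and named reflection amplitudes scaled by
    ``intensity_scale`` (e.g. reduced ALL2/TN3 on activation).
    """
    for frac in (strain_m13, delta_d6, delta_d7, delta_radius):
        if abs(frac) >= 0.05:
            raise ValueError("rest→active fractional changes must stay below 5%")
    rest = simulate_pattern(spec, geom, state="rest")

    amps = dict(spec.amplitudes)
    for name, scale in (intensity_scale or {}).items():
        if name not in amps:
            raise ValueError(f"unknown reflection {name!r} in intensity_scale")
        amps[name] = amps[name] * scale
    active_helix = HelixParams(
        d6_a=spec.helix.d6_a * (1.0 + delta_d6),
        d7_a=spec.helix.d7_a * (1.0 + delta_d7),
        radius_nm=spec.helix.radius_nm * (1.0 + delta_radius),  # type: ignore[operator]
    )
    active_spec = replace(
        spec,
        helix=active_helix,
        amplitudes=amps,
        d_m13_a=spec.m13_spacing_a * (1.0 + strain_m13),
    )
    active = simulate_pattern(active_spec, geom, state="active")
    return rest, active


# ---- mechanics ground-truth models and generators ---------------------------


@dataclass
class HillSpec:
    """Force-frequency sigmoid: F(f) = Fmin + (Fmax − Fmin)/(1 + (F50/f)^nH)."""

    fmin_mn: float = 5.0
    fmax_mn: float = 400.0
    f50_hz: float = 45.0
    nh: float = 3.0

    def __post_init__(self) -> None:
        if not (self.fmax_mn > self.fmin_mn >= 0):
            raise ValueError("require Fmax > Fmin >= 0")
        if self.f50_hz <= 0 or self.nh <= 0:
            raise ValueError("F50 and nH must be positive")

    def force(self, f_hz: np.ndarray | float) -> np.ndarray | float:
        f = np.asarray(f_hz, dtype=float)
        y = self.fmin_mn + (self.fmax_mn - self.fmin_mn) / (1.0 + (self.f50_hz / f) ** self.nh)
        return y if y.ndim else float(y)


@dataclass
class PCaSpec:
    """Force-pCa Hill model: F = Fmax / (1 + 10^(nH·(pCa − pCa50)))."""

    fmax: float = 120.0
    pca50: float = 5.9
    nh: float = 5.0

    def __post_init__(self) -> None:
        if self.fmax <= 0 or self.nh <= 0:
            raise ValueError("Fmax and nH must be positive")

    def force(self, pca: np.ndarray | float) -> np.ndarray | float:
        p = np.asarray(pca, dtype=float)
        y = self.fmax / (1.0 + 10.0 ** (self.nh * (p - self.pca50)))
        return y if y.ndim else float(y)


@dataclass
class KtrSpec:
    """Two-phase force redevelopment: F = Fss·((1−e^(−ktr·t)) + (1−e^(−k·t))) + c."""

    fss: float = 60.0
    ktr_per_s: float = 20.0
    k_per_s: float = 2.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ktr_per_s > self.k_per_s > 0):
            raise ValueError("require ktr > k > 0 (fast phase faster than slow)")

    def force(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        y = self.fss * ((1.0 - np.exp(-self.ktr_per_s * t))
                        + (1.0 - np.exp(-self.k_per_s * t))) + self.c
        return y if y.ndim else float(y)


@dataclass
class VelocitySpec:
    """Slack test: delay(s) = t0 + slack_fraction / v (v in lengths/s)."""

    v_lengths_per_s: float = 2.0
    t0_ms: float = 2.0

    def delay_s(self, slack_pct: np.ndarray | float) -> np.ndarray | float:
        s = np.asarray(slack_pct, dtype=float) / 100.0
        y = self.t0_ms * 1e-3 + s / self.v_lengths_per_s
        return y if y.ndim else float(y)


@dataclass
class MechSpec:
    """Bundle of mechanics ground truths plus per-signal noise SDs and a seed."""

    hill: HillSpec = field(default_factory=HillSpec)
    pca: PCaSpec = field(default_factory=PCaSpec)
    ktr: KtrSpec = field(default_factory=KtrSpec)
    velocity: VelocitySpec = field(default_factory=VelocitySpec)
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


#: stimulation frequencies used for the fast-twitch (EDL) force-frequency design
EDL_FREQUENCIES_HZ = (1.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0)
#: soleus omits the 200 Hz point
SOLEUS_FREQUENCIES_HZ = EDL_FREQUENCIES_HZ[:-1]
#: slack-test release amplitudes (% of initial length)
SLACK_PERCENTS = (8.0, 9.0, 10.0, 11.0, 13.0, 15.0)
#: activation series from low to high calcium
PCA_SERIES = (6.5, 6.2, 6.0, 5.9, 5.8, 5.7, 5.6, 5.4, 5.2, 5.0, 4.5, 4.0)


def simulate_force_frequency(spec: MechSpec,
                             freqs_hz: Sequence[float] = EDL_FREQUENCIES_HZ) -> pd.DataFrame:
    freqs = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("stimulation frequencies must be positive")
    force = np.asarray(spec.hill.force(freqs), dtype=float)
    sd = spec.noise_sd.get("force_frequency", 0.0)
    if sd > 0:
        force = force + spec._rng(10).normal(0.0, sd, size=force.shape)
    return pd.DataFrame({"frequency_hz": freqs, "force_mn": force})


def simulate_force_pca(spec: MechSpec, pcas: Sequence[float] = PCA_SERIES) -> pd.DataFrame:
    pca = np.asarray(pcas, dtype=float)
    force = np.asarray(spec.pca.force(pca), dtype=float)
    sd = spec.noise_sd.get("force_pca", 0.0)
    if sd > 0:
        force = force + spec._rng(11).normal(0.0, sd, size=force.shape)
    return pd.DataFrame({"pca": pca, "force": force})


def simulate_ktr_trace(spec: MechSpec, t_s: Sequence[float] | None = None) -> pd.DataFrame:
    if t_s is None:
        t_s = np.arange(0.0, 2.0, 1e-3)
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    force = np.asarray(spec.ktr.force(t), dtype=float)
    sd = spec.noise_sd.get("ktr", 0.0)
    if sd > 0:
        force = force + spec._rng(12).normal(0.0, sd, size=force.shape)
    return pd.DataFrame({"t_s": t, "force": force})


def simulate_slack_test(spec: MechSpec,
                        slack_pcts: Sequence[float] = SLACK_PERCENTS) -> pd.DataFrame:
    pct = np.asarray(slack_pcts, dtype=float)
    delay = np.asarray(spec.velocity.delay_s(pct), dtype=float)
    sd = spec.noise_sd.get("slack", 0.0)
    if sd > 0:
        delay = delay + spec._rng(13).normal(0.0, sd, size=delay.shape)
    return pd.DataFrame({"slack_pct": pct, "delay_s": delay})


def simulate_tetanus(
    fmax: float = 400.0,
    rise_rate_per_s: float = 40.0,
    decay_rate_per_s: float = 25.0,
    stim_end_s: float = 0.5,
    t_end_s: float = 1.2,
    dt_s: float = 1e-3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tetanic force trace: exponential rise during stimulation, decay after."""
    t = np.arange(0.0, t_end_s, dt_s)
    rise = fmax * (1.0 - np.exp(-rise_rate_per_s * t))
    f_end = fmax * (1.0 - np.exp(-rise_rate_per_s * stim_end_s))
    decay = f_end * np.exp(-decay_rate_per_s * (t - stim_end_s))
    force = np.where(t <= stim_end_s, rise, decay)
    if noise_sd > 0:
        force = force + np.random.default_rng([seed, 14]).normal(0.0, noise_sd, size=force.shape)
    return pd.DataFrame({"t_s": t, "force_mn": force})


def simulate_epitope_profile(
    length_true_um: float,
    z_center_um: float = 4.0,
    width_um: float = 0.12,
    grid_um: np.ndarray | None = None,
    amplitude: float = 1.0,
    background: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pointed-end-marker profile across a Z-disk: two Gaussian peaks at
    z_center ± thin-filament length, on a flat background."""
    if grid_um is None:
        grid_um = np.arange(z_center_um - 2.5, z_center_um + 2.5, 0.02)
    x = np.asarray(grid_um, dtype=float)
    prof = background + amplitude * (
        np.exp(-0.5 * ((x - (z_center_um - length_true_um)) / width_um) ** 2)
        + np.exp(-0.5 * ((x - (z_center_um + length_true_um)) / width_um) ** 2)
    )
    if noise_sd > 0:
        prof = prof + np.random.default_rng([seed, 15]).normal(0.0, noise_sd, size=prof.shape)
    return pd.DataFrame({"position_um": x, "intensity": prof})
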