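"""Derived thin-filament structural quantities.

F-actin is a double helix that can equivalently be described by two
one-start (genetic) helices: a long-pitch left-handed helix whose pitch
d6 appears as the ~59 Å sixth actin layer line (ALL6) and a short-pitch
right-handed helix whose pitch d7 appears as the ~51 Å seventh layer line
(ALL7).  With a common monomer axial rise h, one subunit advances h along
the axis while rotating by 2π·h/d7 one way and 2π·h/d6 the other, and the
two rotations add to a full turn-per-subunit constraint::

    h/d6 + h/d7 = 1        ⇒  h = 1 / (1/d6 + 1/d7)
    n = d6/h = 1 + d6/d7   (subunits per turn of the one-start helix)

The filament twist is quantified as Δn/n between conditions; a decrease
in n means the helix is wound more tightly (an increase in twist).

The radial position r of the first intensity maximum of ALL6 relates to
the filament radius R through the order-1 Bessel profile |J1(2πRr)|²,
whose first maximum sits at argument 1.8412 (the field convention rounds
this to 1.85): R = 1.85/(2π·r).

Specific-force bookkeeping: an expanded hexagonal lattice dilutes
filaments per unit myofibril cross-section as 1/spacing², and a reduced
myofibrillar fractional area subtracts percentage points directly; the
two contributions are summed additively (the multiplicative combination
is also computed and reported, never substituted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import units

#: Field convention for the first-maximum argument of J1.
BESSEL_J1_FIRST_MAX_CONVENTION = 1.85
#: Exact first maximum of J1 (numerical argmax, 6 significant figures).
BESSEL_J1_FIRST_MAX_EXACT = 1.84118


class StructureError(ValueError):
    """Invalid input to a structural derivation."""


@dataclass
class HelixParams:
    """One-start helix description of the actin filament.

    Attributes
    ----------
    d6_a, d7_a:
        Left- and right-handed one-start pitches (Å), from the ALL6 and
        ALL7 axial spacings.  d6 > d7 for F-actin.
    radius_nm:
        Filament radius R (nm), from the ALL6 radial first maximum.
    rise_a:
        Monomer axial rise h (Å).  If omitted it is derived from the
        pitches; the measured 27 Å meridional (M13) provides an
        independent estimate whose agreement tests the constant-rise
        assumption.
    """

    d6_a: float
    d7_a: float
    radius_nm: float | None = None
    rise_a: float | None = None

    def __post_init__(self) -> None:
        if not (self.d6_a > self.d7_a > 0):
            raise StructureError(
                f"require d6 > d7 > 0 (left-handed pitch exceeds right-handed); "
                f"got d6={self.d6_a}, d7={self.d7_a}"
            )
        if self.radius_nm is not None and self.radius_nm <= 0:
            raise StructureError("filament radius must be positive")

    @property
    def h_a(self) -> float:
        """Monomer axial rise h (Å): explicit if set, else 1/(1/d6 + 1/d7)."""
        if self.rise_a is not None:
            return self.rise_a
        return 1.0 / (1.0 / self.d6_a + 1.0 / self.d7_a)

    @property
    def n_subunits_per_turn(self) -> float:
        """Subunits per turn n = 1 + d6/d7."""
        return 1.0 + self.d6_a / self.d7_a


def helix_from_layerlines(d6_a: float, d7_a: float, radius_nm: float | None = None) -> HelixParams:
    """Build :class:`HelixParams` from measured layer-line pitches (Å)."""
    return HelixParams(d6_a=d6_a, d7_a=d7_a, radius_nm=radius_nm)


def twist_change(wt: HelixParams, mut: HelixParams) -> float:
    """Fractional change in subunits per turn, Δn/n = (n_mut − n_wt)/n_wt.

    Sign convention: reported as computed; a *decrease* in n is an
    *increase* in helical twist.
    """
    n_wt = wt.n_subunits_per_turn
    n_mut = mut.n_subunits_per_turn
    return (n_mut - n_wt) / n_wt


def actin_radius(r_first_max_inv_nm: float,
                 bessel_constant: float = BESSEL_J1_FIRST_MAX_CONVENTION) -> float:
    """Filament radius R (nm) from the ALL6 radial first maximum r (nm⁻¹).

    R = c/(2π·r) with c the J1 first-maximum argument (1.85 by field
    convention; pass :data:`BESSEL_J1_FIRST_MAX_EXACT` for the exact
    1.84118, ~0.5% lower R).
    """
    if r_first_max_inv_nm <= 0:
        raise StructureError("radial first-maximum position must be positive")
    return bessel_constant / (2.0 * math.pi * r_first_max_inv_nm)


def j1_squared_argmax() -> float:
    """Numerically locate the first maximum of |J1(x)|² (oracle for 1.8412)."""
    from scipy.special import j1

    res = optimize.minimize_scalar(lambda x: -j1(x) ** 2, bounds=(0.5, 3.0), method="bounded")
    return float(res.x)


# ---- per-filament force and stiffness --------------------------------------


def force_per_thin_filament(
    specific_force_mn_mm2: float,
    myofibrillar_fraction: float,
    d10_nm: float,
    thin_per_thick: float = 2.0,
) -> float:
    """Convert whole-muscle specific force to force per thin filament (pN).

    The hexagonal unit cell of the myofilament lattice has area
    2·d10²/√3 and contains one thick filament and ``thin_per_thick`` thin
    filaments (2 in vertebrate muscle), so the cross-section per thin
    filament is (2·d10²/√3)/thin_per_thick.  Only the myofibrillar
    fraction of the fiber cross-section bears filaments.
    """
    if specific_force_mn_mm2 < 0:
        raise StructureError("specific force must be non-negative")
    if not (0 < myofibrillar_fraction <= 1):
        raise StructureError("myofibrillar fraction must be in (0, 1]")
    if d10_nm <= 0 or thin_per_thick <= 0:
        raise StructureError("d10 and thin:thick ratio must be positive")
    area_per_thin_nm2 = (2.0 * d10_nm**2 / math.sqrt(3.0)) / thin_per_thick
    sigma_pn_nm2 = specific_force_mn_mm2 * units.MN_PER_MM2_TO_PN_PER_NM2
    return sigma_pn_nm2 * myofibrillar_fraction * area_per_thin_nm2


@dataclass(frozen=True)
class StiffnessResult:
    """Distributed thin-filament stiffness from axial strain under load."""

    strain: float
    force_per_filament_pn: float
    kappa_pn_per_nm_per_um: float


def thin_filament_stiffness(force_per_filament_pn: float, strain: float) -> StiffnessResult:
    """κ = F/(ε·1000) in pN/nm/µm.

    ε is the fractional extension of the actin monomer spacing (from the
    27 Å meridional spacing change during the tetanus plateau); the 1000
    converts strain per filament-µm into nm of extension per µm.
    """
    if strain <= 0:
        raise StructureError("strain must be positive for a stiffness estimate")
    if force_per_filament_pn < 0:
        raise StructureError("force must be non-negative")
    kappa = force_per_filament_pn / (strain * 1000.0)
    return StiffnessResult(strain=strain, force_per_filament_pn=force_per_filament_pn,
                           kappa_pn_per_nm_per_um=kappa)


# ---- lattice spacing and the specific-force deficit budget ------------------


def thin_thick_spacing(d10_nm: float) -> float:
    """Thin-thick filament center-to-center distance = (2/3)·d1,0 (nm)."""
    if d10_nm <= 0:
        raise StructureError("d10 must be positive")
    return (2.0 / 3.0) * d10_nm


def lattice_force_deficit(spacing_ref_nm: float, spacing_test_nm: float) -> float:
    """Percent loss of filaments per unit cross-section from lattice expansion.

    Filament areal density scales as 1/spacing², so
    deficit% = 100·(1 − (ref/test)²); positive when the test lattice is
    expanded relative to the reference.
    """
    if spacing_ref_nm <= 0 or spacing_test_nm <= 0:
        raise StructureError("spacings must be positive")
    return 100.0 * (1.0 - (spacing_ref_nm / spacing_test_nm) ** 2)


def myofibrillar_deficit(frac_ref: float, frac_test: float) -> float:
    """Percentage-point loss of myofibrillar fractional area: 100·(ref − test)."""
    for f in (frac_ref, frac_test):
        if not (0 <= f <= 1):
            raise StructureError("fractional areas must be within [0, 1]")
    return 100.0 * (frac_ref - frac_test)


@dataclass(frozen=True)
class DeficitReport:
    """Additive budget of expected specific-force loss.

    ``combined_pct`` is the additive sum of the lattice and myofibrillar
    contributions (percentage-point bookkeeping);
    ``combined_multiplicative_pct`` carries the alternative
    100·(1 − (1−l/100)(1−m/100)) alongside for reference.
    """

    lattice_pct: float
    myofibrillar_pct: float
    combined_pct: float
    combined_multiplicative_pct: float


def combined_deficit(lattice_pct: float, myofibrillar_pct: float) -> DeficitReport:
    """Combine the two deficit contributions additively (components echoed)."""
    combined = lattice_pct + myofibrillar_pct
    mult = 100.0 * (1.0 - (1.0 - lattice_pct / 100.0) * (1.0 - myofibrillar_pct / 100.0))
    return DeficitReport(
        lattice_pct=lattice_pct,
        myofibrillar_pct=myofibrillar_pct,
        combined_pct=combined,
        combined_multiplicative_pct=mult,
    )


# ---- length-measurement corrections ----------------------------------------


def shrinkage_correct(length_measured_um: float, thick_measured_um: float,
                      thick_reference_um: float = 1.6) -> float:
    """Rescale an EM-measured filament length for preparation shrinkage.

    Thick filaments have a fixed in-vivo length (1.6 µm reference), so the
    ratio reference/measured calibrates the shrinkage of each micrograph.
    """
    if min(length_measured_um, thick_measured_um, thick_reference_um) <= 0:
        raise StructureError("lengths must be positive")
    return length_measured_um * (thick_reference_um / thick_measured_um)


def filament_length_from_profile(position_um: np.ndarray, intensity: np.ndarray) -> float:
    """Thin-filament length from a pointed-end-marker intensity profile (µm).

    The profile across a Z-disk shows two flanking peaks (the pointed-end
    epitope of the thin filaments on either side); each is fit with a
    Gaussian + constant and the length is half the peak-to-peak distance.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    position_um = np.asarray(position_um, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    # peak *detection* on a lightly smoothed copy (noise spikes would
    # otherwise split one epitope peak in two); fitting uses raw data
    smooth = gaussian_filter1d(intensity, sigma=max(2.0, len(intensity) / 100.0))
    base = np.median(smooth)
    amp = smooth.max() - base
    peaks, _ = find_peaks(smooth, height=base + 0.3 * amp,
                          distance=max(5, len(intensity) // 20))
    if len(peaks) < 2:
        raise StructureError("need at least two resolvable epitope peaks")
    # the two most intense peaks flank the Z-disk
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    centers = sorted(_gauss_center(position_um, intensity, p) for p in top2)
    return 0.5 * (centers[1] - centers[0])


def _gauss_center(x: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Gaussian + constant fit around a local peak; returns the center."""
    dx = float(np.median(np.diff(x)))
    half = max(3, int(round(0.15 * len(x) / 2)))
    lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
    xs, ys = x[lo:hi], y[lo:hi]
    base = ys.min()

    def model(x_, amp, mu, sig, c):
        return amp * np.exp(-((x_ - mu) ** 2) / (2 * sig**2)) + c

    p0 = [ys.max() - base, x[idx], 2 * dx, base]
    popt, _ = optimize.curve_fit(model, xs, ys, p0=p0, maxfev=10000)
    return float(popt[1])
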