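"""Spacings and intensities of named reflections from folded patterns.

Meridional reflections and layer lines are measured on an axial
projection: intensity summed over a radial band (default
0 ≤ R ≤ 0.053 nm⁻¹) per axial bin, with the two meridian sides averaged.
Axial spacings come from the centroid of the background-corrected peak
within a window (local linear baseline from the window flanks);
intensities from a Gaussian + linear-baseline fit, normalized by the
exposure's summed diffuse background so that rest/active ratios are
comparable across exposures.  Equatorial lattice spacings (d1,0 and the
√3-related d1,1) come from Gaussian fits to the radial projection of a
narrow equatorial band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.signal import find_peaks

from . import units
from .geometry import DetectorImage, _mirror_indices

#: radial integration band for axial projections (nm⁻¹)
DEFAULT_RADIAL_BAND = (0.0, 0.053)

#: canonical axial spacings (Å) used to center default measurement windows
CANONICAL_SPACINGS_A = {"M13": 27.3, "ALL6": 59.0, "ALL7": 51.0, "ALL2": 180.0, "TN3": 127.5}


class AnalysisError(RuntimeError):
    """A measurement could not be made (degenerate window, failed fit...)."""


class UndefinedCentroidError(AnalysisError):
    """Non-positive net signal in a centroid window."""


@dataclass
class ProjectionTrace:
    """1D projection of a pattern onto the axial or radial direction.

    ``coordinate`` is strictly increasing: |z| in Å⁻¹ for axial traces,
    |r| in nm⁻¹ for radial traces.  ``band`` records the integration
    range used in the orthogonal coordinate (provenance).
    """

    axis: str
    coordinate: np.ndarray
    intensity: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis not in ("axial", "radial"):
            raise ValueError("axis must be 'axial' or 'radial'")
        if np.any(np.diff(self.coordinate) <= 0):
            raise ValueError("trace coordinate must be strictly increasing")

    def window_slice(self, window: tuple[float, float]) -> slice:
        lo, hi = window
        if hi <= lo:
            raise AnalysisError(f"empty window {window}")
        i0 = int(np.searchsorted(self.coordinate, lo, side="left"))
        i1 = int(np.searchsorted(self.coordinate, hi, side="right"))
        if i1 - i0 < 4:
            raise AnalysisError(f"window {window} covers fewer than 4 bins")
        return slice(i0, i1)


def axial_projection(img: DetectorImage,
                     radial_band: tuple[float, float] = DEFAULT_RADIAL_BAND) -> ProjectionTrace:
    """Project intensity onto the meridian over a radial band.

    Sums counts per axial bin over columns with ``band[0] ≤ |r| ≤
    band[1]`` and averages the two meridian sides (row-mirror pairs about
    the beam center).  Expects a quadrant-folded image; works on any.
    """
    lo, hi = radial_band
    if hi <= lo:
        raise AnalysisError("empty radial band")
    r_nm, z_a = img.geometry.reciprocal_grids()
    colsel = (np.abs(r_nm[0]) >= lo) & (np.abs(r_nm[0]) <= hi)
    if not colsel.any():
        raise AnalysisError("radial band selects no columns")
    data = np.where(img.valid, img.counts, 0.0)
    rowsum = data[:, colsel].sum(axis=1)

    z_rows = z_a[:, 0]
    nrow = len(z_rows)
    mrow, vrow = _mirror_indices(nrow, img.geometry.beam_center[0])
    upper = np.where(z_rows > 0)[0]
    coord = z_rows[upper]
    inten = np.where(
        vrow[upper],
        0.5 * (rowsum[upper] + rowsum[mrow[upper]]),
        rowsum[upper],
    )
    order = np.argsort(coord)
    return ProjectionTrace(axis="axial", coordinate=coord[order], intensity=inten[order],
                           band=(lo, hi))


def radial_projection(img: DetectorImage,
                      axial_window: tuple[float, float]) -> ProjectionTrace:
    """Project intensity onto the equatorial direction over an axial window.

    Sums counts per radial bin over rows with ``window[0] ≤ |z| ≤
    window[1]`` (both sides of the equator) and averages the two sides of
    the meridian.
    """
    lo, hi = axial_window
    if hi <= lo:
        raise AnalysisError("empty axial window")
    r_nm, z_a = img.geometry.reciprocal_grids()
    rowsel = (np.abs(z_a[:, 0]) >= lo) & (np.abs(z_a[:, 0]) <= hi)
    if not rowsel.any():
        raise AnalysisError("axial window selects no rows")
    data = np.where(img.valid, img.counts, 0.0)
    colsum = data[rowsel, :].sum(axis=0)

    r_cols = r_nm[0]
    ncol = len(r_cols)
    mcol, vcol = _mirror_indices(ncol, img.geometry.beam_center[1])
    right = np.where(r_cols > 0)[0]
    coord = r_cols[right]
    inten = np.where(
        vcol[right],
        0.5 * (colsum[right] + colsum[mcol[right]]),
        colsum[right],
    )
    order = np.argsort(coord)
    return ProjectionTrace(axis="radial", coordinate=coord[order], intensity=inten[order],
                           band=(lo, hi))


# ---- peak measurements ------------------------------------------------------


def _flank_baseline(x: np.ndarray, y: np.ndarray, flank_frac: float = 0.15) -> np.ndarray:
    """Local linear baseline fit through the window flanks."""
    n = len(x)
    nb = max(2, int(round(flank_frac * n)))
    xs = np.concatenate([x[:nb], x[-nb:]])
    ys = np.concatenate([y[:nb], y[-nb:]])
    slope, icpt = np.polyfit(xs, ys, 1)
    return icpt + slope * x


def centroid_spacing(trace: ProjectionTrace, window: tuple[float, float],
                     baseline: str = "linear") -> tuple[float, float]:
    """Axial spacing (Å) from the intensity centroid of a peak window.

    Returns ``(spacing_a, se_a)``.  The centroid is the plain discrete
    intensity-weighted mean coordinate of the baseline-corrected samples
    (``baseline='linear'`` fits the window flanks; ``'none'`` uses the raw
    samples).  The SE comes from the intensity-weighted second moment.
    """
    sl = trace.window_slice(window)
    x, y = trace.coordinate[sl], trace.intensity[sl]
    net = y - _flank_baseline(x, y) if baseline == "linear" else y.copy()
    total = net.sum()
    if total <= 0:
        raise UndefinedCentroidError(
            f"non-positive net signal ({total:.3g}) in window {window}")
    zc = float(np.sum(net * x) / total)
    if zc <= 0:
        raise UndefinedCentroidError("centroid at or below the equator")
    var = float(np.sum(net * (x - zc) ** 2) / total)
    se_z = np.sqrt(max(var, 0.0) / max(len(x), 1))
    spacing = units.spacing_angstrom(zc)
    return spacing, se_z / zc**2  # d = 1/z → σ_d = σ_z / z²


def _gauss_linear(x, amp, mu, sig, a, b):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sig**2)) + a + b * x


def fit_reflection_intensity(
    trace: ProjectionTrace,
    window: tuple[float, float],
    diffuse_sum: float | None = None,
) -> tuple[float, float]:
    """Integrated reflection intensity from a Gaussian + linear-baseline fit.

    Returns ``(intensity, se)``: the Gaussian area amp·σ·√(2π), divided by
    ``diffuse_sum`` when given (normalization across exposures).  Fit
    failure raises :class:`AnalysisError` with diagnostics.
    """
    sl = trace.window_slice(window)
    x, y = trace.coordinate[sl], trace.intensity[sl]
    base = _flank_baseline(x, y)
    net = y - base
    if net.max() <= 0:
        raise AnalysisError(f"no positive signal in window {window}")
    i0 = int(np.argmax(net))
    dx = float(np.median(np.diff(x)))
    p0 = [net[i0], x[i0], max(2.0 * dx, (x[-1] - x[0]) / 10.0), float(np.median(y)), 0.0]
    try:
        popt, pcov = optimize.curve_fit(
            _gauss_linear, x, y, p0=p0, maxfev=20000,
            bounds=([0.0, x[0], dx / 4.0, -np.inf, -np.inf],
                    [np.inf, x[-1], (x[-1] - x[0]), np.inf, np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        raise AnalysisError(f"Gaussian fit failed in window {window}: {exc}") from exc
    amp, _, sig = popt[0], popt[1], abs(popt[2])
    area = amp * sig * np.sqrt(2.0 * np.pi)
    var = (pcov[0, 0] * (sig * np.sqrt(2 * np.pi)) ** 2
           + pcov[2, 2] * (amp * np.sqrt(2 * np.pi)) ** 2
           + 2.0 * pcov[0, 2] * amp * sig * 2 * np.pi)
    se = float(np.sqrt(max(var, 0.0)))
    if diffuse_sum is not None:
        if diffuse_sum <= 0:
            raise AnalysisError("diffuse normalization sum must be positive")
        area /= diffuse_sum
        se /= diffuse_sum
    return float(area), se


def radial_first_maximum(
    img: DetectorImage,
    layerline_window: tuple[float, float],
    r_min_inv_nm: float = 0.01,
    method: str = "parabolic",
    centroid_halfwidth_bins: int = 3,
) -> float:
    """Distance (nm⁻¹) of the first off-meridian intensity maximum.

    Projects the layer-line axial window onto the radial axis, locates the
    smallest-r local maximum beyond ``r_min`` that exceeds 3× the local
    noise SD, and refines it to sub-pixel precision — by default with a
    parabolic (quadratic) fit through the five samples around the discrete
    maximum, or with an intensity centroid over ±``centroid_halfwidth_bins``
    (``method='centroid'``).
    """
    trace = radial_projection(img, layerline_window)
    x, y = trace.coordinate, trace.intensity
    sel = x >= r_min_inv_nm
    xs, ys = x[sel], y[sel]
    if len(xs) < 5:
        raise AnalysisError("too few radial bins beyond r_min")
    noise_sd = float(np.std(np.diff(ys)) / np.sqrt(2.0))
    floor = ys.min() + 3.0 * noise_sd
    peaks, _ = find_peaks(ys, height=floor)
    if len(peaks) == 0:
        raise AnalysisError("no off-meridian maximum found in the layer-line window")
    p = int(peaks[0])  # smallest-r qualifying local maximum
    if method == "parabolic":
        lo, hi = max(0, p - 2), min(len(xs), p + 3)
        coef = np.polyfit(xs[lo:hi], ys[lo:hi], 2)
        if coef[0] >= 0:
            return float(xs[p])
        return float(-coef[1] / (2.0 * coef[0]))
    elif method == "centroid":
        w = centroid_halfwidth_bins
        lo, hi = max(0, p - w), min(len(xs), p + w + 1)
        seg_x, seg_y = xs[lo:hi], ys[lo:hi]
        net = seg_y - seg_y.min()
        if net.sum() <= 0:
            raise UndefinedCentroidError("flat peak region")
        return float(np.sum(net * seg_x) / net.sum())
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EquatorResult:
    """Lattice spacings and equatorial intensities."""

    d10_nm: float
    d11_nm: float | None
    i10: float
    i11: float | None


def equator_analysis(img: DetectorImage,
                     axial_band_inv_a: float = 1.0e-3,
                     r_min_inv_nm: float = 0.01) -> EquatorResult:
    """Measure d1,0 (and d1,1 when present) from the equatorial trace.

    Fits Gaussian + linear baseline around the two innermost equatorial
    peaks; d = 1/r_center.  A missing 1,1 reflection yields ``d11=None``
    rather than a failure.
    """
    trace = radial_projection(img, (0.0, axial_band_inv_a))
    x, y = trace.coordinate, trace.intensity
    sel = x >= r_min_inv_nm
    xs, ys = x[sel], y[sel]
    noise_sd = float(np.std(np.diff(ys)) / np.sqrt(2.0))
    prom = max(5.0 * noise_sd, 0.02 * (ys.max() - ys.min()))
    peaks, _ = find_peaks(ys, prominence=prom)
    if len(peaks) == 0:
        raise AnalysisError("no equatorial reflection found")

    def refine(p: int) -> tuple[float, float]:
        dx = float(np.median(np.diff(xs)))
        half = max(4, int(round(3.0 * dx / dx)))
        lo, hi = max(0, p - 6), min(len(xs), p + 7)
        seg_x, seg_y = xs[lo:hi], ys[lo:hi]
        p0 = [seg_y[p - lo] - seg_y.min(), xs[p], 2.0 * dx, seg_y.min(), 0.0]
        popt, _ = optimize.curve_fit(_gauss_linear, seg_x, seg_y, p0=p0, maxfev=20000)
        amp, mu, sig = popt[0], popt[1], abs(popt[2])
        return float(mu), float(amp * sig * np.sqrt(2.0 * np.pi))

    r10, i10 = refine(int(peaks[0]))
    d10 = units.spacing_nm(r10)
    d11 = i11 = None
    if len(peaks) >= 2:
        r11, i11_val = refine(int(peaks[1]))
        d11 = units.spacing_nm(r11)
        i11 = i11_val
    return EquatorResult(d10_nm=d10, d11_nm=d11, i10=i10, i11=i11)


# ---- reflection sets and state comparisons ----------------------------------


@dataclass
class ReflectionMeasurement:
    """One named reflection: spacing, radial position and/or intensity."""

    name: str
    axial_spacing_a: float | None = None
    axial_spacing_se_a: float | None = None
    radial_position_inv_nm: float | None = None
    intensity: float | None = None
    intensity_se: float | None = None


@dataclass
class ReflectionSet:
    """All measured reflections of one exposure plus the lattice spacing."""

    state: str
    measurements: dict[str, ReflectionMeasurement] = field(default_factory=dict)
    d10_nm: float | None = None
    d11_nm: float | None = None
    diffuse_sum: float | None = None

    def __getitem__(self, name: str) -> ReflectionMeasurement:
        return self.measurements[name]


def default_windows(layerline_halfwidth_inv_a: float = 1.2e-3,
                    meridional_halfwidth_inv_a: float = 1.5e-3) -> dict[str, tuple[float, float]]:
    """Axial measurement windows centered on the canonical spacings.

    Windows are wide enough (≥5 peak σ at the default simulator widths)
    that the flank-baseline bins sit on background, not on peak tails,
    yet narrow enough that ALL6 and ALL7 do not invade each other.
    """
    out = {}
    for name, d in CANONICAL_SPACINGS_A.items():
        z0 = 1.0 / d
        hw = (layerline_halfwidth_inv_a if name in ("ALL6", "ALL7")
              else meridional_halfwidth_inv_a)
        out[name] = (z0 - hw, z0 + hw)
    return out


def measure_pattern(
    img: DetectorImage,
    diffuse_sum: float | None = None,
    windows: dict[str, tuple[float, float]] | None = None,
    radial_band: tuple[float, float] = DEFAULT_RADIAL_BAND,
    state: str = "rest",
    measure_equator: bool = True,
    all6_radius_window: tuple[float, float] | None = None,
) -> ReflectionSet:
    """Measure every analysed reflection of one (folded) pattern.

    Axial spacings and intensities for M13, TN3, ALL2, ALL6, ALL7 from the
    axial projection; the ALL6 radial first-maximum position; and the
    equatorial lattice spacings.  Reflections whose windows contain no
    signal are skipped rather than failing the whole set.
    """
    if windows is None:
        windows = default_windows()
    result = ReflectionSet(state=state, diffuse_sum=diffuse_sum)
    trace = axial_projection(img, radial_band)
    for name, window in windows.items():
        meas = ReflectionMeasurement(name=name)
        try:
            meas.axial_spacing_a, meas.axial_spacing_se_a = centroid_spacing(trace, window)
            meas.intensity, meas.intensity_se = fit_reflection_intensity(
                trace, window, diffuse_sum=diffuse_sum)
        except AnalysisError:
            continue
        result.measurements[name] = meas

    if all6_radius_window is None:
        all6_radius_window = windows.get("ALL6", (1 / 59.0 - 8e-4, 1 / 59.0 + 8e-4))
    try:
        r_first = radial_first_maximum(img, all6_radius_window)
        if "ALL6" in result.measurements:
            result.measurements["ALL6"].radial_position_inv_nm = r_first
    except AnalysisError:
        pass

    if measure_equator:
        try:
            eq = equator_analysis(img)
            result.d10_nm, result.d11_nm = eq.d10_nm, eq.d11_nm
            result.measurements["E10"] = ReflectionMeasurement(name="E10", intensity=eq.i10)
            if eq.d11_nm is not None:
                result.measurements["E11"] = ReflectionMeasurement(name="E11", intensity=eq.i11)
        except AnalysisError:
            pass
    return result


def spacing_change(rest: ReflectionSet, active: ReflectionSet, name: str) -> float:
    """Fractional spacing change (d_active − d_rest)/d_rest of a reflection."""
    d_rest = rest[name].axial_spacing_a
    d_active = active[name].axial_spacing_a
    if d_rest is None or d_active is None:
        raise AnalysisError(f"spacing of {name} missing in one state")
    return (d_active - d_rest) / d_rest


def intensity_change(rest: ReflectionSet, active: ReflectionSet, name: str) -> float:
    """Intensity ratio I_active/I_rest (diffuse-sum-normalized intensities)."""
    i_rest = rest[name].intensity
    i_active = active[name].intensity
    if i_rest is None or i_active is None or i_rest == 0:
        raise AnalysisError(f"intensity of {name} missing or zero in one state")
    return i_active / i_rest
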