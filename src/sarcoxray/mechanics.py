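"""Muscle-mechanics curve fitting.

Models fitted (all by bounded nonlinear least squares):

* force-frequency sigmoid
  ``F(f) = Fmin + (Fmax − Fmin)/(1 + (F50/f)^nH)``;
* force-pCa Hill relation on [Ca²⁺] (pCa = −log₁₀[Ca²⁺]),
  ``F(pCa) = Fmax/(1 + 10^(nH·(pCa − pCa50)))`` — the "allosteric
  sigmoidal" form is the same model in another parameterization;
* two-phase force redevelopment after release-restretch,
  ``F(t) = Fss·((1 − e^(−ktr·t)) + (1 − e^(−k·t))) + c`` with
  ktr > k (rates returned sorted descending);
* slack-test unloaded shortening velocity (slope of release distance vs
  recovery delay);
* linear active stiffness from ±length steps.

``compare_curves_ftest`` is the extra-sum-of-squares (nested-model) F-test
of the null hypothesis that one curve fits all datasets.

Fit initialization follows the data: Fmax/Fmin from the extremes, the
half-point by interpolation, nH = 2; all rates and nH are bounded
positive, since unbounded Hill fits are multimodal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class FitError(RuntimeError):
    """A curve fit failed to converge; message carries diagnostics."""


def hill_force_frequency(f, fmin, fmax, f50, nh):
    f = np.asarray(f, dtype=float)
    return fmin + (fmax - fmin) / (1.0 + (f50 / f) ** nh)


def hill_force_pca(pca, fmax, pca50, nh):
    pca = np.asarray(pca, dtype=float)
    return fmax / (1.0 + 10.0 ** (nh * (pca - pca50)))


def ktr_biexponential(t, fss, ktr, k, c):
    t = np.asarray(t, dtype=float)
    return fss * ((1.0 - np.exp(-ktr * t)) + (1.0 - np.exp(-k * t))) + c


@dataclass
class HillFit:
    """Fitted force-frequency sigmoid."""

    fmin: float
    fmax: float
    f50_hz: float
    nh: float
    se: dict
    rss: float
    dof: int
    f50_in_range: bool

    def predict(self, f_hz):
        return hill_force_frequency(f_hz, self.fmin, self.fmax, self.f50_hz, self.nh)

    def predict_normalized(self, f_hz):
        """Relative-to-Fmax curve (the normalized force-frequency relation)."""
        return np.asarray(self.predict(f_hz)) / self.fmax


@dataclass
class PCaFit:
    """Fitted force-pCa Hill relation (calcium sensitivity pCa50, cooperativity nH)."""

    fmax: float
    pca50: float
    nh: float
    se: dict
    rss: float
    dof: int

    def predict(self, pca):
        return hill_force_pca(pca, self.fmax, self.pca50, self.nh)


@dataclass
class KtrFit:
    """Fitted two-phase force redevelopment; ktr is the fast-phase rate."""

    fss: float
    ktr_per_s: float
    k_per_s: float
    c: float
    fast_phase_share: float
    se: dict
    rss: float
    dof: int

    def predict(self, t_s):
        return ktr_biexponential(t_s, self.fss, self.ktr_per_s, self.k_per_s, self.c)


@dataclass
class VelocityFit:
    """Unloaded shortening velocity from the slack test."""

    velocity_lengths_per_s: float
    velocity_se: float
    intercept_s: float
    rss: float
    dof: int


@dataclass
class LinearFit:
    slope: float
    slope_se: float
    intercept: float
    rss: float
    dof: int


def _as_xy(data, xcol, ycol) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return data[xcol].to_numpy(float), data[ycol].to_numpy(float)
    x, y = data
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _curve_fit(model, x, y, p0, bounds, names) -> tuple[np.ndarray, dict, float]:
    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=40000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{model.__name__} fit failed (p0={p0}): {exc}") from exc
    resid = y - model(x, *popt)
    rss = float(resid @ resid)
    diag = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return popt, dict(zip(names, diag)), rss


def fit_force_frequency(data, xcol: str = "frequency_hz", ycol: str = "force_mn") -> HillFit:
    """Fit the force-frequency sigmoid; requires ≥5 frequencies."""
    f, y = _as_xy(data, xcol, ycol)
    if len(f) < 5:
        raise FitError("need at least 5 stimulation frequencies")
    fmin0, fmax0 = float(y.min()), float(y.max())
    half = 0.5 * (fmin0 + fmax0)
    order = np.argsort(f)
    f50_0 = float(np.interp(half, y[order], f[order])) if fmax0 > fmin0 else float(np.median(f))
    f50_0 = min(max(f50_0, f.min()), f.max())
    p0 = [fmin0, fmax0, f50_0, 2.0]
    span = fmax0 - fmin0 if fmax0 > fmin0 else 1.0
    bounds = ([fmin0 - span, fmin0, 1e-6, 0.1], [fmax0, fmax0 + span, 10 * f.max(), 50.0])
    popt, se, rss = _curve_fit(hill_force_frequency, f, y, p0, bounds,
                               ["fmin", "fmax", "f50_hz", "nh"])
    dof = len(f) - 4
    return HillFit(fmin=popt[0], fmax=popt[1], f50_hz=popt[2], nh=popt[3],
                   se=se, rss=rss, dof=dof,
                   f50_in_range=bool(f.min() <= popt[2] <= f.max()))


def fit_force_pca(data, xcol: str = "pca", ycol: str = "force") -> PCaFit:
    """Fit the force-pCa Hill relation (force decreasing with pCa)."""
    pca, y = _as_xy(data, xcol, ycol)
    if len(pca) < 4:
        raise FitError("need at least 4 pCa points")
    fmax0 = float(y.max())
    order = np.argsort(y)
    pca50_0 = float(np.interp(0.5 * fmax0, y[order], pca[order]))
    p0 = [fmax0, pca50_0, 2.0]
    bounds = ([1e-9, pca.min() - 2.0, 0.1], [10 * fmax0 if fmax0 > 0 else 1.0,
                                             pca.max() + 2.0, 50.0])
    popt, se, rss = _curve_fit(hill_force_pca, pca, y, p0, bounds, ["fmax", "pca50", "nh"])
    return PCaFit(fmax=popt[0], pca50=popt[1], nh=popt[2], se=se, rss=rss, dof=len(pca) - 3)


def fit_ktr(data, xcol: str = "t_s", ycol: str = "force",
            shared_amplitude: bool = True) -> KtrFit:
    """Fit the two-phase force-redevelopment curve.

    ``shared_amplitude=True`` fits the printed tied-amplitude form (both
    phases rise by Fss, so the amplitude share is exactly 0.5);
    ``False`` frees the two phase amplitudes and reports the fast-phase
    amplitude share A_fast/(A_fast + A_slow).  Fitted rates are returned
    sorted descending, ktr being the fast one.
    """
    t, y = _as_xy(data, xcol, ycol)
    c0 = float(y[np.argmin(t)])
    rise = float(y.max() - c0)
    span = t.max() - t.min()
    if span <= 0:
        raise FitError("degenerate time grid")
    # fast rate from the first 63%-of-rise crossing (fast phase dominates there)
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    above = np.where(ys >= c0 + 0.63 * rise)[0] if rise > 0 else np.array([])
    t63 = float(ts[above[0]]) if len(above) else span / 10.0
    r_fast0 = 1.0 / max(t63, span / 1e4)

    if shared_amplitude:
        p0 = [max(rise / 2.0, 1e-6), r_fast0, r_fast0 / 10.0, c0]
        bounds = ([0.0, 1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf, np.inf])
        popt, se, rss = _curve_fit(ktr_biexponential, t, y, p0, bounds,
                                   ["fss", "ktr_per_s", "k_per_s", "c"])
        fss, r1, r2, c = popt
        if r2 > r1:
            r1, r2 = r2, r1
            se["ktr_per_s"], se["k_per_s"] = se["k_per_s"], se["ktr_per_s"]
        return KtrFit(fss=fss, ktr_per_s=r1, k_per_s=r2, c=c, fast_phase_share=0.5,
                      se=se, rss=rss, dof=len(t) - 4)

    def model(t_, a1, r1, a2, r2, c_):
        return a1 * (1.0 - np.exp(-r1 * t_)) + a2 * (1.0 - np.exp(-r2 * t_)) + c_

    p0 = [0.9 * rise, r_fast0, 0.1 * rise, r_fast0 / 10.0, c0]
    bounds = ([0.0, 1e-6, 0.0, 1e-6, -np.inf], [np.inf] * 4 + [np.inf])
    popt, se, rss = _curve_fit(model, t, y, p0, bounds, ["a1", "r1", "a2", "r2", "c"])
    a1, r1, a2, r2, c = popt
    if r2 > r1:
        a1, r1, a2, r2 = a2, r2, a1, r1
    share = a1 / (a1 + a2) if (a1 + a2) > 0 else np.nan
    return KtrFit(fss=a1, ktr_per_s=r1, k_per_s=r2, c=c, fast_phase_share=float(share),
                  se=se, rss=rss, dof=len(t) - 5)


def unloaded_velocity(data, xcol: str = "slack_pct", ycol: str = "delay_s") -> VelocityFit:
    """Unloaded shortening velocity (lengths/s) from the slack test.

    The recovery delay is regressed on the release distance (time carries
    the noise): delay = t0 + distance/v; v = 1/slope, with the intercept
    t0 returned as the activation delay.  SE of v by the delta method.
    """
    pct, delay = _as_xy(data, xcol, ycol)
    dist = pct / 100.0  # fractions of initial length
    res = stats.linregress(dist, delay)
    if res.slope <= 0:
        raise FitError("non-positive delay-vs-distance slope; no velocity defined")
    v = 1.0 / res.slope
    v_se = res.stderr / res.slope**2
    resid = delay - (res.intercept + res.slope * dist)
    return VelocityFit(velocity_lengths_per_s=float(v), velocity_se=float(v_se),
                       intercept_s=float(res.intercept), rss=float(resid @ resid),
                       dof=len(pct) - 2)


def active_stiffness(data, xcol: str = "dl_pct", ycol: str = "df",
                     through_origin: bool = False) -> LinearFit:
    """Active stiffness: slope of tension change vs ±length steps (%)."""
    dl, df = _as_xy(data, xcol, ycol)
    if through_origin:
        slope = float(dl @ df / (dl @ dl))
        resid = df - slope * dl
        dof = len(dl) - 1
        sse = float(resid @ resid)
        slope_se = float(np.sqrt(sse / max(dof, 1) / (dl @ dl)))
        return LinearFit(slope=slope, slope_se=slope_se, intercept=0.0, rss=sse, dof=dof)
    res = stats.linregress(dl, df)
    resid = df - (res.intercept + res.slope * dl)
    return LinearFit(slope=float(res.slope), slope_se=float(res.stderr),
                     intercept=float(res.intercept), rss=float(resid @ resid),
                     dof=len(dl) - 2)


# ---- muscle geometry and normalization --------------------------------------

#: muscle density (mg/mm³)
MUSCLE_DENSITY_MG_MM3 = 1.056
#: fiber-to-muscle length ratios
FIBER_LENGTH_RATIO = {"EDL": 0.51, "soleus": 0.72}


@dataclass(frozen=True)
class MuscleGeometry:
    """Whole-muscle geometry for PCSA normalization."""

    mass_mg: float
    l0_mm: float
    muscle_type: str
    density_mg_mm3: float = MUSCLE_DENSITY_MG_MM3

    def __post_init__(self) -> None:
        if self.mass_mg <= 0 or self.l0_mm <= 0 or self.density_mg_mm3 <= 0:
            raise ValueError("mass, length and density must be positive")
        if self.muscle_type not in FIBER_LENGTH_RATIO:
            raise ValueError(f"muscle_type must be one of {sorted(FIBER_LENGTH_RATIO)}")

    @property
    def fiber_ratio(self) -> float:
        return FIBER_LENGTH_RATIO[self.muscle_type]

    @property
    def fiber_length_mm(self) -> float:
        return self.l0_mm * self.fiber_ratio


def pcsa(geom: MuscleGeometry) -> float:
    """Physiological cross-sectional area (mm²): mass/(density × fiber length)."""
    return geom.mass_mg / (geom.density_mg_mm3 * geom.fiber_length_mm)


def specific_force(force_mn: float, pcsa_mm2: float) -> float:
    """Force normalized to PCSA (mN/mm²)."""
    if pcsa_mm2 <= 0:
        raise ValueError("PCSA must be positive")
    return force_mn / pcsa_mm2


# ---- tetanus kinetics -------------------------------------------------------


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """First linear-interpolated crossing of `level`."""
    if rising:
        hit = np.where((y[:-1] < level) & (y[1:] >= level))[0]
    else:
        hit = np.where((y[:-1] > level) & (y[1:] <= level))[0]
    if len(hit) == 0:
        raise FitError(f"force trace never crosses level {level:.4g}")
    i = int(hit[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def tetanus_kinetics(trace, stim_onset_s: float = 0.0, stim_end_s: float = 0.5,
                     xcol: str = "t_s", ycol: str = "force_mn") -> dict[str, float]:
    """Half-activation and half-relaxation times (ms) of a tetanus trace.

    Time to ½ maximal force is measured from stimulus onset to the first
    interpolated crossing of half the plateau (maximum) force; time to ½
    relaxation from the end of stimulation to the decay through half the
    force at stimulation end.
    """
    t, y = _as_xy(trace, xcol, ycol)
    rise_sel = t >= stim_onset_s
    t_r, y_r = t[rise_sel], y[rise_sel]
    fmax = float(y_r.max())
    t_half_rise = _interp_crossing(t_r, y_r, fmax / 2.0, rising=True) - stim_onset_s

    decay_sel = t >= stim_end_s
    t_d, y_d = t[decay_sel], y[decay_sel]
    if len(t_d) < 2:
        raise FitError("no samples after end of stimulation")
    f_end = float(y_d[0])
    t_half_relax = _interp_crossing(t_d, y_d, f_end / 2.0, rising=False) - stim_end_s
    return {"time_to_half_force_ms": t_half_rise * 1e3,
            "time_to_half_relaxation_ms": t_half_relax * 1e3}


# ---- one-curve-fits-all nested F-test ---------------------------------------

_FTEST_MODELS = {
    "hill_ff": (fit_force_frequency, 4),
    "hill_pca": (fit_force_pca, 3),
}


def compare_curves_ftest(datasets, model: str = "hill_ff",
                         xcol: str | None = None, ycol: str | None = None) -> dict[str, float]:
    """Extra-sum-of-squares F-test: does one curve fit all datasets?

    Fits the model to each dataset separately and once to the pooled data;
    F = ((SS_pooled − SS_separate)/(df_pooled − df_separate)) /
    (SS_separate/df_separate), with the p-value from the F distribution.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to compare")
    fitter, nparam = _FTEST_MODELS[model]
    cols = {}
    if xcol:
        cols["xcol"] = xcol
    if ycol:
        cols["ycol"] = ycol

    xs, ys = [], []
    ss_sep = 0.0
    n_total = 0
    for i, d in enumerate(datasets):
        x, y = _as_xy(d, cols.get("xcol", "frequency_hz" if model == "hill_ff" else "pca"),
                      cols.get("ycol", "force_mn" if model == "hill_ff" else "force"))
        try:
            fit = fitter((x, y))
        except FitError as exc:
            raise FitError(f"separate fit failed for dataset {i}: {exc}") from exc
        ss_sep += fit.rss
        xs.append(x)
        ys.append(y)
        n_total += len(x)
    df_sep = n_total - nparam * len(datasets)
    pooled = (np.concatenate(xs), np.concatenate(ys))
    ss_pool = fitter(pooled).rss
    df_pool = n_total - nparam

    dfn = df_pool - df_sep
    if df_sep <= 0 or dfn <= 0:
        raise FitError("not enough points for the nested F-test")
    if ss_sep <= 0.0:
        # perfect separate fits: F undefined unless pooling adds no misfit
        fstat = 0.0 if ss_pool <= max(1e-9 * n_total, 1e-12) else np.inf
    else:
        fstat = ((ss_pool - ss_sep) / dfn) / (ss_sep / df_sep)
    fstat = max(fstat, 0.0)
    p = float(stats.f.sf(fstat, dfn, df_sep))
    return {"F": float(fstat), "dfn": int(dfn), "dfd": int(df_sep), "p": p,
            "ss_pooled": float(ss_pool), "ss_separate": float(ss_sep)}
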