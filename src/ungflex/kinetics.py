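"""Steady-state UNG kinetics from continuous 2AP fluorescence traces.

Excision of uracil opposite 2AP leaves an abasic site, relieving the
stacking quench and raising the fluorescence. A continuous trace F(t) at
fixed substrate concentration therefore tracks product formation, and the
initial velocity is

    V0 = ([S]0 / dF_total) * (dF/dt)|0        [M/s],

where dF_total is the full fluorescence change at completion. V0 versus
[S]0 is then fitted with the Michaelis-Menten equation by variance-weighted
Levenberg-Marquardt least squares, giving K_M, V_max (hence
k_cat = V_max / E0) and the specificity constant k_cat/K_M that ranks UNG
substrate preference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DEFAULT_E0_M",
    "KineticTrace",
    "V0Point",
    "MMFit",
    "initial_velocity",
    "fit_mm",
    "specificity_table",
]

#: Final UNG concentration in the assay mixture (M).
DEFAULT_E0_M: float = 0.16e-9

#: Substrate concentrations assayed (M); traces outside this range warn.
ASSAYED_RANGE_M: tuple[float, float] = (0.075e-6, 6e-6)


@dataclass(frozen=True)
class KineticTrace:
    """Continuous fluorescence trace after enzyme addition, one [S]0."""

    time: np.ndarray  # s
    intensity: np.ndarray  # arbitrary units
    substrate_conc: float  # M
    enzyme_conc: float = DEFAULT_E0_M  # M

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", f)
        if t.ndim != 1 or t.size != f.size:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.substrate_conc <= 0:
            raise ValueError("substrate concentration must be > 0")
        lo, hi = ASSAYED_RANGE_M
        if not lo <= self.substrate_conc <= hi:
            warnings.warn(
                f"[S]0 = {self.substrate_conc:.3g} M outside the assayed "
                f"range [{lo:.3g}, {hi:.3g}] M",
                stacklevel=3,
            )


@dataclass(frozen=True)
class V0Point:
    """Initial velocity at one substrate concentration."""

    substrate_conc: float  # M
    v0: float  # M/s
    variance: float  # (M/s)^2
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("V0 must be >= 0")


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten parameters with standard errors."""

    km: float  # M
    km_se: float
    vmax: float  # M/s
    vmax_se: float
    kcat: float  # 1/s
    specificity: float  # kcat/KM, 1/(M s)
    specificity_se: float
    enzyme_conc: float
    covariance: np.ndarray
    ill_conditioned: bool = False


def initial_velocity(
    trace: KineticTrace,
    slope_fraction: float = 0.2,
    delta_f: float | None = None,
    baseline: "float | str" = "first",
) -> V0Point:
    """Initial velocity from the early slope of a fluorescence progress trace.

    The total change dF is (plateau - baseline), with the plateau taken as
    the mean of the final 5% of points unless an explicit ``delta_f`` is
    supplied (useful when the trace was not run to completion). The initial
    slope is the t=0 derivative of a local quadratic least-squares fit over
    the leading segment where the rise is at most ``slope_fraction * dF``:
    the quadratic term absorbs the progress curve's concavity, which would
    bias a straight-line slope low by about half the window fraction. The
    default 20% window balances that (third-order) truncation bias against
    the noise amplification of narrow windows. ``baseline`` is the first
    point ('first') or an explicit pre-addition level.

    V0 is invariant under affine rescaling of the intensity: both dF and the
    slope scale by the same factor.
    """
    t, f = trace.time, trace.intensity
    if isinstance(baseline, str):
        if baseline != "first":
            raise ValueError("baseline must be 'first' or an explicit value")
        f0 = float(f[0])
    else:
        f0 = float(baseline)

    if delta_f is None:
        n_tail = max(int(0.05 * f.size), 3)
        plateau = float(np.mean(f[-n_tail:]))
        delta_f = plateau - f0
        tail_slope = abs(np.polyfit(t[-n_tail:], f[-n_tail:], 1)[0])
        if delta_f > 0 and tail_slope * (t[-1] - t[0]) > 0.05 * delta_f:
            warnings.warn("trace has not plateaued; dF may be underestimated", stacklevel=2)
    if delta_f <= 0:
        return V0Point(trace.substrate_conc, 0.0, math.inf, n_repeats=1)

    noise = float(np.std(np.diff(f[: max(f.size // 20, 5)]))) / math.sqrt(2.0)
    if delta_f <= 3.0 * noise:
        return V0Point(trace.substrate_conc, 0.0, math.inf, n_repeats=1)

    rise = f - f0
    beyond = np.nonzero(rise > slope_fraction * delta_f)[0]
    end = int(beyond[0]) if beyond.size else f.size  # leading segment only
    end = max(end, 3)
    seg = slice(0, end)
    ts, fs = t[seg] - t[0], f[seg]
    # quadratic local fit: the progress curve is concave, so a straight line
    # over the rise window biases the t=0 slope low by ~slope_fraction/2
    degree = 2 if end >= 10 else 1
    design = np.vander(ts, degree + 1, increasing=True)
    coef, _, _, _ = np.linalg.lstsq(design, fs, rcond=None)
    slope = float(coef[1])
    resid = fs - design @ coef
    s2 = float(np.sum(resid**2)) / max(end - (degree + 1), 1)
    try:
        cov = s2 * np.linalg.inv(design.T @ design)
        slope_var = float(cov[1, 1])
    except np.linalg.LinAlgError:
        slope_var = math.inf

    v0 = trace.substrate_conc * float(slope) / delta_f
    v0_var = (trace.substrate_conc / delta_f) ** 2 * slope_var
    return V0Point(trace.substrate_conc, max(v0, 0.0), max(v0_var, 1e-300), n_repeats=1)


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_mm(points: "list[V0Point]", enzyme_conc: float = DEFAULT_E0_M) -> MMFit:
    """Variance-weighted Michaelis-Menten fit of V0 versus [S]0.

    Weights are the reciprocals of the V0 variances (points with infinite
    variance are dropped). k_cat = V_max/E0; the specificity constant
    k_cat/K_M carries a first-order propagated standard error using the full
    (V_max, K_M) covariance.
    """
    pts = [p for p in points if math.isfinite(p.variance) and p.variance > 0]
    if len(pts) < 2:
        raise ValueError("need at least 2 finite-variance V0 points")
    s = np.array([p.substrate_conc for p in pts])
    v = np.array([p.v0 for p in pts])
    sigma = np.sqrt(np.array([p.variance for p in pts]))
    if len(set(np.round(np.log10(s), 6))) < 4:
        warnings.warn("fewer than 4 distinct substrate concentrations", stacklevel=2)

    vmax0 = float(np.max(v)) or 1e-12
    km0 = float(np.median(s))
    popt, pcov = curve_fit(
        _mm, s, v, p0=[vmax0, km0], sigma=sigma, absolute_sigma=True,
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
    )
    vmax, km = float(popt[0]), float(popt[1])
    vmax_se, km_se = float(np.sqrt(pcov[0, 0])), float(np.sqrt(pcov[1, 1]))

    ill = bool(km < 0.5 * s.min() or km > 2.0 * s.max())
    if ill:
        warnings.warn(
            "K_M outside the sampled concentration range; fit is ill-conditioned",
            stacklevel=2,
        )

    kcat = vmax / enzyme_conc
    spec = kcat / km
    # d(spec)/d(vmax) = 1/(E0 KM); d(spec)/d(KM) = -vmax/(E0 KM^2)
    g = np.array([1.0 / (enzyme_conc * km), -vmax / (enzyme_conc * km**2)])
    spec_se = float(np.sqrt(g @ pcov @ g))
    if not km > 0 or not vmax > 0:
        raise RuntimeError("fit returned non-positive Michaelis-Menten parameters")
    return MMFit(
        km=km, km_se=km_se, vmax=vmax, vmax_se=vmax_se, kcat=kcat,
        specificity=spec, specificity_se=spec_se, enzyme_conc=enzyme_conc,
        covariance=pcov, ill_conditioned=ill,
    )


def specificity_table(fits: "dict[str, MMFit]") -> pd.DataFrame:
    """Substrates ranked by specificity constant, with pairwise ratios.

    The returned frame is sorted by descending k_cat/K_M and includes a
    ``ratio_to_best`` column plus one ``ratio_vs_<id>`` column per substrate.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = [
        {
            "substrate": name,
            "kcat_over_km": fit.specificity,
            "kcat_over_km_se": fit.specificity_se,
            "km": fit.km,
            "kcat": fit.kcat,
        }
        for name, fit in fits.items()
    ]
    df = pd.DataFrame(rows).sort_values("kcat_over_km", ascending=False).reset_index(drop=True)
    best = df["kcat_over_km"].iloc[0]
    df["ratio_to_best"] = df["kcat_over_km"] / best
    for name in df["substrate"]:
        ref = float(df.loc[df["substrate"] == name, "kcat_over_km"].iloc[0])
        df[f"ratio_vs_{name}"] = df["kcat_over_km"] / ref
    return df
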