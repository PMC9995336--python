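"""Imino-proton exchange-rate fitting from water magnetization transfer.

Base-pair opening exposes the imino proton to solvent, letting it exchange
with water at rate ``k_ex``. In the magnetization-transfer experiment, water
is inverted and the imino peak area A(t) transiently dips as inverted water
magnetization flows through exchange into the imino site, then recovers:

    A(t)/A0 = 1 - E*k_ex/(R1w - R1n) * (exp(-R1n*t) - exp(-R1w*t))

where E is the measured water-inversion efficiency, R1w the water
longitudinal relaxation rate, and R1n the total imino relaxation rate
(intrinsic relaxation plus solvent exchange, so k_ex <= R1n). The depth of
the dip scales with k_ex; its shape is set by R1n and R1w.

Fitting follows the sequential protocol: first R1n is determined with the
transfer amplitude treated as a nuisance parameter, then k_ex is refit alone
with R1n, R1w and E held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "ExchangeSeries",
    "ExchangeFit",
    "exchange_model",
    "fit_r1w",
    "fit_exchange",
    "default_delay_grid",
]


def default_delay_grid(n: int = 24, t_min: float = 1e-3, t_max: float = 15.0) -> np.ndarray:
    """Log-spaced variable-delay grid (default 24 points, 1 ms to 15 s)."""
    return np.geomspace(t_min, t_max, n)


@dataclass(frozen=True)
class ExchangeSeries:
    """Imino peak areas versus exchange delay for one resonance.

    ``efficiency`` (E) and ``r1w`` are measured calibration constants, not
    fit parameters. ``a0`` is the equilibrium peak area.
    """

    delays: np.ndarray
    areas: np.ndarray
    a0: float
    efficiency: float
    r1w: float
    residue: str = ""

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "areas", areas)
        if delays.ndim != 1 or delays.size != areas.size:
            raise ValueError("delays and areas must be 1-D arrays of equal length")
        if np.any(np.diff(delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if self.a0 <= 0:
            raise ValueError(f"equilibrium area A0 must be > 0, got {self.a0}")
        if not 0 < self.efficiency <= 2:
            raise ValueError(f"inversion efficiency must be in (0, 2], got {self.efficiency}")
        if self.r1w <= 0:
            raise ValueError(f"R1w must be > 0, got {self.r1w}")


@dataclass(frozen=True)
class ExchangeFit:
    """Result of the two-stage exchange fit."""

    k_ex: float
    k_ex_se: float
    r1n: float
    r1n_se: float
    residual_norm: float
    covariance: np.ndarray | None = None
    #: Set when the transfer dip is not resolved above noise: k_ex is then an
    #: upper bound, not an estimate.
    upper_bound_flag: bool = field(default=False)


# Threshold below which the (R1w - R1n) denominator switches to the series
# limit form; chosen so both branches agree to ~1e-9 relative.
_DEGENERATE_TOL = 1e-7


def exchange_model(
    t: "np.ndarray | float",
    k_ex: float,
    r1n: float,
    r1w: float,
    efficiency: float,
) -> np.ndarray:
    """Normalized recovery A(t)/A0 of an imino peak after water inversion.

    Handles the removable singularity at R1n == R1w via the limit form
    ``1 - E*k_ex*t*exp(-R1n*t)``.
    """
    t = np.asarray(t, dtype=float)
    if r1n < 0 or r1w < 0 or k_ex < 0:
        raise ValueError("rates must be non-negative")
    dr = r1w - r1n
    if abs(dr) < _DEGENERATE_TOL * max(r1n, r1w, 1.0):
        return 1.0 - efficiency * k_ex * t * np.exp(-r1n * t)
    return 1.0 - efficiency * k_ex / dr * (np.exp(-r1n * t) - np.exp(-r1w * t))


def fit_r1w(
    delays: np.ndarray,
    signal: np.ndarray,
) -> tuple[float, float]:
    """Water longitudinal relaxation rate from a saturation-recovery series.

    Fits S(t) = S_inf * (1 - exp(-R1w * t)) and returns (R1w, standard error).
    """
    t = np.asarray(delays, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.size < 6:
        raise ValueError(f"need at least 6 delay points, got {t.size}")

    s_inf0 = float(np.max(s)) or 1.0
    # crude rate guess from the delay where recovery reaches ~63%
    frac = s / s_inf0
    idx = np.searchsorted(frac, 0.632)
    r0 = 1.0 / t[min(idx, t.size - 1)] if t[min(idx, t.size - 1)] > 0 else 1.0

    def model(tt, s_inf, r1w):
        return s_inf * (1.0 - np.exp(-r1w * tt))

    popt, pcov = curve_fit(
        model, t, s, p0=[s_inf0, r0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
    )
    r1w = float(popt[1])
    r1w_se = float(np.sqrt(pcov[1, 1]))
    if r1w <= 0:
        raise RuntimeError("saturation-recovery fit returned a non-positive rate")
    return r1w, r1w_se


def fit_exchange(series: ExchangeSeries) -> ExchangeFit:
    """Two-stage fit of the water magnetization-transfer recovery.

    Stage 1 fits (R1n, B) with B = E*k_ex a free transfer amplitude, so R1n
    is identified by the curve shape alone. Stage 2 refits k_ex as the sole
    free parameter with R1n, R1w and E fixed; its standard error comes from
    the stage-2 Jacobian. The physical constraint k_ex <= R1n is enforced as
    a soft penalty to avoid boundary-stuck fits.

    Invariant to common rescaling of areas and A0 (only the ratio enters).
    """
    t = series.delays
    y = series.areas / series.a0
    e, r1w = series.efficiency, series.r1w

    dip_depth = float(1.0 - np.min(y))
    noise = _noise_scale(y)

    # ---- stage 1: (R1n, B) with B = E*k_ex ----
    def resid1(p):
        r1n, b = p
        model = 1.0 - b / (r1w - r1n) * (np.exp(-r1n * t) - np.exp(-r1w * t)) \
            if abs(r1w - r1n) > _DEGENERATE_TOL else 1.0 - b * t * np.exp(-r1n * t)
        return model - y

    # initial guesses: R1n from the dip position (t_dip ~ ln(R1n/R1w)/(R1n-R1w)),
    # scanned over a coarse grid for robustness
    best = None
    for r1n0 in np.geomspace(max(2.0 * r1w, 0.1), 100.0, 8):
        b0 = max(dip_depth * max(r1n0, 1.0), 1e-6)
        try:
            sol = least_squares(
                resid1, [r1n0, b0], bounds=([r1w * (1 + 1e-9), 0.0], [np.inf, np.inf]),
                xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("stage-1 exchange fit failed to converge")
    r1n = float(best.x[0])
    if r1n <= r1w:
        raise RuntimeError(
            f"fitted R1n ({r1n:.3g}) does not exceed R1w ({r1w:.3g}); model invalid"
        )
    r1n_se = _se_from_jacobian(best)[0]

    # ---- stage 2: k_ex alone, soft penalty keeping k_ex <= R1n ----
    def fit_kex(r1n_fixed: float, k0: float):
        def resid2(p):
            (k_ex,) = p
            r = exchange_model(t, k_ex, r1n_fixed, r1w, e) - y
            penalty = max(0.0, k_ex - r1n_fixed) * 10.0
            return np.append(r, penalty)

        return least_squares(resid2, [max(k0, 1e-9)], bounds=([0.0], [np.inf]),
                             xtol=1e-12, ftol=1e-12)

    k0 = min(float(best.x[1]) / e, r1n)
    sol2 = fit_kex(r1n, k0)
    k_ex = float(sol2.x[0])
    k_se_cond = _se_from_jacobian(sol2, n_extra=1)[0]

    # The conditional SE understates the error: R1n is itself estimated, and
    # k_ex trades off against it. Widen by first-order propagation of the
    # stage-1 R1n uncertainty (finite-difference sensitivity of the stage-2
    # estimate to R1n).
    k_sens = 0.0
    if np.isfinite(r1n_se) and r1n_se > 0:
        delta = min(r1n_se, 0.25 * (r1n - r1w))
        if delta > 0:
            k_hi = float(fit_kex(r1n + delta, k_ex).x[0])
            k_lo = float(fit_kex(max(r1n - delta, r1w * (1 + 1e-9)), k_ex).x[0])
            k_sens = 0.5 * abs(k_hi - k_lo) * (r1n_se / delta)
    k_se = float(np.hypot(k_se_cond, k_sens))

    upper_bound = dip_depth <= 3.0 * noise
    if upper_bound:
        warnings.warn(
            f"transfer dip ({dip_depth:.3g}) not resolved above noise "
            f"({noise:.3g}); k_ex is an upper bound",
            stacklevel=2,
        )
    cov2 = None
    if sol2.jac is not None:
        cov2 = _covariance(sol2, n_extra=1)
    return ExchangeFit(
        k_ex=k_ex,
        k_ex_se=k_se,
        r1n=r1n,
        r1n_se=r1n_se,
        residual_norm=float(np.linalg.norm(sol2.fun[:-1])),
        covariance=cov2,
        upper_bound_flag=upper_bound,
    )


def _noise_scale(y: np.ndarray) -> float:
    """Robust noise estimate from first differences of the normalized areas."""
    if y.size < 3:
        return 0.0
    return float(np.median(np.abs(np.diff(y))) / 0.9538)  # MAD of diffs -> sigma


def _covariance(sol, n_extra: int = 0) -> np.ndarray:
    """Parameter covariance from a least_squares solution Jacobian."""
    m = sol.fun.size - n_extra
    n = sol.x.size
    dof = max(m - n, 1)
    s2 = float(np.sum(sol.fun[: m] ** 2)) / dof
    jtj = sol.jac[:m].T @ sol.jac[:m]
    try:
        return s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return np.full((n, n), np.nan)


def _se_from_jacobian(sol, n_extra: int = 0) -> np.ndarray:
    cov = _covariance(sol, n_extra=n_extra)
    return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
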