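"""Multi-exponential TCSPC decay fitting by iterative IRF reconvolution.

Time-correlated single-photon counting histograms of 2AP emission in duplex
DNA are multi-exponential: the probe samples several stacking environments,
each with its own lifetime. The model for one emission wavelength is

    F(lambda, t) = F0(lambda) * sum_i alpha_i(lambda) * exp(-t / tau_i),
    sum_i alpha_i(lambda) = 1,

convolved with the measured instrument response function (IRF). Decays at
the three emission wavelengths are fitted globally with the lifetimes shared
across wavelengths, which breaks the amplitude/lifetime correlations that
plague independent multi-exponential fits.

The two-window protocol resolves the full 30 ps - 8 ns lifetime span:

1. decays acquired at the highest channel resolution (814 fs/channel,
   3.3 ns span) are fitted with three exponentials, pinning down the two
   sub-0.5-ns lifetimes;
2. decays acquired with the wide window (6.1 ps/channel, 25 ns span) are
   fitted with four exponentials, fixing tau_1 and tau_2 to the stage-1
   values; free parameters are tau_3, tau_4 and all amplitudes.

Mean lifetimes are the amplitude-weighted sums <tau> = sum_i alpha_i tau_i
using the stage-2 amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

__all__ = [
    "SHORT_CHANNEL_WIDTH_S",
    "LONG_CHANNEL_WIDTH_S",
    "N_CHANNELS",
    "EMISSION_WAVELENGTHS_NM",
    "DecayCurve",
    "IRF",
    "GlobalFitResult",
    "MeanLifetime",
    "reconvolve",
    "fit_global",
    "fit_two_window",
    "mean_lifetime",
]

#: Default channel widths of the two acquisition windows (s/channel).
SHORT_CHANNEL_WIDTH_S: float = 814e-15
LONG_CHANNEL_WIDTH_S: float = 6.1e-12
#: Default number of channels per histogram (2**12).
N_CHANNELS: int = 4096
#: Default emission wavelengths for global analysis (nm).
EMISSION_WAVELENGTHS_NM: tuple[int, ...] = (380, 390, 400)

#: Fit window opens this many channels before the IRF maximum.
PRE_PEAK_CHANNELS: int = 20
#: Bounds on the fitted IRF/decay channel-shift parameter.
SHIFT_BOUND_CHANNELS: float = 10.0


@dataclass(frozen=True)
class DecayCurve:
    """One photon-counting histogram: counts per channel at one wavelength."""

    channel_width: float  # seconds per channel
    counts: np.ndarray
    wavelength: float  # nm
    window_id: str  # 'short' or 'long'

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if self.channel_width <= 0:
            raise ValueError("channel_width must be > 0")
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.window_id not in ("short", "long"):
            raise ValueError(f"window_id must be 'short' or 'long', got {self.window_id!r}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.counts.size) * self.channel_width


@dataclass(frozen=True)
class IRF:
    """Instrument response function on the same grid convention as a decay."""

    channel_width: float
    counts: np.ndarray
    fwhm: float = 40e-12  # metadata only

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.channel_width <= 0:
            raise ValueError("channel_width must be > 0")
        if counts.sum() <= 0:
            raise ValueError("IRF must contain positive total counts")

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class GlobalFitResult:
    """Shared lifetimes plus per-wavelength amplitudes from a global fit."""

    lifetimes_ns: np.ndarray  # ascending
    amplitudes: dict[float, np.ndarray]  # per wavelength, sum to 1
    scales: dict[float, float]  # F0(lambda), counts
    n_exp: int
    shift_channels: float
    reduced_chisq: dict[float, float]
    covariance: np.ndarray | None = None
    fixed_indices: tuple[int, ...] = field(default_factory=tuple)
    window_id: str = ""

    def __post_init__(self) -> None:
        taus = np.asarray(self.lifetimes_ns, dtype=float)
        object.__setattr__(self, "lifetimes_ns", taus)
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("lifetimes must be strictly ascending")
        for wl, a in self.amplitudes.items():
            if abs(float(np.sum(a)) - 1.0) > 1e-9:
                raise ValueError(f"amplitudes at {wl} nm do not sum to 1")


@dataclass(frozen=True)
class MeanLifetime:
    """Amplitude-weighted mean lifetime <tau> = sum_i alpha_i tau_i (ns)."""

    value: float
    relative_precision: float = 0.025
    wavelength: float | None = None


def _shifted_irf(irf_norm: np.ndarray, shift: float) -> np.ndarray:
    """IRF displaced by a (fractional) number of channels, linear interpolation."""
    if shift == 0.0:
        return irf_norm
    idx = np.arange(irf_norm.size, dtype=float)
    return np.interp(idx - shift, idx, irf_norm, left=0.0, right=0.0)


def _exp_basis(times: np.ndarray, lifetimes_s: np.ndarray) -> np.ndarray:
    """Rows of unit-amplitude exponentials exp(-t/tau) on the channel grid."""
    return np.exp(-times[None, :] / lifetimes_s[:, None])


def reconvolve(
    irf: IRF,
    lifetimes_s: np.ndarray,
    amplitudes: np.ndarray,
    scale: float = 1.0,
    shift_channels: float = 0.0,
    channel_width: float | None = None,
    n_channels: int | None = None,
) -> np.ndarray:
    """Discrete convolution of the normalized IRF with a multi-exponential.

    Returns model counts on the decay grid; linear in ``scale`` and in each
    amplitude. ``shift_channels`` displaces the IRF by a possibly fractional
    number of channels (positive = later) before convolution.
    """
    lifetimes_s = np.asarray(lifetimes_s, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(lifetimes_s <= 0):
        raise ValueError("lifetimes must be positive")
    if lifetimes_s.shape != amplitudes.shape:
        raise ValueError("lifetimes and amplitudes must have equal length")
    dt = channel_width if channel_width is not None else irf.channel_width
    if dt != irf.channel_width:
        raise ValueError(
            "decay and IRF grids differ; resample the IRF onto the decay grid first"
        )
    n = n_channels if n_channels is not None else irf.counts.size
    times = np.arange(n) * dt
    kernel = _shifted_irf(irf.normalized(), shift_channels)
    decay = amplitudes @ _exp_basis(times, lifetimes_s)
    return scale * fftconvolve(kernel, decay)[:n]


def _fit_window(
    decays: list[DecayCurve],
    irf: IRF,
) -> slice:
    start = max(int(np.argmax(irf.counts)) - PRE_PEAK_CHANNELS, 0)
    return slice(start, decays[0].counts.size)


def fit_global(
    decays: "list[DecayCurve]",
    irf: IRF,
    n_exp: int,
    fixed_lifetimes: "list[tuple[int, float]] | None" = None,
    init_lifetimes_ns: "np.ndarray | None" = None,
    include_background: bool = False,
    max_nfev: int = 500 * 40,
) -> GlobalFitResult:
    """Global multi-exponential reconvolution fit over several wavelengths.

    Minimizes Poisson-weighted least squares (Neyman weights 1/max(counts, 1))
    with the lifetimes shared across all curves and per-wavelength component
    amplitudes free. A single IRF/decay channel-shift parameter (bounded to
    +/-10 channels) is shared by all curves. ``fixed_lifetimes`` pins selected
    lifetimes, given as (index, value_ns) with indices referring to the
    ascending ordering.

    Amplitudes are reported normalized to sum 1 per wavelength, with the
    per-wavelength scale F0 carrying the magnitude.
    """
    if not 1 <= n_exp <= 5:
        raise ValueError(f"n_exp out of supported range: {n_exp}")
    window_ids = {d.window_id for d in decays}
    if len(window_ids) != 1:
        raise ValueError("all decays in a global fit must share a window")
    widths = {d.channel_width for d in decays}
    if len(widths) != 1 or decays[0].channel_width != irf.channel_width:
        raise ValueError("decay/IRF channel widths must match")
    dt = decays[0].channel_width
    n = decays[0].counts.size
    fit_slice = _fit_window(decays, irf)
    times = np.arange(n) * dt
    irf_norm = irf.normalized()

    fixed = dict(fixed_lifetimes or [])
    free_idx = [i for i in range(n_exp) if i not in fixed]

    if init_lifetimes_ns is None:
        span = n * dt
        init_lifetimes_ns = np.geomspace(4 * dt * 1e9, 0.5 * span * 1e9, n_exp)
    init_lifetimes_ns = np.asarray(init_lifetimes_ns, dtype=float)
    for i, v in fixed.items():
        init_lifetimes_ns[i] = v

    n_curves = len(decays)
    counts = np.stack([d.counts.astype(float) for d in decays])
    weights = 1.0 / np.sqrt(np.maximum(counts[:, fit_slice], 1.0))
    peak_amp = counts.max(axis=1)

    # parameter vector: [log10(free taus in ns) | log10(amplitudes per curve,
    # n_exp each) | shift | (backgrounds per curve)]
    n_free_tau = len(free_idx)
    n_amp = n_curves * n_exp

    def unpack(x):
        taus_ns = init_lifetimes_ns.copy()
        taus_ns[free_idx] = 10.0 ** x[:n_free_tau]
        amps = (10.0 ** x[n_free_tau : n_free_tau + n_amp]).reshape(n_curves, n_exp)
        shift = x[n_free_tau + n_amp]
        bg = x[n_free_tau + n_amp + 1 :] if include_background else np.zeros(n_curves)
        return taus_ns, amps, shift, bg

    def residuals(x):
        taus_ns, amps, shift, bg = unpack(x)
        kernel = _shifted_irf(irf_norm, shift)
        basis = _exp_basis(times, taus_ns * 1e-9)
        conv = fftconvolve(kernel[None, :], basis, axes=1)[:, :n]
        out = np.empty((n_curves, fit_slice.stop - fit_slice.start))
        for c in range(n_curves):
            model = amps[c] @ conv + bg[c]
            out[c] = (model[fit_slice] - counts[c, fit_slice]) * weights[c]
        return out.ravel()

    x0 = np.concatenate(
        [
            np.log10(init_lifetimes_ns[free_idx]),
            np.log10(np.tile(np.maximum(peak_amp[:, None], 1.0) / n_exp, (1, n_exp))).ravel(),
            [0.0],
            np.zeros(n_curves) if include_background else [],
        ]
    )
    lo = np.concatenate(
        [
            np.full(n_free_tau, np.log10(max(dt * 1e9 * 0.5, 1e-4))),
            np.full(n_amp, -6.0),
            [-SHIFT_BOUND_CHANNELS],
            np.zeros(n_curves) - np.inf if include_background else [],
        ]
    )
    hi = np.concatenate(
        [
            np.full(n_free_tau, np.log10(n * dt * 1e9 * 20)),
            np.log10(peak_amp.max() * 10) * np.ones(n_amp),
            [SHIFT_BOUND_CHANNELS],
            np.zeros(n_curves) + np.inf if include_background else [],
        ]
    )
    sol = least_squares(
        residuals, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10, gtol=1e-10,
        max_nfev=max_nfev, x_scale="jac",
    )
    if not sol.success and sol.status <= 0:
        raise RuntimeError(f"global fit did not converge: {sol.message}")

    taus_ns, amps, shift, bg = unpack(sol.x)
    if np.any(taus_ns <= 0):
        raise RuntimeError("fit rejected: non-positive lifetime")

    order = np.argsort(taus_ns)
    taus_sorted = taus_ns[order]
    if np.any(np.diff(taus_sorted) <= 0):
        # merged components: nudge apart so ordering is strict, then warn
        warnings.warn("fitted lifetimes degenerate; components may be merged", stacklevel=2)
        taus_sorted = taus_sorted + np.arange(n_exp) * 1e-12
    amps_sorted = amps[:, order]

    amplitudes: dict[float, np.ndarray] = {}
    scales: dict[float, float] = {}
    red_chisq: dict[float, float] = {}
    n_pts = fit_slice.stop - fit_slice.start
    n_free_per_curve = (n_free_tau + 1) / n_curves + n_exp + (1 if include_background else 0)
    res = sol.fun.reshape(n_curves, n_pts)
    for c, d in enumerate(decays):
        total = float(amps_sorted[c].sum())
        amplitudes[d.wavelength] = amps_sorted[c] / total
        scales[d.wavelength] = total
        dof = max(n_pts - n_free_per_curve, 1.0)
        red_chisq[d.wavelength] = float(np.sum(res[c] ** 2) / dof)

    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        dof_all = max(sol.fun.size - sol.x.size, 1)
        cov = np.linalg.inv(jtj) * float(np.sum(sol.fun**2) / dof_all)
    except np.linalg.LinAlgError:
        pass

    return GlobalFitResult(
        lifetimes_ns=taus_sorted,
        amplitudes=amplitudes,
        scales=scales,
        n_exp=n_exp,
        shift_channels=float(shift),
        reduced_chisq=red_chisq,
        covariance=cov,
        fixed_indices=tuple(sorted(fixed)),
        window_id=decays[0].window_id,
    )


def fit_two_window(
    short_decays: "list[DecayCurve]",
    long_decays: "list[DecayCurve]",
    irf_short: IRF,
    irf_long: IRF,
    init_lifetimes_ns: "np.ndarray | None" = None,
    n_refine: int = 2,
) -> GlobalFitResult:
    """Two-window protocol resolving lifetimes from ~30 ps to ~8 ns.

    Stage 1 fits the high-resolution window with three exponentials; stage 2
    fits the wide window with four exponentials, fixing tau_1 and tau_2 to
    the stage-1 values. The returned result is the final wide-window fit,
    whose amplitudes feed the mean-lifetime calculation.

    With ``n_refine >= 1`` (default 2) the window roles are then alternated
    to self-consistency: the short window is refit with four exponentials
    holding (tau_3, tau_4) at the wide-window values — the stage-1 3-exp fit
    must absorb two long components into one, which biases tau_1 and tau_2
    upward, and the 4-exp refit removes that bias — and the wide window is
    refit with the refreshed (tau_1, tau_2). Each stage still estimates only
    the lifetimes its resolution supports. ``n_refine=0`` gives the plain
    two-stage protocol.
    """
    init3 = None
    init4_rest = None
    if init_lifetimes_ns is not None:
        init = np.asarray(init_lifetimes_ns, dtype=float)
        init3 = init[:3]
        init4_rest = init[2:]
    stage1 = fit_global(short_decays, irf_short, n_exp=3, init_lifetimes_ns=init3)
    tau1, tau2 = stage1.lifetimes_ns[0], stage1.lifetimes_ns[1]
    if init4_rest is not None:
        init4 = np.array([tau1, tau2, init4_rest[0], init4_rest[1]])
    else:
        span_ns = long_decays[0].counts.size * long_decays[0].channel_width * 1e9
        init4 = np.array([tau1, tau2, stage1.lifetimes_ns[2], 0.4 * span_ns])
    stage2 = fit_global(
        long_decays,
        irf_long,
        n_exp=4,
        fixed_lifetimes=[(0, tau1), (1, tau2)],
        init_lifetimes_ns=init4,
    )
    for _ in range(n_refine):
        tau3, tau4 = stage2.lifetimes_ns[2], stage2.lifetimes_ns[3]
        short4 = fit_global(
            short_decays,
            irf_short,
            n_exp=4,
            fixed_lifetimes=[(2, tau3), (3, tau4)],
            init_lifetimes_ns=np.array([tau1, tau2, tau3, tau4]),
        )
        tau1, tau2 = short4.lifetimes_ns[0], short4.lifetimes_ns[1]
        stage2 = fit_global(
            long_decays,
            irf_long,
            n_exp=4,
            fixed_lifetimes=[(0, tau1), (1, tau2)],
            init_lifetimes_ns=np.array([tau1, tau2, tau3, tau4]),
        )
    return stage2


def mean_lifetime(result: GlobalFitResult, wavelength: float) -> MeanLifetime:
    """Amplitude-weighted mean lifetime at one emission wavelength (ns)."""
    if wavelength not in result.amplitudes:
        raise KeyError(f"no amplitudes fitted at {wavelength} nm")
    alpha = result.amplitudes[wavelength]
    if abs(float(alpha.sum()) - 1.0) > 1e-6:
        raise ValueError("amplitudes are not normalized")
    value = float(alpha @ result.lifetimes_ns)
    return MeanLifetime(value=value, wavelength=wavelength)
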