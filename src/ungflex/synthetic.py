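"""Ground-truth-labelled synthetic inputs for every analysis stage.

Each generator emulates one class of raw measurement with the study's
sampling design and returns the generated data together with the ground
truth that produced it, so every fitting and estimation routine in the
package can be validated by parameter recovery without any external data:

- :func:`gen_tcspc` — paired photon-counting decay sets (814 fs/channel and
  6.1 ps/channel windows, 2**12 channels, three emission wavelengths) with a
  Gaussian IRF (default FWHM 40 ps) and Poisson counting noise;
- :func:`gen_exchange` — imino-peak recovery areas on a 24-point log-spaced
  delay grid (1 ms - 15 s) with additive Gaussian noise;
- :func:`gen_kinetic_trace` — continuous fluorescence progress traces per
  substrate concentration, with product formation from numerically
  integrated Michaelis-Menten kinetics (E0 default 0.16 nM, substrate
  concentrations spanning 0.075-6 uM);
- :func:`gen_steps` — per-frame base-step parameter tables with Gaussian
  fluctuations and optional AR(1) frame-to-frame correlation;
- :func:`gen_flips` — two-state (intra/extra-helical) Markov-chain flipping
  series with state-conditional distance/angle emissions straddling the
  4.5 A / 40 deg classification thresholds.

All randomness flows from one seeded generator per SimSpec, with sub-streams
keyed by stage name: identical specs reproduce identical bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp

from .exchange import ExchangeSeries, exchange_model, default_delay_grid
from .geometry import FlipSeries, StepParamSeries
from .kinetics import DEFAULT_E0_M, KineticTrace
from .tcspc import (
    IRF,
    LONG_CHANNEL_WIDTH_S,
    N_CHANNELS,
    SHORT_CHANNEL_WIDTH_S,
    EMISSION_WAVELENGTHS_NM,
    DecayCurve,
    reconvolve,
)

__all__ = [
    "SimSpec",
    "TcspcSim",
    "ExchangeSim",
    "KineticSim",
    "StepsSim",
    "FlipsSim",
    "gen_tcspc",
    "gen_exchange",
    "gen_kinetic_trace",
    "gen_steps",
    "gen_flips",
    "gaussian_irf",
]

_STAGES = ("tcspc", "exchange", "kinetics", "steps", "flips", "photophys")


@dataclass(frozen=True)
class SimSpec:
    """Seeded, stage-tagged simulation request.

    ``parameters`` carries the stage-specific ground truth; ``noise`` the
    stage-specific noise record. Missing entries fall back to the study
    defaults documented in each generator. Identical specs (including seed)
    reproduce byte-identical output.
    """

    seed: int
    stage: str
    parameters: dict[str, Any] = field(default_factory=dict)
    noise: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")

    def rng(self) -> np.random.Generator:
        """Sub-stream keyed by (seed, stage), independent across stages."""
        return np.random.default_rng([self.seed, _STAGES.index(self.stage)])


# ---------------------------------------------------------------------------
# TCSPC
# ---------------------------------------------------------------------------

#: Default ground-truth lifetimes spanning the ~30 ps - 8 ns range (ns).
DEFAULT_LIFETIMES_NS: tuple[float, ...] = (0.03, 0.4, 1.5, 8.0)
#: Default per-wavelength amplitude sets (rows sum to 1).
DEFAULT_AMPLITUDES: dict[int, tuple[float, ...]] = {
    380: (0.45, 0.30, 0.15, 0.10),
    390: (0.40, 0.30, 0.20, 0.10),
    400: (0.35, 0.30, 0.22, 0.13),
}
#: Default peak count level of a decay histogram (counts in the peak channel).
DEFAULT_PEAK_COUNTS: float = 1e4
DEFAULT_IRF_FWHM_S: float = 40e-12
#: IRF center as a fraction of the acquisition window.
_IRF_POSITION_FRACTION: float = 0.06


@dataclass(frozen=True)
class TcspcSim:
    """Paired two-window decay sets with the ground truth attached."""

    short_decays: list[DecayCurve]
    long_decays: list[DecayCurve]
    irf_short: IRF
    irf_long: IRF
    truth: dict[str, Any]


def gaussian_irf(
    channel_width: float,
    n_channels: int,
    fwhm: float = DEFAULT_IRF_FWHM_S,
    center: float | None = None,
    total_counts: float = 1e6,
) -> IRF:
    """Gaussian instrument response on a decay grid (area = total_counts)."""
    if center is None:
        center = _IRF_POSITION_FRACTION * channel_width * n_channels
    t = np.arange(n_channels) * channel_width
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    profile = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    if profile.sum() == 0.0:  # delta limit: all mass in the nearest channel
        profile = np.zeros(n_channels)
        profile[int(round(center / channel_width))] = 1.0
    return IRF(channel_width=channel_width, counts=total_counts * profile / profile.sum(), fwhm=fwhm)


def gen_tcspc(spec: SimSpec) -> TcspcSim:
    """Two-window, three-wavelength decay sets with Poisson counting noise.

    Ground truth: four strictly increasing lifetimes (default 0.03, 0.4,
    1.5, 8 ns), per-wavelength amplitudes summing to 1, and a peak count
    level. Counts are Poisson draws around the discrete convolution of the
    multi-exponential with a Gaussian IRF (default FWHM 40 ps) on each
    window's grid (defaults 814 fs/channel and 6.1 ps/channel, 4096
    channels each). Set noise={'poisson': False} for noise-free histograms.
    """
    if spec.stage != "tcspc":
        raise ValueError(f"spec stage is {spec.stage!r}, expected 'tcspc'")
    p = spec.parameters
    taus_ns = np.asarray(p.get("lifetimes_ns", DEFAULT_LIFETIMES_NS), dtype=float)
    if np.any(np.diff(taus_ns) <= 0) or np.any(taus_ns <= 0):
        raise ValueError("lifetimes must be positive and strictly increasing")
    amplitudes = {
        float(wl): np.asarray(a, dtype=float)
        for wl, a in p.get("amplitudes", DEFAULT_AMPLITUDES).items()
    }
    for wl, a in amplitudes.items():
        if a.size != taus_ns.size:
            raise ValueError(f"amplitude set at {wl} nm does not match lifetime count")
        if abs(float(a.sum()) - 1.0) > 1e-9:
            raise ValueError(f"amplitudes at {wl} nm must sum to 1")
    peak = float(p.get("peak_counts", DEFAULT_PEAK_COUNTS))
    fwhm = float(p.get("irf_fwhm_s", DEFAULT_IRF_FWHM_S))
    n_channels = int(p.get("n_channels", N_CHANNELS))
    widths = {
        "short": float(p.get("short_channel_width_s", SHORT_CHANNEL_WIDTH_S)),
        "long": float(p.get("long_channel_width_s", LONG_CHANNEL_WIDTH_S)),
    }
    poisson = bool(spec.noise.get("poisson", True))
    rng = spec.rng()

    irfs: dict[str, IRF] = {}
    decays: dict[str, list[DecayCurve]] = {"short": [], "long": []}
    for window, dt in widths.items():
        irf = gaussian_irf(dt, n_channels, fwhm=fwhm)
        irfs[window] = irf
        for wl in sorted(amplitudes):
            model = reconvolve(irf, taus_ns * 1e-9, amplitudes[wl], scale=1.0)
            model = np.clip(model, 0.0, None)  # FFT round-off can dip below zero
            model *= peak / model.max()
            counts = rng.poisson(model).astype(float) if poisson else model
            decays[window].append(
                DecayCurve(channel_width=dt, counts=counts, wavelength=wl, window_id=window)
            )

    truth = {
        "lifetimes_ns": taus_ns,
        "amplitudes": amplitudes,
        "peak_counts": peak,
        "irf_fwhm_s": fwhm,
        "mean_tau_ns": {
            wl: float(a @ taus_ns) for wl, a in amplitudes.items()
        },
    }
    return TcspcSim(
        short_decays=decays["short"],
        long_decays=decays["long"],
        irf_short=irfs["short"],
        irf_long=irfs["long"],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Imino exchange
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeSim:
    series: ExchangeSeries
    truth: dict[str, float]


def gen_exchange(spec: SimSpec) -> ExchangeSim:
    """Water magnetization-transfer recovery series with Gaussian area noise.

    Ground truth (k_ex, R1n, R1w, E, A0) must satisfy R1n > R1w and
    k_ex <= R1n. Defaults: k_ex 10.24 s^-1, R1w 0.3 s^-1, E 0.95, A0 1.0,
    on a 24-point log-spaced 1 ms - 15 s delay grid; noise SD is a fraction
    of A0 (default 0.01). R1n is the sum of the intrinsic imino relaxation
    rate and k_ex, so its default tracks k_ex: R1n = k_ex + 1.76 s^-1
    (giving 12.0 s^-1 at the default k_ex).
    """
    if spec.stage != "exchange":
        raise ValueError(f"spec stage is {spec.stage!r}, expected 'exchange'")
    p = spec.parameters
    k_ex = float(p.get("k_ex", 10.24))
    r1n = float(p.get("r1n", k_ex + 1.76))
    r1w = float(p.get("r1w", 0.3))
    eff = float(p.get("efficiency", 0.95))
    a0 = float(p.get("a0", 1.0))
    if min(k_ex, r1n, r1w) < 0:
        raise ValueError("rates must be non-negative")
    if r1n <= r1w:
        raise ValueError("model degenerate: R1n must exceed R1w")
    if k_ex > r1n:
        raise ValueError("k_ex cannot exceed R1n (R1n includes the exchange rate)")
    delays = np.asarray(p.get("delays", default_delay_grid()), dtype=float)
    noise_sd = float(spec.noise.get("area_sd_frac", 0.01)) * a0
    rng = spec.rng()

    clean = a0 * exchange_model(delays, k_ex, r1n, r1w, eff)
    areas = clean + rng.normal(0.0, noise_sd, size=delays.size) if noise_sd > 0 else clean
    series = ExchangeSeries(
        delays=delays, areas=areas, a0=a0, efficiency=eff, r1w=r1w,
        residue=str(p.get("residue", "U6")),
    )
    truth = {"k_ex": k_ex, "r1n": r1n, "r1w": r1w, "efficiency": eff, "a0": a0,
             "noise_sd": noise_sd}
    return ExchangeSim(series=series, truth=truth)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

#: Default substrate concentrations spanning the assayed range (M).
DEFAULT_S0_LIST_M: tuple[float, ...] = (
    0.075e-6, 0.15e-6, 0.3e-6, 0.75e-6, 1.5e-6, 3e-6, 6e-6
)


@dataclass(frozen=True)
class KineticSim:
    traces: list[KineticTrace]
    truth: dict[str, Any]


def _progress_curve(s0: float, vmax: float, km: float, t_end: float, n_points: int):
    """Product concentration [P](t) from d[P]/dt = Vmax (S0-P)/(KM + S0-P)."""
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda _t, p: [vmax * (s0 - p[0]) / (km + s0 - p[0])],
        (0.0, t_end), [0.0], t_eval=t_eval, method="LSODA",
        rtol=1e-9, atol=1e-12 * s0,
    )
    return t_eval, np.clip(sol.y[0], 0.0, s0)


def _completion_time(s0: float, vmax: float, km: float, fraction: float = 0.99) -> float:
    """Time to reach a completion fraction, from the integrated rate law
    Vmax t = P + KM ln(S0/(S0-P))."""
    p = fraction * s0
    return (p + km * math.log(s0 / (s0 - p))) / vmax


def gen_kinetic_trace(spec: SimSpec) -> KineticSim:
    """Continuous fluorescence progress traces, one per substrate concentration.

    Ground truth: K_M (default 1 uM), k_cat (default 5 s^-1), E0 (default
    0.16 nM), substrate list spanning 0.075-6 uM, fluorescence change dF
    (default 100) and baseline (default 10). Product concentration comes
    from numerically integrated Michaelis-Menten progress (not the linear
    regime), F(t) = baseline + dF*[P](t)/S0, plus Gaussian noise with SD a
    fraction of dF (default 0.005). The stored truth includes the exact
    initial velocity V0 = Vmax*S0/(KM+S0) per trace.
    """
    if spec.stage != "kinetics":
        raise ValueError(f"spec stage is {spec.stage!r}, expected 'kinetics'")
    p = spec.parameters
    km = float(p.get("km", 1e-6))
    kcat = float(p.get("kcat", 5.0))
    e0 = float(p.get("e0", DEFAULT_E0_M))
    if min(km, kcat, e0) <= 0:
        raise ValueError("K_M, k_cat and E0 must be positive")
    s0_list = np.asarray(p.get("s0_list", DEFAULT_S0_LIST_M), dtype=float)
    if np.any(s0_list <= 0):
        raise ValueError("substrate concentrations must be positive")
    delta_f = float(p.get("delta_f", 100.0))
    baseline = float(p.get("baseline", 10.0))
    # a continuous fluorimeter trace sampled at ~0.5-1 s intervals over the
    # hour-scale runs here yields thousands of points
    n_points = int(p.get("n_points", 4000))
    completion = float(p.get("completion", 0.99))
    noise_sd = float(spec.noise.get("sd_frac_delta_f", 0.005)) * delta_f
    rng = spec.rng()

    vmax = kcat * e0
    traces, v0_true = [], {}
    for s0 in s0_list:
        t_end = float(p.get("t_end", _completion_time(s0, vmax, km, completion)))
        t, prod = _progress_curve(s0, vmax, km, t_end, n_points)
        f = baseline + delta_f * prod / s0
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=f.size)
        traces.append(KineticTrace(time=t, intensity=f, substrate_conc=s0, enzyme_conc=e0))
        v0_true[float(s0)] = vmax * s0 / (km + s0)
    truth = {
        "km": km, "kcat": kcat, "e0": e0, "vmax": vmax, "delta_f": delta_f,
        "baseline": baseline, "noise_sd": noise_sd, "v0": v0_true,
    }
    return KineticSim(traces=traces, truth=truth)


# ---------------------------------------------------------------------------
# Base-step parameters
# ---------------------------------------------------------------------------

#: B-DNA-like default means and fluctuation SDs for the six step parameters
#: (shift, slide, rise in A; tilt, roll, twist in deg).
DEFAULT_STEP_MEANS: tuple[float, ...] = (0.0, 0.0, 3.32, 0.0, 0.0, 34.3)
DEFAULT_STEP_SDS: tuple[float, ...] = (0.5, 0.5, 0.25, 3.0, 5.0, 4.0)


@dataclass(frozen=True)
class StepsSim:
    steps: StepParamSeries
    truth: dict[str, Any]


def gen_steps(spec: SimSpec) -> StepsSim:
    """Gaussian per-frame base-step parameter tables, optionally AR(1).

    Ground truth: per-step means and SDs for all six parameters (defaults:
    twist 34.3 deg, rise 3.32 A, zero translations/rotations otherwise, with
    B-DNA-like SDs), frame count, and an optional AR(1) frame-to-frame
    correlation rho (0 = independent frames). For independent frames the
    torsional ground truth is Var(Omega) = sum of included twist variances;
    the stored truth records that figure for the winding-sum exclusion mask.
    """
    if spec.stage != "steps":
        raise ValueError(f"spec stage is {spec.stage!r}, expected 'steps'")
    p = spec.parameters
    n_steps = int(p.get("n_steps", 14))
    n_frames = int(p.get("n_frames", 5000))
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    uracil_step = p.get("uracil_step", 6)
    rho = float(p.get("rho", 0.0))
    if not -1.0 < rho < 1.0:
        raise ValueError("AR(1) coefficient must be in (-1, 1)")

    means = np.broadcast_to(
        np.asarray(p.get("means", DEFAULT_STEP_MEANS), dtype=float), (n_steps, 6)
    ).copy()
    sds = np.broadcast_to(
        np.asarray(p.get("sds", DEFAULT_STEP_SDS), dtype=float), (n_steps, 6)
    ).copy()
    if np.any(sds < 0):
        raise ValueError("fluctuation SDs must be non-negative")
    rng = spec.rng()

    z = rng.standard_normal((n_frames, n_steps, 6))
    if rho != 0.0:
        # stationary AR(1) with unit marginal variance
        for f in range(1, n_frames):
            z[f] = rho * z[f - 1] + math.sqrt(1.0 - rho**2) * z[f]
    params = means[None] + sds[None] * z

    series = StepParamSeries(
        params=params,
        step_labels=tuple(f"S{i}/S{i+1}" for i in range(n_steps)),
        uracil_step=uracil_step,
    )
    inc = series.winding_steps()
    var_omega = float(np.sum(np.deg2rad(sds[inc, 5]) ** 2))
    truth = {
        "means": means, "sds": sds, "rho": rho, "n_frames": n_frames,
        "uracil_step": uracil_step,
        "var_omega_rad2": var_omega,
        "statistical_inefficiency": (1.0 + rho) / (1.0 - rho),
        "contour_a": float(means[series.interior_steps(), 2].sum()),
    }
    return StepsSim(steps=series, truth=truth)


# ---------------------------------------------------------------------------
# Flipping series
# ---------------------------------------------------------------------------

#: State-conditional emission defaults straddling the 4.5 A / 40 deg rule:
#: intra-helical frames sit well inside both thresholds, extra-helical ones
#: well outside (major-groove, hence negative angles).
DEFAULT_INTRA_EMISSION = {"dist_mean": 2.9, "dist_sd": 0.2, "angle_mean": 10.0, "angle_sd": 8.0}
DEFAULT_EXTRA_EMISSION = {"dist_mean": 8.0, "dist_sd": 1.5, "angle_mean": -90.0, "angle_sd": 25.0}


@dataclass(frozen=True)
class FlipsSim:
    flips: FlipSeries
    states: np.ndarray  # True = intra-helical
    truth: dict[str, Any]


def gen_flips(spec: SimSpec) -> FlipsSim:
    """Two-state Markov-chain flipping series with state-conditional emissions.

    Ground truth: stationary intra-helical fraction (default 0.57) and mean
    intra-state dwell time in frames (default 50), from which the two
    switching probabilities follow. Intra frames emit distance ~ N(2.9, 0.2)
    A and angle ~ N(10, 8) deg; extra frames N(8, 1.5) A and N(-90, 25) deg
    (all configurable). The chain starts from its stationary distribution,
    so the empirical intra fraction converges to the stationary value.
    """
    if spec.stage != "flips":
        raise ValueError(f"spec stage is {spec.stage!r}, expected 'flips'")
    p = spec.parameters
    f_intra = float(p.get("intra_fraction", 0.57))
    if not 0.0 <= f_intra <= 1.0:
        raise ValueError("stationary intra fraction must be in [0, 1]")
    dwell = float(p.get("dwell_frames", 50.0))
    n_frames = int(p.get("n_frames", 20000))
    intra_em = {**DEFAULT_INTRA_EMISSION, **p.get("intra_emission", {})}
    extra_em = {**DEFAULT_EXTRA_EMISSION, **p.get("extra_emission", {})}
    rng = spec.rng()

    # transition probabilities from dwell time and stationarity
    if f_intra in (0.0, 1.0):
        states = np.full(n_frames, bool(f_intra))
        p_out_intra = p_out_extra = 0.0
    else:
        p_out_intra = min(1.0 / dwell, 1.0)
        p_out_extra = min(p_out_intra * f_intra / (1.0 - f_intra), 1.0)
        states = np.empty(n_frames, dtype=bool)
        states[0] = rng.random() < f_intra
        u = rng.random(n_frames - 1)
        for i in range(1, n_frames):
            leave = p_out_intra if states[i - 1] else p_out_extra
            states[i] = states[i - 1] ^ (u[i - 1] < leave)

    def emit(em, n):
        d = rng.normal(em["dist_mean"], em["dist_sd"], n)
        a = rng.normal(em["angle_mean"], em["angle_sd"], n)
        return np.clip(d, 0.5, None), np.clip(a, -180.0, 180.0)

    dist = np.empty(n_frames)
    angle = np.empty(n_frames)
    n_intra = int(states.sum())
    dist[states], angle[states] = emit(intra_em, n_intra)
    dist[~states], angle[~states] = emit(extra_em, n_frames - n_intra)

    truth = {
        "intra_fraction": f_intra,
        "dwell_frames": dwell,
        "p_out_intra": p_out_intra,
        "p_out_extra": p_out_extra,
        "empirical_intra": float(states.mean()),
        "intra_emission": intra_em,
        "extra_emission": extra_em,
    }
    return FlipsSim(flips=FlipSeries(dist, angle), states=states, truth=truth)
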