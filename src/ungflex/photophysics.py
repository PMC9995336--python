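"""Relative quantum yields and the dark stacked fraction of 2-aminopurine.

2-aminopurine (2AP) placed opposite uracil reports on local base stacking:
probes stacked so strongly that their lifetime falls below the instrument
resolution of a photon-counting experiment (~40 ps) emit too fast to appear
in the fitted decay. Their fractional population ``alpha0`` is recovered by
comparing the steady-state quantum yield (which counts every emitted photon)
with the mean lifetime of the *detected* decay components:

    alpha0 = 1 - (tau_2AP / <tau>) * (phi / phi_2AP)

with the free-riboside reference values ``phi_2AP = 0.68`` and
``tau_2AP = 10.2 ns``. A larger ``alpha0`` means a larger dark, highly
stacked population and hence a stiffer duplex around the lesion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PHI_2AP",
    "TAU_2AP_NS",
    "QYObservation",
    "Alpha0Result",
    "relative_qy",
    "alpha0",
    "alpha0_error",
    "ci_halfwidth",
]

#: Fluorescence quantum yield of free 2AP riboside in water (reference).
PHI_2AP: float = 0.68
#: Fluorescence lifetime of free 2AP riboside in water, nanoseconds.
TAU_2AP_NS: float = 10.2

#: Default relative precision of a mean-lifetime determination (2.5%).
DEFAULT_TAU_PRECISION: float = 0.025

#: Absorbance above which inner-filter effects become a concern.
ABSORBANCE_WARN_LEVEL: float = 0.05


@dataclass(frozen=True)
class QYObservation:
    """One steady-state measurement for a relative quantum-yield ratio.

    Parameters
    ----------
    intensity:
        Integrated emission intensity over the full fluorescence band
        (arbitrary units, blank-subtracted).
    absorbance:
        Absorbance at the excitation wavelength (315 nm). Kept below 0.05
        in practice to avoid inner-filter effects.
    """

    intensity: float
    absorbance: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"integrated intensity must be >= 0, got {self.intensity}")
        if self.absorbance <= 0:
            raise ValueError(f"absorbance must be > 0, got {self.absorbance}")
        if self.absorbance > ABSORBANCE_WARN_LEVEL:
            import warnings

            warnings.warn(
                f"absorbance {self.absorbance} exceeds {ABSORBANCE_WARN_LEVEL}; "
                "inner-filter effects may bias the quantum yield",
                stacklevel=3,
            )


@dataclass(frozen=True)
class Alpha0Result:
    """Dark stacked fraction with propagated uncertainty and its inputs."""

    value: float
    error: float
    mean_tau_ns: float
    dtau_ns: float
    phi: float
    dphi: float
    phi_ref: float = PHI_2AP
    tau_ref_ns: float = TAU_2AP_NS
    #: True when value falls outside [0, 1]: the lifetime/quantum-yield pair
    #: is physically inconsistent and should be inspected, not clipped.
    unphysical: bool = field(default=False)


def relative_qy(sample: QYObservation, reference: QYObservation, phi_ref: float = PHI_2AP) -> float:
    """Quantum yield of a sample relative to a reference fluorophore.

    phi_S = phi_R * (I_S / I_R) * (1 - 10**-A_R) / (1 - 10**-A_S)

    The absorbance factors convert absorbances to fractions of absorbed
    light; for optically thin samples they reduce to the A_R/A_S ratio.
    """
    if reference.intensity == 0:
        raise ZeroDivisionError("reference intensity is zero")
    absorbed_ref = 1.0 - 10.0 ** (-reference.absorbance)
    absorbed_sample = 1.0 - 10.0 ** (-sample.absorbance)
    if absorbed_sample == 0:
        raise ZeroDivisionError("sample absorbs no light (absorbance factor is zero)")
    return phi_ref * (sample.intensity / reference.intensity) * absorbed_ref / absorbed_sample


def alpha0(
    mean_tau_ns: float,
    phi: float,
    *,
    phi_ref: float = PHI_2AP,
    tau_ref_ns: float = TAU_2AP_NS,
) -> Alpha0Result:
    """Dark (highly stacked) 2AP fraction from mean lifetime and quantum yield.

    The detected decay accounts for a quantum yield of
    ``phi_ref * <tau>/tau_ref``; any shortfall of the measured ``phi``
    against that prediction is attributed to the sub-resolution population.
    Values outside [0, 1] are returned flagged ``unphysical`` rather than
    clipped, preserving their diagnostic value.
    """
    if mean_tau_ns <= 0:
        raise ValueError(f"mean lifetime must be > 0, got {mean_tau_ns}")
    if phi <= 0:
        raise ValueError(f"quantum yield must be > 0, got {phi}")
    value = 1.0 - (tau_ref_ns / mean_tau_ns) * (phi / phi_ref)
    return Alpha0Result(
        value=value,
        error=0.0,
        mean_tau_ns=mean_tau_ns,
        dtau_ns=0.0,
        phi=phi,
        dphi=0.0,
        phi_ref=phi_ref,
        tau_ref_ns=tau_ref_ns,
        unphysical=not (0.0 <= value <= 1.0),
    )


def alpha0_error(
    phi: float,
    dphi: float,
    mean_tau_ns: float,
    dtau_ns: float | None = None,
    *,
    phi_ref: float = PHI_2AP,
    tau_ref_ns: float = TAU_2AP_NS,
) -> float:
    """First-order propagated uncertainty of the dark fraction.

    Quadrature sum of the quantum-yield and mean-lifetime terms:

        d_alpha0 = sqrt[ (tau_ref/phi_ref * dphi / <tau>)**2
                       + (tau_ref/phi_ref * phi * dtau / <tau>**2)**2 ]

    When ``dtau_ns`` is not supplied, the pooled 2.5% relative precision of
    mean-lifetime determinations is used.
    """
    if phi <= 0 or mean_tau_ns <= 0:
        raise ValueError("phi and mean_tau_ns must be > 0")
    if dphi < 0:
        raise ValueError("dphi must be >= 0")
    if dtau_ns is None:
        dtau_ns = DEFAULT_TAU_PRECISION * mean_tau_ns
    if dtau_ns < 0:
        raise ValueError("dtau_ns must be >= 0")
    k = tau_ref_ns / phi_ref
    term_phi = k * dphi / mean_tau_ns
    term_tau = k * phi * dtau_ns / mean_tau_ns**2
    return math.hypot(term_phi, term_tau)


def alpha0_with_error(
    mean_tau_ns: float,
    phi: float,
    dphi: float,
    dtau_ns: float | None = None,
    *,
    phi_ref: float = PHI_2AP,
    tau_ref_ns: float = TAU_2AP_NS,
) -> Alpha0Result:
    """Convenience wrapper combining :func:`alpha0` and :func:`alpha0_error`."""
    base = alpha0(mean_tau_ns, phi, phi_ref=phi_ref, tau_ref_ns=tau_ref_ns)
    if dtau_ns is None:
        dtau_ns = DEFAULT_TAU_PRECISION * mean_tau_ns
    err = alpha0_error(
        phi, dphi, mean_tau_ns, dtau_ns, phi_ref=phi_ref, tau_ref_ns=tau_ref_ns
    )
    return Alpha0Result(
        value=base.value,
        error=err,
        mean_tau_ns=mean_tau_ns,
        dtau_ns=dtau_ns,
        phi=phi,
        dphi=dphi,
        phi_ref=phi_ref,
        tau_ref_ns=tau_ref_ns,
        unphysical=base.unphysical,
    )


def ci_halfwidth(
    values: "np.ndarray | list[float] | None" = None,
    *,
    n: int | None = None,
    sd: float | None = None,
    level: float = 0.95,
) -> float:
    """Half-width of the Student-t confidence interval of a sample mean.

    Either pass the replicate ``values`` directly, or the summary pair
    ``(n, sd)``. Returns ``t_{1-(1-level)/2, n-1} * sd / sqrt(n)``.
    """
    if values is not None:
        arr = np.asarray(values, dtype=float)
        n = arr.size
        sd = float(np.std(arr, ddof=1)) if n >= 2 else 0.0
    if n is None or sd is None:
        raise ValueError("provide either replicate values or both n and sd")
    if n < 2:
        raise ValueError(f"need at least 2 replicates, got n={n}")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    t = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df=n - 1)
    return float(t * sd / math.sqrt(n))
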