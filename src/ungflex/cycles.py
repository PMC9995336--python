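"""Double-mutant thermodynamic cycles for the bases flanking uracil.

Rate-like quantities (imino-proton exchange rates, or enzymatic specificity
constants k_cat/K_M) are converted to transition-state free-energy
differences,

    ddG(1 -> 2) = -R*T*ln(k2 / k1)        [kJ/mol],

and arranged on a thermodynamic square whose corners are the four flanking
motifs XY in {AT, AA, TT, TA} (X = base 5' of uracil, Y = base 3'). The
coupling free energy between the two flanking positions,

    dG_coup = ddG(AT->TT) - ddG(AA->TA) = ddG(AT->AA) - ddG(TT->TA)
            = R*T*ln[(k_AT * k_TA) / (k_TT * k_AA)],

is zero when the 5' and 3' substitutions act independently (multiplicative
rates) and nonzero when the flanking base pairs are allosterically coupled.
Both routes around the square are computed; their agreement is an algebraic
identity and is reported as a residual (machine precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GAS_CONSTANT_KJ", "MOTIFS", "RateQuad", "CycleResult", "ddg", "coupling", "cycle_consistency"]

#: Gas constant in kJ/(mol*K).
GAS_CONSTANT_KJ: float = 8.314e-3

#: Flanking-motif labels: first letter 5' of uracil, second letter 3'.
MOTIFS: tuple[str, ...] = ("AT", "AA", "TT", "TA")


@dataclass(frozen=True)
class RateQuad:
    """Four rate-like quantities indexed by flanking motif, with uncertainties.

    ``rate_kind`` distinguishes imino exchange rates ('k_ex') from enzymatic
    specificity constants ('kcat_over_KM'); cycles may only be compared across
    quads of the same kind.
    """

    rates: dict[str, float]
    errors: dict[str, float] = field(default_factory=dict)
    rate_kind: str = "k_ex"
    temperature: float = 293.15
    label: str = ""

    def __post_init__(self) -> None:
        missing = [m for m in MOTIFS if m not in self.rates]
        if missing:
            raise ValueError(f"incomplete quad: missing motifs {missing}")
        for m in MOTIFS:
            if self.rates[m] <= 0:
                raise ValueError(f"rate for motif {m} must be > 0, got {self.rates[m]}")
            if self.errors.get(m, 0.0) < 0:
                raise ValueError(f"uncertainty for motif {m} must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    def error(self, motif: str) -> float:
        return self.errors.get(motif, 0.0)


@dataclass(frozen=True)
class CycleResult:
    """Coupling free energy and the four edge free-energy differences."""

    coupling_kj: float
    sigma_kj: float
    #: Edge ddG values (kJ/mol) keyed by 'XY->X'Y'' transition labels.
    edges_kj: dict[str, float]
    #: |route1 - route2| for the two ways around the square; an algebraic
    #: identity, so this is zero to machine precision.
    route_residual_kj: float
    temperature: float
    rate_kind: str


def ddg(k1: float, k2: float, temperature: float = 293.15) -> float:
    """Transition-state free-energy difference -RT ln(k2/k1) in kJ/mol.

    Negative when k2 > k1, i.e. the second sequence has the lower barrier.
    Invariant under common rescaling of both rates.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return -GAS_CONSTANT_KJ * temperature * math.log(k2 / k1)


def coupling(quad: RateQuad) -> CycleResult:
    """Coupling free energy of the double-mutant square, with quadrature error.

    sigma = R*T*sqrt(sum_i (sigma_ki / ki)^2) over the four rates (first-order
    propagation of ln k). Rates with no stated uncertainty contribute zero.
    """
    t = quad.temperature
    k = quad.rates
    edges = {
        "AT->TT": ddg(k["AT"], k["TT"], t),
        "AA->TA": ddg(k["AA"], k["TA"], t),
        "AT->AA": ddg(k["AT"], k["AA"], t),
        "TT->TA": ddg(k["TT"], k["TA"], t),
    }
    route1 = edges["AT->TT"] - edges["AA->TA"]
    route2 = edges["AT->AA"] - edges["TT->TA"]
    value = GAS_CONSTANT_KJ * t * math.log(k["AT"] * k["TA"] / (k["TT"] * k["AA"]))
    rel_sq = sum((quad.error(m) / k[m]) ** 2 for m in MOTIFS)
    sigma = GAS_CONSTANT_KJ * t * math.sqrt(rel_sq)
    return CycleResult(
        coupling_kj=value,
        sigma_kj=sigma,
        edges_kj=edges,
        route_residual_kj=abs(route1 - route2),
        temperature=t,
        rate_kind=quad.rate_kind,
    )


def cycle_consistency(quad_a: RateQuad, quad_b: RateQuad) -> "pd.DataFrame":
    """Cross-series free-energy differences between two backgrounds.

    For two quads sharing rate kind and temperature but differing in the
    surrounding sequence, reports ddG(b_XY -> a_XY) per motif with propagated
    error, plus whether each agrees with the per-motif mean within one
    propagated sigma — additive background effects give identical values for
    every motif (and identical couplings for the two series).
    """
    import pandas as pd

    if quad_a.rate_kind != quad_b.rate_kind:
        raise ValueError(
            f"rate kinds differ: {quad_a.rate_kind!r} vs {quad_b.rate_kind!r}"
        )
    if quad_a.temperature != quad_b.temperature:
        raise ValueError("temperatures differ between quads")
    t = quad_a.temperature
    rows = []
    for m in MOTIFS:
        value = ddg(quad_b.rates[m], quad_a.rates[m], t)
        rel = math.hypot(
            quad_a.error(m) / quad_a.rates[m], quad_b.error(m) / quad_b.rates[m]
        )
        rows.append({"motif": m, "ddg_kj": value, "sigma_kj": GAS_CONSTANT_KJ * t * rel})
    df = pd.DataFrame(rows)
    mean = df["ddg_kj"].mean()
    df["consistent"] = np.abs(df["ddg_kj"] - mean) <= np.maximum(df["sigma_kj"], 1e-12)
    return df
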