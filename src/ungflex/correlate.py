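"""Cross-technique correlation tables for per-substrate observables.

Collects one record per DNA substrate — enzymatic specificity constant
k_cat/K_M, dark stacked fraction alpha0, imino exchange rate k_ex, and the
MD flexibility metrics (BPL, TPL, SD of bending and flipping angles, percent
intra-helical) — and computes the pairwise Pearson correlations and
ordinary-least-squares regression lines used to relate UNG efficiency to
substrate flexibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SubstrateRecord", "CorrelationResult", "pearson", "figure_tables", "PANELS"]


@dataclass(frozen=True)
class SubstrateRecord:
    """All measured observables for one substrate (missing ones are NaN)."""

    substrate: str
    motif: str
    kcat_over_km: float = math.nan
    kcat_over_km_err: float = math.nan
    alpha0: float = math.nan
    alpha0_err: float = math.nan
    k_ex: float = math.nan
    k_ex_err: float = math.nan
    bpl_a: float = math.nan
    tpl_a: float = math.nan
    sd_bend_deg: float = math.nan
    sd_flip_deg: float = math.nan
    pct_intra: float = math.nan

    def __post_init__(self) -> None:
        if len(self.substrate) >= 3 and self.substrate[-2:].isalpha():
            if self.motif and self.substrate[-2:].upper() != self.motif.upper():
                raise ValueError(
                    f"motif {self.motif!r} inconsistent with id {self.substrate!r}"
                )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its OLS line for one variable pair."""

    x_var: str
    y_var: str
    r: float
    slope: float
    intercept: float
    n: int
    p_value: float
    excluded: tuple[str, ...] = field(default_factory=tuple)


def pearson(x: np.ndarray, y: np.ndarray, x_var: str = "x", y_var: str = "y") -> CorrelationResult:
    """Sample Pearson correlation coefficient with OLS slope/intercept.

    The two-sided p-value uses the exact t-transform of r with n - 2 degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        x_var=x_var, y_var=y_var, r=float(r), slope=float(slope),
        intercept=float(intercept), n=int(x.size), p_value=float(p),
    )


#: Variable pairs of the standard correlation panels (x, y).
PANELS: tuple[tuple[str, str], ...] = (
    ("alpha0", "kcat_over_km"),
    ("k_ex", "kcat_over_km"),
    ("alpha0", "bpl_a"),
    ("alpha0", "tpl_a"),
    ("alpha0", "sd_bend_deg"),
    ("bpl_a", "sd_flip_deg"),
    ("tpl_a", "sd_flip_deg"),
    ("sd_bend_deg", "sd_flip_deg"),
    ("alpha0", "sd_flip_deg"),
    ("k_ex", "sd_flip_deg"),
)


def figure_tables(
    records: "list[SubstrateRecord]",
    panels: tuple[tuple[str, str], ...] = PANELS,
    leave_out: "str | None" = None,
) -> pd.DataFrame:
    """Correlation results for every populated variable pair.

    Each panel uses the records where both variables are finite; panels with
    fewer than 3 such records are skipped (with a notice column would be
    overkill — they are simply absent from the output). ``leave_out``
    recomputes every panel excluding the named substrate, appending rows
    flagged by the ``excluded`` column; the result is independent of record
    order.
    """
    df = pd.DataFrame([asdict(r) for r in records]).sort_values("substrate")
    rows = []
    exclusion_sets: list[list[str]] = [[]]
    if leave_out:
        exclusion_sets.append([leave_out])
    for x_var, y_var in panels:
        for excl in exclusion_sets:
            sub = df[~df["substrate"].isin(excl)]
            mask = np.isfinite(sub[x_var]) & np.isfinite(sub[y_var])
            if mask.sum() < 3:
                continue
            res = pearson(
                sub.loc[mask, x_var].to_numpy(),
                sub.loc[mask, y_var].to_numpy(),
                x_var,
                y_var,
            )
            rows.append(
                {
                    "x": x_var,
                    "y": y_var,
                    "r": res.r,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "n": res.n,
                    "p_value": res.p_value,
                    "excluded": ",".join(excl),
                }
            )
    return pd.DataFrame(rows)
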