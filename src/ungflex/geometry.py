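"""DNA flexibility observables from base-pair step parameters and coordinates.

Consumes per-frame base-step parameter tables (3DNA convention: shift,
slide, rise in angstroms; tilt, roll, twist in degrees per step) and,
optionally, flipping coordinates, and computes:

- global bending angle per frame by the MADBEND construction: each step's
  (tilt, roll) deflection is rotated in-plane by the cumulative helical
  twist of the preceding included steps, and the bending angle is the norm
  of the vector sum — deflections in phase with the helical screw add,
  out-of-phase deflections cancel;
- contour length L as the sum of the helical rise over included steps;
- bending persistence length BPL = -L * d ln P(phi) / d(1 - cos phi), from
  an ordinary least-squares line through the log histogram of bending
  angles against (1 - cos phi);
- total winding angle Omega (sum of included twists) and torsional
  persistence length TPL = L / Var(Omega) with the variance in radians^2;
- the base-flipping pseudo-dihedral angle and the flipped-state rule
  (hydrogen-bond distance > 4.5 A AND |flip angle| > 40 deg), giving the
  percent of time the uracil is intra-helical;
- decorrelation subsampling via the statistical inefficiency
  g = 1 + 2 sum_t C(t), emulating the standard trajectory-thinning step.

Terminal base steps fray and are excluded from the bending and contour
analyses; the winding sum further excludes the steps flanking the uracil,
which decouples base flipping from the torsional statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FLIP_DISTANCE_CUTOFF_A",
    "FLIP_ANGLE_CUTOFF_DEG",
    "StepParamSeries",
    "FlipSeries",
    "FlexibilityMetrics",
    "madbend_angle",
    "madbend_series",
    "contour_length",
    "bend_persistence_length",
    "winding_angle",
    "torsional_persistence_length",
    "pseudo_dihedral",
    "classify_flipped",
    "decorrelate",
    "statistical_inefficiency",
    "flex_summary",
]

#: Flipped-state thresholds: hydrogen-bond distance and pseudo-dihedral.
FLIP_DISTANCE_CUTOFF_A: float = 4.5
FLIP_ANGLE_CUTOFF_DEG: float = 40.0

STEP_COLUMNS = ("shift", "slide", "rise", "tilt", "roll", "twist")


@dataclass(frozen=True)
class StepParamSeries:
    """Per-frame, per-step hexads of base-step parameters.

    ``params`` has shape (n_frames, n_steps, 6) ordered as
    (shift, slide, rise, tilt, roll, twist). ``uracil_step`` indexes the
    step 5' of the uracil (so steps ``uracil_step`` and ``uracil_step + 1``
    flank the lesion base pair).
    """

    params: np.ndarray
    step_labels: tuple[str, ...] = ()
    uracil_step: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        object.__setattr__(self, "params", p)
        if p.ndim != 3 or p.shape[2] != 6:
            raise ValueError("params must have shape (n_frames, n_steps, 6)")
        if p.shape[0] < 1:
            raise ValueError("need at least one frame")
        if np.any(p[:, :, 2] <= 0):
            raise ValueError("helical rise must be positive for every step")
        if self.step_labels and len(self.step_labels) != p.shape[1]:
            raise ValueError("step_labels length must match n_steps")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def n_steps(self) -> int:
        return self.params.shape[1]

    def column(self, name: str) -> np.ndarray:
        """(n_frames, n_steps) array of one step parameter."""
        return self.params[:, :, STEP_COLUMNS.index(name)]

    def interior_steps(self, n_terminal: int = 1) -> np.ndarray:
        """Step indices with ``n_terminal`` steps trimmed from each end."""
        return np.arange(n_terminal, self.n_steps - n_terminal)

    def winding_steps(self, n_terminal: int = 2) -> np.ndarray:
        """Included steps for the winding sum: trims ``n_terminal`` steps per
        end and the two steps flanking the uracil base pair."""
        idx = set(range(n_terminal, self.n_steps - n_terminal))
        if self.uracil_step is not None:
            idx -= {self.uracil_step, self.uracil_step + 1}
        return np.array(sorted(idx), dtype=int)

    @classmethod
    def from_long_frame(
        cls, df: pd.DataFrame, uracil_step: int | None = None
    ) -> "StepParamSeries":
        """Build from a long-format table (frame, step_label, six parameters)."""
        frames = np.sort(df["frame"].unique())
        labels = list(df[df["frame"] == frames[0]]["step_label"])
        wide = df.sort_values(["frame", "step"]) if "step" in df else df.sort_values("frame")
        n_f, n_s = frames.size, len(labels)
        arr = wide[list(STEP_COLUMNS)].to_numpy(dtype=float).reshape(n_f, n_s, 6)
        return cls(params=arr, step_labels=tuple(labels), uracil_step=uracil_step)


@dataclass(frozen=True)
class FlipSeries:
    """Per-frame uracil hydrogen-bond distance and flipping pseudo-dihedral.

    Negative angles correspond to major-groove flipping, positive to minor.
    """

    distance_a: np.ndarray
    angle_deg: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_a, dtype=float)
        a = np.asarray(self.angle_deg, dtype=float)
        object.__setattr__(self, "distance_a", d)
        object.__setattr__(self, "angle_deg", a)
        if d.ndim != 1 or d.size != a.size:
            raise ValueError("distance and angle must be 1-D arrays of equal length")
        if d.size == 0:
            raise ValueError("series is empty")
        if np.any(d <= 0):
            raise ValueError("distances must be positive")

    @property
    def n_frames(self) -> int:
        return self.distance_a.size


@dataclass(frozen=True)
class FlexibilityMetrics:
    """Per-substrate flexibility summary (averages over replicas)."""

    bpl_a: float
    tpl_a: float
    sd_bend_deg: float
    sd_flip_deg: float
    pct_intra: float
    n_decorrelated: int
    bpl_sd: float = math.nan
    tpl_sd: float = math.nan
    sd_bend_sd: float = math.nan
    sd_flip_sd: float = math.nan
    pct_intra_sd: float = math.nan
    n_replicas: int = 1


def madbend_angle(
    tilt: np.ndarray,
    roll: np.ndarray,
    twist: np.ndarray,
    included: "np.ndarray | None" = None,
) -> float:
    """Global bending angle (degrees) from per-step tilt/roll/twist.

    Each included step contributes the deflection vector (tilt_i, roll_i)
    rotated by the cumulative twist of the *preceding* included steps; the
    bending angle is the Euclidean norm of the vector sum. Two equal rolls
    separated by 180 deg of helical twist therefore cancel exactly.
    """
    tilt = np.asarray(tilt, dtype=float)
    roll = np.asarray(roll, dtype=float)
    twist = np.asarray(twist, dtype=float)
    if not tilt.shape == roll.shape == twist.shape:
        raise ValueError("tilt, roll, twist must be aligned arrays")
    if included is None:
        included = np.arange(tilt.size)
    included = np.asarray(included, dtype=int)
    if included.size == 0:
        raise ValueError("no steps included in the bending sum")
    t = np.deg2rad(tilt[included])
    r = np.deg2rad(roll[included])
    tw = np.deg2rad(twist[included])
    phase = np.concatenate([[0.0], np.cumsum(tw)[:-1]])
    x = t * np.cos(phase) - r * np.sin(phase)
    y = t * np.sin(phase) + r * np.cos(phase)
    return float(np.rad2deg(math.hypot(float(x.sum()), float(y.sum()))))


def madbend_series(steps: StepParamSeries, n_terminal: int = 1) -> np.ndarray:
    """Per-frame MADBEND bending angles with terminal steps excluded."""
    inc = steps.interior_steps(n_terminal)
    tilt, roll, twist = steps.column("tilt"), steps.column("roll"), steps.column("twist")
    return np.array(
        [madbend_angle(tilt[f], roll[f], twist[f], inc) for f in range(steps.n_frames)]
    )


def contour_length(
    rise: np.ndarray, included: "np.ndarray | None" = None
) -> "float | np.ndarray":
    """Contour length: sum of the helical rise over included steps.

    Accepts a single frame (1-D) or a frame stack (2-D, frames x steps);
    returns a scalar or per-frame array accordingly.
    """
    rise = np.asarray(rise, dtype=float)
    if included is not None:
        rise = rise[..., np.asarray(included, dtype=int)]
    total = rise.sum(axis=-1)
    return float(total) if np.ndim(total) == 0 else total


def bend_persistence_length(
    bend_deg: np.ndarray,
    contour_a: float,
    n_bins: int = 30,
) -> float:
    """Bending persistence length from the bending-angle distribution.

    For a worm-like chain the probability of a bending angle phi follows
    ln P(phi) = const - (BPL/L) * (1 - cos phi), so BPL is -L times the
    slope of ln P against (1 - cos phi). P is the histogram density of the
    observed angles over ``n_bins`` equal-width bins (empty bins dropped).
    The regression is weighted by bin occupancy: Var[ln n] ~ 1/n, and
    without weights the near-empty tail bins dominate the slope.
    """
    phi = np.deg2rad(np.asarray(bend_deg, dtype=float))
    if contour_a <= 0:
        raise ValueError("contour length must be positive")
    if phi.size < 500:
        warnings.warn(
            f"only {phi.size} bending samples; persistence length will be noisy",
            stacklevel=2,
        )
    raw, edges = np.histogram(phi, bins=n_bins)
    density = raw / (phi.size * np.diff(edges))
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = raw > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 non-empty histogram bins")
    x = 1.0 - np.cos(centers[keep])
    y = np.log(density[keep])
    slope = np.polyfit(x, y, 1, w=np.sqrt(raw[keep]))[0]
    return float(-contour_a * slope)


def winding_angle(
    steps: StepParamSeries, n_terminal: int = 2, degrees: bool = False
) -> np.ndarray:
    """Per-frame total winding angle: sum of included twists.

    Excludes ``n_terminal`` steps at each end (fraying) and, when the uracil
    step is flagged, the two steps flanking the lesion (flipping). Radians
    by default; pass ``degrees=True`` for display.
    """
    inc = steps.winding_steps(n_terminal)
    if inc.size == 0:
        raise ValueError("no steps left in the winding sum after exclusions")
    omega = np.deg2rad(steps.column("twist")[:, inc].sum(axis=1))
    return np.rad2deg(omega) if degrees else omega


def torsional_persistence_length(omega_rad: np.ndarray, contour_a: float) -> float:
    """Torsional persistence length TPL = L / Var(Omega), Omega in radians."""
    omega = np.asarray(omega_rad, dtype=float)
    if omega.size < 2:
        raise ValueError("need at least 2 winding-angle samples")
    if contour_a <= 0:
        raise ValueError("contour length must be positive")
    var = float(np.var(omega, ddof=1))
    if var == 0.0:
        raise ValueError("winding angle has zero variance; TPL undefined")
    return contour_a / var


def pseudo_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) about the p2-p3 axis.

    Standard atan2 convention: positive when p4 rotates counter-clockwise
    from the p1 side looking down the p2->p3 axis. Used with the centers of
    mass (uracil base ring, uracil backbone, backbone of residue 8, backbone
    of the complementary base) this is the base-flipping angle.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("collinear points: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    angle = math.degrees(math.atan2(float(np.cross(n1, n2) @ b2n), float(n1 @ n2)))
    return 180.0 if angle <= -180.0 else angle


def classify_flipped(
    flips: FlipSeries,
    distance_cutoff: float = FLIP_DISTANCE_CUTOFF_A,
    angle_cutoff: float = FLIP_ANGLE_CUTOFF_DEG,
) -> tuple[np.ndarray, float]:
    """Per-frame flipped classification and the percent time intra-helical.

    A frame is flipped when the uracil hydrogen-bond distance strictly
    exceeds the cutoff AND the pseudo-dihedral magnitude strictly exceeds
    the angle cutoff. Returns (flipped mask, % intra-helical).
    """
    flipped = (flips.distance_a > distance_cutoff) & (
        np.abs(flips.angle_deg) > angle_cutoff
    )
    pct_intra = 100.0 * (1.0 - float(flipped.mean()))
    return flipped, pct_intra


def statistical_inefficiency(series: np.ndarray) -> float:
    """Statistical inefficiency g = 1 + 2 sum_t C(t) of a scalar series.

    The normalized autocorrelation C(t) is summed up to the first
    non-positive value. Constant series return the series length (every
    frame redundant), with a warning.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var == 0.0:
        warnings.warn("constant series: statistical inefficiency capped at n", stacklevel=2)
        return float(n)
    g = 1.0
    for t in range(1, n):
        c = float(xc[:-t] @ xc[t:]) / ((n - t) * var)
        if c <= 0.0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def decorrelate(series: np.ndarray, target_n: int = 100) -> np.ndarray:
    """Indices of approximately independent frames, evenly thinned.

    Subsamples at stride ceil(g) (g the statistical inefficiency) and then
    thins evenly to at most ``target_n`` frames. If fewer than ``target_n``
    decorrelated frames exist, all of them are returned with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < target_n:
        raise ValueError(f"series length {x.size} is shorter than target_n={target_n}")
    g = statistical_inefficiency(x)
    stride = int(math.ceil(g))
    idx = np.arange(0, x.size, stride)
    if idx.size < target_n:
        warnings.warn(
            f"only {idx.size} decorrelated frames available (target {target_n})",
            stacklevel=2,
        )
        return idx
    pick = np.linspace(0, idx.size - 1, target_n).round().astype(int)
    return idx[pick]


def _replica_metrics(
    steps: StepParamSeries, flips: FlipSeries, target_n: int, intra_all_frames: bool
) -> tuple[float, float, float, float, float, int]:
    bend = madbend_series(steps)
    idx = decorrelate(bend, target_n=target_n)
    contour = float(np.mean(contour_length(steps.column("rise"), steps.interior_steps())))
    bpl = bend_persistence_length(bend[idx], contour)
    omega = winding_angle(steps)
    tpl = torsional_persistence_length(omega[idx], contour)
    sd_bend = float(np.std(bend[idx], ddof=1))
    sd_flip = float(np.std(flips.angle_deg[idx], ddof=1))
    if intra_all_frames:
        _, pct_intra = classify_flipped(flips)
    else:
        _, pct_intra = classify_flipped(
            FlipSeries(flips.distance_a[idx], flips.angle_deg[idx])
        )
    return bpl, tpl, sd_bend, sd_flip, pct_intra, int(idx.size)


def flex_summary(
    replicas: "list[tuple[StepParamSeries, FlipSeries]]",
    target_n: int = 100,
    intra_all_frames: bool = True,
) -> FlexibilityMetrics:
    """Full flexibility summary, averaged over replica trajectories.

    Per replica: decorrelates on the bending-angle series, then computes
    BPL, TPL, SD of the bending angle, SD of the flipping angle (on the
    decorrelated frames) and the percent time intra-helical (on all frames
    by default; set ``intra_all_frames=False`` to use decorrelated frames).
    Reports means and standard deviations across replicas.
    """
    if not replicas:
        raise ValueError("no replicas supplied")
    for steps, flips in replicas:
        if steps.n_frames != flips.n_frames:
            raise ValueError("step and flip series are not frame-aligned")
        if steps.n_frames < 2:
            raise ValueError("a single frame has no fluctuations; metrics undefined")
    per = np.array(
        [_replica_metrics(s, f, target_n, intra_all_frames) for s, f in replicas]
    )
    mean = per.mean(axis=0)
    sd = per.std(axis=0, ddof=1) if len(replicas) > 1 else np.full(per.shape[1], math.nan)
    return FlexibilityMetrics(
        bpl_a=float(mean[0]),
        tpl_a=float(mean[1]),
        sd_bend_deg=float(mean[2]),
        sd_flip_deg=float(mean[3]),
        pct_intra=float(mean[4]),
        n_decorrelated=int(mean[5]),
        bpl_sd=float(sd[0]),
        tpl_sd=float(sd[1]),
        sd_bend_sd=float(sd[2]),
        sd_flip_sd=float(sd[3]),
        pct_intra_sd=float(sd[4]),
        n_replicas=len(replicas),
    )


def flip_series_from_trajectory(
    topology: str,
    trajectory: str,
    uracil_resid: int = 6,
    partner_resid: int = 19,
    anchor_resid: int = 8,
    hbond_atoms: tuple[str, str] = ("HN3", "N1"),
) -> FlipSeries:
    """Extract a :class:`FlipSeries` from coordinates via MDAnalysis.

    Optional adapter: requires the ``traj`` extra. Centers of mass use the
    uracil base-ring heavy atoms, and phosphate+sugar heavy atoms for the
    named backbone residues; the hydrogen-bond distance defaults to uracil
    HN3 to partner N1.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "trajectory reading requires MDAnalysis (install the 'traj' extra)"
        ) from exc

    u = mda.Universe(topology, trajectory)
    ring = u.select_atoms(
        f"resid {uracil_resid} and name N1 C2 N3 C4 C5 C6 and not name H*"
    )
    backbone_sel = "name P OP1 OP2 O5' C5' C4' O4' C3' O3' C2' C1'"
    bb_u = u.select_atoms(f"resid {uracil_resid} and ({backbone_sel})")
    bb_anchor = u.select_atoms(f"resid {anchor_resid} and ({backbone_sel})")
    bb_partner = u.select_atoms(f"resid {partner_resid} and ({backbone_sel})")
    h = u.select_atoms(f"resid {uracil_resid} and name {hbond_atoms[0]}")
    n = u.select_atoms(f"resid {partner_resid} and name {hbond_atoms[1]}")
    for sel, what in [(ring, "base ring"), (bb_u, "uracil backbone"),
                      (bb_anchor, "anchor backbone"), (bb_partner, "partner backbone"),
                      (h, "imino proton"), (n, "acceptor nitrogen")]:
        if len(sel) == 0:
            raise ValueError(f"empty atom selection for {what}")
    dist, ang = [], []
    for _ in u.trajectory:
        dist.append(float(np.linalg.norm(h.positions[0] - n.positions[0])))
        ang.append(
            pseudo_dihedral(
                ring.center_of_mass(), bb_u.center_of_mass(),
                bb_anchor.center_of_mass(), bb_partner.center_of_mass(),
            )
        )
    return FlipSeries(np.array(dist), np.array(ang))
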