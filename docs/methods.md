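# Methods

This note documents the models, the estimation procedures, the defaults and
the numerical choices in `ungflex`, and what the synthetic-data validation
does and does not establish.

## Scientific setting

UNG excises uracil after trapping a spontaneous extrahelical excursion of the
base, and the catalytically competent complex requires the DNA to be both
bent and base-flipped. Sequence-dependent excision efficiency should then
track the intrinsic deformability of the duplex around the lesion. The
package quantifies both sides of that relation: enzyme efficiency as the
specificity constant k_cat/K_M, and substrate deformability through three
independent probes — the dark stacked fraction of a 2-aminopurine (2AP)
reporter placed opposite the uracil, the imino-proton exchange rate of the
uracil base pair, and flexibility metrics computed from base-step parameter
trajectories. Substrates are labelled by the bases flanking the uracil
(motifs AT, AA, TT, TA, written 5′→3′).

## TCSPC decay analysis (`ungflex.tcspc`)

**Model.** F(λ,t) = F₀(λ) Σᵢ αᵢ(λ) e^(−t/τᵢ), Σᵢ αᵢ(λ) = 1, convolved with
the measured instrument response function (IRF). Decays at 380/390/400 nm
are fitted globally with shared lifetimes, which is what makes four-component
amplitude/lifetime sets identifiable at all.

**Two-window protocol.** Lifetimes span ~30 ps to ~8 ns — more than two
decades — so one acquisition window cannot resolve them all. Histograms are
acquired at 814 fs/channel (3.3 ns span, 4096 channels) and 6.1 ps/channel
(25 ns span). Stage 1 fits the short window with three exponentials; stage 2
fits the long window with four, fixing (τ₁, τ₂) at the stage-1 values, so
each window determines the lifetimes its resolution supports. Mean lifetimes
⟨τ⟩ = Σ αᵢτᵢ use the stage-2 amplitudes.

**Refinement (this package's choice).** The literal two-stage protocol has
an intrinsic bias at exactly the conditions of interest: the stage-1 3-exp
model must absorb two nanosecond components into one, and the best-fit
solution drags τ₁ and τ₂ up by 10–20% (measured on noise-free synthetic
data). `fit_two_window` therefore alternates the window roles to
self-consistency: the short window is refit with four exponentials holding
(τ₃, τ₄) fixed, then the long window is refit with the refreshed (τ₁, τ₂).
Convergence is geometric (~5× error reduction per cycle); the default is two
cycles, and `n_refine=0` reproduces the plain protocol. With Poisson noise
at 10⁴ peak counts, all four lifetimes are recovered within ~5% and ⟨τ⟩
within ~1%.

**Numerics.** Poisson (Neyman) weights 1/max(counts, 1); a fractional
IRF/decay channel-shift parameter bounded to ±10 channels (linear
interpolation of the IRF); fit range opens 20 channels before the IRF
maximum; amplitudes fitted in log space and renormalized afterwards;
lifetimes sorted ascending with amplitudes permuted accordingly; convolution
by FFT, validated against an O(N²) direct sum to 1e−10. No background term
by default (`include_background=True` adds one per curve).

## Photophysics (`ungflex.photophysics`)

Relative quantum yield: φ_S = φ_R (I_S/I_R)(1−10^(−A_R))/(1−10^(−A_S)),
default reference free 2AP riboside in water (φ_R = 0.68). Absorbances above
0.05 trigger an inner-filter warning. Dark fraction:
α₀ = 1 − (τ₂AP/⟨τ⟩)(φ/φ₂AP) with τ₂AP = 10.2 ns, φ₂AP = 0.68 — the
population quenched faster than the ~40 ps instrument resolution. Its
uncertainty is the quadrature sum of the φ and ⟨τ⟩ terms; when no per-sample
Δ⟨τ⟩ is available the pooled 2.5% relative precision of mean-lifetime
determinations is used (both paths are exposed). Values outside [0, 1] are
returned flagged `unphysical`, never clipped: they diagnose inconsistent
(φ, ⟨τ⟩) pairs. Replicate statistics use the Student-t confidence interval
of the mean.

## Enzyme kinetics (`ungflex.kinetics`)

V₀ = ([S]₀/ΔF)(dF/dt)₀ from continuous traces, with ΔF = plateau − baseline
(plateau: mean of the final 5% of points; baseline: first point or an
explicit pre-addition level; an explicit ΔF supports truncated traces). The
initial slope is the t = 0 derivative of a local quadratic fit over the
leading segment where the rise is ≤ 20% of ΔF. The quadratic term absorbs
the progress curve's concavity (a straight line biases the slope low by
about half the window fraction); the 20% default balances the remaining
third-order truncation bias against noise amplification — at the simulated
noise level (0.5% of ΔF) worst-case V₀ error is ~4%, versus ~14% for a 10%
window. `slope_fraction` remains a parameter.

The Michaelis–Menten fit is Levenberg–Marquardt least squares of
V₀ = V_max S/(K_M + S) weighted by reciprocal variances; k_cat = V_max/E₀
(E₀ = 0.16 nM) and k_cat/K_M carries a first-order propagated SE from the
full covariance. Fits with K_M outside the sampled concentration range are
flagged ill-conditioned.

## Imino-proton exchange (`ungflex.exchange`)

Recovery model after water inversion:
A(t)/A₀ = 1 − E·k_ex/(R₁w−R₁n)·(e^(−R₁n t) − e^(−R₁w t)), with the
removable singularity at R₁n = R₁w evaluated by its limit form
1 − E·k_ex·t·e^(−R₁n t) (both branches agree to ~1e−9 at the switch). E and
R₁w are measured inputs; R₁w comes from a saturation-recovery
mono-exponential fit S(t) = S∞(1 − e^(−R₁w t)).

Fitting is sequential: stage 1 fits (R₁n, B) with B = E·k_ex a nuisance
amplitude, so R₁n is identified by curve shape (multi-start over a coarse
R₁n grid guards against local minima); stage 2 refits k_ex alone with R₁n,
R₁w, E fixed, with the physical bound k_ex ≤ R₁n applied as a soft penalty.
The reported k_ex SE widens the stage-2 (conditional) error by the
finite-difference sensitivity of k_ex to R₁n times the stage-1 R₁n SE;
without this the SE covers the truth at ~30% instead of the nominal ~68%
(measured coverage after widening: 70–75% at 1% noise). A transfer dip
smaller than 3× the noise floor flags k_ex as an upper bound.

## Thermodynamic cycles (`ungflex.cycles`)

ΔΔG‡₁→₂ = −RT ln(k₂/k₁) in kJ/mol (R = 8.314 J mol⁻¹ K⁻¹, default
T = 293.15 K, the NMR temperature). The double-mutant square over the four
flanking motifs gives ΔG_coup = RT ln[(k_AT·k_TA)/(k_TT·k_AA)]; both edge
routes are evaluated and their residual reported (an algebraic identity,
zero to machine precision — a computation check, not a statistics one).
Uncertainty is first-order quadrature in ln k: σ = RT·√Σ(σ_k/k)²; this
matches log-normal Monte-Carlo propagation within 5% for relative rate
errors up to ~15%. `cycle_consistency` compares two quads differing only in
background sequence: additive background effects shift every motif's
cross-series ΔG‡ by the same constant and preserve the coupling.

## DNA geometry (`ungflex.geometry`)

**Bending.** MADBEND-style construction: each step contributes the
deflection vector (tilt, roll) rotated in-plane by the cumulative twist of
the preceding included steps; the bending angle ɸ is the norm of the vector
sum, so deflections in phase with the helical screw add and out-of-phase
ones cancel. Phasing uses the full cumulative twist of preceding steps (not
a half-step offset). Agreement with an exact rotation-matrix-composition
oracle is within 0.5° for |tilt|, |roll| ≤ 5° over 10 steps. Terminal steps
are excluded from ɸ and contour-length analyses (end fraying).

**Persistence lengths.** Contour length L = Σ rise over included steps. BPL
is −L times the slope of ln P(ɸ) against (1 − cos ɸ), with P the histogram
density of ɸ itself over 30 equal-width bins (no sin ɸ Jacobian division —
the validation law is constructed to match this reading). The regression is
weighted by √(bin count): Var[ln n] ≈ 1/n, and unweighted fits are dominated
by near-empty tail bins (25%+ seed-to-seed scatter, measured). TPL =
L/Var(Ω) with the winding angle Ω = Σ twist in radians over included steps;
the winding sum additionally excludes the two steps flanking the uracil
(base flipping would otherwise contaminate the torsional statistics).

**Flipping.** The flipping angle is the signed pseudo-dihedral (atan2
convention, range (−180°, 180°], negative = major groove) of the four
centers of mass: uracil base ring, uracil backbone, backbone of residue 8,
backbone of the complementary base (mass-weighted; backbone = phosphate +
sugar heavy atoms). A frame is flipped when the uracil–partner hydrogen-bond
distance strictly exceeds 4.5 Å AND |angle| strictly exceeds 40°; % time
intra-helical is 100·(1 − flipped fraction). An optional MDAnalysis adapter
extracts both series from coordinates; all estimators also accept
precomputed tables.

**Decorrelation.** Statistical inefficiency g = 1 + 2Σₜ C(t) (normalized
autocorrelation summed to its first non-positive value, with the (1 − t/N)
finite-series factor); frames are subsampled at stride ⌈g⌉ and evenly
thinned to 100 per replica, which is how all trajectory-scale metrics are
computed. `flex_summary` applies this per replica using the bending-angle
series, then reports means ± SD over replicas. The % intra-helical uses all
frames by default (`intra_all_frames=False` switches to decorrelated frames).

## Synthetic data (`ungflex.synthetic`)

Each generator emulates one input class under the study's sampling design
and attaches the generating truth:

- **TCSPC**: Poisson counts around the IRF-convolved multi-exponential on
  both window grids; Gaussian IRF, FWHM 40 ps (a measured IRF table can be
  supplied instead); defaults τ = (0.03, 0.4, 1.5, 8) ns with
  wavelength-dependent amplitude sets, peak 10⁴ counts. Peak counts are not
  stated by the source studies; 10⁴ is typical practice and configurable.
- **Exchange**: 24 log-spaced delays, 1 ms–15 s; additive Gaussian noise,
  default SD 1% of A₀ (not stated by the source; chosen to reproduce the
  printed relative errors of the fastest rates). R₁n is the sum of the
  intrinsic imino relaxation rate and k_ex, so its default tracks the truth:
  R₁n = k_ex + 1.76 s⁻¹ (12.0 s⁻¹ at the default k_ex = 10.24 s⁻¹). Holding
  R₁n fixed while varying k_ex would imply wildly varying intrinsic
  relaxation and makes slow-exchange recovery artificially ill-posed.
- **Kinetics**: product formation by numerical integration of
  d[P]/dt = V_max(S₀−P)/(K_M+S₀−P) (LSODA, rtol 1e−9) — not the linear
  regime, so the V₀ window choice is genuinely exercised; trace duration set
  by the integrated rate law to 99% completion; F = baseline + ΔF·P/S₀ plus
  Gaussian noise (default 0.5% of ΔF); 4000 points per trace (~0.5–1 s
  sampling over hour-scale runs). Ground-truth K_M = 1 µM and k_cat = 5 s⁻¹
  are field-plausible for E. coli UNG and sit inside the assayed 0.075–6 µM
  substrate range; E₀ = 0.16 nM.
- **Steps**: Gaussian per-step fluctuations around B-DNA means (twist 34.3°,
  rise 3.32 Å), optional stationary AR(1) frame-to-frame correlation —
  sufficient to exercise decorrelation, and the only correlation model
  offered. Torsional truth Var(Ω) = Σ σ²_twist over included steps.
- **Flips**: two-state Markov chain (stationary intra fraction, mean dwell)
  with Gaussian state-conditional emissions straddling the 4.5 Å/40°
  thresholds; the truth records both the chain parameters and the empirical
  state fraction.

All randomness flows from `numpy.random.default_rng([seed, stage])`:
identical `SimSpec`s reproduce identical bytes, and stages draw from
independent sub-streams.

**What passing tests show — and don't.** Recovery tests prove the estimators
are correct and calibrated under the stated noise models. Real data add
effects the generators deliberately omit: instrument drift and afterpulsing
in TCSPC, spectral overlap and baseline distortions in NMR (peak areas are
taken as inputs; deconvolution is upstream), photobleaching and lamp
fluctuations in the kinetic assay (assumed corrected at acquisition), and
force-field error plus true long-time correlations in MD. Synthetic
validation bounds estimator error, not measurement systematics.

## Pipeline (`ungflex.pipeline`)

`run_pipeline` drives an all-synthetic study from one YAML/dict config: per
substrate it simulates and fits every stage, merges the per-substrate
records, computes the correlation panels and — when all four motifs are
present — both coupling energies. Per-substrate, per-stage seeds derive from
the master seed via CRC-keyed `SeedSequence`s, so reruns are byte-identical
and adding a substrate does not shift the others' streams. The default
four-substrate configuration grades ground-truth flexibility TA > AA > TT ≈
AT, mirroring the qualitative ordering the measurements support; its TCSPC
stage is off by default (the photophysics inputs are then taken from the
config) and `run_tcspc: true` enables the full two-window fit per substrate.

## Known limitations

- The TCSPC fitter reports per-curve reduced χ² against an approximate
  per-curve dof split; global dof bookkeeping across shared parameters is
  approximate by one or two counts.
- BPL assumes the worm-like-chain exponential law holds over the sampled
  angle range; strongly bimodal bending (e.g. flipped-state kinks) violates
  it and shows up as bin-count sensitivity.
- The exchange fit treats E and R₁w as exact; their measurement errors are
  not propagated (they are typically small relative to the R₁n term).
- `cycle_consistency` tests additivity only pairwise between two series; it
  does not fit a joint additive model.
- The trajectory adapter assumes standard DNA atom naming (N1/C2/.../C1')
  and is exercised against synthetic tables, not against a reference
  trajectory, in the test suite.
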