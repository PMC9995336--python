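# ungflex

Biophysical analysis of how DNA substrate flexibility controls the efficiency
of uracil-DNA glycosylase (UNG), the base-excision-repair enzyme that removes
uracil from duplex DNA by flipping the base out of the helix. UNG prefers
some sequence contexts over others; the working hypothesis this toolkit
supports is that the intrinsic deformability of the DNA around the lesion —
not duplex stability — sets the excision efficiency.

The package implements, as one consistent library, the five analyses that
connect enzyme kinetics to substrate dynamics, plus synthetic-data generators
with attached ground truth so every estimator can be validated end to end:

| analysis | module | core quantity |
| --- | --- | --- |
| TCSPC lifetime fitting (IRF reconvolution, two-window global fit) | `ungflex.tcspc` | lifetimes τᵢ, amplitudes αᵢ(λ), ⟨τ⟩ = Σ αᵢτᵢ |
| 2AP photophysics | `ungflex.photophysics` | relative quantum yield φ; dark stacked fraction α₀ = 1 − (τ₂AP/⟨τ⟩)(φ/φ₂AP) |
| Continuous-assay enzyme kinetics | `ungflex.kinetics` | V₀ = ([S]₀/ΔF)(dF/dt)₀; weighted Michaelis–Menten fit → K_M, k_cat, k_cat/K_M |
| NMR imino-proton exchange | `ungflex.exchange` | A(t)/A₀ = 1 − E·k_ex/(R₁w−R₁n)·(e^(−R₁n t) − e^(−R₁w t)) → k_ex |
| Double-mutant thermodynamic cycles | `ungflex.cycles` | ΔΔG‡ = −RT ln(k₂/k₁); ΔG_coup = RT ln[(k_AT·k_TA)/(k_TT·k_AA)] |
| MD-derived flexibility metrics | `ungflex.geometry` | MADBEND bending angle ɸ, BPL = −L·∂lnP(ɸ)/∂(1−cos ɸ), TPL = L/Var(Ω), flipping pseudo-dihedral, % intra-helical |
| Synthetic data with ground truth | `ungflex.synthetic` | Poisson decay histograms, exchange series, progress traces, step-parameter and flipping trajectories |
| Cross-technique correlations & runner | `ungflex.correlate`, `ungflex.pipeline` | Pearson r panels; config-driven simulate→fit→correlate study |

The audience is experimental biophysicists and simulators who need these
fits reproducible outside vendor software: the formulas above are the exact
model functions fitted, with uncertainties propagated to the final coupling
energies and correlation panels.

## Worked example

Coupling between the bases flanking the uracil, from measured imino-proton
exchange rates (`examples/coupling_cycle.py`):

```text
ddG(TT -> TA) = -6.54 kJ/mol (3' T -> A with 5' T: strong stabilization)
ddG(AA -> TA) = -2.75 kJ/mol

coupling energy: 3.89 +/- 0.40 kJ/mol
route consistency residual: 4.4e-16 kJ/mol
```

Substituting the 3′ thymine by adenine lowers the base-pair-opening barrier
by 6.5 kJ/mol when the 5′ neighbour is T, but by much less when it is A: the
two flanking positions are allosterically coupled (ΔG_coup ≈ 3.9 kJ/mol; it
would be 0 for independent positions). The residual confirms the two routes
around the thermodynamic square agree identically.

Fitting a simulated exchange recovery series at the fastest measured uracil
rate (`examples/imino_exchange.py`):

```text
delays: 24 points, 1 ms - 15 s
R1n  = 11.66 +/- 0.19 1/s
k_ex = 10.04 +/- 0.14 1/s (true 10.24)
```

The other examples cover TCSPC lifetime recovery, the dark fraction α₀,
Michaelis–Menten fitting from raw traces, MD flexibility metrics, and the
full simulate→fit→correlate pipeline (`examples/full_pipeline.py`), whose
correlation panels reproduce the expected signatures: k_cat/K_M
anti-correlates with α₀ and correlates with k_ex.

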