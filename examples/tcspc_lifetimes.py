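"""Fit multi-exponential 2AP decays with the two-window reconvolution protocol.

Simulates photon-counting histograms at three emission wavelengths in both
acquisition windows (814 fs/channel and 6.1 ps/channel), then runs the global
two-window fit and compares the recovered lifetimes with the ground truth.
"""

import numpy as np

from ungflex import SimSpec, fit_two_window, gen_tcspc, mean_lifetime

sim = gen_tcspc(SimSpec(seed=1, stage="tcspc"))
fit = fit_two_window(sim.short_decays, sim.long_decays, sim.irf_short, sim.irf_long)

print("lifetimes (ns):")
print("  true:  ", np.round(sim.truth["lifetimes_ns"], 3))
print("  fitted:", np.round(fit.lifetimes_ns, 3))
for wl in sorted(fit.amplitudes):
    mt = mean_lifetime(fit, wl)
    print(
        f"  {wl:.0f} nm: alpha = {np.round(fit.amplitudes[wl], 3)}, "
        f"<tau> = {mt.value:.3f} ns (true {sim.truth['mean_tau_ns'][wl]:.3f})"
    )
print(
    "\nThe shared lifetimes span ~30 ps to 8 ns; the amplitude-weighted mean "
    "lifetime per wavelength feeds the dark-fraction (alpha0) calculation."
)
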