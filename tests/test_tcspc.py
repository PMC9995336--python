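"""IRF reconvolution, global fitting, the two-window protocol, <tau>."""

import numpy as np
import pytest

from conftest import TRUE_TAUS_NS
from ungflex.synthetic import SimSpec, gaussian_irf, gen_tcspc
from ungflex.tcspc import (
    IRF,
    DecayCurve,
    GlobalFitResult,
    fit_global,
    fit_two_window,
    mean_lifetime,
    reconvolve,
)


def direct_convolution_oracle(irf_counts, channel_width, lifetimes_s, amplitudes):
    """O(N^2) direct-sum convolution of the normalized IRF with the decay."""
    n = irf_counts.size
    kernel = irf_counts / irf_counts.sum()
    t = np.arange(n) * channel_width
    decay = sum(a * np.exp(-t / tau) for a, tau in zip(amplitudes, lifetimes_s))
    out = np.zeros(n)
    for k in range(n):
        for j in range(k + 1):
            out[k] += kernel[j] * decay[k - j]
    return out


class TestReconvolve:
    def test_delta_irf_gives_pure_exponential(self):
        dt = 1e-11
        counts = np.zeros(256)
        counts[0] = 1.0
        irf = IRF(channel_width=dt, counts=counts)
        model = reconvolve(irf, np.array([1e-9]), np.array([1.0]), scale=5.0)
        t = np.arange(256) * dt
        assert np.allclose(model, 5.0 * np.exp(-t / 1e-9), rtol=1e-10)

    def test_matches_direct_sum_oracle(self):
        dt = 4e-12
        irf = gaussian_irf(dt, 512, fwhm=40e-12)
        taus = np.array([30e-12, 400e-12])
        amps = np.array([0.7, 0.3])
        fast = reconvolve(irf, taus, amps, scale=1.0)
        slow = direct_convolution_oracle(irf.counts, dt, taus, amps)
        assert np.allclose(fast, slow, rtol=1e-10, atol=1e-12)
        # with the 40 ps IRF the peak is delayed and broadened vs pure decay
        assert np.argmax(fast) > 0

    def test_linearity_in_scale(self):
        irf = gaussian_irf(1e-11, 256)
        one = reconvolve(irf, np.array([1e-9]), np.array([1.0]), scale=1.0)
        two = reconvolve(irf, np.array([1e-9]), np.array([1.0]), scale=2.0)
        assert np.allclose(two, 2.0 * one, rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        irf = gaussian_irf(1e-11, 256)
        with pytest.raises(ValueError, match="grids differ"):
            reconvolve(irf, np.array([1e-9]), np.array([1.0]), channel_width=2e-11)


class TestFitGlobal:
    def test_noise_free_exact_recovery(self):
        """Perfect-model limit: parameters exact, reduced chi-square ~ 0."""
        sim = gen_tcspc(
            SimSpec(
                seed=0,
                stage="tcspc",
                parameters={
                    "lifetimes_ns": (0.05, 0.5, 2.0),
                    "amplitudes": {380: (0.5, 0.3, 0.2), 390: (0.4, 0.35, 0.25),
                                   400: (0.3, 0.4, 0.3)},
                    "n_channels": 2048,
                },
                noise={"poisson": False},
            )
        )
        fit = fit_global(sim.short_decays, sim.irf_short, n_exp=3)
        assert fit.lifetimes_ns == pytest.approx([0.05, 0.5, 2.0], rel=1e-6)
        for wl, true_a in sim.truth["amplitudes"].items():
            assert fit.amplitudes[wl] == pytest.approx(np.asarray(true_a), abs=1e-6)
        assert max(fit.reduced_chisq.values()) < 1e-12

    def test_identical_decays_give_identical_amplitudes(self):
        sim = gen_tcspc(
            SimSpec(seed=4, stage="tcspc",
                    parameters={"lifetimes_ns": (0.05, 0.5, 2.0),
                                "amplitudes": {380: (0.5, 0.3, 0.2)},
                                "n_channels": 2048})
        )
        d = sim.short_decays[0]
        triple = [
            DecayCurve(d.channel_width, d.counts, wl, d.window_id)
            for wl in (380.0, 390.0, 400.0)
        ]
        fit = fit_global(triple, sim.irf_short, n_exp=3)
        a = list(fit.amplitudes.values())
        assert np.allclose(a[0], a[1]) and np.allclose(a[1], a[2])

    def test_fourth_term_does_not_improve_three_exp_truth(self):
        """On 3-exponential truth a 4th short-window term is not justified."""
        sim = gen_tcspc(
            SimSpec(seed=5, stage="tcspc",
                    parameters={"lifetimes_ns": (0.05, 0.5, 2.0),
                                "amplitudes": {380: (0.5, 0.3, 0.2),
                                               390: (0.4, 0.35, 0.25),
                                               400: (0.3, 0.4, 0.3)}})
        )
        fit3 = fit_global(sim.short_decays, sim.irf_short, n_exp=3)
        fit4 = fit_global(sim.short_decays, sim.irf_short, n_exp=4)
        chi3 = np.mean(list(fit3.reduced_chisq.values()))
        chi4 = np.mean(list(fit4.reduced_chisq.values()))
        assert chi4 >= chi3 * (1.0 - 0.01)

    def test_mixed_windows_rejected(self):
        sim = gen_tcspc(SimSpec(seed=0, stage="tcspc"))
        with pytest.raises(ValueError, match="share a window"):
            fit_global(
                [sim.short_decays[0], sim.long_decays[0]], sim.irf_short, n_exp=3
            )


class TestTwoWindow:
    def test_recovery_at_study_conditions(self, tcspc_sim, tcspc_fit):
        """All four lifetimes within 10%, <tau> within 5%, at 1e4 peak counts."""
        rel = tcspc_fit.lifetimes_ns / TRUE_TAUS_NS - 1.0
        assert np.all(np.abs(rel) <= 0.10), rel
        for wl, true_mt in tcspc_sim.truth["mean_tau_ns"].items():
            assert mean_lifetime(tcspc_fit, wl).value == pytest.approx(true_mt, rel=0.05)

    def test_amplitudes_normalized_through_both_stages(self, tcspc_fit):
        for a in tcspc_fit.amplitudes.values():
            assert float(np.sum(a)) == pytest.approx(1.0, abs=1e-9)

    def test_plain_protocol_fixed_parameter_contract(self):
        """Without refinement, stage-2 tau1/tau2 equal stage-1 values exactly."""
        sim = gen_tcspc(SimSpec(seed=12, stage="tcspc"))
        stage1 = fit_global(sim.short_decays, sim.irf_short, n_exp=3)
        plain = fit_two_window(
            sim.short_decays, sim.long_decays, sim.irf_short, sim.irf_long, n_refine=0
        )
        assert plain.lifetimes_ns[0] == stage1.lifetimes_ns[0]
        assert plain.lifetimes_ns[1] == stage1.lifetimes_ns[1]
        assert plain.fixed_indices == (0, 1)

    def test_bias_shrinks_with_count_level(self):
        """Median lifetime recovery error decreases from 1e3 to 1e5 peak counts."""
        med = {}
        for peak in (1e3, 1e5):
            errs = []
            for seed in range(3):
                sim = gen_tcspc(
                    SimSpec(seed=100 + seed, stage="tcspc",
                            parameters={"peak_counts": peak})
                )
                fit = fit_two_window(
                    sim.short_decays, sim.long_decays, sim.irf_short, sim.irf_long,
                    n_refine=1,
                )
                errs.append(np.abs(fit.lifetimes_ns / TRUE_TAUS_NS - 1.0))
            med[peak] = float(np.median(errs))
        assert med[1e5] < med[1e3]


class TestMeanLifetime:
    def test_single_exponential(self):
        res = GlobalFitResult(
            lifetimes_ns=np.array([2.0]), amplitudes={380.0: np.array([1.0])},
            scales={380.0: 1.0}, n_exp=1, shift_channels=0.0,
            reduced_chisq={380.0: 1.0},
        )
        assert mean_lifetime(res, 380.0).value == 2.0

    def test_weighted_sum(self):
        res = GlobalFitResult(
            lifetimes_ns=np.array([0.03, 0.4, 1.5, 8.0]),
            amplitudes={390.0: np.array([0.2, 0.3, 0.4, 0.1])},
            scales={390.0: 1.0}, n_exp=4, shift_channels=0.0,
            reduced_chisq={390.0: 1.0},
        )
        assert mean_lifetime(res, 390.0).value == pytest.approx(1.526, abs=1e-9)

    def test_symmetric_pair(self):
        res = GlobalFitResult(
            lifetimes_ns=np.array([1.0, 3.0]),
            amplitudes={380.0: np.array([0.5, 0.5])},
            scales={380.0: 1.0}, n_exp=2, shift_channels=0.0,
            reduced_chisq={380.0: 1.0},
        )
        assert mean_lifetime(res, 380.0).value == pytest.approx(2.0)

    def test_mean_lies_between_extremes(self, tcspc_fit):
        for wl in tcspc_fit.amplitudes:
            mt = mean_lifetime(tcspc_fit, wl).value
            assert tcspc_fit.lifetimes_ns[0] <= mt <= tcspc_fit.lifetimes_ns[-1]


class TestGenerator:
    def test_determinism(self):
        spec = SimSpec(seed=77, stage="tcspc")
        a = gen_tcspc(spec)
        b = gen_tcspc(spec)
        for da, db in zip(a.short_decays + a.long_decays, b.short_decays + b.long_decays):
            assert np.array_equal(da.counts, db.counts)

    def test_window_resolutions_default_to_study_design(self):
        sim = gen_tcspc(SimSpec(seed=0, stage="tcspc"))
        assert sim.short_decays[0].channel_width == pytest.approx(814e-15)
        assert sim.long_decays[0].channel_width == pytest.approx(6.1e-12)
        assert sim.short_decays[0].counts.size == 4096
        assert len(sim.short_decays) == 3

    def test_single_exponential_no_noise_delta_irf_is_pure_decay(self):
        sim = gen_tcspc(
            SimSpec(
                seed=0, stage="tcspc",
                parameters={
                    "lifetimes_ns": (1.0,),
                    "amplitudes": {380: (1.0,)},
                    "irf_fwhm_s": 1e-16,  # effectively a delta on this grid
                    "n_channels": 1024,
                    "long_channel_width_s": 6.1e-12,
                },
                noise={"poisson": False},
            )
        )
        d = sim.long_decays[0]
        t = d.times
        peak_idx = int(np.argmax(d.counts))
        expected = d.counts[peak_idx] * np.exp(-(t[peak_idx:] - t[peak_idx]) / 1e-9)
        assert np.allclose(d.counts[peak_idx:], expected, rtol=1e-6)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            gen_tcspc(
                SimSpec(seed=0, stage="tcspc", parameters={"lifetimes_ns": (1.0, 0.5)})
            )
        with pytest.raises(ValueError, match="sum to 1"):
            gen_tcspc(
                SimSpec(
                    seed=0, stage="tcspc",
                    parameters={"lifetimes_ns": (0.1, 1.0),
                                "amplitudes": {380: (0.5, 0.6)}},
                )
            )
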