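"""Bending/torsion observables, flipping classification, decorrelation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ungflex.geometry import (
    FlipSeries,
    StepParamSeries,
    bend_persistence_length,
    classify_flipped,
    contour_length,
    decorrelate,
    flex_summary,
    madbend_angle,
    madbend_series,
    pseudo_dihedral,
    statistical_inefficiency,
    torsional_persistence_length,
    winding_angle,
)
from ungflex.synthetic import SimSpec, gen_flips, gen_steps


def rotation_composition_angle(tilt, roll, twist):
    """Oracle: compose exact per-step rotations (tilt about x, roll about y,
    twist about the helix axis) and measure the angle between the initial
    and final helix-axis directions."""

    def rx(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    m = np.eye(3)
    for t, r, w in zip(np.deg2rad(tilt), np.deg2rad(roll), np.deg2rad(twist)):
        m = m @ rx(t) @ ry(r) @ rz(w)
    cosang = np.clip(m[:, 2] @ np.array([0.0, 0.0, 1.0]), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(cosang)))


class TestMadbend:
    def test_straight_helix_has_zero_bend(self):
        n = 10
        assert madbend_angle(np.zeros(n), np.zeros(n), np.full(n, 34.3)) == 0.0

    def test_single_deflection_passes_through(self):
        assert madbend_angle([0.0], [10.0], [0.0]) == pytest.approx(10.0)
        assert madbend_angle([7.0], [0.0], [20.0]) == pytest.approx(7.0)

    def test_opposing_phased_deflections_cancel(self):
        # two equal rolls with 180 deg of twist in between
        assert madbend_angle([0, 0], [10, 10], [180, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_in_phase_deflections_add(self):
        assert madbend_angle([0, 0], [10, 10], [360, 0]) == pytest.approx(20.0)

    def test_matches_rotation_matrix_oracle(self):
        """Linear phased-sum vs exact rotation composition, small angles."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = 10
            tilt = rng.uniform(-5, 5, n)
            roll = rng.uniform(-5, 5, n)
            twist = rng.normal(34.3, 3.0, n)
            assert madbend_angle(tilt, roll, twist) == pytest.approx(
                rotation_composition_angle(tilt, roll, twist), abs=0.5
            )

    def test_empty_inclusion_rejected(self):
        with pytest.raises(ValueError):
            madbend_angle([1.0], [1.0], [30.0], included=np.array([], dtype=int))


class TestContourLength:
    def test_sum_of_rise(self):
        assert contour_length(np.full(10, 3.32)) == pytest.approx(33.2)

    def test_terminal_exclusion_bookkeeping(self):
        rise = np.arange(1.0, 11.0)  # 10 steps
        included = np.arange(1, 9)  # drop first and last
        assert contour_length(rise, included) == pytest.approx(rise[1:-1].sum())

    def test_per_frame_stack(self):
        rise = np.tile(np.full(8, 3.0), (5, 1))
        out = contour_length(rise)
        assert out.shape == (5,)
        assert np.allclose(out, 24.0)


class TestBendPersistenceLength:
    @pytest.mark.parametrize("rate,expected", [(20.0, 800.0), (10.0, 400.0)])
    def test_recovers_constructed_wormlike_law(self, rate, expected):
        """phi sampled from density ~ exp(-rate*(1-cos phi)): BPL = L*rate."""
        rng = np.random.default_rng(int(rate))
        phi = []
        while len(phi) < 100_000:
            cand = rng.uniform(0.0, np.pi, 200_000)
            keep = rng.random(200_000) < np.exp(-rate * (1.0 - np.cos(cand)))
            phi.extend(cand[keep])
        samples_deg = np.rad2deg(np.array(phi[:100_000]))
        assert bend_persistence_length(samples_deg, 40.0) == pytest.approx(
            expected, rel=0.10
        )

    def test_linearity_in_contour_length(self):
        rng = np.random.default_rng(1)
        samples = np.rad2deg(np.abs(rng.normal(0.0, 0.3, 20_000)))
        full = bend_persistence_length(samples, 40.0)
        half = bend_persistence_length(samples, 20.0)
        assert half == pytest.approx(full / 2.0, rel=1e-12)

    def test_bin_count_insensitivity(self):
        rng = np.random.default_rng(2)
        rate = 15.0
        cand = rng.uniform(0.0, np.pi, 2_000_000)
        keep = rng.random(cand.size) < np.exp(-rate * (1.0 - np.cos(cand)))
        samples = np.rad2deg(cand[keep][:100_000])
        values = [
            bend_persistence_length(samples, 40.0, n_bins=nb) for nb in (20, 30, 50)
        ]
        assert max(values) / min(values) <= 1.2

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            bend_persistence_length(np.full(1000, 10.0), 40.0, n_bins=30)


class TestWindingAndTPL:
    def test_winding_sum_and_exclusions(self):
        sim = gen_steps(
            SimSpec(seed=0, stage="steps",
                    parameters={"n_steps": 14, "n_frames": 10, "uracil_step": 6,
                                "sds": [0.0] * 6})
        )
        inc = sim.steps.winding_steps()
        # 14 steps - 2 terminals each end - steps 6 and 7 flanking the uracil
        assert inc.size == 8
        assert set(inc) == set(range(2, 12)) - {6, 7}
        omega = winding_angle(sim.steps, degrees=True)
        assert np.allclose(omega, 34.3 * 8)

    def test_constant_twist_has_zero_variance_error(self):
        sim = gen_steps(
            SimSpec(seed=0, stage="steps",
                    parameters={"n_frames": 50, "sds": [0.0] * 6})
        )
        with pytest.raises(ValueError, match="zero variance"):
            torsional_persistence_length(winding_angle(sim.steps), 40.0)

    def test_tpl_closed_form_ten_steps(self):
        """10 independent steps, twist SD 4 deg, L = 40 A -> TPL = 820.7 A."""
        sim = gen_steps(
            SimSpec(seed=3, stage="steps",
                    parameters={"n_steps": 14, "n_frames": 10_000,
                                "uracil_step": None,
                                "sds": [0.0, 0.0, 0.0, 0.0, 0.0, 4.0]})
        )
        omega = winding_angle(sim.steps)
        assert sim.steps.winding_steps().size == 10
        expected = 40.0 / (10.0 * np.deg2rad(4.0) ** 2)  # 820.7
        assert torsional_persistence_length(omega, 40.0) == pytest.approx(
            expected, rel=0.10
        )

    def test_variance_matches_truth_sum(self):
        sim = gen_steps(SimSpec(seed=4, stage="steps", parameters={"n_frames": 10_000}))
        omega = winding_angle(sim.steps)
        assert float(np.var(omega, ddof=1)) == pytest.approx(
            sim.truth["var_omega_rad2"], rel=0.05
        )

    def test_doubling_variance_halves_tpl(self):
        rng = np.random.default_rng(5)
        omega = rng.normal(6.0, 0.1, 5000)
        tpl1 = torsional_persistence_length(omega, 40.0)
        tpl2 = torsional_persistence_length(
            6.0 + (omega - 6.0) * np.sqrt(2.0), 40.0
        )
        assert tpl2 == pytest.approx(tpl1 / 2.0, rel=1e-9)


class TestPseudoDihedral:
    def test_planar_trans_is_180(self):
        assert pseudo_dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_right_angle_sign_convention(self):
        assert pseudo_dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)) == pytest.approx(90.0)
        assert pseudo_dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, -1)) == pytest.approx(-90.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_rigid_motion_invariance_and_reflection_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1, (4, 3))
        base = pseudo_dihedral(*pts)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = rng.normal(0, 5, 3)
        moved = pts @ q.T + shift
        assert pseudo_dihedral(*moved) == pytest.approx(base, abs=1e-8)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        if abs(base) != 180.0:
            assert pseudo_dihedral(*mirrored) == pytest.approx(-base, abs=1e-8)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            pseudo_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestClassifyFlipped:
    def test_clear_intra_frame(self):
        flips = FlipSeries(np.array([2.9]), np.array([0.0]))
        mask, pct = classify_flipped(flips)
        assert not mask[0]
        assert pct == 100.0

    def test_boundary_is_strict(self):
        # exactly at the distance threshold: still intra-helical
        flips = FlipSeries(np.array([4.5, 4.51, 4.51]), np.array([-90.0, -40.0, -40.01]))
        mask, _ = classify_flipped(flips)
        assert list(mask) == [False, False, True]

    def test_idempotent_on_masked_series(self):
        sim = gen_flips(SimSpec(seed=1, stage="flips", parameters={"n_frames": 2000}))
        mask, pct = classify_flipped(sim.flips)
        sub = FlipSeries(sim.flips.distance_a[~mask], sim.flips.angle_deg[~mask])
        _, pct_sub = classify_flipped(sub)
        assert pct_sub == 100.0

    def test_markov_fraction_recovery_within_ci(self):
        """Recovered intra fraction matches the chain+emission closed form."""
        from scipy.stats import norm

        f_intra, dwell, n = 0.57, 50.0, 100_000
        sim = gen_flips(
            SimSpec(seed=2, stage="flips",
                    parameters={"intra_fraction": f_intra, "dwell_frames": dwell,
                                "n_frames": n})
        )
        _, pct = classify_flipped(sim.flips)
        # closed-form classification probabilities from the Gaussian emissions
        em_i, em_e = sim.truth["intra_emission"], sim.truth["extra_emission"]
        p_flip_given_extra = norm.sf(4.5, em_e["dist_mean"], em_e["dist_sd"]) * (
            norm.cdf(-40.0, em_e["angle_mean"], em_e["angle_sd"])
            + norm.sf(40.0, em_e["angle_mean"], em_e["angle_sd"])
        )
        p_flip_given_intra = norm.sf(4.5, em_i["dist_mean"], em_i["dist_sd"])
        expected_intra = 100.0 * (
            1.0 - f_intra * p_flip_given_intra - (1.0 - f_intra) * p_flip_given_extra
        )
        # chain-limited effective sample size: n / g with g ~ 2*dwell_total
        g = 1.0 + 2.0 * dwell * (1.0 - f_intra)  # autocorrelation time of the chain
        se = 100.0 * np.sqrt(f_intra * (1 - f_intra) / (n / (2 * g)))
        assert abs(pct - expected_intra) <= 3.0 * se

    def test_all_intra_chain(self):
        sim = gen_flips(
            SimSpec(seed=3, stage="flips",
                    parameters={"intra_fraction": 1.0, "n_frames": 500})
        )
        assert classify_flipped(sim.flips)[1] == 100.0


class TestDecorrelate:
    def test_white_noise_stride_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20_000)
        assert statistical_inefficiency(x) == pytest.approx(1.0, abs=0.2)
        idx = decorrelate(x, target_n=100)
        assert idx.size == 100

    def test_ar1_inefficiency(self):
        """AR(1) rho=0.9: g = (1+rho)/(1-rho) = 19, within 30%."""
        sim = gen_steps(
            SimSpec(seed=6, stage="steps",
                    parameters={"n_frames": 100_000, "rho": 0.9})
        )
        g = statistical_inefficiency(sim.steps.column("twist")[:, 5])
        assert g == pytest.approx(19.0, rel=0.30)

    def test_constant_series_capped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            g = statistical_inefficiency(np.full(500, 3.0))
        assert g == 500.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            decorrelate(np.arange(50.0), target_n=100)

    def test_insufficient_decorrelated_frames_warn(self):
        sim = gen_steps(
            SimSpec(seed=7, stage="steps",
                    parameters={"n_frames": 600, "rho": 0.95})
        )
        with pytest.warns(UserWarning, match="decorrelated"):
            idx = decorrelate(sim.steps.column("twist")[:, 5], target_n=100)
        assert idx.size < 100


class TestFlexSummary:
    def test_single_frame_rejected(self):
        sim = gen_steps(SimSpec(seed=0, stage="steps", parameters={"n_frames": 10}))
        one = StepParamSeries(sim.steps.params[:1], uracil_step=6)
        flips = FlipSeries(np.array([2.9]), np.array([0.0]))
        with pytest.raises(ValueError, match="single frame"):
            flex_summary([(one, flips)])

    def test_stiff_vs_floppy_ordering(self):
        def replicas(twist_sd, roll_sd, seed0):
            reps = []
            for rep in range(2):
                st_sim = gen_steps(
                    SimSpec(seed=seed0 + rep, stage="steps",
                            parameters={"n_frames": 3000,
                                        "sds": [0.4, 0.4, 0.2, 2.0, roll_sd, twist_sd]})
                )
                fl_sim = gen_flips(
                    SimSpec(seed=seed0 + rep, stage="flips",
                            parameters={"n_frames": 3000, "intra_fraction": 0.8})
                )
                reps.append((st_sim.steps, fl_sim.flips))
            return reps

        stiff = flex_summary(replicas(2.0, 2.5, 100))
        floppy = flex_summary(replicas(6.0, 8.0, 200))
        assert stiff.bpl_a > floppy.bpl_a
        assert stiff.tpl_a > floppy.tpl_a
        assert stiff.sd_bend_deg < floppy.sd_bend_deg

    def test_replica_statistics_reported(self):
        reps = []
        for rep in range(3):
            st_sim = gen_steps(
                SimSpec(seed=300 + rep, stage="steps", parameters={"n_frames": 2000})
            )
            fl_sim = gen_flips(
                SimSpec(seed=300 + rep, stage="flips",
                        parameters={"n_frames": 2000, "intra_fraction": 0.57})
            )
            reps.append((st_sim.steps, fl_sim.flips))
        metrics = flex_summary(reps)
        assert metrics.n_replicas == 3
        assert metrics.n_decorrelated == 100
        assert np.isfinite(metrics.bpl_sd)
        assert 0.0 <= metrics.pct_intra <= 100.0

    def test_step_moment_table_reproducible(self):
        """Per-step mean/SD of the central steps match the generator truth."""
        sim = gen_steps(SimSpec(seed=8, stage="steps", parameters={"n_frames": 20_000}))
        uracil = sim.truth["uracil_step"]
        for col, j in [("twist", 5), ("roll", 4), ("rise", 2)]:
            data = sim.steps.column(col)[:, uracil]
            assert float(np.mean(data)) == pytest.approx(
                sim.truth["means"][uracil, j], abs=4 * sim.truth["sds"][uracil, j] / np.sqrt(20_000)
            )
            assert float(np.std(data, ddof=1)) == pytest.approx(
                sim.truth["sds"][uracil, j], rel=0.05
            )
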