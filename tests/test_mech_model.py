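"""Three-state linker mechanics: geometry, composition, equilibrium and
stochastic kinetics, constant-velocity pulling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cadmech.force_curves import detect_force_peaks, segment_phases_fit, smooth_and_bin
from cadmech.mech_model import (
    MechModel,
    Segment,
    ThreeStateLinker,
    compose_stiffness,
    first_passage_to_extended,
    geometric_extension,
    gillespie_constant_force,
    parallel_stiffness,
    quasistatic_force_extension,
    series_stiffness,
    simulate_constant_velocity,
)


class TestGeometricExtension:
    def test_no_angle_change_gives_zero(self):
        assert geometric_extension([4.5, 4.5], [90.0], [90.0]) == 0.0

    def test_two_repeat_straightening_closed_form(self):
        got = geometric_extension([4.5, 4.5], [90.0], [0.0])
        assert got == pytest.approx(9.0 - 4.5 * math.sqrt(2), abs=1e-12)

    def test_straight_arm_plus_bent_repeat(self):
        # collinear 9 nm arm plus a 4.5 nm repeat at 90°, straightened
        got = geometric_extension([9.0, 4.5], [90.0], [0.0])
        assert got == pytest.approx(13.5 - math.hypot(9.0, 4.5), abs=1e-9)
        assert got == pytest.approx(3.44, abs=0.01)

    def test_negative_length_is_error(self):
        with pytest.raises(ValueError):
            geometric_extension([-1.0, 4.5], [90.0], [0.0])

    @given(
        lengths=st.lists(st.floats(1.0, 10.0), min_size=2, max_size=4),
        angles=st.lists(st.floats(-170.0, 170.0), min_size=1, max_size=3),
        new_angles=st.lists(st.floats(-170.0, 170.0), min_size=1, max_size=3),
    )
    def test_invariant_under_reflection_and_reversal(self, lengths, angles, new_angles):
        n = len(lengths) - 1
        angles, new_angles = angles[:n], new_angles[:n]
        if len(angles) < n or len(new_angles) < n:
            return
        base = geometric_extension(lengths, angles, new_angles)
        reflected = geometric_extension(lengths, [-a for a in angles], [-a for a in new_angles])
        reversed_ = geometric_extension(
            lengths[::-1], angles[::-1], new_angles[::-1]
        )
        assert base == pytest.approx(reflected, abs=1e-9)
        assert base == pytest.approx(reversed_, abs=1e-9)


class TestStiffnessComposition:
    def test_single_element_identity(self):
        assert compose_stiffness([570.0]) == 570.0

    def test_parallel_dimer_bound(self):
        assert compose_stiffness([8.4], n_strands=2) == pytest.approx(16.8)
        assert compose_stiffness([8.4], n_strands=2) > 16.0

    def test_series_of_phase_stiffnesses(self):
        assert compose_stiffness([30.0, 445.0]) == pytest.approx(28.105, abs=0.01)

    def test_series_never_exceeds_softest_element(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ks = rng.uniform(1.0, 1000.0, size=rng.integers(1, 6))
            assert series_stiffness(ks) <= ks.min() + 1e-9

    def test_parallel_is_exact_sum(self):
        assert parallel_stiffness([1.5, 2.5, 3.0]) == pytest.approx(7.0, abs=1e-12)

    def test_zero_stiffness_is_error(self):
        with pytest.raises(ValueError):
            series_stiffness([570.0, 0.0])


class TestQuasistatic:
    def test_bent_ground_state_at_zero_force(self):
        linker = ThreeStateLinker(dg1=6.0, dg2=6.0)
        model = MechModel(linkers=[linker])
        ext = quasistatic_force_extension(model, [0.0])
        assert ext[0] < 0.1 * (linker.dx1 + linker.dx2)

    def test_two_state_midpoint_gives_half_occupancy(self):
        # suppress the extended state; at F* = ΔG₁·k_BT/Δx₁ the intermediate
        # is isoenergetic with the native state
        linker = ThreeStateLinker(dg1=7.0, dg2=500.0)
        model = MechModel(linkers=[linker])
        f_star = linker.dg1 * model.kbt / linker.dx1
        occ = linker.occupancies(f_star, model.kbt)
        assert occ[1] == pytest.approx(0.5, abs=1e-9)
        ext = quasistatic_force_extension(model, [f_star])
        elastic = f_star / model.chain_stiffness
        assert ext[0] - elastic == pytest.approx(linker.dx1 / 2, abs=1e-9)

    def test_saturation_at_large_force(self):
        linker = ThreeStateLinker()
        model = MechModel(linkers=[linker])
        F = 500.0
        ext = quasistatic_force_extension(model, [F])
        assert ext[0] - F / model.chain_stiffness == pytest.approx(
            linker.dx1 + linker.dx2, abs=1e-3
        )

    def test_extension_monotonic_in_force(self):
        model = MechModel()
        F = np.linspace(0.0, 120.0, 200)
        ext = quasistatic_force_extension(model, F)
        assert np.all(np.diff(ext) >= -1e-12)

    def test_two_identical_strands_double_the_stiffness(self):
        """extension_2strand(2F) == extension_1strand(F) exactly, i.e. the
        force-extension curve is scaled by 2 in force."""
        single = MechModel(n_strands=1)
        double = MechModel(n_strands=2)
        F = np.linspace(1.0, 60.0, 30)
        e1 = quasistatic_force_extension(single, F)
        e2 = quasistatic_force_extension(double, 2.0 * F)
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_non_monotonic_grid_is_error(self):
        with pytest.raises(ValueError):
            quasistatic_force_extension(MechModel(), [0.0, 10.0, 5.0])


class TestGillespie:
    def test_frozen_kinetics_stays_in_initial_state(self):
        model = MechModel(linkers=[ThreeStateLinker(k0=0.0)])
        traj = gillespie_constant_force(model, 50.0, 1000.0, seed=1)
        assert np.array_equal(traj.states, [0])
        assert traj.occupancy()[0] == 1.0

    def test_occupancies_match_boltzmann(self):
        """Long-run state occupancies against the closed-form Boltzmann
        weights of the force-tilted energies (3-SE tolerance)."""
        linker = ThreeStateLinker(dg1=1.5, dg2=1.5, k0=1.0e9)
        model = MechModel(linkers=[linker])
        F = 3.0
        traj = gillespie_constant_force(model, F, 100_000.0, seed=2)
        n_events = len(traj.event_times)
        assert n_events > 10_000
        occ = traj.occupancy()
        expected = linker.occupancies(F, model.kbt)
        # effective SE of a time-averaged occupancy ~ sqrt(p(1-p)/n_dwells)
        for p_hat, p in zip(occ, expected):
            se = math.sqrt(p * (1 - p) / (n_events / 3))
            assert abs(p_hat - p) < max(3 * se, 0.01)
        assert np.abs(occ - expected).max() < 0.05  # KS-style bound

    def test_native_dwell_times_are_exponential_with_exit_rate(self):
        linker = ThreeStateLinker(dg1=1.0, dg2=1.0, k0=1.0e9)
        model = MechModel(linkers=[linker])
        F = 5.0
        traj = gillespie_constant_force(model, F, 200_000.0, seed=3)
        bounds = np.concatenate([traj.event_times, [traj.duration]])
        dwells = np.diff(bounds)[:-1]
        native = dwells[traj.states[:-1] == 0]
        assert len(native) >= 500
        exit_rate_per_ns = sum(linker.rates(0, F, model.kbt).values()) * 1e-9
        mean, expected = native.mean(), 1.0 / exit_rate_per_ns
        se = native.std(ddof=1) / math.sqrt(len(native))
        assert abs(mean - expected) < 3 * se

    def test_rate_overflow_is_reported(self):
        model = MechModel(linkers=[ThreeStateLinker(k0=1.0e7)])
        with pytest.raises(ValueError, match="rate"):
            gillespie_constant_force(model, 1.0e5, 10.0, seed=0)

    def test_resting_tension_rarely_reaches_extended_state(self):
        """Default calibration: at 10 pN over 1 μs the linker essentially
        never unbends fully; at 25 pN it typically does within 1 μs."""
        model = MechModel()
        reached = [
            first_passage_to_extended(model, 10.0, 1000.0, seed=s) is not None
            for s in range(60)
        ]
        assert np.mean(reached) < 0.05

    def test_intermediate_force_unbends_within_microsecond(self):
        model = MechModel()
        fp = [first_passage_to_extended(model, 25.0, 4000.0, seed=s) for s in range(301)]
        fp = [f if f is not None else 4000.0 for f in fp]
        assert np.median(fp) < 1000.0


class TestConstantVelocity:
    def test_hookean_limit_slope_equals_chain_stiffness(self):
        """With frozen (canonical-stiff) linkers the response is linear in
        the protein's end-to-end extension with slope k_chain."""
        model = MechModel(linkers=[ThreeStateLinker(k0=0.0)])
        trace, _ = simulate_constant_velocity(model, 0.5, duration_ns=20.0, seed=1)
        mask = trace.force > 1.0
        slope = np.polyfit(trace.extension[mask], trace.force[mask], 1)[0]
        assert slope == pytest.approx(model.chain_stiffness, rel=1e-6)

    def test_three_state_linker_gives_two_phases(self):
        model = MechModel()
        trace, st_traj = simulate_constant_velocity(model, 0.1, seed=3)
        assert st_traj.states[-1] == 2          # fully unbent by the end
        _, binned = smooth_and_bin(trace)
        fit = segment_phases_fit(binned.extension, binned.mean)
        assert not fit.single_phase
        assert fit.k_phase1 < fit.k_phase2

    def test_unbending_transition_produces_detected_force_drop(self):
        model = MechModel()
        trace, st_traj = simulate_constant_velocity(model, 0.1, seed=3)
        smoothed, _ = smooth_and_bin(trace)
        peaks = detect_force_peaks(smoothed, prominence=10.0)
        assert len(peaks) >= 1
        assert max(p.drop for p in peaks) > 10.0

    def test_too_large_time_step_is_error(self):
        model = MechModel(linkers=[ThreeStateLinker(k0=1.0e14)])
        with pytest.raises(ValueError, match="time step"):
            simulate_constant_velocity(model, 0.1, duration_ns=5.0, dt_ns=0.01, seed=0)

    def test_deterministic_for_fixed_seed(self):
        model = MechModel()
        t1, _ = simulate_constant_velocity(model, 0.2, dt_ns=0.002, seed=9)
        t2, _ = simulate_constant_velocity(model, 0.2, dt_ns=0.002, seed=9)
        assert np.array_equal(t1.force, t2.force)


def test_segment_and_linker_parameter_validation():
    with pytest.raises(ValueError):
        Segment(length=-1.0)
    with pytest.raises(ValueError):
        ThreeStateLinker(dg1=-1.0)
    with pytest.raises(ValueError):
        MechModel(n_strands=0)
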