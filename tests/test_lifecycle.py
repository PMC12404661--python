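"""Life-cycle simulator: hand-derived values, invariants, and the independent
odds-product oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biphasix.lifecycle import (
    FitnessParameters,
    initialize_plate,
    milestone,
    replicator_update,
    simulate,
    simulate_stochastic,
    step_cycle,
)


def odds_oracle(p0: float, w_w: float, w_p: float, n_cycles: int):
    """Independent trajectory: per phase, odds of A multiply by w/(1-w)."""
    odds = p0 / (1 - p0)
    worm, plate = [], []
    for _ in range(n_cycles):
        odds *= w_w / (1 - w_w)
        worm.append(odds / (1 + odds))
        odds *= w_p / (1 - w_p)
        plate.append(odds / (1 + odds))
    return np.array(worm), np.array(plate)


class TestInitializePlate:
    @pytest.mark.parametrize(
        "p0,expected",
        [(0.5, (5e8, 5e8)), (1.0, (1e9, 0.0)), (0.699, (6.99e8, 3.01e8))],
    )
    def test_inoculum_split(self, p0, expected):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9, K_P=1e9, prop_A_initial=p0)
        n_a, n_b = initialize_plate(params)
        assert n_a == pytest.approx(expected[0])
        assert n_b == pytest.approx(expected[1])
        assert n_a + n_b == pytest.approx(params.K_P)


class TestReplicatorUpdate:
    @pytest.mark.parametrize(
        "p,w,expected",
        [
            (0.5, 0.5, 0.5),
            (0.3, 0.7, 0.5),  # 0.21 / (0.21 + 0.21)
            (0.5, 0.9, 0.9),  # 0.45 / (0.45 + 0.05)
            (0.0, 0.9, 0.0),  # extinction is absorbing
            (1.0, 0.1, 1.0),
            (0.3, 1.0, 1.0),  # deterministic sweep
            (0.3, 0.0, 0.0),
        ],
    )
    def test_pointwise(self, p, w, expected):
        assert replicator_update(p, w) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            replicator_update(1.2, 0.5)

    @given(
        p=st.floats(0.01, 0.99),
        w=st.floats(0.01, 0.99),
        dp=st.floats(0.001, 0.2),
    )
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing_in_p_and_w(self, p, w, dp):
        p2, w2 = min(p + dp, 0.999), min(w + dp, 0.999)
        assert replicator_update(p2, w) > replicator_update(p, w)
        assert replicator_update(p, w2) > replicator_update(p, w)

    @given(p=st.floats(0.001, 0.999))
    @settings(max_examples=50, derandomize=True)
    def test_neutral_fitness_is_identity(self, p):
        assert replicator_update(p, 0.5) == pytest.approx(p, abs=1e-15)


class TestStepCycle:
    def test_replicator_two_phase_example(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9)
        prop_w, prop_p = step_cycle(0.5, params, mode="replicator")
        assert prop_w == pytest.approx(0.3)
        assert prop_p == pytest.approx(27 / 34)

    def test_literal_matches_printed_product_form(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9, K_W=1e4)
        prop_w, _ = step_cycle(0.5, params, mode="literal")
        assert prop_w * params.K_W == pytest.approx(0.15 * params.K_W)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            step_cycle(0.5, FitnessParameters(w_W_A=0.3, w_P_A=0.9), mode="bogus")


class TestSimulate:
    def test_three_cycle_trajectory(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9, prop_A_initial=0.5)
        traj = simulate(params, n_cycles=3)
        assert traj.prop_P_A[1:] == pytest.approx([0.794, 0.937, 0.983], abs=1e-3)
        assert traj.prop_W_A == pytest.approx([0.3, 0.623, 0.864], abs=1e-3)

    def test_conservation_of_phase_totals(self):
        params = FitnessParameters(w_W_A=0.2, w_P_A=0.8, K_W=1e4, K_P=1e9)
        traj = simulate(params, n_cycles=10)
        assert np.allclose(traj.n_P_A + traj.n_P_B, params.K_P)
        assert np.allclose(traj.n_W_A + traj.n_W_B, params.K_W)

    def test_neutral_parameters_are_fixed_point(self):
        params = FitnessParameters(w_W_A=0.5, w_P_A=0.5, prop_A_initial=0.37)
        traj = simulate(params, n_cycles=8)
        assert np.allclose(traj.prop_P_A, 0.37)
        assert np.allclose(traj.prop_W_A, 0.37)

    @given(
        w_w=st.floats(0.5, 0.95),
        w_p=st.floats(0.55, 0.95),
        p0=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, derandomize=True)
    def test_plate_monotone_increase_when_favoured(self, w_w, w_p, p0):
        params = FitnessParameters(w_W_A=w_w, w_P_A=w_p, prop_A_initial=p0)
        traj = simulate(params, n_cycles=12)
        p = np.concatenate([[traj.prop_P_A[0]], traj.prop_P_A[1:]])
        diffs = np.diff(p)
        assert all(d > 0 or p[i + 1] > 1 - 1e-12 for i, d in enumerate(diffs))

    def test_literal_mode_declines_with_subunit_fitness(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9, prop_A_initial=0.5)
        traj = simulate(params, n_cycles=5, mode="literal")
        assert np.all(np.diff(traj.prop_P_A) < 0)

    @given(
        w_w=st.floats(0.05, 0.95),
        w_p=st.floats(0.05, 0.95),
        p0=st.floats(0.05, 0.95),
    )
    @settings(max_examples=60, derandomize=True)
    def test_odds_oracle_equivalence(self, w_w, w_p, p0):
        params = FitnessParameters(w_W_A=w_w, w_P_A=w_p, prop_A_initial=p0)
        traj = simulate(params, n_cycles=10)
        worm, plate = odds_oracle(p0, w_w, w_p, 10)
        assert np.max(np.abs(traj.prop_W_A - worm)) < 1e-12
        assert np.max(np.abs(traj.prop_P_A[1:] - plate)) < 1e-12

    @given(
        w_w=st.floats(0.05, 0.95),
        w_p=st.floats(0.05, 0.95),
        p0=st.floats(0.05, 0.95),
    )
    @settings(max_examples=40, derandomize=True)
    def test_species_relabelling_symmetry(self, w_w, w_p, p0):
        a = simulate(FitnessParameters(w_W_A=w_w, w_P_A=w_p, prop_A_initial=p0), 8)
        b = simulate(
            FitnessParameters(
                w_W_A=1 - w_w, w_P_A=1 - w_p, prop_A_initial=1 - p0
            ),
            8,
        )
        assert np.allclose(a.prop_W_A, 1 - b.prop_W_A, atol=1e-12)
        assert np.allclose(a.prop_P_A, 1 - b.prop_P_A, atol=1e-12)


class TestMilestone:
    def test_toy_sequences(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9, prop_A_initial=0.5)
        traj = simulate(params, n_cycles=3)
        assert milestone(traj, "worm", 0.5) == 2
        assert milestone(traj, "plate", 0.99) is None  # max is 0.982

    def test_strict_crossing_required(self):
        traj = simulate(FitnessParameters(w_W_A=0.5, w_P_A=0.5), n_cycles=5)
        assert milestone(traj, "worm", 0.5) is None

    def test_threshold_domain(self):
        traj = simulate(FitnessParameters(w_W_A=0.3, w_P_A=0.9), n_cycles=2)
        with pytest.raises(ValueError):
            milestone(traj, "worm", 1.0)


class TestStochastic:
    def test_seed_reproducibility(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9)
        a = simulate_stochastic(params, n_cycles=5, seed=7, n_runs=20)
        b = simulate_stochastic(params, n_cycles=5, seed=7, n_runs=20)
        assert np.array_equal(a.prop_P_A, b.prop_P_A)
        assert np.array_equal(a.prop_W_A, b.prop_W_A)

    def test_extinction_is_absorbing(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9, prop_A_initial=0.0)
        ens = simulate_stochastic(params, n_cycles=6, seed=1, n_runs=10)
        assert np.all(ens.prop_P_A == 0.0)
        assert np.all(ens.prop_W_A == 0.0)

    def test_large_population_limit_matches_deterministic(self):
        params = FitnessParameters(w_W_A=0.35, w_P_A=0.85)
        det = simulate(params, n_cycles=8)
        ens = simulate_stochastic(
            params,
            n_cycles=8,
            transfer_fraction=1.0,
            n_worm_founders=10**7,
            seed=3,
            n_runs=100,
        )
        mean = ens.prop_W_A.mean(axis=0)
        se = ens.prop_W_A.std(axis=0, ddof=1) / np.sqrt(ens.n_runs)
        assert np.all(np.abs(mean - det.prop_W_A) <= 3 * se + 1e-9)

    def test_invalid_arguments(self):
        params = FitnessParameters(w_W_A=0.3, w_P_A=0.9)
        with pytest.raises(ValueError):
            simulate_stochastic(params, transfer_fraction=0.0)
        with pytest.raises(ValueError):
            simulate_stochastic(params, n_worm_founders=0)
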