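import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statesim import (
    RandomStream,
    SimulationConfig,
    generate_fixture,
    parse_stt,
    propagate,
    recorded_ages,
    resolve_seed,
    simulate_cohort,
    simulate_individual,
    step,
)


class TestRandomStream:
    def test_equal_seeds_give_identical_sequences(self):
        a, b = RandomStream(7), RandomStream(7)
        assert [a.next_uniform() for _ in range(10_000)] == [b.next_uniform() for _ in range(10_000)]

    def test_variates_in_unit_interval_and_position_counted(self):
        s = RandomStream(0)
        u = s.uniforms(5_000)
        assert ((0 <= u) & (u < 1)).all()
        assert s.position == 5_000

    def test_empirical_mean_near_half(self):
        # CLT: 3 sigma for 1e6 uniforms is 3/(sqrt(12)*1e3) < 0.001
        u = RandomStream(123).uniforms(1_000_000)
        assert abs(u.mean() - 0.5) < 0.002

    def test_block_draws_match_scalar_draws(self):
        block = RandomStream(99).uniforms((3, 4))
        scalar = RandomStream(99)
        expected = np.array([[scalar.next_uniform() for _ in range(4)] for _ in range(3)])
        assert np.array_equal(block, expected)

    def test_clock_seed_resolves_to_fresh_integers(self):
        seeds = {resolve_seed("clock") for _ in range(3)}
        assert all(0 <= s < 2**31 for s in seeds)
        assert resolve_seed(17) == 17


class TestStep:
    @pytest.mark.parametrize(
        "age, u, expected",
        [
            (15, 0.03, "symp"),
            (15, 0.05, "treated"),  # boundary draw is left-closed
            (15, 0.1199, "treated"),
            (15, 0.40, "occult"),  # residual stay mass 0.88
            (50, 0.06, "treated"),  # only one rule active in [40, 80)
            (50, 0.08, "occult"),
            (85, 0.0, "occult"),  # outside every band
        ],
    )
    def test_occult_cumulative_intervals(self, example_model, age, u, expected):
        assert step(example_model, "occult", age, u) == expected

    def test_absorbing_state_always_stays(self, example_model):
        assert step(example_model, "treated", 30, 0.999) == "treated"

    def test_explicit_self_rule_not_laid_as_interval(self):
        # with the self rule laid first, u=0.1 would wrongly stay
        model = parse_stt("a a 0 10 0.8\na b 0 10 0.2")
        assert step(model, "a", 5, 0.1) == "b"
        assert step(model, "a", 5, 0.25) == "a"

    def test_unknown_state_raises(self, example_model):
        with pytest.raises(KeyError):
            step(example_model, "nosuch", 15, 0.5)


class _FixedStream:
    """Stand-in stream returning scripted draws."""

    def __init__(self, values):
        self.values = list(values)
        self.position = 0

    def next_uniform(self):
        self.position += 1
        return self.values.pop(0)


class TestSimulateIndividual:
    def test_one_step_transition_on_low_draw(self, twostate_model):
        cfg = SimulationConfig(20, 21, 1, 1, initialstate="normal")
        traj = simulate_individual(twostate_model, cfg, _FixedStream([0.3]), id=1)
        assert traj.states == ("normal", "cin1")

    def test_one_step_stay_on_high_draw(self, twostate_model):
        cfg = SimulationConfig(20, 21, 1, 1, initialstate="normal")
        traj = simulate_individual(twostate_model, cfg, _FixedStream([0.7]), id=1)
        assert traj.states == ("normal", "normal")

    def test_start_in_alternative_state(self, example_model):
        cfg = SimulationConfig(12, 14, 2, 1, initialstate="cin1")
        traj = simulate_individual(example_model, cfg, _FixedStream([0.9]), id=1)
        assert traj.states == ("cin1", "cin1")  # 0.9 >= 0.3, stays

    def test_exactly_one_variate_per_step_even_when_absorbed(self, example_model):
        cfg = SimulationConfig(12, 80, 2, 1, initialstate="normal")
        stream = RandomStream(1)
        traj = simulate_individual(example_model, cfg, stream, id=1)
        assert len(traj.states) == len(recorded_ages(cfg))
        assert stream.position == len(recorded_ages(cfg)) - 1


class TestSimulateCohort:
    def test_example_run_shape(self, example_model):
        cfg = SimulationConfig(12, 80, 2, 5, initialstate="normal")
        cohort = simulate_cohort(example_model, cfg)
        assert cohort.number == 5
        assert [t.id for t in cohort.trajectories] == [1, 2, 3, 4, 5]
        assert all(len(t.states) == 35 for t in cohort.trajectories)
        assert all(t.states[0] == "normal" for t in cohort.trajectories)

    def test_one_step_fraction_within_binomial_envelope(self, twostate_model, twostate_config):
        cohort = simulate_cohort(twostate_model, twostate_config)
        frac = cohort.counts_at(21).get("cin1", 0) / 1000
        assert 0.45 <= frac <= 0.55  # 3 sigma around 0.5 at n=1000

    def test_same_seed_gives_identical_cohort(self, twostate_model, twostate_config):
        assert simulate_cohort(twostate_model, twostate_config) == simulate_cohort(
            twostate_model, twostate_config
        )

    def test_seed_argument_overrides_config(self, twostate_model, twostate_config):
        a = simulate_cohort(twostate_model, twostate_config, seed=1)
        b = simulate_cohort(twostate_model, twostate_config, seed=2)
        c = simulate_cohort(twostate_model, twostate_config, seed=1)
        assert a == c and a != b

    def test_matches_sequential_individuals_on_shared_stream(self, example_model):
        """The vectorized cohort path must consume the exact same draws as
        simulating individuals one after the other without resetting."""
        cfg = SimulationConfig(12, 80, 2, 50, initialstate="normal", seed=11)
        cohort = simulate_cohort(example_model, cfg)
        stream = RandomStream(11)
        for traj in cohort.trajectories:
            expected = simulate_individual(example_model, cfg, stream, traj.id)
            assert traj.states == expected.states
        assert stream.position == 50 * cfg.n_steps

    def test_variates_consumed_depends_only_on_geometry(self, example_model):
        # an all-absorbed cohort and a busy one consume the same stream length
        cfg = SimulationConfig(12, 80, 2, 20, initialstate="normal", seed=3)
        follow_on = RandomStream(3)
        follow_on.uniforms((20, cfg.n_steps))
        marker = follow_on.next_uniform()
        for initial in ("normal", "cin1"):
            cfg_i = SimulationConfig(12, 80, 2, 20, initialstate=initial, seed=3)
            simulate_cohort(example_model, cfg_i)
            s = RandomStream(3)
            s.uniforms((20, cfg_i.n_steps))
            assert s.next_uniform() == marker

    def test_absorbing_closure(self, example_model):
        cfg = SimulationConfig(12, 80, 2, 200, initialstate="normal", seed=5)
        cohort = simulate_cohort(example_model, cfg)
        for traj in cohort.trajectories:
            for absorbing in ("symp", "treated"):
                if absorbing in traj.states:
                    k = traj.states.index(absorbing)
                    assert set(traj.states[k:]) == {absorbing}

    def test_invalid_model_rejected(self):
        model = parse_stt("a b 0 10 0.7\na c 0 10 0.7")
        cfg = SimulationConfig(0, 10, 1, 5, initialstate="a")
        with pytest.raises(ValueError, match="validation"):
            simulate_cohort(model, cfg)

    def test_empty_model_rejected(self):
        cfg = SimulationConfig(0, 10, 1, 5, initialstate="a")
        with pytest.raises(ValueError, match="no rules"):
            simulate_cohort(parse_stt(""), cfg)


class TestAgainstAnalyticOracle:
    def test_two_state_closed_form(self, twostate_model):
        """P(left initial state after k steps) = 1 - (1-p)^k."""
        cfg = SimulationConfig(20, 26, 1, 100_000, initialstate="normal", seed=21)
        cohort = simulate_cohort(twostate_model, cfg)
        for k, age in enumerate(recorded_ages(cfg)):
            expected = 1 - 0.5**k
            frac = cohort.counts_at(age).get("cin1", 0) / cfg.number
            sigma = np.sqrt(expected * (1 - expected) / cfg.number)
            assert abs(frac - expected) <= 4 * sigma + 1e-12

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2**16))
    def test_empirical_frequencies_match_propagation(self, seed):
        model, cfg = generate_fixture(n_states=4, n_rules=6, seed=seed, number=20_000)
        cohort = simulate_cohort(model, cfg)
        for dist in propagate(model, cfg):
            counts = cohort.counts_at(dist.age)
            for s in model.states:
                p = dist.mass.get(s, 0.0)
                sigma = np.sqrt(p * (1 - p) / cfg.number)
                assert abs(counts.get(s, 0) / cfg.number - p) <= 4 * sigma + 1e-12
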