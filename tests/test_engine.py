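"""Engine: determinism, update-order semantics, delays, clamps, summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats

import stomasim as ss
from stomasim import rules as R
from stomasim.fixtures import build_model
from stomasim.model import NodeSpec


def _n(name, max_level=1, initial=0, role="internal", delay=0):
    return NodeSpec(name=name, max_level=max_level, initial_level=initial,
                    role=role, delay_steps=delay)


class TestDeterminism:
    def test_same_seed_identical_ensembles(self, toys):
        cfg = ss.ExperimentConfig(n_steps=8, n_replicates=50, seed=42)
        a = ss.run_ensemble(toys["oscillator"], cfg)
        b = ss.run_ensemble(toys["oscillator"], cfg)
        assert np.array_equal(a.levels, b.levels)

    def test_different_seeds_differ(self, toys):
        a = ss.run_ensemble(toys["oscillator"],
                            ss.ExperimentConfig(n_steps=8, n_replicates=50, seed=1))
        b = ss.run_ensemble(toys["oscillator"],
                            ss.ExperimentConfig(n_steps=8, n_replicates=50, seed=2))
        assert not np.array_equal(a.levels, b.levels)

    def test_guard_cell_bit_identical(self, guard_cell):
        cfg = ss.ExperimentConfig(n_steps=18, n_replicates=20, seed=7,
                                  signal_levels=ss.condition_signals("dual"))
        a = ss.run_ensemble(guard_cell, cfg)
        b = ss.run_ensemble(guard_cell, cfg)
        assert np.array_equal(a.levels, b.levels)


class TestUpdateSemantics:
    def test_chain_saturates_within_three_steps(self, toys):
        cfg = ss.ExperimentConfig(n_steps=3, n_replicates=40, seed=0,
                                  signal_levels={"S": 1})
        ens = ss.run_ensemble(toys["chain"], cfg)
        assert np.all(ens.levels[:, -1, :] == 1)

    def test_output_updated_last_sees_same_step_state(self):
        # O copies A; because the output updates after the internals, it
        # equals A's *new* value already at step 1
        m = build_model([_n("S", role="signal"), _n("A"), _n("O", role="output")],
                        {"A": "S", "O": "A"})
        traj = ss.run_replicate(m, ss.ExperimentConfig(
            n_steps=2, n_replicates=1, seed=0, signal_levels={"S": 1}))
        names = m.node_names
        assert traj[1][names.index("A")] == 1
        assert traj[1][names.index("O")] == 1

    def test_degenerate_zero_steps_returns_initial_state(self, toys):
        cfg = ss.ExperimentConfig(n_steps=0, n_replicates=5, seed=0)
        ens = ss.run_ensemble(toys["oscillator"], cfg)
        assert ens.levels.shape[1] == 1
        assert np.all(ens.node_levels("A") == 1)

    def test_mutual_inhibition_resolves_evenly(self, toys):
        # symmetric start: random order picks a winner; ~50/50 at large n
        cfg = ss.ExperimentConfig(n_steps=6, n_replicates=2000, seed=5)
        ens = ss.run_ensemble(toys["oscillator"], cfg)
        a_wins = float(np.mean(ens.node_levels("A")[:, -1]))
        assert 0.45 < a_wins < 0.55
        # every replicate is at one of the two fixed points
        final_a = ens.node_levels("A")[:, -1]
        final_b = ens.node_levels("B")[:, -1]
        assert np.all(final_a + final_b == 1)

    def test_fixed_points_persist(self, toys):
        cfg = ss.ExperimentConfig(n_steps=12, n_replicates=30, seed=9,
                                  signal_levels={"S": 1})
        ens = ss.run_ensemble(toys["chain"], cfg)
        # once every rule is satisfied (by step 3) nothing changes
        for t in range(4, 13):
            assert np.array_equal(ens.levels[:, t, :], ens.levels[:, 3, :])

    def test_step1_distribution_matches_permutation_oracle(self):
        """Random-order update = uniform sampling of update sequences.

        For a cascade X=1, Y=X, Z=Y (all initially 0) the step-1 outcome
        is decided entirely by the drawn permutation, so exhaustive
        enumeration of the 6 orders gives the exact distribution:
        P(Z=1)=1/6 (X<Y<Z), P(Y=1,Z=0)=1/3, P(Y=0)=1/2.
        """
        m = build_model(
            [_n("X"), _n("Y"), _n("Z"), _n("O", role="output")],
            {"X": "1", "Y": "X", "Z": "Y", "O": "Z"})
        internal = ["X", "Y", "Z"]
        # oracle: enumerate permutations, sequential interpreted updates
        outcomes = {}
        for perm in itertools.permutations(internal):
            state = {n: 0.0 for n in m.node_names}
            for node in perm:
                state[node] = R.evaluate(m.rules[node], state, 0, 1)
            key = tuple(state[n] for n in internal)
            outcomes[key] = outcomes.get(key, 0) + 1
        expected = {k: v / 6 for k, v in outcomes.items()}

        cfg = ss.ExperimentConfig(n_steps=1, n_replicates=6000, seed=11)
        ens = ss.run_ensemble(m, cfg)
        idx = [ens.node_names.index(n) for n in internal]
        observed: dict[tuple, int] = {}
        for row in ens.levels[:, 1, idx]:
            key = tuple(row)
            observed[key] = observed.get(key, 0) + 1
        assert set(observed) == set(expected)
        keys = sorted(expected)
        chi = stats.chisquare([observed[k] for k in keys],
                              [expected[k] * 6000 for k in keys])
        assert chi.pvalue > 1e-3


class TestSignalsClampsDelays:
    def test_clamped_node_holds_level_every_step(self, guard_cell):
        cfg = ss.ExperimentConfig(
            n_steps=12, n_replicates=15, seed=3,
            signal_levels=ss.condition_signals("dual"),
            clamps={"H_ATPase_complex": 9.0, "sucrose": 0.0})
        ens = ss.run_ensemble(guard_cell, cfg)
        assert np.all(ens.node_levels("H_ATPase_complex") == 9)
        assert np.all(ens.node_levels("sucrose") == 0)

    def test_clamp_outside_range_rejected(self, guard_cell):
        cfg = ss.ExperimentConfig(clamps={"sucrose": 7})
        with pytest.raises(ValueError, match="outside"):
            ss.run_ensemble(guard_cell, cfg)

    def test_signal_level_outside_range_rejected(self, guard_cell):
        cfg = ss.ExperimentConfig(signal_levels={"CO2": 5})
        with pytest.raises(ValueError, match="outside"):
            ss.run_ensemble(guard_cell, cfg)

    def test_schedule_change_points_persist(self, toys):
        cfg = ss.ExperimentConfig(n_steps=6, n_replicates=10, seed=0,
                                  signal_schedule={"S": {2: 1, 4: 0}})
        ens = ss.run_ensemble(toys["chain"], cfg)
        s = ens.node_levels("S")[0]
        assert list(s) == [0, 0, 1, 1, 0, 0, 0]

    def test_delay_lags_regulator_lookup(self):
        # A copies S with a 3-step delay: S switches on at step 2, so the
        # lagged lookup first sees it at step 5 (instead of step 2)
        lagged = build_model([_n("S", role="signal"), _n("A", delay=3),
                              _n("O", role="output")],
                             {"A": "S", "O": "A"})
        cfg = ss.ExperimentConfig(n_steps=8, n_replicates=4, seed=0,
                                  signal_schedule={"S": {2: 1}})
        ens = ss.run_ensemble(lagged, cfg)
        a = ens.node_levels("A")[0]
        assert list(a) == [0, 0, 0, 0, 0, 1, 1, 1, 1]

    def test_prehistory_equals_initial_state(self):
        # signal already on at step 0: the lagged lookup reads the
        # initial state, so the delayed node responds immediately
        lagged = build_model([_n("S", role="signal"), _n("A", delay=5),
                              _n("O", role="output")],
                             {"A": "S", "O": "A"})
        cfg = ss.ExperimentConfig(n_steps=3, n_replicates=4, seed=0,
                                  signal_levels={"S": 1})
        ens = ss.run_ensemble(lagged, cfg)
        assert list(ens.node_levels("A")[0]) == [0, 1, 1, 1]


class TestContainmentAndStats:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_levels_stay_in_declared_ranges(self, seed):
        m = ss.random_model(n_nodes=8, edge_density=0.4, max_level=3, seed=seed)
        cfg = ss.ExperimentConfig(n_steps=10, n_replicates=30, seed=seed,
                                  signal_levels={"n0": 1})
        ens = ss.run_ensemble(m, cfg)
        for node in m.nodes:
            levels = ens.node_levels(node.name)
            assert levels.min() >= node.min_level
            assert levels.max() <= node.max_level

    def test_guard_cell_levels_stay_in_ranges(self, guard_cell):
        cfg = ss.ExperimentConfig(n_steps=18, n_replicates=40, seed=2,
                                  signal_levels=ss.condition_signals("dual", 0, 1))
        ens = ss.run_ensemble(guard_cell, cfg)
        for node in guard_cell.nodes:
            levels = ens.node_levels(node.name)
            assert levels.min() >= node.min_level
            assert levels.max() <= node.max_level
            if node.kind == "integer":
                assert np.all(levels == np.round(levels))

    def test_mean_and_sem_consistent_with_levels(self, toys):
        cfg = ss.ExperimentConfig(n_steps=5, n_replicates=64, seed=8)
        ens = ss.run_ensemble(toys["oscillator"], cfg)
        assert np.allclose(ens.mean_trajectory, ens.levels.mean(axis=0))
        assert np.allclose(ens.sem_trajectory,
                           ens.levels.std(axis=0, ddof=1) / 8.0)

    def test_sem_shrinks_with_replicates(self, guard_cell):
        # across-replicate dispersion is largest mid-rise; the SEM there
        # must fall as the ensemble grows
        sems = []
        for n in (60, 240, 960):
            cfg = ss.ExperimentConfig(n_steps=8, n_replicates=n, seed=4,
                                      signal_levels=ss.condition_signals("dual"))
            ens = ss.run_ensemble(guard_cell, cfg)
            j = ens.node_names.index("stomatal_opening")
            sems.append(float(ens.sem_trajectory[5, j]))
        assert sems[0] > sems[1] > sems[2]
        # 16x more replicates: SEM should drop by roughly 4 (allow 2.5-6.5)
        assert 2.5 < sems[0] / sems[2] < 6.5


class TestSummaries:
    def test_step_change_pins_attainment_times(self):
        # every replicate jumps 0 -> max at the same step k: t50 = t95 = k
        levels = np.zeros((10, 6, 1))
        levels[:, 3:, 0] = 4.0
        ens = ss.EnsembleResult(levels=levels, node_names=["x"],
                                config=ss.ExperimentConfig())
        s = ss.summarize(ens, "x")
        assert (s.max_level, s.t50, s.t95) == (4.0, 3, 3)

    def test_flat_zero_reports_zeros(self, guard_cell):
        cfg = ss.ExperimentConfig(n_steps=10, n_replicates=10, seed=0,
                                  signal_levels=ss.condition_signals("dark"))
        ens = ss.run_ensemble(guard_cell, cfg)
        s = ss.summarize(ens, "stomatal_opening")
        assert (s.max_level, s.t50, s.t95) == (0.0, 0, 0)

    def test_unknown_node_raises(self, toys):
        ens = ss.run_ensemble(toys["chain"],
                              ss.ExperimentConfig(n_steps=2, n_replicates=3, seed=0))
        with pytest.raises(KeyError):
            ss.summarize(ens, "nope")

    def test_tidy_frame_shape(self, toys):
        ens = ss.run_ensemble(toys["chain"],
                              ss.ExperimentConfig(n_steps=2, n_replicates=3, seed=0))
        df = ens.to_frame()
        assert len(df) == 3 * 3 * 4
        assert set(df.columns) == {"replicate", "step", "node", "level"}


class TestSynchronousOracle:
    def test_cycle_rotates_under_synchronous_update(self, toys):
        m = toys["cycle3"]
        state = m.initial_state()  # A on, B and C off
        seen = [dict(state)]
        for _ in range(3):
            state = ss.engine.synchronous_step(m, state)
            seen.append(dict(state))
        # the single ON token rotates A -> B -> C -> A
        assert [s["A"] for s in seen] == [1, 0, 0, 1]
        assert [s["B"] for s in seen] == [0, 1, 0, 0]
        assert [s["C"] for s in seen] == [0, 0, 1, 0]
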