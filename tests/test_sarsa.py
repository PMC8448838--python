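"""Policy rewards, SARSA updates, roulette selection and the dataset."""

import math

import numpy as np
import pytest

import tmesim as ts
from tmesim import sarsa as sr


class TestPolicyStateValue:
    def _cell(self, grid, rng, **over):
        ts.seed_tumor(grid, 1, rng)
        cell = grid.cells.agent(0)
        for k, v in over.items():
            setattr(cell, k, v)
        return cell

    def test_division_counter_is_raw(self, tiny_grid, rng):
        cell = self._cell(tiny_grid, rng, divctr=50)
        rule = next(r for r in sr.cell_rules() if r.id == 7)
        site = divmod(int(cell.tme), tiny_grid.n)
        x = sr.policy_state_value(cell, tiny_grid.tme(*site), rule,
                                  tiny_grid.config.scales())
        assert x == 50.0

    def test_vessel_age_is_raw(self, tiny_grid):
        from tmesim.agents import VesselSystem

        vs = VesselSystem(tiny_grid)
        tip = vs.spawn_tip([100.0, 100.0])
        tip.age = 18
        rule = next(r for r in sr.VESSEL_RULES if r.id == 6)
        x = sr.policy_state_value(tip, tiny_grid.tme(0, 0), rule,
                                  tiny_grid.config.scales())
        assert x == 18.0

    def test_oxygen_scaled_to_threshold_at_boundary(self, tiny_grid, rng):
        cell = self._cell(tiny_grid, rng)
        scales = tiny_grid.config.scales()
        tiny_grid.conc[0] = 1.175 * scales["oxygen"]
        site = divmod(int(cell.tme), tiny_grid.n)
        rule = next(r for r in sr.cell_rules() if r.id == 1)
        x = sr.policy_state_value(cell, tiny_grid.tme(*site), rule, scales)
        assert x == pytest.approx(1.175)

    def test_inapplicable_rule_rejected(self, tiny_grid, rng):
        cell = self._cell(tiny_grid, rng)
        rule = next(r for r in sr.VESSEL_RULES if r.id == 5)
        with pytest.raises(ValueError):
            sr.policy_state_value(cell, tiny_grid.tme(0, 0), rule,
                                  tiny_grid.config.scales())


class TestComputeReward:
    RULES = sr.cell_rules(carrying_capacity=100)

    def _values(self, **over):
        base = {"oxygen": 2.35, "glucose": 32.0, "tnfa_eff": 0.0,
                "tgfa_eff": 0.0, "division_counter": 0.0,
                "proliferation_delay": 0.0, "oxygen_deficiency": 0.0,
                "neighbors": 0.0}
        base.update(over)
        return base

    def test_at_threshold_contribution_is_zero(self):
        rule = next(r for r in self.RULES if r.id == 7)
        assert rule.contribution(50.0, "quiescence") == 0.0
        assert rule.contribution(50.0, "proliferation") == 0.0

    def test_rule7_above_threshold(self):
        rule = next(r for r in self.RULES if r.id == 7)
        assert rule.contribution(52.0, "quiescence") == pytest.approx(
            math.tanh(2.0))
        assert rule.contribution(52.0, "proliferation") == pytest.approx(
            -math.tanh(2.0))

    def test_unmentioned_action_contributes_zero(self):
        rule = next(r for r in self.RULES if r.id == 7)
        assert rule.contribution(52.0, "hypoxia") == 0.0

    def test_reward_is_sum_over_rules(self):
        vals = self._values(division_counter=52.0)
        r = sr.compute_reward(vals, "quiescence", self.RULES)
        manual = sum(rule.contribution(vals[rule.variable], "quiescence")
                     for rule in self.RULES)
        assert r == pytest.approx(manual)

    def test_reward_matrix_matches_rule_sum(self, rng):
        vals = {k: rng.random(20) * s for k, s in (
            ("oxygen", 4), ("glucose", 40), ("tnfa_eff", 2), ("tgfa_eff", 2),
            ("division_counter", 100), ("proliferation_delay", 10),
            ("oxygen_deficiency", 100), ("neighbors", 100))}
        mat = sr.cell_reward_matrix(vals, carrying_capacity=100)
        for i in range(20):
            row_vals = {k: float(v[i]) for k, v in vals.items()}
            for a, name in enumerate(ts.CELL_PHENOTYPES):
                assert mat[i, a] == pytest.approx(
                    sr.compute_reward(row_vals, name, self.RULES), abs=1e-12)

    def test_vessel_reward_matrix(self):
        mat = sr.vessel_reward_matrix(np.array([0.5]), np.array([20.0]),
                                      np.array([True]))
        assert mat[0, 2] == pytest.approx(math.tanh(0.2))  # sprout
        assert mat[0, 1] == pytest.approx(math.tanh(2.0))  # branch (tip)
        stalk = sr.vessel_reward_matrix(np.array([0.5]), np.array([20.0]),
                                        np.array([False]))
        assert stalk[0, 1] == 0.0  # rule 6 does not apply to stalks


class TestSarsaUpdate:
    def test_zero_learning_rate_is_identity(self):
        q = np.ones((3, 2))
        sr.sarsa_update(q, 0, 0, 5.0, 1, 1, alpha=0.0, gamma=0.9)
        assert q[0, 0] == 1.0

    def test_full_replacement(self):
        q = np.zeros((3, 2))
        q[1, 1] = 2.0
        sr.sarsa_update(q, 0, 0, 1.0, 1, 1, alpha=1.0, gamma=0.9)
        assert q[0, 0] == pytest.approx(1.0 + 0.9 * 2.0)

    def test_hand_arithmetic(self):
        q = np.zeros((2, 1))
        q[0, 0], q[1, 0] = 1.0, 2.0
        out = sr.sarsa_update(q, 0, 0, 1.0, 1, 0, alpha=0.5, gamma=0.9)
        assert out == pytest.approx(0.5 * 1.0 + 0.5 * (1.0 + 1.8))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            sr.sarsa_update(np.zeros((2, 2)), 0, 0, 0.0, 1, 1, alpha=1.5, gamma=0.9)

    def test_batch_update_equals_sequential_oracle(self, rng):
        """The grouped formula reproduces scalar sequential updates exactly."""
        for _ in range(10):
            q0 = rng.normal(size=(4, 3))
            m = 50
            s = rng.integers(0, 4, m)
            a = rng.integers(0, 3, m)
            targets = rng.normal(size=m)
            order = rng.permutation(m)
            alpha = 0.3
            q_seq = q0.copy()
            for j in order:
                q_seq[s[j], a[j]] = ((1 - alpha) * q_seq[s[j], a[j]]
                                     + alpha * targets[j])
            q_batch = q0.copy()
            sr.batch_sarsa_update(q_batch, s, a, targets, alpha, order)
            assert np.allclose(q_batch, q_seq, atol=1e-12)


class TestRouletteSelection:
    def test_printed_scheme_proportions(self):
        """Q = {a: 1, b: 3}: P(b) converges to 0.75 (binomial oracle)."""
        rng = np.random.default_rng(0)
        draws = np.array([sr.weighted_random_action(np.array([1.0, 3.0]), rng)
                          for _ in range(100_000)])
        assert abs((draws == 1).mean() - 0.75) < 0.01

    def test_all_equal_is_uniform(self):
        rng = np.random.default_rng(1)
        draws = np.array([sr.weighted_random_action(np.zeros(4), rng)
                          for _ in range(20_000)])
        freq = np.bincount(draws, minlength=4) / draws.size
        assert np.allclose(freq, 0.25, atol=0.02)

    def test_single_action(self):
        rng = np.random.default_rng(2)
        assert sr.weighted_random_action(np.array([0.3]), rng) == 0

    def test_empty_action_set_rejected(self):
        with pytest.raises(ValueError):
            sr.weighted_random_action(np.array([]), np.random.default_rng(0))

    def test_negative_q_shifted(self):
        rng = np.random.default_rng(3)
        draws = np.array([sr.weighted_random_action(np.array([-2.0, 0.0]), rng)
                          for _ in range(50_000)])
        # shifted weights {eps, 2+eps}: the worst action almost never fires
        assert (draws == 0).mean() < 0.001

    def test_vectorized_frequencies_match_chi2(self):
        """Frequencies match shifted-Q proportions (χ², p > 0.01, 1e5 draws)."""
        from scipy import stats

        rng = np.random.default_rng(4)
        q = np.array([0.5, 1.5, 2.0])
        rows = np.tile(q, (100_000, 1))
        actions = sr.roulette_select(rows, rng)
        observed = np.bincount(actions, minlength=3)
        expected = q / q.sum() * actions.size
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_vectorized_respects_availability(self):
        rng = np.random.default_rng(5)
        rows = np.tile(np.array([5.0, 1.0, 1.0]), (1000, 1))
        avail = np.tile(np.array([False, True, True]), (1000, 1))
        actions = sr.roulette_select(rows, rng, avail)
        assert (actions != 0).all()


class TestStateIndex:
    def test_cell_state_bits(self):
        vals = {"oxygen": np.array([2.0]), "glucose": np.array([20.0]),
                "tnfa_eff": np.array([0.0]), "tgfa_eff": np.array([1.0]),
                "division_counter": np.array([0.0]),
                "proliferation_delay": np.array([0.0]),
                "oxygen_deficiency": np.array([0.0])}
        s = sr.cell_state_index(vals)
        # bits: o2=1, glu>16=1, glu>8=1, tnfa=0, tgfa=1, div=0, delay=0, o2t=0
        assert s[0] == int("11101000", 2)

    def test_vessel_state_bits(self):
        assert sr.vessel_state_index(np.array(0.5), np.array(20.0)) == 3
        assert sr.vessel_state_index(np.array(0.1), np.array(5.0)) == 0


class TestExperienceDataset:
    def _record(self):
        return np.arange(len(sr.CELL_RECORD_COLUMNS), dtype=float)

    def test_reward_at_threshold_not_appended(self):
        ds = sr.ExperienceDataset("cell")
        ds.append(self._record(), np.array([0.0]), threshold=0.0, repetition=0)
        assert len(ds) == 0

    def test_reward_above_threshold_appended(self):
        ds = sr.ExperienceDataset("cell")
        ds.append(self._record(), np.array([1.0]), threshold=0.0, repetition=0)
        assert len(ds) == 1

    def test_counting_oracle(self, rng):
        ds = sr.ExperienceDataset("cell")
        rewards = np.concatenate([rng.uniform(0.1, 1, 40), rng.uniform(-1, -0.1, 60)])
        records = np.tile(self._record(), (100, 1))
        ds.append(records, rewards, threshold=0.0, repetition=2)
        assert len(ds) == 40
        assert (ds.to_frame()["repetition"] == 2).all()

    def test_schema_mismatch_rejected(self):
        ds = sr.ExperienceDataset("vessel")
        with pytest.raises(ValueError):
            ds.append(self._record(), np.array([1.0]), 0.0, 0)

    def test_csv_round_trip(self, tmp_path, rng):
        ds = sr.ExperienceDataset("cell")
        ds.append(np.tile(self._record(), (5, 1)), np.ones(5), 0.0, 0)
        ds.save(tmp_path / "ds")
        import json
        import pandas as pd

        frame = pd.read_csv(tmp_path / "ds.csv")
        schema = json.loads((tmp_path / "ds.schema.json").read_text())
        assert list(frame.columns) == schema["columns"] == ds.columns
        assert len(frame) == 5


class TestSarsaConvergence:
    def test_three_state_chain_reaches_analytic_q(self):
        """Deterministic chain s0→s1→s2(absorbing), reward 1 on the last hop.

        Under the always-advance policy Q*(s1)=1, Q*(s0)=γ.
        """
        gamma, alpha = 0.9, 0.2
        q = np.zeros((3, 1))
        for _ in range(400):
            sr.sarsa_update(q, 0, 0, 0.0, 1, 0, alpha, gamma)
            sr.sarsa_update(q, 1, 0, 1.0, 2, 0, alpha, gamma)
        assert q[1, 0] == pytest.approx(1.0, abs=1e-3)
        assert q[0, 0] == pytest.approx(gamma, abs=1e-3)

    def test_corridor_matches_value_iteration(self):
        """4-state corridor, actions left/right, reward on reaching the end.

        Greedy-from-Q after ε-greedy SARSA matches the value-iteration
        optimum to 1e-3.
        """
        n_states, gamma, alpha = 4, 0.9, 0.1
        terminal = n_states  # absorbing index
        def step(s, a):
            s2 = s + (1 if a == 1 else -1)
            s2 = max(s2, 0)
            if s2 >= n_states - 1:
                return terminal, 1.0
            return s2, 0.0

        # value iteration oracle
        v = np.zeros(n_states + 1)
        for _ in range(500):
            nv = v.copy()
            for s in range(n_states):
                nv[s] = max(step(s, a)[1] + gamma * v[step(s, a)[0]]
                            for a in (0, 1))
            v = nv
        q_star = np.zeros((n_states, 2))
        for s in range(n_states):
            for a in (0, 1):
                s2, r = step(s, a)
                q_star[s, a] = r + gamma * v[s2]

        rng = np.random.default_rng(0)
        q = np.zeros((n_states + 1, 2))
        for episode in range(4000):
            eps = 0.3 if episode < 3000 else 0.0  # GLIE: explore, then greedy
            s = int(rng.integers(n_states))
            a = int(rng.integers(2)) if rng.random() < eps else int(q[s].argmax())
            while s != terminal:
                s2, r = step(s, a)
                a2 = int(rng.integers(2)) if rng.random() < eps else int(q[s2].argmax())
                sr.sarsa_update(q, s, a, r, s2, a2, alpha, gamma)
                s, a = s2, a2
        greedy = q[:n_states].argmax(axis=1)
        assert (greedy == q_star.argmax(axis=1)).all()
        # on-policy values at the greedy actions approach Q*
        assert np.allclose(q[np.arange(n_states), greedy],
                           q_star[np.arange(n_states), greedy], atol=1e-3)
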