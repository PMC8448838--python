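"""Cell/vessel agent mechanics: movement, division, sprouting, anastomosis."""

import numpy as np
import pytest

import tmesim as ts
from tmesim import agents
from tmesim.params import (
    HYPOXIA,
    MIGRATION,
    NECROSIS,
    PROLIFERATION,
    QUIESCENCE,
    V_BRANCH,
    V_QUIESCENCE,
    V_SPROUT,
)


def seeded_grid(n_cells=1, domain_cm=0.1, seed=0, **cfg_over):
    cfg = ts.SimulationConfig(domain_cm=domain_cm, initial_cells=max(n_cells, 1),
                              **cfg_over)
    grid = ts.build_grid(cfg)
    ts.seed_tumor(grid, n_cells, np.random.default_rng(seed))
    ts.init_fields(grid)
    return grid


class TestMooreNeighbors:
    def test_interior_has_eight(self, tiny_grid):
        assert len(agents.moore_neighbors(tiny_grid, (2, 2))) == 8

    def test_corner_has_three(self, tiny_grid):
        assert len(agents.moore_neighbors(tiny_grid, (0, 0))) == 3

    def test_one_by_one_grid_empty(self):
        cfg = ts.SimulationConfig(domain_cm=0.02, initial_cells=1)
        grid = ts.build_grid(cfg)
        assert agents.moore_neighbors(grid, (0, 0)) == []

    def test_invalid_site_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            agents.moore_neighbors(tiny_grid, (9, 9))


class TestSelectDestination:
    def test_strict_maximum_is_deterministic(self, tiny_grid, rng):
        tiny_grid.conc[0][:] = 1.0
        tiny_grid.conc[0][1, 2] = 50.0
        for _ in range(5):
            dest = agents.select_destination_tme(tiny_grid, (2, 2),
                                                 "max-nutrient", False, rng)
            assert dest == (1, 2)

    def test_tie_breaks_are_random(self, tiny_grid, rng):
        tiny_grid.conc[4][:] = 0.5
        picks = {agents.select_destination_tme(tiny_grid, (2, 2), "max-vegf",
                                               False, rng)
                 for _ in range(200)}
        assert len(picks) > 3  # spread over the 9 equal candidates

    def test_vegf_candidates_include_current_site(self, tiny_grid, rng):
        tiny_grid.conc[4][:] = 0.0
        tiny_grid.conc[4][2, 2] = 9.0
        assert agents.select_destination_tme(tiny_grid, (2, 2), "max-vegf",
                                             False, rng) == (2, 2)

    def test_no_space_returns_none(self, rng):
        grid = seeded_grid(1)
        occ = np.full((grid.n, grid.n), grid.config.carrying_capacity)
        dest = agents.select_destination_tme(grid, (2, 2), "max-nutrient",
                                             True, rng, occupancy=occ)
        assert dest is None


class TestCellExecution:
    def test_migration_45um_arrives_in_one_episode(self, rng):
        grid = seeded_grid(1)
        cell = grid.cells.agent(0)
        cell.phenotype = MIGRATION
        cell.committed = True
        start = cell.pos.copy()
        grid.cells.dest[0] = start + np.array([45.0, 0.0])
        delta = agents.execute_cell_phenotype(cell, grid, rng)
        assert delta["arrived"]
        assert not cell.committed

    def test_migration_90um_takes_two_episodes(self, rng):
        grid = seeded_grid(1)
        cell = grid.cells.agent(0)
        cell.phenotype = MIGRATION
        cell.committed = True
        grid.cells.dest[0] = grid.cells.pos[0] + np.array([0.0, 90.0])
        d1 = agents.execute_cell_phenotype(cell, grid, rng)
        assert d1["moved"] and not d1["arrived"]
        cell.committed = True
        cell.phenotype = MIGRATION
        d2 = agents.execute_cell_phenotype(cell, grid, rng)
        assert d2["arrived"]

    def test_committed_migrator_moves_at_fixed_speed(self, rng):
        grid = seeded_grid(1)
        cell = grid.cells.agent(0)
        cell.phenotype = MIGRATION
        cell.committed = True
        start = grid.cells.pos[0].copy()
        grid.cells.dest[0] = start + np.array([200.0, 0.0])
        agents.execute_cell_phenotype(cell, grid, rng)
        assert np.hypot(*(grid.cells.pos[0] - start)) == pytest.approx(45.0)

    def test_proliferation_blocked_when_full_increments_delay(self, rng):
        cfg_over = dict(carrying_capacity=4)
        grid = seeded_grid(4 * 25, domain_cm=0.1, **cfg_over)  # grid full
        cell = grid.cells.agent(0)
        cell.phenotype = PROLIFERATION
        cell.cycle = grid.config.division_period_h
        n0 = grid.cells.n
        delta = agents.execute_cell_phenotype(cell, grid, rng)
        assert not delta["divided"]
        assert grid.cells.n == n0
        assert cell.delay == 1

    def test_division_after_cycle_accumulation(self, rng):
        grid = seeded_grid(1)
        cell = grid.cells.agent(0)
        cell.phenotype = PROLIFERATION
        period = grid.config.division_period_h
        for _ in range(period):
            delta = agents.execute_cell_phenotype(cell, grid, rng)
        assert delta["divided"]
        assert grid.cells.n == 2
        assert cell.divctr == 1
        assert grid.cells.divctr[1] == 1  # offspring inherits the count

    def test_necrosis_is_absorbing_and_ticks_timer(self, rng):
        grid = seeded_grid(1)
        cell = grid.cells.agent(0)
        cell.phenotype = NECROSIS
        agents.execute_cell_phenotype(cell, grid, rng)
        assert cell.inert
        assert cell.o2timer == 1

    def test_hypoxia_ticks_oxygen_deficiency_timer(self, rng):
        grid = seeded_grid(1)
        cell = grid.cells.agent(0)
        cell.phenotype = HYPOXIA
        agents.execute_cell_phenotype(cell, grid, rng)
        assert cell.o2timer == 1
        assert not cell.inert


class TestStepCellsVectorized:
    def test_capacity_never_exceeded(self, rng):
        cfg = ts.SimulationConfig(domain_cm=0.1, initial_cells=80,
                                  carrying_capacity=5, division_period_h=1)
        grid = ts.build_grid(cfg)
        ts.seed_tumor(grid, 80, rng)
        ts.init_fields(grid)
        pop = grid.cells
        for _ in range(10):
            pop.phen[: pop.n] = rng.integers(0, 5, pop.n)
            agents.step_cells(pop, grid, rng)
            assert grid.cell_counts().max() <= 5

    def test_agent_bookkeeping_closure(self, rng):
        """Every cell's recorded TME matches its physical position."""
        grid = seeded_grid(200, domain_cm=0.1, division_period_h=1)
        pop = grid.cells
        for _ in range(8):
            pop.phen[: pop.n] = rng.integers(0, 5, pop.n)
            agents.step_cells(pop, grid, rng)
        n = pop.n
        cols = np.minimum((pop.pos[:n, 0] // grid.tme_um).astype(int), grid.n - 1)
        rows = np.minimum((pop.pos[:n, 1] // grid.tme_um).astype(int), grid.n - 1)
        assert (pop.tme[:n] == rows * grid.n + cols).all()

    def test_matches_scalar_path_for_single_cell(self, rng):
        """The vectorized engine and the scalar wrapper share mechanics."""
        g1 = seeded_grid(1, seed=3)
        g2 = seeded_grid(1, seed=3)
        for g in (g1, g2):
            g.cells.phen[0] = HYPOXIA
        agents.execute_cell_phenotype(g1.cells.agent(0), g1, rng)
        agents.step_cells(g2.cells, g2, rng)
        assert g1.cells.o2timer[0] == g2.cells.o2timer[0] == 1
        assert g1.cells.age[0] == g2.cells.age[0] == 1


class TestVessels:
    def _system(self, domain_cm=0.1):
        cfg = ts.SimulationConfig(domain_cm=domain_cm, initial_cells=1)
        grid = ts.build_grid(cfg)
        return grid, agents.VesselSystem(grid)

    def test_committed_tip_60um_arrives_and_deposits_stalk(self, rng):
        grid, vs = self._system()
        tip = vs.spawn_tip([100.0, 100.0])
        tip.committed = True
        tip.dest = np.array([160.0, 100.0])
        delta = agents.execute_vessel_phenotype(vs, tip, grid, rng, V_SPROUT)
        assert delta["arrived"]
        assert vs.n_segments == 1
        assert vs.total_length_um == pytest.approx(60.0)

    def test_120um_takes_two_episodes_two_stalks(self, rng):
        grid, vs = self._system()
        tip = vs.spawn_tip([100.0, 100.0])
        tip.committed = True
        tip.dest = np.array([220.0, 100.0])
        d1 = agents.execute_vessel_phenotype(vs, tip, grid, rng, V_SPROUT)
        assert d1["moved"] and not d1["arrived"]
        d2 = agents.execute_vessel_phenotype(vs, tip, grid, rng, V_SPROUT)
        assert d2["arrived"]
        assert vs.n_segments == 2
        assert vs.total_length_um == pytest.approx(120.0)

    def test_total_elongation_is_60um_per_episode(self, rng):
        grid, vs = self._system(domain_cm=0.2)
        tip = vs.spawn_tip([100.0, 100.0])
        tip.committed = True
        tip.dest = np.array([1900.0, 100.0])
        k = 5
        for _ in range(k):
            agents.execute_vessel_phenotype(vs, tip, grid, rng, V_SPROUT)
        assert vs.total_length_um == pytest.approx(60.0 * k)

    def test_anastomosis_on_entering_foreign_vessel_tme(self, rng):
        grid, vs = self._system()
        foreign_path = vs.new_path()
        vs.add_stalk([450.0, 50.0], [450.0, 150.0], foreign_path)
        tip = vs.spawn_tip([180.0, 100.0])
        tip.committed = True
        tip.dest = np.array([470.0, 100.0])
        fused = False
        for _ in range(6):
            delta = agents.execute_vessel_phenotype(vs, tip, grid, rng, V_SPROUT)
            if delta["anastomosed"]:
                fused = True
                break
        assert fused
        assert tip not in vs.tips

    def test_branch_spawns_tip_and_counts_branch_point(self, rng):
        grid, vs = self._system()
        grid.conc[4][1, 1] = 2.0
        tip = vs.spawn_tip([100.0, 100.0])
        tip.age = 20
        delta = agents.execute_vessel_phenotype(vs, tip, grid, rng, V_BRANCH)
        assert delta["branched"]
        assert len(vs.tips) == 2
        assert vs.n_branch_points == 1
        assert tip.age == 0  # branching resets the sprout generation

    def test_commitment_locks_sprout_phenotype(self, rng):
        grid, vs = self._system()
        tip = vs.spawn_tip([100.0, 100.0])
        tip.committed = True
        tip.dest = np.array([1000.0, 100.0])
        agents.execute_vessel_phenotype(vs, tip, grid, rng, V_QUIESCENCE)
        assert tip.phenotype == V_SPROUT  # quiescence request overridden
        assert vs.n_segments == 1

    def test_quiescent_uncommitted_tip_does_not_move(self, rng):
        grid, vs = self._system()
        tip = vs.spawn_tip([100.0, 100.0])
        delta = agents.execute_vessel_phenotype(vs, tip, grid, rng, V_QUIESCENCE)
        assert not delta["moved"]
        assert vs.n_segments == 0

    def test_mean_path_length(self, rng):
        grid, vs = self._system()
        p = vs.new_path()
        vs.add_stalk([0.0, 0.0], [300.0, 0.0], p)
        p2 = vs.new_path()
        vs.add_stalk([0.0, 400.0], [100.0, 400.0], p2)
        assert vs.mean_path_length_um() == pytest.approx(200.0)
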