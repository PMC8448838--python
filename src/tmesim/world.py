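"""Orchestration: the per-episode loop and the train/test pipeline.

Every episode runs the three scales in order: microscopic (receptor
binding), mesoscopic (phenotype decision and execution for cells and
vessels) and macroscopic (field diffusion with sources/sinks).  During the
training phase phenotypes are drawn by Q-roulette and every transition
yields a reward, a SARSA update and -- above the reward threshold -- a
candidate experience record.  During the test phase the trained classifiers
predict phenotypes and no rewards are computed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import sarsa as sr
from .agents import (
    CellPopulation,
    VesselSystem,
    execute_vessel_phenotype,
    step_cells,
    vegf_neighborhood_max,
)
from .fields import step_fields
from .grid import build_grid, init_fields, seed_tumor
from .params import (
    MIGRATION,
    NECROSIS,
    POLICY_THRESHOLDS,
    V_BRANCH,
    V_QUIESCENCE,
    V_SPROUT,
    SimulationConfig,
)

#: endothelial maturation time (episodes) before a stalk segment may source
#: a new sprout; shares the vessel-age policy timescale
_T_VESSEL_AGE = POLICY_THRESHOLDS["vessel_age"]
from .predictor import ClassifierSpec, PhenotypeModel, fit_classifier
from .signaling import step_signaling
from .validation import census_row, extract_series, validation_report
from .vasculature import VesselNetwork, assimilate_network, load_vessels_into


@dataclasses.dataclass
class World:
    """Mutable simulation state for one phase run."""

    config: SimulationConfig
    grid: object
    vessels: VesselSystem
    rng: np.random.Generator
    phase: str = "train"
    episode: int = 0
    q_cell: sr.QModel | None = None
    q_vessel: sr.QModel | None = None
    ds_cell: sr.ExperienceDataset | None = None
    ds_vessel: sr.ExperienceDataset | None = None
    cell_model: PhenotypeModel | None = None
    vessel_model: PhenotypeModel | None = None
    observed_net: VesselNetwork | None = None  # assimilated mid-run
    evaluate_rewards: bool = False  # post-hoc reward logging in test phase
    repetition: int = 0
    history: list = dataclasses.field(default_factory=list)
    reward_log: list = dataclasses.field(default_factory=list)
    # per-episode caches
    _c_prev: np.ndarray | None = None
    _modal_prev: np.ndarray | None = None

    @property
    def cells(self) -> CellPopulation:
        return self.grid.cells


def build_world(config: SimulationConfig, net: VesselNetwork,
                rng: np.random.Generator, phase: str = "train") -> World:
    """Grid + vessels + tumor + fields, ready for episode 1."""
    grid = build_grid(config)
    vessels = VesselSystem(grid)
    load_vessels_into(grid, vessels, net)
    seed_tumor(grid, config.initial_cells, rng)
    init_fields(grid)
    world = World(config=config, grid=grid, vessels=vessels, rng=rng, phase=phase)
    world._c_prev = grid.conc.copy()
    world._modal_prev = _modal_phenotype(grid)
    world.history.append(census_row(0, grid, vessels))
    return world


def _modal_phenotype(grid) -> np.ndarray:
    pc = grid.phenotype_counts().reshape(5, -1)
    return np.where(pc.sum(axis=0) > 0, pc.argmax(axis=0), -1)


# -- cell records -------------------------------------------------------------


def _cell_records(world: World, idx: np.ndarray, q_cur: np.ndarray,
                  actions: np.ndarray) -> np.ndarray:
    """Assemble experience-record rows (without provenance) for cells idx."""
    grid, pop = world.grid, world.cells
    tme = pop.tme[idx]
    pc = grid.phenotype_counts().reshape(5, -1)
    occ = pc.sum(axis=0)
    modal = _modal_phenotype(grid)
    prev_conc = world._c_prev.reshape(5, -1)[:, tme].T
    conc = grid.conc.reshape(5, -1)[:, tme].T
    cols = [
        prev_conc, conc,
        occ[tme], pop.prev_divctr[idx], pop.divctr[idx],
        pc[NECROSIS][tme], pc[3][tme],
        pop.age[idx], pop.delay[idx], pop.o2timer[idx],
        pop.prev_q[idx], q_cur,
        pop.prev_phen[idx], actions,
        world._modal_prev[tme], modal[tme],
    ]
    return np.column_stack([np.asarray(c, dtype=float) for c in cols])


def _vessel_records(world: World, sites: np.ndarray, ages: np.ndarray,
                    q_prev: np.ndarray, q_cur: np.ndarray,
                    prev_actions: np.ndarray, actions: np.ndarray) -> np.ndarray:
    grid = world.grid
    prev_conc = world._c_prev.reshape(5, -1)[:, sites].T
    conc = grid.conc.reshape(5, -1)[:, sites].T
    n_vessels = (grid.stalk_count + grid.tip_count).reshape(-1)[sites]
    branching_by_site = np.zeros(grid.n_sites)
    sprouting_by_site = np.zeros(grid.n_sites)
    for t in world.vessels.tips:
        s = _flat_site(grid, t.pos)
        if t.committed:
            sprouting_by_site[s] += 1
        if t.phenotype == V_BRANCH:
            branching_by_site[s] += 1
    n_branching = branching_by_site[sites]
    n_sprouting = sprouting_by_site[sites]
    modal = np.zeros(sites.size)  # modal vessel phenotype: quiescence baseline
    cols = [prev_conc, conc, n_vessels, n_branching, n_sprouting, ages,
            q_prev, q_cur, prev_actions, actions, modal, modal]
    return np.column_stack([np.asarray(c, dtype=float) for c in cols])


def _flat_site(grid, pos) -> int:
    r, c = grid.site_of(*pos)
    return r * grid.n + c


# -- the episode --------------------------------------------------------------


def run_episode(world: World) -> World:
    """One full episode: micro → meso (cells, vessels) → macro."""
    cfg = world.config
    grid = world.grid
    pop = world.cells
    rng = world.rng
    try:
        step_signaling(pop, grid)
        mean_reward = _decide_and_step_cells(world)
        _decide_and_step_vessels(world)
        world._c_prev = grid.conc.copy()
        world._modal_prev = _modal_phenotype(grid)
        n = pop.n
        pop.prev_divctr[:n] = pop.divctr[:n]
        step_fields(grid)
        world.episode += 1
        if (world.observed_net is not None
                and world.episode == cfg.assimilation_episode):
            assimilate_network(grid, world.vessels, world.observed_net,
                               world.episode)
        row = census_row(world.episode, grid, world.vessels)
        if mean_reward is not None:
            row["mean_reward"] = mean_reward
        world.history.append(row)
        if mean_reward is not None:
            world.reward_log.append((world.repetition, world.episode, mean_reward))
    except Exception as err:
        raise RuntimeError(f"episode {world.episode + 1} failed: {err}") from err
    return world


def _decide_and_step_cells(world: World) -> float | None:
    cfg, grid, pop, rng = world.config, world.grid, world.cells, world.rng
    n = pop.n
    if n == 0:
        return None
    values = sr.cell_state_values(pop, grid)
    s_cur = sr.cell_state_index(values)
    train = world.phase == "train"
    if train:
        q_rows = world.q_cell.q[s_cur]
        actions = sr.roulette_select(q_rows, rng)
    else:
        feats = _cell_records(world, np.arange(n), np.zeros(n), pop.phen[:n])
        feats = _drop_columns(feats, sr.CELL_RECORD_COLUMNS,
                              world.cell_model.feature_columns)
        actions = world.cell_model.sample(feats, rng)
    # forced actions: migration commitments and inert necrotic cells
    committed = pop.committed[:n]
    actions = np.where(committed, MIGRATION, actions)
    actions = np.where(pop.inert[:n], NECROSIS, actions)
    actions = actions.astype(np.int64)
    mean_reward = None
    if train or world.evaluate_rewards:
        rmat = sr.cell_reward_matrix(values, cfg.carrying_capacity)
        r_chosen = rmat[np.arange(n), actions]
        mean_reward = float(r_chosen.mean())
    if train:
        q_cur = world.q_cell.q[s_cur, actions]
        # SARSA: update Q(s_t, a_t) toward r_{t+1} + γ Q(s_{t+1}, a_{t+1}),
        # where r_{t+1} scores the previous action in the state it produced
        has_prev = pop.prev_state[:n] >= 0
        if has_prev.any():
            idx = np.flatnonzero(has_prev)
            r_prev = rmat[idx, pop.prev_phen[idx].astype(np.int64)]
            targets = r_prev + cfg.gamma * q_cur[idx]
            order = rng.permutation(idx.size)
            sr.batch_sarsa_update(world.q_cell.q, pop.prev_state[idx],
                                  pop.prev_phen[idx].astype(np.int64),
                                  targets, cfg.alpha, order)
        # record a seeded subsample of reward-eligible transitions; only
        # genuine decisions enter the dataset (locked migration commitments
        # and inert necrotic cells are not choices the policy made this
        # episode, and would swamp the label mixture)
        thr = -np.inf if cfg.reward_threshold is None else cfg.reward_threshold
        eligible = np.flatnonzero((r_chosen > thr) & ~committed & ~pop.inert[:n])
        if eligible.size and world.ds_cell is not None:
            k = min(cfg.record_quota_cells, eligible.size)
            sample = rng.choice(eligible, size=k, replace=False)
            recs = _cell_records(world, sample, q_cur[sample], actions[sample])
            world.ds_cell.append(recs, r_chosen[sample], thr, world.repetition)
        pop.prev_state[:n] = s_cur
        pop.prev_q[:n] = q_cur
    pop.prev_phen[:n] = actions.astype(np.int8)
    pop.phen[:n] = actions.astype(np.int8)
    step_cells(pop, grid, rng)
    return mean_reward


def _drop_columns(records: np.ndarray, columns, feature_columns) -> np.ndarray:
    keep = [i for i, c in enumerate(columns) if c in feature_columns]
    return records[:, keep]


def _decide_and_step_vessels(world: World) -> None:
    cfg, grid, rng = world.config, world.grid, world.rng
    vs = world.vessels
    train = world.phase == "train"
    scales = cfg.scales()
    vegf_nb = vegf_neighborhood_max(grid).reshape(-1) / scales["vegf"]

    # ---- stalk agents (vectorized decision; sprouting spawns a new tip)
    n_seg = vs.n_segments
    if n_seg:
        sites = vs.stalk_sites()
        ages = vs.stalk_ages(world.episode).astype(float)
        vegf = vegf_nb[sites]
        state = sr.vessel_state_index(vegf, ages)
        avail = np.ones((n_seg, 3), dtype=bool)
        avail[:, V_BRANCH] = False  # stalks never branch
        # sprout-source eligibility: a VEGF stimulus above the sprouting
        # threshold (angiogenic actions require the pro-angiogenic signal),
        # endothelial maturation, a per-segment re-sprout cooldown, and
        # lateral inhibition (no new sprout within one TME -- capillary
        # spacing -- of an active tip)
        from scipy import ndimage as _ndi

        tip_near = _ndi.maximum_filter(
            (grid.tip_count > 0).astype(np.int8), size=3, mode="nearest"
        ).reshape(-1)[sites] > 0
        mature = ages >= _T_VESSEL_AGE
        cooled = (world.episode - vs.seg_last_sprout) >= _T_VESSEL_AGE
        stimulated = vegf > POLICY_THRESHOLDS["vegf"]
        avail[:, V_SPROUT] = cooled & ~tip_near & mature & stimulated
        if train:
            actions = sr.roulette_select(world.q_vessel.q[state], rng, avail)
        else:
            # only segments that could actually sprout need a prediction;
            # the rest are quiescent by construction
            actions = np.full(n_seg, V_QUIESCENCE, dtype=np.int64)
            cand = np.flatnonzero(avail[:, V_SPROUT])
            if cand.size:
                q0 = np.zeros(cand.size)
                prev_a = np.maximum(vs.seg_prev_action[cand], V_QUIESCENCE)
                recs = _vessel_records(world, sites[cand], ages[cand],
                                       q0, q0, prev_a, q0)
                feats = _drop_columns(recs, sr.VESSEL_RECORD_COLUMNS,
                                      world.vessel_model.feature_columns)
                pred = world.vessel_model.sample(feats, rng)
                ok = avail[cand, pred]
                actions[cand[ok]] = pred[ok]
            vs.seg_prev_action[:] = actions
        if train:
            _vessel_sarsa_stalks(world, state, actions, vegf, ages, sites,
                                 avail[:, V_SPROUT])
        # tip-cell selection: at most one new sprout per stimulated
        # neighborhood per episode (the selected tip laterally inhibits the
        # rest of the stimulated wall)
        new_sprouts = np.flatnonzero(actions == V_SPROUT)
        blocked: set[int] = set()
        for j in rng.permutation(new_sprouts):
            site = int(sites[j])
            if site in blocked:
                continue
            r0, c0 = divmod(site, grid.n)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r0 + dr, c0 + dc
                    if 0 <= rr < grid.n and 0 <= cc < grid.n:
                        blocked.add(rr * grid.n + cc)
            mid = (vs.seg_p0[j] + vs.seg_p1[j]) / 2.0
            vs.seg_last_sprout[j] = world.episode
            vs.spawn_tip(mid)
            vs.n_branch_points += 1

    # ---- tip agents (vectorized decisions, per-agent mechanics)
    tips = list(vs.tips)
    if not tips:
        return
    n_tip = len(tips)
    tpos = np.array([t.pos for t in tips])
    cols = np.minimum((tpos[:, 0] // grid.tme_um).astype(np.int64), grid.n - 1)
    rows = np.minimum((tpos[:, 1] // grid.tme_um).astype(np.int64), grid.n - 1)
    tsite = rows * grid.n + cols
    tvegf = vegf_nb[tsite]
    tage = np.array([float(t.age) for t in tips])
    tstate = sr.vessel_state_index(tvegf, tage)
    tcommitted = np.array([t.committed for t in tips])
    stimulated = tvegf > POLICY_THRESHOLDS["vegf"]
    if train:
        actions = sr.roulette_select(world.q_vessel.q[tstate], rng)
    else:
        prev_a = np.array([max(t.prev_action, V_QUIESCENCE) for t in tips])
        z = np.zeros(n_tip)
        recs = _vessel_records(world, tsite, tage, z, z, prev_a, z)
        feats = _drop_columns(recs, sr.VESSEL_RECORD_COLUMNS,
                              world.vessel_model.feature_columns)
        actions = world.vessel_model.sample(feats, rng)
    # commitment locks sprouting; no angiogenic action without VEGF
    actions = np.where(tcommitted, V_SPROUT,
                       np.where(stimulated, actions, V_QUIESCENCE)).astype(int)
    if train:
        q_cur = world.q_vessel.q[tstate, actions]
        rmat = sr.vessel_reward_matrix(tvegf, tage, np.ones(n_tip, dtype=bool))
        prev_s = np.array([t.prev_state for t in tips])
        prev_a = np.array([t.prev_action for t in tips])
        has_prev = prev_s >= 0
        if has_prev.any():
            idx = np.flatnonzero(has_prev)
            targets = rmat[idx, prev_a[idx]] + cfg.gamma * q_cur[idx]
            sr.batch_sarsa_update(world.q_vessel.q, prev_s[idx], prev_a[idx],
                                  targets, cfg.alpha, rng.permutation(idx.size))
        r_chosen = rmat[np.arange(n_tip), actions]
        thr = -np.inf if cfg.reward_threshold is None else cfg.reward_threshold
        if world.ds_vessel is not None:
            eligible = np.flatnonzero((r_chosen > thr) & stimulated
                                      & ~tcommitted)
            if eligible.size:
                k = min(cfg.record_quota_vessels, eligible.size)
                sample = rng.choice(eligible, size=k, replace=False)
                recs = _vessel_records(world, tsite[sample], tage[sample],
                                       np.array([tips[j].prev_q for j in sample]),
                                       q_cur[sample], prev_a[sample],
                                       actions[sample])
                world.ds_vessel.append(recs, r_chosen[sample], thr,
                                       world.repetition)
        for j, tip in enumerate(tips):
            tip.prev_state = int(tstate[j])
            tip.prev_action = int(actions[j])
            tip.prev_q = float(q_cur[j])
    else:
        for j, tip in enumerate(tips):
            tip.prev_action = int(actions[j])
    for j, tip in enumerate(tips):
        # a tip that has arrived and idles without a VEGF stimulus loses tip
        # identity and reverts to stalk (no endothelial leader without a
        # chemotactic target)
        if (not tip.committed and actions[j] == V_QUIESCENCE
                and not stimulated[j]):
            vs.remove_tip(tip)
            continue
        execute_vessel_phenotype(vs, tip, grid, rng, phenotype=int(actions[j]),
                                 episode=world.episode)


def _vessel_sarsa_stalks(world, state, actions, vegf, ages, sites,
                         had_choice) -> None:
    cfg = world.config
    vs = world.vessels
    q = world.q_vessel.q
    prev_s = vs.seg_prev_state.copy()
    prev_a = vs.seg_prev_action.copy()
    q_cur = q[state, actions]
    rmat = sr.vessel_reward_matrix(vegf, ages, np.zeros(vegf.size, dtype=bool))
    has_prev = prev_s >= 0
    if has_prev.any():
        idx = np.flatnonzero(has_prev)
        targets = rmat[idx, prev_a[idx]] + cfg.gamma * q_cur[idx]
        sr.batch_sarsa_update(q, prev_s[idx], prev_a[idx], targets, cfg.alpha,
                              world.rng.permutation(idx.size))
    r_chosen = rmat[np.arange(vegf.size), actions]
    if world.ds_vessel is not None:
        thr = -np.inf if cfg.reward_threshold is None else cfg.reward_threshold
        eligible = np.flatnonzero((r_chosen > thr) & had_choice)
        if eligible.size:
            k = min(cfg.record_quota_vessels, eligible.size)
            sample = world.rng.choice(eligible, size=k, replace=False)
            recs = _vessel_records(world, sites[sample], ages[sample],
                                   vs.seg_prev_q[sample],
                                   q_cur[sample], prev_a[sample],
                                   actions[sample])
            world.ds_vessel.append(recs, r_chosen[sample], thr,
                                   world.repetition)
    vs.seg_prev_state[:] = state
    vs.seg_prev_action[:] = actions
    vs.seg_prev_q[:] = q_cur


# -- phases -------------------------------------------------------------------


@dataclasses.dataclass
class TrainingResult:
    q_cell: sr.QModel
    q_vessel: sr.QModel
    ds_cell: sr.ExperienceDataset
    ds_vessel: sr.ExperienceDataset
    reward_curve: list[float]  # mean cell reward per repetition
    last_history: list[dict]


def run_training(config: SimulationConfig, net: VesselNetwork,
                 rng: np.random.Generator | None = None,
                 grid=None, observed_net: VesselNetwork | None = None,
                 progress=None) -> TrainingResult:
    """The full training phase: repetitions of the episode loop with the
    Q-tables and the experience dataset carried between repetitions."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q_cell = sr.QModel(sr.N_CELL_STATES, 5)
    q_vessel = sr.QModel(sr.N_VESSEL_STATES, 3)
    ds_cell = sr.ExperienceDataset("cell")
    ds_vessel = sr.ExperienceDataset("vessel")
    reward_curve: list[float] = []
    last_history: list[dict] = []
    for rep in range(config.n_repetitions):
        rep_rng = np.random.default_rng(rng.integers(2**31))
        world = build_world(config, net, rep_rng, phase="train")
        world.q_cell, world.q_vessel = q_cell, q_vessel
        world.ds_cell, world.ds_vessel = ds_cell, ds_vessel
        world.observed_net = observed_net
        world.repetition = rep
        for _ in range(config.n_episodes):
            run_episode(world)
        rewards = [r for (_, _, r) in world.reward_log]
        reward_curve.append(float(np.mean(rewards)) if rewards else 0.0)
        last_history = world.history
        if progress is not None:
            progress(rep, reward_curve[-1], len(ds_cell))
    return TrainingResult(q_cell, q_vessel, ds_cell, ds_vessel,
                          reward_curve, last_history)


def fit_models(config: SimulationConfig, result: TrainingResult,
               rng: np.random.Generator) -> tuple[PhenotypeModel, PhenotypeModel]:
    """Fit the cell (5-way) and vessel (3-way) phenotype classifiers."""
    spec_c = ClassifierSpec(5, config.hidden_layers, config.nn_epochs,
                            config.nn_learning_rate)
    spec_v = ClassifierSpec(3, config.hidden_layers, config.nn_epochs,
                            config.nn_learning_rate)
    cell_model = fit_classifier(result.ds_cell, spec_c, rng,
                                max_records=config.fit_max_records)
    vessel_model = fit_classifier(result.ds_vessel, spec_v, rng,
                                  max_records=config.fit_max_records)
    return cell_model, vessel_model


def run_test(config: SimulationConfig, net: VesselNetwork,
             cell_model: PhenotypeModel, vessel_model: PhenotypeModel,
             rng: np.random.Generator | None = None,
             observed_net: VesselNetwork | None = None,
             evaluate_rewards: bool = False) -> World:
    """The test phase: classifier-driven phenotypes, no reward computation
    (unless post-hoc evaluation is requested)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    world = build_world(config, net, rng, phase="test")
    world.cell_model = cell_model
    world.vessel_model = vessel_model
    world.observed_net = observed_net
    world.evaluate_rewards = evaluate_rewards
    for _ in range(config.n_episodes):
        run_episode(world)
    return world


def run_pipeline(config: SimulationConfig,
                 train_net: VesselNetwork,
                 test_net: VesselNetwork | None = None,
                 train_observed: VesselNetwork | None = None,
                 test_observed: VesselNetwork | None = None,
                 rng: np.random.Generator | None = None,
                 progress=None) -> dict:
    """Train, fit the classifiers, run the test phase, and validate.

    Returns a dict with the training result, test series, and the
    validation report of the test run.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    result = run_training(config, train_net, rng=rng,
                          observed_net=train_observed, progress=progress)
    cell_model, vessel_model = fit_models(config, result, rng)
    world = run_test(config, test_net if test_net is not None else train_net,
                     cell_model, vessel_model, rng=rng,
                     observed_net=test_observed)
    series = extract_series(world.history)
    report = validation_report(series, initial_cells=config.initial_cells)
    return {
        "training": result,
        "cell_model": cell_model,
        "vessel_model": vessel_model,
        "test_world": world,
        "series": series,
        "report": report,
    }
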