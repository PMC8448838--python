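"""Mesoscopic scale: cell and vessel agents and their phenotype mechanics.

Cancer cells live in a growable struct-of-arrays :class:`CellPopulation`
(the per-episode engine is fully vectorized); :class:`CellAgent` is a light
per-cell view used by the scalar operations and the tests.  Microvessels are
a :class:`VesselSystem`: an append-only store of stalk segments plus a small
list of active :class:`TipAgent` leaders.

Movement constants: a migrating cell advances 45 µm per 1-h episode
(0.75 µm/min); a sprouting tip elongates 60 µm per episode (1 µm/min),
depositing a stalk segment behind it at every move.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .params import (
    GLUCOSE,
    HYPOXIA,
    MIGRATION,
    NECROSIS,
    OXYGEN,
    PROLIFERATION,
    QUIESCENCE,
    VEGF,
    SimulationConfig,
)

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class CellPopulation:
    """Struct-of-arrays store for cancer-cell agents."""

    _FIELDS = (
        ("pos", np.float64, 2),  # µm within the domain
        ("tme", np.int64, None),  # flat site index (row * n + col)
        ("phen", np.int8, None),
        ("age", np.int32, None),
        ("divctr", np.int32, None),
        ("delay", np.int32, None),  # proliferation time delay
        ("o2timer", np.int32, None),  # oxygen-deficiency timer
        ("cycle", np.int32, None),  # accumulated proliferation episodes
        ("inert", np.bool_, None),  # necrotic cells become inert
        ("committed", np.bool_, None),
        ("dest", np.float64, 2),  # movement destination (µm)
        ("b_egfr", np.float64, None),  # bound EGFR fraction
        ("b_tnfr", np.float64, None),  # bound TNFR fraction
        ("prev_phen", np.int8, None),
        ("prev_state", np.int32, None),
        ("prev_q", np.float64, None),
        ("prev_divctr", np.int32, None),
    )

    def __init__(self, capacity: int = 64):
        self.n = 0
        self._cap = max(capacity, 1)
        for name, dtype, width in self._FIELDS:
            shape = (self._cap,) if width is None else (self._cap, width)
            setattr(self, name, np.zeros(shape, dtype=dtype))
        self.prev_phen[:] = -1
        self.prev_state[:] = -1

    def _grow(self, need: int) -> None:
        if self.n + need <= self._cap:
            return
        while self.n + need > self._cap:
            self._cap *= 2
        for name, dtype, width in self._FIELDS:
            old = getattr(self, name)
            shape = (self._cap,) if width is None else (self._cap, width)
            new = np.zeros(shape, dtype=dtype)
            new[: self.n] = old[: self.n]
            if name in ("prev_phen", "prev_state"):
                new[self.n:] = -1
            setattr(self, name, new)

    def add(self, *, x, y, tme, phen, **extra) -> np.ndarray:
        """Append cells; returns the new indices.  Counters default to zero."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k = x.size
        self._grow(k)
        sl = slice(self.n, self.n + k)
        self.pos[sl, 0] = x
        self.pos[sl, 1] = np.atleast_1d(y)
        self.tme[sl] = np.atleast_1d(tme)
        self.phen[sl] = np.atleast_1d(phen)
        self.prev_phen[sl] = -1
        self.prev_state[sl] = -1
        for name, val in extra.items():
            getattr(self, name)[sl] = val
        self.n += k
        return np.arange(sl.start, sl.stop)

    def agent(self, i: int) -> "CellAgent":
        return CellAgent(self, i)


class CellAgent:
    """Attribute view of one cell inside a :class:`CellPopulation`."""

    def __init__(self, pop: CellPopulation, index: int):
        object.__setattr__(self, "pop", pop)
        object.__setattr__(self, "index", index)

    def __getattr__(self, name):
        return getattr(self.pop, name)[self.index]

    def __setattr__(self, name, value):
        prop = getattr(type(self), name, None)
        if isinstance(prop, property) and prop.fset is not None:
            prop.fset(self, value)
        else:
            getattr(self.pop, name)[self.index] = value

    @property
    def phenotype(self) -> int:
        return int(self.pop.phen[self.index])

    @phenotype.setter
    def phenotype(self, value: int) -> None:
        self.pop.phen[self.index] = value


# -- neighborhood and destination selection ---------------------------------


def moore_neighbors(grid, site: tuple[int, int]) -> list[tuple[int, int]]:
    """The ≤ 8 orthogonal/diagonal neighbors, truncated at the boundary."""
    r, c = site
    if not (0 <= r < grid.n and 0 <= c < grid.n):
        raise ValueError(f"site {site} outside {grid.n}x{grid.n} grid")
    return [
        (r + dr, c + dc)
        for dr, dc in _MOORE
        if 0 <= r + dr < grid.n and 0 <= c + dc < grid.n
    ]


def nutrient_score(grid) -> np.ndarray:
    """Policy-scaled oxygen + glucose, the "nutrient concentration" used for
    destination choices."""
    s = grid.config.scales()
    return grid.conc[OXYGEN] / s["oxygen"] + grid.conc[GLUCOSE] / s["glucose"]


def select_destination_tme(
    grid,
    site: tuple[int, int],
    criterion: str,
    require_space: bool,
    rng: np.random.Generator,
    include_current: bool | None = None,
    occupancy: np.ndarray | None = None,
) -> tuple[int, int] | None:
    """Argmax destination among the Moore candidates; random tie-break.

    ``max-VEGF`` considers the current site plus its Moore neighbors,
    ``max-nutrient`` the Moore neighbors only (``include_current`` overrides).
    With ``require_space``, candidates at carrying capacity are excluded;
    returns ``None`` when no candidate qualifies.
    """
    if criterion == "max-vegf":
        values = grid.conc[VEGF]
        current = True if include_current is None else include_current
    elif criterion == "max-nutrient":
        values = nutrient_score(grid)
        current = False if include_current is None else include_current
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    candidates = moore_neighbors(grid, site)
    if current:
        candidates = [site] + candidates
    if require_space:
        occ = grid.cell_counts() if occupancy is None else occupancy
        cap = grid.config.carrying_capacity
        if occ.ndim == 1:
            occ = occ.reshape(grid.n, grid.n)
        candidates = [s for s in candidates if occ[s] < cap]
    if not candidates:
        return None
    vals = np.array([values[s] for s in candidates])
    best = np.flatnonzero(vals == vals.max())
    return candidates[best[rng.integers(best.size)]]


# -- scalar cell phenotype execution -----------------------------------------


def execute_cell_phenotype(cell: CellAgent, grid, rng: np.random.Generator) -> dict:
    """Execute one cell's already-chosen phenotype for this episode.

    Returns a small delta dict (``{"divided": bool, "moved": bool, ...}``)
    for inspection.  The vectorized engine :func:`step_cells` applies the
    same mechanics to the whole population.
    """
    pop, i = cell.pop, cell.index
    if grid.cells is not pop:
        raise RuntimeError("cell is not registered in this grid's population")
    delta = {"divided": False, "moved": False, "arrived": False}
    phen = int(pop.phen[i])
    pop.age[i] += 1
    cfg = grid.config
    if phen == PROLIFERATION:
        pop.cycle[i] += 1
        if pop.cycle[i] >= cfg.division_period_h:
            occ = grid.cell_counts()
            dest = select_destination_tme(
                grid, _site(pop, i, grid), "max-nutrient", True, rng,
                include_current=True, occupancy=occ,
            )
            if dest is None:
                pop.delay[i] += 1
                pop.cycle[i] = cfg.division_period_h  # retry when space appears
            else:
                _spawn_offspring(pop, grid, np.array([i]),
                                 np.array([dest[0] * grid.n + dest[1]]), rng)
                delta["divided"] = True
    elif phen == MIGRATION:
        if not pop.committed[i]:
            dest = select_destination_tme(
                grid, _site(pop, i, grid), "max-nutrient", True, rng)
            if dest is not None:
                r, c = dest
                pop.dest[i] = [(c + rng.random()) * grid.tme_um,
                               (r + rng.random()) * grid.tme_um]
                pop.committed[i] = True
        if pop.committed[i]:
            occ = grid.cell_counts()
            moved, arrived = _advance_migrator(pop, grid, i, occ, cfg)
            delta["moved"], delta["arrived"] = moved, arrived
    elif phen in (HYPOXIA, NECROSIS):
        pop.o2timer[i] += 1
        if phen == NECROSIS:
            pop.inert[i] = True
    # quiescence: reduced uptake only, no movement
    return delta


def _site(pop, i, grid):
    return divmod(int(pop.tme[i]), grid.n)


def _advance_migrator(pop, grid, i, occ, cfg):
    step = cfg.migration_um_per_episode
    vec = pop.dest[i] - pop.pos[i]
    dist = float(np.hypot(*vec))
    new_pos = pop.dest[i].copy() if dist <= step else pop.pos[i] + vec * (step / dist)
    new_site = grid.site_of(*new_pos)
    old_flat = int(pop.tme[i])
    new_flat = new_site[0] * grid.n + new_site[1]
    if new_flat != old_flat and occ.reshape(-1)[new_flat] >= cfg.carrying_capacity:
        return False, False  # blocked at a full site; wait
    pop.pos[i] = new_pos
    pop.tme[i] = new_flat
    arrived = dist <= step
    if arrived:
        pop.committed[i] = False
    return True, arrived


def _spawn_offspring(pop, grid, parents, dest_flat, rng):
    """Create one offspring per parent at a random point in its destination."""
    k = parents.size
    rows, cols = np.divmod(dest_flat, grid.n)
    xs = (cols + rng.random(k)) * grid.tme_um
    ys = (rows + rng.random(k)) * grid.tme_um
    pop.divctr[parents] += 1
    pop.cycle[parents] = 0
    pop.add(
        x=xs, y=ys, tme=dest_flat, phen=np.full(k, PROLIFERATION, dtype=np.int8),
        divctr=pop.divctr[parents],
        b_egfr=pop.b_egfr[parents], b_tnfr=pop.b_tnfr[parents],
    )


# -- vectorized per-episode cell engine --------------------------------------


def step_cells(pop: CellPopulation, grid, rng: np.random.Generator) -> dict:
    """Execute the already-chosen phenotypes of every cell, vectorized.

    Capacity-contended moves (divisions, TME crossings) are granted in a
    random priority order against live occupancy, so no site ever exceeds
    the carrying capacity.  Destination choices use start-of-episode fields.
    """
    cfg = grid.config
    n = pop.n
    if n == 0:
        return {"divisions": 0, "arrivals": 0}
    occ = np.bincount(pop.tme[:n], minlength=grid.n_sites)
    cap = cfg.carrying_capacity
    phen = pop.phen[:n]
    pop.age[:n] += 1
    hyponec = (phen == HYPOXIA) | (phen == NECROSIS)
    pop.o2timer[:n][hyponec] += 1
    pop.inert[:n][phen == NECROSIS] = True

    nut = nutrient_score(grid).reshape(-1)
    divisions = 0
    prolif = np.flatnonzero(phen == PROLIFERATION)
    if prolif.size:
        pop.cycle[prolif] += 1
        ready = prolif[pop.cycle[prolif] >= cfg.division_period_h]
        if ready.size:
            dest = _pick_neighbor_sites(
                grid, pop.tme[ready], nut, occ, cap, rng, include_current=True)
            ok = dest >= 0
            pop.delay[ready[~ok]] += 1
            pop.cycle[ready[~ok]] = cfg.division_period_h
            granted = _grant_capacity(dest[ok], occ, cap, rng)
            parents = ready[ok][granted]
            blocked = ready[ok][~granted]
            pop.delay[blocked] += 1
            pop.cycle[blocked] = cfg.division_period_h
            if parents.size:
                d = dest[ok][granted]
                np.add.at(occ, d, 1)
                _spawn_offspring(pop, grid, parents, d, rng)
                divisions = parents.size

    arrivals = 0
    migr = np.flatnonzero((pop.phen[:n] == MIGRATION) & ~pop.inert[:n])
    if migr.size:
        uncom = migr[~pop.committed[migr]]
        if uncom.size:
            dest = _pick_neighbor_sites(
                grid, pop.tme[uncom], nut, occ, cap, rng, include_current=False)
            ok = dest >= 0
            rows, cols = np.divmod(dest[ok], grid.n)
            k = ok.sum()
            pop.dest[uncom[ok], 0] = (cols + rng.random(k)) * grid.tme_um
            pop.dest[uncom[ok], 1] = (rows + rng.random(k)) * grid.tme_um
            pop.committed[uncom[ok]] = True
        movers = migr[pop.committed[migr]]
        if movers.size:
            arrivals = _advance_migrators(pop, grid, movers, occ, cfg, rng)
    return {"divisions": divisions, "arrivals": arrivals}


def _pick_neighbor_sites(grid, tme_flat, values_flat, occ, cap, rng,
                         include_current: bool) -> np.ndarray:
    """Vectorized argmax-with-space over Moore candidates; -1 when none."""
    n = grid.n
    rows, cols = np.divmod(tme_flat, n)
    offsets = ([(0, 0)] if include_current else []) + _MOORE
    k = len(offsets)
    cand = np.empty((tme_flat.size, k), dtype=np.int64)
    valid = np.empty((tme_flat.size, k), dtype=bool)
    for j, (dr, dc) in enumerate(offsets):
        rr, cc = rows + dr, cols + dc
        inb = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        idx = np.where(inb, rr * n + cc, 0)
        cand[:, j] = idx
        valid[:, j] = inb & (occ[idx] < cap)
    vals = np.where(valid, values_flat[cand], -np.inf)
    # random tie-break: perturb order by random keys among equal maxima
    best = vals.max(axis=1, keepdims=True)
    is_best = (vals == best) & valid
    noise = rng.random(is_best.shape)
    choice = np.argmax(np.where(is_best, noise, -1.0), axis=1)
    out = cand[np.arange(tme_flat.size), choice]
    out[~valid.any(axis=1)] = -1
    return out


def _grant_capacity(dest, occ, cap, rng) -> np.ndarray:
    """Grant one slot per request in random priority order; bool mask."""
    granted = np.zeros(dest.size, dtype=bool)
    if dest.size == 0:
        return granted
    perm = rng.permutation(dest.size)
    order = perm[np.argsort(dest[perm], kind="stable")]
    d_sorted = dest[order]
    starts = np.flatnonzero(np.r_[True, d_sorted[1:] != d_sorted[:-1]])
    rank = np.arange(d_sorted.size) - np.repeat(starts, np.diff(np.r_[starts, d_sorted.size]))
    free = np.maximum(cap - occ[d_sorted], 0)
    granted[order] = rank < free
    return granted


def _advance_migrators(pop, grid, movers, occ, cfg, rng) -> int:
    step = cfg.migration_um_per_episode
    vec = pop.dest[movers] - pop.pos[movers]
    dist = np.hypot(vec[:, 0], vec[:, 1])
    arriving = dist <= step
    scale = np.where(arriving, 1.0, step / np.maximum(dist, 1e-12))
    new_pos = pop.pos[movers] + vec * scale[:, None]
    cols = np.minimum((new_pos[:, 0] // grid.tme_um).astype(np.int64), grid.n - 1)
    rows = np.minimum((new_pos[:, 1] // grid.tme_um).astype(np.int64), grid.n - 1)
    new_flat = rows * grid.n + cols
    crossing = new_flat != pop.tme[movers]
    allowed = ~crossing
    if crossing.any():
        idx = np.flatnonzero(crossing)
        granted = _grant_capacity(new_flat[idx], occ, cfg.carrying_capacity, rng)
        allowed[idx[granted]] = True
        np.add.at(occ, new_flat[idx[granted]], 1)
        np.add.at(occ, pop.tme[movers[idx[granted]]], -1)
    sel = movers[allowed]
    pop.pos[sel] = new_pos[allowed]
    pop.tme[sel] = new_flat[allowed]
    done = allowed & arriving
    pop.committed[movers[done]] = False
    return int(done.sum())


# -- vessels ------------------------------------------------------------------


@dataclasses.dataclass(eq=False)
class TipAgent:
    """The leading endothelial cell of a growing sprout."""

    pos: np.ndarray  # µm
    path_id: int
    age: int = 0
    committed: bool = False
    dest: np.ndarray | None = None
    phenotype: int = 0  # V_QUIESCENCE until a sprout commitment is made
    prev_state: int = -1
    prev_action: int = -1
    prev_q: float = 0.0


class VesselSystem:
    """The live microvascular network: stalk segments plus active tips.

    Scalar summaries (total length, path count, branch-point count) are
    maintained incrementally; they feed the validation time series.
    """

    _FIELDS = (
        ("seg_p0", np.float64, 2),
        ("seg_p1", np.float64, 2),
        ("seg_path", np.int64, None),
        ("seg_birth", np.int64, None),  # episode the segment appeared
        ("seg_last_sprout", np.int64, None),  # last sprout-sourcing episode
        # SARSA bookkeeping for stalk agents (previous state/action/Q)
        ("seg_prev_state", np.int64, None),
        ("seg_prev_action", np.int64, None),
        ("seg_prev_q", np.float64, None),
    )

    def __init__(self, grid):
        self.grid = grid
        self._n = 0
        self._cap = 64
        for name, dtype, width in self._FIELDS:
            shape = (self._cap,) if width is None else (self._cap, width)
            setattr(self, "_" + name, np.zeros(shape, dtype=dtype))
        self.tips: list[TipAgent] = []
        self.total_length_um = 0.0
        self.n_paths = 0
        self.n_branch_points = 0
        self._next_path = 0

    def _grow(self) -> None:
        if self._n < self._cap:
            return
        self._cap *= 2
        for name, dtype, width in self._FIELDS:
            old = getattr(self, "_" + name)
            shape = (self._cap,) if width is None else (self._cap, width)
            new = np.zeros(shape, dtype=dtype)
            new[: self._n] = old[: self._n]
            setattr(self, "_" + name, new)

    # live views over the segment store
    @property
    def seg_p0(self) -> np.ndarray:
        return self._seg_p0[: self._n]

    @property
    def seg_p1(self) -> np.ndarray:
        return self._seg_p1[: self._n]

    @property
    def seg_path(self) -> np.ndarray:
        return self._seg_path[: self._n]

    @property
    def seg_birth(self) -> np.ndarray:
        return self._seg_birth[: self._n]

    @property
    def seg_last_sprout(self) -> np.ndarray:
        return self._seg_last_sprout[: self._n]

    @property
    def seg_prev_state(self) -> np.ndarray:
        return self._seg_prev_state[: self._n]

    @property
    def seg_prev_action(self) -> np.ndarray:
        return self._seg_prev_action[: self._n]

    @property
    def seg_prev_q(self) -> np.ndarray:
        return self._seg_prev_q[: self._n]

    @property
    def n_segments(self) -> int:
        return self._n

    def mean_path_length_um(self) -> float:
        return self.total_length_um / self.n_paths if self.n_paths else 0.0

    def stalk_ages(self, episode: int) -> np.ndarray:
        return episode - self.seg_birth

    def stalk_sites(self) -> np.ndarray:
        """Flat TME index of each stalk segment's midpoint."""
        if self._n == 0:
            return np.empty(0, dtype=np.int64)
        mids = (self.seg_p0 + self.seg_p1) / 2.0
        n, tme = self.grid.n, self.grid.tme_um
        cols = np.minimum((mids[:, 0] // tme).astype(np.int64), n - 1)
        rows = np.minimum((mids[:, 1] // tme).astype(np.int64), n - 1)
        return rows * n + cols

    def new_path(self) -> int:
        self._next_path += 1
        self.n_paths += 1
        return self._next_path - 1

    def add_stalk(self, p0, p1, path_id: int, register: bool = True,
                  episode: int = 0) -> int:
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        self._grow()
        seg_id = self._n
        self._seg_p0[seg_id] = p0
        self._seg_p1[seg_id] = p1
        self._seg_path[seg_id] = path_id
        self._seg_birth[seg_id] = episode
        self._seg_last_sprout[seg_id] = -(10**9)
        self._seg_prev_state[seg_id] = -1
        self._seg_prev_action[seg_id] = -1
        self._seg_prev_q[seg_id] = 0.0
        self._n += 1
        length = float(np.hypot(*(p1 - p0)))
        self.total_length_um += length
        if register:
            self.grid.register_segment(seg_id, p0, p1, "stalk")
        return seg_id

    def spawn_tip(self, pos, path_id: int | None = None) -> TipAgent:
        tip = TipAgent(np.asarray(pos, dtype=float),
                       self.new_path() if path_id is None else path_id)
        self.tips.append(tip)
        r, c = self.grid.site_of(*tip.pos)
        self.grid.tip_count[r, c] += 1
        return tip

    def remove_tip(self, tip: TipAgent) -> None:
        r, c = self.grid.site_of(*tip.pos)
        self.grid.tip_count[r, c] -= 1
        self.tips.remove(tip)

    def move_tip(self, tip: TipAgent, new_pos) -> None:
        r0, c0 = self.grid.site_of(*tip.pos)
        r1, c1 = self.grid.site_of(*np.asarray(new_pos, dtype=float))
        if (r0, c0) != (r1, c1):
            self.grid.tip_count[r0, c0] -= 1
            self.grid.tip_count[r1, c1] += 1
        tip.pos = np.asarray(new_pos, dtype=float)

    def paths_at_site(self, site: tuple[int, int]) -> set[int]:
        return {self.seg_path[s] for s in self.grid.segments_at(*site)
                if s < self.n_segments}


def vegf_neighborhood_max(grid) -> np.ndarray:
    """Max VEGF over each site and its Moore neighbors (vessel sensing).

    Vessels are near-perfect local VEGF sinks, so an agent senses the factor
    over the same current-plus-Moore candidate set it may sprout into.
    """
    return ndimage.maximum_filter(grid.conc[VEGF], size=3, mode="nearest")


def execute_vessel_phenotype(vs: VesselSystem, tip: TipAgent, grid,
                             rng: np.random.Generator,
                             phenotype: int | None = None,
                             episode: int = 0) -> dict:
    """Execute one tip's chosen phenotype (sprout / branch / quiescence).

    A sprouting tip commits to a random point inside the max-VEGF TME among
    its current site and Moore neighbors, advances 60 µm per episode along
    the straight line, and deposits a new stalk segment at each move; it
    keeps the sprout phenotype until arrival.  A branching tip spawns a new
    tip aimed at the second-highest-VEGF neighbor.  A tip entering a TME
    already containing a non-parent segment anastomoses: it joins the
    network and is retired as quiescent stalk.
    """
    from .params import V_BRANCH, V_QUIESCENCE, V_SPROUT

    cfg = grid.config
    delta = {"moved": False, "arrived": False, "branched": False, "anastomosed": False}
    tip.age += 1
    phen = tip.phenotype if phenotype is None else phenotype
    if tip.committed:
        phen = V_SPROUT  # commitment locks the sprout phenotype
    tip.phenotype = phen
    if phen == V_BRANCH:
        site = grid.site_of(*tip.pos)
        second = _second_highest_vegf_neighbor(grid, site, rng)
        new_tip = vs.spawn_tip(tip.pos.copy())
        if second is not None:
            r, c = second
            new_tip.dest = np.array([(c + rng.random()) * grid.tme_um,
                                     (r + rng.random()) * grid.tme_um])
            new_tip.committed = True
            new_tip.phenotype = V_SPROUT
        vs.n_branch_points += 1
        tip.age = 0
        delta["branched"] = True
        return delta
    if phen != V_SPROUT:
        return delta
    if not tip.committed:
        site = grid.site_of(*tip.pos)
        dest = select_destination_tme(grid, site, "max-vegf", False, rng)
        r, c = dest
        tip.dest = np.array([(c + rng.random()) * grid.tme_um,
                             (r + rng.random()) * grid.tme_um])
        tip.committed = True
    vec = tip.dest - tip.pos
    dist = float(np.hypot(*vec))
    step = cfg.sprout_um_per_episode
    new_pos = tip.dest.copy() if dist <= step else tip.pos + vec * (step / dist)
    vs.add_stalk(tip.pos, new_pos, tip.path_id, episode=episode)
    own_site_before = grid.site_of(*tip.pos)
    vs.move_tip(tip, new_pos)
    delta["moved"] = True
    if dist <= step:
        tip.committed = False
        tip.phenotype = V_QUIESCENCE
        delta["arrived"] = True
    new_site = grid.site_of(*tip.pos)
    if new_site != own_site_before:
        foreign = vs.paths_at_site(new_site) - {tip.path_id}
        other_tip = grid.tip_count[new_site] > 1  # self is counted
        if foreign or other_tip:
            vs.remove_tip(tip)
            vs.n_branch_points += 1
            delta["anastomosed"] = True
    return delta


def _second_highest_vegf_neighbor(grid, site, rng):
    neigh = moore_neighbors(grid, site)
    if len(neigh) < 2:
        return neigh[0] if neigh else None
    vals = np.array([grid.conc[VEGF][s] for s in neigh])
    order = np.argsort(-(vals + 1e-12 * rng.random(vals.size)))
    return neigh[order[1]]
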