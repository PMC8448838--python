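"""Training phase: policy rules, rewards, SARSA updates and the experience
dataset.

The ten behavioral policies compare a per-agent state variable x against a
threshold T and favor actions on each side.  The per-transition reward is
the sum over applicable rules of tanh(x − T) when the chosen action is
favored above the threshold and tanh(T − x) when favored below (zero when
the rule does not mention the action).  Q-values live in a tabular model
indexed by the bit-vector of threshold comparisons -- the minimal
discretization of the rule variables -- and are updated on-policy:

    Q(s,a) ← (1−α)·Q(s,a) + α·[r + γ·Q(s',a')]

Actions during training are drawn by roulette selection proportional to the
Q-values of the current state, shifted to be non-negative.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import (
    CELL_PHENOTYPES,
    HYPOXIA,
    MIGRATION,
    NECROSIS,
    POLICY_THRESHOLDS,
    PROLIFERATION,
    QUIESCENCE,
    V_BRANCH,
    V_QUIESCENCE,
    V_SPROUT,
    VESSEL_PHENOTYPES,
    SimulationConfig,
)

ROULETTE_EPS = 1e-6


@dataclasses.dataclass(frozen=True)
class PolicyRule:
    """One behavioral policy: a state variable, thresholds, favored actions."""

    id: int
    variable: str
    threshold: float
    above: tuple[str, ...]  # actions favored when x > threshold
    below: tuple[str, ...]  # actions favored when x < threshold
    applies: str  # cell | tip | vessel
    band_low: float | None = None  # rule 2: lower (dead) threshold
    band_actions: tuple[str, ...] = ()  # favored inside the band

    def contribution(self, x: float, action: str) -> float:
        """This rule's reward contribution for ``action`` at state value x."""
        if action in self.above:
            return float(np.tanh(x - self.threshold))
        if action in self.below:
            ref = self.band_low if self.band_low is not None else self.threshold
            return float(np.tanh(ref - x))
        if action in self.band_actions:
            return float(np.tanh(np.minimum(x - self.band_low, self.threshold - x)))
        return 0.0


_T = POLICY_THRESHOLDS

#: Table-2 policies for cancer cells.  Rule 10 has no printed threshold; the
#: crowding midpoint (half the carrying capacity) is used, one-sided.
def cell_rules(carrying_capacity: int = 100) -> tuple[PolicyRule, ...]:
    return (
        PolicyRule(1, "oxygen", _T["oxygen"],
                   ("proliferation", "migration"), ("hypoxia", "necrosis"), "cell"),
        PolicyRule(2, "glucose", _T["glucose_active"],
                   ("proliferation", "migration"), ("necrosis",), "cell",
                   band_low=_T["glucose_dead"], band_actions=("quiescence",)),
        PolicyRule(3, "tnfa_eff", _T["tnfa"], ("necrosis",), ("quiescence",), "cell"),
        PolicyRule(4, "tgfa_eff", _T["tgfa"], ("proliferation",), ("migration",), "cell"),
        PolicyRule(7, "division_counter", _T["division_counter"],
                   ("quiescence",), ("proliferation",), "cell"),
        PolicyRule(8, "proliferation_delay", _T["proliferation_delay"],
                   ("hypoxia",), ("quiescence",), "cell"),
        PolicyRule(9, "oxygen_deficiency", _T["oxygen_deficiency"],
                   ("necrosis",), ("hypoxia",), "cell"),
        PolicyRule(10, "neighbors", carrying_capacity / 2.0,
                   ("migration",), (), "cell"),
    )


VESSEL_RULES = (
    PolicyRule(5, "vegf", _T["vegf"], ("sprout",), ("quiescence",), "vessel"),
    PolicyRule(6, "vessel_age", _T["vessel_age"], ("branch",), ("quiescence",), "tip"),
)


def policy_state_value(agent, tme, rule: PolicyRule, scales: dict[str, float],
                       grid=None) -> float:
    """The state variable x feeding one rule, on the policy scale.

    Counters and ages are raw; concentrations are divided by the per-material
    policy scale; the effective growth-factor signals are ligand x bound
    fraction.  Vessel VEGF sensing uses the neighborhood maximum when the
    grid is supplied.
    """
    v = rule.variable
    if rule.applies == "cell":
        if not hasattr(agent, "phen") and not hasattr(agent, "phenotype"):
            raise ValueError(f"rule {rule.id} applies to cells")
        if v == "oxygen":
            return float(tme.conc[0]) / scales["oxygen"]
        if v == "glucose":
            return float(tme.conc[1]) / scales["glucose"]
        if v == "tgfa_eff":
            return float(tme.conc[2]) * float(agent.b_egfr) / scales["tgfa"]
        if v == "tnfa_eff":
            return float(tme.conc[3]) * float(agent.b_tnfr) / scales["tnfa"]
        if v == "division_counter":
            return float(agent.divctr)
        if v == "proliferation_delay":
            return float(agent.delay)
        if v == "oxygen_deficiency":
            return float(agent.o2timer)
        if v == "neighbors":
            return float(max(tme.n_cells - 1, 0))
    else:
        if not hasattr(agent, "path_id"):
            raise ValueError(f"rule {rule.id} applies to vessels")
        if v == "vegf":
            if grid is not None:
                from .agents import vegf_neighborhood_max

                return float(vegf_neighborhood_max(grid)[tme.row, tme.col]) / scales["vegf"]
            return float(tme.conc[4]) / scales["vegf"]
        if v == "vessel_age":
            return float(agent.age)
    raise ValueError(f"rule {rule.id} ({v}) not applicable to this agent")


def compute_reward(values: dict[str, float], action: str,
                   rules: tuple[PolicyRule, ...]) -> float:
    """Reward r = Σ_rules contribution(x, action) over applicable rules."""
    return float(sum(r.contribution(values[r.variable], action) for r in rules
                     if r.variable in values))


# -- Q model ------------------------------------------------------------------


class QModel:
    """Tabular Q shared per agent class, indexed by threshold bit-vectors."""

    def __init__(self, n_states: int, n_actions: int):
        self.q = np.zeros((n_states, n_actions))

    def __call__(self, s: int, a: int) -> float:
        return float(self.q[s, a])

    def row(self, s) -> np.ndarray:
        return self.q[s]


def sarsa_update(q: np.ndarray, s: int, a: int, r: float, s2: int, a2: int,
                 alpha: float, gamma: float) -> float:
    """One on-policy temporal-difference update; returns the new Q(s,a)."""
    if not (0.0 <= alpha <= 1.0 and 0.0 <= gamma <= 1.0):
        raise ValueError("alpha and gamma must lie in [0, 1]")
    q[s, a] = (1.0 - alpha) * q[s, a] + alpha * (r + gamma * q[s2, a2])
    return float(q[s, a])


def batch_sarsa_update(q: np.ndarray, s: np.ndarray, a: np.ndarray,
                       targets: np.ndarray, alpha: float,
                       order: np.ndarray | None = None) -> None:
    """Apply many sequential SARSA updates to a shared table, vectorized.

    ``targets`` are r + γ·Q(s', a') evaluated against the pre-update table.
    For k updates hitting the same (s, a) in positions j = 0..k−1 of
    ``order``, the exact sequential result is

        Q ← (1−α)^k Q + α Σ_j (1−α)^{k−1−j} t_j

    which is what this computes per group.
    """
    m = s.size
    if m == 0:
        return
    if order is None:
        order = np.arange(m)
    n_actions = q.shape[1]
    keys = s[order] * n_actions + a[order]
    sort = np.argsort(keys, kind="stable")
    ks = keys[sort]
    ts = targets[order][sort]
    starts = np.flatnonzero(np.r_[True, ks[1:] != ks[:-1]])
    counts = np.diff(np.r_[starts, ks.size])
    rank = np.arange(ks.size) - np.repeat(starts, counts)
    k_of = np.repeat(counts, counts)
    with np.errstate(under="ignore"):
        w = alpha * (1.0 - alpha) ** (k_of - 1 - rank)
        decay_flat = (1.0 - alpha) ** counts
    flat = q.reshape(-1)
    ukeys = ks[starts]
    contrib = np.zeros_like(ukeys, dtype=float)
    np.add.at(contrib, np.repeat(np.arange(ukeys.size), counts), w * ts)
    flat[ukeys] = flat[ukeys] * decay_flat + contrib


# -- action selection ---------------------------------------------------------


def weighted_random_action(q_values: np.ndarray, rng: np.random.Generator,
                           available: np.ndarray | None = None) -> int:
    """Roulette selection proportional to shifted Q over available actions.

    Q-values are shifted by −min + ε so the printed scheme (draw in
    [0, ΣQ)) applies to negative values as well; all-equal Q reduces to a
    uniform draw.
    """
    q_values = np.asarray(q_values, dtype=float)
    if available is None:
        available = np.ones(q_values.size, dtype=bool)
    idx = np.flatnonzero(available)
    if idx.size == 0:
        raise ValueError("empty action set")
    w = q_values[idx]
    lo = w.min()
    if lo < 0:
        w = w - lo + ROULETTE_EPS  # negative Q: shift into the printed scheme
    total = w.sum()
    if total <= 0:
        return int(idx[rng.integers(idx.size)])  # all-zero Q: uniform
    u = rng.random() * total
    return int(idx[np.searchsorted(np.cumsum(w), u, side="right").clip(0, idx.size - 1)])


def roulette_select(q_rows: np.ndarray, rng: np.random.Generator,
                    available: np.ndarray | None = None) -> np.ndarray:
    """Vectorized roulette selection, one action per row."""
    n, k = q_rows.shape
    if available is None:
        available = np.ones_like(q_rows, dtype=bool)
    masked = np.where(available, q_rows, np.inf)
    mins = np.minimum(masked.min(axis=1, keepdims=True), 0.0)
    w = np.where(available, q_rows - mins, 0.0)
    w = np.where(available & (mins < 0), w + ROULETTE_EPS, w)
    total = w.sum(axis=1, keepdims=True)
    # all-zero rows: uniform over the available actions
    zero = total[:, 0] <= 0
    if zero.any():
        w[zero] = available[zero].astype(float)
        total = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    u = rng.random(n) * total[:, 0]
    return np.minimum((u[:, None] >= cum).sum(axis=1), k - 1)


# -- state discretization -----------------------------------------------------

N_CELL_STATES = 2 ** 8
N_VESSEL_STATES = 2 ** 2


def cell_state_index(values: dict[str, np.ndarray]) -> np.ndarray:
    """Threshold-binarized state index for cells (8 comparison bits)."""
    t = POLICY_THRESHOLDS
    bits = [
        values["oxygen"] > t["oxygen"],
        values["glucose"] > t["glucose_active"],
        values["glucose"] > t["glucose_dead"],
        values["tnfa_eff"] > t["tnfa"],
        values["tgfa_eff"] > t["tgfa"],
        values["division_counter"] > t["division_counter"],
        values["proliferation_delay"] > t["proliferation_delay"],
        values["oxygen_deficiency"] > t["oxygen_deficiency"],
    ]
    out = np.zeros_like(np.asarray(bits[0]), dtype=np.int64)
    for b in bits:
        out = (out << 1) | np.asarray(b).astype(np.int64)
    return out


def vessel_state_index(vegf: np.ndarray, age: np.ndarray) -> np.ndarray:
    t = POLICY_THRESHOLDS
    return ((np.asarray(vegf) > t["vegf"]).astype(np.int64) << 1) | (
        np.asarray(age) > t["vessel_age"]).astype(np.int64)


# -- vectorized state values and rewards for the population -------------------


def cell_state_values(pop, grid) -> dict[str, np.ndarray]:
    """Policy-scale state variables for every cell, as arrays."""
    from .signaling import effective_ligands

    n = pop.n
    s = grid.config.scales()
    tme = pop.tme[:n]
    tgfa_eff, tnfa_eff = effective_ligands(pop, grid)
    occ = np.bincount(tme, minlength=grid.n_sites)
    return {
        "oxygen": grid.conc[0].reshape(-1)[tme] / s["oxygen"],
        "glucose": grid.conc[1].reshape(-1)[tme] / s["glucose"],
        "tgfa_eff": tgfa_eff / s["tgfa"],
        "tnfa_eff": tnfa_eff / s["tnfa"],
        "division_counter": pop.divctr[:n].astype(float),
        "proliferation_delay": pop.delay[:n].astype(float),
        "oxygen_deficiency": pop.o2timer[:n].astype(float),
        "neighbors": np.maximum(occ[tme] - 1, 0).astype(float),
    }


def cell_reward_matrix(values: dict[str, np.ndarray],
                       carrying_capacity: int) -> np.ndarray:
    """(n, 5) reward matrix over the five cell phenotypes."""
    t = _T
    n = values["oxygen"].size
    out = np.zeros((n, 5))
    c1 = np.tanh(values["oxygen"] - t["oxygen"])
    out[:, PROLIFERATION] += c1
    out[:, MIGRATION] += c1
    out[:, HYPOXIA] -= c1
    out[:, NECROSIS] -= c1
    g = values["glucose"]
    c2 = np.tanh(g - t["glucose_active"])
    out[:, PROLIFERATION] += c2
    out[:, MIGRATION] += c2
    out[:, NECROSIS] += np.tanh(t["glucose_dead"] - g)
    out[:, QUIESCENCE] += np.tanh(
        np.minimum(g - t["glucose_dead"], t["glucose_active"] - g))
    c3 = np.tanh(values["tnfa_eff"] - t["tnfa"])
    out[:, NECROSIS] += c3
    out[:, QUIESCENCE] -= c3
    c4 = np.tanh(values["tgfa_eff"] - t["tgfa"])
    out[:, PROLIFERATION] += c4
    out[:, MIGRATION] -= c4
    c7 = np.tanh(values["division_counter"] - t["division_counter"])
    out[:, QUIESCENCE] += c7
    out[:, PROLIFERATION] -= c7
    c8 = np.tanh(values["proliferation_delay"] - t["proliferation_delay"])
    out[:, HYPOXIA] += c8
    out[:, QUIESCENCE] -= c8
    c9 = np.tanh(values["oxygen_deficiency"] - t["oxygen_deficiency"])
    out[:, NECROSIS] += c9
    out[:, HYPOXIA] -= c9
    out[:, MIGRATION] += np.tanh(values["neighbors"] - carrying_capacity / 2.0)
    return out


def vessel_reward_matrix(vegf: np.ndarray, age: np.ndarray,
                         is_tip: np.ndarray) -> np.ndarray:
    """(n, 3) reward matrix over quiescence/branch/sprout for vessels."""
    t = _T
    n = np.asarray(vegf).size
    out = np.zeros((n, 3))
    c5 = np.tanh(np.asarray(vegf) - t["vegf"])
    out[:, V_SPROUT] += c5
    out[:, V_QUIESCENCE] -= c5
    c6 = np.tanh(np.asarray(age) - t["vessel_age"])
    out[:, V_BRANCH] += np.where(is_tip, c6, 0.0)
    out[:, V_QUIESCENCE] -= np.where(is_tip, c6, 0.0)
    return out


# -- experience dataset -------------------------------------------------------

CELL_RECORD_COLUMNS = (
    [f"prev_{m}" for m in ("oxygen", "glucose", "tgfa", "tnfa", "vegf")]
    + ["oxygen", "glucose", "tgfa", "tnfa", "vegf"]
    + ["n_cells", "prev_divctr", "divctr", "n_necrotic", "n_hypoxic",
       "age", "delay", "o2timer", "prev_q", "q",
       "prev_phen", "phen", "prev_nb_phen", "nb_phen"]
)
VESSEL_RECORD_COLUMNS = (
    [f"prev_{m}" for m in ("oxygen", "glucose", "tgfa", "tnfa", "vegf")]
    + ["oxygen", "glucose", "tgfa", "tnfa", "vegf"]
    + ["n_vessels", "n_branching", "n_sprouting", "age",
       "prev_q", "q", "prev_phen", "phen", "prev_nb_phen", "nb_phen"]
)
#: the classifier's label column (the phenotype just chosen)
LABEL_COLUMN = "phen"


class ExperienceDataset:
    """Append-only record store built during the training phase.

    Records survive across training repetitions; the ``repetition`` column
    tracks provenance.
    """

    def __init__(self, agent_class: str):
        if agent_class not in ("cell", "vessel"):
            raise ValueError("agent_class must be cell|vessel")
        self.agent_class = agent_class
        self.columns = list(CELL_RECORD_COLUMNS if agent_class == "cell"
                            else VESSEL_RECORD_COLUMNS) + ["repetition"]
        self._chunks: list[np.ndarray] = []
        self._n = 0

    def __len__(self) -> int:
        return self._n

    def append(self, records: np.ndarray, rewards: np.ndarray,
               threshold: float, repetition: int) -> int:
        """Add the records whose reward strictly exceeds the threshold."""
        records = np.atleast_2d(records)
        if records.shape[1] != len(self.columns) - 1:
            raise ValueError(
                f"record has {records.shape[1]} attributes, schema expects "
                f"{len(self.columns) - 1}")
        keep = np.asarray(rewards) > threshold
        if keep.any():
            block = np.column_stack(
                [records[keep], np.full(int(keep.sum()), repetition, dtype=float)])
            self._chunks.append(block)
            self._n += block.shape[0]
        return int(keep.sum())

    def to_array(self) -> np.ndarray:
        if not self._chunks:
            return np.empty((0, len(self.columns)))
        if len(self._chunks) > 1:
            self._chunks = [np.vstack(self._chunks)]
        return self._chunks[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.to_array(), columns=self.columns)

    def save(self, base) -> None:
        import json
        from pathlib import Path

        base = Path(base)
        self.to_frame().to_csv(base.with_suffix(".csv"), index=False)
        base.with_suffix(".schema.json").write_text(json.dumps(
            {"agent_class": self.agent_class, "columns": self.columns,
             "label": LABEL_COLUMN}, indent=2))


def record_transition(dataset: ExperienceDataset, record: np.ndarray, r: float,
                      config: SimulationConfig) -> ExperienceDataset:
    """Append one transition iff its reward strictly exceeds the threshold."""
    thr = (-np.inf if config.reward_threshold is None
           else config.reward_threshold)
    dataset.append(np.atleast_2d(record), np.atleast_1d(r), thr, repetition=-1)
    return dataset


def train(config, grid=None, net=None, rng=None):
    """Run the training phase; see :func:`tmesim.world.run_training`."""
    from .world import run_training

    return run_training(config, grid=grid, net=net, rng=rng)
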