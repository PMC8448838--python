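"""Microscopic scale: EGFR/TNFR ligand binding.

Each cell carries a bound-receptor fraction b ∈ [0, 1] per pathway (EGFR
for TGFα, TNFR for TNFα), evolving by first-order mass action

    db/dt = k_on · L · (1 − b) − k_off · b

with L the local ligand concentration (µM).  The update uses the exact
exponential solution of this linear ODE over the episode, which is
unconditionally stable and shares its fixed point

    b* = k_on·L / (k_on·L + k_off)

with the sub-stepped Euler scheme it replaces.  The policy layer consumes
the product L·b as the cell's effective TGFα/TNFα state variable.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import TGFA, TNFA


@dataclasses.dataclass
class ReceptorState:
    b_egfr: float
    b_tnfr: float

    def __post_init__(self) -> None:
        for b in (self.b_egfr, self.b_tnfr):
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"bound fraction {b} outside [0, 1]")


def bind_update(b, ligand, k_on: float, k_off: float, dt_s: float):
    """Advance bound fractions by the closed-form mass-action solution."""
    if k_on < 0 or k_off < 0:
        raise ValueError("rate constants must be non-negative")
    a = k_on * np.asarray(ligand, dtype=float)
    rate = a + k_off
    with np.errstate(divide="ignore", invalid="ignore"):
        b_star = np.where(rate > 0, a / np.where(rate > 0, rate, 1.0), np.asarray(b))
    return b_star + (np.asarray(b) - b_star) * np.exp(-rate * dt_s)


def equilibrium(ligand: float, k_on: float, k_off: float) -> float:
    """Hill-1 steady-state bound fraction."""
    a = k_on * ligand
    return a / (a + k_off) if (a + k_off) > 0 else 0.0


def signaling_step(cell, tme, dt_s: float, k_on: float, k_off: float) -> ReceptorState:
    """Update one cell's receptor state from its TME's ligand levels.

    Returns the new state; the cell's stored fractions are updated in place.
    """
    l_tgfa = float(tme.conc[TGFA])
    l_tnfa = float(tme.conc[TNFA])
    cell.b_egfr = float(bind_update(cell.b_egfr, l_tgfa, k_on, k_off, dt_s))
    cell.b_tnfr = float(bind_update(cell.b_tnfr, l_tnfa, k_on, k_off, dt_s))
    return ReceptorState(float(cell.b_egfr), float(cell.b_tnfr))


def step_signaling(pop, grid) -> None:
    """Vectorized receptor update for the whole population."""
    n = pop.n
    if n == 0:
        return
    cfg = grid.config
    tme = pop.tme[:n]
    l_tgfa = grid.conc[TGFA].reshape(-1)[tme]
    l_tnfa = grid.conc[TNFA].reshape(-1)[tme]
    pop.b_egfr[:n] = bind_update(pop.b_egfr[:n], l_tgfa, cfg.k_on, cfg.k_off, cfg.dt_s)
    pop.b_tnfr[:n] = bind_update(pop.b_tnfr[:n], l_tnfa, cfg.k_on, cfg.k_off, cfg.dt_s)


def effective_ligands(pop, grid) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell effective (TGFα, TNFα) = L · b, the policy state variables."""
    n = pop.n
    tme = pop.tme[:n]
    l_tgfa = grid.conc[TGFA].reshape(-1)[tme]
    l_tnfa = grid.conc[TNFA].reshape(-1)[tme]
    return l_tgfa * pop.b_egfr[:n], l_tnfa * pop.b_tnfr[:n]
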