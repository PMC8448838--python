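"""Macroscopic scale: per-episode evolution of the five concentration fields.

Each episode the lattice concentration of every material M is advanced as

    C(t+1) = C(t) + Δt·D_M·ΔC(t)/A + S(t) − U(t) − W(t)

where ΔC is the summed concentration difference over the Moore neighbors
(no-flux boundary), A the TME area, and S/U/W the per-TME secretion, uptake
and waste terms.  The literal explicit step is unstable for the tabulated
diffusion coefficients (D·Δt/A reaches ≈ 6), so the diffusion part of each
episode is split into ceil(16·D·Δt/A) equal sub-steps, keeping the per-step
coefficient at or below 1/16 of the 8-neighbor stencil's stability bound;
sources and sinks are applied once per episode, after which fields are
clamped to [0, c_max].

Nutrient exchange with the vasculature follows the vessel-radius sum R
(3x10⁻³ cm per stalk, 1x10⁻³ cm per tip crossing the TME) and the lumen
concentration ζ (5.7x10⁴/1.7x10⁴ µM glucose and 56/42 µM oxygen per
stalk/tip).  VEGF is secreted by cells in phenotype-dependent tiers
(2⁰..2⁴ from proliferation to necrosis, times 10⁻²), taken up by vessels,
and decays by 1% of the local concentration per crossing vessel segment.
Nutrient uptake uses the reversed tier (2⁴..2⁰, times 10⁻³·C).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .params import (
    GLUCOSE,
    MATERIALS,
    OXYGEN,
    TGFA,
    TNFA,
    VEGF,
    MaterialParams,
)

#: per-segment radius contribution (cm)
RADIUS_STALK_CM = 3e-3
RADIUS_TIP_CM = 1e-3

#: lumen concentrations ζ (µM) per crossing segment
LUMEN = {
    ("stalk", "glucose"): 5.7e4,
    ("stalk", "oxygen"): 5.6e1,
    ("tip", "glucose"): 1.7e4,
    ("tip", "oxygen"): 4.2e1,
}

#: VEGF secretion tier by phenotype (proliferation..necrosis)
S_VEGF_TIER = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
#: nutrient uptake tier by phenotype (proliferation..necrosis)
U_N_TIER = np.array([16.0, 8.0, 4.0, 2.0, 1.0])

VEGF_SECRETION_SCALE = 1e-2
NUTRIENT_UPTAKE_SCALE = 1e-3
VEGF_DECAY_PER_VESSEL = 1e-2

#: sub-stepping safety factor: per-sub-step diffusion number <= 1/16
STABILITY_FACTOR = 16.0


class FieldInstabilityError(RuntimeError):
    pass


@dataclasses.dataclass
class SourceSinkTerms:
    """Per-lattice S/U/W arrays (µM) for one episode, one material each."""

    secretion: np.ndarray  # (5, n, n)
    uptake: np.ndarray
    waste: np.ndarray


# -- per-TME scalar operations (the unit-test surface) ------------------------


def moore_delta(field: np.ndarray, site: tuple[int, int]) -> float:
    """Σ(Ć − C) over the existing Moore neighbors of ``site`` (no-flux)."""
    r, c = site
    h, w = field.shape
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"site {site} outside {h}x{w} field")
    total = 0.0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                total += field[rr, cc] - field[r, c]
    return total


def vessel_radius_sum(tme) -> float:
    """R (cm): 3x10⁻³ per stalk plus 1x10⁻³ per tip crossing the TME."""
    return RADIUS_STALK_CM * tme.n_stalk + RADIUS_TIP_CM * tme.n_tip


def lumen_concentration(tme, material: str) -> float:
    """ζ (µM) summed over crossing segments; nutrients only."""
    if material not in ("glucose", "oxygen"):
        raise ValueError(f"lumen concentration is defined for nutrients, not {material!r}")
    return (tme.n_stalk * LUMEN[("stalk", material)]
            + tme.n_tip * LUMEN[("tip", material)])


def secretion(tme, material: str, materials: dict[str, MaterialParams],
              dt_s: float, area_cm2: float) -> float:
    """S (µM) for one TME.

    Nutrients: transmural exchange 2πΔtA⁻¹·R·ρ·(ζ−C), floored at zero.
    VEGF: 10⁻² times the summed phenotype tier of resident cells.
    TGFα/TNFα: constant per-cell secretion Δt·Σρ.
    """
    if material not in MATERIALS:
        raise ValueError(f"unknown material {material!r}")
    mi = MATERIALS.index(material)
    if material in ("glucose", "oxygen"):
        r = vessel_radius_sum(tme)
        if r == 0.0:
            return 0.0
        zeta = lumen_concentration(tme, material)
        s = 2.0 * math.pi * dt_s / area_cm2 * r * materials[material].rho * (
            zeta - tme.conc[mi])
        return max(s, 0.0)
    if material == "vegf":
        return VEGF_SECRETION_SCALE * float(S_VEGF_TIER @ tme.phen_counts)
    # TGFα / TNFα
    return dt_s * materials[material].rho * tme.n_cells


def uptake(tme, material: str, materials: dict[str, MaterialParams],
           dt_s: float, area_cm2: float) -> float:
    """U (µM): zero for TGFα/TNFα; vessel absorption for VEGF; cell
    consumption 10⁻³·C·ΣU_N for nutrients.  Capped at the local C."""
    mi = MATERIALS.index(material)
    c = float(tme.conc[mi])
    if material in ("tgfa", "tnfa"):
        return 0.0
    if material == "vegf":
        u = (2.0 * math.pi * dt_s / area_cm2 * vessel_radius_sum(tme)
             * materials["vegf"].rho * c)
        return min(u, c)
    u = NUTRIENT_UPTAKE_SCALE * c * float(U_N_TIER @ tme.phen_counts)
    return min(u, c)


def decay(tme, material: str) -> float:
    """W (µM): each crossing vessel segment removes 1% of local VEGF."""
    if material != "vegf":
        return 0.0
    mi = MATERIALS.index(material)
    c = float(tme.conc[mi])
    return min(VEGF_DECAY_PER_VESSEL * c * tme.n_segments, c)


# -- vectorized lattice operations --------------------------------------------


_NEIGHBOR_COUNT_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _neighbor_count(shape: tuple[int, int]) -> np.ndarray:
    count = _NEIGHBOR_COUNT_CACHE.get(shape)
    if count is None:
        count = np.full(shape, 8.0)
        count[0, :] = count[-1, :] = count[:, 0] = count[:, -1] = 5.0
        count[0, 0] = count[0, -1] = count[-1, 0] = count[-1, -1] = 3.0
        if shape[0] == 1 or shape[1] == 1:  # degenerate strips
            count = np.zeros(shape)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr = slice(max(-dr, 0), shape[0] + min(-dr, 0))
                    cc = slice(max(-dc, 0), shape[1] + min(-dc, 0))
                    count[rr, cc] += 1.0
        _NEIGHBOR_COUNT_CACHE[shape] = count
    return count


def moore_delta_field(field: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
    """Vectorized Σ(Ć − C) over existing Moore neighbors (no-flux).

    The 3x3 box sum is separable: accumulate along rows, then columns, then
    subtract the center and the per-site neighbor count times C.
    """
    rs = field.copy()
    rs[1:] += field[:-1]
    rs[:-1] += field[1:]
    if out is None:
        out = rs.copy()
    else:
        out[:] = rs
    out[:, 1:] += rs[:, :-1]
    out[:, :-1] += rs[:, 1:]
    # the box sum counts the center once: delta = box − (count+1)·C
    out -= (_neighbor_count(field.shape) + 1.0) * field
    return out


def diffusion_substeps(d: float, dt_s: float, area_cm2: float) -> int:
    return max(1, math.ceil(STABILITY_FACTOR * d * dt_s / area_cm2))


def compute_terms(grid, phen_counts: np.ndarray | None = None) -> SourceSinkTerms:
    """Vectorized S/U/W lattices for the current episode."""
    cfg = grid.config
    mats = cfg.materials
    dt, area = cfg.dt_s, cfg.tme_area_cm2
    n = grid.n
    pc = grid.phenotype_counts() if phen_counts is None else phen_counts
    n_cells = pc.sum(axis=0)
    r_sum = RADIUS_STALK_CM * grid.stalk_count + RADIUS_TIP_CM * grid.tip_count
    coef = 2.0 * math.pi * dt / area
    s = np.zeros((5, n, n))
    u = np.zeros((5, n, n))
    w = np.zeros((5, n, n))
    for mi, name in ((OXYGEN, "oxygen"), (GLUCOSE, "glucose")):
        zeta = (grid.stalk_count * LUMEN[("stalk", name)]
                + grid.tip_count * LUMEN[("tip", name)])
        s[mi] = np.maximum(coef * r_sum * mats[name].rho * (zeta - grid.conc[mi]), 0.0)
        u[mi] = np.minimum(
            NUTRIENT_UPTAKE_SCALE * grid.conc[mi] * np.tensordot(U_N_TIER, pc, axes=1),
            grid.conc[mi])
    s[VEGF] = VEGF_SECRETION_SCALE * np.tensordot(S_VEGF_TIER, pc, axes=1)
    u[VEGF] = np.minimum(coef * r_sum * mats["vegf"].rho * grid.conc[VEGF],
                         grid.conc[VEGF])
    n_seg = grid.stalk_count + grid.tip_count
    w[VEGF] = np.minimum(VEGF_DECAY_PER_VESSEL * grid.conc[VEGF] * n_seg,
                         grid.conc[VEGF])
    for mi, name in ((TGFA, "tgfa"), (TNFA, "tnfa")):
        s[mi] = dt * mats[name].rho * n_cells
    return SourceSinkTerms(s, u, w)


def step_fields(grid, terms: SourceSinkTerms | None = None) -> None:
    """Advance all five fields by one episode (diffusion, then S−U−W, clamp)."""
    from .grid import clamp_concentrations

    cfg = grid.config
    mats = cfg.materials
    dt, area = cfg.dt_s, cfg.tme_area_cm2
    if terms is None:
        terms = compute_terms(grid)
    for mi, name in enumerate(MATERIALS):
        d = mats[name].d
        nsub = diffusion_substeps(d, dt, area)
        coef = d * dt / (area * nsub)
        c = grid.conc[mi]
        buf = np.empty_like(c)
        for _ in range(nsub):
            c += coef * moore_delta_field(c, out=buf)
        if not np.isfinite(c).all():
            raise FieldInstabilityError(
                f"diffusion diverged for {name} after {nsub} sub-steps")
        c += terms.secretion[mi] - terms.uptake[mi] - terms.waste[mi]
    clamp_concentrations(grid)
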