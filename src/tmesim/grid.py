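"""The TME lattice.

A :class:`TMEGrid` subdivides the square simulation domain into tumor
microenvironments (TMEs) of 200 x 200 µm.  Each site carries a homogeneous
concentration of the five diffusible factors, a roster of resident cancer
cells, and references to the microvessel segments passing through it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import (
    GLUCOSE,
    MATERIALS,
    OXYGEN,
    TGFA,
    TNFA,
    VEGF,
    ConfigurationError,
    MaterialParams,
    SimulationConfig,
    validate_materials,
)


@dataclasses.dataclass
class TME:
    """A read-mostly view of one lattice site.

    ``conc`` is the five-vector of concentrations (µM) in canonical material
    order; ``phen_counts`` counts resident cells by phenotype; ``n_stalk`` /
    ``n_tip`` count vessel segments by kind.
    """

    row: int
    col: int
    conc: np.ndarray
    phen_counts: np.ndarray
    n_stalk: int
    n_tip: int
    segment_ids: list[int]
    d_tme: float = np.nan

    @property
    def n_cells(self) -> int:
        return int(self.phen_counts.sum())

    @property
    def n_segments(self) -> int:
        return self.n_stalk + self.n_tip


class TMEGrid:
    """Square lattice of TMEs with vessel registration bookkeeping."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        n = config.grid_side
        self.n = n
        self.tme_um = config.tme_um
        #: concentration lattice, shape (5, n, n), µM
        self.conc = np.zeros((5, n, n))
        self.stalk_count = np.zeros((n, n), dtype=np.int32)
        self.tip_count = np.zeros((n, n), dtype=np.int32)
        #: per-site list of registered segment ids (sparse)
        self.site_segments: dict[tuple[int, int], list[int]] = {}
        # vessel representative point per site (length-weighted mean of the
        # sub-segments crossing the site), used for d_TME
        self._vp_sum = np.zeros((n, n, 2))
        self._vp_weight = np.zeros((n, n))
        self.cells = None  # CellPopulation, attached by seed_tumor
        self.clamp_events = 0  # concentration clamps applied so far

    # -- geometry -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.n * self.n

    def site_of(self, x_um: float, y_um: float) -> tuple[int, int]:
        """Map a point in µm to (row, col); row indexes y."""
        c = min(int(x_um // self.tme_um), self.n - 1)
        r = min(int(y_um // self.tme_um), self.n - 1)
        return r, c

    def in_bounds_um(self, x_um: float, y_um: float) -> bool:
        side = self.n * self.tme_um
        return 0.0 <= x_um <= side and 0.0 <= y_um <= side

    # -- vessel registration ------------------------------------------------

    def register_segment(self, seg_id: int, p0_um, p1_um, label: str) -> None:
        """Rasterize one vessel segment onto the sites it passes through.

        Uses exact parametric clipping against the gridlines, so the per-site
        sub-lengths sum to the full segment length and corner-touching sites
        (zero sub-length) are not registered.
        """
        if label not in ("stalk", "tip"):
            raise ValueError(f"segment label must be stalk|tip, got {label!r}")
        p0 = np.asarray(p0_um, dtype=float)
        p1 = np.asarray(p1_um, dtype=float)
        s0, s1 = self.site_of(*p0), self.site_of(*p1)
        if s0 == s1 and self.in_bounds_um(*p0) and self.in_bounds_um(*p1):
            # fast path: the segment lies within a single site
            parts = [(s0, float(np.hypot(*(p1 - p0))), (p0 + p1) / 2.0)]
        else:
            parts = self._clip(p0, p1)
        for (r, c), sublen, mid in parts:
            self.site_segments.setdefault((r, c), []).append(seg_id)
            if label == "stalk":
                self.stalk_count[r, c] += 1
            else:
                self.tip_count[r, c] += 1
            self._vp_sum[r, c] += sublen * np.asarray(mid)
            self._vp_weight[r, c] += sublen

    def _clip(self, p0_um, p1_um):
        p0 = np.asarray(p0_um, dtype=float)
        p1 = np.asarray(p1_um, dtype=float)
        for p in (p0, p1):
            if not self.in_bounds_um(*p):
                raise ValueError(
                    f"segment endpoint {tuple(p)} µm lies outside the "
                    f"{self.n * self.tme_um:g} µm domain"
                )
        length = float(np.hypot(*(p1 - p0)))
        if length == 0.0:
            yield (*self.site_of(*p0),), 0.0, p0
            return
        ts = [0.0, 1.0]
        for axis in range(2):
            lo, hi = sorted((p0[axis], p1[axis]))
            k0 = int(np.ceil(lo / self.tme_um))
            k1 = int(np.floor(hi / self.tme_um))
            for k in range(k0, k1 + 1):
                denom = p1[axis] - p0[axis]
                if denom != 0.0:
                    t = (k * self.tme_um - p0[axis]) / denom
                    if 0.0 < t < 1.0:
                        ts.append(t)
        ts = np.unique(ts)
        for ta, tb in zip(ts[:-1], ts[1:]):
            sub = (tb - ta) * length
            if sub <= 1e-12:
                continue
            mid = p0 + 0.5 * (ta + tb) * (p1 - p0)
            yield self.site_of(*mid), sub, mid

    def segments_at(self, row: int, col: int) -> list[int]:
        return self.site_segments.get((row, col), [])

    # -- occupancy ----------------------------------------------------------

    def cell_counts(self) -> np.ndarray:
        """(n, n) int array of resident cells per site (all phenotypes)."""
        if self.cells is None or self.cells.n == 0:
            return np.zeros((self.n, self.n), dtype=np.int64)
        flat = np.bincount(self.cells.tme[: self.cells.n], minlength=self.n_sites)
        return flat.reshape(self.n, self.n)

    def phenotype_counts(self) -> np.ndarray:
        """(5, n, n) cell counts by phenotype."""
        out = np.zeros((5, self.n_sites), dtype=np.int64)
        if self.cells is not None and self.cells.n > 0:
            tme = self.cells.tme[: self.cells.n]
            phen = self.cells.phen[: self.cells.n]
            np.add.at(out, (phen, tme), 1)
        return out.reshape(5, self.n, self.n)

    def tme(self, row: int, col: int) -> TME:
        pc = self.phenotype_counts()[:, row, col]
        return TME(
            row,
            col,
            self.conc[:, row, col].copy(),
            pc,
            int(self.stalk_count[row, col]),
            int(self.tip_count[row, col]),
            list(self.segments_at(row, col)),
        )

    # -- d_TME --------------------------------------------------------------

    def compute_d_tme(self) -> np.ndarray:
        """Mean cell-vessel distance per site, in TME side-length units.

        Sites lacking cells or vessels take the configured far-distance
        sentinel.
        """
        far = self.config.far_distance
        out = np.full((self.n, self.n), far)
        has_vessel = self._vp_weight > 0
        if self.cells is None or self.cells.n == 0 or not has_vessel.any():
            return out
        vp = np.where(
            self._vp_weight[..., None] > 0,
            self._vp_sum / np.maximum(self._vp_weight, 1e-300)[..., None],
            0.0,
        )
        n = self.cells.n
        tme = self.cells.tme[:n]
        pos = self.cells.pos[:n]
        rows, cols = np.divmod(tme, self.n)
        site_has_vessel = has_vessel[rows, cols]
        if not site_has_vessel.any():
            return out
        sel = site_has_vessel
        d = np.hypot(
            pos[sel, 0] - vp[rows[sel], cols[sel], 0],
            pos[sel, 1] - vp[rows[sel], cols[sel], 1],
        ) / self.tme_um
        dsum = np.zeros(self.n_sites)
        dcnt = np.zeros(self.n_sites)
        np.add.at(dsum, tme[sel], d)
        np.add.at(dcnt, tme[sel], 1)
        mask = dcnt > 0
        flat = out.reshape(-1)
        flat[mask] = dsum[mask] / dcnt[mask]
        return out


# -- module operations -------------------------------------------------------


def build_grid(config: SimulationConfig) -> TMEGrid:
    """Construct the empty lattice: (side/tme)² sites, zero concentrations."""
    return TMEGrid(config)


def init_fields(
    grid: TMEGrid,
    materials: dict[str, MaterialParams] | None = None,
    sigma2: float | None = None,
) -> TMEGrid:
    """Initialize the concentration fields from the cell-vessel geometry.

    Oxygen and glucose start at ``c_normal + (c_max - c_normal) ·
    exp(-2 d_TME / σ²)`` so that well-perfused sites (d_TME → 0) sit at the
    maximum concentration and avascular sites relax to normal tissue levels.
    TGFα/TNFα use the growth-factor branch ``c_normal · exp(-2 D_M / σ²)``
    (a spatially uniform field, the diffusion coefficient being a constant);
    with ``eq1_use_dtme_for_growth_factors`` set, d_TME is substituted for
    D_M.  VEGF starts at zero.  All values are clamped to [0, c_max].
    """
    materials = materials if materials is not None else grid.config.materials
    validate_materials(materials)
    sigma2 = sigma2 if sigma2 is not None else grid.config.sigma2
    if sigma2 <= 0:
        raise ConfigurationError("sigma2 must be > 0")
    d = grid.compute_d_tme()
    for idx, name in ((OXYGEN, "oxygen"), (GLUCOSE, "glucose")):
        m = materials[name]
        grid.conc[idx] = m.c_normal + (m.c_max - m.c_normal) * np.exp(-2.0 * d / sigma2)
    for idx, name in ((TGFA, "tgfa"), (TNFA, "tnfa")):
        m = materials[name]
        if grid.config.eq1_use_dtme_for_growth_factors:
            grid.conc[idx] = m.c_normal * np.exp(-2.0 * d / sigma2)
        else:
            grid.conc[idx] = np.full((grid.n, grid.n), m.c_normal * np.exp(-2.0 * m.d / sigma2))
    grid.conc[VEGF] = 0.0
    clamp_concentrations(grid, materials)
    return grid


def clamp_concentrations(grid: TMEGrid, materials: dict[str, MaterialParams] | None = None) -> None:
    """Clamp every field into [0, c_max]; counts clamp events."""
    materials = materials if materials is not None else grid.config.materials
    for idx, name in enumerate(MATERIALS):
        hi = materials[name].c_max
        c = grid.conc[idx]
        lo_mask = c < 0.0
        if hi is not None:
            hi_mask = c > hi
            grid.clamp_events += int(lo_mask.sum() + hi_mask.sum())
            np.clip(c, 0.0, hi, out=c)
        else:
            grid.clamp_events += int(lo_mask.sum())
            np.clip(c, 0.0, None, out=c)


def seed_tumor(grid: TMEGrid, n: int, rng: np.random.Generator):
    """Place ``n`` cancer cells at the domain center with random phenotypes.

    Sites are filled outward from the central TME in concentric Moore
    (Chebyshev) rings, each up to the carrying capacity; the fill order
    within a ring is deterministic (row-major), so identical seeds give
    identical placements.
    """
    from .agents import CellPopulation  # local import to avoid a cycle

    if n < 1:
        raise ValueError("need at least one cell")
    cap = grid.config.carrying_capacity
    total_capacity = cap * grid.n_sites
    if n > total_capacity:
        raise ConfigurationError(
            f"cannot seed {n} cells: grid capacity is {total_capacity} "
            f"({grid.n_sites} sites x {cap} cells)"
        )
    center = grid.n // 2
    order: list[tuple[int, int]] = []
    remaining = n
    ring = 0
    while remaining > 0:
        sites = _ring_sites(center, ring, grid.n)
        for s in sites:
            take = min(cap, remaining)
            order.append((s, take))
            remaining -= take
            if remaining == 0:
                break
        ring += 1
    pop = CellPopulation(capacity=max(2 * n, 64))
    for (r, c), k in order:
        xs = (c + rng.random(k)) * grid.tme_um
        ys = (r + rng.random(k)) * grid.tme_um
        phen = rng.integers(0, 5, size=k)
        pop.add(
            x=xs, y=ys, tme=np.full(k, r * grid.n + c, dtype=np.int64), phen=phen
        )
    grid.cells = pop
    return grid


def _ring_sites(center: int, ring: int, n: int) -> list[tuple[int, int]]:
    """Sites at Chebyshev distance ``ring`` from the center, row-major."""
    out = []
    for r in range(center - ring, center + ring + 1):
        for c in range(center - ring, center + ring + 1):
            if max(abs(r - center), abs(c - center)) == ring and 0 <= r < n and 0 <= c < n:
                out.append((r, c))
    return out
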