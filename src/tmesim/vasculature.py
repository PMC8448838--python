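"""Vessel-network acquisition.

The microvascular input to a simulation is a spatial graph of tip/stalk
segments.  It can come from a grayscale angiographic image (two-cluster
K-means segmentation of the bright-vessel/dark-background raster, then
morphological skeletonization and graph tracing), from a vessel-graph file,
or from the in-repo synthetic phantom generator, which emulates a sparse
branching bright-vessel network at 20 µm/pixel and returns the exact
generating graph alongside the raster.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize
from sklearn.cluster import KMeans

from .params import POLICY_THRESHOLDS

#: age (episodes) at which a segment counts as established vasculature
_MATURE_EPISODES = int(POLICY_THRESHOLDS["vessel_age"])


@dataclasses.dataclass
class GrayImage:
    """A 2-D grayscale raster with physical pixel size."""

    pixels: np.ndarray  # 2-D, non-negative intensities
    pixel_um: float = 20.0
    bandpass: tuple[float, float] | None = None  # intensity window (low, high)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D raster")
        if (self.pixels < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.pixel_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclasses.dataclass
class Segment:
    src: int
    dst: int
    label: str  # tip | stalk
    length_um: float


class VesselNetwork:
    """A spatial graph of microvessel segments.

    Nodes are points in cm; segments connect node pairs and carry a
    ``tip``/``stalk`` label and a length in µm.  Branch points are nodes of
    degree >= 3.
    """

    def __init__(self):
        self.nodes: dict[int, tuple[float, float]] = {}  # id -> (x_cm, y_cm)
        self.segments: list[Segment] = []

    def add_node(self, x_cm: float, y_cm: float) -> int:
        nid = len(self.nodes)
        self.nodes[nid] = (float(x_cm), float(y_cm))
        return nid

    def add_segment(self, src: int, dst: int, label: str, length_um: float) -> None:
        if src == dst:
            raise ValueError("self-loop segments are not allowed")
        if length_um <= 0:
            raise ValueError("segment length must be positive")
        if label not in ("tip", "stalk"):
            raise ValueError(f"label must be tip|stalk, got {label!r}")
        self.segments.append(Segment(src, dst, label, float(length_um)))

    def degrees(self) -> dict[int, int]:
        deg = {nid: 0 for nid in self.nodes}
        for s in self.segments:
            deg[s.src] += 1
            deg[s.dst] += 1
        return deg

    @property
    def branch_points(self) -> list[int]:
        return [nid for nid, d in self.degrees().items() if d >= 3]

    @property
    def tip_nodes(self) -> list[int]:
        return [nid for nid, d in self.degrees().items() if d == 1]

    @property
    def total_length_um(self) -> float:
        return sum(s.length_um for s in self.segments)

    def validate(self) -> None:
        """Check the structural invariants (tip labels on degree-1 ends)."""
        deg = self.degrees()
        for s in self.segments:
            if s.label == "tip" and deg[s.src] > 1 and deg[s.dst] > 1:
                raise ValueError(
                    f"tip-labeled segment {s.src}-{s.dst} has no degree-1 endpoint")

    # -- file interface (CSV pair + JSON sidecar) ---------------------------

    def save(self, base: str | Path) -> None:
        base = Path(base)
        pd.DataFrame(
            [(nid, x, y) for nid, (x, y) in self.nodes.items()],
            columns=["node_id", "x_cm", "y_cm"],
        ).to_csv(base.with_suffix(".nodes.csv"), index=False)
        pd.DataFrame(
            [(s.src, s.dst, s.label, s.length_um) for s in self.segments],
            columns=["src", "dst", "label", "length_um"],
        ).to_csv(base.with_suffix(".edges.csv"), index=False)
        meta = {
            "n_nodes": len(self.nodes),
            "n_segments": len(self.segments),
            "n_branch_points": len(self.branch_points),
            "total_length_um": self.total_length_um,
        }
        base.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, base: str | Path) -> "VesselNetwork":
        base = Path(base)
        net = cls()
        nodes = pd.read_csv(base.with_suffix(".nodes.csv"))
        for _, row in nodes.iterrows():
            net.nodes[int(row.node_id)] = (float(row.x_cm), float(row.y_cm))
        edges = pd.read_csv(base.with_suffix(".edges.csv"))
        for _, row in edges.iterrows():
            net.add_segment(int(row.src), int(row.dst), row.label, float(row.length_um))
        return net


# -- segmentation -------------------------------------------------------------


def kmeans_segment(image: GrayImage, k: int = 2,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Two-cluster K-means on pixel intensities; bright cluster = vessel.

    The optional intensity bandpass (the analogue of a 500-1000 HU window on
    CT data) is applied first: intensities outside the window are treated as
    background.  Lloyd's algorithm runs on the unique intensity values with
    multiplicity weights, which is exact and fast for rasters.
    """
    if k < 2:
        raise ValueError("cannot partition an image into fewer than 2 clusters")
    px = image.pixels.astype(float)
    if image.bandpass is not None:
        lo, hi = image.bandpass
        px = np.where((px >= lo) & (px <= hi), px, 0.0)
    vals, counts = np.unique(px, return_counts=True)
    if vals.size < k:
        raise ValueError("no intensity contrast: image has fewer distinct "
                         f"levels ({vals.size}) than clusters ({k})")
    seed = int(rng.integers(2**31)) if rng is not None else 0
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(vals.reshape(-1, 1), sample_weight=counts)
    bright = int(np.argmax(km.cluster_centers_.ravel()))
    bright_vals = set(vals[labels == bright])
    mask = np.isin(px, sorted(bright_vals))
    return mask


# -- skeleton -> graph ---------------------------------------------------------

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def extract_network(mask: np.ndarray, pixel_um: float = 20.0) -> VesselNetwork:
    """Trace a binary vessel mask into a node/segment graph.

    The mask is skeletonized; skeleton pixels with != 2 neighbors are node
    pixels (adjacent node pixels are merged into one junction node), and the
    degree-2 chains between nodes become segments whose length is the
    pixel-gap count times the pixel size.  Degree-1 ends are labeled
    ``tip``, interior segments ``stalk``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    skel = skeletonize(mask)
    nbr = ndimage.convolve(skel.astype(np.int8), np.array(
        [[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int8), mode="constant")
    node_px = skel & (nbr != 2)
    labels, n_nodes = ndimage.label(node_px, structure=np.ones((3, 3)))
    net = VesselNetwork()
    centroids = ndimage.center_of_mass(node_px, labels, range(1, n_nodes + 1))
    for r, c in centroids:
        net.add_node(c * pixel_um * 1e-4, r * pixel_um * 1e-4)

    chain_px = skel & ~node_px
    visited = np.zeros_like(skel, dtype=bool)
    raw_edges: list[tuple[int, int, int]] = []  # (src, dst, gap_count)
    node_coords = np.argwhere(node_px)
    for r0, c0 in node_coords:
        src = labels[r0, c0] - 1
        for dr, dc in _N8:
            r, c = r0 + dr, c0 + dc
            if not _inb(skel, r, c) or not skel[r, c]:
                continue
            if node_px[r, c]:
                dst = labels[r, c] - 1
                if dst != src:
                    # direct node-to-node contact between different clusters
                    if (src, dst) not in [(e[0], e[1]) for e in raw_edges] and \
                       (dst, src) not in [(e[0], e[1]) for e in raw_edges]:
                        raw_edges.append((src, dst, 1))
                continue
            if visited[r, c]:
                continue
            gaps = 1
            pr, pc = r0, c0
            cr, cc = r, c
            while True:
                visited[cr, cc] = True
                nxt = None
                for dr2, dc2 in _N8:
                    rr, cc2 = cr + dr2, cc + dc2
                    if not _inb(skel, rr, cc2) or not skel[rr, cc2]:
                        continue
                    if (rr, cc2) == (pr, pc):
                        continue
                    if node_px[rr, cc2]:
                        nxt = ("node", rr, cc2)
                        break
                    if chain_px[rr, cc2] and not visited[rr, cc2]:
                        nxt = ("chain", rr, cc2)
                        break
                if nxt is None:
                    # dangling chain end (shouldn't normally happen)
                    dst = net.add_node(cc * pixel_um * 1e-4, cr * pixel_um * 1e-4)
                    raw_edges.append((src, dst, gaps))
                    break
                kind, rr, cc2 = nxt
                gaps += 1
                if kind == "node":
                    raw_edges.append((src, labels[rr, cc2] - 1, gaps))
                    break
                pr, pc, cr, cc = cr, cc, rr, cc2
    # cycles with no node pixel at all: pick an arbitrary start per cycle
    leftover = chain_px & ~visited
    while leftover.any():
        r0, c0 = map(int, np.argwhere(leftover)[0])
        nid = net.add_node(c0 * pixel_um * 1e-4, r0 * pixel_um * 1e-4)
        gaps = 0
        pr, pc = -9, -9
        cr, cc = r0, c0
        while True:
            visited[cr, cc] = True
            nxt = None
            for dr2, dc2 in _N8:
                rr, cc2 = cr + dr2, cc + dc2
                if _inb(skel, rr, cc2) and chain_px[rr, cc2] and \
                        not visited[rr, cc2] and (rr, cc2) != (pr, pc):
                    nxt = (rr, cc2)
                    break
            if nxt is None:
                break
            gaps += 1
            pr, pc, cr, cc = cr, cc, *nxt
        if gaps > 0:
            raw_edges.append((nid, nid + 0, gaps))  # skip: cycle back to self
        leftover = chain_px & ~visited

    deg: dict[int, int] = {}
    kept = []
    for src, dst, gaps in raw_edges:
        if src == dst:
            continue
        kept.append((src, dst, gaps))
        deg[src] = deg.get(src, 0) + 1
        deg[dst] = deg.get(dst, 0) + 1
    for src, dst, gaps in kept:
        label = "tip" if deg.get(src, 0) == 1 or deg.get(dst, 0) == 1 else "stalk"
        net.add_segment(src, dst, label, gaps * pixel_um)
    return net


def _inb(a, r, c) -> bool:
    return 0 <= r < a.shape[0] and 0 <= c < a.shape[1]


# -- synthetic phantom ---------------------------------------------------------


@dataclasses.dataclass
class PhantomParams:
    """Branching-random-walk phantom configuration.

    Defaults draw a sparse network of a few trunks on a 20 µm/pixel raster,
    mimicking a segmented microvascular image.
    """

    shape: tuple[int, int] = (250, 250)  # pixels
    pixel_um: float = 20.0
    n_trunks: int = 3
    branch_prob: float = 0.04  # per step
    step_px: int = 8
    n_steps: int = 24
    turn_sd_deg: float = 12.0
    branch_angle_deg: float = 35.0
    foreground: float = 220.0
    background: float = 15.0
    noise_sd: float = 0.0
    min_separation_px: int = 3


def synth_phantom(params: PhantomParams,
                  rng: np.random.Generator) -> tuple[GrayImage, VesselNetwork]:
    """Render a branching random walk and return raster + ground-truth graph.

    Walkers advance in straight steps with angular jitter and occasionally
    branch; a walker terminates rather than approach a foreign vessel closer
    than ``min_separation_px`` (keeping the drawn network non-overlapping so
    that the segmentation/extraction round trip is exact on noise-free
    output).
    """
    if params.n_trunks < 1:
        raise ValueError("need at least one trunk")
    h, w = params.shape
    img = np.full((h, w), params.background)
    occupied = np.zeros((h, w), dtype=bool)
    net = VesselNetwork()
    px_cm = params.pixel_um * 1e-4

    def blocked(r, c, own: set[tuple[int, int]]) -> bool:
        s = params.min_separation_px
        r0, r1 = max(0, r - s), min(h, r + s + 1)
        c0, c1 = max(0, c - s), min(w, c + s + 1)
        for rr in range(r0, r1):
            for cc in range(c0, c1):
                if occupied[rr, cc] and (rr, cc) not in own:
                    return True
        return False

    # walker: (row, col, angle, node_id, own_recent_pixels, depth)
    walkers = []
    for _ in range(params.n_trunks):
        edge = rng.integers(4)
        if edge == 0:
            r, c, ang = 1, int(rng.integers(10, w - 10)), np.pi / 2
        elif edge == 1:
            r, c, ang = h - 2, int(rng.integers(10, w - 10)), -np.pi / 2
        elif edge == 2:
            r, c, ang = int(rng.integers(10, h - 10)), 1, 0.0
        else:
            r, c, ang = int(rng.integers(10, h - 10)), w - 2, np.pi
        nid = net.add_node(c * px_cm, r * px_cm)
        walkers.append([r, c, ang, nid, set(), params.n_steps])

    edges: list[tuple[int, int]] = []
    while walkers:
        r, c, ang, nid, own, steps = walkers.pop(0)
        if steps <= 0:
            continue
        nr = int(round(r + params.step_px * np.sin(ang)))
        nc = int(round(c + params.step_px * np.cos(ang)))
        if not (1 <= nr < h - 1 and 1 <= nc < w - 1) or blocked(nr, nc, own):
            continue  # walker terminates at the boundary or near a vessel
        rr, cc = draw_line(int(r), int(c), nr, nc)
        img[rr, cc] = params.foreground
        occupied[rr, cc] = True
        own = set(zip(rr.tolist(), cc.tolist())) | own
        own = set(list(own)[-6 * params.step_px:]) if len(own) > 12 * params.step_px else own
        new_nid = net.add_node(nc * px_cm, nr * px_cm)
        edges.append((nid, new_nid))
        ang2 = ang + np.deg2rad(params.turn_sd_deg) * rng.standard_normal()
        if rng.random() < params.branch_prob and steps > 2:
            dev = np.deg2rad(params.branch_angle_deg)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            walkers.append([nr, nc, ang2 + sign * dev, new_nid, set(own), steps - 1])
            ang2 = ang2 - sign * dev
        walkers.append([nr, nc, ang2, new_nid, own, steps - 1])

    deg: dict[int, int] = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    for a, b in edges:
        (xa, ya), (xb, yb) = net.nodes[a], net.nodes[b]
        length = float(np.hypot(xb - xa, yb - ya)) * 1e4
        label = "tip" if deg.get(a, 0) == 1 or deg.get(b, 0) == 1 else "stalk"
        net.add_segment(a, b, label, max(length, 1e-9))
    if params.noise_sd > 0:
        img = np.clip(img + params.noise_sd * rng.standard_normal(img.shape), 0, None)
    return GrayImage(img, params.pixel_um), net


# -- grid embedding and assimilation ------------------------------------------


def embed_network(grid, net: VesselNetwork):
    """Rasterize every segment of ``net`` onto the TMEs it passes through.

    Each crossed TME records the segment id and its tip/stalk label (feeding
    the vessel-radius and lumen-concentration sums).  There is no limit on
    vessels per TME.  Raises if any node lies outside the grid.
    """
    offenders = [
        nid for nid, (x, y) in net.nodes.items()
        if not grid.in_bounds_um(x * 1e4, y * 1e4)
    ]
    if offenders:
        raise ValueError(f"network nodes outside the grid domain: {offenders}")
    for seg_id, seg in enumerate(net.segments):
        p0 = np.asarray(net.nodes[seg.src]) * 1e4
        p1 = np.asarray(net.nodes[seg.dst]) * 1e4
        grid.register_segment(seg_id, p0, p1, seg.label)
    return grid


def merge_networks(current: VesselNetwork, observed: VesselNetwork,
                   tol_um: float) -> VesselNetwork:
    """Set-union of two networks; near-duplicate segments collapse to the
    observed copy.

    Two segments are duplicates when their midpoints lie within ``tol_um``
    (one TME side length by default in the pipeline).
    """
    out = VesselNetwork()
    remap_obs = {nid: out.add_node(*xy) for nid, xy in observed.nodes.items()}
    obs_mids = []
    for s in observed.segments:
        out.add_segment(remap_obs[s.src], remap_obs[s.dst], s.label, s.length_um)
        obs_mids.append(_midpoint_um(observed, s))
    obs_mids = np.asarray(obs_mids) if obs_mids else np.empty((0, 2))
    remap_cur: dict[int, int] = {}
    for s in current.segments:
        mid = _midpoint_um(current, s)
        if obs_mids.size and np.hypot(*(obs_mids - mid).T).min() <= tol_um:
            continue  # duplicate: keep the observed copy
        for nid in (s.src, s.dst):
            if nid not in remap_cur:
                remap_cur[nid] = out.add_node(*current.nodes[nid])
        out.add_segment(remap_cur[s.src], remap_cur[s.dst], s.label, s.length_um)
    return out


def _midpoint_um(net: VesselNetwork, s: Segment) -> np.ndarray:
    a = np.asarray(net.nodes[s.src])
    b = np.asarray(net.nodes[s.dst])
    return (a + b) / 2.0 * 1e4


def assimilate_network(grid, vessels, observed: VesselNetwork, episode: int,
                       tol_um: float | None = None):
    """Merge an observed network into the live simulation at a checkpoint.

    Observed segments with no live counterpart within one TME side length
    are added to the :class:`VesselSystem` (and registered on the grid);
    duplicates are collapsed to the observed copy, i.e. ignored.  An empty
    observation is a no-op.
    """
    tol = grid.tme_um if tol_um is None else tol_um
    if not observed.segments:
        return grid
    live_mids = ((vessels.seg_p0 + vessels.seg_p1) / 2.0
                 if vessels.n_segments else np.empty((0, 2)))
    deg = observed.degrees()
    for s in observed.segments:
        mid = _midpoint_um(observed, s)
        if live_mids.size and np.hypot(*(live_mids - mid).T).min() <= tol:
            continue
        p0 = np.asarray(observed.nodes[s.src]) * 1e4
        p1 = np.asarray(observed.nodes[s.dst]) * 1e4
        path = vessels.new_path()
        # observed segments are established vasculature: born mature
        vessels.add_stalk(p0, p1, path, episode=episode - _MATURE_EPISODES)
        if s.label == "tip":
            tip_end = p1 if deg[s.dst] == 1 else p0
            vessels.spawn_tip(tip_end, path_id=path)
    return grid


def load_vessels_into(grid, vessels, net: VesselNetwork) -> None:
    """Install an observed network as the initial live vasculature."""
    deg = net.degrees()
    for s in net.segments:
        p0 = np.asarray(net.nodes[s.src]) * 1e4
        p1 = np.asarray(net.nodes[s.dst]) * 1e4
        path = vessels.new_path()
        vessels.add_stalk(p0, p1, path, episode=-_MATURE_EPISODES)
        if s.label == "tip":
            tip_end = p1 if deg[s.dst] == 1 else p0
            vessels.spawn_tip(tip_end, path_id=path)
    vessels.n_branch_points += len(net.branch_points)


# -- image IO ------------------------------------------------------------------


def read_image(path: str | Path, pixel_um: float = 20.0,
               bandpass: tuple[float, float] | None = None) -> GrayImage:
    """Read a single-channel TIFF/PNG or a single-slice DICOM."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        px = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        px = px * slope + intercept  # Hounsfield units
        if bandpass is not None:
            px = np.where((px >= bandpass[0]) & (px <= bandpass[1]), px, px.min())
        px = px - px.min()
        return GrayImage(px, pixel_um)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = np.asarray(tifffile.imread(str(path)), dtype=float)
    else:
        import imageio.v3 as iio

        px = np.asarray(iio.imread(str(path)), dtype=float)
    if px.ndim == 3:
        px = px.mean(axis=-1)
    return GrayImage(px, pixel_um, bandpass)
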