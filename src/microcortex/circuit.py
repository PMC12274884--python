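"""Hexagonal-column cortical circuits and apposition connectivity.

A circuit is a hexagonal prism column (side α, height H along +Y, the
pia-ward axis) tiled with six neighbor columns to avoid boundary effects;
analysis is restricted to the central column. Somata are placed uniformly in
each prism, morphologies are cloned onto the somata (rotation about +Y plus
minimal coordinate jitter), and connectivity is computed from appositions:
cell i connects to cell j when some axonal segment of i passes within a
threshold distance (default 2 μm) of a dendritic segment of j; the
apposition count is the number of such axonal segments.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .morphology import (
    NeuronMorphology,
    DENDRITE_TYPES,
    graft_axon,
    scale_morphology,
)
from .network import Connectome

SQRT3 = np.sqrt(3.0)
_HEX_NORMAL_ANGLES = np.deg2rad(30 + 60 * np.arange(6))
_HEX_NORMALS = np.column_stack([np.cos(_HEX_NORMAL_ANGLES), np.sin(_HEX_NORMAL_ANGLES)])


def hex_prism_volume(side: float, height: float) -> float:
    """Volume of a hexagonal prism, in mm³ (side/height in μm)."""
    return (3.0 * SQRT3 / 2.0) * side**2 * height / 1e9


def points_in_hexagon(xz: np.ndarray, side: float, center=(0.0, 0.0)) -> np.ndarray:
    """Boolean mask of 2D points inside a regular hexagon of circumradius
    ``side`` (vertices at angles 0°, 60°, ...)."""
    rel = np.atleast_2d(xz) - np.asarray(center)
    apothem = SQRT3 / 2.0 * side
    return np.all(rel @ _HEX_NORMALS.T <= apothem + 1e-9, axis=1)


def hex_tile_centers(side: float, n_columns: int = 7) -> np.ndarray:
    """XZ centers of the central column and its ring of neighbors."""
    centers = [(0.0, 0.0)]
    for ang in _HEX_NORMAL_ANGLES:
        centers.append((SQRT3 * side * np.cos(ang), SQRT3 * side * np.sin(ang)))
    return np.array(centers[:n_columns])


@dataclass
class ColumnSpec:
    side: float  # μm
    height: float  # μm
    n_pc: int
    n_in: int
    n_columns: int = 7

    def __post_init__(self):
        if self.side <= 0 or self.height <= 0:
            raise ValueError("side and height must be positive")
        if self.n_pc < 0 or self.n_in < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def column_volume_mm3(self) -> float:
        return hex_prism_volume(self.side, self.height)


def full_column_spec(species) -> ColumnSpec:
    """Full-size column for a species parameter record."""
    return ColumnSpec(
        side=species.column_side,
        height=species.layer_thickness,
        n_pc=species.column_pc_count,
        n_in=species.column_in_count,
    )


def desk_scale_spec(species, scale: float = 0.05) -> ColumnSpec:
    """Desk-scale column: cell counts scaled by ``scale`` with densities
    preserved via a proportionally smaller hexagon side (height fixed)."""
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    return ColumnSpec(
        side=species.column_side * np.sqrt(scale),
        height=species.layer_thickness,
        n_pc=int(round(species.column_pc_count * scale)),
        n_in=int(round(species.column_in_count * scale)),
    )


@dataclass
class Circuit:
    """Placed cells (positions, classes, morphology assignments)."""

    cells: pd.DataFrame
    spec: ColumnSpec
    seed: int
    pools: dict = field(default_factory=dict)
    jitter_sd: float = 0.0
    rotate: bool = True

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def central_column_ids(self) -> np.ndarray:
        return self.cells.index[self.cells["column"] == 0].to_numpy()

    def positions(self) -> np.ndarray:
        return self.cells[["x", "y", "z"]].to_numpy()

    def _cell_rng(self, cell_id: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 7919, int(cell_id)]))

    def morphology_of(self, cell_id: int) -> NeuronMorphology:
        """The clone placed at a cell: donor morphology rotated about +Y,
        translated to the soma position, with seeded coordinate jitter."""
        row = self.cells.loc[cell_id]
        donor = self.pools[row["cell_class"]][int(row["pool_index"])]
        theta = float(row["angle"])
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        position = row[["x", "y", "z"]].to_numpy(dtype=float)
        rng = self._cell_rng(cell_id)
        trees = []
        for tree in donor.neurites:
            pts = (tree.points - donor.soma_center) @ R.T + position
            if self.jitter_sd > 0:
                pts = pts + rng.normal(scale=self.jitter_sd, size=pts.shape)
            trees.append(replace(tree, points=pts))
        return NeuronMorphology(position, donor.soma_radius, trees, donor.meta)

    def cell_segments(self, cell_id: int, neurite_types) -> tuple[np.ndarray, np.ndarray]:
        m = self.morphology_of(cell_id)
        starts, ends = [], []
        for tree in m.trees(neurite_types):
            p0, p1 = tree.segments()
            starts.append(p0)
            ends.append(p1)
        if not starts:
            return np.zeros((0, 3)), np.zeros((0, 3))
        return np.vstack(starts), np.vstack(ends)


def build_circuit(spec: ColumnSpec, seed: int = 0) -> Circuit:
    """Place somata uniformly in 7 tiled hexagonal prisms (central + ring).

    Per column: ``n_pc`` pyramidal cells and ``n_in`` interneurons; no layer
    2 vs 3 distinction and no density gradients."""
    rng = np.random.default_rng(seed)
    centers = hex_tile_centers(spec.side, spec.n_columns)
    rows = []
    n_per = spec.n_pc + spec.n_in
    for col, (cx, cz) in enumerate(centers):
        pts = np.empty((n_per, 2))
        got = 0
        while got < n_per:
            batch = rng.uniform(-spec.side, spec.side, size=(2 * (n_per - got) + 16, 2))
            keep = batch[points_in_hexagon(batch, spec.side)]
            take = min(len(keep), n_per - got)
            pts[got : got + take] = keep[:take]
            got += take
        ys = rng.uniform(0.0, spec.height, size=n_per)
        classes = ["PC"] * spec.n_pc + ["IN"] * spec.n_in
        for k in range(n_per):
            rows.append(
                {
                    "x": pts[k, 0] + cx,
                    "y": ys[k],
                    "z": pts[k, 1] + cz,
                    "cell_class": classes[k],
                    "column": col,
                }
            )
    cells = pd.DataFrame(rows)
    cells.index.name = "cell_id"
    return Circuit(cells, spec, seed)


def assign_morphologies(
    circuit: Circuit,
    pool,
    jitter_sd: float = 1.0,
    seed: int | None = None,
    rotate: bool = True,
) -> Circuit:
    """Assign each cell a donor morphology of its class (round-robin over a
    seeded shuffle of the class pool) plus a clone transform: a uniform
    rotation angle about +Y (disabled with ``rotate=False``) and coordinate
    jitter of the given sd."""
    seed = circuit.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    pools: dict[str, list] = {}
    for m in pool:
        pools.setdefault(m.meta.cell_class, []).append(m)
    cells = circuit.cells.copy()
    cells["pool_index"] = -1
    cells["angle"] = 0.0
    for cls, members in pools.items():
        order = rng.permutation(len(members))
        ids = cells.index[cells["cell_class"] == cls].to_numpy()
        cells.loc[ids, "pool_index"] = order[np.arange(len(ids)) % len(members)]
        if rotate:
            cells.loc[ids, "angle"] = rng.uniform(0.0, 2 * np.pi, size=len(ids))
    missing = set(cells["cell_class"]) - set(pools)
    if missing:
        raise ValueError(f"no morphologies in pool for class(es) {sorted(missing)}")
    return Circuit(cells, circuit.spec, seed, pools, jitter_sd, rotate)


# ---------------------------------------------------------------------------
# Segment-to-segment distances


def segment_distances(p1, q1, p2, q2) -> np.ndarray:
    """Minimum distances between 3D line segments [p1,q1] and [p2,q2]
    (vectorized closed form, degenerate segments handled)."""
    p1, q1, p2, q2 = (
        np.asarray(a, dtype=np.float64).reshape(-1, 3) for a in (p1, q1, p2, q2)
    )
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    a_deg = a < 1e-18
    e_deg = e < 1e-18
    denom = a * e - b * b
    safe_denom = np.where(denom > 1e-18, denom, 1.0)
    s = np.where(denom > 1e-18, np.clip((b * f - c * e) / safe_denom, 0.0, 1.0), 0.0)
    safe_e = np.where(e_deg, 1.0, e)
    t = np.where(e_deg, 0.0, (b * s + f) / safe_e)
    t_cl = np.clip(t, 0.0, 1.0)
    safe_a = np.where(a_deg, 1.0, a)
    s_recl = np.clip((b * t_cl - c) / safe_a, 0.0, 1.0)
    s = np.where(t_cl != t, s_recl, s)
    s = np.where(e_deg & ~a_deg, np.clip(-c / safe_a, 0.0, 1.0), s)
    s = np.where(a_deg, 0.0, s)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t_cl[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


# ---------------------------------------------------------------------------
# Appositions


def _gather_segments(circuit: Circuit, cell_ids, neurite_types):
    p0s, p1s, owner = [], [], []
    for cid in cell_ids:
        p0, p1 = circuit.cell_segments(cid, neurite_types)
        p0s.append(p0)
        p1s.append(p1)
        owner.append(np.full(len(p0), cid))
    p0 = np.vstack(p0s) if p0s else np.zeros((0, 3))
    p1 = np.vstack(p1s) if p1s else np.zeros((0, 3))
    own = np.concatenate(owner) if owner else np.zeros(0, dtype=int)
    return p0, p1, own


def compute_appositions(
    circuit: Circuit,
    threshold: float = 2.0,
    cells=None,
    method: str = "index",
    chunk: int = 250_000,
) -> Connectome:
    """Directed apposition connectome among ``cells`` (central column by
    default): edge i→j iff some axon segment of i comes within ``threshold``
    μm of a dendrite segment of j; the per-edge count is the number of such
    axon segments. The spatial-index path prunes candidate segment pairs
    with a KD-tree on segment midpoints using a rigorously conservative
    radius, so it returns exactly the brute-force result.
    """
    if not circuit.pools:
        raise ValueError("morphologies not assigned; call assign_morphologies first")
    if cells is None:
        cells = circuit.central_column_ids
    cells = np.asarray(cells)
    a_p0, a_p1, a_own = _gather_segments(circuit, cells, ("axon",))
    d_p0, d_p1, d_own = _gather_segments(circuit, cells, DENDRITE_TYPES)
    if len(a_p0) == 0:
        raise ValueError("no axons in circuit cells")
    node_of = {cid: k for k, cid in enumerate(cells)}

    if method == "index":
        a_mid = 0.5 * (a_p0 + a_p1)
        d_mid = 0.5 * (d_p0 + d_p1)
        a_half = 0.5 * np.linalg.norm(a_p1 - a_p0, axis=1)
        d_half = 0.5 * np.linalg.norm(d_p1 - d_p0, axis=1)
        # midpoints of segments closer than threshold are provably within this
        radius = threshold + float(a_half.max(initial=0.0) + d_half.max(initial=0.0))
        d_tree = cKDTree(d_mid)
        hits_a, hits_d = [], []
        q_chunk = max(1, chunk // 256)  # bounds candidate-list memory
        for lo in range(0, len(a_mid), q_chunk):
            hi = min(lo + q_chunk, len(a_mid))
            lists = d_tree.query_ball_point(a_mid[lo:hi], radius)
            lens = np.fromiter((len(l) for l in lists), np.int64, count=hi - lo)
            total = int(lens.sum())
            if total == 0:
                continue
            ai = np.repeat(np.arange(lo, hi), lens)
            dj = np.fromiter((j for l in lists for j in l), np.int64, count=total)
            for s in range(0, total, chunk):
                sl = slice(s, s + chunk)
                dist = segment_distances(
                    a_p0[ai[sl]], a_p1[ai[sl]], d_p0[dj[sl]], d_p1[dj[sl]]
                )
                ok = dist <= threshold
                hits_a.append(ai[sl][ok])
                hits_d.append(dj[sl][ok])
        hit_a = np.concatenate(hits_a) if hits_a else np.zeros(0, dtype=np.int64)
        hit_d = np.concatenate(hits_d) if hits_d else np.zeros(0, dtype=np.int64)
    elif method == "brute":
        na, nd = len(a_p0), len(d_p0)
        hit_a_list, hit_d_list = [], []
        rows = max(1, chunk // max(nd, 1))
        for lo in range(0, na, rows):
            hi = min(lo + rows, na)
            AI, DJ = np.meshgrid(np.arange(lo, hi), np.arange(nd), indexing="ij")
            AI, DJ = AI.ravel(), DJ.ravel()
            dist = segment_distances(a_p0[AI], a_p1[AI], d_p0[DJ], d_p1[DJ])
            ok = dist <= threshold
            hit_a_list.append(AI[ok])
            hit_d_list.append(DJ[ok])
        hit_a = np.concatenate(hit_a_list)
        hit_d = np.concatenate(hit_d_list)
    else:
        raise ValueError(f"unknown method {method!r}")

    src = a_own[hit_a]
    dst = d_own[hit_d]
    keep = src != dst
    trip = np.unique(
        np.column_stack([src[keep], dst[keep], hit_a[keep]]), axis=0
    )  # distinct (src, dst, axon segment)
    n = len(cells)
    if len(trip):
        rows = np.array([node_of[s] for s in trip[:, 0]])
        cols = np.array([node_of[t] for t in trip[:, 1]])
        mat = sparse.csr_matrix(
            (np.ones(len(trip), dtype=np.int64), (rows, cols)), shape=(n, n)
        )
    else:
        mat = sparse.csr_matrix((n, n), dtype=np.int64)
    classes = circuit.cells.loc[cells, "cell_class"].to_numpy()
    return Connectome(mat, classes, cells)


# ---------------------------------------------------------------------------
# Hybrid circuit and neighbor counts


def make_hybrid_pool(mouse_pool, human_pool) -> list:
    """Hybrid donors: mouse dendrites scaled (per cell class) so the total
    dendritic length matches the human pool mean, with human axons grafted."""
    human_by_class: dict[str, list] = {}
    for m in human_pool:
        human_by_class.setdefault(m.meta.cell_class, []).append(m)
    out = []
    counters: dict[str, int] = {}
    for donor in mouse_pool:
        cls = donor.meta.cell_class
        humans = human_by_class.get(cls)
        if not humans:
            raise ValueError(f"human pool has no morphologies of class {cls}")
        target = float(np.mean([h.total_dendritic_length for h in humans]))
        factor = target / donor.total_dendritic_length
        scaled = scale_morphology(donor, factor)
        k = counters.get(cls, 0)
        counters[cls] = k + 1
        hybrid = graft_axon(scaled, humans[k % len(humans)])
        hybrid.meta = replace(hybrid.meta, species="hybrid")
        out.append(hybrid)
    return out


def build_hybrid_circuit(
    human_spec: ColumnSpec,
    mouse_pool,
    human_pool,
    seed: int = 0,
    jitter_sd: float = 1.0,
) -> Circuit:
    """Human-dimensioned column (human thickness and densities) populated
    with scaled-mouse dendrites carrying grafted human axons."""
    pool = make_hybrid_pool(mouse_pool, human_pool)
    circuit = build_circuit(human_spec, seed)
    return assign_morphologies(circuit, pool, jitter_sd=jitter_sd, seed=seed)


def neighbor_counts(circuit: Circuit, radii) -> pd.DataFrame:
    """Mean number of other somata within each radius of a central-column
    cell (neighbors from all 7 columns count)."""
    radii = np.asarray(radii, dtype=float)
    pos = circuit.positions()
    tree = cKDTree(pos)
    central = circuit.central_column_ids
    rows = []
    for r in radii:
        if r <= 0:
            rows.append({"radius": r, "mean_count": 0.0})
            continue
        counts = tree.query_ball_point(pos[central], r, return_length=True) - 1
        rows.append({"radius": r, "mean_count": float(np.mean(counts))})
    return pd.DataFrame(rows)
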