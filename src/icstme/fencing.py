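"""Fencing clusters of exhausted CD8+ T cells around melanoma cells.

"Fencing" is the accumulation of exhausted CD8+ T cells in contact
clusters that touch melanoma cells, shielding the tumor from still-active
T cells.  A *fencing cluster* is a connected component of exhausted T
cells (connected through shared chambers / nearest-neighbor chambers on
the lattice, or through center distance <= radius in point-cloud data) in
which at least one member is in contact with a melanoma cell.  The
*fencing fraction* is the share of all exhausted T cells that sit in
fencing clusters of at least ``min_size`` members (default 3).  Its null
distribution is built by permuting cell-type labels over a pool of
non-melanoma cells while keeping every position fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cohort import MODEL_TYPES, TYPE_INDEX, LatticeState, Slide, ValidationError

POOLS = ("immune", "all_but_melanoma")
IMMUNE_TYPES = ("t_active", "t_exhausted", "tam")


@dataclass
class FencingCluster:
    members: list  # chamber (row, col) tuples in lattice mode, cell indices in point mode
    size: int  # number of exhausted T cells in the cluster
    touches_melanoma: bool


@dataclass
class FencingResult:
    clusters: list[FencingCluster]
    fraction: float
    total_exhausted: int
    min_size: int
    mode: str  # "lattice" or "points"


@dataclass
class PermutationNull:
    fractions: np.ndarray
    n_perm: int
    pool: str

    @property
    def mean(self) -> float:
        return float(self.fractions.mean())


def _components(n: int, edges_i: np.ndarray, edges_j: np.ndarray) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=int)
    data = np.ones(edges_i.size, dtype=np.int8)
    graph = coo_matrix((data, (edges_i, edges_j)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def fencing_clusters_lattice(
    state: LatticeState, neighborhood: str = "moore8"
) -> list[FencingCluster]:
    """Connected clusters of exhausted T cells on the chamber grid.

    Chambers holding exhausted T cells are connected when identical or
    adjacent under the neighborhood; all cells within one chamber are
    mutually in contact.  A cluster touches melanoma when any member
    chamber has a melanoma cell in itself or its neighborhood.
    """
    if neighborhood not in ("moore8", "vonneumann4"):
        raise ValidationError(f"unknown neighborhood {neighborhood!r}")
    tex = state.counts[TYPE_INDEX["t_exhausted"]]
    mel = state.counts[TYPE_INDEX["melanoma"]]
    occupied = np.argwhere(tex > 0)
    n = occupied.shape[0]
    if n == 0:
        return []
    index = {(int(r), int(c)): k for k, (r, c) in enumerate(occupied)}
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if neighborhood == "moore8":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    ei, ej = [], []
    for k, (r, c) in enumerate(occupied):
        for dr, dc in offsets:
            other = index.get((int(r) + dr, int(c) + dc))
            if other is not None:
                ei.append(k)
                ej.append(other)
    labels = _components(n, np.array(ei, dtype=int), np.array(ej, dtype=int))
    nr, nc = tex.shape
    clusters = []
    for lab in np.unique(labels):
        chambers = [tuple(map(int, occupied[k])) for k in np.flatnonzero(labels == lab)]
        size = int(sum(tex[r, c] for r, c in chambers))
        touches = False
        for r, c in chambers:
            if mel[r, c] > 0:
                touches = True
                break
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and mel[rr, cc] > 0:
                    touches = True
                    break
            if touches:
                break
        clusters.append(FencingCluster(chambers, size, touches))
    return clusters


def fencing_clusters_points(cells: pd.DataFrame, radius: float = 15.0) -> list[FencingCluster]:
    """Connected clusters of exhausted T cells in a point cloud.

    Two cells are neighbors when their centers are within ``radius`` um
    (default 15 um, a nucleus-to-nucleus contact distance for these cell
    types).  ``cells`` needs columns x, y, cell_type; cluster members are
    row positions of exhausted T cells within ``cells``.
    """
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    tex_idx = np.flatnonzero((cells["cell_type"] == "t_exhausted").to_numpy())
    mel_idx = np.flatnonzero((cells["cell_type"] == "melanoma").to_numpy())
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    n = tex_idx.size
    if n == 0:
        return []
    tex_xy = xy[tex_idx]
    tree = cKDTree(tex_xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    labels = _components(n, pairs[:, 0], pairs[:, 1])
    touches = np.zeros(n, dtype=bool)
    if mel_idx.size:
        mel_tree = cKDTree(xy[mel_idx])
        dist, _ = mel_tree.query(tex_xy, k=1, distance_upper_bound=radius * (1 + 1e-12))
        touches = dist <= radius
    clusters = []
    for lab in np.unique(labels):
        member_pos = np.flatnonzero(labels == lab)
        clusters.append(
            FencingCluster(
                members=[int(tex_idx[k]) for k in member_pos],
                size=int(member_pos.size),
                touches_melanoma=bool(touches[member_pos].any()),
            )
        )
    return clusters


def fencing_fraction(
    clusters: list[FencingCluster], total_exhausted: int, min_size: int = 3
) -> float:
    """Share of exhausted T cells in melanoma-touching clusters of size >= min_size.

    Defined as 0 when there are no exhausted T cells, so the metric can be
    traced from t = 0 of a simulation.
    """
    if total_exhausted == 0:
        return 0.0
    qualifying = sum(c.size for c in clusters if c.touches_melanoma and c.size >= min_size)
    return qualifying / total_exhausted


def analyze(
    obj: LatticeState | Slide | pd.DataFrame,
    min_size: int = 3,
    neighborhood: str = "moore8",
    radius: float = 15.0,
) -> FencingResult:
    """Cluster decomposition plus fencing fraction for a lattice or point cloud."""
    if isinstance(obj, LatticeState):
        clusters = fencing_clusters_lattice(obj, neighborhood)
        total = obj.type_counts()["t_exhausted"]
        mode = "lattice"
    else:
        cells = obj.cells if isinstance(obj, Slide) else obj
        clusters = fencing_clusters_points(cells, radius)
        total = int((cells["cell_type"] == "t_exhausted").sum())
        mode = "points"
    return FencingResult(
        clusters, fencing_fraction(clusters, total, min_size), total, min_size, mode
    )


def _pool_types(pool: str, present: set[str]) -> set[str]:
    if pool == "immune":
        return set(IMMUNE_TYPES)
    if pool == "all_but_melanoma":
        return {t for t in present if t != "melanoma"}
    raise ValidationError(f"unknown pool {pool!r}; expected one of {POOLS}")


def permutation_null(
    obj: LatticeState | Slide | pd.DataFrame,
    pool: str = "all_but_melanoma",
    n_perm: int = 1000,
    min_size: int = 3,
    neighborhood: str = "moore8",
    radius: float = 15.0,
    seed: int = 0,
) -> PermutationNull:
    """Null fencing fractions from label permutations over the pool.

    Every permutation shuffles the type labels of pool cells across the
    pool's fixed positions (melanoma cells are never touched), preserving
    the count of every cell type exactly.
    """
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_perm)
    if isinstance(obj, LatticeState):
        types_present = {t for t, n in obj.type_counts().items() if n > 0}
        ptypes = _pool_types(pool, types_present) & set(MODEL_TYPES)
        slots_ch = []  # flat chamber index of each pool cell
        slots_tp = []
        nr, nc = obj.n_rows, obj.n_cols
        for t in sorted(ptypes):
            ti = TYPE_INDEX[t]
            flat = obj.counts[ti].ravel()
            for ch in np.flatnonzero(flat):
                slots_ch.extend([ch] * int(flat[ch]))
                slots_tp.extend([ti] * int(flat[ch]))
        if not slots_ch:
            raise ValidationError("empty permutation pool")
        slots_ch = np.array(slots_ch)
        slots_tp = np.array(slots_tp)
        mel = obj.counts[TYPE_INDEX["melanoma"]]
        total_tex = int(np.sum(slots_tp == TYPE_INDEX["t_exhausted"]))
        for k in range(n_perm):
            perm_tp = rng.permutation(slots_tp)
            tex_flat = np.bincount(
                slots_ch[perm_tp == TYPE_INDEX["t_exhausted"]], minlength=nr * nc
            )
            counts = np.zeros_like(obj.counts)
            counts[TYPE_INDEX["melanoma"]] = mel
            counts[TYPE_INDEX["t_exhausted"]] = tex_flat.reshape(nr, nc)
            state = LatticeState(counts, obj.l0, cap=max(obj.cap, int(counts.sum(0).max())))
            clusters = fencing_clusters_lattice(state, neighborhood)
            fracs[k] = fencing_fraction(clusters, total_tex, min_size)
    else:
        cells = (obj.cells if isinstance(obj, Slide) else obj).reset_index(drop=True)
        types = cells["cell_type"].to_numpy()
        ptypes = _pool_types(pool, set(types))
        pool_mask = np.isin(types, sorted(ptypes))
        if not pool_mask.any():
            raise ValidationError("empty permutation pool")
        pool_idx = np.flatnonzero(pool_mask)
        pool_labels = types[pool_idx].copy()
        total_tex = int(np.sum(pool_labels == "t_exhausted")) + int(
            np.sum(types[~pool_mask] == "t_exhausted")
        )
        for k in range(n_perm):
            shuffled = rng.permutation(pool_labels)
            new_types = types.copy()
            new_types[pool_idx] = shuffled
            perm_cells = cells.assign(cell_type=new_types)
            clusters = fencing_clusters_points(perm_cells, radius)
            fracs[k] = fencing_fraction(clusters, total_tex, min_size)
    return PermutationNull(fracs, n_perm, pool)


def radius_sweep(
    cells: pd.DataFrame | Slide, radii, min_size: int = 3
) -> pd.DataFrame:
    """Fencing fraction of a point cloud at several neighbor radii."""
    rows = []
    for r in radii:
        res = analyze(cells, min_size=min_size, radius=float(r))
        rows.append({"radius_um": float(r), "fraction": res.fraction})
    return pd.DataFrame(rows)
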