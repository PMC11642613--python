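"""Fencing clusters: hand-traced cases, union-find oracle, permutation nulls."""

import numpy as np
import pytest
from conftest import make_cells, rates

from icstme import LatticeState, SimConfig, ValidationError, simulate, slide_to_lattice
from icstme.fencing import (
    analyze,
    fencing_clusters_lattice,
    fencing_clusters_points,
    fencing_fraction,
    permutation_null,
    radius_sweep,
)


def lattice_with(cells, shape=(12, 12), cap=8):
    counts = np.zeros((4, *shape), np.int64)
    for entry in cells:
        t, r, c = entry[:3]
        counts[t, r, c] += entry[3] if len(entry) > 3 else 1
    return LatticeState(counts, cap=cap)


class UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, i):
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i, j):
        self.p[self.find(i)] = self.find(j)


def oracle_point_clusters(cells, radius):
    """Brute-force O(n^2) union-find decomposition of exhausted T cells."""
    tex = cells[cells["cell_type"] == "t_exhausted"]
    idx = tex.index.to_list()
    xy = tex[["x", "y"]].to_numpy(float)
    mel = cells[cells["cell_type"] == "melanoma"][["x", "y"]].to_numpy(float)
    uf = UnionFind(len(idx))
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            if np.hypot(*(xy[i] - xy[j])) <= radius:
                uf.union(i, j)
    groups = {}
    for i in range(len(idx)):
        groups.setdefault(uf.find(i), []).append(i)
    out = []
    for members in groups.values():
        touches = False
        if len(mel):
            for i in members:
                if np.sqrt(((mel - xy[i]) ** 2).sum(axis=1)).min() <= radius:
                    touches = True
                    break
        out.append((frozenset(idx[i] for i in members), touches))
    return set(out)


def oracle_lattice_clusters(state, neighborhood="moore8"):
    tex = state.counts[2]
    mel = state.counts[0]
    coords = [tuple(map(int, rc)) for rc in np.argwhere(tex > 0)]
    uf = UnionFind(len(coords))
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if neighborhood == "moore8":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for i, a in enumerate(coords):
        for j, b in enumerate(coords[:i]):
            if (a[0] - b[0], a[1] - b[1]) in offsets:
                uf.union(i, j)
    groups = {}
    for i in range(len(coords)):
        groups.setdefault(uf.find(i), []).append(i)
    nr, nc = tex.shape
    out = set()
    for members in groups.values():
        chambers = frozenset(coords[i] for i in members)
        size = int(sum(tex[rc] for rc in chambers))
        touches = any(
            0 <= r + dr < nr and 0 <= c + dc < nc and mel[r + dr, c + dc] > 0
            for (r, c) in chambers
            for dr, dc in offsets + [(0, 0)]
        )
        out.add((chambers, size, touches))
    return out


class TestLatticeClusters:
    def test_hand_traced_chain(self):
        # melanoma at (5,5); exhausted chain at (5,6),(5,7),(5,8): one
        # 3-cell cluster whose head touches the melanoma chamber
        state = lattice_with([(0, 5, 5), (2, 5, 6), (2, 5, 7), (2, 5, 8)])
        clusters = fencing_clusters_lattice(state)
        assert len(clusters) == 1
        (c,) = clusters
        assert c.size == 3 and c.touches_melanoma
        assert fencing_fraction(clusters, 3, min_size=3) == 1.0
        assert fencing_fraction(clusters, 3, min_size=4) == 0.0

    def test_no_melanoma_no_fencing(self):
        state = lattice_with([(2, 1, 1), (2, 1, 2), (2, 2, 1)])
        clusters = fencing_clusters_lattice(state)
        assert len(clusters) == 1 and not clusters[0].touches_melanoma
        assert fencing_fraction(clusters, 3) == 0.0

    def test_same_chamber_cells_form_one_cluster(self):
        state = lattice_with([(2, 3, 3, 4), (0, 3, 4)])
        (c,) = fencing_clusters_lattice(state)
        assert c.size == 4 and c.touches_melanoma

    def test_empty_input(self):
        assert fencing_clusters_lattice(lattice_with([])) == []

    @pytest.mark.parametrize("neighborhood", ["moore8", "vonneumann4"])
    def test_matches_union_find_oracle(self, neighborhood):
        rng = np.random.default_rng(2)
        cells = [(2, rng.integers(12), rng.integers(12)) for _ in range(120)]
        cells += [(0, rng.integers(12), rng.integers(12)) for _ in range(60)]
        state = lattice_with(cells, cap=10**6)
        got = {
            (frozenset(c.members), c.size, c.touches_melanoma)
            for c in fencing_clusters_lattice(state, neighborhood)
        }
        assert got == oracle_lattice_clusters(state, neighborhood)


class TestPointClusters:
    def test_isolated_cells_are_singletons(self):
        cells = make_cells(
            [(0, 0, "t_exhausted"), (100, 0, "t_exhausted"), (200, 200, "melanoma")]
        )
        clusters = fencing_clusters_points(cells, radius=15)
        assert sorted(c.size for c in clusters) == [1, 1]
        assert not any(c.touches_melanoma for c in clusters)

    def test_radius_inclusive(self):
        cells = make_cells([(0, 0, "t_exhausted"), (15.0, 0, "t_exhausted")])
        assert len(fencing_clusters_points(cells, radius=15)) == 1

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        n = 500
        cells = make_cells(
            [
                (x, y, t)
                for x, y, t in zip(
                    rng.uniform(0, 400, n),
                    rng.uniform(0, 400, n),
                    rng.choice(["t_exhausted", "melanoma", "t_active"], n, p=[0.5, 0.3, 0.2]),
                )
            ]
        )
        got = {
            (frozenset(c.members), c.touches_melanoma)
            for c in fencing_clusters_points(cells, radius=15)
        }
        assert got == oracle_point_clusters(cells, 15.0)

    def test_clusters_partition_exhausted_cells(self):
        rng = np.random.default_rng(8)
        cells = make_cells(
            [(x, y, "t_exhausted") for x, y in rng.uniform(0, 200, (150, 2))]
        )
        clusters = fencing_clusters_points(cells, radius=15)
        members = [i for c in clusters for i in c.members]
        assert sorted(members) == list(range(150))

    def test_fraction_monotone_in_min_size_and_radius(self):
        rng = np.random.default_rng(9)
        rows = [(x, y, "t_exhausted") for x, y in rng.uniform(0, 300, (120, 2))]
        rows += [(x, y, "melanoma") for x, y in rng.uniform(0, 300, (80, 2))]
        cells = make_cells(rows)
        fr = [analyze(cells, min_size=k, radius=15).fraction for k in (1, 3, 5, 8)]
        assert all(a >= b for a, b in zip(fr, fr[1:]))
        sweep = radius_sweep(cells, [5, 10, 15, 25, 40])["fraction"]
        assert (sweep.diff().dropna() >= 0).all()


class TestFractionArithmetic:
    def test_two_qualifying_clusters(self):
        from icstme.fencing import FencingCluster

        clusters = [
            FencingCluster([], 3, True),
            FencingCluster([], 5, True),
            FencingCluster([], 4, False),
            FencingCluster([], 2, True),
        ]
        assert fencing_fraction(clusters, 20, min_size=3) == pytest.approx(0.4)

    def test_zero_exhausted_defined_as_zero(self):
        assert fencing_fraction([], 0) == 0.0


class TestPermutationNull:
    def test_labels_conserved_every_permutation(self):
        rng = np.random.default_rng(1)
        rows = [(x, y, t) for (x, y), t in zip(
            rng.uniform(0, 200, (100, 2)),
            rng.choice(["t_exhausted", "t_active", "tam", "melanoma"], 100),
        )]
        cells = make_cells(rows)
        # permuting labels over fixed positions cannot change type totals:
        # the null fractions stay within [0, 1] and use the same total
        null = permutation_null(cells, "all_but_melanoma", n_perm=50, seed=0)
        assert null.fractions.shape == (50,)
        assert ((null.fractions >= 0) & (null.fractions <= 1)).all()

    def test_pool_of_only_exhausted_has_zero_variance(self):
        rng = np.random.default_rng(4)
        rows = [(x, y, "t_exhausted") for x, y in rng.uniform(0, 100, (40, 2))]
        rows += [(x, y, "melanoma") for x, y in rng.uniform(0, 100, (20, 2))]
        cells = make_cells(rows)
        null = permutation_null(cells, "all_but_melanoma", n_perm=20, seed=0)
        assert np.ptp(null.fractions) == 0.0

    def test_empty_pool_is_error(self):
        cells = make_cells([(1, 1, "melanoma")])
        with pytest.raises(ValidationError):
            permutation_null(cells, "all_but_melanoma", n_perm=5)

    def test_adjacent_construction_beats_null(self):
        # exhausted T cells packed against a melanoma block, pool cells
        # spread far away: the observed fencing fraction exceeds the null
        rng = np.random.default_rng(6)
        rows = [(200 + i * 10, 200, "t_exhausted") for i in range(8)]
        rows += [(200 + i * 10, 190, "melanoma") for i in range(8)]
        rows += [(x, y, "t_active") for x, y in rng.uniform(600, 1000, (80, 2))]
        cells = make_cells(rows)
        obs = analyze(cells, radius=15).fraction
        null = permutation_null(cells, "all_but_melanoma", n_perm=200, seed=3)
        assert obs == 1.0
        assert null.mean < obs

    def test_lattice_mode_null(self):
        state_cells = [(2, 5, c) for c in range(4, 8)] + [(0, 5, 3, 3)]
        state_cells += [(1, r, c) for r in range(12) for c in (0, 11)]
        state = lattice_with(state_cells)
        obs = analyze(state).fraction
        null = permutation_null(state, "immune", n_perm=100, seed=2)
        assert obs == 1.0
        assert null.mean < obs
        assert ((null.fractions >= 0) & (null.fractions <= 1)).all()


class TestSimulationClosesLoop:
    def test_exhaustion_generates_fencing_above_null(self, mixed_slide):
        # with bC > 0 exhausted T cells pile up at melanoma contact zones
        lat = slide_to_lattice(mixed_slide)
        p = rates(l=0.05, bC=0.3, bM=0.0, r_hop_T=1.2, r_prolif_mel=0.02)
        tr = simulate(lat, p, SimConfig(t_end=72, record_every=72), seed=4,
                      snapshot_times=[72.0])
        snap = tr.snapshots[72.0]
        res = analyze(snap)
        assert res.total_exhausted > 10
        null = permutation_null(snap, "immune", n_perm=100, seed=0)
        assert res.fraction > null.mean

    def test_no_exhaustion_no_fencing(self, mixed_slide):
        lat = slide_to_lattice(mixed_slide)
        p = rates(l=0.05, r_hop_T=1.2, r_prolif_mel=0.02)
        tr = simulate(lat, p, SimConfig(t_end=72, record_every=72), seed=4,
                      snapshot_times=[72.0])
        snap = tr.snapshots[72.0]
        assert analyze(snap).total_exhausted == 0
        assert analyze(snap).fraction == 0.0
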