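"""Numerical body-bar rigidity analysis at generic coordinates.

This is the linear-algebra counterpart of the combinatorial pebble game:
bodies get random generic placements, every bar becomes one row of the
rigidity matrix, and independence/DOF/cluster questions reduce to matrix
ranks and null spaces.  By Tay's theorem the generic rank agrees with the
(6,6) count matroid, so this module serves as ground truth for toy
frameworks and as the oracle side of dual-route tests — the pebble game
never calls into it.

A body's infinitesimal motion is (v, w): point velocity at p is
v + w x (p - c).  A bar attached at generic points p_u, p_v with direction
d = p_u - p_v contributes the row  [d, (p_u - c_u) x d]  on body u and the
negated analogue on body v.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

from .network import Constraint, ConstraintNetwork

__all__ = ["GenericFramework", "generic_coordinates", "rank_analysis"]

_RANK_TOL = 1e-8


def generic_coordinates(
    n_bodies: int, seed: int | None = None, min_separation: float = 0.05
) -> np.ndarray:
    """Random generic body centers in the unit box, rejecting near-coincident
    placements that could create non-generic degeneracies."""
    rng = np.random.default_rng(seed)
    centers = np.empty((n_bodies, 3))
    placed = 0
    while placed < n_bodies:
        cand = rng.uniform(0.0, 1.0, size=3)
        if placed == 0 or np.min(np.linalg.norm(centers[:placed] - cand, axis=1)) > min_separation:
            centers[placed] = cand
            placed += 1
    return centers


class GenericFramework:
    """A body-bar framework realized at generic coordinates."""

    def __init__(self, n_bodies: int, seed: int | None = None):
        self.n = n_bodies
        self.rng = np.random.default_rng(seed)
        self.centers = generic_coordinates(n_bodies, seed=self.rng.integers(2**31))
        self.rows: list[np.ndarray] = []

    def _bar_row(self, u: int, v: int) -> np.ndarray:
        p_u = self.centers[u] + self.rng.normal(scale=0.3, size=3)
        p_v = self.centers[v] + self.rng.normal(scale=0.3, size=3)
        d = p_u - p_v
        row = np.zeros(6 * self.n)
        row[6 * u : 6 * u + 3] = d
        row[6 * u + 3 : 6 * u + 6] = np.cross(p_u - self.centers[u], d)
        row[6 * v : 6 * v + 3] = -d
        row[6 * v + 3 : 6 * v + 6] = -np.cross(p_v - self.centers[v], d)
        return row

    def add_bars(self, u: int, v: int, count: int = 1) -> None:
        for _ in range(count):
            self.rows.append(self._bar_row(u, v))

    def matrix(self) -> np.ndarray:
        if not self.rows:
            return np.zeros((0, 6 * self.n))
        return np.vstack(self.rows)

    def rank(self) -> int:
        m = self.matrix()
        if m.size == 0:
            return 0
        return int(np.linalg.matrix_rank(m, tol=_RANK_TOL * max(m.shape)))

    def motion_space(self) -> np.ndarray:
        """Null space of the rigidity matrix (includes trivial motions)."""
        m = self.matrix()
        if m.shape[0] == 0:
            return np.eye(6 * self.n)
        return null_space(m, rcond=_RANK_TOL)

    def relative_dof(self, u: int, v: int, motions: np.ndarray | None = None) -> int:
        """Dimension of the relative motion of bodies u, v within the motion
        space: rank of 6 generic test bars projected onto the null space."""
        if motions is None:
            motions = self.motion_space()
        if motions.shape[1] == 0:
            return 0
        test = np.vstack([self._bar_row(u, v) for _ in range(6)])
        proj = test @ motions
        return int(np.linalg.matrix_rank(proj, tol=_RANK_TOL * max(proj.shape)))


@dataclass
class RankAnalysis:
    independent_bars: int
    internal_dof: int
    n_components: int
    rigid_partition: list[frozenset[int]]
    bond_labels: dict[int, str]          # rotatable bond id -> locked | hinge
    flexible_groups: list[tuple[tuple[int, ...], int]]  # (bond ids, internal DOF)
    redundant_per_cluster: dict[frozenset[int], int]


def rank_analysis(
    net: ConstraintNetwork,
    engaged_hbonds: Sequence[int] = (),
    native_torsions: Sequence[int] = (),
    seed: int = 0,
) -> RankAnalysis:
    """Full rank/null-space analysis of one framework realization.

    Mirrors the pebble game's outputs (independent-bar count, rigid cluster
    partition, locked/hinge labels, flexible groupings with their internal
    DOF) using only numerical linear algebra plus graph contraction.
    """
    import networkx as nx

    engaged_hb = frozenset(engaged_hbonds)
    native = frozenset(native_torsions)
    torsion_by_bond = {c.rotatable_bond: c for c in net.torsions}
    mechanical: list[Constraint] = list(net.covalent)
    mechanical += [c for c in net.hbonds if c.id in engaged_hb]
    mechanical += [torsion_by_bond[b] for b in sorted(native)]

    fw = GenericFramework(net.n_bodies, seed=seed)
    graph = nx.Graph()
    graph.add_nodes_from(range(net.n_bodies))
    for c in mechanical:
        for (i, j, bars) in c.edges:
            fw.add_bars(i, j, bars)
            graph.add_edge(i, j)
    rank = fw.rank()
    n_comp = nx.number_connected_components(graph)
    internal = 6 * net.n_bodies - rank - 6 * n_comp

    motions = fw.motion_space()
    parent = list(range(net.n_bodies))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in graph.edges:
        if find(i) != find(j) and fw.relative_dof(i, j, motions) == 0:
            ri, rj = find(i), find(j)
            parent[ri] = rj

    members: dict[int, set[int]] = {}
    for b in range(net.n_bodies):
        members.setdefault(find(b), set()).add(b)
    partition = [frozenset(v) for _, v in sorted(members.items())]

    # redundant bars per rigid cluster: bars internal to a cluster minus the
    # rank of the cluster's own sub-matrix
    redundant: dict[frozenset[int], int] = {}
    for cluster in partition:
        if len(cluster) == 1:
            continue
        sub = GenericFramework(net.n_bodies, seed=seed + 1)
        nbars = 0
        for c in mechanical:
            for (i, j, bars) in c.edges:
                if i in cluster and j in cluster:
                    sub.add_bars(i, j, bars)
                    nbars += bars
        srank = sub.rank()
        if nbars - srank > 0:
            redundant[cluster] = nbars - srank

    bond_labels: dict[int, str] = {}
    hinge = []
    for bond in net.rotatable_bonds:
        if find(bond.i) == find(bond.j):
            bond_labels[bond.id] = "locked"
        else:
            bond_labels[bond.id] = "hinge"
            hinge.append(bond)

    # flexible grouping by biconnected components of the contracted graph
    flexible_groups: list[tuple[tuple[int, ...], int]] = []
    if hinge:
        simple = nx.Graph()
        simple.add_nodes_from({find(b) for b in range(net.n_bodies)})
        mult: dict[tuple[int, int], int] = {}
        for c in mechanical:
            for (i, j, _) in c.edges:
                ri, rj = find(i), find(j)
                if ri != rj:
                    p = (min(ri, rj), max(ri, rj))
                    mult[p] = mult.get(p, 0) + 1
                    simple.add_edge(*p)
        bridges = {
            (min(u, v), max(u, v))
            for u, v in nx.bridges(simple)
            if mult[(min(u, v), max(u, v))] == 1
        }
        comp_of_edge: dict[tuple[int, int], int] = {}
        for comp_id, comp_edges in enumerate(nx.biconnected_component_edges(simple)):
            for u, v in comp_edges:
                comp_of_edge[(min(u, v), max(u, v))] = comp_id
        singles = []
        grouped: dict[int, list] = {}
        for bond in hinge:
            p = (min(find(bond.i), find(bond.j)), max(find(bond.i), find(bond.j)))
            if p in bridges:
                singles.append(bond)
            else:
                grouped.setdefault(comp_of_edge[p], []).append(bond)
        for bond in sorted(singles, key=lambda b: b.id):
            flexible_groups.append(((bond.id,), 1))
        for comp_id in sorted(grouped):
            bonds_in = sorted(grouped[comp_id], key=lambda b: b.id)
            roots = set()
            for (u, v), cid in comp_of_edge.items():
                if cid == comp_id:
                    roots |= {u, v}
            bodies: set[int] = set()
            for r in roots:
                bodies |= members[r]
            sub = GenericFramework(net.n_bodies, seed=seed + 2)
            nbars = 0
            for c in mechanical:
                for (i, j, bars) in c.edges:
                    if i in bodies and j in bodies:
                        sub.add_bars(i, j, bars)
                        nbars += bars
            # columns of absent bodies are identically zero, so the sub-matrix
            # rank counts only constraints inside the region
            a_dof = 6 * len(bodies) - 6 - sub.rank()
            flexible_groups.append((tuple(b.id for b in bonds_in), a_dof))

    return RankAnalysis(
        independent_bars=rank,
        internal_dof=internal,
        n_components=n_comp,
        rigid_partition=partition,
        bond_labels=bond_labels,
        flexible_groups=flexible_groups,
        redundant_per_cluster=redundant,
    )
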