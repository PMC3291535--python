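"""The (6,6) body-bar pebble game and rigidity decomposition.

Bodies carry 6 pebbles (their 6 trivial rigid-body degrees of freedom).
Bars are inserted one at a time, in ascending order of their entropy weight
(quenched bars first, ties broken by constraint id) — the insertion order
that yields the lowest upper bound on the conformational entropy.  A bar is
*independent* when 7 pebbles can be gathered across its two endpoints
(6 trivial relative DOF withheld plus the one the bar removes); otherwise it
is *redundant*.  Pebble searches run depth-first along the directed cover
graph with path reversal.

After the game the framework decomposes into

* **rigid clusters** — maximal sets of mutually rigid bodies (a pair is
  mutually rigid when at most 6 pebbles can be gathered on it), labelled
  *over-constrained* when redundant bars fall inside them (B counts those
  bars, D the locked a-priori rotatable bonds) and *isostatic* otherwise;
* **flexible clusters** — a-priori rotatable bonds that survive as hinges.
  A hinge that is a bridge in the cluster-contracted multigraph is an
  isolated rotor (H = A = 1); hinges sharing a biconnected component are
  coupled into one collective motion, whose independent DOF count A is the
  internal DOF of the induced sub-framework.

Every a-priori rotatable bond lands in exactly one cluster.  Disordered
torsion bars (which carry no mechanical constraint) are inserted *after*
the decomposition purely for entropy bookkeeping: the count of independent
disordered torsions per flexible region equals that region's internal DOF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .network import Constraint, ConstraintNetwork

__all__ = ["PebbleGame", "RigidityDecomposition", "ClusterInfo", "run_pebble_game", "cluster_counts"]

K_PEBBLES = 6


class PebbleGame:
    """Directed-graph pebble game with DFS pebble search and path reversal."""

    def __init__(self, n_bodies: int):
        self.n = n_bodies
        self.pebbles = [K_PEBBLES] * n_bodies
        # directed multigraph as adjacency counts: out[u][v] = #covered bars u->v
        self.out: list[dict[int, int]] = [dict() for _ in range(n_bodies)]

    # -- pebble search ------------------------------------------------------
    def _find_pebble(self, root: int, blocked: frozenset[int]) -> bool:
        """Move one additional free pebble to ``root`` from elsewhere;
        vertices in ``blocked`` are neither traversed nor robbed.  Returns
        True on success."""
        parent: dict[int, int] = {root: -1}
        stack = [root]
        found = -1
        while stack:
            u = stack.pop()
            for v in self.out[u]:
                if self.out[u][v] <= 0 or v in parent or v in blocked:
                    continue
                parent[v] = u
                if self.pebbles[v] > 0:
                    found = v
                    stack.clear()
                    break
                stack.append(v)
        if found < 0:
            return False
        # reverse the path root -> ... -> found, moving the pebble to root
        v = found
        while parent[v] != -1:
            u = parent[v]
            self.out[u][v] -= 1
            if self.out[u][v] == 0:
                del self.out[u][v]
            self.out[v][u] = self.out[v].get(u, 0) + 1
            v = u
        self.pebbles[found] -= 1
        self.pebbles[root] += 1
        return True

    def _gather(self, u: int, v: int, target: int) -> bool:
        """Gather pebbles on {u, v} until their total reaches ``target``."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if self.pebbles[u] < K_PEBBLES and self._find_pebble(u, frozenset((v,))):
                continue
            if self.pebbles[v] < K_PEBBLES and self._find_pebble(v, frozenset((u,))):
                continue
            return False
        return True

    # -- public operations --------------------------------------------------
    def add_bar(self, u: int, v: int) -> bool:
        """Insert one bar between bodies u, v.  True if independent."""
        if u == v:
            raise ValueError("self-bars are not allowed")
        if not self._gather(u, v, K_PEBBLES + 1):
            return False
        # cover: take a pebble from u (or v) and orient the bar
        if self.pebbles[u] > 0:
            self.pebbles[u] -= 1
            self.out[u][v] = self.out[u].get(v, 0) + 1
        else:
            self.pebbles[v] -= 1
            self.out[v][u] = self.out[v].get(u, 0) + 1
        return True

    def mutually_rigid(self, u: int, v: int) -> bool:
        """A pair is mutually rigid iff a 7th pebble cannot be gathered."""
        return not self._gather(u, v, K_PEBBLES + 1)

    @property
    def free_pebbles(self) -> int:
        return sum(self.pebbles)


@dataclass
class ClusterInfo:
    """One cluster of a-priori rotatable bonds.

    For flexible clusters ``n_bonds`` is H and ``count`` is A (independent
    DOF); for over-constrained ones ``n_bonds`` is D and ``count`` is B
    (redundant bars); isostatic clusters carry neither (count = 0).
    """

    label: str  # flexible | isostatic | overconstrained
    bond_ids: tuple[int, ...]
    n_bonds: int
    count: int
    bodies: frozenset[int] = field(default_factory=frozenset)

    @property
    def f(self) -> float:
        # A <= H always, so the flexible density is naturally in [0, 1]; the
        # redundant-bar density B/D can exceed 1 on heavily braced regions
        # and is saturated so FI stays a signed density on [-1, 1]
        if self.label == "flexible":
            return self.count / self.n_bonds if self.n_bonds else 0.0
        if self.label == "overconstrained":
            return -min(1.0, self.count / self.n_bonds) if self.n_bonds else 0.0
        return 0.0


@dataclass
class RigidityDecomposition:
    """Pebble-game output: independence labels and the cluster partition."""

    n_bodies: int
    free_pebbles: int
    total_bars: int
    independent_bars: int
    # per-constraint (independent bar count, total bar count)
    constraint_bars: dict[int, tuple[int, int]]
    clusters: list[ClusterInfo]
    bond_cluster: dict[int, int]
    # disordered-torsion bookkeeping (filled when the network carries torsions)
    n_nat_total: int = 0
    n_nat_indep: int = 0
    n_dis_total: int = 0
    n_dis_indep: int = 0

    @property
    def redundant_bars(self) -> int:
        return self.total_bars - self.independent_bars

    def bond_f(self, bond_id: int) -> float:
        return self.clusters[self.bond_cluster[bond_id]].f

    def constraint_independence(self, cid: int) -> float:
        ind, tot = self.constraint_bars[cid]
        return ind / tot if tot else 1.0


def _insertion_order(constraints: Sequence[Constraint]) -> list[Constraint]:
    kind_priority = {"covalent": 0, "torsion": 1, "hbond": 2}
    return sorted(
        constraints,
        key=lambda c: (0 if c.quenched else 1, c.entropy_weight, kind_priority[c.kind], c.id),
    )


def run_pebble_game(
    net: ConstraintNetwork,
    engaged_hbonds: Iterable[int] = (),
    native_torsions: Iterable[int] = (),
) -> RigidityDecomposition:
    """Run the (6,6) pebble game on one framework realization.

    ``engaged_hbonds`` are H-bond constraint ids that are present;
    ``native_torsions`` are rotatable-bond ids whose torsion is native
    (contributing one bar).  Covalent constraints are always on.
    """
    engaged_hb = frozenset(engaged_hbonds)
    native = frozenset(native_torsions)
    torsion_by_bond = {c.rotatable_bond: c for c in net.torsions}

    mechanical: list[Constraint] = list(net.covalent)
    for c in net.hbonds:
        if c.id in engaged_hb:
            mechanical.append(c)
    for bond_id in native:
        if bond_id not in torsion_by_bond:
            raise ValueError(f"no torsion constraint for rotatable bond {bond_id}")
        mechanical.append(torsion_by_bond[bond_id])

    game = PebbleGame(net.n_bodies)
    constraint_bars: dict[int, tuple[int, int]] = {}
    redundant_edges: list[tuple[int, int]] = []
    total = indep_total = 0
    nat_indep = 0
    for c in _insertion_order(mechanical):
        ind = tot = 0
        for (i, j, bars) in c.edges:
            for _ in range(bars):
                tot += 1
                if game.add_bar(i, j):
                    ind += 1
                else:
                    redundant_edges.append((i, j))
        constraint_bars[c.id] = (ind, tot)
        total += tot
        indep_total += ind
        if c.kind == "torsion":
            nat_indep += ind

    # ---- rigid clusters over bodies --------------------------------------
    parent = list(range(net.n_bodies))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    adjacency: set[tuple[int, int]] = set()
    for c in mechanical:
        for (i, j, _) in c.edges:
            adjacency.add((min(i, j), max(i, j)))
    for i, j in sorted(adjacency):
        if find(i) != find(j) and game.mutually_rigid(i, j):
            union(i, j)

    # ---- cluster partition of the a-priori rotatable bonds ----------------
    rigid_members: dict[int, set[int]] = {}
    for b in range(net.n_bodies):
        rigid_members.setdefault(find(b), set()).add(b)

    redundant_in: dict[int, int] = {}
    for i, j in redundant_edges:
        if find(i) == find(j):
            redundant_in[find(i)] = redundant_in.get(find(i), 0) + 1

    clusters: list[ClusterInfo] = []
    bond_cluster: dict[int, int] = {}

    locked_by_root: dict[int, list[int]] = {}
    hinge_bonds = []
    for bond in net.rotatable_bonds:
        if find(bond.i) == find(bond.j):
            locked_by_root.setdefault(find(bond.i), []).append(bond.id)
        else:
            hinge_bonds.append(bond)

    for root, bond_ids in sorted(locked_by_root.items()):
        b_count = redundant_in.get(root, 0)
        label = "overconstrained" if b_count > 0 else "isostatic"
        info = ClusterInfo(
            label=label,
            bond_ids=tuple(sorted(bond_ids)),
            n_bonds=len(bond_ids),
            count=b_count if label == "overconstrained" else 0,
            bodies=frozenset(rigid_members[root]),
        )
        for bid in bond_ids:
            bond_cluster[bid] = len(clusters)
        clusters.append(info)

    # contracted multigraph: nodes = rigid cluster roots, edges = constraints
    # whose bar groups span two clusters
    if hinge_bonds:
        multi = nx.MultiGraph()
        multi.add_nodes_from({find(b) for b in range(net.n_bodies)})
        for c in mechanical:
            for gidx, (i, j, bars) in enumerate(c.edges):
                ri, rj = find(i), find(j)
                if ri != rj:
                    multi.add_edge(ri, rj, key=("c", c.id, gidx))

        simple = nx.Graph()
        simple.add_nodes_from(multi.nodes)
        pair_multiplicity: dict[tuple[int, int], int] = {}
        for u, v, k in multi.edges(keys=True):
            pu, pv = min(u, v), max(u, v)
            pair_multiplicity[(pu, pv)] = pair_multiplicity.get((pu, pv), 0) + 1
            simple.add_edge(pu, pv)
        bridges = set()
        for u, v in nx.bridges(simple):
            pu, pv = min(u, v), max(u, v)
            if pair_multiplicity[(pu, pv)] == 1:
                bridges.add((pu, pv))

        # biconnected components of the contracted graph (by edge)
        comp_of_edge: dict[tuple[int, int], int] = {}
        for comp_id, comp_edges in enumerate(nx.biconnected_component_edges(simple)):
            for u, v in comp_edges:
                comp_of_edge[(min(u, v), max(u, v))] = comp_id

        bridge_bonds: list = []
        grouped: dict[int, list] = {}
        for bond in hinge_bonds:
            ri, rj = find(bond.i), find(bond.j)
            pair = (min(ri, rj), max(ri, rj))
            if pair in bridges:
                bridge_bonds.append(bond)
            else:
                grouped.setdefault(comp_of_edge[pair], []).append(bond)

        for bond in sorted(bridge_bonds, key=lambda b: b.id):
            bond_cluster[bond.id] = len(clusters)
            clusters.append(
                ClusterInfo(
                    label="flexible",
                    bond_ids=(bond.id,),
                    n_bonds=1,
                    count=1,
                    bodies=frozenset(rigid_members[find(bond.i)] | rigid_members[find(bond.j)]),
                )
            )

        for comp_id in sorted(grouped):
            bonds_in = sorted(grouped[comp_id], key=lambda b: b.id)
            # region bodies: every body of every rigid cluster touched by the
            # biconnected component's edges
            comp_roots = set()
            for (u, v), cid_ in comp_of_edge.items():
                if cid_ == comp_id:
                    comp_roots.add(u)
                    comp_roots.add(v)
            bodies = set()
            for root in comp_roots:
                bodies |= rigid_members[root]
            a_dof = _internal_dof(mechanical, bodies)
            bond_ids = tuple(b.id for b in bonds_in)
            for bid in bond_ids:
                bond_cluster[bid] = len(clusters)
            clusters.append(
                ClusterInfo(
                    label="flexible",
                    bond_ids=bond_ids,
                    n_bonds=len(bond_ids),
                    count=a_dof,
                    bodies=frozenset(bodies),
                )
            )

    decomp = RigidityDecomposition(
        n_bodies=net.n_bodies,
        free_pebbles=game.free_pebbles,
        total_bars=total,
        independent_bars=indep_total,
        constraint_bars=constraint_bars,
        clusters=clusters,
        bond_cluster=bond_cluster,
    )

    # ---- disordered torsion bookkeeping (entropy attenuation) -------------
    if torsion_by_bond:
        dis_bonds = [b for b in net.rotatable_bonds if b.id not in native]
        dis_indep = 0
        for bond in sorted(dis_bonds, key=lambda b: b.id):
            if game.add_bar(bond.i, bond.j):
                dis_indep += 1
        decomp.n_nat_total = len(native)
        decomp.n_nat_indep = nat_indep
        decomp.n_dis_total = len(dis_bonds)
        decomp.n_dis_indep = dis_indep
    return decomp


def _internal_dof(mechanical: Sequence[Constraint], bodies: set[int]) -> int:
    """Internal DOF of the sub-framework induced by ``bodies``: run a fresh
    pebble game on the induced bars; internal DOF = free pebbles - 6."""
    index = {b: i for i, b in enumerate(sorted(bodies))}
    game = PebbleGame(len(bodies))
    for c in mechanical:
        for (i, j, bars) in c.edges:
            if i in index and j in index:
                for _ in range(bars):
                    game.add_bar(index[i], index[j])
    return game.free_pebbles - 6


def cluster_counts(decomp: RigidityDecomposition) -> list[tuple[str, int, int]]:
    """Per-cluster (label, H, A) for flexible and (label, D, B) for
    over-constrained clusters; isostatic clusters report (label, D, 0)."""
    return [(c.label, c.n_bonds, c.count) for c in decomp.clusters]
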