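"""Body-bar constraint networks for the minimal Distance Constraint Model.

Atoms are rigid bodies with 6 degrees of freedom.  Three constraint kinds
connect them:

* **covalent** bonds — quenched (always present).  A generic single bond
  contributes 5 bars, locking lengths and angles but leaving the dihedral
  rotation; bonds whose rotation is chemically forbidden (the peptide bond,
  ring bonds, bonds to terminal atoms) carry a 6th quenched bar.
* **hydrogen bonds** — fluctuating.  Each candidate carries a geometry
  dependent enthalpy ``u_hb`` from a Mayo-type empirical potential and an
  entropy weight ``gamma_hb`` that is a linear function of that enthalpy
  (stronger bond, lower entropy).  Salt bridges are a special case with a
  fixed favourable energy.  An engaged H-bond places 5 bars from the donor
  hydrogen to the acceptor plus 1 bar to the acceptor antecedent.
* **torsions** — every a-priori rotatable bond carries a fluctuating torsion
  force that is either *native* (enthalpy ``v_nat``, entropy ``delta_nat``,
  one bar locking the dihedral) or *disordered* (``v_dis``, ``delta_dis``,
  no mechanical bar).

The Mayo-potential constants and the linear ``gamma_hb(u_hb)`` map are not
uniquely fixed by the model definition; the defaults below are documented
reconstructions, exposed in :class:`NetworkConfig` so alternatives can be
tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import networkx as nx

from .structure import AtomRecord, STANDARD_RESIDUES

__all__ = [
    "Constraint",
    "RotatableBond",
    "ConstraintNetwork",
    "DCMParameters",
    "NetworkConfig",
    "build_covalent_framework",
    "detect_hbonds",
    "hbond_entropy",
    "assign_torsion_constraints",
    "build_network",
    "write_hbond_table",
]

R_GAS = 1.987e-3  # kcal/(mol K)


@dataclass(frozen=True)
class DCMParameters:
    """mDCM thermodynamic parameters.

    ``u_sol``, ``v_nat`` and ``delta_nat`` are the fitting parameters;
    ``v_dis``/``delta_dis`` and the gamma(u) coefficients are held fixed.
    Enthalpies in kcal/mol, entropy weights are pure numbers (multiplied by
    R when entering the free energy).
    """

    u_sol: float = -2.0
    v_nat: float = -0.3
    delta_nat: float = 1.24
    v_dis: float = 0.0
    delta_dis: float = 1.85
    gamma_slope: float = 0.4     # per (kcal/mol); positive: weaker bond, more entropy
    gamma_intercept: float = 3.2

    def __post_init__(self) -> None:
        if not self.v_nat < self.v_dis:
            raise ValueError("v_nat must be < v_dis")
        if not self.delta_nat < self.delta_dis:
            raise ValueError("delta_nat must be < delta_dis")


@dataclass
class NetworkConfig:
    """The ``network:`` config block (cutoffs, bar multiplicities, potential)."""

    # H-bond geometry cutoffs
    max_da_distance: float = 3.5      # donor-acceptor distance cutoff, A
    min_dha_angle: float = 100.0      # donor-H-acceptor angle cutoff, degrees
    min_sequence_separation: int = 2  # exclude i, i+1 backbone pairs
    # Mayo-type potential (reconstructed constants)
    hb_well_depth: float = 8.0        # D0, kcal/mol
    hb_well_distance: float = 2.8     # R0, donor-acceptor equilibrium distance, A
    energy_ceiling: float = -0.1      # discard weaker (less favourable) candidates
    salt_bridge_energy: float = -10.0
    # bar multiplicities (body-bar convention)
    bars_covalent: int = 5
    bars_locked: int = 6
    bars_hbond: int = 5               # donor-H to acceptor
    bars_hbond_antecedent: int = 1
    bars_torsion: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        """Read the ``network:`` block of a YAML config file."""
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("network", doc))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump({"network": self.to_dict()}, fh, sort_keys=True)


@dataclass(frozen=True)
class Constraint:
    """A typed constraint between bodies.

    ``edges`` is a tuple of ``(i, j, bars)`` bar groups (H-bonds have two:
    the main donor-H/acceptor group and the antecedent bar).  For torsion
    constraints ``enthalpy``/``entropy_weight`` hold the native-state
    parameters and ``enthalpy_dis``/``entropy_weight_dis`` the disordered
    ones; ``rotatable_bond`` links back to the a-priori rotatable bond.
    """

    id: int
    kind: str  # covalent | hbond | torsion
    edges: tuple[tuple[int, int, int], ...]
    enthalpy: float = 0.0
    entropy_weight: float = 0.0
    quenched: bool = False
    enthalpy_dis: float = 0.0
    entropy_weight_dis: float = 0.0
    rotatable_bond: int | None = None
    donor: int | None = None
    hydrogen: int | None = None
    acceptor: int | None = None
    antecedent: int | None = None
    salt_bridge: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("covalent", "hbond", "torsion"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "covalent" and not self.quenched:
            raise ValueError("covalent constraints must be quenched")
        if any(b < 1 for _, _, b in self.edges):
            raise ValueError("bar multiplicity must be >= 1")

    @property
    def n_bars(self) -> int:
        return sum(b for _, _, b in self.edges)

    @property
    def endpoints(self) -> tuple[int, int]:
        return self.edges[0][0], self.edges[0][1]


@dataclass(frozen=True)
class RotatableBond:
    """An a-priori rotatable bond (the unit FI is reported on)."""

    id: int
    i: int
    j: int
    residue_index: int | None = None
    angle: str | None = None  # 'phi' | 'psi' | 'chi' | None for toys


@dataclass
class ConstraintNetwork:
    """Bodies plus typed constraints: the graph the pebble game runs on."""

    n_bodies: int
    constraints: list[Constraint] = field(default_factory=list)
    rotatable_bonds: list[RotatableBond] = field(default_factory=list)

    @property
    def covalent(self) -> list[Constraint]:
        return [c for c in self.constraints if c.kind == "covalent"]

    @property
    def hbonds(self) -> list[Constraint]:
        return [c for c in self.constraints if c.kind == "hbond"]

    @property
    def torsions(self) -> list[Constraint]:
        return [c for c in self.constraints if c.kind == "torsion"]

    @property
    def n_hb_max(self) -> int:
        return len(self.hbonds)

    @property
    def n_tor(self) -> int:
        return len(self.torsions)

    def next_id(self) -> int:
        return max((c.id for c in self.constraints), default=-1) + 1

    def validate(self) -> None:
        tor_bonds = [c.rotatable_bond for c in self.torsions]
        if len(set(tor_bonds)) != len(tor_bonds):
            raise ValueError("each rotatable bond may carry at most one torsion constraint")
        known = {b.id for b in self.rotatable_bonds}
        if any(t not in known for t in tor_bonds):
            raise ValueError("torsion constraint refers to unknown rotatable bond")


# ---------------------------------------------------------------------------
# Covalent framework from atoms
# ---------------------------------------------------------------------------

#: Heavy-atom connectivity for the 20 standard residues (bonds within the
#: residue, by atom name).  The backbone N-CA, CA-C, C-O bonds are implied
#: for every residue; the inter-residue peptide bond C(i)-N(i+1) is added
#: separately.  Hydrogens attach to their nearest heavy atom geometrically.
SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
}

BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O")]

#: donors/acceptors for salt-bridge special casing
_SB_DONOR_RES = {"LYS", "ARG", "HIS"}
_SB_ACCEPTOR_RES = {"ASP", "GLU"}
_SB_DONOR_ATOMS = {"NZ", "NE", "NH1", "NH2", "ND1", "NE2"}
_SB_ACCEPTOR_ATOMS = {"OD1", "OD2", "OE1", "OE2"}


def _covalent_bonds(atoms: Sequence[AtomRecord]) -> list[tuple[int, int]]:
    """Resolve covalent connectivity from the residue topology table.

    Heavy atoms bond by name within each residue; consecutive residues of a
    chain bond C(i)-N(i+1); hydrogens attach to the nearest heavy atom
    within 1.35 A.
    """
    index: dict[tuple[str, int, str], int] = {}
    for pos, a in enumerate(atoms):
        index[(a.chain, a.residue_index, a.name)] = pos
    bonds: set[tuple[int, int]] = set()

    residues: dict[tuple[str, int], str] = {}
    for a in atoms:
        residues.setdefault((a.chain, a.residue_index), a.residue_name)

    for (chain, ridx), resname in residues.items():
        if resname not in STANDARD_RESIDUES:
            raise ValueError(f"no topology for residue {resname} {chain}:{ridx}")
        pairs = BACKBONE_BONDS + SIDECHAIN_BONDS[resname]
        for a_name, b_name in pairs:
            ia = index.get((chain, ridx, a_name))
            ib = index.get((chain, ridx, b_name))
            if ia is not None and ib is not None:
                bonds.add((min(ia, ib), max(ia, ib)))
        # OXT on C-terminal residues
        ioxt = index.get((chain, ridx, "OXT"))
        ic = index.get((chain, ridx, "C"))
        if ioxt is not None and ic is not None:
            bonds.add((min(ic, ioxt), max(ic, ioxt)))
        # peptide bond to the next residue of the same chain
        ic = index.get((chain, ridx, "C"))
        inext = index.get((chain, ridx + 1, "N"))
        if ic is not None and inext is not None:
            bonds.add((min(ic, inext), max(ic, inext)))

    # hydrogens: nearest heavy atom in the same residue
    coords = np.array([a.xyz for a in atoms])
    for pos, a in enumerate(atoms):
        if a.element != "H":
            continue
        same_res = [
            p for p, b in enumerate(atoms)
            if b.element != "H" and b.chain == a.chain and b.residue_index == a.residue_index
        ]
        if not same_res:
            raise ValueError(f"hydrogen {a.name} {a.chain}:{a.residue_index} has no heavy partner")
        d = np.linalg.norm(coords[same_res] - coords[pos], axis=1)
        k = int(np.argmin(d))
        if d[k] > 1.35:
            raise ValueError(
                f"hydrogen {a.name} {a.chain}:{a.residue_index} is {d[k]:.2f} A from the "
                "nearest heavy atom; cannot resolve connectivity"
            )
        bonds.add((min(pos, same_res[k]), max(pos, same_res[k])))
    return sorted(bonds)


def build_covalent_framework(
    atoms: Sequence[AtomRecord], config: NetworkConfig | None = None
) -> ConstraintNetwork:
    """Build the quenched covalent part of the framework.

    Each covalent bond contributes 5 quenched bars; non-rotatable bonds
    (peptide bonds, ring bonds, bonds to terminal atoms) a 6th.  The
    a-priori rotatable bonds (phi, psi, chi, ...) are enumerated here; for
    proline the ring locks N-CA, so only psi survives.
    """
    config = config or NetworkConfig()
    bonds = _covalent_bonds(atoms)
    degree = np.zeros(len(atoms), dtype=int)
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
    for pos in np.nonzero(degree == 0)[0]:
        a = atoms[pos]
        raise ValueError(f"atom {a.name} {a.chain}:{a.residue_index} has no covalent partner")

    g = nx.Graph(bonds)
    ring_edges: set[tuple[int, int]] = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add((min(a, b), max(a, b)))

    def is_peptide(i: int, j: int) -> bool:
        ai, aj = atoms[i], atoms[j]
        pair = {ai.name, aj.name}
        return pair == {"C", "N"} and ai.residue_index != aj.residue_index

    net = ConstraintNetwork(n_bodies=len(atoms))
    cid = 0
    for i, j in bonds:
        rotatable = (
            degree[i] >= 2
            and degree[j] >= 2
            and (i, j) not in ring_edges
            and not is_peptide(i, j)
        )
        bars = config.bars_covalent if rotatable else config.bars_locked
        net.constraints.append(
            Constraint(id=cid, kind="covalent", edges=((i, j, bars),), quenched=True)
        )
        cid += 1
        if rotatable:
            bond_id = len(net.rotatable_bonds)
            ai, aj = atoms[i], atoms[j]
            angle = None
            residx = None
            names = (ai.name, aj.name)
            if set(names) == {"N", "CA"}:
                angle, residx = "phi", ai.residue_index
            elif set(names) == {"CA", "C"}:
                angle, residx = "psi", ai.residue_index
            elif ai.element != "H" and aj.element != "H":
                angle, residx = "chi", ai.residue_index
            net.rotatable_bonds.append(
                RotatableBond(id=bond_id, i=i, j=j, residue_index=residx, angle=angle)
            )
    return net


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _mayo_energy(
    r_da: float, cos2_dha: float, cos2_haa: float, config: NetworkConfig
) -> float:
    """Mayo-type distance and angular H-bond energy (reconstruction).

    E = D0 [5 (R0/R)^12 - 6 (R0/R)^10] * cos^2(theta_DHA) * cos^2(theta_HAA),
    with R the donor-acceptor distance.  The radial well has its minimum -D0
    at R = R0; the angular terms gate out bent geometries.
    """
    x = config.hb_well_distance / r_da
    radial = config.hb_well_depth * (5.0 * x**12 - 6.0 * x**10)
    return radial * cos2_dha * cos2_haa


def hbond_entropy(u_hb: float, params: DCMParameters) -> float:
    """Linear entropy map gamma_hb(u_hb) = slope * u + intercept, clamped >= 0."""
    if not np.isfinite(u_hb):
        raise ValueError("u_hb must be finite")
    return max(0.0, params.gamma_slope * u_hb + params.gamma_intercept)


def detect_hbonds(
    atoms: Sequence[AtomRecord],
    config: NetworkConfig | None = None,
    params: DCMParameters | None = None,
    covalent_bonds: list[tuple[int, int]] | None = None,
) -> list[Constraint]:
    """Detect candidate hydrogen bonds from local geometry.

    Donors are N/O/S atoms with an attached hydrogen; acceptors are O atoms
    and two-coordinate nitrogens.  Candidates are filtered by donor-acceptor
    distance and the D-H...A angle, scored with the Mayo-type potential, and
    kept only when more favourable than ``energy_ceiling``.  Salt-bridge
    pairs (Lys/Arg/His side-chain N to Asp/Glu carboxylate O) get a fixed
    special-case energy.  Detection is deterministic.
    """
    config = config or NetworkConfig()
    params = params or DCMParameters()
    bonds = covalent_bonds if covalent_bonds is not None else _covalent_bonds(atoms)
    adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)

    coords = np.array([a.xyz for a in atoms])

    donors = []  # (donor_idx, h_idx)
    for pos, a in enumerate(atoms):
        if a.element in ("N", "O", "S"):
            for nb in adj[pos]:
                if atoms[nb].element == "H":
                    donors.append((pos, nb))
    acceptors = []
    for pos, a in enumerate(atoms):
        heavy_deg = sum(1 for nb in adj[pos] if atoms[nb].element != "H")
        if a.element == "O" or (a.element == "N" and heavy_deg <= 2 and not adj_has_h(adj, atoms, pos)):
            acceptors.append(pos)

    out: list[Constraint] = []
    cid = 0
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx) or a_idx in adj[d_idx]:
                continue
            ad, aa = atoms[d_idx], atoms[a_idx]
            if ad.chain == aa.chain and abs(ad.residue_index - aa.residue_index) < config.min_sequence_separation:
                continue
            r_da = float(np.linalg.norm(coords[a_idx] - coords[d_idx]))
            if r_da > config.max_da_distance or r_da < 2.0:
                continue
            # D-H...A angle at the hydrogen
            v1 = coords[d_idx] - coords[h_idx]
            v2 = coords[a_idx] - coords[h_idx]
            cos_dha = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle_dha = math.degrees(math.acos(np.clip(cos_dha, -1.0, 1.0)))
            if angle_dha < config.min_dha_angle:
                continue
            heavy_nb = [nb for nb in adj[a_idx] if atoms[nb].element != "H"]
            antecedent = heavy_nb[0] if heavy_nb else None
            if antecedent is not None:
                w1 = coords[h_idx] - coords[a_idx]
                w2 = coords[antecedent] - coords[a_idx]
                cos_haa = float(np.dot(w1, w2) / (np.linalg.norm(w1) * np.linalg.norm(w2)))
                angle_haa = math.degrees(math.acos(np.clip(cos_haa, -1.0, 1.0)))
                if angle_haa < 90.0:
                    continue
                cos2_haa = cos_haa**2
            else:
                cos2_haa = 1.0

            is_sb = (
                ad.residue_name in _SB_DONOR_RES
                and ad.name in _SB_DONOR_ATOMS
                and aa.residue_name in _SB_ACCEPTOR_RES
                and aa.name in _SB_ACCEPTOR_ATOMS
            )
            if is_sb:
                u = config.salt_bridge_energy
            else:
                u = _mayo_energy(r_da, cos_dha**2, cos2_haa, config)
            if u > config.energy_ceiling:
                continue
            edges = [(h_idx, a_idx, config.bars_hbond)]
            if antecedent is not None and config.bars_hbond_antecedent > 0:
                edges.append((h_idx, antecedent, config.bars_hbond_antecedent))
            out.append(
                Constraint(
                    id=cid,
                    kind="hbond",
                    edges=tuple(edges),
                    enthalpy=u,
                    entropy_weight=hbond_entropy(u, params),
                    donor=d_idx,
                    hydrogen=h_idx,
                    acceptor=a_idx,
                    antecedent=antecedent,
                    salt_bridge=is_sb,
                )
            )
            cid += 1
    out.sort(key=lambda c: (c.donor, c.acceptor))
    return [replace(c, id=i) for i, c in enumerate(out)]


def adj_has_h(adj: dict[int, list[int]], atoms: Sequence[AtomRecord], pos: int) -> bool:
    return any(atoms[nb].element == "H" for nb in adj[pos])


# ---------------------------------------------------------------------------
# Torsions and network assembly
# ---------------------------------------------------------------------------

def assign_torsion_constraints(
    net: ConstraintNetwork, params: DCMParameters, config: NetworkConfig | None = None
) -> ConstraintNetwork:
    """Attach a fluctuating torsion constraint to every a-priori rotatable bond.

    When engaged natively the torsion contributes one bar locking the
    dihedral (with v_nat / delta_nat); disordered torsions contribute no bar
    and carry v_dis / delta_dis.
    """
    config = config or NetworkConfig()
    net = ConstraintNetwork(
        n_bodies=net.n_bodies,
        constraints=[c for c in net.constraints if c.kind != "torsion"],
        rotatable_bonds=list(net.rotatable_bonds),
    )
    cid = net.next_id()
    for bond in net.rotatable_bonds:
        net.constraints.append(
            Constraint(
                id=cid,
                kind="torsion",
                edges=((bond.i, bond.j, config.bars_torsion),),
                enthalpy=params.v_nat,
                entropy_weight=params.delta_nat,
                enthalpy_dis=params.v_dis,
                entropy_weight_dis=params.delta_dis,
                rotatable_bond=bond.id,
            )
        )
        cid += 1
    net.validate()
    return net


def build_network(
    atoms: Sequence[AtomRecord],
    params: DCMParameters | None = None,
    config: NetworkConfig | None = None,
) -> ConstraintNetwork:
    """Full maximal graph: covalent framework + candidate H-bonds + torsions."""
    params = params or DCMParameters()
    config = config or NetworkConfig()
    net = build_covalent_framework(atoms, config)
    cid = net.next_id()
    for hb in detect_hbonds(atoms, config, params):
        net.constraints.append(replace(hb, id=cid))
        cid += 1
    return assign_torsion_constraints(net, params, config)


def write_hbond_table(hbonds: Sequence[Constraint], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "donor": c.donor,
                "acceptor": c.acceptor,
                "u_hb": c.enthalpy,
                "gamma_hb": c.entropy_weight,
                "salt_bridge": c.salt_bridge,
            }
            for c in hbonds
        ]
    ).to_csv(path, sep="\t", index=False)
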