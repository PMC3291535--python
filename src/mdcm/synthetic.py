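"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here, seeded and
deterministic:

* toy body-bar frameworks whose rigidity decomposition is known in closed
  form (or certified by the generic rank oracle),
* polymer pseudo-proteins — geometrically valid poly-glycine backbones with
  designed hydrogen-bond networks that the geometric detector recovers,
* synthetic heat-capacity curves from the exact ensemble path at known
  parameters (the recovery target for model parameterization),
* Gaussian null profiles for calibrating the response-binning statistics.

Each generator emits its ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import (
    Constraint,
    ConstraintNetwork,
    DCMParameters,
    NetworkConfig,
    RotatableBond,
)
from .structure import AtomRecord, ResidueAnnotation

__all__ = [
    "ToyFrameworkSpec",
    "make_toy_framework",
    "make_ensemble_toy",
    "make_polymer_protein",
    "make_synthetic_cp",
    "make_null_profiles",
]


@dataclass(frozen=True)
class ToyFrameworkSpec:
    """Specification of a toy body-bar framework."""

    topology: str  # rotor_chain | ring | locked_triangle | over_braced_pair | random
    n_bodies: int = 4
    extra_bars: int = 0
    seed: int = 0


@dataclass
class ToyGroundTruth:
    """Expected rigidity structure of a generated toy framework."""

    independent_bars: int
    internal_dof: int
    # list of (label, bond_ids, n_bonds, count) mirroring ClusterInfo
    clusters: list[tuple[str, tuple[int, ...], int, int]] = field(default_factory=list)
    certified_by: str = "closed_form"  # or "rank_oracle"


def _cov(cid: int, i: int, j: int, bars: int) -> Constraint:
    return Constraint(id=cid, kind="covalent", edges=((i, j, bars),), quenched=True)


def make_toy_framework(spec: ToyFrameworkSpec) -> tuple[ConstraintNetwork, ToyGroundTruth]:
    """Build a toy framework plus its exact expected decomposition.

    Closed forms: a rotor chain of n bodies has n-1 independent single-bond
    flexible clusters; a 5-bar ring of n bodies has n-6 internal DOF (one
    collective flexible cluster for n >= 7, isostatic at n = 6, and 6-n
    redundant bars in one over-constrained cluster for n < 6); an
    over-braced pair with e extra bars is over-constrained with B = e.
    Random frameworks are certified by the generic rank oracle.
    """
    n = spec.n_bodies
    net = ConstraintNetwork(n_bodies=n)
    gt = ToyGroundTruth(independent_bars=0, internal_dof=0)

    if spec.topology == "rotor_chain":
        if n < 2:
            raise ValueError("rotor_chain needs >= 2 bodies")
        for k in range(n - 1):
            net.constraints.append(_cov(k, k, k + 1, 5))
            net.rotatable_bonds.append(RotatableBond(id=k, i=k, j=k + 1))
        gt.independent_bars = 5 * (n - 1)
        gt.internal_dof = n - 1
        gt.clusters = [("flexible", (k,), 1, 1) for k in range(n - 1)]

    elif spec.topology == "ring":
        if n < 3:
            raise ValueError("ring needs >= 3 bodies")
        for k in range(n):
            net.constraints.append(_cov(k, k, (k + 1) % n, 5))
            net.rotatable_bonds.append(RotatableBond(id=k, i=k, j=(k + 1) % n))
        bonds = tuple(range(n))
        if n >= 7:
            gt.independent_bars = 5 * n
            gt.internal_dof = n - 6
            gt.clusters = [("flexible", bonds, n, n - 6)]
        elif n == 6:
            gt.independent_bars = 30
            gt.internal_dof = 0
            gt.clusters = [("isostatic", bonds, n, 0)]
        else:
            gt.independent_bars = 6 * n - 6
            gt.internal_dof = 0
            gt.clusters = [("overconstrained", bonds, n, 6 - n)]

    elif spec.topology == "locked_triangle":
        # isostatic triangle (6+5+1 bars) plus extra bars on the 1-bar edge
        net.constraints.append(_cov(0, 0, 1, 6))
        net.constraints.append(_cov(1, 1, 2, 5))
        net.constraints.append(_cov(2, 0, 2, 1 + spec.extra_bars))
        net.rotatable_bonds.append(RotatableBond(id=0, i=1, j=2))
        gt.independent_bars = 12
        gt.internal_dof = 0
        if spec.extra_bars > 0:
            gt.clusters = [("overconstrained", (0,), 1, spec.extra_bars)]
        else:
            gt.clusters = [("isostatic", (0,), 1, 0)]

    elif spec.topology == "over_braced_pair":
        net.constraints.append(_cov(0, 0, 1, 5))
        net.constraints.append(_cov(1, 0, 1, 1 + spec.extra_bars))
        net.rotatable_bonds.append(RotatableBond(id=0, i=0, j=1))
        gt.independent_bars = 6
        gt.internal_dof = 0
        gt.clusters = [("overconstrained", (0,), 1, spec.extra_bars)]
        if spec.extra_bars == 0:
            gt.clusters = [("isostatic", (0,), 1, 0)]

    elif spec.topology == "random":
        rng = np.random.default_rng(spec.seed)
        cid = 0
        # random spanning tree keeps the framework connected
        for k in range(1, n):
            anchor = int(rng.integers(0, k))
            bars = int(rng.choice([5, 5, 6]))
            net.constraints.append(_cov(cid, anchor, k, bars))
            if bars == 5:
                net.rotatable_bonds.append(
                    RotatableBond(id=len(net.rotatable_bonds), i=anchor, j=k)
                )
            cid += 1
        for _ in range(spec.extra_bars):
            i, j = rng.choice(n, size=2, replace=False)
            net.constraints.append(_cov(cid, int(min(i, j)), int(max(i, j)), int(rng.integers(1, 4))))
            cid += 1
        gt = _ground_truth_from_oracle(net, seed=spec.seed)
    else:
        raise ValueError(f"unknown toy topology {spec.topology!r}")

    return net, gt


def _ground_truth_from_oracle(net: ConstraintNetwork, seed: int) -> ToyGroundTruth:
    from .rankoracle import rank_analysis

    ra = rank_analysis(net, seed=seed)
    clusters: list[tuple[str, tuple[int, ...], int, int]] = []
    # locked bonds grouped by rigid cluster
    by_cluster: dict[frozenset, list[int]] = {}
    for bond in net.rotatable_bonds:
        if ra.bond_labels[bond.id] == "locked":
            home = next(c for c in ra.rigid_partition if bond.i in c)
            by_cluster.setdefault(home, []).append(bond.id)
    for cluster, bonds in sorted(by_cluster.items(), key=lambda kv: min(kv[1])):
        b = ra.redundant_per_cluster.get(cluster, 0)
        label = "overconstrained" if b > 0 else "isostatic"
        clusters.append((label, tuple(sorted(bonds)), len(bonds), b))
    for bond_ids, a_dof in ra.flexible_groups:
        clusters.append(("flexible", bond_ids, len(bond_ids), a_dof))
    return ToyGroundTruth(
        independent_bars=ra.independent_bars,
        internal_dof=ra.internal_dof,
        clusters=clusters,
        certified_by="rank_oracle",
    )


# ---------------------------------------------------------------------------
# Ensemble toys: rotor chains with fluctuating H-bonds and torsions
# ---------------------------------------------------------------------------

def make_ensemble_toy(
    n_rotors: int = 4,
    n_hbonds: int = 3,
    params: DCMParameters | None = None,
    seed: int = 0,
    u_range: tuple[float, float] = (-4.0, -1.0),
) -> ConstraintNetwork:
    """A small DCM network: a rotor chain whose bonds carry fluctuating
    torsions, cross-linked by H-bond constraints with heterogeneous
    energies.  Small enough for exact enumeration of the full ensemble."""
    params = params or DCMParameters()
    rng = np.random.default_rng(seed)
    n_bodies = n_rotors + 1
    net = ConstraintNetwork(n_bodies=n_bodies)
    cid = 0
    for k in range(n_rotors):
        net.constraints.append(_cov(cid, k, k + 1, 5))
        net.rotatable_bonds.append(RotatableBond(id=k, i=k, j=k + 1))
        cid += 1
    # H-bonds between bodies >= 2 apart, 6 bars total like a real H-bond
    pairs = [(i, j) for i in range(n_bodies) for j in range(i + 2, n_bodies)]
    if n_hbonds > len(pairs):
        raise ValueError("too many H-bonds for this chain length")
    chosen = rng.choice(len(pairs), size=n_hbonds, replace=False)
    from .network import hbond_entropy

    for k, idx in enumerate(sorted(chosen)):
        i, j = pairs[idx]
        u = float(rng.uniform(*u_range))
        net.constraints.append(
            Constraint(
                id=cid,
                kind="hbond",
                edges=((i, j, 5), (i, j - 1, 1)),  # 1 bar to the acceptor's chain antecedent
                enthalpy=u,
                entropy_weight=hbond_entropy(u, params),
                donor=i,
                acceptor=j,
            )
        )
        cid += 1
    for bond in net.rotatable_bonds:
        net.constraints.append(
            Constraint(
                id=cid,
                kind="torsion",
                edges=((bond.i, bond.j, 1),),
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


# ---------------------------------------------------------------------------
# Polymer pseudo-proteins
# ---------------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_N_H = 1.010
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, length: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement of atom d given three predecessors (angles in deg)."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(dih),
            length * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_polymer_protein(
    n_res: int,
    hbond_pattern: str = "helix_like",
    seed: int = 0,
    config: NetworkConfig | None = None,
) -> tuple[list[AtomRecord], list[ResidueAnnotation], int | None]:
    """Generate a poly-glycine backbone with a designed H-bond network.

    ``helix_like`` uses ideal alpha-helical torsions (phi = -57, psi = -47)
    so the amide of residue i donates to the carbonyl of residue i-4: the
    designed count is n_res - 4 and the geometric detector recovers it
    exactly.  ``sheet_like`` builds an extended strand (phi = -139,
    psi = 135; no internal H-bonds, strand annotations).  ``random`` draws
    torsions uniformly; its designed count is None (whatever geometry
    happens to produce, deterministically in the seed).

    Returns (atoms, annotations, designed_hbond_count).
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if hbond_pattern == "helix_like":
        phis = [-57.0] * n_res
        psis = [-47.0] * n_res
        designed: int | None = max(0, n_res - 4)
        ss = "helix"
    elif hbond_pattern == "sheet_like":
        phis = [-139.0] * n_res
        psis = [135.0] * n_res
        designed = 0
        ss = "strand"
    elif hbond_pattern == "random":
        phis = list(rng.uniform(-180, 180, size=n_res))
        psis = list(rng.uniform(-180, 180, size=n_res))
        designed = None
        ss = "coil"
    else:
        raise ValueError(f"unknown hbond_pattern {hbond_pattern!r}")

    omega = 180.0
    # seed the first three backbone atoms
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(1, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(1, "CA")] = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _ANG_N_CA_C)
    coords[(1, "C")] = coords[(1, "CA")] + _BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])

    for r in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[(r, "N")], coords[(r, "CA")], coords[(r, "C")]
        n_new = _place(n_prev, ca_prev, c_prev, _BOND_C_N, _ANG_CA_C_N, psis[r - 1])
        ca_new = _place(ca_prev, c_prev, n_new, _BOND_N_CA, _ANG_C_N_CA, omega)
        c_new = _place(c_prev, n_new, ca_new, _BOND_CA_C, _ANG_N_CA_C, phis[r])
        coords[(r + 1, "N")] = n_new
        coords[(r + 1, "CA")] = ca_new
        coords[(r + 1, "C")] = c_new

    # carbonyl oxygens: in the peptide plane, trans to the next N (the last
    # residue places O trans to its own CA-N direction)
    for r in range(1, n_res + 1):
        ca, c = coords[(r, "CA")], coords[(r, "C")]
        if (r + 1, "N") in coords:
            coords[(r, "O")] = _place(coords[(r + 1, "N")], ca, c, _BOND_C_O, 121.0, 180.0)
        else:
            coords[(r, "O")] = _place(coords[(r, "N")], ca, c, _BOND_C_O, 121.0, 180.0)
    # amide hydrogens: bisector of C(prev)-N and CA-N, in the peptide plane
    for r in range(1, n_res + 1):
        n = coords[(r, "N")]
        ca = coords[(r, "CA")]
        if r > 1:
            other = coords[(r - 1, "C")]
        else:
            other = n + np.array([0.0, 0.0, 1.0])
        u = (other - n) / np.linalg.norm(other - n)
        v = (ca - n) / np.linalg.norm(ca - n)
        h_dir = -(u + v)
        h_dir /= np.linalg.norm(h_dir)
        coords[(r, "H")] = n + _BOND_N_H * h_dir

    atoms: list[AtomRecord] = []
    serial = 0
    for r in range(1, n_res + 1):
        for name, element in (("N", "N"), ("H", "H"), ("CA", "C"), ("C", "C"), ("O", "O")):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_index=r,
                    residue_name="GLY",
                    chain="A",
                    coords=tuple(float(x) for x in coords[(r, name)]),
                    bfactor=10.0,
                    occupancy=1.0,
                )
            )

    annotations = [
        ResidueAnnotation(residue_index=r, rel_sasa=None, ss_class=ss,
                          subdomain="alpha" if r <= n_res // 2 else "beta")
        for r in range(1, n_res + 1)
    ]
    return atoms, annotations, designed


# ---------------------------------------------------------------------------
# Synthetic heat-capacity curves and null profiles
# ---------------------------------------------------------------------------

def make_synthetic_cp(
    net: ConstraintNetwork,
    params: DCMParameters,
    T_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-ensemble Cp(T) at known parameters plus Gaussian noise.

    ``noise_sd`` is relative to the peak height (0.02 = 2% noise).  With
    noise_sd = 0 the table equals the exact heat-capacity output bitwise.
    """
    from .ensemble import LandscapeBuilder, heat_capacity

    builder = LandscapeBuilder(net, params, exhaustive_only=True)
    T, cp, _ = heat_capacity(builder, T_grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(scale=noise_sd * np.max(np.abs(cp)), size=cp.shape)
    return T, cp


def make_null_profiles(
    baseline_mean: Sequence[float],
    baseline_sigma: Sequence[float],
    n_mutants: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n_mutants`` profiles positionwise from N(mean, sigma)."""
    mean = np.asarray(baseline_mean, float)
    sigma = np.asarray(baseline_sigma, float)
    if mean.shape != sigma.shape:
        raise ValueError("mean and sigma shapes must match")
    rng = np.random.default_rng(seed)
    return rng.normal(loc=mean, scale=sigma, size=(n_mutants,) + mean.shape)
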