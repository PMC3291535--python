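"""Quantified stability/flexibility relationships: FI and CC.

Per framework, every a-priori rotatable bond i carries a flexibility index
f_i determined by the cluster it falls in: +A/H in a flexible region (the
density of independent degrees of freedom over its H member bonds), -B/D in
an over-constrained region (the density of redundant constraints), and 0 in
an isostatically rigid region.  The pairwise cooperativity value f_mn
equals the shared cluster's f when bonds m and n sit in the same cluster
and 0 when they sit in distinct clusters — including two *different* rigid
clusters, so CC distinguishes co-rigidity within one cluster from mere
simultaneous rigidity.

The reported FI vector and CC matrix are double averages: an arithmetic
mean over the frameworks of each macrostate, then a Gibbs-weighted average
over the native basin of the free-energy landscape at the melting
temperature.  Positive entries mark correlated flexibility, negative ones
co-rigidity, zero mechanical decoupling or marginal (isostatic) rigidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensemble import Landscape, native_basin_average
from .network import ConstraintNetwork
from .pebble import RigidityDecomposition

__all__ = ["QSFRProfile", "flexibility_index", "cc_entry", "framework_cc", "ensemble_qsfr"]


def flexibility_index(decomp: RigidityDecomposition, bond_ids: Sequence[int] | None = None) -> np.ndarray:
    """Per-rotatable-bond flexibility index of a single framework."""
    if bond_ids is None:
        bond_ids = sorted(decomp.bond_cluster)
    return np.array([decomp.bond_f(b) for b in bond_ids])


def cc_entry(decomp: RigidityDecomposition, m: int, n: int) -> float:
    """Pair value f_mn for two a-priori rotatable bonds of one framework."""
    cm, cn = decomp.bond_cluster[m], decomp.bond_cluster[n]
    if cm != cn:
        return 0.0
    return decomp.clusters[cm].f


def framework_cc(decomp: RigidityDecomposition, bond_ids: Sequence[int] | None = None) -> np.ndarray:
    """Full symmetric pair matrix of one framework."""
    if bond_ids is None:
        bond_ids = sorted(decomp.bond_cluster)
    cl = np.array([decomp.bond_cluster[b] for b in bond_ids])
    fv = np.array([decomp.bond_f(b) for b in bond_ids])
    same = cl[:, None] == cl[None, :]
    return np.where(same, fv[:, None], 0.0)


@dataclass
class QSFRProfile:
    """Ensemble-averaged FI and CC with provenance."""

    fi_bond: np.ndarray
    cc_bond: np.ndarray
    bond_ids: list[int]
    fi_residue: dict[int, float] | None = None
    cc_residue: np.ndarray | None = None
    residue_indices: list[int] | None = None
    provenance: dict = field(default_factory=dict)


def ensemble_qsfr(
    landscape: Landscape,
    net: ConstraintNetwork | None = None,
    aggregation: str = "mean",
) -> QSFRProfile:
    """Native-basin Gibbs average of FI and CC at the landscape temperature.

    When the network carries phi/psi metadata, bond values are aggregated to
    per-residue FI (mean of the residue's phi and psi bonds by default;
    ``aggregation`` may be 'mean', 'min' or 'max') and the residue-level CC
    is the mean over the backbone-bond pairs of the two residues.
    """
    fi = np.asarray(native_basin_average(landscape, "fi"), float)
    cc = np.asarray(native_basin_average(landscape, "fpair"), float)
    cc = 0.5 * (cc + cc.T)  # exact symmetry against roundoff
    bond_ids = list(range(len(fi)))

    profile = QSFRProfile(
        fi_bond=fi,
        cc_bond=cc,
        bond_ids=bond_ids,
        provenance={
            "temperature": landscape.temperature,
            "tm": landscape.tm,
            "basin_size": len(landscape.native_basin),
            "basin_min": landscape.basin_min,
            **landscape.metadata,
        },
    )

    if net is not None:
        backbone: dict[int, list[int]] = {}
        for bond in net.rotatable_bonds:
            if bond.angle in ("phi", "psi") and bond.residue_index is not None:
                backbone.setdefault(bond.residue_index, []).append(bond.id)
        if backbone:
            reducer = {"mean": np.mean, "min": np.min, "max": np.max}[aggregation]
            residues = sorted(backbone)
            profile.fi_residue = {
                r: float(reducer(fi[backbone[r]])) for r in residues
            }
            n_res = len(residues)
            cc_res = np.zeros((n_res, n_res))
            for a, ra in enumerate(residues):
                for b, rb in enumerate(residues):
                    block = cc[np.ix_(backbone[ra], backbone[rb])]
                    cc_res[a, b] = float(np.mean(block))
            cc_res = 0.5 * (cc_res + cc_res.T)
            profile.cc_residue = cc_res
            profile.residue_indices = residues
    return profile
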