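"""Structure input/output and per-residue annotations.

Reads prepared (protonated, minimized) all-atom PDB structures into flat
:class:`AtomRecord` lists, computes relative solvent accessibility with the
Shrake-Rupley algorithm, assigns accessibility tertiles, and round-trips the
pipeline's tabular artifacts (FI profiles, CC matrices, response tables,
heat-capacity curves, B-factor tables) as plain TSV/JSON.

PDB dialect: coordinates are taken from the first MODEL only; for alternate
locations the highest-occupancy conformer is kept (ties broken in favour of
altloc 'A'); HETATM records, including crystallographic waters, are dropped;
insertion codes are rejected because the analysis assumes a plain 1-based
author numbering per chain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ResidueAnnotation",
    "read_structure",
    "write_structure",
    "compute_sasa",
    "compute_relative_sasa",
    "tertile_classes",
    "read_annotations",
    "write_annotations",
    "read_cp_curve",
    "write_cp_curve",
    "read_bfactors",
    "write_bfactors",
    "read_fi_profile",
    "write_fi_profile",
    "read_cc_matrix",
    "write_cc_matrix",
    "write_run_metadata",
    "read_run_metadata",
    "MAX_SASA",
    "STANDARD_RESIDUES",
]

#: Theoretical maximum solvent accessible surface areas (A^2) per residue
#: type, in the style of the Tien et al. Gly-X-Gly reference state.  Used to
#: convert numeric SASA to relative accessibility in [0, 1].
MAX_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

STANDARD_RESIDUES = frozenset(MAX_SASA)

#: Documented SASA constants: water-probe radius (A) and sphere resolution.
SASA_PROBE_RADIUS = 1.4
SASA_N_POINTS = 960


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of a prepared structure.

    ``residue_index`` is the 1-based author numbering within the chain;
    ``coords`` are Cartesian, in Angstrom; ``bfactor`` in A^2.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    coords: tuple[float, float, float]
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class ResidueAnnotation:
    """Per-residue annotation: accessibility, secondary structure, subdomain."""

    residue_index: int
    rel_sasa: float | None = None
    ss_class: str = "coil"  # helix | strand | coil
    subdomain: str = "alpha"  # alpha | beta

    def __post_init__(self) -> None:
        if self.ss_class not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown ss_class {self.ss_class!r}")
        if self.subdomain not in ("alpha", "beta"):
            raise ValueError(f"unknown subdomain {self.subdomain!r}")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, require_hydrogens: bool = True) -> list[AtomRecord]:
    """Read ATOM records of the first model of a PDB file.

    Alternate locations keep the highest-occupancy conformer (ties -> 'A');
    HETATM records (including waters) are dropped; insertion codes raise.
    With ``require_hydrogens`` every standard residue must carry at least one
    explicit hydrogen (proline's backbone amide has none, so proline is only
    required to carry one if any hydrogens were deposited for it elsewhere).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - empty file
        raise ValueError(f"no coordinate model found in {path}")

    records: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():
                continue  # HETATM (waters included) dropped entirely
            if icode.strip():
                raise ValueError(
                    f"insertion code {icode!r} at residue {resseq} is not supported"
                )
            for atom in residue:
                if atom.is_disordered():
                    alts = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    atom = alts[0]
                serial += 1
                occ = atom.get_occupancy()
                records.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.get_name(),
                        element=(atom.element or _guess_element(atom.get_name())).upper(),
                        residue_index=int(resseq),
                        residue_name=residue.get_resname().strip(),
                        chain=chain.id.strip() or "A",
                        coords=tuple(float(x) for x in atom.get_coord()),
                        bfactor=float(atom.get_bfactor() or 0.0),
                        occupancy=float(min(max(occ if occ is not None else 1.0, 0.0), 1.0)),
                    )
                )

    if require_hydrogens:
        _check_hydrogens(records)
    return records


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1] if stripped else "X"


def _check_hydrogens(records: Sequence[AtomRecord]) -> None:
    """H-bond detection needs explicit hydrogens; fail loudly if absent."""
    by_res: dict[tuple[str, int], list[AtomRecord]] = {}
    for rec in records:
        by_res.setdefault((rec.chain, rec.residue_index), []).append(rec)
    for (chain, idx), atoms in by_res.items():
        resname = atoms[0].residue_name
        if resname not in STANDARD_RESIDUES or resname == "PRO":
            continue
        if not any(a.element == "H" for a in atoms):
            raise ValueError(
                f"residue {resname} {chain}:{idx} has no explicit hydrogens; "
                "H-bond detection requires a protonated structure"
            )


def write_structure(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write AtomRecords as a minimal single-model PDB file."""
    lines = []
    for a in atoms:
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.coords
        lines.append(
            f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3s} {a.chain:1s}"
            f"{a.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

def compute_sasa(atoms: Sequence[AtomRecord]) -> dict[int, float]:
    """Numeric Shrake-Rupley SASA (A^2) per residue (hydrogens excluded)."""
    from Bio.PDB.SASA import ShrakeRupley
    from Bio.PDB.StructureBuilder import StructureBuilder

    heavy = [a for a in atoms if a.element != "H"]
    if not heavy:
        raise ValueError("no heavy atoms supplied")
    builder = StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    seen_chain = None
    seen_res = None
    for a in heavy:
        if a.chain != seen_chain:
            builder.init_chain(a.chain)
            builder.init_seg("    ")
            seen_chain = a.chain
            seen_res = None
        key = (a.chain, a.residue_index)
        if key != seen_res:
            builder.init_residue(a.residue_name, " ", a.residue_index, " ")
            seen_res = key
        builder.init_atom(
            a.name, np.asarray(a.coords, dtype=float), a.bfactor, a.occupancy,
            " ", a.name, a.serial, element=a.element.capitalize(),
        )
    structure = builder.get_structure()
    sr = ShrakeRupley(probe_radius=SASA_PROBE_RADIUS, n_points=SASA_N_POINTS)
    sr.compute(structure, level="R")
    out: dict[int, float] = {}
    for residue in structure.get_residues():
        out[residue.id[1]] = float(residue.sasa)
    return out


def compute_relative_sasa(atoms: Sequence[AtomRecord]) -> dict[int, float]:
    """Relative SASA per residue: numeric SASA / reference maximum, clipped to [0, 1].

    Raises for residue types missing from the reference table.
    """
    by_res: dict[int, str] = {}
    for a in atoms:
        by_res.setdefault(a.residue_index, a.residue_name)
    unknown = sorted(
        {f"{name} {idx}" for idx, name in by_res.items() if name not in MAX_SASA}
    )
    if unknown:
        raise ValueError(f"no reference maximum SASA for residue(s): {', '.join(unknown)}")
    raw = compute_sasa(atoms)
    return {
        idx: float(np.clip(raw.get(idx, 0.0) / MAX_SASA[by_res[idx]], 0.0, 1.0))
        for idx in by_res
    }


def tertile_classes(values: Sequence[float] | dict[int, float]) -> list[str] | dict[int, str]:
    """Split per-residue scalars into buried / moderate / exposed tertiles.

    Ranks are split into three contiguous groups whose sizes differ by at
    most one (earlier groups take the remainder); ties in value are broken by
    residue order so the assignment is deterministic.
    """
    if isinstance(values, dict):
        keys = sorted(values)
        labels = tertile_classes([values[k] for k in keys])
        return dict(zip(keys, labels))
    vals = np.asarray(list(values), dtype=float)
    n = len(vals)
    if n < 3:
        raise ValueError("need at least 3 residues for tertile classification")
    order = np.lexsort((np.arange(n), vals))  # value, then index
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    names = ["buried", "moderate", "exposed"]
    pos = 0
    for name, size in zip(names, sizes):
        labels[order[pos : pos + size]] = name
        pos += size
    return list(labels)


# ---------------------------------------------------------------------------
# Tabular artifacts (every writer has a matching reader)
# ---------------------------------------------------------------------------

def write_annotations(annotations: Iterable[ResidueAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "residue_index": a.residue_index,
                "rel_sasa": "" if a.rel_sasa is None else a.rel_sasa,
                "ss_class": a.ss_class,
                "subdomain": a.subdomain,
            }
            for a in annotations
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[ResidueAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        rel = row.get("rel_sasa")
        rel = None if (rel is None or (isinstance(rel, float) and np.isnan(rel)) or rel == "") else float(rel)
        out.append(
            ResidueAnnotation(
                residue_index=int(row["residue_index"]),
                rel_sasa=rel,
                ss_class=str(row["ss_class"]),
                subdomain=str(row["subdomain"]),
            )
        )
    return out


def validate_annotations(atoms: Sequence[AtomRecord], annotations: Sequence[ResidueAnnotation]) -> None:
    """Every residue of the structure must be annotated exactly once."""
    res = sorted({a.residue_index for a in atoms})
    ann = [a.residue_index for a in annotations]
    if sorted(ann) != res or len(set(ann)) != len(ann):
        raise ValueError("annotations must cover every residue exactly once")


def write_cp_curve(T: Sequence[float], cp: Sequence[float], path: str | Path) -> None:
    pd.DataFrame({"T_K": T, "Cp_kcal_per_mol_K": cp}).to_csv(path, sep="\t", index=False)


def read_cp_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["T_K"].to_numpy(float), df["Cp_kcal_per_mol_K"].to_numpy(float)


def write_bfactors(bfactors: dict[int, float], path: str | Path) -> None:
    pd.DataFrame(
        {"residue_index": list(bfactors), "bfactor": list(bfactors.values())}
    ).to_csv(path, sep="\t", index=False)


def read_bfactors(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["residue_index"].astype(int), df["bfactor"].astype(float)))


def write_fi_profile(fi: dict[int, float], path: str | Path) -> None:
    pd.DataFrame({"residue_index": list(fi), "FI": list(fi.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_fi_profile(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["residue_index"].astype(int), df["FI"].astype(float)))


def write_cc_matrix(cc: np.ndarray, residue_indices: Sequence[int], path: str | Path) -> None:
    idx = [str(i) for i in residue_indices]
    pd.DataFrame(np.asarray(cc, float), index=idx, columns=idx).to_csv(path, sep="\t")


def read_cc_matrix(path: str | Path) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [int(c) for c in df.columns]


def write_run_metadata(metadata: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True, default=str) + "\n")


def read_run_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Heuristic secondary-structure helper
# ---------------------------------------------------------------------------

def heuristic_ss_classes(
    atoms: Sequence[AtomRecord], hbonds: Sequence[tuple[int, int]]
) -> dict[int, str]:
    """HEURISTIC helix/strand/coil assignment from backbone H-bond patterns.

    A residue whose amide nitrogen donates to the carbonyl of residue i-4 (or
    accepts from i+4) is called helix; extended stretches (|Ca(i)-Ca(i+2)|
    > 6.4 A) are called strand; everything else coil.  This is a convenience
    labelled heuristic: production annotations should come from an annotation
    file.
    """
    res_of: dict[int, int] = {}
    ca: dict[int, np.ndarray] = {}
    for pos, a in enumerate(atoms):
        res_of[pos] = a.residue_index
        if a.name == "CA":
            ca[a.residue_index] = a.xyz
    residues = sorted({a.residue_index for a in atoms})
    labels = {r: "coil" for r in residues}
    for i, j in hbonds:
        ri, rj = res_of[i], res_of[j]
        if abs(ri - rj) == 4:
            for r in range(min(ri, rj), max(ri, rj) + 1):
                if r in labels:
                    labels[r] = "helix"
    for r in residues:
        if labels[r] != "coil":
            continue
        if r in ca and (r + 2) in ca and np.linalg.norm(ca[r] - ca[r + 2]) > 6.4:
            labels[r] = "strand"
    return labels
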