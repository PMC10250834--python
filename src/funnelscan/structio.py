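"""Structure and energy-table input/output.

Containers for docked two-protein complexes (receptor/ligand chain
partition), PDB reading/writing through biotite, Rosetta-style and TSV
energy tables, the interaction-energy arithmetic, and the structure-quality
filter used to discard low-confidence or oversized predicted structures.

Per-residue prediction confidence follows the pLDDT convention of predicted
structure databases: a 0-100 score stored in the B-factor column.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


class EnergyTableError(ValueError):
    """Raised for malformed energy tables."""


#: Backbone atom names, in the fixed order used by every interface score.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a protein residue.

    ``confidence`` carries the per-residue model confidence (pLDDT, 0-100)
    when the source file provides it in the B-factor column.
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    confidence: float | None = None
    altloc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.confidence is not None and not 0.0 <= self.confidence <= 100.0:
            raise StructureError(f"atom {self.name}: confidence {self.confidence} outside [0, 100]")


@dataclass(frozen=True)
class Residue:
    """One residue: (sequence number, insertion code, name, heavy atoms)."""

    seq_id: int
    ins_code: str
    res_name: str
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.ins_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def confidence(self) -> float | None:
        """Per-residue confidence (first atom's B-factor value)."""
        return self.atoms[0].confidence if self.atoms else None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ChainStructure:
    """An ordered protein chain."""

    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise StructureError(f"chain {self.chain_id}: empty chain")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError(f"chain {self.chain_id}: duplicate residue identifiers")

    def __len__(self) -> int:
        return len(self.residues)

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([r.coords() for r in self.residues])

    def ca_coords(self) -> np.ndarray:
        """CA trace in residue order; every residue must carry a CA atom."""
        cas = []
        for r in self.residues:
            ca = r.atom("CA")
            if ca is None:
                raise StructureError(
                    f"chain {self.chain_id}: residue {r.seq_id}{r.ins_code} has no CA atom"
                )
            cas.append(ca.coords)
        return np.array(cas, dtype=float)

    def with_coords(self, coords: np.ndarray) -> "ChainStructure":
        """Return a copy with all heavy-atom coordinates replaced (same order)."""
        coords = np.asarray(coords, dtype=float)
        out, k = [], 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(
                    AtomRecord(a.name, a.element, coords[k], a.occupancy, a.confidence, a.altloc)
                )
                k += 1
            out.append(Residue(r.seq_id, r.ins_code, r.res_name, tuple(atoms)))
        if k != len(coords):
            raise StructureError("coordinate array does not match atom count")
        return ChainStructure(self.chain_id, tuple(out))


@dataclass(frozen=True)
class ComplexStructure:
    """A docked complex with a receptor/ligand chain partition.

    ``partition`` is a pair of disjoint, non-empty chain-id tuples:
    side A (enzyme/receptor) and side B (partner/ligand).
    """

    chains: tuple[ChainStructure, ...]
    partition: tuple[tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate chain ids")
        side_a, side_b = (tuple(self.partition[0]), tuple(self.partition[1]))
        object.__setattr__(self, "partition", (side_a, side_b))
        if not side_a or not side_b:
            raise StructureError("both partition sides must be non-empty")
        if set(side_a) & set(side_b):
            raise StructureError("partition sides overlap")
        missing = (set(side_a) | set(side_b)) - set(ids)
        if missing:
            raise StructureError(f"partition names chains absent from structure: {sorted(missing)}")

    def chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def side_chains(self, side: int) -> tuple[ChainStructure, ...]:
        return tuple(self.chain(cid) for cid in self.partition[side])

    def side_heavy_coords(self, side: int) -> np.ndarray:
        return np.vstack([c.heavy_coords() for c in self.side_chains(side)])

    def partitioned_chains(self) -> tuple[ChainStructure, ...]:
        """Chains of both sides, side A first, in partition order."""
        return self.side_chains(0) + self.side_chains(1)

    def all_heavy_coords(self) -> np.ndarray:
        return np.vstack([c.heavy_coords() for c in self.partitioned_chains()])

    def n_residues(self) -> int:
        return sum(len(c) for c in self.partitioned_chains())

    def residue(self, chain_id: str, seq_id: int, ins_code: str = "") -> Residue:
        for r in self.chain(chain_id).residues:
            if r.seq_id == seq_id and r.ins_code == ins_code:
                return r
        raise KeyError((chain_id, seq_id, ins_code))


@dataclass(frozen=True)
class DecoyEnsemble:
    """Ordered docked decoys of one protein pair plus per-decoy energies."""

    decoys: tuple[tuple[str, ComplexStructure], ...]
    energies: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.decoys:
            raise StructureError("empty ensemble")
        ids = [d for d, _ in self.decoys]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate decoy ids")
        if set(ids) != set(self.energies):
            raise EnergyTableError("decoy ids and energy table ids do not match")
        ref = self.decoys[0][1]
        signature = _composition_signature(ref)
        for decoy_id, comp in self.decoys[1:]:
            if _composition_signature(comp) != signature:
                raise StructureError(f"decoy {decoy_id}: chain/residue composition differs")

    def __len__(self) -> int:
        return len(self.decoys)

    @property
    def decoy_ids(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.decoys)

    def structure(self, decoy_id: str) -> ComplexStructure:
        for d, comp in self.decoys:
            if d == decoy_id:
                return comp
        raise KeyError(decoy_id)


def _composition_signature(comp: ComplexStructure):
    return tuple(
        (c.chain_id, tuple((r.seq_id, r.ins_code, r.res_name) for r in c.residues))
        for c in comp.partitioned_chains()
    )


# ---------------------------------------------------------------------------
# PDB input/output
# ---------------------------------------------------------------------------

def read_pdb(path: str | os.PathLike, partition: Sequence[Sequence[str]]) -> ComplexStructure:
    """Read a PDB coordinate file into a :class:`ComplexStructure`.

    Hydrogens and HETATM records are dropped; for altloc duplicates the
    highest-occupancy location is kept (ties resolved to the first seen).
    Per-residue confidence is taken from the B-factor column.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(
        model=1, altloc="occupancy", extra_fields=["occupancy", "b_factor"]
    )
    atoms = atoms[~atoms.hetero]
    atoms = atoms[(atoms.element != "H") & (atoms.element != "D")]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no protein heavy atoms")

    chains: list[ChainStructure] = []
    for chain_id in _stable_unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == chain_id]
        residues: list[Residue] = []
        for start in struc.get_residue_starts(sub):
            mask = (
                (sub.res_id == sub.res_id[start])
                & (sub.ins_code == sub.ins_code[start])
            )
            res_atoms = sub[mask & (sub.chain_id == chain_id)]
            recs = tuple(
                AtomRecord(
                    name=res_atoms.atom_name[i],
                    element=res_atoms.element[i],
                    coords=res_atoms.coord[i],
                    occupancy=float(np.clip(res_atoms.occupancy[i], 0.0, 1.0)),
                    confidence=float(res_atoms.b_factor[i]),
                )
                for i in range(res_atoms.array_length())
            )
            residues.append(
                Residue(
                    seq_id=int(sub.res_id[start]),
                    ins_code=str(sub.ins_code[start]),
                    res_name=str(sub.res_name[start]),
                    atoms=recs,
                )
            )
        chains.append(ChainStructure(str(chain_id), tuple(residues)))
    return ComplexStructure(tuple(chains), (tuple(partition[0]), tuple(partition[1])))


def write_pdb(structure: ComplexStructure, path: str | os.PathLike) -> None:
    """Write a complex as fixed-width PDB ATOM records (Angstrom, 3 decimals).

    The confidence value is written to the B-factor column, so
    ``read_pdb(write_pdb(x))`` round-trips all retained fields.
    """
    n_atoms = sum(len(r.atoms) for c in structure.chains for r in c.residues)
    if n_atoms == 0:
        raise StructureError("cannot write an empty structure")
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("occupancy", float)
    arr.add_annotation("b_factor", float)
    k = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                arr.chain_id[k] = chain.chain_id
                arr.res_id[k] = res.seq_id
                arr.ins_code[k] = res.ins_code
                arr.res_name[k] = res.res_name
                arr.atom_name[k] = atom.name
                arr.element[k] = atom.element
                arr.hetero[k] = False
                arr.occupancy[k] = atom.occupancy
                arr.b_factor[k] = atom.confidence if atom.confidence is not None else 0.0
                arr.coord[k] = atom.coords
                k += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _stable_unique(values: np.ndarray) -> list:
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

def read_energy_table(
    path: str | os.PathLike, energy_column: str = "total_score"
) -> dict[str, float]:
    """Read per-decoy interaction energies (kcal/mol).

    Two dialects are accepted:

    * a TSV/CSV with columns ``decoy_id`` and ``interaction_energy``
      (header optional for plain two-column files), and
    * a Rosetta-style whitespace score table with a ``description`` id
      column, where ``energy_column`` names the energy column.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise EnergyTableError(f"{path}: no parsable rows")

    def tokens(line: str) -> list[str]:
        line = line.removeprefix("SCORE:").strip()
        if "\t" in line:
            return [t.strip() for t in line.split("\t")]
        if "," in line:
            return [t.strip() for t in line.split(",")]
        return line.split()

    header = tokens(lines[0])
    energies: dict[str, float] = {}

    if "description" in header:
        id_col = header.index("description")
        if energy_column not in header:
            raise EnergyTableError(f"{path}: energy column {energy_column!r} not in header")
        e_col = header.index(energy_column)
        rows = lines[1:]
        cols = (id_col, e_col)
    else:
        if header and _is_float(header[-1]):
            rows = lines  # header-less two-column file
        else:
            lowered = [h.lower() for h in header]
            if "decoy_id" not in lowered or "interaction_energy" not in lowered:
                raise EnergyTableError(
                    f"{path}: expected decoy_id/interaction_energy header or a "
                    "Rosetta score table with a description column"
                )
            rows = lines[1:]
        cols = None

    for ln in rows:
        parts = tokens(ln)
        if cols is not None:
            if max(cols) >= len(parts):
                raise EnergyTableError(f"{path}: malformed row: {ln!r}")
            decoy_id, raw = parts[cols[0]], parts[cols[1]]
        else:
            if len(parts) != 2:
                raise EnergyTableError(f"{path}: malformed row: {ln!r}")
            decoy_id, raw = parts
        if not _is_float(raw) or not math.isfinite(float(raw)):
            raise EnergyTableError(f"{path}: non-finite energy for {decoy_id!r}: {raw!r}")
        if decoy_id in energies:
            raise EnergyTableError(f"{path}: duplicate decoy id {decoy_id!r}")
        energies[decoy_id] = float(raw)

    if not energies:
        raise EnergyTableError(f"{path}: no parsable rows")
    return energies


def _is_float(token: str) -> bool:
    try:
        float(token.replace("−", "-"))
        return True
    except ValueError:
        return False


def write_energy_table(energies: Mapping[str, float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("decoy_id\tinteraction_energy\n")
        for decoy_id, e in energies.items():
            fh.write(f"{decoy_id}\t{e:.6f}\n")


def interaction_energy(complex_energy: float, component_energies: Iterable[float]) -> float:
    """Interaction energy: score of the complex minus the sum of the scores
    of its isolated components (kcal/mol)."""
    components = list(component_energies)
    if not components:
        raise ValueError("component energies must be non-empty")
    values = [complex_energy, *components]
    if not all(math.isfinite(v) for v in values):
        raise ValueError("non-finite energy input")
    return complex_energy - sum(components)


# ---------------------------------------------------------------------------
# Structure-quality filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SideVerdict:
    side: str
    n_residues: int
    high_confidence_fraction: float
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class QualityVerdict:
    sides: tuple[SideVerdict, SideVerdict]

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.sides)


def quality_filter(
    structure: ComplexStructure,
    confidence_cutoff: float = 90.0,
    min_fraction: float = 0.70,
    max_residues: int = 700,
) -> QualityVerdict:
    """Per-side quality screen for predicted structures.

    A side fails if the fraction of residues with confidence strictly above
    ``confidence_cutoff`` falls below ``min_fraction``, or if it has strictly
    more than ``max_residues`` residues. The complex passes only if both
    sides pass. Both inequalities on the cutoffs are strict by design.
    """
    verdicts = []
    for side_idx, side_name in ((0, "A"), (1, "B")):
        residues = [r for c in structure.side_chains(side_idx) for r in c.residues]
        n = len(residues)
        confs = [r.confidence for r in residues]
        if any(c is None for c in confs):
            raise StructureError(f"side {side_name}: missing confidence values")
        frac = float(np.mean([c > confidence_cutoff for c in confs]))
        reasons = []
        if n > max_residues:
            reasons.append(f"side {side_name}: {n} residues > {max_residues}")
        if frac < min_fraction:
            reasons.append(
                f"side {side_name}: only {frac:.1%} of residues above "
                f"confidence {confidence_cutoff:g} (< {min_fraction:.0%})"
            )
        verdicts.append(SideVerdict(side_name, n, frac, not reasons, tuple(reasons)))
    return QualityVerdict((verdicts[0], verdicts[1]))
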