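"""Positional scores of docking decoys against the strongest-interacting pose.

A docking ensemble carries no native complex, so every positional score is
measured against the decoy with the lowest interaction energy (the
"strongest interacting" reference). The scores are:

* **iRMS** — RMSD of interface-residue backbone atoms (N, CA, C, O) after
  optimal superposition of those atoms, where the interface is every residue
  with a heavy atom within 10 A of the opposite protein in the reference.
* **TM-score** — length-normalized similarity of a CA trace,
  max over superpositions of (1/L_target) * sum_i 1 / (1 + (d_i/d0)^2),
  with d0(L) = 1.24 * (L - 15)^(1/3) - 1.8 (floored at 0.5 A).
* **rTM** — harmonic mean of the per-protein TM-scores, each measured in the
  single frame that maximizes the whole-complex TM-score (per-chain
  re-superposition would trivially yield 1 for rigid decoys).
* **iTM** — TM-score restricted to interface residues, normalized by the
  interface length; **riTM** — harmonic mean of the per-side iTM-scores.

Harmonic averaging keeps one large, well-recovered protein (or interface
side) from dominating the complex score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    GeometryError,
    RigidTransform,
    kabsch_superpose,
    pairs_within,
)
from .structio import (
    BACKBONE_ATOMS,
    ComplexStructure,
    DecoyEnsemble,
    StructureError,
)

ResidueKey = tuple[str, int, str]  # (chain_id, seq number, insertion code)
AtomKey = tuple[str, int, str, str]


class InterfaceError(StructureError):
    """Raised when no usable interface exists."""


@dataclass(frozen=True)
class InterfaceDefinition:
    """Interface residues of the reference decoy, per side, plus the ordered
    backbone atom list every interface score is evaluated on."""

    residues_a: tuple[ResidueKey, ...]
    residues_b: tuple[ResidueKey, ...]
    backbone_atoms: tuple[AtomKey, ...]
    cutoff: float

    @property
    def l_interface_total(self) -> int:
        return len(self.residues_a) + len(self.residues_b)

    @property
    def l_interface_per_side(self) -> tuple[int, int]:
        return (len(self.residues_a), len(self.residues_b))

    @property
    def n_backbone(self) -> int:
        return len(self.backbone_atoms)


def select_reference(ensemble: DecoyEnsemble) -> str:
    """Id of the strongest-interacting decoy (minimum interaction energy).

    Ties resolve to the earliest decoy in ensemble order.
    """
    best_id, best_e = None, np.inf
    for decoy_id, _ in ensemble.decoys:
        e = ensemble.energies[decoy_id]
        if e < best_e:
            best_id, best_e = decoy_id, e
    assert best_id is not None
    return best_id


def _side_atoms(comp: ComplexStructure, side: int):
    """Heavy-atom coords of one side plus a per-atom residue-key index."""
    coords, res_keys = [], []
    for chain in comp.side_chains(side):
        for res in chain.residues:
            key = (chain.chain_id, res.seq_id, res.ins_code)
            for atom in res.atoms:
                coords.append(atom.coords)
                res_keys.append(key)
    return np.array(coords, dtype=float), res_keys


def detect_interface(reference: ComplexStructure, cutoff: float = 10.0) -> InterfaceDefinition:
    """Find interface residues: any heavy atom within ``cutoff`` of the other side."""
    coords_a, keys_a = _side_atoms(reference, 0)
    coords_b, keys_b = _side_atoms(reference, 1)
    hits = pairs_within(coords_a, coords_b, cutoff)
    iface_a = {keys_a[i] for i, _ in hits}
    iface_b = {keys_b[j] for _, j in hits}
    if not iface_a or not iface_b:
        raise InterfaceError(
            f"no residue pair within {cutoff:g} A; the chains are not in contact"
        )

    residues_a, residues_b, backbone = [], [], []
    for side, iface, bucket in ((0, iface_a, residues_a), (1, iface_b, residues_b)):
        for chain in reference.side_chains(side):
            for res in chain.residues:
                key = (chain.chain_id, res.seq_id, res.ins_code)
                if key not in iface:
                    continue
                bucket.append(key)
                for name in BACKBONE_ATOMS:
                    if res.atom(name) is not None:
                        backbone.append((*key, name))
    if len(backbone) < 3:
        raise InterfaceError("fewer than 3 interface backbone atoms; cannot superpose")
    return InterfaceDefinition(tuple(residues_a), tuple(residues_b), tuple(backbone), cutoff)


def _shared_backbone(
    decoy: ComplexStructure, reference: ComplexStructure, iface: InterfaceDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Paired interface-backbone coordinates, in the interface's fixed order.

    An atom missing from either structure is skipped in both, so the pairing
    stays consistent.
    """
    coords_d, coords_r = [], []
    for chain_id, seq_id, ins_code, name in iface.backbone_atoms:
        atom_d = decoy.residue(chain_id, seq_id, ins_code).atom(name)
        atom_r = reference.residue(chain_id, seq_id, ins_code).atom(name)
        if atom_d is None or atom_r is None:
            continue
        coords_d.append(atom_d.coords)
        coords_r.append(atom_r.coords)
    if len(coords_d) < 3:
        raise InterfaceError("fewer than 3 shared interface backbone atoms remain")
    return np.array(coords_d, dtype=float), np.array(coords_r, dtype=float)


def _interface_superpose(
    decoy: ComplexStructure, reference: ComplexStructure, iface: InterfaceDefinition
) -> tuple[RigidTransform, float]:
    """Superpose decoy interface backbone atoms onto the reference's."""
    coords_d, coords_r = _shared_backbone(decoy, reference, iface)
    return kabsch_superpose(coords_d, coords_r)


def irms(
    decoy: ComplexStructure, reference: ComplexStructure, iface: InterfaceDefinition
) -> float:
    """Interface RMSD (A): minimized backbone RMSD over interface residues."""
    _, rmsd = _interface_superpose(decoy, reference, iface)
    return rmsd


# ---------------------------------------------------------------------------
# TM-score family
# ---------------------------------------------------------------------------

def d0(length: int) -> float:
    """TM-score distance scale d0(L) = 1.24 (L-15)^{1/3} - 1.8, floored at 0.5 A.

    The floor covers short lengths where the printed formula turns
    non-positive (L <= 15 uses the floor directly).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _tm_value(dists: np.ndarray, d0_value: float, norm_length: int) -> float:
    return float(np.sum(1.0 / (1.0 + (dists / d0_value) ** 2)) / norm_length)


def _refine_superposition(
    model: np.ndarray,
    template: np.ndarray,
    start: RigidTransform,
    d0_value: float,
    score_fn,
    max_iter: int = 20,
):
    """Iterative TM-style refinement from a seed superposition.

    Re-superposes on the residues closer than a cutoff that shrinks from
    8 A down to max(d0, 4.5) A, until the included set is stable. Yields
    (score, transform) for every visited superposition.
    """
    floor = max(d0_value, 4.5)
    d_cut = max(8.0, floor)
    transform = start
    prev_sel = None
    for _ in range(max_iter):
        d = np.linalg.norm(transform.apply(model) - template, axis=1)
        yield score_fn(d), transform
        sel = d < d_cut
        grow = d_cut
        while sel.sum() < 3:
            grow += 0.5
            if grow > d.max() + 1.0:
                return
            sel = d < grow
        at_floor = d_cut <= floor
        if prev_sel is not None and at_floor and np.array_equal(sel, prev_sel):
            return
        prev_sel = sel
        try:
            transform, _ = kabsch_superpose(model[sel], template[sel])
        except GeometryError:
            return
        if not at_floor:
            d_cut = max(floor, d_cut - 1.0)


def _window_seeds(length: int):
    lengths = sorted({length, max(4, length // 2), max(4, length // 4)}, reverse=True)
    for wl in lengths:
        if wl > length:
            continue
        stride = max(1, wl // 2)
        starts = list(range(0, length - wl + 1, stride))
        if starts[-1] != length - wl:
            starts.append(length - wl)
        for s in starts:
            yield np.arange(s, s + wl)


@dataclass(frozen=True)
class TMResult:
    score: float
    transform: RigidTransform


def tm_score(
    model: np.ndarray, template: np.ndarray, norm_length: int | None = None
) -> TMResult:
    """TM-score of two same-protein CA traces with the identity residue mapping.

    Superpositions are seeded from sliding windows (full length, halves,
    quarters; minimum 4 residues) and refined iteratively; the maximum score
    over all visited superpositions is returned.
    """
    model = np.asarray(model, dtype=float)
    template = np.asarray(template, dtype=float)
    if model.shape != template.shape or model.ndim != 2:
        raise ValueError("model and template must be matching (n, 3) CA arrays")
    n = len(model)
    if n < 3:
        raise ValueError("TM-score needs at least 3 residues")
    norm = int(norm_length) if norm_length is not None else n
    d0_value = d0(norm)

    best_score, best_transform = -np.inf, RigidTransform.identity()
    score_fn = lambda d: _tm_value(d, d0_value, norm)  # noqa: E731
    for idx in _window_seeds(n):
        try:
            seed, _ = kabsch_superpose(model[idx], template[idx])
        except GeometryError:
            continue
        for score, transform in _refine_superposition(
            model, template, seed, d0_value, score_fn
        ):
            if score > best_score:
                best_score, best_transform = score, transform
    if not np.isfinite(best_score):
        raise GeometryError("no valid superposition seed (degenerate CA trace)")
    return TMResult(best_score, best_transform)


def _complex_ca(comp: ComplexStructure) -> np.ndarray:
    return np.vstack([c.ca_coords() for c in comp.partitioned_chains()])


def complex_tm_frame(
    decoy: ComplexStructure, reference: ComplexStructure
) -> tuple[RigidTransform, float]:
    """Common frame: the superposition maximizing the whole-complex TM-score
    of the concatenated CA trace (normalized by the total residue count)."""
    result = tm_score(_complex_ca(decoy), _complex_ca(reference), decoy.n_residues())
    return result.transform, result.score


@dataclass(frozen=True)
class RtmResult:
    rtm: float
    tm_per_chain: dict[str, float]
    complex_tm: float


def harmonic_mean(values: Sequence[float]) -> float:
    values = list(values)
    if any(v <= 0 for v in values):
        raise ValueError("harmonic mean requires strictly positive inputs")
    return len(values) / sum(1.0 / v for v in values)


def rtm_score(decoy: ComplexStructure, reference: ComplexStructure) -> RtmResult:
    """rTM: harmonic mean of per-protein TM-scores measured in the common frame.

    Distances use the complex-wide optimal frame with no per-chain
    re-superposition, so a chain that has moved relative to the complex
    scores below 1 even though its internal geometry is unchanged.
    """
    frame, complex_tm = complex_tm_frame(decoy, reference)
    per_chain: dict[str, float] = {}
    for chain_d, chain_r in zip(decoy.partitioned_chains(), reference.partitioned_chains()):
        moved = frame.apply(chain_d.ca_coords())
        d = np.linalg.norm(moved - chain_r.ca_coords(), axis=1)
        per_chain[chain_d.chain_id] = _tm_value(d, d0(len(chain_d)), len(chain_d))
    return RtmResult(harmonic_mean(list(per_chain.values())), per_chain, complex_tm)


def _interface_ca(comp: ComplexStructure, iface: InterfaceDefinition):
    """Interface-residue CA coordinates and a per-residue side mask (0=A, 1=B)."""
    coords, sides = [], []
    for side, keys in ((0, iface.residues_a), (1, iface.residues_b)):
        for chain_id, seq_id, ins_code in keys:
            ca = comp.residue(chain_id, seq_id, ins_code).atom("CA")
            if ca is None:
                raise InterfaceError(
                    f"interface residue {chain_id}{seq_id}{ins_code} has no CA atom"
                )
            coords.append(ca.coords)
            sides.append(side)
    return np.array(coords, dtype=float), np.array(sides)


@dataclass(frozen=True)
class ItmResult:
    itm_complex: float
    itm_side_a: float
    itm_side_b: float
    ritm: float


def itm_scores(
    decoy: ComplexStructure, reference: ComplexStructure, iface: InterfaceDefinition
) -> ItmResult:
    """Interface TM-scores.

    The superposition starts from the iRMS interface-backbone frame (a free
    TM search is under-determined on small interfaces) and is refined on the
    interface CA set; the frame with the highest whole-interface score is
    kept. Per-side scores are measured in that frame, each normalized by its
    own side's interface residue count; riTM is their harmonic mean.
    """
    n_a, n_b = iface.l_interface_per_side
    if n_a < 1 or n_b < 1:
        raise InterfaceError("each side needs at least one interface residue")
    ca_d, sides = _interface_ca(decoy, iface)
    ca_r, _ = _interface_ca(reference, iface)
    total = iface.l_interface_total
    d0_total = d0(total)
    base, _ = _interface_superpose(decoy, reference, iface)

    score_fn = lambda d: _tm_value(d, d0_total, total)  # noqa: E731
    best_score, best_transform = -np.inf, base
    for score, transform in _refine_superposition(ca_d, ca_r, base, d0_total, score_fn):
        if score > best_score:
            best_score, best_transform = score, transform

    d = np.linalg.norm(best_transform.apply(ca_d) - ca_r, axis=1)
    side_scores = []
    for side, count in ((0, n_a), (1, n_b)):
        side_scores.append(_tm_value(d[sides == side], d0(count), count))
    return ItmResult(
        itm_complex=best_score,
        itm_side_a=side_scores[0],
        itm_side_b=side_scores[1],
        ritm=harmonic_mean(side_scores),
    )


# ---------------------------------------------------------------------------
# Per-ensemble metrics table
# ---------------------------------------------------------------------------

@dataclass
class MetricsTable:
    """Per-decoy interaction-energy distribution of one ensemble.

    Columns: ``decoy_id, energy_kcal_mol, irms_A, tm_chain_<id>..., rtm,
    itm_complex, itm_side_a, itm_side_b, ritm`` (TM-family columns are
    absent when the table was computed positional-only).
    """

    df: pd.DataFrame
    reference_id: str
    interface: InterfaceDefinition | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_tm_scores(self) -> bool:
        return "rtm" in self.df.columns

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# reference_id={self.reference_id}\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "MetricsTable":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# reference_id="):
                raise ValueError(f"{path}: missing reference_id header line")
            reference_id = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        return cls(df=df, reference_id=reference_id)


def compute_metrics(
    ensemble: DecoyEnsemble,
    cutoff: float = 10.0,
    include_tm: bool = True,
) -> MetricsTable:
    """Full per-decoy metrics table for one ensemble.

    Selects the strongest-interacting decoy as reference, detects its
    interface, and scores every decoy against it. ``include_tm=False``
    computes the positional-only table (energy + iRMS), which is much
    cheaper and sufficient for funnel statistics.
    """
    ref_id = select_reference(ensemble)
    reference = ensemble.structure(ref_id)
    iface = detect_interface(reference, cutoff)

    chain_ids = [c.chain_id for c in reference.partitioned_chains()]
    rows = []
    for decoy_id, decoy in ensemble.decoys:
        row = {
            "decoy_id": decoy_id,
            "energy_kcal_mol": float(ensemble.energies[decoy_id]),
            "irms_A": irms(decoy, reference, iface),
        }
        if include_tm:
            rtm = rtm_score(decoy, reference)
            itm = itm_scores(decoy, reference, iface)
            for cid in chain_ids:
                row[f"tm_chain_{cid}"] = rtm.tm_per_chain[cid]
            row["rtm"] = rtm.rtm
            row["itm_complex"] = itm.itm_complex
            row["itm_side_a"] = itm.itm_side_a
            row["itm_side_b"] = itm.itm_side_b
            row["ritm"] = itm.ritm
        rows.append(row)
    return MetricsTable(df=pd.DataFrame(rows), reference_id=ref_id, interface=iface)
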