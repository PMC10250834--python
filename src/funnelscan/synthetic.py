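"""Seeded synthetic docking-decoy ensembles.

Stands in for rigid-body docking output in every test and benchmark: two
self-avoiding toy chains are placed in contact ~1,000 times, either as a
funnel-shaped ensemble (a fraction of poses cluster around one native
orientation and receive energies that deepen toward it) or as a scattered
one (uniform orientations, zero-mean noise energies). The joint
(energy, iRMS) law of the generator is the qualitative phenomenon under
study — a narrow energy funnel at low iRMS for specific partners versus a
flat cloud for random pairs — not a physical force field.

All randomness flows from one seeded generator per ensemble, so every
artifact is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, min_interchain_distance
from .scores import compute_metrics, detect_interface, irms
from .structio import (
    AtomRecord,
    ChainStructure,
    ComplexStructure,
    DecoyEnsemble,
    Residue,
    write_energy_table,
    write_pdb,
)


class GenerationError(RuntimeError):
    """Raised when a synthetic construction fails its geometric contract."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one simulated docking ensemble.

    Defaults emulate a rigid-body docking run of a specific interaction:
    1,000 poses of which 15% fall in the native funnel, a 20 kcal/mol
    funnel depth relaxing at 1 kcal/mol per A of iRMS, 2 kcal/mol energy
    noise, and chains kept in contact at a 4.5 A heavy-atom gap.
    """

    mode: str = "funnel"            # "funnel" | "scattered" | "broad"
    n_decoys: int = 1000
    chain_lengths: tuple[int, int] = (30, 30)
    funnel_fraction: float = 0.15   # fraction of near-native poses
    rot_sigma: float = 10.0         # degrees, half-normal orientation jitter
    trans_sigma: float = 2.0        # A, lateral contact-point jitter
    depth: float = 20.0             # kcal/mol, funnel depth at iRMS 0
    slope: float = 1.0              # kcal/mol per A of iRMS
    noise_sigma: float = 2.0        # kcal/mol, energy noise
    contact_gap: float = 4.5        # A, heavy-atom contact distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("funnel", "scattered", "broad"):
            raise ValueError("mode must be 'funnel', 'scattered' or 'broad'")
        if not 0.0 <= self.funnel_fraction <= 1.0:
            raise ValueError("funnel_fraction must be in [0, 1]")
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        if self.contact_gap <= 0:
            raise ValueError("contact_gap must be positive")


#: Idealized backbone offsets from each CA (global frame), Angstrom.
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, -0.80, 0.45]),
    "C": np.array([1.25, 0.70, -0.40]),
    "O": np.array([2.10, 1.55, -0.45]),
}
_DEFAULT_CONFIDENCE = 95.0

_CA_STEP = 3.8          # consecutive CA-CA distance, A
_MIN_NONADJ = 4.0       # minimum non-consecutive CA-CA distance, A


def make_toy_chain(
    n_residues: int, seed: int, chain_id: str = "A", max_restarts: int = 50
) -> ChainStructure:
    """Self-avoiding persistent random CA walk with idealized N/C/O atoms.

    Consecutive CA-CA distances are exactly 3.8 A; no two non-consecutive
    CA atoms come closer than 4.0 A.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        cas = _try_walk(n_residues, rng)
        if cas is not None:
            return _chain_from_cas(cas, chain_id)
    raise GenerationError(f"self-avoiding walk failed after {max_restarts} restarts")


def _try_walk(n: int, rng: np.random.Generator) -> np.ndarray | None:
    cas = np.zeros((n, 3))
    direction = _unit(rng.normal(size=3))
    cas[1] = cas[0] + _CA_STEP * direction
    for i in range(2, n):
        for _ in range(100):
            cand_dir = _unit(0.8 * direction + 0.6 * _unit(rng.normal(size=3)))
            cand = cas[i - 1] + _CA_STEP * cand_dir
            d = np.linalg.norm(cas[: i - 1] - cand, axis=1)
            if np.all(d >= _MIN_NONADJ):
                cas[i] = cand
                direction = cand_dir
                break
        else:
            return None
    return cas


def _chain_from_cas(cas: np.ndarray, chain_id: str) -> ChainStructure:
    residues = []
    for i, ca in enumerate(cas):
        atoms = [AtomRecord("N", "N", ca + _BACKBONE_OFFSETS["N"], 1.0, _DEFAULT_CONFIDENCE)]
        atoms.append(AtomRecord("CA", "C", ca, 1.0, _DEFAULT_CONFIDENCE))
        atoms.append(AtomRecord("C", "C", ca + _BACKBONE_OFFSETS["C"], 1.0, _DEFAULT_CONFIDENCE))
        atoms.append(AtomRecord("O", "O", ca + _BACKBONE_OFFSETS["O"], 1.0, _DEFAULT_CONFIDENCE))
        residues.append(Residue(i + 1, "", "ALA", tuple(atoms)))
    return ChainStructure(chain_id, tuple(residues))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GenerationError("zero-length direction")
    return v / n


def random_rotation(rng: np.random.Generator) -> RigidTransform:
    """Uniform random rotation via normalized 4-vector quaternion sampling."""
    q = _unit(rng.normal(size=4))
    return RigidTransform(Rotation.from_quat(q).as_matrix(), np.zeros(3))


def small_rotation(rng: np.random.Generator, sigma_deg: float) -> RigidTransform:
    """Rotation by a half-normal(sigma) angle about a uniform random axis."""
    angle = abs(rng.normal(0.0, math.radians(sigma_deg)))
    axis = _unit(rng.normal(size=3))
    return RigidTransform(Rotation.from_rotvec(angle * axis).as_matrix(), np.zeros(3))


def sample_contact_pose(
    receptor: ChainStructure,
    ligand: ChainStructure,
    rotation: RigidTransform,
    direction: np.ndarray,
    gap: float = 4.5,
    tol: float = 0.05,
) -> ComplexStructure:
    """Place the rotated ligand in contact with the receptor.

    The ligand is rotated about its centroid, then slid along ``direction``
    (from the receptor centroid) by bisection until the minimum inter-chain
    heavy-atom distance equals ``gap`` within ``tol``.
    """
    direction = _unit(np.asarray(direction, dtype=float))
    rec_coords = receptor.heavy_coords()
    lig_coords = ligand.heavy_coords()
    lig_centered = (lig_coords - lig_coords.mean(axis=0)) @ rotation.rotation.T
    rec_center = rec_coords.mean(axis=0)

    def min_dist(t: float) -> float:
        return min_interchain_distance(rec_coords, lig_centered + rec_center + t * direction)

    r_rec = float(np.max(np.linalg.norm(rec_coords - rec_center, axis=1)))
    r_lig = float(np.max(np.linalg.norm(lig_centered, axis=1)))
    t_low, t_high = 0.0, r_rec + r_lig + gap + 5.0
    f_low = min_dist(t_low) - gap
    if f_low > 0:
        # Sparse chains can interleave without touching at zero offset;
        # scan the slide axis for any below-gap placement.
        ts = np.linspace(-t_high, t_high, 81)
        fs = np.array([min_dist(t) - gap for t in ts])
        if fs.min() > 0:
            raise GenerationError("no contact below the gap along this direction")
        t_low = float(ts[np.argmin(fs)])
        f_low = float(fs.min())
    for _ in range(80):
        t_mid = 0.5 * (t_low + t_high)
        f_mid = min_dist(t_mid) - gap
        if abs(f_mid) <= tol:
            t_low = t_high = t_mid
            break
        if f_mid < 0:
            t_low = t_mid
        else:
            t_high = t_mid
    t_final = 0.5 * (t_low + t_high)
    if abs(min_dist(t_final) - gap) > 0.1:
        raise GenerationError("contact slide did not converge")
    placed = lig_centered + rec_center + t_final * direction
    lig_chain = ligand.with_coords(placed)
    return ComplexStructure(
        (receptor, lig_chain), ((receptor.chain_id,), (ligand.chain_id,))
    )


def generate_ensemble(spec: SyntheticSpec) -> tuple[DecoyEnsemble, ComplexStructure]:
    """One seeded decoy ensemble plus the underlying native pose.

    Funnel mode fixes a native contact pose; ``ceil(funnel_fraction * n)``
    decoys perturb it (half-normal rotation jitter, lateral contact-point
    jitter) and receive energies ``-depth + slope * iRMS + N(0, noise)``
    where iRMS is measured post hoc against the native pose. The remaining
    decoys are uniform-orientation contact poses with ``N(0, noise)``
    energies. Scattered mode generates only the latter.

    Broad mode emulates a broad funnel-like landscape — strong interaction
    energies at scattered interacting positions, the archetypal confusable
    non-interactor. Energies are produced by the exact funnel-mode pipeline
    (a hidden native pose, jittered poses, post-hoc iRMS), so their marginal
    law matches funnel mode decoy for decoy, but every stored pose is an
    independent uniform-orientation contact pose: the energy-position
    coupling is severed while the energy distribution is preserved.
    """
    rng = np.random.default_rng(spec.seed)
    seed_rec, seed_lig = rng.integers(2**31, size=2)
    receptor = make_toy_chain(spec.chain_lengths[0], int(seed_rec), "A")
    ligand = make_toy_chain(spec.chain_lengths[1], int(seed_lig), "B")

    n_funnel = (
        math.ceil(spec.funnel_fraction * spec.n_decoys)
        if spec.mode in ("funnel", "broad")
        else 0
    )
    decoys: list[tuple[str, ComplexStructure]] = []
    energies: dict[str, float] = {}

    native = None
    for _ in range(20):  # redraw on unreachable contact directions
        native_rot = random_rotation(rng)
        native_dir = _unit(rng.normal(size=3))
        try:
            native = sample_contact_pose(
                receptor, ligand, native_rot, native_dir, spec.contact_gap
            )
            break
        except GenerationError:
            continue
    if native is None:
        raise GenerationError("could not place the native contact pose")
    if n_funnel:
        native_iface = detect_interface(native)
        contact_arm = float(
            np.linalg.norm(
                native.chain("B").heavy_coords().mean(axis=0)
                - native.chain("A").heavy_coords().mean(axis=0)
            )
        )
    for k in range(spec.n_decoys):
        decoy_id = f"decoy_{k + 1:04d}"
        pose = None
        for _ in range(20):  # redraw on unreachable contact directions
            try:
                if k < n_funnel:
                    jitter = small_rotation(rng, spec.rot_sigma)
                    rot = RigidTransform(jitter.rotation @ native_rot.rotation, np.zeros(3))
                    direction = _unit(
                        native_dir + rng.normal(0.0, spec.trans_sigma / contact_arm, size=3)
                    )
                else:
                    rot = random_rotation(rng)
                    direction = _unit(rng.normal(size=3))
                pose = sample_contact_pose(receptor, ligand, rot, direction, spec.contact_gap)
                break
            except GenerationError:
                continue
        if pose is None:
            raise GenerationError(f"could not place decoy {decoy_id}")
        if k < n_funnel:
            displacement = irms(pose, native, native_iface)
            energy = -spec.depth + spec.slope * displacement + rng.normal(0.0, spec.noise_sigma)
            if spec.mode == "broad":
                # Keep the funnel-law energy, discard the funnel pose.
                pose = _scatter_pose(receptor, ligand, spec, rng)
        else:
            energy = rng.normal(0.0, spec.noise_sigma)
        decoys.append((decoy_id, pose))
        energies[decoy_id] = float(energy)
    return DecoyEnsemble(tuple(decoys), energies), native


def _scatter_pose(receptor, ligand, spec: SyntheticSpec, rng) -> ComplexStructure:
    for _ in range(20):
        try:
            return sample_contact_pose(
                receptor, ligand, random_rotation(rng), _unit(rng.normal(size=3)),
                spec.contact_gap,
            )
        except GenerationError:
            continue
    raise GenerationError("could not place a scattered pose")


#: Per-ensemble parameter ranges used when simulating a labeled dataset.
DEFAULT_PARAM_RANGES = {
    "funnel_fraction": (0.10, 0.20),
    "depth": (15.0, 25.0),
    "rot_sigma": (5.0, 15.0),
}


def _draw_specs(
    n_pos: int,
    n_neg: int,
    base: SyntheticSpec,
    param_ranges: dict | None,
    master_seed: int,
    negative_mode: str = "scattered",
) -> list[tuple[str, str, SyntheticSpec]]:
    ranges = DEFAULT_PARAM_RANGES if param_ranges is None else param_ranges
    rng = np.random.default_rng(master_seed)
    out = []
    for label, count, mode in (("positive", n_pos, "funnel"), ("negative", n_neg, negative_mode)):
        for i in range(count):
            overrides = {
                key: float(rng.uniform(lo, hi)) for key, (lo, hi) in sorted(ranges.items())
            }
            seed = int(rng.integers(2**31))
            spec = replace(base, mode=mode, seed=seed, **overrides)
            out.append((f"{label[:3]}_{i + 1:03d}", label, spec))
    return out


def generate_dataset(
    n_pos: int,
    n_neg: int,
    out_dir: str | os.PathLike,
    base_spec: SyntheticSpec | None = None,
    param_ranges: dict | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Write a labeled on-disk dataset of decoy ensembles.

    Layout: ``<pair_id>/decoy_<k>.pdb`` + ``<pair_id>/energies.tsv`` per
    ensemble and a top-level ``manifest.tsv`` (pair_id, label, path),
    directly consumable by the analyze/screen commands. Fully reproducible
    from ``master_seed``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one ensemble per label")
    base = base_spec if base_spec is not None else SyntheticSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair_id, label, spec in _draw_specs(n_pos, n_neg, base, param_ranges, master_seed):
        pair_dir = out_dir / pair_id
        pair_dir.mkdir(exist_ok=True)
        ensemble, _ = generate_ensemble(spec)
        for decoy_id, comp in ensemble.decoys:
            write_pdb(comp, pair_dir / f"{decoy_id}.pdb")
        write_energy_table(ensemble.energies, pair_dir / "energies.tsv")
        rows.append({"pair_id": pair_id, "label": label, "path": pair_id})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def simulate_metrics_tables(
    n_pos: int,
    n_neg: int,
    base_spec: SyntheticSpec | None = None,
    param_ranges: dict | None = None,
    master_seed: int = 0,
    include_tm: bool = False,
    negative_mode: str = "scattered",
):
    """In-memory benchmark: generate ensembles and score them directly.

    Returns (metrics tables, labels) without touching disk; the workhorse
    behind the classifier and funnel-screen benchmarks.
    """
    base = base_spec if base_spec is not None else SyntheticSpec()
    tables, labels = [], []
    for _, label, spec in _draw_specs(
        n_pos, n_neg, base, param_ranges, master_seed, negative_mode
    ):
        ensemble, _ = generate_ensemble(spec)
        tables.append(compute_metrics(ensemble, include_tm=include_tm))
        labels.append(label)
    return tables, labels


def weak_funnel_spec(base: SyntheticSpec | None = None) -> SyntheticSpec:
    """Base conditions of the weak-funnel benchmark (funnel depth reduced
    from 20 to 8 kcal/mol, emulating weak transient interactions)."""
    base = base if base is not None else SyntheticSpec()
    return replace(base, depth=8.0)


def weak_funnel_benchmark(
    n_pos: int,
    n_neg: int,
    base_spec: SyntheticSpec | None = None,
    master_seed: int = 0,
):
    """Benchmark where the energy column alone is uninformative.

    Positives are reduced-depth funnel ensembles; negatives are broad
    ensembles whose energies follow the identical marginal law but whose
    poses are scattered. Only the energy-position coupling separates the
    classes, so a classifier fed energies alone sits near chance while one
    that also sees iRMS can exploit the coupling.

    Returns (metrics tables, labels).
    """
    base = weak_funnel_spec(base_spec)
    return simulate_metrics_tables(
        n_pos, n_neg, base, param_ranges={}, master_seed=master_seed,
        negative_mode="broad",
    )
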