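"""Shared fixtures: small deterministic structures and the session-scoped
synthetic benchmarks every statistical test draws from."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from funnelscan.scores import MetricsTable
from funnelscan.structio import AtomRecord, ChainStructure, ComplexStructure, Residue
from funnelscan.synthetic import (
    SyntheticSpec,
    generate_ensemble,
    make_toy_chain,
    sample_contact_pose,
    simulate_metrics_tables,
    weak_funnel_benchmark,
)


def line_chain(n: int, chain_id: str = "A", confidence: float = 95.0,
               offset=(0.0, 0.0, 0.0)) -> ChainStructure:
    """Straight CA trace with full backbone; cheap deterministic scaffold."""
    offsets = {"N": np.array([-1.2, -0.8, 0.45]), "CA": np.zeros(3),
               "C": np.array([1.25, 0.7, -0.4]), "O": np.array([2.1, 1.55, -0.45])}
    residues = []
    for i in range(n):
        ca = np.array([3.8 * i, 0.0, 0.0]) + np.asarray(offset, dtype=float)
        atoms = tuple(
            AtomRecord(name, "C" if name in ("CA", "C") else name, ca + off, 1.0, confidence)
            for name, off in offsets.items()
        )
        residues.append(Residue(i + 1, "", "ALA", atoms))
    return ChainStructure(chain_id, tuple(residues))


def two_chain_complex(sep: float = 6.0, n: int = 6) -> ComplexStructure:
    """Two parallel straight chains ``sep`` Angstrom apart in y."""
    a = line_chain(n, "A")
    b = line_chain(n, "B", offset=(0.0, sep, 0.0))
    return ComplexStructure((a, b), (("A",), ("B",)))


def metrics_from_values(energies, irms_values) -> MetricsTable:
    """Metrics table straight from raw value lists (no structures involved)."""
    energies = np.asarray(energies, dtype=float)
    irms_values = np.asarray(irms_values, dtype=float)
    ids = [f"d{i + 1}" for i in range(len(energies))]
    df = pd.DataFrame(
        {"decoy_id": ids, "energy_kcal_mol": energies, "irms_A": irms_values}
    )
    return MetricsTable(df=df, reference_id=ids[int(np.argmin(energies))])


@pytest.fixture(scope="session")
def contact_complex():
    """A random-walk two-chain complex in contact (seeded)."""
    rec = make_toy_chain(12, seed=11, chain_id="A")
    lig = make_toy_chain(12, seed=12, chain_id="B")
    from funnelscan.geometry import RigidTransform

    return sample_contact_pose(rec, lig, RigidTransform.identity(), (1.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def small_funnel_ensemble():
    """12-decoy funnel ensemble, small chains; used for score identities."""
    spec = SyntheticSpec(n_decoys=12, chain_lengths=(12, 12), seed=3)
    ensemble, native = generate_ensemble(spec)
    return ensemble


@pytest.fixture(scope="session")
def funnel_scatter_benchmark():
    """20 funnel + 20 scattered ensembles of 200 decoys, matched design.

    Each funnel/scattered pair shares a seed (identical chain geometry), so
    group comparisons measure the funnel effect rather than nuisance
    chain-shape spread; parameters are held at the generator defaults.
    """
    from funnelscan.scores import compute_metrics
    from funnelscan.synthetic import generate_ensemble

    tables, labels = [], []
    for i in range(20):
        for mode, label in (("funnel", "positive"), ("scattered", "negative")):
            spec = SyntheticSpec(
                mode=mode, n_decoys=200, chain_lengths=(20, 20), seed=1000 + i
            )
            ensemble, _ = generate_ensemble(spec)
            tables.append(compute_metrics(ensemble, include_tm=False))
            labels.append(label)
    return tables, labels


@pytest.fixture(scope="session")
def separable_benchmark():
    """50 funnel + 50 scattered ensembles of 150 decoys for classifier tests."""
    base = SyntheticSpec(n_decoys=150, chain_lengths=(14, 14))
    tables, labels = simulate_metrics_tables(
        50, 50, base, param_ranges={}, master_seed=202, include_tm=False
    )
    return tables, labels


@pytest.fixture(scope="session")
def weak_benchmark():
    """Weak-funnel benchmark: energy marginals matched, coupling only in pose."""
    base = SyntheticSpec(n_decoys=150, chain_lengths=(14, 14))
    return weak_funnel_benchmark(20, 20, base, master_seed=303)
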