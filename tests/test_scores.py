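"""Interface detection, iRMS and the TM-score family."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from funnelscan.geometry import RigidTransform, horn_superpose
from funnelscan.scores import (
    InterfaceError,
    MetricsTable,
    _tm_value,
    complex_tm_frame,
    compute_metrics,
    d0,
    detect_interface,
    harmonic_mean,
    irms,
    itm_scores,
    rtm_score,
    select_reference,
    tm_score,
)
from funnelscan.structio import ComplexStructure, DecoyEnsemble
from funnelscan.synthetic import make_toy_chain, sample_contact_pose

from conftest import line_chain, two_chain_complex


def rigidly_moved(comp: ComplexStructure, seed: int = 0) -> ComplexStructure:
    """Whole-complex rigid motion (same transform for every chain)."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    t = RigidTransform(
        Rotation.from_quat(q / np.linalg.norm(q)).as_matrix(), rng.normal(scale=8.0, size=3)
    )
    chains = tuple(c.with_coords(t.apply(c.heavy_coords())) for c in comp.chains)
    return ComplexStructure(chains, comp.partition)


class TestSelectReference:
    def _ensemble(self, energies):
        comp = two_chain_complex()
        return DecoyEnsemble(
            tuple((k, comp) for k in energies), dict(energies)
        )

    def test_minimum_energy_wins(self):
        ens = self._ensemble({"d1": -3.0, "d2": -7.0, "d3": 0.0})
        assert select_reference(ens) == "d2"

    def test_tie_goes_to_earliest(self):
        ens = self._ensemble({"d1": -7.0, "d2": -7.0})
        assert select_reference(ens) == "d1"

    def test_all_positive_energies_still_have_a_minimum(self):
        # FFT-docking ensembles with only unfavorable energies are analyzed too.
        ens = self._ensemble({"d1": 4.0, "d2": 2.5, "d3": 9.0})
        assert select_reference(ens) == "d2"


class TestDetectInterface:
    def test_cutoff_includes_pair_just_inside(self):
        comp = two_chain_complex(sep=9.9, n=1)
        # single residues: backbone atoms 8 >= 3
        iface = detect_interface(comp, cutoff=10.0)
        assert iface.l_interface_per_side == (1, 1)

    def test_separated_chains_have_no_interface(self):
        comp = two_chain_complex(sep=40.0, n=4)
        with pytest.raises(InterfaceError):
            detect_interface(comp, cutoff=10.0)

    def test_matches_brute_force_all_pairs(self, contact_complex):
        iface = detect_interface(contact_complex, cutoff=10.0)
        expected_a, expected_b = set(), set()
        a_res = [(c.chain_id, r) for c in contact_complex.side_chains(0) for r in c.residues]
        b_res = [(c.chain_id, r) for c in contact_complex.side_chains(1) for r in c.residues]
        for cid_a, ra in a_res:
            for cid_b, rb in b_res:
                dmin = min(
                    np.linalg.norm(x.coords - y.coords) for x in ra.atoms for y in rb.atoms
                )
                if dmin <= 10.0:
                    expected_a.add((cid_a, ra.seq_id, ra.ins_code))
                    expected_b.add((cid_b, rb.seq_id, rb.ins_code))
        assert set(iface.residues_a) == expected_a
        assert set(iface.residues_b) == expected_b
        assert iface.l_interface_total == len(expected_a) + len(expected_b)


class TestIrms:
    def test_self_comparison_is_zero(self, contact_complex):
        iface = detect_interface(contact_complex)
        assert irms(contact_complex, contact_complex, iface) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_of_whole_complex_is_removed(self, contact_complex):
        iface = detect_interface(contact_complex)
        moved = rigidly_moved(contact_complex, seed=5)
        assert irms(moved, contact_complex, iface) == pytest.approx(0.0, abs=1e-7)

    def test_displaced_ligand_matches_quaternion_oracle(self, contact_complex):
        iface = detect_interface(contact_complex)
        chains = []
        for c in contact_complex.chains:
            coords = c.heavy_coords()
            if c.chain_id == "B":
                coords = coords + np.array([3.0, 0.0, 0.0])
            chains.append(c.with_coords(coords))
        decoy = ComplexStructure(tuple(chains), contact_complex.partition)

        from funnelscan.scores import _shared_backbone

        coords_d, coords_r = _shared_backbone(decoy, contact_complex, iface)
        _, oracle = horn_superpose(coords_d, coords_r)
        assert irms(decoy, contact_complex, iface) == pytest.approx(oracle, abs=1e-6)
        assert irms(decoy, contact_complex, iface) > 0.5


class TestD0:
    def test_printed_formula_at_153(self):
        assert d0(153) == pytest.approx(1.24 * 138 ** (1 / 3) - 1.8, abs=1e-12)
        assert d0(153) == pytest.approx(4.6079, abs=1e-3)

    def test_small_lengths_hit_floor(self):
        # 1.24 * 1 - 1.8 = -0.56 -> floored
        assert d0(16) == 0.5
        assert d0(15) == 0.5
        assert d0(1) == 0.5

    def test_monotone_beyond_floor(self):
        values = [d0(length) for length in range(16, 400)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestTmScore:
    def test_self_comparison_is_one(self):
        ca = make_toy_chain(20, seed=2).ca_coords()
        assert tm_score(ca, ca).score == pytest.approx(1.0)

    def test_all_residues_at_d0_scores_half(self):
        # The score kernel forces 1/(1+1) when every aligned distance is d0.
        n = 40
        dists = np.full(n, d0(n))
        assert _tm_value(dists, d0(n), n) == pytest.approx(0.5)

    def test_iterative_search_beats_single_superposition_with_outliers(self):
        from funnelscan.geometry import kabsch_superpose

        ca = make_toy_chain(30, seed=9).ca_coords()
        damaged = ca.copy()
        damaged[10:13] += 20.0  # 3 residues thrown 20 A off
        t, _ = kabsch_superpose(damaged, ca)
        naive = _tm_value(np.linalg.norm(t.apply(damaged) - ca, axis=1), d0(30), 30)
        result = tm_score(damaged, ca, 30)
        assert result.score > naive

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            tm_score(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_score_kernel_decreases_with_any_distance(self):
        rng = np.random.default_rng(0)
        dists = rng.uniform(0, 10, size=25)
        base = _tm_value(dists, d0(25), 25)
        for i in range(25):
            bumped = dists.copy()
            bumped[i] += 1.0
            assert _tm_value(bumped, d0(25), 25) < base


class TestComplexFrameAndRtm:
    def test_self_frame_is_identity(self, contact_complex):
        frame, score = complex_tm_frame(contact_complex, contact_complex)
        assert score == pytest.approx(1.0)
        assert np.allclose(frame.rotation, np.eye(3), atol=1e-6)

    def test_rigid_motion_recovered(self, contact_complex):
        moved = rigidly_moved(contact_complex, seed=8)
        frame, score = complex_tm_frame(moved, contact_complex)
        assert score == pytest.approx(1.0, abs=1e-9)
        recovered = frame.apply(np.vstack([c.ca_coords() for c in moved.partitioned_chains()]))
        original = np.vstack([c.ca_coords() for c in contact_complex.partitioned_chains()])
        assert np.allclose(recovered, original, atol=1e-6)

    def test_rtm_self_is_one(self, contact_complex):
        assert rtm_score(contact_complex, contact_complex).rtm == pytest.approx(1.0)

    def test_harmonic_mean_identities(self):
        assert harmonic_mean([1.0, 1.0 / 3.0]) == pytest.approx(0.5)
        for s in (0.17, 0.5, 0.93):
            assert harmonic_mean([s, s, s]) == pytest.approx(s)

    def test_harmonic_between_min_and_max_and_below_arithmetic(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            vals = rng.uniform(0.05, 1.0, size=rng.integers(2, 5))
            h = harmonic_mean(vals)
            assert min(vals) - 1e-12 <= h <= max(vals) + 1e-12
            assert h <= np.mean(vals) + 1e-12

    def test_per_chain_tm_decreases_along_displacement_ramp(self, contact_complex):
        scores = []
        for shift in (0.0, 1.0, 2.0, 4.0, 8.0):
            chains = []
            for c in contact_complex.chains:
                coords = c.heavy_coords()
                if c.chain_id == "B":
                    coords = coords + np.array([0.0, 0.0, shift])
                chains.append(c.with_coords(coords))
            decoy = ComplexStructure(tuple(chains), contact_complex.partition)
            scores.append(rtm_score(decoy, contact_complex).tm_per_chain["B"])
        assert all(b <= a + 1e-9 for a, b in zip(scores, scores[1:]))
        assert scores[-1] < scores[0]


class TestItm:
    def test_self_comparison_is_one(self, contact_complex):
        iface = detect_interface(contact_complex)
        result = itm_scores(contact_complex, contact_complex, iface)
        assert result.itm_complex == pytest.approx(1.0)
        assert result.ritm == pytest.approx(1.0)

    def test_ritm_dragged_toward_worse_side(self, small_funnel_ensemble):
        table = compute_metrics(small_funnel_ensemble, include_tm=True)
        df = table.df[table.df.decoy_id != table.reference_id]
        worse = np.minimum(df.itm_side_a, df.itm_side_b)
        better = np.maximum(df.itm_side_a, df.itm_side_b)
        assert (df.ritm <= better + 1e-9).all()
        assert (df.ritm >= worse - 1e-9).all()
        # harmonic mean sits below the arithmetic midpoint
        assert (df.ritm <= (df.itm_side_a + df.itm_side_b) / 2 + 1e-9).all()


class TestComputeMetrics:
    def test_reference_row_is_exact(self, small_funnel_ensemble):
        table = compute_metrics(small_funnel_ensemble, include_tm=True)
        row = table.df[table.df.decoy_id == table.reference_id].iloc[0]
        assert row.irms_A == pytest.approx(0.0, abs=1e-9)
        for col in ("rtm", "itm_complex", "itm_side_a", "itm_side_b", "ritm"):
            assert row[col] == pytest.approx(1.0, abs=1e-9)

    def test_all_scores_in_unit_interval(self, small_funnel_ensemble):
        df = compute_metrics(small_funnel_ensemble, include_tm=True).df
        for col in ("rtm", "itm_complex", "itm_side_a", "itm_side_b", "ritm"):
            assert (df[col] > 0).all()
            assert (df[col] <= 1.0 + 1e-12).all()
        assert (df.irms_A >= 0).all()

    def test_input_order_does_not_matter(self, small_funnel_ensemble):
        table = compute_metrics(small_funnel_ensemble, include_tm=False)
        shuffled = DecoyEnsemble(
            tuple(reversed(small_funnel_ensemble.decoys)), small_funnel_ensemble.energies
        )
        table2 = compute_metrics(shuffled, include_tm=False)
        merged = table.df.set_index("decoy_id").join(
            table2.df.set_index("decoy_id"), rsuffix="_2"
        )
        assert np.allclose(merged.irms_A, merged.irms_A_2, atol=1e-9)
        assert table.reference_id == table2.reference_id

    def test_tsv_round_trip_and_byte_stability(self, small_funnel_ensemble, tmp_path):
        table = compute_metrics(small_funnel_ensemble, include_tm=True)
        p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        table.to_tsv(p1)
        compute_metrics(small_funnel_ensemble, include_tm=True).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = MetricsTable.from_tsv(p1)
        assert back.reference_id == table.reference_id
        assert np.allclose(back.df.irms_A, table.df.irms_A, atol=1e-6)
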