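"""Cα-trace I/O, synCP algebra, and the synthetic generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpsearch import structio
from cpsearch.cpalign import kabsch

from conftest import random_trace


def _write_pdb(path, ca_lines):
    path.write_text("".join(ca_lines) + "TER\nEND\n")


def _ca_line(serial, resseq, x, y, z, name="CA", altloc=" ", occ=1.00):
    return (
        f"ATOM  {serial:>5d}  {name:<3s}{altloc}GLY A{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           C\n"
    )


class TestReadCaTrace:
    def test_too_few_residues_is_an_error(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        _write_pdb(p, [_ca_line(i + 1, i + 1, 3.8 * i, 0, 0) for i in range(4)])
        with pytest.raises(ValueError, match="[Cc]α|residues|need"):
            structio.read_ca_trace(p)

    def test_reads_coords_in_file_order(self, tmp_path):
        p = tmp_path / "six.pdb"
        xs = [0.0, 3.8, 7.6, 11.4, 15.2, 19.0]
        _write_pdb(p, [_ca_line(i + 1, i + 1, x, 1.0, 2.0) for i, x in enumerate(xs)])
        trace = structio.read_ca_trace(p)
        assert len(trace) == 6
        np.testing.assert_allclose(trace.coords[:, 0], xs, atol=1e-3)

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        lines = [_ca_line(i + 1, i + 1, 3.8 * i, 0, 0) for i in range(2)]
        # residue 3 with two altlocs; B has higher occupancy and must win
        lines.append(_ca_line(3, 3, 7.6, 0, 0, altloc="A", occ=0.3))
        lines.append(_ca_line(4, 3, 7.6, 5.0, 0, altloc="B", occ=0.7))
        lines += [_ca_line(5 + i, 4 + i, 11.4 + 3.8 * i, 0, 0) for i in range(3)]
        _write_pdb(p, lines)
        trace = structio.read_ca_trace(p)
        assert len(trace) == 6
        assert trace.coords[2, 1] == pytest.approx(5.0, abs=1e-3)

    def test_residues_without_ca_are_skipped(self, tmp_path):
        p = tmp_path / "gappy.pdb"
        lines = [_ca_line(i + 1, i + 1, 3.8 * i, 0, 0) for i in range(5)]
        lines.insert(2, _ca_line(99, 99, 1.0, 1.0, 1.0, name="CB"))
        _write_pdb(p, lines)
        assert len(structio.read_ca_trace(p)) == 5


class TestWriteCaTrace:
    def test_roundtrip_preserves_coords_to_pdb_precision(self, tmp_path):
        trace = random_trace(np.random.default_rng(0), 37)
        structio.write_ca_trace(trace, tmp_path / "t.pdb")
        back = structio.read_ca_trace(tmp_path / "t.pdb")
        np.testing.assert_allclose(back.coords, trace.coords, atol=1e-3)

    def test_writes_one_atom_record_per_residue(self, tmp_path):
        trace = random_trace(np.random.default_rng(1), 100)
        structio.write_ca_trace(trace, tmp_path / "t.pdb")
        text = (tmp_path / "t.pdb").read_text()
        assert sum(1 for line in text.splitlines() if line.startswith("ATOM")) == 100

    def test_field_overflow_is_an_error(self, tmp_path):
        trace = random_trace(np.random.default_rng(2), 10)
        big = structio.CaTrace(id="big", coords=trace.coords + 10000.0)
        with pytest.raises(ValueError, match="overflow"):
            structio.write_ca_trace(big, tmp_path / "big.pdb")


class TestSynCP:
    def test_matches_cyclic_reordering_definition(self):
        trace = random_trace(np.random.default_rng(3), 5)
        child = structio.syncp(trace, 1).child
        expected = trace.coords[[1, 2, 3, 4, 0]]
        np.testing.assert_array_equal(child.coords, expected)

    def test_k_zero_is_identity(self):
        trace = random_trace(np.random.default_rng(4), 9)
        np.testing.assert_array_equal(structio.syncp(trace, 0).child.coords, trace.coords)

    def test_out_of_range_k_rejected(self):
        trace = random_trace(np.random.default_rng(5), 8)
        for k in (-1, 8, 12):
            with pytest.raises(ValueError):
                structio.syncp(trace, k)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(n=st.integers(5, 50), k=st.integers(0, 200), seed=st.integers(0, 10))
    def test_group_inverse_restores_order_exactly(self, n, k, seed):
        """synCP by k then by n-k is the identity permutation, coordinates bit-equal."""
        k = k % n
        trace = random_trace(np.random.default_rng(seed), n)
        child = structio.syncp(trace, k).child
        back = structio.syncp(child, (n - k) % n).child
        np.testing.assert_array_equal(back.coords, trace.coords)

    def test_coordinate_multiset_conserved(self):
        trace = random_trace(np.random.default_rng(6), 23)
        child = structio.syncp(trace, 11).child
        a = np.sort(trace.coords.view([("", float)] * 3), axis=0)
        b = np.sort(child.coords.view([("", float)] * 3), axis=0)
        np.testing.assert_array_equal(a, b)


class TestEnumerateSynCPs:
    def test_yields_exactly_n_records_with_all_cuts(self):
        trace = random_trace(np.random.default_rng(7), 5)
        records = list(structio.enumerate_syncps(trace))
        assert [r.k for r in records] == [0, 1, 2, 3, 4]

    def test_all_children_share_one_coordinate_multiset(self):
        trace = random_trace(np.random.default_rng(8), 12)
        sets = {
            tuple(sorted(map(tuple, r.child.coords)))
            for r in structio.enumerate_syncps(trace)
        }
        assert len(sets) == 1

    def test_all_vs_all_enumeration_size(self):
        a = random_trace(np.random.default_rng(9), 7)
        b = random_trace(np.random.default_rng(10), 9)
        pairs = [
            (ra.k, rb.k)
            for ra in structio.enumerate_syncps(a)
            for rb in structio.enumerate_syncps(b)
        ]
        assert len(pairs) == 7 * 9


class TestSyntheticFamily:
    def test_zero_noise_members_superpose_exactly(self):
        fam = structio.make_synthetic_family(4, 30, 0.0, seed=11)
        for member in fam[1:]:
            _, _, rmsd = kabsch(member.coords, fam[0].coords, check_degenerate=False)
            assert rmsd < 1e-9

    def test_same_seed_reproduces_coordinates(self):
        a = structio.make_synthetic_family(3, 40, 0.5, seed=12)
        b = structio.make_synthetic_family(3, 40, 0.5, seed=12)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.coords, tb.coords)

    def test_within_family_rmsd_below_between_family(self):
        fam_a = structio.make_synthetic_family(4, 40, 0.5, seed=13)
        fam_b = structio.make_synthetic_family(4, 40, 0.5, seed=14)
        within, between = [], []
        for i in range(4):
            for j in range(i + 1, 4):
                within.append(kabsch(fam_a[i].coords, fam_a[j].coords, check_degenerate=False)[2])
            for j in range(4):
                between.append(kabsch(fam_a[i].coords, fam_b[j].coords, check_degenerate=False)[2])
        wins = sum(1 for w in within for b in between if w < b)
        assert wins / (len(within) * len(between)) >= 0.95

    def test_rejects_invalid_sizes(self):
        with pytest.raises(ValueError):
            structio.make_synthetic_family(0, 30, 0.1, seed=0)
        with pytest.raises(ValueError):
            structio.make_synthetic_family(2, 10, 0.1, seed=0)


class TestCPBenchmark:
    def test_planted_pairs_have_equal_length_and_multisets(self):
        bm = structio.make_cp_benchmark(4, 3, 40, 0.0, seed=20)
        for a, b in bm.cp_pairs:
            ta, tb = bm.trace(a), bm.trace(b)
            assert len(ta) == len(tb)
            ma = sorted(map(tuple, np.round(ta.coords, 6)))
            mb = sorted(map(tuple, np.round(tb.coords, 6)))
            assert ma == mb

    def test_determinism_is_byte_identical(self):
        a = structio.make_cp_benchmark(3, 3, 40, 0.2, seed=21)
        b = structio.make_cp_benchmark(3, 3, 40, 0.2, seed=21)
        assert a.cp_pairs == b.cp_pairs and a.decoy_pairs == b.decoy_pairs
        for ta, tb in zip(a.traces, b.traces):
            assert ta.coords.tobytes() == tb.coords.tobytes()

    def test_planted_cut_recovered_by_exhaustive_superposition(self):
        """Brute-force Kabsch over all cyclic shifts finds the planted cut."""
        bm = structio.make_cp_benchmark(3, 3, 40, 0.0, seed=22)
        for a, b in bm.cp_pairs:
            ta, tb = bm.trace(a), bm.trace(b)
            planted = int(tb.source.split("k=")[1].split(")")[0])
            rmsds = [
                kabsch(np.roll(ta.coords, -k, axis=0), tb.coords, check_degenerate=False)[2]
                for k in range(len(ta))
            ]
            assert int(np.argmin(rmsds)) == planted
            assert min(rmsds) < 1e-9

    def test_pairs_reference_known_traces_and_do_not_overlap(self):
        bm = structio.make_cp_benchmark(5, 3, 40, 0.3, seed=23)
        ids = {t.id for t in bm.traces}
        for a, b in bm.cp_pairs + bm.decoy_pairs:
            assert a in ids and b in ids
        assert not set(bm.cp_pairs) & set(bm.decoy_pairs)
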