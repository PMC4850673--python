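"""Masked distances and single-linkage preclustering vs brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import iped
from iped.contigs import UniqueSequence
from oracles import bf_precluster


def _mask(length, positions=()):
    m = np.zeros(length, bool)
    m[list(positions)] = True
    return m


def _random_table(rng, n_uniques, length, mask_rate=0.05, alphabet="ACGT"):
    base = rng.choice(list(alphabet), size=length)
    rows = []
    for i in range(n_uniques):
        seq = base.copy()
        k = rng.integers(0, max(2, length // 8))
        for j in rng.choice(length, size=k, replace=False):
            seq[j] = rng.choice(list(alphabet))
        mask = rng.random(length) < mask_rate
        abundance = int(rng.integers(1, 50))
        rows.append(
            UniqueSequence(
                id=f"u{i}",
                seq="".join(seq),
                abundance=abundance,
                member_ids=[f"u{i}_m{j}" for j in range(abundance)],
                mask=mask,
            )
        )
    return rows


class TestMaskedDistance:
    @pytest.mark.parametrize(
        "a, ma, b, mb, expected",
        [
            ("ACGT", (), "ACGT", (), 0),
            ("ACGT", (), "AGGT", (), 1),
            ("ACGT", (1,), "AGGT", (), 0),  # masked position does not count
            ("ACGT", (), "AGGT", (1,), 0),  # mask on either member suppresses
            ("AC-T", (), "AG-T", (), 1),  # gap-gap column never counts
            ("AC-T", (), "ACAT", (), 1),  # gap vs base counts
        ],
    )
    def test_examples(self, a, ma, b, mb, expected):
        assert iped.masked_distance(a, _mask(4, ma), b, _mask(4, mb)) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            iped.masked_distance("ACGT", None, "ACG", None)

    @settings(max_examples=150, derandomize=True)
    @given(
        st.integers(1, 60),
        st.data(),
    )
    def test_symmetry_and_mask_monotonicity(self, length, data):
        seq = st.text(alphabet="ACGT-", min_size=length, max_size=length)
        mask = st.lists(st.booleans(), min_size=length, max_size=length)
        a, b = data.draw(seq), data.draw(seq)
        ma, mb = np.array(data.draw(mask)), np.array(data.draw(mask))
        d = iped.masked_distance(a, ma, b, mb)
        assert d == iped.masked_distance(b, mb, a, ma)
        assert d <= iped.masked_distance(a, None, b, None)


class TestAllowedDiffs:
    @pytest.mark.parametrize("length, expected", [(250, 2), (430, 4), (50, 1), (100, 1), (199, 1)])
    def test_one_per_hundred_floor_clamped(self, length, expected):
        assert iped.allowed_diffs(length) == expected

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            iped.allowed_diffs(0)


class TestPrecluster:
    def test_rare_merges_into_abundant(self):
        a = UniqueSequence("A", "ACGTACGTAC", 100, [f"a{i}" for i in range(100)])
        b = UniqueSequence("B", "ACGTACGTAA", 5, [f"b{i}" for i in range(5)])
        result = iped.precluster([a, b], diffs=1)
        assert result.merge_map == {"A": "A", "B": "A"}
        assert result.table[0].abundance == 105
        assert [r.rare_id for r in result.records] == ["B"]
        assert result.records[0].distance == 1

    def test_singleton_table_unchanged(self):
        a = UniqueSequence("A", "ACGTACGTAC", 3, ["x", "y", "z"])
        result = iped.precluster([a], diffs=2)
        assert result.merge_map == {"A": "A"}
        assert result.table[0].abundance == 3

    def test_equal_abundance_never_merges(self):
        a = UniqueSequence("A", "ACGTACGTAC", 5, [f"a{i}" for i in range(5)])
        b = UniqueSequence("B", "ACGTACGTAA", 5, [f"b{i}" for i in range(5)])
        result = iped.precluster([a, b], diffs=2)
        assert result.merge_map == {"A": "A", "B": "B"}

    def test_mask_enables_merge(self):
        # distance 2 > diffs=1, but one difference is masked on the rare side
        a = UniqueSequence("A", "ACGTACGTAC", 50, [f"a{i}" for i in range(50)])
        b = UniqueSequence(
            "B", "AGGTACGTAA", 5, [f"b{i}" for i in range(5)], mask=_mask(10, (1,))
        )
        assert iped.precluster([a, b], diffs=1).merge_map["B"] == "A"
        b.mask = _mask(10)
        assert iped.precluster([a, b], diffs=1).merge_map["B"] == "B"

    def test_unequal_lengths_rejected(self):
        a = UniqueSequence("A", "ACGT", 2, ["x", "y"])
        b = UniqueSequence("B", "ACGTA", 1, ["z"])
        with pytest.raises(ValueError, match="equal-length"):
            iped.precluster([a, b])

    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(25):
            n = int(rng.integers(2, 30))
            length = int(rng.integers(20, 60))
            table = _random_table(rng, n, length)
            diffs = int(rng.integers(1, 4))
            result = iped.precluster(table, diffs=diffs)
            oracle_map, oracle_ab = bf_precluster(
                [(u.id, u.seq, u.abundance, u.mask) for u in table], diffs
            )
            assert result.merge_map == oracle_map
            assert {u.id: u.abundance for u in result.table} == oracle_ab
            assert sum(u.abundance for u in result.table) == sum(u.abundance for u in table)

    def test_empty_masks_reproduce_plain_baseline(self, rng):
        table = _random_table(rng, 20, 40, mask_rate=0.0)
        result_a = iped.precluster(table, diffs=2)
        result_b = iped.precluster(
            [
                UniqueSequence(u.id, u.seq, u.abundance, list(u.member_ids))
                for u in table
            ],
            diffs=2,
        )
        assert result_a.merge_map == result_b.merge_map

    def test_auto_diffs_uses_ungapped_length(self):
        # 250 ungapped nt -> 2 allowed differences
        base = "ACGT" * 62 + "AC"
        variant = "TT" + base[2:]
        a = UniqueSequence("A", base, 50, [f"a{i}" for i in range(50)])
        b = UniqueSequence("B", variant, 2, ["b0", "b1"])
        assert iped.precluster([a, b], diffs="auto").merge_map["B"] == "A"


class TestRevertAndEmit:
    def test_outputs_are_input_sequences(self, rng):
        table = _random_table(rng, 15, 30)
        input_seqs = {u.seq for u in table}
        result = iped.precluster(table, diffs=2)
        for u in iped.revert_and_emit(result):
            assert u.seq in input_seqs
            assert not u.mask.any()

    def test_no_merges_identity(self):
        a = UniqueSequence("A", "AAAAAAAAAA", 5, [f"a{i}" for i in range(5)])
        b = UniqueSequence("B", "CCCCCCCCCC", 3, [f"b{i}" for i in range(3)])
        out = iped.revert_and_emit(iped.precluster([a, b], diffs=1))
        assert [(u.id, u.seq, u.abundance) for u in out] == [
            ("A", "AAAAAAAAAA", 5),
            ("B", "CCCCCCCCCC", 3),
        ]

    def test_merged_abundance_and_membership(self):
        a = UniqueSequence("A", "ACGTACGTAC", 100, [f"a{i}" for i in range(100)])
        b = UniqueSequence("B", "ACGTACGTAA", 5, [f"b{i}" for i in range(5)])
        out = iped.revert_and_emit(iped.precluster([a, b], diffs=1))
        assert len(out) == 1
        assert out[0].seq == "ACGTACGTAC"
        assert out[0].abundance == 105
        assert set(out[0].member_ids) == {f"a{i}" for i in range(100)} | {
            f"b{i}" for i in range(5)
        }


def test_mask_tsv_roundtrip(tmp_path, rng):
    table = _random_table(rng, 10, 25)
    path = tmp_path / "masks.tsv"
    from iped.precluster import read_masks, write_masks

    write_masks(table, path)
    back = read_masks(path, {u.id: len(u.seq) for u in table})
    for u in table:
        np.testing.assert_array_equal(back[u.id], u.mask)
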