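"""MAF slicing, stitching, profile merging, trimming, p-distances."""
import io

import numpy as np
import pytest

from paleoeve import alnkit as ak

from conftest import pdistance_bruteforce

MAF_TEXT = """##maf version=1

a score=10.0
s ref.chr1 100 11 + 1000 ACG--TACGTACG
s spA.chr5  40 13 + 500  ACGTTTACGTACG
s spB.chr2  10 10 - 300  AC---TACGTACG

a score=5.0
s ref.chr1 150 5 + 1000 CCCCC
s spA.chr5  60 5 + 500  GGGCC
"""


@pytest.fixture()
def maf_blocks():
    return ak.read_maf(io.StringIO(MAF_TEXT))


class TestMafIO:
    def test_parse_rows(self, maf_blocks):
        assert len(maf_blocks) == 2
        ref = maf_blocks[0].reference
        assert (ref.src, ref.start, ref.size, ref.strand) == ("ref.chr1", 100, 11, 1)
        assert maf_blocks[0].rows[2].strand == -1

    def test_roundtrip(self, maf_blocks, tmp_path):
        path = tmp_path / "t.maf"
        ak.write_maf(maf_blocks, str(path))
        again = ak.read_maf(str(path))
        assert [r.text for b in again for r in b.rows] == \
               [r.text for b in maf_blocks for r in b.rows]


class TestExtractMafRegion:
    def _column_scan_oracle(self, block, lo, hi):
        """Columns whose reference (ungapped) coordinate falls in [lo, hi)."""
        ref = block.reference
        pos = ref.start
        cols = []
        for c, ch in enumerate(ref.text):
            if ch != "-":
                if lo <= pos < hi:
                    cols.append(c)
                pos += 1
        return cols

    def test_clip_matches_column_scan(self, maf_blocks):
        region = ak.RegionSpec("ref.chr1", 103, 108, "r")
        out = ak.extract_maf_region(maf_blocks, region)
        assert len(out) == 1
        cols = self._column_scan_oracle(maf_blocks[0], 103, 108)
        expected = "".join(maf_blocks[0].reference.text[c] for c in
                           range(cols[0], cols[-1] + 1))
        assert out[0].reference.text == expected
        assert out[0].reference.start == 103
        # non-reference rows keep exact coordinates
        spa = out[0].rows[1]
        before = sum(1 for ch in maf_blocks[0].rows[1].text[:cols[0]] if ch != "-")
        assert spa.start == 40 + before

    def test_disjoint_region_empty(self, maf_blocks):
        assert ak.extract_maf_region(maf_blocks,
                                     ak.RegionSpec("ref.chr1", 400, 500, "r")) == []

    def test_exact_block_returned_unchanged(self, maf_blocks):
        out = ak.extract_maf_region(maf_blocks, ak.RegionSpec("ref.chr1", 150, 155, "r"))
        assert out[0].reference.text == "CCCCC"
        assert out[0].rows[1].text == "GGGCC"

    def test_wrong_reference_id_empty(self, maf_blocks):
        assert ak.extract_maf_region(maf_blocks,
                                     ak.RegionSpec("other.chr1", 100, 110, "r")) == []


class TestMafToFasta:
    def test_concatenation_and_padding(self, maf_blocks):
        aln = ak.maf_to_fasta(maf_blocks, ["ref", "spA", "spB"])
        assert aln.n_columns == 13 + 5
        assert aln.row("spB").endswith("-" * 5)  # spB absent from block 2
        assert aln.row("ref") == "ACG--TACGTACG" + "CCCCC"

    def test_overlapping_blocks_rejected(self, maf_blocks):
        clone = ak.MafBlock([ak.MafRow("ref.chr1", 105, 5, 1, 1000, "AAAAA")])
        with pytest.raises(ValueError, match="overlap"):
            ak.maf_to_fasta(maf_blocks + [clone], ["ref"])

    def test_fasta_maf_fasta_roundtrip(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), 40)) for _ in range(3)]
        rows = [r if set(r) != {"-"} else "A" * 40 for r in rows]
        ids = ["sp1", "sp2", "sp3"]
        blocks = []
        start = {i: 0 for i in ids}
        for lo in range(0, 40, 10):
            brs = []
            for i, r in enumerate(ids):
                text = rows[i][lo:lo + 10]
                size = sum(1 for c in text if c != "-")
                brs.append(ak.MafRow(f"{r}.c", start[r], size, 1, 100, text))
                start[r] += size
            blocks.append(ak.MafBlock(brs))
        back = ak.maf_to_fasta(blocks, ids)
        assert back.rows == rows


class TestMergeAlignments:
    def _nw_oracle(self, pa, pb, S, g):
        """Plain quadratic needleman-wunsch on column profiles."""
        wa, wb = len(pa), len(pb)
        H = [[0.0] * (wb + 1) for _ in range(wa + 1)]
        for i in range(1, wa + 1):
            H[i][0] = -g * i
        for j in range(1, wb + 1):
            H[0][j] = -g * j
        for i in range(1, wa + 1):
            for j in range(1, wb + 1):
                H[i][j] = max(H[i - 1][j - 1] + S[i - 1][j - 1],
                              H[i - 1][j] - g, H[i][j - 1] - g)
        return H[wa][wb]

    def test_identity_merge_adds_no_gaps(self):
        a = ak.MultipleAlignment(["x", "y"], ["ACGT-A", "AC-TAA"])
        b = ak.MultipleAlignment(["p", "q"], ["ACGT-A", "AC-TAA"])
        merged = ak.merge_alignments(a, b)
        assert merged.n_columns == 6
        assert merged.row("x") == "ACGT-A"
        assert merged.row("p") == "ACGT-A"

    def test_width_bounds(self, rng):
        a = ak.MultipleAlignment(["x"], ["".join(rng.choice(list("ACGT"), 10))])
        b = ak.MultipleAlignment(["y"], ["".join(rng.choice(list("ACGT"), 12))])
        merged = ak.merge_alignments(a, b)
        assert 12 <= merged.n_columns <= 22

    def test_id_collision_rejected(self):
        a = ak.MultipleAlignment(["x"], ["ACGT"])
        b = ak.MultipleAlignment(["x"], ["ACGT"])
        with pytest.raises(ValueError, match="collision"):
            ak.merge_alignments(a, b)

    def test_matches_profile_nw_oracle(self, rng):
        """The merged alignment realises the exhaustive profile-NW optimum
        on gap-free toy inputs."""
        from paleoeve.alnkit import _profile

        for trial in range(5):
            a = ak.MultipleAlignment(
                ["a1", "a2", "a3"],
                ["".join(rng.choice(list("ACGT"), 8)) for _ in range(3)])
            b = ak.MultipleAlignment(
                ["b1", "b2", "b3"],
                ["".join(rng.choice(list("ACGT"), 9)) for _ in range(3)])
            merged = ak.merge_alignments(a, b)
            m5 = np.full((5, 5), -1.0)
            np.fill_diagonal(m5, 2.0)
            m5[4, :] = -1.0
            m5[:, 4] = -1.0
            m5[4, 4] = 0.0
            S = _profile(a) @ m5 @ _profile(b).T
            oracle = self._nw_oracle(_profile(a), _profile(b), S, 2.0)
            # inputs are gap-free, so an all-gap merged column is an
            # inserted gap and any other column consumes an input column
            score, ia, ib = 0.0, 0, 0
            for col in range(merged.n_columns):
                a_gap = all(merged.rows[k][col] == "-" for k in range(3))
                b_gap = all(merged.rows[3 + k][col] == "-" for k in range(3))
                assert not (a_gap and b_gap)
                if a_gap or b_gap:
                    score -= 2.0
                    ia += not a_gap
                    ib += not b_gap
                else:
                    score += S[ia, ib]
                    ia += 1
                    ib += 1
            assert (ia, ib) == (8, 9)
            assert score == pytest.approx(oracle)


class TestTrimColumns:
    def test_threshold_one_keeps_everything(self):
        aln = ak.MultipleAlignment(["a", "b"], ["A-G", "AC-"])
        out = ak.trim_columns(aln, 1.0)
        assert out.rows == aln.rows
        assert out.column_map == [0, 1, 2]

    def test_threshold_zero_keeps_only_gapless(self):
        aln = ak.MultipleAlignment(["a", "b"], ["A-GT", "ACG-"])
        out = ak.trim_columns(aln, 0.0)
        assert out.rows == ["AG", "AG"]
        assert out.column_map == [0, 2]

    def test_constructed_gap_fractions(self):
        cols = ["AAAAA", "AAAA-", "AA---", "A----", "-----"]  # 0,.2,.6,.8,1
        rows = ["".join(cols[c][r] for c in range(5)) for r in range(5)]
        aln = ak.MultipleAlignment([f"s{i}" for i in range(5)], rows)
        out = ak.trim_columns(aln, 0.5)
        assert out.n_columns == 2
        assert out.column_map == [0, 1]

    def test_all_columns_removed_yields_empty(self):
        aln = ak.MultipleAlignment(["a", "b"], ["--", "--"])
        out = ak.trim_columns(aln, 0.5)
        assert out.n_columns == 0


class TestPairwisePDistance:
    def test_simple_quarter_distance(self):
        aln = ak.MultipleAlignment(["a", "b"], ["ACGT", "ACGA"])
        dm = ak.pairwise_p_distance(aln)
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_excludes_gap_columns(self):
        aln = ak.MultipleAlignment(["a", "b"], ["AC-T", "ACGT"])
        dm = ak.pairwise_p_distance(aln)
        assert dm.values[0, 1] == 0.0

    def test_ambiguity_codes_excluded(self):
        aln = ak.MultipleAlignment(["a", "b"], ["ANRT", "AAGT"])
        dm = ak.pairwise_p_distance(aln)
        assert dm.values[0, 1] == 0.0  # only A and T columns compared

    def test_no_comparable_sites_flagged(self):
        aln = ak.MultipleAlignment(["a", "b"], ["A--", "-CC"])
        dm = ak.pairwise_p_distance(aln)
        assert np.isnan(dm.values[0, 1])
        assert dm.undefined_pairs == [("a", "b")]

    def test_matches_double_loop_oracle(self, rng):
        rows = ["".join(rng.choice(list("ACGT-N"), 100)) for _ in range(10)]
        aln = ak.MultipleAlignment([f"s{i}" for i in range(10)], rows)
        dm = ak.pairwise_p_distance(aln)
        oracle = pdistance_bruteforce(rows)
        assert np.allclose(dm.values, oracle, equal_nan=True)

    def test_matrix_properties(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(6)]
        dm = ak.pairwise_p_distance(
            ak.MultipleAlignment([f"s{i}" for i in range(6)], rows))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.nanmax(dm.values) <= 1.0
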