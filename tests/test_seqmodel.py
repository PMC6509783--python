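"""Alignment primitives: optimality, identity, trimming, p-distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gh45tools.seqmodel import (Alignment, SequenceError, SequenceRecord,
                                _BLOSUM62, global_align, p_distance,
                                p_distance_matrix, pairwise_identity,
                                read_alignment, read_fasta, trim_columns,
                                write_fasta)

GAP_OPEN, GAP_EXTEND = 10, 1


# --- independent oracle: enumerate every global alignment ------------------

def _score_alignment(cols):
    """Affine score of an alignment given as (char|None, char|None) columns."""
    score, in_gap_a, in_gap_b = 0.0, False, False
    for x, y in cols:
        if x is not None and y is not None:
            score += _BLOSUM62[x, y]
            in_gap_a = in_gap_b = False
        elif y is None:                      # gap in b
            score -= GAP_EXTEND + (0 if in_gap_b else GAP_OPEN)
            in_gap_b, in_gap_a = True, False
        else:                                # gap in a
            score -= GAP_EXTEND + (0 if in_gap_a else GAP_OPEN)
            in_gap_a, in_gap_b = True, False
    return score


def brute_force_best(a, b):
    """Maximum affine-gap score over all global alignments (exhaustive)."""
    best = [-np.inf]

    def go(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], _score_alignment(cols))
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            go(i + 1, j, cols + [(a[i], None)])
        if j < len(b):
            go(i, j + 1, cols + [(None, b[j])])

    go(0, 0, [])
    return best[0]


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("DDA", "DDA")
        assert aln.aligned_a == "DDA" and aln.aligned_b == "DDA"
        expected = sum(_BLOSUM62[c, c] for c in "DDA")
        assert aln.score == expected

    def test_single_gap_column(self):
        aln = global_align("DA", "DGA")
        assert aln.aligned_a == "D-A" and aln.aligned_b == "DGA"
        assert aln.score == (_BLOSUM62["D", "D"] + _BLOSUM62["A", "A"]
                             - (GAP_OPEN + GAP_EXTEND))

    @pytest.mark.parametrize("a,b", [("", "DDA"), ("DDA", "")])
    def test_empty_sequence_rejected(self, a, b):
        with pytest.raises(SequenceError):
            global_align(a, b)

    def test_unknown_letter_names_position(self):
        with pytest.raises(SequenceError, match="position 3"):
            global_align("DDXDD", "DDD")

    def test_no_gap_in_both_columns(self):
        aln = global_align("ACDEF", "KLM")
        assert not any(x == "-" and y == "-" for x, y in aln.columns())
        assert aln.aligned_a.replace("-", "") == "ACDEF"
        assert aln.aligned_b.replace("-", "") == "KLM"

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(40):
            a = "".join(rng.choice(letters, size=rng.integers(1, 7)))
            b = "".join(rng.choice(letters, size=rng.integers(1, 7)))
            assert global_align(a, b).score == pytest.approx(
                brute_force_best(a, b))

    def test_matches_biopython_score(self):
        """Independent check against Biopython's affine-gap aligner."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = _BLOSUM62
        aligner.mode = "global"
        # Biopython charges open on the first gap position
        aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
        aligner.extend_gap_score = -GAP_EXTEND
        rng = np.random.default_rng(7)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(letters, size=rng.integers(5, 40)))
            b = "".join(rng.choice(letters, size=rng.integers(5, 40)))
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))


class TestPairwiseIdentity:
    def test_self_identity_is_one(self):
        assert pairwise_identity("MKVLA", "MKVLA") == 1.0

    def test_disjoint_identity_is_zero(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_single_substitution(self):
        assert pairwise_identity("AAAAAAAAAA", "AAAAAAAAAC") == pytest.approx(0.9)

    def test_fragment_scores_full_identity(self):
        # shorter-sequence denominator: a perfect fragment is identical
        assert pairwise_identity("MKVLAWGHE", "MKVLA") == 1.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=15),
           st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=15))
    def test_symmetric(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def _aln(rows):
    return Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])


class TestTrimColumns:
    def test_all_gap_column_removed(self):
        out = trim_columns(_aln(["A-C", "A-C", "A-C", "A-C"]))
        assert [r.residues for r in out.rows] == ["AC"] * 4

    def test_threshold_is_strict(self):
        # 2/4 gaps (0.5) retained, 3/4 (0.75) removed at the default 0.5
        out = trim_columns(_aln(["AAC", "A-C", "A--", "A--"]))
        assert [r.residues for r in out.rows] == ["AC", "AC", "A-", "A-"]

    def test_gap_free_unchanged(self):
        rows = ["ACD", "EFG", "HIK", "LMN"]
        out = trim_columns(_aln(rows))
        assert [r.residues for r in out.rows] == rows

    def test_idempotent_and_count_matches_direct_tally(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("AC-"), size=30)) for _ in range(6)]
        # avoid rows that become empty-string records
        rows = [r if r.strip("-") else "A" * 30 for r in rows]
        aln = _aln(rows)
        once = trim_columns(aln, 0.5)
        direct = sum(
            1 for k in range(aln.ncol)
            if sum(r[k] == "-" for r in rows) / len(rows) <= 0.5
        )
        assert once.ncol == direct
        assert [r.residues for r in trim_columns(once, 0.5).rows] == \
            [r.residues for r in once.rows]

    def test_empty_alignment_rejected(self):
        with pytest.raises(SequenceError):
            Alignment([])


class TestPDistance:
    def test_self_distance_zero(self):
        assert p_distance("ACD-", "ACD-") == 0.0

    def test_gap_sites_excluded(self):
        assert p_distance("AAC-", "AAG-") == pytest.approx(1 / 3)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(SequenceError):
            p_distance("A---", "-AAA")

    def test_matrix_agrees_with_pairwise(self):
        rows = ["ACDEF", "ACDEG", "KCDE-", "ACD--"]
        aln = _aln(rows)
        labels, d = p_distance_matrix(aln)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert d[i, j] == pytest.approx(
                        p_distance(rows[i], rows[j]))
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


class TestFastaIO:
    def test_roundtrip_with_taxonomy_tokens(self, tmp_path):
        recs = [
            SequenceRecord("q1", "MKVLA", taxon="Phaedon_cochleariae",
                           lineage=("Arthropoda", "Coleoptera")),
            SequenceRecord("q2", "MKVLC"),
        ]
        path = tmp_path / "x.faa"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert back == recs

    def test_sidecar_tsv_takes_precedence(self, tmp_path):
        path = tmp_path / "x.faa"
        write_fasta([SequenceRecord("q1", "MKVLA", taxon="wrong")], path)
        tsv = tmp_path / "tax.tsv"
        tsv.write_text("#id\ttaxon\tlineage\nq1\tright\tFungi;Sordariales\n")
        back = read_fasta(path, taxonomy_tsv=tsv)
        assert back[0].taxon == "right"
        assert back[0].lineage == ("Fungi", "Sordariales")

    def test_dot_gaps_normalised(self, tmp_path):
        (tmp_path / "a.afa").write_text(">r1\nAC.D\n>r2\nACDD\n")
        aln = read_alignment(tmp_path / "a.afa")
        assert aln.row("r1").residues == "AC-D"

    def test_duplicate_ids_rejected(self, tmp_path):
        (tmp_path / "a.faa").write_text(">r1\nACD\n>r1\nACD\n")
        with pytest.raises(SequenceError, match="duplicate"):
            read_fasta(tmp_path / "a.faa")

    def test_empty_fasta_rejected(self, tmp_path):
        (tmp_path / "a.faa").write_text("")
        with pytest.raises(SequenceError):
            read_fasta(tmp_path / "a.faa")
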