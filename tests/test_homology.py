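"""Local aligner (vs independent oracles), cross-dataset comparison,
classification, grouping and consensus identity."""

import itertools

import numpy as np
import pytest
from Bio import Align

from telokit.homology import (
    AlignmentParams,
    classify_and_group,
    cross_compare,
    extend_orthologs,
    identity_to_consensus,
    local_align,
    mean_pairwise_identity,
    sw_score,
)
from telokit.io import TranscriptRecord

P = AlignmentParams()


def biopython_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    """Independent reference: Biopython's C pairwise aligner with the same
    BLAST gap semantics (first gapped base costs open+extend)."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = -(params.gap_open + params.gap_extend)
    al.extend_gap_score = -params.gap_extend
    return al


def enumerate_best_score(a, b, params):
    """Exhaustive oracle: recursively enumerate every local alignment path
    (no dynamic programming) and return the best affine-gap score."""
    oe = params.gap_open + params.gap_extend
    best = 0

    def rec(i, j, last, score):
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            s = params.match if a[i] == b[j] else params.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if last is not None:  # gaps at the start of a local alignment never help
            if i < len(a):
                rec(i + 1, j, "F", score - (params.gap_extend if last == "F" else oe))
            if j < len(b):
                rec(i, j + 1, "E", score - (params.gap_extend if last == "E" else oe))

    for i in range(len(a)):
        for j in range(len(b)):
            rec(i, j, None, 0)
    return best


def rescore(aq, asub, params):
    """Recompute an alignment's score from its aligned strings."""
    score = 0
    run = None
    for x, y in zip(aq, asub):
        if x == "-" or y == "-":
            gap = "q" if x == "-" else "s"
            score -= params.gap_extend + (params.gap_open if run != gap else 0)
            run = gap
        else:
            score += params.match if x == y else params.mismatch
            run = None
    return score


class TestLocalAlign:
    def test_self_alignment(self):
        aln = local_align("GACG", "GACG")
        assert aln.score == 8 and aln.identity == 1.0
        assert aln.query_interval == (0, 4) and aln.subject_interval == (0, 4)

    def test_mismatch_beats_split(self):
        # one central mismatch: 7*2 - 3 = 11 beats two clean 3-mer segments
        assert local_align("ACGTACGT", "ACGAACGT").score == 11

    def test_minus_strand(self):
        aln = local_align("AAAA", "TTTT")
        assert aln.score == 8 and aln.strand == "-"
        assert aln.subject_interval == (0, 4)

    def test_score_matches_alignment_path(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(25):
            a = "".join(rng.choice(bases, size=int(rng.integers(10, 80))))
            b = "".join(rng.choice(bases, size=int(rng.integers(10, 80))))
            aln = local_align(a, b)
            if aln.score:
                assert rescore(aln.aligned_query, aln.aligned_subject, P) == aln.score
                qs, qe = aln.query_interval
                assert aln.aligned_query.replace("-", "") == a[qs:qe]

    def test_score_only_pass_agrees_with_traceback(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(25):
            a = "".join(rng.choice(bases, size=int(rng.integers(5, 60))))
            b = "".join(rng.choice(bases, size=int(rng.integers(5, 60))))
            score, strand = sw_score(a, b, P)
            assert score == local_align(a, b).score

    def test_symmetry_and_self_score(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, size=30))
            b = "".join(rng.choice(bases, size=45))
            assert sw_score(a, b, P)[0] == sw_score(b, a, P)[0]
            assert local_align(a, a).score == 2 * len(a)

    def test_exhaustive_enumeration_oracle_small(self):
        """Equals a pure path-enumeration oracle on all AC-string pairs of
        length <= 3 (no DP in the oracle)."""
        strings = [
            "".join(t)
            for n in (1, 2, 3)
            for t in itertools.product("AC", repeat=n)
        ]
        for a in strings:
            for b in strings:
                expected = enumerate_best_score(a, b, P)
                got, _ = sw_score(a, b, P, both_strands=False)
                assert got == expected, (a, b)

    def test_reference_aligner_on_random_pairs(self, rng):
        """Equals Biopython's independent local aligner on seeded random
        AC-pairs up to length 8 (both scoring schemes)."""
        for params in (P, P.relaxed()):
            ref = biopython_aligner(params)
            for _ in range(800):
                a = "".join(rng.choice(["A", "C"], size=int(rng.integers(1, 9))))
                b = "".join(rng.choice(["A", "C"], size=int(rng.integers(1, 9))))
                got, _ = sw_score(a, b, params, both_strands=False)
                assert got == int(ref.score(a, b)), (a, b)

    def test_size_cap(self):
        with pytest.raises(ValueError, match="cap"):
            local_align("A" * 100_001, "ACGT")

    def test_pure_python_scorer_agrees_with_compiled_kernel(self, rng):
        """The interpreter fallback and the compiled bulk kernel are the
        same recurrence; keep them in lockstep."""
        from telokit.homology import _encode, _gotoh_score_py

        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 50))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 50))))
            got, _ = sw_score(a, b, P, both_strands=False)
            assert _gotoh_score_py(_encode(a), _encode(b), 2, -3, 7, 2) == got


def _records(ds, seqs):
    return [TranscriptRecord(f"t{i}", s, ds) for i, s in enumerate(seqs, 1)]


def _random_seq(rng, n):
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), size=n))


class TestCrossCompare:
    def test_identical_datasets_all_shared(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(3)]
        matrix, hits = cross_compare(
            {"a": _records("a", seqs), "b": _records("b", seqs)}
        )
        assert all(c == "shared_in_all" for c in matrix.classes)
        assert matrix.values.all()

    def test_shared_7mer_only_is_unique(self, rng):
        perm = "ACCCTAA"
        a = "".join(rng.choice(list("ACGT"), size=100)) + perm
        b = perm + "".join(rng.choice(list("ACGT"), size=100))
        matrix, hits = cross_compare(
            {"a": _records("a", [a]), "b": _records("b", [b])}
        )
        assert hits == []
        assert matrix.classes == ["unique", "unique"]

    def test_empty_dataset_column_retained(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=80))]
        matrix, _ = cross_compare(
            {"a": _records("a", seqs), "b": []}
        )
        assert matrix.datasets == ["a", "b"]
        assert matrix.classes == ["unique"]

    def test_planted_orthologs_shared_in_all(self, small_spec):
        from telokit.simulate import simulate_datasets

        datasets, truth = simulate_datasets(small_spec)
        # candidate subsets: the planted TR plus a few decoys per dataset
        subsets = {
            ds: [r for r in recs
                 if r.id == truth.planted_id[ds] or r.id.endswith("decoy1")
                 or r.id.endswith("decoy2")]
            for ds, recs in datasets.items()
        }
        matrix, hits = cross_compare(subsets)
        for r, (ds, tid) in enumerate(matrix.rows):
            expected = "shared_in_all" if tid == truth.planted_id[ds] else "unique"
            assert matrix.classes[r] == expected

    def test_needs_two_datasets(self):
        with pytest.raises(ValueError):
            cross_compare({"a": []})


class TestClassifyAndGroup:
    def test_final_set_requires_full_coverage(self, small_spec):
        from telokit.simulate import simulate_datasets

        datasets, truth = simulate_datasets(small_spec)
        subsets = {
            ds: [r for r in recs if r.id == truth.planted_id[ds]
                 or r.id.endswith("decoy3")]
            for ds, recs in datasets.items()
        }
        matrix, hits = cross_compare(subsets)
        groups, final = classify_and_group(matrix, hits)
        assert len(final) == 1
        assert {m[1] for m in final[0].members} == set(truth.planted_id.values())

    def test_adding_uncovered_dataset_shrinks_final_set(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=90))]
        three = {
            "a": _records("a", seqs),
            "b": _records("b", seqs),
            "c": _records("c", ["".join(rng.choice(list("ACGT"), size=90))]),
        }
        m2, h2 = cross_compare({k: three[k] for k in ("a", "b")})
        _, final2 = classify_and_group(m2, h2)
        m3, h3 = cross_compare(three)
        _, final3 = classify_and_group(m3, h3)
        assert len(final2) == 1 and len(final3) == 0

    def test_representative_is_longest_member(self, rng):
        long = "".join(rng.choice(list("ACGT"), size=80))
        matrix, hits = cross_compare(
            {"a": _records("a", [long + "ACGT" * 5]), "b": _records("b", [long])}
        )
        seqs = {("a", "t1"): long + "ACGT" * 5, ("b", "t1"): long}
        groups, _ = classify_and_group(matrix, hits, seqs)
        assert groups[0].representative == ("a", "t1")


class TestExtendOrthologs:
    def test_self_hit_tops_ranking(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        query = TranscriptRecord("q", seq, "a")
        targets = [TranscriptRecord("q", seq, "a"),
                   TranscriptRecord("x", "".join(rng.choice(list("ACGT"), size=120)), "a")]
        hits = extend_orthologs(query, targets)
        assert hits[0].target_id == "q"
        assert hits[0].alignment.score == 2 * len(seq)

    def test_no_homolog_empty_ranking(self, rng):
        query = TranscriptRecord("q", "".join(rng.choice(list("ACGT"), size=100)), "a")
        targets = [TranscriptRecord("x", "".join(rng.choice(list("ACGT"), size=100)), "b")]
        assert extend_orthologs(query, targets) == []

    def test_relaxed_mode_recovers_deeply_diverged_ortholog(self):
        """A heavily substituted ortholog is missed by strict +2/-3 scoring
        but found by the permissive +1/-1 pass with halved cutoff."""
        rng = np.random.default_rng(0)
        bases = list("ACGT")
        seq = "".join(rng.choice(bases, size=600))
        diverged = list(seq)
        for i in np.flatnonzero(rng.random(len(seq)) < 0.5):
            diverged[i] = [b for b in bases if b != diverged[i]][rng.integers(0, 3)]
        query = TranscriptRecord("q", seq, "a")
        target = [TranscriptRecord("d", "".join(diverged), "b")]
        strict = extend_orthologs(query, target, relaxed=False)
        relaxed = extend_orthologs(query, target, relaxed=True)
        assert strict == []
        assert relaxed and relaxed[0].target_id == "d"

    def test_template_window_annotation(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=90))
        query = TranscriptRecord("q", core, "a")
        with_template = TranscriptRecord("t", core + "CCCTAACCCTAAC", "b")
        hits = extend_orthologs(query, [with_template])
        assert hits and hits[0].has_template_window


class TestIdentityToConsensus:
    def test_identical_rows(self):
        idents, mean, cons = identity_to_consensus(["ACGT", "ACGT"])
        assert idents == [1.0, 1.0] and mean == 1.0 and cons == "ACGT"

    def test_gap_and_tie_rules(self):
        idents, mean, cons = identity_to_consensus(["AC-T", "ACGT"])
        assert cons == "ACGT"
        assert idents == [1.0, 1.0]

    def test_tie_broken_alphabetically(self):
        _, _, cons = identity_to_consensus(["A", "C"])
        assert cons == "A"

    def test_simulated_15pct_divergence_regime(self, rng):
        """Rows mutated at 15% from a common ancestor sit near 85% identity
        to the consensus."""
        bases = list("ACGT")
        ancestor = "".join(rng.choice(bases, size=600))
        rows = []
        for _ in range(6):
            row = list(ancestor)
            for i in np.flatnonzero(rng.random(len(row)) < 0.15):
                row[i] = [b for b in bases if b != row[i]][rng.integers(0, 3)]
            rows.append("".join(row))
        _, mean, _ = identity_to_consensus(rows)
        assert 0.82 <= mean <= 0.88

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            identity_to_consensus(["ACGT", "AC"])

    def test_pairwise_variant_exposed(self):
        assert mean_pairwise_identity(["ACGT", "ACGA"]) == 0.75
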