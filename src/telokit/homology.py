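"""Cross-species homology: local alignment, all-to-all candidate comparison,
presence classification and ortholog grouping.

The aligner is a Smith-Waterman / Gotoh dynamic program with BLASTN-style
scoring (reward +2, penalty -3, gap open 5, gap extend 2; a k-base gap costs
open + k*extend) searched over both strands of the subject.  Candidate sets
from different species are compared all-to-all; transcripts are classified
by the datasets in which they have passing hits, and single-linkage
components over passing hits form ortholog groups.  The final candidate set
consists of the groups whose members span every dataset.

Sequences here are TR-scale (hundreds of nucleotides), so the full O(nm)
dynamic program is used rather than word seeding; a numba-compiled kernel
accelerates the bulk score-only pass when numba is importable, with a pure
Python fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io import TranscriptRecord
from .motif import enumerate_compatible_motifs, reverse_complement

__all__ = [
    "AlignmentParams",
    "LocalAlignment",
    "PresenceMatrix",
    "OrthologGroup",
    "PairwiseHit",
    "local_align",
    "sw_score",
    "cross_compare",
    "classify_and_group",
    "extend_orthologs",
    "identity_to_consensus",
    "mean_pairwise_identity",
]

_NEG = -(10**9)
_MAX_LEN = 100_000


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and hit-acceptance parameters (BLASTN-style defaults)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 40
    min_identity: float = 0.70
    min_length: int = 40

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")

    def relaxed(self) -> "AlignmentParams":
        """The permissive pass: +1/-1 scoring with a halved score cutoff."""
        return replace(self, match=1, mismatch=-1, min_score=self.min_score // 2)


@dataclass(frozen=True)
class LocalAlignment:
    """One optimal local alignment.

    Intervals are 0-based half-open on the original (input-orientation)
    sequences; for a minus-strand alignment the subject interval refers to
    the forward coordinates of the subject.  Identity counts gap columns in
    the denominator.
    """

    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    score: int
    identity: float
    strand: str  # '+' or '-'
    aligned_length: int
    aligned_query: str = ""
    aligned_subject: str = ""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _gotoh_score_py(A: np.ndarray, B: np.ndarray, match: int, mismatch: int,
                    oe: int, ext: int) -> int:
    n, m = len(A), len(B)
    H = [0] * (m + 1)
    F = [_NEG] * (m + 1)
    best = 0
    for i in range(n):
        ai = A[i]
        E = _NEG
        diag = 0
        for j in range(1, m + 1):
            E = max(H[j - 1] - oe, E - ext)
            F[j] = max(H[j] - oe, F[j] - ext)
            s = match if ai == B[j - 1] else mismatch
            h = diag + s
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def _gotoh_score_kernel(A, B, match, mismatch, oe, ext):
    # body mirrors _gotoh_score_py; kept separate so numba sees a plain loop
    n = A.shape[0]
    m = B.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, -(10**9), dtype=np.int64)
    best = 0
    for i in range(n):
        ai = A[i]
        E = -(10**9)
        diag = 0
        for j in range(1, m + 1):
            e1 = H[j - 1] - oe
            e2 = E - ext
            E = e1 if e1 > e2 else e2
            f1 = H[j] - oe
            f2 = F[j] - ext
            F[j] = f1 if f1 > f2 else f2
            s = match if ai == B[j - 1] else mismatch
            h = diag + s
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


try:  # compiled bulk kernel; falls back to the python loop
    from numba import njit

    _gotoh_score_fast = njit(cache=True)(_gotoh_score_kernel)
except Exception:  # pragma: no cover - numba present in supported envs
    _gotoh_score_fast = None


def sw_score(a: str, b: str, params: AlignmentParams,
             both_strands: bool = True) -> tuple[int, str]:
    """Best local-alignment score (and strand) without traceback."""
    _check_sizes(a, b)
    oe = params.gap_open + params.gap_extend
    A, Bp = _encode(a), _encode(b)
    if _gotoh_score_fast is not None:
        score_fn = _gotoh_score_fast
    else:
        score_fn = _gotoh_score_py
    best = int(score_fn(A, Bp, params.match, params.mismatch, oe, params.gap_extend))
    strand = "+"
    if both_strands:
        Bm = _encode(reverse_complement(b))
        minus = int(score_fn(A, Bm, params.match, params.mismatch, oe, params.gap_extend))
        if minus > best:
            best, strand = minus, "-"
    return best, strand


def _check_sizes(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) > _MAX_LEN or len(b) > _MAX_LEN:
        raise ValueError(
            f"sequence exceeds the {_MAX_LEN} nt cap of this TR-scale aligner"
        )


def _align_plus(a: str, b: str, params: AlignmentParams) -> LocalAlignment:
    """Full DP with traceback on the given orientations.

    Traceback ties are broken diagonal > up (gap in subject) > left (gap in
    query); among equal-scoring end cells the smallest (i, j) wins.
    """
    n, m = len(a), len(b)
    match, mismatch = params.match, params.mismatch
    oe = params.gap_open + params.gap_extend
    ext = params.gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - oe, Ei[j - 1] - ext)
            Fi[j] = max(Hi1[j] - oe, Fi1[j] - ext)
            s = match if ai == b[j - 1] else mismatch
            h = max(0, Hi1[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return LocalAlignment((0, 0), (0, 0), 0, 0.0, "+", 0)

    # traceback
    i, j, state = bi, bj, "H"
    cols_q: list[str] = []
    cols_s: list[str] = []
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + s:
                cols_q.append(a[i - 1])
                cols_s.append(b[j - 1])
                i, j = i - 1, j - 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - defensive
                raise AssertionError("inconsistent traceback")
        elif state == "F":
            cols_q.append(a[i - 1])
            cols_s.append("-")
            if F[i, j] == H[i - 1, j] - oe:
                state = "H"
            i -= 1
        else:  # E
            cols_q.append("-")
            cols_s.append(b[j - 1])
            if E[i, j] == H[i, j - 1] - oe:
                state = "H"
            j -= 1
    aq = "".join(reversed(cols_q))
    asub = "".join(reversed(cols_s))
    ncols = len(aq)
    matches = sum(x == y and x != "-" for x, y in zip(aq, asub))
    return LocalAlignment(
        query_interval=(i, bi),
        subject_interval=(j, bj),
        score=int(best),
        identity=matches / ncols,
        strand="+",
        aligned_length=ncols,
        aligned_query=aq,
        aligned_subject=asub,
    )


def local_align(a: str, b: str, params: AlignmentParams | None = None,
                both_strands: bool = True) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of *a* against *b*.

    With ``both_strands`` the reverse complement of *b* is also searched and
    the better strand returned; the subject interval is always reported in
    forward coordinates of *b*.
    """
    params = params or AlignmentParams()
    _check_sizes(a, b)
    plus = _align_plus(a, b, params)
    if not both_strands:
        return plus
    minus = _align_plus(a, reverse_complement(b), params)
    if minus.score > plus.score:
        s, e = minus.subject_interval
        return replace(
            minus,
            strand="-",
            subject_interval=(len(b) - e, len(b) - s),
        )
    return plus


@dataclass(frozen=True)
class PairwiseHit:
    """A passing hit between candidates of two datasets."""

    query: tuple[str, str]  # (dataset, id)
    subject: tuple[str, str]
    alignment: LocalAlignment


@dataclass
class PresenceMatrix:
    """Candidate x dataset boolean homology-presence matrix with row classes."""

    rows: list[tuple[str, str]]  # (dataset, id), deterministic order
    datasets: list[str]
    values: np.ndarray  # bool, shape (len(rows), len(datasets))
    classes: list[str] = field(default_factory=list)  # per row

    def presence(self, row: tuple[str, str], dataset: str) -> bool:
        return bool(self.values[self.rows.index(row), self.datasets.index(dataset)])


def _passes(aln: LocalAlignment, params: AlignmentParams) -> bool:
    return (
        aln.score >= params.min_score
        and aln.identity >= params.min_identity
        and aln.aligned_length >= params.min_length
    )


def cross_compare(
    candidate_sets: dict[str, Sequence[TranscriptRecord]],
    params: AlignmentParams | None = None,
    word_prefilter: int | None = None,
) -> tuple[PresenceMatrix, list[PairwiseHit]]:
    """All-to-all comparison of per-dataset candidate sets.

    A candidate is present in another dataset when some candidate there
    aligns with score >= min_score, identity >= min_identity and aligned
    length >= min_length.  Returns the presence matrix (with per-row classes
    shared_in_all / shared_in_some / unique) and the list of passing
    pairwise hits.  ``word_prefilter=k`` skips pairs sharing no exact k-mer
    (an optional shortcut for very large candidate sets; off by default).
    """
    params = params or AlignmentParams()
    if len(candidate_sets) < 2:
        raise ValueError("cross comparison needs at least two datasets")
    datasets = sorted(candidate_sets)
    rows: list[tuple[str, str]] = []
    seqs: dict[tuple[str, str], str] = {}
    for ds in datasets:
        for rec in sorted(candidate_sets[ds], key=lambda r: r.id):
            key = (ds, rec.id)
            rows.append(key)
            seqs[key] = rec.sequence

    kmer_sets: dict[tuple[str, str], frozenset[str]] = {}
    if word_prefilter:
        k = word_prefilter
        for key, s in seqs.items():
            fwd = {s[i : i + k] for i in range(len(s) - k + 1)}
            rc = reverse_complement(s)
            fwd.update(rc[i : i + k] for i in range(len(rc) - k + 1))
            kmer_sets[key] = frozenset(fwd)

    values = np.zeros((len(rows), len(datasets)), dtype=bool)
    row_index = {key: r for r, key in enumerate(rows)}
    ds_index = {ds: c for c, ds in enumerate(datasets)}
    for key in rows:
        values[row_index[key], ds_index[key[0]]] = True  # own dataset

    hits: list[PairwiseHit] = []
    for x, key_a in enumerate(rows):
        for key_b in rows[x + 1 :]:
            if key_a[0] == key_b[0]:
                continue
            if word_prefilter and kmer_sets[key_a].isdisjoint(kmer_sets[key_b]):
                continue
            a, b = seqs[key_a], seqs[key_b]
            score, strand = sw_score(a, b, params)
            if score < params.min_score:
                continue
            if strand == "+":
                aln = _align_plus(a, b, params)
            else:
                aln = local_align(a, b, params)
            if _passes(aln, params):
                values[row_index[key_a], ds_index[key_b[0]]] = True
                values[row_index[key_b], ds_index[key_a[0]]] = True
                hits.append(PairwiseHit(key_a, key_b, aln))

    classes = []
    for r, key in enumerate(rows):
        n_present = int(values[r].sum())
        if n_present == len(datasets):
            classes.append("shared_in_all")
        elif n_present > 1:
            classes.append("shared_in_some")
        else:
            classes.append("unique")
    return PresenceMatrix(rows, datasets, values, classes), hits


@dataclass(frozen=True)
class OrthologGroup:
    """A single-linkage component of candidates under passing pairwise hits."""

    members: tuple[tuple[str, str], ...]
    datasets_covered: frozenset[str]
    representative: tuple[str, str]


def classify_and_group(
    matrix: PresenceMatrix,
    hits: list[PairwiseHit],
    sequences: dict[tuple[str, str], str] | None = None,
) -> tuple[list[OrthologGroup], list[OrthologGroup]]:
    """Build ortholog groups and the final candidate set.

    Groups are connected components under passing hits (single linkage).
    The final set comprises groups whose members span every dataset of the
    matrix.  Returns (all groups, final set), groups sorted by dataset
    coverage then size, both descending.  ``sequences`` (key -> sequence)
    lets the representative be the longest member; without it the
    lexicographically smallest id represents.
    """
    parent = {key: key for key in matrix.rows}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for hit in hits:
        ra, rb = find(hit.query), find(hit.subject)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    comps: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for key in matrix.rows:
        comps.setdefault(find(key), []).append(key)

    groups = []
    for members in comps.values():
        members = tuple(sorted(members))
        covered = frozenset(ds for ds, _ in members)
        if sequences:
            rep = min(members, key=lambda k: (-len(sequences[k]), k[1], k[0]))
        else:
            rep = min(members, key=lambda k: (k[1], k[0]))
        groups.append(OrthologGroup(members, covered, rep))
    groups.sort(key=lambda g: (-len(g.datasets_covered), -len(g.members), g.members))
    final = [g for g in groups if g.datasets_covered == set(matrix.datasets)]
    return groups, final


@dataclass(frozen=True)
class ExtendHit:
    """A ranked hit from query-driven ortholog extension."""

    target_id: str
    alignment: LocalAlignment
    has_template_window: bool


def extend_orthologs(
    query: TranscriptRecord,
    targets: Iterable[TranscriptRecord],
    params: AlignmentParams | None = None,
    relaxed: bool = False,
    min_unit: int = 5,
    max_unit: int = 15,
) -> list[ExtendHit]:
    """Search a new species' transcripts with a known TR as query.

    ``relaxed`` switches to the permissive +1/-1 scoring with a halved score
    cutoff — the second-pass search used when orthologs are too diverged for
    strict scoring.  Each passing hit is annotated with whether the target
    contains a periodic template window (a telomere-template-like stretch),
    the computational stand-in for manual inspection of conserved regions.
    """
    params = params or AlignmentParams()
    if relaxed:
        params = params.relaxed()
    out: list[ExtendHit] = []
    for rec in targets:
        score, strand = sw_score(query.sequence, rec.sequence, params)
        if score < params.min_score:
            continue
        aln = local_align(query.sequence, rec.sequence, params)
        windows = enumerate_compatible_motifs(rec.sequence, min_unit, max_unit)
        out.append(ExtendHit(rec.id, aln, bool(windows)))
    out.sort(key=lambda h: (-h.alignment.score, h.target_id))
    return out


def _consensus(msa: Sequence[str]) -> str:
    ncol = len(msa[0])
    cons = []
    for c in range(ncol):
        counts: dict[str, int] = {}
        for row in msa:
            ch = row[c]
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            cons.append("-")
        else:
            best = max(counts.values())
            cons.append(min(ch for ch, k in counts.items() if k == best))
    return "".join(cons)


def identity_to_consensus(msa: Sequence[str]) -> tuple[list[float], float, str]:
    """Per-sequence and mean identity to the majority-rule consensus.

    Consensus: per-column majority over non-gap residues (tie broken
    alphabetically; all-gap columns stay gaps).  A sequence's identity is
    its matches to the consensus over the columns where it is non-gap.
    Returns (per-sequence identities, mean, consensus).
    """
    if not msa:
        raise ValueError("empty alignment")
    ncol = len(msa[0])
    if any(len(row) != ncol for row in msa):
        raise ValueError("ragged alignment: rows differ in aligned length")
    cons = _consensus(msa)
    idents: list[float] = []
    for row in msa:
        non_gap = sum(ch != "-" for ch in row)
        if non_gap == 0:
            idents.append(0.0)
            continue
        matches = sum(ch != "-" and ch == cc for ch, cc in zip(row, cons))
        idents.append(matches / non_gap)
    return idents, float(np.mean(idents)), cons


def mean_pairwise_identity(msa: Sequence[str]) -> float:
    """Mean identity over all row pairs (columns where both are non-gap) —
    the alternative reading of 'pairwise identity' for a consensus report."""
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    ncol = len(msa[0])
    if any(len(row) != ncol for row in msa):
        raise ValueError("ragged alignment: rows differ in aligned length")
    vals = []
    for i in range(len(msa)):
        for j in range(i + 1, len(msa)):
            both = [(x, y) for x, y in zip(msa[i], msa[j]) if x != "-" and y != "-"]
            if both:
                vals.append(sum(x == y for x, y in both) / len(both))
    return float(np.mean(vals))
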