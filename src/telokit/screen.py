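"""Candidate-TR screening of assembled transcriptomes.

Transcripts containing any minimal-template permutation of the telomere
repeat are pulled out of each per-species transcript set.  Matching is exact
and case-insensitive over the full (unwrapped) sequence; with
``strand_mode="both"`` a transcript also hits when it contains the reverse
complement of a permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import TranscriptRecord
from .motif import reverse_complement

__all__ = ["CandidateHit", "scan_transcripts", "summarize_screen"]


@dataclass(frozen=True)
class CandidateHit:
    """All occurrences of one permutation in one transcript (one strand)."""

    transcript: TranscriptRecord
    permutation: str
    positions: tuple[int, ...]
    strand: str = "sense"  # sense | antisense

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"bad strand {self.strand!r}")
        target = (
            self.permutation
            if self.strand == "sense"
            else reverse_complement(self.permutation)
        )
        k = len(target)
        seq = self.transcript.sequence
        for p in self.positions:
            if seq[p : p + k] != target:
                raise ValueError(
                    f"position {p} in {self.transcript.id} does not match "
                    f"{target!r}"
                )


def _find_all(seq: str, sub: str) -> tuple[int, ...]:
    """All (possibly overlapping) start offsets of sub in seq."""
    out = []
    i = seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return tuple(out)


def scan_transcripts(
    records,
    permutations: set[str] | frozenset[str] | list[str],
    strand_mode: str = "sense",
) -> list[CandidateHit]:
    """Screen transcripts for minimal-template permutations.

    Parameters
    ----------
    records:
        Iterable of TranscriptRecord (whole sequences; FASTA line wrapping is
        irrelevant here, unlike a line-based grep).
    permutations:
        Non-empty set of equal-length permutation strings.
    strand_mode:
        "sense" (stranded assemblies; the default) or "both".
    """
    perms = sorted(set(p.upper() for p in permutations))
    if not perms:
        raise ValueError("permutation set must be non-empty")
    lengths = {len(p) for p in perms}
    if len(lengths) != 1:
        raise ValueError(f"permutations must share one length, got {sorted(lengths)}")
    if strand_mode not in ("sense", "both"):
        raise ValueError(f"strand_mode must be 'sense' or 'both', got {strand_mode!r}")

    seen_ids: dict[str, set[str]] = {}
    hits: list[CandidateHit] = []
    for rec in records:
        ids = seen_ids.setdefault(rec.dataset, set())
        if rec.id in ids:
            raise ValueError(
                f"duplicate transcript id {rec.id!r} within dataset {rec.dataset!r}"
            )
        ids.add(rec.id)
        seq = rec.sequence
        for perm in perms:
            pos = _find_all(seq, perm)
            if pos:
                hits.append(CandidateHit(rec, perm, pos, "sense"))
            if strand_mode == "both":
                rc = reverse_complement(perm)
                pos = _find_all(seq, rc)
                if pos:
                    hits.append(CandidateHit(rec, perm, pos, "antisense"))
    return hits


@dataclass
class ScreenReport:
    """Per-dataset screening summary."""

    datasets: list[str]
    total_transcripts: dict[str, int]
    candidate_transcripts: dict[str, int]
    hits_per_permutation: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, str, int]]:
        rows = []
        for ds in self.datasets:
            for perm in sorted(self.hits_per_permutation.get(ds, {})):
                rows.append((ds, perm, self.hits_per_permutation[ds][perm]))
        return rows


def summarize_screen(
    hits: list[CandidateHit], totals: dict[str, int]
) -> ScreenReport:
    """Summarize a screen: total vs candidate transcript counts per dataset
    and hit counts per permutation, in deterministic (dataset, permutation)
    order."""
    for hit in hits:
        if hit.transcript.dataset not in totals:
            raise ValueError(
                f"dataset {hit.transcript.dataset!r} in hits but not in totals"
            )
    datasets = sorted(totals)
    candidates: dict[str, set[str]] = {ds: set() for ds in datasets}
    per_perm: dict[str, dict[str, int]] = {ds: {} for ds in datasets}
    for hit in hits:
        ds = hit.transcript.dataset
        candidates[ds].add(hit.transcript.id)
        per_perm[ds][hit.permutation] = (
            per_perm[ds].get(hit.permutation, 0) + len(hit.positions)
        )
    return ScreenReport(
        datasets=datasets,
        total_transcripts={ds: totals[ds] for ds in datasets},
        candidate_transcripts={ds: len(candidates[ds]) for ds in datasets},
        hits_per_permutation=per_perm,
    )
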