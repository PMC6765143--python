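"""Telomere-motif algebra.

A telomere repeat is a circular object: all rotations of the unit denote the
same motif.  The telomerase RNA (TR) template region is a C-rich stretch of
the TR transcript corresponding to the C-strand of the telomere repeat,
elongated by at least one nucleotide beyond a full unit (the anchor that
pairs with the existing telomere 3' end).  This module provides rotations,
strand conversion, minimal-template permutation sets, smallest-period
inference, and prediction of the telomere motif a template would synthesize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

__all__ = [
    "AlphabetError",
    "DegenerateTemplateError",
    "NoPeriodicTemplateError",
    "TemplateMotifMismatchError",
    "TelomereMotif",
    "TemplateRegion",
    "reverse_complement",
    "canonical_rotation",
    "display_rotation",
    "minimal_period",
    "c_strand_unit",
    "template_permutations",
    "predict_telomere_motif",
    "template_span",
    "enumerate_compatible_motifs",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STRICT_ALPHABET = frozenset("ACGT")
_ALPHABET_N = frozenset("ACGTN")


class AlphabetError(ValueError):
    """Sequence contains a character outside the allowed nucleotide alphabet."""


class DegenerateTemplateError(ValueError):
    """Template's smallest period is below the minimum plausible unit length."""


class NoPeriodicTemplateError(ValueError):
    """No period within range leaves at least one nucleotide of overhang."""


class TemplateMotifMismatchError(ValueError):
    """Template is not a substring of the motif's circular C-strand repeat."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    if not _ALPHABET_N.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET_N)
        raise AlphabetError(f"non-nucleotide characters: {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_rotation(unit: str) -> str:
    """Lexicographically minimal rotation of *unit* (motif identity form).

    Idempotent, and identical for every rotation of the same unit, so it can
    serve as a dictionary key for "same telomere motif".
    """
    if not unit:
        raise ValueError("empty unit has no rotations")
    doubled = unit + unit
    n = len(unit)
    return min(doubled[i : i + n] for i in range(n))


def _circular_g_runs(unit: str) -> list[tuple[int, int]]:
    """Maximal circular runs of G as (start, length), start in [0, len)."""
    n = len(unit)
    if set(unit) == {"G"}:
        return [(0, n)]
    runs: list[tuple[int, int]] = []
    doubled = unit + unit
    i = 0
    while i < n:
        if doubled[i] == "G" and doubled[i - 1 if i else n - 1] != "G":
            j = i
            while j < i + n and doubled[j] == "G":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def display_rotation(unit: str) -> str:
    """Human-facing rotation: start immediately 3' of the longest circular G-run.

    Telomere motifs are conventionally written ending in the G-tract
    (TTTAGGG, TTAGGG, CTCGGTTATGGG).  Ties between equally long G-runs are
    broken by taking the lexicographically smallest of the tied rotations.
    Units without any G fall back to the canonical rotation.
    """
    runs = _circular_g_runs(unit)
    if not runs:
        return canonical_rotation(unit)
    best = max(length for _, length in runs)
    n = len(unit)
    doubled = unit + unit
    candidates = [
        doubled[(start + length) % n : (start + length) % n + n]
        for start, length in runs
        if length == best
    ]
    return min(candidates)


def minimal_period(seq: str) -> int:
    """Smallest p >= 1 with seq[i] == seq[i+p] for all i < len(seq) - p.

    Equals len(seq) when the string has no smaller period.
    """
    if not seq:
        raise ValueError("empty sequence has no period")
    n = len(seq)
    for p in range(1, n):
        if all(seq[i] == seq[i + p] for i in range(n - p)):
            return p
    return n


@dataclass(frozen=True)
class TelomereMotif:
    """A primitive circular telomere repeat unit, G-strand convention.

    Parameters
    ----------
    g_strand_unit:
        Repeat unit written 5'->3' on the G-rich strand, in any rotation.

    Raises
    ------
    AlphabetError
        If the unit contains characters outside {A, C, G, T}.
    ValueError
        If the unit is empty or non-primitive (its smallest period is
        shorter than its length, e.g. "TTAGGGTTAGGG").
    """

    g_strand_unit: str
    length: int = field(init=False)
    canonical_form: str = field(init=False)
    display_form: str = field(init=False)

    def __post_init__(self) -> None:
        unit = self.g_strand_unit
        if not unit:
            raise ValueError("telomere motif unit must be non-empty")
        if not _STRICT_ALPHABET.issuperset(unit):
            bad = sorted(set(unit) - _STRICT_ALPHABET)
            raise AlphabetError(f"motif unit restricted to ACGT, got {bad!r}")
        p = minimal_period(unit)
        if p < len(unit) and len(unit) % p == 0:
            raise ValueError(
                f"unit {unit!r} is non-primitive (it is a whole repetition "
                f"of its {p}-nt prefix)"
            )
        object.__setattr__(self, "length", len(unit))
        object.__setattr__(self, "canonical_form", canonical_rotation(unit))
        object.__setattr__(self, "display_form", display_rotation(unit))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, TelomereMotif):
            return self.canonical_form == other.canonical_form
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.canonical_form)

    def __str__(self) -> str:
        return self.display_form


def c_strand_unit(motif: TelomereMotif) -> str:
    """One rotation of the C-strand (template-strand) repeat unit."""
    return reverse_complement(motif.g_strand_unit)


def template_permutations(motif: TelomereMotif, extension: int = 1) -> set[str]:
    """All minimal-template permutations: distinct (L + extension)-mers of the
    circular C-strand repeat.

    For a primitive L-bp motif and extension < L this yields exactly L
    strings — the screening k-mers used to pull candidate TR transcripts out
    of an assembled transcriptome.
    """
    if extension < 1:
        raise ValueError("extension must be >= 1")
    unit = c_strand_unit(motif)
    L = len(unit)
    if extension >= L:
        warnings.warn(
            f"extension {extension} >= unit length {L}: permutations wrap "
            "more than one full repeat",
            stacklevel=2,
        )
    reps = unit * (2 + extension // L)
    k = L + extension
    return {reps[i : i + k] for i in range(L)}


@dataclass(frozen=True)
class TemplateRegion:
    """A C-rich TR subsequence consistent with a circular telomere repeat.

    ``unit_c`` is the first period-length prefix of the template; the motif
    the template would direct telomerase to synthesize is the reverse
    complement of that unit (reported in display rotation).  ``anchor_nt``
    is the overhang beyond whole repeat units: for templates spanning less
    than two units it is length - period (the paper-style "additional N nt"
    anchor); beyond that, length mod period.
    """

    sequence: str
    period: int
    unit_c: str
    predicted_motif: TelomereMotif
    anchor_nt: int
    span_units: Fraction
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.span_units * self.period != len(self.sequence):
            raise ValueError("span_units inconsistent with period and length")


def _anchor_nt(length: int, period: int) -> int:
    if length < 2 * period:
        return length - period
    return length % period


def predict_telomere_motif(
    template: str, min_unit: int = 5, max_unit: int = 15
) -> TemplateRegion:
    """Infer the repeat unit of a template region and predict its telomere motif.

    The template must repeat with some period in [min_unit, max_unit] and be
    elongated by at least one nucleotide beyond one full unit.

    Examples
    --------
    >>> predict_telomere_motif("CTAAACCCT").predicted_motif.display_form
    'TTTAGGG'
    >>> predict_telomere_motif("AACCGAGCCCATAACCGA").span_units
    Fraction(3, 2)
    """
    if not _STRICT_ALPHABET.issuperset(template):
        bad = sorted(set(template) - _STRICT_ALPHABET)
        raise AlphabetError(f"template restricted to ACGT, got {bad!r}")
    if len(template) < min_unit + 1:
        raise NoPeriodicTemplateError(
            f"template of {len(template)} nt cannot hold a {min_unit}-nt unit "
            "plus a 1-nt anchor"
        )
    period = minimal_period(template)
    if period < min_unit:
        raise DegenerateTemplateError(
            f"degenerate template: smallest period {period} < min_unit {min_unit}"
        )
    if period > max_unit or len(template) < period + 1:
        raise NoPeriodicTemplateError(
            f"no periodic template: smallest period {period} exceeds "
            f"max_unit {max_unit} or leaves no anchor overhang"
        )
    unit_c = template[:period]
    motif = TelomereMotif(display_rotation(reverse_complement(unit_c)))
    return TemplateRegion(
        sequence=template,
        period=period,
        unit_c=unit_c,
        predicted_motif=motif,
        anchor_nt=_anchor_nt(len(template), period),
        span_units=Fraction(len(template), period),
    )


def template_span(template: str, motif: TelomereMotif) -> Fraction:
    """Span of *template* in telomere repeat units of *motif*.

    Verifies that the template is a substring of the circular C-strand
    repeat before dividing; an 18-nt template over a 12-bp unit spans 3/2
    units.
    """
    unit = c_strand_unit(motif)
    L = len(unit)
    reps = unit * (len(template) // L + 2)
    if not template or template not in reps:
        raise TemplateMotifMismatchError(
            f"template {template!r} is not a substring of the circular "
            f"C-strand repeat of motif {motif.display_form}"
        )
    return Fraction(len(template), L)


def enumerate_compatible_motifs(
    template: str, min_unit: int = 5, max_unit: int = 15
) -> list[tuple[tuple[int, int], TelomereMotif]]:
    """All maximal periodic windows of *template* and their predicted motifs.

    For every period p in [min_unit, max_unit], every maximal window that is
    p-periodic with length >= p + 1 yields one ((start, end), motif) entry
    (0-based half-open).  Windows whose length-p unit is itself periodic are
    skipped: the shorter true period already reports that motif.  Mixed-type
    templates (e.g. adjacent human- and Arabidopsis-type stretches) produce
    several entries.  Windows containing N are never periodic.  Sorted by
    window length descending, then period ascending, then start.
    """
    n = len(template)
    entries: list[tuple[tuple[int, int], TelomereMotif]] = []
    for p in range(min_unit, max_unit + 1):
        if n < p + 1:
            break
        i = 0
        while i < n - p:
            if template[i] == template[i + p] and template[i] in _STRICT_ALPHABET:
                j = i
                while (
                    j < n - p
                    and template[j] == template[j + p]
                    and template[j] in _STRICT_ALPHABET
                ):
                    j += 1
                start, end = i, j + p
                window = template[start:end]
                unit = window[:p]
                q = minimal_period(unit)
                if not (q < p and p % q == 0) and _STRICT_ALPHABET.issuperset(
                    window
                ):
                    motif = TelomereMotif(display_rotation(reverse_complement(unit)))
                    entries.append(((start, end), motif))
                i = j + 1
            else:
                i += 1
    entries.sort(key=lambda e: (-(e[0][1] - e[0][0]), _entry_period(e), e[0][0]))
    return entries


def _entry_period(entry: tuple[tuple[int, int], TelomereMotif]) -> int:
    return entry[1].length
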