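"""Annotation of candidate TR transcripts and genes.

Plant TR genes share a conserved architecture: an Upstream Sequence Element
(USE) and TATA box in the Pol III promoter, a 5' G-rich region, the template
domain, a conserved box downstream of it, C-rich and AT-rich regions toward
the 3' end, and a poly-T Pol III terminator.  This module locates these
elements on a TR transcript and its genomic context: the template domain via
periodic-window search, compositional regions via sliding windows, promoter
elements via log-odds position weight matrices built from user-supplied site
alignments, and the terminator as a thymidine run.  Read-based support for
the transcript ends (TSS/TTS) is computed by terminal k-mer containment.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .io import write_gff3
from .motif import (
    TemplateRegion,
    enumerate_compatible_motifs,
    reverse_complement,
)

__all__ = [
    "PWM",
    "FeatureAnnotation",
    "find_template_domain",
    "composition_scan",
    "build_pwm",
    "scan_pwm",
    "find_pol3_terminator",
    "end_support",
    "annotate_tr",
    "fallback_tata_scan",
]

FEATURE_TYPES = frozenset(
    {"template", "g_rich", "c_rich", "at_rich", "tata", "use", "terminator",
     "conserved_box"}
)

DEFAULT_COMPOSITION_THRESHOLDS = {"g_rich": 0.5, "c_rich": 0.5, "at_rich": 0.8}
UNIFORM_BACKGROUND = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass(frozen=True)
class FeatureAnnotation:
    """A located TR gene element, 0-based half-open on the annotated sequence."""

    feature: str
    interval: tuple[int, int]
    score: float
    strand: str = "+"
    note: str = ""

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature!r}")
        if self.interval[0] < 0 or self.interval[1] < self.interval[0]:
            raise ValueError(f"bad interval {self.interval}")


def find_template_domain(
    tr_seq: str,
    min_unit: int = 5,
    max_unit: int = 15,
    min_span: Fraction = Fraction(9, 7),
) -> list[TemplateRegion]:
    """Candidate template domains of a TR transcript.

    Maximal periodic windows are filtered for biological plausibility: span
    at least ``min_span`` repeat units (default 9/7, one unit plus the
    2-nt Arabidopsis-style anchor), a C-strand unit with C content >= 0.25,
    and at least three distinct bases in the unit (rejecting low-complexity
    tracts).  Ranked by span (descending), then 5'-most first.
    """
    candidates: list[TemplateRegion] = []
    for (start, end), motif in enumerate_compatible_motifs(tr_seq, min_unit, max_unit):
        window = tr_seq[start:end]
        p = motif.length
        span = Fraction(len(window), p)
        if span < min_span:
            continue
        unit_c = window[:p]
        if unit_c.count("C") / p < 0.25:
            continue
        if len(set(unit_c)) < 3:
            continue
        anchor = len(window) - p if len(window) < 2 * p else len(window) % p
        candidates.append(
            TemplateRegion(
                sequence=window,
                period=p,
                unit_c=unit_c,
                predicted_motif=motif,
                anchor_nt=anchor,
                span_units=span,
                start=start,
                end=end,
            )
        )
    candidates.sort(key=lambda t: (-t.span_units, t.start))
    return candidates


def composition_scan(
    seq: str,
    window: int = 15,
    thresholds: dict[str, float] | None = None,
) -> list[FeatureAnnotation]:
    """Sliding-window base-composition features (g_rich / c_rich / at_rich).

    Windows meeting a threshold are merged (adjacent or overlapping, same
    type) into maximal intervals scored by the best window inside them.
    """
    th = dict(DEFAULT_COMPOSITION_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")

    def frac(w: str, feature: str) -> float:
        if feature == "g_rich":
            return w.count("G") / len(w)
        if feature == "c_rich":
            return w.count("C") / len(w)
        return (w.count("A") + w.count("T")) / len(w)

    favored = {"g_rich": set("G"), "c_rich": set("C"), "at_rich": set("AT")}

    def emit(feature, s, e):
        # trim terminal bases that do not belong to the composition class,
        # then rescore as the best full window inside the trimmed interval
        fav = favored[feature]
        while s < e and seq[s] not in fav:
            s += 1
        while e > s and seq[e - 1] not in fav:
            e -= 1
        if s >= e:
            return None
        if e - s >= window:
            score = max(
                frac(seq[i : i + window], feature) for i in range(s, e - window + 1)
            )
        else:
            score = frac(seq[s:e], feature)
        return FeatureAnnotation(feature, (s, e), score)

    out: list[FeatureAnnotation] = []
    for feature in ("g_rich", "c_rich", "at_rich"):
        cut = th[feature]
        open_start = None
        open_end = 0
        for i in range(len(seq) - window + 1):
            f = frac(seq[i : i + window], feature)
            if f >= cut:
                if open_start is None or i > open_end:
                    if open_start is not None:
                        feat = emit(feature, open_start, open_end)
                        if feat:
                            out.append(feat)
                    open_start = i
                open_end = i + window
        if open_start is not None:
            feat = emit(feature, open_start, open_end)
            if feat:
                out.append(feat)
    out.sort(key=lambda a: (a.interval, a.feature))
    return out


@dataclass(frozen=True)
class PWM:
    """Log-odds (base 2) position weight matrix with pseudocounts."""

    weights: tuple[dict[str, float], ...]
    background: dict[str, float]
    n_sites: int

    @property
    def length(self) -> int:
        return len(self.weights)

    @property
    def max_score(self) -> float:
        return sum(max(col.values()) for col in self.weights)

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length must equal PWM length")
        total = 0.0
        for col, ch in zip(self.weights, window):
            if ch not in col:
                return -math.inf  # N or other ambiguity: unscorable window
            total += col[ch]
        return total


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.5,
    background: dict[str, float] | None = None,
) -> PWM:
    """Build a PWM from >= 2 equal-length ungapped aligned sites.

    weight[i][b] = log2(((count_ib + pseudocount) / (n + 4 * pseudocount))
    / background[b]).
    """
    if len(sites) < 2:
        raise ValueError("need at least two aligned sites")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("sites must all have the same length")
    if any("-" in s for s in sites):
        raise ValueError("sites must be ungapped")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = dict(background or UNIFORM_BACKGROUND)
    n = len(sites)
    cols = []
    for i in range(length):
        counts = {b: 0 for b in "ACGT"}
        for s in sites:
            ch = s[i].upper()
            if ch not in counts:
                raise ValueError(f"non-ACGT character {ch!r} in site column {i}")
            counts[ch] += 1
        col = {
            b: math.log2(
                ((counts[b] + pseudocount) / (n + 4 * pseudocount)) / bg[b]
            )
            for b in "ACGT"
        }
        cols.append(col)
    return PWM(tuple(cols), bg, n)


def scan_pwm(
    seq: str,
    pwm: PWM,
    feature: str = "use",
    min_fraction_of_max: float = 0.8,
    strand_mode: str = "sense",
    best_per_locus: bool = False,
) -> list[FeatureAnnotation]:
    """All PWM hits scoring >= min_fraction_of_max * max score, best first.

    With ``best_per_locus`` overlapping hits are reduced to the best-scoring
    one per locus.
    """
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than the PWM")
    cutoff = min_fraction_of_max * pwm.max_score
    hits: list[FeatureAnnotation] = []
    strands = [("+", seq)]
    if strand_mode == "both":
        strands.append(("-", reverse_complement(seq)))
    for strand, s in strands:
        for i in range(len(s) - pwm.length + 1):
            sc = pwm.score(s[i : i + pwm.length])
            if sc >= cutoff:
                if strand == "+":
                    iv = (i, i + pwm.length)
                else:
                    iv = (len(seq) - i - pwm.length, len(seq) - i)
                hits.append(FeatureAnnotation(feature, iv, sc, strand))
    hits.sort(key=lambda h: (-h.score, h.interval))
    if best_per_locus:
        kept: list[FeatureAnnotation] = []
        for h in hits:
            if all(
                h.interval[1] <= k.interval[0] or h.interval[0] >= k.interval[1]
                for k in kept
            ):
                kept.append(h)
        hits = kept
    return hits


def fallback_tata_scan(seq: str, max_mismatch: int = 1) -> list[FeatureAnnotation]:
    """Heuristic TATA search: literal TATAAA allowing <= max_mismatch.

    A stopgap when no TATA site alignment is supplied; the score is the
    fraction of matching positions.
    """
    motif = "TATAAA"
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        mm = sum(a != b for a, b in zip(seq[i : i + len(motif)], motif))
        if mm <= max_mismatch:
            hits.append(
                FeatureAnnotation(
                    "tata",
                    (i, i + len(motif)),
                    (len(motif) - mm) / len(motif),
                    note="heuristic",
                )
            )
    hits.sort(key=lambda h: (-h.score, h.interval))
    return hits


def find_pol3_terminator(
    downstream_seq: str, min_t: int = 4, search_span: int = 200
) -> FeatureAnnotation | None:
    """First run of >= min_t consecutive T within search_span of the start.

    RNA polymerase III terminates at a thymidine run on the non-template
    strand; >= 4 T is the usual plant threshold.
    """
    limit = min(len(downstream_seq), search_span)
    i = 0
    while i < limit:
        if downstream_seq[i] == "T":
            j = i
            while j < len(downstream_seq) and downstream_seq[j] == "T":
                j += 1
            if j - i >= min_t:
                return FeatureAnnotation("terminator", (i, j), float(j - i))
            i = j
        else:
            i += 1
    return None


def end_support(
    transcript: str,
    reads: Iterable[str],
    k: int = 20,
    max_mismatch: int = 0,
) -> tuple[int, int]:
    """Read support for the transcript's 5' and 3' ends.

    Counts reads containing the first / last k transcript bases in either
    orientation (a read may support both ends).  ``max_mismatch > 0``
    switches to a fuzzy sliding comparison.
    """
    if k > len(transcript):
        raise ValueError("k exceeds transcript length")
    head, tail = transcript[:k], transcript[-k:]
    n5 = n3 = 0
    for read in reads:
        if k > len(read):
            raise ValueError("k exceeds read length")
        variants = (read, reverse_complement(read))
        if _contains(variants, head, max_mismatch):
            n5 += 1
        if _contains(variants, tail, max_mismatch):
            n3 += 1
    return n5, n3


def _contains(variants: tuple[str, str], kmer: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return any(kmer in v for v in variants)
    k = len(kmer)
    for v in variants:
        for i in range(len(v) - k + 1):
            if sum(a != b for a, b in zip(v[i : i + k], kmer)) <= max_mismatch:
                return True
    return False


@dataclass
class AnnotationResult:
    """Features from one TR annotation run, plus template candidates."""

    transcript_features: list[FeatureAnnotation]
    upstream_features: list[FeatureAnnotation] = field(default_factory=list)
    downstream_features: list[FeatureAnnotation] = field(default_factory=list)
    template_candidates: list[TemplateRegion] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_gff3(self, handle_or_path, seqid: str = "TR") -> None:
        rows = []
        for feat in sorted(self.transcript_features, key=lambda f: f.interval):
            rows.append(
                (seqid, feat.feature, feat.interval[0], feat.interval[1],
                 feat.score, feat.strand)
            )
        for feat in sorted(self.upstream_features, key=lambda f: f.interval):
            rows.append(
                (seqid + "_upstream", feat.feature, feat.interval[0],
                 feat.interval[1], feat.score, feat.strand)
            )
        for feat in sorted(self.downstream_features, key=lambda f: f.interval):
            rows.append(
                (seqid + "_downstream", feat.feature, feat.interval[0],
                 feat.interval[1], feat.score, feat.strand)
            )
        write_gff3(rows, handle_or_path)


def annotate_tr(
    tr_seq: str,
    upstream: str | None = None,
    downstream: str | None = None,
    pwms: dict[str, PWM] | None = None,
    min_unit: int = 5,
    max_unit: int = 15,
    composition_window: int = 15,
    composition_thresholds: dict[str, float] | None = None,
    min_t: int = 4,
    pwm_min_fraction: float = 0.8,
    log=sys.stderr,
) -> AnnotationResult:
    """Full TR gene annotation.

    The transcript is scanned for the template domain and compositional
    regions; promoter PWMs (keys "use", "tata", optionally "conserved_box")
    run on the upstream genomic context only, and the Pol III terminator
    search on the downstream context.  Without upstream context and TATA
    sites, the literal TATAAA fallback runs on the upstream sequence if
    given; promoter features are simply absent otherwise.
    """
    pwms = pwms or {}
    warnings_list: list[str] = []

    template_candidates = find_template_domain(tr_seq, min_unit, max_unit)
    tr_features: list[FeatureAnnotation] = []
    if template_candidates:
        # periodic windows arise by chance in C-rich tracts, so every
        # candidate is reported, annotated with its rank; cross-species
        # conservation, not periodicity alone, settles the true template
        top = template_candidates[0]
        overlapping = [
            t for t in template_candidates[1:]
            if t.start < top.end and top.start < t.end
        ]
        for rank, cand in enumerate(template_candidates, 1):
            tr_features.append(
                FeatureAnnotation(
                    "template",
                    (cand.start, cand.end),
                    float(cand.span_units),
                    note=f"rank={rank};motif={cand.predicted_motif.display_form}",
                )
            )
        if overlapping:
            warnings_list.append(
                f"{len(overlapping)} template candidate(s) overlap the "
                "top-ranked one"
            )
    tr_features.extend(
        composition_scan(tr_seq, composition_window, composition_thresholds)
    )
    if "conserved_box" in pwms:
        tr_features.extend(
            scan_pwm(tr_seq, pwms["conserved_box"], "conserved_box",
                     pwm_min_fraction, best_per_locus=True)
        )
    tr_features.sort(key=lambda f: (f.interval, f.feature))

    up_features: list[FeatureAnnotation] = []
    if upstream:
        if "use" in pwms:
            up_features.extend(
                scan_pwm(upstream, pwms["use"], "use", pwm_min_fraction,
                         best_per_locus=True)
            )
        if "tata" in pwms:
            up_features.extend(
                scan_pwm(upstream, pwms["tata"], "tata", pwm_min_fraction,
                         best_per_locus=True)
            )
        else:
            up_features.extend(fallback_tata_scan(upstream)[:1])
        up_features.sort(key=lambda f: (f.interval, f.feature))
    else:
        warnings_list.append("no upstream context: promoter features not scanned")

    down_features: list[FeatureAnnotation] = []
    if downstream:
        term = find_pol3_terminator(downstream, min_t=min_t)
        if term is not None:
            down_features.append(term)
    else:
        warnings_list.append("no downstream context: terminator not scanned")

    for msg in warnings_list:
        print(f"annotate_tr: {msg}", file=log)
    return AnnotationResult(
        transcript_features=tr_features,
        upstream_features=up_features,
        downstream_features=down_features,
        template_candidates=template_candidates,
        warnings=warnings_list,
    )
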