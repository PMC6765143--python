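"""Computational companions to telomerase activity and telomere length assays.

TRAP (Telomere Repeat Amplification Protocol) products are a substrate
primer elongated by tandem telomere repeats and capped by the reverse
primer's annealing site; sequenced products are decomposed here into
primer + repeat units + trailing partial, and product-length ladders yield
the repeat periodicity.  TRF (Terminal Restriction Fragment) Southern-blot
intensity profiles are summarized by a weighted median telomere length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .motif import TelomereMotif, reverse_complement

__all__ = [
    "TrapDecomposition",
    "TrfProfile",
    "parse_trap_product",
    "ladder_periodicity",
    "trf_weighted_median",
]


@dataclass(frozen=True)
class TrapDecomposition:
    """Structure of one sequenced TRAP product.

    ``units`` holds (unit-as-observed, mismatches-vs-best-rotation) pairs in
    5'->3' order.  Concatenating the observed primer, all unit strings, the
    trailing partial and the reverse-primer segment reconstructs the input
    exactly.
    """

    product: str
    primer_interval: tuple[int, int]
    units: tuple[tuple[str, int], ...]
    n_complete_units: int
    variant_units: int
    trailing_partial: str
    reverse_primer_found: bool
    reverse_primer_segment: str = ""

    def __post_init__(self) -> None:
        rebuilt = (
            self.product[self.primer_interval[0] : self.primer_interval[1]]
            + "".join(u for u, _ in self.units)
            + self.trailing_partial
            + self.reverse_primer_segment
        )
        if rebuilt != self.product:
            raise ValueError("decomposition does not reconstruct the product")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def parse_trap_product(
    product: str,
    substrate_primer: str,
    reverse_primer: str,
    motif: TelomereMotif,
    max_mismatch_per_unit: int = 1,
) -> TrapDecomposition:
    """Greedy left-to-right decomposition of a TRAP product.

    The product must begin with the substrate primer (<= 1 mismatch).  After
    the primer, successive windows of unit length are matched against all
    rotations of the G-strand repeat; the rotation with fewest mismatches is
    accepted when within ``max_mismatch_per_unit`` (ties keep the phase of
    the previous unit).  Parsing stops at the reverse complement of the
    reverse primer or at the end of the sequence; any unmatched remainder is
    the trailing partial.
    """
    if not product:
        raise ValueError("empty product")
    np_ = len(substrate_primer)
    if len(product) < np_ or _hamming(product[:np_], substrate_primer) > 1:
        raise ValueError("primer not located at the product 5' end")

    unit0 = motif.display_form
    L = motif.length
    rotations = [(unit0 + unit0)[r : r + L] for r in range(L)]
    rev_site = reverse_complement(reverse_primer)

    units: list[tuple[str, int]] = []
    pos = np_
    prev_rot: int | None = None
    rev_found = False
    rev_segment = ""
    while True:
        rest = product[pos:]
        if rest.startswith(rev_site):
            rev_found = True
            rev_segment = rest
            rest = ""
            break
        if len(rest) < L:
            break
        window = product[pos : pos + L]
        mismatches = [_hamming(window, rot) for rot in rotations]
        best = min(mismatches)
        if best > max_mismatch_per_unit:
            break
        tied = [r for r, mm in enumerate(mismatches) if mm == best]
        if prev_rot in tied:
            rot = prev_rot
        else:
            rot = tied[0]
        units.append((window, best))
        prev_rot = rot
        pos += L

    trailing = "" if rev_found else product[pos:]
    if not rev_found and rev_site and rev_site in trailing:
        # reverse primer reached mid-window: split it off the remainder
        cut = trailing.index(rev_site)
        rev_found = True
        rev_segment = trailing[cut:]
        trailing = trailing[:cut]
    return TrapDecomposition(
        product=product,
        primer_interval=(0, np_),
        units=tuple(units),
        n_complete_units=len(units),
        variant_units=sum(1 for _, mm in units if mm > 0),
        trailing_partial=trailing,
        reverse_primer_found=rev_found,
        reverse_primer_segment=rev_segment,
    )


def ladder_periodicity(product_lengths: Sequence[int]) -> int:
    """Periodicity of a TRAP ladder: the modal gap between successive
    distinct product lengths (ties broken toward the smaller gap)."""
    if len(product_lengths) < 3:
        raise ValueError("need at least three product lengths")
    uniq = sorted(set(product_lengths))
    diffs = [b - a for a, b in zip(uniq, uniq[1:])]
    if not diffs:
        raise ValueError("all product lengths identical")
    counts: dict[int, int] = {}
    for d in diffs:
        counts[d] = counts.get(d, 0) + 1
    best = max(counts.values())
    return min(d for d, k in counts.items() if k == best)


@dataclass(frozen=True)
class TrfProfile:
    """A TRF lane as an ordered (fragment size in bp, intensity) profile."""

    points: tuple[tuple[float, float], ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        sizes = [s for s, _ in self.points]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        if any(i < 0 for _, i in self.points):
            raise ValueError("intensities must be non-negative")
        if sum(max(i - self.background, 0.0) for _, i in self.points) <= 0:
            raise ValueError("no intensity above background")


def trf_weighted_median(profile: TrfProfile, length_correction: bool = True) -> float:
    """Weighted median telomere length from a TRF intensity profile.

    With ``length_correction`` (default) each band's weight is
    intensity / size — the molar correction for longer fragments binding
    proportionally more probe; without it, raw intensity.  The result is the
    smallest size whose cumulative normalized weight reaches 0.5.
    """
    weights = []
    for size, intensity in profile.points:
        inten = max(intensity - profile.background, 0.0)
        weights.append(inten / size if length_correction else inten)
    total = sum(weights)
    if total <= 0:
        raise ValueError("no intensity above background")
    acc = 0.0
    for (size, _), w in zip(profile.points, weights):
        acc += w / total
        if acc >= 0.5:
            return float(size)
    return float(profile.points[-1][0])  # pragma: no cover - acc reaches 1
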