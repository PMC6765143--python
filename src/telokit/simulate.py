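"""Seeded synthetic data: transcript sets with planted TR orthologs, TR gene
contexts, sequencing reads, TRAP products and TRF profiles.

The transcriptome simulator emulates the statistical structure of a
comparative TR screen: in each of several species' assembled transcript
sets, one true TR ortholog (derived from a common ancestor by independent
substitutions) hides among hundreds of decoy transcripts, a fraction of
which carry a telomere-like minimal-template permutation purely by chance.
All randomness flows from one mandatory seed through a single numpy
Generator; identical specs give byte-identical output.

What this emulates — and what it does not: planted orthologs diverge by
i.i.d. substitutions only (no indels, no assembly fragmentation, no
chimeras), decoys are i.i.d. background rather than real transcripts, and
read simulation is uniform and error-free.  Recovery results on this bed
demonstrate the pipeline's logic, not its behaviour on raw Trinity output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import TranscriptRecord, write_fasta, write_fastq
from .motif import TelomereMotif, c_strand_unit, template_permutations

__all__ = [
    "SimulationSpec",
    "TruthTable",
    "simulate_datasets",
    "simulate_tr_gene",
    "simulate_gene_set",
    "simulate_reads",
    "simulate_trap_products",
    "simulate_trf_profile",
    "USE_CONSENSUS",
    "TATA_CONSENSUS",
]

BASES = np.array(list("ACGT"))

# Planted promoter elements: USE consensus of plant snRNA-type Pol III
# promoters, and the canonical TATA box.
USE_CONSENSUS = "TCCCACATCG"
TATA_CONSENSUS = "TATAAA"

# Synthetic stand-ins for the substrate / reverse TRAP primers (the real
# primer sequences are assay configuration, not built in).
SYNTH_SUBSTRATE_PRIMER = "ACGCTAGCTGACTGAACTCA"
SYNTH_REVERSE_PRIMER = "TGCATCAGGATCCAGTGAAC"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic comparative screen.

    Defaults mirror the regime of a real screen: four species, 500 decoy
    transcripts each (200-600 nt, uniform base composition), 10% of decoys
    contaminated with one random minimal-template permutation, and a planted
    TR family at 15% per-copy divergence from the common ancestor with the
    template protected (a TR whose template has decayed would not be found
    by any template-driven method, nor be a functional telomerase RNA).
    The planted 240-nt transcript carries the conserved architecture:
    5' G-rich region, template (1.5 units for the default motif), conserved
    box, C-rich region and AT-rich tail.
    """

    seed: int
    n_datasets: int = 4
    decoys_per_dataset: int = 500
    decoy_length: tuple[int, int] = (200, 600)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: TelomereMotif = field(default_factory=lambda: TelomereMotif("TTAGGG"))
    transcript_length: int = 240
    g_rich_len: int = 20
    template_whole_units: int = 1
    template_anchor_nt: int = 3
    conserved_box_len: int = 25
    c_rich_len: int = 20
    at_rich_len: int = 15
    divergence: float = 0.15
    contamination: float = 0.10
    protect_template: bool = True

    def __post_init__(self) -> None:
        for rate in (self.divergence, self.contamination):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.template_whole_units < 1 or self.template_anchor_nt < 1:
            raise ValueError("template must span at least one unit plus one nt")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def template_length(self) -> int:
        return self.template_whole_units * self.motif.length + self.template_anchor_nt

    def element_lengths(self) -> dict[str, int]:
        return {
            "g_rich": self.g_rich_len,
            "template": self.template_length,
            "conserved_box": self.conserved_box_len,
            "c_rich": self.c_rich_len,
            "at_rich": self.at_rich_len,
        }


@dataclass
class TruthTable:
    """Ground truth of one simulation run, re-verifiable against the FASTA."""

    planted_id: dict[str, str]  # dataset -> planted TR id
    template_interval: dict[str, tuple[int, int]]  # on the planted transcript
    element_intervals: dict[str, dict[str, tuple[int, int]]]
    contaminated: dict[str, set[str]]  # dataset -> contaminated decoy ids
    ancestor: str = ""


def _random_seq(rng: np.random.Generator, n: int, probs) -> str:
    return "".join(rng.choice(BASES, size=n, p=list(probs)))


def _biased_block(rng: np.random.Generator, n: int, favored: str, p: float) -> str:
    """Block where each favored base has total probability p (split evenly),
    the rest shared by the remaining bases."""
    probs = []
    others = [b for b in "ACGT" if b not in favored]
    for b in "ACGT":
        probs.append(p / len(favored) if b in favored else (1 - p) / len(others))
    return _random_seq(rng, n, probs)


def _build_ancestor(spec: SimulationSpec, rng: np.random.Generator):
    """Ancestral TR transcript with its element intervals."""
    unit = c_strand_unit(spec.motif)
    reps = unit * (spec.template_whole_units + 1)
    template = reps[: spec.template_length]

    blocks = [
        ("g_rich", _biased_block(rng, spec.g_rich_len, "G", 0.85)),
        ("spacer1", None),
        ("template", template),
        ("conserved_box", _random_seq(rng, spec.conserved_box_len, spec.background)),
        ("spacer2", None),
        ("c_rich", _biased_block(rng, spec.c_rich_len, "C", 0.85)),
        ("at_rich", _biased_block(rng, spec.at_rich_len, "AT", 0.9)),
    ]
    fixed = sum(len(s) for _, s in blocks if s is not None)
    filler = spec.transcript_length - fixed
    if filler < 2:
        raise ValueError(
            f"architecture ({fixed} nt of elements) exceeds transcript length "
            f"{spec.transcript_length}"
        )
    len1 = filler // 2
    parts: list[str] = []
    intervals: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, seq in blocks:
        if seq is None:
            seq = _random_seq(rng, len1 if name == "spacer1" else filler - len1,
                              spec.background)
        else:
            intervals[name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)
    return "".join(parts), intervals


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: tuple[int, int] | None = None,
) -> str:
    if rate == 0.0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        if protected and protected[0] <= i < protected[1]:
            continue
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_datasets(
    spec: SimulationSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, list[TranscriptRecord]], TruthTable]:
    """Simulate per-species transcript sets with one planted TR each.

    Returns dataset -> records plus the truth table; with ``out_dir`` each
    dataset is also written as 60-column FASTA (one file per dataset).
    """
    rng = np.random.default_rng(spec.seed)
    ancestor, intervals = _build_ancestor(spec, rng)
    perms = sorted(template_permutations(spec.motif, 1))
    protected = intervals["template"] if spec.protect_template else None

    datasets: dict[str, list[TranscriptRecord]] = {}
    truth = TruthTable(
        planted_id={},
        template_interval={},
        element_intervals={},
        contaminated={},
        ancestor=ancestor,
    )
    lo, hi = spec.decoy_length
    for d in range(spec.n_datasets):
        ds = f"species{d + 1}"
        planted_seq = _mutate(ancestor, spec.divergence, rng, protected)
        tr_id = f"{ds}_TR_planted"
        records = [TranscriptRecord(tr_id, planted_seq, ds)]
        contaminated: set[str] = set()
        for k in range(spec.decoys_per_dataset):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length, spec.background)
            did = f"{ds}_decoy{k + 1}"
            if rng.random() < spec.contamination:
                perm = perms[rng.integers(0, len(perms))]
                at = int(rng.integers(0, length - len(perm) + 1))
                seq = seq[:at] + perm + seq[at + len(perm) :]
                contaminated.add(did)
            records.append(TranscriptRecord(did, seq, ds))
        datasets[ds] = records
        truth.planted_id[ds] = tr_id
        truth.template_interval[ds] = intervals["template"]
        truth.element_intervals[ds] = dict(intervals)
        truth.contaminated[ds] = contaminated

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ds, records in datasets.items():
            write_fasta(records, out_dir / f"{ds}.fasta")
    return datasets, truth


def simulate_tr_gene(
    spec: SimulationSpec,
    rng: np.random.Generator,
    upstream_len: int = 100,
    downstream_len: int = 60,
    use_offset: int = 30,
    tata_offset: int = 68,
    terminator_offset: int = 10,
    terminator_len: int = 6,
    site_noise: float = 0.0,
) -> dict:
    """One full TR gene: upstream promoter context (USE then TATA), the
    transcript, and downstream context with a poly-T terminator.

    Offsets are 0-based starts within the respective context sequences.
    Returns a dict with sequences and planted truth intervals.
    """
    transcript, intervals = _build_ancestor(spec, rng)
    up = list(_random_seq(rng, upstream_len, spec.background))
    use_site = _mutate(USE_CONSENSUS, site_noise, rng)
    tata_site = TATA_CONSENSUS
    up[use_offset : use_offset + len(use_site)] = use_site
    up[tata_offset : tata_offset + len(tata_site)] = tata_site
    down = list(_random_seq(rng, downstream_len, spec.background))
    # keep spontaneous T-runs out of the pre-terminator stretch
    for i in range(terminator_offset):
        if down[i] == "T":
            down[i] = "A"
    down[terminator_offset : terminator_offset + terminator_len] = (
        "T" * terminator_len
    )
    if terminator_offset + terminator_len < downstream_len:
        down[terminator_offset + terminator_len] = "C"
    return {
        "upstream": "".join(up),
        "transcript": transcript,
        "downstream": "".join(down),
        "use_interval": (use_offset, use_offset + len(USE_CONSENSUS)),
        "use_site": use_site,
        "tata_interval": (tata_offset, tata_offset + len(TATA_CONSENSUS)),
        "terminator_interval": (
            terminator_offset,
            terminator_offset + terminator_len,
        ),
        "element_intervals": intervals,
    }


def simulate_gene_set(
    spec: SimulationSpec, n: int = 100, site_noise: float = 0.05
) -> list[dict]:
    """n independent TR genes with noisy planted USE sites (for PWM work)."""
    rng = np.random.default_rng(spec.seed)
    return [simulate_tr_gene(spec, rng, site_noise=site_noise) for _ in range(n)]


def simulate_reads(
    transcript: str,
    n: int,
    read_len: int,
    seed: int,
    out_path: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Uniform error-free reads over a transcript, strand flipped at 0.5.

    Start positions are uniform on [0, len - read_len]; with ``out_path``
    the reads are written as fixed-quality FASTQ.
    """
    if n <= 0:
        raise ValueError("read count must be positive")
    if read_len > len(transcript):
        raise ValueError("read length exceeds transcript length")
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGTN", "TGCAN")
    reads = []
    for i in range(n):
        start = int(rng.integers(0, len(transcript) - read_len + 1))
        seq = transcript[start : start + read_len]
        if rng.random() < 0.5:
            seq = seq.translate(comp)[::-1]
        reads.append((f"read{i + 1}", seq))
    if out_path is not None:
        write_fastq(reads, out_path)
    return reads


def simulate_trap_products(
    motif: TelomereMotif,
    n: int,
    seed: int,
    substrate_primer: str = SYNTH_SUBSTRATE_PRIMER,
    reverse_primer: str = SYNTH_REVERSE_PRIMER,
    unit_geom_p: float = 0.25,
    max_units: int = 20,
    mismatch_prob: float = 0.0,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Seeded TRAP products with known unit counts.

    Unit counts follow a truncated geometric distribution (shorter products
    amplify better); each unit independently carries one planted mismatch
    with probability ``mismatch_prob``.  Returns (name, product) pairs and
    the per-product truth (unit count, variant count).
    """
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGT", "TGCA")
    rev_site = reverse_primer.translate(comp)[::-1]
    unit = motif.display_form
    L = motif.length
    products = []
    truth = []
    for i in range(n):
        k = min(int(rng.geometric(unit_geom_p)), max_units)
        units = []
        variants = 0
        for _ in range(k):
            u = list(unit)
            if mismatch_prob and rng.random() < mismatch_prob:
                j = int(rng.integers(0, L))
                u[j] = [b for b in "ACGT" if b != u[j]][rng.integers(0, 3)]
                variants += 1
            units.append("".join(u))
        product = substrate_primer + "".join(units) + rev_site
        products.append((f"trap{i + 1}", product))
        truth.append({"n_units": k, "variant_units": variants})
    return products, truth


def simulate_trf_profile(
    median_bp: float = 3000.0,
    sigma: float = 0.3,
    n_bins: int = 200,
    seed: int = 0,
    noise: float = 0.0,
    background: float = 0.0,
    size_range: tuple[float, float] = (500.0, 12000.0),
):
    """Discretized log-normal TRF profile with a known median.

    Intensities are proportional to the log-normal density (median
    ``median_bp``, log-scale ``sigma``) on an even size grid, plus optional
    multiplicative noise and a constant background offset.  Returns a
    TrfProfile.
    """
    from .assays import TrfProfile

    rng = np.random.default_rng(seed)
    sizes = np.linspace(size_range[0], size_range[1], n_bins)
    x = (np.log(sizes) - np.log(median_bp)) / sigma
    dens = np.exp(-0.5 * x * x) / sizes
    if noise:
        dens = dens * (1.0 + noise * rng.standard_normal(n_bins))
        dens = np.clip(dens, 0.0, None)
    dens = dens / dens.max() + background
    return TrfProfile(
        points=tuple((float(s), float(i)) for s, i in zip(sizes, dens)),
        background=background,
    )
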