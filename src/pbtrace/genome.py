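"""Toy genomes, transgene constructs, and TTAA-targeted insertion.

The simulator models the event a PiggyBac-style transposon produces in a
host genome: the transposase cuts at a TTAA tetranucleotide and the
ITR-flanked cargo is inserted so that the TTAA target site is duplicated,
leaving one full copy of the motif on each side of the transgene.  The
duplicated motif (the target-site duplication, TSD) is what downstream
junction calling can recover and report.

Coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ToyGenome",
    "TransgeneConstruct",
    "PlantedInsertion",
    "InsertionTruth",
    "reverse_complement",
    "make_toy_genome",
    "insert_transgene",
    "excise_transgene",
    "write_fasta",
    "read_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ToyGenome:
    """Named chromosome sequences (uppercase A/C/G/T/N)."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if not _ALPHABET.issuperset(seq):
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"chromosome {name!r} has invalid bases {bad}")

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass
class TransgeneConstruct:
    """An ITR-flanked cargo sequence, e.g. a promoter-reporter circuit.

    ``itr_left`` and ``itr_right`` are 0-based half-open sub-intervals of
    ``sequence`` marking the inverted terminal repeats that bound the
    mobilised cargo.
    """

    name: str
    sequence: str
    itr_left: tuple[int, int]
    itr_right: tuple[int, int]
    payload: str = "Ef1a-GFP"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 100:
            raise ValueError("construct sequence must be >= 100 bp")
        for label, (a, b) in (("itr_left", self.itr_left), ("itr_right", self.itr_right)):
            if not (0 <= a < b <= n):
                raise ValueError(f"{label} interval {a, b} out of bounds for length {n}")
        if self.itr_left[1] > self.itr_right[0]:
            raise ValueError("ITR intervals overlap")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PlantedInsertion:
    """Ground-truth description of where a transgene is planted.

    ``ttaa_start`` is the 0-based position of the TSD motif in the
    *pre-insertion* chromosome.
    """

    chrom: str
    ttaa_start: int
    orientation: str = "forward"  # or "reverse"
    tsd: str = "TTAA"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if not self.tsd:
            raise ValueError("tsd motif must be nonempty")


@dataclass
class InsertionTruth:
    """What a perfect caller should report for a planted insertion.

    ``junction`` is the 1-based pair of genome bases flanking the insertion
    point in the original genome: the transgene sits between
    ``junction[0]`` and ``junction[1]`` (which is ``junction[0] + 1``),
    immediately downstream of the TSD motif.
    """

    chrom: str
    junction: tuple[int, int]
    orientation: str
    tsd: str
    inserted_length: int
    site: PlantedInsertion = field(repr=False, default=None)


def make_toy_genome(
    n_chrom: int,
    lengths: int | list[int],
    gc_fraction: float = 0.42,
    seed: int = 0,
    name_prefix: str = "chr",
) -> ToyGenome:
    """Generate a random multi-chromosome genome.

    Base composition follows ``gc_fraction``; every chromosome is
    guaranteed at least one TTAA occurrence (planted post hoc at the
    midpoint if the random draw produced none, so insertion sites always
    exist).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    if any(L < 1000 for L in lengths):
        raise ValueError("chromosome lengths must be >= 1 kb")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms: dict[str, str] = {}
    for i, L in enumerate(lengths):
        draw = rng.choice(bases, size=L, p=[p_at, p_gc, p_gc, p_at])
        seq = draw.tobytes().decode("ascii")
        if "TTAA" not in seq:
            mid = L // 2
            seq = seq[:mid] + "TTAA" + seq[mid + 4 :]
        chroms[f"{name_prefix}{i + 1}"] = seq
    return ToyGenome(chroms)


def insert_transgene(
    genome: ToyGenome,
    construct: TransgeneConstruct,
    site: PlantedInsertion,
) -> tuple[ToyGenome, InsertionTruth]:
    """Insert ``construct`` at a TTAA site, duplicating the target motif.

    The modified chromosome is ``prefix(..ttaa_start+|tsd|) + cargo + tsd
    + suffix``: because the prefix already ends with the original motif
    copy, the cargo ends up flanked by one full TSD copy on each side.
    Reverse orientation inserts the reverse complement of the cargo.
    """
    if site.chrom not in genome.chromosomes:
        raise KeyError(f"unknown chromosome {site.chrom!r}")
    seq = genome.chromosomes[site.chrom]
    tsd = site.tsd
    s = site.ttaa_start
    if s < 0 or seq[s : s + len(tsd)] != tsd:
        raise ValueError(
            f"TSD motif {tsd!r} not present at {site.chrom}:{s} "
            f"(found {seq[s:s + len(tsd)]!r})"
        )
    cargo = construct.sequence
    if site.orientation == "reverse":
        cargo = reverse_complement(cargo)
    cut = s + len(tsd)
    modified = seq[:cut] + cargo + tsd + seq[cut:]
    chroms = dict(genome.chromosomes)
    chroms[site.chrom] = modified
    truth = InsertionTruth(
        chrom=site.chrom,
        junction=(cut, cut + 1),  # 1-based: last base of TSD, first base after
        orientation=site.orientation,
        tsd=tsd,
        inserted_length=len(cargo) + len(tsd),
        site=site,
    )
    return ToyGenome(chroms), truth


def excise_transgene(genome: ToyGenome, truth: InsertionTruth) -> ToyGenome:
    """Remove the transgene plus exactly one TSD copy; inverse of insertion."""
    seq = genome.chromosomes[truth.chrom]
    cut = truth.junction[0]  # == 0-based position just past the left TSD copy
    restored = seq[:cut] + seq[cut + truth.inserted_length :]
    chroms = dict(genome.chromosomes)
    chroms[truth.chrom] = restored
    return ToyGenome(chroms)


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def default_construct(seed: int = 99, length: int = 2000, name: str = "PB-Ef1a-GFP") -> TransgeneConstruct:
    """A synthetic stand-in for the ITR-flanked promoter-reporter circuit.

    The real plasmid sequence is not public; this generates a random cargo
    with 300 bp terminal repeats marked as ITRs, adequate for junction
    discovery (the caller only needs a sequence distinguishable from the
    genome).
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=length).tobytes().decode("ascii")
    return TransgeneConstruct(
        name=name,
        sequence=seq,
        itr_left=(0, 300),
        itr_right=(length - 300, length),
    )
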