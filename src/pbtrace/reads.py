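"""Paired-end short-read simulation with a Phred quality model.

Fragments of ~350 bp are drawn uniformly over positions and strands;
150 bp mates are read from the two fragment ends (mate 1 from the 5' end,
mate 2 reverse-complemented from the 3' end), substitution errors applied
at a fixed per-base rate, and qualities emitted Phred+33.  A truth table
records each fragment's origin so downstream stages can be checked
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ToyGenome, reverse_complement

__all__ = ["ReadSimParams", "ReadPair", "simulate_paired_reads", "write_fastq_pairs", "read_fastq"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadSimParams:
    read_length: int = 150
    fragment_mean: int = 350
    fragment_sd: int = 30
    coverage: float = 20.0
    error_rate: float = 0.001
    quality_model: str = "decay"  # "decay": Q38 at cycle 1 -> Q28 at last cycle; or "constant"
    constant_quality: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must be <= fragment_mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.quality_model not in ("decay", "constant"):
            raise ValueError("quality_model must be 'decay' or 'constant'")


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray


def _quality_template(params: ReadSimParams) -> np.ndarray:
    n = params.read_length
    if params.quality_model == "constant":
        return np.full(n, params.constant_quality, dtype=np.int64)
    return np.round(np.linspace(38, 28, n)).astype(np.int64)


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size == 0:
        return seq
    seq = seq.copy()
    for i in hits:
        # substitute with a uniformly chosen different base
        choices = _BASES[_BASES != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return seq


def simulate_paired_reads(
    genome: ToyGenome, params: ReadSimParams
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate paired reads over every chromosome of ``genome``.

    Returns the read pairs and a truth table with one row per fragment:
    read_id, chrom, fragment start/end (0-based half-open) and the strand
    the fragment was sequenced from.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    qual = _quality_template(params)
    pairs: list[ReadPair] = []
    truth_rows: list[tuple] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        if L < params.fragment_mean + 4 * params.fragment_sd:
            raise ValueError(
                f"chromosome {chrom!r} ({L} bp) shorter than the fragment model allows"
            )
        n_frag = int(round(params.coverage * L / (2.0 * rl)))
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        frag_lens = np.clip(
            np.round(rng.normal(params.fragment_mean, params.fragment_sd, n_frag)),
            rl,
            L,
        ).astype(np.int64)
        starts = rng.integers(0, L - frag_lens + 1)
        strands = rng.integers(0, 2, n_frag)  # 0: '+', 1: '-'
        for i in range(n_frag):
            s, fl, rev = int(starts[i]), int(frag_lens[i]), bool(strands[i])
            frag = arr[s : s + fl]
            if rev:
                # fragment sequenced from the reverse strand: mate 1 is the
                # revcomp of the fragment 3' end
                m1 = _revcomp_u8(frag[-rl:])
                m2 = frag[:rl]
            else:
                m1 = frag[:rl]
                m2 = _revcomp_u8(frag[-rl:])
            m1 = _apply_errors(m1, params.error_rate, rng)
            m2 = _apply_errors(m2, params.error_rate, rng)
            rid = f"sim_{chrom}_{i:07d}"
            pairs.append(
                ReadPair(
                    read_id=rid,
                    seq1=m1.tobytes().decode("ascii"),
                    qual1=qual,
                    seq2=m2.tobytes().decode("ascii"),
                    qual2=qual,
                )
            )
            truth_rows.append((rid, chrom, s, s + fl, "-" if rev else "+"))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "chrom", "start", "end", "strand"])
    return pairs, truth


_RC_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _RC_TABLE[a] = b


def _revcomp_u8(arr: np.ndarray) -> np.ndarray:
    return _RC_TABLE[arr][::-1]


def write_fastq_pairs(
    pairs: list[ReadPair], path1, path2, mate_suffix: bool = True
) -> None:
    """Write mates to two Phred+33 FASTQ files.

    ``mate_suffix`` appends ``/1`` and ``/2`` to the read ids (classic
    style); otherwise both mates carry the bare id (modern style).
    """
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            s1 = "/1" if mate_suffix else ""
            s2 = "/2" if mate_suffix else ""
            q1 = (p.qual1 + 33).astype(np.uint8).tobytes().decode("ascii")
            q2 = (p.qual2 + 33).astype(np.uint8).tobytes().decode("ascii")
            f1.write(f"@{p.read_id}{s1}\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.read_id}{s2}\n{p.seq2}\n+\n{q2}\n")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# read-origin truth table: 0-based half-open fragment intervals\n")
        truth.to_csv(fh, sep="\t", index=False)


def read_fastq(path) -> list[tuple[str, str, np.ndarray]]:
    """Read a Phred+33 FASTQ into (id, sequence, quality-array) tuples."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qline = fh.readline().strip()
            rid = header[1:].split()[0].strip()
            qual = np.frombuffer(qline.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
            out.append((rid, seq.upper(), qual))
    return out
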