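"""Seeded, ungapped local alignment with soft-clipping, plus duplicate
removal and SAM text input/output.

The aligner is deliberately minimal: it seeds with exact k-mers (default
k = 45), extends ungapped along the seed diagonal with an X-drop rule,
and reports the unextendable read ends as soft clips.  Soft clips are the
point — they carry the transgene/genome junction signal the integration
caller consumes.  Indel-tolerant alignment is delegated to external
aligners via the SAM reader.

Ties are broken deterministically by (score desc, reference name asc,
position asc, forward strand first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import reverse_complement

__all__ = [
    "AlignmentRecord",
    "SeedIndex",
    "Scoring",
    "build_index",
    "align_read",
    "align_pairs",
    "remove_duplicates",
    "write_sam",
    "read_sam",
]


@dataclass
class Scoring:
    match: int = 1
    mismatch: int = -2
    min_score: int = 40
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.match < 1 or self.mismatch > -1:
            raise ValueError("need match >= 1 and mismatch <= -1")


@dataclass
class AlignmentRecord:
    """One read's placement, SAM-like: sequence stored in reference-forward
    orientation (reverse-complemented for minus-strand alignments)."""

    read_id: str
    mapped: bool
    ref: str | None = None
    pos: int = 0  # 1-based leftmost *matched* reference position
    strand: str = "+"
    cigar: list[tuple[str, int]] = field(default_factory=list)  # ops 'S'/'M'
    nm: int = 0
    score: int = 0
    seq: str = ""
    quals: np.ndarray | None = None
    mate_number: int = 1
    mate_ref: str | None = None
    mate_pos: int = 0
    mate_strand: str = "+"
    mate_mapped: bool = False

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def leading_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def trailing_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def match_length(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")

    @property
    def end(self) -> int:
        """1-based rightmost matched reference position."""
        return self.pos + self.match_length - 1

    def unclipped_5prime(self) -> int:
        """Coordinate of the original read's 5' end, clips projected out
        (the duplicate-marking coordinate)."""
        if self.strand == "+":
            return self.pos - self.leading_clip
        return self.end + self.trailing_clip


@dataclass
class SeedIndex:
    k: int
    refs: dict[str, str]
    arrays: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    kmers: dict[bytes, list[tuple[str, int]]] = field(repr=False, default_factory=dict)


def build_index(references: dict[str, str], k: int = 45) -> SeedIndex:
    """Index every exact k-mer of the references (positions on the forward
    strand; queries probe both read strands, which is equivalent to a
    double-stranded index).  k-mers containing N are skipped."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if not references:
        raise ValueError("references must be non-empty")
    shortest = min(len(s) for s in references.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest reference ({shortest} bp)")
    idx = SeedIndex(k=k, refs=dict(references))
    for name, seq in references.items():
        b = seq.encode("ascii")
        idx.arrays[name] = np.frombuffer(b, dtype=np.uint8)
        kmers = idx.kmers
        has_n = "N" in seq
        for i in range(len(b) - k + 1):
            word = b[i : i + k]
            if has_n and b"N" in word:
                continue
            kmers.setdefault(word, []).append((name, i))
    return idx


def _seed_offsets(read_len: int, k: int, n_offsets: int = 7) -> list[int]:
    last = read_len - k
    if last <= 0:
        return [0] if last == 0 else []
    return sorted({int(round(x)) for x in np.linspace(0, last, n_offsets)})


def _extend(
    read_arr: np.ndarray,
    ref_arr: np.ndarray,
    refstart: int,
    seed_lo: int,
    seed_hi: int,
    scoring: Scoring,
) -> tuple[int, int, int, int] | None:
    """X-drop ungapped extension of the seed along its diagonal.

    Returns (read_start, read_end, score, n_mismatch) of the matched
    segment, or None if the seed falls outside the reference overlap.
    """
    n = read_arr.size
    a = max(0, -refstart)
    b = min(n, ref_arr.size - refstart)
    if seed_lo < a or seed_hi > b:
        return None
    m = read_arr[a:b] == ref_arr[refstart + a : refstart + b]
    s = np.where(m, scoring.match, scoring.mismatch).astype(np.int64)
    lo, hi = seed_lo - a, seed_hi - a
    # rightward from the seed end
    right = s[hi:]
    if right.size:
        c = np.cumsum(right)
        peak = np.maximum.accumulate(c)
        dead = np.nonzero(peak - c > scoring.xdrop)[0]
        stop = dead[0] if dead.size else c.size
        if stop > 0 and (best := c[:stop].max()) > 0:
            j = hi + int(np.argmax(c[:stop])) + 1
            right_gain = int(best)
        else:
            j, right_gain = hi, 0
    else:
        j, right_gain = hi, 0
    # leftward from the seed start
    left = s[:lo][::-1]
    if left.size:
        c = np.cumsum(left)
        peak = np.maximum.accumulate(c)
        dead = np.nonzero(peak - c > scoring.xdrop)[0]
        stop = dead[0] if dead.size else c.size
        if stop > 0 and (best := c[:stop].max()) > 0:
            i = lo - (int(np.argmax(c[:stop])) + 1)
            left_gain = int(best)
        else:
            i, left_gain = lo, 0
    else:
        i, left_gain = lo, 0
    seed_score = int(s[lo:hi].sum())
    score = seed_score + left_gain + right_gain
    nm = int(np.count_nonzero(~m[i:j]))
    return i + a, j + a, score, nm


def align_read(
    read_id: str,
    seq: str,
    index: SeedIndex,
    scoring: Scoring | None = None,
    quals: np.ndarray | None = None,
    max_candidates: int = 50,
) -> AlignmentRecord:
    """Best-scoring ungapped placement of one read (or its reverse
    complement); unmapped is a value, not an error."""
    if scoring is None:
        scoring = Scoring()
    k = index.k
    seq = seq.upper()
    n = len(seq)
    candidates: dict[tuple[str, int, str], int] = {}
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        if n < k:
            break
        b = oriented.encode("ascii")
        for off in _seed_offsets(n, k):
            for ref, pos in index.kmers.get(b[off : off + k], ()):
                key = (ref, pos - off, strand)
                if key not in candidates:
                    candidates[key] = off
    if not candidates:
        return AlignmentRecord(read_id=read_id, mapped=False, seq=seq, quals=quals)
    if len(candidates) > max_candidates:
        candidates = dict(sorted(candidates.items())[:max_candidates])

    read_arrs = {
        "+": np.frombuffer(seq.encode("ascii"), dtype=np.uint8),
        "-": np.frombuffer(reverse_complement(seq).encode("ascii"), dtype=np.uint8),
    }
    best = None
    for (ref, refstart, strand), off in candidates.items():
        ext = _extend(read_arrs[strand], index.arrays[ref], refstart, off, off + k, scoring)
        if ext is None:
            continue
        i, j, score, nm = ext
        key = (-score, ref, refstart + i, 0 if strand == "+" else 1)
        if best is None or key < best[0]:
            best = (key, ref, refstart + i, strand, i, j, score, nm)
    if best is None or best[6] < scoring.min_score:
        return AlignmentRecord(read_id=read_id, mapped=False, seq=seq, quals=quals)
    _, ref, pos0, strand, i, j, score, nm = best
    cigar: list[tuple[str, int]] = []
    if i > 0:
        cigar.append(("S", i))
    cigar.append(("M", j - i))
    if n - j > 0:
        cigar.append(("S", n - j))
    oriented_quals = quals
    if quals is not None and strand == "-":
        oriented_quals = quals[::-1]
    return AlignmentRecord(
        read_id=read_id,
        mapped=True,
        ref=ref,
        pos=pos0 + 1,
        strand=strand,
        cigar=cigar,
        nm=nm,
        score=score,
        seq=seq if strand == "+" else reverse_complement(seq),
        quals=oriented_quals,
    )


def align_pairs(
    pairs,
    index: SeedIndex,
    scoring: Scoring | None = None,
) -> list[AlignmentRecord]:
    """Align both mates of each pair independently and cross-fill mate
    coordinates.  Accepts ReadPair objects or (id, seq1, qual1, seq2,
    qual2) tuples; returns a flat record list (mate 1 before mate 2)."""
    records: list[AlignmentRecord] = []
    for p in pairs:
        if hasattr(p, "read_id"):
            rid, s1, q1, s2, q2 = p.read_id, p.seq1, p.qual1, p.seq2, p.qual2
        else:
            rid, s1, q1, s2, q2 = p
        r1 = align_read(rid, s1, index, scoring, quals=q1)
        r2 = align_read(rid, s2, index, scoring, quals=q2)
        r1.mate_number, r2.mate_number = 1, 2
        r1.mate_ref, r1.mate_pos, r1.mate_strand, r1.mate_mapped = r2.ref, r2.pos, r2.strand, r2.mapped
        r2.mate_ref, r2.mate_pos, r2.mate_strand, r2.mate_mapped = r1.ref, r1.pos, r1.strand, r1.mapped
        records.extend((r1, r2))
    return records


def _dup_coord(rec: AlignmentRecord):
    if not rec.mapped:
        return None
    return (rec.ref, rec.unclipped_5prime(), rec.strand)


def remove_duplicates(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse read pairs whose two mates share both duplicate
    coordinates (reference, clip-projected 5' position, strand); the
    representative is the pair with the highest summed base quality, ties
    by read id.  Mapped singletons deduplicate by their own coordinate;
    fully unmapped reads pass through."""
    by_read: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.read_id not in by_read:
            order.append(rec.read_id)
        by_read.setdefault(rec.read_id, []).append(rec)

    def qual_sum(recs: list[AlignmentRecord]) -> int:
        return int(sum(int(r.quals.sum()) for r in recs if r.quals is not None))

    winners: dict[tuple, tuple] = {}  # coord key -> (neg qual, read_id)
    passthrough: set[str] = set()
    for rid in order:
        recs = by_read[rid]
        coords = sorted((_dup_coord(r) for r in recs), key=lambda c: (c is None, c))
        if all(c is None for c in coords):
            passthrough.add(rid)
            continue
        key = tuple(coords)
        cand = (-qual_sum(recs), rid)
        if key not in winners or cand < winners[key]:
            winners[key] = cand
    keep = passthrough | {rid for _, rid in winners.values()}
    return [rec for rec in records if rec.read_id in keep]


def _flag(rec: AlignmentRecord, paired: bool) -> int:
    f = 0
    if paired:
        f |= 0x1
        f |= 0x40 if rec.mate_number == 1 else 0x80
        if not rec.mate_mapped:
            f |= 0x8
        elif rec.mate_strand == "-":
            f |= 0x20
    if not rec.mapped:
        f |= 0x4
    elif rec.strand == "-":
        f |= 0x10
    return f


def write_sam(records: list[AlignmentRecord], ref_lengths: dict[str, int], path, paired: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, L in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{L}\n")
        fh.write("@PG\tID:pbtrace\tPN:pbtrace\n")
        for rec in records:
            cig = "".join(f"{n}{op}" for op, n in rec.cigar) if rec.mapped else "*"
            qual = (
                (np.asarray(rec.quals, dtype=np.int64) + 33).astype(np.uint8).tobytes().decode("ascii")
                if rec.quals is not None
                else "*"
            )
            rnext, pnext = "*", 0
            if paired and rec.mate_mapped:
                rnext = "=" if rec.mate_ref == rec.ref else rec.mate_ref
                pnext = rec.mate_pos
            fields = [
                rec.read_id,
                str(_flag(rec, paired)),
                rec.ref if rec.mapped else "*",
                str(rec.pos if rec.mapped else 0),
                "60" if rec.mapped else "0",
                cig,
                rnext,
                str(pnext),
                "0",
                rec.seq or "*",
                qual,
            ]
            if rec.mapped:
                fields.append(f"NM:i:{rec.nm}")
            fh.write("\t".join(fields) + "\n")


def read_sam(path) -> list[AlignmentRecord]:
    """Read SAM/BAM from any aligner into AlignmentRecords.

    Internal CIGAR keeps only the leading/trailing soft clips and a single
    matched block covering the rest of the read; that is all the junction
    caller needs (M/=/X/I consume read bases, D/N consume none)."""
    import pysam

    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence or ""
            quals = (
                np.asarray(aln.query_qualities, dtype=np.int64)
                if aln.query_qualities is not None
                else None
            )
            rec = AlignmentRecord(
                read_id=aln.query_name,
                mapped=not aln.is_unmapped,
                seq=seq,
                quals=quals,
                mate_number=2 if aln.is_read2 else 1,
            )
            if rec.mapped:
                ct = aln.cigartuples or []
                lead = ct[0][1] if ct and ct[0][0] == 4 else 0
                trail = ct[-1][1] if len(ct) > 1 and ct[-1][0] == 4 else 0
                rec.ref = aln.reference_name
                rec.pos = aln.reference_start + 1
                rec.strand = "-" if aln.is_reverse else "+"
                cigar = []
                if lead:
                    cigar.append(("S", lead))
                cigar.append(("M", len(seq) - lead - trail))
                if trail:
                    cigar.append(("S", trail))
                rec.cigar = cigar
                rec.nm = int(aln.get_tag("NM")) if aln.has_tag("NM") else 0
            if aln.is_paired and not aln.mate_is_unmapped and aln.next_reference_name:
                rec.mate_mapped = True
                rec.mate_ref = aln.next_reference_name
                rec.mate_pos = aln.next_reference_start + 1
                rec.mate_strand = "-" if aln.mate_is_reverse else "+"
            out.append(rec)
    return out
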