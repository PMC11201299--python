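"""Transgene integration-site discovery from soft-clipped reads.

The junction between host genome and an integrated transgene shows up in
whole-genome paired-end data as reads that align partly to one sequence
and partly to the other: the aligner anchors one part and soft-clips the
rest.  The caller

1. extracts soft-clipped read ends (``extract_softclipped``),
2. locally realigns each clipped sequence against genome + transgene
   (``realign_clips``),
3. clusters the implied genome-side breakpoints (``cluster_junctions``),
4. pairs a left-flank and a right-flank cluster into an integration call
   with orientation and target-site-duplication check
   (``call_integration``), and
5. validates the call by building a hybrid reference (genome flank +
   TSD + transgene + TSD + genome flank) and counting reads that realign
   across each junction without clipping (``validate_with_hybrid``).

Breakpoint conventions: a *left-flank* observation names the last genome
base before the insertion point (L); a *right-flank* observation names
the first genome base after it (R).  With a duplicated TTAA target site
the two overlap: R = L - |TSD| + 1.  The reported junction interval is
(L, L+1), 1-based inclusive — the two genome bases bracketing the
insertion point.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .align import AlignmentRecord, Scoring, align_read, build_index
from .genome import ToyGenome, TransgeneConstruct, reverse_complement

__all__ = [
    "SoftClipEvidence",
    "ClipHit",
    "JunctionCluster",
    "IntegrationCall",
    "HybridReference",
    "ValidationResult",
    "extract_softclipped",
    "realign_clips",
    "cluster_junctions",
    "call_integration",
    "build_hybrid_reference",
    "validate_with_hybrid",
    "screen_vector_integration",
]


@dataclass
class SoftClipEvidence:
    read_id: str
    anchor_ref: str
    anchor_pos: int  # 1-based matched base adjacent to the clip
    side: str  # 'left' | 'right' (position of the clip relative to the anchor)
    clipped_seq: str  # reference-forward orientation, as stored in the record
    anchor_strand: str


@dataclass
class ClipHit:
    evidence_index: int
    target: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    identity: float  # percent
    score: float


@dataclass
class JunctionCluster:
    chrom: str
    flank: str  # 'left': breakpoints are L; 'right': breakpoints are R
    breakpoint: int  # modal position, 1-based
    spread: int
    support: int
    orientation: str | None  # 'forward' | 'reverse' | None when mixed
    transgene_side: str | None  # '5p' | '3p' side of the construct at this junction
    consensus_clip: str
    positions: list[int] = field(default_factory=list, repr=False)


@dataclass
class IntegrationCall:
    chrom: str
    junction: tuple[int, int]  # two adjacent 1-based genome bases
    orientation: str  # 'forward' | 'reverse' | 'ambiguous'
    status: str  # 'PASS' | 'CANDIDATE' | 'AMBIGUOUS'
    tsd_found: str | None
    left_support: int
    right_support: int
    annotation: str | None = None
    validation: "ValidationResult | None" = None

    @property
    def total_support(self) -> int:
        return self.left_support + self.right_support


@dataclass
class HybridReference:
    sequence: str
    chrom: str
    flank_up: int
    flank_down: int
    tsd: str
    orientation: str
    transgene_name: str
    junction_left: int  # 1-based hybrid pos of the last base before the cargo
    junction_right: int  # 1-based hybrid pos of the last cargo/TSD base
    segments: list[tuple[int, int, str, int, str]] = field(repr=False, default_factory=list)
    # segments: (hybrid_start0, length, source_name, source_start0, strand)

    def map_to_source(self, hybrid_pos: int) -> tuple[str, int, str]:
        """Map a 1-based hybrid position to (source, 1-based position, strand)."""
        p = hybrid_pos - 1
        for h0, length, src, s0, strand in self.segments:
            if h0 <= p < h0 + length:
                off = p - h0
                if strand == "+":
                    return src, s0 + off + 1, "+"
                return src, s0 + (length - 1 - off) + 1, "-"
        raise IndexError(f"hybrid position {hybrid_pos} out of range")


@dataclass
class ValidationResult:
    left_spanning: int
    right_spanning: int
    min_support: int

    @property
    def passed(self) -> bool:
        return self.left_spanning >= self.min_support and self.right_spanning >= self.min_support


def extract_softclipped(
    records: list[AlignmentRecord], min_clip_len: int = 20
) -> list[SoftClipEvidence]:
    """One evidence item per soft clip of length >= ``min_clip_len``;
    records clipped on both sides yield two items."""
    out: list[SoftClipEvidence] = []
    for rec in records:
        if not rec.mapped:
            continue
        if not rec.seq:
            raise ValueError(f"record {rec.read_id!r} lacks sequence data")
        lead, trail = rec.leading_clip, rec.trailing_clip
        if lead >= min_clip_len:
            out.append(
                SoftClipEvidence(
                    read_id=rec.read_id,
                    anchor_ref=rec.ref,
                    anchor_pos=rec.pos,
                    side="left",
                    clipped_seq=rec.seq[:lead],
                    anchor_strand=rec.strand,
                )
            )
        if trail >= min_clip_len:
            out.append(
                SoftClipEvidence(
                    read_id=rec.read_id,
                    anchor_ref=rec.ref,
                    anchor_pos=rec.end,
                    side="right",
                    clipped_seq=rec.seq[-trail:],
                    anchor_strand=rec.strand,
                )
            )
    return out


def _make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _seed_windows(query: str, kmers: dict, k: int) -> set[tuple[str, int]]:
    """Candidate (target, diagonal-start) pairs from exact k-mer probes."""
    b = query.encode("ascii")
    cands: set[tuple[str, int]] = set()
    step = max(1, (len(b) - k) // 8) if len(b) > k else 1
    offsets = list(range(0, len(b) - k + 1, step))
    if offsets and offsets[-1] != len(b) - k:
        offsets.append(len(b) - k)
    for off in offsets:
        for ref, pos in kmers.get(b[off : off + k], ()):
            cands.add((ref, pos - off))
    return cands


def realign_clips(
    evidence: list[SoftClipEvidence],
    targets: dict[str, str],
    min_identity: float = 95.0,
    min_len: int = 20,
    seed_k: int = 16,
) -> list[ClipHit]:
    """Best local alignment of each clipped sequence against all targets,
    both strands; BLAST-like seeded Smith-Waterman with affine gaps.

    Exact ``seed_k``-mers nominate target windows; a full affine-gap
    local alignment is then computed on the windowed target only.  Hits
    below ``min_identity`` percent or aligned length < ``min_len`` are
    discarded.  At most one hit (the best) is reported per evidence item;
    ties break by (target name, position)."""
    if not targets:
        raise ValueError("empty target set")
    kmers: dict[bytes, list[tuple[str, int]]] = {}
    for name, seq in targets.items():
        b = seq.encode("ascii")
        for i in range(len(b) - seed_k + 1):
            word = b[i : i + seed_k]
            if b"N" not in word:
                kmers.setdefault(word, []).append((name, i))
    aligner = _make_local_aligner()
    pad = 30
    hits: list[ClipHit] = []
    for idx, ev in enumerate(evidence):
        clip = ev.clipped_seq
        if len(clip) < seed_k:
            continue
        best: tuple | None = None
        for strand, query in (("+", clip), ("-", reverse_complement(clip))):
            for ref, diag in _seed_windows(query, kmers, seed_k):
                tseq = targets[ref]
                w0 = max(0, diag - pad)
                w1 = min(len(tseq), diag + len(query) + pad)
                window = tseq[w0:w1]
                alns = aligner.align(window, query)
                if not alns:
                    continue
                aln = alns[0]
                counts = aln.counts()
                ncols = counts.identities + counts.mismatches + counts.gaps
                if ncols == 0:
                    continue
                identity = 100.0 * counts.identities / ncols
                t_start = int(aln.aligned[0][0][0]) + w0
                t_end = int(aln.aligned[0][-1][1]) + w0
                aligned_len = t_end - t_start
                if identity < min_identity or aligned_len < min_len:
                    continue
                key = (-aln.score, ref, t_start, 0 if strand == "+" else 1)
                if best is None or key < best[0]:
                    best = (key, ref, t_start, t_end, strand, identity, float(aln.score))
        if best is not None:
            _, ref, t_start, t_end, strand, identity, score = best
            hits.append(
                ClipHit(
                    evidence_index=idx,
                    target=ref,
                    start=t_start + 1,
                    end=t_end,
                    strand=strand,
                    identity=identity,
                    score=score,
                )
            )
    return hits


@dataclass
class _JunctionObs:
    chrom: str
    flank: str
    breakpoint: int
    orientation: str
    transgene_side: str | None
    clip_away: str | None  # clip oriented away from the junction (insert side)


def _observations(
    evidence: list[SoftClipEvidence],
    hits: list[ClipHit],
    genome_names: set[str],
    transgene_name: str,
    transgene_length: int,
) -> list[_JunctionObs]:
    obs: list[_JunctionObs] = []
    for hit in hits:
        ev = evidence[hit.evidence_index]
        orientation = "forward" if hit.strand == "+" else "reverse"
        if ev.anchor_ref in genome_names and hit.target == transgene_name:
            # genome-anchored read, clip realigns to the transgene
            flank = "left" if ev.side == "right" else "right"
            breakpoint = ev.anchor_pos
            # transgene base adjacent to the junction
            adjacent_is_right_in_clip = ev.side == "left"
            if adjacent_is_right_in_clip == (hit.strand == "+"):
                tg_adj = hit.end
            else:
                tg_adj = hit.start
            side = "5p" if tg_adj <= transgene_length / 2 else "3p"
            clip_away = ev.clipped_seq if flank == "left" else ev.clipped_seq[::-1]
            obs.append(_JunctionObs(ev.anchor_ref, flank, breakpoint, orientation, side, clip_away))
        elif ev.anchor_ref == transgene_name and hit.target in genome_names:
            # transgene-anchored read, clip realigns to the genome
            adjacent_is_right_in_clip = ev.side == "left"
            if adjacent_is_right_in_clip == (hit.strand == "+"):
                flank, breakpoint = "left", hit.end
            else:
                flank, breakpoint = "right", hit.start
            side = "5p" if ev.anchor_pos <= transgene_length / 2 else "3p"
            obs.append(_JunctionObs(hit.target, flank, breakpoint, orientation, side, None))
    return obs


def _consensus(clips: list[str]) -> str:
    """Majority base per column; clips are aligned at their first base."""
    if not clips:
        return ""
    width = max(len(c) for c in clips)
    cols = []
    for i in range(width):
        counter = Counter(c[i] for c in clips if len(c) > i)
        cols.append(counter.most_common(1)[0][0])
    return "".join(cols)


def cluster_junctions(
    evidence: list[SoftClipEvidence],
    hits: list[ClipHit],
    genome_names,
    transgene_name: str,
    transgene_length: int,
    tolerance: int = 5,
) -> list[JunctionCluster]:
    """Merge genome-side breakpoints within ``tolerance`` bp on the same
    chromosome and flank; modal breakpoint (ties -> smallest)."""
    observations = _observations(
        evidence, hits, set(genome_names), transgene_name, transgene_length
    )
    groups: dict[tuple[str, str], list[_JunctionObs]] = {}
    for o in observations:
        groups.setdefault((o.chrom, o.flank), []).append(o)
    clusters: list[JunctionCluster] = []
    for (chrom, flank), members in sorted(groups.items()):
        members.sort(key=lambda o: o.breakpoint)
        block: list[_JunctionObs] = []
        for o in members:
            if block and o.breakpoint - block[-1].breakpoint > tolerance:
                clusters.append(_finish_cluster(chrom, flank, block))
                block = []
            block.append(o)
        if block:
            clusters.append(_finish_cluster(chrom, flank, block))
    return clusters


def _finish_cluster(chrom: str, flank: str, block: list[_JunctionObs]) -> JunctionCluster:
    positions = [o.breakpoint for o in block]
    counts = Counter(positions)
    top = max(counts.values())
    modal = min(p for p, c in counts.items() if c == top)
    orients = Counter(o.orientation for o in block)
    orientation = None
    if len(orients) == 1:
        orientation = next(iter(orients))
    elif orients:
        (o1, c1), (o2, c2) = orients.most_common(2)[:2]
        if c1 > c2:
            orientation = o1
    sides = Counter(o.transgene_side for o in block if o.transgene_side)
    side = sides.most_common(1)[0][0] if sides else None
    clips = [o.clip_away for o in block if o.clip_away]
    consensus = _consensus(clips)
    if flank == "right" and consensus:
        consensus = consensus[::-1]
    return JunctionCluster(
        chrom=chrom,
        flank=flank,
        breakpoint=modal,
        spread=max(positions) - min(positions),
        support=len(block),
        orientation=orientation,
        transgene_side=side,
        consensus_clip=consensus,
        positions=positions,
    )


def call_integration(
    clusters: list[JunctionCluster],
    genome: ToyGenome,
    transgene: TransgeneConstruct,
    tsd_motif: str = "TTAA",
    min_support: int = 3,
    tolerance: int = 5,
    annotations: list[tuple[str, int, int, str]] | None = None,
) -> list[IntegrationCall]:
    """Pair left- and right-flank junction clusters into integration calls.

    A PASS call needs both flanks supported (>= ``min_support`` each) and
    a consistent orientation; single-sided clusters are reported as
    CANDIDATE, contradictory orientations as AMBIGUOUS.  TSD detection is
    advisory: the motif is reported when it occupies the breakpoint-
    adjacent bases on both junctions, and its absence does not veto the
    call.  Calls are sorted by total support, descending."""
    lefts = [c for c in clusters if c.flank == "left"]
    rights = [c for c in clusters if c.flank == "right"]
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int, int]] = []
    for i, lc in enumerate(lefts):
        for j, rc in enumerate(rights):
            if lc.chrom != rc.chrom:
                continue
            if abs(lc.breakpoint - rc.breakpoint) <= len(tsd_motif) + tolerance:
                pairs.append((lc.support + rc.support, i, j))
    calls: list[IntegrationCall] = []
    for _, i, j in sorted(pairs, key=lambda t: (-t[0], t[1], t[2])):
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        lc, rc = lefts[i], rights[j]
        chrom_seq = genome.chromosomes[lc.chrom]
        orientations = {o for o in (lc.orientation, rc.orientation) if o is not None}
        if len(orientations) == 1:
            orientation = next(iter(orientations))
            status = "PASS" if lc.support >= min_support and rc.support >= min_support else "CANDIDATE"
        else:
            orientation, status = "ambiguous", "AMBIGUOUS"
        # Chance homology between the transgene ends and the genome lets the
        # aligner extend a few bases past the true junction, shifting every
        # breakpoint in a cluster identically.  The bases are identical on
        # both sides, so the shift is a genuine ambiguity; the TSD motif
        # resolves it: snap to the nearest motif-consistent position within
        # the cluster tolerance.
        L = lc.breakpoint
        tsd_found = None
        m = len(tsd_motif)
        snapped = _snap_to_motif(chrom_seq, lc.breakpoint, rc.breakpoint, tsd_motif, tolerance)
        if snapped is not None:
            L, tsd_found = snapped, tsd_motif
        elif rc.breakpoint == L - m + 1 and chrom_seq[L - m : L] == tsd_motif:
            tsd_found = tsd_motif
        calls.append(
            IntegrationCall(
                chrom=lc.chrom,
                junction=(L, L + 1),
                orientation=orientation,
                status=status,
                tsd_found=tsd_found,
                left_support=lc.support,
                right_support=rc.support,
                annotation=_annotate(lc.chrom, L, annotations),
            )
        )
    for i, lc in enumerate(lefts):
        if i not in used_l and lc.support >= min_support:
            chrom_seq = genome.chromosomes[lc.chrom]
            L = _snap_single(chrom_seq, lc.breakpoint, "left", tsd_motif, tolerance)
            calls.append(
                IntegrationCall(
                    chrom=lc.chrom,
                    junction=(L, L + 1),
                    orientation=lc.orientation or "ambiguous",
                    status="CANDIDATE",
                    tsd_found=None,
                    left_support=lc.support,
                    right_support=0,
                    annotation=_annotate(lc.chrom, lc.breakpoint, annotations),
                )
            )
    for j, rc in enumerate(rights):
        if j not in used_r and rc.support >= min_support:
            chrom_seq = genome.chromosomes[rc.chrom]
            L = _snap_single(chrom_seq, rc.breakpoint, "right", tsd_motif, tolerance)
            calls.append(
                IntegrationCall(
                    chrom=rc.chrom,
                    junction=(L, L + 1),
                    orientation=rc.orientation or "ambiguous",
                    status="CANDIDATE",
                    tsd_found=None,
                    left_support=0,
                    right_support=rc.support,
                    annotation=_annotate(rc.chrom, rc.breakpoint, annotations),
                )
            )
    calls.sort(key=lambda c: (-c.total_support, c.chrom, c.junction))
    return calls


def _snap_to_motif(
    chrom_seq: str, left_bp: int, right_bp: int, motif: str, tolerance: int
) -> int | None:
    """Find the motif-consistent insertion point nearest the observed
    left breakpoint: a position L with the motif at its left (1-based
    genome bases L-|motif|+1..L) and the right breakpoint within
    tolerance of the duplicated copy's start.  Returns L or None."""
    m = len(motif)
    best: tuple[int, int] | None = None
    for L in range(max(m, left_bp - tolerance), left_bp + tolerance + 1):
        if L > len(chrom_seq):
            break
        if chrom_seq[L - m : L] != motif:
            continue
        if abs((L - m + 1) - right_bp) > tolerance:
            continue
        cand = (abs(L - left_bp), L)
        if best is None or cand < best:
            best = cand
    return None if best is None else best[1]


def _snap_single(chrom_seq: str, bp: int, flank: str, motif: str, tolerance: int) -> int:
    """Motif-aware insertion point for a single-sided cluster.

    Left flank: the breakpoint already names the last base before the
    insertion; snap to the nearest position with the motif ending there.
    Right flank: the breakpoint names the first base after the insertion,
    which under a duplicated target site is the *start* of the motif, so
    the insertion point sits |motif|-1 bases to its right.  Without a
    motif nearby the observed breakpoint is kept."""
    m = len(motif)
    best: tuple[int, int] | None = None
    for delta in range(-tolerance, tolerance + 1):
        if flank == "left":
            L = bp + delta
            ok = L >= m and chrom_seq[L - m : L] == motif
        else:
            R = bp + delta
            L = R + m - 1
            ok = R >= 1 and L <= len(chrom_seq) and chrom_seq[R - 1 : R - 1 + m] == motif
        if ok:
            cand = (abs(delta), L)
            if best is None or cand < best:
                best = cand
    if best is not None:
        return best[1]
    return bp if flank == "left" else bp - 1


def _annotate(chrom: str, pos: int, annotations) -> str | None:
    if not annotations:
        return None
    for a_chrom, start, end, label in annotations:
        if a_chrom == chrom and start <= pos <= end:
            return label
    return None


def build_hybrid_reference(
    call: IntegrationCall,
    genome: ToyGenome,
    transgene: TransgeneConstruct,
    flank: int = 500,
) -> HybridReference:
    """Assemble genome-flank + TSD + oriented transgene + TSD + genome-flank.

    Flanks that would extend past a chromosome end are truncated with a
    warning.  The coordinate map covers every hybrid base."""
    chrom_seq = genome.chromosomes[call.chrom]
    L = call.junction[0]  # 1-based last genome base before the insertion
    tsd = call.tsd_found or ""
    m = len(tsd)
    orientation = call.orientation if call.orientation in ("forward", "reverse") else "forward"
    cargo = transgene.sequence if orientation == "forward" else reverse_complement(transgene.sequence)
    up_end = L - m  # 0-based exclusive end of the upstream flank
    up_start = up_end - flank
    if up_start < 0:
        warnings.warn(f"upstream flank truncated at chromosome start ({-up_start} bp short)")
        up_start = 0
    down_start = L  # 0-based
    down_end = down_start + flank
    if down_end > len(chrom_seq):
        warnings.warn(f"downstream flank truncated at chromosome end")
        down_end = len(chrom_seq)
    up = chrom_seq[up_start:up_end]
    down = chrom_seq[down_start:down_end]
    sequence = up + tsd + cargo + tsd + down
    segments: list[tuple[int, int, str, int, str]] = []
    h = 0
    segments.append((h, len(up), call.chrom, up_start, "+"))
    h += len(up)
    if m:
        segments.append((h, m, call.chrom, up_end, "+"))
        h += m
    tg_strand = "+" if orientation == "forward" else "-"
    segments.append((h, len(cargo), transgene.name, 0, tg_strand))
    h += len(cargo)
    if m:
        segments.append((h, m, call.chrom, up_end, "+"))
        h += m
    segments.append((h, len(down), call.chrom, down_start, "+"))
    junction_left = len(up) + m
    junction_right = junction_left + len(cargo) + m
    return HybridReference(
        sequence=sequence,
        chrom=call.chrom,
        flank_up=len(up),
        flank_down=len(down),
        tsd=tsd,
        orientation=orientation,
        transgene_name=transgene.name,
        junction_left=junction_left,
        junction_right=junction_right,
        segments=segments,
    )


def _iter_read_seqs(reads):
    for r in reads:
        if hasattr(r, "seq1"):  # ReadPair
            yield f"{r.read_id}/1", r.seq1
            yield f"{r.read_id}/2", r.seq2
        elif hasattr(r, "sequence"):  # ReadRecord
            yield r.id, r.sequence
        else:
            yield r[0], r[1]


def validate_with_hybrid(
    call: IntegrationCall,
    hybrid: HybridReference,
    reads,
    min_span: int = 20,
    min_support: int = 3,
    scoring: Scoring | None = None,
    seed_k: int = 45,
) -> ValidationResult:
    """Realign reads to the hybrid; a read validates a junction when it
    aligns clip-free and covers >= ``min_span`` bases on each side."""
    read_len = max((len(s) for _, s in _iter_read_seqs(reads)), default=0)
    if read_len and len(hybrid.sequence) < read_len:
        raise ValueError("hybrid reference shorter than the read length")
    index = build_index({"hybrid": hybrid.sequence}, k=min(seed_k, len(hybrid.sequence)))
    left = right = 0
    for rid, seq in _iter_read_seqs(reads):
        rec = align_read(rid, seq, index, scoring)
        if not rec.mapped or rec.leading_clip or rec.trailing_clip:
            continue
        for jpos, bump in ((hybrid.junction_left, "L"), (hybrid.junction_right, "R")):
            if rec.pos <= jpos - min_span + 1 and rec.end >= jpos + min_span:
                if bump == "L":
                    left += 1
                else:
                    right += 1
    return ValidationResult(left_spanning=left, right_spanning=right, min_support=min_support)


def screen_vector_integration(
    pairs,
    vector_sequence: str,
    genome: ToyGenome,
    min_clip_len: int = 20,
    min_support: int = 2,
    scoring: Scoring | None = None,
    seed_k: int = 45,
) -> int:
    """Screen reads for genome-linked junctions with a vector backbone
    (e.g. the transposase plasmid): 0 means no detectable integration.

    Episomal (unintegrated) vector reads align fully within the vector
    and produce no genome-linked junction clusters."""
    if not vector_sequence:
        raise ValueError("empty vector sequence")
    from .align import align_pairs, remove_duplicates

    refs = dict(genome.chromosomes)
    refs["vector"] = vector_sequence
    index = build_index(refs, k=seed_k)
    records = remove_duplicates(align_pairs(pairs, index, scoring))
    evidence = extract_softclipped(records, min_clip_len=min_clip_len)
    hits = realign_clips(evidence, refs)
    clusters = cluster_junctions(
        evidence, hits, set(genome.chromosomes), "vector", len(vector_sequence)
    )
    return sum(1 for c in clusters if c.support >= min_support)
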