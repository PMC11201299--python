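"""End-to-end integration-site discovery: QC -> align -> dedup ->
soft-clip extraction -> clip realignment -> junction clustering ->
calling -> hybrid-reference validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .align import Scoring, align_pairs, build_index, remove_duplicates
from .caller import (
    IntegrationCall,
    build_hybrid_reference,
    call_integration,
    cluster_junctions,
    extract_softclipped,
    realign_clips,
    validate_with_hybrid,
)
from .genome import ToyGenome, TransgeneConstruct
from .qc import QcReport, QcThresholds, ReadRecord, filter_pairs

__all__ = ["CallerConfig", "PipelineResult", "discover_integrations"]


@dataclass
class CallerConfig:
    seed_k: int = 45
    scoring: Scoring = field(default_factory=Scoring)
    qc: QcThresholds = field(default_factory=QcThresholds)
    min_clip_len: int = 20
    min_identity: float = 95.0
    min_realign_len: int = 20
    cluster_tolerance: int = 5
    min_support: int = 3
    tsd_motif: str = "TTAA"
    hybrid_flank: int = 500
    min_span: int = 20
    run_qc: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    calls: list[IntegrationCall]
    qc_report: QcReport | None
    n_aligned: int
    n_after_dedup: int
    n_evidence: int
    n_hits: int
    n_clusters: int
    config: CallerConfig

    @property
    def pass_calls(self) -> list[IntegrationCall]:
        return [c for c in self.calls if c.status == "PASS"]

    def thresholds_json(self) -> str:
        return json.dumps(self.config.to_dict(), indent=2)


def _pairs_to_records(pairs) -> list[tuple[ReadRecord, ReadRecord]]:
    out = []
    for p in pairs:
        q1 = p.qual1 if p.qual1 is not None else np.full(len(p.seq1), 35)
        q2 = p.qual2 if p.qual2 is not None else np.full(len(p.seq2), 35)
        out.append(
            (ReadRecord(f"{p.read_id}/1", p.seq1, q1), ReadRecord(f"{p.read_id}/2", p.seq2, q2))
        )
    return out


def discover_integrations(
    genome: ToyGenome,
    transgene: TransgeneConstruct,
    pairs,
    config: CallerConfig | None = None,
    annotations: list[tuple[str, int, int, str]] | None = None,
) -> PipelineResult:
    """Run the full calling pipeline on simulated or real read pairs.

    ``pairs`` is a sequence of ReadPair objects.  A call reaches PASS
    status only if both junctions are supported by >= ``min_support``
    clip observations *and* the hybrid-reference validation finds >=
    ``min_support`` clip-free spanning reads at both junctions."""
    if config is None:
        config = CallerConfig()

    qc_report = None
    if config.run_qc:
        mate_records = _pairs_to_records(pairs)
        kept, _, qc_report = filter_pairs(mate_records, config.qc)
        kept_ids = {m1.id[:-2] for m1, _ in kept}
        pairs = [p for p in pairs if p.read_id in kept_ids]

    refs = dict(genome.chromosomes)
    refs[transgene.name] = transgene.sequence
    index = build_index(refs, k=config.seed_k)
    records = align_pairs(pairs, index, config.scoring)
    n_aligned = sum(1 for r in records if r.mapped)
    records = remove_duplicates(records)
    n_after_dedup = sum(1 for r in records if r.mapped)

    evidence = extract_softclipped(records, min_clip_len=config.min_clip_len)
    hits = realign_clips(
        evidence, refs, min_identity=config.min_identity, min_len=config.min_realign_len
    )
    clusters = cluster_junctions(
        evidence,
        hits,
        set(genome.chromosomes),
        transgene.name,
        len(transgene),
        tolerance=config.cluster_tolerance,
    )
    calls = call_integration(
        clusters,
        genome,
        transgene,
        tsd_motif=config.tsd_motif,
        min_support=config.min_support,
        tolerance=config.cluster_tolerance,
        annotations=annotations,
    )
    for call in calls:
        if call.status != "PASS":
            continue
        hybrid = build_hybrid_reference(call, genome, transgene, flank=config.hybrid_flank)
        call.validation = validate_with_hybrid(
            call,
            hybrid,
            pairs,
            min_span=config.min_span,
            min_support=config.min_support,
            scoring=config.scoring,
        )
        if not call.validation.passed:
            call.status = "CANDIDATE"
    return PipelineResult(
        calls=calls,
        qc_report=qc_report,
        n_aligned=n_aligned,
        n_after_dedup=n_after_dedup,
        n_evidence=len(evidence),
        n_hits=len(hits),
        n_clusters=len(clusters),
        config=config,
    )


def write_call_report(calls: list[IntegrationCall], path, sample_id: str = "sample") -> None:
    """Tab-separated report in the style of a published integration table:
    Chromosome, Insert Site, Orientation, Overlapping gene, supports,
    validation status."""
    with open(path, "w") as fh:
        fh.write(
            "ID\tChromosome\tInsert Site\tOrientation\tOverlapping gene\t"
            "Left support\tRight support\tTSD\tValidation\tStatus\n"
        )
        for c in calls:
            site = f"{c.junction[0]:,}-{c.junction[1]:,}"
            val = "-"
            if c.validation is not None:
                val = f"{c.validation.left_spanning}/{c.validation.right_spanning}"
            fh.write(
                "\t".join(
                    [
                        sample_id,
                        c.chrom,
                        site,
                        c.orientation.capitalize(),
                        c.annotation or "-",
                        str(c.left_support),
                        str(c.right_support),
                        c.tsd_found or "-",
                        val,
                        c.status,
                    ]
                )
                + "\n"
            )


def write_call_bed(calls: list[IntegrationCall], path, name: str = "transgene") -> None:
    """BED6: 0-based half-open junction interval, score = total support,
    strand from orientation."""
    with open(path, "w") as fh:
        for c in calls:
            strand = {"forward": "+", "reverse": "-"}.get(c.orientation, ".")
            fh.write(
                f"{c.chrom}\t{c.junction[0] - 1}\t{c.junction[1]}\t{name}\t"
                f"{c.total_support}\t{strand}\n"
            )
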