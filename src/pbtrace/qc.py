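"""Read quality-control filters.

A read is discarded when any of three rules fires, evaluated in order:

1. N rule — more than 10% of bases are N (strict inequality);
2. low-quality-fraction rule — more than 40% of bases are below Q20;
3. mean-quality rule — arithmetic mean Phred score below Q20.

Boundary reads (exactly 10% N, exactly Q20 mean, exactly 40% sub-Q20)
pass: the thresholds are strict.  N bases contribute their recorded
quality score (clamped at 0) to the mean and low-quality fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReadRecord", "QcThresholds", "QcReport", "read_passes", "filter_pairs"]

RULE_N = "n_fraction"
RULE_LOWQ = "lowq_fraction"
RULE_MEAN = "mean_quality"


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred scores

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != self.qualities.size:
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")
        if self.qualities.size and (self.qualities.min() < 0 or self.qualities.max() > 60):
            raise ValueError(f"read {self.id!r}: Phred scores must be in [0, 60]")


@dataclass
class QcThresholds:
    max_n_fraction: float = 0.10
    max_lowq_fraction: float = 0.40
    lowq_cutoff: int = 20
    min_mean_quality: float = 20.0

    def __post_init__(self) -> None:
        for f in (self.max_n_fraction, self.max_lowq_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.lowq_cutoff < 0 or self.min_mean_quality < 0:
            raise ValueError("quality cutoffs must be non-negative")


def read_passes(read: ReadRecord, t: QcThresholds | None = None) -> tuple[bool, str | None]:
    """Apply the three discard rules; returns (passes, first_failing_rule)."""
    if t is None:
        t = QcThresholds()
    n = len(read.sequence)
    if n == 0:
        raise ValueError("empty read")
    qual = np.maximum(read.qualities, 0)
    n_frac = read.sequence.count("N") / n
    if n_frac > t.max_n_fraction:
        return False, RULE_N
    if np.count_nonzero(qual < t.lowq_cutoff) / n > t.max_lowq_fraction:
        return False, RULE_LOWQ
    if qual.mean() < t.min_mean_quality:
        return False, RULE_MEAN
    return True, None


@dataclass
class QcReport:
    total_pairs: int = 0
    kept_pairs: int = 0
    orphans: int = 0
    rule_failures: dict[str, int] = field(
        default_factory=lambda: {RULE_N: 0, RULE_LOWQ: 0, RULE_MEAN: 0}
    )

    @property
    def dropped_pairs(self) -> int:
        return self.total_pairs - self.kept_pairs

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "kept_pairs": self.kept_pairs,
            "dropped_pairs": self.dropped_pairs,
            "orphans": self.orphans,
            "rule_failures": dict(self.rule_failures),
        }


def filter_pairs(
    pairs: list[tuple[ReadRecord, ReadRecord]],
    t: QcThresholds | None = None,
    policy: str = "drop-pair",
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord], QcReport]:
    """Filter mate pairs, preserving input order.

    ``drop-pair`` (default) discards the whole pair when either mate
    fails; ``drop-single`` keeps the passing mate as an orphan.  Each
    failing mate increments exactly one rule counter (its first failing
    rule).
    """
    if policy not in ("drop-pair", "drop-single"):
        raise ValueError(f"unknown pair policy {policy!r}")
    if t is None:
        t = QcThresholds()
    report = QcReport()
    kept: list[tuple[ReadRecord, ReadRecord]] = []
    orphans: list[ReadRecord] = []
    for m1, m2 in pairs:
        if _pair_id(m1.id) != _pair_id(m2.id):
            raise ValueError(f"unmatched mate ids: {m1.id!r} vs {m2.id!r}")
        report.total_pairs += 1
        ok1, why1 = read_passes(m1, t)
        ok2, why2 = read_passes(m2, t)
        for why in (why1, why2):
            if why is not None:
                report.rule_failures[why] += 1
        if ok1 and ok2:
            kept.append((m1, m2))
            report.kept_pairs += 1
        elif policy == "drop-single":
            if ok1:
                orphans.append(m1)
            if ok2:
                orphans.append(m2)
            report.orphans += int(ok1) + int(ok2)
    return kept, orphans, report


def _pair_id(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id
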