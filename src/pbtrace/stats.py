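"""Comparative-CT relative expression and summary-statistics t-tests.

The comparative-CT (2^-ddCt) method: per sample, the target gene's Ct is
normalized against a reference gene (dCt = Ct_target - Ct_reference);
each dCt is then referenced to the mean dCt of a calibrator group
(ddCt), and relative expression is 2^-ddCt.  Group fold changes are
summarized by the geometric mean, the natural average on the fold scale.

The t-test operates on published summary statistics (mean, SD or SEM,
n), e.g. sperm-motility tables, so printed results can be re-analyzed
without raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CtPanel",
    "RelativeExpressionResult",
    "SummaryGroup",
    "TTestResult",
    "delta_delta_ct",
    "t_test_from_summary",
]


@dataclass
class CtPanel:
    """Per-sample, per-gene qPCR cycle-threshold values.

    ``data`` has columns sample, gene, ct (replicate rows allowed; they
    are averaged arithmetically before differencing)."""

    data: pd.DataFrame
    target_gene: str
    reference_gene: str
    calibrator_samples: list[str]

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"panel data needs columns {sorted(required)}")
        if not np.isfinite(self.data["ct"]).all():
            raise ValueError("all Ct values must be finite")
        samples = set(self.data["sample"])
        with_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        if samples - with_ref:
            missing = sorted(samples - with_ref)
            raise ValueError(f"reference gene {self.reference_gene!r} missing in samples {missing}")
        if not set(self.calibrator_samples) <= samples:
            raise ValueError("calibrator samples not present in panel")


@dataclass
class RelativeExpressionResult:
    per_sample: pd.DataFrame  # columns: sample, delta_ct, delta_delta_ct, fold
    calibrator_samples: list[str]

    @property
    def fold_change(self) -> float:
        """Geometric-mean fold of the non-calibrator samples."""
        mask = ~self.per_sample["sample"].isin(self.calibrator_samples)
        folds = self.per_sample.loc[mask, "fold"]
        if folds.empty:
            return 1.0
        return float(np.exp(np.log(folds).mean()))


def delta_delta_ct(panel: CtPanel) -> RelativeExpressionResult:
    """Comparative-CT quantification: dCt per sample, ddCt against the
    calibrator-group mean dCt, fold = 2^-ddCt."""
    means = (
        panel.data.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack()
    )
    if panel.target_gene not in means.columns:
        raise ValueError(f"target gene {panel.target_gene!r} absent from panel")
    dct = means[panel.target_gene] - means[panel.reference_gene]
    calibrator_dct = float(dct.loc[panel.calibrator_samples].mean())
    ddct = dct - calibrator_dct
    out = pd.DataFrame(
        {
            "sample": dct.index,
            "delta_ct": dct.values,
            "delta_delta_ct": ddct.values,
            "fold": np.power(2.0, -ddct.values),
        }
    ).reset_index(drop=True)
    return RelativeExpressionResult(per_sample=out, calibrator_samples=list(panel.calibrator_samples))


@dataclass
class SummaryGroup:
    label: str
    mean: float
    dispersion: float
    n: int
    dispersion_kind: str = "sd"  # or "sem"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dispersion_kind not in ("sd", "sem"):
            raise ValueError("dispersion_kind must be 'sd' or 'sem'")

    @property
    def sd(self) -> float:
        return self.dispersion * math.sqrt(self.n) if self.dispersion_kind == "sem" else self.dispersion


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    tails: int
    significant: bool  # at the conventional 0.05 level
    degenerate: bool = False  # zero dispersion in both groups


def t_test_from_summary(
    a: SummaryGroup,
    b: SummaryGroup,
    variant: str = "student_pooled",
    tails: int = 2,
) -> TTestResult:
    """Two-sample t-test from summary statistics.

    ``student_pooled`` assumes equal variances; ``welch`` does not.
    One-tailed p is for the observed direction of the difference.
    Degenerate inputs (zero dispersion in both groups): equal means give
    t = 0 with the maximally non-significant p; unequal means give p = 0,
    flagged."""
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if a.sd == 0.0 and b.sd == 0.0:
        df = a.n + b.n - 2
        if a.mean == b.mean:
            return TTestResult(0.0, df, 0.5 if tails == 1 else 1.0, variant, tails, False, True)
        t = math.inf if a.mean > b.mean else -math.inf
        return TTestResult(t, df, 0.0, variant, tails, True, True)
    t, p2 = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "student_pooled")
    )
    t = float(t)
    if variant == "student_pooled":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(p2) if tails == 2 else float(p2) / 2.0
    return TTestResult(t, float(df), p, variant, tails, p < 0.05)
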