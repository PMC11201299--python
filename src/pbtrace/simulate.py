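"""Offspring-genotype and qPCR-panel simulators with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import CtPanel

__all__ = ["simulate_offspring", "simulate_ct_panel"]


def simulate_offspring(
    sire_locus_count: int, n_offspring: int, seed: int = 0
) -> list[frozenset[int]]:
    """Genotypes of a hemizygous carrier x wild-type cross.

    Each of the sire's loci (labelled 0..k-1) transmits independently
    with probability 1/2; the dam contributes none.  Returns one locus
    set per offspring."""
    if sire_locus_count < 0:
        raise ValueError("sire_locus_count must be >= 0")
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    if sire_locus_count == 0:
        return [frozenset()] * n_offspring
    draws = rng.random((n_offspring, sire_locus_count)) < 0.5
    return [frozenset(np.nonzero(row)[0].tolist()) for row in draws]


def simulate_ct_panel(
    true_fold_change: float,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_gene: str = "Akap1",
    reference_gene: str = "Actb",
    base_target_ct: float = 28.0,
    base_reference_ct: float = 18.0,
) -> CtPanel:
    """Ct values for a calibrator group and a treated group whose target
    expression differs by ``true_fold_change``.

    The treated group's target Ct is offset by -log2(fold) relative to
    the calibrator after reference normalization; Gaussian noise of SD
    ``noise_sd`` cycles is added to every Ct measurement.  At zero noise
    the comparative-CT method recovers the fold change exactly."""
    if true_fold_change <= 0:
        raise ValueError("fold change must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    shift = -np.log2(true_fold_change)
    def noise() -> float:
        return float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0

    for group, offset in (("control", 0.0), ("treated", shift)):
        for i in range(n_replicates):
            sample = f"{group}_{i + 1}"
            rows.append((sample, target_gene, base_target_ct + offset + noise()))
            rows.append((sample, reference_gene, base_reference_ct + noise()))
    data = pd.DataFrame(rows, columns=["sample", "gene", "ct"])
    calibrators = [f"control_{i + 1}" for i in range(n_replicates)]
    return CtPanel(
        data=data,
        target_gene=target_gene,
        reference_gene=reference_gene,
        calibrator_samples=calibrators,
    )
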