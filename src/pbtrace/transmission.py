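"""Mendelian transmission of hemizygous transgene loci.

A founder carries k unlinked hemizygous insertion loci; backcrossed to
wild type, each locus transmits independently with probability 1/2, so a
fraction 1 - (1/2)^k of offspring carry at least one locus.  Repeated
backcrossing with carrier selection reduces the locus count toward one,
at which point half the litter is transgene-positive — the stopping
criterion for sequencing a late-generation carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SegregationObservation",
    "PedigreeConfig",
    "BreedingTrajectory",
    "expected_positive_fraction",
    "segregation_test",
    "infer_locus_count",
    "simulate_breeding",
]


@dataclass
class SegregationObservation:
    n_offspring: int
    n_positive: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_offspring:
            raise ValueError("need 0 <= n_positive <= n_offspring")


@dataclass
class PedigreeConfig:
    founder_locus_count: int = 4
    generations: int = 6
    litter_size: int = 10
    selection: str = "random_carrier"  # or "max_locus_carrier"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founder_locus_count < 1 or self.generations < 1 or self.litter_size < 1:
            raise ValueError("counts must be positive integers")
        if self.selection not in ("random_carrier", "max_locus_carrier"):
            raise ValueError(f"unknown selection policy {self.selection!r}")


@dataclass
class BreedingTrajectory:
    sire_locus_counts: list[int]  # per generation, starting with the founder
    carrier_fractions: list[float]  # per litter
    terminated_early: bool = False

    @property
    def final_locus_count(self) -> int:
        return self.sire_locus_counts[-1]


def expected_positive_fraction(k: int) -> float:
    """P(offspring carries >= 1 locus) for a k-locus hemizygous sire x
    wild-type dam: 1 - (1/2)^k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 1.0 - 0.5**k


def segregation_test(obs: SegregationObservation, null_fraction: float = 0.5) -> float:
    """Exact two-sided binomial test of the observed carrier count against
    ``null_fraction`` (probabilities <= that of the observation summed)."""
    if obs.n_offspring == 0:
        raise ValueError("n_offspring must be > 0")
    if not 0.0 < null_fraction < 1.0:
        raise ValueError("null_fraction must be in (0, 1)")
    return float(
        sps.binomtest(obs.n_positive, obs.n_offspring, null_fraction, alternative="two-sided").pvalue
    )


@dataclass
class LocusCountEstimate:
    k_hat: int | None
    log_likelihoods: dict[int, float]
    saturated: bool = False  # likelihood still rising at k_max

    @property
    def defined(self) -> bool:
        return self.k_hat is not None


def infer_locus_count(obs: SegregationObservation, k_max: int = 10) -> LocusCountEstimate:
    """Maximum-likelihood locus count from one litter's carrier count.

    The likelihood is Binomial(n, 1 - (1/2)^k); beyond a few loci the
    expected fraction saturates near 1, so large k are unresolvable and a
    k_hat == k_max estimate is flagged as saturated.  With zero positive
    offspring there is no carrier evidence and k_hat is undefined."""
    loglik = {
        k: float(sps.binom.logpmf(obs.n_positive, obs.n_offspring, expected_positive_fraction(k)))
        for k in range(1, k_max + 1)
    }
    if obs.n_positive == 0:
        return LocusCountEstimate(k_hat=None, log_likelihoods=loglik)
    k_hat = max(loglik, key=lambda k: (loglik[k], -k))
    return LocusCountEstimate(
        k_hat=k_hat, log_likelihoods=loglik, saturated=(k_hat == k_max)
    )


def simulate_breeding(config: PedigreeConfig) -> BreedingTrajectory:
    """Simulate the backcross scheme: each generation the selected sire's
    loci transmit independently (p = 1/2) to a litter, and the next sire
    is chosen among carriers per the selection policy.  A litter with no
    carriers terminates the trajectory early (flagged)."""
    rng = np.random.default_rng(config.seed)
    k = config.founder_locus_count
    counts = [k]
    fractions: list[float] = []
    terminated = False
    for _ in range(config.generations):
        litter = rng.random((config.litter_size, k)) < 0.5
        carrier_counts = litter.sum(axis=1)
        carriers = np.nonzero(carrier_counts > 0)[0]
        fractions.append(float(carriers.size / config.litter_size))
        if carriers.size == 0:
            terminated = True
            break
        if config.selection == "max_locus_carrier":
            best = carrier_counts[carriers].max()
            pool = carriers[carrier_counts[carriers] == best]
        else:
            pool = carriers
        chosen = int(pool[rng.integers(0, pool.size)])
        k = int(carrier_counts[chosen])
        counts.append(k)
    return BreedingTrajectory(
        sire_locus_counts=counts, carrier_fractions=fractions, terminated_early=terminated
    )
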