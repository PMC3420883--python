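"""Monte Carlo null for the total number of haplotype classes shared
between two populations across all genes.

Under the no-differentiation null, both populations are samples from one
metapopulation whose per-gene haplotype frequency vector is taken from the
observed data (by default the unweighted mean of the two populations'
frequency vectors).  Each replicate draws, per gene, an n1-chromosome and
an independent n2-chromosome multinomial sample from that vector; a class
is shared when it appears in both draws, and the per-replicate statistic is
the total shared count summed over genes.  The tail probability of the
observed total is read from a Gaussian fitted to the replicate totals, so
that probabilities below Monte Carlo resolution can still be reported; the
empirical fraction is kept alongside.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog import HaplotypeClass
from .errors import InputError

__all__ = [
    "SharingNullResult",
    "pooled_frequencies",
    "observed_shared_total",
    "simulate_shared",
    "gaussian_tail_p",
]


@dataclasses.dataclass
class SharingNullResult:
    level: str
    replicates: int
    seed: int
    totals: np.ndarray  # per-replicate total shared counts
    mean: float
    sd: float
    observed_total: int | None = None
    gaussian_p_lower: float | None = None
    empirical_p_lower: float | None = None


def _freqs_from_counts(c1: np.ndarray, c2: np.ndarray, n1: int, n2: int, pooling: str) -> np.ndarray:
    if pooling == "mean_of_frequencies":
        f = 0.5 * (c1 / n1 + c2 / n2)
    elif pooling == "pooled_counts":
        f = (c1 + c2) / (n1 + n2)
    else:
        raise InputError(f"unknown pooling mode {pooling!r}")
    return f / f.sum()


def pooled_frequencies(
    classes_by_gene: Mapping[str, Sequence[HaplotypeClass]],
    populations: tuple[str, str],
    pooling: str = "mean_of_frequencies",
) -> dict[str, np.ndarray]:
    """Per-gene metapopulation frequency vectors over the observed classes.

    ``mean_of_frequencies`` averages the two populations' class-frequency
    vectors without weighting by sample size; ``pooled_counts`` divides
    combined counts by combined chromosomes.  Every observed class enters
    the vector, including singletons and whole-gene-deletion classes.
    """
    p1, p2 = populations
    out: dict[str, np.ndarray] = {}
    for gene, classes in classes_by_gene.items():
        c1 = np.array([cls.counts.get(p1, 0) for cls in classes], dtype=float)
        c2 = np.array([cls.counts.get(p2, 0) for cls in classes], dtype=float)
        n1, n2 = c1.sum(), c2.sum()
        if n1 == 0 or n2 == 0:
            raise InputError(f"{gene}: a focal population has zero sampled chromosomes")
        out[gene] = _freqs_from_counts(c1, c2, n1, n2, pooling)
    return out


def observed_shared_total(
    classes_by_gene: Mapping[str, Sequence[HaplotypeClass]],
    populations: tuple[str, str],
) -> int:
    """Total number of classes observed in both focal populations."""
    p1, p2 = populations
    return sum(
        1
        for classes in classes_by_gene.values()
        for cls in classes
        if cls.counts.get(p1, 0) > 0 and cls.counts.get(p2, 0) > 0
    )


def simulate_shared(
    freqs_by_gene: Mapping[str, np.ndarray],
    n1: int,
    n2: int,
    replicates: int = 10_000,
    seed: int = 0,
    level: str = "",
) -> SharingNullResult:
    """Simulate the null distribution of the total shared-class count."""
    if replicates < 1:
        raise InputError("need at least one replicate")
    rng = np.random.default_rng(seed)
    totals = np.zeros(replicates, dtype=np.int64)
    for gene in freqs_by_gene:
        f = np.asarray(freqs_by_gene[gene], dtype=float)
        if n1 > 0 and n2 > 0:
            draw1 = rng.multinomial(n1, f, size=replicates)
            draw2 = rng.multinomial(n2, f, size=replicates)
            totals += ((draw1 > 0) & (draw2 > 0)).sum(axis=1)
        # if either sample is empty nothing can be shared at this gene
    return SharingNullResult(
        level=level,
        replicates=replicates,
        seed=seed,
        totals=totals,
        mean=float(totals.mean()),
        sd=float(totals.std(ddof=1)) if replicates > 1 else 0.0,
    )


def gaussian_tail_p(result: SharingNullResult, observed: int) -> SharingNullResult:
    """Lower-tail probability of seeing <= ``observed`` shared classes under
    a Gaussian fitted to the replicate totals (plus the raw empirical
    fraction).  Returns the result annotated in place."""
    result.observed_total = int(observed)
    if result.sd == 0:
        result.gaussian_p_lower = 1.0 if observed >= result.mean else 0.0
    else:
        result.gaussian_p_lower = float(
            stats.norm.cdf((observed - result.mean) / result.sd)
        )
    result.empirical_p_lower = float((result.totals <= observed).mean())
    return result
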