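"""Neutrality tests: Tajima's D with a coalescent-simulated null,
a Fisher exact test on the pi_N/pi_S contrast, and a Wilcoxon rank-sum
comparison of D distributions against putatively neutral non-coding loci.

The coalescent null simulates standard neutral genealogies (no
recombination): with j ancestral lineages the waiting time to the next
coalescence is exponential with rate j(j-1)/2 (time in units of 2N
generations), and mutations fall on branches as a Poisson process with
rate theta/2 per unit branch length, with theta estimated from the
observed number of segregating sites by Watterson's formula
theta = S / a1.  Tajima's D is recomputed from each simulated
site-frequency configuration, giving the two-sided Monte Carlo p-value.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .diversity import nucleotide_diversity, syn_nonsyn_components
from .errors import InputError

__all__ = [
    "TajimaComponents",
    "CoalescentNull",
    "tajima_constants",
    "tajimas_d",
    "simulate_null_d",
    "tajima_p",
    "pin_pis_test",
    "compare_d_distributions",
]


@dataclasses.dataclass
class TajimaComponents:
    n: int
    S: int
    k_bar: float  # mean pairwise differences (count, not per site)
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float  # NaN when S == 0


@dataclasses.dataclass
class CoalescentNull:
    replicates: int
    conditioning: str  # theta_watterson | fixed_S
    seed: int
    d_values: np.ndarray  # NaN where a replicate had S = 0

    @property
    def n_segregating(self) -> int:
        return int(np.isfinite(self.d_values).sum())


def tajima_constants(n: int) -> dict[str, float]:
    """The standard constants of Tajima's variance normalisation."""
    if n < 2:
        raise InputError("need n >= 2")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _d_from_counts(n: int, S, k_bar, const) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    k_bar = np.asarray(k_bar, dtype=float)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (k_bar - S / const["a1"]) / np.sqrt(var)
    # S = 0 leaves D undefined; so does n < 4, where the variance constants
    # c1 and c2 vanish identically
    return np.where((S > 0) & (var > 0), d, np.nan)


def tajimas_d(aln_or_seqs) -> TajimaComponents:
    """Tajima's D for one population's (gap-eliminated) alignment."""
    if isinstance(aln_or_seqs, (list, tuple)):
        seqs = list(aln_or_seqs)
    else:
        seqs = list(aln_or_seqs.sequences.values())
    n = len(seqs)
    if n < 2:
        raise InputError("Tajima's D needs n >= 2")
    pi, L, S = nucleotide_diversity(seqs)
    k_bar = pi * L if L else 0.0
    const = tajima_constants(n)
    D = float(_d_from_counts(n, S, k_bar, const)) if S > 0 else float("nan")
    return TajimaComponents(n=n, S=S, k_bar=float(k_bar), D=D, **const)


# ---------------------------------------------------------------------------
# coalescent null


def _simulate_branch_lengths(n: int, replicates: int, rng: np.random.Generator) -> np.ndarray:
    """Total branch length subtending i descendants (i = 1..n-1), per
    replicate, under the standard Kingman coalescent; vectorised across
    replicates.  Returns an array of shape (replicates, n-1)."""
    R = replicates
    # descendant count of each active lineage; -1 marks a dead slot
    desc = np.ones((R, n), dtype=np.int64)
    active = np.tile(np.arange(n), (R, 1))  # indices of live slots
    lengths = np.zeros((R, n), dtype=float)  # accumulated length per slot
    by_class = np.zeros((R, n - 1), dtype=float)
    rows = np.arange(R)
    for k in range(n, 1, -1):
        rate = k * (k - 1) / 2.0
        dt = rng.exponential(1.0 / rate, size=R)
        # every live lineage ages by dt
        live = active[:, :k]
        lengths[rows[:, None], live] += dt[:, None]
        # choose a random pair (i < j among the k live slots) per replicate
        i = rng.integers(0, k, size=R)
        j = rng.integers(0, k - 1, size=R)
        j = np.where(j >= i, j + 1, j)
        slot_i = active[rows, i]
        slot_j = active[rows, j]
        # the two merging lineages close out: bank their lengths by class
        for slot in (slot_i, slot_j):
            cls = desc[rows, slot] - 1
            by_class[rows, cls] += lengths[rows, slot]
            lengths[rows, slot] = 0.0
        # merged lineage lives in slot_i; retire slot_j by swapping it with
        # the last live position
        desc[rows, slot_i] = desc[rows, slot_i] + desc[rows, slot_j]
        desc[rows, slot_j] = -1
        last = active[:, k - 1].copy()
        active[rows, j] = last
        active[:, k - 1] = -1
        # keep slot_i where it is (it may have been swapped into position j's
        # place only if i == k-1, handled by the swap above)
    return by_class


def simulate_null_d(
    n: int,
    S_obs: int,
    replicates: int = 10_000,
    seed: int = 0,
    conditioning: str = "theta_watterson",
) -> CoalescentNull:
    """Simulate the neutral-coalescent null distribution of Tajima's D.

    ``theta_watterson`` (default): mutations are Poisson with rate
    theta/2 per unit branch length, theta = S_obs / a1; replicates may
    then have any S, including 0 (D undefined, kept as NaN).
    ``fixed_S``: exactly S_obs mutations are dropped on branches chosen
    proportionally to length (sensitivity-analysis mode).
    """
    if replicates < 1:
        raise InputError("need at least one replicate")
    if n < 2 or S_obs < 1:
        raise InputError("need n >= 2 and S_obs >= 1")
    rng = np.random.default_rng(seed)
    const = tajima_constants(n)
    by_class = _simulate_branch_lengths(n, replicates, rng)  # (R, n-1)
    if conditioning == "theta_watterson":
        theta = S_obs / const["a1"]
        mut = rng.poisson(0.5 * theta * by_class)
    elif conditioning == "fixed_S":
        tot = by_class.sum(axis=1, keepdims=True)
        p = by_class / tot
        mut = np.empty_like(by_class, dtype=np.int64)
        for r in range(replicates):  # multinomial is per-row
            mut[r] = rng.multinomial(S_obs, p[r])
    else:
        raise InputError(f"unknown conditioning {conditioning!r}")
    S_sim = mut.sum(axis=1)
    i = np.arange(1, n)
    pair_weight = 2.0 * i * (n - i) / (n * (n - 1))
    k_bar = mut @ pair_weight
    d = _d_from_counts(n, S_sim, k_bar, const)
    return CoalescentNull(
        replicates=replicates, conditioning=conditioning, seed=seed, d_values=d
    )


def tajima_p(d_obs: float, null: CoalescentNull) -> tuple[float, bool]:
    """Two-sided Monte Carlo p-value for an observed D against the null.

    Replicates with S = 0 (NaN D) stay in the denominator as
    non-exceedances.  Returns (p, is_floor): when no replicate is as
    extreme, p is floored at 1/replicates and flagged, to be reported as
    '< 1/replicates'.
    """
    vals = null.d_values
    R = len(vals)
    if R == 0 or not np.isfinite(vals).any():
        return float("nan"), False
    if not math.isfinite(d_obs):
        return float("nan"), False
    finite = vals[np.isfinite(vals)]
    lower = (finite <= d_obs).sum() / R
    upper = (finite >= d_obs).sum() / R
    p = min(1.0, 2.0 * min(lower, upper))
    if p <= 0.0:
        return 1.0 / R, True
    return float(p), False


# ---------------------------------------------------------------------------
# class-level selection tests


def pin_pis_test(aln_or_seqs) -> tuple[float, float, dict]:
    """pi_N/pi_S with a two-sided Fisher exact test.

    The 2x2 table contrasts [rounded mean nonsynonymous differences,
    rounded mean synonymous differences] against the remaining
    [nonsynonymous sites - differences, synonymous sites - differences].
    Returns (ratio, p, metadata); ratio is NaN and no test is run when
    pi_S = 0.
    """
    comp = syn_nonsyn_components(aln_or_seqs)
    meta = dict(comp)
    if not comp["syn_diffs"] or not comp["syn_sites"] or comp["pi_s"] == 0:
        return float("nan"), float("nan"), meta
    ratio = comp["pi_n"] / comp["pi_s"]
    nd = round(comp["nonsyn_diffs"])
    sd = round(comp["syn_diffs"])
    table = [
        [nd, sd],
        [round(comp["nonsyn_sites"] - comp["nonsyn_diffs"]),
         round(comp["syn_sites"] - comp["syn_diffs"])],
    ]
    if min(min(row) for row in table) < 0:  # saturated divergence: no test
        return float(ratio), float("nan"), meta
    _, p = stats.fisher_exact(table, alternative="two-sided")
    meta["table"] = table
    return float(ratio), float(p), meta


def compare_d_distributions(
    d_genes, d_reference
) -> tuple[float, float]:
    """Median D of the gene set and a two-sided Wilcoxon rank-sum p-value
    against a non-coding reference set.  NA values (monomorphic loci) are
    removed listwise; exact enumeration when the combined size is <= 20 and
    there are no ties, normal approximation with tie correction otherwise.
    """
    x = np.asarray([d for d in d_genes if np.isfinite(d)], dtype=float)
    y = np.asarray([d for d in d_reference if np.isfinite(d)], dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan"), float("nan")
    median = float(np.median(x))
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return median, float(res.pvalue)
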