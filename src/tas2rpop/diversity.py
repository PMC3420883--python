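"""Within- and between-population diversity statistics.

All statistics are *uncorrected proportions* (no Jukes–Cantor correction):
intraspecific distances here are far below saturation, and the printed
magnitudes in receptor surveys of this kind are consistent with raw values.
Internally everything is a raw proportion in [0, 1]; report writers may
display values x100.

Gap handling is "complete deletion": any alignment column containing a gap
('-') or an undetermined base ('N') is removed before computing a statistic,
per analysis unit (per gene and population for pi; across the union of both
populations for d_XY).

Synonymous/nonsynonymous site and difference counting follows the
Nei–Gojobori method: per codon, the synonymous site count at each position
is the fraction of the 3 possible substitutions that preserve the amino
acid; pairwise differences between codons differing at >1 position are
averaged over all mutational pathways, excluding pathways that pass through
a stop codon (unless all do).
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .errors import InputError
from .io import GeneAlignment

__all__ = [
    "CODON_TO_AA",
    "nucleotide_diversity",
    "nei_gojobori_sites",
    "codon_pathway_differences",
    "syn_nonsyn_diversity",
    "dxy",
    "site_fst",
    "empirical_percentile",
    "concatenate_class",
]

_BASES = "ACGT"

# standard nuclear genetic code; '*' marks stop
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

STOP_CODONS = frozenset(c for c, a in CODON_TO_AA.items() if a == "*")
START_CODON = "ATG"


def translate(seq: str) -> str:
    """Translate an in-frame DNA string; codons with gaps/N become 'X'."""
    return "".join(
        CODON_TO_AA.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


# ---------------------------------------------------------------------------
# column helpers


def _as_matrix(seqs: Sequence[str]) -> np.ndarray:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise InputError(f"sequences of unequal length: {sorted(lengths)}")
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def _complete_deletion(mat: np.ndarray) -> np.ndarray:
    """Drop every column containing a gap or an N."""
    bad = ((mat == b"-") | (mat == b"N")).any(axis=0)
    return mat[:, ~bad]


def _seqs_of(aln_or_seqs) -> list[str]:
    if isinstance(aln_or_seqs, GeneAlignment):
        return list(aln_or_seqs.sequences.values())
    return list(aln_or_seqs)


# ---------------------------------------------------------------------------
# pi


def nucleotide_diversity(aln_or_seqs) -> tuple[float, int, int]:
    """Mean pairwise nucleotide difference per site within one population.

    Returns ``(pi, L, S)`` where L is the number of analyzed sites after
    complete deletion of gap/N columns and S the number of segregating
    sites among them.  ``pi`` is NaN when n < 2 or L = 0.
    """
    seqs = _seqs_of(aln_or_seqs)
    n = len(seqs)
    if n < 2:
        return float("nan"), 0, 0
    mat = _complete_deletion(_as_matrix(seqs))
    L = mat.shape[1]
    if L == 0:
        return float("nan"), 0, 0
    # pi from per-column allele counts: sum over unordered pairs of
    # mismatch probability, normalised by C(n,2) and L
    mismatch_pairs = 0.0
    S = 0
    for col in range(L):
        _, counts = np.unique(mat[:, col], return_counts=True)
        if len(counts) > 1:
            S += 1
            mismatch_pairs += (n * n - int((counts.astype(np.int64) ** 2).sum())) / 2.0
    pi = mismatch_pairs / (n * (n - 1) / 2.0) / L
    return pi, L, S


# ---------------------------------------------------------------------------
# Nei–Gojobori


@lru_cache(maxsize=None)
def nei_gojobori_sites(codons: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for an in-frame codon string.

    Per codon position, the synonymous fraction is (number of the 3 possible
    base changes that preserve the amino acid) / 3; changes creating a stop
    codon count as nonsynonymous.  Stop codons themselves contribute no
    sites and must be stripped by the caller along with the start codon.
    """
    if len(codons) % 3:
        raise InputError("codon string length must be a multiple of 3")
    syn = 0.0
    ncod = 0
    for i in range(0, len(codons), 3):
        codon = codons[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None or aa == "*":
            continue
        ncod += 1
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if CODON_TO_AA[mut] == aa:
                    syn += 1.0 / 3.0
    return syn, 3.0 * ncod - syn


@lru_cache(maxsize=None)
def codon_pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    codons, averaging over all orderings of the differing positions.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all are used (the difference is then dominated by nonsense steps).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    stopfree: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        s = ns = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                s += 1.0
            else:
                ns += 1.0
            if CODON_TO_AA[nxt] == "*":
                through_stop = True
            cur = nxt
        paths.append((s, ns))
        if not through_stop:
            stopfree.append((s, ns))
    use = stopfree if stopfree else paths
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


def _codon_columns(seqs: list[str]) -> list[int]:
    """Indices of analyzable codons: in the column-triplet frame, excluding
    the start codon, the terminal codon, and any codon containing gap/N in
    any sequence."""
    L = len(seqs[0])
    if L % 3:
        raise InputError(f"aligned length {L} is not a multiple of 3")
    ncod = L // 3
    keep = []
    for j in range(1, ncod - 1):  # drop start and terminal stop codon
        cols = slice(3 * j, 3 * j + 3)
        if any(("-" in s[cols]) or ("N" in s[cols]) for s in seqs):
            continue
        keep.append(j)
    return keep


def syn_nonsyn_components(aln_or_seqs) -> dict:
    """Nei–Gojobori components for one population's alignment.

    Returns mean pairwise synonymous/nonsynonymous difference counts, the
    mean synonymous/nonsynonymous site counts (averaged over haplotypes),
    and the derived pi_S and pi_N, as a dict.
    """
    seqs = _seqs_of(aln_or_seqs)
    n = len(seqs)
    if n < 2:
        return dict(pi_s=float("nan"), pi_n=float("nan"), syn_sites=0.0,
                    nonsyn_sites=0.0, syn_diffs=0.0, nonsyn_diffs=0.0, n=n)
    keep = _codon_columns(seqs)
    codon_strings = [
        "".join(s[3 * j : 3 * j + 3] for j in keep) for s in seqs
    ]
    site_counts = {}
    syn_site_sum = nonsyn_site_sum = 0.0
    # collapse identical haplotypes: pairwise sums only need unique pairs
    # weighted by multiplicity
    uniq: dict[str, int] = {}
    for cs in codon_strings:
        uniq[cs] = uniq.get(cs, 0) + 1
    for cs, mult in uniq.items():
        if cs not in site_counts:
            site_counts[cs] = nei_gojobori_sites(cs)
        s, ns = site_counts[cs]
        syn_site_sum += mult * s
        nonsyn_site_sum += mult * ns
    syn_sites = syn_site_sum / n
    nonsyn_sites = nonsyn_site_sum / n
    uniq_seqs = list(uniq)
    # only polymorphic codons can contribute pairwise differences
    ncod = len(uniq_seqs[0]) // 3 if uniq_seqs else 0
    poly = [
        k
        for k in range(ncod)
        if len({cs[3 * k : 3 * k + 3] for cs in uniq_seqs}) > 1
    ]
    sd_tot = nd_tot = 0.0
    npairs = n * (n - 1) // 2
    for (a, ma), (b, mb) in itertools.combinations(uniq.items(), 2):
        w = ma * mb
        for k in poly:
            s, ns = codon_pathway_differences(a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3])
            sd_tot += w * s
            nd_tot += w * ns
    syn_diffs = sd_tot / npairs
    nonsyn_diffs = nd_tot / npairs
    pi_s = syn_diffs / syn_sites if syn_sites > 0 else float("nan")
    pi_n = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else float("nan")
    return dict(pi_s=pi_s, pi_n=pi_n, syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
                syn_diffs=syn_diffs, nonsyn_diffs=nonsyn_diffs, n=n)


def syn_nonsyn_diversity(aln_or_seqs) -> tuple[float, float]:
    """(pi_S, pi_N) for one population's alignment."""
    comp = syn_nonsyn_components(aln_or_seqs)
    return comp["pi_s"], comp["pi_n"]


# ---------------------------------------------------------------------------
# d_XY


def dxy(aln_a, aln_b) -> float:
    """Mean per-site difference over all between-population pairs.

    Complete deletion of gap/N columns is applied across the union of the
    two populations.  NaN if either population is empty.
    """
    seqs_a = _seqs_of(aln_a)
    seqs_b = _seqs_of(aln_b)
    if not seqs_a or not seqs_b:
        return float("nan")
    mat = _complete_deletion(_as_matrix(seqs_a + seqs_b))
    L = mat.shape[1]
    if L == 0:
        return float("nan")
    a = mat[: len(seqs_a)]
    b = mat[len(seqs_a) :]
    total = 0
    for row in a:
        total += int((b != row[None, :]).sum())
    return total / (len(seqs_a) * len(seqs_b)) / L


# ---------------------------------------------------------------------------
# per-site F_ST


def site_fst(counts_a: tuple[int, int], counts_b: tuple[int, int]) -> float:
    """Per-site F_ST from derived-allele counts, Hudson–Slatkin–Maddison form.

    ``counts_a`` and ``counts_b`` are (derived count k, sampled chromosomes n)
    in each population.  F_ST = 1 - Hw/Hb with Hw the sample-size-weighted
    mean of the unbiased within-population heterozygosities 2k(n-k)/(n(n-1))
    and Hb = (kA(nB-kB) + kB(nA-kA)) / (nA nB).  NaN when Hb = 0; equals 1
    exactly iff both populations are internally monomorphic and different.
    """
    ka, na = counts_a
    kb, nb = counts_b
    if na < 2 or nb < 2:
        raise InputError("site_fst needs >=2 chromosomes per population")
    hw_a = 2.0 * ka * (na - ka) / (na * (na - 1))
    hw_b = 2.0 * kb * (nb - kb) / (nb * (nb - 1))
    hw = (na * hw_a + nb * hw_b) / (na + nb)
    hb = (ka * (nb - kb) + kb * (na - ka)) / (na * nb)
    if hb == 0:
        return float("nan")
    return 1.0 - hw / hb


def empirical_percentile(value: float, reference: Iterable[float]) -> float:
    """Upper-tail empirical probability: fraction of reference values >= value
    (ties counted in the tail)."""
    ref = np.asarray(list(reference), dtype=float)
    if ref.size == 0:
        raise InputError("empty reference distribution")
    return float((ref >= value).mean())


# ---------------------------------------------------------------------------
# concatenation


def concatenate_class(
    alignments: Sequence[GeneAlignment],
    on_mismatch: str = "intersect",
    gene_id: str = "concatenated",
    class_label: str | None = None,
) -> GeneAlignment:
    """Column-wise concatenation of a class of genes, in the given order.

    Chromosome sets may differ between genes when some chromosomes carry
    whole-gene deletions; with ``on_mismatch='intersect'`` (default) any
    chromosome missing from some member gene is dropped from the whole
    concatenation, keeping the alignment rectangular.  With ``'error'`` an
    inconsistent chromosome set raises.
    """
    if not alignments:
        raise InputError("nothing to concatenate")
    sets = [set(a.sequences) for a in alignments]
    common = set.intersection(*sets)
    if on_mismatch == "error" and any(s != common for s in sets):
        raise InputError("inconsistent chromosome sets across genes")
    order = [c for c in alignments[0].sequences if c in common]
    seqs = {c: "".join(a.sequences[c] for a in alignments) for c in order}
    return GeneAlignment(
        gene_id=gene_id,
        sequences=seqs,
        class_label=class_label or alignments[0].class_label,
    )
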