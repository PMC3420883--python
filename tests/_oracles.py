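"""Independent brute-force oracles used to check the package's statistics.

Everything here is deliberately naive (all-pairs loops, literal formulas,
Biopython translation) and shares no code with the implementation paths it
verifies.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def drop_bad_columns(seqs: list[str]) -> list[str]:
    cols = [
        i
        for i in range(len(seqs[0]))
        if all(s[i] not in "-N" for s in seqs)
    ]
    return ["".join(s[i] for i in cols) for s in seqs]


def pi_bruteforce(seqs: list[str]) -> tuple[float, int, int]:
    """All-pairs Hamming / C(n,2) / L after dropping gap/N columns."""
    clean = drop_bad_columns(seqs)
    n, L = len(clean), len(clean[0])
    if n < 2 or L == 0:
        return math.nan, 0, 0
    diffs = sum(
        sum(a != b for a, b in zip(x, y))
        for x, y in itertools.combinations(clean, 2)
    )
    S = sum(len(set(col)) > 1 for col in zip(*clean))
    return diffs / (n * (n - 1) / 2) / L, L, S


def dxy_bruteforce(seqs_a: list[str], seqs_b: list[str]) -> float:
    clean = drop_bad_columns(seqs_a + seqs_b)
    a, b = clean[: len(seqs_a)], clean[len(seqs_a) :]
    L = len(clean[0])
    total = sum(
        sum(x != y for x, y in zip(s, t)) for s in a for t in b
    )
    return total / (len(a) * len(b)) / L


def ng_sites_enumerate(codon: str) -> tuple[float, float]:
    """Nei–Gojobori site counts by enumerating all 9 single-base changes."""
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(mut) == aa:
                syn += 1 / 3
    return syn, 3 - syn


def ng_pathway_enumerate(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences, excluding pathways through
    stop codons unless all pass through one."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    all_paths, clean_paths = [], []
    for order in itertools.permutations(diff):
        cur, s, ns, hit_stop = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if translate_codon(cur) == translate_codon(nxt):
                s += 1
            else:
                ns += 1
            if translate_codon(nxt) == "*":
                hit_stop = True
            cur = nxt
        all_paths.append((s, ns))
        if not hit_stop:
            clean_paths.append((s, ns))
    use = clean_paths or all_paths
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


def pin_pis_bruteforce(seqs: list[str]) -> tuple[float, float]:
    """pi_S and pi_N by exhaustive pair-and-pathway enumeration over
    analyzable codons (start, terminal and gap/N codons excluded)."""
    n = len(seqs)
    L = len(seqs[0])
    keep = [
        j
        for j in range(1, L // 3 - 1)
        if all(set(s[3 * j : 3 * j + 3]).isdisjoint("-N") for s in seqs)
    ]
    sites = []
    for s in seqs:
        tot_s = tot_n = 0.0
        for j in keep:
            a, b = ng_sites_enumerate(s[3 * j : 3 * j + 3])
            tot_s += a
            tot_n += b
        sites.append((tot_s, tot_n))
    mean_syn_sites = sum(x for x, _ in sites) / n
    mean_nonsyn_sites = sum(y for _, y in sites) / n
    sd = nd = 0.0
    for x, y in itertools.combinations(seqs, 2):
        for j in keep:
            s, ns = ng_pathway_enumerate(x[3 * j : 3 * j + 3], y[3 * j : 3 * j + 3])
            sd += s
            nd += ns
    npairs = n * (n - 1) / 2
    pi_s = (sd / npairs) / mean_syn_sites if mean_syn_sites else math.nan
    pi_n = (nd / npairs) / mean_nonsyn_sites if mean_nonsyn_sites else math.nan
    return pi_s, pi_n


def tajimas_d_literal(seqs: list[str]) -> float:
    """Tajima's D from the literal 1989 formulas, direct summation."""
    clean = drop_bad_columns(seqs)
    n = len(clean)
    pi, L, S = pi_bruteforce(seqs)
    if S == 0:
        return math.nan
    k_bar = pi * L
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # undefined for n < 4, where c1 = c2 = 0
        return math.nan
    return (k_bar - S / a1) / math.sqrt(var)


def random_alignment(rng, n: int, n_codons: int, mut_rate: float = 0.04) -> list[str]:
    """Random in-frame alignment: an ATG...stop ORF plus per-sequence random
    substitutions (interior positions only, never creating a stop)."""
    interior = []
    while len(interior) < n_codons - 2:
        c = "".join(rng.choice(list(BASES), size=3))
        if translate_codon(c) != "*":
            interior.append(c)
    anc = "ATG" + "".join(interior) + "TAA"
    out = []
    for _ in range(n):
        s = list(anc)
        for pos in range(3, len(anc) - 3):
            if rng.random() < mut_rate:
                choices = [b for b in BASES if b != s[pos]]
                b = choices[rng.integers(0, 3)]
                ci = pos // 3
                trial = s[3 * ci : 3 * ci + 3]
                trial[pos % 3] = b
                if translate_codon("".join(trial)) != "*":
                    s[pos] = b
        out.append("".join(s))
    return out
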