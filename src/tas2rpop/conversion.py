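"""Ectopic gene-conversion tract detection between paralogous genes.

A candidate recipient haplotype is screened for *informative sites*:
positions where (i) the donor-locus consensus differs from the recipient
consensus (majority over the other recipient haplotypes), (ii) the
candidate carries the donor state, and (iii) that state is a strict
minority among the other recipient haplotypes — co-carriers of the same
conversion event may share it, but the recipient majority may not, which
keeps ancestral shared polymorphism out.  A conversion tract is a maximal
run of consecutive informative sites uninterrupted by a discordant
diagnostic site (a position where donor and recipient consensus differ but
the candidate retains the recipient state).  Tract endpoints are reported
at the outermost informative sites — true endpoints between diagnostic
sites are unidentifiable — and tracts supported by fewer than
``min_support`` informative sites (default 2) are discarded to suppress
single-site homoplasy.

Paralogs are assumed pre-aligned to a common coordinate frame (equal-length
CDS, as holds for the receptor-cluster paralogs analysed here); unequal
lengths require a supplied pairwise alignment.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InputError
from .io import GeneAlignment

__all__ = ["ConversionTract", "informative_sites", "detect_tracts"]

_ALPHABET = "ACGTN-"
_CODE = {ord(c): i for i, c in enumerate(_ALPHABET)}
_N_IDX, _GAP_IDX = 4, 5


@dataclasses.dataclass
class ConversionTract:
    recipient_gene: str
    donor_gene: str
    recipient_haplotypes: tuple[str, ...]
    start: int  # CDS 1-based inclusive, on the recipient
    end: int
    informative_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def support(self) -> int:
        return len(self.informative_positions)


def _encode(alignment: GeneAlignment) -> np.ndarray:
    raw = np.frombuffer(
        "".join(alignment.sequences.values()).encode(), dtype=np.uint8
    ).reshape(len(alignment.sequences), alignment.length)
    out = np.empty_like(raw)
    for byte, idx in _CODE.items():
        out[raw == byte] = idx
    return out


def _column_counts(mat: np.ndarray) -> np.ndarray:
    """(6, L) state counts per column."""
    L = mat.shape[1]
    counts = np.zeros((len(_ALPHABET), L), dtype=np.int32)
    for idx in range(len(_ALPHABET)):
        counts[idx] = (mat == idx).sum(axis=0)
    return counts


def _consensus_idx(counts: np.ndarray, prefer: np.ndarray | None = None) -> np.ndarray:
    """Column-wise majority state; ties break toward ``prefer`` (a row of
    state indices, e.g. the reference haplotype) when given, else toward the
    alphabetically first state."""
    c = counts.astype(np.float64)
    if prefer is not None:
        c[prefer, np.arange(c.shape[1])] += 0.5
    return c.argmax(axis=0)


class _TractScanner:
    """Shared per-(recipient, donor) precomputation for all candidates."""

    def __init__(self, recipient: GeneAlignment, donor: GeneAlignment):
        if recipient.length != donor.length:
            raise InputError(
                f"{recipient.gene_id}/{donor.gene_id}: paralogs must share a "
                "coordinate frame (supply a pairwise alignment for unequal lengths)"
            )
        self.recipient = recipient
        self.ids = list(recipient.sequences)
        self.mat = _encode(recipient)
        self.counts = _column_counts(self.mat)
        donor_mat = _encode(donor)
        donor_prefer = None
        if donor.reference_id in donor.sequences:
            donor_prefer = donor_mat[list(donor.sequences).index(donor.reference_id)]
        self.donor_cons = _consensus_idx(_column_counts(donor_mat), donor_prefer)
        self.ref_row = None
        if recipient.reference_id in recipient.sequences:
            self.ref_row = self.mat[self.ids.index(recipient.reference_id)]
        # alignability: >=50% consensus identity over non-gap donor columns
        recip_cons_all = _consensus_idx(self.counts, self.ref_row)
        ident = (recip_cons_all == self.donor_cons).sum()
        if ident < 0.5 * recipient.length:
            raise InputError(
                f"{recipient.gene_id}/{donor.gene_id}: consensus identity below 50%"
            )

    def diagnostic_masks(self, candidate: str) -> tuple[np.ndarray, np.ndarray]:
        """(informative, discordant) boolean masks over columns for one
        candidate haplotype."""
        row = self.ids.index(candidate)
        cand = self.mat[row]
        n_others = len(self.ids) - 1
        counts_others = self.counts.copy()
        counts_others[cand, np.arange(self.mat.shape[1])] -= 1
        recip_cons = _consensus_idx(
            counts_others if n_others else self.counts, self.ref_row
        )
        d = self.donor_cons
        diagnostic = (d != recip_cons) & (d != _N_IDX) & (d != _GAP_IDX)
        donor_count_others = counts_others[d, np.arange(self.mat.shape[1])]
        minority = (2 * donor_count_others < n_others) if n_others else np.ones_like(d, bool)
        informative = diagnostic & (cand == d) & minority
        discordant = diagnostic & (cand != d)
        return informative, discordant


def informative_sites(
    recipient: GeneAlignment, donor: GeneAlignment, candidate: str
) -> list[int]:
    """CDS positions (1-based) diagnostic of donor origin on ``candidate``."""
    if candidate not in recipient.sequences:
        raise InputError(f"candidate {candidate!r} not in recipient alignment")
    scanner = _TractScanner(recipient, donor)
    informative, _ = scanner.diagnostic_masks(candidate)
    return [int(i) + 1 for i in np.flatnonzero(informative)]


def detect_tracts(
    recipient: GeneAlignment,
    donor: GeneAlignment,
    min_support: int = 2,
) -> list[ConversionTract]:
    """Detect conversion tracts on every recipient haplotype.

    Haplotypes sharing an identical informative-site profile are reported
    together in one tract record.
    """
    scanner = _TractScanner(recipient, donor)
    tracts: dict[tuple[int, ...], list[str]] = {}
    for candidate in recipient.sequences:
        informative, discordant = scanner.diagnostic_masks(candidate)
        sites = [int(i) + 1 for i in np.flatnonzero(informative)]
        if not sites:
            continue
        disc = np.flatnonzero(discordant) + 1
        # split runs of informative sites at intervening discordant sites
        runs: list[list[int]] = [[sites[0]]]
        for prev, cur in zip(sites, sites[1:]):
            if ((disc > prev) & (disc < cur)).any():
                runs.append([cur])
            else:
                runs[-1].append(cur)
        for run in runs:
            if len(run) < min_support:
                continue
            tracts.setdefault(tuple(run), []).append(candidate)
    return [
        ConversionTract(
            recipient_gene=recipient.gene_id,
            donor_gene=donor.gene_id,
            recipient_haplotypes=tuple(haps),
            start=run[0],
            end=run[-1],
            informative_positions=run,
        )
        for run, haps in sorted(tracts.items())
    ]
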