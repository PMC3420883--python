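"""Variant calling, coding-effect classification and haplotype cataloguing.

Variants are called against a designated reference haplotype in the same
alignment.  Every variable site becomes a :class:`SiteVariant` with one of
six effect classes: synonymous, nonsynonymous, loss_of_start, gain_of_stop,
loss_of_stop, or indel (frameshifting when the net length change is not a
multiple of 3).

Functional status of a whole haplotype is decided by three lesion rules
(any one suffices for a segregating pseudogene):

* no ATG at CDS positions 1-3 **and** no rescuing alternative ATG at 4-6;
* an internal stop codon before the terminal codon;
* net indel length not a multiple of 3 (frameshift).

Chromosomes lacking the entire gene (no amplicon: a whole-gene deletion,
the copy-number variant class) form their own non-functional haplotype
class per gene.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diversity import CODON_TO_AA, START_CODON, STOP_CODONS, translate
from .errors import InputError
from .io import GeneAlignment, PopulationManifest

__all__ = [
    "SiteVariant",
    "HaplotypeClass",
    "SharingSummary",
    "call_variants",
    "functional_status",
    "lesion_signature",
    "catalog_table",
    "collapse_haplotypes",
    "sharing_summary",
    "deletion_span",
]

EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "loss_of_start",
    "gain_of_stop",
    "loss_of_stop",
    "indel",
)


@dataclasses.dataclass
class SiteVariant:
    """One variable site or indel, with per-population derived counts."""

    gene_id: str
    position: int  # CDS 1-based; for indels the first affected position
    ref_state: str
    alt_state: str
    effect: str
    frameshift: bool
    counts: dict[str, tuple[int, int]]  # population -> (derived, sampled)
    carrier_ids: tuple[str, ...] = ()

    def frequency(self, population: str) -> float:
        k, n = self.counts.get(population, (0, 0))
        return k / n if n else float("nan")


@dataclasses.dataclass
class HaplotypeClass:
    """A collapsed nucleotide- or protein-level haplotype class."""

    gene_id: str
    level: str  # nucleotide | protein
    key: str  # canonical sequence / signature; "" for whole-gene deletions
    status: str  # functional | nonfunctional
    mechanism: str  # none | pseudogene | whole_gene_deletion
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclasses.dataclass
class SharingSummary:
    level: str
    total_classes: int
    unique_to_one_population: int
    shared: int
    per_population: dict[str, dict[str, int]]
    high_frequency_only: bool


# ---------------------------------------------------------------------------
# functional status


def functional_status(haplotype: str | None) -> tuple[str, str]:
    """Classify one ungapped CDS haplotype (or ``None`` for a whole-gene
    deletion) as (status, mechanism).

    A loss of the ATG at positions 1-3 is rescued by an in-frame
    alternative ATG at positions 4-6; such haplotypes stay functional.
    """
    if haplotype is None:
        return "nonfunctional", "whole_gene_deletion"
    seq = haplotype.replace("-", "").upper()
    if not seq:
        raise InputError("empty haplotype is not a valid CDS (use None for deletions)")
    if len(seq) % 3:
        return "nonfunctional", "pseudogene"  # frameshift
    if seq[0:3] == START_CODON:
        offset = 0
    elif seq[3:6] == START_CODON:
        offset = 3
    else:
        return "nonfunctional", "pseudogene"  # no start codon
    frame = seq[offset:]
    for i in range(0, len(frame) - 3, 3):  # exclude terminal codon
        if CODON_TO_AA.get(frame[i : i + 3]) == "*":
            return "nonfunctional", "pseudogene"  # premature stop
    return "functional", "none"


def lesion_signature(haplotype: str) -> str:
    """Compact description of why a haplotype is a pseudogene ('' if intact).

    Distinct lesions (different stop positions, different frameshifts) give
    distinct signatures, so two independent nonsense alleles with the same
    truncated product remain distinguishable protein classes.
    """
    seq = haplotype.replace("-", "").upper()
    parts = []
    if len(seq) % 3:
        parts.append(f"frameshift:{len(seq) % 3}")
    offset = 0 if seq[0:3] == START_CODON else (3 if seq[3:6] == START_CODON else -1)
    if offset < 0:
        parts.append("no_start")
        offset = 0
    frame = seq[offset : len(seq) - (len(seq) - offset) % 3]
    for i in range(0, max(len(frame) - 3, 0), 3):
        if CODON_TO_AA.get(frame[i : i + 3]) == "*":
            parts.append(f"stop@{i // 3 + 1}")
            break
    return ",".join(parts)


# ---------------------------------------------------------------------------
# variant calling


def _classify_substitution(
    ref_codon: str, new_codon: str, codon_index: int, is_terminal: bool
) -> str:
    if codon_index == 0 and ref_codon == START_CODON and new_codon != START_CODON:
        return "loss_of_start"
    ref_aa = CODON_TO_AA.get(ref_codon)
    new_aa = CODON_TO_AA.get(new_codon)
    if is_terminal and ref_aa == "*" and new_aa != "*":
        return "loss_of_stop"
    if not is_terminal and new_aa == "*" and ref_aa != "*":
        return "gain_of_stop"
    if ref_aa is not None and ref_aa == new_aa:
        return "synonymous"
    return "nonsynonymous"


def call_variants(
    alignment: GeneAlignment,
    manifest: PopulationManifest,
    reference_id: str | None = None,
    reference_seq: str | None = None,
) -> list[SiteVariant]:
    """Call one SiteVariant per (variable column, alt state) and per
    contiguous gap run, classified on the reference reading frame.

    The reference haplotype is either a chromosome in the alignment
    (``reference_id``) or an externally supplied sequence aligned to the
    same columns (``reference_seq``, e.g. a simulated ancestor).  Derived
    polarity is "non-reference" throughout.

    Multi-base substitutions inside one codon of one haplotype are
    classified by direct translation of the carrier codon against the
    reference codon, so loss-of-start / gain-of-stop semantics follow the
    realized protein, not each base in isolation.
    """
    if reference_seq is not None:
        ref_id = None
        ref = reference_seq.upper()
        if len(ref) != alignment.length:
            raise InputError(
                f"{alignment.gene_id}: reference sequence not aligned to the "
                f"alignment columns ({len(ref)} vs {alignment.length})"
            )
    else:
        ref_id = reference_id or alignment.reference_id
        if ref_id is None or ref_id not in alignment.sequences:
            raise InputError(f"{alignment.gene_id}: reference {ref_id!r} not in alignment")
        ref = alignment.sequences[ref_id]
    if "-" in ref[:3]:
        raise InputError(f"{alignment.gene_id}: reference has gaps at the start codon")

    # reference CDS <-> alignment column maps
    cols_of_cds: list[int] = [i for i, ch in enumerate(ref) if ch != "-"]
    cds_of_col = {col: i for i, col in enumerate(cols_of_cds)}
    ref_cds = "".join(ref[c] for c in cols_of_cds)
    n_codons = len(ref_cds) // 3

    pops = manifest.populations
    in_manifest = {c for c in alignment.sequences if c != ref_id and c in manifest._pop}
    denom = {
        p: sum(1 for c in in_manifest if manifest.population_of(c) == p)
        for p in pops
    }
    others = [
        (cid, s) for cid, s in alignment.sequences.items() if cid in in_manifest
    ]

    variants: list[SiteVariant] = []

    # substitutions
    for col in cols_of_cds:
        ref_state = ref[col]
        by_alt: dict[str, list[str]] = defaultdict(list)
        for cid, s in others:
            ch = s[col]
            if ch not in ("-", "N") and ch != ref_state:
                by_alt[ch].append(cid)
        for alt, carriers in sorted(by_alt.items()):
            cds_pos = cds_of_col[col]
            ci = cds_pos // 3
            ref_codon = ref_cds[3 * ci : 3 * ci + 3]
            # carrier codon, for direct-translation classification
            codon_cols = cols_of_cds[3 * ci : 3 * ci + 3]
            carrier_seq = alignment.sequences[carriers[0]]
            new_codon = "".join(carrier_seq[c] for c in codon_cols)
            if len(ref_codon) < 3 or "-" in new_codon or "N" in new_codon:
                new_codon = (
                    ref_codon[: cds_pos % 3] + alt + ref_codon[cds_pos % 3 + 1 :]
                )
            effect = _classify_substitution(ref_codon, new_codon, ci, ci == n_codons - 1)
            counts = {
                p: (
                    sum(1 for c in carriers if manifest.population_of(c) == p),
                    denom[p],
                )
                for p in pops
            }
            variants.append(
                SiteVariant(
                    gene_id=alignment.gene_id,
                    position=cds_pos + 1,
                    ref_state=ref_state,
                    alt_state=alt,
                    effect=effect,
                    frameshift=False,
                    counts=counts,
                    carrier_ids=tuple(carriers),
                )
            )

    # indels: gap runs relative to the reference
    indel_groups: dict[tuple[int, str, str], list[str]] = defaultdict(list)
    L = alignment.length
    for cid, s in others:
        if cid == ref_id:
            continue
        col = 0
        while col < L:
            if s[col] == "-" and ref[col] != "-":  # deletion in carrier
                start = col
                while col < L and s[col] == "-" and ref[col] != "-":
                    col += 1
                deleted = ref[start:col]
                pos = cds_of_col[start] + 1
                indel_groups[(pos, deleted, "")].append(cid)
            elif ref[col] == "-" and s[col] != "-":  # insertion in carrier
                start = col
                while col < L and ref[col] == "-" and s[col] != "-":
                    col += 1
                inserted = s[start:col]
                nxt = next((c for c in cols_of_cds if c >= col), None)
                pos = (cds_of_col[nxt] + 1) if nxt is not None else len(ref_cds) + 1
                indel_groups[(pos, "", inserted)].append(cid)
            else:
                col += 1
    for (pos, ref_state, alt_state), carriers in sorted(indel_groups.items()):
        net = abs(len(alt_state) - len(ref_state))
        counts = {
            p: (sum(1 for c in carriers if manifest.population_of(c) == p), denom[p])
            for p in pops
        }
        variants.append(
            SiteVariant(
                gene_id=alignment.gene_id,
                position=pos,
                ref_state=ref_state,
                alt_state=alt_state,
                effect="indel",
                frameshift=bool(net % 3),
                counts=counts,
                carrier_ids=tuple(sorted(carriers)),
            )
        )

    variants.sort(key=lambda v: (v.position, v.ref_state, v.alt_state))
    return variants


# ---------------------------------------------------------------------------
# Table-1-style catalog

_LESION_EFFECTS = {"loss_of_start", "gain_of_stop", "loss_of_stop", "indel"}

_MUTATION_LABEL = {
    "loss_of_start": "LIC",
    "gain_of_stop": "GTC",
    "loss_of_stop": "LTC",
}


def _freq_cell(k: int, n: int) -> str:
    if k == 0 or n == 0:
        return "0"
    return f"{k}/{n} ({round(100 * k / n)}%)"


def catalog_table(
    variants: Iterable[SiteVariant],
    alignments: Mapping[str, GeneAlignment],
    manifest: PopulationManifest,
) -> pd.DataFrame:
    """Catalog of loss-of-function-class variations: one row per
    (gene, mutation class), with a function verdict obtained by running
    :func:`functional_status` on an actual carrier haplotype, and
    per-population allele frequencies rendered as ``k/n (percent)``.

    Whole-gene-deletion rows are appended from the manifest flags.
    """
    pops = manifest.populations
    rows = []
    for v in variants:
        if v.effect not in _LESION_EFFECTS:
            continue
        if v.effect == "indel":
            net = abs(len(v.alt_state) - len(v.ref_state))
            label = f"{net} bp {'ins.' if v.alt_state else 'del.'}"
        else:
            label = _MUTATION_LABEL[v.effect]
        carrier = alignments[v.gene_id].sequences[v.carrier_ids[0]]
        status, _ = functional_status(carrier)
        row = {
            "gene": v.gene_id,
            "mutation": label,
            "function": "Non-functional" if status == "nonfunctional" else "Functional",
        }
        for p in pops:
            k, n = v.counts.get(p, (0, 0))
            row[p] = _freq_cell(k, n)
        rows.append(row)
    for gene_id in alignments:
        deleted = manifest.deleted_chromosomes(gene_id)
        if not deleted:
            continue
        row = {"gene": gene_id, "mutation": "WGD", "function": "Non-functional"}
        for p in pops:
            k = len(manifest.deleted_chromosomes(gene_id, p))
            n = len(manifest.chromosomes(p))  # all sampled chromosomes of p
            row[p] = _freq_cell(k, n)
        rows.append(row)
    cols = ["gene", "mutation", "function", *pops]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# haplotype collapsing & sharing


def collapse_haplotypes(
    alignment: GeneAlignment, manifest: PopulationManifest, level: str
) -> list[HaplotypeClass]:
    """Collapse chromosomes into nucleotide- or protein-level classes.

    Nucleotide classes key on the full aligned sequence.  Protein classes
    key on the predicted translation for functional haplotypes and on
    (lesion signature + translated-through product) for pseudogenes, so
    independent lesions remain distinct.  Deletion-flagged chromosomes form
    one whole-gene-deletion class per gene (empty key).
    """
    if level not in ("nucleotide", "protein"):
        raise InputError(f"unknown collapse level {level!r}")
    pops = manifest.populations
    groups: dict[tuple[str, str, str], dict[str, int]] = {}
    order: list[tuple[str, str, str]] = []
    for cid, seq in alignment.sequences.items():
        if level == "nucleotide":
            key, status, mech = seq, "", ""
            status, mech = functional_status(seq)
        else:
            ungapped = seq.replace("-", "")
            status, mech = functional_status(ungapped)
            if status == "functional":
                offset = 0 if ungapped[0:3] == START_CODON else 3
                key = translate(ungapped[offset:])
            else:
                key = lesion_signature(ungapped) + "|" + translate(ungapped)
        gkey = (key, status, mech)
        if gkey not in groups:
            groups[gkey] = {p: 0 for p in pops}
            order.append(gkey)
        groups[gkey][manifest.population_of(cid)] += 1
    classes = [
        HaplotypeClass(alignment.gene_id, level, key, status, mech, groups[(key, status, mech)])
        for (key, status, mech) in order
    ]
    deleted = manifest.deleted_chromosomes(alignment.gene_id)
    if deleted:
        counts = {p: 0 for p in pops}
        for c in deleted:
            counts[manifest.population_of(c)] += 1
        classes.append(
            HaplotypeClass(
                alignment.gene_id, level, "", "nonfunctional", "whole_gene_deletion", counts
            )
        )
    return classes


def sharing_summary(
    classes_by_gene: Mapping[str, Sequence[HaplotypeClass]],
    populations: Sequence[str],
    high_frequency_only: bool = False,
) -> SharingSummary:
    """Aggregate, over genes, how many haplotype classes are unique to a
    single population versus shared.

    With ``high_frequency_only`` classes observed on <=1 chromosome overall
    (singletons) are removed first, mirroring the rare-haplotype filter.
    """
    populations = list(populations)
    level = ""
    total = unique = 0
    per_pop = {p: {"unique": 0, "present": 0} for p in populations}
    for gene, classes in classes_by_gene.items():
        for cls in classes:
            unknown = [p for p in populations if p not in cls.counts]
            if unknown:
                raise InputError(f"unknown population label(s) {unknown}")
            level = cls.level
            counts = {p: cls.counts[p] for p in populations}
            tot = sum(counts.values())
            if tot == 0:
                continue
            if high_frequency_only and tot <= 1:
                continue
            total += 1
            nonzero = [p for p, k in counts.items() if k > 0]
            for p in nonzero:
                per_pop[p]["present"] += 1
            if len(nonzero) == 1:
                unique += 1
                per_pop[nonzero[0]]["unique"] += 1
    return SharingSummary(
        level=level,
        total_classes=total,
        unique_to_one_population=unique,
        shared=total - unique,
        per_population=per_pop,
        high_frequency_only=high_frequency_only,
    )


def deletion_span(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive genomic interval."""
    if start > end:
        raise InputError(f"start {start} > end {end}")
    return end - start + 1
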