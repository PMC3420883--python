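"""The published catalogue of loss-of-function-class variations observed in
the chimpanzee bitter-taste-receptor survey: 19 variant entries across four
subspecies populations, spanning frameshift indels, loss-of-start alleles
(one rescued by an alternative ATG at CDS positions 4-6), premature stop
codons, ectopic conversion tracts, and a whole-gene-deletion copy-number
variant shared by a tandem trio of genes.

Each entry records the mutation class, the functional annotations needed to
adjudicate it (alternative-start rescue, conversion), and the observed
allele counts.  :func:`realize_variant` constructs a representative CDS
haplotype embodying the lesion so the rows can be pushed through
:func:`tas2rpop.catalog.functional_status` rather than hard-coding verdicts.
"""

from __future__ import annotations

import re

from .catalog import functional_status
from .diversity import CODON_TO_AA
from .errors import InputError

__all__ = ["VARIANT_ROWS", "realize_variant", "classify_row", "count_nonfunctional",
           "combined_nonfunctional_frequency"]

# counts are (derived, sampled chromosomes) per population
VARIANT_ROWS: list[dict] = [
    dict(gene="cTAS2R1", mutation="1 bp del.", counts={"western": (22, 92)}),
    dict(gene="cTAS2R3", mutation="LIC", alt_start=True,
         counts={"western": (75, 92), "eastern": (20, 20), "central": (4, 4),
                 "nigerian_cameroonian": (2, 2)}),
    dict(gene="cTAS2R7", mutation="GTC", counts={"central": (1, 4)}),
    dict(gene="cTAS2R30", mutation="19 bp ins.", counts={"western": (3, 92)}),
    dict(gene="cTAS2R31", mutation="GTC", counts={"western": (9, 92)}),
    dict(gene="cTAS2R38", mutation="LIC", counts={"western": (70, 92)}),
    dict(gene="cTAS2R40", mutation="GTC", counts={"eastern": (1, 20)}),
    dict(gene="cTAS2R42", mutation="5 bp del.",
         counts={"western": (24, 92), "eastern": (10, 20), "central": (1, 4),
                 "nigerian_cameroonian": (1, 2)}),
    dict(gene="cTAS2R43", mutation="1 bp ins.", counts={"western": (11, 92)}),
    dict(gene="cTAS2R43", mutation="LIC", counts={"eastern": (3, 20)}),
    dict(gene="cTAS2R43", mutation="WGD", counts={"eastern": (3, 20)}),
    dict(gene="cTAS2R45", mutation="4 bp del.", counts={"western": (11, 92)}),
    dict(gene="cTAS2R45", mutation="LIC", counts={"central": (3, 4)}),
    dict(gene="cTAS2R46", mutation="GTC", counts={"eastern": (3, 20)}),
    dict(gene="cTAS2R46", mutation="WGD", counts={"eastern": (3, 20)}),
    dict(gene="cTAS2R46", mutation="73 bp GC", conversion=True,
         donor="cTAS2R31", interval=(514, 586),
         counts={"nigerian_cameroonian": (1, 2)}),
    dict(gene="cTAS2R60", mutation="2 bp del.",
         counts={"central": (2, 4), "nigerian_cameroonian": (1, 2)}),
    dict(gene="cTAS2R64", mutation="WGD", counts={"eastern": (3, 20)}),
    dict(gene="cTAS2R64", mutation="133 bp GC", conversion=True,
         donor="cTAS2R19", interval=(141, 273),
         counts={"eastern": (2, 20)}),
]

_MUT_RE = re.compile(r"^(\d+) bp (del|ins|GC)\.?$")
_CDS_LENGTH = 900
_FILLER = "CTT"  # Leu: no stop reachable across CTT|CTT boundaries


def _base_orf(alt_start: bool) -> str:
    ncod = _CDS_LENGTH // 3
    codons = ["ATG", "ATG" if alt_start else _FILLER]
    codons += [_FILLER] * (ncod - 3)
    codons.append("TAA")
    return "".join(codons)


def realize_variant(mutation: str, alt_start: bool = False,
                    interval: tuple[int, int] | None = None) -> str | None:
    """Construct a representative CDS haplotype carrying one mutation class.

    ``None`` encodes a whole-gene deletion.  Conversion tracts are realized
    as an in-frame block of donor-state substitutions over ``interval``
    chosen never to introduce a stop codon, matching the nonreciprocal
    copy-paste nature of ectopic conversion.
    """
    seq = _base_orf(alt_start)
    if mutation == "WGD":
        return None
    if mutation == "LIC":
        return "G" + seq[1:]
    if mutation == "GTC":
        mid = (_CDS_LENGTH // 6) * 3  # an interior codon
        return seq[:mid] + "TAA" + seq[mid + 3 :]
    m = _MUT_RE.match(mutation)
    if not m:
        raise InputError(f"unrecognized mutation class {mutation!r}")
    size, kind = int(m.group(1)), m.group(2)
    if kind == "del":
        start = 300
        return seq[:start] + seq[start + size :]
    if kind == "ins":
        start = 300
        return seq[:start] + "A" * size + seq[start:]
    # conversion tract: substitutions over [start, end], stop-free
    start, end = interval if interval else (301, 300 + size)
    if end - start + 1 != size:
        raise InputError(f"interval {interval} inconsistent with {size} bp tract")
    out = list(seq)
    for pos in range(start - 1, end):
        ci = pos // 3
        codon = out[3 * ci : 3 * ci + 3]
        for base in "ACGT":
            if base == out[pos]:
                continue
            trial = codon.copy()
            trial[pos - 3 * ci] = base
            if CODON_TO_AA.get("".join(trial), "*") != "*":
                out[pos] = base
                break
    return "".join(out)


def classify_row(row: dict) -> str:
    """Run the functional-status classifier on a realized haplotype for one
    catalogue entry; returns 'Functional' or 'Non-functional'."""
    hap = realize_variant(
        row["mutation"],
        alt_start=row.get("alt_start", False),
        interval=row.get("interval"),
    )
    status, _ = functional_status(hap)
    return "Non-functional" if status == "nonfunctional" else "Functional"


def count_nonfunctional(rows: list[dict] | None = None) -> int:
    rows = VARIANT_ROWS if rows is None else rows
    return sum(classify_row(r) == "Non-functional" for r in rows)


def combined_nonfunctional_frequency(gene: str, population: str,
                                     rows: list[dict] | None = None) -> float:
    """Summed frequency of all non-functional variant classes of one gene in
    one population (independent lesions on distinct haplotypes add)."""
    rows = VARIANT_ROWS if rows is None else rows
    total = 0.0
    for r in rows:
        if r["gene"] != gene or population not in r["counts"]:
            continue
        if classify_row(r) == "Non-functional":
            k, n = r["counts"][population]
            total += k / n
    return total
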