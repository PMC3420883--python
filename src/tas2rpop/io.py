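"""Readers, writers and the shared data model.

The unit of observation throughout the package is a *phased chromosome*: a
single haploid coding-sequence haplotype sampled from one subject of one
population (chimpanzee subspecies).  Alignments travel as FASTA, everything
tabular as TSV.

Coordinate convention: CDS positions are 1-based, with the A of the
annotated ATG translation-start codon as position 1.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, AlphabetError, InputError

ALPHABET = frozenset("ACGTN-")

#: sentinel used for chromosomes carrying a whole-gene deletion
WHOLE_GENE_DELETION = None


@dataclasses.dataclass
class GeneAlignment:
    """Aligned coding haplotypes for one gene.

    ``sequences`` maps chromosome id -> aligned DNA string; insertion order
    is preserved and meaningful (round-trips through FASTA).
    """

    gene_id: str
    sequences: dict[str, str]
    class_label: str = "old"
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"{self.gene_id}: unequal aligned lengths {sorted(lengths)}"
            )
        bad = set("".join(self.sequences.values())) - ALPHABET
        if bad:
            raise AlphabetError(f"{self.gene_id}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def chromosome_ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, chromosome_ids: Iterable[str]) -> "GeneAlignment":
        keep = [c for c in chromosome_ids if c in self.sequences]
        return GeneAlignment(
            gene_id=self.gene_id,
            sequences={c: self.sequences[c] for c in keep},
            class_label=self.class_label,
            reference_id=self.reference_id,
        )

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-byte strings."""
        if not self.sequences:
            return np.empty((0, 0), dtype="S1")
        return np.frombuffer(
            "".join(self.sequences.values()).encode(), dtype="S1"
        ).reshape(len(self.sequences), self.length)


@dataclasses.dataclass
class PopulationManifest:
    """chromosome -> (subject, population), plus whole-gene-deletion flags.

    A chromosome flagged deleted for gene *g* must not appear in that
    gene's alignment; its absence is what carries the copy-number signal.
    """

    entries: list[tuple[str, str, str]]
    deletions: set[tuple[str, str]] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        dup = [c for c, k in Counter(ids).items() if k > 1]
        if dup:
            raise InputError(f"duplicate chromosome ids in manifest: {dup}")
        self._pop = {c: p for c, _, p in self.entries}

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, p in self.entries:
            seen.setdefault(p)
        return list(seen)

    def population_of(self, chromosome_id: str) -> str:
        return self._pop[chromosome_id]

    def chromosomes(self, population: str, gene_id: str | None = None) -> list[str]:
        """Chromosomes of one population, minus deletion-flagged ones for gene_id."""
        out = [c for c, _, p in self.entries if p == population]
        if gene_id is not None:
            out = [c for c in out if (c, gene_id) not in self.deletions]
        return out

    def deleted_chromosomes(self, gene_id: str, population: str | None = None) -> list[str]:
        out = [c for c, g in sorted(self.deletions) if g == gene_id]
        if population is not None:
            out = [c for c in out if self._pop[c] == population]
        return out

    def population_sizes(self, gene_id: str | None = None) -> dict[str, int]:
        return {p: len(self.chromosomes(p, gene_id)) for p in self.populations}


@dataclasses.dataclass
class GeneConfig:
    """Gene inventory: class membership and CDS lengths, plus paralog groups
    eligible as gene-conversion donors."""

    genes: list[tuple[str, str, int]]  # (gene_id, class_label, cds_length)
    paralog_groups: list[frozenset[str]] = dataclasses.field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.genes]

    def class_of(self, gene_id: str) -> str:
        for g, c, _ in self.genes:
            if g == gene_id:
                return c
        raise InputError(f"unknown gene {gene_id}")

    def genes_in_class(self, class_label: str) -> list[str]:
        return [g for g, c, _ in self.genes if c == class_label]


# ---------------------------------------------------------------------------
# FASTA


def read_alignment(
    path: str | Path,
    gene_id: str,
    class_label: str = "old",
    reference_id: str | None = None,
) -> GeneAlignment:
    """Read one gene's aligned haplotypes from FASTA (any line wrapping)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: empty FASTA")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise InputError(f"{path}: duplicate record id {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return GeneAlignment(gene_id, seqs, class_label=class_label, reference_id=reference_id)


def write_alignment(alignment: GeneAlignment, path: str | Path) -> None:
    """Write FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s), id=c, description="") for c, s in alignment.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# TSV manifests and configs

_DELETION_HEADER = "#DELETIONS"
_PARALOG_HEADER = "#PARALOGS"


def read_manifest(path: str | Path, known_genes: Sequence[str] | None = None) -> PopulationManifest:
    """Read a population manifest.

    Layout: a header line ``chromosome<TAB>subject<TAB>population`` followed
    by one row per phased chromosome; an optional ``#DELETIONS`` section with
    ``chromosome<TAB>gene`` rows flags whole-gene deletions.
    """
    entries: list[tuple[str, str, str]] = []
    deletions: set[tuple[str, str]] = set()
    section = "entries"
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise InputError(f"{path}: empty manifest")
    it = iter(lines)
    header = next(it).split("\t")
    if [h.lower() for h in header[:3]] != ["chromosome", "subject", "population"]:
        raise InputError(f"{path}: unexpected manifest header {header}")
    for ln in it:
        if ln == _DELETION_HEADER:
            section = "deletions"
            continue
        parts = ln.split("\t")
        if section == "entries":
            if len(parts) < 3:
                raise InputError(f"{path}: bad manifest row {ln!r}")
            entries.append((parts[0], parts[1], parts[2]))
        else:
            if len(parts) < 2:
                raise InputError(f"{path}: bad deletion row {ln!r}")
            chrom, gene = parts[0], parts[1]
            if known_genes is not None and gene not in known_genes:
                raise InputError(f"{path}: deletion row names unknown gene {gene}")
            deletions.add((chrom, gene))
    return PopulationManifest(entries, deletions)


def write_manifest(manifest: PopulationManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tsubject\tpopulation\n")
        for c, s, p in manifest.entries:
            fh.write(f"{c}\t{s}\t{p}\n")
        if manifest.deletions:
            fh.write(_DELETION_HEADER + "\n")
            for c, g in sorted(manifest.deletions):
                fh.write(f"{c}\t{g}\n")


def read_gene_config(path: str | Path) -> GeneConfig:
    """Read the gene config TSV: ``gene<TAB>class<TAB>cds_length`` rows, then
    an optional ``#PARALOGS`` section of comma-separated gene-id groups."""
    genes: list[tuple[str, str, int]] = []
    groups: list[frozenset[str]] = []
    section = "genes"
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise InputError(f"{path}: empty gene config")
    it = iter(lines)
    header = next(it).split("\t")
    if [h.lower() for h in header[:3]] != ["gene", "class", "cds_length"]:
        raise InputError(f"{path}: unexpected gene-config header {header}")
    for ln in it:
        if ln == _PARALOG_HEADER:
            section = "paralogs"
            continue
        if section == "genes":
            g, c, L = ln.split("\t")[:3]
            genes.append((g, c, int(L)))
        else:
            groups.append(frozenset(ln.split("\t")[0].split(",")))
    known = {g for g, _, _ in genes}
    for grp in groups:
        unknown = grp - known
        if unknown:
            raise InputError(f"{path}: paralog group names unknown genes {sorted(unknown)}")
    return GeneConfig(genes, groups)


def write_gene_config(config: GeneConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tclass\tcds_length\n")
        for g, c, L in config.genes:
            fh.write(f"{g}\t{c}\t{L}\n")
        if config.paralog_groups:
            fh.write(_PARALOG_HEADER + "\n")
            for grp in config.paralog_groups:
                fh.write(",".join(sorted(grp)) + "\n")


def read_snv_table(path: str | Path) -> pd.DataFrame:
    """Read a reference SNV table (long format): locus, position, population,
    derived, n — one row per (SNV, population)."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "population": str})
    required = {"locus", "position", "population", "derived", "n"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: SNV table missing columns {sorted(missing)}")
    per_site = df.groupby(["locus", "position"])["n"].apply(lambda s: (s > 0).sum())
    if (per_site < 2).any():
        raise InputError(f"{path}: every SNV needs >=2 populations with nonzero n")
    return df


# ---------------------------------------------------------------------------
# Reports

#: fixed float precision per report name (diversity-style values print with
#: 3 decimals, simulation summaries with 1)
_FLOAT_FORMATS = {
    "variants": "%.3f",
    "diversity": "%.3f",
    "selection": "%.3f",
    "fst": "%.3f",
    "sharing": "%.1f",
    "tracts": "%.1f",
}


def write_report(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each result table as ``<name>.tsv`` under ``outdir``.

    Deterministic: fixed column order (as given), fixed float precision,
    so re-running on identical inputs is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FORMATS.get(name, "%.6g"))
        written.append(p)
    return written
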