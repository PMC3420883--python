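"""Synthetic multi-gene, multi-population phased haplotype datasets.

The generator emulates the design of a subspecies-level receptor-gene
resequencing survey: ~28 coding loci of 876–1002 bp, two focal populations
(92 and 20 phased chromosomes by default), neutral background variation,
and injected lesions — loss-of-start substitutions (optionally rescued by
an alternative in-frame ATG at positions 4–6), premature stop codons,
frameshift indels, whole-gene deletions, and donor→recipient conversion
tracts between paralogs.

Model choices:

* Background variation per gene is a standard neutral coalescent sample of
  all chromosomes jointly (panmictic pool), under an infinite-sites
  approximation on finite sequence (site resampled on collision).
* Population structure is added on top: each population receives
  Poisson(divergence_scale x theta_locus) private substitutions, each at a
  frequency drawn uniformly on (0, 1] in that population (materialized as
  an exact carrier count, occasionally fixed).  divergence_scale = 0 is
  exact panmixia; larger values monotonically increase differentiation and
  erode haplotype sharing, with a continuous per-site F_ST spectrum rather
  than an all-or-nothing one.
* Background and divergence mutations are constrained to be non-lesional
  (they never create or destroy start/stop codons), so every
  non-functional haplotype in a dataset traces back to an explicit lesion
  spec and the truth record is exhaustive.
* Lesion frequencies are materialized as exact counts round(f*n), not
  Bernoulli draws, so truth frequencies are exact.
* One named substream per gene (and per concern within a gene) derives
  from the single global seed, so adding genes never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigError
from .io import GeneAlignment, GeneConfig, PopulationManifest

__all__ = [
    "LesionSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "inject_conversion_tract",
    "generate_reference_loci",
    "study_config",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_START = "ATG"

# codon table indirection kept local to avoid circular import
from .diversity import CODON_TO_AA  # noqa: E402


@dataclasses.dataclass
class LesionSpec:
    """One injected lesion: which gene, what kind, at which exact frequency
    in which population(s)."""

    gene: str
    lesion_type: str  # loss_of_start | gain_of_stop | frameshift_indel |
    #                   whole_gene_deletion | conversion_tract
    frequencies: dict[str, float]  # population -> target frequency
    interval: tuple[int, int] | None = None  # conversion tracts, 1-based incl.
    donor: str | None = None  # conversion tracts
    indel_length: int = 1
    insertion: bool = False
    alt_start_rescue: bool = False  # loss_of_start with ATG at positions 4-6

    _TYPES = (
        "loss_of_start",
        "gain_of_stop",
        "frameshift_indel",
        "whole_gene_deletion",
        "conversion_tract",
    )

    def validate(self) -> None:
        if self.lesion_type not in self._TYPES:
            raise ConfigError(f"unknown lesion type {self.lesion_type!r}")
        for pop, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{self.gene}: frequency {f} outside [0,1]")
        if self.lesion_type == "conversion_tract":
            if self.donor is None or self.interval is None:
                raise ConfigError(f"{self.gene}: conversion tract needs donor and interval")
        if self.lesion_type == "frameshift_indel" and self.indel_length % 3 == 0:
            raise ConfigError(f"{self.gene}: indel length {self.indel_length} is in-frame")


@dataclasses.dataclass
class SyntheticConfig:
    n_genes: int = 28
    cds_length_range: tuple[int, int] = (876, 1002)
    populations: Sequence[tuple[str, int]] = (("western", 92), ("eastern", 20))
    theta_per_site: float = 0.0015
    divergence_scale: float = 0.0
    lesion_specs: Sequence[LesionSpec] = ()
    paralog_groups: Sequence[frozenset[str]] = ()
    paralog_divergence: float = 0.04  # per-site divergence between paralogs
    n_human_cluster: int | None = None  # default: 9/28 of genes
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"gene{i + 1:02d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        lo, hi = self.cds_length_range
        if lo < 9 or hi < lo:
            raise ConfigError(f"bad cds_length_range {self.cds_length_range}")
        genes = set(self.gene_ids())
        for spec in self.lesion_specs:
            spec.validate()
            if spec.gene not in genes:
                raise ConfigError(f"lesion names unknown gene {spec.gene}")
            for pop in spec.frequencies:
                if pop not in {p for p, _ in self.populations}:
                    raise ConfigError(f"lesion names unknown population {pop}")


@dataclasses.dataclass
class SyntheticDataset:
    alignments: dict[str, GeneAlignment]
    manifest: PopulationManifest
    gene_config: GeneConfig
    ancestral: dict[str, str]  # per-gene ancestral reference, aligned to the
    #                            emitted columns (gaps at injected insertions)
    truth: pd.DataFrame
    config: SyntheticConfig

    def __iter__(self):  # allow (alignments, manifest, truth) unpacking
        return iter((self.alignments, self.manifest, self.truth))


# ---------------------------------------------------------------------------
# sequence helpers


def _random_orf(rng: np.random.Generator, length: int, alt_start: bool) -> str:
    """Random open reading frame: ATG, non-stop interior codons, terminal
    stop.  Codon 2 is forced to (or away from) ATG depending on whether an
    alternative-start rescue is wanted."""
    if length % 3:
        raise ConfigError(f"CDS length {length} not divisible by 3")
    ncod = length // 3
    codons = [_START]
    while len(codons) < ncod - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if CODON_TO_AA.get(c, "*") == "*" or c == _START:
            continue
        codons.append(c)
    if alt_start:
        codons[1] = _START
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _neutral_site(
    rng: np.random.Generator,
    anc: str,
    used: set[int],
    protect: bool,
) -> tuple[int, str]:
    """Pick an unused site and a derived base; with ``protect`` the change
    may not create a stop codon or touch the start/terminal codons."""
    L = len(anc)
    lo, hi = (3, L - 3) if protect else (0, L)
    for _ in range(100 * L):
        site = int(rng.integers(lo, hi))
        if site in used:
            continue
        base = _BASES[rng.integers(0, 4)]
        if base == anc[site]:
            continue
        if protect:
            ci = site // 3
            codon = anc[3 * ci : 3 * ci + 3]
            mut = codon[: site % 3] + base + codon[site % 3 + 1 :]
            if CODON_TO_AA.get(mut, "*") == "*":
                continue
        used.add(site)
        return site, base
    raise ConfigError("could not place a mutation (sequence saturated)")


def _coalescent_sample(
    rng: np.random.Generator,
    n: int,
    anc: str,
    theta_locus: float,
    used: set[int],
    protect: bool,
) -> list[bytearray]:
    """Neutral Kingman coalescent sample of n haplotypes from ancestor
    ``anc`` with Poisson(theta/2 per unit branch) infinite-sites mutations."""
    haps = [bytearray(anc, "ascii") for _ in range(n)]
    if n < 2 or theta_locus <= 0:
        return haps
    active: list[tuple[set[int], float]] = [({i}, 0.0) for i in range(n)]
    branches: list[tuple[set[int], float]] = []
    k = n
    while k > 1:
        dt = float(rng.exponential(2.0 / (k * (k - 1))))
        active = [(tips, ln + dt) for tips, ln in active]
        i, j = rng.choice(k, size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        tips_i, len_i = active[i]
        tips_j, len_j = active[j]
        branches.append((tips_i, len_i))
        branches.append((tips_j, len_j))
        merged = (tips_i | tips_j, 0.0)
        active[i] = merged
        active.pop(j)
        k -= 1
    for tips, length in branches:
        for _ in range(int(rng.poisson(0.5 * theta_locus * length))):
            site, base = _neutral_site(rng, anc, used, protect)
            for t in tips:
                haps[t][site] = ord(base)
    return haps


# ---------------------------------------------------------------------------
# lesion injection


def _materialize_count(freq: float, n: int) -> int:
    k = int(round(freq * n))
    if k > n:
        raise ConfigError(f"frequency {freq} infeasible for n={n}")
    return k


def inject_conversion_tract(
    alignment: GeneAlignment,
    donor: GeneAlignment,
    interval: tuple[int, int],
    chromosomes: Iterable[str],
) -> GeneAlignment:
    """Overwrite ``interval`` (CDS 1-based inclusive) on the listed
    chromosomes with the donor consensus; everything else untouched."""
    start, end = interval
    if not (1 <= start <= end <= alignment.length):
        raise ConfigError(f"interval {interval} outside CDS of length {alignment.length}")
    if donor.length != alignment.length:
        raise ConfigError("donor and recipient must share a coordinate frame")
    chromosomes = set(chromosomes)
    # local import avoids a cycle at module load
    from .conversion import _ALPHABET, _column_counts, _consensus_idx, _encode

    donor_mat = _encode(donor)
    prefer = None
    if donor.reference_id in donor.sequences:
        prefer = donor_mat[list(donor.sequences).index(donor.reference_id)]
    donor_cons = "".join(
        _ALPHABET[i] for i in _consensus_idx(_column_counts(donor_mat), prefer)
    )
    seqs = {}
    for cid, s in alignment.sequences.items():
        if cid in chromosomes:
            s = s[: start - 1] + donor_cons[start - 1 : end] + s[end:]
        seqs[cid] = s
    return GeneAlignment(
        alignment.gene_id, seqs, class_label=alignment.class_label,
        reference_id=alignment.reference_id,
    )


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate per-gene alignments, the population manifest and an exact
    truth record of every injected lesion."""
    config.validate()
    genes = config.gene_ids()
    n_hc = config.n_human_cluster
    if n_hc is None:
        n_hc = int(round(config.n_genes * 9 / 28))
    class_of = {
        g: ("human_cluster" if i >= config.n_genes - n_hc else "old")
        for i, g in enumerate(genes)
    }

    # manifest: two chromosomes per subject
    entries = []
    for pop, n in config.populations:
        for i in range(n):
            entries.append((f"{pop}_c{i + 1:03d}", f"{pop}_s{i // 2 + 1:03d}", pop))
    deletions: set[tuple[str, str]] = set()

    group_of = {g: grp for grp in config.paralog_groups for g in grp}
    specs_by_gene: dict[str, list[LesionSpec]] = {}
    for spec in config.lesion_specs:
        specs_by_gene.setdefault(spec.gene, []).append(spec)

    # gene lengths; paralog-group members share one length and one ancestral ORF
    lengths: dict[str, int] = {}
    group_anc: dict[frozenset, str] = {}
    lo, hi = config.cds_length_range
    for g in genes:
        rng = substream(config.seed, f"length/{g}")
        grp = group_of.get(g)
        if grp is not None and any(m in lengths for m in grp):
            lengths[g] = next(lengths[m] for m in grp if m in lengths)
        else:
            lengths[g] = int(rng.integers(lo // 3, hi // 3 + 1)) * 3

    ancestral: dict[str, str] = {}
    for g in genes:
        rng = substream(config.seed, f"orf/{g}")
        rescue = any(
            s.lesion_type == "loss_of_start" and s.alt_start_rescue
            for s in specs_by_gene.get(g, [])
        )
        grp = group_of.get(g)
        if grp is None:
            ancestral[g] = _random_orf(rng, lengths[g], alt_start=rescue)
        else:
            if grp not in group_anc:
                group_anc[grp] = _random_orf(
                    substream(config.seed, f"orf-group/{'|'.join(sorted(grp))}"),
                    lengths[g],
                    alt_start=rescue,
                )
            anc = bytearray(group_anc[grp], "ascii")
            used: set[int] = set()
            n_div = int(rng.poisson(config.paralog_divergence * lengths[g]))
            for _ in range(n_div):
                site, base = _neutral_site(rng, group_anc[grp], used, protect=True)
                anc[site] = ord(base)
            if rescue:
                anc[3:6] = b"ATG"
            ancestral[g] = anc.decode()

    pops = [p for p, _ in config.populations]
    pop_slices: dict[str, list[int]] = {}
    offset = 0
    for pop, n in config.populations:
        pop_slices[pop] = list(range(offset, offset + n))
        offset += n
    n_total = offset
    chrom_ids = [e[0] for e in entries]

    alignments: dict[str, GeneAlignment] = {}
    truth_rows: list[dict] = []
    conversion_specs: list[tuple[LesionSpec, list[str]]] = []

    for g in genes:
        rng = substream(config.seed, f"sample/{g}")
        L = lengths[g]
        anc = ancestral[g]
        theta_locus = config.theta_per_site * L
        used: set[int] = set()
        haps = _coalescent_sample(rng, n_total, anc, theta_locus, used, protect=True)

        # population-private substitutions (divergence): random frequency,
        # materialized as an exact carrier count
        if config.divergence_scale > 0:
            for pop in pops:
                m = int(rng.poisson(config.divergence_scale * theta_locus))
                for _ in range(m):
                    site, base = _neutral_site(rng, anc, used, protect=True)
                    npop = len(pop_slices[pop])
                    k = max(1, int(round(rng.uniform(0.0, 1.0) * npop)))
                    carriers = rng.choice(pop_slices[pop], size=k, replace=False)
                    for t in carriers:
                        haps[t][site] = ord(base)
                    truth_rows.append(
                        dict(gene=g, lesion_type="divergence_substitution",
                             population=pop, start=site + 1, end=site + 1,
                             effect="substitution", count=k,
                             n=npop, donor="", carriers="")
                    )

        seqs = {chrom_ids[t]: haps[t].decode() for t in range(n_total)}
        removed: set[str] = set()
        ref_aligned = anc  # gains gap columns if an insertion is injected

        # insertions add alignment columns, so apply them after every lesion
        # addressed in ungapped CDS coordinates
        gene_specs = sorted(
            specs_by_gene.get(g, []),
            key=lambda s: s.lesion_type == "frameshift_indel" and s.insertion,
        )
        for spec in gene_specs:
            lrng = substream(config.seed, f"lesion/{g}/{spec.lesion_type}")
            if spec.lesion_type == "conversion_tract":
                carriers_all: list[str] = []
                for pop, f in sorted(spec.frequencies.items()):
                    avail = [chrom_ids[t] for t in pop_slices[pop] if chrom_ids[t] not in removed]
                    k = _materialize_count(f, len(avail))
                    carriers_all += [avail[i] for i in lrng.choice(len(avail), size=k, replace=False)]
                conversion_specs.append((spec, carriers_all))
                continue
            for pop, f in sorted(spec.frequencies.items()):
                avail = [chrom_ids[t] for t in pop_slices[pop] if chrom_ids[t] not in removed]
                k = _materialize_count(f, len(avail))
                if k == 0:
                    continue
                carriers = [avail[i] for i in sorted(lrng.choice(len(avail), size=k, replace=False))]
                if spec.lesion_type == "whole_gene_deletion":
                    for c in carriers:
                        removed.add(c)
                        del seqs[c]
                        deletions.add((c, g))
                    truth_rows.append(
                        dict(gene=g, lesion_type="whole_gene_deletion", population=pop,
                             start=0, end=0, effect="whole_gene_deletion",
                             count=k, n=len(avail), donor="",
                             carriers=",".join(carriers))
                    )
                    continue
                if spec.lesion_type == "loss_of_start":
                    pos, ref, alt, effect = 1, anc[0], "G", "loss_of_start"
                    for c in carriers:
                        seqs[c] = "G" + seqs[c][1:]
                elif spec.lesion_type == "gain_of_stop":
                    pos, ref, alt = _stoppable_site(anc)
                    effect = "gain_of_stop"
                    for c in carriers:
                        seqs[c] = seqs[c][: pos - 1] + alt + seqs[c][pos:]
                elif spec.lesion_type == "frameshift_indel":
                    dlen = spec.indel_length
                    start = 3 + 3 * int(lrng.integers(1, (L - dlen - 6) // 3))
                    effect = "indel"
                    if spec.insertion:
                        # realized as an insertion column block in the alignment
                        ins = "".join(_BASES[lrng.integers(0, 4)] for _ in range(dlen))
                        newseqs = {}
                        for cid, s in seqs.items():
                            block = ins if cid in carriers else "-" * dlen
                            newseqs[cid] = s[:start] + block + s[start:]
                        seqs = newseqs
                        ref_aligned = ref_aligned[:start] + "-" * dlen + ref_aligned[start:]
                        pos, ref, alt = start + 1, "", ins
                    else:
                        for c in carriers:
                            seqs[c] = seqs[c][:start] + "-" * dlen + seqs[c][start + dlen :]
                        pos, ref, alt = start + 1, anc[start : start + dlen], ""
                else:  # pragma: no cover - validated earlier
                    raise ConfigError(spec.lesion_type)
                truth_rows.append(
                    dict(gene=g, lesion_type=spec.lesion_type, population=pop,
                         start=pos, end=pos + max(len(ref) - 1, 0), effect=effect,
                         count=k, n=len(avail), donor="",
                         carriers=",".join(carriers))
                )

        alignments[g] = GeneAlignment(
            g, seqs, class_label=class_of[g], reference_id=None
        )
        ancestral[g] = ref_aligned

    # conversion tracts need the donor alignment, hence a second pass
    for spec, carriers in conversion_specs:
        recipient = alignments[spec.gene]
        donor = alignments[spec.donor]
        alignments[spec.gene] = inject_conversion_tract(
            recipient, donor, spec.interval, carriers
        )
        by_pop: dict[str, int] = {}
        manifest_pop = {c: p for c, _, p in entries}
        for c in carriers:
            by_pop[manifest_pop[c]] = by_pop.get(manifest_pop[c], 0) + 1
        for pop, k in sorted(by_pop.items()):
            truth_rows.append(
                dict(gene=spec.gene, lesion_type="conversion_tract", population=pop,
                     start=spec.interval[0], end=spec.interval[1],
                     effect="conversion_tract", count=k,
                     n=sum(1 for c, _, p in entries if p == pop),
                     donor=spec.donor, carriers=",".join(sorted(carriers)))
            )

    manifest = PopulationManifest(entries, deletions)
    gene_config = GeneConfig(
        genes=[(g, class_of[g], lengths[g]) for g in genes],
        paralog_groups=list(config.paralog_groups),
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "lesion_type", "population", "start", "end", "effect",
                 "count", "n", "donor", "carriers"],
    )
    return SyntheticDataset(alignments, manifest, gene_config, ancestral, truth, config)


def _stoppable_site(anc: str) -> tuple[int, str, str]:
    """First interior codon one substitution away from a stop codon:
    returns (CDS position 1-based, ref base, stop-creating base)."""
    ncod = len(anc) // 3
    for ci in range(1, ncod - 1):
        codon = anc[3 * ci : 3 * ci + 3]
        for stop in _STOPS:
            diff = [k for k in range(3) if codon[k] != stop[k]]
            if len(diff) == 1:
                k = diff[0]
                return 3 * ci + k + 1, codon[k], stop[k]
    raise ConfigError("no single-substitution stop available in ancestral ORF")


def generate_reference_loci(
    config: SyntheticConfig,
    n_loci: int = 26,
    locus_length: int = 861,
    label: str = "noncoding",
) -> dict[str, GeneAlignment]:
    """Putatively neutral non-coding loci over the same chromosomes, sharing
    the configured theta and divergence — the empirical reference for the
    per-SNV F_ST screen and the D-distribution comparison."""
    entries = []
    for pop, n in config.populations:
        for i in range(n):
            entries.append((f"{pop}_c{i + 1:03d}", f"{pop}_s{i // 2 + 1:03d}", pop))
    chrom_ids = [e[0] for e in entries]
    pop_slices: dict[str, list[int]] = {}
    offset = 0
    for pop, n in config.populations:
        pop_slices[pop] = list(range(offset, offset + n))
        offset += n
    out: dict[str, GeneAlignment] = {}
    for i in range(n_loci):
        name = f"{label}{i + 1:02d}"
        rng = substream(config.seed, f"reference/{name}")
        anc = "".join(_BASES[b] for b in rng.integers(0, 4, size=locus_length))
        used: set[int] = set()
        theta_locus = config.theta_per_site * locus_length
        haps = _coalescent_sample(rng, offset, anc, theta_locus, used, protect=False)
        if config.divergence_scale > 0:
            for pop in pop_slices:
                m = int(rng.poisson(config.divergence_scale * theta_locus))
                for _ in range(m):
                    site, base = _neutral_site(rng, anc, used, protect=False)
                    npop = len(pop_slices[pop])
                    k = max(1, int(round(rng.uniform(0.0, 1.0) * npop)))
                    for t in rng.choice(pop_slices[pop], size=k, replace=False):
                        haps[t][site] = ord(base)
        out[name] = GeneAlignment(
            name, {chrom_ids[t]: haps[t].decode() for t in range(offset)},
            class_label="noncoding",
        )
    return out


def study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study-like configuration: 28 genes (19 'old' + 9
    'human cluster'), 92 western + 20 eastern chromosomes, and a lesion set
    emulating the catalogued classes — frameshift indels, rescued and
    unrescued loss-of-start alleles, premature stops, a shared whole-gene
    deletion across a tandem trio, and two paralog conversion tracts."""
    lesions = [
        LesionSpec("gene01", "frameshift_indel", {"western": 24 / 92}, indel_length=1),
        LesionSpec("gene03", "loss_of_start", {"western": 75 / 92, "eastern": 1.0},
                   alt_start_rescue=True),
        LesionSpec("gene13", "loss_of_start", {"western": 70 / 92}),
        LesionSpec("gene07", "gain_of_stop", {"eastern": 1 / 20}),
        LesionSpec("gene17", "frameshift_indel", {"western": 24 / 92, "eastern": 10 / 20},
                   indel_length=5),
        LesionSpec("gene22", "whole_gene_deletion", {"eastern": 3 / 20}),
        LesionSpec("gene24", "whole_gene_deletion", {"eastern": 3 / 20}),
        LesionSpec("gene24", "gain_of_stop", {"eastern": 3 / 20}),
        LesionSpec("gene28", "whole_gene_deletion", {"eastern": 3 / 20}),
        LesionSpec("gene24", "conversion_tract", {"eastern": 0.0, "western": 2 / 92},
                   interval=(514, 586), donor="gene23"),
        LesionSpec("gene28", "conversion_tract", {"eastern": 2 / 20},
                   interval=(141, 273), donor="gene27"),
    ]
    cfg = dict(
        n_genes=28,
        populations=(("western", 92), ("eastern", 20)),
        theta_per_site=0.0015,
        divergence_scale=0.5,
        lesion_specs=lesions,
        paralog_groups=(frozenset({"gene23", "gene24"}), frozenset({"gene27", "gene28"})),
        seed=seed,
    )
    cfg.update(overrides)
    return SyntheticConfig(**cfg)
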