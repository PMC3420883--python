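"""End-to-end orchestration: catalog -> diversity -> neutrality tests ->
sharing null -> conversion scan, from files or an in-memory dataset, with
per-stage named random substreams and deterministic TSV reports.

The stage order follows the analysis narrative: first catalogue what
segregates (variants, functional status, haplotype classes and their
subspecies sharing), then quantify diversity and differentiation, then test
departures from neutrality, then ask whether the observed level of
haplotype sharing is compatible with an undifferentiated metapopulation,
and finally scan paralog pairs for ectopic conversion tracts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import catalog as cat
from . import conversion as conv
from . import diversity as div
from . import neutrality as neu
from . import sharing as shr
from ._rng import substream
from .errors import ConfigError, InputError
from .io import (
    GeneAlignment,
    GeneConfig,
    PopulationManifest,
    read_alignment,
    read_gene_config,
    read_manifest,
    write_report,
)

__all__ = ["RunConfig", "run_pipeline", "fst_outlier_screen",
           "fst_records", "diversity_table", "neutrality_table"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Inputs are either file paths (``alignments_dir`` with one
    ``<gene>.fasta`` per gene, plus manifest/gene-config TSVs) or the
    in-memory equivalents (``alignments``/``manifest``/``gene_config``),
    which take precedence when given.
    """

    out_dir: str | Path = "results/pipeline"
    alignments_dir: str | Path | None = None
    manifest_path: str | Path | None = None
    gene_config_path: str | Path | None = None
    alignments: Mapping[str, GeneAlignment] | None = None
    manifest: PopulationManifest | None = None
    gene_config: GeneConfig | None = None
    references: Mapping[str, str] | None = None  # per-gene reference CDS
    reference_fst: Sequence[float] | None = None  # empirical neutral F_ST null
    reference_d: Sequence[float] | None = None  # non-coding per-locus Tajima D
    focal_pair: tuple[str, str] = ("western", "eastern")
    sharing_replicates: int = 10_000
    coalescent_replicates: int = 10_000
    pooling: str = "mean_of_frequencies"
    fst_outlier_quantile: float = 0.05
    high_frequency_only: bool = False
    seed: int = 0
    stages: tuple[str, ...] = ("catalog", "diversity", "tests", "sharing", "conversion")

    def load(self) -> tuple[dict[str, GeneAlignment], PopulationManifest, GeneConfig]:
        if self.alignments is not None:
            if self.manifest is None or self.gene_config is None:
                raise ConfigError("in-memory inputs need alignments, manifest and gene_config")
            return dict(self.alignments), self.manifest, self.gene_config
        for p, what in ((self.manifest_path, "manifest"),
                        (self.gene_config_path, "gene config"),
                        (self.alignments_dir, "alignments directory")):
            if p is None or not Path(p).exists():
                raise ConfigError(f"missing {what}: {p}")
        gene_config = read_gene_config(self.gene_config_path)
        manifest = read_manifest(self.manifest_path, known_genes=gene_config.gene_ids)
        alignments = {}
        for gene_id, class_label, _ in gene_config.genes:
            path = Path(self.alignments_dir) / f"{gene_id}.fasta"
            if not path.exists():
                raise ConfigError(f"missing alignment file {path}")
            alignments[gene_id] = read_alignment(path, gene_id, class_label=class_label)
        return alignments, manifest, gene_config


# ---------------------------------------------------------------------------
# table builders


def fst_records(
    variants_by_gene: Mapping[str, Sequence[cat.SiteVariant]],
    focal_pair: tuple[str, str],
) -> pd.DataFrame:
    """Per-SNV F_ST between the focal pair (indels excluded; chromosomes
    carrying whole-gene deletions are already absent from the denominators).
    Sites with no between-population diversity are NA, never 0."""
    p1, p2 = focal_pair
    rows = []
    for gene, variants in variants_by_gene.items():
        for v in variants:
            if v.effect == "indel":
                continue
            k1, n1 = v.counts.get(p1, (0, 0))
            k2, n2 = v.counts.get(p2, (0, 0))
            if n1 < 2 or n2 < 2:
                continue
            if (k1 + k2) == 0 or (k1 + k2) == (n1 + n2):
                continue  # not segregating across the pair
            fst = div.site_fst((k1, n1), (k2, n2))
            rows.append(dict(gene=gene, position=v.position, effect=v.effect,
                             ref=v.ref_state, alt=v.alt_state,
                             k1=k1, n1=n1, k2=k2, n2=n2,
                             fst=fst if math.isfinite(fst) else np.nan))
    return pd.DataFrame(rows, columns=["gene", "position", "effect", "ref", "alt",
                                       "k1", "n1", "k2", "n2", "fst"])


def fst_outlier_screen(
    fst_table: pd.DataFrame,
    reference_fst: Sequence[float],
    quantile: float = 0.05,
) -> pd.DataFrame:
    """Annotate each coding SNV with its upper-tail empirical probability in
    the neutral non-coding reference F_ST distribution; flag SNVs whose
    tail probability is below ``quantile``."""
    ref = [f for f in reference_fst if math.isfinite(f)]
    if not ref:
        raise InputError("empty reference F_ST distribution")
    out = fst_table.copy()
    out["tail_p"] = [
        div.empirical_percentile(f, ref) if math.isfinite(f) else np.nan
        for f in out["fst"]
    ]
    out["outlier"] = out["tail_p"] < quantile
    return out


def diversity_table(
    alignments: Mapping[str, GeneAlignment],
    manifest: PopulationManifest,
    gene_config: GeneConfig,
    focal_pair: tuple[str, str],
    scale: float = 100.0,
) -> pd.DataFrame:
    """Per-gene and per-class-concatenated diversity summary.

    pi, pi_S, pi_N and d_XY are printed x``scale`` (100 by default, i.e.
    percent-style display); n, L and S are raw.
    """
    p1, p2 = focal_pair
    rows = []

    def _one(gene_id, class_label, aln, length):
        row = dict(clazz=class_label, gene=gene_id, length=length)
        for pop, tag in ((p1, "1"), (p2, "2")):
            sub = aln.subset(manifest.chromosomes(pop, aln.gene_id))
            pi, L, S = div.nucleotide_diversity(sub)
            pi_s, pi_n = div.syn_nonsyn_diversity(sub)
            row[f"n{tag}"] = len(sub.sequences)
            row[f"L{tag}"] = L
            row[f"S{tag}"] = S
            row[f"pi{tag}"] = scale * pi if math.isfinite(pi) else np.nan
            row[f"pi_s{tag}"] = scale * pi_s if math.isfinite(pi_s) else np.nan
            row[f"pi_n{tag}"] = scale * pi_n if math.isfinite(pi_n) else np.nan
        d = div.dxy(
            aln.subset(manifest.chromosomes(p1, aln.gene_id)),
            aln.subset(manifest.chromosomes(p2, aln.gene_id)),
        )
        row["d_xy"] = scale * d if math.isfinite(d) else np.nan
        row["scale_note"] = f"x{scale:g}"
        rows.append(row)

    for class_label in ("old", "human_cluster"):
        members = [g for g in gene_config.genes_in_class(class_label) if g in alignments]
        if not members:
            continue
        for g in members:
            _one(g, class_label, alignments[g], alignments[g].length)
        concat = div.concatenate_class([alignments[g] for g in members],
                                       gene_id=f"{class_label}_concatenated")
        _one(f"{class_label}_concatenated", class_label, concat, concat.length)
    return pd.DataFrame(rows)


def neutrality_table(
    alignments: Mapping[str, GeneAlignment],
    manifest: PopulationManifest,
    focal_pair: tuple[str, str],
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Tajima's D per gene x focal population, with the coalescent p-value."""
    rows = []
    for gene, aln in alignments.items():
        for pop in focal_pair:
            sub = aln.subset(manifest.chromosomes(pop, gene))
            if len(sub.sequences) < 2:
                continue
            comp = neu.tajimas_d(sub)
            if comp.S > 0:
                null = neu.simulate_null_d(
                    comp.n, comp.S, replicates=replicates,
                    seed=substream(seed, f"coalescent/{gene}/{pop}").integers(2**31),
                )
                p, floored = neu.tajima_p(comp.D, null)
            else:
                p, floored = float("nan"), False
            rows.append(dict(gene=gene, population=pop, n=comp.n, S=comp.S,
                             k_bar=comp.k_bar, D=comp.D, p=p,
                             p_is_floor=floored))
    return pd.DataFrame(rows, columns=["gene", "population", "n", "S", "k_bar",
                                       "D", "p", "p_is_floor"])


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns all result tables and writes
    TSV reports plus a machine-readable run manifest under ``out_dir``.

    Any stage error aborts with a stage-tagged message; partial outputs are
    kept next to an ``INCOMPLETE`` marker file.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    stage = "load"
    try:
        alignments, manifest, gene_config = config.load()
        p1, p2 = config.focal_pair
        for p in config.focal_pair:
            if p not in manifest.populations:
                raise ConfigError(f"focal population {p!r} not in manifest")

        if "catalog" in config.stages:
            stage = "catalog"
            variants_by_gene = {
                g: cat.call_variants(
                    aln, manifest,
                    reference_seq=(config.references or {}).get(g),
                    reference_id=aln.reference_id if not (config.references or {}).get(g) else None,
                )
                for g, aln in alignments.items()
            }
            results["variants"] = variants_by_gene
            tables["variants"] = cat.catalog_table(
                [v for vs in variants_by_gene.values() for v in vs],
                alignments, manifest,
            )
            classes = {}
            for level in ("nucleotide", "protein"):
                classes[level] = {
                    g: cat.collapse_haplotypes(aln, manifest, level)
                    for g, aln in alignments.items()
                }
                summary = cat.sharing_summary(
                    classes[level], list(config.focal_pair),
                    high_frequency_only=config.high_frequency_only,
                )
                results[f"sharing_summary_{level}"] = summary
            results["classes"] = classes
            tables["haplotype_sharing"] = pd.DataFrame(
                [
                    dict(level=lv,
                         total=results[f"sharing_summary_{lv}"].total_classes,
                         unique=results[f"sharing_summary_{lv}"].unique_to_one_population,
                         shared=results[f"sharing_summary_{lv}"].shared)
                    for lv in ("nucleotide", "protein")
                ]
            )

        if "diversity" in config.stages:
            stage = "diversity"
            tables["diversity"] = diversity_table(
                alignments, manifest, gene_config, config.focal_pair
            )
            if "catalog" in config.stages:
                fst = fst_records(results["variants"], config.focal_pair)
                if config.reference_fst is not None and len(fst):
                    fst = fst_outlier_screen(
                        fst, config.reference_fst, config.fst_outlier_quantile
                    )
                tables["fst"] = fst

        if "tests" in config.stages:
            stage = "tests"
            tables["tajima"] = neutrality_table(
                alignments, manifest, config.focal_pair,
                config.coalescent_replicates, config.seed,
            )
            sel_rows = []
            for class_label in ("old", "human_cluster"):
                members = [g for g in gene_config.genes_in_class(class_label)
                           if g in alignments]
                if not members:
                    continue
                concat = div.concatenate_class([alignments[g] for g in members])
                for pop in config.focal_pair:
                    sub = concat.subset(
                        [c for c in concat.sequences
                         if manifest.population_of(c) == pop]
                    )
                    ratio, p_fisher, _ = neu.pin_pis_test(sub)
                    d_vals = tables["tajima"].query(
                        "population == @pop and gene in @members"
                    )["D"].tolist()
                    if config.reference_d is not None:
                        med, p_w = neu.compare_d_distributions(
                            d_vals, config.reference_d
                        )
                    else:
                        med = (float(np.median([d for d in d_vals if math.isfinite(d)]))
                               if any(math.isfinite(d) for d in d_vals) else float("nan"))
                        p_w = float("nan")
                    sel_rows.append(dict(population=pop, clazz=class_label,
                                         pin_pis=ratio, p_fisher=p_fisher,
                                         median_d=med, p_wilcoxon=p_w))
            tables["selection"] = pd.DataFrame(sel_rows)

        if "sharing" in config.stages:
            stage = "sharing"
            if "catalog" not in config.stages:
                raise ConfigError("sharing stage needs the catalog stage")
            n1 = len(manifest.chromosomes(p1))
            n2 = len(manifest.chromosomes(p2))
            share_rows = []
            for level in ("nucleotide", "protein"):
                freqs = shr.pooled_frequencies(
                    results["classes"][level], config.focal_pair, config.pooling
                )
                null = shr.simulate_shared(
                    freqs, n1, n2, replicates=config.sharing_replicates,
                    seed=int(substream(config.seed, f"sharing/{level}").integers(2**31)),
                    level=level,
                )
                observed = shr.observed_shared_total(
                    results["classes"][level], config.focal_pair
                )
                null = shr.gaussian_tail_p(null, observed)
                results[f"sharing_null_{level}"] = null
                share_rows.append(dict(
                    level=level, replicates=null.replicates, mean=null.mean,
                    sd=null.sd, observed=observed,
                    gaussian_p_lower=null.gaussian_p_lower,
                    empirical_p_lower=null.empirical_p_lower,
                    pooling=config.pooling,
                ))
            tables["sharing"] = pd.DataFrame(share_rows)

        if "conversion" in config.stages:
            stage = "conversion"
            tract_rows = []
            for group in gene_config.paralog_groups:
                members = sorted(g for g in group if g in alignments)
                for recipient in members:
                    for donor in members:
                        if donor == recipient:
                            continue
                        if alignments[recipient].length != alignments[donor].length:
                            continue
                        tracts = conv.detect_tracts(
                            alignments[recipient], alignments[donor]
                        )
                        for t in tracts:
                            tract_rows.append(dict(
                                recipient=t.recipient_gene, donor=t.donor_gene,
                                start=t.start, end=t.end, length=t.length,
                                support=t.support,
                                haplotypes=",".join(t.recipient_haplotypes),
                            ))
            tables["tracts"] = pd.DataFrame(
                tract_rows, columns=["recipient", "donor", "start", "end",
                                     "length", "support", "haplotypes"])

        stage = "report"
        write_report(tables, out_dir)
        run_manifest = dict(
            seed=config.seed,
            focal_pair=list(config.focal_pair),
            pooling=config.pooling,
            sharing_replicates=config.sharing_replicates,
            coalescent_replicates=config.coalescent_replicates,
            fst_outlier_quantile=config.fst_outlier_quantile,
            stages=list(config.stages),
            genes=list(alignments),
            population_sizes=manifest.population_sizes(),
            derived_polarity="non-reference",
        )
        (out_dir / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=2, sort_keys=True) + "\n"
        )
        incomplete = out_dir / "INCOMPLETE"
        if incomplete.exists():
            incomplete.unlink()
    except Exception as exc:
        (out_dir / "INCOMPLETE").write_text(f"stage={stage}: {exc}\n")
        write_report(tables, out_dir)  # keep partial outputs
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    results["tables"] = tables
    return results
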