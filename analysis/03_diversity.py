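#!/usr/bin/env python
"""Diversity and differentiation: pi, pi_S/pi_N, d_XY, per-SNV F_ST.

Computes the per-gene and class-concatenated diversity summary (printed
x100), the per-SNV F_ST table between western and eastern samples, and the
empirical outlier screen against the F_ST distribution of the neutral
non-coding reference loci (flagging SNVs with tail probability < 5%).
"""

import argparse
import importlib.util
import math
from pathlib import Path

from tas2rpop.catalog import call_variants
from tas2rpop.diversity import site_fst
from tas2rpop.io import read_alignment, write_report
from tas2rpop.pipeline import diversity_table, fst_outlier_screen, fst_records

_cat = importlib.util.spec_from_file_location(
    "catalog_driver", Path(__file__).parent / "02_catalog.py"
)
catalog_driver = importlib.util.module_from_spec(_cat)
_cat.loader.exec_module(catalog_driver)


def reference_fst_values(data: Path, manifest) -> list[float]:
    out = []
    for path in sorted((data / "reference_loci").glob("*.fasta")):
        aln = read_alignment(path, path.stem, class_label="noncoding")
        ref_id = aln.chromosome_ids[0]
        for v in call_variants(aln, manifest, reference_id=ref_id):
            if v.effect == "indel":
                continue
            (k1, n1), (k2, n2) = v.counts["western"], v.counts["eastern"]
            if 0 < k1 + k2 < n1 + n2:
                f = site_fst((k1, n1), (k2, n2))
                if math.isfinite(f):
                    out.append(f)
    return out


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out_root / "data"
    alignments, manifest, gene_config, ancestral = catalog_driver.load_dataset(data)

    div = diversity_table(alignments, manifest, gene_config, ("western", "eastern"))

    variants_by_gene = {
        g: call_variants(aln, manifest, reference_seq=ancestral[g])
        for g, aln in alignments.items()
    }
    fst = fst_records(variants_by_gene, ("western", "eastern"))
    ref = reference_fst_values(data, manifest)
    fst = fst_outlier_screen(fst, ref, quantile=0.05)

    write_report({"diversity": div, "fst": fst}, args.out_root / "tables")

    for cls in ("old", "human_cluster"):
        row = div[div.gene == f"{cls}_concatenated"].iloc[0]
        print(f"{cls:<14} concatenated ({row.length} bp): "
              f"pi_w={row.pi1:.3f} pi_e={row.pi2:.3f} d_xy={row.d_xy:.3f} (x100)")
    n_out = int(fst.outlier.sum())
    print(f"{len(fst)} coding SNVs vs {len(ref)} neutral reference SNVs: "
          f"{n_out} F_ST outliers at the 5% empirical tail "
          f"(max F_ST={fst.fst.max():.3f})")


if __name__ == "__main__":
    main()
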