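#!/usr/bin/env python
"""Directional Kendall-tau stage: rank the miRNAs driving patient-vs-brother distance.

Reads the miRNA matrix and sample sheet, computes each miRNA's signed share
of the within-family tau distance summed over families, attaches one-sided
within-family permutation p-values (up- and downregulated alternatives),
writes the per-miRNA report and a Ward dendrogram of the individuals, and
checks the planted shifts against the truth table.
"""

import argparse
from pathlib import Path

from ginipipe import io
from ginipipe.famtau import (
    RankedProfileSet,
    pairwise_distance_matrix,
    permutation_pvalues,
    ward_cluster,
)
from ginipipe.pipeline import derive_seed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--indir", type=Path, default=Path("scratch/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("-B", "--permutations", type=int, default=2000)
    args = ap.parse_args()

    values = io.read_expression_matrix(args.indir / "mirna_matrix.tsv")
    sheet = io.read_sample_sheet(args.indir / "mirna_samples.tsv", require_pairs=True)
    meta = sheet.set_index("sample_id")
    meta["is_patient"] = meta["status"] == "affected"
    profiles = RankedProfileSet(values=values, sample_meta=meta)

    perm = permutation_pvalues(profiles, n_permutations=args.permutations,
                               seed=derive_seed(args.seed, "famtau"))
    report = perm.report()
    io.write_tsv(report.reset_index(names="mirna_id"), args.outdir / "mirna_directional.tsv")
    tree = ward_cluster(pairwise_distance_matrix(profiles))
    io.write_newick(tree.to_newick(), args.outdir / "mirna_dendrogram.nwk")

    truth = io.read_tsv(args.indir / "mirna_truth.tsv").set_index("mirna_id")
    top_up = report.head(3)
    top_down = report.tail(3).iloc[::-1]
    print(f"{len(report)} miRNAs over {values.shape[1]} individuals, "
          f"B={args.permutations} within-family permutations")
    print("top upregulated (overall distance, p_up):")
    for mid, row in top_up.iterrows():
        print(f"  {mid}  D={row['overall_distance']:+.4f}  p_up={row['p_up']:.4f}  "
              f"truth={truth.loc[mid, 'direction']}")
    print("top downregulated (overall distance, p_down):")
    for mid, row in top_down.iterrows():
        print(f"  {mid}  D={row['overall_distance']:+.4f}  p_down={row['p_down']:.4f}  "
              f"truth={truth.loc[mid, 'direction']}")


if __name__ == "__main__":
    main()
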