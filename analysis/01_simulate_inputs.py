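#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Emulates the sibling-pair study design: six families of one affected man and
one healthy brother with two-color NMD arrays, nine families of brothers
with a 333-miRNA expression matrix, miRNA/target sequences with planted
sites and variants, and a carrier-count table drawn at the published control
frequency and odds ratio.  Raw inputs go under scratch/inputs/ (bulky,
regenerated on demand); truth tables go with them so later stages can score
themselves.
"""

import argparse
from pathlib import Path

import pandas as pd

from ginipipe import io, simulate
from ginipipe.pipeline import derive_seed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("scratch/inputs"))
    ap.add_argument("--n-probes", type=int, default=2000)
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    design = simulate.StudyDesign(n_families=6, seed=derive_seed(args.seed, "nmd"))
    nmd_cfg = simulate.NmdSimConfig(
        n_probes=args.n_probes, n_true_genes=5, n_stress_genes=10,
        effect_log_ratio=1.0, noise_sd=0.1, in_region_fraction=0.1,
    )
    samples, nmd_truth = simulate.simulate_nmd_arrays(design, nmd_cfg)
    meta = {"seed": args.seed, "config_hash": io.config_hash(vars(args))}
    for s in samples:
        io.write_array_sample(s, out / "arrays" / f"{s.sample_id}.tsv", meta=meta)
    io.write_sample_sheet(design.sample_sheet(), out / "samples.tsv", meta=meta)
    io.write_tsv(nmd_truth, out / "nmd_truth.tsv", meta=meta)
    print(f"wrote {len(samples)} two-color arrays x {args.n_probes} probes "
          f"(5 NMD-true genes, 10 stress genes planted)")

    mirna_design = simulate.StudyDesign(n_families=9, seed=derive_seed(args.seed, "mirna"))
    mirna_cfg = simulate.MirnaSimConfig(n_mirnas=333, n_up=3, n_down=3, shift=2.0,
                                        family_sd=0.5, noise_sd=0.3)
    expr, mirna_truth = simulate.simulate_mirna_matrix(mirna_design, mirna_cfg)
    io.write_expression_matrix(expr.values, out / "mirna_matrix.tsv", meta=meta)
    io.write_sample_sheet(mirna_design.sample_sheet(), out / "mirna_samples.tsv", meta=meta)
    io.write_tsv(mirna_truth, out / "mirna_truth.tsv", meta=meta)
    print(f"wrote miRNA matrix {expr.values.shape[0]} x {expr.values.shape[1]} "
          f"(3 up- and 3 down-shifted miRNAs planted)")

    seq_cfg = simulate.SequenceSimConfig()
    mirnas, targets, variants, seq_truth = simulate.simulate_sequences_and_variants(
        seq_cfg, seed=derive_seed(args.seed, "seq")
    )
    io.write_fasta(mirnas, out / "mirnas.fa")
    io.write_fasta(targets, out / "targets.fa")
    io.write_variant_table(variants, out / "variants.tsv", meta=meta)
    io.write_tsv(seq_truth, out / "seq_truth.tsv", meta=meta)
    n_site = int(seq_truth["in_site"].sum())
    print(f"wrote {len(mirnas)} miRNAs, {len(targets)} targets, {len(variants)} variants "
          f"({n_site} inside planted sites)")


if __name__ == "__main__":
    main()
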