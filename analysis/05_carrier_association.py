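#!/usr/bin/env python
"""Association stage: odds ratios for the MAGEC1 start-codon variant carrier counts.

Uses the published genotyped group counts bundled with the package: each
case group (unselected PC, HPC probands) is tested against the pooled
blood-donor/BPH controls and against all four control groups, with Woolf
95% confidence intervals and chi-square p-values, mirroring the study's
association table.
"""

import argparse
from pathlib import Path

import pandas as pd

from ginipipe import io
from ginipipe.association import (
    ContingencyTable2x2,
    carrier_frequency,
    odds_ratio_woolf,
    pool_controls,
)
from ginipipe.datasets import CONTROL_POOLS, carrier_count_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = carrier_count_table().set_index("group")
    rows = []
    for case_group in ("unselected_pc", "hpc_probands"):
        case = counts.loc[case_group]
        freq = carrier_frequency(int(case["carriers"]), int(case["total"]))
        for pool_name, members in CONTROL_POOLS.items():
            k, n = pool_controls(
                [(int(counts.loc[g, "carriers"]), int(counts.loc[g, "total"])) for g in members]
            )
            res = odds_ratio_woolf(
                ContingencyTable2x2(
                    int(case["carriers"]), int(case["total"] - case["carriers"]),
                    k, n - k, case_label=case_group, control_label=pool_name,
                )
            )
            rows.append(
                {
                    "group": case_group,
                    "carrier_frequency": freq.formatted(),
                    "controls": pool_name,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                }
            )
            print(f"{case_group} {freq.formatted()} vs {pool_name} ({k}/{n}): "
                  f"OR {res.formatted()}, p = {res.p_value:.3f}")
    io.write_tsv(pd.DataFrame(rows), args.outdir / "association.tsv")


if __name__ == "__main__":
    main()
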