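#!/usr/bin/env python
"""Kruskal-Wallis + Dunn comparisons of every metric across DIV groups.

Reads results/metrics.csv if 04_band_metrics.py has run (recomputes it
otherwise), tests each metric across the seven DIV groups and writes the
omnibus and pairwise tables to results/.
"""

import argparse
import subprocess
import sys
from pathlib import Path

import pandas as pd

from neuroftir.stats import compare_metrics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--adjust", default="bonferroni", choices=["bonferroni", "holm", "none"])
    args = ap.parse_args()

    metrics_csv = Path("results/metrics.csv")
    if not metrics_csv.exists():
        subprocess.run(
            [sys.executable, "analysis/04_band_metrics.py", "--seed", str(args.seed)],
            check=True,
        )
    table = pd.read_csv(metrics_csv)
    results = compare_metrics(table, adjustment=args.adjust)

    pd.DataFrame(
        [{"metric": r.metric, "H": r.H, "df": r.df, "p": r.p_omnibus} for r in results]
    ).to_csv("results/stats_omnibus.csv", index=False, float_format="%.6g")
    pd.DataFrame(
        [
            {
                "metric": r.metric,
                "group_i": c.group_i,
                "group_j": c.group_j,
                "z": c.z,
                "p": c.p,
                "p_adjusted": c.p_adjusted,
                "stars": c.stars,
            }
            for r in results
            for c in r.pairwise
        ]
    ).to_csv("results/stats_pairwise.csv", index=False, float_format="%.6g")

    print(f"{'metric':22s} {'H':>8s} {'p_omnibus':>10s}  DIV2-vs-14")
    for r in results:
        c = r.pair(2, 14)
        print(f"{r.metric:22s} {r.H:8.2f} {r.p_omnibus:10.2e}  {c.stars}")
    print("tables -> results/stats_omnibus.csv, results/stats_pairwise.csv")


if __name__ == "__main__":
    main()
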