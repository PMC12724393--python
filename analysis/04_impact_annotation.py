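"""Predicted impact of deletions on complexes, tRNAs and microproteins.

Annotates every junction against the rCRS catalog, aggregates cumulative
read % per complex / tRNA / microprotein per sample, and compares the
burden across groups with Kruskal-Wallis + Dunn tests within each region.
Also exports the sample x tRNA burden matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from mtaging.deletions import (impact_long_table, metrics_table,
                               read_deletion_table)
from mtaging.reference import default_catalog
from mtaging.stats import kruskal_dunn


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    catalog = default_catalog()
    calls = read_deletion_table(args.cohort / "deletions.tsv")
    meta = pd.read_csv(args.cohort / "metadata.tsv", sep="\t")
    impact_long_table(calls, catalog).to_csv(
        args.out / "impact_annotations.tsv", sep="\t", index=False)

    metrics = metrics_table(
        calls, catalog,
        all_samples=list(zip(meta.sample_id.astype(str),
                             meta.benchmark_coverage)))
    merged = metrics.merge(meta[["sample_id", "region"]], on="sample_id")

    comparisons = []
    for region in ("FC", "CER"):
        sub = merged[merged.region == region]
        complexes = {cx: sub[f"complex_{cx}_read_pct"].to_numpy()
                     for cx in ("I", "III", "IV", "V")}
        res = kruskal_dunn(complexes)
        print(f"{region} complexes: Kruskal-Wallis H = {res.H_statistic:.1f} "
              f"(p = {res.H_p_value:.2e})")
        frame = res.to_frame()
        frame.insert(0, "region", region)
        frame.insert(1, "grouping", "complex")
        comparisons.append(frame)

        mdp_cols = [c for c in sub.columns if c.startswith("mdp_")]
        mdps = {c.removeprefix("mdp_").removesuffix("_read_pct"):
                sub[c].to_numpy() for c in mdp_cols}
        if len(mdps) >= 2:
            res = kruskal_dunn(mdps)
            top = (sub[mdp_cols].mean().sort_values(ascending=False)
                   .index[0].removeprefix("mdp_").removesuffix("_read_pct"))
            print(f"{region} microproteins: H = {res.H_statistic:.1f} "
                  f"(p = {res.H_p_value:.2e}); highest burden: {top}")
            frame = res.to_frame()
            frame.insert(0, "region", region)
            frame.insert(1, "grouping", "MDP")
            comparisons.append(frame)

    pd.concat(comparisons, ignore_index=True).to_csv(
        args.out / "impact_group_tests.tsv", sep="\t", index=False)

    trna_cols = [c for c in merged.columns if c.startswith("trna_")]
    trna = merged[["sample_id", "region", *trna_cols]]
    trna.to_csv(args.out / "trna_burden_matrix.tsv", sep="\t", index=False)
    print(f"tRNA burden matrix: {len(trna)} samples x {len(trna_cols)} tRNAs")


if __name__ == "__main__":
    main()
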