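"""SNV burden by ploidy class, haplogroup stratum and age.

Counts homoplasmic (VAF >= 0.9) and heteroplasmic (0.1 < VAF < 0.9)
variants per sample, compares HV vs Non-HV strata with rank-based
regression (age, sex and benchmark coverage as covariates), and fits
linear age models for heteroplasmic counts per region.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mtaging.pipeline import SEX_CODE
from mtaging.stats import ols_fit, rank_fit
from mtaging.variants import read_snv_table, variant_profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    calls = read_snv_table(args.cohort / "snvs.tsv")
    meta = pd.read_csv(args.cohort / "metadata.tsv", sep="\t")
    by_sample: dict[str, list] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    rows = []
    for r in meta.itertuples(index=False):
        p = variant_profile(by_sample.get(str(r.sample_id), []), r.haplogroup,
                            sample_id=str(r.sample_id))
        rows.append({"sample_id": str(r.sample_id),
                     "homoplasmic_count": p.homoplasmic_count,
                     "heteroplasmic_count": p.heteroplasmic_count,
                     "hv_category": p.hv_category})
    profiles = pd.DataFrame(rows)
    profiles.to_csv(args.out / "variant_profiles.tsv", sep="\t", index=False)

    df = profiles.merge(meta[["sample_id", "region", "age", "sex",
                              "benchmark_coverage"]].assign(
        sample_id=meta.sample_id.astype(str)), on="sample_id")
    df["sex_code"] = df["sex"].map(SEX_CODE)
    df["nonhv"] = (df.hv_category == "NonHV").astype(float)

    models = {}
    for region in ("FC", "CER"):
        sub = df[df.region == region]
        fit = rank_fit(sub, "homoplasmic_count",
                       ["nonhv", "age", "sex_code", "benchmark_coverage"])
        g = sub.groupby("hv_category")["homoplasmic_count"].agg(["mean", "std"])
        print(f"{region} homoplasmic SNVs: NonHV {g.loc['NonHV', 'mean']:.1f} ± "
              f"{g.loc['NonHV', 'std']:.1f} vs HV {g.loc['HV', 'mean']:.1f} ± "
              f"{g.loc['HV', 'std']:.1f} (rank p = {fit.p_values['nonhv']:.2e})")
        models[f"homoplasmic_hv_{region}"] = fit.to_dict()

        het = ols_fit(sub, "heteroplasmic_count",
                      ["age", "benchmark_coverage", "sex_code"])
        print(f"{region} heteroplasmic SNVs vs age: slope "
              f"{het.coefficients['age']:+.4f}/y (p = {het.p_values['age']:.3g})")
        models[f"heteroplasmic_age_{region}"] = het.to_dict()
    (args.out / "snv_models.json").write_text(json.dumps(models, indent=2))


if __name__ == "__main__":
    main()
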