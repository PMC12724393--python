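"""End-to-end orchestration: annotate -> metrics -> stats -> GWAS -> report.

``run_pipeline`` is a pure function of (inputs, config, seed): given the same
input tables and configuration it writes byte-identical outputs, and the run
manifest records input checksums so reruns are auditable.  Stages log row
counts so filter attrition can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .deletions import (DeletionTableError, default_top30_catalog,
                        impact_long_table, load_top30_catalog, metrics_table,
                        cohort_summary, read_deletion_table, METRIC_COLUMNS)
from .gwas import eligible_pairs, gwas_report, results_table, run_mtgwas
from .reference import default_catalog, load_genome, rcrs_genome
from .repeats import AlleleSubstitution, repeat_delta
from .stats import bin_delta, exp_regression, ols_fit, rank_fit
from .variants import (copy_number_table, read_coverage_table, read_snv_table,
                       genotype_matrix, variant_profile)

logger = logging.getLogger("mtaging.pipeline")

SEX_CODE = {"F": 0.0, "M": 1.0}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    deletions_tsv: str
    snvs_tsv: str
    metadata_tsv: str
    coverage_tsv: str
    out_dir: str
    reference_fasta: str | None = None   # default: vendored rCRS
    top30_json: str | None = None
    seed: int = 0
    run_gwas: bool = True
    gwas_min_carriers: int = 10
    gwas_max_distance: int = 10
    alpha: float = 0.05
    repeat_window: int = 15
    age_bins: tuple[float, ...] = (30.0, 45.0, 60.0)

    def validate(self) -> None:
        paths = {
            "deletions_tsv": self.deletions_tsv, "snvs_tsv": self.snvs_tsv,
            "metadata_tsv": self.metadata_tsv, "coverage_tsv": self.coverage_tsv,
        }
        if self.reference_fasta:
            paths["reference_fasta"] = self.reference_fasta
        if self.top30_json:
            paths["top30_json"] = self.top30_json
        missing = [k for k, p in paths.items() if not Path(p).is_file()]
        if missing:
            raise PipelineError("validate", f"missing input files: {missing}")
        if not 0 < self.alpha <= 1:
            raise PipelineError("validate", "alpha must be in (0, 1]")
        if self.gwas_min_carriers < 1 or self.gwas_max_distance < 0:
            raise PipelineError("validate", "bad GWAS filter thresholds")


DATA_DICTIONARY = {
    "copy_number.tsv": {
        "mt_mean_depth": "reads (mean MT depth)",
        "autosomal_mean_depth": "reads (mean autosomal depth)",
        "mtdna_copy_number": "mtDNA copies per diploid cell",
    },
    "sample_metrics.tsv": {
        "benchmark_coverage": "reads (mean depth, RNR1+CYB segments)",
        "n_unique_deletions": "count of distinct junctions",
        "deletions_per_10k": "unique junctions per 10,000x benchmark coverage",
        "cumulative_read_pct": "percent (0-100)",
        "read_pct_lt1000": "percent (0-100), deletions < 1000 bp",
        "read_pct_ge1000": "percent (0-100), deletions >= 1000 bp",
        "top30_read_pct": "percent (0-100), catalog junctions",
        "common_del_read_pct": "percent (0-100), junction 8471-13449",
        "complex_*_read_pct": "percent (0-100) impacting that complex",
        "trna_*_read_pct": "percent (0-100) impacting that tRNA",
        "mdp_*_read_pct": "percent (0-100) impacting that microprotein",
    },
    "variant_profiles.tsv": {
        "homoplasmic_count": "count (VAF >= 0.9)",
        "heteroplasmic_count": "count (0.1 < VAF < 0.9)",
    },
    "gwas_results.tsv": {
        "beta": "change in SNP presence per percent deletion read",
        "p": "two-sided p-value", "threshold": "Bonferroni alpha/n_tests",
    },
}


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            name: _sha256(p)
            for name, p in [
                ("deletions_tsv", config.deletions_tsv),
                ("snvs_tsv", config.snvs_tsv),
                ("metadata_tsv", config.metadata_tsv),
                ("coverage_tsv", config.coverage_tsv),
            ]
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # ---- load -------------------------------------------------------------
    info = stage("load")
    try:
        genome = (load_genome(config.reference_fasta)
                  if config.reference_fasta else rcrs_genome())
        catalog = default_catalog(genome.length)
        metadata = pd.read_csv(config.metadata_tsv, sep="\t")
        calls = read_deletion_table(config.deletions_tsv)
        snv_calls = read_snv_table(config.snvs_tsv)
        coverage = read_coverage_table(config.coverage_tsv)
        top30 = (load_top30_catalog(config.top30_json)
                 if config.top30_json else default_top30_catalog())
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc
    metadata["sample_id"] = metadata["sample_id"].astype(str)
    info.update(n_samples=len(metadata), n_deletion_rows=len(calls),
                n_snv_rows=len(snv_calls))
    samples = metadata["sample_id"].tolist()
    regions = sorted(metadata["region"].unique())
    meta_ix = metadata.set_index("sample_id")

    # ---- copy number ------------------------------------------------------
    info = stage("copy_number")
    cn = copy_number_table(coverage)
    cn = cn.merge(metadata[["sample_id", "region", "age", "sex"]], on="sample_id")
    cn["sex_code"] = cn["sex"].map(SEX_CODE)
    _write_tsv(cn.drop(columns="sex_code"), out / "copy_number.tsv")
    cn_models = {}
    cn["region_code"] = (cn["region"] == regions[-1]).astype(float)
    if cn["region"].nunique() > 1:
        rk = rank_fit(cn, "mtdna_copy_number", ["region_code", "age", "sex_code"])
        cn_models["region_rank"] = rk.to_dict()
    for region in regions:
        sub = cn[cn["region"] == region]
        fit = ols_fit(sub, "mtdna_copy_number", ["age", "sex_code"])
        cn_models[f"age_{region}"] = fit.to_dict()
        cn_models[f"age_{region}"]["delta_per_15y"] = bin_delta(fit, 30.0, 15.0)
    (out / "copy_number_models.json").write_text(json.dumps(cn_models, indent=2))
    info.update(n_rows=len(cn))

    # ---- deletion metrics -------------------------------------------------
    info = stage("deletion_metrics")
    benchmarks = {}
    for c in calls:
        benchmarks[c.sample_id] = c.benchmark_coverage
    all_samples = []
    for sid in samples:
        bench = benchmarks.get(sid)
        if bench is None and "benchmark_coverage" in meta_ix.columns:
            bench = float(meta_ix.loc[sid, "benchmark_coverage"])
        if bench is not None:
            all_samples.append((sid, bench))
    try:
        metrics = metrics_table(calls, catalog, top30, all_samples)
    except DeletionTableError as exc:
        raise PipelineError("deletion_metrics", str(exc)) from exc
    _write_tsv(metrics, out / "sample_metrics.tsv")
    summary = cohort_summary(metrics, metadata)
    _write_tsv(summary, out / "cohort_summary.tsv")
    info.update(n_samples=len(metrics))

    # ---- deletion age models ----------------------------------------------
    info = stage("deletion_age_models")
    merged = metrics.merge(metadata[["sample_id", "region", "age", "sex"]],
                           on="sample_id")
    merged["sex_code"] = merged["sex"].map(SEX_CODE)
    age_models: dict = {}
    for region in regions:
        sub = merged[merged["region"] == region]
        age_models[region] = {}
        for metric in METRIC_COLUMNS:
            if metric not in sub.columns or len(sub) < 6:
                continue
            fit = exp_regression(sub, metric, "age",
                                 ["benchmark_coverage", "sex_code"])
            entry = fit.to_dict()
            entry["bin_deltas_15y"] = {
                f"{int(a)}-{int(a + 15)}": bin_delta(fit, a, 15.0)
                for a in config.age_bins
            }
            age_models[region][metric] = entry
    (out / "deletion_age_models.json").write_text(json.dumps(age_models, indent=2))
    info.update(n_models=sum(len(v) for v in age_models.values()))

    # ---- impact annotation ------------------------------------------------
    info = stage("impact_annotation")
    impacts = impact_long_table(calls, catalog)
    _write_tsv(impacts, out / "impact_annotations.tsv")
    info.update(n_rows=len(impacts))

    # ---- SNV profiles -----------------------------------------------------
    info = stage("snv_profiles")
    by_sample: dict[str, list] = {sid: [] for sid in samples}
    for c in snv_calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    prof_rows = []
    for sid in samples:
        hap = str(meta_ix.loc[sid, "haplogroup"]) if "haplogroup" in meta_ix.columns else "U"
        p = variant_profile(by_sample.get(sid, []), hap, sample_id=sid)
        prof_rows.append({"sample_id": sid,
                          "homoplasmic_count": p.homoplasmic_count,
                          "heteroplasmic_count": p.heteroplasmic_count,
                          "haplogroup": p.haplogroup_label,
                          "hv_category": p.hv_category})
    profiles = pd.DataFrame(prof_rows)
    _write_tsv(profiles, out / "variant_profiles.tsv")
    info.update(n_samples=len(profiles))

    # ---- MT-GWAS + repeat mechanism ---------------------------------------
    info = stage("mtgwas")
    gwas_frames = []
    report_frames = []
    if config.run_gwas:
        geno = genotype_matrix(snv_calls, samples)
        covars = metadata[["sample_id", "age", "sex"]].copy()
        covars["sex"] = covars["sex"].map(SEX_CODE)
        covars["benchmark_coverage"] = [
            benchmarks.get(s, meta_ix.loc[s].get("benchmark_coverage", float("nan")))
            for s in covars["sample_id"]
        ]
        for region in regions:
            region_samples = metadata.loc[metadata["region"] == region,
                                          "sample_id"].tolist()
            pairs = eligible_pairs(geno, calls, metadata, region,
                                   config.gwas_min_carriers,
                                   config.gwas_max_distance)
            if not pairs:
                continue
            region_geno = geno.loc[region_samples]
            results = run_mtgwas(pairs, region_geno, calls,
                                 covars[covars["sample_id"].isin(region_samples)],
                                 config.alpha)
            gwas_frames.append(results_table(results))
            deltas = {}
            for r in results:
                pos = r.pair.snp_position
                label = r.pair.snp.split(":")[1]
                ref, alt = label.split(">")
                try:
                    sub = AlleleSubstitution(pos, ref, alt)
                    ra, aa = repeat_delta(genome, *r.pair.junction, sub,
                                          config.repeat_window)
                    deltas[(r.pair.snp, r.pair.junction)] = (
                        ra.repeat_length, aa.repeat_length)
                except ValueError:
                    continue
            report_frames.append(gwas_report(results, deltas))
    gwas_df = (pd.concat(gwas_frames, ignore_index=True)
               if gwas_frames else pd.DataFrame())
    report_df = (pd.concat(report_frames, ignore_index=True)
                 if report_frames else pd.DataFrame())
    _write_tsv(gwas_df, out / "gwas_results.tsv")
    _write_tsv(report_df, out / "gwas_repeat_report.tsv")
    info.update(n_tests=int(len(gwas_df)))

    # ---- finalize ---------------------------------------------------------
    (out / "data_dictionary.json").write_text(json.dumps(DATA_DICTIONARY, indent=2))
    output_names = [
        "copy_number.tsv", "copy_number_models.json", "sample_metrics.tsv",
        "cohort_summary.tsv", "deletion_age_models.json",
        "impact_annotations.tsv", "variant_profiles.tsv", "gwas_results.tsv",
        "gwas_repeat_report.tsv", "data_dictionary.json",
    ]
    manifest["outputs"] = {name: _sha256(out / name) for name in output_names}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
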