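"""Seeded synthetic cohort generator.

Generates a two-region brain cohort (frontal cortex "FC" and cerebellum
"CER") with the statistical structure of a population WGS mtDNA study:

* ages uniform over 0.4-100 years, sexes balanced, haplogroup labels with a
  realistic HV fraction per region;
* mtDNA copy number with region-specific means (~4537 FC vs ~1367 CER,
  a ~3.3-fold contrast) and a mild negative linear age slope, plus the
  matching coverage summaries (autosomal depth ~34x);
* per-sample deletion tables drawn from a fixed 50-junction catalog that
  includes the canonical common deletion (8471, 13449): the per-sample
  cumulative deletion read percent follows an exponential (log-linear) age
  model, unique-junction counts follow a Poisson rate with the same
  exponential age growth, and supporting reads respect a 1-read detection
  floor, so low-burden samples show zero-inflation;
* per-sample SNV tables: homoplasmic counts drawn per haplogroup category
  (NonHV markedly higher than HV), heteroplasmic counts age-increasing in
  FC only;
* optionally, a planted SNP:deletion association for power studies.

Every quantity is drawn from one ``numpy`` generator seeded by the config,
so a cohort is bit-identically reproducible, and the generating parameters
are embedded as ``ground_truth`` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deletions import COMMON_DELETION, DeletionCall, Junction
from .reference import MitoGenome, rcrs_genome
from .variants import CoverageSummary, SnvCall, hv_category

REGIONS = ("FC", "CER")

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

_HV_LABELS = ("H1", "H2a", "H3b", "H5", "V1a", "HV0")
_NONHV_LABELS = ("U5b1", "K1a", "J1c", "T2b", "L3e2", "W1", "X2b", "I1a",
                 "N1b", "A2")

# paper-motif junctions carried by the catalog so junction-level analyses
# (common-deletion metric, repeat-mechanism pairs) have material to work on
SPECIAL_JUNCTIONS: tuple[Junction, ...] = (
    COMMON_DELETION, (7816, 14807), (12369, 14004), (8775, 14771),
)

_CATALOG_SEED = 20230777  # fixed: the junction catalog is a study condition


def build_junction_catalog(n_junctions: int = 50) -> tuple[tuple[Junction, bool], ...]:
    """Deterministic simulation catalog of (junction, is_large) entries.

    The first entries are the named junctions above (all >= 1000 bp); the
    remainder are drawn once from the major arc, 60% large (>= 1000 bp) and
    40% small, and never regenerated per cohort.
    """
    rng = np.random.default_rng(_CATALOG_SEED)
    entries: list[tuple[Junction, bool]] = [(j, True) for j in SPECIAL_JUNCTIONS]
    seen = set(SPECIAL_JUNCTIONS)
    n_extra = n_junctions - len(entries)
    n_large = int(round(0.6 * n_extra))
    sizes = [True] * n_large + [False] * (n_extra - n_large)
    for is_large in sizes:
        while True:
            if is_large:
                size = int(rng.integers(1200, 9000))
            else:
                size = int(rng.integers(60, 900))
            bp5 = int(rng.integers(5800, 16020 - size - 1))
            junction = (bp5, bp5 + size + 1)
            if junction not in seen:
                seen.add(junction)
                entries.append((junction, is_large))
                break
    return tuple(entries)


def _marker_pool(genome: MitoGenome) -> tuple[tuple[int, str, str], ...]:
    """Fixed pool of homoplasmic marker sites (pos, ref, alt).

    Includes the three repeat-modulating SNPs next to their catalog
    junctions, a handful of sites placed within 10 bp of other catalog
    breakpoints (null material for association filters), and a spread of
    background sites.
    """
    catalog = build_junction_catalog()
    positions: list[int] = [14798, 12372, 14766]
    # near-breakpoint null sites for a few ordinary catalog junctions
    for (bp5, bp3), _ in catalog[4:12]:
        positions.append(bp5 - 4)
        positions.append(bp3 + 6)
    background = [709, 930, 1243, 1719, 2092, 2358, 3010, 3480, 3915, 4216,
                  4529, 4917, 5263, 5460, 6026, 6371, 6776, 7325, 7650, 8020,
                  8448, 8994, 9305, 9698, 10034, 10550, 11002, 11467, 11923,
                  12558, 12810, 13263, 13708, 14110, 14470, 15043, 15326,
                  15607, 15924, 16126, 16223, 16356, 16390, 1048, 1438, 2706,
                  3594, 4769, 5147, 6253, 7861, 9540, 10398, 11719, 13105]
    positions.extend(p for p in background if p not in positions)
    pool = []
    for pos in positions:
        ref = genome.base(pos)
        if ref == "N":
            continue
        pool.append((pos, ref, _TRANSITION[ref]))
    return tuple(pool)


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters; defaults are the study conditions."""

    seed: int = 0
    n_per_region: Mapping[str, int] = field(
        default_factory=lambda: {"FC": 143, "CER": 149})
    age_range: tuple[float, float] = (0.4, 100.0)
    hv_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 60 / 143, "CER": 72 / 149})
    # copy number (per diploid cell) and its linear age trend
    cn_mean: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 4536.805, "CER": 1367.205})
    cn_sd: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 1376.705, "CER": 687.661})
    cn_age_slope: Mapping[str, float] = field(
        default_factory=lambda: {"FC": -193.23 / 15, "CER": -37.14 / 15})
    autosomal_depth_mean: float = 34.28
    autosomal_depth_sd: float = 4.04
    # deletion burden targets (cohort means) and exponential age slope
    dels_per_10k_mean: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 9.759, "CER": 3.189})
    cumulative_read_pct_mean: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 0.780, "CER": 0.135})
    deletion_ln_age_slope: float = float(np.log(2) / 26)  # doubles every 26 y
    deletion_noise_sd: float = 1.0
    benchmark_mean: float = 10_000.0
    benchmark_sd: float = 1_200.0
    large_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 0.8, "CER": 0.2})
    n_junctions: int = 50
    # SNVs
    homoplasmic_mean: Mapping[str, float] = field(
        default_factory=lambda: {"FC:NonHV": 33.89, "FC:HV": 11.93,
                                 "CER:NonHV": 31.03, "CER:HV": 11.71})
    homoplasmic_sd: Mapping[str, float] = field(
        default_factory=lambda: {"FC:NonHV": 5.25, "FC:HV": 3.49,
                                 "CER:NonHV": 7.75, "CER:HV": 3.00})
    heteroplasmic_base: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 0.30, "CER": 2.0})
    heteroplasmic_age_slope: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 0.012, "CER": 0.0})

    def validate(self) -> None:
        if self.deletion_noise_sd <= 0 or self.benchmark_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        for r in REGIONS:
            if self.n_per_region[r] < 1:
                raise ValueError("need at least one sample per region")
            if not 0 <= self.hv_fraction[r] <= 1:
                raise ValueError("hv_fraction must be in [0, 1]")
        lo, hi = self.age_range
        if not 0 < lo < hi:
            raise ValueError("invalid age range")


@dataclass(frozen=True)
class SyntheticCohort:
    metadata: pd.DataFrame      # sample_id, region, age, sex, haplogroup,
                                # hv_category, benchmark_coverage
    deletions: pd.DataFrame     # deletion-table dialect (long)
    snvs: pd.DataFrame          # snv-table dialect (long)
    coverage: pd.DataFrame      # sample_id, mt_mean_depth, autosomal_mean_depth
    ground_truth: dict
    config: CohortConfig

    def deletion_calls(self) -> list[DeletionCall]:
        return [
            DeletionCall(str(r.sample_id), int(r.bp5), int(r.bp3),
                         int(r.supporting_reads), float(r.read_pct),
                         float(r.benchmark_coverage))
            for r in self.deletions.itertuples(index=False)
        ]

    def snv_calls(self) -> list[SnvCall]:
        return [
            SnvCall(str(r.sample_id), int(r.position), str(r.ref), str(r.alt),
                    float(r.vaf))
            for r in self.snvs.itertuples(index=False)
        ]

    def coverage_summaries(self) -> list[CoverageSummary]:
        return [
            CoverageSummary(str(r.sample_id), float(r.mt_mean_depth),
                            float(r.autosomal_mean_depth))
            for r in self.coverage.itertuples(index=False)
        ]

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [("metadata", self.metadata),
                            ("deletions", self.deletions),
                            ("snvs", self.snvs),
                            ("coverage", self.coverage)]:
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def _mean_exp_age(slope: float, age_range: tuple[float, float]) -> float:
    lo, hi = age_range
    if slope == 0:
        return 1.0
    return (np.exp(slope * hi) - np.exp(slope * lo)) / (slope * (hi - lo))


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a cohort from ``config`` (defaults: the study conditions)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = rcrs_genome()
    catalog = build_junction_catalog(config.n_junctions)
    pool = _marker_pool(genome)
    b1 = config.deletion_ln_age_slope
    sigma = config.deletion_noise_sd
    age_gain = _mean_exp_age(b1, config.age_range)
    age_mid = sum(config.age_range) / 2.0
    age_var = (config.age_range[1] - config.age_range[0]) ** 2 / 12.0

    # base catalog weights decay with rank so a few junctions are common
    base_w = 1.0 / (np.arange(len(catalog)) + 3.0)
    is_large = np.array([large for _, large in catalog])

    meta_rows, del_rows, snv_rows, cov_rows = [], [], [], []
    truth: dict = {
        "deletion_ln_age_slope": b1,
        "cumulative_ln_intercept": {},
        "dels_per_10k_ln_intercept": {},
        "planted": None,
    }
    for region in REGIONS:
        n = config.n_per_region[region]
        c0 = (np.log(config.cumulative_read_pct_mean[region] + 0.01)
              - sigma**2 / 2.0 - np.log(age_gain))
        a0 = np.log(config.dels_per_10k_mean[region]) - np.log(age_gain)
        truth["cumulative_ln_intercept"][region] = float(c0)
        truth["dels_per_10k_ln_intercept"][region] = float(a0)
        lf = config.large_fraction[region]
        w = base_w * np.where(is_large, lf, 1.0 - lf)
        w = w / w.sum()
        cn_slope = config.cn_age_slope[region]
        cn_resid = np.sqrt(max(config.cn_sd[region] ** 2
                               - cn_slope**2 * age_var,
                               (0.3 * config.cn_sd[region]) ** 2))
        for i in range(n):
            sid = f"{region}_{i:03d}"
            age = float(rng.uniform(*config.age_range))
            sex = "F" if rng.random() < 0.5 else "M"
            is_hv = rng.random() < config.hv_fraction[region]
            labels = _HV_LABELS if is_hv else _NONHV_LABELS
            haplogroup = labels[int(rng.integers(len(labels)))]
            benchmark = float(np.round(
                max(2000.0, rng.normal(config.benchmark_mean,
                                       config.benchmark_sd)), 1))

            # --- copy number & coverage -------------------------------------
            cn = max(50.0, config.cn_mean[region]
                     + cn_slope * (age - age_mid)
                     + rng.normal(0.0, cn_resid))
            autosomal = max(10.0, rng.normal(config.autosomal_depth_mean,
                                             config.autosomal_depth_sd))
            cov_rows.append({"sample_id": sid,
                             "mt_mean_depth": round(cn * autosomal / 2.0, 3),
                             "autosomal_mean_depth": round(autosomal, 3)})

            # --- deletions ---------------------------------------------------
            lam = np.exp(a0 + b1 * age) * benchmark / 10_000.0
            n_junc = int(rng.poisson(lam))
            cumulative = max(0.0, np.exp(c0 + b1 * age
                                         + rng.normal(0.0, sigma)) - 0.01)
            total_reads = int(round(cumulative * benchmark / 100.0))
            if total_reads > 0:
                # supporting reads must land on some junction; the detection
                # floor (1 read per junction) caps how many junctions can
                # carry them
                n_junc = max(n_junc, 1)
            n_junc = min(n_junc, len(catalog), total_reads)
            if n_junc > 0:
                idx = rng.choice(len(catalog), size=n_junc, replace=False, p=w)
                extra = rng.multinomial(total_reads - n_junc,
                                        np.full(n_junc, 1.0 / n_junc))
                reads = 1 + extra
                for k, j in enumerate(idx):
                    (bp5, bp3), _ = catalog[j]
                    del_rows.append({
                        "sample_id": sid, "bp5": bp5, "bp3": bp3,
                        "supporting_reads": int(reads[k]),
                        "read_pct": round(reads[k] / benchmark * 100.0, 6),
                        "benchmark_coverage": benchmark,
                    })

            # --- SNVs --------------------------------------------------------
            cat = f"{region}:{'HV' if is_hv else 'NonHV'}"
            k_homo = int(np.clip(round(rng.normal(
                config.homoplasmic_mean[cat], config.homoplasmic_sd[cat])),
                0, len(pool)))
            used_positions: set[int] = set()
            if k_homo > 0:
                chosen = rng.choice(len(pool), size=k_homo, replace=False)
                for j in sorted(chosen):
                    pos, ref, alt = pool[j]
                    used_positions.add(pos)
                    snv_rows.append({"sample_id": sid, "position": pos,
                                     "ref": ref, "alt": alt,
                                     "vaf": round(rng.uniform(0.92, 0.999), 4)})
            lam_het = (config.heteroplasmic_base[region]
                       + config.heteroplasmic_age_slope[region] * age)
            for _ in range(int(rng.poisson(lam_het))):
                pos = int(rng.integers(200, 16500))
                ref = genome.base(pos)
                if ref == "N" or pos in used_positions:
                    continue
                used_positions.add(pos)
                snv_rows.append({"sample_id": sid, "position": pos,
                                 "ref": ref, "alt": _TRANSITION[ref],
                                 "vaf": round(rng.uniform(0.15, 0.85), 4)})

            meta_rows.append({"sample_id": sid, "region": region,
                              "age": round(age, 3), "sex": sex,
                              "haplogroup": haplogroup,
                              "hv_category": hv_category(haplogroup),
                              "benchmark_coverage": benchmark})

    del_cols = ["sample_id", "bp5", "bp3", "supporting_reads", "read_pct",
                "benchmark_coverage"]
    snv_cols = ["sample_id", "position", "ref", "alt", "vaf"]
    return SyntheticCohort(
        metadata=pd.DataFrame(meta_rows),
        deletions=pd.DataFrame(del_rows, columns=del_cols),
        snvs=pd.DataFrame(snv_rows, columns=snv_cols),
        coverage=pd.DataFrame(cov_rows),
        ground_truth=truth,
        config=config,
    )


def plant_association(
    cohort: SyntheticCohort,
    snp: tuple[int, str, str],
    junction: Junction,
    effect_sd: float,
) -> SyntheticCohort:
    """Shift the junction's read percent upward in carriers of the SNP's
    alternate allele by ``effect_sd`` times the cohort-wide SD of that
    junction's read percent (absent calls count as 0).  Everything else is
    left untouched; the operation is deterministic.
    """
    pos, ref, alt = snp
    snvs = cohort.snvs
    carriers = set(
        snvs.loc[(snvs["position"] == pos) & (snvs["alt"] == alt)
                 & (snvs["vaf"] >= 0.9), "sample_id"]
    )
    if not carriers and effect_sd != 0:
        raise ValueError(f"no carriers of {ref}{pos}{alt} in cohort")
    catalog_junctions = {j for j, _ in build_junction_catalog(cohort.config.n_junctions)}
    if junction not in catalog_junctions:
        raise ValueError(f"junction {junction} not in the simulation catalog")
    if effect_sd == 0:
        return replace(cohort, ground_truth={**cohort.ground_truth,
                                             "planted": None})

    dels = cohort.deletions.copy()
    meta = cohort.metadata.set_index("sample_id")
    mask = (dels["bp5"] == junction[0]) & (dels["bp3"] == junction[1])
    pct = pd.Series(0.0, index=meta.index)
    present = dels.loc[mask].set_index("sample_id")["read_pct"]
    pct.loc[present.index] = present.to_numpy()
    sd = float(pct.std(ddof=1))
    if sd == 0:
        raise ValueError(f"junction {junction} has zero read-percent variance")
    delta = effect_sd * sd

    new_rows = []
    for sid in sorted(carriers):
        benchmark = float(meta.loc[sid, "benchmark_coverage"])
        new_pct = pct.loc[sid] + delta
        reads = max(1, int(round(new_pct * benchmark / 100.0)))
        row_mask = mask & (dels["sample_id"] == sid)
        if row_mask.any():
            dels.loc[row_mask, "supporting_reads"] = reads
            dels.loc[row_mask, "read_pct"] = round(reads / benchmark * 100.0, 6)
        else:
            new_rows.append({"sample_id": sid, "bp5": junction[0],
                             "bp3": junction[1], "supporting_reads": reads,
                             "read_pct": round(reads / benchmark * 100.0, 6),
                             "benchmark_coverage": benchmark})
    if new_rows:
        dels = pd.concat([dels, pd.DataFrame(new_rows)], ignore_index=True)
        dels = dels.sort_values(["sample_id", "bp5", "bp3"],
                                kind="stable").reset_index(drop=True)
    truth = {**cohort.ground_truth,
             "planted": {"snp": list(snp), "junction": list(junction),
                         "effect_sd": effect_sd, "delta_read_pct": delta}}
    return replace(cohort, deletions=dels, ground_truth=truth)
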