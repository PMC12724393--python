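"""Mitochondrial genome-wide association between homoplasmic SNPs and
large-deletion abundance (MT-GWAS).

Only SNP:deletion pairs that could plausibly share a mechanism are tested:
(a) the deletion is carried (>= 1 supporting read for the exact junction) by
at least ``min_carriers`` subjects in the region; (b) the SNP's reference
and alternate homoplasmic classes each contain at least ``min_carriers``
subjects; and (c) the SNP lies within ``max_distance`` bp of either deletion
breakpoint.  For every eligible pair a linear model

    SNP presence/absence ~ deletion read % + MT benchmark coverage + age + sex

is fitted within the region, and significance is controlled by the
Bonferroni threshold alpha / n_tests with n_tests counted per region.
Samples without the deletion contribute a read percent of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deletions import DeletionCall, Junction
from .stats import StatsError, bonferroni, ols_fit


class GwasError(ValueError):
    pass


@dataclass(frozen=True)
class GwasPair:
    snp: str                      # "<pos>:<ref>><alt>" genotype-matrix label
    snp_position: int
    junction: Junction
    region: str
    n_snp_carriers: int
    n_deletion_carriers: int
    min_breakpoint_distance: int


@dataclass(frozen=True)
class GwasResult:
    pair: GwasPair
    beta: float
    p: float
    n_tests: int
    threshold: float
    testable: bool

    @property
    def significant(self) -> bool:
        return self.testable and self.p < self.threshold


def _snp_position(label: str) -> int:
    return int(label.split(":")[0])


def eligible_pairs(
    genotypes: pd.DataFrame,
    deletion_calls: Sequence[DeletionCall],
    metadata: pd.DataFrame,
    region: str,
    min_carriers: int = 10,
    max_distance: int = 10,
) -> list[GwasPair]:
    """All and only the SNP:deletion pairs passing the frequency and
    breakpoint-proximity filters for one region.

    ``genotypes`` is the binary homoplasmic matrix (samples x variants);
    ``metadata`` must carry sample_id and region columns.
    """
    region_samples = metadata.loc[metadata["region"] == region, "sample_id"]
    region_samples = [s for s in region_samples if s in genotypes.index]
    if not region_samples:
        raise GwasError(f"no samples for region {region!r}")
    geno = genotypes.loc[region_samples]
    n = len(region_samples)

    carriers_by_junction: dict[Junction, set[str]] = {}
    sample_set = set(region_samples)
    for c in deletion_calls:
        if c.sample_id in sample_set and c.supporting_reads >= 1:
            carriers_by_junction.setdefault(c.junction, set()).add(c.sample_id)

    pairs: list[GwasPair] = []
    for junction, carriers in sorted(carriers_by_junction.items()):
        if len(carriers) < min_carriers:
            continue
        bp5, bp3 = junction
        for label in geno.columns:
            pos = _snp_position(label)
            dist = min(abs(pos - bp5), abs(pos - bp3))
            if dist > max_distance:
                continue
            alt_carriers = int(geno[label].sum())
            if alt_carriers < min_carriers or n - alt_carriers < min_carriers:
                continue
            pairs.append(
                GwasPair(
                    snp=label, snp_position=pos, junction=junction,
                    region=region, n_snp_carriers=alt_carriers,
                    n_deletion_carriers=len(carriers),
                    min_breakpoint_distance=dist,
                )
            )
    return pairs


def run_mtgwas(
    pairs: Sequence[GwasPair],
    genotypes: pd.DataFrame,
    deletion_calls: Sequence[DeletionCall],
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    orientation: str = "snp_response",
) -> list[GwasResult]:
    """One association fit per eligible pair.

    ``covariates`` must carry sample_id, benchmark_coverage, age and sex for
    every sample of the pairs' region.  Pairs whose SNP response is constant
    in the region are reported untestable but still count toward n_tests.

    ``orientation``: "snp_response" fits the binary SNP on deletion read %
    (the reported scan's orientation); "deletion_response" fits the reverse
    model (read % on the SNP) for sensitivity analysis.
    """
    if orientation not in ("snp_response", "deletion_response"):
        raise GwasError(f"unknown orientation {orientation!r}")
    if not pairs:
        return []
    regions = {p.region for p in pairs}
    if len(regions) > 1:
        raise GwasError("pairs from several regions; run per region")

    read_pct: dict[tuple[str, Junction], float] = {}
    for c in deletion_calls:
        key = (c.sample_id, c.junction)
        read_pct[key] = read_pct.get(key, 0.0) + c.read_pct

    cov = covariates.set_index("sample_id")
    n_tests = len(pairs)
    threshold = bonferroni(alpha, n_tests)
    results: list[GwasResult] = []
    for pair in pairs:
        samples = [s for s in genotypes.index if s in cov.index]
        y = genotypes.loc[samples, pair.snp].to_numpy(dtype=float)
        data = pd.DataFrame(
            {
                "snp": y,
                "read_pct": [read_pct.get((s, pair.junction), 0.0) for s in samples],
                "benchmark_coverage": cov.loc[samples, "benchmark_coverage"].to_numpy(),
                "age": cov.loc[samples, "age"].to_numpy(),
                "sex": cov.loc[samples, "sex"].to_numpy(),
            }
        )
        response, predictor = (("snp", "read_pct")
                               if orientation == "snp_response"
                               else ("read_pct", "snp"))
        if data[response].nunique() < 2:
            results.append(GwasResult(pair, float("nan"), float("nan"),
                                      n_tests, threshold, testable=False))
            continue
        # covariates constant within the region carry no information and
        # would make the design rank-deficient
        terms = [predictor] + [
            t for t in ("benchmark_coverage", "age", "sex")
            if data[t].nunique() > 1
        ]
        try:
            fit = ols_fit(data, response, terms)
        except StatsError:
            results.append(GwasResult(pair, float("nan"), float("nan"),
                                      n_tests, threshold, testable=False))
            continue
        results.append(
            GwasResult(pair, fit.coefficients[predictor],
                       fit.p_values[predictor], n_tests, threshold,
                       testable=True)
        )
    return results


def results_table(results: Sequence[GwasResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "region": r.pair.region, "snp": r.pair.snp,
                "bp5": r.pair.junction[0], "bp3": r.pair.junction[1],
                "n_snp_carriers": r.pair.n_snp_carriers,
                "n_deletion_carriers": r.pair.n_deletion_carriers,
                "min_breakpoint_distance": r.pair.min_breakpoint_distance,
                "beta": r.beta, "p": r.p, "n_tests": r.n_tests,
                "threshold": r.threshold, "testable": r.testable,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def gwas_report(
    results: Sequence[GwasResult],
    repeat_deltas: Mapping[tuple[str, Junction], tuple[int, int]],
) -> pd.DataFrame:
    """Join association direction with repeat-length direction.

    ``repeat_deltas`` maps (snp label, junction) to (ref, alt) repeat lengths.
    A significant association is mechanistically consistent when the allele
    that lengthens the repeat is the allele with more deletion: beta > 0 with
    a lengthening alternate allele, or beta < 0 with a shortening one.
    """
    rows = []
    for r in results:
        key = (r.pair.snp, r.pair.junction)
        if key not in repeat_deltas:
            if r.significant:
                raise GwasError(f"missing repeat assessment for significant {key}")
            ref_len = alt_len = None
            consistent = None
        else:
            ref_len, alt_len = repeat_deltas[key]
            if alt_len == ref_len or not np.isfinite(r.beta):
                consistent = None
            else:
                consistent = (r.beta > 0) == (alt_len > ref_len)
        rows.append(
            {
                "region": r.pair.region, "snp": r.pair.snp,
                "bp5": r.pair.junction[0], "bp3": r.pair.junction[1],
                "beta": r.beta, "p": r.p, "threshold": r.threshold,
                "significant": r.significant,
                "ref_repeat_bp": ref_len, "alt_repeat_bp": alt_len,
                "consistent_with_repeat_mechanism": consistent,
            }
        )
    return pd.DataFrame(rows)
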