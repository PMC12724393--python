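"""Large mtDNA deletion tables, burden metrics and impact annotation.

Input is a per-sample breakpoint table in the style a junction caller writes
for WGS data: one row per deletion junction with the last retained 5' base
(``bp5``), the first retained 3' base (``bp3``), the number of supporting
reads, the deletion read percent (supporting reads normalised to the MT
benchmark coverage x 100) and the benchmark coverage itself (mean depth over
two 250-bp segments in MT-RNR1 and MT-CYB).

Conventions: the deleted span is ``[bp5+1, bp3-1]`` and the deletion size is
``bp3 - bp5 - 1``, which makes the canonical "common deletion" junction
(8471, 13449) the familiar 4,977-bp event.  Junctions wrapping the origin of
numbering (bp3 <= bp5) are accepted but flagged, and sized circularly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import FeatureCatalog, FeatureOverlap, features_in_span

Junction = tuple[int, int]

COMMON_DELETION: Junction = (8471, 13449)
SIZE_CUTOFF_BP = 1000

_COLUMN_ALIASES = {
    "sample_id": {"sample_id", "sample", "id", "sampleid"},
    "bp5": {"bp5", "5' break", "5_break", "break5", "5p", "five_prime"},
    "bp3": {"bp3", "3' break", "3_break", "break3", "3p", "three_prime"},
    "supporting_reads": {"supporting_reads", "reads", "deletion_reads"},
    "read_pct": {"read_pct", "deletion_read_%", "deletion read %", "read_percent"},
    "benchmark_coverage": {"benchmark_coverage", "benchmark", "mt_benchmark_coverage"},
}


class DeletionTableError(ValueError):
    pass


@dataclass(frozen=True)
class DeletionCall:
    """One deletion junction observed in one sample."""

    sample_id: str
    bp5: int
    bp3: int
    supporting_reads: int
    read_pct: float
    benchmark_coverage: float

    def __post_init__(self) -> None:
        if self.read_pct < 0:
            raise DeletionTableError("read_pct must be >= 0")
        if self.benchmark_coverage <= 0:
            raise DeletionTableError("benchmark_coverage must be > 0")
        if self.supporting_reads < 0:
            raise DeletionTableError("supporting_reads must be >= 0")
        if not self.wraps_origin and self.bp3 <= self.bp5 + 1:
            raise DeletionTableError("bp3 must exceed bp5 + 1 (>=1 base deleted)")

    @property
    def junction(self) -> Junction:
        return (self.bp5, self.bp3)

    @property
    def wraps_origin(self) -> bool:
        return self.bp3 <= self.bp5


def deletion_size(call: DeletionCall, genome_length: int = 16569) -> int:
    """Bases removed by the deletion (breakpoints are retained bases)."""
    if call.wraps_origin:
        return genome_length - (call.bp5 - call.bp3) - 1
    return call.bp3 - call.bp5 - 1


def deleted_span(call: DeletionCall, genome_length: int = 16569) -> Junction:
    """1-based inclusive deleted span [bp5+1, bp3-1], wrap-aware."""
    start = call.bp5 + 1 if call.bp5 < genome_length else 1
    end = call.bp3 - 1 if call.bp3 > 1 else genome_length
    return (start, end)


def read_deletion_table(
    tsv_source, on_invalid: str = "skip"
) -> list[DeletionCall]:
    """Parse a tab-delimited deletion table into validated calls.

    ``on_invalid``: "skip" drops invalid rows with a row-numbered warning,
    "raise" aborts on the first invalid row.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str)
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace("%", "_%")
        for canon, aliases in _COLUMN_ALIASES.items():
            if key in aliases or col.strip().lower() in aliases:
                rename[col] = canon
    df = df.rename(columns=rename)
    missing = set(_COLUMN_ALIASES) - set(df.columns)
    if missing:
        raise DeletionTableError(f"missing columns: {sorted(missing)}")

    calls: list[DeletionCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            call = DeletionCall(
                sample_id=str(row.sample_id),
                bp5=int(row.bp5),
                bp3=int(row.bp3),
                supporting_reads=int(float(row.supporting_reads)),
                read_pct=float(row.read_pct),
                benchmark_coverage=float(row.benchmark_coverage),
            )
        except (ValueError, TypeError) as exc:
            if on_invalid == "raise":
                raise DeletionTableError(f"row {i}: {exc}") from exc
            warnings.warn(f"row {i} rejected: {exc}", stacklevel=2)
            continue
        if call.wraps_origin:
            warnings.warn(f"row {i}: junction {call.junction} wraps the origin",
                          stacklevel=2)
        calls.append(call)
    return calls


def write_deletion_table(calls: Iterable[DeletionCall], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id, "bp5": c.bp5, "bp3": c.bp3,
                "supporting_reads": c.supporting_reads,
                "read_pct": c.read_pct,
                "benchmark_coverage": c.benchmark_coverage,
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# impact annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpactAnnotation:
    """Predicted functional impact of one deletion."""

    genes: tuple[tuple[str, str], ...]        # (gene name, removed|truncated)
    complexes: frozenset[str]                 # subset of {I, III, IV, V}
    tRNAs: tuple[str, ...]
    MDPs: tuple[str, ...]
    removes_OL: bool

    def to_dict(self) -> dict:
        return {
            "genes": [list(g) for g in self.genes],
            "complexes": sorted(self.complexes),
            "tRNAs": list(self.tRNAs),
            "MDPs": list(self.MDPs),
            "removes_OL": self.removes_OL,
        }


def annotate_impact(call: DeletionCall, catalog: FeatureCatalog) -> ImpactAnnotation:
    """Features overlapping the deleted span; a deletion that removes or
    truncates any gene of a complex is classed as impacting that complex."""
    start, end = deleted_span(call, catalog.genome_length)
    hits = features_in_span(catalog, start, end)
    genes = tuple(
        (h.feature.name, h.impact) for h in hits if h.feature.category == "protein"
    )
    complexes = frozenset(
        h.feature.complex_id for h in hits if h.feature.category == "protein"
    )
    trnas = tuple(h.feature.name for h in hits if h.feature.category == "tRNA")
    mdps = tuple(h.feature.name for h in hits if h.feature.category == "MDP")
    removes_ol = any(h.feature.name == "OL" for h in hits)
    return ImpactAnnotation(genes, complexes, trnas, mdps, removes_ol)


def impact_long_table(
    calls: Iterable[DeletionCall], catalog: FeatureCatalog
) -> pd.DataFrame:
    """Long-format (sample, junction, feature, impact) annotation table."""
    rows = []
    for c in calls:
        start, end = deleted_span(c, catalog.genome_length)
        for h in features_in_span(catalog, start, end):
            rows.append(
                {
                    "sample_id": c.sample_id, "bp5": c.bp5, "bp3": c.bp3,
                    "feature": h.feature.name, "category": h.feature.category,
                    "impact": h.impact,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "bp5", "bp3", "feature",
                                       "category", "impact"])


# ---------------------------------------------------------------------------
# per-sample burden metrics
# ---------------------------------------------------------------------------

def default_top30_catalog() -> frozenset[Junction]:
    """Junctions counted in the "Top 30" metric.

    Only the common deletion is universally published with exact breakpoints;
    the packaged default therefore contains that single junction, and studies
    with a fuller validated catalog supply it via ``load_top30_catalog``.
    """
    return frozenset({COMMON_DELETION})


def load_top30_catalog(path) -> frozenset[Junction]:
    """Load a junction catalog from JSON: {"junctions": [[bp5, bp3], ...]}."""
    data = json.loads(Path(path).read_text())
    return frozenset((int(a), int(b)) for a, b in data["junctions"])


@dataclass(frozen=True)
class SampleDeletionMetrics:
    sample_id: str
    benchmark_coverage: float
    n_unique_deletions: int
    deletions_per_10k: float
    cumulative_read_pct: float
    read_pct_lt1000: float
    read_pct_ge1000: float
    top30_read_pct: float
    common_del_read_pct: float
    complex_read_pct: Mapping[str, float] = field(default_factory=dict)
    trna_read_pct: Mapping[str, float] = field(default_factory=dict)
    mdp_read_pct: Mapping[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "benchmark_coverage": self.benchmark_coverage,
            "n_unique_deletions": self.n_unique_deletions,
            "deletions_per_10k": self.deletions_per_10k,
            "cumulative_read_pct": self.cumulative_read_pct,
            "read_pct_lt1000": self.read_pct_lt1000,
            "read_pct_ge1000": self.read_pct_ge1000,
            "top30_read_pct": self.top30_read_pct,
            "common_del_read_pct": self.common_del_read_pct,
        }
        for cx, v in self.complex_read_pct.items():
            row[f"complex_{cx}_read_pct"] = v
        for t, v in self.trna_read_pct.items():
            row[f"trna_{t}_read_pct"] = v
        for m, v in self.mdp_read_pct.items():
            row[f"mdp_{m}_read_pct"] = v
        return row


def sample_metrics(
    calls: Sequence[DeletionCall],
    catalog: FeatureCatalog,
    top30_catalog: frozenset[Junction] | None = None,
    sample_id: str | None = None,
    benchmark_coverage: float | None = None,
    min_reads: int = 0,
) -> SampleDeletionMetrics:
    """Normalised deletion burden metrics for one sample.

    All calls must share one sample id and one benchmark coverage.  For an
    empty call list, ``sample_id`` and ``benchmark_coverage`` must be given.
    ``min_reads`` optionally drops junctions below a supporting-read floor
    before counting (no floor by default).
    """
    top30 = default_top30_catalog() if top30_catalog is None else top30_catalog
    calls = [c for c in calls if c.supporting_reads >= min_reads]
    if calls:
        sids = {c.sample_id for c in calls}
        if len(sids) > 1:
            raise DeletionTableError(f"calls from several samples: {sorted(sids)}")
        benchmarks = {c.benchmark_coverage for c in calls}
        if len(benchmarks) > 1:
            raise DeletionTableError(
                f"inconsistent benchmark coverage within sample: {sorted(benchmarks)}"
            )
        sample_id = calls[0].sample_id
        benchmark_coverage = calls[0].benchmark_coverage
    if sample_id is None or benchmark_coverage is None:
        raise DeletionTableError(
            "sample_id and benchmark_coverage required when there are no calls"
        )

    # deduplicate junctions (summing read support of duplicate rows)
    by_junction: dict[Junction, float] = {}
    for c in calls:
        by_junction[c.junction] = by_junction.get(c.junction, 0.0) + c.read_pct

    n_unique = len(by_junction)
    per10k = n_unique / benchmark_coverage * 10_000
    cumulative = sum(by_junction.values())
    lt1000 = ge1000 = 0.0
    complexes: dict[str, float] = {cx: 0.0 for cx in ("I", "III", "IV", "V")}
    trnas: dict[str, float] = {}
    mdps: dict[str, float] = {}
    top30_pct = 0.0
    common_pct = by_junction.get(COMMON_DELETION, 0.0)
    for (bp5, bp3), pct in by_junction.items():
        call = DeletionCall(sample_id, bp5, bp3, 0, pct, benchmark_coverage)
        if deletion_size(call, catalog.genome_length) >= SIZE_CUTOFF_BP:
            ge1000 += pct
        else:
            lt1000 += pct
        if (bp5, bp3) in top30:
            top30_pct += pct
        ann = annotate_impact(call, catalog)
        for cx in ann.complexes:
            complexes[cx] += pct
        for t in ann.tRNAs:
            trnas[t] = trnas.get(t, 0.0) + pct
        for m in ann.MDPs:
            mdps[m] = mdps.get(m, 0.0) + pct

    return SampleDeletionMetrics(
        sample_id=sample_id,
        benchmark_coverage=benchmark_coverage,
        n_unique_deletions=n_unique,
        deletions_per_10k=per10k,
        cumulative_read_pct=cumulative,
        read_pct_lt1000=lt1000,
        read_pct_ge1000=ge1000,
        top30_read_pct=top30_pct,
        common_del_read_pct=common_pct,
        complex_read_pct=complexes,
        trna_read_pct=trnas,
        mdp_read_pct=mdps,
    )


def metrics_table(
    calls: Iterable[DeletionCall],
    catalog: FeatureCatalog,
    top30_catalog: frozenset[Junction] | None = None,
    all_samples: Iterable[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-sample metric rows for a cohort of calls.

    ``all_samples`` optionally lists (sample_id, benchmark_coverage) pairs so
    samples without any detected deletion still contribute all-zero rows.
    """
    groups: dict[str, list[DeletionCall]] = {}
    for c in calls:
        groups.setdefault(c.sample_id, []).append(c)
    rows = []
    seen = set()
    for sid, group in groups.items():
        rows.append(sample_metrics(group, catalog, top30_catalog).to_row())
        seen.add(sid)
    if all_samples is not None:
        for sid, benchmark in all_samples:
            if sid not in seen:
                rows.append(
                    sample_metrics([], catalog, top30_catalog,
                                   sample_id=sid,
                                   benchmark_coverage=benchmark).to_row()
                )
    return pd.DataFrame(rows).fillna(0.0)


METRIC_COLUMNS = [
    "deletions_per_10k", "cumulative_read_pct", "read_pct_lt1000",
    "read_pct_ge1000", "top30_read_pct", "common_del_read_pct",
]


def cohort_summary(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    metric_columns: Sequence[str] | None = None,
    regions: tuple[str, str] = ("FC", "CER"),
) -> pd.DataFrame:
    """Per-region mean and SD of each metric plus the FC/CER fold change.

    ``metadata`` must map sample_id to a ``region`` column covering every
    sample in ``metrics``.
    """
    cols = list(metric_columns) if metric_columns else [
        c for c in METRIC_COLUMNS if c in metrics.columns
    ]
    merged = metrics.merge(metadata[["sample_id", "region"]], on="sample_id",
                           how="left")
    if merged["region"].isna().any():
        missing = merged.loc[merged["region"].isna(), "sample_id"].tolist()
        raise DeletionTableError(f"samples without region metadata: {missing[:5]}")
    rows = []
    num, den = regions
    for col in cols:
        by = merged.groupby("region")[col]
        means, sds, ns = by.mean(), by.std(ddof=1), by.count()
        for region in means.index:
            if ns[region] == 0:
                raise DeletionTableError(f"region {region} has no samples")
        fold = np.nan
        if num in means.index and den in means.index and means[den] != 0:
            fold = means[num] / means[den]
        row = {"metric": col, f"fold_{num}_over_{den}": fold}
        for region in means.index:
            row[f"mean_{region}"] = means[region]
            row[f"sd_{region}"] = sds[region]
            row[f"n_{region}"] = int(ns[region])
        rows.append(row)
    return pd.DataFrame(rows)
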