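"""Mitochondrial SNVs, heteroplasmy classes, haplogroup strata and copy number.

A variant caller reports, per sample, each position where an alternate
allele is present along with its variant allele frequency (VAF, the fraction
of reads carrying the alternate allele).  Because mtDNA is polyploid within
a cell, variants are classed by VAF: homoplasmic when VAF >= 0.9 (effectively
all molecules carry the allele, typically an inherited haplogroup marker),
heteroplasmic when 0.1 < VAF < 0.9 (a mixed, usually somatic state), and
excluded below that (indistinguishable from noise).

mtDNA copy number per diploid cell is estimated from WGS coverage as
``2 x mean MT depth / mean autosomal depth``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

HOMOPLASMY_MIN_VAF = 0.9
HETEROPLASMY_MIN_VAF = 0.1

PloidyClass = Literal["homoplasmic", "heteroplasmic", "excluded"]
HvCategory = Literal["HV", "NonHV"]

_SNV_ALIASES = {
    "sample_id": {"sample_id", "sample", "id"},
    "position": {"position", "pos"},
    "ref": {"ref", "reference"},
    "alt": {"alt", "variant"},
    "vaf": {"vaf", "variantlevel", "variant_level", "af"},
}


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class SnvCall:
    sample_id: str
    position: int
    ref: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise VariantError(f"VAF {self.vaf} outside [0, 1]")
        if self.ref == self.alt:
            raise VariantError("ref and alt are identical")


@dataclass(frozen=True)
class CoverageSummary:
    sample_id: str
    mt_mean_depth: float
    autosomal_mean_depth: float

    def __post_init__(self) -> None:
        if self.mt_mean_depth < 0 or self.autosomal_mean_depth < 0:
            raise VariantError("depths must be >= 0")


@dataclass(frozen=True)
class SampleVariantProfile:
    sample_id: str
    homoplasmic_count: int
    heteroplasmic_count: int
    haplogroup_label: str
    hv_category: HvCategory


def classify_snv(vaf: float) -> PloidyClass:
    """Partition a VAF into homoplasmic / heteroplasmic / excluded.

    Boundaries follow the standard thresholds: >= 0.9 homoplasmic (inclusive),
    (0.1, 0.9) heteroplasmic, <= 0.1 excluded.
    """
    if not 0.0 <= vaf <= 1.0:
        raise VariantError(f"VAF {vaf} outside [0, 1]")
    if vaf >= HOMOPLASMY_MIN_VAF:
        return "homoplasmic"
    if vaf > HETEROPLASMY_MIN_VAF:
        return "heteroplasmic"
    return "excluded"


def hv_category(haplogroup_label: str) -> HvCategory:
    """HV when the top-level haplogroup letter is H or V (incl. HV* precursors).

    Classification is purely label-prefix based: K, J, T, U stay NonHV
    regardless of phylogenetic descent from R.
    """
    label = haplogroup_label.strip().upper()
    if not label:
        raise VariantError("empty haplogroup label")
    if label.startswith(("H", "V")):
        return "HV"
    return "NonHV"


def variant_profile(
    snv_calls: Sequence[SnvCall], haplogroup_label: str,
    sample_id: str | None = None,
) -> SampleVariantProfile:
    """Counts of homoplasmic / heteroplasmic variants for one sample.

    Distinct (position, alt) pairs are counted; excluded-class calls are not.
    """
    if snv_calls:
        sids = {c.sample_id for c in snv_calls}
        if len(sids) > 1:
            raise VariantError(f"calls from several samples: {sorted(sids)}")
        sample_id = snv_calls[0].sample_id
    homo = {(c.position, c.alt) for c in snv_calls
            if classify_snv(c.vaf) == "homoplasmic"}
    hetero = {(c.position, c.alt) for c in snv_calls
              if classify_snv(c.vaf) == "heteroplasmic"}
    return SampleVariantProfile(
        sample_id=sample_id or "",
        homoplasmic_count=len(homo),
        heteroplasmic_count=len(hetero),
        haplogroup_label=haplogroup_label,
        hv_category=hv_category(haplogroup_label),
    )


def genotype_matrix(
    snv_calls: Iterable[SnvCall], samples: Sequence[str]
) -> pd.DataFrame:
    """Binary sample x variant matrix: 1 iff a homoplasmic call (VAF >= 0.9)
    exists for (sample, position, alt); anything else is 0.

    Columns are labelled ``"<position>:<ref>><alt>"``.  Conflicting duplicate
    calls (same sample/position/alt, VAFs on both sides of the homoplasmy
    threshold) raise.
    """
    rows = [
        (c.sample_id, c.position, c.ref, c.alt,
         1 if classify_snv(c.vaf) == "homoplasmic" else 0)
        for c in snv_calls
    ]
    index = pd.Index(samples, name="sample_id")
    if not rows:
        return pd.DataFrame(index=index, dtype=int)
    df = pd.DataFrame(rows, columns=["sample_id", "position", "ref", "alt", "val"])
    n_states = df.groupby(["sample_id", "position", "alt"])["val"].nunique()
    if (n_states > 1).any():
        key = n_states[n_states > 1].index[0]
        raise VariantError(f"conflicting duplicate calls for {key}")
    df["label"] = (df["position"].astype(str) + ":" + df["ref"] + ">" + df["alt"])
    order = (df[["position", "ref", "alt", "label"]]
             .drop_duplicates()
             .sort_values(["position", "ref", "alt"])["label"].tolist())
    pivot = df.pivot_table(index="sample_id", columns="label", values="val",
                           aggfunc="max")
    return pivot.reindex(index=index, columns=order).fillna(0).astype(int)


def mtdna_copy_number(coverage: CoverageSummary) -> float:
    """Copies of mtDNA per diploid cell: 2 x MT depth / autosomal depth."""
    if coverage.autosomal_mean_depth <= 0:
        raise VariantError("autosomal depth must be > 0 for copy number")
    return 2.0 * coverage.mt_mean_depth / coverage.autosomal_mean_depth


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_snv_table(tsv_source) -> list[SnvCall]:
    """Read a variant-caller style TSV (ID/sample, Pos, Ref, Variant,
    VariantLevel column names are accepted, case-insensitively)."""
    df = pd.read_csv(tsv_source, sep="\t", dtype=str)
    rename = {}
    for col in df.columns:
        for canon, aliases in _SNV_ALIASES.items():
            if col.strip().lower() in aliases:
                rename[col] = canon
    df = df.rename(columns=rename)
    missing = set(_SNV_ALIASES) - set(df.columns)
    if missing:
        raise VariantError(f"missing columns: {sorted(missing)}")
    return [
        SnvCall(
            sample_id=str(r.sample_id), position=int(r.position),
            ref=str(r.ref).upper(), alt=str(r.alt).upper(), vaf=float(r.vaf),
        )
        for r in df.itertuples(index=False)
    ]


def write_snv_table(calls: Iterable[SnvCall], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": c.sample_id, "position": c.position, "ref": c.ref,
             "alt": c.alt, "vaf": c.vaf}
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_vcf(vcf_source, sample_id: str | None = None) -> list[SnvCall]:
    """Minimal single-sample VCF ingestion (AF from INFO or FORMAT)."""
    import pysam

    calls: list[SnvCall] = []
    with pysam.VariantFile(str(vcf_source)) as vcf:
        vcf_samples = list(vcf.header.samples)
        sid = sample_id or (vcf_samples[0] if vcf_samples else "sample")
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # substitutions only
                af = None
                if "AF" in rec.info:
                    info_af = rec.info["AF"]
                    af = info_af[0] if isinstance(info_af, tuple) else info_af
                elif vcf_samples and "AF" in rec.samples[vcf_samples[0]]:
                    fmt_af = rec.samples[vcf_samples[0]]["AF"]
                    af = fmt_af[0] if isinstance(fmt_af, tuple) else fmt_af
                if af is None:
                    continue
                calls.append(
                    SnvCall(sample_id=sid, position=rec.pos, ref=rec.ref,
                            alt=alt, vaf=float(af))
                )
    return calls


def read_coverage_table(tsv_source) -> list[CoverageSummary]:
    df = pd.read_csv(tsv_source, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return [
        CoverageSummary(
            sample_id=str(r.sample_id),
            mt_mean_depth=float(r.mt_mean_depth),
            autosomal_mean_depth=float(r.autosomal_mean_depth),
        )
        for r in df.itertuples(index=False)
    ]


def copy_number_table(coverage: Iterable[CoverageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample_id": c.sample_id, "mt_mean_depth": c.mt_mean_depth,
             "autosomal_mean_depth": c.autosomal_mean_depth,
             "mtdna_copy_number": mtdna_copy_number(c)}
            for c in coverage
        ]
    )
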