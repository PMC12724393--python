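"""Mitochondrial reference genome and feature catalog.

The human mitochondrial genome is a 16,569-bp circular molecule carrying 13
protein-coding genes (subunits of respiratory-chain Complexes I, III, IV and
V), 22 tRNAs, 2 rRNAs, the replication origins of the heavy and light strands,
and a set of small open reading frames encoding mitochondrial-derived
microproteins (MDPs) such as humanin, MOTS-c and SHMOOSE.  All coordinates in
this package are 1-based inclusive positions on the revised Cambridge
Reference Sequence (rCRS, NC_012920.1), the universal numbering system for
human mtDNA.  Circularity is handled by allowing "wrapping" spans whose start
exceeds their end (the control region, for example, runs 16024..576).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
SUBSTITUTION_BASES = frozenset("ACGT")

Category = Literal["protein", "tRNA", "rRNA", "origin", "MDP", "control_region"]
ComplexId = Literal["I", "III", "IV", "V"]
Arc = Literal["major", "minor"]


class ReferenceError(ValueError):
    """Raised for malformed reference input (multi-record FASTA, bad alphabet)."""


@dataclass(frozen=True)
class MitoGenome:
    """A (circular) mitochondrial reference sequence.

    ``sequence`` is stored uppercased; ``length`` always equals
    ``len(sequence)``.  Positions handed to :meth:`base` are 1-based.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        illegal = set(self.sequence) - VALID_BASES
        if illegal:
            raise ReferenceError(
                f"sequence contains non-nucleotide characters: {sorted(illegal)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ReferenceError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive span [start, end]; wraps if start > end."""
        if not (1 <= start <= self.length and 1 <= end <= self.length):
            raise ReferenceError(f"span {start}-{end} outside 1..{self.length}")
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ReferenceError("wrapping span on a non-circular genome")
        return self.sequence[start - 1 :] + self.sequence[:end]


def load_genome(fasta_source: str | Path, circular: bool = True) -> MitoGenome:
    """Load a single-record FASTA as a :class:`MitoGenome`.

    Raises :class:`ReferenceError` if the file holds more than one record or
    the sequence contains characters outside A/C/G/T/N.
    """
    records = list(SeqIO.parse(str(fasta_source), "fasta"))
    if not records:
        raise ReferenceError(f"no FASTA records in {fasta_source}")
    if len(records) > 1:
        raise ReferenceError(
            f"ambiguous reference: {len(records)} records in {fasta_source}"
        )
    rec = records[0]
    return MitoGenome(name=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def rcrs_genome() -> MitoGenome:
    """The vendored rCRS (NC_012920.1) reference."""
    with resources.as_file(
        resources.files("mtaging.data").joinpath("rCRS.fasta")
    ) as path:
        return load_genome(path)


def substitute_allele(genome: MitoGenome, position: int, base: str) -> MitoGenome:
    """Return a copy of ``genome`` differing only at ``position`` (1-based)."""
    if base not in SUBSTITUTION_BASES:
        raise ReferenceError(f"invalid substitution base {base!r}")
    if not 1 <= position <= genome.length:
        raise ReferenceError(f"position {position} outside 1..{genome.length}")
    seq = genome.sequence
    return replace(genome, sequence=seq[: position - 1] + base + seq[position:])


# ---------------------------------------------------------------------------
# feature catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeFeature:
    name: str
    category: Category
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    complex_id: ComplexId | None = None
    arc: Arc = "major"

    @property
    def length(self) -> int:
        # wrapping features are only created by the catalog with a known genome
        # length; callers needing the wrapped length use FeatureCatalog.
        if self.start <= self.end:
            return self.end - self.start + 1
        raise ValueError("length of a wrapping feature depends on genome length")

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """Linear 1-based intervals covering the feature on the circle."""
        if self.start <= self.end:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (1, self.end)]

    def span_length(self, genome_length: int) -> int:
        return sum(e - s + 1 for s, e in self.intervals(genome_length))


@dataclass(frozen=True)
class FeatureOverlap:
    feature: GenomeFeature
    impact: Literal["removed", "truncated"]
    overlap_bp: int


# Standard rCRS gene coordinates.  The light-strand replication origin (OL)
# and the OH-containing control region bound the short ("minor") arc of the
# circle; everything on the long path between OL and the control region is
# the "major" arc, which harbours most large deletions.
_PROTEINS: list[tuple[str, int, int, ComplexId]] = [
    ("MT-ND1", 3307, 4262, "I"),
    ("MT-ND2", 4470, 5511, "I"),
    ("MT-CO1", 5904, 7445, "IV"),
    ("MT-CO2", 7586, 8269, "IV"),
    ("MT-ATP8", 8366, 8572, "V"),
    ("MT-ATP6", 8527, 9207, "V"),
    ("MT-CO3", 9207, 9990, "IV"),
    ("MT-ND3", 10059, 10404, "I"),
    ("MT-ND4L", 10470, 10766, "I"),
    ("MT-ND4", 10760, 12137, "I"),
    ("MT-ND5", 12337, 14148, "I"),
    ("MT-ND6", 14149, 14673, "I"),
    ("MT-CYB", 14747, 15887, "III"),
]

_TRNAS: list[tuple[str, int, int]] = [
    ("MT-TF", 577, 647), ("MT-TV", 1602, 1670), ("MT-TL1", 3230, 3304),
    ("MT-TI", 4263, 4331), ("MT-TQ", 4329, 4400), ("MT-TM", 4402, 4469),
    ("MT-TW", 5512, 5579), ("MT-TA", 5587, 5655), ("MT-TN", 5657, 5729),
    ("MT-TC", 5761, 5826), ("MT-TY", 5826, 5891), ("MT-TS1", 7446, 7514),
    ("MT-TD", 7518, 7585), ("MT-TK", 8295, 8364), ("MT-TG", 9991, 10058),
    ("MT-TR", 10405, 10469), ("MT-TH", 12138, 12206), ("MT-TS2", 12207, 12265),
    ("MT-TL2", 12266, 12336), ("MT-TE", 14674, 14742), ("MT-TT", 15888, 15953),
    ("MT-TP", 15956, 16023),
]

_RRNAS = [("MT-RNR1", 648, 1601), ("MT-RNR2", 1671, 3229)]

# Microprotein ORFs.  mtALTND4, SHMOOSE and gau coordinates are as reported in
# the microprotein literature; humanin, MOTS-c and the SHLP family lie inside
# the two rRNA genes between positions 1343 and 3052 (MOTS-c in MT-RNR1, the
# others in MT-RNR2).
_MDPS: list[tuple[str, int, int]] = [
    ("MOTS-c", 1343, 1393),
    ("humanin", 1634, 1708),
    ("SHLP2", 1771, 1851),
    ("SHLP3", 1821, 1937),
    ("SHLP5", 2086, 2160),
    ("SHLP4", 2442, 2522),
    ("SHLP1", 2485, 2559),
    ("SHLP6", 2990, 3052),
    ("gau", 6288, 6590),
    ("mtALTND4", 11557, 11856),
    ("SHMOOSE", 12234, 12410),
]

_ORIGINS = [("OH", 110, 441), ("OL", 5721, 5798)]
_CONTROL_REGION = ("CR", 16024, 576)  # wraps the origin of numbering

# minor arc: between the OH-bearing control region and OL (inclusive of OL)
_MINOR_ARC = (442, 5798)


@dataclass(frozen=True)
class FeatureCatalog:
    """The annotated rCRS feature map all impact queries run against."""

    features: tuple[GenomeFeature, ...]
    genome_length: int

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ReferenceError("duplicate feature names in catalog")
        for f in self.features:
            if not (1 <= f.start <= self.genome_length
                    and 1 <= f.end <= self.genome_length):
                raise ReferenceError(f"{f.name}: coordinates outside genome")
            if f.start > f.end and f.category != "control_region":
                raise ReferenceError(f"{f.name}: only control_region may wrap")
            if (f.complex_id is not None) != (f.category == "protein"):
                raise ReferenceError(f"{f.name}: complex set iff protein")

    def by_name(self, name: str) -> GenomeFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def of_category(self, category: Category) -> list[GenomeFeature]:
        return [f for f in self.features if f.category == category]

    def complex_members(self, complex_id: ComplexId) -> list[GenomeFeature]:
        if complex_id not in ("I", "III", "IV", "V"):
            raise ReferenceError(f"unknown complex {complex_id!r}")
        return [f for f in self.features if f.complex_id == complex_id]


def _arc_of(start: int, end: int) -> Arc:
    lo, hi = _MINOR_ARC
    return "minor" if (start >= lo and end <= hi and start <= end) else "major"


def default_catalog(genome_length: int = 16569) -> FeatureCatalog:
    """The hard-coded rCRS catalog: 13 proteins, 22 tRNAs, 2 rRNAs, 11 MDPs,
    the two replication origins and the control region."""
    feats: list[GenomeFeature] = []
    for name, s, e, cx in _PROTEINS:
        feats.append(GenomeFeature(name, "protein", s, e, cx, _arc_of(s, e)))
    for name, s, e in _TRNAS:
        feats.append(GenomeFeature(name, "tRNA", s, e, None, _arc_of(s, e)))
    for name, s, e in _RRNAS:
        feats.append(GenomeFeature(name, "rRNA", s, e, None, _arc_of(s, e)))
    for name, s, e in _MDPS:
        feats.append(GenomeFeature(name, "MDP", s, e, None, _arc_of(s, e)))
    for name, s, e in _ORIGINS:
        feats.append(GenomeFeature(name, "origin", s, e, None, _arc_of(s, e)))
    name, s, e = _CONTROL_REGION
    feats.append(GenomeFeature(name, "control_region", s, e, None, "major"))
    return FeatureCatalog(tuple(feats), genome_length)


def complex_length(catalog: FeatureCatalog, complex_id: ComplexId) -> int:
    """Total bp of the protein genes of one respiratory-chain complex.

    With the standard rCRS coordinates this gives 6356 (I), 1141 (III),
    3010 (IV) and 888 (V).
    """
    members = catalog.complex_members(complex_id)
    if not members:
        raise ReferenceError(f"unknown complex {complex_id!r}")
    return sum(f.end - f.start + 1 for f in members)


def _span_intervals(start: int, end: int, genome_length: int) -> list[tuple[int, int]]:
    if start <= end:
        return [(start, end)]
    return [(start, genome_length), (1, end)]


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def features_in_span(
    catalog: FeatureCatalog,
    span_start: int | None,
    span_end: int | None,
    categories: Iterable[Category] | None = None,
) -> list[FeatureOverlap]:
    """All catalog features sharing at least one base with the (circular) span.

    A span with ``span_start > span_end`` wraps the origin of numbering.
    Passing ``None`` for either bound denotes the empty span.  Each hit is
    tagged ``removed`` (feature fully inside the span) or ``truncated``
    (partial overlap).
    """
    if span_start is None or span_end is None:
        return []
    L = catalog.genome_length
    if not (1 <= span_start <= L and 1 <= span_end <= L):
        raise ReferenceError(f"span {span_start}-{span_end} outside 1..{L}")
    span = _span_intervals(span_start, span_end, L)
    wanted = set(categories) if categories is not None else None
    hits: list[FeatureOverlap] = []
    for f in catalog.features:
        if wanted is not None and f.category not in wanted:
            continue
        ov = _overlap_bp(span, f.intervals(L))
        if ov == 0:
            continue
        impact = "removed" if ov == f.span_length(L) else "truncated"
        hits.append(FeatureOverlap(f, impact, ov))
    return hits


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def catalog_to_bed(catalog: FeatureCatalog) -> str:
    """BED (0-based half-open) text for the catalog; wrapping features are
    emitted as two lines sharing a name."""
    lines = []
    for f in catalog.features:
        for s, e in f.intervals(catalog.genome_length):
            lines.append(f"chrM\t{s - 1}\t{e}\t{f.name}\t0\t+")
    return "\n".join(lines) + "\n"


def catalog_to_gff3(catalog: FeatureCatalog) -> str:
    type_map = {
        "protein": "gene", "tRNA": "tRNA_gene", "rRNA": "rRNA_gene",
        "origin": "origin_of_replication", "MDP": "ORF",
        "control_region": "D_loop",
    }
    lines = ["##gff-version 3"]
    for f in catalog.features:
        for s, e in f.intervals(catalog.genome_length):
            attrs = f"ID={f.name};arc={f.arc}"
            if f.complex_id:
                attrs += f";complex={f.complex_id}"
            lines.append(
                f"chrM\tmtaging\t{type_map[f.category]}\t{s}\t{e}\t.\t+\t.\t{attrs}"
            )
    return "\n".join(lines) + "\n"
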