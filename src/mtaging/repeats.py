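"""Direct-repeat analysis of deletion junctions.

Large mtDNA deletions are thought to arise when two identical sequence
stretches (direct repeats, typically ~6-22 nt) located far apart on the
genome mispair during replication or repair.  The breakpoints reported by a
junction caller then fall in or next to the two repeat copies.  A homoplasmic
SNP near a breakpoint can lengthen or shorten the perfect repeat, changing
how favourable the mispairing is — the mechanistic link this module
quantifies.

Definition used here: for a junction (bp5, bp3) — bp5 the last retained 5'
base, bp3 the first retained 3' base — the two flanks are laid on the
*junction diagonal*, comparing position ``bp5 + t`` against ``bp3 - 1 + t``
for offsets ``t`` in ``[-window, window]``.  The repeat associated with the
junction is the longest run of consecutive matches on that diagonal.  The
shared offset reflects the biology: in the deleted molecule the two flanks
are joined in register, so only equally-shifted substring pairs can mediate
the mispairing.  An unconstrained search over all substring pairs in the two
windows instead picks up unrelated coincidental matches nearby.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Literal

from .reference import MitoGenome, substitute_allele

DeltaClass = Literal["lengthens", "shortens", "neutral"]

_LABEL_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleSubstitution:
    """A single-base substitution such as T14798C (ref T, position 14798, alt C)."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise RepeatError("ref and alt alleles are identical")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise RepeatError("alleles must be A/C/G/T")

    @property
    def label(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"

    @classmethod
    def from_label(cls, label: str) -> "AlleleSubstitution":
        m = _LABEL_RE.match(label.strip().upper())
        if not m:
            raise RepeatError(f"cannot parse substitution label {label!r}")
        return cls(position=int(m.group(2)), ref=m.group(1), alt=m.group(3))


@dataclass(frozen=True)
class RepeatAssessment:
    bp5: int
    bp3: int
    repeat_length: int
    copy5_span: tuple[int, int] | None  # 1-based inclusive, None if length 0
    copy3_span: tuple[int, int] | None
    repeat_sequence: str

    def to_dict(self) -> dict:
        return {
            "bp5": self.bp5, "bp3": self.bp3,
            "repeat_length": self.repeat_length,
            "copy5_span": list(self.copy5_span) if self.copy5_span else None,
            "copy3_span": list(self.copy3_span) if self.copy3_span else None,
            "repeat_sequence": self.repeat_sequence,
        }


def _check_window(genome: MitoGenome, bp5: int, bp3: int, window: int,
                  circular: bool) -> None:
    if window < 1:
        raise RepeatError("window must be >= 1")
    if not (1 <= bp5 <= genome.length and 1 <= bp3 <= genome.length):
        raise RepeatError(f"junction ({bp5}, {bp3}) outside 1..{genome.length}")
    if not circular:
        lo = min(bp5 - window, bp3 - 1 - window)
        hi = max(bp5 + window, bp3 - 1 + window)
        if lo < 1 or hi > genome.length:
            raise RepeatError(
                "window extends past genome bounds; pass circular=True to wrap"
            )


def max_direct_repeat(
    genome: MitoGenome, bp5: int, bp3: int, window: int = 15,
    circular: bool = False,
) -> RepeatAssessment:
    """Longest perfect direct repeat on the junction diagonal of (bp5, bp3).

    Ties between equally long runs are broken in favour of the leftmost
    (most 5') copy, which recovers the repeat a junction caller would report
    upstream of each breakpoint.  ``N`` never matches.  Returns a zero-length assessment when no base matches anywhere
    in the window.
    """
    _check_window(genome, bp5, bp3, window, circular)
    L = genome.length
    seq = genome.sequence

    def base(pos: int) -> str:
        return seq[(pos - 1) % L]

    runs: list[tuple[int, int]] = []  # (t_start, t_end) inclusive offsets
    t0 = None
    for t in range(-window, window + 2):
        if t <= window:
            a, b = base(bp5 + t), base(bp3 - 1 + t)
            match = a == b and a != "N"
        else:
            match = False
        if match and t0 is None:
            t0 = t
        elif not match and t0 is not None:
            runs.append((t0, t - 1))
            t0 = None
    if not runs:
        return RepeatAssessment(bp5, bp3, 0, None, None, "")

    def rank(run: tuple[int, int]) -> tuple[int, int]:
        a, b = run
        return (-(b - a + 1), a)

    a, b = min(runs, key=rank)
    length = b - a + 1
    copy5 = (bp5 + a, bp5 + b)
    copy3 = (bp3 - 1 + a, bp3 - 1 + b)
    motif = "".join(base(p) for p in range(copy5[0], copy5[0] + length))
    return RepeatAssessment(bp5, bp3, length, copy5, copy3, motif)


def repeat_delta(
    genome: MitoGenome,
    bp5: int,
    bp3: int,
    substitution: AlleleSubstitution,
    window: int = 15,
    circular: bool = False,
) -> tuple[RepeatAssessment, RepeatAssessment]:
    """Repeat assessments for the reference and alternate alleles of a SNP.

    The reference allele of ``substitution`` must match the genome.  A warning
    is emitted when the SNP lies outside the search window of both
    breakpoints (it then cannot change the result).
    """
    if genome.base(substitution.position) != substitution.ref:
        raise RepeatError(
            f"reference mismatch at {substitution.position}: genome has "
            f"{genome.base(substitution.position)}, substitution says "
            f"{substitution.ref}"
        )
    near5 = abs(substitution.position - bp5) <= window
    near3 = abs(substitution.position - (bp3 - 1)) <= window
    if not (near5 or near3):
        warnings.warn(
            f"substitution {substitution.label} lies outside the {window}-bp "
            f"windows of junction ({bp5}, {bp3})", stacklevel=2,
        )
    ref_assess = max_direct_repeat(genome, bp5, bp3, window, circular)
    alt_genome = substitute_allele(genome, substitution.position, substitution.alt)
    alt_assess = max_direct_repeat(alt_genome, bp5, bp3, window, circular)
    return ref_assess, alt_assess


def classify_delta(ref_length: int, alt_length: int) -> DeltaClass:
    """Direction of the repeat-length change caused by the alternate allele."""
    if ref_length < 0 or alt_length < 0:
        raise RepeatError("repeat lengths must be non-negative")
    if alt_length > ref_length:
        return "lengthens"
    if alt_length < ref_length:
        return "shortens"
    return "neutral"
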