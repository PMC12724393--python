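import numpy as np
import pytest

from mtaging.reference import MitoGenome, default_catalog, rcrs_genome


@pytest.fixture(scope="session")
def rcrs():
    return rcrs_genome()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_genome(rng, length=4000, name="rand") -> MitoGenome:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return MitoGenome(name=name, sequence=seq)


# ---------------------------------------------------------------------------
# independent oracles used by several test modules
# ---------------------------------------------------------------------------

def span_positions(start: int, end: int, genome_length: int) -> set[int]:
    """All 1-based positions in the circular span [start, end]."""
    if start <= end:
        return set(range(start, end + 1))
    return set(range(start, genome_length + 1)) | set(range(1, end + 1))


def brute_force_overlaps(catalog, start: int, end: int) -> dict[str, str]:
    """Per-base membership oracle: feature name -> removed|truncated."""
    span = span_positions(start, end, catalog.genome_length)
    out = {}
    for f in catalog.features:
        fpos = span_positions(f.start, f.end, catalog.genome_length)
        shared = fpos & span
        if shared:
            out[f.name] = "removed" if shared == fpos else "truncated"
    return out


def brute_force_repeat(sequence: str, bp5: int, bp3: int, window: int):
    """Exhaustive enumeration of substring pairs in the two breakpoint
    windows that sit in junction register (copy3 - copy5 == bp3 - 1 - bp5),
    maximising length and breaking ties toward the leftmost 5' copy.

    Returns (length, copy5_start) with copy5_start None when no pair exists.
    """
    shift = (bp3 - 1) - bp5
    best = (0, None)
    lo = bp5 - window
    hi = bp5 + window
    for L in range(1, 2 * window + 2):
        found = None
        for s5 in range(lo, hi - L + 2):
            s3 = s5 + shift
            a = sequence[s5 - 1 : s5 - 1 + L]
            b = sequence[s3 - 1 : s3 - 1 + L]
            if len(a) < L or len(b) < L or "N" in a:
                continue
            if a == b:
                found = s5
                break  # leftmost pair of this length
        if found is not None:
            best = (L, found)
    return best
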