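import numpy as np
import pytest

from nrescan import motifs

_FULL = frozenset("ACGT")


@pytest.fixture(scope="session")
def ir1():
    return motifs.ir1_pattern()


def naive_scan(seq, pattern, max_mm, strands="both"):
    """Independent per-position, per-strand comparison oracle for scan()."""
    seq = seq.upper()
    L = pattern.length
    profiles = [("+", pattern.full.sets)]
    if strands == "both" and not pattern.self_rc:
        profiles.append(("-", pattern.full.reverse_complement().sets))
    hits = []
    for strand, sets in profiles:
        for pos in range(len(seq) - L + 1):
            mm = 0
            for i, allowed in enumerate(sets):
                if allowed == _FULL:
                    continue
                if seq[pos + i] not in allowed:
                    mm += 1
            if mm <= max_mm:
                hits.append((pos, strand, mm))
    return sorted(hits)


def random_pattern(rng: np.random.Generator) -> motifs.ResponseElementPattern:
    """A random half-site (length 4-7, random allowed sets) in a random geometry."""
    bases = "ACGT"
    n = int(rng.integers(4, 8))
    sets = []
    for _ in range(n):
        size = int(rng.integers(1, 4))
        sets.append(frozenset(rng.choice(list(bases), size=size, replace=False)))
    half = motifs.IUPACPattern(tuple(sets))
    geometry = motifs.RepeatGeometry(
        ["IR", "DR", "ER"][int(rng.integers(3))], int(rng.integers(0, 5))
    )
    return motifs.compile_element(half, geometry)


def random_sequence(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))
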