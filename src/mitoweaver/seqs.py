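"""Low-level DNA string helpers shared across the pipeline.

All sequences are uppercase ACGT(N) strings; coordinates are 0-based
half-open everywhere inside the package (conversion to 1-based closed
GFF3 happens only at file boundaries, in :mod:`mitoweaver.formats`).
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.array(list("ACGT"))


def complement(s: str) -> str:
    """Base-wise complement without reversal (the 'C' repeat relation)."""
    return s.translate(_COMP)


def reverse(s: str) -> str:
    """Plain reversal without complementation (the 'R' repeat relation)."""
    return s[::-1]


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def gc_content(s: str) -> float:
    """GC fraction over unambiguous bases; 0.0 for an empty/all-N string."""
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random i.i.d. sequence with expected GC fraction ``gc``."""
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def kmers_unique_in(seq: str, k: int) -> dict[str, int]:
    """k-mer -> position for k-mers occurring exactly once in ``seq``.

    k-mers containing N are never indexed.
    """
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        if km in seen:
            dup.add(km)
        else:
            seen[km] = i
    for km in dup:
        del seen[km]
    return seen
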