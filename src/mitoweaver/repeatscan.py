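"""Dispersed repeat finder (classes F/P/R/C) and MISA-style SSR scanner.

Dispersed repeats are maximal exact pairs of length >= min_len whose second
copy is identical (F, forward), reverse-complemented (P, palindrome),
reversed (R, reverse) or complemented (C, complement). Hits are found by
seeding every min_len-mer and extending; a hit is emitted only from its
leftmost seed, which enforces maximality without a suffix structure. N never
matches anything, including another N.

SSRs are maximal perfect tandem runs of a primitive 1-6 bp unit meeting the
MISA minimum repeat counts (10 for mono-, 6 for di-, 5 for tri- through
hexanucleotide motifs), reported under a canonical motif class that is
invariant under rotation and strand (e.g. "A/T", "AT/TA").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqs import complement, revcomp

DEFAULT_MIN_REPEAT_LEN = 30
DEFAULT_SSR_MINIMA = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class RepeatHit:
    cls: str  # F, P, R or C
    loc1: tuple[str, int, int]  # (contig, start, length)
    loc2: tuple[str, int, int]
    length: int


@dataclass(frozen=True)
class SSRHit:
    motif: str
    motif_class: str
    unit: int
    count: int
    contig: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------


def _maximal_matches(x: str, y: str, L: int, skip_identity: bool):
    """Maximal exact matches of length >= L between x and y.

    Yields (i, j, length). Matches are emitted once, from the seed at their
    left edge. ``skip_identity`` drops the trivial x==y self-match (i == j).
    """
    index: dict[str, list[int]] = {}
    for i in range(len(x) - L + 1):
        w = x[i : i + L]
        if "N" in w:
            continue
        index.setdefault(w, []).append(i)
    nx_, ny = len(x), len(y)
    for j in range(ny - L + 1):
        w = y[j : j + L]
        hits = index.get(w)
        if not hits:
            continue
        for i in hits:
            if skip_identity and i == j:
                continue
            # emit only from the leftmost seed of the run
            if i > 0 and j > 0 and x[i - 1] == y[j - 1] and x[i - 1] != "N":
                continue
            e = L
            while (
                i + e < nx_
                and j + e < ny
                and x[i + e] == y[j + e]
                and x[i + e] != "N"
            ):
                e += 1
            yield i, j, e


_TRANSFORM = {
    "F": lambda s: s,
    "P": revcomp,
    "R": lambda s: s[::-1],
    "C": complement,
}


def _map_back(cls: str, j: int, length: int, n: int) -> int:
    """Start of the matched window in original coordinates of the target."""
    if cls in ("P", "R"):
        return n - j - length
    return j


def resolve_self_overlap(
    cls: str, start1: int, start2: int, length: int
) -> tuple[int, int, int] | None:
    """Shrink a same-contig match until its two copies no longer overlap.

    Forward matches with overlapping copies are tandem periodicities (SSR
    territory) and are dropped outright. For P/R the two copies converge, so
    trimming one column shrinks the overlap by two; for C the copies run in
    parallel and the non-overlapping core is exactly the offset between them.
    Returns (start1, start2, length) with start1 <= start2, or None.
    """
    if start2 < start1:
        start1, start2 = start2, start1
    overlap = start1 + length - start2
    if overlap <= 0:
        return start1, start2, length
    if cls == "F":
        return None
    if cls == "C":
        return start1, start2, start2 - start1
    # P/R: copies face each other; trim the facing ends
    t = (overlap + 1) // 2
    return start1, start2 + t, length - t


def find_dispersed_repeats(
    seqs: dict[str, str], min_len: int = DEFAULT_MIN_REPEAT_LEN
) -> list[RepeatHit]:
    """All maximal F/P/R/C repeat pairs of length >= min_len.

    Same-contig pairs whose copies would overlap are resolved by
    :func:`resolve_self_overlap`, so e.g. a perfect palindrome is reported
    as one P hit whose two arms touch.
    """
    if min_len < 8:
        raise ValueError(f"min_len must be >= 8, got {min_len}")
    names = sorted(seqs)
    out: set[RepeatHit] = set()
    for ci, name1 in enumerate(names):
        s1 = seqs[name1]
        for name2 in names[ci:]:
            s2 = seqs[name2]
            same = name1 == name2
            for cls, tf in _TRANSFORM.items():
                y = tf(s2)
                skip_ident = same and cls == "F"
                for i, j, length in _maximal_matches(s1, y, min_len, skip_ident):
                    j0 = _map_back(cls, j, length, len(s2))
                    if same:
                        resolved = resolve_self_overlap(cls, i, j0, length)
                        if resolved is None:
                            continue
                        i, j0, length = resolved
                        if length < min_len:
                            continue
                    loc1 = (name1, i, length)
                    loc2 = (name2, j0, length)
                    if loc2 < loc1:
                        loc1, loc2 = loc2, loc1
                    out.add(RepeatHit(cls, loc1, loc2, length))
    return sorted(out, key=lambda h: (h.cls, h.loc1, h.loc2))


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_ssr_class(motif: str) -> str:
    """Canonical motif class: all rotations of the motif and of its reverse
    complement, sorted and joined (MISA-style grouping, e.g. 'A/T')."""
    rc = revcomp(motif)
    variants = {motif[i:] + motif[:i] for i in range(len(motif))}
    variants |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return "/".join(sorted(variants))


def find_ssrs(
    seqs: dict[str, str], minima: dict[int, int] | None = None
) -> list[SSRHit]:
    """Maximal perfect tandem repeats meeting per-unit-length minima.

    A run of period u is reported once, over its full maximal extent (which
    may end in a partial unit); the repeat count is the number of complete
    units. Non-primitive units (e.g. 'AA' as a dinucleotide) are never
    reported, and a shorter-unit hit fully contained in a longer-unit hit is
    suppressed.
    """
    minima = dict(DEFAULT_SSR_MINIMA if minima is None else minima)
    out: list[SSRHit] = []
    for contig in sorted(seqs):
        s = seqs[contig]
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        valid = arr != ord("N")
        contig_hits: list[SSRHit] = []
        for u in sorted(minima):
            if len(s) < 2 * u:
                continue
            eq = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
            padded = np.concatenate(([False], eq, [False]))
            edges = np.flatnonzero(np.diff(padded.view(np.int8)))
            for rs, re in zip(edges[::2], edges[1::2]):
                span = int(re - rs) + u
                count = span // u
                if count < minima[u]:
                    continue
                unit = s[rs : rs + u]
                if not _is_primitive(unit):
                    continue
                contig_hits.append(
                    SSRHit(
                        motif=unit,
                        motif_class=canonical_ssr_class(unit),
                        unit=u,
                        count=count,
                        contig=contig,
                        start=int(rs),
                        end=int(rs) + span,
                    )
                )
        # longest-unit-first: drop shorter-unit hits swallowed by a longer one
        contig_hits.sort(key=lambda h: (-h.unit, h.start))
        kept: list[SSRHit] = []
        for h in contig_hits:
            if any(
                k.unit > h.unit and k.start <= h.start and h.end <= k.end
                for k in kept
            ):
                continue
            kept.append(h)
        out.extend(sorted(kept, key=lambda h: (h.start, h.unit)))
    return out
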