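"""Small alignment utilities.

``banded_global`` is a linear-gap Needleman-Wunsch restricted to a diagonal
band, with a fixed deterministic tie-break (diagonal, then up = consume a
query base, then left). It is meant for near-identical sequences such as
orthologous CDSs, where the band comfortably contains the optimal path.
"""

from __future__ import annotations

NEG = -(10**9)


def banded_global(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    band: int | None = None,
) -> tuple[str, str, int]:
    """Globally align ``a`` against ``b``; returns (aligned_a, aligned_b, score).

    Tie-break on equal scores prefers diagonal, then up (gap in ``b``), then
    left — the alignment path is fully deterministic.
    """
    la, lb = len(a), len(b)
    if band is None:
        band = abs(la - lb) + 32
    band = max(band, abs(la - lb) + 1)

    # score[i][j] with j stored sparsely in [lo_i, hi_i)
    prev: dict[int, int] = {j: gap * j for j in range(0, min(lb, band) + 1)}
    ptr: list[dict[int, int]] = []  # 0=diag, 1=up, 2=left
    for i in range(1, la + 1):
        lo = max(0, i - band)
        hi = min(lb, i + band)
        cur: dict[int, int] = {}
        row_ptr: dict[int, int] = {}
        for j in range(lo, hi + 1):
            if j == 0:
                cur[0] = gap * i
                row_ptr[0] = 1
                continue
            diag = prev.get(j - 1, NEG)
            sc_d = diag + (match if a[i - 1] == b[j - 1] else mismatch) if diag > NEG else NEG
            up = prev.get(j, NEG)
            sc_u = up + gap if up > NEG else NEG
            left = cur.get(j - 1, NEG)
            sc_l = left + gap if left > NEG else NEG
            best = max(sc_d, sc_u, sc_l)
            cur[j] = best
            if best == sc_d:
                row_ptr[j] = 0
            elif best == sc_u:
                row_ptr[j] = 1
            else:
                row_ptr[j] = 2
        ptr.append(row_ptr)
        prev = cur
    score = prev.get(lb, NEG)
    if score <= NEG:
        raise ValueError("band too narrow for a global alignment path")

    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        move = ptr[i - 1][j] if i > 0 else 2
        if j == 0:
            move = 1
        if move == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score
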