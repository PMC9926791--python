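"""The junction (linkage) primitive shared by the generator and the reconciler.

A junction is an adjacency between two stable-contig ends, optionally
mediated by a repeat segment of the assembly graph. Plant mitogenomes are
reported here as a multigraph of such junctions (the reticulate
conformation) rather than as a single master circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, eq=False)
class Junction:
    """An adjacency between two contig ends.

    ``end_a``/``end_b`` are ``(contig_id, side)`` with side ``"L"`` (5' end of
    the contig's plus strand) or ``"R"`` (3' end). ``mediator`` names the
    repeat segment spanning the junction, or ``None`` for a direct link.
    ``mediator_orient`` records which orientation of the mediator joins
    end_a to end_b; it is bookkeeping for amplicon assembly and takes no
    part in equality or the signature.
    """

    end_a: tuple[str, str]
    end_b: tuple[str, str]
    mediator: str | None = None
    mediator_orient: str = field(default="+", compare=False)

    def __post_init__(self) -> None:
        for _, side in (self.end_a, self.end_b):
            if side not in ("L", "R"):
                raise ValueError(f"junction side must be L or R, got {side!r}")

    @property
    def signature(self) -> str:
        """Canonical string, invariant under end swap and global strand flip."""
        ends = sorted(f"{c}.{s}" for c, s in (self.end_a, self.end_b))
        return f"{ends[0]}--{ends[1]}|{self.mediator or '.'}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Junction):
            return NotImplemented
        return self.signature == other.signature

    def __hash__(self) -> int:
        return hash(self.signature)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.signature
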