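"""Readers and writers for the standard formats the pipeline touches.

FASTA, GFA1 (S/L lines, blunt ``0M`` links, depth in ``DP:f:`` tags), GFF3
(1-based closed on disk), BED (0-based half-open) and TSV. Internally every
coordinate is 0-based half-open; conversion happens only here, at the file
boundary, so the strand/off-by-one logic lives in exactly one place.

Gene models split across contigs are represented as one record per part,
tied together by a shared ``locus`` and an explicit ``part_order`` GFF3
attribute (the on-disk encoding of a manually spliced multi-contig gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SegmentRecord:
    """One graph segment or stable contig: an id, a sequence, optional depth."""

    id: str
    sequence: str
    depth: float | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def link_ends(a: str, ao: str, b: str, bo: str) -> tuple[tuple[str, str], tuple[str, str]]:
    """Map an oriented GFA link to the two physical segment ends it joins.

    ``L a + b +`` joins the right (3') end of a to the left (5') end of b.
    """
    end_a = (a, "R" if ao == "+" else "L")
    end_b = (b, "L" if bo == "+" else "R")
    return end_a, end_b


def canonical_link(link: tuple[str, str, str, str, int]) -> tuple[str, str, str, str, int]:
    a, ao, b, bo, ov = link
    mirror = (b, _flip(bo), a, _flip(ao), ov)
    return min(link, mirror)


@dataclass
class AssemblyGraph:
    """Segments plus oriented links: the DBG 'connection network'."""

    segments: dict[str, SegmentRecord] = field(default_factory=dict)
    links: set[tuple[str, str, str, str, int]] = field(default_factory=set)

    def add_segment(self, rec: SegmentRecord) -> None:
        if rec.id in self.segments:
            raise ValueError(f"duplicate segment id {rec.id!r}")
        if not rec.sequence:
            raise ValueError(f"segment {rec.id!r} has an empty sequence")
        self.segments[rec.id] = rec

    def add_link(self, a: str, ao: str, b: str, bo: str, overlap: int = 0) -> None:
        for seg in (a, b):
            if seg not in self.segments:
                raise ValueError(f"link references unknown segment {seg!r}")
        self.links.add(canonical_link((a, ao, b, bo, overlap)))

    def has_link(self, a: str, ao: str, b: str, bo: str) -> bool:
        target = canonical_link((a, ao, b, bo, 0))[:4]
        return any(ln[:4] == target for ln in self.links)

    def links_at(self, seg: str, side: str) -> list[tuple[str, str, int]]:
        """All (other_segment, other_side, overlap) attached to one segment end."""
        out = []
        for a, ao, b, bo, ov in self.links:
            ea, eb = link_ends(a, ao, b, bo)
            if ea == (seg, side):
                out.append((eb[0], eb[1], ov))
            if eb == (seg, side):
                out.append((ea[0], ea[1], ov))
        return sorted(out)

    def degree(self, seg: str) -> int:
        return len(self.links_at(seg, "L")) + len(self.links_at(seg, "R"))


@dataclass
class GeneModel:
    """One gene part on one contig; multi-contig genes share a ``gene_id``.

    ``exons`` are 0-based half-open, sorted by genomic start, non-overlapping.
    Splicing order on the coding strand is handled by consumers (minus-strand
    parts are reverse-complemented after genomic-order concatenation).
    """

    gene_id: str
    part_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    product_class: str = "CDS"
    part_order: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if any(s >= e or s < 0 for s, e in ex):
            raise ValueError(f"gene {self.gene_id}: empty or negative exon")
        self.exons = ex

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


# ---------------------------------------------------------------------------
# coordinate conversions (GFF3 <-> internal/BED)
# ---------------------------------------------------------------------------


def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFA1
# ---------------------------------------------------------------------------


def read_gfa(path: str | Path) -> AssemblyGraph:
    """Parse a GFA1 file (S and L lines; ``DP:f:`` depth tags honoured)."""
    graph = AssemblyGraph()
    pending_links: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed S line")
                name, seq = fields[1], fields[2]
                depth = None
                for opt in fields[3:]:
                    if opt.startswith("DP:f:"):
                        depth = float(opt[5:])
                graph.add_segment(SegmentRecord(name, seq.upper(), depth))
            elif tag == "L":
                pending_links.append((lineno, fields))
            elif tag == "H":
                continue
            else:
                log.warning("%s:%d: ignoring unknown GFA line type %r", path, lineno, tag)
    for lineno, fields in pending_links:
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: malformed L line")
        a, ao, b, bo, cigar = fields[1:6]
        for seg in (a, b):
            if seg not in graph.segments:
                raise ValueError(
                    f"{path}:{lineno}: L line references unknown segment {seg!r}"
                )
        overlap = 0 if cigar in ("0M", "*") else int(cigar.rstrip("M"))
        graph.add_link(a, ao, b, bo, overlap)
    return graph


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name in sorted(graph.segments):
            rec = graph.segments[name]
            tags = f"\tLN:i:{len(rec.sequence)}"
            if rec.depth is not None:
                tags += f"\tDP:f:{rec.depth:.3f}"
            fh.write(f"S\t{name}\t{rec.sequence}{tags}\n")
        for a, ao, b, bo, ov in sorted(graph.links):
            fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t{ov}M\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_CLASS = {"mRNA": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_CLASS_TRANSCRIPT = {v: k for k, v in _TRANSCRIPT_CLASS.items()}


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk and "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Resolve gene -> transcript -> exon parent/child chains into GeneModels.

    An exon/CDS whose Parent is unknown is a hard error naming the feature.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, str] = {}  # transcript id -> gene part id
    exons: dict[str, list[tuple[int, int]]] = {}
    tclass: dict[str, str] = {}
    orphans: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attr_text = f
            attrs = _parse_attrs(attr_text)
            iv = gff_to_internal(int(start), int(end))
            if ftype == "gene":
                pid = attrs["ID"]
                genes[pid] = {
                    "part_id": pid,
                    "gene_id": attrs.get("locus", pid),
                    "contig": contig,
                    "strand": strand,
                    "part_order": int(attrs.get("part_order", 1)),
                }
            elif ftype in _TRANSCRIPT_CLASS:
                tid = attrs["ID"]
                transcripts[tid] = attrs["Parent"]
                tclass[tid] = _TRANSCRIPT_CLASS[ftype]
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}: {ftype} without Parent: {line!r}")
                if ftype == "exon":
                    exons.setdefault(parent, [])
                    if iv not in exons[parent]:
                        exons[parent].append(iv)
                if parent not in transcripts and parent not in genes:
                    orphans.append(attrs.get("ID", f"{ftype}@{contig}:{start}"))
    if orphans:
        raise ValueError(f"{path}: features with unknown Parent: {sorted(set(orphans))}")
    models = []
    for tid, part_id in transcripts.items():
        if part_id not in genes:
            raise ValueError(f"{path}: transcript {tid!r} has unknown Parent {part_id!r}")
        meta = genes[part_id]
        models.append(
            GeneModel(
                gene_id=meta["gene_id"],
                part_id=part_id,
                contig=meta["contig"],
                strand=meta["strand"],
                exons=sorted(exons.get(tid, [])),
                product_class=tclass[tid],
                part_order=meta["part_order"],
            )
        )
    models.sort(key=lambda m: (m.contig, m.span, m.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.contig, m.span, m.gene_id)):
            g1, g2 = internal_to_gff(*m.span)
            fh.write(
                f"{m.contig}\tmitoweaver\tgene\t{g1}\t{g2}\t.\t{m.strand}\t.\t"
                f"ID={m.part_id};locus={m.gene_id};part_order={m.part_order}\n"
            )
            ttype = _CLASS_TRANSCRIPT[m.product_class]
            tid = f"{m.part_id}.t"
            fh.write(
                f"{m.contig}\tmitoweaver\t{ttype}\t{g1}\t{g2}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.part_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                e1, e2 = internal_to_gff(s, e)
                fh.write(
                    f"{m.contig}\tmitoweaver\texon\t{e1}\t{e2}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
                if m.product_class == "CDS":
                    fh.write(
                        f"{m.contig}\tmitoweaver\tCDS\t{e1}\t{e2}\t.\t{m.strand}\t0\t"
                        f"Parent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def write_bed(records: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) rows; already 0-based."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
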