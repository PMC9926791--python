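"""Resolve a reticulate mitogenome conformation.

The core procedure: stable long-read contigs are threaded through the De
Bruijn 'connection network' by shared unique k-mer anchors; contig ends that
meet at (or across) a shared repeat segment become junctions; repeat copy
numbers follow from read depth relative to a gene-bearing baseline; contigs
at sub-stoichiometric depth are flagged as a minor conformation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from statistics import median

from .formats import AssemblyGraph, GeneModel, SegmentRecord, link_ends
from .junctions import Junction
from .seqs import kmers_unique_in, revcomp

log = logging.getLogger(__name__)

DEFAULT_ANCHOR_K = 31
DEFAULT_MINOR_FRACTION = 0.5


@dataclass
class GraphPath:
    """One contig threaded onto the graph: an oriented segment walk."""

    contig_id: str
    path: list[tuple[str, str]]  # (segment, orient)
    anchor_coverage: float

    @property
    def segments(self) -> list[str]:
        return [seg for seg, _ in self.path]

    def terminal_ends(self) -> dict[tuple[str, str], tuple[str, str]]:
        """Map of graph ends -> canonical contig ends for this path.

        The canonical contig side is expressed in the frame of the graph, so
        it does not change if the input contig is reverse-complemented.
        """
        if not self.path:
            return {}
        s1, o1 = self.path[0]
        s2, o2 = self.path[-1]
        entry = (s1, "L" if o1 == "+" else "R")
        exit_ = (s2, "R" if o2 == "+" else "L")
        return {
            entry: (self.contig_id, "L" if o1 == "+" else "R"),
            exit_: (self.contig_id, "R" if o2 == "+" else "L"),
        }


@dataclass
class ResolvedStructure:
    """The reticulate conformation of one accession."""

    accession: str
    contigs: list[SegmentRecord]
    junctions: list[Junction]
    copy_number: dict[str, int]  # per contig and per graph segment
    minor_flags: dict[str, bool]  # per contig
    baseline_depth: float
    conformation_length: int
    paths: list[GraphPath] = field(default_factory=list, repr=False)
    graph: AssemblyGraph | None = field(default=None, repr=False)

    def junction_multiset(self) -> dict[str, int]:
        return dict(Counter(j.signature for j in self.junctions))

    def junction_set(self) -> set[str]:
        return {j.signature for j in self.junctions}


# ---------------------------------------------------------------------------
# contig threading
# ---------------------------------------------------------------------------


def _graph_anchor_index(graph: AssemblyGraph, k: int) -> dict[str, tuple[str, int]]:
    """k-mer -> (segment, pos) for k-mers unique within their segment and
    occurring in only one segment; cached on the graph instance."""
    key = (k, len(graph.segments), len(graph.links))
    cache = getattr(graph, "_anchor_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    index: dict[str, tuple[str, int]] = {}
    ambiguous: set[str] = set()
    for seg_id in sorted(graph.segments):
        for km, pos in kmers_unique_in(graph.segments[seg_id].sequence, k).items():
            if km in index or km in ambiguous:
                ambiguous.add(km)
                index.pop(km, None)
            else:
                index[km] = (seg_id, pos)
    graph._anchor_cache = (key, index)
    return index


def thread_contig(
    contig: SegmentRecord, graph: AssemblyGraph, k: int = DEFAULT_ANCHOR_K
) -> GraphPath:
    """Thread one stable contig through the assembly graph.

    Shared unique k-mers are chained colinearly per (segment, strand) on the
    dominant diagonal (ties resolved to the leftmost anchor on the contig);
    the resulting segment intervals, ordered along the contig, must be
    consecutive links of the graph, otherwise the implied missing link is a
    hard error naming the segment pair.
    """
    if len(contig.sequence) < k:
        raise ValueError(f"contig {contig.id} shorter than anchor size k={k}")
    short = [s for s, rec in graph.segments.items() if len(rec.sequence) < k]
    if short:
        raise ValueError(
            f"anchor size k={k} exceeds the shortest graph segment ({short[0]})"
        )
    index = _graph_anchor_index(graph, k)
    seq = contig.sequence

    # anchors per (segment, strand) grouped by diagonal
    groups: dict[tuple[str, str, int], list[int]] = {}
    for km, i in kmers_unique_in(seq, k).items():
        hit = index.get(km)
        if hit is not None:
            seg, pos = hit
            groups.setdefault((seg, "+", i - pos), []).append(i)
        hit = index.get(revcomp(km))
        if hit is not None:
            seg, pos = hit
            groups.setdefault((seg, "-", i + pos), []).append(i)
    if not groups:
        log.warning("contig %s produced no anchors against the graph", contig.id)
        return GraphPath(contig.id, [], 0.0)

    # dominant diagonal per (segment, strand): most anchors, then leftmost
    best: dict[tuple[str, str], tuple[int, int, list[int]]] = {}
    for (seg, strand, _diag), pos_list in groups.items():
        pos_list.sort()
        key = (seg, strand)
        rank = (-len(pos_list), pos_list[0])
        if key not in best or rank < best[key][:2]:
            best[key] = (*rank, pos_list)
    # one strand per segment: the one with more anchors (then leftmost)
    per_seg: dict[str, tuple[int, int, str, list[int]]] = {}
    for seg, strand in sorted(best):
        neg_n, start, pos_list = best[(seg, strand)]
        if seg not in per_seg or (neg_n, start) < per_seg[seg][:2]:
            per_seg[seg] = (neg_n, start, strand, pos_list)

    intervals = []  # (contig_start, contig_end, seg, strand, n_anchors)
    for seg, (_, _, strand, pos_list) in per_seg.items():
        intervals.append((pos_list[0], pos_list[-1] + k, seg, strand, len(pos_list)))
    intervals.sort()

    def linked(a: str, oa: str, b: str, ob: str) -> bool:
        out_side = "R" if oa == "+" else "L"
        in_side = "L" if ob == "+" else "R"
        return (b, in_side) in {(s, sd) for s, sd, _ in graph.links_at(a, out_side)}

    # longest link-consistent chain by DP over candidate intervals:
    # maximize total anchors, break ties toward the leftmost chain
    n_iv = len(intervals)
    dp = [iv[4] for iv in intervals]
    parent = [-1] * n_iv
    for i in range(n_iv):
        si, _ei, gi, oi_, ai = intervals[i]
        for j in range(i):
            ej, gj, oj = intervals[j][1], intervals[j][2], intervals[j][3]
            if ej > si + k:  # more than a k-mer of overlap: incompatible claims
                continue
            if not linked(gj, oj, gi, oi_):
                continue
            if dp[j] + ai > dp[i]:
                dp[i] = dp[j] + ai
                parent[i] = j
    best = max(range(n_iv), key=lambda i: (dp[i], -intervals[i][0]))
    chain_idx = []
    node = best
    while node != -1:
        chain_idx.append(node)
        node = parent[node]
    chain_idx.reverse()
    chain = [intervals[i] for i in chain_idx]

    # a strong anchor interval that the consistent chain cannot include
    # implies a link missing from the graph: that is a hard error, whereas
    # weak stray matches (e.g. small dispersed repeats) are simply dropped
    chain_anchors = sum(iv[4] for iv in chain)
    chosen = set(chain_idx)
    for i, iv in enumerate(intervals):
        if i in chosen:
            continue
        overlaps = any(not (iv[1] <= c[0] or c[1] <= iv[0]) for c in chain)
        if not overlaps and iv[4] >= 0.2 * chain_anchors:
            raise ValueError(
                f"contig {contig.id}: chain implies a graph link between "
                f"{chain[-1][2]} and {iv[2]} that is absent from the graph"
            )

    path = [(seg, strand) for _, _, seg, strand, _ in chain]
    covered = sum(e - s for s, e, *_ in chain)
    return GraphPath(contig.id, path, min(1.0, covered / len(seq)))


# ---------------------------------------------------------------------------
# junction recovery
# ---------------------------------------------------------------------------


def build_linkage_graph(
    paths: list[GraphPath], graph: AssemblyGraph
) -> list[Junction]:
    """Derive the junction multiset from threaded contigs plus graph links.

    Graph segments not claimed by any contig path are repeat mediators: every
    (left-end neighbour, right-end neighbour) contig-end pair across such a
    segment is one junction. Links joining two contig terminal ends directly
    are junctions without a mediator.
    """
    term: dict[tuple[str, str], tuple[str, str]] = {}
    covered: set[str] = set()
    for p in paths:
        covered.update(p.segments)
        for graph_end, contig_end in p.terminal_ends().items():
            if graph_end in term:
                log.warning("graph end %s claimed by two contigs", graph_end)
            term[graph_end] = contig_end
    mediators = sorted(set(graph.segments) - covered)

    junctions: list[Junction] = []
    for a, ao, b, bo, _ in sorted(graph.links):
        ea, eb = link_ends(a, ao, b, bo)
        if ea in term and eb in term:
            junctions.append(Junction(term[ea], term[eb], mediator=None))
    for med in mediators:
        left = [
            term[(s, sd)]
            for s, sd, _ in graph.links_at(med, "L")
            if (s, sd) in term
        ]
        right = [
            term[(s, sd)]
            for s, sd, _ in graph.links_at(med, "R")
            if (s, sd) in term
        ]
        for ea in left:
            for eb in right:
                junctions.append(Junction(ea, eb, mediator=med, mediator_orient="+"))
    return junctions


# ---------------------------------------------------------------------------
# copy number and minor conformation from depth
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def estimate_copy_number(
    graph: AssemblyGraph,
    gene_bearing: set[str],
    minor_fraction: float = DEFAULT_MINOR_FRACTION,
) -> tuple[dict[str, int], dict[str, bool], float]:
    """Per-segment copy number and minor-conformation flags from depth.

    The baseline is the median depth of gene-bearing segments (gene-free
    segments are depth outliers: repeats run at copy-fold depth, minor
    conformation contigs below it). Copy = round-half-up(depth/baseline),
    floored at 1; segments under ``minor_fraction`` of baseline are minor.
    """
    missing = [s for s, rec in graph.segments.items() if rec.depth is None]
    if missing:
        raise ValueError(f"segments without depth: {sorted(missing)[:5]}")
    known = [s for s in gene_bearing if s in graph.segments]
    if not known:
        raise ValueError("no gene-bearing segments to establish a depth baseline")
    baseline = median(graph.segments[s].depth for s in sorted(known))
    if baseline <= 0:
        raise ValueError("gene-bearing baseline depth is zero")
    copy: dict[str, int] = {}
    minor: dict[str, bool] = {}
    for seg, rec in graph.segments.items():
        ratio = rec.depth / baseline
        copy[seg] = max(1, _round_half_up(ratio))
        minor[seg] = ratio < minor_fraction
    return copy, minor, baseline


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def resolve_structure(
    accession: str,
    contigs: list[SegmentRecord],
    graph: AssemblyGraph,
    gene_models: list[GeneModel],
    k: int = DEFAULT_ANCHOR_K,
    minor_fraction: float = DEFAULT_MINOR_FRACTION,
) -> ResolvedStructure:
    """Thread contigs, recover junctions, estimate copy numbers: the full
    per-accession structure resolution."""
    paths = [thread_contig(c, graph, k) for c in contigs]
    junctions = build_linkage_graph(paths, graph)

    gene_contigs = {m.contig for m in gene_models}
    gene_bearing = {
        seg for p in paths if p.contig_id in gene_contigs for seg in p.segments
    }
    if not gene_bearing:
        # unannotated input: every contig-claimed segment anchors the baseline
        log.warning("no gene-bearing contigs; using all threaded segments as baseline")
        gene_bearing = {seg for p in paths for seg in p.segments}
    seg_copy, seg_minor, baseline = estimate_copy_number(graph, gene_bearing, minor_fraction)

    copy_number = dict(seg_copy)
    minor_flags: dict[str, bool] = {}
    for contig, path in zip(contigs, paths):
        segs = path.segments
        if segs:
            total = sum(len(graph.segments[s].sequence) for s in segs)
            depth = (
                sum(graph.segments[s].depth * len(graph.segments[s].sequence) for s in segs)
                / total
            )
        else:
            depth = baseline
        ratio = depth / baseline
        copy_number[contig.id] = max(1, _round_half_up(ratio))
        minor_flags[contig.id] = ratio < minor_fraction

    conformation_length = sum(
        len(rec.sequence) * seg_copy[seg] for seg, rec in graph.segments.items()
    )
    return ResolvedStructure(
        accession=accession,
        contigs=contigs,
        junctions=junctions,
        copy_number=copy_number,
        minor_flags=minor_flags,
        baseline_depth=baseline,
        conformation_length=conformation_length,
        paths=paths,
        graph=graph,
    )


# ---------------------------------------------------------------------------
# in-silico junction amplicons
# ---------------------------------------------------------------------------


def junction_amplicon(
    structure: ResolvedStructure,
    junction: Junction,
    left_flank: int,
    right_flank: int,
) -> tuple[str, int]:
    """Splice the sequence across a junction, as a PCR amplicon template.

    Flanks must lie in the primer design window of 500-2000 bp; the amplicon
    is left flank + mediator (if any) + right flank. Flanks longer than the
    contig are truncated with a warning.
    """
    for f in (left_flank, right_flank):
        if not 500 <= f <= 2000:
            raise ValueError(f"flank {f} outside the 500-2000 bp primer window")
    if junction.signature not in structure.junction_set():
        raise ValueError(f"junction {junction.signature} not present in structure")
    seqs = {c.id: c.sequence for c in structure.contigs}

    def flank_seq(end: tuple[str, str], flank: int, leaving: bool) -> str:
        ctg, side = end
        s = seqs[ctg]
        if flank > len(s):
            log.warning(
                "flank %d truncated to contig %s length %d", flank, ctg, len(s)
            )
            flank = len(s)
        if leaving:  # sequence runs ... -> junction
            return s[-flank:] if side == "R" else revcomp(s[:flank])
        # junction -> sequence continues
        return s[:flank] if side == "L" else revcomp(s[-flank:])

    left = flank_seq(junction.end_a, left_flank, leaving=True)
    med = ""
    if junction.mediator is not None:
        if structure.graph is None or junction.mediator not in structure.graph.segments:
            raise ValueError(f"mediator {junction.mediator} not in graph")
        med = structure.graph.segments[junction.mediator].sequence
        if junction.mediator_orient == "-":
            med = revcomp(med)
    right = flank_seq(junction.end_b, right_flank, leaving=False)
    return left + med + right, len(left) + len(med) + len(right)
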