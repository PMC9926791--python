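"""Synthetic reticulate organellar genomes with full truth registries.

The generator emulates what the real pipeline consumes: a repeat-collapsed
De Bruijn assembly graph (each repeat appears once, linked to all of its
genomic neighbours), stable long-read contigs (the unique regions between
repeats), per-segment read depth (repeats at copy-number-fold depth,
minor-conformation contigs at sub-stoichiometric depth), organellar gene
annotations, and nuclear genomes carrying planted organelle-derived
insertions (NUMT/NUPT analogues) with exactly known identity.

Everything is seeded: the same spec and seed give byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd

_CIGAR_OPS = re.compile(r"(\d+)([=XIDM])")

from .formats import AssemblyGraph, GeneModel, SegmentRecord
from .junctions import Junction
from .seqs import gc_content, random_dna, revcomp

End = tuple[str, str]  # (segment/contig id, "L"|"R")


# ---------------------------------------------------------------------------
# specs and truth containers
# ---------------------------------------------------------------------------


@dataclass
class TruthSpec:
    """Parameters of one synthetic reticulate mitogenome.

    Defaults emulate the study conditions for a plant mitogenome: a ~420 kbp
    genome over 9 unique contigs, three copy-2 repeats of 12.4/3.6/4 kbp
    (the named repeats of the sorghum reference), mean read depth 83x with
    lognormal noise at CV 0.1, and two gene-free contigs at sub-stoichiometric
    depth representing a minor conformation.
    """

    seed: int = 0
    n_unique_segments: int = 9
    unique_len_range: tuple[int, int] = (30_000, 54_000)
    repeat_segments: list[tuple[int, int]] = field(
        default_factory=lambda: [(12_400, 2), (3_600, 2), (4_000, 2)]
    )
    junction_edges: list[tuple[End, End]] | None = None  # None -> random wiring
    depth_mean: float = 83.0
    minor_contig_fraction: float = 2 / 9
    minor_depth_ratio: float = 0.375
    depth_noise_cv: float = 0.1
    gc_target: float = 0.437
    graph_k: int = 55  # DBG overlap parameter; repeats must exceed it
    max_fragments: int = 2  # graph pieces per unique segment (>=1)
    gene_every: int = 12_000  # one gene per this many bp of non-minor contig
    unique_segments: list[tuple[str, int]] | None = None  # explicit override
    plant_dispersed: int = 2  # small F/P repeat pairs written into contigs
    plant_ssrs: int = 3  # microsatellite runs written into contigs

    def repeat_names(self) -> list[str]:
        return [f"rep{i + 1}" for i in range(len(self.repeat_segments))]

    def validate(self) -> None:
        if self.n_unique_segments < 1 and not self.unique_segments:
            raise ValueError("need at least one unique segment")
        for length, copy in self.repeat_segments:
            if copy < 2:
                raise ValueError(f"repeat copy number must be >= 2, got {copy}")
            if length < self.graph_k:
                raise ValueError(
                    f"repeat of {length} bp is shorter than the graph overlap "
                    f"parameter k={self.graph_k}; such a repeat would not collapse "
                    "in the assembly graph"
                )
        n = len(self.unique_segments) if self.unique_segments else self.n_unique_segments
        m = len(self.repeat_segments)
        if self.junction_edges is None and m == 0 and n > 1:
            raise ValueError(
                "disconnected junction spec: multiple unique segments but no "
                "repeats or explicit junction edges to connect them"
            )
        if self.junction_edges is None and m > 0:
            slots = 2 * sum(c for _, c in self.repeat_segments)
            if slots < n + m - 1:
                raise ValueError(
                    f"disconnected junction spec: {slots} repeat attachment slots "
                    f"cannot connect {n} contigs through {m} repeats"
                )


@dataclass
class SyntheticTruth:
    """The planted structure against which recovery is scored."""

    spec: TruthSpec
    segment_sequences: dict[str, str]  # contig and repeat ids -> sequence
    contig_ids: list[str]
    repeat_ids: list[str]
    attachments: dict[str, dict[str, list[End]]]  # repeat -> side -> contig ends
    direct_links: list[tuple[End, End]]
    true_junctions: list[Junction]
    true_copy_numbers: dict[str, int]  # per graph segment and per contig
    minor_contigs: set[str]
    gene_models: list[GeneModel]
    piece_map: dict[str, list[tuple[str, int, int]]]  # contig -> (piece, start, end)
    genome_length: int
    contexts: dict[str, str]  # junction signature -> local conformation sequence
    planted_dispersed: list[tuple] = field(default_factory=list)
    planted_ssrs: list[tuple] = field(default_factory=list)

    def junction_multiset(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for j in self.true_junctions:
            out[j.signature] = out.get(j.signature, 0) + 1
        return out


# ---------------------------------------------------------------------------
# structure simulation
# ---------------------------------------------------------------------------


def _make_link(end1: End, end2: End) -> tuple[str, str, str, str]:
    """Oriented GFA link joining two physical segment ends."""
    a, sa = end1
    b, sb = end2
    return (a, "+" if sa == "R" else "-", b, "+" if sb == "L" else "-")


def _random_attachments(
    rng: np.random.Generator,
    contigs: list[str],
    repeats: list[tuple[str, int]],
) -> dict[str, dict[str, list[End]]]:
    """Wire repeats to contig ends: connected, every contig attached,
    per-repeat attachment count equal to its copy number on each end."""
    all_ends: list[End] = [(c, s) for c in contigs for s in ("L", "R")]
    unattached = list(contigs)
    rng.shuffle(unattached)
    attached_ends: list[End] = []
    att: dict[str, dict[str, list[End]]] = {}
    used_links: set[tuple[End, str, str]] = set()

    def take_end(prefer_new: bool, rep: str, side: str) -> End:
        if prefer_new and unattached:
            ctg = unattached.pop()
            end = (ctg, "L" if rng.random() < 0.5 else "R")
        else:
            candidates = [e for e in all_ends if (e, rep, side) not in used_links]
            end = candidates[rng.integers(len(candidates))]
        return end

    for k, (rep, copy) in enumerate(repeats):
        att[rep] = {"L": [], "R": []}
        for i in range(copy):
            for side in ("L", "R"):
                if k > 0 and i == 0 and side == "L" and attached_ends:
                    # bridge: tie this repeat into the existing component
                    pool = [
                        e for e in attached_ends if (e, rep, side) not in used_links
                    ]
                    end = pool[rng.integers(len(pool))]
                else:
                    end = take_end(prefer_new=True, rep=rep, side=side)
                att[rep][side].append(end)
                used_links.add((end, rep, side))
                attached_ends.append(end)
    if unattached:
        raise ValueError(
            f"disconnected junction spec: contigs {unattached} could not be "
            "attached to any repeat"
        )
    return att


def _plant_genes(
    rng: np.random.Generator,
    contig_lens: dict[str, int],
    minor: set[str],
    gene_every: int,
) -> list[GeneModel]:
    models: list[GeneModel] = []
    counter = 0
    for ctg in sorted(contig_lens):
        if ctg in minor:
            continue  # minor-conformation contigs are gene-free
        length = contig_lens[ctg]
        n_genes = max(1, int(round(length / gene_every)))
        taken: list[tuple[int, int]] = []
        for _ in range(n_genes * 4):  # rejection sampling with head-room
            if len(taken) >= n_genes:
                break
            is_cds = rng.random() < 0.9
            span = int(rng.integers(900, 2500)) if is_cds else int(rng.integers(70, 90))
            if length < span + 401:
                continue
            start = int(rng.integers(200, length - span - 200))
            if any(s < start + span and start < e for s, e in taken):
                continue
            taken.append((start, start + span))
            counter += 1
            n_ex = int(rng.integers(1, 4)) if is_cds else 1
            exons = _split_into_exons(rng, start, start + span, n_ex)
            models.append(
                GeneModel(
                    gene_id=f"g{counter:03d}",
                    part_id=f"g{counter:03d}_p1",
                    contig=ctg,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                    product_class="CDS" if is_cds else "tRNA",
                )
            )
    return models


def _split_into_exons(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> list[tuple[int, int]]:
    span = end - start
    if n_exons == 1 or span < n_exons * 150 + (n_exons - 1) * 120:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(150, span - 150), size=2 * (n_exons - 1), replace=False))
    exons = []
    pos = start
    for i in range(n_exons - 1):
        ex_end = start + int(cuts[2 * i])
        intron_end = start + int(cuts[2 * i + 1])
        if ex_end - pos >= 30 and intron_end > ex_end:
            exons.append((pos, ex_end))
            pos = intron_end
    exons.append((pos, end))
    return [iv for iv in exons if iv[1] > iv[0]]


def _plant_dispersed(
    rng: np.random.Generator, seqs: dict[str, str], contigs: list[str], n: int
) -> list[tuple[str, tuple[str, int, int], tuple[str, int, int]]]:
    """Write small F/P repeat pairs into contig sequences (registry is the
    planted location; chance flank matches may extend the maximal pair by a
    base or two, so consumers should test for containment, not equality)."""
    out = []
    big = [c for c in contigs if len(seqs[c]) >= 3_000]
    for _ in range(n):
        if not big:
            break
        length = int(rng.integers(80, 300))
        src_ctg = big[int(rng.integers(len(big)))]
        dst_ctg = big[int(rng.integers(len(big)))]
        src = int(rng.integers(500, len(seqs[src_ctg]) - length - 500))
        dst = int(rng.integers(500, len(seqs[dst_ctg]) - length - 500))
        if src_ctg == dst_ctg and abs(dst - src) < length + 10:
            continue
        cls = "F" if rng.random() < 0.6 else "P"
        block = seqs[src_ctg][src : src + length]
        payload = block if cls == "F" else revcomp(block)
        s = seqs[dst_ctg]
        seqs[dst_ctg] = s[:dst] + payload + s[dst + length :]
        out.append((cls, (src_ctg, src, length), (dst_ctg, dst, length)))
    return out


def _plant_ssrs(
    rng: np.random.Generator, seqs: dict[str, str], contigs: list[str], n: int
) -> list[tuple[str, str, int, int]]:
    """Write microsatellite runs into contig sequences; returns
    (contig, motif, start, count) records."""
    motifs = ["A", "T", "AT", "AG", "CT", "AAG", "AAT"]
    minima = {1: 10, 2: 6, 3: 5}
    out = []
    big = [c for c in contigs if len(seqs[c]) >= 3_000]
    for _ in range(n):
        if not big:
            break
        motif = motifs[int(rng.integers(len(motifs)))]
        count = int(minima[len(motif)] + rng.integers(2, 9))
        run = motif * count
        ctg = big[int(rng.integers(len(big)))]
        pos = int(rng.integers(500, len(seqs[ctg]) - len(run) - 500))
        s = seqs[ctg]
        seqs[ctg] = s[:pos] + run + s[pos + len(run) :]
        out.append((ctg, motif, pos, count))
    return out


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _cross_junctions(
    attachments: dict[str, dict[str, list[End]]],
    direct_links: list[tuple[End, End]],
) -> list[Junction]:
    """All left x right contig-end pairs across each repeat, plus direct links."""
    out: list[Junction] = []
    for rep in sorted(attachments):
        for ea in attachments[rep]["L"]:
            for eb in attachments[rep]["R"]:
                out.append(Junction(ea, eb, mediator=rep, mediator_orient="+"))
    for ea, eb in direct_links:
        out.append(Junction(ea, eb, mediator=None))
    return out


def _junction_context(seqs: dict[str, str], j: Junction) -> str:
    """The local conformation sequence reading through a junction."""
    ca, sa = j.end_a
    cb, sb = j.end_b
    left = seqs[ca] if sa == "R" else revcomp(seqs[ca])
    right = seqs[cb] if sb == "L" else revcomp(seqs[cb])
    med = ""
    if j.mediator is not None:
        med = seqs[j.mediator]
        if j.mediator_orient == "-":
            med = revcomp(med)
    return left + med + right


def simulate_structure(
    spec: TruthSpec,
) -> tuple[SyntheticTruth, AssemblyGraph, list[SegmentRecord]]:
    """Generate one reticulate genome: truth registry, DBG graph, stable contigs.

    The emitted GFA is repeat-collapsed: each repeat is one segment linked to
    every neighbouring contig end; unique segments may additionally be split
    into 1..max_fragments colinear graph pieces (a DBG fragments unique
    sequence too), which the stable contigs then span.
    """
    spec.validate()
    # namespaced stream: the same integer seed used for another generator
    # (e.g. the nuclear simulator) must never reproduce these draws
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5712C7]))

    # --- segment identities and lengths
    if spec.unique_segments is not None:
        contig_ids = [name for name, _ in spec.unique_segments]
        contig_lens = {name: length for name, length in spec.unique_segments}
    else:
        contig_ids = [f"ctg{i + 1}" for i in range(spec.n_unique_segments)]
        lo, hi = spec.unique_len_range
        contig_lens = {c: int(rng.integers(lo, hi + 1)) for c in contig_ids}
    repeat_ids = spec.repeat_names()
    repeat_lens = {r: length for r, (length, _) in zip(repeat_ids, spec.repeat_segments)}
    copy_of = {r: copy for r, (_, copy) in zip(repeat_ids, spec.repeat_segments)}

    seqs = {c: random_dna(rng, contig_lens[c], spec.gc_target) for c in contig_ids}
    seqs.update({r: random_dna(rng, repeat_lens[r], spec.gc_target) for r in repeat_ids})
    planted_dispersed = _plant_dispersed(rng, seqs, contig_ids, spec.plant_dispersed)
    planted_ssrs = _plant_ssrs(rng, seqs, contig_ids, spec.plant_ssrs)

    # --- wiring
    direct_links: list[tuple[End, End]] = []
    if spec.junction_edges is not None:
        attachments = {r: {"L": [], "R": []} for r in repeat_ids}
        for end1, end2 in spec.junction_edges:
            (a, sa), (b, sb) = end1, end2
            if a in attachments and b in attachments:
                raise ValueError("repeat-to-repeat junction edges are not supported")
            if b in attachments:
                (a, sa), (b, sb) = (b, sb), (a, sa)
            if a in attachments:
                attachments[a][sa].append((b, sb))
            else:
                direct_links.append(((a, sa), (b, sb)))
        for rep in repeat_ids:
            for side in ("L", "R"):
                got = len(attachments[rep][side])
                if got != copy_of[rep]:
                    raise ValueError(
                        f"repeat {rep} has {got} attachments on side {side}, "
                        f"expected copy number {copy_of[rep]}"
                    )
    else:
        attachments = (
            _random_attachments(
                rng, contig_ids, [(r, copy_of[r]) for r in repeat_ids]
            )
            if repeat_ids
            else {}
        )

    junctions = _cross_junctions(attachments, direct_links)
    _check_connected(contig_ids, junctions)

    # --- minor contigs and gene models
    n_minor = int(round(spec.minor_contig_fraction * len(contig_ids)))
    n_minor = min(n_minor, max(0, len(contig_ids) - 1))
    minor = {str(c) for c in rng.permutation(contig_ids)[:n_minor]}
    genes = _plant_genes(rng, contig_lens, minor, spec.gene_every)

    # --- graph: fragment unique segments into colinear pieces
    graph = AssemblyGraph()
    piece_map: dict[str, list[tuple[str, int, int]]] = {}
    for ctg in contig_ids:
        length = contig_lens[ctg]
        n_pieces = 1
        if spec.max_fragments > 1 and length >= 1000:
            n_pieces = int(rng.integers(1, spec.max_fragments + 1))
        cuts = []
        if n_pieces > 1:
            cuts = sorted(
                int(x) for x in rng.choice(
                    np.arange(500, length - 500), size=n_pieces - 1, replace=False
                )
            )
        bounds = [0] + cuts + [length]
        pieces = []
        base_depth = spec.depth_mean * (
            spec.minor_depth_ratio if ctg in minor else 1.0
        )
        for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
            pid = ctg if len(bounds) == 2 else f"{ctg}.p{i + 1}"
            depth = base_depth * _lognormal(rng, spec.depth_noise_cv)
            graph.add_segment(SegmentRecord(pid, seqs[ctg][s:e], depth))
            pieces.append((pid, s, e))
        piece_map[ctg] = pieces
        for (p1, _, _), (p2, _, _) in zip(pieces, pieces[1:]):
            graph.add_link(p1, "+", p2, "+")
    for rep in repeat_ids:
        depth = spec.depth_mean * copy_of[rep] * _lognormal(rng, spec.depth_noise_cv)
        graph.add_segment(SegmentRecord(rep, seqs[rep], depth))

    def graph_end(end: End) -> End:
        ctg, side = end
        if ctg in piece_map:
            pieces = piece_map[ctg]
            return (pieces[0][0], "L") if side == "L" else (pieces[-1][0], "R")
        return end

    for rep in repeat_ids:
        for side in ("L", "R"):
            for end in attachments[rep][side]:
                graph.add_link(*_make_link(graph_end(end), (rep, side)))
    for ea, eb in direct_links:
        graph.add_link(*_make_link(graph_end(ea), graph_end(eb)))

    # --- outputs
    contigs = [SegmentRecord(c, seqs[c]) for c in contig_ids]
    copy_numbers = {c: 1 for c in contig_ids}
    copy_numbers.update({pid: 1 for ps in piece_map.values() for pid, _, _ in ps})
    copy_numbers.update(copy_of)
    genome_length = sum(contig_lens.values()) + sum(
        repeat_lens[r] * copy_of[r] for r in repeat_ids
    )
    contexts = {j.signature: _junction_context(seqs, j) for j in junctions}
    truth = SyntheticTruth(
        spec=spec,
        segment_sequences=seqs,
        contig_ids=contig_ids,
        repeat_ids=repeat_ids,
        attachments=attachments,
        direct_links=direct_links,
        true_junctions=junctions,
        true_copy_numbers=copy_numbers,
        minor_contigs=minor,
        gene_models=genes,
        piece_map=piece_map,
        genome_length=genome_length,
        contexts=contexts,
        planted_dispersed=planted_dispersed,
        planted_ssrs=planted_ssrs,
    )
    return truth, graph, contigs


def _check_connected(contig_ids: list[str], junctions: list[Junction]) -> None:
    if len(contig_ids) <= 1:
        return
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(contig_ids)
    for j in junctions:
        g.add_edge(j.end_a[0], j.end_b[0])
    if not nx.is_connected(g):
        raise ValueError("disconnected junction spec: junction multigraph is not connected")


def rewire_junctions(
    truth: SyntheticTruth, n_moves: int = 1, seed: int = 0
) -> tuple[SyntheticTruth, AssemblyGraph]:
    """Move ``n_moves`` repeat attachments to different contig ends.

    Models an accession sharing contigs but differing in linkage (the
    R931945-2-2 pattern: same type, a couple of different contig linkages).
    Each move changes ``copy_number`` junctions of one repeat. Returns a new
    self-consistent truth plus the rebuilt graph; contig ids, lengths and
    copy numbers are preserved while sequences and depths are re-drawn.
    """
    all_ends = [(c, s) for c in truth.contig_ids for s in ("L", "R")]
    reps = sorted(truth.attachments)
    last_err: Exception | None = None
    for attempt in range(64):  # a move may disconnect the multigraph; retry
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        att = {
            r: {s: list(v) for s, v in sides.items()}
            for r, sides in truth.attachments.items()
        }
        for _ in range(n_moves):
            rep = reps[rng.integers(len(reps))]
            side = "L" if rng.random() < 0.5 else "R"
            idx = int(rng.integers(len(att[rep][side])))
            current = set(att[rep][side])
            candidates = [e for e in all_ends if e not in current]
            att[rep][side][idx] = candidates[rng.integers(len(candidates))]
        new_spec = replace(
            truth.spec,
            junction_edges=[
                ((rep, s_rep), end)
                for rep in reps
                for s_rep in ("L", "R")
                for end in att[rep][s_rep]
            ]
            + list(truth.direct_links),
            unique_segments=[
                (c, len(truth.segment_sequences[c])) for c in truth.contig_ids
            ],
        )
        try:
            new_truth, new_graph, _ = simulate_structure(new_spec)
        except ValueError as err:
            last_err = err
            continue
        return new_truth, new_graph
    raise ValueError(f"could not rewire into a connected structure: {last_err}")


# ---------------------------------------------------------------------------
# presets emulating the three structural types
# ---------------------------------------------------------------------------

_PRESETS = {
    # 9 contigs, three copy-2 repeats -> 12 cross junctions (the type-I worked
    # example: all 12 linkages over nine contigs); two gene-free minor contigs.
    "I": dict(
        n_unique_segments=9,
        unique_len_range=(30_000, 54_000),
        repeat_segments=[(12_400, 2), (3_600, 2), (4_000, 2)],
        minor_contig_fraction=2 / 9,
    ),
    # 6 contigs, ~395 kbp, two repeats -> 8 junctions.
    "II": dict(
        n_unique_segments=6,
        unique_len_range=(45_000, 62_000),
        repeat_segments=[(12_400, 2), (33_000, 2)],
        minor_contig_fraction=0.0,
    ),
    # 6 contigs, ~444 kbp, three repeats -> 12 junctions.
    "III": dict(
        n_unique_segments=6,
        unique_len_range=(48_000, 66_000),
        repeat_segments=[(12_400, 2), (4_000, 2), (33_000, 2)],
        minor_contig_fraction=0.0,
    ),
}


def preset_spec(label: str, seed: int = 0, scale: float = 1.0) -> TruthSpec:
    """A TruthSpec emulating structural type I, II or III.

    ``scale`` < 1 shrinks all lengths proportionally (floor 600 bp) for quick
    demonstrations; counts, copy numbers and depths are unchanged.
    """
    if label not in _PRESETS:
        raise ValueError(f"unknown preset {label!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[label])
    if scale != 1.0:
        lo, hi = kw["unique_len_range"]
        kw["unique_len_range"] = (max(600, int(lo * scale)), max(1200, int(hi * scale)))
        kw["repeat_segments"] = [
            (max(600, int(length * scale)), copy) for length, copy in kw["repeat_segments"]
        ]
    return TruthSpec(seed=seed, **kw)


def random_spec(
    seed: int,
    n_unique_range: tuple[int, int] = (6, 9),
    unique_len_range: tuple[int, int] = (6_000, 12_000),
    repeat_len_range: tuple[int, int] = (2_000, 4_000),
    depth_range: tuple[float, float] = (50.0, 85.0),
    depth_noise_cv: float = 0.1,
    minor_contig_fraction: float = 0.125,
) -> TruthSpec:
    """Random study-condition spec for recovery ensembles: 6-9 contigs,
    copy-2 repeats of >=2 kbp, depth 50-85x, lognormal noise at CV 0.1.

    The repeat count is drawn from {2, 3} subject to the connectivity
    constraint (each copy-2 repeat offers four attachment slots, so m repeats
    can tie together at most 4m - m + 1 contigs).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A11DA]))
    n = int(rng.integers(n_unique_range[0], n_unique_range[1] + 1))
    m_min = max(2, -(-(n - 1) // 3))  # ceil((n-1)/3), at least 2
    m = int(rng.integers(m_min, 4))
    repeats = [
        (int(rng.integers(repeat_len_range[0], repeat_len_range[1] + 1)), 2)
        for _ in range(m)
    ]
    return TruthSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_unique_segments=n,
        unique_len_range=unique_len_range,
        repeat_segments=repeats,
        depth_mean=float(rng.uniform(*depth_range)),
        minor_contig_fraction=minor_contig_fraction,
        depth_noise_cv=depth_noise_cv,
    )


# ---------------------------------------------------------------------------
# nuclear genomes with planted organellar insertions
# ---------------------------------------------------------------------------


def _alignment_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment of a vs b (matches over
    alignment columns, minimum-edit path)."""
    if a == b:
        return 1.0
    result = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for length, op in _CIGAR_OPS.findall(result["cigar"]):
        columns += int(length)
        if op == "=":
            matches += int(length)
    return matches / columns


def _apply_edits(
    rng: np.random.Generator, seq: str, e: int
) -> tuple[str, int, int, int]:
    """Apply e edits: 90% substitutions, 10% single-base indels (half ins)."""
    L = len(seq)
    n_indel = int(round(0.1 * e))
    n_ins = int(round(0.05 * e))
    n_del = n_indel - n_ins
    n_sub = e - n_indel
    bases = "ACGT"
    chars = list(seq)
    pos = rng.choice(L, size=n_sub + n_del, replace=False)
    sub_pos, del_pos = pos[:n_sub], pos[n_sub:]
    for p in sub_pos:
        old = chars[p]
        alts = [b for b in bases if b != old]
        chars[p] = alts[int(rng.integers(3))]
    for p in sorted(del_pos, reverse=True):
        del chars[int(p)]
    for p in sorted(rng.integers(0, len(chars) + 1, size=n_ins), reverse=True):
        chars.insert(int(p), bases[int(rng.integers(4))])
    return "".join(chars), n_sub, n_ins, n_del


def mutate_to_identity(
    rng: np.random.Generator, seq: str, target_identity: float
) -> tuple[str, float, int, int, int]:
    """Mutate ``seq`` so that its alignment identity to the original is as
    close as possible to ``target_identity``.

    Edits are 90% substitutions and 10% single-base indels (half insertions).
    The realized identity is measured on the optimal (minimum-edit) global
    alignment of the mutated copy against the original - adjacent random
    edits occasionally compress, so the optimal path, which is what any
    aligner will see, is the recorded truth. The edit count is adjusted
    until the realized value is within +/-0.5 points of the target (subject
    to the 1/length granularity). Returns
    (mutated, realized_identity, n_sub, n_ins, n_del).
    """
    L = len(seq)
    if target_identity >= 1.0:
        return seq, 1.0, 0, 0, 0
    e = int(round((1.0 - target_identity) * L))
    best: tuple[float, tuple] | None = None
    for _ in range(8):
        e = max(1, min(e, int(L * 0.45)))
        mutated, n_sub, n_ins, n_del = _apply_edits(rng, seq, e)
        realized = _alignment_identity(mutated, seq)
        gap = abs(realized - target_identity)
        if best is None or gap < best[0]:
            best = (gap, (mutated, realized, n_sub, n_ins, n_del))
        if gap <= 0.005:
            break
        # one edit moves identity by roughly 1/L
        e += int(round((realized - target_identity) * L)) or (
            1 if realized > target_identity else -1
        )
    return best[1]


def _plant_nuclear_genes(
    rng: np.random.Generator, length: int, density: float, chrom: str
) -> list[GeneModel]:
    n_genes = int(round(density * length / 1e6))
    models = []
    if n_genes == 0:
        return models
    # evenly spaced loci with jitter keeps genes non-overlapping by design
    pitch = length // (n_genes + 1)
    for i in range(n_genes):
        centre = (i + 1) * pitch + int(rng.integers(-pitch // 6, pitch // 6 + 1))
        span = int(rng.integers(2_000, min(6_000, max(2_001, pitch // 2))))
        start = max(1_000, centre - span // 2)
        end = min(length - 1_000, start + span)
        if end - start < 1_200:
            continue
        n_ex = int(rng.integers(2, 5))
        exons = _split_into_exons(rng, start, end, n_ex)
        models.append(
            GeneModel(
                gene_id=f"{chrom}g{i + 1:04d}",
                part_id=f"{chrom}g{i + 1:04d}_p1",
                contig=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
            )
        )
    return models


def _region_intervals(
    models: list[GeneModel], length: int
) -> dict[str, list[tuple[int, int]]]:
    exons = sorted(iv for m in models for iv in m.exons)
    spans = sorted(m.span for m in models)
    introns = []
    for m in models:
        s, e = m.span
        pos = s
        for xs, xe in m.exons:
            if xs > pos:
                introns.append((pos, xs))
            pos = xe
        if pos < e:
            introns.append((pos, e))
    intergenic = []
    pos = 0
    for s, e in spans:
        if s > pos:
            intergenic.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        intergenic.append((pos, length))
    return {"exon": exons, "intron": sorted(introns), "intergenic": intergenic}


def simulate_nuclear_with_inserts(
    organelles: dict[str, dict[str, str]],
    nuclear_len: int,
    annotation_density: float,
    inserts: list[tuple[str, int, float, str]],
    seed: int = 0,
    gc: float = 0.37,
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Build a nuclear chromosome with planted organellar insertions.

    ``organelles`` maps source name ("mt"/"pt") to its sequence dict;
    ``inserts`` is a list of (source, length, target_identity, region_class)
    with region_class one of exon/intron/intergenic. The registry records the
    exact realized identity and final nuclear coordinates of every insert.
    A feature whose class hosts an insert is stretched around it, so the
    insert genuinely resides in that region class of the final annotation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9C1EA2]))
    for src, length, ident, region in inserts:
        if not 0.70 <= ident <= 1.00:
            raise ValueError(f"target identity {ident} outside [0.70, 1.00]")
        if length < 50:
            raise ValueError(f"insert length {length} below the 50 bp minimum")
        if src not in organelles:
            raise ValueError(f"unknown organelle source {src!r}")
    background = random_dna(rng, nuclear_len, gc)
    models = _plant_nuclear_genes(rng, nuclear_len, annotation_density, chrom)
    regions = _region_intervals(models, nuclear_len)

    planned = []
    used_points: set[int] = set()
    for src, length, ident, region in inserts:
        pool = [iv for iv in regions[region] if iv[1] - iv[0] > 40]
        if not pool:
            raise ValueError(f"no {region!r} intervals available in the annotation")
        org_seqs = organelles[src]
        fitting = sorted(o for o, s in org_seqs.items() if len(s) >= length)
        if not fitting:
            raise ValueError(
                f"no {src} sequence is long enough for a {length} bp insert"
            )
        org_id = fitting[int(rng.integers(len(fitting)))]
        org_seq = org_seqs[org_id]
        org_start = int(rng.integers(0, len(org_seq) - length + 1))
        source_seq = org_seq[org_start : org_start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        payload = source_seq if strand == "+" else revcomp(source_seq)
        mutated, realized, n_sub, n_ins, n_del = mutate_to_identity(
            rng, payload, ident
        )
        for _ in range(200):
            s, e = pool[int(rng.integers(len(pool)))]
            margin = min(15, (e - s) // 3)
            point = int(rng.integers(s + margin, e - margin))
            if point not in used_points:
                used_points.add(point)
                break
        planned.append(
            dict(
                source=src,
                org_id=org_id,
                org_start=org_start,
                org_end=org_start + length,
                strand=strand,
                point=point,
                seq=mutated,
                target_identity=ident,
                realized_identity=realized,
                region=region,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )
    planned.sort(key=lambda d: d["point"])

    def offset_before(x: int) -> int:
        return sum(len(p["seq"]) for p in planned if p["point"] <= x)

    def offset_strict(x: int) -> int:
        return sum(len(p["seq"]) for p in planned if p["point"] < x)

    parts, pos = [], 0
    for p in planned:
        parts.append(background[pos : p["point"]])
        parts.append(p["seq"])
        pos = p["point"]
    parts.append(background[pos:])
    final_seq = "".join(parts)

    shifted_models = []
    for m in models:
        shifted_models.append(
            GeneModel(
                gene_id=m.gene_id,
                part_id=m.part_id,
                contig=m.contig,
                strand=m.strand,
                exons=[(s + offset_before(s), e + offset_before(e)) for s, e in m.exons],
                product_class=m.product_class,
            )
        )

    rows = []
    for p in planned:
        start = p["point"] + offset_strict(p["point"])
        rows.append(
            dict(
                source=p["source"],
                org_id=p["org_id"],
                org_start=p["org_start"],
                org_end=p["org_end"],
                chrom=chrom,
                nuc_start=start,
                nuc_end=start + len(p["seq"]),
                strand=p["strand"],
                target_identity=p["target_identity"],
                realized_identity=p["realized_identity"],
                region=p["region"],
                n_sub=p["n_sub"],
                n_ins=p["n_ins"],
                n_del=p["n_del"],
                insert_gc=gc_content(p["seq"]),
            )
        )
    registry = pd.DataFrame(
        rows,
        columns=[
            "source", "org_id", "org_start", "org_end", "chrom", "nuc_start",
            "nuc_end", "strand", "target_identity", "realized_identity",
            "region", "n_sub", "n_ins", "n_del", "insert_gc",
        ],
    )
    return {chrom: final_seq}, shifted_models, registry


# ---------------------------------------------------------------------------
# CDS SNP injection
# ---------------------------------------------------------------------------


def inject_cds_snps(
    base_cds: dict[str, str],
    accessions: list[str],
    group_of: dict[str, str],
    n_snp_genes: int,
    intermediate: str | None = None,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame, str | None]:
    """Plant one biallelic substitution per chosen gene, splitting the groups.

    Accessions in the intermediate's own (base) group carry the reference
    allele, all other groups the alternate. The intermediate accession takes
    its base-group allele everywhere except at one designated gene where it
    takes the other allele (the nad6-style exception). Returns per-accession
    CDS sets, the truth SNP table, and the designated exception gene.
    """
    genes = sorted(base_cds)
    if n_snp_genes > len(genes):
        raise ValueError(
            f"n_snp_genes={n_snp_genes} exceeds the {len(genes)} available genes"
        )
    groups = sorted(set(group_of.values()))
    if len(groups) < 2:
        raise ValueError("need at least two accession groups")
    if intermediate is not None and intermediate not in accessions:
        raise ValueError(f"intermediate accession {intermediate!r} not in accessions")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCD51F1]))
    base_group = group_of[intermediate] if intermediate else groups[0]

    snp_genes = sorted(str(g) for g in rng.choice(genes, size=n_snp_genes, replace=False))
    exception_gene = (
        str(snp_genes[int(rng.integers(n_snp_genes))])
        if intermediate and n_snp_genes
        else None
    )

    per_acc: dict[str, dict[str, str]] = {a: dict(base_cds) for a in accessions}
    rows = []
    for gene in snp_genes:
        seq = base_cds[gene]
        pos = int(rng.integers(0, len(seq)))
        ref = seq[pos]
        alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
        alleles = {}
        for acc in accessions:
            take_alt = group_of[acc] != base_group
            if acc == intermediate:
                take_alt = gene == exception_gene
            if take_alt:
                s = per_acc[acc][gene]
                per_acc[acc][gene] = s[:pos] + alt + s[pos + 1 :]
            alleles[acc] = alt if take_alt else ref
        rows.append(dict(gene=gene, pos=pos, ref=ref, alt=alt, **alleles))
    truth = pd.DataFrame(rows, columns=["gene", "pos", "ref", "alt", *accessions])
    return per_acc, truth, exception_gene
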