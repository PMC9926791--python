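"""Ortholog CDS extraction, SNP calling, and allele-sharing groups.

Plant mitochondrial CDSs evolve very slowly: across accessions of one
species most genes are identical and the few variable genes carry single
biallelic substitutions. Accessions are grouped by the majority bipartition
those shared SNPs induce; an accession that disagrees with its group at some
sites (concordance < 1) is flagged intermediate — the signature of a
complex-pedigree line that clusters with one group at all loci except one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import banded_global
from .formats import GeneModel
from .seqs import revcomp

LENGTH_DISCORDANCE = 0.10
MAX_GAP_FRACTION = 0.5


@dataclass
class SNPSite:
    gene: str
    column: int  # 1-based alignment/reference column
    alleles: dict[str, str]  # accession -> base (gaps omitted)

    def bipartition(self) -> tuple[tuple[str, ...], ...]:
        """Canonical allele-induced partition of the accessions."""
        by_allele: dict[str, list[str]] = {}
        for acc, base in self.alleles.items():
            by_allele.setdefault(base, []).append(acc)
        parts = sorted(tuple(sorted(v)) for v in by_allele.values())
        return tuple(parts)


@dataclass
class GroupingResult:
    groups: tuple[tuple[str, ...], ...]
    concordance: dict[str, float]
    intermediates: list[str]
    ambiguous: bool = False
    n_sites: int = 0
    length_discordant: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def extract_cds(genome: dict[str, str], models: list[GeneModel]) -> dict[str, str]:
    """Spliced CDS per gene from one genome.

    Exons are concatenated in genomic order and reverse-complemented for
    minus-strand parts; multi-contig genes are assembled in declared
    part order. Non-CDS models (tRNA/rRNA) are skipped.
    """
    parts: dict[str, list[tuple[int, str]]] = {}
    for m in models:
        if m.product_class != "CDS":
            continue
        if m.contig not in genome:
            raise ValueError(f"gene {m.gene_id}: contig {m.contig} not in genome")
        seq = genome[m.contig]
        for s, e in m.exons:
            if e > len(seq):
                raise ValueError(
                    f"gene {m.gene_id}: exon [{s}, {e}) outside contig "
                    f"{m.contig} of length {len(seq)}"
                )
        spliced = "".join(seq[s:e] for s, e in m.exons)
        if m.strand == "-":
            spliced = revcomp(spliced)
        parts.setdefault(m.gene_id, []).append((m.part_order, spliced))
    out = {}
    for gene, chunk in parts.items():
        out[gene] = "".join(s for _, s in sorted(chunk))
    return out


def extract_cds_panel(
    genomes: dict[str, dict[str, str]],
    models: dict[str, list[GeneModel]],
) -> dict[str, dict[str, str]]:
    """gene -> accession -> spliced CDS across a panel of accessions."""
    panel: dict[str, dict[str, str]] = {}
    for acc in sorted(genomes):
        for gene, seq in extract_cds(genomes[acc], models[acc]).items():
            panel.setdefault(gene, {})[acc] = seq
    return panel


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------


def _column_matrix(seqs: dict[str, str]) -> tuple[dict[str, str], list[str]]:
    """Place every accession's CDS on common columns.

    Equal-length sets are compared column-wise directly. Otherwise each
    sequence is globally aligned (match +1, mismatch -1, gap -2) to a
    reference of the modal length and projected onto reference columns;
    insertions relative to the reference are not columns.
    """
    accs = sorted(seqs)
    lens = {len(seqs[a]) for a in accs}
    if len(lens) == 1:
        return dict(seqs), accs
    modal_len = Counter(len(seqs[a]) for a in accs).most_common(1)[0][0]
    ref_acc = next(a for a in accs if len(seqs[a]) == modal_len)
    ref = seqs[ref_acc]
    rows = {ref_acc: ref}
    for acc in accs:
        if acc == ref_acc:
            continue
        aln_a, aln_r, _ = banded_global(seqs[acc], ref)
        row = []
        for ca, cr in zip(aln_a, aln_r):
            if cr != "-":  # reference columns only
                row.append(ca)
        rows[acc] = "".join(row)
    return rows, accs


def call_snps(orthologs: dict[str, dict[str, str]]) -> tuple[list[SNPSite], list[str]]:
    """Variable columns per gene across accessions.

    Genes whose CDS lengths differ by more than 10% from the median are
    reported length-discordant and excluded (near-identical orthologs are
    expected; larger divergence signals an annotation problem). Columns
    gapped in more than half the accessions are skipped; gaps are not
    alleles. Returns (sites, length_discordant_genes).
    """
    sites: list[SNPSite] = []
    discordant: list[str] = []
    for gene in sorted(orthologs):
        seqs = orthologs[gene]
        if len(seqs) < 2:
            continue
        lens = sorted(len(s) for s in seqs.values())
        med = lens[len(lens) // 2]
        if med == 0 or (lens[-1] - lens[0]) / med > LENGTH_DISCORDANCE:
            discordant.append(gene)
            continue
        rows, accs = _column_matrix(seqs)
        n_cols = min(len(rows[a]) for a in accs)
        for col in range(n_cols):
            column = {a: rows[a][col] for a in accs}
            bases = {a: b for a, b in column.items() if b in "ACGT"}
            if len(bases) < len(accs) * (1 - MAX_GAP_FRACTION):
                continue
            if len(set(bases.values())) >= 2:
                sites.append(SNPSite(gene=gene, column=col + 1, alleles=bases))
    return sites, discordant


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def group_accessions(sites: list[SNPSite]) -> GroupingResult:
    """Consensus groups from the majority bipartition across SNP sites.

    Per-accession concordance is the fraction of sites where the accession
    carries its group's majority allele; any accession below 1.0 is an
    intermediate. A tie between bipartitions is broken lexicographically on
    the canonical partition string and flagged ambiguous.
    """
    if not sites:
        raise ValueError("need at least one SNP site to group accessions")
    counts = Counter(site.bipartition() for site in sites)
    top = max(counts.values())
    winners = sorted(str(p) for p, c in counts.items() if c == top)
    ambiguous = len(winners) > 1
    consensus = next(p for p in counts if str(p) == winners[0])

    group_of = {acc: gi for gi, part in enumerate(consensus) for acc in part}
    accs = sorted(group_of)
    agree = {a: 0 for a in accs}
    seen = {a: 0 for a in accs}
    for site in sites:
        for gi, part in enumerate(consensus):
            members = [a for a in part if a in site.alleles]
            if not members:
                continue
            tally = Counter(site.alleles[a] for a in members)
            majority = sorted(tally, key=lambda b: (-tally[b], b))[0]
            for a in members:
                seen[a] += 1
                if site.alleles[a] == majority:
                    agree[a] += 1
    concordance = {
        a: (agree[a] / seen[a]) if seen[a] else 1.0 for a in accs
    }
    intermediates = sorted(a for a in accs if concordance[a] < 1.0)
    return GroupingResult(
        groups=consensus,
        concordance=concordance,
        intermediates=intermediates,
        ambiguous=ambiguous,
        n_sites=len(sites),
    )
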