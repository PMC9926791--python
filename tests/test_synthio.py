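from collections import Counter

import numpy as np
import pytest

from mitoweaver import synthio
from mitoweaver.formats import write_fasta, write_gfa
from mitoweaver.junctions import Junction
from mitoweaver.seqs import gc_content, random_dna
from mitoweaver.synthio import (
    TruthSpec, inject_cds_snps, mutate_to_identity, preset_spec,
    simulate_nuclear_with_inserts, simulate_structure,
)
from mitoweaver.transferscan import RegionIndex


class TestStructureSimulation:
    def test_explicit_cross_wiring_matches_hand_enumeration(self):
        # A-R-B / C-R: one copy-2 repeat with contig ends A.R, C.R on its
        # left and B.L, C.L on its right -> 4 links at R, 4 cross junctions
        spec = TruthSpec(
            seed=1,
            unique_segments=[("A", 2000), ("B", 2000), ("C", 2000)],
            repeat_segments=[(600, 2)],
            junction_edges=[
                (("A", "R"), ("rep1", "L")),
                (("C", "R"), ("rep1", "L")),
                (("rep1", "R"), ("B", "L")),
                (("rep1", "R"), ("C", "L")),
            ],
            max_fragments=1,
            minor_contig_fraction=0.0,
        )
        truth, graph, contigs = simulate_structure(spec)
        assert len(graph.segments) == 4
        assert len(contigs) == 3
        assert len(graph.links_at("rep1", "L")) + len(graph.links_at("rep1", "R")) == 4
        expected = {
            Junction(("A", "R"), ("B", "L"), "rep1").signature,
            Junction(("A", "R"), ("C", "L"), "rep1").signature,
            Junction(("C", "R"), ("B", "L"), "rep1").signature,
            Junction(("C", "R"), ("C", "L"), "rep1").signature,
        }
        assert set(truth.junction_multiset()) == expected

    def test_single_circle_degenerate_case(self):
        spec = TruthSpec(
            seed=0, n_unique_segments=1, unique_len_range=(2000, 2500),
            repeat_segments=[], minor_contig_fraction=0.0, max_fragments=1,
        )
        truth, graph, contigs = simulate_structure(spec)
        assert len(contigs) == 1
        assert truth.true_junctions == []
        assert len(graph.segments) == 1 and len(graph.links) == 0

    def test_type_one_preset_has_twelve_junctions_over_nine_contigs(self):
        truth, graph, contigs = simulate_structure(preset_spec("I", seed=3, scale=0.1))
        assert len(contigs) == 9
        assert len(truth.true_junctions) == 12

    def test_length_conservation_is_exact(self, small_truth):
        truth, graph, contigs = small_truth
        spec = truth.spec
        repeats = dict(zip(truth.repeat_ids, spec.repeat_segments))
        expected = sum(len(c.sequence) for c in contigs) + sum(
            length * copy for length, copy in spec.repeat_segments
        )
        assert truth.genome_length == expected
        # graph segments at copy number reconstruct the same total (0M links)
        total = sum(
            len(rec.sequence) * truth.true_copy_numbers[s]
            for s, rec in graph.segments.items()
        )
        assert total == truth.genome_length

    def test_every_junction_is_a_short_path_in_the_gfa(self, small_truth):
        truth, graph, contigs = small_truth

        def graph_end(end):
            ctg, side = end
            pieces = truth.piece_map[ctg]
            return (pieces[0][0], "L") if side == "L" else (pieces[-1][0], "R")

        for j in truth.true_junctions:
            ea, eb = graph_end(j.end_a), graph_end(j.end_b)
            if j.mediator is None:
                assert (eb[0], eb[1]) in {
                    (s, sd) for s, sd, _ in graph.links_at(*ea)
                }
            else:
                left = {(s, sd) for s, sd, _ in graph.links_at(j.mediator, "L")}
                right = {(s, sd) for s, sd, _ in graph.links_at(j.mediator, "R")}
                assert ea in left and eb in right

    def test_seeded_determinism_byte_identical(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            spec = preset_spec("II", seed=5, scale=0.05)
            truth, graph, contigs = simulate_structure(spec)
            d = tmp_path / sub
            d.mkdir()
            write_fasta({c.id: c.sequence for c in contigs}, d / "c.fa")
            write_gfa(graph, d / "g.gfa")
            outs.append((d / "c.fa").read_bytes() + (d / "g.gfa").read_bytes())
        assert outs[0] == outs[1]

    def test_rejects_repeat_shorter_than_graph_k(self):
        spec = TruthSpec(seed=0, repeat_segments=[(40, 2)])
        with pytest.raises(ValueError, match="overlap"):
            spec.validate()

    def test_rejects_disconnected_wiring(self):
        spec = TruthSpec(
            seed=0, n_unique_segments=9,
            repeat_segments=[(2000, 2)],  # 4 slots cannot reach 9 contigs
        )
        with pytest.raises(ValueError, match="disconnected"):
            spec.validate()

    def test_minor_contigs_are_gene_free(self, small_truth):
        truth, _, _ = small_truth
        gene_contigs = {m.contig for m in truth.gene_models}
        assert not (truth.minor_contigs & gene_contigs)


class TestMutateToIdentity:
    def test_identity_target_means_no_mutations(self, rng):
        seq = random_dna(rng, 500)
        mutated, realized, s, i, d = mutate_to_identity(rng, seq, 1.0)
        assert mutated == seq and realized == 1.0 and (s, i, d) == (0, 0, 0)

    def test_realized_identity_is_the_optimal_alignment_value(self, rng):
        seq = random_dna(rng, 1000)
        mutated, realized, s, i, d = mutate_to_identity(rng, seq, 0.87)
        # the optimal path can only compress the applied edit script
        assert realized >= 1.0 - (s + i + d) / (1000 + i) - 1e-9
        assert abs(realized - 0.87) <= 0.005
        assert len(mutated) == 1000 + i - d


class TestNuclearInserts:
    def _organelles(self, rng):
        return {"mt": {"mt1": random_dna(rng, 20000, 0.44)}}

    def test_registry_mean_tracks_target_mean(self, rng):
        orgs = self._organelles(rng)
        targets = rng.uniform(0.80, 1.00, size=50)
        inserts = [("mt", 300, float(t), "intergenic") for t in targets]
        _, _, reg = simulate_nuclear_with_inserts(
            orgs, 150_000, annotation_density=0, inserts=inserts, seed=9
        )
        assert abs(reg.realized_identity.mean() - targets.mean()) <= 0.01
        assert (abs(reg.realized_identity - reg.target_identity) <= 0.005).all()

    def test_inserts_land_in_requested_region_class(self, rng):
        orgs = self._organelles(rng)
        inserts = [
            ("mt", 400, 0.95, "exon"),
            ("mt", 400, 0.95, "intron"),
            ("mt", 400, 0.95, "intergenic"),
        ]
        nuc, models, reg = simulate_nuclear_with_inserts(
            orgs, 120_000, annotation_density=80, inserts=inserts, seed=2
        )
        index = RegionIndex.from_annotation(models, {c: len(s) for c, s in nuc.items()})
        for _, row in reg.iterrows():
            ivs = index.classes[row.region][row.chrom]
            assert any(s <= row.nuc_start and row.nuc_end <= e for s, e in ivs), (
                row.region, row.nuc_start, row.nuc_end
            )

    def test_insert_sequence_identity_verified_against_source(self, rng):
        # realized identity in the registry is consistent with what a direct
        # alignment of the planted nuclear span to its source gives
        from mitoweaver.align import banded_global
        from mitoweaver.seqs import revcomp

        orgs = self._organelles(rng)
        nuc, _, reg = simulate_nuclear_with_inserts(
            orgs, 80_000, 0, [("mt", 500, 0.9, "intergenic")], seed=4
        )
        row = reg.iloc[0]
        insert = nuc[row.chrom][row.nuc_start : row.nuc_end]
        source = orgs["mt"][row.org_id][row.org_start : row.org_end]
        if row.strand == "-":
            source = revcomp(source)
        a, b, _ = banded_global(insert, source)
        matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        assert abs(100 * matches / len(a) - 100 * row.realized_identity) < 1.0

    def test_absent_region_class_is_an_error_naming_it(self, rng):
        orgs = self._organelles(rng)
        with pytest.raises(ValueError, match="exon"):
            simulate_nuclear_with_inserts(
                orgs, 50_000, annotation_density=0,
                inserts=[("mt", 200, 0.9, "exon")], seed=1,
            )

    def test_identity_and_length_preconditions(self, rng):
        orgs = self._organelles(rng)
        with pytest.raises(ValueError, match="identity"):
            simulate_nuclear_with_inserts(orgs, 50_000, 0, [("mt", 200, 0.5, "intergenic")], 1)
        with pytest.raises(ValueError, match="50"):
            simulate_nuclear_with_inserts(orgs, 50_000, 0, [("mt", 30, 0.9, "intergenic")], 1)


class TestInjectCdsSnps:
    BASE = {f"gene{i}": "ATGAAACCCGGGTTTAAACCCGGGTGA" for i in range(6)}
    ACCS = ["a1", "a2", "a3", "a4", "b1", "b2", "b3"]
    GROUPS = {"a1": "I", "a2": "I", "a3": "I", "a4": "I", "b1": "II", "b2": "II", "b3": "II"}

    def test_intermediate_matches_base_group_at_all_but_one_gene(self):
        panel, truth, exception_gene = inject_cds_snps(
            self.BASE, self.ACCS, self.GROUPS, n_snp_genes=4,
            intermediate="a4", seed=8,
        )
        assert len(truth) == 4
        agree = 0
        for _, row in truth.iterrows():
            assert {row[a] for a in self.ACCS} == {row.ref, row.alt}
            if row["a4"] == row["a1"]:
                agree += 1
            else:
                assert row.gene == exception_gene
        assert agree == 3

    def test_zero_snp_genes_means_identical_panels(self):
        panel, truth, _ = inject_cds_snps(
            self.BASE, self.ACCS, self.GROUPS, n_snp_genes=0, seed=1
        )
        assert truth.empty
        assert all(panel[a] == self.BASE for a in self.ACCS)

    def test_determinism(self):
        out1 = inject_cds_snps(self.BASE, self.ACCS, self.GROUPS, 3, "a4", seed=5)
        out2 = inject_cds_snps(self.BASE, self.ACCS, self.GROUPS, 3, "a4", seed=5)
        assert out1[0] == out2[0]
        assert out1[1].equals(out2[1])

    def test_too_many_snp_genes_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            inject_cds_snps(self.BASE, self.ACCS, self.GROUPS, 99, seed=0)


class TestPlantedScannersTruth:
    def test_gc_target_is_respected(self, small_truth):
        truth, _, contigs = small_truth
        gc = gc_content("".join(c.sequence for c in contigs))
        assert abs(gc - truth.spec.gc_target) < 0.02
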