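from collections import Counter

import pytest

from mitoweaver import reconcile, synthio
from mitoweaver.formats import AssemblyGraph, SegmentRecord
from mitoweaver.reconcile import (
    build_linkage_graph, estimate_copy_number, junction_amplicon,
    resolve_structure, thread_contig,
)
from mitoweaver.seqs import random_dna, revcomp


def _linear_graph(rng, lens=(3000, 900, 3000), names=("A", "R", "B")):
    g = AssemblyGraph()
    seqs = {}
    for name, L in zip(names, lens):
        seqs[name] = random_dna(rng, L)
        g.add_segment(SegmentRecord(name, seqs[name], depth=50.0))
    g.add_link("A", "+", "R", "+")
    g.add_link("R", "+", "B", "+")
    return g, seqs


class TestThreading:
    def test_contig_identical_to_segment(self, rng):
        g, seqs = _linear_graph(rng)
        path = thread_contig(SegmentRecord("c", seqs["A"]), g)
        assert path.path == [("A", "+")]
        assert path.anchor_coverage == 1.0

    def test_contig_spanning_repeat(self, rng):
        g, seqs = _linear_graph(rng)
        contig = SegmentRecord("c", seqs["A"] + seqs["R"] + seqs["B"])
        path = thread_contig(contig, g)
        assert path.path == [("A", "+"), ("R", "+"), ("B", "+")]
        assert path.anchor_coverage > 0.95

    def test_reverse_complement_flips_orientations(self, rng):
        g, seqs = _linear_graph(rng)
        contig = SegmentRecord("c", revcomp(seqs["A"] + seqs["R"] + seqs["B"]))
        path = thread_contig(contig, g)
        assert path.path == [("B", "-"), ("R", "-"), ("A", "-")]
        # terminal ends are expressed in the graph frame: identical mapping
        fwd = thread_contig(SegmentRecord("c", seqs["A"] + seqs["R"] + seqs["B"]), g)
        assert path.terminal_ends() == fwd.terminal_ends()

    def test_missing_link_is_an_error_naming_the_pair(self, rng):
        g = AssemblyGraph()
        a, b = random_dna(rng, 2000), random_dna(rng, 2000)
        g.add_segment(SegmentRecord("A", a, depth=1.0))
        g.add_segment(SegmentRecord("B", b, depth=1.0))
        with pytest.raises(ValueError, match="A.*B|B.*A"):
            thread_contig(SegmentRecord("c", a + b), g)

    def test_no_anchors_is_empty_not_fatal(self, rng):
        g, _ = _linear_graph(rng)
        path = thread_contig(SegmentRecord("c", random_dna(rng, 1000)), g)
        assert path.path == [] and path.anchor_coverage == 0.0

    def test_contig_shorter_than_k_rejected(self, rng):
        g, _ = _linear_graph(rng)
        with pytest.raises(ValueError, match="shorter"):
            thread_contig(SegmentRecord("c", "ACGT"), g)


class TestLinkageGraph:
    def test_single_contig_no_repeats_no_junctions(self, rng):
        g = AssemblyGraph()
        s = random_dna(rng, 2000)
        g.add_segment(SegmentRecord("A", s, depth=1.0))
        paths = [thread_contig(SegmentRecord("ctg1", s), g)]
        assert build_linkage_graph(paths, g) == []

    def test_cross_repeat_pairing(self, rng):
        # A.R and C.R on the repeat's left; B.L and C.L on its right
        g = AssemblyGraph()
        seqs = {n: random_dna(rng, 2500) for n in "ABC"}
        rep = random_dna(rng, 700)
        for n in "ABC":
            g.add_segment(SegmentRecord(n, seqs[n], depth=50.0))
        g.add_segment(SegmentRecord("R", rep, depth=100.0))
        g.add_link("A", "+", "R", "+")
        g.add_link("C", "+", "R", "+")
        g.add_link("R", "+", "B", "+")
        g.add_link("R", "+", "C", "+")
        paths = [thread_contig(SegmentRecord(n, seqs[n]), g) for n in "ABC"]
        junctions = build_linkage_graph(paths, g)
        sigs = sorted(j.signature for j in junctions)
        assert len(junctions) == 4
        assert sigs == sorted(
            [
                "A.R--B.L|R", "A.R--C.L|R", "B.L--C.R|R", "C.L--C.R|R",
            ]
        )

    def test_planted_structure_recovered_exactly(self, small_structure):
        truth, _, _, st = small_structure
        assert Counter(st.junction_multiset()) == Counter(truth.junction_multiset())

    def test_strand_invariance_of_junction_signatures(self, small_truth):
        truth, graph, contigs = small_truth
        st_fwd = resolve_structure("f", contigs, graph, truth.gene_models)
        flipped = [SegmentRecord(c.id, revcomp(c.sequence)) for c in contigs]
        st_rev = resolve_structure("r", flipped, graph, truth.gene_models)
        assert Counter(st_fwd.junction_multiset()) == Counter(st_rev.junction_multiset())
        assert st_fwd.copy_number == st_rev.copy_number


class TestCopyNumber:
    def _depth_graph(self, depths):
        g = AssemblyGraph()
        for i, d in enumerate(depths):
            g.add_segment(SegmentRecord(f"s{i}", "ACGT" * 100, depth=d))
        return g

    def test_repeat_at_twice_baseline_gets_copy_two(self):
        g = self._depth_graph([80.0, 80.0, 80.0, 160.0])
        copy, minor, baseline = estimate_copy_number(g, {"s0", "s1", "s2"})
        assert baseline == 80.0
        assert copy["s3"] == 2 and not minor["s3"]

    def test_equal_depths_all_copy_one_no_minor(self):
        g = self._depth_graph([60.0] * 5)
        copy, minor, _ = estimate_copy_number(g, {"s0", "s1"})
        assert set(copy.values()) == {1}
        assert not any(minor.values())

    def test_minor_contig_flagged_below_half_baseline(self):
        g = self._depth_graph([80.0, 80.0, 30.0])
        copy, minor, _ = estimate_copy_number(g, {"s0", "s1"})
        assert minor["s2"] and copy["s2"] == 1  # present, sub-stoichiometric

    def test_zero_baseline_is_an_error(self):
        g = self._depth_graph([0.0, 0.0, 10.0])
        with pytest.raises(ValueError, match="zero"):
            estimate_copy_number(g, {"s0", "s1"})

    def test_missing_depth_is_an_error(self):
        g = AssemblyGraph()
        g.add_segment(SegmentRecord("s0", "ACGT" * 50))
        with pytest.raises(ValueError, match="depth"):
            estimate_copy_number(g, {"s0"})

    def test_rounding_is_half_up(self):
        g = self._depth_graph([100.0, 100.0, 250.0, 149.0])
        copy, _, _ = estimate_copy_number(g, {"s0", "s1"})
        assert copy["s2"] == 3  # 2.5 rounds up
        assert copy["s3"] == 1  # 1.49 rounds down


class TestConservation:
    def test_conformation_length_equals_sum_length_times_copy(self, small_structure):
        truth, graph, _, st = small_structure
        expected = sum(
            len(rec.sequence) * st.copy_number[s] for s, rec in graph.segments.items()
        )
        assert st.conformation_length == expected
        assert st.conformation_length == truth.genome_length


class TestAmplicons:
    def test_flank_additivity_without_mediator(self, rng):
        seqs = {n: random_dna(rng, 3000) for n in ("x", "y")}
        g = AssemblyGraph()
        for n, s in seqs.items():
            g.add_segment(SegmentRecord(n, s, depth=50.0))
        g.add_link("x", "+", "y", "+")
        contigs = [SegmentRecord(n, s) for n, s in seqs.items()]
        st = resolve_structure("a", contigs, g, [], minor_fraction=0.5)
        [j] = st.junctions
        amp, length = junction_amplicon(st, j, 800, 1200)
        assert length == 2000 and len(amp) == 2000
        assert amp == seqs["x"][-800:] + seqs["y"][:1200]

    def test_mediator_length_enters_the_amplicon(self, rng):
        # a 1,995 bp gene-free mediator with 500 bp flanks -> 2,995 bp product
        g = AssemblyGraph()
        seqs = {"u1": random_dna(rng, 4000), "u2": random_dna(rng, 4000)}
        med = random_dna(rng, 1995)
        g.add_segment(SegmentRecord("u1", seqs["u1"], depth=50.0))
        g.add_segment(SegmentRecord("u2", seqs["u2"], depth=50.0))
        g.add_segment(SegmentRecord("ctg6", med, depth=400.0))
        g.add_link("u1", "+", "ctg6", "+")
        g.add_link("ctg6", "+", "u2", "+")
        contigs = [SegmentRecord(n, s) for n, s in seqs.items()]
        st = resolve_structure("a", contigs, g, [])
        [j] = st.junctions
        amp, length = junction_amplicon(st, j, 500, 500)
        assert length == 2995
        assert amp == seqs["u1"][-500:] + med + seqs["u2"][:500]

    def test_every_amplicon_is_substring_of_a_true_conformation(self, small_structure):
        truth, _, _, st = small_structure
        for j in st.junctions:
            amp, _ = junction_amplicon(st, j, 600, 600)
            ctx = truth.contexts[j.signature]
            assert amp in ctx or revcomp(amp) in ctx

    def test_flank_window_validated(self, small_structure):
        *_, st = small_structure
        with pytest.raises(ValueError, match="500-2000"):
            junction_amplicon(st, st.junctions[0], 100, 800)

    def test_unknown_junction_rejected(self, small_structure):
        from mitoweaver.junctions import Junction

        *_, st = small_structure
        ghost = Junction(("nope", "L"), ("nada", "R"), None)
        with pytest.raises(ValueError, match="not present"):
            junction_amplicon(st, ghost, 800, 800)


class TestRecoveryEnsembleSmall:
    def test_twenty_seeded_structures_recover_exactly(self):
        exact = 0
        copy_ok = copy_total = 0
        for seed in range(20):
            truth, graph, contigs = synthio.simulate_structure(synthio.random_spec(seed))
            st = resolve_structure("a", contigs, graph, truth.gene_models)
            exact += Counter(st.junction_multiset()) == Counter(truth.junction_multiset())
            for s, c in truth.true_copy_numbers.items():
                copy_total += 1
                copy_ok += st.copy_number[s] == c
        assert exact >= 19
        assert copy_ok / copy_total >= 0.99
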