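import numpy as np
import pytest

from oracles import transfer_oracle
from mitoweaver import synthio
from mitoweaver.formats import GeneModel
from mitoweaver.seqs import random_dna
from mitoweaver.transferscan import (
    RegionIndex, TransferHit, bin_counts, gc_profiles, identity_bin,
    length_bin, partition_source, region_deposition, scan_transfers,
)


class TestBinSemantics:
    @pytest.mark.parametrize(
        "identity,expected",
        [(80.0, "80-89"), (89.99, "80-89"), (90.0, "90-100"), (100.0, "90-100")],
    )
    def test_identity_bins_partition_at_ninety(self, identity, expected):
        assert identity_bin(identity) == expected

    @pytest.mark.parametrize(
        "length,expected",
        [(100, "100-199"), (199, "100-199"), (999, "900-999"), (1000, "1000+"),
         (4321, "1000+")],
    )
    def test_length_bins(self, length, expected):
        assert length_bin(length) == expected

    def test_bin_conservation(self, rng):
        mt = {"mt1": random_dna(rng, 30_000, 0.44)}
        inserts = [("mt", int(rng.integers(120, 2500)), float(rng.uniform(0.82, 1.0)),
                    "intergenic") for _ in range(12)]
        nuc, _, _ = synthio.simulate_nuclear_with_inserts(
            {"mt": mt}, 120_000, 0, inserts, seed=5
        )
        hits = scan_transfers(mt, nuc, organelle="mt")
        assert bin_counts(hits)["count"].sum() == len(hits)


class TestScan:
    def test_perfect_insert_scores_identity_one_hundred(self, rng):
        mt = {"mt1": random_dna(rng, 20_000, 0.44)}
        nuc, _, reg = synthio.simulate_nuclear_with_inserts(
            {"mt": mt}, 60_000, 0, [("mt", 800, 1.00, "intergenic")], seed=3
        )
        hits = scan_transfers(mt, nuc, organelle="mt")
        assert len(hits) == 1
        assert hits[0].identity == 100.0
        assert hits[0].identity_bin == "90-100"

    def test_planted_150bp_85pct_insert_bins(self, rng):
        mt = {"mt1": random_dna(rng, 20_000, 0.44)}
        nuc, _, reg = synthio.simulate_nuclear_with_inserts(
            {"mt": mt}, 60_000, 0, [("mt", 150, 0.85, "intergenic")], seed=7
        )
        hits = scan_transfers(mt, nuc, organelle="mt")
        assert len(hits) == 1
        assert hits[0].identity_bin == "80-89"
        assert hits[0].length_bin == "100-199"

    def test_below_threshold_identity_not_reported(self, rng):
        mt = {"mt1": random_dna(rng, 20_000, 0.44)}
        nuc, _, _ = synthio.simulate_nuclear_with_inserts(
            {"mt": mt}, 60_000, 0, [("mt", 600, 0.72, "intergenic")], seed=4
        )
        hits = scan_transfers(mt, nuc, organelle="mt")
        assert all(h.identity >= 80.0 for h in hits)
        assert not any(h.length > 400 for h in hits)

    def test_minus_strand_insert_found_with_strand_flag(self, rng):
        mt = {"mt1": random_dna(rng, 20_000, 0.44)}
        for seed in range(6):
            nuc, _, reg = synthio.simulate_nuclear_with_inserts(
                {"mt": mt}, 60_000, 0, [("mt", 700, 0.95, "intergenic")], seed=seed
            )
            [hit] = scan_transfers(mt, nuc, organelle="mt")
            assert hit.strand == reg.iloc[0].strand
            # a local aligner may keep a short net-positive flank extension
            assert abs(hit.start - reg.iloc[0].nuc_start) <= 30
            assert abs(hit.end - reg.iloc[0].nuc_end) <= 30
            assert hit.identity_bin == "90-100"

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            scan_transfers({}, {"c": "ACGT"})

    def test_oracle_equivalence_on_small_fixture(self, rng):
        from oracles import make_transfer_fixture

        mt, nuc, _ = make_transfer_fixture(6)
        mine = scan_transfers(mt, nuc, organelle="mt")
        ref = transfer_oracle(mt, nuc)
        assert len(mine) == len(ref) == 3
        for o in ref:
            match = [
                h for h in mine
                if h.chrom == o["chrom"]
                and min(h.end, o["end"]) - max(h.start, o["start"])
                >= 0.85 * (o["end"] - o["start"])
            ]
            assert match, o
            h = match[0]
            # identity conventions differ where end extents differ: the
            # score-maximizing oracle may drag extra flank into the span
            span_ratio = (h.end - h.start) / (o["end"] - o["start"])
            tolerance = 2.0 if 0.95 <= span_ratio <= 1.05 else 5.0
            assert abs(h.identity - o["identity"]) <= tolerance


class TestSourcePartition:
    def _hit(self, org_start, org_end):
        return TransferHit(
            organelle="mt", org_id="mt1", org_start=org_start, org_end=org_end,
            chrom="chr1", start=0, end=org_end - org_start, strand="+",
            identity=95.0, length=org_end - org_start,
        )

    MODELS = [GeneModel("g1", "g1_p1", "mt1", "+", [(1000, 2000)])]

    def test_hit_fully_inside_cds(self):
        df = partition_source([self._hit(1200, 1700)], self.MODELS)
        assert df.iloc[0].cds_fraction == 1.0

    def test_half_overlap_splits_evenly(self):
        df = partition_source([self._hit(500, 1500)], self.MODELS)
        assert df.iloc[0].cds_bp == 500
        assert df.iloc[0].noncds_bp == 500
        assert df.iloc[0].cds_fraction == 0.5

    def test_constructed_forty_percent_cds(self):
        hits = [self._hit(1000, 1400), self._hit(3000, 3600)]  # 400 CDS, 600 not
        df = partition_source(hits, self.MODELS)
        assert abs(df.iloc[0].cds_fraction - 0.40) < 0.01


class TestRegionDeposition:
    def _index(self, chrom_len=500_000, exon_total=250_000):
        # one synthetic annotation: alternating exon blocks to a known total
        models = []
        block = 25_000
        pos = 0
        made = 0
        i = 0
        while made < exon_total:
            models.append(
                GeneModel(f"g{i}", f"g{i}_p1", "chr1", "+", [(pos, pos + block)])
            )
            made += block
            pos += 2 * block
            i += 1
        return RegionIndex.from_annotation(models, {"chr1": chrom_len})

    def _hit(self, start, end):
        return TransferHit(
            organelle="mt", org_id="mt1", org_start=0, org_end=end - start,
            chrom="chr1", start=start, end=end, strand="+",
            identity=95.0, length=end - start,
        )

    def test_one_kbp_hit_in_quarter_megabase_exon_space(self):
        index = self._index()
        df = region_deposition([self._hit(1000, 2000)], index)
        exon_row = df[(df.region == "exon") & (df.chrom == "chr1")].iloc[0]
        assert exon_row.region_bp == 250_000
        assert exon_row.percent == pytest.approx(0.4)

    def test_no_hits_gives_zeros(self):
        df = region_deposition([], self._index())
        assert (df.percent.dropna() == 0).all()

    def test_overlapping_hits_counted_once(self):
        index = self._index()
        df = region_deposition(
            [self._hit(1000, 2000), self._hit(1500, 2500)], index
        )
        exon_row = df[df.region == "exon"].iloc[0]
        assert exon_row.covered_bp == 1500

    def test_classes_tile_the_chromosome(self):
        index = self._index()
        total = sum(
            index.lengths[("chr1", cls)] for cls in ("exon", "intron", "intergenic")
        )
        assert total == 500_000


class TestGC:
    def _hit(self, chrom, start, end, identity=95.0):
        return TransferHit(
            organelle="mt", org_id="mt1", org_start=0, org_end=end - start,
            chrom=chrom, start=start, end=end, strand="+",
            identity=identity, length=end - start,
        )

    def test_all_gc_insert_scores_hundred(self):
        nuc = {"c": "A" * 2000 + "GGCC" + "A" * 2000}
        df = gc_profiles([self._hit("c", 2000, 2004)], nuc)
        insert = df[df.kind == "insert"].iloc[0]
        assert insert.gc == 1.0
        flanks = df[df.kind != "insert"]
        assert (flanks.gc == 0.0).all()

    def test_insert_gc_exceeds_flank_gc_for_recent_transfers(self, rng):
        mt = {"mt1": random_dna(rng, 30_000, 0.44)}
        inserts = [("mt", 800, 0.97, "intergenic") for _ in range(8)]
        nuc, _, _ = synthio.simulate_nuclear_with_inserts(
            {"mt": mt}, 150_000, 0, inserts, seed=8, gc=0.37
        )
        hits = scan_transfers(mt, nuc, organelle="mt")
        df = gc_profiles(hits, nuc)
        recent = df[df.identity_bin == "90-100"]
        mean_insert = recent[recent.kind == "insert"].gc.mean()
        mean_flank = recent[recent.kind != "insert"].gc.mean()
        assert mean_insert > mean_flank
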