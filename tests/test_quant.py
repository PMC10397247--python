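"""Barcode counting, error collapsing, mapping and score quantification."""
import io
import math

import numpy as np
import pandas as pd
import pytest

from ccortho import synth
from ccortho.quant import (
    BarcodeCountTable,
    BarcodeMap,
    InteractionRecord,
    build_map,
    cluster_barcodes,
    extract_barcodes,
    interaction_scores,
    replicate_agreement,
)


def fastq_text(seqs):
    return "".join(
        f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs)
    )


BC1 = "ACGTACGTACGTACGTACGT"
BC2 = "TTTTGGGGCCCCAAAATTTT"


class TestExtractBarcodes:
    def test_identical_reads_collapse_to_one_barcode(self):
        table = extract_barcodes(io.StringIO(fastq_text([BC1] * 3)), offset=0)
        assert table.counts.to_dict() == {BC1: 3}

    def test_short_reads_dropped_and_tallied(self):
        table = extract_barcodes(
            io.StringIO(fastq_text([BC1, BC1[:10]])), offset=0
        )
        assert table.counts.to_dict() == {BC1: 1}
        assert table.dropped["too_short"] == 1

    def test_ambiguous_bases_dropped(self):
        bad = "N" + BC1[1:]
        table = extract_barcodes(io.StringIO(fastq_text([bad, BC1])), offset=0)
        assert table.counts.to_dict() == {BC1: 1}
        assert table.dropped["ambiguous_base"] == 1

    def test_offset_window(self):
        reads = ["GGGG" + BC1 + "TTTT"]
        table = extract_barcodes(io.StringIO(fastq_text(reads)), offset=4)
        assert table.counts.to_dict() == {BC1: 1}

    def test_simulated_reads_match_ground_truth(self):
        rng = np.random.default_rng(0)
        barcodes = ["".join("ACGT"[i] for i in rng.integers(0, 4, 20)) for _ in range(10)]
        truth = {bc: int(rng.integers(50, 150)) for bc in barcodes}
        reads = [bc for bc in barcodes for _ in range(truth[bc])]
        rng.shuffle(reads)
        table = extract_barcodes(io.StringIO(fastq_text(reads)), offset=0)
        assert table.counts.to_dict() == truth


class TestClusterBarcodes:
    def make(self, counts):
        return BarcodeCountTable("s", "DNA", 0, pd.Series(counts))

    def test_distance_zero_is_identity(self):
        t = self.make({BC1: 100, BC2: 5})
        out = cluster_barcodes(t, max_dist=0)
        assert out.counts.to_dict() == t.counts.to_dict()

    def test_neighbor_merges_into_dominant_centroid(self):
        near = "A" + BC1[1:]  # wait: differs at position 0 only
        near = "G" + BC1[1:]
        t = self.make({BC1: 100, near: 5})
        out = cluster_barcodes(t, max_dist=1)
        assert out.counts.to_dict() == {BC1: 105}

    def test_distant_barcodes_stay_separate(self):
        t = self.make({BC1: 100, BC2: 50})
        out = cluster_barcodes(t, max_dist=1)
        assert len(out.counts) == 2

    def test_count_conservation_on_simulated_errors(self):
        """0.5% per-base errors over 50 true barcodes: centroids equal
        the true set and not a single read is lost."""
        rng = np.random.default_rng(1)
        inter = pd.DataFrame(
            [
                {"idX": f"X{i}", "idY": f"Y{i}", "score": 0.0}
                for i in range(25)
            ]
        )
        cfg = synth.SynthConfig(
            seed=2, barcodes_per_pair=2, dna_depth=200, error_rate=0.005
        )
        assay = synth.simulate_barcode_data(inter, cfg)
        raw = extract_barcodes(assay.fastq_records("DNA", 0), offset=0)
        clustered = cluster_barcodes(raw, max_dist=1)
        assert clustered.total == raw.total  # exact conservation
        truth = set(assay.dna[0].counts.index)
        # every true barcode survives as a centroid; the only other
        # centroids are rare reads with two or more errors
        assert truth <= set(clustered.counts.index)
        stray = clustered.counts.drop(index=sorted(truth)).sum()
        assert stray <= 0.005 * clustered.total


class TestBuildMap:
    REF = {"AAACCC": ("X1", "Y1"), "GGGTTT": ("X2", "Y2")}

    def test_unanimous_barcode_is_mapped(self):
        reads = [("AAACCC", BC1)] * 4
        bmap = build_map(reads, self.REF)
        assert bmap.lookup() == {BC1: ("X1", "Y1")}

    def test_even_split_is_excluded(self):
        reads = [("AAACCC", BC1)] * 2 + [("GGGTTT", BC1)] * 2
        bmap = build_map(reads, self.REF)
        assert len(bmap) == 0

    def test_non_design_reads_ignored(self):
        reads = [("AAACCC", BC1)] * 3 + [("CATCAT", BC1)]
        bmap = build_map(reads, self.REF)
        assert bmap.lookup() == {BC1: ("X1", "Y1")}

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_map([], {})

    def test_chimeric_contamination_tolerated(self):
        """2% chimeric reads leave >= 99% of barcodes correctly assigned."""
        rng = np.random.default_rng(3)
        designs = {f"SEQ{i:03d}": (f"X{i}", f"Y{i}") for i in range(50)}
        seqs = list(designs)
        barcodes = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, 20))
            for _ in range(200)
        ]
        truth = {bc: seqs[i % 50] for i, bc in enumerate(barcodes)}
        reads = []
        for bc in barcodes:
            for _ in range(20):
                if rng.random() < 0.02:  # chimera: wrong protein region
                    reads.append((seqs[rng.integers(50)], bc))
                else:
                    reads.append((truth[bc], bc))
        bmap = build_map(reads, designs)
        correct = sum(
            bmap.lookup().get(bc) == designs[truth[bc]] for bc in barcodes
        )
        assert correct >= 0.99 * len(barcodes)


class TestInteractionScores:
    def make_tables(self, rna_counts, dna_counts):
        rna = [
            BarcodeCountTable(f"r{i}", "RNA", i, pd.Series(c))
            for i, c in enumerate(rna_counts)
        ]
        dna = [
            BarcodeCountTable(f"d{i}", "DNA", i, pd.Series(c))
            for i, c in enumerate(dna_counts)
        ]
        return rna, dna

    def make_map(self, barcodes, pair=("X", "Y")):
        return BarcodeMap(
            pd.DataFrame(
                [
                    {"barcode": bc, "idX": pair[0], "idY": pair[1]}
                    for bc in barcodes
                ]
            )
        )

    def test_ln_median_of_ratios(self):
        bcs = ["A" * 20, "C" * 20, "G" * 20]
        rna, dna = self.make_tables(
            [{bcs[0]: 20, bcs[1]: 30, bcs[2]: 40}],
            [{bcs[0]: 10, bcs[1]: 10, bcs[2]: 10}],
        )
        result = interaction_scores(rna, dna, self.make_map(bcs))
        (rec,) = result.records
        assert rec.interaction_score == pytest.approx(math.log(3.0))
        assert rec.n_barcodes == 3

    def test_barcode_below_dna_floor_in_any_replicate_excluded(self):
        bcs = ["A" * 20, "C" * 20]
        rna, dna = self.make_tables(
            [{bcs[0]: 100, bcs[1]: 100}],
            [{bcs[0]: 10, bcs[1]: 10}, {bcs[0]: 12, bcs[1]: 9}],
        )
        result = interaction_scores(rna, dna, self.make_map(bcs))
        (rec,) = result.records
        assert rec.n_barcodes == 1
        assert result.n_barcodes_filtered == 1

    def test_doubling_rna_adds_ln2(self):
        bcs = ["A" * 20, "C" * 20, "G" * 20]
        rna_counts = {bcs[0]: 20, bcs[1]: 30, bcs[2]: 40}
        dna_counts = {bc: 10 for bc in bcs}
        rna, dna = self.make_tables([rna_counts], [dna_counts])
        base = interaction_scores(rna, dna, self.make_map(bcs))
        rna2, dna2 = self.make_tables(
            [{k: 2 * v for k, v in rna_counts.items()}], [dna_counts]
        )
        doubled = interaction_scores(rna2, dna2, self.make_map(bcs))
        assert doubled.records[0].interaction_score == pytest.approx(
            base.records[0].interaction_score + math.log(2.0)
        )

    def test_all_zero_rna_is_flagged_not_dropped(self):
        bcs = ["A" * 20]
        rna, dna = self.make_tables([{bcs[0]: 0}], [{bcs[0]: 50}])
        result = interaction_scores(rna, dna, self.make_map(bcs))
        (rec,) = result.records
        assert rec.interaction_score == -math.inf
        assert rec.flagged

    def test_pair_with_no_retained_barcodes_tallied(self):
        bcs = ["A" * 20]
        rna, dna = self.make_tables([{bcs[0]: 5}], [{bcs[0]: 3}])
        result = interaction_scores(rna, dna, self.make_map(bcs))
        assert len(result.records) == 0
        assert result.pairs_dropped == [("X", "Y")]

    def test_score_invariant_to_row_order_and_relabeling(self):
        rng = np.random.default_rng(4)
        bcs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 20)) for _ in range(6)]
        rna_c = {bc: int(rng.integers(20, 200)) for bc in bcs}
        dna_c = {bc: int(rng.integers(10, 100)) for bc in bcs}
        rna, dna = self.make_tables([rna_c], [dna_c])
        base = interaction_scores(rna, dna, self.make_map(bcs))
        # relabel barcodes consistently and shuffle row order
        fresh = [
            "ACGT"[i % 4] * 10 + "ACGT"[(i // 4) % 4] * 10
            for i in range(len(bcs))
        ]
        perm = dict(zip(bcs, fresh))
        rna2, dna2 = self.make_tables(
            [{perm[bc]: rna_c[bc] for bc in reversed(bcs)}],
            [{perm[bc]: dna_c[bc] for bc in reversed(bcs)}],
        )
        relabeled = interaction_scores(
            rna2, dna2, self.make_map([perm[bc] for bc in bcs])
        )
        assert relabeled.records[0].interaction_score == pytest.approx(
            base.records[0].interaction_score
        )

    def test_median_robust_to_minority_corruption(self):
        rng = np.random.default_rng(5)
        bcs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 20)) for _ in range(7)]
        dna_c = {bc: 100 for bc in bcs}
        rna_c = {bc: int(100 * math.exp(0.5)) for bc in bcs}
        rna, dna = self.make_tables([rna_c], [dna_c])
        clean = interaction_scores(rna, dna, self.make_map(bcs))
        # corrupt 3 of 7 barcode ratios by a huge factor
        corrupted = dict(rna_c)
        for bc in bcs[:3]:
            corrupted[bc] = rna_c[bc] * 1000
        rna2, dna2 = self.make_tables([corrupted], [dna_c])
        dirty = interaction_scores(rna2, dna2, self.make_map(bcs))
        lo = math.log(min(rna_c[bc] / 100 for bc in bcs))
        hi = math.log(max(rna_c[bc] / 100 for bc in bcs))
        assert lo <= dirty.records[0].interaction_score <= hi
        assert dirty.records[0].interaction_score == pytest.approx(
            clean.records[0].interaction_score
        )

    def test_low_depth_filters_everything(self):
        inter = pd.DataFrame(
            [{"idX": "A", "idY": "B", "score": 0.0}]
        )
        cfg = synth.SynthConfig(seed=9, dna_depth=2.0)
        assay = synth.simulate_barcode_data(inter, cfg)
        result = interaction_scores(
            assay.rna, assay.dna, assay.barcode_map, min_dna_reads=50
        )
        assert len(result.records) == 0

    def test_end_to_end_recovery_at_high_depth(self):
        """Planted scores in [-3, 2] recovered at r2 >= 0.95."""
        rng = np.random.default_rng(6)
        inter = pd.DataFrame(
            [
                {"idX": f"X{i:03d}", "idY": f"Y{i:03d}", "score": float(s)}
                for i, s in enumerate(rng.uniform(-3, 2, 120))
            ]
        )
        cfg = synth.SynthConfig(seed=7, dna_depth=1000, rna_dispersion=50)
        assay = synth.simulate_barcode_data(inter, cfg)
        result = interaction_scores(assay.rna, assay.dna, assay.barcode_map)
        est = result.to_frame().set_index(["idX", "idY"])["interaction_score"]
        truth = inter.set_index(["idX", "idY"])["score"]
        est, truth = est.align(truth, join="inner")
        assert len(est) >= 100
        r = np.corrcoef(est.to_numpy(), truth.to_numpy())[0, 1]
        assert r**2 >= 0.95

    def test_near_infinite_depth_is_almost_exact(self):
        """At depth 1e5 with near-Poisson dispersion and no read errors
        the ln-median estimate is within 0.05 of truth."""
        rng = np.random.default_rng(8)
        inter = pd.DataFrame(
            [
                {"idX": f"X{i}", "idY": f"Y{i}", "score": float(s)}
                for i, s in enumerate(rng.uniform(-3, 2, 20))
            ]
        )
        cfg = synth.SynthConfig(
            seed=9, dna_depth=1e5, rna_dispersion=1e5, error_rate=0.0
        )
        assay = synth.simulate_barcode_data(inter, cfg)
        result = interaction_scores(assay.rna, assay.dna, assay.barcode_map)
        est = result.to_frame().set_index(["idX", "idY"])["interaction_score"]
        truth = inter.set_index(["idX", "idY"])["score"]
        est, truth = est.align(truth, join="inner")
        assert np.abs(est.to_numpy() - truth.to_numpy()).max() <= 0.05


class TestReplicateAgreement:
    def rec(self, pair, score):
        return InteractionRecord(pair[0], pair[1], "XY", score, 3)

    def test_identical_inputs_correlate_perfectly(self):
        recs = [self.rec((f"X{i}", "Y"), float(i)) for i in range(5)]
        agree = replicate_agreement(recs, recs)
        assert agree.pearson_r == pytest.approx(1.0)
        assert agree.max_abs_delta == 0.0

    def test_disjoint_pair_sets_error(self):
        r1 = [self.rec((f"A{i}", "Y"), 1.0) for i in range(5)]
        r2 = [self.rec((f"B{i}", "Y"), 1.0) for i in range(5)]
        with pytest.raises(ValueError):
            replicate_agreement(r1, r2)

    def test_simulated_replicates_exceed_098(self):
        """256 pairs spanning 4 log-units with sd 0.1 replicate noise."""
        rng = np.random.default_rng(10)
        truth = rng.uniform(-2, 2, 256)
        r1 = [
            self.rec((f"X{i}", f"Y{i}"), float(t + rng.normal(0, 0.1)))
            for i, t in enumerate(truth)
        ]
        r2 = [
            self.rec((f"X{i}", f"Y{i}"), float(t + rng.normal(0, 0.1)))
            for i, t in enumerate(truth)
        ]
        agree = replicate_agreement(r1, r2)
        assert agree.pearson_r > 0.98
        assert agree.n_shared == 256
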