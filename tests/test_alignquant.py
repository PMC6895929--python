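"""Alignment, classification and library accounting."""

import random

import numpy as np
import pandas as pd
import pytest

from mirseq.alignquant import (build_kmer_index, align_read,
                               classify_and_count, summarize_library,
                               normalize_counts, round_half_up,
                               CountMatrix, expressed_mirna_counts)
from mirseq.io import revcomp
from mirseq.preprocess import PreprocessStats


def _brute_force_hits(read, refs, max_mm, both_strands=False):
    out = set()
    for name, seq in refs.items():
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", revcomp(seq)))
        for strand, s in strands:
            for start in range(len(s) - len(read) + 1):
                mm = sum(a != b for a, b in zip(read, s[start:start
                                                        + len(read)]))
                if mm <= max_mm:
                    fwd = start if strand == "+" \
                        else len(s) - start - len(read)
                    out.add((name, fwd, strand, mm))
    return out


class TestKmerIndex:
    def test_posting_count_is_length_minus_k_plus_one(self):
        idx = build_kmer_index({"r": "ACGTACGT"}, 4)
        assert sum(len(v) for v in idx.postings.values()) == 5

    def test_duplicate_references_keep_both_postings(self):
        idx = build_kmer_index({"a": "ACGTACGTACGT",
                                "b": "ACGTACGTACGT"}, 6)
        names = {n for plist in idx.postings.values()
                 for n, _, _ in plist}
        assert names == {"a", "b"}

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="tiny"):
            build_kmer_index({"tiny": "ACG"}, 8)

    def test_sampled_substrings_found_at_true_locus(self):
        rng = random.Random(0)
        genome = "".join(rng.choice("ACGT") for _ in range(1000))
        idx = build_kmer_index({"chr": genome}, 12)
        for _ in range(100):
            start = rng.randint(0, 1000 - 25)
            read = genome[start:start + 25]
            hits = align_read(read, idx, 0)
            assert any(h.start == start for h in hits)


class TestAlignRead:
    def test_exact_mature_read_single_perfect_hit(self):
        refs = {"mirA": "TGAGGTAGTAGGTTGTATAGTT"}
        idx = build_kmer_index(refs, 8)
        hits = align_read(refs["mirA"], idx, 1)
        assert len(hits) == 1
        assert hits[0].mismatches == 0 and hits[0].start == 0

    def test_two_mismatches_rejected_at_limit_one(self):
        ref = "TGAGGTAGTAGGTTGTATAGTT"
        read = "AGAGGTAGTAGGTTGTATAGTA"     # subs at both ends
        idx = build_kmer_index({"m": ref}, 8)
        assert align_read(read, idx, 1) == []

    def test_agrees_with_brute_force_hamming_scan(self):
        rng = random.Random(7)
        refs = {f"ref{i}": "".join(rng.choice("ACGT") for _ in range(60))
                for i in range(20)}
        idx = build_kmer_index(refs, 8)
        for _ in range(500):
            src = refs[f"ref{rng.randrange(20)}"]
            start = rng.randint(0, 60 - 20)
            read = list(src[start:start + 20])
            if rng.random() < 0.7:
                p = rng.randrange(20)
                read[p] = rng.choice("ACGT")
            read = "".join(read)
            got = {(h.ref_id, h.start, h.strand, h.mismatches)
                   for h in align_read(read, idx, 1)}
            assert got == _brute_force_hits(read, refs, 1)

    def test_both_strand_hits_report_forward_coordinates(self):
        rng = random.Random(3)
        genome = {"chr": "".join(rng.choice("ACGT") for _ in range(500))}
        idx = build_kmer_index(genome, 8, both_strands=True)
        start = 100
        read = revcomp(genome["chr"][start:start + 22])
        hits = align_read(read, idx, 0)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.start == start for h in minus)


class TestClassifyAndCount:
    def test_every_read_lands_in_exactly_one_class(self, sim_run):
        for lib, reads in sim_run["clean_libs"].items():
            total = sum(sim_run["class_counts"][lib].values())
            assert total == len(reads)

    def test_class_counts_match_simulation_truth(self, sim_run):
        truth = sim_run["truth"]
        for lib, cc in sim_run["class_counts"].items():
            t = truth[truth["library"] == lib]
            n_trna = int(t.loc[t["kind"] == "trna", "count"].sum())
            # preprocessing may drop a handful of reads
            assert abs(cc.get("tRNA", 0) - n_trna) <= 0.05 * max(n_trna, 20)
            n_mirna = int(t.loc[t["kind"] == "mirna", "count"].sum())
            assert abs(cc.get("miRNA", 0) - n_mirna) \
                <= 0.05 * max(n_mirna, 20)

    def test_count_matrix_tracks_truth_counts(self, sim_run):
        from mirseq.simdata import truth_mirna_counts
        truth = truth_mirna_counts(sim_run["truth"])
        got = sim_run["matrix"].rounded()
        for mir in truth.index:
            for lib in truth.columns:
                assert abs(int(got.loc[mir, lib])
                           - int(truth.loc[mir, lib])) <= \
                    max(3, 0.02 * truth.loc[mir, lib])

    def test_unmappable_reads_all_unmapped(self, toy_genome):
        libs = {"l1": [(f"r{i}", "ACGT" * 5 + "AA") for i in range(5)]}
        # poly-ACGT repeat is absent from the random toy genome
        cc, cm, gh = classify_and_count(
            libs, toy_genome.mature, toy_genome.trna, toy_genome.rrna,
            "TGGAATTCTCGGGTGCCAAGG", {"chr0": "TTTT" * 100}, [])
        total = sum(cc["l1"].values())
        assert total == 5
        assert cc["l1"].get("unmapped", 0) + cc["l1"].get("genome", 0) == 5

    def test_precursor_arm_read_counted_via_genome_pass(self, toy_genome):
        # a read from inside a known locus but absent from the mature
        # reference is credited to the miRNA by the overlap adjustment
        feat = next(f for f in toy_genome.features
                    if f.ftype == "known_mirna")
        if feat.strand == "+":
            seq = toy_genome.genome[feat.chrom][
                feat.mature_start:feat.mature_end + 2]
        else:
            seq = revcomp(toy_genome.genome[feat.chrom][
                feat.mature_start - 2:feat.mature_end])
        libs = {"l1": [("r0", seq)]}
        cc, cm, gh = classify_and_count(
            libs, toy_genome.mature, toy_genome.trna, toy_genome.rrna,
            "TGGAATTCTCGGGTGCCAAGG", toy_genome.genome,
            toy_genome.known_mirna_bed())
        assert cc["l1"].get("miRNA", 0) == 1
        assert cm.raw.loc[feat.feature_id, "l1"] == 1.0


class TestLibrarySummary:
    # printed library summary: four libraries of a published run
    PRINTED = [
        ("EV_rep1", 1442378, 753866, 540145, 40071, 2235, 30,
         77.27, 71.65, 5.32, 0.30, 0.0040, 582481),
        ("EV_rep2", 751538, 340244, 251022, 9763, 575, 8,
         76.82, 73.78, 2.87, 0.17, 0.0024, 261368),
        ("R273H_rep1", 1292998, 566961, 453934, 7932, 406, 11,
         81.54, 80.06, 1.40, 0.07, 0.0019, 462283),
        ("R273H_rep2", 874753, 500523, 408055, 11191, 767, 5,
         83.92, 81.53, 2.24, 0.15, 0.0010, 420018),
    ]

    @pytest.mark.parametrize("row", PRINTED, ids=[r[0] for r in PRINTED])
    def test_published_percentages_reproduced(self, row):
        (lib, raw, pre, mir, trna, rrna, ad,
         pct_tot, pct_mir, pct_trna, pct_rrna, pct_ad, total) = row
        s = summarize_library(
            lib, PreprocessStats(total_raw=raw, after_preprocessing=pre),
            {"miRNA": mir, "tRNA": trna, "rRNA": rrna, "adapter": ad})
        assert s.mapped_total == total
        pct = s.percentages()
        assert pct["mapped_total"] == pct_tot
        assert pct["mapped_mirna"] == pct_mir
        assert pct["mapped_trna"] == pct_trna
        assert pct["mapped_rrna"] == pct_rrna
        assert pct["mapped_adapter"] == pct_ad

    def test_zero_read_library_yields_null_percentages(self):
        s = summarize_library("empty", PreprocessStats(), {})
        assert s.percentages()["mapped_total"] is None

    def test_rounding_is_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.005, 2) == 0.01


class TestNormalization:
    def _matrix(self):
        raw = pd.DataFrame({"l1": [50.0, 0.0], "l2": [25.0, 25.0]},
                           index=["m1", "m2"])
        return CountMatrix(raw=raw, mapped_totals={"l1": 10 ** 6,
                                                   "l2": 50})

    def test_rpm_definition(self):
        cm = normalize_counts(self._matrix(), "RPM")
        assert cm.layers["RPM"].loc["m1", "l1"] == 50.0

    def test_rpm_columns_sum_to_million_when_all_reads_mirna(self):
        raw = pd.DataFrame({"l1": [30.0, 70.0]}, index=["a", "b"])
        cm = CountMatrix(raw=raw, mapped_totals={"l1": 100})
        cm = normalize_counts(cm, "RPM")
        assert cm.layers["RPM"]["l1"].sum() == pytest.approx(1e6)

    def test_constant_row_zscore_is_zero(self):
        raw = pd.DataFrame({"l1": [5.0], "l2": [5.0]}, index=["m"])
        cm = CountMatrix(raw=raw, mapped_totals={"l1": 10, "l2": 10})
        cm = normalize_counts(cm, "zscore")
        assert (cm.layers["zscore"].loc["m"] == 0).all()

    def test_zero_total_rejected(self):
        raw = pd.DataFrame({"l1": [5.0]}, index=["m"])
        cm = CountMatrix(raw=raw, mapped_totals={"l1": 0})
        with pytest.raises(ValueError):
            normalize_counts(cm, "RPM")

    def test_expressed_counts_thresholds(self):
        raw = pd.DataFrame({"l1": [1.0, 2.0, 5.0]},
                           index=["a", "b", "c"])
        cm = CountMatrix(raw=raw, mapped_totals={"l1": 8})
        e = expressed_mirna_counts(cm)
        assert e.loc["l1", "expressed_ge1"] == 3
        assert e.loc["l1", "expressed_ge3"] == 1
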