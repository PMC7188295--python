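"""Demultiplexing, filtering and the denoising haplotype caller."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdrhaplo import (CallerParams, ErrorModel, PopulationConfig,
                      call_haplotypes, demultiplex, filter_reads, merge_tables,
                      simulate_pool, validate_frequency_table)
from kdrhaplo.refpanel import SimulatedRead, reverse_complement
from conftest import make_manifest


def mkread(seq, qual=None, pop="P1", seg="IIS6"):
    return SimulatedRead("r", seq, qual or ("?" * len(seq)), "", pop, seg)


def reads_from_counts(counts, pop="P1", seg="IIS6"):
    out = []
    for seq, n in counts.items():
        out.extend(mkread(seq, pop=pop, seg=seg) for _ in range(n))
    return out


class TestDemultiplex:
    def test_exact_barcode_assigned_and_stripped(self):
        man = make_manifest(("AAAACCCC", "P1", "x", "y", 2000),
                            ("GGGGTTTT", "P2", "x", "y", 2000))
        reads = [mkread("AAAACCCC" + "ACGT" * 10)]
        assigned, unassigned = demultiplex(reads, man, CallerParams())
        assert not unassigned
        assert len(assigned["P1"]) == 1
        assert assigned["P1"][0].sequence == "ACGT" * 10

    def test_ambiguous_read_goes_unassigned(self):
        # read prefix within one mismatch of both barcodes
        man = make_manifest(("AAAAAAAA", "P1", "x", "y", 2000),
                            ("AAAAAAAT", "P2", "x", "y", 2000))
        reads = [mkread("AAAAAAAC" + "ACGT" * 10)]
        assigned, unassigned = demultiplex(reads, man, CallerParams())
        assert len(unassigned) == 1
        assert not assigned["P1"] and not assigned["P2"]

    def test_simulated_reads_all_assigned(self, panel, one_pop_manifest):
        cfg = PopulationConfig("P1", "Brazil", "South America", 2010,
                               {"IIS6": {"2s6_A_03": 1.0}},
                               barcode="ACGTACGTAC", reads_per_segment=1000)
        reads = simulate_pool(cfg, panel, ErrorModel(0, 0, 1, 30), seed=3)
        assigned, unassigned = demultiplex(reads, one_pop_manifest,
                                           CallerParams())
        assert not unassigned
        assert len(assigned["P1"]) == 1000

    def test_read_conservation(self, panel, one_pop_manifest):
        cfg = PopulationConfig("P1", "Brazil", "South America", 2010,
                               {"IIS6": {"2s6_A_03": 1.0}},
                               barcode="ACGTACGTAC", reads_per_segment=500)
        reads = simulate_pool(cfg, panel, ErrorModel(0.05, 0.01, 3, 30), seed=3)
        assigned, unassigned = demultiplex(reads, one_pop_manifest,
                                           CallerParams())
        assert sum(map(len, assigned.values())) + len(unassigned) == len(reads)

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty manifest"):
            demultiplex([], pd.DataFrame(columns=["barcode", "population_id"]),
                        CallerParams())


class TestFilterReads:
    def test_error_free_read_retained_and_trimmed(self, models, pidx):
        m = models["IIS6"]
        q = "I" * 352  # Phred 40
        kept = filter_reads([mkread(pidx["2s6_A_03"].sequence, q)], m,
                            CallerParams())
        assert len(kept) == 1
        fwd, rev = m.primers
        assert len(kept[0].sequence) == 352 - len(fwd) - len(rev)

    def test_short_read_dropped(self, models):
        m = models["IIS6"]
        seq = m.sequence[:25] + m.sequence[-25:]  # primers intact, 50 bp
        assert not filter_reads([mkread(seq, "I" * 50)], m, CallerParams())

    def test_reverse_strand_read_reoriented(self, models, pidx):
        m = models["IIS6"]
        fwd_seq = pidx["2s6_A_03"].sequence
        rc = reverse_complement(fwd_seq)
        kept = filter_reads([mkread(rc, "I" * len(rc))], m, CallerParams())
        assert len(kept) == 1
        lo, hi = m.inner_interval
        assert kept[0].sequence == fwd_seq[lo:hi]

    def test_low_quality_read_dropped(self, models, pidx):
        m = models["IIS6"]
        seq = pidx["2s6_A_03"].sequence
        kept = filter_reads([mkread(seq, "+" * len(seq))], m,  # Phred 10
                            CallerParams())
        assert not kept


class TestCallHaplotypes:
    H1 = "ACGTACGTACGTACGTACGTACGTACGTAC"
    H2 = "ACGTACGTACTTTGTACGTACGTACGTAGG"  # >2 edits from H1

    def test_distinct_haplotypes_not_merged(self):
        calls = call_haplotypes(
            reads_from_counts({self.H1: 900, self.H2: 100}), CallerParams())
        assert [(c.sequence, c.frequency) for c in calls] == \
               [(self.H1, 0.9), (self.H2, 0.1)]

    def test_error_cloud_absorbed(self):
        err = self.H1[:10] + "T" + self.H1[11:]
        assert err != self.H1
        calls = call_haplotypes(reads_from_counts({self.H1: 990, err: 10}),
                                CallerParams())
        assert len(calls) == 1
        assert calls[0].sequence == self.H1
        assert calls[0].frequency == 1.0
        assert calls[0].read_count == 1000

    def test_homopolymer_length_variant_merged_despite_ratio(self):
        base = "ACGTAAAACGTACGTACGTACGTACGTACG"  # contains AAAA run
        minus1 = base.replace("AAAA", "AAA", 1)
        # ratio 2 < abundance_ratio, merged anyway (homopolymer rule)
        calls = call_haplotypes(reads_from_counts({base: 200, minus1: 100}),
                                CallerParams())
        assert len(calls) == 1
        assert calls[0].sequence == base

    def test_denoiser_idempotence(self):
        err = self.H1[:5] + "T" + self.H1[6:]
        calls = call_haplotypes(
            reads_from_counts({self.H1: 900, self.H2: 80, err: 20}),
            CallerParams())
        rebuilt = reads_from_counts({c.sequence: c.read_count for c in calls})
        again = call_haplotypes(rebuilt, CallerParams())
        assert [(c.sequence, c.read_count) for c in again] == \
               [(c.sequence, c.read_count) for c in calls]

    @given(floors=st.lists(
        st.floats(min_value=0.0, max_value=0.49), min_size=2, max_size=2))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_floor_never_adds_calls(self, floors):
        lo, hi = sorted(floors)
        counts = {self.H1: 600, self.H2: 300,
                  "ACGT" * 7 + "TT": 60, "TGCA" * 7 + "GG": 40}
        n_lo = len(call_haplotypes(reads_from_counts(counts),
                                   CallerParams(frequency_floor=lo)))
        n_hi = len(call_haplotypes(reads_from_counts(counts),
                                   CallerParams(frequency_floor=hi)))
        assert n_hi <= n_lo

    def test_empty_input_warns_and_drops(self):
        with pytest.warns(UserWarning, match="no retained reads"):
            assert call_haplotypes([], CallerParams(), "P", "IIS6") == []

    def test_frequencies_sum_to_one(self):
        calls = call_haplotypes(
            reads_from_counts({self.H1: 700, self.H2: 300}), CallerParams())
        assert abs(sum(c.frequency for c in calls) - 1.0) < 1e-9


class TestMergeTables:
    def _calls(self, pop, counts, seg="IIS6"):
        total = sum(counts.values())
        from kdrhaplo import HaplotypeCall

        return [HaplotypeCall(pop, seg, s, n, n / total)
                for s, n in counts.items()]

    def test_shared_sequence_shares_name(self):
        man = make_manifest(("AAAA", "P1", "x", "y", 2000),
                            ("CCCC", "P2", "x", "y", 2001),
                            ("GGGG", "P3", "x", "y", 2002))
        seq = "ACGT" * 10
        calls = {p: self._calls(p, {seq: 100}) for p in ("P1", "P2", "P3")}
        table, name_to_seq = merge_tables(calls, man)
        assert table["haplotype_name"].nunique() == 1
        assert len(table) == 3
        assert name_to_seq[table["haplotype_name"].iloc[0]] == seq

    def test_most_abundant_gets_rank_zero(self):
        man = make_manifest(("AAAA", "P1", "x", "y", 2000))
        big, small = "AAAA" * 10, "CCCC" * 10
        table, _ = merge_tables({"P1": self._calls("P1", {big: 900, small: 100})},
                                man)
        names = dict(zip(table["read_count"], table["haplotype_name"]))
        assert names[900] == "2s6_00"
        assert names[100] == "2s6_01"

    def test_disjoint_haplotypes_get_distinct_names(self):
        man = make_manifest(("AAAA", "P1", "x", "y", 2000),
                            ("CCCC", "P2", "x", "y", 2001))
        table, _ = merge_tables(
            {"P1": self._calls("P1", {"AAAA" * 10: 100}),
             "P2": self._calls("P2", {"CCCC" * 10: 100})}, man)
        assert table["haplotype_name"].nunique() == 2
        validate_frequency_table(table)

    def test_name_map_pins_panel_names(self):
        man = make_manifest(("AAAA", "P1", "x", "y", 2000))
        seq = "ACGT" * 10
        table, _ = merge_tables({"P1": self._calls("P1", {seq: 10})}, man,
                                name_map={seq: "2s6_A_03"})
        assert list(table["haplotype_name"]) == ["2s6_A_03"]
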