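"""Mutational steps, parsimony limit and network construction."""

import functools
import itertools

import networkx as nx
import pytest

from kdrhaplo import (build_network, connection_limit, export_network,
                      import_network, mutational_steps, parsimony_probability)

# --- independent oracle ----------------------------------------------------
# Exhaustive dynamic programme over all global alignments (match +1,
# mismatch -2, gap open -4, extend -1): among maximum-score alignments,
# the minimum of substitutions + gap runs.  Written independently of the
# library path (which delegates alignment to biopython).


def oracle_steps(a: str, b: str) -> int:
    @functools.cache
    def best(i, j, state):
        if i == len(a) and j == len(b):
            return (0, 0)
        cands = []
        if i < len(a) and j < len(b):
            sc, st = best(i + 1, j + 1, "M")
            if a[i] == b[j]:
                cands.append((sc + 1, st))
            else:
                cands.append((sc - 2, st + 1))
        if i < len(a):
            sc, st = best(i + 1, j, "X")
            cands.append((sc - (1 if state == "X" else 4),
                          st + (0 if state == "X" else 1)))
        if j < len(b):
            sc, st = best(i, j + 1, "Y")
            cands.append((sc - (1 if state == "Y" else 4),
                          st + (0 if state == "Y" else 1)))
        top = max(sc for sc, _ in cands)
        return (top, min(st for sc, st in cands if sc == top))

    return best(0, 0, "M")[1] if a != b else 0


# 20-mer toy panel mirroring the real panel's relational structure:
# a central wild type, single-substitution derivatives, a double mutant,
# an indel-separated second clade, and one distant outlier.
BASE = "ACGTTGCAAGCTTACGGATC"
TOY = {
    "t_A03": BASE,
    "t_A01": BASE[:5] + "C" + BASE[6:],
    "t_A02": BASE[:12] + "G" + BASE[13:],
    "t_A06": BASE[:3] + "A" + BASE[4:12] + "C" + BASE[13:],
    "t_B00": BASE[:8] + BASE[10:16] + "C" + BASE[17:],   # 2 bp del + sub
    "t_B04": BASE[:2] + "T" + BASE[3:8] + BASE[10:16] + "C" + BASE[17:],
    "t_ins": BASE[:10] + "AA" + BASE[10:],
    "t_far": "TTGCA" + BASE[5:9] + "CCAT" + BASE[13:17] + "GGA",
}


class TestMutationalSteps:
    def test_identical_sequences_are_zero_steps(self):
        assert mutational_steps(BASE, BASE) == 0

    def test_single_kdr_substitution_is_one_step(self, pidx):
        assert mutational_steps(pidx["2s6_A_02"].sequence,
                                pidx["2s6_A_03"].sequence) == 1

    def test_gap_run_plus_substitution_is_two_steps(self):
        a = "ACGTTGCAAGCTTACGGATCACGT"
        b = a[:6] + a[10:20] + "G" + a[21:]  # one 4 bp deletion + one sub
        assert mutational_steps(a, b) == 2
        assert oracle_steps(a, b) == 2

    def test_symmetry(self):
        for u, v in itertools.combinations(TOY.values(), 2):
            assert mutational_steps(u, v) == mutational_steps(v, u)

    def test_oracle_equivalence_on_toy_panel(self):
        for u, v in itertools.combinations(TOY.values(), 2):
            assert mutational_steps(u, v) == oracle_steps(u, v)


class TestConnectionLimit:
    def test_vanishing_confidence_connects_everything(self):
        assert connection_limit(50, 1e-30) == 50

    def test_limit_matches_independent_transcription(self):
        # straight transcription of the multiple-hit parsimony estimator
        def oracle_limit(m, conf):
            best = 1
            for j in range(2, m + 1):
                p = 1.0
                for i in range(1, j):
                    p *= 1.0 - i / m
                if p >= conf:
                    best = j
                else:
                    break
            return best

        for m in (50, 200, 352, 354, 500):
            assert connection_limit(m, 0.95) == oracle_limit(m, 0.95)
        assert parsimony_probability(1, 354) == 1.0

    def test_limit_monotone_in_sequence_length(self):
        limits = [connection_limit(m, 0.95) for m in range(50, 501, 10)]
        assert all(b >= a for a, b in zip(limits, limits[1:]))


class TestBuildNetwork:
    def test_kdr_haplotypes_star_around_a03(self, pidx):
        subset = {n: pidx[n].sequence
                  for n in ("2s6_A_01", "2s6_A_02", "2s6_A_03", "2s6_A_06")}
        net = build_network(subset)
        e = {tuple(sorted((u, v))): d for u, v, d in
             net.graph.edges(data="steps")}
        assert e[("2s6_A_01", "2s6_A_03")] == 1
        assert e[("2s6_A_02", "2s6_A_03")] == 1
        assert e[("2s6_A_03", "2s6_A_06")] == 2
        assert len(e) == 3

    def test_asian_double_mutant_attaches_to_1534c_haplotype(self, pidx, panel):
        seqs = {h.name: h.sequence for h in panel if h.segment_id == "IIIS6"}
        net = build_network(seqs)
        assert net.graph.has_edge("3s6_13", "3s6_01")
        assert net.graph.edges["3s6_13", "3s6_01"]["steps"] == 1

    def test_single_haplotype_network(self):
        net = build_network({"h": BASE})
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_pairs_beyond_limit_stay_disconnected(self):
        # limit(20, 0.95) = 2; t_far sits >2 steps from everything
        net = build_network({"t_A03": TOY["t_A03"], "t_far": TOY["t_far"]})
        assert net.connection_limit == 2
        assert net.graph.number_of_edges() == 0
        assert len(net.components) == 2

    def test_edge_steps_match_oracle_on_all_small_subsets(self):
        names = sorted(TOY)
        for k in range(2, 7):
            for subset in itertools.combinations(names, k):
                net = build_network({n: TOY[n] for n in subset})
                for u, v, d in net.graph.edges(data="steps"):
                    assert d == oracle_steps(TOY[u], TOY[v]), (u, v)

    def test_components_carry_minimum_spanning_weight(self):
        """Retained edges span each component at minimal total steps."""
        names = sorted(set(TOY) - {"t_far"})
        for k in range(3, 7):
            for subset in itertools.combinations(names, k):
                seqs = {n: TOY[n] for n in subset}
                net = build_network(seqs)
                full = nx.Graph()
                for u, v in itertools.combinations(subset, 2):
                    s = oracle_steps(TOY[u], TOY[v])
                    if 0 < s <= net.connection_limit:
                        full.add_edge(u, v, steps=s)
                for comp in net.components:
                    if len(comp) < 2:
                        continue
                    got = nx.minimum_spanning_tree(
                        net.graph.subgraph(comp), weight="steps")
                    want = nx.minimum_spanning_tree(
                        full.subgraph(comp), weight="steps")
                    assert got.size(weight="steps") == want.size(weight="steps")


class TestGraphMLRoundTrip:
    def test_attributes_survive_round_trip(self, tmp_path, pidx):
        seqs = {n: pidx[n].sequence
                for n in ("2s6_A_02", "2s6_A_03", "2s6_B_00")}
        net = build_network(seqs, frequencies={"2s6_A_03": 0.5,
                                               "2s6_A_02": 0.3,
                                               "2s6_B_00": 0.2},
                            labels={"2s6_A_02": "V1016I"})
        path = tmp_path / "net.graphml"
        export_network(net, path)
        back = import_network(path)
        assert nx.is_isomorphic(net.graph, back.graph)
        assert back.connection_limit == net.connection_limit
        assert back.graph.nodes["2s6_A_02"]["label"] == "V1016I"
        assert back.graph.nodes["2s6_A_03"]["frequency"] == 0.5
        for u, v, d in net.graph.edges(data="steps"):
            assert back.graph.edges[u, v]["steps"] == d

    def test_empty_network_round_trips(self, tmp_path):
        net = build_network({})
        path = tmp_path / "empty.graphml"
        export_network(net, path)
        assert import_network(path).graph.number_of_nodes() == 0
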