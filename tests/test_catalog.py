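"""Catalogue stage tests: clustering, paralog flags, redundancy closure,
low-complexity and mitochondrial screens, candidate selection, tiling."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radcapkit._seq import revcomp
from radcapkit.catalog import (CatalogLocus, CatalogThresholds, dust_score,
                               build_catalog, cluster_within_sample,
                               mask_low_complexity, purge_similar_loci,
                               screen_mitochondrial, select_candidates,
                               synonymize_redundant, tile_offsets,
                               tile_probes, SampleCluster)
from conftest import make_read, random_seq

T = CatalogThresholds()


def _mutate_at(seq: str, positions: list[int]) -> str:
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = sub[out[p]]
    return "".join(out)


class TestClusterWithinSample:
    def test_identical_reads_form_one_clean_cluster(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 140)
        clusters = cluster_within_sample([make_read(seq, rid=f"r{i}")
                                          for i in range(20)], T)
        assert len(clusters) == 1
        assert clusters[0].consensus == seq
        assert clusters[0].het_columns == []
        assert clusters[0].depth == 20

    def test_two_alleles_give_ambiguity_columns(self):
        rng = np.random.default_rng(1)
        x = random_seq(rng, 140)
        y = _mutate_at(x, [30, 90])
        reads = ([make_read(x, rid=f"x{i}") for i in range(10)]
                 + [make_read(y, rid=f"y{i}") for i in range(10)])
        clusters = cluster_within_sample(reads, T)
        assert len(clusters) == 1
        assert sorted(clusters[0].het_columns) == [30, 90]

    def test_reads_below_similarity_split(self):
        rng = np.random.default_rng(2)
        x = random_seq(rng, 140)
        y = _mutate_at(x, list(range(0, 140, 14)))   # 10 diffs = 92.9%
        reads = ([make_read(x, rid=f"x{i}") for i in range(5)]
                 + [make_read(y, rid=f"y{i}") for i in range(5)])
        assert len(cluster_within_sample(reads, T)) == 2

    def test_short_and_empty_inputs(self):
        assert cluster_within_sample([], T) == []
        assert cluster_within_sample([make_read("ACGT" * 10)], T) == []

    def test_high_het_cluster_discarded(self):
        rng = np.random.default_rng(3)
        x = random_seq(rng, 60)
        # 31 of 60 ambiguous columns: just over the 0.5 het-fraction cap;
        # mutations confined to the front so the tail stays seedable
        y = _mutate_at(x, list(range(0, 31)))
        t = CatalogThresholds(within_sim=0.4, max_mismatch=60)
        reads = ([make_read(x, rid=f"x{i}") for i in range(5)]
                 + [make_read(y, rid=f"y{i}") for i in range(5)])
        assert cluster_within_sample(reads, t) == []


class TestBuildCatalog:
    def _clusters(self, seqs_by_sample):
        return {s: [SampleCluster(seq, 10, [], sample=s) for seq in seqs]
                for s, seqs in seqs_by_sample.items()}

    def test_same_consensus_groups_across_samples(self):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 150)
        cat = build_catalog(self._clusters(
            {f"s{i}": [seq] for i in range(5)}), T.across_sim, T)
        assert len(cat) == 1
        assert cat[0].n_individuals == 5
        assert cat[0].consensus == seq

    @pytest.mark.parametrize("n_het,flagged", [(5, True), (4, False)])
    def test_shared_het_boundary(self, n_het, flagged):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 150)
        het = seq[:70] + "R" + seq[71:]     # A/G ambiguity at column 70
        base = seq[:70] + "A" + seq[71:]
        clusters = {}
        for i in range(8):
            s = het if i < n_het else base
            clusters[f"s{i}"] = [SampleCluster(s, 10, [70] if i < n_het
                                               else [], sample=f"s{i}")]
        cat = build_catalog(clusters, T.across_sim, T)
        assert len(cat) == 1
        assert ("paralog_shared_het" in cat[0].flags) is flagged

    def test_too_many_distinct_bases_flags_paralog(self):
        rng = np.random.default_rng(6)
        seq = random_seq(rng, 150)
        variants = [seq[:70] + b + seq[71:] for b in "ACGT"]
        clusters = {f"s{i}": [SampleCluster(variants[i], 10, [],
                                            sample=f"s{i}")]
                    for i in range(4)}
        cat = build_catalog(clusters, 0.9, T)
        assert len(cat) == 1
        assert "paralog_shared_het" in cat[0].flags

    def test_reverse_complement_consensi_group_together(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 150)
        cat = build_catalog(self._clusters(
            {"s0": [seq], "s1": [revcomp(seq)]}), T.across_sim, T)
        assert len(cat) == 1
        assert cat[0].n_individuals == 2


def _locus(lid, seq, source="sp1", samples=10):
    return CatalogLocus(locus_id=lid, consensus=seq,
                        per_sample_alleles={f"s{i}": (seq, seq)
                                            for i in range(samples)},
                        source_assembly=source,
                        sample_consensi={f"s{i}": seq
                                         for i in range(samples)})


class TestSynonymizeRedundant:
    def test_identical_loci_merge(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 160)
        merged, n = synonymize_redundant(
            [[_locus("a", seq, "sp1")], [_locus("b", seq, "sp2")]], T)
        assert len(merged) == 1 and n == 1
        assert "redundant_resolved" in merged[0].flags

    def test_dissimilar_loci_stay_separate(self):
        rng = np.random.default_rng(9)
        merged, n = synonymize_redundant(
            [[_locus("a", random_seq(rng, 160), "sp1")],
             [_locus("b", random_seq(rng, 160), "sp2")]], T)
        assert len(merged) == 2 and n == 0

    def test_transitive_chain_collapses_to_one_group(self):
        """A~B and B~C merge all three even when A and C alone would not
        (union-find closure, checked against a brute-force connected
        component)."""
        rng = np.random.default_rng(10)
        a = random_seq(rng, 200)
        b = _mutate_at(a, list(range(0, 200, 18)))   # 12 diffs: 94% to a
        c = _mutate_at(b, list(range(9, 200, 18)))   # 11 more: a~c 88.5%
        cats = [[_locus("a", a, "sp1")], [_locus("b", b, "sp2")],
                [_locus("c", c, "combined")]]
        # brute-force closure oracle over pairwise >=90% identity
        seqs = {"a": a, "b": b, "c": c}
        ids = sorted(seqs)
        import itertools
        edges = {(x, y) for x, y in itertools.combinations(ids, 2)
                 if sum(u == v for u, v in zip(seqs[x], seqs[y])) / 200 >= 0.90}
        assert ("a", "b") in edges and ("b", "c") in edges \
            and ("a", "c") not in edges
        merged, n = synonymize_redundant(cats, T)
        assert len(merged) == 1 and n == 2


class TestPurgeSimilar:
    def test_near_identical_pair_both_flagged(self):
        rng = np.random.default_rng(11)
        a = random_seq(rng, 200)
        b = _mutate_at(a, list(range(0, 200, 20)))   # 95% identity
        cat = purge_similar_loci([_locus("a", a), _locus("b", b)], T)
        assert all("paralog_similarity" in l.flags for l in cat)

    def test_half_length_similarity_not_flagged(self):
        """95%-identical over only half the length misses the 55%
        coverage requirement."""
        rng = np.random.default_rng(12)
        shared = random_seq(rng, 100)
        rot = str.maketrans("ACGT", "CGTA")
        a = shared + random_seq(rng, 100)
        b = _mutate_at(shared, list(range(0, 100, 20))) \
            + (random_seq(rng, 100)).translate(rot)
        cat = purge_similar_loci([_locus("a", a), _locus("b", b)], T)
        assert all("paralog_similarity" not in l.flags for l in cat)

    def test_mutually_dissimilar_catalogue_unflagged(self):
        rng = np.random.default_rng(13)
        cat = [_locus(f"l{i}", random_seq(rng, 180)) for i in range(6)]
        purge_similar_loci(cat, T)
        assert all("paralog_similarity" not in l.flags for l in cat)


class TestLowComplexity:
    def test_homopolymer_run_flagged(self):
        rng = np.random.default_rng(14)
        seq = random_seq(rng, 100) + "A" * 10 + random_seq(rng, 100)
        cat = mask_low_complexity([_locus("a", seq)])
        assert "low_complexity" in cat[0].flags

    def test_random_sequence_unflagged(self):
        rng = np.random.default_rng(15)
        cat = mask_low_complexity([_locus(f"l{i}", random_seq(rng, 200))
                                   for i in range(10)])
        assert all("low_complexity" not in l.flags for l in cat)

    def test_dinucleotide_repeat_flagged_by_dust(self):
        seq = "AC" * 100
        assert dust_score(seq) > 2.0
        cat = mask_low_complexity([_locus("a", seq)])
        assert "low_complexity" in cat[0].flags

    def test_dust_score_matches_bruteforce_triplet_count(self):
        rng = np.random.default_rng(16)
        seq = random_seq(rng, 64)
        counts = Counter(seq[i:i + 3] for i in range(62))
        expect = sum(c * (c - 1) / 2 for c in counts.values()) / 61
        assert dust_score(seq) == pytest.approx(expect)


class TestMitoScreen:
    rng = np.random.default_rng(17)
    mito = random_seq(rng, 3000)

    def test_verbatim_segment_flagged(self):
        cat = screen_mitochondrial([_locus("a", self.mito[500:700])],
                                   self.mito)
        assert "mitochondrial" in cat[0].flags

    def test_reverse_complement_segment_flagged(self):
        cat = screen_mitochondrial(
            [_locus("a", revcomp(self.mito[1000:1180]))], self.mito)
        assert "mitochondrial" in cat[0].flags

    def test_unrelated_locus_unflagged(self):
        rng = np.random.default_rng(18)
        cat = screen_mitochondrial([_locus("a", random_seq(rng, 200))],
                                   self.mito)
        assert "mitochondrial" not in cat[0].flags

    def test_missing_reference_warns_and_skips(self):
        with pytest.warns(UserWarning):
            cat = screen_mitochondrial([_locus("a", "ACGT" * 50)], None)
        assert cat[0].flags == set()


class TestSelectCandidates:
    @pytest.mark.parametrize("n,source,expected", [
        (10, "sp1", True), (9, "sp1", False),
        (20, "combined", True), (19, "combined", False),
    ])
    def test_minimum_individuals_boundary(self, n, source, expected):
        rng = np.random.default_rng(19)
        loc = _locus("a", random_seq(rng, 150), source, samples=n)
        got = select_candidates([loc], T)
        assert (len(got) == 1) is expected

    def test_discard_flag_blocks_candidacy(self):
        rng = np.random.default_rng(20)
        loc = _locus("a", random_seq(rng, 150), samples=40)
        loc.flags.add("paralog_similarity")
        assert select_candidates([loc], T) == []


class TestTileProbes:
    @pytest.mark.parametrize("length,offsets", [
        (140, [0, 20]),
        (120, [0]),
        (240, [0, 60, 120]),
        (300, [0, 60, 120, 180]),
    ])
    def test_offsets_follow_end_anchoring_rule(self, length, offsets):
        assert tile_offsets(length) == offsets

    def test_probe_records_have_correct_sequences(self):
        rng = np.random.default_rng(21)
        seq = random_seq(rng, 140)
        probes = tile_probes([_locus("a", seq)], T)
        assert [p.offset for p in probes] == [0, 20]
        assert all(p.sequence == seq[p.offset:p.offset + 120]
                   for p in probes)

    def test_short_template_raises_with_locus_name(self):
        with pytest.raises(ValueError, match="shorty"):
            tile_probes([_locus("shorty", "ACGT" * 20)], T)

    @given(st.integers(min_value=121, max_value=180))
    @settings(max_examples=30, deadline=None)
    def test_lengths_in_two_probe_band_yield_exactly_two(self, length):
        assert len(tile_offsets(length)) == 2


def test_flag_sets_are_monotone_under_catalogue_growth():
    """Adding loci to a catalogue never removes a flag from an existing
    locus (flags only accumulate)."""
    rng = np.random.default_rng(22)
    a = random_seq(rng, 200)
    b = _mutate_at(a, list(range(0, 200, 25)))
    base = [_locus("a", a), _locus("b", b)]
    purge_similar_loci(base, T)
    flags_before = [set(l.flags) for l in base]
    extra = base + [_locus(f"x{i}", random_seq(rng, 200)) for i in range(3)]
    purge_similar_loci(extra, T)
    for loc, before in zip(extra[:2], flags_before):
        assert before <= loc.flags
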