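"""Mapping, duplicate-marking, reference-building and coverage tests."""

from collections import Counter

import numpy as np
import pytest

from conftest import make_read, random_seq
from radcapkit._seq import best_window_identity_ds, revcomp
from radcapkit.capture import (AlignmentRecord, CaptureParams,
                               EmptyReferenceError, build_reference,
                               coverage_metrics, map_reads, mark_duplicates)
from radcapkit.readproc import merge_all
from radcapkit.simdata import SimulationConfig, emit_reads, simulate_truth


_rng = np.random.default_rng(0)
_REF = {f"locus{i}": random_seq(_rng, 200) for i in range(5)}


class TestMapReads:
    ref = _REF

    def test_unique_read_maps_with_max_quality(self):
        read = make_read(self.ref["locus2"][30:170], rid="u")
        recs, stats = map_reads([read], self.ref)
        assert stats["mapped"] == 1
        assert recs[0].locus_id == "locus2"
        assert recs[0].maq == 60
        assert (recs[0].start, recs[0].end) == (30, 170)

    def test_reverse_strand_read_mapped(self):
        read = make_read(revcomp(self.ref["locus1"][20:160]), rid="rc")
        recs, _ = map_reads([read], self.ref)
        assert recs[0].locus_id == "locus1"
        assert recs[0].strand == "-"
        assert recs[0].seq == self.ref["locus1"][20:160]

    def test_read_tied_between_duplicated_loci_excluded(self):
        dup_ref = dict(self.ref)
        dup_ref["copy"] = dup_ref["locus0"]
        read = make_read(dup_ref["locus0"][10:150], rid="t")
        recs, stats = map_reads([read], dup_ref)
        assert recs == [] and stats["low_maq"] == 1

    def test_unrelated_read_unmapped(self):
        rng = np.random.default_rng(1)
        recs, stats = map_reads([make_read(random_seq(rng, 140))], self.ref)
        assert recs == [] and stats["unmapped"] == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            map_reads([make_read("ACGT" * 40)], {})

    def test_divergent_reads_map_to_true_locus(self):
        """Reads at 5% divergence from the reference still map home."""
        rng = np.random.default_rng(2)
        reads = []
        for locus, seq in self.ref.items():
            for i in range(20):
                codes = list(seq[20:180])
                for p in rng.choice(160, size=8, replace=False):
                    codes[p] = "ACGT"[(("ACGT".index(codes[p])) + 1) % 4]
                reads.append(make_read("".join(codes), rid=f"{locus}:{i}"))
        recs, _ = map_reads(reads, self.ref)
        correct = sum(r.locus_id == r.read_id.split(":")[0] for r in recs)
        assert len(recs) >= 0.95 * len(reads)
        assert correct / len(recs) >= 0.95

    def test_raising_maq_floor_never_increases_mapped_count(self):
        dup_ref = dict(self.ref)
        dup_ref["near_copy"] = self.ref["locus0"][:150] + random_seq(
            np.random.default_rng(3), 50)
        rng = np.random.default_rng(4)
        reads = [make_read(dup_ref[l][s:s + 140], rid=f"{l}:{s}")
                 for l in dup_ref for s in (0, 30, 60)]
        counts = []
        for floor in (0, 5, 20, 60):
            recs, _ = map_reads(reads, dup_ref,
                                CaptureParams(maq_min=floor))
            counts.append(len(recs))
        assert counts == sorted(counts, reverse=True)


def _aln(read_id, start, insert, strand="+", sample="s", qsum=40):
    return AlignmentRecord(read_id=read_id, locus_id="L", start=start,
                           end=start + insert, strand=strand,
                           n_mismatch=0, maq=60, insert_len=insert,
                           sample=sample, seq="A" * insert,
                           qual=np.full(insert, qsum, dtype=np.uint8))


class TestMarkDuplicates:
    def test_three_identical_fragments_flag_two(self):
        group = [_aln(f"r{i}", 10, 150) for i in range(3)]
        mark_duplicates(group)
        assert sum(r.is_duplicate for r in group) == 2

    def test_different_insert_lengths_not_duplicates(self):
        group = [_aln("a", 10, 180), _aln("b", 10, 181)]
        mark_duplicates(group)
        assert not any(r.is_duplicate for r in group)

    def test_highest_quality_member_kept(self):
        good = _aln("good", 5, 100, qsum=40)
        bad = _aln("bad", 5, 100, qsum=10)
        mark_duplicates([bad, good])
        assert bad.is_duplicate and not good.is_duplicate

    def test_marking_is_idempotent(self):
        group = [_aln(f"r{i}", 0, 120) for i in range(4)] \
            + [_aln("x", 3, 120), _aln("y", 0, 121)]
        mark_duplicates(group)
        first = [r.is_duplicate for r in group]
        mark_duplicates(group)
        assert [r.is_duplicate for r in group] == first

    def test_injected_duplicate_fraction_recovered(
            self, small_capture_experiment):
        cfg, truth, pairs, _ = small_capture_experiment
        merged, _, _ = merge_all(pairs)
        ref = {r.id: r.seq for r in truth.ancestral_loci}
        recs = []
        by_sample = {}
        for m in merged:
            by_sample.setdefault(m.id.split(":")[1], []).append(m)
        for sample, reads in by_sample.items():
            rr, _ = map_reads(reads, ref, sample=sample)
            recs.extend(rr)
        mark_duplicates(recs)
        recovered = sum(r.is_duplicate for r in recs) / len(recs)
        injected = len(truth.duplicate_read_ids) / len(pairs)
        assert abs(recovered - injected) <= 0.02


class TestBuildReference:
    def _experiment(self, n_loci=40, n_targeted=28, seed=50):
        cfg = SimulationConfig(
            seed=seed, n_loci=n_loci, n_individuals_per_species=5,
            species_divergences={"A": 0.02, "B": 0.05, "C": 0.08})
        truth = simulate_truth(cfg)
        pairs, _ = emit_reads(truth, cfg, "capture")
        merged, _, _ = merge_all(pairs)
        by_sample = {}
        for m in merged:
            by_sample.setdefault(m.id.split(":")[1], []).append(m)
        templates = {r.id: r.seq for r in truth.ancestral_loci[:n_targeted]}
        return cfg, truth, by_sample, templates

    def test_cluster_size_floor_is_forty_reads(self):
        rng = np.random.default_rng(5)
        seq_a, seq_b = random_seq(rng, 180), random_seq(rng, 180)
        reads = {"s": [make_read(seq_a, rid=f"a{i}") for i in range(40)]
                 + [make_read(seq_b, rid=f"b{i}") for i in range(39)]}
        loci = build_reference(reads, {}, None)
        assert len(loci) == 1
        assert loci[0].n_supporting_reads == 40

    def test_no_surviving_cluster_raises(self):
        rng = np.random.default_rng(6)
        reads = {"s": [make_read(random_seq(rng, 180))
                       for _ in range(10)]}
        with pytest.raises(EmptyReferenceError):
            build_reference(reads, {}, None)

    def test_overlapping_clusters_merge_into_one_locus(self):
        rng = np.random.default_rng(7)
        locus = random_seq(rng, 260)
        left = locus[:180]
        right = locus[50:]               # 130 bp shared: above the 120 floor
        reads = {"s": [make_read(left, rid=f"l{i}") for i in range(50)]
                 + [make_read(right, rid=f"r{i}") for i in range(50)]}
        loci = build_reference(reads, {}, None)
        assert len(loci) == 1

    def test_recovery_and_target_labels_on_simulation(self):
        cfg, truth, by_sample, templates = self._experiment()
        loci = build_reference(by_sample, templates, None)
        truth_seqs = {r.id: r.seq for r in truth.ancestral_loci}
        assign = {}
        for l in loci:
            best, bid = 0.0, None
            for tid, tseq in truth_seqs.items():
                w = min(120, len(l.sequence), len(tseq))
                ident = best_window_identity_ds(l.sequence, tseq, w)
                if ident > best:
                    best, bid = ident, tid
            assign[l.ref_id] = bid
        hits = Counter(assign.values())
        single = sum(1 for t in truth_seqs if hits[t] == 1)
        assert single >= 0.95 * len(truth_seqs)
        correct = sum(
            (l.origin == ("on_target" if assign[l.ref_id] in templates
                          else "off_target")) for l in loci)
        assert correct / len(loci) >= 0.95


class TestCoverageMetrics:
    ref = {"L": "A" * 100}

    def test_single_full_length_read_gives_depth_one(self):
        rec = _aln("r", 0, 100)
        prof = coverage_metrics([rec], self.ref)["s"]
        assert prof.mean_target_depth == pytest.approx(1.0)
        assert prof.het_read_rate == 0.0

    def test_gc_only_reads_give_hundred_percent(self):
        rec = _aln("r", 0, 100)
        rec.seq = "GC" * 50
        prof = coverage_metrics([rec], self.ref)["s"]
        assert prof.gc_percent == pytest.approx(100.0)

    def test_duplicates_excluded_from_depth(self):
        a, b = _aln("a", 0, 100), _aln("b", 0, 100)
        b.is_duplicate = True
        prof = coverage_metrics([a, b], self.ref)["s"]
        assert prof.mean_target_depth == pytest.approx(1.0)
        assert prof.n_duplicates == 1

    def test_error_rate_matches_het_read_rate(self):
        """With sequencing errors only, the heterozygous read rate equals
        the fraction of bases mutated away from the reference."""
        rng = np.random.default_rng(8)
        ref_seq = random_seq(rng, 200)
        n_err = 0
        recs = []
        for i in range(50):
            codes = list(ref_seq)
            hits = rng.random(200) < 0.01
            for p in np.flatnonzero(hits):
                codes[p] = "ACGT"[("ACGT".index(codes[p]) + 1) % 4]
            n_err += int(hits.sum())
            rec = _aln(f"r{i}", 0, 200)
            rec.locus_id = "L"
            rec.seq = "".join(codes)
            recs.append(rec)
        prof = coverage_metrics(recs, {"L": ref_seq})["s"]
        assert prof.het_read_rate == pytest.approx(n_err / (50 * 200))
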