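"""Read mapping, PCR-duplicate marking, assembly-based reference
construction and per-sample coverage metrics.

Mapping is seed-and-extend: a 15-mer index nominates candidate loci, edlib
verifies the placement on both strands, and mapping quality is the margin
between the best and second-best locus score (capped at 60).  Duplicates
are fragments identical in (locus, start, insert length, strand) within a
sample — sonicated capture fragments are unlikely to coincide unless they
are PCR copies.  The assembly-based reference greedily clusters merged
reads at 90% identity, drops weak clusters, merges over-split clusters that
overlap by >= 120 bp at >= 85% identity, and labels loci on/off-target by
reciprocal best hit against the probe-template set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._seq import (KmerIndex, best_window_identity_ds, locate, revcomp,
                   seq_to_codes)
from .records import SeqRead


@dataclass
class CaptureParams:
    maq_min: int = 5
    cluster_sim: float = 0.90
    min_cluster_reads: int = 40
    merge_min_overlap: int = 120
    merge_sim: float = 0.85
    rbh_identity_min: float = 0.75
    map_min_identity: float = 0.75
    kmer_k: int = 15


@dataclass
class AlignmentRecord:
    """A read placed on a reference locus (0-based, half-open)."""

    read_id: str
    locus_id: str
    start: int
    end: int
    strand: str
    n_mismatch: int
    maq: int
    insert_len: int
    sample: str = ""
    is_duplicate: bool = False
    #: read sequence in reference orientation
    seq: str = ""
    qual: np.ndarray | None = None


@dataclass
class ReferenceLocus:
    ref_id: str
    sequence: str
    n_supporting_reads: int
    origin: str = "off_target"          # on_target | off_target
    probe_hit: str | None = None
    flags: set[str] = field(default_factory=set)


@dataclass
class SampleProfile:
    """Per-sample alignment summary metrics."""

    sample: str
    n_reads: int = 0
    n_duplicates: int = 0
    mean_target_depth: float = 0.0      # non-duplicate aligned bases / ref bp
    gc_percent: float = 0.0
    #: fraction of aligned read bases disagreeing with the reference
    #: consensus, over all aligned columns
    het_read_rate: float = 0.0


class EmptyReferenceError(RuntimeError):
    """No cluster survived reference construction."""


def map_reads(reads: list[SeqRead], reference: dict[str, str],
              params: CaptureParams | None = None, sample: str = ""
              ) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Map reads against reference loci; returns (records with maQ >=
    maq_min, counter of outcomes).

    maQ = min(60, best score - second best score) over candidate loci,
    with score = read length - 2 * edit distance; a unique hit scores
    maQ 60, a perfect tie 0.
    """
    params = params or CaptureParams()
    if not reference:
        raise ValueError("empty reference")
    index = KmerIndex(k=params.kmer_k)
    for name, seq in reference.items():
        index.add(name, seq)
    records: list[AlignmentRecord] = []
    stats = {"mapped": 0, "unmapped": 0, "low_maq": 0}
    for read in reads:
        rc = revcomp(read.seq)
        cand = set(index.candidates(read.seq, stride=4))
        cand |= set(index.candidates(rc, stride=4))
        hits = []  # (score, locus, strand, start, end, dist)
        for locus in cand:
            ref = reference[locus]
            best = None
            for strand, q in (("+", read.seq), ("-", rc)):
                s, e, d = locate(q, ref)
                score = len(q) - 2 * d
                if best is None or score > best[0]:
                    best = (score, locus, strand, s, e, d)
            hits.append(best)
        if not hits:
            stats["unmapped"] += 1
            continue
        hits.sort(key=lambda h: (-h[0], h[1]))
        score, locus, strand, s, e, d = hits[0]
        if 1.0 - d / len(read.seq) < params.map_min_identity:
            stats["unmapped"] += 1
            continue
        maq = 60 if len(hits) == 1 else min(60, score - hits[1][0])
        if maq < params.maq_min:
            stats["low_maq"] += 1
            continue
        seq = read.seq if strand == "+" else rc
        qual = read.qual if strand == "+" else (
            read.qual[::-1] if read.qual is not None else None)
        records.append(AlignmentRecord(
            read_id=read.id, locus_id=locus, start=s, end=e, strand=strand,
            n_mismatch=d, maq=maq, insert_len=len(read.seq), sample=sample,
            seq=seq, qual=qual))
        stats["mapped"] += 1
    return records, stats


def mark_duplicates(alignments: list[AlignmentRecord]
                    ) -> list[AlignmentRecord]:
    """Flag PCR duplicates in place and return the list.

    Within a sample, fragments sharing (locus, start, insert length,
    strand) form a duplicate group; the member with the highest summed
    base quality (ties: lexicographically smallest read id) is kept.
    Idempotent.
    """
    groups: dict[tuple, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        groups[(rec.sample, rec.locus_id, rec.start, rec.insert_len,
                rec.strand)].append(rec)
    for group in groups.values():
        if len(group) == 1:
            group[0].is_duplicate = False
            continue
        def quality(rec: AlignmentRecord) -> float:
            return float(np.sum(rec.qual)) if rec.qual is not None else 0.0
        keeper = min(group, key=lambda r: (-quality(r), r.read_id))
        for rec in group:
            rec.is_duplicate = rec is not keeper
    return alignments


def _greedy_cluster_reads(reads: list[SeqRead], params: CaptureParams
                          ) -> list[tuple[str, list[tuple[SeqRead, int, str]]]]:
    """Greedy length-descending clustering at ``cluster_sim`` identity.

    Returns [(seed_seq, [(read, offset_on_seed, strand), ...])].  Seeds are
    the longest fragments, so members always place inside their seed.
    """
    order = sorted(reads, key=lambda r: (-len(r.seq), r.seq))
    index = KmerIndex(k=params.kmer_k)
    seeds: list[str] = []
    members: list[list[tuple[SeqRead, int, str]]] = []
    for read in order:
        rc = revcomp(read.seq)
        cand: dict[str, None] = {}
        for name in index.candidates(read.seq, stride=4, min_shared=2):
            cand.setdefault(name)
        for name in index.candidates(rc, stride=4, min_shared=2):
            cand.setdefault(name)
        best = None  # (identity, seed_i, offset, strand)
        for name in cand:
            i = int(name)
            for strand, q in (("+", read.seq), ("-", rc)):
                s, e, d = locate(q, seeds[i])
                ident = 1.0 - d / len(q)
                if ident >= params.cluster_sim and (
                        best is None or ident > best[0]):
                    best = (ident, i, s, strand)
        if best is None:
            index.add(str(len(seeds)), read.seq)
            seeds.append(read.seq)
            members.append([(read, 0, "+")])
        else:
            _, i, s, strand = best
            members[i].append((read, s, strand))
    return list(zip(seeds, members))


def _cluster_consensus(seed: str,
                       members: list[tuple[SeqRead, int, str]]) -> str:
    L = len(seed)
    counts = np.zeros((4, L), dtype=np.int32)
    for read, off, strand in members:
        seq = read.seq if strand == "+" else revcomp(read.seq)
        codes = seq_to_codes(seq)
        n = min(len(codes), L - off)
        valid = codes[:n] < 4
        np.add.at(counts, (codes[:n][valid], off + np.flatnonzero(valid)), 1)
    called = counts.argmax(axis=0)
    covered = counts.sum(axis=0) > 0
    seed_codes = seq_to_codes(seed)
    called = np.where(covered, called, np.minimum(seed_codes, 3))
    return "".join("ACGT"[c] for c in called)


def build_reference(merged_reads_by_sample: dict[str, list[SeqRead]],
                    probe_templates: dict[str, str],
                    mito_ref: str | None = None,
                    params: CaptureParams | None = None
                    ) -> list[ReferenceLocus]:
    """Build the assembly-based reference from modern samples' merged reads.

    Pipeline: greedy clustering at 90% identity; clusters with fewer than
    ``min_cluster_reads`` dropped; over-split clusters whose consensi
    overlap >= ``merge_min_overlap`` bp at >= ``merge_sim`` identity merged
    (transitively) into one locus keeping the longest consensus; reciprocal
    best hit against the probe-template set labels on/off-target;
    mitochondrial and chimeric consensi are flagged and excluded from the
    returned reference.

    Museum reads must not be passed here — callers select modern samples.
    """
    params = params or CaptureParams()
    reads = [r for sample in sorted(merged_reads_by_sample)
             for r in merged_reads_by_sample[sample]]
    clusters = _greedy_cluster_reads(reads, params)
    clusters = [(seed, mem) for seed, mem in clusters
                if len(mem) >= params.min_cluster_reads]
    if not clusters:
        raise EmptyReferenceError(
            f"no cluster reached {params.min_cluster_reads} reads")

    consensi = [_cluster_consensus(seed, mem) for seed, mem in clusters]
    support = [len(mem) for _, mem in clusters]

    # merge over-split clusters (transitive closure)
    parent = list(range(len(consensi)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    index = KmerIndex(k=params.kmer_k)
    for i, cons in enumerate(consensi):
        index.add(str(i), cons)
    for i, cons in enumerate(consensi):
        for name in index.candidates_ds(cons, stride=4, min_shared=2):
            j = int(name)
            if j <= i:
                continue
            shorter, longer = sorted((cons, consensi[j]), key=len)
            w = min(params.merge_min_overlap, len(shorter))
            if best_window_identity_ds(shorter, longer, w) >= params.merge_sim:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(consensi)):
        groups[find(i)].append(i)

    loci: list[ReferenceLocus] = []
    for gi, root in enumerate(sorted(groups)):
        idxs = groups[root]
        rep = max(idxs, key=lambda i: (len(consensi[i]), -i))
        loci.append(ReferenceLocus(
            ref_id=f"ref{gi:05d}", sequence=consensi[rep],
            n_supporting_reads=sum(support[i] for i in idxs)))

    _label_targets(loci, probe_templates, params)
    tindex = KmerIndex(k=params.kmer_k)
    for name, seq in probe_templates.items():
        tindex.add(name, seq)
    for locus in loci:
        if mito_ref and best_window_identity_ds(
                locus.sequence, mito_ref,
                max(30, len(locus.sequence) // 2)) >= 0.80:
            locus.flags.add("mitochondrial")
        _flag_chimera(locus, probe_templates, tindex, params)
    return [l for l in loci if not (l.flags & {"mitochondrial", "chimera",
                                               "artefact"})]


def _best_template_hit(seq: str, templates: dict[str, str],
                       tindex: KmerIndex, params: CaptureParams
                       ) -> tuple[str | None, float]:
    best_t, best_ident = None, 0.0
    for name in tindex.candidates_ds(seq, stride=4):
        tmpl = templates[name]
        shorter, longer = sorted((seq, tmpl), key=len)
        w = max(30, int(0.5 * len(shorter)))
        ident = best_window_identity_ds(shorter, longer, w)
        if ident > best_ident or (ident == best_ident and best_t is not None
                                  and name < best_t):
            best_t, best_ident = name, ident
    return best_t, best_ident


def _label_targets(loci: list[ReferenceLocus], templates: dict[str, str],
                   params: CaptureParams) -> None:
    """Reciprocal-best-hit labelling of on/off-target reference loci."""
    if not templates:
        return
    tindex = KmerIndex(k=params.kmer_k)
    for name, seq in templates.items():
        tindex.add(name, seq)
    lindex = KmerIndex(k=params.kmer_k)
    for locus in loci:
        lindex.add(locus.ref_id, locus.sequence)
    by_id = {l.ref_id: l for l in loci}

    forward: dict[str, tuple[str | None, float]] = {}
    for locus in loci:
        forward[locus.ref_id] = _best_template_hit(
            locus.sequence, templates, tindex, params)
    reverse: dict[str, str | None] = {}
    for name, seq in templates.items():
        best_l, best_ident = None, 0.0
        for lid in lindex.candidates_ds(seq, stride=4):
            shorter, longer = sorted((seq, by_id[lid].sequence), key=len)
            w = max(30, int(0.5 * len(shorter)))
            ident = best_window_identity_ds(shorter, longer, w)
            if ident > best_ident:
                best_l, best_ident = lid, ident
        reverse[name] = best_l

    for locus in loci:
        tmpl, ident = forward[locus.ref_id]
        if (tmpl is not None and ident >= params.rbh_identity_min
                and reverse.get(tmpl) == locus.ref_id):
            locus.origin = "on_target"
            locus.probe_hit = tmpl
        else:
            locus.origin = "off_target"
            locus.probe_hit = None


def _flag_chimera(locus: ReferenceLocus, templates: dict[str, str],
                  tindex: KmerIndex, params: CaptureParams) -> None:
    """A consensus whose 5' and 3' halves best-hit different templates is
    a putative assembly chimera."""
    if not templates or len(locus.sequence) < 120:
        return
    half = len(locus.sequence) // 2
    left, lident = _best_template_hit(locus.sequence[:half], templates,
                                      tindex, params)
    right, rident = _best_template_hit(locus.sequence[half:], templates,
                                       tindex, params)
    if (left and right and left != right
            and lident >= params.rbh_identity_min
            and rident >= params.rbh_identity_min):
        locus.flags.add("chimera")


def coverage_metrics(alignments: list[AlignmentRecord],
                     reference: dict[str, str]) -> dict[str, SampleProfile]:
    """Per-sample coverage, GC% and heterozygous read rate from
    duplicate-marked alignments.

    mean_target_depth = non-duplicate aligned bases / total reference
    length; het_read_rate = aligned read bases disagreeing with the
    reference, over all aligned columns (duplicates excluded from both).
    """
    total_ref = sum(len(s) for s in reference.values())
    ref_codes = {k: seq_to_codes(v) for k, v in reference.items()}
    profiles: dict[str, SampleProfile] = {}
    acc: dict[str, list[float]] = defaultdict(lambda: [0, 0, 0, 0, 0])
    # [aligned_bases, gc_bases, mismatch_bases, n_reads, n_dup]
    for rec in alignments:
        a = acc[rec.sample]
        a[3] += 1
        if rec.is_duplicate:
            a[4] += 1
            continue
        codes = seq_to_codes(rec.seq)
        n = min(len(codes), rec.end - rec.start)
        a[0] += n
        a[1] += int(np.count_nonzero((codes[:n] == 1) | (codes[:n] == 2)))
        ref = ref_codes[rec.locus_id][rec.start:rec.start + n]
        a[2] += int(np.count_nonzero(codes[:n] != ref))
    for sample, (bases, gc, mism, n_reads, n_dup) in sorted(acc.items()):
        profiles[sample] = SampleProfile(
            sample=sample, n_reads=int(n_reads), n_duplicates=int(n_dup),
            mean_target_depth=bases / total_ref if total_ref else 0.0,
            gc_percent=100.0 * gc / bases if bases else 0.0,
            het_read_rate=mism / bases if bases else 0.0)
    return profiles
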