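"""Raw paired-read processing: quality trimming, contaminant screening,
overlap merging and dual-index demultiplexing.

These are the first four steps of the capture pipeline.  The contaminant
screen is a canonical k-mer membership test (keep/remove only, no taxonomic
labels); merging is a deterministic best-overlap scan with a mismatch cap.
A strict whole-read mean-quality threshold (Phred 33 by default) governs
discards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, seq_to_codes
from .records import ReadPair, SeqRead


@dataclass
class ReadProcParams:
    min_mean_phred: float = 33.0
    trim_qual: int = 20
    ddrad_min_len: int = 140
    capture_max_len: int = 220
    min_overlap: int = 20
    max_overlap_mismatch: float = 0.10
    kmer_k: int = 31
    contaminant_kmer_frac: float = 0.5
    index_mismatch_allow: int = 1
    adapters: tuple[str, ...] = ()
    min_adapter_match: int = 8


@dataclass
class StageCounts:
    """Read-conservation bookkeeping: kept + discarded = input, per stage."""

    input: int = 0
    kept: int = 0
    discarded: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def count(self, reason: str) -> None:
        self.discarded += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def _trim_read(read: SeqRead, params: ReadProcParams) -> SeqRead:
    if read.qual is None or len(read.qual) != len(read.seq):
        raise ValueError(f"read {read.id}: malformed or missing quality string")
    seq, qual = read.seq, read.qual
    # adapter removal: semi-global match of an adapter prefix at any suffix
    for adapter in params.adapters:
        cut = _find_adapter(seq, adapter, params)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
    # 3' low-quality trimming
    end = len(seq)
    while end > 0 and qual[end - 1] < params.trim_qual:
        end -= 1
    return SeqRead(read.id, seq[:end], qual[:end])


def _find_adapter(seq: str, adapter: str, params: ReadProcParams) -> int | None:
    """Leftmost position where a prefix of *adapter* matches the read
    suffix with <= 10% mismatches and >= min_adapter_match bases."""
    a = seq_to_codes(adapter)
    s = seq_to_codes(seq)
    for i in range(len(seq) - params.min_adapter_match + 1):
        n = min(len(seq) - i, len(adapter))
        mism = int(np.count_nonzero(s[i:i + n] != a[:n]))
        if mism <= 0.10 * n:
            return i
    return None


def quality_trim(pair: ReadPair, params: ReadProcParams | None = None
                 ) -> ReadPair | None:
    """Trim 3' low-quality tails and adapter suffixes; discard the whole
    pair (return None) when either mate's mean Phred falls below
    ``min_mean_phred``."""
    params = params or ReadProcParams()
    r1 = _trim_read(pair.read1, params)
    r2 = _trim_read(pair.read2, params)
    if r1.mean_qual < params.min_mean_phred or r2.mean_qual < params.min_mean_phred:
        return None
    return ReadPair(r1, r2, i5=pair.i5, i7=pair.i7)


def quality_trim_all(pairs: list[ReadPair],
                     params: ReadProcParams | None = None
                     ) -> tuple[list[ReadPair], StageCounts]:
    params = params or ReadProcParams()
    counts = StageCounts(input=len(pairs))
    kept = []
    for p in pairs:
        out = quality_trim(p, params)
        if out is None:
            counts.count("mean_phred")
        else:
            kept.append(out)
            counts.kept += 1
    return kept, counts


def canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        out.add(min(kmer, revcomp(kmer)))
    return out


def build_contaminant_index(references: list[str], k: int = 31) -> set[str]:
    index: set[str] = set()
    for ref in references:
        index |= canonical_kmers(ref, k)
    return index


def screen_contaminants(pairs: list[ReadPair],
                        contaminant_refs: list[str],
                        params: ReadProcParams | None = None
                        ) -> tuple[list[ReadPair], StageCounts]:
    """Remove pairs in which either mate shares >= ``contaminant_kmer_frac``
    of its canonical k-mers with the contaminant reference set."""
    params = params or ReadProcParams()
    counts = StageCounts(input=len(pairs))
    if not contaminant_refs:
        warnings.warn("empty contaminant reference set; screening skipped")
        counts.kept = len(pairs)
        return list(pairs), counts
    index = build_contaminant_index(contaminant_refs, params.kmer_k)
    kept = []
    for p in pairs:
        flagged = False
        for read in (p.read1, p.read2):
            kmers = canonical_kmers(read.seq, params.kmer_k)
            if kmers and sum(k in index for k in kmers) / len(kmers) \
                    >= params.contaminant_kmer_frac:
                flagged = True
                break
        if flagged:
            counts.count("contaminant")
        else:
            kept.append(p)
            counts.kept += 1
    return kept, counts


def _overlap_mismatches(c1: np.ndarray, c2: np.ndarray, o: int) -> int:
    return int(np.count_nonzero(c1[len(c1) - o:] != c2[:o]))


def merge_pairs(pair: ReadPair, params: ReadProcParams | None = None,
                mode: str = "capture") -> SeqRead | None:
    """Merge mates over their best 3' overlap, or return None.

    The longest overlap >= ``min_overlap`` with mismatch fraction <=
    ``max_overlap_mismatch`` wins; overlap bases resolve to the
    higher-quality call.  Merged fragments are truncated to
    ``capture_max_len``; in ``ddrad`` mode fragments shorter than
    ``ddrad_min_len`` are discarded.
    """
    params = params or ReadProcParams()
    r1 = pair.read1
    if r1.qual is None or pair.read2.qual is None:
        # qualities are required downstream; default to a flat Q30
        r1 = SeqRead(r1.id, r1.seq, np.full(len(r1.seq), 30, dtype=np.uint8))
        r2_ = pair.read2
        pair = ReadPair(r1, SeqRead(r2_.id, r2_.seq,
                                    np.full(len(r2_.seq), 30, dtype=np.uint8)),
                        i5=pair.i5, i7=pair.i7)
    seq2 = revcomp(pair.read2.seq)
    qual2 = pair.read2.qual[::-1]
    c1 = seq_to_codes(r1.seq)
    c2 = seq_to_codes(seq2)
    n1, n2 = len(c1), len(c2)
    max_o = min(n1, n2)

    best_o = 0
    # fast path: seed candidate overlaps with exact 16-mers of the mate
    candidates: list[int] = []
    for seed_off in (0, 16, 32):
        seed = seq2[seed_off:seed_off + 16]
        if len(seed) < 16:
            break
        p = r1.seq.find(seed)
        while p >= 0:
            o = n1 - (p - seed_off)
            if params.min_overlap <= o <= max_o:
                candidates.append(o)
            p = r1.seq.find(seed, p + 1)
    for o in sorted(set(candidates), reverse=True):
        if _overlap_mismatches(c1, c2, o) <= params.max_overlap_mismatch * o:
            best_o = o
            break
    if best_o == 0:       # exhaustive fallback for error-laden overlaps
        for o in range(max_o, params.min_overlap - 1, -1):
            if _overlap_mismatches(c1, c2, o) <= params.max_overlap_mismatch * o:
                best_o = o
                break
    if best_o == 0:
        return None

    o = best_o
    left_seq, left_q = r1.seq[:n1 - o], r1.qual[:n1 - o]
    right_seq, right_q = seq2[o:], qual2[o:]
    ov1, ovq1 = r1.seq[n1 - o:], r1.qual[n1 - o:]
    ov2, ovq2 = seq2[:o], qual2[:o]
    take1 = np.asarray(ovq1) >= np.asarray(ovq2)
    ov = "".join(a if t else b for a, b, t in zip(ov1, ov2, take1))
    ovq = np.maximum(np.asarray(ovq1), np.asarray(ovq2))
    merged_seq = left_seq + ov + right_seq
    merged_q = np.concatenate([np.asarray(left_q), ovq, np.asarray(right_q)])
    if len(merged_seq) > params.capture_max_len:
        merged_seq = merged_seq[:params.capture_max_len]
        merged_q = merged_q[:params.capture_max_len]
    if mode == "ddrad" and len(merged_seq) < params.ddrad_min_len:
        return None
    return SeqRead(pair.id, merged_seq, merged_q.astype(np.uint8))


def merge_all(pairs: list[ReadPair], params: ReadProcParams | None = None,
              mode: str = "capture"
              ) -> tuple[list[SeqRead], list[ReadPair], StageCounts]:
    """Merge every pair; returns (merged, unmerged pairs, counts)."""
    params = params or ReadProcParams()
    counts = StageCounts(input=len(pairs))
    merged, unmerged = [], []
    for p in pairs:
        m = merge_pairs(p, params, mode=mode)
        if m is None:
            unmerged.append(p)
            counts.count("unmerged")
        else:
            merged.append(m)
            counts.kept += 1
    return merged, unmerged, counts


def _index_dist(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(pairs: list[ReadPair],
                sample_sheet: dict[tuple[str, str], str],
                params: ReadProcParams | None = None
                ) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign pairs to samples by dual index within
    ``index_mismatch_allow`` mismatches per index; ambiguous or
    non-matching pairs land in the unassigned pile.

    Index pairs on the sheet must be mutually >= 2*allow+1 mismatches
    apart (summed over both indexes) or a configuration error is raised.
    """
    params = params or ReadProcParams()
    entries = list(sample_sheet.items())
    min_sep = 2 * params.index_mismatch_allow + 1
    for i, ((i5a, i7a), _) in enumerate(entries):
        for (i5b, i7b), _ in entries[i + 1:]:
            if _index_dist(i5a, i5b) + _index_dist(i7a, i7b) < min_sep:
                raise ValueError(
                    f"sample sheet index pairs ({i5a},{i7a}) and "
                    f"({i5b},{i7b}) are closer than {min_sep} mismatches")
    assigned: dict[str, list[ReadPair]] = {s: [] for s in sample_sheet.values()}
    unassigned: list[ReadPair] = []
    for p in pairs:
        hits = [sample for (i5, i7), sample in entries
                if _index_dist(p.i5, i5) <= params.index_mismatch_allow
                and _index_dist(p.i7, i7) <= params.index_mismatch_allow]
        if len(hits) == 1:
            assigned[hits[0]].append(p)
        else:
            unassigned.append(p)
    return assigned, unassigned
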