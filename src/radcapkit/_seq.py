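"""Low-level sequence utilities shared across modules.

Everything here works on plain ``str`` sequences over the DNA alphabet
(IUPAC ambiguity codes tolerated in reverse complement) plus numpy
``uint8`` code arrays (A=0, C=1, G=2, T=3, other=4) for fast column-wise
arithmetic.  Pairwise identity goes through edlib; approximate search is
seeded with a k-mer index.
"""

from __future__ import annotations

from collections import defaultdict

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def hamming(a: str, b: str) -> int:
    """Mismatch count over the common prefix length of two strings."""
    n = min(len(a), len(b))
    return int(np.count_nonzero(seq_to_codes(a[:n]) != seq_to_codes(b[:n])))


def edit_distance(query: str, target: str, mode: str = "NW") -> int:
    return edlib.align(query, target, mode=mode, task="distance")["editDistance"]


def global_identity(a: str, b: str) -> float:
    """NW identity: matches / alignment length, gaps count as mismatches.

    Approximated as 1 - editDistance / max(len); exact when the alignment
    carries no compensating gap pairs, which holds for the indel-free data
    this toolkit deals in.
    """
    if not a or not b:
        return 0.0
    d = edit_distance(a, b, mode="NW")
    return 1.0 - d / max(len(a), len(b))


def infix_identity(query: str, target: str) -> float:
    """Identity of the best placement of *query* inside *target* (HW mode)."""
    if not query or not target:
        return 0.0
    d = edit_distance(query, target, mode="HW")
    return 1.0 - d / len(query)


def contained_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence placed inside the longer one."""
    return infix_identity(a, b) if len(a) <= len(b) else infix_identity(b, a)


def locate(query: str, target: str) -> tuple[int, int, int]:
    """Best infix placement of query in target: (start, end_exclusive, dist)."""
    res = edlib.align(query, target, mode="HW", task="locations")
    s, e = res["locations"][0]
    return s, e + 1, res["editDistance"]


class KmerIndex:
    """Exact k-mer index over named reference sequences.

    Used as a prefilter: a query only needs alignment against references
    with which it shares at least ``min_shared`` k-mers.
    """

    def __init__(self, k: int = 15):
        self.k = k
        self._index: dict[str, list[int]] = defaultdict(list)
        self._names: list[str] = []

    def add(self, name: str, seq: str, stride: int = 1) -> None:
        ref_i = len(self._names)
        self._names.append(name)
        k = self.k
        for i in range(0, len(seq) - k + 1, stride):
            self._index[seq[i:i + k]].append(ref_i)

    def candidates(self, seq: str, stride: int = 4,
                   min_shared: int = 1) -> list[str]:
        """Reference names sharing >= min_shared k-mers with *seq*,
        most-shared first (ties by insertion order)."""
        k = self.k
        counts: dict[int, int] = defaultdict(int)
        for i in range(0, len(seq) - k + 1, stride):
            for ref_i in self._index.get(seq[i:i + k], ()):
                counts[ref_i] += 1
        hits = [(n, i) for i, n in counts.items() if n >= min_shared]
        hits.sort(key=lambda t: (-t[0], t[1]))
        return [self._names[i] for _, i in hits]

    def candidates_ds(self, seq: str, stride: int = 4,
                      min_shared: int = 1) -> list[str]:
        """Strand-aware :meth:`candidates`: union over both orientations."""
        fwd = self.candidates(seq, stride, min_shared)
        rev = self.candidates(revcomp(seq), stride, min_shared)
        seen: dict[str, None] = {}
        for name in fwd + rev:
            seen.setdefault(name)
        return list(seen)


def _diagonal_offsets(query: str, target: str, k: int) -> list[int]:
    """Candidate ungapped offsets of query on target from shared k-mers."""
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(target) - k + 1):
        pos[target[i:i + k]].append(i)
    offsets: set[int] = set()
    for i in range(0, len(query) - k + 1):
        for j in pos.get(query[i:i + k], ()):
            offsets.add(j - i)
    return sorted(offsets)


def best_window_identity(query: str, target: str, window: int,
                         k: int = 15) -> float:
    """Best ungapped identity over any length-*window* overlap of query
    on target.

    Candidate placements come from shared k-mers (no shared k-mer means
    identity 0.0 — sequences that disjoint cannot pass any threshold of
    interest here).  Within each candidate diagonal the maximum sliding
    window identity is computed with a cumulative-sum scan.  Gap-free by
    design: the data this serves (restriction loci, probes) carries
    substitutions, not indels.
    """
    if window <= 0 or len(query) < min(window, 1):
        return 0.0
    q = seq_to_codes(query)
    t = seq_to_codes(target)
    best = 0.0
    for off in _diagonal_offsets(query, target, k):
        qs = max(0, -off)
        ts = max(0, off)
        n = min(len(q) - qs, len(t) - ts)
        if n < window:
            continue
        m = (q[qs:qs + n] == t[ts:ts + n]).astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(m)))
        wins = cs[window:] - cs[:-window]
        best = max(best, float(wins.max()) / window)
    return best


def best_window_identity_ds(query: str, target: str, window: int,
                            k: int = 15) -> float:
    """Strand-aware :func:`best_window_identity`."""
    return max(best_window_identity(query, target, window, k),
               best_window_identity(revcomp(query), target, window, k))
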