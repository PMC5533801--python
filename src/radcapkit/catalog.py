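"""ddRAD loci catalogue construction and probe-template selection.

A miniature RAD assembler: greedy within-sample clustering of reads into
allele clusters with IUPAC consensus, greedy across-sample clustering into
catalogue loci, paralog screening by shared heterozygosity and by pairwise
similarity, low-complexity masking, mitochondrial screening, redundancy
resolution across assemblies, candidate selection and 120-mer probe tiling.

Identity is defined as matches / alignment columns of a global alignment of
the compared region, gaps counted as mismatches; greedy seeding is by
descending read abundance with ties broken lexicographically, which keeps
every stage deterministic.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._seq import (KmerIndex, best_window_identity_ds, global_identity,
                   hamming, revcomp, seq_to_codes)
from .records import SeqRead

#: flags that exclude a locus from probe-template candidacy
DISCARD_FLAGS = frozenset({"paralog_shared_het", "paralog_similarity",
                           "low_complexity"})

_IUPAC2 = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GT"): "K",
           frozenset("AC"): "M", frozenset("CG"): "S", frozenset("AT"): "W"}
_AMBIG = set(_IUPAC2.values())


@dataclass
class CatalogThresholds:
    """All knobs of the catalogue stage, defaults as used throughout."""

    within_sim: float = 0.95
    across_sim: float = 0.85
    max_mismatch: int = 3
    max_site_het: float = 0.5
    shared_het_max_individuals: int = 4
    paralog_filter: int = 3
    min_individuals_single: int = 10
    min_individuals_combined: int = 20
    purge_similarity: float = 0.90
    purge_coverage: float = 0.55
    assembly_sim: float = 0.75
    probe_len: int = 120
    probe_step: int = 60


@dataclass
class SampleCluster:
    """Within-sample allele cluster: consensus with IUPAC het columns."""

    consensus: str
    depth: int
    het_columns: list[int]
    sample: str = ""

    @property
    def alleles(self) -> tuple[str, str]:
        """Expand ambiguity columns into an (unphased) allele pair."""
        a0, a1 = [], []
        for ch in self.consensus:
            if ch in _AMBIG:
                pair = next(k for k, v in _IUPAC2.items() if v == ch)
                b0, b1 = sorted(pair)
                a0.append(b0)
                a1.append(b1)
            else:
                a0.append(ch)
                a1.append(ch)
        return "".join(a0), "".join(a1)


@dataclass
class CatalogLocus:
    """A consensus locus with per-sample allele pairs and filter flags."""

    locus_id: str
    consensus: str
    per_sample_alleles: dict[str, tuple[str, str]]
    source_assembly: str = "combined"
    flags: set[str] = field(default_factory=set)
    #: per-sample cluster consensi (IUPAC), for shared-het screening
    sample_consensi: dict[str, str] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.per_sample_alleles)

    @property
    def discarded(self) -> bool:
        return bool(self.flags & DISCARD_FLAGS)


@dataclass
class Probe:
    """A 120-mer capture probe tiled from a template locus."""

    probe_id: str
    parent_locus_id: str
    offset: int
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != 120:
            raise ValueError(f"probe {self.probe_id} is not 120 bp")


def _column_consensus(columns: np.ndarray, weights: np.ndarray) -> tuple[str, list[int]]:
    """IUPAC consensus over a (reads x positions) code matrix.

    A column is called ambiguous when two bases each carry more than 25%
    of the column depth.
    """
    out = []
    het_cols = []
    n_pos = columns.shape[1]
    total = weights.sum()
    for j in range(n_pos):
        counts = np.bincount(columns[:, j], weights=weights,
                             minlength=5)[:4]
        if counts.sum() == 0:
            out.append("N")
            continue
        order = np.argsort(-counts, kind="stable")
        b0, b1 = int(order[0]), int(order[1])
        if counts[b1] > 0.25 * total and counts[b0] > 0.25 * total:
            out.append(_IUPAC2[frozenset("ACGT"[b] for b in (b0, b1))])
            het_cols.append(j)
        else:
            out.append("ACGT"[b0])
    return "".join(out), het_cols


def cluster_within_sample(reads: list[SeqRead],
                          thresholds: CatalogThresholds | None = None,
                          sample: str = "") -> list[SampleCluster]:
    """Greedily cluster one sample's reads into allele clusters.

    Reads join a seed when identity >= ``within_sim`` AND mismatches <=
    ``max_mismatch``; seeds are unique sequences in order of descending
    abundance.  Clusters whose fraction of ambiguous consensus columns
    exceeds ``max_site_het`` are discarded (putative paralog stacks).
    Reads shorter than 50 bp are rejected.
    """
    t = thresholds or CatalogThresholds()
    reads = [r for r in reads if len(r) >= 50]
    if not reads:
        return []
    abundance = Counter(r.seq for r in reads)
    uniq = sorted(abundance, key=lambda s: (-abundance[s], s))

    seeds: list[str] = []
    members: list[list[str]] = []
    index = KmerIndex(k=15)
    for seq in uniq:
        best_i, best_ident, best_seq = -1, 0.0, seq
        for name in index.candidates_ds(seq, stride=4):
            i = int(name)
            for oriented in (seq, revcomp(seq)):
                ident = global_identity(oriented, seeds[i])
                if (ident >= t.within_sim
                        and hamming(oriented, seeds[i]) <= t.max_mismatch
                        and abs(len(seq) - len(seeds[i])) <= t.max_mismatch
                        and ident > best_ident):
                    best_i, best_ident, best_seq = i, ident, oriented
        if best_i < 0:
            index.add(str(len(seeds)), seq)
            seeds.append(seq)
            members.append([(seq, abundance[seq])])
        else:
            members[best_i].append((best_seq, abundance[seq]))

    clusters: list[SampleCluster] = []
    for seed, mem in zip(seeds, members):
        L = len(seed)
        mat = np.full((len(mem), L), 4, dtype=np.uint8)
        w = np.zeros(len(mem))
        for i, (seq, count) in enumerate(mem):
            codes = seq_to_codes(seq)[:L]
            mat[i, :len(codes)] = codes
            w[i] = count
        cons, het_cols = _column_consensus(mat, w)
        depth = int(w.sum())
        if L and len(het_cols) / L > t.max_site_het:
            continue
        clusters.append(SampleCluster(cons, depth, het_cols, sample=sample))
    clusters.sort(key=lambda c: (-c.depth, c.consensus))
    return clusters


def build_catalog(per_sample_clusters: dict[str, list[SampleCluster]],
                  sim: float | None = None,
                  thresholds: CatalogThresholds | None = None,
                  source_assembly: str = "combined") -> list[CatalogLocus]:
    """Across-sample greedy clustering of sample consensi into catalogue
    loci at similarity ``sim``, with paralog screening.

    A locus is flagged ``paralog_shared_het`` when the same consensus
    column is heterozygous in more than ``shared_het_max_individuals``
    samples, or when any column shows more than ``paralog_filter``
    distinct bases across samples.
    """
    t = thresholds or CatalogThresholds()
    if sim is None:
        sim = t.across_sim
    items = []
    for sample, clusters in per_sample_clusters.items():
        for c in clusters:
            items.append((sample, c))
    items.sort(key=lambda it: (-it[1].depth, it[1].consensus, it[0]))

    seeds: list[str] = []
    grouped: list[list[tuple[str, SampleCluster]]] = []
    index = KmerIndex(k=15)
    for sample, c in items:
        plain = re.sub(f"[{''.join(_AMBIG)}]", "N", c.consensus)
        best_i, best_ident, flip = -1, 0.0, False
        for name in index.candidates_ds(plain, stride=4):
            i = int(name)
            for rev in (False, True):
                cand_seq = revcomp(plain) if rev else plain
                ident = global_identity(cand_seq, seeds[i])
                if ident >= sim and ident > best_ident:
                    best_i, best_ident, flip = i, ident, rev
        if best_i < 0:
            index.add(str(len(seeds)), plain)
            seeds.append(plain)
            grouped.append([(sample, c)])
        else:
            if flip:
                c = SampleCluster(revcomp(c.consensus), c.depth,
                                  [len(c.consensus) - 1 - j
                                   for j in reversed(c.het_columns)],
                                  sample=c.sample)
            grouped[best_i].append((sample, c))

    loci: list[CatalogLocus] = []
    for gi, group in enumerate(grouped):
        L = len(group[0][1].consensus)
        per_sample: dict[str, tuple[str, str]] = {}
        consensi: dict[str, str] = {}
        for sample, c in group:
            if sample in per_sample:      # two clusters = two alleles
                prev = consensi[sample]
                per_sample[sample] = (prev, c.consensus)
            else:
                per_sample[sample] = c.alleles
                consensi[sample] = c.consensus
        mat = np.full((len(group), L), 4, dtype=np.uint8)
        for i, (_, c) in enumerate(group):
            codes = seq_to_codes(c.consensus)[:L]
            mat[i, :len(codes)] = codes
        cons, _ = _column_consensus(mat, np.ones(len(group)))
        locus = CatalogLocus(
            locus_id=f"{source_assembly}_{gi:05d}", consensus=cons,
            per_sample_alleles=per_sample, source_assembly=source_assembly,
            sample_consensi=consensi)
        _flag_shared_het(locus, t)
        loci.append(locus)
    return loci


def _flag_shared_het(locus: CatalogLocus, t: CatalogThresholds) -> None:
    L = len(locus.consensus)
    het_count = np.zeros(L, dtype=int)
    base_sets: list[set[str]] = [set() for _ in range(L)]
    for sample, cons in locus.sample_consensi.items():
        for j, ch in enumerate(cons[:L]):
            if ch in _AMBIG:
                het_count[j] += 1
        a0, a1 = locus.per_sample_alleles[sample]
        for j in range(min(L, len(a0), len(a1))):
            base_sets[j].add(a0[j])
            base_sets[j].add(a1[j])
    if het_count.max(initial=0) > t.shared_het_max_individuals:
        locus.flags.add("paralog_shared_het")
    if any(len(s - {"N"}) > t.paralog_filter for s in base_sets):
        locus.flags.add("paralog_shared_het")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def synonymize_redundant(catalogs: list[list[CatalogLocus]],
                         thresholds: CatalogThresholds | None = None
                         ) -> tuple[list[CatalogLocus], int]:
    """Merge loci present in multiple assemblies into single loci.

    Loci from *different* source assemblies whose consensi match at
    identity >= ``purge_similarity`` over >= ``purge_coverage`` of the
    shorter length are merged (transitively); the merged locus keeps the
    longer consensus and the union of per-sample alleles, and carries the
    informational flag ``redundant_resolved``.  Returns (merged catalogue,
    number of merge events).
    """
    if len(catalogs) < 2:
        raise ValueError("synonymize_redundant needs at least two catalogues")
    t = thresholds or CatalogThresholds()
    all_loci = [loc for cat in catalogs for loc in cat]
    uf = _UnionFind(len(all_loci))
    index = KmerIndex(k=15)
    for i, loc in enumerate(all_loci):
        index.add(str(i), loc.consensus)
    for i, loc in enumerate(all_loci):
        for name in index.candidates_ds(loc.consensus, stride=4, min_shared=2):
            j = int(name)
            other = all_loci[j]
            if j <= i or other.source_assembly == loc.source_assembly:
                continue
            shorter, longer = sorted((loc.consensus, other.consensus),
                                     key=len)
            w = int(np.ceil(t.purge_coverage * len(shorter)))
            if best_window_identity_ds(shorter, longer, w) >= t.purge_similarity:
                uf.union(i, j)

    groups: dict[int, list[CatalogLocus]] = defaultdict(list)
    for i, loc in enumerate(all_loci):
        groups[uf.find(i)].append(loc)

    merged: list[CatalogLocus] = []
    n_merges = 0
    for root in sorted(groups):
        group = groups[root]
        if len(group) == 1:
            merged.append(group[0])
            continue
        n_merges += len(group) - 1
        group.sort(key=lambda l: (-len(l.consensus), l.locus_id))
        keeper = group[0]
        per_sample = dict(keeper.per_sample_alleles)
        consensi = dict(keeper.sample_consensi)
        flags = set(keeper.flags) | {"redundant_resolved"}
        for other in group[1:]:
            for s, alleles in other.per_sample_alleles.items():
                per_sample.setdefault(s, alleles)
            for s, cons in other.sample_consensi.items():
                consensi.setdefault(s, cons)
            flags |= other.flags
        merged.append(CatalogLocus(
            locus_id=keeper.locus_id, consensus=keeper.consensus,
            per_sample_alleles=per_sample,
            source_assembly=keeper.source_assembly, flags=flags,
            sample_consensi=consensi))
    return merged, n_merges


def purge_similar_loci(catalogue: list[CatalogLocus],
                       thresholds: CatalogThresholds | None = None
                       ) -> list[CatalogLocus]:
    """Flag paralog families by pairwise similarity.

    Any pair of loci matching at identity > ``purge_similarity`` over >=
    ``purge_coverage`` of the shorter locus flags BOTH loci with
    ``paralog_similarity``.  Pairs are pre-screened by shared k-mers
    (pairs below the liberal ``assembly_sim`` grouping threshold share
    none of interest).  Flags are only ever added, never removed.
    """
    t = thresholds or CatalogThresholds()
    index = KmerIndex(k=15)
    for i, loc in enumerate(catalogue):
        index.add(str(i), loc.consensus)
    for i, loc in enumerate(catalogue):
        for name in index.candidates_ds(loc.consensus, stride=4, min_shared=2):
            j = int(name)
            if j <= i:
                continue
            other = catalogue[j]
            shorter, longer = sorted((loc.consensus, other.consensus),
                                     key=len)
            w = int(np.ceil(t.purge_coverage * len(shorter)))
            ident = best_window_identity_ds(shorter, longer, w)
            if ident > t.purge_similarity:
                loc.flags.add("paralog_similarity")
                other.flags.add("paralog_similarity")
    return catalogue


def dust_score(seq: str, window: int = 64, step: int = 32) -> float:
    """DUST-style low-complexity score: max over windows of
    sum(c*(c-1)/2) over triplet counts c, normalised by (#triplets - 1).
    """
    best = 0.0
    n = len(seq)
    starts = range(0, max(1, n - window + 1), step)
    for s in starts:
        chunk = seq[s:s + window]
        if len(chunk) < 4:
            continue
        counts = Counter(chunk[i:i + 3] for i in range(len(chunk) - 2))
        n_trip = len(chunk) - 2
        score = sum(c * (c - 1) / 2 for c in counts.values()) / max(1, n_trip - 1)
        best = max(best, score)
    return best


def mask_low_complexity(catalogue: list[CatalogLocus],
                        max_homopolymer: int = 10,
                        dust_threshold: float = 2.0) -> list[CatalogLocus]:
    """Flag loci containing a homopolymer run >= ``max_homopolymer`` or a
    DUST score above ``dust_threshold`` with ``low_complexity``."""
    run_re = re.compile("|".join(f"{b}{{{max_homopolymer},}}" for b in "ACGT"))
    for loc in catalogue:
        if run_re.search(loc.consensus) or dust_score(loc.consensus) > dust_threshold:
            loc.flags.add("low_complexity")
    return catalogue


def screen_mitochondrial(catalogue: list[CatalogLocus],
                         mito_reference: str | None,
                         min_identity: float = 0.80,
                         min_coverage: float = 0.50) -> list[CatalogLocus]:
    """Flag loci aligning to the mitochondrial reference (either strand)
    at >= ``min_identity`` over >= ``min_coverage`` of the locus length.

    Flagged loci stay in the catalogue; whether they feed probe templates
    is decided at selection time.  A missing reference skips screening
    with a warning.
    """
    if not mito_reference:
        warnings.warn("no mitochondrial reference supplied; screen skipped")
        return catalogue
    for loc in catalogue:
        w = int(np.ceil(min_coverage * len(loc.consensus)))
        if best_window_identity_ds(loc.consensus, mito_reference,
                                   w) >= min_identity:
            loc.flags.add("mitochondrial")
    return catalogue


def select_candidates(catalogue: list[CatalogLocus],
                      thresholds: CatalogThresholds | None = None,
                      include_mitochondrial: bool = True
                      ) -> list[CatalogLocus]:
    """Flag probe-template candidates.

    A locus qualifies when it carries no discard flag and is shared across
    at least ``min_individuals_single`` individuals (single-species
    assembly) or ``min_individuals_combined`` (combined assembly).
    Mitochondrial loci are retained by default.
    """
    t = thresholds or CatalogThresholds()
    out = []
    for loc in catalogue:
        if loc.discarded:
            continue
        if not include_mitochondrial and "mitochondrial" in loc.flags:
            continue
        need = (t.min_individuals_combined
                if loc.source_assembly == "combined"
                else t.min_individuals_single)
        if loc.n_individuals >= need:
            loc.flags.add("candidate")
            out.append(loc)
    return out


def tile_offsets(length: int, probe_len: int = 120,
                 step: int = 60) -> list[int]:
    """Probe start offsets for one template: stepped starts plus a
    right-anchored final probe; duplicate offsets collapse."""
    if length < probe_len:
        raise ValueError(f"template shorter than probe length ({length} bp)")
    offsets = set(range(0, length - probe_len + 1, step))
    offsets.add(length - probe_len)
    return sorted(offsets)


def tile_probes(templates: list[CatalogLocus],
                thresholds: CatalogThresholds | None = None) -> list[Probe]:
    """Tile 120-mer probes at 60 bp step along every template, the final
    probe right-anchored at (length - 120).  Errors name the offending
    locus."""
    t = thresholds or CatalogThresholds()
    probes: list[Probe] = []
    for loc in templates:
        seq = loc.consensus
        if len(seq) < t.probe_len:
            raise ValueError(
                f"template {loc.locus_id} is {len(seq)} bp, shorter than "
                f"the {t.probe_len} bp probe length")
        for off in tile_offsets(len(seq), t.probe_len, t.probe_step):
            probes.append(Probe(f"{loc.locus_id}_p{off:04d}", loc.locus_id,
                                off, seq[off:off + t.probe_len]))
    return probes
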