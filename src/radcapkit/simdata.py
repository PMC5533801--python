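"""Synthetic multi-species ddRAD / target-capture experiments with known truth.

The generator emulates, at desk scale, the phenomena a reduced-representation
capture study has to cope with:

* restriction loci drawn from a common ancestor, with a 6 bp restriction
  half-site at each end (a double-digest design: one enzyme motif per side);
* species divergence under an equal-rates (Jukes-Cantor-style) substitution
  model, parameterised as per-site substitution probability from the ancestor;
* within-individual heterozygosity at rate ``theta_het`` per site;
* allele dropout from ddRAD libraries whenever a restriction half-site carries
  a substitution — the classic source of RAD missing data;
* capture-mode coverage decay with divergence from the probe design species
  (efficiency halves every ``capture_halflife`` substitutions/site), but loci
  are never lost outright: hybridisation pulls down divergent fragments at
  reduced, non-zero rate;
* sonication-style random fragments (capture) vs whole-locus restriction
  fragments (ddRAD) — the fragment-identity contrast that makes PCR duplicate
  marking possible in capture libraries only;
* PCR duplicates: exact fragment copies with independent sequencing errors;
* museum mode: short inserts plus terminal cytosine deamination, C->T from
  the 5' end and G->A from the 3' end with probability
  ``damage_delta * damage_lambda**(position-1)``.

Substitutions only — no indels and no realistic error profiles by design, so
closed-form expectations stay available for every downstream test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .records import ReadPair, SeqRead

# Double-digest motifs flanking every ancestral locus (EcoRI / PstI style).
LEFT_SITE = "GAATTC"
RIGHT_SITE = "CTGCAG"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 0
    n_loci: int = 100
    locus_length_range: tuple[int, int] = (140, 220)
    species_divergences: dict[str, float] = field(
        default_factory=lambda: {"spA": 0.02, "spB": 0.05, "spC": 0.08})
    n_individuals_per_species: int = 8
    theta_het: float = 0.005
    restriction_site_len: int = 6
    dropout_per_substitution: float = 1.0
    capture_halflife: float = 0.05
    coverage_mean: float = 20.0
    error_rate: float = 0.01
    duplicate_fraction: float = 0.0
    damage_delta: float = 0.0
    damage_lambda: float = 0.5
    fragmentation_mean: int = 70
    era: str = "modern"
    read_len: int = 120
    fragment_len_mean: int = 170
    fragment_len_sd: int = 25

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        lo, hi = self.locus_length_range
        if not (121 <= lo <= hi <= 1000):
            raise ValueError("locus_length_range must lie within [121, 1000]")
        for name, d in self.species_divergences.items():
            if not 0.0 <= d <= 0.75:
                raise ValueError(
                    f"divergence for {name} must be in [0, 0.75], got {d}")
        for attr in ("theta_het", "dropout_per_substitution", "error_rate",
                     "duplicate_fraction", "damage_delta", "damage_lambda"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be a probability, got {v}")
        if self.era not in ("modern", "museum"):
            raise ValueError(f"era must be 'modern' or 'museum', got {self.era}")

    @property
    def individuals(self) -> list[tuple[str, str]]:
        """(sample_id, species) in deterministic order."""
        out = []
        for sp in self.species_divergences:
            for i in range(self.n_individuals_per_species):
                out.append((f"{sp}_{i:02d}", sp))
        return out

    @property
    def base_quality(self) -> int:
        """Constant Phred quality matching the configured error rate."""
        if self.error_rate <= 0:
            return 40
        return int(np.clip(round(-10 * math.log10(self.error_rate)), 2, 40))


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    config: SimulationConfig
    ancestral_loci: list[SeqRead]
    species_haplotypes: dict[tuple[str, str], str]
    #: (sample, locus) -> (allele0, allele1) full sequences
    genotypes: dict[tuple[str, str], tuple[str, str]]
    #: (sample, locus, allele index) dropped from a ddRAD library
    dropout_events: set[tuple[str, str, int]]
    duplicate_read_ids: set[str] = field(default_factory=set)
    #: read id -> [(0-based fragment position, original, observed)]
    damaged_positions: dict[str, list[tuple[int, str, str]]] = field(
        default_factory=dict)

    @property
    def locus_ids(self) -> list[str]:
        return [r.id for r in self.ancestral_loci]

    def locus_seq(self, locus_id: str) -> str:
        for r in self.ancestral_loci:
            if r.id == locus_id:
                return r.seq
        raise KeyError(locus_id)

    def site_genotype(self, sample: str, locus: str, site: int) -> tuple[str, str]:
        a0, a1 = self.genotypes[(sample, locus)]
        return a0[site], a1[site]


def _mutate(rng: np.random.Generator, codes: np.ndarray,
            p: float) -> np.ndarray:
    """Substitute each site with probability p, uniformly to another base."""
    out = codes.copy()
    hit = np.flatnonzero(rng.random(len(codes)) < p)
    if len(hit):
        out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


def _codes(seq: str) -> np.ndarray:
    from ._seq import seq_to_codes
    return seq_to_codes(seq).astype(np.int64)


def _to_seq(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Draw ancestral loci, species haplotypes, individual genotypes and
    ddRAD dropout events under *config*.

    Deterministic: the same config (including seed) yields an identical
    TruthSet.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0xA1])
    lo, hi = config.locus_length_range
    rs = config.restriction_site_len
    left = _codes(LEFT_SITE[:rs].ljust(rs, "A"))
    right = _codes(RIGHT_SITE[:rs].rjust(rs, "A"))

    ancestral: list[SeqRead] = []
    anc_codes: dict[str, np.ndarray] = {}
    for i in range(config.n_loci):
        length = int(rng.integers(lo, hi + 1))
        mid = rng.integers(0, 4, size=length - 2 * rs)
        codes = np.concatenate([left, mid, right])
        lid = f"locus{i:05d}"
        ancestral.append(SeqRead(lid, _to_seq(codes)))
        anc_codes[lid] = codes

    haplotypes: dict[tuple[str, str], str] = {}
    hap_codes: dict[tuple[str, str], np.ndarray] = {}
    for sp, div in config.species_divergences.items():
        for lid, codes in anc_codes.items():
            h = _mutate(rng, codes, div)
            hap_codes[(sp, lid)] = h
            haplotypes[(sp, lid)] = _to_seq(h)

    genotypes: dict[tuple[str, str], tuple[str, str]] = {}
    dropout: set[tuple[str, str, int]] = set()
    for sample, sp in config.individuals:
        for lid in anc_codes:
            base = hap_codes[(sp, lid)]
            alleles = [base.copy(), base.copy()]
            het = np.flatnonzero(rng.random(len(base)) < config.theta_het)
            for site in het:
                which = int(rng.integers(0, 2))
                alleles[which][site] = (alleles[which][site]
                                        + rng.integers(1, 4)) % 4
            genotypes[(sample, lid)] = (_to_seq(alleles[0]),
                                        _to_seq(alleles[1]))
            anc = anc_codes[lid]
            ends = np.concatenate([np.arange(rs), np.arange(len(anc) - rs,
                                                            len(anc))])
            for ai, allele in enumerate(alleles):
                n_sub = int(np.count_nonzero(allele[ends] != anc[ends]))
                if n_sub == 0:
                    continue
                p_drop = 1.0 - (1.0 - config.dropout_per_substitution) ** n_sub
                if rng.random() < p_drop:
                    dropout.add((sample, lid, ai))

    return TruthSet(config=config, ancestral_loci=ancestral,
                    species_haplotypes=haplotypes, genotypes=genotypes,
                    dropout_events=dropout)


def _apply_damage(rng: np.random.Generator, frag: list[str],
                  delta: float, lam: float) -> list[tuple[int, str, str]]:
    """Terminal deamination in the emitted fragment orientation.

    C->T with probability delta*lam**p5 near the 5' end and G->A with the
    same law from the 3' end (p counted 0-based here, 1-based in the model).
    Mutates *frag* in place; returns the event list.
    """
    events = []
    n = len(frag)
    for p in range(n):
        if frag[p] == "C":
            if rng.random() < delta * lam ** p:
                frag[p] = "T"
                events.append((p, "C", "T"))
        elif frag[p] == "G":
            if rng.random() < delta * lam ** (n - 1 - p):
                frag[p] = "A"
                events.append((p, "G", "A"))
    return events


def _sequencing_errors(rng: np.random.Generator, seq: str,
                       error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def make_index_sets(n: int, rng: np.random.Generator,
                    length: int = 8, min_dist: int = 3) -> list[str]:
    """Draw n index sequences pairwise >= min_dist mismatches apart."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(_BASES[rng.integers(0, 4, size=length)])
        if all(sum(a != b for a, b in zip(cand, prev)) >= min_dist
               for prev in out):
            out.append(cand)
    return out


def emit_reads(truth: TruthSet, config: SimulationConfig,
               mode: str) -> tuple[list[ReadPair], dict[tuple[str, str], str]]:
    """Emit paired FASTQ-style reads for *truth* in ``ddrad`` or ``capture``
    mode, returning (pairs, sample sheet mapping (i5, i7) -> sample).

    ddRAD mode emits whole-locus restriction fragments and suppresses
    dropped alleles entirely; capture mode emits sonication-style random
    fragments from both alleles, with per-locus coverage downweighted by
    ``2**(-divergence/capture_halflife)`` but floored at one fragment per
    individual and locus (enrichment decays, loci are not lost).

    Duplicate fragments, museum fragmentation/deamination and sequencing
    errors are recorded in the TruthSet (``duplicate_read_ids``,
    ``damaged_positions``).
    """
    if mode not in ("ddrad", "capture"):
        raise ValueError(f"mode must be 'ddrad' or 'capture', got {mode!r}")
    rng = np.random.default_rng(
        [config.seed, 0xE2, 0 if mode == "ddrad" else 1])
    truth.duplicate_read_ids = set()
    truth.damaged_positions = {}

    individuals = config.individuals
    i5_set = make_index_sets(max(2, math.ceil(math.sqrt(len(individuals)))),
                             rng)
    i7_set = make_index_sets(len(i5_set), rng)
    sheet: dict[tuple[str, str], str] = {}
    sample_index: dict[str, tuple[str, str]] = {}
    for i, (sample, _) in enumerate(individuals):
        key = (i5_set[i % len(i5_set)], i7_set[i // len(i5_set)])
        sheet[key] = sample
        sample_index[sample] = key

    museum = config.era == "museum"
    q = config.base_quality if not museum else min(config.base_quality, 30)

    # ---- draw unique fragments -------------------------------------------
    fragments = []  # (sample, locus, allele_i, start, length, strand, seq)
    for sample, sp in individuals:
        div = config.species_divergences[sp]
        for locus in truth.locus_ids:
            alleles = truth.genotypes[(sample, locus)]
            llen = len(alleles[0])
            if mode == "capture":
                rate = config.coverage_mean * 2.0 ** (-div / config.capture_halflife)
                n_per = rng.poisson(rate / 2.0, size=2)
                if n_per.sum() == 0:
                    n_per[int(rng.integers(0, 2))] = 1
            else:
                n_per = rng.poisson(config.coverage_mean / 2.0, size=2)
                for ai in range(2):
                    if (sample, locus, ai) in truth.dropout_events:
                        n_per[ai] = 0
            for ai in range(2):
                for _ in range(int(n_per[ai])):
                    if mode == "ddrad":
                        start, flen = 0, llen
                    elif museum:
                        flen = int(np.clip(
                            round(rng.normal(config.fragmentation_mean,
                                             config.fragmentation_mean / 4)),
                            40, min(llen, 220)))
                        start = int(rng.integers(0, llen - flen + 1))
                    else:
                        # sonication insert; mean scales down for short loci
                        # so lengths do not pile up at the locus boundary
                        mean_eff = min(config.fragment_len_mean,
                                       int(0.75 * llen))
                        flen = int(np.clip(
                            round(rng.normal(mean_eff,
                                             config.fragment_len_sd)),
                            80, min(llen, 220)))
                        start = int(rng.integers(0, llen - flen + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    frag = alleles[ai][start:start + flen]
                    if strand == "-":
                        frag = revcomp(frag)
                    fragments.append((sample, locus, ai, start, flen,
                                      strand, frag))

    # ---- PCR duplicates ---------------------------------------------------
    f = config.duplicate_fraction
    n_dup = int(round(f / (1.0 - f) * len(fragments))) if f > 0 else 0
    dup_sources = (rng.integers(0, len(fragments), size=n_dup)
                   if n_dup else [])

    # ---- damage, errors, read pairs --------------------------------------
    pairs: list[ReadPair] = []
    damaged_frags: dict[int, tuple[str, list]] = {}
    serial = 0

    def emit(frag_idx: int, is_dup: bool) -> None:
        nonlocal serial
        sample, locus, ai, start, flen, strand, frag = fragments[frag_idx]
        if frag_idx in damaged_frags:          # duplicates share the template
            frag, events = damaged_frags[frag_idx]
        elif museum and config.damage_delta > 0:
            arr = list(frag)
            events = _apply_damage(rng, arr, config.damage_delta,
                                   config.damage_lambda)
            frag = "".join(arr)
            damaged_frags[frag_idx] = (frag, events)
        else:
            events = []
            damaged_frags[frag_idx] = (frag, events)
        rid = (f"sim:{sample}:{locus}:{ai}:{start}:{flen}:{strand}:{serial:07d}")
        serial += 1
        if is_dup:
            truth.duplicate_read_ids.add(rid)
        if events:
            truth.damaged_positions[rid] = list(events)
        rl = config.read_len
        r1 = _sequencing_errors(rng, frag[:rl], config.error_rate)
        r2 = _sequencing_errors(rng, revcomp(frag)[:rl], config.error_rate)
        qual1 = np.full(len(r1), q, dtype=np.uint8)
        qual2 = np.full(len(r2), q, dtype=np.uint8)
        i5, i7 = sample_index[sample]
        pairs.append(ReadPair(SeqRead(rid + "/1", r1, qual1),
                              SeqRead(rid + "/2", r2, qual2), i5=i5, i7=i7))

    for idx in range(len(fragments)):
        emit(idx, False)
    for src in dup_sources:
        emit(int(src), True)

    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order], sheet


def truth_alignments(merged_reads: list[SeqRead]) -> list:
    """Perfect alignments reconstructed from simulator read ids.

    Merged reads carry their origin in the id
    (``sim:sample:locus:allele:start:length:strand:serial``); this places
    each one at its true coordinates with maQ 60, bypassing the mapper.
    Useful for evaluating the caller and damage profiler in isolation.
    """
    from ._seq import revcomp as _rc
    from .capture import AlignmentRecord
    out = []
    for read in merged_reads:
        _, sample, locus, _ai, start, flen, strand, _ = read.id.split(":")
        start, flen = int(start), int(flen)
        seq = read.seq if strand == "+" else _rc(read.seq)
        qual = read.qual
        if strand == "-" and qual is not None:
            qual = qual[::-1]
        out.append(AlignmentRecord(
            read_id=read.id, locus_id=locus, start=start,
            end=start + min(flen, len(read.seq)), strand=strand,
            n_mismatch=0, maq=60, insert_len=len(read.seq), sample=sample,
            seq=seq, qual=qual))
    return out


def missing_locus_fraction(truth: TruthSet,
                           pairs: list[ReadPair]) -> dict[str, float]:
    """Per-sample fraction of loci with zero emitted fragments.

    Reads are attributed by their simulator-truth ids.
    """
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        _, sample, locus = p.read1.id.split(":")[:3]
        seen.add((sample, locus))
    loci = truth.locus_ids
    out = {}
    for sample, _ in truth.config.individuals:
        n_missing = sum((sample, lid) not in seen for lid in loci)
        out[sample] = n_missing / len(loci)
    return out
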