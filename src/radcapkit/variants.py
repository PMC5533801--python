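"""Diploid genotype calling from duplicate-marked alignments and the
hard-filter battery producing an analysis-ready biallelic variant set.

The caller is a standard per-site diploid likelihood model with a flat
genotype prior: P(base | hom) = 1-e for the matching allele and e/3
otherwise, a heterozygote emits either allele at probability 1/2, with e
taken from the base quality.  Site annotations follow the conventional
hard-filter vocabulary: QUAL (phred-scaled probability that every sample
is homozygous reference), QD (QUAL over the summed depth of
alt-carrying samples), MQ (root-mean-square mapping quality), FS
(phred-scaled two-sided Fisher exact strand test) and a rank-sum z of
alt vs ref distances from the nearer read end.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._seq import seq_to_codes
from .capture import AlignmentRecord

_GENOTYPES = ("0/0", "0/1", "1/1")


@dataclass
class FilterThresholds:
    qd_min: float = 4.0
    mq_rms_min: float = 18.0
    qual_min: float = 40.0
    fs_max: float = 60.0
    site_depth_min: int = 5
    min_samples_at_depth: int = 8
    read_pos_z_min: float = -12.0
    biallelic_only: bool = True


@dataclass
class SampleCall:
    genotype: str = "./."      # 0/0, 0/1, 1/1 or ./.
    depth: int = 0
    allele_depths: tuple[int, int] = (0, 0)
    gq: float = 0.0
    log10_likelihoods: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class VariantSite:
    ref_id: str
    pos: int                   # 0-based
    ref_base: str
    alt_bases: list[str]
    per_sample: dict[str, SampleCall] = field(default_factory=dict)
    qual: float = 0.0
    qd: float = 0.0
    mq_rms: float = 0.0
    fs: float = 0.0
    read_pos_z: float = 0.0
    filter_status: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.filter_status

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_bases) == 1

    def allele_counts(self) -> tuple[int, int]:
        """(ref, alt) allele counts over called genotypes."""
        n_ref = n_alt = 0
        for call in self.per_sample.values():
            if call.genotype == "./.":
                continue
            alt = call.genotype.count("1")
            n_alt += alt
            n_ref += 2 - alt
        return n_ref, n_alt

    def major_minor(self) -> tuple[str, str] | None:
        """Major and minor allele by frequency; ties resolve the
        reference base as major.  None for monomorphic calls."""
        if not self.alt_bases:
            return None
        n_ref, n_alt = self.allele_counts()
        if n_alt == 0:
            return None
        if n_alt > n_ref:
            return self.alt_bases[0], self.ref_base
        return self.ref_base, self.alt_bases[0]


def genotype_log10_likelihoods(n_ref: int, n_alt: int, n_other: int,
                               error_rate: float
                               ) -> tuple[float, float, float]:
    """log10 likelihoods of (hom-ref, het, hom-alt) for a pileup with
    constant per-base error rate."""
    e = min(max(error_rate, 1e-6), 0.75)
    log_match = math.log10(1 - e)
    log_err = math.log10(e / 3)
    log_het = math.log10(0.5 * (1 - e) + 0.5 * e / 3)
    ll_rr = n_ref * log_match + (n_alt + n_other) * log_err
    ll_aa = n_alt * log_match + (n_ref + n_other) * log_err
    ll_ra = (n_ref + n_alt) * log_het + n_other * log_err
    return ll_rr, ll_ra, ll_aa


def call_genotype(n_ref: int, n_alt: int, n_other: int,
                  error_rate: float) -> SampleCall:
    """Maximum-likelihood diploid genotype with flat prior; GQ is the
    phred gap to the runner-up.  Zero depth yields a missing call."""
    depth = n_ref + n_alt + n_other
    if depth == 0:
        return SampleCall()
    lls = genotype_log10_likelihoods(n_ref, n_alt, n_other, error_rate)
    order = sorted(range(3), key=lambda i: -lls[i])
    gq = 10.0 * (lls[order[0]] - lls[order[1]])
    return SampleCall(genotype=_GENOTYPES[order[0]], depth=depth,
                      allele_depths=(n_ref, n_alt), gq=gq,
                      log10_likelihoods=lls)


def _log10_p_homref(lls: tuple[float, float, float]) -> float:
    """log10 posterior probability of hom-ref under a flat prior."""
    m = max(lls)
    total = sum(10.0 ** (l - m) for l in lls)
    return (lls[0] - m) - math.log10(total)


@dataclass
class SitePileup:
    """Columnar pileup of one site: parallel arrays over covering reads."""

    samples: np.ndarray    # int index into `sample_names`
    codes: np.ndarray      # base codes 0..4
    quals: np.ndarray
    strands: np.ndarray    # 0 = '+', 1 = '-'
    dists: np.ndarray      # distance from the nearer read end
    maqs: np.ndarray
    sample_names: list[str]


def _locus_arrays(alignments: list[AlignmentRecord], locus_len: int
                  ) -> tuple[np.ndarray, ...] | None:
    """Concatenate per-base arrays over all non-duplicate alignments."""
    pos_l, code_l, qual_l, samp_l, strand_l, dist_l, maq_l = ([] for _ in range(7))
    names: list[str] = []
    name_idx: dict[str, int] = {}
    for rec in alignments:
        if rec.is_duplicate:
            continue
        codes = seq_to_codes(rec.seq)
        n = min(len(codes), rec.end - rec.start, locus_len - rec.start)
        if n <= 0:
            continue
        if rec.sample not in name_idx:
            name_idx[rec.sample] = len(names)
            names.append(rec.sample)
        quals = (rec.qual[:n] if rec.qual is not None
                 else np.full(n, 30, dtype=np.uint8))
        k = np.arange(n)
        pos_l.append(rec.start + k)
        code_l.append(codes[:n])
        qual_l.append(np.asarray(quals, dtype=np.int16))
        samp_l.append(np.full(n, name_idx[rec.sample], dtype=np.int32))
        strand_l.append(np.full(n, 0 if rec.strand == "+" else 1,
                                dtype=np.int8))
        dist_l.append(np.minimum(k, n - 1 - k).astype(np.int32))
        maq_l.append(np.full(n, rec.maq, dtype=np.int16))
    if not pos_l:
        return None
    return (np.concatenate(pos_l), np.concatenate(code_l),
            np.concatenate(qual_l), np.concatenate(samp_l),
            np.concatenate(strand_l), np.concatenate(dist_l),
            np.concatenate(maq_l), names)


def call_variants(alignments: list[AlignmentRecord],
                  reference: dict[str, str],
                  min_alt_reads: int = 2) -> list[VariantSite]:
    """Call and annotate variant sites over every reference locus.

    A site is emitted when at least ``min_alt_reads`` non-duplicate reads
    support a non-reference base.  Alt alleles are all non-reference bases
    reaching that support; multi-allelic sites are emitted and left to the
    biallelic hard filter.
    """
    by_locus: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        by_locus[rec.locus_id].append(rec)
    sites: list[VariantSite] = []
    for locus in sorted(by_locus):
        ref_seq = reference[locus]
        ref_codes = seq_to_codes(ref_seq).astype(np.int64)
        arrays = _locus_arrays(by_locus[locus], len(ref_seq))
        if arrays is None:
            continue
        pos, codes, quals, samps, strands, dists, maqs, names = arrays
        # per-position per-base counts to find candidate variant sites
        valid = codes < 4
        counts = np.zeros((len(ref_seq), 4), dtype=np.int32)
        np.add.at(counts, (pos[valid], codes[valid].astype(np.int64)), 1)
        nonref = counts.copy()
        nonref[np.arange(len(ref_seq)), ref_codes] = 0
        cand_pos = np.flatnonzero(nonref.max(axis=1) >= min_alt_reads)
        for p in cand_pos:
            mask = pos == p
            pile = SitePileup(samples=samps[mask], codes=codes[mask],
                              quals=quals[mask], strands=strands[mask],
                              dists=dists[mask], maqs=maqs[mask],
                              sample_names=names)
            ref_code = int(ref_codes[p])
            order = np.argsort(-nonref[p])
            alt_codes = [int(c) for c in order
                         if c != ref_code and nonref[p, c] >= min_alt_reads]
            sites.append(_call_site(locus, int(p), ref_code, alt_codes, pile))
    return sites


def _call_site(locus: str, pos: int, ref_code: int, alt_codes: list[int],
               pile: SitePileup) -> VariantSite:
    alt0 = alt_codes[0]
    site = VariantSite(ref_id=locus, pos=pos, ref_base="ACGT"[ref_code],
                       alt_bases=["ACGT"[c] for c in alt_codes])
    log10_homref_sum = 0.0
    for si in sorted(set(int(s) for s in pile.samples)):
        mask = pile.samples == si
        obs = pile.codes[mask]
        n_ref = int(np.count_nonzero(obs == ref_code))
        n_alt = int(np.count_nonzero(obs == alt0))
        n_other = int(mask.sum()) - n_ref - n_alt
        e = 10.0 ** (-float(np.mean(pile.quals[mask])) / 10.0)
        call = call_genotype(n_ref, n_alt, n_other, e)
        site.per_sample[pile.sample_names[si]] = call
        log10_homref_sum += _log10_p_homref(call.log10_likelihoods)
    site.qual = -10.0 * log10_homref_sum
    annotate_site(site, pile)
    return site


def annotate_site(site: VariantSite, pile: SitePileup) -> VariantSite:
    """Fill QD, MQ rms, FS and the read-position rank-sum z statistic."""
    ref_code = "ACGT".index(site.ref_base)
    alt_code = "ACGT".index(site.alt_bases[0]) if site.alt_bases else -1

    variant_depth = sum(
        call.depth for s, call in site.per_sample.items()
        if "1" in call.genotype)
    site.qd = site.qual / variant_depth if variant_depth else 0.0

    site.mq_rms = (float(np.sqrt(np.mean(pile.maqs.astype(float) ** 2)))
                   if len(pile.maqs) else 0.0)

    is_ref = pile.codes == ref_code
    is_alt = pile.codes == alt_code
    table = np.array(
        [[np.count_nonzero(is_ref & (pile.strands == 0)),
          np.count_nonzero(is_ref & (pile.strands == 1))],
         [np.count_nonzero(is_alt & (pile.strands == 0)),
          np.count_nonzero(is_alt & (pile.strands == 1))]])
    site.fs = fisher_strand(table)
    ref_dists = pile.dists[is_ref]
    alt_dists = pile.dists[is_alt]
    if len(ref_dists) and len(alt_dists):
        z = sps.ranksums(alt_dists, ref_dists).statistic
        site.read_pos_z = 0.0 if math.isnan(z) else float(z)
    else:
        site.read_pos_z = 0.0
    return site


def fisher_strand(table: np.ndarray) -> float:
    """Phred-scaled two-sided Fisher exact p of a 2x2 strand/allele
    table; degenerate margins give 0."""
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0
    p = sps.fisher_exact(table, alternative="two-sided")[1]
    return max(0.0, -10.0 * math.log10(max(p, 1e-300)))


def hard_filter(sites: list[VariantSite],
                thresholds: FilterThresholds | None = None
                ) -> tuple[list[VariantSite], dict[str, int]]:
    """Apply the hard-filter battery; returns (PASS sites, per-filter
    failure counts).

    A site fails when QD < 4, MQ rms < 18, QUAL < 40, FS > 60, fewer than
    8 samples reach 5X depth, or (for heterozygous-driven sites) the
    read-position z falls below -12.  Only biallelic PASS sites are
    retained.
    """
    t = thresholds or FilterThresholds()
    counts: dict[str, int] = defaultdict(int)
    passed = []
    for site in sites:
        site.filter_status = set()
        if site.qd < t.qd_min:
            site.filter_status.add("QD")
        if site.mq_rms < t.mq_rms_min:
            site.filter_status.add("MQ")
        if site.qual < t.qual_min:
            site.filter_status.add("QUAL")
        if site.fs > t.fs_max:
            site.filter_status.add("FS")
        n_at_depth = sum(1 for c in site.per_sample.values()
                         if c.depth >= t.site_depth_min)
        if n_at_depth < t.min_samples_at_depth:
            site.filter_status.add("depth")
        has_het = any(c.genotype == "0/1" for c in site.per_sample.values())
        if has_het and site.read_pos_z < t.read_pos_z_min:
            site.filter_status.add("ReadPos")
        if t.biallelic_only and not site.is_biallelic:
            site.filter_status.add("biallelic")
        if site.filter_status:
            for name in site.filter_status:
                counts[name] += 1
        else:
            passed.append(site)
    return passed, dict(counts)


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class VariantSummary:
    n_sites: int
    n_transitions: int
    n_transversions: int
    tstv: float                       # inf marker when no transversions
    n_deamination_candidates: int
    per_species_snps: dict[str, int]
    snps_per_locus: dict[str, int]


def variant_summaries(sites: list[VariantSite],
                      species_of: dict[str, str] | None = None
                      ) -> VariantSummary:
    """ts/tv ratio, deamination-candidate counts and per-species /
    per-locus SNP counts over (typically PASS) sites.

    A deamination candidate is a site whose major-to-minor direction is
    C->T or G->A.
    """
    n_ts = n_tv = n_deam = 0
    per_species: dict[str, int] = defaultdict(int)
    per_locus: dict[str, int] = defaultdict(int)
    for site in sites:
        if not site.alt_bases:
            continue
        pair = frozenset((site.ref_base, site.alt_bases[0]))
        if pair in _TRANSITIONS:
            n_ts += 1
        else:
            n_tv += 1
        mm = site.major_minor()
        if mm in (("C", "T"), ("G", "A")):
            n_deam += 1
        per_locus[site.ref_id] += 1
        if species_of:
            seen = set()
            for sample, call in site.per_sample.items():
                if "1" in call.genotype and sample in species_of:
                    seen.add(species_of[sample])
            for sp in seen:
                per_species[sp] += 1
    tstv = n_ts / n_tv if n_tv else math.inf
    return VariantSummary(n_sites=len(sites), n_transitions=n_ts,
                          n_transversions=n_tv, tstv=tstv,
                          n_deamination_candidates=n_deam,
                          per_species_snps=dict(per_species),
                          snps_per_locus=dict(per_locus))
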