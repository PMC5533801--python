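"""Museum-DNA handling: empirical deamination profiling, coverage-based
sample exclusion and the directional deamination variant filter.

Post-mortem cytosine deamination reads as C->T near the 5' end of a
fragment and G->A near the 3' end (the complementary strand's signal),
decaying roughly exponentially with distance from the end.  The profiler
measures those mismatch frequencies position-by-position against the
reference and fits f(p) = delta * lambda**(p-1); the variant filter removes
whole sites whose major-to-minor direction matches the damage directions,
uniformly for modern and museum samples, because deamination is directional
(C->T / G->A, never T->C / A->G).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ._seq import revcomp, seq_to_codes
from .capture import AlignmentRecord
from .variants import VariantSite

_C, _G, _T, _A = 1, 2, 3, 0


@dataclass
class DamageProfile:
    sample: str
    ct_5prime: np.ndarray          # C->T frequency by 5' read position 1..P
    ga_3prime: np.ndarray          # G->A frequency by distance from 3' end
    fitted_delta: float = 0.0
    fitted_lambda: float = 0.0
    background: float = 0.0        # mismatch rate at interior positions
    no_damage: bool = False
    reliable: bool = True
    n_informative: int = 0


@dataclass
class SampleQC:
    """Per-sample QC verdict from coverage and lab metadata.

    Flags: ``low_coverage`` (mean target depth < 2.0X, excluded from
    population analysis), ``low_purity`` (A260/A280 <= 1.0) and
    ``low_yield`` (concentration <= 30 ng/uL) — the latter two are
    rule-of-thumb warnings only.
    """

    sample: str
    mean_target_coverage: float
    a260_a280: float | None = None
    conc_ng_ul: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.mean_target_coverage < 2.0:
            self.flags.add("low_coverage")
        if self.a260_a280 is not None and self.a260_a280 <= 1.0:
            self.flags.add("low_purity")
        if self.conc_ng_ul is not None and self.conc_ng_ul <= 30:
            self.flags.add("low_yield")


def _decay(p, delta, lam):
    return delta * lam ** (p - 1)


def profile_damage(alignments: list[AlignmentRecord],
                   reference: dict[str, str],
                   max_pos: int = 25) -> dict[str, DamageProfile]:
    """Per-sample empirical damage profiles from non-duplicate alignments.

    For each position p from the fragment 5' end the frequency of
    reference-C read-T mismatches, and symmetrically reference-G read-A
    from the 3' end; an exponential decay is least-squares fitted to the
    5' C->T vector.  Profiles whose fitted amplitude stays below twice the
    interior background mismatch rate are reported as no-damage; profiles
    with fewer than 1000 informative positions are marked unreliable.
    """
    ref_codes = {k: seq_to_codes(v) for k, v in reference.items()}
    ct_hit = defaultdict(lambda: np.zeros(max_pos))
    ct_tot = defaultdict(lambda: np.zeros(max_pos))
    ga_hit = defaultdict(lambda: np.zeros(max_pos))
    ga_tot = defaultdict(lambda: np.zeros(max_pos))
    mm_int = defaultdict(float)
    tot_int = defaultdict(float)

    for rec in alignments:
        if rec.is_duplicate:
            continue
        ref = ref_codes[rec.locus_id][rec.start:rec.end]
        # recover the fragment's emitted orientation
        if rec.strand == "+":
            read = seq_to_codes(rec.seq)[:len(ref)]
        else:
            read = seq_to_codes(revcomp(rec.seq))[:len(ref)]
            ref = seq_to_codes(revcomp(
                reference[rec.locus_id][rec.start:rec.end]))[:len(read)]
        n = min(len(read), len(ref))
        if n == 0:
            continue
        read, ref = read[:n], ref[:n]
        p5 = np.arange(n)
        p3 = n - 1 - p5
        s = rec.sample
        m5 = (p5 < max_pos) & (ref == _C)
        ct_tot[s][p5[m5]] += 1
        ct_hit[s][p5[m5 & (read == _T)]] += 1
        m3 = (p3 < max_pos) & (ref == _G)
        ga_tot[s][p3[m3]] += 1
        ga_hit[s][p3[m3 & (read == _A)]] += 1
        interior = (p5 >= 10) & (p3 >= 10)
        tot_int[s] += int(interior.sum())
        mm_int[s] += int(np.count_nonzero(read[interior] != ref[interior]))

    profiles: dict[str, DamageProfile] = {}
    for sample in sorted(ct_tot):
        with np.errstate(divide="ignore", invalid="ignore"):
            ct = np.where(ct_tot[sample] > 0,
                          ct_hit[sample] / np.maximum(ct_tot[sample], 1), 0.0)
            ga = np.where(ga_tot[sample] > 0,
                          ga_hit[sample] / np.maximum(ga_tot[sample], 1), 0.0)
        background = (mm_int[sample] / tot_int[sample]
                      if tot_int[sample] else 0.0)
        n_informative = int(ct_tot[sample].sum() + ga_tot[sample].sum())
        pvec = np.arange(1, max_pos + 1, dtype=float)
        weights = np.sqrt(np.maximum(ct_tot[sample], 1))
        try:
            (delta, lam), _ = curve_fit(
                _decay, pvec, ct, p0=(max(ct[0], 1e-3), 0.5),
                sigma=1.0 / weights, bounds=([0.0, 1e-6], [1.0, 0.9999]),
                maxfev=5000)
        except RuntimeError:
            delta, lam = 0.0, 0.5
        profiles[sample] = DamageProfile(
            sample=sample, ct_5prime=ct, ga_3prime=ga,
            fitted_delta=float(delta), fitted_lambda=float(lam),
            background=background,
            no_damage=bool(delta < 2.0 * background),
            reliable=n_informative >= 1000,
            n_informative=n_informative)
    return profiles


def qc_exclude(samples: list[SampleQC], min_cov: float = 2.0
               ) -> tuple[list[SampleQC], list[dict]]:
    """Remove samples below ``min_cov`` mean target coverage; purity and
    yield flags stay as warnings only.  Returns (retained, report)."""
    retained, report = [], []
    for s in samples:
        excluded = s.mean_target_coverage < min_cov
        report.append({
            "sample": s.sample,
            "mean_target_coverage": s.mean_target_coverage,
            "excluded": excluded,
            "warnings": sorted(s.flags - {"low_coverage"}),
        })
        if not excluded:
            retained.append(s)
    return retained, report


_DIRECTIONAL = {("C", "T"), ("G", "A")}


def deamination_filter(sites: list[VariantSite]
                       ) -> tuple[list[VariantSite], list[VariantSite]]:
    """Remove sites whose major-to-minor substitution direction is C->T
    or G->A, from every sample (modern and museum alike).

    T->C, A->G and all transversion directions are retained; the major
    allele is the overall-frequency majority with ties resolved toward
    the reference base.  Returns (kept, removed).
    """
    kept, removed = [], []
    for site in sites:
        mm = site.major_minor()
        if mm is not None and (mm[0], mm[1]) in _DIRECTIONAL:
            removed.append(site)
        else:
            kept.append(site)
    return kept, removed
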