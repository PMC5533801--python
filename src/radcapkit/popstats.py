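"""Population-genetic summaries: site filtering, LD pruning,
Weir-Cockerham Fst, diversity / locus-sharing tables and PCA.

Genotypes live in a samples x sites int8 matrix counting alt alleles
(0/1/2, -1 missing).  The Fst estimator is the Weir & Cockerham (1984)
variance-component estimator: per biallelic site the among-population (a),
among-individual-within-population (b) and within-individual (c)
components, per-site theta = a/(a+b+c) and the global ratio-of-sums
theta = sum(a) / sum(a+b+c).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .variants import VariantSite

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix with sample and site metadata."""

    genotypes: np.ndarray               # (n_samples, n_sites) int8
    samples: list[str]
    species: list[str]
    sites: list[tuple[str, int]]        # (locus, pos)
    #: optional per-site (ref, alt) bases
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotype matrix shape does not match metadata")
        bad = ~np.isin(g, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        self.genotypes = g
        if len(self.species) != len(self.samples):
            raise ValueError("one species label per sample required")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, keep],
            samples=self.samples, species=self.species,
            sites=[self.sites[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool else [self.sites[i] for i in keep],
            alleles=([self.alleles[i] for i in np.flatnonzero(keep)]
                     if self.alleles and keep.dtype == bool
                     else [self.alleles[i] for i in keep] if self.alleles
                     else []))


def sites_to_matrix(sites: list[VariantSite], samples: list[str],
                    species_of: dict[str, str]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from called variant sites."""
    code = {"0/0": 0, "0/1": 1, "1/1": 2, "./.": MISSING}
    g = np.full((len(samples), len(sites)), MISSING, dtype=np.int8)
    meta, alleles = [], []
    for j, site in enumerate(sites):
        meta.append((site.ref_id, site.pos))
        alleles.append((site.ref_base,
                        site.alt_bases[0] if site.alt_bases else "."))
        for i, s in enumerate(samples):
            call = site.per_sample.get(s)
            if call is not None:
                g[i, j] = code[call.genotype]
    return GenotypeMatrix(genotypes=g, samples=samples,
                          species=[species_of[s] for s in samples],
                          sites=meta, alleles=alleles)


def _maf(col: np.ndarray) -> float:
    obs = col[col != MISSING]
    if len(obs) == 0:
        return 0.0
    p = obs.sum() / (2 * len(obs))
    return min(p, 1 - p)


def site_filters(matrix: GenotypeMatrix, max_missing: float = 0.10,
                 maf_min: float = 0.05) -> GenotypeMatrix:
    """Drop sites with missing fraction > ``max_missing`` or minor-allele
    frequency below ``maf_min`` (strict: MAF exactly at the threshold is
    kept); fixed sites (MAF 0) always go.  Idempotent."""
    g = matrix.genotypes
    n = matrix.n_samples
    keep = np.ones(matrix.n_sites, dtype=bool)
    for j in range(matrix.n_sites):
        col = g[:, j]
        missing_frac = np.count_nonzero(col == MISSING) / n
        maf = _maf(col)
        if missing_frac > max_missing or maf < maf_min or maf == 0.0:
            keep[j] = False
    return matrix.subset_sites(keep)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 3:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(matrix: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.5) -> GenotypeMatrix:
    """Sliding-window LD pruning on genotype correlation.

    Within each window, while any retained pair exceeds ``r2_max`` the
    member with more missing data is dropped (ties: lower MAF, then later
    position).  Deterministic.
    """
    g = matrix.genotypes
    n_sites = matrix.n_sites
    removed = np.zeros(n_sites, dtype=bool)
    missing = (g == MISSING).sum(axis=0)
    mafs = np.array([_maf(g[:, j]) for j in range(n_sites)])

    def drop_priority(j: int) -> tuple:
        # max() picks the victim: more missing, then lower MAF, then later
        return (missing[j], -mafs[j], j)

    for start in range(0, max(1, n_sites - 1), step):
        idx = [j for j in range(start, min(start + window, n_sites))
               if not removed[j]]
        changed = True
        while changed:
            changed = False
            worst = None
            for ii, j1 in enumerate(idx):
                for j2 in idx[ii + 1:]:
                    if _pairwise_r2(g[:, j1], g[:, j2]) > r2_max:
                        victim = max(j1, j2, key=drop_priority)
                        if worst is None or drop_priority(victim) > drop_priority(worst):
                            worst = victim
            if worst is not None:
                removed[worst] = True
                idx.remove(worst)
                changed = True
        if start + window >= n_sites:
            break
    return matrix.subset_sites(~removed)


@dataclass
class FstComponents:
    """Weir-Cockerham variance components and theta estimates."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_site_theta: np.ndarray
    global_theta: float
    n_populations: int
    n_sites_used: int


def wc_fst(matrix: GenotypeMatrix,
           populations: list[str] | None = None) -> FstComponents:
    """Weir & Cockerham (1984) theta from a genotype matrix.

    Per biallelic polymorphic site: mean sample size n-bar, the squared
    coefficient of sample-size variation correction nc, weighted mean
    allele frequency p-bar, among-population frequency variance s2 and
    mean observed heterozygosity h-bar feed the a/b/c variance
    components.  Global theta is the ratio of sums.  Monomorphic sites
    are skipped.
    """
    pops = populations if populations is not None else matrix.species
    if len(pops) != matrix.n_samples:
        raise ValueError("one population label per sample required")
    labels = sorted(set(pops))
    r = len(labels)
    if r < 2:
        raise ValueError("wc_fst needs at least two populations")
    pop_rows = {lab: np.array([i for i, p in enumerate(pops) if p == lab])
                for lab in labels}

    g = matrix.genotypes
    a_l, b_l, c_l = [], [], []
    for j in range(matrix.n_sites):
        col = g[:, j]
        n_i, p_i, h_i = [], [], []
        for lab in labels:
            sub = col[pop_rows[lab]]
            sub = sub[sub != MISSING]
            if len(sub) == 0:
                break
            n_i.append(len(sub))
            p_i.append(sub.sum() / (2 * len(sub)))
            h_i.append(np.count_nonzero(sub == 1) / len(sub))
        else:
            n_i = np.asarray(n_i, dtype=float)
            p_i = np.asarray(p_i)
            h_i = np.asarray(h_i)
            nbar = n_i.mean()
            p_bar = (n_i * p_i).sum() / (r * nbar)
            if p_bar <= 0.0 or p_bar >= 1.0 or nbar <= 1:
                continue
            nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            pq = p_bar * (1 - p_bar)
            a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4)
                               / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            a_l.append(a)
            b_l.append(b)
            c_l.append(c)
    a_arr = np.asarray(a_l)
    b_arr = np.asarray(b_l)
    c_arr = np.asarray(c_l)
    denom = a_arr + b_arr + c_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(denom != 0, a_arr / np.where(denom == 0, 1, denom),
                            np.nan)
    total = denom.sum()
    global_theta = float(a_arr.sum() / total) if total != 0 else float("nan")
    return FstComponents(a=a_arr, b=b_arr, c=c_arr, per_site_theta=per_site,
                         global_theta=global_theta, n_populations=r,
                         n_sites_used=len(a_arr))


@dataclass
class DiversityReport:
    maf: np.ndarray
    obs_het: np.ndarray
    mean_het: float
    sd_het: float
    #: loci occurring in exactly k of n species -> count
    sharing_histogram: dict[int, int]
    per_sample_missing_pct: dict[str, float]
    per_locus_missing_frac: dict[str, float]


def diversity_and_sharing(matrix: GenotypeMatrix) -> DiversityReport:
    """Per-site MAF and observed heterozygosity, the k-of-n locus-sharing
    histogram (locus present in a species when >= 1 individual of that
    species is genotyped there) and per-sample / per-locus missingness."""
    g = matrix.genotypes
    maf = np.array([_maf(g[:, j]) for j in range(matrix.n_sites)])
    obs_het = np.zeros(matrix.n_sites)
    for j in range(matrix.n_sites):
        col = g[:, j]
        obs = col[col != MISSING]
        obs_het[j] = (np.count_nonzero(obs == 1) / len(obs)
                      if len(obs) else 0.0)

    species = sorted(set(matrix.species))
    sp_rows = {sp: np.array([i for i, s in enumerate(matrix.species)
                             if s == sp]) for sp in species}
    locus_sites: dict[str, list[int]] = defaultdict(list)
    for j, (locus, _) in enumerate(matrix.sites):
        locus_sites[locus].append(j)
    sharing: dict[int, int] = defaultdict(int)
    per_locus_missing: dict[str, float] = {}
    for locus, cols in locus_sites.items():
        sub = g[:, cols]
        k = sum(1 for sp in species
                if np.any(sub[sp_rows[sp], :] != MISSING))
        sharing[k] += 1
        per_locus_missing[locus] = float(
            np.count_nonzero(sub == MISSING) / sub.size)

    per_sample_missing = {
        s: 100.0 * np.count_nonzero(g[i, :] == MISSING) / max(1, matrix.n_sites)
        for i, s in enumerate(matrix.samples)}
    return DiversityReport(
        maf=maf, obs_het=obs_het,
        mean_het=float(obs_het.mean()) if len(obs_het) else 0.0,
        sd_het=float(obs_het.std()) if len(obs_het) else 0.0,
        sharing_histogram=dict(sharing),
        per_sample_missing_pct=per_sample_missing,
        per_locus_missing_frac=per_locus_missing)


@dataclass
class PcaResult:
    coordinates: np.ndarray        # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray           # (n_sites_used, n_components)


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of allele-frequency-standardised genotypes.

    Missing genotypes are mean-imputed per site; sites are centred and
    scaled by sqrt(p(1-p)); zero-variance sites are dropped.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    if matrix.n_samples < 3:
        raise ValueError("pca needs at least 3 samples")
    g = matrix.genotypes.astype(float)
    g[g == MISSING] = np.nan
    means = np.nanmean(g, axis=0)
    p = means / 2.0
    scale = np.sqrt(p * (1 - p))
    usable = scale > 0
    x = g[:, usable]
    mcol = means[usable]
    inds = np.where(np.isnan(x))
    x[inds] = mcol[inds[1]]
    x = (x - mcol) / scale[usable]
    if x.shape[1] == 0:
        k = min(n_components, matrix.n_samples)
        return PcaResult(np.zeros((matrix.n_samples, k)), np.zeros(k),
                         np.zeros((0, k)))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for comp in range(k):
        col = loadings[:, comp]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            loadings[:, comp] = -col
            coords[:, comp] = -coords[:, comp]
    var = s ** 2
    ratio = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return PcaResult(coordinates=coords, explained_variance_ratio=ratio,
                     loadings=loadings)
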