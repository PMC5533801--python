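"""Population-statistics tests: site filters, LD pruning, Weir-Cockerham
theta against an independent oracle, sharing histogram, PCA."""

import itertools

import numpy as np
import pytest

from radcapkit.popstats import (GenotypeMatrix, MISSING, diversity_and_sharing,
                                ld_prune, pca, site_filters, wc_fst)


def _matrix(g, species=None):
    g = np.asarray(g, dtype=np.int8)
    n, m = g.shape
    return GenotypeMatrix(g, [f"s{i}" for i in range(n)],
                          species or ["A"] * n,
                          [("locus", j) for j in range(m)])


def oracle_wc_theta(g, pops):
    """Textbook Weir-Cockerham variance components, written directly from
    the per-population sums (independent of the implementation)."""
    labels = sorted(set(pops))
    r = len(labels)
    num = den = 0.0
    for j in range(g.shape[1]):
        n_i, p_i, h_i = [], [], []
        ok = True
        for lab in labels:
            rows = [i for i, p in enumerate(pops) if p == lab]
            col = [g[i, j] for i in rows if g[i, j] != MISSING]
            if not col:
                ok = False
                break
            n_i.append(len(col))
            p_i.append(sum(col) / (2 * len(col)))
            h_i.append(sum(1 for x in col if x == 1) / len(col))
        if not ok:
            continue
        nbar = sum(n_i) / r
        if nbar <= 1:
            continue
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        pq = pbar * (1 - pbar)
        a = nbar / nc * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pq - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


class TestSiteFilters:
    def test_missing_fraction_boundary(self):
        g = np.zeros((10, 2), dtype=np.int8)
        g[:, 0] = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        g[:2, 1] = MISSING
        g[2:, 1] = [1, 0, 1, 0, 1, 0, 1, 1]
        out = site_filters(_matrix(g))
        assert out.sites == [("locus", 0)]     # 0.2 missing > 0.1 removed

    def test_fixed_sites_removed(self):
        g = np.zeros((6, 2), dtype=np.int8)
        g[:, 1] = [0, 1, 0, 1, 0, 1]
        assert site_filters(_matrix(g)).sites == [("locus", 1)]

    def test_maf_exactly_at_threshold_kept(self):
        # 1 alt in 20 chromosomes = MAF 0.05: strict "< 0.05" keeps it
        g = np.zeros((10, 1), dtype=np.int8)
        g[0, 0] = 1
        assert site_filters(_matrix(g)).n_sites == 1
        # 1 alt in 22 chromosomes = 0.045 < 0.05: removed
        g2 = np.zeros((11, 1), dtype=np.int8)
        g2[0, 0] = 1
        assert site_filters(_matrix(g2)).n_sites == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        once = site_filters(_matrix(g))
        twice = site_filters(once)
        assert np.array_equal(once.genotypes, twice.genotypes)
        assert once.sites == twice.sites


class TestLdPrune:
    def test_duplicated_column_pruned(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1]])
        out = ld_prune(_matrix(g))
        assert out.n_sites == 1
        assert out.sites == [("locus", 0)]     # later position dropped

    def test_anticorrelated_pair_pruned(self):
        g = np.array([[0, 2], [2, 0], [0, 2], [2, 0], [1, 1]])
        assert ld_prune(_matrix(g)).n_sites == 1

    def test_member_with_more_missing_is_dropped(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [0, MISSING], [1, 1],
                      [2, 2]])
        out = ld_prune(_matrix(g))
        assert out.sites == [("locus", 0)]

    def test_independent_sites_survive(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=(60, 30)).astype(np.int8)
        out = ld_prune(_matrix(g))
        assert out.n_sites >= 28       # chance r2 > 0.5 at n=60 is rare


class TestWcFst:
    def test_all_heterozygotes_give_zero_theta(self):
        m = _matrix([[1], [1], [1], [1]], ["A", "A", "B", "B"])
        f = wc_fst(m)
        assert f.a[0] == pytest.approx(0.0, abs=1e-12)
        assert f.b[0] == pytest.approx(-0.25, abs=1e-12)
        assert f.c[0] == pytest.approx(0.5, abs=1e-12)
        assert f.global_theta == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_give_theta_one(self):
        m = _matrix([[0], [0], [2], [2]], ["A", "A", "B", "B"])
        f = wc_fst(m)
        assert f.a[0] == pytest.approx(0.5, abs=1e-12)
        assert f.b[0] == pytest.approx(0.0, abs=1e-12)
        assert f.c[0] == pytest.approx(0.0, abs=1e-12)
        assert f.global_theta == pytest.approx(1.0, abs=1e-12)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            wc_fst(_matrix([[1], [1]], ["A", "A"]))

    def test_matches_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for trial in range(100):
            n = int(rng.integers(6, 16))
            m = int(rng.integers(3, 12))
            g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            g[rng.random((n, m)) < 0.1] = MISSING
            pops = ["A"] * (n // 2) + ["B"] * (n - n // 2)
            mat = GenotypeMatrix(g, [f"s{i}" for i in range(n)], pops,
                                 [("l", j) for j in range(m)])
            got = wc_fst(mat).global_theta
            want = oracle_wc_theta(g, pops)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_panmictic_pool_gives_near_zero_theta(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 500)
        g = rng.binomial(2, p, size=(100, 500)).astype(np.int8)
        mat = GenotypeMatrix(g, [f"s{i}" for i in range(100)],
                             ["A"] * 50 + ["B"] * 50,
                             [("l", j) for j in range(500)])
        assert abs(wc_fst(mat).global_theta) < 0.01


class TestDiversityAndSharing:
    def test_locus_present_in_all_species_lands_in_top_bin(self):
        g = np.zeros((6, 2), dtype=np.int8)
        g[0, :] = 1
        m = _matrix(g, ["A", "A", "B", "B", "C", "C"])
        d = diversity_and_sharing(m)
        assert d.sharing_histogram == {3: 1}

    def test_histogram_matches_bruteforce_enumeration(self):
        """5 loci x 3 species presence patterns enumerated by hand."""
        rng = np.random.default_rng(4)
        species = ["A", "A", "B", "B", "C", "C"]
        sites, cols = [], []
        presence = {}
        for li, pattern in enumerate(itertools.islice(
                itertools.product([True, False], repeat=3), 5)):
            presence[f"L{li}"] = pattern
            for k in range(2):           # two sites per locus
                sites.append((f"L{li}", k))
                col = np.full(6, MISSING, dtype=np.int8)
                for si, present in enumerate(pattern):
                    if present:
                        col[2 * si:2 * si + 2] = rng.integers(0, 3, 2)
                cols.append(col)
        g = np.stack(cols, axis=1)
        m = GenotypeMatrix(g, [f"s{i}" for i in range(6)], species, sites)
        d = diversity_and_sharing(m)
        expect = {}
        for pat in presence.values():
            expect[sum(pat)] = expect.get(sum(pat), 0) + 1
        assert d.sharing_histogram == expect

    def test_maf_and_het_for_textbook_genotypes(self):
        m = _matrix([[0], [1], [2]])
        d = diversity_and_sharing(m)
        assert d.maf[0] == pytest.approx(0.5)
        assert d.obs_het[0] == pytest.approx(1 / 3)


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.2, size=(12, 40)).astype(np.int8)
        g[6:, :20] = 2                # fixed differences in half the sites
        m = _matrix(g, ["A"] * 6 + ["B"] * 6)
        res = pca(m)
        pc1 = res.coordinates[:, 0]
        assert max(pc1[:6]) < min(pc1[6:]) or min(pc1[:6]) > max(pc1[6:])

    def test_identical_samples_sit_at_origin(self):
        g = np.tile([0, 1, 2, 0, 1], (5, 1)).astype(np.int8)
        res = pca(_matrix(g))
        assert np.allclose(res.coordinates, 0.0)

    def test_sample_permutation_permutes_rows_only(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        res = pca(_matrix(g))
        perm = rng.permutation(8)
        res_p = pca(_matrix(g[perm]))
        assert np.allclose(res_p.coordinates, res.coordinates[perm],
                           atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca(_matrix(np.zeros((2, 5), dtype=np.int8)))
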