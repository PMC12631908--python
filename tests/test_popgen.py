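"""Site QC and windowed pi / Tajima's D / Weir-Cockerham FST.

Each statistic is checked against an independently coded brute-force oracle
that works from the primary definitions: pairwise allele differences for pi,
the direct 1989 formula for Tajima's D, and the per-site variance-component
expressions for WC FST.
"""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from satkit.io_formats import GenotypeMatrix
from satkit.popgen import (TajimaCoefficients, filter_sites, hwe_exact_p,
                           site_pi, stratify_regions, tajima_d_from_window,
                           weighted_fst, window_stats)


def make_matrix(geno, n_a, n_b, chrom="chr1", start_pos=1):
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    assert n_samples == n_a + n_b
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return GenotypeMatrix(
        np.full(n_sites, chrom, dtype=object),
        np.arange(start_pos, start_pos + n_sites),
        np.full(n_sites, "A", dtype=object),
        np.full(n_sites, "G", dtype=object),
        samples,
        {"A": samples[:n_a], "B": samples[n_a:]},
        geno,
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_site_pi(g):
    """Average pairwise difference over all allele pairs, from enumeration."""
    alleles = []
    for dose in g:
        if dose < 0:
            continue
        alleles += [1] * dose + [0] * (2 - dose)
    if len(alleles) < 2:
        return 0.0
    diffs = sum(a != b for a, b in combinations(alleles, 2))
    return diffs / math.comb(len(alleles), 2)


def oracle_tajima_d(pi_sum, s, n):
    """Direct transcription of the 1989 formula."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def oracle_wc_fst(ga, gb):
    """Weir-Cockerham weighted FST, re-derived per site with plain loops."""
    num = den = 0.0
    for i in range(ga.shape[0]):
        g1 = [x for x in ga[i] if x >= 0]
        g2 = [x for x in gb[i] if x >= 0]
        n1, n2 = len(g1), len(g2)
        if n1 == 0 or n2 == 0:
            continue
        p1 = sum(g1) / (2 * n1)
        p2 = sum(g2) / (2 * n2)
        h1 = sum(1 for x in g1 if x == 1) / n1
        h2 = sum(1 for x in g2 if x == 1) / n2
        r = 2
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1)
                         * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def oracle_hwe_exact(n_het, n_ref, n_alt):
    """Exact HWE p by full enumeration with rational arithmetic."""
    n = n_het + n_ref + n_alt
    rare = n_het + 2 * min(n_ref, n_alt)

    def weight(k):
        hom_rare = (rare - k) // 2
        hom_common = n - k - hom_rare
        if hom_rare < 0 or hom_common < 0:
            return Fraction(0)
        return Fraction(2**k * math.factorial(n),
                        math.factorial(k) * math.factorial(hom_rare)
                        * math.factorial(hom_common))

    ks = [k for k in range(rare % 2, rare + 1, 2)]
    weights = {k: weight(k) for k in ks}
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

class TestFilterSites:
    def test_maf_threshold(self):
        # 20 diploids; 1 het -> MAF 1/40 = 0.025 < 0.05 excluded;
        # 4 hets -> MAF 0.1 kept
        g_low = [[1] + [0] * 19]
        g_ok = [[1, 1, 1, 1] + [0] * 16]
        gm = make_matrix(np.vstack([g_low, g_ok]), 10, 10)
        kept, tally = filter_sites(gm)
        assert tally.maf == 1 and tally.kept == 1
        assert kept.pos[0] == 2

    def test_missing_threshold(self):
        g = np.zeros((1, 20), dtype=np.int8)
        g[0, :5] = -1  # 25% missing
        g[0, 5:10] = 1
        gm = make_matrix(g, 10, 10)
        _, tally = filter_sites(gm, max_missing=0.2)
        assert tally.missing == 1

    def test_all_het_excluded_by_hwe(self):
        gm = make_matrix(np.ones((1, 20), dtype=np.int8), 10, 10)
        _, tally = filter_sites(gm, hwe_p_min=1e-5)
        assert tally.hwe == 1
        assert hwe_exact_p(20, 0, 0) < 1e-5

    @pytest.mark.parametrize("het,ref,alt", [
        (20, 0, 0), (10, 5, 5), (3, 10, 7), (0, 12, 8), (1, 19, 0), (7, 7, 6),
    ])
    def test_hwe_matches_enumeration_oracle(self, het, ref, alt):
        assert hwe_exact_p(het, ref, alt) == pytest.approx(
            oracle_hwe_exact(het, ref, alt), abs=1e-12)

    def test_empty_result_is_not_an_error(self):
        gm = make_matrix(np.zeros((3, 10), dtype=np.int8), 5, 5)
        kept, tally = filter_sites(gm)  # monomorphic sites: MAF 0
        assert kept.n_sites == 0 and tally.maf == 3


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

class TestWindowStats:
    def test_monomorphic_window(self):
        gm = make_matrix(np.zeros((5, 8), dtype=np.int8), 4, 4)
        ws = window_stats(gm, "A", "B", window=100, chrom_lengths={"chr1": 100})[0]
        assert ws.pops["A"].s == 0
        assert ws.pops["A"].pi == 0
        assert ws.pops["A"].tajima_d is None
        assert math.isnan(ws.fst)

    def test_empty_window_retained(self):
        gm = make_matrix(np.zeros((1, 8), dtype=np.int8), 4, 4)
        stats = window_stats(gm, "A", "B", window=50, chrom_lengths={"chr1": 100})
        assert len(stats) == 2
        assert stats[1].n_sites == 0

    def test_pi_matches_pairwise_oracle(self, rng):
        g = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = -1
        for i in range(len(g)):
            assert site_pi(g[i]) == pytest.approx(oracle_site_pi(g[i]), abs=1e-10)

    def test_tajima_d_matches_direct_formula(self):
        # fixture: 4 samples (8 haplotypes), 3 segregating sites
        g = np.array([
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [2, 1, 1, 0],
        ], dtype=np.int8)
        gm = make_matrix(g, 2, 2)
        ws = window_stats(gm, "A", "B", window=100, chrom_lengths={"chr1": 100})[0]
        # oracle from first principles, pooling both populations is not done:
        # per-population D for pop "A" (2 diploids = 4 haplotypes)
        pi_sum = sum(oracle_site_pi(g[i, :2]) for i in range(3))
        s = sum(1 for i in range(3) if 0 < g[i, :2].sum() < 4)
        expected = oracle_tajima_d(pi_sum, s, 4)
        assert ws.pops["A"].tajima_d == pytest.approx(expected, abs=1e-10)

    def test_identical_populations_fst_near_zero(self, rng):
        # mirrored populations: the WC estimator is ~0 with the small
        # negative finite-sample correction its b/c terms introduce
        half = rng.integers(0, 3, size=(40, 20)).astype(np.int8)
        g = np.concatenate([half, half], axis=1)
        gm = make_matrix(g, 20, 20)
        ws = window_stats(gm, "A", "B", window=100, chrom_lengths={"chr1": 100})[0]
        assert ws.fst == pytest.approx(oracle_wc_fst(half, half), abs=1e-10)
        assert abs(ws.fst) < 0.05
        assert ws.fst <= 0

    def test_oracle_equivalence_random_matrices(self, rng):
        """pi / S / D / FST against brute-force oracles on small matrices."""
        for trial in range(5):
            n_sites = int(rng.integers(10, 50))
            g = rng.integers(0, 3, size=(n_sites, 10)).astype(np.int8)
            g[rng.random(g.shape) < 0.05] = -1
            gm = make_matrix(g, 5, 5)
            ws = window_stats(gm, "A", "B", window=64, chrom_lengths={"chr1": 64})[0]

            ga, gb = g[:, :5], g[:, 5:]
            fst = oracle_wc_fst(ga, gb)
            if math.isnan(fst):
                assert math.isnan(ws.fst)
            else:
                assert ws.fst == pytest.approx(fst, abs=1e-10)

            pi_a = sum(oracle_site_pi(row) for row in ga) / 64
            assert ws.pops["A"].pi == pytest.approx(pi_a, abs=1e-10)

            s_b = sum(1 for row in gb
                      if 0 < sum(x for x in row if x >= 0) < 2 * sum(x >= 0 for x in row))
            assert ws.pops["B"].s == s_b

    def test_tajima_d_sign_on_constructed_spectra(self):
        # excess singletons -> negative D; intermediate frequencies -> positive
        n = 10
        singletons = np.zeros((20, n), dtype=np.int8)
        singletons[:, 0] = 1
        gm = make_matrix(singletons, 5, 5)
        ws = window_stats(gm, "A", "B", window=100, chrom_lengths={"chr1": 100})[0]
        d_pool = [p.tajima_d for p in ws.pops.values()]
        assert all(d < 0 for d in d_pool if d is not None)

        # allele frequency 0.5 *within each population* at every site
        balanced = np.tile([2, 2, 0, 0, 1, 2, 2, 0, 0, 1], (20, 1)).astype(np.int8)
        gm = make_matrix(balanced, 5, 5)
        ws = window_stats(gm, "A", "B", window=100, chrom_lengths={"chr1": 100})[0]
        assert ws.pops["A"].tajima_d is not None and ws.pops["A"].tajima_d > 0

    def test_coefficients_positive(self):
        for n in (4, 10, 40, 100):
            c = TajimaCoefficients.for_n(n)
            assert min(c.a1, c.a2, c.b1, c.b2, c.c1, c.c2, c.e1, c.e2) > 0


# ---------------------------------------------------------------------------
# Region stratification
# ---------------------------------------------------------------------------

class TestStratify:
    def test_constant_windows(self, truth_partition):
        gm = make_matrix(np.zeros((0, 8), dtype=np.int8), 4, 4)
        lengths = {c: truth_partition[c].length for c in truth_partition.chroms}
        stats = window_stats(gm, "A", "B", window=10_000, chrom_lengths=lengths)
        for ws in stats:
            ws.pops["A"].pi = 0.5
            ws.pops["B"].pi = 0.5
        summaries = stratify_regions(stats, truth_partition)
        for s in summaries:
            if s.statistic.startswith("pi:"):
                assert s.mean == pytest.approx(0.5)
                assert s.sd == pytest.approx(0.0)

    def test_empty_region_reported_with_zero_count(self, truth_partition):
        stats = []
        summaries = stratify_regions(stats, truth_partition)
        assert all(s.count == 0 and s.mean is None for s in summaries)
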