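"""Diversity and FST estimators against brute-force and transcription oracles."""

import itertools

import numpy as np
import pytest

from sweeptx import popgen_stats as ps
from sweeptx.core_io import MISSING
from sweeptx.errors import ConfigError
from sweeptx.synthetic_data import SimConfig, simulate_genotypes

from conftest import make_gm


# ---------------------------------------------------------------------------
# oracles (kept independent of the implementation under test)
# ---------------------------------------------------------------------------

def pi_pair_oracle(n_ref: int, n_alt: int) -> float:
    """Enumerate every pair of sampled alleles; fraction that differ."""
    alleles = [0] * n_ref + [1] * n_alt
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def wc84_oracle(geno_a: np.ndarray, geno_b: np.ndarray) -> tuple[float, float, float]:
    """Step-by-step transcription of the Weir & Cockerham (1984) two-population
    ANOVA for one biallelic site, from diploid dosage vectors (no missing)."""
    r = 2
    n = [len(geno_a), len(geno_b)]
    p = [np.mean(geno_a) / 2.0, np.mean(geno_b) / 2.0]
    h = [np.mean(geno_a == 1), np.mean(geno_b == 1)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni ** 2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    ssq = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * ssq
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _counts_from(geno: np.ndarray) -> ps.SiteCounts:
    geno = np.atleast_2d(geno)
    return ps.SiteCounts(
        n_ind=np.full(geno.shape[1], geno.shape[0]),
        n_alt=geno.sum(axis=0),
        n_het=(geno == 1).sum(axis=0),
    )


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

class TestMakeWindows:
    def test_overhanging_last_windows_truncated(self):
        w = ps.make_windows({"chr1": 100_000})
        assert [x.start for x in w] == [0, 20_000, 40_000, 60_000, 80_000]
        assert (w[-1].start, w[-1].end) == (80_000, 100_000)

    def test_exact_multiple_length(self):
        w = ps.make_windows({"chr1": 40_000})
        assert [(x.start, x.end) for x in w] == [(0, 40_000), (20_000, 40_000)]

    def test_count_matches_enumeration_oracle(self):
        lengths = {"chr1": 123_456, "chr2": 40_000, "chr3": 19_999}
        expected = 0
        for length in lengths.values():
            s = 0
            while s < length:
                expected += 1
                s += 20_000
        assert len(ps.make_windows(lengths)) == expected

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigError):
            ps.make_windows({"chr1": 100}, size=10, step=20)
        with pytest.raises(ConfigError):
            ps.make_windows({"chr1": -5})


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestSitePi:
    @pytest.mark.parametrize("n_ref,n_alt", [(2, 2), (1, 1), (3, 0), (5, 3), (1, 7)])
    def test_matches_pair_enumeration(self, n_ref, n_alt):
        assert ps.site_pi(n_ref, n_alt) == pytest.approx(
            pi_pair_oracle(n_ref, n_alt), abs=1e-12)

    def test_too_few_alleles_is_nan(self):
        assert np.isnan(ps.site_pi(1, 0))
        assert np.isnan(ps.site_pi(0, 0))


class TestWindowPi:
    def test_single_site_in_40kb_window(self):
        # one site with n_ref = n_alt = 2 (pi = 2/3) spread over 40 kb
        gm = make_gm([[1], [1]], pos=[150], pops=["A"] * 2)
        pi, n = ps.window_pi(gm, "A", [ps.Window("chr1", 0, 40_000)])
        assert pi[0] == pytest.approx((2 / 3) / 40_000)
        assert pi[0] == pytest.approx(1.667e-5, rel=1e-3)
        assert n[0] == 1

    def test_empty_window_marked(self):
        gm = make_gm([[0], [2]], pos=[150], pops=["A"] * 2)
        pi, n = ps.window_pi(gm, "A", [ps.Window("chr1", 40_000, 80_000)])
        assert pi[0] == 0.0 and n[0] == 0

    def test_window_sum_matches_per_site_enumeration(self, rng):
        dosage = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=50, replace=False))
        gm = make_gm(dosage, pos=pos, pops=["A"] * 6)
        windows = ps.make_windows({"chr1": 100_000})
        pi, _ = ps.window_pi(gm, "A", windows)
        for w, got in zip(windows, pi):
            total = 0.0
            for j in range(50):
                if w.start + 1 <= pos[j] <= w.end:
                    n_alt = int(dosage[:, j].sum())
                    total += pi_pair_oracle(12 - n_alt, n_alt)
            assert got == pytest.approx(total / w.span, abs=1e-12)

    def test_invariant_to_allele_label_swap(self, two_pop_gm):
        import dataclasses
        windows = ps.make_windows({"chr1": 1_000_000})
        pi1, _ = ps.window_pi(two_pop_gm, "pop1", windows)
        swapped = np.where(two_pop_gm.dosage == MISSING, MISSING,
                           2 - two_pop_gm.dosage).astype(np.int8)
        gm2 = dataclasses.replace(two_pop_gm, dosage=swapped)
        pi2, _ = ps.window_pi(gm2, "pop1", windows)
        np.testing.assert_allclose(pi1, pi2, atol=1e-15)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

class TestSiteFst:
    def test_fixed_difference_is_one(self):
        a = np.zeros((8, 1), dtype=np.int8)
        b = np.full((8, 1), 2, dtype=np.int8)
        comp_a, comp_b, comp_c, usable = ps.site_fst_components(
            _counts_from(a), _counts_from(b))
        assert usable[0]
        assert comp_a[0] / (comp_a[0] + comp_b[0] + comp_c[0]) == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self, rng):
        g = rng.integers(0, 3, size=(8, 20)).astype(np.int8)
        a, b, c, usable = ps.site_fst_components(_counts_from(g), _counts_from(g))
        poly = usable & ((a + b + c) > 0)
        assert np.all(a[poly] <= 1e-12)

    def test_components_match_transcription_oracle(self, rng):
        for _ in range(200):
            ga = rng.integers(0, 3, size=8).astype(np.int8)
            gb = rng.integers(0, 3, size=8).astype(np.int8)
            a, b, c, usable = ps.site_fst_components(
                _counts_from(ga[:, None]), _counts_from(gb[:, None]))
            oa, ob, oc = wc84_oracle(ga, gb)
            assert a[0] == pytest.approx(oa, abs=1e-10)
            assert b[0] == pytest.approx(ob, abs=1e-10)
            assert c[0] == pytest.approx(oc, abs=1e-10)


class TestWindowFst:
    def test_fixed_difference_window_is_one(self):
        dosage = np.vstack([np.zeros((4, 10)), np.full((4, 10), 2)]).astype(np.int8)
        gm = make_gm(dosage)
        fst, defined = ps.window_fst(gm, "A", "B", [ps.Window("chr1", 0, 40_000)])
        assert defined[0] and fst[0] == pytest.approx(1.0)

    def test_monomorphic_window_undefined(self):
        gm = make_gm(np.zeros((8, 5), dtype=np.int8))
        fst, defined = ps.window_fst(gm, "A", "B", [ps.Window("chr1", 0, 40_000)])
        assert not defined[0] and np.isnan(fst[0])

    def test_ratio_of_sums_matches_oracle_windowwise(self, rng):
        dosage = rng.integers(0, 3, size=(16, 20)).astype(np.int8)
        pos = np.arange(1, 21) * 1000
        gm = make_gm(dosage, pos=pos)
        fst, defined = ps.window_fst(gm, "A", "B", [ps.Window("chr1", 0, 40_000)])
        num = den = 0.0
        for j in range(20):
            oa, ob, oc = wc84_oracle(dosage[:8, j], dosage[8:, j])
            num += oa
            den += oa + ob + oc
        assert defined[0]
        assert fst[0] == pytest.approx(num / den, abs=1e-10)

    def test_centered_at_zero_without_differentiation(self):
        cfg = SimConfig(seed=31, chrom_lengths={"chr1": 2_000_000},
                        n_snps=20_000, fst_background=0.0)
        gm, _ = simulate_genotypes(cfg)
        wt = ps.window_scan(gm, cfg.chrom_lengths)
        vals = wt["fst_pop1_pop2"].dropna()
        assert abs(vals.mean()) < 0.01
        assert vals.max() <= 1.0

    def test_mean_fst_monotone_in_simulated_f(self):
        means = []
        for f in (0.02, 0.1, 0.3):
            cfg = SimConfig(seed=32, chrom_lengths={"chr1": 1_000_000},
                            n_snps=10_000, fst_background=f)
            gm, _ = simulate_genotypes(cfg)
            wt = ps.window_scan(gm, cfg.chrom_lengths)
            means.append(wt["fst_pop1_pop2"].dropna().mean())
        assert means[0] < means[1] < means[2]

    def test_hudson_estimator_agrees_on_strong_signal(self, two_pop_gm):
        windows = ps.make_windows({"chr1": 1_000_000})
        wc, _ = ps.window_fst(two_pop_gm, "pop1", "pop2", windows)
        hu, _ = ps.window_fst(two_pop_gm, "pop1", "pop2", windows, estimator="hudson")
        assert np.corrcoef(wc, hu)[0, 1] > 0.95

    def test_subsampling_consistency(self):
        """Doubling sample size moves mean window diversity < 5%."""
        means = []
        for n in (8, 16):
            cfg = SimConfig(seed=33, samples_per_pop=n,
                            chrom_lengths={"chr1": 1_000_000}, n_snps=10_000,
                            fst_background=0.05)
            gm, _ = simulate_genotypes(cfg)
            windows = ps.make_windows(cfg.chrom_lengths)
            pi, _ = ps.window_pi(gm, "pop1", windows)
            means.append(pi.mean())
        assert abs(means[1] - means[0]) / means[0] < 0.05
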