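"""Exact tests, regression, diversity, sweep test and substitution counts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from packtir.io import VariantPanel
from packtir.popstats import (allele_frequency_spectrum, codon_site_counts,
                              fisher_exact, fit_count_regression,
                              gc_content, per_site_pi,
                              region_substitution_test,
                              sweep_empirical_pvalue, windowed_pi)
from packtir.simulate import (SimulationConfig, simulate_species_counts,
                              simulate_variant_panel)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive enumeration over tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2) == 0 or min(c1, n - c1) == 0:
        return 1.0
    rv = stats.hypergeom(n, r1, c1)
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(k_lo, k_hi + 1)
    pmfs = rv.pmf(ks)
    return float(pmfs[pmfs <= p_obs * (1 + 1e-7)].sum())


class TestFisher:
    def test_reference_two_sided(self):
        assert fisher_exact([[3, 20], [481, 856]], "two") == \
            pytest.approx(0.026, abs=5e-4)

    def test_reference_one_sided(self):
        assert fisher_exact([[5, 3], [5, 20]], "one") == \
            pytest.approx(0.036, abs=5e-4)
        assert fisher_exact([[12, 5], [0, 3]], "one") == \
            pytest.approx(0.049, abs=5e-4)

    def test_balanced_table_gives_one(self):
        assert fisher_exact([[1, 1], [1, 1]], "two") == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])

    def test_matches_enumeration_small_tables(self):
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b + c + d == 0:
                continue
            got = fisher_exact([[a, b], [c, d]], "two")
            assert got == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), rel=1e-9, abs=1e-12)


class TestRegression:
    def test_exact_linear_fit(self):
        r = fit_count_regression([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r.slope == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.p_value < 1e-6

    def test_closed_form_oracle_six_points(self):
        x = np.array([1.0, 2, 3, 5, 8, 13])
        y = np.array([2.0, 3, 7, 11, 14, 29])
        r = fit_count_regression(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r2 = sxy ** 2 / (sxx * ((y - y.mean()) ** 2).sum())
        assert r.slope == pytest.approx(slope, rel=1e-12)
        assert r.r_squared == pytest.approx(r2, rel=1e-12)
        # F equals t^2 with (1, n-2) df and reproduces the p-value
        assert r.p_value == pytest.approx(
            stats.f.sf(r.f_stat, 1, 4), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_count_regression([3, 3, 3, 3], [1, 2, 3, 4])

    def test_recovers_planted_capture_rate(self):
        """Poisson counts at 2 captures per 10,000 TE copies regress back
        to the planted rate within 20%."""
        x, y = simulate_species_counts(n_species=55, rate=2e-4, seed=8)
        r = fit_count_regression(x, y)
        assert r.slope == pytest.approx(2e-4, rel=0.2)


class TestAFS:
    def test_all_singletons(self):
        m = pd.DataFrame(np.eye(4, dtype=int))
        afs = allele_frequency_spectrum(m)
        assert afs.singleton_fraction == 1.0

    def test_hand_matrix(self):
        m = pd.DataFrame({"i1": [1, 0, 0, 0], "i2": [1, 1, 0, 0],
                          "i3": [1, 1, 1, 1]})
        afs = allele_frequency_spectrum(m)
        assert afs.frequencies.tolist() == [0.25, 0.5, 1.0]
        assert afs.singleton_fraction == pytest.approx(1 / 3)

    def test_zero_carrier_insertions_excluded(self):
        m = pd.DataFrame({"i1": [1, 0], "dead": [0, 0]})
        afs = allele_frequency_spectrum(m)
        assert list(afs.frequencies.index) == ["i1"]


class TestWindowedPi:
    def _panel(self, geno, positions=None, chrom="c1"):
        geno = np.asarray(geno, dtype=np.int8)
        n_sites, n_lines = geno.shape
        positions = np.asarray(
            positions if positions is not None else np.arange(n_sites) * 10,
            dtype=np.int64)
        return VariantPanel([f"L{i}" for i in range(n_lines)],
                            np.array([chrom] * n_sites, dtype=object),
                            positions, geno)

    def test_worked_example(self):
        """4 lines, allele counts (2,2): per-site pi = 2*2*2/(4*3); two such
        sites in one 1,000 bp window give pi = 0.0013333."""
        panel = self._panel([[1, 1, 0, 0], [0, 1, 0, 1]], [100, 200])
        pi_site = per_site_pi(panel.genotypes)
        assert pi_site[0] == pytest.approx(2 / 3)
        w = windowed_pi(panel, "c1", span=(0, 1000))[0]
        assert w.pi == pytest.approx(2 * (2 / 3) / 1000)
        assert w.n_snps == 2

    def test_empty_window_gives_zero(self):
        panel = self._panel(np.zeros((0, 4), dtype=np.int8), [])
        w = windowed_pi(panel, "c1", span=(0, 1000))[0]
        assert w.pi == 0.0

    def test_matches_pairwise_hamming_oracle(self, rng):
        """pi equals mean pairwise differences / window length."""
        n_lines, n_sites = 8, 40
        geno = (rng.random((n_sites, n_lines)) < 0.3).astype(np.int8)
        geno[rng.random((n_sites, n_lines)) < 0.05] = -1
        panel = self._panel(geno, np.sort(rng.choice(2000, n_sites,
                                                     replace=False)))
        window = 2000
        got = windowed_pi(panel, "c1", span=(0, window), window=window)[0].pi
        total = 0.0
        for s in range(n_sites):
            row = geno[s]
            called = row[row >= 0]
            k = len(called)
            if k < 2:
                continue
            diffs = sum(1 for i, j in itertools.combinations(range(k), 2)
                        if called[i] != called[j])
            total += diffs / (k * (k - 1) / 2)
        assert got == pytest.approx(total / window, abs=1e-12)

    def test_invariant_to_relabeling_and_allele_flip(self, rng):
        geno = (rng.random((20, 6)) < 0.4).astype(np.int8)
        panel = self._panel(geno)
        base = windowed_pi(panel, "c1", span=(0, 1000))[0].pi
        perm = rng.permutation(6)
        assert windowed_pi(self._panel(geno[:, perm]), "c1",
                           span=(0, 1000))[0].pi == pytest.approx(base)
        flipped = geno.copy()
        flipped[3] = 1 - flipped[3]
        assert windowed_pi(self._panel(flipped), "c1",
                           span=(0, 1000))[0].pi == pytest.approx(base)


class TestSweep:
    def test_planted_sweep_detected(self):
        cfg = SimulationConfig()
        panel, carriers = simulate_variant_panel(cfg, seed=2)
        mid = cfg.panel.region_len // 2
        res = sweep_empirical_pvalue(panel, "chrP", carriers,
                                     (mid - 5000, mid + 5000),
                                     n_reps=1000, seed=3)
        assert res.observed_ratio < 1
        assert res.empirical_p <= 0.05
        assert res.empirical_p == res.n_le / res.n_reps

    def test_observed_above_all_replicates_gives_one(self):
        """When the noncarriers are monomorphic over the span, the observed
        ratio is infinite and every replicate is <= it."""
        rng = np.random.default_rng(5)
        n_sites, n_lines = 200, 20
        geno = (rng.random((n_sites, n_lines)) < 0.3).astype(np.int8)
        # noncarriers flat across every window touching the observed span
        geno[:75, 10:] = 0
        positions = np.arange(n_sites) * 20
        panel = VariantPanel([f"L{i}" for i in range(n_lines)],
                             np.array(["c1"] * n_sites, dtype=object),
                             positions.astype(np.int64), geno,
                             is_synonymous=np.ones(n_sites, dtype=bool))
        res = sweep_empirical_pvalue(panel, "c1", [f"L{i}" for i in range(10)],
                                     (0, 1000), n_reps=200, seed=1)
        assert res.observed_ratio == np.inf
        assert res.empirical_p == 1.0

    def test_seeded_rerun_is_bit_identical(self):
        cfg = SimulationConfig()
        panel, carriers = simulate_variant_panel(cfg, seed=4)
        mid = cfg.panel.region_len // 2
        kw = dict(n_reps=300, seed=17)
        a = sweep_empirical_pvalue(panel, "chrP", carriers,
                                   (mid - 5000, mid + 5000), **kw)
        b = sweep_empirical_pvalue(panel, "chrP", carriers,
                                   (mid - 5000, mid + 5000), **kw)
        assert a.n_le == b.n_le

    def test_missing_synonymous_flags_rejected(self):
        panel = VariantPanel(["a", "b", "c", "d"],
                             np.array(["c1"], dtype=object),
                             np.array([10], dtype=np.int64),
                             np.zeros((1, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            sweep_empirical_pvalue(panel, "c1", ["a"], (0, 100))


class TestSubstitutionCounts:
    def test_phenylalanine_codon_site_fraction(self):
        syn, non = codon_site_counts("TTT")
        assert syn == pytest.approx(1 / 3)
        assert non == pytest.approx(8 / 3)

    def test_identical_sequences_give_zero_counts(self):
        aln = {"out": "ATGAAATTT", "in1": "ATGAAATTT"}
        res = region_substitution_test(aln, "out", ["r1", "r1", "r2"])
        assert sum(res.obs_syn.values()) == 0
        assert sum(res.obs_nonsyn.values()) == 0

    def test_expected_proportions_sum_to_one(self):
        aln = {"out": "ATGAAATTTGGGCCC", "in1": "ATGAAGTTTGGACCC"}
        res = region_substitution_test(aln, "out",
                                       ["r1", "r1", "r2", "r2", "r3"])
        assert sum(res.exp_syn_prop.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(res.exp_nonsyn_prop.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_synonymous_change_classified(self):
        aln = {"out": "TTT", "in1": "TTC"}       # Phe -> Phe
        res = region_substitution_test(aln, "out", ["r1"])
        assert res.obs_syn["r1"] == 1.0
        assert res.obs_nonsyn["r1"] == 0.0

    def test_two_hit_codon_pathway_averaged(self):
        # TTT -> GTA: paths TTT->GTT(V, non)->GTA(V, syn) and
        # TTT->TTA(L, non)->GTA(V, non): average (0.5 syn, 1.5 non)
        aln = {"out": "TTT", "in1": "GTA"}
        res = region_substitution_test(aln, "out", ["r1"])
        assert res.obs_syn["r1"] == pytest.approx(0.5)
        assert res.obs_nonsyn["r1"] == pytest.approx(1.5)

    def test_frame_breaking_gap_rejected(self):
        aln = {"out": "ATG-AA", "in1": "ATGAAA"}
        with pytest.raises(ValueError, match="codon"):
            region_substitution_test(aln, "out", ["r1", "r1"])

    def test_region_site_counts_sum_to_whole_gene(self):
        seq = "ATGAAATTTGGGCCCTACTGA"
        aln = {"out": seq, "in1": seq}
        regions = ["r1", "r2", "r1", "r3", "r2", "r3", "r1"]
        res = region_substitution_test(aln, "out", regions)
        whole_syn = sum(codon_site_counts(seq[i:i + 3])[0]
                        for i in range(0, len(seq), 3))
        assert sum(res.obs_syn.values()) == 0
        assert res.total_syn_sites == pytest.approx(whole_syn, abs=1e-9)


def test_gc_content_ignores_n():
    assert gc_content("GGCCAATT") == 0.5
    assert gc_content("GCNN") == 1.0
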