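"""Composite-likelihood machinery: analytic limits, normalization, drift
recovery, LD weights, and scan invariants (localization runs in
test_acceptance)."""

import numpy as np
import pytest
from scipy import stats

import polysweep as ps
import polysweep.xpclr as xp

from conftest import counts_from_haplotypes


class TestEstimateOmega:
    def test_identical_exact_frequencies_give_zero(self):
        # counts given as exact frequencies with huge n: estimator -> 0
        from polysweep.variants import AlleleCounts

        n = 10**7
        m = np.array([int(0.3 * n), int(0.7 * n), int(0.5 * n)])
        counts = AlleleCounts(
            m=m, n=np.full(3, n), n_het=np.zeros(3, int), n_called=np.full(3, n // 2)
        )
        model = xp.estimate_omega(counts, counts)
        assert model.omega == pytest.approx(0.0, abs=1e-6)

    def test_hand_evaluated_ten_site_toy(self):
        from polysweep.variants import AlleleCounts

        rng = np.random.default_rng(5)
        n1, n2 = 20, 30
        m1 = rng.integers(1, n1, 10)
        m2 = rng.integers(0, n2 + 1, 10)
        c1 = AlleleCounts(m1, np.full(10, n1), np.zeros(10, int), np.full(10, 10))
        c2 = AlleleCounts(m2, np.full(10, n2), np.zeros(10, int), np.full(10, 15))
        # direct transcription of the estimator formula
        terms = []
        for a, b in zip(m1, m2):
            p1, p2 = a / n1, b / n2
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (n1 - 1)
                - p2 * (1 - p2) / (n2 - 1)
            )
            den = p1 * (1 - p1) * n1 / (n1 - 1)
            terms.append(num / den)
        expected = max(float(np.mean(terms)), 0.0)
        with pytest.warns(UserWarning, match="usable sites"):
            model = xp.estimate_omega(c1, c2)
        assert model.omega == pytest.approx(expected, abs=1e-12)

    def test_recovers_generator_omega(self):
        # 5 seeds at n = 60/60, 30k SNPs: mean within 10% of truth
        for omega_true in (0.02, 0.1):
            estimates = []
            for seed in range(5):
                cfg = ps.SimConfig(
                    n_snps=30_000, chrom_length=6_000_000, omega=omega_true,
                    seed=seed,
                )
                pair = ps.simulate_neutral_pair(cfg)
                model = xp.estimate_omega(
                    counts_from_haplotypes(pair.hap_ref),
                    counts_from_haplotypes(pair.hap_obj),
                )
                estimates.append(model.omega)
            assert np.mean(estimates) == pytest.approx(omega_true, rel=0.10)

    def test_no_usable_sites_raises(self):
        from polysweep.variants import AlleleCounts

        fixed = AlleleCounts(
            np.array([0, 10]), np.full(2, 10), np.zeros(2, int), np.full(2, 5)
        )
        with pytest.raises(ValueError, match="usable"):
            xp.estimate_omega(fixed, fixed)


class TestSiteLikelihoods:
    def test_zero_drift_limit_is_binomial(self):
        ll = xp.neutral_site_loglik(3, 10, 0.3, xp.DriftModel(1e-12))
        assert np.exp(ll) == pytest.approx(stats.binom.pmf(3, 10, 0.3), abs=1e-4)

    @pytest.mark.parametrize("p1,omega", [(0.3, 0.05), (0.5, 0.2), (0.05, 0.01),
                                          (0.9, 0.5), (0.5, 1e-3)])
    def test_neutral_normalizes(self, p1, omega):
        model = xp.DriftModel(omega)
        total = sum(np.exp(xp.neutral_site_loglik(m, 20, p1, model)) for m in range(21))
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("kappa", [0.0, 0.3, 0.5, 0.9, 1.0])
    def test_sweep_normalizes(self, kappa):
        model = xp.DriftModel(0.05)
        total = sum(
            np.exp(xp.sweep_site_loglik(m, 20, 0.4, model, kappa)) for m in range(21)
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_kappa_zero_equals_neutral(self):
        model = xp.DriftModel(0.08)
        for m in (0, 3, 11, 20):
            assert xp.sweep_site_loglik(m, 20, 0.35, model, 0.0) == pytest.approx(
                xp.neutral_site_loglik(m, 20, 0.35, model), abs=1e-9
            )

    def test_kappa_one_forbids_intermediate_counts(self):
        model = xp.DriftModel(0.05)
        assert xp.sweep_site_loglik(7, 20, 0.4, model, 1.0) == xp.LOG_FLOOR
        # all mass on loss/fixation
        p0 = np.exp(xp.sweep_site_loglik(0, 20, 0.4, model, 1.0))
        p20 = np.exp(xp.sweep_site_loglik(20, 20, 0.4, model, 1.0))
        assert p0 + p20 == pytest.approx(1.0, abs=1e-9)

    def test_neutral_matches_monte_carlo(self, rng):
        # marginal pmf of m2 under the truncated-Gaussian drift model
        p1, omega, n2 = 0.5, 0.05, 20
        draws = 10**6
        x = np.clip(rng.normal(p1, np.sqrt(omega * p1 * (1 - p1)), draws), 0, 1)
        m2 = rng.binomial(n2, x)
        model = xp.DriftModel(omega)
        for m in (0, 5, 10, 15, 20):
            mc = np.mean(m2 == m)
            se = np.sqrt(mc * (1 - mc) / draws)
            exact = np.exp(xp.neutral_site_loglik(m, n2, p1, model))
            assert abs(exact - mc) < 3 * se + 1e-4

    def test_invalid_inputs_rejected(self):
        model = xp.DriftModel(0.05)
        with pytest.raises(ValueError):
            xp.sweep_site_loglik(1, 10, 0.5, model, 1.5)
        with pytest.raises(ValueError):
            xp.neutral_site_loglik(1, 10, 1.0, model)
        with pytest.raises(ValueError):
            xp.DriftModel(-0.1)


class TestSnpWeights:
    def test_uncorrelated_all_ones(self, rng):
        hap = rng.integers(0, 2, (10, 400)).astype(float)
        w = xp.snp_weights(hap, r2_cutoff=0.7)
        assert np.allclose(w, 1.0)

    def test_three_identical_share_weight(self):
        row = np.array([0, 1, 1, 0, 1, 0], float)
        hap = np.vstack([row, row, row])
        assert np.allclose(xp.snp_weights(hap), 1 / 3)

    def test_matches_brute_force_enumeration(self, rng):
        hap = (rng.random((6, 30)) < 0.5).astype(float)
        hap[1] = hap[0]  # force one correlated pair
        w = xp.snp_weights(hap, r2_cutoff=0.7)
        for k in range(6):
            m = 0
            for j in range(6):
                sk, sj = hap[k].std(), hap[j].std()
                if k == j:
                    r2 = 1.0
                elif sk == 0 or sj == 0:
                    r2 = 0.0
                else:
                    r2 = np.corrcoef(hap[k], hap[j])[0, 1] ** 2
                m += r2 >= 0.7
            assert w[k] == pytest.approx(1 / m)


@pytest.fixture(scope="module")
def neutral_scan():
    cfg = ps.SimConfig(n_snps=1_500, chrom_length=400_000, omega=0.1, seed=9)
    pair = ps.simulate_neutral_pair(cfg)
    cr = counts_from_haplotypes(pair.hap_ref)
    co = counts_from_haplotypes(pair.hap_obj)
    model = xp.estimate_omega(cr, co)
    params = xp.ScanParams(seed=1, grid_bp=10_000)
    return xp.xpclr_scan(
        cr, co, pair.hap_obj, pair.positions, pair.genetic_map, params, model
    )


class TestScan:

    def test_scores_nonnegative_and_median_small(self, neutral_scan):
        s = neutral_scan["score"].to_numpy()
        s = s[np.isfinite(s)]
        assert np.all(s >= 0)
        assert np.median(s) < 10.0  # neutral data: no systematic sweep signal

    def test_allele_label_flip_invariance(self):
        cfg = ps.SimConfig(n_snps=400, chrom_length=100_000, omega=0.1, seed=13)
        pair = ps.simulate_neutral_pair(cfg)
        cr = counts_from_haplotypes(pair.hap_ref)
        co = counts_from_haplotypes(pair.hap_obj)
        cr_f = counts_from_haplotypes(1 - pair.hap_ref)
        co_f = counts_from_haplotypes(1 - pair.hap_obj)
        model = xp.DriftModel(0.1)
        params = xp.ScanParams(seed=3, grid_bp=20_000, interp_knots=0)
        a = xp.xpclr_scan(
            cr, co, pair.hap_obj, pair.positions, pair.genetic_map, params, model
        )
        b = xp.xpclr_scan(
            cr_f, co_f, 1 - pair.hap_obj, pair.positions, pair.genetic_map,
            params, model,
        )
        np.testing.assert_allclose(
            a["score"].to_numpy(), b["score"].to_numpy(), atol=1e-6
        )

    def test_single_snp_window_neutral_sigma_scores_zero(self):
        from polysweep.variants import AlleleCounts
        from polysweep.genmap import linear_map

        counts_r = AlleleCounts(
            np.array([6]), np.array([20]), np.array([0]), np.array([10])
        )
        counts_o = AlleleCounts(
            np.array([9]), np.array([20]), np.array([0]), np.array([10])
        )
        hap = np.array([[0] * 10 + [1] * 10], dtype=np.int8)
        # a sigma so small that kappa == 0 beyond the site itself; the grid
        # point sits away from the SNP, so the sweep model reduces to neutral
        params = xp.ScanParams(
            sigma_grid=np.array([1e-12]), grid_bp=50, seed=0, interp_knots=0
        )
        track = xp.xpclr_scan(
            counts_r, counts_o, hap, np.array([5_000]), linear_map(10_000),
            params, xp.DriftModel(0.05),
        )
        on_snp = track["pos"] == 5_000
        assert np.allclose(track.loc[~on_snp, "score"].dropna(), 0.0, atol=1e-9)

    def test_deterministic_given_seed(self, neutral_scan):
        cfg = ps.SimConfig(n_snps=1_500, chrom_length=400_000, omega=0.1, seed=9)
        pair = ps.simulate_neutral_pair(cfg)
        cr = counts_from_haplotypes(pair.hap_ref)
        co = counts_from_haplotypes(pair.hap_obj)
        model = xp.estimate_omega(cr, co)
        params = xp.ScanParams(seed=1, grid_bp=10_000)
        again = xp.xpclr_scan(
            cr, co, pair.hap_obj, pair.positions, pair.genetic_map, params, model
        )
        assert again.equals(neutral_scan)
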