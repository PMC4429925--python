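"""Multi-trait-scale transforms, derived genetic parameters, MCMC diagnostics."""

import numpy as np
import pytest
from scipy import stats

import sirsem as ss
from sirsem.exceptions import InputError
from sirsem.structure import preset_structure
from sirsem.summaries import (
    TransformedDraw,
    autocorrelation,
    correlations,
    diagnostics,
    effective_sample_size,
    heritability,
    hpd_interval,
    running_mean,
    sd_units,
    summarize_chain,
    to_mtm_scale,
    variance_loss,
)


def _random_pd(rng, n=4, scale=1.0):
    return stats.wishart.rvs(df=n + 3, scale=scale * np.eye(n) / (n + 3),
                             random_state=rng)


def _random_acyclic_lambda(rng, n=4):
    perm = rng.permutation(n)
    lam = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            if rng.random() < 0.6:
                lam[perm[i], perm[j]] = rng.normal(scale=1.0)
    return lam


class TestToMtmScale:
    def test_zero_lambda_is_identity(self, rng):
        G, P, H = (_random_pd(rng) for _ in range(3))
        R = np.diag(rng.uniform(0.5, 2, 4))
        d = to_mtm_scale(G, P, H, R, np.zeros((4, 4)))
        assert np.allclose(d.G, G) and np.allclose(d.R, R)

    def test_single_edge_hand_algebra(self):
        """With only lambda43 = c and diagonal R: R*44 = r4 + c^2 r3 and
        R*34 = c r3 (2x2 block algebra)."""
        c = -1.901
        s = preset_structure("M2")
        lam = s.lambda_matrix([c])
        r = np.array([1.1, 0.7, 2.3, 3.9])
        d = to_mtm_scale(np.eye(4), np.eye(4), np.eye(4), np.diag(r), lam)
        assert d.R[3, 3] == pytest.approx(r[3] + c**2 * r[2], abs=1e-12)
        assert d.R[2, 3] == pytest.approx(c * r[2], abs=1e-12)
        assert d.R[0, 0] == pytest.approx(r[0])

    def test_round_trip_and_psd_preservation(self, rng):
        for _ in range(200):
            lam = _random_acyclic_lambda(rng)
            G = _random_pd(rng)
            d = to_mtm_scale(G, G, G, G, lam)
            B = np.eye(4) - lam
            assert np.allclose(B @ d.G @ B.T, G, atol=1e-10 * max(1, np.abs(G).max()))
            assert np.linalg.eigvalsh(d.G).min() >= -1e-10


class TestDerivedScalars:
    def test_heritability_published_arithmetic(self):
        d = TransformedDraw(
            G=np.array([[3.829]]), P=np.array([[0.0]]),
            H=np.array([[0.0]]), R=np.array([[81.998 - 3.829]]),
        )
        assert round(heritability(d, 0), 3) == 0.187
        d2 = TransformedDraw(
            G=np.array([[0.536]]), P=np.array([[0.0]]),
            H=np.array([[0.0]]), R=np.array([[22.108 - 0.536]]),
        )
        assert round(heritability(d2, 0), 3) == 0.097

    def test_zero_sire_variance_gives_zero_heritability(self):
        d = TransformedDraw(G=np.array([[0.0]]), P=np.array([[1.0]]),
                            H=np.array([[1.0]]), R=np.array([[1.0]]))
        assert heritability(d, 0) == 0.0

    def test_correlations_diagonal_and_symmetry(self, rng):
        d = TransformedDraw(G=np.diag([1.0, 2.0, 3.0, 4.0]),
                            P=_random_pd(rng), H=_random_pd(rng),
                            R=_random_pd(rng))
        g, p = correlations(d)
        assert np.allclose(g, np.eye(4))  # diagonal G -> no genetic correlation
        for m in (g, p):
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)
            assert np.abs(m).max() <= 1.0 + 1e-12

    @pytest.mark.parametrize(
        "lam,sdx,sdy,expected",
        [
            (-1.901, 3.80, 8.53, -0.8469),
            (0.242, 1.66, 3.80, 0.1057),
            (18.823, 0.23, 8.53, 0.5075),
            (0.0, 3.80, 8.53, 0.0),
        ],
    )
    def test_sd_units_worked_examples(self, lam, sdx, sdy, expected):
        assert round(sd_units(lam, sdx, sdy), 4) == expected

    def test_sd_units_rescaling_invariance(self):
        # x -> a x with lambda -> lambda / a leaves the SD-unit value fixed
        a = 7.3
        assert sd_units(-1.901 / a, a * 3.80, 8.53) == pytest.approx(
            sd_units(-1.901, 3.80, 8.53)
        )

    def test_sd_units_zero_sd_rejected(self):
        with pytest.raises(InputError):
            sd_units(1.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "v0,vk,expected", [(3.829, 0.536, 86.0), (3.829, 3.829, 0.0),
                           (81.998, 11.902, 85.5)]
    )
    def test_variance_loss_worked_examples(self, v0, vk, expected):
        assert round(variance_loss(v0, vk), 1) == expected


class TestHpdInterval:
    def test_standard_normal_quantiles(self):
        # shortest-interval endpoints have MC error ~0.05 at this n
        x = np.random.default_rng(5).standard_normal(10_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.16)
        assert hi == pytest.approx(1.96, abs=0.16)

    def test_constant_samples_zero_width(self):
        assert hpd_interval(np.full(500, 2.5)) == (2.5, 2.5)

    def test_shorter_than_equal_tail_on_skewed_draws(self):
        x = np.random.default_rng(8).chisquare(3, size=20_000)
        lo, hi = hpd_interval(x, 0.95)
        eq_lo, eq_hi = np.quantile(x, [0.025, 0.975])
        assert (hi - lo) <= (eq_hi - eq_lo)
        assert lo < eq_lo  # mass shifts toward the mode at zero

    def test_cross_check_against_arviz(self):
        az = pytest.importorskip("arviz")
        x = np.random.default_rng(3).normal(2.0, 1.5, size=8000)
        lo, hi = hpd_interval(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)


class TestEffectiveSampleSize:
    def test_iid_draws(self):
        x = np.random.default_rng(1).standard_normal(20_000)
        assert effective_sample_size(x) == pytest.approx(20_000, rel=0.1)

    def test_ar1_closed_form(self):
        rho, n = 0.9, 50_000
        rng = np.random.default_rng(2)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_chain_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(effective_sample_size(np.ones(100)))

    def test_autocorrelation_lag_zero_is_one(self, rng):
        x = rng.standard_normal(500)
        assert autocorrelation(x, 5)[0] == pytest.approx(1.0)

    def test_running_mean_converges_to_mean(self, rng):
        x = rng.standard_normal(1000)
        assert running_mean(x)[-1] == pytest.approx(x.mean())


class TestChainSummaries:
    def test_m0_chain_sem_and_mtm_scales_coincide(self, m0_chain):
        lams = m0_chain.lambda_matrices()
        assert np.abs(lams).max() == 0.0
        summary = summarize_chain(m0_chain)
        g_direct = m0_chain.G_samples[:, 3, 3]
        assert np.allclose(summary.samples["sigma2_s"][:, 3], g_direct)

    def test_phenotypic_variance_is_component_sum(self, m2_chain):
        summary = summarize_chain(m2_chain)
        vc = summary.variance_components
        total = (vc["sigma2_s"] + vc["sigma2_p"] + vc["sigma2_h"] + vc["sigma2_e"])
        assert np.allclose(total, vc["sigma2_y"], rtol=1e-10)

    def test_genetic_correlation_sign_recovery(self, m2_chain):
        """A chain fitted to data with a strong negative coagulation-time ->
        curd-firmness path shows a strongly negative genetic correlation on
        the multi-trait scale."""
        summary = summarize_chain(m2_chain)
        assert summary.genetic_correlation.loc["RCT", "a30"] < -0.5

    def test_variance_loss_against_baseline(self, m2_chain, m0_chain):
        """The coagulation-time path absorbs most of the direct curd-firmness
        variance: structural-scale components shrink sharply versus the
        no-edge baseline fitted to the same records."""
        summary = summarize_chain(m2_chain, baseline=m0_chain)
        loss = summary.variance_loss_table
        assert loss is not None
        point = loss.set_index("component")["loss_pct_point"]
        assert 30 < point["sigma2_y"] <= 100
        # with only ~13 sires at this scale the sire variance is heavily
        # prior-shrunk in both chains, so only the direction is informative
        assert point["sigma2_s"] > 0
        # direct heritability stays a proper fraction
        assert 0 <= point["h2_direct"] <= 1

    def test_sd_units_attached_when_sds_given(self, m2_chain, m2_sim):
        sds = {t: float(m2_sim.records[t].std(ddof=1)) for t in m2_chain.traits}
        summary = summarize_chain(m2_chain, data_sds=sds)
        ce = summary.causal_effects
        expected = ce["estimate"][0] * sds["RCT"] / sds["a30"]
        assert ce["sd_units"][0] == pytest.approx(expected)

    def test_diagnostics_frame(self, m2_chain):
        d = diagnostics({"lambda43": m2_chain.lambda_samples[:, 0]})
        row = d.loc["lambda43"]
        assert row["hpd_low"] <= row["mean"] <= row["hpd_high"]
        assert 0 < row["ess"] <= m2_chain.n_samples * 1.5
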