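"""Sampler building blocks: reduction, conjugate updates, Metropolis steps."""

import numpy as np
import pandas as pd
import pytest

import sirsem as ss
from sirsem.exceptions import InputError
from sirsem.sampler import (
    ChainConfig,
    _initial_state,
    mh_structural,
    prepare_data,
    reduce_records,
)
from sirsem.structure import make_structure, preset_structure


class TestChainConfig:
    @pytest.mark.parametrize(
        "n_iter,burn,thin,expected",
        [(1000, 200, 4, 200), (100, 0, 1, 100), (1500, 500, 2, 500)],
    )
    def test_retained_count(self, n_iter, burn, thin, expected):
        assert ChainConfig(n_iter=n_iter, burn_in=burn, thin=thin).n_retained == expected

    def test_invalid_protocol_rejected(self):
        with pytest.raises(InputError):
            ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(InputError):
            ChainConfig(thin=0)


class TestReduceRecords:
    def test_zero_lambda_is_identity(self, rng):
        Y = rng.standard_normal((10, 4))
        assert np.array_equal(reduce_records(Y, np.zeros((4, 4))), Y)

    def test_hand_arithmetic_single_edge(self):
        # record (RCT=18.9, a30=23.0) under lambda43 = -1.901:
        # y*4 = 23.0 - (-1.901) * 18.9 = 58.9289
        s = preset_structure("M2")
        lam = s.lambda_matrix({("RCT", "a30"): -1.901})
        Y = np.array([[2.35, 2.46, 18.9, 23.0]])
        ystar = reduce_records(Y, lam)
        assert ystar[0, 3] == pytest.approx(58.9289, abs=1e-10)
        assert np.allclose(ystar[0, :3], Y[0, :3])

    def test_round_trip(self, rng):
        s = preset_structure("M3")
        lam = s.lambda_matrix([-0.267, 12.845, -1.792])
        Y = rng.standard_normal((50, 4))
        back = reduce_records(Y, lam) @ np.linalg.inv(np.eye(4) - lam).T
        assert np.allclose(back, Y, atol=1e-12)


def _stripped_data(n, rng, trait="y"):
    """Single-trait records with no random-effect columns."""
    records = pd.DataFrame(
        {
            "dim_class": rng.integers(1, 5, size=n),
            trait: rng.standard_normal(n) * 2.0 + 1.0,
        }
    )
    structure = make_structure([], traits=(trait,))
    return records, structure


class TestGibbsLocation:
    def test_single_record_conjugate_posterior(self, rng):
        """One trait, one record, fixed residual variance: the sampled
        intercept follows the scalar normal-normal posterior."""
        records = pd.DataFrame({"dim_class": [4], "y": [3.0]})
        structure = make_structure([], traits=("y",))
        data = prepare_data(records, structure, components=())
        priors = ss.PriorSpec(nu=6.0, scale_R=np.array([[4.0]])).resolve(np.array([1.0]))
        state = _initial_state(data, priors)
        sigma2, c = 2.0, priors.fixed_effect_variance
        state.R = np.array([[sigma2]])
        draws = np.empty(4000)
        for i in range(4000):
            ss.gibbs_location(state, data, priors, rng)
            draws[i] = state.b[0, 0]
        post_var = 1.0 / (1.0 / sigma2 + 1.0 / c)
        post_mean = post_var * 3.0 / sigma2
        assert draws.mean() == pytest.approx(post_mean, abs=4 * np.sqrt(post_var / 4000))
        assert draws.var() == pytest.approx(post_var, rel=0.1)

    def test_small_residual_variance_recovers_least_squares(self, rng):
        """As R -> eps I the sampled fixed effects pin to the least-squares fit."""
        records, structure = _stripped_data(200, rng)
        beta = np.array([1.0, 0.5, -0.3, 0.2])
        from sirsem.simulate import dim_design_matrix

        X = dim_design_matrix(records["dim_class"].to_numpy())
        records["y"] = X @ beta  # noiseless responses
        data = prepare_data(records, structure, components=())
        priors = ss.PriorSpec().resolve(np.array([1.0]))
        state = _initial_state(data, priors)
        state.R = np.array([[1e-10]])
        ss.gibbs_location(state, data, priors, rng)
        assert np.allclose(state.b[:, 0], beta, atol=1e-4)


class TestGibbsCovariances:
    def test_prior_only_draws_match_inverse_wishart_mean(self, rng):
        """With no data rows and zero effects the covariance draws are the
        prior inverse-Wishart, mean S / (nu - p - 1)."""
        traits = ("u", "v")
        structure = make_structure([], traits=traits)
        records = pd.DataFrame({"dim_class": [], "cow": [], "u": [], "v": []})
        data = prepare_data(records, structure, components=("pe",))
        nu = 20.0
        target = np.diag([2.0, 3.0])
        S = (nu - 3.0) * target
        priors = ss.PriorSpec(
            nu=nu, scale_P=S, scale_G=S, scale_H=S, scale_R=S
        ).resolve(np.array([1.0, 1.0]))
        state = _initial_state(data, priors)
        draws = np.empty((2000, 2, 2))
        for i in range(2000):
            ss.gibbs_covariances(state, data, priors, rng)
            draws[i] = state.P
        assert np.allclose(draws.mean(axis=0), target, rtol=0.05, atol=0.05)

    def test_sem_residual_covariance_is_diagonal(self, m2_chain):
        off = m2_chain.R_samples.copy()
        off[:, np.arange(4), np.arange(4)] = 0.0
        assert np.abs(off).max() == 0.0

    def test_mtm_residual_covariance_is_full(self, m0_chain):
        off = m0_chain.R_samples.copy()
        off[:, np.arange(4), np.arange(4)] = 0.0
        assert np.abs(off).max() > 0.0


class TestMetropolisStructural:
    def test_zero_step_accepts_everything(self, m2_sim):
        structure = preset_structure("M2")
        data = prepare_data(m2_sim.records, structure, m2_sim.design.pedigree)
        priors = ss.PriorSpec().resolve(data.Y.var(axis=0, ddof=1))
        state = _initial_state(data, priors)
        rng = np.random.default_rng(0)
        for _ in range(20):
            accepted = mh_structural(state, data, priors, np.zeros(1), rng)
            assert accepted.all()

    def test_degenerate_prior_pins_coefficients_at_zero(self, m2_sim):
        structure = preset_structure("M2")
        cfg = ChainConfig(n_iter=200, burn_in=50, thin=1, seed=3)
        chain = ss.run_chain(
            m2_sim.records, structure, m2_sim.design.pedigree,
            priors=ss.PriorSpec(tau2=1e-12), config=cfg,
        )
        assert np.abs(chain.lambda_samples).max() < 1e-4

    def test_mh_matches_closed_form_conditional(self, m2_sim):
        """Holding every other parameter fixed, the Metropolis chain for one
        coefficient must converge to its analytically available normal full
        conditional (the conjugate form is used only as this oracle)."""
        structure = preset_structure("M2")
        data = prepare_data(m2_sim.records, structure, m2_sim.design.pedigree)
        priors = ss.PriorSpec().resolve(data.Y.var(axis=0, ddof=1))
        state = _initial_state(data, priors)
        rng = np.random.default_rng(42)
        # a light warm-up of the location/covariance blocks, then freeze them
        for _ in range(30):
            ss.gibbs_location(state, data, priors, rng)
            ss.gibbs_covariances(state, data, priors, rng)
        row, col = data.edge_pos[0]
        mean_part = (
            data.X @ state.b
            + state.h[data.herd_idx]
            + state.p[data.cow_idx]
            + state.s[data.sire_idx]
        )
        # closed-form conditional: quadratic in lambda
        yx = data.Y[:, col]
        partial = data.Y[:, row] - mean_part[:, row]
        r_y = state.R[row, row]
        prec = yx @ yx / r_y + 1.0 / priors.tau2
        mu = (yx @ partial / r_y + priors.lambda0 / priors.tau2) / prec
        sd = np.sqrt(1.0 / prec)

        steps = np.array([2.5 * sd])  # near-optimal random walk scale
        draws = np.empty(6000)
        for i in range(6000):
            mh_structural(state, data, priors, steps, rng)
            draws[i] = state.lam[0]
        ess = ss.effective_sample_size(draws[1000:])
        mc_err = sd / np.sqrt(max(ess, 10))
        assert draws[1000:].mean() == pytest.approx(mu, abs=5 * mc_err)
        assert draws[1000:].std() == pytest.approx(sd, rel=0.15)


class TestRunChain:
    def test_fixed_seed_bit_identical(self, tiny_sim):
        structure = preset_structure("M2")
        cfg = ChainConfig(n_iter=150, burn_in=50, thin=1, seed=11)
        c1 = ss.run_chain(tiny_sim.records, structure, tiny_sim.design.pedigree, config=cfg)
        c2 = ss.run_chain(tiny_sim.records, structure, tiny_sim.design.pedigree, config=cfg)
        assert np.array_equal(c1.lambda_samples, c2.lambda_samples)
        assert np.array_equal(c1.G_samples, c2.G_samples)

    def test_recovers_generating_coefficient(self, m2_chain, m2_truth):
        lam = m2_chain.lambda_samples[:, 0]
        truth = m2_truth.Lambda[3, 2]
        assert abs(lam.mean() - truth) < 4 * lam.std()

    def test_acceptance_rates_in_open_interval(self, m2_chain):
        for rate in m2_chain.acceptance.values():
            assert 0.0 < rate < 1.0

    def test_chain_save_load_round_trip(self, tmp_path, m2_chain):
        m2_chain.save(tmp_path / "chain")
        again = ss.PosteriorChain.load(tmp_path / "chain")
        assert again.structure.edges == m2_chain.structure.edges
        assert np.allclose(again.lambda_samples, m2_chain.lambda_samples)
        assert np.allclose(again.G_samples, m2_chain.G_samples)
        assert np.allclose(again.b_samples, m2_chain.b_samples)

    def test_missing_trait_column_rejected(self, tiny_sim):
        bad = tiny_sim.records.drop(columns=["RCT"])
        with pytest.raises(InputError, match="trait"):
            prepare_data(bad, preset_structure("M2"), tiny_sim.design.pedigree)

    def test_sire_component_requires_pedigree(self, tiny_sim):
        with pytest.raises(InputError, match="pedigree"):
            prepare_data(tiny_sim.records, preset_structure("M2"), None)
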