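import numpy as np
import pytest

from nichepart.core.types import IsotopeSample, ValidationError
from nichepart.mixing import (
    TEF,
    MixingPosterior,
    SourceDistribution,
    fit_mixing_model,
    mixture_moments,
    select_sources,
    summarize_posterior,
)


def src(name, mu, omega=(0.5, 0.5), q=(0.45, 0.10)):
    return SourceDistribution(name=name, mu=mu, omega=omega, q=q)


WELL_SEPARATED = [
    src("a", (-32.0, 3.0)),
    src("b", (-24.0, 8.0)),
    src("c", (-28.0, 12.0)),
]


class TestMixtureMoments:
    def test_tef_defaults_match_configuration(self):
        tef = TEF()
        assert tef.d15N_mean == 3.23 and tef.d15N_sd == 0.79
        assert tef.d13C_mean == 1.03 and tef.d13C_sd == 0.29

    def test_equal_concentrations_reduce_to_plain_mixture(self):
        # with all q equal, m_j(p) must equal sum p_k (mu_jk + lambda_j)
        tef = TEF()
        sources = [src("a", (-32.0, 3.0), q=(0.4, 0.1)), src("b", (-24.0, 8.0), q=(0.4, 0.1))]
        p = np.array([0.3, 0.7])
        m, _ = mixture_moments(p, sources, tef)
        plain = p @ (np.array([s.mu for s in sources]) + tef.mean)
        assert m == pytest.approx(plain, abs=1e-12)

    def test_concentration_weighting_hand_example(self):
        # q_C = (0.5, 0.1), p = (0.5, 0.5): carbon weight of source 1 is 5/6
        tef = TEF(d13C_mean=0.0, d13C_sd=0.0, d15N_mean=0.0, d15N_sd=0.0)
        sources = [src("a", (-30.0, 5.0), omega=(0, 0), q=(0.5, 0.1)),
                   src("b", (-20.0, 5.0), omega=(0, 0), q=(0.1, 0.1))]
        m, _ = mixture_moments(np.array([0.5, 0.5]), sources, tef)
        expected_c = (5 / 6) * -30.0 + (1 / 6) * -20.0
        assert m[0] == pytest.approx(expected_c, abs=1e-12)

    def test_degenerate_single_source_mean_plus_tef(self):
        m, s2 = mixture_moments(np.array([1.0, 0.0]), WELL_SEPARATED[:2], TEF())
        assert m[0] == pytest.approx(-32.0 + 1.03)
        assert m[1] == pytest.approx(3.0 + 3.23)


class TestFitMixingModel:
    def test_point_identification(self):
        tef = TEF(d13C_sd=0.01, d15N_sd=0.01, d13C_mean=1.03, d15N_mean=3.23)
        sources = [src(n, mu, omega=(0.01, 0.01)) for n, mu in
                   [("a", (-32.0, 3.0)), ("b", (-24.0, 8.0)), ("c", (-28.0, 12.0))]]
        m, _ = mixture_moments(np.array([1.0, 0.0, 0.0]), sources, tef)
        x = np.tile(m, (20, 1)) + np.random.default_rng(0).normal(0, 0.01, size=(20, 2))
        post = fit_mixing_model(x[:, 0], x[:, 1], sources, tef,
                                chains=2, iterations=3000, burn_in=1000, seed=1)
        assert post.mean()[0] > 0.95

    def test_identical_sources_recover_prior(self):
        tef = TEF()
        sources = [src("a", (-28.0, 6.0)), src("b", (-28.0, 6.0))]
        rng = np.random.default_rng(3)
        x = rng.normal([-28.0 + 1.03, 6.0 + 3.23], 0.8, size=(25, 2))
        post = fit_mixing_model(x[:, 0], x[:, 1], sources, tef,
                                chains=2, iterations=4000, burn_in=1500, seed=2)
        assert 0.45 <= post.mean()[0] <= 0.55

    def test_draws_on_simplex(self):
        rng = np.random.default_rng(0)
        x = rng.normal([-28, 8], 1.0, size=(10, 2))
        post = fit_mixing_model(x[:, 0], x[:, 1], WELL_SEPARATED, TEF(),
                                chains=2, iterations=1500, burn_in=500, seed=0)
        assert (post.draws >= 0).all()
        assert np.allclose(post.draws.sum(axis=1), 1.0, atol=1e-9)
        assert post.mean().sum() == pytest.approx(1.0)

    def test_exact_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        x = rng.normal([-28, 8], 1.0, size=(10, 2))
        kwargs = dict(chains=2, iterations=1200, burn_in=400, seed=11)
        p1 = fit_mixing_model(x[:, 0], x[:, 1], WELL_SEPARATED, TEF(), **kwargs)
        p2 = fit_mixing_model(x[:, 0], x[:, 1], WELL_SEPARATED, TEF(), **kwargs)
        assert np.array_equal(p1.draws, p2.draws)
        assert np.array_equal(p1.sigma_draws, p2.sigma_draws)

    def test_diagnostics_present(self):
        rng = np.random.default_rng(0)
        x = rng.normal([-28, 8], 1.0, size=(10, 2))
        post = fit_mixing_model(x[:, 0], x[:, 1], WELL_SEPARATED, TEF(),
                                chains=3, iterations=1500, burn_in=500, seed=0)
        assert post.rhat.shape == (3,)
        assert post.ess.shape == (3,)
        assert np.isfinite(post.rhat).all()

    def test_too_few_sources_rejected(self):
        with pytest.raises(ValidationError, match="2-5 sources"):
            fit_mixing_model([-28.0], [8.0], WELL_SEPARATED[:1], TEF())

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError, match="2 chains"):
            fit_mixing_model([-28.0], [8.0], WELL_SEPARATED, TEF(), chains=1)

    def test_no_consumers_rejected(self):
        with pytest.raises(ValidationError, match="consumer"):
            fit_mixing_model([], [], WELL_SEPARATED, TEF())


class TestSelectSources:
    def samples(self):
        out = []

        def grp(name, n, mu):
            rng = np.random.default_rng(abs(hash(name)) % 2**31)
            for i in range(n):
                out.append(IsotopeSample(f"{name}{i}", name,
                                         d13C=mu[0] + 0.1 * i, d15N=mu[1] + 0.1 * i,
                                         pct_C=45.0, pct_N=10.0))

        grp("zooplankton", 6, (-32, 3))
        grp("littoral_invertebrates", 6, (-24, 1.5))
        grp("profundal_invertebrates", 6, (-28.5, 5))
        grp("benthic_invertebrates", 12, (-25.5, 2.5))
        grp("whitefish_prey", 5, (-29, 7.5))
        grp("charr_prey", 5, (-29.5, 7.2))
        grp("juvenile_trout", 5, (-28.5, 7.8))
        return out

    SETS = {
        "trout": ["fish", "benthic_invertebrates", "zooplankton"],
        "charr": ["profundal_invertebrates", "littoral_invertebrates", "zooplankton"],
        "whitefish": ["profundal_invertebrates", "littoral_invertebrates", "zooplankton"],
    }
    POOLS = {"fish": ["whitefish_prey", "charr_prey", "juvenile_trout"]}

    def test_trout_gets_pooled_fish_source(self):
        sources = select_sources("trout", self.samples(), self.SETS, self.POOLS)
        names = [s.name for s in sources]
        assert names == ["fish", "benthic_invertebrates", "zooplankton"]
        fish = sources[0]
        assert fish.n_samples == 15  # 5 + 5 + 5 pooled

    def test_charr_source_set(self):
        sources = select_sources("charr", self.samples(), self.SETS, self.POOLS)
        assert [s.name for s in sources] == [
            "profundal_invertebrates", "littoral_invertebrates", "zooplankton"]
        assert all(s.n_samples == 6 for s in sources)

    def test_unmapped_species_errors(self):
        with pytest.raises(ValidationError, match="no source set"):
            select_sources("pike", self.samples(), self.SETS, self.POOLS)

    def test_absent_group_errors(self):
        with pytest.raises(ValidationError, match="absent"):
            select_sources("charr", [], self.SETS, self.POOLS)


class TestSummarizePosterior:
    def make_posterior(self, draws):
        draws = np.asarray(draws, float)
        return MixingPosterior(source_names=("a", "b", "c"), draws=draws,
                               sigma_draws=np.zeros((len(draws), 2)), n_chains=2,
                               rhat=np.ones(3), ess=np.full(3, float(len(draws))))

    def test_constant_draws(self):
        post = self.make_posterior(np.tile([0.5, 0.3, 0.2], (50, 1)))
        s = summarize_posterior(post).set_index("source")
        for name, v in zip("abc", (0.5, 0.3, 0.2)):
            assert s.loc[name, "mean"] == pytest.approx(v)
            assert s.loc[name, "p5"] == pytest.approx(v)
            assert s.loc[name, "p95"] == pytest.approx(v)
            assert s.loc[name, "mode"] == pytest.approx(v)

    def test_two_draw_means(self):
        post = self.make_posterior([[1, 0, 0], [0, 1, 0]])
        s = summarize_posterior(post).set_index("source")
        assert s.loc["a", "mean"] == pytest.approx(0.5)
        assert s.loc["b", "mean"] == pytest.approx(0.5)
        assert s.loc["c", "mean"] == pytest.approx(0.0)

    def test_percentile_ordering(self, rng):
        draws = rng.dirichlet(np.ones(3), size=200)
        s = summarize_posterior(self.make_posterior(draws))
        assert (s["p5"] <= s["p95"]).all()
        assert (s["lo95"] <= s["hi95"]).all()

    def test_empty_draws_rejected(self):
        post = self.make_posterior(np.zeros((0, 3)))
        with pytest.raises(ValidationError, match="empty"):
            summarize_posterior(post)
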