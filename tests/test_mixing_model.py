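"""Likelihood, sampler, diagnostics, and geometry of the mixing model."""

import math

import numpy as np
import pytest
from scipy import stats

from nichemix.isotope_core import IsotopePair, SourceDistribution
from nichemix.mixing_model import (
    Chain,
    ChainConfig,
    DiscriminationFactor,
    MixingProblem,
    PosteriorDraw,
    adjust_sources,
    effective_sample_size,
    gelman_rubin,
    geometric_point_estimate,
    log_posterior,
    sample_posterior,
    split_rhat,
    summarize_posterior,
)
from nichemix.synthetic_data import GroupSpec, ScenarioSpec, gen_consumers

FAST = ChainConfig(chains=3, burn_in=1500, iterations=6000, thin=3, seed=7)


def _problem(consumers, sources, **kw):
    return MixingProblem(np.asarray(consumers, dtype=float), sources, **kw)


class TestAdjustSources:
    def test_zero_tdf_is_identity(self, fall_sources_red):
        mu, var = adjust_sources(fall_sources_red, DiscriminationFactor((0.0, 0.0)))
        np.testing.assert_allclose(mu[0], fall_sources_red[0].mean_array)
        np.testing.assert_allclose(var[0], fall_sources_red[0].sd_array ** 2)

    def test_red_seeds_shift(self, source_table):
        mu, _ = adjust_sources([source_table["red_seeds"]], DiscriminationFactor())
        np.testing.assert_allclose(mu[0], [-21.37 + 3.4, 0.55 + 2.4])

    def test_tdf_sd_adds_variance_not_sd(self, source_table):
        src = source_table["red_seeds"]
        _, var0 = adjust_sources([src], DiscriminationFactor(sd=(0.0, 0.0)))
        _, var1 = adjust_sources([src], DiscriminationFactor(sd=(1.0, 1.0)))
        np.testing.assert_allclose(var1[0], var0[0] + 1.0)


def _logpost_oracle(p, sigma, consumers, sources, tdf, alpha, sd_max):
    """Direct transcription of the marginalised SIMM density with scipy."""
    mu = np.array([s.mean_array for s in sources]) + np.asarray(tdf.delta)
    var = np.array([s.sd_array**2 for s in sources]) + np.asarray(tdf.sd) ** 2
    lp = stats.dirichlet.logpdf(np.asarray(p), np.asarray(alpha))
    lp += -2.0 * math.log(sd_max)  # flat priors on both residual SDs
    for x in consumers:
        for j in range(2):
            m = float(np.dot(p, mu[:, j]))
            v = float(np.dot(np.square(p), var[:, j]) + sigma[j] ** 2)
            lp += stats.norm.logpdf(x[j], m, math.sqrt(v))
    return lp


class TestLogPosterior:
    def test_single_source_density_peaks_at_adjusted_mean(self, source_table):
        src = source_table["red_seeds"]
        mu, _ = adjust_sources([src], DiscriminationFactor())
        at_mean = _problem([mu[0]], [src])
        off_mean = _problem([mu[0] + 2.0], [src])
        draw = PosteriorDraw(np.array([1.0]), np.array([0.5, 0.5]))
        assert log_posterior(draw, at_mean) > log_posterior(draw, off_mean)

    def test_permutation_symmetry_for_identical_sources(self):
        s1 = SourceDistribution("a", IsotopePair(-20.0, 3.0), (1.0, 1.0), 5)
        s2 = SourceDistribution("b", IsotopePair(-20.0, 3.0), (1.0, 1.0), 5)
        prob = _problem([[-18.0, 5.0]], [s1, s2])
        d1 = PosteriorDraw(np.array([0.2, 0.8]), np.array([1.0, 1.0]))
        d2 = PosteriorDraw(np.array([0.8, 0.2]), np.array([1.0, 1.0]))
        assert log_posterior(d1, prob) == pytest.approx(log_posterior(d2, prob))

    def test_matches_independent_transcription(self, fall_sources_red, rng):
        consumers = rng.normal([-19.0, 4.0], 1.0, size=(4, 2))
        prob = _problem(consumers, fall_sources_red)
        for _ in range(5):
            p = rng.dirichlet([1.0, 1.0, 1.0])
            sigma = rng.uniform(0.1, 3.0, 2)
            ours = log_posterior(PosteriorDraw(p, sigma), prob)
            oracle = _logpost_oracle(p, sigma, consumers, fall_sources_red,
                                     prob.tdf, prob.prior_alpha, prob.residual_sd_max)
            assert ours == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize(
        "p,sigma",
        [
            ([0.7, 0.2, 0.2], [1.0, 1.0]),  # sums to 1.1
            ([0.5, 0.6, -0.1], [1.0, 1.0]),  # negative component
            ([0.5, 0.3, 0.2], [0.0, 1.0]),  # sigma at boundary
            ([0.5, 0.3, 0.2], [25.0, 1.0]),  # sigma above max
        ],
    )
    def test_out_of_support_is_minus_inf(self, fall_sources_red, p, sigma):
        prob = _problem([[-19.0, 4.0]], fall_sources_red)
        draw = PosteriorDraw(np.array(p, dtype=float), np.array(sigma, dtype=float))
        assert log_posterior(draw, prob) == -math.inf


class TestSampler:
    def test_single_source_gives_unit_proportion(self, source_table):
        prob = _problem([[-18.0, 3.0]], [source_table["red_seeds"]])
        chains = sample_posterior(prob, FAST)
        for c in chains:
            np.testing.assert_array_equal(c.p, 1.0)

    def test_every_draw_on_simplex_within_1e12(self, fall_sources_red, rng):
        consumers = rng.normal([-19.0, 4.0], 0.8, size=(10, 2))
        prob = _problem(consumers, fall_sources_red)
        chains = sample_posterior(prob, FAST)
        for c in chains:
            assert np.all(np.abs(c.p.sum(axis=1) - 1.0) < 1e-12)
            assert np.all(c.p >= 0)
            assert np.all((c.sigma_res > 0) & (c.sigma_res < prob.residual_sd_max))

    def test_reproducible_given_seed(self, fall_sources_red):
        prob = _problem([[-19.0, 4.0], [-18.5, 3.5]], fall_sources_red)
        a = sample_posterior(prob, FAST)
        b = sample_posterior(prob, FAST)
        np.testing.assert_array_equal(a[0].p, b[0].p)
        np.testing.assert_array_equal(a[2].sigma_res, b[2].sigma_res)

    def test_prior_recovery_with_likelihood_off(self, fall_sources_red):
        alpha = np.array([1.0, 2.0, 3.0])
        prob = _problem([[-19.0, 4.0]], fall_sources_red, prior_alpha=alpha)
        chains = sample_posterior(prob, FAST, prior_only=True)
        pooled = np.concatenate([c.p for c in chains])
        np.testing.assert_allclose(pooled.mean(axis=0), alpha / alpha.sum(), atol=0.03)

    def test_parameter_recovery_short_chain(self, separated_sources):
        spec = ScenarioSpec(
            source_items=[(s.name, s.n, s.mean.d13c, s.sd[0], s.mean.d15n, s.sd[1])
                          for s in separated_sources],
            groups=[GroupSpec("G", ["A", "B", "C"], [0.6, 0.3, 0.1], 100)],
            residual_sd=(0.3, 0.3),
        )
        cons = gen_consumers(spec, spec.groups[0], seed=11)
        prob = _problem(cons[["d13c", "d15n"]].to_numpy(), separated_sources)
        est = summarize_posterior(sample_posterior(prob, FAST), prob)
        np.testing.assert_allclose(est.mean, [0.6, 0.3, 0.1], atol=0.05)

    def test_label_permutation_equivariance(self, separated_sources, rng):
        consumers = rng.normal([-20.0, 4.0], 0.5, size=(30, 2))
        prob = _problem(consumers, separated_sources)
        perm = [1, 0, 2]
        prob_perm = _problem(consumers, [separated_sources[i] for i in perm])
        m1 = summarize_posterior(sample_posterior(prob, FAST), prob).mean
        m2 = summarize_posterior(sample_posterior(prob_perm, FAST), prob_perm).mean
        np.testing.assert_allclose(m1[perm], m2, atol=0.02)

    def test_cri_narrows_with_sample_size(self, separated_sources):
        widths = []
        for n in (10, 100, 1000):
            spec = ScenarioSpec(
                source_items=[(s.name, s.n, s.mean.d13c, s.sd[0], s.mean.d15n, s.sd[1])
                              for s in separated_sources],
                groups=[GroupSpec("G", ["A", "B", "C"], [0.6, 0.3, 0.1], n)],
                residual_sd=(0.3, 0.3),
            )
            w = []
            for seed in (3, 4):
                cons = gen_consumers(spec, spec.groups[0], seed=seed)
                prob = _problem(cons[["d13c", "d15n"]].to_numpy(), separated_sources)
                est = summarize_posterior(sample_posterior(prob, FAST), prob)
                w.append(float(np.mean(est.hi95 - est.lo95)))
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]


def _rhat_oracle(x):
    """Textbook split-R-hat, loop-coded independently."""
    m, n = x.shape
    n -= n % 2
    halves = []
    for c in range(m):
        halves.append(x[c, : n // 2])
        halves.append(x[c, n // 2 : n])
    halves = np.array(halves)
    mm, nn = halves.shape
    means = halves.mean(axis=1)
    W = sum(np.var(h, ddof=1) for h in halves) / mm
    B = nn / (mm - 1) * sum((mu - means.mean()) ** 2 for mu in means)
    return math.sqrt(((nn - 1) / nn * W + B / nn) / W)


class TestDiagnostics:
    def test_stationary_chains_near_one(self, rng):
        x = rng.normal(size=(3, 400))
        assert split_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_constant_chains_diverge(self):
        x = np.vstack([np.zeros(100) + 1e-9 * np.arange(100), np.ones(100)])
        assert split_rhat(x) > 1.1

    def test_matches_textbook_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(4, 200)) + rng.normal(size=(4, 1))
            assert split_rhat(x) == pytest.approx(_rhat_oracle(x), abs=1e-8)

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.normal(size=(4, 500))
        ours = split_rhat(x)
        theirs = float(az.rhat(az.convert_to_dataset(x), method="split")["x"].values)
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_unequal_chain_lengths_rejected(self):
        chains = [
            Chain(np.ones((100, 2)) / 2, np.ones((100, 2)), 0.3, 1.0),
            Chain(np.ones((80, 2)) / 2, np.ones((80, 2)), 0.3, 1.0),
        ]
        with pytest.raises(ValueError, match="unequal"):
            gelman_rubin(chains)

    def test_ess_iid_draws_near_total(self, rng):
        x = rng.normal(size=(4, 1000))
        ess = effective_sample_size(x)
        assert 2500 < ess <= 4100

    def test_ess_autocorrelated_much_smaller(self, rng):
        n = 2000
        e = rng.normal(size=(2, n))
        x = np.zeros((2, n))
        for t in range(1, n):
            x[:, t] = 0.95 * x[:, t - 1] + e[:, t]
        assert effective_sample_size(x) < 2 * n / 10


class TestSummaries:
    def test_degenerate_draws_give_point_summary(self, fall_sources_red):
        p = np.tile([0.5, 0.3, 0.2], (600, 1))
        sig = np.ones((600, 2))
        chains = [Chain(p.copy(), sig.copy(), 0.3, 1.0) for _ in range(2)]
        prob = _problem([[-19.0, 4.0]], fall_sources_red)
        est = summarize_posterior(chains, prob)
        np.testing.assert_allclose(est.mean, [0.5, 0.3, 0.2])
        np.testing.assert_allclose(est.hi95 - est.lo95, 0.0, atol=1e-12)

    def test_symmetric_two_source_problem(self):
        a = SourceDistribution("a", IsotopePair(-22.0, 2.0), (1.0, 1.0), 5)
        b = SourceDistribution("b", IsotopePair(-16.0, 6.0), (1.0, 1.0), 5)
        # consumer at the unadjusted midpoint of the TDF-shifted sources
        mid = (np.array([-22.0, 2.0]) + np.array([-16.0, 6.0])) / 2 + np.array([3.4, 2.4])
        prob = _problem([mid], [a, b])
        est = summarize_posterior(sample_posterior(prob, FAST), prob)
        np.testing.assert_allclose(est.mean, [0.5, 0.5], atol=0.02)

    def test_posterior_means_sum_to_one(self, fall_sources_red, rng):
        consumers = rng.normal([-19.0, 4.0], 0.8, size=(20, 2))
        prob = _problem(consumers, fall_sources_red)
        est = summarize_posterior(sample_posterior(prob, FAST), prob)
        assert abs(est.mean.sum() - 1.0) < 1e-6
        assert np.all(est.lo95 - 1e-9 <= est.mean) and np.all(est.mean <= est.hi95 + 1e-9)

    def test_too_few_draws_rejected(self, fall_sources_red):
        chains = [Chain(np.ones((100, 3)) / 3, np.ones((100, 2)), 0.3, 1.0)] * 2
        prob = _problem([[-19.0, 4.0]], fall_sources_red)
        with pytest.raises(ValueError, match="1000"):
            summarize_posterior(chains, prob)


class TestGeometry:
    def test_consumer_at_vertex_gives_indicator(self, fall_sources_red):
        mu, _ = adjust_sources(fall_sources_red, DiscriminationFactor())
        prob = _problem([mu[1]], fall_sources_red)  # at the truffle vertex
        p, feasible = geometric_point_estimate(prob)
        assert feasible
        np.testing.assert_allclose(p, [0.0, 1.0, 0.0], atol=1e-9)

    def test_mgrs_fall_solution_matches_linear_oracle(self, fall_sources_red):
        prob = _problem([[-18.93, 3.90]], fall_sources_red)
        p, feasible = geometric_point_estimate(prob)
        assert feasible
        # independent 3x3 solve
        mu, _ = adjust_sources(fall_sources_red, DiscriminationFactor())
        A = np.vstack([mu.T, np.ones(3)])
        expected = np.linalg.solve(A, np.array([-18.93, 3.90, 1.0]))
        np.testing.assert_allclose(p, expected, atol=1e-12)
        np.testing.assert_allclose(p, [0.70, 0.20, 0.10], atol=0.02)

    def test_sf_aberts_is_infeasible(self, source_table, fall_sources_red):
        sources = [source_table["aberts_seeds"], fall_sources_red[1], fall_sources_red[2]]
        prob = _problem([[-19.80, 7.41]], sources)
        p, feasible = geometric_point_estimate(prob)
        assert not feasible
        assert p[2] < 0  # the grouped fungi/phloem component goes negative

    def test_collinear_sources_raise(self):
        srcs = [
            SourceDistribution("a", IsotopePair(-20.0, 0.0), (1.0, 1.0), 5),
            SourceDistribution("b", IsotopePair(-22.0, 2.0), (1.0, 1.0), 5),
            SourceDistribution("c", IsotopePair(-24.0, 4.0), (1.0, 1.0), 5),
        ]
        prob = _problem([[-21.0, 1.0]], srcs)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            geometric_point_estimate(prob)

    def test_more_than_three_sources_rejected(self, source_table):
        srcs = [source_table[k] for k in ("red_seeds", "truffles", "mushrooms", "phloem")]
        with pytest.raises(ValueError, match="K <= 3"):
            geometric_point_estimate(_problem([[-19.0, 4.0]], srcs))
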