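import math
from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from coastmix import (ConsumerRecord, MCMCConfig, PosteriorResult,
                      SourceDistribution, TEFScenario, aggregate, fit_consumer,
                      identifiability_check, log_likelihood, mixture_moments,
                      sources_from_summaries)
from coastmix.group_stats import GroupSummary
from coastmix.simm import NAMED_SCENARIOS


def _scenario(e13=3.0, s13=0.0, e15=3.0, s15=0.0):
    """Zero-SD enrichment stand-in for deterministic moment oracles."""
    return SimpleNamespace(name="toy", eps13C_mean=e13, eps13C_sd=s13,
                           eps15N_mean=e15, eps15N_sd=s15)


def _two_sources(conc=(50.0, 50.0), sds=(0.0, 0.0)):
    return [
        SourceDistribution("terrestrial_plant", -26.0, sds[0], 5.0, sds[0],
                           conc[0], conc[0]),
        SourceDistribution("marine_vertebrate", -12.0, sds[1], 16.0, sds[1],
                           conc[1], conc[1]),
    ]


def test_named_scenarios_fix_means_and_sds():
    means = {"low_C_low_N": (3, 3), "low_C_high_N": (3, 6),
             "high_C_low_N": (5, 3), "high_C_high_N": (5, 6)}
    for name, (e13, e15) in means.items():
        sc = NAMED_SCENARIOS[name]
        assert (sc.eps13C_mean, sc.eps15N_mean) == (e13, e15)
        assert sc.eps13C_sd == sc.eps15N_sd == 0.5


def test_tef_scenario_requires_positive_sd():
    with pytest.raises(ValueError):
        TEFScenario("bad", 3.0, 0.0, 3.0, 0.5)


# --- mixture moments -------------------------------------------------------

def test_equal_concentration_midpoint():
    mu, var = mixture_moments([0.5, 0.5], _two_sources(), _scenario(), "C")
    assert mu == pytest.approx(-16.0)  # midpoint of (-23, -9)
    assert var == 0.0


def test_concentration_weighting_hand_arithmetic():
    mu, var = mixture_moments([0.5, 0.5], _two_sources(conc=(50.0, 25.0)),
                              _scenario(), "C")
    # weights (2/3, 1/3): (2/3)(-23) + (1/3)(-9)
    assert mu == pytest.approx((2 / 3) * -23 + (1 / 3) * -9)


def test_pure_source_moments():
    src = _two_sources(sds=(1.5, 2.0))
    sc = _scenario(e13=3.0, s13=0.5)
    mu, var = mixture_moments([0.0, 1.0], src, sc, "C")
    assert mu == pytest.approx(-12.0 + 3.0)
    assert var == pytest.approx(2.0 ** 2 + 0.5 ** 2)


def test_mixture_moments_rejects_off_simplex():
    with pytest.raises(ValueError):
        mixture_moments([0.7, 0.7], _two_sources(), _scenario(), "C")


# --- likelihood ------------------------------------------------------------

def test_loglik_at_mode_unit_variance():
    src = [replace(s, sd13C=math.sqrt(1 - 0.5 ** 2), sd15N=math.sqrt(1 - 0.5 ** 2))
           for s in _two_sources()]
    sc = _scenario(s13=0.5, s15=0.5)  # total variance 1 per element for pure source
    mu_C, _ = mixture_moments([1.0, 0.0], src, sc, "C")
    mu_N, _ = mixture_moments([1.0, 0.0], src, sc, "N")
    consumer = ConsumerRecord("c", "unknown", mu_C, mu_N)
    ll = log_likelihood(consumer, [1.0, 0.0], src, sc)
    assert ll == pytest.approx(2 * math.log(1 / math.sqrt(2 * math.pi)))


def test_loglik_decreases_when_sd_doubles():
    src = _two_sources(sds=(1.0, 1.0))
    sc = _scenario(s13=0.5, s15=0.5)
    mu_C, _ = mixture_moments([0.5, 0.5], src, sc, "C")
    mu_N, _ = mixture_moments([0.5, 0.5], src, sc, "N")
    consumer = ConsumerRecord("c", "unknown", mu_C, mu_N)
    wide = _two_sources(sds=(2.0, 2.0))
    assert log_likelihood(consumer, [0.5, 0.5], src, sc) > \
        log_likelihood(consumer, [0.5, 0.5], wide, sc)


def test_loglik_zero_variance_off_mean_is_minus_inf():
    src = _two_sources()
    consumer = ConsumerRecord("c", "unknown", -100.0, 0.0)
    assert log_likelihood(consumer, [0.5, 0.5], src, _scenario()) == -math.inf


def test_loglik_matches_quadrature_oracle(four_sources, tef):
    # direct normal-density arithmetic, independent of the packed fast path
    consumer = ConsumerRecord("c", "unknown", -15.0, 13.0)
    p = np.array([0.1, 0.2, 0.3, 0.4])
    expected = 0.0
    for element, delta in (("C", -15.0), ("N", 13.0)):
        mu, var = mixture_moments(p, four_sources, tef, element)
        expected += -0.5 * (math.log(2 * math.pi * var) + (delta - mu) ** 2 / var)
    assert log_likelihood(consumer, p, four_sources, tef) == pytest.approx(expected)


# --- fitting ---------------------------------------------------------------

FAST = MCMCConfig(chain_length=4000, burn_in=2000, thin=2, n_chains=2, seed=9)


def test_every_retained_draw_on_simplex(four_sources, tef):
    consumer = ConsumerRecord("c", "unknown", -14.0, 15.0)
    res = fit_consumer(consumer, four_sources, tef, mcmc=FAST)
    draws = res.draws
    assert np.allclose(draws.sum(axis=1), 1.0, atol=1e-9)
    assert (draws >= 0).all() and (draws <= 1).all()


def test_dominant_source_recovered(four_sources, tef):
    tight = [replace(s, sd13C=0.3, sd15N=0.3) for s in four_sources]
    mv = tight[3]
    consumer = ConsumerRecord("c", "unknown",
                              mv.mu13C + tef.eps13C_mean, mv.mu15N + tef.eps15N_mean)
    res = fit_consumer(consumer, tight, tef,
                       mcmc=MCMCConfig(8000, 4000, 2, 2, seed=4))
    assert res.means["marine_vertebrate"] > 0.85


def test_prior_recovery_when_likelihood_flat(four_sources):
    # enormous enrichment SD swamps the data: posterior ~ Dirichlet(1,1,1,1)
    flat = TEFScenario("flat", 3.0, 1e6, 6.0, 1e6)
    consumer = ConsumerRecord("c", "unknown", -15.0, 13.0)
    res = fit_consumer(consumer, four_sources, flat,
                       mcmc=MCMCConfig(12000, 4000, 4, 2, seed=2))
    for name, m in res.means.items():
        assert m == pytest.approx(0.25, abs=0.03)


def test_identical_sources_flagged_nonidentifiable(four_sources, tef):
    twins = list(four_sources)
    twins[2] = replace(twins[3], group="marine_invertebrate")
    consumer = ConsumerRecord("c", "unknown", -11.0, 20.0)
    res = fit_consumer(consumer, twins, tef, mcmc=FAST)
    flagged = identifiability_check(res)
    assert ("marine_invertebrate", "marine_vertebrate") in \
        [(a, b) for a, b, _ in flagged]


def test_marine_mean_monotone_in_consumer_d13C(four_sources, tef):
    means = []
    for i, d13 in enumerate([-20.0, -16.0, -12.0]):
        consumer = ConsumerRecord("c", "unknown", d13, 13.0)
        res = fit_consumer(consumer, four_sources, tef,
                           mcmc=MCMCConfig(6000, 3000, 3, 2, seed=5 + i))
        means.append(aggregate(res)["marine"]["mean"])
    assert means[0] < means[1] < means[2]


def test_fit_rejects_impossible_consumer():
    src = _two_sources()  # zero variance everywhere
    consumer = ConsumerRecord("c", "unknown", 0.0, 0.0)  # far outside support
    with pytest.raises(ValueError):
        fit_consumer(consumer, src, _scenario(), mcmc=FAST)


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(burn_in=10_000, chain_length=10_000)
    with pytest.raises(ValueError):
        MCMCConfig(n_chains=1)
    with pytest.raises(ValueError):
        MCMCConfig(thin=0)


def test_same_seed_reproduces_draws(four_sources, tef):
    consumer = ConsumerRecord("c", "unknown", -14.0, 15.0)
    a = fit_consumer(consumer, four_sources, tef, mcmc=FAST)
    b = fit_consumer(consumer, four_sources, tef, mcmc=FAST)
    assert np.array_equal(a.draws_by_chain, b.draws_by_chain)


# --- identifiability & aggregation on constructed draws --------------------

def _result_from_draws(draws):
    draws = np.asarray(draws, float)
    return PosteriorResult("c", "s",
                           ("terrestrial_plant", "terrestrial_vertebrate",
                            "marine_invertebrate", "marine_vertebrate"),
                           draws[None, :, :])


def test_anticorrelated_pair_flagged(rng):
    u = rng.uniform(0.1, 0.4, 500)
    draws = np.column_stack([np.full(500, 0.25), 0.25 + (0.25 - u), u,
                             np.full(500, 0.25)])
    draws /= draws.sum(axis=1, keepdims=True)
    flagged = identifiability_check(_result_from_draws(draws))
    assert any({a, b} == {"terrestrial_vertebrate", "marine_invertebrate"}
               for a, b, _ in flagged)


def test_independent_draws_not_flagged(rng):
    draws = rng.dirichlet([5, 5, 5, 5], 2000)
    assert identifiability_check(_result_from_draws(draws)) == []


def test_aggregate_constant_draws():
    draws = np.full((400, 4), 0.25)
    agg = aggregate(_result_from_draws(draws))
    assert agg["marine"]["ci95"] == (0.5, 0.5)
    assert agg["marine"]["mean"] + agg["terrestrial"]["mean"] == pytest.approx(1.0)


def test_aggregate_on_sums_not_sum_of_cis(rng):
    # anti-correlated marine components: aggregate interval collapses
    u = rng.uniform(0.05, 0.45, 1000)
    draws = np.column_stack([np.full(1000, 0.25), np.full(1000, 0.25),
                             u, 0.5 - u])
    agg = aggregate(_result_from_draws(draws))
    lo, hi = agg["marine"]["ci95"]
    assert hi - lo < 1e-9  # the sum is constant even though components vary
    naive = (np.quantile(draws[:, 2], 0.975) - np.quantile(draws[:, 2], 0.025)
             + np.quantile(draws[:, 3], 0.975) - np.quantile(draws[:, 3], 0.025))
    assert naive > 0.1


def test_aggregate_requires_complete_grouping(four_sources, tef):
    consumer = ConsumerRecord("c", "unknown", -14.0, 15.0)
    res = fit_consumer(consumer, four_sources, tef, mcmc=FAST)
    with pytest.raises(ValueError):
        aggregate(res, {"terrestrial_plant": "terrestrial"})


def test_marine_terrestrial_sums_to_one(four_sources, tef):
    consumer = ConsumerRecord("c", "unknown", -14.0, 15.0)
    res = fit_consumer(consumer, four_sources, tef, mcmc=FAST)
    idx_m = [2, 3]
    idx_t = [0, 1]
    sums = res.draws[:, idx_m].sum(axis=1) + res.draws[:, idx_t].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_sources_from_summaries_proxy_substitution():
    summaries = {"terrestrial_plant": GroupSummary(
        "terrestrial_plant", 10, -25.0, 1.0, 5.0, 1.0, 42.0, float("nan"))}
    with pytest.raises(ValueError):
        sources_from_summaries(summaries)
    dists = sources_from_summaries(summaries,
                                   pct_N_proxies={"terrestrial_plant": 2.5})
    assert dists[0].conc_N == 2.5
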