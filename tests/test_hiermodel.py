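import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairflight.hiermodel import (
    McmcConfig,
    fit_coupling_model,
    fit_leadership_model,
    fit_pair_model,
    fit_spacing_model,
    pair_model_loglik,
    relative_effects,
    rhat,
    ess,
)
from pairflight.hiermodel.samplers import inv_logit
from pairflight.synthio import make_birds, simulate_flight_summaries, simulate_wingbeat_rows
from pairflight.synthio.config import PopulationConfig, TruthRecord

FAST = McmcConfig(chains=2, warmup=500, iters=500)
TINY = McmcConfig(chains=2, warmup=300, iters=300)


class TestRhat:
    def test_identical_white_noise_chains(self, rng):
        chains = rng.standard_normal((4, 2000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.05)

    def test_disjoint_means(self, rng):
        # closed form: B/W explodes when chain means are 0 vs 10
        chains = np.vstack(
            [rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)]
        )
        assert rhat(chains) > 3.0

    def test_converged_sampler_run(self):
        post_chains = np.random.default_rng(0).standard_normal((4, 4000))
        assert rhat(post_chains) <= 1.1

    def test_matches_arviz(self, rng):
        # independent oracle: arviz implements the same split-chain statistic
        az = pytest.importorskip("arviz")
        for _ in range(3):
            chains = rng.standard_normal((4, 500)) + rng.normal(0, 0.3, (4, 1))
            mine = rhat(chains)
            theirs = float(az.rhat(chains, method="split"))
            assert mine == pytest.approx(theirs, abs=0.01)

    def test_single_chain_error(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.standard_normal((1, 100)))

    def test_ess_white_noise(self, rng):
        chains = rng.standard_normal((2, 2000))
        assert ess(chains) > 1000


def _summaries(seed, n_birds=12, n_solo=8, n_pair=8, delta0=1.0, delta1=0.0, sd=0.2):
    birds = make_birds(n_birds, seed)
    truth = TruthRecord(delta0_hz=delta0, delta1_hz_per_mm=delta1, residual_sd_hz=sd)
    return simulate_flight_summaries(
        birds, truth, n_solo=n_solo, n_pair=n_pair, seed=seed + 1000
    )


class TestPairModel:
    def test_delta0_recovery(self):
        df = _summaries(seed=42, n_birds=20, n_solo=12, n_pair=12)
        post = fit_pair_model(df, cfg=FAST, seed=0)
        assert post.converged
        assert post.mean("delta0") == pytest.approx(1.0, abs=0.15)

    def test_no_pair_rows_prior_posterior(self):
        df = _summaries(seed=3)
        solo_only = df[df.is_pair == 0].reset_index(drop=True)
        post = fit_pair_model(solo_only, cfg=FAST, seed=1)
        assert "no_pair_rows" in post.flags
        prior_sd = post.diagnostics["prior_effect_scale"]
        assert abs(post.mean("delta0")) < prior_sd / 3.0
        assert post.sd("delta0") == pytest.approx(prior_sd, rel=0.2)

    def test_coverage_and_delta1_zero(self):
        # 20 replicates at reduced scale: the 95% interval for delta0 covers
        # the truth in >= 17, and for delta1 (true 0) covers 0 in >= 18
        hits_d0, hits_d1 = 0, 0
        for rep in range(20):
            df = _summaries(seed=100 + rep, n_birds=8, n_solo=4, n_pair=4)
            post = fit_pair_model(df, cfg=TINY, seed=rep)
            lo, hi = post.ci("delta0")
            hits_d0 += lo <= 1.0 <= hi
            lo, hi = post.ci("delta1")
            hits_d1 += lo <= 0.0 <= hi
        assert hits_d0 >= 17
        assert hits_d1 >= 18

    def test_posterior_contraction(self):
        sds_small, sds_large = [], []
        for rep in range(3):
            small = _summaries(seed=200 + rep, n_birds=8, n_solo=4, n_pair=4)
            large = _summaries(seed=200 + rep, n_birds=8, n_solo=8, n_pair=8)
            sds_small.append(fit_pair_model(small, cfg=TINY, seed=rep).sd("delta0"))
            sds_large.append(fit_pair_model(large, cfg=TINY, seed=rep).sd("delta0"))
        assert np.mean(sds_large) < np.mean(sds_small)

    def test_mixing_weight_bounds(self):
        df = _summaries(seed=5)
        post = fit_pair_model(df, cfg=TINY, seed=2)
        dt = df.loc[df.is_pair == 1, "tarsus_diff_mm"].median()
        omega = inv_logit(post.pooled("eta1") + post.pooled("eta_slope") * dt)
        assert np.all((omega > 0.0) & (omega < 1.0))

    def test_likelihood_reduction_solo_only(self):
        # with is_pair = 0 everywhere the model is exactly mu_i + gamma.X
        df = _summaries(seed=6)
        solo = df[df.is_pair == 0].reset_index(drop=True)
        mu = solo.groupby("bird_id").median_freq_hz.mean().to_dict()
        params = {
            "delta0": 0.7,  # must be irrelevant for solo rows
            "delta1": -0.2,
            "eta1": 0.3,
            "eta_slope": 0.1,
            "sigma": 0.25,
            "mu": mu,
        }
        got = pair_model_loglik(solo, params)
        expected = float(
            np.sum(
                stats.norm.logpdf(
                    solo.median_freq_hz,
                    loc=solo.bird_id.map(mu),
                    scale=0.25,
                )
            )
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_missing_response_error(self):
        df = _summaries(seed=7)
        with pytest.raises(ValueError):
            fit_pair_model(df, response="nope", cfg=TINY)


class TestSpacingModel:
    def test_recovery_reduced_scale(self):
        rows = simulate_wingbeat_rows(
            n_pair_flights=30, n_solo_flights=30, beats_per_flight=50, seed=9
        )
        post = fit_spacing_model(rows, cfg=FAST, seed=3)
        assert post.converged
        assert post.mean("delta_pair0") == pytest.approx(1.21, abs=0.15)
        assert post.mean("spacing_slope") == pytest.approx(-0.011, abs=0.003)

    def test_zero_slope_interval_contains_zero(self):
        rows = simulate_wingbeat_rows(
            n_pair_flights=20, n_solo_flights=20, beats_per_flight=30,
            spacing_slope_hz_per_m=0.0, seed=10,
        )
        post = fit_spacing_model(rows, cfg=FAST, seed=4)
        lo, hi = post.ci("spacing_slope")
        assert lo <= 0.0 <= hi

    def test_linear_predictor_at_50m(self):
        # prediction identity on the fitted linear model
        assert 1.21 + 50 * (-0.011) == pytest.approx(0.66)

    def test_missing_column_error(self):
        with pytest.raises(ValueError):
            fit_spacing_model(pd.DataFrame({"freq_hz": [1.0]}), cfg=TINY)


def _coupling_frame(rng, beta, n_pairs=8, flights=10, noise=0.1):
    rows = []
    for p in range(n_pairs):
        base = rng.normal(6.5, 0.3)
        for _ in range(flights):
            f = base + rng.normal(0, 0.3)
            rows.append(
                {
                    "pair_id": f"P{p}",
                    "front_value": f,
                    "behind_value": base * (1 - beta) + beta * f + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestCouplingModel:
    def test_direct_correlation_recovery(self, rng):
        df = _coupling_frame(rng, beta=1.0)
        post = fit_coupling_model(df, cfg=FAST, seed=5)
        assert 0.8 <= post.mean("beta") <= 1.2

    def test_independent_front_back(self, rng):
        df = _coupling_frame(rng, beta=0.0)
        post = fit_coupling_model(df, cfg=FAST, seed=6)
        lo, hi = post.ci("beta")
        assert lo <= 0.0 <= hi

    def test_negative_slope_recovery(self, rng):
        df = _coupling_frame(rng, beta=-0.24)
        post = fit_coupling_model(df, cfg=FAST, seed=7)
        assert post.mean("beta") == pytest.approx(-0.24, abs=0.3)

    def test_single_flight_pair_flagged(self, rng):
        df = _coupling_frame(rng, beta=1.0, flights=1)
        post = fit_coupling_model(df, cfg=TINY, seed=8)
        assert "slope_unidentifiable_pairs" in post.flags


class TestLeadershipModel:
    def test_null_predictor(self, rng):
        s = rng.normal(0, 1.5, 80)
        f = rng.integers(0, 2, 80).astype(float)
        post = fit_leadership_model(
            pd.DataFrame({"front": f, "tarsus_diff": s}), "tarsus_diff", cfg=FAST, seed=9
        )
        lo, hi = post.ci("beta")
        assert lo <= 0.0 <= hi

    def test_strong_effect_excludes_zero(self, rng):
        s = rng.normal(0, 2.0, 80)
        f = (s + rng.normal(0, 0.5, 80) > 0).astype(float)
        post = fit_leadership_model(
            pd.DataFrame({"front": f, "mass_diff": s}), "mass_diff", cfg=FAST, seed=10
        )
        lo, hi = post.ci("beta")
        assert lo > 0.0

    def test_balanced_coin_flip(self, rng):
        f = np.tile([0.0, 1.0], 40)
        s = rng.normal(0, 1.0, 80)
        post = fit_leadership_model(
            pd.DataFrame({"front": f, "x": s}), "x", cfg=FAST, seed=11
        )
        p_lead = float(np.mean(inv_logit(post.pooled("alpha"))))
        assert p_lead == pytest.approx(0.5, abs=0.1)

    def test_separation_flagged(self):
        s = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        f = (s > 0).astype(float)
        post = fit_leadership_model(
            pd.DataFrame({"front": f, "x": s}), "x", cfg=TINY, seed=12
        )
        assert "complete_separation" in post.flags


class TestRelativeEffects:
    def test_paper_percentages(self):
        assert relative_effects(1.00, 5.48) == pytest.approx(18.2, abs=0.05)
        assert relative_effects(-4.65, 20.68) == pytest.approx(-22.5, abs=0.02)

    def test_zero_effect(self):
        assert relative_effects(0.0, 5.48) == 0.0

    def test_zero_baseline_error(self):
        with pytest.raises(ValueError):
            relative_effects(1.0, 0.0)

    def test_posterior_table(self):
        df = _summaries(seed=13)
        post = fit_pair_model(df, cfg=TINY, seed=13)
        table = relative_effects(post, 5.48, params=("delta0",))
        row = table.iloc[0]
        assert row["pct_mean"] == pytest.approx(post.mean("delta0") / 5.48 * 100.0)
        assert row["pct_q2.5"] < row["pct_mean"] < row["pct_q97.5"]
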