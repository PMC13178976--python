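"""Posterior summaries, pooling, contrasts, and small-model fits."""

import numpy as np
import pandas as pd
import pytest

from teamdynam.covariates import build_dyad_design, dichotomize_ratings
from teamdynam.inference import (
    EffectSpec,
    PoolingError,
    contrast_contexts,
    evidence_grade,
    fit_model,
    pool_imputations,
    probability_of_direction,
    summarize_draws,
    summarize_effects,
)


@pytest.mark.parametrize(
    "draws,expected",
    [
        ([1.0, 2.0, 0.5], 1.0),          # unanimous positive
        ([-1.0, 1.0, 2.0, 3.0], 0.75),   # median 1.5, 3 of 4 positive
        ([-1.0, 1.0], 0.5),              # tied median -> 0.5 by convention
        ([-3.0, -1.0, -2.0, 4.0], 0.75),
    ],
)
def test_probability_of_direction(draws, expected):
    assert probability_of_direction(np.array(draws)) == expected


def test_pd_bounds_and_ci_implication():
    """pd in [0.5, 1]; CI excluding 0 implies pd >= 0.975 (up to 1/n)."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        d = rng.normal(rng.normal(), rng.uniform(0.1, 2.0), size=400)
        s = summarize_draws(d, "x")
        assert 0.5 <= s.pd <= 1.0
        if s.ci_low > 0 or s.ci_high < 0:
            assert s.pd >= 0.975 - 1.0 / d.size


def test_summarize_draws_quantiles():
    d = np.array([-1.0, 1.0, 2.0, 3.0])
    s = summarize_draws(d, "x")
    assert s.median == 1.5
    assert s.ci_low <= s.median <= s.ci_high
    assert s.pd == 0.75


@pytest.mark.parametrize(
    "lo,hi,pd_val,grade",
    [
        (0.1, 0.9, 0.99, "strong"),
        (-0.1, 0.9, 0.96, "moderate"),
        (-0.1, 0.9, 0.93, "weak"),
        (-0.5, 0.5, 0.6, "insufficient"),
    ],
)
def test_evidence_grades(lo, hi, pd_val, grade):
    assert evidence_grade(lo, hi, pd_val) == grade


def _fake_post(values_by_col, spec=None, contexts=("uni", "lab"), imputation=0):
    from teamdynam.inference import PosteriorDraws

    df = pd.DataFrame(values_by_col)
    return PosteriorDraws(
        draws=df,
        chain=np.zeros(len(df), dtype=int),
        imputation=np.full(len(df), imputation),
        spec=spec or EffectSpec(effects=("inertia", "woman_woman")),
        contexts=tuple(contexts),
        teams=("t1",),
    )


class TestPooling:
    def cols(self, scale=1.0):
        rng = np.random.default_rng(3)
        return {
            "beta[woman_woman,uni]": rng.normal(size=100) * scale,
            "beta[woman_woman,lab]": rng.normal(size=100),
            "gamma[inertia,uni]": rng.normal(size=100),
            "gamma[inertia,lab]": rng.normal(size=100),
            "log_sigma[inertia]": rng.normal(size=100),
            "sigma[inertia]": np.abs(rng.normal(size=100)),
            "alpha[inertia,t1]": rng.normal(size=100),
        }

    def test_single_run_is_identity(self):
        p = _fake_post(self.cols())
        assert pool_imputations([p]) is p

    def test_concatenation_and_sizes(self):
        runs = [_fake_post(self.cols(), imputation=m) for m in range(3)]
        pooled = pool_imputations(runs)
        assert pooled.n_draws == 300
        assert set(np.unique(pooled.imputation)) == {0, 1, 2}

    def test_pooled_median_matches_sort_oracle(self):
        runs = [_fake_post(self.cols(s)) for s in (0.5, 1.0, 2.0)]
        pooled = pool_imputations(runs)
        col = "beta[woman_woman,uni]"
        all_vals = np.concatenate([r.draws[col].to_numpy() for r in runs])
        sorted_vals = sorted(all_vals)  # independent sort-based median
        n = len(sorted_vals)
        oracle = 0.5 * (sorted_vals[n // 2 - 1] + sorted_vals[n // 2])
        assert np.median(pooled.draws[col]) == pytest.approx(oracle, abs=1e-15)

    def test_pooling_is_order_invariant(self):
        runs = [_fake_post(self.cols(s)) for s in (0.5, 1.0, 2.0)]
        s1 = summarize_effects(pool_imputations(runs))
        s2 = summarize_effects(pool_imputations(runs[::-1]))
        pd.testing.assert_frame_equal(
            s1.sort_values("parameter").reset_index(drop=True),
            s2.sort_values("parameter").reset_index(drop=True),
        )

    def test_spec_mismatch_rejected(self):
        a = _fake_post(self.cols())
        b = _fake_post(self.cols(), spec=EffectSpec(effects=("inertia", "man_man"),))
        with pytest.raises(PoolingError):
            pool_imputations([a, b])


class TestContrasts:
    def test_self_contrast_is_null(self):
        p = _fake_post(
            {
                "beta[woman_woman,uni]": np.array([0.1, 0.2, 0.3, 0.4]),
                "beta[woman_woman,lab]": np.array([0.0, 0.0, 0.0, 0.0]),
            }
        )
        s = contrast_contexts(p, "woman_woman", "uni", "uni")
        assert s.median == 0.0 and s.pd == 0.5

    def test_hand_computed_difference(self):
        p = _fake_post(
            {
                "beta[woman_woman,uni]": np.array([0.1, 0.2]),
                "beta[woman_woman,lab]": np.array([0.5, 0.7]),
            }
        )
        s = contrast_contexts(p, "woman_woman", "lab", "uni")
        assert s.median == pytest.approx(0.45)  # draws {0.4, 0.5}

    def test_unknown_context_rejected(self):
        p = _fake_post({"beta[woman_woman,uni]": np.zeros(4),
                        "beta[woman_woman,lab]": np.zeros(4)})
        with pytest.raises(KeyError):
            contrast_contexts(p, "woman_woman", "uni", "bus")

    def test_independent_symmetric_blocks_median(self):
        """For independent symmetric posteriors of equal shape the contrast
        median equals the difference of the context medians (Monte Carlo)."""
        rng = np.random.default_rng(11)
        a = rng.normal(0.8, 0.3, size=100_000)
        b = rng.normal(0.2, 0.3, size=100_000)
        p = _fake_post({"beta[woman_woman,uni]": a, "beta[woman_woman,lab]": b})
        s = contrast_contexts(p, "woman_woman", "uni", "lab")
        assert s.median == pytest.approx(np.median(a) - np.median(b), abs=0.01)


@pytest.fixture(scope="module")
def single_team_fit():
    """Small null-model fit shared by the fit tests: zero true effects."""
    from teamdynam.simulate import SimConfig, simulate_study

    cfg = SimConfig(
        seed=21,
        teams_per_context={"lab": 1},
        team_size_range=(8, 8),
        events_per_team=600,
        missing_rate=0.0,
        true_coefficients={},
        sigma_inertia=0.0,
    )
    study = simulate_study(cfg)
    designs = build_dyad_design(
        study.actors,
        {t: dichotomize_ratings(m) for t, m in study.advice_ratings.items()},
        {t: dichotomize_ratings(m) for t, m in study.friendship_ratings.items()},
        study.colocation,
    )
    post = fit_model(
        study.events, designs, study.presence,
        chains=2, draws=200, warmup=150, seed=3,
    )
    return study, designs, post


class TestFitModel:
    def test_null_truth_cis_straddle_zero(self, single_team_fit):
        _, _, post = single_team_fit
        summary = summarize_effects(post)
        fixed = summary[summary["parameter"].str.startswith("beta[")]
        # all true coefficients are zero: expect overwhelming CI coverage
        inside = (
            (fixed["ci_2.5"] <= 0.0) & (0.0 <= fixed["ci_97.5"])
        )
        assert inside.mean() >= 0.85

    def test_seeded_reproducibility(self, single_team_fit):
        study, designs, post = single_team_fit
        again = fit_model(
            study.events, designs, study.presence,
            chains=2, draws=200, warmup=150, seed=3,
        )
        pd.testing.assert_frame_equal(post.draws, again.draws)

    def test_draw_bookkeeping(self, single_team_fit):
        _, _, post = single_team_fit
        assert post.n_draws == 2 * 200
        assert set(np.unique(post.chain)) == {0, 1}
        assert (post.draws["sigma[inertia]"] > 0).all()
        assert post.diagnostics is not None

    def test_emcee_cross_check(self, single_team_fit):
        """Independent sampler agreement on posterior location/scale.

        The same log-posterior is sampled with emcee's affine-invariant
        ensemble; marginal medians of a few coefficients must agree with
        the package HMC within Monte-Carlo error.
        """
        import emcee

        study, designs, post = single_team_fit
        from teamdynam.dynam import precompute_sequence
        from teamdynam.inference import _make_logp, _Parametrisation, _StackedData

        teams = sorted(study.events)
        pres = {
            g: precompute_sequence(study.events[g], designs[g], study.presence[g])
            for g in teams
        }
        spec = EffectSpec()
        tc = {g: designs[g].context for g in teams}
        par = _Parametrisation(spec, ["lab"], teams, tc)
        stacked = _StackedData(pres, teams)
        lg = _make_logp(stacked, par)

        nwalkers = 2 * par.dim + 2
        rng = np.random.default_rng(0)
        p0 = 0.05 * rng.standard_normal((nwalkers, par.dim))
        sampler = emcee.EnsembleSampler(
            nwalkers, par.dim, lambda x: lg(x)[0],
        )
        sampler.random_state = np.random.RandomState(1)
        sampler.run_mcmc(p0, 900, progress=False)
        chain = sampler.get_chain(discard=500, flat=True)

        for name in ["beta[woman_woman,lab]", "beta[recency,lab]"]:
            k = par.ix(name)
            hmc_med = np.median(post.draws[name])
            emcee_med = np.median(chain[:, k])
            spread = np.std(post.draws[name])
            assert abs(hmc_med - emcee_med) < 0.5 * spread + 0.05
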