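"""Synthetic study generator: rosters, surveys, events, detections."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teamdynam.covariates import dichotomize_ratings
from teamdynam.dynam import ALL_EFFECTS
from teamdynam.simulate import (
    SimConfig,
    SimConfigError,
    expand_to_detections,
    generate_rosters,
    generate_survey_networks,
    inject_missingness,
    make_presence,
    simulate_event_sequence,
    simulate_study,
)


class TestConfig:
    def test_seed_is_mandatory(self):
        with pytest.raises((SimConfigError, TypeError)):
            SimConfig(seed=None)

    def test_small_teams_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, team_size_range=(3, 5))

    def test_probability_bounds_checked(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, p_woman=1.4)


class TestRosters:
    def test_default_setting_team_sizes(self):
        cfg = SimConfig(seed=0)
        actors = generate_rosters(cfg)
        sizes = actors.table.groupby("team_id").size()
        assert len(sizes) == 11  # 3 + 5 + 3 teams
        assert sizes.between(7, 17).all()

    def test_gender_share_binomial(self):
        cfg = SimConfig(seed=1, teams_per_context={"lab": 100},
                        team_size_range=(10, 10), p_woman=0.45)
        actors = generate_rosters(cfg)
        n = len(actors.table)
        share = (actors.table["gender"] == "woman").mean()
        se = np.sqrt(0.45 * 0.55 / n)
        assert abs(share - 0.45) < 2 * se + 1e-9 or abs(share - 0.45) < 0.02

    def test_seeded_reproducibility(self):
        a = generate_rosters(SimConfig(seed=3))
        b = generate_rosters(SimConfig(seed=3))
        pd.testing.assert_frame_equal(a.table, b.table)


class TestSurveyNetworks:
    def test_reciprocity_exceeds_permutation_null(self):
        cfg = SimConfig(seed=5, teams_per_context={"lab": 4},
                        team_size_range=(10, 10),
                        survey_reciprocity=2.0, survey_density=-1.0)
        actors = generate_rosters(cfg)
        adv, _ = generate_survey_networks(actors, cfg)
        rng = np.random.default_rng(0)
        obs_recip, null_recips = 0, []
        mats = [dichotomize_ratings(m).to_numpy() for m in adv.values()]
        obs_recip = sum(int(np.nansum(m * m.T)) for m in mats)
        for _ in range(200):
            tot = 0
            for m in mats:
                n = len(m)
                perm = rng.permutation(n)
                mp = m[perm][:, perm]
                tot += int(np.nansum(m * mp.T))
            null_recips.append(tot)
        assert obs_recip > np.percentile(null_recips, 99)

    def test_zero_density_limit_no_ties(self):
        cfg = SimConfig(seed=6, teams_per_context={"lab": 2},
                        survey_density=-30.0, survey_homophily=0.0,
                        survey_reciprocity=0.0)
        actors = generate_rosters(cfg)
        adv, fri = generate_survey_networks(actors, cfg)
        for m in list(adv.values()) + list(fri.values()):
            vals = m.to_numpy()
            off = ~np.eye(len(m), dtype=bool)
            assert (vals[off] <= 3).all()  # dichotomised: empty network

    def test_ratings_in_range_and_seeded(self):
        cfg = SimConfig(seed=7, teams_per_context={"uni": 1})
        actors = generate_rosters(cfg)
        a1, f1 = generate_survey_networks(actors, cfg)
        a2, _ = generate_survey_networks(actors, cfg)
        for t in a1:
            off = ~np.eye(len(a1[t]), dtype=bool)
            assert np.isin(a1[t].to_numpy()[off], [1, 2, 3, 4, 5]).all()
            pd.testing.assert_frame_equal(a1[t], a2[t])


@pytest.fixture(scope="module")
def six_design():
    from teamdynam.covariates import build_dyad_design
    from conftest import empty_net

    cfg = SimConfig(seed=8, teams_per_context={"uni": 1},
                    team_size_range=(6, 6))
    actors = generate_rosters(cfg)
    ids = actors.team_members(actors.teams[0])["actor_id"].tolist()
    nets = {actors.teams[0]: empty_net(ids)}
    designs = build_dyad_design(actors, nets, nets, nets)
    return cfg, actors, designs[actors.teams[0]]


class TestEventSimulation:
    def test_null_model_uniform_dyads(self, six_design):
        cfg, actors, design = six_design
        presence = make_presence(actors)[actors.teams[0]]
        seq = simulate_event_sequence(
            design, presence, np.zeros(len(ALL_EFFECTS)), 10_000, seed=1
        )
        counts = seq.events.groupby(["i", "j"]).size()
        assert len(counts) == 15
        chi = stats.chisquare(counts.to_numpy())
        assert chi.pvalue > 0.01

    def test_homophily_raises_within_group_share(self, six_design):
        cfg, actors, design = six_design
        presence = make_presence(actors)[actors.teams[0]]
        truth = np.zeros(len(ALL_EFFECTS))
        k = ALL_EFFECTS.index("woman_woman")
        truth[k] = 1.0
        seq = simulate_event_sequence(design, presence, truth, 4000, seed=2)
        ww = design.matrix[:, :, 1]  # woman_woman indicator plane
        ids = design.actors
        is_ww = {
            (ids[a], ids[b]): ww[a, b]
            for a in range(6) for b in range(a + 1, 6)
        }
        share = np.mean(
            [is_ww[(i, j)] for i, j in zip(seq.events["i"], seq.events["j"])]
        )
        n_ww = sum(is_ww.values())
        null_exp = n_ww / 15
        # exact enumeration of the stationary coordination probabilities at
        # the history-free state (endogenous coefficients are zero, so the
        # pair distribution is constant over the sequence)
        import math

        eta = {d: 1.0 if is_ww[d] else 0.0 for d in is_ww}

        def e(i, j):
            return eta[(i, j)] if (i, j) in eta else eta[(j, i)]

        def p_dir(i, j):
            den = sum(math.exp(e(i, k)) for k in ids if k != i)
            return math.exp(e(i, j)) / den

        weights = {d: p_dir(*d) * p_dir(d[1], d[0]) for d in eta}
        z = sum(weights.values())
        enum_exp = sum(w for d, w in weights.items() if is_ww[d]) / z
        assert share > null_exp
        se = np.sqrt(enum_exp * (1 - enum_exp) / len(seq.events))
        assert abs(share - enum_exp) < 4 * se + 0.01

    def test_zero_events_degenerate(self, six_design):
        cfg, actors, design = six_design
        presence = make_presence(actors)[actors.teams[0]]
        seq = simulate_event_sequence(
            design, presence, np.zeros(len(ALL_EFFECTS)), 0, seed=3
        )
        assert len(seq) == 0

    def test_times_increase_within_presence(self, six_design):
        cfg, actors, design = six_design
        presence = make_presence(actors)[actors.teams[0]]
        seq = simulate_event_sequence(
            design, presence, np.zeros(len(ALL_EFFECTS)), 200, seed=4
        )
        t = seq.events["time_s"].to_numpy()
        assert (np.diff(t) >= 0).all()
        a0 = design.actors[0]
        assert all(presence.is_present(a0, x) for x in t)


class TestDetections:
    def test_each_event_yields_at_least_two_detections(self, six_design):
        cfg, actors, design = six_design
        presence = make_presence(actors)[actors.teams[0]]
        seq = simulate_event_sequence(
            design, presence, np.zeros(len(ALL_EFFECTS)), 50, seed=5
        )
        det = expand_to_detections(seq, cfg, seed=6)
        per_event = det.records.groupby(
            [np.floor(det.records["time"] / 75.0), "badge_a", "badge_b"]
        ).size()
        assert (per_event >= 2).all()

    def test_rate_cap_never_exceeded(self, six_design):
        cfg, actors, design = six_design
        cfg2 = SimConfig(seed=9, teams_per_context={"uni": 1},
                         detection_rate_per_min=500.0,
                         event_duration_mean_s=70.0)
        presence = make_presence(actors)[actors.teams[0]]
        seq = simulate_event_sequence(
            design, presence, np.zeros(len(ALL_EFFECTS)), 60, seed=7
        )
        det = expand_to_detections(seq, cfg2, seed=8)
        per_minute = det.records.groupby(
            [np.floor(det.records["time"] / 60.0), "badge_a", "badge_b"]
        ).size()
        assert per_minute.max() <= 50


class TestMissingness:
    def test_rate_zero_unchanged(self, tiny_study):
        out = inject_missingness(tiny_study.actors, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.table, tiny_study.actors.table)

    def test_rate_one_all_masked(self, tiny_study):
        out = inject_missingness(tiny_study.actors, 1.0, seed=1)
        assert out.table["age_years"].isna().all()
        assert out.table["tenure_months"].isna().all()

    def test_rate_binomial_on_ratings(self):
        rng_ids = [f"a{k}" for k in range(100)]
        mat = pd.DataFrame(
            np.ones((100, 100)), index=rng_ids, columns=rng_ids
        )
        out = inject_missingness({"t": mat}, 0.2, seed=2)["t"]
        off = ~np.eye(100, dtype=bool)
        frac = np.isnan(out.to_numpy()[off]).mean()
        n = off.sum()
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se

    def test_gender_never_masked(self, tiny_study):
        out = inject_missingness(tiny_study.actors, 0.5, seed=3)
        assert not out.table["gender"].isna().any()
        assert not out.table["seniority"].isna().any()


def test_study_bundle_serialises_truth(tmp_path, tiny_study):
    tiny_study.save_truth(tmp_path / "truth.json")
    import json

    payload = json.loads((tmp_path / "truth.json").read_text())
    assert payload["effect_order"] == list(ALL_EFFECTS)
    assert set(payload["truth"]) == set(tiny_study.events)
    k = payload["effect_order"].index("woman_woman")
    assert payload["truth"][tiny_study.actors.teams[0]][k] == -0.5
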