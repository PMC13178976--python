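"""End-to-end orchestration: aggregate -> covariates -> impute -> fit ->
summarise -> probability ratios.

The stages are plain functions over the library's containers; the CLI and
the reproduction scripts are thin wrappers around them.  Every run can
serialise its resolved configuration and posterior draws next to its
outputs so results are reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import ActorTable, build_dyad_design, dichotomize_ratings
from .defaults import CHAINS, DRAWS, MIN_DETECTIONS, N_IMPUTATIONS, WINDOW_S
from .imputation import ImputationSet, impute_all
from .inference import (
    EffectSpec,
    PosteriorDraws,
    fit_model,
    pool_imputations,
    summarize_effects,
)
from .sensor_events import (
    DetectionLog,
    EventSequence,
    PresenceSchedule,
    aggregate_detections,
)


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    seed: int
    window_s: float = WINDOW_S
    min_detections: int = MIN_DETECTIONS
    n_imputations: int = N_IMPUTATIONS
    chains: int = CHAINS
    draws: int = DRAWS
    warmup: int | None = None
    imputation_draws: int = 600
    imputation_warmup: int = 400
    max_leapfrog: int = 20
    random_effects: tuple[str, ...] = ("inertia",)

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.min_detections < 1:
            raise ValueError("min_detections must be >= 1")
        if self.n_imputations < 1 or self.chains < 1 or self.draws < 2:
            raise ValueError("n_imputations/chains/draws out of range")

    def to_json(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["random_effects"] = list(self.random_effects)
        return d


def aggregate_all(
    detections: dict[str, DetectionLog],
    presence: dict[str, PresenceSchedule],
    contexts: dict[str, str],
    config: RunConfig,
) -> dict[str, EventSequence]:
    """Stage 1: per-team detection aggregation."""
    return {
        team: aggregate_detections(
            log,
            presence[team],
            team=team,
            context=contexts[team],
            window_s=config.window_s,
            min_detections=config.min_detections,
        )
        for team, log in detections.items()
    }


def impute_stage(
    actors: ActorTable,
    advice_ratings: dict[str, pd.DataFrame],
    friendship_ratings: dict[str, pd.DataFrame],
    config: RunConfig,
) -> ImputationSet:
    """Stage 2-3: dichotomise ratings and multiply impute all covariates."""
    advice_b = {t: dichotomize_ratings(m) for t, m in advice_ratings.items()}
    friendship_b = {
        t: dichotomize_ratings(m) for t, m in friendship_ratings.items()
    }
    return impute_all(
        actors,
        advice_b,
        friendship_b,
        M=config.n_imputations,
        seed=config.seed,
        draws=config.imputation_draws,
        warmup=config.imputation_warmup,
    )


def fit_stage(
    events: dict[str, EventSequence],
    imputations: ImputationSet,
    colocation: dict[str, pd.DataFrame],
    presence: dict[str, PresenceSchedule],
    config: RunConfig,
    spec: EffectSpec | None = None,
) -> tuple[PosteriorDraws, list[PosteriorDraws]]:
    """Stage 4: fit the hierarchical model per imputation and pool."""
    spec = spec or EffectSpec(random_effects=config.random_effects)
    rng = np.random.default_rng(config.seed + 1)
    runs = []
    for m in range(imputations.M):
        designs = build_dyad_design(
            imputations.actors[m],
            imputations.advice[m],
            imputations.friendship[m],
            colocation,
        )
        runs.append(
            fit_model(
                events,
                designs,
                presence,
                spec=spec,
                chains=config.chains,
                draws=config.draws,
                warmup=config.warmup,
                seed=int(rng.integers(2**31 - 1)),
                imputation=m,
                max_leapfrog=config.max_leapfrog,
            )
        )
    return pool_imputations(runs), runs


@dataclass
class RunArtifacts:
    config: RunConfig
    events: dict[str, EventSequence]
    imputations: ImputationSet
    pooled: PosteriorDraws
    per_imputation: list[PosteriorDraws]
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.summary is None:
            self.summary = summarize_effects(self.pooled)


def run_pipeline(
    detections: dict[str, DetectionLog],
    presence: dict[str, PresenceSchedule],
    actors: ActorTable,
    advice_ratings: dict[str, pd.DataFrame],
    friendship_ratings: dict[str, pd.DataFrame],
    colocation: dict[str, pd.DataFrame],
    config: RunConfig,
) -> RunArtifacts:
    """Execute all stages in order on in-memory inputs."""
    config.validate()
    contexts = {t: actors.context_of(t) for t in actors.teams}
    events = aggregate_all(detections, presence, contexts, config)
    imputations = impute_stage(actors, advice_ratings, friendship_ratings, config)
    pooled, runs = fit_stage(events, imputations, colocation, presence, config)
    return RunArtifacts(
        config=config,
        events=events,
        imputations=imputations,
        pooled=pooled,
        per_imputation=runs,
    )


def run_synthetic_recovery(
    seed: int,
    events_per_team: int = 1000,
    teams_per_context: dict | None = None,
    team_size: int = 8,
    M: int = 5,
    chains: int = 2,
    draws: int = 250,
    warmup: int = 120,
    missing_rate: float = 0.2,
    imputation_draws: int = 400,
    imputation_warmup: int = 300,
    max_leapfrog: int = 8,
) -> dict:
    """Full-pipeline parameter recovery on synthetic data.

    Simulates a study from the generative model (three contexts, two teams
    each by default, known nonzero woman-woman and junior-junior effects,
    random inertia slopes), re-expands events to raw detections, aggregates
    them back, multiply imputes 20% MAR-missing covariates, fits the
    hierarchical model per imputation and pools.  Returns the pooled
    posterior, the generating truth, and recovery metrics: the minimum pd
    across truly nonzero fixed effects (with the correct sign) and the
    share of generating values covered by their 95% intervals.
    """
    from .inference import summarize_draws
    from .simulate import SimConfig, simulate_study

    cfg = SimConfig(
        seed=seed,
        teams_per_context=teams_per_context or {"uni": 2, "lab": 2, "bus": 2},
        team_size_range=(team_size, team_size),
        events_per_team=events_per_team,
        missing_rate=missing_rate,
    )
    study = simulate_study(cfg)
    run_cfg = RunConfig(
        seed=seed,
        n_imputations=M,
        chains=chains,
        draws=draws,
        warmup=warmup,
        imputation_draws=imputation_draws,
        imputation_warmup=imputation_warmup,
        max_leapfrog=max_leapfrog,
    )
    contexts = {t: study.actors.context_of(t) for t in study.actors.teams}
    events = aggregate_all(study.detections, study.presence, contexts, run_cfg)
    imputations = impute_stage(
        study.actors_observed, study.advice_observed,
        study.friendship_observed, run_cfg,
    )
    pooled, _ = fit_stage(
        events, imputations, study.colocation, study.presence, run_cfg
    )

    true_effects = {
        eff: v for eff, v in cfg.true_coefficients.items() if v != 0.0
    }
    sign_pds: dict[str, float] = {}
    covered, total = 0, 0
    for eff, val in true_effects.items():
        for c in pooled.contexts:
            d = pooled.beta(eff, c)
            s = summarize_draws(d, f"{eff},{c}")
            correct_sign = np.sign(s.median) == np.sign(val)
            sign_pds[f"{eff},{c}"] = s.pd if correct_sign else 1.0 - s.pd
            covered += int(s.ci_low <= val <= s.ci_high)
            total += 1
    # hypermean and SD of the random inertia slope
    for c in pooled.contexts:
        s = summarize_draws(pooled.beta("inertia", c), f"inertia,{c}")
        covered += int(s.ci_low <= cfg.gamma_inertia <= s.ci_high)
        total += 1
    s_sigma = summarize_draws(pooled.column("sigma[inertia]"), "sigma")
    covered += int(s_sigma.ci_low <= cfg.sigma_inertia <= s_sigma.ci_high)
    total += 1
    return {
        "study": study,
        "events": events,
        "pooled": pooled,
        "truth": cfg.true_coefficients,
        "sign_pds": sign_pds,
        "min_sign_pd": min(sign_pds.values()),
        "coverage": covered / total,
        "n_events": int(sum(len(e) for e in events.values())),
    }


def save_draws(post: PosteriorDraws, outdir) -> None:
    """Serialise draws as CSV plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    df = post.draws.copy()
    df["chain"] = post.chain
    df["imputation"] = post.imputation
    df.to_csv(out / "draws.csv", index=False)
    manifest = {
        "effects": list(post.spec.effects),
        "random_effects": list(post.spec.random_effects),
        "prior_scale_fixed": post.spec.prior_scale_fixed,
        "prior_scale_sigma": post.spec.prior_scale_sigma,
        "contexts": list(post.contexts),
        "teams": list(post.teams),
        "meta": {k: v for k, v in post.meta.items()},
    }
    (out / "draws_manifest.json").write_text(json.dumps(manifest, indent=2))
    if post.diagnostics is not None:
        post.diagnostics.to_csv(out / "diagnostics.csv", index=False)


def load_draws(indir) -> PosteriorDraws:
    """Inverse of :func:`save_draws`."""
    indir = Path(indir)
    manifest = json.loads((indir / "draws_manifest.json").read_text())
    df = pd.read_csv(indir / "draws.csv")
    chain = df.pop("chain").to_numpy()
    imputation = df.pop("imputation").to_numpy()
    spec = EffectSpec(
        effects=tuple(manifest["effects"]),
        random_effects=tuple(manifest["random_effects"]),
        prior_scale_fixed=manifest["prior_scale_fixed"],
        prior_scale_sigma=manifest["prior_scale_sigma"],
    )
    return PosteriorDraws(
        draws=df,
        chain=chain,
        imputation=imputation,
        spec=spec,
        contexts=tuple(manifest["contexts"]),
        teams=tuple(manifest["teams"]),
        meta=manifest.get("meta", {}),
    )


def write_report(artifacts: RunArtifacts, outdir, pr_requests=()) -> None:
    """Write the coefficient, contrast and PR tables for a run.

    ``pr_requests`` is an iterable of (numerator, denominator)
    :class:`~teamdynam.ratios.PrototypicalDyad` pairs; an empty list
    yields an empty PR table, not an error.
    """
    from .inference import contrast_contexts
    from .ratios import probability_ratio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts.summary.to_csv(out / "coefficients.csv", index=False)

    rows = []
    ctx = artifacts.pooled.contexts
    for eff in artifacts.pooled.spec.effects:
        for a in range(len(ctx)):
            for b in range(a + 1, len(ctx)):
                s = contrast_contexts(artifacts.pooled, eff, ctx[b], ctx[a])
                rows.append(
                    {
                        "effect": eff,
                        "contrast": f"{ctx[b]}-{ctx[a]}",
                        "median": s.median,
                        "ci_2.5": s.ci_low,
                        "ci_97.5": s.ci_high,
                        "pd": s.pd,
                        "evidence_grade": s.evidence,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "contrasts.csv", index=False)

    pr_rows = []
    for num, den in pr_requests:
        r = probability_ratio(num, den, artifacts.pooled)
        pr_rows.append(
            {
                "context": num.context,
                "numerator": f"{num.gender_pair}/{num.seniority_pair}",
                "denominator": f"{den.gender_pair}/{den.seniority_pair}",
                "median": r.median,
                "ci_2.5": r.ci_low,
                "ci_97.5": r.ci_high,
                "pd": r.pd,
            }
        )
    pd.DataFrame(
        pr_rows,
        columns=[
            "context", "numerator", "denominator",
            "median", "ci_2.5", "ci_97.5", "pd",
        ],
    ).to_csv(out / "probability_ratios.csv", index=False)
    (out / "run_config.json").write_text(
        json.dumps(artifacts.config.to_json(), indent=2)
    )
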