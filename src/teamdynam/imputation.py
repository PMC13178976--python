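"""Multiple imputation of survey covariates.

Two hierarchical Bayesian imputation engines, both sampled with the
package's HMC machinery so the whole pipeline shares one inferential
framework:

* **Actor covariates** (age, team tenure): their logarithms follow a
  jointly normal model with team-level random intercepts and
  gender/seniority fixed effects.  Missing log-values are latent
  quantities sampled along with the parameters, so each retained posterior
  draw is a completed dataset and positivity is guaranteed by the log
  scale.

* **Dyadic networks** (dichotomised advice / friendship): a hierarchical
  p2-type model — dyad-wise logistic with density and reciprocity terms,
  sender/receiver normal random effects shared across teams, dyadic
  same-gender / same-seniority covariates, and sender/receiver gender and
  seniority.  Dyads with unobserved entries are marginalised in the
  likelihood; missing entries are then drawn from the conditional
  posterior predictive per retained draw.  Sender-receiver covariance is
  omitted (independent random effects), a documented simplification.

Missingness is assumed MAR conditional on team, gender and seniority.
Observed values are never altered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import ActorTable
from .hmc import quiet_fp, safe_exp, sample_hmc

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    """Imputation model cannot be fit on the given data."""


@dataclass
class ImputationSet:
    """M completed copies of the survey inputs.

    Observed entries are identical across copies; only imputed cells vary.
    """

    actors: list[ActorTable]
    advice: list[dict[str, pd.DataFrame]]
    friendship: list[dict[str, pd.DataFrame]]
    M: int
    seed: int
    manifest: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        """One directory per imputation, same file schemas as the inputs."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for m in range(self.M):
            d = out / f"imputation_{m:03d}"
            d.mkdir(exist_ok=True)
            self.actors[m].table.to_csv(d / "actors.csv", index=False)
            for name, nets in (("advice", self.advice[m]),
                               ("friendship", self.friendship[m])):
                rows = []
                for team, mat in nets.items():
                    for a in mat.index:
                        for b in mat.columns:
                            if a != b:
                                rows.append((team, a, b, int(mat.loc[a, b])))
                pd.DataFrame(
                    rows, columns=["team", "from", "to", "tie"]
                ).to_csv(d / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps({"M": self.M, "seed": self.seed, **self.manifest}, indent=2)
        )


# --------------------------------------------------------------------------
# actor-level covariates: hierarchical lognormal
# --------------------------------------------------------------------------

def _thin_indices(n_total: int, M: int) -> np.ndarray:
    """M equally spaced draw indices (widest possible spacing)."""
    return np.linspace(0, n_total - 1, M).round().astype(int)


def impute_actor_covariates(
    actors: ActorTable,
    M: int,
    seed: int,
    draws: int = 600,
    warmup: int = 400,
) -> list[ActorTable]:
    """Return M completed actor tables with age/tenure filled in.

    The model, per actor i in team g (w = woman, s = senior):

        log age_i    = a0 + a_w w_i + a_s s_i + u_g^a + eps_a
        log tenure_i = t0 + t_w w_i + t_s s_i + t_a log age_i + u_g^t + eps_t

    which is a joint bivariate normal for (log age, log tenure) with
    team random intercepts u ~ N(0, tau^2) (non-centred).  Missing
    log-values are sampled as latent quantities.
    """
    if M < 1:
        raise ImputationError("M must be >= 1")
    df = actors.table.reset_index(drop=True)
    age = np.log(df["age_years"].to_numpy(dtype=float))
    ten = np.log(df["tenure_months"].to_numpy(dtype=float))
    miss_a = ~np.isfinite(age)
    miss_t = ~np.isfinite(ten)
    if not (miss_a.any() or miss_t.any()):
        return [ActorTable(df.copy()) for _ in range(M)]
    if miss_a.all():
        raise ImputationError("age missing for every actor; cannot fit")
    if miss_t.all():
        raise ImputationError("tenure missing for every actor; cannot fit")

    teams = sorted(df["team_id"].unique())
    g_idx = df["team_id"].map({t: k for k, t in enumerate(teams)}).to_numpy()
    G, N = len(teams), len(df)
    woman = (df["gender"] == "woman").to_numpy(dtype=float)
    senior = (df["seniority"] == "senior").to_numpy(dtype=float)
    X = np.column_stack([np.ones(N), woman, senior])
    obs_a = np.where(miss_a, 0.0, age)
    obs_t = np.where(miss_t, 0.0, ten)
    ia_miss = np.where(miss_a)[0]
    it_miss = np.where(miss_t)[0]
    center_a = float(np.nanmean(np.where(miss_a, np.nan, age)))

    # theta layout: a(3), t(3), t_age, log_sig(2), log_tau(2),
    #               za(G), zt(G), miss_age, miss_ten
    n_head = 3 + 3 + 1 + 2 + 2
    dim = n_head + 2 * G + len(ia_miss) + len(it_miss)
    sl_za = slice(n_head, n_head + G)
    sl_zt = slice(n_head + G, n_head + 2 * G)
    sl_ma = slice(n_head + 2 * G, n_head + 2 * G + len(ia_miss))
    sl_mt = slice(n_head + 2 * G + len(ia_miss), dim)

    @quiet_fp
    def logp_grad(th: np.ndarray) -> tuple[float, np.ndarray]:
        a, t = th[0:3], th[3:6]
        t_age = th[6]
        sig_a, sig_t = safe_exp(th[7]), safe_exp(th[8])
        tau_a, tau_t = safe_exp(th[9]), safe_exp(th[10])
        za, zt = th[sl_za], th[sl_zt]
        y_a = obs_a.copy()
        y_a[ia_miss] = th[sl_ma]
        y_t = obs_t.copy()
        y_t[it_miss] = th[sl_mt]

        mu_a = X @ a + tau_a * za[g_idx]
        r_a = y_a - mu_a
        mu_t = X @ t + t_age * (y_a - center_a) + tau_t * zt[g_idx]
        r_t = y_t - mu_t

        lp = (
            -0.5 * float(r_a @ r_a) / sig_a**2 - N * np.log(sig_a)
            - 0.5 * float(r_t @ r_t) / sig_t**2 - N * np.log(sig_t)
            - 0.5 * float(za @ za) - 0.5 * float(zt @ zt)
        )
        # weak priors on coefficients; half-normal(1.5) on scales (log par.)
        coefs = th[0:7]
        lp += -0.5 * float(coefs @ coefs) / 2.0**2
        for k in (7, 8, 9, 10):
            s = safe_exp(th[k])
            lp += -0.5 * s**2 / 1.5**2 + th[k]

        g = np.zeros(dim)
        d_ra = -r_a / sig_a**2          # d lp / d mu_a (negated residual)
        d_rt = -r_t / sig_t**2
        g[0:3] = -(X.T @ d_ra)
        g[3:6] = -(X.T @ d_rt)
        g[6] = -float(d_rt @ (y_a - center_a))
        g[7] = float(r_a @ r_a) / sig_a**2 - N
        g[8] = float(r_t @ r_t) / sig_t**2 - N
        g[9] = -float(d_ra @ (tau_a * za[g_idx])) # d/d log tau via mu_a
        g[10] = -float(d_rt @ (tau_t * zt[g_idx]))
        np.add.at(g, np.arange(G)[g_idx] + sl_za.start, -tau_a * d_ra)
        g[sl_za] -= za
        np.add.at(g, np.arange(G)[g_idx] + sl_zt.start, -tau_t * d_rt)
        g[sl_zt] -= zt
        # latent missing values: appear in r_a and (via t_age) in mu_t
        g[sl_ma] = d_ra[ia_miss] - t_age * d_rt[ia_miss]
        g[sl_mt] = d_rt[it_miss]
        g[0:7] += -coefs / 2.0**2
        for k in (7, 8, 9, 10):
            s = safe_exp(th[k])
            g[k] += -(s**2) / 1.5**2 + 1.0
        return lp, g

    rng = np.random.default_rng(seed)
    x0 = 0.1 * rng.standard_normal(dim)
    x0[sl_ma] = center_a
    x0[sl_mt] = float(np.nanmean(np.where(miss_t, np.nan, ten)))
    bounds = [(-25.0, 25.0)] * dim
    for k in (7, 8, 9, 10):  # log-scales boxed during the mode search
        bounds[k] = (-4.0, 3.0)
    res = sample_hmc(logp_grad, x0, n_draws=draws, warmup=warmup,
                     seed=int(rng.integers(2**31 - 1)), map_bounds=bounds)
    out: list[ActorTable] = []
    for k in _thin_indices(draws, M):
        th = res.draws[k]
        comp = df.copy()
        comp.loc[miss_a, "age_years"] = np.exp(th[sl_ma])
        comp.loc[miss_t, "tenure_months"] = np.exp(th[sl_mt])
        out.append(ActorTable(comp))
    return out


# --------------------------------------------------------------------------
# dyadic networks: hierarchical p2
# --------------------------------------------------------------------------

def _dyad_arrays(nets: dict[str, pd.DataFrame], actors: ActorTable):
    """Stack all within-team unordered dyads into flat arrays."""
    ids: list[str] = []
    for team in actors.teams:
        ids += actors.team_members(team)["actor_id"].tolist()
    pos = {a: k for k, a in enumerate(ids)}
    df = actors.table.set_index("actor_id")
    woman = np.array([float(df.loc[a, "gender"] == "woman") for a in ids])
    senior = np.array([float(df.loc[a, "seniority"] == "senior") for a in ids])

    di, dj, y_ij, y_ji = [], [], [], []
    for team in actors.teams:
        members = actors.team_members(team)["actor_id"].tolist()
        mat = nets[team]
        if list(mat.index) != members or list(mat.columns) != members:
            raise ImputationError(
                f"network matrix for team {team} not conformable with roster"
            )
        vals = mat.to_numpy(dtype=float)
        n_obs = np.isfinite(vals[~np.eye(len(members), dtype=bool)]).sum()
        if n_obs == 0:
            logger.warning(
                "team %s has no observed ties; imputing from the "
                "cross-team hierarchical prior", team,
            )
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                di.append(pos[members[a]])
                dj.append(pos[members[b]])
                y_ij.append(vals[a, b])
                y_ji.append(vals[b, a])
    return (ids, woman, senior, np.array(di), np.array(dj),
            np.array(y_ij, dtype=float), np.array(y_ji, dtype=float))


def impute_dyadic_networks(
    nets: dict[str, pd.DataFrame],
    actors: ActorTable,
    M: int,
    seed: int,
    draws: int = 600,
    warmup: int = 400,
) -> tuple[list[dict[str, pd.DataFrame]], pd.DataFrame]:
    """Return (M completed per-team binary matrices, parameter summary).

    Each unordered dyad (i, j) has four joint states for the directed pair
    (y_ij, y_ji) with unnormalised log-scores 0, m_ij, m_ji and
    m_ij + m_ji + rho, where

        m_ij = mu + d_sg same_gender + d_ss same_seniority
             + b_sw w_i + b_ss s_i + b_rw w_j + b_rs s_j + A_i + B_j.

    Dyads with missing components contribute the marginal over compatible
    states.  The parameter summary carries posterior medians of the fixed
    effects (density mu, reciprocity rho, covariates) for diagnostics.
    """
    if M < 1:
        raise ImputationError("M must be >= 1")
    any_missing = any(
        np.isnan(m.to_numpy()[~np.eye(len(m), dtype=bool)]).any()
        for m in nets.values()
    )
    (ids, woman, senior, di, dj, y_ij, y_ji) = _dyad_arrays(nets, actors)
    N, D = len(ids), len(di)
    same_g = (woman[di] == woman[dj]).astype(float)
    same_s = (senior[di] == senior[dj]).astype(float)

    # fixed-effect design for m_ij and m_ji (shared dyadic covariates)
    # columns: mu, d_sg, d_ss, b_sw, b_ss, b_rw, b_rs
    X_ij = np.column_stack(
        [np.ones(D), same_g, same_s, woman[di], senior[di], woman[dj], senior[dj]]
    )
    X_ji = np.column_stack(
        [np.ones(D), same_g, same_s, woman[dj], senior[dj], woman[di], senior[di]]
    )
    n_fix = 7
    # theta: fixed(7), rho, log_sA, log_sB, zA(N), zB(N)
    n_head = n_fix + 3
    dim = n_head + 2 * N
    sl_zA = slice(n_head, n_head + N)
    sl_zB = slice(n_head + N, dim)

    obs_ij = np.isfinite(y_ij)
    obs_ji = np.isfinite(y_ji)
    # compatibility masks over the 4 states (00, 10, 01, 11) per dyad;
    # state order: (y_ij, y_ji) = (0,0), (1,0), (0,1), (1,1)
    state_yij = np.array([0.0, 1.0, 0.0, 1.0])
    state_yji = np.array([0.0, 0.0, 1.0, 1.0])
    compat = np.ones((D, 4), dtype=bool)
    compat &= ~(obs_ij[:, None] & (state_yij[None, :] != np.nan_to_num(y_ij)[:, None]))
    compat &= ~(obs_ji[:, None] & (state_yji[None, :] != np.nan_to_num(y_ji)[:, None]))

    def scores(th: np.ndarray):
        fx = th[:n_fix]
        rho = th[n_fix]
        sA, sB = safe_exp(th[n_fix + 1]), safe_exp(th[n_fix + 2])
        A = sA * th[sl_zA]
        B = sB * th[sl_zB]
        m_ij = X_ij @ fx + A[di] + B[dj]
        m_ji = X_ji @ fx + A[dj] + B[di]
        s = np.zeros((D, 4))
        s[:, 1] = m_ij
        s[:, 2] = m_ji
        s[:, 3] = m_ij + m_ji + rho
        return s, (sA, sB)

    def _softmax_rows(s, mask):
        sm = np.where(mask, s, -np.inf)
        mx = sm.max(axis=1, keepdims=True)
        e = np.exp(sm - mx)
        tot = e.sum(axis=1, keepdims=True)
        return e / tot, np.squeeze(mx + np.log(tot), axis=1)

    full_mask = np.ones((D, 4), dtype=bool)

    @quiet_fp
    def logp_grad(th: np.ndarray) -> tuple[float, np.ndarray]:
        s, (sA, sB) = scores(th)
        p_num, logZ_num = _softmax_rows(s, compat)
        p_all, logZ_all = _softmax_rows(s, full_mask)
        lp = float((logZ_num - logZ_all).sum())
        # dL/ds_state = E_compat[state] - E_all[state]
        dS = p_num - p_all
        d_mij = dS[:, 1] + dS[:, 3]
        d_mji = dS[:, 2] + dS[:, 3]
        d_rho = float(dS[:, 3].sum())
        g = np.zeros(dim)
        g[:n_fix] = X_ij.T @ d_mij + X_ji.T @ d_mji
        g[n_fix] = d_rho
        dA = np.zeros(N)
        dB = np.zeros(N)
        np.add.at(dA, di, d_mij)
        np.add.at(dA, dj, d_mji)
        np.add.at(dB, dj, d_mij)
        np.add.at(dB, di, d_mji)
        zA, zB = th[sl_zA], th[sl_zB]
        g[n_fix + 1] = float(dA @ (sA * zA))
        g[n_fix + 2] = float(dB @ (sB * zB))
        g[sl_zA] = sA * dA - zA
        g[sl_zB] = sB * dB - zB
        lp += -0.5 * float(zA @ zA) - 0.5 * float(zB @ zB)
        # priors: N(0,2^2) fixed & rho, half-normal(1) scales
        head = th[: n_fix + 1]
        lp += -0.5 * float(head @ head) / 2.0**2
        g[: n_fix + 1] += -head / 2.0**2
        for k in (n_fix + 1, n_fix + 2):
            sc = safe_exp(th[k])
            lp += -0.5 * sc**2 + th[k]
            g[k] += -(sc**2) + 1.0
        return lp, g

    rng = np.random.default_rng(seed)
    x0 = 0.1 * rng.standard_normal(dim)
    bounds = [(-25.0, 25.0)] * dim
    for k in (n_fix + 1, n_fix + 2):  # log-scales boxed during mode search
        bounds[k] = (-4.0, 3.0)
    res = sample_hmc(logp_grad, x0, n_draws=draws, warmup=warmup,
                     seed=int(rng.integers(2**31 - 1)), map_bounds=bounds)

    fixed_names = ["density", "same_gender", "same_seniority",
                   "sender_woman", "sender_senior",
                   "receiver_woman", "receiver_senior", "reciprocity"]
    summary = pd.DataFrame(
        {
            "parameter": fixed_names,
            "median": np.median(res.draws[:, : n_fix + 1], axis=0),
            "ci_2.5": np.percentile(res.draws[:, : n_fix + 1], 2.5, axis=0),
            "ci_97.5": np.percentile(res.draws[:, : n_fix + 1], 97.5, axis=0),
            "pd": [
                _pd_col(res.draws[:, k]) for k in range(n_fix + 1)
            ],
        }
    )

    completions: list[dict[str, pd.DataFrame]] = []
    if not any_missing:
        for _ in range(M):
            completions.append({t: m.copy() for t, m in nets.items()})
        return completions, summary

    pred_rng = np.random.default_rng(seed + 1)
    for k in _thin_indices(draws, M):
        th = res.draws[k]
        s, _ = scores(th)
        p_num, _ = _softmax_rows(s, compat)
        states = np.array(
            [pred_rng.choice(4, p=p_num[d]) for d in range(D)]
        )
        fill_ij = state_yij[states]
        fill_ji = state_yji[states]
        comp = {t: m.copy() for t, m in nets.items()}
        d = 0
        for team in actors.teams:
            members = actors.team_members(team)["actor_id"].tolist()
            mat = comp[team]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    if not obs_ij[d]:
                        mat.iloc[a, b] = fill_ij[d]
                    if not obs_ji[d]:
                        mat.iloc[b, a] = fill_ji[d]
                    d += 1
        completions.append(comp)
    return completions, summary


def _pd_col(draws: np.ndarray) -> float:
    from .inference import probability_of_direction

    return probability_of_direction(draws)


def impute_all(
    actors: ActorTable,
    advice: dict[str, pd.DataFrame],
    friendship: dict[str, pd.DataFrame],
    M: int,
    seed: int,
    draws: int = 600,
    warmup: int = 400,
) -> ImputationSet:
    """Run both imputation engines and bundle the M completed datasets."""
    rng = np.random.default_rng(seed)
    actor_sets = impute_actor_covariates(
        actors, M, seed=int(rng.integers(2**31 - 1)),
        draws=draws, warmup=warmup,
    )
    adv_sets, adv_sum = impute_dyadic_networks(
        advice, actors, M, seed=int(rng.integers(2**31 - 1)),
        draws=draws, warmup=warmup,
    )
    fri_sets, fri_sum = impute_dyadic_networks(
        friendship, actors, M, seed=int(rng.integers(2**31 - 1)),
        draws=draws, warmup=warmup,
    )
    return ImputationSet(
        actors=actor_sets,
        advice=adv_sets,
        friendship=fri_sets,
        M=M,
        seed=seed,
        manifest={
            "advice_model": adv_sum.to_dict(orient="records"),
            "friendship_model": fri_sum.to_dict(orient="records"),
            "draws": draws,
            "warmup": warmup,
        },
    )
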