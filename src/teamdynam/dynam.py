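"""Coordination dynamic network actor model (DyNAM) engine.

Undirected relational events are modelled as a two-sided choice: the
probability that actors i and j engage in the next event is proportional to
the product of the two directed multinomial-logit choice probabilities,

    p(i -> j; y, beta) = exp(beta' s(i,j,y)) / sum_{k in A\\{i}} exp(beta' s(i,k,y))

    P_{i<->j}(y) = p(i->j) p(j->i) / sum_{k<l in A} p(k->l) p(l->k)

where ``y`` is the process state (event history plus the set A of available
actors) and ``s(i,j,y)`` stacks endogenous statistics (inertia, degree,
recency) and exogenous dyadic indicators.  The event rate is taken constant,
so the sequence likelihood conditions on event occurrence and multiplies the
pair probabilities at the pre-event states.

Endogenous statistic functional forms follow common relational-event
conventions and are swappable plug-ins:

* ``inertia`` — raw count of the dyad's past events;
* ``degree``  — mean past-event degree of the two actors, normalised by
  team size, (deg(i)+deg(j)) / (2 (n-1));
* ``recency`` — reciprocal rank 1/(1+r) of the dyad's last event among all
  dyads' last events (0 if the dyad never interacted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .covariates import EXOGENOUS_EFFECTS, DyadDesign
from .sensor_events import EventSequence, PresenceSchedule

ENDOGENOUS_EFFECTS = ("inertia", "degree", "recency")
ALL_EFFECTS = ENDOGENOUS_EFFECTS + EXOGENOUS_EFFECTS


class StateError(ValueError):
    """Event incompatible with the current process state."""


class NoChoiceError(ValueError):
    """Fewer than two available actors; no event can occur."""


@dataclass
class ProcessState:
    """Evolving event-history state for one team.

    Tracks pairwise past-event counts, the per-actor degrees they imply,
    and the sequence index of each dyad's last event (for recency ranks),
    together with the availability mask derived from the presence schedule.
    """

    actors: list[str]
    presence: PresenceSchedule
    time: float = 0.0
    counts: np.ndarray = field(default=None)  # (n, n) symmetric
    last_seq: np.ndarray = field(default=None)  # (n, n), -1 = never
    n_events: int = 0

    def __post_init__(self) -> None:
        n = len(self.actors)
        if self.counts is None:
            self.counts = np.zeros((n, n))
        if self.last_seq is None:
            self.last_seq = np.full((n, n), -1, dtype=np.int64)
        self._index = {a: k for k, a in enumerate(self.actors)}

    @property
    def n(self) -> int:
        return len(self.actors)

    def idx(self, actor: str) -> int:
        return self._index[actor]

    def degrees(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def availability(self, t: float | None = None) -> np.ndarray:
        return self.presence.available(self.actors, self.time if t is None else t)

    def recency_ranks(self) -> np.ndarray:
        """Rank of each dyad's last event (0 = most recent); -1 if never."""
        n = self.n
        iu = np.triu_indices(n, k=1)
        last = self.last_seq[iu]
        ranks = np.full_like(last, -1)
        active = last >= 0
        order = np.argsort(-last[active], kind="stable")
        ranks_active = np.empty_like(order)
        ranks_active[order] = np.arange(order.size)
        ranks[active] = ranks_active
        out = np.full((n, n), -1, dtype=np.int64)
        out[iu] = ranks
        out.T[iu] = ranks
        return out

    def evolve(self, t: float, i: str, j: str) -> None:
        """Register event (t, i, j); both actors must be available at t."""
        if i == j:
            raise StateError("self-event")
        avail = self.presence.available(self.actors, t)
        a, b = self.idx(i), self.idx(j)
        if not (avail[a] and avail[b]):
            raise StateError(f"actor unavailable at t={t} for event ({i},{j})")
        self.counts[a, b] += 1
        self.counts[b, a] += 1
        self.last_seq[a, b] = self.n_events
        self.last_seq[b, a] = self.n_events
        self.n_events += 1
        self.time = t


def _inertia_stat(state: ProcessState) -> np.ndarray:
    return state.counts.copy()


def _degree_stat(state: ProcessState) -> np.ndarray:
    deg = state.degrees()
    return (deg[:, None] + deg[None, :]) / (2.0 * (state.n - 1))


def _recency_stat(state: ProcessState) -> np.ndarray:
    ranks = state.recency_ranks()
    out = np.zeros_like(ranks, dtype=float)
    active = ranks >= 0
    out[active] = 1.0 / (1.0 + ranks[active])
    return out


#: Plug-in registry: name -> function(state) -> (n, n) statistic matrix.
ENDOGENOUS_PLUGINS: dict[str, Callable[[ProcessState], np.ndarray]] = {
    "inertia": _inertia_stat,
    "degree": _degree_stat,
    "recency": _recency_stat,
}


def endogenous_matrices(state: ProcessState) -> np.ndarray:
    """Stack the endogenous statistics into an (n, n, 3) array."""
    mats = [ENDOGENOUS_PLUGINS[name](state) for name in ENDOGENOUS_EFFECTS]
    out = np.stack(mats, axis=-1)
    out[np.eye(state.n, dtype=bool)] = 0.0
    return out


def compute_statistics(
    state: ProcessState, design: DyadDesign, dyad: tuple[str, str]
) -> np.ndarray:
    """Statistics vector s(i, j, y) in :data:`ALL_EFFECTS` order."""
    a, b = state.idx(dyad[0]), state.idx(dyad[1])
    endo = endogenous_matrices(state)[a, b]
    exo = design.matrix[a, b]
    return np.concatenate([endo, exo])


def _eta_matrix(
    state: ProcessState, design: DyadDesign, params: np.ndarray
) -> np.ndarray:
    """Linear predictor eta_ij = beta' s(i,j,y) for all ordered pairs."""
    params = np.asarray(params, dtype=float)
    if params.shape != (len(ALL_EFFECTS),):
        raise ValueError(
            f"expected {len(ALL_EFFECTS)} coefficients, got {params.shape}"
        )
    stats = np.concatenate([endogenous_matrices(state), design.matrix], axis=-1)
    return stats @ params


def choice_probabilities(
    i: str, state: ProcessState, design: DyadDesign, params: np.ndarray,
    avail: np.ndarray | None = None,
) -> dict[str, float]:
    """Directed partner-choice distribution p(i -> j) over available j."""
    if avail is None:
        avail = state.availability()
    a = state.idx(i)
    if not avail[a]:
        raise NoChoiceError(f"actor {i} not available")
    if avail.sum() < 2:
        raise NoChoiceError("fewer than two available actors")
    eta = _eta_matrix(state, design, params)[a]
    mask = avail.copy()
    mask[a] = False
    z = eta[mask] - eta[mask].max()  # max-shift for stability
    p = np.exp(z)
    p /= p.sum()
    probs = {actor: 0.0 for actor in state.actors}
    for actor, prob in zip(np.array(state.actors)[mask], p):
        probs[str(actor)] = float(prob)
    return probs


def pair_probabilities(
    state: ProcessState, design: DyadDesign, params: np.ndarray,
    avail: np.ndarray | None = None,
) -> dict[tuple[str, str], float]:
    """Undirected next-event distribution over available dyads (i < j)."""
    if avail is None:
        avail = state.availability()
    if avail.sum() < 2:
        raise NoChoiceError("fewer than two available actors")
    eta = _eta_matrix(state, design, params)
    log_u = _pair_log_weights(eta, avail)
    iu = np.triu_indices(state.n, k=1)
    ok = avail[iu[0]] & avail[iu[1]]
    logw = log_u[iu][ok]
    w = np.exp(logw - logsumexp(logw))
    out: dict[tuple[str, str], float] = {}
    for (a, b), prob in zip(zip(iu[0][ok], iu[1][ok]), w):
        out[(state.actors[a], state.actors[b])] = float(prob)
    return out


def _pair_log_weights(eta: np.ndarray, avail: np.ndarray) -> np.ndarray:
    """log[p(i->j) p(j->i)] up to the common pair normaliser, as (n, n).

    With symmetric statistics eta_ij = eta_ji, so
    log p(i->j)p(j->i) = 2 eta_ij - logZ_i - logZ_j with
    Z_i = sum_{k in A\\{i}} exp(eta_ik).
    """
    n = eta.shape[0]
    masked = np.where(
        avail[None, :] & avail[:, None] & ~np.eye(n, dtype=bool), eta, -np.inf
    )
    with np.errstate(divide="ignore"):
        logz = logsumexp(masked, axis=1)
    return 2.0 * eta - logz[:, None] - logz[None, :]


@dataclass
class PrecomputedSequence:
    """Per-event statistics for fast repeated likelihood evaluation.

    The process state evolves deterministically given the observed events,
    so the (n, n, 3) endogenous statistics, the availability masks and the
    observed dyad indices can be computed once and reused for every
    coefficient vector.
    """

    endo: np.ndarray        # (E, n, n, 3)
    exo: np.ndarray         # (n, n, K_exo)
    avail: np.ndarray       # (E, n) bool
    obs_i: np.ndarray       # (E,) int
    obs_j: np.ndarray       # (E,) int
    actors: list[str]
    team: str
    context: str

    @property
    def n_events(self) -> int:
        return len(self.obs_i)


def precompute_sequence(
    events: EventSequence, design: DyadDesign, presence: PresenceSchedule
) -> PrecomputedSequence:
    """Replay the event sequence once, recording pre-event statistics."""
    actors = design.actors
    state = ProcessState(actors=actors, presence=presence)
    E = len(events)
    n = len(actors)
    endo = np.zeros((E, n, n, len(ENDOGENOUS_EFFECTS)))
    avail = np.zeros((E, n), dtype=bool)
    obs_i = np.zeros(E, dtype=np.int64)
    obs_j = np.zeros(E, dtype=np.int64)
    for e, row in enumerate(events.events.itertuples(index=False)):
        t, i, j = float(row.time_s), str(row.i), str(row.j)
        av = presence.available(actors, t)
        if av.sum() < 2:
            raise StateError(f"fewer than two available actors at t={t}")
        endo[e] = endogenous_matrices(state)
        avail[e] = av
        obs_i[e], obs_j[e] = state.idx(i), state.idx(j)
        state.evolve(t, i, j)
    return PrecomputedSequence(
        endo=endo,
        exo=design.matrix,
        avail=avail,
        obs_i=obs_i,
        obs_j=obs_j,
        actors=actors,
        team=design.team,
        context=design.context,
    )


def _pair_loglik_core_numpy(
    eta: np.ndarray,
    avail: np.ndarray,
    obs_i: np.ndarray,
    obs_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Event log-probabilities and eta-gradient for a batch of events.

    ``eta`` is the symmetric (E, n, n) linear predictor, ``avail`` the
    (E, n) availability mask, ``obs_i``/``obs_j`` the observed dyad
    indices.  Returns (ll, G): per-event log pair-probabilities and the
    (E, n, n) gradient of their sum with respect to eta (G carries half
    the unordered-pair derivative per ordered entry, so contracting G with
    symmetric statistics over ordered entries gives the exact gradient).
    """
    E, n = avail.shape
    eye = np.eye(n, dtype=bool)
    pair_ok = avail[:, :, None] & avail[:, None, :] & ~eye
    neg = np.finfo(float).min / 4
    eta_m = np.where(pair_ok, eta, neg)

    # directed choice log-normalisers and probabilities
    row_max = eta_m.max(axis=2, keepdims=True)
    ex = np.exp(eta_m - row_max)
    ex[~pair_ok] = 0.0
    rows = ex.sum(axis=2, keepdims=True)
    rows_safe = np.where(rows == 0.0, 1.0, rows)  # unavailable senders
    with np.errstate(divide="ignore"):
        logz = np.squeeze(row_max + np.log(rows_safe), axis=2)  # (E, n)
    p_dir = ex / rows_safe  # p(i->j), rows sum to 1 on available senders

    # unordered-pair weights
    log_u = 2.0 * eta - logz[:, :, None] - logz[:, None, :]
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    log_u_m = np.where(pair_ok & upper, log_u, neg)
    flat = log_u_m.reshape(E, -1)
    fmax = flat.max(axis=1, keepdims=True)
    w = np.exp(flat - fmax)
    w[~(pair_ok & upper).reshape(E, -1)] = 0.0
    wsum = w.sum(axis=1)
    log_s = np.squeeze(fmax, axis=1) + np.log(wsum)  # log pair normaliser

    ev = np.arange(E)
    ll = log_u[ev, obs_i, obs_j] - log_s

    # gradient wrt eta (symmetric parametrisation, unordered pairs)
    P = (w / wsum[:, None]).reshape(E, n, n)  # pair probabilities, upper tri
    P = P + P.transpose(0, 2, 1)
    O = np.zeros((E, n, n))
    O[ev, obs_i, obs_j] = 1.0
    O[ev, obs_j, obs_i] = 1.0
    # c_i = 1[i in observed dyad] - sum_j P_ij
    c = O.sum(axis=2) - P.sum(axis=2)  # (E, n)
    # dL/deta_{kl} for the unordered pair {k,l} is
    #   2(O_kl - P_kl) - c_k p(k->l) - c_l p(l->k);
    # G holds half of it at each ordered entry so that summing G * S over
    # ordered entries of the symmetric statistics S gives the exact gradient.
    G = (O - P) - 0.5 * (
        c[:, :, None] * p_dir + c[:, None, :] * p_dir.transpose(0, 2, 1)
    )
    return ll, G


try:
    from numba import njit

    @njit(cache=True)
    def _pair_loglik_core_jit(eta, avail, obs_i, obs_j):  # pragma: no cover
        E, n, _ = eta.shape
        ll = np.zeros(E)
        G = np.zeros((E, n, n))
        logz = np.empty(n)
        p_dir = np.empty((n, n))
        P = np.empty((n, n))
        for e in range(E):
            # directed choice softmax per available sender
            for i in range(n):
                if not avail[e, i]:
                    logz[i] = 0.0
                    for j in range(n):
                        p_dir[i, j] = 0.0
                    continue
                m = -1.0e308
                for j in range(n):
                    if j != i and avail[e, j] and eta[e, i, j] > m:
                        m = eta[e, i, j]
                s = 0.0
                for j in range(n):
                    if j != i and avail[e, j]:
                        p_dir[i, j] = np.exp(eta[e, i, j] - m)
                        s += p_dir[i, j]
                    else:
                        p_dir[i, j] = 0.0
                logz[i] = m + np.log(s)
                for j in range(n):
                    p_dir[i, j] /= s
            # unordered pair weights
            mmax = -1.0e308
            for i in range(n):
                if not avail[e, i]:
                    continue
                for j in range(i + 1, n):
                    if avail[e, j]:
                        u = 2.0 * eta[e, i, j] - logz[i] - logz[j]
                        if u > mmax:
                            mmax = u
            ssum = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    if avail[e, i] and avail[e, j]:
                        P[i, j] = np.exp(
                            2.0 * eta[e, i, j] - logz[i] - logz[j] - mmax
                        )
                        ssum += P[i, j]
                    else:
                        P[i, j] = 0.0
            oi, oj = obs_i[e], obs_j[e]
            a, b = min(oi, oj), max(oi, oj)
            log_s = mmax + np.log(ssum)
            ll[e] = 2.0 * eta[e, a, b] - logz[a] - logz[b] - log_s
            # gradient wrt eta (symmetric)
            for i in range(n):
                for j in range(i + 1, n):
                    P[i, j] /= ssum
            for i in range(n):
                w_i = 0.0
                for j in range(n):
                    if j < i:
                        w_i += P[j, i]
                    elif j > i:
                        w_i += P[i, j]
                c_i = (1.0 if (i == a or i == b) else 0.0) - w_i
                logz[i] = c_i  # reuse buffer for c
            for i in range(n):
                for j in range(i + 1, n):
                    o_ij = 1.0 if (i == a and j == b) else 0.0
                    g = (o_ij - P[i, j]) - 0.5 * (
                        logz[i] * p_dir[i, j] + logz[j] * p_dir[j, i]
                    )
                    G[e, i, j] = g
                    G[e, j, i] = g
        return ll, G

    def pair_loglik_core(eta, avail, obs_i, obs_j):
        return _pair_loglik_core_jit(
            np.ascontiguousarray(eta), avail,
            obs_i.astype(np.int64), obs_j.astype(np.int64),
        )

    pair_loglik_core.__doc__ = _pair_loglik_core_numpy.__doc__

    @njit(cache=True)
    def stacked_loglik_grad(
        endo, exo_eta, team_of, avail, obs_i, obs_j, b_endo
    ):  # pragma: no cover
        """Fused likelihood + gradient over all teams' stacked events.

        ``endo`` (E, n, n, 3) endogenous statistics, ``exo_eta`` (T, n, n)
        per-team exogenous predictor, ``b_endo`` (T, 3) per-team endogenous
        coefficients.  Returns (total loglik, per-team eta-gradient sums
        (T, n, n), per-team endogenous-coefficient gradients (T, 3)).
        """
        E, n, _, ne = endo.shape
        T = exo_eta.shape[0]
        total = 0.0
        G_team = np.zeros((T, n, n))
        g_endo = np.zeros((T, ne))
        eta = np.empty((n, n))
        logz = np.empty(n)
        cbuf = np.empty(n)
        p_dir = np.empty((n, n))
        P = np.empty((n, n))
        for e in range(E):
            t = team_of[e]
            for i in range(n):
                for j in range(n):
                    v = exo_eta[t, i, j]
                    for k in range(ne):
                        v += endo[e, i, j, k] * b_endo[t, k]
                    eta[i, j] = v
            for i in range(n):
                if not avail[e, i]:
                    logz[i] = 0.0
                    for j in range(n):
                        p_dir[i, j] = 0.0
                    continue
                m = -1.0e308
                for j in range(n):
                    if j != i and avail[e, j] and eta[i, j] > m:
                        m = eta[i, j]
                s = 0.0
                for j in range(n):
                    if j != i and avail[e, j]:
                        p_dir[i, j] = np.exp(eta[i, j] - m)
                        s += p_dir[i, j]
                    else:
                        p_dir[i, j] = 0.0
                logz[i] = m + np.log(s)
                for j in range(n):
                    p_dir[i, j] /= s
            mmax = -1.0e308
            for i in range(n):
                if not avail[e, i]:
                    continue
                for j in range(i + 1, n):
                    if avail[e, j]:
                        u = 2.0 * eta[i, j] - logz[i] - logz[j]
                        if u > mmax:
                            mmax = u
            ssum = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    if avail[e, i] and avail[e, j]:
                        P[i, j] = np.exp(
                            2.0 * eta[i, j] - logz[i] - logz[j] - mmax
                        )
                        ssum += P[i, j]
                    else:
                        P[i, j] = 0.0
            oi, oj = obs_i[e], obs_j[e]
            a, b = min(oi, oj), max(oi, oj)
            total += 2.0 * eta[a, b] - logz[a] - logz[b] - mmax - np.log(ssum)
            for i in range(n):
                for j in range(i + 1, n):
                    P[i, j] /= ssum
            for i in range(n):
                w_i = 0.0
                for j in range(n):
                    if j < i:
                        w_i += P[j, i]
                    elif j > i:
                        w_i += P[i, j]
                cbuf[i] = (1.0 if (i == a or i == b) else 0.0) - w_i
            for i in range(n):
                for j in range(i + 1, n):
                    o_ij = 1.0 if (i == a and j == b) else 0.0
                    g = (o_ij - P[i, j]) - 0.5 * (
                        cbuf[i] * p_dir[i, j] + cbuf[j] * p_dir[j, i]
                    )
                    G_team[t, i, j] += g
                    G_team[t, j, i] += g
                    for k in range(ne):
                        g_endo[t, k] += 2.0 * g * endo[e, i, j, k]
        return total, G_team, g_endo

except ImportError:  # pragma: no cover
    pair_loglik_core = _pair_loglik_core_numpy
    stacked_loglik_grad = None


def sequence_loglik(
    events: EventSequence,
    design: DyadDesign,
    presence: PresenceSchedule,
    params: np.ndarray,
) -> float:
    """Log-likelihood of an event sequence under the coordination model."""
    pre = precompute_sequence(events, design, presence)
    return float(loglik_precomputed(pre, params))


def _eta_from_params(pre: PrecomputedSequence, params: np.ndarray) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    beta_endo = params[: len(ENDOGENOUS_EFFECTS)]
    beta_exo = params[len(ENDOGENOUS_EFFECTS):]
    return pre.endo @ beta_endo + pre.exo @ beta_exo  # (E, n, n)


def loglik_precomputed(pre: PrecomputedSequence, params: np.ndarray) -> float:
    eta = _eta_from_params(pre, params)
    ll, _ = pair_loglik_core(eta, pre.avail, pre.obs_i, pre.obs_j)
    return float(ll.sum())


def loglik_and_grad_precomputed(
    pre: PrecomputedSequence, params: np.ndarray
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its gradient with respect to the coefficients.

    The chain rule contracts the eta-gradient with the statistics; all
    arrays are symmetric and G carries half the unordered-pair derivative
    per ordered entry, so the plain ordered-entry contraction is exact.
    """
    eta = _eta_from_params(pre, params)
    ll, G = pair_loglik_core(eta, pre.avail, pre.obs_i, pre.obs_j)
    g_endo = np.einsum("enm,enmk->k", G, pre.endo)
    g_exo = (G.sum(axis=0)[:, :, None] * pre.exo).sum(axis=(0, 1))
    return float(ll.sum()), np.concatenate([g_endo, g_exo])


def sequence_loglik_slow(
    events: EventSequence,
    design: DyadDesign,
    presence: PresenceSchedule,
    params: np.ndarray,
) -> float:
    """Reference implementation: explicit per-event pair_probabilities loop."""
    state = ProcessState(actors=design.actors, presence=presence)
    total = 0.0
    for row in events.events.itertuples(index=False):
        t, i, j = float(row.time_s), str(row.i), str(row.j)
        probs = pair_probabilities(
            state, design, params, avail=presence.available(design.actors, t)
        )
        key = (i, j) if (i, j) in probs else (j, i)
        total += np.log(probs[key])
        state.evolve(t, i, j)
    return float(total)
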