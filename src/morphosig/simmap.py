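"""Stochastic character mapping and transition-weighted rate assignment.

A stochastic map is one full substitution history of a character over the
tree, drawn from the posterior of histories given the observed tip states
and a fitted rate matrix: node states are sampled from their joint
conditional distribution (root from its posterior, then each child given
its parent), and the path along every branch is simulated conditional on
its endpoint states.  Endpoint-conditioned paths use rejection sampling
with a bounded number of attempts and fall back to exact uniformization
sampling, so pathological rate/branch combinations cannot stall a run.

Averaging the per-type transition counts over many maps (1000 by default
in the pipeline) gives the expected number of i->j changes; for characters
whose best model allows a different rate per ordered state pair, the
character's single summary rate is the mean of the fitted pairwise rates
weighted by those counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MISSING
from .mk import MkFit, ModelComparison, RateMatrix, _edge_probs, prune_loglik, _root_prior
from .tree import TimeTree

__all__ = [
    "SimmapHistory",
    "TransitionSummary",
    "CharacterAssessment",
    "sample_history",
    "sample_histories",
    "count_transitions",
    "assign_rate",
]


@dataclass
class SimmapHistory:
    """One sampled substitution history.

    ``events[v]`` lists the changes on the edge above node ``v`` as
    ``(position_from_parent_end, from_state, to_state)`` tuples in order;
    ``node_states[v]`` is the sampled state at node ``v``.
    """

    node_states: np.ndarray
    events: dict[int, list[tuple[float, int, int]]]
    k: int

    def transition_counts(self) -> np.ndarray:
        """k x k matrix of realised i->j change counts (diagonal zero)."""
        C = np.zeros((self.k, self.k))
        for evs in self.events.values():
            for _, a, b in evs:
                C[a, b] += 1
        return C

    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())


@dataclass
class TransitionSummary:
    """Mean per-ordered-pair transition counts over M maps."""

    mean_counts: np.ndarray  # k x k, diagonal 0
    n_maps: int

    @property
    def total(self) -> float:
        return float(self.mean_counts.sum())


def _sample_node_states(
    tree: TimeTree, L: np.ndarray, P: np.ndarray, prior: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw all node states from their joint conditional distribution."""
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    w = prior * L[tree.root]
    w = w / w.sum()
    states[tree.root] = rng.choice(w.size, p=w)
    for v in tree.postorder[::-1]:  # preorder
        if v == tree.root:
            continue
        a = states[tree.parent[v]]
        w = P[v][a, :] * L[v]
        s = w.sum()
        if s <= 0:  # numerically impossible branch; fall back to row only
            w = P[v][a, :].copy()
            s = w.sum()
        states[v] = rng.choice(w.size, p=w / s)
    return states


def _path_rejection(
    Q: np.ndarray, t: float, a: int, b: int, rng: np.random.Generator,
    max_attempts: int,
) -> list[tuple[float, int, int]] | None:
    """Forward-simulate paths from ``a``; accept those ending in ``b``."""
    k = Q.shape[0]
    exit_rates = -np.diag(Q)
    for _ in range(max_attempts):
        s, pos, evs = a, 0.0, []
        while True:
            lam = exit_rates[s]
            if lam <= 0:
                break
            pos += rng.exponential(1.0 / lam)
            if pos >= t:
                break
            w = Q[s].copy()
            w[s] = 0.0
            nxt = rng.choice(k, p=w / w.sum())
            evs.append((pos, s, nxt))
            s = nxt
        if s == b:
            return evs
    return None


def _path_uniformization(
    Q: np.ndarray, t: float, a: int, b: int, rng: np.random.Generator,
    max_jumps: int = 10_000,
) -> list[tuple[float, int, int]]:
    """Exact endpoint-conditioned path via uniformization.

    The number of uniformized jumps N is drawn from
    P(N=n | a,b) ∝ Pois(n; Λt) (R^n)_ab with R = I + Q/Λ; intermediate
    states follow the conditioned uniformized chain; virtual (self) jumps
    are discarded; jump times are uniform order statistics on (0, t).
    """
    k = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0 or t <= 0:
        if a != b:
            raise RuntimeError("zero-rate edge with mismatched endpoints")
        return []
    R = np.eye(k) + Q / lam
    mu = lam * t
    # sequential sampling of N: terms w_n = e^-mu mu^n / n! * (R^n)_ab
    u = rng.random()
    Rpowers = [np.eye(k)]
    log_pois = -mu  # log of e^-mu mu^0/0!
    total = 0.0
    terms = []
    pab = None
    n = 0
    # first pass: accumulate normaliser until tail is negligible
    while True:
        w = np.exp(log_pois) * Rpowers[-1][a, b]
        terms.append(w)
        total += w
        n += 1
        if n > max_jumps:
            raise RuntimeError("uniformization failed to converge")
        Rpowers.append(Rpowers[-1] @ R)
        log_pois += np.log(mu) - np.log(n)
        # Poisson tail bound: stop once remaining mass cannot matter
        if n > mu + 10 * np.sqrt(mu) + 20 and np.exp(log_pois) < 1e-14 * max(total, 1e-300):
            break
    if total <= 0:
        raise RuntimeError(f"endpoint pair ({a},{b}) unreachable on edge")
    acc = 0.0
    N = len(terms) - 1
    for i, w in enumerate(terms):
        acc += w / total
        if u <= acc:
            N = i
            break
    # sample intermediate uniformized states s_0=a .. s_N=b
    seq = [a]
    for i in range(1, N):
        prev = seq[-1]
        w = R[prev, :] * Rpowers[N - i][:, b]
        s = w.sum()
        seq.append(int(rng.choice(k, p=w / s)))
    if N >= 1:
        seq.append(b)
    times = np.sort(rng.random(N)) * t
    evs = []
    for pos, (s0, s1) in zip(times, zip(seq[:-1], seq[1:])):
        if s0 != s1:
            evs.append((float(pos), int(s0), int(s1)))
    return evs


def sample_history(
    tree: TimeTree,
    tip_states,
    rm: RateMatrix,
    seed,
    root_prior: str | np.ndarray = "uniform",
    rejection_cap: int = 1000,
) -> SimmapHistory:
    """Draw one stochastic map of a character under rate matrix ``rm``."""
    return sample_histories(tree, tip_states, rm, 1, seed, root_prior,
                            rejection_cap)[0]


def sample_histories(
    tree: TimeTree,
    tip_states,
    rm: RateMatrix,
    n_maps: int,
    seed,
    root_prior: str | np.ndarray = "uniform",
    rejection_cap: int = 1000,
) -> list[SimmapHistory]:
    """Draw ``n_maps`` stochastic maps (shared pruning pass, one RNG)."""
    tip_states = np.asarray(tip_states)
    rng = np.random.default_rng(seed)
    k = rm.k
    lnL, L, _, P = prune_loglik(tree, tip_states, rm, root_prior,
                                return_partials=True)
    if not np.isfinite(lnL):
        raise RuntimeError("cannot map a character with zero likelihood")
    if P is None:  # ER fast path returns no matrices; build them
        P = _edge_probs(rm.Q, tree.edge_length)
    prior = _root_prior(rm, root_prior)
    out = []
    for _ in range(n_maps):
        states = _sample_node_states(tree, L, P, prior, rng)
        events: dict[int, list[tuple[float, int, int]]] = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            a, b = int(states[tree.parent[v]]), int(states[v])
            t = float(tree.edge_length[v])
            if t == 0.0:
                if a != b:
                    raise RuntimeError(f"state change across zero-length edge {v}")
                events[v] = []
                continue
            path = _path_rejection(rm.Q, t, a, b, rng, rejection_cap)
            if path is None:
                path = _path_uniformization(rm.Q, t, a, b, rng)
            events[v] = path
        # tip states must match the data wherever known
        for i in range(tree.n_tips):
            if tip_states[i] != MISSING and states[i] != tip_states[i]:
                raise AssertionError("sampled history contradicts tip data")
        out.append(SimmapHistory(states, events, k))
    return out


def count_transitions(histories: list[SimmapHistory]) -> TransitionSummary:
    """Arithmetic mean of per-map i->j transition counts."""
    if not histories:
        raise ValueError("need at least one history")
    k = histories[0].k
    C = np.zeros((k, k))
    for h in histories:
        if h.k != k:
            raise ValueError("histories have inconsistent state counts")
        C += h.transition_counts()
    return TransitionSummary(C / len(histories), len(histories))


def assign_rate(
    er_fit: MkFit,
    ard_fit: MkFit | None,
    comparison: ModelComparison,
    counts: TransitionSummary | None,
) -> float:
    """Single summary rate for a character after ER-vs-ARD model choice.

    ER winner: the fitted shared rate.  ARD winner: the mean of the fitted
    per-pair rates weighted by the mean number of times each ordered
    transition occurred over the sampled maps; pairs never realised
    contribute nothing.  If no transitions were realised at all (degenerate
    maps), falls back to the unweighted mean of the ARD rates.
    """
    w_er = comparison.weight_of("ER")
    w_ard = comparison.weight_of("ARD") if ard_fit is not None else 0.0
    if w_er >= w_ard or ard_fit is None:
        return float(er_fit.params["rates"])
    if counts is None:
        raise ValueError("ARD winner requires transition counts")
    k = ard_fit.k
    off = ~np.eye(k, dtype=bool)
    q = ard_fit.rate_matrix.Q[off]
    n = counts.mean_counts[off]
    tot = n.sum()
    if tot <= 0:
        return float(q.mean())
    return float((q * n).sum() / tot)


@dataclass
class CharacterAssessment:
    """Per-character results: signal, rate-homogeneity support, rate."""

    char_id: str
    partition: str | None
    k: int
    n_taxa_used: int
    lam: float
    lnL_lambda: float
    lnL_er: float
    lnL_ard: float
    aic_er: float
    aic_ard: float
    er_weight: float
    chosen_model: str
    rate: float
    converged: bool
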