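"""Continuous-time Markov (Mk) machinery for discrete characters.

Everything downstream rests on this module: rate matrices (equal-rates and
all-rates-different parameterisations), transition probabilities, the
Felsenstein pruning likelihood with per-node scaling, Pagel's lambda fitted
jointly with an ER rate, and AIC / Akaike-weight model comparison.

Conventions
-----------
* Rates are expected transitions per Myr; branch lengths are Myr.
* Tip states are dense integers ``0..k-1``; ``-1`` marks a missing score
  and contributes an all-ones partial likelihood.
* The root prior is uniform over the k states by default (configurable to
  the stationary distribution of the fitted Q); the choice is recorded in
  fit metadata.
* Optimisation is in log-rate space, L-BFGS-B, bounds [1e-8, 1e3]
  transitions/Myr, seeded random restarts plus a parsimony-based start
  (minimum number of changes / total tree length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .data_io import MISSING
from .tree import TimeTree

__all__ = [
    "RateMatrix",
    "MkFit",
    "ModelComparison",
    "OptimConfig",
    "build_q",
    "transition_probs",
    "prune_loglik",
    "fit_mk",
    "fit_lambda",
    "aic",
    "akaike_weights",
]

RATE_LO = 1e-8
RATE_HI = 1e3


@dataclass(frozen=True)
class RateMatrix:
    """Instantaneous rate matrix Q with rows summing to zero."""

    Q: np.ndarray
    structure: str = "CUSTOM"  # ER | ARD | CUSTOM

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        k = Q.shape[0]
        if Q.shape != (k, k) or k < 2:
            raise ValueError("Q must be square with k >= 2")
        off = Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(off), initial=0.0)):
            raise ValueError("rows of Q must sum to zero")

    @property
    def k(self) -> int:
        return self.Q.shape[0]

    @property
    def off_diagonal(self) -> np.ndarray:
        """Ordered off-diagonal rates, row-major (q01, q02, ..., q10, ...)."""
        k = self.k
        return self.Q[~np.eye(k, dtype=bool)].reshape(k, k - 1).ravel()

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left null vector of Q, normalised)."""
        w, v = np.linalg.eig(self.Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def build_q(k: int, rates, structure: str = "ER") -> RateMatrix:
    """Assemble a k-state rate matrix.

    ER takes a single rate shared by every ordered state pair; ARD takes
    ``k*(k-1)`` rates filling the off-diagonal row-major (q_01, q_02, ...,
    q_10, q_12, ...).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    Q = np.zeros((k, k))
    if structure == "ER":
        if rates.size != 1:
            raise ValueError("ER takes exactly one rate")
        Q[:] = rates[0]
        np.fill_diagonal(Q, 0.0)
    elif structure == "ARD":
        if rates.size != k * (k - 1):
            raise ValueError(f"ARD with k={k} takes {k * (k - 1)} rates")
        Q[~np.eye(k, dtype=bool)] = rates.reshape(k, k - 1).reshape(-1)
        # note: boolean assignment is row-major, matching off_diagonal
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, structure)


def transition_probs(rm: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1."""
    if t < 0:
        raise ValueError("time must be non-negative")
    Q = rm.Q if isinstance(rm, RateMatrix) else np.asarray(rm, dtype=float)
    k = Q.shape[0]
    struct = rm.structure if isinstance(rm, RateMatrix) else "CUSTOM"
    if struct == "ER":
        q = Q[0, 1]
        e = np.exp(-k * q * t)
        P = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(P, 1.0 / k + (1.0 - 1.0 / k) * e)
        return P
    P = expm(Q * t)
    return np.clip(P, 0.0, 1.0)


def _edge_probs(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for a batch of times, via eigendecomposition when stable.

    Returns an array of shape ``(len(ts), k, k)``.  Falls back to expm per
    time when the eigenvector matrix is ill-conditioned (defective Q).
    """
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            E = np.exp(np.multiply.outer(ts, w))  # (m, k)
            P = np.einsum("ij,mj,jl->mil", V, E, Vinv)
            P = np.real(P)
            return np.clip(P, 0.0, 1.0)
    except np.linalg.LinAlgError:
        pass
    return np.stack([np.clip(expm(Q * t), 0.0, 1.0) for t in ts])


# ----------------------------------------------------------------------
# pruning likelihood
# ----------------------------------------------------------------------

def _tip_partials(tree: TimeTree, tip_states: np.ndarray, k: int) -> np.ndarray:
    L = np.ones((tree.n_nodes, k))
    for i in range(tree.n_tips):
        s = int(tip_states[i])
        if s == MISSING:
            continue
        if s < 0 or s >= k:
            raise ValueError(f"tip state {s} out of range for k={k}")
        L[i] = 0.0
        L[i, s] = 1.0
    return L


def prune_loglik(
    tree: TimeTree,
    tip_states,
    rm: RateMatrix,
    root_prior: str | np.ndarray = "uniform",
    return_partials: bool = False,
):
    """Felsenstein pruning log-likelihood of a character on a tree.

    Missing tips (state ``-1``) contribute all-ones partials.  Partial
    likelihoods are rescaled at every internal node, with the scale factors
    accumulated in log space, so deep trees and slow rates do not
    underflow.  Polytomies are handled naturally (product over any number
    of children).

    With ``return_partials=True`` also returns the (unscaled-shape) partial
    likelihood array, per-node log scale factors and the per-edge
    transition matrices — the ingredients stochastic mapping needs.
    """
    tip_states = np.asarray(tip_states)
    k = rm.k
    L = _tip_partials(tree, tip_states, k)
    log_scale = np.zeros(tree.n_nodes)

    er = rm.structure == "ER"
    if er:
        q = rm.Q[0, 1]
        e = np.exp(-k * q * tree.edge_length)
        p_same = 1.0 / k + (1.0 - 1.0 / k) * e
        p_diff = (1.0 - e) / k
        P = None
    else:
        P = _edge_probs(rm.Q, tree.edge_length)

    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        acc = np.ones(k)
        sc = 0.0
        for c in kids:
            if er:
                s = L[c].sum()
                msg = p_diff[c] * s + (p_same[c] - p_diff[c]) * L[c]
            else:
                msg = P[c] @ L[c]
            acc = acc * msg
            sc += log_scale[c]
        m = acc.max()
        if m <= 0.0 or not np.isfinite(m):
            # impossible data under this Q (numerically zero likelihood)
            if return_partials:
                return -np.inf, L, log_scale, P
            return -np.inf
        L[v] = acc / m
        log_scale[v] = sc + np.log(m)

    prior = _root_prior(rm, root_prior)
    lik = float(prior @ L[tree.root])
    if lik <= 0.0:
        lnL = -np.inf
    else:
        lnL = np.log(lik) + log_scale[tree.root]
    if return_partials:
        return lnL, L, log_scale, P
    return lnL


def _root_prior(rm: RateMatrix, root_prior) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            return np.full(rm.k, 1.0 / rm.k)
        if root_prior == "stationary":
            return rm.stationary()
        raise ValueError(f"unknown root prior {root_prior!r}")
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (rm.k,) or np.any(prior < 0):
        raise ValueError("root prior must be a length-k non-negative vector")
    return prior / prior.sum()


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class OptimConfig:
    """Optimiser settings shared by all Mk fits."""

    rate_lo: float = RATE_LO
    rate_hi: float = RATE_HI
    n_restarts: int = 5
    seed: int = 0
    root_prior: str = "uniform"
    lambda_grid: int = 11  # profile grid points on [0, 1]


@dataclass
class MkFit:
    """A fitted Mk model (ER, ARD or lambda+ER)."""

    model: str  # ER | ARD | LAMBDA_ER
    lnL: float
    params: dict
    n_free: int
    converged: bool
    n_restarts_used: int
    k: int
    rate_matrix: RateMatrix | None = None
    root_prior: str = "uniform"

    @property
    def aic(self) -> float:
        return aic(self.lnL, self.n_free)


def aic(lnL: float, n_free: int) -> float:
    """Akaike information criterion, 2*n_free - 2*lnL."""
    if n_free < 1:
        raise ValueError("n_free must be >= 1")
    return 2.0 * n_free - 2.0 * lnL


def akaike_weights(aics) -> np.ndarray:
    """exp(-delta_i/2) normalised; delta_i = AIC_i - min AIC."""
    a = np.asarray(aics, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two AIC values")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite AIC")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelComparison:
    """Candidate fits compared by AIC / Akaike weights.

    Exact AIC ties resolve to the model listed first (callers list ER
    before ARD, so the simpler model wins ties).
    """

    fits: list[MkFit]
    delta: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        aics = np.array([f.aic for f in self.fits])
        self.delta = aics - aics.min()
        self.weights = akaike_weights(aics)

    @property
    def best(self) -> MkFit:
        return self.fits[int(np.argmin(self.delta))]

    def weight_of(self, model: str) -> float:
        for f, w in zip(self.fits, self.weights):
            if f.model == model:
                return float(w)
        raise KeyError(model)


def parsimony_changes(tree: TimeTree, tip_states: np.ndarray, k: int) -> int:
    """Fitch count of the minimum number of state changes (missing = any)."""
    full = (1 << k) - 1
    sets = np.zeros(tree.n_nodes, dtype=np.int64)
    for i in range(tree.n_tips):
        s = int(tip_states[i])
        sets[i] = full if s == MISSING else (1 << s)
    changes = 0
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        inter = full
        union = 0
        for c in kids:
            inter &= sets[c]
            union |= sets[c]
        if inter:
            sets[v] = inter
        else:
            sets[v] = union
            changes += 1
    return changes


def _heuristic_rate(tree: TimeTree, tip_states: np.ndarray, k: int,
                    cfg: OptimConfig) -> float:
    total = tree.total_length()
    if total <= 0:
        return 1.0
    changes = max(parsimony_changes(tree, tip_states, k), 1)
    return float(np.clip(changes / total, cfg.rate_lo * 10, cfg.rate_hi / 10))


def _shrink_to_plateau_edge(negll, x_opt: np.ndarray, f_opt: float, lo: float,
                            tol: float = 1e-6, iters: int = 40) -> np.ndarray:
    """Smallest rates attaining the optimum, coordinate-wise.

    Above the saturation rate the Mk likelihood is flat, so the optimiser
    can stop anywhere on the plateau; reported rates would then depend on
    the starting point.  For each coordinate, bisect down to the smallest
    log-rate whose joint negative log-likelihood stays within ``tol`` of
    the optimum.  Interior (identified) optima are left untouched because
    any decrease immediately costs likelihood.
    """
    x = np.array(x_opt, dtype=float)
    budget = f_opt + tol
    for j in range(x.size):
        if x[j] <= lo:
            continue
        trial = x.copy()
        trial[j] = lo
        if negll(trial) <= budget:
            x = trial
            continue
        hi_j, lo_j = x[j], lo
        for _ in range(iters):
            mid = 0.5 * (hi_j + lo_j)
            trial[j] = mid
            if negll(trial) <= budget:
                hi_j = mid
            else:
                lo_j = mid
        trial[j] = hi_j
        x = trial
    return x


def fit_mk(
    tree: TimeTree,
    tip_states,
    structure: str = "ER",
    config: OptimConfig | None = None,
    k: int | None = None,
) -> MkFit:
    """Maximum-likelihood fit of an ER or ARD Mk model.

    Needs at least 3 tips with known states and k >= 2 observed states.
    Optimisation runs in log-rate space from a parsimony-based start plus
    seeded random restarts; the best optimum is kept and the convergence
    flag reflects whether any start converged.
    """
    cfg = config or OptimConfig()
    tip_states = np.asarray(tip_states)
    known = tip_states[: tree.n_tips] != MISSING
    if known.sum() < 3:
        raise ValueError("need at least 3 known-scored tips")
    if k is None:
        k = int(tip_states[: tree.n_tips][known].max()) + 1
    if k < 2:
        raise ValueError("need k >= 2 observed states")
    n_par = 1 if structure == "ER" else k * (k - 1)
    if structure not in ("ER", "ARD"):
        raise ValueError(f"unknown structure {structure!r}")

    lo, hi = np.log(cfg.rate_lo), np.log(cfg.rate_hi)

    def negll(logr: np.ndarray) -> float:
        rm = build_q(k, np.exp(logr), structure)
        ll = prune_loglik(tree, tip_states, rm, cfg.root_prior)
        return -ll if np.isfinite(ll) else 1e300

    rng = np.random.default_rng(cfg.seed)
    r0 = _heuristic_rate(tree, tip_states, k, cfg)
    starts = [np.full(n_par, np.log(r0))]
    for _ in range(cfg.n_restarts):
        starts.append(rng.uniform(np.log(1e-5), np.log(10.0), size=n_par))

    best = None
    any_ok = False
    used = 0
    for x0 in starts:
        used += 1
        res = minimize(negll, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * n_par)
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x_best = _shrink_to_plateau_edge(negll, best.x, best.fun, lo)
    rates = np.exp(x_best)
    lnL = -float(min(best.fun, negll(x_best)))
    rm = build_q(k, rates, structure)
    params = {"rates": rates if n_par > 1 else float(rates[0])}
    return MkFit(structure, lnL, params, n_par,
                 converged=any_ok, n_restarts_used=used, k=k,
                 rate_matrix=rm, root_prior=cfg.root_prior)


def fit_lambda(
    tree: TimeTree,
    tip_states,
    config: OptimConfig | None = None,
    k: int | None = None,
) -> MkFit:
    """Joint MLE of (lambda, q) for the lambda-transformed ER model.

    Pagel's lambda scales internal branches while preserving tip depths;
    the profile likelihood over a lambda grid on [0, 1] (re-optimising the
    single ER rate at each point) is refined by a bounded scalar search
    around the best grid point.  lambda near 1 means the character's state
    distribution tracks the tree; near 0, independence of phylogeny.
    """
    cfg = config or OptimConfig()
    tip_states = np.asarray(tip_states)
    known = tip_states[: tree.n_tips] != MISSING
    if known.sum() < 3:
        raise ValueError("need at least 3 known-scored tips")
    if k is None:
        k = int(tip_states[: tree.n_tips][known].max()) + 1
    if k < 2:
        raise ValueError("need k >= 2 observed states")
    tree.require_ultrametric()

    lo, hi = np.log(cfg.rate_lo), np.log(cfg.rate_hi)
    r0 = _heuristic_rate(tree, tip_states, k, cfg)
    cache: dict[float, tuple[float, float]] = {}

    def profile(lam: float) -> tuple[float, float]:
        """Best (lnL, q) at a fixed lambda."""
        lam = float(np.clip(lam, 0.0, 1.0))
        key = round(lam, 12)
        if key in cache:
            return cache[key]
        tlam = tree.lambda_transform(lam)

        def neg(logq: float) -> float:
            rm = build_q(k, np.exp(logq), "ER")
            ll = prune_loglik(tlam, tip_states, rm, cfg.root_prior)
            return -ll if np.isfinite(ll) else 1e300

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        # guard against the bounded search settling far from the
        # parsimony-scale rate on a flat shoulder
        cand = [(-res.fun, float(np.exp(res.x))), (-neg(np.log(r0)), r0)]
        best = max(cand)
        cache[key] = best
        return best

    grid = np.linspace(0.0, 1.0, cfg.lambda_grid)
    prof = [profile(l) for l in grid]
    i_best = int(np.argmax([p[0] for p in prof]))
    a = grid[max(i_best - 1, 0)]
    b = grid[min(i_best + 1, len(grid) - 1)]
    if b > a:
        res = minimize_scalar(lambda l: -profile(l)[0], bounds=(a, b),
                              method="bounded", options={"xatol": 1e-4})
        lam_hat = float(np.clip(res.x, 0.0, 1.0))
    else:
        lam_hat = float(grid[i_best])
    # keep whichever of grid-best / refined is better
    cand = [(prof[i_best][0], float(grid[i_best])), (profile(lam_hat)[0], lam_hat)]
    lnL, lam_hat = max((ll, l) for ll, l in cand)
    _, q_hat = profile(lam_hat)
    rm = build_q(k, q_hat, "ER")
    return MkFit("LAMBDA_ER", float(lnL), {"lambda": lam_hat, "q": q_hat},
                 n_free=2, converged=True, n_restarts_used=len(grid), k=k,
                 rate_matrix=rm, root_prior=cfg.root_prior)
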