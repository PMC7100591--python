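"""Correlated-evolution test for binary character pairs (Pagel 1994).

Two binary characters are recoded as one four-state joint character
(00 -> 0, 01 -> 1, 10 -> 2, 11 -> 3) and two Markov models are fitted to
it on the same tree:

* independent — each trait keeps its own gain and loss rate regardless of
  the other trait's state (4 free rates);
* dependent — each trait's gain and loss rates may differ with the state
  of the other trait (8 free rates).

Simultaneous double transitions (00<->11, 01<->10) have rate zero in both
models.  The models are compared by AIC; the Akaike weight of the
independent model is the per-pair measure of how well the pair obeys the
independence assumption (1 = independent, 0 = strongly correlated).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data_io import MISSING, CharacterMatrix
from .mk import MkFit, OptimConfig, RateMatrix, akaike_weights, prune_loglik
from .tree import TimeTree

__all__ = [
    "PairResult",
    "combine_binary",
    "build_pagel_q",
    "fit_independent",
    "fit_dependent",
    "compare_pair",
    "independence_scan",
]

logger = logging.getLogger("morphosig")

# joint-state encoding: 0=(x0,y0) 1=(x0,y1) 2=(x1,y0) 3=(x1,y1)
_INDEP_SLOTS = [
    # (i, j, param index): x gains/losses use params 0/1, y use 2/3
    (0, 2, 0), (1, 3, 0),  # x: 0->1 (alpha_x)
    (2, 0, 1), (3, 1, 1),  # x: 1->0 (beta_x)
    (0, 1, 2), (2, 3, 2),  # y: 0->1 (alpha_y)
    (1, 0, 3), (3, 2, 3),  # y: 1->0 (beta_y)
]
_DEP_SLOTS = [
    # each single-trait transition gets its own rate, indexed by context
    (0, 2, 0),  # x 0->1 | y=0
    (1, 3, 1),  # x 0->1 | y=1
    (2, 0, 2),  # x 1->0 | y=0
    (3, 1, 3),  # x 1->0 | y=1
    (0, 1, 4),  # y 0->1 | x=0
    (2, 3, 5),  # y 0->1 | x=1
    (1, 0, 6),  # y 1->0 | x=0
    (3, 2, 7),  # y 1->0 | x=1
]


def combine_binary(x, y) -> np.ndarray:
    """Joint 4-state recoding of two binary characters.

    A taxon unknown in either member is MISSING in the joint character.
    Raises if either character shows a state outside {0, 1}.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("characters must score the same taxa")
    for name, arr in (("x", x), ("y", y)):
        known = arr[arr != MISSING]
        if known.size and known.max() > 1:
            raise ValueError(f"character {name} is not binary")
    joint = 2 * x + y
    joint[(x == MISSING) | (y == MISSING)] = MISSING
    return joint.astype(np.int16)


def build_pagel_q(rates, dependent: bool) -> RateMatrix:
    """Four-state rate matrix with double transitions fixed at zero."""
    slots = _DEP_SLOTS if dependent else _INDEP_SLOTS
    n_par = 8 if dependent else 4
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (n_par,):
        raise ValueError(f"expected {n_par} rates, got {rates.shape}")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    Q = np.zeros((4, 4))
    for i, j, p in slots:
        Q[i, j] = rates[p]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, "CUSTOM")


def _fit_pagel(
    tree: TimeTree, joint_states: np.ndarray, dependent: bool,
    cfg: OptimConfig,
) -> MkFit:
    n_par = 8 if dependent else 4
    lo, hi = np.log(cfg.rate_lo), np.log(cfg.rate_hi)

    def negll(logr: np.ndarray) -> float:
        rm = build_pagel_q(np.exp(logr), dependent)
        ll = prune_loglik(tree, joint_states, rm, cfg.root_prior)
        return -ll if np.isfinite(ll) else 1e300

    total = tree.total_length()
    r0 = np.log(max(2.0 / max(total, 1e-9), cfg.rate_lo * 10))
    rng = np.random.default_rng(cfg.seed)
    starts = [np.full(n_par, r0)]
    for _ in range(cfg.n_restarts):
        starts.append(rng.uniform(np.log(1e-5), np.log(10.0), size=n_par))
    best, any_ok = None, False
    for x0 in starts:
        res = minimize(negll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * n_par)
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    return MkFit(
        "DEP" if dependent else "INDEP", -float(best.fun),
        {"rates": rates}, n_par, converged=any_ok,
        n_restarts_used=len(starts), k=4,
        rate_matrix=build_pagel_q(rates, dependent), root_prior=cfg.root_prior,
    )


def fit_independent(tree: TimeTree, joint_states, config: OptimConfig | None = None) -> MkFit:
    """MLE of the 4-rate independent model on the joint character."""
    return _fit_pagel(tree, np.asarray(joint_states), False, config or OptimConfig())


def fit_dependent(tree: TimeTree, joint_states, config: OptimConfig | None = None) -> MkFit:
    """MLE of the 8-rate dependent model on the joint character."""
    return _fit_pagel(tree, np.asarray(joint_states), True, config or OptimConfig())


@dataclass
class PairResult:
    """Independence test result for one character pair."""

    char_x: str
    char_y: str
    partition: str | None
    n_taxa_used: int
    lnL_indep: float
    lnL_dep: float
    aic_indep: float
    aic_dep: float
    w_indep: float

    @property
    def w_dep(self) -> float:
        return 1.0 - self.w_indep


def compare_pair(
    tree: TimeTree,
    x,
    y,
    config: OptimConfig | None = None,
    partition: str | None = None,
    ids: tuple[str, str] = ("x", "y"),
) -> PairResult:
    """Fit both models to one binary pair and compare by Akaike weight."""
    cfg = config or OptimConfig()
    joint = combine_binary(x, y)
    known = joint != MISSING
    if known.sum() < 3:
        raise ValueError("fewer than 3 jointly known-scored taxa")
    fit_i = _fit_pagel(tree, joint, False, cfg)
    fit_d = _fit_pagel(tree, joint, True, cfg)
    # enforce nesting numerically: the dependent model contains the
    # independent optimum, so restart it from there if it fell short
    if fit_d.lnL < fit_i.lnL:
        r = fit_i.params["rates"]
        x0 = np.log(np.clip(np.repeat(r, 2), cfg.rate_lo, cfg.rate_hi))
        res = minimize(
            lambda lr: -prune_loglik(tree, joint, build_pagel_q(np.exp(lr), True),
                                     cfg.root_prior),
            x0, method="L-BFGS-B",
            bounds=[(np.log(cfg.rate_lo), np.log(cfg.rate_hi))] * 8,
        )
        if -res.fun > fit_d.lnL:
            rates = np.exp(res.x)
            fit_d = MkFit("DEP", -float(res.fun), {"rates": rates}, 8,
                          converged=True, n_restarts_used=fit_d.n_restarts_used + 1,
                          k=4, rate_matrix=build_pagel_q(rates, True),
                          root_prior=cfg.root_prior)
    w = akaike_weights([fit_i.aic, fit_d.aic])
    return PairResult(
        ids[0], ids[1], partition, int(known.sum()),
        fit_i.lnL, fit_d.lnL, fit_i.aic, fit_d.aic, float(w[0]),
    )


def independence_scan(
    tree: TimeTree,
    matrix: CharacterMatrix,
    partitions: dict[str, str],
    config: OptimConfig | None = None,
    max_unknown_frac: float = 0.25,
    cross_partition: bool = False,
    max_pairs: int | None = None,
    seed: int = 0,
) -> list[PairResult]:
    """Independence test over all binary character pairs within partitions.

    Pairs are formed within each partition (``cross_partition=True`` lifts
    the restriction).  For each pair, taxa unknown in either character are
    dropped and the unknown-fraction exclusion rule is applied to the
    pair's joint unknown fraction.  ``max_pairs`` draws a seeded random
    subsample of the candidate pairs, for desk-scale runs.
    """
    cfg = config or OptimConfig()
    binary = [c for c in matrix.char_ids if matrix.n_states(c) == 2]
    if cross_partition:
        candidates = [(a, b, None) for a, b in itertools.combinations(binary, 2)]
    else:
        candidates = []
        for part in sorted(set(partitions.get(c) for c in binary) - {None}):
            members = [c for c in binary if partitions.get(c) == part]
            candidates.extend((a, b, part) for a, b in itertools.combinations(members, 2))
    if max_pairs is not None and len(candidates) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=max_pairs, replace=False)
        candidates = [candidates[i] for i in sorted(idx)]
    results = []
    for a, b, part in candidates:
        joint = combine_binary(matrix.column(a), matrix.column(b))
        known = joint != MISSING
        n_unknown = int((~known).sum())
        if n_unknown > max_unknown_frac * matrix.n_taxa:
            logger.info("pair (%s,%s): skipped, %d/%d jointly unknown",
                        a, b, n_unknown, matrix.n_taxa)
            continue
        if known.sum() < 3:
            logger.info("pair (%s,%s): skipped, <3 jointly known taxa", a, b)
            continue
        keep = [t for t, m in zip(matrix.taxa, known) if m]
        sub = tree.prune_to(keep) if n_unknown else tree
        st = {t: int(s) for t, s in zip(matrix.taxa, joint) if s != MISSING}
        joint_sub = np.array([st[t] for t in sub.labels], dtype=np.int16)
        xs = joint_sub // 2
        ys = joint_sub % 2
        if np.unique(xs).size < 2 or np.unique(ys).size < 2:
            logger.info("pair (%s,%s): skipped, a member is invariant on the "
                        "joint view", a, b)
            continue
        try:
            results.append(compare_pair(sub, xs, ys, cfg, part, (a, b)))
        except Exception as exc:  # per-pair failures must not kill the scan
            logger.warning("pair (%s,%s): fit failed: %s", a, b, exc)
    return results
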