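"""End-to-end orchestration of the partition analysis.

Stages, mirroring the analysis protocol:

1. ``run_assess`` — per retained, non-excluded character: Pagel's lambda
   (joint with an ER rate), ER and ARD Mk fits compared by Akaike weight,
   and an assigned evolutionary rate (the ER rate, or the stochastic-map
   transition-weighted mean of the ARD rates).
2. ``run_pairs`` — Pagel independence test over binary pairs within
   partitions.
3. ``run_compare`` — partition-level GLS null/H1 comparisons for each
   metric, per-partition medians, and Kendall's tau correlations.

Every stage is a pure function of (inputs, config, seed): per-character
and per-pair RNG streams are fanned out deterministically from the master
seed keyed by character id, so a subset run reproduces the corresponding
rows of a full run.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (CharacterMatrix, CharacterView, character_view,
                      load_partitions, read_matrix, reconcile,
                      validate_partitions)
from .mk import ModelComparison, OptimConfig, fit_lambda, fit_mk
from .pairs import PairResult, independence_scan
from .partition_stats import PartitionSummary, gls_compare, partition_summary
from .simmap import (CharacterAssessment, assign_rate, count_transitions,
                     sample_histories)
from .tree import TimeTree, read_tree

__all__ = ["RunConfig", "assess_character", "run_assess", "run_pairs",
           "run_compare", "load_inputs"]

logger = logging.getLogger("morphosig")


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the analysis defaults."""

    tree_path: str | None = None
    tree_schema: str = "newick"
    matrix_path: str | None = None
    partitions_path: str | None = None
    max_unknown_frac: float = 0.25
    n_maps: int = 1000
    seed: int = 0
    optim: OptimConfig = field(default_factory=OptimConfig)
    cross_partition_pairs: bool = False
    max_pairs: int | None = None
    root_prior: str = "uniform"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_unknown_frac < 1.0):
            raise ValueError("max_unknown_frac must be in (0, 1)")
        if self.n_maps < 1:
            raise ValueError("n_maps must be >= 1")
        if self.optim.root_prior != self.root_prior:
            self.optim = replace(self.optim, root_prior=self.root_prior)

    def char_seed(self, char_id: str) -> int:
        """Deterministic per-character seed fanned out from the master."""
        h = hashlib.sha256(f"{self.seed}:{char_id}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def metadata(self) -> dict:
        return {
            "package": f"morphosig {__version__}",
            "seed": self.seed,
            "root_prior": self.root_prior,
            "n_maps": self.n_maps,
            "max_unknown_frac": self.max_unknown_frac,
            "pairing": "cross-partition" if self.cross_partition_pairs
                       else "within-partition",
            "tau_variant": "tau-b",
        }


def load_inputs(config: RunConfig):
    """Read and reconcile the three input files named in the config."""
    tree = read_tree(config.tree_path, config.tree_schema)
    matrix = read_matrix(config.matrix_path)
    tree, matrix, report = reconcile(tree, matrix)
    partitions = load_partitions(config.partitions_path)
    validate_partitions(matrix, partitions)
    return tree, matrix, partitions, report


def assess_character(
    view: CharacterView,
    config: RunConfig,
    partition: str | None = None,
) -> CharacterAssessment:
    """Full per-character assessment on an included character view."""
    if view.excluded:
        raise ValueError(f"character {view.char_id} is excluded: {view.reason}")
    tree, states = view.tree, view.tip_states
    seed = config.char_seed(view.char_id)
    opt = replace(config.optim, seed=seed)
    lam_fit = fit_lambda(tree, states, opt)
    er_fit = fit_mk(tree, states, "ER", opt)
    ard_fit = fit_mk(tree, states, "ARD", opt)
    comparison = ModelComparison([er_fit, ard_fit])  # ER first: ties -> ER
    er_weight = float(comparison.weights[0])
    chosen = "ER" if er_weight >= comparison.weights[1] else "ARD"
    counts = None
    if chosen == "ARD":
        histories = sample_histories(
            tree, states, ard_fit.rate_matrix, config.n_maps,
            seed=np.random.SeedSequence([seed, 1]),
            root_prior=config.root_prior,
        )
        counts = count_transitions(histories)
    rate = assign_rate(er_fit, ard_fit, comparison, counts)
    return CharacterAssessment(
        char_id=view.char_id, partition=partition, k=view.k,
        n_taxa_used=tree.n_tips, lam=float(lam_fit.params["lambda"]),
        lnL_lambda=lam_fit.lnL, lnL_er=er_fit.lnL, lnL_ard=ard_fit.lnL,
        aic_er=er_fit.aic, aic_ard=ard_fit.aic, er_weight=er_weight,
        chosen_model=chosen, rate=float(rate),
        converged=er_fit.converged and ard_fit.converged,
    )


def run_assess(
    tree: TimeTree,
    matrix: CharacterMatrix,
    partitions: dict[str, str],
    config: RunConfig,
) -> tuple[list[CharacterAssessment], list[CharacterView]]:
    """Assess every retained character; collect exclusions with reasons."""
    assessments, excluded = [], []
    for cid in matrix.char_ids:
        view = character_view(tree, matrix, cid, config.max_unknown_frac)
        if view.excluded:
            logger.info("character %s excluded: %s", cid, view.reason)
            excluded.append(view)
            continue
        try:
            assessments.append(assess_character(view, config, partitions.get(cid)))
        except Exception as exc:
            logger.warning("character %s: assessment failed: %s", cid, exc)
            view.excluded, view.reason = True, f"fit failed: {exc}"
            excluded.append(view)
    return assessments, excluded


def run_pairs(
    tree: TimeTree,
    matrix: CharacterMatrix,
    partitions: dict[str, str],
    config: RunConfig,
) -> list[PairResult]:
    """Independence scan with the run's optimiser settings and seed."""
    opt = replace(config.optim, seed=config.char_seed("pairs"))
    return independence_scan(
        tree, matrix, partitions, opt,
        max_unknown_frac=config.max_unknown_frac,
        cross_partition=config.cross_partition_pairs,
        max_pairs=config.max_pairs, seed=config.char_seed("pair-subsample"),
    )


def run_compare(
    assessments: list[CharacterAssessment],
    pair_results: list[PairResult],
    partitions: dict[str, str],
) -> tuple[dict[str, pd.DataFrame], PartitionSummary]:
    """Partition-level GLS comparisons and the summary/correlation tables.

    Returns one tidy DataFrame per metric (lambda, ER weight, rate across
    characters; independent-model weight across pairs), each with a row
    per focal partition, plus the :class:`PartitionSummary`.
    """
    per_char = pd.DataFrame([
        {"partition": a.partition or partitions.get(a.char_id),
         "lambda": a.lam, "er_weight": a.er_weight, "rate": a.rate}
        for a in assessments
    ])
    metrics = {"lambda": "lambda", "er_weight": "er_weight", "rate": "rate"}
    reports: dict[str, pd.DataFrame] = {}
    for name, col in metrics.items():
        rows = []
        for part in sorted(per_char["partition"].dropna().unique()):
            try:
                c = gls_compare(per_char[col], per_char["partition"], part, name)
            except ValueError as exc:
                logger.warning("GLS %s / %s skipped: %s", name, part, exc)
                continue
            rows.append(vars(c))
        reports[name] = pd.DataFrame(rows)
    if pair_results:
        w = [p.w_indep for p in pair_results]
        lab = [p.partition for p in pair_results]
        rows = []
        for part in sorted({l for l in lab if l is not None}):
            try:
                c = gls_compare(w, lab, part, "w_indep")
            except ValueError as exc:
                logger.warning("GLS w_indep / %s skipped: %s", part, exc)
                continue
            rows.append(vars(c))
        reports["w_indep"] = pd.DataFrame(rows)
    summary = partition_summary(assessments, pair_results, partitions)
    return reports, summary


# ----------------------------------------------------------------------
# tidy CSV export with a metadata header
# ----------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path, config: RunConfig) -> None:
    """Write a tidy table with ``#``-prefixed run-metadata header lines."""
    with open(path, "w") as fh:
        for key, val in config.metadata().items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def assessments_frame(assessments: list[CharacterAssessment],
                      excluded: list[CharacterView]) -> pd.DataFrame:
    rows = [vars(a) for a in assessments]
    df = pd.DataFrame(rows)
    if excluded:
        ex = pd.DataFrame([
            {"char_id": v.char_id, "excluded_reason": v.reason}
            for v in excluded
        ])
        df = pd.concat([df, ex], ignore_index=True)
    return df


def pairs_frame(pair_results: list[PairResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pair_results])
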