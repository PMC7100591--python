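"""Character matrices, taxon reconciliation and partition maps.

Discrete morphological matrices arrive as NEXUS CHARACTERS/DATA blocks.
Cells may be scored with a definite state symbol, unknown (``?``), a gap
(``-``) or a polymorphic/ambiguous set such as ``{01}``.  Everything that is
not a single definite state is treated as missing (the analyses below only
distinguish "known state" from "unknown"); the gap symbol is folded into
missing by default because matrices of this kind rarely give it a distinct
meaning.  States of each character are recoded to dense integers
``0..k-1`` in order of first appearance down the taxon list.

The reconciliation step mirrors the standard protocol for optimising
morphological characters over an independently derived molecular tree: drop
taxa absent from either source, then drop characters left invariant, then —
per character — drop unknown-scored taxa from the tree and exclude the
character entirely when more than a configurable fraction (default 25%) of
the reconciled taxa are unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .tree import TimeTree, TreeError

__all__ = [
    "MISSING",
    "PARTITION_LABELS",
    "PARTITION_ALIASES",
    "CharacterMatrix",
    "CharacterView",
    "MatrixError",
    "PartitionError",
    "ReconciliationError",
    "read_matrix",
    "reconcile",
    "character_view",
    "load_partitions",
    "normalise_partition_label",
]

logger = logging.getLogger("morphosig")

#: Sentinel for unknown / inapplicable / polymorphic scores.
MISSING: int = -1

#: Canonical skeletal-region partition labels.
PARTITION_LABELS = ("teeth", "skull", "vertebrae", "forelimb", "hindlimb", "soft_tissue")

#: Accepted synonyms -> canonical label.
PARTITION_ALIASES: dict[str, str] = {
    "teeth": "teeth",
    "dental": "teeth",
    "tooth": "teeth",
    "skull": "skull",
    "cranial": "skull",
    "cranium": "skull",
    "vertebrae": "vertebrae",
    "axial": "vertebrae",
    "vertebral": "vertebrae",
    "forelimb": "forelimb",
    "pectoral": "forelimb",
    "hindlimb": "hindlimb",
    "pelvic": "hindlimb",
    "soft_tissue": "soft_tissue",
    "soft tissue": "soft_tissue",
    "soft-tissue": "soft_tissue",
    "soft": "soft_tissue",
}


class MatrixError(ValueError):
    """Malformed character matrix input."""


class ReconciliationError(ValueError):
    """Tree and matrix cannot be reconciled (too few shared taxa)."""


class PartitionError(ValueError):
    """Invalid or incomplete character -> partition mapping."""


@dataclass
class CharacterMatrix:
    """Taxa x discrete characters, densely recoded, with MISSING = -1.

    ``states`` is an ``(n_taxa, n_chars)`` integer array; ``char_ids`` keeps
    the original character identifiers (1-based column numbers for NEXUS
    input) so partition maps survive filtering.
    """

    taxa: list[str]
    states: np.ndarray
    char_ids: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.shape != (len(self.taxa), len(self.char_ids)):
            raise MatrixError("states shape does not match taxa x characters")
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon labels in matrix")
        if len(set(self.char_ids)) != len(self.char_ids):
            raise MatrixError("duplicate character ids")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.char_ids)

    def column(self, char_id: str) -> np.ndarray:
        return self.states[:, self.char_ids.index(str(char_id))]

    def score(self, taxon: str, char_id: str) -> int:
        return int(self.states[self.taxa.index(taxon), self.char_ids.index(str(char_id))])

    def n_states(self, char_id: str) -> int:
        col = self.column(char_id)
        known = col[col != MISSING]
        return int(known.max()) + 1 if known.size else 0

    def recoded(self) -> "CharacterMatrix":
        """Recode every character's observed states to dense 0..k-1."""
        out = self.states.copy()
        for j in range(self.n_chars):
            col = out[:, j]
            known = np.unique(col[col != MISSING])
            remap = {int(s): i for i, s in enumerate(known)}
            for s, i in remap.items():
                col[self.states[:, j] == s] = i
        return CharacterMatrix(list(self.taxa), out, list(self.char_ids))

    def subset_taxa(self, keep: list[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in keep]
        return CharacterMatrix(list(keep), self.states[idx, :], list(self.char_ids))

    def subset_chars(self, keep_ids: list[str]) -> "CharacterMatrix":
        idx = [self.char_ids.index(c) for c in keep_ids]
        return CharacterMatrix(list(self.taxa), self.states[:, idx], list(keep_ids))


def read_matrix(path) -> CharacterMatrix:
    """Read a NEXUS discrete character matrix.

    ``?``, the gap symbol and polymorphic/ambiguous scores (``{01}``,
    ``(01)``) all map to :data:`MISSING`; definite states are recoded
    densely per character.  Character ids are 1-based column numbers as
    strings.
    """
    try:
        data = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises assorted error types
        raise MatrixError(f"failed to parse NEXUS matrix {path}: {exc}") from exc
    taxa = [t.label for t in data.taxon_namespace]
    nchar = max((len(data[t]) for t in data.taxon_namespace), default=0)
    states = np.full((len(taxa), nchar), MISSING, dtype=np.int16)
    for i, taxon in enumerate(data.taxon_namespace):
        seq = data[taxon]
        if len(seq) != nchar:
            raise MatrixError(
                f"taxon {taxon.label!r}: row length {len(seq)} != NCHAR {nchar}"
            )
        for j, cell in enumerate(seq):
            states[i, j] = _decode_cell(cell, taxon.label, j)
    matrix = CharacterMatrix(taxa, states, [str(j + 1) for j in range(nchar)])
    return matrix.recoded()


def _decode_cell(cell, taxon: str, j: int) -> int:
    """Map a dendropy state cell to a dense-codeable int or MISSING."""
    state = getattr(cell, "value", cell)  # CharacterDataCell vs StateIdentity
    fundamental = state.fundamental_states
    if len(fundamental) != 1:
        return MISSING  # ?, gap-as-missing, polymorphic, ambiguous
    sym = next(iter(fundamental)).symbol
    if sym in ("?", "-"):
        return MISSING
    try:
        return int(sym)
    except ValueError as exc:
        raise MatrixError(
            f"undeclared or non-numeric state symbol {sym!r} at taxon {taxon!r}, "
            f"character {j + 1}"
        ) from exc


# ----------------------------------------------------------------------
# reconciliation
# ----------------------------------------------------------------------

@dataclass
class ReconcileReport:
    dropped_taxa_tree: list[str] = field(default_factory=list)
    dropped_taxa_matrix: list[str] = field(default_factory=list)
    dropped_invariant_chars: list[str] = field(default_factory=list)


def reconcile(
    tree: TimeTree, matrix: CharacterMatrix
) -> tuple[TimeTree, CharacterMatrix, ReconcileReport]:
    """Prune tree and matrix to their shared taxa; drop invariant characters.

    Characters that show no variation among the surviving taxa carry no
    information for any downstream fit and are removed.  Requires at least
    3 shared taxa.  Idempotent.
    """
    shared = [t for t in tree.labels if t in set(matrix.taxa)]
    if len(shared) < 3:
        raise ReconciliationError(
            f"only {len(shared)} taxa shared between tree and matrix (need >= 3)"
        )
    report = ReconcileReport(
        dropped_taxa_tree=sorted(set(tree.labels) - set(shared)),
        dropped_taxa_matrix=sorted(set(matrix.taxa) - set(shared)),
    )
    new_tree = tree.prune_to(shared) if report.dropped_taxa_tree else tree
    sub = matrix.subset_taxa(shared)
    keep = []
    for c in sub.char_ids:
        col = sub.column(c)
        known = np.unique(col[col != MISSING])
        if known.size >= 2:
            keep.append(c)
        else:
            report.dropped_invariant_chars.append(c)
    result = sub.subset_chars(keep).recoded()
    for t in report.dropped_taxa_tree:
        logger.info("reconcile: dropped taxon %r (tree only)", t)
    for t in report.dropped_taxa_matrix:
        logger.info("reconcile: dropped taxon %r (matrix only)", t)
    for c in report.dropped_invariant_chars:
        logger.info("reconcile: dropped character %s (invariant after pruning)", c)
    return new_tree, result, report


@dataclass
class CharacterView:
    """A character restricted to its known-scored taxa, or its exclusion.

    When included, ``tree`` is pruned to the taxa with definite scores and
    ``tip_states[i]`` is the dense state of ``tree.labels[i]``.
    """

    char_id: str
    excluded: bool
    reason: str | None = None
    tree: TimeTree | None = None
    tip_states: np.ndarray | None = None
    n_unknown: int = 0
    n_total: int = 0

    @property
    def k(self) -> int:
        if self.tip_states is None:
            return 0
        return int(self.tip_states.max()) + 1


def character_view(
    tree: TimeTree,
    matrix: CharacterMatrix,
    char_id: str,
    max_unknown_frac: float = 0.25,
) -> CharacterView:
    """Per-character tree view: drop unknown-scored taxa, apply the 25% rule.

    A character is excluded when its unknown fraction *strictly* exceeds
    ``max_unknown_frac`` of the reconciled taxon set (exactly 25% unknown is
    kept), or when fewer than 3 taxa have known scores.
    """
    char_id = str(char_id)
    col = matrix.column(char_id)
    known_mask = col != MISSING
    n_total = matrix.n_taxa
    n_unknown = int((~known_mask).sum())
    if n_unknown > max_unknown_frac * n_total:
        return CharacterView(
            char_id, True,
            reason=f"{n_unknown}/{n_total} taxa unknown (> {max_unknown_frac:.0%})",
            n_unknown=n_unknown, n_total=n_total,
        )
    keep = [t for t, m in zip(matrix.taxa, known_mask) if m]
    if len(keep) < 3:
        return CharacterView(
            char_id, True,
            reason=f"only {len(keep)} known-scored taxa (need >= 3)",
            n_unknown=n_unknown, n_total=n_total,
        )
    sub_tree = tree.prune_to(keep) if n_unknown else tree
    order = {t: s for t, s in zip(matrix.taxa, col) if s != MISSING}
    # recode densely over the known taxa (pruning can drop states)
    raw = np.array([order[t] for t in sub_tree.labels], dtype=np.int16)
    uniq = np.unique(raw)
    remap = {int(s): i for i, s in enumerate(uniq)}
    tip_states = np.array([remap[int(s)] for s in raw], dtype=np.int16)
    if len(uniq) < 2:
        return CharacterView(
            char_id, True, reason="invariant over known-scored taxa",
            n_unknown=n_unknown, n_total=n_total,
        )
    return CharacterView(
        char_id, False, tree=sub_tree, tip_states=tip_states,
        n_unknown=n_unknown, n_total=n_total,
    )


# ----------------------------------------------------------------------
# partitions
# ----------------------------------------------------------------------

def normalise_partition_label(label: str) -> str:
    key = label.strip().lower().replace("_", " ")
    key = PARTITION_ALIASES.get(key) or PARTITION_ALIASES.get(key.replace(" ", "_"))
    if key is None:
        raise PartitionError(
            f"unknown partition label {label!r}; expected one of {PARTITION_LABELS} "
            f"or an alias {sorted(PARTITION_ALIASES)}"
        )
    return key


def load_partitions(path) -> dict[str, str]:
    """Read a two-column (character id, partition label) table.

    Labels are normalised through the alias table (e.g. ``dental`` ->
    ``teeth``, ``cranial`` -> ``skull``).  A header row is detected and
    skipped.
    """
    df = pd.read_csv(path, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise PartitionError("partition table must have two columns: id, label")
    first = str(df.iloc[0, 1]).strip().lower().replace("-", "_").replace(" ", "_")
    if first not in PARTITION_ALIASES and first.replace("_", " ") not in PARTITION_ALIASES:
        df = df.iloc[1:, :]  # header row
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        cid = str(row.iloc[0]).strip()
        mapping[cid] = normalise_partition_label(str(row.iloc[1]))
    return mapping


def validate_partitions(matrix: CharacterMatrix, partitions: dict[str, str]) -> None:
    unmapped = [c for c in matrix.char_ids if c not in partitions]
    if unmapped:
        raise PartitionError(f"characters without a partition label: {unmapped}")
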