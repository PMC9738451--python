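"""Per-gene timepoint hierarchies and binary expression-pattern selection.

Each gene's significant pairwise calls induce a set of directed
"higher at a than at b" relations between timepoints (its *hierarchy*).
Every binary pattern over the timepoints -- 1 meaning dynamically high,
0 dynamically low -- is scored against the hierarchy by counting agreeing
up/down timepoint labels and subtracting disagreeing ones, and the
best-scoring pattern becomes the gene's row in the binary gene-time
matrix. Selection is by exhaustive enumeration of all 2^T patterns.

Two scoring readings are provided. ``labelwise`` (default) scores the
"up" label on *a* and the "down" label on *b* of every relation
independently (+1 agree / -1 disagree per label). ``pairwise`` scores
each relation as a unit: +1 only when the pattern orders the pair
correctly (1 at *a*, 0 at *b*), -1 when it orders it backwards, 0 when
the pattern leaves the pair unresolved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regenatlas.de import NOT_SIGNIFICANT, UP_IN_A, UP_IN_B, PairwiseDEResult
from regenatlas.design import TimepointDesign

logger = logging.getLogger(__name__)

MAX_TIMEPOINTS = 20  # exhaustive enumeration bound: 2^20 candidate patterns

SCORING_MODES = ("labelwise", "pairwise")
TIE_BREAKS = ("min_ones_lex", "lex")


@dataclass(frozen=True)
class GeneHierarchy:
    """Directed higher-than relations between timepoints for one gene.

    A relation ``(a, b)`` reads "expression significantly higher at
    timepoint a than at timepoint b". At most one orientation per
    timepoint pair survives; conflicting orientations arising from
    different comparisons cancel and are dropped.
    """

    gene_id: str
    timepoints: tuple[str, ...]
    relations: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        known = set(self.timepoints)
        for a, b in self.relations:
            if a not in known or b not in known:
                raise ValueError(
                    f"relation ({a}, {b}) names a timepoint outside the design"
                )
            if (b, a) in self.relations:
                raise ValueError(f"conflicting orientations for pair ({a}, {b})")

    def reversed(self) -> "GeneHierarchy":
        """Hierarchy with every relation's direction flipped."""
        return GeneHierarchy(
            gene_id=self.gene_id,
            timepoints=self.timepoints,
            relations=frozenset((b, a) for a, b in self.relations),
        )


@dataclass(frozen=True)
class BinaryPattern:
    """A 0/1 assignment over timepoints with its score against a hierarchy."""

    bits: tuple[int, ...]
    score: int

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("pattern bits must be 0 or 1")

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass
class BinaryMatrix:
    """Gene x timepoint 0/1 matrix plus the provenance of its construction."""

    values: pd.DataFrame  # index gene ids, columns timepoint labels, 0/1
    provenance: dict = field(default_factory=dict)
    scores: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def universe(self) -> set[str]:
        return set(self.values.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)

    def active_at(self, timepoint: str) -> set[str]:
        col = self.values[timepoint]
        return set(col.index[col == 1])


def _directions_at(result: PairwiseDEResult, fdr_threshold: float) -> pd.Series:
    """Direction calls re-thresholded at the requested FDR level."""
    tab = result.table
    sig = tab["fdr"].to_numpy() < fdr_threshold
    lfc = tab["log2_fold_change"].to_numpy()
    direction = np.full(len(tab), NOT_SIGNIFICANT, dtype=object)
    direction[sig & (lfc > 0)] = UP_IN_B
    direction[sig & (lfc < 0)] = UP_IN_A
    return pd.Series(direction, index=tab["gene_id"].to_numpy())


def build_hierarchy(
    de_results: list[PairwiseDEResult],
    gene_id: str,
    timepoints: tuple[str, ...] | None = None,
    fdr_threshold: float | None = None,
) -> GeneHierarchy:
    """Collect one gene's directed timepoint relations from its DE calls.

    Individual-pair comparisons contribute one relation; a comparison of
    contiguous groups A vs B is decomposed into all member pairs, each
    oriented by the group-level direction. Duplicates are merged;
    opposite orientations of the same pair (from different comparisons)
    cancel and are both dropped with a warning. A gene absent from a
    comparison's table is treated as not significant there.
    """
    if timepoints is None:
        seen: list[str] = []
        for res in de_results:
            for t in res.comparison.group_a + res.comparison.group_b:
                if t not in seen:
                    seen.append(t)
        timepoints = tuple(seen)
    found = False
    votes: set[tuple[str, str]] = set()
    for res in de_results:
        thr = fdr_threshold if fdr_threshold is not None else res.fdr_threshold
        directions = _directions_at(res, thr)
        if gene_id not in directions.index:
            continue
        found = True
        call = directions[gene_id]
        if call == NOT_SIGNIFICANT:
            continue
        a_grp, b_grp = res.comparison.group_a, res.comparison.group_b
        if call == UP_IN_B:
            votes.update((b, a) for b in b_grp for a in a_grp)
        else:
            votes.update((a, b) for a in a_grp for b in b_grp)
    if not found:
        raise KeyError(f"gene {gene_id!r} absent from every DE result")
    conflicts = {(a, b) for (a, b) in votes if (b, a) in votes}
    if conflicts:
        pairs = sorted({tuple(sorted(c)) for c in conflicts})
        warnings.warn(
            f"gene {gene_id}: dropping conflicting relations for pairs {pairs}",
            stacklevel=2,
        )
    return GeneHierarchy(
        gene_id=gene_id,
        timepoints=timepoints,
        relations=frozenset(votes - conflicts),
    )


def score_pattern(
    bits: tuple[int, ...] | list[int],
    hierarchy: GeneHierarchy,
    mode: str = "labelwise",
) -> int:
    """Score one binary pattern against a hierarchy.

    labelwise: every relation (a, b) contributes +1 if ``bits[a] == 1``
    else -1, plus +1 if ``bits[b] == 0`` else -1. pairwise: +1 iff the
    pattern has 1 at a and 0 at b, -1 iff 0 at a and 1 at b, else 0.
    """
    if mode not in SCORING_MODES:
        raise ValueError(f"unknown scoring mode {mode!r}")
    if len(bits) != len(hierarchy.timepoints):
        raise ValueError(
            f"pattern length {len(bits)} != design size {len(hierarchy.timepoints)}"
        )
    index = {t: i for i, t in enumerate(hierarchy.timepoints)}
    score = 0
    for a, b in hierarchy.relations:
        ba, bb = bits[index[a]], bits[index[b]]
        if mode == "labelwise":
            score += (1 if ba == 1 else -1) + (1 if bb == 0 else -1)
        else:
            if ba == 1 and bb == 0:
                score += 1
            elif ba == 0 and bb == 1:
                score -= 1
    return score


def _enumerate_bits(T: int) -> np.ndarray:
    """All 2^T bit vectors, row i = binary expansion of i (t0 = most
    significant), i.e. rows in lexicographic order of the bit string."""
    idx = np.arange(1 << T, dtype=np.int64)
    shifts = T - 1 - np.arange(T)
    return ((idx[:, None] >> shifts) & 1).astype(np.int8)


def best_pattern(
    hierarchy: GeneHierarchy,
    mode: str = "labelwise",
    tie_break: str = "min_ones_lex",
) -> BinaryPattern:
    """Exhaustively enumerate all 2^T patterns and return the best scorer.

    Ties are broken by fewest 1-bits then lexicographically smallest bit
    string in timepoint order (``min_ones_lex``, the default; ``lex``
    drops the popcount step). The all-zero pattern always scores 0, so
    the maximum is never negative.
    """
    if mode not in SCORING_MODES:
        raise ValueError(f"unknown scoring mode {mode!r}")
    if tie_break not in TIE_BREAKS:
        raise ValueError(f"unknown tie-break rule {tie_break!r}")
    T = len(hierarchy.timepoints)
    if T < 1 or T > MAX_TIMEPOINTS:
        raise ValueError(f"number of timepoints must be in [1, {MAX_TIMEPOINTS}]")
    bits = _enumerate_bits(T)
    index = {t: i for i, t in enumerate(hierarchy.timepoints)}
    scores = np.zeros(len(bits), dtype=np.int64)
    for a, b in hierarchy.relations:
        ba = bits[:, index[a]].astype(np.int64)
        bb = bits[:, index[b]].astype(np.int64)
        if mode == "labelwise":
            scores += (2 * ba - 1) + (1 - 2 * bb)
        else:
            scores += (ba & (1 - bb)) - ((1 - ba) & bb)
    best_score = scores.max()
    candidates = np.flatnonzero(scores == best_score)
    if tie_break == "min_ones_lex":
        ones = bits[candidates].sum(axis=1)
        candidates = candidates[ones == ones.min()]
    chosen = candidates[0]  # rows are already in lexicographic order
    return BinaryPattern(bits=tuple(int(x) for x in bits[chosen]), score=int(best_score))


def binarize_all(
    de_results: list[PairwiseDEResult],
    design: TimepointDesign,
    mode: str = "labelwise",
    fdr_threshold: float = 0.05,
    tie_break: str = "min_ones_lex",
) -> BinaryMatrix:
    """Build the binary gene-time matrix: hierarchy + best pattern per gene.

    Rows follow the gene order of the first DE table; every gene present
    in any table gets exactly one row.
    """
    if not de_results:
        raise ValueError("no DE results supplied")
    timepoints = tuple(design.timepoints)
    gene_order: list[str] = []
    seen = set()
    for res in de_results:
        for g in res.table["gene_id"]:
            if g not in seen:
                seen.add(g)
                gene_order.append(g)
    # Precompute re-thresholded direction calls once per comparison; the
    # per-gene loop then only gathers votes and enumerates patterns.
    calls = [
        (_directions_at(res, fdr_threshold), res.comparison) for res in de_results
    ]
    rows = np.zeros((len(gene_order), len(timepoints)), dtype=np.int8)
    scores = np.zeros(len(gene_order), dtype=np.int64)
    for i, gene in enumerate(gene_order):
        votes: set[tuple[str, str]] = set()
        for directions, comp in calls:
            call = directions.get(gene, NOT_SIGNIFICANT)
            if call == UP_IN_B:
                votes.update((b, a) for b in comp.group_b for a in comp.group_a)
            elif call == UP_IN_A:
                votes.update((a, b) for a in comp.group_a for b in comp.group_b)
        conflicts = {(a, b) for (a, b) in votes if (b, a) in votes}
        if conflicts:
            pairs = sorted({tuple(sorted(c)) for c in conflicts})
            warnings.warn(
                f"gene {gene}: dropping conflicting relations for pairs {pairs}",
                stacklevel=2,
            )
        try:
            hierarchy = GeneHierarchy(
                gene_id=gene,
                timepoints=timepoints,
                relations=frozenset(votes - conflicts),
            )
            pattern = best_pattern(hierarchy, mode=mode, tie_break=tie_break)
        except Exception as exc:
            raise RuntimeError(f"binarization failed for gene {gene!r}") from exc
        rows[i] = pattern.bits
        scores[i] = pattern.score
    values = pd.DataFrame(rows, index=gene_order, columns=list(timepoints))
    provenance = {
        "comparisons": [res.comparison.name for res in de_results],
        "fdr_threshold": fdr_threshold,
        "scoring_mode": mode,
        "tie_break": tie_break,
        "n_genes": len(gene_order),
        "timepoints": list(timepoints),
    }
    return BinaryMatrix(
        values=values,
        provenance=provenance,
        scores=pd.Series(scores, index=gene_order, name="score"),
    )
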