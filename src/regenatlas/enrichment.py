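"""Gene-set curation, baseline-subtracted enrichment curves, and ORA.

The enrichment statistic per gene set and timepoint is the percentage
of the set's genes marked active (1) in the binary gene-time matrix,
compared against a hypergeometric null: drawing the set's size ``s`` at
random from the matrix universe of ``N`` genes of which ``K_t`` are
active at timepoint t. The null mean (100 * K_t / N) and a band -- one
standard deviation by default, or central quantiles at any level -- are
subtracted from the raw percentage, and anything negative is clamped to
0% (a negative enrichment percentage carries no meaning here).

Gene sets arrive keyed by gene symbols and are curated onto species
gene ids via a homology map: unmapped symbols are dropped, and a symbol
matching several gene ids contributes all of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regenatlas.patterns import BinaryMatrix

logger = logging.getLogger(__name__)

#: Band conventions: "sd1" = 1 standard deviation (the 68% band);
#: "qXX" = central XX% quantile interval of the hypergeometric overlap.
DEFAULT_CI_LEVEL = "sd1"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (species ids after curation)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if any(not m for m in self.members):
            raise ValueError(f"gene set {self.name!r} contains an empty id")


@dataclass(frozen=True)
class HomologyMap:
    """Symbol -> species gene ids associations (one-to-many allowed)."""

    associations: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for sym, ids in self.associations.items():
            if not sym or any(not g for g in ids):
                raise ValueError("empty id strings in homology map")

    def lookup(self, symbol: str) -> frozenset[str]:
        return self.associations.get(symbol, frozenset())

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "HomologyMap":
        assoc: dict[str, set[str]] = {}
        for symbol, gene_id in pairs:
            assoc.setdefault(symbol, set()).add(gene_id)
        return cls({s: frozenset(g) for s, g in assoc.items()})


@dataclass
class EnrichmentCurve:
    """Per-timepoint enrichment of one gene set against its null baseline.

    ``table`` columns: timepoint, raw_percent, baseline_percent,
    band_low_percent, band_high_percent (both after baseline subtraction
    and the 0% floor), adjusted_percent = max(0, raw - baseline).
    """

    set_name: str
    table: pd.DataFrame
    ci_level: str = DEFAULT_CI_LEVEL
    effective_set_size: int = 0
    universe_size: int = 0


@dataclass
class ORAResult:
    """Hypergeometric over-representation test results across gene sets.

    ``table`` columns: set_name, set_size, overlap, expected_overlap,
    p_value (upper tail), fdr (Benjamini-Hochberg), significant.
    """

    table: pd.DataFrame
    query_size: int
    universe_size: int
    fdr_threshold: float = 0.05


def curate_geneset(
    raw_symbols: list[str] | set[str],
    homology: HomologyMap,
    name: str = "",
    description: str = "",
) -> GeneSet:
    """Map a symbol-keyed set onto species gene ids.

    Symbols without a homolog are dropped (count logged); a symbol with
    several matching gene ids contributes all of them; the result is
    deduplicated. An empty curated set is returned flagged by its empty
    member set -- callers exclude it from enrichment.
    """
    members: set[str] = set()
    unmapped = 0
    for symbol in raw_symbols:
        ids = homology.lookup(symbol)
        if ids:
            members.update(ids)
        else:
            unmapped += 1
    if unmapped:
        logger.info(
            "curate_geneset(%s): dropped %d unmapped of %d symbols",
            name,
            unmapped,
            len(list(raw_symbols)),
        )
    if not members:
        logger.warning("curate_geneset(%s): no symbol mapped; set is empty", name)
    return GeneSet(name=name, members=frozenset(members), description=description)


def active_proportion(matrix: BinaryMatrix, geneset: GeneSet, timepoint: str) -> float:
    """Percent of the set's in-matrix members active (1) at a timepoint."""
    present = geneset.members & matrix.universe
    dropped = len(geneset.members) - len(present)
    if dropped:
        logger.info(
            "active_proportion(%s): %d members absent from matrix",
            geneset.name,
            dropped,
        )
    if not present:
        raise ValueError(
            f"gene set {geneset.name!r} has no members in the matrix universe"
        )
    active = matrix.active_at(timepoint)
    return 100.0 * len(present & active) / len(present)


def hypergeometric_baseline(
    N: int, K_t: int, s: int, level: str = DEFAULT_CI_LEVEL
) -> tuple[float, float, float]:
    """Null expectation and band for the active percentage of a random set.

    For a set of size ``s`` drawn without replacement from ``N`` genes of
    which ``K_t`` are active, the overlap X is Hypergeom(N, K_t, s);
    baseline = 100 * K_t / N. Returns ``(baseline, low, high)`` in
    percent-of-s units where ``[low, high]`` is the band *before*
    subtraction: baseline -/+ one SD for ``level="sd1"`` (halfwidth
    100*sqrt(s*(K/N)*(1-K/N)*(N-s)/(N-1))/s), or the central quantile
    interval of X (as percent of s) for ``level="qXX"``.
    """
    if not (0 <= K_t <= N):
        raise ValueError("require 0 <= K_t <= N")
    if not (1 <= s <= N):
        raise ValueError("require 1 <= s <= N")
    baseline = 100.0 * K_t / N
    if level == "sd1":
        if N == 1:
            halfwidth = 0.0
        else:
            var = s * (K_t / N) * (1 - K_t / N) * (N - s) / (N - 1)
            halfwidth = 100.0 * np.sqrt(var) / s
        return baseline, baseline - halfwidth, baseline + halfwidth
    if level.startswith("q"):
        conf = float(level[1:]) / 100.0
        if not 0 < conf < 1:
            raise ValueError(f"quantile level out of range: {level!r}")
        dist = stats.hypergeom(N, K_t, s)
        lo = dist.ppf((1 - conf) / 2)
        hi = dist.ppf(1 - (1 - conf) / 2)
        return baseline, 100.0 * lo / s, 100.0 * hi / s
    raise ValueError(f"unknown CI level {level!r} (use 'sd1' or e.g. 'q50', 'q99')")


def enrichment_curve(
    matrix: BinaryMatrix, geneset: GeneSet, level: str = DEFAULT_CI_LEVEL
) -> EnrichmentCurve:
    """Baseline-subtracted enrichment of one gene set along the timeline.

    Per timepoint: raw active percent, hypergeometric baseline
    (100 * K_t / N with N the matrix universe and K_t its active genes),
    adjusted = max(0, raw - baseline), and the band after the same
    subtraction and 0% floor.
    """
    present = geneset.members & matrix.universe
    if not present:
        raise ValueError(
            f"gene set {geneset.name!r} has no members in the matrix universe"
        )
    N = len(matrix.universe)
    s = len(present)
    rows = []
    for t in matrix.timepoints:
        raw = active_proportion(matrix, geneset, t)
        K_t = int(matrix.values[t].sum())
        baseline, lo, hi = hypergeometric_baseline(N, K_t, s, level=level)
        rows.append(
            {
                "timepoint": t,
                "raw_percent": raw,
                "baseline_percent": baseline,
                "band_low_percent": max(0.0, lo - baseline),
                "band_high_percent": max(0.0, hi - baseline),
                "adjusted_percent": max(0.0, raw - baseline),
            }
        )
    return EnrichmentCurve(
        set_name=geneset.name,
        table=pd.DataFrame(rows),
        ci_level=level,
        effective_set_size=s,
        universe_size=N,
    )


def ora_test(
    query: set[str],
    universe: set[str],
    genesets: list[GeneSet],
    fdr_threshold: float = 0.05,
) -> ORAResult:
    """Upper-tail hypergeometric over-representation test per gene set.

    For each set (intersected with the universe): overlap k with the
    query, p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|set|,
    n=|query|); Benjamini-Hochberg across sets; significant at
    fdr < threshold. An empty query yields p = 1 everywhere.
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for gs in genesets:
        members = gs.members & universe
        if not members:
            logger.warning("ora_test: set %r empty within universe; skipped", gs.name)
            continue
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
        rows.append(
            {
                "set_name": gs.name,
                "set_size": K,
                "overlap": k,
                "expected_overlap": K * n / N if N else 0.0,
                "p_value": min(1.0, p),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap", "expected_overlap", "p_value"]
    )
    if len(table):
        _, fdr, _, _ = multipletests(table["p_value"], method="fdr_bh")
        table["fdr"] = fdr
    else:
        table["fdr"] = pd.Series(dtype=float)
    table["significant"] = table["fdr"] < fdr_threshold
    return ORAResult(
        table=table, query_size=n, universe_size=N, fdr_threshold=fdr_threshold
    )
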