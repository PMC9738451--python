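"""Count filtering, normalization, and pairwise differential expression.

The differential-expression backend here is a deliberately simple,
documented stand-in: a negative-binomial Wald-type test with
method-of-moments gene-wise dispersion and median-of-ratios size factors.
Downstream pattern construction consumes only the per-gene *direction*
call of each comparison, so any DE engine producing
(gene, comparison, direction) can be swapped in behind the same contract.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regenatlas.design import TimepointDesign

logger = logging.getLogger(__name__)

UP_IN_B = "up_in_b"
UP_IN_A = "up_in_a"
NOT_SIGNIFICANT = "not_significant"

_PSEUDOCOUNT = 0.5
_DISPERSION_FLOOR = 1e-8
#: Weight (in pseudo-degrees-of-freedom) of the across-gene common
#: dispersion when moderating noisy gene-wise estimates at few replicates.
_DISPERSION_PRIOR_DF = 10.0


@dataclass
class CountMatrix:
    """Integer gene x sample counts tied to a timepoint design.

    ``counts`` is a genes-by-samples DataFrame (index = gene ids, columns =
    sample ids); ``design`` maps every sample to a timepoint label and its
    position in timepoint order.
    """

    counts: pd.DataFrame
    design: pd.DataFrame  # columns: sample_id, timepoint, order

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if not {"sample_id", "timepoint", "order"} <= set(self.design.columns):
            raise ValueError("design requires columns sample_id, timepoint, order")
        if self.design["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        known = set(self.design["sample_id"])
        unknown = [s for s in self.counts.columns if s not in known]
        if unknown:
            raise ValueError(f"samples missing from design: {unknown}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def timepoints(self) -> list[str]:
        """Timepoint labels in experimental order."""
        ordered = self.design.drop_duplicates("timepoint").sort_values("order")
        return list(ordered["timepoint"])

    def samples_for(self, timepoint: str) -> list[str]:
        sel = self.design[self.design["timepoint"] == timepoint]["sample_id"]
        samples = [s for s in sel if s in set(self.counts.columns)]
        if not samples:
            raise KeyError(f"no samples for timepoint {timepoint!r}")
        return samples

    def timepoint_design(self) -> TimepointDesign:
        ordered = self.design.sort_values(["order", "sample_id"])
        labels, reps = [], []
        for _, grp in ordered.groupby("order", sort=True):
            labels.append(grp["timepoint"].iloc[0])
            reps.append(int(len(grp)))
        return TimepointDesign(tuple(labels), tuple(reps))


@dataclass(frozen=True)
class FilterConfig:
    """Low-count pre-filter: retain genes with >= min_count reads in >=
    min_samples samples (defaults 5 and 2)."""

    min_count: int = 5
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_samples < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class Comparison:
    """Two disjoint contiguous runs of timepoints, compared B over A."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("comparison groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("comparison groups must be disjoint")

    @property
    def name(self) -> str:
        return "+".join(self.group_a) + "_vs_" + "+".join(self.group_b)

    def validate_contiguous(self, design_order: list[str]) -> None:
        for group in (self.group_a, self.group_b):
            idx = [design_order.index(t) for t in group]
            if sorted(idx) != list(range(min(idx), max(idx) + 1)):
                raise ValueError(f"group {group} is not contiguous in {design_order}")


@dataclass
class PairwiseDEResult:
    """Per-gene differential-expression calls for one comparison.

    ``table`` columns: gene_id, log2_fold_change (B over A), p_value, fdr,
    direction in {up_in_b, up_in_a, not_significant}.
    """

    comparison: Comparison
    table: pd.DataFrame
    fdr_threshold: float = 0.05
    backend: str = "nb_wald"

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != NOT_SIGNIFICANT]


def filter_genes(counts: CountMatrix, cfg: FilterConfig = FilterConfig()) -> CountMatrix:
    """Apply the low-count pre-filter, preserving gene order and all samples.

    A gene survives iff at least ``cfg.min_samples`` samples have at least
    ``cfg.min_count`` supporting reads.
    """
    mask = (counts.counts >= cfg.min_count).sum(axis=1) >= cfg.min_samples
    kept = counts.counts.loc[mask]
    n_in, n_out = len(counts.counts), len(kept)
    logger.info("filter_genes: retained %d of %d genes", n_out, n_in)
    if n_out == 0:
        warnings.warn("all genes removed by filtering", stacklevel=2)
    return CountMatrix(counts=kept, design=counts.design)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    Each sample's factor is the median, over genes expressed in every
    sample, of that sample's count divided by the gene's geometric mean
    across samples. Falls back to total-count ratios when no gene is
    expressed everywhere.
    """
    mat = counts.counts.to_numpy(dtype=float)
    eligible = (mat > 0).all(axis=1)
    if not eligible.any():
        logger.warning(
            "size_factors: no gene expressed in all samples; "
            "falling back to total-count ratio normalization"
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot normalize: a sample has zero total counts")
        factors = totals / stats.gmean(totals)
    else:
        sub = mat[eligible]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        ratios = sub / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def all_comparisons(design: TimepointDesign, mode: str = "pairs") -> list[Comparison]:
    """Enumerate timepoint comparisons for a design.

    ``pairs``: all unordered pairs of individual timepoints (earlier
    timepoint as group A). ``contiguous_groups``: additionally every pair
    of disjoint contiguous runs, the earlier run as group A. Ordering is
    deterministic: by group-A start, then group-A length, then group-B
    start, then group-B length.
    """
    T = design.n_timepoints
    if T < 2:
        raise ValueError("need at least two timepoints to compare")
    labels = design.timepoints
    if mode == "pairs":
        runs = [(i, i) for i in range(T)]
    elif mode == "contiguous_groups":
        runs = [(i, j) for i in range(T) for j in range(i, T)]
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")
    comparisons = []
    for (i, j), (k, l) in itertools.product(runs, runs):
        if j < k:  # run A ends strictly before run B starts
            comparisons.append(
                Comparison(
                    group_a=tuple(labels[i : j + 1]),
                    group_b=tuple(labels[k : l + 1]),
                )
            )
    comparisons.sort(
        key=lambda c: (
            labels.index(c.group_a[0]),
            len(c.group_a),
            labels.index(c.group_b[0]),
            len(c.group_b),
        )
    )
    return comparisons


def _moment_dispersion(
    norm_a: np.ndarray, norm_b: np.ndarray
) -> tuple[np.ndarray, float]:
    """Moderated gene-wise NB dispersion from normalized counts.

    Per gene, pools within-group variances (Bessel-corrected) and solves
    var = mu + alpha * mu^2 for alpha. Raw method-of-moments estimates at
    two or three replicates are extremely noisy, so each is shrunk toward
    the across-gene median with prior weight ``_DISPERSION_PRIOR_DF``
    pseudo-degrees-of-freedom (the gene's own estimate keeps weight equal
    to its residual df). Returns the moderated dispersions, floored at
    1e-8, and the total degrees of freedom (residual + prior) backing
    each estimate.
    """
    na, nb = norm_a.shape[1], norm_b.shape[1]
    dfs = max(na - 1, 0) + max(nb - 1, 0)
    if dfs == 0:
        raise ValueError("dispersion unidentifiable: need > 2 samples overall")
    va = norm_a.var(axis=1, ddof=1) if na > 1 else 0.0
    vb = norm_b.var(axis=1, ddof=1) if nb > 1 else 0.0
    pooled = (max(na - 1, 0) * va + max(nb - 1, 0) * vb) / dfs
    mu = (norm_a.sum(axis=1) + norm_b.sum(axis=1)) / (na + nb)
    mu_safe = np.maximum(mu, 1e-8)
    alpha_gene = np.maximum(_DISPERSION_FLOOR, (pooled - mu_safe) / mu_safe**2)
    alpha_common = float(np.median(alpha_gene))
    alpha = (dfs * alpha_gene + _DISPERSION_PRIOR_DF * alpha_common) / (
        dfs + _DISPERSION_PRIOR_DF
    )
    return np.maximum(_DISPERSION_FLOOR, alpha), dfs + _DISPERSION_PRIOR_DF


def pairwise_de(
    counts: CountMatrix,
    comparison: Comparison,
    fdr_threshold: float = 0.05,
    factors: pd.Series | None = None,
) -> PairwiseDEResult:
    """Negative-binomial Wald-type differential expression, B over A.

    Counts are scaled by median-of-ratios size factors (estimated on the
    full matrix unless ``factors`` is given). Per gene, the log2 fold
    change is ``log2((m_b + 1/2) / (m_a + 1/2))`` of normalized group
    means, its standard error comes from the NB variance model
    ``var = mu + alpha mu^2`` with a moderated method-of-moments
    dispersion, and the Wald statistic is referred to a Student-t whose
    degrees of freedom add the dispersion prior's weight to the residual
    df (small-sample calibration; see docs). FDR is Benjamini-Hochberg
    across genes within the comparison.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    samples_a = [s for t in comparison.group_a for s in counts.samples_for(t)]
    samples_b = [s for t in comparison.group_b for s in counts.samples_for(t)]
    if len(samples_a) + len(samples_b) <= 2:
        raise ValueError(
            "dispersion unidentifiable: comparison needs more than two samples"
        )
    if factors is None:
        factors = size_factors(counts)
    sf_a = factors[samples_a].to_numpy()
    sf_b = factors[samples_b].to_numpy()
    raw_a = counts.counts[samples_a].to_numpy(dtype=float)
    raw_b = counts.counts[samples_b].to_numpy(dtype=float)
    norm_a = raw_a / sf_a
    norm_b = raw_b / sf_b
    na, nb = norm_a.shape[1], norm_b.shape[1]

    m_a = norm_a.mean(axis=1)
    m_b = norm_b.mean(axis=1)
    lfc = np.log2((m_b + _PSEUDOCOUNT) / (m_a + _PSEUDOCOUNT))

    alpha, df_total = _moment_dispersion(norm_a, norm_b)
    # var of a normalized count K_j / sf_j with K_j ~ NB(sf_j mu, alpha):
    # mu / sf_j + alpha mu^2; group-mean variance averages over replicates.
    var_ma = (m_a * np.mean(1.0 / sf_a) + alpha * m_a**2) / na
    var_mb = (m_b * np.mean(1.0 / sf_b) + alpha * m_b**2) / nb
    ln2 = np.log(2.0)
    se = (
        np.sqrt(
            var_ma / (m_a + _PSEUDOCOUNT) ** 2 + var_mb / (m_b + _PSEUDOCOUNT) ** 2
        )
        / ln2
    )
    wald = np.where(se > 0, lfc / np.maximum(se, 1e-300), 0.0)
    # t reference with moderated degrees of freedom: the dispersion behind
    # each SE pools the gene's residual df with the across-gene prior.
    pvals = 2.0 * stats.t.sf(np.abs(wald), df=df_total)
    pvals = np.clip(pvals, 0.0, 1.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    direction = np.full(len(lfc), NOT_SIGNIFICANT, dtype=object)
    sig = fdr < fdr_threshold
    direction[sig & (lfc > 0)] = UP_IN_B
    direction[sig & (lfc < 0)] = UP_IN_A

    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )
    return PairwiseDEResult(
        comparison=comparison, table=table, fdr_threshold=fdr_threshold
    )


def run_all_pairwise(
    counts: CountMatrix,
    mode: str = "pairs",
    fdr_threshold: float = 0.05,
) -> list[PairwiseDEResult]:
    """Run pairwise_de over every comparison of the design, sharing one
    set of size factors."""
    design = counts.timepoint_design()
    comparisons = all_comparisons(design, mode=mode)
    factors = size_factors(counts)
    return [
        pairwise_de(counts, comp, fdr_threshold=fdr_threshold, factors=factors)
        for comp in comparisons
    ]
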