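"""Negative-binomial time-course count simulator with planted truth.

Emulates the statistical structure the downstream analysis assumes: a
gene x sample integer count matrix over ordered timepoints in which a
chosen fraction of genes carries a planted binary temporal pattern (a
multiplicative fold change wherever the pattern is 1), counts are
overdispersed (variance = mu + alpha mu^2) and samples differ by
multiplicative size factors. Also plants gene sets over-represented for
genes active at a chosen timepoint, with matched random controls.

Defaults mirror the study layout: five ordered states (uncut control
then 2, 7, 14, 21 days post-amputation) with replicate counts
(3, 2, 2, 3, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regenatlas.de import CountMatrix
from regenatlas.design import TimepointDesign
from regenatlas.enrichment import GeneSet


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the count simulator.

    fold_change multiplies the baseline mean wherever a gene's planted
    pattern is 1; baseline means are log-normal
    (log mu ~ Normal(baseline_mean_log_mu, baseline_mean_log_sigma));
    per-gene dispersion alpha and per-sample size factors are uniform on
    their ranges.
    """

    n_genes: int = 2000
    design: TimepointDesign = field(default_factory=TimepointDesign)
    frac_patterned: float = 0.3
    fold_change: float = 8.0
    baseline_mean_log_mu: float = 4.0
    baseline_mean_log_sigma: float = 1.0
    dispersion_range: tuple[float, float] = (0.01, 0.1)
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_patterned <= 1.0:
            raise ValueError("frac_patterned must lie in [0, 1]")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")
        if self.baseline_mean_log_sigma < 0:
            raise ValueError("baseline_mean_log_sigma must be >= 0")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise ValueError("dispersion_range must be positive and ordered")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be positive and ordered")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated matrix.

    ``genes`` columns: gene_id, pattern (bit string in timepoint order),
    mu (baseline mean), alpha (dispersion). ``size_factors`` indexed by
    sample id. Null genes carry the all-zero pattern.
    """

    genes: pd.DataFrame
    size_factors: pd.Series
    design: TimepointDesign

    def pattern_array(self) -> np.ndarray:
        """(n_genes, T) 0/1 array of true patterns."""
        return np.array(
            [[int(c) for c in p] for p in self.genes["pattern"]], dtype=np.int8
        )

    def patterned_genes(self) -> list[str]:
        mask = self.genes["pattern"].str.contains("1")
        return list(self.genes.loc[mask, "gene_id"])

    def null_genes(self) -> list[str]:
        mask = ~self.genes["pattern"].str.contains("1")
        return list(self.genes.loc[mask, "gene_id"])

    def active_at(self, timepoint: str) -> list[str]:
        t = self.design.order_of(timepoint)
        mask = self.genes["pattern"].str[t] == "1"
        return list(self.genes.loc[mask, "gene_id"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, alpha) with variance mean + alpha mean^2, via the
    (n, p) = (1/alpha, 1/(1 + alpha mean)) parameterization."""
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a count matrix and its ground truth.

    Gene g in sample j of timepoint t is
    NB(sf_j * mu_g * fold_change^{pattern_g[t]}, alpha_g). A
    ``frac_patterned`` Bernoulli draw selects patterned genes, each
    receiving a pattern uniform over the 2^T - 1 non-zero binary
    vectors; the rest are all-zero (null). Fixed seed gives bit-identical
    output.
    """
    design = config.design
    rng = np.random.default_rng(config.seed)
    T = design.n_timepoints
    n = config.n_genes

    gene_ids = [f"g{str(i).zfill(len(str(n)))}" for i in range(1, n + 1)]
    mu = np.exp(
        rng.normal(config.baseline_mean_log_mu, config.baseline_mean_log_sigma, size=n)
    )
    alpha = rng.uniform(*config.dispersion_range, size=n)
    sf = rng.uniform(*config.size_factor_range, size=design.n_samples)

    patterned = rng.random(n) < config.frac_patterned
    patterns = np.zeros((n, T), dtype=np.int8)
    n_patterned = int(patterned.sum())
    if n_patterned and T >= 1:
        # uniform over non-zero bit vectors: integers 1 .. 2^T - 1
        codes = rng.integers(1, 1 << T, size=n_patterned)
        shifts = T - 1 - np.arange(T)
        patterns[patterned] = ((codes[:, None] >> shifts) & 1).astype(np.int8)

    # per-sample timepoint index
    t_of_sample = np.concatenate(
        [np.full(r, t) for t, r in enumerate(design.replicates)]
    )
    mean = (
        sf[None, :]
        * mu[:, None]
        * config.fold_change ** patterns[:, t_of_sample].astype(float)
    )
    counts = _nb_draw(rng, mean, np.broadcast_to(alpha[:, None], mean.shape))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design.sample_ids)
    matrix = CountMatrix(counts=counts_df, design=design.to_frame())
    truth = SimulationTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "pattern": ["".join(str(b) for b in row) for row in patterns],
                "mu": mu,
                "alpha": alpha,
            }
        ),
        size_factors=pd.Series(sf, index=design.sample_ids, name="size_factor"),
        design=design,
    )
    return matrix, truth


def simulate_genesets(
    truth: SimulationTruth,
    n_sets: int,
    set_size: int,
    target_timepoint: str,
    purity: float,
    seed: int = 0,
    exclusive: bool = False,
) -> tuple[list[GeneSet], list[GeneSet]]:
    """Plant gene sets enriched for genes truly active at one timepoint.

    Each planted set draws ``round(purity * set_size)`` members (without
    replacement) from genes whose true pattern is 1 at the target
    timepoint and the remainder uniformly from the other genes. Returns
    ``(planted, controls)`` where controls are purity-0 random sets of
    the same size.

    With ``exclusive=True`` the enriched members are drawn only from
    genes active at the target timepoint and at no other (pattern = the
    indicator vector of the target). Because uniformly drawn patterns
    couple activity across timepoints (a gene high at t is high at any
    other timepoint with probability one half), only exclusive planting
    produces sets whose enrichment is confined to the target timepoint.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    if n_sets < 0 or set_size < 1:
        raise ValueError("n_sets must be >= 0 and set_size >= 1")
    all_genes = list(truth.genes["gene_id"])
    if set_size > len(all_genes):
        raise ValueError("set_size exceeds number of simulated genes")
    if exclusive:
        t = truth.design.order_of(target_timepoint)
        target = "".join(
            "1" if i == t else "0" for i in range(truth.design.n_timepoints)
        )
        mask = truth.genes["pattern"] == target
        active = list(truth.genes.loc[mask, "gene_id"])
    else:
        active = truth.active_at(target_timepoint)
    n_active_draw = int(round(purity * set_size))
    if n_active_draw > len(active):
        raise ValueError(
            f"not enough genes active at {target_timepoint!r}: "
            f"need {n_active_draw}, have {len(active)}"
        )
    rng = np.random.default_rng(seed)
    active_arr = np.array(active)
    rest_arr = np.array(sorted(set(all_genes) - set(active)))
    planted, controls = [], []
    for i in range(n_sets):
        members = set(rng.choice(active_arr, size=n_active_draw, replace=False))
        filler_pool = np.array([g for g in all_genes if g not in members])
        members |= set(
            rng.choice(filler_pool, size=set_size - n_active_draw, replace=False)
        )
        planted.append(
            GeneSet(
                name=f"planted_{target_timepoint}_{i + 1}",
                members=frozenset(members),
                description=f"planted purity={purity} at {target_timepoint}",
            )
        )
        ctrl = rng.choice(np.array(all_genes), size=set_size, replace=False)
        controls.append(
            GeneSet(
                name=f"control_{i + 1}",
                members=frozenset(ctrl),
                description="matched random control",
            )
        )
    return planted, controls
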