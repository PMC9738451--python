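"""Hierarchy construction and binary-pattern scoring / selection.

The selection algorithm is cross-checked against an independent
brute-force scorer written in plain Python below: it re-implements the
scoring rules directly from their definitions and enumerates patterns
with itertools, sharing no code with the package path it validates.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regenatlas import (
    Comparison,
    GeneHierarchy,
    SimulationConfig,
    best_pattern,
    binarize_all,
    build_hierarchy,
    score_pattern,
    simulate_counts,
)
from regenatlas.de import PairwiseDEResult, run_all_pairwise, filter_genes
from regenatlas.design import TimepointDesign

T5 = tuple(f"t{i}" for i in range(5))


# ------------------------------------------------ independent oracle

def oracle_score(bits, relations, timepoints, mode):
    idx = {t: i for i, t in enumerate(timepoints)}
    total = 0
    for a, b in relations:
        up_ok = bits[idx[a]] == 1
        down_ok = bits[idx[b]] == 0
        if mode == "labelwise":
            total += (1 if up_ok else -1) + (1 if down_ok else -1)
        else:
            if up_ok and down_ok:
                total += 1
            elif not up_ok and not down_ok:
                total -= 1
    return total


def oracle_best(relations, timepoints, mode="labelwise"):
    best_key, best_bits, best_s = None, None, None
    for bits in itertools.product((0, 1), repeat=len(timepoints)):
        s = oracle_score(bits, relations, timepoints, mode)
        key = (-s, sum(bits), bits)  # max score, fewest ones, lex smallest
        if best_key is None or key < best_key:
            best_key, best_bits, best_s = key, bits, s
    return best_bits, best_s


def random_hierarchy(rng, timepoints, p_relation=0.5):
    """Random orientation of a random subset of timepoint pairs."""
    relations = set()
    for a, b in itertools.combinations(timepoints, 2):
        if rng.random() < p_relation:
            relations.add((a, b) if rng.random() < 0.5 else (b, a))
    return GeneHierarchy(gene_id="g", timepoints=tuple(timepoints),
                         relations=frozenset(relations))


# ---------------------------------------------------------- scoring

class TestScorePattern:
    def test_empty_hierarchy_scores_zero_everywhere(self):
        h = GeneHierarchy("g", T5)
        for bits in itertools.product((0, 1), repeat=5):
            assert score_pattern(bits, h, "labelwise") == 0
            assert score_pattern(bits, h, "pairwise") == 0

    def test_single_relation_labelwise_accounting(self):
        h = GeneHierarchy("g", T5, frozenset({("t1", "t0")}))
        assert score_pattern((0, 1, 0, 0, 0), h, "labelwise") == 2
        assert score_pattern((1, 0, 0, 0, 0), h, "labelwise") == -2

    def test_three_relations_perfect_pattern(self):
        h = GeneHierarchy(
            "g", T5, frozenset({("t1", "t0"), ("t2", "t0"), ("t1", "t3")})
        )
        assert score_pattern((0, 1, 1, 0, 0), h, "labelwise") == 6
        # exhaustive check: 6 is the maximum over all 32 patterns
        assert max(
            score_pattern(b, h, "labelwise")
            for b in itertools.product((0, 1), repeat=5)
        ) == 6

    def test_pairwise_mode_neutral_on_unresolved_pairs(self):
        h = GeneHierarchy("g", T5, frozenset({("t1", "t0")}))
        # both ends equal: the pair is unresolved, no reward or penalty
        assert score_pattern((0, 0, 0, 0, 0), h, "pairwise") == 0
        assert score_pattern((1, 1, 0, 0, 0), h, "pairwise") == 0
        assert score_pattern((0, 1, 0, 0, 0), h, "pairwise") == 1
        assert score_pattern((1, 0, 0, 0, 0), h, "pairwise") == -1

    def test_wrong_length_rejected(self):
        h = GeneHierarchy("g", T5)
        with pytest.raises(ValueError, match="length"):
            score_pattern((0, 1), h)

    def test_relation_outside_design_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            GeneHierarchy("g", ("t0", "t1"), frozenset({("t9", "t0")}))

    @given(st.integers(0, 2**32 - 1))
    def test_matches_oracle_scoring(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hierarchy(rng, T5)
        bits = tuple(int(b) for b in rng.integers(0, 2, size=5))
        for mode in ("labelwise", "pairwise"):
            assert score_pattern(bits, h, mode) == oracle_score(
                bits, h.relations, T5, mode
            )


# --------------------------------------------------------- selection

class TestBestPattern:
    def test_empty_hierarchy_gives_all_zero(self):
        p = best_pattern(GeneHierarchy("g", T5))
        assert p.bits == (0, 0, 0, 0, 0)
        assert p.score == 0

    def test_two_timepoint_enumeration(self):
        h = GeneHierarchy("g", ("t0", "t1"), frozenset({("t1", "t0")}))
        p = best_pattern(h)
        assert p.bits == (0, 1)
        assert p.score == 2
        scores = {
            bits: score_pattern(bits, h)
            for bits in [(0, 0), (0, 1), (1, 0), (1, 1)]
        }
        assert scores == {(0, 0): 0, (0, 1): 2, (1, 0): -2, (1, 1): 0}

    @pytest.mark.parametrize("mode", ["labelwise", "pairwise"])
    def test_oracle_equivalence_on_random_hierarchies(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(300):
            h = random_hierarchy(rng, T5)
            p = best_pattern(h, mode=mode)
            bits, score = oracle_best(h.relations, T5, mode)
            assert p.score == score
            assert p.bits == bits

    def test_score_bounds_and_floor(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            h = random_hierarchy(rng, T5)
            p = best_pattern(h)
            R = len(h.relations)
            assert -2 * R <= p.score <= 2 * R
            assert p.score >= score_pattern((0,) * 5, h)
            assert p.score >= 0

    def test_complement_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            h = random_hierarchy(rng, T5)
            rev = h.reversed()
            p = best_pattern(h)
            q = best_pattern(rev)
            assert p.score == q.score
            complement = tuple(1 - b for b in p.bits)
            assert score_pattern(complement, rev) == q.score

    def test_tie_break_prefers_fewest_ones_then_lex(self):
        # two disconnected relations tie many patterns at the max
        h = GeneHierarchy(
            "g", ("t0", "t1", "t2", "t3"),
            frozenset({("t1", "t0"), ("t1", "t2")}),
        )
        p = best_pattern(h)
        assert p.bits == (0, 1, 0, 0)
        # lex rule alone keeps the same score but may pick another pattern
        q = best_pattern(h, tie_break="lex")
        assert q.score == p.score

    def test_too_many_timepoints_rejected(self):
        h = GeneHierarchy("g", tuple(f"x{i}" for i in range(21)))
        with pytest.raises(ValueError):
            best_pattern(h)


# --------------------------------------------------------- hierarchy

def _de_result(comparison, calls, fdr_threshold=0.05):
    """Fabricate a PairwiseDEResult from {gene: direction}."""
    rows = []
    for gene, direction in calls.items():
        sig = direction != "not_significant"
        lfc = 0.0
        if direction == "up_in_b":
            lfc = 2.0
        elif direction == "up_in_a":
            lfc = -2.0
        rows.append(
            {"gene_id": gene, "log2_fold_change": lfc,
             "p_value": 0.001 if sig else 0.9,
             "fdr": 0.001 if sig else 0.9, "direction": direction}
        )
    return PairwiseDEResult(comparison=comparison, table=pd.DataFrame(rows),
                            fdr_threshold=fdr_threshold)


class TestBuildHierarchy:
    def test_no_significant_calls_gives_empty_relations(self):
        res = _de_result(Comparison(("t0",), ("t1",)), {"g": "not_significant"})
        h = build_hierarchy([res], "g", timepoints=("t0", "t1"))
        assert h.relations == frozenset()

    def test_direction_calls_map_to_relations(self):
        r1 = _de_result(Comparison(("control",), ("2dpa",)), {"g": "up_in_b"})
        r2 = _de_result(Comparison(("control",), ("7dpa",)), {"g": "up_in_b"})
        h = build_hierarchy([r1, r2], "g",
                            timepoints=("control", "2dpa", "7dpa"))
        assert h.relations == frozenset(
            {("2dpa", "control"), ("7dpa", "control")}
        )

    def test_group_comparison_decomposed(self):
        res = _de_result(Comparison(("t0",), ("t1", "t2")), {"g": "up_in_b"})
        h = build_hierarchy([res], "g", timepoints=("t0", "t1", "t2"))
        assert h.relations == frozenset({("t1", "t0"), ("t2", "t0")})

    def test_conflicting_relations_cancel_with_warning(self):
        r1 = _de_result(Comparison(("t0",), ("t1",)), {"g": "up_in_b"})
        r2 = _de_result(Comparison(("t0",), ("t1", "t2")), {"g": "up_in_a"})
        with pytest.warns(UserWarning, match="conflicting"):
            h = build_hierarchy([r1, r2], "g", timepoints=("t0", "t1", "t2"))
        # (t1,t0) and (t0,t1) cancel; (t0,t2) survives
        assert h.relations == frozenset({("t0", "t2")})

    def test_unknown_gene_rejected(self):
        res = _de_result(Comparison(("t0",), ("t1",)), {"g": "up_in_b"})
        with pytest.raises(KeyError):
            build_hierarchy([res], "nope", timepoints=("t0", "t1"))


class TestBinarizeAll:
    def test_all_non_significant_gives_zero_matrix(self):
        design = TimepointDesign(("t0", "t1"), (2, 2))
        res = _de_result(
            Comparison(("t0",), ("t1",)),
            {f"g{i}": "not_significant" for i in range(5)},
        )
        bm = binarize_all([res], design)
        assert bm.values.shape == (5, 2)
        assert (bm.values.to_numpy() == 0).all()

    def test_planted_pattern_recovered_in_high_signal_regime(self):
        design = TimepointDesign()
        config = SimulationConfig(
            n_genes=300, design=design, frac_patterned=0.3, fold_change=8.0,
            dispersion_range=(0.05, 0.05), seed=67,
        )
        matrix, truth = simulate_counts(config)
        filtered = filter_genes(matrix)
        bm = binarize_all(run_all_pairwise(filtered), design)
        pattern = truth.genes.set_index("gene_id")["pattern"]
        want = pattern[pattern == "01100"].index
        want = [g for g in want if g in bm.values.index]
        assert want, "simulation produced no gene with pattern 01100"
        recovered = [
            "".join(str(b) for b in bm.values.loc[g]) for g in want
        ]
        assert sum(r == "01100" for r in recovered) / len(recovered) >= 0.8

    def test_dimensions_and_provenance(self, design5):
        res = _de_result(
            Comparison(("control",), ("2dpa",)), {"a": "up_in_b", "b": "not_significant"}
        )
        bm = binarize_all([res], design5, mode="pairwise", fdr_threshold=0.01)
        assert bm.values.shape == (2, 5)
        assert bm.provenance["scoring_mode"] == "pairwise"
        assert bm.provenance["fdr_threshold"] == 0.01
        assert bm.provenance["comparisons"] == ["control_vs_2dpa"]
        assert set(bm.values.columns) == set(design5.timepoints)

    def test_rethresholding_uses_requested_fdr(self, design5):
        res = _de_result(Comparison(("control",), ("2dpa",)), {"a": "up_in_b"})
        # fdr of the call is 0.001; at threshold 1e-4 nothing is significant
        strict = binarize_all([res], design5, fdr_threshold=1e-4)
        assert (strict.values.to_numpy() == 0).all()
        loose = binarize_all([res], design5, fdr_threshold=0.05)
        assert loose.values.loc["a", "2dpa"] == 1
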