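"""Shapley decomposition: exact identities, oracle equivalence, sampling."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import iop_lifecycle as il
from iop_lifecycle.exceptions import ShareUndefined
from iop_lifecycle.shapley import d_of_subset

GROUPING = il.DEFAULT_GROUPING


def orderings_oracle(values, labels):
    """Average marginal contribution over all N! orderings — the defining
    formulation of the Shapley value, independent of the subset-weight
    combination rule."""
    totals = {c: 0.0 for c in labels}
    count = 0
    for order in permutations(labels):
        prefix = frozenset()
        prev = 0.0
        for c in order:
            prefix = prefix | {c}
            cur = values[prefix]
            totals[c] += cur - prev
            prev = cur
        count += 1
    return {c: t / count for c, t in totals.items()}


@pytest.fixture(scope="module")
def cell(coded_cell):
    return coded_cell


@pytest.fixture(scope="module")
def exact_result(cell):
    spec = il.ShapleySpec(players=GROUPING)
    return il.shapley_decompose(cell, spec, "outcome_any")


class TestDOfSubset:
    def test_empty_subset_is_zero(self, cell):
        assert d_of_subset(cell, [], "outcome_any") == 0.0

    def test_full_subset_matches_estimate_cell(self, cell):
        d = d_of_subset(cell, list(il.CIRCUMSTANCES), "outcome_any")
        res = il.estimate_cell(cell, "outcome_any", il.CIRCUMSTANCES)
        assert d == pytest.approx(res.d_index, abs=1e-14)

    def test_pure_noise_circumstance_small_d(self):
        """A single circumstance with zero true effect yields a near-null D."""
        cfg = il.null_config(n_per_cell=5000, countries=("A",),
                             cohort_bounds=((1950, 1955),), age_grid=(55,),
                             seed=3)
        coded, _ = il.code_panel(il.generate_panel(cfg))
        coded[["outcome_any", "outcome_ge_median"]] = il.build_outcomes(coded, 55)
        assert d_of_subset(coded, ["harm"], "outcome_any") < 0.05


class TestExactDecomposition:
    def test_efficiency(self, exact_result):
        assert abs(sum(exact_result.rc.values()) - 1.0) < 1e-10

    def test_two_player_closed_form(self, cell):
        spec = il.ShapleySpec(players={"A": ["harm"], "B": ["financial_hardship"]})
        res = il.shapley_decompose(cell, spec, "outcome_any")
        v = res.d_by_subset
        dA, dB = v[frozenset({"A"})], v[frozenset({"B"})]
        dAB = v[frozenset({"A", "B"})]
        rc_a = (0.5 * dA + 0.5 * (dAB - dB)) / dAB
        assert res.rc["A"] == pytest.approx(rc_a, abs=1e-12)
        oracle = orderings_oracle(v, ["A", "B"])
        assert res.rc["A"] == pytest.approx(oracle["A"] / dAB, abs=1e-12)

    def test_orderings_oracle_equivalence_n4(self, exact_result):
        oracle = orderings_oracle(exact_result.d_by_subset, list(GROUPING))
        for player, rc in exact_result.rc.items():
            assert rc == pytest.approx(
                oracle[player] / exact_result.d_full, abs=1e-10)

    def test_symmetry_identical_columns(self, cell):
        df = cell.assign(harm_copy=cell["harm"])
        spec = il.ShapleySpec(players={"A": ["harm"], "B": ["harm_copy"]})
        res = il.shapley_decompose(df, spec, "outcome_any")
        assert res.rc["A"] == pytest.approx(0.5, abs=1e-10)
        assert res.rc["B"] == pytest.approx(0.5, abs=1e-10)

    def test_null_player_constant_column_zero(self, cell):
        df = cell.assign(const_col=1)
        spec = il.ShapleySpec(players={"MAIN": list(il.CIRCUMSTANCES),
                                       "NULL": ["const_col"]})
        res = il.shapley_decompose(df, spec, "outcome_any")
        assert res.rc["NULL"] == 0.0
        assert res.rc["MAIN"] == pytest.approx(1.0, abs=1e-12)

    def test_share_undefined_when_d_zero(self, cell):
        df = cell.assign(c1=1, c2=2)
        spec = il.ShapleySpec(players={"A": ["c1"], "B": ["c2"]})
        with pytest.raises(ShareUndefined):
            il.shapley_decompose(df, spec, "outcome_any")

    def test_d_full_invariant_to_grouping_scheme(self, cell):
        """Partitioning the same circumstance set differently never changes
        the full-model index (correlated circumstances included)."""
        r1 = il.shapley_decompose(
            cell, il.ShapleySpec(players=il.DEFAULT_GROUPING), "outcome_any")
        r2 = il.shapley_decompose(
            cell, il.ShapleySpec(players=il.SPLIT_HARM_GROUPING), "outcome_any")
        assert r1.d_full == r2.d_full


class TestSampling:
    def test_requires_seed_and_permutations(self):
        with pytest.raises(ValueError):
            il.ShapleySpec(players=GROUPING, method="sampling",
                           n_permutations=100)
        with pytest.raises(ValueError):
            il.ShapleySpec(players=GROUPING, method="sampling", seed=1)

    def test_converges_to_exact(self, cell, exact_result):
        errs = []
        for n_perm in (100, 10_000):
            spec = il.ShapleySpec(players=GROUPING, method="sampling",
                                  n_permutations=n_perm, seed=5)
            res = il.shapley_decompose(cell, spec, "outcome_any")
            errs.append(max(abs(res.rc[p] - exact_result.rc[p])
                            for p in GROUPING))
            assert abs(sum(res.rc.values()) - 1.0) < 1e-10  # per-ordering identity
            for p in GROUPING:  # within ~4 Monte-Carlo SEs of exact
                if np.isfinite(res.se[p]) and res.se[p] > 0:
                    assert abs(res.rc[p] - exact_result.rc[p]) < 5 * res.se[p]
        assert errs[1] < errs[0]


class TestAggregation:
    def test_identity_partition_unchanged(self, exact_result):
        agg = il.aggregate_contributions(
            exact_result, {p: [p] for p in exact_result.rc})
        assert agg == pytest.approx(exact_result.rc)

    def test_all_in_one_supergroup_gives_unity(self, exact_result):
        agg = il.aggregate_contributions(
            exact_result, {"ALL": list(exact_result.rc)})
        assert agg["ALL"] == pytest.approx(1.0, abs=1e-10)

    def test_non_partition_rejected(self, exact_result):
        with pytest.raises(ValueError):
            il.aggregate_contributions(exact_result, {"X": ["ACE"]})
        with pytest.raises(ValueError):
            il.aggregate_contributions(
                exact_result,
                {"X": list(exact_result.rc), "Y": ["ACE"]})

    def test_split_harm_reaggregation_close_to_combined(self, cell):
        """Re-grouping harm and relationship into one ACE player changes the
        coalition structure, so aggregated split shares approximate — but do
        not exactly equal — the combined-ACE share; the full index is
        identical."""
        combined = il.shapley_decompose(
            cell, il.ShapleySpec(players=il.DEFAULT_GROUPING), "outcome_any")
        split = il.shapley_decompose(
            cell, il.ShapleySpec(players=il.SPLIT_HARM_GROUPING), "outcome_any")
        agg = il.aggregate_contributions(
            split, {"ACE": ["HARM", "RELATIONSHIP"], "SES": ["SES"],
                    "GENDER": ["GENDER"], "CHILD_HEALTH": ["CHILD_HEALTH"]})
        assert split.d_full == combined.d_full
        for player, share in combined.rc.items():
            assert abs(agg[player] - share) < 0.05


class TestSpecValidation:
    def test_overlapping_players_rejected(self):
        with pytest.raises(ValueError):
            il.ShapleySpec(players={"A": ["harm"], "B": ["harm"]})

    def test_empty_player_rejected(self):
        with pytest.raises(ValueError):
            il.ShapleySpec(players={"A": []})
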