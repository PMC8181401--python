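import itertools

import numpy as np
import pandas as pd
import pytest

import pairrank as pr
from pairrank.errors import ValidationError
from pairrank.pair_engine import (
    assign_groups,
    binarize_pairs,
    mad_filter,
    median_absolute_deviation,
    prevalence_filter,
    restrict_to_genes,
    risk_score,
)


def brute_force_binarize(expr: pd.DataFrame) -> pd.DataFrame:
    """Independent oracle: explicit loops over all gene pairs and samples."""
    genes = list(expr.index)
    rows = {}
    for a, b in itertools.combinations(genes, 2):
        rows[f"{a}|{b}"] = [
            1 if expr.loc[a, s] > expr.loc[b, s] else 0 for s in expr.columns
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)


class TestMadFilter:
    def test_constant_gene_removed(self):
        expr = pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 9.0], "s3": [5.0, 2.0]},
                            index=["FLAT", "VAR"])
        assert list(mad_filter(expr, 0.5).index) == ["VAR"]

    def test_mad_exactly_at_threshold_removed(self):
        # values (1, 1.5, 2): median 1.5, abs deviations (0.5, 0, 0.5), MAD 0.5
        expr = pd.DataFrame([[1.0, 1.5, 2.0]], index=["G"], columns=list("abc"))
        assert mad_filter(expr, 0.5).empty

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.uniform(0, 10, size=(10, 20)),
                            index=[f"g{i}" for i in range(10)])
        kept = mad_filter(expr, 0.5)
        for g in expr.index:
            x = expr.loc[g].to_numpy()
            mad = np.median(np.abs(x - np.median(x)))
            assert (g in kept.index) == (mad > 0.5)

    def test_no_consistency_constant(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
        assert median_absolute_deviation(x) == 1.0

    def test_single_sample_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["G"])
        with pytest.raises(ValidationError, match="2 samples"):
            mad_filter(expr)


class TestRestrictToGenes:
    def test_disjoint_list_rejected(self, small_expr):
        with pytest.raises(ValidationError, match="no symbols"):
            restrict_to_genes(small_expr, {"NOPE"})

    def test_superset_is_identity(self, small_expr):
        genes = set(small_expr.index) | {"EXTRA"}
        pd.testing.assert_frame_equal(restrict_to_genes(small_expr, genes),
                                      small_expr)

    def test_partial_overlap(self, small_expr):
        genes = set(list(small_expr.index)[:4]) | {"X", "Y", "Z"}
        out = restrict_to_genes(small_expr, genes)
        assert len(out) == 4
        assert set(out.index) <= genes


class TestBinarize:
    def test_simple_comparisons(self):
        expr = pd.DataFrame({"s1": [5.0, 3.0], "s2": [2.0, 2.0]},
                            index=["a", "b"])
        ind = binarize_pairs(expr)
        assert ind.loc["a|b", "s1"] == 1  # higher first gene scores 1
        assert ind.loc["a|b", "s2"] == 0  # ties score 0

    def test_four_genes_give_six_pairs_matching_oracle(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.uniform(0, 10, size=(4, 7)),
                            index=list("wxyz"),
                            columns=[f"s{j}" for j in range(7)])
        ind = binarize_pairs(expr)
        assert len(ind) == 6
        pd.testing.assert_frame_equal(
            ind.astype(int), brute_force_binarize(expr).astype(int),
            check_names=False,
        )

    def test_fewer_than_two_genes_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["G"])
        with pytest.raises(ValidationError, match="2 genes"):
            binarize_pairs(expr)

    def test_antisymmetry_on_tie_free_data(self, small_expr):
        ind = binarize_pairs(small_expr)
        rev = binarize_pairs(small_expr.iloc[::-1])
        for pid in ind.index:
            a, b = pid.split("|")
            assert (ind.loc[pid] + rev.loc[f"{b}|{a}"] == 1).all()


class TestMonotoneInvariance:
    TRANSFORMS = [lambda x: 2 * x + 7, lambda x: x**3, lambda x: np.log(x + 1)]

    def test_indicators_bit_identical_under_monotone_transforms(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            expr = pd.DataFrame(rng.uniform(0, 10, size=(8, 9)),
                                index=[f"g{i}" for i in range(8)])
            baseline = binarize_pairs(expr)
            distorted = expr.copy()
            for j, col in enumerate(expr.columns):
                distorted[col] = self.TRANSFORMS[j % 3](expr[col])
            pd.testing.assert_frame_equal(binarize_pairs(distorted), baseline)

    def test_risk_scores_identical_under_monotone_transforms(
        self, bundled_signature
    ):
        rng = np.random.default_rng(13)
        genes = sorted(bundled_signature.genes)
        expr = pd.DataFrame(rng.uniform(1, 100, size=(len(genes), 12)),
                            index=genes)
        scores = risk_score(binarize_pairs(expr), bundled_signature)
        distorted = expr.copy()
        for j, col in enumerate(expr.columns):
            distorted[col] = self.TRANSFORMS[j % 3](expr[col])
        scores2 = risk_score(binarize_pairs(distorted), bundled_signature)
        assert (scores == scores2).all()


class TestPrevalenceFilter:
    def test_minority_below_threshold_discarded(self):
        ind = pd.DataFrame([[1] + [0] * 9], index=["a|b"],
                           columns=[f"s{j}" for j in range(10)])
        assert prevalence_filter(ind, 0.2).empty

    def test_all_ones_discarded(self):
        ind = pd.DataFrame([[1] * 10], index=["a|b"],
                           columns=[f"s{j}" for j in range(10)])
        assert prevalence_filter(ind, 0.2).empty

    def test_exact_boundary_kept(self):
        # 2 ones among 10 samples = exactly 20%: "less than" discards, so kept
        ind = pd.DataFrame([[1, 1] + [0] * 8], index=["a|b"],
                           columns=[f"s{j}" for j in range(10)])
        assert list(prevalence_filter(ind, 0.2).index) == ["a|b"]

    def test_retained_pairs_satisfy_prevalence_bound(self, small_expr):
        ind = prevalence_filter(binarize_pairs(small_expr), 0.25)
        means = ind.mean(axis=1)
        assert ((means >= 0.25) & (means <= 0.75)).all()


class TestRiskScore:
    def test_all_zero_indicators_score_zero(self, bundled_signature):
        pairs = [f"{a}|{b}" for a, b in bundled_signature.pairs]
        ind = pd.DataFrame(0, index=pairs, columns=["s1", "s2"])
        assert (risk_score(ind, bundled_signature) == 0).all()

    def test_all_one_indicators_score_coefficient_sum(self, bundled_signature):
        # oracle: sum of the printed coefficient column, independent of scoring
        expected = float(np.sum(bundled_signature.coefficients))
        pairs = [f"{a}|{b}" for a, b in bundled_signature.pairs]
        ind = pd.DataFrame(1, index=pairs, columns=["s1"])
        assert risk_score(ind, bundled_signature)["s1"] == pytest.approx(expected)

    def test_reversed_pair_scores_via_complement(self, bundled_signature):
        rng = np.random.default_rng(5)
        genes = sorted(bundled_signature.genes)
        expr = pd.DataFrame(rng.uniform(1, 100, size=(len(genes), 10)),
                            index=genes)
        forward = risk_score(binarize_pairs(expr), bundled_signature)
        reversed_ = risk_score(binarize_pairs(expr.iloc[::-1]),
                               bundled_signature)
        assert np.allclose(forward, reversed_)

    def test_missing_genes_reported(self, bundled_signature):
        ind = pd.DataFrame([[1]], index=["NOT|THERE"], columns=["s1"])
        with pytest.raises(ValidationError, match="unresolvable"):
            risk_score(ind, bundled_signature)

    def test_linearity_in_coefficients(self, small_expr):
        ind = binarize_pairs(small_expr)
        pairs = [tuple(p.split("|")) for p in ind.index[:5]]
        rng = np.random.default_rng(9)
        c1, c2 = rng.normal(size=5), rng.normal(size=5)
        s1 = risk_score(ind, pr.GenePairSignature(pairs=pairs, coefficients=c1))
        s2 = risk_score(ind, pr.GenePairSignature(pairs=pairs, coefficients=c2))
        s12 = risk_score(ind, pr.GenePairSignature(pairs=pairs,
                                                   coefficients=c1 + c2))
        assert np.allclose(s12, s1 + s2)


class TestAssignGroups:
    def test_boundary_goes_low(self):
        scores = pd.Series([-1.0, 0.0, 1.0], index=list("abc"))
        assert assign_groups(scores, 0.0).tolist() == ["low", "low", "high"]

    def test_all_below_cutoff(self):
        scores = pd.Series([-3.0, -2.0], index=list("ab"))
        assert (assign_groups(scores, 0.0) == "low").all()

    def test_matches_elementwise_comparison(self):
        rng = np.random.default_rng(21)
        scores = pd.Series(rng.normal(size=50))
        labels = assign_groups(scores, 0.3)
        for s, lab in zip(scores, labels):
            assert lab == ("high" if s > 0.3 else "low")
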