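"""TMB, MATH, recurrent sites and contingency statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import immunophen as ip
from immunophen.genomics import math_scores_per_sample


def make_muts(rows):
    return ip.MutationTable(
        pd.DataFrame(
            rows,
            columns=[
                "Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome",
                "Start_Position", "Variant_Classification",
                "t_ref_count", "t_alt_count",
            ],
        )
    )


def flat_muts(sample, n, chrom="1", pos0=1000):
    return [
        (sample, f"GENE{i}", chrom, pos0 + i, "Missense_Mutation", 70, 30)
        for i in range(n)
    ]


class TestTmb:
    def test_identity_ratio_and_linearity(self):
        muts = make_muts(flat_muts("s1", 38))
        res = ip.compute_tmb(muts, capture_size_mb=38.0)
        assert res.table.loc["s1", "tmb"] == 1.0
        doubled = make_muts(flat_muts("s1", 76))
        assert ip.compute_tmb(doubled, capture_size_mb=38.0).table.loc["s1", "tmb"] == 2.0

    def test_absent_samples_zero_and_log_missing(self):
        muts = make_muts(flat_muts("s1", 10))
        res = ip.compute_tmb(muts, samples=["s1", "s2"])
        assert res.table.loc["s2", "mutation_count"] == 0
        assert np.isnan(res.table.loc["s2", "log2_tmb"])  # 0 on the log scale

    def test_variant_class_filter(self):
        rows = flat_muts("s1", 5) + [
            ("s1", "X", "1", 99, "Silent", 70, 30)
        ]
        res = ip.compute_tmb(make_muts(rows), variant_classes=["Missense_Mutation"])
        assert res.table.loc["s1", "mutation_count"] == 5

    def test_capture_guard(self):
        with pytest.raises(ValueError, match="positive"):
            ip.compute_tmb(make_muts(flat_muts("s1", 1)), capture_size_mb=0)


class TestMathScore:
    def test_hand_evaluation(self):
        """VAFs [0.2, 0.25, 0.3]: med 0.25, MAD 1.4826*0.05 -> MATH 29.652."""
        assert ip.math_score([0.2, 0.25, 0.3]) == pytest.approx(29.652)

    def test_identical_vafs_zero(self):
        assert ip.math_score([0.3, 0.3, 0.3]) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=0.45), min_size=3, max_size=12),
        st.floats(min_value=0.2, max_value=2.0),
    )
    def test_scale_invariance(self, vafs, c):
        scaled = [v * c for v in vafs]  # bounds keep scaled VAFs within (0, 0.9]
        assert ip.math_score(vafs) == pytest.approx(ip.math_score(scaled), rel=1e-9)

    def test_mean_preserving_spread_increases_math(self):
        tight = [0.24, 0.25, 0.26]
        wide = [0.15, 0.25, 0.35]
        assert ip.math_score(wide) > ip.math_score(tight)

    def test_guards(self):
        with pytest.raises(ValueError, match="at least 2"):
            ip.math_score([0.3])
        with pytest.raises(ValueError, match="VAFs must lie"):
            ip.math_score([0.0, 0.5])

    def test_per_sample_scores(self):
        rows = [
            ("s1", "A", "1", 1, "Missense_Mutation", 80, 20),
            ("s1", "B", "1", 2, "Missense_Mutation", 75, 25),
            ("s1", "C", "1", 3, "Missense_Mutation", 70, 30),
            ("s2", "A", "1", 4, "Missense_Mutation", 50, 50),
        ]
        scores = math_scores_per_sample(make_muts(rows))
        assert scores["s1"] == pytest.approx(29.652)
        assert "s2" not in scores  # single VAF: MATH undefined


class TestRecurrentSites:
    def test_strict_threshold_boundary(self):
        six = make_muts(
            [(f"s{i}", "X", "7", 100, "Missense_Mutation", 70, 30) for i in range(6)]
        )
        five = make_muts(
            [(f"s{i}", "X", "7", 100, "Missense_Mutation", 70, 30) for i in range(5)]
        )
        hits6 = ip.recurrent_site_counts(six, min_n=5)
        assert len(hits6) == 1 and hits6.iloc[0]["count"] == 6
        assert len(ip.recurrent_site_counts(five, min_n=5)) == 0


class TestChiSquare:
    def test_hand_evaluated_2x2(self):
        """[[10,20],[20,10]]: every expected cell is 15 -> chi2 = 20/3."""
        table = ip.ContingencyTable(pd.DataFrame([[10, 20], [20, 10]]))
        stat, df, p = ip.chi_square_test(table)
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_proportional_rows_independent(self):
        stat, _, p = ip.chi_square_test(
            ip.ContingencyTable(pd.DataFrame([[10, 20], [20, 40]]))
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula_fuzz(self):
        """100 random tables vs an explicit sum((O-E)^2/E) implementation."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 50, size=(r, c))
            stat, df, p = ip.chi_square_test(ip.ContingencyTable(pd.DataFrame(counts)))
            total = counts.sum()
            expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
            direct = ((counts - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(direct, abs=1e-9)
            assert df == (r - 1) * (c - 1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ip.chi_square_test(ip.ContingencyTable(pd.DataFrame([[0, 0], [1, 2]])))


class TestPhenotypeFeatureTable:
    def test_one_sample_per_phenotype(self):
        labels = pd.Series(
            ["immune-L", "immune-M", "immune-H"], index=["a", "b", "c"]
        )
        feature = pd.Series(["mut", "mut", "mut"], index=["a", "b", "c"])
        table = ip.phenotype_feature_table(labels, feature)
        assert table.counts.shape == (3, 1)
        assert (table.counts["mut"] == 1).all()
        assert list(table.counts.index) == ["immune-L", "immune-M", "immune-H"]

    def test_missing_feature_excluded(self, caplog):
        labels = pd.Series(["immune-L", "immune-H"], index=["a", "b"])
        feature = pd.Series(["mut", None], index=["a", "b"])
        with caplog.at_level("WARNING"):
            table = ip.phenotype_feature_table(labels, feature)
        assert table.counts.to_numpy().sum() == 1
        assert "excluding 1" in caplog.text

    def test_planted_proportions_recovered(self):
        """Phenotype-dependent feature rates come back within binomial error."""
        rng = np.random.default_rng(14)
        n = 600
        labels = pd.Series(
            rng.choice(["immune-L", "immune-M", "immune-H"], size=n),
            index=[f"s{i}" for i in range(n)],
        )
        rates = {"immune-L": 0.7, "immune-M": 0.5, "immune-H": 0.25}
        feature = pd.Series(
            [
                "MT" if rng.random() < rates[lab] else "WT"
                for lab in labels
            ],
            index=labels.index,
        )
        table = ip.phenotype_feature_table(labels, feature).counts
        for lab, rate in rates.items():
            tot = table.loc[lab].sum()
            phat = table.loc[lab, "MT"] / tot
            assert abs(phat - rate) < 3 * np.sqrt(rate * (1 - rate) / tot)

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            ip.phenotype_feature_table(
                pd.Series(["immune-L"], index=["a"]), pd.Series(["x"], index=["b"])
            )
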