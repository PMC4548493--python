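"""Odds ratios, observed/expected comparisons, Bonferroni correction,
per-amino-acid mutability and ROC area."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from intersav.reference_data import region_table
from intersav.stats import (
    ContingencyTable, bonferroni, chisq_obs_vs_expected, expected_counts,
    odds_ratio, per_aa_mutability, region_pair_report, roc_auc, woolf_se,
)


class TestOddsRatio:
    def test_equal_rates_identity(self):
        assert odds_ratio(10, 100, 10, 100).or_value == pytest.approx(1.0)

    def test_reciprocal_pairs(self):
        r1 = odds_ratio(215, 13486, 251, 23478)
        r2 = odds_ratio(251, 23478, 215, 13486)
        assert r1.or_value * r2.or_value == pytest.approx(1.0)

    def test_p_value_matches_2x2_chi_square_oracle(self):
        res = odds_ratio(215, 13486, 1494, 72467)
        table = np.array([[215, 13486 - 215], [1494, 72467 - 1494]])
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
        assert res.p_raw == pytest.approx(p)
        assert f"{res.p_raw:.1g}" == "0.0004"

    def test_ci_contains_point_estimate_and_widens(self):
        narrow = odds_ratio(30, 300, 20, 400, conf_level=0.95)
        wide = odds_ratio(30, 300, 20, 400, conf_level=0.99)
        assert narrow.ci_low <= narrow.or_value <= narrow.ci_high
        assert wide.ci_low < narrow.ci_low and wide.ci_high > narrow.ci_high

    def test_zero_cell_haldane_anscombe(self):
        res = odds_ratio(0, 50, 5, 50)
        assert res.zero_cell_corrected
        assert res.or_value == pytest.approx((0.5 / 50.5) / (5.5 / 45.5))

    def test_woolf_se_formula(self):
        se = woolf_se(10, 110, 20, 220)
        assert se == pytest.approx(np.sqrt(1 / 10 + 1 / 100 + 1 / 20 + 1 / 200))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            odds_ratio(-1, 10, 1, 10)


class TestExpectedCounts:
    def test_single_region_table(self):
        t = ContingencyTable("disease", {"only": 50}, {"only": 7})
        df = expected_counts(t)
        assert df["expected"].iloc[0] == pytest.approx(7)
        assert df["o_over_e"].iloc[0] == pytest.approx(1.0)

    def test_conservation(self):
        t = region_table("disease")
        df = expected_counts(t)
        assert df["expected"].sum() == pytest.approx(df["observed"].sum())

    def test_observed_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            ContingencyTable("d", {"a": 5}, {"a": 6})


class TestChisqObsVsExpected:
    def test_zero_statistic_when_equal(self):
        stat, p = chisq_obs_vs_expected([5, 5], [5.0, 5.0])
        assert stat == 0 and p == pytest.approx(1.0)

    def test_two_cell_equals_squared_z_binomial(self):
        # with two cells the Pearson statistic equals the square of the
        # normal-approximation binomial z statistic
        n, k, p0 = 200, 65, 0.25
        stat, _ = chisq_obs_vs_expected([k, n - k], [n * p0, n * (1 - p0)])
        z = (k - n * p0) / np.sqrt(n * p0 * (1 - p0))
        assert stat == pytest.approx(z ** 2)

    def test_reference_disease_table_highly_significant(self):
        t = region_table("disease")
        df = expected_counts(t)
        stat, p = chisq_obs_vs_expected(df["observed"], df["expected"])
        assert p < 1e-5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chisq_obs_vs_expected([1, 2], [1.0])


class TestBonferroni:
    def test_fixture_pairs(self):
        assert bonferroni([0.003], 6)[0] == pytest.approx(0.018)
        assert bonferroni([0.016], 6)[0] == pytest.approx(0.096)

    def test_capped_at_one(self):
        assert bonferroni([0.5], 6) == [1.0]

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 6)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestRegionPairReport:
    def test_six_rows_with_adjustment(self):
        rep = region_pair_report(region_table("disease"))
        assert len(rep) == 6
        assert (rep["p_adjusted"] >= rep["p_raw"] - 1e-15).all()

    def test_zero_observed_flagged(self):
        t = ContingencyTable(
            "disease",
            {"buried": 100, "core": 100, "rim": 100, "surface": 100},
            {"buried": 0, "core": 0, "rim": 0, "surface": 0},
        )
        rep = region_pair_report(t)
        assert rep["zero_cell_corrected"].all()


class TestPerAaMutability:
    def test_all_disease_arginine(self):
        savs = pd.DataFrame({
            "wt_aa": ["R", "R", "L"],
            "region": ["core", "core", "rim"],
            "category": ["disease", "disease", "polymorphism"],
        })
        comp = pd.DataFrame({
            "aa": ["R", "L"], "region": ["core", "rim"], "n_residues": [2, 10],
        })
        out = per_aa_mutability(savs, comp)
        arg = out[(out.wt_aa == "R") & (out.category == "disease")]
        assert arg["frequency"].iloc[0] == pytest.approx(1.0)
        assert not ((out.wt_aa == "R") & (out.category == "polymorphism")).any()

    def test_frequencies_recompose_to_whole_protein_rate(self):
        rng = np.random.default_rng(4)
        comp = pd.DataFrame({
            "aa": ["R"] * 4,
            "region": ["buried", "core", "rim", "surface"],
            "n_residues": [40, 10, 20, 30],
        })
        counts = rng.integers(0, 10, size=4)
        savs = pd.DataFrame({
            "wt_aa": ["R"] * int(counts.sum()),
            "region": np.repeat(comp["region"], counts),
            "category": "disease",
        })
        out = per_aa_mutability(savs, comp)
        whole = (out["frequency"] * out["n_residues"]).sum() / comp["n_residues"].sum()
        assert whole == pytest.approx(counts.sum() / 100)

    def test_simulation_recovers_elevated_rate(self):
        # arginine placed at 4x the rate of leucine: the recovered
        # frequency ratio matches within sampling error
        rng = np.random.default_rng(0)
        n = 4000
        comp = pd.DataFrame({
            "aa": ["R", "L"], "region": ["core", "core"], "n_residues": [n, n],
        })
        savs_r = rng.binomial(n, 0.08)
        savs_l = rng.binomial(n, 0.02)
        savs = pd.DataFrame({
            "wt_aa": ["R"] * savs_r + ["L"] * savs_l,
            "region": "core",
            "category": "disease",
        })
        out = per_aa_mutability(savs, comp).set_index("wt_aa")
        ratio = out.loc["R", "frequency"] / out.loc["L", "frequency"]
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_zero_denominator_is_nan(self):
        savs = pd.DataFrame({"wt_aa": ["R"], "region": ["core"],
                             "category": ["disease"]})
        comp = pd.DataFrame({"aa": ["R"], "region": ["core"], "n_residues": [0]})
        out = per_aa_mutability(savs, comp)
        assert np.isnan(out["frequency"].iloc[0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.4]
        labels = [0, 0, 1, 1, 0, 1]
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        concordant = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        assert roc_auc(scores, labels) == pytest.approx(
            concordant / (len(pos) * len(neg)))

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.4).astype(int)
        assert roc_auc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def test_or_coverage_over_replicates():
    """The Woolf 95% CI covers the generating odds ratio in at least
    93% of 200 simulated tables."""
    from intersav.reference_data import OBSERVED, REGION_TOTALS
    rng = np.random.default_rng(2024)
    p_core = OBSERVED["disease"]["core"] / REGION_TOTALS["core"]
    p_rim = OBSERVED["disease"]["rim"] / REGION_TOTALS["rim"]
    true_or = (p_core / (1 - p_core)) / (p_rim / (1 - p_rim))
    n_core, n_rim = REGION_TOTALS["core"], REGION_TOTALS["rim"]
    hits = 0
    for _ in range(200):
        obs_c = rng.binomial(n_core, p_core)
        obs_r = rng.binomial(n_rim, p_rim)
        res = odds_ratio(obs_c, n_core, obs_r, n_rim)
        if res.ci_low <= true_or <= res.ci_high:
            hits += 1
    assert hits >= 186  # 93% of 200
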