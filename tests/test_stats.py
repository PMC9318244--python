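"""Normality gating, paired/group tests, rank post hoc, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lesionfd.stats import (
    StatsReport,
    correlation_matrix,
    dunn_bonferroni,
    fisher_lsd,
    group_comparison,
    melanoma_subgroup_test,
    normality_gate,
    paired_illumination_test,
)


def make_records(values_by_group: dict, illumination="PL", variable="shape_fd"):
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append(
                {"lesion_id": f"{g}{i}", "group": g, "illumination": illumination,
                 variable: v}
            )
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_normal_samples_pass_in_most_seeds(self):
        passes = sum(
            normality_gate({"g": np.random.default_rng(s).normal(0, 1, 50)})
            == "parametric"
            for s in range(100)
        )
        assert passes >= 95

    def test_heavy_tailed_lognormal_fails(self):
        fails = sum(
            normality_gate({"g": np.random.default_rng(s).lognormal(0, 1.5, 50)})
            == "nonparametric"
            for s in range(20)
        )
        assert fails == 20

    def test_constant_vector_nonparametric(self):
        assert normality_gate({"g": np.full(10, 3.0)}) == "nonparametric"

    def test_tiny_sample_nonparametric(self):
        assert normality_gate({"g": np.array([1.0, 2.0])}) == "nonparametric"

    def test_any_failing_group_forces_nonparametric(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(size=50), "b": rng.lognormal(0, 1.5, 50)}
        assert normality_gate(groups) == "nonparametric"


class TestPairedIlluminationTest:
    def _paired_df(self, pl, npl, group="BN"):
        rows = []
        for i, (a, b) in enumerate(zip(pl, npl)):
            rows.append({"lesion_id": f"L{i}", "group": group, "illumination": "PL",
                         "shape_fd": a})
            rows.append({"lesion_id": f"L{i}", "group": group, "illumination": "NPL",
                         "shape_fd": b})
        return pd.DataFrame(rows)

    def test_identical_arms_not_significant(self):
        v = np.random.default_rng(1).normal(1.4, 0.05, 20)
        rep = paired_illumination_test(self._paired_df(v, v), "shape_fd")
        row = rep.table.iloc[0]
        assert row["mean_difference"] == 0
        assert row["p"] > 0.05

    def test_systematic_shift_detected(self):
        rng = np.random.default_rng(2)
        pl = rng.normal(1.40, 0.04, 30)
        npl = pl + 0.03 + rng.normal(0, 0.01, 30)
        rep = paired_illumination_test(self._paired_df(pl, npl), "shape_fd")
        assert rep.table.iloc[0]["p"] < 0.001

    def test_label_swap_flips_difference_keeps_p(self):
        rng = np.random.default_rng(3)
        pl = rng.normal(1.40, 0.04, 25)
        npl = pl + 0.02 + rng.normal(0, 0.015, 25)
        a = paired_illumination_test(self._paired_df(pl, npl), "shape_fd").table.iloc[0]
        b = paired_illumination_test(self._paired_df(npl, pl), "shape_fd").table.iloc[0]
        assert a["mean_difference"] == pytest.approx(-b["mean_difference"])
        assert a["p"] == pytest.approx(b["p"])

    def test_unpaired_lesion_excluded(self, caplog):
        import logging

        df = self._paired_df(np.ones(5) + np.arange(5) * 0.01,
                             np.ones(5) + np.arange(5) * 0.02)
        df = df.drop(df.index[-1])  # orphan one PL record
        with caplog.at_level(logging.WARNING):
            rep = paired_illumination_test(df, "shape_fd")
        assert rep.table.iloc[0]["n"] == 4
        assert "unpaired" in caplog.text


class TestGroupComparison:
    def test_identical_samples_null(self):
        base = np.random.default_rng(5).normal(1.45, 0.05, 20)
        df = make_records({"MM": base, "DN": base, "BN": base})
        rep = group_comparison(df, "shape_fd")
        pw = rep.pairwise
        for a in pw.index:
            for b in pw.columns:
                if a != b:
                    assert pw.loc[a, b] > 0.05

    def test_printed_effect_sizes_separate_extreme_groups(self):
        # group means/SDs/ns shaped like the polarized shape-FD summary
        rng = np.random.default_rng(7)
        df = make_records({
            "MM": rng.normal(1.3885, 0.0404, 20),
            "DN": rng.normal(1.4225, 0.0393, 23),
            "BN": rng.normal(1.4713, 0.0579, 54),
        })
        rep = group_comparison(df, "shape_fd")
        assert rep.pairwise.loc["MM", "BN"] < 0.001

    def test_null_permutation_p_uniform(self):
        rng = np.random.default_rng(11)
        pool = rng.normal(0, 1, 60)
        pvals = []
        for _ in range(200):
            labels = rng.permutation(np.repeat(["MM", "DN", "BN"], 20))
            df = pd.DataFrame({"group": labels, "v": pool})
            groups = {g: df.loc[df.group == g, "v"].to_numpy() for g in ("MM", "DN", "BN")}
            pvals.append(float(sps.kruskal(*groups.values()).pvalue))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_nonparametric_branch_reports_mean_ranks(self):
        rng = np.random.default_rng(13)
        df = make_records({g: rng.lognormal(0, 1.5, 20) for g in ("MM", "DN", "BN")})
        rep = group_comparison(df, "shape_fd")
        assert "Kruskal" in rep.test_name
        assert "mean_rank" in rep.table.columns

    def test_small_group_rejected(self):
        df = make_records({"MM": [1, 2], "BN": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="n >= 3"):
            group_comparison(df, "shape_fd")


class TestPostHocMachinery:
    def test_fisher_lsd_matches_pooled_t_by_hand(self):
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([2.0, 3, 4]),
                  "c": np.array([5.0, 6, 7])}
        pw = fisher_lsd(groups)
        # hand: MSE = 1.0 (each group var 1, df 6), se = sqrt(1*(2/3))
        t = (1 / np.sqrt(2 / 3))
        expected = 2 * sps.t.sf(t, 6)
        assert pw.loc["a", "b"] == pytest.approx(expected)
        assert (pw.values.T == pw.values)[~np.isnan(pw.values)].all()

    def test_dunn_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(17)
        base = rng.normal(0, 1, 30)
        groups = {"a": base, "b": base + 1e-4 * rng.normal(size=30), "c": base + 5}
        pw, ranks = dunn_bonferroni(groups)
        assert pw.loc["a", "b"] == 1.0  # near-identical pair, Bonferroni capped
        assert pw.loc["a", "c"] < 0.01
        assert set(ranks.index) == {"a", "b", "c"}

    def test_dunn_mean_ranks_ordering(self):
        groups = {"lo": np.arange(10.0), "hi": np.arange(10.0) + 100}
        pw, ranks = dunn_bonferroni(groups)
        assert ranks["hi"] > ranks["lo"]


class TestCorrelationMatrix:
    def _records(self, fd, area, group="BN", illum="PL"):
        n = len(fd)
        return pd.DataFrame({
            "lesion_id": [f"x{i}" for i in range(n)], "group": group,
            "illumination": illum, "shape_fd": fd, "area": area,
            "perimeter": np.sqrt(area),
        })

    def test_perfect_monotone_decreasing(self):
        fd = np.linspace(1.5, 1.3, 10)
        area = np.linspace(10, 100, 10)
        out = correlation_matrix(self._records(fd, area))
        r = out[(out.group == "BN") & (out.illumination == "PL")
                & (out.pair == "shape_fd vs area")]["spearman_r"].item()
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_mostly_uncorrelated(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            out = correlation_matrix(
                self._records(rng.normal(1.4, 0.05, 50), rng.uniform(5, 50, 50))
            )
            r = out[out.pair == "shape_fd vs area"]["spearman_r"].iloc[0]
            hits += abs(r) < 0.3
        assert hits >= 95

    def test_ties_only_reported_missing(self):
        out = correlation_matrix(self._records(np.full(10, 1.4), np.arange(10.0)))
        assert out[out.pair == "shape_fd vs area"]["spearman_r"].isna().all()


class TestMelanomaSubgroups:
    def _df(self, in_situ, invasive, variable="shape_fd"):
        rows = []
        for stage, vals in (("in_situ", in_situ), ("invasive", invasive)):
            for i, v in enumerate(vals):
                rows.append({"lesion_id": f"{stage}{i}", "group": "MM",
                             "melanoma_stage": stage, variable: v})
        return pd.DataFrame(rows)

    def test_identical_subgroups_not_significant(self):
        v = np.random.default_rng(23).normal(1.4, 0.02, 10)
        rep = melanoma_subgroup_test(self._df(v, v), "shape_fd")
        assert rep.extra["p"] > 0.9

    def test_separated_subgroups_detected(self):
        rng = np.random.default_rng(29)
        rep = melanoma_subgroup_test(
            self._df(rng.normal(1.4166, 0.0165, 8), rng.normal(1.3708, 0.0165, 12)),
            "shape_fd",
        )
        assert rep.extra["p"] < 0.05

    def test_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(1.42, 0.02, 8), rng.normal(1.37, 0.02, 12)
        p1 = melanoma_subgroup_test(self._df(a, b), "shape_fd").extra["p"]
        p2 = melanoma_subgroup_test(self._df(b, a), "shape_fd").extra["p"]
        assert p1 == pytest.approx(p2)

    def test_empty_subgroup_unavailable(self):
        rep = melanoma_subgroup_test(self._df([], [1.3, 1.4, 1.5]), "shape_fd")
        assert rep.test_name == "unavailable"
        assert isinstance(rep, StatsReport) and rep.table.empty
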