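"""Group-comparison statistics for the lesion measurements.

The analysis design: every variable is first screened with the
Shapiro–Wilk normality test per group at α = 0.05. If all groups pass,
parametric tests are used (paired/unpaired Student t, one-way ANOVA with
Fisher LSD post hoc); otherwise nonparametric analogues (Wilcoxon
signed-rank, Mann–Whitney U, Kruskal–Wallis with Dunn-type multiple
comparison of mean ranks, Bonferroni-adjusted and capped at 1). Spearman
correlations relate shape FD to lesion area and perimeter per group and
illumination.

Scipy supplies every individual test; this module owns the gating,
pairing, rank post hoc and table assembly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05
GROUP_ORDER = ("MM", "DN", "BN")


@dataclass(frozen=True)
class StatsReport:
    """One comparison table: the test used, summary rows, pairwise p's."""

    test_name: str
    variable: str
    normality_decision: str  # "parametric" | "nonparametric"
    table: pd.DataFrame
    pairwise: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normality gate


def normality_gate(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> str:
    """Shapiro–Wilk screen: 'parametric' only if every group passes.

    Groups with n < 3 or zero variance cannot be tested and force the
    nonparametric branch (logged).
    """
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 3:
            logger.info("group %s has n=%d < 3: nonparametric by default", name, v.size)
            return "nonparametric"
        if np.ptp(v) == 0:
            logger.info("group %s is constant: nonparametric by default", name)
            return "nonparametric"
        if sps.shapiro(v).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# post hoc machinery


def fisher_lsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Fisher least-significant-difference pairwise p's after ANOVA.

    Pairwise t statistics use the pooled within-group mean square with
    N - k degrees of freedom; no family-wise correction, by design.
    """
    names = list(groups)
    vals = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    ns = {g: v.size for g, v in vals.items()}
    n_total = sum(ns.values())
    k = len(names)
    if any(n < 2 for n in ns.values()) or n_total <= k:
        raise ValueError("Fisher LSD needs at least 2 observations per group")
    mse = sum(((v - v.mean()) ** 2).sum() for v in vals.values()) / (n_total - k)
    df = n_total - k
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        t = (vals[a].mean() - vals[b].mean()) / se
        p = 2.0 * sps.t.sf(abs(t), df)
        out.loc[a, b] = out.loc[b, a] = p
    return out


def dunn_bonferroni(groups: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.Series]:
    """Dunn's multiple comparison of mean ranks, Bonferroni-adjusted.

    z statistics are built from the joint-ranking mean ranks with the
    standard tie correction; each two-sided p is multiplied by the number
    of pairs and capped at 1. Returns the pairwise p matrix and the mean
    ranks.
    """
    names = list(groups)
    vals = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    ns = {g: v.size for g, v in vals.items()}
    pooled = np.concatenate([vals[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = float(ranks[start : start + ns[g]].mean())
        start += ns[g]
    # tie correction: 1 - sum(t^3 - t) / (N^3 - N)
    _, counts = np.unique(pooled, return_counts=True)
    ties = ((counts**3 - counts).sum()) / (n_total**3 - n_total)
    correction = 1.0 - ties
    m = len(names) * (len(names) - 1) // 2
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a, b in itertools.combinations(names, 2):
        if ns[a] < 3 or ns[b] < 3:
            continue  # cell reported as unavailable
        var = (n_total * (n_total + 1) / 12.0) * correction * (1.0 / ns[a] + 1.0 / ns[b])
        z = abs(mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(z) * m)
        out.loc[a, b] = out.loc[b, a] = p
    return out, pd.Series(mean_ranks, name="mean_rank")


# ---------------------------------------------------------------------------
# analysis-design operations


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"records are missing columns {missing}")


def paired_illumination_test(records: pd.DataFrame, variable: str) -> StatsReport:
    """Per-group PL vs NPL comparison of one variable on paired lesions.

    Lesions lacking either illumination record are excluded with a
    warning. The normality gate runs on the paired differences of every
    group; the parametric branch is the paired Student t, the
    nonparametric one the Wilcoxon signed-rank test.
    """
    _require_columns(records, ["lesion_id", "group", "illumination", variable])
    wide = records.pivot_table(
        index=["lesion_id", "group"], columns="illumination", values=variable
    ).reset_index()
    incomplete = wide[wide[["PL", "NPL"]].isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "excluding %d unpaired lesion(s): %s",
            len(incomplete),
            list(incomplete["lesion_id"]),
        )
        wide = wide.dropna(subset=["PL", "NPL"])
    groups_present = [g for g in GROUP_ORDER if g in set(wide["group"])] or sorted(
        set(wide["group"])
    )
    diffs = {g: (wide.loc[wide.group == g, "PL"] - wide.loc[wide.group == g, "NPL"]).to_numpy()
             for g in groups_present}
    decision = normality_gate(diffs)
    rows = []
    for g in groups_present:
        sub = wide[wide.group == g]
        pl, npl = sub["PL"].to_numpy(float), sub["NPL"].to_numpy(float)
        d = pl - npl
        if decision == "parametric":
            p = float(sps.ttest_rel(pl, npl).pvalue) if len(d) > 1 else np.nan
        else:
            p = float(sps.wilcoxon(pl, npl).pvalue) if np.any(d != 0) else 1.0
        rows.append(
            {
                "group": g,
                "variable": variable,
                "mean_PL": pl.mean(),
                "sd_PL": pl.std(ddof=1) if len(pl) > 1 else np.nan,
                "mean_NPL": npl.mean(),
                "sd_NPL": npl.std(ddof=1) if len(npl) > 1 else np.nan,
                "n": len(sub),
                "mean_difference": d.mean(),
                "p": p,
            }
        )
    name = "paired t-test" if decision == "parametric" else "Wilcoxon signed-rank"
    return StatsReport(name, variable, decision, pd.DataFrame(rows))


def group_comparison(
    records: pd.DataFrame,
    variable: str,
    illumination: str | None = None,
) -> StatsReport:
    """Compare one variable across lesion groups (ANOVA+LSD or KW+Dunn).

    When ``illumination`` is given, only records of that illumination
    enter. The normality gate runs per group; the parametric branch is
    one-way ANOVA with Fisher LSD pairwise p's, the nonparametric branch
    Kruskal–Wallis with Bonferroni-capped Dunn comparisons and mean ranks.
    """
    _require_columns(records, ["group", variable])
    df = records
    if illumination is not None:
        df = df[df["illumination"] == illumination]
    df = df.dropna(subset=[variable])
    groups_present = [g for g in GROUP_ORDER if g in set(df["group"])] or sorted(
        set(df["group"])
    )
    if len(groups_present) < 2:
        raise ValueError("need at least two groups to compare")
    groups = {g: df.loc[df.group == g, variable].to_numpy(float) for g in groups_present}
    if any(v.size < 3 for v in groups.values()):
        raise ValueError("every group needs n >= 3")
    decision = normality_gate(groups)
    summary_rows = []
    if decision == "parametric":
        overall = float(sps.f_oneway(*groups.values()).pvalue)
        pairwise = fisher_lsd(groups)
        for g, v in groups.items():
            summary_rows.append(
                {"group": g, "n": v.size, "mean": v.mean(), "sd": v.std(ddof=1)}
            )
        name = "one-way ANOVA + Fisher LSD"
    else:
        overall = float(sps.kruskal(*groups.values()).pvalue)
        pairwise, mean_ranks = dunn_bonferroni(groups)
        for g, v in groups.items():
            summary_rows.append(
                {"group": g, "n": v.size, "mean": v.mean(), "sd": v.std(ddof=1),
                 "mean_rank": mean_ranks[g]}
            )
        name = "Kruskal-Wallis + Dunn (Bonferroni)"
    return StatsReport(
        name,
        variable,
        decision,
        pd.DataFrame(summary_rows),
        pairwise=pairwise,
        extra={"overall_p": overall, "illumination": illumination},
    )


def correlation_matrix(records: pd.DataFrame, variable: str = "shape_fd") -> pd.DataFrame:
    """Spearman r of shape FD vs area and perimeter, per group × illumination.

    Groups with fewer than 5 lesions, or ties-only vectors, are reported
    as missing.
    """
    _require_columns(records, ["group", "illumination", variable, "area", "perimeter"])
    rows = []
    groups_present = [g for g in GROUP_ORDER if g in set(records["group"])]
    for g in groups_present:
        for illum in ("PL", "NPL"):
            sub = records[(records.group == g) & (records.illumination == illum)]
            for other in ("area", "perimeter"):
                pair = sub[[variable, other]].dropna()
                if len(pair) < 5 or pair[variable].nunique() < 2 or pair[other].nunique() < 2:
                    r = np.nan
                else:
                    r = float(sps.spearmanr(pair[variable], pair[other]).statistic)
                rows.append(
                    {"group": g, "illumination": illum,
                     "pair": f"{variable} vs {other}", "spearman_r": r,
                     "n": len(pair)}
                )
    return pd.DataFrame(rows)


def melanoma_subgroup_test(
    records: pd.DataFrame,
    variable: str,
    paired_variable: bool = False,
) -> StatsReport:
    """Compare melanoma in-situ vs invasive subgroups on one variable.

    Uses the normality gate to pick the unpaired Student t or the
    Mann–Whitney U test. For lesion-level shape FD the gate typically
    lands parametric; ROI-level surface FD is heavier-tailed and lands
    nonparametric, mirroring the analysis design.
    """
    _require_columns(records, ["group", "melanoma_stage", variable])
    mm = records[(records.group == "MM") & records["melanoma_stage"].notna()]
    mm = mm.dropna(subset=[variable])
    stages = ("in_situ", "invasive")
    groups = {s: mm.loc[mm.melanoma_stage == s, variable].to_numpy(float) for s in stages}
    if any(v.size == 0 for v in groups.values()):
        empty = [s for s, v in groups.items() if v.size == 0]
        return StatsReport(
            "unavailable", variable, "nonparametric",
            pd.DataFrame(), extra={"reason": f"empty subgroup(s): {empty}"},
        )
    decision = normality_gate(groups)
    a, b = groups["in_situ"], groups["invasive"]
    if decision == "parametric":
        p = float(sps.ttest_ind(a, b).pvalue)
        name = "unpaired t-test"
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        name = "Mann-Whitney U"
    table = pd.DataFrame(
        [
            {"subgroup": s, "n": v.size, "mean": v.mean(),
             "sd": v.std(ddof=1) if v.size > 1 else np.nan}
            for s, v in groups.items()
        ]
    )
    return StatsReport(name, variable, decision, table, extra={"p": p})
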