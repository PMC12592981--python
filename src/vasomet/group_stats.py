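"""Group-level statistics for the morphometry and permeability readouts.

Covers the tests used to compare genotype groups: Kruskal-Wallis omnibus with
Conover-Iman rank post-hoc, two-way ANOVA with Tukey HSD, two-way
repeated-measures (split-plot) ANOVA with Greenhouse-Geisser sphericity
correction, Wilcoxon signed-rank, and relative qPCR quantification
(delta-delta-Ct / RQ). Ties are handled by midranks throughout; Conover
p-values are unadjusted by default (Holm and Bonferroni available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult", "kruskal_wallis", "conover_posthoc", "anova_two_way",
    "rm_anova_two_way", "wilcoxon_signed_rank", "ddct_rq",
]


class StatsError(ValueError):
    """Raised for designs the requested test cannot handle."""


@dataclass
class TestResult:
    """A named test statistic with degrees of freedom, p-value and, for
    post-hoc procedures, the pairwise comparison table."""

    name: str
    statistic: float
    df: tuple[float, ...] | float
    pvalue: float
    table: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def _as_groups(data: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    for k, v in groups.items():
        if v.size < 1:
            raise StatsError(f"group {k!r} is empty")
    return groups


def _rank_stats(groups: dict[str, np.ndarray]):
    """Pooled midranks, per-group mean ranks, and the tie-corrected H."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = np.array([groups[g].size for g in labels])
    N = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum(n)
    mean_ranks = np.array([r.mean() for r in np.split(ranks, bounds[:-1])])
    h = (12.0 / (N * (N + 1))) * np.sum(n * (mean_ranks - (N + 1) / 2.0) ** 2)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N) if N > 1 else 1.0
    if tie_corr > 0:
        h /= tie_corr
    return labels, ranks, n, N, mean_ranks, h


def kruskal_wallis(data: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with midrank tie correction, chi-square p on k-1 df.

    All observations identical is not an error: H = 0, p = 1.
    """
    groups = _as_groups(data)
    k = len(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        return TestResult("Kruskal-Wallis H", 0.0, float(k - 1), 1.0)
    h, p = stats.kruskal(*groups.values())
    return TestResult("Kruskal-Wallis H", float(h), float(k - 1), float(p))


def conover_posthoc(data: Mapping[str, Sequence[float]],
                    adjust: str | None = None) -> TestResult:
    """Conover-Iman all-pairs rank t-tests after Kruskal-Wallis.

    ``t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 * ((N-1-H)/(N-k)) * (1/n_i + 1/n_j))``
    on N-k degrees of freedom, where S^2 is the variance of the pooled
    midranks and H the tie-corrected Kruskal-Wallis statistic. p-values are
    two-sided; ``adjust`` may be None (default), 'holm' or 'bonferroni'.
    """
    groups = _as_groups(data)
    labels, ranks, n, N, mean_ranks, h = _rank_stats(groups)
    k = len(labels)
    if N <= k:
        raise StatsError("need more observations than groups")
    s2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    scale = s2 * (N - 1 - h) / (N - k)
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(labels), 2):
        denom2 = scale * (1.0 / n[i] + 1.0 / n[j])
        if denom2 <= 0:  # all observations identical
            t, p = 0.0, 1.0
        else:
            t = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom2)
            p = 2.0 * stats.t.sf(abs(t), df=N - k)
        rows.append({"group_a": gi, "group_b": gj, "statistic": float(t),
                     "p_raw": float(min(p, 1.0))})
    table = pd.DataFrame(rows)
    if adjust is None or adjust == "none":
        table["p_adj"] = table["p_raw"]
    elif adjust in ("holm", "bonferroni"):
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p_raw"], method=adjust)[1]
    else:
        raise StatsError(f"unknown adjustment {adjust!r}")
    return TestResult("Conover-Iman t", float(h), float(N - k),
                      float(table["p_adj"].min()), table=table,
                      extra={"adjust": adjust or "none"})


def conover_pvalue(result: TestResult, a: str, b: str,
                   adjusted: bool = True) -> float:
    """Pairwise p from a Conover table, symmetric in comparison order."""
    t = result.table
    col = "p_adj" if adjusted else "p_raw"
    hit = t[((t.group_a == a) & (t.group_b == b)) |
            ((t.group_a == b) & (t.group_b == a))]
    if hit.empty:
        raise StatsError(f"no comparison {a!r} vs {b!r}")
    return float(hit.iloc[0][col])


def anova_two_way(df: pd.DataFrame, dv: str, factor_a: str, factor_b: str,
                  tukey: bool = False) -> TestResult:
    """Two-way ANOVA (type II sums of squares) with optional Tukey HSD.

    Returns the interaction row as headline statistic; the full effect table
    (both main effects and the interaction) is in ``table``. Zero-variance
    data yields F = 0, not NaN.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df.rename(columns={dv: "_y", factor_a: "_a", factor_b: "_b"})
    cells = d.groupby(["_a", "_b"], observed=True).size()
    n_a, n_b = d["_a"].nunique(), d["_b"].nunique()
    if len(cells) < n_a * n_b:
        raise StatsError("empty cells in the two-way design")
    model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={"C(_a)": factor_a, "C(_b)": factor_b,
                            "C(_a):C(_b)": f"{factor_a}:{factor_b}"})
    # effects with negligible SS (incl. 0/0 noise-free designs): F = 0, p = 1
    data_scale = float((d["_y"].to_numpy() ** 2).sum()) + 1.0
    zero = aov["sum_sq"].abs() <= 1e-12 * data_scale
    aov.loc[zero, "F"] = 0.0
    aov.loc[zero, "PR(>F)"] = 1.0
    aov.loc["Residual", ["F", "PR(>F)"]] = np.nan
    inter = f"{factor_a}:{factor_b}"
    res = TestResult(
        "two-way ANOVA F", float(aov.loc[inter, "F"]),
        (float(aov.loc[inter, "df"]), float(aov.loc["Residual", "df"])),
        float(aov.loc[inter, "PR(>F)"]), table=aov.reset_index())
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        combo = d["_a"].astype(str) + ":" + d["_b"].astype(str)
        tk = pairwise_tukeyhsd(d["_y"], combo)
        res.extra["tukey"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0])
    return res


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a within-subject covariance matrix.

    Equals 1 exactly under sphericity (e.g. any compound-symmetric
    covariance) and 1/(k-1) at the opposite extreme. Note the *sample*
    estimate is biased downward by roughly (k-1)/n even when the population
    is spherical.
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    denom = (k - 1) * np.sum(Sc ** 2)
    eps = (np.trace(Sc) ** 2 / denom) if denom > 0 else 1.0
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_two_way(df: pd.DataFrame, dv: str = "value",
                     subject: str = "subject", within: str = "time",
                     between: str = "group",
                     correction: str | None = "greenhouse_geisser"
                     ) -> TestResult:
    """Two-way repeated-measures (split-plot) ANOVA: one between-subject
    factor, one within-subject factor, every subject observed at every
    within level.

    Greenhouse-Geisser epsilon (from the double-centered pooled within-group
    covariance of the repeated measures) multiplies the within-effect degrees
    of freedom when ``correction='greenhouse_geisser'``; fractional reported
    dfs are the corrected ones. The headline statistic is the interaction F.
    """
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv,
                          aggfunc="mean", observed=True)
    if wide.isna().any().any():
        raise StatsError("unbalanced design: every subject needs every "
                         "within-factor level")
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise StatsError("duplicate observations per subject x within cell")
    y = wide.to_numpy(dtype=float)           # (N subjects, k levels)
    grp = wide.index.get_level_values(1).to_numpy()
    glabels, ginv = np.unique(grp, return_inverse=True)
    g, k = glabels.size, y.shape[1]
    N = y.shape[0]
    if g < 2 or k < 2:
        raise StatsError("need >= 2 groups and >= 2 within levels")
    n_i = np.bincount(ginv)

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[ginv == i].mean() for i in range(g)])
    time_means = y.mean(axis=0)
    cell_means = np.vstack([y[ginv == i].mean(axis=0) for i in range(g)])

    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_group = k * np.sum(n_i * (group_means - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_time = np.sum(n_i.sum() * (time_means - grand) ** 2)
    ss_inter = np.sum(n_i[:, None] * (cell_means - group_means[:, None]
                                      - time_means[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = ss_total - ss_group - ss_subj_within - ss_time - ss_inter

    df_group, df_subj = g - 1, N - g
    df_time, df_inter = k - 1, (g - 1) * (k - 1)
    df_error = (N - g) * (k - 1)

    ms = lambda ss, d: ss / d if d > 0 else np.nan
    f_group = ms(ss_group, df_group) / ms(ss_subj_within, df_subj)
    f_time = ms(ss_time, df_time) / ms(ss_error, df_error)
    f_inter = ms(ss_inter, df_inter) / ms(ss_error, df_error)

    # Greenhouse-Geisser epsilon from the pooled within-group covariance
    resid = y - cell_means[ginv]
    S = resid.T @ resid / (N - g) if N - g > 0 else np.eye(k)
    eps = gg_epsilon(S)
    use_gg = correction in ("greenhouse_geisser", "gg")
    e = eps if use_gg else 1.0

    p_group = stats.f.sf(f_group, df_group, df_subj)
    p_time = stats.f.sf(f_time, e * df_time, e * df_error)
    p_inter = stats.f.sf(f_inter, e * df_inter, e * df_error)

    table = pd.DataFrame([
        {"effect": between, "ss": ss_group, "df1": df_group, "df2": df_subj,
         "F": f_group, "p": p_group, "eps": np.nan},
        {"effect": within, "ss": ss_time, "df1": e * df_time,
         "df2": e * df_error, "F": f_time, "p": p_time, "eps": eps},
        {"effect": f"{within}x{between}", "ss": ss_inter, "df1": e * df_inter,
         "df2": e * df_error, "F": f_inter, "p": p_inter, "eps": eps},
    ])
    return TestResult("RM-ANOVA interaction F", float(f_inter),
                      (float(e * df_inter), float(e * df_error)),
                      float(p_inter), table=table,
                      extra={"eps": eps, "correction": correction or "none"})


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None
                         ) -> TestResult:
    """Wilcoxon signed-rank on paired differences.

    Zero differences are discarded (Wilcoxon's rule); the exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise StatsError("all paired differences are zero")
    exact_ok = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    method = "exact" if exact_ok else "approx"
    w, p = stats.wilcoxon(d, method=method, correction=(method == "approx"))
    return TestResult("Wilcoxon W", float(w), float(d.size), float(p),
                      extra={"method": method})


def ddct_rq(records: pd.DataFrame, calibrator_group: str,
            sample: str = "sample", group: str = "group",
            ct_target: str = "ct_target", ct_reference: str = "ct_reference"
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative qPCR quantification by the delta-delta-Ct method.

    Technical replicates (rows sharing a sample id) are averaged per
    biological sample first. Per sample: ``dCt = Ct_target - Ct_reference``.
    Per group: ``ddCt = mean dCt(group) - mean dCt(calibrator)`` and
    ``RQ = 2**(-ddCt)``; ``-ddCt`` is reported alongside.
    """
    df = records[[sample, group, ct_target, ct_reference]].copy()
    if df[[ct_target, ct_reference]].isna().any().any():
        raise StatsError("missing Ct values")
    if not (np.isfinite(df[ct_target]).all() and np.isfinite(df[ct_reference]).all()):
        raise StatsError("Ct values must be finite")
    if (df[ct_target] <= 0).any() or (df[ct_reference] <= 0).any():
        raise StatsError("Ct values must be positive")
    per_sample = (df.groupby([sample, group], observed=True)
                  .mean(numeric_only=True).reset_index())
    per_sample["dct"] = per_sample[ct_target] - per_sample[ct_reference]
    if calibrator_group not in set(per_sample[group]):
        raise StatsError(f"calibrator group {calibrator_group!r} not present")
    cal = per_sample.loc[per_sample[group] == calibrator_group, "dct"].mean()
    per_group = (per_sample.groupby(group, observed=True)["dct"].mean()
                 .rename("mean_dct").reset_index())
    per_group["ddct"] = per_group["mean_dct"] - cal
    per_group["minus_ddct"] = -per_group["ddct"]
    per_group["rq"] = 2.0 ** (-per_group["ddct"])
    per_sample["rq_vs_calibrator"] = 2.0 ** (-(per_sample["dct"] - cal))
    return per_sample, per_group
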