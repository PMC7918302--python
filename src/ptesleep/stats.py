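"""Group statistics for pipeline outputs.

Implements the study's battery: one-way ANOVA with Holm-adjusted
pairwise contrasts, a split-plot ("mixed") ANOVA with group as the
between-animal fixed factor and diurnal bin as the repeated factor
(Tukey-Kramer pairwise correction), Welch two-sample t-tests with
Bonferroni doubling, and hourly event-vs-wake Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sci
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, InsufficientReplicationError


# ---------------------------------------------------------------- Welch

def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicationError("Welch t needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sci.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_bonferroni(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Welch t per named pair; p multiplied by the comparison count.

    Corrected p is capped at 1; the uncapped product is kept in
    ``p_corrected_uncapped``.
    """
    if not pairs:
        raise ConfigurationError("no pairs to test")
    m = n_comparisons if n_comparisons is not None else len(pairs)
    rows = []
    for name, (a, b) in pairs.items():
        t, df, p = welch_t(a, b)
        rows.append(
            {
                "contrast": name,
                "t": t,
                "df": df,
                "p_uncorrected": p,
                "p_corrected": min(1.0, m * p),
                "p_corrected_uncapped": m * p,
                "method": f"welch_t_bonferroni_x{m}",
            }
        )
    return pd.DataFrame(rows).set_index("contrast")


# ------------------------------------------------------- one-way ANOVA

def one_way_anova_holm(
    groups: dict[str, np.ndarray],
    contrasts: list[tuple[str, str]] | None = None,
) -> dict:
    """Classical one-way F test plus Holm-adjusted pairwise t contrasts.

    Pairwise contrasts use the pooled ANOVA error term.  A design where
    every group has zero variance is flagged and reported as a limit
    case rather than raising.
    """
    names = list(groups)
    if len(names) < 2:
        raise ConfigurationError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise InsufficientReplicationError("each group needs >= 2 values")

    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    n_tot = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrays)))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1, df2 = k - 1, n_tot - k
    degenerate = ss_within == 0
    if degenerate:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(sci.f.sf(F, df1, df2))
    mse = ss_within / df2 if df2 > 0 else np.nan

    if contrasts is None:
        contrasts = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)]
    raw = []
    for ga, gb in contrasts:
        a, b = groups[ga], groups[gb]
        if degenerate:
            equal = np.mean(a) == np.mean(b)
            raw.append((ga, gb, 0.0 if equal else np.inf, 1.0 if equal else 0.0))
            continue
        se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        t = (np.mean(a) - np.mean(b)) / se
        raw.append((ga, gb, float(t), float(2 * sci.t.sf(abs(t), df2))))
    pvals = [r[3] for r in raw]
    adj = multipletests(pvals, method="holm")[1] if pvals else []
    table = pd.DataFrame(
        [
            {"group_a": ga, "group_b": gb, "t": t, "p_raw": p_raw, "p_holm": p_adj}
            for (ga, gb, t, p_raw), p_adj in zip(raw, adj)
        ]
    )
    return {
        "test": "one_way_anova",
        "F": float(F),
        "df1": df1,
        "df2": df2,
        "p": float(p),
        "degenerate": degenerate,
        "contrasts": table,
    }


# ----------------------------------------------- split-plot mixed ANOVA

def tukey_kramer(
    means: dict[str, float],
    ns: dict[str, int],
    mse: float,
    df_error: int,
) -> pd.DataFrame:
    """Tukey-Kramer pairwise p-values from the studentized range.

    Reduces to classical Tukey HSD for balanced group sizes.
    """
    names = list(means)
    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
            if se == 0:
                q = np.inf if means[a] != means[b] else 0.0
            else:
                q = abs(means[a] - means[b]) / se
            p = float(sci.studentized_range.sf(q, k, df_error))
            rows.append({"group_a": a, "group_b": b, "q": float(q), "p_tukey": p})
    return pd.DataFrame(rows)


def mixed_anova(
    df: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    animal: str = "animal_id",
    time_bin: str = "bin",
) -> dict:
    """Split-plot ANOVA: group between animals, bin repeated within.

    Expects one value per animal x bin (complete crossed design).  The
    group effect is tested against between-animal variation (animals
    within groups), the bin and interaction effects against the
    within-animal residual.  Tukey-Kramer pairwise p-values are computed
    on animal means with the between-animal error term.  With a single
    bin this degenerates to a one-way ANOVA on animal values.
    """
    d = df[[animal, group, time_bin, value]].dropna()
    bins = sorted(d[time_bin].unique())
    animals = d[animal].unique()
    grp_of = d.drop_duplicates(animal).set_index(animal)[group]
    groups = sorted(grp_of.unique())
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups")
    if len(bins) < 2:
        res = one_way_anova_holm(
            {g: d.loc[d[group] == g, value].to_numpy() for g in groups}
        )
        res["warning"] = "single bin: degenerated to one-way ANOVA"
        return res

    pivot = d.pivot_table(index=animal, columns=time_bin, values=value)
    if pivot.isna().any().any():
        raise ConfigurationError("design must be complete (every animal x bin)")
    y = pivot.to_numpy()
    N, b = y.shape
    garr = grp_of.loc[pivot.index].to_numpy()
    k = len(groups)
    if N <= k:
        raise InsufficientReplicationError("need more animals than groups")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    bin_means = y.mean(axis=0)
    group_sizes = {g: int(np.sum(garr == g)) for g in groups}
    group_means = {g: float(subj_means[garr == g].mean()) for g in groups}

    ss_between_subj = b * float(((subj_means - grand) ** 2).sum())
    ss_group = b * float(
        sum(group_sizes[g] * (group_means[g] - grand) ** 2 for g in groups)
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_bin = N * float(((bin_means - grand) ** 2).sum())
    ss_int = 0.0
    for g in groups:
        cell = y[garr == g]
        cell_means = cell.mean(axis=0)
        ss_int += group_sizes[g] * float(
            ((cell_means - group_means[g] - bin_means + grand) ** 2).sum()
        )
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_between_subj - ss_bin - ss_int

    df_group, df_subj = k - 1, N - k
    df_bin, df_int = b - 1, (k - 1) * (b - 1)
    df_err = (N - k) * (b - 1)

    ms_group = ss_group / df_group
    ms_subj = ss_subj_within / df_subj
    ms_bin = ss_bin / df_bin
    ms_int = ss_int / df_int
    ms_err = max(ss_err, 0.0) / df_err

    def ftest(ms_num, df_num, ms_den, df_den):
        if ms_den == 0:
            return (np.inf if ms_num > 0 else 0.0,
                    0.0 if ms_num > 0 else 1.0)
        F = ms_num / ms_den
        return float(F), float(sci.f.sf(F, df_num, df_den))

    F_g, p_g = ftest(ms_group, df_group, ms_subj, df_subj)
    F_b, p_b = ftest(ms_bin, df_bin, ms_err, df_err)
    F_i, p_i = ftest(ms_int, df_int, ms_err, df_err)

    tukey = tukey_kramer(group_means, group_sizes, ms_subj / b, df_subj)
    return {
        "test": "split_plot_anova",
        "group": {"F": F_g, "df1": df_group, "df2": df_subj, "p": p_g},
        "bin": {"F": F_b, "df1": df_bin, "df2": df_err, "p": p_b},
        "interaction": {"F": F_i, "df1": df_int, "df2": df_err, "p": p_i},
        "tukey_kramer": tukey,
    }


# ---------------------------------------------------------- correlation

def hourly_event_wake_correlation(
    events_per_hour: np.ndarray, wake_min_per_hour: np.ndarray
) -> dict:
    """Pearson correlation of hourly event counts with hourly wake time."""
    x = np.asarray(events_per_hour, dtype=float)
    y = np.asarray(wake_min_per_hour, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigurationError("need >= 3 paired hours")
    if x.std() == 0 or y.std() == 0:
        return {"r": np.nan, "r2": np.nan, "p": np.nan, "n": len(x),
                "note": "zero variance; correlation undefined"}
    r, p = sci.pearsonr(x, y)
    return {"r": float(r), "r2": float(r * r), "p": float(p), "n": len(x)}


def skewness_report(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Descriptive skewness per group (no gating is applied)."""
    return pd.DataFrame(
        [
            {"group": g, "n": len(v), "skewness": float(sci.skew(np.asarray(v, float)))}
            for g, v in groups.items()
        ]
    ).set_index("group")
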