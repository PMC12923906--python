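"""Nonparametric session/group statistics with Holm correction.

Within-group comparisons across sessions use a Friedman omnibus when the
design is paired (every animal measured in every session) and Kruskal-Wallis
otherwise, followed by pairwise Wilcoxon signed-rank or rank-sum tests.
Between-group comparisons use two-sided Mann-Whitney U.  All pairwise
families are Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError


@dataclass
class StatReport:
    omnibus_test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns a, b, test, statistic, p_raw, p_holm


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never below raw)."""
    p_values = np.asarray(p_values, dtype=float)
    if len(p_values) == 0:
        return p_values
    return multipletests(p_values, method="holm")[1]


def _is_paired(table: pd.DataFrame, sessions: list[str]) -> bool:
    counts = table.pivot_table(
        index="animal_id", columns="session", values="value", aggfunc="count"
    )
    return (
        not counts.empty
        and set(sessions) <= set(counts.columns)
        and (counts[sessions].fillna(0) == 1).all().all()
    )


def compare_sessions_within(
    table: pd.DataFrame,
    group: str | None = None,
    metric: str | None = None,
    paired: bool | None = None,
) -> StatReport:
    """Omnibus + Holm-adjusted pairwise comparison of a metric across sessions.

    ``table`` is tidy with columns animal_id, session, value (plus optional
    group / metric_name columns filtered by the keyword arguments).  When
    ``paired`` is None the design is inspected: one value per animal per
    session selects the paired family (Friedman + signed-rank).
    """
    df = table.copy()
    if group is not None and "group" in df.columns:
        df = df[df["group"] == group]
    if metric is not None and "metric_name" in df.columns:
        df = df[df["metric_name"] == metric]
    sessions = sorted(df["session"].unique())
    if len(sessions) < 2:
        raise ValidationError("need at least 2 sessions to compare")
    if paired is None:
        paired = "animal_id" in df.columns and _is_paired(df, sessions)

    by_session = {s: df.loc[df["session"] == s, "value"].to_numpy() for s in sessions}
    if min(len(v) for v in by_session.values()) < 2:
        raise ValidationError("need at least 2 observations per session")

    if paired:
        wide = df.pivot_table(index="animal_id", columns="session", values="value")
        wide = wide[sessions].dropna()
        cols = [wide[s].to_numpy() for s in sessions]
        if all(np.array_equal(c, cols[0]) for c in cols[1:]):
            stat, p = 0.0, 1.0
            omnibus = "friedman" if len(cols) >= 3 else "wilcoxon-signed-rank"
        elif len(cols) >= 3:
            stat, p = stats.friedmanchisquare(*cols)
            omnibus = "friedman"
        else:  # two paired sessions: the signed-rank test is the omnibus
            stat, p = stats.wilcoxon(cols[0], cols[1])
            omnibus = "wilcoxon-signed-rank"
    else:
        cols = [by_session[s] for s in sessions]
        pooled = np.concatenate(cols)
        if np.all(pooled == pooled[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*cols)
        omnibus = "kruskal-wallis"

    rows = []
    for a, b in combinations(sessions, 2):
        if paired:
            xa = wide[a].to_numpy()
            xb = wide[b].to_numpy()
            if np.array_equal(xa, xb):
                s_ab, p_ab, test = 0.0, 1.0, "wilcoxon-signed-rank"
            else:
                s_ab, p_ab = stats.wilcoxon(xa, xb)
                test = "wilcoxon-signed-rank"
        else:
            s_ab, p_ab = stats.ranksums(by_session[a], by_session[b])
            test = "wilcoxon-rank-sum"
        rows.append({"a": a, "b": b, "test": test, "statistic": float(s_ab), "p_raw": float(p_ab)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    return StatReport(omnibus, float(stat), float(p), pairwise)


def compare_groups_between(
    table: pd.DataFrame, session: str, metric: str | None = None
) -> StatReport:
    """Two-sided Mann-Whitney U between the two groups at one session.

    Exact p-values are used for samples of at most 25 without ties, the
    normal approximation with tie correction otherwise.
    """
    df = table[table["session"] == session]
    if metric is not None and "metric_name" in df.columns:
        df = df[df["metric_name"] == metric]
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, found {groups}")
    x = df.loc[df["group"] == groups[0], "value"].to_numpy()
    y = df.loc[df["group"] == groups[1], "value"].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 25 and not has_ties) else "asymptotic"
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    pairwise = pd.DataFrame(
        [
            {
                "a": groups[0],
                "b": groups[1],
                "test": f"mann-whitney-u ({method})",
                "statistic": float(stat),
                "p_raw": float(p),
                "p_holm": float(p),
            }
        ]
    )
    return StatReport(f"mann-whitney-u ({method})", float(stat), float(p), pairwise)
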