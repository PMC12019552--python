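"""Group-comparison statistics for figure-style reporting.

Per-group means with 95% confidence intervals, Student/Welch two-sample
t-tests, and one-way ANOVA followed by Tukey's HSD with a compact letter
display (groups sharing a letter are not significantly different at alpha).

ANOVA and Tukey come from scipy; the compact letter display is computed here
so that the sharing property is exact: two groups share a letter if and only
if their Tukey-adjusted p-value is >= alpha.  Letters are assigned from the
maximal cliques of the not-significantly-different graph, ordered by
descending group mean, which yields the same display the insert-and-absorb
procedure produces.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats


def group_summary(table: pd.DataFrame, value: str = "value",
                  group: str | list[str] = "group",
                  conf: float = 0.95) -> pd.DataFrame:
    """Per-group mean, n, SD and confidence half-width (t-based).

    CI half-width = t(1 - (1-conf)/2, n-1) * sd / sqrt(n); groups of n < 2
    get NaN half-widths.
    """
    keys = [group] if isinstance(group, str) else list(group)
    rows = []
    for name, grp in table.groupby(keys, sort=True):
        v = grp[value].to_numpy(dtype=float)
        n = len(v)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if n > 1 else float("nan")
        if n > 1:
            half = float(stats.t.ppf(1 - (1 - conf) / 2, n - 1) * sd / np.sqrt(n))
        else:
            half = float("nan")
        key = name if isinstance(name, tuple) else (name,)
        rows.append((*key, n, mean, sd, half))
    return pd.DataFrame(rows, columns=[*keys, "n", "mean", "sd", "ci95_half"])


def two_sample_test(a, b, kind: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t-test; ``kind`` is 'student' or 'welch'.

    Degenerate all-equal inputs (zero pooled variance, equal means) return
    (0.0, 1.0) instead of NaN.
    """
    if kind not in ("student", "welch"):
        raise ValueError(f"kind must be 'student' or 'welch', got {kind!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two_sample_test needs n >= 2 per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=(kind == "student"))
    return float(res.statistic), float(res.pvalue)


def tukey_pvalues(table: pd.DataFrame, value: str = "value",
                  group: str = "group") -> pd.DataFrame:
    """All-pairs Tukey HSD adjusted p-values as a tidy (g1, g2, p_adj) table."""
    names = sorted(table[group].unique().tolist())
    samples = [table.loc[table[group] == g_, value].to_numpy(dtype=float)
               for g_ in names]
    res = stats.tukey_hsd(*samples)
    return pd.DataFrame(
        [(names[i], names[j], float(res.pvalue[i, j]))
         for i, j in combinations(range(len(names)), 2)],
        columns=["group1", "group2", "p_adj"])


def compact_letter_display(groups: list, sig_pairs: set[frozenset],
                           means: dict | None = None) -> dict:
    """Letters such that two groups share one iff their pair is NOT in
    ``sig_pairs``.

    Builds the graph whose edges join not-significantly-different groups and
    letters its maximal cliques, ordered by the best (largest-mean) member so
    'a' labels the top group.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for x in groups:
        for y in groups:
            if x != y and frozenset((x, y)) not in sig_pairs:
                g.add_edge(x, y)
    cliques = list(nx.find_cliques(g))
    if means:
        cliques.sort(key=lambda c: -max(means[m] for m in c))
    else:
        cliques.sort(key=lambda c: sorted(groups.index(m) for m in c))
    letters = {grp: "" for grp in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, clique in enumerate(cliques):
        ch = alphabet[li % len(alphabet)] * (li // len(alphabet) + 1)
        for member in clique:
            letters[member] += ch
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def anova_tukey_letters(table: pd.DataFrame, alpha: float = 0.05,
                        value: str = "value", group: str = "group"
                        ) -> tuple[float, float, dict]:
    """One-way ANOVA + Tukey HSD + compact letter display.

    Returns ``(F, p_anova, letters)`` with one letter string per group.
    Identical (zero-variance, equal) data across all groups degenerates to a
    single shared letter.
    """
    names = sorted(table[group].unique().tolist())
    if len(names) < 2:
        raise ValueError("anova_tukey_letters needs >= 2 groups")
    samples = [table.loc[table[group] == g_, value].to_numpy(dtype=float)
               for g_ in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    allv = np.concatenate(samples)
    means = {g_: float(s.mean()) for g_, s in zip(names, samples)}
    if np.ptp(allv) == 0:
        return 0.0, 1.0, {g_: "a" for g_ in names}
    f_stat, p_anova = stats.f_oneway(*samples)
    pvals = tukey_pvalues(table, value=value, group=group)
    sig = {frozenset((r.group1, r.group2))
           for r in pvals.itertuples() if r.p_adj < alpha}
    letters = compact_letter_display(names, sig, means)
    return float(f_stat), float(p_anova), letters
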