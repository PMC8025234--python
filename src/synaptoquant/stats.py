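"""Group-comparison routing and percent-of-control normalization.

The routing mirrors the standard decision tree of the source field:
D'Agostino-Pearson omnibus normality per group at alpha = 0.05 (groups with
n < 8 are too small for the omnibus test and are assumed normal);
all-normal two-group comparisons use the unpaired two-tailed t test, any
non-normal group routes to Mann-Whitney U; with more than two groups the
parametric route is one-way ANOVA with Tukey's post hoc and the
nonparametric route Kruskal-Wallis with Dunn's post hoc. Significance
stars: * p < 0.05, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparison:
    groups: Dict[str, np.ndarray]
    normality: Dict[str, bool]
    normality_assumed: Dict[str, bool]  # True where n < cutoff
    test_used: str  # t | mann_whitney | anova_tukey | kruskal_dunn
    p_values: pd.DataFrame  # columns: group1, group2, p, stars

    def summary(self) -> str:
        lines = [f"test: {self.test_used}"]
        for name, vals in self.groups.items():
            tag = " (assumed)" if self.normality_assumed[name] else ""
            lines.append(
                f"  {name}: n={len(vals)}, normal={self.normality[name]}{tag}"
            )
        lines.append(self.p_values.to_string(index=False))
        return "\n".join(lines)


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def is_normal(
    values: np.ndarray, alpha: float = 0.05, small_n_cutoff: int = 8
) -> Tuple[bool, bool]:
    """(normal, assumed): D'Agostino-Pearson omnibus test, or assumed normal
    when n < small_n_cutoff (the omnibus test needs at least 8 samples)."""
    values = np.asarray(values, dtype=np.float64)
    if len(values) < small_n_cutoff:
        return True, True
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.normaltest(values)
    return bool(p > alpha), False


def dunn_posthoc(
    samples: Sequence[np.ndarray], names: Sequence[str]
) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis.

    Uses the pooled-rank statistic with tie correction; p values are
    Bonferroni-adjusted over all pairwise comparisons.
    """
    all_vals = np.concatenate(samples)
    n_tot = len(all_vals)
    ranks = sps.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1))
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + len(s)].mean())
        sizes.append(len(s))
        start += len(s)
    k = len(samples)
    n_comp = k * (k - 1) // 2
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        se = np.sqrt(
            (n_tot * (n_tot + 1) / 12.0 - tie) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = abs(mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * sps.norm.sf(z) * n_comp)
        rows.append({"group1": names[a], "group2": names[b], "p": p})
    return pd.DataFrame(rows)


def route_and_test(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    small_n_cutoff: int = 8,
) -> GroupComparison:
    """Run the routed comparison across named groups.

    Routing is a pure function of (per-group n, per-group normality flag,
    number of groups): all normal & 2 groups -> unpaired two-tailed t; any
    non-normal & 2 groups -> Mann-Whitney U; all normal & >2 groups ->
    one-way ANOVA + Tukey HSD; otherwise Kruskal-Wallis + Dunn.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for k, v in arrs.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    normal, assumed = {}, {}
    for k, v in arrs.items():
        normal[k], assumed[k] = is_normal(v, alpha, small_n_cutoff)
    all_normal = all(normal.values())
    names = list(arrs)
    vals = [arrs[k] for k in names]

    if len(arrs) == 2:
        a, b = vals
        if all_normal:
            test = "t"
            _, p = sps.ttest_ind(a, b, equal_var=True)
        else:
            test = "mann_whitney"
            _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        pvals = pd.DataFrame(
            [{"group1": names[0], "group2": names[1], "p": float(p)}]
        )
    else:
        if all_normal:
            test = "anova_tukey"
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            data = np.concatenate(vals)
            labels = np.concatenate([[n] * len(v) for n, v in zip(names, vals)])
            res = pairwise_tukeyhsd(data, labels, alpha=alpha)
            tbl = res.summary().data
            pvals = pd.DataFrame(
                [
                    {"group1": r[0], "group2": r[1], "p": float(r[3])}
                    for r in tbl[1:]
                ]
            )
        else:
            test = "kruskal_dunn"
            sps.kruskal(*vals)
            pvals = dunn_posthoc(vals, names)
    pvals["stars"] = [stars(p) for p in pvals["p"]]
    return GroupComparison(
        groups=arrs,
        normality=normal,
        normality_assumed=assumed,
        test_used=test,
        p_values=pvals,
    )


def percent_of_control(
    values: Sequence[float], control_values: Sequence[float]
) -> np.ndarray:
    """Normalize values to the control-group mean (wild-type = 100%)."""
    control_values = np.asarray(control_values, dtype=np.float64)
    m = control_values.mean()
    if m == 0:
        raise ValueError("control mean is zero")
    return 100.0 * np.asarray(values, dtype=np.float64) / m


def compare_table(
    table: pd.DataFrame,
    group_col: str,
    value_col: str,
    control: str | None = None,
    **kwargs,
) -> Tuple[GroupComparison, pd.DataFrame]:
    """Route-and-test a tidy metrics table; optionally add percent-of-control.

    Returns the comparison and a copy of the table with a
    ``{value_col}_pct_of_control`` column when ``control`` names a group.
    """
    groups = {
        str(name): sub[value_col].to_numpy()
        for name, sub in table.groupby(group_col, sort=False)
    }
    cmp = route_and_test(groups, **kwargs)
    out = table.copy()
    if control is not None:
        if str(control) not in groups:
            raise ValueError(f"control group {control!r} not in table")
        out[f"{value_col}_pct_of_control"] = percent_of_control(
            table[value_col].to_numpy(), groups[str(control)]
        )
    return cmp, out
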