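"""Multi-group comparison toolchain producing compact-letter displays.

The pipeline mirrors standard feed-composition practice for k substrates
measured in triplicate: Shapiro-Wilk normality on raw replicates, Levene's
test (mean-centered) for variance homogeneity, then either

* one-way ANOVA + Duncan's multiple range test (homogeneous variances), or
* Welch's ANOVA + Dunnett's T3 pairwise test (heterogeneous variances),

with Fisher's LSD available as a control-vs-others reference.  Pairwise
decisions are summarised as a compact letter display (CLD): groups sharing a
letter do not differ significantly at the chosen alpha.

Duncan's test has no closed form: the least significant range for a span of
p ordered means uses the studentized-range quantile at the protection level
alpha_p = 1 - (1 - alpha)**(p - 1); a difference is significant only when
its own range test and every containing range test exceed their critical
ranges.  Quantiles are cached, so simulation loops stay fast.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateDataError(ValueError):
    """Raised when data carry no variance information a test needs."""


GroupData = Mapping[str, Sequence[float]]


def _as_groups(groups: GroupData) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2, has {v.size}")
    return out


# ---------------------------------------------------------------------------
# Omnibus tests


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a single replicate list (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input: W undefined")
    W, p = stats.shapiro(x)
    return float(W), float(p)


def levene(groups: GroupData) -> tuple[float, float]:
    """Levene's homogeneity test on absolute deviations from group means."""
    g = _as_groups(groups)
    if all(np.ptp(v) == 0 for v in g.values()):
        raise DegenerateDataError("zero variance in every group")
    stat, p = stats.levene(*g.values(), center="mean")
    return float(stat), float(p)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float  # pooled error mean square, reused by post-hoc tests


def one_way_anova(groups: GroupData) -> AnovaResult:
    """Classical one-way between/within decomposition."""
    g = _as_groups(groups)
    arrays = list(g.values())
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, int(ns.sum()) - k
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=F, df_between=df_b, df_within=df_w, p=p, ms_within=ms_w)


def welch_anova(groups: GroupData) -> tuple[float, int, float, float]:
    """Welch's heteroscedastic one-way ANOVA: F*, df1, df2, p."""
    g = _as_groups(groups)
    means = np.array([v.mean() for v in g.values()])
    variances = np.array([v.var(ddof=1) for v in g.values()])
    ns = np.array([v.size for v in g.values()], dtype=float)
    if np.any(variances == 0):
        raise DegenerateDataError("zero within-group variance: Welch weights undefined")
    w = ns / variances
    W = w.sum()
    mw = (w * means).sum() / W
    k = len(g)
    A = (w * (means - mw) ** 2).sum() / (k - 1)
    h = ((1 - w / W) ** 2 / (ns - 1)).sum()
    B = 1 + 2 * (k - 2) / (k**2 - 1) * h
    F = A / B
    df2 = (k**2 - 1) / (3 * h)
    p = float(stats.f.sf(F, k - 1, df2))
    return float(F), k - 1, float(df2), p


# ---------------------------------------------------------------------------
# Pairwise machinery and letters


@dataclass(frozen=True)
class PairwiseComparison:
    group1: str
    group2: str
    difference: float  # mean(group2) - mean(group1)
    critical: float  # threshold |difference| must exceed
    significant: bool
    note: str = ""


@dataclass
class ComparisonResult:
    """Omnibus statistic, pairwise table and compact letter display."""

    method: str  # anova+duncan | anova+lsd | welch+dunnettT3
    statistic: float
    df: tuple[float, float]
    p: float
    means: dict[str, float]
    letters: dict[str, str]
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    alpha: float = 0.05
    flags: list[str] = field(default_factory=list)

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.pairwise])

    def share_letter(self, g1: str, g2: str) -> bool:
        return bool(set(self.letters[g1]) & set(self.letters[g2]))


def _maximal_cliques(nodes: list[str], adj: dict[str, set[str]]) -> list[set[str]]:
    """Bron-Kerbosch with pivoting; fine for the handful of groups used here."""
    cliques: list[set[str]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        pivot = max(p | x, key=lambda u: len(adj[u] & p))
        for v in list(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(nodes), set())
    return cliques


def letters_from_pairwise(
    means: Mapping[str, float],
    significant: Mapping[tuple[str, str], bool],
    orientation: str = "asc",
) -> dict[str, str]:
    """Compact letter display from a pairwise significance relation.

    Letters are the maximal cliques of the "not significantly different"
    graph, so two groups share a letter iff their pairwise comparison is
    non-significant.  With ``orientation='asc'`` the letter 'a' goes to the
    clique containing the smallest mean (the convention used for composition
    tables here); ``'desc'`` starts from the largest mean.
    """
    nodes = list(means)
    adj = {n: set() for n in nodes}
    for (g1, g2), sig in significant.items():
        if not sig:
            adj[g1].add(g2)
            adj[g2].add(g1)
    cliques = _maximal_cliques(nodes, adj)
    reverse = orientation == "desc"
    cliques.sort(key=lambda c: min(means[g] for g in c), reverse=reverse)
    # deduplicate letter-equivalent cliques defensively
    assigned: dict[str, list[str]] = {n: [] for n in nodes}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            assigned[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in assigned.items()}


@lru_cache(maxsize=4096)
def duncan_critical_q(p: int, df: int, alpha: float) -> float:
    """Duncan's protected studentized-range quantile for a span of p means."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))


def duncan_letters(
    groups: GroupData, alpha: float = 0.05, orientation: str = "asc"
) -> ComparisonResult:
    """Duncan's multiple range test with a compact letter display.

    Uses the pooled ANOVA error mean square; unbalanced designs fall back to
    the harmonic mean group size with a warning.
    """
    g = _as_groups(groups)
    anova = one_way_anova(g)
    names = sorted(g, key=lambda k: g[k].mean())
    means = {k: float(g[k].mean()) for k in names}
    ns = [g[k].size for k in names]
    flags: list[str] = []
    if len(set(ns)) > 1:
        warnings.warn("unbalanced groups: using harmonic mean n for Duncan ranges",
                      stacklevel=2)
        flags.append("harmonic_mean_n")
    n_h = len(ns) / sum(1.0 / n for n in ns)
    se = math.sqrt(anova.ms_within / n_h)
    k = len(names)

    # raw range tests over every span of the ordered means
    raw = {}
    for i, j in itertools.combinations(range(k), 2):
        span = j - i + 1
        diff = means[names[j]] - means[names[i]]
        if se == 0:
            crit = 0.0
            raw[(i, j)] = (diff > 0, crit)
        else:
            crit = duncan_critical_q(span, anova.df_within, alpha) * se
            raw[(i, j)] = (diff > crit, crit)
    # protection: a pair inside any non-significant containing range is ns
    significant: dict[tuple[str, str], bool] = {}
    pairwise: list[PairwiseComparison] = []
    for i, j in itertools.combinations(range(k), 2):
        sig, crit = raw[(i, j)]
        if sig:
            for a, b in raw:
                if a <= i and b >= j and not raw[(a, b)][0]:
                    sig = False
                    break
        pair = (names[i], names[j])
        significant[pair] = sig
        pairwise.append(
            PairwiseComparison(
                group1=names[i], group2=names[j],
                difference=means[names[j]] - means[names[i]],
                critical=crit, significant=sig,
            )
        )
    letters = letters_from_pairwise(means, significant, orientation)
    return ComparisonResult(
        method="anova+duncan",
        statistic=anova.F,
        df=(anova.df_between, anova.df_within),
        p=anova.p,
        means=means,
        letters=letters,
        pairwise=pairwise,
        alpha=alpha,
        flags=flags,
    )


def lsd_pairwise(
    groups: GroupData, control: str, alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Fisher's LSD of a control group against every other group.

    t-based comparisons with the pooled ANOVA error mean square.
    """
    g = _as_groups(groups)
    if control not in g:
        raise KeyError(f"unknown control group {control!r}")
    anova = one_way_anova(g)
    tcrit = stats.t.ppf(1 - alpha / 2, anova.df_within)
    out = []
    for other in g:
        if other == control:
            continue
        se = math.sqrt(anova.ms_within * (1 / g[control].size + 1 / g[other].size))
        lsd = tcrit * se
        diff = float(g[other].mean() - g[control].mean())
        out.append(
            PairwiseComparison(
                group1=control, group2=other, difference=diff,
                critical=float(lsd), significant=bool(abs(diff) > lsd),
            )
        )
    return out


def _smm_critical(n_comparisons: int, df: float, alpha: float) -> float:
    """Studentized-maximum-modulus critical point.

    Computed via the Sidak relation |t| quantile at 1-(1-alpha)^(1/r), exact
    under independence of the r comparisons and a close upper approximation
    otherwise.
    """
    a_star = 1.0 - (1.0 - alpha) ** (1.0 / n_comparisons)
    return float(stats.t.ppf(1.0 - a_star / 2.0, df))


def welch_dunnett_t3(
    groups: GroupData, alpha: float = 0.05, orientation: str = "asc"
) -> ComparisonResult:
    """Welch's ANOVA with Dunnett's T3 pairwise comparisons and letters.

    Each pair uses its own Welch-Satterthwaite degrees of freedom; the
    critical point comes from the studentized maximum modulus over all
    k(k-1)/2 comparisons.  A pair of zero-variance groups is decided by the
    limit rule (significant iff the means differ) and flagged.
    """
    g = _as_groups(groups)
    names = sorted(g, key=lambda k: g[k].mean())
    means = {k: float(g[k].mean()) for k in names}
    k = len(names)
    r = k * (k - 1) // 2
    flags: list[str] = []
    try:
        F, df1, df2, p = welch_anova(g)
    except DegenerateDataError:
        F, df1, df2, p = math.nan, k - 1, math.nan, math.nan
        flags.append("welch_f_undefined_zero_variance")

    significant: dict[tuple[str, str], bool] = {}
    pairwise: list[PairwiseComparison] = []
    for g1, g2 in itertools.combinations(names, 2):
        x, y = g[g1], g[g2]
        v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        diff = float(y.mean() - x.mean())
        if v1 + v2 == 0:
            sig = diff != 0.0
            crit = 0.0
            note = "zero-variance pair: limit rule"
            flags.append(f"zero_variance_pair:{g1}|{g2}")
        else:
            df_pair = (v1 + v2) ** 2 / (
                (v1**2 / (x.size - 1)) + (v2**2 / (y.size - 1))
            )
            crit = _smm_critical(r, df_pair, alpha) * math.sqrt(v1 + v2)
            sig = abs(diff) > crit
            note = ""
        significant[(g1, g2)] = sig
        pairwise.append(
            PairwiseComparison(group1=g1, group2=g2, difference=diff,
                               critical=float(crit), significant=bool(sig), note=note)
        )
    letters = letters_from_pairwise(means, significant, orientation)
    return ComparisonResult(
        method="welch+dunnettT3",
        statistic=F,
        df=(df1, df2),
        p=p,
        means=means,
        letters=letters,
        pairwise=pairwise,
        alpha=alpha,
        flags=flags,
    )


def compare_groups(
    groups: GroupData,
    alpha: float = 0.05,
    orientation: str = "asc",
    force: str | None = None,
) -> ComparisonResult:
    """Levene-gated comparison pipeline.

    Levene p < alpha routes to Welch + Dunnett T3, otherwise to
    ANOVA + Duncan.  ``force`` in {'duncan', 'dunnettT3'} overrides the gate.
    """
    if force == "duncan":
        return duncan_letters(groups, alpha, orientation)
    if force == "dunnettT3":
        return welch_dunnett_t3(groups, alpha, orientation)
    if force is not None:
        raise ValueError(f"unknown forced method {force!r}")
    try:
        _, lev_p = levene(groups)
    except DegenerateDataError:
        return duncan_letters(groups, alpha, orientation)
    if lev_p < alpha:
        try:
            return welch_dunnett_t3(groups, alpha, orientation)
        except DegenerateDataError:
            pass
    return duncan_letters(groups, alpha, orientation)
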