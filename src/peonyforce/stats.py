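"""Inferential layer: ANOVA, Duncan's multiple range test with compact
letter display, Pearson correlations, thresholded correlation networks
and ordinary least-squares dose-response fits.

Duncan's test uses exact critical values from the studentized-range
distribution at the span-adjusted protection level
alpha_p = 1 - (1 - alpha)**(p - 1) instead of digitized historical
tables; this agrees with the printed tables to their precision and is
reproducible to machine precision.  The "protected" variant (default)
assigns a single shared letter whenever the omnibus ANOVA is not
significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effect one-way decomposition; F = MSB/MSW.

    With zero variance both between and within groups the F ratio is
    undefined and returned as NaN.
    """
    if len(groups) < 2:
        raise DomainError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise DomainError(f"group {i} has n={a.size}; need n >= 2")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0.0:
        if msb == 0.0:
            return AnovaResult(np.nan, np.nan, df_b, df_w, msb, msw)
        return AnovaResult(np.inf, 0.0, df_b, df_w, msb, msw)
    F = msb / msw
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, float(msb), float(msw))


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuncanResult:
    trait_code: str | None
    means: "pd.Series"           # group -> mean, descending
    letters: dict[str, str]      # group -> letter string
    alpha: float
    anova: AnovaResult
    n_harmonic: float
    protected: bool


def duncan_critical_range(
    span: int, df_within: int, ms_within: float, n_harmonic: float, alpha: float
) -> float:
    """Least significant range for a span of *span* ordered means."""
    if df_within < 1:
        raise DomainError("df_within must be >= 1")
    if span < 2:
        raise DomainError("span must be >= 2")
    protection = (1.0 - alpha) ** (span - 1)
    q = float(sps.studentized_range.ppf(protection, span, df_within))
    return q * np.sqrt(ms_within / n_harmonic)


def _cld_from_intervals(
    group_order: Sequence[str], nonsig: set[tuple[int, int]]
) -> dict[str, str]:
    """Letters from maximal non-significant intervals of sorted means."""
    k = len(group_order)
    maximal = [
        (i, j)
        for (i, j) in sorted(nonsig)
        if not any(
            (a <= i and j <= b and (a, b) != (i, j)) for (a, b) in nonsig
        )
    ]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    intervals = maximal + [(i, i) for i in range(k) if i not in covered]
    intervals.sort()
    letters: dict[str, list[str]] = {g: [] for g in group_order}
    for idx, (i, j) in enumerate(intervals):
        letter = chr(ord("a") + idx)
        for pos in range(i, j + 1):
            letters[group_order[pos]].append(letter)
    return {g: "".join(ls) for g, ls in letters.items()}


def duncan_letters(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    protected: bool = True,
    trait_code: str | None = None,
) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Means are sorted descending; the widest spans are tested first and
    any span not exceeding its critical range is declared homogeneous
    together with everything it contains (the standard stepwise
    protection).  Unequal group sizes use the harmonic mean n.
    """
    names = list(groups)
    anova = one_way_anova([groups[g] for g in names])
    ns = np.array([len(groups[g]) for g in names], dtype=float)
    n_h = float(len(ns) / np.sum(1.0 / ns))
    means = pd.Series(
        {g: float(np.mean(np.asarray(groups[g], dtype=float))) for g in names}
    ).sort_values(ascending=False, kind="mergesort")
    order = list(means.index)
    k = len(order)

    if protected and not (np.isfinite(anova.p) and anova.p < alpha):
        letters = {g: "a" for g in order}
        return DuncanResult(
            trait_code, means, letters, alpha, anova, n_h, protected
        )

    nonsig: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):
        crit = duncan_critical_range(
            span, anova.df_within, anova.ms_within, n_h, alpha
        )
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for (a, b) in nonsig):
                nonsig.add((i, j))
                continue
            gap = means.iloc[i] - means.iloc[j]
            if gap <= crit:
                nonsig.add((i, j))
    letters = _cld_from_intervals(order, nonsig)
    return DuncanResult(trait_code, means, letters, alpha, anova, n_h, protected)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _stars(p: float, star_levels: tuple[float, float]) -> str:
    if p < star_levels[1]:
        return "**"
    if p < star_levels[0]:
        return "*"
    return ""


def correlation_matrix(
    table: pd.DataFrame,
    star_levels: tuple[float, float] = (0.05, 0.01),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson matrix over the columns of *table*.

    Returns (r, p, stars) frames with unit diagonal, empty-string
    diagonal stars, and NaN rows/columns for constant traits.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    stars = pd.DataFrame("", index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        pair = table[[a, b]].dropna()
        try:
            rr, pp = pearson_with_p(pair[a], pair[b])
        except DomainError:
            rr, pp = np.nan, np.nan
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
        s = "" if np.isnan(pp) else _stars(pp, star_levels)
        stars.loc[a, b] = stars.loc[b, a] = s
    for c in cols:
        if table[c].dropna().nunique() <= 1:
            r.loc[c, :] = r.loc[:, c] = np.nan
            r.loc[c, c] = np.nan
    return r, p, stars


# ---------------------------------------------------------------------------
# correlation network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationNetwork:
    graph: nx.Graph
    edges: pd.DataFrame            # node1, node2, r, p, sign
    weighted_degree: pd.Series     # node -> sum of |r| over kept edges
    r_threshold: float
    alpha: float


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.4,
    alpha: float = 0.05,
) -> CorrelationNetwork:
    """Keep edge (i, j) iff |r| >= r_threshold and p < alpha.

    Isolated nodes are retained with weighted degree 0.  The node
    weighted degree (sum of |r| over incident kept edges) is the size
    measure used for network hubs.
    """
    nodes = list(r.columns)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    rows = []
    for a, b in itertools.combinations(nodes, 2):
        rr, pp = float(r.loc[a, b]), float(p.loc[a, b])
        if np.isnan(rr) or np.isnan(pp):
            continue
        if abs(rr) >= r_threshold and pp < alpha:
            g.add_edge(a, b, r=rr, p=pp, weight=abs(rr))
            rows.append(
                {
                    "node1": a,
                    "node2": b,
                    "r": rr,
                    "p": pp,
                    "sign": "positive" if rr > 0 else "negative",
                }
            )
    edges = pd.DataFrame(rows, columns=["node1", "node2", "r", "p", "sign"])
    wdeg = pd.Series(
        {n: float(sum(d["weight"] for _, _, d in g.edges(n, data=True))) for n in nodes}
    )
    for n, w in wdeg.items():
        g.nodes[n]["weighted_degree"] = w
    return CorrelationNetwork(g, edges, wdeg, r_threshold, alpha)


# ---------------------------------------------------------------------------
# dose-response OLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OlsFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    slope_se: float
    log_x: bool = False


def ols_fit(
    x: Sequence[float], y: Sequence[float], log_x: bool = False
) -> OlsFit:
    """Simple least-squares line with slope test and R^2.

    ``log_x`` fits y against ln(x) for the saturating "fast then slow"
    dose-response shape; off by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    if log_x:
        if np.any(x <= 0):
            raise DomainError("log predictor requires positive x")
        x = np.log(x)
    if np.std(x) == 0:
        raise DomainError("zero variance in x")
    res = sps.linregress(x, y)
    if np.std(y) == 0:
        r2, p = 0.0, 1.0
    else:
        r2, p = float(res.rvalue**2), float(res.pvalue)
    return OlsFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_slope=p,
        n=int(x.size),
        slope_se=float(res.stderr),
        log_x=log_x,
    )
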