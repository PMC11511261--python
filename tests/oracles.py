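"""Independent brute-force reference implementations used only by tests.

These deliberately take the slow, explicit route (exhaustive
enumeration, fixpoint closure, triple loops) so they share no code path
with the package implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps


def brute_duncan_share(groups: dict, alpha: float = 0.05) -> dict:
    """All-pairs Duncan significance by exhaustive homogeneous-interval
    closure.

    Returns {(g1, g2): share_letter_bool} for every unordered pair,
    computed from the textbook stepwise rule: an interval of the
    descending-sorted means is homogeneous if its endpoint gap does not
    exceed the critical range for its span, or if it is contained in a
    larger homogeneous interval; two groups are not significantly
    different iff the interval they span is homogeneous.  The closure is
    found by fixpoint iteration over all intervals.
    """
    names = list(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    k = len(names)
    all_vals = np.concatenate([arrays[g] for g in names])
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_w = all_vals.size - k
    msw = ssw / df_w
    F = (ssb / (k - 1)) / msw
    p_anova = sps.f.sf(F, k - 1, df_w)

    order = sorted(names, key=lambda g: -arrays[g].mean())
    means = [arrays[g].mean() for g in order]
    n_h = k / sum(1.0 / arrays[g].size for g in names)

    if not p_anova < alpha:
        return {frozenset(pr): True for pr in itertools.combinations(names, 2)}

    def crit(span: int) -> float:
        q = sps.studentized_range.ppf((1 - alpha) ** (span - 1), span, df_w)
        return q * np.sqrt(msw / n_h)

    intervals = [
        (i, j) for i in range(k) for j in range(i + 1, k)
    ]
    homog = {
        (i, j) for (i, j) in intervals if means[i] - means[j] <= crit(j - i + 1)
    }
    changed = True
    while changed:
        changed = False
        for (i, j) in intervals:
            if (i, j) in homog:
                continue
            for (a, b) in list(homog):
                if a <= i and j <= b:
                    homog.add((i, j))
                    changed = True
                    break
    share = {}
    for i, j in intervals:
        share[frozenset((order[i], order[j]))] = (i, j) in homog
    return share


def letters_share(letters: dict) -> dict:
    """Pair-sharing relation implied by a compact letter display."""
    names = list(letters)
    return {
        frozenset((a, b)): bool(set(letters[a]) & set(letters[b]))
        for a, b in itertools.combinations(names, 2)
    }


def brute_network_edges(r, p, r_threshold: float, alpha: float) -> set:
    """Edge set by direct filtering of every matrix cell."""
    nodes = list(r.columns)
    edges = set()
    for a in nodes:
        for b in nodes:
            if a >= b:
                continue
            rr, pp = float(r.loc[a, b]), float(p.loc[a, b])
            if np.isnan(rr) or np.isnan(pp):
                continue
            if abs(rr) >= r_threshold and pp < alpha:
                edges.add((a, b))
    return edges


def brute_level_means(design, response) -> dict:
    """K by explicit triple loops over factors, levels and groups."""
    out = {}
    for f in ("A", "B", "C"):
        levels = sorted({g.level(f) for g in design.non_control})
        for rank, lev in enumerate(levels, start=1):
            total, count = 0.0, 0
            for g in design.non_control:
                if g.level(f) == lev:
                    total += float(response[g.group_id])
                    count += 1
            out[(f, rank)] = total / count
    return out
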