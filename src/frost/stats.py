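"""Trend and contrast statistics for the community analysis.

Covers the three statistical families used downstream of the trait and
community modules: ordinary least-squares trends of per-plot quantities
against altitude, Kruskal–Wallis contrasts across growth forms with a
Nemenyi post hoc (rank-sum / studentized-range form, tie-corrected) and a
compact letter display, and Pearson/Spearman trait correlations with an
automatic normality-based switch.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupContrast:
    kw_statistic: float
    kw_p: float
    pairwise: dict[tuple[str, str], float]  # symmetric post hoc p-values
    letters: dict[str, str]                 # compact letter display


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str  # "pearson" | "spearman"


def linear_trend(y, altitude) -> RegressionResult:
    """OLS fit of a per-plot quantity on altitude; two-sided slope p.

    NA pairs are dropped; at least three complete pairs are required, and
    the altitudes must vary.  A constant response is reported as a flat
    line (slope 0, R² 0, p 1) rather than an undefined fit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(altitude, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise InputError(f"linear_trend needs >= 3 complete pairs, got {y.size}")
    if np.ptp(x) == 0:
        raise InputError("altitude has zero variance")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(y.size))
    fit = sps.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2, float(fit.pvalue),
                            int(y.size))


def _nemenyi_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Tie-corrected Nemenyi p-values from pooled-rank mean differences.

    q = |r̄_i − r̄_j| / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j)) with the tie
    term T = Σ(t³ − t) / (12(N − 1)); p from the studentized range
    distribution with k groups and infinite df (q·√2 on its scale).
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [samples[g].size for g in names])
    mean_rank = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                 for i, g in enumerate(names)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    a = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(names)
    out: dict[tuple[str, str], float] = {}
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(a * (1.0 / samples[g1].size + 1.0 / samples[g2].size))
        q = abs(mean_rank[g1] - mean_rank[g2]) / se * np.sqrt(2.0)
        p = float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
        out[(g1, g2)] = p
        out[(g2, g1)] = p
    return out


def compact_letter_display(order: list[str],
                           pairwise: dict[tuple[str, str], float],
                           alpha: float) -> dict[str, str]:
    """Insert-and-absorb letter assignment from a pairwise p matrix.

    Groups sharing any letter are not significantly different at
    ``alpha``; significantly different pairs never share a letter.
    """
    letter_sets: list[set[str]] = [set(order)]
    for g1, g2 in itertools.combinations(order, 2):
        if pairwise.get((g1, g2), 1.0) >= alpha:
            continue
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            for split in (s - {g1}, s - {g2}):
                if split and not any(split <= other for other in letter_sets):
                    letter_sets.append(split)
    # stable ordering: letter sets sorted by their first member's rank
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, s in enumerate(letter_sets):
        for g in order:
            if g in s:
                letters[g] += alphabet[i]
    return letters


def kruskal_nemenyi(values, groups, alpha: float = DEFAULT_ALPHA) -> GroupContrast:
    """Kruskal–Wallis across groups with Nemenyi pairwise post hoc.

    Groups with fewer than two members are excluded with a warning (small
    groups such as a three-species shrub class are kept).  Letters are
    assigned from the post hoc p matrix at ``alpha``.
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float),
                          "group": list(groups)}).dropna()
    samples: dict[str, np.ndarray] = {}
    for g, grp in frame.groupby("group", sort=True):
        v = grp["value"].to_numpy()
        if v.size < 2:
            warnings.warn(f"group {g!r} has n={v.size} < 2; excluded from "
                          f"the contrast", stacklevel=2)
            continue
        samples[str(g)] = v
    if len(samples) < 2:
        raise InputError("need >= 2 groups with >= 2 members each")
    kw = sps.kruskal(*samples.values())
    pairwise = _nemenyi_pairwise(samples)
    order = sorted(samples, key=lambda g: samples[g].mean())
    letters = compact_letter_display(order, pairwise, alpha)
    return GroupContrast(float(kw.statistic), float(kw.pvalue),
                         pairwise, letters)


def trait_correlation(x, y, method: str = "auto") -> CorrelationResult:
    """Pearson or Spearman correlation between two species-level traits.

    ``auto`` picks Pearson when both variables pass Shapiro–Wilk normality
    at 0.05, Spearman otherwise; NA pairs are dropped, at least four
    complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise InputError(f"trait_correlation needs >= 4 complete pairs, "
                         f"got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance in one of the variables")
    if method == "auto":
        normal = (sps.shapiro(x).pvalue >= 0.05
                  and sps.shapiro(y).pvalue >= 0.05)
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(r.statistic), float(r.pvalue), method)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (optional; trends are reported raw by
    default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
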