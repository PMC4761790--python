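"""Freezing-resistance mechanism classification.

Comparing a species' ice nucleation temperature (NT) with its damage
temperature (LT50) separates three strategies on the cooling axis:

* **FT** (freezing tolerant): LT50 significantly lower than NT — tissue
  survives extracellular ice formation and is damaged only well below it.
* **FA** (freezing avoidant): LT50 not significantly different from NT —
  damage coincides with ice formation; survival relies on supercooling.
* **FS** (freezing sensitive): LT50 significantly higher (warmer) than NT —
  damage occurs before any ice forms.

The parametric/nonparametric switch follows the usual practice: a t-test
when both samples look normal (Shapiro–Wilk) with homogeneous variances
(Levene), a Mann–Whitney U otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class MechanismClass:
    value: str                  # one of {"FT", "FA", "FS"}
    p_value: float              # NaN when classification is by censoring
    test_used: str              # t_test | mann_whitney | wilcoxon | censored | degenerate


def choose_test(sample_a, sample_b, alpha: float = DEFAULT_ALPHA) -> str:
    """Pick 't_test' or 'mann_whitney' for a two-sample comparison.

    The t-test requires both samples to pass Shapiro–Wilk normality at
    ``alpha`` and a Levene homogeneity-of-variance check; any failure —
    including degenerate zero-variance samples, for which normality is
    undefined — falls back to Mann–Whitney.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InputError(f"choose_test needs n >= 3 per sample, got "
                         f"{a.size} and {b.size}")
    for sample in (a, b):
        if np.ptp(sample) == 0:
            return "mann_whitney"
        if stats.shapiro(sample).pvalue < alpha:
            return "mann_whitney"
    if stats.levene(a, b, center="median").pvalue < alpha:
        return "mann_whitney"
    return "t_test"


def _one_sample_p(nt: np.ndarray, value: float, alpha: float) -> tuple[float, str]:
    d = nt - value
    if np.all(d == 0):
        return 1.0, "degenerate"
    if np.ptp(nt) == 0:
        # constant replicates strictly away from the reference value:
        # the difference is exact, not sampled
        logger.info("one-sample comparison with zero-variance NT replicates")
        return 0.0, "degenerate"
    if stats.shapiro(nt).pvalue >= alpha:
        return float(stats.ttest_1samp(nt, value).pvalue), "t_test"
    return float(stats.wilcoxon(d).pvalue), "wilcoxon"


def classify_mechanism(nt_samples, lt50_samples,
                       alpha: float = DEFAULT_ALPHA) -> MechanismClass:
    """Classify FT / FA / FS from NT replicates and LT50 value(s).

    With a single LT50 value (the default species-level estimate) the NT
    replicates are compared against it one-sample; with LT50 replicates a
    two-sample comparison via :func:`choose_test` is used.  An all-NaN
    LT50 sample means damage was censored below the coldest tested
    temperature — provably below every NT — and classifies FT outright.
    """
    nt = np.asarray(nt_samples, dtype=float)
    lt = np.atleast_1d(np.asarray(lt50_samples, dtype=float))
    if nt.size < 3:
        raise InputError(f"need >= 3 NT replicates, got {nt.size}")
    lt = lt[~np.isnan(lt)]
    if lt.size == 0:
        logger.info("LT50 censored below tested range; classified FT")
        return MechanismClass("FT", float("nan"), "censored")

    if lt.size == 1:
        p, test = _one_sample_p(nt, float(lt[0]), alpha)
    else:
        if lt.size < 3:
            # too few replicates for the assumption checks; rank-based test
            test = "mann_whitney"
        else:
            test = choose_test(nt, lt, alpha)
        if test == "t_test":
            p = float(stats.ttest_ind(nt, lt, equal_var=True).pvalue)
        else:
            p = float(stats.mannwhitneyu(nt, lt, alternative="two-sided").pvalue)

    if p >= alpha:
        return MechanismClass("FA", p, test)
    value = "FT" if lt.mean() < nt.mean() else "FS"
    return MechanismClass(value, p, test)


def mechanism_proportions(community, profiles: dict[str, str]) -> pd.DataFrame:
    """Per-plot FT/FA/FS fractions among present, classified species.

    ``community`` is a :class:`frost.community.CommunityMatrix`;
    ``profiles`` maps species_id → mechanism class.  Species present with
    positive cover but lacking a classification are dropped with a
    warning; a plot with zero classified species yields an NA row.
    Fractions sum to 1 per plot by construction.
    """
    cover = community.cover
    unclassified = sorted(set(cover.columns) - set(profiles))
    present_unclassified = [s for s in unclassified if (cover[s] > 0).any()]
    if present_unclassified:
        warnings.warn(f"{len(present_unclassified)} species present without a "
                      f"mechanism class, dropped: {present_unclassified}",
                      stacklevel=2)
    rows = []
    for plot_id in cover.index:
        present = [s for s in cover.columns
                   if cover.at[plot_id, s] > 0 and s in profiles]
        counts = {"FT": 0, "FA": 0, "FS": 0}
        for s in present:
            counts[profiles[s]] += 1
        n = len(present)
        rows.append({
            "plot_id": plot_id,
            "altitude_m": community.altitude_m[plot_id],
            "ft": counts["FT"] / n if n else np.nan,
            "fa": counts["FA"] / n if n else np.nan,
            "fs": counts["FS"] / n if n else np.nan,
            "n_classified": n,
        })
    return pd.DataFrame(rows)
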