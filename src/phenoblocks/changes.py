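"""Change-score construction and univariate screening of a two-phase cohort.

The pipeline's primitive is the per-subject change score
``delta = chronic - baseline``.  Each trait is screened for a significant
phase shift with a paired Wilcoxon test under Bonferroni correction.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["compute_changes", "paired_test", "screen_traits"]


def _complete_cases(df: pd.DataFrame, phase: str) -> pd.DataFrame:
    mask = df.notna().all(axis=1)
    dropped = df.index[~mask].tolist()
    if dropped:
        logger.info("dropping %d subject(s) with missing %s values: %s",
                    len(dropped), phase, dropped)
    return df.loc[mask]


def compute_changes(baseline: pd.DataFrame, chronic: pd.DataFrame) -> pd.DataFrame:
    """Per-subject trait differences ``chronic - baseline``.

    Both inputs are subjects x traits DataFrames indexed by subject id with
    identical trait sets.  Subjects present in only one phase, or with any
    missing trait in either phase, are dropped (complete-case) and logged.
    Row order follows the baseline table.
    """
    if set(baseline.columns) != set(chronic.columns):
        only_b = sorted(set(baseline.columns) - set(chronic.columns))
        only_c = sorted(set(chronic.columns) - set(baseline.columns))
        raise ValueError(
            f"trait sets differ between phases (baseline-only: {only_b}, "
            f"chronic-only: {only_c})"
        )
    if baseline.index.has_duplicates or chronic.index.has_duplicates:
        raise ValueError("duplicate subject ids in a phase table")
    baseline = _complete_cases(baseline, "baseline")
    chronic = _complete_cases(chronic, "chronic")
    shared = baseline.index.intersection(chronic.index)  # keeps baseline order
    lost = baseline.index.difference(chronic.index).tolist() + \
        chronic.index.difference(baseline.index).tolist()
    if lost:
        logger.info("dropping %d subject(s) present in one phase only: %s",
                    len(lost), lost)
    if len(shared) == 0:
        raise ValueError("no subjects shared between the two phases")
    return chronic.loc[shared, baseline.columns] - baseline.loc[shared]


def paired_test(
    x_baseline: np.ndarray,
    x_chronic: np.ndarray,
    *,
    variant: str = "signed-rank",
) -> tuple[float, float]:
    """Two-sided paired test of a phase shift for one trait.

    ``variant='signed-rank'`` (default) is the paired Wilcoxon signed-rank
    test on the differences: zero differences are dropped, ties get average
    ranks, and the null distribution is enumerated exactly for n <= 25
    pairs, otherwise the normal approximation with continuity correction is
    used.  ``variant='rank-sum'`` instead compares the two phases with the
    (unpaired) Wilcoxon rank-sum test.

    Returns ``(statistic, p_two_sided)``.
    """
    x_baseline = np.asarray(x_baseline, dtype=float)
    x_chronic = np.asarray(x_chronic, dtype=float)
    if x_baseline.shape != x_chronic.shape:
        raise ValueError("phase vectors must have equal length")
    if len(x_baseline) < 5:
        raise ValueError("need at least 5 pairs")
    if variant == "rank-sum":
        res = stats.ranksums(x_chronic, x_baseline)
        return float(res.statistic), float(res.pvalue)
    if variant != "signed-rank":
        raise ValueError(f"unknown variant {variant!r}")
    d = x_chronic - x_baseline
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; p = 1", UserWarning, stacklevel=2)
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    if len(nonzero) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on small-n approx
        res = stats.wilcoxon(
            d, zero_method="wilcox", correction=True, method=method,
            alternative="two-sided",
        )
    return float(res.statistic), float(res.pvalue)


def screen_traits(
    baseline: pd.DataFrame,
    chronic: pd.DataFrame,
    *,
    variant: str = "signed-rank",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait paired screening with Bonferroni correction.

    Returns a DataFrame with columns ``trait, statistic, p_raw,
    p_bonferroni, significant`` where ``p_bonferroni = min(1, m * p_raw)``
    for m tested traits and significance is ``p_bonferroni < alpha``.
    """
    change = compute_changes(baseline, chronic)
    subjects = change.index
    m = change.shape[1]
    rows = []
    for trait in change.columns:
        stat, p = paired_test(
            baseline.loc[subjects, trait].values,
            chronic.loc[subjects, trait].values,
            variant=variant,
        )
        rows.append(
            {
                "trait": trait,
                "statistic": stat,
                "p_raw": p,
                "p_bonferroni": min(1.0, m * p),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
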