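"""Enrichment statistics for read-end proportions against genomic fractions.

The central comparison: a class of features (enhancers, super enhancers)
occupies a fraction q of the genome; a fraction p of read ends falls inside
the class.  Enrichment is summarized two ways:

* odds ratio vs the genome average, (p/(1-p)) / (q/(1-q)), and
* fold of proportions, p/q.

Significance is a one-degree-of-freedom goodness-of-fit chi-square of the
observed (in, out) read split against expectation (n*q, n*(1-q)), without
continuity correction.  A 2x2 contingency chi-square (also df=1, no
correction) covers condition-vs-condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Smallest p-value distinguishable from zero in R's chi-square tail;
#: values at or below this floor are conventionally printed "< 2.2e-16".
P_VALUE_FLOOR = 2.2e-16


@dataclass
class EnrichmentResult:
    p: float
    q: float
    odds_ratio: float
    fold: float
    chisq_stat: float | None = None
    df: int | None = None
    p_value: float | None = None
    low_expected: bool = False


@dataclass
class ContingencyResult:
    stat: float
    df: int
    p_value: float
    odds_ratio: float
    haldane_corrected: bool = False


def format_p_value(p: float) -> str:
    """Render a p-value, flooring values below tail resolution."""
    return f"< {P_VALUE_FLOOR:.1e}" if p < P_VALUE_FLOOR else f"{p:.3g}"


def _check_proportion(value: float, label: str) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{label} = {value} is degenerate; require 0 < {label} < 1")


def proportion_odds_ratio(
    k_in: int | None = None,
    n_total: int | None = None,
    len_in: int | None = None,
    len_total: int | None = None,
    p: float | None = None,
    q: float | None = None,
) -> EnrichmentResult:
    """Odds ratio and fold of a read-end proportion over a genomic fraction.

    Pass counts (k_in, n_total) and lengths (len_in, len_total), or the
    proportions (p, q) directly when only those are available.  The chi-square
    goodness-of-fit is attached only when counts are given.
    """
    if p is None:
        if k_in is None or n_total is None:
            raise ValueError("provide either counts (k_in, n_total) or p")
        p = k_in / n_total
    if q is None:
        if len_in is None or len_total is None:
            raise ValueError("provide either lengths (len_in, len_total) or q")
        q = len_in / len_total
    _check_proportion(p, "p")
    _check_proportion(q, "q")
    result = EnrichmentResult(
        p=p,
        q=q,
        odds_ratio=(p / (1 - p)) / (q / (1 - q)),
        fold=p / q,
    )
    if k_in is not None and n_total is not None:
        stat, df, pv, low = _gof_chisq(k_in, n_total, q)
        result.chisq_stat, result.df, result.p_value, result.low_expected = (
            stat, df, pv, low,
        )
    return result


def _gof_chisq(k_in: int, n_total: int, q: float) -> tuple[float, int, float, bool]:
    expected = np.array([n_total * q, n_total * (1 - q)])
    observed = np.array([k_in, n_total - k_in])
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, 1, float(sps.chi2.sf(stat, df=1)), bool((expected < 1).any())


def enrichment_chisq(
    k_in: int, n_total: int, len_in: int, len_total: int
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of the in/out read split vs genomic fraction q.

    The genomic fraction is treated as a fixed expectation (one free cell,
    df=1), not as a sampled margin; this is deliberately not the 2x2
    contingency statistic.
    """
    q = len_in / len_total
    _check_proportion(q, "q")
    if not 0 < k_in < n_total:
        raise ValueError("k_in must satisfy 0 < k_in < n_total")
    stat, df, pv, _low = _gof_chisq(k_in, n_total, q)
    return stat, df, pv


def contingency_chisq(table) -> ContingencyResult:
    """Pearson chi-square (df=1, no continuity correction) and OR of a 2x2 table.

    OR = (a*d)/(b*c).  If any cell is zero the OR is computed on the
    Haldane-corrected table (0.5 added to every cell) and flagged; a zero
    margin is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    stat, p_value, df, _ = sps.chi2_contingency(t, correction=False)
    corrected = bool((t == 0).any())
    ot = t + 0.5 if corrected else t
    odds_ratio = (ot[0, 0] * ot[1, 1]) / (ot[0, 1] * ot[1, 0])
    return ContingencyResult(float(stat), int(df), float(p_value), float(odds_ratio), corrected)


def fold_of_proportions(p: float, q: float) -> float:
    """Ratio of proportions p/q (the 'fold over genome average')."""
    if q <= 0:
        raise ValueError("q must be > 0")
    return p / q
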