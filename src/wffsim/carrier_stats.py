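"""Analytic statistics on carrier counts.

Carrier frequencies with exact (Clopper-Pearson) binomial confidence
intervals, the probability of seeing no carriers in a small sample,
Fisher's exact test for comparing two carrier counts, and carrier
frequencies by 5-year birth cohort.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "ContingencyTable2x2",
    "carrier_frequency",
    "binomial_exact_ci",
    "wilson_ci",
    "prob_no_carriers",
    "fisher_exact_two_sided",
    "cohort_frequencies",
    "default_cohort_bins",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GenotypeCounts:
    """Carriers out of a genotyped total."""

    n_carriers: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_carriers <= self.n_total:
            raise ValueError("need 0 <= n_carriers <= n_total")


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out as [[a, b], [c, d]]: rows carrier/noncarrier, columns group 1/group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all counts must be non-negative")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def degenerate(self) -> bool:
        """A zero margin: the test carries no information."""
        t = self.as_array
        return bool(np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0))


def carrier_frequency(counts: GenotypeCounts) -> float:
    """Observed proportion of carriers."""
    return counts.n_carriers / counts.n_total


def binomial_exact_ci(counts: GenotypeCounts, confidence: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval.

    low = Beta^{-1}(alpha/2; k, n-k+1), high = Beta^{-1}(1-alpha/2; k+1, n-k)
    with the conventions low = 0 for k = 0 and high = 1 for k = n.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    k, n = counts.n_carriers, counts.n_total
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def wilson_ci(counts: GenotypeCounts, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval, offered as the non-exact alternative."""
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    res = stats.binomtest(counts.n_carriers, counts.n_total).proportion_ci(
        confidence_level=confidence, method="wilson"
    )
    return float(res.low), float(res.high)


def prob_no_carriers(p: float, n: int) -> float:
    """Probability of drawing only noncarriers in a sample of size n: (1-p)^n."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return float((1.0 - p) ** n)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact test p-value.

    Uses the standard "sum of small p" definition: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table.
    Degenerate margins return p = 1 by convention (logged).
    """
    if table.degenerate:
        logger.info("degenerate 2x2 margins %s; returning p = 1", table.as_array.tolist())
        return 1.0
    return float(stats.fisher_exact(table.as_array, alternative="two-sided")[1])


def default_cohort_bins(start: int = 1971, end: int = 2020) -> list[tuple[int, int]]:
    """Nine birth cohorts: a ten-year first cohort, then 5-year intervals.

    The first cohort spans 1971-1980; 5-year cohorts follow up to ``end``.
    This reconciles nine cohorts over 1971-2020 with a 5-year birth
    interval.
    """
    bins = [(start, start + 9)]
    y = start + 10
    while y <= end:
        bins.append((y, min(y + 4, end)))
        y += 5
    return bins


def cohort_frequencies(
    records: Union[pd.DataFrame, Iterable],
    bins: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Carrier counts and frequencies per birth-year cohort.

    ``records`` is a DataFrame (or iterable of records) with columns/fields
    ``animal_id``, ``birth_year`` and ``status`` ("carrier"/"noncarrier").
    Records outside the configured year range are rejected with a warning.
    Empty cohorts get a missing (NaN) frequency, not zero.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [(r.animal_id, r.birth_year, r.status) for r in records],
            columns=["animal_id", "birth_year", "status"],
        )
    bins = bins or default_cohort_bins()
    lo, hi = bins[0][0], bins[-1][1]

    bad_status = ~records["status"].isin(["carrier", "noncarrier"])
    if bad_status.any():
        raise ValueError(f"unknown status values: {records.loc[bad_status, 'status'].unique()}")
    out_of_range = (records["birth_year"] < lo) | (records["birth_year"] > hi)
    if out_of_range.any():
        warnings.warn(
            f"rejected {int(out_of_range.sum())} record(s) with birth_year outside "
            f"[{lo}, {hi}]",
            stacklevel=2,
        )
        records = records.loc[~out_of_range]

    rows = []
    for start, end in bins:
        in_bin = records[(records["birth_year"] >= start) & (records["birth_year"] <= end)]
        n = len(in_bin)
        k = int((in_bin["status"] == "carrier").sum())
        rows.append(
            {
                "cohort": f"{start}-{end}",
                "start": start,
                "end": end,
                "n_carriers": k,
                "n_total": n,
                "frequency": (k / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
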