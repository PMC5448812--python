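"""Contingency statistics, proportion intervals, and frequency estimators.

These are the shared statistical primitives of the package: the exact
(Fisher) and likelihood-ratio (G) contingency tests used to compare strains
and particle-configuration distributions, Wald/Wilson confidence intervals
for proportions (e.g. meiosis-I nondisjunction frequencies), and reversion
frequencies from fluctuation-style plating assays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "TestResult",
    "ProportionEstimate",
    "ReversionFrequency",
    "fisher_exact_two_tailed",
    "g_test",
    "proportion_wald_ci",
    "reversion_frequency",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of observed counts with optional axis labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("grand total must be positive")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        for labels, size, name in (
            (self.row_labels, counts.shape[0], "row_labels"),
            (self.col_labels, counts.shape[1], "col_labels"),
        ):
            if labels is not None and len(labels) != size:
                raise ValueError(f"{name} length does not match table shape")

    @classmethod
    def from_tsv(cls, path) -> "ContingencyTable":
        """Read a labelled count table from TSV (first column = row labels)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            df.to_numpy(),
            row_labels=tuple(map(str, df.index)),
            col_labels=tuple(map(str, df.columns)),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class TestResult:
    """Outcome of a contingency test.

    ``statistic`` is the G statistic for likelihood-ratio tests and None for
    the exact test, where no test statistic is defined.
    """

    p_value: float
    method: str
    statistic: float | None = None
    df: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1 when present")

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "statistic": self.statistic,
                "df": self.df,
                "p_value": self.p_value,
            }
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion k/n with a symmetric-style confidence interval.

    ``ci_half_width`` is half the CI span; for the (default) Wald interval
    the interval is exactly p_hat +/- ci_half_width, matching the
    "mean +/- 95% CI" presentation of segregation-defect frequencies.
    """

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "wald"

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")

    @property
    def ci_half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)

    @property
    def percent(self) -> float:
        return 100.0 * self.p_hat

    @property
    def percent_half_width(self) -> float:
        return 100.0 * self.ci_half_width


@dataclass(frozen=True)
class ReversionFrequency:
    """Revertants per colony-forming unit, aggregated over cultures."""

    replicate_frequencies: tuple[float, ...]
    aggregate: float
    sd: float
    rule: str = "mean"
    normalized: float | None = None
    revertants: tuple[int, ...] = field(default=(), repr=False)
    cfu: tuple[float, ...] = field(default=(), repr=False)


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def fisher_exact_two_tailed(table) -> TestResult:
    """Two-tailed Fisher exact test on a 2x2 table.

    The two-tailed p-value follows the probability-mass convention: the sum
    of hypergeometric probabilities of every table with the same margins
    whose probability does not exceed that of the observed table.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    counts = t.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("test undefined: a margin of the table is zero")
    _, p = scipy.stats.fisher_exact(counts, alternative="two-sided")
    return TestResult(p_value=min(float(p), 1.0), method="fisher_exact_two_tailed")


def g_test(table) -> TestResult:
    """Likelihood-ratio (G) test of independence on an r x c table.

    G = 2 sum O_ij ln(O_ij / E_ij) over cells with O_ij > 0, with expected
    counts from the margins; df = (r-1)(c-1); p from the chi-square upper
    tail. No Williams or continuity correction is applied.
    """
    t = _as_table(table)
    counts = t.counts.astype(float)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("test undefined: a row or column sums to zero")
    expected = np.outer(row, col) / counts.sum()
    mask = counts > 0
    g = 2.0 * float(np.sum(counts[mask] * np.log(counts[mask] / expected[mask])))
    g = max(g, 0.0)  # guard tiny negative round-off on proportional tables
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(scipy.stats.chi2.sf(g, df))
    return TestResult(p_value=p, method="g_test", statistic=g, df=df)


def proportion_wald_ci(k: int, n: int, level: float = 0.95, method: str = "wald") -> ProportionEstimate:
    """Proportion estimate with a Wald (default) or Wilson confidence interval.

    The Wald interval is p_hat +/- z * sqrt(p_hat (1 - p_hat) / n); the Wilson
    score interval is available for small counts where the Wald interval is
    known to undercover.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p_hat = k / n
    if method == "wald":
        z = scipy.stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
        low, high = p_hat - half, p_hat + half
    elif method == "wilson":
        low, high = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return ProportionEstimate(
        k=int(k), n=int(n), p_hat=p_hat,
        ci_low=float(low), ci_high=float(high), level=level, method=method,
    )


def reversion_frequency(
    replicates: Sequence[tuple[int, float]],
    aggregate_rule: str = "mean",
    reference: float | None = None,
) -> ReversionFrequency:
    """Revertants per CFU for each culture, aggregated across cultures.

    Each replicate is a (revertant count, colony-forming units) pair from an
    independent culture. The default aggregate is the mean across cultures
    (matching a mean +/- SD presentation); ``aggregate_rule="median"`` gives a
    jackpot-robust alternative. If ``reference`` is given (e.g. the aggregate
    frequency of a fully repair-deficient strain), the normalized frequency
    aggregate/reference is also reported.
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate is required")
    revs, cfus = zip(*replicates)
    if any(c <= 0 for c in cfus):
        raise ValueError("cfu must be positive for every replicate")
    if any(r < 0 for r in revs):
        raise ValueError("revertant counts must be non-negative")
    freqs = np.array([r / c for r, c in zip(revs, cfus)], dtype=float)
    if aggregate_rule == "mean":
        agg = float(np.mean(freqs))
    elif aggregate_rule == "median":
        agg = float(np.median(freqs))
    else:
        raise ValueError(f"unknown aggregate rule: {aggregate_rule!r}")
    sd = float(np.std(freqs, ddof=1)) if len(freqs) > 1 else 0.0
    normalized = None
    if reference is not None:
        if reference <= 0:
            raise ValueError("reference frequency must be positive")
        normalized = agg / reference
    return ReversionFrequency(
        replicate_frequencies=tuple(freqs.tolist()),
        aggregate=agg,
        sd=sd,
        rule=aggregate_rule,
        normalized=normalized,
        revertants=tuple(int(r) for r in revs),
        cfu=tuple(float(c) for c in cfus),
    )
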