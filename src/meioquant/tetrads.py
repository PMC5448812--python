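"""Tetrad classification, Perkins map distances, and nondisjunction rates.

The spore-autonomous fluorescence assay places an RFP reporter at CEN8 and a
GFP reporter at ARG4 on one homolog of chromosome VIII, and a BFP reporter at
THR1 on the other homolog. Each spore of a tetrad inherits one chromatid, so
the pattern of red/green/blue fluorescence across the four spores reveals the
tetrad type (PD/NPD/TT) in the two test intervals (CEN8-ARG4 and ARG4-THR1)
and meiosis-I nondisjunction of chromosome VIII, without dissection.

Chromatid-to-pattern dictionary (R = red at CEN8, G = green at ARG4,
B = blue at THR1):

* parental:                 ``RG-`` and ``--B``
* interval-1 recombinant:   ``R-B`` and ``-G-``
* interval-2 recombinant:   ``RGB`` and ``---``
* double recombinant:       ``R--`` and ``-GB``

A tetrad with two triple-positive and two dark spores is the MI
nondisjunction pattern: the two disomic spores carry both homologs (hence all
three fluorophores) and the two nullisomic spores carry none. The identical
pattern can also arise from a four-chromatid double crossover in the
ARG4-THR1 interval; following the rarity argument for double crossovers in
the smaller interval, every such tetrad is counted as MI nondisjunction and
flagged ambiguous so it can be excluded in sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .stats import (
    ProportionEstimate,
    TestResult,
    fisher_exact_two_tailed,
    g_test,
    proportion_wald_ci,
)

__all__ = [
    "INTERVALS",
    "TetradType",
    "TetradClass",
    "IntervalCounts",
    "TetradCounts",
    "GeneticDistance",
    "StrainComparison",
    "parse_spore",
    "format_spore",
    "classify_tetrad",
    "classify_tetrads",
    "tally",
    "perkins_distance",
    "nondisjunction_rate",
    "compare_strains",
    "read_tetrad_tsv",
    "write_tetrad_tsv",
]

#: The two test intervals, in chromosomal order CEN8 -> ARG4 -> THR1.
INTERVALS = ("CEN8-ARG4", "ARG4-THR1")

_CHANNELS = "RGB"  # column order of the flag arrays
_ND_KEY = frozenset({(True, True, True), (False, False, False)})


class TetradType(str, Enum):
    PD = "PD"
    NPD = "NPD"
    TT = "TT"


@dataclass(frozen=True)
class TetradClass:
    """Classification of one tetrad."""

    interval1: TetradType | None
    interval2: TetradType | None
    nd: bool = False
    ambiguous: bool = False
    aberrant: bool = False

    def __post_init__(self):
        if self.nd and (self.interval1 is not None or self.interval2 is not None):
            raise ValueError("nondisjunction tetrads carry no interval types")
        if self.ambiguous and not self.nd:
            raise ValueError("only the nondisjunction pattern is ambiguous")


@dataclass(frozen=True)
class IntervalCounts:
    """PD/NPD/TT tallies for one interval."""

    pd: int
    npd: int
    tt: int

    def __post_init__(self):
        if min(self.pd, self.npd, self.tt) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.pd + self.npd + self.tt

    def scaled(self, factor: int) -> "IntervalCounts":
        return IntervalCounts(self.pd * factor, self.npd * factor, self.tt * factor)


@dataclass(frozen=True)
class TetradCounts:
    """Per-strain tetrad tallies: interval types, nondisjunction, exclusions."""

    intervals: dict[str, IntervalCounts]
    nd: int
    aberrant: int
    n: int

    def __post_init__(self):
        for name, c in self.intervals.items():
            if c.total + self.nd + self.aberrant != self.n:
                raise ValueError(
                    f"interval {name!r}: PD+NPD+TT+nd+aberrant != n"
                )


@dataclass(frozen=True)
class GeneticDistance:
    """Perkins map distance with a delta-method standard error."""

    cM: float
    se: float
    n: int

    def __post_init__(self):
        if self.cM < 0 or self.se < 0:
            raise ValueError("cM and se must be non-negative")


def parse_spore(code: str) -> tuple[bool, bool, bool]:
    """Parse a 3-character spore code like ``"RG-"`` into presence flags."""
    if len(code) != 3:
        raise ValueError(f"spore code must have 3 characters, got {code!r}")
    flags = []
    for ch, channel in zip(code, _CHANNELS):
        if ch == channel:
            flags.append(True)
        elif ch == "-":
            flags.append(False)
        else:
            raise ValueError(f"invalid character {ch!r} in spore code {code!r}")
    return tuple(flags)


def format_spore(flags) -> str:
    return "".join(c if f else "-" for f, c in zip(flags, _CHANNELS))


def classify_tetrad(pattern) -> TetradClass:
    """Classify a single 4-spore fluorescence pattern.

    ``pattern`` is a sequence of four spore codes (``"RG-"`` style strings)
    or four boolean triples. Aberrant tetrads are those whose markers do not
    segregate 2:2 (other than the nondisjunction pattern).
    """
    flags = _pattern_to_flags(pattern)
    cls = classify_tetrads(flags[np.newaxis])
    row = cls.iloc[0]
    return TetradClass(
        interval1=None if row.nd or row.aberrant else TetradType(row.interval1),
        interval2=None if row.nd or row.aberrant else TetradType(row.interval2),
        nd=bool(row.nd),
        ambiguous=bool(row.ambiguous),
        aberrant=bool(row.aberrant),
    )


def _pattern_to_flags(pattern) -> np.ndarray:
    spores = list(pattern)
    if len(spores) != 4:
        raise ValueError(f"a tetrad has 4 spores, got {len(spores)}")
    rows = [parse_spore(s) if isinstance(s, str) else tuple(map(bool, s)) for s in spores]
    if any(len(r) != 3 for r in rows):
        raise ValueError("each spore needs 3 marker flags")
    return np.array(rows, dtype=bool)


_TYPE_BY_REC = {0: "PD", 2: "TT", 4: "NPD"}


def classify_tetrads(flags: np.ndarray) -> pd.DataFrame:
    """Vectorised classification of an (n, 4, 3) boolean flag array.

    Returns a DataFrame with columns interval1, interval2 (PD/NPD/TT or NA),
    nd, ambiguous, aberrant.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.ndim != 3 or flags.shape[1:] != (4, 3):
        raise ValueError("expected flags of shape (n, 4, 3)")
    n = flags.shape[0]

    # MI nondisjunction: two all-on spores and two all-off spores.
    n_on = flags.sum(axis=2)  # markers per spore
    nd = (np.sort(n_on, axis=1) == [0, 0, 3, 3]).all(axis=1)

    # 2:2 segregation of each marker.
    per_channel = flags.sum(axis=1)  # (n, 3)
    two_two = (per_channel == 2).all(axis=1)
    aberrant = ~two_two & ~nd

    # Homolog of origin at each locus: CEN8 and ARG4 reporters mark homolog 1,
    # the THR1 reporter marks homolog 2.
    hom1_cen8 = flags[:, :, 0]
    hom1_arg4 = flags[:, :, 1]
    hom1_thr1 = ~flags[:, :, 2]
    rec1 = (hom1_cen8 != hom1_arg4).sum(axis=1)
    rec2 = (hom1_arg4 != hom1_thr1).sum(axis=1)

    interval1 = np.full(n, None, dtype=object)
    interval2 = np.full(n, None, dtype=object)
    ok = ~nd & ~aberrant
    for rec, out in ((rec1, interval1), (rec2, interval2)):
        for k, label in _TYPE_BY_REC.items():
            out[ok & (rec == k)] = label

    return pd.DataFrame(
        {
            "interval1": interval1,
            "interval2": interval2,
            "nd": nd,
            "ambiguous": nd,  # the ND pattern is exactly the ambiguous one
            "aberrant": aberrant,
        }
    )


def tally(classified: pd.DataFrame, ambiguous: str = "nd") -> TetradCounts:
    """Tally a classification table into per-interval counts.

    ``ambiguous`` controls the two-triple-positive/two-dark pattern, which is
    compatible with both MI nondisjunction and a four-chromatid double
    crossover in the second interval:

    * ``"nd"`` (default): count as nondisjunction — appropriate for real
      strains, where segregation defects dominate this pattern;
    * ``"npd"``: count as interval-1 PD / interval-2 NPD — appropriate when
      nondisjunction is known to be absent (e.g. simulations without it),
      where the default rule would deflate the second interval's distance;
    * ``"exclude"``: drop from all tallies (sensitivity analysis).
    """
    n = len(classified)
    amb = int(classified["ambiguous"].sum())
    aberrant = int(classified["aberrant"].sum())
    intervals = {}
    for name, col in zip(INTERVALS, ("interval1", "interval2")):
        vc = classified[col].value_counts()
        intervals[name] = IntervalCounts(
            pd=int(vc.get("PD", 0)), npd=int(vc.get("NPD", 0)), tt=int(vc.get("TT", 0))
        )
    if ambiguous == "nd":
        nd = amb
    elif ambiguous == "npd":
        nd = 0
        i1, i2 = (intervals[name] for name in INTERVALS)
        intervals[INTERVALS[0]] = IntervalCounts(i1.pd + amb, i1.npd, i1.tt)
        intervals[INTERVALS[1]] = IntervalCounts(i2.pd, i2.npd + amb, i2.tt)
    elif ambiguous == "exclude":
        nd = 0
        n -= amb
    else:
        raise ValueError(f"unknown ambiguous policy: {ambiguous!r}")
    return TetradCounts(intervals=intervals, nd=nd, aberrant=aberrant, n=n)


def _interval_counts(counts, interval) -> IntervalCounts:
    if isinstance(counts, IntervalCounts):
        return counts
    if isinstance(counts, TetradCounts):
        if isinstance(interval, int):
            interval = INTERVALS[interval - 1]
        return counts.intervals[interval]
    pd_, npd, tt = counts
    return IntervalCounts(pd_, npd, tt)


def perkins_distance(counts, interval=None) -> GeneticDistance:
    """Perkins map distance cM = 100 (6 NPD + TT) / (2 (PD + NPD + TT)).

    The Perkins formula corrects tetratype-based distances for double
    crossovers under the assumption of no chromatid interference. The
    standard error comes from the multinomial delta method on the tetratype
    and NPD fractions t and p:

        se = 50 sqrt[(t (1 - t) + 36 p (1 - p) - 12 t p) / n].
    """
    c = _interval_counts(counts, interval)
    n = c.total
    if n == 0:
        raise ValueError("no informative tetrads: PD + NPD + TT = 0")
    t = c.tt / n
    p = c.npd / n
    cm = 100.0 * (6 * c.npd + c.tt) / (2.0 * n)
    var = (t * (1 - t) + 36 * p * (1 - p) - 12 * t * p) / n
    se = 50.0 * float(np.sqrt(max(var, 0.0)))
    return GeneticDistance(cM=cm, se=se, n=n)


def nondisjunction_rate(counts: TetradCounts, level: float = 0.95) -> ProportionEstimate:
    """MI nondisjunction frequency nd/n with a Wald confidence interval.

    The returned estimate is on the proportion scale; use ``.percent`` for
    the percent presentation of segregation-defect plots.
    """
    if counts.n <= 0:
        raise ValueError("no tetrads scored")
    return proportion_wald_ci(counts.nd, counts.n, level=level)


@dataclass(frozen=True)
class StrainComparison:
    """Paired test results comparing two strains' tetrad data."""

    crossover_tests: dict[str, TestResult]
    nd_test: TestResult
    distance_ratio: dict[str, float]
    percent_of_reference: dict[str, float]


def compare_strains(a: TetradCounts, b: TetradCounts, table: str = "tetrads") -> StrainComparison:
    """Compare crossovers and nondisjunction between two strains.

    Crossovers are compared per interval by a G test, by default on the
    2x3 strain-by-(PD, NPD, TT) table (``table="tetrads"``); with
    ``table="spores"`` the comparison is on the 2x2 recombinant/parental
    spore table, counting 2 recombinant chromatids per TT and 4 per NPD.
    Nondisjunction is compared by a two-tailed Fisher exact test on the
    (nd, n - nd) table. Distance ratios a/b and the percent-of-reference
    normalisation (strain a as percent of strain b) are also reported.
    """
    if set(a.intervals) != set(b.intervals):
        raise ValueError("strains were not scored in the same intervals")
    crossover_tests: dict[str, TestResult] = {}
    ratio: dict[str, float] = {}
    percent: dict[str, float] = {}
    for name in a.intervals:
        ca, cb = a.intervals[name], b.intervals[name]
        if table == "tetrads":
            grid = [[ca.pd, ca.npd, ca.tt], [cb.pd, cb.npd, cb.tt]]
        elif table == "spores":
            grid = [
                [2 * ca.tt + 4 * ca.npd, 4 * ca.total - 2 * ca.tt - 4 * ca.npd],
                [2 * cb.tt + 4 * cb.npd, 4 * cb.total - 2 * cb.tt - 4 * cb.npd],
            ]
        else:
            raise ValueError(f"unknown table layout: {table!r}")
        # Drop all-zero columns (e.g. no NPDs in either strain) before testing.
        grid = np.asarray(grid)
        grid = grid[:, grid.sum(axis=0) > 0]
        crossover_tests[name] = g_test(grid)
        da = perkins_distance(ca)
        db = perkins_distance(cb)
        ratio[name] = da.cM / db.cM if db.cM > 0 else float("inf")
        percent[name] = 100.0 * da.cM / db.cM if db.cM > 0 else float("inf")
    if a.nd == 0 and b.nd == 0:
        # No events in either strain: the exact test is degenerate and no
        # difference is detectable.
        nd_test = TestResult(p_value=1.0, method="fisher_exact_two_tailed")
    else:
        nd_test = fisher_exact_two_tailed(
            [[a.nd, a.n - a.nd], [b.nd, b.n - b.nd]]
        )
    return StrainComparison(
        crossover_tests=crossover_tests,
        nd_test=nd_test,
        distance_ratio=ratio,
        percent_of_reference=percent,
    )


def read_tetrad_tsv(path) -> np.ndarray:
    """Read a per-tetrad TSV (tetrad_id, spore1..spore4) into a flag array."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c for c in df.columns if c.lower().startswith("spore")]
    if len(cols) != 4:
        raise ValueError("expected four spore columns (spore1..spore4)")
    flags = np.array(
        [[parse_spore(code) for code in row] for row in df[cols].to_numpy()],
        dtype=bool,
    )
    return flags


def write_tetrad_tsv(flags: np.ndarray, path) -> None:
    """Write an (n, 4, 3) flag array as a per-tetrad TSV."""
    flags = np.asarray(flags, dtype=bool)
    rows = {
        "tetrad_id": np.arange(1, flags.shape[0] + 1),
    }
    for j in range(4):
        rows[f"spore{j + 1}"] = [format_spore(f) for f in flags[:, j]]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
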