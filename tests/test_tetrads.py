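"""Tetrad classification, Perkins distances, and strain comparisons."""

import math
from itertools import product

import numpy as np
import pytest

from meioquant import simulate
from meioquant.stats import fisher_exact_two_tailed
from meioquant.tetrads import (
    INTERVALS,
    IntervalCounts,
    classify_tetrad,
    classify_tetrads,
    compare_strains,
    nondisjunction_rate,
    perkins_distance,
    read_tetrad_tsv,
    tally,
    write_tetrad_tsv,
)


class TestClassifyTetrad:
    @pytest.mark.parametrize(
        "pattern, i1, i2",
        [
            # no recombination: two parental chromatid classes
            (["RG-", "RG-", "--B", "--B"], "PD", "PD"),
            # single interval-1 crossover: R-B / -G- recombinants
            (["RG-", "R-B", "-G-", "--B"], "TT", "PD"),
            # single interval-2 crossover: RGB / --- recombinants
            (["RGB", "RG-", "---", "--B"], "PD", "TT"),
            # double recombinants R-- / -GB are recombinant in both intervals
            (["R--", "-GB", "RG-", "--B"], "TT", "TT"),
            # four-chromatid double crossover in interval 1
            (["R-B", "R-B", "-G-", "-G-"], "NPD", "PD"),
        ],
    )
    def test_canonical_patterns(self, pattern, i1, i2):
        cls = classify_tetrad(pattern)
        assert (cls.interval1, cls.interval2) == (i1, i2)
        assert not cls.nd and not cls.aberrant

    def test_nd_pattern_is_ambiguous_nondisjunction(self):
        cls = classify_tetrad(["RGB", "RGB", "---", "---"])
        assert cls.nd and cls.ambiguous
        assert cls.interval1 is None and cls.interval2 is None

    def test_non_2_to_2_segregation_is_aberrant(self):
        cls = classify_tetrad(["RG-", "RG-", "RG-", "--B"])
        assert cls.aberrant and not cls.nd

    def test_spore_order_irrelevant(self):
        a = classify_tetrad(["RG-", "R-B", "-G-", "--B"])
        b = classify_tetrad(["--B", "-G-", "R-B", "RG-"])
        assert (a.interval1, a.interval2) == (b.interval1, b.interval2)

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_tetrad(["RG-", "RG-", "--B"])
        with pytest.raises(ValueError):
            classify_tetrad(["XG-", "RG-", "--B", "--B"])

    def test_agrees_with_simulator_ground_truth(self):
        sim = simulate.simulate_tetrads(20_000, 12.0, 8.0, nd_prob=0.01, seed=42)
        cls = classify_tetrads(sim.patterns)
        # The ambiguous pattern (true interval-2 NPD with interval-1 PD, or
        # true nondisjunction) is the only allowed disagreement.
        plain = ~cls["ambiguous"]
        assert (cls.loc[plain, "interval1"] == sim.truth.loc[plain, "interval1"]).all()
        assert (cls.loc[plain, "interval2"] == sim.truth.loc[plain, "interval2"]).all()
        assert not cls["aberrant"].any()
        # every true nondisjunction is classified as such
        assert cls.loc[sim.truth["nd"], "nd"].all()


def two_crossover_enumeration():
    """Exact tetrad-type distribution given exactly 2 crossovers in one interval.

    Enumerates the 16 equally likely chromatid choices: each crossover joins
    one chromatid currently carrying homolog-1 content distal of the interval
    with one carrying homolog-2 content (2 x 2 choices per crossover).
    """
    outcomes = {"PD": 0, "TT": 0, "NPD": 0}
    for picks in product(range(2), range(2), range(2), range(2)):
        content = [0, 0, 1, 1]  # distal homolog content per chromatid
        for j in range(2):
            ones = [i for i, c in enumerate(content) if c == 0]
            twos = [i for i, c in enumerate(content) if c == 1]
            a, b = ones[picks[2 * j]], twos[picks[2 * j + 1]]
            content[a], content[b] = content[b], content[a]
        rec = sum(1 for i, c in enumerate(content) if (i < 2) != (c == 0))
        outcomes[{0: "PD", 2: "TT", 4: "NPD"}[rec]] += 1
    return {k: v / 16 for k, v in outcomes.items()}


class TestTwoCrossoverRatio:
    def test_enumeration_oracle_gives_quarter_half_quarter(self):
        assert two_crossover_enumeration() == {"PD": 0.25, "TT": 0.5, "NPD": 0.25}

    def test_simulator_matches_conditional_on_two_crossovers(self):
        sim = simulate.simulate_tetrads(150_000, 25.0, 0.0, seed=7)
        sub = sim.truth[sim.truth.n_co1 == 2]
        freq = sub.interval1.value_counts(normalize=True)
        n = len(sub)
        assert n > 3000
        for typ, expected in (("PD", 0.25), ("TT", 0.5), ("NPD", 0.25)):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(freq[typ] - expected) < 4 * se


class TestPerkinsDistance:
    @pytest.mark.parametrize(
        "counts, cm",
        [
            ((100, 0, 0), 0.0),
            ((80, 0, 20), 10.0),
            ((70, 5, 25), 27.5),
        ],
    )
    def test_printed_formula(self, counts, cm):
        assert perkins_distance(counts).cM == pytest.approx(cm)

    def test_delta_method_se(self):
        c = IntervalCounts(70, 5, 25)
        n = c.total
        t, p = c.tt / n, c.npd / n
        expected = 50 * math.sqrt((t * (1 - t) + 36 * p * (1 - p) - 12 * t * p) / n)
        assert perkins_distance(c).se == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("factor", [2, 10, 100])
    def test_count_scaling(self, factor):
        base = IntervalCounts(80, 3, 17)
        d1 = perkins_distance(base)
        d2 = perkins_distance(base.scaled(factor))
        assert d2.cM == pytest.approx(d1.cM, rel=1e-12)
        assert d2.se == pytest.approx(d1.se / math.sqrt(factor), rel=1e-12)

    def test_no_informative_tetrads(self):
        with pytest.raises(ValueError):
            perkins_distance((0, 0, 0))

    def test_recovers_generative_distance_small_d(self):
        sim = simulate.simulate_tetrads(100_000, 10.0, 4.0, seed=3)
        counts = tally(classify_tetrads(sim.patterns), ambiguous="npd")
        for name, d_true in zip(INTERVALS, (10.0, 4.0)):
            est = perkins_distance(counts, name)
            assert abs(est.cM - d_true) < 3 * est.se + 0.02 * d_true


class TestNondisjunctionRate:
    def test_printed_wild_type_example(self):
        counts = tally_from(nd=1, pd=1067, tt=180, npd=20)
        est = nondisjunction_rate(counts)
        assert est.percent == pytest.approx(100 / 1268, rel=1e-12)
        assert round(est.percent, 1) == 0.1

    def test_zero_case(self):
        est = nondisjunction_rate(tally_from(nd=0, pd=1000))
        assert est.percent == 0.0 and est.percent_half_width == 0.0

    def test_wald_half_width(self):
        est = nondisjunction_rate(tally_from(nd=15, pd=1285))
        p = 15 / 1300
        assert est.percent == pytest.approx(100 * p)
        assert est.percent_half_width == pytest.approx(
            100 * 1.959964 * math.sqrt(p * (1 - p) / 1300), rel=1e-5
        )


def tally_from(nd=0, pd=0, npd=0, tt=0, aberrant=0):
    from meioquant.tetrads import TetradCounts

    n = pd + npd + tt + nd + aberrant
    return TetradCounts(
        intervals={name: IntervalCounts(pd, npd, tt) for name in INTERVALS},
        nd=nd,
        aberrant=aberrant,
        n=n,
    )


class TestCompareStrains:
    def test_identical_strains(self):
        a = tally_from(nd=5, pd=500, npd=5, tt=90)
        res = compare_strains(a, a)
        for t in res.crossover_tests.values():
            assert t.statistic == pytest.approx(0.0, abs=1e-10)
            assert t.p_value == pytest.approx(1.0)
        assert res.nd_test.p_value == 1.0
        assert all(v == pytest.approx(100.0) for v in res.percent_of_reference.values())

    def test_nd_fisher_matches_oracle(self):
        from oracles import fisher_enumeration_oracle

        a = tally_from(nd=29, pd=2300, npd=21, tt=170)
        b = tally_from(nd=12, pd=2310, npd=18, tt=170)
        res = compare_strains(a, b)
        expected = fisher_enumeration_oracle(29, a.n - 29, 12, b.n - 12)
        assert res.nd_test.p_value == pytest.approx(expected, rel=1e-9)

    def test_percent_of_wild_type_normalization(self):
        # 7.0 cM mutant vs 11.63 cM reference -> 60.2% of wild type
        mut = tally_from(pd=8600, tt=1400)  # Perkins 7.0 cM
        wt = tally_from(pd=77240, npd=100, tt=22660)
        assert perkins_distance(mut, INTERVALS[0]).cM == pytest.approx(7.0)
        assert perkins_distance(wt, INTERVALS[0]).cM == pytest.approx(11.63)
        res = compare_strains(mut, wt)
        assert round(res.percent_of_reference[INTERVALS[0]], 1) == 60.2

    def test_spore_table_layout(self):
        a = tally_from(nd=2, pd=500, npd=5, tt=90)
        b = tally_from(nd=3, pd=480, npd=8, tt=110)
        res = compare_strains(a, b, table="spores")
        for t in res.crossover_tests.values():
            assert t.df == 1


class TestTallyPolicies:
    def test_ambiguous_policies(self):
        patterns = [
            ["RG-", "RG-", "--B", "--B"],
            ["RGB", "RGB", "---", "---"],
            ["RG-", "R-B", "-G-", "--B"],
        ]
        flags = np.array(
            [[list(map(lambda c, ch: c == ch, s, "RGB")) for s in p] for p in patterns]
        )
        cls = classify_tetrads(flags)

        as_nd = tally(cls, ambiguous="nd")
        assert as_nd.nd == 1
        assert as_nd.intervals[INTERVALS[1]].npd == 0

        as_npd = tally(cls, ambiguous="npd")
        assert as_npd.nd == 0
        assert as_npd.intervals[INTERVALS[1]].npd == 1
        assert as_npd.intervals[INTERVALS[0]].pd == 2  # 1 true PD + the DCO tetrad

        excl = tally(cls, ambiguous="exclude")
        assert excl.n == 2 and excl.nd == 0


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        sim = simulate.simulate_tetrads(50, 10.0, 5.0, nd_prob=0.05, seed=11)
        path = tmp_path / "tetrads.tsv"
        write_tetrad_tsv(sim.patterns, path)
        flags = read_tetrad_tsv(path)
        assert np.array_equal(flags, sim.patterns)
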