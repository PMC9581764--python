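import math
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio
from scipy.stats import fisher_exact as scipy_fisher

from amplisplice.classify import AlignedRead, parse_cigar
from amplisplice.quantify import (
    compare_to_controls,
    depth_inclusion,
    fisher_exact_2x2,
    flag_plasma_coq10,
    per_allele_fractions,
)


def _calls(rows):
    return pd.DataFrame(rows, columns=["read_id", "event", "deviation"])


def _alleles(rows):
    return pd.DataFrame(rows, columns=["read_id", "status", "base", "quality"])


class TestPerAlleleFractions:
    def _fixture(self):
        events, alleles = [], []
        i = 0
        for status, event, n in [
            ("alt", "exon5_skip", 56), ("alt", "exon45_skip", 3),
            ("alt", "canonical", 41), ("ref", "exon5_skip", 4),
            ("ref", "canonical", 96), ("missing", "canonical", 5),
            ("alt", "unclassified", 2),
        ]:
            for _ in range(n):
                events.append((f"r{i}", event, 0))
                alleles.append((f"r{i}", status, None, None))
                i += 1
        return _calls(events), _alleles(alleles)

    def test_published_skip_fractions(self):
        q = per_allele_fractions(*self._fixture(),
                                 allele_names={"alt": "variant", "ref": "trans"})
        assert q.fraction("variant", "exon5_skip") == pytest.approx(0.56)
        assert q.fraction("trans", "exon5_skip") == pytest.approx(0.04)
        assert q.fraction("variant", "exon45_skip") == pytest.approx(0.03)
        assert q.excluded == {"missing_allele": 5, "unclassified_event": 2}

    def test_fractions_per_allele_sum_to_one(self):
        q = per_allele_fractions(*self._fixture())
        sums = q.table.groupby("allele_id").fraction.sum()
        assert np.allclose(sums, 1.0)

    def test_invariant_to_read_order(self):
        ev, al = self._fixture()
        q1 = per_allele_fractions(ev, al)
        q2 = per_allele_fractions(
            ev.sample(frac=1, random_state=4), al.sample(frac=1, random_state=9)
        )
        pd.testing.assert_frame_equal(q1.table, q2.table)

    def test_all_canonical_input(self):
        ev = _calls([(f"r{i}", "canonical", 0) for i in range(10)])
        al = _alleles([(f"r{i}", "ref", None, None) for i in range(10)])
        q = per_allele_fractions(ev, al)
        assert q.fraction("ref", "canonical") == 1.0

    def test_allele_with_no_classified_reads_is_flagged(self):
        ev = _calls([("r0", "unclassified", None)])
        al = _alleles([("r0", "alt", None, None)])
        q = per_allele_fractions(ev, al)
        assert q.totals["alt"] == 0
        assert "undefined_fraction:alt" in q.excluded


def _read(read_id, cigar, start):
    ops = parse_cigar(cigar)
    qlen = sum(n for op, n in ops if op in "MIS=X")
    return AlignedRead(read_id, "ref", start, ops, "A" * qlen)


class TestDepthInclusion:
    def test_hand_computed_pileup_three_of_ten(self):
        # alt region 101-110, anchor 201-210; 3 reads cover both, 7 skip alt
        reads = [_read(f"c{i}", "210M", 1) for i in range(3)]
        reads += [_read(f"s{i}", "100M100D10M", 1) for i in range(7)]
        (res,) = depth_inclusion({"x": reads}, (101, 110), (201, 210))
        assert res.inclusion_fraction == pytest.approx(0.3)
        assert res.mean_depth_alt == 3 and res.mean_depth_anchor == 10

    def test_all_reads_including_region_gives_one(self):
        reads = [_read(f"r{i}", "210M", 1) for i in range(5)]
        (res,) = depth_inclusion({"x": reads}, (101, 110), (201, 210))
        assert res.inclusion_fraction == 1.0

    def test_competing_convention(self):
        reads = [_read(f"c{i}", "210M", 1) for i in range(3)]
        reads += [_read(f"s{i}", "100M100D10M", 1) for i in range(7)]
        (res,) = depth_inclusion({"x": reads}, (101, 110), (201, 210),
                                 convention="competing")
        assert res.inclusion_fraction == pytest.approx(3 / 13)

    def test_zero_anchor_depth_is_an_error(self):
        reads = [_read("r0", "50M", 1)]
        with pytest.raises(ZeroDivisionError):
            depth_inclusion({"x": reads}, (1, 10), (201, 210))

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            depth_inclusion({}, (100, 200), (150, 250))

    def test_depth_route_equals_read_proportion_route(self, pdss1_small):
        """Mean-depth inclusion equals per-read counting for whole-exon regions."""
        q = pdss1_small.quant
        for allele in ("A", "G"):
            assert pdss1_small.inclusion[allele].inclusion_fraction == pytest.approx(
                q.fraction(allele, "alt_exon")
            )


# -- independent oracle: exact-rational enumeration of the conditional law --


def _support(a, b, c, d):
    m1, m2, n1 = a + b, c + d, a + c
    return range(max(0, n1 - m2), min(n1, m1) + 1), m1, m2, n1


def oracle_p_two_sided(a, b, c, d):
    ks, m1, m2, n1 = _support(a, b, c, d)
    w = {k: Fraction(math.comb(m1, k) * math.comb(m2, n1 - k)) for k in ks}
    total = sum(w.values())
    p_obs = w[a] / total
    return float(sum(p for p in (w[k] / total for k in ks) if p <= p_obs))


def oracle_cmle(a, b, c, d):
    """Solve E_psi[K] = a by float bisection on exact-integer weights."""
    ks, m1, m2, n1 = _support(a, b, c, d)
    ks = list(ks)
    w = [math.comb(m1, k) * math.comb(m2, n1 - k) for k in ks]
    if a == ks[0]:
        return 0.0
    if a == ks[-1]:
        return math.inf

    def mean(psi):
        probs = [wk * psi**k for wk, k in zip(w, ks)]
        s = sum(probs)
        return sum(p * k for p, k in zip(probs, ks)) / s

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if mean(mid) < a:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def all_small_tables(max_margin=6):
    for a, b, c, d in product(range(max_margin + 1), repeat=4):
        if (a + b <= max_margin and c + d <= max_margin
                and a + c <= max_margin and b + d <= max_margin
                and a + b > 0 and c + d > 0 and a + c > 0 and b + d > 0):
            yield a, b, c, d


class TestFisherExact:
    def test_symmetric_unit_table(self):
        r = fisher_exact_2x2([[1, 1], [1, 1]])
        assert r.p_two_sided == pytest.approx(1.0)
        assert r.or_cmle == pytest.approx(1.0)

    def test_enumeration_oracle_all_margins_up_to_six(self):
        """p and CMLE agree with exact-rational enumeration to 1e-9."""
        for a, b, c, d in all_small_tables():
            r = fisher_exact_2x2([[a, b], [c, d]])
            assert r.p_two_sided == pytest.approx(
                oracle_p_two_sided(a, b, c, d), abs=1e-9
            ), (a, b, c, d)
            o = oracle_cmle(a, b, c, d)
            if math.isinf(o):
                assert math.isinf(r.or_cmle)
            else:
                assert r.or_cmle == pytest.approx(o, rel=1e-9, abs=1e-9), (a, b, c, d)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 19], [411, 282353]],
            [[10, 5], [7, 12]],
            [[2, 8], [9, 3]],
            [[40, 12], [13, 44]],
            [[1, 9], [11, 2]],
        ],
    )
    def test_matches_scipy_conditional_convention(self, table):
        r = fisher_exact_2x2(table)
        s = scipy_odds_ratio(table)
        ci = s.confidence_interval(0.95)
        assert r.or_cmle == pytest.approx(s.statistic, rel=1e-6)
        assert r.ci_low == pytest.approx(ci.low, rel=1e-6)
        assert r.ci_high == pytest.approx(ci.high, rel=1e-6)
        assert r.p_two_sided == pytest.approx(scipy_fisher(table)[1], rel=1e-9)

    def test_ci_widens_with_confidence_level(self):
        widths = []
        for conf in (0.8, 0.9, 0.95, 0.99):
            r = fisher_exact_2x2([[10, 5], [7, 12]], conf=conf)
            assert r.ci_low <= r.or_cmle <= r.ci_high
            widths.append(r.ci_high - r.ci_low)
        assert widths == sorted(widths)

    def test_degenerate_margin_gives_p_one_or_undefined(self):
        r = fisher_exact_2x2([[0, 0], [5, 8]])
        assert r.p_two_sided == 1.0 and math.isnan(r.or_cmle)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_ci_coverage_at_known_psi(self):
        """Empirical CI coverage at psi = 3 stays within 3% of nominal."""
        a0, b0, c0, d0 = 6, 6, 6, 6  # margins of the sampled tables
        ks, m1, m2, n1 = _support(a0, b0, c0, d0)
        ks = np.array(list(ks))
        psi = 3.0
        w = np.array([math.comb(m1, k) * math.comb(m2, n1 - k) for k in ks], float)
        p = w * psi ** ks
        p /= p.sum()
        rng = np.random.default_rng(2024)
        draws = rng.choice(ks, size=1000, p=p)
        cis = {}
        for k in np.unique(draws):
            a = int(k)
            r = fisher_exact_2x2([[a, m1 - a], [n1 - a, m2 - n1 + a]])
            cis[a] = (r.ci_low, r.ci_high)
        covered = np.mean([cis[int(k)][0] <= psi <= cis[int(k)][1] for k in draws])
        assert covered >= 0.95 - 0.03


class TestControlsAndFlagging:
    def test_case_outside_control_band_is_flagged(self):
        r = compare_to_controls(0.9025, [0.065, 0.08, 0.1014])
        assert r.outside_range

    def test_case_equal_to_control_extreme_is_not_flagged(self):
        assert not compare_to_controls(0.1014, [0.065, 0.1014]).outside_range

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            compare_to_controls(0.5, [])

    @pytest.mark.parametrize(
        "value,expected",
        [(39.33, "below"), (195.45, "below"), (227.0, "within"),
         (1432.0, "within"), (1500.0, "above")],
    )
    def test_plasma_reference_range_flags(self, value, expected):
        assert flag_plasma_coq10(value) == expected

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            flag_plasma_coq10(-1.0)
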