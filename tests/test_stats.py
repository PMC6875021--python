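"""Agreement statistics against brute-force and closed-form oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from annuseg.core import BinaryMask, ValidationError
from annuseg.sizing import DeviceSelection, OUT_OF_RANGE_LOW
from annuseg.stats import (
    CohortCase,
    PairedSeries,
    agreement_report,
    bland_altman,
    dice,
    evaluate_cohort,
    paired_difference,
    pearson,
    shapiro_wilk,
    size_agreement,
    wilcoxon_signed_rank,
)


def mask(arr):
    a = np.asarray(arr, dtype=bool)
    return BinaryMask(values=a, spacing=(1.0, 1.0))


class TestDice:
    def test_identical_masks(self):
        m = mask(np.eye(5))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(mask(a), mask(b)) == 0.0

    def test_constructed_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(mask(a), mask(b)) == pytest.approx(0.5)

    def test_matches_set_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.uniform(size=(12, 12)) > 0.5
            b = rng.uniform(size=(12, 12)) > 0.5
            sa = {tuple(idx) for idx in np.argwhere(a)}
            sb = {tuple(idx) for idx in np.argwhere(b)}
            expected = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert dice(mask(a), mask(b)) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = mask(rng.uniform(size=(8, 8)) > 0.4)
        b = mask(rng.uniform(size=(8, 8)) > 0.6)
        assert dice(a, b) == dice(b, a)

    def test_errors(self):
        with pytest.raises(ValidationError):
            dice(mask(np.zeros((3, 3))), mask(np.zeros((4, 4))))
        with pytest.raises(ValidationError):
            dice(mask(np.zeros((3, 3))), mask(np.zeros((3, 3))))


def wilcoxon_bruteforce(d):
    """Full 2^n sign-flip enumeration with Pratt zero handling."""
    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    nz = d != 0
    r = ranks[nz]
    w_obs = r[d[nz] > 0].sum()
    stats = [
        np.asarray(signs, dtype=float) @ r
        for signs in itertools.product([0, 1], repeat=len(r))
    ]
    stats = np.array(stats)
    n = len(stats)
    cdf = np.sum(stats <= w_obs + 1e-12) / n
    sf = np.sum(stats >= w_obs - 1e-12) / n
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        _, p, degenerate = wilcoxon_signed_rank(np.array([1, 2, 3, 4, 5, 6.0]))
        assert not degenerate
        assert p == pytest.approx(2 / 64)

    def test_exact_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        cases = [rng.normal(size=n) for n in (4, 7, 10, 12)]
        cases.append(np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0]))  # ties
        cases.append(np.array([0.0, 1.0, -2.0, 3.0, 0.0, 4.0, 5.0]))  # zeros
        for d in cases:
            _, p, _ = wilcoxon_signed_rank(d)
            assert p == pytest.approx(wilcoxon_bruteforce(d), abs=1e-12)

    def test_degenerate_all_zero(self):
        _, p, degenerate = wilcoxon_signed_rank(np.zeros(5))
        assert degenerate and p == 1.0

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, size=25)
        _, p_exact, _ = wilcoxon_signed_rank(d, exact_max_n=25)
        _, p_normal, _ = wilcoxon_signed_rank(d, exact_max_n=10)
        assert p_normal == pytest.approx(p_exact, abs=0.02)


class TestPairedDifference:
    def test_identical_series_degenerate(self):
        s = PairedSeries(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        mean, sd, p, degenerate = paired_difference(s)
        assert mean == 0.0 and sd == 0.0 and p == 1.0 and degenerate

    def test_alternating_differences_sample_sd(self):
        b = np.array([5.0, 6.0, 7.0, 8.0])
        s = PairedSeries(b + np.array([1.0, -1.0, 1.0, -1.0]), b)
        mean, sd, _, _ = paired_difference(s)
        assert mean == 0.0
        assert sd == pytest.approx(math.sqrt(4 / 3), abs=1e-4)
        assert sd == pytest.approx(1.1547, abs=1e-4)

    def test_length_and_finiteness_validated(self):
        with pytest.raises(ValidationError):
            PairedSeries(np.array([1.0, 2]), np.array([1.0, 2]))
        with pytest.raises(ValidationError):
            PairedSeries(np.array([1.0, 2, np.nan]), np.array([1.0, 2, 3]))


class TestBlandAltman:
    def test_identical_series(self):
        s = PairedSeries(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        ba = bland_altman(s)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_alternating_differences_loa(self):
        b = np.array([5.0, 6.0, 7.0, 8.0])
        ba = bland_altman(PairedSeries(b + np.array([1.0, -1.0, 1.0, -1.0]), b))
        assert ba.loa_low == pytest.approx(-2.263, abs=1e-3)
        assert ba.loa_high == pytest.approx(2.263, abs=1e-3)

    @given(c=st.floats(-50, 50))
    def test_translation_equivariance(self, c):
        rng = np.random.default_rng(4)
        a = rng.normal(10, 2, size=8)
        b = rng.normal(10, 2, size=8)
        base = bland_altman(PairedSeries(a, b))
        shifted = bland_altman(PairedSeries(a + c, b))
        assert shifted.bias == pytest.approx(base.bias + c, abs=1e-9)
        assert shifted.loa_high - shifted.loa_low == pytest.approx(
            base.loa_high - base.loa_low, abs=1e-9
        )

    @given(k=st.floats(0.1, 10))
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(5)
        a = rng.normal(10, 2, size=8)
        b = rng.normal(10, 2, size=8)
        base = bland_altman(PairedSeries(a, b))
        scaled = bland_altman(PairedSeries(k * a, k * b))
        assert scaled.bias == pytest.approx(k * base.bias, rel=1e-9, abs=1e-9)
        assert scaled.loa_high == pytest.approx(k * base.loa_high, rel=1e-9, abs=1e-9)


class TestPearson:
    def test_perfect_positive_linear(self):
        a = np.array([1.0, 2, 3, 4])
        assert pearson(PairedSeries(a, 2 * a + 3)) == pytest.approx(1.0)

    def test_perfect_negative(self):
        a = np.array([1.0, 2, 3, 4])
        assert pearson(PairedSeries(a, -a)) == pytest.approx(-1.0)

    def test_closed_form_example(self):
        assert pearson(
            PairedSeries(np.array([1.0, 2, 3]), np.array([1.0, 3, 2]))
        ) == pytest.approx(0.5)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            pearson(PairedSeries(np.array([2.0, 2, 2]), np.array([1.0, 2, 3])))

    @given(slope=st.floats(0.1, 5), intercept=st.floats(-10, 10))
    def test_invariance_under_positive_affine_transform(self, slope, intercept):
        rng = np.random.default_rng(6)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        r0 = pearson(PairedSeries(a, b))
        r1 = pearson(PairedSeries(slope * a + intercept, b))
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestShapiroWilk:
    def test_rejects_uniform_at_large_n(self):
        rng = np.random.default_rng(7)
        _, p = shapiro_wilk(rng.uniform(size=5000))
        assert p < 0.001

    def test_type_one_error_on_normal_draws(self):
        passes = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, p = shapiro_wilk(rng.normal(size=50))
            passes += p > 0.01
        assert passes >= 95

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.full(10, 3.0))
        with pytest.raises(ValidationError):
            shapiro_wilk(np.array([1.0, 2.0]))


def selections(labels, family="F"):
    return [DeviceSelection(family, l, 100.0) for l in labels]


class TestSizeAgreement:
    def test_identical_sequences(self):
        sel = selections(["23", "26", "26", "29"])
        res = size_agreement(sel, sel)
        assert res.ratio == 1.0 and res.n_under == 0 and res.n_over == 0

    def test_118_pairs_13_disagreements(self):
        a = ["23"] * 118
        b = ["23"] * 105 + ["26"] * 13
        res = size_agreement(selections(a), selections(b))
        assert res.ratio == pytest.approx(105 / 118)
        assert res.n_under == 13 and res.n_over == 0

    def test_confusion_table_counts_sentinels(self):
        a = selections(["23", OUT_OF_RANGE_LOW, "26"])
        b = selections(["23", "23", "23"])
        res = size_agreement(a, b)
        assert res.table.loc[OUT_OF_RANGE_LOW, "23"] == 1
        assert res.table.loc["26", "23"] == 1
        assert res.table.to_numpy().sum() == 3
        assert res.n_under == 1 and res.n_over == 1

    def test_errors(self):
        with pytest.raises(ValidationError):
            size_agreement([], [])
        with pytest.raises(ValidationError):
            size_agreement(selections(["23"]), selections(["23", "26"]))
        with pytest.raises(ValidationError):
            size_agreement(selections(["23"], "A"), selections(["23"], "B"))


class TestEvaluateCohort:
    def _cases(self, rng, n=8, with_masks=True):
        cases = {}
        for i in range(n):
            area = rng.uniform(350, 550)
            perim = math.sqrt(4 * math.pi * area) * rng.uniform(1.01, 1.05)
            m = None
            if with_masks:
                m = BinaryMask(rng.uniform(size=(16, 16)) > 0.5, spacing=(1.0, 1.0))
            cases[f"case{i}"] = CohortCase(area=area, perimeter=perim, mask=m)
        return cases

    def test_self_comparison_identity(self, charts):
        rng = np.random.default_rng(8)
        truths = self._cases(rng)
        report = evaluate_cohort(truths, truths, charts)
        assert report.area.mean_diff == 0.0
        assert (report.area.loa_low, report.area.loa_high) == (0.0, 0.0)
        assert report.perimeter.mean_diff == 0.0
        assert report.dice_mean == 1.0
        assert report.sapien.ratio == 1.0 and report.evolut.ratio == 1.0
        assert report.area.degenerate and report.area.wilcoxon_p == 1.0

    def test_order_invariance(self, charts):
        rng = np.random.default_rng(9)
        truths = self._cases(rng)
        jittered = {
            k: CohortCase(c.area * 1.01, c.perimeter * 1.005, c.mask)
            for k, c in truths.items()
        }
        r1 = evaluate_cohort(jittered, truths, charts)
        shuffled = dict(reversed(list(jittered.items())))
        r2 = evaluate_cohort(shuffled, truths, charts)
        assert r1.area == r2.area and r1.perimeter == r2.perimeter
        assert r1.sapien.ratio == r2.sapien.ratio

    def test_unmatched_ids_listed(self, charts):
        rng = np.random.default_rng(10)
        truths = self._cases(rng)
        detections = dict(truths)
        detections["extra"] = CohortCase(400.0, 75.0)
        with pytest.raises(ValidationError, match="extra"):
            evaluate_cohort(detections, truths, charts)

    def test_report_fields_finite_and_bounded(self, charts):
        rng = np.random.default_rng(11)
        truths = self._cases(rng, with_masks=False)
        jittered = {
            k: CohortCase(c.area + rng.normal(0, 5), c.perimeter + rng.normal(0, 0.5))
            for k, c in truths.items()
        }
        report = evaluate_cohort(jittered, truths, charts)
        for rep in (report.area, report.perimeter):
            assert rep.loa_low <= rep.mean_diff <= rep.loa_high
            assert -1 <= rep.pearson_r <= 1
            assert 0 <= rep.wilcoxon_p <= 1
        assert report.dice_mean is None


def test_agreement_report_composition():
    rng = np.random.default_rng(12)
    a = rng.normal(450, 40, size=20)
    b = a + rng.normal(2, 10, size=20)
    rep = agreement_report(PairedSeries(a, b))
    ba = bland_altman(PairedSeries(a, b))
    assert rep.mean_diff == pytest.approx(ba.bias)
    assert rep.loa_low == pytest.approx(ba.loa_low)
    assert rep.n == 20
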