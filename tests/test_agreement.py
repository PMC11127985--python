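"""Agreement and classification statistics vs independent oracles."""

import numpy as np
import pytest
from scipy import special, stats

from liverroi import (
    PairedReadings,
    agreement_report,
    bland_altman,
    classification_performance,
    error_and_correlation,
    icc_absolute_single,
    ks_compare,
)


def _pairs(method, reference):
    method = np.asarray(method, float)
    return PairedReadings(list(range(len(method))), method, np.asarray(reference, float))


class TestKS:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = ks_compare(a, a)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ks_compare([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert stat == 1.0

    def test_asymptotic_p_matches_kolmogorov_series(self):
        # oracle: explicit ECDF sup + the alternating Kolmogorov series
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0, 1, 100)
        stat, p = ks_compare(a, b)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        stat_oracle = np.abs(ecdf_a - ecdf_b).max()
        x = np.sqrt(len(a) * len(b) / (len(a) + len(b))) * stat_oracle
        p_oracle = 2 * sum((-1) ** (k - 1) * np.exp(-2 * k**2 * x**2) for k in range(1, 101))
        assert stat == pytest.approx(stat_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([1.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_readings(self):
        p = _pairs([50.0, 55.0, 60.0], [50.0, 55.0, 60.0])
        assert bland_altman(p) == (0.0, 0.0, 0.0)

    def test_two_point_loa(self):
        # diffs {-2, +2}: LOA = 0 +/- 1.96 * sqrt(8)
        p = _pairs([48.0, 62.0], [50.0, 60.0])
        mean_diff, lo, hi = bland_altman(p)
        expected = 1.96 * np.sqrt(8.0)
        assert mean_diff == 0.0
        assert lo == pytest.approx(-expected)
        assert hi == pytest.approx(expected)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(55, 10, 30)
        meth = ref + rng.normal(0, 2, 30)
        base = bland_altman(_pairs(meth, ref))
        shifted = bland_altman(_pairs(meth + 7.5, ref))
        assert shifted == pytest.approx(tuple(v + 7.5 for v in base))


class TestErrorAndCorrelation:
    def test_mae_mse_arithmetic(self):
        p = _pairs([51.0, 63.0], [50.0, 60.0])  # diffs {1, 3}
        mae, mse, _ = error_and_correlation(p)
        assert mae == 2.0
        assert mse == 5.0

    def test_monotone_rho(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert error_and_correlation(_pairs(x, x ** 3))[2] == pytest.approx(1.0)
        assert error_and_correlation(_pairs(x, -(x ** 3)))[2] == pytest.approx(-1.0)

    def test_tied_ranks_match_brute_force(self):
        method = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        ref = np.array([2.0, 1.0, 4.0, 4.0, 6.0])

        def ranks(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
                i = j + 1
            return r

        rho_oracle = np.corrcoef(ranks(method), ranks(ref))[0, 1]
        _, _, rho = error_and_correlation(_pairs(method, ref))
        assert rho == pytest.approx(rho_oracle, abs=1e-12)


def icc2_sums_of_squares_oracle(x):
    """Direct two-way ANOVA decomposition, written out longhand."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.array([50.0, 55.0, 60.0, 45.0, 52.0, 58.0])
        x = np.column_stack([col, col])
        icc, lo, hi = icc_absolute_single(x)
        assert icc == pytest.approx(1.0)
        assert lo <= icc <= hi + 1e-12

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 2))
        icc, _, _ = icc_absolute_single(x)
        assert abs(icc) < 3 / np.sqrt(200)

    def test_toy_matrix_matches_sums_of_squares_oracle(self):
        x = np.array([[9.0, 2.0], [6.0, 1.0], [8.0, 4.0], [7.0, 1.0], [10.0, 5.0], [6.0, 2.0]])
        icc, _, _ = icc_absolute_single(x)
        assert icc == pytest.approx(icc2_sums_of_squares_oracle(x), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pingouin_reference(self, seed):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        k = int(rng.integers(2, 6))
        subj = rng.normal(0, 5, size=(n, 1))
        x = 50 + subj + rng.normal(0, 2, size=(n, k)) + rng.normal(0, 1, size=(1, k))
        icc, lo, hi = icc_absolute_single(x)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        assert (lo, hi) == pytest.approx(tuple(row[ci_col]), abs=0.01)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="ICC"):
            icc_absolute_single(np.full((6, 2), 5.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_single(np.random.default_rng(0).normal(size=(4, 2)))


def auc_all_pairs_oracle(scores, labels):
    """Exhaustive concordance count on negated scores, with tie credit."""
    pos = [-s for s, l in zip(scores, labels) if l]
    neg = [-s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestClassification:
    def test_perfect_separation(self):
        rep = classification_performance([30.0, 35.0, 55.0, 60.0], [1, 1, 0, 0], n_boot=50, seed=0)
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0

    def test_threshold_confusion_counts(self):
        rep = classification_performance([35.0, 38.0, 45.0, 50.0], [1, 1, 0, 0],
                                         threshold_hu=40.0, n_boot=10, seed=0)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 0, 2, 0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_auc_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.normal(50, 10, 120), 0)  # rounding forces ties
        labels = rng.random(120) < 0.3
        labels[:2] = [True, False]
        rep = classification_performance(scores, labels, n_boot=0, seed=0)
        assert rep.auc == pytest.approx(auc_all_pairs_oracle(scores, labels), abs=1e-12)

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(50, 10, 500)
        labels = np.zeros(500, dtype=bool)
        labels[:250] = True
        rng.shuffle(labels)
        rep = classification_performance(scores, labels, n_boot=0, seed=0)
        n1 = n0 = 250
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(rep.auc - 0.5) < 3 * se

    def test_bootstrap_ci_contains_point_and_shrinks(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (50, 200, 800):
            scores = np.concatenate([rng.normal(35, 5, n // 4), rng.normal(55, 8, 3 * n // 4)])
            labels = np.concatenate([np.ones(n // 4, bool), np.zeros(3 * n // 4, bool)])
            rep = classification_performance(scores, labels, n_boot=300, seed=1)
            assert rep.auc_ci[0] - 1e-12 <= rep.auc <= rep.auc_ci[1] + 1e-12
            assert rep.sens_ci[0] <= rep.sensitivity <= rep.sens_ci[1]
            assert rep.spec_ci[0] <= rep.specificity <= rep.spec_ci[1]
            widths.append(rep.auc_ci[1] - rep.auc_ci[0])
        assert widths[0] > widths[2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_performance([30.0, 35.0], [1, 1], n_boot=10, seed=0)

    def test_bootstrap_deterministic_for_seed(self):
        scores = np.random.default_rng(9).normal(45, 10, 60)
        labels = scores < 42
        labels[0] = ~labels[0]
        r1 = classification_performance(scores, labels, n_boot=200, seed=5)
        r2 = classification_performance(scores, labels, n_boot=200, seed=5)
        assert r1 == r2


class TestAgreementReport:
    def test_report_internal_consistency(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(55, 11, 80)
        meth = ref + rng.normal(0.5, 2.0, 80)
        rep = agreement_report(_pairs(meth, ref))
        assert rep.loa_low_hu <= rep.mean_diff_hu <= rep.loa_high_hu
        assert -1 <= rep.icc <= 1
        assert rep.mae ** 2 <= rep.mse + 1e-12
        assert rep.icc_ci_low <= rep.icc <= rep.icc_ci_high
        assert rep.spearman_rho > 0.9
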