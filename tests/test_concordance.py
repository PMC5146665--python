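"""Concordance screen: correlation, sign test, robust fit, gene decisions."""
import math

import numpy as np
import pytest

from orthowindow.concordance import (
    classify_gene,
    concordance_summary,
    finalize_annotation,
    flag_outliers,
    pearson_r,
    robust_line_fit,
    sign_test,
)
from orthowindow.models import (
    EXCLUDED_LOW_R,
    RETAIN,
    RETAIN_RESCUED,
    DegenerateDataError,
    FilterConfig,
    GeneConcordance,
    InvalidInputError,
)


def enumerate_sign_p(k, n, alternative):
    """Exact Binomial(n, 1/2) tails by direct enumeration."""
    pmf = [math.comb(n, i) / 2**n for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    return min(1.0, 2 * min(lower, upper))


class TestSignTest:
    def test_qpcr_worked_example(self):
        assert sign_test(6, 7, "greater") == 0.0625

    def test_all_successes_two_sided(self):
        assert sign_test(10, 10, "two_sided") == pytest.approx(0.001953125)

    def test_balanced_is_one(self):
        assert sign_test(5, 10, "two_sided") == 1.0

    def test_matches_enumeration_everywhere(self):
        for n in range(1, 21):
            for k in range(n + 1):
                for alt in ("greater", "less", "two_sided"):
                    assert sign_test(k, n, alt) == pytest.approx(
                        enumerate_sign_p(k, n, alt), abs=1e-12
                    )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            sign_test(0, 0)
        with pytest.raises(InvalidInputError):
            sign_test(5, 4)


class TestPearson:
    def test_identity_and_affine(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, 5 * x + 2) == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            expected = cov / (x.std() * y.std())
            assert pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_undefined(self):
        assert pearson_r(np.ones(5), np.arange(5.0)) is None

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            pearson_r(np.ones(4), np.ones(5))


class TestRobustLine:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, scaled = robust_line_fit(x, 2 * x + 1)
        assert slope == pytest.approx(2.0, abs=1e-8)
        assert intercept == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.abs(scaled) < 1e-6)

    def test_clean_data_matches_ols(self, rng):
        """With bounded noise below the Huber threshold the fit is OLS."""
        x = np.linspace(0, 10, 40)
        noise = rng.uniform(0.05, 0.1, size=40) * rng.choice([-1, 1], size=40)
        y = 3 * x + 2 + noise
        slope, intercept, _ = robust_line_fit(x, y)
        ols_slope, ols_intercept = np.polyfit(x, y, 1)
        assert slope == pytest.approx(ols_slope, abs=1e-6)
        assert intercept == pytest.approx(ols_intercept, abs=1e-6)

    def test_gross_outlier_downweighted(self):
        x = np.arange(10.0)
        y = x.copy()
        y[5] = 500.0
        slope, _, scaled = robust_line_fit(x, y)
        assert abs(slope - 1.0) < 0.1
        assert abs(scaled[5]) > 2.5
        assert flag_outliers(scaled) == {5}

    def test_zero_x_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            robust_line_fit(np.ones(5), np.arange(5.0))


class TestFlagOutliers:
    def test_all_zero_residuals(self):
        assert flag_outliers(np.zeros(10)) == set()

    def test_threshold_is_strict(self):
        assert flag_outliers(np.array([0.0, 2.5, -2.5]), 2.5) == set()
        assert flag_outliers(np.array([0.0, 2.6, -2.6]), 2.5) == {1, 2}


class TestClassifyGene:
    def test_high_r_retained(self, rng):
        b = rng.lognormal(0, 1, size=20)
        a = 2 * b + rng.normal(0, 0.01, size=20)
        conc = classify_gene("g", a, b)
        assert conc.pearson_r > 0.4
        assert conc.decision == RETAIN

    def test_low_r_consistent_sign_rescued(self, rng):
        b = rng.lognormal(0, 1, size=15)
        a = rng.permutation(b) + b.max()  # a > b in all 15 windows, r low
        conc = classify_gene("g", a, b)
        assert conc.pearson_r < 0.4
        assert conc.sign_k == conc.sign_n == 15
        assert conc.sign_p == pytest.approx(2 / 2**15)
        assert conc.decision == RETAIN_RESCUED
        assert conc.outlier_windows == frozenset()
        assert len(conc.retained_windows) == 15

    def test_low_r_balanced_signs_excluded(self):
        rng = np.random.default_rng(3)
        b = rng.lognormal(0, 1, size=16)
        a = rng.permutation(b)  # independent-ish, balanced signs
        conc = classify_gene("g", a, b)
        assert conc.decision == EXCLUDED_LOW_R
        assert conc.retained_windows == frozenset()

    def test_scale_invariance(self, rng):
        """The decision is invariant to positive rescaling of either profile."""
        b = rng.lognormal(0, 1, size=20)
        a = 1.5 * b * rng.lognormal(0, 0.1, size=20)
        base = classify_gene("g", a, b)
        scaled = classify_gene("g", a * 37.0, b, FilterConfig())
        assert scaled.decision == base.decision
        assert scaled.retained_windows == base.retained_windows
        assert scaled.pearson_r == pytest.approx(base.pearson_r)

    def test_too_few_windows_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_gene("g", np.ones(3), np.ones(3))

    def test_constant_profiles_excluded_not_crash(self):
        conc = classify_gene("g", np.ones(6), np.ones(6))
        assert conc.decision == EXCLUDED_LOW_R  # r undefined, sign test all ties


def _toy_annotation():
    from test_coverage import _toy_annotation as build

    return build(n_windows=6)


def test_finalize_identity_when_all_retained():
    ann = _toy_annotation()
    conc = GeneConcordance(
        gene_id="p1", n_windows=6, pearson_r=0.9, sign_k=3, sign_n=6, sign_p=1.0,
        decision=RETAIN, retained_windows=frozenset(range(6)),
    )
    final = finalize_annotation(ann, {"p1": conc})
    assert final.pairs["p1"].n_windows == 6


def test_finalize_drops_excluded_gene_and_outlier_windows():
    ann = _toy_annotation()
    conc = GeneConcordance(
        gene_id="p1", n_windows=6, pearson_r=0.9, sign_k=3, sign_n=6, sign_p=1.0,
        outlier_windows=frozenset({2}), decision=RETAIN,
        retained_windows=frozenset({0, 1, 3, 4, 5}),
    )
    final = finalize_annotation(ann, {"p1": conc})
    pann = final.pairs["p1"]
    assert pann.n_windows == 5
    assert {w.window_index for w in pann.windows} == {0, 1, 3, 4, 5}
    # both species lose the same window
    assert all(w.genomic_a.window_index == w.genomic_b.window_index for w in pann.windows)

    excluded = GeneConcordance(
        gene_id="p1", n_windows=6, pearson_r=0.1, sign_k=3, sign_n=6, sign_p=1.0,
        decision=EXCLUDED_LOW_R,
    )
    final2 = finalize_annotation(ann, {"p1": excluded})
    assert "p1" not in final2.pairs


def test_finalize_missing_concordance_is_error():
    ann = _toy_annotation()
    with pytest.raises(InvalidInputError):
        finalize_annotation(ann, {})


def test_summary_counts():
    concs = {
        f"g{i}": GeneConcordance(
            gene_id=f"g{i}", n_windows=5, pearson_r=r, sign_k=0, sign_n=5,
            sign_p=1.0, decision=RETAIN if r > 0.4 else EXCLUDED_LOW_R,
        )
        for i, r in enumerate([0.95, 0.96, 0.2, -0.5])
    }
    counts, edges, tallies = concordance_summary(concs, n_bins=20)
    assert counts.sum() == 4
    assert tallies == {RETAIN: 2, EXCLUDED_LOW_R: 2}
    assert counts[-1] == 2  # both 0.95s in the top bin
    with pytest.raises(InvalidInputError):
        concordance_summary({})


class TestParameterRecovery:
    """Population-level behavior of the full screen on synthetic coverage."""

    def _run(self, tmp_path, **overrides):
        from orthowindow.io import read_samples_tsv, read_windows_tsv
        from orthowindow.pipeline import stage_coverage, stage_filter
        from orthowindow.simulate import SimConfig, make_fixture_dataset

        cfg = SimConfig(
            n_genes=200, seed=31, ancestor_length_range=(500, 1500),
            noise_sigma_log=0.2, bias_window_fraction=0.0, **overrides,
        )
        make_fixture_dataset(cfg, tmp_path)
        ann = read_windows_tsv(tmp_path / "windows.tsv")
        cov = stage_coverage(ann, read_samples_tsv(tmp_path / "samples_coverage.tsv"))
        _, final, report = stage_filter(ann, cov)
        return ann, report

    def test_concordant_genes_retained(self, tmp_path):
        ann, report = self._run(tmp_path / "conc", fraction_discordant=0.0)
        retained = report["decision"].isin([RETAIN, RETAIN_RESCUED])
        assert retained.mean() >= 0.95

    def test_discordant_genes_excluded(self, tmp_path):
        ann, report = self._run(tmp_path / "disc", fraction_discordant=1.0)
        excluded = ~report["decision"].isin([RETAIN, RETAIN_RESCUED])
        assert excluded.mean() >= 0.9
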