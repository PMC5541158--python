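"""Logistic fits, the per-KO screen, Bonferroni control, TCDB flags."""

import numpy as np
import pandas as pd
import pytest

from traitsignal import synthetic_data as syn
from traitsignal.enrichment import (
    EnrichmentResult,
    ScreenConfig,
    annotate_transporters,
    bonferroni_threshold,
    classify_transporter,
    fit_logistic,
    ko_screen,
    marker_table_results,
    packaged_marker_table,
    packaged_tcdb,
    summarize_screen,
)


class TestBonferroni:
    def test_study_family_size(self):
        assert f"{bonferroni_threshold(0.05, 6889):.1e}" == "7.3e-06"

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_models_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _logistic_data(rng, n=300, beta0=0.0, beta1=1.0):
    x = rng.uniform(-2.5, 2.5, size=n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n) < p).astype(float)
    return y, x


class TestFitLogistic:
    def test_agrees_with_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            y, x = _logistic_data(rng, n=120, beta1=rng.uniform(-1.5, 1.5))
            if y.min() == y.max():
                continue
            fit = fit_logistic(y, x)
            ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-6)
            assert fit.p_value == pytest.approx(ref.pvalues[1], rel=1e-4)

    def test_perfect_separation_flagged(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(float)
        fit = fit_logistic(y, x)
        assert fit.separated
        assert not fit.converged
        assert np.isnan(fit.p_value)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(10), np.arange(10.0))

    def test_constant_x_errors(self):
        y = np.array([0.0, 1.0] * 5)
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(y, np.ones(10))

    def test_sign_invariance(self, rng):
        y, x = _logistic_data(rng, n=200, beta1=0.8)
        f1 = fit_logistic(y, x)
        f2 = fit_logistic(y, -x)
        assert f1.beta1 == pytest.approx(-f2.beta1, abs=1e-9)
        assert f1.p_value == pytest.approx(f2.p_value, abs=1e-9)

    def test_lr_and_wald_agree_on_calls(self, rng):
        # the two tests are asymptotically equivalent; at n=400 they must
        # agree on rejection at alpha=0.05 for clear effects and clear nulls
        for beta1 in (0.0, 0.8):
            for _ in range(5):
                y, x = _logistic_data(rng, n=400, beta1=beta1)
                pw = fit_logistic(y, x, test="wald").p_value
                pl = fit_logistic(y, x, test="lr").p_value
                assert np.isfinite(pl) and 0.0 <= pl <= 1.0
                if min(pw, pl) < 0.01 or max(pw, pl) > 0.2:
                    assert (pw < 0.05) == (pl < 0.05)

    def test_planted_slope_inside_own_wald_interval(self):
        # ~95% coverage of the true slope; fixed seeds keep this exact
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            r = np.random.default_rng(1000 + i)
            x = r.uniform(4, 9, size=400)
            xc = x - 6.5
            p = 1.0 / (1.0 + np.exp(-2.0 * xc))
            y = (r.random(400) < p).astype(float)
            fit = fit_logistic(y, xc)
            if not fit.converged:
                continue
            lo, hi = fit.beta1 - 1.96 * fit.se1, fit.beta1 + 1.96 * fit.se1
            hits += int(lo <= 2.0 <= hi)
        assert hits >= 88  # 95% nominal, wide slack for binomial noise


class TestKoScreen:
    def _optima(self, n=200, seed=0):
        r = np.random.default_rng(seed)
        return pd.Series(r.uniform(4, 9, n), index=[f"S{i:04d}" for i in range(n)])

    def test_constant_ko_untestable_and_excluded_from_m(self):
        opt = self._optima(60, seed=1)
        mat, _ = syn.simulate_ko_matrix(opt, n_kos=10, n_planted=0, seed=2)
        mat["K11111"] = 1  # present everywhere
        results = ko_screen(mat, opt, ScreenConfig())
        by_ko = {r.ko_id: r for r in results}
        assert by_ko["K11111"].reason.startswith("untestable")
        tested = [r for r in results if not r.reason]
        assert len(tested) <= 10

    def test_results_invariant_to_row_and_column_order(self):
        opt = self._optima(80, seed=3)
        mat, _ = syn.simulate_ko_matrix(opt, n_kos=12, n_planted=2, seed=4)
        res_a = {r.ko_id: r.p_value for r in ko_screen(mat, opt, ScreenConfig())}
        shuffled = mat.iloc[::-1, ::-1]
        res_b = {
            r.ko_id: r.p_value
            for r in ko_screen(shuffled, opt.iloc[::-1], ScreenConfig())
        }
        assert set(res_a) == set(res_b)
        for ko in res_a:
            if np.isnan(res_a[ko]):
                assert np.isnan(res_b[ko])
            else:
                assert res_a[ko] == pytest.approx(res_b[ko], abs=1e-9)

    def test_listwise_deletion_of_missing_optima(self):
        opt = self._optima(100, seed=5)
        mat, _ = syn.simulate_ko_matrix(opt, n_kos=8, n_planted=0, seed=6)
        opt_missing = opt.copy()
        opt_missing.iloc[:30] = np.nan
        results = ko_screen(mat, opt_missing, ScreenConfig())
        assert all(r.reason or r.p_value >= 0 for r in results)

    def test_no_testable_kos_errors(self):
        opt = self._optima(20, seed=7)
        mat = pd.DataFrame({"K00001": 1}, index=opt.index)
        with pytest.raises(ValueError, match="testable"):
            ko_screen(mat, opt, ScreenConfig())

    def test_m_override_changes_cutoff(self):
        opt = self._optima(150, seed=8)
        mat, truth = syn.simulate_ko_matrix(
            opt, n_kos=5, n_planted=5, beta1=1.0, seed=9
        )
        loose = ko_screen(mat, opt, ScreenConfig(m=1))
        strict = ko_screen(mat, opt, ScreenConfig(m=10**9))
        assert sum(r.significant for r in loose) >= sum(
            r.significant for r in strict
        )
        assert not any(r.significant for r in strict)


class TestTransporters:
    def test_reference_markers(self):
        tcdb = packaged_tcdb()
        assert classify_transporter("K01546", tcdb) is True
        assert classify_transporter("K08677", tcdb) is False
        assert classify_transporter("K99999", tcdb) is False

    def test_malformed_ko_id(self):
        with pytest.raises(ValueError, match="malformed"):
            classify_transporter("X123", set())

    def test_snapshot_agrees_with_marker_table_flags(self):
        table = packaged_marker_table()
        tcdb = packaged_tcdb()
        for row in table.itertuples(index=False):
            assert classify_transporter(row.ko_id, tcdb) == (row.tcdb == "Yes")


class TestSummarizeScreen:
    def test_marker_reference_counts(self):
        out = summarize_screen(marker_table_results()).set_index("trait")
        assert out.loc["ph", "n_enriched"] == 33
        assert out.loc["ph", "n_transporter"] == 26
        assert out.loc["ph", "pct_transporter"] == 79
        assert out.loc["salinity", "n_enriched"] == 14
        assert out.loc["salinity", "n_transporter"] == 9
        assert out.loc["salinity", "pct_transporter"] == 64

    def test_empty_results(self):
        assert summarize_screen([]).empty

    def test_rounding_two_thirds(self):
        results = [
            EnrichmentResult("K00001", "ph", "+", 1e-9, True, transporter=True),
            EnrichmentResult("K00002", "ph", "+", 1e-9, True, transporter=True),
            EnrichmentResult("K00003", "ph", "-", 1e-9, True, transporter=False),
        ]
        out = summarize_screen(results)
        assert out.pct_transporter.iloc[0] == 67

    def test_annotate_transporters_fills_flags(self):
        results = [EnrichmentResult("K01546", "ph", "-", 1e-9, True)]
        out = annotate_transporters(results, packaged_tcdb())
        assert out[0].transporter is True
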