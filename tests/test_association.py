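"""Logistic association, omnibus LRT, ranked scans, heterogeneity."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from hlafinemap import (
    ContingencyTable2x2,
    fit_logistic,
    heterogeneity,
    odds_ratio,
    omnibus_position_test,
    scan,
)
from hlafinemap.association import AliasingWarning


def carrier_vectors(a, b, c, d):
    """0/1 exposure and phenotype vectors realising a 2x2 carrier table."""
    y = np.array([1] * (a + b) + [0] * (c + d))
    x = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return y, x


class TestFitLogistic:
    def test_saturated_fit_equals_cross_product_or(self):
        # the KIR3DS1 carrier row: 185/397 cases vs 92/282 controls
        y, x = carrier_vectors(185, 212, 92, 190)
        res = fit_logistic(y, pd.Series(x, name="KIR3DS1"))
        assert res.or_ == pytest.approx((185 * 190) / (212 * 92), rel=1e-9)
        assert round(res.or_, 2) == 1.80
        assert res.ci95[0] < res.or_ < res.ci95[1]

    def test_matches_contingency_or_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(5, 80, size=4)
            y, x = carrier_vectors(a, b, c, d)
            res = fit_logistic(y, pd.Series(x, name="t"))
            or_, _ = odds_ratio(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert res.or_ == pytest.approx(or_, rel=1e-6)

    def test_zero_variance_term_errors(self):
        y = np.array([0, 1] * 20)
        with pytest.raises(ValueError, match="zero variance"):
            fit_logistic(y, np.ones(40))

    def test_recovers_planted_effect(self):
        beta_true, estimates = 0.8, []
        rng = np.random.default_rng(77)
        for _ in range(10):
            x = rng.binomial(2, 0.3, size=5000).astype(float)
            p = 1 / (1 + np.exp(-(-1.0 + beta_true * x)))
            y = rng.binomial(1, p)
            estimates.append(fit_logistic(y, pd.Series(x, name="g")).beta)
        assert abs(np.mean(estimates) - beta_true) < 0.05

    def test_collinear_condition_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.binomial(2, 0.3, 400).astype(float), name="x")
        y = rng.binomial(1, 0.4, 400)
        with pytest.warns(AliasingWarning):
            res = fit_logistic(y, x, condition=[x.rename("dup")])
        assert np.isfinite(res.p)

    def test_separation_flagged_not_silent(self):
        y = np.array([1] * 20 + [0] * 20)
        x = pd.Series(y.astype(float), name="sep")  # perfect separation
        res = fit_logistic(y, x)
        assert res.unstable

    def test_missing_dosages_dropped(self):
        rng = np.random.default_rng(8)
        x = pd.Series(rng.binomial(2, 0.3, 300).astype(float), name="x")
        x.iloc[:30] = np.nan
        y = pd.Series(rng.binomial(1, 0.5, 300), index=x.index)
        res = fit_logistic(y, x)
        assert res.n_cases + res.n_controls == 270


class TestOmnibus:
    @staticmethod
    def _position(rng, n=600, k=3, betas=(0.0, 0.0)):
        """Residue dosage columns at one position: two alleles per subject
        drawn over k residues; betas apply to the first k-1 residues."""
        probs = np.ones(k) / k
        a1 = rng.choice(k, size=n, p=probs)
        a2 = rng.choice(k, size=n, p=probs)
        cols = np.zeros((n, k))
        for j in range(k):
            cols[:, j] = (a1 == j).astype(float) + (a2 == j).astype(float)
        eta = -0.3 + sum(betas[j] * cols[:, j] for j in range(len(betas)))
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame(cols, columns=[f"r{j}" for j in range(k)])
        return y, df

    def test_biallelic_position_equals_single_term_lrt(self, rng):
        y, cols = self._position(rng, k=2, betas=(0.6,))
        p_omni, df = omnibus_position_test(y, cols)
        assert df == 1
        # direct single-term LRT
        import statsmodels.api as sm

        X = sm.add_constant(cols.iloc[:, [1]])
        full = sm.Logit(y, X).fit(disp=0)
        null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        p_direct = st.chi2.sf(2 * (full.llf - null.llf), 1)
        assert p_omni == pytest.approx(p_direct, rel=1e-6)

    def test_reference_residue_choice_is_irrelevant(self, rng):
        y, cols = self._position(rng, k=3, betas=(0.5, -0.2))
        ps = []
        for ref in range(3):
            order = [c for j, c in enumerate(cols.columns) if j != ref]
            ps.append(omnibus_position_test(y, cols[[cols.columns[ref]] + order])[0])
        assert max(ps) - min(ps) < 1e-8

    def test_causal_position_beats_null_residue_wald(self, rng):
        y, cols = self._position(rng, n=1500, k=3, betas=(0.7, 0.0))
        p_omni, _ = omnibus_position_test(y, cols)
        p_null_residue = fit_logistic(y, cols["r1"]).p
        assert p_omni < p_null_residue

    def test_single_column_directs_to_fit_logistic(self, rng):
        y, cols = self._position(rng, k=2)
        with pytest.raises(ValueError, match="fit_logistic"):
            omnibus_position_test(y, cols.iloc[:, :1])

    def test_wald_lrt_agree_within_factor_two(self, rng):
        y, cols = self._position(rng, n=1200, k=2, betas=(0.4,))
        p_omni, _ = omnibus_position_test(y, cols)
        p_wald = fit_logistic(y, cols.iloc[:, 1]).p
        assert 0.5 < (p_wald / p_omni) < 2.0


class TestScan:
    def test_planted_effect_ranks_first(self, rng):
        hits = 0
        for _ in range(20):
            n = 800
            cols = pd.DataFrame(
                {f"t{j}": rng.binomial(2, 0.25, n).astype(float) for j in range(12)}
            )
            eta = -0.4 + 0.8 * cols["t0"]
            y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
            if scan(y, cols)[0].term == "t0":
                hits += 1
        assert hits >= 19

    def test_empty_column_set_gives_empty_list(self):
        assert scan(np.array([0, 1, 0, 1]), pd.DataFrame(index=range(4))) == []

    def test_ordering_deterministic(self, rng):
        n = 300
        cols = pd.DataFrame({f"t{j}": rng.binomial(2, 0.3, n).astype(float) for j in range(6)})
        y = rng.binomial(1, 0.5, n)
        r1 = [r.term for r in scan(y, cols)]
        r2 = [r.term for r in scan(y, cols)]
        assert r1 == r2


class TestHeterogeneity:
    def test_identical_betas_give_zero(self):
        h = heterogeneity([(0.5, 0.1), (0.5, 0.2), (0.5, 0.15)])
        assert h.q == pytest.approx(0.0, abs=1e-12)
        assert h.i2 == 0.0

    def test_closed_form_three_cohorts(self):
        h = heterogeneity([(0.5, 0.1), (0.5, 0.1), (1.5, 0.1)])
        assert h.q == pytest.approx(200 / 3, rel=1e-12)
        assert h.i2 == pytest.approx((h.q - 2) / h.q * 100, rel=1e-12)
        assert h.i2 == pytest.approx(97.0, abs=0.01)

    def test_matches_statsmodels_fixed_effect(self):
        from statsmodels.stats.meta_analysis import combine_effects

        betas, ses = [0.2, 0.7, 0.4, 1.1], [0.15, 0.3, 0.2, 0.5]
        h = heterogeneity(list(zip(betas, ses)))
        res = combine_effects(np.array(betas), np.array(ses) ** 2)
        assert h.q == pytest.approx(float(res.q), rel=1e-10)
        assert h.i2 / 100 == pytest.approx(float(res.i2), rel=1e-8)
        assert h.pooled_beta == pytest.approx(float(res.mean_effect_fe), rel=1e-10)

    def test_single_cohort_errors(self):
        with pytest.raises(ValueError, match="2"):
            heterogeneity([(0.5, 0.1)])

    def test_i2_bounded(self):
        h = heterogeneity([(0.1, 0.5), (0.12, 0.5), (0.08, 0.5)])
        assert 0.0 <= h.i2 <= 100.0
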