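"""Logistic/linear association, Firth fallback, FDR, crude OR and SNP tagging."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cnvresp.assoc import (
    assoc_segment_linear,
    assoc_segment_logistic,
    bh_fdr,
    build_covariate_design,
    crude_or,
    firth_logistic,
    fit_logistic,
    snp_cnv_r2,
)

from _oracles import bh_brute_force, irls_logistic


def _labels(y: np.ndarray, delta_cdai: np.ndarray | None = None) -> pd.DataFrame:
    n = y.shape[0]
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "das28_baseline": rng.normal(6.2, 0.9, n),
            "cdai_baseline": rng.normal(33, 10, n),
            "delta_cdai": delta_cdai if delta_cdai is not None else rng.normal(15, 8, n),
            "eular_class": np.where(y == 1, "none", "moderate"),
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        X = pd.DataFrame({"intercept": np.ones(100)})
        fit = fit_logistic(y, X)
        assert fit.beta[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)

    def test_matches_textbook_irls(self):
        """statsmodels-backed fit equals hand-rolled IRLS on 50 random datasets."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = 80
            X = pd.DataFrame(
                {
                    "intercept": np.ones(n),
                    "x1": rng.normal(size=n),
                    "x2": rng.binomial(1, 0.4, n).astype(float),
                }
            )
            eta = -0.5 + 0.8 * X["x1"] - 0.6 * X["x2"]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() in (0, n):
                continue
            fit = fit_logistic(y, X)
            ref = irls_logistic(y, X.to_numpy())
            assert np.abs(fit.beta - ref).max() < 1e-6

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"intercept": np.ones(30), "a": np.arange(30.0)})
        X["b"] = 2 * X["a"]
        y = np.array([0.0, 1.0] * 15)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(y, X)

    def test_separation_triggers_firth_and_stays_finite(self):
        n = 40
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()  # complete separation
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_logistic(y, X)
        assert fit.method == "firth"
        assert np.all(np.isfinite(fit.beta)) and np.all(np.isfinite(fit.se))

    def test_firth_shrinks_relative_to_mle_direction(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.binomial(1, 0.3, n).astype(float)
        y = rng.binomial(1, np.where(x == 1, 0.8, 0.3)).astype(float)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        mle = fit_logistic(y, X)
        fir = firth_logistic(y, X)
        assert abs(fir.beta[1]) < abs(mle.beta[1]) + 0.5  # penalized toward zero


class TestSegmentLogistic:
    def test_covariate_free_fit_equals_crude_or(self):
        """With a saturated binary predictor and no covariates the model OR is
        the contingency-table cross-product ratio."""
        # carriers: 12 cases / 18 controls; non-carriers: 20 / 150
        y = np.array([1.0] * 12 + [0.0] * 18 + [1.0] * 20 + [0.0] * 150)
        cn = np.array([1] * 30 + [2] * 170)
        labels = _labels(y)
        res = assoc_segment_logistic(pd.Series(cn, index=labels.index), labels)
        want = crude_or(12, 20, 18, 150)
        assert res.or_ == pytest.approx(want.or_, rel=1e-6)
        assert res.method == "mle"
        assert res.ci_low < res.beta < res.ci_high

    def test_degenerate_predictor_rejected(self):
        y = np.array([1.0] * 5 + [0.0] * 45)
        labels = _labels(y)
        cn = pd.Series(np.full(50, 2), index=labels.index)
        with pytest.raises(ValueError, match="degenerate predictor"):
            assoc_segment_logistic(cn, labels)

    def test_duplication_carriers_count_as_reference(self):
        y = np.array([1.0] * 10 + [0.0] * 90)
        labels = _labels(y)
        cn = np.full(100, 2)
        cn[:20] = 1
        cn[95:] = 3  # duplications -> reference class under deletion coding
        res = assoc_segment_logistic(pd.Series(cn, index=labels.index), labels)
        assert res.n_carriers == 20 and res.coding == "deletion_carrier"

    def test_sparse_cells_switch_to_firth(self):
        y = np.array([1.0] * 3 + [0.0] * 197)
        cn = np.full(200, 2)
        cn[:10] = 1
        labels = _labels(y)
        res = assoc_segment_logistic(pd.Series(cn, index=labels.index), labels)
        assert res.method == "firth"


class TestSegmentLinear:
    def test_exact_linear_outcome_recovers_coefficient(self):
        n = 120
        cn = np.array([1] * 30 + [2] * 90)
        carrier = (cn <= 1).astype(float)
        delta = 10.0 + 5.0 * carrier
        labels = _labels(np.zeros(n), delta_cdai=delta)
        res = assoc_segment_linear(pd.Series(cn, index=labels.index), labels)
        assert res.beta == pytest.approx(5.0, abs=1e-8)
        assert res.p_value < 1e-12

    def test_orientation_flip_negates_beta_only(self):
        rng = np.random.default_rng(5)
        n = 150
        cn = np.where(rng.random(n) < 0.2, 1, 2)
        delta = rng.normal(12, 6, n) - 3.0 * (cn == 1)
        labels = _labels(np.zeros(n), delta_cdai=delta)
        col = pd.Series(cn, index=labels.index)
        a = assoc_segment_linear(col, labels, orientation="improvement")
        b = assoc_segment_linear(col, labels, orientation="worsening")
        assert b.beta == pytest.approx(-a.beta, rel=1e-9)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-9)

    def test_null_coverage_under_permutation(self):
        """Carrier CI covers zero in >= 94% of label permutations."""
        rng = np.random.default_rng(8)
        n = 200
        delta = rng.normal(12, 6, n)
        labels = _labels(np.zeros(n), delta_cdai=delta)
        base = np.array([1] * 20 + [2] * 180)
        covered = 0
        reps = 500
        for _ in range(reps):
            cn = pd.Series(rng.permutation(base), index=labels.index)
            res = assoc_segment_linear(cn, labels)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered / reps >= 0.94


class TestBhFdr:
    def test_uniformly_small_p_all_significant(self):
        flags, adj = bh_fdr(np.full(10, 0.01), q=0.05)
        assert flags.all() and np.allclose(adj, 0.01)

    def test_hand_stepped_example(self):
        flags, adj = bh_fdr([0.001, 0.01, 0.02, 0.9], q=0.05)
        assert flags.tolist() == [True, True, True, False]
        assert adj[0] == pytest.approx(0.004)

    def test_single_p_unchanged(self):
        flags, adj = bh_fdr([0.049], q=0.05)
        assert flags.tolist() == [True] and adj[0] == pytest.approx(0.049)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
        st.floats(0.01, 0.2),
    )
    def test_matches_brute_force_definition(self, ps, q):
        flags, _ = bh_fdr(ps, q=q)
        assert flags.tolist() == bh_brute_force(np.array(ps), q).tolist()


class TestCrudeOr:
    def test_unit_table(self):
        assert crude_or(1, 1, 1, 1).or_ == pytest.approx(1.0)

    def test_published_carrier_table(self):
        """7/32 carrier non-responders vs 13/325 carrier responders."""
        res = crude_or(7, 25, 13, 312)
        assert res.or_ == pytest.approx(6.72, abs=0.01)
        assert not res.corrected
        assert res.ci_low < res.or_ < res.ci_high

    def test_zero_cell_corrected(self):
        res = crude_or(5, 10, 0, 20)
        assert res.corrected and np.isfinite(res.or_)


class TestSnpTagging:
    @staticmethod
    def _frame(cols: dict[str, np.ndarray]) -> pd.DataFrame:
        n = len(next(iter(cols.values())))
        return pd.DataFrame(cols, index=pd.Index([f"S{i}" for i in range(n)]))

    def test_identical_dosage_r2_one(self):
        dd = pd.Series([0, 1, 2, 1, 0, 1], index=[f"S{i}" for i in range(6)])
        snps = self._frame({"rs1": dd.to_numpy()})
        (res,) = snp_cnv_r2(snps, pd.Series({"rs1": 500}), dd, "seg", 400, 600)
        assert res.r2 == pytest.approx(1.0)

    def test_monomorphic_snp_flagged_zero(self):
        dd = pd.Series([0, 1, 2, 1], index=[f"S{i}" for i in range(4)])
        snps = self._frame({"rs1": np.zeros(4)})
        (res,) = snp_cnv_r2(snps, pd.Series({"rs1": 500}), dd, "seg", 400, 600)
        assert res.r2 == 0.0 and res.monomorphic

    def test_snp_outside_window_ignored(self):
        dd = pd.Series([0, 1, 2, 1], index=[f"S{i}" for i in range(4)])
        snps = self._frame({"rs_far": np.array([0, 1, 0, 1])})
        out = snp_cnv_r2(snps, pd.Series({"rs_far": 5_000_000}), dd, "seg", 400, 600,
                         window=1_000_000)
        assert out == []

    def test_independent_snp_null_expectation(self):
        """E[r^2] for an unlinked SNP is ~1/(n-1)."""
        rng = np.random.default_rng(21)
        n = 357
        dd = pd.Series(rng.binomial(1, 0.056, n), index=[f"S{i}" for i in range(n)])
        cols = {f"rs{j}": rng.binomial(2, 0.3, n) for j in range(400)}
        snps = self._frame(cols)
        pos = pd.Series({f"rs{j}": 1000 + j for j in range(400)})
        out = snp_cnv_r2(snps, pos, dd, "seg", 900, 1500)
        mean_r2 = np.mean([r.r2 for r in out])
        assert mean_r2 == pytest.approx(1 / (n - 1), rel=0.35)


class TestCovariateDesign:
    def test_drug_reference_coding(self):
        cov = pd.DataFrame(
            {
                "bmi": [22.0, 25.0], "sex": [1, 0],
                "drug": ["etanercept", "adalimumab"], "mtx": [1, 0],
                "pc1": [0.1, -0.2], "pc2": [0.0, 0.3],
            },
            index=["S0", "S1"],
        )
        X = build_covariate_design(cov, n_pcs=1)
        # only drug categories observed in the cohort yield indicators
        assert list(X.columns) == ["bmi", "sex", "mtx", "drug_adalimumab", "pc1"]
        assert X.loc["S1", "drug_adalimumab"] == 1.0
        assert X.loc["S0", "drug_adalimumab"] == 0.0

    def test_unknown_drug_rejected(self):
        cov = pd.DataFrame(
            {"bmi": [22.0], "sex": [1], "drug": ["aspirin"], "mtx": [0]}, index=["S0"]
        )
        with pytest.raises(ValueError, match="unknown drug"):
            build_covariate_design(cov)
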