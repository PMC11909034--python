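"""OLS fits, variance moderation, contrasts, FDR and DEP calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfmark.core import ValidationError
from csfmark.diffexpr import (
    PairwiseModeratedTest,
    adjust_fdr,
    bh_adjust,
    call_deps,
    fit_protein_models,
    moderate_variances,
    test_contrasts,
)
from conftest import make_matrix, make_meta


def toy_fit(values, patients, tps, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    meta = make_meta(samples, patients, tps)
    m = make_matrix(values, scale="vst", samples=samples)
    return fit_protein_models(m, meta), m, meta


def brute_force_bh(p):
    """Step-up definition computed directly."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


class TestProteinFits:
    def test_hand_computable_two_by_two(self):
        # patients A, B at months 0 and 2; y = [0, 1, 2, 3]
        fits, _, _ = toy_fit([0.0, 1.0, 2.0, 3.0], ["A", "A", "B", "B"], [0, 2, 0, 2])
        # per-patient change is +1 at month 2; patient B sits +2 above A
        assert fits.coef.loc["P0", "tp2"] - fits.coef.loc["P0", "tp0"] == pytest.approx(1.0)
        assert fits.coef.loc["P0", "patient[B]"] == pytest.approx(2.0)
        assert fits.sigma2.loc["P0"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n_pat, n_tp = int(rng.integers(2, 5)), int(rng.integers(2, 4))
            schedule = (0, 2, 10, 18)[:n_tp]
            patients = [f"p{i}" for i in range(n_pat) for _ in schedule]
            tps = list(schedule) * n_pat
            vals = rng.normal(0, 1, (3, len(patients)))
            fits, _, _ = toy_fit(vals, patients, tps)
            # independent oracle: lstsq on an independently built design
            D = np.column_stack(
                [[1.0 * (t == u) for t in tps] for u in schedule]
                + [[1.0 * (p == q) for p in patients] for q in sorted(set(patients))[1:]]
            )
            for g in range(3):
                beta, res, *_ = np.linalg.lstsq(D, vals[g], rcond=None)
                np.testing.assert_allclose(fits.coef.iloc[g].to_numpy(), beta, atol=1e-10)

    def test_noise_free_effect_recovered_exactly(self):
        patients = ["A", "A", "B", "B", "C", "C"]
        tps = [0, 10, 0, 10, 0, 10]
        vals = [[5.0, 6.0, 7.0, 8.0, 3.0, 4.0]]  # +1 at month 10 for everyone
        fits, _, _ = toy_fit(vals, patients, tps)
        assert fits.coef.loc["P0", "tp10"] - fits.coef.loc["P0", "tp0"] == pytest.approx(1.0)
        assert fits.sigma2.loc["P0"] == pytest.approx(0.0, abs=1e-20)

    def test_sample_order_invariance(self, rng):
        patients = ["A", "A", "B", "B", "C", "C"]
        tps = [0, 10, 0, 10, 0, 10]
        vals = rng.normal(0, 1, (4, 6))
        fits1, m, meta = toy_fit(vals, patients, tps)
        perm = [3, 0, 5, 1, 4, 2]
        fits2, _, _ = toy_fit(
            vals[:, perm],
            [patients[i] for i in perm],
            [tps[i] for i in perm],
            samples=[f"s{i}" for i in perm],
        )
        pd.testing.assert_frame_equal(fits1.coef, fits2.coef, atol=1e-10)

    def test_incomplete_matrix_rejected(self):
        vals = np.array([[1.0, np.nan, 2.0, 3.0]])
        with pytest.raises(ValidationError):
            toy_fit(vals, ["A", "A", "B", "B"], [0, 2, 0, 2])

    def test_confounded_design_lists_aliased_columns(self):
        with pytest.raises(ValidationError, match="aliased"):
            toy_fit(np.ones((1, 4)), ["A", "A", "B", "B"], [0, 0, 2, 2])


class TestModeration:
    def _random_fits(self, rng, n=200, d=10, equal_var=False):
        patients = [f"p{i}" for i in range(4) for _ in range(4)]
        tps = [0, 2, 10, 18] * 4
        vals = rng.normal(0, 1, (n, 16))
        fits, _, _ = toy_fit(vals, patients, tps)
        if equal_var:
            fits.sigma2[:] = 2.5
        return fits

    def test_equal_variances_gives_classical_t(self, rng):
        fits = self._random_fits(rng, equal_var=True)
        mfit = moderate_variances(fits)
        assert np.isinf(mfit.prior_df)
        assert mfit.prior_var == pytest.approx(2.5)
        table_mod = test_contrasts(mfit)
        table_cls = test_contrasts(moderate_variances(fits, prior_df=0))
        np.testing.assert_allclose(table_mod["t"], table_cls["t"], atol=1e-9)

    def test_zero_prior_df_is_classical(self, rng):
        fits = self._random_fits(rng)
        mfit = moderate_variances(fits, prior_df=0)
        np.testing.assert_allclose(mfit.s2_post, fits.sigma2, atol=0)
        table = test_contrasts(mfit)
        # p-values match a direct t CDF evaluation with d degrees of freedom
        sub = table.iloc[:5]
        c_idx = [fits.design_columns.index("tp2"), fits.design_columns.index("tp0")]
        c = np.zeros(len(fits.design_columns))
        c[c_idx[0]], c[c_idx[1]] = 1.0, -1.0
        v_c = c @ fits.xtx_inv @ c
        for _, row in sub[sub["contrast"] == "m2_vs_m0"].iterrows():
            s2 = fits.sigma2.loc[row["protein"]]
            t_expected = row["log2fc"] / np.sqrt(s2 * v_c)
            p_expected = 2 * stats.t.sf(abs(t_expected), fits.df_resid)
            assert row["t"] == pytest.approx(t_expected, abs=1e-9)
            assert row["p"] == pytest.approx(p_expected, abs=1e-9)

    def test_posterior_between_prior_and_sample(self, rng):
        fits = self._random_fits(rng)
        mfit = moderate_variances(fits)
        s2 = fits.sigma2.to_numpy()
        post = mfit.s2_post.to_numpy()
        lo = np.minimum(s2, mfit.prior_var)
        hi = np.maximum(s2, mfit.prior_var)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


class TestContrasts:
    def test_all_pairwise_contrasts_emitted(self, rng):
        schedule = (0, 2, 10, 18, 26, 34, 42)
        patients = [f"p{i}" for i in range(2) for _ in schedule]
        tps = list(schedule) * 2
        vals = rng.normal(0, 1, (12, 14))
        fits, _, _ = toy_fit(vals, patients, tps)
        table = test_contrasts(moderate_variances(fits))
        assert table["contrast"].nunique() == 21  # C(7, 2)

    def test_zero_estimate_gives_t0_p1(self):
        patients = ["A", "A", "B", "B", "C", "C", "D", "D"]
        tps = [0, 2, 0, 2, 0, 2, 0, 2]
        # per-patient changes +1, -1, +1, -1: contrast estimate cancels to
        # exactly zero while the residual variance stays positive
        vals = np.array([[0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0]])
        fits, _, _ = toy_fit(vals, patients, tps)
        assert fits.sigma2.loc["P0"] > 0
        mfit = moderate_variances(fits, prior_df=0)
        table = test_contrasts(mfit)
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_absent_timepoint_rejected(self, rng):
        patients = ["A", "A", "B", "B"]
        fits, _, _ = toy_fit(rng.normal(0, 1, (12, 4)), patients, [0, 2, 0, 2])
        with pytest.raises(ValidationError, match="10"):
            test_contrasts(moderate_variances(fits), schedule=(0, 2, 10))


class TestFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_scope_per_contrast_vs_global(self):
        table = pd.DataFrame(
            {
                "protein": ["A", "B", "A", "B"],
                "contrast": ["c1", "c1", "c2", "c2"],
                "log2fc": [1.0, 1.0, 1.0, 1.0],
                "t": [1.0] * 4,
                "p": [0.01, 0.04, 0.5, 0.9],
            }
        )
        per = adjust_fdr(table, scope="per_contrast")
        assert per.loc[0, "fdr"] == pytest.approx(0.02)
        glob = adjust_fdr(table, scope="global")
        assert glob.loc[0, "fdr"] == pytest.approx(0.04)


class TestDEPCalling:
    def _table(self, fdr, fc):
        return pd.DataFrame(
            {
                "protein": ["X"],
                "contrast": ["m10_vs_m0"],
                "log2fc": [fc],
                "t": [1.0],
                "p": [fdr],
                "fdr": [fdr],
            }
        )

    def test_boundary_inside(self):
        out = call_deps(self._table(0.049, 0.51))
        assert bool(out.loc[0, "is_dep"])

    def test_strict_boundaries_excluded(self):
        assert not bool(call_deps(self._table(0.05, 0.51)).loc[0, "is_dep"])
        assert not bool(call_deps(self._table(0.049, 0.5)).loc[0, "is_dep"])

    def test_dep_counts_monotone_in_thresholds(self, rng):
        table = pd.DataFrame(
            {
                "protein": [f"P{i}" for i in range(300)],
                "contrast": "m10_vs_m0",
                "log2fc": rng.normal(0, 1, 300),
                "t": rng.normal(0, 2, 300),
                "p": rng.uniform(0, 1, 300),
            }
        )
        table = adjust_fdr(table)
        counts_alpha = [
            call_deps(table, fdr_alpha=a)["is_dep"].sum() for a in (0.2, 0.1, 0.05, 0.01)
        ]
        assert counts_alpha == sorted(counts_alpha, reverse=True)
        counts_fc = [
            call_deps(table, log2fc_min=f)["is_dep"].sum() for f in (0.0, 0.5, 1.0, 2.0)
        ]
        assert counts_fc == sorted(counts_fc, reverse=True)


class TestEstimatorFacade:
    def test_results_match_functions(self, rng, tiny_cohort):
        patients = ["A", "A", "B", "B", "C", "C", "D", "D"]
        tps = [0, 10] * 4
        X = pd.DataFrame(
            rng.normal(0, 1, (8, 30)), index=[f"s{i}" for i in range(8)]
        )
        est = PairwiseModeratedTest().fit(X, timepoints=tps, patients=patients)
        assert set(est.results_.columns) >= {"protein", "contrast", "log2fc", "t", "p", "fdr", "is_dep", "direction"}
        assert est.prior_df_ >= 0
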