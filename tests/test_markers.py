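"""Consistency scores, change-change correlations, cutoffs, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfmark.benchmarks import scaled_config
from csfmark.core import ValidationError
from csfmark.markers import (
    CutoffResponseClassifier,
    clinical_correlation,
    clinical_deltas,
    consistency_scores,
    cutoff_classifier,
    enrichment_test,
    pearson_with_p,
    protein_deltas,
    routine_parameter_correlations,
    scan_cutoffs,
)
from csfmark.simulate import simulate_cohort
from conftest import make_matrix, make_meta


def delta_frame(values, patients=None, timepoint=10):
    values = np.asarray(values, dtype=float)
    patients = patients or [f"p{i}" for i in range(len(values))]
    return pd.DataFrame(
        {"patient_id": patients, "timepoint_months": timepoint, "delta": values}
    )


class TestConsistencyScores:
    def _cohort(self, deltas):
        """One protein; patients move from 10 by the given deltas at month 10."""
        n = len(deltas)
        samples = [f"p{i}_t{t}" for i in range(n) for t in (0, 10)]
        patients = [f"p{i}" for i in range(n) for _ in range(2)]
        tps = [0, 10] * n
        meta = make_meta(samples, patients, tps)
        vals = np.array([[10.0 + (d if t == 10 else 0.0) for (d, t) in zip(np.repeat(deltas, 2), tps)]])
        return make_matrix(vals, scale="vst", samples=samples), meta

    def test_all_concordant(self):
        m, meta = self._cohort([1.0, 2.0, 0.5, 0.1])
        cm = consistency_scores(m, meta, {"P0": 1})
        assert cm.fraction.loc["P0", "m10"] == pytest.approx(1.0)
        assert cm.n_evaluable.loc["P0", "m10"] == 4

    def test_three_up_one_down(self):
        m, meta = self._cohort([1.0, 2.0, 0.5, -0.3])
        cm = consistency_scores(m, meta, {"P0": 1})
        assert cm.fraction.loc["P0", "m10"] == pytest.approx(0.75)

    def test_zero_change_counts_against(self):
        m, meta = self._cohort([1.0, 0.0])
        cm = consistency_scores(m, meta, {"P0": 1})
        assert cm.fraction.loc["P0", "m10"] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_cohorts(self, rng):
        for _ in range(30):
            n_pat, n_tp = int(rng.integers(2, 6)), int(rng.integers(2, 4))
            schedule = [0, 10, 18][:n_tp]
            samples, patients, tps = [], [], []
            present = {}
            for i in range(n_pat):
                for t in schedule:
                    if t == 0 or rng.random() < 0.8:
                        samples.append(f"p{i}_t{t}")
                        patients.append(f"p{i}")
                        tps.append(t)
                        present[(f"p{i}", t)] = len(samples) - 1
            vals = rng.normal(0, 1, (3, len(samples)))
            vals[rng.random(vals.shape) < 0.15] = np.nan
            m = make_matrix(vals, scale="vst", samples=samples)
            meta = make_meta(samples, patients, tps)
            signs = {"P0": 1, "P1": -1, "P2": 1}
            cm = consistency_scores(m, meta, signs)
            for g, protein in enumerate(["P0", "P1", "P2"]):
                for t in schedule[1:]:
                    if f"m{t}" not in cm.fraction.columns:
                        # no sample anywhere at this timepoint
                        assert all((p, t) not in present for p in set(patients))
                        continue
                    conc = total = 0
                    for i in range(n_pat):
                        a = present.get((f"p{i}", 0))
                        b = present.get((f"p{i}", t))
                        if a is None or b is None:
                            continue
                        if np.isnan(vals[g, a]) or np.isnan(vals[g, b]):
                            continue
                        total += 1
                        conc += int(np.sign(vals[g, b] - vals[g, a]) == signs[protein])
                    got = cm.fraction.loc[protein, f"m{t}"]
                    if total == 0:
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(conc / total)

    def test_planted_direction_fully_consistent_without_noise(self, rng):
        import dataclasses
        config = dataclasses.replace(
            scaled_config(n_timepoints=4, n_proteins=100, n_patients=6),
            multiplicative_sd=0.0,
            additive_sd=0.0,
            factor_loading_sd=0.0,
            missing_rate=0.0,
            n_low_quality_samples=0,
            broad_shift_fraction=0.0,
            n_coupled=0,
        )
        tmt, _, meta, _, truth = simulate_cohort(config, seed=2)
        from csfmark.preprocess import vst_normalize

        normalized, _ = vst_normalize(tmt)
        signs = dict(zip(truth.dep_effects["protein"], truth.dep_effects["sign"]))
        cm = consistency_scores(normalized, meta, signs)
        onset = f"m{config.dep_onset_month}"
        assert (cm.fraction[onset].dropna() == 1.0).all()


class TestPearson:
    def test_perfect_correlation(self):
        r, p, n = pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_permutation_test(self, rng):
        x = rng.normal(0, 1, 8)
        y = 0.5 * x + rng.normal(0, 1, 8)
        r, p, _ = pearson_with_p(x, y)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            count += abs(rp) >= abs(r) - 1e-12
        p_perm = count / n_perm
        assert abs(p - p_perm) < 0.03

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(200):
            x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
            pvals.append(pearson_with_p(x, y)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_feature_skipped(self, caplog):
        dx = delta_frame([1.0, 1.0, 1.0])
        dx["protein"] = "FLAT"
        dy = delta_frame([0.5, -0.2, 1.0])
        with caplog.at_level("INFO"):
            out = clinical_correlation(dx, dy)
        assert out.empty


class TestRoutineCorrelations:
    def test_coupled_signs_and_null_parameter(self):
        neg_q, null_p = [], []
        for seed in range(10):
            *_, clinical, _ = simulate_cohort(scaled_config(n_proteins=50), seed=100 + seed)
            out = routine_parameter_correlations(clinical).set_index("parameter")
            neg_q.append(out.loc["qalb", "r"] < 0)
            null_p.append(out.loc["total_protein", "p"] > 0.05)
        assert sum(neg_q) >= 9
        assert sum(null_p) >= 9

    def test_constant_parameter_skipped(self, caplog):
        clinical = pd.DataFrame(
            {
                "patient_id": ["A", "A", "B", "B", "C", "C"],
                "timepoint_months": [0, 10] * 3,
                "hfmse": [20, 25, 30, 28, 10, 14],
                "glucose": [60.0] * 6,
            }
        )
        with caplog.at_level("INFO"):
            out = routine_parameter_correlations(clinical, parameters=("glucose",))
        assert out.empty


class TestCutoffRules:
    def test_total_abstention_flagged(self):
        dx = delta_frame([0.1, -0.1, 0.05])
        dy = delta_frame([1.0, -1.0, 2.0])
        rule = cutoff_classifier(dx, dy, theta=5.0)
        assert rule.abstention_rate == 1.0
        assert rule.concordance is None

    def test_monotone_relation_perfect(self):
        dx = delta_frame([1.0, 2.0, -1.5, -0.8, 0.9, -1.2])
        dy = delta_frame([3.0, 5.0, -4.0, -1.0, 2.0, -2.0])
        rule = cutoff_classifier(dx, dy, theta=0.5)
        assert rule.concordance == pytest.approx(1.0)
        assert rule.abstention_rate == 0.0

    def test_sign_invariance_of_truth(self):
        dx = delta_frame([1.0, -2.0, 0.7, -0.9, 1.4, -0.2])
        dy_raw = np.array([2.0, -1.0, 4.0, -3.0, 0.5, 1.0])
        base = cutoff_classifier(dx, delta_frame(dy_raw), theta=0.5)
        for transform in (lambda v: 3 * v, np.tanh, lambda v: v**3):
            rule = cutoff_classifier(dx, delta_frame(transform(dy_raw)), theta=0.5)
            assert rule.concordance == base.concordance
            assert rule.confusion == base.confusion

    def test_scan_returns_grid_member_and_prefers_smaller_theta(self):
        dx = delta_frame([1.0, 2.0, -1.5, -0.8, 0.9, -1.2])
        dy = delta_frame([3.0, 5.0, -4.0, -1.0, 2.0, -2.0])
        rule = scan_cutoffs(dx, dy, grid=(0.25, 0.5))
        assert rule.threshold == 0.25  # equal concordance -> smaller theta

    def test_scan_matches_brute_force(self, rng):
        grid = (0.2, 0.4, 0.6, 0.8)
        for _ in range(50):
            dx = delta_frame(rng.normal(0, 1, 6))
            dy = delta_frame(rng.normal(0.3, 1, 6))
            rule = scan_cutoffs(dx, dy, grid, min_covered=0.5)
            best = None
            for theta in grid:
                r = cutoff_classifier(dx, dy, theta)
                if r.concordance is None or (1 - r.abstention_rate) < 0.5:
                    continue
                if best is None or r.concordance > best.concordance + 1e-12:
                    best = r
            if best is None:
                assert rule.threshold == grid[0]
            else:
                assert rule.threshold == best.threshold
                assert rule.concordance == best.concordance

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            scan_cutoffs(delta_frame([1.0]), delta_frame([1.0]), grid=())

    def test_estimator_fit_predict(self):
        x = np.array([1.0, 2.0, -1.5, -0.8, 0.9, -1.2])
        y = np.array([3.0, 5.0, -4.0, -1.0, 2.0, -2.0])
        clf = CutoffResponseClassifier(grid=(0.25, 0.5)).fit(x, y)
        assert clf.theta_ == 0.25
        pred = clf.predict([2.0, -2.0, 0.0])
        assert list(pred) == ["improved_or_stable", "not_improved_or_worse", "abstain"]


def hypergeom_tail(k, N, K, n):
    """Direct combinatorial upper-tail sum."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


class TestEnrichment:
    def test_hand_computable_tail(self):
        background = {f"b{i}" for i in range(20)}
        hits = {f"b{i}" for i in range(5)}
        term = {f"b{i}" for i in range(1, 6)}  # overlap with hits = 4
        out = enrichment_test(hits, background, {"T": term})
        assert out.loc[0, "overlap"] == 4
        assert out.loc[0, "p"] == pytest.approx(hypergeom_tail(4, 20, 5, 5), abs=1e-12)

    def test_full_overlap_term(self):
        background = {f"b{i}" for i in range(10)}
        hits = {"b0", "b1", "b2"}
        out = enrichment_test(hits, background, {"T": hits})
        assert out.loc[0, "p"] == pytest.approx(hypergeom_tail(3, 10, 3, 3), abs=1e-12)

    def test_disjoint_term_p_one(self):
        background = {f"b{i}" for i in range(10)}
        out = enrichment_test({"b0"}, background, {"T": {"b5", "b6"}})
        assert out.loc[0, "overlap"] == 0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_term_outside_background_skipped(self):
        out = enrichment_test({"b0"}, {"b0", "b1"}, {"T": {"zzz"}})
        assert out.empty

    def test_hits_must_be_subset(self):
        with pytest.raises(ValidationError):
            enrichment_test({"x"}, {"b0"}, {"T": {"b0"}})


class TestDeltas:
    def test_baseline_excluded_by_default(self, tiny_cohort):
        tmt, _, meta, clinical, _ = tiny_cohort
        dy = clinical_deltas(clinical, "hfmse")
        assert (dy["timepoint_months"] != 0).all()
        dy_incl = clinical_deltas(clinical, "hfmse", include_baseline=True)
        base = dy_incl[dy_incl["timepoint_months"] == 0]
        assert (base["delta"] == 0).all()

    def test_protein_deltas_join_protein_matrix(self, tiny_cohort):
        tmt, _, meta, _, _ = tiny_cohort
        dx = protein_deltas(tmt, meta)
        one = dx[(dx["protein"] == "ALB") & (dx["patient_id"] == "SMA01")]
        assert len(one) == len(set(one["timepoint_months"]))
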