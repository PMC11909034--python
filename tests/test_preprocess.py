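"""Sample QC, detection filtering, VST and kNN imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from csfmark.core import ValidationError
from csfmark.preprocess import (
    KNNProteinImputer,
    filter_detection,
    filter_low_intensity_samples,
    glog2,
    knn_impute,
    vst_normalize,
)
from conftest import make_matrix, make_meta


class TestSampleFilter:
    def test_below_threshold_removed(self):
        m = make_matrix([[50.0, 150.0, 200.0], [50.0, 150.0, 200.0]])
        out, removed = filter_low_intensity_samples(m, threshold=225.0)
        assert removed == ["s0"]
        assert list(out.sample_ids) == ["s1", "s2"]

    def test_threshold_zero_keeps_all(self):
        m = make_matrix([[1.0, 2.0]])
        out, removed = filter_low_intensity_samples(m, threshold=0.0)
        assert removed == []
        assert out.n_samples == 2

    def test_all_removed_is_error(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            filter_low_intensity_samples(m, threshold=1e9)

    def test_planted_low_quality_samples_removed_exactly(self, tiny_cohort):
        tmt, _, meta, _, truth = tiny_cohort
        _, removed = filter_low_intensity_samples(tmt, threshold=225.0)
        assert sorted(removed) == sorted(truth.low_quality_samples)


def brute_force_detection(observed: np.ndarray, patients, mwp: int, mp: int) -> np.ndarray:
    """Direct double loop over (protein, patient) implementing the rule."""
    keep = np.zeros(observed.shape[0], dtype=bool)
    unique_patients = sorted(set(patients))
    for p in range(observed.shape[0]):
        per_patient = {
            u: sum(observed[p, j] for j in range(observed.shape[1]) if patients[j] == u)
            for u in unique_patients
        }
        within = any(c >= mwp for c in per_patient.values())
        across = sum(c >= 1 for c in per_patient.values()) >= mp
        keep[p] = within and across
    return keep


class TestDetectionFilter:
    def _toy(self):
        # 4 patients x 2 samples each
        samples = [f"s{i}" for i in range(8)]
        patients = ["A", "A", "B", "B", "C", "C", "D", "D"]
        meta = make_meta(samples, patients, [0, 2, 0, 2, 0, 2, 0, 2])
        return samples, patients, meta

    def test_two_in_one_patient_only_dropped(self):
        samples, patients, meta = self._toy()
        vals = np.full((1, 8), np.nan)
        vals[0, 0] = vals[0, 1] = 5.0  # twice in patient A only
        m = make_matrix(vals, samples=samples)
        out = filter_detection(m, meta)
        assert out.n_proteins == 0

    def test_two_in_one_one_in_other_kept(self):
        samples, patients, meta = self._toy()
        vals = np.full((1, 8), np.nan)
        vals[0, 0] = vals[0, 1] = 5.0
        vals[0, 2] = 7.0  # once in patient B
        m = make_matrix(vals, samples=samples)
        out = filter_detection(m, meta)
        assert list(out.protein_ids) == ["P0"]

    def test_fully_observed_unchanged(self):
        samples, patients, meta = self._toy()
        m = make_matrix(np.arange(24, dtype=float).reshape(3, 8), samples=samples)
        out = filter_detection(m, meta)
        pd.testing.assert_frame_equal(out.data, m.data)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_prot = int(rng.integers(1, 10))
        n_pat = int(rng.integers(2, 5))
        reps = int(rng.integers(1, 4))
        patients = [f"p{i}" for i in range(n_pat) for _ in range(reps)]
        n_samp = len(patients)
        samples = [f"s{i}" for i in range(n_samp)]
        tps = [t for t in range(reps) for _ in range(n_pat)][:n_samp]
        schedule = (0, 2, 10, 18, 26, 34, 42)
        meta = make_meta(samples, patients, [schedule[t] for t in range(reps)] * n_pat)
        vals = rng.uniform(1, 10, (n_prot, n_samp))
        vals[rng.random((n_prot, n_samp)) < 0.5] = np.nan
        m = make_matrix(vals, samples=samples)
        mwp = int(rng.integers(1, 4))
        mp = int(rng.integers(1, 4))
        out = filter_detection(m, meta, min_within_patient=mwp, min_patients=mp)
        expected = brute_force_detection(~np.isnan(vals), patients, mwp, mp)
        assert list(out.protein_ids) == [f"P{i}" for i in np.flatnonzero(expected)]


class TestVST:
    def test_glog_reduces_to_log2(self):
        assert abs(glog2(1e6, 0.0) - np.log2(1e6)) < 1e-6
        assert abs(glog2(1e6, 1.0) - np.log2(1e6)) < 1e-6

    def test_scaled_sample_recalibrated(self, rng):
        base = rng.lognormal(8, 2, 200)
        vals = np.column_stack([base, base * 4.0, base * 0.5])
        m = make_matrix(vals)
        out, params = vst_normalize(m)
        medians = np.nanmedian(out.values, axis=0)
        assert np.max(np.abs(medians - medians[0])) < 1e-8
        assert (params.scales > 0).all()

    def test_monotone_per_sample(self, rng):
        vals = rng.lognormal(6, 3, (50, 8))
        m = make_matrix(vals)
        out, _ = vst_normalize(m)
        for j in range(8):
            order_in = np.argsort(vals[:, j])
            order_out = np.argsort(out.values[:, j])
            np.testing.assert_array_equal(order_in, order_out)

    def test_missing_stays_missing(self, rng):
        vals = rng.lognormal(6, 2, (30, 6))
        vals[2, 3] = np.nan
        out, _ = vst_normalize(make_matrix(vals))
        assert np.isnan(out.values[2, 3])
        assert np.isnan(out.values).sum() == 1

    def test_requires_raw_scale(self, rng):
        m = make_matrix(rng.lognormal(6, 2, (30, 6)), scale="vst")
        with pytest.raises(ValidationError):
            vst_normalize(m)


class TestKNNImpute:
    def test_twin_protein_fills_missing(self):
        vals = np.array([[1.0, 2.0, 3.0, np.nan], [1.0, 2.0, 3.0, 4.0], [9.0, 9.0, 9.0, 9.0]])
        m = make_matrix(vals, scale="vst")
        out = knn_impute(m, k=1)
        assert out.values[0, 3] == pytest.approx(4.0)

    def test_fully_observed_unchanged(self, rng):
        m = make_matrix(rng.normal(10, 1, (20, 5)), scale="vst")
        out = knn_impute(m, k=3)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_observed_never_altered_and_complete(self, rng):
        vals = rng.normal(10, 2, (40, 10))
        mask = rng.random((40, 10)) < 0.1
        vals[mask] = np.nan
        vals[:, 0] = rng.normal(10, 2, 40)  # every protein observed somewhere
        m = make_matrix(vals, scale="vst")
        out = knn_impute(m, k=5)
        assert not np.isnan(out.values).any()
        observed = ~np.isnan(vals)
        np.testing.assert_array_equal(out.values[observed], vals[observed])

    def test_empty_protein_named(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0], [1.0, 2.5]])
        m = make_matrix(vals, scale="vst", proteins=["EMPTY", "B", "C"])
        with pytest.raises(ValidationError, match="EMPTY"):
            knn_impute(m, k=1)

    def test_protein_mean_fallback_when_few_candidates(self):
        # k=10 but only 2 possible neighbors -> protein mean is used
        vals = np.array([[1.0, 5.0, np.nan], [0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        m = make_matrix(vals, scale="vst")
        out = knn_impute(m, k=10)
        assert out.values[0, 2] == pytest.approx(3.0)

    def test_deterministic_tie_break_by_protein_id(self):
        # two equidistant neighbors with different values at the target
        vals = np.array(
            [
                [1.0, 1.0, np.nan],
                [2.0, 2.0, 10.0],  # P1
                [0.0, 0.0, 20.0],  # P2, same distance to P0 as P1
            ]
        )
        m = make_matrix(vals, scale="vst")
        out = knn_impute(m, k=1)
        assert out.values[0, 2] == pytest.approx(10.0)  # P1 < P2 lexicographically

    def test_estimator_interface(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (6, 12)))
        X.iloc[0, 3] = np.nan
        imp = KNNProteinImputer(n_neighbors=3).fit(X)
        out = imp.transform(X)
        assert not out.isna().any().any()
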