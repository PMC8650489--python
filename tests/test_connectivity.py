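"""Entropy, mutual information and NMI estimators."""

import math

import numpy as np
import pytest

from nmigraph import (ROITimeSeries, build_connectivity_matrix,
                      mutual_information, nmi_coefficient, shannon_entropy)
from nmigraph.connectivity import default_bins

LOG2 = math.log(2)


class TestShannonEntropy:
    @pytest.mark.parametrize("x, bins, expected", [
        ([3.0, 3.0, 3.0, 3.0], 2, 0.0),                    # constant: one bin
        ([0, 0, 1, 1], 2, LOG2),                           # uniform over 2 bins
        ([0, 0, 0, 1], 2, 0.5623351446188083),             # plug-in -(3/4 log 3/4 + 1/4 log 1/4)
    ])
    def test_plugin_values(self, x, bins, expected):
        assert shannon_entropy(x, bins) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.0, np.nan, 1.0], 2)

    def test_matches_numpy_histogram_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        for bins in (2, 5, 14):
            counts, _ = np.histogram(x, bins=bins)
            p = counts[counts > 0] / counts.sum()
            assert shannon_entropy(x, bins) == pytest.approx(
                -np.sum(p * np.log(p)), abs=1e-12)


class TestMutualInformation:
    def test_factorizing_joint_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1], 2) == 0.0

    def test_identity_equals_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        assert mutual_information(x, x, 10) == pytest.approx(
            shannon_entropy(x, 10), abs=1e-12)

    def test_hand_oracle(self):
        # joint histogram {(0,0):1, (0,1):1, (1,1):2} over 4 samples
        assert mutual_information([0, 0, 1, 1], [0, 1, 1, 1], 2) == pytest.approx(
            0.2157615543388356, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2, 3], [1, 2], 2)


class TestNMICoefficient:
    def test_self_dependence_is_one(self):
        x = np.random.default_rng(0).normal(size=360)
        assert nmi_coefficient(x, x, 19).nmi == pytest.approx(1.0, abs=1e-12)

    def test_independence_is_zero(self):
        assert nmi_coefficient([0, 0, 1, 1], [0, 1, 0, 1], 2).nmi == 0.0

    def test_hand_oracle(self):
        est = nmi_coefficient([0, 0, 1, 1], [0, 1, 1, 1], 2)
        expected = 0.2157615543388356 / math.sqrt(LOG2 * 0.5623351446188083)
        assert est.nmi == pytest.approx(expected, abs=1e-12)
        assert est.nmi == pytest.approx(0.3455920299442112, abs=1e-12)

    def test_constant_series_degenerate_zero(self):
        est = nmi_coefficient([1.0, 1.0, 1.0], [0.0, 1.0, 2.0], 2)
        assert est.nmi == 0.0
        assert est.degenerate

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_exact(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 80))
        assert nmi_coefficient(x, y, 9).nmi == nmi_coefficient(y, x, 9).nmi

    def test_base_invariance(self):
        # recompute the ratio with base-2 entropies: identical by cancellation
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 120))
        est = nmi_coefficient(x, y, 11)
        bits = (est.mi / LOG2) / math.sqrt((est.h_x / LOG2) * (est.h_y / LOG2))
        assert est.nmi == pytest.approx(bits, abs=1e-12)

    def test_noise_does_not_increase_dependence(self):
        # data-processing sanity: median NMI non-increasing in noise sd
        medians = []
        for sd in (0.0, 1.0, 4.0):
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                x = rng.normal(size=300)
                y = x + sd * rng.normal(size=300)
                vals.append(nmi_coefficient(x, y).nmi)
            medians.append(np.median(vals))
        assert medians[0] >= medians[1] >= medians[2]


class TestBuildConnectivityMatrix:
    def _ts(self, values):
        values = np.asarray(values, dtype=float)
        return ROITimeSeries(values=values,
                             roi_names=[f"r{i}" for i in range(values.shape[0])],
                             tr_s=2.5)

    def test_identical_rows_give_unit_weight(self):
        row = np.random.default_rng(0).normal(size=50)
        cm = build_connectivity_matrix(self._ts([row, row]))
        assert cm.weights[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert cm.weights[0, 0] == 0.0

    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(5)
        ts = self._ts(rng.normal(size=(6, 70)))
        cm = build_connectivity_matrix(ts)
        for i in range(6):
            for j in range(i + 1, 6):
                expected = nmi_coefficient(ts.values[i], ts.values[j], cm.n_bins).nmi
                assert cm.weights[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matrix_invariants(self):
        rng = np.random.default_rng(9)
        cm = build_connectivity_matrix(self._ts(rng.normal(size=(8, 60))))
        assert np.array_equal(cm.weights, cm.weights.T)
        assert np.all((cm.weights >= 0) & (cm.weights <= 1))
        assert np.all(np.diag(cm.weights) == 0)

    def test_default_bin_rule(self):
        assert default_bins(360) == 19
        rng = np.random.default_rng(2)
        cm = build_connectivity_matrix(self._ts(rng.normal(size=(3, 100))))
        assert cm.n_bins == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_modules_raise_within_module_nmi(self, seed):
        from nmigraph import (censor_motion, select_task_volumes, simulate_subject,
                              small_spec)
        spec = small_spec(seed=seed, n_rois=30, within=0.8, between=0.1)
        ts, motion = simulate_subject(spec, "A", 0)
        ts = select_task_volumes(ts, spec.design, censor_motion(motion.mm))
        cm = build_connectivity_matrix(ts)
        aff = spec.structure.affiliation
        same = aff[:, None] == aff[None, :]
        off = ~np.eye(30, dtype=bool)
        assert cm.weights[same & off].mean() > cm.weights[~same].mean()
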