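"""Confusion-matrix statistics and area agreement, with brute-force oracles."""

import numpy as np
import pytest

from phenocrop.validation import accuracy_metrics, area_agreement, confusion_matrix


def brute_force_metrics(m):
    """Independent straight-loop implementation of OA/UA/PA/F1/kappa."""
    m = np.asarray(m, dtype=float)
    k = m.shape[0]
    n = m.sum()
    oa = sum(m[i, i] for i in range(k)) / n
    pe = sum(m[i, :].sum() * m[:, i].sum() for i in range(k)) / n**2
    kappa = (oa - pe) / (1 - pe)
    pa = [m[i, i] / m[i, :].sum() if m[i, :].sum() else None for i in range(k)]
    ua = [m[i, i] / m[:, i].sum() if m[:, i].sum() else None for i in range(k)]
    f1 = [
        2 * u * p / (u + p) if (u is not None and p is not None and u + p) else None
        for u, p in zip(ua, pa)
    ]
    return oa, kappa, ua, pa, f1


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        labels = ["a", "b", "c", "d"] * 5
        m = confusion_matrix(labels, labels, ["a", "b", "c", "d"])
        assert m.sum() == 20 and np.trace(m) == 20

    def test_single_off_diagonal_sample(self):
        m = confusion_matrix(["rice"], ["wheat"], ["rice", "wheat"])
        assert m[0, 1] == 1 and m.sum() == 1

    def test_matches_independent_tally_on_random_labels(self):
        rng = np.random.default_rng(0)
        classes = list("abcd")
        pred = rng.choice(classes, 1000)
        ref = rng.choice(classes, 1000)
        m = confusion_matrix(pred, ref, classes)
        from sklearn.metrics import confusion_matrix as sk_cm

        # sklearn rows are true labels; ours are predictions
        assert np.array_equal(m, sk_cm(ref, pred, labels=classes).T)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="class order"):
            confusion_matrix(["x"], ["a"], ["a", "b"])


class TestAccuracyMetrics:
    def test_reference_table_statistics(self, reference_matrix):
        """The published national accuracy table reproduces exactly at 2 dp:
        OA 89.10 %, kappa 0.85, and the printed per-class PA/UA/F1."""
        rep = accuracy_metrics(reference_matrix, ("rice", "wheat", "maize", "others"))
        assert reference_matrix.sum() == 18379
        assert round(100 * rep.oa, 2) == 89.10
        assert round(rep.kappa, 2) == 0.85
        assert [round(rep.pa[c], 2) for c in rep.classes] == [92.83, 83.55, 90.43, 85.81]
        assert [round(rep.ua[c], 2) for c in rep.classes] == [90.13, 90.98, 91.20, 84.63]
        assert [round(rep.f1[c], 2) for c in rep.classes] == [0.91, 0.87, 0.91, 0.85]

    def test_identity_matrix_is_perfect(self):
        rep = accuracy_metrics(np.eye(4) * 10)
        assert rep.oa == 1.0 and rep.kappa == 1.0

    def test_uniform_matrix_has_zero_kappa(self):
        rep = accuracy_metrics(np.full((3, 3), 7))
        assert rep.kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = rng.integers(2, 6)
            m = rng.integers(0, 50, (k, k))
            m[np.diag_indices(k)] += 1  # avoid empty rows/cols
            rep = accuracy_metrics(m)
            oa, kappa, ua, pa, f1 = brute_force_metrics(m)
            assert abs(rep.oa - oa) < 1e-12
            assert abs(rep.kappa - kappa) < 1e-12
            for i, c in enumerate(rep.classes):
                assert abs(rep.ua[c] - 100 * ua[i]) < 1e-10
                assert abs(rep.pa[c] - 100 * pa[i]) < 1e-10
                assert abs(rep.f1[c] - f1[i]) < 1e-12

    def test_class_permutation_preserves_oa_and_kappa(self):
        rng = np.random.default_rng(2)
        m = rng.integers(1, 30, (4, 4))
        rep = accuracy_metrics(m, "abcd")
        perm = [2, 0, 3, 1]
        rep_p = accuracy_metrics(m[np.ix_(perm, perm)], [list("abcd")[i] for i in perm])
        assert rep_p.oa == pytest.approx(rep.oa, abs=1e-15)
        assert rep_p.kappa == pytest.approx(rep.kappa, abs=1e-15)
        for c in "abcd":
            assert rep_p.f1[c] == pytest.approx(rep.f1[c], abs=1e-15)

    def test_f1_consistent_with_ua_pa(self, reference_matrix):
        rep = accuracy_metrics(reference_matrix)
        for c in rep.classes:
            u, p = rep.ua[c] / 100, rep.pa[c] / 100
            assert rep.f1[c] == pytest.approx(2 * u * p / (u + p), abs=1e-12)

    def test_zero_column_reports_none_not_nan(self):
        m = np.array([[5, 0], [3, 0]])
        rep = accuracy_metrics(m, ("a", "b"))
        assert rep.ua["b"] is None and rep.f1["b"] is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="grand total"):
            accuracy_metrics(np.zeros((2, 2)))


class TestAreaAgreement:
    def test_perfect_agreement(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        slope, intercept, r2 = area_agreement(ref, ref)
        assert (slope, intercept, r2) == (1.0, 0.0, 1.0)

    def test_proportional_bias_keeps_r2(self):
        ref = np.array([10.0, 20.0, 30.0])
        slope, _, r2 = area_agreement(2 * ref, ref)
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_noisy_agreement_monte_carlo(self):
        rng = np.random.default_rng(42)
        ref = rng.uniform(100, 1000, 30)
        est = ref + rng.normal(0, 0.1 * ref.std(), 30)  # noise sd = 10 % of spread
        _, _, r2 = area_agreement(est, ref)
        assert 0.95 <= r2 <= 1.0

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            area_agreement(np.r_[1.0, 2.0, 3.0], np.r_[5.0, 5.0, 5.0])

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="3 regions"):
            area_agreement(np.r_[1.0, 2.0], np.r_[1.0, 2.0])
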