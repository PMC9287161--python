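import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from sigcrf.metrics import (EvalRecord, MccMode, confusion_matrix,
                            cs_precision_recall, detection_mcc, gorodkin_mcc,
                            mcc_from_counts, multiclass_mcc,
                            performance_by_identity_bin)
from sigcrf.types import OrganismGroup, SpClass


def rec(i, true, pred, true_cs=None, pred_cs=None, group=None, ident=None):
    return EvalRecord(
        id=f"r{i}", true_class=true, predicted_class=pred, true_cs=true_cs,
        predicted_cs=pred_cs,
        organism_group=group or OrganismGroup.EUKARYA,
        max_train_identity=ident)


def make_binary_records(tp, tn, fp, fn, sp_type=SpClass.SEC_SPI):
    records = []
    i = 0
    for _ in range(tp):
        records.append(rec(i, sp_type, sp_type, true_cs=10)); i += 1
    for _ in range(tn):
        records.append(rec(i, SpClass.NO_SP, SpClass.NO_SP)); i += 1
    for _ in range(fp):
        records.append(rec(i, SpClass.NO_SP, sp_type)); i += 1
    for _ in range(fn):
        records.append(rec(i, sp_type, SpClass.NO_SP, true_cs=10)); i += 1
    return records


class TestDetectionMcc:
    def test_perfect(self):
        records = make_binary_records(10, 10, 0, 0)
        assert detection_mcc(records, SpClass.SEC_SPI, None,
                             MccMode.MCC1) == pytest.approx(1.0)

    def test_printed_counts_closed_form(self):
        tp, tn, fp, fn = 8, 85, 5, 2
        expected = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        records = make_binary_records(tp, tn, fp, fn)
        assert detection_mcc(records, SpClass.SEC_SPI, None,
                             MccMode.MCC2) == pytest.approx(expected)

    def test_matches_sklearn(self, rng):
        y_true = rng.integers(0, 2, size=400)
        y_pred = rng.integers(0, 2, size=400)
        records = [
            rec(i,
                SpClass.SEC_SPI if t else SpClass.NO_SP,
                SpClass.SEC_SPI if p else SpClass.NO_SP,
                true_cs=10 if t else None)
            for i, (t, p) in enumerate(zip(y_true, y_pred))]
        ours = detection_mcc(records, SpClass.SEC_SPI, None, MccMode.MCC1)
        assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_random_predictions_near_zero(self, rng):
        y_true = rng.integers(0, 2, size=4000)
        y_pred = rng.integers(0, 2, size=4000)
        records = [
            rec(i,
                SpClass.SEC_SPI if t else SpClass.NO_SP,
                SpClass.SEC_SPI if p else SpClass.NO_SP,
                true_cs=10 if t else None)
            for i, (t, p) in enumerate(zip(y_true, y_pred))]
        assert abs(detection_mcc(records, SpClass.SEC_SPI, None,
                                 MccMode.MCC2)) < 0.1

    def test_mcc1_excludes_other_sp_types(self):
        records = make_binary_records(5, 5, 0, 0)
        # other-type sequences misclassified as SPI hurt MCC2 but not MCC1
        records += [rec(100 + i, SpClass.SEC_SPII, SpClass.SEC_SPI,
                        true_cs=12) for i in range(5)]
        assert detection_mcc(records, SpClass.SEC_SPI, None,
                             MccMode.MCC1) == pytest.approx(1.0)
        assert detection_mcc(records, SpClass.SEC_SPI, None,
                             MccMode.MCC2) < 1.0

    def test_group_restriction(self):
        records = [
            rec(0, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=5,
                group=OrganismGroup.EUKARYA),
            rec(1, SpClass.SEC_SPI, SpClass.NO_SP, true_cs=5,
                group=OrganismGroup.ARCHAEA),
            rec(2, SpClass.NO_SP, SpClass.NO_SP,
                group=OrganismGroup.EUKARYA),
        ]
        assert detection_mcc(records, SpClass.SEC_SPI,
                             OrganismGroup.EUKARYA,
                             MccMode.MCC2) == pytest.approx(1.0)

    def test_degenerate_returns_zero_with_warning(self):
        records = [rec(0, SpClass.NO_SP, SpClass.NO_SP)] * 3
        with pytest.warns(UserWarning, match="degenerate"):
            assert detection_mcc(records, SpClass.SEC_SPI, None,
                                 MccMode.MCC2) == 0.0

    def test_no_sp_as_positive_class_mcc2(self):
        records = make_binary_records(7, 9, 2, 1)
        swapped = detection_mcc(records, SpClass.NO_SP, None, MccMode.MCC2)
        direct = detection_mcc(records, SpClass.SEC_SPI, None, MccMode.MCC2)
        assert swapped == pytest.approx(direct)  # binary symmetry
        with pytest.raises(ValueError):
            detection_mcc(records, SpClass.NO_SP, None, MccMode.MCC1)


class TestCsPrecisionRecall:
    def test_all_exact(self):
        records = [rec(i, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=20,
                       pred_cs=20) for i in range(5)]
        assert cs_precision_recall(records, SpClass.SEC_SPI, 0) == (1.0, 1.0)

    def test_window_rule(self):
        records = [rec(0, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=20,
                       pred_cs=22)]
        for window, ok in [(0, False), (1, False), (2, True), (3, True)]:
            prec, recall = cs_precision_recall(records, SpClass.SEC_SPI,
                                               window)
            assert (prec == 1.0) is ok
            assert (recall == 1.0) is ok

    def test_hand_counted_example(self):
        """10 true SPI; 8 predicted SPI with CS (6 within window); 1
        predicted SPII with a CS -> precision 6/8, recall 6/10."""
        records = []
        for i in range(6):  # correct class, CS within window
            records.append(rec(i, SpClass.SEC_SPI, SpClass.SEC_SPI,
                               true_cs=20, pred_cs=20))
        for i in range(6, 8):  # correct class, CS outside window
            records.append(rec(i, SpClass.SEC_SPI, SpClass.SEC_SPI,
                               true_cs=20, pred_cs=30))
        records.append(rec(8, SpClass.SEC_SPI, SpClass.SEC_SPII,
                           true_cs=20, pred_cs=20))  # wrong class
        records.append(rec(9, SpClass.SEC_SPI, SpClass.NO_SP, true_cs=20))
        prec, recall = cs_precision_recall(records, SpClass.SEC_SPI, 2)
        assert prec == pytest.approx(6 / 8)
        assert recall == pytest.approx(6 / 10)

    def test_monotone_in_window(self, rng):
        records = []
        for i in range(50):
            true_cs = int(rng.integers(10, 30))
            pred_cs = true_cs + int(rng.integers(-4, 5))
            pred_class = SpClass.SEC_SPI if rng.random() < 0.8 \
                else SpClass.NO_SP
            records.append(rec(i, SpClass.SEC_SPI, pred_class,
                               true_cs=true_cs,
                               pred_cs=pred_cs if pred_class.is_sp else None))
        prev_p, prev_r = -1.0, -1.0
        for window in (0, 1, 2, 3):
            p, r = cs_precision_recall(records, SpClass.SEC_SPI, window)
            assert p >= prev_p and r >= prev_r
            prev_p, prev_r = p, r

    def test_no_predictions_flagged(self):
        records = [rec(0, SpClass.SEC_SPI, SpClass.NO_SP, true_cs=10)]
        with pytest.warns(UserWarning, match="no predicted CSs"):
            prec, recall = cs_precision_recall(records, SpClass.SEC_SPI, 0)
        assert prec == 0.0 and recall == 0.0

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            cs_precision_recall([], SpClass.SEC_SPI, 5)


class TestMulticlassMcc:
    def test_identity_confusion(self):
        assert gorodkin_mcc(np.diag([5, 8, 3])) == pytest.approx(1.0)

    def test_binary_reduction(self):
        conf = np.array([[8, 2], [5, 85]])
        tp, fn, fp, tn = 8, 2, 5, 85
        assert gorodkin_mcc(conf) == pytest.approx(
            mcc_from_counts(tp, tn, fp, fn))

    def test_matches_sklearn_multiclass(self, rng):
        y_true = rng.integers(0, 4, size=500)
        y_pred = rng.integers(0, 4, size=500)
        conf = np.zeros((4, 4))
        for t, p in zip(y_true, y_pred):
            conf[t, p] += 1
        assert gorodkin_mcc(conf) == pytest.approx(
            matthews_corrcoef(y_true, y_pred))

    def test_known_3x3(self):
        # independently computed from the covariance form
        conf = np.array([[10, 2, 1], [3, 12, 0], [1, 1, 9]])
        n = conf.sum()
        row, col = conf.sum(1), conf.sum(0)
        expected = (np.trace(conf) * n - row @ col) / (
            math.sqrt(n * n - row @ row) * math.sqrt(n * n - col @ col))
        assert gorodkin_mcc(conf) == pytest.approx(expected)

    def test_requires_two_classes(self):
        records = [rec(0, SpClass.NO_SP, SpClass.NO_SP)]
        with pytest.raises(ValueError):
            multiclass_mcc(records)


class TestIdentityBins:
    def test_single_bin_equals_overall(self):
        records = [rec(i, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=9,
                       ident=0.5) for i in range(4)]
        records += [rec(9, SpClass.NO_SP, SpClass.NO_SP, ident=0.55)]
        out = performance_by_identity_bin(records, [0.4, 0.6])
        assert list(out) == [0]
        assert out[0] == pytest.approx(multiclass_mcc(records))

    def test_perfect_and_random_bins(self, rng):
        records = []
        i = 0
        for _ in range(200):  # perfect bin at low identity
            cls = SpClass.SEC_SPI if rng.random() < 0.5 else SpClass.NO_SP
            records.append(rec(i, cls, cls, true_cs=9 if cls.is_sp else None,
                               ident=0.35)); i += 1
        for _ in range(2000):  # random bin at high identity
            t = SpClass.SEC_SPI if rng.random() < 0.5 else SpClass.NO_SP
            p = SpClass.SEC_SPI if rng.random() < 0.5 else SpClass.NO_SP
            records.append(rec(i, t, p, true_cs=9 if t.is_sp else None,
                               ident=0.95)); i += 1
        out = performance_by_identity_bin(records, [0.3, 0.6, 1.0])
        assert out[0] == pytest.approx(1.0)
        assert abs(out[1]) < 0.1

    def test_empty_bin_absent(self):
        records = [rec(0, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=9,
                       ident=0.95),
                   rec(1, SpClass.NO_SP, SpClass.NO_SP, ident=0.92)]
        out = performance_by_identity_bin(records, [0.3, 0.6, 1.0])
        assert 0 not in out and 1 in out

    def test_hand_counted_bin(self):
        records = [
            rec(0, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=9, ident=0.45),
            rec(1, SpClass.NO_SP, SpClass.SEC_SPI, ident=0.5),
            rec(2, SpClass.NO_SP, SpClass.NO_SP, ident=0.42),
            rec(3, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=9, ident=0.48),
        ]
        conf = confusion_matrix(records)
        out = performance_by_identity_bin(records, [0.4, 0.6])
        assert out[0] == pytest.approx(gorodkin_mcc(conf))

    def test_top_edge_inclusive(self):
        records = [rec(0, SpClass.SEC_SPI, SpClass.SEC_SPI, true_cs=9,
                       ident=1.0),
                   rec(1, SpClass.NO_SP, SpClass.NO_SP, ident=1.0)]
        out = performance_by_identity_bin(records, [0.3, 0.6, 1.0])
        assert 1 in out


def test_eval_record_cs_consistency():
    with pytest.raises(ValueError):
        EvalRecord(id="x", true_class=SpClass.SEC_SPI,
                   predicted_class=SpClass.NO_SP)
    with pytest.raises(ValueError):
        EvalRecord(id="x", true_class=SpClass.NO_SP,
                   predicted_class=SpClass.NO_SP, true_cs=5)
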