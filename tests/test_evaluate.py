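"""Error matrix construction and accuracy metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rectile.classify import LabelRaster
from rectile.errors import ParameterError
from rectile.evaluate import (
    AccuracyReport,
    ErrorMatrix,
    accuracy_report,
    confusion,
    f1,
    kappa,
    oa,
    pa,
    stratified_split,
    ua,
)
from rectile.raster import CLASSES, SamplePoint


def mat_of(counts):
    return ErrorMatrix(np.asarray(counts))


def _label_raster(values):
    return LabelRaster(np.asarray(values, dtype=np.int16), (0.0, float(len(values)), 1.0, 1.0))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        lr = _label_raster([[0, 1], [2, 3]])
        pts = [
            SamplePoint(c + 0.5, 1.5 - r, CLASSES[lr.labels[r, c]], "validation")
            for r in range(2) for c in range(2)
        ]
        m = confusion(lr, pts)
        assert np.trace(m.counts) == 4 == m.total

    def test_single_misclassification_cell(self):
        lr = _label_raster([[CLASSES.index("unused")]])
        pts = [SamplePoint(0.5, 0.5, "grassland", "validation")]
        m = confusion(lr, pts)
        assert m.counts[CLASSES.index("unused"), CLASSES.index("grassland")] == 1
        assert m.total == 1

    def test_point_order_invariance(self):
        rng = np.random.default_rng(0)
        lr = _label_raster(rng.integers(0, 6, (5, 5)))
        pts = [
            SamplePoint(
                c + 0.5, 5 - r - 0.5, CLASSES[rng.integers(0, 6)], "validation"
            )
            for r in range(5) for c in range(5)
        ]
        m1 = confusion(lr, pts)
        m2 = confusion(lr, pts[::-1])
        np.testing.assert_array_equal(m1.counts, m2.counts)

    def test_nodata_and_outside_points_excluded(self):
        lr = _label_raster([[0, -1]])
        pts = [
            SamplePoint(0.5, 0.5, "cultivated", "validation"),
            SamplePoint(1.5, 0.5, "cultivated", "validation"),  # nodata px
            SamplePoint(9.0, 9.0, "cultivated", "validation"),  # outside
        ]
        assert confusion(lr, pts).total == 1


class TestOverallMetrics:
    def test_oa_identity_and_zero_diagonal(self):
        assert oa(mat_of(np.eye(6, dtype=int) * 5)) == 100.0
        off = np.ones((6, 6), dtype=int) - np.eye(6, dtype=int)
        assert oa(mat_of(off)) == 0.0

    def test_kappa_identity_is_one(self):
        assert kappa(mat_of(np.eye(6, dtype=int) * 7)) == pytest.approx(1.0)

    def test_kappa_hand_worked_2x2(self):
        # p_o = 0.85, p_e = 0.56 -> kappa = 0.29/0.44
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0], counts[0, 1] = 25, 5
        counts[1, 0], counts[1, 1] = 10, 60
        assert kappa(mat_of(counts)) == pytest.approx(0.29 / 0.44, abs=1e-12)

    def test_kappa_uniform_matrix_is_zero(self):
        assert kappa(mat_of(np.full((6, 6), 4))) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 30), min_size=36, max_size=36))
    def test_kappa_matches_pairwise_enumeration_oracle(self, cells):
        """Chance agreement enumerated over all (predicted, reference)
        label pairs drawn independently from the margins."""
        counts = np.asarray(cells).reshape(6, 6)
        n = counts.sum()
        if n == 0:
            return
        m = mat_of(counts)
        pred = np.repeat(np.arange(6), counts.sum(axis=1))
        ref = np.repeat(np.arange(6), counts.sum(axis=0))
        p_e = np.mean(pred[:, None] == ref[None, :])
        p_o = np.trace(counts) / n
        if p_e == 1.0:
            assert np.isnan(kappa(m))
        else:
            expected = (p_o - p_e) / (1 - p_e)
            assert kappa(m) == pytest.approx(expected, abs=1e-12)

    def test_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, (6, 6))
        pred, ref = [], []
        for i in range(6):
            for j in range(6):
                pred += [i] * counts[i, j]
                ref += [j] * counts[i, j]
        assert kappa(mat_of(counts)) == pytest.approx(
            cohen_kappa_score(ref, pred), abs=1e-12
        )


class TestPerClassMetrics:
    def test_pa_ua_f1_hand_values(self):
        counts = np.zeros((6, 6), dtype=int)
        g = CLASSES.index("grassland")
        counts[g, g] = 80
        counts[g, CLASSES.index("unused")] = 20  # commission
        counts[CLASSES.index("unused"), g] = 10  # omission
        m = mat_of(counts)
        assert pa(m, "grassland") == pytest.approx(100 * 80 / 90)
        assert ua(m, "grassland") == pytest.approx(100 * 80 / 100)
        p, u = 100 * 80 / 90, 80.0
        assert f1(m, "grassland") == pytest.approx(2 * p * u / (p + u))

    def test_empty_column_gives_zero_pa(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 5
        assert pa(mat_of(counts), "grassland") == 0.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ParameterError):
            pa(mat_of(np.eye(6, dtype=int)), "desert")

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 30), min_size=36, max_size=36))
    def test_f1_between_pa_and_ua(self, cells):
        m = mat_of(np.asarray(cells).reshape(6, 6))
        for cls in CLASSES:
            p, u, h = pa(m, cls), ua(m, cls), f1(m, cls)
            assert min(p, u) - 1e-9 <= h <= max(p, u) + 1e-9

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 30), min_size=36, max_size=36))
    def test_oa_is_column_weighted_mean_of_pa(self, cells):
        counts = np.asarray(cells).reshape(6, 6)
        if counts.sum() == 0:
            return
        m = mat_of(counts)
        cols = counts.sum(axis=0)
        weighted = sum(
            pa(m, c) * cols[i] for i, c in enumerate(CLASSES)
        ) / counts.sum()
        assert oa(m) == pytest.approx(weighted, abs=1e-9)


class TestStratifiedSplit:
    def _points(self, n=40):
        rng = np.random.default_rng(2)
        return [
            SamplePoint(x, y, CLASSES[i % 4])
            for i, (x, y) in enumerate(rng.random((n, 2)))
        ]

    def test_split_fraction_per_class(self):
        pts = stratified_split(self._points(), 0.7, seed=1)
        for cls in set(p.label for p in pts):
            members = [p for p in pts if p.label == cls]
            n_train = sum(p.split == "train" for p in members)
            assert n_train == round(0.7 * len(members))

    def test_seeded_and_order_preserving(self):
        pts = self._points()
        a = stratified_split(pts, 0.7, seed=4)
        b = stratified_split(pts, 0.7, seed=4)
        assert a == b
        assert [(p.x, p.y) for p in a] == [(p.x, p.y) for p in pts]

    def test_invalid_fraction(self):
        with pytest.raises(ParameterError):
            stratified_split(self._points(), 1.0)


def test_accuracy_report_roundtrip(tmp_path):
    m = mat_of(np.eye(6, dtype=int) * 10)
    rep = accuracy_report(m)
    assert rep.oa == 100.0 and rep.n == 60
    path = tmp_path / "rep.json"
    rep.to_json(path)
    import json

    assert json.loads(path.read_text())["oa"] == 100.0
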