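import numpy as np
import pytest

from dbtdet.froc_eval import (
    FrocCurve, MatchCriteria, bootstrap_ci, froc_breast, froc_slice, froc_volume,
    is_true_positive, sensitivity_at,
)
from dbtdet.ground_truth import GroundTruthBox3D
from dbtdet.io_formats import LesionClass, LesionType, PredictedBox, View

from .oracles import brute_froc, brute_froc_breast


def gt_box(x, y, w, h, center_slice=30, n_slices=60):
    from dbtdet.ground_truth import evaluation_slice_range

    lo, hi = evaluation_slice_range(center_slice, n_slices)
    return GroundTruthBox3D(x=x, y=y, width=w, height=h, center_slice=center_slice,
                            slice_lo=lo, slice_hi=hi,
                            lesion_class=LesionClass.CANCER,
                            lesion_type=LesionType.MASS)


def pred(cx, cy, z=30, score=0.9, w=20.0, h=20.0):
    return PredictedBox(x=cx - w / 2, y=cy - h / 2, width=w, height=h, z=z,
                        score=score)


class TestIsTruePositive:
    def test_hundred_pixel_floor(self):
        # gt 100x100 at (200,200): half-diagonal 70.7, floor 100 wins
        gt = gt_box(150, 150, 100, 100)
        assert is_true_positive(pred(290, 200), gt, 60)       # distance 90 < 100

    def test_beyond_floor_and_diagonal(self):
        gt = gt_box(150, 150, 100, 100)
        assert not is_true_positive(pred(310, 200), gt, 60)   # distance 110

    def test_half_diagonal_dominates_for_large_gt(self):
        # gt 300x400: diagonal 500, half 250 > floor
        gt = gt_box(50, 0, 300, 400)
        assert is_true_positive(pred(200 + 240, 200), gt, 60)      # 240 < 250
        assert not is_true_positive(pred(200 + 260, 200), gt, 60)  # 260 > 250

    def test_z_window_boundaries(self):
        gt = gt_box(150, 150, 100, 100, center_slice=30, n_slices=60)
        # 25% of 60 slices = 15 -> window [15, 45]
        assert is_true_positive(pred(200, 200, z=15), gt, 60)
        assert is_true_positive(pred(200, 200, z=45), gt, 60)
        assert not is_true_positive(pred(200, 200, z=14), gt, 60)
        assert not is_true_positive(pred(200, 200, z=46), gt, 60)

    def test_containment_option(self):
        gt = gt_box(150, 150, 100, 100)
        p = pred(260, 200)  # distance 60: TP by default, center outside gt box
        assert is_true_positive(p, gt, 60)
        strict = MatchCriteria(require_containment=True)
        assert not is_true_positive(p, gt, 60, strict)
        assert is_true_positive(pred(240, 200), gt, 60, strict)


def make_key(i):
    return (f"P{i}", "1.2", View.LCC)


class TestFrocVolume:
    def test_perfect_predictions(self):
        predictions, gts, ns = {}, {}, {}
        for i in range(3):
            key = make_key(i)
            gts[key] = [gt_box(100, 100, 50, 50)]
            predictions[key] = [pred(125, 125, score=0.9)]
            ns[key] = 60
        curve = froc_volume(predictions, gts, ns)
        assert curve.points == [(0.0, 1.0)]

    def test_no_predictions(self):
        key = make_key(0)
        curve = froc_volume({key: []}, {key: [gt_box(0, 0, 10, 10)]}, {key: 60})
        assert all(s == 0.0 for _, s in curve.points)

    def test_missing_prediction_entry_errors(self):
        key = make_key(0)
        with pytest.raises(ValueError):
            froc_volume({}, {key: [gt_box(0, 0, 10, 10)]}, {key: 60})

    def test_lesion_free_volumes_count_in_denominator(self):
        k0, k1 = make_key(0), make_key(1)
        predictions = {k0: [pred(125, 125, score=0.9)], k1: [pred(500, 500, score=0.8)]}
        gts = {k0: [gt_box(100, 100, 50, 50)]}
        curve = froc_volume(predictions, gts, {k0: 60, k1: 60})
        # at threshold 0.8: 1 TP, 1 FP over 2 volumes
        assert (0.5, 1.0) in curve.points

    def test_oracle_equivalence_1000_scenarios(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n_vol = int(rng.integers(1, 6))
            predictions, gts, ns, raw_p, raw_g = {}, {}, {}, {}, {}
            total_gt = 0
            for i in range(n_vol):
                key = make_key(i)
                ns[key] = int(rng.integers(20, 80))
                # ground truths separated by > 2x the matching radius so
                # eligibility regions are disjoint and greedy == optimal
                centers = [(300, 300), (900, 300), (300, 900), (900, 900)]
                n_gt = int(rng.integers(0, 4))
                g_list, g_raw = [], []
                for g in range(n_gt):
                    cx, cy = centers[g]
                    w, h = (float(rng.uniform(20, 100)) for _ in range(2))
                    cs = int(rng.integers(0, ns[key]))
                    g_list.append(gt_box(cx - w / 2, cy - h / 2, w, h,
                                         center_slice=cs, n_slices=ns[key]))
                    g_raw.append((cx - w / 2, cy - h / 2, w, h, cs))
                n_pred = int(rng.integers(0, 6))
                p_list, p_raw = [], []
                for _ in range(n_pred):
                    cx = float(rng.uniform(0, 1200))
                    cy = float(rng.uniform(0, 1200))
                    z = int(rng.integers(0, ns[key]))
                    s = float(rng.uniform(0.01, 1.0))
                    p_list.append(pred(cx, cy, z=z, score=s))
                    p_raw.append((cx - 10, cy - 10, 20.0, 20.0, z, s))
                predictions[key], gts[key] = p_list, g_list
                raw_p[key], raw_g[key] = p_raw, g_raw
                total_gt += n_gt
            if total_gt == 0:
                continue
            curve = froc_volume(predictions, gts, ns)
            expected = brute_froc(raw_p, raw_g, ns)
            if not expected:
                expected = [(0.0, 0.0)]
            assert len(curve.points) == len(expected)
            for (fa, sa), (fb, sb) in zip(curve.points, expected):
                assert fa == pytest.approx(fb)
                assert sa == pytest.approx(sb)

    def test_adding_fp_never_raises_curve(self, rng):
        key = make_key(0)
        gts = {key: [gt_box(100, 100, 50, 50)]}
        ns = {key: 60}
        base = [pred(125, 125, score=0.7)]
        extra = base + [pred(800, 800, score=0.95)]
        c_base = froc_volume({key: base}, gts, ns)
        c_extra = froc_volume({key: extra}, gts, ns)
        for fp_rate in (0.0, 0.5, 1.0, 2.0, 5.0):
            assert sensitivity_at(c_extra, fp_rate) <= sensitivity_at(c_base, fp_rate) + 1e-12

    def test_adding_tp_never_lowers_curve(self):
        k0, k1 = make_key(0), make_key(1)
        gts = {k0: [gt_box(100, 100, 50, 50)], k1: [gt_box(100, 100, 50, 50)]}
        ns = {k0: 60, k1: 60}
        base = {k0: [pred(125, 125, score=0.7)], k1: []}
        more = {k0: [pred(125, 125, score=0.7)], k1: [pred(125, 125, score=0.9)]}
        c_base = froc_volume(base, gts, ns)
        c_more = froc_volume(more, gts, ns)
        for fp_rate in (0.0, 0.5, 1.0, 2.0, 5.0):
            assert sensitivity_at(c_more, fp_rate) >= sensitivity_at(c_base, fp_rate) - 1e-12


class TestFrocBreast:
    def breast_scenario(self):
        # one patient, lesion seen on LCC but missed on LMLO
        kcc = ("P0", "1.2", View.LCC)
        kmlo = ("P0", "1.2", View.LMLO)
        predictions = {kcc: [pred(125, 125, score=0.9)], kmlo: []}
        gts = {kcc: [gt_box(100, 100, 50, 50)], kmlo: [gt_box(100, 100, 50, 50)]}
        ns = {kcc: 60, kmlo: 60}
        return predictions, gts, ns

    def test_any_view_rule(self):
        predictions, gts, ns = self.breast_scenario()
        curve = froc_breast(predictions, gts, ns)
        assert sensitivity_at(curve, 0.0) == 1.0  # breast detected via CC view

    def test_volume_mode_differs(self):
        predictions, gts, ns = self.breast_scenario()
        curve = froc_volume(predictions, gts, ns)
        assert sensitivity_at(curve, 0.0) == 0.5  # only 1 of 2 lesions found

    def test_any_lesion_rule(self):
        key = ("P0", "1.2", View.RCC)
        predictions = {key: [pred(125, 125, score=0.9)]}
        gts = {key: [gt_box(100, 100, 50, 50), gt_box(875, 875, 50, 50)]}
        curve = froc_breast(predictions, gts, {key: 60})
        assert sensitivity_at(curve, 0.0) == 1.0

    def test_oracle_equivalence_four_breasts(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            predictions, gts, ns, views = {}, {}, {}, {}
            raw_p, raw_g = {}, {}
            centers = [(300, 300), (900, 300), (300, 900)]
            total = 0
            for p_i in range(2):           # 2 patients x 2 lateralities
                for view in (View.LCC, View.RCC, View.LMLO, View.RMLO):
                    key = (f"P{p_i}", "1.2", view)
                    ns[key] = 40
                    views[key] = view.value
                    n_gt = int(rng.integers(0, 3))
                    g_list, g_raw = [], []
                    for g in range(n_gt):
                        cx, cy = centers[g]
                        w, h = (float(rng.uniform(20, 100)) for _ in range(2))
                        cs = int(rng.integers(0, 40))
                        g_list.append(gt_box(cx - w / 2, cy - h / 2, w, h,
                                             center_slice=cs, n_slices=40))
                        g_raw.append((cx - w / 2, cy - h / 2, w, h, cs))
                    n_pred = int(rng.integers(0, 4))
                    p_list, p_raw = [], []
                    for _ in range(n_pred):
                        cx, cy = (float(rng.uniform(0, 1200)) for _ in range(2))
                        z = int(rng.integers(0, 40))
                        s = float(rng.uniform(0.01, 1.0))
                        p_list.append(pred(cx, cy, z=z, score=s))
                        p_raw.append((cx - 10, cy - 10, 20.0, 20.0, z, s))
                    predictions[key], gts[key] = p_list, g_list
                    raw_p[key], raw_g[key] = p_raw, g_raw
                    total += n_gt
            if total == 0:
                continue
            curve = froc_breast(predictions, gts, ns)
            expected = brute_froc_breast(raw_p, raw_g, ns, views)
            if not expected:
                expected = [(0.0, 0.0)]
            assert len(curve.points) == len(expected)
            for (fa, sa), (fb, sb) in zip(curve.points, expected):
                assert fa == pytest.approx(fb)
                assert sa == pytest.approx(sb)

    def test_unparseable_laterality_errors(self):
        key = ("P0", "1.2", "XCC")
        with pytest.raises(ValueError):
            froc_breast({key: []}, {key: [gt_box(0, 0, 10, 10)]}, {key: 60})


class TestFrocSlice:
    def test_no_z_condition(self):
        # z never matters: each crop is its own 1-slice unit
        preds = [[pred(125, 125, z=0, score=0.9)], []]
        gts = [[gt_box(100, 100, 50, 50, center_slice=0, n_slices=1)],
               [gt_box(100, 100, 50, 50, center_slice=0, n_slices=1)]]
        curve = froc_slice(preds, gts)
        assert curve.unit == "slice"
        assert sensitivity_at(curve, 2.0) == 0.5


class TestSensitivityAt:
    def curve(self):
        return FrocCurve(points=[(0.0, 0.3), (1.0, 0.5), (3.0, 0.8)], unit="volume")

    def test_step_rule(self):
        assert sensitivity_at(self.curve(), 2.0) == 0.5

    def test_beyond_last_point(self):
        assert sensitivity_at(self.curve(), 10.0) == 0.8

    def test_at_zero(self):
        assert sensitivity_at(self.curve(), 0.0) == 0.3

    def test_before_first_point(self):
        c = FrocCurve(points=[(1.0, 0.5)], unit="volume")
        assert sensitivity_at(c, 0.5) == 0.0

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            sensitivity_at(FrocCurve(points=[], unit="volume"), 1.0)


class TestBootstrapCi:
    def perfect_data(self, n=10):
        predictions, gts, ns = {}, {}, {}
        for i in range(n):
            key = make_key(i)
            predictions[key] = [pred(125, 125, score=0.9)]
            gts[key] = [gt_box(100, 100, 50, 50)]
            ns[key] = 60
        return predictions, gts, ns

    @staticmethod
    def sens_metric(preds, gts, ns):
        total = sum(len(v) for v in gts.values())
        hit = sum(
            1
            for key, lesions in gts.items()
            for gt in lesions
            if any(is_true_positive(p, gt, ns[key]) for p in preds[key])
        )
        return hit / total

    def test_degenerate_metric_ci(self):
        predictions, gts, ns = self.perfect_data()
        lo, hi = bootstrap_ci(predictions, gts, ns, self.sens_metric,
                              n_boot=50, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        predictions, gts, ns = self.perfect_data(6)
        # knock out half the detections
        for i in range(3):
            predictions[make_key(i)] = []
        a = bootstrap_ci(predictions, gts, ns, self.sens_metric, n_boot=100, seed=9)
        b = bootstrap_ci(predictions, gts, ns, self.sens_metric, n_boot=100, seed=9)
        assert a == b

    def test_binomial_toy_width(self):
        # 100 patients, per-patient detection ~ Bernoulli(0.65)
        rng = np.random.default_rng(2024)
        predictions, gts, ns = {}, {}, {}
        for i in range(100):
            key = make_key(i)
            hit = rng.random() < 0.65
            predictions[key] = [pred(125, 125, score=0.9)] if hit else []
            gts[key] = [gt_box(100, 100, 50, 50)]
            ns[key] = 60
        lo, hi = bootstrap_ci(predictions, gts, ns, self.sens_metric,
                              n_boot=2000, seed=5)
        p_hat = np.mean([1.0 if predictions[make_key(i)] else 0.0 for i in range(100)])
        expected_width = 2 * 1.96 * np.sqrt(p_hat * (1 - p_hat) / 100)
        assert (hi - lo) == pytest.approx(expected_width, rel=0.20)
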