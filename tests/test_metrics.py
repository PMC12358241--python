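"""Evaluation-metric tests: hand-computed confusion cases, brute-force
set-based and all-pairs oracles, algebraic identities and aggregation."""

import json

import numpy as np
import pytest

from mranet.backbone import ConfigurationError, DimensionError
from mranet.metrics import (binarize, boundary_points, confusion_counts,
                            evaluate_dataset, hausdorff_distance,
                            overlap_metrics)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def set_based_metrics(pred, gt):
    """Overlap metrics from explicit coordinate sets (independent route)."""
    a = {tuple(p) for p in np.argwhere(np.asarray(pred, dtype=bool))}
    b = {tuple(p) for p in np.argwhere(np.asarray(gt, dtype=bool))}
    if not a and not b:
        return {k: 1.0 for k in ("iou", "dsc", "recall", "precision", "f2")}
    if not a or not b:
        return {k: 0.0 for k in ("iou", "dsc", "recall", "precision", "f2")}
    inter = len(a & b)
    iou = inter / len(a | b)
    dsc = 2 * inter / (len(a) + len(b))
    recall = inter / len(b)
    precision = inter / len(a)
    denom = 4 * precision + recall
    f2 = 5 * precision * recall / denom if denom else 0.0
    return {"iou": iou, "dsc": dsc, "recall": recall,
            "precision": precision, "f2": f2}


def brute_force_hausdorff(pred, gt):
    """All-pairs double loop over boundary points."""
    a = boundary_points(pred)
    b = boundary_points(gt)
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        h, w = np.asarray(pred).shape
        return float(np.hypot(h - 1, w - 1))

    def directed(u, v):
        worst = 0.0
        for p in u:
            best = min(float(np.hypot(p[0] - q[0], p[1] - q[1])) for q in v)
            worst = max(worst, best)
        return worst

    return max(directed(a, b), directed(b, a))


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------

def test_binarize_threshold_and_tie_break():
    pred = np.array([[0.6, 0.5], [0.499, 0.0]])
    np.testing.assert_array_equal(binarize(pred, 0.5),
                                  [[1, 1], [0, 0]])  # ties go foreground
    np.testing.assert_array_equal(binarize(np.full((2, 2), 0.6)), 1)


def test_binarize_rejects_bad_threshold():
    for bad in (0.0, 1.0, 1.5, -0.1):
        with pytest.raises(ConfigurationError):
            binarize(np.zeros((2, 2)), bad)


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def test_identical_nonempty_masks_score_one():
    m = (np.arange(25).reshape(5, 5) % 3 == 0).astype(np.uint8)
    rec = overlap_metrics(m, m)
    assert all(rec[k] == 1.0 for k in rec)


def test_hand_computed_confusion_case():
    # TP=6, FP=2, FN=2 on a 16-pixel canvas
    gt = np.zeros(16, dtype=np.uint8)
    gt[:8] = 1
    pred = np.zeros(16, dtype=np.uint8)
    pred[:6] = 1       # 6 true positives
    pred[8:10] = 1     # 2 false positives
    c = confusion_counts(pred.reshape(4, 4), gt.reshape(4, 4))
    assert (c.tp, c.fp, c.fn, c.tn) == (6, 2, 2, 6)
    assert c.total == 16
    rec = overlap_metrics(pred.reshape(4, 4), gt.reshape(4, 4))
    assert rec["precision"] == 0.75
    assert rec["recall"] == 0.75
    assert rec["iou"] == 0.6
    assert rec["dsc"] == 0.75
    assert abs(rec["f2"] - 5 * 0.75 * 0.75 / (4 * 0.75 + 0.75)) < 1e-12


def test_disjoint_masks_score_zero():
    a = np.zeros((4, 4), dtype=np.uint8)
    a[0, 0] = 1
    b = np.zeros((4, 4), dtype=np.uint8)
    b[3, 3] = 1
    rec = overlap_metrics(a, b)
    assert all(v == 0.0 for v in rec.values())


def test_empty_mask_conventions():
    empty = np.zeros((3, 3), dtype=np.uint8)
    full = np.ones((3, 3), dtype=np.uint8)
    assert all(v == 1.0 for v in overlap_metrics(empty, empty).values())
    assert all(v == 0.0 for v in overlap_metrics(empty, full).values())
    assert all(v == 0.0 for v in overlap_metrics(full, empty).values())


def test_non_binary_input_rejected():
    with pytest.raises(ValueError, match="binary"):
        overlap_metrics(np.full((2, 2), 0.5), np.zeros((2, 2)))


def test_dsc_iou_identity_on_random_pairs(rng):
    for _ in range(200):
        a = (rng.random((8, 8)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        b = (rng.random((8, 8)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        rec = overlap_metrics(a, b)
        assert abs(rec["dsc"] - 2 * rec["iou"] / (1 + rec["iou"])) < 1e-12


def test_f2_weights_recall_over_precision(rng):
    seen = 0
    for _ in range(300):
        a = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        b = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        rec = overlap_metrics(a, b)
        p, r = rec["precision"], rec["recall"]
        if r > p > 0:
            f1 = 2 * p * r / (p + r)
            assert rec["f2"] > f1
            seen += 1
    assert seen > 10  # the property was actually exercised


# ---------------------------------------------------------------------------
# Hausdorff distance
# ---------------------------------------------------------------------------

def test_hausdorff_identical_masks_zero():
    m = np.zeros((6, 6), dtype=np.uint8)
    m[2:5, 1:4] = 1
    assert hausdorff_distance(m, m) == 0.0


def test_hausdorff_single_pixels_euclidean():
    a = np.zeros((5, 6), dtype=np.uint8)
    a[0, 0] = 1
    b = np.zeros((5, 6), dtype=np.uint8)
    b[3, 4] = 1
    assert hausdorff_distance(a, b) == 5.0  # 3-4-5 triangle


def test_hausdorff_symmetric_and_empty_conventions(rng):
    a = (rng.random((7, 7)) < 0.4).astype(np.uint8)
    b = (rng.random((7, 7)) < 0.4).astype(np.uint8)
    assert hausdorff_distance(a, b) == hausdorff_distance(b, a)
    empty = np.zeros((7, 7), dtype=np.uint8)
    assert hausdorff_distance(empty, empty) == 0.0
    assert hausdorff_distance(a, empty) == np.hypot(6, 6)


def test_hausdorff_matches_all_pairs_oracle(rng):
    for _ in range(20):
        a = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        b = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        assert hausdorff_distance(a, b) == brute_force_hausdorff(a, b)


def test_boundary_definition_4_connectivity():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[1:4, 1:4] = 1
    pts = {tuple(p) for p in boundary_points(m)}
    assert (2, 2) not in pts  # interior pixel
    assert (1, 1) in pts and (3, 3) in pts
    # border-touching foreground is boundary even if 4-neighbours are set
    full = np.ones((3, 3), dtype=np.uint8)
    assert len(boundary_points(full)) == 8  # all but the centre


def test_metric_suite_matches_oracles_on_random_pairs(rng):
    for _ in range(100):
        a = (rng.random((16, 16)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        b = (rng.random((16, 16)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        rec = overlap_metrics(a, b)
        oracle = set_based_metrics(a, b)
        for key in oracle:
            assert rec[key] == pytest.approx(oracle[key], abs=0.0), key
        assert hausdorff_distance(a, b) == brute_force_hausdorff(a, b)


# ---------------------------------------------------------------------------
# dataset aggregation + report writers
# ---------------------------------------------------------------------------

def test_single_image_means_equal_per_image():
    m = (np.arange(16).reshape(4, 4) % 2).astype(float)
    rep = evaluate_dataset([m], [m.astype(np.uint8)])
    assert rep.n_images == 1
    assert rep.means["mDSC"] == rep.per_image[0]["dsc"]


def test_means_are_arithmetic_means():
    a = np.ones((4, 4))
    ga = np.ones((4, 4), dtype=np.uint8)
    b = np.zeros((4, 4))
    b[:2] = 1.0
    gb = np.ones((4, 4), dtype=np.uint8)
    rep = evaluate_dataset([a, b], [ga, gb])
    assert rep.per_image[0]["dsc"] == 1.0
    assert abs(rep.per_image[1]["dsc"] - 2 / 3) < 1e-12
    for col, mean_name in [("dsc", "mDSC"), ("iou", "mIoU"), ("hd", "HD")]:
        recomputed = np.mean([r[col] for r in rep.per_image])
        assert abs(rep.means[mean_name] - recomputed) < 1e-12


def test_evaluate_dataset_validates_inputs():
    with pytest.raises(ValueError, match="at least one"):
        evaluate_dataset([], [])
    with pytest.raises(ValueError, match="mismatch"):
        evaluate_dataset([np.zeros((2, 2))], [])


def test_report_writers_roundtrip(tmp_path, rng):
    preds = [rng.random((8, 8)) for _ in range(3)]
    gts = [(rng.random((8, 8)) < 0.5).astype(np.uint8) for _ in range(3)]
    rep = evaluate_dataset(preds, gts)
    jpath = tmp_path / "report.json"
    cpath = tmp_path / "report.csv"
    rep.write_json(jpath)
    rep.write_csv(cpath)
    loaded = json.loads(jpath.read_text())
    assert loaded["n_images"] == 3
    assert loaded["means"] == rep.means
    lines = cpath.read_text().strip().splitlines()
    assert lines[0] == "image,iou,dsc,recall,precision,f2,hd"
    assert len(lines) == 5  # header + 3 images + means row
    assert lines[-1].startswith("mean,")
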