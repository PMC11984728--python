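import numpy as np
import pandas as pd
import pytest

from cardiopcct import (STRUCTURE_IDS, SeedSet, aggregate_eval,
                        evaluate_segmentation, region_grow_segment,
                        seeds_from_labels)
from cardiopcct.segmentation import estimate_noise_sd

# Published per-structure test-set metrics of the CT-input network
# (LV, RV, LA, RA, aorta, venae cavae, pulmonary artery, myocardium).
CT_DICE = [0.7772, 0.8886, 0.8641, 0.9137, 0.8538, 0.7936, 0.8404, 0.8757]
CT_ACCURACY = [0.9979, 0.9988, 0.9991, 0.9986, 0.9965, 0.9973, 0.9917, 0.9904]


def test_aggregate_matches_published_summary_rows():
    table = pd.DataFrame({"dice": CT_DICE, "accuracy": CT_ACCURACY})
    agg = aggregate_eval(table)
    assert round(float(agg.loc["mean", "dice"]), 4) == 0.8509
    assert round(float(agg.loc["mean", "accuracy"]), 4) == 0.9963
    # sample (n-1) standard deviation is the printed convention
    assert round(float(agg.loc["sd", "dice"]), 4) == 0.0463
    assert round(float(agg.loc["sd", "accuracy"]), 4) == 0.0034


def test_aggregate_single_row_sd_zero():
    agg = aggregate_eval(pd.DataFrame({"dice": [0.9]}))
    assert float(agg.loc["sd", "dice"]) == 0.0
    with pytest.raises(ValueError, match="at least one"):
        aggregate_eval(pd.DataFrame({"dice": []}))


def test_evaluate_segmentation_hand_case():
    truth = np.zeros((4, 4, 4), dtype=np.uint8)
    truth[1:3, 1:3, 1:3] = 1  # 8 LV voxels
    pred = np.zeros_like(truth)
    pred[1:3, 1:3, 1:4] = 1  # 12 predicted: 8 TP, 4 FP
    rep = evaluate_segmentation(pred, truth, class_names=("LV",))
    row = rep.loc["LV"]
    assert row["precision"] == pytest.approx(8 / 12)
    assert row["recall"] == pytest.approx(1.0)
    assert row["dice"] == pytest.approx(16 / 20)
    assert row["jaccard"] == pytest.approx(8 / 12)
    assert row["accuracy"] == pytest.approx((64 - 4) / 64)


def test_absent_class_reported_nan_not_zero():
    truth = np.zeros((3, 3, 3), dtype=np.uint8)
    pred = np.zeros_like(truth)
    rep = evaluate_segmentation(pred, truth, class_names=("LV", "RV"))
    assert rep.loc["LV"].isna().all()


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shapes differ"):
        evaluate_segmentation(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


def test_region_growing_on_noiseless_phantom(phantom48):
    vol = phantom48.mu_volume(0, 29.5)
    seeds = SeedSet(seeds=seeds_from_labels(phantom48.labels[0]),
                    default_tolerance=0.002)
    pred = region_grow_segment(vol, seeds)
    rep = evaluate_segmentation(pred, phantom48.labels[0])
    # myocardium is the only tissue-intensity class: recovered essentially exactly
    assert rep.loc["myocardium", "dice"] > 0.95
    # blood-pool classes share one intensity; competitive growth still yields
    # high overall agreement
    assert rep.loc["mean", "dice"] > 0.8


def test_seed_in_air_leaves_class_empty(phantom48):
    vol = phantom48.mu_volume(0, 29.5)
    seeds = SeedSet(seeds={"LV": [(0, 0, 0)]}, default_tolerance=0.001)
    with pytest.warns(UserWarning, match="lies in air"):
        pred = region_grow_segment(vol, seeds)
    assert not np.any(pred == STRUCTURE_IDS["LV"])


def test_seed_validation():
    seeds = SeedSet(seeds={"LV": [(99, 0, 0)]}, default_tolerance=1.0)
    with pytest.raises(ValueError, match="outside volume"):
        seeds.validate((10, 10, 10))
    bad = SeedSet(seeds={"spleen": [(0, 0, 0)]}, default_tolerance=1.0)
    with pytest.raises(ValueError, match="unknown structure"):
        bad.validate((10, 10, 10))
    none = SeedSet(seeds={"LV": [(0, 0, 0)]})
    with pytest.raises(ValueError, match="no tolerance"):
        none.tol_for("LV")


def test_region_growing_deterministic(phantom48):
    vol = phantom48.mu_volume(0, 29.5)
    seeds = SeedSet(seeds=seeds_from_labels(phantom48.labels[0]),
                    default_tolerance=0.002)
    a = region_grow_segment(vol, seeds)
    b = region_grow_segment(vol, seeds)
    assert np.array_equal(a, b)


def test_tolerance_bounds_leakage(phantom48):
    # a tolerance below the blood/tissue contrast keeps blood out of tissue
    vol = phantom48.mu_volume(0, 29.5)
    seeds = SeedSet(seeds=seeds_from_labels(phantom48.labels[0]),
                    default_tolerance=0.002)
    pred = region_grow_segment(vol, seeds)
    blood = np.isin(pred, [1, 2, 3, 4, 5, 6, 7])
    myo_truth = phantom48.labels[0] == STRUCTURE_IDS["myocardium"]
    leak = np.sum(blood & myo_truth) / myo_truth.sum()
    assert leak < 0.05


def test_noise_sd_estimate(rng):
    vol = rng.normal(0.0, 0.5, (32, 32, 32))
    assert estimate_noise_sd(vol) == pytest.approx(0.5, rel=0.2)
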