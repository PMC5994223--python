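"""Segmentation, calibration, detection, assignment and region metrics."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import brute_force_assign, run_quantification
from pairfish.quantify import (
    CalibrationError, CalibrationResult, Dot, NucleusSet, assign_dots,
    calibrate, detect_dots, quantify_region, segment_nuclei,
)
from pairfish.simulate import SimParams, simulate_field


def manual_cal(thr, diam=3.0):
    return CalibrationResult(
        intensity_threshold=thr, diameter_threshold_px=diam,
        ko_background_mean=0.0, ko_background_sd=0.0, k_sigma=0.0,
    )


def disk_mask(shape, centers_radii):
    """Labelled disks for constructed fixtures."""
    mask = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for label, (cy, cx, r) in enumerate(centers_radii, start=1):
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = label
    return mask


def nucleus_set_from_mask(mask):
    from skimage.measure import regionprops
    import pandas as pd
    recs = [{"label": p.label, "centroid_row": p.centroid[0],
             "centroid_col": p.centroid[1], "area_px": int(p.area),
             "equivalent_diameter": p.equivalent_diameter_area}
            for p in regionprops(mask)]
    return NucleusSet(label_mask=mask, records=pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# segmentation

def test_blank_channel_segments_to_zero_nuclei():
    assert len(segment_nuclei(np.zeros((64, 64)))) == 0


def test_segmentation_recovers_simulated_nuclei():
    params = SimParams(seed=21)
    img, truth = simulate_field(params)
    nuclei = segment_nuclei(img.nuclear)
    assert len(nuclei) == params.n_nuclei
    true_centers = np.array([c for _, c, _ in truth.nuclei])
    est = nuclei.records[["centroid_row", "centroid_col"]].to_numpy()
    d, _ = cKDTree(true_centers).query(est)
    assert d.max() < 2.0


def test_watershed_splits_fused_disks():
    img = np.zeros((64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    for cy, cx in [(32, 24), (32, 40)]:  # overlapping disks with a neck
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 100] = 1000.0
    img[0, 0] = 1.0  # break constant-image degeneracy for Otsu
    nuclei = segment_nuclei(img, min_area_px=30, smoothing_sigma=1.0)
    assert len(nuclei) == 2


def test_segmentation_labels_consecutive_and_disjoint():
    img, _ = simulate_field(SimParams(image_shape=(256, 256), n_nuclei=25, seed=4))
    nuclei = segment_nuclei(img.nuclear)
    labels = sorted(nuclei.labels)
    assert labels == list(range(1, len(labels) + 1))
    assert set(np.unique(nuclei.label_mask)) == {0, *labels}


# ---------------------------------------------------------------------------
# calibration

def test_calibration_threshold_from_ko_noise_statistics():
    rng = np.random.default_rng(0)
    ko = rng.normal(100.0, 10.0, size=(512, 512))
    cal = calibrate([ko], k_sigma=3.0)
    assert cal.intensity_threshold == pytest.approx(130.0, abs=1.0)
    assert cal.ko_background_mean == pytest.approx(100.0, abs=0.5)
    assert cal.diameter_threshold_px == 3.0  # the default >= 3 px rule
    cal0 = calibrate([ko], k_sigma=0.0)
    assert cal0.intensity_threshold == pytest.approx(cal0.ko_background_mean)


def test_calibration_requires_negative_control():
    with pytest.raises(CalibrationError):
        calibrate([])
    with pytest.raises(CalibrationError):
        calibrate([np.zeros((8, 8))], k_sigma=-1.0)


def test_calibration_wt_derived_diameter():
    rng = np.random.default_rng(1)
    ko = rng.normal(100.0, 10.0, size=(256, 256))
    wt = rng.normal(100.0, 10.0, size=(256, 256))
    yy, xx = np.mgrid[0:256, 0:256]
    diams = []
    for cy, cx in [(40, 40), (120, 200), (200, 80)]:
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= 5 ** 2
        wt[disk] = 5000.0
        diams.append(2 * math.sqrt(disk.sum() / math.pi))
    cal = calibrate([ko], [wt], mode="wt-derived", wt_fraction=0.5)
    assert cal.wt_mean_dot_diameter == pytest.approx(np.mean(diams), abs=0.5)
    assert cal.diameter_threshold_px == math.floor(cal.wt_mean_dot_diameter * 0.5)
    assert cal.diameter_threshold_px == 5.0


def test_calibration_percentile_mode():
    rng = np.random.default_rng(2)
    ko = rng.normal(100.0, 10.0, size=(512, 512))
    cal = calibrate([ko], stat_mode="percentile", percentile=99.9)
    assert cal.intensity_threshold == pytest.approx(
        np.percentile(ko, 99.9), rel=1e-9)


# ---------------------------------------------------------------------------
# detection

def test_detect_blank_image_yields_nothing():
    assert detect_dots(np.zeros((64, 64)), manual_cal(50.0)) == []


def test_diameter_filter_boundary():
    """Components below ~3 px equivalent diameter are rejected; those at or
    above are retained (area 7 -> 2.99 px rejected, area 8 -> 3.19 px kept)."""
    img = np.zeros((64, 64))
    img[5:7, 5:7] = 200.0            # area 4, eq diam 2.26 -> rejected
    img[20:22, 20:24] = 200.0        # area 8, eq diam 3.19 -> retained
    img[40:41, 40:47] = 200.0        # area 7, eq diam 2.99 -> rejected
    img[50:53, 50:53] = 200.0        # area 9, eq diam 3.39 -> retained
    dots = detect_dots(img, manual_cal(100.0))
    assert sorted(d.area_px for d in dots) == [8, 9]
    assert all(d.equivalent_diameter >= 3.0 - 1e-9 for d in dots)


def test_detection_strictly_above_threshold_and_connectivity():
    img = np.zeros((32, 32))
    img[4:7, 4:7] = 100.0  # exactly at threshold -> not "above"
    assert detect_dots(img, manual_cal(100.0)) == []
    # diagonal touching merges under 8-connectivity, splits under 4
    img = np.zeros((32, 32))
    img[8:11, 8:11] = 200.0
    img[11:14, 11:14] = 200.0
    assert len(detect_dots(img, manual_cal(100.0), connectivity=8)) == 1
    assert len(detect_dots(img, manual_cal(100.0), connectivity=4)) == 2


def test_declump_splits_fused_dots():
    yy, xx = np.mgrid[0:48, 0:48]
    img = np.zeros((48, 48))
    for cy, cx in [(24, 20), (24, 29)]:
        img += 800.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.5 ** 2))
    merged = detect_dots(img, manual_cal(100.0))
    assert len(merged) == 1
    split = detect_dots(img, manual_cal(100.0), declump=True,
                        max_single_dot_area_px=40)
    assert len(split) == 2


def test_raising_threshold_never_increases_dot_count():
    img, _ = simulate_field(SimParams(image_shape=(256, 256), n_nuclei=30, seed=9))
    counts = [len(detect_dots(img.signal, manual_cal(t)))
              for t in (320.0, 360.0, 420.0, 600.0)]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# assignment

def test_dot_inside_nucleus_gets_zero_distance():
    mask = disk_mask((64, 64), [(10, 10, 5)] * 0 + [(10, 10, 5), (40, 40, 5),
                                                    (20, 50, 4), (50, 15, 4),
                                                    (32, 28, 4)])
    nuclei = nucleus_set_from_mask(mask)
    d = Dot(centroid=(32.0, 28.0), area_px=9, equivalent_diameter=3.4,
            mean_intensity=1.0)
    assign_dots([d], nuclei)
    assert d.assigned_label == 5 and d.distance_to_nucleus == 0.0


def test_equidistant_dot_goes_to_lowest_label():
    mask = np.zeros((32, 64), dtype=np.int32)
    mask[10:20, 10:15] = 2   # right edge at col 14
    mask[10:20, 35:40] = 7   # left edge at col 35
    nuclei = nucleus_set_from_mask(mask)
    # centroid not on an integer pixel, equidistant to both masks
    d = Dot(centroid=(15.3, 24.5), area_px=9, equivalent_diameter=3.4,
            mean_intensity=1.0)
    assign_dots([d], nuclei)
    assert d.assigned_label == 2


def test_far_dot_stays_unassigned():
    mask = disk_mask((128, 128), [(20, 20, 6)])
    nuclei = nucleus_set_from_mask(mask)
    d = Dot(centroid=(120.0, 120.0), area_px=9, equivalent_diameter=3.4,
            mean_intensity=1.0)
    assign_dots([d], nuclei, max_distance_px=30.0)
    assert d.assigned_label is None


def test_no_nuclei_warns_and_leaves_unassigned():
    nuclei = segment_nuclei(np.zeros((32, 32)))
    d = Dot(centroid=(5.0, 5.0), area_px=9, equivalent_diameter=3.4,
            mean_intensity=1.0)
    with pytest.warns(UserWarning):
        assign_dots([d], nuclei)
    assert d.assigned_label is None


def test_assignment_agrees_with_brute_force_on_random_fields():
    """Accelerated nearest-mask search must replicate the exhaustive oracle
    for every dot, including the tie rule."""
    rng = np.random.default_rng(17)
    for _ in range(3):
        centers = [(rng.uniform(10, 118), rng.uniform(10, 118),
                    rng.uniform(4, 8)) for _ in range(12)]
        mask = disk_mask((128, 128), centers)
        nuclei = nucleus_set_from_mask(mask)
        dots = [Dot(centroid=(rng.uniform(0, 128), rng.uniform(0, 128)),
                    area_px=9, equivalent_diameter=3.4, mean_intensity=1.0)
                for _ in range(60)]
        assign_dots(dots, nuclei)
        expected = brute_force_assign(dots, nuclei)
        for d, (lab, dist) in zip(dots, expected):
            assert d.assigned_label == lab
            if lab is not None:
                assert d.distance_to_nucleus == pytest.approx(dist, abs=1e-9)


# ---------------------------------------------------------------------------
# region metrics

def _dots_with_counts(nuclei, counts):
    dots = []
    for label, k in counts.items():
        for _ in range(k):
            d = Dot(centroid=(0.0, 0.0), area_px=9, equivalent_diameter=3.4,
                    mean_intensity=1.0)
            d.assigned_label = label
            dots.append(d)
    return dots


def test_region_metric_arithmetic():
    mask = disk_mask((256, 256), [(20 + 22 * i, 128, 8) for i in range(10)])
    nuclei = nucleus_set_from_mask(mask)
    dots = _dots_with_counts(nuclei, {1: 3, 4: 1})
    table = quantify_region(dots, nuclei, field_area_mm2=0.5)
    assert table.pct_positive_cells == 20.0
    assert table.mean_dots_per_positive_cell == 2.0
    assert table.dots_per_area == len(dots) / 0.5
    assert table.per_cell.dot_count.sum() == table.n_assigned == 4
    assert table.histogram.set_index("bin").n_cells.to_dict()[1] == 1
    assert table.histogram.set_index("bin").n_cells.to_dict()[3] == 1


def test_zero_nuclei_reports_missing_not_zero():
    nuclei = segment_nuclei(np.zeros((32, 32)))
    table = quantify_region([], nuclei, field_area_mm2=0.1)
    assert math.isnan(table.pct_positive_cells)
    assert math.isnan(table.mean_dots_per_positive_cell)
    assert table.dots_per_area == 0.0


def test_histogram_last_bin_open_ended():
    mask = disk_mask((128, 128), [(20, 20, 8), (60, 60, 8)])
    nuclei = nucleus_set_from_mask(mask)
    dots = _dots_with_counts(nuclei, {1: 20, 2: 2})
    table = quantify_region(dots, nuclei, 0.1, histogram_max_bin=15)
    h = table.histogram.set_index("bin").n_cells
    assert h[15] == 1 and h[2] == 1 and h.sum() == 2


def test_raising_positivity_cutoff_never_increases_pct():
    _, _, _, nuclei, dots, _ = run_quantification(
        SimParams(image_shape=(256, 256), n_nuclei=40, seed=2))
    pcts = [quantify_region(dots, nuclei, 0.1, positive_min_dots=m
                            ).pct_positive_cells for m in (1, 2, 3, 5)]
    assert pcts == sorted(pcts, reverse=True)


def test_count_conservation_assigned_plus_unassigned():
    _, _, _, nuclei, dots, table = run_quantification(
        SimParams(image_shape=(256, 256), n_nuclei=40, seed=3))
    unassigned = sum(1 for d in dots if d.assigned_label is None)
    assert table.per_cell.dot_count.sum() + unassigned == len(dots)


def test_pipeline_invariant_under_integer_translation():
    params = SimParams(image_shape=(256, 256), n_nuclei=25, seed=5)
    img, _ = simulate_field(params)
    cal = manual_cal(360.0)

    def metrics(nuclear, signal):
        nuclei = segment_nuclei(nuclear)
        dots = detect_dots(signal, cal)
        assign_dots(dots, nuclei)
        t = quantify_region(dots, nuclei, params.field_area_mm2)
        return (t.n_nuclei, t.n_dots, t.pct_positive_cells,
                sorted(t.per_cell.dot_count))

    shifted = metrics(np.roll(img.nuclear, (7, 11), axis=(0, 1)),
                      np.roll(img.signal, (7, 11), axis=(0, 1)))
    assert metrics(img.nuclear, img.signal) == shifted
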