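import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pairfish.minigene import erbb4_minigene
from pairfish.quantify import (
    assign_dots, calibrate, detect_dots, quantify_region, segment_nuclei,
)
from pairfish.simulate import SimParams, simulate_field, simulate_negative_control


@pytest.fixture(scope="session")
def gene_model():
    return erbb4_minigene()


@pytest.fixture(scope="session")
def model_by_id(gene_model):
    return {iso.isoform_id: iso for iso in gene_model}


@pytest.fixture(scope="session")
def small_params():
    """A fast small field for pipeline-level tests."""
    return SimParams(image_shape=(256, 256), n_nuclei=40, seed=0)


def run_quantification(params: SimParams, cal_seed_offset: int = 5000):
    """Full pipeline on one simulated field, calibrated on a matched KO field."""
    img, truth = simulate_field(params)
    ko_img, _ = simulate_negative_control(
        dataclasses.replace(params, seed=params.seed + cal_seed_offset)
    )
    cal = calibrate([ko_img.signal])
    nuclei = segment_nuclei(img.nuclear)
    dots = detect_dots(img.signal, cal)
    assign_dots(dots, nuclei)
    table = quantify_region(dots, nuclei, params.field_area_mm2)
    return img, truth, cal, nuclei, dots, table


def brute_force_assign(dots, nuclei, max_distance_px=30.0):
    """Independent exhaustive nearest-mask assignment oracle.

    For each dot, the distance to each nucleus is 0 if the rounded centroid
    pixel lies in its mask, else the minimum Euclidean distance from the
    sub-pixel centroid to any mask pixel; the dot goes to the closest nucleus
    (lowest label on ties) if within ``max_distance_px``.
    """
    mask = nuclei.label_mask
    labels = sorted(int(l) for l in nuclei.labels)
    pixels = {l: np.argwhere(mask == l) for l in labels}
    out = []
    for d in dots:
        r, c = d.centroid
        ri = min(max(int(round(r)), 0), mask.shape[0] - 1)
        ci = min(max(int(round(c)), 0), mask.shape[1] - 1)
        best_label, best_dist = None, np.inf
        for l in labels:
            if mask[ri, ci] == l:
                dist = 0.0
            else:
                px = pixels[l]
                dist = float(np.sqrt(
                    ((px[:, 0] - r) ** 2 + (px[:, 1] - c) ** 2).min()
                ))
            if dist < best_dist - 1e-9:
                best_label, best_dist = l, dist
        if best_dist > max_distance_px:
            best_label = None
        out.append((best_label, best_dist))
    return out
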