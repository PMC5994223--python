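"""End-to-end composition: calibrate -> segment -> detect -> assign ->
quantify -> (optional) group statistics, with provenance-stamped CSV/JSON
outputs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .quantify import (
    CalibrationResult, CellQuantTable, assign_dots, calibrate, detect_dots,
    quantify_region, segment_nuclei,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunResult", "read_channels", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunResult:
    calibration: CalibrationResult
    tables: dict[str, CellQuantTable]
    region_summary: pd.DataFrame
    output_dir: Path | None = None
    files: dict[str, Path] = field(default_factory=dict)


def read_channels(path: str | Path, config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Read (nuclear, signal) channels from a single- or multi-page TIFF."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        return arr, arr
    if arr.ndim == 3:
        # channel axis is whichever axis is smallest (pages or last axis)
        ch_axis = int(np.argmin(arr.shape))
        arr = np.moveaxis(arr, ch_axis, 0)
        try:
            return arr[config.nuclear_channel], arr[config.signal_channel]
        except IndexError as err:
            raise PipelineError("io", f"channel index out of range for {path}: {err}")
    raise PipelineError("io", f"unsupported TIFF dimensionality {arr.shape}")


def _provenance_header(config: RunConfig) -> str:
    return (f"# pairfish {__version__}\n"
            f"# config_hash: {config.config_hash()}\n")


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> Path:
    with path.open("w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def run_pipeline(
    config: RunConfig,
    ko_images: Sequence[str | Path] | Sequence[tuple[np.ndarray, np.ndarray]],
    sample_images: dict[str, str | Path] | dict[str, tuple[np.ndarray, np.ndarray]],
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the full workflow.

    ``ko_images`` are negative-control fields used only for intensity
    calibration; ``sample_images`` maps an image id to a TIFF path or an
    in-memory ``(nuclear, signal)`` pair.  Writes calibration JSON, per-cell
    CSVs and a region-summary CSV (all stamped with the config hash) when
    ``out_dir`` is given.
    """
    t0 = time.perf_counter()
    if not ko_images:
        raise PipelineError("calibration", "calibration requires a negative control")
    if not sample_images:
        raise PipelineError("io", "no sample images given")

    def load(item):
        if isinstance(item, (str, Path)):
            return read_channels(item, config)
        return item

    try:
        ko_pairs = [load(im) for im in ko_images]
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineError("io", f"failed reading KO images: {err}")

    try:
        cal = calibrate(
            [sig for _, sig in ko_pairs],
            k_sigma=config.k_sigma,
            fixed_diameter_px=config.fixed_diameter_px,
            mode=config.diameter_mode,
            wt_fraction=config.wt_fraction,
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("calibration", str(err))
    log.info("calibration: threshold=%.2f diameter>=%.2f px (%.2fs)",
             cal.intensity_threshold, cal.diameter_threshold_px,
             time.perf_counter() - t0)

    area_per_px_mm2 = (config.pixel_size_um * 1e-3) ** 2
    tables: dict[str, CellQuantTable] = {}
    summary_rows = []
    for image_id, item in sample_images.items():
        ts = time.perf_counter()
        nuclear, signal = load(item)
        try:
            nuclei = segment_nuclei(
                nuclear,
                min_area_px=config.min_nucleus_area_px,
                max_area_px=config.max_nucleus_area_px,
                smoothing_sigma=config.smoothing_sigma,
            )
        except Exception as err:  # noqa: BLE001
            raise PipelineError("segmentation", f"{image_id}: {err}")
        try:
            dots = detect_dots(
                signal, cal,
                connectivity=config.connectivity,
                declump=config.declump,
                max_single_dot_area_px=config.max_single_dot_area_px,
            )
            assign_dots(dots, nuclei, max_distance_px=config.max_distance_px)
        except Exception as err:  # noqa: BLE001
            raise PipelineError("detection", f"{image_id}: {err}")
        table = quantify_region(
            dots, nuclei, signal.size * area_per_px_mm2,
            positive_min_dots=config.positive_min_dots,
            histogram_max_bin=config.histogram_max_bin,
        )
        tables[image_id] = table
        summary_rows.append({
            "image_id": image_id,
            "n_nuclei": table.n_nuclei,
            "n_dots": table.n_dots,
            "n_assigned": table.n_assigned,
            "dots_per_mm2": table.dots_per_area,
            "pct_positive_cells": table.pct_positive_cells,
            "mean_dots_per_positive_cell": table.mean_dots_per_positive_cell,
        })
        log.info("%s: %d nuclei, %d dots (%.2fs)", image_id,
                 table.n_nuclei, table.n_dots, time.perf_counter() - ts)

    region_summary = pd.DataFrame(summary_rows)
    result = RunResult(calibration=cal, tables=tables,
                       region_summary=region_summary)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cal_path = out / "calibration.json"
        cal_path.write_text(json.dumps(
            {"config_hash": config.config_hash(),
             "pairfish_version": __version__, **cal.to_dict()},
            indent=1, sort_keys=True,
        ))
        result.files["calibration"] = cal_path
        for image_id, table in tables.items():
            df = table.per_cell.copy()
            df.insert(0, "image_id", image_id)
            result.files[f"per_cell/{image_id}"] = _write_csv(
                df, out / f"per_cell_{image_id}.csv", config)
            hist = table.histogram.copy()
            hist.insert(0, "image_id", image_id)
            result.files[f"histogram/{image_id}"] = _write_csv(
                hist, out / f"histogram_{image_id}.csv", config)
        result.files["region_summary"] = _write_csv(
            region_summary, out / "region_summary.csv", config)
        result.output_dir = out
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return result
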