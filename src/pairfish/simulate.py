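"""Synthetic two-channel ISH fields with full ground truth.

Emulates the imaging regime of chromogenic/fluorescent single-pair-probe ISH
on tissue sections: a nuclear-stain channel of non-overlapping roughly
circular nuclei, and a signal channel of sparse diffraction-limited puncta
("dots") placed perinuclearly around the fraction of cells that express the
target, plus a low uniform rate of isolated nonspecific background dots.
Negative-control (knock-out-like) fields are the same model with the
expressing fraction forced to zero, so residual signal is background only.
Occasional "clump" artifacts — a cell's dots fused into one accumulation, as
produced by enzymatic dye conversion on abundant targets — can be simulated.

Every field comes with its :class:`GroundTruth` (nuclei, per-cell true dot
counts, dot coordinates with ownership), making detection, assignment and the
downstream statistics testable without real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimParams", "GroundTruth", "FieldImage",
    "simulate_field", "simulate_negative_control", "write_field",
]

_DTYPE = np.uint16
_DTYPE_MAX = np.iinfo(_DTYPE).max


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic field.

    Defaults emulate a 20x-like acquisition (0.325 µm/px, 16-bit) of a field
    with ~200 nuclei in which 20 % of cells express the target at a mean of
    5 dots/cell, with a sparse nonspecific background of isolated dots.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.325
    n_nuclei: int = 200
    nucleus_radius_px: tuple[float, float] = (8.0, 12.0)
    positive_fraction: float = 0.20
    dots_family: Literal["poisson", "gamma-poisson"] = "poisson"
    dots_mean: float = 5.0
    dots_dispersion: float = 1.0  # gamma shape for gamma-poisson
    dot_peak_intensity: tuple[float, float] = (1500.0, 200.0)  # (mean, sd)
    psf_sigma_px: float = 1.2
    baseline: float = 200.0
    background_noise_sd: float = 50.0
    background_dot_rate_per_mm2: float = 150.0
    clump_prob: float = 0.02
    annulus: tuple[float, float] = (0.2, 1.2)  # x nucleus radius
    min_dot_spacing_px: float | None = 7.0
    nucleus_intensity: tuple[float, float] = (3000.0, 300.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        for name in ("background_dot_rate_per_mm2", "dots_mean",
                     "background_noise_sd", "clump_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nucleus_radius_px[0] > self.nucleus_radius_px[1]:
            raise ValueError("nucleus_radius_px must be (min, max)")

    @property
    def field_area_mm2(self) -> float:
        r, c = self.image_shape
        return r * c * (self.pixel_size_um * 1e-3) ** 2


@dataclass
class FieldImage:
    nuclear: np.ndarray  # uint16, (rows, cols)
    signal: np.ndarray   # uint16, (rows, cols)
    pixel_size_um: float


@dataclass
class GroundTruth:
    """Known nuclei and dots of a simulated field.

    ``dot_coords`` rows are (row, col, owner_label); owner_label is the
    owning nucleus label, or 0 for unowned background dots.
    """

    nuclei: list[tuple[int, tuple[float, float], float]]  # (label, centroid, radius)
    per_cell_true_count: dict[int, int]
    dot_coords: list[tuple[float, float, int]] = field(default_factory=list)

    @property
    def n_owned_dots(self) -> int:
        return sum(1 for *_, owner in self.dot_coords if owner != 0)

    @property
    def n_background_dots(self) -> int:
        return sum(1 for *_, owner in self.dot_coords if owner == 0)


def _place_nuclei(params: SimParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping nuclei (>=2 px clearance)."""
    rows, cols = params.image_shape
    r_min, r_max = params.nucleus_radius_px
    margin = r_max + 2.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts, max_attempts = 0, 200 * max(params.n_nuclei, 1)
    while len(centers) < params.n_nuclei:
        if attempts >= max_attempts:
            raise SimulationError(
                f"could not place {params.n_nuclei} non-overlapping nuclei in "
                f"{params.image_shape} after {max_attempts} attempts; reduce "
                "n_nuclei or nucleus_radius_px"
            )
        attempts += 1
        r = rng.uniform(r_min, r_max)
        cy = rng.uniform(margin, rows - margin)
        cx = rng.uniform(margin, cols - margin)
        ok = all(
            (cy - y) ** 2 + (cx - x) ** 2 >= (r + rr + 2.0) ** 2
            for (y, x), rr in zip(centers, radii)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def _render_gaussians(shape, coords, amplitudes, sigma) -> np.ndarray:
    """Sum of isotropic 2-D Gaussians, rendered on a +/-4 sigma support."""
    img = np.zeros(shape, dtype=np.float64)
    half = max(1, int(np.ceil(4 * sigma)))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    for (r, c), amp in zip(coords, amplitudes):
        ri, ci = int(round(r)), int(round(c))
        dy, dx = r - ri, c - ci
        patch = amp * np.exp(
            -((yy - dy) ** 2 + (xx - dx) ** 2) / (2.0 * sigma ** 2)
        )
        r0, r1 = ri - half, ri + half + 1
        c0, c1 = ci - half, ci + half + 1
        pr0, pc0 = max(0, -r0), max(0, -c0)
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(shape[0], r1), min(shape[1], c1)
        if r1 <= r0 or c1 <= c0:
            continue
        img[r0:r1, c0:c1] += patch[pr0:pr0 + (r1 - r0), pc0:pc0 + (c1 - c0)]
    return img


def _sample_counts(params: SimParams, n: int, rng: np.random.Generator):
    if params.dots_family == "poisson":
        return rng.poisson(params.dots_mean, size=n)
    # gamma-poisson (negative binomial): mean m, gamma shape = dispersion
    shape = params.dots_dispersion
    lam = rng.gamma(shape, params.dots_mean / shape, size=n)
    return rng.poisson(lam)


def simulate_field(params: SimParams) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel field and its ground truth.

    Reproducible: the same ``params`` (including ``seed``) yield bit-identical
    images and identical ground truth.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_shape

    centers, radii = _place_nuclei(params, rng)
    labels = list(range(1, len(centers) + 1))

    # ---- nuclear channel: smoothed disks + read noise
    yy, xx = np.mgrid[0:rows, 0:cols]
    nuclear = np.full((rows, cols), params.baseline, dtype=np.float64)
    for (cy, cx), r in zip(centers, radii):
        amp = rng.normal(*params.nucleus_intensity)
        y0, y1 = int(cy - r - 3), int(cy + r + 4)
        x0, x1 = int(cx - r - 3), int(cx + r + 4)
        sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        d = np.sqrt((sub_y - cy) ** 2 + (sub_x - cx) ** 2)
        # soft-edged disk (1.5 px shoulder) approximates optical blur
        nuclear[y0:y1, x0:x1] += amp / (1.0 + np.exp((d - r) / 0.75))
    nuclear += rng.normal(0.0, params.background_noise_sd, size=(rows, cols))

    # ---- expression draw
    expressing = rng.random(len(centers)) < params.positive_fraction
    counts = _sample_counts(params, len(centers), rng)
    counts[~expressing] = 0

    dot_coords: list[tuple[float, float, int]] = []
    per_cell: dict[int, int] = {}

    def spaced_ok(r, c) -> bool:
        if params.min_dot_spacing_px is None:
            return True
        s2 = params.min_dot_spacing_px ** 2
        return all((r - dr) ** 2 + (c - dc) ** 2 >= s2
                   for dr, dc, _ in dot_coords)

    lo_f, hi_f = params.annulus
    for label, (cy, cx), rad, k in zip(labels, centers, radii, counts):
        per_cell[label] = int(k)
        if k == 0:
            continue
        placed = 0
        guard = 0
        while placed < k and guard < 500 * k:
            guard += 1
            rho = rad * np.sqrt(rng.uniform(lo_f ** 2, hi_f ** 2))
            theta = rng.uniform(0, 2 * np.pi)
            r = cy + rho * np.sin(theta)
            c = cx + rho * np.cos(theta)
            if not (3 <= r < rows - 3 and 3 <= c < cols - 3):
                continue
            if not spaced_ok(r, c):
                continue
            dot_coords.append((float(r), float(c), label))
            placed += 1
        # clump artifact: collapse the cell's dots onto one center (<1 px jitter)
        if placed > 1 and rng.random() < params.clump_prob:
            center_idx = len(dot_coords) - placed
            r0, c0, _ = dot_coords[center_idx]
            for i in range(center_idx, len(dot_coords)):
                jr, jc = rng.uniform(-0.5, 0.5, size=2)
                dot_coords[i] = (float(r0 + jr), float(c0 + jc), label)
        per_cell[label] = placed

    # ---- background (nonspecific) dots, uniform over the field
    n_bg = rng.poisson(params.background_dot_rate_per_mm2 * params.field_area_mm2)
    placed_bg = 0
    guard = 0
    while placed_bg < n_bg and guard < 1000 * max(n_bg, 1):
        guard += 1
        r = rng.uniform(3, rows - 3)
        c = rng.uniform(3, cols - 3)
        if not spaced_ok(r, c):
            continue
        dot_coords.append((float(r), float(c), 0))
        placed_bg += 1

    # ---- signal channel
    signal = np.full((rows, cols), params.baseline, dtype=np.float64)
    if dot_coords:
        amp_mean, amp_sd = params.dot_peak_intensity
        amps = rng.normal(amp_mean, amp_sd, size=len(dot_coords))
        amps = np.clip(amps, amp_mean * 0.2, None)
        signal += _render_gaussians(
            (rows, cols), [(r, c) for r, c, _ in dot_coords], amps,
            params.psf_sigma_px,
        )
    signal += rng.normal(0.0, params.background_noise_sd, size=(rows, cols))

    image = FieldImage(
        nuclear=np.clip(np.rint(nuclear), 0, _DTYPE_MAX).astype(_DTYPE),
        signal=np.clip(np.rint(signal), 0, _DTYPE_MAX).astype(_DTYPE),
        pixel_size_um=params.pixel_size_um,
    )
    truth = GroundTruth(
        nuclei=[(l, (cy, cx), r)
                for l, (cy, cx), r in zip(labels, centers, radii)],
        per_cell_true_count=per_cell,
        dot_coords=dot_coords,
    )
    return image, truth


def simulate_negative_control(params: SimParams) -> tuple[FieldImage, GroundTruth]:
    """Knock-out-like field: no expressing cells, background dots only."""
    return simulate_field(dataclasses.replace(params, positive_fraction=0.0))


def write_field(
    image: FieldImage, truth: GroundTruth, out_dir: str | Path,
    stem: str = "field",
) -> dict[str, Path]:
    """Write a two-page TIFF plus ground-truth JSON and per-cell truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = out / f"{stem}.tif"
    tifffile.imwrite(
        tif, np.stack([image.nuclear, image.signal]),
        metadata={"axes": "CYX", "pixel_size_um": image.pixel_size_um},
    )
    gt_json = out / f"{stem}_truth.json"
    gt_json.write_text(json.dumps({
        "pixel_size_um": image.pixel_size_um,
        "nuclei": [
            {"label": l, "centroid": list(cen), "radius": r}
            for l, cen, r in truth.nuclei
        ],
        "per_cell_true_count": {str(k): v
                                for k, v in truth.per_cell_true_count.items()},
        "dot_coords": [list(d) for d in truth.dot_coords],
    }, indent=1))
    csv_path = out / f"{stem}_truth_cells.csv"
    pd.DataFrame(
        [{"nucleus_label": l, "true_dot_count": truth.per_cell_true_count[l]}
         for l, _, _ in truth.nuclei]
    ).to_csv(csv_path, index=False)
    return {"tiff": tif, "truth_json": gt_json, "truth_csv": csv_path}
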