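"""2D cell detection with shape filters, laminar assignment and colocalization.

Re-implementation of a particle-counting chain for confocal slice images:
optional median filter, Gaussian high-pass, local-mean (disk neighbourhood)
thresholding with a signed offset, 8-connected components, area and
circularity filters in physical units, and minimum-distance suppression.
Detected cells can then be binned into cortical layers (boundaries supplied
as pixel rows, drawn from a nuclear stain) and scored for marker
colocalization.

Offset sign convention: a pixel is positive iff value > local_mean - offset,
so the conventional offset of -30 demands value > local_mean + 30. This
matches the "Mean" auto-local-threshold convention of the common ImageJ
plugins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "CellCounterParams",
    "Cell2D",
    "detect_cells",
    "assign_layers",
    "colocalize",
    "local_mean_positive",
]

OUTSIDE_LAYER = "outside"


@dataclass
class CellCounterParams:
    """Detector parameterization, physical units where stated."""

    pixel_size_um: float = 0.645
    hp_sigma_um: float = 8.0
    local_radius_px: int = 25
    offset: float = -30.0
    area_range_um2: tuple[float, float] = (15.0, 140.0)
    circularity_range: tuple[float, float] = (0.1, 1.0)
    min_distance_um: float = 1.0
    median_radius_px: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.area_range_um2[0] > self.area_range_um2[1]:
            raise ValueError("area_range_um2 must be ordered")
        if self.circularity_range[0] > self.circularity_range[1]:
            raise ValueError("circularity_range must be ordered")
        if self.local_radius_px < 1:
            raise ValueError("local_radius_px must be >= 1")
        if self.median_radius_px < 0:
            raise ValueError("median_radius_px must be >= 0")


@dataclass
class Cell2D:
    """One detected cell. ``pixels`` holds the component's (row, col) indices
    in pixel coordinates for downstream colocalization."""

    centroid_um: tuple[float, float]  # (row_um, col_um)
    area_um2: float
    circularity: float
    layer: str | None = None
    markers: set[str] = field(default_factory=set)
    pixels: np.ndarray | None = None

    @property
    def centroid_px(self) -> tuple[float, float]:
        if self.pixels is None:
            raise ValueError("pixel support not retained")
        return tuple(self.pixels.mean(axis=0))


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def local_mean_positive(image: np.ndarray, params: CellCounterParams) -> np.ndarray:
    """Binary map of pixels exceeding the local disk mean minus ``offset``.

    The local mean is edge-normalized (the disk is clipped at image borders),
    so adding a constant to the whole image leaves the result unchanged.
    """
    img = np.asarray(image, dtype=float)
    disk = _disk_footprint(params.local_radius_px).astype(float)
    num = fftconvolve(img, disk, mode="same")
    den = fftconvolve(np.ones_like(img), disk, mode="same")
    local_mean = num / den
    return img > local_mean - params.offset


def _high_pass(image: np.ndarray, params: CellCounterParams) -> np.ndarray:
    sigma_px = params.hp_sigma_um / params.pixel_size_um
    img = np.asarray(image, dtype=float)
    return img - ndimage.gaussian_filter(img, sigma_px)


def _circularity(area_px: float, perimeter_px: float) -> float:
    if perimeter_px <= 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * area_px / perimeter_px**2)


def detect_cells(image: np.ndarray, params: CellCounterParams | None = None) -> list[Cell2D]:
    """Detect cells in a single-channel 2D image.

    Steps, in order: optional median filter; Gaussian high-pass; local-mean
    threshold; 8-connected components; area and circularity filters
    (circularity = 4 pi A / P^2 with the Crofton perimeter estimator, clipped
    at 1); minimum-distance suppression keeping the larger area (ties broken
    toward the lower (row, col) centroid).
    """
    if params is None:
        params = CellCounterParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got ndim={img.ndim}")
    if params.median_radius_px > 0:
        img = ndimage.median_filter(img, footprint=_disk_footprint(params.median_radius_px))
    img = _high_pass(img, params)
    binary = local_mean_positive(img, params)
    labels = cc_label(binary, connectivity=2)
    px2 = params.pixel_size_um**2
    cells: list[Cell2D] = []
    for prop in regionprops(labels):
        area_um2 = prop.area * px2
        if not params.area_range_um2[0] <= area_um2 <= params.area_range_um2[1]:
            continue
        circ = _circularity(prop.area, prop.perimeter_crofton)
        if not params.circularity_range[0] <= circ <= params.circularity_range[1]:
            continue
        cells.append(
            Cell2D(
                centroid_um=(
                    prop.centroid[0] * params.pixel_size_um,
                    prop.centroid[1] * params.pixel_size_um,
                ),
                area_um2=float(area_um2),
                circularity=float(circ),
                pixels=prop.coords.copy(),
            )
        )
    return _suppress_close(cells, params.min_distance_um)


def _suppress_close(cells: list[Cell2D], min_distance_um: float) -> list[Cell2D]:
    """Greedy suppression: keep larger-area cells; drop any remaining cell
    whose centroid lies closer than ``min_distance_um`` to a kept one."""
    order = sorted(
        cells, key=lambda c: (-c.area_um2, c.centroid_um[0], c.centroid_um[1])
    )
    kept: list[Cell2D] = []
    for c in order:
        if all(
            math.dist(c.centroid_um, k.centroid_um) >= min_distance_um for k in kept
        ):
            kept.append(c)
    kept.sort(key=lambda c: c.centroid_um)
    return kept


def assign_layers(
    cells: list[Cell2D],
    layer_boundaries_px: list[float],
    pixel_size_um: float = 0.645,
    layer_names: list[str] | None = None,
) -> pd.DataFrame:
    """Bin cells into cortical layers by centroid row.

    ``layer_boundaries_px`` are strictly increasing row coordinates; layer i
    spans [b_i, b_{i+1}) (half-open). Cells outside the outermost boundaries
    go to the sentinel layer "outside". Fractions are percentages of all
    cells and sum to 100 when any cell exists. Also sets ``cell.layer``.
    """
    b = list(layer_boundaries_px)
    if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
        raise ValueError("layer boundaries must be strictly increasing")
    if layer_names is None:
        layer_names = [f"layer_{i + 1}" for i in range(len(b) - 1)]
    if len(layer_names) != len(b) - 1:
        raise ValueError("need one name per layer interval")
    counts = {name: 0 for name in layer_names}
    counts[OUTSIDE_LAYER] = 0
    for c in cells:
        row_px = c.centroid_um[0] / pixel_size_um
        k = np.searchsorted(b, row_px, side="right") - 1
        if 0 <= k < len(layer_names) and row_px >= b[0]:
            name = layer_names[k]
        else:
            name = OUTSIDE_LAYER
        c.layer = name
        counts[name] += 1
    total = sum(counts.values())
    rows = [
        {
            "layer": name,
            "count": n,
            "fraction_pct": 100.0 * n / total if total else 0.0,
        }
        for name, n in counts.items()
        if not (name == OUTSIDE_LAYER and n == 0)
    ]
    return pd.DataFrame(rows, columns=["layer", "count", "fraction_pct"])


def colocalize(
    cells: list[Cell2D],
    marker_images: dict[str, np.ndarray],
    params: CellCounterParams | None = None,
    overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Score marker colocalization for detected cells.

    A cell is positive for a marker iff at least ``overlap_fraction`` of its
    pixels exceed that marker image's local-mean threshold (the same rule as
    the detection binarization). Updates ``cell.markers`` and returns a
    per-marker table (marker, co_positive_count, fraction_pct) where
    fractions are percentages of all detected cells.
    """
    if params is None:
        params = CellCounterParams()
    rows = []
    for name, img in marker_images.items():
        img = np.asarray(img, dtype=float)
        if img.ndim != 2:
            raise ValueError("marker images must be 2D")
        if cells:
            max_r = max(int(c.pixels[:, 0].max()) for c in cells if c.pixels is not None)
            max_c = max(int(c.pixels[:, 1].max()) for c in cells if c.pixels is not None)
            if img.shape[0] <= max_r or img.shape[1] <= max_c:
                raise ValueError(f"marker image {name!r} does not cover the detection image")
        binary = local_mean_positive(img, params)
        n_pos = 0
        for c in cells:
            if c.pixels is None:
                raise ValueError("cells lack pixel support; re-run detect_cells")
            frac = binary[c.pixels[:, 0], c.pixels[:, 1]].mean()
            if frac >= overlap_fraction:
                c.markers.add(name)
                n_pos += 1
        rows.append(
            {
                "marker": name,
                "co_positive_count": n_pos,
                "fraction_pct": 100.0 * n_pos / len(cells) if cells else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["marker", "co_positive_count", "fraction_pct"])
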