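"""Image-based cell shape quantification for suspension cultures.

Segments bright cells from a grayscale micrograph, measures each region's
ellipse-equivalent axes from second-order central moments, and computes
the roundness index

    R_c = 4 * area / (pi * major_axis^2),

which for an ideal ellipse equals the minor/major axis ratio.  Cells with
``R_c`` strictly above a threshold (0.8 by default) are counted as round;
the round-cell frequency is

    f_r = (# cells with R_c > threshold) / (total cells examined).

Circularity ``4 pi A / P^2`` is also measured as a secondary descriptor
but never used for ``f_r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import imageio.v3 as iio
from skimage import measure, segmentation
from skimage.filters import threshold_otsu

from .hydrodynamics import InvalidInputError
from .kinetics import UndefinedStatisticError

__all__ = [
    "CellRegion",
    "MorphologySummary",
    "ROUNDNESS_THRESHOLD",
    "DEFAULT_MIN_AREA",
    "read_image",
    "segment_cells",
    "roundness",
    "round_fraction",
]

#: Roundness threshold separating round from stretched cells.
ROUNDNESS_THRESHOLD = 0.8

#: Smallest region (px^2) kept by segmentation; rejects debris/noise specks.
DEFAULT_MIN_AREA = 50


@dataclass(frozen=True)
class CellRegion:
    """Per-cell shape measurements in pixel units."""

    label: int
    area: float  # px^2
    perimeter: float  # px
    major_axis: float  # px, ellipse-equivalent
    minor_axis: float  # px
    centroid: tuple[float, float]  # (row, col)
    roundness: float  # 4A / (pi major^2), clamped to (0, 1]
    circularity: float  # 4 pi A / P^2, secondary descriptor


@dataclass(frozen=True)
class MorphologySummary:
    """Round-cell frequency over a set of measured regions."""

    n_cells: int
    f_r: float
    threshold: float
    roundness_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "roundness_values", np.asarray(self.roundness_values, dtype=float)
        )


def read_image(path) -> np.ndarray:
    """Load a grayscale PNG/TIFF as a 2-D float array.

    RGB(A) images are averaged to a single channel.
    """
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D grayscale image, got shape {img.shape}")
    return img.astype(float)


def roundness(area: float, major_axis: float) -> float:
    """Roundness ``R_c = 4 A / (pi L_major^2)``, clamped to (0, 1].

    Rasterization can push the raw value slightly above 1 for small
    discs; values are clamped at 1.
    """
    if not (area > 0 and major_axis > 0):
        raise InvalidInputError(
            f"degenerate region: area={area}, major_axis={major_axis}"
        )
    return min(4.0 * area / (math.pi * major_axis**2), 1.0)


def segment_cells(
    image: np.ndarray,
    min_area: float = DEFAULT_MIN_AREA,
    threshold: Optional[float] = None,
) -> list[CellRegion]:
    """Segment bright cells on a dark background.

    Foreground is everything above Otsu's histogram-bimodality threshold
    unless a numeric ``threshold`` is given.  Connected components use
    8-connectivity; regions touching the image border or smaller than
    ``min_area`` are discarded.  A fully uniform image yields an empty
    list (not an error).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D image, got shape {img.shape}")
    if threshold is None:
        if np.ptp(img) == 0:
            return []
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    mask = segmentation.clear_border(mask)
    labels = measure.label(mask, connectivity=2)

    regions: list[CellRegion] = []
    for props in measure.regionprops(labels):
        if props.area < min_area:
            continue
        major = float(props.axis_major_length)
        minor = float(props.axis_minor_length)
        if major <= 0 or minor <= 0:
            continue
        perim = float(props.perimeter)
        regions.append(
            CellRegion(
                label=int(props.label),
                area=float(props.area),
                perimeter=perim,
                major_axis=major,
                minor_axis=minor,
                centroid=tuple(float(c) for c in props.centroid),
                roundness=roundness(float(props.area), major),
                circularity=4.0 * math.pi * float(props.area) / perim**2 if perim > 0 else float("nan"),
            )
        )
    return regions


def round_fraction(
    regions: Sequence[Union[CellRegion, float]],
    threshold: float = ROUNDNESS_THRESHOLD,
) -> MorphologySummary:
    """Round-cell frequency ``f_r`` with strict inequality at the threshold.

    Accepts :class:`CellRegion` objects or bare roundness values.
    """
    if len(regions) == 0:
        raise UndefinedStatisticError("round fraction undefined for an empty region list")
    values = np.array(
        [r.roundness if isinstance(r, CellRegion) else float(r) for r in regions]
    )
    f_r = float(np.count_nonzero(values > threshold)) / values.size
    return MorphologySummary(
        n_cells=int(values.size), f_r=f_r, threshold=threshold, roundness_values=values
    )
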