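"""ImageJ-style morphometric and intensity features of segmented nuclei.

Definitions follow the ImageJ User Guide conventions: the fitted ellipse
comes from central second-order moments, circularity is clamped at 1.0 on
coarse rasters, intensity skewness/kurtosis use the biased moment
estimators with kurtosis reported as excess.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.measure import approximate_polygon, find_contours, regionprops

from .segment import LabeledObject, PerimeterTrace, trace_perimeter, perimeter_length

__all__ = ["MorphometricRecord", "measure", "summarize_morpho", "FEATURE_NAMES"]

FEATURE_NAMES = [
    "area",
    "perimeter",
    "circularity",
    "aspect_ratio",
    "roundness",
    "solidity",
    "intensity_mean",
    "intensity_sd",
    "intensity_median",
    "intensity_skew",
    "intensity_kurt",
]


@dataclass
class MorphometricRecord:
    """Size, shape and gray-level statistics of one nucleus.

    area μm², perimeter μm, the shape ratios unitless, intensities in gray
    levels of the source image bit depth.
    """

    area: float
    perimeter: float
    circularity: float
    aspect_ratio: float
    roundness: float
    solidity: float
    intensity_mean: float
    intensity_sd: float
    intensity_median: float
    intensity_skew: float
    intensity_kurt: float
    ram_id: str = ""
    label: int = 0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if not (0 < self.circularity <= 1):
            raise ValueError("circularity out of (0, 1]")
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio must be >= 1")
        if not (0 < self.roundness <= 1 and 0 < self.solidity <= 1):
            raise ValueError("roundness/solidity out of (0, 1]")

    def to_dict(self) -> dict[str, float]:
        d = asdict(self)
        return {k: d[k] for k in FEATURE_NAMES}


def _biased_skew(x: np.ndarray) -> float:
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - x.mean()) ** 3) / m2**1.5)


def _biased_excess_kurtosis(x: np.ndarray) -> float:
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - x.mean()) ** 4) / m2**2 - 3.0)


def _subpixel_perimeter(
    mask: np.ndarray, pixel_size_um: float, tolerance_px: float = 1.0
) -> float:
    """Boundary length of the simplified marching-squares contour.

    The 0.5-level contour is reduced with Ramer–Douglas–Peucker at a
    one-pixel tolerance, which removes the rasterization staircase: the
    estimate is within ~1 % of the true length for smooth outlines (raw
    chain-code lengths overestimate those by ~5 %) while recovering the
    exact sides of polygonal objects.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    longest = max(contours, key=len)
    ring = longest[:-1] if np.allclose(longest[0], longest[-1]) else longest
    # canonical start and orientation so the simplification (and hence the
    # length) is identical for translated or 90-degree-rotated masks
    x, y = ring[:, 1], ring[:, 0]
    if np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        ring = ring[::-1]
    d2 = np.sum((ring - ring.mean(axis=0)) ** 2, axis=1)
    ring = np.roll(ring, -int(np.argmax(np.round(d2, 9))), axis=0)
    closed = np.vstack([ring, ring[:1]])
    simplified = approximate_polygon(closed, tolerance_px)
    d = np.diff(simplified, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum()) * pixel_size_um


def measure(
    obj: LabeledObject,
    intensity_image: np.ndarray,
    pixel_size_um: float,
    trace: PerimeterTrace | None = None,
    perimeter_method: str = "subpixel",
    ram_id: str = "",
) -> MorphometricRecord:
    """Measure one accepted object against its intensity image.

    area = pixel count × pixel_size²; perimeter from the boundary contour
    (``perimeter_method``: ``"subpixel"`` marching-squares length, the
    default, accurate for both smooth and polygonal outlines;
    ``"chain"`` / ``"chain_corrected"`` use the traced chain-code length);
    circularity = 4π·area/perimeter² clamped at 1;
    ellipse axes from second-order moments give aspect_ratio = major/minor
    and roundness = 4·area/(π·major²); solidity = area / convex-hull area;
    intensity statistics are computed over the member pixels only.
    """
    if intensity_image.shape != obj.image_shape:
        raise ValueError("intensity image shape does not match the segmented image")
    if trace is None:
        trace = trace_perimeter(obj, pixel_size_um, ram_id=ram_id)
    prop = regionprops(obj.mask.astype(np.uint8))[0]
    minor = prop.axis_minor_length * pixel_size_um
    major = prop.axis_major_length * pixel_size_um
    if minor <= 0:
        raise ValueError("degenerate ellipse fit (zero minor axis)")

    area = obj.area_px * pixel_size_um**2
    if perimeter_method == "subpixel":
        perim = _subpixel_perimeter(obj.mask, pixel_size_um)
    elif perimeter_method in {"chain", "chain_corrected"}:
        perim = perimeter_length(trace, corner_correction=perimeter_method == "chain_corrected")
    else:
        raise ValueError(f"unknown perimeter method {perimeter_method!r}")
    circ = min(1.0, 4.0 * np.pi * area / perim**2)
    roundness = min(1.0, 4.0 * area / (np.pi * major**2))
    values = obj.pixel_values(intensity_image).astype(float)

    return MorphometricRecord(
        area=float(area),
        perimeter=float(perim),
        circularity=float(circ),
        aspect_ratio=float(major / minor),
        roundness=float(roundness),
        solidity=float(obj.solidity),
        intensity_mean=float(values.mean()),
        intensity_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        intensity_median=float(np.median(values)),
        intensity_skew=_biased_skew(values),
        intensity_kurt=_biased_excess_kurtosis(values),
        ram_id=ram_id,
        label=obj.label,
    )


def summarize_morpho(records: list[MorphometricRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean and SEM over one ram's nuclei.

    Returns a DataFrame indexed by feature with columns ``mean`` and
    ``sem``.  Requires at least two records.
    """
    if isinstance(records, pd.DataFrame):
        df = records[FEATURE_NAMES]
    else:
        if len(records) == 0:
            raise ValueError("no morphometric records")
        df = pd.DataFrame([r.to_dict() for r in records])
    if len(df) < 2:
        raise ValueError("need at least 2 records to summarize")
    out = pd.DataFrame(
        {"mean": df.mean(), "sem": df.std(ddof=1) / np.sqrt(len(df))}
    )
    if out.isna().any().any():
        raise ValueError("NaN in morphometric summary")
    return out
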