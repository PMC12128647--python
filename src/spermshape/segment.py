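"""Nucleus segmentation: Laplacian-of-Gaussian thresholding, object QC and
perimeter tracing.

The workflow mirrors the fluorescence-image stage of sperm-head morphometry:
a Hoechst-stained nucleus image is filtered with a Laplacian of Gaussian,
thresholded, labeled, and each accepted object is reduced to a closed
perimeter trace in calibrated μm coordinates.  Objects that are too small or
large, touch the image border, or look like fused/overlapping nuclei (low
solidity or outsized area) are rejected with an explicit reason so the
audit trail matches a manual overlay check.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from . import _geometry as geom

__all__ = [
    "SegmentationError",
    "LabeledObject",
    "PerimeterTrace",
    "QCReport",
    "log_threshold",
    "extract_objects",
    "trace_perimeter",
    "perimeter_length",
    "overlay_qc",
    "segment_image",
]

#: default LoG scale (μm): about the nucleus edge scale, smooths shot noise
DEFAULT_SIGMA_UM = 0.3
#: area gates (μm^2) around the ~28 μm^2 nominal ram sperm nucleus
DEFAULT_MIN_AREA_UM2 = 10.0
DEFAULT_MAX_AREA_UM2 = 80.0
#: fused-object detection: solidity below this, or area above
#: ``DEFAULT_FUSED_AREA_FACTOR`` times the in-image median, flags an overlap
DEFAULT_SOLIDITY_CUTOFF = 0.92
DEFAULT_FUSED_AREA_FACTOR = 1.6

_CORNER_CORRECTION = 0.948  # optional smoothing factor for staircase perimeters


class SegmentationError(RuntimeError):
    pass


@dataclass
class LabeledObject:
    """One 8-connected component of a binary nucleus mask."""

    label: int
    mask: np.ndarray              # local boolean patch
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    image_shape: tuple[int, int]
    touches_border: bool
    area_px: int
    solidity: float
    rejected_reason: str = "none"  # none|too_small|too_large|border|overlap|interrupted_perimeter|manual

    @property
    def accepted(self) -> bool:
        return self.rejected_reason == "none"

    def full_mask(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out

    def pixel_values(self, image: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return np.asarray(image[r0:r1, c0:c1])[self.mask]


@dataclass
class PerimeterTrace:
    """Ordered closed contour of one nucleus in calibrated μm coordinates.

    Vertices are stored open (the closing edge is implicit); use
    :meth:`closed_vertices` for the explicit first==last convention.
    Orientation is counterclockwise in a y-up Cartesian frame with the
    origin at the image bottom-left.
    """

    vertices: np.ndarray          # (N, 2) x_um, y_um, open convention
    pixel_size_um: float
    ram_id: str = ""
    label: int = 0
    n_axial_steps: int = 0        # chain-code bookkeeping (0 when not pixel-traced)
    n_diagonal_steps: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if len(self.vertices) < 8:
            raise SegmentationError(
                f"interrupted_perimeter: only {len(self.vertices)} boundary vertices"
            )
        self.vertices = geom.ensure_ccw(self.vertices)

    def closed_vertices(self) -> np.ndarray:
        return np.vstack([self.vertices, self.vertices[:1]])

    def is_simple(self) -> bool:
        return geom.is_simple(self.vertices)

    def centroid(self) -> np.ndarray:
        return geom.polygon_centroid(self.vertices)

    def area(self) -> float:
        return abs(geom.signed_area(self.vertices))


def log_threshold(
    image: np.ndarray,
    sigma_um: float = DEFAULT_SIGMA_UM,
    pixel_size_um: float = 0.11,
    threshold_policy: str | float = "otsu",
) -> np.ndarray:
    """Binary nucleus mask from the negated Laplacian-of-Gaussian response.

    Policies
    --------
    ``"otsu"`` (default)
        Otsu's threshold on the -LoG response selects significant bright
        objects; the mask of each is then grown out to the response
        zero-crossing, which for a blurred step edge sits on the true
        boundary (a raw Otsu level would bite into the object by a
        fraction of the blur width).
    ``"otsu_level"``
        Plain Otsu level on the response, no zero-crossing refinement.
    float
        Explicit response threshold.

    Holes are filled.  A constant image yields an empty mask.
    """
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if sigma_um <= 0 or pixel_size_um <= 0:
        raise ValueError("sigma_um and pixel_size_um must be positive")
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    sigma_px = sigma_um / pixel_size_um
    response = -ndi.gaussian_laplace(img, sigma=sigma_px)

    if isinstance(threshold_policy, (int, float)) and not isinstance(threshold_policy, bool):
        mask = response > float(threshold_policy)
    elif threshold_policy == "otsu_level":
        mask = response > threshold_otsu(response)
    elif threshold_policy == "otsu":
        seeds = response > threshold_otsu(response)
        positive = response > 0.0
        # keep positive-response components that contain an Otsu seed
        lab, n = ndi.label(positive, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return np.zeros(img.shape, dtype=bool)
        seeded = np.unique(lab[seeds & (lab > 0)])
        mask = np.isin(lab, seeded[seeded > 0])
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    return ndi.binary_fill_holes(mask)


def extract_objects(
    mask: np.ndarray,
    pixel_size_um: float = 0.11,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_AREA_UM2,
    solidity_cutoff: float = DEFAULT_SOLIDITY_CUTOFF,
    fused_area_factor: float = DEFAULT_FUSED_AREA_FACTOR,
) -> list[LabeledObject]:
    """Label the mask (8-connectivity) and apply accept/reject QC gates.

    Rejection reasons: ``too_small`` / ``too_large`` (area gates in μm^2),
    ``border`` (touches the image edge), ``overlap`` (solidity below the
    cutoff, or area above ``fused_area_factor`` times the median object
    area in this mask — the automated stand-in for manual deletion of
    fused nuclei).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    px_area = pixel_size_um**2
    props = regionprops(labels)
    areas = np.array([p.area for p in props], dtype=float) * px_area
    median_area = float(np.median(areas[(areas >= min_area_um2) & (areas <= max_area_um2)])) \
        if np.any((areas >= min_area_um2) & (areas <= max_area_um2)) else float(np.median(areas))

    H, W = mask.shape
    out: list[LabeledObject] = []
    for p, area_um2 in zip(props, areas):
        r0, c0, r1, c1 = p.bbox
        touches = r0 == 0 or c0 == 0 or r1 == H or c1 == W
        reason = "none"
        if touches:
            reason = "border"
        elif area_um2 < min_area_um2:
            reason = "too_small"
        elif area_um2 > max_area_um2:
            reason = "too_large"
        elif p.solidity < solidity_cutoff or area_um2 > fused_area_factor * median_area:
            reason = "overlap"
        out.append(
            LabeledObject(
                label=int(p.label),
                mask=p.image.copy(),
                bbox=(r0, c0, r1, c1),
                image_shape=(H, W),
                touches_border=touches,
                area_px=int(p.area),
                solidity=float(p.solidity),
                rejected_reason=reason,
            )
        )
    return out


_MOORE_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)


_DIR_LOOKUP = {tuple(off): i for i, off in enumerate(map(tuple, _MOORE_OFFSETS))}


def _moore_boundary(mask: np.ndarray) -> np.ndarray:
    """8-connected outer-boundary pixel chain (row, col), Moore tracing.

    Clockwise scan around the current pixel starting just past the
    backtrack pixel; terminates when the start pixel is re-entered with
    the same backtrack (Jacob's stopping criterion).
    """
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # uppermost-leftmost in raster order
    back = (start[0], start[1] - 1)       # west neighbor: background by construction
    boundary = [start]
    cur, first_state = start, None
    while True:
        base = _DIR_LOOKUP[(back[0] - cur[0], back[1] - cur[1])]
        for k in range(1, 9):
            d = (base + k) % 8
            nb = (cur[0] + int(_MOORE_OFFSETS[d][0]), cur[1] + int(_MOORE_OFFSETS[d][1]))
            if padded[nb]:
                new_back = (
                    cur[0] + int(_MOORE_OFFSETS[(base + k - 1) % 8][0]),
                    cur[1] + int(_MOORE_OFFSETS[(base + k - 1) % 8][1]),
                )
                if nb == start and (new_back == (start[0], start[1] - 1) or first_state == (nb, new_back)):
                    return np.array(boundary) - 1  # unpad
                if first_state is None:
                    first_state = (nb, new_back)
                boundary.append(nb)
                cur, back = nb, new_back
                break
        else:  # isolated pixel
            return np.array(boundary) - 1
        if len(boundary) > 4 * mask.size + 8:
            raise SegmentationError("boundary tracing failed to close")


def trace_perimeter(
    obj: LabeledObject, pixel_size_um: float, ram_id: str = ""
) -> PerimeterTrace:
    """Outer perimeter of an accepted object as a closed μm-coordinate trace.

    The 8-connected outer boundary is followed through pixel centers and
    converted to Cartesian μm with y increasing upward (origin at the image
    bottom-left), counterclockwise.  Raises on objects with fewer than 8
    boundary pixels.
    """
    if not obj.accepted:
        raise SegmentationError(f"object {obj.label} was rejected ({obj.rejected_reason})")
    chain = _moore_boundary(obj.mask)
    # deduplicate revisited pixels while keeping order (thin protrusions)
    if len(chain) >= 2:
        keep = np.ones(len(chain), dtype=bool)
        keep[1:] = np.any(np.diff(chain, axis=0) != 0, axis=1)
        chain = chain[keep]
    if len(chain) < 8:
        raise SegmentationError(
            f"interrupted_perimeter: object {obj.label} has {len(chain)} boundary pixels"
        )
    steps = np.diff(np.vstack([chain, chain[:1]]), axis=0)
    diag = np.sum(np.all(np.abs(steps) == 1, axis=1))
    axial = len(steps) - diag

    r0, c0, _, _ = obj.bbox
    H = obj.image_shape[0]
    rows = chain[:, 0] + r0
    cols = chain[:, 1] + c0
    x = cols * pixel_size_um
    y = (H - 1 - rows) * pixel_size_um
    return PerimeterTrace(
        vertices=np.column_stack([x, y]),
        pixel_size_um=pixel_size_um,
        ram_id=ram_id,
        label=obj.label,
        n_axial_steps=int(axial),
        n_diagonal_steps=int(diag),
    )


def perimeter_length(trace: PerimeterTrace, corner_correction: bool = False) -> float:
    """Closed perimeter length in μm.

    For pixel-traced boundaries this is the chain-code length (1 per axial
    step, sqrt(2) per diagonal step, times the pixel size); for arbitrary
    polygons it is the closed polyline length.  ``corner_correction``
    multiplies by 0.948 to compensate staircase overestimation of smooth
    outlines (off by default).
    """
    if trace.n_axial_steps + trace.n_diagonal_steps == len(trace.vertices):
        length = (trace.n_axial_steps + np.sqrt(2.0) * trace.n_diagonal_steps) * trace.pixel_size_um
    else:
        closed = trace.closed_vertices()
        length = float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))
    if corner_correction:
        length *= _CORNER_CORRECTION
    return float(length)


@dataclass
class QCReport:
    """Perimeter-overlay quality control: per-object verdicts and an overlay."""

    table: pd.DataFrame            # label, accepted, reason, in_bounds
    overlay: np.ndarray            # phase image with traces painted

    @property
    def accepted_labels(self) -> list[int]:
        return [int(l) for l in self.table.loc[self.table["accepted"], "label"]]

    @property
    def n_rejected(self) -> int:
        return int((~self.table["accepted"]).sum())


def overlay_qc(
    phase_image: np.ndarray,
    traces: list[PerimeterTrace],
    objects: list[LabeledObject] | None = None,
    manual_reject: tuple[int, ...] = (),
) -> QCReport:
    """Paint traces onto the phase-contrast image and tabulate verdicts.

    ``objects`` supplies QC rejections from :func:`extract_objects` (matched
    by label); ``manual_reject`` is the label list replacing interactive
    deletion.  Traces falling outside the image are flagged.
    """
    phase = np.asarray(phase_image)
    overlay = phase.astype(float).copy()
    H, W = phase.shape[:2]
    paint = float(overlay.max() if overlay.size else 255.0)
    reasons = {o.label: o.rejected_reason for o in objects or []}

    rows = []
    for t in traces:
        s = t.pixel_size_um
        cols = np.round(t.vertices[:, 0] / s).astype(int)
        rws = np.round(H - 1 - t.vertices[:, 1] / s).astype(int)
        inside = (cols >= 0) & (cols < W) & (rws >= 0) & (rws < H)
        overlay[rws[inside], cols[inside]] = paint
        reason = reasons.get(t.label, "none")
        if t.label in manual_reject:
            reason = "manual"
        if not inside.all():
            reason = "out_of_bounds" if reason == "none" else reason
        rows.append(
            {
                "label": t.label,
                "accepted": reason == "none",
                "reason": reason,
                "in_bounds": bool(inside.all()),
            }
        )
    for o in objects or []:
        if o.rejected_reason != "none" and o.label not in {r["label"] for r in rows}:
            rows.append(
                {"label": o.label, "accepted": False, "reason": o.rejected_reason, "in_bounds": True}
            )
    table = pd.DataFrame(rows, columns=["label", "accepted", "reason", "in_bounds"])
    return QCReport(table=table, overlay=overlay)


def segment_image(
    image: np.ndarray,
    pixel_size_um: float = 0.11,
    sigma_um: float = DEFAULT_SIGMA_UM,
    threshold_policy: str | float = "otsu",
    ram_id: str = "",
    **qc_kwargs,
) -> tuple[list[LabeledObject], list[PerimeterTrace]]:
    """Full segmentation pass: threshold, label/QC, trace accepted objects."""
    mask = log_threshold(image, sigma_um, pixel_size_um, threshold_policy)
    objects = extract_objects(mask, pixel_size_um, **qc_kwargs)
    traces = []
    for obj in objects:
        if not obj.accepted:
            continue
        try:
            traces.append(trace_perimeter(obj, pixel_size_um, ram_id=ram_id))
        except SegmentationError:
            obj.rejected_reason = "interrupted_perimeter"
            warnings.warn(f"object {obj.label}: interrupted perimeter, rejected")
    return objects, traces
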