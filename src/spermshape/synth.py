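"""Synthetic sperm-nucleus cohorts and fluorescence images with ground truth.

No image data accompany the study this pipeline emulates, so every
downstream stage is exercised against cohorts generated here.  The
generator encodes the published cohort conditions for Merino rams:

* adequate-fertility (AF) and low-fertility (LF) groups of 47 and 9 rams
  with ~100 analyzed sperm nuclei each;
* group-mean harmonic amplitudes HA0–HA5 (μm) and their SEMs for sperm
  head shape, with head elongation (HA2) the chief group separator
  (0.905 AF vs 0.872 LF);
* nuclear gray-level intensity scales (~99 AF vs ~111 LF on an 8-bit-like
  scale) and a ~28 μm² nominal nucleus area;
* conception rates of 95.1 ± 0.6 (AF) vs 79.7 ± 2.5 (LF) percent
  (mean ± SEM), population mean 89.0 with SD 6.6 and the 1-SD cutoff 82.4.

Dispersion is split hierarchically: the between-ram SD of each feature is
the AF-column SEM scaled by √47, and the sperm-to-sperm SD within a ram
is the AF-column SEM scaled by √100.  The AF column supplies both spreads
for both groups because the SEM gap between the columns mostly reflects
the 47-vs-9 group sizes rather than biology.  Under this split the
expected two-sample t-statistic for mean HA2 across the default cohort is
≈2 (p of a few percent), consistent with the reported borderline
elongation signal.

Shapes are sampled as truncated Fourier contours and re-centred so the
polar origin coincides with the area centroid (the frame in which
harmonic amplitudes are defined and measured downstream); the stored
truth coefficients therefore describe the rendered contour exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats
from scipy.spatial import ConvexHull

from .fha import HarmonicSet, RamShapeSummary, summarize_ram
from .morpho import FEATURE_NAMES
from .segment import PerimeterTrace

__all__ = [
    "GROUP_HA_MEANS",
    "GROUP_HA_SEMS",
    "GROUP_INTENSITY",
    "REFERENCE_COHORT",
    "CONCEPTION",
    "ShapePopulationParams",
    "FertilityRecord",
    "SyntheticGroundTruth",
    "RenderParams",
    "FieldResult",
    "RamTruth",
    "Cohort",
    "sample_shape_params",
    "recenter_harmonics",
    "sample_nucleus_harmonics",
    "render_nucleus",
    "generate_field",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# Published cohort conditions (all lengths in μm, intensities in gray levels)

GROUP_HA_MEANS = {
    "AF": np.array([2.851, 0.085, 0.905, 0.078, 0.153, 0.024]),
    "LF": np.array([2.838, 0.087, 0.872, 0.082, 0.143, 0.024]),
}
GROUP_HA_SEMS = {
    "AF": np.array([0.010, 0.002, 0.006, 0.002, 0.003, 0.001]),
    "LF": np.array([0.029, 0.005, 0.024, 0.006, 0.011, 0.002]),
}
#: group mean nuclear intensity and its SEM (gray levels, 8-bit-like scale)
GROUP_INTENSITY = {"AF": (99.168, 3.015), "LF": (110.737, 10.719)}
#: rams per group in the reference discriminant cohort
REFERENCE_COHORT = {"AF": 47, "LF": 9}
SPERM_PER_RAM = 100
#: conception rate structure: (AF mean, AF SEM, AF n), (LF mean, LF SEM, LF n),
#: population cutoff = mean - SD = 89.0 - 6.6
CONCEPTION = {
    "AF": (95.1, 0.6, 41),
    "LF": (79.7, 2.5, 27),
    "cutoff": 82.4,
}

#: between-ram SD: AF-column SEM × sqrt(47), shared by both groups
_BETWEEN_RAM_SD = GROUP_HA_SEMS["AF"] * np.sqrt(REFERENCE_COHORT["AF"])
_BETWEEN_RAM_INT_SD = GROUP_INTENSITY["AF"][1] * np.sqrt(REFERENCE_COHORT["AF"])
#: sperm-to-sperm intensity spread within one ram (gray levels)
_WITHIN_RAM_INT_SD = 6.0


@dataclass
class ShapePopulationParams:
    """Shape/intensity sampling parameters for one fertility group."""

    group_label: str
    ha_means: np.ndarray          # HA0..HA5, μm
    ha_sds: np.ndarray            # per-sperm SDs, μm
    phase_jitter: float = 0.25    # radians, per-harmonic phase scatter
    intensity_mean: float = 100.0
    intensity_sd: float = _WITHIN_RAM_INT_SD
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.ha_means = np.asarray(self.ha_means, dtype=float)
        self.ha_sds = np.asarray(self.ha_sds, dtype=float)
        if self.group_label not in {"AF", "LF"}:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.ha_means.shape != (6,) or self.ha_sds.shape != (6,):
            raise ValueError("ha_means and ha_sds must have 6 entries (HA0..HA5)")
        if self.ha_means[0] <= 0:
            raise ValueError("HA0 mean must be positive")
        if np.any(self.ha_sds < 0):
            raise ValueError("ha_sds must be nonnegative")
        if not (0 < self.intensity_mean < 2**self.bit_depth):
            raise ValueError("intensity_mean outside the image bit depth")


@dataclass
class FertilityRecord:
    ram_id: str
    conception_rate: float
    group: str = "unassigned"

    def __post_init__(self) -> None:
        if not 0 <= self.conception_rate <= 100:
            raise ValueError("conception rate must be within [0, 100]")


@dataclass
class SyntheticGroundTruth:
    """True description of one rendered nucleus."""

    harmonics: HarmonicSet        # centroid-frame coefficients, μm
    centroid_px: tuple[float, float]   # (col, row) in the rendered image
    rotation_rad: float
    ram_id: str = ""
    group: str = "unassigned"
    overlap_flag: bool = False
    intensity: float = 100.0
    bbox: tuple[int, int, int, int] | None = None   # (r0, c0, r1, c1)
    mask: np.ndarray | None = None                  # local boolean patch

    def __post_init__(self) -> None:
        if self.mask is not None and not self.mask.any():
            raise ValueError("ground-truth mask is empty")

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class RenderParams:
    """Widefield-fluorescence rendering model.

    Gaussian PSF (σ 0.15 μm, typical for a 40× widefield objective),
    Poisson shot noise plus Gaussian read noise (SD 2 gray levels), and a
    smooth multiplicative chromatin texture inside the nucleus.  The
    relative texture SD of 0.15 reproduces the published within-nucleus
    gray-level SD scale (~18 at mean ~99, ~20 at mean ~111).  Images are
    8-bit by default; the bit depth is configurable.
    """

    psf_sigma_um: float = 0.15
    read_noise_sd: float = 2.0
    background: float = 10.0
    texture_rel_sd: float = 0.15
    texture_sigma_um: float = 0.5
    bit_depth: int = 8

    @property
    def max_gray(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth <= 8 else np.uint16


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_shape_params(group: str, rng_seed=None) -> ShapePopulationParams:
    """Default shape-population parameters for one fertility group.

    ``ha_means`` are the published group means; ``ha_sds`` are per-sperm
    SDs obtained by scaling the AF-column SEMs by √100 (the per-ram sample
    size).  The AF column is used for *both* groups: SEM differences
    between the columns reflect the group sizes (47 vs 9 rams), not a
    genuine difference in sperm-to-sperm variability, and importing them
    would let dispersion features separate the groups trivially.
    """
    if group not in GROUP_HA_MEANS:
        raise ValueError(f"unknown group label {group!r}; expected 'AF' or 'LF'")
    del rng_seed  # defaults are deterministic; reserved for future stochastic variants
    return ShapePopulationParams(
        group_label=group,
        ha_means=GROUP_HA_MEANS[group].copy(),
        ha_sds=GROUP_HA_SEMS["AF"] * np.sqrt(SPERM_PER_RAM),
        intensity_mean=GROUP_INTENSITY[group][0],
    )


# ---------------------------------------------------------------------------
# shape sampling

_DENSE_N = 256
_DENSE_THETA = np.arange(_DENSE_N) * (2 * np.pi / _DENSE_N)
_DTH = 2 * np.pi / _DENSE_N


def recenter_harmonics(h: HarmonicSet, tol: float = 1e-10, max_iter: int = 60) -> HarmonicSet:
    """Re-express a truncated Fourier contour about its area centroid.

    Iterates shift-and-refit until the area centroid of the band-limited
    contour is at the polar origin; the fixed point is the frame in which
    harmonic amplitudes are defined (polar axes through the center of
    mass).  The first-harmonic content changes most (it trades off against
    translation); higher amplitudes move at second order.
    """
    cur = h
    K = h.max_harmonic
    k = np.arange(1, K + 1)
    for _ in range(max_iter):
        r = cur.radius(_DENSE_THETA)
        if np.any(r <= 0):
            raise ValueError("contour self-intersects during recentring")
        area = 0.5 * np.sum(r**2) * _DTH
        cx = np.sum(r**3 * np.cos(_DENSE_THETA)) / 3 * _DTH / area
        cy = np.sum(r**3 * np.sin(_DENSE_THETA)) / 3 * _DTH / area
        if np.hypot(cx, cy) < tol:
            return cur
        x = r * np.cos(_DENSE_THETA) - cx
        y = r * np.sin(_DENSE_THETA) - cy
        th = np.arctan2(y, x)
        rr = np.hypot(x, y)
        ang = np.multiply.outer(th, k)
        X = np.hstack([np.ones((_DENSE_N, 1)), np.cos(ang), np.sin(ang)])
        coef, *_ = np.linalg.lstsq(X, rr, rcond=None)
        cur = HarmonicSet(c0=float(coef[0]), a=coef[1 : K + 1], b=coef[K + 1 :])
    return cur


def sample_nucleus_harmonics(
    params: ShapePopulationParams, n: int, rng_seed=None
) -> list[HarmonicSet]:
    """Draw per-sperm harmonic sets around the population means.

    Amplitudes are Gaussian around ``ha_means`` with ``ha_sds`` (reflected
    at zero for k >= 1); each harmonic carries a canonical phase of zero
    (anterior/posterior asymmetry enters through HA1/HA3) jittered by
    ``phase_jitter``.  All contours are re-centred to the centroid frame.
    """
    rng = _as_rng(rng_seed)
    out = []
    for _ in range(n):
        amp = rng.normal(params.ha_means, params.ha_sds)
        amp[0] = max(amp[0], 1.0)
        amp[1:] = np.abs(amp[1:])
        phi = rng.normal(0.0, params.phase_jitter, size=5)
        h = HarmonicSet(c0=float(amp[0]), a=amp[1:] * np.cos(phi), b=amp[1:] * np.sin(phi))
        if params.ha_sds[1:].sum() == 0 and params.phase_jitter == 0:
            pass  # degenerate population: identical shapes stay identical
        out.append(recenter_harmonics(h))
    return out


# ---------------------------------------------------------------------------
# rendering

def _rasterize(
    h: HarmonicSet,
    centroid_px: tuple[float, float],
    rotation: float,
    pixel_size_um: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the rotated contour.

    Evaluated only inside the contour's bounding window for speed.
    """
    cx, cy = centroid_px
    r_max_px = float(h.radius(_DENSE_THETA).max()) / pixel_size_um
    r0 = max(0, int(np.floor(cy - r_max_px - 1)))
    r1 = min(shape[0], int(np.ceil(cy + r_max_px + 2)))
    c0 = max(0, int(np.floor(cx - r_max_px - 1)))
    c1 = min(shape[1], int(np.ceil(cx + r_max_px + 2)))
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rows, cols = np.mgrid[r0:r1, c0:c1]
    x = (cols - cx) * pixel_size_um
    y = (cy - rows) * pixel_size_um  # y up
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x) - rotation
    out[r0:r1, c0:c1] = rho <= h.radius(theta.ravel()).reshape(rho.shape)
    return out


def render_nucleus(
    harmonics: HarmonicSet,
    pose: tuple[float, float, float] | None = None,
    pixel_size_um: float = 0.11,
    noise_params: RenderParams | None = None,
    rng_seed=None,
    patch_shape: tuple[int, int] | None = None,
    intensity: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one nucleus into an image patch; returns (image, true mask).

    The mask is the rasterized interior of r(θ); the image is the mask
    filled at ``intensity`` (modulated by chromatin texture), blurred with
    the Gaussian PSF, with Poisson shot noise and Gaussian read noise
    added.  Deterministic for a fixed seed.  Raises if the contour
    self-intersects or the nucleus does not fit in the patch.
    """
    p = noise_params or RenderParams()
    rng = _as_rng(rng_seed)
    r_dense = harmonics.radius(_DENSE_THETA)
    if np.any(r_dense <= 0):
        raise ValueError("self-intersecting contour (non-positive radius)")
    r_max = float(r_dense.max())
    margin_px = int(np.ceil((r_max + 3 * p.psf_sigma_um) / pixel_size_um)) + 2
    if r_max / pixel_size_um < 10:
        raise ValueError("pixel size too coarse: nucleus spans fewer than 20 px")
    if patch_shape is None:
        n = 2 * margin_px + 1
        patch_shape = (n, n)
    if pose is None:
        pose = (patch_shape[1] / 2.0, patch_shape[0] / 2.0, 0.0)
    cx, cy, rot = pose
    if not (
        margin_px - 1 <= cx <= patch_shape[1] - margin_px
        and margin_px - 1 <= cy <= patch_shape[0] - margin_px
    ):
        raise ValueError("nucleus exceeds patch bounds at this pose")
    mask = _rasterize(harmonics, (cx, cy), rot, pixel_size_um, patch_shape)
    image = _expose(mask[None, ...].astype(float) * intensity, p, pixel_size_um, rng)[0]
    return image, mask


def _expose(
    fills: np.ndarray, p: RenderParams, pixel_size_um: float, rng: np.random.Generator
) -> np.ndarray:
    """Optics + camera model applied to a stack of fill images."""
    sig_psf = p.psf_sigma_um / pixel_size_um
    sig_tex = p.texture_sigma_um / pixel_size_um
    out = np.empty(fills.shape, dtype=np.float64)
    for i, fill in enumerate(fills):
        if p.texture_rel_sd > 0:
            g = ndi.gaussian_filter(rng.normal(size=fill.shape), sig_tex)
            sd = g.std()
            if sd > 0:
                g /= sd
            texture = np.clip(1.0 + p.texture_rel_sd * g, 0.2, None)
        else:
            texture = 1.0
        photons = ndi.gaussian_filter(fill * texture, sig_psf) + p.background
        noisy = rng.poisson(np.clip(photons, 0, None)).astype(float)
        noisy += rng.normal(0.0, p.read_noise_sd, size=fill.shape)
        out[i] = noisy
    return np.clip(np.round(out), 0, p.max_gray).astype(p.dtype)


@dataclass
class FieldResult:
    fluorescence: np.ndarray
    phase: np.ndarray
    truth: list[SyntheticGroundTruth]

    def label_image(self) -> np.ndarray:
        out = np.zeros(self.fluorescence.shape, dtype=np.uint16)
        for i, t in enumerate(self.truth, start=1):
            r0, c0, r1, c1 = t.bbox
            out[r0:r1, c0:c1][t.mask] = i
        return out


def generate_field(
    n_nuclei: int,
    field_size_px: tuple[int, int] = (512, 512),
    params: ShapePopulationParams | None = None,
    overlap_fraction: float = 0.0,
    rng_seed=None,
    pixel_size_um: float = 0.11,
    render_params: RenderParams | None = None,
    ram_id: str = "",
    max_attempts_per_nucleus: int = 500,
) -> FieldResult:
    """Simulate one microscope field with ground truth.

    Nuclei are placed at random poses without touching each other except a
    requested ``overlap_fraction`` that is deliberately placed onto an
    existing nucleus (both partners are flagged) to exercise rejection QC.
    The phase-like channel is a contrast-inverted, halo-blurred rendering
    of the same field.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = _as_rng(rng_seed)
    p = render_params or RenderParams()
    params = params or sample_shape_params("AF")
    H, W = field_size_px

    harmonic_sets = sample_nucleus_harmonics(params, n_nuclei, rng)
    intensities = rng.normal(params.intensity_mean, params.intensity_sd, size=n_nuclei)
    intensities = np.clip(intensities, 10, p.max_gray)
    n_overlap = int(round(overlap_fraction * n_nuclei))

    placed: list[tuple[float, float, float]] = []  # (cx, cy, r_max_px)
    truth: list[SyntheticGroundTruth] = []
    fill = np.zeros((H, W), dtype=float)
    for i, h in enumerate(harmonic_sets):
        r_max_px = float(h.radius(_DENSE_THETA).max()) / pixel_size_um
        margin = r_max_px + 3 * p.psf_sigma_um / pixel_size_um + 2
        if 2 * margin >= min(H, W):
            raise ValueError("field too small for the nucleus size")
        want_overlap = i >= n_nuclei - n_overlap and placed
        rot = rng.uniform(0, 2 * np.pi)
        mask = None
        for attempt in range(max_attempts_per_nucleus):
            if want_overlap:
                j = int(rng.integers(len(placed)))
                ox, oy, orad = placed[j]
                ang = rng.uniform(0, 2 * np.pi)
                d = rng.uniform(0.35, 0.65) * (orad + r_max_px)
                cx, cy = ox + d * np.cos(ang), oy + d * np.sin(ang)
                if not (margin <= cx <= W - margin and margin <= cy <= H - margin):
                    continue
                cand = _rasterize(h, (cx, cy), rot, pixel_size_um, (H, W))
                # a deliberate overlap must genuinely intersect its partner
                if not (cand & truth[j].full_mask((H, W))).any():
                    continue
                mask = cand
                truth[j].overlap_flag = True
                break
            cx = rng.uniform(margin, W - margin)
            cy = rng.uniform(margin, H - margin)
            ok = all(
                np.hypot(cx - ox, cy - oy) > r_max_px + orad + 2 for ox, oy, orad in placed
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{n_nuclei}; placed {len(placed)}"
            )
        if mask is None:
            mask = _rasterize(h, (cx, cy), rot, pixel_size_um, (H, W))
        rows, cols = np.nonzero(mask)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        local = mask[bbox[0] : bbox[2], bbox[1] : bbox[3]]
        fill += mask * intensities[i]
        placed.append((cx, cy, r_max_px))
        truth.append(
            SyntheticGroundTruth(
                harmonics=h,
                centroid_px=(cx, cy),
                rotation_rad=rot,
                ram_id=ram_id,
                group=params.group_label,
                overlap_flag=bool(want_overlap),
                intensity=float(intensities[i]),
                bbox=bbox,
                mask=local,
            )
        )

    fluor = _expose(fill[None, ...], p, pixel_size_um, rng)[0]
    phase = _phase_render(fill, p, pixel_size_um, rng)
    return FieldResult(fluorescence=fluor, phase=phase, truth=truth)


def _phase_render(
    fill: np.ndarray, p: RenderParams, pixel_size_um: float, rng: np.random.Generator
) -> np.ndarray:
    """Contrast-inverted, halo-blurred companion image (phase-contrast-like)."""
    sig = p.psf_sigma_um / pixel_size_um
    body = ndi.gaussian_filter(fill, sig)
    halo = ndi.gaussian_filter(fill, 6 * sig)
    bright = 0.82 * p.max_gray
    img = bright - 0.5 * body + 0.18 * halo + rng.normal(0, p.read_noise_sd, fill.shape)
    return np.clip(np.round(img), 0, p.max_gray).astype(p.dtype)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class RamTruth:
    """Per-ram ground truth: shapes, intensities and optional renderings."""

    ram_id: str
    group: str
    conception_rate: float
    harmonic_sets: list[HarmonicSet]
    sperm_intensity: np.ndarray
    traces: list[PerimeterTrace] | None = None
    patches: list[tuple[np.ndarray, np.ndarray]] | None = None  # (image, true mask)

    @property
    def n_sperm(self) -> int:
        return len(self.harmonic_sets)

    def true_amplitudes(self) -> np.ndarray:
        return np.array([h.amplitudes for h in self.harmonic_sets])


@dataclass
class Cohort:
    rams: list[RamTruth]
    fertility: list[FertilityRecord]
    pixel_size_um: float
    detail: str
    _morpho_truth: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    @property
    def n_nuclei(self) -> int:
        return sum(r.n_sperm for r in self.rams)

    def labels(self) -> pd.Series:
        return pd.Series({r.ram_id: r.group for r in self.rams}, name="group")

    def fertility_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"ram_id": f.ram_id, "conception_rate": f.conception_rate, "group": f.group}
                for f in self.fertility
            ]
        )

    def feature_matrix(self) -> pd.DataFrame:
        """Per-ram summaries from the *true* shapes and the morphometric model.

        The image route (render → segment → measure → FHA) lives in
        :mod:`spermshape.pipeline`; this matrix is the generator's own
        ground-truth feature table.
        """
        rows = []
        for ram in self.rams:
            morpho = self._morpho_truth[ram.ram_id].mean()
            s = summarize_ram(
                ram.harmonic_sets,
                morpho_means=morpho.to_dict(),
                ram_id=ram.ram_id,
                group=ram.group,
            )
            rows.append(s.to_row())
        df = pd.DataFrame(rows).set_index("ram_id")
        return df

    def summaries(self) -> list[RamShapeSummary]:
        out = []
        for ram in self.rams:
            morpho = self._morpho_truth[ram.ram_id].mean()
            out.append(
                summarize_ram(
                    ram.harmonic_sets,
                    morpho_means=morpho.to_dict(),
                    ram_id=ram.ram_id,
                    group=ram.group,
                )
            )
        return out


def _draw_conception_rates(group: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rates consistent with thresholding at the published 82.4 cutoff."""
    cutoff = CONCEPTION["cutoff"]
    if group == "AF":
        mean, sem, n_ref = CONCEPTION["AF"]
        sd = sem * np.sqrt(n_ref)
        a, b = (cutoff - mean) / sd, (100.0 - mean) / sd
        return scipy.stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    # LF: half-normal tail below the cutoff whose mean matches 79.7
    scale = (cutoff - CONCEPTION["LF"][0]) / np.sqrt(2 / np.pi)
    return np.clip(cutoff - np.abs(rng.normal(0, scale, size=n)) - 1e-6, 0.0, None)


def _true_morpho_frame(
    ram: RamTruth, p: RenderParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Analytic geometric features plus the parametric intensity model.

    Geometry (area, perimeter, moment ellipse, convex hull) is evaluated on
    the true contours by quadrature; gray-level statistics follow the
    renderer's physics (shot noise + read noise + multiplicative texture)
    without rasterizing, so summary-level cohorts stay cheap.
    """
    n = ram.n_sperm
    theta = _DENSE_THETA
    R = np.stack([h.radius(theta) for h in ram.harmonic_sets])  # (n, N)
    dR = np.stack(
        [
            np.sum(
                [
                    j * (-h.a[j - 1] * np.sin(j * theta) + h.b[j - 1] * np.cos(j * theta))
                    for j in range(1, h.max_harmonic + 1)
                ],
                axis=0,
            )
            for h in ram.harmonic_sets
        ]
    )
    area = 0.5 * np.sum(R**2, axis=1) * _DTH
    perim = np.sum(np.sqrt(R**2 + dR**2), axis=1) * _DTH
    mu20 = 0.25 * np.sum(R**4 * np.cos(theta) ** 2, axis=1) * _DTH
    mu02 = 0.25 * np.sum(R**4 * np.sin(theta) ** 2, axis=1) * _DTH
    mu11 = 0.25 * np.sum(R**4 * np.sin(theta) * np.cos(theta), axis=1) * _DTH
    tr, det = mu20 + mu02, mu20 * mu02 - mu11**2
    disc = np.sqrt(np.clip(tr**2 - 4 * det, 0, None))
    lam1, lam2 = (tr + disc) / 2, (tr - disc) / 2
    major = 4 * np.sqrt(lam1 / area)
    minor = 4 * np.sqrt(lam2 / area)

    solidity = np.empty(n)
    sub = theta[::8]
    for i, h in enumerate(ram.harmonic_sets):
        r = h.radius(sub)
        pts = np.column_stack([r * np.cos(sub), r * np.sin(sub)])
        solidity[i] = min(1.0, area[i] / ConvexHull(pts).volume)

    mean_i = ram.sperm_intensity
    sd_i = np.sqrt(
        p.read_noise_sd**2 + mean_i + (p.texture_rel_sd * mean_i) ** 2
    ) * rng.normal(1.0, 0.03, size=n)
    return pd.DataFrame(
        {
            "area": area,
            "perimeter": perim,
            "circularity": np.minimum(1.0, 4 * np.pi * area / perim**2),
            "aspect_ratio": major / minor,
            "roundness": np.minimum(1.0, 4 * area / (np.pi * major**2)),
            "solidity": solidity,
            "intensity_mean": mean_i,
            "intensity_sd": sd_i,
            "intensity_median": mean_i + rng.normal(0.0, 0.6, size=n),
            "intensity_skew": rng.normal(-0.05, 0.10, size=n),
            "intensity_kurt": rng.normal(0.0, 0.20, size=n),
        }
    )[FEATURE_NAMES]


def generate_cohort(
    n_af_rams: int = REFERENCE_COHORT["AF"],
    n_lf_rams: int = REFERENCE_COHORT["LF"],
    sperm_per_ram: int = SPERM_PER_RAM,
    rng_seed=None,
    detail: str = "traces",
    pixel_size_um: float = 0.11,
    trace_vertices: int = 720,
    render_params: RenderParams | None = None,
) -> Cohort:
    """Simulate a two-group ram cohort with known ground truth.

    ``detail`` controls how much is materialized per sperm:
    ``"summary"`` — true harmonic sets and the analytic/parametric
    morphometric table only; ``"traces"`` — adds true perimeter polygons;
    ``"images"`` — additionally renders each nucleus into its own patch.
    Identical seeds give identical cohorts.
    """
    if n_af_rams < 1 or n_lf_rams < 1 or sperm_per_ram < 1:
        raise ValueError("counts must be >= 1")
    if detail not in {"summary", "traces", "images"}:
        raise ValueError(f"unknown detail level {detail!r}")
    rng = _as_rng(rng_seed)
    p = render_params or RenderParams()

    rams: list[RamTruth] = []
    fertility: list[FertilityRecord] = []
    morpho_truth: dict[str, pd.DataFrame] = {}
    for group, n_group in (("AF", n_af_rams), ("LF", n_lf_rams)):
        base = sample_shape_params(group)
        rates = _draw_conception_rates(group, n_group, rng)
        for j in range(n_group):
            ram_id = f"{group}{j + 1:03d}"
            ram_means = rng.normal(base.ha_means, _BETWEEN_RAM_SD)
            ram_int = float(
                np.clip(rng.normal(base.intensity_mean, _BETWEEN_RAM_INT_SD), 40, 0.85 * p.max_gray)
            )
            params = replace(base, ha_means=ram_means, intensity_mean=ram_int)
            hsets = sample_nucleus_harmonics(params, sperm_per_ram, rng)
            intensities = np.clip(
                rng.normal(ram_int, params.intensity_sd, size=sperm_per_ram), 10, p.max_gray
            )
            ram = RamTruth(
                ram_id=ram_id,
                group=group,
                conception_rate=float(np.clip(rates[j], 0, 100)),
                harmonic_sets=hsets,
                sperm_intensity=intensities,
            )
            if detail in {"traces", "images"}:
                ram.traces = [
                    PerimeterTrace(
                        vertices=h.to_polygon(trace_vertices),
                        pixel_size_um=pixel_size_um,
                        ram_id=ram_id,
                        label=i + 1,
                    )
                    for i, h in enumerate(hsets)
                ]
            if detail == "images":
                ram.patches = [
                    render_nucleus(
                        h,
                        pixel_size_um=pixel_size_um,
                        noise_params=p,
                        rng_seed=rng,
                        intensity=float(intensities[i]),
                    )
                    for i, h in enumerate(hsets)
                ]
            morpho_truth[ram_id] = _true_morpho_frame(ram, p, rng)
            rams.append(ram)
            fertility.append(
                FertilityRecord(ram_id=ram_id, conception_rate=ram.conception_rate, group=group)
            )
    return Cohort(
        rams=rams,
        fertility=fertility,
        pixel_size_um=pixel_size_um,
        detail=detail,
        _morpho_truth=morpho_truth,
    )
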