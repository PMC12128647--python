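"""Fourier harmonic amplitude (FHA) analysis of nucleus perimeters.

A closed sperm-nucleus contour is expressed in polar form about its area
centroid, r(θ), and a truncated Fourier series

    r(θ) ≈ c0 + Σ_{k=1..K} (a_k cos kθ + b_k sin kθ),   K = 5,

is fitted by ordinary least squares ("trigonometric regression").  The
reported shape descriptors are the harmonic amplitudes

    HA0 = c0 (mean radius, μm),  HA_k = sqrt(a_k² + b_k²)  (k = 1..5),

which are rotation-invariant because the amplitude absorbs phase.  HA0
tracks overall size, HA1 anterior curvature, HA2 head elongation, and
HA3–HA5 posterior tapering.  Per-animal dispersion of each amplitude
(variance, skewness, kurtosis across ~100 sperm) completes the feature
set used by the fertility discriminant.

For equally spaced angles the least-squares solution coincides with the
discrete Fourier transform of the sampled radii, which the test suite
exploits as an independent oracle.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from . import _geometry as geom
from .segment import PerimeterTrace

__all__ = [
    "PolarProfile",
    "HarmonicSet",
    "RamShapeSummary",
    "AverageShape",
    "NonStarShapeError",
    "to_polar",
    "fit_fourier",
    "harmonics_from_trace",
    "summarize_ram",
    "average_shape",
]

#: equal-angle samples for polar resampling; far above the 2K+1 minimum so
#: aliasing of smooth head contours is negligible
DEFAULT_N_SAMPLES = 128
DEFAULT_MAX_HARMONIC = 5


class NonStarShapeError(ValueError):
    """Raised when a contour is not star-shaped about its area centroid."""


@dataclass
class PolarProfile:
    """Polar radius samples of one contour about its area centroid."""

    centroid: np.ndarray          # (x_um, y_um) in the source frame
    theta: np.ndarray             # strictly increasing, [0, 2π)
    r: np.ndarray                 # μm, positive
    non_star: bool = False        # any ray crossed the boundary more than once

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta samples must be strictly increasing")
        if not np.all(np.isfinite(self.r)) or np.any(self.r <= 0):
            raise ValueError("radii must be finite and positive")

    @property
    def n_samples(self) -> int:
        return len(self.theta)


@dataclass
class HarmonicSet:
    """Truncated Fourier description of one nucleus contour (μm units)."""

    c0: float
    a: np.ndarray                 # cosine coefficients, k = 1..K
    b: np.ndarray                 # sine coefficients, k = 1..K
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have equal length")

    @property
    def max_harmonic(self) -> int:
        return len(self.a)

    @property
    def amplitudes(self) -> np.ndarray:
        """[HA0, HA1, ..., HAK]; HA0 is the mean radius."""
        return np.concatenate([[self.c0], np.hypot(self.a, self.b)])

    def radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        k = np.arange(1, self.max_harmonic + 1)
        ang = np.multiply.outer(theta, k)
        return self.c0 + np.cos(ang) @ self.a + np.sin(ang) @ self.b

    def sample_profile(self, n_samples: int = DEFAULT_N_SAMPLES) -> PolarProfile:
        """Exact equal-angle polar samples of the analytic contour."""
        theta = np.arange(n_samples) * (2 * np.pi / n_samples)
        r = self.radius(theta)
        if np.any(r <= 0):
            raise ValueError("contour self-intersects (non-positive radius)")
        return PolarProfile(centroid=np.zeros(2), theta=theta, r=r)

    def to_polygon(self, n_vertices: int = 360) -> np.ndarray:
        theta = np.arange(n_vertices) * (2 * np.pi / n_vertices)
        r = self.radius(theta)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    def rotated(self, angle: float) -> "HarmonicSet":
        """Coefficients of the same shape rotated counterclockwise by ``angle``."""
        k = np.arange(1, self.max_harmonic + 1)
        c, s = np.cos(k * angle), np.sin(k * angle)
        return HarmonicSet(
            c0=self.c0,
            a=self.a * c - self.b * s,
            b=self.a * s + self.b * c,
            residual_rms=self.residual_rms,
        )

    def reflected(self) -> "HarmonicSet":
        """Coefficients after reflection across the x-axis (y -> -y)."""
        return HarmonicSet(c0=self.c0, a=self.a.copy(), b=-self.b, residual_rms=self.residual_rms)

    def area(self) -> float:
        """Exact enclosed area: π c0² + (π/2) Σ (a_k² + b_k²)."""
        return float(np.pi * self.c0**2 + 0.5 * np.pi * np.sum(self.a**2 + self.b**2))


def _design_matrix(theta: np.ndarray, max_harmonic: int) -> np.ndarray:
    k = np.arange(1, max_harmonic + 1)
    ang = np.multiply.outer(theta, k)
    return np.hstack([np.ones((len(theta), 1)), np.cos(ang), np.sin(ang)])


def to_polar(
    trace: PerimeterTrace | np.ndarray,
    n_samples: int = DEFAULT_N_SAMPLES,
    radial_offset_um: float = 0.0,
) -> PolarProfile:
    """Resample a closed contour at equally spaced angles about its centroid.

    The boundary is intersected with rays from the polygon's area centroid;
    if a ray crosses more than once (contour not star-shaped) the farthest
    crossing is used and the profile is flagged.  ``radial_offset_um`` is
    added to every radius — pass half a pixel when the trace runs through
    boundary-pixel centers, which sit about half a pixel inside the
    continuous contour (digitization correction).

    Raises :class:`NonStarShapeError` when the centroid falls outside the
    polygon.
    """
    vertices = trace.vertices if isinstance(trace, PerimeterTrace) else np.asarray(trace, float)
    centroid = geom.polygon_centroid(vertices)
    if not geom.point_in_polygon(centroid, vertices):
        raise NonStarShapeError("area centroid lies outside the contour")
    theta = np.arange(n_samples) * (2 * np.pi / n_samples)
    r, multi = geom.ray_radii(vertices, centroid, theta)
    if np.any(np.isnan(r)):
        raise NonStarShapeError("some rays from the centroid never cross the contour")
    return PolarProfile(
        centroid=centroid,
        theta=theta,
        r=r + radial_offset_um,
        non_star=bool(np.any(multi)),
    )


def fit_fourier(
    profile: PolarProfile, max_harmonic: int = DEFAULT_MAX_HARMONIC
) -> HarmonicSet:
    """Least-squares truncated Fourier fit of the polar radius profile.

    Requires at least 2K+1 samples.  For equally spaced angles the result
    equals the DFT-derived coefficients.
    """
    K = int(max_harmonic)
    if profile.n_samples < 2 * K + 1:
        raise ValueError(f"need at least {2 * K + 1} samples for K={K}")
    X = _design_matrix(profile.theta, K)
    coef, _, rank, _ = np.linalg.lstsq(X, profile.r, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design (duplicate or degenerate angles)")
    resid = profile.r - X @ coef
    return HarmonicSet(
        c0=float(coef[0]),
        a=coef[1 : K + 1],
        b=coef[K + 1 :],
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def harmonics_from_trace(
    trace: PerimeterTrace | np.ndarray,
    n_samples: int = DEFAULT_N_SAMPLES,
    max_harmonic: int = DEFAULT_MAX_HARMONIC,
    radial_offset_um: float = 0.0,
) -> HarmonicSet:
    """Convenience: polar resampling followed by the Fourier fit."""
    return fit_fourier(to_polar(trace, n_samples, radial_offset_um), max_harmonic)


@dataclass
class RamShapeSummary:
    """Per-ram feature vector: HA moments plus mean morphometrics."""

    ram_id: str
    n_sperm: int
    features: dict[str, float] = field(default_factory=dict)
    group: str = "unassigned"
    degenerate: bool = False      # some amplitude had zero variance

    def to_row(self) -> dict[str, float]:
        return {"ram_id": self.ram_id, "group": self.group, "n_sperm": self.n_sperm,
                **self.features}


def summarize_ram(
    harmonic_sets: list[HarmonicSet],
    morpho_means: dict[str, float] | None = None,
    ram_id: str = "",
    group: str = "unassigned",
) -> RamShapeSummary:
    """Per-ram amplitude moments (mean, unbiased variance, adjusted
    Fisher–Pearson skewness, excess kurtosis) joined with mean morphometrics.

    Zero-variance amplitudes report skewness/kurtosis of 0 and set the
    degenerate flag.
    """
    if len(harmonic_sets) < 2:
        raise ValueError("need at least 2 nuclei per ram")
    amp = np.array([h.amplitudes for h in harmonic_sets])  # (n, K+1)
    feats: dict[str, float] = {}
    degenerate = False
    for k in range(amp.shape[1]):
        x = amp[:, k]
        var = float(np.var(x, ddof=1))
        feats[f"ha{k}_mean"] = float(np.mean(x))
        feats[f"ha{k}_var"] = var
        if var == 0.0:
            degenerate = True
            feats[f"ha{k}_skew"] = 0.0
            feats[f"ha{k}_kurt"] = 0.0
        else:
            feats[f"ha{k}_skew"] = float(scipy.stats.skew(x, bias=False))
            feats[f"ha{k}_kurt"] = float(scipy.stats.kurtosis(x, fisher=True, bias=False))
    if morpho_means:
        feats.update({k: float(v) for k, v in morpho_means.items()})
    if any(not np.isfinite(v) for v in feats.values()):
        raise ValueError("non-finite feature encountered")
    return RamShapeSummary(
        ram_id=ram_id, n_sperm=amp.shape[0], features=feats, group=group, degenerate=degenerate
    )


@dataclass
class AverageShape:
    """Cohort mean contour in the aligned frame."""

    theta: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    n_shapes: int

    def polygon(self) -> np.ndarray:
        return np.column_stack(
            [self.mean_r * np.cos(self.theta), self.mean_r * np.sin(self.theta)]
        )


def _alignment_transform(vertices: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Centroid, rotation and reflection normalizing one contour.

    The shape is centred on its area centroid and rotated so the major
    principal axis is horizontal; the anterior end (toward which the area
    mass is concentrated, i.e. the third moment tail points away) faces
    +x, and the shape is reflected if needed so the signed area skew along
    the minor axis is non-negative.  Uses exact polygon moments, so the
    transform is exactly equivariant under rotation of the input.
    """
    c = geom.polygon_centroid(vertices)
    shifted = vertices - c
    mu = {
        (p, q): geom.polygon_moment(shifted, p, q)
        for p in range(4)
        for q in range(4 - p)
    }
    aniso = (mu[(2, 0)] - mu[(0, 2)]) ** 2 + 4 * mu[(1, 1)] ** 2
    if aniso < 1e-12 * (mu[(2, 0)] + mu[(0, 2)]) ** 2:
        warnings.warn("near-circular shape: alignment orientation is arbitrary")
    angle = geom.principal_axis_angle(mu)
    rot = np.array([[np.cos(-angle), -np.sin(-angle)], [np.sin(-angle), np.cos(-angle)]])
    aligned = shifted @ rot.T
    if geom.polygon_moment(aligned, 3, 0) > 0:
        angle += np.pi
        aligned = -aligned
    reflect = geom.polygon_moment(aligned, 0, 3) < 0
    return c, angle, reflect


def average_shape(
    shapes: list[PerimeterTrace] | list[HarmonicSet] | list[np.ndarray],
    n_samples: int = 256,
    alignment_policy: str = "principal_axis",
) -> AverageShape:
    """Average contour of many nuclei after pose normalization.

    Each shape is centred, rotated so its major axis is horizontal with the
    anterior end at +x, optionally reflected (see ``_alignment_transform``),
    resampled at common angles, and the radii are averaged.  Returns the
    mean polygon and the per-angle SD.  ``alignment_policy="none"`` skips
    pose normalization (shapes assumed pre-aligned).
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 shapes to average")
    if alignment_policy not in {"principal_axis", "none"}:
        raise ValueError(f"unknown alignment policy {alignment_policy!r}")
    theta = np.arange(n_samples) * (2 * np.pi / n_samples)
    radii = np.empty((len(shapes), n_samples))
    for i, s in enumerate(shapes):
        if isinstance(s, HarmonicSet):
            vertices = s.to_polygon(max(720, 4 * n_samples))
        elif isinstance(s, PerimeterTrace):
            vertices = s.vertices
        else:
            vertices = np.asarray(s, dtype=float)
        if alignment_policy == "principal_axis":
            c, angle, reflect = _alignment_transform(vertices)
            # query the *original* polygon along rotated rays: exact, no
            # resampling loss from an intermediate rotated copy
            q_theta = angle + (-theta if reflect else theta)
            r, _ = geom.ray_radii(vertices, c, q_theta)
        else:
            c = geom.polygon_centroid(vertices)
            r, _ = geom.ray_radii(vertices, c, theta)
        if np.any(np.isnan(r)):
            raise NonStarShapeError("shape not star-shaped about its centroid")
        radii[i] = r
    return AverageShape(
        theta=theta,
        mean_r=radii.mean(axis=0),
        sd_r=radii.std(axis=0, ddof=0),
        n_shapes=len(shapes),
    )
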