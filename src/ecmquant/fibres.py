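"""ECM fibre orientation by the structure tensor, and alignment statistics.

Per-pixel orientation is the axis of least intensity variation of the
Gaussian-windowed structure tensor; the summary statistic is the fraction of
(weighted) orientation mass within 10° of the modal orientation, a measure of
how aligned the fibre field is.  Angles are axial, degrees in (-90, 90],
measured from +x towards +y with y up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import structure_tensor

from .spheroid import max_project

__all__ = [
    "OrientationField",
    "OrientationDistribution",
    "structure_tensor_orientation",
    "orientation_histogram",
    "mode_orientation",
    "aligned_fraction",
    "project_stacks",
    "angles_to_distribution",
]


@dataclass
class OrientationField:
    """Per-pixel axial orientation (deg in (-90, 90]) with non-negative
    weights (gradient energy by default, coherence optionally)."""

    angle_deg: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if self.angle_deg.shape != self.weight.shape:
            raise ValueError("angle/weight shapes differ")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")


@dataclass
class OrientationDistribution:
    """Normalised circular histogram over (-90, 90], period 180°."""

    bin_centers_deg: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_centers_deg.shape != self.mass.shape:
            raise ValueError("shape mismatch")
        if not math.isclose(float(self.mass.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("mass must sum to 1")


def structure_tensor_orientation(
    img: np.ndarray,
    window_sigma_px: float = 2.0,
    presmooth_sigma_px: float = 1.0,
    weighting: str = "energy",
) -> OrientationField:
    """Per-pixel fibre orientation from the structure tensor.

    The image is pre-smoothed (``presmooth_sigma_px``), gradients are taken by
    central differences, and the tensor components Jxx = <Ix^2>, Jyy = <Iy^2>,
    Jxy = <Ix Iy> are averaged in a Gaussian window of ``window_sigma_px``.
    The fibre axis (perpendicular to the dominant gradient) is
    theta = 1/2 * atan2(2 Jxy, Jxx - Jyy) + 90°, mapped to (-90, 90].

    ``weighting`` selects the per-pixel weight: ``"energy"`` (Jxx + Jyy) or
    ``"coherence"`` ((l1 - l2)/(l1 + l2), 0 where the energy vanishes).
    A constant image yields all-zero weights (angles set to 0) with a warning.
    """
    if window_sigma_px <= 0:
        raise ValueError("window_sigma_px must be positive")
    img = np.asarray(img, dtype=np.float64)
    if presmooth_sigma_px > 0:
        img = ndi.gaussian_filter(img, presmooth_sigma_px, mode="reflect")
    Arr, Arc, Acc = structure_tensor(img, sigma=window_sigma_px, mode="reflect", order="rc")
    # x = col, y up = -row  =>  Jxx = Acc, Jyy = Arr, Jxy = -Arc
    jxx, jyy, jxy = Acc, Arr, -Arc
    theta_grad = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = np.degrees(theta_grad) + 90.0          # fibre axis ⟂ gradient
    theta = (theta + 90.0) % 180.0 - 90.0
    theta[theta == -90.0] = 90.0

    energy = jxx + jyy
    if weighting == "energy":
        weight = energy
    elif weighting == "coherence":
        l_diff = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            weight = np.where(energy > 0, l_diff / np.where(energy > 0, energy, 1.0), 0.0)
    else:
        raise ValueError("weighting must be 'energy' or 'coherence'")
    zero = energy <= 0
    theta = np.where(zero, 0.0, theta)
    weight = np.where(zero, 0.0, weight)
    if not np.any(weight > 0):
        warnings.warn("orientation field has zero total weight (constant image?)")
    return OrientationField(angle_deg=theta, weight=weight)


def orientation_histogram(
    field: OrientationField, binwidth_deg: float = 1.0
) -> OrientationDistribution:
    """Weight-weighted orientation histogram over (-90, 90], normalised to 1."""
    if 180.0 % binwidth_deg:
        raise ValueError("binwidth must divide 180")
    edges = np.arange(-90.0, 90.0 + binwidth_deg / 2, binwidth_deg)
    mass, _ = np.histogram(
        field.angle_deg.ravel(), bins=edges, weights=field.weight.ravel()
    )
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total weight: orientation distribution undefined")
    centers = edges[:-1] + binwidth_deg / 2.0
    return OrientationDistribution(bin_centers_deg=centers, mass=mass / total)


def angles_to_distribution(
    angles_deg: np.ndarray,
    binwidth_deg: float = 1.0,
    weights: np.ndarray | None = None,
) -> OrientationDistribution:
    """Histogram of raw axial angle samples (unit weights by default)."""
    angles = np.asarray(angles_deg, dtype=np.float64)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float)
    return orientation_histogram(
        OrientationField(angle_deg=angles, weight=w), binwidth_deg
    )


def mode_orientation(dist: OrientationDistribution) -> float:
    """Bin centre of maximal mass; ties resolve to the smallest angle."""
    return float(dist.bin_centers_deg[int(np.argmax(dist.mass))])


def aligned_fraction(dist: OrientationDistribution, halfwidth_deg: float = 10.0) -> float:
    """Orientation mass within ±``halfwidth_deg`` of the mode, with circular
    wrap-around at ±90° (period 180°).  Bins whose centres lie within the
    window, inclusive, are counted: with 1° bins and a 10° half-width that is
    21 bins, so a continuous-uniform field gives ≈ 21/180."""
    mode = mode_orientation(dist)
    d = np.abs((dist.bin_centers_deg - mode + 90.0) % 180.0 - 90.0)
    return float(dist.mass[d <= halfwidth_deg + 1e-9].sum())


def project_stacks(stacks) -> list[np.ndarray]:
    """Maximal projection of each z-stack (one projected field per stack)."""
    return [max_project(s) for s in stacks]
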