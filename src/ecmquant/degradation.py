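"""Collagen-degradation and matrix-topography quantification.

Covers the DQ-collagen assay (degraded area per cell; low/medium/high ring
scoring and the weighted H-score), second-harmonic-generation mean intensity,
and AFM RMS roughness (Rq).

The H-score of a condition with image counts (n_low, n_medium, n_high) is the
class-weighted mean

    H = (1·n_low + 2·n_medium + 3·n_high) / n_total,   H ∈ [1, 3],

and conditions are compared by the ratio of their H-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops

__all__ = [
    "DegradationRecord",
    "RingMeasurement",
    "degraded_area_per_cell",
    "classify_ring",
    "h_score",
    "degradation_ratio",
    "measure_rings",
    "score_field",
    "shg_mean_intensity",
    "rq_roughness",
]

#: default class boundaries on ring-width / cytoplasm-diameter; midpoints of
#: the anchor ratios 1/4–1/3 and 1/3–1/2
DEFAULT_C12 = 0.29
DEFAULT_C23 = 0.42


@dataclass
class DegradationRecord:
    """Per-condition class counts and H-score."""

    n_low: int
    n_medium: int
    n_high: int

    def __post_init__(self) -> None:
        if min(self.n_low, self.n_medium, self.n_high) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_low + self.n_medium + self.n_high

    @property
    def h_score(self) -> float:
        return h_score(self.n_low, self.n_medium, self.n_high)


@dataclass
class RingMeasurement:
    """Peri-cytoplasmic degradation ring of one cell."""

    ring_width_px: float
    cytoplasm_diameter_px: float

    @property
    def ratio(self) -> float:
        r = self.ring_width_px / self.cytoplasm_diameter_px
        if not 0 <= r < 1:
            raise ValueError("ring/diameter ratio must lie in [0, 1)")
        return r


def h_score(n_low: int, n_medium: int, n_high: int) -> float:
    """Weighted mean degradation class, H = (1·n1 + 2·n2 + 3·n3) / n."""
    n = n_low + n_medium + n_high
    if n <= 0:
        raise ValueError("H-score undefined for zero images")
    if min(n_low, n_medium, n_high) < 0:
        raise ValueError("counts must be non-negative")
    return (1 * n_low + 2 * n_medium + 3 * n_high) / n


def degradation_ratio(h_treated: float, h_control: float) -> float:
    """Fold change in degradation between two conditions' H-scores."""
    if h_control <= 0:
        raise ValueError("control H-score must be positive")
    return h_treated / h_control


def classify_ring(
    m: RingMeasurement, c12: float = DEFAULT_C12, c23: float = DEFAULT_C23
) -> int:
    """Intensity class of a degradation ring: 1 (low, ratio < c12),
    2 (medium), 3 (high, ratio >= c23).  The anchors are ring widths of
    <1/4, ~1/3 and ~1/2 of the cytoplasmic diameter."""
    if not 0 < c12 < c23 < 1:
        raise ValueError("need 0 < c12 < c23 < 1")
    r = m.ratio
    if r < c12:
        return 1
    if r < c23:
        return 2
    return 3


# ---------------------------------------------------------------------------
# image measurement
# ---------------------------------------------------------------------------


def _background_level(dq: np.ndarray, border_px: int = 8) -> float:
    """Robust intact-collagen intensity from the image border frame."""
    b = border_px
    frame = np.concatenate(
        [dq[:b].ravel(), dq[-b:].ravel(), dq[:, :b].ravel(), dq[:, -b:].ravel()]
    )
    return float(np.median(frame))


def count_nuclei(nuclei: np.ndarray, min_distance: int = 5) -> int:
    """Nucleus count by local-maxima blob detection on the DAPI channel."""
    nuclei = np.asarray(nuclei, dtype=np.float64)
    if nuclei.max() <= 0:
        return 0
    sm = ndi.gaussian_filter(nuclei, 1.0)
    peaks = peak_local_max(sm, min_distance=min_distance, threshold_abs=0.3 * sm.max())
    return len(peaks)


def degraded_area_per_cell(
    dq: np.ndarray,
    nuclei: np.ndarray,
    threshold_fraction: float = 0.5,
    border_px: int = 8,
) -> float:
    """Degraded DQ-collagen area normalised to cell number.

    Degraded pixels are those below ``threshold_fraction`` of the robust
    background intensity (median of the cell-free border frame); degradation
    abolishes the fluorescence of the quenched-collagen substrate.  Cell
    number comes from blob detection on the nuclear channel.
    """
    dq = np.asarray(dq, dtype=np.float64)
    if dq.shape != np.asarray(nuclei).shape:
        raise ValueError("channel shapes differ")
    n = count_nuclei(nuclei)
    if n == 0:
        raise ValueError("no nuclei detected")
    bg = _background_level(dq, border_px)
    degraded = dq < threshold_fraction * bg
    return float(degraded.sum()) / n


def measure_rings(
    dq: np.ndarray,
    cytoplasm: np.ndarray,
    threshold_fraction: float = 0.5,
    border_px: int = 8,
) -> list[RingMeasurement]:
    """Measure the peri-cytoplasmic degradation ring of every cell.

    Cells are the connected components of the cytoplasm channel (half-max
    threshold).  Degraded (dark-DQ) pixels are assigned to the nearest cell;
    per cell the ring width is recovered from the annulus area:
    w = sqrt(R² + A/π) − R with R the equivalent cytoplasm radius.
    """
    dq = np.asarray(dq, dtype=np.float64)
    cyto = np.asarray(cytoplasm, dtype=np.float64)
    if cyto.max() <= 0:
        return []
    cells = label(cyto > 0.5 * cyto.max())
    props = regionprops(cells)
    if not props:
        return []
    bg = _background_level(dq, border_px)
    degraded = dq < threshold_fraction * bg
    # nearest-cell assignment of degraded pixels
    _, (ir, ic) = ndi.distance_transform_edt(cells == 0, return_indices=True)
    owner = cells[ir, ic]
    out: list[RingMeasurement] = []
    for p in props:
        ring_area = float(np.sum(degraded & (owner == p.label)))
        R = math.sqrt(p.area / math.pi)
        wring = math.sqrt(R * R + ring_area / math.pi) - R
        out.append(RingMeasurement(ring_width_px=wring, cytoplasm_diameter_px=2 * R))
    return out


def score_field(
    dq: np.ndarray,
    cytoplasm: np.ndarray,
    c12: float = DEFAULT_C12,
    c23: float = DEFAULT_C23,
    per: str = "cell",
) -> DegradationRecord:
    """Classify every cell's ring (or the image's mean ring, per='image')
    and aggregate to a DegradationRecord."""
    rings = measure_rings(dq, cytoplasm)
    if not rings:
        raise ValueError("no cells found")
    if per == "image":
        mean_ratio = float(np.mean([m.ratio for m in rings]))
        rings = [RingMeasurement(mean_ratio, 1.0)]
    classes = [classify_ring(m, c12, c23) for m in rings]
    return DegradationRecord(
        n_low=classes.count(1), n_medium=classes.count(2), n_high=classes.count(3)
    )


# ---------------------------------------------------------------------------
# SHG and AFM
# ---------------------------------------------------------------------------


def shg_mean_intensity(
    zstack, n_rois: int = 3, roi_size: tuple[int, int] | None = None
) -> list[float]:
    """Mean intensity of the z-stack *sum* projection in ``n_rois`` equal,
    non-overlapping grid-placed ROIs (vertical strips by default)."""
    stack = [np.asarray(s, dtype=np.float64) for s in zstack]
    if not stack:
        raise ValueError("empty stack")
    proj = np.sum(stack, axis=0)
    h, w = proj.shape
    if roi_size is None:
        roi_w = w // n_rois
        roi_size = (h, roi_w)
    rh, rw = roi_size
    if rh > h or rw * n_rois > w:
        raise ValueError("ROIs do not fit")
    return [float(proj[:rh, i * rw : (i + 1) * rw].mean()) for i in range(n_rois)]


def rq_roughness(height: np.ndarray, level: bool = False) -> float:
    """RMS roughness Rq = sqrt(mean((z − mean z)²)) of a height map.

    With ``level=True`` a least-squares plane is removed first (tilt
    correction); the default follows the plain RMS-about-the-mean definition.
    """
    z = np.asarray(height, dtype=np.float64)
    if z.size < 2:
        raise ValueError("need at least 2 pixels")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite heights")
    if level:
        h, w = z.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        A = np.column_stack([np.ones(z.size), xx.ravel(), yy.ravel()])
        coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
        z = z - (A @ coef).reshape(z.shape)
    return float(np.sqrt(np.mean((z - z.mean()) ** 2)))
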