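"""Synthetic fixtures with machine-readable ground truth.

Every downstream quantification stage (spheroid invasion, fibre orientation,
DQ-collagen degradation, AFM roughness, signature/survival scoring) can be
exercised against images and tables generated here, where the planted geometry
is known exactly.  All generators are pure functions of an explicit integer
seed; no global random state is touched.

Conventions
-----------
* Images are float64 arrays in (row, col) storage; coordinates are reported as
  (x, y) = (col, row), 0-based.
* Orientation angles are axial (period 180°) in degrees, in (-90, 90], measured
  from the +x axis towards +y with y pointing *up* (standard maths convention on
  a displayed image this means counter-clockwise).
* Nuclei are rendered as isotropic Gaussian spots with sigma = nucleus_radius/2,
  truncated at 3 sigma, blended by per-pixel maximum (fluorophores saturate
  rather than sum in a dense core).  The ground-truth "footprint" of a nucleus
  is its full-width-half-maximum disc, radius sigma*sqrt(2 ln 2).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpheroidSpec",
    "SpheroidGroundTruth",
    "FibreFieldSpec",
    "DegradationFieldSpec",
    "DegradationImages",
    "DegradationGroundTruth",
    "SurvivalSimSpec",
    "ExpressionDataset",
    "SurvivalGroundTruth",
    "nucleus_footprint_radius",
    "make_spheroid_image",
    "make_fibre_image",
    "make_stripe_image",
    "make_degradation_image",
    "make_height_map",
    "make_expression_dataset",
    "write_ground_truth_json",
]

#: Ring-width / cytoplasm-diameter ratio ranges the three degradation classes
#: are drawn from (low, medium, high).  Anchors: class 1 < 1/4, class 2 ~ 1/3,
#: class 3 ~ 1/2 of the cytoplasmic diameter.
RING_RATIO_RANGES = ((0.12, 0.22), (0.30, 0.36), (0.45, 0.55))


def nucleus_footprint_radius(nucleus_radius_px: float) -> float:
    """FWHM radius of the rendered Gaussian nucleus (sigma = r/2)."""
    return 0.5 * nucleus_radius_px * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# spheroid invasion fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpheroidSpec:
    """Geometry and imaging parameters of one synthetic spheroid field.

    The field emulates a Hoechst (nuclear) channel: a dense spheroid core of
    radius ``core_radius_px``, an invasive halo of ``halo_cell_count`` nuclei
    scattered in the annulus up to ``halo_outer_radius_px``, and
    ``single_cell_count`` individually invading nuclei placed beyond
    ``single_cell_min_dist_px`` from the centre.  ``snr`` is peak nuclear
    signal over the additive Gaussian noise sigma; the illumination gradient
    is a multiplicative planar ramp of mean 1 and half-range
    ``illumination_gradient_amplitude``.
    """

    image_size_px: tuple[int, int] = (384, 384)
    core_radius_px: float = 55.0
    halo_cell_count: int = 180
    halo_outer_radius_px: float = 130.0
    single_cell_count: int = 20
    single_cell_min_dist_px: float = 170.0
    nucleus_radius_px: float = 5.0
    snr: float = 8.0
    illumination_gradient_amplitude: float = 0.2
    seed: int = 0
    n_slices: int = 3

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image_size_px must be positive")
        if not (
            0
            < self.core_radius_px
            < self.halo_outer_radius_px
            < self.single_cell_min_dist_px
            < min(h, w) / 2
        ):
            raise ValueError(
                "require core_radius < halo_outer_radius < single_cell_min_dist"
                " < min(image_size)/2"
            )
        if self.halo_cell_count < 0 or self.single_cell_count < 0:
            raise ValueError("counts must be non-negative")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0 <= self.illumination_gradient_amplitude < 1:
            raise ValueError("illumination_gradient_amplitude must be in [0, 1)")
        if self.n_slices < 1:
            raise ValueError("need at least one z-slice")


@dataclass
class SpheroidGroundTruth:
    """Planted geometry of a synthetic spheroid field.

    Areas are pixel counts of the planted masks: ``core_area_px2`` the core
    disc, ``halo_area_px2`` the union of halo-nucleus FWHM footprints outside
    the core disc.  ``single_cell_centroids`` are (x, y) pairs.
    """

    core_area_px2: int
    halo_area_px2: int
    single_cell_centroids: list[tuple[float, float]]
    centre_px: tuple[float, float]
    core_radius_px: float
    nucleus_radius_px: float
    halo_centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def invasive_area_pct(self) -> float:
        total = self.core_area_px2 + self.halo_area_px2
        return 100.0 * self.halo_area_px2 / total if total else float("nan")


def _render_spots(
    shape: tuple[int, int],
    centres: np.ndarray,
    sigma: float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Max-blend Gaussian spots (truncated at 3 sigma) into an image."""
    img = np.zeros(shape, dtype=np.float64) if out is None else out
    if len(centres) == 0:
        return img
    r = int(math.ceil(3.0 * sigma))
    h, w = shape
    ax = np.arange(-r, r + 1, dtype=np.float64)
    for cx, cy in centres:
        col, row = int(round(cx)), int(round(cy))
        r0, r1 = max(row - r, 0), min(row + r + 1, h)
        c0, c1 = max(col - r, 0), min(col + r + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1, dtype=np.float64) - cy
        xx = np.arange(c0, c1, dtype=np.float64) - cx
        d2 = yy[:, None] ** 2 + xx[None, :] ** 2
        spot = np.exp(-d2 / (2.0 * sigma * sigma))
        spot[d2 > (3.0 * sigma) ** 2] = 0.0
        np.maximum(img[r0:r1, c0:c1], spot, out=img[r0:r1, c0:c1])
    return img


def _illumination_ramp(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative planar shading field, normalised to mean 1."""
    h, w = shape
    theta = rng.uniform(0, 2 * math.pi)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    u = (xx - (w - 1) / 2) / max(w - 1, 1) * math.cos(theta) + (
        yy - (h - 1) / 2
    ) / max(h - 1, 1) * math.sin(theta)
    # u in [-~0.5, ~0.5] along the ramp direction, zero mean by symmetry
    ramp = 1.0 + 2.0 * amplitude * u
    return ramp / ramp.mean()


def make_spheroid_image(
    spec: SpheroidSpec,
) -> tuple[list[np.ndarray], SpheroidGroundTruth]:
    """Render a synthetic Hoechst z-stack of an invading spheroid.

    Returns the stack (list of 2-D float arrays, peak nuclear signal 1.0
    before shading/noise) and the exact planted geometry.  The maximal
    projection of the stack contains the dense core disc, every halo nucleus
    and every isolated single cell.

    Raises
    ------
    ValueError
        If the requested number of single cells cannot be placed in the
        available area outside ``single_cell_min_dist_px``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    sigma = spec.nucleus_radius_px / 2.0
    fp = nucleus_footprint_radius(spec.nucleus_radius_px)

    # halo nuclei: uniform over the annulus (area-uniform radius)
    r2 = rng.uniform(spec.core_radius_px**2, spec.halo_outer_radius_px**2, spec.halo_cell_count)
    ang = rng.uniform(0, 2 * math.pi, spec.halo_cell_count)
    halo = np.column_stack([cx + np.sqrt(r2) * np.cos(ang), cy + np.sqrt(r2) * np.sin(ang)])

    # isolated single cells: rejection sampling with margin and separation
    singles: list[tuple[float, float]] = []
    margin = 3.0 * sigma + 1.0
    min_sep = 4.0 * spec.nucleus_radius_px
    tries = 0
    while len(singles) < spec.single_cell_count:
        tries += 1
        if tries > 20000:
            raise ValueError(
                f"cannot place {spec.single_cell_count} isolated cells beyond "
                f"{spec.single_cell_min_dist_px} px in a {h}x{w} image"
            )
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if math.hypot(x - cx, y - cy) < spec.single_cell_min_dist_px:
            continue
        if any(math.hypot(x - sx, y - sy) < min_sep for sx, sy in singles):
            continue
        singles.append((x, y))

    # dense core: a filled disc at full nuclear intensity with slight texture
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dist = np.hypot(xx - cx, yy - cy)
    core_profile = np.clip((spec.core_radius_px - dist) / max(sigma, 1.0) + 0.5, 0.0, 1.0)

    # distribute halo + single nuclei across slices; core present in every slice
    slice_of = rng.integers(0, spec.n_slices, len(halo) + len(singles))
    shading = _illumination_ramp((h, w), spec.illumination_gradient_amplitude, rng)
    noise_sigma = 0.0 if math.isinf(spec.snr) else 1.0 / spec.snr

    all_centres = np.concatenate([halo, np.asarray(singles).reshape(-1, 2)]) if (
        len(halo) or singles
    ) else np.empty((0, 2))
    stack: list[np.ndarray] = []
    for z in range(spec.n_slices):
        signal = core_profile.copy()
        centres_z = all_centres[slice_of == z] if len(all_centres) else all_centres
        _render_spots((h, w), centres_z, sigma, out=signal)
        img = signal * shading
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=(h, w))
        stack.append(img)

    core_mask = dist <= spec.core_radius_px
    halo_mask = np.zeros((h, w), dtype=bool)
    for hx, hy in halo:
        halo_mask |= np.hypot(xx - hx, yy - hy) <= fp
    halo_mask &= ~core_mask

    truth = SpheroidGroundTruth(
        core_area_px2=int(core_mask.sum()),
        halo_area_px2=int(halo_mask.sum()),
        single_cell_centroids=[(float(x), float(y)) for x, y in singles],
        centre_px=(cx, cy),
        core_radius_px=spec.core_radius_px,
        nucleus_radius_px=spec.nucleus_radius_px,
        halo_centroids=[(float(x), float(y)) for x, y in halo],
    )
    return stack, truth


# ---------------------------------------------------------------------------
# fibre orientation fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FibreFieldSpec:
    """Synthetic ECM fibre micrograph: anti-aliased line segments whose axial
    orientations follow a von Mises distribution on the doubled angle 2θ
    (kappa = 0 is uniform; larger kappa concentrates around mean_angle_deg)."""

    image_size_px: tuple[int, int] = (512, 512)
    fibre_count: int = 300
    mean_angle_deg: float = 0.0
    concentration_kappa: float = 2.0
    fibre_length_px: float = 80.0
    fibre_width_px: float = 2.0
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fibre_count <= 0:
            raise ValueError("fibre_count must be positive")
        if self.concentration_kappa < 0:
            raise ValueError("concentration kappa must be >= 0")
        if not -90 < self.mean_angle_deg <= 90:
            raise ValueError("mean_angle_deg must lie in (-90, 90]")
        if self.fibre_length_px <= 0 or self.fibre_width_px <= 0:
            raise ValueError("fibre geometry must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def sample_axial_angles(
    n: int, mean_angle_deg: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw axial angles (deg, period 180) from von Mises on the doubled angle."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        theta = rng.uniform(-90.0, 90.0, n)
    else:
        phi = rng.vonmises(math.radians(2.0 * mean_angle_deg), kappa, n)
        theta = np.degrees(phi) / 2.0
    # map to (-90, 90]
    theta = (theta + 90.0) % 180.0 - 90.0
    theta[theta == -90.0] = 90.0
    return theta


def make_fibre_image(spec: FibreFieldSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a fibre field; returns (image, drawn axial angles in degrees)."""
    from skimage.draw import line_aa

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    angles = sample_axial_angles(
        spec.fibre_count, spec.mean_angle_deg, spec.concentration_kappa, rng
    )
    img = np.zeros((h, w), dtype=np.float64)
    half = spec.fibre_length_px / 2.0
    n_strands = max(1, int(round(spec.fibre_width_px)))
    for theta in angles:
        t = math.radians(theta)
        # direction in (col, row) with y pointing up => drow = -sin
        dx, dy = math.cos(t), -math.sin(t)
        nx, ny = -dy, dx  # unit normal
        cx0 = rng.uniform(0, w - 1)
        cy0 = rng.uniform(0, h - 1)
        for k in range(n_strands):
            off = k - (n_strands - 1) / 2.0
            x0, y0 = cx0 - half * dx + off * nx, cy0 - half * dy + off * ny
            x1, y1 = cx0 + half * dx + off * nx, cy0 + half * dy + off * ny
            rr, cc, val = line_aa(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc, val = rr[keep], cc[keep], val[keep]
            np.maximum.at(img, (rr, cc), val)
    if not math.isinf(spec.snr):
        img = img + rng.normal(0.0, 1.0 / spec.snr, size=(h, w))
    return img, angles


def make_stripe_image(
    angle_deg: float, shape: tuple[int, int] = (256, 256), period_px: float = 12.0
) -> np.ndarray:
    """Sinusoidal stripe pattern whose stripes run along ``angle_deg`` (axial
    convention: from +x towards +y, y up)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    t = math.radians(angle_deg)
    # gradient direction is the stripe normal (angle + 90 deg)
    gx, gy = -math.sin(t), math.cos(t)  # (col, y-up) components of the normal
    phase = 2 * math.pi * (xx * gx + (-yy) * gy) / period_px
    return 0.5 + 0.5 * np.cos(phase)


# ---------------------------------------------------------------------------
# DQ-collagen degradation fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegradationFieldSpec:
    """Synthetic DQ-collagen well: cells (cytoplasm disc + nucleus) sitting on
    a bright intact-collagen background, each surrounded by a dark
    peri-cytoplasmic ring of degraded (quenched-away) collagen whose
    width/diameter ratio is drawn from one of three intensity classes."""

    cell_count: int = 300
    class_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    cytoplasm_diameter_px: float = 30.0
    background_intensity: float = 1.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")
        p = np.asarray(self.class_probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or np.any(p > 1) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class_probabilities must be a 3-vector in [0,1] summing to 1")
        if self.cytoplasm_diameter_px <= 0 or self.background_intensity <= 0:
            raise ValueError("geometry/intensity must be positive")


@dataclass
class DegradationImages:
    dq: np.ndarray          # intact DQ collagen (dark where degraded)
    cytoplasm: np.ndarray   # phalloidin-like channel
    nuclei: np.ndarray      # DAPI-like channel


@dataclass
class DegradationGroundTruth:
    labels: list[int]                        # true class per cell (1/2/3)
    centres_px: list[tuple[float, float]]    # (x, y)
    ring_ratios: list[float]                 # ring width / cytoplasm diameter
    ring_areas_px2: list[float]              # analytic annulus areas
    cytoplasm_diameter_px: float


def make_degradation_image(
    spec: DegradationFieldSpec,
) -> tuple[DegradationImages, DegradationGroundTruth]:
    """Render the three-channel degradation field and the true class labels.

    Cells are laid out on a jittered grid so cytoplasm discs and degradation
    rings never overlap; the DQ channel is ``background_intensity`` everywhere
    except the rings, which are quenched to ~5% of background.
    """
    rng = np.random.default_rng(spec.seed)
    D = spec.cytoplasm_diameter_px
    R = D / 2.0
    max_ring = RING_RATIO_RANGES[2][1] * D
    pitch = int(math.ceil(2 * (R + max_ring) + 8))
    n = spec.cell_count
    if n == 0:
        blank = np.full((64, 64), spec.background_intensity)
        imgs = DegradationImages(blank.copy(), np.zeros((64, 64)), np.zeros((64, 64)))
        return imgs, DegradationGroundTruth([], [], [], [], D)

    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    border = pitch  # cell-free frame for background estimation
    h = nrows * pitch + 2 * border
    w = ncols * pitch + 2 * border

    labels = rng.choice([1, 2, 3], size=n, p=np.asarray(spec.class_probabilities))
    ratios = np.array(
        [rng.uniform(*RING_RATIO_RANGES[lab - 1]) for lab in labels]
    )
    jitter = (pitch / 2.0) - (R + max_ring) - 2.0

    dq = np.full((h, w), spec.background_intensity, dtype=np.float64)
    cyto = np.zeros((h, w), dtype=np.float64)
    nuc = np.zeros((h, w), dtype=np.float64)
    centres: list[tuple[float, float]] = []
    ring_areas: list[float] = []
    for i in range(n):
        gr, gc = divmod(i, ncols)
        cy = border + gr * pitch + pitch / 2.0 + rng.uniform(-jitter, jitter)
        cx = border + gc * pitch + pitch / 2.0 + rng.uniform(-jitter, jitter)
        wring = ratios[i] * D
        rad = int(math.ceil(R + wring)) + 2
        r0, r1 = int(cy) - rad, int(cy) + rad + 1
        c0, c1 = int(cx) - rad, int(cx) + rad + 1
        yy = np.arange(r0, r1, dtype=np.float64) - cy
        xx = np.arange(c0, c1, dtype=np.float64) - cx
        d = np.hypot(yy[:, None], xx[None, :])
        # soft-edged discs (half-pixel anti-aliasing) so areas are accurate
        cyto[r0:r1, c0:c1] = np.maximum(
            cyto[r0:r1, c0:c1], np.clip(R - d + 0.5, 0, 1)
        )
        nuc[r0:r1, c0:c1] = np.maximum(
            nuc[r0:r1, c0:c1], np.clip(R / 3.0 - d + 0.5, 0, 1)
        )
        ring = np.clip(d - R + 0.5, 0, 1) * np.clip(R + wring - d + 0.5, 0, 1)
        dq[r0:r1, c0:c1] -= 0.95 * spec.background_intensity * ring
        centres.append((float(cx), float(cy)))
        ring_areas.append(math.pi * ((R + wring) ** 2 - R**2))

    if spec.noise_sigma > 0:
        dq = dq + rng.normal(0, spec.noise_sigma * spec.background_intensity, dq.shape)
    imgs = DegradationImages(dq, cyto, nuc)
    truth = DegradationGroundTruth(
        labels=[int(x) for x in labels],
        centres_px=centres,
        ring_ratios=[float(r) for r in ratios],
        ring_areas_px2=ring_areas,
        cytoplasm_diameter_px=D,
    )
    return imgs, truth


# ---------------------------------------------------------------------------
# AFM height maps
# ---------------------------------------------------------------------------


def make_height_map(
    pattern: str,
    amplitude: float,
    size: tuple[int, int] = (128, 128),
    n_periods: int = 4,
) -> tuple[np.ndarray, float]:
    """Height matrix with a closed-form RMS roughness Rq.

    Patterns: ``constant`` (Rq = 0), ``two_level`` (±amplitude on each half,
    Rq = amplitude), ``sinusoid`` (amplitude A over an integer number of
    periods, Rq = A/sqrt(2)).
    """
    h, w = size
    if pattern == "constant":
        return np.full((h, w), amplitude, dtype=np.float64), 0.0
    if pattern == "two_level":
        if w % 2:
            raise ValueError("two_level needs an even width")
        z = np.empty((h, w), dtype=np.float64)
        z[:, : w // 2] = amplitude
        z[:, w // 2 :] = -amplitude
        return z, abs(amplitude)
    if pattern == "sinusoid":
        if w % n_periods:
            raise ValueError("width must be a multiple of n_periods")
        x = np.arange(w, dtype=np.float64)
        z = amplitude * np.sin(2 * math.pi * n_periods * x / w)
        return np.tile(z, (h, 1)), abs(amplitude) / math.sqrt(2.0)
    raise ValueError(f"unknown pattern {pattern!r}")


# ---------------------------------------------------------------------------
# expression / survival fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Expression matrix (log2(x+1) scale) with a planted signature whose
    per-sample geometric-mean score is bimodal, plus exponential survival
    where the true high-score half carries ``hazard_ratio_high_vs_low``."""

    n_samples: int = 200
    n_genes: int = 500
    signature_genes: tuple[str, ...] = tuple(f"SIG{i}" for i in range(12))
    hazard_ratio_high_vs_low: float = 2.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.2
    score_separation_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.hazard_ratio_high_vs_low <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if len(self.signature_genes) == 0:
            raise ValueError("signature must contain at least one gene")
        if len(self.signature_genes) > self.n_genes:
            raise ValueError("signature larger than the gene universe")


@dataclass
class ExpressionDataset:
    """Genes x samples matrix of log2(x+1)-normalised expression with an
    optional survival table (columns: time, event) indexed by sample."""

    values: "object"   # pandas.DataFrame, genes x samples
    survival: "object" = None  # pandas.DataFrame or None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SurvivalGroundTruth:
    true_score: "object"      # pandas.Series per sample
    true_group: "object"      # pandas.Series of {"high","low"}


def make_expression_dataset(
    spec: SurvivalSimSpec,
) -> tuple[ExpressionDataset, SurvivalGroundTruth]:
    """Simulate the expression matrix and survival table.

    Exactly half the samples (rounded down) are planted "high": their
    signature genes are shifted up by ``score_separation_sd`` within-group
    standard deviations.  Event times are exponential with hazard
    ``baseline_hazard`` (low) or ``baseline_hazard * hazard_ratio`` (high);
    censoring is independent: with probability ``censoring_rate`` a sample is
    censored uniformly before its event.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    sig = list(spec.signature_genes)
    other = [f"G{i}" for i in range(g - len(sig))]
    genes = sig + other
    samples = [f"S{i:04d}" for i in range(n)]

    values = np.clip(rng.normal(6.0, 1.5, size=(g, n)), 0.01, None)

    # planted groups: an exact half split, randomly assigned
    z = np.zeros(n, dtype=bool)
    z[rng.permutation(n)[: n // 2]] = True
    within_sd = 0.5
    base_level = 5.0
    latent = base_level + spec.score_separation_sd * within_sd * z + rng.normal(
        0.0, within_sd, n
    )
    for i in range(len(sig)):
        values[i, :] = np.clip(latent + rng.normal(0.0, 0.3, n), 0.01, None)

    df = pd.DataFrame(values, index=genes, columns=samples)

    # survival: geometric-mean score of the planted signature defines truth
    true_score = pd.Series(np.exp(np.mean(np.log(values[: len(sig), :]), axis=0)), index=samples)
    med = true_score.median()
    true_group = pd.Series(
        np.where(true_score > med, "high", "low"), index=samples
    )
    hazard = spec.baseline_hazard * np.where(
        true_group.values == "high", spec.hazard_ratio_high_vs_low, 1.0
    )
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=n) < spec.censoring_rate
    time = np.where(censored, rng.uniform(0, t_event), t_event)
    event = (~censored).astype(int)
    surv = pd.DataFrame({"time": time, "event": event}, index=samples)

    ds = ExpressionDataset(values=df, survival=surv)
    return ds, SurvivalGroundTruth(true_score=true_score, true_group=true_group)


# ---------------------------------------------------------------------------
# ground-truth serialisation
# ---------------------------------------------------------------------------


def write_ground_truth_json(truth, path: str | Path) -> None:
    """Write any ground-truth dataclass as a JSON sidecar.

    Coordinates are 0-based (x = column, y = row); spheroid single-cell
    centroids are stored under ``centroids_px``.
    """
    d = dataclasses.asdict(truth)
    if "single_cell_centroids" in d:
        d["centroids_px"] = d.pop("single_cell_centroids")
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(type(o).__name__)
    Path(path).write_text(json.dumps(d, indent=1, default=_default))
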