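"""Digital chest phantoms and the gridless-radiograph forward model.

The forward model maps a 2-D "digital body part" — per-pixel soft-tissue and
bone thickness, in cm — to the signal recorded at the detector: a primary
(directly transmitted) image given by Beer–Lambert attenuation with effective
monoenergetic coefficients, plus a scatter field produced by convolving the
primary with non-stationary, non-isotropic point-spread functions whose width,
shape and amplitude depend on the local equivalent thickness, plus Poisson
counting noise.  The same forward model is both the synthetic test-data source
and the engine inside the inverse scatter solver.

Geometry is parallel-beam: thickness maps are co-registered with the detector
grid (0-based, row-major, pixel centers); source–image distance is metadata
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

__all__ = [
    "MaterialTable",
    "DigitalPhantom",
    "AcquisitionConfig",
    "RawImage",
    "ScatterField",
    "PhantomSpec",
    "SimulatedRadiograph",
    "make_phantom",
    "insert_curve",
    "primary_transmission",
    "scatter_psf",
    "scatter_field",
    "simulate_raw",
    "GeometryError",
]

# Calibration constant in the exposure-index definition (no vendor standard is
# public; printed EI values are treated as non-reproducible metadata).
EXPOSURE_INDEX_GAIN = 0.09

MAX_TOTAL_THICKNESS_CM = 60.0


class GeometryError(ValueError):
    """Phantom geometry does not fit inside the requested image bounds."""


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialTable:
    """Effective linear attenuation coefficients and scatter parameters.

    ``mu_tissue`` and ``mu_bone`` are tabulated at integer kVp over
    ``[kvp_min, kvp_max]`` in 1/cm.  A monoenergetic effective-attenuation
    model is used per kVp (no spectral integration), which keeps the forward
    model invertible.  Scatter amplitude follows a saturating scatter fraction
    ``f(t) = f_max * (1 - exp(-t / t_scale))`` of equivalent tissue thickness
    ``t`` (cm); the PSF widths grow linearly with ``t`` (see
    :func:`scatter_psf`).
    """

    kvp_grid: np.ndarray
    mu_tissue_table: np.ndarray
    mu_bone_table: np.ndarray
    spr_max: float = 5.0
    scatter_t_scale_cm: float = 14.0
    # PSF width model, mm at the patient exit plane
    sigma_narrow_mm: tuple[float, float] = (3.0, 0.5)   # intercept, slope/cm
    sigma_broad_mm: tuple[float, float] = (12.0, 1.5)
    narrow_weight: float = 0.55
    anisotropy_ratio: float = 1.5

    @classmethod
    def default(cls) -> "MaterialTable":
        kvp = np.arange(60, 101, dtype=float)
        mu_t = 0.20 + 0.18 * np.exp(-(kvp - 60.0) / 35.0)
        mu_b = 0.45 + 0.50 * np.exp(-(kvp - 60.0) / 30.0)
        return cls(kvp_grid=kvp, mu_tissue_table=mu_t, mu_bone_table=mu_b)

    def __post_init__(self) -> None:
        k = np.asarray(self.kvp_grid, dtype=float)
        mt = np.asarray(self.mu_tissue_table, dtype=float)
        mb = np.asarray(self.mu_bone_table, dtype=float)
        if not (len(k) == len(mt) == len(mb)):
            raise ValueError("material table length mismatch")
        if not np.all(mt > 0) or not np.all(mb > mt):
            raise ValueError("require mu_bone > mu_tissue > 0 at every kVp")
        if np.any(np.diff(mt) > 0) or np.any(np.diff(mb) > 0):
            raise ValueError("attenuation coefficients must not increase with kVp")

    @property
    def kvp_min(self) -> float:
        return float(self.kvp_grid[0])

    @property
    def kvp_max(self) -> float:
        return float(self.kvp_grid[-1])

    def _check_kvp(self, kvp: float) -> None:
        if not (self.kvp_min <= kvp <= self.kvp_max):
            raise ValueError(
                f"kVp {kvp} outside tabulated range "
                f"[{self.kvp_min}, {self.kvp_max}]"
            )

    def mu_tissue(self, kvp: float) -> float:
        """Effective tissue attenuation (1/cm) at ``kvp``, linearly interpolated."""
        self._check_kvp(kvp)
        return float(np.interp(kvp, self.kvp_grid, self.mu_tissue_table))

    def mu_bone(self, kvp: float) -> float:
        self._check_kvp(kvp)
        return float(np.interp(kvp, self.kvp_grid, self.mu_bone_table))

    def bone_equivalence(self, kvp: float) -> float:
        """Tissue-equivalent thickness of 1 cm of bone (mu_bone/mu_tissue)."""
        return self.mu_bone(kvp) / self.mu_tissue(kvp)

    def spr(self, t_equiv_cm):
        """Local scatter-to-primary ratio S/P for equivalent thickness (cm).

        Saturating growth spr_max * (1 - exp(-t/t_scale)); a gridless AP
        chest reaches ratios of 2-6 behind the mediastinum.
        """
        t = np.asarray(t_equiv_cm, dtype=float)
        r = self.spr_max * (1.0 - np.exp(-t / self.scatter_t_scale_cm))
        return r if r.ndim else float(r)

    def scatter_fraction(self, t_equiv_cm):
        """Scatter fraction f = S/(S+P) in [0, 1), monotone in thickness."""
        r = np.asarray(self.spr(t_equiv_cm))
        f = r / (1.0 + r)
        return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class DigitalPhantom:
    """Per-pixel soft-tissue and bone thickness maps (cm)."""

    t_tissue: np.ndarray
    t_bone: np.ndarray
    pixel_pitch_mm: float = 1.6
    insert_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_tissue = np.asarray(self.t_tissue, dtype=float)
        self.t_bone = np.asarray(self.t_bone, dtype=float)
        if self.t_tissue.shape != self.t_bone.shape:
            raise ValueError("tissue and bone maps must share a shape")
        for name, arr in (("t_tissue", self.t_tissue), ("t_bone", self.t_bone)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if np.any(self.t_tissue + self.t_bone > MAX_TOTAL_THICKNESS_CM):
            raise ValueError(
                f"total thickness exceeds {MAX_TOTAL_THICKNESS_CM} cm"
            )
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.t_tissue.shape

    def equivalent_thickness(self, materials: MaterialTable, kvp: float) -> np.ndarray:
        """Tissue-equivalent thickness map t_tissue + (mu_b/mu_t) * t_bone."""
        return self.t_tissue + materials.bone_equivalence(kvp) * self.t_bone


@dataclass
class AcquisitionConfig:
    """X-ray acquisition settings for one exposure.

    ``i0`` is the unattenuated source fluence in detector counts per pixel at
    1 mAs; the flat-field signal is ``i0 * mas``.
    """

    kvp: float = 85.0
    mas: float = 2.6
    i0: float = 2.0e4
    sid_cm: float = 180.0
    detector_gain: float = 1.0
    pixel_pitch_mm: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.i0 <= 0 or self.mas <= 0:
            raise ValueError("i0 and mAs must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")

    def validate_against(self, materials: MaterialTable) -> None:
        materials._check_kvp(self.kvp)


@dataclass
class RawImage:
    """Detector-intensity array (counts) with acquisition metadata."""

    intensity: np.ndarray
    config: AcquisitionConfig
    exposure_index: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.exposure_index <= 0:
            raise ValueError("exposure_index must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class ScatterField:
    """Per-pixel scatter signal (counts) paired with a primary image."""

    s: np.ndarray
    mean_spr: float
    truncation_loss: float = 0.0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s < 0):
            raise ValueError("scatter must be non-negative")


def exposure_index(intensity: np.ndarray, config: AcquisitionConfig) -> float:
    """EI = 100 * median(counts) / (I0 * g0): a detector-dose summary, linear
    in mAs for a fixed patient (as vendor exposure indices are)."""
    return float(
        100.0 * np.median(intensity) / (config.i0 * EXPOSURE_INDEX_GAIN)
    )


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parametric chest-like phantom: thorax ellipse of tissue, two lung
    ellipses of reduced thickness, ribs and spine of bone, and an optional
    thin curvilinear tube insert (nasogastric/endotracheal hardware
    stand-in)."""

    shape: tuple[int, int] = (256, 256)
    pixel_pitch_mm: float = 1.6
    thorax_semiaxes_cm: tuple[float, float] = (17.0, 13.0)  # (half-width x, half-height y)
    thorax_thickness_cm: float = 22.0
    # baseline patient tissue covering the whole field (shoulders, abdomen,
    # arms): an AP bedside chest leaves almost no unattenuated detector area
    body_thickness_cm: float = 9.0
    lung_deficit: float = 0.65        # fractional tissue reduction inside lungs
    rib_count: int = 6
    rib_thickness_cm: float = 0.35
    spine_width_cm: float = 3.0
    spine_thickness_cm: float = 1.8
    tube_insert: bool = True
    insert_bone_equiv_cm: float = 0.3
    insert_halfwidth_px: float = 1.0

    def __post_init__(self) -> None:
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise GeometryError("phantom shape must be at least 64x64")
        if self.body_thickness_cm > self.thorax_thickness_cm:
            raise GeometryError("body slab thicker than the thorax peak")
        half_w_px = 10.0 * self.thorax_semiaxes_cm[0] / self.pixel_pitch_mm
        half_h_px = 10.0 * self.thorax_semiaxes_cm[1] / self.pixel_pitch_mm
        if 2 * half_w_px >= self.shape[1] or 2 * half_h_px >= self.shape[0]:
            raise GeometryError("thorax axes exceed image bounds")


def insert_curve(spec: PhantomSpec, seed: int, n_samples: int = 2048) -> np.ndarray:
    """Parametric tube path, (n, 2) array of (row, col) pixel coordinates.

    A gentle S-curve descending from the upper airway into the mediastinum;
    the seed jitters the lateral amplitude so repeated phantoms differ.
    """
    rng = np.random.default_rng(seed)
    rows, cols = spec.shape
    cy, cx = float(rows // 2), float(cols // 2)
    half_h_px = 10.0 * spec.thorax_semiaxes_cm[1] / spec.pixel_pitch_mm
    amp = (0.05 + 0.04 * rng.random()) * cols
    t = np.linspace(0.0, 1.0, n_samples)
    r = cy - 0.85 * half_h_px + t * 1.5 * half_h_px
    c = cx + amp * np.sin(2.2 * math.pi * t) * t
    return np.column_stack([r, c])


def _ellipse_mask(shape, center, semiaxes_px):
    yy, xx = np.indices(shape)
    dy = (yy - center[0]) / semiaxes_px[0]
    dx = (xx - center[1]) / semiaxes_px[1]
    return dy * dy + dx * dx <= 1.0


def make_phantom(spec: PhantomSpec, seed: int = 0) -> DigitalPhantom:
    """Build a deterministic chest-like :class:`DigitalPhantom` from a spec.

    A baseline body slab covers the whole field; the thorax is an ellipse of
    tissue with an elliptical-cap thickness profile whose maximum equals
    ``thorax_thickness_cm`` exactly (the center lands on a pixel); lungs
    reduce tissue thickness, ribs and spine add bone, and the optional tube
    insert adds a thin (<= 3 px wide) curvilinear bone-equivalent track.
    """
    rows, cols = spec.shape
    cy, cx = float(rows // 2), float(cols // 2)
    px_per_cm = 10.0 / spec.pixel_pitch_mm
    ax_px = spec.thorax_semiaxes_cm[0] * px_per_cm  # x (col) semi-axis
    ay_px = spec.thorax_semiaxes_cm[1] * px_per_cm  # y (row) semi-axis

    yy, xx = np.indices((rows, cols), dtype=float)
    if ax_px > 0 and ay_px > 0:
        r2 = ((xx - cx) / ax_px) ** 2 + ((yy - cy) / ay_px) ** 2
    else:
        r2 = np.full((rows, cols), np.inf)
    profile = np.sqrt(np.clip(1.0 - r2, 0.0, None))
    t_tissue = spec.body_thickness_cm + (
        spec.thorax_thickness_cm - spec.body_thickness_cm
    ) * profile
    thorax = r2 <= 1.0

    t_bone = np.zeros_like(t_tissue)
    rng = np.random.default_rng(seed)

    if spec.lung_deficit > 0 and spec.thorax_thickness_cm > 0:
        lung_ax = 0.38 * ax_px
        lung_ay = 0.62 * ay_px
        for side in (-1.0, 1.0):
            lung = _ellipse_mask(
                (rows, cols),
                (cy - 0.08 * ay_px, cx + side * 0.48 * ax_px),
                (lung_ay, lung_ax),
            )
            t_tissue[lung] *= 1.0 - spec.lung_deficit

    if spec.spine_width_cm > 0 and spec.spine_thickness_cm > 0:
        half_w = 0.5 * spec.spine_width_cm * px_per_cm
        spine = (np.abs(xx - cx) <= half_w) & thorax
        t_bone[spine] += spec.spine_thickness_cm

    if spec.rib_count > 0 and spec.rib_thickness_cm > 0:
        # evenly spaced horizontal bands with a small seeded vertical jitter
        offsets = rng.uniform(-1.5, 1.5, size=spec.rib_count)
        centers = np.linspace(cy - 0.75 * ay_px, cy + 0.75 * ay_px, spec.rib_count)
        band_half = max(1.0, 0.06 * ay_px / spec.rib_count + 1.0)
        for rc, off in zip(centers + offsets, offsets):
            band = (np.abs(yy - rc) <= band_half) & thorax
            t_bone[band] += spec.rib_thickness_cm

    insert_mask = None
    if spec.tube_insert:
        pts = insert_curve(spec, seed)
        insert_mask = rasterize_curve(
            pts, (rows, cols), spec.insert_halfwidth_px
        )
        t_bone[insert_mask] += spec.insert_bone_equiv_cm

    return DigitalPhantom(
        t_tissue=t_tissue,
        t_bone=t_bone,
        pixel_pitch_mm=spec.pixel_pitch_mm,
        insert_mask=insert_mask,
    )


def rasterize_curve(points: np.ndarray, shape, halfwidth_px: float) -> np.ndarray:
    """Mark pixels whose center lies within ``halfwidth_px`` of a densely
    sampled curve (distance to the sample set, via a KD-tree)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    yy, xx = np.indices(shape)
    centers = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    hits = tree.query_ball_point(centers, r=halfwidth_px, return_length=True)
    return (hits > 0).reshape(shape)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def primary_transmission(
    phantom: DigitalPhantom,
    config: AcquisitionConfig,
    materials: MaterialTable | None = None,
) -> np.ndarray:
    """Beer–Lambert primary image: I0*mAs*exp(-mu_t*t_t - mu_b*t_b), counts."""
    materials = materials or MaterialTable.default()
    config.validate_against(materials)
    mu_t = materials.mu_tissue(config.kvp)
    mu_b = materials.mu_bone(config.kvp)
    return (
        config.i0
        * config.mas
        * np.exp(-mu_t * phantom.t_tissue - mu_b * phantom.t_bone)
    )


def scatter_psf(
    t_tissue_cm: float,
    t_bone_cm: float,
    config: AcquisitionConfig,
    orientation: Sequence[float] = (0.0, 0.0),
    materials: MaterialTable | None = None,
    pixel_pitch_mm: float | None = None,
) -> tuple[np.ndarray, float]:
    """Scatter kernel and scatter fraction at one thickness.

    Returns a unit-sum kernel K (mixture of a narrow and a broad elliptical
    Gaussian whose widths grow with equivalent thickness, elongated along
    ``orientation`` = (dy, dx)) and the scatter fraction f in [0, 1).  Zero
    thickness degenerates to f = 0 and a discrete delta.
    """
    if t_tissue_cm < 0 or t_bone_cm < 0:
        raise ValueError("thicknesses must be non-negative")
    materials = materials or MaterialTable.default()
    t_eq = t_tissue_cm + materials.bone_equivalence(config.kvp) * t_bone_cm
    if t_eq <= 0:
        return np.ones((1, 1)), 0.0
    f = float(materials.scatter_fraction(t_eq))
    pitch = pixel_pitch_mm if pixel_pitch_mm is not None else config.pixel_pitch_mm

    s_n = (materials.sigma_narrow_mm[0] + materials.sigma_narrow_mm[1] * t_eq) / pitch
    s_b = (materials.sigma_broad_mm[0] + materials.sigma_broad_mm[1] * t_eq) / pitch

    v = np.asarray(orientation, dtype=float)
    norm = float(np.hypot(*v))
    if norm < 1e-12:
        u = None  # isotropic
        stretch = 1.0
    else:
        u = v / norm
        stretch = math.sqrt(materials.anisotropy_ratio)

    half = int(math.ceil(3.5 * s_b * stretch))
    half = max(half, 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    if u is None:
        a, b = yy, xx
    else:
        a = yy * u[0] + xx * u[1]          # along the major axis
        b = -yy * u[1] + xx * u[0]
    k = np.zeros_like(yy)
    for sigma, w in ((s_n, materials.narrow_weight), (s_b, 1.0 - materials.narrow_weight)):
        sa = sigma * stretch
        sb = sigma / stretch
        k += w * np.exp(-0.5 * (a / sa) ** 2 - 0.5 * (b / sb) ** 2)
    k /= k.sum()
    return k, f


def _bin_weights(t_eq: np.ndarray, centers: np.ndarray) -> list[np.ndarray]:
    """Partition-of-unity hat weights of each pixel over thickness bins."""
    nb = len(centers)
    if nb == 1:
        return [np.ones_like(t_eq)]
    weights = [np.zeros_like(t_eq) for _ in range(nb)]
    idx = np.clip(np.searchsorted(centers, t_eq) - 1, 0, nb - 2)
    lo = centers[idx]
    hi = centers[idx + 1]
    frac = np.clip((t_eq - lo) / (hi - lo), 0.0, 1.0)
    for b in range(nb):
        w = np.zeros_like(t_eq)
        w[idx == b] = 1.0 - frac[idx == b]
        w[idx + 1 == b] += frac[idx + 1 == b]
        weights[b] = w
    return weights


def scatter_field(
    phantom: DigitalPhantom,
    primary: np.ndarray,
    config: AcquisitionConfig,
    materials: MaterialTable | None = None,
    n_bins: int = 8,
) -> ScatterField:
    """Non-stationary scatter field via thickness-binned kernel convolution.

    The scatter source spr(t)*P — so a wide uniform slab lands at pointwise
    scatter-to-primary ratio spr(t) — is split over ``n_bins``
    equivalent-thickness bins with per-pixel linear interpolation weights (a
    partition of unity); each bin is convolved with the kernel evaluated at
    the bin-center thickness and the bin's dominant local orientation.
    Approximates a continuously varying PSF while keeping a handful of FFT
    convolutions.
    """
    materials = materials or MaterialTable.default()
    if primary.shape != phantom.shape:
        raise ValueError("primary and phantom shapes differ")
    t_eq = phantom.equivalent_thickness(materials, config.kvp)
    src = primary * materials.spr(t_eq)
    total_src = float(src.sum())
    if total_src <= 0:
        return ScatterField(np.zeros_like(primary), 0.0, 0.0)

    occupied = t_eq > 0
    t_lo = float(t_eq[occupied].min())
    t_hi = float(t_eq[occupied].max())
    if t_hi - t_lo < 1e-9:
        centers = np.array([t_hi])
    else:
        centers = np.linspace(t_lo, t_hi, n_bins)
    weights = _bin_weights(t_eq, centers)

    # orientation from the gradient structure tensor of the smoothed
    # thickness map, averaged per bin; weak anisotropy -> isotropic kernel
    sm = gaussian_filter(t_eq, sigma=4.0, mode="nearest")
    gy, gx = np.gradient(sm)
    jyy, jxx, jxy = gy * gy, gx * gx, gx * gy

    s = np.zeros_like(primary)
    for w_b, c in zip(weights, centers):
        contrib = src * w_b
        mass = contrib.sum()
        if mass <= 0:
            continue
        tyy = float((jyy * contrib).sum() / mass)
        txx = float((jxx * contrib).sum() / mass)
        txy = float((jxy * contrib).sum() / mass)
        tr = tyy + txx
        det = tyy * txx - txy * txy
        disc = math.sqrt(max(0.25 * tr * tr - det, 0.0))
        lam1 = 0.5 * tr + disc
        lam2 = 0.5 * tr - disc
        coherence = (lam1 - lam2) / (lam1 + lam2) if lam1 + lam2 > 1e-30 else 0.0
        if coherence > 0.2:
            # principal gradient direction; elongate the kernel across it
            if abs(txy) > 1e-30:
                g = np.array([lam1 - txx, txy])
            else:
                g = np.array([1.0, 0.0]) if tyy >= txx else np.array([0.0, 1.0])
            orientation = (-g[1], g[0])
        else:
            orientation = (0.0, 0.0)
        kern, _ = scatter_psf(
            float(c), 0.0, config, orientation, materials, phantom.pixel_pitch_mm
        )
        # edge-replicated padding: the patient continues beyond the collimated
        # field, so scatter flows in across the boundary roughly as it flows
        # out; this also keeps the energy bookkeeping tight
        half = kern.shape[0] // 2
        padded = np.pad(contrib, half, mode="reflect")
        conv = fftconvolve(padded, kern, mode="same")
        s += conv[half : half + contrib.shape[0], half : half + contrib.shape[1]]

    np.clip(s, 0.0, None, out=s)
    loss = 1.0 - float(s.sum()) / total_src
    mean_spr = float(s.mean() / primary.mean())
    return ScatterField(s, mean_spr, loss)


@dataclass
class SimulatedRadiograph:
    """A simulated exposure with its ground-truth decomposition retained."""

    raw: RawImage
    primary: np.ndarray
    scatter: ScatterField
    phantom: DigitalPhantom


def simulate_raw(
    phantom: DigitalPhantom,
    config: AcquisitionConfig,
    materials: MaterialTable | None = None,
) -> SimulatedRadiograph:
    """Simulate one exposure: intensity ~ Poisson(P + S), seeded."""
    materials = materials or MaterialTable.default()
    p = primary_transmission(phantom, config, materials)
    sf = scatter_field(phantom, p, config, materials)
    rng = np.random.default_rng(config.seed)
    intensity = rng.poisson(p + sf.s).astype(float)
    ei = exposure_index(intensity, config)
    raw = RawImage(intensity=intensity, config=config, exposure_index=ei)
    return SimulatedRadiograph(raw=raw, primary=p, scatter=sf, phantom=phantom)
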