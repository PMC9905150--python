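"""Inverse-problem scatter estimation.

Given a measured gridless radiograph, iteratively refine a digital phantom
(per-pixel tissue and bone thickness) until the forward model reproduces the
measurement to within counting statistics; the scatter component of the final
forward simulation is the scatter estimate.  The solve runs on a coarse grid
(scatter is spatially smooth) and the estimated field is upsampled to full
resolution by bicubic interpolation.

The stopping rule is a global reduced chi-square against Poisson errors:
iteration ends once the simulated and measured images cannot be distinguished
from the underlying statistical noise, or when refinement stalls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .phantom_forward import (
    AcquisitionConfig,
    DigitalPhantom,
    MaterialTable,
    RawImage,
    primary_transmission,
    scatter_field,
)

__all__ = [
    "SolverConfig",
    "ScatterEstimate",
    "downsample_log",
    "block_mean",
    "chi2_residual",
    "refine_phantom",
    "estimate_scatter",
]


@dataclass
class SolverConfig:
    """Inverse-solver controls.

    ``downsample_factor=None`` picks a factor so the solve grid is roughly
    64x64.  ``chi2_tolerance`` operationalizes "agreement within statistical
    error" as a target reduced chi-square; ``step_damping`` and the thickness
    smoothing scale are stabilizers of the coordinate-descent refinement.
    """

    downsample_factor: int | None = None
    max_iterations: int = 40
    chi2_tolerance: float = 1.05
    step_damping: float = 0.7
    smoothing_px: float = 0.7
    tissue_cap_cm: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downsample_factor is not None and self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.chi2_tolerance < 1.0:
            raise ValueError("chi2_tolerance must be >= 1")
        if not (0.0 < self.step_damping <= 1.0):
            raise ValueError("step_damping must be in (0, 1]")


@dataclass
class ScatterEstimate:
    """Full-resolution scatter estimate with solver diagnostics."""

    s_hat: np.ndarray
    phantom_hat: DigitalPhantom
    trace: list[float]
    converged: bool
    n_floored: int = 0

    @property
    def final_chi2(self) -> float:
        return self.trace[-1] if self.trace else math.inf


def block_mean(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample; partial edge blocks are averaged over their
    actual pixel count, so the output shape is ceil(shape/factor)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return image.astype(float, copy=True)
    r_idx = np.arange(0, image.shape[0], factor)
    c_idx = np.arange(0, image.shape[1], factor)
    sums = np.add.reduceat(np.add.reduceat(image, r_idx, axis=0), c_idx, axis=1)
    rc = np.minimum(r_idx + factor, image.shape[0]) - r_idx
    cc = np.minimum(c_idx + factor, image.shape[1]) - c_idx
    return sums / np.outer(rc, cc)


def downsample_log(image: RawImage, factor: int) -> tuple[np.ndarray, int]:
    """Block-mean downsample then negative-log normalize.

    Returns ``(-log(mean_counts / (I0*mAs)), n_floored)`` where pixels that
    would be non-positive are floored at 1 count and counted.
    """
    low = block_mean(image.intensity, factor)
    n_floored = int(np.count_nonzero(low < 1.0))
    if n_floored:
        warnings.warn(f"floored {n_floored} non-positive pixels at 1 count")
        low = np.maximum(low, 1.0)
    i_ref = image.config.i0 * image.config.mas
    return -np.log(low / i_ref), n_floored


def chi2_residual(measured, simulated) -> tuple[np.ndarray, float]:
    """Poisson-normalized residual and global reduced chi-square.

    residual = (measured - simulated)/sqrt(max(simulated, 1));
    reduced chi-square = mean(residual**2).
    """
    m = measured.intensity if isinstance(measured, RawImage) else np.asarray(measured, float)
    s = np.asarray(simulated, dtype=float)
    if m.shape != s.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {s.shape}")
    residual = (m - s) / np.sqrt(np.maximum(s, 1.0))
    return residual, float(np.mean(residual**2))


def refine_phantom(
    phantom_hat: DigitalPhantom,
    measured: np.ndarray,
    simulated: np.ndarray,
    config: AcquisitionConfig,
    solver: SolverConfig,
    materials: MaterialTable | None = None,
) -> DigitalPhantom:
    """One morphological refinement of the thickness maps.

    The log-ratio of measured to simulated intensity converts directly to an
    equivalent-thickness correction dt = -damping * log(m/s) / mu_tissue,
    smoothed at the solver scale; where the accumulated tissue thickness
    exceeds a physiological cap the excess is re-apportioned to bone at the
    attenuation-equivalent rate.  Maps are clipped non-negative.
    """
    materials = materials or MaterialTable.default()
    mu_t = materials.mu_tissue(config.kvp)
    mu_b = materials.mu_bone(config.kvp)
    ratio = np.maximum(measured, 1e-12) / np.maximum(simulated, 1e-12)
    dt = -solver.step_damping * np.log(ratio) / mu_t
    if solver.smoothing_px > 0:
        dt = gaussian_filter(dt, sigma=solver.smoothing_px, mode="nearest")
    t_tissue = np.clip(phantom_hat.t_tissue + dt, 0.0, None)
    t_bone = phantom_hat.t_bone.copy()
    excess = t_tissue - solver.tissue_cap_cm
    over = excess > 0
    if np.any(over):
        t_bone[over] += excess[over] * mu_t / mu_b
        t_tissue[over] = solver.tissue_cap_cm
    # respect the phantom's physical total-thickness bound
    from .phantom_forward import MAX_TOTAL_THICKNESS_CM

    np.minimum(t_bone, MAX_TOTAL_THICKNESS_CM - t_tissue, out=t_bone)
    np.clip(t_bone, 0.0, None, out=t_bone)
    return DigitalPhantom(
        t_tissue=t_tissue,
        t_bone=t_bone,
        pixel_pitch_mm=phantom_hat.pixel_pitch_mm,
    )


def _forward_lowres(
    phantom: DigitalPhantom,
    config: AcquisitionConfig,
    materials: MaterialTable,
) -> tuple[np.ndarray, np.ndarray]:
    p = primary_transmission(phantom, config, materials)
    sf = scatter_field(phantom, p, config, materials)
    return p, sf.s


def estimate_scatter(
    measured: RawImage,
    config: SolverConfig | None = None,
    materials: MaterialTable | None = None,
    init_phantom: DigitalPhantom | None = None,
) -> ScatterEstimate:
    """Estimate the scatter field of a measured raw image.

    Runs the refine-simulate-compare loop at solver resolution until the
    reduced chi-square reaches ``chi2_tolerance`` or refinement stalls, then
    upsamples the final simulated scatter to full resolution (bicubic).  A
    warm start may be supplied via ``init_phantom`` (given at solver
    resolution or full resolution).
    """
    config = config or SolverConfig()
    materials = materials or MaterialTable.default()
    acq = measured.config
    acq.validate_against(materials)

    n = max(measured.shape)
    factor = config.downsample_factor or max(1, round(n / 64))
    meas_low = block_mean(measured.intensity, factor)
    n_floored = int(np.count_nonzero(meas_low < 1.0))
    meas_low = np.maximum(meas_low, 1.0)

    acq_low = AcquisitionConfig(
        kvp=acq.kvp,
        mas=acq.mas,
        i0=acq.i0,
        sid_cm=acq.sid_cm,
        detector_gain=acq.detector_gain,
        pixel_pitch_mm=acq.pixel_pitch_mm * factor,
        seed=acq.seed,
    )

    if init_phantom is not None:
        t_t = init_phantom.t_tissue
        t_b = init_phantom.t_bone
        if t_t.shape != meas_low.shape:
            zf = (meas_low.shape[0] / t_t.shape[0], meas_low.shape[1] / t_t.shape[1])
            t_t = np.clip(zoom(t_t, zf, order=1, grid_mode=True, mode="nearest"), 0, None)
            t_b = np.clip(zoom(t_b, zf, order=1, grid_mode=True, mode="nearest"), 0, None)
        phantom_hat = DigitalPhantom(t_t, t_b, pixel_pitch_mm=acq_low.pixel_pitch_mm)
    else:
        # uniform tissue slab matching the image-median attenuation, no bone
        i_ref = acq.i0 * acq.mas
        att = max(-math.log(float(np.median(meas_low)) / i_ref), 0.0)
        t0 = min(att / materials.mu_tissue(acq.kvp), config.tissue_cap_cm)
        phantom_hat = DigitalPhantom(
            np.full(meas_low.shape, t0),
            np.zeros(meas_low.shape),
            pixel_pitch_mm=acq_low.pixel_pitch_mm,
        )

    p_low, s_low = _forward_lowres(phantom_hat, acq_low, materials)
    _, chi2 = chi2_residual(meas_low, p_low + s_low)
    trace = [chi2]
    converged = chi2 <= config.chi2_tolerance

    for _ in range(config.max_iterations):
        if converged:
            break
        sim = p_low + s_low
        solver = config
        accepted = False
        for backtrack in range(4):
            damped = SolverConfig(
                downsample_factor=config.downsample_factor,
                max_iterations=config.max_iterations,
                chi2_tolerance=config.chi2_tolerance,
                step_damping=config.step_damping * (0.5**backtrack),
                smoothing_px=config.smoothing_px,
                tissue_cap_cm=config.tissue_cap_cm,
                seed=config.seed,
            )
            trial = refine_phantom(
                phantom_hat, meas_low, sim, acq_low, damped, materials
            )
            p_try, s_try = _forward_lowres(trial, acq_low, materials)
            _, chi2_try = chi2_residual(meas_low, p_try + s_try)
            if chi2_try <= chi2:
                phantom_hat, p_low, s_low, chi2 = trial, p_try, s_try, chi2_try
                accepted = True
                break
        if not accepted:
            break
        trace.append(chi2)
        converged = chi2 <= config.chi2_tolerance

    if not converged:
        warnings.warn(
            f"scatter solver did not reach chi2 <= {config.chi2_tolerance} "
            f"(final {chi2:.3f})"
        )

    # upsample the smooth scatter field back to the detector grid
    if factor == 1:
        s_hat = s_low.copy()
    else:
        zf = (measured.shape[0] / s_low.shape[0], measured.shape[1] / s_low.shape[1])
        s_hat = zoom(s_low, zf, order=3, grid_mode=True, mode="nearest")
        np.clip(s_hat, 0.0, None, out=s_hat)

    return ScatterEstimate(
        s_hat=s_hat,
        phantom_hat=phantom_hat,
        trace=trace,
        converged=converged,
        n_floored=n_floored,
    )
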