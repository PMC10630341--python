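"""Quality metrics, birefringence uncertainty, and FoV/SBP accounting.

The first-order uncertainty of the inverted birefringence parameters under
fluctuations of the normalized polarization differences (Q1, Q2) is

    var(theta) ~ <dQ^2> / (8 * Q0^2)
    var(delta) ~ <dQ^2> / (2 * (1 - Q0^2))

with Q0^2 = Q1^2 + Q2^2 and <dQ^2> = var(Q1) + var(Q2).  A Monte-Carlo
harness verifies the formulas by drawing noisy Q maps and re-inverting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from . import jones
from .propagation import SystemGeometry

__all__ = [
    "UncertaintyEstimate",
    "uncertainty_variances",
    "monte_carlo_uncertainty",
    "ssim",
    "mse",
    "r_squared_orientation",
    "fov_sbp",
]


@dataclass(frozen=True)
class UncertaintyEstimate:
    """First-order variances of orientation and retardance estimates.

    Variances are infinite (flagged, not raised) outside the valid domain:
    var_theta needs Q0^2 > 0, var_delta needs Q0^2 < 1.
    """

    var_theta: float
    var_delta: float
    q0_sq: float
    dq_sq: float


def uncertainty_variances(q0_sq: float, dq_sq: float) -> UncertaintyEstimate:
    """First-order propagated variances of (theta_hat, delta_hat)."""
    if dq_sq < 0 or q0_sq < 0:
        raise ValueError("Q0^2 and dQ^2 must be nonnegative")
    var_theta = dq_sq / (8.0 * q0_sq) if q0_sq > 0 else np.inf
    var_delta = dq_sq / (2.0 * (1.0 - q0_sq)) if q0_sq < 1 else np.inf
    return UncertaintyEstimate(var_theta=float(var_theta), var_delta=float(var_delta),
                               q0_sq=float(q0_sq), dq_sq=float(dq_sq))


def monte_carlo_uncertainty(delta0: float, theta0: float, q_noise_sd: float,
                            n_trials: int = 100_000, seed: int = 0) -> tuple[float, float]:
    """Empirical variances of the inverted (theta_hat, delta_hat) under
    independent Gaussian noise of standard deviation ``q_noise_sd`` on each
    of Q1 and Q2 (so <dQ^2> = 2 * q_noise_sd**2)."""
    if n_trials < 1000:
        raise ValueError("n_trials must be >= 1000")
    if q_noise_sd < 0:
        raise ValueError("q_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    q1 = np.sin(delta0) * np.sin(2 * theta0) + rng.normal(0.0, q_noise_sd, n_trials)
    q2 = np.sin(delta0) * np.cos(2 * theta0) + rng.normal(0.0, q_noise_sd, n_trials)
    q = jones.QMaps(q1=q1, q2=q2)
    delta_hat, _ = jones.retardation_map(q)
    theta_hat, _ = jones.orientation_map(q)
    # orientation is pi-periodic: center deviations on the true angle
    dev = np.mod(theta_hat - theta0 + np.pi / 2.0, np.pi) - np.pi / 2.0
    dev = dev - dev.mean()
    var_theta = float(np.mean(dev ** 2))
    var_delta = float(np.var(delta_hat))
    return var_theta, var_delta


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity with an 11x11 Gaussian window (sigma 1.5),
    stabilizers K1=0.01, K2=0.03."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = float(hi - lo) or 1.0
    return float(structural_similarity(a, b, data_range=data_range,
                                       gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False,
                                       K1=0.01, K2=0.03))


def mse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((a - b) ** 2))


def r_squared_orientation(estimated_deg: np.ndarray, true_deg: np.ndarray) -> float:
    """Coefficient of determination of estimated vs true orientation angles.

    Orientations live on a 180-degree circle; each estimate is first moved
    to the branch nearest its true value, then the ordinary R^2 of the
    estimates against the truth is evaluated (mirroring a linear regression
    of measured orientation against rotation angle).
    """
    est = np.asarray(estimated_deg, dtype=float)
    true = np.asarray(true_deg, dtype=float)
    if est.shape != true.shape:
        raise ValueError("length mismatch")
    if est.size < 3:
        raise ValueError("need at least 3 angles")
    est = est - 180.0 * np.round((est - true) / 180.0)
    ss_res = np.sum((est - true) ** 2)
    ss_tot = np.sum((true - true.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return float(1.0 - ss_res / ss_tot)


def fov_sbp(geometry: SystemGeometry, half_pitch_um: float) -> tuple[float, float]:
    """Field of view (mm^2) and space-bandwidth product (pixels).

    Sensor side lengths are rounded to 0.01 mm before multiplying (the
    convention used when quoting e.g. 7.07 mm x 8.45 mm = 59.74 mm^2); the
    SBP = FoV / half_pitch^2 is reported to two significant figures.
    """
    if half_pitch_um <= 0:
        raise ValueError("half_pitch_um must be > 0")
    ny, nx = geometry.sensor_px
    side_y = round(ny * geometry.pixel_um / 1000.0, 2)
    side_x = round(nx * geometry.pixel_um / 1000.0, 2)
    fov_mm2 = round(side_y * side_x, 2)
    sbp = fov_mm2 * 1e6 / half_pitch_um ** 2
    sbp = float(f"{sbp:.2g}")
    return fov_mm2, sbp
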