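"""Jones-calculus forward model and birefringence inversion.

A thin anisotropic specimen is described per pixel by a phase retardance
``delta`` (radians) and an in-plane optic-axis orientation ``theta``
(radians, defined modulo pi).  Circularly polarized light traverses the
specimen and is analyzed by one of four linear polarizers
(psi = 0, 45, 90, 135 degrees) on a division-of-focal-plane sensor.  The
four analyzed intensities are

    (I_0, I_45, I_90, I_135) = I/2 * (1 - sin d sin 2t,
                                      1 + sin d cos 2t,
                                      1 + sin d sin 2t,
                                      1 - sin d cos 2t)

from which two normalized differences

    Q1 = (I_90 - I_0) / (I_90 + I_0)   = sin d sin 2t
    Q2 = (I_45 - I_135) / (I_45 + I_135) = sin d cos 2t

invert to delta = asin(sqrt(Q1^2 + Q2^2)) and theta = atan2(Q1, Q2) / 2.

Note on the sign of Q2: with the intensity model above, the difference has
to be taken as (I_45 - I_135) for Q2 = sin d cos 2t to hold; the opposite
ordering flips its sign.  This module uses the algebraically consistent
form, so the forward model and the inversion round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "PSI_ANGLES_DEG",
    "RetOriMap",
    "ChannelIntensities",
    "QMaps",
    "CrystalPhysical",
    "sample_jones_matrix",
    "analyzer_jones",
    "channel_field",
    "analyzed_scalar",
    "channel_intensities",
    "compute_q_maps",
    "retardation_map",
    "orientation_map",
    "retardation_from_physical",
]

#: Analyzer orientations of the four polarization channels, degrees.
PSI_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass
class RetOriMap:
    """Per-pixel retardance / optic-axis description of a thin specimen.

    Parameters
    ----------
    delta : ndarray
        Phase retardance in radians, values in ``[0, pi]``.
    theta : ndarray
        Optic-axis orientation in radians; reported modulo pi.
    phase : ndarray, optional
        Isotropic (mean) phase of the specimen, radians.
    amplitude : ndarray, optional
        Isotropic amplitude transmittance in ``[0, 1]``.
    """

    delta: np.ndarray
    theta: np.ndarray
    phase: np.ndarray | None = None
    amplitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta = _as_finite_array(self.delta, "delta")
        self.theta = _as_finite_array(self.theta, "theta")
        _check_same_shape(self.delta, self.theta)
        if np.any(self.delta < 0) or np.any(self.delta > np.pi):
            raise ValueError("delta must lie in [0, pi]")
        self.theta = np.mod(self.theta, np.pi)
        for name in ("phase", "amplitude"):
            val = getattr(self, name)
            if val is not None:
                val = _as_finite_array(val, name)
                _check_same_shape(self.delta, val)
                setattr(self, name, val)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.delta.shape

    def complex_transmittance(self) -> np.ndarray:
        """Scalar (isotropic) part amplitude * exp(i * phase)."""
        out = np.ones(self.shape, dtype=complex)
        if self.amplitude is not None:
            out = out * self.amplitude
        if self.phase is not None:
            out = out * np.exp(1j * self.phase)
        return out


@dataclass
class ChannelIntensities:
    """Intensities of the four analyzed polarization channels."""

    i0: np.ndarray
    i45: np.ndarray
    i90: np.ndarray
    i135: np.ndarray
    incident: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        grids = [self.i0, self.i45, self.i90, self.i135]
        for g in grids[1:]:
            _check_same_shape(np.asarray(grids[0]), np.asarray(g))
        for g in grids:
            if np.any(np.asarray(g) < 0):
                raise ValueError("channel intensities must be nonnegative")

    def as_dict(self) -> dict[float, np.ndarray]:
        return {0.0: self.i0, 45.0: self.i45, 90.0: self.i90, 135.0: self.i135}

    def __getitem__(self, psi_deg: float) -> np.ndarray:
        return self.as_dict()[float(psi_deg) % 180.0]


@dataclass
class QMaps:
    """Normalized polarization differences Q1 = sin d sin 2t, Q2 = sin d cos 2t.

    ``invalid`` flags pixels where a channel-sum denominator vanished.
    """

    q1: np.ndarray
    q2: np.ndarray
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q1 = np.asarray(self.q1, dtype=float)
        self.q2 = np.asarray(self.q2, dtype=float)
        _check_same_shape(self.q1, self.q2)
        if self.invalid is None:
            self.invalid = np.zeros(self.q1.shape, dtype=bool)
        else:
            self.invalid = np.asarray(self.invalid, dtype=bool)

    @property
    def q0_sq(self) -> np.ndarray:
        return self.q1 ** 2 + self.q2 ** 2


@dataclass(frozen=True)
class CrystalPhysical:
    """Physical description of a uniaxial crystal slab.

    birefringence: Delta-n (unitless); thickness_um and wavelength_um in
    micrometres; refractive_index is carried as metadata only.
    """

    birefringence: float
    thickness_um: float
    wavelength_um: float
    refractive_index: float | None = None

    def __post_init__(self) -> None:
        if self.birefringence < 0:
            raise ValueError("birefringence must be >= 0")
        if self.thickness_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("thickness and wavelength must be > 0")


def sample_jones_matrix(delta, theta) -> np.ndarray:
    """Jones matrix of a thin retarder, shape ``delta.shape + (2, 2)``.

    Equivalent to R(theta) @ diag(e^{i d/2}, e^{-i d/2}) @ R(-theta) with a
    unit-determinant phase convention; diattenuation is neglected (thin
    specimen).  The matrix is unitary at every pixel.
    """
    delta = _as_finite_array(delta, "delta")
    theta = _as_finite_array(theta, "theta")
    _check_same_shape(delta, theta)
    c, s = np.cos(theta), np.sin(theta)
    e = np.exp(-1j * delta)
    pre = np.exp(1j * delta / 2.0)
    off = (1.0 - e) * s * c
    out = np.empty(delta.shape + (2, 2), dtype=complex)
    out[..., 0, 0] = pre * (c ** 2 + e * s ** 2)
    out[..., 0, 1] = pre * off
    out[..., 1, 0] = pre * off
    out[..., 1, 1] = pre * (s ** 2 + e * c ** 2)
    return out


def analyzer_jones(psi: float) -> np.ndarray:
    """Jones matrix of an ideal linear polarizer at angle ``psi`` (radians)."""
    if not np.isfinite(psi):
        raise ValueError("psi must be finite")
    c, s = np.cos(psi), np.sin(psi)
    return np.array([[c * c, s * c], [s * c, s * s]])


def _input_jones_vector(intensity, handedness: int) -> tuple[np.ndarray, np.ndarray]:
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be >= 0")
    amp = np.sqrt(intensity / 2.0)
    if handedness not in (+1, -1):
        raise ValueError("handedness must be +1 or -1")
    return amp, amp * (1j * handedness)


def channel_field(delta, theta, psi: float, intensity=1.0, handedness: int = +1) -> np.ndarray:
    """Analyzed Jones vector E_out = J_psi @ J_s @ E_in, shape ``(...,2)``.

    The incident light is circularly polarized, E_in = sqrt(I/2) * (1, i*h)
    with handedness h = +1 by default.  |E_out|^2 reproduces the closed-form
    channel intensities.
    """
    js = sample_jones_matrix(delta, theta)
    ex, ey = _input_jones_vector(intensity, handedness)
    # J_s @ E_in
    vx = js[..., 0, 0] * ex + js[..., 0, 1] * ey
    vy = js[..., 1, 0] * ex + js[..., 1, 1] * ey
    c, s = np.cos(psi), np.sin(psi)
    scal = c * vx + s * vy  # projection onto the analyzer axis
    out = np.empty(np.shape(vx) + (2,), dtype=complex)
    out[..., 0] = c * scal
    out[..., 1] = s * scal
    return out


def analyzed_scalar(delta, theta, psi: float, intensity=1.0, handedness: int = +1) -> np.ndarray:
    """Complex amplitude along the analyzer axis (the scalar wave that
    propagates after the analyzer); ``|analyzed_scalar|**2`` is the channel
    intensity."""
    js = sample_jones_matrix(delta, theta)
    ex, ey = _input_jones_vector(intensity, handedness)
    vx = js[..., 0, 0] * ex + js[..., 0, 1] * ey
    vy = js[..., 1, 0] * ex + js[..., 1, 1] * ey
    c, s = np.cos(psi), np.sin(psi)
    return c * vx + s * vy


def channel_intensities(delta, theta, intensity=1.0, handedness: int = +1) -> ChannelIntensities:
    """Closed-form four-channel intensities for a circular input state."""
    delta = _as_finite_array(delta, "delta")
    theta = _as_finite_array(theta, "theta")
    _check_same_shape(delta, theta)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be >= 0")
    sd = np.sin(delta) * handedness
    s2t, c2t = np.sin(2 * theta), np.cos(2 * theta)
    half = intensity / 2.0
    return ChannelIntensities(
        i0=half * (1.0 - sd * s2t),
        i45=half * (1.0 + sd * c2t),
        i90=half * (1.0 + sd * s2t),
        i135=half * (1.0 - sd * c2t),
        incident=intensity,
    )


def compute_q_maps(ch: ChannelIntensities, eps: float = 1e-12) -> QMaps:
    """Normalized channel differences; vanishing denominators are flagged.

    Q1 = (I90 - I0)/(I90 + I0), Q2 = (I45 - I135)/(I45 + I135).
    """
    i0 = np.asarray(ch.i0, dtype=float)
    i45 = np.asarray(ch.i45, dtype=float)
    i90 = np.asarray(ch.i90, dtype=float)
    i135 = np.asarray(ch.i135, dtype=float)
    s1 = i90 + i0
    s2 = i45 + i135
    invalid = (s1 <= eps) | (s2 <= eps)
    q1 = np.where(invalid, 0.0, (i90 - i0) / np.where(invalid, 1.0, s1))
    q2 = np.where(invalid, 0.0, (i45 - i135) / np.where(invalid, 1.0, s2))
    return QMaps(q1=q1, q2=q2, invalid=invalid)


class InversionResult(NamedTuple):
    values: np.ndarray
    flagged: np.ndarray


def retardation_map(q: QMaps) -> InversionResult:
    """delta = asin(sqrt(Q1^2+Q2^2)), clipped into [0, pi/2].

    Noise can push Q1^2 + Q2^2 above one; those pixels are clipped to pi/2
    and flagged rather than wrapped.
    """
    q0 = np.sqrt(q.q0_sq)
    clipped = q0 > 1.0
    delta = np.arcsin(np.minimum(q0, 1.0))
    return InversionResult(values=delta, flagged=clipped | q.invalid)


def orientation_map(q: QMaps) -> InversionResult:
    """theta = atan2(Q1, Q2)/2 mapped into [0, pi).

    The two-argument arctangent keeps the full 180-degree orientation range;
    pixels with Q1 = Q2 = 0 have undefined orientation and are flagged.
    """
    theta = 0.5 * np.arctan2(q.q1, q.q2)
    theta = np.mod(theta, np.pi)
    undefined = (q.q1 == 0.0) & (q.q2 == 0.0)
    return InversionResult(values=theta, flagged=undefined | q.invalid)


def retardation_from_physical(c: CrystalPhysical) -> float:
    """Retardance (radians) of a uniaxial slab: 2*pi*Delta_n*d/lambda."""
    return float(2.0 * np.pi * c.birefringence * c.thickness_um / c.wavelength_um)
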