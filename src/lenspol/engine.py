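"""Mask-modulated ptychographic phase retrieval.

Recovers the complex object field of one polarization channel from the
per-LED intensity stack by an ePIE-style sequential projection: for each
LED the current object estimate is illuminated by that LED's tilt ramp,
propagated to the known binary mask, modulated, propagated to the sensor,
constrained to the measured amplitude, and the correction is propagated
back through the mask to update the object.  The mask is known by design
(it is fabricated), so by default only the object is updated; an optional
ePIE mask refinement is available.

The LED sweep order is fixed row-major for bit-reproducibility (a seeded
shuffle is available).  Stopping is a fixed epoch count, not a tolerance,
so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .propagation import ComplexField, SystemGeometry, led_tilt, transfer_function
from .scenes import BinaryMask

__all__ = [
    "ReconSettings",
    "ReconResult",
    "reconstruct_channel",
    "initialize_object",
    "data_residual",
]

_AMP_EPS = 1e-12


@dataclass(frozen=True)
class ReconSettings:
    """Reconstruction hyper-parameters.

    iterations: number of full sweeps over the LED set.
    step_size: update relaxation in (0, 1].
    init_mode: 'flat' (unit field) or 'backprop' (back-propagated central
        frame amplitude).
    upsample: reconstruction-grid refinement factor; for upsample > 1 the
        amplitude constraint is applied after binning intensity back to
        sensor pixels.
    pad_factor: zero-padding of the internal propagation FFTs.  The default
        of 1 is appropriate for mm-scale gaps at a 3.45 um pitch, where the
        diffraction spread is tens of pixels; raise it for long throws.
    mask_refine: jointly refine the modulator estimate (off by default —
        the binary mask is known).
    shuffle: seeded random LED order per epoch instead of row-major.
    interp_weight: relaxation of the amplitude constraint at sensor sites
        whose value was interpolated by demosaicing rather than measured
        (requires ``measured_parity``).  Micro-polarizer sampling measures
        each channel on one pixel parity only; demosaiced estimates guide
        the update with this weight in (0, 1], while truly measured sites
        are always enforced fully.  Full-resolution data is unaffected.
    """

    iterations: int = 50
    step_size: float = 1.0
    init_mode: str = "flat"
    upsample: int = 1
    seed: int = 0
    mask_refine: bool = False
    pad_factor: int = 1
    shuffle: bool = False
    interp_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.step_size <= 1.0:
            raise ValueError("step_size must be in (0, 1]")
        if self.init_mode not in ("flat", "backprop"):
            raise ValueError("init_mode must be 'flat' or 'backprop'")
        if self.upsample < 1 or self.pad_factor < 1:
            raise ValueError("upsample and pad_factor must be >= 1")
        if not 0.0 <= self.interp_weight <= 1.0:
            raise ValueError("interp_weight must be in [0, 1]")


@dataclass
class ReconResult:
    """Recovered complex object plus the per-epoch data residual."""

    object: ComplexField
    error_history: np.ndarray
    settings: ReconSettings = field(default_factory=ReconSettings)
    mask: np.ndarray | None = None


class _Propagator:
    """Cached angular-spectrum transfer pair for one gap."""

    def __init__(self, shape, pitch_um, wavelength_um, z_mm, pad_factor=1):
        self.pad = pad_factor
        self.shape = shape
        py, px = shape[0] * pad_factor, shape[1] * pad_factor
        z_um = z_mm * 1000.0
        self.h_fwd = transfer_function((py, px), pitch_um, wavelength_um, z_um)
        self.h_bwd = transfer_function((py, px), pitch_um, wavelength_um, -z_um)

    def _apply(self, values: np.ndarray, h: np.ndarray) -> np.ndarray:
        if self.pad == 1:
            return np.fft.ifft2(np.fft.fft2(values) * h)
        ny, nx = self.shape
        py, px = h.shape
        oy, ox = (py - ny) // 2, (px - nx) // 2
        work = np.zeros((py, px), dtype=complex)
        work[oy:oy + ny, ox:ox + nx] = values
        out = np.fft.ifft2(np.fft.fft2(work) * h)
        return out[oy:oy + ny, ox:ox + nx]

    def fwd(self, values: np.ndarray) -> np.ndarray:
        return self._apply(values, self.h_fwd)

    def bwd(self, values: np.ndarray) -> np.ndarray:
        return self._apply(values, self.h_bwd)


def _mask_values(mask: BinaryMask | np.ndarray | None, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=float)
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=float)
    if values.shape != tuple(shape):
        raise ValueError("mask shape does not match the reconstruction grid")
    return values.astype(float)


def _bin_intensity(intensity: np.ndarray, u: int) -> np.ndarray:
    """Mean intensity over u x u sub-pixel blocks."""
    ny, nx = intensity.shape
    return intensity.reshape(ny // u, u, nx // u, u).mean(axis=(1, 3))


def initialize_object(measured: np.ndarray, geometry: SystemGeometry,
                      init_mode: str = "flat", pitch_um: float | None = None,
                      pad_factor: int = 1) -> np.ndarray:
    """Initial object estimate: unit field, or the central-LED frame's
    amplitude back-propagated from the sensor to the object plane."""
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 3 or measured.shape[0] == 0:
        raise ValueError("measured must be a non-empty (leds, ny, nx) stack")
    shape = measured.shape[1:]
    if init_mode == "flat":
        return np.ones(shape, dtype=complex)
    if init_mode == "backprop":
        pitch = pitch_um or geometry.pixel_um
        central = np.sqrt(measured[measured.shape[0] // 2])
        z = geometry.z_obj_mask_mm + geometry.z_mask_sensor_mm
        prop = _Propagator(shape, pitch, geometry.wavelength_um, z, pad_factor)
        return prop.bwd(central.astype(complex))
    raise ValueError(f"unknown init_mode {init_mode!r}")


def reconstruct_channel(measured: np.ndarray, led_indices: list[tuple[int, int]],
                        mask: BinaryMask | np.ndarray | None, geometry: SystemGeometry,
                        settings: ReconSettings | None = None,
                        pitch_um: float | None = None,
                        measured_parity: tuple[int, int] | None = None) -> ReconResult:
    """Recover one channel's complex object field from its LED stack.

    ``measured`` is the (n_leds, ny, nx) stack of sensor-plane intensities
    for this channel (demosaiced, or full-resolution reference data).
    ``measured_parity`` gives the (row, col) pixel parity at which this
    channel was physically sampled by the micro-polarizer mosaic; when set,
    the amplitude constraint is fully enforced there and relaxed to
    ``settings.interp_weight`` at demosaic-interpolated sites.
    """
    settings = settings or ReconSettings()
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 3 or measured.shape[0] != len(led_indices):
        raise ValueError("measurement count must equal LED count")
    sensor_pitch = pitch_um or geometry.pixel_um
    u = settings.upsample
    sensor_shape = measured.shape[1:]
    shape = (sensor_shape[0] * u, sensor_shape[1] * u)
    pitch = sensor_pitch / u

    m = _mask_values(mask, sensor_shape)
    if u > 1:
        m = np.kron(m, np.ones((u, u)))
    m = m.astype(complex)
    m_max_sq = float(np.max(np.abs(m)) ** 2)
    if m_max_sq == 0.0:
        raise ValueError("mask blocks all light")

    prop1 = _Propagator(shape, pitch, geometry.wavelength_um,
                        geometry.z_obj_mask_mm, settings.pad_factor)
    prop2 = _Propagator(shape, pitch, geometry.wavelength_um,
                        geometry.z_mask_sensor_mm, settings.pad_factor)
    ramps = [led_tilt(geometry, idx, shape, pitch_um=pitch) for idx in led_indices]
    sqrt_i = np.sqrt(np.clip(measured, 0.0, None))

    if measured_parity is None:
        weight = None
    else:
        weight = np.full(sensor_shape, settings.interp_weight)
        weight[measured_parity[0]::2, measured_parity[1]::2] = 1.0
        if u > 1:
            weight = np.kron(weight, np.ones((u, u)))

    if settings.init_mode == "flat":
        obj = np.ones(shape, dtype=complex)
    else:
        obj = initialize_object(measured, geometry, settings.init_mode,
                                pitch_um=sensor_pitch, pad_factor=settings.pad_factor)
        if u > 1:
            obj = np.kron(obj, np.ones((u, u)))

    rng = np.random.default_rng(settings.seed)
    n_leds = len(led_indices)
    step = settings.step_size
    history = np.empty(settings.iterations)
    for epoch in range(settings.iterations):
        order = rng.permutation(n_leds) if settings.shuffle else range(n_leds)
        err = 0.0
        for l in order:
            ramp = ramps[l]
            psi_mask = prop1.fwd(obj * ramp)
            psi_exit = m * psi_mask
            psi_sens = prop2.fwd(psi_exit)
            amp = np.abs(psi_sens)
            if u > 1:
                amp_meas = np.kron(np.sqrt(_bin_intensity(amp ** 2, u)), np.ones((u, u)))
                target = np.kron(sqrt_i[l], np.ones((u, u)))
            else:
                amp_meas = amp
                target = sqrt_i[l]
            err += float(np.mean((amp_meas - target) ** 2))
            gain = target / (amp_meas + _AMP_EPS)
            if weight is not None:
                gain = 1.0 + weight * (gain - 1.0)
            psi_sens_new = psi_sens * gain
            # back-propagation of the correction (the propagating band is
            # complete at this sampling, so the difference form is exact)
            diff_exit = prop2.bwd(psi_sens_new - psi_sens)
            psi_mask_new = psi_mask + step * np.conj(m) * diff_exit / m_max_sq
            if settings.mask_refine:
                pm_max = float(np.max(np.abs(psi_mask)) ** 2)
                m = m + step * np.conj(psi_mask) * (m * (psi_mask_new - psi_mask)) / (pm_max + _AMP_EPS)
                m_max_sq = float(np.max(np.abs(m)) ** 2)
            obj = prop1.bwd(psi_mask_new) * np.conj(ramp)
        history[epoch] = err / n_leds

    result_mask = np.abs(m) if settings.mask_refine else None
    return ReconResult(object=ComplexField(obj, pitch, geometry.wavelength_um),
                       error_history=history, settings=settings, mask=result_mask)


def data_residual(obj: ComplexField | np.ndarray, measured: np.ndarray,
                  led_indices: list[tuple[int, int]],
                  mask: BinaryMask | np.ndarray | None, geometry: SystemGeometry,
                  pitch_um: float | None = None, pad_factor: int = 1) -> float:
    """Mean squared amplitude mismatch of the forward model against the
    measured stack; zero iff the object reproduces every frame.  Invariant
    under a global phase of the object."""
    if isinstance(obj, ComplexField):
        values = obj.values
        pitch = obj.pitch_um
    else:
        values = np.asarray(obj, dtype=complex)
        pitch = pitch_um or geometry.pixel_um
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 3 or measured.shape[0] != len(led_indices):
        raise ValueError("measurement count must equal LED count")
    if measured.shape[1:] != values.shape:
        raise ValueError("object/measurement shape mismatch")
    m = _mask_values(mask, values.shape)
    prop1 = _Propagator(values.shape, pitch, geometry.wavelength_um,
                        geometry.z_obj_mask_mm, pad_factor)
    prop2 = _Propagator(values.shape, pitch, geometry.wavelength_um,
                        geometry.z_mask_sensor_mm, pad_factor)
    total = 0.0
    for l, idx in enumerate(led_indices):
        ramp = led_tilt(geometry, idx, values.shape, pitch_um=pitch)
        psi_sens = prop2.fwd(m * prop1.fwd(values * ramp))
        total += float(np.mean((np.abs(psi_sens) - np.sqrt(measured[l])) ** 2))
    return total / len(led_indices)
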