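"""Scalar free-space propagation and LED illumination geometry.

Propagation uses the band-limited angular-spectrum method: the field is
decomposed into plane waves, each advanced by exp(i*kz*z), with evanescent
components suppressed and a distance-dependent band limit to avoid the
wrap-around artefacts of the periodic FFT representation.

Geometry follows the lens-less layout: an LED array at a few hundred mm
standoff provides tilted plane-wave illumination; the object sits on a
random binary amplitude mask a couple of mm above a division-of-focal-plane
polarization sensor.

Coordinate convention (shared by all modules): origin at the grid center,
x to the right (columns), y down (rows), half-open pixel convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ComplexField",
    "SystemGeometry",
    "angular_spectrum_propagate",
    "transfer_function",
    "led_offset_mm",
    "led_tilt",
    "led_angle",
    "centered_coords_um",
]


@dataclass
class ComplexField:
    """2D complex scalar field with its sampling pitch and wavelength (um)."""

    values: np.ndarray
    pitch_um: float
    wavelength_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("field must be 2D")
        if self.pitch_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("pitch and wavelength must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def total_power(self) -> float:
        return float(np.sum(self.intensity()))


@dataclass(frozen=True)
class SystemGeometry:
    """Physical constants of the lens-less polarization imager.

    Defaults reflect a 9x9 LED array of 4 mm pitch at 400 mm standoff
    (on-axis illumination angles up to 2.29 deg), a 514.5 nm center
    wavelength, a 3.45 um pixel on a 2048x2448 sensor and a binary mask
    with a 27.6 um feature (8 sensor pixels).  The object-to-mask and
    mask-to-sensor gaps are not hardware-calibrated quantities here; they
    default to 1.0 and 1.5 mm and are configurable.
    """

    led_pitch_mm: float = 4.0
    led_grid: tuple[int, int] = (9, 9)
    led_distance_mm: float = 400.0
    wavelength_um: float = 0.5145
    pixel_um: float = 3.45
    sensor_px: tuple[int, int] = (2048, 2448)
    z_obj_mask_mm: float = 1.0
    z_mask_sensor_mm: float = 1.5
    mask_feature_um: float = 27.6

    def __post_init__(self) -> None:
        for name in ("led_pitch_mm", "led_distance_mm", "wavelength_um",
                     "pixel_um", "z_obj_mask_mm", "z_mask_sensor_mm",
                     "mask_feature_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(n <= 0 for n in self.led_grid) or any(n <= 0 for n in self.sensor_px):
            raise ValueError("grid sizes must be positive")
        ratio = self.mask_feature_um / self.pixel_um
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError("mask_feature_um must be an integer multiple of pixel_um")

    @property
    def mask_feature_px(self) -> int:
        return int(round(self.mask_feature_um / self.pixel_um))

    @property
    def n_leds(self) -> int:
        return self.led_grid[0] * self.led_grid[1]

    def led_indices(self) -> list[tuple[int, int]]:
        """Row-major enumeration of the LED grid."""
        nr, nc = self.led_grid
        return [(r, c) for r in range(nr) for c in range(nc)]

    def with_(self, **kwargs) -> "SystemGeometry":
        return replace(self, **kwargs)


def centered_coords_um(shape: tuple[int, int], pitch_um: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinate grids in um, origin at the grid center."""
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch_um
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch_um
    return np.meshgrid(x, y)


def transfer_function(shape: tuple[int, int], pitch_um: float, wavelength_um: float,
                      z_um: float, band_limit: bool = True) -> np.ndarray:
    """Angular-spectrum transfer function for propagation by ``z_um``.

    Evanescent components are zeroed; with ``band_limit`` the local-frequency
    bound of the sampled transfer phase additionally restricts the passband
    (important for large z relative to the aperture).
    """
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pitch_um)
    fx = np.fft.fftfreq(nx, d=pitch_um)
    fxg, fyg = np.meshgrid(fx, fy)
    arg = 1.0 / wavelength_um ** 2 - fxg ** 2 - fyg ** 2
    propagating = arg > 0
    kz = 2.0 * np.pi * np.sqrt(np.where(propagating, arg, 0.0))
    h = np.where(propagating, np.exp(1j * kz * z_um), 0.0)
    if band_limit and z_um != 0.0:
        dfy = 1.0 / (ny * pitch_um)
        dfx = 1.0 / (nx * pitch_um)
        zab = abs(z_um)
        fx_lim = 1.0 / (wavelength_um * np.sqrt((2.0 * dfx * zab) ** 2 + 1.0))
        fy_lim = 1.0 / (wavelength_um * np.sqrt((2.0 * dfy * zab) ** 2 + 1.0))
        h = np.where((np.abs(fxg) <= fx_lim) & (np.abs(fyg) <= fy_lim), h, 0.0)
    return h


def angular_spectrum_propagate(f: ComplexField, z_mm: float, pad_factor: int = 2,
                               band_limit: bool = True) -> ComplexField:
    """Propagate a field by ``z_mm`` (negative z back-propagates).

    ``pad_factor`` zero-pads the grid before the FFT to suppress periodic
    wrap-around; the result is cropped back to the original extent.
    """
    if not np.all(np.isfinite(f.values)):
        raise ValueError("field must be finite")
    if z_mm == 0.0:
        return ComplexField(f.values.copy(), f.pitch_um, f.wavelength_um)
    ny, nx = f.shape
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    py, px = ny * pad_factor, nx * pad_factor
    work = np.zeros((py, px), dtype=complex)
    oy, ox = (py - ny) // 2, (px - nx) // 2
    work[oy:oy + ny, ox:ox + nx] = f.values
    h = transfer_function((py, px), f.pitch_um, f.wavelength_um,
                          z_mm * 1000.0, band_limit=band_limit)
    out = np.fft.ifft2(np.fft.fft2(work) * h)
    return ComplexField(out[oy:oy + ny, ox:ox + nx], f.pitch_um, f.wavelength_um)


def led_offset_mm(geometry: SystemGeometry, led_index: tuple[int, int]) -> tuple[float, float]:
    """Lateral (dx, dy) offset of an LED from the optical axis, mm."""
    r, c = led_index
    nr, nc = geometry.led_grid
    if not (0 <= r < nr and 0 <= c < nc):
        raise IndexError(f"LED index {led_index} outside {geometry.led_grid} grid")
    dy = (r - (nr - 1) / 2.0) * geometry.led_pitch_mm
    dx = (c - (nc - 1) / 2.0) * geometry.led_pitch_mm
    return dx, dy


def led_direction_cosines(geometry: SystemGeometry, led_index: tuple[int, int]) -> tuple[float, float]:
    dx, dy = led_offset_mm(geometry, led_index)
    z = geometry.led_distance_mm
    hyp = np.sqrt(dx ** 2 + dy ** 2 + z ** 2)
    return dx / hyp, dy / hyp


def led_tilt(geometry: SystemGeometry, led_index: tuple[int, int],
             shape: tuple[int, int], pitch_um: float | None = None) -> np.ndarray:
    """Unit-amplitude plane-wave phase ramp on the object plane for one LED.

    The 400 mm standoff makes the spherical wavefront locally planar across
    the few-mm field of view, so each LED is modelled as a tilted plane wave
    with direction cosines set by its lateral offset.
    """
    if pitch_um is None:
        pitch_um = geometry.pixel_um
    ux, uy = led_direction_cosines(geometry, led_index)
    x, y = centered_coords_um(shape, pitch_um)
    return np.exp(1j * 2.0 * np.pi * (ux * x + uy * y) / geometry.wavelength_um)


def led_angle(geometry: SystemGeometry, led_index: tuple[int, int]) -> float:
    """Polar illumination tilt of one LED, degrees."""
    dx, dy = led_offset_mm(geometry, led_index)
    rho = np.sqrt(dx ** 2 + dy ** 2)
    return float(np.degrees(np.arctan2(rho, geometry.led_distance_mm)))
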