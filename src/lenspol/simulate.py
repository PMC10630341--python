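"""Forward acquisition simulator.

For each LED the tilted circularly polarized plane wave traverses the thin
birefringent object, is analyzed into four linear polarization channels,
propagates to the binary amplitude mask, is modulated, propagates to the
sensor, and the four channel intensities are sampled through the 2x2
micro-polarizer mosaic of the division-of-focal-plane sensor.  Optional
shot + read noise completes the camera model.

Because free-space propagation acts component-wise and the analyzer is a
fixed projector, analyzing at the object plane and propagating the scalar
analyzed component is exactly equivalent to propagating the full Jones
vector and analyzing at the sensor; the simulator uses the scalar form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import jones
from .jones import RetOriMap, PSI_ANGLES_DEG
from .propagation import ComplexField, SystemGeometry, angular_spectrum_propagate, led_tilt
from .scenes import BinaryMask

__all__ = [
    "MosaicLayout",
    "RawFrame",
    "CaptureStack",
    "NoiseModel",
    "object_exit_channel",
    "capture_channels",
    "capture_frame",
    "capture_stack",
    "mosaic_sample",
    "apply_noise",
]


@dataclass(frozen=True)
class MosaicLayout:
    """2x2 assignment of analyzer angles (degrees) to pixel parities.

    ``angles_deg[r][c]`` is the analyzer angle of pixels with row parity r
    and column parity c.  The default is a common commercial arrangement;
    it is configurable because real sensors differ.
    """

    angles_deg: tuple[tuple[float, float], tuple[float, float]] = ((90.0, 45.0), (135.0, 0.0))

    def __post_init__(self) -> None:
        flat = [a for row in self.angles_deg for a in row]
        if sorted(flat) != sorted(PSI_ANGLES_DEG):
            raise ValueError("layout must contain each of 0/45/90/135 exactly once")

    def parity_of(self, psi_deg: float) -> tuple[int, int]:
        for r in range(2):
            for c in range(2):
                if self.angles_deg[r][c] == psi_deg:
                    return r, c
        raise KeyError(psi_deg)


@dataclass
class RawFrame:
    """One mosaicked sensor frame for one LED."""

    values: np.ndarray
    led_index: tuple[int, int]
    layout: MosaicLayout = field(default_factory=MosaicLayout)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("frame values must be nonnegative")


@dataclass
class CaptureStack:
    """Ordered raw frames (row-major LED order) plus the geometry used."""

    frames: list[RawFrame]
    geometry: SystemGeometry
    layout: MosaicLayout = field(default_factory=MosaicLayout)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def led_indices(self) -> list[tuple[int, int]]:
        return [f.led_index for f in self.frames]

    def as_array(self) -> np.ndarray:
        return np.stack([f.values for f in self.frames])


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise at ``photon_scale`` expected counts per unit
    intensity plus Gaussian read noise, clipped at zero."""

    photon_scale: float = 1e4
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


def object_exit_channel(scene: RetOriMap, psi_deg: float, tilt: np.ndarray,
                        geometry: SystemGeometry, intensity: float = 1.0,
                        handedness: int = +1, pitch_um: float | None = None) -> ComplexField:
    """Analyzed scalar exit wave of one polarization channel at the object
    plane (tilted circular illumination included)."""
    if tilt.shape != scene.shape:
        raise ValueError("tilt/scene shape mismatch")
    scal = jones.analyzed_scalar(scene.delta, scene.theta, np.deg2rad(psi_deg),
                                 intensity=intensity, handedness=handedness)
    values = scal * scene.complex_transmittance() * tilt
    return ComplexField(values, pitch_um or geometry.pixel_um, geometry.wavelength_um)


def capture_channels(scene: RetOriMap, mask: BinaryMask | None, geometry: SystemGeometry,
                     led_index: tuple[int, int], intensity: float = 1.0,
                     handedness: int = +1, pad_factor: int = 1,
                     pitch_um: float | None = None) -> dict[float, np.ndarray]:
    """Pre-mosaic sensor-plane intensities of the four channels for one LED
    (the full-resolution reference a non-mosaicked camera would record)."""
    pitch = pitch_um or geometry.pixel_um
    tilt = led_tilt(geometry, led_index, scene.shape, pitch_um=pitch)
    if mask is not None and mask.shape != scene.shape:
        raise ValueError("mask/scene shape mismatch")
    out: dict[float, np.ndarray] = {}
    for psi in PSI_ANGLES_DEG:
        f = object_exit_channel(scene, psi, tilt, geometry, intensity=intensity,
                                handedness=handedness, pitch_um=pitch)
        f = angular_spectrum_propagate(f, geometry.z_obj_mask_mm, pad_factor=pad_factor)
        if mask is not None:
            f = ComplexField(f.values * mask.values, f.pitch_um, f.wavelength_um)
        f = angular_spectrum_propagate(f, geometry.z_mask_sensor_mm, pad_factor=pad_factor)
        out[psi] = f.intensity()
    return out


def mosaic_sample(channels: dict[float, np.ndarray] | jones.ChannelIntensities,
                  layout: MosaicLayout | None = None) -> np.ndarray:
    """Sample four full-resolution channel images through the 2x2 mosaic."""
    if isinstance(channels, jones.ChannelIntensities):
        channels = channels.as_dict()
    layout = layout or MosaicLayout()
    grids = [np.asarray(channels[psi]) for psi in PSI_ANGLES_DEG]
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("channel shapes differ")
    out = np.empty(shape, dtype=float)
    for psi, grid in zip(PSI_ANGLES_DEG, grids):
        r, c = layout.parity_of(psi)
        out[r::2, c::2] = grid[r::2, c::2]
    return out


def apply_noise(values: np.ndarray, model: NoiseModel,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Poisson(photon_scale * I) + N(0, read_noise_sd), clipped at zero,
    returned on the original intensity scale."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("frame must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    counts = rng.poisson(model.photon_scale * values).astype(float)
    if model.read_noise_sd > 0:
        counts += rng.normal(0.0, model.read_noise_sd, size=values.shape)
    counts = np.clip(counts, 0.0, None)
    scale = model.photon_scale if model.photon_scale > 0 else 1.0
    return counts / scale


def capture_frame(scene: RetOriMap, mask: BinaryMask | None, geometry: SystemGeometry,
                  led_index: tuple[int, int], noise: NoiseModel | None = None,
                  layout: MosaicLayout | None = None, intensity: float = 1.0,
                  handedness: int = +1, pad_factor: int = 1,
                  pitch_um: float | None = None,
                  rng: np.random.Generator | None = None) -> RawFrame:
    """Simulate one mosaicked raw frame for one LED."""
    layout = layout or MosaicLayout()
    channels = capture_channels(scene, mask, geometry, led_index, intensity=intensity,
                                handedness=handedness, pad_factor=pad_factor,
                                pitch_um=pitch_um)
    raw = mosaic_sample(channels, layout)
    if noise is not None:
        raw = apply_noise(raw, noise, rng=rng)
    return RawFrame(values=raw, led_index=led_index, layout=layout)


def capture_stack(scene: RetOriMap, mask: BinaryMask | None, geometry: SystemGeometry,
                  noise: NoiseModel | None = None, layout: MosaicLayout | None = None,
                  intensity: float = 1.0, handedness: int = +1,
                  pad_factor: int = 1, pitch_um: float | None = None) -> CaptureStack:
    """Simulate the full acquisition, one frame per LED in row-major order."""
    layout = layout or MosaicLayout()
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    frames = [
        capture_frame(scene, mask, geometry, idx, noise=noise, layout=layout,
                      intensity=intensity, handedness=handedness,
                      pad_factor=pad_factor, pitch_um=pitch_um, rng=rng)
        for idx in geometry.led_indices()
    ]
    return CaptureStack(frames=frames, geometry=geometry, layout=layout)
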