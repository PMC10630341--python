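"""End-to-end birefringence reconstruction.

Orchestrates the full chain: raw mosaicked capture stack -> per-channel
demosaicing -> per-channel ptychographic reconstruction -> normalized
polarization differences (Q maps) -> retardance / optic-axis / mean-phase
maps -> pseudo-color rendering and orientation overlays.

Per-channel ptychographic recovery carries an arbitrary global phase; it is
fixed by subtracting the circular mean phase over a background border
region (default: the outer 5% of the image) before the four channel phases
are averaged into the mean-phase map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb

from . import jones
from .jones import PSI_ANGLES_DEG, QMaps
from .propagation import ComplexField, SystemGeometry
from .scenes import BinaryMask
from .simulate import CaptureStack
from .demosaic import demosaic_frame
from .engine import ReconSettings, reconstruct_channel

__all__ = [
    "BirefringenceResult",
    "run_pipeline",
    "reconstruct_channels",
    "mean_phase",
    "render_pseudo_color",
    "orientation_overlay",
]


@dataclass
class BirefringenceResult:
    """Quantitative maps recovered by the full pipeline.

    delta in [0, pi/2] rad, theta in [0, pi) rad, phase in rad; ``channels``
    holds the recovered complex object per analyzer angle; ``flagged`` marks
    pixels where the inversion clipped or was undefined.
    """

    delta: np.ndarray
    theta: np.ndarray
    phase: np.ndarray
    channels: dict[float, ComplexField]
    qmaps: QMaps
    flagged: np.ndarray
    error_history: dict[float, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _border_mask(shape: tuple[int, int], border_frac: float) -> np.ndarray:
    ny, nx = shape
    b = max(1, int(round(border_frac * min(ny, nx))))
    m = np.zeros(shape, dtype=bool)
    m[:b, :] = m[-b:, :] = True
    m[:, :b] = m[:, -b:] = True
    return m


def mean_phase(phase_maps: Sequence[np.ndarray], border_frac: float = 0.05) -> np.ndarray:
    """Average of the channel phase maps after per-map background alignment.

    Each map's gauge is fixed by subtracting the circular mean of its phase
    over the border region, then the aligned maps are averaged pixel-wise.
    """
    phase_maps = [np.asarray(p, dtype=float) for p in phase_maps]
    shape = phase_maps[0].shape
    if any(p.shape != shape for p in phase_maps):
        raise ValueError("phase maps must share a shape")
    border = _border_mask(shape, border_frac)
    aligned = []
    for p in phase_maps:
        offset = np.angle(np.mean(np.exp(1j * p[border])))
        aligned.append(np.angle(np.exp(1j * (p - offset))))
    return np.mean(aligned, axis=0)


def reconstruct_channels(measured: dict[float, np.ndarray],
                         led_indices: list[tuple[int, int]],
                         mask: BinaryMask | np.ndarray | None,
                         geometry: SystemGeometry,
                         settings: ReconSettings | None = None,
                         pitch_um: float | None = None,
                         border_frac: float = 0.05,
                         provenance: dict | None = None,
                         parities: dict[float, tuple[int, int]] | None = None) -> BirefringenceResult:
    """Reconstruct all four channels and invert the Jones model.

    ``measured`` maps each analyzer angle (deg) to its (n_leds, ny, nx)
    intensity stack — demosaiced data, or full-resolution reference stacks.
    ``parities`` (for demosaiced data) gives each channel's measured pixel
    parity so the engine can weight real samples above interpolated ones.
    """
    settings = settings or ReconSettings()
    channels: dict[float, ComplexField] = {}
    histories: dict[float, np.ndarray] = {}
    for psi in PSI_ANGLES_DEG:
        res = reconstruct_channel(measured[psi], led_indices, mask, geometry,
                                  settings=settings, pitch_um=pitch_um,
                                  measured_parity=None if parities is None else parities[psi])
        channels[psi] = res.object
        histories[psi] = res.error_history

    intensities = jones.ChannelIntensities(
        i0=channels[0.0].intensity(), i45=channels[45.0].intensity(),
        i90=channels[90.0].intensity(), i135=channels[135.0].intensity())
    q = jones.compute_q_maps(intensities)
    delta, delta_flags = jones.retardation_map(q)
    theta, theta_flags = jones.orientation_map(q)
    phase = mean_phase([np.angle(channels[psi].values) for psi in PSI_ANGLES_DEG],
                       border_frac=border_frac)
    prov = dict(provenance or {})
    prov.setdefault("settings", settings)
    prov.setdefault("geometry", geometry)
    return BirefringenceResult(delta=delta, theta=theta, phase=phase,
                               channels=channels, qmaps=q,
                               flagged=delta_flags | theta_flags,
                               error_history=histories, provenance=prov)


def run_pipeline(stack: CaptureStack, mask: BinaryMask | np.ndarray | None,
                 settings: ReconSettings | None = None,
                 demosaic_method: str = "np",
                 pitch_um: float | None = None,
                 border_frac: float = 0.05) -> BirefringenceResult:
    """Full chain from a mosaicked capture stack to birefringence maps."""
    settings = settings or ReconSettings()
    n = len(stack)
    shape = stack.frames[0].values.shape
    measured = {psi: np.empty((n,) + shape) for psi in PSI_ANGLES_DEG}
    for i, frame in enumerate(stack.frames):
        chans = demosaic_frame(frame, method=demosaic_method, layout=stack.layout)
        for psi in PSI_ANGLES_DEG:
            measured[psi][i] = chans[psi]
    provenance = {"demosaic_method": demosaic_method, "n_frames": n,
                  "layout": stack.layout, "seed": settings.seed}
    parities = {psi: stack.layout.parity_of(psi) for psi in PSI_ANGLES_DEG}
    return reconstruct_channels(measured, stack.led_indices, mask, stack.geometry,
                                settings=settings, pitch_um=pitch_um,
                                border_frac=border_frac, provenance=provenance,
                                parities=parities)


def render_pseudo_color(delta: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Joint rendering: hue encodes orientation (cyclic over pi), brightness
    encodes retardance (full at pi/2); isotropic pixels render black."""
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    hsv = np.stack([
        np.mod(theta, np.pi) / np.pi,
        np.ones_like(delta),
        np.clip(delta / (np.pi / 2.0), 0.0, 1.0),
    ], axis=-1)
    return hsv_to_rgb(hsv)


@dataclass(frozen=True)
class OverlaySegment:
    """Mean-orientation indicator for one analysis window."""

    center_um: tuple[float, float]  # (y, x) from the image origin (top-left)
    angle_rad: float
    length_um: float


def orientation_overlay(theta: np.ndarray, delta: np.ndarray, window_um: float,
                        pitch_um: float, min_delta: float = 0.05,
                        length_frac: float = 0.8) -> list[OverlaySegment]:
    """Retardance-weighted circular mean orientation per non-overlapping
    window (axes doubled: theta_bar = atan2(<sin 2t>, <cos 2t>)/2).  Windows
    whose mean retardance falls below ``min_delta`` emit no segment."""
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if theta.shape != delta.shape:
        raise ValueError("theta/delta shape mismatch")
    w = int(round(window_um / pitch_um))
    if w < 2:
        raise ValueError("window must span at least 2 pixels")
    ny, nx = theta.shape
    segments: list[OverlaySegment] = []
    for r0 in range(0, ny - w + 1, w):
        for c0 in range(0, nx - w + 1, w):
            d = delta[r0:r0 + w, c0:c0 + w]
            if d.mean() <= min_delta:
                continue
            t = theta[r0:r0 + w, c0:c0 + w]
            s = np.sum(d * np.sin(2 * t))
            c = np.sum(d * np.cos(2 * t))
            ang = np.mod(0.5 * np.arctan2(s, c), np.pi)
            center = ((r0 + (w - 1) / 2.0) * pitch_um, (c0 + (w - 1) / 2.0) * pitch_um)
            segments.append(OverlaySegment(center_um=center, angle_rad=float(ang),
                                           length_um=length_frac * window_um))
    return segments
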