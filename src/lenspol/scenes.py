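"""Synthetic masks and test objects.

Generators for the structures used to exercise the simulator and
reconstruction chain: a block-random binary amplitude mask, a Siemens-star
birefringent target, a needle-shaped crystal (monosodium-urate-like, fast
axis along the needle), and a USAF-style three-bar amplitude target.

Targets are generated at the reconstruction grid pitch; edges are hard
(no sub-pixel anti-aliasing) unless a supersampling factor is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .jones import RetOriMap

__all__ = [
    "BinaryMask",
    "random_binary_mask",
    "siemens_star",
    "needle_crystal",
    "usaf_like_target",
    "default_usaf_specs",
]


@dataclass
class BinaryMask:
    """Block-structured random binary amplitude mask.

    ``values`` is {0,1} and piecewise constant on feature_px x feature_px
    blocks; the open fraction is enforced exactly at the block level.
    """

    values: np.ndarray
    feature_px: int
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def open_fraction(self) -> float:
        return float(np.mean(self.values))


def random_binary_mask(shape_px: tuple[int, int], feature_px: int = 8,
                       open_ratio: float = 0.5, seed: int = 0) -> BinaryMask:
    """Random binary mask with an exact open-block count.

    The number of open blocks is round(open_ratio * n_blocks); their
    placement is a seeded permutation, so the realized open fraction does
    not fluctuate with the seed.
    """
    ny, nx = shape_px
    if ny % feature_px or nx % feature_px:
        raise ValueError("shape must be divisible by feature_px")
    if not 0.0 < open_ratio < 1.0:
        raise ValueError("open_ratio must be in (0, 1)")
    by, bx = ny // feature_px, nx // feature_px
    n_blocks = by * bx
    n_open = int(round(open_ratio * n_blocks))
    flat = np.zeros(n_blocks, dtype=np.uint8)
    flat[:n_open] = 1
    rng = np.random.default_rng(seed)
    rng.shuffle(flat)
    blocks = flat.reshape(by, bx)
    values = np.kron(blocks, np.ones((feature_px, feature_px), dtype=np.uint8))
    return BinaryMask(values=values, feature_px=feature_px, seed=seed)


def siemens_star(shape_px: tuple[int, int], n_sectors: int = 8,
                 delta0: float = np.pi / 4, radius_px: float | None = None,
                 inner_radius_px: float | None = None) -> RetOriMap:
    """Siemens-star birefringent target.

    Alternating angular sectors carry retardance ``delta0``; within a sector
    the optic axis points along the sector bisector azimuth (mod pi).
    Sectors are laid out so that one birefringent sector is bisected by the
    +x axis.  A small isotropic disc at the center keeps the spokes
    disjoint, giving exactly ``n_sectors/2`` birefringent wedges.
    """
    if n_sectors < 2 or n_sectors % 2:
        raise ValueError("n_sectors must be even and >= 2")
    if not 0.0 < delta0 <= np.pi / 2:
        raise ValueError("delta0 must be in (0, pi/2]")
    ny, nx = shape_px
    if radius_px is None:
        radius_px = 0.45 * min(ny, nx)
    if inner_radius_px is None:
        inner_radius_px = max(2.0, 0.04 * radius_px)
    if not 0 <= inner_radius_px < radius_px <= min(ny, nx) / 2.0 + 1:
        raise ValueError("invalid radii for the given grid")
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    xg, yg = np.meshgrid(x, y)
    r = np.hypot(xg, yg)
    half = np.pi / n_sectors
    phi = np.mod(np.arctan2(yg, xg) + half, 2.0 * np.pi)  # sector 0 bisected by +x
    sector = np.floor(phi / (2.0 * half)).astype(int)
    on = (sector % 2 == 0) & (r >= inner_radius_px) & (r <= radius_px)
    bisector = sector * 2.0 * half  # azimuth of each sector's bisector
    delta = np.where(on, delta0, 0.0)
    theta = np.where(on, np.mod(bisector, np.pi), 0.0)
    return RetOriMap(delta=delta, theta=theta)


def needle_crystal(shape_px: tuple[int, int], axis_angle: float,
                   delta0: float, length_px: float, width_px: float,
                   center_px: tuple[float, float] | None = None) -> RetOriMap:
    """Needle-shaped uniaxial crystal: a rotated rectangle with its optic
    axis along the needle direction (``axis_angle`` radians, mod pi)."""
    ny, nx = shape_px
    if width_px < 2:
        raise ValueError("width_px must be >= 2")
    if center_px is None:
        center_px = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center_px
    ca, sa = np.cos(axis_angle), np.sin(axis_angle)
    # rotated corner extents must stay on the grid
    hx = abs(ca) * length_px / 2 + abs(sa) * width_px / 2
    hy = abs(sa) * length_px / 2 + abs(ca) * width_px / 2
    if cx - hx < 0 or cx + hx > nx - 1 or cy - hy < 0 or cy + hy > ny - 1:
        raise ValueError("needle exceeds the grid")
    y = np.arange(ny) - cy
    x = np.arange(nx) - cx
    xg, yg = np.meshgrid(x, y)
    u = ca * xg + sa * yg        # along the needle
    v = -sa * xg + ca * yg       # across the needle
    inside = (np.abs(u) <= length_px / 2.0) & (np.abs(v) <= width_px / 2.0)
    delta = np.where(inside, delta0, 0.0)
    theta = np.where(inside, np.mod(axis_angle, np.pi), 0.0)
    return RetOriMap(delta=delta, theta=theta)


def default_usaf_specs(shape_px: tuple[int, int]) -> list[tuple[int, int, int, int, str]]:
    """Three-bar groups of decreasing pitch placed over the grid.

    Each spec is (row, col, bar_width_px, length_px, orientation) with
    orientation 'h' (bars stacked vertically) or 'v' (side by side).
    """
    ny, nx = shape_px
    widths = [max(2, ny // 16), max(2, ny // 24), max(2, ny // 32), max(2, ny // 48)]
    specs = []
    row = ny // 8
    for w in widths:
        length = 6 * w
        if row + length > ny - 2:
            break
        if nx // 8 + 5 * w <= nx:
            specs.append((row, nx // 8, w, length, "v"))
        if row + 5 * w <= ny and nx // 2 + length <= nx:
            specs.append((row, nx // 2, w, length, "h"))
        row += length + max(4, w)
    return specs


def usaf_like_target(shape_px: tuple[int, int],
                     bar_specs: list[tuple[int, int, int, int, str]] | None = None) -> np.ndarray:
    """Binary amplitude target with three-bar groups (opaque bars on a clear
    field).  A group with bar width w has spatial period 2w, i.e. a spectrum
    peak at frequency 1/(2w) cycles per pixel."""
    ny, nx = shape_px
    amp = np.ones((ny, nx), dtype=float)
    if bar_specs is None:
        return amp
    for row, col, w, length, orient in bar_specs:
        if w < 1 or length < 1:
            raise ValueError("bar width and length must be >= 1")
        if orient == "v":
            # three vertical bars side by side, separated by w
            if row + length > ny or col + 5 * w > nx or row < 0 or col < 0:
                raise ValueError("bar group exceeds the grid")
            for k in range(3):
                amp[row:row + length, col + 2 * k * w: col + 2 * k * w + w] = 0.0
        elif orient == "h":
            if row + 5 * w > ny or col + length > nx or row < 0 or col < 0:
                raise ValueError("bar group exceeds the grid")
            for k in range(3):
                amp[row + 2 * k * w: row + 2 * k * w + w, col:col + length] = 0.0
        else:
            raise ValueError(f"unknown orientation {orient!r}")
    return amp
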