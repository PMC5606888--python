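"""Sampling-effort bias surface from target-group occurrence records.

A Gaussian kernel density field of survey records, affinely rescaled to
the interval [1, 30]: cells in heavily surveyed areas get weight 30, the
least surveyed get 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occurrences import OccurrenceSet
from .raster import Raster

__all__ = ["BiasSurface", "kernel_density", "rescale_bias", "build_bias_surface"]

BIAS_MIN = 1.0
BIAS_MAX = 30.0


@dataclass
class BiasSurface:
    grid: Raster
    bandwidth: float


def kernel_density(
    points: OccurrenceSet, template: Raster, bandwidth: float
) -> Raster:
    """Sum of isotropic Gaussian kernels evaluated at cell centres.

    Each kernel carries the planar normalisation 1/(2*pi*sigma^2) so the
    field integrates to the number of points.  Nodata cells in the template
    stay nodata.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(points) == 0:
        raise ValueError("kernel density needs at least one point")
    cx, cy = template.grid.cell_centers()
    dens = np.zeros(template.grid.shape)
    norm = 1.0 / (2.0 * np.pi * bandwidth**2)
    inv2s2 = 1.0 / (2.0 * bandwidth**2)
    # chunk over points to bound memory on large grids
    xy = points.xy
    for start in range(0, len(xy), 256):
        chunk = xy[start : start + 256]
        dx = cx[..., None] - chunk[:, 0]
        dy = cy[..., None] - chunk[:, 1]
        dens += norm * np.exp(-(dx**2 + dy**2) * inv2s2).sum(axis=-1)
    dens = np.where(template.mask, dens, template.nodata)
    return template.with_values(dens)


def rescale_bias(density: Raster, bandwidth: float = float("nan")) -> BiasSurface:
    """Affine map of the density field onto [1, 30]; constant fields map to 1."""
    vals = density.valid_values()
    if len(vals) == 0:
        raise ValueError("density raster has no valid cells")
    if np.any(vals < 0):
        raise ValueError("density must be non-negative")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        scaled = np.full_like(density.values, BIAS_MIN)
    else:
        scaled = BIAS_MIN + (density.values - lo) * (BIAS_MAX - BIAS_MIN) / (hi - lo)
    scaled = np.where(density.mask, scaled, density.nodata)
    return BiasSurface(density.with_values(scaled), bandwidth)


def build_bias_surface(
    points: OccurrenceSet, template: Raster, bandwidth: float | None = None
) -> BiasSurface:
    """Kernel density then 1-30 rescale; bandwidth defaults to 2 cell sizes."""
    if bandwidth is None:
        bandwidth = 2.0 * template.grid.cellsize
    dens = kernel_density(points, template, bandwidth)
    surface = rescale_bias(dens, bandwidth)
    return surface
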