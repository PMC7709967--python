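"""Dipole lattice, antenna ring, and phantom rasterization.

The forward-model zone is a uniform n × n lattice of dipoles spanning a
square of side ``extent``; dipoles sit at the lattice *nodes*, so the
node-to-node spacing is ``extent / (n_side - 1)``.  Indexing is row-major:
dipole ``i`` lives at ``(row, col) = (i // n_side, i % n_side)`` with the
column index running along +x and the row index along +y.

Antennas are ideal electric line sources placed uniformly on a circle
(the measurement ring).  A phantom is a set of circular dielectric
inclusions inside an imaging circle; every dipole not covered by an
inclusion carries the coupling-bath properties, while the *background*
medium (which defines the Green's function) is kept slightly different
from the bath so that no dipole has exactly zero contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid2D",
    "AntennaArray",
    "Inclusion",
    "PhantomSpec",
    "build_grid",
    "build_antenna_ring",
    "rasterize_phantom",
]


@dataclass(frozen=True)
class Grid2D:
    """Uniform square dipole lattice (dipoles at nodes, row-major order)."""

    n_side: int
    extent: float
    center: np.ndarray
    spacing: float
    positions: np.ndarray  # (N, 2), row-major

    @property
    def N(self) -> int:
        return self.n_side**2

    def index_to_rowcol(self, i):
        return np.divmod(np.asarray(i), self.n_side)

    def rowcol_to_index(self, row, col):
        return np.asarray(row) * self.n_side + np.asarray(col)


@dataclass(frozen=True)
class AntennaArray:
    """Antennas equally spaced on a circle, counter-clockwise from start_angle."""

    count: int
    diameter: float
    center: np.ndarray
    positions: np.ndarray  # (count, 2)
    start_angle_deg: float = 0.0

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class Inclusion:
    """Homogeneous circular inclusion: center (m), diameter (m), eps_r, sigma (S/m)."""

    center: tuple[float, float]
    diameter: float
    eps_r: float
    sigma: float


@dataclass(frozen=True)
class PhantomSpec:
    """Imaging circle, inclusions, bath (eps, sigma) and background (eps, sigma).

    ``bath`` is the coupling liquid assigned to every dipole outside the
    inclusions; ``background`` defines the Green's function medium and must
    differ from the bath permittivity (otherwise the polarizability of bath
    dipoles vanishes and the system diagonal blows up).
    """

    imaging_radius: float
    inclusions: tuple[Inclusion, ...]
    bath: tuple[float, float]
    background: tuple[float, float]

    def __post_init__(self):
        if self.imaging_radius <= 0:
            raise ValueError("imaging_radius must be positive")
        if self.bath[0] == self.background[0]:
            raise ValueError(
                "eps_bath must differ from eps_bk: equal values give zero "
                "polarizability at bath dipoles and an infinite diagonal; "
                "offset the background slightly (e.g. 22 vs 21.99)"
            )
        for inc in self.inclusions:
            c = np.hypot(*inc.center)
            if c + inc.diameter / 2.0 > self.imaging_radius * (1 + 1e-12):
                raise ValueError(
                    f"inclusion at {inc.center} (d={inc.diameter}) extends "
                    f"beyond the imaging circle of radius {self.imaging_radius}"
                )


def build_grid(n_side: int, extent: float, center=(0.0, 0.0)) -> Grid2D:
    """Build an ``n_side`` × ``n_side`` node-centered dipole grid.

    Parameters
    ----------
    n_side : dipoles per side (>= 2).
    extent : physical side length in meters (> 0).
    center : grid center (m).
    """
    if n_side < 2:
        raise ValueError(f"n_side must be >= 2, got {n_side}")
    if extent <= 0:
        raise ValueError(f"extent must be positive, got {extent}")
    center = np.asarray(center, dtype=float)
    spacing = extent / (n_side - 1)
    axis = np.linspace(-extent / 2.0, extent / 2.0, n_side)
    # row-major: row -> y, col -> x
    X, Y = np.meshgrid(center[0] + axis, center[1] + axis, indexing="xy")
    positions = np.column_stack([X.ravel(), Y.ravel()])
    return Grid2D(n_side=n_side, extent=float(extent), center=center,
                  spacing=float(spacing), positions=positions)


def build_antenna_ring(count: int, diameter: float, center=(0.0, 0.0),
                       start_angle_deg: float = 0.0) -> AntennaArray:
    """Place ``count`` antennas uniformly on a circle, CCW from the start angle."""
    if count < 1:
        raise ValueError(f"antenna count must be >= 1, got {count}")
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    center = np.asarray(center, dtype=float)
    theta = np.deg2rad(start_angle_deg) + 2.0 * np.pi * np.arange(count) / count
    positions = center + (diameter / 2.0) * np.column_stack(
        [np.cos(theta), np.sin(theta)])
    return AntennaArray(count=count, diameter=float(diameter), center=center,
                        positions=positions, start_angle_deg=float(start_angle_deg))


def rasterize_phantom(grid: Grid2D, spec: PhantomSpec, omega: float):
    """Assign material properties to every dipole of ``grid``.

    Each dipole gets the bath (eps, sigma) unless it falls inside an
    inclusion disk (boundary dipoles, distance == radius, belong to the
    inclusion).  Returns a :class:`dda2d.physics.MediumMap` carrying the
    per-dipole map plus the background medium at angular frequency ``omega``.
    """
    from .physics import BackgroundMedium, MediumMap

    half = grid.extent / 2.0
    if spec.imaging_radius > half * np.sqrt(2.0) * (1 + 1e-12):
        raise ValueError("imaging circle does not fit within the grid extent")

    eps_r = np.full(grid.N, spec.bath[0], dtype=float)
    sigma = np.full(grid.N, spec.bath[1], dtype=float)
    for inc in spec.inclusions:
        d = np.hypot(grid.positions[:, 0] - inc.center[0],
                     grid.positions[:, 1] - inc.center[1])
        mask = d <= inc.diameter / 2.0
        eps_r[mask] = inc.eps_r
        sigma[mask] = inc.sigma
    background = BackgroundMedium(eps_r=spec.background[0],
                                  sigma=spec.background[1], omega=omega)
    return MediumMap(grid=grid, eps_r=eps_r, sigma=sigma, background=background,
                     bath=spec.bath)
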