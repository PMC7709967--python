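"""Electromagnetic kernels: wavenumbers, polarizability, Green's function, line source.

Conventions
-----------
Time dependence is ``exp(+j omega t)``, so outgoing cylindrical waves are
Hankel functions of the second kind and the complex relative permittivity
of a lossy medium is ``eps_c = eps_r - j sigma / (omega eps0)``; the square
root of ``k^2 = omega^2 mu0 eps0 eps_c`` is taken on the branch with
``Im(k) <= 0`` so fields decay with distance.

Polarizability
--------------
Two per-dipole polarizability schemes are provided:

``"maxwell-garnett"``
    The dimensionless 2D contrast factor
    ``alpha = (eps_t - eps_b) / (eps_t + eps_b)`` (optionally scaled by a
    dimension factor of 2, the m-dimensional Clausius-Mossotti prefactor).
    This is the effective-medium mixture form; it is *not* dimensionally
    consistent with the scalar Green's-function coupling and does not
    converge to the physical field under grid refinement.

``"calibrated"`` (default for the forward pipeline)
    ``alpha_i = h^2 (k_i^2 - k_bk^2) = omega^2 mu0 eps0 h^2 (eps_c,i - eps_c,bk)``
    with ``h`` the lattice spacing — the weak-form discretization of the
    2D Lippmann-Schwinger volume integral, which makes the dipole system
    the exact midpoint-rule discretization of the continuous scattering
    problem and converges to the analytic solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import hankel2

__all__ = [
    "MU_0", "EPS_0",
    "BackgroundMedium", "MediumMap", "SourceSpec",
    "complex_permittivity", "complex_wavenumber",
    "polarizability_2d", "polarizability_2d_mixture", "polarizability_map",
    "green_2d", "incident_field_els",
]

MU_0 = 4.0e-7 * np.pi            # vacuum permeability, H/m
EPS_0 = 8.8541878128e-12         # vacuum permittivity, F/m


def complex_permittivity(eps_r, sigma, omega):
    """eps_c = eps_r - j sigma/(omega eps0) under the e^{+j omega t} convention."""
    return np.asarray(eps_r, dtype=complex) - 1j * np.asarray(sigma) / (omega * EPS_0)


def complex_wavenumber(eps_r, sigma, omega):
    """Complex wavenumber k (1/m) with Im(k) <= 0 (decaying outgoing waves).

    k^2 = omega^2 mu0 eps0 eps_c; the principal square root of eps_c with
    Re(eps_c) > 0, Im(eps_c) <= 0 lies in the fourth quadrant, which is
    exactly the decaying branch.
    """
    eps_r = np.asarray(eps_r, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if omega <= 0:
        raise ValueError("omega must be positive")
    if np.any(eps_r <= 0):
        raise ValueError("eps_r must be positive")
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    k0 = omega * np.sqrt(MU_0 * EPS_0)
    return k0 * np.sqrt(complex_permittivity(eps_r, sigma, omega))


@dataclass(frozen=True)
class BackgroundMedium:
    """Homogeneous background: relative permittivity, conductivity, frequency."""

    eps_r: float
    sigma: float
    omega: float

    def __post_init__(self):
        if self.eps_r <= 0 or self.sigma < 0 or self.omega <= 0:
            raise ValueError("require eps_r > 0, sigma >= 0, omega > 0")

    @cached_property
    def eps_c(self) -> complex:
        return complex(complex_permittivity(self.eps_r, self.sigma, self.omega))

    @cached_property
    def k(self) -> complex:
        return complex(complex_wavenumber(self.eps_r, self.sigma, self.omega))

    @property
    def k_squared(self) -> complex:
        return self.k**2


@dataclass(frozen=True)
class SourceSpec:
    """Electric line source: current amplitude I0 (A), frequency, position (m)."""

    I0: float
    omega: float
    position: np.ndarray

    def __post_init__(self):
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass(frozen=True)
class MediumMap:
    """Per-dipole (eps_r, sigma) over a grid, plus the background medium."""

    grid: "object"
    eps_r: np.ndarray
    sigma: np.ndarray
    background: BackgroundMedium
    bath: tuple[float, float] | None = None
    mixture_components: tuple[tuple[float, complex], ...] | None = None

    def __post_init__(self):
        if len(self.eps_r) != self.grid.N or len(self.sigma) != self.grid.N:
            raise ValueError("per-dipole arrays must have length grid.N")
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("conductivities must be non-negative")
        if self.mixture_components is not None:
            total = sum(c for c, _ in self.mixture_components)
            if total > 1 + 1e-12:
                raise ValueError("mixture concentrations must sum to <= 1")

    @property
    def chi(self) -> np.ndarray:
        """Electric susceptibility chi = eps_r - 1 per dipole."""
        return np.asarray(self.eps_r) - 1.0

    @property
    def eps_c(self) -> np.ndarray:
        return complex_permittivity(self.eps_r, self.sigma, self.background.omega)


def polarizability_2d(eps_t, eps_b, dimension_factor: float = 1.0):
    """Dimensionless 2D polarizability (eps_t - eps_b)/(eps_t + eps_b).

    ``dimension_factor`` reconciles the two printed conventions: the
    m-dimensional Clausius-Mossotti prefactor gives 2 in 2D, while the
    operative Maxwell-Garnett definition carries no prefactor (default 1).
    """
    eps_t = np.asarray(eps_t, dtype=complex)
    eps_b = np.asarray(eps_b, dtype=complex)
    den = eps_t + eps_b
    if np.any(np.abs(den) == 0):
        raise ZeroDivisionError("degenerate polarizability: eps_t + eps_b = 0")
    return dimension_factor * (eps_t - eps_b) / den


def polarizability_2d_mixture(components, eps_b, dimension_factor: float = 1.0):
    """Maxwell-Garnett mixture: sum of c_k-weighted single-component terms.

    ``components`` is an iterable of (c_k, eps_k) pairs; concentrations are
    area fractions in 2D and must sum to <= 1.
    """
    total = 0.0 + 0.0j
    csum = 0.0
    for c_k, eps_k in components:
        csum += c_k
        total = total + c_k * polarizability_2d(eps_k, eps_b, dimension_factor)
    if csum > 1 + 1e-12:
        raise ValueError("mixture concentrations must sum to <= 1")
    return total


def polarizability_map(medium: MediumMap, scheme: str = "calibrated",
                       dimension_factor: float = 1.0) -> np.ndarray:
    """Per-dipole complex polarizability for the system diagonal (1/alpha).

    See the module docstring for the two schemes.  Raises if any dipole has
    exactly zero contrast against the background (use the bath/background
    permittivity offset).
    """
    bg = medium.background
    eps_t = medium.eps_c
    if scheme == "maxwell-garnett":
        alpha = polarizability_2d(eps_t, bg.eps_c, dimension_factor)
    elif scheme == "calibrated":
        h = medium.grid.spacing
        alpha = (bg.omega**2 * MU_0 * EPS_0) * h**2 * (eps_t - bg.eps_c)
    else:
        raise ValueError(f"unknown polarizability scheme {scheme!r}")
    if np.any(alpha == 0):
        raise ValueError(
            "zero polarizability at some dipoles (permittivity equals the "
            "background exactly); offset eps_bath from eps_bk")
    return alpha


def green_2d(distance, k_b):
    """Scalar 2D Helmholtz Green's function -(j/4) H0^(2)(k_b r).

    ``distance`` must be strictly positive: the self term is never evaluated
    through this kernel (the system diagonal is 1/alpha instead).
    """
    distance = np.asarray(distance, dtype=float)
    if np.any(distance <= 0):
        raise ValueError("green_2d requires strictly positive distances "
                         "(the singular self-term is handled by 1/alpha)")
    return -0.25j * hankel2(0, k_b * distance)


def incident_field_els(points, source: SourceSpec, background: BackgroundMedium):
    """Electric line source field E_inc = (I0 omega mu0 / 4) H0^(2)(k_b |rho - rho_a|).

    Vectorized over an (M, 2) array of evaluation points; raises if any point
    coincides with the source position.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.hypot(points[:, 0] - source.position[0],
                 points[:, 1] - source.position[1])
    if np.any(r == 0):
        raise ValueError("evaluation point coincides with the line source")
    amp = source.I0 * source.omega * MU_0 / 4.0
    return amp * hankel2(0, background.k * r)
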