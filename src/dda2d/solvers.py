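"""Dense direct and COCG/COCR iterative solvers for the complex-symmetric system.

COCG and COCR are Krylov methods for complex *symmetric* (not Hermitian)
matrices built on the unconjugated bilinear form ``<x, y> = sum_i x_i y_i``.
Both need exactly one operator application per iteration, which is what
makes the FFT-accelerated matvec pay off.  Residuals are not monotone for
COCG; convergence is declared on the relative 2-norm residual against
``||b||`` and confirmed with one true-residual evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = ["SolverConfig", "SolveReport", "direct_solve", "cocg_solve",
           "cocr_solve", "iterative_solve"]


@dataclass(frozen=True)
class SolverConfig:
    method: str = "cocg"           # direct | cocg | cocr
    backend: str = "fft"           # dense | fft
    tolerance: float = 1e-5        # relative residual ||b - Ax|| / ||b||
    max_iterations: int = 5000
    breakdown_tolerance: float = 1e-30

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.method not in ("direct", "cocg", "cocr"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.backend not in ("dense", "fft"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class SolveReport:
    method: str
    iterations: int
    residual_history: list[float]
    converged: bool
    matvec_count: int
    breakdown: bool = False
    message: str = ""
    condition_estimate: float | None = None


def _as_matvec(op):
    if hasattr(op, "matvec"):
        return op.matvec
    A = np.asarray(op)
    return lambda x: A @ x


def direct_solve(A, b, estimate_condition: bool = False):
    """Gaussian-elimination (LU) solve of the dense system.

    Returns ``(P, SolveReport)``; the report optionally carries a 1-norm
    condition estimate.  Raises on singular matrices.
    """
    M = np.asarray(A)
    b = np.asarray(b, dtype=complex)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("A must be square")
    if b.shape[0] != M.shape[0]:
        raise ValueError("b length must match A")
    lu, piv = scipy.linalg.lu_factor(M)
    diag = np.abs(np.diag(lu))
    if np.any(diag == 0):
        raise np.linalg.LinAlgError("singular system matrix")
    P = scipy.linalg.lu_solve((lu, piv), b)
    nb = np.linalg.norm(b)
    res = np.linalg.norm(b - M @ P) / nb if nb > 0 else 0.0
    cond = None
    if estimate_condition:
        cond = float(np.linalg.cond(M, 2))
    return P, SolveReport(method="direct", iterations=0,
                          residual_history=[float(res)], converged=True,
                          matvec_count=0, condition_estimate=cond)


def cocg_solve(op, b, cfg: SolverConfig | None = None):
    """Conjugate orthogonal conjugate gradient (van der Vorst-Melissen).

    One operator application per iteration; the unconjugated inner product
    replaces the Hermitian one of classical CG.  Near-vanishing ``r^T r`` or
    ``p^T A p`` is flagged as breakdown (non-convergence), never silently
    ignored.
    """
    cfg = cfg or SolverConfig(method="cocg")
    matvec = _as_matvec(op)
    b = np.asarray(b, dtype=complex)
    nb = np.linalg.norm(b)
    if nb == 0:
        return np.zeros_like(b), SolveReport(
            method="cocg", iterations=0, residual_history=[0.0],
            converged=True, matvec_count=0)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rho = r @ r
    history: list[float] = []
    matvecs = 0
    for it in range(1, cfg.max_iterations + 1):
        q = matvec(p)
        matvecs += 1
        mu = p @ q
        if abs(mu) < cfg.breakdown_tolerance * np.linalg.norm(p) * np.linalg.norm(q):
            return x, SolveReport(method="cocg", iterations=it - 1,
                                  residual_history=history, converged=False,
                                  matvec_count=matvecs, breakdown=True,
                                  message="pivot breakdown: p^T A p ~ 0")
        step = rho / mu
        x += step * p
        r -= step * q
        res = np.linalg.norm(r) / nb
        history.append(float(res))
        if res <= cfg.tolerance:
            true_res = np.linalg.norm(b - matvec(x)) / nb
            history[-1] = float(true_res)
            if true_res <= cfg.tolerance:
                return x, SolveReport(method="cocg", iterations=it,
                                      residual_history=history, converged=True,
                                      matvec_count=matvecs)
        rho_new = r @ r
        if abs(rho_new) < cfg.breakdown_tolerance * np.linalg.norm(r) ** 2:
            return x, SolveReport(method="cocg", iterations=it,
                                  residual_history=history, converged=False,
                                  matvec_count=matvecs, breakdown=True,
                                  message="breakdown: r^T r ~ 0 before convergence")
        p = r + (rho_new / rho) * p
        rho = rho_new
    return x, SolveReport(method="cocg", iterations=cfg.max_iterations,
                          residual_history=history, converged=False,
                          matvec_count=matvecs,
                          message="max_iterations reached")


def cocr_solve(op, b, cfg: SolverConfig | None = None):
    """Conjugate orthogonal conjugate residual (Sogabe-Zhang recurrence).

    Like COCG but orthogonalizes the residuals in the A-weighted bilinear
    form; one operator application per iteration after the initial ``A r0``.
    """
    cfg = cfg or SolverConfig(method="cocr")
    matvec = _as_matvec(op)
    b = np.asarray(b, dtype=complex)
    nb = np.linalg.norm(b)
    if nb == 0:
        return np.zeros_like(b), SolveReport(
            method="cocr", iterations=0, residual_history=[0.0],
            converged=True, matvec_count=0)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    ar = matvec(r)
    ap = ar.copy()
    matvecs = 1
    rho = r @ ar
    history: list[float] = []
    for it in range(1, cfg.max_iterations + 1):
        sigma = ap @ ap
        if abs(sigma) < cfg.breakdown_tolerance * np.linalg.norm(ap) ** 2:
            return x, SolveReport(method="cocr", iterations=it - 1,
                                  residual_history=history, converged=False,
                                  matvec_count=matvecs, breakdown=True,
                                  message="breakdown: (Ap)^T (Ap) ~ 0")
        step = rho / sigma
        x += step * p
        r -= step * ap
        res = np.linalg.norm(r) / nb
        history.append(float(res))
        if res <= cfg.tolerance:
            true_res = np.linalg.norm(b - matvec(x)) / nb
            history[-1] = float(true_res)
            if true_res <= cfg.tolerance:
                return x, SolveReport(method="cocr", iterations=it,
                                      residual_history=history, converged=True,
                                      matvec_count=matvecs)
        ar = matvec(r)
        matvecs += 1
        rho_new = r @ ar
        if abs(rho_new) < cfg.breakdown_tolerance * np.linalg.norm(r) ** 2:
            return x, SolveReport(method="cocr", iterations=it,
                                  residual_history=history, converged=False,
                                  matvec_count=matvecs, breakdown=True,
                                  message="breakdown: r^T A r ~ 0 before convergence")
        beta = rho_new / rho
        rho = rho_new
        p = r + beta * p
        ap = ar + beta * ap
    return x, SolveReport(method="cocr", iterations=cfg.max_iterations,
                          residual_history=history, converged=False,
                          matvec_count=matvecs,
                          message="max_iterations reached")


def iterative_solve(op, b, cfg: SolverConfig):
    """Dispatch on cfg.method (cocg | cocr | direct)."""
    if cfg.method == "cocg":
        return cocg_solve(op, b, cfg)
    if cfg.method == "cocr":
        return cocr_solve(op, b, cfg)
    return direct_solve(op, b)
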