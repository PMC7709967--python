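"""Orchestration: end-to-end forward runs, sweeps, benchmarks, validation.

Everything here is deterministic plumbing over the library modules: build
the scene from a :class:`~dda2d.config.RunConfig`, solve one right-hand side
per transmitting antenna (reusing the operator and its FFT spectra), and
write columnar text outputs stamped with the package version and the
resolved-config digest.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, config as _config
from .assembly import FastOperator, assemble_dense
from .fields import background_sweep, scattered_field_at, total_field_at_dipoles
from .physics import SourceSpec, incident_field_els
from .solvers import SolverConfig, iterative_solve
from .validation import dda_vs_analytic

log = logging.getLogger("dda2d")

DEFAULT_SWEEP_EPS_BK = (21.0, 21.9, 21.99, 21.999, 21.9999)

__all__ = ["run_forward", "run_sweep", "run_bench", "run_validate",
           "DEFAULT_SWEEP_EPS_BK"]


def _header(cfg: _config.RunConfig, extra: str = "") -> str:
    lines = [f"# dda2d {__version__}", f"# config sha256:{_config.config_digest(cfg)}"]
    if extra:
        lines.append(f"# {extra}")
    return "\n".join(lines) + "\n"


def _write_table(path: Path, cfg, df: pd.DataFrame, note: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg, note))
        df.to_csv(fh, index=False, lineterminator="\n")


def _field_frame(points: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "x_m": points[:, 0], "y_m": points[:, 1],
        "re_E": values.real, "im_E": values.imag,
        "abs_E": np.abs(values),
        "phase_deg": np.degrees(np.angle(values)),  # wraps at +/-180
    })


def _solver_config(cfg: _config.RunConfig) -> SolverConfig:
    s = cfg.solver
    return SolverConfig(method=s.method, backend=s.backend,
                        tolerance=s.tolerance, max_iterations=s.max_iterations)


def run_forward(cfg: _config.RunConfig, out_dir=None):
    """Solve the forward problem for every transmitting antenna.

    Writes, per antenna: dipole total-field map, receiver fields (total and
    scattered at the non-transmitting antennas), and dipole moments; plus a
    JSON solve report.  Returns a summary dict.
    """
    out = Path(out_dir if out_dir is not None else cfg.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    grid = _config.build_grid_from_config(cfg)
    antennas = _config.build_antennas(cfg)
    medium = _config.build_medium(cfg, grid=grid)
    alpha = _config.build_alpha(cfg, medium)
    op = _config.build_operator(cfg, grid, alpha, medium.background)
    solver_cfg = _solver_config(cfg)
    w = _config.omega(cfg)

    reports = []
    for a in range(antennas.count):
        source = SourceSpec(I0=cfg.source.I0, omega=w,
                            position=antennas.positions[a])
        b = incident_field_els(grid.positions, source, medium.background)
        P, report = iterative_solve(op, b, solver_cfg)
        if not report.converged:
            raise RuntimeError(
                f"solver did not converge for antenna {a}: {report.message}")
        log.debug("antenna %d: %s converged in %d iterations (res %.3e)",
                  a, report.method, report.iterations,
                  report.residual_history[-1] if report.residual_history else 0.0)
        e_tot = total_field_at_dipoles(P, alpha).values
        receivers = np.delete(antennas.positions, a, axis=0)
        e_scat_rx = scattered_field_at(receivers, P, grid, medium.background).values
        e_tot_rx = e_scat_rx + incident_field_els(receivers, source,
                                                  medium.background)

        _write_table(out / f"dipole_field_a{a:02d}.csv", cfg,
                     _field_frame(grid.positions, e_tot),
                     f"total field at dipoles, antenna {a}")
        rx = _field_frame(receivers, e_tot_rx)
        rx.insert(2, "re_E_scat", e_scat_rx.real)
        rx.insert(3, "im_E_scat", e_scat_rx.imag)
        _write_table(out / f"receiver_field_a{a:02d}.csv", cfg, rx,
                     f"receiver fields, antenna {a}")
        mom = pd.DataFrame({"x_m": grid.positions[:, 0],
                            "y_m": grid.positions[:, 1],
                            "re_P": P.real, "im_P": P.imag})
        _write_table(out / f"dipole_moments_a{a:02d}.csv", cfg, mom,
                     f"dipole moments, antenna {a}")
        reports.append({"antenna": a, "method": report.method,
                        "iterations": report.iterations,
                        "matvec_count": report.matvec_count,
                        "converged": report.converged,
                        "final_residual": report.residual_history[-1]
                        if report.residual_history else 0.0})
    summary = {"version": __version__, "config_digest": _config.config_digest(cfg),
               "n_antennas": antennas.count, "N": grid.N, "reports": reports}
    (out / "solve_report.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def run_sweep(cfg: _config.RunConfig, eps_bk_values=DEFAULT_SWEEP_EPS_BK,
              out_dir=None):
    """Background-permittivity sweep; writes the table and returns it."""
    table = background_sweep(cfg, eps_bk_values)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(out / "background_sweep.csv", cfg, table,
                     "condition numbers and relative error vs eps_bk")
    return table


def _time_matvec(apply_fn, x, repeats: int = 3) -> float:
    best = np.inf
    for _ in range(repeats):
        t0 = time.perf_counter()
        apply_fn(x)
        best = min(best, time.perf_counter() - t0)
    return best


def run_bench(cfg: _config.RunConfig, n_sides=(21, 41, 65, 81), out_dir=None,
              check_equal: bool = True):
    """Per-application cost of dense vs FFT matvec across grid sizes.

    Reports wall times for one operator application per backend on the same
    machine (their ratio is the hardware-free complexity signal: N^2 dense
    vs N log N FFT), plus an equality check of the two products.
    """
    rows = []
    for n_side in n_sides:
        grid = _config.build_grid_from_config(
            cfg.model_copy(update={"grid": cfg.grid.model_copy(
                update={"n_side": n_side})}))
        medium = _config.build_medium(cfg, grid=grid)
        alpha = _config.build_alpha(cfg, medium)
        dense = assemble_dense(grid, alpha, medium.background)
        fast = FastOperator(grid, alpha, medium.background,
                            strategy=cfg.solver.matvec_strategy,
                            power_of_two=cfg.solver.power_of_two_padding)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(grid.N) + 1j * rng.standard_normal(grid.N)
        equal = True
        if check_equal:
            yd, yf = dense.matvec(x), fast.matvec(x)
            equal = bool(np.linalg.norm(yd - yf) / np.linalg.norm(yd) < 1e-10)
        t_dense = _time_matvec(dense.matvec, x)
        t_fft = _time_matvec(fast.matvec, x)
        rows.append({"n_side": n_side, "N": grid.N,
                     "t_dense_s": t_dense, "t_fft_s": t_fft,
                     "ratio_dense_over_fft": t_dense / t_fft,
                     "products_equal": equal})
        del dense
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(out / "bench_matvec.csv", cfg, table,
                     "per-application matvec cost, dense vs FFT backend")
    return table


def run_validate(cfg: _config.RunConfig, grid_sides=(17, 33, 65),
                 threshold: float = 0.05, out_dir=None):
    """Compare the dipole solver against the analytic cylinder series.

    Returns ``(table, passed)`` where ``passed`` requires the receiver-field
    discrepancy to fall monotonically with refinement and to end below
    ``threshold`` on the finest grid.
    """
    table = dda_vs_analytic(cfg, grid_sides=grid_sides)
    d = table["total_rel_discrepancy"].to_numpy()
    passed = bool(np.all(np.diff(d) < 0) and d[-1] < threshold)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(out / "validate_cylinder.csv", cfg, table,
                     "DDA vs analytic cylinder series at receivers")
    return table, passed
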