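"""System assembly: dense matrix, block-Toeplitz generator, circulant FFT matvec.

The dipole-moment system is complex symmetric: ``A[i,i] = 1/alpha_i`` and
``A[i,j] = -G(rho_i, rho_j)`` for ``i != j``.  On a uniform grid the
off-diagonal part depends only on the displacement ``(row_i - row_j,
col_i - col_j)``, so ``G`` is block Toeplitz with Toeplitz blocks (BTTB).
Splitting the matrix into its diagonal and off-diagonal parts, the
off-diagonal product ``G x`` becomes a 2D discrete convolution that is
evaluated with FFTs after circulant embedding; a symmetric n x n Toeplitz
block embeds into a circulant of size ``2n - 2`` (81 -> 160), optionally
zero-padded to the next power of two (160 -> 256) for the FFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .geometry import Grid2D
from .physics import BackgroundMedium, green_2d

__all__ = [
    "DenseSystemMatrix", "BTTBGenerator", "FastOperator",
    "assemble_dense", "build_bttb_generator",
    "embed_circulant_block", "circulant_matvec", "fast_matvec",
    "next_power_of_two",
]


def next_power_of_two(n: int) -> int:
    return 1 << max(0, int(n - 1)).bit_length()


@dataclass(frozen=True)
class DenseSystemMatrix:
    """Dense N x N complex-symmetric system matrix with its diagonal alpha."""

    A: np.ndarray
    alpha: np.ndarray

    @property
    def shape(self):
        return self.A.shape

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.shape[0] != self.A.shape[1]:
            raise ValueError("dimension mismatch in dense matvec")
        return self.A @ x

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.A, dtype=dtype)


@dataclass(frozen=True)
class BTTBGenerator:
    """Green's-kernel table indexed by displacement (Delta row, Delta col).

    ``table[dr + n - 1, dc + n - 1] = G(h * hypot(dr, dc))`` for
    ``(dr, dc) != (0, 0)``; the (0, 0) entry is zero because the diagonal is
    carried separately as ``1/alpha``.
    """

    table: np.ndarray  # (2n-1, 2n-1)
    n_side: int

    def value(self, drow: int, dcol: int) -> complex:
        n = self.n_side
        return self.table[drow + n - 1, dcol + n - 1]

    def reconstruct_offdiag(self) -> np.ndarray:
        """Dense off-diagonal G matrix from the displacement table (tests/small n)."""
        n = self.n_side
        if n > 40:
            raise ValueError("dense reconstruction guarded to small grids")
        idx = np.arange(n * n)
        rows, cols = np.divmod(idx, n)
        dr = rows[:, None] - rows[None, :]
        dc = cols[:, None] - cols[None, :]
        return self.table[dr + n - 1, dc + n - 1]


def assemble_dense(grid: Grid2D, alpha: np.ndarray,
                   background: BackgroundMedium) -> DenseSystemMatrix:
    """Assemble the dense system: diag 1/alpha, off-diagonal -G(|rho_i - rho_j|)."""
    alpha = np.asarray(alpha, dtype=complex)
    if alpha.shape[0] != grid.N:
        raise ValueError("alpha must have length grid.N")
    if np.any(alpha == 0):
        raise ValueError("alpha contains zeros; offset eps_bath from eps_bk "
                         "so every dipole has nonzero contrast")
    p = grid.positions
    D = np.hypot(p[:, 0, None] - p[None, :, 0], p[:, 1, None] - p[None, :, 1])
    np.fill_diagonal(D, 1.0)  # placeholder, overwritten below
    A = -green_2d(D, background.k)
    np.fill_diagonal(A, 1.0 / alpha)
    return DenseSystemMatrix(A=A, alpha=alpha)


def build_bttb_generator(grid: Grid2D,
                         background: BackgroundMedium) -> BTTBGenerator:
    """Displacement-indexed Green's kernel table for the uniform grid."""
    n = grid.n_side
    d = np.arange(-(n - 1), n)
    DR, DC = np.meshgrid(d, d, indexing="ij")
    dist = grid.spacing * np.hypot(DR, DC)
    table = np.zeros_like(dist, dtype=complex)
    mask = dist > 0
    table[mask] = green_2d(dist[mask], background.k)
    return BTTBGenerator(table=table, n_side=n)


def embed_circulant_block(first_row, first_col=None, power_of_two: bool = True):
    """Embed a symmetric n x n Toeplitz block into a circulant generator.

    Returns ``(generator, embedded_size, fft_length)`` where the generator is
    the first row of the circulant: the Toeplitz first row followed by its
    reversed interior, of length ``2n - 2`` (81 -> 160).  ``fft_length`` is
    the next power of two >= embedded_size when ``power_of_two`` (160 -> 256),
    else the embedded size itself.
    """
    first_row = np.asarray(first_row)
    n = first_row.shape[0]
    if n < 2:
        raise ValueError("Toeplitz block must have n >= 2")
    if first_col is not None:
        first_col = np.asarray(first_col)
        if first_col[0] != first_row[0]:
            raise ValueError("first_row[0] must equal first_col[0]")
        if not np.allclose(first_col, first_row):
            raise ValueError("circulant embedding implemented for symmetric "
                             "Toeplitz blocks (first_col == first_row)")
    generator = np.concatenate([first_row, first_row[-2:0:-1]])
    embedded_size = 2 * n - 2
    fft_length = next_power_of_two(embedded_size) if power_of_two else embedded_size
    return generator, embedded_size, fft_length


def _wrap_kernel_1d(first_row: np.ndarray, length: int) -> np.ndarray:
    """Lay out symmetric-Toeplitz coefficients t_d at cyclic offsets d mod length.

    For length == 2n - 2 this reproduces the canonical circulant generator;
    for longer (power-of-two padded) lengths the negative displacements wrap
    to the tail and the middle stays zero, which keeps the cyclic convolution
    exact on the first n coordinates.
    """
    n = first_row.shape[0]
    if length < 2 * n - 2:
        raise ValueError("fft length too short for exact embedding")
    c = np.zeros(length, dtype=complex)
    d = np.arange(-(n - 1), n)
    c[d % length] = first_row[np.abs(d)]
    return c


class FastOperator:
    """FFT-accelerated operator ``x -> diag(1/alpha) x - G x``.

    Stores only O(N) data: the diagonal and precomputed circulant spectra of
    the Green's kernel (never the dense N x N matrix).  Two equivalent matvec
    strategies are provided:

    ``"full2d"``   one 2D block-circulant embedding of the whole BTTB kernel;
    ``"block1d"``  per-block 1D circulant multiplications, with the 2n - 1
                   distinct block spectra reused across block rows.
    """

    def __init__(self, grid: Grid2D, alpha: np.ndarray,
                 background: BackgroundMedium, strategy: str = "full2d",
                 power_of_two: bool = True):
        alpha = np.asarray(alpha, dtype=complex)
        if alpha.shape[0] != grid.N:
            raise ValueError("alpha must have length grid.N")
        if np.any(alpha == 0):
            raise ValueError("alpha contains zeros")
        if strategy not in ("full2d", "block1d"):
            raise ValueError(f"unknown matvec strategy {strategy!r}")
        n = grid.n_side
        gen = build_bttb_generator(grid, background)
        self.n_side = n
        self.N = grid.N
        self.strategy = strategy
        self.diagonal = 1.0 / alpha
        self.embedded_size = 2 * n - 2
        self.fft_length = (next_power_of_two(self.embedded_size)
                           if power_of_two else self.embedded_size)
        L = self.fft_length
        if strategy == "full2d":
            d = np.arange(-(n - 1), n)
            kernel = np.zeros((L, L), dtype=complex)
            kernel[np.ix_(d % L, d % L)] = gen.table
            self._spectrum2d = sfft.fft2(kernel)
        else:
            # one spectrum per distinct block offset |Delta row| = 0..n-1
            rows = gen.table[(n - 1):, (n - 1):]  # table[dr, dc>=0], dr >= 0
            spectra = np.empty((n, L), dtype=complex)
            for dr in range(n):
                spectra[dr] = sfft.fft(_wrap_kernel_1d(rows[dr], L))
            self._spectra1d = spectra

    @property
    def shape(self):
        return (self.N, self.N)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=complex)
        if x.shape != (self.N,):
            raise ValueError(f"expected vector of length {self.N}, got {x.shape}")
        n, L = self.n_side, self.fft_length
        X = x.reshape(n, n)
        if self.strategy == "full2d":
            Xp = np.zeros((L, L), dtype=complex)
            Xp[:n, :n] = X
            conv = sfft.ifft2(self._spectrum2d * sfft.fft2(Xp))[:n, :n]
        else:
            Xh = sfft.fft(X, n=L, axis=1)
            Yh = self._spectra1d[0][None, :] * Xh
            for dr in range(1, n):
                S = self._spectra1d[dr]
                Yh[dr:] += S * Xh[: n - dr]
                Yh[: n - dr] += S * Xh[dr:]
            conv = sfft.ifft(Yh, axis=1)[:, :n]
        return self.diagonal * x - conv.ravel()


def circulant_matvec(first_row, x, power_of_two: bool = True):
    """Multiply a symmetric Toeplitz matrix (given by its first row) by x via FFT."""
    first_row = np.asarray(first_row, dtype=complex)
    x = np.asarray(x, dtype=complex)
    n = first_row.shape[0]
    if x.shape[0] != n:
        raise ValueError("dimension mismatch")
    _, embedded_size, L = embed_circulant_block(first_row, power_of_two=power_of_two)
    c = _wrap_kernel_1d(first_row, L)
    return sfft.ifft(sfft.fft(c) * sfft.fft(x, n=L))[:n]


def fast_matvec(op: FastOperator, x: np.ndarray) -> np.ndarray:
    """Apply the split operator diag(1/alpha) x - G x via FFT convolution."""
    return op.matvec(x)
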