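import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dda2d import (FastOperator, assemble_dense, build_bttb_generator,
                   build_grid, circulant_matvec, embed_circulant_block,
                   fast_matvec, green_2d, next_power_of_two)


@pytest.fixture
def system(scene_factory):
    grid, medium, alpha = scene_factory(5)
    return grid, medium.background, alpha


from functools import lru_cache

from dda2d import BackgroundMedium, polarizability_map, rasterize_phantom
from dda2d.geometry import Inclusion, PhantomSpec
from tests.conftest import OMEGA


@lru_cache(maxsize=1)
def _cached_small_operator():
    """6 x 6 default-phantom operator, shared across hypothesis examples."""
    grid = build_grid(6, 0.40)
    spec = PhantomSpec(imaging_radius=0.076,
                       inclusions=(Inclusion((0, 0), 0.06, 40.0, 1.0),),
                       bath=(22.0, 1.0), background=(21.99, 1.0))
    medium = rasterize_phantom(grid, spec, OMEGA)
    alpha = polarizability_map(medium)
    return grid, FastOperator(grid, alpha, medium.background)


class TestDense:
    def test_smallest_grid_entries_by_definition(self, scene_factory):
        grid, medium, alpha = scene_factory(2)
        A = assemble_dense(grid, alpha, medium.background).A
        assert np.allclose(np.diag(A), 1.0 / alpha, rtol=1e-15)
        for i in range(4):
            for j in range(4):
                if i != j:
                    d = np.linalg.norm(grid.positions[i] - grid.positions[j])
                    assert A[i, j] == pytest.approx(-green_2d(d, medium.background.k),
                                                    rel=1e-12)

    def test_exactly_symmetric(self, system):
        grid, bg, alpha = system
        A = assemble_dense(grid, alpha, bg).A
        assert np.max(np.abs(A - A.T)) == 0.0

    def test_offdiagonal_bruteforce(self, system):
        """Every off-diagonal entry equals -green_2d for that pair (exhaustive)."""
        grid, bg, alpha = system
        A = assemble_dense(grid, alpha, bg).A
        for i in range(grid.N):
            for j in range(grid.N):
                if i != j:
                    d = np.linalg.norm(grid.positions[i] - grid.positions[j])
                    assert A[i, j] == pytest.approx(-green_2d(d, bg.k), rel=1e-12)

    def test_zero_alpha_rejected(self, system):
        grid, bg, alpha = system
        bad = alpha.copy()
        bad[3] = 0.0
        with pytest.raises(ValueError, match="offset"):
            assemble_dense(grid, bad, bg)


class TestBTTBGenerator:
    def test_reconstruction_matches_dense_offdiagonal(self, scene_factory):
        grid, medium, alpha = scene_factory(4)
        gen = build_bttb_generator(grid, medium.background)
        G = gen.reconstruct_offdiag()
        A = assemble_dense(grid, alpha, medium.background).A
        off = -A.copy()
        np.fill_diagonal(off, 0.0)
        # same kernel values up to last-ulp differences in the distance paths
        assert np.allclose(G, off, rtol=1e-12, atol=0)
        assert np.array_equal(G == 0, off == 0)

    def test_table_symmetric_under_negation(self, scene_factory):
        grid, medium, _ = scene_factory(6)
        gen = build_bttb_generator(grid, medium.background)
        assert np.array_equal(gen.table, gen.table[::-1, ::-1])

    def test_diagonal_entry_excluded(self, scene_factory):
        grid, medium, _ = scene_factory(6)
        gen = build_bttb_generator(grid, medium.background)
        assert gen.value(0, 0) == 0.0


class TestCirculantEmbedding:
    def test_bench_block_sizes(self):
        """81-wide Toeplitz block embeds to 160 (79 added), FFT-padded to 256."""
        row = np.arange(81, dtype=complex)
        gen, embedded, fft_len = embed_circulant_block(row)
        assert embedded == 160 and embedded - 81 == 79
        assert fft_len == 256
        assert len(gen) == 160
        _, _, no_pad = embed_circulant_block(row, power_of_two=False)
        assert no_pad == 160

    def test_three_by_three_generator(self, rng):
        a, b, c = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        gen, embedded, _ = embed_circulant_block(np.array([a, b, c]))
        assert embedded == 4
        assert np.array_equal(gen, np.array([a, b, c, b]))
        T = np.array([[a, b, c], [b, a, b], [c, b, a]])
        x = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        for pow2 in (True, False):
            y = circulant_matvec(np.array([a, b, c]), x, power_of_two=pow2)
            assert np.allclose(y, T @ x, rtol=1e-12)

    def test_padded_fft_product_matches_dense(self, rng):
        # power-of-two padding beyond 2n-2 must not corrupt the cyclic product
        n = 7
        row = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        T = np.empty((n, n), dtype=complex)
        for i in range(n):
            for j in range(n):
                T[i, j] = row[abs(i - j)]
        x = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        assert np.allclose(circulant_matvec(row, x), T @ x, rtol=1e-12)

    def test_too_small_block(self):
        with pytest.raises(ValueError):
            embed_circulant_block(np.array([1.0]))

    def test_asymmetric_block_rejected(self):
        with pytest.raises(ValueError):
            embed_circulant_block(np.array([1.0, 2.0, 3.0]),
                                  first_col=np.array([1.0, 5.0, 6.0]))

    def test_next_power_of_two(self):
        assert [next_power_of_two(v) for v in (1, 2, 3, 160, 256)] == \
            [1, 2, 4, 256, 256]


class TestFastMatvec:
    @pytest.mark.parametrize("strategy", ["full2d", "block1d"])
    def test_zero_vector(self, system, strategy):
        grid, bg, alpha = system
        op = FastOperator(grid, alpha, bg, strategy=strategy)
        assert np.allclose(fast_matvec(op, np.zeros(grid.N, complex)), 0.0)

    @pytest.mark.parametrize("strategy", ["full2d", "block1d"])
    def test_unit_vectors_give_dense_columns(self, system, strategy):
        grid, bg, alpha = system
        A = assemble_dense(grid, alpha, bg).A
        op = FastOperator(grid, alpha, bg, strategy=strategy)
        for k in range(grid.N):
            e = np.zeros(grid.N, dtype=complex)
            e[k] = 1.0
            assert np.allclose(op.matvec(e), A[:, k], rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("strategy", ["full2d", "block1d"])
    @pytest.mark.parametrize("pow2", [True, False])
    def test_random_vectors_match_dense(self, scene_factory, rng, strategy, pow2):
        grid, medium, alpha = scene_factory(9)
        dense = assemble_dense(grid, alpha, medium.background)
        op = FastOperator(grid, alpha, medium.background, strategy=strategy,
                          power_of_two=pow2)
        for _ in range(10):
            x = rng.standard_normal(grid.N) + 1j * rng.standard_normal(grid.N)
            yd = dense.matvec(x)
            assert np.linalg.norm(op.matvec(x) - yd) / np.linalg.norm(yd) < 1e-10

    def test_strategies_agree(self, scene_factory, rng):
        grid, medium, alpha = scene_factory(12)
        op2 = FastOperator(grid, alpha, medium.background, strategy="full2d")
        op1 = FastOperator(grid, alpha, medium.background, strategy="block1d")
        x = rng.standard_normal(grid.N) + 1j * rng.standard_normal(grid.N)
        y2, y1 = op2.matvec(x), op1.matvec(x)
        assert np.linalg.norm(y1 - y2) / np.linalg.norm(y2) < 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1),
           a=st.complex_numbers(max_magnitude=10, allow_nan=False,
                                allow_infinity=False),
           b=st.complex_numbers(max_magnitude=10, allow_nan=False,
                                allow_infinity=False))
    def test_linearity(self, seed, a, b):
        grid, op = _cached_small_operator()
        r = np.random.default_rng(seed)
        x = r.standard_normal(grid.N) + 1j * r.standard_normal(grid.N)
        y = r.standard_normal(grid.N) + 1j * r.standard_normal(grid.N)
        lhs = op.matvec(a * x + b * y)
        rhs = a * op.matvec(x) + b * op.matvec(y)
        assert np.linalg.norm(lhs - rhs) <= 1e-10 * max(np.linalg.norm(rhs), 1.0)

    def test_bilinear_symmetry(self, scene_factory, rng):
        """x^T (A y) = y^T (A x): unconjugated complex symmetry of the operator."""
        grid, medium, alpha = scene_factory(9)
        op = FastOperator(grid, alpha, medium.background)
        for _ in range(5):
            x = rng.standard_normal(grid.N) + 1j * rng.standard_normal(grid.N)
            y = rng.standard_normal(grid.N) + 1j * rng.standard_normal(grid.N)
            lhs, rhs = x @ op.matvec(y), y @ op.matvec(x)
            assert abs(lhs - rhs) / abs(rhs) < 1e-10

    def test_memory_contract(self, scene_factory):
        """Operator stores O(N) complex values, never the dense N x N matrix."""
        grid, medium, alpha = scene_factory(33)
        for strategy in ("full2d", "block1d"):
            op = FastOperator(grid, alpha, medium.background, strategy=strategy)
            stored = sum(v.size for v in vars(op).values()
                         if isinstance(v, np.ndarray))
            assert stored <= 10 * grid.N
            assert all(v.size < grid.N**2 for v in vars(op).values()
                       if isinstance(v, np.ndarray))

    def test_dimension_mismatch(self, system):
        grid, bg, alpha = system
        op = FastOperator(grid, alpha, bg)
        with pytest.raises(ValueError):
            op.matvec(np.zeros(grid.N + 1, dtype=complex))
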