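import numpy as np
import pytest

from vcsd.conductors import InfiniteHomogeneousConductor
from vcsd.errors import RankDeficiencyError, SelectionError
from vcsd.forward import LeadField, assemble_leadfield
from vcsd.geometry import build_grid, build_lattice_array, centered_grid
from vcsd.inverse import (
    VCSDSolver,
    build_laplacian,
    default_lambda_grid,
    solve_vcsd,
    solve_vcsd_primal,
)
from vcsd.simulation import NoiseSpec, PhantomSpec, add_noise, gaussian_phantom


def brute_force_solution(g_csd, lap_dense, phi, lam):
    a = g_csd.T @ g_csd + lam * lap_dense.T @ lap_dense
    return np.linalg.solve(a, g_csd.T @ phi)


def brute_force_gcv(g_csd, lap_dense, phi, lam):
    n = g_csd.shape[0]
    a = g_csd.T @ g_csd + lam * lap_dense.T @ lap_dense
    p = np.eye(n) - g_csd @ np.linalg.solve(a, g_csd.T)
    return float(np.sum((p @ phi) ** 2) / np.trace(p) ** 2)


@pytest.fixture(scope="module")
def random_system(rng):
    """10 electrodes observing a 2x3x4 grid (M=24) in a homogeneous medium."""
    grid = build_grid((-25, -25, 400), (2, 3, 4), 50.0)
    pos = np.c_[rng.uniform(-150, 150, (10, 2)), rng.uniform(350, 650, 10)]
    from vcsd.geometry import ElectrodeArray

    arr = ElectrodeArray(positions=pos, n_x=0, n_y=0, n_z=0)
    lf = assemble_leadfield(arr, grid, InfiniteHomogeneousConductor(0.3))
    return lf


class TestLaplacian:
    def test_interior_row_sums_to_zero(self):
        grid = build_grid((0, 0, 0), (3, 3, 3), 50.0)
        lap = build_laplacian(grid).matrix
        center = grid.flat_index(1, 1, 1)
        assert lap[center].sum() == pytest.approx(0.0, abs=1e-18)
        assert lap[center, center] == pytest.approx(-6 / 50.0 ** 2)

    def test_corner_row_sum(self):
        grid = build_grid((0, 0, 0), (3, 3, 3), 50.0)
        lap = build_laplacian(grid).matrix
        assert lap[0].sum() == pytest.approx(-3 / 50.0 ** 2)

    def test_2x2x2_matches_hand_expansion(self):
        d = 100.0
        grid = build_grid((0, 0, 0), (2, 2, 2), d)
        lap = build_laplacian(grid).matrix.toarray()
        expect = np.full((8, 8), 0.0)
        for j in range(8):
            expect[j, j] = -6 / d ** 2
            from vcsd.geometry import neighbor_indices

            for k in neighbor_indices(grid, j):
                expect[j, k] = 1 / d ** 2
        np.testing.assert_allclose(lap, expect)

    def test_symmetry_and_sparsity_pattern(self):
        grid = build_grid((0, 0, 0), (4, 3, 4), 25.0)
        lap = build_laplacian(grid).matrix
        assert (lap != lap.T).nnz == 0
        pos = grid.positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        adj = np.isclose(d, grid.d)
        off = lap.toarray().copy()
        np.fill_diagonal(off, 0.0)
        np.testing.assert_array_equal(off != 0, adj)


class TestSolveAgainstBruteForce:
    @pytest.mark.parametrize("lam_scale", [1e-4, 1.0, 1e4])
    def test_dual_path_matches_dense_inverse(self, random_system, rng, lam_scale):
        lf = random_system
        lap = build_laplacian(lf.grid)
        solver = VCSDSolver(lf, lap)
        lam = lam_scale * default_lambda_grid(solver.g_csd, lap)[20]
        phi = rng.normal(size=lf.n_electrodes)
        expect = brute_force_solution(solver.g_csd, lap.matrix.toarray(), phi, lam)
        got = solver.solve(phi, lam=lam).values
        np.testing.assert_allclose(got, expect, rtol=1e-8, atol=1e-8 * np.abs(expect).max())

    def test_primal_path_agrees(self, random_system, rng):
        lf = random_system
        lap = build_laplacian(lf.grid)
        solver = VCSDSolver(lf, lap)
        lam = default_lambda_grid(solver.g_csd, lap)[18]
        phi = rng.normal(size=lf.n_electrodes)
        dual = solver.solve(phi, lam=lam).values
        primal = solve_vcsd_primal(lf, phi, lap, lam=lam).values
        np.testing.assert_allclose(dual, primal, rtol=1e-7,
                                   atol=1e-9 * np.abs(primal).max())

    def test_zero_potentials_give_zero_csd(self, random_system):
        est = solve_vcsd(random_system, np.zeros(10), lam=1e-3)
        np.testing.assert_array_equal(est.values, 0.0)
        assert est.method == "vcsd"

    def test_penalty_dominance_shrinks_solution(self, random_system, rng):
        lf = random_system
        solver = VCSDSolver(lf)
        phi = rng.normal(size=lf.n_electrodes)
        lam0 = default_lambda_grid(solver.g_csd, solver.laplacian)[25]
        norms = [np.linalg.norm(solver.solve(phi, lam=lam0 * f).values)
                 for f in (1.0, 1e6, 1e12)]
        assert norms[0] > norms[1] > norms[2]

    def test_row_permutation_invariance(self, random_system, rng):
        lf = random_system
        phi = rng.normal(size=lf.n_electrodes)
        perm = rng.permutation(lf.n_electrodes)
        lf_perm = LeadField(matrix=lf.matrix[perm], array=lf.array,
                            grid=lf.grid, conductor_kind=lf.conductor_kind)
        lam = 1e-2 * default_lambda_grid(lf.matrix * lf.grid.d ** 3,
                                         build_laplacian(lf.grid))[20]
        a = solve_vcsd(lf, phi, lam=lam).values
        b = solve_vcsd(lf_perm, phi[perm], lam=lam).values
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_lambda_zero_rejected_when_rank_deficient(self, random_system):
        with pytest.raises(RankDeficiencyError):
            VCSDSolver(random_system).solve(np.ones(10), lam=0.0)


class TestGCV:
    def test_matches_dense_transcription(self, rng):
        arr = build_lattice_array((2, 2, 2), 100.0, origin=(-50, -50, 300))
        grid = build_grid((-25, -25, 325), (3, 3, 3), 50.0)
        lf = assemble_leadfield(arr, grid, InfiniteHomogeneousConductor(0.3))
        lap = build_laplacian(grid)
        solver = VCSDSolver(lf, lap)
        phi = rng.normal(size=8)
        for lam in default_lambda_grid(solver.g_csd, lap)[[5, 20, 35]]:
            got = solver.gcv(phi, lam)
            expect = brute_force_gcv(solver.g_csd, lap.matrix.toarray(), phi, lam)
            assert got == pytest.approx(expect, rel=1e-8)

    def test_zero_potentials_zero_score(self, random_system):
        solver = VCSDSolver(random_system)
        for lam in solver.lambda_grid[[0, 20, 39]]:
            assert solver.gcv(np.zeros(10), lam) == 0.0

    def test_quadratic_homogeneity_in_data(self, random_system, rng):
        solver = VCSDSolver(random_system)
        phi = rng.normal(size=10)
        lam = solver.lambda_grid[22]
        assert solver.gcv(3.0 * phi, lam) == pytest.approx(
            9.0 * solver.gcv(phi, lam), rel=1e-12)

    def test_finite_over_wide_lambda_range(self, random_system, rng):
        solver = VCSDSolver(random_system)
        phi = rng.normal(size=10)
        scale = default_lambda_grid(solver.g_csd, solver.laplacian)[20]
        lams = scale * np.logspace(-12, 6, 30)
        scores = [solver.gcv(phi, lam) for lam in lams]
        assert np.all(np.isfinite(scores))


class TestSelectLambda:
    def test_single_element_grid(self, random_system, rng):
        solver = VCSDSolver(random_system)
        phi = rng.normal(size=10)
        lam, scores = solver.select_lambda(phi, lambda_grid=[0.5])
        assert lam == 0.5 and len(scores) == 1

    def test_returned_lambda_attains_minimum(self, random_system, rng):
        solver = VCSDSolver(random_system)
        phi = rng.normal(size=10)
        lam, scores = solver.select_lambda(phi)
        k = np.where(solver.lambda_grid == lam)[0][0]
        assert scores[k] == scores.min()

    def test_ties_break_toward_larger_lambda(self, random_system):
        solver = VCSDSolver(random_system)
        # zero data scores 0 everywhere -> pick the largest grid point
        lam, _ = solver.select_lambda(np.zeros(10))
        assert lam == solver.lambda_grid[-1]

    def test_all_nan_scores_raise(self, random_system, monkeypatch):
        solver = VCSDSolver(random_system)
        monkeypatch.setattr(VCSDSolver, "gcv", lambda self, p, l: np.nan)
        with pytest.raises(SelectionError):
            solver.select_lambda(np.ones(10))

    def test_noisier_data_selects_larger_lambda(self):
        """Median selected lambda rises with the noise level (20 seeds)."""
        arr = build_lattice_array((3, 3, 4), 150.0, origin=(-150, -150, 300))
        grid = centered_grid(arr, (6, 6, 8), 75.0, offset=(20.0, 20.0, 20.0))
        lf = assemble_leadfield(arr, grid, InfiniteHomogeneousConductor(0.3))
        solver = VCSDSolver(lf)
        truth = gaussian_phantom(
            grid, PhantomSpec("gaussian_isotropic", 500.0, 200.0))
        phi = lf.matrix @ (truth.values * grid.d ** 3)
        lows, highs = [], []
        for seed in range(20):
            lo = add_noise(phi, NoiseSpec(beta=0.01, seed=seed))
            hi = add_noise(phi, NoiseSpec(beta=0.5, seed=seed))
            lows.append(solver.select_lambda(lo)[0])
            highs.append(solver.select_lambda(hi)[0])
        assert np.median(highs) >= np.median(lows)
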