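"""Niche-factor model: closed-form one-dimensional cases, the uniform
null, brute-force generalized-Rayleigh oracles, and the published-table
aggregation arithmetic."""

import numpy as np
import pytest

from cnva.cnfa import fit_cnfa, total_marginality, total_sensitivity
from cnva.grid import GridSpec
from cnva.prep import standardize
from cnva.ranges import HabitatWeights
from cnva.stack import ClimateStack
from cnva.synthetic import SpeciesSpec, WorldSpec, generate_climate, generate_species
from cnva.ranges import occurrence_weights


def _uniform_weights(grid):
    n = grid.n_rows * grid.n_cols
    return HabitatWeights(grid=grid, weights=np.full(grid.shape, 1.0 / n))


def _stack(values, names=None):
    P, r, c = values.shape
    return ClimateStack(
        GridSpec(r, c, 0.1),
        names or [f"v{i}" for i in range(P)],
        values,
        np.ones((r, c), bool),
    )


class TestFitCnfa:
    def test_uniform_species_is_the_null_model(self):
        rng = np.random.default_rng(0)
        std = standardize(_stack(rng.standard_normal((3, 100, 100))))
        model = fit_cnfa(std, _uniform_weights(std.grid))
        assert model.M < 1e-6
        assert np.max(np.abs(model.rho - 1)) < 0.05
        assert np.max(np.abs(model.s - model.s.mean())) < 0.1

    def test_one_dimensional_variance_ratio_closed_form(self):
        # weights concentrate the species where the variable is close to
        # its mean; the specialization equals var_G / var_S computed
        # directly from the same weights
        rng = np.random.default_rng(1)
        std = standardize(_stack(rng.standard_normal((1, 100, 100))))
        z = std.values[0]
        w = np.exp(-0.5 * z**2 / (1.0 / 3.0))  # target species var 0.25
        w /= w.sum()
        model = fit_cnfa(std, HabitatWeights(grid=std.grid, weights=w))
        m = (w * z).sum()
        var_s = (w * (z - m) ** 2).sum()
        assert model.rho[0] == pytest.approx(1.0 / var_s, rel=1e-10)
        assert model.s[0] == pytest.approx(1.0 / var_s, rel=1e-10)
        assert model.rho[0] == pytest.approx(4.0, rel=0.15)  # construction target

    def test_narrow_variable_scores_higher_sensitivity(self):
        # species narrow in variable 1 (SD 0.5) and broad in variable 2
        # (SD 1.0): the sensitivity factor for variable 1 should dominate
        # in nearly every seeded world
        wins = 0
        n_runs = 25
        for seed in range(n_runs):
            wspec = WorldSpec(
                n_rows=48,
                n_cols=48,
                n_vars=2,
                var_correlation=np.eye(2),
                seed=seed,
            )
            current, _ = generate_climate(wspec)
            occ = generate_species(
                SpeciesSpec(
                    name="sp",
                    niche_center=np.zeros(2),
                    niche_sd=np.array([0.5, 1.0]),
                    n_occurrences=80,
                    seed=seed + 1000,
                ),
                current,
            )
            std = standardize(current)
            w = occurrence_weights(occ, current.grid, current.mask)
            model = fit_cnfa(std, w)
            wins += model.s[0] > model.s[1]
        assert wins >= int(0.9 * n_runs)

    def test_eigen_solution_matches_brute_force_rayleigh(self):
        # top specialization axis vs 10^4 random unit vectors constrained
        # to the C_S-orthogonal complement of the marginality axis
        rng = np.random.default_rng(2)
        std = standardize(_stack(rng.standard_normal((3, 20, 25))))
        w = rng.random(std.grid.shape) ** 3
        w /= w.sum()
        model = fit_cnfa(std, HabitatWeights(grid=std.grid, weights=w))

        Z = std.background_matrix()
        p = w.ravel()
        m = p @ Z
        Zc = Z - m
        C_S = (Zc * p[:, None]).T @ Zc
        C_G = np.cov(Z, rowvar=False, bias=True)
        y = m / np.linalg.norm(m)

        best = 0.0
        cands = rng.standard_normal((10_000, 3))
        # project out the C_S-conjugate direction of y
        csy = C_S @ y
        cands -= np.outer(cands @ csy, y) / (y @ csy)
        for a in cands:
            num = a @ C_G @ a
            den = a @ C_S @ a
            if den > 1e-12:
                best = max(best, num / den)
        assert model.rho[1] == pytest.approx(best, rel=0.01)

    def test_scale_equivariance_through_standardization(self):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((3, 40, 40))
        w = rng.random((40, 40))
        w /= w.sum()
        grid = GridSpec(40, 40, 0.1)
        hw = HabitatWeights(grid=grid, weights=w)
        m1 = fit_cnfa(standardize(_stack(raw)), hw)
        scaled = raw.copy()
        scaled[1] *= 37.0  # rescale one raw variable
        m2 = fit_cnfa(standardize(_stack(scaled)), hw)
        assert np.allclose(m1.m, m2.m, atol=1e-10)
        assert np.allclose(m1.rho, m2.rho, atol=1e-8)
        assert np.allclose(m1.s, m2.s, atol=1e-8)

    def test_too_few_occupied_cells_rejected(self):
        rng = np.random.default_rng(4)
        std = standardize(_stack(rng.standard_normal((3, 10, 10))))
        w = np.zeros((10, 10))
        w[0, :3] = 1 / 3
        with pytest.raises(ValueError, match="cells"):
            fit_cnfa(std, HabitatWeights(grid=std.grid, weights=w))

    def test_loadings_have_unit_norm_and_nonnegative_weights(self):
        rng = np.random.default_rng(5)
        std = standardize(_stack(rng.standard_normal((4, 30, 30))))
        w = rng.random((30, 30))
        w /= w.sum()
        model = fit_cnfa(std, HabitatWeights(grid=std.grid, weights=w))
        assert np.allclose(np.linalg.norm(model.w, axis=0), 1.0, atol=1e-8)
        assert np.all(model.w >= 0)
        assert np.all(model.rho >= 0)
        assert np.all(model.s >= 0)


class TestTotals:
    def test_total_marginality_norm(self):
        assert total_marginality(np.zeros(4)) == 0.0
        assert total_marginality(np.array([0.3, 0.4])) == pytest.approx(0.5)
        assert total_marginality(np.array([0.3, 0.4]), legacy_divisor=True) == pytest.approx(0.5 / 1.96)

    @pytest.mark.parametrize(
        "factors,expected",
        [
            ((13.58, 11.19, 6.08, 4.44, 30.62, 7.13), 3.489),
            ((4.13, 3.50, 4.24, 6.54, 9.22, 2.66), 2.247),
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_total_sensitivity_root_mean(self, factors, expected):
        assert total_sensitivity(np.array(factors)) == pytest.approx(expected, abs=0.001)

    def test_flat_mean_mode(self):
        assert total_sensitivity(np.array([2.0, 4.0]), method="mean") == 3.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            total_sensitivity(np.array([]))
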