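"""Spatial surfaces: projection formulas, normalization, classification
and the monotone link between exposure and vulnerability."""

import numpy as np
import pytest

from cnva.cnfa import NicheModel
from cnva.grid import GridSpec
from cnva.ranges import RangeEstimate
from cnva.stack import StandardizedStack
from cnva.surfaces import (
    classify,
    exposure_score,
    exposure_surface,
    sensitivity_surface,
    vulnerability_surface,
)


def _std(values, grid=None):
    P = values.shape[0]
    grid = grid or GridSpec(values.shape[1], values.shape[2], 0.1)
    return StandardizedStack(
        grid,
        [f"v{i}" for i in range(P)],
        values,
        np.ones(values.shape[1:], bool),
        "current",
        mu=np.zeros(P),
        sigma=np.ones(P),
    )


def _range_all(grid):
    return RangeEstimate(
        grid=grid,
        in_range=np.ones(grid.shape, bool),
        score=np.ones(grid.shape),
        threshold=0.5,
    )


def _model(P, m=None, rho=None, w=None):
    m = np.zeros(P) if m is None else np.asarray(m, float)
    rho = np.ones(P) if rho is None else np.asarray(rho, float)
    w = np.eye(P) if w is None else np.asarray(w, float)
    s = w @ rho
    return NicheModel(
        species="t",
        variables=[f"v{i}" for i in range(P)],
        m=m,
        w=w,
        rho=rho,
        s=s,
        M=float(np.linalg.norm(m)),
        S=float(np.sqrt(s.mean())),
        loadings=w,
    )


class TestSensitivitySurface:
    def test_centroid_cell_is_the_minimum(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((2, 9, 9))
        vals[:, 4, 4] = 0.3  # place one cell exactly at the centroid
        model = _model(2, m=[0.3, 0.3])
        surf = sensitivity_surface(model, _std(vals), _range_all(GridSpec(9, 9, 0.1)))
        assert surf.values[4, 4] == 0.0
        assert surf.raw_values[4, 4] == pytest.approx(0.0, abs=1e-12)

    def test_high_specialization_axis_scores_four_fold(self):
        # two cells displaced equally along different axes; rho = (4, 1)
        vals = np.zeros((2, 1, 3))
        vals[0, 0, 1] = 1.0  # displaced along axis 0 (rho 4)
        vals[1, 0, 2] = 1.0  # displaced along axis 1 (rho 1)
        model = _model(2, rho=[4.0, 1.0])
        surf = sensitivity_surface(
            model, _std(vals, GridSpec(1, 3, 0.1)), _range_all(GridSpec(1, 3, 0.1))
        )
        assert surf.raw_values[0, 1] == pytest.approx(4 * surf.raw_values[0, 2])

    def test_constant_climate_rejected(self):
        vals = np.full((2, 8, 8), 0.7)
        model = _model(2, m=[0.0, 0.0])
        with pytest.raises(ValueError, match="constant surface"):
            sensitivity_surface(model, _std(vals), _range_all(GridSpec(8, 8, 0.1)))


class TestExposureSurface:
    def test_identical_future_is_all_zero(self):
        rng = np.random.default_rng(1)
        cur = _std(rng.standard_normal((2, 8, 8)))
        fut = _std(cur.values.copy())
        fut.label = "future"
        surf = exposure_surface(cur, fut, _range_all(cur.grid))
        assert np.all(surf.values[surf.in_range] == 0.0)

    def test_uniform_unit_shift_raw_score_is_one(self):
        rng = np.random.default_rng(2)
        cur = _std(rng.standard_normal((3, 8, 8)))
        fut = _std(cur.values + 1.0)
        assert np.allclose(exposure_score(cur, fut), 1.0)

    def test_north_half_shift_orders_surface(self):
        rng = np.random.default_rng(3)
        cur = _std(rng.standard_normal((2, 10, 10)))
        shift = np.zeros((2, 10, 10))
        shift[:, :5, :] = 1.0  # north rows shifted
        fut = _std(cur.values + shift)
        fut.label = "future"
        surf = exposure_surface(cur, fut, _range_all(cur.grid))
        assert surf.values[:5].min() >= surf.values[5:].max()


class TestVulnerabilitySurface:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        grid = GridSpec(10, 10, 0.1)
        cur = _std(rng.standard_normal((2, 10, 10)), grid)
        fut = _std(cur.values + rng.standard_normal((2, 10, 10)) * 0.3, grid)
        fut.label = "f"
        rng_est = _range_all(grid)
        model = _model(2, m=[0.5, 0.2], rho=[2.0, 1.0])
        sens = sensitivity_surface(model, cur, rng_est)
        expo = exposure_surface(cur, fut, rng_est)
        return sens, expo

    def test_zero_sensitivity_cell_stays_zero(self):
        sens, expo = self._pair()
        vuln = vulnerability_surface(sens, expo)
        i = np.unravel_index(np.nanargmin(sens.values), sens.values.shape)
        assert sens.values[i] == 0.0
        assert vuln.raw_values[i] == 0.0

    def test_monotone_in_exposure(self):
        sens, expo = self._pair(seed=4)
        raw1 = np.sqrt(sens.values * (1 + expo.values))
        bump = expo.values.copy()
        j = (3, 3)
        bump[j] = min(1.0, bump[j] + 0.5)
        raw2 = np.sqrt(sens.values * (1 + bump))
        assert raw2[j] >= raw1[j]

    def test_uniform_random_surface_splits_into_thirds(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(100, 100, 0.1)
        vals = rng.uniform(0, 1, grid.shape)
        classes = classify(vals, np.ones(grid.shape, bool))
        shares = [float((classes == k).mean()) * 100 for k in range(3)]
        assert all(abs(s - 100 / 3) < 3 for s in shares)


class TestClassify:
    def test_example_values(self):
        vals = np.array([[0.2, 0.5, 0.9]])
        classes = classify(vals, np.ones((1, 3), bool))
        assert classes.tolist() == [[0, 1, 2]]

    def test_boundary_assigned_upward(self):
        vals = np.array([[1 / 3, 2 / 3]])
        classes = classify(vals, np.ones((1, 2), bool))
        assert classes.tolist() == [[1, 2]]

    def test_shares_partition_to_100(self):
        rng = np.random.default_rng(6)
        grid = GridSpec(20, 20, 0.1)
        in_range = rng.random(grid.shape) > 0.4
        vals = np.full(grid.shape, np.nan)
        vals[in_range] = rng.uniform(0, 1, int(in_range.sum()))
        from cnva.surfaces import ClassifiedSurface

        surf = ClassifiedSurface(
            grid=grid,
            in_range=in_range,
            values=vals,
            classes=classify(vals, in_range),
            breaks=(1 / 3, 2 / 3),
            quantity="vulnerability",
        )
        assert sum(surf.class_shares().values()) == pytest.approx(100.0, abs=1e-9)

    def test_out_of_unit_interval_rejected(self):
        vals = np.array([[1.2]])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            classify(vals, np.ones((1, 1), bool))

    def test_bad_breaks_rejected(self):
        vals = np.array([[0.5]])
        with pytest.raises(ValueError, match="breaks"):
            classify(vals, np.ones((1, 1), bool), breaks=(0.8, 0.2))
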