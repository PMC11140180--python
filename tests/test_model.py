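"""Forward model evaluation and constrained inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import placentamri as pm
from placentamri.model import (
    DEFAULT_GRID,
    DecideSignalModel,
    FixedCompartmentConstants,
    ModelDomainError,
    PlacentomeModelParams,
    _grid_design,
    t2_to_so2,
)
from placentamri.oximetry import OximetryCalibration
from placentamri.synthetic import NoiseSpec, block_phantom, simulate_placentome

from conftest import draw_feasible_params


class TestForwardSignal:
    def test_normalization_at_origin_is_exact(self, rng):
        for _ in range(200):
            p = draw_feasible_params(rng)
            assert pm.forward_signal(p, b=0.0, te=0.0) == p.s0

    def test_single_compartment_collapse(self):
        # f, v -> 0 leaves only the tissue term S0 exp(-b d) exp(-TE/T2ts)
        p = PlacentomeModelParams(
            f=1e-12, d=1.5e-3, d_star=0.03, t2fb=60.0, v=1e-12, s0=1.0
        )
        got = pm.forward_signal(p, b=400.0, te=84.0)
        assert got == pytest.approx(math.exp(-0.6) * math.exp(-2.0), rel=1e-9)

    def test_three_compartment_sum_matches_scalar_arithmetic(self):
        # independent term-by-term evaluation of the compartment sum
        p = PlacentomeModelParams(
            f=0.3, d=1.5e-3, d_star=0.03, t2fb=60.0, v=0.2, s0=1.0
        )
        b, te = 200.0, 96.0
        expected = (
            0.3 * math.exp(-b * 0.03) * math.exp(-te / 60.0)
            + 0.2 * math.exp(-te / 150.0)
            + 0.5 * math.exp(-b * 1.5e-3) * math.exp(-te / 42.0)
        )
        got = pm.forward_signal(p, b=b, te=te)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.143, abs=5e-4)

    def test_strictly_decreasing_in_b_and_te(self, rng):
        for _ in range(50):
            p = draw_feasible_params(rng)
            b = np.linspace(0, 800, 9)
            s_b = pm.forward_signal(p, b=b, te=80.0)
            assert np.all(np.diff(s_b) < 0)
            te = np.linspace(10, 250, 9)
            s_te = pm.forward_signal(p, b=100.0, te=te)
            assert np.all(np.diff(s_te) < 0)
            assert np.all(s_b > 0) and np.all(s_b <= p.s0)

    @pytest.mark.parametrize(
        "bad, name",
        [
            (dict(f=1.2), "f"),
            (dict(v=-0.1), "v"),
            (dict(d=1.5), "d"),
            (dict(d_star=0.0), "d_star"),
            (dict(t2fb=150.0), "t2fb"),
            (dict(s0=-1.0), "s0"),
            (dict(f=0.6, v=0.6), "f + v"),
        ],
    )
    def test_domain_errors_name_the_parameter(self, bad, name):
        kwargs = dict(f=0.25, d=1.5e-3, d_star=0.03, t2fb=60.0, v=0.25, s0=1.0)
        kwargs.update(bad)
        with pytest.raises(ModelDomainError, match=name.replace("+", r"\+")):
            PlacentomeModelParams(**kwargs)


def _noiseless_series(params, grid=DEFAULT_GRID, shape=(2, 2, 1)):
    maps, mask = block_phantom(shape, [(np.s_[:, :, :], params)])
    series, _ = simulate_placentome(maps, mask, grid, NoiseSpec(model="none"))
    return series


class TestRoiFit:
    def test_noiseless_recovery(self, typical_params):
        fit = pm.fit_roi_average(_noiseless_series(typical_params))
        assert fit.converged
        for n in ("f", "d", "d_star", "t2fb", "v", "s0"):
            assert getattr(fit.params, n) == pytest.approx(
                getattr(typical_params, n), rel=1e-3
            )

    def test_flat_curve_flagged_degenerate(self):
        grid = DEFAULT_GRID
        signal = np.full((2, 2, 1, len(grid)), 50.0)
        series = pm.PlacentomeSeries(
            signal=signal, mask=np.ones((2, 2, 1), bool), grid=grid
        )
        fit = pm.fit_roi_average(series)
        assert fit.degenerate and not fit.converged

    def test_multistart_agreement_on_noiseless_data(self, typical_params):
        series = _noiseless_series(typical_params)
        far_init = PlacentomeModelParams(
            f=0.5, d=5e-3, d_star=0.1, t2fb=40.0, v=0.3, s0=50.0
        )
        a = pm.fit_roi_average(series)
        b = pm.fit_roi_average(series, init=far_init)
        for n in ("f", "d", "d_star", "t2fb", "v", "s0"):
            assert getattr(a.params, n) == pytest.approx(
                getattr(b.params, n), rel=1e-3
            )

    def test_non_identifiable_grid_raises(self, typical_params):
        grid = pm.AcquisitionGrid.from_product((0.0, 100.0, 400.0), (80.0,))
        maps, mask = block_phantom((1, 1, 1), [(np.s_[:, :, :], typical_params)])
        series, _ = simulate_placentome(
            maps, mask, grid, NoiseSpec(model="none")
        )
        with pytest.raises(ValueError, match="non-identifiable"):
            pm.fit_roi_average(series)

    def test_objective_at_solution_beats_truth(self, typical_params, rng):
        # on a small grid the constrained optimum is at least as good as
        # the generating parameters, for clean and noisy curves alike
        grid = pm.AcquisitionGrid.from_product(
            (0.0, 200.0, 600.0), (72.0, 120.0, 192.0)
        )
        X = _grid_design(grid)
        clean = pm.forward_signal(typical_params, b=X[:, 0], te=X[:, 1])
        for noisy in (False, True):
            y = clean.copy()
            if noisy:
                sigma = typical_params.s0 / 50
                y = np.hypot(
                    y + rng.normal(0, sigma, y.shape),
                    rng.normal(0, sigma, y.shape),
                )
            est = DecideSignalModel(init=typical_params).fit(X, y)
            cost_sol = est.residual_norm_**2
            cost_truth = float(np.sum((clean - y) ** 2))
            assert cost_sol <= cost_truth + 1e-8


class TestVoxelwiseFit:
    def test_two_block_phantom_recovery(self, typical_params):
        other = PlacentomeModelParams(
            f=0.35, d=1.2e-3, d_star=0.05, t2fb=80.0, v=0.15, s0=120.0
        )
        maps, mask = block_phantom(
            (4, 4, 1),
            [(np.s_[:2, :, :], typical_params), (np.s_[2:, :, :], other)],
        )
        series, _ = simulate_placentome(maps, mask, noise=NoiseSpec(model="none"))
        out = pm.fit_voxelwise(series)
        for n in ("f", "d", "d_star", "t2fb", "v", "s0"):
            np.testing.assert_allclose(out[n][mask], maps[n][mask], rtol=5e-3)
        assert out.converged[mask].all()
        assert np.isnan(out["f"][~mask]).all()
        assert not out.fitted[~mask].any()

    def test_empty_mask_raises(self, typical_params):
        series = _noiseless_series(typical_params)
        series.mask[:] = False
        with pytest.raises(ValueError, match="empty mask"):
            pm.fit_voxelwise(series)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(data=st.data())
def test_constraint_safety_on_adversarial_curves(data):
    """No returned parameter ever leaves its box, whatever the input curve."""
    n = len(DEFAULT_GRID)
    y = np.array(
        data.draw(
            st.lists(
                st.floats(min_value=1e-3, max_value=1e3),
                min_size=n, max_size=n,
            )
        )
    )
    est = DecideSignalModel(max_iter=60).fit(_grid_design(DEFAULT_GRID), y)
    p = est.params_
    assert 0 < p.f < 1 and 0 < p.v < 1 and p.f + p.v < 1
    assert 0 < p.d < 1 and 0 < p.d_star < 1
    assert 0 < p.t2fb < 150 and p.s0 > 0


class TestT2ToSO2:
    CAL = OximetryCalibration(a=5.0, b=40.0)

    def test_fully_oxygenated_limit(self):
        y, clamped = t2_to_so2(1000.0 / self.CAL.a, self.CAL)
        assert y == pytest.approx(1.0, abs=1e-12) and not clamped

    def test_round_trip(self):
        for y_true in (0.05, 0.3, 0.62, 0.9, 1.0):
            t2 = self.CAL.t2_from_so2(y_true)
            y, _ = t2_to_so2(t2, self.CAL)
            assert y == pytest.approx(y_true, abs=1e-10)

    def test_hand_inversion(self):
        # A + B (1-Y)^2 = 15 with A=5, B=40  =>  Y = 1 - sqrt(10/40) = 0.5
        y, _ = t2_to_so2(1000.0 / 15.0, self.CAL)
        assert y == pytest.approx(0.5, abs=1e-12)

    def test_t2_above_calibration_limit(self):
        with pytest.raises(ValueError, match="fully-oxygenated"):
            t2_to_so2(500.0, self.CAL)
        y, clamped = t2_to_so2(500.0, self.CAL, saturate=True)
        assert y == 1.0 and clamped

    def test_monotone_in_t2(self):
        t2s = np.linspace(25.0, 199.0, 40)
        ys = [t2_to_so2(t, self.CAL)[0] for t in t2s]
        assert np.all(np.diff(ys) > 0)
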