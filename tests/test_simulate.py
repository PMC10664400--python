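"""Integration, forward sensitivities and the synthetic-data generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import odeident as oi


class TestSimulate:
    def test_twocomp_matches_closed_form(self, twocomp):
        t = np.linspace(0.0, 5.0, 25)
        c, p1, p2 = 4.0, 0.7, 0.3
        tr = oi.simulate(twocomp, {"p1": p1, "p2": p2, "x1(0)": c}, t)
        exact_x1 = c * np.exp(-p1 * t)
        exact_x2 = c * p1 / (p2 - p1) * (np.exp(-p1 * t) - np.exp(-p2 * t))
        assert np.allclose(tr.state("x1"), exact_x1, rtol=1e-6)
        assert np.allclose(tr.state("x2"), exact_x2, rtol=1e-6, atol=1e-9)
        # outputs are g applied to the states row-wise
        assert np.array_equal(tr.output("y"), tr.state("x2"))

    def test_betacasein_reduction_is_trajectory_equivalent(
            self, betacasein, betacasein_reduced, betacasein_truth):
        """Algebraic oracle: with I = x0-x the original rate equals
        -b1*E*x/(b2-x) under b1=k*kI/(Km-kI), b2=Km*(kI+x0)/(Km-kI)."""
        k, Km, kI = (betacasein_truth[n] for n in ("k", "Km", "kI"))
        x0 = betacasein.constants["x0"]
        b1 = k * kI / (Km - kI)
        b2 = Km * (kI + x0) / (Km - kI)
        t = np.linspace(0.0, 30.0, 40)
        xa = oi.simulate(betacasein, betacasein_truth, t).output("y")
        xb = oi.simulate(betacasein_reduced, {"b1": b1, "b2": b2}, t).output("y")
        assert np.max(np.abs(xa - xb) / np.abs(xa)) < 1e-8

    def test_monod_washout_manifold(self, monod_haldane):
        """x1(0)=0 is invariant: no biomass can ever appear."""
        t = np.linspace(0.0, 50.0, 30)
        import dataclasses
        states = tuple(
            dataclasses.replace(s, ic_value=0.0) if s.name == "x1" else s
            for s in monod_haldane.states
        )
        model = dataclasses.replace(monod_haldane, states=states)
        tr = oi.simulate(model, {"k": 2.0, "kI": 50.0}, t, oi.ConstantInput(20.0))
        assert np.max(np.abs(tr.state("x1"))) < 1e-10

    def test_self_convergence_under_tolerance_halving(self, monod_haldane):
        t = np.linspace(0.0, 50.0, 30)
        theta = {"k": 2.0, "kI": 50.0}
        u = oi.ConstantInput(20.0)
        a = oi.simulate(monod_haldane, theta, t, u, rtol=1e-6, atol=1e-8)
        b = oi.simulate(monod_haldane, theta, t, u, rtol=5e-7, atol=5e-9)
        scale = np.max(np.abs(a.state_values), axis=0)
        assert np.max(np.abs(a.state_values - b.state_values) / scale) < 10 * 1e-6

    def test_integrator_input_validation(self, twocomp):
        with pytest.raises(ValueError):
            oi.simulate(twocomp, {"p1": 1.0}, np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            oi.simulate(twocomp, {"p1": 1, "p2": 1, "x1(0)": 1}, [1.0, 0.5])


class TestSensitivities:
    def test_matches_central_finite_differences(self, monod_haldane):
        t = np.linspace(0.0, 50.0, 25)
        theta = {"k": 2.0, "kI": 50.0}
        u = oi.ConstantInput(20.0)
        sb = oi.sensitivities(monod_haldane, theta, t, u)
        for j, (name, val) in enumerate([("k", 2.0), ("kI", 50.0)]):
            h = 1e-5 * val
            up = dict(theta); up[name] = val + h
            dn = dict(theta); dn[name] = val - h
            fd = (oi.simulate(monod_haldane, up, t, u).output_values
                  - oi.simulate(monod_haldane, dn, t, u).output_values) / (2 * h)
            an = sb.output_sens[:, :, j]
            assert np.max(np.abs(fd - an)) / np.max(np.abs(an)) < 1e-4

    def test_unmeasured_yield_has_zero_sensitivity(self, methanogenesis):
        """YCH4 enters only the CH4 balance, so xH2 and ng_H2 cannot
        respond to it at all."""
        sb = oi.sensitivities(
            methanogenesis, methanogenesis.metadata["nominal_theta"],
            np.linspace(0.0, 30.0, 15),
        )
        for out in ("xH2", "ng_H2"):
            assert np.max(np.abs(sb.output_sensitivity(out, "YCH4"))) == 0.0

    def test_initial_sensitivity_block_structure(self, twocomp):
        sb = oi.sensitivities(
            twocomp, {"p1": 0.7, "p2": 0.3, "x1(0)": 4.0},
            np.linspace(0.0, 2.0, 5),
        )
        S0 = sb.state_sens[0]
        expected = np.zeros((2, 3))
        expected[0, 2] = 1.0  # d x1(0) / d x1(0)
        assert np.array_equal(S0, expected)


class TestSyntheticData:
    def test_zero_noise_equals_simulation(self, monod_haldane, monod_truth,
                                          monod_grid, monod_input):
        df = oi.generate_synthetic_data(
            monod_haldane, monod_truth, monod_grid, monod_input,
            sigma=0.0, seed=42)
        tr = oi.simulate(monod_haldane, monod_truth, monod_grid, monod_input)
        assert np.array_equal(df["y1"].to_numpy(), tr.output("y1"))
        assert np.array_equal(df["y2"].to_numpy(), tr.output("y2"))

    def test_same_seed_same_table(self, twocomp):
        t = np.linspace(0.0, 5.0, 10)
        theta = {"p1": 0.7, "p2": 0.3, "x1(0)": 4.0}
        a = oi.generate_synthetic_data(twocomp, theta, t, sigma=0.1, seed=7)
        b = oi.generate_synthetic_data(twocomp, theta, t, sigma=0.1, seed=7)
        assert a.equals(b)
        c = oi.generate_synthetic_data(twocomp, theta, t, sigma=0.1, seed=8)
        assert not a.equals(c)

    def test_noise_sd_calibration(self, monod_haldane, monod_truth,
                                  monod_grid, monod_input):
        """Monte-Carlo check of the additive noise model across 200
        replicate seeds: the sample SD of y1 at each time point is
        consistent with the nominal sigma = 0.05.  At 200 replicates a
        per-time sample SD has ~5% relative SE, so the typical point must
        sit within 15% and the worst of the 40 points within a wider
        multiplicity-adjusted band."""
        sims = np.stack([
            oi.generate_synthetic_data(
                monod_haldane, monod_truth, monod_grid, monod_input,
                sigma=0.05, seed=s)["y1"].to_numpy()
            for s in range(200)
        ])
        sd = sims.std(axis=0, ddof=1)
        rel = np.abs(sd - 0.05) / 0.05
        assert np.abs(sd.mean() - 0.05) / 0.05 < 0.15
        assert np.mean(rel < 0.15) >= 0.95
        assert np.all(rel < 0.25)


@given(st.floats(min_value=0.0, max_value=10.0))
@settings(max_examples=25, deadline=None)
def test_piecewise_linear_input_stays_in_node_hull(t):
    sig = oi.PiecewiseLinearInput((0.0, 2.0, 5.0, 10.0), (1.0, 4.0, 0.5, 2.0))
    v = sig(t)
    assert 0.5 - 1e-12 <= v <= 4.0 + 1e-12


def test_piecewise_linear_input_validation():
    with pytest.raises(ValueError):
        oi.PiecewiseLinearInput((0.0, 0.0), (1.0, 2.0))
    with pytest.raises(ValueError):
        oi.PiecewiseLinearInput((0.0, 1.0), (1.0,))
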