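"""FIM reports, multistart least squares and profile likelihood."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import odeident as oi
from odeident.practical import fim_from_output_sens

BETACASEIN_BOUNDS = {"k": (0.1, 10.0), "Km": (0.1, 50.0), "kI": (0.1, 15.0)}
MONOD_BOUNDS = {"k": (0.1, 20.0), "kI": (5.0, 500.0)}


def _linear_output_model():
    """dx/dt = p with x(0)=0, y=x, so y(t) = p*t and S_y(t) = t."""
    return oi.parse_model(json.dumps({
        "name": "linear_rate",
        "states": [{"name": "x", "ic": {"known": True, "value": 0.0}}],
        "parameters": [{"name": "p", "known": False}],
        "inputs": [],
        "constants": {},
        "odes": {"x": "p"},
        "outputs": {"y": "x"},
    }))


class TestFim:
    def test_scalar_closed_form(self):
        """y = p*t at sigma=1: FIM must equal sum of t_k^2."""
        model = _linear_output_model()
        times = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
        rep = oi.compute_fim(model, {"p": 1.3}, oi.Design(times=times, sigma=1.0))
        assert rep.fim.shape == (1, 1)
        assert rep.fim[0, 0] == pytest.approx(np.sum(times ** 2), rel=1e-6)
        assert not rep.singular

    def test_fim_is_symmetric_psd_with_unit_correlation_diagonal(
            self, monod_haldane, monod_grid, monod_input, monod_truth):
        rep = oi.compute_fim(
            monod_haldane, monod_truth,
            oi.Design(times=monod_grid, sigma=0.05, input_signal=monod_input))
        assert np.array_equal(rep.fim, rep.fim.T)
        assert np.all(np.linalg.eigvalsh(rep.fim) > -1e-9)
        assert np.allclose(np.diag(rep.correlations), 1.0)
        assert np.all(np.abs(rep.correlations) <= 1.0 + 1e-12)

    def test_structural_deficiency_gives_singular_fim(
            self, betacasein, betacasein_truth):
        """Noise-free design on the 3-parameter hydrolysis model: the FIM
        rank cannot exceed 2 because only (b1,b2) shape the output."""
        rep = oi.compute_fim(
            betacasein, betacasein_truth,
            oi.Design(times=np.linspace(0.0, 30.0, 20), sigma=0.05))
        assert rep.singular
        assert rep.rank <= 2
        assert rep.sds is None
        assert len(rep.null_directions) >= 1

    def test_information_grows_with_sampling_times(
            self, monod_haldane, monod_truth, monod_input):
        t_small = np.linspace(0.0, 50.0, 10)
        t_large = np.linspace(0.0, 50.0, 20)
        ld = [
            oi.compute_fim(monod_haldane, monod_truth,
                           oi.Design(times=t, sigma=0.05,
                                     input_signal=monod_input)).log_det
            for t in (t_small, t_large)
        ]
        assert ld[1] >= ld[0]

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            oi.Design(times=np.array([1.0]), sigma=0.0).sigma_for("y")


@given(st.floats(min_value=0.25, max_value=4.0))
@settings(max_examples=20, deadline=None)
def test_sigma_scaling_law(c):
    """Scaling every sigma by c multiplies det(FIM) by c^(-2 n): checked on
    a fixed random sensitivity stack."""
    rng = np.random.default_rng(0)
    S = rng.normal(size=(6, 2, 3))
    w = np.array([1.0 / 0.05 ** 2, 1.0 / 0.1 ** 2])
    base = np.linalg.slogdet(fim_from_output_sens(S, w))[1]
    scaled = np.linalg.slogdet(fim_from_output_sens(S, w / c ** 2))[1]
    assert scaled == pytest.approx(base - 2 * 3 * np.log(c), abs=1e-8)


class TestFit:
    def test_zero_noise_recovery(self, monod_haldane, monod_noisefree,
                                 monod_input):
        fit = oi.fit_least_squares(
            monod_haldane, monod_noisefree, MONOD_BOUNDS, sigma=0.05,
            n_starts=6, seed=2, input_signal=monod_input)
        assert fit.theta_hat["k"] == pytest.approx(2.0, rel=1e-3)
        assert fit.theta_hat["kI"] == pytest.approx(50.0, rel=1e-3)
        assert fit.rss < 1e-10
        assert fit.converged_fraction > 0.0

    def test_twocomp_noisefree_two_equal_rss_clusters(self, twocomp):
        """Perfect data, wrong basin: multistart termini must concentrate
        on exactly two (p1,p2,x1(0)) triples with equal (zero) RSS, the
        swapped-parameter ambiguity."""
        t = np.linspace(0.0, 8.0, 30)
        truth = {"p1": 0.9, "p2": 0.25, "x1(0)": 5.0}
        data = oi.generate_synthetic_data(twocomp, truth, t, sigma=0.0, seed=0)
        fit = oi.fit_least_squares(
            twocomp, data,
            {"p1": (0.01, 10.0), "p2": (0.01, 10.0), "x1": (0.1, 50.0)},
            n_starts=30, seed=5)
        clusters = oi.cluster_termini(fit.termini, rss_window=1e-6)
        assert len(clusters) == 2
        a, b = (c["theta"] for c in clusters)
        assert a[0] == pytest.approx(b[1], rel=1e-3)
        assert a[1] == pytest.approx(b[0], rel=1e-3)

    def test_rss_of_best_dominates_all_termini(self, monod_haldane,
                                               monod_noisefree, monod_input):
        fit = oi.fit_least_squares(
            monod_haldane, monod_noisefree, MONOD_BOUNDS, sigma=0.05,
            n_starts=4, seed=0, input_signal=monod_input,
            compute_fim_at_hat=False)
        assert all(fit.rss <= rss + 1e-12 for _, rss in fit.termini)


class TestProfileLikelihood:
    def test_monod_k_profile_has_finite_ci_containing_truth(
            self, monod_haldane, monod_truth, monod_grid, monod_input):
        data = oi.generate_synthetic_data(
            monod_haldane, monod_truth, monod_grid, monod_input,
            sigma=0.05, seed=3)
        fit = oi.fit_least_squares(
            monod_haldane, data, MONOD_BOUNDS, sigma=0.05, n_starts=4,
            seed=2, input_signal=monod_input, compute_fim_at_hat=False)
        prof = oi.profile_likelihood(
            monod_haldane, data, "k", np.linspace(1.6, 2.5, 19), sigma=0.05,
            theta_bounds=MONOD_BOUNDS, fit=fit, input_signal=monod_input)
        assert not prof.flat
        assert not prof.unbounded_low and not prof.unbounded_high
        lo, hi = prof.ci
        assert lo <= 2.0 <= hi

    def test_betacasein_profile_is_flat(self, betacasein, betacasein_noisefree):
        """Structural non-identifiability: along the locally compensable
        (Km,kI) direction the objective stays at zero while k moves."""
        fit = oi.fit_least_squares(
            betacasein, betacasein_noisefree, BETACASEIN_BOUNDS, sigma=0.05,
            n_starts=4, seed=9)
        prof = oi.profile_likelihood(
            betacasein, betacasein_noisefree, "k", np.linspace(0.9, 1.3, 9),
            sigma=0.05, theta_bounds=BETACASEIN_BOUNDS, fit=fit)
        assert prof.flat

    def test_infinite_threshold_covers_whole_grid(self, monod_haldane,
                                                  monod_noisefree, monod_input):
        fit = oi.fit_least_squares(
            monod_haldane, monod_noisefree, MONOD_BOUNDS, sigma=0.05,
            n_starts=2, seed=2, input_signal=monod_input,
            compute_fim_at_hat=False)
        grid = np.linspace(1.5, 2.5, 7)
        prof = oi.profile_likelihood(
            monod_haldane, monod_noisefree, "k", grid, sigma=0.05,
            theta_bounds=MONOD_BOUNDS, fit=fit, threshold=np.inf,
            input_signal=monod_input)
        assert prof.ci == (grid[0], grid[-1])
        assert prof.unbounded_low and prof.unbounded_high


def test_cluster_termini_merges_duplicates():
    x = np.array([1.0, 2.0])
    termini = [(x, 0.1), (x * (1 + 1e-5), 0.1), (x * 2, 0.1)]
    clusters = oi.cluster_termini(termini)
    assert len(clusters) == 2
    assert clusters[0]["size"] == 2
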