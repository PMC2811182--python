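import numpy as np
import pytest

from knockpert import ode
from knockpert.io import PerturbationDataset, Trajectory

from conftest import make_timeseries


def linear_params(alpha=0.0, lam=1.0, beta=(0.0,)):
    return ode.OdeParams.make("linear", alpha=alpha, lam=lam, beta=list(beta))


def sigmoid_params(m=1.0, lam=1.0, b=0.0, beta=(0.0,)):
    return ode.OdeParams.make("sigmoidal", m=m, lam=lam, b=b, beta=list(beta))


class TestRate:
    def test_pure_decay(self):
        spec = ode.OdeModelSpec("linear", 0, (1,))
        assert ode.rate(spec, linear_params(), [1.0, 0.5]) == -1.0

    def test_sigmoid_saturated_off(self):
        spec = ode.OdeModelSpec("sigmoidal", 0, (1,))
        p = sigmoid_params(m=2.0, lam=0.7, b=-1e6, beta=(0.3,))
        assert ode.rate(spec, p, [1.0, 0.5]) == pytest.approx(-0.7, abs=1e-12)

    def test_sigmoid_half_max(self):
        spec = ode.OdeModelSpec("sigmoidal", 0, (1,))
        p = sigmoid_params(m=2.0, lam=0.0, b=0.0, beta=(0.0,))
        assert ode.rate(spec, p, [1.0, 5.0]) == pytest.approx(1.0)


class TestPredictNext:
    def test_pure_decay_heun(self):
        # closed-form Heun update x(1 - lam*h + lam^2 h^2 / 2)
        spec = ode.OdeModelSpec("linear", 0, (1,))
        got = ode.predict_next(spec, linear_params(lam=1.0), [1.0, 0.0], 0.1)
        assert got == pytest.approx(0.905, abs=1e-12)

    def test_constant_rate(self):
        spec = ode.OdeModelSpec("linear", 0, (1,))
        got = ode.predict_next(spec, linear_params(alpha=0.5, lam=0.0), [1.0, 0.0], 0.1)
        assert got == pytest.approx(1.05, abs=1e-12)

    def test_small_dt_limit(self):
        spec = ode.OdeModelSpec("linear", 0, (1,))
        p = linear_params(alpha=0.3, lam=0.8, beta=(0.4,))
        for dt in (1e-4, 1e-6):
            assert ode.predict_next(spec, p, [1.0, 0.7], dt) == pytest.approx(
                1.0, abs=10 * dt
            )

    def test_heun_third_order_local_error(self):
        # |predicted - e^{-lam dt} x| should shrink ~8x as dt halves
        spec = ode.OdeModelSpec("linear", 0, (1,))
        p = linear_params(lam=1.3)
        errs = []
        for dt in (0.2, 0.1, 0.05, 0.025):
            pred = ode.predict_next(spec, p, [1.0, 0.0], dt)
            errs.append(abs(pred - np.exp(-1.3 * dt)))
        ratios = [a / b for a, b in zip(errs, errs[1:])]
        assert all(r > 6.5 for r in ratios)


def simulate_with_stepper(spec, params, reg_paths, x0, times):
    """Trajectory whose target column is generated by the package's own
    one-step predictions (self-consistency oracle)."""
    n = reg_paths.shape[1]
    vals = np.empty((len(times), n))
    vals[0] = x0
    for l in range(1, len(times)):
        vals[l] = reg_paths[l]
        vals[l, spec.target] = ode.predict_next(
            spec, params, vals[l - 1], times[l] - times[l - 1]
        )
    return vals


def make_self_consistent_data(spec, params, seed=0, n_series=3, T=21, n=None):
    rng = np.random.default_rng(seed)
    if n is None:
        n = max([spec.target, *spec.regulators]) + 1
    times = np.linspace(0, 5, T)
    series = []
    for _ in range(n_series):
        paths = np.empty((T, n))
        base = rng.uniform(0.2, 1.5, n)
        amp = rng.uniform(-0.4, 0.4, n)
        freq = rng.uniform(0.3, 1.0, n)
        for g in range(n):
            paths[:, g] = np.maximum(base[g] + amp[g] * np.sin(freq[g] * times), 0.01)
        vals = simulate_with_stepper(spec, params, paths, paths[0], times)
        series.append(Trajectory(times, vals))
    return PerturbationDataset([f"G{i + 1}" for i in range(n)], series)


class TestObjective:
    def test_self_consistency_zero(self):
        spec = ode.OdeModelSpec("linear", 0, (1,))
        p = linear_params(alpha=0.2, lam=0.9, beta=(0.8,))
        data = make_self_consistent_data(spec, p)
        assert ode.objective(spec, p, data) == pytest.approx(0.0, abs=1e-20)

    def test_expected_value_under_noise(self):
        # adding iid N(0, sd^2) to the D predicted points makes E[S] ~ D sd^2;
        # two-point trajectories keep the noise off the prediction seeds
        spec = ode.OdeModelSpec("linear", 0, (1,))
        p = linear_params(alpha=0.2, lam=0.9, beta=(0.8,))
        data = make_self_consistent_data(spec, p, n_series=50, T=2)
        D = sum(len(t.times) - 1 for t in data.series)
        sd = 0.05
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            noisy = PerturbationDataset(
                data.gene_labels,
                [
                    Trajectory(
                        t.times,
                        np.vstack(
                            [
                                t.values[0],
                                t.values[1]
                                + np.concatenate(
                                    [[rng.normal(0, sd)], np.zeros(t.values.shape[1] - 1)]
                                ),
                            ]
                        ),
                    )
                    for t in data.series
                ],
            )
            vals.append(ode.objective(spec, p, noisy))
        assert np.mean(vals) == pytest.approx(D * sd**2, rel=0.1)

    def test_trajectory_order_invariance(self):
        spec = ode.OdeModelSpec("sigmoidal", 0, (1, 2))
        p = sigmoid_params(m=1.2, lam=0.6, b=0.1, beta=(0.5, -0.3))
        data = make_timeseries(3, n_series=3, seed=4)
        rev = PerturbationDataset(data.gene_labels, list(reversed(data.series)))
        assert ode.objective(spec, p, data) == pytest.approx(
            ode.objective(spec, p, rev), rel=1e-14
        )

    def test_too_short_trajectories_error(self):
        data = PerturbationDataset(
            ["G1", "G2"], [Trajectory([0.0], [[1.0, 1.0]])]
        )
        spec = ode.OdeModelSpec("linear", 0, (1,))
        with pytest.raises(ValueError, match="two or more"):
            ode.objective(spec, linear_params(), data)


@pytest.mark.parametrize("model_type", ["linear", "sigmoidal"])
def test_gradient_hessian_match_finite_differences(model_type):
    """Analytic gradient/Hessian of S agree with central finite differences
    to relative error < 1e-5 on random instances."""
    data = make_timeseries(5, seed=1)
    steps = ode.step_arrays(data)
    rng = np.random.default_rng(42)
    for _ in range(5):
        spec = ode.OdeModelSpec(model_type, 0, (1, 2))
        theta = rng.uniform(-0.8, 0.8, spec.n_params)
        theta[0] = abs(theta[0]) + 0.2
        theta[1] = abs(theta[1])
        S, g, H = ode._sgh(spec, theta, steps, True)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            g_fd = (ode._sgh(spec, tp, steps, False)[0] - ode._sgh(spec, tm, steps, False)[0]) / (2 * eps)
            assert g[i] == pytest.approx(g_fd, rel=1e-5, abs=1e-7)
            H_fd = (ode._sgh(spec, tp, steps, True)[1] - ode._sgh(spec, tm, steps, True)[1]) / (2 * eps)
            np.testing.assert_allclose(H[:, i], H_fd, rtol=1e-5, atol=1e-6)


class TestFit:
    def test_noiseless_recovery(self):
        spec = ode.OdeModelSpec("linear", 0, (1,))
        truth = linear_params(alpha=0.2, lam=0.9, beta=(0.8,))
        data = make_self_consistent_data(spec, truth, seed=2)
        f = ode.fit(spec, data, n_restarts=20, seed=0)
        assert f.objective < 1e-8
        assert f.params.beta[0] == pytest.approx(0.8, abs=1e-3)

    def test_wrong_regulator_fits_worse(self):
        spec = ode.OdeModelSpec("linear", 0, (1,))
        truth = linear_params(alpha=0.2, lam=0.9, beta=(0.8,))
        data = make_self_consistent_data(spec, truth, seed=2, n=3)
        f_true = ode.fit(spec, data, n_restarts=20, seed=0)
        f_wrong = ode.fit(ode.OdeModelSpec("linear", 0, (2,)), data, n_restarts=20, seed=0)
        assert f_wrong.objective > 10 * max(f_true.objective, 1e-12)

    def test_more_restarts_never_worse(self):
        data = make_timeseries(4, seed=9)
        spec = ode.OdeModelSpec("sigmoidal", 0, (1, 2, 3))
        s1 = ode.fit(spec, data, n_restarts=1, seed=5).objective
        s100 = ode.fit(spec, data, n_restarts=100, seed=5).objective
        assert s100 <= s1


class TestScans:
    def test_single_scan_count_and_determinism(self):
        data = make_timeseries(4, seed=3)
        fits = ode.scan_single(data, "linear", seed=1, n_restarts=3)
        assert len(fits) == 12
        again = ode.scan_single(data, "linear", seed=1, n_restarts=3)
        assert all(fits[k].objective == again[k].objective for k in fits)

    def test_planted_single_regulator_network(self):
        # each target generated from one true regulator; that regulator's
        # fit must win among the candidates
        rng = np.random.default_rng(0)
        n = 4
        times = np.linspace(0, 5, 21)
        paths = np.empty((21, n))
        for g in range(n):
            paths[:, g] = 1.0 + rng.uniform(-0.5, 0.5) * np.sin(
                rng.uniform(0.3, 1.2) * times + rng.uniform(0, 3)
            )
        truth = {1: 0, 2: 1, 3: 2}  # target -> regulator
        vals = paths.copy()
        specs = {}
        for tgt, reg in truth.items():
            spec = ode.OdeModelSpec("linear", tgt, (reg,))
            p = linear_params(alpha=0.1, lam=0.8, beta=(0.9,))
            for l in range(1, 21):
                vals[l, tgt] = ode.predict_next(
                    spec, p, vals[l - 1], times[l] - times[l - 1]
                )
            specs[tgt] = spec
        data = PerturbationDataset(
            [f"G{i + 1}" for i in range(n)], [Trajectory(times, vals)]
        )
        fits = ode.scan_single(data, "linear", seed=0, n_restarts=10)
        for tgt, reg in truth.items():
            scores = {k: fits[(k, tgt)].objective for k in range(n) if k != tgt}
            assert min(scores, key=scores.get) == reg

    def test_guided_with_empty_base_reduces_to_single(self):
        data = make_timeseries(4, seed=6)
        single = ode.scan_single(data, "linear", seed=2, n_restarts=3)
        guided = ode.scan_guided(data, "linear", {}, seed=2, n_restarts=3)
        assert set(single) == set(guided)
        for k in single:
            assert single[k].objective == guided[k].objective

    def test_guided_skips_base_candidates(self):
        data = make_timeseries(4, seed=6)
        guided = ode.scan_guided(data, "linear", {0: {1}}, seed=2, n_restarts=2)
        assert (1, 0) not in guided
        assert all(1 in f.spec.regulators for (k, j), f in guided.items() if j == 0)

    def test_guided_finds_second_or_input(self):
        # OR-gate target: one activator already known, the other must win
        from knockpert import simulate

        n = 4
        weights = np.zeros((n, n))
        weights[0, 2] = 3.0
        weights[1, 2] = 3.0
        net = simulate.GeneNetwork(
            n=n,
            weights=weights,
            m=np.full(n, 1.0),
            lam=np.full(n, 1.0),
            bias=np.array([0.0, 0.0, -1.5, 0.0]),
            gate=["SUM", "SUM", "OR", "SUM"],
        )
        data = simulate.simulate_perturbations(net, n_series=6, noise_sd=0.0, seed=3)
        guided = ode.scan_guided(data, "sigmoidal", {2: {0}}, seed=0, n_restarts=10)
        scores = {k: guided[(k, 2)].objective for k in (1, 3)}
        assert scores[1] < scores[3]


class TestFlagSignificant:
    def _fits(self, svals, target=0, model_type="linear"):
        out = {}
        for k, s in enumerate(svals, start=1):
            spec = ode.OdeModelSpec(model_type, target, (k,))
            out[(k, target)] = ode.OdeFit(
                spec, linear_params(beta=(0.0,)), float(s), 1, True
            )
        return out

    @pytest.mark.parametrize("svals", [(10, 10, 10, 10, 1), (100, 100, 100, 100, 1)])
    def test_two_sd_rule_can_flag_nothing(self, svals):
        # hand arithmetic: mean 8.2 sd 4.02 -> cut 0.16; mean 80.2 sd 44.3
        # -> cut negative; the outlier is not 2 SDs below in either case
        assert ode.flag_significant(self._fits(svals)) == set()

    def test_all_equal_flags_nothing(self):
        assert ode.flag_significant(self._fits((5, 5, 5, 5))) == set()

    def test_agrees_with_direct_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            svals = rng.uniform(0, 100, size=rng.integers(3, 12))
            flagged = ode.flag_significant(self._fits(svals))
            mu, sd = svals.mean(), svals.std(ddof=1)
            expected = {
                (k + 1, 0) for k, s in enumerate(svals) if s < mu - 2 * sd
            }
            assert flagged == expected

    def test_fewer_than_three_candidates_flags_nothing(self):
        assert ode.flag_significant(self._fits((1, 100))) == set()
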