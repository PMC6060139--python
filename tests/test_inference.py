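"""Inference machinery: distance and NRMSE summaries, priors,
populations, posterior diagnostics, and small end-to-end ABC-SMC
properties (the expensive recovery and selection experiments live in
the acceptance suite)."""

import math

import numpy as np
import pytest

import angiosched as ang
from angiosched.datasets import ArmDataset
from angiosched.inference import (ABCConfig, Population, PriorSpec, abc_smc,
                                  best_fit, distance, nrmse, posterior_shift,
                                  sensitivities, SHARED_NAMES)
from angiosched.simulate import Trajectory


def traj(times, v):
    times = np.asarray(times, float)
    v = np.asarray(v, float)
    z = np.zeros_like(times)
    return Trajectory(times, v, z, z, z)


def arm(name, times, volumes):
    return ArmDataset(name, times, volumes)


class TestDistance:
    def test_exact_match(self):
        a = arm("vehicle", [0, 1, 2], [5.0, 6.0, 7.0])
        sim = {"vehicle": traj([0, 1, 2], [5.0, 6.0, 7.0])}
        assert distance(sim, [a]) == 0.0

    def test_single_point(self):
        a = arm("bvz", [3.0], [10.0])
        sim = {"bvz": traj([3.0], [12.0])}
        assert distance(sim, [a]) == pytest.approx(4.0)

    def test_three_arm_residuals(self):
        """Known injected residuals accumulate as a plain sum of
        squares across arms and times."""
        rng = np.random.default_rng(42)
        times = np.arange(5.0)
        arms, sims, expected = [], {}, 0.0
        for name in ("vehicle", "bvz", "folfox"):
            v = rng.uniform(50, 500, times.size)
            r = rng.normal(0, 10, times.size)
            arms.append(arm(name, times, v))
            sims[name] = traj(times, v + r)
            expected += sum(x * x for x in r)  # independent accumulation
        assert distance(sims, arms) == pytest.approx(expected, rel=1e-12)

    def test_time_mismatch(self):
        a = arm("vehicle", [0, 1], [1.0, 2.0])
        sim = {"vehicle": traj([0, 2], [1.0, 2.0])}
        with pytest.raises(ValueError):
            distance(sim, [a])

    def test_fit_anchor_skips_leading_zeros(self):
        """Leading zero volumes are excluded; the fit starts at the
        first non-zero measurement."""
        a = arm("vehicle", [0, 1, 2, 3], [0.0, 0.0, 5.0, 9.0])
        assert a.first_nonzero == 2
        assert a.v0 == 5.0
        assert a.k0 == 25.0
        sim = {"vehicle": traj([2, 3], [5.0, 9.0])}
        assert distance(sim, [a]) == 0.0


class TestNrmse:
    def test_exact_match(self):
        a = arm("vehicle", [0, 1], [4.0, 6.0])
        assert nrmse({"vehicle": traj([0, 1], [4.0, 6.0])}, [a]) == 0.0

    def test_constant_offset(self):
        """A constant offset delta on an arm with mean mu contributes
        delta / mu."""
        a = arm("bvz", [0, 1, 2], [10.0, 20.0, 30.0])
        sim = {"bvz": traj([0, 1, 2], [14.0, 24.0, 34.0])}
        assert nrmse(sim, [a]) == pytest.approx(4.0 / 20.0)

    def test_three_arm_fixture(self):
        """Hand-computed total over three arms."""
        arms = [arm("vehicle", [0, 1], [10.0, 30.0]),
                arm("bvz", [0, 1], [8.0, 12.0]),
                arm("folfox", [0, 1], [50.0, 50.0])]
        sims = {"vehicle": traj([0, 1], [13.0, 34.0]),
                "bvz": traj([0, 1], [8.0, 12.0]),
                "folfox": traj([0, 1], [40.0, 60.0])}
        expected = math.sqrt((9 + 16) / 2) / 20.0 + 0.0 \
            + math.sqrt((100 + 100) / 2) / 50.0
        assert nrmse(sims, arms) == pytest.approx(expected, rel=1e-12)


class TestPriorSpec:
    def test_default_ranges_and_support(self):
        pri = PriorSpec()
        rng = np.random.default_rng(0)
        for m in (0, 1):
            for _ in range(200):
                th = pri.sample(m, rng)
                assert pri.in_support(m, th)
                assert np.isfinite(pri.log_density(m, th))

    def test_outside_support(self):
        pri = PriorSpec()
        th = pri.sample(0, np.random.default_rng(1))
        th[0] = 99.0
        assert not pri.in_support(0, th)
        assert pri.log_density(0, th) == -np.inf

    def test_log_uniform_option(self):
        pri = PriorSpec(log_uniform=("d",))
        rng = np.random.default_rng(2)
        d_idx = SHARED_NAMES.index("d")
        xs = np.array([pri.sample(1, rng)[d_idx] for _ in range(3000)])
        # median of log-uniform on [1e-5, 1] is ~ 10^-2.5
        assert np.median(xs) == pytest.approx(10 ** -2.5, rel=0.3)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            PriorSpec(ranges={"lambda1": (0.5, 0.5)})


def make_population(rng, n=300, spread=1.0, shift=0.0, model=1):
    pri = PriorSpec()
    theta = np.stack([pri.sample(model, rng) for _ in range(n)])
    theta = theta * spread + shift
    w = rng.uniform(0.5, 1.5, n)
    return Population(np.full(n, model), theta, w / w.sum(),
                      rng.uniform(0, 1, n), 1.0, 0)


class TestPopulation:
    def test_weights_must_normalise(self):
        rng = np.random.default_rng(0)
        pop = make_population(rng)
        with pytest.raises(ValueError):
            Population(pop.m, pop.theta, pop.weights * 2, pop.distances,
                       1.0, 0)

    def test_best_fit(self):
        rng = np.random.default_rng(1)
        pop = make_population(rng)
        # trivial cases
        one = Population(pop.m[:1], pop.theta[:1], np.array([1.0]),
                         np.array([3.0]), 1.0, 0)
        assert best_fit(one).distance == 3.0
        three = Population(pop.m[:3], pop.theta[:3],
                           np.full(3, 1 / 3), np.array([3.0, 1.0, 2.0]),
                           1.0, 0)
        assert np.array_equal(best_fit(three).theta, pop.theta[1])
        # random population vs a full linear scan
        scan = min(range(len(pop)), key=lambda i: pop.distances[i])
        assert np.array_equal(best_fit(pop).theta, pop.theta[scan])

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        pop = make_population(rng, n=50)
        path = tmp_path / "pop.tsv"
        pop.to_csv(path)
        back = Population.from_csv(path, epsilon=1.0, generation=0)
        assert np.allclose(back.theta, pop.theta)
        assert np.allclose(back.weights, pop.weights)
        assert np.array_equal(back.m, pop.m)


class TestPosteriorShift:
    def test_identical_populations(self):
        rng = np.random.default_rng(3)
        pop = make_population(rng)
        assert posterior_shift(pop, pop, "lambda1") == 0.0

    def test_disjoint_supports(self):
        rng = np.random.default_rng(4)
        a = make_population(rng, spread=1.0)
        b = make_population(rng, spread=1.0, shift=1e6)
        assert posterior_shift(a, b, "lambda1") == pytest.approx(1.0)

    def test_matches_bruteforce_cdf(self):
        """Weighted KS equals an explicit CDF sweep over the pooled
        support."""
        rng = np.random.default_rng(5)
        a = make_population(rng, n=80)
        b = make_population(rng, n=120, spread=1.3)
        got = posterior_shift(a, b, "Kf")
        xa, wa = a.marginal("Kf")
        xb, wb = b.marginal("Kf")
        grid = np.unique(np.concatenate([xa, xb]))
        fa = np.array([wa[xa <= x].sum() for x in grid])
        fb = np.array([wb[xb <= x].sum() for x in grid])
        assert got == pytest.approx(np.max(np.abs(fa - fb)), abs=1e-12)


class TestSensitivities:
    def test_uniform_cloud_near_uniform_scores(self):
        """An unconstrained (prior-like) cloud gives no parameter a
        dominant prior-width-scaled score."""
        rng = np.random.default_rng(6)
        pop = make_population(rng, n=4000)
        res = sensitivities(pop, "threshold", scale="prior_width")
        assert not res.singular
        assert res.scores.max() / res.scores.min() < 3.0

    def test_spiked_parameter_dominates(self):
        rng = np.random.default_rng(7)
        pop = make_population(rng, n=2000)
        th = pop.theta.copy()
        th[:, 0] = 0.2 + 1e-6 * rng.standard_normal(len(pop))  # lambda1
        spiked = Population(pop.m, th, pop.weights, pop.distances, 1.0, 0)
        res = sensitivities(spiked, "threshold")
        assert res.scores.idxmax() == "lambda1"
        assert res.scores["lambda1"] > 100 * res.scores.drop("lambda1").max()

    def test_gaussian_cloud_matches_analytic_inverse(self):
        """Correlated Gaussian cloud: scores reproduce the analytic
        precision diagonal."""
        rng = np.random.default_rng(8)
        n, d = 20000, 14
        A = 0.3 * rng.standard_normal((d, d))
        cov = A @ A.T + np.eye(d)
        mean = np.full(d, 5.0)
        theta = rng.multivariate_normal(mean, cov, size=n)
        pop = Population(np.ones(n, dtype=int), theta, np.full(n, 1 / n),
                         rng.uniform(0, 1, n), 1.0, 0)
        res = sensitivities(pop, "threshold")
        expected = np.diag(np.linalg.inv(cov)) * mean ** 2
        assert np.allclose(res.scores.to_numpy(), expected, rtol=0.15)


@pytest.fixture(scope="module")
def tiny_study():
    return ang.studies.make_recovery_study(seed=11)


class TestSmallAbcRuns:
    """End-to-end properties cheap enough for the unit suite."""

    def test_prior_limit_when_tolerance_never_tightens(self, tiny_study):
        """With the tolerance held at its loosest (quantile 1.0 keeps
        epsilon at the worst accepted distance), successive generations
        must reproduce the prior — a direct check of the importance
        weights."""
        ds, truth, schedules = tiny_study
        pops, _ = abc_smc(PriorSpec(), ds, schedules,
                          ABCConfig(n_particles=2000, n_generations=3,
                                    model="threshold", seed=9,
                                    epsilon_quantile=1.0))
        fin = pops[-1]
        for param in ("lambda1", "Kf", "alpha2"):
            lo, hi = PriorSpec().ranges[param]
            x, w = fin.marginal(param)
            order = np.argsort(x)
            emp = np.cumsum(w[order])
            theo = (x[order] - lo) / (hi - lo)
            ks = np.max(np.abs(emp - theo))
            assert ks < 0.05, f"{param}: KS vs prior = {ks:.3f}"

    def test_indistinguishable_models_split_probability(self, tiny_study):
        """When the data carry no chemotherapy signal (untreated-looking
        folfox arm cannot discriminate the two response laws), the
        posterior model probabilities stay near 1/2."""
        growth, _ = ang.studies.recovery_truth()
        g0 = ang.GrowthParams(lambda1=growth.lambda1, lambda2=growth.lambda2,
                              c=growth.c, d=growth.d, alpha=growth.alpha,
                              kf=0.0)
        ds, truth = ang.generate_study(
            g0, ang.ChemoResponse("threshold", alpha2=300.0, hill=15.0),
            dict(ang.studies.PK_TRUE), ang.StudyDesign(), ang.NoiseModel(),
            seed=13)
        schedules = ang.schedules_from_truth(truth)
        pops, _ = abc_smc(PriorSpec(), ds, schedules,
                          ABCConfig(n_particles=400, n_generations=4,
                                    model="both", seed=10,
                                    epsilon_quantile=0.3))
        p = pops[-1].model_probabilities()
        assert 0.15 < p["threshold"] < 0.85

    def test_bookkeeping_and_determinism(self, tiny_study):
        """Weights normalise, epsilon decreases, accepted particles
        stay in the prior support, and a fixed seed reproduces the run
        bit-for-bit regardless of worker count."""
        ds, truth, schedules = tiny_study
        cfg = dict(n_particles=150, n_generations=4, model="both", seed=4,
                   epsilon_quantile=0.3)
        pops1, meta1 = abc_smc(PriorSpec(), ds, schedules,
                               ABCConfig(n_jobs=1, **cfg))
        pops2, meta2 = abc_smc(PriorSpec(), ds, schedules,
                               ABCConfig(n_jobs=2, **cfg))
        pri = PriorSpec()
        eps = [p.epsilon for p in pops1]
        assert all(b <= a for a, b in zip(eps[1:], eps[2:]))
        for pop in pops1:
            assert pop.weights.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(pop.distances <= pop.epsilon)
            for mi, th in zip(pop.m, pop.theta):
                assert pri.in_support(int(mi), th)
        for p1, p2 in zip(pops1, pops2):
            assert np.array_equal(p1.theta, p2.theta)
            assert np.array_equal(p1.weights, p2.weights)
            assert np.array_equal(p1.distances, p2.distances)

    def test_run_files(self, tiny_study, tmp_path):
        ds, truth, schedules = tiny_study
        pops, meta = abc_smc(PriorSpec(), ds, schedules,
                             ABCConfig(n_particles=60, n_generations=2,
                                       model="threshold", seed=5,
                                       epsilon_quantile=0.5))
        ang.save_run(tmp_path / "run", pops, meta)
        assert (tmp_path / "run_gen0.tsv").exists()
        assert (tmp_path / "run_gen1.tsv").exists()
        import json
        m = json.loads((tmp_path / "run_meta.json").read_text())
        assert m["epsilons"][0] is None  # infinity marker
        assert len(m["model_probabilities"]) == 2
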