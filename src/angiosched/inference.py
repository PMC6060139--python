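"""ABC-SMC joint fitting and Bayesian model selection.

Likelihood-free sequential Monte Carlo over the 14-dimensional
parameter vector

    theta = (lambda1, lambda2, c, alpha, d,
             Bk12, Bk21, Bke, Fk12, Fk21, Fke, Kf, x1, x2)

with (x1, x2) = (alpha1, beta1) under the continuous chemotherapy law
and (alpha2, p1) under the threshold law, plus a discrete model
indicator m sampled and perturbed alongside theta so that parameter
inference and model selection happen in one run.

Each proposal simulates the vehicle + bvz + FOLFOX arms simultaneously
(each arm from its own first non-zero volume, carrying capacity five
times that) and is accepted when the pooled squared Euclidean distance
to the observed volume series falls below the generation's tolerance.
Tolerances follow a quantile schedule of the previous generation's
accepted distances; particles are re-weighted with the standard SMC
importance ratio (prior density over the kernel-weighted mixture of the
previous population).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .datasets import ArmDataset
from .params import VC_ML
from .pk import Drug, Schedule
from .simulate import Trajectory

SHARED_NAMES = ("lambda1", "lambda2", "c", "alpha", "d",
                "Bk12", "Bk21", "Bke", "Fk12", "Fk21", "Fke", "Kf")
MODEL_NAMES = {0: ("alpha1", "beta1"), 1: ("alpha2", "p1")}
MODEL_LABELS = {0: "continuous", 1: "threshold"}
MODEL_IDS = {v: k for k, v in MODEL_LABELS.items()}
N_DIM = 14

# index in theta -> index in the _fast parameter vector
_I_LAMBDA1, _I_LAMBDA2, _I_C, _I_ALPHA, _I_D = 0, 1, 2, 3, 4
_I_BK, _I_FK, _I_KF = 5, 8, 11


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors, uniform on the linear scale by
    default.  ``log_uniform`` lifts named parameters (e.g. ``d``, whose
    range spans five decades) onto a log-uniform prior."""

    ranges: dict = field(default_factory=dict)
    log_uniform: tuple = ()

    DEFAULT_RANGES = {
        "lambda1": (0.05, 0.5), "lambda2": (0.0, 0.01),
        "c": (0.0, 10.0), "alpha": (0.0, 10.0), "d": (1e-5, 1.0),
        "Bk12": (0.0, 1.0), "Bk21": (0.0, 1.0), "Bke": (0.0, 1.0),
        "Fk12": (0.0, 1.0), "Fk21": (0.0, 1.0), "Fke": (0.0, 1.0),
        "Kf": (0.0, 1.0),
        "alpha1": (-3.0, 3.0), "beta1": (-3.0, 3.0),
        "alpha2": (0.0, 1000.0), "p1": (0.0, 20.0),
    }

    def __post_init__(self) -> None:
        merged = dict(self.DEFAULT_RANGES)
        merged.update(self.ranges)
        for name, (lo, hi) in merged.items():
            if not lo < hi:
                raise ValueError(f"empty prior range for {name}")
            if name in self.log_uniform and lo <= 0:
                raise ValueError(f"log-uniform prior for {name} needs lo > 0")
        object.__setattr__(self, "ranges", merged)

    def names(self, m: int) -> tuple:
        return SHARED_NAMES + MODEL_NAMES[m]

    def bounds(self, m: int) -> np.ndarray:
        """(14, 2) array of (low, high) for model m."""
        return np.array([self.ranges[n] for n in self.names(m)])

    def sample(self, m: int, rng: np.random.Generator) -> np.ndarray:
        b = self.bounds(m)
        u = rng.uniform(size=N_DIM)
        theta = b[:, 0] + u * (b[:, 1] - b[:, 0])
        for i, name in enumerate(self.names(m)):
            if name in self.log_uniform:
                lo, hi = self.ranges[name]
                theta[i] = lo * (hi / lo) ** u[i]
        return theta

    def log_density(self, m: int, theta: np.ndarray) -> float:
        """Log prior density; -inf outside the support."""
        total = 0.0
        for i, name in enumerate(self.names(m)):
            lo, hi = self.ranges[name]
            x = theta[i]
            if not (lo <= x <= hi):
                return -np.inf
            if name in self.log_uniform:
                total += -math.log(x) - math.log(math.log(hi / lo))
            else:
                total += -math.log(hi - lo)
        return total

    def in_support(self, m: int, theta: np.ndarray) -> bool:
        b = self.bounds(m)
        return bool(np.all(theta >= b[:, 0]) and np.all(theta <= b[:, 1]))


@dataclass(frozen=True)
class Particle:
    """One weighted (model, theta) sample of an ABC posterior."""

    m: int
    theta: np.ndarray
    weight: float
    distance: float

    def as_dict(self) -> dict:
        names = SHARED_NAMES + MODEL_NAMES[self.m]
        out = dict(zip(names, self.theta))
        out["model"] = MODEL_LABELS[self.m]
        return out


@dataclass
class Population:
    """One ABC-SMC generation: N weighted particles plus bookkeeping."""

    m: np.ndarray          # (N,) model indicators
    theta: np.ndarray      # (N, 14)
    weights: np.ndarray    # (N,), sums to 1
    distances: np.ndarray  # (N,)
    epsilon: float
    generation: int

    def __post_init__(self) -> None:
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-10):
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return self.m.shape[0]

    def model_probabilities(self) -> dict:
        return {MODEL_LABELS[mi]: float(self.weights[self.m == mi].sum())
                for mi in (0, 1)}

    def marginal(self, param: str, model: str | None = None):
        """(values, normalised weights) of one parameter's marginal."""
        if param in SHARED_NAMES:
            idx = SHARED_NAMES.index(param)
            sel = np.ones(len(self), dtype=bool)
            if model is not None:
                sel = self.m == MODEL_IDS[model]
        else:
            for mi, names in MODEL_NAMES.items():
                if param in names:
                    idx = len(SHARED_NAMES) + names.index(param)
                    sel = self.m == mi
                    break
            else:
                raise KeyError(param)
        if not np.any(sel):
            raise ValueError(f"no particles carry parameter {param!r}")
        w = self.weights[sel]
        return self.theta[sel, idx], w / w.sum()

    def to_frame(self) -> pd.DataFrame:
        cols = {"model": [MODEL_LABELS[mi] for mi in self.m]}
        for i, name in enumerate(SHARED_NAMES):
            cols[name] = self.theta[:, i]
        cols["x1"] = self.theta[:, 12]
        cols["x2"] = self.theta[:, 13]
        cols["weight"] = self.weights
        cols["distance"] = self.distances
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.17g")

    @classmethod
    def from_csv(cls, path, epsilon: float = math.nan,
                 generation: int = -1) -> "Population":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        theta = np.column_stack([df[n].to_numpy() for n in SHARED_NAMES]
                                + [df["x1"].to_numpy(), df["x2"].to_numpy()])
        m = np.array([MODEL_IDS[s] for s in df["model"]])
        return cls(m, theta, df["weight"].to_numpy(),
                   df["distance"].to_numpy(), epsilon, generation)


# ---------------------------------------------------------------------------
# Distance / goodness-of-fit summaries
# ---------------------------------------------------------------------------

def distance(simulated: dict, observed: list[ArmDataset]) -> float:
    """Pooled squared Euclidean distance between simulated and observed
    tumour-volume series, summed over arms and measurement times."""
    total = 0.0
    for arm in observed:
        traj: Trajectory = simulated[arm.arm]
        if traj.times.shape != arm.fit_times.shape or \
                not np.allclose(traj.times, arm.fit_times):
            raise ValueError(f"simulated times do not match arm {arm.arm!r}")
        total += float(np.sum((traj.v - arm.fit_volumes) ** 2))
    return total


def nrmse(simulated: dict, observed: list[ArmDataset]) -> float:
    """Total normalised RMSE: per-arm RMSE divided by that arm's mean
    observed volume, summed over arms."""
    total = 0.0
    for arm in observed:
        traj: Trajectory = simulated[arm.arm]
        mu = float(np.mean(arm.fit_volumes))
        if mu <= 0:
            raise ValueError(f"arm {arm.arm!r} has non-positive mean volume")
        rmse = math.sqrt(float(np.mean((traj.v - arm.fit_volumes) ** 2)))
        total += rmse / mu
    return total


# ---------------------------------------------------------------------------
# ABC-SMC machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ABCConfig:
    n_particles: int = 2000
    n_generations: int = 8
    model: str = "both"          # "continuous" | "threshold" | "both"
    seed: int = 0
    epsilon_quantile: float = 0.1
    kernel_scale: float = 2.0   # kernel covariance = scale x local scatter
    model_switch_prob: float = 0.05
    sim_rtol: float = 1e-4      # forward-simulation error control; errors
    sim_atol: float = 1e-2      # far below measurement noise (mm^3)
    max_step: float = 1.0       # day
    vc: float = VC_ML
    max_proposals_factor: int = 500
    max_total_sims: int | None = None  # graceful stop for budgeted runs
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.model not in ("continuous", "threshold", "both"):
            raise ValueError(f"unknown model {self.model!r}")


class _ArmSetup:
    """Precomputed integration scaffolding for one observed arm."""

    def __init__(self, arm: ArmDataset, schedule: Schedule):
        self.arm = arm
        self.v_obs = arm.fit_volumes
        self.v0 = arm.v0
        self.k0 = arm.k0
        t_eval = arm.fit_times
        kinks = schedule.kink_times()
        kinks = kinks[(kinks > t_eval[0]) & (kinks < t_eval[-1])]
        self.nodes = np.union1d(t_eval, kinks)
        self.mask = np.isin(self.nodes, t_eval)
        for drug, attr in ((Drug.BVZ, "bvz"), (Drug.FOLFOX, "fol")):
            ev = [e for e in schedule.events
                  if e.drug is drug and e.t_start < t_eval[-1]]
            setattr(self, attr, (
                np.array([e.t_start for e in ev]),
                np.array([e.dose_mg / e.t_inf for e in ev]),
                np.array([e.t_inf for e in ev])))


class _StudyPack:
    """All arms' scaffolding concatenated for the fused distance kernel."""

    def __init__(self, arms: list[_ArmSetup]):
        self.node_cat = np.concatenate([a.nodes for a in arms])
        self.node_off = np.cumsum([0] + [a.nodes.size for a in arms])
        self.mask_cat = np.concatenate([a.mask for a in arms])
        self.vobs_cat = np.concatenate([a.v_obs for a in arms])
        self.v0s = np.array([a.v0 for a in arms])
        self.k0s = np.array([a.k0 for a in arms])
        self.bt0 = np.concatenate([a.bvz[0] for a in arms])
        self.brate = np.concatenate([a.bvz[1] for a in arms])
        self.btinf = np.concatenate([a.bvz[2] for a in arms])
        self.boff = np.cumsum([0] + [a.bvz[0].size for a in arms])
        self.ft0 = np.concatenate([a.fol[0] for a in arms])
        self.frate = np.concatenate([a.fol[1] for a in arms])
        self.ftinf = np.concatenate([a.fol[2] for a in arms])
        self.foff = np.cumsum([0] + [a.fol[0].size for a in arms])


def _pk_hybrid(k12: float, k21: float, ke: float, vc: float):
    """(a, b, A, B) or None when degenerate/invalid (proposal rejected)."""
    if k12 <= 0 or k21 <= 0 or ke <= 0:
        return None
    sigma = k12 + k21 + ke
    disc = sigma * sigma - 4.0 * k21 * ke
    b = 0.5 * (sigma - math.sqrt(max(disc, 0.0)))
    if b <= 0:
        return None
    a = k21 * ke / b
    if abs(a - b) / max(a, b) < 1e-8:
        return None
    A = (a - k21) / ((a - b) * vc)
    B = (b - k21) / ((b - a) * vc)
    return a, b, A, B


def _evaluate(theta: np.ndarray, m: int, pack: _StudyPack,
              config: "ABCConfig", eps: float = np.inf) -> float:
    """Distance of one proposal, or +inf when the simulation fails or
    the accumulated distance exceeds ``eps`` (early abort)."""
    if theta[_I_C] <= 0:
        return np.inf
    vc = config.vc
    pkb = _pk_hybrid(theta[5], theta[6], theta[7], vc)
    pkf = _pk_hybrid(theta[8], theta[9], theta[10], vc)
    if pkb is None or pkf is None:
        return np.inf
    par = np.array([theta[0], theta[1], theta[2], theta[4], theta[3],
                    1.0, 0.0, 0.0, theta[11], float(m),
                    theta[12], theta[13]])
    return float(_fast.sse_study(
        eps, pack.node_cat, pack.node_off, pack.mask_cat, pack.vobs_cat,
        pack.v0s, pack.k0s, par, config.sim_rtol, config.sim_atol,
        config.max_step,
        pack.bt0, pack.brate, pack.btinf, pack.boff, *pkb,
        pack.ft0, pack.frate, pack.ftinf, pack.foff, *pkf))


def _map_distances(tasks, pack, config, eps, n_jobs):
    """Evaluate proposals; deterministic for any worker count because
    every task is a pure function of its (theta, m)."""
    if n_jobs == 1 or len(tasks) < 4:
        return [_evaluate(th, m, pack, config, eps) for th, m in tasks]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=n_jobs, backend="threading")(
        delayed(_evaluate)(th, m, pack, config, eps) for th, m in tasks)


class _KernelState:
    """Per-parent local-covariance perturbation kernel for one model.

    For each potential parent in the previous generation, the kernel
    covariance is the weighted scatter about the parent of the previous
    particles whose distance already meets the next tolerance (falling
    back to all the model's particles when fewer than ``N_DIM + 1``
    qualify, which keeps a nearly-extinct model exploring widely),
    scaled by ``kernel_scale`` and ridged with a small diagonal jitter
    so Cholesky factorisation always succeeds.
    """

    def __init__(self, prev: "Population", mi: int, epsilon: float,
                 priors: PriorSpec, kernel_scale: float):
        sel = prev.m == mi
        self.theta = prev.theta[sel]
        w = prev.weights[sel]
        self.w = w / w.sum()
        self.cum_w = np.cumsum(self.w)
        good = prev.distances[sel] <= epsilon
        if np.sum(good) < N_DIM + 1:
            good = np.ones(self.theta.shape[0], dtype=bool)
        th_g = self.theta[good]
        w_g = self.w[good]
        w_g = w_g / w_g.sum()
        bounds = priors.bounds(mi)
        jitter = np.diag((1e-6 * (bounds[:, 1] - bounds[:, 0])) ** 2)
        n = self.theta.shape[0]
        self.chols = np.empty((n, N_DIM, N_DIM))
        self.log_dets = np.empty(n)
        for k in range(n):
            xc = th_g - self.theta[k]
            cov = kernel_scale * (xc * w_g[:, None]).T @ xc + jitter
            for boost in range(6):
                try:
                    chol = np.linalg.cholesky(cov)
                    break
                except np.linalg.LinAlgError:
                    cov = cov + jitter * 10.0 ** (2 * (boost + 1))
            else:
                raise RuntimeError("kernel covariance not factorisable")
            self.chols[k] = chol
            self.log_dets[k] = float(np.sum(np.log(np.diag(chol))))

    def log_mixture(self, theta_acc: np.ndarray) -> np.ndarray:
        """log sum_k w_k N(theta_i; theta_k, Sigma_k) for each row i."""
        from scipy.linalg import solve_triangular
        from scipy.special import logsumexp
        n_acc = theta_acc.shape[0]
        n_par = self.theta.shape[0]
        log_k = np.empty((n_par, n_acc))
        halflog2pi = 0.5 * N_DIM * math.log(2.0 * math.pi)
        for k in range(n_par):
            diff = (theta_acc - self.theta[k]).T
            z = solve_triangular(self.chols[k], diff, lower=True,
                                 check_finite=False)
            log_k[k] = (-0.5 * np.sum(z * z, axis=0)
                        - self.log_dets[k] - halflog2pi)
        return logsumexp(log_k, axis=0, b=self.w[:, None])


def abc_smc(priors: PriorSpec, observed: list[ArmDataset],
            schedules: dict, config: ABCConfig,
            progress: bool = False) -> tuple[list[Population], dict]:
    """Run ABC-SMC with simultaneous model selection.

    Parameters
    ----------
    observed
        Arm datasets (vehicle + monotherapies for the study design the
        procedure was built for, but any set works).
    schedules
        Mapping arm label -> :class:`Schedule` actually administered.

    Returns
    -------
    (populations, metadata)
        One :class:`Population` per generation and a metadata dict with
        the epsilon schedule, acceptance rates and per-generation model
        probabilities.
    """
    rng = np.random.default_rng(config.seed)
    arms = [_ArmSetup(a, schedules[a.arm]) for a in observed]
    pack = _StudyPack(arms)
    if config.model == "both":
        models = [0, 1]
    else:
        models = [MODEL_IDS[config.model]]
    N = config.n_particles
    meta = {"seed": config.seed, "n_particles": N, "epsilons": [],
            "acceptance_rates": [], "model_probabilities": [],
            "n_failed_simulations": 0, "total_sims": 0, "stalled": False}

    # Generation 0: straight prior sampling, epsilon = inf.
    m_arr = np.empty(N, dtype=np.int64)
    theta_arr = np.empty((N, N_DIM))
    dist_arr = np.empty(N)
    accepted = 0
    proposals = 0
    batch = max(64, N // 4)
    while accepted < N:
        tasks = []
        for _ in range(min(batch, (N - accepted) * 2)):
            m = models[rng.integers(len(models))]
            tasks.append((priors.sample(m, rng), m))
        dists = _map_distances(tasks, pack, config, np.inf, config.n_jobs)
        proposals += len(tasks)
        for (th, m), dv in zip(tasks, dists):
            if not np.isfinite(dv):
                meta["n_failed_simulations"] += 1
                continue
            if accepted < N:
                m_arr[accepted] = m
                theta_arr[accepted] = th
                dist_arr[accepted] = dv
                accepted += 1
        if proposals > config.max_proposals_factor * N:
            raise RuntimeError("generation 0: too many failed prior draws")
    pop = Population(m_arr, theta_arr, np.full(N, 1.0 / N), dist_arr,
                     np.inf, 0)
    populations = [pop]
    meta["total_sims"] += proposals
    meta["epsilons"].append(np.inf)
    meta["acceptance_rates"].append(N / proposals)
    meta["model_probabilities"].append(pop.model_probabilities())
    if progress:
        print(f"gen 0: eps=inf acc={N / proposals:.3f} "
              f"P(m)={pop.model_probabilities()}", flush=True)

    for gen in range(1, config.n_generations):
        prev = populations[-1]
        epsilon = float(np.quantile(prev.distances, config.epsilon_quantile))
        alive = [mi for mi in models if np.any(prev.m == mi)]
        # Per-model scaffolding from the previous generation.  The
        # perturbation kernel is a per-parent multivariate normal whose
        # covariance is the weighted scatter, about that parent, of the
        # previous particles already satisfying the new tolerance
        # (optimal local covariance).  This tracks the curved, strongly
        # correlated ridges of this posterior (e.g. the c-alpha-d
        # surface) that a single global covariance cannot follow.
        prev_by_model = {mi: _KernelState(prev, mi, epsilon, priors,
                                          config.kernel_scale)
                         for mi in alive}
        w_model_prev = {mi: float(prev.weights[prev.m == mi].sum())
                        for mi in alive}
        cum_w = np.cumsum(prev.weights)

        m_arr = np.empty(N, dtype=np.int64)
        theta_arr = np.empty((N, N_DIM))
        dist_arr = np.empty(N)
        accepted = 0
        proposals = 0   # simulated proposals; support-rejections are free
        empty_streak = 0
        bounds_by_model = {mi: priors.bounds(mi) for mi in alive}
        while accepted < N:
            # Batched proposal generation: draw parents, perturb model
            # indicators, then resample-and-perturb theta within the
            # proposed model with its local-covariance kernel.
            p_hat = max(accepted / proposals, 0.005) if proposals else 0.1
            B = int(np.clip((N - accepted) / p_hat, 256, 8192))
            j = np.minimum(np.searchsorted(cum_w, rng.random(B)),
                           len(prev) - 1)
            m_prop = prev.m[j].copy()
            if len(alive) > 1:
                sw = rng.random(B) < config.model_switch_prob
                m_prop[sw] = alive[0] + alive[1] - m_prop[sw]
            th_prop = np.empty((B, N_DIM))
            ok = np.zeros(B, dtype=bool)
            for mi in alive:
                sel = np.nonzero(m_prop == mi)[0]
                if sel.size == 0:
                    continue
                ks = prev_by_model[mi]
                k = np.minimum(np.searchsorted(ks.cum_w,
                                               rng.random(sel.size)),
                               ks.theta.shape[0] - 1)
                z = rng.standard_normal((sel.size, N_DIM))
                th_prop[sel] = ks.theta[k] + np.einsum(
                    "bij,bj->bi", ks.chols[k], z)
                b = bounds_by_model[mi]
                ok[sel] = np.all((th_prop[sel] >= b[:, 0])
                                 & (th_prop[sel] <= b[:, 1]), axis=1)
            cand = np.nonzero(ok)[0]
            if cand.size == 0:
                empty_streak += 1
                if empty_streak > 5000:
                    raise RuntimeError(
                        f"generation {gen}: kernel cannot reach the prior "
                        "support")
                continue
            empty_streak = 0
            tasks = [(th_prop[i], int(m_prop[i])) for i in cand]
            dists = _map_distances(tasks, pack, config, epsilon,
                                   config.n_jobs)
            proposals += len(tasks)
            for (th, m), dv in zip(tasks, dists):
                if not np.isfinite(dv):
                    meta["n_failed_simulations"] += 1
                    continue
                if dv <= epsilon and accepted < N:
                    m_arr[accepted] = m
                    theta_arr[accepted] = th
                    dist_arr[accepted] = dv
                    accepted += 1
            if proposals > config.max_proposals_factor * N:
                meta["stalled"] = (
                    f"generation {gen} abandoned: acceptance collapsed "
                    f"({accepted}/{proposals} at eps={epsilon:.3g})")
                break
            if config.max_total_sims is not None and \
                    meta["total_sims"] + proposals > config.max_total_sims:
                meta["stalled"] = (
                    f"generation {gen} abandoned: simulation budget "
                    f"{config.max_total_sims} exhausted")
                break
        meta["total_sims"] += proposals
        if meta["stalled"]:
            # the incomplete generation is dropped; the last completed
            # population stands as the result
            if progress:
                print(f"stopped early: {meta['stalled']}", flush=True)
            break

        weights = _smc_weights(m_arr, theta_arr, prev_by_model, w_model_prev,
                               priors, alive, config.model_switch_prob)
        pop = Population(m_arr, theta_arr, weights, dist_arr, epsilon, gen)
        populations.append(pop)
        meta["epsilons"].append(epsilon)
        meta["acceptance_rates"].append(accepted / proposals)
        meta["model_probabilities"].append(pop.model_probabilities())
        if progress:
            print(f"gen {gen}: eps={epsilon:.4g} acc={accepted / proposals:.3f} "
                  f"sims={proposals} P(m)={pop.model_probabilities()}",
                  flush=True)
    return populations, meta


def _smc_weights(m_arr, theta_arr, prev_by_model, w_model_prev, priors,
                 alive, switch_prob) -> np.ndarray:
    """Importance weights: prior / (model-kernel mixture x theta-kernel
    mixture over the previous generation), normalised to 1; computed in
    log space."""
    N = m_arr.shape[0]
    log_w = np.full(N, -np.inf)
    for mi in alive:
        idx = np.nonzero(m_arr == mi)[0]
        if idx.size == 0:
            continue
        # Model-transition mixture S1 = sum_j w_j KM(mi | m_j).
        if len(alive) > 1:
            s1 = sum(w_model_prev[mj] * ((1.0 - switch_prob) if mj == mi
                                         else switch_prob)
                     for mj in alive)
        else:
            s1 = 1.0
        log_mix = prev_by_model[mi].log_mixture(theta_arr[idx])
        for pos, i in enumerate(idx):
            log_prior = priors.log_density(mi, theta_arr[i]) \
                - math.log(len(alive))
            log_w[i] = log_prior - math.log(s1) - log_mix[pos]
    peak = float(np.max(log_w))
    if not np.isfinite(peak):
        raise RuntimeError("all SMC weights vanished")
    weights = np.exp(log_w - peak)
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# Posterior diagnostics
# ---------------------------------------------------------------------------

def best_fit(pop: Population) -> Particle:
    """Particle with the least squared error (first occurrence on ties)."""
    if len(pop) == 0:
        raise ValueError("empty population")
    i = int(np.argmin(pop.distances))
    return Particle(int(pop.m[i]), pop.theta[i].copy(),
                    float(pop.weights[i]), float(pop.distances[i]))


@dataclass(frozen=True)
class SensitivityResult:
    scores: pd.Series
    singular: bool


def sensitivities(pop: Population, model: str,
                  priors: PriorSpec | None = None,
                  scale: str = "mean") -> SensitivityResult:
    """Precision-based relative sensitivities.

    Inverts the weighted covariance of the posterior sample (particles
    of ``model``); a large diagonal entry of the precision matrix means
    the parameter is tightly conditionally constrained by the data
    (i.e. the fit is sensitive to it).  To make entries comparable
    across parameters with different units, each is scaled by the
    squared weighted posterior mean (``scale="mean"``, the default:
    an inverse squared conditional coefficient of variation) or by the
    squared prior range width (``scale="prior_width"``).  Singular
    covariances fall back to the pseudo-inverse, flagged.
    """
    priors = priors or PriorSpec()
    mi = MODEL_IDS[model]
    sel = pop.m == mi
    names = priors.names(mi)
    th = pop.theta[sel]
    w = pop.weights[sel]
    if th.shape[0] < N_DIM + 1:
        raise ValueError("too few particles of that model for a covariance")
    w = w / w.sum()
    mu = w @ th
    xc = th - mu
    cov = (xc * w[:, None]).T @ xc / (1.0 - float(np.sum(w ** 2)))
    singular = False
    try:
        prec = np.linalg.inv(cov)
        if not np.all(np.isfinite(prec)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(cov)
        singular = True
    if scale == "mean":
        factors = mu ** 2
    elif scale == "prior_width":
        factors = np.array([priors.ranges[n][1] - priors.ranges[n][0]
                            for n in names]) ** 2
    else:
        raise ValueError(f"unknown scale {scale!r}")
    scores = np.diag(prec) * factors
    return SensitivityResult(pd.Series(scores, index=list(names)), singular)


def posterior_shift(pop_a: Population, pop_b: Population, param: str,
                    model: str | None = None) -> float:
    """Weighted two-sample Kolmogorov-Smirnov statistic between one
    parameter's marginals in two populations (0 = identical, 1 =
    disjoint supports)."""
    xa, wa = pop_a.marginal(param, model)
    xb, wb = pop_b.marginal(param, model)
    grid = np.concatenate([xa, xb])
    order = np.argsort(grid, kind="stable")
    grid = grid[order]
    fa = _weighted_cdf(xa, wa, grid)
    fb = _weighted_cdf(xb, wb, grid)
    return float(np.max(np.abs(fa - fb)))


def _weighted_cdf(x, w, grid):
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cw = np.cumsum(w[order])
    idx = np.searchsorted(xs, grid, side="right")
    return np.concatenate([[0.0], cw])[idx]


def credible_interval(pop: Population, param: str, level: float = 0.95,
                      model: str | None = None) -> tuple[float, float]:
    """Weighted equal-tailed credible interval of one marginal."""
    x, w = pop.marginal(param, model)
    order = np.argsort(x)
    xs, cw = x[order], np.cumsum(w[order])
    lo = (1.0 - level) / 2.0
    return (float(np.interp(lo, cw, xs)), float(np.interp(1.0 - lo, cw, xs)))


def posterior_median(pop: Population, param: str,
                     model: str | None = None) -> float:
    x, w = pop.marginal(param, model)
    order = np.argsort(x)
    return float(np.interp(0.5, np.cumsum(w[order]), x[order]))


def save_run(prefix, populations: list[Population], meta: dict) -> None:
    """Write one delimited-text file per generation plus a JSON
    metadata sidecar."""
    from pathlib import Path
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for pop in populations:
        pop.to_csv(f"{prefix}_gen{pop.generation}.tsv")
    clean = dict(meta)
    clean["epsilons"] = [None if not np.isfinite(e) else float(e)
                         for e in meta["epsilons"]]
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump(clean, fh, indent=2)
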