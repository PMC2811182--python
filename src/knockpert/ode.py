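"""Differential-equation models of gene expression rates from perturbation
time series.

Each target gene j is modelled by dx_j/dt = g(regulators) - lambda_j * x_j
with either a linear production term

    g = alpha_j + sum_k beta_jk * x_k          (linear model)

or a sigmoidal one

    g = m_j * sigmoid(sum_k beta_jk * x_k + b_j)   (sigmoidal model)

over a small candidate regulator set R_j (no self-regulation). The model is
scored by one-step-ahead prediction: from the observed state at each time
point, a single second-order Runge-Kutta (Heun) step predicts the target's
level at the next time point, and the objective S is the summed squared
prediction error over all consecutive pairs in all trajectories. Because
regulators are held at their observed values within a step and the target
does not regulate itself, the production term is constant within the step
and the Heun update collapses to the closed form

    pred = x + h * (1 - h*lambda/2) * (g - lambda*x)

whose gradient and Hessian with respect to the parameters are available
analytically; S is minimised by Newton's method from random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import PerturbationDataset

__all__ = [
    "OdeModelSpec",
    "OdeParams",
    "OdeFit",
    "rate",
    "predict_next",
    "objective",
    "objective_gradient_hessian",
    "fit",
    "scan_single",
    "scan_guided",
    "flag_significant",
]

MODEL_TYPES = ("linear", "sigmoidal")

NEWTON_MAX_ITER = 100
NEWTON_REL_TOL = 1e-10


@dataclass(frozen=True)
class OdeModelSpec:
    """Model family, target gene index and ordered candidate regulator set."""

    model_type: str
    target: int
    regulators: tuple[int, ...]

    def __post_init__(self):
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model type {self.model_type!r}")
        if len(self.regulators) == 0:
            raise ValueError("regulator set must be nonempty")
        if self.target in self.regulators:
            raise ValueError("no self-regulation")
        if len(set(self.regulators)) != len(self.regulators):
            raise ValueError("duplicate regulator")

    @property
    def n_params(self) -> int:
        return len(self.regulators) + (2 if self.model_type == "linear" else 3)


@dataclass
class OdeParams:
    """Parameter vector for one model.

    Linear: basal rate ``alpha`` (expr/time), decay ``lam`` (1/time), one
    weight ``beta`` per regulator (1/time). Sigmoidal: maximum rate ``m``
    (expr/time), decay ``lam``, weights ``beta`` (per unit expr) and bias
    ``b`` (dimensionless); ``alpha``/``m`` share a slot internally.
    """

    model_type: str
    theta: np.ndarray  # [alpha|m, lam, (b,) beta_1..beta_K]

    @property
    def lam(self) -> float:
        return float(self.theta[1])

    @property
    def alpha(self) -> float:
        if self.model_type != "linear":
            raise AttributeError("alpha is a linear-model parameter")
        return float(self.theta[0])

    @property
    def m(self) -> float:
        if self.model_type != "sigmoidal":
            raise AttributeError("m is a sigmoidal-model parameter")
        return float(self.theta[0])

    @property
    def b(self) -> float:
        if self.model_type != "sigmoidal":
            raise AttributeError("b is a sigmoidal-model parameter")
        return float(self.theta[2])

    @property
    def beta(self) -> np.ndarray:
        off = 2 if self.model_type == "linear" else 3
        return self.theta[off:]

    @classmethod
    def make(cls, model_type, *, lam, beta, alpha=None, m=None, b=None):
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        if model_type == "linear":
            theta = np.concatenate([[alpha, lam], beta])
        else:
            theta = np.concatenate([[m, lam, b], beta])
        return cls(model_type, theta)


@dataclass
class OdeFit:
    """Best fit found for one spec: parameters, objective S, bookkeeping."""

    spec: OdeModelSpec
    params: OdeParams
    objective: float
    restarts_used: int
    converged: bool


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # overflow-safe logistic


def _production(spec: OdeModelSpec, params: OdeParams, state: np.ndarray) -> float:
    xr = np.asarray(state, dtype=float)[list(spec.regulators)]
    if spec.model_type == "linear":
        return params.alpha + float(xr @ params.beta)
    return params.m * float(_sigmoid(float(xr @ params.beta) + params.b))


def rate(spec: OdeModelSpec, params: OdeParams, state) -> float:
    """Instantaneous expression rate dx_j/dt at a full network state."""
    x_j = float(np.asarray(state, dtype=float)[spec.target])
    return _production(spec, params, state) - params.lam * x_j


def predict_next(spec: OdeModelSpec, params: OdeParams, state_at_t, dt: float) -> float:
    """One Heun (trapezoidal RK2) step of the target from the observed state.

    Regulators are held at their observed values; the prediction is floored
    at zero (expression is a concentration).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x_j = float(np.asarray(state_at_t, dtype=float)[spec.target])
    g = _production(spec, params, state_at_t)
    lam = params.lam
    pred = x_j + dt * (1.0 - dt * lam / 2.0) * (g - lam * x_j)
    return max(pred, 0.0)


# ---------------------------------------------------------------------------
# vectorised objective over all one-step transitions of a dataset


@dataclass
class _StepArrays:
    """All consecutive time-point pairs of a dataset, flattened."""

    h: np.ndarray  # (D,) step widths
    x_prev: np.ndarray  # (D, n) observed state at the step start
    x_next: np.ndarray  # (D, n) observed state at the step end


def step_arrays(data: PerturbationDataset) -> _StepArrays:
    hs, prevs, nexts = [], [], []
    for traj in data.series:
        if len(traj.times) < 2:
            continue
        hs.append(np.diff(traj.times))
        prevs.append(traj.values[:-1])
        nexts.append(traj.values[1:])
    if not hs:
        raise ValueError("no trajectory has two or more time points")
    return _StepArrays(np.concatenate(hs), np.vstack(prevs), np.vstack(nexts))


def _unpack(spec, theta):
    if spec.model_type == "linear":
        return theta[0], theta[1], None, theta[2:]
    return theta[0], theta[1], theta[2], theta[3:]


def _sgh_batch(
    spec: OdeModelSpec, Theta: np.ndarray, steps: _StepArrays, want_derivs: bool
):
    """Objective S (and optionally analytic gradient/Hessian) for a batch of
    parameter vectors ``Theta`` of shape (R, p). Returns S (R,), grad (R, p),
    Hessian (R, p, p)."""
    h = steps.h  # (D,)
    x = steps.x_prev[:, spec.target]
    y = steps.x_next[:, spec.target]
    Xr = steps.x_prev[:, list(spec.regulators)]  # (D, K)
    R, p = Theta.shape
    linear = spec.model_type == "linear"
    off = 2 if linear else 3
    a_or_m = Theta[:, 0]  # (R,)
    lam = Theta[:, 1]
    beta = Theta[:, off:]  # (R, K)

    if linear:
        g = a_or_m[None, :] + Xr @ beta.T  # (D, R)
    else:
        z = Xr @ beta.T + Theta[:, 2][None, :]
        s = _sigmoid(z)
        g = a_or_m[None, :] * s

    c = h[:, None] * (1.0 - h[:, None] * lam[None, :] / 2.0)  # (D, R)
    A = g - lam[None, :] * x[:, None]
    pred = x[:, None] + c * A
    act = pred >= 0.0
    e = np.where(act, y[:, None] - pred, y[:, None])
    S = np.einsum("dr,dr->r", e, e)
    if not want_derivs:
        return S, None, None

    # dg/dphi over the production parameters (all but lam), (D, R, p-1)
    dg = np.empty((h.shape[0], R, p - 1))
    if linear:
        dg[:, :, 0] = 1.0
        dg[:, :, 1:] = Xr[:, None, :]
    else:
        sp = s * (1.0 - s)
        dg[:, :, 0] = s
        dg[:, :, 1] = a_or_m[None, :] * sp
        dg[:, :, 2:] = (a_or_m[None, :] * sp)[:, :, None] * Xr[:, None, :]

    # Jacobian of pred, columns [g-param 0, lam, g-params rest]
    J = np.empty((h.shape[0], R, p))
    J[:, :, 0] = c * dg[:, :, 0]
    J[:, :, 1] = (-0.5 * h**2)[:, None] * A - c * x[:, None]
    J[:, :, 2:] = c[:, :, None] * dg[:, :, 1:]

    ea = np.where(act, e, 0.0)  # floored steps carry no derivative
    Jm = J * act[:, :, None]
    grad = -2.0 * np.einsum("dr,drp->rp", ea, Jm)
    H = 2.0 * np.einsum("drp,drq->rpq", Jm, Jm)

    # second-derivative corrections: -2 sum_d e_d * d2pred_d
    H[:, 1, 1] += -2.0 * np.einsum("dr,d->r", ea, h**2 * x)
    idx = [0] + list(range(2, p))
    cross = -2.0 * np.einsum("dr,drt->rt", ea * (-0.5 * h**2)[:, None], dg)
    H[:, 1, idx] += cross
    H[:, idx, 1] += cross
    if not linear:
        spp = sp * (1.0 - 2.0 * s)
        feats = np.column_stack([np.ones_like(x), Xr])  # (D, K+1), dz/d(b, beta)
        w = ea * c
        mz = np.einsum("dr,dk->rk", w * sp, feats)  # d2g/dm dz
        zz = np.einsum("dr,dk,dl->rkl", w * spp * a_or_m[None, :], feats, feats)
        zidx = list(range(2, p))
        H[:, 0, zidx] += -2.0 * mz
        H[:, zidx, 0] += -2.0 * mz
        for ti, i in enumerate(zidx):
            H[:, i, zidx] += -2.0 * zz[:, ti, :]
    return S, grad, H


def _sgh(spec: OdeModelSpec, theta: np.ndarray, steps: _StepArrays, want_derivs: bool):
    """Single-parameter-vector wrapper around the batched kernel."""
    S, grad, H = _sgh_batch(spec, np.asarray(theta)[None, :], steps, want_derivs)
    if not want_derivs:
        return float(S[0]), None, None
    return float(S[0]), grad[0], H[0]


def objective(spec: OdeModelSpec, params: OdeParams, data: PerturbationDataset) -> float:
    """Summed squared one-step prediction error over all consecutive time
    points of all trajectories."""
    S, _, _ = _sgh(spec, params.theta, step_arrays(data), want_derivs=False)
    return S


def objective_gradient_hessian(spec, params, data):
    """S with its analytic gradient and Hessian (the Newton ingredients)."""
    return _sgh(spec, params.theta, step_arrays(data), want_derivs=True)


# ---------------------------------------------------------------------------
# Newton multistart


def _project(spec, theta):
    theta[1] = max(theta[1], 0.0)  # lam >= 0
    if spec.model_type == "sigmoidal":
        theta[0] = max(theta[0], 0.0)  # m >= 0
    return theta


def _random_start(spec, rng):
    p = spec.n_params
    theta = np.empty(p)
    theta[0] = rng.uniform(0, 1)  # alpha or m
    theta[1] = rng.uniform(0, 1)  # lam
    off = 2
    if spec.model_type == "sigmoidal":
        theta[2] = rng.uniform(-1, 1)  # b
        off = 3
    theta[off:] = rng.uniform(-1, 1, size=p - off)
    return theta


def _project_batch(spec, Theta):
    Theta[:, 1] = np.maximum(Theta[:, 1], 0.0)  # lam >= 0
    if spec.model_type == "sigmoidal":
        Theta[:, 0] = np.maximum(Theta[:, 0], 0.0)  # m >= 0
    return Theta


def _newton_batch(spec, Theta0, steps):
    """Safeguarded Newton descent run in parallel over all restarts.

    Per restart: Newton steps with the analytic Hessian, damped to positive
    definiteness (H + mu*I from the smallest eigenvalue) when needed, a
    backtracking line search on every step, nonnegativity projection of
    decay/maximum rate, and the relative-improvement stopping rule. Returns
    (Theta, S, converged) arrays over restarts.
    """
    R, p = Theta0.shape
    Theta = _project_batch(spec, Theta0.copy())
    S, G, H = _sgh_batch(spec, Theta, steps, True)
    converged = np.zeros(R, dtype=bool)
    active = np.arange(R)
    for _ in range(NEWTON_MAX_ITER):
        if active.size == 0:
            break
        Ga, Ha, Sa = G[active], H[active], S[active]
        gn = np.linalg.norm(Ga, axis=1)
        done_g = (gn == 0) | ~np.isfinite(gn)
        # damp Hessians to strict positive definiteness
        eigmin = np.linalg.eigvalsh(Ha)[:, 0]
        scale = np.maximum(np.trace(Ha, axis1=1, axis2=2) / p, 1e-8)
        mu = np.maximum(0.0, -eigmin) + 1e-9 * scale
        Hd = Ha + mu[:, None, None] * np.eye(p)[None]
        try:
            step = np.linalg.solve(Hd, Ga[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = Ga / np.maximum(gn, 1e-300)[:, None]
        bad = ~np.all(np.isfinite(step), axis=1) | (
            np.einsum("rp,rp->r", step, Ga) <= 0
        )
        if bad.any():
            step[bad] = Ga[bad] / np.maximum(gn[bad], 1e-300)[:, None]
        # vectorised backtracking line search
        t = np.ones(active.size)
        found = done_g.copy()
        cand = Theta[active].copy()
        S_new = Sa.copy()
        for _ in range(25):
            todo = ~found
            if not todo.any():
                break
            trial = _project_batch(
                spec, Theta[active][todo] - t[todo, None] * step[todo]
            )
            S_t = _sgh_batch(spec, trial, steps, False)[0]
            ok = np.isfinite(S_t) & (S_t < Sa[todo])
            ti = np.nonzero(todo)[0]
            hit = ti[ok]
            cand[hit] = trial[ok]
            S_new[hit] = S_t[ok]
            found[hit] = True
            t[ti[~ok]] *= 0.5
        improved = found & ~done_g
        # restarts with no descent step (or zero gradient) are at a minimum
        stalled = ~improved
        converged[active[stalled]] = True
        rel_drop = (Sa - S_new) / np.maximum(Sa, 1e-300)
        idx = active[improved]
        Theta[idx] = cand[improved]
        S[idx] = S_new[improved]
        small = improved & (rel_drop < NEWTON_REL_TOL)
        converged[active[small]] = True
        active = active[improved & (rel_drop >= NEWTON_REL_TOL)]
        if active.size:
            Sn, Gn, Hn = _sgh_batch(spec, Theta[active], steps, True)
            G[active], H[active] = Gn, Hn
    return Theta, S, converged


def fit(
    spec: OdeModelSpec,
    data: PerturbationDataset | _StepArrays,
    n_restarts: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> OdeFit:
    """Minimise S by Newton's method from ``n_restarts`` random initial
    parameter vectors and keep the best local minimum.

    Restart draws: weights and bias Uniform(-1, 1); rates and decay
    Uniform(0, 1). Decay and maximum rate are projected to be nonnegative.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    steps = data if isinstance(data, _StepArrays) else step_arrays(data)
    rng = np.random.default_rng(seed)
    Theta0 = np.stack([_random_start(spec, rng) for _ in range(n_restarts)])
    Theta, S, conv = _newton_batch(spec, Theta0, steps)
    finite = np.isfinite(S)
    if not finite.any():  # every restart diverged: report best iterate anyway
        best = int(np.nanargmin(S))
        return OdeFit(
            spec, OdeParams(spec.model_type, Theta[best]), float(S[best]), n_restarts, False
        )
    S = np.where(finite, S, np.inf)
    best = int(np.argmin(S))
    return OdeFit(
        spec,
        OdeParams(spec.model_type, Theta[best]),
        float(S[best]),
        n_restarts,
        bool(conv[best]),
    )


def _pair_seed(seed, j, k, tag):
    return np.random.SeedSequence(entropy=int(seed) % 2**31, spawn_key=(j, k, tag))


def scan_single(
    data: PerturbationDataset,
    model_type: str,
    seed: int = 0,
    n_restarts: int = 100,
) -> dict[tuple[int, int], OdeFit]:
    """Fit one single-regulator model per ordered (candidate k, target j)
    pair; returns ``{(k, j): OdeFit}``. Deterministic given ``seed`` (restart
    draws are keyed by the pair, not by iteration order)."""
    n = data.n_genes
    steps = step_arrays(data)
    out = {}
    for j in range(n):
        for k in range(n):
            if k == j:
                continue
            spec = OdeModelSpec(model_type, j, (k,))
            out[(k, j)] = fit(spec, steps, n_restarts, _pair_seed(seed, j, k, 0))
    return out


def scan_guided(
    data: PerturbationDataset,
    model_type: str,
    base_regulators: Mapping[int, set[int]],
    seed: int = 0,
    n_restarts: int = 100,
) -> dict[tuple[int, int], OdeFit]:
    """Guided scan: for each target j, fit models whose regulator set is the
    high-confidence base set plus one extra candidate k; the fit's S scores
    the edge (k -> j). Candidates already in the base set are skipped."""
    n = data.n_genes
    steps = step_arrays(data)
    out = {}
    for j in range(n):
        base = set(base_regulators.get(j, set())) - {j}
        for k in range(n):
            if k == j or k in base:
                continue
            regs = tuple(sorted(base | {k}))
            spec = OdeModelSpec(model_type, j, regs)
            # restart draws keyed by the base size so an empty base reduces
            # bit-exactly to the single-regulator scan
            out[(k, j)] = fit(spec, steps, n_restarts, _pair_seed(seed, j, k, len(base)))
    return out


def flag_significant(
    fits: Mapping[tuple[int, int], OdeFit] | Sequence[OdeFit],
    k_sd: float = 2.0,
) -> set[tuple[int, int]]:
    """Flag candidate edges whose objective is more than ``k_sd`` sample
    standard deviations below the mean of their target's candidate fits.

    Statistics are pooled per target gene (and the caller supplies fits of a
    single model type), so targets on different expression scales stay
    comparable. With fewer than 3 candidates, or zero spread, nothing is
    flagged.
    """
    if not isinstance(fits, Mapping):
        fits = {(f.spec.regulators[-1], f.spec.target): f for f in fits}
    by_target: dict[int, list[tuple[tuple[int, int], float]]] = {}
    for pair, f in fits.items():
        by_target.setdefault(f.spec.target, []).append((pair, f.objective))
    flagged = set()
    for target, items in by_target.items():
        if len(items) < 3:
            continue
        vals = np.array([s for _, s in items])
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        cut = mu - k_sd * sd
        flagged.update(pair for (pair, s) in items if s < cut)
    return flagged
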