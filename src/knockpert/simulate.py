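"""In silico gene-network benchmark generator.

Produces everything the inference pipeline consumes — a known signed
network, homozygous and heterozygous deletion steady states, perturbation
trajectories, and additive Gaussian measurement noise — with the structure
of the in silico reverse-engineering challenges: a few dozen genes, sparse
signed regulation, sigmoidal production kinetics and first-order decay,

    dx_i/dt = m_i * g_i(x) - lambda_i * x_i,

where g_i combines the per-regulator drives w_k * x_k either additively
inside one sigmoid (SUM gate) or through max/min of per-regulator sigmoids
(OR/AND gates). OR gates create the classic blind spot of single-deletion
data: two redundant activators whose individual deletion barely moves the
target, while perturbation trajectories still expose them.

Homozygous deletion clamps the deleted gene at zero expression;
heterozygous deletion halves its maximum production rate (gene dosage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .io import (
    DeletionDataset,
    GoldStandard,
    PerturbationDataset,
    Trajectory,
    default_labels,
    write_deletion,
    write_gold_standard,
    write_timeseries,
)

__all__ = [
    "GeneNetwork",
    "BenchmarkBundle",
    "random_network",
    "steady_state",
    "simulate_deletions",
    "simulate_perturbations",
    "generate_benchmark",
]

GATES = ("SUM", "OR", "AND")


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class GeneNetwork:
    """Signed weighted regulatory network with sigmoidal dynamics.

    ``weights[i, j]`` is the signed drive of regulator i on target j (zero =
    no edge). ``m``, ``lam``, ``bias`` are per-gene maximum production rate,
    decay rate and sigmoid bias; ``gate[j]`` sets how multiple regulators of
    j combine.
    """

    n: int
    weights: np.ndarray  # (n, n), [i, j] regulator i -> target j
    m: np.ndarray
    lam: np.ndarray
    bias: np.ndarray
    gate: list[str]
    gene_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.gene_labels:
            self.gene_labels = default_labels(self.n)
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("no self-edges")
        if np.any(self.lam <= 0) or np.any(self.m <= 0):
            raise ValueError("decay and production rates must be positive")
        for g in self.gate:
            if g not in GATES:
                raise ValueError(f"unknown gate {g!r}")

    def edges(self) -> dict[tuple[int, int], int]:
        out = {}
        for i, j in zip(*np.nonzero(self.weights)):
            out[(int(i), int(j))] = 1 if self.weights[i, j] > 0 else -1
        return out

    def gold_standard(self) -> GoldStandard:
        signs = {
            (self.gene_labels[i], self.gene_labels[j]): s
            for (i, j), s in self.edges().items()
        }
        return GoldStandard(list(self.gene_labels), signs)

    def production(self, x: np.ndarray, m: np.ndarray) -> np.ndarray:
        """Gated production term m_j * g_j(x) for all genes at state x."""
        out = np.empty(self.n)
        drives = self.weights * x[:, None]  # (regulator, target)
        for j in range(self.n):
            regs = np.nonzero(self.weights[:, j])[0]
            if len(regs) == 0 or self.gate[j] == "SUM":
                z = drives[regs, j].sum() + self.bias[j]
                out[j] = m[j] * _sigmoid(z)
            else:
                per = _sigmoid(drives[regs, j] + self.bias[j])
                out[j] = m[j] * (per.max() if self.gate[j] == "OR" else per.min())
        return out


def random_network(
    n: int,
    edge_density: float = 0.15,
    activator_fraction: float = 0.75,
    gate_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> GeneNetwork:
    """Sample a random signed network with DREAM-like kinetic parameters.

    Edges are Bernoulli(edge_density) over the n(n-1) ordered non-self
    pairs; at least half the genes are guaranteed one regulator (resampling
    up to 50 times). Weight magnitudes ~ U(2, 4) give strong, clearly
    saturating regulation; decay and maximum rates ~ U(0.5, 1.5); the bias
    centres unregulated genes mid-range.
    """
    if not 0 < edge_density < 1:
        raise ValueError("edge_density must be in (0, 1)")
    gate_mix = gate_mix or {"SUM": 0.8, "OR": 0.2}
    gates, probs = zip(*gate_mix.items())
    rng = np.random.default_rng(seed)
    for _ in range(50):
        adj = rng.random((n, n)) < edge_density
        np.fill_diagonal(adj, False)
        if (adj.any(axis=0).sum()) >= n / 2:
            break
    else:
        raise ValueError("edge density too low to give half the genes a regulator")
    signs = np.where(rng.random((n, n)) < activator_fraction, 1.0, -1.0)
    mags = rng.uniform(2.0, 4.0, size=(n, n))
    weights = np.where(adj, signs * mags, 0.0)
    m = rng.uniform(0.5, 1.5, size=n)
    lam = rng.uniform(0.5, 1.5, size=n)
    gate = list(rng.choice(gates, size=n, p=np.array(probs) / np.sum(probs)))
    # bias: unregulated genes sit mid-range; regulated genes get a bias that
    # roughly centres the sigmoid at typical regulator activity
    bias = rng.uniform(-0.5, 0.5, size=n)
    for j in range(n):
        regs = np.nonzero(weights[:, j])[0]
        if len(regs) and gate[j] == "SUM":
            # offset half the expected total drive at x ~ m/lam scale
            bias[j] -= 0.5 * weights[regs, j].sum()
        elif len(regs):
            bias[j] -= 0.5 * np.mean(weights[regs, j])
    return GeneNetwork(n=n, weights=weights, m=m, lam=lam, bias=bias, gate=gate)


def _condition_arrays(net: GeneNetwork, condition: str | tuple[str, int]):
    """Resolve a condition spec into (m vector, clamped gene or None)."""
    if condition == "wt":
        return net.m.copy(), None
    kind, gene = condition
    if kind == "hom":
        return net.m.copy(), gene
    if kind == "het":
        m = net.m.copy()
        m[gene] *= 0.5
        return m, None
    raise ValueError(f"unknown condition {condition!r}")


def _rhs(net, m, clamp):
    def f(_t, x):
        dx = net.production(x, m) - net.lam * x
        if clamp is not None:
            dx[clamp] = 0.0
        return dx

    return f


def steady_state(
    net: GeneNetwork,
    condition: str | tuple[str, int] = "wt",
    tol: float = 1e-9,
    t_max: float = 2000.0,
) -> np.ndarray:
    """Integrate the dynamics to steady state (sup-norm of dx/dt < tol).

    ``condition`` is ``"wt"``, ``("hom", i)`` (gene i clamped at 0) or
    ``("het", i)`` (gene i's production halved). Raises if the residual has
    not converged within the time budget (oscillatory networks).
    """
    m, clamp = _condition_arrays(net, condition)
    x = net.m / net.lam * 0.5
    if clamp is not None:
        x[clamp] = 0.0
    f = _rhs(net, m, clamp)
    t = 0.0
    chunk = 50.0
    while t < t_max:
        sol = solve_ivp(f, (0, chunk), x, method="LSODA", rtol=1e-10, atol=1e-12)
        x = sol.y[:, -1]
        if clamp is not None:
            x[clamp] = 0.0
        t += chunk
        resid = np.max(np.abs(f(0.0, x)))
        if resid < tol:
            return np.maximum(x, 0.0)
    raise RuntimeError(f"steady state not reached; residual {resid:.3g}")


def simulate_deletions(
    net: GeneNetwork,
    zygosity: str = "homozygous",
    noise_sd: float = 0.025,
    seed: int = 0,
) -> DeletionDataset:
    """Steady-state matrix over wild type and all single-gene deletions,
    plus iid additive Gaussian measurement noise, clamped at zero."""
    rng = np.random.default_rng(seed)
    kind = "hom" if zygosity == "homozygous" else "het"
    wt = steady_state(net, "wt")
    rows = np.stack([steady_state(net, (kind, i)) for i in range(net.n)])
    if noise_sd > 0:
        wt = wt + rng.normal(0, noise_sd, size=wt.shape)
        rows = rows + rng.normal(0, noise_sd, size=rows.shape)
    return DeletionDataset(
        list(net.gene_labels),
        np.maximum(wt, 0.0),
        np.maximum(rows, 0.0),
        zygosity,
    )


def simulate_perturbations(
    net: GeneNetwork,
    n_series: int = 4,
    T: int = 21,
    dt: float = 0.25,
    init_scale: float = 1.0,
    noise_sd: float = 0.025,
    seed: int = 0,
) -> PerturbationDataset:
    """Trajectories after random initial perturbations.

    Each series starts from the wild-type steady state perturbed
    multiplicatively (lognormal with sd ``init_scale``) and is recorded at
    ``T`` uniform time points ``0, dt, ..., (T-1)*dt`` with additive noise.
    """
    rng = np.random.default_rng(seed)
    wt = steady_state(net, "wt")
    f = _rhs(net, net.m, None)
    times = np.arange(T) * dt
    series = []
    for _ in range(n_series):
        x0 = wt * rng.lognormal(0.0, init_scale, size=net.n)
        sol = solve_ivp(
            f, (0, times[-1]), x0, t_eval=times, method="LSODA", rtol=1e-8, atol=1e-10
        )
        vals = sol.y.T
        if noise_sd > 0:
            vals = vals + rng.normal(0, noise_sd, size=vals.shape)
        series.append(Trajectory(times.copy(), np.maximum(vals, 0.0)))
    return PerturbationDataset(list(net.gene_labels), series)


@dataclass
class BenchmarkBundle:
    """A complete benchmark: ground-truth network plus the three datasets."""

    network: GeneNetwork
    hom: DeletionDataset
    het: DeletionDataset
    perturb: PerturbationDataset
    noise_sd: float

    @property
    def gold(self) -> GoldStandard:
        return self.network.gold_standard()

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_deletion(self.hom, outdir / "knockouts.tsv")
        write_deletion(self.het, outdir / "knockdowns.tsv")
        write_timeseries(self.perturb, outdir / "timeseries.tsv")
        write_gold_standard(self.gold, outdir / "goldstandard.tsv")


def generate_benchmark(
    n: int,
    seed: int = 0,
    edge_density: float = 0.15,
    activator_fraction: float = 0.75,
    gate_mix: dict[str, float] | None = None,
    noise_sd: float = 0.025,
    n_series: int = 4,
    T: int = 21,
    dt: float = 0.25,
) -> BenchmarkBundle:
    """Generate a full benchmark bundle; all randomness flows from ``seed``."""
    ss = np.random.SeedSequence(seed)
    s_net, s_hom, s_het, s_pert = ss.spawn(4)
    net = random_network(n, edge_density, activator_fraction, gate_mix, seed=s_net)
    hom = simulate_deletions(net, "homozygous", noise_sd, seed=s_hom)
    het = simulate_deletions(net, "heterozygous", noise_sd, seed=s_het)
    perturb = simulate_perturbations(
        net, n_series=n_series, T=T, dt=dt, noise_sd=noise_sd, seed=s_pert
    )
    return BenchmarkBundle(net, hom, het, perturb, noise_sd)
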