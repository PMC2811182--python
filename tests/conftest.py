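import numpy as np
import pytest

from knockpert import pipeline, simulate
from knockpert.io import DeletionDataset, PerturbationDataset, Trajectory


@pytest.fixture(scope="session")
def bench10():
    """A seeded 10-gene benchmark bundle with default noise."""
    return simulate.generate_benchmark(10, seed=0)


@pytest.fixture(scope="session")
def ranked10(bench10):
    """Full inference on the session benchmark (desk-scale restarts)."""
    cfg = pipeline.RunConfig(seed=0)
    return pipeline.run_inference(bench10.hom, bench10.perturb, bench10.het, cfg)


@pytest.fixture(scope="session")
def star_bench():
    """Deletion-only-signal benchmark: one hub regulator, strong edges,
    low noise; deleting the hub moves its targets far beyond the noise,
    deleting anything else moves nothing."""
    n = 8
    weights = np.zeros((n, n))
    for j in range(1, n):
        weights[0, j] = 3.5
    net = simulate.GeneNetwork(
        n=n,
        weights=weights,
        m=np.full(n, 1.0),
        lam=np.full(n, 1.0),
        bias=np.array([0.5] + [-1.75] * (n - 1)),
        gate=["SUM"] * n,
    )
    ss = np.random.SeedSequence(7)
    s_hom, s_het, s_p = ss.spawn(3)
    hom = simulate.simulate_deletions(net, "homozygous", 0.01, seed=s_hom)
    het = simulate.simulate_deletions(net, "heterozygous", 0.01, seed=s_het)
    perturb = simulate.simulate_perturbations(net, noise_sd=0.01, seed=s_p)
    return simulate.BenchmarkBundle(net, hom, het, perturb, 0.01)


def make_timeseries(n_genes=5, n_series=2, T=11, seed=0, dt=0.5):
    """Arbitrary smooth positive trajectories (not from any network)."""
    rng = np.random.default_rng(seed)
    times = np.arange(T) * dt
    series = []
    for _ in range(n_series):
        base = rng.uniform(0.2, 1.5, n_genes)
        amp = rng.uniform(-0.5, 0.5, n_genes)
        freq = rng.uniform(0.2, 1.0, n_genes)
        vals = base[None, :] + amp[None, :] * np.sin(freq[None, :] * times[:, None])
        series.append(Trajectory(times.copy(), np.maximum(vals, 0.01)))
    labels = [f"G{i + 1}" for i in range(n_genes)]
    return PerturbationDataset(labels, series)
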