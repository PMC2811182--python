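"""Merging noise-model and ODE-model evidence into one ranked edge list.

Predictions are issued in seven confidence batches; every ordered non-self
gene pair is assigned to the first batch whose criterion it meets:

1. regulation probability > 0.99 under the homozygous-deletion noise model;
2. objective two standard deviations below the target's average under BOTH
   the linear and the sigmoidal single-regulator models;
3. as 2, for the guided models;
4. as 2, but flagged by only ONE of the two model types;
5. as 4, for the guided models;
6. probability > 0.95 under both the homozygous and heterozygous noise
   models, with agreeing signs;
7. everything else, ordered by homozygous probability.

The final ranking concatenates the batches. The batch precedence can be
permuted (``swap_batches``) to reproduce ablations such as exchanging the
deletion-driven and perturbation-driven first tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .noise import NoiseModel
from .ode import OdeFit, flag_significant

__all__ = ["PredictionEntry", "RankedPredictions", "assemble", "swap_batches"]


@dataclass
class PredictionEntry:
    regulator: str
    target: str
    batch: int
    score: float
    sign: int
    provenance: str = ""


@dataclass
class RankedPredictions:
    """Ordered list over the n(n-1) candidate edges with batch labels.

    ``validate_partition=False`` relaxes the full-coverage invariant (used
    for lists read back from disk, which may be truncated submissions).
    """

    entries: list[PredictionEntry]
    gene_labels: list[str] | None = None
    validate_partition: bool = True

    def __post_init__(self):
        pairs = [(e.regulator, e.target) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pair in ranking")
        if any(e.regulator == e.target for e in self.entries):
            raise ValueError("self-pair in ranking")
        if self.validate_partition:
            if self.gene_labels is None:
                raise ValueError("gene_labels required to validate the partition")
            n = len(self.gene_labels)
            if len(self.entries) != n * (n - 1):
                raise ValueError(
                    f"ranking must cover all {n * (n - 1)} ordered pairs, "
                    f"got {len(self.entries)}"
                )
            batches = [e.batch for e in self.entries]
            if any(b2 < b1 for b1, b2 in zip(batches, batches[1:])):
                raise ValueError("batch numbers must be nondecreasing")

    def __len__(self):
        return len(self.entries)

    def batch_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for e in self.entries:
            sizes[e.batch] = sizes.get(e.batch, 0) + 1
        return sizes

    def pairs(self) -> list[tuple[str, str]]:
        return [(e.regulator, e.target) for e in self.entries]


def _zscores(values: dict[tuple[int, int], float]) -> dict[tuple[int, int], float]:
    arr = np.array(list(values.values()))
    mu, sd = arr.mean(), arr.std(ddof=1) if len(arr) > 1 else 0.0
    if sd == 0:
        return {k: 0.0 for k in values}
    return {k: (v - mu) / sd for k, v in values.items()}


@dataclass
class _BatchInputs:
    """Per-pair evidence shared by assemble and swap_batches."""

    n: int
    labels: list[str]
    hom_prob: np.ndarray
    hom_sign: np.ndarray
    het_prob: np.ndarray | None
    het_sign: np.ndarray | None
    flags_single: dict[str, set]  # model_type -> flagged pairs
    flags_guided: dict[str, set]
    z_single: dict[str, dict]  # model_type -> pair -> z of (-S)
    z_guided: dict[str, dict]
    neg_s_single: dict[str, dict]
    neg_s_guided: dict[str, dict]
    beta_sign_single: dict[str, dict]


def _prepare(noise_hom, noise_het, single_fits, guided_fits, k_sd, b1_prob, b6_prob):
    n = noise_hom.prob.shape[0]
    flags_single, flags_guided = {}, {}
    z_single, z_guided = {}, {}
    neg_s_single, neg_s_guided = {}, {}
    beta_sign = {}
    for mt, fits in single_fits.items():
        flags_single[mt] = flag_significant(fits, k_sd)
        neg_s = {pair: -f.objective for pair, f in fits.items()}
        neg_s_single[mt] = neg_s
        z_single[mt] = _zscores(neg_s)
        beta_sign[mt] = {
            pair: (1 if f.params.beta[f.spec.regulators.index(pair[0])] >= 0 else -1)
            for pair, f in fits.items()
        }
    for mt, fits in (guided_fits or {}).items():
        flags_guided[mt] = flag_significant(fits, k_sd)
        neg_s = {pair: -f.objective for pair, f in fits.items()}
        neg_s_guided[mt] = neg_s
        z_guided[mt] = _zscores(neg_s)
    return _BatchInputs(
        n=n,
        labels=None,
        hom_prob=noise_hom.prob,
        hom_sign=noise_hom.sign,
        het_prob=None if noise_het is None else noise_het.prob,
        het_sign=None if noise_het is None else noise_het.sign,
        flags_single=flags_single,
        flags_guided=flags_guided,
        z_single=z_single,
        z_guided=z_guided,
        neg_s_single=neg_s_single,
        neg_s_guided=neg_s_guided,
        beta_sign_single=beta_sign,
    )


def _criteria(inp: _BatchInputs, b1_prob: float, b6_prob: float):
    """Batch membership tests and within-batch sort keys, indexed 1..7.

    Each element is (member(pair) -> bool, key(pair) -> sortable desc)."""
    mts = list(inp.flags_single)
    both_single = (
        set.intersection(*inp.flags_single.values()) if inp.flags_single else set()
    )
    any_single = set.union(*inp.flags_single.values()) if inp.flags_single else set()
    both_guided = (
        set.intersection(*inp.flags_guided.values()) if inp.flags_guided else set()
    )
    any_guided = set.union(*inp.flags_guided.values()) if inp.flags_guided else set()

    def hom_p(pair):
        return inp.hom_prob[pair]

    def z_mean(zmaps, pair):
        vals = [zm[pair] for zm in zmaps.values() if pair in zm]
        return float(np.mean(vals)) if vals else -np.inf

    def one_type_score(flags, neg_s, pair):
        # score under the (unique) flagging model type
        for mt in mts:
            if pair in flags.get(mt, set()) and pair in neg_s.get(mt, {}):
                return neg_s[mt][pair]
        return -np.inf

    def b6_member(pair):
        if inp.het_prob is None:
            return False
        return (
            inp.hom_prob[pair] > b6_prob
            and inp.het_prob[pair] > b6_prob
            and inp.hom_sign[pair] == inp.het_sign[pair]
        )

    return {
        1: (lambda p: inp.hom_prob[p] > b1_prob, hom_p),
        2: (lambda p: p in both_single, lambda p: z_mean(inp.z_single, p)),
        3: (lambda p: p in both_guided, lambda p: z_mean(inp.z_guided, p)),
        4: (
            lambda p: p in any_single and p not in both_single,
            lambda p: one_type_score(inp.flags_single, inp.neg_s_single, p),
        ),
        5: (
            lambda p: p in any_guided and p not in both_guided,
            lambda p: one_type_score(inp.flags_guided, inp.neg_s_guided, p),
        ),
        6: (
            b6_member,
            lambda p: min(inp.hom_prob[p], inp.het_prob[p])
            if inp.het_prob is not None
            else -np.inf,
        ),
        7: (lambda p: True, hom_p),
    }


def _pair_sign(inp: _BatchInputs, pair, batch_kind: int) -> int:
    """Sign from the model that placed the pair: deletion-deviation direction
    for noise batches, sign of the regulator's beta for ODE batches."""
    if batch_kind in (2, 3, 4, 5):
        for mt, signs in inp.beta_sign_single.items():
            if pair in signs:
                return signs[pair]
    return int(inp.hom_sign[pair])


def _assemble_order(
    labels, inp: _BatchInputs, order: Sequence[int], b1_prob: float, b6_prob: float
) -> RankedPredictions:
    crit = _criteria(inp, b1_prob, b6_prob)
    n = inp.n
    all_pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    remaining = list(all_pairs)
    entries = []
    prov = {
        1: "noise_hom",
        2: "ode_single_both",
        3: "ode_guided_both",
        4: "ode_single_one",
        5: "ode_guided_one",
        6: "noise_hom+het",
        7: "remainder",
    }
    for pos, orig_batch in enumerate(order, start=1):
        member, key = crit[orig_batch]
        hits = [p for p in remaining if member(p)]
        # deterministic: secondary key hom probability, then lexicographic
        hits.sort(key=lambda p: (-key(p), -inp.hom_prob[p], p))
        for p in hits:
            entries.append(
                PredictionEntry(
                    regulator=labels[p[0]],
                    target=labels[p[1]],
                    batch=pos,
                    score=float(key(p)),
                    sign=_pair_sign(inp, p, orig_batch),
                    provenance=prov[orig_batch],
                )
            )
        kept = set(hits)
        remaining = [p for p in remaining if p not in kept]
    return RankedPredictions(entries=entries, gene_labels=list(labels))


def assemble(
    noise_hom: NoiseModel,
    noise_het: NoiseModel | None,
    single_fits: Mapping[str, Mapping[tuple[int, int], OdeFit]],
    guided_fits: Mapping[str, Mapping[tuple[int, int], OdeFit]] | None,
    gene_labels: Sequence[str],
    b1_prob: float = 0.99,
    b6_prob: float = 0.95,
    k_sd: float = 2.0,
) -> RankedPredictions:
    """Assign every ordered pair to the first of the seven batches it
    satisfies and return the concatenated ranking.

    ``single_fits`` / ``guided_fits`` map model type ("linear", "sigmoidal")
    to per-pair fits. Without heterozygous data batch 6 is empty.
    """
    import warnings

    if noise_het is None:
        warnings.warn("no heterozygous noise model: batch 6 will be empty")
    inp = _prepare(noise_hom, noise_het, single_fits, guided_fits or {}, k_sd, b1_prob, b6_prob)
    return _assemble_order(list(gene_labels), inp, range(1, 8), b1_prob, b6_prob)


def swap_batches(
    order: Sequence[int],
    noise_hom: NoiseModel,
    noise_het: NoiseModel | None,
    single_fits,
    guided_fits,
    gene_labels: Sequence[str],
    b1_prob: float = 0.99,
    b6_prob: float = 0.95,
    k_sd: float = 2.0,
) -> RankedPredictions:
    """Re-run the greedy batch assignment under a permuted precedence.

    ``order`` is a permutation of 1..7 giving the original batch criteria in
    their new precedence; output batch numbers are positions in this order.
    """
    if sorted(order) != list(range(1, 8)):
        raise ValueError("order must be a permutation of 1..7")
    inp = _prepare(noise_hom, noise_het, single_fits, guided_fits or {}, k_sd, b1_prob, b6_prob)
    return _assemble_order(list(gene_labels), inp, list(order), b1_prob, b6_prob)
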