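"""Scoring ranked edge predictions against a gold-standard network.

Metrics follow the DREAM in silico challenge conventions: AUROC and AUPR of
the full ranking, empirical p-values from random permutations of the
ranking, geometric-mean aggregation across networks with the overall score
-(1/2) log10(pAUPR * pAUROC), per-batch predicted/correct tables, and an
exact hypergeometric upper-tail test for whether the perturbation-driven
batches (2-6) recover more of the edges missed by batch 1 than chance.
Edge signs are not scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from sklearn.metrics import average_precision_score, roc_auc_score

from .combine import RankedPredictions
from .io import GoldStandard

__all__ = [
    "EvaluationReport",
    "auroc",
    "aupr",
    "permutation_pvalue",
    "aggregate",
    "batch_table",
    "batch_enrichment_pvalue",
    "evaluate",
]


def _labels_scores(ranked: RankedPredictions, gold: GoldStandard):
    pairs = ranked.pairs()
    y = np.array([1 if p in gold.edges else 0 for p in pairs])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("gold standard is empty or covers every pair; metrics undefined")
    # score by position: earlier = more confident; ties impossible
    scores = np.arange(len(pairs), 0, -1, dtype=float)
    return y, scores


def auroc(ranked: RankedPredictions, gold: GoldStandard) -> float:
    """Area under the ROC curve of the full ranking (trapezoidal)."""
    y, s = _labels_scores(ranked, gold)
    return float(roc_auc_score(y, s))


def aupr(ranked: RankedPredictions, gold: GoldStandard) -> float:
    """Area under the precision-recall curve (step-wise summation)."""
    y, s = _labels_scores(ranked, gold)
    return float(average_precision_score(y, s))


def permutation_pvalue(
    metric,
    ranked: RankedPredictions,
    gold: GoldStandard,
    B: int = 100_000,
    seed: int = 0,
) -> float:
    """Empirical p-value of a ranking metric under uniform shuffles of the
    ranking, with the add-one estimator (1 + #{>= observed}) / (B + 1)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    y, _ = _labels_scores(ranked, gold)
    observed = _metric_on_labels(metric, y)
    rng = np.random.default_rng(seed)
    hits = 0
    yy = y.copy()
    for _ in range(B):
        rng.shuffle(yy)
        if _metric_on_labels(metric, yy) >= observed:
            hits += 1
    return (1 + hits) / (B + 1)


def _metric_on_labels(metric, y):
    s = np.arange(len(y), 0, -1, dtype=float)
    if metric in ("auroc", auroc):
        return float(roc_auc_score(y, s))
    if metric in ("aupr", aupr):
        return float(average_precision_score(y, s))
    raise ValueError(f"unknown metric {metric!r}")


def aggregate(p_aupr: list[float], p_auroc: list[float]):
    """Geometric means of the per-network p-values and the overall score
    -(1/2) log10(pbar_AUPR * pbar_AUROC)."""
    for p in list(p_aupr) + list(p_auroc):
        if p <= 0:
            raise ValueError("p-values must be positive")
    g_pr = float(np.exp(np.mean(np.log(p_aupr))))
    g_roc = float(np.exp(np.mean(np.log(p_auroc))))
    score = -0.5 * np.log10(g_pr * g_roc)
    return g_pr, g_roc, float(score)


def batch_table(ranked: RankedPredictions, gold: GoldStandard):
    """Per-batch (predicted, correct) counts for batches 1..7 plus a Total
    row, the structure of the challenge accuracy tables."""
    table = {b: [0, 0] for b in range(1, 8)}
    for e in ranked.entries:
        row = table.setdefault(e.batch, [0, 0])
        row[0] += 1
        if (e.regulator, e.target) in gold.edges:
            row[1] += 1
    total = [sum(r[0] for r in table.values()), sum(r[1] for r in table.values())]
    out = {b: tuple(r) for b, r in sorted(table.items())}
    out["Total"] = tuple(total)
    return out


def batch_enrichment_pvalue(n_remaining: int, K_missed: int, n_pred: int, c: int) -> float:
    """Exact hypergeometric upper tail P(X >= c).

    Population: the ``n_remaining`` pairs not predicted in batch 1, of which
    ``K_missed`` are true edges batch 1 missed; ``n_pred`` draws are the
    predictions of batches 2-6 and ``c`` of them are correct.
    """
    if not (0 <= K_missed <= n_remaining and 0 <= n_pred <= n_remaining):
        raise ValueError("infeasible counts")
    if not (0 <= c <= min(K_missed, n_pred)):
        raise ValueError("c must be between 0 and min(K_missed, n_pred)")
    return float(hypergeom.sf(c - 1, n_remaining, K_missed, n_pred))


def enrichment_from_table(table) -> float:
    """Batch-enrichment p-value computed from a batch_table result."""
    total_pred, total_corr = table["Total"]
    b1_pred, b1_corr = table[1]
    n_remaining = total_pred - b1_pred
    K_missed = total_corr - b1_corr
    n_pred = sum(table[b][0] for b in range(2, 7))
    c = sum(table[b][1] for b in range(2, 7))
    return batch_enrichment_pvalue(n_remaining, K_missed, n_pred, c)


@dataclass
class EvaluationReport:
    auroc: float
    aupr: float
    p_auroc: float | None
    p_aupr: float | None
    batch_counts: dict | None
    enrichment_p: float | None

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "p_auroc": self.p_auroc,
            "p_aupr": self.p_aupr,
            "batch_counts": None
            if self.batch_counts is None
            else {str(k): list(v) for k, v in self.batch_counts.items()},
            "enrichment_p": self.enrichment_p,
        }

    def render(self) -> str:
        lines = [f"AUROC\t{self.auroc:.4f}", f"AUPR\t{self.aupr:.4f}"]
        if self.p_auroc is not None:
            lines.append(f"pAUROC\t{self.p_auroc:.3g}")
        if self.p_aupr is not None:
            lines.append(f"pAUPR\t{self.p_aupr:.3g}")
        if self.batch_counts is not None:
            lines.append("Batch\tPredicted\tCorrect")
            for b, (pred, corr) in self.batch_counts.items():
                lines.append(f"{b}\t{pred}\t{corr}")
        if self.enrichment_p is not None:
            lines.append(f"Enrichment p (batches 2-6)\t{self.enrichment_p:.4g}")
        return "\n".join(lines)


def evaluate(
    ranked: RankedPredictions,
    gold: GoldStandard,
    B: int = 0,
    seed: int = 0,
) -> EvaluationReport:
    """Full report; permutation p-values only when B > 0 (they dominate the
    cost at the published 100,000-permutation setting). Batch rows are
    omitted for rankings without batch labels (e.g. read back from disk).
    """
    has_batches = any(e.batch >= 1 for e in ranked.entries)
    table = batch_table(ranked, gold) if has_batches else None
    return EvaluationReport(
        auroc=auroc(ranked, gold),
        aupr=aupr(ranked, gold),
        p_auroc=permutation_pvalue("auroc", ranked, gold, B, seed) if B else None,
        p_aupr=permutation_pvalue("aupr", ranked, gold, B, seed + 1) if B else None,
        batch_counts=table,
        enrichment_p=None if table is None else enrichment_from_table(table),
    )
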