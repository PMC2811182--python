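"""Gaussian noise models for deletion steady-state data.

Every measured expression level is modelled as the true signal plus a small
zero-mean Gaussian measurement/biological noise, independent of the gene.
A gene whose level in a deletion strain deviates from its wild-type
reference by more than the noise plausibly explains is a candidate target
of the deleted gene. Because neither the true wild-type levels nor the
noise variance are observable, both are refined iteratively:

1. classify every ordered pair (deleted gene i, observed gene j) by the
   two-sided tail probability of its deviation; pairs with p >= alpha join
   the "unaffected" set U;
2. re-estimate the noise variance from the residuals over U;
3. re-estimate each gene's wild-type reference as the mean of its levels in
   strains where it was judged unaffected (the observed wild type included).

Iteration stops when U reaches a fixpoint. The regulation probability of a
pair is one minus its final tail probability; the rank of these
probabilities is the deletion-data evidence for regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io import DeletionDataset

__all__ = ["NoiseModel", "deviation_pvalue", "fit_noise_model", "regulation_probabilities"]

SIGMA_FLOOR = 1e-8  # expression units; guards degenerate noiseless input


@dataclass
class NoiseModel:
    """Fitted noise model for one deletion dataset.

    ``prob[i, j]`` is the probability that gene i regulates gene j (diagonal
    is NaN); ``sign[i, j]`` the inferred sign. ``references`` are the
    estimated true wild-type levels and ``sigma`` the pooled noise SD.
    ``sigma_per_gene`` keeps the per-gene initial estimates as a diagnostic.
    """

    references: np.ndarray
    sigma: float
    sigma_per_gene: np.ndarray
    unregulated_pairs: set[tuple[int, int]]
    prob: np.ndarray
    sign: np.ndarray
    iterations_run: int
    zygosity: str = "homozygous"


def deviation_pvalue(x, r, sigma) -> np.ndarray | float:
    """Two-sided Gaussian tail probability of observing a deviation at least
    as large as |x - r| under noise SD ``sigma``. Returns 1 at x == r."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = np.abs(np.asarray(x, dtype=float) - np.asarray(r, dtype=float)) / sigma
    p = 2.0 * norm.sf(z)
    return p if p.ndim else float(p)


def _truncation_factor(alpha: float) -> float:
    """Consistency correction for estimating the noise variance from the
    pairs retained at gate ``alpha``.

    The unaffected set keeps residuals with |z| < z_a (z_a the two-sided
    alpha quantile), so their raw mean square underestimates sigma^2 by the
    truncated-normal factor 1 - 2 z_a phi(z_a) / (1 - alpha); dividing by it
    keeps the estimator unbiased under the null and stops the
    shrink-reclassify feedback loop from collapsing sigma.
    """
    if alpha <= 0:
        return 1.0
    z_a = norm.isf(alpha / 2)
    return 1.0 - 2.0 * z_a * norm.pdf(z_a) / (1.0 - alpha)


def _classify(strains, refs, sigma, alpha):
    """Boolean mask of off-diagonal pairs judged unaffected (p >= alpha)."""
    p = 2.0 * norm.sf(np.abs(strains - refs[None, :]) / sigma)
    mask = p >= alpha
    np.fill_diagonal(mask, False)
    return mask


def fit_noise_model(
    data: DeletionDataset,
    alpha: float = 0.05,
    max_iter: int = 50,
    pool_sigma: bool = True,
) -> NoiseModel:
    """Fit the iterative noise model to a deletion dataset.

    ``alpha`` is the gate p-value separating potential regulation from the
    unaffected set (0.05 is deliberately conservative: only clearly quiet
    pairs refine the error model). With ``pool_sigma`` (default) the variance
    re-estimate pools residuals across genes, matching the gene-independent
    noise assumption; per-gene initial variances are used only for the first
    classification pass. ``pool_sigma=False`` keeps per-gene variances
    throughout.
    """
    n = data.n_genes
    if n < 2:
        raise ValueError("need at least 2 genes")
    strains = data.strains
    refs = data.wild_type.copy()

    # initial per-gene variance: sample variance of the gene's levels across
    # all deletion strains (ddof=1)
    var0 = strains.var(axis=0, ddof=1)
    sigma_per_gene = np.sqrt(np.maximum(var0, SIGMA_FLOOR**2))
    sigma_row = sigma_per_gene[None, :]

    mask_prev = None
    iterations = 0
    mask = _classify(strains, refs, sigma_row, alpha)
    for iterations in range(1, max_iter + 1):
        if not mask.any():
            raise ValueError(
                "unaffected set is empty; noise SD cannot be estimated "
                "(try a larger alpha)"
            )
        resid = strains - refs[None, :]
        tf = _truncation_factor(alpha)
        if pool_sigma:
            sigma2 = float(np.mean(resid[mask] ** 2)) / tf
            sigma_val = max(np.sqrt(sigma2), SIGMA_FLOOR)
            sigma_row = np.full((1, n), sigma_val)
        else:
            counts = mask.sum(axis=0)
            sq = np.where(mask, resid**2, 0.0).sum(axis=0)
            per = np.where(counts > 0, sq / np.maximum(counts, 1) / tf, sigma_row[0] ** 2)
            sigma_row = np.sqrt(np.maximum(per, SIGMA_FLOOR**2))[None, :]
        # step 3: reference = mean of unaffected observations plus the
        # observed wild type (itself an unbiased observation of the truth)
        counts = mask.sum(axis=0) + 1
        refs = (np.where(mask, strains, 0.0).sum(axis=0) + data.wild_type) / counts

        mask_prev = mask
        mask = _classify(strains, refs, sigma_row, alpha)
        if np.array_equal(mask, mask_prev):
            break

    p = 2.0 * norm.sf(np.abs(strains - refs[None, :]) / sigma_row)
    prob = 1.0 - p
    np.fill_diagonal(prob, np.nan)
    # deletion lowering the target => deleted gene was an activator
    sign = np.where(strains < refs[None, :], 1, -1)
    np.fill_diagonal(sign, 0)
    U = {(i, j) for i, j in zip(*np.nonzero(mask))}
    sigma_scalar = float(sigma_row.mean()) if pool_sigma else float(
        np.sqrt(np.mean(sigma_row**2))
    )
    return NoiseModel(
        references=refs,
        sigma=sigma_scalar,
        sigma_per_gene=sigma_row[0].copy() if not pool_sigma else sigma_per_gene,
        unregulated_pairs=U,
        prob=prob,
        sign=sign,
        iterations_run=iterations,
        zygosity=data.zygosity,
    )


def regulation_probabilities(model: NoiseModel, data: DeletionDataset):
    """Recompute (prob, sign) matrices for ``data`` under a fitted model.

    ``prob[i, j] = 1 - deviation_pvalue(x_ij, r_j, sigma)``; the diagonal is
    NaN (no self-regulation). Signs follow the activator-lowered-by-deletion
    convention; pass ``paper_literal_signs=True`` nowhere — flip via
    ``flip_signs`` if the inverted reading is wanted.
    """
    if data.strains.shape[1] != model.references.shape[0]:
        raise ValueError("model/data shape mismatch")
    p = deviation_pvalue(data.strains, model.references[None, :], model.sigma)
    prob = 1.0 - np.asarray(p)
    np.fill_diagonal(prob, np.nan)
    sign = np.where(data.strains < model.references[None, :], 1, -1)
    np.fill_diagonal(sign, 0)
    return prob, sign


def flip_signs(model: NoiseModel) -> NoiseModel:
    """Return a copy with the literal higher-than-reference=activation sign
    convention (the inverse of the default biological reading)."""
    flipped = NoiseModel(**{**model.__dict__})
    flipped.sign = -model.sign
    return flipped
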