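"""Gene selection from posterior draws.

The Bayesian lasso shrinks but never zeroes coefficients, so selection
works through per-draw *conditional MAP* estimates: for each retained
draw the coefficients' conditional posterior mode is the solution of a
lasso problem (conditioning on that draw's shrinkage parameters, error
scale, covariate effects, loadings and latent response), which is
exactly sparse.  The empirical frequency with which a gene's
coefficient is non-zero across draws is its posterior inclusion
probability; ``1 - p`` estimates the local false discovery rate, and a
sorted-probability threshold controls the average Bayesian FDR at a
target level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoLars, LinearRegression

from .data import GenomicsDataset
from .engine import PosteriorSamples, design_blocks

__all__ = [
    "SelectionResult",
    "weighted_lasso",
    "conditional_map_lasso",
    "posterior_inclusion_probabilities",
    "bfdr_threshold",
    "select_genes",
]

_LAM_FLOOR = 1e-10  # below this the penalty is treated as absent (OLS limit)


@dataclass(frozen=True)
class SelectionResult:
    """Per-gene, per-effect-type inclusion probabilities and the FDR cut.

    ``table`` has one row per (gene, effect type) with the posterior
    inclusion probability and the selection flag at level ``alpha``;
    ``threshold`` is the probability cutoff phi_alpha (``inf`` when
    nothing can be selected).
    """

    table: pd.DataFrame
    alpha: float
    threshold: float

    def selected(self, effect_type: str | None = None) -> tuple[str, ...]:
        t = self.table[self.table["selected"] == 1]
        if effect_type is not None:
            t = t[t["effect_type"] == effect_type]
        return tuple(t["gene_id"])

    def probabilities(self, effect_type: str) -> pd.Series:
        t = self.table[self.table["effect_type"] == effect_type]
        return pd.Series(t["posterior_probability"].to_numpy(), index=t["gene_id"].to_numpy())


def weighted_lasso(
    response: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Exact minimizer of ``||r - D b||^2 + 2*sigma*sum_j w_j |b_j|``.

    Per-column penalty weights (here the block shrinkage parameters
    lambda) are folded into a single-penalty lasso by rescaling column
    j by ``1/w_j`` and the solution back by the same factor; the
    rescaled problem is solved exactly on the least-angle-regression
    homotopy path.  Weights at or below a tiny floor disable the
    penalty (ordinary least squares limit).
    """
    r = np.asarray(response, dtype=float)
    D = np.asarray(design, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or sigma < 0:
        raise ValueError("penalty weights and sigma must be non-negative")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(D)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite values in the conditional-MAP problem")
    n = len(r)
    if np.all(w <= _LAM_FLOOR) or sigma <= _LAM_FLOOR:
        return LinearRegression(fit_intercept=False).fit(D, r).coef_
    w = np.maximum(w, _LAM_FLOOR)
    model = LassoLars(alpha=sigma / n, fit_intercept=False, fit_path=False, max_iter=2000)
    model.fit(D / w, r)
    return np.ravel(model.coef_) / w


def _draw_problem(
    samples: PosteriorSamples, ds: GenomicsDataset, s: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[tuple[str, int]]]:
    """Assemble (response, design, weights, sigma, block layout) for draw s."""
    blocks = design_blocks(samples, ds, s)
    cov_c = ds.covariates.to_numpy(dtype=float) - samples.centers["covariates"] \
        if ds.covariates.shape[1] else np.zeros((ds.n_samples, 0))
    C = cov_c
    if samples.family != "continuous":
        C = np.hstack([np.ones((ds.n_samples, 1)), cov_c])
    if samples.family == "continuous":
        resp = ds.outcome.values - samples.centers["y"]
    else:
        resp = samples.draws["z"][s]
    r = resp - C @ samples.draws["gamma"][s]

    parts, weights, layout = [], [], []
    for name in samples.block_names:
        D = blocks[name]
        lam = float(np.sqrt(samples.draws[f"lam2_{name}"][s]))
        parts.append(D)
        weights.append(np.full(D.shape[1], lam))
        layout.append((name, D.shape[1]))
    sigma = float(np.sqrt(samples.draws["sigma2"][s]))
    return r, np.hstack(parts), np.concatenate(weights), sigma, layout


def conditional_map_lasso(
    samples: PosteriorSamples, ds: GenomicsDataset, s: int
) -> dict[str, np.ndarray]:
    """Sparse conditional-MAP coefficients for retained draw ``s``.

    Conditional on the draw's loadings (hence the expression
    partition), covariate effects, latent response, error scale and the
    block shrinkage parameters, the coefficient mode solves a lasso
    with one penalty level per block.  Returns the exact solution per
    block; its non-zero pattern defines the draw's inclusion
    indicators.
    """
    r, D, w, sigma, layout = _draw_problem(samples, ds, s)
    coef = weighted_lasso(r, D, w, sigma)
    out: dict[str, np.ndarray] = {}
    off = 0
    for name, width in layout:
        out[name] = coef[off : off + width]
        off += width
    return out


def posterior_inclusion_probabilities(
    samples: PosteriorSamples, ds: GenomicsDataset
) -> dict[str, pd.Series]:
    """Empirical non-zero frequencies of the conditional-MAP estimates.

    Returns one probability series per coefficient block (``m`` /
    ``mbar`` for the integrative models, ``g`` / ``meth`` for the
    comparators), indexed by feature label.
    """
    S = samples.n_draws
    counts = {name: np.zeros(len(samples.block_labels[name])) for name in samples.block_names}
    for s in range(S):
        coefs = conditional_map_lasso(samples, ds, s)
        for name, c in coefs.items():
            counts[name] += c != 0.0
    return {
        name: pd.Series(counts[name] / S, index=list(samples.block_labels[name]))
        for name in samples.block_names
    }


def bfdr_threshold(combined: np.ndarray, alpha: float) -> tuple[float, np.ndarray]:
    """Probability cutoff controlling the average Bayesian FDR at ``alpha``.

    With probabilities sorted in descending order p_(1) >= p_(2) >= ...,
    the largest prefix whose mean local FDR ``(1/i) * sum(1 - p_(j))``
    stays at or below ``alpha`` sets the cutoff ``phi = p_(kappa)``;
    every feature with ``p >= phi`` is selected (ties inclusive).  If
    no prefix qualifies the selection is empty and the cutoff is the
    ``+inf`` sentinel.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(combined, dtype=float)
    if p.size == 0:
        return float("inf"), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    order = np.argsort(-p, kind="stable")
    cummean = np.cumsum(1.0 - p[order]) / np.arange(1, p.size + 1)
    ok = np.flatnonzero(cummean <= alpha)
    if ok.size == 0:
        return float("inf"), np.zeros(p.size, dtype=bool)
    phi = float(p[order[ok[-1]]])
    return phi, p >= phi


def select_genes(
    samples: PosteriorSamples, ds: GenomicsDataset, alpha: float = 0.2
) -> SelectionResult:
    """Full selection pipeline: inclusion probabilities + BFDR threshold.

    The combined probability vector concatenates every block's entries
    (for the integrative models: one type-M entry per mapped gene and
    one type-Mbar entry per gene) and a single cutoff is applied across
    all of them.
    """
    probs = posterior_inclusion_probabilities(samples, ds)
    effect_name = {"m": "M", "mbar": "Mbar", "g": "G", "meth": "meth"}
    frames = []
    for name in samples.block_names:
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": probs[name].index,
                    "effect_type": effect_name.get(name, name),
                    "posterior_probability": probs[name].to_numpy(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    phi, mask = bfdr_threshold(table["posterior_probability"].to_numpy(), alpha)
    table["selected"] = mask.astype(int)
    table["alpha"] = alpha
    table["threshold"] = phi
    return SelectionResult(table=table, alpha=alpha, threshold=phi)
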