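"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most direct method available
(exhaustive enumeration, explicit matrix inversion, fixed-point
iteration), deliberately sharing no code with the implementation under
test.
"""

from __future__ import annotations

import numpy as np


def ols_normal_equations(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least squares by explicit inversion of the normal equations."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


def coordinate_descent_lasso(
    r: np.ndarray,
    D: np.ndarray,
    weights: np.ndarray,
    sigma: float,
    tol: float = 1e-12,
    max_sweeps: int = 100000,
) -> np.ndarray:
    """Minimize ||r - D b||^2 + 2*sigma*sum_j w_j |b_j| by cyclic coordinate descent."""
    n, p = D.shape
    b = np.zeros(p)
    col_sq = (D**2).sum(axis=0)
    resid = r.copy()
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            old = b[j]
            rho = D[:, j] @ resid + col_sq[j] * old
            thr = sigma * weights[j]
            if rho > thr:
                new = (rho - thr) / col_sq[j]
            elif rho < -thr:
                new = (rho + thr) / col_sq[j]
            else:
                new = 0.0
            if new != old:
                resid -= D[:, j] * (new - old)
                b[j] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return b


def brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of concordant (positive, negative) pairs, ties half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_c_index(pred: np.ndarray, t: np.ndarray, delta: np.ndarray) -> float:
    """Concordance by exhaustive pair enumeration (Harrell's convention)."""
    num = 0.0
    den = 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if t[i] > t[j] and delta[j] == 1:
                den += 1
                if pred[i] > pred[j]:
                    num += 1.0
                elif pred[i] == pred[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def brute_force_promoter_map(probes, genes, upstream: int, downstream: int):
    """All-pairs interval-intersection probe-to-gene assignment.

    ``probes``: iterable of (chrom, start, end, name);
    ``genes``: iterable of (chrom, start, end, name, strand).
    Intervals are 0-based half-open; the promoter covers
    [TSS - upstream, TSS + downstream) reading along the strand.
    """
    entries = []
    for pc, ps, pe, pname in probes:
        pe = max(pe, ps + 1)
        hits = set()
        for gc, gstart, gend, gname, strand in genes:
            if gc != pc:
                continue
            if strand == "+":
                lo, hi = gstart - upstream, gstart + downstream
            else:
                tss = gend - 1
                lo, hi = tss - downstream + 1, tss + upstream + 1
            if ps < hi and lo < pe:  # interval overlap, half-open
                hits.add(gname)
        entries.extend((pname, g) for g in sorted(hits))
    return tuple(entries)
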