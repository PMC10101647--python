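"""Multiple-comparison helper: two-stage linear step-up FDR control.

The Benjamini–Krieger–Yekutieli two-stage procedure first runs the linear
(Benjamini–Hochberg) step-up at the deflated level q′ = q/(1+q) to estimate
the number of true nulls m̂₀ = m − r₁, then — unless the first stage
rejected nothing or everything — reruns the step-up at level q′·m/m̂₀.
This is the correction applied to post-hoc test families downstream of the
pipeline's per-axon tables.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bky_adjust"]


def _step_up_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Linear step-up (BH): reject the k smallest p-values where
    k = max{ i : p(i) ≤ i·alpha/m }."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.nonzero(below)[0].max()) + 1
        reject[order[:k]] = True
    return reject


def bky_adjust(pvalues, q: float = 0.05) -> np.ndarray:
    """Two-stage linear step-up rejection flags at FDR level ``q``.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]
    q : overall false-discovery-rate level, 0 < q < 1.

    Returns
    -------
    ndarray of bool, one flag per input p-value in input order.

    Raises
    ------
    ValueError
        For p-values outside [0, 1] (or non-finite) or q outside (0, 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _step_up_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0 or r1 == m:
        return stage1
    m0_hat = m - r1
    return _step_up_reject(p, q1 * m / m0_hat)
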