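"""PLS1 regression baseline (NIPALS with deflation).

Single-response partial least squares: components are extracted
sequentially as the X-direction of maximal covariance with the residual
response, X is deflated after each component, and the regression
coefficients are assembled as B = W (P'W)^{-1} q. With the full number of
components the fit collapses to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSRModel", "plsr_fit", "plsr_predict"]


@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (p, k) W
    x_loadings: np.ndarray    # (p, k) P
    y_loadings: np.ndarray    # (k,)   q
    x_scores: np.ndarray      # (n, k) T
    coefficients: np.ndarray  # (p,)


def plsr_fit(features: np.ndarray, targets: np.ndarray, n_components: int) -> PLSRModel:
    """Fit PLS1 by sequential NIPALS extraction; deterministic."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n, p = x.shape
    if y.size != n:
        raise ValueError("features and targets must have equal sample counts")
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must lie in [1, {max_rank}] for a {n}x{p} matrix"
        )
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    e = x - x_mean
    f = y - y_mean
    ws, ps, qs, ts = [], [], [], []
    for _ in range(n_components):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual response orthogonal to X: remaining components are null
            w = np.zeros(p)
            t = np.zeros(n)
            ws.append(w); ts.append(t); ps.append(np.zeros(p)); qs.append(0.0)
            continue
        w = w / norm
        t = e @ w
        tt = float(t @ t)
        p_vec = e.T @ t / tt
        q = float(f @ t / tt)
        e = e - np.outer(t, p_vec)
        f = f - q * t
        ws.append(w); ps.append(p_vec); qs.append(q); ts.append(t)
    W = np.column_stack(ws)
    P = np.column_stack(ps)
    q_arr = np.array(qs)
    T = np.column_stack(ts)
    # B = W (P'W)^{-1} q ; pseudo-inverse guards exhausted-rank null components
    coef = W @ np.linalg.pinv(P.T @ W) @ q_arr
    return PLSRModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q_arr,
        x_scores=T,
        coefficients=coef,
    )


def plsr_predict(model: PLSRModel, features: np.ndarray) -> np.ndarray:
    """Predicted response: (X - x_mean) @ B + y_mean."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.x_mean.size:
        raise ValueError(
            f"feature width {x.shape[1]} != fitted width {model.x_mean.size}"
        )
    return (x - model.x_mean) @ model.coefficients + model.y_mean
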