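"""PCA feature extraction with contribution-rate latent-variable selection.

The number of latent variables (LVs) kept is chosen from the cumulative
contribution rate of the leading eigenvalues of the sample covariance:
phi_i = lambda_i / sum(lambda), Phi_k = sum_{i<=k} phi_i, with the smallest
k reaching a threshold (0.95 by default, 0.99 for the high-fidelity
setting) selected. Columns are mean-centered but not variance-scaled: the
contribution rates operate on covariance eigenvalues, and per-spectrum
scaling is the pretreatment stage's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectrumSet

__all__ = ["PCAModel", "fit_pca", "contribution_rates", "select_k", "transform"]


@dataclass
class PCAModel:
    mean_spectrum: np.ndarray   # (p,)
    loadings: np.ndarray        # (p, m) columns orthonormal, eigenvalue order
    eigenvalues: np.ndarray     # (m,) descending, >= 0
    contribution: np.ndarray    # phi_i
    cumulative: np.ndarray      # Phi_k
    m: int                      # total dimensionality of the spectra
    k_selected: int | None = None


def fit_pca(spectra: SpectrumSet | np.ndarray) -> PCAModel:
    """Eigendecomposition of the sample covariance of mean-centered spectra.

    Deterministic up to loading sign; the sign is fixed by making each
    column's largest-magnitude element positive.
    """
    x = spectra.absorbance if isinstance(spectra, SpectrumSet) else np.asarray(spectra)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-magnitude loading element positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    phi, cum = contribution_rates(evals)
    return PCAModel(
        mean_spectrum=mean,
        loadings=evecs,
        eigenvalues=evals,
        contribution=phi,
        cumulative=cum,
        m=p,
    )


def contribution_rates(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-LV contribution rates phi_i = lambda_i / sum(lambda) and their
    cumulative sums Phi_k."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    total = lam.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero; contribution rates undefined")
    phi = lam / total
    return phi, np.cumsum(phi)


def select_k(cumulative: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative contribution rate reaches the threshold."""
    cum = np.asarray(cumulative, dtype=float)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if threshold > cum[-1] + 1e-12:
        raise ValueError(
            f"threshold {threshold} exceeds the total cumulative rate {cum[-1]:.6f}"
        )
    return int(np.argmax(cum >= threshold - 1e-12)) + 1


def transform(
    spectra: SpectrumSet | np.ndarray, model: PCAModel, k: int | None = None
) -> np.ndarray:
    """Project spectra onto the first k loadings: (X - mean) @ L[:, :k]."""
    x = spectra.absorbance if isinstance(spectra, SpectrumSet) else np.asarray(spectra)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if isinstance(spectra, SpectrumSet) and (
        spectra.wavelengths.size != model.mean_spectrum.size
        or x.shape[1] != model.mean_spectrum.size
    ):
        raise ValueError("wavelength grid does not match the fitted model")
    if x.shape[1] != model.mean_spectrum.size:
        raise ValueError("feature width does not match the fitted model")
    if k is None:
        k = model.k_selected if model.k_selected is not None else model.m
    if k < 0 or k > model.loadings.shape[1]:
        raise ValueError(f"k={k} outside [0, {model.loadings.shape[1]}]")
    return (x - model.mean_spectrum) @ model.loadings[:, :k]
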