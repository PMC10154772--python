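"""Reference PCA and least-squares projection of high-missingness samples."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


def encode_genotypes(G: GenotypeMatrix, literal: bool = False) -> np.ndarray:
    """Encode dosages for PCA: hom ref -> +1, het -> 0, hom alt -> -1,
    missing -> NaN.

    ``literal=True`` switches to the alternative mapping hom ref -> +1,
    hom alt -> 0, het -> -1 (heterozygote outside the homozygote interval);
    kept only as an explicit opt-in.
    """
    c = G.counts
    out = np.full(c.shape, np.nan)
    if literal:
        out[c == 0] = 1.0
        out[c == 2] = 0.0
        out[c == 1] = -1.0
    else:
        out[c == 0] = 1.0
        out[c == 1] = 0.0
        out[c == 2] = -1.0
    out[c == MISSING] = np.nan
    return out


@dataclass
class PCAModel:
    snp_means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # M x C, orthonormal columns
    explained_variance: np.ndarray
    reference_scores: np.ndarray  # N x C

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_reference(
    X: np.ndarray,
    n_components: int,
    scale: bool = False,
    max_missing: float = 0.05,
) -> PCAModel:
    """Fit PCA on an encoded reference matrix (samples x SNPs).

    Reference samples must have less than ``max_missing`` missingness;
    missing entries are mean-imputed for the fit only.  Optional scaling
    divides each SNP by ``sqrt(p(1-p))`` derived from its mean encoding.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError("n_components exceeds matrix rank bound")
    miss_frac = np.isnan(X).mean(axis=1)
    if np.any(miss_frac >= max_missing):
        bad = int(np.argmax(miss_frac))
        raise ValueError(
            f"reference sample {bad} has {miss_frac[bad]:.1%} missingness "
            f"(limit {max_missing:.0%})"
        )
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    Xi = np.where(np.isnan(X), col_mean[None, :], X)
    centered = Xi - col_mean[None, :]
    if scale:
        # encoding mean mu = 1 - 2p  =>  p = (1 - mu)/2
        p = np.clip((1.0 - col_mean) / 2.0, 1e-6, 1.0 - 1e-6)
        scales = np.sqrt(p * (1.0 - p))
    else:
        scales = np.ones(m)
    centered = centered / scales[None, :]
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    explained = s[:n_components] ** 2 / max(n - 1, 1)
    return PCAModel(
        snp_means=col_mean,
        scales=scales,
        loadings=loadings,
        explained_variance=explained,
        reference_scores=scores,
    )


def project(model: PCAModel, x: np.ndarray) -> np.ndarray:
    """Least-squares projection of one encoded sample with missingness.

    Solves ``min_s || x_obs - mu_obs - L_obs s ||`` over the sample's
    non-missing SNPs.  Rank-deficient restricted loadings fall back to the
    minimum-norm solution with a warning.
    """
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    if not np.any(obs):
        raise ValueError("cannot project an all-missing sample")
    L = model.loadings[obs]
    b = (x[obs] - model.snp_means[obs]) / model.scales[obs]
    s, _, rank, _ = np.linalg.lstsq(L, b, rcond=None)
    if rank < model.n_components:
        warnings.warn(
            "restricted loadings are rank deficient; minimum-norm projection"
        )
    return s


def project_matrix(model: PCAModel, X: np.ndarray) -> np.ndarray:
    return np.vstack([project(model, row) for row in np.atleast_2d(X)])
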