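"""Maximum-likelihood ancestry estimation under the binomial mixture model.

Genotypes are modelled as ``n_ij ~ Binomial(c_i, p_ij)`` with
``p_ij = sum_k q_ik f_kj``; Q rows live on the simplex and F entries in
[0, 1].  Fitting uses EM block updates of Q and F, which are monotone in the
log-likelihood, with multiple random restarts and optional hold-out
cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotypes import MISSING, GenotypeMatrix

EPS = 1e-9
F_FLOOR = 1e-6  # keeps F away from the boundary during EM


@dataclass
class AdmixtureFit:
    Q: np.ndarray
    F: np.ndarray
    loglik_trace: np.ndarray
    cv_error: float
    n_iter: int
    seed: int | None
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _prepare(G: GenotypeMatrix, haploid_mode: str = "two_copies"):
    """Return (n, c, mask): dosage matrix, per-sample trial counts and the
    non-missing mask.

    ``haploid_mode`` controls pseudo-haploid samples: "two_copies" keeps the
    {0,2} coding as two pseudo-observations (c=2); "single" treats each call
    as one Bernoulli trial (c=1, dosage halved).
    """
    if haploid_mode not in ("two_copies", "single"):
        raise ValueError(f"unknown haploid_mode {haploid_mode!r}")
    n = G.counts.astype(float)
    mask = G.counts != MISSING
    n[~mask] = 0.0
    c = np.full(G.n_samples, 2.0)
    if haploid_mode == "single":
        ph = G.ploidy == "pseudo_haploid"
        n[ph] /= 2.0
        c[ph] = 1.0
    return n, c, mask


def _check_q(Q: np.ndarray, tol: float = 1e-6) -> None:
    if np.any(Q < -tol) or np.any(np.abs(Q.sum(axis=1) - 1.0) > tol):
        raise ValueError("each Q row must lie on the probability simplex")


def admixture_loglik(
    G: GenotypeMatrix,
    Q: np.ndarray,
    F: np.ndarray,
    haploid_mode: str = "two_copies",
) -> float:
    """Binomial log-likelihood (constant binomial coefficient omitted),
    missing entries skipped, p clamped to [eps, 1-eps]."""
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    _check_q(Q)
    n, c, mask = _prepare(G, haploid_mode)
    if Q.shape != (G.n_samples, F.shape[0]) or F.shape[1] != G.n_snps:
        raise ValueError("Q/F dimensions inconsistent with genotype matrix")
    p = np.clip(Q @ F, EPS, 1.0 - EPS)
    ll = n * np.log(p) + (c[:, None] - n) * np.log1p(-p)
    return float(ll[mask].sum())


def _loglik_arrays(n, c, mask, Q, F) -> float:
    p = np.clip(Q @ F, EPS, 1.0 - EPS)
    ll = n * np.log(p) + (c[:, None] - n) * np.log1p(-p)
    return float(ll[mask].sum())


def _fit_single(n, c, mask, K, rng, tol, max_iter, init_q="dirichlet"):
    N, M = n.shape
    if init_q == "dirichlet":
        Q = rng.dirichlet(np.ones(K), size=N)
    elif init_q == "uniform":
        # identical rows: paired samples then differ only through their data
        Q = np.full((N, K), 1.0 / K)
    else:
        raise ValueError(f"unknown init_q {init_q!r}")
    F = rng.uniform(0.05, 0.95, size=(K, M))
    if K == 1:
        # closed form: component frequency is the per-SNP sample frequency
        tot = (c[:, None] * mask).sum(axis=0)
        with np.errstate(invalid="ignore"):
            F = np.where(tot > 0, n.sum(axis=0) / np.maximum(tot, 1.0), 0.5)[None, :]
        Q = np.ones((N, 1))
        ll = _loglik_arrays(n, c, mask, Q, F)
        return Q, F, np.array([ll]), 1, True

    # n is zero at missing entries; zeroing (c - n) there as well removes
    # masked sites from both the likelihood and the EM moments
    cn = np.where(mask, c[:, None] - n, 0.0)
    trace: list[float] = []
    converged = False
    it = 0
    while True:
        P = Q @ F
        np.clip(P, EPS, 1.0 - EPS, out=P)
        ll = float((n * np.log(P)).sum() + (cn * np.log1p(-P)).sum())
        trace.append(ll)
        if it > 0 and ll - trace[-2] < tol:
            converged = True
            break
        if it >= max_iter:
            break
        # EM block update; monotone in the log-likelihood
        R = n / P
        S = cn / (1.0 - P)
        A = (R - S) @ F.T + S.sum(axis=1, keepdims=True)
        Qn = Q * A
        Qn /= Qn.sum(axis=1, keepdims=True)
        num = F * (Q.T @ R)  # K x M expected alt draws
        den = num + (1.0 - F) * (Q.T @ S)
        with np.errstate(invalid="ignore"):
            F = np.where(den > 0, num / np.maximum(den, EPS), F)
        np.clip(F, F_FLOOR, 1.0 - F_FLOOR, out=F)
        Q = Qn
        it += 1
    return Q, F, np.asarray(trace), len(trace) - 1, converged


def fit_admixture(
    G: GenotypeMatrix,
    K: int,
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int | None = None,
    cv_folds: int | None = None,
    haploid_mode: str = "two_copies",
    init_q: str = "dirichlet",
) -> AdmixtureFit:
    """Fit the admixture model with ``n_starts`` random restarts.

    When ``cv_folds`` is given, a hold-out cross-validation error is computed
    for every start and the start with the lowest error is returned (ties
    broken by log-likelihood); otherwise selection is by log-likelihood alone
    and ``cv_error`` is NaN.  Non-convergence is reported via the
    ``converged`` flag, not an exception.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if G.n_samples < K:
        raise ValueError("need at least K samples")
    n, c, mask = _prepare(G, haploid_mode)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_starts)
    best = None
    for start, child in enumerate(children):
        rng = np.random.default_rng(child)
        Q, F, trace, n_iter, conv = _fit_single(
            n, c, mask, K, rng, tol, max_iter, init_q=init_q
        )
        if cv_folds:
            cv = cv_error(
                G, K, folds=cv_folds, seed=int(child.generate_state(1)[0]),
                tol=tol, max_iter=max_iter, haploid_mode=haploid_mode,
            )
        else:
            cv = float("nan")
        fit = AdmixtureFit(Q=Q, F=F, loglik_trace=trace, cv_error=cv,
                           n_iter=n_iter, seed=seed, converged=conv)
        if best is None:
            best = fit
        elif cv_folds:
            if (fit.cv_error, -fit.loglik) < (best.cv_error, -best.loglik):
                best = fit
        elif fit.loglik > best.loglik:
            best = fit
    if not best.converged:
        warnings.warn("admixture EM did not reach tolerance; returning last iterate")
    return best


def cv_error(
    G: GenotypeMatrix,
    K: int,
    folds: int = 5,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    haploid_mode: str = "two_copies",
) -> float:
    """Hold-out cross-validation error.

    Non-missing entries are split into ``folds`` random folds; each fold is
    masked, the model refit, and the mean squared deviation between held-out
    dosages and fitted ``c * p`` accumulated.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n, c, mask = _prepare(G, haploid_mode)
    obs = np.flatnonzero(mask.ravel())
    if len(obs) == 0:
        warnings.warn("no non-missing entries to hold out; cv error defined as 0")
        return 0.0
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, folds, len(obs))
    sq_err = 0.0
    n_held = 0
    for fold in range(folds):
        held = obs[assignment == fold]
        if len(held) == 0:
            continue
        fold_mask = mask.copy()
        fold_mask.ravel()[held] = False
        Q, F, _, _, _ = _fit_single(
            np.where(fold_mask, n, 0.0), c, fold_mask, K, rng, tol, max_iter
        )
        p = np.clip(Q @ F, EPS, 1.0 - EPS)
        pred = (c[:, None] * p).ravel()[held]
        truth = n.ravel()[held]
        sq_err += float(((truth - pred) ** 2).sum())
        n_held += len(held)
    if n_held == 0:
        warnings.warn("no entries were held out; cv error defined as 0")
        return 0.0
    return sq_err / n_held


def align_components(Q_est: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permutation ``perm`` such that ``Q_est[:, perm]`` best matches
    ``Q_ref`` (Hungarian assignment on per-component correlations)."""
    Q_est = np.asarray(Q_est, dtype=float)
    Q_ref = np.asarray(Q_ref, dtype=float)
    if Q_est.shape != Q_ref.shape:
        raise ValueError("Q matrices must share a shape to be aligned")
    K = Q_est.shape[1]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = Q_ref[:, i], Q_est[:, j]
            sa, sb = a.std(), b.std()
            if sa > 0 and sb > 0:
                corr[i, j] = np.corrcoef(a, b)[0, 1]
    _, cols = linear_sum_assignment(-corr)
    return cols
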