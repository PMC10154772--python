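"""F4 / ABBA-BABA statistics with weighted block-jackknife standard errors,
and the Hudson Fst estimator."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class JackknifeResult:
    estimate: float
    stderr: float
    z: float
    n_blocks: int
    block_values: np.ndarray
    block_weights: np.ndarray
    n_snps: int = 0


def _z_score(estimate: float, stderr: float) -> float:
    if stderr > 0:
        return estimate / stderr
    if estimate == 0:
        return 0.0
    return math.copysign(math.inf, estimate)


def weighted_jackknife(
    estimate: float, loo_estimates: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one jackknife standard error.

    Uses the unequal-block-size jackknife variance; with equal weights it
    reduces to ``(n-1)/n * sum((theta_i - mean)^2)`` over the delete-one
    estimates.  Invariant under rescaling of the weights.
    """
    loo = np.asarray(loo_estimates, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(loo)
    if n < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    if np.any(w <= 0):
        raise ValueError("block weights must be positive")
    W = w.sum()
    h = W / w
    theta_j = n * estimate - float(((1.0 - w / W) * loo).sum())
    tau = h * estimate - (h - 1.0) * loo
    var = float(((tau - theta_j) ** 2 / (h - 1.0)).sum()) / n
    return estimate, math.sqrt(max(var, 0.0))


def block_jackknife(
    block_values: np.ndarray, block_weights: np.ndarray
) -> tuple[float, float]:
    """Delete-one jackknife for a weighted mean of per-block statistics."""
    v = np.asarray(block_values, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    if len(v) < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    if np.any(w <= 0):
        raise ValueError("block weights must be positive")
    W = w.sum()
    total = float((w * v).sum())
    estimate = total / W
    loo = (total - w * v) / (W - w)
    return weighted_jackknife(estimate, loo, w)


def allele_frequencies(
    G: GenotypeMatrix, group: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency per SNP within ``group``.

    Returns ``(freq, n_alleles)``; ``freq`` is NaN where the group has no
    data.  Diploid samples contribute two allele observations, pseudo-haploid
    samples one.
    """
    if len(group) == 0:
        raise ValueError("group must be non-empty")
    idx = [G.sample_index(s) for s in group]
    counts = G.counts[idx].astype(float)
    mask = counts != MISSING
    ph = (G.ploidy[idx] == "pseudo_haploid")[:, None]
    alt = np.where(mask, np.where(ph, counts / 2.0, counts), 0.0)
    tot = np.where(mask, np.where(ph, 1.0, 2.0), 0.0)
    n_alleles = tot.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_alleles > 0, alt.sum(axis=0) / n_alleles, np.nan)
    return freq, n_alleles.astype(np.int64)


def _block_ids(index: np.ndarray, block_size: int) -> np.ndarray:
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    return index // block_size


def _blocked_mean_jackknife(values, usable, block_size) -> JackknifeResult:
    """Jackknife for a per-SNP mean over contiguous index blocks."""
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        raise ValueError("no usable SNPs")
    vals = values[idx]
    blocks = _block_ids(idx, block_size)
    uniq, inv = np.unique(blocks, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 blocks with data")
    sums = np.bincount(inv, weights=vals)
    weights = np.bincount(inv).astype(float)
    block_means = sums / weights
    estimate, stderr = block_jackknife(block_means, weights)
    return JackknifeResult(
        estimate=estimate,
        stderr=stderr,
        z=_z_score(estimate, stderr),
        n_blocks=len(uniq),
        block_values=block_means,
        block_weights=weights,
        n_snps=len(idx),
    )


def f4(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    block_size: int = 100,
) -> JackknifeResult:
    """F4 statistic: mean over usable SNPs of ``(a-b)(c-d)`` with a
    delete-one block jackknife over contiguous SNP blocks."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    usable = ~(np.isnan(a) | np.isnan(b) | np.isnan(c) | np.isnan(d))
    values = np.where(usable, (a - b) * (c - d), 0.0)
    return _blocked_mean_jackknife(values, usable, block_size)


def f4_paired_contrast(
    w: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    x: np.ndarray,
    o: np.ndarray,
    block_size: int = 100,
) -> JackknifeResult:
    """Jackknifed difference ``f4(w, y1; x, o) - f4(w, y2; x, o)`` for two
    libraries of the same individual.

    The per-SNP contrast ``(y2 - y1)(x - o)`` is jackknifed directly, so the
    standard error reflects only where the paired libraries disagree rather
    than the (shared) sampling noise of each F4.  SNPs missing in either
    library or in w/x/o are excluded.
    """
    w, y1, y2, x, o = (np.asarray(v, dtype=float) for v in (w, y1, y2, x, o))
    usable = ~(
        np.isnan(w) | np.isnan(y1) | np.isnan(y2) | np.isnan(x) | np.isnan(o)
    )
    values = np.where(usable, (y2 - y1) * (x - o), 0.0)
    return _blocked_mean_jackknife(values, usable, block_size)


def abba_baba(
    h1: np.ndarray,
    h2: np.ndarray,
    h3: np.ndarray,
    outgroup: np.ndarray,
    window: int = 100,
) -> JackknifeResult:
    """ABBA-BABA D statistic on four haploid 0/1 vectors.

    Sites are polarized by the outgroup (its allele is the A state);
    ``D = (nABBA - nBABA) / (nABBA + nBABA)`` with a delete-one jackknife
    over uniform windows of ``window`` SNPs.
    """
    h1, h2, h3, o = (np.asarray(v, dtype=float) for v in (h1, h2, h3, outgroup))
    usable = np.ones(len(h1), dtype=bool)
    for v in (h1, h2, h3, o):
        usable &= np.isin(v, (0.0, 1.0))
    d1, d2, d3 = (np.where(usable, v != o, False) for v in (h1, h2, h3))
    abba = (~d1) & d2 & d3 & usable
    baba = d1 & (~d2) & d3 & usable

    idx = np.arange(len(h1))
    blocks = _block_ids(idx, window)
    uniq = np.unique(blocks)
    n_abba = np.array([abba[blocks == u].sum() for u in uniq], dtype=float)
    n_baba = np.array([baba[blocks == u].sum() for u in uniq], dtype=float)
    num, den = n_abba - n_baba, n_abba + n_baba
    keep = den > 0
    if den.sum() == 0:
        raise ValueError("no ABBA or BABA sites: D statistic undefined")
    num, den = num[keep], den[keep]
    if len(num) < 2:
        raise ValueError("need at least 2 windows with informative sites")
    N, D_tot = num.sum(), den.sum()
    estimate = N / D_tot
    loo = (N - num) / (D_tot - den)
    estimate, stderr = weighted_jackknife(estimate, loo, den)
    return JackknifeResult(
        estimate=float(estimate),
        stderr=stderr,
        z=_z_score(estimate, stderr),
        n_blocks=len(num),
        block_values=num / den,
        block_weights=den,
        n_snps=int(D_tot),
    )


def hudson_fst(
    freq1: np.ndarray,
    n1: np.ndarray,
    freq2: np.ndarray,
    n2: np.ndarray,
) -> float:
    """Hudson Fst, ratio-of-averages form with sample-size correction.

    ``n1``/``n2`` are allele (not individual) counts per SNP.  With a single
    allele observed (haploid library) the frequency is 0 or 1 and the
    within-group correction vanishes.
    """
    p1, p2 = np.asarray(freq1, dtype=float), np.asarray(freq2, dtype=float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    ok = ~(np.isnan(p1) | np.isnan(p2)) & (n1 >= 1) & (n2 >= 1)
    if not np.any(ok):
        raise ValueError("no usable SNPs for Fst")
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
        - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den.sum() == 0:
        raise ValueError("Fst denominator is zero (no variation)")
    return float(num.sum() / den.sum())


def hudson_fst_groups(groups: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Average pairwise Hudson Fst over a list of ``(freq, n_alleles)``."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    vals = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            vals.append(hudson_fst(groups[i][0], groups[i][1],
                                   groups[j][0], groups[j][1]))
    return float(np.mean(vals))
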