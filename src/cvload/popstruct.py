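"""Population differentiation (Weir-Cockerham FST) and genotype PCA.

The FST estimator is the moment estimator of Weir & Cockerham built from
three variance components per site: a (among populations), b (among
individuals within populations) and c (within individuals), with
theta-hat = a / (a + b + c). Per-site theta may be negative; no clamping is
applied. Two genome-wide summaries are reported: the unweighted mean of
per-site theta (the convention of the common command-line tools) and the
better-behaved ratio-of-sums estimate sum(a) / sum(a+b+c).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_store import MISSING, AlleleCounts, GenotypeMatrix, VariantKey

log = logging.getLogger(__name__)

#: Differentiation bins, left-closed right-open: <0.05 less, 0.05-0.15
#: moderate, 0.15-0.25 high, >=0.25 severe.
DIFFERENTIATION_EDGES = (0.05, 0.15, 0.25)


@dataclass
class FstSiteResult:
    key: VariantKey | None
    a: float
    b: float
    c: float
    theta: float | None

    @property
    def defined(self) -> bool:
        return self.theta is not None


@dataclass
class FstSummary:
    """Unweighted mean of per-site theta plus the ratio-of-sums estimate."""

    mean_theta: float
    weighted_theta: float
    n_sites_used: int


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized variance components for sites x populations arrays.

    n: diploid sample sizes, p: allele frequencies, h: observed heterozygote
    frequencies. All shape (sites, r) with r >= 2 populations; callers must
    ensure every n >= 2.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[1]
    nbar = n.sum(axis=1) / r
    nc = (r * nbar - (n**2).sum(axis=1) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=1) / (r * nbar)
    s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=1) / (r * nbar)
    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def wc_fst_site(
    n: Sequence[float], p: Sequence[float], h: Sequence[float], key: VariantKey | None = None
) -> FstSiteResult:
    """Weir-Cockerham variance components and theta-hat for one site.

    Parameters are per-population diploid sample sizes, allele frequencies
    and heterozygote frequencies. Theta is undefined (None) when a+b+c = 0,
    which happens exactly at sites monomorphic with no heterozygotes
    everywhere.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if n.shape[1] < 2:
        raise ValueError("Weir-Cockerham FST needs at least 2 populations")
    if (n < 2).any():
        raise ValueError("every population must contribute n_i >= 2 individuals")
    a, b, c = _wc_components(n, p, h)
    denom = a[0] + b[0] + c[0]
    theta = None if denom == 0 else float(a[0] / denom)
    return FstSiteResult(key=key, a=float(a[0]), b=float(b[0]), c=float(c[0]), theta=theta)


def wc_fst_sites(
    n: np.ndarray,
    p: np.ndarray,
    h: np.ndarray,
    keys: Sequence[VariantKey] | None = None,
) -> pd.DataFrame:
    """Per-site components/theta over many sites at once.

    Sites where any population has n_i < 2 are skipped (NaN row, reason
    recorded) rather than estimated from a single individual.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    ok = (n >= 2).all(axis=1)
    a = np.full(n.shape[0], np.nan)
    b = np.full(n.shape[0], np.nan)
    c = np.full(n.shape[0], np.nan)
    if ok.any():
        a[ok], b[ok], c[ok] = _wc_components(n[ok], p[ok], h[ok])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    reason = np.where(~ok, "n_i<2", np.where(denom == 0, "monomorphic", ""))
    df = pd.DataFrame({"a": a, "b": b, "c": c, "theta": theta, "skip_reason": reason})
    if keys is not None:
        df.insert(0, "chrom", [k.chrom for k in keys])
        df.insert(1, "pos", [k.pos for k in keys])
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("wc_fst_sites: %d sites skipped (some n_i < 2)", n_skipped)
    return df


def fst_from_counts(
    counts: AlleleCounts,
    populations: Sequence[str] | None = None,
    hwe_het: bool = False,
) -> pd.DataFrame:
    """Per-site FST table straight from genotype-derived allele counts.

    Heterozygote frequencies come from the observed genotype tallies; with
    ``hwe_het=True`` (site-level data without genotypes) they are imputed
    under Hardy-Weinberg as 2p(1-p) and the output is flagged.
    """
    pops = list(populations) if populations else list(counts.populations)
    idx = [counts.pop_index(p) for p in pops]
    n = counts.n_called[:, idx].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, counts.alt_count[:, idx] / np.maximum(2 * n, 1), np.nan)
        h = (
            2 * p * (1 - p)
            if hwe_het
            else np.where(n > 0, counts.het[:, idx] / np.maximum(n, 1), np.nan)
        )
    df = wc_fst_sites(n, p, h, keys=counts.variants)
    df["hwe_imputed_het"] = bool(hwe_het)
    return df


def fst_summary(sites) -> FstSummary:
    """Summarize per-site results: unweighted mean and ratio-of-sums theta.

    Undefined sites (monomorphic or skipped) are excluded; negatives are
    kept. Both summaries use the same site set.
    """
    if isinstance(sites, pd.DataFrame):
        a = sites["a"].to_numpy(float)
        b = sites["b"].to_numpy(float)
        c = sites["c"].to_numpy(float)
        theta = sites["theta"].to_numpy(float)
    else:
        rows = list(sites)
        a = np.array([s.a for s in rows], dtype=float)
        b = np.array([s.b for s in rows], dtype=float)
        c = np.array([s.c for s in rows], dtype=float)
        theta = np.array(
            [np.nan if s.theta is None else s.theta for s in rows], dtype=float
        )
    keep = ~np.isnan(theta)
    if not keep.any():
        raise ValueError("no sites with defined theta")
    denom = (a + b + c)[keep].sum()
    return FstSummary(
        mean_theta=float(theta[keep].mean()),
        weighted_theta=float(a[keep].sum() / denom),
        n_sites_used=int(keep.sum()),
    )


def fst_enrichment(deleterious: FstSummary, background: FstSummary) -> float | None:
    """Mean-theta ratio of the deleterious set over the all-SNV background.

    Returns None (and logs) when the background mean is zero.
    """
    if background.mean_theta == 0:
        log.warning("fst_enrichment: background mean theta is zero; ratio undefined")
        return None
    return deleterious.mean_theta / background.mean_theta


def classify_differentiation(theta: float | None) -> str:
    """Bin a per-site theta: less / moderate / high / severe / undefined.

    Bins are left-closed, right-open; 0.05 -> moderate, 0.25 -> severe.
    """
    if theta is None or (isinstance(theta, float) and np.isnan(theta)):
        return "undefined"
    lo, mid, hi = DIFFERENTIATION_EDGES
    if theta < lo:
        return "less"
    if theta < mid:
        return "moderate"
    if theta < hi:
        return "high"
    return "severe"


def percentile_rank(theta: float, background: Sequence[float] | np.ndarray) -> float:
    """'Top X%' rank: share of background sites with strictly greater theta."""
    bg = np.asarray(background, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        raise ValueError("background is empty")
    return float((bg > theta).sum()) / bg.size * 100.0


@dataclass
class PcaResult:
    """Genotype PCA: eigenvalues (descending) and orthonormal sample coordinates."""

    eigenvalues: np.ndarray
    coords: np.ndarray  # samples x k
    samples: list[str]
    site_means: np.ndarray
    site_scales: np.ndarray
    sites_used: list[VariantKey]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])]
        )
        df.insert(0, "sample", self.samples)
        return df


def pca(matrix: GenotypeMatrix, k: int = 10) -> PcaResult:
    """PCA of the normalized dosage matrix (the standard genotype scaling).

    Missing dosages are imputed to the site mean; each site is centered by
    its mean dosage and scaled by sqrt(p(1-p)) with p = mean dosage / 2;
    zero-variance and all-missing sites are dropped. Eigenvalues/coordinates
    come from the sample covariance (1/m) X X^T of the normalized samples x
    sites matrix X.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.dosages.T.astype(float)  # samples x sites
    X[matrix.dosages.T == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    phat = col_mean / 2.0
    keep = np.isfinite(phat) & (phat > 0) & (phat < 1)
    if not keep.any():
        raise ValueError("no polymorphic sites available for PCA")
    X = X[:, keep]
    means = col_mean[keep]
    scales = np.sqrt(phat[keep] * (1 - phat[keep]))
    X = (X - means) / scales
    m = X.shape[1]
    # SVD of X gives the eigensystem of (1/m) X X^T without forming it
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / m
    rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
    if rank == 0:
        raise ValueError("normalized genotype matrix has no variation among samples")
    if k > rank:
        log.warning("pca: k=%d exceeds matrix rank %d; truncating", k, rank)
        k = rank
    return PcaResult(
        eigenvalues=eigvals[:k],
        coords=u[:, :k],
        samples=list(matrix.samples),
        site_means=means,
        site_scales=scales,
        sites_used=[v for v, kp in zip(matrix.variants, keep) if kp],
    )
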