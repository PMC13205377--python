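"""Genomic relationship matrix, REML variance components, and mixed-model GWAS.

Implements the one-random-effect GBLUP model

    y = X b + u + e,    u ~ N(0, G * sigma_u^2),    e ~ N(0, I * sigma_e^2)

where G = W W' / m is the genomic relationship matrix built from the
centered and standardized marker matrix W.  Restricted maximum likelihood
is computed exactly via a single spectral decomposition of G followed by a
one-dimensional search over the variance ratio; the association scan adds
one marker at a time as a fixed effect while holding the null variance
components fixed across markers (the P3D / EMMAX device), which makes a
full-panel scan a single pass of dense linear algebra.

Genomic heritability is reported as h2 = sigma_u^2 / (sigma_u^2 + sigma_e^2),
with a standard error from the inverse expected information and the delta
method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .simdata import GenotypeMatrix

__all__ = [
    "StandardizedMarkers",
    "GRM",
    "VarianceComponents",
    "GWASResult",
    "maf_filter",
    "build_grm",
    "reml_fit",
    "gwas_scan",
]

_LOG10 = np.log(10.0)


class QuantgenError(ValueError):
    """Raised on invalid inputs to the quantitative-genetic routines."""


@dataclass
class StandardizedMarkers:
    """Marker matrix with columns centered by 2p and scaled by sqrt(2p(1-p))."""

    W: np.ndarray
    freq: np.ndarray
    marker_ids: list[str]


@dataclass
class GRM:
    """Genomic relationship matrix G = WW'/m with its eigendecomposition cache."""

    values: np.ndarray
    n_markers: int
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, clipped at 0) and eigenvectors of G.

        Computed once and cached; REML and the GWAS scan share it.
        """
        if self._eig is None:
            d, U = linalg.eigh(self.values)
            if d.min() < -1e-8 * max(d.max(), 1.0):
                raise QuantgenError(
                    f"G is not positive semidefinite (min eigenvalue {d.min():.3g})"
                )
            self._eig = (np.clip(d, 0.0, None), U)
        return self._eig


@dataclass
class VarianceComponents:
    """REML estimates for the one-random-effect GBLUP model."""

    sigma2_u: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    beta: np.ndarray
    boundary: bool

    @property
    def ratio(self) -> float:
        """Variance ratio lambda = sigma_u^2 / sigma_e^2."""
        return self.sigma2_u / self.sigma2_e


@dataclass
class GWASResult:
    """Per-marker effects, Wald p-values and the -log10(p) ranking.

    ``table`` has one row per tested marker with columns
    ``marker_id, effect, se, p, neglog10p, rank, flag``; rank 1 is the most
    significant marker.  Ties in -log10(p) break by marker index (scan
    order), so rankings are deterministic.
    """

    table: pd.DataFrame

    def top(self, k: int) -> list[str]:
        """Marker ids of the ``k`` most significant markers."""
        t = self.table.sort_values("rank")
        return t["marker_id"].head(k).tolist()


def maf_filter(geno: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Remove markers whose minor allele frequency is strictly below ``threshold``.

    A marker with MAF exactly equal to the threshold is retained.  Marker
    order is preserved.
    """
    p = geno.allele_freq
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= threshold
    if not keep.any():
        raise QuantgenError("MAF filter removed every marker")
    return GenotypeMatrix(
        codes=geno.codes[:, keep],
        animal_ids=list(geno.animal_ids),
        marker_ids=[m for m, k in zip(geno.marker_ids, keep) if k],
    )


def build_grm(geno: GenotypeMatrix) -> tuple[StandardizedMarkers, GRM]:
    """Standardize markers by observed frequencies and form G = WW'/m.

    Column j of W is (codes_j - 2 p_j) / sqrt(2 p_j (1 - p_j)) with p_j the
    observed allele frequency.  Monomorphic columns have zero variance and
    must be removed by :func:`maf_filter` first.
    """
    codes = np.asarray(geno.codes, dtype=np.float64)
    p = codes.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    if np.any(scale == 0.0):
        bad = [geno.marker_ids[j] for j in np.nonzero(scale == 0.0)[0][:5]]
        raise QuantgenError(f"zero-variance marker column(s), e.g. {bad}; filter first")
    W = (codes - 2.0 * p) / scale
    m = W.shape[1]
    G = (W @ W.T) / m
    return StandardizedMarkers(W=W, freq=p, marker_ids=list(geno.marker_ids)), GRM(G, m)


def _profiled_reml(loglam: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profiled restricted log-likelihood at log variance ratio ``loglam``.

    Returns (loglik, beta, sigma2_e).  All quantities are computed in the
    eigenbasis of G, where H = lam*D + I is diagonal.
    """
    n, p = Xt.shape
    lam = np.exp(loglam)
    h = lam * d + 1.0
    hinv = 1.0 / h
    XtH = Xt * hinv[:, None]
    A = Xt.T @ XtH
    b = np.linalg.solve(A, XtH.T @ yt)
    r = yt - Xt @ b
    rss = float(r @ (hinv * r))
    s2e = rss / (n - p)
    sign, logdetA = np.linalg.slogdet(A)
    _, logdetXX = np.linalg.slogdet(Xt.T @ Xt)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * s2e) + 1.0)
        + float(np.sum(np.log(h)))
        + logdetA
        - logdetXX
    )
    return ll, b, s2e


def _h2_se(s2u: float, s2e: float, Xt: np.ndarray, d: np.ndarray) -> float:
    """Delta-method SE of h2 from the expected REML information on (s2u, s2e)."""
    v = s2u * d + s2e
    vinv = 1.0 / v
    XtV = Xt * vinv[:, None]
    A = Xt.T @ XtV
    P = np.diag(vinv) - XtV @ np.linalg.solve(A, XtV.T)
    PD = P * d[None, :]  # P @ diag(d)
    i11 = 0.5 * float(np.sum(PD * PD.T))
    i12 = 0.5 * float(np.sum(PD * P))  # P symmetric
    i22 = 0.5 * float(np.sum(P * P))
    info = np.array([[i11, i12], [i12, i22]])
    cov = np.linalg.pinv(info)
    s = s2u + s2e
    grad = np.array([s2e, -s2u]) / s**2
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    G: GRM | np.ndarray,
    *,
    loglam_bounds: tuple[float, float] = (-10.0, 10.0),
) -> VarianceComponents:
    """REML variance components and genomic heritability under GBLUP.

    Parameters
    ----------
    y : phenotype vector, one record per animal (Z = I).
    X : fixed-effect design including the intercept column; must be full
        column rank.
    G : genomic relationship matrix (``GRM`` or plain array).

    The restricted likelihood is profiled down to the single variance ratio
    lambda = sigma_u^2/sigma_e^2 and maximized by bounded scalar search on
    log(lambda); the bounds act as boundary estimates (h2 ~ 0 or ~ 1) and
    are flagged when attained.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = y.size
    if X.shape[0] != n:
        raise QuantgenError(f"X has {X.shape[0]} rows for {n} phenotypes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise QuantgenError("fixed-effect design X is rank deficient")
    grm = G if isinstance(G, GRM) else GRM(np.asarray(G, dtype=np.float64), 0)
    if grm.values.shape != (n, n):
        raise QuantgenError("G dimension does not match phenotype vector")
    d, U = grm.eig()
    yt = U.T @ y
    Xt = U.T @ X

    def neg(loglam: float) -> float:
        return -_profiled_reml(loglam, yt, Xt, d)[0]

    lo, hi = loglam_bounds
    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    candidates = [(neg(lo), lo, True), (neg(hi), hi, True), (res.fun, res.x, False)]
    fbest, loglam, boundary = min(candidates, key=lambda c: c[0])
    # the bounded search can also park at a bound without flagging
    boundary = boundary or min(loglam - lo, hi - loglam) < 1e-4

    ll, beta, s2e = _profiled_reml(loglam, yt, Xt, d)
    lam = np.exp(loglam)
    s2u = lam * s2e
    h2 = s2u / (s2u + s2e)
    se = _h2_se(s2u, s2e, Xt, d)
    return VarianceComponents(
        sigma2_u=float(s2u),
        sigma2_e=float(s2e),
        h2=float(h2),
        se_h2=se,
        loglik=float(ll),
        beta=beta,
        boundary=bool(boundary),
    )


def gwas_scan(
    y: np.ndarray,
    X: np.ndarray,
    geno: GenotypeMatrix,
    G: GRM | np.ndarray | None = None,
    vc: VarianceComponents | None = None,
) -> GWASResult:
    """Single-marker mixed-model scan with null components held fixed.

    The GBLUP variance components are estimated once under the null model
    (no marker term) and the resulting variance ratio is reused for every
    marker; each marker then enters as one extra fixed effect estimated by
    generalized least squares, with a Wald t-test on residual degrees of
    freedom.  Markers collinear with the fixed effects get p = 1 and a flag.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, p = X.shape
    if G is None:
        _, G = build_grm(geno)
    grm = G if isinstance(G, GRM) else GRM(np.asarray(G, dtype=np.float64), 0)
    if vc is None:
        vc = reml_fit(y, X, grm)
    d, U = grm.eig()
    lam = vc.sigma2_u / vc.sigma2_e
    w = 1.0 / np.sqrt(lam * d + 1.0)

    yt = w * (U.T @ y)
    Xt = w[:, None] * (U.T @ X)
    codes = np.asarray(geno.codes, dtype=np.float64)
    Mc = codes - codes.mean(axis=0)  # center; intercept is in X
    Mt = w[:, None] * (U.T @ Mc)

    Q, _ = np.linalg.qr(Xt)
    ytr = yt - Q @ (Q.T @ yt)
    Mtr = Mt - Q @ (Q.T @ Mt)

    den = np.einsum("ij,ij->j", Mtr, Mtr)
    tot = float(ytr @ ytr)
    df = n - p - 1
    ok = den > 1e-10 * n
    den_safe = np.where(ok, den, 1.0)
    eff = (Mtr.T @ ytr) / den_safe
    rss = np.maximum(tot - eff**2 * den_safe, 0.0)
    sig2 = rss / df
    se = np.sqrt(sig2 / den_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, eff / se, 0.0)
    # -log10 p from the log survival function to keep precision at tiny p
    logp = np.log(2.0) + stats.t.logsf(np.abs(tstat), df)
    logp = np.minimum(logp, 0.0)
    neglog10p = -logp / _LOG10
    pval = np.exp(logp)

    eff = np.where(ok, eff, 0.0)
    se = np.where(ok, se, np.nan)
    pval = np.where(ok, pval, 1.0)
    neglog10p = np.where(ok, neglog10p, 0.0)

    order = np.lexsort((np.arange(len(pval)), -neglog10p))
    rank = np.empty(len(pval), dtype=np.int64)
    rank[order] = np.arange(1, len(pval) + 1)
    table = pd.DataFrame(
        {
            "marker_id": geno.marker_ids,
            "effect": eff,
            "se": se,
            "p": pval,
            "neglog10p": neglog10p,
            "rank": rank,
            "flag": np.where(ok, "", "collinear"),
        }
    )
    return GWASResult(table=table)
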