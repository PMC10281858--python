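"""Set-based linear mixed model: kernels, REML variance components, LRT.

For a neighborhood with per-sample feature rows l_i (the aggregated SNP
dosages), the model is

    y = Xf beta_f + u + eps,   u ~ N(0, sigma_s^2 Ks),  eps ~ N(0, sigma_e^2 I)

where Ks is a linear (l_i . l_j) or inhomogeneous quadratic ((1 + l_i . l_j)^2)
kernel over samples, rescaled to unit diagonal. The association statistic is
the likelihood-ratio between the restricted maximum likelihood (REML) fits of
the alternative (sigma_s^2 >= 0 free) and the null (sigma_s^2 = 0).

The REML fit eigendecomposes the kernel once, rotates y and Xf into the
eigenbasis and optimizes the single variance ratio delta = sigma_e^2/sigma_s^2
with closed-form profiled variance and fixed effects, so each set costs
O(n * ns^2) like the FaST-LMM family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

LOG10_DELTA_BOUNDS = (-8.0, 8.0)
DELTA_XATOL = 1e-6
_EIG_REL_TOL = 1e-12


class UntestableNeighborhood(Exception):
    """Raised when a neighborhood has no usable SNP signal (ns = 0 or a
    degenerate all-zero kernel)."""


class SetTestError(Exception):
    """Raised on numerical failure (non-finite restricted likelihood)."""


@dataclass
class KernelMatrix:
    """An n x n SNP-set similarity matrix over samples."""

    values: np.ndarray
    kind: str  # 'linear' or 'poly'
    normalized: bool = False


@dataclass
class LmmFit:
    """REML estimates for one (neighborhood, phenotype) fit."""

    sigma_s2: float
    sigma_e2: float
    beta_f: np.ndarray
    restricted_ll: float
    converged: bool


@dataclass
class SetStatistic:
    """Likelihood-ratio statistic for one neighborhood."""

    gene_id: str
    t: float
    ns: int


# ---------------------------------------------------------------------------
# design and kernels


def build_design(features, dataset, assignment=None, standardize: bool = True) -> np.ndarray:
    """Per-sample feature matrix L (n x ns) for one neighborhood.

    ``assignment`` maps each slot to the genotype column currently occupying
    it (identity when None — the observed, unrotated pass). With
    ``standardize`` each column is scaled to mean 0, variance 1; constant
    columns are zeroed.
    """
    if features.ns == 0:
        raise UntestableNeighborhood(
            f"neighborhood of {features.gene_id!r} contains no SNPs"
        )
    if assignment is None:
        cols = features.snp_slots
    else:
        cols = np.array([assignment[int(s)] for s in features.snp_slots], dtype=int)
    L = dataset.dosages[:, cols].astype(float)
    if standardize:
        mu = L.mean(axis=0)
        sd = L.std(axis=0)
        nz = sd > 0
        L = L - mu
        L[:, nz] /= sd[nz]
        L[:, ~nz] = 0.0
    return L


def compute_kernel(L: np.ndarray, kind: str = "linear") -> KernelMatrix:
    """Linear (inner product) or inhomogeneous quadratic sample-similarity kernel."""
    L = np.asarray(L, dtype=float)
    if not np.isfinite(L).all():
        raise ValueError("design matrix contains non-finite values")
    gram = L @ L.T
    if kind == "linear":
        values = gram
    elif kind == "poly":
        values = (1.0 + gram) ** 2
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return KernelMatrix(values=values, kind=kind, normalized=False)


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Rescale to unit diagonal: K_ij / sqrt(K_ii K_jj).

    Rows/columns with a zero raw diagonal are set to zero (diagonal included)
    and the event is logged — such samples carry no set signal.
    """
    V = np.asarray(K.values, dtype=float)
    d = np.diag(V).copy()
    pos = d > 0
    scale = np.zeros_like(d)
    scale[pos] = 1.0 / np.sqrt(d[pos])
    out = V * np.outer(scale, scale)
    np.fill_diagonal(out, np.where(pos, 1.0, 0.0))
    if not pos.all():
        logger.info("kernel has %d zero-diagonal samples; zeroed", int((~pos).sum()))
    return KernelMatrix(values=out, kind=K.kind, normalized=True)


# ---------------------------------------------------------------------------
# REML


def _check_fixed_effects(y: np.ndarray, Xf: np.ndarray):
    y = np.asarray(y, dtype=float).ravel()
    Xf = np.atleast_2d(np.asarray(Xf, dtype=float))
    if Xf.shape[0] != y.shape[0]:
        Xf = Xf.T
    n, nf = Xf.shape
    if y.shape[0] != n:
        raise ValueError("y and Xf have incompatible shapes")
    if n <= nf:
        raise ValueError(f"need n > nf, got n={n}, nf={nf}")
    if np.linalg.matrix_rank(Xf) < nf:
        raise ValueError("fixed-effect matrix Xf is rank deficient")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    return y, Xf


def reml_fit_null(y, Xf) -> LmmFit:
    """Null model (sigma_s^2 = 0): OLS fixed effects, REML residual variance.

    sigma_e^2 = RSS / (n - nf); the restricted log-likelihood is the standard
    REML expression, in the same convention as the alternative fit so the two
    are directly comparable.
    """
    y, Xf = _check_fixed_effects(y, Xf)
    n, nf = Xf.shape
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    resid = y - Xf @ beta
    rss = float(resid @ resid)
    dof = n - nf
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        raise SetTestError("null model has (near-)zero residual variance")
    sigma_e2 = rss / dof
    ll = -0.5 * dof * (np.log(2 * np.pi * sigma_e2) + 1.0)
    return LmmFit(
        sigma_s2=0.0,
        sigma_e2=sigma_e2,
        beta_f=beta,
        restricted_ll=float(ll),
        converged=True,
    )


class _RemlProfile:
    """Profiled restricted likelihood over the variance ratio delta.

    Covariance is parameterized as sigma^2 (K + delta I) with
    sigma_s^2 = sigma^2 and sigma_e^2 = sigma^2 * delta. The kernel is
    eigendecomposed once; eigenvalues below a relative tolerance are treated
    as exactly zero and handled through the complement-space identities, so
    low-rank (ns < n) kernels cost O(n ns^2).
    """

    def __init__(self, y: np.ndarray, Xf: np.ndarray, lam: np.ndarray, U1: np.ndarray):
        self.n, self.nf = Xf.shape
        self.dof = self.n - self.nf
        self.lam = lam
        self.rank = len(lam)
        self.U1y = U1.T @ y
        self.U1X = U1.T @ Xf
        self.yty = float(y @ y)
        self.Xty = Xf.T @ y
        self.XtX = Xf.T @ Xf
        sign, self.logdet_XtX = np.linalg.slogdet(self.XtX)
        if sign <= 0:
            raise SetTestError("Xf'Xf is singular")
        # complement-space moments (exact zeros when the kernel is full rank)
        self.cXtX = self.XtX - self.U1X.T @ self.U1X
        self.cXty = self.Xty - self.U1X.T @ self.U1y
        self.cyty = self.yty - float(self.U1y @ self.U1y)

    def loglik(self, log10_delta: float):
        """Restricted log-likelihood maximized over sigma^2 and beta at this delta.

        Returns (ll, sigma2, beta).
        """
        delta = 10.0 ** log10_delta
        w1 = 1.0 / (self.lam + delta)
        XtHiX = (self.U1X.T * w1) @ self.U1X + self.cXtX / delta
        XtHiy = (self.U1X.T * w1) @ self.U1y + self.cXty / delta
        yHiy = float(self.U1y @ (w1 * self.U1y)) + self.cyty / delta
        try:
            beta = np.linalg.solve(XtHiX, XtHiy)
        except np.linalg.LinAlgError:
            return -np.inf, np.nan, None
        quad = yHiy - float(XtHiy @ beta)
        if quad <= 0 or not np.isfinite(quad):
            return -np.inf, np.nan, None
        sigma2 = quad / self.dof
        logdet_H = float(np.log(self.lam + delta).sum()) + (self.n - self.rank) * np.log(delta)
        sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return -np.inf, np.nan, None
        ll = -0.5 * (
            self.dof * (np.log(2 * np.pi * sigma2) + 1.0)
            + logdet_H
            + logdet_XtHiX
            - self.logdet_XtX
        )
        return float(ll), sigma2, beta


def _eig_from_kernel(V: np.ndarray):
    """Nonzero eigenpairs of a PSD kernel (ascending eigh, small/negative
    eigenvalues treated as exact zeros)."""
    w, U = np.linalg.eigh(V)
    keep = w > max(w[-1], 0.0) * _EIG_REL_TOL
    return w[keep], U[:, keep]


def _eig_from_normalized_design(L: np.ndarray):
    """Nonzero eigenpairs of the unit-diagonal linear kernel, without forming it.

    The normalized kernel is B B' with B = diag(1/||l_i||) L (zero rows for
    samples with no signal), so its spectrum comes from an economy SVD of B —
    O(n ns^2) instead of O(n^3).
    """
    d = np.einsum("ij,ij->i", L, L)
    scale = np.zeros_like(d)
    nz = d > 0
    scale[nz] = 1.0 / np.sqrt(d[nz])
    B = L * scale[:, None]
    U, s, _ = np.linalg.svd(B, full_matrices=False)
    lam = s**2
    keep = lam > max(float(lam[0]) if len(lam) else 0.0, 0.0) * _EIG_REL_TOL
    return lam[keep], U[:, keep]


def _fit_alt_from_eig(y, Xf, lam, U1) -> LmmFit:
    """Grid + Brent optimization of the profiled REML over delta, with the
    sigma_s^2 = 0 boundary evaluated explicitly (ties go to the null)."""
    prof = _RemlProfile(y, Xf, lam, U1)
    lo, hi = LOG10_DELTA_BOUNDS
    grid = np.linspace(lo, hi, 33)
    lls = np.array([prof.loglik(g)[0] for g in grid])
    if not np.isfinite(lls).any():
        raise SetTestError("restricted likelihood non-finite across delta grid")
    best = int(np.argmax(lls))
    blo = grid[max(0, best - 1)]
    bhi = grid[min(len(grid) - 1, best + 1)]
    res = minimize_scalar(
        lambda g: -prof.loglik(g)[0],
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": DELTA_XATOL},
    )
    candidates = [grid[best], float(res.x)]
    ll_best, g_best = -np.inf, None
    for g in candidates:
        ll, _, _ = prof.loglik(g)
        if ll > ll_best:
            ll_best, g_best = ll, g
    ll, sigma2, beta = prof.loglik(g_best)
    null_fit = reml_fit_null(y, Xf)
    tie_tol = 1e-9 * (1.0 + abs(null_fit.restricted_ll))
    if not np.isfinite(ll) or ll <= null_fit.restricted_ll + tie_tol:
        # boundary sigma_s^2 = 0 wins (ties broken toward the null)
        return LmmFit(
            sigma_s2=0.0,
            sigma_e2=null_fit.sigma_e2,
            beta_f=null_fit.beta_f,
            restricted_ll=null_fit.restricted_ll,
            converged=True,
        )
    delta = 10.0 ** g_best
    return LmmFit(
        sigma_s2=float(sigma2),
        sigma_e2=float(sigma2 * delta),
        beta_f=beta,
        restricted_ll=float(ll),
        converged=bool(res.success),
    )


def reml_fit_alt(y, Xf, K: KernelMatrix) -> LmmFit:
    """Alternative model: REML over sigma_s^2 >= 0, sigma_e^2 > 0.

    Eigendecomposes the kernel once, then optimizes the variance ratio
    delta = sigma_e^2/sigma_s^2 on log10 delta in [-8, 8] (coarse grid to
    bracket, Brent to polish) with closed-form profiled sigma^2 and beta_f.
    Raises :class:`UntestableNeighborhood` for an all-zero kernel and
    :class:`SetTestError` on numerical failure.
    """
    y, Xf = _check_fixed_effects(y, Xf)
    V = np.asarray(K.values, dtype=float)
    if not np.isfinite(V).any() or np.abs(V).max() == 0.0:
        raise UntestableNeighborhood("kernel is identically zero")
    lam, U1 = _eig_from_kernel(V)
    return _fit_alt_from_eig(y, Xf, lam, U1)


def lrt_statistic(fit_alt: LmmFit, fit_null: LmmFit, gene_id: str = "", ns: int = 0) -> SetStatistic:
    """t = max(0, 2 * (ll_alt - ll_null)); the clip absorbs the sigma_s^2 = 0
    boundary and tiny numerical deficits."""
    if not (np.isfinite(fit_alt.restricted_ll) and np.isfinite(fit_null.restricted_ll)):
        raise SetTestError("non-finite restricted likelihood in LRT")
    t = max(0.0, 2.0 * (fit_alt.restricted_ll - fit_null.restricted_ll))
    return SetStatistic(gene_id=gene_id, t=float(t), ns=int(ns))


def set_statistic(
    y, Xf, L, kernel_kind: str, gene_id: str = "", fit_null: LmmFit | None = None
) -> SetStatistic:
    """Kernel -> normalization -> REML alt/null -> LRT for one design.

    The null fit depends only on (y, Xf); pass a precomputed one when scoring
    many neighborhoods against the same phenotype. The linear kernel skips the
    explicit n x n matrix via an economy SVD of the normalized design.
    """
    y, Xf = _check_fixed_effects(y, Xf)
    if np.abs(L).max() == 0.0 and kernel_kind == "linear":
        raise UntestableNeighborhood("normalized kernel is identically zero")
    if kernel_kind == "linear":
        lam, U1 = _eig_from_normalized_design(np.asarray(L, dtype=float))
        if len(lam) == 0:
            raise UntestableNeighborhood("normalized kernel is identically zero")
        fit_alt = _fit_alt_from_eig(y, Xf, lam, U1)
    else:
        K = normalize_kernel(compute_kernel(L, kernel_kind))
        if np.abs(K.values).max() == 0.0:
            raise UntestableNeighborhood("normalized kernel is identically zero")
        fit_alt = reml_fit_alt(y, Xf, K)
    if fit_null is None:
        fit_null = reml_fit_null(y, Xf)
    return lrt_statistic(fit_alt, fit_null, gene_id=gene_id, ns=L.shape[1])
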