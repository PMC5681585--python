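"""One-variance-component linear mixed model for cis-SNP set testing.

The model is  e = X b + Z beta + eps  with  beta ~ N(0, tau^2 I_p)  and
eps ~ N(0, sigma^2 I_n), so  e ~ N(X b, sigma^2 (lambda Z Z' + I_n))  with
lambda = tau^2 / sigma^2.  Everything here works in the eigenbasis of the
covariate-projected genotype cross-product, which reduces the restricted
likelihood to a cheap one-dimensional function of lambda and makes both the
fit and the simulation-based null fast.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "CovariateMatrix",
    "ExpressionVector",
    "SpectralDecomposition",
    "RemlFit",
    "WeightsVector",
    "spectral_decompose",
    "restricted_loglik",
    "fit_reml",
    "score_test",
    "blue_weights",
    "lambda_grid",
    "batch_lrt",
]

#: eigenvalues below EIG_TOL * max(eig) are treated as exactly zero
EIG_TOL = 1e-8
#: LRT statistics below this are snapped to the boundary value 0
ZERO_TOL = 1e-8

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix plus variant metadata.

    ``variants`` is a DataFrame with columns ``id, chrom, pos, ref, alt``
    (positions 1-based).  Dosages must lie in [0, 2]; NaNs are allowed on
    construction and resolved by :meth:`impute_missing`.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        n, p = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample IDs for {n} dosage rows")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant records for {p} dosage columns")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table missing columns: {missing_cols}")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant ID: {dup!r}")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def impute_missing(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-variant mean."""
        if not np.isnan(self.dosages).any():
            return self
        d = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return GenotypeMatrix(self.samples, self.variants.reset_index(drop=True), d)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, min(f, 1 - f) with f = mean/2."""
        f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def take_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.samples,
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def reorder_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variants, self.dosages[idx, :])


@dataclass
class CovariateMatrix:
    """n x q fixed-effect design (an intercept is appended internally later)."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("covariates must form a 2-D matrix")
        if not self.names:
            self.names = [f"cov{i}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("covariate names do not match the number of columns")


@dataclass
class ExpressionVector:
    """Length-n continuous phenotype aligned to the genotype samples."""

    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.samples) != self.values.size:
            raise ValueError("sample IDs do not match the phenotype length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype contains non-finite values")


@dataclass
class SpectralDecomposition:
    """Eigen-representation of Z' P0 Z plus the phenotype in the rotated basis.

    ``xi`` holds the K nonzero eigenvalues (descending), ``u`` the first K
    components of the rotated phenotype; the remaining n - q - K components
    enter only through their sum of squares ``tail_ss``.  ``rss`` is the
    full residual sum of squares ||P0 e||^2 = sum(u^2) + tail_ss.
    """

    xi: np.ndarray
    u: np.ndarray
    rss: float
    dof: int
    total_ss: float = 1.0
    _rot: np.ndarray | None = None  # K x n rotation for new vectors
    _q2: np.ndarray | None = None  # n x (n-q) orthonormal complement of X
    _zsvd: tuple | None = None  # (Uz, sz) economy SVD of raw Z
    _X: np.ndarray | None = None
    _Z: np.ndarray | None = None
    _e: np.ndarray | None = None

    @property
    def K(self) -> int:
        return int(self.xi.size)

    @property
    def tail_ss(self) -> float:
        return float(self.rss - np.sum(self.u**2))

    def fingerprint(self) -> str:
        """Stable hash of the eigenvalue spectrum (identifies the SNP set)."""
        h = hashlib.sha1()
        h.update(np.round(self.xi, 6).tobytes())
        h.update(str(self.dof).encode())
        return h.hexdigest()[:12]

    def rotate(self, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rotate phenotype vectors (n x m) into (m x K squared heads, m tails)."""
        if self._rot is None or self._q2 is None:
            raise ValueError("decomposition was built without a rotation basis")
        E = np.atleast_2d(np.asarray(E, dtype=float))
        if E.shape[0] != self._q2.shape[0]:
            E = E.T
        heads = self._rot @ E  # K x m
        proj_ss = np.sum((self._q2.T @ E) ** 2, axis=0)
        tails = proj_ss - np.sum(heads**2, axis=0)
        return (heads.T**2, np.maximum(tails, 0.0))


@dataclass
class RemlFit:
    """REML estimate of the variance-component model and the LRT statistic."""

    lambda_hat: float
    sigma2_hat: float
    tau2_hat: float
    h2: float
    loglik_alt: float
    loglik_null: float
    T: float
    b_hat: np.ndarray | None
    converged: bool
    iterations: int


@dataclass
class WeightsVector:
    """Per-variant BLUE effect estimates for one gene, keyed by variant + alleles."""

    gene_id: str
    variants: pd.DataFrame
    beta: np.ndarray
    lambda_hat: float
    h2: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if len(self.variants) != self.beta.size:
            raise ValueError("weights do not match the variant records")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite weight")


# ---------------------------------------------------------------------------
# spectral decomposition
# ---------------------------------------------------------------------------


def _design_with_intercept(X: CovariateMatrix | None, n: int) -> np.ndarray:
    """Internal fixed-effect design: user covariates plus an intercept column."""
    if X is None:
        return np.ones((n, 1))
    V = X.values
    if V.shape[0] != n:
        raise ValueError("covariate rows do not match the sample count")
    # skip the intercept if a constant column is already present
    has_const = np.any(np.all(V == V[0, :], axis=0) & (np.abs(V[0, :]) > 0))
    if has_const:
        return V.copy()
    return np.column_stack([np.ones(n), V])


def _check_full_rank(Xd: np.ndarray, names: list[str]) -> None:
    n, q = Xd.shape
    if n <= q:
        raise ValueError(f"need more samples ({n}) than fixed-effect columns ({q})")
    _, r = np.linalg.qr(Xd)
    diag = np.abs(np.diag(r))
    bad = np.flatnonzero(diag <= 1e-10 * max(diag.max(), 1.0))
    if bad.size:
        labels = [names[i] if i < len(names) else f"col{i}" for i in bad]
        raise ValueError(f"covariate matrix is rank deficient; dependent columns: {labels}")


def spectral_decompose(
    Z: GenotypeMatrix | np.ndarray,
    X: CovariateMatrix | None,
    e: ExpressionVector | np.ndarray,
) -> SpectralDecomposition:
    """Eigen-decompose Z' P0 Z and express the phenotype in that basis.

    P0 projects orthogonally to the span of the fixed-effect design (user
    covariates plus an internal intercept).  Returns eigenvalues in
    descending order and the rotated phenotype; ties keep the numerical
    ordering of the SVD, which is deterministic for fixed input.
    """
    Zd = Z.dosages if isinstance(Z, GenotypeMatrix) else np.asarray(Z, dtype=float)
    ev = e.values if isinstance(e, ExpressionVector) else np.asarray(e, dtype=float).ravel()
    n, p = Zd.shape
    if ev.size != n:
        raise ValueError("phenotype length does not match the genotype sample count")
    if isinstance(Z, GenotypeMatrix) and isinstance(e, ExpressionVector):
        if Z.samples != e.samples:
            raise ValueError("genotype and expression sample IDs are not aligned")

    names = ["intercept"] + (X.names if X is not None else [])
    Xd = _design_with_intercept(X, n)
    _check_full_rank(Xd, names)
    q = Xd.shape[1]

    Qfull, _ = np.linalg.qr(Xd, mode="complete")
    Q2 = Qfull[:, q:]  # n x (n - q) orthonormal complement

    A = Q2.T @ Zd  # (n-q) x p
    if p == 0 or not np.any(A):
        xi = np.empty(0)
        rot = np.empty((0, n))
        u = np.empty(0)
    else:
        Ua, s, _ = np.linalg.svd(A, full_matrices=False)
        xi_all = s**2
        K = int(np.sum(xi_all > EIG_TOL * xi_all[0])) if xi_all.size else 0
        xi = xi_all[:K]
        rot = Ua[:, :K].T @ Q2.T  # K x n
        u = rot @ ev

    pe = Q2.T @ ev
    rss = float(pe @ pe)
    total_ss = float(ev @ ev)

    if p:
        Uz, sz, _ = np.linalg.svd(Zd, full_matrices=False)
    else:
        Uz, sz = np.empty((n, 0)), np.empty(0)

    return SpectralDecomposition(
        xi=xi,
        u=u,
        rss=rss,
        dof=n - q,
        total_ss=total_ss,
        _rot=rot,
        _q2=Q2,
        _zsvd=(Uz, sz),
        _X=Xd,
        _Z=Zd,
        _e=ev,
    )


# ---------------------------------------------------------------------------
# restricted likelihood and the shared lambda search
# ---------------------------------------------------------------------------


def _check_nondegenerate(sd: SpectralDecomposition) -> None:
    if sd.rss <= 1e-12 * max(sd.total_ss, 1e-300):
        raise ValueError("degenerate phenotype: zero residual after covariate projection")


def restricted_loglik(sd: SpectralDecomposition, lam: float) -> float:
    """Restricted log-likelihood profiled over sigma^2 at signal-to-noise lam."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    _check_nondegenerate(sd)
    denom = 1.0 + lam * sd.xi
    s2 = (np.sum(sd.u**2 / denom) + sd.tail_ss) / sd.dof
    return -0.5 * (sd.dof * np.log(2 * np.pi * s2) + np.sum(np.log(denom)) + sd.dof)


def lambda_grid(n_points: int = 101, lo: float = -5.0, hi: float = 5.0) -> np.ndarray:
    """Shared search grid: lambda = 0 plus a log10 grid on [lo, hi]."""
    return np.concatenate([[0.0], np.logspace(lo, hi, n_points)])


def _criterion_at(
    xi: np.ndarray, U2: np.ndarray, tails: np.ndarray, dof: int, lam: np.ndarray
) -> np.ndarray:
    """T(lambda) = dof*log(S0/S(lambda)) - sum log(1+lambda*xi), per-row lambda."""
    A = 1.0 + lam[:, None] * xi[None, :]
    S0 = U2.sum(axis=1) + tails
    S = (U2 / A).sum(axis=1) + tails
    return dof * (np.log(S0) - np.log(S)) - np.log(A).sum(axis=1)


def batch_lrt(
    xi: np.ndarray,
    U2: np.ndarray,
    tails: np.ndarray,
    dof: int,
    grid: np.ndarray | None = None,
    refine_iters: int = 12,
    chunk: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """LRT statistics T and argmax lambdas for many rotated phenotypes at once.

    ``U2`` is (m, K) of squared rotated components, ``tails`` (m,) the
    squared norm beyond the K-th component.  The search is the shared
    0-plus-log10 grid followed by vectorized ternary refinement inside the
    bracketing interval, so observed statistics and simulated null draws see
    the same discretization.
    """
    xi = np.asarray(xi, dtype=float)
    U2 = np.atleast_2d(np.asarray(U2, dtype=float))
    tails = np.broadcast_to(np.asarray(tails, dtype=float), (U2.shape[0],)).copy()
    if grid is None:
        grid = lambda_grid()
    m = U2.shape[0]
    if xi.size == 0:
        return np.zeros(m), np.zeros(m)

    T = np.empty(m)
    lam_hat = np.empty(m)
    logdet = np.log1p(np.outer(grid, xi)).sum(axis=1)  # (G,)
    C = 1.0 / (1.0 + np.outer(grid, xi))  # (G, K)

    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        u2 = U2[sl]
        tl = tails[sl]
        S0 = u2.sum(axis=1) + tl
        S = u2 @ C.T + tl[:, None]  # (b, G)
        F = dof * (np.log(S0)[:, None] - np.log(S)) - logdet[None, :]
        idx = np.argmax(F, axis=1)
        f_best = F[np.arange(len(idx)), idx]
        lam_best = grid[idx]

        lo = grid[np.maximum(idx - 1, 0)]
        hi = grid[np.minimum(idx + 1, len(grid) - 1)]
        for _ in range(refine_iters):
            m1 = lo + (hi - lo) / 3.0
            m2 = hi - (hi - lo) / 3.0
            f1 = _criterion_at(xi, u2, tl, dof, m1)
            f2 = _criterion_at(xi, u2, tl, dof, m2)
            left = f1 >= f2
            hi = np.where(left, m2, hi)
            lo = np.where(left, lo, m1)
        lam_mid = 0.5 * (lo + hi)
        f_mid = _criterion_at(xi, u2, tl, dof, lam_mid)
        use_mid = f_mid > f_best
        f_best = np.where(use_mid, f_mid, f_best)
        lam_best = np.where(use_mid, lam_mid, lam_best)

        f_best = np.where(f_best < ZERO_TOL, 0.0, f_best)
        lam_best = np.where(f_best == 0.0, 0.0, lam_best)
        T[sl] = f_best
        lam_hat[sl] = lam_best

    return T, lam_hat


# ---------------------------------------------------------------------------
# REML fit, score test, BLUE
# ---------------------------------------------------------------------------


def fit_reml(
    sd: SpectralDecomposition,
    grid: np.ndarray | None = None,
    refine_iters: int = 60,
) -> RemlFit:
    """Maximize the restricted likelihood over lambda >= 0 and form the LRT.

    Bracketed search on the shared grid followed by ternary polish; the
    statistic T = 2*[l(lambda_hat) - l(0)] is clipped at zero so the
    boundary case lambda_hat = 0 gives T = 0 exactly.
    """
    _check_nondegenerate(sd)
    if grid is None:
        grid = lambda_grid()
    T, lam = batch_lrt(
        sd.xi, sd.u[None, :] ** 2, np.array([sd.tail_ss]), sd.dof, grid, refine_iters
    )
    T = float(T[0])
    lam = float(lam[0])
    converged = True
    if sd.K and lam >= grid[-1]:
        warnings.warn("lambda search hit the upper bound; fit flagged as not converged")
        converged = False

    denom = 1.0 + lam * sd.xi
    sigma2 = (np.sum(sd.u**2 / denom) + sd.tail_ss) / sd.dof
    ll_alt = restricted_loglik(sd, lam)
    ll_null = restricted_loglik(sd, 0.0)
    b_hat = _gls_fixed_effects(sd, lam) if sd._X is not None and sd._e is not None else None
    return RemlFit(
        lambda_hat=lam,
        sigma2_hat=float(sigma2),
        tau2_hat=float(lam * sigma2),
        h2=float(lam / (1.0 + lam)),
        loglik_alt=float(ll_alt),
        loglik_null=float(ll_null),
        T=T,
        b_hat=b_hat,
        converged=converged,
        iterations=refine_iters,
    )


def _vinv_apply(sd: SpectralDecomposition, lam: float, M: np.ndarray) -> np.ndarray:
    """(lam Z Z' + I)^-1 M through the economy SVD of Z (no n x n inverse)."""
    Uz, sz = sd._zsvd
    if lam == 0 or sz.size == 0:
        return np.asarray(M, dtype=float)
    d = lam * sz**2 / (1.0 + lam * sz**2)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        return M - Uz @ (d * (Uz.T @ M))
    return M - Uz @ (d[:, None] * (Uz.T @ M))


def _gls_fixed_effects(sd: SpectralDecomposition, lam: float) -> np.ndarray:
    X, e = sd._X, sd._e
    VinvX = _vinv_apply(sd, lam, X)
    Vinve = _vinv_apply(sd, lam, e)
    return np.linalg.solve(X.T @ VinvX, X.T @ Vinve)


def score_test(
    sd: SpectralDecomposition,
    method: str = "liu",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Variance-component score test of lambda = 0.

    Q = sum xi_s u_s^2 / (2 sigma0^4); the null law is the weighted
    chi-square mixture sum (xi_s / (2 sigma0^2)) chi2_1, evaluated by Liu
    moment matching (default) or Monte Carlo.
    """
    _check_nondegenerate(sd)
    sigma02 = sd.rss / sd.dof
    if sd.K == 0:
        return 0.0, 1.0
    Q = float(np.sum(sd.xi * sd.u**2) / (2.0 * sigma02**2))
    weights = sd.xi / (2.0 * sigma02)
    if Q <= 0:
        return 0.0, 1.0
    if method == "liu":
        p = _liu_sf(Q, weights)
    elif method == "mc":
        rng = np.random.default_rng(seed)
        draws = rng.chisquare(1.0, size=(n_draws, weights.size)) @ weights
        p = (np.sum(draws >= Q) + 1.0) / (n_draws + 1.0)
    else:
        raise ValueError(f"unknown score-test method {method!r}")
    return Q, float(min(max(p, np.nextafter(0, 1)), 1.0))


def _liu_sf(q: float, w: np.ndarray) -> float:
    """Upper tail of sum w_s chi2_1 via moment-matched (noncentral) chi-square."""
    c1 = w.sum()
    c2 = np.sum(w**2)
    c3 = np.sum(w**3)
    c4 = np.sum(w**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dfl = a**2 - 2.0 * delta
    else:
        delta = 0.0
        dfl = 1.0 / s2
        a = np.sqrt(dfl)
    tstar = (q - c1) / np.sqrt(2.0 * c2)
    x = tstar * np.sqrt(2.0 * (dfl + 2.0 * delta)) + dfl + delta
    if delta > 0:
        return float(stats.ncx2.sf(x, dfl, delta))
    return float(stats.chi2.sf(x, dfl))


def blue_weights(
    Z: GenotypeMatrix | np.ndarray,
    X: CovariateMatrix | None,
    e: ExpressionVector | np.ndarray,
    fit: RemlFit,
    gene_id: str = "",
) -> WeightsVector:
    """Best linear unbiased estimator of the per-SNP random effects.

    beta_hat = lam Z' (lam Z Z' + I)^-1 (e - X b_gls), evaluated through the
    economy SVD of Z so no n x n matrix is ever inverted.
    """
    if fit is None or fit.lambda_hat is None:
        raise ValueError("a fitted RemlFit with lambda_hat is required")
    Zd = Z.dosages if isinstance(Z, GenotypeMatrix) else np.asarray(Z, dtype=float)
    ev = e.values if isinstance(e, ExpressionVector) else np.asarray(e, dtype=float).ravel()
    n, p = Zd.shape
    lam = fit.lambda_hat
    variants = (
        Z.variants.copy()
        if isinstance(Z, GenotypeMatrix)
        else pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(p)],
                "chrom": "0",
                "pos": np.arange(1, p + 1),
                "ref": "A",
                "alt": "G",
            }
        )
    )
    if lam == 0.0:
        return WeightsVector(gene_id, variants, np.zeros(p), 0.0, 0.0)

    Xd = _design_with_intercept(X, n)
    Uz, sz, _ = np.linalg.svd(Zd, full_matrices=False)
    d = lam * sz**2 / (1.0 + lam * sz**2)

    def vinv(M):
        if M.ndim == 1:
            return M - Uz @ (d * (Uz.T @ M))
        return M - Uz @ (d[:, None] * (Uz.T @ M))

    VinvX = vinv(Xd)
    b = np.linalg.solve(Xd.T @ VinvX, Xd.T @ vinv(ev))
    r = ev - Xd @ b
    beta = lam * (Zd.T @ vinv(r))
    return WeightsVector(gene_id, variants, beta, lam, fit.h2)
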