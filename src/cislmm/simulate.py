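"""Synthetic genotypes/expression and the type-I-error / power study harness.

Genotypes are HWE dosages built from two haplotypes; optional LD is induced
by an AR(1) Gaussian copula on the latent haplotype variables, so ``rho``
is the latent autocorrelation between adjacent sites (rho = 0 gives
independent SNPs).  Expression is e = Z beta + eps with beta ~ N(0, tau^2)
on a random subset of columns and eps ~ N(0, I).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import GenotypeMatrix, spectral_decompose
from .nulldist import exact_pvalue, fit_mixture, mixture_pvalue, simulate_null_draws

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_expression",
    "expected_lambda",
    "run_power_study",
]


@dataclass
class SimulationConfig:
    """Design of one power/type-I study in the Table-1 layout."""

    n: int = 465
    p: int = 100
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.0
    tau2_values: tuple[float, ...] = (0.03**2, 0.08**2, 0.10**2)
    n_selected: tuple[int, ...] = (10, 25, 50, 75, 100)
    replicates: int = 10_000
    alpha: float = 1e-4
    M: int = 100_000
    L_values: tuple[int, ...] = (10_000,)
    mixture_method: str = "moment"
    seed: int = 0
    regenerate_genotypes: bool = False
    center_genotypes: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.maf_bounds
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if any(t < 0 for t in self.tau2_values):
            raise ValueError("tau^2 must be nonnegative")
        if max(self.n_selected) > self.p:
            raise ValueError("cannot select more SNPs than simulated")


def simulate_genotypes(
    n: int,
    p: int,
    maf_bounds: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.0,
    seed: int | None = None,
    chrom: str = "1",
    max_redraws: int = 200,
) -> GenotypeMatrix:
    """HWE dosage matrix with per-SNP frequency ~ U(maf bounds) and AR(1) LD.

    Each of the two haplotypes per individual carries latent AR(1) standard
    normals; the allele at site j is 1 when the latent value falls below the
    frequency threshold.  Sites whose realized MAF falls at or below the
    lower bound get their frequency redrawn (latent values kept, preserving
    the LD structure).
    """
    lo, hi = maf_bounds
    rng = np.random.default_rng(seed)
    freq = rng.uniform(lo, hi, size=p)

    lat = rng.standard_normal((2 * n, p))
    if rho > 0:
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, p):
            lat[:, j] = rho * lat[:, j - 1] + scale * lat[:, j]

    from scipy.stats import norm

    def realize(f):
        thresh = norm.ppf(f)
        hap = (lat < thresh[None, :]).astype(float)
        return hap[:n] + hap[n:]

    dos = realize(freq)
    for _ in range(max_redraws):
        f_hat = dos.mean(axis=0) / 2.0
        maf = np.minimum(f_hat, 1.0 - f_hat)
        bad = maf <= lo
        if not bad.any():
            break
        freq[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
        thresh = norm.ppf(freq[bad])
        hap = (lat[:, bad] < thresh[None, :]).astype(float)
        dos[:, bad] = hap[:n] + hap[n:]

    variants = pd.DataFrame(
        {
            "id": [f"snp{j + 1:05d}" for j in range(p)],
            "chrom": chrom,
            "pos": np.arange(1, p + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dos)


def simulate_expression(
    Z: GenotypeMatrix | np.ndarray,
    tau: float,
    n_causal: int | None = None,
    seed: int | None = None,
    return_truth: bool = False,
):
    """e = Z beta + eps on a random column subset; tau = 0 gives pure noise."""
    Zd = Z.dosages if isinstance(Z, GenotypeMatrix) else np.asarray(Z, dtype=float)
    n, p = Zd.shape
    rng = np.random.default_rng(seed)
    if n_causal is None:
        n_causal = p
    if n_causal > p:
        raise ValueError("more causal SNPs requested than available")
    chosen = np.sort(rng.choice(p, size=n_causal, replace=False))
    beta = rng.normal(0.0, tau, size=n_causal) if tau > 0 else np.zeros(n_causal)
    e = Zd[:, chosen] @ beta + rng.standard_normal(n)
    if return_truth:
        return e, {"causal": chosen, "beta": beta}
    return e


def expected_lambda(Z, tau2: float, sigma2: float = 1.0) -> float:
    """True signal-to-noise ratio lambda = tau^2 / sigma^2 under e = Z beta + eps.

    The genotype cross-product Z Z' enters the covariance raw, so the
    per-SNP dosage scale is absorbed by Z Z' itself and the model's lambda
    is exactly the effect-size variance over the noise variance.
    """
    return float(tau2 / sigma2)


def _cell_statistics(Z_cell, R, tau, seed, refine_iters=12):
    """Observed LRT statistics for R replicate phenotypes sharing one Z.

    The eigenbasis is computed once; replicate phenotypes are rotated in a
    single matrix product and the lambda search runs batched.
    """
    from .lmm import batch_lrt

    Zd = Z_cell.dosages if isinstance(Z_cell, GenotypeMatrix) else Z_cell
    n, p = Zd.shape
    sd = spectral_decompose(Zd, None, np.zeros(n))
    rng = np.random.default_rng(seed)
    B = rng.normal(0.0, tau, size=(p, R)) if tau > 0 else np.zeros((p, R))
    E = Zd @ B + rng.standard_normal((n, R))
    U2, tails = sd.rotate(E)
    T, _ = batch_lrt(sd.xi, U2, tails, sd.dof, refine_iters=refine_iters)
    return sd, T


def _bootstrap_power_se(T_obs, draws, alpha, n_boot, rng, mode, mixture_method="moment"):
    """SE of a power estimate from resampling the null draws.

    The binomial replicate noise misses the Monte-Carlo error carried by the
    finite null sample (the empirical tail quantile for the exact test, the
    fitted (phi, kappa) for the mixture), which dominates at small alpha.
    """
    from .nulldist import ExactNull

    M = draws.size
    powers = np.empty(n_boot)
    for b in range(n_boot):
        res = np.sort(draws[rng.integers(0, M, size=M)])
        null_b = ExactNull(draws=res, M=M, seed=None, fingerprint="boot")
        if mode == "exact":
            p = exact_pvalue(T_obs, null_b)
        else:
            mix = fit_mixture(null_b, method=mixture_method)
            p = mixture_pvalue(T_obs, mix)
        powers[b] = np.mean(p < alpha)
    return float(powers.std(ddof=1))


def run_power_study(
    config: SimulationConfig, progress: bool = False, n_boot: int = 40
) -> pd.DataFrame:
    """Estimate eLRT and aLRT power/type-I error over the (tau^2, SNP-count) grid.

    Per cell the SNP subset, its eigen-decomposition and both null
    distributions are computed once and shared across replicates.  Returns
    a long-format table with one row per (tau^2, n SNPs, method, L);
    ``se`` is the binomial replicate SE and ``se_mc`` additionally folds in
    the bootstrap uncertainty of the finite null-draw sample.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    geno_ss, *cell_ss = root.spawn(1 + len(cfg.tau2_values) * len(cfg.n_selected))
    Z = simulate_genotypes(
        cfg.n, cfg.p, cfg.maf_bounds, cfg.rho, seed=geno_ss.generate_state(1)[0]
    )
    Zd = Z.dosages - Z.dosages.mean(axis=0) if cfg.center_genotypes else Z.dosages

    rows = []
    cell_iter = [(t2, k) for t2 in cfg.tau2_values for k in cfg.n_selected]
    for (tau2, k), ss in zip(cell_iter, cell_ss):
        s_sel, s_null, s_mix, s_rep = ss.generate_state(4)
        rng = np.random.default_rng(s_sel)
        cols = np.sort(rng.choice(cfg.p, size=k, replace=False))
        Z_cell = Zd[:, cols]
        sd, T_obs = _cell_statistics(Z_cell, cfg.replicates, np.sqrt(tau2), s_rep)

        boot_rng = np.random.default_rng(ss.generate_state(5)[4])
        null = simulate_null_draws(sd, cfg.M, seed=int(s_null))
        p_exact = exact_pvalue(T_obs, null)
        power_e = float(np.mean(p_exact < cfg.alpha))
        se_e = float(np.sqrt(power_e * (1 - power_e) / cfg.replicates))
        se_null = _bootstrap_power_se(
            T_obs, null.draws, cfg.alpha, n_boot, boot_rng, "exact"
        )
        rows.append(
            {
                "tau2": tau2,
                "n_snps": k,
                "method": "eLRT",
                "L": cfg.M,
                "power": power_e,
                "se": se_e,
                "se_mc": float(np.hypot(se_e, se_null)),
                "replicates": cfg.replicates,
                "alpha": cfg.alpha,
            }
        )
        for L in cfg.L_values:
            approx = simulate_null_draws(sd, L, seed=int(s_mix) + L)
            mix = fit_mixture(approx, method=cfg.mixture_method)
            p_mix = mixture_pvalue(T_obs, mix)
            power_a = float(np.mean(p_mix < cfg.alpha))
            se_a = float(np.sqrt(power_a * (1 - power_a) / cfg.replicates))
            se_fit = _bootstrap_power_se(
                T_obs, approx.draws, cfg.alpha, n_boot, boot_rng, "mixture",
                cfg.mixture_method,
            )
            rows.append(
                {
                    "tau2": tau2,
                    "n_snps": k,
                    "method": "aLRT",
                    "L": L,
                    "power": power_a,
                    "se": se_a,
                    "se_mc": float(np.hypot(se_a, se_fit)),
                    "replicates": cfg.replicates,
                    "alpha": cfg.alpha,
                }
            )
        if progress:
            print(f"cell tau2={tau2:.4f} k={k}: eLRT power={power_e:.4f}")
    return pd.DataFrame(rows)
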