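"""Genome scan for eGenes: filtering, cis-window extraction, per-gene tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import (
    CovariateMatrix,
    ExpressionVector,
    GenotypeMatrix,
    fit_reml,
    score_test,
    spectral_decompose,
)
from .nulldist import exact_pvalue, fit_mixture, mixture_pvalue, simulate_null_draws

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GeneTestResult",
    "ScanConfig",
    "quantile_normalize",
    "select_genes",
    "extract_cis_snps",
    "test_gene",
    "scan",
]

RESULT_COLUMNS = [
    "gene_id",
    "chrom",
    "tss",
    "n_snps",
    "lambda_hat",
    "h2",
    "T",
    "p_alrt",
    "p_elrt",
    "p_score",
    "egene_flag",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"TSS must be >= 1 (gene {self.gene_id})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of '+', '-', '.' (gene {self.gene_id})")


@dataclass
class GeneTestResult:
    gene_id: str
    chrom: str
    tss: int
    n_snps: int
    lambda_hat: float
    h2: float
    T: float
    p_alrt: float
    p_elrt: float | None = None
    p_score: float | None = None
    egene_flag: bool = False
    window: tuple[int, int] = (0, 0)


@dataclass
class ScanConfig:
    """Tuning knobs for the eGene scan."""

    window_bp: int = 10_000
    maf_min: float = 0.05
    min_snps: int = 10
    min_expressed_frac: float = 0.5
    alpha: float = 0.05
    L: int = 10_000
    M: int = 100_000
    run_elrt: bool = False
    run_score: bool = False
    mixture_method: str = "moment"
    seed: int = 0
    covariates: CovariateMatrix | None = None
    elrt_refine_margin: float = 0.0  # refine with eLRT when p_alrt < margin * threshold

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.min_snps <= 0 or self.L <= 0 or self.M <= 0:
            raise ValueError("thresholds and draw counts must be positive")


def quantile_normalize(raw: ExpressionVector | np.ndarray) -> np.ndarray:
    """Map values onto standard-normal quantiles Phi^-1((rank - 0.5)/n).

    Average ranks are used for ties; a strictly monotone transform of the
    input leaves the output unchanged.
    """
    x = raw.values if isinstance(raw, ExpressionVector) else np.asarray(raw, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples to quantile normalize")
    if np.ptp(x) == 0:
        raise ValueError("constant expression vector cannot be normalized")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def extract_cis_snps(
    gene: GeneRecord,
    Z_all: GenotypeMatrix,
    window_bp: int = 10_000,
    maf_min: float = 0.05,
) -> GenotypeMatrix:
    """Variants within the closed TSS-centered window with MAF strictly above maf_min.

    Window is [TSS - W/2, TSS + W/2] in 1-based coordinates, strand-agnostic.
    """
    half = window_bp // 2
    lo, hi = gene.tss - half, gene.tss + half
    v = Z_all.variants
    in_win = (v["chrom"].astype(str) == str(gene.chrom)) & (v["pos"] >= lo) & (v["pos"] <= hi)
    sub = Z_all.take_variants(in_win.to_numpy())
    if sub.n_variants == 0:
        return sub
    return sub.take_variants(sub.maf() > maf_min)


def select_genes(
    genes: list[GeneRecord],
    expression: pd.DataFrame,
    Z_all: GenotypeMatrix,
    config: ScanConfig | None = None,
) -> list[GeneRecord]:
    """Keep protein-coding genes expressed in at least half the samples with
    at least ``min_snps`` qualifying cis-SNPs."""
    cfg = config or ScanConfig()
    n = expression.shape[1]
    need = int(np.ceil(cfg.min_expressed_frac * n))
    kept = []
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        if g.gene_id not in expression.index:
            continue
        expressed = int((expression.loc[g.gene_id].to_numpy() > 0).sum())
        if expressed < need:
            continue
        cis = extract_cis_snps(g, Z_all, cfg.window_bp, cfg.maf_min)
        if cis.n_variants < cfg.min_snps:
            continue
        kept.append(g)
    logger.info("select_genes kept %d of %d genes", len(kept), len(genes))
    return kept


def test_gene(
    gene: GeneRecord,
    Z_cis: GenotypeMatrix,
    e_raw: ExpressionVector,
    config: ScanConfig | None = None,
) -> GeneTestResult:
    """Quantile-normalize, decompose, fit REML and compute aLRT (and
    optionally eLRT / score) p-values for a single gene."""
    cfg = config or ScanConfig()
    if Z_cis.n_variants < cfg.min_snps:
        raise ValueError(
            f"gene {gene.gene_id}: {Z_cis.n_variants} cis-SNPs below the "
            f"minimum of {cfg.min_snps}"
        )
    e_norm = quantile_normalize(e_raw)
    sd = spectral_decompose(
        Z_cis, cfg.covariates, ExpressionVector(e_norm, list(e_raw.samples))
    )
    fit = fit_reml(sd)

    gene_seed = np.random.SeedSequence([cfg.seed, abs(hash(gene.gene_id)) % 2**31])
    s_alrt, s_elrt = gene_seed.generate_state(2)
    approx = simulate_null_draws(sd, cfg.L, seed=int(s_alrt))
    mix = fit_mixture(approx, method=cfg.mixture_method)
    p_alrt = float(mixture_pvalue(fit.T, mix))

    p_elrt = None
    if cfg.run_elrt:
        null = simulate_null_draws(sd, cfg.M, seed=int(s_elrt))
        p_elrt = float(exact_pvalue(fit.T, null))
    p_score = None
    if cfg.run_score:
        _, p_score = score_test(sd)

    half = cfg.window_bp // 2
    return GeneTestResult(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        tss=gene.tss,
        n_snps=Z_cis.n_variants,
        lambda_hat=fit.lambda_hat,
        h2=fit.h2,
        T=fit.T,
        p_alrt=p_alrt,
        p_elrt=p_elrt,
        p_score=p_score,
        window=(gene.tss - half, gene.tss + half),
    )


def scan(
    genes: list[GeneRecord],
    expression: pd.DataFrame,
    Z_all: GenotypeMatrix,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Test every eligible gene and apply Bonferroni control at ``alpha``.

    Returns a DataFrame with one row per tested gene; ``egene_flag`` is set
    by comparing the aLRT p-value to alpha / (number of tested genes).
    Genes whose test raises are skipped with a logged reason.
    """
    cfg = config or ScanConfig()
    eligible = select_genes(genes, expression, Z_all, cfg)
    if not eligible:
        logger.warning("no testable genes after filtering")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    results: list[GeneTestResult] = []
    for g in eligible:
        try:
            Z_cis = extract_cis_snps(g, Z_all, cfg.window_bp, cfg.maf_min)
            e_raw = ExpressionVector(
                expression.loc[g.gene_id].to_numpy(dtype=float),
                list(expression.columns),
            )
            results.append(test_gene(g, Z_cis, e_raw, cfg))
        except (ValueError, KeyError) as exc:  # pragma: no cover - defensive
            logger.warning("gene %s skipped: %s", g.gene_id, exc)

    G = len(results)
    threshold = cfg.alpha / G if G else cfg.alpha
    # optional eLRT refinement near the significance boundary
    if cfg.elrt_refine_margin > 0:
        from .nulldist import simulate_null_draws as _snd

        for r, g in zip(results, eligible):
            if r.p_elrt is None and r.p_alrt < cfg.elrt_refine_margin * threshold:
                Z_cis = extract_cis_snps(g, Z_all, cfg.window_bp, cfg.maf_min)
                e_raw = ExpressionVector(
                    expression.loc[g.gene_id].to_numpy(dtype=float),
                    list(expression.columns),
                )
                e_norm = quantile_normalize(e_raw)
                sd = spectral_decompose(
                    Z_cis, cfg.covariates, ExpressionVector(e_norm, list(e_raw.samples))
                )
                null = _snd(sd, cfg.M, seed=cfg.seed)
                r.p_elrt = float(exact_pvalue(r.T, null))

    rows = []
    for r in results:
        r.egene_flag = bool(r.p_alrt <= threshold)
        rows.append(
            {
                "gene_id": r.gene_id,
                "chrom": r.chrom,
                "tss": r.tss,
                "n_snps": r.n_snps,
                "lambda_hat": r.lambda_hat,
                "h2": r.h2,
                "T": r.T,
                "p_alrt": r.p_alrt,
                "p_elrt": r.p_elrt,
                "p_score": r.p_score,
                "egene_flag": r.egene_flag,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_tested"] = G
    df.attrs["egenes_per_chrom"] = (
        df[df["egene_flag"]].groupby("chrom").size().to_dict() if G else {}
    )
    logger.info(
        "scan tested %d genes, %d eGenes at Bonferroni threshold %.3g",
        G,
        int(df["egene_flag"].sum()) if G else 0,
        threshold,
    )
    return df
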