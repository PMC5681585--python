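"""Gene-level association in an independent genotyped cohort.

Cis-SNP weights trained on a reference transcriptome panel are matched to
the cohort's variants (allele-aware), expression is imputed as G @ beta,
and the imputed expression is tested against the phenotype with logistic
(binary) or linear (continuous) regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import GenotypeMatrix, WeightsVector

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeVector",
    "PredixcanResult",
    "harmonize",
    "impute_expression",
    "association_test",
    "run_predixcan",
]

AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PhenotypeVector:
    samples: list[str]
    values: np.ndarray
    kind: str  # "binary" or "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.samples) != self.values.size:
            raise ValueError("phenotype length does not match sample IDs")
        if self.kind not in {"binary", "continuous"}:
            raise ValueError("kind must be 'binary' or 'continuous'")
        if self.kind == "binary" and not set(np.unique(self.values)) <= {0.0, 1.0}:
            raise ValueError("binary phenotype must be coded 0/1")
        if np.unique(self.values).size < 2:
            raise ValueError("phenotype must take at least two distinct values")


@dataclass
class PredixcanResult:
    gene_id: str
    n_matched: int
    n_training: int
    effect: float | None
    se: float | None
    p: float | None
    h2: float
    significant: bool = False
    note: str = ""


def _is_ambiguous(ref: str, alt: str) -> bool:
    return frozenset({ref.upper(), alt.upper()}) in AMBIGUOUS_PAIRS


def harmonize(
    weights: WeightsVector, G: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Align training weights with cohort variants, allele-aware.

    Matching is by variant ID.  Exact ref/alt agreement keeps the weight;
    swapped alleles flip the weight sign (dosage 2-g symmetry); opposite-
    strand complements are accepted unless the site is strand-ambiguous
    (A/T or C/G), in which case any non-exact match is dropped.  Returns
    (aligned weights, aligned n x m dosage submatrix, drop counts).
    """
    gv = G.variants.set_index("id")
    w_aligned = []
    col_idx = []
    counts = {"matched": 0, "unmatched": 0, "allele_mismatch": 0, "ambiguous_dropped": 0}
    for j, row in enumerate(weights.variants.itertuples(index=False)):
        vid = row.id
        if vid not in gv.index:
            counts["unmatched"] += 1
            continue
        t_ref, t_alt = row.ref.upper(), row.alt.upper()
        g_ref, g_alt = str(gv.loc[vid, "ref"]).upper(), str(gv.loc[vid, "alt"]).upper()
        flip = None
        if (g_ref, g_alt) == (t_ref, t_alt):
            flip = False
        elif _is_ambiguous(t_ref, t_alt) or _is_ambiguous(g_ref, g_alt):
            counts["ambiguous_dropped"] += 1
            continue
        elif (g_ref, g_alt) == (t_alt, t_ref):
            flip = True
        elif (g_ref, g_alt) == (COMPLEMENT.get(t_ref, "?"), COMPLEMENT.get(t_alt, "?")):
            flip = False
        elif (g_ref, g_alt) == (COMPLEMENT.get(t_alt, "?"), COMPLEMENT.get(t_ref, "?")):
            flip = True
        else:
            counts["allele_mismatch"] += 1
            continue
        counts["matched"] += 1
        w_aligned.append(-weights.beta[j] if flip else weights.beta[j])
        col_idx.append(int(gv.index.get_loc(vid)))
    if not w_aligned:
        raise ValueError(f"gene {weights.gene_id}: zero variants matched")
    logger.info("harmonize %s: %s", weights.gene_id, counts)
    return np.asarray(w_aligned), G.dosages[:, col_idx], counts


def impute_expression(aligned_weights: np.ndarray, aligned_dosages: np.ndarray) -> np.ndarray:
    """e_hat = G @ beta over the matched variants."""
    return np.asarray(aligned_dosages, dtype=float) @ np.asarray(aligned_weights, dtype=float)


def association_test(
    ehat: np.ndarray,
    y: PhenotypeVector,
    covariates: np.ndarray | None = None,
    gene_id: str = "",
    h2: float = np.nan,
    n_training: int = 0,
) -> PredixcanResult:
    """Wald test of the imputed-expression coefficient.

    Binary phenotype: logistic regression; continuous: OLS with a t-test.
    On logistic non-convergence / separation the result is flagged and a
    score test from the null model is used as the fallback p-value.
    """
    ehat = np.asarray(ehat, dtype=float).ravel()
    if np.ptp(ehat) == 0:
        return PredixcanResult(
            gene_id, 0, n_training, None, None, None, h2,
            note="constant imputed expression; skipped",
        )
    n = ehat.size
    X = np.column_stack([np.ones(n), ehat])
    if covariates is not None:
        X = np.column_stack([X, np.atleast_2d(covariates)])
    note = ""
    if y.kind == "binary":
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y.values, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True) or not np.isfinite(
                res.bse[1]
            ) or res.bse[1] > 1e4:
                raise np.linalg.LinAlgError("unstable logistic fit")
            effect, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
        except Exception:
            # score test from the null model survives separation
            p0 = y.values.mean()
            r = y.values - p0
            U = float(ehat @ r)
            ec = ehat - ehat.mean()
            V = p0 * (1 - p0) * float(ec @ ec)
            stat = U**2 / V if V > 0 else 0.0
            p = float(stats.chi2.sf(stat, 1))
            effect, se = None, None
            note = "logistic fit unstable (separation?); score-test fallback"
            logger.warning("gene %s: %s", gene_id, note)
    else:
        res = sm.OLS(y.values, X).fit()
        effect, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return PredixcanResult(gene_id, 0, n_training, effect, se, p, h2, note=note)


def run_predixcan(
    weights_db: dict[str, WeightsVector],
    G: GenotypeMatrix,
    y: PhenotypeVector,
    covariates: np.ndarray | None = None,
    h2_min: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Impute-and-test every gene with training heritability strictly above h2_min.

    Bonferroni control at ``alpha`` over the genes actually tested.
    """
    if G.samples != y.samples:
        raise ValueError("cohort genotype and phenotype samples are not aligned")
    rows = []
    tested = []
    for gene_id, w in weights_db.items():
        if not (w.h2 > h2_min):
            continue
        try:
            wa, Ga, counts = harmonize(w, G)
        except ValueError as exc:
            logger.warning("%s", exc)
            rows.append(
                PredixcanResult(gene_id, 0, len(w.beta), None, None, None, w.h2,
                                note="no matched variants")
            )
            continue
        ehat = impute_expression(wa, Ga)
        res = association_test(ehat, y, covariates, gene_id, w.h2, len(w.beta))
        res.n_matched = int(counts["matched"])
        rows.append(res)
        if res.p is not None:
            tested.append(res)
    G_tests = len(tested)
    threshold = alpha / G_tests if G_tests else alpha
    for r in rows:
        r.significant = r.p is not None and r.p <= threshold
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "n_matched": [r.n_matched for r in rows],
            "n_training": [r.n_training for r in rows],
            "effect": [r.effect for r in rows],
            "se": [r.se for r in rows],
            "p": [r.p for r in rows],
            "h2": [r.h2 for r in rows],
            "significant": [r.significant for r in rows],
            "note": [r.note for r in rows],
        }
    )
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_tested"] = G_tests
    return df
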