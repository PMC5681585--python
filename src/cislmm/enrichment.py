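"""eGene enrichment over approximately independent LD blocks.

The enrichment fold of a block is the ratio of its share of the scope's
eGenes to its share of the scope's length; a one-sided z-test compares one
block's fold against the mean and standard deviation of the other blocks
in the same scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDBlock",
    "fold_from_counts",
    "assign_genes_to_blocks",
    "enrichment_folds",
    "block_ztest",
]

FOLD_COLUMNS = ["block_id", "chrom", "start", "end", "n_egenes", "fold", "z", "p"]


@dataclass(frozen=True)
class LDBlock:
    """Half-open interval [start, end) on a chromosome, in base pairs."""

    block_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"block {self.block_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def fold_from_counts(g_b: float, G_c: float, l_b: float, L_c: float) -> float:
    """(g_b / G_c) / (l_b / L_c): block eGene share over block length share."""
    if G_c <= 0:
        raise ValueError("scope must contain at least one eGene")
    if l_b <= 0 or L_c <= 0:
        raise ValueError("lengths must be positive")
    return (g_b / G_c) / (l_b / L_c)


def _check_no_overlap(blocks: list[LDBlock]) -> None:
    by_chrom: dict[str, list[LDBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping blocks on {chrom}: {a.block_id} and {b.block_id}"
                )


def assign_genes_to_blocks(
    genes: pd.DataFrame, blocks: list[LDBlock]
) -> dict[str, str | None]:
    """Map gene_id -> block_id of the block whose interval contains the TSS.

    ``genes`` needs columns gene_id, chrom, tss.  Genes outside every block
    map to None.  Overlapping blocks are an error.
    """
    _check_no_overlap(blocks)
    by_chrom: dict[str, list[LDBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(str(b.chrom), []).append(b)
    for bs in by_chrom.values():
        bs.sort(key=lambda b: b.start)

    mapping: dict[str, str | None] = {}
    for row in genes.itertuples(index=False):
        mapping[row.gene_id] = None
        for b in by_chrom.get(str(row.chrom), []):
            if b.contains(int(row.tss)):
                mapping[row.gene_id] = b.block_id
                break
    return mapping


def enrichment_folds(
    results: pd.DataFrame,
    blocks: list[LDBlock],
    scope: str = "chromosome",
    scope_length: dict[str, float] | float | None = None,
) -> pd.DataFrame:
    """Enrichment fold per block, scoped per chromosome (default) or genome-wide.

    ``results`` needs columns gene_id, chrom, tss, egene_flag.  The scope
    length defaults to the summed block lengths; pass ``scope_length`` (a
    chrom -> bp mapping, or a single number for genome scope) to use total
    chromosome lengths instead, as in published worked examples.
    """
    if scope not in {"chromosome", "genome"}:
        raise ValueError("scope must be 'chromosome' or 'genome'")
    egenes = results[results["egene_flag"].astype(bool)]
    mapping = assign_genes_to_blocks(
        egenes[["gene_id", "chrom", "tss"]], blocks
    )
    counts: dict[str, int] = {b.block_id: 0 for b in blocks}
    for bid in mapping.values():
        if bid is not None:
            counts[bid] += 1

    rows = []
    if scope == "genome":
        scopes = {"genome": blocks}
    else:
        scopes = {}
        for b in blocks:
            scopes.setdefault(str(b.chrom), []).append(b)

    for key, bs in scopes.items():
        G_c = sum(counts[b.block_id] for b in bs)
        if G_c == 0:
            import warnings

            warnings.warn(f"scope {key}: no eGenes; skipped")
            continue
        if scope_length is None:
            L_c = float(sum(b.length for b in bs))
        elif isinstance(scope_length, dict):
            L_c = float(scope_length.get(key, sum(b.length for b in bs)))
        else:
            L_c = float(scope_length)
        for b in bs:
            g_b = counts[b.block_id]
            fold = fold_from_counts(g_b, G_c, b.length, L_c) if g_b else 0.0
            rows.append(
                {
                    "block_id": b.block_id,
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "n_egenes": g_b,
                    "fold": fold,
                    "z": np.nan,
                    "p": np.nan,
                    "scope": key,
                }
            )
    return pd.DataFrame(rows, columns=FOLD_COLUMNS + ["scope"])


def block_ztest(folds: pd.DataFrame, block_id: str) -> tuple[float, float]:
    """One-sided z-test of a block's fold against the other blocks in scope.

    z = (fold_target - mean(others)) / sd(others); p is the standard-normal
    upper tail.  The median of the other folds is attached to the result
    frame attrs for descriptive reporting.
    """
    target = folds[folds["block_id"] == block_id]
    if target.empty:
        raise KeyError(f"block {block_id!r} not present in the fold table")
    target = target.iloc[0]
    scope_key = target.get("scope", None)
    others = folds[folds["block_id"] != block_id]
    if scope_key is not None and "scope" in folds.columns:
        others = others[others["scope"] == scope_key]
    if len(others) < 3:
        raise ValueError("need at least 3 other blocks in scope for the z-test")
    vals = others["fold"].to_numpy(dtype=float)
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance among other blocks; z-test undefined")
    z = (float(target["fold"]) - vals.mean()) / sd
    p = float(stats.norm.sf(z))
    folds.attrs["median_other_fold"] = float(np.median(vals))
    return float(z), p
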