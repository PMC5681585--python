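"""Readers and writers for the on-disk formats.

Internal coordinates are 1-based closed; BED input (0-based half-open) is
converted at this boundary and nowhere else.  All sample alignment is done
by ID.  TSV dialects: tab-separated, '.' for missing, UTF-8.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import LDBlock
from .lmm import GenotypeMatrix, WeightsVector
from .predixcan import PhenotypeVector
from .scan import GeneRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_dosage_tsv",
    "read_vcf",
    "write_dosage_tsv",
    "read_expression",
    "read_annotation",
    "read_blocks",
    "read_phenotype",
    "write_results",
    "write_weights",
    "read_weights",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'tsv'); guessed from the suffix if omitted."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Dosage TSV: header 'variant_id chrom pos ref alt <sample...>', one row
    per variant; '.' marks a missing dosage (mean-imputed)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    required = ["variant_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage TSV missing columns {missing}")
    samples = [c for c in df.columns if c not in required]
    if not samples:
        raise ValueError(f"{path}: no sample columns")
    dosages = df[samples].to_numpy(dtype=float).T  # samples x variants
    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        logger.info("%s: %d missing dosages mean-imputed", path, n_missing)
    variants = df[required].rename(columns={"variant_id": "id"}).reset_index(drop=True)
    gm = GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)
    return gm.impute_missing()


def read_vcf(path, multiallelic: str = "skip") -> GenotypeMatrix:
    """VCF reader using cyvcf2; DS is preferred, GT summed to dosage otherwise.

    Multi-allelic records are skipped (default) or split taking the first
    alternate allele (``multiallelic='first'``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            if multiallelic == "skip":
                logger.info("%s: skipping multi-allelic record at line %d", path, i + 1)
                continue
            if not rec.ALT:
                continue
        ds = None
        try:
            raw = rec.format("DS")
            if raw is not None:
                ds = np.asarray(raw, dtype=float).ravel()
        except (KeyError, ValueError):
            ds = None
        if ds is None:
            # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            ds = np.asarray(rec.gt_types, dtype=float)
            ds[ds == 2] = np.nan
            ds[ds == 3] = 2.0
        if ds.size != len(samples):
            raise ValueError(f"{path}: malformed record for {rec.ID} (line {i + 1})")
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(ds)
    if not rows:
        raise ValueError(f"{path}: no usable variant records")
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    gm = GenotypeMatrix(samples=samples, variants=variants, dosages=np.array(rows).T)
    return gm.impute_missing()


def write_dosage_tsv(path, gm: GenotypeMatrix) -> None:
    v = gm.variants
    with open(path, "w") as fh:
        fh.write("variant_id\tchrom\tpos\tref\talt\t" + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_variants):
            row = "\t".join(f"{x:.10g}" for x in gm.dosages[:, j])
            fh.write(
                f"{v['id'].iloc[j]}\t{v['chrom'].iloc[j]}\t{int(v['pos'].iloc[j])}\t"
                f"{v['ref'].iloc[j]}\t{v['alt'].iloc[j]}\t{row}\n"
            )


# ---------------------------------------------------------------------------
# expression / annotation / blocks / phenotype
# ---------------------------------------------------------------------------


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with a gene_id first column and sample-ID header."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs in header")
    return df


_GFF_ATTR = re.compile(r"(\w+)[=\s]\"?([^;\"]+)\"?")


def read_annotation(path) -> list[GeneRecord]:
    """Gene annotation: GFF3 ('gene' features; gene_id/gene_type attributes)
    or a 5-column TSV (gene_id, chrom, tss, strand, biotype)."""
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                first = line
                break
    if not first:
        raise ValueError(f"{path}: empty annotation")
    if len(first.split("\t")) == 9:
        return _read_gff3(path)
    return _read_annotation_tsv(path)


def _read_gff3(path) -> list[GeneRecord]:
    genes = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2].lower() != "gene":
                continue
            attrs = dict(_GFF_ATTR.findall(f[8]))
            gid = attrs.get("gene_id") or attrs.get("ID")
            if gid is None:
                raise ValueError(f"{path}: gene feature without gene_id: {line.strip()}")
            if gid in seen:
                raise ValueError(f"{path}: duplicate gene ID {gid!r}")
            seen.add(gid)
            strand = f[6] if f[6] in {"+", "-"} else "."
            start, end = int(f[3]), int(f[4])
            tss = start if strand != "-" else end
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    chrom=f[0],
                    tss=tss,
                    strand=strand,
                    biotype=attrs.get("gene_type", attrs.get("gene_biotype", "unknown")),
                )
            )
    if not genes:
        raise ValueError(f"{path}: no gene features found")
    return genes


def _read_annotation_tsv(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = ["gene_id", "chrom", "tss"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {missing}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene IDs")
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=getattr(r, "strand", "+") if getattr(r, "strand", "+") in {"+", "-"} else ".",
            biotype=str(getattr(r, "biotype", "protein_coding")),
        )
        for r in df.itertuples(index=False)
    ]


def read_blocks(path) -> list[LDBlock]:
    """BED (0-based half-open) -> internal 1-based blocks [start+1, end+1).

    The half-open convention is preserved: a TSS equal to the BED end falls
    in the next block.
    """
    blocks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = re.split(r"\s+", line)
            if len(f) < 3:
                raise ValueError(f"{path}: malformed BED line {i + 1}")
            chrom, start0, end0 = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"block{i + 1}"
            blocks.append(
                LDBlock(block_id=name, chrom=chrom, start=start0 + 1, end=end0 + 1)
            )
    if not blocks:
        raise ValueError(f"{path}: no blocks found")
    logger.info("%s: %d blocks (BED 0-based converted to 1-based)", path, len(blocks))
    return blocks


def read_phenotype(path, kind: str | None = None) -> PhenotypeVector:
    """Two-column TSV (sample_id, value); kind auto-detected unless given."""
    df = pd.read_csv(path, sep="\t", na_values=["."])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype TSV needs sample_id and value columns")
    if df.empty:
        raise ValueError(f"{path}: empty phenotype file")
    sid, val = df.columns[:2]
    if df[sid].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    values = df[val].to_numpy(dtype=float)
    if kind is None:
        kind = "binary" if set(np.unique(values)) <= {0.0, 1.0} else "continuous"
    return PhenotypeVector(samples=[str(s) for s in df[sid]], values=values, kind=kind)


# ---------------------------------------------------------------------------
# results and weights
# ---------------------------------------------------------------------------


def _header_comment(config: dict | None) -> str:
    from . import __version__

    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha1(cfg.encode()).hexdigest()[:12]
    return f"# cislmm {__version__}\tconfig_sha1={digest}\tconfig={cfg}\n"


def write_results(df: pd.DataFrame, path, config: dict | None = None) -> None:
    """Write a result table as TSV with provenance header comments.

    Float p-value-like columns are rendered in scientific notation with six
    significant digits; missing values as '.'.
    """
    out = df.copy()
    for col in out.columns:
        if col.startswith("p") or col in {"p_alrt", "p_elrt", "p_score"}:
            out[col] = [
                "." if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.6e}"
                for v in out[col]
            ]
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        for key in ("bonferroni_threshold", "n_tested"):
            if key in df.attrs:
                fh.write(f"# {key}={df.attrs[key]!r}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep=".")


def write_weights(path, weights: list[WeightsVector], config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        fh.write("gene_id\tvariant_id\tref\talt\tweight\tlambda_hat\th2\n")
        for w in weights:
            for j, row in enumerate(w.variants.itertuples(index=False)):
                fh.write(
                    f"{w.gene_id}\t{row.id}\t{row.ref}\t{row.alt}\t"
                    f"{w.beta[j]:.17g}\t{w.lambda_hat:.17g}\t{w.h2:.17g}\n"
                )


def read_weights(path) -> dict[str, WeightsVector]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    out: dict[str, WeightsVector] = {}
    for gid, grp in df.groupby("gene_id", sort=False):
        variants = pd.DataFrame(
            {
                "id": grp["variant_id"].to_numpy(),
                "chrom": "0",
                "pos": np.arange(1, len(grp) + 1),
                "ref": grp["ref"].to_numpy(),
                "alt": grp["alt"].to_numpy(),
            }
        )
        out[str(gid)] = WeightsVector(
            gene_id=str(gid),
            variants=variants,
            beta=grp["weight"].to_numpy(dtype=float),
            lambda_hat=float(grp["lambda_hat"].iloc[0]),
            h2=float(grp["h2"].iloc[0]),
        )
    if not out:
        raise ValueError(f"{path}: no weights found")
    return out
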