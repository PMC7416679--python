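"""File formats.

* GWAS summary statistics: tab-delimited with header ``SNP A1 A2 Z [N]``
  (the LDSC munge dialect).
* Portable weight TSV: one row per (gene, SNP) with columns
  ``gene chrom start end snp a1 a2 weight cis_h2 [eqtl_z]``.
* PLINK bed/bim/fam (SNP-major bed, no missing genotypes on write; dosages
  count copies of the bim A1 allele).
* GMT gene sets; 3-column BED risk-locus intervals (0-based half-open on
  disk, converted to 1-based inclusive internally).
* Result TSVs mirroring the per-gene and per-set report tables.

Writers are deterministic: stable orders, 6-significant-digit floats,
scientific notation for p < 1e-3.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ConditionalResult,
    GeneSetCollection,
    GenotypePanel,
    GseaResult,
    GwasConditioned,
    GwasSummary,
    Locus,
    SnpRecord,
    TwasResult,
    WeightSet,
)

logger = logging.getLogger(__name__)


def _fmt(x: float) -> str:
    if x != x:
        return "NA"
    if x != 0 and abs(x) < 1e-3:
        return f"{x:.6E}"
    return f"{x:.6g}"


# ---------------------------------------------------------------- sumstats

def read_sumstats(path: str | Path) -> GwasSummary:
    """Read an LDSC-dialect sumstats TSV; skips non-numeric Z rows with a log."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        raise ValueError(f"{path}: empty sumstats file")
    cols = {c.upper(): c for c in df.columns}
    missing = [c for c in ("SNP", "A1", "A2", "Z") if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    z = pd.to_numeric(df[cols["Z"]], errors="coerce")
    bad = z.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header and 1-based
        logger.warning("%s: skipped %d rows with non-numeric Z (lines %s)",
                       path, int(bad.sum()), lines[:10])
    df = df[~bad.to_numpy()]
    z = z[~bad.to_numpy()]
    dup = df[cols["SNP"]].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicated SNP id {df[cols['SNP']][dup].iloc[0]}")
    n = (pd.to_numeric(df[cols["N"]], errors="coerce")
         if "N" in cols else pd.Series(np.nan, index=df.index))
    table = pd.DataFrame({
        "snp": df[cols["SNP"]].to_numpy(),
        "a1": df[cols["A1"]].str.upper().to_numpy(),
        "a2": df[cols["A2"]].str.upper().to_numpy(),
        "z": z.to_numpy(dtype=float),
        "n": n.to_numpy(dtype=float),
    })
    if table.empty:
        raise ValueError(f"{path}: no usable rows")
    return GwasSummary(table)


def write_sumstats(gwas: GwasSummary, path: str | Path) -> None:
    df = gwas.table.rename(columns={"snp": "SNP", "a1": "A1", "a2": "A2",
                                    "z": "Z", "n": "N"})
    df = df.assign(Z=[f"{v:.10g}" for v in df["Z"]],
                   N=[("NA" if v != v else f"{v:g}") for v in df["N"]])
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- weights

_WEIGHT_COLS = ["gene", "chrom", "start", "end", "snp", "a1", "a2",
                "weight", "cis_h2"]


def read_weights(path: str | Path) -> list[WeightSet]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _WEIGHT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    has_eqtl = "eqtl_z" in df.columns
    out = []
    for gene, grp in df.groupby("gene", sort=True):
        out.append(WeightSet(
            gene_id=str(gene),
            chrom=str(grp["chrom"].iloc[0]),
            start=int(grp["start"].iloc[0]),
            end=int(grp["end"].iloc[0]),
            snp_ids=grp["snp"].astype(str).tolist(),
            a1=grp["a1"].astype(str).str.upper().tolist(),
            a2=grp["a2"].astype(str).str.upper().tolist(),
            w=grp["weight"].to_numpy(dtype=float),
            cis_h2=float(grp["cis_h2"].iloc[0]),
            eqtl_z=grp["eqtl_z"].to_numpy(dtype=float) if has_eqtl else None,
        ))
    if not out:
        raise ValueError(f"{path}: no weight sets")
    return out


def write_weights(weight_sets: Sequence[WeightSet], path: str | Path) -> None:
    rows = []
    any_eqtl = any(ws.eqtl_z is not None for ws in weight_sets)
    for ws in sorted(weight_sets, key=lambda s: s.gene_id):
        for i, snp in enumerate(ws.snp_ids):
            row = {
                "gene": ws.gene_id, "chrom": ws.chrom,
                "start": ws.start, "end": ws.end,
                "snp": snp, "a1": ws.a1[i], "a2": ws.a2[i],
                "weight": f"{ws.w[i]:.10g}", "cis_h2": f"{ws.cis_h2:.6g}",
            }
            if any_eqtl:
                row["eqtl_z"] = (f"{ws.eqtl_z[i]:.10g}"
                                 if ws.eqtl_z is not None else "NA")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- PLINK

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes -> dosage of A1: 00 hom A1, 10 het, 11 hom A2 (01 = missing)
_CODE_TO_DOSAGE = {0b00: 2, 0b10: 1, 0b11: 0}
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in panel.snps:
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t0\t{rec.bp}\t{rec.a1}\t{rec.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(panel.n_individuals):
            fh.write(f"F{i + 1}\tI{i + 1}\t0\t0\t0\t-9\n")
    n = panel.n_individuals
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = bytearray(n_bytes)
        for j in range(panel.n_snps):
            col = panel.dosages[:, j]
            for k in range(n_bytes):
                byte = 0
                for b in range(4):
                    i = 4 * k + b
                    if i < n:
                        byte |= _DOSAGE_TO_CODE[int(col[i])] << (2 * b)
                    # trailing padding bits stay 0 (hom A1 codes, unread)
                buf[k] = byte
            fh.write(buf)


def read_plink(prefix: str | Path) -> GenotypePanel:
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "bp", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != n_bytes * m:
        raise ValueError(
            f"{prefix}: bed payload ({len(body)} bytes) does not match "
            f"{n} individuals x {m} SNPs from fam/bim")
    data = np.frombuffer(body, dtype=np.uint8).reshape(m, n_bytes)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(data >> (2 * b)) & 0b11 for b in range(4)], axis=2)
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    if np.any(codes == 0b01):
        raise ValueError(f"{prefix}.bed: missing genotypes are not supported")
    lut = np.zeros(4, dtype=np.int8)
    for code, dosage in _CODE_TO_DOSAGE.items():
        lut[code] = dosage
    dosages = lut[codes].T  # individuals x SNPs

    records = []
    for j, row in enumerate(bim.itertuples(index=False)):
        col = dosages[:, j].astype(float)
        freq = col.mean() / 2.0
        records.append(SnpRecord(
            snp_id=str(row.snp), chrom=str(row.chrom), bp=int(row.bp),
            a1=str(row.a1).upper(), a2=str(row.a2).upper(),
            maf=float(min(freq, 1.0 - freq)),
        ))
    return GenotypePanel(snps=records, dosages=dosages)


# --------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name}")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + list(collection.sets[name])) + "\n")


# --------------------------------------------------------------------- BED

def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """3-column BED -> (chrom, start, end) 1-based inclusive."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 BED columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
            if end0 <= start0 or start0 < 0:
                raise ValueError(f"{path}:{lineno}: malformed interval")
            out.append((parts[0].removeprefix("chr"), start0 + 1, end0))
    return out


def write_bed_intervals(intervals: Sequence[tuple[str, int, int]],
                        path: str | Path) -> None:
    """(chrom, start, end) 1-based inclusive -> 3-column BED on disk."""
    with open(path, "w") as fh:
        for chrom, start1, end1 in intervals:
            fh.write(f"{chrom}\t{start1 - 1}\t{end1}\n")


# ----------------------------------------------------------------- results

TWAS_COLUMNS = ["Gene", "Chromosome", "Gene Start", "Gene End", "Top GWAS ID",
                "GWAS Z", "Top eQTL ID", "Top eQTL Z", "TWAS Z", "TWAS P",
                "N SNPs", "Significant"]


def write_twas_results(results: Sequence[TwasResult], path: str | Path) -> None:
    rows = [{
        "Gene": r.gene_id, "Chromosome": r.chrom,
        "Gene Start": r.start, "Gene End": r.end,
        "Top GWAS ID": r.top_gwas_snp, "GWAS Z": _fmt(r.top_gwas_z),
        "Top eQTL ID": r.top_eqtl_snp, "Top eQTL Z": _fmt(r.top_eqtl_z),
        "TWAS Z": _fmt(r.twas_z), "TWAS P": _fmt(r.twas_p),
        "N SNPs": r.n_snps_used, "Significant": int(r.significant),
    } for r in results]
    pd.DataFrame(rows, columns=TWAS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_twas_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"Gene": "gene", "TWAS Z": "twas_z",
                              "TWAS P": "twas_p"})


def write_loci(loci: Sequence[Locus],
               conditional: dict[str, Sequence[ConditionalResult]],
               explained: dict[str, bool],
               path: str | Path) -> None:
    rows = []
    for locus in loci:
        cond = conditional.get(locus.locus_id, [])
        indep = [c.gene_id for c in cond if c.independent]
        rows.append({
            "Locus": locus.locus_id, "Chromosome": locus.chrom,
            "Start": locus.start, "End": locus.end,
            "N Genes": len(locus.members),
            "Members": ",".join(locus.members),
            "Lead Gene": locus.lead_gene,
            "Independent Genes": ",".join(indep),
            "N Independent": len(indep),
            "Sentinel Explained": (
                "NA" if locus.locus_id not in explained
                else int(explained[locus.locus_id])),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_conditioned_snps(records: Sequence[GwasConditioned],
                           path: str | Path) -> None:
    rows = [{
        "SNP": r.snp_id, "Marginal Z": _fmt(r.marginal_z),
        "Conditional Z": _fmt(r.conditional_z),
        "Sentinel": int(r.sentinel),
        "Fully Explained Predictor": int(r.fully_explained_predictor),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


GSEA_COLUMNS = ["Gene set", "Beta", "SE", "N cis-h2 genes in set",
                "N genes in set", "P value", "P FDR"]


def write_gsea_results(results: Sequence[GseaResult], path: str | Path) -> None:
    rows = [{
        "Gene set": r.set_id, "Beta": _fmt(r.beta), "SE": _fmt(r.se),
        "N cis-h2 genes in set": r.n_cis_h2_genes_in_set,
        "N genes in set": r.n_genes_in_set,
        "P value": _fmt(r.p), "P FDR": _fmt(r.fdr),
    } for r in results]
    pd.DataFrame(rows, columns=GSEA_COLUMNS).to_csv(path, sep="\t", index=False)
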