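"""Readers and writers for the pipeline's on-disk formats.

Coordinate conventions are enforced at this boundary: VCF is 1-based closed,
BED and BedGraph are 0-based half-open.  VCF goes through pysam; tabular
matrices are plain TSV with a header row (samples as rows, gene/drug ids as
columns).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import pysam

from .config import CHROM_LENGTHS, CHROMOSOMES

__all__ = [
    "write_vcf",
    "read_variants",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed6",
    "read_bed6",
    "write_matrix",
    "read_matrix",
    "write_drugs",
    "read_drugs",
    "read_score_table",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_BASES = frozenset("ACGT")

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "gene"]


def write_vcf(variants: pd.DataFrame, path: PathLike, build: str = "hg38") -> None:
    """Write a variant table as minimal uncompressed VCFv4.2.

    One ALT per record, 1-based positions, gene annotation (when present) in
    ``INFO/GENE``, genome build declared via a ``##reference`` header line.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##reference={build}")
    for chrom in CHROMOSOMES:
        header.contigs.add(chrom, length=CHROM_LENGTHS[chrom])
    header.info.add("GENE", 1, "String", "Annotated gene symbol")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in variants.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            gene = getattr(row, "gene", "")
            if isinstance(gene, str) and gene:
                rec.info["GENE"] = gene
            vcf.write(rec)


def read_variants(
    path: PathLike,
    sample_id: Optional[str] = None,
) -> pd.DataFrame:
    """Read SNVs from a VCF or an ANNOVAR-style annotation TSV.

    Multi-allelic records are split into one row per ALT.  Non-SNV records
    (indels, MNVs) and records on non-canonical contigs (chrM, alt/random
    scaffolds) are dropped, with counts logged.  The genome build, when
    declared in the VCF header (``##reference=``), is carried in
    ``DataFrame.attrs["build"]``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt", ".csv"):
        return _read_annotation_table(path, sample_id)
    sample = sample_id if sample_id is not None else path.stem
    rows = []
    n_non_snv = 0
    n_noncanonical = 0
    build = None
    with pysam.VariantFile(str(path)) as vcf:
        for line in str(vcf.header).splitlines():
            if line.startswith("##reference="):
                build = line.split("=", 1)[1].strip()
        has_gene_tag = "GENE" in vcf.header.info
        for rec in vcf:
            chrom = rec.chrom if rec.chrom.startswith("chr") else f"chr{rec.chrom}"
            if chrom not in CHROMOSOMES:
                n_noncanonical += 1
                continue
            gene = rec.info.get("GENE", "") if has_gene_tag else ""
            if isinstance(gene, tuple):
                gene = gene[0] if gene else ""
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref not in _BASES or alt not in _BASES:
                    n_non_snv += 1
                    continue
                rows.append((sample, chrom, rec.pos, rec.ref, alt, gene or ""))
    if n_non_snv:
        logger.info("dropped %d non-SNV allele(s) from %s", n_non_snv, path.name)
    if n_noncanonical:
        logger.info("dropped %d record(s) on non-canonical contigs from %s", n_noncanonical, path.name)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if build:
        df.attrs["build"] = build
    return df


_ANNOVAR_ALIASES = {
    "chr": "chrom", "chromosome": "chrom", "chrom": "chrom",
    "start": "pos", "pos": "pos", "position": "pos",
    "ref": "ref", "reference": "ref",
    "alt": "alt", "observed": "alt",
    "gene": "gene", "gene.refgene": "gene", "gene_refgene": "gene",
    "sample": "sample_id", "sample_id": "sample_id",
}


def _read_annotation_table(path: Path, sample_id: Optional[str]) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype={"Chr": str, "chrom": str})
    cols = {}
    for c in raw.columns:
        key = c.strip().lower()
        if key in _ANNOVAR_ALIASES and _ANNOVAR_ALIASES[key] not in cols:
            cols[_ANNOVAR_ALIASES[key]] = c
    missing = {"chrom", "pos", "ref", "alt"} - set(cols)
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {sorted(missing)}")
    df = pd.DataFrame(
        {
            "sample_id": raw[cols["sample_id"]] if "sample_id" in cols else (sample_id or path.stem),
            "chrom": raw[cols["chrom"]].astype(str),
            "pos": raw[cols["pos"]].astype(int),
            "ref": raw[cols["ref"]].astype(str).str.upper(),
            "alt": raw[cols["alt"]].astype(str).str.upper(),
            "gene": raw[cols["gene"]].fillna("") if "gene" in cols else "",
        }
    )
    df["chrom"] = np.where(df["chrom"].str.startswith("chr"), df["chrom"], "chr" + df["chrom"])
    snv = df["ref"].isin(_BASES) & df["alt"].isin(_BASES)
    canonical = df["chrom"].isin(CHROMOSOMES)
    dropped = (~snv).sum()
    if dropped:
        logger.info("dropped %d non-SNV row(s) from %s", dropped, path.name)
    off = (snv & ~canonical).sum()
    if off:
        logger.info("dropped %d non-canonical contig row(s) from %s", off, path.name)
    return df[snv & canonical].reset_index(drop=True)


def write_bedgraph(track: pd.DataFrame, path: PathLike) -> None:
    """Write a depth track (chrom, start, end, depth; 0-based half-open)."""
    track[["chrom", "start", "end", "depth"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": int, "end": int, "depth": float},
    )
    return df


def write_bed6(genes: pd.DataFrame, path: PathLike) -> None:
    """Write gene intervals as BED6 (name column carries the gene symbol)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene"],
            "score": 0,
            "strand": "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "start": int, "end": int, "gene": str},
    )
    return df


def read_gff3_genes(path: PathLike) -> pd.DataFrame:
    """Read gene features from GFF3 (1-based closed -> 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("gene_id") or attrs.get("ID", "")
            rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def write_matrix(df: pd.DataFrame, path: PathLike, index_label: Optional[str] = None) -> None:
    """Write a samples-as-rows matrix TSV with a header row of column ids."""
    df.to_csv(path, sep="\t", index_label=index_label or df.index.name or "id")


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_drugs(drugs: pd.DataFrame, path: PathLike) -> None:
    drugs.to_csv(path, sep="\t", index_label=drugs.index.name or "drug_id")


def read_drugs(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={"fingerprint": str})


def read_score_table(path: PathLike) -> pd.Series:
    """Read a two-column (gene, score) TSV into a Series indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    gene_col, score_col = df.columns[:2]
    return pd.Series(df[score_col].to_numpy(), index=df[gene_col], name="score")
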