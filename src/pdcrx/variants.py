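"""Descriptive WES summarisation: somatic subtraction, per-chromosome SNP
counts, substitution spectra, gene-level coverage, mutation matrices and
ranked-list overlap.

A *variant table* is a DataFrame with columns ``sample_id, chrom, pos, ref,
alt, gene`` (1-based positions, single-base ref/alt, canonical chromosomes
only).  Somatic mutations are defined by subtraction: a tumour variant is
somatic if its (chrom, pos, ref, alt) key is absent from the matched
germline calls.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import CHROMOSOMES, SUBSTITUTION_TYPES

__all__ = [
    "somatic_filter",
    "chrom_distribution",
    "substitution_spectrum",
    "per_gene_coverage",
    "mutation_matrix",
    "topk_overlap",
]

logger = logging.getLogger(__name__)

_KEY = ["chrom", "pos", "ref", "alt"]


def somatic_filter(tumor: pd.DataFrame, germline: pd.DataFrame) -> pd.DataFrame:
    """Tumour-only variants: anti-join of tumour against germline on
    (chrom, pos, ref, alt).

    Raises ``ValueError`` when both tables declare a genome build and they
    disagree.
    """
    tb = tumor.attrs.get("build")
    gb = germline.attrs.get("build")
    if tb and gb and tb != gb:
        raise ValueError(f"genome build mismatch: tumor={tb!r} germline={gb!r}")
    germ_keys = set(map(tuple, germline[_KEY].itertuples(index=False, name=None)))
    mask = [
        key not in germ_keys
        for key in tumor[_KEY].itertuples(index=False, name=None)
    ]
    out = tumor[mask].reset_index(drop=True)
    out.attrs.update(tumor.attrs)
    return out


def chrom_distribution(variants: pd.DataFrame) -> pd.DataFrame:
    """Per-sample SNV counts over the 24 canonical chromosomes.

    Chromosomes with no records are reported as 0; an unknown chromosome
    label raises ``ValueError`` listing the offenders.
    """
    unknown = sorted(set(variants["chrom"]) - set(CHROMOSOMES))
    if unknown:
        raise ValueError(f"unknown chromosome label(s): {unknown}")
    counts = (
        variants.groupby(["sample_id", "chrom"], sort=False).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=CHROMOSOMES, fill_value=0)
    counts.columns.name = "chrom"
    return counts.astype(int)


def substitution_spectrum(variants: pd.DataFrame) -> pd.DataFrame:
    """Per-sample counts over the 12 ordered substitution types.

    No strand collapsing: C>T and G>A are tallied separately.
    """
    sub = variants["ref"].str.cat(variants["alt"], sep=">")
    bad = sorted(set(sub) - set(SUBSTITUTION_TYPES))
    if bad:
        raise ValueError(f"non-SNV substitution(s): {bad}")
    counts = (
        variants.assign(substitution=sub)
        .groupby(["sample_id", "substitution"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=SUBSTITUTION_TYPES, fill_value=0)
    )
    counts.columns.name = "substitution"
    return counts.astype(int)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.array(merged_s), np.array(merged_e)


def per_gene_coverage(depth: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Gene-level mean sequencing depth from a per-base BedGraph track.

    For each gene (its intervals merged first), the mean depth is the
    length-weighted average ``sum(depth * overlap_bp) / sum(gene_bp)``, with
    uncovered gene bases counted as depth 0 — the quantity bedtools
    ``genomecov`` yields after aggregating per-base depth over an annotation.

    Returns a DataFrame with columns ``gene, mean_depth, interval_bp``.
    ``depth`` intervals must be non-overlapping and half-open; any interval
    with ``end <= start`` raises ``ValueError`` (coordinate-system mismatch).
    """
    if len(depth) and (depth["end"] <= depth["start"]).any():
        raise ValueError("depth interval with end <= start: BedGraph must be 0-based half-open")
    rows = []
    depth_by_chrom = {c: g.sort_values("start") for c, g in depth.groupby("chrom")}
    for gene, grp in genes.groupby("gene", sort=True):
        total_bp = 0
        weighted = 0.0
        for chrom, sub in grp.groupby("chrom"):
            gs, ge = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            total_bp += int((ge - gs).sum())
            track = depth_by_chrom.get(chrom)
            if track is None:
                continue
            ds = track["start"].to_numpy()
            de = track["end"].to_numpy()
            dv = track["depth"].to_numpy()
            for s, e in zip(gs, ge):
                ov = np.minimum(de, e) - np.maximum(ds, s)
                pos = ov > 0
                weighted += float((dv[pos] * ov[pos]).sum())
        rows.append((gene, weighted / total_bp if total_bp else 0.0, total_bp))
    return pd.DataFrame(rows, columns=["gene", "mean_depth", "interval_bp"])


def mutation_matrix(variants: pd.DataFrame, panel: Sequence[str]) -> pd.DataFrame:
    """Binary sample x panel matrix: 1 iff the sample has >=1 SNV in the gene.

    Variants annotated to off-panel genes (or with no gene) are ignored; the
    ignored count is logged.  Samples with no panel hits keep an all-zero row.
    """
    panel = list(panel)
    if not panel or len(set(panel)) != len(panel):
        raise ValueError("panel must be a non-empty list of unique gene names")
    samples = pd.unique(variants["sample_id"])
    on_panel = variants["gene"].isin(panel)
    ignored = int((~on_panel).sum())
    if ignored:
        logger.info("ignored %d variant(s) in off-panel genes", ignored)
    hit = variants[on_panel]
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=panel, dtype=np.int8)
    if len(hit):
        flags = (
            hit.groupby(["sample_id", "gene"], sort=False).size().clip(upper=1).unstack(fill_value=0)
        )
        mat.loc[flags.index, flags.columns] = flags.astype(np.int8)
    return mat


def _top_k(scores: pd.Series, k: int) -> set:
    if scores.index.has_duplicates:
        dups = scores.index[scores.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene name(s) in score table: {dups}")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds table size {len(scores)}")
    # ties at rank k broken lexicographically by gene name
    ranked = scores.sort_index().sort_values(ascending=False, kind="mergesort")
    return set(ranked.index[:k])


def topk_overlap(
    scores_a: Union[pd.Series, pd.DataFrame],
    scores_b: Union[pd.Series, pd.DataFrame],
    k: int,
) -> list:
    """Genes shared between the top-``k`` of two per-gene score tables.

    Mirrors driver-list comparisons in which the k highest-scoring genes of
    each cohort are intersected.  Ties at rank k are broken lexicographically
    by gene name.  Returns the sorted shared gene list.
    """
    def _as_series(t):
        if isinstance(t, pd.DataFrame):
            return pd.Series(t.iloc[:, 1].to_numpy(), index=t.iloc[:, 0])
        return t

    a = _top_k(_as_series(scores_a), k)
    b = _top_k(_as_series(scores_b), k)
    return sorted(a & b)
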