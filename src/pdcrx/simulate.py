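"""Synthetic-data generators with planted, recoverable structure.

Every input the pipeline consumes can be generated here: sparse binary
mutation profiles over a gene panel, drug fingerprint libraries partitioned
into mechanism classes, dose-response matrices with a planted
genotype -> drug-class sensitivity rule and missing entries, paired
tumour/germline variant tables, and per-base coverage tracks.  The planted
rule is returned alongside the data so downstream stages can be tested
against known ground truth.

Reproducibility: one global integer seed feeds a splittable
``numpy.random.SeedSequence``; each output draws from its own child stream,
so regenerating one output never perturbs another.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    CHROM_LENGTHS,
    CHROMOSOMES,
    SUBSTITUTION_TYPES,
    ConfigError,
    PlantedRule,
    SimConfig,
)

__all__ = [
    "generate_pdc_cohort",
    "generate_paired_vcfs",
    "generate_patient_profiles",
    "generate_coverage",
    "fingerprint_matrix",
]

# fixed stream indices so every output has its own child generator
_STREAM_MUTATIONS = 0
_STREAM_FINGERPRINTS = 1
_STREAM_RESPONSE = 2
_STREAM_MISSING = 3
_STREAM_VCF = 4
_STREAM_PATIENTS = 5
_STREAM_RULE = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def _cell_names(n: int) -> list[str]:
    return [f"PDC{i + 1:04d}" for i in range(n)]


def _drug_names(n: int) -> list[str]:
    return [f"D{i + 1:03d}" for i in range(n)]


def _class_names(n: int) -> list[str]:
    return [f"MOA{i + 1:02d}" for i in range(n)]


def fingerprint_matrix(drugs: pd.DataFrame) -> np.ndarray:
    """Decode the ``fingerprint`` bit-string column into an int8 matrix."""
    fps = drugs["fingerprint"].astype(str)
    lengths = fps.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"fingerprints must share one length, found {sorted(lengths)}")
    return np.array([[int(b) for b in fp] for fp in fps], dtype=np.int8)


def generate_pdc_cohort(
    cfg: SimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedRule]:
    """Simulate a PDC pharmacogenomics training screen.

    Returns ``(mutations, drugs, sensitivity, rule)``:

    * ``mutations`` — ``n_cells x n_genes`` binary DataFrame (cell x panel);
      each entry is Bernoulli(``mutation_rate``).
    * ``drugs`` — DataFrame indexed by drug id with columns ``drug_class`` and
      ``fingerprint`` (a 0/1 bit-string).  Classes are assigned round-robin;
      each class owns ``fingerprint_len // 4`` "core" bits that are always set
      for its drugs, plus sparse random bits, so within-class Tanimoto
      similarity exceeds between-class similarity in expectation.
    * ``sensitivity`` — ``n_cells x n_drugs`` AUC_DR matrix with NaN for the
      masked ``missing_frac`` of entries.  AUC_DR(cell, drug) =
      ``baseline_auc`` − ``effect_size``·[cell mutated in the target gene of
      drug's class] + N(0, ``noise_sd``); lower AUC_DR = more sensitive.
    * ``rule`` — the planted class -> target-gene map and direction flag.
    """
    genes = _gene_names(cfg.n_genes)
    cells = _cell_names(cfg.n_cells)
    drug_ids = _drug_names(cfg.n_drugs)
    classes = _class_names(cfg.n_classes)

    rule_rng = _rng(cfg.seed, _STREAM_RULE)
    target_idx = rule_rng.choice(cfg.n_genes, size=cfg.n_classes, replace=False)
    rule = PlantedRule(
        class_target={c: genes[g] for c, g in zip(classes, target_idx)},
        direction="lower_is_sensitive",
    )

    mut_rng = _rng(cfg.seed, _STREAM_MUTATIONS)
    mutations = pd.DataFrame(
        mut_rng.binomial(1, cfg.mutation_rate, size=(cfg.n_cells, cfg.n_genes)).astype(np.int8),
        index=pd.Index(cells, name="cell_id"),
        columns=genes,
    )

    fp_rng = _rng(cfg.seed, _STREAM_FINGERPRINTS)
    k_core = max(1, cfg.fingerprint_len // 4)
    core_bits = {
        c: fp_rng.choice(cfg.fingerprint_len, size=k_core, replace=False) for c in classes
    }
    drug_class = [classes[i % cfg.n_classes] for i in range(cfg.n_drugs)]
    fp_rows = []
    for cls in drug_class:
        bits = (fp_rng.random(cfg.fingerprint_len) < 0.1).astype(np.int8)
        bits[core_bits[cls]] = 1
        fp_rows.append("".join(map(str, bits)))
    drugs = pd.DataFrame(
        {"drug_class": drug_class, "fingerprint": fp_rows},
        index=pd.Index(drug_ids, name="drug_id"),
    )

    resp_rng = _rng(cfg.seed, _STREAM_RESPONSE)
    target_of_drug = np.array(
        [genes.index(rule.class_target[cls]) for cls in drug_class]
    )
    sensitive = mutations.to_numpy()[:, target_of_drug].astype(float)  # cells x drugs
    auc = cfg.baseline_auc - cfg.effect_size * sensitive
    if cfg.noise_sd > 0:
        auc = auc + resp_rng.normal(0.0, cfg.noise_sd, size=auc.shape)

    miss_rng = _rng(cfg.seed, _STREAM_MISSING)
    mask = miss_rng.random(auc.shape) < cfg.missing_frac
    auc = np.where(mask, np.nan, auc)
    sensitivity = pd.DataFrame(
        auc, index=pd.Index(cells, name="cell_id"), columns=drug_ids
    )

    return mutations, drugs, sensitivity, rule


def _draw_variants(
    rng: np.random.Generator,
    cfg: SimConfig,
    n: int,
    taken: set,
) -> pd.DataFrame:
    """Draw ``n`` SNVs with unique (chrom, pos), avoiding ``taken`` sites."""
    chrom_p = np.asarray(cfg.per_chrom_weights, dtype=float)
    chrom_p = chrom_p / chrom_p.sum()
    rows = []
    while len(rows) < n:
        chrom = CHROMOSOMES[rng.choice(len(CHROMOSOMES), p=chrom_p)]
        pos = int(rng.integers(1, CHROM_LENGTHS[chrom] + 1))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        sub = SUBSTITUTION_TYPES[rng.choice(len(SUBSTITUTION_TYPES), p=np.asarray(cfg.spectrum_probs))]
        ref, alt = sub.split(">")
        rows.append((chrom, pos, ref, alt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.astype({"chrom": str, "pos": np.int64, "ref": str, "alt": str})


def generate_paired_vcfs(
    cfg: SimConfig,
    n_somatic: int,
    n_germline: int,
    sample_id: str = "patient",
    gene_pool: Optional[Sequence[str]] = None,
    genic_frac: float = 0.8,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a tumour/germline variant-call pair for one patient.

    Germline SNVs appear in both tables; exactly ``n_somatic`` additional
    tumour-only SNVs are planted.  Chromosomes follow ``per_chrom_weights``,
    substitution types follow ``spectrum_probs``, positions are unique per
    chromosome.  If ``gene_pool`` is given, a ``genic_frac`` share of variants
    is annotated with a gene drawn from the pool (others left blank).

    Returns ``(tumor, germline, somatic)`` variant tables; ``somatic`` is the
    planted tumour-only subset, the ground truth for somatic subtraction.
    """
    if n_somatic < 0 or n_germline < 0:
        raise ConfigError("variant counts must be >= 0")
    rng = _rng(cfg.seed, _STREAM_VCF)
    taken: set = set()
    germ = _draw_variants(rng, cfg, n_germline, taken)
    som = _draw_variants(rng, cfg, n_somatic, taken)

    def _annotate(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        if gene_pool is not None and len(df):
            pool = list(gene_pool)
            genic = rng.random(len(df)) < genic_frac
            gene = np.where(
                genic, [pool[i] for i in rng.integers(0, len(pool), size=len(df))], ""
            )
            df["gene"] = gene
        else:
            df["gene"] = ""
        return df

    germ = _annotate(germ)
    som = _annotate(som)
    tumor = pd.concat([germ, som], ignore_index=True)
    tumor.insert(0, "sample_id", sample_id)
    germline = germ.copy()
    germline.insert(0, "sample_id", sample_id)
    somatic = som.copy()
    somatic.insert(0, "sample_id", sample_id)
    for df in (tumor, germline, somatic):
        df.attrs["build"] = "hg38"
        df.sort_values(["chrom", "pos"], inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)
    return tumor, germline, somatic


def generate_patient_profiles(
    cfg: SimConfig,
    rule: PlantedRule,
    n_patients: int,
    background_rate: Optional[float] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Simulate patient mutation profiles, each sensitised to one drug class.

    Patient ``i`` is assigned class ``i mod n_classes`` and is guaranteed
    mutated in that class's planted target gene; the other class-target genes
    are forced wild-type so the planted signal is unambiguous.  Non-target
    panel genes mutate at ``background_rate`` (default: ``cfg.mutation_rate``).

    Returns ``(profiles, assigned_class)``.
    """
    genes = _gene_names(cfg.n_genes)
    classes = list(rule.class_target)
    rate = cfg.mutation_rate if background_rate is None else background_rate
    rng = _rng(cfg.seed, _STREAM_PATIENTS)
    prof = rng.binomial(1, rate, size=(n_patients, cfg.n_genes)).astype(np.int8)
    target_col = {c: genes.index(g) for c, g in rule.class_target.items()}
    assigned = [classes[i % len(classes)] for i in range(n_patients)]
    for i, cls in enumerate(assigned):
        for c, col in target_col.items():
            prof[i, col] = 1 if c == cls else 0
    ids = [f"PT{i + 1:03d}" for i in range(n_patients)]
    profiles = pd.DataFrame(prof, index=pd.Index(ids, name="patient_id"), columns=genes)
    return profiles, pd.Series(assigned, index=profiles.index, name="planted_class")


def generate_coverage(
    genes: pd.DataFrame,
    depth: Mapping[str, float],
) -> pd.DataFrame:
    """Build a BedGraph-style depth track with constant depth per gene.

    ``genes`` holds 0-based half-open intervals (columns chrom, start, end,
    gene; a gene may span several intervals).  Every base inside gene *g* gets
    depth ``depth[g]``; intergenic bases are depth 0 and omitted, as bedtools
    ``genomecov -bga`` would omit them with ``-bg``.  Overlapping intervals
    from genes with conflicting depths raise ``ValueError``.
    """
    required = {"chrom", "start", "end", "gene"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene annotation needs columns {sorted(required)}")
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("degenerate gene interval (end <= start)")
    track = genes.copy()
    track["depth"] = track["gene"].map(lambda g: float(depth[g]))
    track = track.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    for chrom, grp in track.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        depths = grp["depth"].to_numpy()
        overlap = starts[1:] < ends[:-1]
        if np.any(overlap & (depths[1:] != depths[:-1])):
            raise ValueError(f"overlapping genes with conflicting depths on {chrom}")
    return track[["chrom", "start", "end", "depth"]]
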