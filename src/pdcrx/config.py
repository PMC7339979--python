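"""Configuration objects and genome-scale constants.

The simulator emulates the statistical shape of a patient-derived-cell (PDC)
pharmacogenomic screen — by default 462 cells profiled on a 91-gene somatic
mutation panel and screened against 60 small molecules — together with paired
tumour/germline whole-exome variant calls.  Every tunable lives in
:class:`SimConfig`; invalid values raise :class:`ConfigError` naming the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Tuple

import numpy as np

__all__ = [
    "ConfigError",
    "SimConfig",
    "PlantedRule",
    "SUBSTITUTION_TYPES",
    "CHROMOSOMES",
    "CHROM_LENGTHS",
    "default_spectrum_probs",
    "default_chrom_weights",
]


class ConfigError(ValueError):
    """A configuration field failed validation."""


#: The 12 ordered single-base substitution types, tallied without
#: pyrimidine-strand collapsing (C>T and G>A are counted separately).
SUBSTITUTION_TYPES: Tuple[str, ...] = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

#: Canonical chromosome order used for all per-chromosome tallies.
CHROMOSOMES: Tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

#: Approximate hg38 chromosome lengths (bp); used to draw variant positions.
CHROM_LENGTHS: Mapping[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895, "chrY": 57_227_415,
}


def default_spectrum_probs() -> Tuple[float, ...]:
    """Default substitution-type probabilities.

    C>T and G>A dominate (0.25 each), mirroring the transition-heavy spectra
    reported for gastric adenocarcinoma exomes; the remaining ten types share
    the rest uniformly.
    """
    probs = {t: 0.05 for t in SUBSTITUTION_TYPES}
    probs["C>T"] = 0.25
    probs["G>A"] = 0.25
    return tuple(probs[t] for t in SUBSTITUTION_TYPES)


def default_chrom_weights(chr7_boost: float = 3.0) -> Tuple[float, ...]:
    """Chromosome sampling weights: length-proportional with chr7 boosted.

    The boost emulates the excess of SNPs on chromosome 7 observed in the
    plateau gastric-cancer cohort the simulator models.
    """
    w = np.array([CHROM_LENGTHS[c] for c in CHROMOSOMES], dtype=float)
    w /= w.sum()
    w[CHROMOSOMES.index("chr7")] *= chr7_boost
    return tuple(w)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic PDC pharmacogenomics cohort.

    Defaults reproduce the scale of the training screen the pipeline targets:
    462 cells, 60 drugs, a 91-gene mutation panel.
    """

    n_cells: int = 462
    n_drugs: int = 60
    n_genes: int = 91
    n_classes: int = 6
    fingerprint_len: int = 128
    mutation_rate: float = 0.5
    effect_size: float = 0.5
    noise_sd: float = 0.1
    missing_frac: float = 0.2
    baseline_auc: float = 0.7
    spectrum_probs: Tuple[float, ...] = field(default_factory=default_spectrum_probs)
    per_chrom_weights: Tuple[float, ...] = field(default_factory=default_chrom_weights)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_drugs", "n_genes", "n_classes", "fingerprint_len"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        _check_prob("mutation_rate", self.mutation_rate)
        _check_prob("missing_frac", self.missing_frac)
        _check_prob("effect_size", self.effect_size)
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.n_classes > self.n_drugs:
            raise ConfigError("n_classes must not exceed n_drugs")
        if self.n_classes > self.n_genes:
            raise ConfigError("n_classes must not exceed n_genes")
        sp = tuple(float(p) for p in self.spectrum_probs)
        if len(sp) != len(SUBSTITUTION_TYPES):
            raise ConfigError(
                f"spectrum_probs must have {len(SUBSTITUTION_TYPES)} entries, got {len(sp)}"
            )
        for p in sp:
            _check_prob("spectrum_probs", p)
        if abs(sum(sp) - 1.0) > 1e-9:
            raise ConfigError(f"spectrum_probs must sum to 1, got {sum(sp)!r}")
        cw = tuple(float(w) for w in self.per_chrom_weights)
        if len(cw) != len(CHROMOSOMES):
            raise ConfigError(
                f"per_chrom_weights must have {len(CHROMOSOMES)} entries, got {len(cw)}"
            )
        if any(w < 0 for w in cw) or sum(cw) <= 0:
            raise ConfigError("per_chrom_weights must be non-negative with positive sum")
        object.__setattr__(self, "spectrum_probs", sp)
        object.__setattr__(self, "per_chrom_weights", cw)

    def replace(self, **kwargs) -> "SimConfig":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(kwargs)
        return SimConfig(**values)


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth genotype -> drug-class sensitivity map planted by the simulator.

    ``class_target`` maps each drug mechanism class to the single panel gene
    whose mutation confers sensitivity to drugs of that class.  ``direction``
    records the dose-response convention so no downstream stage hard-codes it:
    ``"lower_is_sensitive"`` means a smaller AUC_DR indicates a more sensitive
    (cell, drug) pair, the CTRP convention.
    """

    class_target: Mapping[str, str]
    direction: str = "lower_is_sensitive"

    def __post_init__(self) -> None:
        targets = list(self.class_target.values())
        if len(set(targets)) != len(targets):
            raise ConfigError("each drug class must map to a distinct target gene")
        if self.direction not in ("lower_is_sensitive", "higher_is_sensitive"):
            raise ConfigError(f"unknown direction {self.direction!r}")
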