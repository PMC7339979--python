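"""End-to-end orchestration: simulate -> summarise -> kernels -> train ->
predict -> report, with a reproducibility manifest.

The manifest records the resolved configuration, the seed, the package
version and a SHA-256 digest of every artifact, so two runs with the same
seed can be compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, kernels, model as model_mod, ranking, simulate, variants
from .config import ConfigError, SimConfig

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


#: Coarse SVM grid used by the demo pipeline: the middle decades of the full
#: search space, keeping a desk-scale run-all under a few minutes.
COARSE_SVM_GRID = tuple(
    {"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in (0.01, 0.1, 1.0)
)


def _demo_sim() -> SimConfig:
    # desk-scale cohort: 200 cells x 40 drugs in 4 mechanism classes
    return SimConfig(n_cells=200, n_drugs=40, n_classes=4)


@dataclass(frozen=True)
class RunConfig:
    """One config for a full pipeline run; unknown keys are rejected."""

    sim: SimConfig = field(default_factory=_demo_sim)
    n_patients: int = 30
    n_somatic: int = 50
    n_germline: int = 1000
    digitalize_rule: str = "quantile"
    digitalize_q: float = 0.5
    model_kind: str = "svm"
    folds: int = 5
    cv_unit: str = "pair"
    coverage_mean_depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.digitalize_q <= 1.0):
            raise ConfigError(f"digitalize_q must be in [0, 1], got {self.digitalize_q}")
        if self.model_kind.lower() not in ("rf", "svm", "dn"):
            raise ConfigError(f"model_kind must be rf, svm or dn, got {self.model_kind!r}")
        if self.n_patients <= 0 or self.n_somatic < 0 or self.n_germline < 0:
            raise ConfigError("patient/variant counts out of range")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        data = dict(data)
        sim_data = data.pop("sim", {})
        known_sim = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(sim_data) - known_sim
        if unknown:
            raise ConfigError(f"unknown sim key(s): {sorted(unknown)}")
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        seed = data.get("seed", 0)
        sim_data.setdefault("seed", seed)
        return cls(sim=SimConfig(**sim_data), **data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["sim"]["spectrum_probs"] = list(d["sim"]["spectrum_probs"])
        d["sim"]["per_chrom_weights"] = list(d["sim"]["per_chrom_weights"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir: Union[str, Path]) -> Dict:
    """Execute every stage into ``outdir`` and return the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim if cfg.sim.seed == cfg.seed else cfg.sim.replace(seed=cfg.seed)

    stage = "simulate"
    try:
        mutations, drugs, sensitivity, rule = simulate.generate_pdc_cohort(sim)
        io.write_matrix(mutations, out / "cohort_mutations.tsv", "cell_id")
        io.write_drugs(drugs, out / "drugs.tsv")
        io.write_matrix(sensitivity.round(9), out / "sensitivity.tsv", "cell_id")
        tumor, germline, planted = simulate.generate_paired_vcfs(
            sim, cfg.n_somatic, cfg.n_germline, sample_id="patient1",
            gene_pool=list(mutations.columns),
        )
        io.write_vcf(tumor, out / "tumor.vcf")
        io.write_vcf(germline, out / "germline.vcf")

        stage = "summarize"
        tumor_read = io.read_variants(out / "tumor.vcf", sample_id="patient1")
        germ_read = io.read_variants(out / "germline.vcf", sample_id="patient1")
        somatic = variants.somatic_filter(tumor_read, germ_read)
        somatic.to_csv(out / "somatic.tsv", sep="\t", index=False)
        variants.chrom_distribution(somatic).to_csv(out / "chrom_counts.tsv", sep="\t")
        variants.substitution_spectrum(somatic).to_csv(out / "spectrum.tsv", sep="\t")

        stage = "coverage"
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
        cov_genes = pd.DataFrame(
            {
                "chrom": "chr7",
                "start": np.arange(20) * 100_000,
                "end": np.arange(20) * 100_000 + 2_000,
                "gene": [f"G{i + 1:03d}" for i in range(20)],
            }
        )
        depths = {
            g: float(max(1.0, d))
            for g, d in zip(cov_genes["gene"], rng.normal(cfg.coverage_mean_depth, 15, 20).round(1))
        }
        track = simulate.generate_coverage(cov_genes, depths)
        io.write_bedgraph(track, out / "coverage.bedgraph")
        io.write_bed6(cov_genes, out / "genes.bed")
        cov = variants.per_gene_coverage(
            io.read_bedgraph(out / "coverage.bedgraph"), io.read_bed6(out / "genes.bed")
        )
        cov.to_csv(out / "gene_coverage.tsv", sep="\t", index=False)

        stage = "kernels"
        Kg = kernels.genomic_kernel(mutations)
        Kc = kernels.chemical_kernel(drugs)
        io.write_matrix(Kg.to_frame().round(9), out / "genomic_kernel.tsv", "cell_id")
        io.write_matrix(Kc.to_frame().round(9), out / "chemical_kernel.tsv", "drug_id")

        stage = "train"
        labeled = model_mod.digitalize(sensitivity, rule=cfg.digitalize_rule, q=cfg.digitalize_q)
        labeled.pairs.to_csv(out / "labeled_pairs.tsv", sep="\t", index=False)
        feats = kernels.build_pair_features(labeled.pairs, Kg, Kc)
        grid = COARSE_SVM_GRID if cfg.model_kind.lower() == "svm" else None
        trained = model_mod.train(
            labeled, feats, kind=cfg.model_kind, grid=grid, folds=cfg.folds,
            seed=cfg.seed, cv_unit=cfg.cv_unit, reference=(mutations, drugs),
        )
        model_mod.save_model(trained, out / "model.joblib")

        stage = "predict"
        patients, planted_class = simulate.generate_patient_profiles(sim, rule, cfg.n_patients)
        io.write_matrix(patients, out / "patient_mutations.tsv", "patient_id")
        preds = ranking.predict_patients(trained, patients, drugs)
        preds.round({"score": 9}).to_csv(out / "predictions.tsv", sep="\t", index=False)

        stage = "report"
        class_matrix, assignment = ranking.group_by_class(preds)
        class_matrix.round(9).to_csv(out / "class_scores.tsv", sep="\t")
        report = pd.DataFrame(
            {"assigned_class": assignment, "planted_class": planted_class}
        )
        report.to_csv(out / "patient_groups.tsv", sep="\t")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "cv_auc": trained.cv_auc,
        "model_kind": trained.model_kind,
        "hyperparams": {k: (list(v) if isinstance(v, tuple) else v) for k, v in trained.hyperparams.items()},
        "n_somatic_recovered": int(len(somatic)),
        "digests": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
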