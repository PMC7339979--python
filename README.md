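# pdcrx

Kernel-based prediction of effective targeted therapies for cancer patients
from somatic-mutation profiles, trained on patient-derived-cell (PDC)
pharmacogenomics — together with the descriptive whole-exome summaries that
accompany such an analysis (somatic subtraction, per-chromosome SNP counts,
substitution spectra, gene-level coverage, ranked driver-list overlap).

The package is aimed at computational pharmacogenomics work where the
training resource is a drug screen on patient-derived cells (hundreds of
cells × tens of compounds, a gene-panel mutation matrix, dose-response AUCs
with missing entries) and the deployment targets are patients with only a
somatic mutation profile. Because such screens are rarely redistributable,
every input can be generated by the built-in simulator with *planted*,
recoverable structure, so the whole pipeline is testable end to end.

## The model

Let cells $c$ carry binary mutation profiles $m_c \in \{0,1\}^G$ over a gene
panel and drugs $d$ carry chemical fingerprints $f_d \in \{0,1\}^B$. Two
bounded, positive-semidefinite kernels encode each side:

- genomic kernel $K_g(c, c') = J(m_c, m_{c'}) = \frac{|m_c \cap m_{c'}|}{|m_c \cup m_{c'}|}$ (Jaccard),
- chemical kernel $K_c(d, d') = T(f_d, f_{d'})$ — the Tanimoto coefficient,
  the same statistic on fingerprint bits.

Continuous dose-response values $\mathrm{AUC_{DR}}(c,d)$ (lower = more
sensitive) are **digitalized** by a per-drug median split into binary labels
on the edges of the cell–drug bipartite graph. Each labeled pair is
represented by the concatenation of the cell's kernel row over all training
cells and the drug's kernel row over all training drugs ("anchor"
similarities), and fed to an interchangeable classifier — random forest,
RBF-kernel SVM (penalty $C$ and width $\gamma$ tuned by grid search with
stratified 5-fold cross-validation), or a small feed-forward network —
scored by AUROC on held-out folds. A new patient enters purely through
kernel rows against the anchors, so prediction needs no refit; drugs are
ranked per patient by sensitive-class probability and summarised per
mechanism class (the patient × class matrix used to group patients by
predicted kinase-inhibitor response).

## Worked example

`examples/` contains one short script per capability. Training and ranking
(`examples/03_train_response_model.py`, `examples/04_rank_patient_therapies.py`)
on a 120-cell × 24-drug simulated screen print:

```
genomic kernel (120, 120), chemical kernel (24, 24)
labeled pairs: 2270 (50% sensitive)
selected hyperparameters: {'C': 100.0, 'gamma': 1.0}
cross-validated AUROC: 0.983 (probability a held-out sensitive pair outranks a resistant one)

top-3 drugs for PT001 (planted class MOA01):
  rank 1: D013 [MOA01] score 0.963
  rank 2: D017 [MOA01] score 0.956
  rank 3: D021 [MOA01] score 0.946
argmax-class recovery vs planted truth: 100% of 20 patients
```

The cross-validated AUROC of 0.983 says the tuned SVM almost always ranks a
held-out sensitive (cell, drug) pair above a resistant one; the patient
block shows that for a patient whose profile carries the MOA01-sensitising
mutation, all three top-ranked drugs belong to that class, and the
argmax-of-class-means assignment recovers every simulated patient's planted
class.

The same stages are scriptable from a shell:

```bash
pdcrx run-all --seed 7 --outdir out/      # simulate -> ... -> report + manifest
pdcrx overlap scores_a.tsv scores_b.tsv --k 30
```

`run-all` writes a manifest with SHA-256 digests of every artifact; rerunning
with the same seed reproduces them byte for byte.

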