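"""Per-patient drug ranking and grouping by drug mechanism class.

A trained response model scores every (patient, drug) pair via kernel rows
against its training anchors; drugs are then ranked within each patient and
summarised per mechanism class (mean score), yielding the patient x class
matrix used to group patients by their predicted kinase-inhibitor response.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .kernels import binary_similarity
from .model import TrainedResponseModel, _scores
from .simulate import fingerprint_matrix

__all__ = ["predict_patients", "group_by_class"]


def predict_patients(
    model: TrainedResponseModel,
    patients: pd.DataFrame,
    drugs: pd.DataFrame,
) -> pd.DataFrame:
    """Score every (patient, drug) pair and rank drugs within each patient.

    ``patients`` is a binary mutation matrix on the training gene panel;
    ``drugs`` carries ``drug_class`` and ``fingerprint`` columns with
    fingerprints of the training length.  Returns a complete table with
    columns ``patient_id, drug_id, drug_class, score, rank`` where ``score``
    is the classifier's sensitive-class probability and ranks (1 = best) are
    assigned per patient by descending score, ties broken by drug id.
    """
    if model.reference_profiles is None or model.reference_drugs is None:
        raise ValueError("model carries no reference cohort; train with reference=")
    ref_prof = model.reference_profiles
    ref_drugs = model.reference_drugs
    if list(patients.columns) != list(ref_prof.columns):
        raise ValueError("patient profiles are not on the training gene panel")
    ref_fp = fingerprint_matrix(ref_drugs.loc[list(model.anchor_drugs)])
    fp = fingerprint_matrix(drugs)
    if fp.shape[1] != ref_fp.shape[1]:
        raise ValueError(
            f"fingerprint length {fp.shape[1]} differs from training length {ref_fp.shape[1]}"
        )
    if "drug_class" not in drugs.columns or drugs["drug_class"].isna().any():
        raise ValueError("every drug needs a drug_class label")

    # kernel rows against the anchors; no refit needed for unseen patients
    Kg_rows = binary_similarity(
        patients.to_numpy(), ref_prof.loc[list(model.anchor_cells)].to_numpy(),
        kind=model.kernel_kind,
    )
    Kc_rows = binary_similarity(fp, ref_fp, kind=model.kernel_kind)

    n_p, n_d = len(patients), len(drugs)
    X = np.hstack(
        [
            np.repeat(Kg_rows, n_d, axis=0),
            np.tile(Kc_rows, (n_p, 1)),
        ]
    )
    scores = _scores(model.estimator, X)
    table = pd.DataFrame(
        {
            "patient_id": np.repeat(patients.index.to_numpy(), n_d),
            "drug_id": np.tile(drugs.index.to_numpy(), n_p),
            "drug_class": np.tile(drugs["drug_class"].to_numpy(), n_p),
            "score": scores,
        }
    )
    table = table.sort_values(
        ["patient_id", "score", "drug_id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = table.groupby("patient_id").cumcount() + 1
    return table


def group_by_class(
    preds: pd.DataFrame,
    method: str = "argmax",
    n_groups: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Summarise predictions per drug mechanism class and group patients.

    The class score of a patient is the mean predicted score over that
    class's drugs.  ``method="argmax"`` assigns each patient to the class
    with the highest mean (ties broken by class name); ``method="hierarchical"``
    instead cuts an average-linkage Euclidean dendrogram over the class-score
    rows into ``n_groups`` clusters (for figure-style patient grouping).

    Returns ``(class_matrix, assignment)``.
    """
    if preds["drug_class"].isna().any() or (preds["drug_class"] == "").any():
        raise ValueError("unlabeled drug in prediction table")
    matrix = (
        preds.pivot_table(index="patient_id", columns="drug_class", values="score", aggfunc="mean")
        .sort_index()
    )
    matrix = matrix[sorted(matrix.columns)]
    if method == "argmax":
        assignment = matrix.idxmax(axis=1)
    elif method == "hierarchical":
        k = n_groups or len(matrix.columns)
        Z = linkage(matrix.to_numpy(), method="average", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
        assignment = pd.Series(
            [f"group{g}" for g in labels], index=matrix.index, name="group"
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    assignment.name = "assigned_class"
    return matrix, assignment
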