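"""New-case prediction: class membership and reoffending risk for cases
without an observed outcome.

At prediction time the outcome is unknown, so class membership is the
concomitant prior pi(x | z^c) (covariates only) and the outcome
distribution is the full mixture f(y | z^c, z^p).  A post-hoc mode that
conditions class membership on an observed outcome exists for internal
validation.  Cases with missing fields are rejected outright — the tool
does not impute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import CaseRecord, Codebook, EncodedDesign, default_codebook, encode
from .model import (
    LCRAParameters,
    membership_log_probs,
    outcome_log_probs,
    posterior_class_probs,
)
from scipy.special import logsumexp

__all__ = ["Prediction", "predict_case", "predict_batch", "predictions_frame"]

#: two outcome probabilities closer than this are reported as a tie
TIE_TOLERANCE = 1e-6


@dataclass
class Prediction:
    """Per-case class membership and predicted reoffending category."""

    case_id: str
    class_posterior: np.ndarray  # K-simplex from covariates
    modal_class: int
    outcome_probs: np.ndarray  # 3-simplex from the mixture
    modal_outcome: int
    outcome_label: str
    tie_flag: bool


def _predict_design(
    design: EncodedDesign,
    params: LCRAParameters,
    tie_tolerance: float = TIE_TOLERANCE,
) -> list[Prediction]:
    logpi = membership_log_probs(design.covariate_matrix, params)
    logf = outcome_log_probs(design.predictor_matrix, params)
    mix = np.exp(logsumexp(logpi[:, :, None] + logf, axis=1))
    pi = np.exp(logpi)
    preds: list[Prediction] = []
    for i in range(design.n):
        p = mix[i]
        # argmax breaks exact ties toward the less severe category
        modal = int(np.argmax(p))
        top2 = np.sort(p)[-2:] if p.size > 1 else np.array([0.0, p[0]])
        tie = bool(top2[1] - top2[0] < tie_tolerance)
        preds.append(
            Prediction(
                case_id=design.case_ids[i],
                class_posterior=pi[i],
                modal_class=int(np.argmax(pi[i])),
                outcome_probs=p,
                modal_outcome=modal,
                outcome_label=params.outcome_labels[modal],
                tie_flag=tie,
            )
        )
    return preds


def predict_case(
    record: CaseRecord,
    params: LCRAParameters,
    codebook: Codebook | None = None,
    tie_tolerance: float = TIE_TOLERANCE,
) -> Prediction:
    """Predict class membership and reoffending category for one case.

    Any observed outcome on the record is ignored; missing covariates or
    predictors reject the case with the offending field list.
    """
    codebook = codebook or default_codebook()
    design = encode([record], codebook)
    return _predict_design(design, params, tie_tolerance)[0]


def predict_batch(
    records: list[CaseRecord] | EncodedDesign,
    params: LCRAParameters,
    codebook: Codebook | None = None,
    tie_tolerance: float = TIE_TOLERANCE,
) -> tuple[list[Prediction], dict[str, int]]:
    """Predict a batch of cases; also return modal-category counts.

    Deterministic and invariant to case order (per-case computation); the
    summary counts are the tabulation of modal outcomes.
    """
    if isinstance(records, EncodedDesign):
        design = records
    else:
        codebook = codebook or default_codebook()
        design = encode(records, codebook)
    preds = _predict_design(design, params, tie_tolerance)
    summary = {label: 0 for label in params.outcome_labels}
    for p in preds:
        summary[p.outcome_label] += 1
    return preds, summary


def predictions_frame(preds: list[Prediction], params: LCRAParameters) -> pd.DataFrame:
    """Tabular export: id, K membership columns, modal class, 3 outcome
    probability columns, modal outcome, tie flag."""
    rows = []
    for p in preds:
        row: dict = {"id": p.case_id}
        for k, lab in enumerate(params.class_labels):
            row[f"p_class_{k + 1}"] = p.class_posterior[k]
        row["modal_class"] = p.modal_class + 1
        row["modal_class_label"] = params.class_labels[p.modal_class]
        for c, lab in enumerate(params.outcome_labels):
            row[f"p_{lab}"] = p.outcome_probs[c]
        row["modal_outcome"] = p.outcome_label
        row["tie_flag"] = p.tie_flag
        rows.append(row)
    return pd.DataFrame(rows)


def posthoc_class_assignment(design: EncodedDesign, params: LCRAParameters) -> np.ndarray:
    """Internal-validation mode: modal class from the outcome-conditioned
    posterior (requires observed outcomes)."""
    return posterior_class_probs(design, params).modal()
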