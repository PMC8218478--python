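"""External-validation metrics: confusion tables and multi-class
sensitivity / specificity / PPV / NPV.

Two metric conventions are first-class:

* ``standard`` — for category c, with the confusion table oriented rows =
  observed, columns = predicted: sensitivity = TP/row, PPV = TP/column,
  specificity and NPV from the complementary cells;
* ``as-published`` — the same four formulas with the observed and
  predicted margins exchanged, i.e. standard metrics on the transposed
  table.  Published multi-class validation tables sometimes follow this
  orientation, and overall accuracy (trace/N) is identical under both, so
  both are emitted and tagged rather than silently choosing one.

Zero-denominator metrics are reported as 0.0 with a degenerate-denominator
flag (the convention used when no case is predicted in a category) rather
than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codebook import OUTCOME_LEVELS

__all__ = ["ConfusionTable", "MetricReport", "build_confusion", "metric_report",
           "compare_predictor_blocks"]

CONVENTIONS = ("standard", "as-published")


@dataclass
class ConfusionTable:
    """3x3 observed (rows) x predicted (columns) counts."""

    counts: np.ndarray
    labels: tuple[str, ...] = OUTCOME_LEVELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square and match the labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.n if self.n else 0.0

    def transposed(self) -> "ConfusionTable":
        return ConfusionTable(self.counts.T.copy(), self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="observed"),
            columns=pd.Index(self.labels, name="predicted"),
        )
        df["total"] = df.sum(axis=1)
        df.loc["total"] = df.sum(axis=0)
        return df


@dataclass
class MetricReport:
    """Per-category sensitivity/specificity/PPV/NPV plus overall accuracy."""

    sensitivity: dict[str, float]
    specificity: dict[str, float]
    ppv: dict[str, float]
    npv: dict[str, float]
    accuracy: float
    convention: str
    degenerate: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }
        df = pd.DataFrame(rows).T
        df.index.name = "metric"
        df["convention"] = self.convention
        return df

    def rounded(self, ndigits: int = 2) -> "MetricReport":
        """Display rounding (half-up); raw values stay in the report."""
        from decimal import Decimal, ROUND_HALF_UP

        def r(x: float) -> float:
            return float(
                Decimal(repr(float(x))).quantize(Decimal(10) ** -ndigits, ROUND_HALF_UP)
            )

        return MetricReport(
            sensitivity={k: r(v) for k, v in self.sensitivity.items()},
            specificity={k: r(v) for k, v in self.specificity.items()},
            ppv={k: r(v) for k, v in self.ppv.items()},
            npv={k: r(v) for k, v in self.npv.items()},
            accuracy=r(self.accuracy),
            convention=self.convention,
            degenerate=self.degenerate,
        )


def build_confusion(
    observed: Sequence[str | int],
    predicted: Sequence[str | int],
    labels: tuple[str, ...] = OUTCOME_LEVELS,
) -> ConfusionTable:
    """Tabulate observed x predicted category pairs.

    Accepts labels or integer codes; lengths must match.
    """
    if len(observed) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(observed)} observed vs {len(predicted)} predicted"
        )

    def code(v) -> int:
        if isinstance(v, (int, np.integer)):
            if not 0 <= int(v) < len(labels):
                raise ValueError(f"category code {v} out of range")
            return int(v)
        if v not in labels:
            raise ValueError(f"unknown category label {v!r}")
        return labels.index(v)

    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for o, p in zip(observed, predicted):
        counts[code(o), code(p)] += 1
    return ConfusionTable(counts, labels)


def metric_report(table: ConfusionTable, convention: str = "standard") -> MetricReport:
    """Per-category metrics under the requested margin convention."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    M = table.counts if convention == "standard" else table.counts.T
    N = table.n
    sens, spec, ppv, npv = {}, {}, {}, {}
    degenerate: dict[str, list[str]] = {}

    def ratio(num: float, den: float, cat: str, name: str) -> float:
        if den == 0:
            degenerate.setdefault(cat, []).append(name)
            return 0.0
        return num / den

    for c, cat in enumerate(table.labels):
        tp = M[c, c]
        fn = M[c, :].sum() - tp
        fp = M[:, c].sum() - tp
        tn = N - tp - fn - fp
        sens[cat] = ratio(tp, tp + fn, cat, "sensitivity")
        spec[cat] = ratio(tn, tn + fp, cat, "specificity")
        ppv[cat] = ratio(tp, tp + fp, cat, "ppv")
        npv[cat] = ratio(tn, tn + fn, cat, "npv")
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=table.accuracy,
        convention=convention,
        degenerate=degenerate,
    )


def compare_predictor_blocks(
    fit_full,
    fit_reduced,
    holdout_design,
    convention: str = "standard",
) -> dict:
    """Compare holdout predictions of the full model (with neurobiological
    predictors) and the reduced model (within-class intercepts only).

    Both models predict the same holdout cases; the return value carries a
    MetricReport per model, the two confusion tables, and a per-metric
    delta table (full − reduced).  No direction is assumed or enforced.
    """
    from .predict import predict_batch

    y_obs = holdout_design.outcomes_or_raise()

    def predict_with(fitted):
        d = holdout_design
        if fitted.params.n_predictors != d.predictor_matrix.shape[1]:
            d = d.without_predictors()
        return predict_batch(d, fitted.params)[0]

    preds_full = predict_with(fit_full)
    preds_red = predict_with(fit_reduced)
    labels = tuple(fit_full.params.outcome_labels)
    tab_full = build_confusion(y_obs.tolist(), [p.modal_outcome for p in preds_full], labels)
    tab_red = build_confusion(y_obs.tolist(), [p.modal_outcome for p in preds_red], labels)
    rep_full = metric_report(tab_full, convention)
    rep_red = metric_report(tab_red, convention)
    delta = rep_full.to_frame().drop(columns="convention") - rep_red.to_frame().drop(
        columns="convention"
    )
    return {
        "full": rep_full,
        "reduced": rep_red,
        "confusion_full": tab_full,
        "confusion_reduced": tab_red,
        "delta": delta,
        "accuracy_delta": rep_full.accuracy - rep_red.accuracy,
    }
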