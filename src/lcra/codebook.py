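"""Case records, variable codebook, recoding and design-matrix encoding.

The analysis distinguishes two groups of independent variables:

* nine psychosocial *covariates* (concomitant variables) that drive latent
  class membership — age, neighbourhood SES, ethnicity, the three YPI-s
  psychopathic-trait dimensions, the three BPM-Y problem scales, criminal
  friends, substance-use category, treatment motivation (ATMQ) and childhood
  trauma (CTQ-SF);
* eight continuous neurobiological *predictors* used inside each class —
  heart rate, pre-ejection period and respiratory sinus arrhythmia at rest
  and as task reactivity, plus salivary cortisol and testosterone.

The outcome is a three-category reoffending status at 12 months after
release: no offending, non-violent offending, violent offending.

Dummy coding of the categorical covariates yields exactly 17 covariate
columns (1 age + 2 SES + 2 ethnicity + 3 YPI + 3 BPM + 1 criminal friends +
3 substance use + 1 motivation + 1 trauma) and 8 predictor columns; these
column counts are structural invariants checked on every encode.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SES_LEVELS",
    "ETHNICITY_LEVELS",
    "FRIENDS_LEVELS",
    "SUBSTANCE_LEVELS",
    "OUTCOME_LEVELS",
    "CaseRecord",
    "Codebook",
    "EncodedDesign",
    "EncodingError",
    "default_codebook",
    "recode_substance_use",
    "encode",
    "read_cases",
    "write_cases",
]

SES_LEVELS = ("low", "middle", "high")
ETHNICITY_LEVELS = ("Dutch", "Western", "non-Western")
FRIENDS_LEVELS = ("no", "yes")
SUBSTANCE_LEVELS = (
    "non-user",
    "recreational",
    "multiple-one-substance",
    "multiple-multidrug",
)
OUTCOME_LEVELS = ("no", "non-violent", "violent")

#: continuous covariate fields, in design-matrix order
_CONTINUOUS_COVARIATES = (
    "age",
    "ypi_interpersonal",
    "ypi_affective",
    "ypi_behavioral",
    "bpm_internalizing",
    "bpm_externalizing",
    "bpm_attention",
    "treatment_motivation",
    "trauma",
)

#: neurobiological predictor fields, in design-matrix order
PREDICTOR_FIELDS = (
    "hr_rest",
    "pep_rest",
    "rsa_rest",
    "hr_react",
    "pep_react",
    "rsa_react",
    "cortisol",
    "testosterone",
)

_CATEGORICAL = {
    "ses": SES_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "criminal_friends": FRIENDS_LEVELS,
    "substance_use": SUBSTANCE_LEVELS,
}


@dataclass
class CaseRecord:
    """A single juvenile's covariates, predictors and optional outcome.

    RSA at rest is expected on the log scale (the scale on which it is
    conventionally reported); the reader validates plausibility only and
    never transforms.
    """

    id: str
    age: float
    ses: str
    ethnicity: str
    ypi_interpersonal: float
    ypi_affective: float
    ypi_behavioral: float
    bpm_internalizing: float
    bpm_externalizing: float
    bpm_attention: float
    criminal_friends: str
    substance_use: str
    treatment_motivation: float
    trauma: float
    hr_rest: float
    pep_rest: float
    rsa_rest: float
    hr_react: float
    pep_react: float
    rsa_react: float
    cortisol: float
    testosterone: float
    outcome: str | None = None

    def validate(self) -> list[str]:
        """Return a list of problems (empty when the record is valid)."""
        problems: list[str] = []
        for fld, levels in _CATEGORICAL.items():
            val = getattr(self, fld)
            if val not in levels:
                problems.append(f"{fld}={val!r} not in {levels}")
        if self.outcome is not None and self.outcome not in OUTCOME_LEVELS:
            problems.append(f"outcome={self.outcome!r} not in {OUTCOME_LEVELS}")
        for fld in _CONTINUOUS_COVARIATES + PREDICTOR_FIELDS:
            val = getattr(self, fld)
            if val is None or (isinstance(val, float) and not np.isfinite(val)):
                problems.append(f"{fld} missing or non-finite")
        return problems


@dataclass(frozen=True)
class Codebook:
    """Variable roles, levels, reference levels and recoding rules.

    Every case-record field maps to exactly one role (covariate, predictor
    or outcome).  Reference levels are fixed here so that the dummy coding —
    and hence every coefficient — is reproducible across runs.
    """

    covariate_fields: tuple[str, ...]
    predictor_fields: tuple[str, ...]
    categorical_levels: Mapping[str, tuple[str, ...]]
    reference_levels: Mapping[str, str]
    outcome_levels: tuple[str, ...] = OUTCOME_LEVELS

    @property
    def covariate_columns(self) -> list[str]:
        """Design-matrix column names for the covariate block (length 17)."""
        cols: list[str] = []
        for fld in self.covariate_fields:
            if fld in self.categorical_levels:
                ref = self.reference_levels[fld]
                cols.extend(
                    f"{fld}[{lvl}]"
                    for lvl in self.categorical_levels[fld]
                    if lvl != ref
                )
            else:
                cols.append(fld)
        return cols

    @property
    def predictor_columns(self) -> list[str]:
        return list(self.predictor_fields)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "covariate_fields": list(self.covariate_fields),
            "predictor_fields": list(self.predictor_fields),
            "categorical_levels": {k: list(v) for k, v in self.categorical_levels.items()},
            "reference_levels": dict(self.reference_levels),
            "outcome_levels": list(self.outcome_levels),
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        doc = json.loads(Path(path).read_text())
        return cls(
            covariate_fields=tuple(doc["covariate_fields"]),
            predictor_fields=tuple(doc["predictor_fields"]),
            categorical_levels={k: tuple(v) for k, v in doc["categorical_levels"].items()},
            reference_levels=doc["reference_levels"],
            outcome_levels=tuple(doc["outcome_levels"]),
        )


def default_codebook() -> Codebook:
    """The study codebook: 9 covariates, 8 predictors, fixed references.

    Reference levels are ses=low, ethnicity=Dutch, criminal_friends=no,
    substance_use=non-user (the first-listed level of each variable); any
    fixed choice is statistically equivalent, but it must be recorded for
    coefficients to be comparable across runs.
    """
    return Codebook(
        covariate_fields=(
            "age",
            "ses",
            "ethnicity",
            "ypi_interpersonal",
            "ypi_affective",
            "ypi_behavioral",
            "bpm_internalizing",
            "bpm_externalizing",
            "bpm_attention",
            "criminal_friends",
            "substance_use",
            "treatment_motivation",
            "trauma",
        ),
        predictor_fields=PREDICTOR_FIELDS,
        categorical_levels=dict(_CATEGORICAL),
        reference_levels={
            "ses": "low",
            "ethnicity": "Dutch",
            "criminal_friends": "no",
            "substance_use": "non-user",
        },
    )


class EncodingError(ValueError):
    """Raised when case records cannot be encoded (missing/unknown values)."""


@dataclass
class EncodedDesign:
    """Dummy-coded design matrices for a set of cases.

    ``outcome_vector`` uses integer codes 0=no, 1=non-violent, 2=violent and
    -1 for a missing outcome (prediction-only cases).
    """

    covariate_matrix: np.ndarray
    predictor_matrix: np.ndarray
    outcome_vector: np.ndarray
    covariate_names: list[str]
    predictor_names: list[str]
    reference_levels: dict[str, str]
    case_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.covariate_matrix = np.asarray(self.covariate_matrix, dtype=float)
        self.predictor_matrix = np.asarray(self.predictor_matrix, dtype=float)
        self.outcome_vector = np.asarray(self.outcome_vector, dtype=int)
        n = self.covariate_matrix.shape[0]
        if self.predictor_matrix.shape[0] != n or self.outcome_vector.shape[0] != n:
            raise ValueError("design blocks have inconsistent row counts")
        if self.covariate_matrix.shape[1] != len(self.covariate_names):
            raise ValueError("covariate names do not match matrix width")
        if self.predictor_matrix.shape[1] != len(self.predictor_names):
            raise ValueError("predictor names do not match matrix width")
        if not self.case_ids:
            self.case_ids = [str(i) for i in range(n)]

    @property
    def n(self) -> int:
        return self.covariate_matrix.shape[0]

    @property
    def has_outcomes(self) -> bool:
        return self.n > 0 and bool(np.all(self.outcome_vector >= 0))

    def outcomes_or_raise(self) -> np.ndarray:
        missing = [self.case_ids[i] for i in np.nonzero(self.outcome_vector < 0)[0]]
        if missing:
            raise ValueError(f"outcome missing for cases: {missing}")
        return self.outcome_vector

    def without_predictors(self) -> "EncodedDesign":
        """The reduced design: within-class regressions on intercepts only."""
        return EncodedDesign(
            covariate_matrix=self.covariate_matrix,
            predictor_matrix=np.empty((self.n, 0)),
            outcome_vector=self.outcome_vector,
            covariate_names=list(self.covariate_names),
            predictor_names=[],
            reference_levels=dict(self.reference_levels),
            case_ids=list(self.case_ids),
        )

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EncodedDesign":
        idx = np.asarray(idx)
        return EncodedDesign(
            covariate_matrix=self.covariate_matrix[idx],
            predictor_matrix=self.predictor_matrix[idx],
            outcome_vector=self.outcome_vector[idx],
            covariate_names=list(self.covariate_names),
            predictor_names=list(self.predictor_names),
            reference_levels=dict(self.reference_levels),
            case_ids=[self.case_ids[int(i)] for i in idx],
        )

    def with_outcomes(self, y: np.ndarray) -> "EncodedDesign":
        out = dataclasses.replace(self, outcome_vector=np.asarray(y, dtype=int))
        out.case_ids = list(self.case_ids)
        return out


def recode_substance_use(
    lifetime: Mapping[str, int],
    month: Mapping[str, int] | None = None,
) -> str:
    """Collapse per-drug frequency ratings into the four-level use category.

    Each drug carries an ordinal rating on an 11-point scale: 1 = never
    used, 2 = 1–10 times, 3 = 11–20 times, ... 11 = 91–100 times.  A drug
    with rating >= 3 (more than 10 times) counts as *multiple use* of that
    substance; a rating of 2 counts as recreational use.  Categories:

    * ``non-user`` — every rating 1;
    * ``recreational`` — at least one rating 2, none above;
    * ``multiple-one-substance`` — exactly one drug rated >= 3, with or
      without other recreational use;
    * ``multiple-multidrug`` — two or more drugs rated >= 3.

    When both lifetime and past-month ratings are supplied the per-drug
    rating used is their maximum (the questionnaire asks both windows while
    the category definitions reference yearly frequency; taking the maximum
    is the most inclusive consistent reading and is applied uniformly).
    """
    combined: dict[str, int] = {}
    for source in (lifetime, month or {}):
        for drug, rating in source.items():
            if not isinstance(rating, (int, np.integer)) or not 1 <= int(rating) <= 11:
                raise ValueError(
                    f"invalid substance-use rating for {drug!r}: {rating!r} "
                    "(expected an integer in 1..11)"
                )
            combined[drug] = max(combined.get(drug, 1), int(rating))
    heavy = sum(1 for r in combined.values() if r >= 3)
    any_use = any(r >= 2 for r in combined.values())
    if heavy >= 2:
        return "multiple-multidrug"
    if heavy == 1:
        return "multiple-one-substance"
    if any_use:
        return "recreational"
    return "non-user"


def _encode_one(record: CaseRecord, codebook: Codebook) -> tuple[list[float], list[float]]:
    cov: list[float] = []
    for fld in codebook.covariate_fields:
        if fld in codebook.categorical_levels:
            ref = codebook.reference_levels[fld]
            val = getattr(record, fld)
            for lvl in codebook.categorical_levels[fld]:
                if lvl != ref:
                    cov.append(1.0 if val == lvl else 0.0)
        else:
            cov.append(float(getattr(record, fld)))
    pred = [float(getattr(record, fld)) for fld in codebook.predictor_fields]
    return cov, pred


def encode(
    records: Iterable[CaseRecord],
    codebook: Codebook | None = None,
    standardize: bool = False,
) -> EncodedDesign:
    """Encode case records into the 17-column covariate and 8-column
    predictor design matrices.

    Complete cases only: a record with any missing covariate or predictor is
    rejected, and all rejected ids are reported in a single error.  The
    optional ``standardize`` flag z-scores the continuous columns (off by
    default; the parameter count and likelihood bookkeeping are invariant to
    it).
    """
    codebook = codebook or default_codebook()
    records = list(records)
    problems = {r.id: p for r in records if (p := r.validate())}
    if problems:
        detail = "; ".join(f"{cid}: {', '.join(p)}" for cid, p in problems.items())
        raise EncodingError(f"cases rejected (complete-case analysis): {detail}")

    cov_names = codebook.covariate_columns
    pred_names = codebook.predictor_columns
    n = len(records)
    Zc = np.empty((n, len(cov_names)))
    Zp = np.empty((n, len(pred_names)))
    y = np.empty(n, dtype=int)
    for i, rec in enumerate(records):
        cov, pred = _encode_one(rec, codebook)
        Zc[i] = cov
        Zp[i] = pred
        y[i] = codebook.outcome_levels.index(rec.outcome) if rec.outcome is not None else -1

    assert Zc.shape[1] == 17, "covariate design must have exactly 17 columns"
    assert Zp.shape[1] == 8, "predictor design must have exactly 8 columns"

    if standardize and n > 1:
        for M in (Zc, Zp):
            for j in range(M.shape[1]):
                col = M[:, j]
                if set(np.unique(col)) - {0.0, 1.0}:  # continuous column
                    sd = col.std()
                    if sd > 0:
                        M[:, j] = (col - col.mean()) / sd

    return EncodedDesign(
        covariate_matrix=Zc,
        predictor_matrix=Zp,
        outcome_vector=y,
        covariate_names=cov_names,
        predictor_names=pred_names,
        reference_levels=dict(codebook.reference_levels),
        case_ids=[r.id for r in records],
    )


_CSV_COLUMNS = [f.name for f in dataclasses.fields(CaseRecord)]


def write_cases(records: Iterable[CaseRecord], path: str | Path) -> None:
    """Write case records as UTF-8 CSV, one row per case."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        if d["outcome"] is None:
            d["outcome"] = ""
        rows.append(d)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_cases(path: str | Path, codebook: Codebook | None = None) -> list[CaseRecord]:
    """Read case records from CSV; the outcome column is optional.

    Malformed rows and unknown category labels raise with the offending
    line number / label.
    """
    codebook = codebook or default_codebook()
    df = pd.read_csv(path, dtype={"id": str})
    required = [c for c in _CSV_COLUMNS if c != "outcome"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"CSV is missing required columns: {missing_cols}")
    has_outcome = "outcome" in df.columns
    records: list[CaseRecord] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        kwargs: dict = {}
        for col in required:
            val = row[col]
            if col in ("id", *_CATEGORICAL):
                val = str(val)
                if col in _CATEGORICAL and val not in _CATEGORICAL[col]:
                    raise ValueError(f"line {line}: unknown {col} label {val!r}")
            else:
                try:
                    val = float(val)
                except (TypeError, ValueError):
                    raise ValueError(f"line {line}: malformed value {row[col]!r} in column {col!r}") from None
            kwargs[col] = val
        outcome = None
        if has_outcome:
            raw = row["outcome"]
            if not (pd.isna(raw) or str(raw) == ""):
                outcome = str(raw)
                if outcome not in codebook.outcome_levels:
                    raise ValueError(f"line {line}: unknown outcome label {outcome!r}")
        records.append(CaseRecord(outcome=outcome, **kwargs))
    return records
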