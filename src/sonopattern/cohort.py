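"""Patient-level cohort container, data dictionary, validated I/O and rater agreement.

A cohort is a flat table: one row per patient, categorical ultrasound
features coded as 0-based integers in dictionary order, clinical covariates,
the chemotherapy regimen, the pathological-response assessment system
(RCB or MP) and the binary non-response outcome. Validation is strict
complete-case: unknown category labels or missing outcomes are errors, never
silently dropped rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "DataDictionary",
    "Cohort",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "cohens_kappa",
    "COVARIATE_COLUMNS",
    "REGIMEN_LEVELS",
]

#: Clinical covariates carried alongside the ultrasound features.
COVARIATE_COLUMNS = (
    "age",
    "bmi",
    "menopausal_status",
    "family_history",
    "childbirth_history",
    "er",
    "pr",
    "her2",
    "ki67_high",
)

REGIMEN_LEVELS = ("taxane", "anthracycline", "combined")


class CohortValidationError(ValueError):
    """Raised when a cohort table fails dictionary or completeness checks."""


@dataclass(frozen=True)
class DataDictionary:
    """Declared category levels for every ultrasound feature.

    Levels are ordered; the first listed level is the reference level and
    maps to code 0. Codes are 0-based integers in declared order.
    """

    levels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        names = list(self.levels)
        if len(set(names)) != len(names):
            raise CohortValidationError("feature names must be unique")
        for name, lv in self.levels.items():
            if len(lv) < 2:
                raise CohortValidationError(f"feature {name!r} declares fewer than 2 levels")
            if len(set(lv)) != len(lv):
                raise CohortValidationError(f"feature {name!r} has duplicate level labels")

    @property
    def feature_names(self) -> list[str]:
        return list(self.levels)

    @property
    def n_levels(self) -> np.ndarray:
        """Number of declared levels K_j per feature, in dictionary order."""
        return np.array([len(v) for v in self.levels.values()], dtype=int)

    def encode(self, name: str, label: str) -> int:
        try:
            return self.levels[name].index(label)
        except ValueError:
            raise CohortValidationError(
                f"label {label!r} is not a declared level of feature {name!r}"
            ) from None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.levels.items()}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DataDictionary":
        raw = json.loads(Path(path).read_text())
        return cls({k: tuple(v) for k, v in raw.items()})


@dataclass
class Cohort:
    """A validated patient table plus its data dictionary.

    ``data`` holds integer feature codes (one column per dictionary feature),
    the covariates of :data:`COVARIATE_COLUMNS`, ``regimen`` (0/1/2 for
    taxane/anthracycline/combined), ``assessment_system`` ("RCB" or "MP") and
    ``non_response`` (0/1). Synthetic cohorts additionally carry
    ``true_class``.
    """

    data: pd.DataFrame
    dictionary: DataDictionary
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return self.dictionary.feature_names

    @property
    def features(self) -> pd.DataFrame:
        """The categorical feature block (integer codes)."""
        return self.data[self.feature_names]

    @property
    def outcome(self) -> np.ndarray:
        return self.data["non_response"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    def subset(self, mask: np.ndarray) -> "Cohort":
        sub = self.data.loc[np.asarray(mask)].reset_index(drop=True)
        return Cohort(sub, self.dictionary, dict(self.meta))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise CohortValidationError("cohort is empty")
        missing_cols = [c for c in self.feature_names + ["non_response"] if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing columns: {missing_cols}")
        bad_rows: list[str] = []
        for name, K in zip(self.feature_names, self.dictionary.n_levels):
            col = df[name]
            if col.isna().any():
                bad_rows.append(f"{name}: missing in rows {list(df.index[col.isna()])[:5]}")
                continue
            vals = col.to_numpy()
            out = (vals < 0) | (vals >= K)
            if out.any():
                bad_rows.append(f"{name}: out-of-dictionary codes in rows {list(df.index[out])[:5]}")
        if bad_rows:
            raise CohortValidationError("invalid feature values — " + "; ".join(bad_rows))
        y = df["non_response"]
        if y.isna().any():
            raise CohortValidationError(
                f"missing outcome in rows {list(df.index[y.isna()])[:5]}"
            )
        if not set(np.unique(y.to_numpy())) <= {0, 1}:
            raise CohortValidationError("non_response must be binary 0/1")

    def qc_report(self) -> dict:
        """Row/outcome bookkeeping logged after every successful load."""
        sys_counts = (
            self.data["assessment_system"].value_counts().to_dict()
            if "assessment_system" in self.data
            else {}
        )
        return {
            "n_patients": self.n,
            "n_features": len(self.feature_names),
            "n_non_response": self.n_events,
            "non_response_rate_pct": round(100.0 * self.n_events / self.n, 2),
            "assessment_systems": {str(k): int(v) for k, v in sys_counts.items()},
        }


# -- file I/O ------------------------------------------------------------

def load_cohort(path: str | Path, dictionary: DataDictionary, sep: str = ",") -> Cohort:
    """Read a delimited patient table and validate it against *dictionary*.

    Feature columns may contain either dictionary labels or integer codes;
    labels are mapped to 0-based codes in declared order. Any value outside
    the dictionary, or a missing outcome, raises
    :class:`CohortValidationError` naming the offending rows/columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(f"{path} is empty") from None
    if len(df) == 0:
        raise CohortValidationError(f"{path} has a header but no rows")
    for name in dictionary.feature_names:
        if name not in df.columns:
            raise CohortValidationError(f"feature column {name!r} missing from {path}")
        col = df[name]
        if col.dtype == object:
            df[name] = [dictionary.encode(name, str(v)) for v in col]
    return Cohort(df, dictionary)


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write the cohort as delimited text (integer category codes)."""
    cohort.data.to_csv(path, sep=sep, index=False)


# -- inter-rater agreement ----------------------------------------------

def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa between two raters over a shared category space.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of the two raters' marginals. Two constant, identical rating
    vectors agree perfectly and return 1 (the formula is 0/0 there).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be 1-D and of equal length")
    if len(a) == 0:
        raise ValueError("rating vectors must be non-empty")
    if np.array_equal(a, b) and len(np.unique(a)) == 1:
        return 1.0
    return float(cohen_kappa_score(a, b))
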