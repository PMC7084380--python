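"""Survey-table ingestion, clinical outcome derivation and province aggregation.

The analysis operates on four binary outcomes of the metabolic syndrome,
derived from raw clinical fields of a cross-sectional health survey:

* **diabetes** — fasting glucose >= 126 mg/dl OR self-reported diagnosis;
* **obesity** — body-mass index >= 30 kg/m^2;
* **hypertension** — systolic BP >= 140 mmHg OR diastolic BP >= 90 mmHg OR
  self-reported antihypertensive treatment;
* **elevated_ldl** — LDL cholesterol above an ATP-III-style cutoff that
  depends on the cardiovascular-risk (CVR) category: > 100 mg/dl with
  existing cardiovascular disease, > 130 mg/dl at moderate CVR,
  > 160 mg/dl at low CVR.

Any clinical field may be missing.  Disjunctive rules follow a conservative
three-valued logic: an outcome is 1 as soon as any observed arm fires, 0 only
when every arm is observed and fails, and *masked-missing* otherwise.  The
LDL rule, a case analysis rather than a disjunction, is resolved whenever the
observed fields determine the answer for every possible value of the missing
ones (e.g. LDL > 160 is elevated under all CVR categories).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OUTCOMES",
    "CVR_CATEGORIES",
    "LDL_CUTOFFS",
    "ValidationError",
    "SurveyIndividual",
    "OutcomeVector",
    "ProvinceAggregate",
    "derive_outcomes",
    "aggregate_to_province",
    "descriptive_statistics",
    "read_survey_table",
    "write_survey_table",
    "read_province_table",
    "write_province_table",
]

#: Fixed outcome ordering used by every module (K = 4).
OUTCOMES: tuple[str, ...] = ("diabetes", "obesity", "hypertension", "elevated_ldl")

CVR_CATEGORIES: tuple[str, ...] = ("existing_cvd", "moderate_cvr", "low_cvr")

#: LDL threshold (mg/dl, strict ">") per cardiovascular-risk category.
LDL_CUTOFFS: dict[str, float] = {
    "existing_cvd": 100.0,
    "moderate_cvr": 130.0,
    "low_cvr": 160.0,
}

#: Minimum age of the survey's target population (adults >= 15 years).
MIN_TARGET_AGE = 15.0

#: Missing-value tokens accepted on input (configurable per call).
DEFAULT_NA_TOKENS: tuple[str, ...] = ("", "NA", "NaN")


class ValidationError(ValueError):
    """Raised when a survey record violates a structural or range constraint."""


@dataclass
class SurveyIndividual:
    """One survey respondent with raw clinical and design fields.

    ``province_id`` is 1-based and must lie within the adjacency graph's node
    range.  ``sex`` is coded 1 = male, 0 = female.  ``sampling_weight`` is the
    survey design weight (inverse inclusion probability); it is consumed as a
    predictor, never recomputed.  Clinical fields are ``None`` when missing.
    """

    person_id: str
    province_id: int
    age: float
    sex: int
    sampling_weight: float
    fasting_glucose: float | None = None
    self_report_diabetes: int | None = None
    bmi: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    hta_treatment: int | None = None
    ldl: float | None = None
    cvr_category: str | None = None

    def __post_init__(self) -> None:
        if self.sampling_weight is None or not self.sampling_weight > 0:
            raise ValidationError(
                f"sampling_weight must be positive for person {self.person_id!r}"
            )
        if self.age is None or self.age < 0:
            raise ValidationError(f"age must be non-negative for person {self.person_id!r}")
        if self.age < MIN_TARGET_AGE:
            warnings.warn(
                f"person {self.person_id!r} has age {self.age} below the survey "
                f"target population (>= {MIN_TARGET_AGE} years)",
                stacklevel=2,
            )
        if self.sex not in (0, 1):
            raise ValidationError(f"sex must be 0/1 for person {self.person_id!r}")
        if self.province_id < 1:
            raise ValidationError(
                f"province_id must be a positive 1-based id, got {self.province_id} "
                f"for person {self.person_id!r}"
            )
        if self.cvr_category is not None and self.cvr_category not in CVR_CATEGORIES:
            raise ValidationError(
                f"unknown cvr_category {self.cvr_category!r} for person {self.person_id!r}"
            )
        for name in ("fasting_glucose", "bmi", "sbp", "dbp", "ldl"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValidationError(
                    f"negative value {val} for field {name!r} of person {self.person_id!r}"
                )


@dataclass
class OutcomeVector:
    """Derived binary outcomes y_ik with an observation mask.

    ``y[k]`` is meaningful only where ``observed_mask[k]`` is True; masked
    slots are stored as 0 and must never be read without consulting the mask.
    """

    y: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.y.shape != (len(OUTCOMES),) or self.observed_mask.shape != (len(OUTCOMES),):
            raise ValidationError("OutcomeVector requires exactly K=4 slots")


@dataclass
class ProvinceAggregate:
    """Aggregated province record feeding the binomial (area-level) model.

    ``case_counts[k]`` counts observed positives only, and ``n_observed[k]``
    the respondents for whom outcome ``k`` could be determined — the binomial
    denominator at the aggregate scale.  ``sampled_flag`` is the indicator
    I_j used by the sampling-weight imputation rule.
    """

    province_id: int
    n_sampled: int
    case_counts: np.ndarray
    n_observed: np.ndarray
    mean_age: float | None
    prop_male: float | None
    mean_weight: float | None
    sampled_flag: int
    population: int | None = None  # carried as metadata only, unused by the model

    def __post_init__(self) -> None:
        self.case_counts = np.asarray(self.case_counts, dtype=np.int64)
        self.n_observed = np.asarray(self.n_observed, dtype=np.int64)
        if (self.sampled_flag == 0) != (self.n_sampled == 0):
            raise ValidationError(
                f"province {self.province_id}: sampled_flag must be 0 iff n_sampled is 0"
            )
        if np.any(self.case_counts > self.n_observed):
            raise ValidationError(
                f"province {self.province_id}: case counts exceed observed counts"
            )

    @property
    def crude_prevalence(self) -> np.ndarray:
        """y_jk / n_jk per outcome (NaN where no outcome was observed)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_observed > 0, self.case_counts / self.n_observed, np.nan
            )


def _disjunction(arms: Sequence[tuple[bool, bool]]) -> tuple[int, bool]:
    """Three-valued OR over (observed, fired) arms -> (value, observed)."""
    if any(obs and fired for obs, fired in arms):
        return 1, True
    if all(obs for obs, _ in arms):
        return 0, True
    return 0, False


def derive_outcomes(ind: SurveyIndividual) -> OutcomeVector:
    """Apply the four clinical case definitions to one respondent.

    Returns the outcome vector (diabetes, obesity, hypertension,
    elevated_ldl) with its observation mask.  Raising any of the continuous
    clinical inputs can never flip a derived 1 back to 0 (the rules are
    monotone threshold rules).
    """
    y = np.zeros(len(OUTCOMES), dtype=np.int8)
    mask = np.zeros(len(OUTCOMES), dtype=bool)

    # diabetes: glucose >= 126 OR self-reported diagnosis
    g, sr = ind.fasting_glucose, ind.self_report_diabetes
    val, obs = _disjunction(
        [(g is not None, g is not None and g >= 126.0),
         (sr is not None, sr == 1)]
    )
    y[0], mask[0] = val, obs

    # obesity: BMI >= 30
    if ind.bmi is not None:
        y[1], mask[1] = int(ind.bmi >= 30.0), True

    # hypertension: SBP >= 140 OR DBP >= 90 OR treatment
    val, obs = _disjunction(
        [(ind.sbp is not None, ind.sbp is not None and ind.sbp >= 140.0),
         (ind.dbp is not None, ind.dbp is not None and ind.dbp >= 90.0),
         (ind.hta_treatment is not None, ind.hta_treatment == 1)]
    )
    y[2], mask[2] = val, obs

    # elevated LDL: strict ">" against a CVR-dependent cutoff.  With the CVR
    # category missing the determination is still made when the observed LDL
    # settles the answer under every category.
    if ind.ldl is not None:
        if ind.cvr_category is not None:
            y[3] = int(ind.ldl > LDL_CUTOFFS[ind.cvr_category])
            mask[3] = True
        else:
            over_all = all(ind.ldl > c for c in LDL_CUTOFFS.values())
            under_all = all(not ind.ldl > c for c in LDL_CUTOFFS.values())
            if over_all or under_all:
                y[3], mask[3] = int(over_all), True

    return OutcomeVector(y=y, observed_mask=mask)


def aggregate_to_province(
    individuals: Sequence[SurveyIndividual],
    graph_size: int,
    outcomes: Sequence[OutcomeVector] | None = None,
) -> list[ProvinceAggregate]:
    """Aggregate respondents to one record per graph node.

    Produces a record for every node 1..``graph_size`` including unsampled
    ones (``sampled_flag`` 0, counts 0, covariates missing).  Case counts sum
    observed outcomes only; the mean sampling weight is the arithmetic mean
    of the respondents' weights in the province.
    """
    if outcomes is None:
        outcomes = [derive_outcomes(ind) for ind in individuals]
    if len(outcomes) != len(individuals):
        raise ValidationError("outcomes must align one-to-one with individuals")

    K = len(OUTCOMES)
    n = np.zeros(graph_size, dtype=np.int64)
    cases = np.zeros((graph_size, K), dtype=np.int64)
    nobs = np.zeros((graph_size, K), dtype=np.int64)
    age_sum = np.zeros(graph_size)
    male_sum = np.zeros(graph_size)
    w_sum = np.zeros(graph_size)

    for ind, ov in zip(individuals, outcomes):
        if not 1 <= ind.province_id <= graph_size:
            raise ValidationError(
                f"province_id {ind.province_id} of person {ind.person_id!r} "
                f"outside graph range 1..{graph_size}"
            )
        j = ind.province_id - 1
        n[j] += 1
        age_sum[j] += ind.age
        male_sum[j] += ind.sex
        w_sum[j] += ind.sampling_weight
        nobs[j] += ov.observed_mask
        cases[j] += np.where(ov.observed_mask, ov.y, 0)

    out = []
    for j in range(graph_size):
        sampled = int(n[j] > 0)
        out.append(
            ProvinceAggregate(
                province_id=j + 1,
                n_sampled=int(n[j]),
                case_counts=cases[j],
                n_observed=nobs[j],
                mean_age=age_sum[j] / n[j] if sampled else None,
                prop_male=male_sum[j] / n[j] if sampled else None,
                mean_weight=w_sum[j] / n[j] if sampled else None,
                sampled_flag=sampled,
            )
        )
    return out


def descriptive_statistics(
    individuals: Sequence[SurveyIndividual],
    outcomes: Sequence[OutcomeVector] | None = None,
) -> pd.DataFrame:
    """Descriptive table: means/rates overall and by sex with test p-values.

    Continuous variables (age, BMI) are compared between sexes with a Welch
    two-sample t-test; outcome rates with a two-proportion chi-square test
    (no continuity correction).  The sex split itself is tested against an
    even 50/50 participation with an exact binomial test.
    """
    if len(individuals) == 0:
        raise ValidationError("descriptive_statistics requires at least one individual")
    if outcomes is None:
        outcomes = [derive_outcomes(ind) for ind in individuals]

    sex = np.array([ind.sex for ind in individuals])
    rows = []

    n_male = int(sex.sum())
    n_total = len(individuals)
    p_part = stats.binomtest(n_male, n_total, 0.5).pvalue
    rows.append(
        {"variable": "participation", "overall": float(n_total),
         "male": n_male / n_total, "female": 1 - n_male / n_total, "p_value": p_part}
    )

    for name in ("age", "bmi"):
        vals = np.array(
            [getattr(ind, name) if getattr(ind, name) is not None else np.nan
             for ind in individuals], dtype=float
        )
        ok = ~np.isnan(vals)
        vm, vf = vals[ok & (sex == 1)], vals[ok & (sex == 0)]
        if len(vm) >= 2 and len(vf) >= 2:
            p = stats.ttest_ind(vm, vf, equal_var=False).pvalue
        else:
            p = np.nan
        rows.append(
            {"variable": name, "overall": float(np.nanmean(vals)) if ok.any() else np.nan,
             "male": vm.mean() if len(vm) else np.nan,
             "female": vf.mean() if len(vf) else np.nan, "p_value": p}
        )

    Y = np.stack([ov.y for ov in outcomes])
    M = np.stack([ov.observed_mask for ov in outcomes])
    for k, outcome in enumerate(OUTCOMES):
        obs = M[:, k]
        yk = Y[:, k]
        nm = int((obs & (sex == 1)).sum())
        nf = int((obs & (sex == 0)).sum())
        cm = int(yk[obs & (sex == 1)].sum())
        cf = int(yk[obs & (sex == 0)].sum())
        p = two_proportion_pvalue(cm, nm, cf, nf)
        rows.append(
            {"variable": outcome,
             "overall": yk[obs].mean() if obs.any() else np.nan,
             "male": cm / nm if nm else np.nan,
             "female": cf / nf if nf else np.nan, "p_value": p}
        )
    return pd.DataFrame(rows)


def two_proportion_pvalue(c1: int, n1: int, c2: int, n2: int) -> float:
    """Two-proportion chi-square p-value (2x2 table, no continuity correction).

    Equals the squared two-sample z-test for proportions.  Returns 1.0 when
    the pooled table is degenerate (all successes or all failures).
    """
    if n1 < 2 or n2 < 2:
        return float("nan")
    table = np.array([[c1, n1 - c1], [c2, n2 - c2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=False)[1])


# ---------------------------------------------------------------------------
# Delimited I/O

_REQUIRED_COLUMNS = ("person_id", "province_id", "age", "sex", "sampling_weight")
_OPTIONAL_COLUMNS = (
    "fasting_glucose", "self_report_diabetes", "bmi", "sbp", "dbp",
    "hta_treatment", "ldl", "cvr_category",
)
_INT_FIELDS = {"province_id", "sex", "self_report_diabetes", "hta_treatment"}


def read_survey_table(
    path: str | Path,
    column_map: dict[str, str] | str | Path | None = None,
    sep: str | None = None,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> list[SurveyIndividual]:
    """Read a delimited survey table (comma or tab, header row).

    ``column_map`` maps canonical field names to the file's column names,
    either as a dict or as a path to a YAML file with a ``columns:`` mapping.
    Unknown columns raise a warning; missing required columns an error.
    """
    if isinstance(column_map, (str, Path)):
        import yaml

        with open(column_map) as fh:
            cfg = yaml.safe_load(fh) or {}
        column_map = cfg.get("columns", cfg)
    column_map = dict(column_map or {})

    df = pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c",
        na_values=list(na_tokens), keep_default_na=False, dtype=str,
    )
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)

    known = set(_REQUIRED_COLUMNS) | set(_OPTIONAL_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    individuals = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for name in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS:
            if name not in df.columns:
                continue
            raw = row[name]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                val = None
            elif name in ("person_id", "cvr_category"):
                val = str(raw)
            elif name in _INT_FIELDS:
                val = int(float(raw))
            else:
                val = float(raw)
            if name in _REQUIRED_COLUMNS and val is None:
                raise ValidationError(f"required field {name!r} missing in row {row.name}")
            kwargs[name] = val
        individuals.append(SurveyIndividual(**kwargs))
    return individuals


def write_survey_table(
    individuals: Sequence[SurveyIndividual], path: str | Path, sep: str = ","
) -> None:
    """Write individuals in the dialect :func:`read_survey_table` accepts."""
    cols = [f.name for f in dc_fields(SurveyIndividual)]
    rows = [{c: getattr(ind, c) for c in cols} for ind in individuals]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False, na_rep="NA")


_PROVINCE_COLUMNS = [
    "province_id", "n_sampled", *(f"cases_{o}" for o in OUTCOMES),
    *(f"n_obs_{o}" for o in OUTCOMES), "mean_age", "prop_male", "mean_weight",
    "sampled_flag",
]


def write_province_table(
    aggregates: Sequence[ProvinceAggregate], path: str | Path, sep: str = ","
) -> None:
    """Write the province aggregate table as delimited text."""
    rows = []
    for a in aggregates:
        row = {"province_id": a.province_id, "n_sampled": a.n_sampled,
               "mean_age": a.mean_age, "prop_male": a.prop_male,
               "mean_weight": a.mean_weight, "sampled_flag": a.sampled_flag}
        for k, o in enumerate(OUTCOMES):
            row[f"cases_{o}"] = int(a.case_counts[k])
            row[f"n_obs_{o}"] = int(a.n_observed[k])
        rows.append(row)
    pd.DataFrame(rows, columns=_PROVINCE_COLUMNS).to_csv(
        path, sep=sep, index=False, na_rep="NA"
    )


def read_province_table(path: str | Path, sep: str = ",") -> list[ProvinceAggregate]:
    """Inverse of :func:`write_province_table` (round-trip identity)."""
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            ProvinceAggregate(
                province_id=int(row["province_id"]),
                n_sampled=int(row["n_sampled"]),
                case_counts=np.array([row[f"cases_{o}"] for o in OUTCOMES], dtype=np.int64),
                n_observed=np.array([row[f"n_obs_{o}"] for o in OUTCOMES], dtype=np.int64),
                mean_age=None if pd.isna(row["mean_age"]) else float(row["mean_age"]),
                prop_male=None if pd.isna(row["prop_male"]) else float(row["prop_male"]),
                mean_weight=None if pd.isna(row["mean_weight"]) else float(row["mean_weight"]),
                sampled_flag=int(row["sampled_flag"]),
            )
        )
    return out
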