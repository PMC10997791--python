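"""Ancestry-stratified PheWAS engine.

Reduces an individual-level cohort table to per-stratum, per-phenotype
association summary statistics under the standard PheWAS model:

* case status for a PheCode requires at least 2 occurrences of the code
  (single mentions are treated as control, for positive predictive value);
* PheCodes at 0.5% prevalence or less in a stratum are excluded, as are
  integer-level (parent) codes with at least one retained decimal
  descendant — filtering is per stratum;
* binary phenotypes: logistic regression of case status on allele dosage,
  adjusted for age, sex, years of EHR follow-up, and utilization measured
  as the natural log of the total PheCode count;
* labs: per-subject median of all available measurements, log-transformed,
  then ordinary least squares with the same covariates.

The dosage coefficient and its standard error from each stratum become a
:class:`~hetfdr.core_stats.GroupAssociation`; phenotypes surviving in both
strata are paired into :class:`~hetfdr.core_stats.PhenotypeRecord` for
heterogeneity testing, the rest are reported separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_stats import GroupAssociation, PhenotypeRecord

__all__ = [
    "CohortTable",
    "PhenotypeCatalog",
    "define_case_status",
    "filter_phenotypes",
    "aggregate_lab",
    "fit_binary_association",
    "fit_lab_association",
    "run_stratified_phewas",
    "PhewasResult",
]

logger = logging.getLogger(__name__)

PREVALENCE_FLOOR = 0.005
MIN_LAB_SUBJECTS = 30


@dataclass(frozen=True)
class CohortTable:
    """Individual-level cohort.

    ``subjects``: one row per subject with columns ``subject_id``,
    ``ancestry``, ``dosage`` (0/1/2 copies of the minor allele), ``age``
    (years), ``sex`` (binary), ``followup`` (years), ``code_total``
    (total PheCode occurrences, >= 1 so its log is defined).
    ``phecode_counts``: long table ``subject_id, phecode, count`` (sparse;
    absent rows mean zero).  ``labs``: long table
    ``subject_id, lab, value`` with one row per measurement (positive).
    """

    subjects: pd.DataFrame
    phecode_counts: pd.DataFrame
    labs: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "ancestry", "dosage", "age", "sex", "followup", "code_total"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise ValueError(f"subjects table missing columns: {sorted(missing)}")
        dosage = self.subjects["dosage"]
        if not dosage.isin([0, 1, 2]).all():
            raise ValueError("dosage must be 0, 1 or 2")
        if (self.subjects["code_total"] < 1).any():
            raise ValueError("code_total must be >= 1 (log utilization must be defined)")
        if (self.subjects["followup"] < 0).any():
            raise ValueError("followup must be non-negative")

    @property
    def strata(self) -> list[str]:
        return sorted(self.subjects["ancestry"].unique())


@dataclass(frozen=True)
class PhenotypeCatalog:
    """PheCode list with its string-derived hierarchy, plus lab names.

    Integer-level codes (no decimal point) are parents of decimal
    descendants sharing the integer prefix: "250" is the parent of "250.1"
    and "250.2".
    """

    phecodes: tuple[str, ...]
    labs: tuple[str, ...] = ()

    def descendants(self, code: str) -> list[str]:
        if "." in code:
            return []
        prefix = code + "."
        return [c for c in self.phecodes if c.startswith(prefix)]

    @classmethod
    def from_cohort(cls, cohort: CohortTable) -> "PhenotypeCatalog":
        codes = tuple(sorted(cohort.phecode_counts["phecode"].unique()))
        labs = tuple(sorted(cohort.labs["lab"].unique()))
        return cls(phecodes=codes, labs=labs)


def define_case_status(count: int) -> int:
    """1 iff the subject has at least 2 occurrences of the PheCode."""
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count!r}")
    return int(count >= 2)


def case_matrix(cohort: CohortTable) -> pd.DataFrame:
    """Subjects x PheCodes 0/1 case matrix under the at-least-2-codes rule."""
    counts = cohort.phecode_counts
    wide = counts.pivot_table(
        index="subject_id", columns="phecode", values="count", aggfunc="sum", fill_value=0
    )
    cases = (wide >= 2).astype(int)
    return cases.reindex(cohort.subjects["subject_id"], fill_value=0)


def filter_phenotypes(
    catalog: PhenotypeCatalog, cases: pd.DataFrame, stratum_ids: Sequence[str]
) -> list[str]:
    """Retained PheCodes for one stratum.

    Drops codes whose stratum prevalence is 0.5% or less (the boundary is
    excluded), then drops integer-level codes with at least one retained
    descendant.  Order-stable in catalog order and idempotent.
    """
    stratum_ids = list(stratum_ids)
    if not stratum_ids:
        raise ValueError("empty stratum")
    sub = cases.reindex(stratum_ids, fill_value=0)
    prevalence = sub.mean(axis=0)
    common = [
        c for c in catalog.phecodes if c in prevalence.index and prevalence[c] > PREVALENCE_FLOOR
    ]
    common_set = set(common)
    retained = []
    for code in common:
        if "." not in code and any(d in common_set for d in catalog.descendants(code)):
            continue  # parent with a retained descendant
        retained.append(code)
    return retained


def aggregate_lab(measurements: Sequence[float]) -> float:
    """Per-subject lab value: the median of all available measurements.

    An even count yields the mean of the two central order statistics.
    Raises on an empty list — a subject with no measurements is excluded
    for that lab, never zero-filled.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements; subject should be excluded for this lab")
    return float(np.median(np.asarray(measurements, dtype=float)))


def _covariate_design(sub: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, dosage, age, sex, followup, log utilization.

    A covariate that is constant within the stratum (sex, in a heavily male
    cohort) is dropped with a warning; a constant dosage makes the fit
    impossible and is handled by the callers.
    """
    cols: dict[str, np.ndarray] = {
        "const": np.ones(len(sub)),
        "dosage": sub["dosage"].to_numpy(dtype=float),
        "age": sub["age"].to_numpy(dtype=float),
        "sex": sub["sex"].to_numpy(dtype=float),
        "followup": sub["followup"].to_numpy(dtype=float),
        "log_code_total": np.log(sub["code_total"].to_numpy(dtype=float)),
    }
    for name in ("sex", "age", "followup", "log_code_total"):
        if np.ptp(cols[name]) == 0:
            warnings.warn(f"covariate {name!r} is constant in stratum; dropped", stacklevel=3)
            del cols[name]
    return np.column_stack(list(cols.values())), list(cols)


def fit_binary_association(
    stratum: pd.DataFrame, case: np.ndarray, phecode: str
) -> GroupAssociation | None:
    """Logistic regression of case status on dosage plus covariates.

    Returns the dosage log-odds-ratio per allele copy with its standard
    error, or ``None`` (with a logged reason) when the stratum has no
    cases, no controls, constant dosage, or the fit does not converge —
    such phenotype/stratum pairs are excluded rather than imputed.
    """
    case = np.asarray(case, dtype=float)
    group = str(stratum["ancestry"].iloc[0])
    if case.sum() == 0 or case.sum() == len(case):
        logger.info("%s/%s skipped: all-%s", phecode, group, "case" if case.sum() else "control")
        return None
    if stratum["dosage"].nunique() < 2:
        logger.info("%s/%s skipped: constant dosage", phecode, group)
        return None
    X, names = _covariate_design(stratum)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(case, X).fit(disp=0, maxiter=100)
        idx = names.index("dosage")
        beta, se = float(fit.params[idx]), float(fit.bse[idx])
        if not (np.isfinite(beta) and np.isfinite(se) and se > 0) or se > 1e3:
            raise ValueError("unstable fit (separation?)")
    except Exception as exc:
        logger.info("%s/%s skipped: %s", phecode, group, exc)
        return None
    return GroupAssociation(group_id=group, beta=beta, se=se, n=len(stratum))


def fit_lab_association(
    stratum: pd.DataFrame, lab_values: pd.Series, lab: str
) -> GroupAssociation | None:
    """OLS of log median lab value on dosage plus covariates.

    ``lab_values`` is indexed by subject_id (one median per measured
    subject); unmeasured or non-positive values are excluded with a count
    logged.  Requires at least 30 measured subjects and non-constant
    dosage.
    """
    group = str(stratum["ancestry"].iloc[0])
    sub = stratum.set_index("subject_id")
    values = lab_values.reindex(sub.index).dropna()
    n_nonpos = int((values <= 0).sum())
    if n_nonpos:
        logger.info("%s/%s: excluding %d non-positive lab values", lab, group, n_nonpos)
        values = values[values > 0]
    if len(values) < MIN_LAB_SUBJECTS:
        logger.info("%s/%s skipped: only %d measured subjects", lab, group, len(values))
        return None
    sub = sub.loc[values.index].reset_index()
    if sub["dosage"].nunique() < 2:
        logger.info("%s/%s skipped: constant dosage", lab, group)
        return None
    X, names = _covariate_design(sub)
    fit = sm.OLS(np.log(values.to_numpy(dtype=float)), X).fit()
    idx = names.index("dosage")
    return GroupAssociation(
        group_id=group, beta=float(fit.params[idx]), se=float(fit.bse[idx]), n=len(sub)
    )


@dataclass
class PhewasResult:
    """Output of the stratified PheWAS.

    ``records``: phenotypes fitted in both strata, paired for heterogeneity
    testing.  ``unpaired``: associations surviving in only one stratum.
    ``skipped``: (phenotype, stratum, reason) triples for auditability.
    """

    records: list[PhenotypeRecord]
    unpaired: list[GroupAssociation] = field(default_factory=list)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)


def run_stratified_phewas(
    cohort: CohortTable, catalog: PhenotypeCatalog | None = None
) -> PhewasResult:
    """Full stratified PheWAS: case definition, filters, fits, pairing.

    Deterministic given the cohort (all fits are seed-free maximum
    likelihood / least squares).
    """
    strata = cohort.strata
    if len(strata) != 2:
        raise ValueError(f"exactly two ancestry strata required, found {strata}")
    if catalog is None:
        catalog = PhenotypeCatalog.from_cohort(cohort)

    cases = case_matrix(cohort)
    lab_medians = (
        cohort.labs.groupby(["lab", "subject_id"])["value"].median()
        if len(cohort.labs)
        else pd.Series(dtype=float)
    )

    by_group: dict[str, dict[str, GroupAssociation]] = {s: {} for s in strata}
    kinds: dict[str, str] = {}
    skipped: list[tuple[str, str, str]] = []
    for s in strata:
        stratum = cohort.subjects[cohort.subjects["ancestry"] == s].reset_index(drop=True)
        ids = stratum["subject_id"].tolist()
        retained = filter_phenotypes(catalog, cases, ids)
        dropped = [c for c in catalog.phecodes if c not in retained]
        skipped.extend((c, s, "filtered (prevalence/hierarchy)") for c in dropped)
        stratum_cases = cases.reindex(ids, fill_value=0)
        for code in retained:
            assoc = fit_binary_association(stratum, stratum_cases[code].to_numpy(), code)
            if assoc is None:
                skipped.append((code, s, "fit skipped"))
            else:
                by_group[s][code] = assoc
                kinds[code] = "binary"
        for lab in catalog.labs:
            values = (
                lab_medians.loc[lab] if len(lab_medians) and lab in lab_medians.index.levels[0]
                else pd.Series(dtype=float)
            )
            assoc = fit_lab_association(stratum, values, lab)
            if assoc is None:
                skipped.append((lab, s, "fit skipped"))
            else:
                by_group[s][lab] = assoc
                kinds[lab] = "continuous"

    a, b = strata
    records, unpaired = [], []
    for name in list(catalog.phecodes) + list(catalog.labs):
        in_a, in_b = name in by_group[a], name in by_group[b]
        if in_a and in_b:
            records.append(
                PhenotypeRecord(
                    phenotype_id=name,
                    trait_kind=kinds[name],
                    assoc_a=by_group[a][name],
                    assoc_b=by_group[b][name],
                )
            )
        elif in_a or in_b:
            unpaired.append(by_group[a if in_a else b][name])
    logger.info(
        "stratified PheWAS: %d paired, %d unpaired, %d skipped entries",
        len(records), len(unpaired), len(skipped),
    )
    return PhewasResult(records=records, unpaired=unpaired, skipped=skipped)
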