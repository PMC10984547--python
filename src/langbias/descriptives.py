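"""Descriptive summaries of review characteristics and covariate preparation.

Categorical characteristics are reported as counts with integer-rounded
percentages (denominators exclude missing values, matching how extraction
tables with footnoted missingness are usually tabulated); metric
characteristics as median (IQR) [range] with type-7 (linear-interpolation)
quartiles.  Covariate preparation dummy-codes each characteristic against
its reference level, centers publication year on the cohort mean, and
enters search precision on the logit scale; rows with a missing model
covariate are dropped (complete-case) with the count logged.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model_io import SRRecord, ValidationError
from .firth_logistic import DesignMatrix

logger = logging.getLogger("langbias")

__all__ = ["search_precision", "prepare_covariates", "summarize", "nonenglish_share"]

PRECISION_CLAMP = 1e-6  # exact 1.0 clamped to 1 - this before the logit


def search_precision(n_included: int, n_retrieved: int) -> float:
    """Included studies divided by deduplicated search records."""
    if n_included < 1:
        raise ValidationError("search_precision: n_included must be >= 1")
    if n_retrieved < n_included:
        raise ValidationError(
            f"search_precision: n_included ({n_included}) exceeds "
            f"n_retrieved ({n_retrieved})")
    return n_included / n_retrieved


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


# reference levels: first level of each tuple
_DUMMIES = {
    "n_authors_band": ("1-3", "4-6", "7-9"),
    "continent": ("America", "AsiaOther", "Europe"),
    "sr_type": ("diagnostic", "epidemiological", "interventional"),
    "study_type": ("animal", "human", "invitro"),
}


def prepare_covariates(records: Sequence[SRRecord]) -> DesignMatrix:
    """Build the multivariable design for the non-English-inclusion model.

    Response: whether the review included at least one non-English study.
    Covariates: author band, continent, review type, centered year,
    registration, number of included studies, logit search precision,
    language restriction, explicit exclusion of non-English studies,
    librarian involvement, whether a meta-analysis was performed, review
    type of question, and type of included studies.
    """
    if not records:
        raise ValidationError("prepare_covariates: empty record list")
    usable = [r for r in records
              if r.n_retrieved is not None and r.language_restriction is not None]
    dropped = len(records) - len(usable)
    if dropped:
        logger.info("prepare_covariates: %d record(s) dropped for missing "
                    "precision or language-restriction status", dropped)
    if not usable:
        raise ValidationError("prepare_covariates: no complete-case records")
    year_mean = float(np.mean([r.year for r in usable]))
    rows = []
    for r in usable:
        p = search_precision(r.n_included, r.n_retrieved)
        if p >= 1.0:
            logger.warning("prepare_covariates: SR %s has precision 1.0; "
                           "clamped before logit", r.sr_id)
            p = 1.0 - PRECISION_CLAMP
        row = {"intercept": 1.0}
        for field, levels in _DUMMIES.items():
            val = getattr(r, field)
            for lev in levels[1:]:
                row[f"{field}[{lev}]"] = float(val == lev)
        row["noncochrane"] = float(not r.cochrane)
        row["year_centered"] = r.year - year_mean
        row["prospero"] = float(r.prospero)
        row["n_included"] = float(r.n_included)
        row["precision_logit"] = _logit(p)
        row["language_restriction"] = float(r.language_restriction)
        row["excluded_nonenglish"] = float(r.excluded_nonenglish)
        row["librarian"] = float(r.librarian)
        row["ma_performed"] = float(r.ma_performed)
        rows.append(row)
    X = pd.DataFrame(rows)
    # unused factor levels / characteristics without variation contribute
    # constant columns; drop them (they are unidentifiable), keep intercept
    constant = [c for c in X.columns
                if c != "intercept" and X[c].nunique() == 1]
    if constant:
        logger.info("prepare_covariates: dropping constant column(s) %s",
                    constant)
        X = X.drop(columns=constant)
    y = np.array([float(r.non_english_included) for r in usable])
    return DesignMatrix(columns=X, response=y)


_CATEGORICAL = [
    ("n_authors_band", ("1-3", "4-6", "7-9")),
    ("continent", ("America", "AsiaOther", "Europe")),
    ("cochrane", (True, False)),
    ("year", (2017, 2018, 2019, 2020, 2021)),
    ("prospero", (False, True)),
    ("non_english_included", (False, True)),
    ("language_restriction", (False, True)),
    ("excluded_nonenglish", (False, True)),
    ("librarian", (False, True)),
    ("ma_performed", (False, True)),
    ("sr_type", ("diagnostic", "epidemiological", "interventional")),
    ("study_type", ("animal", "human", "invitro")),
]


def _metric_row(values: list[float]) -> dict:
    if not values:
        return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan,
                "min": np.nan, "max": np.nan}
    a = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(a, [0.25, 0.5, 0.75])  # type-7 interpolation
    return {"n": len(a), "median": float(med), "q1": float(q1),
            "q3": float(q3), "min": float(a.min()), "max": float(a.max())}


def summarize(records: Sequence[SRRecord]) -> dict[str, pd.DataFrame]:
    """Frequency and metric summaries overall and by non-English inclusion.

    Returns ``{"categorical": ..., "metric": ...}``.  Percentages are
    rounded to integers; percentage denominators are the non-missing counts
    within each column group.
    """
    if not records:
        raise ValidationError("summarize: empty record list")
    groups = {
        "overall": list(records),
        "no": [r for r in records if not r.non_english_included],
        "yes": [r for r in records if r.non_english_included],
    }
    cat_rows = []
    for field, levels in _CATEGORICAL:
        for lev in levels:
            row = {"field": field, "level": lev}
            for gname, grp in groups.items():
                vals = [getattr(r, field) for r in grp]
                nonmiss = [v for v in vals if v is not None]
                n = sum(v == lev for v in nonmiss)
                denom = len(nonmiss)
                row[f"n_{gname}"] = n
                row[f"pct_{gname}"] = int(round(100.0 * n / denom)) if denom else 0
            cat_rows.append(row)
    metric_rows = []
    metric_fields = {
        "n_included": lambda r: r.n_included,
        "precision": lambda r: (search_precision(r.n_included, r.n_retrieved)
                                if r.n_retrieved is not None else None),
        "n_nonenglish_langs": lambda r: r.n_nonenglish_langs,
    }
    for field, get in metric_fields.items():
        for gname, grp in groups.items():
            vals = [get(r) for r in grp]
            vals = [v for v in vals if v is not None]
            metric_rows.append({"field": field, "group": gname, **_metric_row(vals)})
    return {"categorical": pd.DataFrame(cat_rows),
            "metric": pd.DataFrame(metric_rows)}


def nonenglish_share(records: Sequence[SRRecord],
                     per_sr_counts: Sequence[int]) -> float:
    """Percent of non-English studies among all studies included in the
    reviews; ``per_sr_counts`` holds each review's non-English study count,
    aligned with ``records``."""
    if len(records) != len(per_sr_counts):
        raise ValidationError("nonenglish_share: counts must align with records")
    total = sum(r.n_included for r in records)
    if total == 0:
        raise ValidationError("nonenglish_share: zero total included studies")
    ne = sum(per_sr_counts)
    return 100.0 * ne / total
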