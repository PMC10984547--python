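"""Domain types and delimited-text I/O for the language-bias analysis.

Two tabular inputs drive the pipeline:

* a *trial table* — one row per trial (arm-level group statistics or an
  already-standardized contrast), nested in meta-analyses via ``ma_id``;
* a *systematic-review (SR) characteristics table* — one row per review.

Both are comma-delimited UTF-8 with a mandatory header.  Booleans are coded
``yes``/``no`` and missing values as empty fields, mirroring the wording of
typical extraction spreadsheets.  Readers validate every invariant on entry
and never coerce silently; writers round-trip all values at full precision.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("langbias")

__all__ = [
    "ValidationError",
    "TrialRecord",
    "MetaAnalysisData",
    "EffectEstimate",
    "DeltaSMD",
    "BiasSummary",
    "SRRecord",
    "LogisticFit",
    "read_trial_table",
    "read_sr_table",
    "write_trial_table",
    "write_sr_table",
    "write_results",
    "forest_table",
    "bias_summary_dict",
]


class ValidationError(ValueError):
    """Raised when a record or table violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_DATA_LEVELS = ("arm", "contrast")


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """One trial's effect data, either arm-level or contrast-level.

    Arm-level rows carry per-group mean, SD and size for two arms; the
    standardized mean difference is computed downstream.  Contrast-level rows
    carry the SMD and its standard error exactly as reported in the source
    forest plot.
    """

    trial_id: str
    ma_id: str
    non_english: bool
    data_level: str
    arm1_mean: float | None = None
    arm1_sd: float | None = None
    arm1_n: int | None = None
    arm2_mean: float | None = None
    arm2_sd: float | None = None
    arm2_n: int | None = None
    smd: float | None = None
    smd_se: float | None = None

    def __post_init__(self) -> None:
        if self.data_level not in _DATA_LEVELS:
            raise ValidationError(
                f"trial {self.trial_id!r}: data_level must be one of {_DATA_LEVELS}, "
                f"got {self.data_level!r}"
            )
        arm_fields = (self.arm1_mean, self.arm1_sd, self.arm1_n,
                      self.arm2_mean, self.arm2_sd, self.arm2_n)
        contrast_fields = (self.smd, self.smd_se)
        if self.data_level == "arm":
            if any(f is None for f in arm_fields):
                raise ValidationError(
                    f"trial {self.trial_id!r}: arm-level row missing arm fields"
                )
            if any(f is not None for f in contrast_fields):
                raise ValidationError(
                    f"trial {self.trial_id!r}: arm-level row must not carry smd/smd_se"
                )
            for label, sd in (("arm1_sd", self.arm1_sd), ("arm2_sd", self.arm2_sd)):
                if not sd > 0:
                    raise ValidationError(
                        f"trial {self.trial_id!r}: {label} must be > 0, got {sd}"
                    )
            for label, n in (("arm1_n", self.arm1_n), ("arm2_n", self.arm2_n)):
                if not (isinstance(n, int) and n >= 2):
                    raise ValidationError(
                        f"trial {self.trial_id!r}: {label} must be an integer >= 2, got {n}"
                    )
        else:
            if any(f is not None for f in arm_fields):
                raise ValidationError(
                    f"trial {self.trial_id!r}: contrast-level row must not carry arm fields"
                )
            if any(f is None for f in contrast_fields):
                raise ValidationError(
                    f"trial {self.trial_id!r}: contrast-level row missing smd/smd_se"
                )
            if not self.smd_se > 0:
                raise ValidationError(
                    f"trial {self.trial_id!r}: smd_se must be > 0, got {self.smd_se}"
                )


_OUTCOME_ROLES = ("primary", "secondary")


@dataclass(slots=True)
class MetaAnalysisData:
    """One meta-analysis: an ordered set of trials sharing an ``ma_id``.

    Trial order is preserved exactly as read (forest-plot order); the
    pipeline never re-sorts.
    """

    ma_id: str
    sr_id: str
    outcome_role: str
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.outcome_role not in _OUTCOME_ROLES:
            raise ValidationError(
                f"meta-analysis {self.ma_id!r}: outcome_role must be one of "
                f"{_OUTCOME_ROLES}, got {self.outcome_role!r}"
            )
        seen: set[str] = set()
        for t in self.trials:
            if t.ma_id != self.ma_id:
                raise ValidationError(
                    f"meta-analysis {self.ma_id!r}: trial {t.trial_id!r} "
                    f"carries ma_id {t.ma_id!r}"
                )
            if t.trial_id in seen:
                raise ValidationError(
                    f"meta-analysis {self.ma_id!r}: duplicate trial_id {t.trial_id!r}"
                )
            seen.add(t.trial_id)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_nonenglish(self) -> int:
        return sum(t.non_english for t in self.trials)


@dataclass(frozen=True, slots=True)
class EffectEstimate:
    """A study effect on the SMD scale with its sampling variance."""

    y: float
    v: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValidationError(f"effect variance must be > 0, got {self.v}")


@dataclass(frozen=True, slots=True)
class DeltaSMD:
    """Stage-1 result for one meta-analysis: the non-English-vs-English
    difference in SMD (ΔSMD), its variance, and the within-meta-analysis
    heterogeneity τ² under which it was estimated."""

    ma_id: str
    delta: float
    var_delta: float
    tau2: float
    k_total: int
    k_nonenglish: int

    def __post_init__(self) -> None:
        if not self.var_delta > 0:
            raise ValidationError(f"{self.ma_id}: var_delta must be > 0")
        if self.tau2 < 0:
            raise ValidationError(f"{self.ma_id}: tau2 must be >= 0")
        if self.k_total < 3:
            raise ValidationError(f"{self.ma_id}: k_total must be >= 3")
        if self.k_nonenglish < 1:
            raise ValidationError(f"{self.ma_id}: k_nonenglish must be >= 1")


@dataclass(frozen=True, slots=True)
class BiasSummary:
    """Stage-2 pooled ΔSMD across meta-analyses.

    ``kappa2`` is the between-meta-analysis variance of the ΔSMDs (zero by
    definition under the fixed-effect model).  Negative pooled values mean
    non-English trials yield larger effects in the reported direction.
    """

    model: str
    pooled_delta: float
    ci_low: float
    ci_high: float
    p_value: float
    kappa2: float
    n_ma: int

    def __post_init__(self) -> None:
        if self.model not in ("random", "fixed"):
            raise ValidationError(f"model must be 'random' or 'fixed', got {self.model!r}")
        if self.model == "fixed" and self.kappa2 != 0.0:
            raise ValidationError("fixed-effect summary must have kappa2 = 0")
        if not (self.ci_low <= self.pooled_delta <= self.ci_high):
            raise ValidationError("pooled estimate outside its confidence interval")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value outside [0, 1]: {self.p_value}")


_AUTHOR_BANDS = ("1-3", "4-6", "7-9")
_CONTINENTS = ("America", "AsiaOther", "Europe")
_SR_TYPES = ("diagnostic", "epidemiological", "interventional")
_STUDY_TYPES = ("animal", "human", "invitro")
_YEARS = (2017, 2018, 2019, 2020, 2021)


@dataclass(frozen=True, slots=True)
class SRRecord:
    """Characteristics of one systematic review.

    ``n_retrieved`` (deduplicated search records), ``n_nonenglish_langs`` and
    ``language_restriction`` admit explicit missingness (``None``); everything
    else is mandatory.
    """

    sr_id: str
    n_authors_band: str
    continent: str
    cochrane: bool
    year: int
    prospero: bool
    n_included: int
    n_retrieved: int | None
    non_english_included: bool
    n_nonenglish_langs: int | None
    language_restriction: bool | None
    excluded_nonenglish: bool
    librarian: bool
    ma_performed: bool
    sr_type: str
    study_type: str

    def __post_init__(self) -> None:
        def _enum(name: str, value, allowed) -> None:
            if value not in allowed:
                raise ValidationError(
                    f"SR {self.sr_id!r}: {name} must be one of {allowed}, got {value!r}"
                )

        _enum("n_authors_band", self.n_authors_band, _AUTHOR_BANDS)
        _enum("continent", self.continent, _CONTINENTS)
        _enum("sr_type", self.sr_type, _SR_TYPES)
        _enum("study_type", self.study_type, _STUDY_TYPES)
        if self.year not in _YEARS:
            raise ValidationError(
                f"SR {self.sr_id!r}: year must be within {_YEARS[0]}-{_YEARS[-1]}, "
                f"got {self.year}"
            )
        if not self.n_included >= 1:
            raise ValidationError(f"SR {self.sr_id!r}: n_included must be >= 1")
        if self.n_retrieved is not None and self.n_retrieved < self.n_included:
            raise ValidationError(
                f"SR {self.sr_id!r}: n_retrieved ({self.n_retrieved}) < "
                f"n_included ({self.n_included})"
            )
        if self.n_nonenglish_langs is not None and self.n_nonenglish_langs < 0:
            raise ValidationError(f"SR {self.sr_id!r}: n_nonenglish_langs must be >= 0")


@dataclass(slots=True)
class LogisticFit:
    """Coefficients and inference from a (possibly penalized) logistic fit."""

    coef_names: list[str]
    beta: "list[float]"
    or_: "list[float]"
    ci_low: "list[float]"
    ci_high: "list[float]"
    p_values: "list[float]"
    method: str
    converged: bool
    loglik: float = float("nan")
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("mle", "firth"):
            raise ValidationError(f"method must be 'mle' or 'firth', got {self.method!r}")
        for b, o in zip(self.beta, self.or_):
            if math.isfinite(b) and abs(o - math.exp(b)) > 1e-8 * max(1.0, o):
                raise ValidationError("or_ must equal exp(beta) elementwise")
        for lo, hi in zip(self.ci_low, self.ci_high):
            if math.isfinite(lo) and math.isfinite(hi) and not lo < hi:
                raise ValidationError("ci_low must be < ci_high where finite")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.coef_names,
                "beta": self.beta,
                "or": self.or_,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            }
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_id", "ma_id", "sr_id", "outcome_role", "non_english", "data_level",
    "arm1_mean", "arm1_sd", "arm1_n", "arm2_mean", "arm2_sd", "arm2_n",
    "smd", "smd_se",
]

_SR_COLUMNS = [
    "sr_id", "n_authors_band", "continent", "cochrane", "year", "prospero",
    "n_included", "n_retrieved", "non_english_included", "n_nonenglish_langs",
    "language_restriction", "excluded_nonenglish", "librarian", "ma_performed",
    "sr_type", "study_type",
]


def _parse_bool(value, row: int, col: str):
    if value is None:
        return None
    s = str(value).strip().lower()
    if s in ("yes", "true", "1"):
        return True
    if s in ("no", "false", "0"):
        return False
    raise ValidationError(f"row {row}: field {col!r}: expected yes/no, got {value!r}")


def _opt_float(value, row: int, col: str) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {row}: field {col!r}: not a number: {value!r}") from exc


def _opt_int(value, row: int, col: str) -> int | None:
    f = _opt_float(value, row, col)
    if f is None:
        return None
    if f != int(f):
        raise ValidationError(f"row {row}: field {col!r}: expected an integer, got {value!r}")
    return int(f)


def _read_csv(path: str | Path, required: Sequence[str], dialect: Mapping | None) -> pd.DataFrame:
    opts = {"sep": ",", "encoding": "utf-8"}
    if dialect:
        opts.update(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **opts)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_trial_table(path: str | Path, dialect: Mapping | None = None) -> list[MetaAnalysisData]:
    """Read a trial table and group rows into meta-analyses.

    Rows are grouped by ``ma_id`` in first-appearance order; within a
    meta-analysis, file order is preserved.  Every row is validated against
    the :class:`TrialRecord` invariants; errors name the offending row.
    """
    df = _read_csv(path, _TRIAL_COLUMNS, dialect)
    mas: dict[str, MetaAnalysisData] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        r = row._asdict()
        try:
            rec = TrialRecord(
                trial_id=str(r["trial_id"]),
                ma_id=str(r["ma_id"]),
                non_english=_parse_bool(r["non_english"], i, "non_english"),
                data_level=str(r["data_level"]).strip(),
                arm1_mean=_opt_float(r["arm1_mean"], i, "arm1_mean"),
                arm1_sd=_opt_float(r["arm1_sd"], i, "arm1_sd"),
                arm1_n=_opt_int(r["arm1_n"], i, "arm1_n"),
                arm2_mean=_opt_float(r["arm2_mean"], i, "arm2_mean"),
                arm2_sd=_opt_float(r["arm2_sd"], i, "arm2_sd"),
                arm2_n=_opt_int(r["arm2_n"], i, "arm2_n"),
                smd=_opt_float(r["smd"], i, "smd"),
                smd_se=_opt_float(r["smd_se"], i, "smd_se"),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        ma_id = rec.ma_id
        sr_id = str(r["sr_id"])
        role = str(r["outcome_role"]).strip()
        if ma_id not in mas:
            mas[ma_id] = MetaAnalysisData(ma_id=ma_id, sr_id=sr_id, outcome_role=role)
        else:
            if mas[ma_id].sr_id != sr_id or mas[ma_id].outcome_role != role:
                raise ValidationError(
                    f"row {i}: meta-analysis {ma_id!r} has inconsistent "
                    f"sr_id/outcome_role across rows"
                )
        mas[ma_id].trials.append(rec)
    out = []
    for ma in mas.values():
        # re-run invariant checks now that the trial list is complete
        out.append(MetaAnalysisData(ma.ma_id, ma.sr_id, ma.outcome_role, ma.trials))
    return out


def read_sr_table(path: str | Path, dialect: Mapping | None = None) -> list[SRRecord]:
    """Read a systematic-review characteristics table.

    Missing values must be empty fields and are only allowed in
    ``n_retrieved``, ``n_nonenglish_langs`` and ``language_restriction``.
    """
    df = _read_csv(path, _SR_COLUMNS, dialect)
    if df.empty:
        logger.warning("read_sr_table: %s contains no records", path)
        return []
    records: list[SRRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        try:
            lr_raw = r["language_restriction"]
            lr = None if not str(lr_raw).strip() else _parse_bool(lr_raw, i, "language_restriction")
            records.append(SRRecord(
                sr_id=str(r["sr_id"]),
                n_authors_band=str(r["n_authors_band"]).strip(),
                continent=str(r["continent"]).strip(),
                cochrane=_parse_bool(r["cochrane"], i, "cochrane"),
                year=_opt_int(r["year"], i, "year"),
                prospero=_parse_bool(r["prospero"], i, "prospero"),
                n_included=_opt_int(r["n_included"], i, "n_included"),
                n_retrieved=_opt_int(r["n_retrieved"], i, "n_retrieved"),
                non_english_included=_parse_bool(r["non_english_included"], i, "non_english_included"),
                n_nonenglish_langs=_opt_int(r["n_nonenglish_langs"], i, "n_nonenglish_langs"),
                language_restriction=lr,
                excluded_nonenglish=_parse_bool(r["excluded_nonenglish"], i, "excluded_nonenglish"),
                librarian=_parse_bool(r["librarian"], i, "librarian"),
                ma_performed=_parse_bool(r["ma_performed"], i, "ma_performed"),
                sr_type=str(r["sr_type"]).strip(),
                study_type=str(r["study_type"]).strip(),
            ))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _bool_str(b: bool | None) -> str:
    if b is None:
        return ""
    return "yes" if b else "no"


def write_trial_table(mas: Iterable[MetaAnalysisData], path: str | Path) -> None:
    """Write meta-analyses back to the canonical trial-table CSV."""
    rows = []
    for ma in mas:
        for t in ma.trials:
            rows.append({
                "trial_id": t.trial_id,
                "ma_id": t.ma_id,
                "sr_id": ma.sr_id,
                "outcome_role": ma.outcome_role,
                "non_english": _bool_str(t.non_english),
                "data_level": t.data_level,
                "arm1_mean": t.arm1_mean, "arm1_sd": t.arm1_sd, "arm1_n": t.arm1_n,
                "arm2_mean": t.arm2_mean, "arm2_sd": t.arm2_sd, "arm2_n": t.arm2_n,
                "smd": t.smd, "smd_se": t.smd_se,
            })
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def write_sr_table(records: Iterable[SRRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sr_id": r.sr_id,
            "n_authors_band": r.n_authors_band,
            "continent": r.continent,
            "cochrane": _bool_str(r.cochrane),
            "year": r.year,
            "prospero": _bool_str(r.prospero),
            "n_included": r.n_included,
            "n_retrieved": "" if r.n_retrieved is None else r.n_retrieved,
            "non_english_included": _bool_str(r.non_english_included),
            "n_nonenglish_langs": "" if r.n_nonenglish_langs is None else r.n_nonenglish_langs,
            "language_restriction": _bool_str(r.language_restriction),
            "excluded_nonenglish": _bool_str(r.excluded_nonenglish),
            "librarian": _bool_str(r.librarian),
            "ma_performed": _bool_str(r.ma_performed),
            "sr_type": r.sr_type,
            "study_type": r.study_type,
        })
    pd.DataFrame(rows, columns=_SR_COLUMNS).to_csv(path, index=False)


def forest_table(deltas: Sequence[DeltaSMD], level: float = 0.95) -> pd.DataFrame:
    """Plot-ready per-meta-analysis ΔSMD table (forest-plot layout)."""
    from scipy.stats import norm

    if not deltas:
        raise ValidationError("forest_table: no stage-1 estimates to tabulate")
    z = norm.ppf(0.5 + level / 2.0)
    rows = [{
        "ma_id": d.ma_id,
        "delta": d.delta,
        "ci_low": d.delta - z * math.sqrt(d.var_delta),
        "ci_high": d.delta + z * math.sqrt(d.var_delta),
        "tau2": d.tau2,
        "k_total": d.k_total,
        "k_nonenglish": d.k_nonenglish,
    } for d in deltas]
    return pd.DataFrame(rows)


def bias_summary_dict(summary: BiasSummary) -> dict:
    return {
        "model": summary.model,
        "pooled_delta": summary.pooled_delta,
        "ci_low": summary.ci_low,
        "ci_high": summary.ci_high,
        "p_value": summary.p_value,
        "kappa2": summary.kappa2,
        "n_ma": summary.n_ma,
    }


def write_results(tables: Mapping[str, pd.DataFrame],
                  out_dir: str | Path,
                  summaries: Mapping[str, Mapping] | None = None) -> list[Path]:
    """Write result tables as CSV and per-analysis summaries as JSON.

    Returns the list of paths written.  Empty tables are rejected: an empty
    analysis output indicates an upstream failure and must not masquerade as
    a result file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        if table is None or len(table) == 0:
            raise ValidationError(f"write_results: table {name!r} is empty")
        p = out / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.17g")
        written.append(p)
    for name, payload in (summaries or {}).items():
        p = out / f"{name}.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(dict(payload), fh, indent=2)
        written.append(p)
    return written
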