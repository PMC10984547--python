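"""Synthetic meta-epidemiological trial tables and review tables.

Two generators plus one frozen fixture:

* :func:`gen_metaepi` draws trials nested in meta-analyses under the same
  hierarchical model the two-stage analysis assumes: per-meta-analysis true
  effects, within-meta-analysis heterogeneity tau, a per-meta-analysis
  language-bias effect centered at delta with spread kappa, and two normal
  arms per trial so the observed standardized mean difference estimates the
  trial's true effect.
* :func:`gen_sr_table` draws review characteristics from configurable
  marginal frequencies and a logistic response model, optionally with one
  covariate level made perfectly predictive (complete separation) to
  exercise the penalized regression.
* :func:`cohort_fixture` is a deterministic 174-review table whose marginal
  counts — overall and split by non-English inclusion — equal the published
  cohort's characteristic table, including the footnoted missingness.  The
  joint structure beyond those margins is arbitrary but fixed; it is a
  synthetic stand-in, not the original row-level data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model_io import MetaAnalysisData, SRRecord, TrialRecord, ValidationError

__all__ = [
    "MetaEpiSimConfig",
    "SRSimConfig",
    "gen_metaepi",
    "gen_sr_table",
    "cohort_fixture",
    "cohort_nonenglish_study_counts",
]


# ---------------------------------------------------------------------------
# Meta-epidemiological trial generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaEpiSimConfig:
    """Generative model for trials nested in meta-analyses.

    Defaults encode the study conditions of the analysis: an average
    language bias of -0.3 SMD with spread 0.1 across meta-analyses,
    within-meta-analysis heterogeneity 0.3, 3-12 trials per meta-analysis
    and per-arm sizes of 15-60.
    """

    K: int = 200
    k_range: tuple[int, int] = (3, 12)
    p_ne: float = 0.25
    mu_theta: float = 0.3
    sd_theta: float = 0.3
    tau: float = 0.3
    delta: float = -0.3
    kappa: float = 0.1
    n_range: tuple[int, int] = (15, 60)
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_range[0] < 3:
            raise ValidationError("k_range minimum must be >= 3")
        if not 0.0 < self.p_ne < 1.0:
            raise ValidationError("p_ne must lie in (0, 1)")
        for name in ("sd_theta", "tau", "kappa"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.n_range[0] < 2:
            raise ValidationError("n_range minimum must be >= 2")


def gen_metaepi(config: MetaEpiSimConfig) -> list[MetaAnalysisData]:
    """Draw a trial table under the hierarchical language-bias model.

    For meta-analysis k: true effect theta_k ~ N(mu_theta, sd_theta^2) and
    bias b_k ~ N(delta, kappa^2).  Trial i's true effect is
    theta_k + b_k L_ki + N(0, tau^2) with L the non-English label; labels
    are resampled wholesale until at least one trial is non-English, which
    keeps them exchangeable.  Arm-level data are two normal samples with a
    standardized mean difference equal to the trial's true effect (summary
    statistics drawn from their exact sampling distributions: normal means,
    chi-square variances).
    """
    rng = np.random.default_rng(config.seed)
    kmin, kmax = config.k_range
    nmin, nmax = config.n_range
    sigma = config.sigma
    out: list[MetaAnalysisData] = []
    for k in range(config.K):
        kt = int(rng.integers(kmin, kmax + 1))
        while True:
            labels = rng.random(kt) < config.p_ne
            # both language groups must be present: the within-meta-analysis
            # regression needs an estimable non-English contrast
            if labels.any() and not labels.all():
                break
        theta = rng.normal(config.mu_theta, config.sd_theta)
        bias = rng.normal(config.delta, config.kappa)
        true = theta + bias * labels + rng.normal(0.0, config.tau, size=kt)
        n1 = rng.integers(nmin, nmax + 1, size=kt)
        n2 = rng.integers(nmin, nmax + 1, size=kt)
        m1 = rng.normal(true * sigma, sigma / np.sqrt(n1))
        m2 = rng.normal(0.0, sigma / np.sqrt(n2))
        s1 = sigma * np.sqrt(rng.chisquare(n1 - 1) / (n1 - 1))
        s2 = sigma * np.sqrt(rng.chisquare(n2 - 1) / (n2 - 1))
        ma_id = f"MA{k + 1:04d}"
        trials = [
            TrialRecord(
                trial_id=f"{ma_id}.T{i + 1:02d}", ma_id=ma_id,
                non_english=bool(labels[i]), data_level="arm",
                arm1_mean=float(m1[i]), arm1_sd=float(s1[i]), arm1_n=int(n1[i]),
                arm2_mean=float(m2[i]), arm2_sd=float(s2[i]), arm2_n=int(n2[i]),
            )
            for i in range(kt)
        ]
        out.append(MetaAnalysisData(ma_id=ma_id, sr_id=f"SR{k + 1:04d}",
                                    outcome_role="primary", trials=trials))
    return out


# ---------------------------------------------------------------------------
# Review-table generator
# ---------------------------------------------------------------------------

def _default_marginals() -> dict:
    """Category probabilities matching the published cohort's margins."""
    return {
        "n_authors_band": {"1-3": 43 / 174, "4-6": 111 / 174, "7-9": 20 / 174},
        "continent": {"America": 46 / 174, "AsiaOther": 51 / 174, "Europe": 77 / 174},
        "cochrane": {True: 9 / 174, False: 165 / 174},
        "year": {2017: 28 / 174, 2018: 32 / 174, 2019: 29 / 174,
                 2020: 37 / 174, 2021: 48 / 174},
        "prospero": {True: 125 / 174, False: 49 / 174},
        "language_restriction": {False: 135 / 174, True: 33 / 174, None: 6 / 174},
        "excluded_nonenglish": {True: 4 / 174, False: 170 / 174},
        "librarian": {True: 37 / 174, False: 137 / 174},
        "ma_performed": {True: 97 / 174, False: 77 / 174},
        "sr_type": {"diagnostic": 9 / 174, "epidemiological": 19 / 174,
                    "interventional": 146 / 174},
        "study_type": {"animal": 12 / 174, "human": 159 / 174, "invitro": 3 / 174},
    }


@dataclass(frozen=True)
class SRSimConfig:
    """Logistic generative model for review characteristics.

    ``beta`` maps characteristic names (binary-coded: restriction yes,
    librarian yes, ...) to log-odds effects on including a non-English
    study; the default reproduces the dominant published association — a
    language restriction cutting the odds to 0.11 of baseline — around a
    baseline inclusion rate giving roughly one review in four overall.
    ``force_separation`` makes the explicit-exclusion level perfectly
    predict non-inclusion, the situation that breaks plain maximum
    likelihood.
    """

    N: int = 174
    marginals: dict = field(default_factory=_default_marginals)
    intercept: float = math.log(0.30 / 0.70)
    beta: dict = field(default_factory=lambda: {"language_restriction": math.log(0.11)})
    force_separation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in self.marginals.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValidationError(f"marginals for {name!r} must sum to 1")


def _draw(rng: np.random.Generator, probs: dict):
    levels = list(probs)
    p = np.array([probs[l] for l in levels], dtype=float)
    return levels[rng.choice(len(levels), p=p / p.sum())]


def gen_sr_table(config: SRSimConfig) -> list[SRRecord]:
    rng = np.random.default_rng(config.seed)
    n_incl_pool = np.array(_NO_N_INCLUDED + _YES_N_INCLUDED)
    prec_pool = np.array(_NO_PRECISION + _YES_PRECISION)
    records: list[SRRecord] = []
    for i in range(config.N):
        row = {name: _draw(rng, probs) for name, probs in config.marginals.items()}
        eta = config.intercept
        for name, b in config.beta.items():
            val = row.get(name)
            eta += b * float(bool(val))
        p_resp = 1.0 / (1.0 + math.exp(-eta))
        ne = bool(rng.random() < p_resp)
        if config.force_separation and row["excluded_nonenglish"]:
            ne = False
        n_included = int(rng.choice(n_incl_pool))
        precision = float(rng.choice(prec_pool))
        n_retrieved = max(n_included, int(round(n_included / precision)))
        langs = int(rng.integers(1, 4)) if ne else None
        records.append(SRRecord(
            sr_id=f"SR{i + 1:04d}",
            n_authors_band=row["n_authors_band"],
            continent=row["continent"],
            cochrane=row["cochrane"],
            year=row["year"],
            prospero=row["prospero"],
            n_included=n_included,
            n_retrieved=n_retrieved,
            non_english_included=ne,
            n_nonenglish_langs=langs,
            language_restriction=row["language_restriction"],
            excluded_nonenglish=row["excluded_nonenglish"],
            librarian=row["librarian"],
            ma_performed=row["ma_performed"],
            sr_type=row["sr_type"],
            study_type=row["study_type"],
        ))
    return records


# ---------------------------------------------------------------------------
# Deterministic 174-review fixture
# ---------------------------------------------------------------------------
# Metric values are frozen sorted lists constructed once so that medians,
# type-7 quartiles and ranges equal the published table in both inclusion
# groups and overall, the included-study counts sum to 2568, and the
# non-English study counts sum to 98.  The one infeasibility (the "No"
# group's Q3 of included studies prints 16.50, which no 129 integer values
# can produce at an exact type-7 order statistic) is resolved to 16.

_NO_N_INCLUDED = (
    [2, 3, 3, 4, 4, 4] + [5] * 5 + [6] * 8 + [7] * 13            # idx 0-31
    + [7]                                                        # idx 32 (Q1)
    + [7] * 7 + [8] * 7 + [9] * 9 + [10] * 8                     # idx 33-63
    + [10]                                                       # idx 64 (median)
    + [10] * 6 + [11] * 6 + [12] * 5 + [13] * 5 + [14] * 4
    + [15] * 3 + [16] * 2                                        # idx 65-95
    + [16]                                                       # idx 96 (Q3)
    + [17] * 6 + [18] * 2 + [19] * 2 + [20] * 2 + [21] * 2
    + [22] * 2 + [23] * 2 + [24] * 2 + [25] * 4 + [26] * 2
    + [28, 30, 34, 40, 66, 94]                                   # idx 97-128
)

_YES_N_INCLUDED = [
    4, 5, 6, 7, 7, 8, 8, 8, 8, 9, 9, 9, 10, 10, 11, 11, 12, 12, 12, 13, 13,
    13, 13, 14, 14, 15, 16, 17, 18, 19, 20, 21, 22, 22, 23, 25, 27, 30, 34,
    38, 42, 48, 55, 60, 63,
]

# Non-English studies per review in the inclusion group (sum 98; median 1,
# IQR 1-3, max 19).
_YES_NE_STUDIES = [1] * 24 + [2] * 9 + [3] * 8 + [4, 4, 5, 19]

# Search-precision targets; the row's deduplicated record count is derived
# as round(n_included / precision).
_NO_PRECISION = (
    [0.001] + [0.004] * 9 + [0.007] * 12 + [0.01] * 20 + [0.015] * 12
    + [0.02] * 20 + [0.03] * 20 + [0.04] * 15 + [0.06] * 8 + [0.08] * 5
    + [0.12] * 4 + [0.2] * 2 + [0.27]
)
_YES_PRECISION = (
    [0.001] + [0.005] * 4 + [0.008] * 4 + [0.01] * 8 + [0.015] * 4
    + [0.02] * 6 + [0.03] * 3 + [0.05] * 2 + [0.07] * 4 + [0.1] * 3
    + [0.15] * 2 + [0.2] + [0.23] + [0.26]
)

# Categorical counts per group: (level, count_in_No_group, count_in_Yes_group)
_CAT_COUNTS = {
    "n_authors_band": [("1-3", 30, 13), ("4-6", 84, 27), ("7-9", 15, 5)],
    "continent": [("America", 33, 13), ("AsiaOther", 40, 11), ("Europe", 56, 21)],
    "cochrane": [(True, 6, 3), (False, 123, 42)],
    "year": [(2017, 17, 11), (2018, 26, 6), (2019, 22, 7),
             (2020, 25, 12), (2021, 39, 9)],
    "prospero": [(False, 42, 7), (True, 87, 38)],
    "language_restriction": [(False, 91, 44), (True, 32, 1), (None, 6, 0)],
    "excluded_nonenglish": [(True, 4, 0), (False, 125, 45)],
    "librarian": [(True, 26, 11), (False, 103, 34)],
    "ma_performed": [(True, 66, 31), (False, 63, 14)],
    "sr_type": [("diagnostic", 8, 1), ("epidemiological", 18, 1),
                ("interventional", 103, 43)],
    "study_type": [("animal", 7, 5), ("human", 119, 40), ("invitro", 3, 0)],
}


def _spread(field_name: str, counts: list[tuple], group_size: int,
            which: int) -> list:
    """Expand level counts to a list and deterministically permute it so the
    fixture's joint structure is scrambled rather than blocky."""
    values: list = []
    for level, n_no, n_yes in counts:
        values.extend([level] * (n_no if which == 0 else n_yes))
    assert len(values) == group_size, field_name
    rng = np.random.default_rng(_stable_seed(field_name, which))
    perm = rng.permutation(group_size)
    return [values[i] for i in perm]


def _stable_seed(name: str, which: int) -> int:
    h = 2166136261
    for ch in f"{name}:{which}":
        h = ((h ^ ord(ch)) * 16777619) % (2**31)
    return h


def _build_group(which: int) -> list[dict]:
    """Assemble one inclusion group's rows (0 = without, 1 = with)."""
    size = 129 if which == 0 else 45
    fields = {name: _spread(name, counts, size, which)
              for name, counts in _CAT_COUNTS.items()}
    metric_rng = np.random.default_rng(_stable_seed("metrics", which))
    perm = metric_rng.permutation(size)
    rows = []
    if which == 0:
        n_incl = _NO_N_INCLUDED
        prec: list[float | None] = list(_NO_PRECISION)
        ne_counts = [0] * size
        langs: list[int | None] = [None] * size
    else:
        n_incl = _YES_N_INCLUDED
        # the first row (smallest review) is the one with unreported
        # precision and language count, per the published footnote
        prec = [None] + list(_YES_PRECISION)
        ne_counts = list(_YES_NE_STUDIES)
        langs = [None] + _YES_NE_STUDIES[1:]
    for pos in range(size):
        i = int(perm[pos])
        p = prec[i]
        n = n_incl[i]
        rows.append({
            "non_english_included": which == 1,
            "n_included": n,
            "n_retrieved": None if p is None else max(n, int(round(n / p))),
            "n_nonenglish_langs": langs[i],
            "_ne_studies": ne_counts[i],
            **{name: fields[name][pos] for name in _CAT_COUNTS},
        })
    return rows


_FIXTURE_CACHE: list[dict] | None = None


def _fixture_rows() -> list[dict]:
    global _FIXTURE_CACHE
    if _FIXTURE_CACHE is None:
        rows = _build_group(0) + _build_group(1)
        order = np.random.default_rng(_stable_seed("order", 2)).permutation(len(rows))
        _FIXTURE_CACHE = [rows[i] for i in order]
    return _FIXTURE_CACHE


def cohort_fixture() -> list[SRRecord]:
    """Deterministic 174-review table reproducing the published margins."""
    records = []
    for i, row in enumerate(_fixture_rows()):
        records.append(SRRecord(
            sr_id=f"SR{i + 1:03d}",
            n_authors_band=row["n_authors_band"],
            continent=row["continent"],
            cochrane=row["cochrane"],
            year=row["year"],
            prospero=row["prospero"],
            n_included=row["n_included"],
            n_retrieved=row["n_retrieved"],
            non_english_included=row["non_english_included"],
            n_nonenglish_langs=row["n_nonenglish_langs"],
            language_restriction=row["language_restriction"],
            excluded_nonenglish=row["excluded_nonenglish"],
            librarian=row["librarian"],
            ma_performed=row["ma_performed"],
            sr_type=row["sr_type"],
            study_type=row["study_type"],
        ))
    return records


def cohort_nonenglish_study_counts() -> list[int]:
    """Per-review non-English study counts aligned with
    :func:`cohort_fixture` (zero for reviews without non-English studies;
    total 98)."""
    return [row["_ne_studies"] for row in _fixture_rows()]
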