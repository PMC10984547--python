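"""Two-stage estimation of the average language bias across meta-analyses.

Stage 1 runs, within each eligible meta-analysis, a random-effects
meta-regression of trial SMDs on a non-English indicator; the moderator
coefficient is that meta-analysis's ΔSMD (non-English minus English).
Stage 2 pools the ΔSMDs across meta-analyses by inverse-variance
meta-analysis — random-effects by default, with the between-meta-analysis
variance κ² of the ΔSMDs estimated by REML (or DerSimonian–Laird), and a
fixed-effect model as sensitivity analysis.

A negative pooled ΔSMD means non-English trials yield larger effects in
the direction reported by each source meta-analysis.  Outcome directions
are deliberately *not* harmonized across meta-analyses: each ΔSMD is taken
on the scale of its own forest plot.  Callers who wish to harmonize can
pre-flip trial effects per meta-analysis before entry.

Eligibility per review: the first primary-outcome meta-analysis with at
least three trials of which at least one is non-English; failing that, the
first such secondary-outcome meta-analysis; failing that, the review
contributes nothing.  One meta-analysis per review, so no two pooled ΔSMDs
share a review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .data_model_io import (BiasSummary, DeltaSMD, MetaAnalysisData,
                            ValidationError)
from .effect_sizes import to_effect
from .meta_engine import PooledEstimate, meta_regress, pool_fixed, pool_random

__all__ = [
    "select_meta_analysis",
    "select_per_sr",
    "stage1_delta",
    "stage2_pool",
    "language_subset_sensitivity",
    "SubsetSensitivity",
    "run_two_stage",
    "TwoStageResult",
    "replicate_two_stage",
]

MIN_TRIALS = 3
MIN_NONENGLISH = 1


def _unique_trials(ma: MetaAnalysisData) -> tuple[int, int]:
    """(total, non-English) trial counts; a trial contributing several rows
    counts once, and is non-English if any of its rows is flagged."""
    flags: dict[str, bool] = {}
    for t in ma.trials:
        flags[t.trial_id] = flags.get(t.trial_id, False) or t.non_english
    return len(flags), sum(flags.values())


def _eligible(ma: MetaAnalysisData) -> bool:
    total, ne = _unique_trials(ma)
    return total >= MIN_TRIALS and ne >= MIN_NONENGLISH


def select_meta_analysis(mas: Sequence[MetaAnalysisData]) -> MetaAnalysisData | None:
    """Pick one meta-analysis from a review's ordered list.

    First eligible primary-outcome meta-analysis; otherwise the first
    eligible secondary-outcome one; otherwise ``None``.
    """
    for role in ("primary", "secondary"):
        for ma in mas:
            if ma.outcome_role == role and _eligible(ma):
                return ma
    return None


def select_per_sr(mas: Sequence[MetaAnalysisData]) -> list[MetaAnalysisData]:
    """Apply the selection rule review-by-review (one meta-analysis per
    review), preserving review order of first appearance."""
    by_sr: dict[str, list[MetaAnalysisData]] = {}
    for ma in mas:
        by_sr.setdefault(ma.sr_id, []).append(ma)
    selected = []
    for sr_mas in by_sr.values():
        pick = select_meta_analysis(sr_mas)
        if pick is not None:
            selected.append(pick)
    return selected


def stage1_delta(ma: MetaAnalysisData, tau2_method: str = "reml",
                 hedges_correction: bool = True) -> DeltaSMD:
    """ΔSMD for one meta-analysis via binary-moderator meta-regression."""
    effects = [to_effect(t, correct=hedges_correction) for t in ma.trials]
    moderator = [1.0 if t.non_english else 0.0 for t in ma.trials]
    beta, cov, het = meta_regress(effects, moderator, tau2_method=tau2_method)
    total, ne = _unique_trials(ma)
    return DeltaSMD(ma_id=ma.ma_id, delta=float(beta[1]),
                    var_delta=float(cov[1, 1]), tau2=het.tau2,
                    k_total=total, k_nonenglish=ne)


def stage2_pool(deltas: Sequence[DeltaSMD], model: str = "random",
                tau2_method: str = "reml", level: float = 0.95) -> BiasSummary:
    """Pool per-meta-analysis ΔSMDs into an average language bias."""
    if len(deltas) < 2:
        raise ValidationError("stage2_pool: need at least 2 stage-1 estimates")
    from .data_model_io import EffectEstimate
    effects = [EffectEstimate(d.delta, d.var_delta) for d in deltas]
    if model == "random":
        pooled = pool_random(effects, tau2_method=tau2_method, level=level)
        kappa2 = pooled.het.tau2
    elif model == "fixed":
        pooled = pool_fixed(effects, level=level)
        kappa2 = 0.0
    else:
        raise ValidationError(f"stage2_pool: unknown model {model!r}")
    return BiasSummary(model=model, pooled_delta=pooled.mu,
                       ci_low=pooled.ci_low, ci_high=pooled.ci_high,
                       p_value=pooled.p_value, kappa2=kappa2,
                       n_ma=len(deltas))


@dataclass(frozen=True)
class SubsetSensitivity:
    """Pooled SMD of one meta-analysis with all trials vs English-only."""

    ma_id: str
    all_trials: PooledEstimate
    english_only: PooledEstimate | None

    @property
    def english_available(self) -> bool:
        return self.english_only is not None


def language_subset_sensitivity(ma: MetaAnalysisData, tau2_method: str = "reml",
                                hedges_correction: bool = True
                                ) -> SubsetSensitivity:
    """Summary SMD and heterogeneity with and without non-English trials.

    The English-only summary requires at least two English trials; otherwise
    it is flagged unavailable (``english_only is None``).
    """
    all_effects = [to_effect(t, correct=hedges_correction) for t in ma.trials]
    eng_effects = [to_effect(t, correct=hedges_correction)
                   for t in ma.trials if not t.non_english]
    pooled_all = pool_random(all_effects, tau2_method=tau2_method)
    pooled_eng = (pool_random(eng_effects, tau2_method=tau2_method)
                  if len(eng_effects) >= 2 else None)
    return SubsetSensitivity(ma_id=ma.ma_id, all_trials=pooled_all,
                             english_only=pooled_eng)


@dataclass(frozen=True)
class TwoStageResult:
    selected: list[MetaAnalysisData]
    deltas: list[DeltaSMD]
    random: BiasSummary
    fixed: BiasSummary
    subsets: list[SubsetSensitivity]


def run_two_stage(mas: Sequence[MetaAnalysisData], tau2_method: str = "reml",
                  hedges_correction: bool = True) -> TwoStageResult:
    """Selection, stage 1, stage 2 (both models) and subset sensitivity."""
    selected = select_per_sr(mas)
    if len(selected) < 2:
        raise ValidationError(
            f"run_two_stage: only {len(selected)} eligible meta-analyses; "
            "need at least 2")
    deltas = [stage1_delta(ma, tau2_method, hedges_correction) for ma in selected]
    subsets = [language_subset_sensitivity(ma, tau2_method, hedges_correction)
               for ma in selected]
    return TwoStageResult(
        selected=selected,
        deltas=deltas,
        random=stage2_pool(deltas, "random", tau2_method),
        fixed=stage2_pool(deltas, "fixed", tau2_method),
        subsets=subsets,
    )


def replicate_two_stage(config, n_reps: int, model: str = "random",
                        base_seed: int = 0, tau2_method: str = "reml"
                        ) -> list[BiasSummary]:
    """Monte-Carlo replication of the full two-stage pipeline.

    Generates ``n_reps`` independent trial tables from ``config`` (re-seeded
    per replicate) and runs selection, stage 1 and the requested stage-2
    model on each.  Used for parameter-recovery, coverage and size studies.
    """
    from dataclasses import replace

    from .synthetic_data import gen_metaepi

    out: list[BiasSummary] = []
    for r in range(n_reps):
        seed = (base_seed + 1_000_003 * r) % (2**31)
        mas = gen_metaepi(replace(config, seed=seed))
        deltas = [stage1_delta(ma, tau2_method) for ma in select_per_sr(mas)]
        out.append(stage2_pool(deltas, model, tau2_method))
    return out
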