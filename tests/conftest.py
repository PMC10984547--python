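import numpy as np
import pytest

from langbias import MetaAnalysisData, TrialRecord


def arm_trial(trial_id, ma_id, non_english, m1, s1, n1, m2, s2, n2):
    return TrialRecord(trial_id=trial_id, ma_id=ma_id, non_english=non_english,
                       data_level="arm", arm1_mean=m1, arm1_sd=s1, arm1_n=n1,
                       arm2_mean=m2, arm2_sd=s2, arm2_n=n2)


def contrast_trial(trial_id, ma_id, non_english, smd, se):
    return TrialRecord(trial_id=trial_id, ma_id=ma_id, non_english=non_english,
                       data_level="contrast", smd=smd, smd_se=se)


@pytest.fixture
def mixed_ma():
    """One meta-analysis mixing arm- and contrast-level trials."""
    ma_id = "MA1"
    return MetaAnalysisData(ma_id=ma_id, sr_id="SR1", outcome_role="primary",
                            trials=[
                                arm_trial("t1", ma_id, False, 10, 2, 20, 8, 2, 20),
                                arm_trial("t2", ma_id, False, 9.5, 2, 25, 9, 2, 25),
                                contrast_trial("t3", ma_id, True, 0.5, 0.2),
                            ])


@pytest.fixture
def saturated_ma():
    """Three contrast trials with equal SEs: two English at 0, one
    non-English at -0.4; the within-group means are exactly identifiable."""
    ma_id = "MA9"
    return MetaAnalysisData(ma_id=ma_id, sr_id="SR9", outcome_role="primary",
                            trials=[
                                contrast_trial("e1", ma_id, False, 0.0, 0.2),
                                contrast_trial("e2", ma_id, False, 0.0, 0.2),
                                contrast_trial("n1", ma_id, True, -0.4, 0.2),
                            ])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240401)
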