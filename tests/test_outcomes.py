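import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from convoscreen.outcomes import (
    PAPER_CUTOFFS,
    CutoffPolicy,
    DemographicsEncoder,
    dichotomize,
    recompute_cutoffs,
)
from convoscreen.synthetic_cohort import AssessmentScores, SensitiveAttributes


def _scores(**kw):
    base = dict(moca=25, cdr=0.0, lsns6=15, neuroticism=10,
                negative_affect=40.0, social_satisfaction=50.0,
                psych_wellbeing=55.0)
    base.update(kw)
    return AssessmentScores(**base)


class TestDichotomize:
    @pytest.mark.parametrize(
        "field,value,outcome,expected",
        [
            ("moca", 26, "MoCA", 1),    # above the cutoff of 24 -> high
            ("moca", 24, "MoCA", 0),    # boundary: <=24 -> low
            ("moca", 25, "MoCA", 1),
            ("lsns6", 12, "LSNS", 1),   # 12 or less -> socially isolated
            ("lsns6", 13, "LSNS", 0),
            ("cdr", 0.5, "CDR", 1),     # questionable dementia
            ("cdr", 0.0, "CDR", 0),
            ("neuroticism", 16, "Neuroticism", 0),  # median 16: <= -> low
            ("neuroticism", 17, "Neuroticism", 1),
            ("negative_affect", 44.2, "NegativeAffect", 1),  # median 44.10
            ("social_satisfaction", 48.66, "SocialSatisfaction", 0),  # 48.66
            ("psych_wellbeing", 53.8, "PsychWellbeing", 1),  # median 53.70
        ],
    )
    def test_cutoff_rules(self, field, value, outcome, expected):
        labels = dichotomize(_scores(**{field: value}))
        assert labels[outcome] == expected
        assert outcome in labels.cutoffs

    def test_diagnosis_encoding_normal_cognition_is_one(self):
        assert dichotomize(_scores(), diagnosis="NC")["DiagnosisMCI"] == 1
        assert dichotomize(_scores(), diagnosis="MCI")["DiagnosisMCI"] == 0

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(_scores(moca=31))
        with pytest.raises(ValueError):
            dichotomize(_scores(cdr=1.0))

    @given(st.integers(0, 29))
    def test_monotone_in_moca(self, moca):
        lo = dichotomize(_scores(moca=moca))["MoCA"]
        hi = dichotomize(_scores(moca=moca + 1))["MoCA"]
        assert hi >= lo  # raising a score never flips high -> low

    @given(st.floats(20.0, 80.0), st.floats(0.1, 10.0))
    def test_monotone_in_composites(self, value, delta):
        lo = dichotomize(_scores(negative_affect=value))["NegativeAffect"]
        hi = dichotomize(_scores(negative_affect=value + delta))["NegativeAffect"]
        assert hi >= lo


class TestRecomputeCutoffs:
    def test_median_split_near_parity(self, small_cohort):
        policy = recompute_cutoffs(small_cohort)
        labels = [
            dichotomize(r.scores, policy)["NegativeAffect"] for r in small_cohort
        ]
        n = len(labels)
        assert abs(sum(labels) - (n - sum(labels))) <= np.ceil(n / 2)

    def test_instrument_defined_cutoffs_untouched(self, small_cohort):
        policy = recompute_cutoffs(small_cohort)
        assert policy.cutoffs["LSNS"] == PAPER_CUTOFFS["LSNS"]
        assert policy.mode == "recompute"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            CutoffPolicy(mode="bogus")


class TestDemographicsEncoder:
    def _attrs(self, sex="F", age=80, yoe=16):
        return SensitiveAttributes(sex=sex, age_years=age, yoe=yoe,
                                   diagnosis="NC")

    def test_identical_attributes_identical_vectors(self):
        train = [self._attrs(), self._attrs("M", 82, 12), self._attrs("F", 79, 18)]
        enc = DemographicsEncoder().fit(train)
        a, b = enc.transform([self._attrs(), self._attrs()])
        assert np.array_equal(a, b)

    def test_zero_variance_column_encodes_constant_zero(self):
        train = [self._attrs("F", 80, 16), self._attrs("F", 81, 15)]
        enc = DemographicsEncoder().fit(train)
        X = enc.transform(train)
        # sex block has one level with no variance -> z-scored to 0
        assert np.allclose(X[:, : len(enc.sex_levels_)], 0.0)

    def test_age_block_width_counts_distinct_training_ages(self):
        train = [self._attrs(age=a) for a in (78, 80, 80, 83)]
        enc = DemographicsEncoder().fit(train)
        assert enc.age_block_width == 3

    def test_unseen_age_maps_to_zero_onehot_block(self):
        train = [self._attrs(age=a) for a in (78, 80, 83)]
        enc = DemographicsEncoder().fit(train)
        raw = enc._onehot(self._attrs(age=90))
        age_block = raw[-enc.age_block_width:]
        assert np.all(age_block == 0)

    def test_z_scoring_uses_training_statistics(self):
        train = [self._attrs("F", 80, 16), self._attrs("M", 82, 12),
                 self._attrs("F", 80, 16)]
        enc = DemographicsEncoder().fit(train)
        X = enc.transform(train)
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
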