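import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from edss_patterns.binarize import feature_columns
from edss_patterns.catalog import CANONICAL_FEATURES
from edss_patterns.patterns import (ClusterProfile, PatternRuleSet,
                                    assign_pattern, enumerate_rule_partition,
                                    pattern_distribution, profile_clusters)


def _profile(**percents):
    full = {f: 0.0 for f in CANONICAL_FEATURES}
    full.update(percents)
    return ClusterProfile(cluster_id=0, n_assessments=100, percent_high=full)


def _feature_frame(bit_rows, edss=6.0):
    data = {"patient_id": [f"P{i}" for i in range(len(bit_rows))],
            "visit_index": 0, "edss": edss}
    frame = pd.DataFrame(data)
    for j, f in enumerate(CANONICAL_FEATURES):
        frame[f"f_{f}"] = [row[j] for row in bit_rows]
    return frame


class TestProfiles:
    def test_percentage_arithmetic(self):
        rows = [[0] * 15 for _ in range(4)]
        for i in range(3):
            rows[i][CANONICAL_FEATURES.index("tandem_walking")] = 1
        profiles = profile_clusters(_feature_frame(rows), np.zeros(4, dtype=int))
        assert profiles[0].percent_high["tandem_walking"] == 75.0

    def test_all_zero_cluster_profiles_to_zero(self):
        profiles = profile_clusters(_feature_frame([[0] * 15] * 5),
                                    np.zeros(5, dtype=int))
        assert all(v == 0.0 for v in profiles[0].percent_high.values())

    def test_noise_rows_excluded(self):
        rows = [[1] * 15, [0] * 15, [0] * 15]
        labels = np.array([-1, 0, 0])
        profiles = profile_clusters(_feature_frame(rows), labels)
        assert profiles[0].n_assessments == 2
        assert all(v == 0.0 for v in profiles[0].percent_high.values())

    def test_all_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            profile_clusters(_feature_frame([[0] * 15] * 3), np.full(3, -1))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, (30, 15)).tolist()
        labels = rng.integers(0, 3, 30)
        a = profile_clusters(_feature_frame(rows), labels)
        perm = rng.permutation(30)
        b = profile_clusters(_feature_frame([rows[i] for i in perm]), labels[perm])
        assert a == b


class TestAssign:
    def test_printed_tandem_cluster_is_pattern_B(self):
        """A cluster with 98% high tandem walking and everything else ≤ 20%
        (the published EDSS-6.0 example) classifies as B."""
        profile = _profile(tandem_walking=98.0, bmrc_upper=1.0, bmrc_lower=0.0,
                           spasticity_upper=1.0, spasticity_lower=0.0,
                           truncal_ataxia=1.0, tremor_upper=2.0, tremor_lower=7.0,
                           gait_ataxia=0.0, romberg=9.0, superficial_upper=2.0,
                           superficial_lower=9.0, vibration_upper=6.0,
                           vibration_lower=20.0, position_lower=10.0)
        assert assign_pattern(profile) == "B"

    def test_printed_low_impairment_cluster_is_pattern_D(self):
        profile = _profile(bmrc_upper=9.0, bmrc_lower=33.0, spasticity_upper=1.0,
                           spasticity_lower=0.0, truncal_ataxia=0.0,
                           tremor_upper=0.0, tremor_lower=1.0,
                           tandem_walking=0.0, gait_ataxia=0.0, romberg=3.0,
                           superficial_upper=1.0, superficial_lower=8.0,
                           vibration_upper=1.0, vibration_lower=19.0,
                           position_lower=8.0)
        assert assign_pattern(profile) == "D"

    def test_everything_high_resolves_to_A_by_precedence(self):
        assert assign_pattern(_profile(**{f: 100.0 for f in CANONICAL_FEATURES})) == "A"

    def test_exactly_50_percent_is_not_high(self):
        assert assign_pattern(_profile(gait_ataxia=50.0)) == "D"
        assert assign_pattern(_profile(gait_ataxia=50.1)) == "A"

    @given(st.sets(st.sampled_from(CANONICAL_FEATURES)))
    @settings(deadline=None, max_examples=100)
    def test_total_and_monotone_in_group_A(self, high):
        rules = PatternRuleSet()
        label = assign_pattern(_profile(**{f: 100.0 for f in high}), rules)
        assert label in rules.labels
        bumped = assign_pattern(
            _profile(**{f: 100.0 for f in high | {"gait_ataxia"}}), rules)
        assert bumped == "A"

    def test_literal_single_sensory_reading(self):
        rules = PatternRuleSet(single_sensory_literal=True)
        one = _profile(romberg=80.0)
        two = _profile(romberg=80.0, vibration_lower=80.0)
        assert assign_pattern(one, rules) == "C"
        assert assign_pattern(two, rules) == "D"
        assert assign_pattern(two, PatternRuleSet()) == "C"


class TestEnumeration:
    def test_default_rules_reach_exactly_four_labels(self):
        assert enumerate_rule_partition() == {"A", "B", "C", "D"}

    def test_removing_group_C_leaves_three(self):
        rules = PatternRuleSet()
        rules.groups = {"A": rules.groups["A"], "B": rules.groups["B"], "C": ()}
        assert enumerate_rule_partition(rules) == {"A", "B", "D"}


class TestDistribution:
    def test_single_cluster_all_B(self):
        rows = [[0] * 15 for _ in range(6)]
        for row in rows:
            row[CANONICAL_FEATURES.index("tandem_walking")] = 1
        dist = pattern_distribution(_feature_frame(rows), np.zeros(6, dtype=int))
        assert dist.loc[6.0, "B"] == 100.0

    def test_two_equal_clusters_split_fifty_fifty(self):
        rows = [[1] * 15] * 5 + [[0] * 15] * 5
        labels = np.array([0] * 5 + [1] * 5)
        dist = pattern_distribution(_feature_frame(rows), labels)
        assert dist.loc[6.0, "A"] == 50.0 and dist.loc[6.0, "D"] == 50.0

    def test_percents_sum_to_100_noise_reported_separately(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 2, (40, 15)).tolist()
        labels = rng.integers(-1, 3, 40)
        dist = pattern_distribution(_feature_frame(rows), labels)
        assert abs(dist[["A", "B", "C", "D"]].sum(axis=1).iloc[0] - 100.0) < 0.1
        assert "pct_noise" in dist.columns

    def test_planted_shares_track_mixing_weights(self, planted, planted_model):
        table, features = planted
        dist = pattern_distribution(features, planted_model.labels,
                                    by_stratum=False)
        for label, weight in zip("ABCD", (30.0, 25.0, 25.0, 20.0)):
            assert abs(dist.loc["all", label] - weight) <= 5.0, label
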