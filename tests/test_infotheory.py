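import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmdtune import (
    Category,
    categorize_neurons,
    contribution_table,
    mi_from_counts,
    mi_profile,
    mi_threshold,
    spike_action_mi,
)
from pmdtune.infotheory import average_contributions
from pmdtune.preprocess import IndicatorSamples
from pmdtune.simulate import Task

H_QUARTER = 0.8112781244591328  # binary entropy of 1/4


def mi_oracle(spike_counts, sample_counts, p_y=None):
    """Independent brute-force plug-in MI over the 2x4 table (bits).

    Deliberately written as an explicit double loop over spk and y, with
    no shared code with the implementation under test.
    """
    p_y = p_y or [0.25] * 4
    mi = 0.0
    for a in range(4):
        for s in (0, 1):
            n, k = sample_counts[a], spike_counts[a]
            p_s_y = k / n if s == 1 else 1 - k / n
            if p_s_y == 0:
                continue
            p_s = sum(
                p_y[b]
                * (spike_counts[b] / sample_counts[b] if s == 1
                   else 1 - spike_counts[b] / sample_counts[b])
                for b in range(4)
            )
            mi += p_y[a] * p_s_y * math.log2(p_s_y / p_s)
    return mi


def samples_from_counts(spike_counts, sample_counts):
    """IndicatorSamples whose pooled (spk, y) set realizes given counts."""
    spk_rows = []
    labels = []
    for a, (k, n) in enumerate(zip(spike_counts, sample_counts), start=1):
        for i in range(n):
            spk_rows.append([1 if i < k else 0])
            labels.append(a)
    values = np.asarray(spk_rows, dtype=np.uint8)[:, None, :]  # (samples, 1 neuron, 1 step)
    return IndicatorSamples(
        task=Task.REACH,
        neuron_ids=["n0"],
        values=values,
        labels=np.asarray(labels),
        step_s=0.01,
        scope="full_window",
    )


class TestSpikeActionMI:
    def test_frozen_oracle_value(self):
        # value computed with mi_oracle ahead of the implementation
        assert mi_from_counts([30, 10, 10, 10], [100] * 4) == pytest.approx(
            0.037770884716766345, abs=1e-12
        )

    def test_independence_gives_zero(self):
        assert mi_from_counts([25, 25, 25, 25], [100] * 4) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_indicator_gives_binary_entropy(self):
        assert mi_from_counts([100, 0, 0, 0], [100] * 4) == pytest.approx(H_QUARTER, abs=1e-12)

    def test_matches_oracle_on_1000_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = [int(rng.integers(1, 200)) for _ in range(4)]
            k = [int(rng.integers(0, ni + 1)) for ni in n]
            p_y = [x / sum(n) for x in n]
            assert mi_from_counts(k, n, p_y=p_y) == pytest.approx(
                mi_oracle(k, n, p_y=p_y), abs=1e-12
            )

    def test_pooled_samples_path(self):
        samples = samples_from_counts([30, 10, 10, 10], [100] * 4)
        assert spike_action_mi(samples, "n0") == pytest.approx(
            mi_oracle([30, 10, 10, 10], [100] * 4), abs=1e-12
        )

    def test_unbalanced_needs_empirical_prior(self):
        samples = samples_from_counts([5, 5, 5, 5], [50, 50, 50, 60])
        with pytest.raises(ValueError, match="unbalanced"):
            spike_action_mi(samples, "n0")
        value = spike_action_mi(samples, "n0", p_y="empirical")
        assert value == pytest.approx(
            mi_oracle([5, 5, 5, 5], [50, 50, 50, 60],
                      p_y=[50 / 210, 50 / 210, 50 / 210, 60 / 210]),
            abs=1e-12,
        )

    def test_missing_label_errors(self):
        samples = samples_from_counts([5, 5, 5, 0], [50, 50, 50, 1])
        samples.labels[samples.labels == 4] = 3
        with pytest.raises(ValueError, match="missing"):
            spike_action_mi(samples, "n0", p_y="empirical")

    def test_estimator_consistency_bernoulli(self):
        # stationary Bernoulli indicators with known per-action rates:
        # plug-in estimate within 0.005 bits of the closed form at 1e5 samples
        rng = np.random.default_rng(7)
        probs = [0.4, 0.1, 0.1, 0.1]
        n_per = 25_000
        k = [int(rng.binomial(n_per, p)) for p in probs]
        est = mi_from_counts(k, [n_per] * 4)
        exact = mi_oracle([int(p * 1_000_000) for p in probs], [1_000_000] * 4)
        assert abs(est - exact) < 0.005

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4),
        st.data(),
    )
    def test_bounds_property(self, n, data):
        k = [data.draw(st.integers(min_value=0, max_value=ni)) for ni in n]
        p_y = [x / sum(n) for x in n]
        value = mi_from_counts(k, n, p_y=p_y)
        assert 0.0 <= value <= 1.0  # binary spk caps MI at 1 bit


class TestMIThreshold:
    def test_hand_computed_cases(self):
        assert mi_threshold([0.4, 0.3, 0.2, 0.1]) == pytest.approx(0.2)
        assert mi_threshold([0.7]) == pytest.approx(0.7)
        assert mi_threshold([0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.25)

    def test_all_zero_degenerate(self):
        assert mi_threshold([0.0, 0.0]) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mi_threshold([])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0),
            min_size=1, max_size=50, unique=True,
        )
    )
    def test_coverage_invariant(self, values):
        thr = mi_threshold(values, fraction=0.9)
        arr = np.asarray(values)
        total = arr.sum()
        covered = arr[arr >= thr].sum()
        assert covered >= 0.9 * total - 1e-9
        # dropping one copy of the threshold value breaks coverage
        assert covered - thr < 0.9 * total + 1e-9


class TestCategorize:
    def test_definitional_cases(self):
        cats = categorize_neurons([0.5, 0.5, 0.1, 0.0], [0.5, 0.1, 0.5, 0.0], 0.2, 0.2)
        assert cats == [Category.BOTH, Category.REACH_ONLY, Category.GRASP_ONLY,
                        Category.UNTUNED]

    def test_threshold_inclusive(self):
        assert categorize_neurons([0.2], [0.0], 0.2, 0.2) == [Category.REACH_ONLY]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            categorize_neurons([0.1], [0.1, 0.2], 0.1, 0.1)


class TestContributions:
    def _profile(self, mi_reach, mi_grasp, categories):
        import pandas as pd
        from pmdtune.infotheory import MIProfile

        table = pd.DataFrame(
            {"mi_reach": mi_reach, "mi_grasp": mi_grasp,
             "category": [c.value for c in categories]},
            index=pd.Index([f"n{i}" for i in range(len(mi_reach))], name="neuron_id"),
        )
        return MIProfile(table=table, thr_reach=0.0, thr_grasp=0.0)

    def test_single_both_neuron_100pct(self):
        profile = self._profile([0.4], [0.3], [Category.BOTH])
        table = contribution_table(profile)
        assert table.loc["reach", "share_BOTH"] == pytest.approx(100.0)
        assert table.loc["grasp", "share_BOTH"] == pytest.approx(100.0)

    def test_share_arithmetic(self):
        profile = self._profile(
            [0.3, 0.6], [0.0, 0.0], [Category.REACH_ONLY, Category.BOTH]
        )
        table = contribution_table(profile)
        assert table.loc["reach", "share_REACH_ONLY"] == pytest.approx(100 / 3)
        assert table.loc["reach", "share_BOTH"] == pytest.approx(200 / 3)
        assert np.isnan(table.loc["grasp", "share_BOTH"])  # zero total: undefined

    def test_shares_sum_to_100(self, session_pair_indicators):
        profile = mi_profile(*session_pair_indicators)
        table = contribution_table(profile)
        share_cols = [c for c in table.columns if c.startswith("share_")]
        assert table[share_cols].sum(axis=1).to_numpy() == pytest.approx([100.0, 100.0])

    def test_average(self):
        p1 = contribution_table(self._profile([0.4], [0.4], [Category.BOTH]))
        p2 = contribution_table(self._profile([0.2], [0.2], [Category.BOTH]))
        avg = average_contributions([p1, p2])
        assert avg.loc["reach", "total_mi_bits"] == pytest.approx(0.3)


class TestMIProfileEndToEnd:
    def test_untuned_mi_near_zero_large_sample(self):
        # plug-in bias for a 2x4 table is ~ 3 / (2 N ln 2); at 1e5+
        # samples an action-independent neuron's MI must be < 1e-3 bits
        rng = np.random.default_rng(11)
        n_per = 30_000
        k = [int(rng.binomial(n_per, 0.1)) for _ in range(4)]
        assert mi_from_counts(k, [n_per] * 4) < 1e-3

    def test_profile_categories_and_thresholds(self, session_pair_indicators):
        profile = mi_profile(*session_pair_indicators)
        assert set(profile.table.columns) == {"mi_reach", "mi_grasp", "category"}
        assert profile.thr_reach >= 0 and profile.thr_grasp >= 0
        tuned = profile.tuned_subset("reach")
        for nid in tuned:
            assert profile.table.loc[nid, "mi_reach"] >= profile.thr_reach

    def test_roster_mismatch(self, session_pair_indicators):
        reach, grasp = session_pair_indicators
        bad = IndicatorSamples(
            task=grasp.task,
            neuron_ids=grasp.neuron_ids[:-1],
            values=grasp.values[:, :-1, :],
            labels=grasp.labels,
            step_s=grasp.step_s,
            scope=grasp.scope,
        )
        with pytest.raises(ValueError, match="roster"):
            mi_profile(reach, bad)
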