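import math

import pytest

import adjforest as af
from adjforest.analysis import (
    count_conflicts, filter_by_probability, is_ancestral_candidate,
    sample_frequency_matrix, summarize,
)

from conftest import small_instances


class TestCandidates:
    def test_spec_spec_pair_is_candidate(self, fixture2):
        _, inst = fixture2
        assert is_ancestral_candidate(inst.g1.root, inst.g2.root)

    def test_duplication_pair_is_not(self, fixture3):
        _, inst = fixture3
        assert not is_ancestral_candidate(inst.g1.root, inst.g2.root)

    def test_extant_pair_is_not(self, fixture1):
        _, inst = fixture1
        assert not is_ancestral_candidate(inst.g1.root, inst.g2.root)


class TestFiltering:
    def test_threshold_zero_keeps_all_candidates(self, fixture2):
        _, inst = fixture2
        m = af.adjacency_probability_matrix(inst,
                                            params=af.EnsembleParams(kT=1.0))
        assert filter_by_probability(m, 0.0) == {("r1", "r2")}

    def test_threshold_half_keeps_root(self, fixture2):
        _, inst = fixture2
        m = af.adjacency_probability_matrix(inst,
                                            params=af.EnsembleParams(kT=1.0))
        assert filter_by_probability(m, 0.5) == {("r1", "r2")}

    def test_threshold_one_drops_uncertain_root(self, fixture2):
        _, inst = fixture2
        m = af.adjacency_probability_matrix(inst,
                                            params=af.EnsembleParams(kT=1.0))
        assert filter_by_probability(m, 1.0) == set()

    def test_threshold_out_of_range(self, fixture2):
        _, inst = fixture2
        m = af.adjacency_probability_matrix(inst)
        with pytest.raises(af.ModelError):
            filter_by_probability(m, 1.5)


class TestConflicts:
    def test_empty(self):
        assert count_conflicts(set()) == (0, 0)

    def test_star_of_three(self):
        star = {("c", "x"), ("c", "y"), ("c", "z")}
        assert count_conflicts(star) == (4, 1)

    def test_path_of_two(self):
        path = {("a", "b"), ("b", "c")}
        assert count_conflicts(path) == (3, 0)


class TestSummaries:
    def test_counts_monotone_in_threshold(self):
        data = small_instances(8)
        thresholds = [round(0.1 * k, 1) for k in range(1, 11)]
        matrices = {}
        for kT in (0.5, 0.1):
            matrices[kT] = [
                af.adjacency_probability_matrix(
                    inst, params=af.EnsembleParams(kT=kT))
                for _, inst, _ in data]
        table = summarize(matrices, thresholds)
        assert len(table) == 10
        for col in table.columns:
            values = table[col].to_numpy()
            assert all(values[i] >= values[i + 1]
                       for i in range(len(values) - 1))

    def test_empty_matrix_set_gives_zero_table(self):
        table = summarize({0.1: []}, [0.1, 0.5, 1.0])
        assert (table.to_numpy() == 0).all()

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(af.ModelError):
            summarize({0.1: []}, [0.5, 0.1])


class TestSampleFrequency:
    def test_unique_forest_gives_probability_one(self, fixture1):
        _, inst = fixture1
        samples = af.sample_forests(inst, n=20, seed=0)
        m = sample_frequency_matrix(samples)
        assert m.probability("a1", "a2") == 1.0

    def test_single_sample_gives_indicator(self, fixture2):
        _, inst = fixture2
        samples = af.sample_forests(inst, params=af.EnsembleParams(kT=1.0),
                                    n=1, seed=4)
        m = sample_frequency_matrix(samples)
        assert all(e["probability"] in (0.0, 1.0) for _, e in m.items())

    def test_estimator_converges(self, fixture2):
        _, inst = fixture2
        exact = 1 / (1 + math.exp(-2))
        errors = {}
        for n in (100, 10000):
            samples = af.sample_forests(
                inst, params=af.EnsembleParams(kT=1.0), n=n, seed=9)
            m = sample_frequency_matrix(samples)
            errors[n] = abs(m.probability("r1", "r2") - exact)
        assert errors[10000] <= 0.01
        # n^(-1/2) convergence: generous factor over the 10x rate gain
        assert errors[10000] <= max(errors[100], 0.002) * 4

    def test_requires_samples(self):
        with pytest.raises(af.ModelError):
            sample_frequency_matrix([])

    def test_rejects_mixed_instances(self, fixture2, fixture3):
        _, i2 = fixture2
        _, i3 = fixture3
        s2 = af.sample_forests(i2, n=3, seed=0)
        s3 = af.sample_forests(i3, n=3, seed=0)
        with pytest.raises(af.ModelError):
            sample_frequency_matrix(s2 + s3)
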