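import math
from collections import Counter

import numpy as np
import pytest

import adjforest as af
from adjforest.boltzmann import outside_tables, transition_probabilities

from conftest import small_instances


class TestPartitionFunction:
    def test_single_forest(self, fixture1):
        _, inst = fixture1
        for kT in (0.1, 1.0, 10.0):
            res = af.partition_function(inst,
                                        params=af.EnsembleParams(kT=kT))
            assert res.Z == pytest.approx(1.0, rel=1e-12)

    def test_two_forest_spectrum(self, fixture2):
        _, inst = fixture2
        res = af.partition_function(inst, params=af.EnsembleParams(kT=1.0))
        assert res.Z == pytest.approx(1 + math.exp(-2), rel=1e-12)

    def test_duplication_spectrum(self, fixture3):
        _, inst = fixture3
        res = af.partition_function(inst, params=af.EnsembleParams(kT=1.0))
        assert res.Z == pytest.approx(1 + math.exp(-1), rel=1e-12)

    def test_matches_oracle_across_temperatures(self):
        for _, inst, _ in small_instances(25):
            space = af.enumerate_forests(inst)
            for kT in (0.1, 0.5, 1.0, 10.0):
                z_oracle = sum(math.exp(-s / kT) for _, s in space)
                res = af.partition_function(inst,
                                            params=af.EnsembleParams(kT=kT))
                assert res.Z == pytest.approx(z_oracle, rel=1e-9)

    def test_counting_certifies_unambiguity(self):
        for _, inst, _ in small_instances(25):
            space = af.enumerate_forests(inst)
            count = sum(af.compute_tables(inst,
                                          algebra="counting").root_values())
            assert count == len(space)


class TestRescaling:
    def test_no_rescaling_needed_on_fixture(self, fixture2):
        _, inst = fixture2
        assert af.choose_rescaling(inst,
                                   params=af.EnsembleParams(kT=1.0)) == 1.0

    def test_forced_alpha_recovers_Z(self, fixture2, fixture3):
        for _, inst in (fixture2, fixture3):
            base = af.partition_function(inst,
                                         params=af.EnsembleParams(kT=1.0))
            for alpha in (0.5, 2.0, 10.0):
                res = af.partition_function(
                    inst, params=af.EnsembleParams(kT=1.0, alpha=alpha))
                assert res.Z == pytest.approx(base.Z, rel=1e-12)
                assert res.Z_alpha == pytest.approx(
                    base.Z * alpha ** res.kappa_root, rel=1e-12)

    def test_auto_alpha_fixes_underflowing_instance(self):
        params = af.SimulationParams(
            n_species=18, dup_prob=0.28, loss_prob=0.05,
            gain_rate=0.02, break_rate=0.02, seed=1, max_extant_leaves=70)
        _, inst, _ = af.simulate_instance(params)
        kT = 0.01
        with pytest.raises(af.RescalingNeeded):
            af.partition_function(inst, params=af.EnsembleParams(kT=kT))
        alpha = af.choose_rescaling(inst, params=af.EnsembleParams(kT=kT))
        assert alpha > 1.0
        res = af.partition_function(
            inst, params=af.EnsembleParams(kT=kT, alpha=alpha))
        assert np.isfinite(res.Z_alpha) and res.Z_alpha > 0


class TestSampling:
    def test_unique_forest_always_sampled(self, fixture1):
        _, inst = fixture1
        forests = af.sample_forests(inst, n=100, seed=5)
        assert len(forests) == 100
        assert {f.serialize() for f in forests} == {"a1|a2|Extant"}

    def test_boltzmann_frequency(self, fixture2):
        _, inst = fixture2
        forests = af.sample_forests(
            inst, params=af.EnsembleParams(kT=1.0), n=10000, seed=7)
        freq = sum(af.score_forest(f) == 0 for f in forests) / 10000
        assert freq == pytest.approx(1 / (1 + math.exp(-2)), abs=0.01)

    def test_seed_reproducibility(self, fixture3):
        _, inst = fixture3
        a = af.sample_forests(inst, n=50, seed=11)
        b = af.sample_forests(inst, n=50, seed=11)
        assert [f.serialize() for f in a] == [f.serialize() for f in b]

    def test_rescaling_does_not_bias_sampling(self, fixture2):
        _, inst = fixture2
        kT = 1.0
        n = 20000
        freqs = []
        for alpha in (1.0, 10.0):
            forests = af.sample_forests(
                inst, params=af.EnsembleParams(kT=kT, alpha=alpha),
                n=n, seed=3)
            freqs.append(sum(af.score_forest(f) == 0 for f in forests) / n)
        # same distribution within binomial sampling error (3 sigma)
        p = 1 / (1 + math.exp(-2))
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(freqs[0] - freqs[1]) < 6 * sigma

    def test_empty_request(self, fixture1):
        _, inst = fixture1
        assert af.sample_forests(inst, n=0, seed=0) == []

    def test_samples_validate(self):
        for _, inst, _ in small_instances(5):
            for f in af.sample_forests(inst, n=50, seed=2):
                assert af.validate_forest_against_instance(f, inst) == []


class TestInsideOutside:
    def test_root_context_is_unity(self, fixture2, fixture3):
        for _, inst in (fixture2, fixture3):
            res = af.partition_function(inst,
                                        params=af.EnsembleParams(kT=1.0))
            out = outside_tables(res.tables)
            rp = res.tables.scheme.root_pair
            assert out.d[0][rp] == 1.0 and out.d[1][rp] == 1.0

    def test_outside_value_of_extant_pair(self, fixture2):
        _, inst = fixture2
        res = af.partition_function(inst, params=af.EnsembleParams(kT=1.0))
        out = outside_tables(res.tables)
        scheme = res.tables.scheme
        pid = next(i for i, (g1, g2) in enumerate(scheme.pairs)
                   if g1.label == "a1" and g2.label == "a2")
        assert out.d[1][pid] == pytest.approx(1 + math.exp(-2), rel=1e-12)
        # observed extant adjacency: inside*outside/Z == 1
        p = res.tables.c[1][pid] * out.d[1][pid] / res.Z_alpha
        assert p == pytest.approx(1.0, rel=1e-12)

    def test_extant_adjacency_probability_one(self, fixture3):
        _, inst = fixture3
        m = af.adjacency_probability_matrix(inst,
                                            params=af.EnsembleParams(kT=1.0))
        assert m.probability("a1", "a2") == pytest.approx(1.0, abs=1e-12)

    def test_transition_probabilities_conserve_reach(self):
        for _, inst, _ in small_instances(10):
            res = af.partition_function(inst,
                                        params=af.EnsembleParams(kT=1.0))
            out = outside_tables(res.tables)
            probs = transition_probabilities(res.tables, out)
            scheme = res.tables.scheme
            for pid in range(len(scheme.pairs)):
                for state in (0, 1):
                    alts = scheme.transitions[state][pid]
                    if not alts:
                        continue
                    reach = (res.tables.c[state][pid] * out.d[state][pid]
                             / res.Z_alpha)
                    assert sum(probs[tr] for tr in alts) == pytest.approx(
                        reach, abs=1e-12)

    def test_root_branch_probabilities(self, fixture1, fixture2):
        _, inst1 = fixture1
        res = af.partition_function(inst1, params=af.EnsembleParams(kT=1.0))
        c1, c0 = res.tables.root_values()
        assert c1 / res.Z_alpha == pytest.approx(1.0)
        _, inst2 = fixture2
        res2 = af.partition_function(inst2, params=af.EnsembleParams(kT=1.0))
        c1, c0 = res2.tables.root_values()
        assert c1 / res2.Z_alpha == pytest.approx(1 / (1 + math.exp(-2)),
                                                  rel=1e-12)
        assert (c1 + c0) / res2.Z_alpha == pytest.approx(1.0)


class TestAdjacencyMatrix:
    def test_ancestral_probability(self, fixture2):
        _, inst = fixture2
        m = af.adjacency_probability_matrix(inst,
                                            params=af.EnsembleParams(kT=1.0))
        assert m.probability("r1", "r2") == pytest.approx(
            1 / (1 + math.exp(-2)), rel=1e-12)

    def test_high_temperature_limit(self, fixture2):
        _, inst = fixture2
        m = af.adjacency_probability_matrix(
            inst, params=af.EnsembleParams(kT=1e6))
        assert m.probability("r1", "r2") == pytest.approx(0.5, abs=1e-3)

    def test_matches_oracle(self):
        for _, inst, _ in small_instances(15):
            space = af.enumerate_forests(inst)
            _, oracle = af.oracle_probabilities(space, 0.5)
            m = af.adjacency_probability_matrix(
                inst, params=af.EnsembleParams(kT=0.5))
            for pair, entry in m.items():
                assert entry["probability"] == pytest.approx(
                    oracle.get(pair, 0.0), abs=1e-9)

    def test_probabilities_invariant_under_alpha(self):
        _, inst, _ = small_instances(1, start_seed=7)[0]
        base = af.adjacency_probability_matrix(
            inst, params=af.EnsembleParams(kT=0.5))
        for alpha in (0.1, 10.0):
            m = af.adjacency_probability_matrix(
                inst, params=af.EnsembleParams(kT=0.5, alpha=alpha))
            for pair, entry in base.items():
                assert m.probability(*pair) == pytest.approx(
                    entry["probability"], abs=1e-9)
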