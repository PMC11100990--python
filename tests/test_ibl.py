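"""Unit and property tests of the instance-based learning engine, checked
against an independent brute-force transcription of the activation,
retrieval-probability and blending equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ginger.ibl import (AgentParams, Instance, Memory, Option, SimilaritySpec,
                        activation, blended_value, choose, exact_match,
                        prepopulate, record_outcome, retrieval_probabilities)

SIMS = SimilaritySpec(default=exact_match)


# --------------------------------------------------------------------------
# independent brute-force oracle

def oracle_activation(occurrences, clock, d, mu, weighted_sims):
    """Plain transcription: ln(sum of lag^-d) + mu*sum(w*(S-1))."""
    base = math.log(sum((clock - t) ** (-d) for t in occurrences))
    return base + mu * sum(w * (s - 1.0) for w, s in weighted_sims)


def oracle_softmax(acts, tau):
    es = [math.exp(a / tau) for a in acts]
    return [e / sum(es) for e in es]


def oracle_blend(acts, utils, tau):
    p = oracle_softmax(acts, tau)
    return sum(pi * ui for pi, ui in zip(p, utils))


# --------------------------------------------------------------------------
# activation

class TestActivation:
    def test_single_occurrence_at_lag_one_is_zero(self, quiet_params):
        inst = Instance({"a": 1}, 1.0, [4])
        opt = Option({"a": 1})
        assert activation(inst, opt, quiet_params, 5, SIMS) == 0.0

    def test_two_occurrences_lags_one_and_four(self, quiet_params):
        inst = Instance({"a": 1}, 1.0, [1, 4])
        opt = Option({"a": 1})
        a = activation(inst, opt, quiet_params, 5, SIMS)
        assert a == pytest.approx(math.log(1 + 4 ** -0.5), abs=1e-12)
        assert a == pytest.approx(0.405465, abs=1e-6)

    def test_full_mismatch_on_one_attribute(self, quiet_params):
        inst = Instance({"a": 1, "b": 1}, 1.0, [4])
        opt = Option({"a": 1, "b": 2})  # S=0 on b, S=1 on a
        assert activation(inst, opt, quiet_params, 5, SIMS) == -1.0

    def test_empty_occurrences_error(self, quiet_params):
        inst = Instance({"a": 1}, 1.0, [])
        with pytest.raises(ValueError, match="no occurrences"):
            activation(inst, Option({"a": 1}), quiet_params, 5, SIMS)

    def test_future_occurrence_error(self, quiet_params):
        inst = Instance({"a": 1}, 1.0, [5])
        with pytest.raises(ValueError, match="future occurrence"):
            activation(inst, Option({"a": 1}), quiet_params, 5, SIMS)

    def test_missing_similarity_error(self, quiet_params):
        inst = Instance({"a": 1}, 1.0, [1])
        sims = SimilaritySpec(functions={"b": exact_match})  # no default
        with pytest.raises(KeyError, match="missing similarity"):
            activation(inst, Option({"a": 1}), quiet_params, 5, sims)

    @given(lag=st.integers(min_value=1, max_value=500))
    def test_monotone_decreasing_in_lag(self, lag):
        params = AgentParams(noise_on=False)
        inst_a = Instance({"a": 1}, 1.0, [1000 - lag])
        inst_b = Instance({"a": 1}, 1.0, [1000 - lag - 1])
        opt = Option({"a": 1})
        assert (activation(inst_a, opt, params, 1000, SIMS)
                > activation(inst_b, opt, params, 1000, SIMS))

    @given(m=st.integers(min_value=1, max_value=50))
    def test_m_simultaneous_lag_one_occurrences_give_ln_m(self, m):
        # the frequency term: m occurrences all at lag 1 -> ln(m)
        params = AgentParams(noise_on=False)
        inst = Instance({"a": 1}, 1.0, [9] * m)
        a = activation(inst, Option({"a": 1}), params, 10, SIMS)
        assert a == pytest.approx(math.log(m), abs=1e-12)

    def test_noise_changes_value_and_is_seeded(self):
        params = AgentParams(noise_on=True, rng_seed=1)
        inst = Instance({"a": 1}, 1.0, [4])
        opt = Option({"a": 1})
        a1 = activation(inst, opt, params, 5, SIMS, np.random.default_rng(7))
        a2 = activation(inst, opt, params, 5, SIMS, np.random.default_rng(7))
        a3 = activation(inst, opt, params, 5, SIMS, np.random.default_rng(8))
        assert a1 == a2 != a3

    @pytest.mark.parametrize("dist", ["logistic", "normal"])
    def test_noise_distributions_have_zero_median(self, dist):
        params = AgentParams(noise_on=True, noise_dist=dist)
        inst = Instance({"a": 1}, 1.0, [4])
        opt = Option({"a": 1})
        rng = np.random.default_rng(0)
        draws = [activation(inst, opt, params, 5, SIMS, rng) for _ in range(2000)]
        assert abs(np.median(draws)) < 0.05


# --------------------------------------------------------------------------
# retrieval probabilities

class TestRetrieval:
    def test_equal_activations_uniform(self):
        p = retrieval_probabilities([2.5, 2.5, 2.5], tau=0.7)
        assert np.allclose(p, 1 / 3)

    def test_singleton(self):
        assert retrieval_probabilities([3.0], tau=1.0) == pytest.approx([1.0])

    def test_worked_example_zero_ln2(self):
        p = retrieval_probabilities([0.0, math.log(2)], tau=1.0)
        assert np.allclose(p, [1 / 3, 2 / 3], atol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            retrieval_probabilities([], tau=1.0)
        with pytest.raises(ValueError):
            retrieval_probabilities([1.0, math.inf], tau=1.0)
        with pytest.raises(ValueError):
            retrieval_probabilities([1.0], tau=0.0)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(0.05, 5.0), st.floats(-20, 20))
    @settings(max_examples=200)
    def test_sums_to_one_and_shift_invariant(self, acts, tau, shift):
        p = retrieval_probabilities(acts, tau)
        assert abs(p.sum() - 1.0) < 1e-12
        q = retrieval_probabilities([a + shift for a in acts], tau)
        assert np.allclose(p, q, atol=1e-9)

    def test_order_preserving(self):
        p = retrieval_probabilities([1.0, 3.0, 2.0], tau=0.5)
        assert p[1] > p[2] > p[0]

    def test_low_temperature_concentrates_on_max(self):
        p = retrieval_probabilities([0.0, 0.1], tau=1e-6)
        assert p[1] > 1 - 1e-6

    def test_large_activations_numerically_stable(self):
        p = retrieval_probabilities([1000.0, 1001.0], tau=1.0)
        assert np.all(np.isfinite(p)) and abs(p.sum() - 1) < 1e-12


# --------------------------------------------------------------------------
# blending and memory

def _memory_with(instances):
    m = Memory()
    for attrs, u, occs in instances:
        for t in occs:
            m._insert("k", attrs, u, t)
    m.clock = max(t for _, _, occs in instances for t in occs)
    return m


class TestBlending:
    def test_constant_utility(self, quiet_params):
        m = _memory_with([({"a": 1}, 0.7, [1]), ({"a": 2}, 0.7, [2])])
        v = blended_value("k", m, Option({"a": 1}), quiet_params, SIMS)
        assert v == pytest.approx(0.7)

    def test_equal_activation_midpoint(self, quiet_params):
        m = _memory_with([({"a": 1}, 0.0, [2]), ({"a": 1}, 1.0, [2])])
        v = blended_value("k", m, Option({"a": 1}), quiet_params, SIMS)
        assert v == pytest.approx(0.5)

    def test_worked_example_third_twothirds(self):
        # activations 0 and ln2 at tau=1 give weights 1/3, 2/3 on u=0,1
        p = retrieval_probabilities([0.0, math.log(2)], tau=1.0)
        assert float(p @ np.array([0.0, 1.0])) == pytest.approx(2 / 3)

    def test_cold_option_error(self, quiet_params):
        m = Memory()
        with pytest.raises(ValueError, match="cold option"):
            blended_value("k", m, Option({"a": 1}), quiet_params, SIMS)

    def test_bounded_by_stored_utilities(self, quiet_params, rng):
        for _ in range(25):
            n = int(rng.integers(1, 6))
            instances = [({"a": int(rng.integers(3))}, float(rng.normal()),
                          sorted(set(rng.integers(1, 20, size=rng.integers(1, 4)).tolist())))
                         for _ in range(n)]
            m = _memory_with(instances)
            v = blended_value("k", m, Option({"a": 1}), quiet_params, SIMS)
            utils = [u for _, u, _ in instances]
            assert min(utils) - 1e-12 <= v <= max(utils) + 1e-12

    def test_matches_bruteforce_oracle(self, quiet_params, rng):
        """Full pipeline vs independent transcription on <=5-instance memories."""
        for trial in range(50):
            n = int(rng.integers(1, 6))
            clock = 30
            instances = []
            for _ in range(n):
                attrs = {"x": int(rng.integers(3)), "y": int(rng.integers(3))}
                occs = sorted(set(rng.integers(1, clock, size=int(rng.integers(1, 4))).tolist()))
                instances.append((attrs, float(rng.normal()), occs))
            m = _memory_with(instances)
            m.clock = clock - 1
            query = Option({"x": int(rng.integers(3)), "y": int(rng.integers(3))})

            acts = []
            for attrs, u, occs in instances:
                ws = [(1.0, 1.0 if attrs[k] == query.attributes[k] else 0.0)
                      for k in ("x", "y")]
                acts.append(oracle_activation(occs, clock, 0.5, 1.0, ws))
            expected = oracle_blend(acts, [u for _, u, _ in instances],
                                    quiet_params.tau)
            got = blended_value("k", m, query, quiet_params, SIMS)
            assert got == pytest.approx(expected, abs=1e-10)


class TestChoose:
    def test_unique_argmax(self, rng):
        assert choose({"A": 0.2, "B": 0.9, "C": 0.1}, rng) == "B"

    def test_singleton(self, rng):
        assert choose({"A": 1.0}, rng) == "A"

    def test_empty_error(self, rng):
        with pytest.raises(ValueError):
            choose({}, rng)

    def test_tie_break_uniform(self, rng):
        counts = {"A": 0, "B": 0}
        n = 10_000
        for _ in range(n):
            counts[choose({"A": 0.5, "B": 0.5}, rng)] += 1
        assert abs(counts["A"] / n - 0.5) < 0.02  # 3-sigma binomial bound


class TestMemory:
    def test_repeat_observation_deduplicates(self):
        m = Memory()
        opt = Option({"a": 1}, id="A")
        record_outcome(m, opt, 1.0, option_key="k")
        record_outcome(m, opt, 1.0, option_key="k")
        insts = m.instances("k")
        assert len(insts) == 1 and insts[0].occurrences == [1, 2]
        assert m.clock == 2

    def test_distinct_utility_distinct_instance(self):
        m = Memory()
        opt = Option({"a": 1}, id="A")
        record_outcome(m, opt, 1.0, option_key="k")
        record_outcome(m, opt, 0.0, option_key="k")
        assert len(m.instances("k")) == 2

    def test_clock_advances_from_empty(self):
        m = Memory()
        record_outcome(m, Option({"a": 1}, id="A"), 0.5, option_key="k")
        assert m.clock == 1 and len(m.all_instances()) == 1

    def test_nonfinite_utility_rejected(self):
        m = Memory()
        with pytest.raises(ValueError):
            record_outcome(m, Option({"a": 1}, id="A"), math.nan, option_key="k")

    def test_prepopulation_defines_cold_value(self, quiet_params):
        m = Memory()
        prepopulate(m, Option({}, id="p"), 1.0, option_key="k")
        v = blended_value("k", m, Option({"a": 1}), quiet_params, SIMS)
        assert v == pytest.approx(1.0)

    def test_prepopulate_then_observation_is_strictly_between(self, quiet_params):
        m = Memory()
        prepopulate(m, Option({"a": 1}, id="p"), 1.0, option_key="k")
        record_outcome(m, Option({"a": 1}, id="A"), 0.0, option_key="k")
        # convexity: value lies strictly between the two stored utilities,
        # closer to the more recent observation (u=0 at lag 1 vs u=1 at lag 2)
        v = blended_value("k", m, Option({"a": 1}), quiet_params, SIMS)
        assert 0.0 < v < 0.5

    def test_memory_dump_roundtrippable_json(self):
        import json

        m = Memory()
        record_outcome(m, Option({"a": 1, "v": np.array([1.0, 2.0])}, id="A"),
                       1.0, option_key="k")
        dump = json.loads(json.dumps(m.to_dict()))
        assert dump["clock"] == 1
        assert dump["options"]["k"][0]["attributes"]["v"] == [1.0, 2.0]


class TestParams:
    def test_defaults(self):
        p = AgentParams()
        assert (p.d, p.mu, p.sigma) == (0.5, 1.0, 0.25)
        assert p.omega == 1.0
        assert p.tau == pytest.approx(0.25 * math.sqrt(2))

    @pytest.mark.parametrize("bad", [
        {"d": -0.1}, {"sigma": -1}, {"tau": 0.0}, {"tau": -1},
        {"omega": {"a": -1.0}}, {"noise_dist": "cauchy"},
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            AgentParams(**bad)
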