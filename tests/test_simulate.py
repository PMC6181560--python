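"""Ground-truth fidelity of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from selfstim import (
    AgentSpec,
    InputError,
    StimulusProtocol,
    simulate_extinction_session,
    simulate_operant_session,
    simulate_population,
    simulate_unit,
)
from selfstim.simulate import UnitSpec


class TestSimulateUnit:
    def test_seed_determinism(self, protocol20):
        spec = UnitSpec("u", 20.0, "excited", 60.0)
        a = simulate_unit(spec, protocol20, seed=5)
        b = simulate_unit(spec, protocol20, seed=5)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
        c = simulate_unit(spec, protocol20, seed=6)
        assert a.n_spikes != c.n_spikes or not np.array_equal(
            a.spike_times, c.spike_times
        )

    def test_zero_baseline_all_spikes_in_effect_windows(self, protocol20):
        spec = UnitSpec("u", 0.0, "excited", 50.0)
        train = simulate_unit(spec, protocol20, seed=1)
        assert train.n_spikes > 0
        for t in train.spike_times:
            rel = t - protocol20.onset_times
            assert np.any((rel >= 0) & (rel < 1.0))

    def test_effect_rate_within_3_se(self, protocol100):
        spec = UnitSpec("u", 10.0, "excited", 40.0)
        train = simulate_unit(spec, protocol100, seed=2)
        n = sum(
            np.sum((train.spike_times >= o) & (train.spike_times < o + 1.0))
            for o in protocol100.onset_times
        )
        expected = 40.0 * 100
        assert abs(n - expected) <= 3 * np.sqrt(expected)

    def test_inhibited_spec_validation(self):
        with pytest.raises(InputError):
            UnitSpec("u", 10.0, "inhibited", 20.0)
        with pytest.raises(InputError):
            UnitSpec("u", 10.0, "excited", 5.0)

    def test_piecewise_poisson_goodness_of_fit(self):
        """Chi-square GOF of per-trial effect-window counts against the
        specified Poisson law over many trials."""
        protocol = StimulusProtocol.regular(n_trials=1000, inter_trial_interval=3.0)
        spec = UnitSpec("u", 5.0, "excited", 30.0)
        train = simulate_unit(spec, protocol, seed=4)
        counts = [
            np.sum((train.spike_times >= o) & (train.spike_times < o + 1.0))
            for o in protocol.onset_times
        ]
        kmax = int(np.max(counts))
        observed = np.bincount(counts, minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax + 1), 30.0)
        # pool sparse tails so expected counts stay above ~5
        keep = probs * 1000 >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(probs[keep], probs[~keep].sum()) * 1000
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.001


class TestSimulatePopulation:
    def test_all_excited_truth_table(self, protocol20):
        trains, truth = simulate_population(5, (1.0, 0.0, 0.0), protocol20, seed=0)
        assert len(trains) == 5
        assert (truth["response_kind"] == "excited").all()
        assert (truth["response_rate"] > truth["base_rate"]).all()

    def test_seed_determinism(self, protocol20):
        t1, g1 = simulate_population(6, (0.5, 0.3, 0.2), protocol20, seed=9)
        t2, g2 = simulate_population(6, (0.5, 0.3, 0.2), protocol20, seed=9)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.spike_times, b.spike_times)
        assert g1.equals(g2)

    def test_fractions_must_sum_to_one(self, protocol20):
        with pytest.raises(InputError):
            simulate_population(5, (0.5, 0.3, 0.3), protocol20, seed=0)

    def test_class_counts_deterministic(self, protocol20):
        _, truth = simulate_population(10, (0.6, 0.2, 0.2), protocol20, seed=3)
        vc = truth["response_kind"].value_counts()
        assert vc["excited"] == 6 and vc["inhibited"] == 2 and vc["null"] == 2


class TestSimulateOperant:
    def test_zero_rates_empty_log(self):
        spec = AgentSpec(base_poke_rate=0.0, reinforced=False)
        log, truth = simulate_operant_session(spec, seed=1)
        assert log.n_events == 0
        assert truth["n_active"] == 0

    def test_seed_determinism(self):
        a, _ = simulate_operant_session(AgentSpec(), seed=4)
        b, _ = simulate_operant_session(AgentSpec(), seed=4)
        assert a.events == b.events

    def test_log_satisfies_invariants_by_construction(self):
        # EventLog validates on construction; many seeds, no violations
        for seed in range(20):
            log, _ = simulate_operant_session(AgentSpec(), seed=seed)
            times = np.array([t for t, _ in log.events])
            assert times.size == 0 or times[-1] < log.session_duration

    def test_reinforced_agent_prefers_active_and_ramps(self):
        rng = np.random.default_rng(0)
        wins, rises = 0, 0
        n_rep = 50
        for _ in range(n_rep):
            log, truth = simulate_operant_session(AgentSpec(), seed=rng)
            wins += truth["n_active"] > truth["n_inactive"]
            t = np.array([x for x, s in log.events if s == "active"])
            thirds = np.histogram(t, bins=[0, 600, 1200, 1800])[0]
            rises += thirds[2] > thirds[0]
        assert wins >= 0.95 * n_rep
        assert rises >= 0.9 * n_rep

    def test_unreinforced_agent_unbiased(self):
        rng = np.random.default_rng(1)
        diff, total = 0, 0
        for _ in range(100):
            _, truth = simulate_operant_session(
                AgentSpec(base_poke_rate=0.7, reinforced=False), seed=rng
            )
            diff += truth["n_active"] - truth["n_inactive"]
            total += truth["n_active"] + truth["n_inactive"]
        # paired difference within binomial noise (3.3 sigma)
        assert abs(diff) <= 3.3 * np.sqrt(total)

    def test_extinction_prefers_previously_active(self):
        rng = np.random.default_rng(2)
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            log, truth = simulate_operant_session(AgentSpec(), seed=rng)
            ext = simulate_extinction_session(
                AgentSpec(),
                (truth["final_active_rate"], truth["final_inactive_rate"]),
                seed=rng,
            )
            n_prev = sum(1 for _, s in ext.events if s == "active")
            wins += n_prev > len(ext.events) - n_prev
        assert wins >= 0.95 * n_rep
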