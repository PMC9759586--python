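"""Experiment pipelines: closed forms, basin diagnostics, retrieval,
sequences and the transition baseline."""

import numpy as np
import pandas as pd
import pytest

from skam.experiments import (
    ConfigError,
    ExperimentConfig,
    SnrTheoryParams,
    TransitionModelParams,
    estimate_f,
    estimate_mmin,
    lc_from_mmin,
    lc_small_cue,
    m0_small_cue,
    m0_theory,
    overlap_distribution,
    run_retrieval_experiment,
    run_sequence_experiment,
    run_transition_baseline,
    snr_outside_basin,
    snr_theory,
)


class TestClosedForms:
    def test_m0_exact_points(self):
        assert m0_theory(1, 2) == pytest.approx(0.5, abs=1e-12)
        assert m0_theory(1, 4) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert m0_theory(5, 5) == 1.0

    def test_m0_validation(self):
        with pytest.raises(ValueError):
            m0_theory(0, 5)
        with pytest.raises(ValueError):
            m0_theory(6, 5)

    def test_m0_small_cue_limit(self):
        for L in (100, 400):
            for L0 in (1, 2, 4):
                if L0 / L <= 0.1:
                    assert m0_small_cue(L0, L) == pytest.approx(m0_theory(L0, L), rel=0.05)

    def test_lc_inverts_m0_relation(self):
        """A cue of fraction l_c has mean overlap exactly m_min."""
        for m in (0.1, 0.2, 0.5, 0.7):
            lc = lc_from_mmin(m)
            assert 2.0 / np.pi * np.arcsin(np.sqrt(lc)) == pytest.approx(m, abs=1e-12)
        assert lc_from_mmin(0.0) == 0.0

    def test_lc_small_expansion(self):
        # quadratic Taylor error is (pi m / 2)^2 / 3 relative, ~3% at m = 0.2
        for m in (0.05, 0.1, 0.2):
            assert lc_small_cue(m) == pytest.approx(lc_from_mmin(m), rel=0.05)
        assert lc_small_cue(0.3) == pytest.approx(lc_from_mmin(0.3), rel=0.10)

    def test_snr_composition_identity(self):
        """The outside-basin law equals SNR(m) composed with m* = f m0 and
        the small-cue m0, over a parameter grid."""
        for n in (1000, 4000):
            for L, L0 in [(50, 2), (100, 3), (200, 5)]:
                for f in (1.0, 2.2):
                    m = f * m0_small_cue(L0, L)
                    lhs = snr_theory(m, n, L, c=0.65)
                    rhs = snr_outside_basin(n, L, L0, f_alpha=f, c=0.65)
                    assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_snr_linear_in_n(self):
        assert snr_theory(0.3, 2000, 50) == pytest.approx(2 * snr_theory(0.3, 1000, 50))
        assert snr_outside_basin(2000, 50, 2, 2.0) == pytest.approx(
            2 * snr_outside_basin(1000, 50, 2, 2.0)
        )

    def test_theory_params_validation(self):
        with pytest.raises(ValueError):
            SnrTheoryParams(c=0.0)


class TestOverlapDistribution:
    def test_all_exact(self):
        stats = overlap_distribution(np.ones(100), 500)
        assert stats.p1 == 1.0 and np.isnan(stats.m_star)

    def test_bimodal_split(self):
        m = np.concatenate([np.ones(40), np.full(60, 0.3)])
        stats = overlap_distribution(m, 1000)
        assert stats.p1 == pytest.approx(0.4)
        assert stats.m_star == pytest.approx(0.3)
        assert stats.sigma_m == pytest.approx(0.0, abs=1e-12)

    def test_one_flip_tolerance(self):
        # one flipped bit out of N still counts as exact retrieval
        stats = overlap_distribution([1.0 - 2.0 / 1000], 1000)
        assert stats.p1 == 1.0


class TestConfig:
    def test_derives_pattern_count(self):
        cfg = ExperimentConfig(n_units=500, n_pairs=10, cue_size=5, alpha=0.1)
        assert cfg.n_patterns == 50
        assert cfg.dict_size == 5000

    def test_collects_violations(self):
        with pytest.raises(ConfigError) as exc:
            ExperimentConfig(n_units=500, n_pairs=10, cue_size=11, alpha=None, rule="magic")
        msg = str(exc.value)
        assert "cue_size" in msg and "rule" in msg and "alpha or n_patterns" in msg

    def test_pseudoinverse_load_guard(self):
        with pytest.raises(ConfigError, match="P < N"):
            ExperimentConfig(n_units=100, n_pairs=5, cue_size=2, n_patterns=100)


class TestRetrievalExperiment:
    def _cfg(self, **kw):
        base = dict(
            n_units=400, n_pairs=8, cue_size=4, alpha=0.1, dict_size=400,
            n_trials=1, seed=5, distractor_sample=100,
        )
        base.update(kw)
        return ExperimentConfig(**base)

    def test_deterministic_given_seed(self):
        r1 = run_retrieval_experiment(self._cfg())
        r2 = run_retrieval_experiment(self._cfg())
        pd.testing.assert_frame_equal(r1.records, r2.records)
        assert r1.snr == r2.snr

    def test_full_cue_reproduces_baseline(self):
        """With the full structure as cue the network is initialized at a
        stored fixed point, so post-retrieval decoding equals pre-storage
        decoding exactly."""
        res = run_retrieval_experiment(self._cfg(cue_size=8))
        assert res.stats.p1 == 1.0
        assert res.p_error == res.baseline_p_error
        np.testing.assert_allclose(
            res.records.overlap_correct, res.records.baseline_overlap_correct
        )

    def test_in_basin_cue_matches_baseline_error(self):
        """A half-structure cue at alpha = 0.1 lies inside the basin: the
        retrieval is exact and decoding matches the fresh-structure error."""
        res = run_retrieval_experiment(
            self._cfg(n_units=1000, n_pairs=10, cue_size=5, dict_size=2000, seed=2)
        )
        assert res.stats.p1 == 1.0
        assert res.p_error <= res.baseline_p_error + 0.05

    def test_short_cue_beats_chance(self):
        """L0 = 2 of L = 30 at alpha = 0.1 is far outside the basin, yet
        decoding is far better than the 1 - 1/D chance level."""
        cfg = self._cfg(
            n_units=1000, n_pairs=30, cue_size=2, dict_size=2000, seed=3,
            distractor_sample=200,
        )
        res = run_retrieval_experiment(cfg)
        assert res.stats.p1 < 0.5  # cues genuinely outside the basin
        chance = 1.0 - 1.0 / cfg.dict_size
        assert res.p_error > res.baseline_p_error
        # at this desk scale the error is large but far from the ~0.9995
        # chance level; the gap widens with N
        assert res.p_error < chance - 0.2

    def test_attribute_reuse_does_not_break_decoding(self):
        """Sharing one attribute set across all structures leaves the
        decode error within twice the distinct-attribute error."""
        shared = run_retrieval_experiment(
            self._cfg(n_units=1000, n_pairs=10, cue_size=5, dict_size=2000, seed=7)
        )
        distinct = run_retrieval_experiment(
            self._cfg(
                n_units=1000, n_pairs=10, cue_size=5, dict_size=2000, seed=7,
                attribute_sharing=False,
            )
        )
        assert shared.p_error <= 2.0 * distinct.p_error + 0.02

    def test_random_cue_positions(self):
        res = run_retrieval_experiment(self._cfg(cue_random=True))
        assert len(res.records) == 40

    def test_snr_only_mode_skips_error(self):
        res = run_retrieval_experiment(self._cfg(cleanup_mode="snr_only"))
        assert res.p_error is None
        assert res.snr > 0

    def test_serial_update_mode_runs(self):
        res = run_retrieval_experiment(self._cfg(n_units=200, alpha=0.05, update_mode="serial"))
        assert res.stats.n_samples == 10


class TestBasinDiagnostics:
    def test_mmin_is_ordered_in_alpha(self):
        """Basins shrink (m_min grows) as the load increases."""
        grid = np.arange(0.05, 0.61, 0.05)
        low = estimate_mmin(0.05, 500, m0_grid=grid, n_trials=40, seed=1)
        high = estimate_mmin(0.3, 500, m0_grid=grid, n_trials=40, seed=1)
        assert 0.0 < low.m_min < high.m_min < 0.7

    def test_mmin_requires_bracketing_grid(self):
        with pytest.raises(ValueError, match="cross"):
            estimate_mmin(0.1, 400, m0_grid=[0.8, 0.9], n_trials=20, seed=0)

    def test_f_amplifies_at_moderate_load(self):
        """Out-of-basin fixed points overlap more than the cue: f > 1."""
        fest = estimate_f(0.2, 800, m0_grid=[0.2, 0.3], n_trials=100, n_networks=2, seed=3)
        assert fest.f_alpha >= 1.0
        assert np.all(fest.m_star > np.array([0.2, 0.3]))

    def test_f_rejects_in_basin_grid(self):
        with pytest.raises(ValueError, match="inside the basin"):
            estimate_f(0.1, 600, m0_grid=[0.9], n_trials=40, n_networks=1, seed=0)


class TestSequences:
    def test_single_sequence_fully_decoded(self):
        """One stored sequence cued by its first relation is retrieved and
        unrolled without error at high SNR."""
        res = run_sequence_experiment(
            n_units=512, seq_len=5, n_sequences=1, dict_size=400, n_trials=4, seed=0
        )
        assert np.all(res.retrieval_overlap == 1.0)
        assert np.all(res.accuracy_by_position == 1.0)

    def test_accuracy_non_increasing_with_position(self):
        """Sequential clean-up accumulates errors along the sequence."""
        res = run_sequence_experiment(
            n_units=400, seq_len=12, n_sequences=16, dict_size=600, n_trials=3, seed=1
        )
        acc = res.accuracy_by_position
        # smooth comparison: early half at least as accurate as late half
        assert acc[1:6].mean() >= acc[6:].mean() - 0.02

    def test_chain_construction_shares_block(self):
        res = run_sequence_experiment(
            n_units=256, seq_len=4, n_sequences=2, shared_items=1, dict_size=200,
            n_trials=1, seed=2,
        )
        assert set(res.records.seq) == {0, 1}

    def test_validation(self):
        with pytest.raises(ValueError):
            run_sequence_experiment(n_units=64, seq_len=1)
        with pytest.raises(ValueError):
            run_sequence_experiment(n_units=64, seq_len=4, shared_items=4)


class TestTransitionBaseline:
    def test_no_transitions_without_asymmetry(self):
        res = run_transition_baseline(
            [[0, 1, 2]], n_units=300, params=TransitionModelParams(tau=8, lam=1e-9),
            T=40, n_trials=3, seed=0, init_overlap=1.0,
        )
        # the network sits in the first attractor forever
        assert np.all(res.mean_overlaps[:, 0] > 0.99)

    def test_single_sequence_sweeps_in_order(self):
        """lam = 2.5, tau = 8: the state visits the stored patterns in
        sequence order, each peaking near 1."""
        L = 5
        res = run_transition_baseline(
            [list(range(L))], n_units=1000, T=60, n_trials=5, seed=1, init_overlap=0.95
        )
        # judge each trial separately: every pattern is visited (peak
        # overlap near 1) in sequence order
        for trial in res.overlaps:
            peaks = trial.max(axis=0)
            times = trial.argmax(axis=0)
            assert np.all(peaks > 0.8)
            assert np.all(np.diff(times) > 0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            TransitionModelParams(tau=0)
        with pytest.raises(ValueError):
            TransitionModelParams(lam=-1)
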