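"""Composite cyclin signal, reference period, progress alignment, and the
division-probability estimator."""

import numpy as np
import pytest

from lineagesim import (Stimuli, composite_cyclin_signal,
                        division_probability_vs_progress, growth_media,
                        progress_at, reference_signal, simulate_cell)
from lineagesim.cycle_progress import probability_crossing
from lineagesim.fixtures import channel_trajectory


def cyclin_fixture(values_e, values_a, values_b, dt=0.05):
    model_channels = {"cyclinA_cdk2": values_a, "cyclinB_cdk1": values_b}
    return channel_trajectory(values_e, dt, channel="cyclinE_cdk2",
                              extra=model_channels)


class TestCompositeSignal:
    def test_identical_sinusoids_reduce_to_normalized_sinusoid(self):
        t = np.arange(0, 96, 0.05)
        s = 2.0 + np.sin(2 * np.pi * t / 24.0)
        traj = cyclin_fixture(s, s, s)
        sig = composite_cyclin_signal(traj)
        np.testing.assert_allclose(sig.value, s / s.max(), rtol=1e-12)

    def test_normalization_bound(self):
        t = np.arange(0, 48, 0.05)
        a = 2.0 * (1 + np.sin(2 * np.pi * t / 24))
        b = 4.0 * (1 + np.sin(2 * np.pi * t / 24 + 1.0))
        c = 8.0 * (1 + np.sin(2 * np.pi * t / 24 + 2.0))
        sig = composite_cyclin_signal(cyclin_fixture(a, b, c))
        assert sig.value.max() <= 1.0 + 1e-12
        # aligned peaks reach the bound exactly
        sig2 = composite_cyclin_signal(cyclin_fixture(a, 2 * a, 4 * a))
        assert sig2.value.max() == pytest.approx(1.0)

    def test_zero_peak_channel_rejected(self):
        t = np.arange(0, 48, 0.05)
        s = 1 + np.sin(2 * np.pi * t / 24)
        with pytest.raises(ValueError, match="positive peak"):
            composite_cyclin_signal(cyclin_fixture(s, np.zeros_like(s), s))

    def test_phase_shifted_waves_troughs_match_dense_minima(self):
        """Composite troughs agree with brute-force minima of the mean."""
        t = np.arange(0, 144, 0.05)

        def wave(phase, amp):
            return amp * (1.1 + np.sin(2 * np.pi * (t - phase) / 48.0))

        from lineagesim import DetectorConfig

        e, a, b = wave(0.0, 1.0), wave(4.0, 2.0), wave(8.0, 4.0)
        traj = cyclin_fixture(e, a, b)
        sig = composite_cyclin_signal(traj, detector=DetectorConfig(
            peak_min=0.3, prominence_frac=0.1, min_separation=4.0,
            terminal_frac=0.15, prefer="trough"))
        mean = (e / e.max() + a / a.max() + b / b.max()) / 3
        assert len(sig.troughs) >= 2
        for trough in sig.troughs:
            i = np.searchsorted(t, trough)
            lo, hi = max(0, i - 100), min(len(t), i + 100)
            assert mean[i] <= mean[lo:hi].min() + 1e-9


class TestReferenceSignal:
    def test_demo_period_in_oscillator_bounds(self, reference):
        assert 40.0 < reference.period < 60.0
        assert len(reference.troughs) >= 2

    def test_starved_model_has_insufficient_cycles(self, model):
        with pytest.raises(ValueError, match="troughs"):
            reference_signal(model, Stimuli(), duration=96.0)

    def test_period_invariant_to_start_phase(self, model, starved_base,
                                             media, reference):
        """Shift test: starting mid-cycle leaves the measured period alone."""
        long = simulate_cell(starved_base.copy(), media, 260.0, model=model,
                             stochastic_death=False)
        shift = np.searchsorted(long.t, 20.0)
        from lineagesim import CellState

        shifted = CellState(species=long.y[shift].copy(), cell_id="shifted")
        traj = simulate_cell(shifted, media, 220.0, model=model,
                             stochastic_death=False)
        sig = composite_cyclin_signal(traj)
        assert abs(np.diff(sig.troughs).mean() - reference.period) <= 0.2


class TestProgressAt:
    def test_self_alignment_at_trough_is_zero(self, model, media, reference,
                                              starved_base):
        from lineagesim import CellState

        long = simulate_cell(starved_base.copy(), media, 260.0, model=model,
                             stochastic_death=False)
        sig = composite_cyclin_signal(long)
        t0 = sig.troughs[1]
        state = CellState(species=long.y[np.searchsorted(long.t, t0)].copy())
        traj = simulate_cell(state, media, 96.0, model=model,
                             stochastic_death=False)
        est = progress_at(traj, reference, 0.0)
        frac = min(est.fraction, 1.0 - est.fraction)  # circular distance to 0
        assert frac < 0.03
        assert not est.low_quality

    def test_quarter_period_offset(self, model, media, reference,
                                   starved_base):
        from lineagesim import CellState

        long = simulate_cell(starved_base.copy(), media, 260.0, model=model,
                             stochastic_death=False)
        sig = composite_cyclin_signal(long)
        t_q = sig.troughs[1] + 0.25 * reference.period
        state = CellState(species=long.y[np.searchsorted(long.t, t_q)].copy())
        traj = simulate_cell(state, media, 96.0, model=model,
                             stochastic_death=False)
        est = progress_at(traj, reference, 0.0)
        assert est.fraction == pytest.approx(0.25, abs=0.03)

    def test_shift_equivariance(self, model, media, reference, starved_base):
        """Shifting the query time shifts progress by delta/T mod 1."""
        from lineagesim import CellState

        long = simulate_cell(starved_base.copy(), media, 260.0, model=model,
                             stochastic_death=False)
        sig = composite_cyclin_signal(long)
        state = CellState(
            species=long.y[np.searchsorted(long.t, sig.troughs[1])].copy())
        traj = simulate_cell(state, media, 120.0, model=model,
                             stochastic_death=False)
        base = progress_at(traj, reference, 0.0).fraction
        for delta in (6.0, 12.0, 20.0):
            est = progress_at(traj, reference, delta).fraction
            expected = (base + delta / reference.period) % 1.0
            err = min(abs(est - expected), 1 - abs(est - expected))
            assert err < 0.04, delta

    def test_query_outside_span_rejected(self, model, media, reference,
                                         starved_base):
        traj = simulate_cell(starved_base.copy(), media, 10.0, model=model,
                             stochastic_death=False)
        with pytest.raises(ValueError, match="span"):
            progress_at(traj, reference, 50.0)


class TestDivisionProbability:
    def test_all_divided_is_one_on_populated_bins(self):
        rng = np.random.default_rng(1)
        progress = rng.uniform(0, 1, 200)
        table = division_probability_vs_progress(progress,
                                                 np.ones(200, bool))
        populated = table.dropna(subset=["p_divide"])
        assert np.allclose(populated.p_divide, 1.0)

    def test_values_are_probabilities(self):
        rng = np.random.default_rng(2)
        progress = rng.uniform(0, 1, 300)
        divided = rng.random(300) < 0.5
        table = division_probability_vs_progress(progress, divided)
        vals = table.p_divide.dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_disjoint_supports_give_hard_zero_one(self):
        progress = np.concatenate([np.linspace(0.05, 0.25, 80),
                                   np.linspace(0.65, 0.9, 80)])
        divided = np.concatenate([np.zeros(80, bool), np.ones(80, bool)])
        table = division_probability_vs_progress(progress, divided)
        lo = table[(table.progress > 0.07) & (table.progress < 0.23)]
        hi = table[(table.progress > 0.67) & (table.progress < 0.88)]
        assert np.nanmax(lo.p_divide.values) < 0.02
        assert np.nanmin(hi.p_divide.values) > 0.98

    def test_step_rule_threshold_recovered(self):
        """Synthetic generating rule: divide iff progress > 0.1."""
        rng = np.random.default_rng(3)
        progress = rng.uniform(0, 1, 1000)
        divided = progress > 0.1
        table = division_probability_vs_progress(progress, divided)
        crossing = probability_crossing(table)
        assert abs(crossing - 0.1) <= 0.03

    def test_small_groups_fall_back_to_counts(self):
        # one divider among many non-dividers must not raise
        progress = np.linspace(0, 0.9, 50)
        divided = np.zeros(50, bool)
        divided[40] = True
        table = division_probability_vs_progress(progress, divided)
        assert np.nanmax(table.p_divide.values) <= 1.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            division_probability_vs_progress([0.1, 0.2], [True])
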