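"""Demo-model dynamics: starved fixed point, stimulated oscillator,
heterogenization statistics, observables, and conservation."""

import numpy as np
import pytest

from lineagesim import (CellState, Stimuli, build_demo_model, detect_division,
                        get_observable, growth_media, heterogenize_population,
                        simulate_cell)
from lineagesim.cellmodel import lognormal_scalings
from lineagesim.demo_model import EXPRESSION_PARAMS, POOL_MEMBERS
from lineagesim.fixtures import channel_trajectory


class TestSimulateCell:
    def test_identity_and_grid(self, model, starved_base, media):
        traj = simulate_cell(starved_base.copy(), media, 0.05, 0.05,
                             model=model, stochastic_death=False)
        assert len(traj.t) == 2
        np.testing.assert_allclose(traj.y[0], starved_base.species)

    def test_rejects_bad_durations(self, model, starved_base, media):
        with pytest.raises(ValueError):
            simulate_cell(starved_base.copy(), media, 0.0, model=model)
        with pytest.raises(ValueError):
            simulate_cell(starved_base.copy(), media, 1.0, dt=-0.1, model=model)

    def test_nonnegative_concentrations(self, media_trajectory):
        assert media_trajectory.y.min() >= 0.0

    def test_bitwise_reproducible(self, model, starved_base, media):
        runs = []
        for _ in range(2):
            state = starved_base.copy(cell_id="r",
                                      rng=np.random.default_rng(123))
            traj = simulate_cell(state, media, 24.0, model=model)
            runs.append(traj.y)
        assert (runs[0] == runs[1]).all()

    def test_drug_requires_module(self, model, starved_base):
        with pytest.raises(ValueError, match="drug module"):
            simulate_cell(starved_base.copy(),
                          growth_media(drug="trametinib", dose=1.0),
                          1.0, model=model, stochastic_death=False)


class TestStarvedAndStimulated:
    def test_starved_cell_does_not_cycle(self, model, starved_base,
                                         media_trajectory):
        traj = simulate_cell(starved_base.copy(), Stimuli(), 96.0,
                             model=model, stochastic_death=False)
        assert detect_division(traj) == []
        # fixed point: CycB-CDK1 oscillation amplitude over the final 24 h is
        # below 1% of the stimulated pulse amplitude
        b = traj.channel("cyclinB_cdk1")[-480:]
        pulse = media_trajectory.channel("cyclinB_cdk1").max()
        assert b.max() - b.min() < 0.01 * pulse

    def test_stimulated_limit_cycle(self, media_trajectory):
        divisions = np.array(detect_division(media_trajectory))
        assert len(divisions) >= 3
        periods = np.diff(divisions)
        assert periods.std() / periods.mean() < 0.05
        assert 30.0 < periods.mean() < 70.0

    def test_period_matches_fine_step_integration(self, model, starved_base,
                                                  media, media_trajectory):
        """Refined-step oracle: dt/10 reproduces the oscillator period."""
        fine = simulate_cell(starved_base.copy(), media, 150.0, dt=0.005,
                             model=model, stochastic_death=False)
        d_fine = np.array(detect_division(fine))
        d_coarse = np.array(detect_division(media_trajectory))
        p_fine = np.diff(d_fine).mean()
        p_coarse = np.diff(d_coarse[:len(d_fine)]).mean()
        assert abs(p_fine - p_coarse) < 0.2  # hours


class TestHeterogenize:
    def test_zero_cv_cells_identical(self, model, starved_base):
        cells = heterogenize_population(starved_base, 3, cv=0.0, burn_in=2.0,
                                        model=model, seed=1)
        for c in cells[1:]:
            np.testing.assert_array_equal(c.species, cells[0].species)
        assert all(s == 1.0 for s in cells[0].param_scalings.values())

    def test_default_burn_in_is_48h(self):
        import inspect

        sig = inspect.signature(heterogenize_population)
        assert sig.parameters["burn_in"].default == 48.0

    def test_scaling_cv_matches_target(self):
        """Direct-sampling oracle: lognormal scalings hit the requested CV."""
        rng = np.random.default_rng(7)
        draws = {n: [] for n in EXPRESSION_PARAMS}
        for _ in range(5000):
            s = lognormal_scalings(rng, EXPRESSION_PARAMS, cv=0.2)
            for n, v in s.items():
                draws[n].append(v)
        for n, vals in draws.items():
            vals = np.array(vals)
            cv = vals.std() / vals.mean()
            assert abs(cv - 0.2) <= 0.15 * 0.2, n
            assert abs(vals.mean() - 1.0) < 0.02

    def test_states_scaled_per_pool(self, model, starved_base):
        cells = heterogenize_population(starved_base, 5, cv=0.3, burn_in=0.0,
                                        model=model, seed=2)
        for c in cells:
            for pool, members in POOL_MEMBERS.items():
                if pool not in c.param_scalings:
                    continue
                total = sum(c.species[model.species_index(m)] for m in members)
                base_total = sum(starved_base.species[model.species_index(m)]
                                 for m in members)
                np.testing.assert_allclose(
                    total, base_total * c.param_scalings[pool], rtol=1e-9)

    def test_rejects_bad_arguments(self, model, starved_base):
        with pytest.raises(ValueError):
            heterogenize_population(starved_base, 0, model=model)
        with pytest.raises(ValueError):
            heterogenize_population(starved_base, 2, cv=-0.1, model=model)


class TestObservables:
    def test_cleaved_fraction_trivial_cases(self):
        n = 50
        traj = channel_trajectory(np.full(n, 10.0), channel="parp",
                                  extra={"cleaved_parp": np.zeros(n)})
        assert np.all(get_observable(traj, "cleaved_parp_fraction") == 0.0)
        traj = channel_trajectory(np.full(n, 7.0), channel="parp",
                                  extra={"cleaved_parp": np.full(n, 7.0)})
        np.testing.assert_allclose(
            get_observable(traj, "cleaved_parp_fraction"), 0.5)

    def test_unknown_channel_lists_valid(self, media_trajectory):
        with pytest.raises(KeyError, match="cyclinB_cdk1"):
            media_trajectory.channel("nope")

    def test_channel_equals_species_sum(self, model, media_trajectory):
        # cyclinD is defined as free + CDK4/6-complexed Cyclin D
        direct = (media_trajectory.y[:, model.species_index("CycD")]
                  + media_trajectory.y[:, model.species_index("CycD_CDK46")])
        np.testing.assert_allclose(media_trajectory.channel("cyclinD"), direct)

    def test_length_matches_grid(self, media_trajectory):
        for ch in ("erk_activity", "akt_activity", "cyclinB_cdk1"):
            assert len(media_trajectory.channel(ch)) == len(media_trajectory.t)


class TestConservation:
    def test_pools_conserved_under_stimulation(self, model, media_trajectory):
        """Binding pairs only exchange matter: totals stay constant."""
        for pool in ("EGFR", "PI3K", "AKT", "Ras", "MEK", "ERK", "CDK46"):
            cols = [model.species_index(m) for m in POOL_MEMBERS[pool]]
            totals = media_trajectory.y[:, cols].sum(axis=1)
            np.testing.assert_allclose(totals, totals[0], rtol=1e-5)

    def test_parp_total_conserved_through_death(self, model, starved_base):
        state = starved_base.copy(rng=np.random.default_rng(0))
        state.species[model.species_index("DeathSig")] = 1.0
        traj = simulate_cell(state, growth_media(), 24.0, model=model)
        total = traj.channel("parp") + traj.channel("cleaved_parp")
        np.testing.assert_allclose(total, total[0], rtol=1e-6)
        # the latched death signal cleaves more than half of PARP
        assert traj.channel("cleaved_parp_fraction")[-1] > 0.5
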