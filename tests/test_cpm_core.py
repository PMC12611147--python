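"""Cellular-Potts engine: energies, acceptance rule, Monte-Carlo bookkeeping."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pottsnet import (
    CopyAttempt,
    LatticeState,
    ModelParams,
    acceptance_probability,
    delta_energy,
    run_mcs,
    total_energy,
)
from pottsnet.cpm_core import recount_surfaces, recount_volumes

from conftest import random_state


def _random_attempt(state, rng):
    """A random valid copy attempt (source and dest ids differ), or None."""
    H, W = state.shape
    for _ in range(200):
        r, c = int(rng.integers(0, H)), int(rng.integers(0, W))
        dr, dc = [(0, 1), (0, -1), (1, 0), (-1, 0)][int(rng.integers(0, 4))]
        nr, nc = (r + dr) % H, (c + dc) % W
        src, dst = int(state.cell_id_lattice[nr, nc]), int(state.cell_id_lattice[r, c])
        if src != dst:
            return CopyAttempt((nr, nc), (r, c), src, dst)
    return None


class TestTotalEnergy:
    def test_all_medium_lattice_has_zero_energy(self, small_params):
        n = small_params.lattice_size
        state = LatticeState(np.zeros((n, n), dtype=np.int32), np.zeros((n, n)))
        assert total_energy(state, small_params) == 0.0

    def test_single_block_cell_energy_assembled_by_hand(self):
        # one 2x2 cell on 8x8: V=4, S=8 faces, all boundary faces touch medium
        params = ModelParams(
            lattice_size=8, n_cells_initial=1, contact_neighbor_order=1,
            D=0.5, secretion_rate=0.3, pde_substeps=4,
        )
        lattice = np.zeros((8, 8), dtype=np.int32)
        lattice[2:4, 2:4] = 1
        state = LatticeState(lattice, np.zeros((8, 8)))
        expected = (
            8 * params.J_cell_medium
            + params.lambda_volume * (4 - params.V_target) ** 2
            + params.lambda_surface * (8 - params.S_target) ** 2
        )
        assert total_energy(state, params) == pytest.approx(expected, abs=1e-9)

    def test_two_adjacent_single_site_cells_contact_terms(self):
        # 4x4 lattice, cells 1 and 2 side by side: one cell-cell face at J=6,
        # each remaining first-order face touches medium at J=8.2
        params = ModelParams(
            lattice_size=8, n_cells_initial=1, contact_neighbor_order=1,
            D=0.5, secretion_rate=0.3, pde_substeps=4,
        )
        lattice = np.zeros((4, 4), dtype=np.int32)
        lattice[1, 1], lattice[1, 2] = 1, 2
        state = LatticeState(lattice, np.zeros((4, 4)))
        contact = 6.0 + 6 * 8.2  # 1 shared face + 3 medium faces per cell
        constraint = 2 * (
            params.lambda_volume * (1 - params.V_target) ** 2
            + params.lambda_surface * (4 - params.S_target) ** 2
        )
        assert total_energy(state, params) == pytest.approx(contact + constraint, abs=1e-9)

    def test_invalid_state_rejected(self, small_params):
        n = small_params.lattice_size
        state = LatticeState(np.zeros((n, n), dtype=np.int32), np.zeros((n, n)))
        state.field[0, 0] = -1.0
        with pytest.raises(ValueError):
            total_energy(state, small_params)


class TestDeltaEnergy:
    @pytest.mark.parametrize("contact_order", [1, 2])
    def test_incremental_matches_total_energy_oracle(self, rng, contact_order):
        """dH from the incremental path equals the brute-force total-energy
        difference (chemotaxis off) on randomized attempts."""
        params = ModelParams(
            lattice_size=8, n_cells_initial=1, lambda_chemotaxis=0.0,
            contact_neighbor_order=contact_order,
            D=0.5, secretion_rate=0.3, pde_substeps=4,
        )
        checked = 0
        for trial in range(40):
            state = random_state(rng, size=8, n_ids=4)
            for _ in range(30):
                attempt = _random_attempt(state, rng)
                if attempt is None:
                    continue
                dH = delta_energy(state, params, attempt)
                before = total_energy(state, params)
                after_lattice = state.cell_id_lattice.copy()
                after_lattice[attempt.dest_site] = attempt.source_id
                after = total_energy(LatticeState(after_lattice, state.field), params)
                assert dH == pytest.approx(after - before, abs=1e-9)
                checked += 1
        assert checked >= 1000

    def test_same_cell_attempt_rejected(self, rng, small_params):
        lattice = np.zeros((8, 8), dtype=np.int32)
        lattice[2:4, 2:4] = 1
        state = LatticeState(lattice, np.zeros((8, 8)))
        with pytest.raises(ValueError):
            delta_energy(
                state, small_params, CopyAttempt((2, 2), (2, 3), 1, 1)
            )

    def test_uniform_field_chemotaxis_contributes_nothing(self, rng):
        base = dict(lattice_size=8, n_cells_initial=1,
                    D=0.5, secretion_rate=0.3, pde_substeps=4)
        with_chemo = ModelParams(lambda_chemotaxis=2000.0, **base)
        without = ModelParams(lambda_chemotaxis=0.0, **base)
        state = random_state(rng, size=8, n_ids=3)
        state.field[:] = 0.7  # uniform concentration
        for _ in range(50):
            attempt = _random_attempt(state, rng)
            if attempt is None:
                continue
            assert delta_energy(state, with_chemo, attempt) == pytest.approx(
                delta_energy(state, without, attempt), abs=1e-12
            )

    def test_chemotaxis_favors_up_gradient_advance(self):
        params = ModelParams(lattice_size=8, n_cells_initial=1,
                             D=0.5, secretion_rate=0.3, pde_substeps=4)
        lattice = np.zeros((8, 8), dtype=np.int32)
        lattice[4, 3] = 1
        field = np.tile(np.linspace(0.0, 1.0, 8), (8, 1))  # increases with column
        state = LatticeState(lattice, field)
        up = delta_energy(state, params, CopyAttempt((4, 3), (4, 4), 1, 0))
        lattice2 = np.zeros((8, 8), dtype=np.int32)
        lattice2[4, 5] = 1
        state2 = LatticeState(lattice2, field)
        down = delta_energy(state2, params, CopyAttempt((4, 5), (4, 4), 1, 0))
        assert up < down  # advancing toward higher concentration is cheaper


class TestAcceptanceProbability:
    def test_energy_lowering_moves_always_accepted(self):
        assert acceptance_probability(-3.0, 8.0) == 1.0
        assert acceptance_probability(0.0, 0.5) == 1.0

    def test_boltzmann_value_at_unit_ratio(self):
        assert acceptance_probability(8.0, 8.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.0, 0.0)
        with pytest.raises(ValueError):
            acceptance_probability(1.0, -2.0)

    def test_empirical_acceptance_matches_boltzmann_rule(self, rng):
        """Bernoulli frequency of the acceptance rule stays inside the
        3-sigma binomial band of exp(-dH/H')."""
        n = 100_000
        for dH in (4.0, 8.0, 16.0):
            p = acceptance_probability(dH, 8.0)
            accepted = int((rng.random(n) < p).sum())
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(accepted - n * p) < 3 * sigma


class TestRunMcs:
    def test_zero_steps_leaves_state_unchanged(self, small_params, rng):
        from pottsnet import init_state

        state = init_state(small_params, rng)
        before = state.cell_id_lattice.copy()
        run_mcs(state, small_params, rng, 0)
        assert np.array_equal(state.cell_id_lattice, before)
        assert state.mcs == 0

    def test_cached_statistics_match_recount_after_sweeps(self, small_params, rng):
        from pottsnet import init_state

        state = init_state(small_params, rng)
        run_mcs(state, small_params, rng, 50)
        assert state.mcs == 50
        state.validate()  # raises if cached volumes/surfaces drift
        n_ids = len(state.volumes)
        assert np.array_equal(state.volumes,
                              recount_volumes(state.cell_id_lattice, n_ids))
        assert np.array_equal(state.surfaces,
                              recount_surfaces(state.cell_id_lattice, n_ids))

    def test_site_conservation(self, small_params, rng):
        from pottsnet import init_state

        state = init_state(small_params, rng)
        run_mcs(state, small_params, rng, 30)
        assert int(state.volumes.sum()) == int((state.cell_id_lattice > 0).sum())

    def test_energy_descends_in_zero_temperature_limit(self, rng):
        """With H' -> 0+ only energy-lowering copies are accepted, so the
        total energy is non-increasing across MCS."""
        params = ModelParams(
            lattice_size=16, n_cells_initial=3, lambda_chemotaxis=0.0,
            temperature_Hprime=1e-6, D=0.5, secretion_rate=0.0, pde_substeps=4,
        )
        from pottsnet import init_state

        state = init_state(params, rng)
        energies = [total_energy(state, params)]
        for _ in range(6):
            run_mcs(state, params, rng, 5)
            energies.append(total_energy(state, params))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_cyclic_shift_of_initial_state_is_statistically_indistinguishable(self):
        """No preferred lattice origin: energy distributions at MCS 60 from
        shifted and unshifted initial conditions overlap."""
        params = ModelParams(lattice_size=16, n_cells_initial=3,
                             D=0.5, secretion_rate=0.3, pde_substeps=4)
        plain, shifted = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            from pottsnet import init_state

            state = init_state(params, rng)
            s2 = LatticeState(
                np.roll(state.cell_id_lattice, (5, 9), axis=(0, 1)),
                np.roll(state.field, (5, 9), axis=(0, 1)),
            )
            run_mcs(state, params, np.random.default_rng(seed + 1000), 60)
            run_mcs(s2, params, np.random.default_rng(seed + 2000), 60)
            plain.append(total_energy(state, params))
            shifted.append(total_energy(s2, params))
        assert mannwhitneyu(plain, shifted).pvalue > 0.01
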