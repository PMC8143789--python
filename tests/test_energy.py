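import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpmsim.energy import (
    ActModel,
    Adhesion,
    Hamiltonian,
    PerimeterConstraint,
    VolumeConstraint,
    acceptance_probability,
    delta_H,
    delta_act,
    geometric_mean_activity,
    total_H,
)
from cpmsim.errors import ConfigurationError
from cpmsim.lattice import GridSpec, LatticeState, make_disc_cell

from .conftest import naive_total_H, random_blob_state, valid_attempt_pairs


def adhesion_only(j_bg_cell=16.0, j_cell_cell=0.0, n=2):
    J = np.full((n, n), j_cell_cell)
    J[0, :] = J[:, 0] = j_bg_cell
    J[0, 0] = 0.0
    return Hamiltonian(temperature=10, adhesion=Adhesion(J))


class TestConstruction:
    def test_asymmetric_J_rejected(self):
        with pytest.raises(ConfigurationError, match="symmetric"):
            Adhesion(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_background_lambda_must_be_zero(self):
        with pytest.raises(ConfigurationError):
            VolumeConstraint([1.0, 1.0], [0.0, 10.0])

    def test_act_enabled_without_memory_rejected(self):
        with pytest.raises(ConfigurationError):
            ActModel([0.0, 10.0], [0, 0])

    def test_temperature_positive(self):
        with pytest.raises(ConfigurationError):
            Hamiltonian(temperature=0, adhesion=Adhesion(np.zeros((2, 2))))

    def test_at_least_one_term(self):
        with pytest.raises(ConfigurationError):
            Hamiltonian(temperature=10)


class TestTotalH:
    def test_empty_grid_zero(self):
        state = LatticeState(GridSpec(10, 10))
        assert total_H(state, adhesion_only()) == 0.0

    def test_single_pixel_cell_adhesion(self):
        # 8 heterotypic Moore pairs at J = 16 -> H = 128
        state = LatticeState(GridSpec(10, 10))
        cid = state.register_cell(1)
        state.set_pixel((5, 5), cid)
        assert total_H(state, adhesion_only(16.0)) == 128.0

    def test_cell_at_target_volume_zero(self):
        state = LatticeState(GridSpec(20, 20))
        cid = state.register_cell(1)
        make_disc_cell(state, (10, 10), 2.83, cid)  # 25 pixels
        assert state.volume_of(cid) == 25
        ham = Hamiltonian(temperature=10, volume=VolumeConstraint([0, 2.0], [0, 25.0]))
        assert total_H(state, ham) == 0.0

    def test_matches_naive_oracle_on_random_states(self, rng):
        for _ in range(5):
            state = random_blob_state(rng, 15, 15)
            J = rng.integers(0, 20, (3, 3)).astype(float)
            J = (J + J.T) / 2
            np.fill_diagonal(J[:1, :1], 0)
            lam_v = np.array([0.0, 2.0, 3.0])
            tgt_v = np.array([0.0, 10.0, 12.0])
            lam_p = np.array([0.0, 1.0, 2.0])
            tgt_p = np.array([0.0, 12.0, 8.0])
            ham = Hamiltonian(
                temperature=10,
                adhesion=Adhesion(J),
                volume=VolumeConstraint(lam_v, tgt_v),
                perimeter=PerimeterConstraint(lam_p, tgt_p),
            )
            expected = naive_total_H(state, J, lam_v, tgt_v, lam_p, tgt_p)
            assert total_H(state, ham) == pytest.approx(expected, abs=1e-9)

    def test_adhesion_symmetric_under_kind_relabel(self, rng):
        state = random_blob_state(rng, 15, 15, n_kinds=3)
        J = np.array([[0.0, 5, 7], [5, 2, 3], [7, 3, 4]])
        H1 = total_H(state, Hamiltonian(temperature=10, adhesion=Adhesion(J)))
        # swap kinds 1 <-> 2 everywhere and relabel J accordingly
        swapped = LatticeState.from_identity_matrix(
            state.spec,
            state.identity,
            {c: {1: 2, 2: 1}[state.kind_of(c)] for c in range(1, state.n_cells)},
            n_kinds=3,
        )
        perm = [0, 2, 1]
        J2 = J[np.ix_(perm, perm)]
        H2 = total_H(swapped, Hamiltonian(temperature=10, adhesion=Adhesion(J2)))
        assert H1 == H2


class TestDeltaH:
    def test_removing_isolated_single_pixel(self):
        state = LatticeState(GridSpec(10, 10))
        cid = state.register_cell(1)
        state.set_pixel((5, 5), cid)
        # copy background from (4, 5) onto the cell pixel
        assert delta_H(state, adhesion_only(16.0), (4, 5), (5, 5)) == -128.0

    def test_volume_gain_above_target(self):
        state = LatticeState(GridSpec(20, 20))
        cid = state.register_cell(1)
        make_disc_cell(state, (10, 10), 2.83, cid)  # 25 = target
        ham = Hamiltonian(temperature=10, volume=VolumeConstraint([0, 2.0], [0, 25.0]))
        # growing one pixel: 2 * ((26-25)^2 - 0) == 2
        assert delta_H(state, ham, (12, 10), (13, 10)) == 2.0

    def test_null_hamiltonian_zero(self, rng):
        state = random_blob_state(rng, 12, 12)
        ham = Hamiltonian(
            temperature=10,
            adhesion=Adhesion(np.zeros((3, 3))),
            volume=VolumeConstraint([0.0, 0, 0], [0.0, 0, 0]),
        )
        for src, tgt in valid_attempt_pairs(state, rng, 20):
            assert delta_H(state, ham, src, tgt) == 0.0

    def test_equal_identities_rejected(self):
        state = LatticeState(GridSpec(10, 10))
        with pytest.raises(ConfigurationError):
            delta_H(state, adhesion_only(), (1, 1), (2, 2))

    def test_non_neighbors_rejected(self):
        state = LatticeState(GridSpec(10, 10))
        cid = state.register_cell(1)
        state.set_pixel((8, 8), cid)
        with pytest.raises(ConfigurationError):
            delta_H(state, adhesion_only(), (1, 1), (8, 8))

    @pytest.mark.parametrize(
        ("torus", "kernel_name"),
        [(True, "moore"), (False, "moore"), (True, "von_neumann")],
    )
    def test_matches_total_difference(self, rng, torus, kernel_name):
        from cpmsim.lattice import MOORE, VON_NEUMANN

        kernel = MOORE if kernel_name == "moore" else VON_NEUMANN
        # incremental vs global, all three global terms, integer parameters
        for _ in range(4):
            state = random_blob_state(rng, 14, 14, torus_x=torus, torus_y=torus, kernel=kernel)
            J = rng.integers(0, 15, (3, 3))
            J = J + J.T
            ham = Hamiltonian(
                temperature=10,
                adhesion=Adhesion(J.astype(float)),
                volume=VolumeConstraint([0, 3.0, 1.0], [0, 9.0, 14.0]),
                perimeter=PerimeterConstraint([0, 2.0, 1.0], [0, 11.0, 16.0]),
            )
            for src, tgt in valid_attempt_pairs(state, rng, 60):
                before = total_H(state, ham)
                d = delta_H(state, ham, src, tgt)
                old = state.get(tgt)
                state.set_pixel(tgt, state.get(src))
                after = total_H(state, ham)
                state.set_pixel(tgt, old)
                assert d == after - before


class TestActTerm:
    def _active_disc(self, activity=20):
        state = LatticeState(GridSpec(20, 20))
        cid = state.register_cell(1)
        make_disc_cell(state, (10, 10), 3, cid)
        state.activity[state.identity == cid] = activity
        return state, cid

    def test_disabled_lambda_zero(self, rng):
        state, _ = self._active_disc()
        params = ActModel([0.0, 0.0], [0, 20])
        for src, tgt in valid_attempt_pairs(state, rng, 10):
            assert delta_act(state, params, src, tgt) == 0.0

    def test_protrusion_from_uniformly_active_cell(self):
        # GM(source) = 20 (all same-cell neighbors at max), GM(target in bg) = 0
        state, cid = self._active_disc(activity=20)
        params = ActModel([0.0, 100.0], [0, 20])
        src, tgt = (13, 10), (14, 10)  # boundary cell pixel -> adjacent background
        assert state.get(src) == cid and state.get(tgt) == 0
        assert delta_act(state, params, src, tgt) == -100.0

    def test_symmetric_configuration_zero(self):
        state = LatticeState(GridSpec(10, 10))
        c1 = state.register_cell(1)
        c2 = state.register_cell(1)
        state.set_pixel((4, 4), c1, activity=10)
        state.set_pixel((5, 4), c2, activity=10)
        params = ActModel([0.0, 50.0], [0, 20])
        assert delta_act(state, params, (4, 4), (5, 4)) == 0.0

    def test_gm_zero_when_any_factor_zero(self):
        state, cid = self._active_disc(activity=20)
        state.activity[10, 10] = 0  # one dead pixel at the center
        assert geometric_mean_activity(state, (10, 9)) == 0.0

    def test_gm_background_is_zero(self):
        state, _ = self._active_disc()
        assert geometric_mean_activity(state, (0, 0)) == 0.0

    def test_retraction_uses_target_kind_params(self):
        # source is background (act disabled); target belongs to an active cell
        state, cid = self._active_disc(activity=20)
        params = ActModel([0.0, 100.0], [0, 20])
        src, tgt = (14, 10), (13, 10)
        assert state.get(src) == 0 and state.get(tgt) == cid
        d = delta_act(state, params, src, tgt)
        assert d == pytest.approx(5.0 * geometric_mean_activity(state, tgt))
        assert d > 0


class TestAcceptanceProbability:
    def test_favourable_always_succeeds(self):
        assert acceptance_probability(-5.0, 20.0) == 1.0

    def test_delta_equals_temperature(self):
        assert acceptance_probability(20.0, 20.0) == pytest.approx(math.exp(-1))

    def test_zero_delta_accepted(self):
        assert acceptance_probability(0.0, 20.0) == 1.0

    def test_bad_temperature(self):
        with pytest.raises(ConfigurationError):
            acceptance_probability(1.0, 0.0)
        with pytest.raises(ConfigurationError):
            acceptance_probability(1.0, -3.0)

    @settings(max_examples=100, deadline=None)
    @given(
        d1=st.floats(0.01, 100),
        d2=st.floats(0.01, 100),
        t1=st.floats(0.01, 100),
        t2=st.floats(0.01, 100),
    )
    def test_monotonicity(self, d1, d2, t1, t2):
        lo_d, hi_d = sorted([d1, d2])
        lo_t, hi_t = sorted([t1, t2])
        assert acceptance_probability(hi_d, lo_t) <= acceptance_probability(lo_d, lo_t)
        assert acceptance_probability(hi_d, lo_t) <= acceptance_probability(hi_d, hi_t)
        assert 0.0 <= acceptance_probability(hi_d, hi_t) <= 1.0
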