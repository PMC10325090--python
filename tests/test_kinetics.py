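import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from adhesim import validate_params
from adhesim.kinetics import (CatchSlipLaw, attempt_binding, attempt_unbinding,
                              bond_tensions, koff, optimum_force, p_event)
from adhesim.state import FREE, IntegrinEnsemble, LigandLattice, initialize

from oracles import single_bond_lifetime_oracle


class TestCatchSlipLaw:
    def test_zero_force_rate_is_sum_of_amplitudes(self):
        assert koff(0.0) == pytest.approx(2.000004, rel=1e-9)

    def test_rate_at_thirty_piconewton(self):
        # 2 e^-3 + 4e-6 e^9 = 0.131986 /s -> lifetime ~7.58 s
        assert koff(30.0) == pytest.approx(0.1319865, rel=1e-5)
        assert 1.0 / koff(30.0) == pytest.approx(7.577, abs=0.01)

    def test_lifetime_maximising_force_closed_form(self):
        # F* = ln(a1 b1 / (a2 b2)) / (b1 + b2) = 30.06 pN
        assert optimum_force() == pytest.approx(30.06, abs=0.01)

    def test_optimum_against_scipy_minimiser(self):
        res = minimize_scalar(lambda F: koff(F), bounds=(0.0, 100.0),
                              method="bounded")
        assert optimum_force() == pytest.approx(res.x, abs=1e-3)

    def test_slip_regime_weaker_than_unloaded(self):
        # beyond ~43.7 pN the slip pathway makes bonds shorter-lived than at rest
        assert koff(45.0) == pytest.approx(2.95, abs=0.02)
        assert koff(45.0) > koff(0.0)

    def test_single_interior_minimum(self):
        F = np.linspace(0.0, 80.0, 1601)
        k = koff(F)
        sign_changes = np.sum(np.diff(np.sign(np.diff(k))) != 0)
        assert sign_changes == 1
        assert F[np.argmin(k)] == pytest.approx(optimum_force(), abs=0.1)

    def test_rejects_nonpositive_coefficients(self):
        with pytest.raises(ValueError):
            CatchSlipLaw(a1=0.0)

    @given(st.floats(0.0, 60.0), st.floats(0.0, 60.0))
    def test_convexity(self, f1, f2):
        mid = koff((f1 + f2) / 2.0)
        assert mid <= (koff(f1) + koff(f2)) / 2.0 + 1e-12


class TestPEvent:
    def test_examples(self):
        assert p_event(0.0, 1e-4) == 0.0
        assert p_event(1.0, 1e-4) == pytest.approx(9.9995e-5, rel=1e-6)
        assert p_event(1e9, 1e-4) == pytest.approx(1.0)

    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_monotone_in_rate(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert p_event(lo, 1e-4) <= p_event(hi, 1e-4)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            p_event(1.0, 0.0)
        with pytest.raises(ValueError):
            p_event(-1.0, 1e-4)


def _pair_scenario(kon=1.0, dt=1e-4, offsets_nm=((5.0, 0.0),)):
    """One integrin at the origin-adjacent ligand cell, hand-placed ligands."""
    params = validate_params({"seed": 0, "kon_base": kon, "dt": dt,
                              "sample_interval": max(dt, 1.0)})
    n = params.n_integrins
    ens = IntegrinEnsemble(
        positions=np.full((n, 2), 0.26),  # parked far from every ligand
        bound_to=np.full(n, FREE, dtype=np.int64),
        bond_start_time=np.full(n, np.nan),
        total_ligated_time=np.zeros(n),
        enhanced_kon=np.zeros(n, dtype=bool),
    )
    ens.positions[0] = (0.0, 0.0)
    lat = LigandLattice(
        positions=np.array(offsets_nm, dtype=float) * 1e-3,
        occupied_by=np.full(len(offsets_nm), FREE, dtype=np.int64),
    )
    return params, ens, lat


class TestBinding:
    def test_outside_capture_radius_never_binds(self, rng):
        params, ens, lat = _pair_scenario(kon=1e9, offsets_nm=((25.0, 0.0),))
        kon = np.full(ens.n, params.kon_base)
        for _ in range(200):
            attempt_binding(ens, lat, kon, params, rng, t=0.0)
        assert ens.bound_to[0] == FREE

    def test_inside_capture_radius_binds_at_saturating_rate(self, rng):
        params, ens, lat = _pair_scenario(kon=1e9, offsets_nm=((5.0, 0.0),))
        kon = np.full(ens.n, params.kon_base)
        events = attempt_binding(ens, lat, kon, params, rng, t=0.25)
        assert ens.bound_to[0] == 0
        assert lat.occupied_by[0] == 0
        assert events == [(0.25, 0, 0)]

    def test_pairs_with_nearest_free_ligand(self, rng):
        params, ens, lat = _pair_scenario(kon=1e9,
                                          offsets_nm=((18.0, 0.0), (6.0, 0.0)))
        kon = np.full(ens.n, params.kon_base)
        attempt_binding(ens, lat, kon, params, rng, t=0.0)
        assert ens.bound_to[0] == 1  # the 6-nm ligand

    def test_occupied_ligand_not_double_bound(self, rng):
        params, ens, lat = _pair_scenario(kon=1e9, offsets_nm=((5.0, 0.0),))
        ens.positions[1] = (0.002, 0.0)  # second integrin 2 nm from ligand
        kon = np.full(ens.n, params.kon_base)
        attempt_binding(ens, lat, kon, params, rng, t=0.0)
        bound = [i for i in range(ens.n) if ens.bound_to[i] == 0]
        assert len(bound) == 1

    def test_per_step_binding_probability(self, rng):
        """Empirical bind count matches n_sweeps * (1 - exp(-kon dt))."""
        params, ens, lat = _pair_scenario(kon=1.0, dt=0.01)
        kon = np.full(ens.n, params.kon_base)
        n_sweeps, binds = 20_000, 0
        for _ in range(n_sweeps):
            if attempt_binding(ens, lat, kon, params, rng, t=0.0):
                binds += 1
                ens.bound_to[0] = FREE  # reset for the next trial
                lat.occupied_by[0] = FREE
        expected = n_sweeps * p_event(1.0, 0.01)
        assert binds == pytest.approx(expected, abs=4 * np.sqrt(expected))


class TestUnbinding:
    def _frozen_bonds(self, n_bonds, stretch_nm, dt, k_sub=0.6):
        params = validate_params({"seed": 0, "dt": dt, "k_sub": k_sub,
                                  "sample_interval": max(dt, 1.0),
                                  "n_integrins": n_bonds})
        ens, lat = initialize(params)
        rows = params.ligand_rows
        interior = [iy * rows + ix
                    for iy in range(1, rows - 1) for ix in range(1, rows - 1)]
        for b in range(n_bonds):
            j = interior[b]
            ens.bound_to[b] = j
            lat.occupied_by[j] = b
            ens.bond_start_time[b] = 0.0
            ens.positions[b] = lat.positions[j] + [stretch_nm * 1e-3, 0.0]
        return params, ens, lat

    def test_tension_is_spring_force_magnitude(self):
        params, ens, lat = self._frozen_bonds(3, stretch_nm=50.01, dt=0.01)
        T = bond_tensions(ens, lat, params)
        assert T[:3] == pytest.approx(0.6 * 50.0, rel=1e-6)

    def test_unloaded_bond_lifetime_near_half_second(self, rng):
        """Frozen bonds at ~zero tension live 1/koff(0) = 0.5 s on average."""
        dt = 0.01
        params, ens, lat = self._frozen_bonds(300, stretch_nm=0.01, dt=dt)
        lifetimes = self._simulate_lifetimes(params, ens, lat, rng, max_sweeps=2000)
        oracle = single_bond_lifetime_oracle(0.0, 20_000, dt, rng)
        # fixed-dt scheme exceeds the analytic mean by ~dt/2 (< 2 dt)
        assert abs(lifetimes.mean() - oracle["analytic"]) < 2 * dt + 0.09
        assert abs(lifetimes.mean() - oracle["bernoulli"]) < 0.09
        assert abs(oracle["gillespie"] - oracle["analytic"]) < 0.02

    def test_optimally_loaded_bond_lives_fifteen_times_longer(self, rng):
        """At 30 pN the catch pathway extends the mean lifetime to ~7.6 s."""
        dt = 0.05
        params, ens, lat = self._frozen_bonds(200, stretch_nm=50.01, dt=dt)
        lifetimes = self._simulate_lifetimes(params, ens, lat, rng, max_sweeps=2000)
        analytic = 1.0 / koff(30.0)
        assert lifetimes.mean() == pytest.approx(analytic, rel=0.20)
        assert lifetimes.mean() > 10 * 0.5

    @staticmethod
    def _simulate_lifetimes(params, ens, lat, rng, max_sweeps):
        """Hold positions frozen; sweep rupture draws until all bonds fail."""
        lifetimes = np.full(ens.n, np.nan)
        for sweep in range(1, max_sweeps + 1):
            t = sweep * params.dt
            for (tt, i, j, tension, dur) in attempt_unbinding(ens, lat, params, rng, t):
                lifetimes[i] = dur
            if not ens.ligated.any():
                break
        return lifetimes[np.isfinite(lifetimes)]

    def test_rupture_restores_diffusive_state(self, rng):
        params, ens, lat = self._frozen_bonds(5, stretch_nm=0.01, dt=0.01)
        for sweep in range(1, 5000):
            attempt_unbinding(ens, lat, params, rng, t=sweep * params.dt)
            if not ens.ligated.any():
                break
        assert (ens.bound_to == FREE).all()
        assert (lat.occupied_by == FREE).all()
        assert np.isnan(ens.bond_start_time).all()
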