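import numpy as np
import pytest

from adhesim import run, run_replicates, validate_params
from adhesim.engine import Trajectory, new_state, step
from adhesim.state import FREE

from oracles import frozen_bond_state, single_pair_state

KOFF_OFF = {"koff_a1": 1e-12, "koff_a2": 1e-12}   # kinetically frozen bonds
BIND_OFF = {"r_bind": 1e-9}                       # capture radius ~ nothing


class TestStepReference:
    def test_quiescent_state_unchanged(self):
        # zero temperature, no bonds, no myosin: nothing moves
        p = validate_params({"seed": 3, "kBT": 0.0, "zeta": 0.0709, **BIND_OFF})
        st = new_state(p)
        before = st.ensemble.positions.copy()
        step(st)
        np.testing.assert_allclose(st.ensemble.positions, before,
                                   rtol=0, atol=1e-12)
        assert st.t == pytest.approx(p.dt)

    def test_bonded_pair_relaxes_at_spring_rate(self):
        """Deterministic bond relaxation follows dL(t) = dL0 exp(-k t / zeta)."""
        p = validate_params({"seed": 3, "kBT": 0.0, "zeta": 0.0709,
                             "dt": 1e-6, "sample_interval": 1e-3,
                             "t_total": 1.0, "t_burnin": 0.5,
                             "k_sub": 0.6, **KOFF_OFF, **BIND_OFF})
        ens, lat = single_pair_state(p, offset_nm=(30.0, 0.0), bound=True)
        st = new_state(p)
        st.ensemble, st.lattice = ens, lat
        j = ens.bound_to[0]
        n_steps = 200
        for _ in range(n_steps):
            step(st)
        sep = np.linalg.norm(st.ensemble.positions[0] - lat.positions[j]) * 1e3
        rate = p.k_sub * 1e3 / p.zeta  # 1/s
        expected = 30.0 * np.exp(-rate * n_steps * p.dt)
        assert sep == pytest.approx(expected, rel=0.01)

    def test_conservation_and_exclusivity_every_step(self):
        p = validate_params({"seed": 5, "dt": 1e-3, "t_total": 2.0,
                             "t_burnin": 1.0, "kon_base": 50.0})
        st = new_state(p)
        for _ in range(500):
            step(st)
            ens, lat = st.ensemble, st.lattice
            bound = ens.bound_to != FREE
            # conservation: every integrin is free or ligated
            assert bound.sum() + (~bound).sum() == p.n_integrins
            # exclusivity + occupancy is the inverse map of bound_to
            bt = ens.bound_to[bound]
            assert np.unique(bt).size == bt.size
            assert np.array_equal(lat.occupied_by[bt], np.flatnonzero(bound))
            occupied = lat.occupied_by != FREE
            assert occupied.sum() == bound.sum()
            assert (ens.positions >= -0.5).all() and (ens.positions < 0.5).all()
        assert st.ensemble.n_ligated > 0  # the scenario exercises binding


class TestRunBookkeeping:
    def test_step_and_sample_counts(self):
        p = validate_params({"seed": 1, "t_total": 1.0, "t_burnin": 0.5})
        traj = run(p)
        assert traj.n_steps == 10_000
        assert traj.times.tolist() == [1.0]
        assert traj.ligated_count.shape == (1,)

    def test_deterministic_under_fixed_seed(self, short_params):
        a = run(short_params)
        b = run(short_params)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.events.bind_time, b.events.bind_time)
        assert np.array_equal(a.total_ligated_time, b.total_ligated_time)

    def test_replicates_distinct_and_reproducible(self, short_params):
        reps = run_replicates(short_params, 3, base_seed=40)
        assert [t.seed for t in reps] == [40, 41, 42]
        assert not np.array_equal(reps[0].positions, reps[1].positions)
        again = run_replicates(short_params, 3, base_seed=40)
        for a, b in zip(reps, again):
            assert np.array_equal(a.ligated_count, b.ligated_count)

    def test_event_log_consistency(self, short_params):
        traj = run(short_params)
        ev = traj.events
        assert (np.diff(ev.bind_time) >= 0).all()
        assert (np.diff(ev.rupture_time) >= 0).all()
        assert (ev.rupture_duration > 0).all()
        assert (ev.rupture_tension >= 0).all()
        # every rupture has a matching earlier bind of the same pair
        binds = set(zip(ev.bind_integrin, ev.bind_ligand,
                        np.round(ev.bind_time, 9)))
        for i, j, t, d in zip(ev.rupture_integrin, ev.rupture_ligand,
                              ev.rupture_time, ev.rupture_duration):
            assert (i, j, round(t - d, 9)) in binds

    def test_ligated_time_matches_count_integral(self):
        p = validate_params({"seed": 2, "t_total": 20.0, "t_burnin": 1.0,
                             "sample_interval": 0.1})
        traj = run(p)
        integral = traj.ligated_count.sum() * p.sample_interval
        total = traj.total_ligated_time.sum()
        assert total == pytest.approx(integral, rel=0.05)

    @pytest.mark.parametrize("method", ["kernel", "reference"])
    def test_nonfinite_position_aborts_with_diagnostic(self, method):
        from adhesim.state import initialize
        p = validate_params({"seed": 1, "t_total": 1.0, "t_burnin": 0.5})
        ens, lat = initialize(p)
        ens.positions[0, 0] = np.nan
        with pytest.raises(RuntimeError):
            run(p, method=method, initial=(ens, lat))

    def test_runaway_spring_stays_bounded(self):
        """A spring too stiff for the timestep must not corrupt the domain:
        positions remain wrapped even while the bond oscillates wildly."""
        p = validate_params({"seed": 1, "t_total": 1.0, "t_burnin": 0.5,
                             "k_sub": 1e7, "koff_b1": 1e-30, "koff_b2": 1e-30,
                             **BIND_OFF, **KOFF_OFF})
        initial = frozen_bond_state(p, n_bonds=1, stretch_nm=10.0)
        traj = run(p, initial=initial)
        assert np.isfinite(traj.positions).all()
        assert (traj.positions >= -0.5).all() and (traj.positions < 0.5).all()

    def test_roundtrip_hdf5(self, short_params, tmp_path):
        traj = run(short_params)
        path = str(tmp_path / "t.h5")
        traj.save(path)
        back = Trajectory.load(path)
        assert np.array_equal(back.ligated_count, traj.ligated_count)
        assert np.array_equal(back.events.rupture_tension, traj.events.rupture_tension)
        assert back.params == traj.params


class TestKernelPhysics:
    def test_free_diffusion_coefficient(self):
        """Kernel increments reproduce D = 0.058 um^2/s (binding disabled)."""
        p = validate_params({"seed": 11, "t_total": 5.0, "t_burnin": 1.0,
                             "sample_interval": 0.01, **BIND_OFF})
        traj = run(p)
        d = np.diff(traj.positions.astype(float), axis=0)
        d -= np.round(d)  # unwrap: per-0.01s steps are far below half-domain
        var = np.mean(d ** 2)  # per component
        D = var / (2 * 0.01)
        assert D == pytest.approx(p.D_free, rel=0.03)

    def test_infiber_friction_multiplier_reduces_diffusion(self):
        """S2 variant: 5x friction under a domain-wide fiber gives D/5."""
        p = validate_params({"seed": 11, "t_total": 5.0, "t_burnin": 1.0,
                             "sample_interval": 0.01, "fiber_present": True,
                             "fiber_width": 1000.0,
                             "fiber_friction_multiplier": 5.0, **BIND_OFF})
        traj = run(p)
        d = np.diff(traj.positions.astype(float), axis=0)
        d -= np.round(d)
        D = np.mean(d ** 2) / (2 * 0.01)
        assert D == pytest.approx(p.D_free / 5.0, rel=0.03)

    def test_equipartition_of_permanent_bond(self):
        """Stationary extension variance equals kBT/k per component."""
        p = validate_params({"seed": 7, "dt": 1e-6, "t_total": 1.0,
                             "t_burnin": 0.1, "sample_interval": 1e-3,
                             "k_sub": 0.6, "n_integrins": 4,
                             **KOFF_OFF, **BIND_OFF})
        initial = frozen_bond_state(p, n_bonds=4, stretch_nm=0.0)
        lat = initial[1]
        traj = run(p, initial=initial)
        m = traj.window(0.1, 1.0)
        lig_xy = lat.positions[initial[0].bound_to[:4]]
        ext = (traj.positions[m][:, :4, :].astype(float) - lig_xy) * 1e3  # nm
        var = ext.var(axis=(0, 1)).mean()
        assert var == pytest.approx(p.kBT / p.k_sub, rel=0.10)

    def test_kernel_and_reference_agree_statistically(self):
        """Same model, two implementations: steady ligated % must agree."""
        kw = {"t_total": 4.0, "t_burnin": 2.0, "sample_interval": 0.5,
              "k_sub": 0.6}
        pct = {"kernel": [], "reference": []}
        rate = {"kernel": [], "reference": []}
        for method in pct:
            for seed in (21, 22):
                traj = run(validate_params({"seed": seed, **kw}), method=method)
                m = traj.window()
                pct[method].append(traj.ligated_pct[m].mean())
                ev = traj.events
                rate[method].append(np.count_nonzero(ev.bind_time > 2.0) / 2.0)
        assert np.mean(pct["kernel"]) == pytest.approx(np.mean(pct["reference"]), abs=6.0)
        assert np.mean(rate["kernel"]) == pytest.approx(np.mean(rate["reference"]), rel=0.25)

    def test_actin_flow_leaves_bond_tension_unaffected(self):
        """Imposed retrograde flow up to 100 nm/s does not change the
        rupture-tension distribution (the spring absorbs ~0.01 nm offset)."""
        kw = {"t_total": 40.0, "t_burnin": 10.0, "fiber_present": True,
              "P_bundling": 1.0, "k_sub": 0.6}
        means = {}
        for speed in (0.0, 100.0):
            traj = run(validate_params({"seed": 31, "actin_flow_speed": speed, **kw}))
            w = (traj.params.t_burnin, traj.params.t_total)
            t = traj.events.rupture_tension[traj.events.rupture_time > w[0]]
            means[speed] = t.mean()
        assert means[100.0] == pytest.approx(means[0.0], rel=0.10)
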