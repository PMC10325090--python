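"""Run orchestration: the per-step update loop, sampling, and replicates.

Two execution paths produce statistically equivalent trajectories:

* :func:`step` / ``method='reference'`` -- a readable numpy implementation
  composed directly from the :mod:`mechanics`, :mod:`kinetics` and
  :mod:`fiber` operations, driven by a numpy Generator.  Intended for tests
  and short runs.
* ``method='kernel'`` (default) -- the compiled loop in
  :mod:`adhesim._kernel`, ~two orders of magnitude faster, driven by the
  package's xoshiro/ziggurat stream.

Within one step the update order is: (1) resolve per-integrin friction and
binding rate, (2) assemble forces (thermal for everyone; spring and myosin
for ligated integrins in scope), (3) explicit-Euler move and wrap (plus the
optional actin-flow shift), (4) unbinding attempts, (5) binding attempts,
(6) ligated-time accounting.  Sampling records the instantaneous state every
``sample_interval`` (1 s by default); burn-in is a marker used by the
analysis window, not a data deletion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel, _rng
from .fiber import (actin_flow_shift, effective_kon, friction_for, in_fiber,
                    myosin_force, region_from_params)
from .kinetics import attempt_binding, attempt_unbinding, koff, p_event
from .mechanics import minimum_image, thermal_force, thermal_force_std, wrap_positions
from .params import ModelParams, validate_params
from .state import FREE, EventLog, IntegrinEnsemble, LigandLattice, initialize

__all__ = ["SimState", "new_state", "step", "run", "run_replicates", "Trajectory"]


@dataclass
class SimState:
    """Mutable state of an in-progress reference-path simulation."""

    params: ModelParams
    t: float
    ensemble: IntegrinEnsemble
    lattice: LigandLattice
    rng: np.random.Generator
    bind_events: list
    rupture_events: list


def new_state(params: ModelParams, initial=None) -> SimState:
    ens, lat = initialize(params) if initial is None else \
        (initial[0].copy(), initial[1].copy())
    # dynamics stream is separate from the initial-position stream
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed,
                                                       spawn_key=(1,)))
    return SimState(params, 0.0, ens, lat, rng, [], [])


def step(state: SimState) -> SimState:
    """Advance the reference-path state by one timestep ``dt`` in place."""
    p = state.params
    ens, lat = state.ensemble, state.lattice
    region = region_from_params(p)
    t_next = state.t + p.dt

    # (1) per-integrin friction and binding rate
    zeta = friction_for(ens, region, p)
    kon = effective_kon(ens, region, p.P_bundling, p, state.rng)

    # (2) forces: thermal everywhere (std follows the local friction, per
    # fluctuation-dissipation), spring + myosin on ligated integrins
    forces = thermal_force(ens.n, p, state.rng) * np.sqrt(zeta / p.zeta)[:, None]
    bound = np.flatnonzero(ens.ligated)
    if bound.size:
        d = minimum_image(lat.positions[ens.bound_to[bound]] - ens.positions[bound],
                          p.domain_side)
        sep = np.linalg.norm(d, axis=1)
        dL_nm = sep * 1e3 - p.L0
        ok = dL_nm > 0
        mag = np.where(ok, p.k_sub * dL_nm, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(sep[:, None] > 0, d / np.where(sep[:, None] == 0, 1, sep[:, None]), 0.0)
        forces[bound] += unit * mag[:, None]
    forces += myosin_force(ens, region, p)

    # (3) Euler move, actin-flow shift (membership on pre-move position), wrap
    flow = actin_flow_shift(ens, region, p)
    disp = forces / zeta[:, None] * p.dt
    ens.positions = wrap_positions(ens.positions + disp + flow, p.domain_side)
    if not np.isfinite(ens.positions).all():
        raise RuntimeError(f"non-finite integrin position at t={t_next:.6f}s")

    # (4) unbinding, (5) binding
    state.rupture_events += attempt_unbinding(ens, lat, p, state.rng, t_next)
    state.bind_events += attempt_binding(ens, lat, kon, p, state.rng, t_next)

    # (6) ligated-time accounting
    ens.total_ligated_time[ens.ligated] += p.dt
    state.t = t_next
    return state


@dataclass
class Trajectory:
    """Sampled output of one run.

    ``times`` are the whole-``sample_interval`` instants (burn-in included);
    ``positions``/``bound_mask`` are instantaneous snapshots at those times.
    ``total_ligated_time`` sums each integrin's bond lifetimes over the whole
    run, with bonds still closed at ``t_total`` contributing their elapsed
    time.
    """

    params: ModelParams
    seed: int
    method: str
    times: np.ndarray               # (k,) s
    ligated_count: np.ndarray       # (k,) int
    bound_mask: np.ndarray          # (k, n) bool
    positions: np.ndarray           # (k, n, 2) float32, um
    total_ligated_time: np.ndarray  # (n,) s
    events: EventLog
    n_steps: int

    @property
    def ligated_pct(self) -> np.ndarray:
        return 100.0 * self.ligated_count / self.params.n_integrins

    def window(self, t_start: float | None = None, t_end: float | None = None) -> np.ndarray:
        """Boolean mask over samples for an analysis window (defaults:
        burn-in to end of run)."""
        t0 = self.params.t_burnin if t_start is None else t_start
        t1 = self.params.t_total if t_end is None else t_end
        return (self.times > t0) & (self.times <= t1)

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times,
                             "ligated_count": self.ligated_count,
                             "ligated_pct": self.ligated_pct})

    def events_frame(self) -> pd.DataFrame:
        return self.events.to_frame()

    # -- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        """Persist to HDF5 (datasets for samples and events, params echo)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["params_json"] = json.dumps(self.params.asdict())
            f.attrs["seed"] = self.seed
            f.attrs["method"] = self.method
            f.attrs["n_steps"] = self.n_steps
            g = f.create_group("samples")
            g.create_dataset("times", data=self.times)
            g.create_dataset("ligated_count", data=self.ligated_count)
            g.create_dataset("bound_mask", data=self.bound_mask)
            g.create_dataset("positions", data=self.positions)
            f.create_dataset("total_ligated_time", data=self.total_ligated_time)
            e = f.create_group("events")
            for name in ("bind_time", "bind_integrin", "bind_ligand",
                         "rupture_time", "rupture_integrin", "rupture_ligand",
                         "rupture_tension", "rupture_duration"):
                e.create_dataset(name, data=getattr(self.events, name))

    @classmethod
    def load(cls, path: str) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            params = validate_params(json.loads(f.attrs["params_json"]))
            ev = EventLog(**{k: f["events"][k][...] for k in
                             ("bind_time", "bind_integrin", "bind_ligand",
                              "rupture_time", "rupture_integrin", "rupture_ligand",
                              "rupture_tension", "rupture_duration")})
            return cls(params=params, seed=int(f.attrs["seed"]),
                       method=str(f.attrs["method"]),
                       times=f["samples"]["times"][...],
                       ligated_count=f["samples"]["ligated_count"][...],
                       bound_mask=f["samples"]["bound_mask"][...].astype(bool),
                       positions=f["samples"]["positions"][...],
                       total_ligated_time=f["total_ligated_time"][...],
                       events=ev, n_steps=int(f.attrs["n_steps"]))

    def export_csv(self, samples_path: str, events_path: str | None = None) -> None:
        self.samples_frame().to_csv(samples_path, index=False)
        if events_path:
            self.events_frame().to_csv(events_path, index=False)


def _ligated_time_from_events(events: EventLog, bound_to: np.ndarray,
                              bond_start: np.ndarray, t_end: float, n: int) -> np.ndarray:
    tot = np.zeros(n)
    np.add.at(tot, events.rupture_integrin, events.rupture_duration)
    open_bonds = bound_to != FREE
    tot[open_bonds] += t_end - bond_start[open_bonds]
    return tot


def _run_reference(params: ModelParams, initial=None) -> Trajectory:
    state = new_state(params, initial)
    every = params.sample_every
    k = params.n_steps // every
    times = np.empty(k)
    counts = np.empty(k, dtype=np.int64)
    mask = np.zeros((k, params.n_integrins), dtype=bool)
    snaps = np.zeros((k, params.n_integrins, 2), dtype=np.float32)
    s = 0
    for istep in range(params.n_steps):
        step(state)
        if (istep + 1) % every == 0:
            times[s] = state.t
            counts[s] = state.ensemble.n_ligated
            mask[s] = state.ensemble.ligated
            snaps[s] = state.ensemble.positions
            s += 1
    events = EventLog.from_lists(state.bind_events, state.rupture_events)
    tot = _ligated_time_from_events(events, state.ensemble.bound_to,
                                    state.ensemble.bond_start_time,
                                    params.t_total, params.n_integrins)
    return Trajectory(params=params, seed=params.seed, method="reference",
                      times=times, ligated_count=counts, bound_mask=mask,
                      positions=snaps, total_ligated_time=tot,
                      events=events, n_steps=params.n_steps)


def _run_kernel(params: ModelParams, initial=None) -> Trajectory:
    p = params
    ens, lat = initialize(p) if initial is None else \
        (initial[0].copy(), initial[1].copy())
    pos = ens.positions.copy()
    bound_to = ens.bound_to.copy()
    bond_start = ens.bond_start_time.copy()
    occ = lat.occupied_by.copy()

    n_steps = p.n_steps
    every = p.sample_every
    k = n_steps // every
    samp_count = np.zeros(k, dtype=np.int64)
    samp_bound = np.zeros((k, p.n_integrins), dtype=np.uint8)
    samp_pos = np.zeros((k, p.n_integrins, 2), dtype=np.float32)

    kon_max = max(p.kon_base, p.kon_fiber if (p.fiber_present and p.P_bundling > 0) else p.kon_base)
    cap = int(p.n_integrins * kon_max * p.t_total) + 20000
    bind_t = np.empty(cap)
    bind_i = np.empty(cap, dtype=np.int32)
    bind_j = np.empty(cap, dtype=np.int32)
    rup_t = np.empty(cap)
    rup_i = np.empty(cap, dtype=np.int32)
    rup_j = np.empty(cap, dtype=np.int32)
    rup_T = np.empty(cap)
    rup_dur = np.empty(cap)

    # thinning bound for unbinding: koff is convex, so on [0, T_thin] it is
    # bounded by its endpoint values; pick the widest T_thin with a bound
    # within 20% of the zero-force rate
    k0 = koff(0.0, law=_law(p))
    T_thin = 0.0
    for T in np.linspace(0.0, 200.0, 2001):
        if koff(float(T), law=_law(p)) <= 1.2 * k0:
            T_thin = float(T)
    p_off_cap = p_event(1.3 * k0, p.dt)  # margin over the 1.2 selection factor

    p_on_base = p_event(p.kon_base, p.dt)
    p_on_fiber = p_event(p.kon_fiber, p.dt)
    fiber_on = bool(p.fiber_present)
    p_bind_cap = max(p_on_base, p_on_fiber) if (fiber_on and p.P_bundling > 0) else p_on_base

    status, nb, nr, n_samp = _kernel.simulate(
        pos, bound_to, bond_start,
        lat.positions, occ, p.ligand_rows, p.ligand_spacing * 1e-3,
        p.domain_side, p.dt, n_steps, every,
        thermal_force_std(p),
        thermal_force_std(p) * np.sqrt(p.fiber_friction_multiplier),
        p.dt / p.zeta,
        p.dt / (p.zeta * p.fiber_friction_multiplier), p.dt / p.zeta,
        p.k_sub * 1e3, p.L0 * 1e-3, p.r_bind * 1e-3,
        p_on_base, p_on_fiber, p_bind_cap,
        p.koff_a1, p.koff_b1, p.koff_a2, p.koff_b2, T_thin, p_off_cap,
        fiber_on, (p.fiber_width * 1e-3 / 2.0) if fiber_on else -1.0, 0.0,
        p.myo_scope == "global", p.F_myo,
        p.actin_flow_speed * 1e-3 * p.dt, p.P_bundling,
        p.seed, _rng.ZIG_KN, _rng.ZIG_WN, _rng.ZIG_FN,
        samp_count, samp_bound, samp_pos,
        bind_t, bind_i, bind_j,
        rup_t, rup_i, rup_j, rup_T, rup_dur,
    )
    # authoritative finiteness check in numpy: inside the fastmath-compiled
    # kernel a NaN test can be folded away (the in-kernel check is only a
    # best-effort early abort)
    if status == 1 or not np.isfinite(samp_pos[:n_samp]).all() \
            or not np.isfinite(pos).all():
        raise RuntimeError("non-finite integrin position encountered; "
                           "the integration became unstable")
    if status == 2:
        raise RuntimeError("event capacity exceeded")

    events = EventLog(
        bind_time=bind_t[:nb].copy(), bind_integrin=bind_i[:nb].astype(np.int64),
        bind_ligand=bind_j[:nb].astype(np.int64),
        rupture_time=rup_t[:nr].copy(), rupture_integrin=rup_i[:nr].astype(np.int64),
        rupture_ligand=rup_j[:nr].astype(np.int64),
        rupture_tension=rup_T[:nr].copy(), rupture_duration=rup_dur[:nr].copy(),
    )
    tot = _ligated_time_from_events(events, bound_to, bond_start,
                                    p.t_total, p.n_integrins)
    times = (1 + np.arange(k)) * p.sample_interval
    return Trajectory(params=p, seed=p.seed, method="kernel",
                      times=times, ligated_count=samp_count,
                      bound_mask=samp_bound.astype(bool), positions=samp_pos,
                      total_ligated_time=tot, events=events, n_steps=n_steps)


def _law(p: ModelParams):
    from .kinetics import CatchSlipLaw
    return CatchSlipLaw.from_params(p)


def run(params: ModelParams, method: str = "kernel", initial=None) -> Trajectory:
    """Execute a full run and return its :class:`Trajectory`.

    The trajectory is a pure function of ``(params, method)``: rerunning with
    the same seed reproduces it bit for bit.  ``initial`` optionally supplies
    an (ensemble, lattice) pair to start from instead of the seeded uniform
    free state -- used by fixtures that pre-form bonds.
    """
    if method == "kernel":
        return _run_kernel(params, initial)
    if method == "reference":
        return _run_reference(params, initial)
    raise ValueError(f"unknown method {method!r}")


def run_replicates(params: ModelParams, n_reps: int,
                   base_seed: int | None = None,
                   method: str = "kernel") -> list[Trajectory]:
    """Independent replicate runs with seeds base_seed .. base_seed+n_reps-1."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = params.seed if base_seed is None else base_seed
    return [run(params.replace(seed=base + r), method=method) for r in range(n_reps)]
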