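"""Stochastic integrin-ligand binding and catch-slip rupture.

Binding: a free integrin within the capture radius (20 nm, the scale of the
extended integrin headpiece) of at least one free ligand binds during a
timestep with probability 1 - exp(-kon dt), pairing with the nearest free
ligand.  Unbinding: each bond ruptures with probability 1 - exp(-koff(F) dt),
where F = |k_sub * dL| is the spring tension and koff follows a two-pathway
(catch + slip) force dependence

    koff(F) = a1 exp(-b1 F) + a2 exp(+b2 F),

whose lifetime 1/koff peaks at F* = ln(a1 b1 / (a2 b2)) / (b1 + b2)
(~30 pN at the default coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import minimum_image
from .params import ModelParams
from .state import FREE, EventLog, IntegrinEnsemble, LigandLattice

__all__ = ["CatchSlipLaw", "koff", "p_event", "optimum_force",
           "attempt_binding", "attempt_unbinding", "bond_tensions"]


@dataclass(frozen=True)
class CatchSlipLaw:
    """Coefficients of the two-exponential rupture rate."""

    a1: float = 2.0     # 1/s
    b1: float = 0.1     # 1/pN
    a2: float = 4e-6    # 1/s
    b2: float = 0.3     # 1/pN

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0:
            raise ValueError("catch-slip coefficients must be strictly positive")

    @classmethod
    def from_params(cls, params: ModelParams) -> "CatchSlipLaw":
        return cls(params.koff_a1, params.koff_b1, params.koff_a2, params.koff_b2)


def koff(F, law: CatchSlipLaw = CatchSlipLaw()):
    """Rupture rate (1/s) at bond tension ``F`` (pN, magnitude)."""
    F = np.asarray(F, dtype=float)
    out = law.a1 * np.exp(-law.b1 * F) + law.a2 * np.exp(law.b2 * F)
    return float(out) if out.ndim == 0 else out


def optimum_force(law: CatchSlipLaw = CatchSlipLaw()) -> float:
    """Tension (pN) minimising koff, i.e. maximising the bond lifetime."""
    return float(np.log(law.a1 * law.b1 / (law.a2 * law.b2)) / (law.b1 + law.b2))


def p_event(rate, dt: float):
    """Per-step probability of a Poisson event: 1 - exp(-rate*dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    out = -np.expm1(-rate * dt)
    return float(out) if out.ndim == 0 else out


def bond_tensions(ensemble: IntegrinEnsemble, lattice: LigandLattice,
                  params: ModelParams) -> np.ndarray:
    """Spring tension |k_sub * dL| (pN) for every integrin; 0 for free ones."""
    tension = np.zeros(ensemble.n)
    bound = ensemble.ligated
    if bound.any():
        idx = np.flatnonzero(bound)
        lig = lattice.positions[ensemble.bound_to[idx]]
        d = minimum_image(ensemble.positions[idx] - lig, params.domain_side)
        sep_nm = np.linalg.norm(d, axis=1) * 1e3
        tension[idx] = params.k_sub * np.abs(sep_nm - params.L0)
    return tension


def _nearest_free_ligand(pos: np.ndarray, lattice: LigandLattice,
                         params: ModelParams) -> tuple[int, float]:
    """(ligand index, separation nm) of the nearest unoccupied ligand,
    minimum-image metric; (-1, inf) when none exists."""
    free = lattice.occupied_by == FREE
    if not free.any():
        return -1, np.inf
    idx = np.flatnonzero(free)
    d = minimum_image(lattice.positions[idx] - pos, params.domain_side)
    sep = np.linalg.norm(d, axis=1) * 1e3
    k = int(np.argmin(sep))
    return int(idx[k]), float(sep[k])


def attempt_binding(ensemble: IntegrinEnsemble, lattice: LigandLattice,
                    per_integrin_kon: np.ndarray, params: ModelParams,
                    rng: np.random.Generator, t: float) -> list[tuple]:
    """One binding sweep over all free integrins; mutates the state in place.

    Integrins are visited in random order so that contention for a ligand is
    resolved without positional bias.  A free integrin whose nearest free
    ligand lies closer than the capture radius binds it with probability
    p_event(kon_i, dt); the bond forms at the current separation (the spring
    subsequently pulls the integrin in).  Returns the new (t, integrin,
    ligand) bind events.

    One uniform is drawn per free integrin (in visit order) and the partner
    search runs only when it falls below the per-step binding probability --
    an exact thinning of the rare event.
    """
    new_events: list[tuple] = []
    order = rng.permutation(ensemble.n)
    free = order[ensemble.bound_to[order] == FREE]
    if free.size == 0:
        return new_events
    u = rng.random(free.size)
    hits = u < p_event(per_integrin_kon[free], params.dt)
    for i in free[hits]:
        j, sep = _nearest_free_ligand(ensemble.positions[i], lattice, params)
        if j < 0 or sep >= params.r_bind:
            continue
        ensemble.bound_to[i] = j
        lattice.occupied_by[j] = i
        ensemble.bond_start_time[i] = t
        new_events.append((t, int(i), j))
    return new_events


def attempt_unbinding(ensemble: IntegrinEnsemble, lattice: LigandLattice,
                      params: ModelParams, rng: np.random.Generator, t: float,
                      law: CatchSlipLaw | None = None) -> list[tuple]:
    """One rupture sweep over all bonds; mutates the state in place.

    Each bond ruptures with probability p_event(koff(F), dt) at its current
    spring tension F.  Returns the new (t, integrin, ligand, tension,
    duration) rupture events; ruptured integrins become diffusive again.
    """
    law = law or CatchSlipLaw.from_params(params)
    tension = bond_tensions(ensemble, lattice, params)
    bound = np.flatnonzero(ensemble.ligated)
    new_events: list[tuple] = []
    if bound.size == 0:
        return new_events
    p = p_event(koff(tension[bound], law), params.dt)
    ruptured = bound[rng.random(bound.size) < p]
    for i in ruptured:
        j = int(ensemble.bound_to[i])
        duration = t - float(ensemble.bond_start_time[i])
        lattice.occupied_by[j] = FREE
        ensemble.bound_to[i] = FREE
        ensemble.bond_start_time[i] = np.nan
        new_events.append((t, int(i), j, float(tension[i]), duration))
    return new_events
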