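"""Independent brute-force oracles and deterministic fixtures for the suite.

Everything here is deliberately implemented without reusing the package's
force/kinetics code paths, so that agreement between an oracle and the
simulator is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np

from adhesim.params import ModelParams
from adhesim.state import FREE, IntegrinEnsemble, LigandLattice, initialize


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def msd_oracle(tracks: np.ndarray, lag_times: np.ndarray) -> tuple[np.ndarray, float]:
    """MSD curve from unwrapped particle tracks and the implied D estimate.

    ``tracks``: (n_times, n_particles, 2) unwrapped positions at uniform
    spacing.  Returns (msd per lag, D from a least-squares fit of
    MSD = 4 D t through the origin).
    """
    n_t = tracks.shape[0]
    msd = np.empty(lag_times.size)
    steps = np.rint(lag_times / lag_times[0]).astype(int)  # uniform lag grid
    for k, m in enumerate(steps):
        d = tracks[m:] - tracks[:n_t - m]
        msd[k] = np.mean(np.sum(d * d, axis=-1))
    # least-squares fit of MSD = 4 D t through the origin
    D = float(np.sum(lag_times * msd) / (4.0 * np.sum(lag_times ** 2)))
    return msd, D


def catch_slip_rate(F: float, a1=2.0, b1=0.1, a2=4e-6, b2=0.3) -> float:
    """The two-pathway rupture rate, written out independently."""
    return a1 * np.exp(-b1 * F) + a2 * np.exp(b2 * F)


def single_bond_lifetime_oracle(F: float, n_samples: int, dt: float,
                                rng: np.random.Generator) -> dict[str, float]:
    """Mean single-bond lifetime at clamped force from three routes.

    * analytic: 1/koff(F)
    * gillespie: exponential waiting times at constant rate
    * bernoulli: the fixed-timestep scheme (geometric number of steps with
      per-step probability 1 - exp(-koff dt)); its mean exceeds the analytic
      value by ~dt/2 (discretisation bound: 2 dt).
    """
    rate = catch_slip_rate(F)
    analytic = 1.0 / rate
    gillespie = float(rng.exponential(analytic, n_samples).mean())
    p = -np.expm1(-rate * dt)
    bernoulli = float(rng.geometric(p, n_samples).mean() * dt)
    return {"analytic": analytic, "gillespie": gillespie, "bernoulli": bernoulli}


def equipartition_variance(extensions: np.ndarray) -> float:
    """Per-component variance (nm^2) of sampled bond extension components."""
    return float(np.var(extensions))


def principal_angle_bruteforce(points: np.ndarray, n_grid: int = 36_000) -> float:
    """Orientation of the leading principal axis by exhaustive search.

    Scans directions in [0, pi), returns the acute angle (degrees) to the
    x axis of the direction maximising the variance of the projections.
    Independent of any eigen-decomposition.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts - pts.mean(axis=0)
    thetas = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    proj = pts[:, 0, None] * np.cos(thetas) + pts[:, 1, None] * np.sin(thetas)
    best = thetas[np.argmax(proj.var(axis=0))]
    ang = np.degrees(best)
    return min(ang, 180.0 - ang)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def frozen_bond_state(params: ModelParams, n_bonds: int,
                      stretch_nm: float = 0.0) -> tuple[IntegrinEnsemble, LigandLattice]:
    """State with ``n_bonds`` pre-formed bonds on distinct ligands.

    Each bound integrin sits ``stretch_nm`` along +x from its ligand; the
    remaining integrins stay where the seeded initialiser put them.
    """
    ens, lat = initialize(params)
    if n_bonds > min(params.n_integrins, params.n_ligands):
        raise ValueError("too many bonds requested")
    # spread bonds over interior ligands so images never interact
    rows = params.ligand_rows
    interior = [iy * rows + ix
                for iy in range(2, rows - 2) for ix in range(2, rows - 2)]
    lig_idx = np.asarray(interior[:n_bonds], dtype=np.int64)
    for b, j in enumerate(lig_idx):
        ens.bound_to[b] = j
        lat.occupied_by[j] = b
        ens.bond_start_time[b] = 0.0
        ens.positions[b] = lat.positions[j] + np.array([stretch_nm * 1e-3, 0.0])
    return ens, lat


def single_pair_state(params: ModelParams,
                      offset_nm: tuple[float, float] = (0.0, 0.0),
                      bound: bool = True) -> tuple[IntegrinEnsemble, LigandLattice]:
    """One integrin near the central ligand (bound or free)."""
    ens, lat = initialize(params)
    rows = params.ligand_rows
    j = (rows // 2) * rows + rows // 2
    ens.positions[0] = lat.positions[j] + np.array(offset_nm) * 1e-3
    if bound:
        ens.bound_to[0] = j
        lat.occupied_by[j] = 0
        ens.bond_start_time[0] = 0.0
    return ens, lat
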