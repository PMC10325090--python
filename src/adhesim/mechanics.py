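"""Forces and overdamped Langevin motion.

The equation of motion is the high-friction limit of the Langevin equation,

    dr_i = (F_i / zeta_i) dt,      F_i = F_T + F_sub + F_myo,

integrated with an explicit Euler scheme on a periodic square domain.  The
thermal force F_T satisfies the fluctuation-dissipation theorem: each
component is Gaussian with zero mean and standard deviation
sqrt(2 kBT zeta / dt), so the induced per-step displacement has standard
deviation sqrt(2 D dt) (~3.4 nm at the default parameters).  The substrate
force is a Hookean restoring force of the integrin-ligand bond, F_sub =
k_sub * dL toward the ligand, with dL the deviation of the minimum-image
separation from the bond rest length L0.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = ["minimum_image", "thermal_force", "thermal_force_std",
           "bond_extension", "spring_force", "euler_step", "wrap_positions"]


def minimum_image(delta: np.ndarray, side: float) -> np.ndarray:
    """Map separation components into [-side/2, +side/2), preserving congruence
    modulo ``side``."""
    if side <= 0:
        raise ValueError("side must be positive")
    delta = np.asarray(delta, dtype=float)
    return (delta + side / 2.0) % side - side / 2.0


def thermal_force_std(params: ModelParams) -> float:
    """Std of each thermal-force component, pN: sqrt(2 kBT zeta / dt)."""
    return float(np.sqrt(2.0 * params.kBT * 1e-3 * params.zeta / params.dt))


def thermal_force(n: int, params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) array of i.i.d. Gaussian thermal forces, pN."""
    return rng.standard_normal((n, 2)) * thermal_force_std(params)


def bond_extension(ri: np.ndarray, rj: np.ndarray, L0: float, side: float) -> np.ndarray:
    """Signed bond extension dL in nm.

    ``ri``/``rj`` are integrin/ligand positions in um (single pair or (n, 2)
    arrays).  dL = (minimum-image Euclidean separation) - L0; negative when
    the pair is closer than the rest length.
    """
    d = minimum_image(np.asarray(ri, float) - np.asarray(rj, float), side)
    sep_nm = np.linalg.norm(np.atleast_2d(d), axis=1) * 1e3
    out = sep_nm - L0
    return out if np.asarray(ri).ndim > 1 else float(out[0])


def spring_force(dL: float, k_sub: float, unit_vector_to_ligand: np.ndarray) -> np.ndarray:
    """Restoring force of the bond, pN, directed toward the ligand.

    Magnitude k_sub * dL for positive extension.  For dL <= 0 (separation
    below the rest length) the force is zero: the per-axis force law divides
    by dL, and with L0 = 0.01 nm this sub-resthlength configuration is a
    measure-zero case best treated as force-free rather than singular.
    """
    dL = np.asarray(dL, dtype=float)
    u = np.asarray(unit_vector_to_ligand, dtype=float)
    mag = k_sub * np.where(dL > 0.0, dL, 0.0)
    return (u.T * mag).T


def wrap_positions(positions: np.ndarray, side: float) -> np.ndarray:
    """Wrap positions into [-side/2, +side/2) per component."""
    return (positions + side / 2.0) % side - side / 2.0


def euler_step(positions: np.ndarray, forces: np.ndarray, params: ModelParams,
               zeta: np.ndarray | float | None = None) -> np.ndarray:
    """Advance positions by F/zeta*dt and wrap into the periodic domain.

    ``zeta`` may be a per-integrin array (pN s/um) to account for reduced
    in-fiber mobility; it defaults to the uniform value in ``params``.
    Forces are in pN; the displacement F/zeta*dt comes out in um.
    """
    if zeta is None:
        zeta = params.zeta
    zeta = np.asarray(zeta, dtype=float)
    disp = forces / (zeta[..., None] if zeta.ndim else zeta) * params.dt
    return wrap_positions(positions + disp, params.domain_side)
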