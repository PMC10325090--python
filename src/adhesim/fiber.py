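"""The actin fiber: a strip of the domain with locally modified integrin dynamics.

The fiber is not a mechanical object; it is a 300-nm-wide strip (centred on
the domain's x axis by default) inside which three local effects can act:

* bundling-enhanced activation -- free integrins under the fiber draw, each
  step, an enhanced binding rate kon_fiber (default 3/s instead of 1/s) with
  probability P_bundling, mimicking talin-mediated inside-out activation;
* actomyosin contractility -- ligated integrins inside the strip are loaded
  with a constant force F_myo along the fiber axis (+x).  A ``global`` scope
  applies the same load to every ligated integrin regardless of position,
  for experiments on contractility without a fiber template;
* optional variants: a friction multiplier for free in-fiber integrins
  (directed/slowed motion under the fiber) and an imposed retrograde actin
  flow displacing ligated in-fiber integrins along +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .state import IntegrinEnsemble

__all__ = ["FiberRegion", "in_fiber", "effective_kon", "myosin_force",
           "actin_flow_shift", "friction_for", "region_from_params"]


@dataclass(frozen=True)
class FiberRegion:
    """Strip geometry: fixed axis along x, transverse extent ``width`` nm."""

    width: float                 # nm
    center_offset: float = 0.0   # um, transverse offset of the strip centre

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("fiber width must be positive")

    @property
    def axis(self) -> np.ndarray:
        return np.array([1.0, 0.0])

    @property
    def half_width_um(self) -> float:
        return self.width * 1e-3 / 2.0


def region_from_params(params: ModelParams) -> FiberRegion | None:
    """The configured fiber region, or None when no fiber is present."""
    return FiberRegion(params.fiber_width) if params.fiber_present else None


def in_fiber(position: np.ndarray, region: FiberRegion | None) -> np.ndarray | bool:
    """Strip membership (boundary inclusive) of wrapped position(s)."""
    if region is None:
        pos = np.asarray(position, dtype=float)
        return np.zeros(pos.shape[0], bool) if pos.ndim > 1 else False
    pos = np.asarray(position, dtype=float)
    y = pos[..., 1]
    out = np.abs(y - region.center_offset) <= region.half_width_um
    return bool(out) if out.ndim == 0 else out


def effective_kon(ensemble: IntegrinEnsemble, region: FiberRegion | None,
                  P_bundling: float, params: ModelParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-integrin activation/binding rate (1/s) for the current step.

    Free integrins under the fiber draw the enhanced rate with probability
    ``P_bundling`` -- a fresh Bernoulli draw per integrin per step, so the
    expected enhanced fraction equals P_bundling with no persistent state.
    Everyone else keeps the baseline rate.  The draw outcome is recorded in
    ``ensemble.enhanced_kon``.
    """
    rates = np.full(ensemble.n, params.kon_base)
    ensemble.enhanced_kon[:] = False
    if region is None or P_bundling <= 0:
        return rates
    eligible = in_fiber(ensemble.positions, region) & ~ensemble.ligated
    if eligible.any():
        draws = rng.random(int(eligible.sum())) < P_bundling
        idx = np.flatnonzero(eligible)[draws]
        rates[idx] = params.kon_fiber
        ensemble.enhanced_kon[idx] = True
    return rates


def myosin_force(ensemble: IntegrinEnsemble, region: FiberRegion | None,
                 params: ModelParams) -> np.ndarray:
    """(n, 2) actomyosin load, pN: F_myo along +x on ligated integrins in scope.

    Scope is the fiber strip for ``myo_scope='fiber_only'`` and the whole
    domain for ``'global'``; free integrins are never loaded.
    """
    out = np.zeros((ensemble.n, 2))
    if params.F_myo <= 0:
        return out
    if params.myo_scope == "global":
        scope = ensemble.ligated
    else:
        scope = ensemble.ligated & np.asarray(in_fiber(ensemble.positions, region))
    out[scope, 0] = params.F_myo
    return out


def actin_flow_shift(ensemble: IntegrinEnsemble, region: FiberRegion | None,
                     params: ModelParams) -> np.ndarray:
    """(n, 2) per-step displacement (um) from imposed actin flow.

    Ligated integrins under the fiber advect by flow_speed*dt along +x;
    the default speed of 0 disables the feature.
    """
    out = np.zeros((ensemble.n, 2))
    if params.actin_flow_speed <= 0 or region is None:
        return out
    scope = ensemble.ligated & np.asarray(in_fiber(ensemble.positions, region))
    out[scope, 0] = params.actin_flow_speed * 1e-3 * params.dt
    return out


def friction_for(ensemble: IntegrinEnsemble, region: FiberRegion | None,
                 params: ModelParams) -> np.ndarray:
    """Per-integrin friction coefficient, pN s/um.

    Free integrins under the fiber feel zeta * fiber_friction_multiplier
    (the reduced-mobility variant); everyone else the baseline zeta.
    """
    zeta = np.full(ensemble.n, params.zeta)
    if region is not None and params.fiber_friction_multiplier != 1.0:
        slow = np.asarray(in_fiber(ensemble.positions, region)) & ~ensemble.ligated
        zeta[slow] *= params.fiber_friction_multiplier
    return zeta
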