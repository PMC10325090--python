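"""Model parameters: the complete description of one simulation condition.

Every physical constant of the model lives in :class:`ModelParams`.  The
defaults describe the reference condition: a 1 um^2 patch of membrane with 300
mobile integrins over a 21x21 lattice of immobilised ligands spaced 50 nm
apart, integrin diffusion D = 0.058 um^2/s at kBT = 4.11 pN nm (so the
friction coefficient from the Einstein relation is ~0.071 pN s/um), a harmonic
integrin-ligand bond whose spring constant stands in for substrate stiffness,
and two-pathway catch-slip rupture kinetics with maximum bond lifetime near
30 pN.

Unit conventions (kept as the quantities are usually quoted, converted
internally where needed):

====================  =========================
lengths (domain)      um
lengths (bond scale)  nm  (L0, r_bind, spacing, fiber_width)
time                  s
energy                pN nm
force                 pN
stiffness             pN/nm
friction              pN s/um
rates                 1/s
====================  =========================
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = ["ModelParams", "ParameterError", "validate_params", "load_params"]


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


_MYO_SCOPES = ("fiber_only", "global")


@dataclass(frozen=True)
class ModelParams:
    """Validated parameter set of one simulation condition.

    Build instances through :func:`validate_params`, which fills in derived
    quantities (the friction coefficient) and checks every invariant.
    """

    seed: int

    # geometry
    domain_side: float = 1.0          # um
    n_integrins: int = 300
    ligand_rows: int = 21             # lattice vertices per side -> 441 ligands
    ligand_spacing: float = 50.0      # nm

    # integration / sampling
    dt: float = 1e-4                  # s
    t_total: float = 300.0            # s
    t_burnin: float = 100.0           # s; default analysis window starts here
    sample_interval: float = 1.0      # s

    # thermal / mobility
    kBT: float = 4.11                 # pN nm
    D_free: float = 0.058             # um^2/s
    zeta: float | None = None         # pN s/um; derived from kBT/D_free

    # bond mechanics
    k_sub: float = 0.6                # pN/nm (substrate stiffness)
    L0: float = 0.01                  # nm (bond equilibrium length)
    r_bind: float = 20.0              # nm (capture radius)

    # kinetics
    kon_base: float = 1.0             # 1/s
    kon_fiber: float = 3.0            # 1/s (bundling-enhanced activation)
    koff_a1: float = 2.0              # 1/s   catch amplitude
    koff_b1: float = 0.1              # 1/pN  catch exponent
    koff_a2: float = 4e-6             # 1/s   slip amplitude
    koff_b2: float = 0.3              # 1/pN  slip exponent

    # actin fiber
    fiber_present: bool = False
    fiber_width: float = 300.0        # nm
    F_myo: float = 0.0                # pN
    myo_scope: str = "fiber_only"     # where contractile load applies
    P_bundling: float = 0.0
    fiber_friction_multiplier: float = 1.0
    actin_flow_speed: float = 0.0     # nm/s

    # ------------------------------------------------------------------
    @property
    def n_ligands(self) -> int:
        return self.ligand_rows * self.ligand_rows

    @property
    def zeta_einstein(self) -> float:
        """Friction from the Einstein relation, kBT/D, in pN s/um."""
        return (self.kBT * 1e-3) / self.D_free

    @property
    def n_steps(self) -> int:
        return round(self.t_total / self.dt)

    @property
    def sample_every(self) -> int:
        return round(self.sample_interval / self.dt)

    def replace(self, **changes: Any) -> "ModelParams":
        """Validated copy with fields replaced."""
        raw = dataclasses.asdict(self)
        if "kBT" in changes or "D_free" in changes:
            raw["zeta"] = None  # re-derive unless explicitly overridden
        raw.update(changes)
        return validate_params(raw)

    def asdict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def validate_params(raw: Mapping[str, Any] | ModelParams | None = None,
                    **overrides: Any) -> ModelParams:
    """Build a fully validated :class:`ModelParams` from a key/value mapping.

    ``raw`` must supply at least ``seed``; any field not given keeps its
    default.  The friction coefficient ``zeta`` is derived from the Einstein
    relation unless explicitly provided, in which case it must agree with
    kBT/D_free to within 2%.
    """
    if isinstance(raw, ModelParams):
        data = raw.asdict()
    else:
        data = dict(raw) if raw is not None else {}
    data.update(overrides)

    unknown = set(data) - {f.name for f in dataclasses.fields(ModelParams)}
    _require(not unknown, f"unknown parameter(s): {sorted(unknown)}")
    _require("seed" in data, "a seed is required")

    p = ModelParams(**data)

    _require(int(p.seed) == p.seed and p.seed >= 0, "seed must be a non-negative integer")

    for name in ("domain_side", "ligand_spacing", "dt", "t_total",
                 "sample_interval", "D_free", "k_sub", "L0", "r_bind",
                 "kon_base", "kon_fiber", "koff_a1", "koff_b1", "koff_a2",
                 "koff_b2", "fiber_width"):
        _require(getattr(p, name) > 0, f"{name} must be strictly positive")
    _require(p.kBT >= 0, "kBT must be non-negative")
    _require(p.t_burnin >= 0, "t_burnin must be non-negative")
    _require(p.F_myo >= 0, "F_myo must be non-negative")
    _require(p.actin_flow_speed >= 0, "actin_flow_speed must be non-negative")
    _require(p.fiber_friction_multiplier >= 1,
             "fiber_friction_multiplier must be >= 1")
    _require(p.n_integrins >= 1, "n_integrins must be >= 1")
    _require(p.ligand_rows >= 2, "ligand_rows must be >= 2")
    _require(0.0 <= p.P_bundling <= 1.0, "P_bundling must lie in [0, 1]")
    _require(p.myo_scope in _MYO_SCOPES,
             f"myo_scope must be one of {_MYO_SCOPES}")
    _require(p.fiber_width * 1e-3 <= p.domain_side,
             "fiber_width cannot exceed the domain side")

    # lattice geometry: vertices include both edges, spacing must tile the side
    span = (p.ligand_rows - 1) * p.ligand_spacing * 1e-3
    _require(math.isclose(span, p.domain_side, rel_tol=1e-9),
             f"(ligand_rows-1)*ligand_spacing = {span} um "
             f"does not equal domain_side = {p.domain_side} um")

    _require(p.t_burnin < p.t_total, "t_burnin must be smaller than t_total")
    _require(p.dt <= p.sample_interval, "dt must not exceed sample_interval")
    for whole, part, nm in ((p.sample_interval, p.dt, "sample_interval/dt"),
                            (p.t_total, p.sample_interval, "t_total/sample_interval")):
        ratio = whole / part
        _require(abs(ratio - round(ratio)) < 1e-6 * max(ratio, 1.0),
                 f"{nm} must be an integer ({ratio})")

    # friction: single source of truth is the Einstein relation
    if p.zeta is None:
        _require(p.kBT > 0, "zeta must be given explicitly when kBT = 0")
        p = dataclasses.replace(p, zeta=p.zeta_einstein)
    else:
        _require(p.zeta > 0, "zeta must be strictly positive")
        if p.kBT > 0:
            _require(abs(p.zeta - p.zeta_einstein) <= 0.02 * p.zeta_einstein,
                     f"zeta = {p.zeta} violates the Einstein relation "
                     f"kBT/D_free = {p.zeta_einstein:.4f} (2% tolerance); "
                     "use fiber_friction_multiplier for reduced in-fiber mobility")
    return p


def load_params(path: str, **overrides: Any) -> ModelParams:
    """Load parameters from a flat-key YAML file; overrides win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a mapping of parameter names")
    data.update(overrides)
    return validate_params(data)
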