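"""Shared state containers: integrin ensemble, ligand lattice, event log."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = ["IntegrinEnsemble", "LigandLattice", "EventLog",
           "lattice_positions", "initialize", "FREE"]

#: sentinel index meaning "not bound"
FREE = -1


@dataclass
class IntegrinEnsemble:
    """Positions and bound-state bookkeeping of the mobile receptors.

    ``positions`` are wrapped into the periodic domain
    [-side/2, +side/2) x [-side/2, +side/2).  ``bound_to`` holds the ligand
    index of each ligated integrin, or :data:`FREE`.
    """

    positions: np.ndarray                 # (n, 2) um
    bound_to: np.ndarray                  # (n,) int64, FREE when unbound
    bond_start_time: np.ndarray           # (n,) s, NaN when unbound
    total_ligated_time: np.ndarray        # (n,) s
    enhanced_kon: np.ndarray              # (n,) bool, current bundling draw

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def ligated(self) -> np.ndarray:
        return self.bound_to != FREE

    @property
    def n_ligated(self) -> int:
        return int(np.count_nonzero(self.bound_to != FREE))

    def copy(self) -> "IntegrinEnsemble":
        return IntegrinEnsemble(self.positions.copy(), self.bound_to.copy(),
                                self.bond_start_time.copy(),
                                self.total_ligated_time.copy(),
                                self.enhanced_kon.copy())


@dataclass
class LigandLattice:
    """Fixed ligand positions and their exclusive occupancy map.

    Ligand positions include both domain edges (21 vertices per 1-um side for
    50-nm spacing, i.e. 441 ligands) and are never wrapped, so edge ligands on
    opposite sides are periodic images of each other.  ``occupied_by`` is the
    inverse of :attr:`IntegrinEnsemble.bound_to`.
    """

    positions: np.ndarray                 # (m, 2) um, immutable after init
    occupied_by: np.ndarray               # (m,) int64, FREE when unoccupied

    @property
    def m(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "LigandLattice":
        return LigandLattice(self.positions.copy(), self.occupied_by.copy())


@dataclass
class EventLog:
    """Time-stamped binding and rupture events of one run."""

    bind_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    bind_integrin: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    bind_ligand: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    rupture_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    rupture_integrin: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    rupture_ligand: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    rupture_tension: np.ndarray = field(default_factory=lambda: np.empty(0))   # pN
    rupture_duration: np.ndarray = field(default_factory=lambda: np.empty(0))  # s

    @property
    def n_binds(self) -> int:
        return self.bind_time.size

    @property
    def n_ruptures(self) -> int:
        return self.rupture_time.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy table of all events: (time_s, kind, integrin, ligand, tension_pN, duration_s)."""
        binds = pd.DataFrame({
            "time_s": self.bind_time, "kind": "bind",
            "integrin": self.bind_integrin, "ligand": self.bind_ligand,
            "tension_pN": np.nan, "duration_s": np.nan,
        })
        rupts = pd.DataFrame({
            "time_s": self.rupture_time, "kind": "rupture",
            "integrin": self.rupture_integrin, "ligand": self.rupture_ligand,
            "tension_pN": self.rupture_tension, "duration_s": self.rupture_duration,
        })
        out = pd.concat([binds, rupts], ignore_index=True)
        return out.sort_values("time_s", kind="stable").reset_index(drop=True)

    @classmethod
    def from_lists(cls, binds, ruptures) -> "EventLog":
        """Build from lists of (t, i, j) and (t, i, j, tension, duration)."""
        b = np.array(binds, dtype=float).reshape(-1, 3)
        r = np.array(ruptures, dtype=float).reshape(-1, 5)
        return cls(
            bind_time=b[:, 0], bind_integrin=b[:, 1].astype(np.int64),
            bind_ligand=b[:, 2].astype(np.int64),
            rupture_time=r[:, 0], rupture_integrin=r[:, 1].astype(np.int64),
            rupture_ligand=r[:, 2].astype(np.int64),
            rupture_tension=r[:, 3], rupture_duration=r[:, 4],
        )


def lattice_positions(params: ModelParams) -> np.ndarray:
    """Ligand positions at the vertices of the lattice, both edges included.

    The first vertex sits at (-side/2, -side/2); vertices are stored row-major
    with x varying fastest, i.e. index = iy * ligand_rows + ix.
    """
    half = params.domain_side / 2.0
    coords = -half + np.arange(params.ligand_rows) * params.ligand_spacing * 1e-3
    xx, yy = np.meshgrid(coords, coords)  # xx varies along axis 1 (x fastest)
    return np.column_stack([xx.ravel(), yy.ravel()])


def initialize(params: ModelParams) -> tuple[IntegrinEnsemble, LigandLattice]:
    """Seeded initial state: uniform free integrins, empty ligand lattice."""
    rng = np.random.default_rng(params.seed)
    half = params.domain_side / 2.0
    n = params.n_integrins
    pos = rng.uniform(-half, half, size=(n, 2))
    ens = IntegrinEnsemble(
        positions=pos,
        bound_to=np.full(n, FREE, dtype=np.int64),
        bond_start_time=np.full(n, np.nan),
        total_ligated_time=np.zeros(n),
        enhanced_kon=np.zeros(n, dtype=bool),
    )
    lat = LigandLattice(
        positions=lattice_positions(params),
        occupied_by=np.full(params.n_ligands, FREE, dtype=np.int64),
    )
    return ens, lat
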