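"""Time-explicit simulation driver for bonded stem models.

Owns the state arrays, rigid tooling, neighbour-list maintenance and
recording; the per-step physics lives in the compiled kernel
(:mod:`stemdem._kernel`).  Positions are SI (m) internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import _kernel
from .core import (
    BRANCH,
    CONTACT_PP,
    CONTACT_PW,
    STEEL,
    BondParams,
    ContactParams,
    MaterialParams,
    SimConfig,
    _effective_youngs,
    critical_timestep,
)
from .geometry import StemModel

__all__ = ["Wall", "Simulation", "SimRecord", "integrate_step"]

PLANE, SLOTTED_PLANE, CYLINDER = 0, 1, 2

#: neighbour-list skin as a fraction of the particle radius
SKIN_FRACTION = 0.4


@dataclass
class Wall:
    """Rigid tool primitive (SI units)."""

    kind: int
    point: np.ndarray
    normal: np.ndarray
    slot_dir: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.0
    gap_half: float = 0.0
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class SimRecord:
    """Chunk-concatenated recording: times, tool reaction force, energies,
    broken-bond counts and the quasi-staticity flag."""

    time: np.ndarray
    force: np.ndarray  # (n, 3) reaction on the recorded tool / grips
    kinetic_energy: np.ndarray
    strain_energy: np.ndarray
    broken_bonds: np.ndarray
    quasistatic: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "fx_N": self.force[:, 0],
                "fy_N": self.force[:, 1],
                "fz_N": self.force[:, 2],
                "kinetic_J": self.kinetic_energy,
                "strain_J": self.strain_energy,
                "broken_bonds": self.broken_bonds,
            }
        )


def _beta(restitution: float) -> float:
    """Positive damping ratio of the restitution-consistent contact model."""
    ln_e = math.log(restitution)
    return -ln_e / math.sqrt(ln_e * ln_e + math.pi * math.pi)


class Simulation:
    """Explicit bonded-sphere DEM simulation of one stem model.

    Parameters
    ----------
    model : StemModel
        Packed geometry (mm); converted to SI internally.
    bond : BondParams
        Bond law parameters; bonds form at construction for every particle
        pair with centre distance at most ``2 R_ab``.
    config : SimConfig
        Integration settings; ``dt=None`` picks the stability-bounded step.
    """

    def __init__(
        self,
        model: StemModel,
        bond: BondParams,
        config: SimConfig = SimConfig(),
        material: MaterialParams = BRANCH,
        tool_material: MaterialParams = STEEL,
        contact_pp: ContactParams = CONTACT_PP,
        contact_pw: ContactParams = CONTACT_PW,
    ):
        self.model = model
        self.bond = bond
        self.config = config
        self.material = material
        self.contact_pp = contact_pp
        self.contact_pw = contact_pw

        self.r = model.particle_radius * 1e-3
        self.mass = material.density * (4.0 / 3.0) * math.pi * self.r**3
        self.inertia = 0.4 * self.mass * self.r**2

        self.pos = np.ascontiguousarray(model.positions_m())
        n = len(self.pos)
        self.vel = np.zeros((n, 3))
        self.omg = np.zeros((n, 3))
        self.driven = np.zeros(n, dtype=np.uint8)

        pairs = cKDTree(self.pos).query_pairs(
            2.0 * bond.R_ab + 1e-12, output_type="ndarray"
        )
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        self.bond_pairs = np.ascontiguousarray(pairs.astype(np.int64))
        m = len(self.bond_pairs)
        self.bond_fn = np.zeros(m)
        self.bond_ft = np.zeros((m, 3))
        self.bond_mn = np.zeros(m)
        self.bond_ms = np.zeros((m, 3))
        self.bond_ok = np.ones(m, dtype=np.uint8)

        bounds = critical_timestep(self.r, material, bond)
        self.dt = config.dt if config.dt is not None else config.dt_safety_factor * min(
            bounds["rayleigh"], bounds["bond"]
        )
        self.time = 0.0
        self.walls: list[Wall] = []

        self._estar_pp = _effective_youngs(material, material)
        self._estar_pw = _effective_youngs(material, tool_material)
        self._beta_pp = _beta(contact_pp.restitution)
        self._beta_pw = _beta(contact_pw.restitution)
        self._force = np.zeros((n, 3))
        self._torque = np.zeros((n, 3))
        self._skin = SKIN_FRACTION * self.r
        self._cp = self._build_neighbours()

    # ------------------------------------------------------------------ setup
    def add_wall(self, wall: Wall) -> int:
        self.walls.append(wall)
        return len(self.walls) - 1

    def add_plane(self, point, normal, velocity=(0, 0, 0)) -> int:
        return self.add_wall(
            Wall(PLANE, np.asarray(point, float), _unit(normal),
                 velocity=np.asarray(velocity, float))
        )

    def add_slotted_plane(self, point, normal, slot_dir, gap_half,
                          velocity=(0, 0, 0)) -> int:
        return self.add_wall(
            Wall(SLOTTED_PLANE, np.asarray(point, float), _unit(normal),
                 slot_dir=_unit(slot_dir), gap_half=float(gap_half),
                 velocity=np.asarray(velocity, float))
        )

    def add_cylinder(self, point, axis, radius, velocity=(0, 0, 0)) -> int:
        return self.add_wall(
            Wall(CYLINDER, np.asarray(point, float), _unit(axis),
                 radius=float(radius), velocity=np.asarray(velocity, float))
        )

    def set_driven(self, ids, velocity, record: bool = True) -> None:
        """Kinematically drive a particle set at a fixed velocity (grips).

        ``record=True`` marks the set as the one whose net reaction force is
        recorded when no tool is being recorded (the moving grip); a static
        clamp passes ``record=False``.
        """
        idx = np.asarray(ids, int)
        self.driven[idx] = 1 if record else 2
        self.vel[idx] = np.asarray(velocity, float)

    # ------------------------------------------------------------------- run
    def _build_neighbours(self) -> np.ndarray:
        cp = cKDTree(self.pos).query_pairs(
            2.0 * self.r + self._skin, output_type="ndarray"
        )
        if len(cp) == 0:
            return np.empty((0, 2), dtype=np.int64)
        return np.ascontiguousarray(cp.astype(np.int64))

    def _wall_arrays(self):
        nw = len(self.walls)
        wk = np.array([w.kind for w in self.walls], dtype=np.int64)
        wpt = np.array([w.point for w in self.walls], float).reshape(nw, 3)
        wn = np.array([w.normal for w in self.walls], float).reshape(nw, 3)
        ws = np.array([w.slot_dir for w in self.walls], float).reshape(nw, 3)
        wr = np.array([w.radius for w in self.walls], float)
        wg = np.array([w.gap_half for w in self.walls], float)
        wv = np.array([w.velocity for w in self.walls], float).reshape(nw, 3)
        return wk, wpt, wn, ws, wr, wg, wv

    def run(
        self,
        n_steps: int,
        rec_every: int = 1,
        record_wall: int | None = None,
        max_chunk: int = 2000,
    ) -> SimRecord:
        """Advance ``n_steps`` steps, recording every ``rec_every`` steps.

        ``record_wall`` selects the tool whose reaction force is recorded;
        ``None`` records the net force on velocity-driven particles.
        Neighbour lists are rebuilt between kernel chunks sized so that no
        particle can cross the list skin within one chunk.
        """
        n_steps = (n_steps // rec_every) * rec_every
        n_rec = n_steps // rec_every
        rec_force = np.zeros((n_rec, 3))
        rec_ke = np.zeros(n_rec)
        rec_seb = np.zeros(n_rec)
        rec_sec = np.zeros(n_rec)
        rec_broken = np.zeros(n_rec)
        t0 = self.time

        rw = -1 if record_wall is None else int(record_wall)
        wk, wpt, wn, ws, wr, wg, wv = self._wall_arrays()
        done = 0
        out_row = 0
        while done < n_steps:
            vmax = max(
                float(np.abs(self.vel).max(initial=0.0)),
                float(np.abs(wv).max(initial=0.0)),
                1e-3,
            )
            safe = max(1, int(self._skin / (2.0 * vmax * self.dt)))
            chunk_rec = max(1, min(max_chunk // rec_every, safe // rec_every,
                                   n_rec - out_row))
            chunk = max(rec_every, chunk_rec * rec_every)
            chunk = min(chunk, n_steps - done)
            chunk = (chunk // rec_every) * rec_every or rec_every
            nr = chunk // rec_every
            status = _kernel.step_chunk(
                self.pos, self.vel, self.omg, self.driven,
                self.mass, self.inertia, self.r,
                self.bond_pairs, self.bond_fn, self.bond_ft,
                self.bond_mn, self.bond_ms, self.bond_ok,
                self.bond.K_n, self.bond.K_s, self.bond.A_b, self.bond.J,
                self.bond.R_ab, self.bond.sigma_max, self.bond.tau_max,
                self._cp,
                self._estar_pp, self._beta_pp,
                self.contact_pp.static_friction, self.contact_pp.rolling_friction,
                self._estar_pw, self._beta_pw,
                self.contact_pw.static_friction, self.contact_pw.rolling_friction,
                wk, wpt, wn, ws, wr, wg, wv,
                self.dt, self.config.damping, self.config.gravity, 1e-3,
                chunk, rec_every, rw,
                rec_force[out_row : out_row + nr],
                rec_ke[out_row : out_row + nr],
                rec_seb[out_row : out_row + nr],
                rec_sec[out_row : out_row + nr],
                rec_broken[out_row : out_row + nr],
                self._force, self._torque,
            )
            if status != _kernel.STATUS_OK:
                raise RuntimeError(
                    f"simulation unstable at t={self.time + done * self.dt:.3e} s "
                    f"(NaN or particle speed beyond {_kernel.V_ABORT} m/s); "
                    f"reduce dt or loading rate"
                )
            done += chunk
            out_row += nr
            self._cp = self._build_neighbours()
        # write back advanced wall positions
        for w, p in zip(self.walls, wpt):
            w.point = p
        self.time = t0 + n_steps * self.dt
        strain = rec_seb + rec_sec
        # quasi-staticity guard: kinetic energy below 1% of strain energy
        # wherever meaningful strain energy has accumulated
        loaded = strain > max(strain.max(initial=0.0) * 1e-3, 1e-12)
        quasi = bool(np.all(rec_ke[loaded] < 0.01 * strain[loaded])) if loaded.any() else True
        times = t0 + self.dt * rec_every * (1 + np.arange(n_rec))
        return SimRecord(
            time=times,
            force=rec_force,
            kinetic_energy=rec_ke,
            strain_energy=strain,
            broken_bonds=rec_broken,
            quasistatic=quasi,
        )

    def step(self, n: int = 1) -> SimRecord:
        """Advance ``n`` single steps (records every step)."""
        return self.run(n, rec_every=1)

    # ------------------------------------------------------------ inspection
    @property
    def n_broken_bonds(self) -> int:
        return int((self.bond_ok == 0).sum())

    def bond_table(self) -> pd.DataFrame:
        """Per-bond state with acting stresses (for snapshots/logging)."""
        ms = np.linalg.norm(self.bond_ms, axis=1)
        ft = np.linalg.norm(self.bond_ft, axis=1)
        sigma = -self.bond_fn / self.bond.A_b + 2.0 * ms * self.bond.R_ab / self.bond.J
        tau = ft / self.bond.A_b + np.abs(self.bond_mn) * self.bond.R_ab / self.bond.J
        return pd.DataFrame(
            {
                "a": self.bond_pairs[:, 0],
                "b": self.bond_pairs[:, 1],
                "F_n_N": self.bond_fn,
                "F_t_N": ft,
                "M_n_Nm": self.bond_mn,
                "M_s_Nm": ms,
                "sigma_Pa": sigma,
                "tau_Pa": tau,
                "intact": self.bond_ok.astype(bool),
            }
        )

    def particle_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.pos)),
                "x_mm": self.pos[:, 0] * 1e3,
                "y_mm": self.pos[:, 1] * 1e3,
                "z_mm": self.pos[:, 2] * 1e3,
                "vx_m_s": self.vel[:, 0],
                "vy_m_s": self.vel[:, 1],
                "vz_m_s": self.vel[:, 2],
                "driven": self.driven.astype(bool),
            }
        )

    def snapshot(self, particle_path, bond_path=None) -> None:
        """Write CSV state snapshots (particle table, optional bond table)."""
        self.particle_table().to_csv(particle_path, index=False)
        if bond_path is not None:
            self.bond_table().to_csv(bond_path, index=False)


def integrate_step(sim: Simulation, n: int = 1) -> SimRecord:
    """Advance an existing simulation by ``n`` explicit steps."""
    return sim.step(n)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)
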