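"""Virtual mechanical tests and force–displacement curve reduction.

Four load cases mirror the laboratory programme: radial compression between
flat platens, three-point bending, double-support cutting (shear) and axial
tension with kinematic grips.  Each test drives a rigid tool (or grip set)
at constant speed into a bonded, settled stem model and records the reaction
force on the moving tool against its travel.

The physical loading rate (10 mm/min) is not feasible for an explicit
integrator; tests run at a scaled speed (default 0.05 m/s) with a
quasi-staticity guard — the kinetic energy must stay below 1% of the
accumulated strain energy — flagged on every curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BondParams, SimConfig
from .geometry import StemModel, build_stem, pack_cross_section
from .simulation import Simulation

__all__ = [
    "LoadCase",
    "ForceDisplacementCurve",
    "build_specimen",
    "run_test",
    "extract_peak",
    "fit_elastic_slope",
    "locate_first_drop",
    "relative_error",
]

#: nominal laboratory loading speed, mm/min
NOMINAL_SPEED_MM_MIN = 10.0
#: scaled simulation speed, m/s
DEFAULT_SIM_SPEED = 0.05
#: tool-travel sampling interval, mm
SAMPLE_INTERVAL_MM = 0.01

KINDS = ("compression", "bending", "shear", "tension")


@dataclass(frozen=True)
class LoadCase:
    """Geometry and kinematics of one virtual test.

    All lengths mm.  ``speed_mm_min`` is the nominal laboratory rate kept
    for provenance; ``sim_speed`` (m/s) is what the integrator actually
    drives, with quasi-staticity checked per run.
    """

    kind: str
    max_displacement: float
    span: float = 60.0  # bending support span
    indenter_radius: float = 5.0  # bending indenter/support cylinder radius
    blade_thickness: float = 1.5  # shear blade
    blade_angle: float = 150.0  # included wedge angle, deg (edge modelled round)
    support_clearance: float = 2.0  # shear: support gap minus blade thickness
    clamp_length: float = 10.0  # tension grips
    speed_mm_min: float = NOMINAL_SPEED_MM_MIN
    sim_speed: float = DEFAULT_SIM_SPEED
    sample_interval: float = SAMPLE_INTERVAL_MM

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.sim_speed <= 0 or self.speed_mm_min <= 0:
            raise ValueError("loading speed must be positive")
        if self.max_displacement < 0:
            raise ValueError("max_displacement cannot be negative")

    @staticmethod
    def compression(max_displacement: float = 4.0, **kw) -> "LoadCase":
        return LoadCase(kind="compression", max_displacement=max_displacement, **kw)

    @staticmethod
    def bending(max_displacement: float = 10.0, **kw) -> "LoadCase":
        return LoadCase(kind="bending", max_displacement=max_displacement, **kw)

    @staticmethod
    def shear(max_displacement: float = 9.0, **kw) -> "LoadCase":
        return LoadCase(kind="shear", max_displacement=max_displacement, **kw)

    @staticmethod
    def tension(max_displacement: float = 3.0, **kw) -> "LoadCase":
        return LoadCase(kind="tension", max_displacement=max_displacement, **kw)


@dataclass
class ForceDisplacementCurve:
    """Sampled reaction force (N) against tool travel (mm)."""

    displacement: np.ndarray
    force: np.ndarray
    broken_bonds: np.ndarray = field(default_factory=lambda: np.empty(0))
    quasistatic: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, float)
        self.force = np.asarray(self.force, float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if len(self.displacement) > 1 and np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")

    def __len__(self) -> int:
        return len(self.force)

    @property
    def peak_force(self) -> float:
        return extract_peak(self)[0]

    @property
    def peak_displacement(self) -> float:
        return extract_peak(self)[1]

    @property
    def elastic_slope(self) -> float:
        return fit_elastic_slope(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"displacement_mm": self.displacement, "force_N": self.force}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ForceDisplacementCurve":
        df = pd.read_csv(path)
        return ForceDisplacementCurve(
            displacement=df["displacement_mm"].to_numpy(),
            force=df["force_N"].to_numpy(),
        )


def build_specimen(
    diameter: float = 9.3, length: float = 20.0, particle_radius: float = 0.5
) -> StemModel:
    """Convenience: pack and stack a cylindrical specimen (mm)."""
    return build_stem(pack_cross_section(diameter, particle_radius), length)


def _setup_tools(sim: Simulation, case: LoadCase) -> int | None:
    """Place rigid tooling tangent to the specimen; returns the moving tool
    index, or None when grips are driven kinematically (tension)."""
    pos = sim.pos
    r = sim.r
    x_top = pos[:, 0].max() + r
    x_bot = pos[:, 0].min() - r
    z_mid = 0.5 * (pos[:, 2].min() + pos[:, 2].max())
    v = case.sim_speed

    if case.kind == "compression":
        sim.add_plane((x_bot, 0, 0), (1, 0, 0))
        return sim.add_plane((x_top, 0, 0), (-1, 0, 0), velocity=(-v, 0, 0))

    if case.kind == "bending":
        R = case.indenter_radius * 1e-3
        half_span = 0.5 * case.span * 1e-3
        sim.add_cylinder((x_bot - R, 0, z_mid - half_span), (0, 1, 0), R)
        sim.add_cylinder((x_bot - R, 0, z_mid + half_span), (0, 1, 0), R)
        return sim.add_cylinder(
            (x_top + R, 0, z_mid), (0, 1, 0), R, velocity=(-v, 0, 0)
        )

    if case.kind == "shear":
        gap_half = 0.5 * (case.blade_thickness + case.support_clearance) * 1e-3
        sim.add_slotted_plane((x_bot, 0, z_mid), (1, 0, 0), (0, 0, 1), gap_half)
        Rb = 0.5 * case.blade_thickness * 1e-3
        return sim.add_cylinder(
            (x_top + Rb, 0, z_mid), (0, 1, 0), Rb, velocity=(-v, 0, 0)
        )

    # tension
    z = pos[:, 2]
    clamp = case.clamp_length * 1e-3
    lo = z <= z.min() + clamp
    hi = z >= z.max() - clamp
    sim.set_driven(np.where(lo)[0], (0, 0, 0), record=False)
    sim.set_driven(np.where(hi)[0], (0, 0, v), record=True)
    return None


def run_test(
    model: StemModel,
    case: LoadCase,
    bond: BondParams,
    config: SimConfig = SimConfig(),
    **sim_kwargs,
) -> ForceDisplacementCurve:
    """Run one virtual test and return its force–displacement curve.

    The moving tool advances at ``case.sim_speed``; the reaction force is
    averaged over each sampling interval (``case.sample_interval`` of tool
    travel).  The run ends at ``case.max_displacement`` or early once, after
    the first bond rupture, the force falls below 10% of the running peak.
    """
    sim = Simulation(model, bond, config, **sim_kwargs)
    tool = _setup_tools(sim, case)
    if case.max_displacement == 0:
        return ForceDisplacementCurve(
            np.empty(0), np.empty(0), quasistatic=True, meta={"kind": case.kind}
        )

    v = case.sim_speed
    motion = np.zeros(3)
    if tool is not None:
        motion = sim.walls[tool].velocity / np.linalg.norm(sim.walls[tool].velocity)
    else:
        motion = np.array([0.0, 0.0, 1.0])

    rec_every = max(1, int(round(case.sample_interval * 1e-3 / (v * sim.dt))))
    n_samples = int(round(case.max_displacement / case.sample_interval))
    batch = max(1, min(n_samples, 25))  # check the stop rule every 25 samples

    disp, force, broken = [], [], []
    quasi = True
    taken = 0
    while taken < n_samples:
        nb = min(batch, n_samples - taken)
        rec = sim.run(nb * rec_every, rec_every=rec_every, record_wall=tool)
        f = rec.force @ (-motion)
        d0 = taken * case.sample_interval
        disp.append(d0 + case.sample_interval * (1 + np.arange(nb)))
        force.append(f)
        broken.append(rec.broken_bonds)
        quasi = quasi and rec.quasistatic
        taken += nb
        f_all = np.concatenate(force)
        b_all = np.concatenate(broken)
        if b_all[-1] > 0 and f_all[-1] < 0.1 * f_all.max():
            break

    return ForceDisplacementCurve(
        displacement=np.concatenate(disp),
        force=np.concatenate(force),
        broken_bonds=np.concatenate(broken),
        quasistatic=quasi,
        meta={
            "kind": case.kind,
            "sim_speed_m_s": v,
            "dt_s": sim.dt,
            "n_particles": model.n_particles,
            "n_bonds": len(sim.bond_pairs),
        },
    )


def extract_peak(curve: ForceDisplacementCurve) -> tuple[float, float]:
    """Global force maximum and its displacement (ties: smallest travel)."""
    if len(curve) == 0:
        raise ValueError("cannot extract a peak from an empty curve")
    i = int(np.argmax(curve.force))
    return float(curve.force[i]), float(curve.displacement[i])


def fit_elastic_slope(
    curve: ForceDisplacementCurve, window: tuple[float, float] = (0.2, 0.8)
) -> float:
    """Least-squares slope (N/mm) of the elastic stage.

    Fits a straight line to the pre-peak samples whose force lies within
    ``window`` (fractions of the peak force), the default being the
    20–80% range.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError("window fractions must satisfy 0 <= lo < hi <= 1")
    f_max, _ = extract_peak(curve)
    i_peak = int(np.argmax(curve.force))
    mask = np.zeros(len(curve), dtype=bool)
    mask[: i_peak + 1] = True
    mask &= (curve.force >= lo * f_max) & (curve.force <= hi * f_max)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 samples in the elastic-fit window")
    A = np.column_stack([curve.displacement[mask], np.ones(mask.sum())])
    slope, _ = np.linalg.lstsq(A, curve.force[mask], rcond=None)[0]
    return float(slope)


def locate_first_drop(
    curve: ForceDisplacementCurve,
    min_peak_fraction: float = 0.2,
    drop_fraction: float = 0.1,
) -> dict | None:
    """Locate the first substantial force drop of a loading curve.

    Scans for the first local force maximum (of at least
    ``min_peak_fraction`` of the global peak) that is followed by a drop of
    at least ``drop_fraction``; used to characterise the three-phase
    (elastic rise / collapse / compaction re-rise) compression response.
    Returns a summary dict, or None when no such drop exists.
    """
    f = curve.force
    b = curve.broken_bonds if len(curve.broken_bonds) else np.zeros_like(f)
    for i in range(1, len(f) - 1):
        if f[i] >= f[i - 1] and f[i] >= f[i + 1] and f[i] >= min_peak_fraction * f.max():
            rest = f[i + 1 :]
            j = int(np.argmin(rest))
            if rest[j] <= (1.0 - drop_fraction) * f[i]:
                k = i + 1 + j
                return {
                    "i_peak": i,
                    "i_min": k,
                    "peak_N": float(f[i]),
                    "peak_mm": float(curve.displacement[i]),
                    "min_N": float(rest[j]),
                    "drop_fraction": float(1.0 - rest[j] / f[i]),
                    # post-drop recovery relative to the trough; the trough is
                    # floored at 1% of the peak so a near-total collapse does
                    # not produce an unbounded ratio
                    "rerise_ratio": float(
                        rest[j:].max() / max(rest[j], 0.01 * f[i])
                    ),
                    "bonds_broken_at_drop": float(b[k] - b[max(i - 1, 0)]),
                }
    return None


def relative_error(
    measured: float, reference: float, denominator: str = "reference"
) -> float:
    """Relative error in percent, ``100 |measured - reference| / reference``.

    ``denominator="measured"`` divides by the measured value instead (both
    conventions appear in published comparisons; the reference-denominator
    form is the default).
    """
    den = {"reference": reference, "measured": measured}[denominator]
    if den == 0:
        raise ZeroDivisionError("relative error undefined for a zero denominator")
    return 100.0 * abs(measured - reference) / abs(den)
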