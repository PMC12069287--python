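"""Construction of bonded-sphere stem models.

A branch segment is idealised as a circular cylinder packed with equal
spheres.  The cross-section is filled on a square lattice of pitch equal to
one particle diameter, seeded at the section centre, keeping only lattice
points whose centres lie fully inside the section.  Cross-sections are then
stacked along the axis without gaps, so the axial pitch equals the particle
diameter as well.  A single particle type represents epidermis, xylem and
pith alike; the stem is treated as isotropic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ParticleSpec",
    "CrossSectionTemplate",
    "StemModel",
    "pack_cross_section",
    "build_stem",
    "export_particle_table",
    "read_particle_table",
    "PARTICLE_TABLE_COLUMNS",
]

#: default particle radius, mm (half the 1 mm meshing pitch used to place spheres)
DEFAULT_PARTICLE_RADIUS_MM = 0.5

#: geometric tolerance for the non-overlap invariant, mm
OVERLAP_TOL_MM = 1e-6

PARTICLE_TABLE_COLUMNS = [
    "id",
    "type",
    "x_mm",
    "y_mm",
    "z_mm",
    "rot_x_deg",
    "rot_y_deg",
    "rot_z_deg",
]


@dataclass(frozen=True)
class ParticleSpec:
    """One sphere of the stem model (coordinates and radius in mm)."""

    id: int
    center: tuple[float, float, float]
    radius: float
    layer_index: int

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")


@dataclass(frozen=True)
class CrossSectionTemplate:
    """Packed circular cross-section: 2-D centres (mm) plus radii."""

    section_radius: float
    particle_radius: float
    centers: np.ndarray  # (n, 2) mm

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array")
        r = np.hypot(c[:, 0], c[:, 1])
        if np.any(r > self.section_radius - self.particle_radius + OVERLAP_TOL_MM):
            raise ValueError("a particle centre lies outside the admissible disc")

    @property
    def n_particles(self) -> int:
        return len(self.centers)


@dataclass
class StemModel:
    """Particle table plus bond-candidate pairs for one branch segment."""

    particles: list[ParticleSpec]
    length: float  # mm
    diameter: float  # mm
    bond_candidates: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def particle_radius(self) -> float:
        return self.particles[0].radius

    def positions_mm(self) -> np.ndarray:
        return np.array([p.center for p in self.particles], dtype=float)

    def positions_m(self) -> np.ndarray:
        return self.positions_mm() * 1e-3


def pack_cross_section(
    section_diameter: float,
    particle_radius: float = DEFAULT_PARTICLE_RADIUS_MM,
) -> CrossSectionTemplate:
    """Fill a circular section with equal circles on a square lattice.

    The lattice pitch is one particle diameter, the first circle sits at the
    section centre, and only lattice points whose distance from the origin is
    at most ``section_radius - particle_radius`` are kept, so every particle
    lies fully inside the section contour.  The returned ordering is
    deterministic: ring by ring outward (by centre distance), counter-clockwise
    within a ring starting from the +x axis.

    Parameters
    ----------
    section_diameter : float
        Outer diameter of the cross-section, mm.
    particle_radius : float
        Sphere radius, mm.
    """
    if particle_radius <= 0:
        raise ValueError("particle_radius must be positive")
    if section_diameter < 2 * particle_radius:
        raise ValueError(
            f"section diameter {section_diameter} mm cannot hold one particle "
            f"of radius {particle_radius} mm"
        )
    section_radius = section_diameter / 2.0
    keep_radius = section_radius - particle_radius
    pitch = 2.0 * particle_radius
    n_max = int(math.floor(keep_radius / pitch)) + 1
    idx = np.arange(-n_max, n_max + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    xy = np.column_stack([ii.ravel(), jj.ravel()]) * pitch
    dist = np.hypot(xy[:, 0], xy[:, 1])
    keep = dist <= keep_radius + OVERLAP_TOL_MM
    xy, dist = xy[keep], dist[keep]
    ang = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2 * np.pi)
    order = np.lexsort((ang, np.round(dist / OVERLAP_TOL_MM).astype(np.int64)))
    return CrossSectionTemplate(
        section_radius=section_radius,
        particle_radius=particle_radius,
        centers=xy[order],
    )


def build_stem(
    template: CrossSectionTemplate,
    length: float,
    bond_search_radius: float | None = None,
) -> StemModel:
    """Stack cross-section layers axially into a stem model.

    Layers sit at an axial pitch of one particle diameter ("without gaps");
    the number of layers is ``round(length / pitch)``.  Bond candidates are
    all particle pairs whose centre distance does not exceed twice the bond
    search radius (defaulting to ``1.56 * particle_radius``, i.e. the
    mid-range bond radius of the calibration, reaching axial and in-plane
    diagonal neighbours).

    Parameters
    ----------
    template : CrossSectionTemplate
    length : float
        Stem length, mm.
    bond_search_radius : float, optional
        Bonds form for pairs with centre distance <= 2 * this value, mm.
    """
    r = template.particle_radius
    if length < 2 * r:
        raise ValueError("stem length must be at least one particle diameter")
    pitch = 2.0 * r
    n_layers = max(1, int(round(length / pitch)))
    if bond_search_radius is None:
        bond_search_radius = 1.56 * r
    particles: list[ParticleSpec] = []
    pid = 0
    for k in range(n_layers):
        z = (k + 0.5) * pitch
        for cx, cy in template.centers:
            particles.append(
                ParticleSpec(id=pid, center=(float(cx), float(cy), z), radius=r, layer_index=k)
            )
            pid += 1
    pos = np.array([p.center for p in particles])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2.0 * bond_search_radius + OVERLAP_TOL_MM, output_type="ndarray")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return StemModel(
        particles=particles,
        length=n_layers * pitch,
        diameter=2.0 * template.section_radius,
        bond_candidates=pairs,
    )


def export_particle_table(model: StemModel, path) -> None:
    """Write the particle table as CSV.

    Columns: ``id,type,x_mm,y_mm,z_mm,rot_x_deg,rot_y_deg,rot_z_deg``.
    Rotation angles are zero by default (spheres are rotationally symmetric);
    the columns exist so the table doubles as a meta-particle creation rule.
    """
    rows = [
        (p.id, 0, *p.center, 0.0, 0.0, 0.0)
        for p in model.particles
    ]
    df = pd.DataFrame(rows, columns=PARTICLE_TABLE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_particle_table(path, diameter: float | None = None,
                        particle_radius: float = DEFAULT_PARTICLE_RADIUS_MM) -> StemModel:
    """Read a particle table written by :func:`export_particle_table`."""
    df = pd.read_csv(path)
    if list(df.columns) != PARTICLE_TABLE_COLUMNS:
        raise ValueError(
            f"unexpected particle-table header {list(df.columns)}; "
            f"expected {PARTICLE_TABLE_COLUMNS}"
        )
    z = df["z_mm"].to_numpy()
    pitch = 2.0 * particle_radius
    layers = np.round((z - z.min()) / pitch).astype(int)
    particles = [
        ParticleSpec(
            id=int(row.id),
            center=(float(row.x_mm), float(row.y_mm), float(row.z_mm)),
            radius=particle_radius,
            layer_index=int(k),
        )
        for row, k in zip(df.itertuples(index=False), layers)
    ]
    xy = df[["x_mm", "y_mm"]].to_numpy()
    if diameter is None:
        diameter = 2.0 * (np.hypot(xy[:, 0], xy[:, 1]).max() + particle_radius)
    model = StemModel(
        particles=particles,
        length=(layers.max() + 1) * pitch,
        diameter=float(diameter),
    )
    pos = np.array([p.center for p in particles])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2.0 * 1.56 * particle_radius + OVERLAP_TOL_MM, output_type="ndarray")
    model.bond_candidates = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return model
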