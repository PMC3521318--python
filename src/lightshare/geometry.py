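"""Triangulated organ geometry for virtual plant mock-ups.

Organs are planar polygons (leaves) or thin rectangles (stem segments)
triangulated into 3-D meshes in metres.  An organ's inclination is the
dihedral angle between its plane and the horizontal, in degrees; the
tessellation is constructed so that the declared inclination equals the
measured plane angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Organ",
    "PlantMockup",
    "triangle_areas",
    "mesh_area",
    "plane_inclination_deg",
    "organ_tessellate",
]

FOLIAGE_TYPES = frozenset({"stipule", "leaflet", "blade"})
GREEN_TYPES = frozenset({"stipule", "leaflet", "blade", "internode", "stem"})

# outline templates in local (u, v) coordinates, u along length in [0, 1],
# v across width in [-1/2, 1/2] (scaled by length and width respectively)
_OUTLINES = {
    "rhombus": np.array([(0.0, 0.0), (0.5, -0.5), (1.0, 0.0), (0.5, 0.5)]),
    "rect": np.array([(0.0, -0.5), (1.0, -0.5), (1.0, 0.5), (0.0, 0.5)]),
}


def triangle_areas(mesh: np.ndarray) -> np.ndarray:
    """Areas of triangles stored as an (n, 3, 3) vertex array."""
    m = np.asarray(mesh, float)
    if m.size == 0:
        return np.zeros(0)
    cross = np.cross(m[:, 1] - m[:, 0], m[:, 2] - m[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def mesh_area(mesh: np.ndarray) -> float:
    return float(triangle_areas(mesh).sum())


def plane_inclination_deg(mesh: np.ndarray) -> float:
    """Angle between the (planar) mesh and the horizontal, degrees."""
    m = np.asarray(mesh, float)
    n = np.cross(m[0, 1] - m[0, 0], m[0, 2] - m[0, 0])
    nz = abs(n[2]) / np.linalg.norm(n)
    return float(np.degrees(np.arccos(np.clip(nz, -1.0, 1.0))))


@dataclass
class Organ:
    """One plant organ as a tagged triangle mesh (vertices in metres)."""

    species: str
    plant_id: int
    axis_id: int          # 0 = main stem, >= 1 = branch index
    rank: int
    organ_type: str
    mesh: np.ndarray      # (n_tri, 3, 3)
    area: float
    inclination: float    # degrees from horizontal

    def validate(self) -> None:
        if not np.all(np.isfinite(self.mesh)):
            raise ValueError("organ mesh contains non-finite vertices")
        if self.area < 0:
            raise ValueError("organ area must be non-negative")
        measured = mesh_area(self.mesh)
        if abs(measured - self.area) > 1e-9 * max(self.area, 1e-30):
            raise ValueError(
                f"declared area {self.area} differs from mesh area {measured}"
            )

    def translated(self, offset: np.ndarray) -> "Organ":
        return Organ(
            species=self.species, plant_id=self.plant_id, axis_id=self.axis_id,
            rank=self.rank, organ_type=self.organ_type,
            mesh=self.mesh + np.asarray(offset, float),
            area=self.area, inclination=self.inclination,
        )

    def rotated_z(self, angle_deg: float) -> "Organ":
        a = np.radians(angle_deg)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
        )
        return Organ(
            species=self.species, plant_id=self.plant_id, axis_id=self.axis_id,
            rank=self.rank, organ_type=self.organ_type,
            mesh=self.mesh @ rot.T, area=self.area, inclination=self.inclination,
        )


def organ_tessellate(
    organ_type: str,
    length_mm: float,
    width_mm: float,
    inclination_deg: float,
    azimuth_deg: float,
    base: np.ndarray,
    species: str = "pea",
    plant_id: int = 0,
    axis_id: int = 0,
    rank: int = 0,
    outline: str | None = None,
) -> Organ:
    """Build a planar organ mesh.

    The organ's long axis points away from ``base`` with elevation
    ``inclination_deg`` above the horizontal at the given azimuth (a
    negative value makes the organ arch downward); the cross axis is
    horizontal, so the polygon plane makes exactly ``|inclination_deg|``
    with the ground, which is the declared inclination.  Lengths are
    given in millimetres, the mesh is in metres.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("organ dimensions must be non-negative")
    if not -90.0 <= inclination_deg <= 90.0:
        raise ValueError("inclination must lie in [-90, 90] degrees")
    shape = outline or ("rect" if organ_type in ("internode", "stem", "blade") else "rhombus")
    uv = _OUTLINES[shape]

    beta = np.radians(inclination_deg)
    phi = np.radians(azimuth_deg)
    u_axis = np.array([np.cos(beta) * np.cos(phi), np.cos(beta) * np.sin(phi), np.sin(beta)])
    v_axis = np.array([-np.sin(phi), np.cos(phi), 0.0])

    L = length_mm * 1e-3
    W = width_mm * 1e-3
    verts = (
        np.asarray(base, float)
        + uv[:, :1] * L * u_axis
        + uv[:, 1:] * W * v_axis
    )
    # fan triangulation (outlines are convex)
    tris = np.array([[verts[0], verts[i], verts[i + 1]] for i in range(1, len(verts) - 1)])
    if L == 0.0 or W == 0.0:
        tris = np.zeros((0, 3, 3))
    return Organ(
        species=species, plant_id=plant_id, axis_id=axis_id, rank=rank,
        organ_type=organ_type, mesh=tris, area=mesh_area(tris),
        inclination=float(abs(inclination_deg)),
    )


@dataclass
class PlantMockup:
    """A single plant as a collection of tagged organs."""

    species: str
    organs: list[Organ] = field(default_factory=list)
    n_phytomers_main: int = 0
    n_branches: int = 0

    @property
    def height(self) -> float:
        """Maximum vertical vertex coordinate (m); 0 for an empty mock-up."""
        zs = [o.mesh[..., 2].max() for o in self.organs if o.mesh.size]
        return float(max(zs)) if zs else 0.0

    @property
    def green_area_by_type(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for o in self.organs:
            if o.organ_type in GREEN_TYPES:
                out[o.organ_type] = out.get(o.organ_type, 0.0) + o.area
        return out

    @property
    def green_area(self) -> float:
        return sum(self.green_area_by_type.values())

    @property
    def leaf_area_fraction(self) -> float:
        """Share of green area in leaves (stipules + leaflets + blades)."""
        total = self.green_area
        if total == 0.0:
            return float("nan")
        leaf = sum(
            o.area for o in self.organs if o.organ_type in FOLIAGE_TYPES
        )
        return leaf / total

    def export_mesh(self, path) -> None:
        """Write the mock-up to OBJ or PLY with per-organ group tags."""
        import trimesh

        meshes = []
        for i, o in enumerate(self.organs):
            if not o.mesh.size:
                continue
            verts = o.mesh.reshape(-1, 3)
            faces = np.arange(len(verts)).reshape(-1, 3)
            m = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
            m.metadata["name"] = f"{o.species}_{o.organ_type}_{o.axis_id}_{o.rank}_{i}"
            meshes.append(m)
        scene = trimesh.Scene()
        for m in meshes:
            scene.add_geometry(m, geom_name=m.metadata["name"])
        scene.export(str(path))
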