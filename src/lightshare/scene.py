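"""Row-intercrop scene assembly and macroscopic canopy descriptors.

Plants are placed on parallel rows (default 17 cm apart) with wheat and
pea alternating within each row in proportion to their sowing densities
(defaults 125 and 45 plants m-2).  The plot is treated as doubly
periodic in x and y, which emulates an infinite canopy without border
plants; the ray caster wraps organ geometry accordingly.

Descriptors follow the stand conventions: LAI is total green organ area
(leaves and stems) per unit ground area; mean foliage inclination is the
green-area-weighted organ inclination over leaf organs only (stipules,
leaflets, wheat blades); plant height is the maximum organ vertex height
per plant, averaged per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FOLIAGE_TYPES, GREEN_TYPES, Organ, PlantMockup

__all__ = ["SceneSpec", "Scene", "CanopyDescriptors", "assemble_mixture", "canopy_descriptors"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SceneSpec:
    """Mixture plot layout."""

    plot_x: float                 # m, across rows
    plot_y: float                 # m, along rows
    inter_row: float = 0.17       # m
    density_wheat: float = 125.0  # plants m-2
    density_pea: float = 45.0     # plants m-2
    jitter: float = 0.02          # m, max per-plant placement jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.plot_x, self.plot_y, self.inter_row) <= 0:
            raise ConfigurationError("plot dimensions and row spacing must be positive")
        if self.density_wheat < 0 or self.density_pea < 0:
            raise ConfigurationError("densities must be non-negative")

    @property
    def n_rows(self) -> int:
        n = int(round(self.plot_x / self.inter_row))
        if n < 1:
            raise ConfigurationError(
                f"plot width {self.plot_x} m is too small for one row at "
                f"{self.inter_row} m spacing"
            )
        return n

    @property
    def area(self) -> float:
        return self.plot_x * self.plot_y


@dataclass
class Scene:
    """Placed organs of a mixed stand over a periodic rectangular footprint."""

    organs: list[Organ]
    plot_x: float
    plot_y: float
    n_plants: dict[str, int] = field(default_factory=dict)

    @property
    def footprint_area(self) -> float:
        return self.plot_x * self.plot_y

    @property
    def species(self) -> list[str]:
        return sorted({o.species for o in self.organs})

    def triangle_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """All triangles as an (n, 3, 3) array plus per-triangle species
        codes (indices into the returned species list)."""
        species = self.species
        code = {s: i for i, s in enumerate(species)}
        tris, codes = [], []
        for o in self.organs:
            if o.mesh.size:
                tris.append(o.mesh)
                codes.append(np.full(len(o.mesh), code[o.species], dtype=np.int64))
        if not tris:
            return np.zeros((0, 3, 3)), np.zeros(0, dtype=np.int64), species
        return np.concatenate(tris), np.concatenate(codes), species


@dataclass(frozen=True)
class CanopyDescriptors:
    lai_by_species: dict[str, float]
    mean_inclination_by_species: dict[str, float]  # degrees, foliage only
    height_by_species: dict[str, float]            # m, mean per-plant max height
    height_ratio: float                            # wheat / pea

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.lai_by_species:
            rows.append({
                "species": sp,
                "lai": self.lai_by_species[sp],
                "mean_inclination_deg": self.mean_inclination_by_species.get(sp, np.nan),
                "height_m": self.height_by_species.get(sp, np.nan),
            })
        return pd.DataFrame(rows)


def _species_pattern(n_wheat: int, n_pea: int) -> list[str]:
    """Deterministic proportional interleaving of the two species."""
    total = n_wheat + n_pea
    out, placed_w = [], 0
    for k in range(total):
        want_w = round((k + 1) * n_wheat / total)
        if want_w > placed_w:
            out.append("wheat")
            placed_w += 1
        else:
            out.append("pea")
    return out


def assemble_mixture(
    pea: list[PlantMockup],
    wheat: list[PlantMockup],
    spec: SceneSpec,
) -> Scene:
    """Place pea and wheat mock-ups on the row design of ``spec``.

    Plant counts are ``round(density * plot area)`` per species; the
    provided mock-up lists are cycled to fill the counts.  Each placed
    plant gets a seeded random rotation about z and a placement jitter
    of at most ``spec.jitter``.
    """
    if not pea and not wheat:
        raise ConfigurationError("at least one plant mock-up is required")
    n_wheat = int(round(spec.density_wheat * spec.area)) if wheat else 0
    n_pea = int(round(spec.density_pea * spec.area)) if pea else 0
    if n_wheat + n_pea == 0:
        raise ConfigurationError("plot too small: zero plants at the given densities")
    rng = np.random.default_rng(spec.seed)
    n_rows = spec.n_rows
    row_x = (np.arange(n_rows) + 0.5) * spec.plot_x / n_rows

    pattern = _species_pattern(n_wheat, n_pea)
    order = rng.permutation(len(pattern))  # spread species mix across rows
    # deal plants to rows round-robin in pattern order for even row filling
    per_row: list[list[str]] = [[] for _ in range(n_rows)]
    for idx, k in enumerate(order):
        per_row[idx % n_rows].append(pattern[k])

    organs: list[Organ] = []
    counters = {"pea": 0, "wheat": 0}
    sources = {"pea": pea, "wheat": wheat}
    placed = {"pea": 0, "wheat": 0}
    plant_uid = 0
    for rx, row in zip(row_x, per_row):
        n_in_row = len(row)
        if n_in_row == 0:
            continue
        ys = (np.arange(n_in_row) + 0.5) * spec.plot_y / n_in_row
        for sp, y in zip(row, ys):
            mock = sources[sp][counters[sp] % len(sources[sp])]
            counters[sp] += 1
            dx, dy = rng.uniform(-spec.jitter, spec.jitter, size=2)
            rot = float(rng.uniform(0.0, 360.0))
            x = (rx + dx) % spec.plot_x
            yy = (y + dy) % spec.plot_y
            for o in mock.organs:
                oo = o.rotated_z(rot).translated([x, yy, 0.0])
                oo.plant_id = plant_uid
                organs.append(oo)
            placed[sp] += 1
            plant_uid += 1
    return Scene(
        organs=organs, plot_x=spec.plot_x, plot_y=spec.plot_y,
        n_plants={k: v for k, v in placed.items() if v},
    )


def canopy_descriptors(scene: Scene) -> CanopyDescriptors:
    """Per-species LAI, mean foliage inclination and mean plant height."""
    if scene.footprint_area <= 0:
        raise ValueError("scene footprint must have positive area")
    if not scene.organs:
        raise ValueError("scene holds no organs")
    lai: dict[str, float] = {}
    incl_num: dict[str, float] = {}
    incl_den: dict[str, float] = {}
    plant_heights: dict[str, dict[int, float]] = {}
    for o in scene.organs:
        sp = o.species
        if o.organ_type in GREEN_TYPES:
            lai[sp] = lai.get(sp, 0.0) + o.area
        if o.organ_type in FOLIAGE_TYPES and o.area > 0:
            incl_num[sp] = incl_num.get(sp, 0.0) + o.area * o.inclination
            incl_den[sp] = incl_den.get(sp, 0.0) + o.area
        if o.mesh.size:
            h = float(o.mesh[..., 2].max())
            d = plant_heights.setdefault(sp, {})
            d[o.plant_id] = max(d.get(o.plant_id, 0.0), h)
    lai = {sp: a / scene.footprint_area for sp, a in lai.items()}
    incl = {sp: incl_num[sp] / incl_den[sp] for sp in incl_num}
    heights = {
        sp: float(np.mean(list(d.values()))) for sp, d in plant_heights.items()
    }
    if heights.get("pea", 0.0) > 0:
        ratio = heights.get("wheat", np.nan) / heights["pea"]
    else:
        ratio = float("nan")
    return CanopyDescriptors(
        lai_by_species=lai,
        mean_inclination_by_species=incl,
        height_by_species=heights,
        height_ratio=float(ratio),
    )
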