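"""Seeded 3-D mock-up builders for pea cultivars and wheat.

A pea mock-up is assembled phytomer by phytomer: the number of visible
phytomers at thermal time t comes from the cultivar's Schnute development
curve, each organ appears when the curve passes its rank and expands
linearly over a fixed thermal-time window, final organ lengths follow the
cultivar's rank profiles, and stipule/leaflet inclinations follow the
cultivar's thermal-time dynamics.  Branches are drawn (seeded) from the
stage's observed range and reuse the main-stem profiles truncated to
their phytomer count.  Stems are staked upright.

Organ widths are set in two steps: raw aspect ratios (leaf width =
length / 2, stem segments 3 mm wide) give provisional areas; per-type
width factors then make the organ-type shares of green area match the
cultivar's transcribed contributions, and a single calibrated
genotype-level width factor sets the absolute area so that stand LAI
tracks the observed canopies.  Width factors change areas linearly and
leave lengths, heights and inclinations untouched.

Wheat is generated parametrically per stage (a dynamic wheat development
model is out of scope): a vertical culm of the stage height carrying
planar blades, arching downward from their insertion points, whose total
area and area-weighted inclination meet the stage targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Organ, PlantMockup, organ_tessellate
from .genotypes import GenotypeSpec, WheatStage
from .schnute import schnute_eval, schnute_inverse

__all__ = ["build_pea", "build_wheat"]

STEM_WIDTH_MM = 3.0
LEAF_WIDTH_RATIO = 0.5          # raw width : length for stipules and leaflets
BRANCH_OFFSET_MM = 15.0
INTERNODE_GROWTH_DD = 75.0   # internodes elongate faster than leaves expand
PETIOLE_LENGTH_MM = 40.0     # horizontal petiole offset carrying leaflets
STIPULE_OFFSET_MM = 8.0      # stipules insert just off the stem axis
INCLINATION_JITTER_DEG = 3.0    # uniform, zero-mean in expectation

_TYPE_KEY = {"stipule": "stipules", "leaflet": "leaflets",
             "internode": "stems", "stem": "stems"}


@dataclass
class _OrganParams:
    organ_type: str
    length_mm: float
    width_mm: float          # raw width, before calibration factors
    inclination: float       # signed elevation, degrees
    azimuth: float
    base: np.ndarray
    axis_id: int
    rank: int


def _axis_params(
    spec: GenotypeSpec,
    t: float,
    rng: np.random.Generator,
    n_phytomers: int,
    n_max: int,
    axis_id: int,
    base_xy: np.ndarray,
    z0: float,
) -> list[_OrganParams]:
    """Organ parameters (lengths, angles, positions) for one upright axis."""
    out: list[_OrganParams] = []
    z = z0
    stip_incl = spec.stipule_inclination_deg(t)
    leaf_incl = spec.leaflet_inclination_deg(t)
    for i in range(1, n_phytomers + 1):
        r = min(i / n_max, 1.0)
        # an organ becomes visible when the appearance curve passes i - 1/2
        t_app = schnute_inverse(spec.schnute, min(i - 0.5, spec.schnute.y_max))
        g_leaf = float(np.clip((t - t_app) / spec.growth_duration_dd, 0.0, 1.0))
        g_node = float(np.clip((t - t_app) / INTERNODE_GROWTH_DD, 0.0, 1.0))
        if g_leaf == 0.0 and g_node == 0.0:
            continue
        ilen = spec.internode_length_mm(r) * g_node
        out.append(_OrganParams(
            "internode", ilen, STEM_WIDTH_MM, 90.0,
            float(rng.uniform(0.0, 360.0)),
            np.array([base_xy[0], base_xy[1], z]), axis_id, i,
        ))
        z += ilen * 1e-3
        node = np.array([base_xy[0], base_xy[1], z])
        pair_az = float(rng.uniform(0.0, 360.0))
        # width is set from the final length, so organ area expands
        # linearly with growth while length expands to the profile value
        g = g_leaf
        slen_final = spec.stipule_length_mm(r)
        for side in (0.0, 180.0):
            incl = float(np.clip(
                stip_incl + rng.uniform(-INCLINATION_JITTER_DEG, INCLINATION_JITTER_DEG),
                0.0, 90.0,
            ))
            az = np.radians(pair_az + side)
            off = STIPULE_OFFSET_MM * 1e-3 * g
            base = node + off * np.array([np.cos(az), np.sin(az), 0.0])
            out.append(_OrganParams(
                "stipule", slen_final * g, slen_final * LEAF_WIDTH_RATIO, incl,
                pair_az + side, base, axis_id, i,
            ))
        if spec.leaf_type == "leafy":
            llen_final = spec.leaflet_length_mm(r)
            for p in range(spec.leaflet_pairs_per_node):
                for side in (90.0, 270.0):
                    incl = float(np.clip(
                        leaf_incl
                        + rng.uniform(-INCLINATION_JITTER_DEG, INCLINATION_JITTER_DEG),
                        0.0, 90.0,
                    ))
                    # leaflets sit on a petiole extending from the node
                    az = np.radians(pair_az + side + 30.0 * p)
                    off = PETIOLE_LENGTH_MM * 1e-3 * g
                    base = node + off * np.array([np.cos(az), np.sin(az), 0.0])
                    out.append(_OrganParams(
                        "leaflet", llen_final * g, llen_final * LEAF_WIDTH_RATIO, incl,
                        pair_az + side + 30.0 * p, base, axis_id, i,
                    ))
    return out


def _raw_area_m2(p: _OrganParams) -> float:
    # rhombus (leaves): L*W/2; rectangle (stems): L*W
    shape_factor = 0.5 if p.organ_type in ("stipule", "leaflet") else 1.0
    return p.length_mm * p.width_mm * 1e-6 * shape_factor


def _width_factors(params: list[_OrganParams], targets: dict[str, float]) -> dict[str, float]:
    """Per-type width factors matching green-area shares to ``targets``
    exactly among the organ types present, preserving the raw total."""
    raw: dict[str, float] = {}
    for p in params:
        key = _TYPE_KEY[p.organ_type]
        raw[key] = raw.get(key, 0.0) + _raw_area_m2(p)
    total_raw = sum(raw.values())
    present = {k: v for k, v in raw.items() if v > 0}
    if not present:
        return {}
    norm = sum(targets.get(k, 0.0) for k in present)
    if norm == 0.0:
        return {k: 1.0 for k in present}
    return {
        k: (targets.get(k, 0.0) / norm) * total_raw / present[k] for k in present
    }


def build_pea(spec: GenotypeSpec, t: float, seed: int, plant_id: int = 0) -> PlantMockup:
    """Build one pea plant mock-up at thermal time ``t`` (DD after emergence).

    Identical ``(spec, t, seed)`` yield bit-identical mock-ups.  Before
    emergence (no visible phytomer) an empty mock-up is returned.
    """
    if t < 0:
        raise ValueError("thermal time must be non-negative")
    rng = np.random.default_rng(seed)
    n_max = int(round(spec.schnute.y_max))
    n_main = int(round(schnute_eval(spec.schnute, min(t, spec.schnute.t_max))))
    n_main = min(n_main, n_max)
    if n_main <= 0:
        return PlantMockup(species="pea")

    params = _axis_params(spec, t, rng, n_main, n_max, 0, np.zeros(2), 0.0)

    stage = spec.branching_at(t)
    n_branches = 0
    if stage is not None and stage.n_max > 0:
        n_branches = int(rng.integers(stage.n_min, stage.n_max + 1))
        main_nodes_z = np.cumsum(
            [p.length_mm * 1e-3 for p in params if p.axis_id == 0 and p.organ_type == "internode"]
        )
        main_ranks = [p.rank for p in params if p.axis_id == 0 and p.organ_type == "internode"]
        for b in range(n_branches):
            means = stage.phytomers_per_branch
            nb = int(round(means[min(b, len(means) - 1)])) if means else 3
            nb = max(min(nb, n_max), 0)
            if nb == 0:
                continue
            if spec.branch_insertion == "mid":
                lo, hi = spec.branch_insertion_ranks
                ins_rank = int(rng.integers(lo, hi + 1))
            else:
                ins_rank = b + 1
            ins_rank = min(ins_rank, n_main)
            z_ins = 0.0
            for rk, zz in zip(main_ranks, main_nodes_z):
                if rk <= ins_rank:
                    z_ins = float(zz)
            az = rng.uniform(0.0, 2.0 * np.pi)
            off = BRANCH_OFFSET_MM * 1e-3 * np.array([np.cos(az), np.sin(az)])
            params.extend(_axis_params(spec, t, rng, nb, n_max, b + 1, off, z_ins))

    factors = _width_factors(params, spec.area_contributions)
    organs = [
        organ_tessellate(
            p.organ_type, p.length_mm,
            p.width_mm * factors.get(_TYPE_KEY[p.organ_type], 1.0) * spec.area_scale,
            p.inclination, p.azimuth, p.base,
            species="pea", plant_id=plant_id, axis_id=p.axis_id, rank=p.rank,
        )
        for p in params
    ]
    return PlantMockup(
        species="pea", organs=organs,
        n_phytomers_main=n_main, n_branches=n_branches,
    )


# -- wheat -----------------------------------------------------------------

WHEAT_N_BLADES = 6
WHEAT_BLADE_ASPECT = 0.08       # width : length
_WHEAT_BLADE_WEIGHTS = np.array([0.8, 1.0, 1.2, 1.3, 1.1, 0.9])


def build_wheat(
    stage: WheatStage,
    seed: int,
    density: float = 125.0,
    plant_id: int = 0,
) -> PlantMockup:
    """Build one wheat plant for a stand stage.

    ``stage.lai`` is the stand green area index; each plant receives
    ``lai / density`` m2 of green area, split between a thin vertical
    culm of exactly the stage height and planar blades at the stage's
    foliage inclination (zero-mean jitter on individual blades).  Blades
    arch downward from their insertion points so the culm tip sets the
    plant height.
    """
    if stage.lai < 0 or stage.height_m < 0 or not 0 <= stage.inclination_deg <= 90:
        raise ValueError("wheat stage values must be non-negative (inclination in [0, 90])")
    if density <= 0:
        raise ValueError("density must be positive")
    target_area = stage.lai / density
    if target_area == 0.0:
        return PlantMockup(species="wheat")
    rng = np.random.default_rng(seed)

    culm = organ_tessellate(
        "stem", stage.height_m * 1e3, STEM_WIDTH_MM, 90.0,
        float(rng.uniform(0, 360)), np.zeros(3),
        species="wheat", plant_id=plant_id, axis_id=0, rank=0,
    )
    blade_area = max(target_area - culm.area, 0.0)

    organs = [culm]
    weights = _WHEAT_BLADE_WEIGHTS / _WHEAT_BLADE_WEIGHTS.sum()
    attach = np.linspace(0.35, 1.0, WHEAT_N_BLADES) * stage.height_m
    jitters = rng.uniform(-INCLINATION_JITTER_DEG, INCLINATION_JITTER_DEG, WHEAT_N_BLADES)
    jitters -= jitters.mean()  # keep the area-weighted inclination on target
    for k in range(WHEAT_N_BLADES):
        a_k = blade_area * weights[k]
        L_mm = np.sqrt(a_k / WHEAT_BLADE_ASPECT) * 1e3
        W_mm = WHEAT_BLADE_ASPECT * L_mm
        incl = float(np.clip(stage.inclination_deg + jitters[k], 0.0, 90.0))
        organs.append(
            organ_tessellate(
                "blade", L_mm, W_mm, -incl, float(rng.uniform(0, 360)),
                np.array([0.0, 0.0, attach[k]]),
                species="wheat", plant_id=plant_id, axis_id=0, rank=k + 1,
            )
        )
    return PlantMockup(species="wheat", organs=organs, n_phytomers_main=WHEAT_N_BLADES)
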