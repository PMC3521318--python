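"""Genotype parameter sets for the pea mock-up generator.

Each cultivar is described by a plain-text (YAML) parameter file holding
its development curve (Schnute parameters), branching table, organ
final-length profiles over normalized phytomer rank, inclination
dynamics over thermal time and expected organ-type contributions to
green area.  Six contrasting winter pea cultivars are shipped with the
package (two leafy: China, US13; four semi-leafless: Lucy, James,
AOPH10, 886/01), together with the wheat stand stage table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .schnute import SchnuteParams

__all__ = [
    "BranchingStage",
    "GenotypeSpec",
    "WheatStage",
    "load_genotype",
    "load_shipped_genotypes",
    "load_wheat_stages",
    "SHIPPED_CULTIVARS",
]

SHIPPED_CULTIVARS = ("China", "US13", "Lucy", "James", "AOPH10", "886_01")


@dataclass(frozen=True)
class BranchingStage:
    """Branching observed at one developmental stage."""

    stage_dd: float
    n_min: int
    n_max: int
    phytomers_per_branch: tuple[float, ...]  # mean counts for B1, B2, B3...


@dataclass(frozen=True)
class WheatStage:
    """Wheat stand descriptors at one simulation stage."""

    stage_dd: float
    lai: float               # green area index, m2 m-2
    height_m: float
    inclination_deg: float


def _interp(knots: list[list[float]], x: float) -> float:
    k = np.asarray(knots, float)
    return float(np.interp(x, k[:, 0], k[:, 1]))


@dataclass(frozen=True)
class GenotypeSpec:
    """Architectural parameter set for one pea cultivar."""

    name: str
    leaf_type: str                       # "leafy" | "semi-leafless"
    schnute: SchnuteParams
    maturity_dd: float                   # last digitizing date
    branching: tuple[BranchingStage, ...]
    branch_insertion: str                # "basal" | "mid"
    branch_insertion_ranks: tuple[int, int]
    internode_mean_length_mm: float
    internode_multiplier: tuple[tuple[float, float], ...]   # (norm rank, x)
    stipule_length_knots: tuple[tuple[float, float], ...]   # (norm rank, mm)
    leaflet_length_knots: tuple[tuple[float, float], ...]   # leafy only
    stipule_inclination_knots: tuple[tuple[float, float], ...]  # (DD, deg)
    leaflet_inclination_knots: tuple[tuple[float, float], ...]
    area_contributions: dict[str, float]  # stipules / leaflets / stems
    leaflet_pairs_per_node: int
    growth_duration_dd: float
    area_scale: float                    # global width multiplier (calibrated)

    def __post_init__(self) -> None:
        if self.leaf_type not in ("leafy", "semi-leafless"):
            raise ValueError(f"{self.name}: unknown leaf type {self.leaf_type!r}")
        total = sum(self.area_contributions.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(
                f"{self.name}: area contributions sum to {total}, expected 1"
            )
        if self.leaf_type == "semi-leafless" and self.area_contributions.get("leaflets", 0.0) > 0:
            raise ValueError(f"{self.name}: semi-leafless spec declares leaflet area")
        for st in self.branching:
            if st.n_min > st.n_max:
                raise ValueError(f"{self.name}: branching range min > max at {st.stage_dd} DD")
        for knots, label in (
            (self.stipule_length_knots, "stipule lengths"),
            (self.leaflet_length_knots, "leaflet lengths"),
            (self.internode_multiplier, "internode multipliers"),
        ):
            if any(v < 0 for _, v in knots):
                raise ValueError(f"{self.name}: negative {label}")

    # -- profile evaluation ------------------------------------------------
    def internode_length_mm(self, norm_rank: float) -> float:
        return self.internode_mean_length_mm * _interp(
            [list(k) for k in self.internode_multiplier], norm_rank
        )

    def stipule_length_mm(self, norm_rank: float) -> float:
        return _interp([list(k) for k in self.stipule_length_knots], norm_rank)

    def leaflet_length_mm(self, norm_rank: float) -> float:
        if self.leaf_type != "leafy":
            return 0.0
        return _interp([list(k) for k in self.leaflet_length_knots], norm_rank)

    def stipule_inclination_deg(self, t_dd: float) -> float:
        return _interp([list(k) for k in self.stipule_inclination_knots], t_dd)

    def leaflet_inclination_deg(self, t_dd: float) -> float:
        if self.leaf_type != "leafy":
            return 0.0
        return _interp([list(k) for k in self.leaflet_inclination_knots], t_dd)

    def branching_at(self, t_dd: float) -> BranchingStage | None:
        stages = sorted(self.branching, key=lambda s: s.stage_dd)
        current = None
        for st in stages:
            if st.stage_dd <= t_dd:
                current = st
        return current


_REQUIRED_KEYS = {
    "name", "leaf_type", "schnute", "maturity_dd", "branching",
    "branch_insertion", "internode", "stipule", "leaflet",
    "area_contributions", "growth_duration_dd", "area_scale",
}


def _spec_from_dict(raw: dict, source: str) -> GenotypeSpec:
    unknown = set(raw) - _REQUIRED_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ValueError(f"{source}: missing keys {sorted(missing)}")

    sch = raw["schnute"]
    branching = tuple(
        BranchingStage(
            stage_dd=float(b["stage_dd"]),
            n_min=int(b["range"][0]),
            n_max=int(b["range"][1]),
            phytomers_per_branch=tuple(float(v) for v in b.get("phytomers_per_branch", [])),
        )
        for b in raw["branching"]
    )
    ins = raw["branch_insertion"]
    leaflet = raw["leaflet"] or {}
    return GenotypeSpec(
        name=str(raw["name"]),
        leaf_type=str(raw["leaf_type"]),
        schnute=SchnuteParams(
            A=float(sch["A"]), B=float(sch["B"]),
            y_max=float(sch["y_max"]), t_max=float(sch["t_max"]),
        ),
        maturity_dd=float(raw["maturity_dd"]),
        branching=branching,
        branch_insertion=str(ins["mode"]),
        branch_insertion_ranks=tuple(int(v) for v in ins.get("ranks", [1, 3])),
        internode_mean_length_mm=float(raw["internode"]["mean_length_mm"]),
        internode_multiplier=tuple(
            (float(a), float(b)) for a, b in raw["internode"]["multiplier"]
        ),
        stipule_length_knots=tuple(
            (float(a), float(b)) for a, b in raw["stipule"]["length_knots"]
        ),
        leaflet_length_knots=tuple(
            (float(a), float(b)) for a, b in leaflet.get("length_knots", [])
        ),
        stipule_inclination_knots=tuple(
            (float(a), float(b)) for a, b in raw["stipule"]["inclination_knots"]
        ),
        leaflet_inclination_knots=tuple(
            (float(a), float(b)) for a, b in leaflet.get("inclination_knots", [])
        ),
        area_contributions={
            str(k): float(v) for k, v in raw["area_contributions"].items()
        },
        leaflet_pairs_per_node=int(leaflet.get("pairs_per_node", 1)),
        growth_duration_dd=float(raw["growth_duration_dd"]),
        area_scale=float(raw["area_scale"]),
    )


def load_genotype(path) -> GenotypeSpec:
    """Load and validate a genotype parameter file (YAML)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"genotype file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    return _spec_from_dict(raw, source=str(p))


def load_shipped_genotypes(names=SHIPPED_CULTIVARS) -> dict[str, GenotypeSpec]:
    """Load the shipped cultivar parameter files keyed by cultivar name."""
    out = {}
    for name in names:
        ref = resources.files("lightshare") / "data" / f"pea_{name}.yaml"
        raw = yaml.safe_load(ref.read_text())
        spec = _spec_from_dict(raw, source=str(ref))
        out[spec.name] = spec
    return out


def load_wheat_stages() -> dict[float, WheatStage]:
    """Shipped wheat stand descriptors keyed by stage (DD)."""
    ref = resources.files("lightshare") / "data" / "wheat_stages.yaml"
    raw = yaml.safe_load(ref.read_text())
    out = {}
    for row in raw["stages"]:
        st = WheatStage(
            stage_dd=float(row["stage_dd"]), lai=float(row["lai"]),
            height_m=float(row["height_m"]), inclination_deg=float(row["inclination_deg"]),
        )
        out[st.stage_dd] = st
    return out
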