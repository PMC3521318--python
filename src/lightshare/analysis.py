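"""Stage-wise light-sharing experiments and deviation analysis.

For each (stage, cultivar, replicate) a virtual mixture of that cultivar
with wheat is generated, its diffuse interception is ray cast, and the
computed pea share is compared with the turbid-medium (well-mixed)
prediction built from the same scene's descriptors: extinction
coefficients from the per-species mean foliage inclinations and the
relative LAI.  Deviations (computed minus theoretical share) are then
regressed on the theoretical share per stage, and related to the
wheat/pea height ratio with a saturating-exponential curve
``deviation = a (1 - exp(-b (h - 1)))``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .generator import build_pea, build_wheat
from .genotypes import GenotypeSpec, WheatStage
from .raycast import diffuse_interception, species_share
from .scene import SceneSpec, assemble_mixture, canopy_descriptors
from .sky import SkyVault, build_sky
from .theory import extinction_from_inclination, share_theoretical

__all__ = [
    "SimulationRecord",
    "RegressionResult",
    "HeightCurveFit",
    "run_stage_experiment",
    "records_frame",
    "regress_shares",
    "height_ratio_curve",
]


@dataclass(frozen=True)
class SimulationRecord:
    stage: float
    genotype: str
    replicate: int
    p_pea: float                # pea share of mixture LAI
    share_computed: float
    share_theoretical: float
    deviation: float
    height_ratio: float         # wheat / pea
    lai_pea: float
    lai_wheat: float
    k_pea: float
    k_wheat: float
    height_pea: float
    height_wheat: float
    mc_stderr_pea: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int
    slope_se: float
    through_origin: bool


@dataclass(frozen=True)
class HeightCurveFit:
    asymptote: float   # saturation deviation a
    rate: float        # b, per unit height ratio
    r2: float
    saturating: bool   # False when the data carry no height-ratio signal


def _plant_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((seed, *key)).generate_state(1)[0])


def run_stage_experiment(
    stage_dd: float,
    genotypes: dict[str, GenotypeSpec],
    wheat_stage: WheatStage,
    scene_spec: SceneSpec,
    seeds: list[int],
    sky: SkyVault | None = None,
    n_rays_per_sector: int = 20_000,
) -> list[SimulationRecord]:
    """One record per (cultivar, replicate seed).

    Every replicate builds fresh seeded plants, assembles the mixture,
    ray casts the sky vault and derives the well-mixed theoretical share
    from the scene's own descriptors.  All randomness is fanned out from
    the replicate seed by a fixed counter scheme, so records are exactly
    reproducible.
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    if not seeds:
        raise ValueError("need at least one replicate seed")
    sky = sky or build_sky()
    records = []
    for g_idx, (name, spec) in enumerate(sorted(genotypes.items())):
        for rep, seed in enumerate(seeds):
            n_pea = max(int(round(scene_spec.density_pea * scene_spec.area)), 1)
            n_wheat = max(int(round(scene_spec.density_wheat * scene_spec.area)), 1)
            peas = [
                build_pea(spec, stage_dd, _plant_seed(seed, 1, g_idx, i))
                for i in range(n_pea)
            ]
            wheats = [
                build_wheat(
                    wheat_stage, _plant_seed(seed, 2, g_idx, i),
                    density=scene_spec.density_wheat,
                )
                for i in range(n_wheat)
            ]
            sc_spec = SceneSpec(
                plot_x=scene_spec.plot_x, plot_y=scene_spec.plot_y,
                inter_row=scene_spec.inter_row,
                density_wheat=scene_spec.density_wheat,
                density_pea=scene_spec.density_pea,
                jitter=scene_spec.jitter,
                seed=_plant_seed(seed, 3, g_idx),
            )
            scene = assemble_mixture(peas, wheats, sc_spec)
            desc = canopy_descriptors(scene)
            res = diffuse_interception(
                scene, sky, n_rays_per_sector, seed=_plant_seed(seed, 4, g_idx)
            )
            share = species_share(res)
            k_pea = extinction_from_inclination(
                desc.mean_inclination_by_species["pea"], sky
            )
            k_wheat = extinction_from_inclination(
                desc.mean_inclination_by_species["wheat"], sky
            )
            lai_pea = desc.lai_by_species["pea"]
            lai_wheat = desc.lai_by_species["wheat"]
            p = lai_pea / (lai_pea + lai_wheat)
            s_th = share_theoretical(k_pea / k_wheat, p)
            records.append(SimulationRecord(
                stage=stage_dd, genotype=name, replicate=rep,
                p_pea=p, share_computed=share.pea_share,
                share_theoretical=s_th,
                deviation=share.pea_share - s_th,
                height_ratio=desc.height_ratio,
                lai_pea=lai_pea, lai_wheat=lai_wheat,
                k_pea=k_pea, k_wheat=k_wheat,
                height_pea=desc.height_by_species["pea"],
                height_wheat=desc.height_by_species["wheat"],
                mc_stderr_pea=res.mc_stderr["pea"],
            ))
    return records


def records_frame(records: list[SimulationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def regress_shares(
    records: list[SimulationRecord],
    through_origin: bool = False,
) -> RegressionResult:
    """Least-squares regression of computed on theoretical pea share.

    The free-intercept fit is the default; the origin-constrained
    variant (slope = sum xy / sum x^2, uncentered R^2) is available via
    ``through_origin``.
    """
    x = np.array([r.share_theoretical for r in records])
    y = np.array([r.share_computed for r in records])
    n = len(x)
    if n < 2:
        raise ValueError("need at least two records to regress")
    if np.ptp(x) == 0:
        raise ValueError("theoretical shares are all equal; regression undefined")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
        resid = y - slope * x
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum(y**2))
        dof = n - 1
        slope_se = float(np.sqrt(ss_res / dof / np.sum(x * x)))
    else:
        xm, ym = x.mean(), y.mean()
        sxx = np.sum((x - xm) ** 2)
        slope = float(np.sum((x - xm) * (y - ym)) / sxx)
        intercept = float(ym - slope * xm)
        resid = y - slope * x - intercept
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - ym) ** 2))
        dof = n - 2
        slope_se = float(np.sqrt(ss_res / max(dof, 1) / sxx))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return RegressionResult(
        slope=slope, intercept=intercept, r2=float(r2), n=n,
        slope_se=slope_se, through_origin=through_origin,
    )


def height_ratio_curve(records: list[SimulationRecord]) -> HeightCurveFit:
    """Fit deviation = a (1 - exp(-b (h - 1))) against height ratio h >= 1.

    Captures the observed pattern that deviations from the well-mixed
    prediction grow with species height contrast for ratios between 1
    and about 2 and then level off.  Flat data (no height signal) yield
    ``saturating=False``.
    """
    h = np.array([r.height_ratio for r in records])
    d = np.array([r.deviation for r in records])
    keep = h >= 1.0
    h, d = h[keep], d[keep]
    if len(h) < 4:
        raise ValueError("need at least four records with height ratio >= 1")
    if np.ptp(h) < 1e-9:
        raise ValueError("no spread in height ratio; curve fit undefined")

    def model(hh, a, b):
        return a * (1.0 - np.exp(-b * (hh - 1.0)))

    a0 = d[np.argsort(h)][-max(len(h) // 4, 1):].mean() or 0.1
    try:
        popt, _ = curve_fit(
            model, h, d, p0=[a0, 2.0], maxfev=10_000,
            bounds=([-1.0, 0.0], [1.0, 1e3]),
        )
    except RuntimeError as exc:
        raise ValueError(f"height-ratio curve fit failed: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    resid = d - model(h, a, b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    # compare against a constant (mean-deviation) model: if the curve does
    # no better, the data carry no saturating height signal
    saturating = bool(ss_tot > 0 and ss_res < 0.95 * ss_tot and b > 1e-3)
    return HeightCurveFit(asymptote=a, rate=b, r2=float(r2), saturating=saturating)
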