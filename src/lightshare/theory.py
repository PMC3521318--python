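"""Turbid-medium (well-mixed) theory of light sharing in bi-specific canopies.

In a homogeneous mixed canopy obeying Beer-Lambert extinction, the light
interception efficiency (LIE) of species i is

    LIE_i = (K_i L_i / sum_j K_j L_j) * (1 - exp(-sum_j K_j L_j))

with K_i the extinction coefficient and L_i the leaf area index of
species i.  The share of species 1 in total interception is then

    S_1 = K_1 L_1 / (K_1 L_1 + K_2 L_2)
        = alpha p / (alpha p + (1 - p)),   alpha = K_1/K_2,  p = L_1/(L_1+L_2)

because the common exponential factor cancels in the ratio.  Isolines of
S_1 against p at fixed alpha describe how unequal extinction coefficients
(i.e. unequal foliage inclinations) bend light sharing away from the LAI
share; heterogeneous (e.g. height-stratified) canopies deviate from them.

Extinction coefficients are derived from the mean foliage inclination via
the ellipsoidal leaf-angle distribution (Campbell's parameterization):
the distribution parameter x is chosen to match the mean inclination, the
directional coefficient is K(theta) = sqrt(x^2 + tan^2 theta) /
(x + 1.702 (x + 1.12)^-0.708), and a single diffuse-effective K is defined
by matching the sky-integrated interception of a reference canopy of
LAI 1 (documented convention; the dependence on the reference LAI is weak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sky import SkyVault, build_sky

__all__ = [
    "TheoryInputs",
    "TheoryPrediction",
    "IsolineGrid",
    "lie_mixture",
    "share_theoretical",
    "ellipsoidal_x_from_inclination",
    "extinction_directional",
    "extinction_from_inclination",
    "isolines",
]

_X_MAX = 1e4  # planophile limit cap; K -> 1 to ~1e-4


@dataclass(frozen=True)
class TheoryInputs:
    """Per-species extinction coefficients and LAIs of a mixture."""

    K: tuple[float, ...]
    LAI: tuple[float, ...]

    def __post_init__(self) -> None:
        K = np.asarray(self.K, float)
        L = np.asarray(self.LAI, float)
        if K.shape != L.shape or K.ndim != 1 or K.size < 1:
            raise ValueError("K and LAI must be 1-D sequences of equal length >= 1")
        if np.any(K < 0) or np.any(L < 0):
            raise ValueError("K and LAI must be non-negative")
        if np.any((L > 0) & (K <= 0)):
            raise ValueError("species with LAI > 0 must have K > 0")

    @property
    def alpha(self) -> float:
        """K_1 / K_2 for a two-species mixture."""
        if len(self.K) != 2:
            raise ValueError("alpha is defined for two-species mixtures")
        return self.K[0] / self.K[1]


@dataclass(frozen=True)
class TheoryPrediction:
    lie_by_species: tuple[float, ...]
    share_species1: float
    total_interception: float


@dataclass(frozen=True)
class IsolineGrid:
    alpha_values: np.ndarray
    p_grid: np.ndarray
    shares: np.ndarray  # shape (n_alpha, n_p)


def lie_mixture(inputs: TheoryInputs) -> TheoryPrediction:
    """Light interception efficiency of each species in a well-mixed stand."""
    K = np.asarray(inputs.K, float)
    L = np.asarray(inputs.LAI, float)
    kl = K * L
    total_kl = kl.sum()
    if total_kl == 0.0:
        lie = np.zeros_like(kl)
        total = 0.0
    else:
        total = -np.expm1(-total_kl)
        lie = kl / total_kl * total
    share1 = float(lie[0] / lie.sum()) if lie.sum() > 0 else float("nan")
    return TheoryPrediction(
        lie_by_species=tuple(float(v) for v in lie),
        share_species1=share1,
        total_interception=float(total),
    )


def share_theoretical(alpha: float, p) -> np.ndarray | float:
    """Theoretical share of species 1, S = alpha p / (alpha p + 1 - p)."""
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    p_arr = np.asarray(p, float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("relative LAI p must lie in [0, 1]")
    s = alpha * p_arr / (alpha * p_arr + (1.0 - p_arr))
    return float(s) if np.isscalar(p) else s


def ellipsoidal_x_from_inclination(mean_inclination_deg: float) -> float:
    """Ellipsoidal leaf-angle-distribution parameter matching a mean
    leaf inclination (degrees from horizontal).

    Uses Campbell's approximation mean_angle = 9.65 (3 + x)^-1.65 (radians),
    inverted for x; x -> infinity for planophile canopies (capped), x = 1
    recovers the spherical distribution (mean ~ 56 deg, G = 0.5).
    """
    if not 0.0 <= mean_inclination_deg <= 90.0:
        raise ValueError("mean inclination must be in [0, 90] degrees")
    a = np.radians(mean_inclination_deg)
    if a < 1e-9:
        return _X_MAX
    x = (a / 9.65) ** (-1.0 / 1.65) - 3.0
    return float(np.clip(x, 1e-4, _X_MAX))


def extinction_directional(mean_inclination_deg: float, zenith_deg) -> np.ndarray | float:
    """Beam extinction coefficient K(theta) for an ellipsoidal canopy with
    the given mean foliage inclination."""
    x = ellipsoidal_x_from_inclination(mean_inclination_deg)
    th = np.radians(np.asarray(zenith_deg, float))
    k = np.sqrt(x**2 + np.tan(th) ** 2) / (x + 1.702 * (x + 1.12) ** -0.708)
    return float(k) if np.isscalar(zenith_deg) else k


def extinction_from_inclination(
    mean_inclination_deg: float,
    sky: SkyVault | None = None,
    reference_lai: float = 1.0,
) -> float:
    """Diffuse-effective extinction coefficient for a mean foliage inclination.

    Defined as the K solving 1 - exp(-K L) = sum_s w_s (1 - exp(-K(theta_s) L))
    at a reference LAI (default 1), i.e. the homogeneous-canopy coefficient
    that reproduces the sky-vault-integrated interception.
    """
    sky = sky or build_sky()
    kd = extinction_directional(mean_inclination_deg, sky.zeniths)
    intercepted = float(np.sum(sky.weights * -np.expm1(-kd * reference_lai)))
    return float(-np.log1p(-intercepted) / reference_lai)


def isolines(
    alpha_values=None,
    p_grid=None,
) -> IsolineGrid:
    """Theoretical light-sharing isolines S(p) for a set of K-ratios alpha.

    Defaults: alpha log-spaced from 0.1 to 10, p on a 101-point grid.
    """
    alpha_values = (
        np.logspace(-1, 1, 9) if alpha_values is None else np.asarray(alpha_values, float)
    )
    if np.any(alpha_values <= 0):
        raise ValueError("alpha values must be positive")
    p_grid = np.linspace(0.0, 1.0, 101) if p_grid is None else np.asarray(p_grid, float)
    shares = np.vstack([share_theoretical(a, p_grid) for a in alpha_values])
    return IsolineGrid(alpha_values=alpha_values, p_grid=p_grid, shares=shares)
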