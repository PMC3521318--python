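"""Discretized diffuse sky (Uniform Overcast Sky radiance).

The sky vault is split into zenith bands of equal angular width and a set
of azimuth sectors.  Under uniform radiance the diffuse flux reaching a
horizontal surface from the band [theta1, theta2] is proportional to

    int cos(theta) sin(theta) dtheta = (sin^2 theta2 - sin^2 theta1) / 2

so normalized band weights are ``sin^2 theta2 - sin^2 theta1``, split
equally over azimuths.  The default 5 x 4 discretization carries the
direction of each band at its upper zenith boundary (18, 36, 54, 72,
90 deg); the 90 deg entry is replaced by the band's flux-weighted mean
zenith because a horizontal ray never terminates in a periodic scene.
A ``centers`` interpretation (band mid-zeniths) is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SkySector", "SkyVault", "build_sky"]


@dataclass(frozen=True)
class SkySector:
    zenith: float    # degrees from vertical
    azimuth: float   # degrees
    weight: float    # fraction of incident diffuse flux on the horizontal


@dataclass(frozen=True)
class SkyVault:
    sectors: tuple[SkySector, ...]

    def __post_init__(self) -> None:
        w = np.array([s.weight for s in self.sectors])
        if np.any(w < 0):
            raise ValueError("sky sector weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"sky weights must sum to 1, got {w.sum()!r}")

    def __len__(self) -> int:
        return len(self.sectors)

    @property
    def zeniths(self) -> np.ndarray:
        return np.array([s.zenith for s in self.sectors])

    @property
    def azimuths(self) -> np.ndarray:
        return np.array([s.azimuth for s in self.sectors])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.sectors])


def _flux_mean_zenith(th1: float, th2: float) -> float:
    """Flux-weighted mean zenith of a band under uniform radiance (radians)."""
    from scipy.integrate import quad

    num, _ = quad(lambda t: t * np.cos(t) * np.sin(t), th1, th2)
    den, _ = quad(lambda t: np.cos(t) * np.sin(t), th1, th2)
    return num / den


def build_sky(
    n_zenith: int = 5,
    n_azimuth: int = 4,
    direction: str = "boundaries",
) -> SkyVault:
    """Build a diffuse sky vault with ``n_zenith * n_azimuth`` sectors.

    Parameters
    ----------
    n_zenith, n_azimuth : int
        Number of zenith bands (equal width over [0, 90] deg) and of
        azimuth sectors per band.
    direction : {"boundaries", "centers"}
        Whether each band's representative zenith is its upper boundary
        (default; yields 18/36/54/72/90 deg for five bands, with the
        90 deg entry replaced by the band's flux-weighted mean) or the
        band's mid-zenith.
    """
    if n_zenith < 1 or n_azimuth < 1:
        raise ValueError("need at least one zenith band and one azimuth sector")
    if direction not in ("boundaries", "centers"):
        raise ValueError(f"unknown direction convention: {direction!r}")

    edges = np.linspace(0.0, np.pi / 2.0, n_zenith + 1)
    azimuths = (np.arange(n_azimuth) + 0.5) * 360.0 / n_azimuth

    sectors = []
    for th1, th2 in zip(edges[:-1], edges[1:]):
        band_w = np.sin(th2) ** 2 - np.sin(th1) ** 2  # normalized: total = 1
        if direction == "boundaries":
            zen = th2 if th2 < np.pi / 2.0 - 1e-12 else _flux_mean_zenith(th1, th2)
        else:
            zen = 0.5 * (th1 + th2)
        for az in azimuths:
            sectors.append(
                SkySector(
                    zenith=float(np.degrees(zen)),
                    azimuth=float(az),
                    weight=float(band_w / n_azimuth),
                )
            )
    # exact renormalization against rounding
    total = sum(s.weight for s in sectors)
    sectors = [
        SkySector(s.zenith, s.azimuth, s.weight / total) for s in sectors
    ]
    return SkyVault(sectors=tuple(sectors))
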