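"""Forward model: suspension state → predicted optical density.

In the single-scattering (Beer–Lambert) regime the decadic turbidity is
``tau = sigma * C * L / ln 10`` and OD = tau. At higher densities photons
scatter more than once and the OD acquires a parabolic dependence on
concentration, modeled here as ``OD = tau - q * tau²`` with a single
instrument/scatterer-specific coefficient q; the model is valid only on
the monotone branch ``tau <= 1/(2q)`` (beyond lies the photon-diffusion
limit, out of scope).

Plate readers measure through the liquid column, so the effective path
length depends on the fill volume; measured ODs are normalized with
per-volume multiplicative correction factors supplied as instrument
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .scattering import OpticalContext, Scatterer

__all__ = [
    "SuspensionState",
    "PathConfig",
    "MultipleScatteringParams",
    "DEFAULT_VOLUME_CORRECTION",
    "SINGLE_SCATTER_OD_THRESHOLD",
    "turbidity",
    "od_single_scattering",
    "od_multiple_scattering",
    "od_to_turbidity",
    "mixture_od",
    "apply_volume_correction",
    "regime_classify",
    "ValidityError",
]

LN10 = float(np.log(10.0))

#: BMG plate-reader fill-volume → OD correction factors (µl → factor).
DEFAULT_VOLUME_CORRECTION: dict[int, float] = {300: 1.0560, 200: 1.5848, 100: 6.3694}

#: OD below which single scattering dominates (boundary inclusive).
SINGLE_SCATTER_OD_THRESHOLD = 0.2


class ValidityError(ValueError):
    """Model evaluated outside its validity range."""


@dataclass(frozen=True)
class SuspensionState:
    """Particle concentration (ml⁻¹) with its scatterer and optics."""

    concentration_per_ml: float
    scatterer: Scatterer
    context: OpticalContext

    def __post_init__(self) -> None:
        if self.concentration_per_ml < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class PathConfig:
    """Optical path length (cm) and fill-volume correction table."""

    path_length_cm: float = 1.0
    volume_correction: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_CORRECTION)
    )

    def __post_init__(self) -> None:
        if not self.path_length_cm > 0:
            raise ValueError("path_length_cm must be > 0")
        if any(f <= 0 for f in self.volume_correction.values()):
            raise ValueError("volume correction factors must be > 0")


@dataclass(frozen=True)
class MultipleScatteringParams:
    """Quadratic turbidity-correction coefficient q in OD = tau - q*tau²."""

    quad_coeff: float = 0.1

    def __post_init__(self) -> None:
        if self.quad_coeff < 0:
            raise ValueError("quad_coeff must be >= 0")

    @property
    def tau_max(self) -> float:
        """Upper edge of the monotone branch, 1/(2q)."""
        if self.quad_coeff == 0:
            return float("inf")
        return 1.0 / (2.0 * self.quad_coeff)


def turbidity(concentration_per_ml: float, sigma_cm2: float, path_length_cm: float) -> float:
    """Decadic turbidity tau = sigma * C * L / ln 10."""
    if concentration_per_ml < 0 or sigma_cm2 < 0 or path_length_cm <= 0:
        raise ValueError("concentration and sigma must be >= 0, path length > 0")
    return sigma_cm2 * concentration_per_ml * path_length_cm / LN10


def od_single_scattering(
    state: SuspensionState, path: PathConfig, sigma_eff_cm2: float
) -> float:
    """Beer–Lambert OD, linear in concentration."""
    return turbidity(state.concentration_per_ml, sigma_eff_cm2, path.path_length_cm)


def od_multiple_scattering(
    state: SuspensionState,
    path: PathConfig,
    sigma_eff_cm2: float,
    params: MultipleScatteringParams,
) -> float:
    """Parabolic multiple-scattering OD = tau - q*tau².

    Raises :class:`ValidityError` beyond the monotone branch tau > 1/(2q),
    where the parabola turns over and the photon-diffusion limit (out of
    scope) takes over.
    """
    tau = turbidity(state.concentration_per_ml, sigma_eff_cm2, path.path_length_cm)
    return _od_from_tau(tau, params)


def _od_from_tau(tau: float, params: MultipleScatteringParams) -> float:
    q = params.quad_coeff
    if tau > params.tau_max * (1.0 + 1e-12):
        raise ValidityError(
            f"turbidity tau={tau:.4g} beyond the monotone branch tau <= 1/(2q)="
            f"{params.tau_max:.4g}; the photon-diffusion limit is out of scope"
        )
    return float(tau - q * tau * tau)


def od_to_turbidity(od: float, params: MultipleScatteringParams) -> float:
    """Invert OD = tau - q*tau² on the monotone branch."""
    q = params.quad_coeff
    if od < 0:
        raise ValueError("od must be >= 0")
    if q == 0:
        return float(od)
    od_max = params.tau_max - q * params.tau_max**2
    if od > od_max * (1.0 + 1e-12):
        raise ValidityError(f"od={od:.4g} exceeds the model maximum {od_max:.4g}")
    disc = max(1.0 - 4.0 * q * od, 0.0)
    return float((1.0 - np.sqrt(disc)) / (2.0 * q))


def mixture_od(
    states: Sequence[SuspensionState],
    path: PathConfig,
    sigmas_cm2: Sequence[float],
    params: MultipleScatteringParams,
) -> float:
    """OD of a mixed suspension: turbidities add, then the quadratic
    correction applies to the total.

    All components must share the same medium and wavelength.
    """
    if len(states) == 0:
        raise ValueError("at least one component required")
    if len(states) != len(sigmas_cm2):
        raise ValueError("one sigma per component required")
    ctx0 = states[0].context
    for s in states[1:]:
        if s.context != ctx0:
            raise ValueError("mixture components must share the optical context")
    tau_tot = sum(
        turbidity(s.concentration_per_ml, sig, path.path_length_cm)
        for s, sig in zip(states, sigmas_cm2)
    )
    return _od_from_tau(tau_tot, params)


def apply_volume_correction(
    od_measured: float, fill_volume_ul: int, path: PathConfig
) -> float:
    """Normalize a measured OD for the well fill volume.

    Raises ``KeyError`` listing the configured volumes when the fill volume
    has no correction factor.
    """
    table = path.volume_correction
    if fill_volume_ul not in table:
        raise KeyError(
            f"no correction factor for fill volume {fill_volume_ul} µl; "
            f"configured volumes: {sorted(table)}"
        )
    return float(od_measured * table[fill_volume_ul])


def regime_classify(od: float, threshold: float = SINGLE_SCATTER_OD_THRESHOLD) -> str:
    """Classify an OD reading as 'single' or 'multiple' scattering.

    The boundary is inclusive on the single side: od <= threshold → single.
    """
    if od < 0:
        raise ValueError(f"od must be >= 0, got {od}")
    return "single" if od <= threshold else "multiple"
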