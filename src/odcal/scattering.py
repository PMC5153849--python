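"""Single-particle light scattering for turbidity calibration.

Exact Mie efficiencies for homogeneous spheres, the small-particle
(Rayleigh) and soft-particle (anomalous-diffraction / Jöbst) limits, and a
detector-acceptance correction for real spectrophotometer geometries in
which near-forward scattered light still reaches the detector.

Conventions
-----------
* Refractive indices are real (non-absorbing scatterers: polystyrene beads
  and unpigmented microbial cells at 600 nm).
* Relative index ``m = n_particle / n_medium``; size parameter
  ``x = pi * D * n_medium / lambda_vac``.
* Cross-sections are reported in cm² so that ``sigma * C[ml^-1] * L[cm]``
  is dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from numpy.polynomial.legendre import leggauss

__all__ = [
    "Scatterer",
    "OpticalContext",
    "DetectorGeometry",
    "ScatteringResult",
    "size_parameter",
    "relative_index",
    "mie_efficiencies",
    "mie_s1s2",
    "rayleigh_qsca",
    "ada_qext",
    "jobst_sigma",
    "acceptance_correction",
    "effective_sigma_ext",
    "SmallPhaseShiftWarning",
]

#: Largest supported size parameter for the Mie series.
X_MAX = 1.0e4

UM_TO_CM = 1.0e-4


class SmallPhaseShiftWarning(UserWarning):
    """Phase shift outside the small-phase-shift validity range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scatterer:
    """A spherical particle (bead or equivalent-volume-sphere cell).

    Parameters
    ----------
    diameter_um
        Sphere diameter in µm (> 0).
    n_particle
        Real refractive index of the particle (>= 1).
    size_cv
        Coefficient of variation of the diameter for polydisperse
        populations; 0 means monodisperse.
    """

    diameter_um: float
    n_particle: float
    size_cv: float = 0.0

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter_um}")
        if self.n_particle < 1.0:
            raise ValueError(f"n_particle must be >= 1, got {self.n_particle}")
        if self.size_cv < 0:
            raise ValueError(f"size_cv must be >= 0, got {self.size_cv}")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def volume_um3(self) -> float:
        return np.pi / 6.0 * self.diameter_um**3


@dataclass(frozen=True)
class OpticalContext:
    """Illumination and suspension medium.

    ``wavelength_nm`` is the vacuum wavelength; ``n_medium`` the medium's
    real refractive index (1.333 for water at 600 nm).
    """

    wavelength_nm: float = 600.0
    n_medium: float = 1.333

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength_nm}")
        if self.n_medium < 1.0:
            raise ValueError(f"n_medium must be >= 1, got {self.n_medium}")


@dataclass(frozen=True)
class DetectorGeometry:
    """Detector aperture radius and sample-detector distance (both mm).

    The acceptance half-angle ``theta_acc = arctan(R/d)`` sets how much
    near-forward scattered light is wrongly counted as transmitted.
    """

    aperture_radius_mm: float
    detector_distance_mm: float

    def __post_init__(self) -> None:
        if not self.aperture_radius_mm > 0:
            raise ValueError("aperture_radius_mm must be > 0")
        if not self.detector_distance_mm > 0:
            raise ValueError("detector_distance_mm must be > 0")

    @property
    def theta_acc(self) -> float:
        """Acceptance half-angle in radians, in (0, pi/2)."""
        return float(np.arctan(self.aperture_radius_mm / self.detector_distance_mm))


@dataclass(frozen=True)
class ScatteringResult:
    """Extinction/scattering efficiencies, optionally with sigma_ext (cm²)."""

    q_ext: float
    q_sca: float
    sigma_ext_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.q_ext < 0 or self.q_sca < 0:
            raise ValueError("efficiencies must be non-negative")


# ---------------------------------------------------------------------------
# size parameter and limits
# ---------------------------------------------------------------------------


def size_parameter(scatterer: Scatterer, context: OpticalContext) -> float:
    """Mie size parameter ``x = pi * D * n_medium / lambda_vac``."""
    lam_um = context.wavelength_nm * 1.0e-3
    return float(np.pi * scatterer.diameter_um * context.n_medium / lam_um)


def relative_index(scatterer: Scatterer, context: OpticalContext) -> float:
    """Relative refractive index ``m = n_particle / n_medium``."""
    return scatterer.n_particle / context.n_medium


def rayleigh_qsca(x: float, m: float) -> float:
    """Rayleigh scattering efficiency (8/3) x^4 |(m²-1)/(m²+2)|².

    Valid for particles much smaller than the wavelength (x <~ 0.3).
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if m <= 0:
        raise ValueError("m must be > 0")
    lorentz = (m**2 - 1.0) / (m**2 + 2.0)
    return float(8.0 / 3.0 * x**4 * lorentz**2)


def ada_qext(x: float, m: float) -> float:
    """Anomalous-diffraction extinction efficiency for a soft sphere.

    With phase shift ``rho = 2 x (m - 1)``::

        Q = 2 - (4/rho) sin(rho) + (4/rho²) (1 - cos(rho))

    The van de Hulst form, valid for m close to 1 and x >> 1; expanding for
    small rho gives Q -> rho²/2, i.e. the Jöbst small-phase-shift regime.
    """
    if m < 1:
        raise ValueError("soft-particle convention requires m >= 1")
    if x < 0:
        raise ValueError("x must be >= 0")
    rho = 2.0 * x * (m - 1.0)
    if rho == 0.0:
        return 0.0
    if rho < 1.0e-4:
        # series expansion avoids catastrophic cancellation
        return float(rho**2 / 2.0 - rho**4 / 24.0)
    return float(2.0 - 4.0 / rho * np.sin(rho) + 4.0 / rho**2 * (1.0 - np.cos(rho)))


def jobst_sigma(scatterer: Scatterer, context: OpticalContext) -> float:
    """Small-phase-shift extinction cross-section in cm².

    sigma = (rho²/2) * pi r² with rho = 2 x (m - 1): at fixed indices and
    wavelength this is exactly proportional to r^4, the scaling that makes
    OD of bacteria grow with cell volume to the power 4/3. Warns when
    rho > 0.5, outside the small-phase-shift regime.
    """
    x = size_parameter(scatterer, context)
    m = relative_index(scatterer, context)
    if m < 1:
        raise ValueError("soft-particle convention requires n_particle >= n_medium")
    rho = 2.0 * x * (m - 1.0)
    if rho > 0.5:
        warnings.warn(
            f"phase shift rho={rho:.3g} > 0.5: outside the small-phase-shift "
            "regime, sigma ∝ r^4 scaling is approximate",
            SmallPhaseShiftWarning,
            stacklevel=2,
        )
    r_cm = scatterer.radius_um * UM_TO_CM
    return float(rho**2 / 2.0 * np.pi * r_cm**2)


# ---------------------------------------------------------------------------
# Mie series
# ---------------------------------------------------------------------------


def _n_max(x: float, m: float = 1.0) -> int:
    """Series cutoff: Wiscombe criterion, extended to cover n ~ m*x.

    For optically soft but large spheres the partial waves up to n ≈ m·x
    still carry weight, so the cutoff is taken as the larger of the
    Wiscombe bound and ceil(m·x) + 10.
    """
    wiscombe = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    return max(wiscombe, int(np.ceil(m * x)) + 10)


def _mie_ab(x: float, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Mie coefficients a_n, b_n for n = 1..N_max.

    Logarithmic derivative D_n(mx) by downward recurrence (started at
    N_max + 15), Riccati–Bessel psi/chi by upward recurrence.
    """
    nmax = _n_max(x, m)
    mx = m * x
    nstart = nmax + 15

    d = np.zeros(nstart + 1)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    psi0 = np.sin(x)
    psi1 = np.sin(x) / x - np.cos(x)
    chi0 = np.cos(x)
    chi1 = np.cos(x) / x + np.sin(x)
    xi0 = complex(psi0, -chi0)
    xi1 = complex(psi1, -chi1)

    a = np.zeros(nmax, dtype=complex)
    b = np.zeros(nmax, dtype=complex)
    psi_nm1, psi_n = psi0, psi1
    xi_nm1, xi_n = xi0, xi1
    for n in range(1, nmax + 1):
        da = d[n] / m + n / x
        db = d[n] * m + n / x
        a[n - 1] = (da * psi_n - psi_nm1) / (da * xi_n - xi_nm1)
        b[n - 1] = (db * psi_n - psi_nm1) / (db * xi_n - xi_nm1)
        if n < nmax:
            psi_np1 = (2 * n + 1) / x * psi_n - psi_nm1
            xi_np1 = (2 * n + 1) / x * xi_n - xi_nm1
            psi_nm1, psi_n = psi_n, psi_np1
            xi_nm1, xi_n = xi_n, xi_np1
    return a, b


def mie_efficiencies(
    x: float, m: float, radius_um: Optional[float] = None
) -> ScatteringResult:
    """Exact Mie extinction and scattering efficiencies of a sphere.

    Parameters
    ----------
    x
        Size parameter (> 0, <= 1e4).
    m
        Real relative refractive index (> 0).
    radius_um
        If given, ``sigma_ext_cm2 = q_ext * pi * r²`` is filled in.

    Raises
    ------
    ValueError
        For non-positive inputs or x beyond the supported range.
    """
    if not x > 0:
        raise ValueError(f"size parameter must be > 0, got {x}")
    if x > X_MAX:
        raise ValueError(f"size parameter {x} > {X_MAX:g} is outside the supported range")
    if m <= 0:
        raise ValueError(f"relative index must be > 0, got {m}")

    a, b = _mie_ab(x, m)
    n = np.arange(1, a.size + 1)
    q_ext = 2.0 / x**2 * np.sum((2 * n + 1) * (a.real + b.real))
    q_sca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    sigma = None
    if radius_um is not None:
        sigma = float(q_ext * np.pi * (radius_um * UM_TO_CM) ** 2)
    return ScatteringResult(q_ext=float(q_ext), q_sca=float(q_sca), sigma_ext_cm2=sigma)


def mie_s1s2(x: float, m: float, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude functions S1(θ), S2(θ) at cos θ = mu (array)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    a, b = _mie_ab(x, m)
    nmax = a.size
    s1 = np.zeros(mu.shape, dtype=complex)
    s2 = np.zeros(mu.shape, dtype=complex)
    # angular functions pi_n, tau_n by upward recurrence
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)  # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        fac = (2 * n + 1) / (n * (n + 1))
        s1 += fac * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += fac * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_np1 = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_np1
    return s1, s2


# ---------------------------------------------------------------------------
# detector acceptance
# ---------------------------------------------------------------------------


def _q_within(x: float, m: float, theta_acc: float, n_nodes: int) -> float:
    """Scattering efficiency into the forward cone [0, theta_acc]."""
    nodes, wts = leggauss(n_nodes)
    theta = 0.5 * theta_acc * (nodes + 1.0)
    w = 0.5 * theta_acc * wts
    s1, s2 = mie_s1s2(x, m, np.cos(theta))
    integrand = (np.abs(s1) ** 2 + np.abs(s2) ** 2) * np.sin(theta)
    return float(np.sum(w * integrand) / x**2)


def acceptance_correction(
    x: float, m: float, geometry: DetectorGeometry, n_nodes: int = 64
) -> float:
    """Effective extinction efficiency seen by a finite-aperture detector.

    Light scattered into the acceptance cone still reaches the detector, so
    the measured extinction is ``q_ext - q_within`` where ``q_within`` is
    the scattering efficiency integrated over polar angle [0, theta_acc]
    (Gauss–Legendre quadrature, convergence checked by node doubling).
    Result is clipped to [0, q_ext].
    """
    res = mie_efficiencies(x, m)
    theta_acc = geometry.theta_acc
    q1 = _q_within(x, m, theta_acc, n_nodes)
    q2 = _q_within(x, m, theta_acc, 2 * n_nodes)
    if abs(q2 - q1) > 1.0e-6 * max(abs(q2), 1.0e-30):
        q4 = _q_within(x, m, theta_acc, 4 * n_nodes)
        if abs(q4 - q2) > 1.0e-6 * max(abs(q4), 1.0e-30):
            raise ArithmeticError(
                f"acceptance quadrature did not converge at {4 * n_nodes} nodes "
                f"(x={x:g}, theta_acc={theta_acc:g} rad)"
            )
        q2 = q4
    return float(np.clip(res.q_ext - q2, 0.0, res.q_ext))


def effective_sigma_ext(
    scatterer: Scatterer,
    context: OpticalContext,
    geometry: Optional[DetectorGeometry] = None,
    n_quad: int = 11,
) -> float:
    """Ensemble extinction cross-section in cm² for a particle population.

    For monodisperse particles (size_cv = 0) this is q_ext·πr² with q_ext
    from the exact Mie series, reduced for detector acceptance if a
    geometry is supplied (default is an ideal instrument, theta_acc = 0).
    Polydisperse populations are averaged over a lognormal diameter
    distribution with the stated CV using Gauss–Hermite quadrature.
    """
    def one(diameter_um: float) -> float:
        sc = Scatterer(diameter_um, scatterer.n_particle)
        x = size_parameter(sc, context)
        m = relative_index(sc, context)
        if geometry is None:
            q = mie_efficiencies(x, m).q_ext
        else:
            q = acceptance_correction(x, m, geometry)
        return q * np.pi * (diameter_um / 2.0 * UM_TO_CM) ** 2

    if scatterer.size_cv == 0:
        return one(scatterer.diameter_um)

    # lognormal(D) with mean diameter_um and CV size_cv
    s2 = np.log(1.0 + scatterer.size_cv**2)
    mu_log = np.log(scatterer.diameter_um) - s2 / 2.0
    nodes, wts = hermegauss(n_quad)
    wts = wts / np.sqrt(2.0 * np.pi)
    diam = np.exp(mu_log + np.sqrt(s2) * nodes)
    return float(sum(w * one(d) for w, d in zip(wts, diam)))
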