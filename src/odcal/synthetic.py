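"""Synthetic data with known ground truth for every pipeline input.

Emulates the study conditions the calibration method was developed under:

* monodisperse polystyrene bead dilution series (diameters 0.51, 0.96,
  3.00, 10.0 and 15.7 µm, n_p = 1.59, in water), concentrations spanning
  10⁵–10¹² ml⁻¹;
* plate-reader growth curves sampled every 7.5 min as the mean of 5
  reads, with multiplicative readout noise;
* prescribed cell-size trajectories — constant size (minimal-medium
  growth), shrinkage at stationary-phase onset, or β-lactam-style
  filamentation in which biomass keeps growing while the cell count
  stalls;
* Poisson microscope counting in 55.6 × 55.6 × 100 µm fields of view.

Cells and filaments are mapped to equivalent-volume spheres for the
optics. All generators are deterministic under a seed and return their
ground-truth parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import DilutionSeries
from .forward_model import (
    MultipleScatteringParams,
    PathConfig,
    SuspensionState,
    od_multiple_scattering,
    od_to_turbidity,
    turbidity,
    LN10,
)
from .growth import GrowthCurve, S_PER_HR
from .scattering import OpticalContext, Scatterer, effective_sigma_ext

__all__ = [
    "BEAD_DIAMETERS_UM",
    "BEAD_REFRACTIVE_INDEX",
    "WATER",
    "SizeTrajectory",
    "CountingSetup",
    "GrowthTruth",
    "make_bead_series",
    "concentration_grid_for_od",
    "simulate_growth",
    "simulate_od_readout",
    "simulate_counting",
    "DEFAULT_SAMPLING_INTERVAL_S",
    "DEFAULT_N_REPLICATES",
]

#: The reference polystyrene bead set (µm).
BEAD_DIAMETERS_UM = (0.51, 0.96, 3.00, 10.0, 15.7)
BEAD_REFRACTIVE_INDEX = 1.59
WATER = OpticalContext(wavelength_nm=600.0, n_medium=1.333)

#: Plate reader samples OD every 7.5 min; 10 replicate wells.
DEFAULT_SAMPLING_INTERVAL_S = 7.5 * 60.0
DEFAULT_N_REPLICATES = 10
DEFAULT_N_READS = 5
DEFAULT_NOISE_CV = 0.02

#: Equivalent-sphere diameter and refractive index of an E. coli-like cell.
CELL_DIAMETER_UM = 1.0
CELL_REFRACTIVE_INDEX = 1.40


@dataclass(frozen=True)
class SizeTrajectory:
    """Prescribed per-cell size behaviour during growth.

    modes
    -----
    constant
        Diameter fixed at ``diameter_um`` (minimal-medium growth).
    stationary_shrink
        Cell volume falls by ``shrink_fraction`` as the culture approaches
        carrying capacity.
    filamentation
        From ``pulse_start_hr`` to ``pulse_end_hr`` cells elongate instead
        of dividing: the cell count is frozen while per-cell volume tracks
        continuing biomass growth (capped at ``max_amplification``×).
        Afterwards filaments divide back toward baseline volume with time
        constant ``relax_hr``, during which the count rises while the OD
        can fall.
    """

    mode: str = "constant"
    diameter_um: float = CELL_DIAMETER_UM
    shrink_fraction: float = 0.3
    # filamentation onset when the culture reaches OD ~ 0.2 (≈ 5.5 hr at
    # mu = 0.7 hr⁻¹ from the default inoculum); filaments divide back
    # slowly over ~8 hr
    pulse_start_hr: float = 5.5
    pulse_end_hr: float = 9.5
    max_amplification: float = 10.0
    relax_hr: float = 8.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "stationary_shrink", "filamentation"):
            raise ValueError(f"unknown size-trajectory mode {self.mode!r}")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")
        if not 0 <= self.shrink_fraction < 1:
            raise ValueError("shrink_fraction must be in [0, 1)")
        if self.pulse_end_hr <= self.pulse_start_hr:
            raise ValueError("pulse window must have positive length")
        if self.max_amplification < 1:
            raise ValueError("max_amplification must be >= 1")
        if self.relax_hr <= 0:
            raise ValueError("relax_hr must be > 0")


@dataclass(frozen=True)
class CountingSetup:
    """Microscope field-of-view counting geometry."""

    fov_x_um: float = 55.6
    fov_y_um: float = 55.6
    fov_z_um: float = 100.0
    n_fields: int = 30

    def __post_init__(self) -> None:
        if min(self.fov_x_um, self.fov_y_um, self.fov_z_um) <= 0:
            raise ValueError("field dimensions must be > 0")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")

    @property
    def field_volume_ml(self) -> float:
        # 1 µm³ = 1e-12 ml
        return self.fov_x_um * self.fov_y_um * self.fov_z_um * 1.0e-12


@dataclass(frozen=True)
class GrowthTruth:
    """Ground truth returned by :func:`simulate_growth`."""

    time_s: np.ndarray
    n_per_ml: np.ndarray
    diameter_um: np.ndarray
    params: dict


# ---------------------------------------------------------------------------
# bead dilution series
# ---------------------------------------------------------------------------


def concentration_grid_for_od(
    od_min: float,
    od_max: float,
    n: int,
    sigma_cm2: float,
    path: PathConfig,
    params: MultipleScatteringParams,
) -> np.ndarray:
    """Geometric concentration grid whose true ODs span [od_min, od_max]."""
    tau_lo = od_to_turbidity(od_min, params)
    tau_hi = od_to_turbidity(od_max, params)
    c_lo = tau_lo * LN10 / (sigma_cm2 * path.path_length_cm)
    c_hi = tau_hi * LN10 / (sigma_cm2 * path.path_length_cm)
    return np.geomspace(c_lo, c_hi, n)


def make_bead_series(
    diameter_um: float,
    n_particle: float = BEAD_REFRACTIVE_INDEX,
    concentration_grid: Optional[Sequence[float]] = None,
    context: OpticalContext = WATER,
    path: Optional[PathConfig] = None,
    params: Optional[MultipleScatteringParams] = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    n_replicates: int = 1,
    size_cv: float = 0.0,
    seed: int = 0,
) -> tuple[DilutionSeries, dict]:
    """Simulate a bead dilution series measured on a plate reader.

    Each replicate OD is the forward-model OD times (1 + ε) with
    ε ~ Normal(0, noise_cv). Returns the series plus a ground-truth dict
    (forward-model coefficients included) for parameter-recovery checks.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    path = path or PathConfig()
    params = params or MultipleScatteringParams()
    scatterer = Scatterer(diameter_um, n_particle, size_cv)
    sigma = effective_sigma_ext(scatterer, context)
    if concentration_grid is None:
        concentration_grid = concentration_grid_for_od(
            0.05, 2.4, 24, sigma, path, params
        )
    grid = np.asarray(concentration_grid, float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("concentration grid must be positive and increasing")
    rng = np.random.default_rng(seed)
    reps = []
    true_od = []
    for c in grid:
        state = SuspensionState(float(c), scatterer, context)
        od0 = od_multiple_scattering(state, path, sigma, params)
        true_od.append(od0)
        eps = rng.normal(0.0, noise_cv, size=n_replicates) if noise_cv > 0 else np.zeros(n_replicates)
        reps.append(tuple(float(od0 * (1.0 + e)) for e in eps))
    series = DilutionSeries(
        concentrations_per_ml=tuple(float(c) for c in grid),
        od_replicates=tuple(reps),
        scatterer={"diameter_um": diameter_um, "n_particle": n_particle, "size_cv": size_cv},
        instrument_id="synthetic",
    )
    # true OD(C) = (sigma*L/ln10) C - q (sigma*L/ln10)^2 C^2
    k = sigma * path.path_length_cm / LN10
    truth = {
        "seed": seed,
        "sigma_ext_cm2": sigma,
        "noise_cv": noise_cv,
        "quad_coeff": params.quad_coeff,
        "true_coefficients": [0.0, k, -params.quad_coeff * k * k],
        "true_od": true_od,
    }
    return series, truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def simulate_growth(
    model: str = "logistic",
    mu_hr: float = 0.7,
    n0_per_ml: float = 5.0e6,
    carrying_capacity_per_ml: float = 2.0e9,
    size_trajectory: Optional[SizeTrajectory] = None,
    t_grid_s: Optional[Sequence[float]] = None,
    duration_hr: float = 16.0,
) -> GrowthTruth:
    """Noise-free ground-truth growth of a culture.

    ``model`` is "exponential" or "logistic"; the logistic carrying
    capacity is expressed in baseline-cell biovolume equivalents so that
    biomass, not cell count, saturates. The size trajectory converts the
    biomass curve into cell count N(t) and equivalent-sphere diameter
    D(t):

    * constant — N tracks biomass, D fixed;
    * stationary_shrink — per-cell volume falls with saturation, so N
      falls less sharply than biomass alone would suggest;
    * filamentation — N frozen during the pulse while per-cell volume
      rises with biomass, then relaxes back as filaments divide.
    """
    traj = size_trajectory or SizeTrajectory()
    if t_grid_s is None:
        t_grid_s = np.arange(0.0, duration_hr * S_PER_HR + 1, DEFAULT_SAMPLING_INTERVAL_S)
    t = np.asarray(t_grid_s, float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if mu_hr < 0:
        raise ValueError("growth rate must be >= 0")
    th = t / S_PER_HR
    if model == "exponential":
        biomass = n0_per_ml * np.exp(mu_hr * th)
    elif model == "logistic":
        k = carrying_capacity_per_ml
        biomass = k / (1.0 + (k / n0_per_ml - 1.0) * np.exp(-mu_hr * th))
    else:
        raise ValueError(f"unknown growth model {model!r}")

    d0 = traj.diameter_um
    if traj.mode == "constant":
        n = biomass.copy()
        diam = np.full_like(t, d0)
    elif traj.mode == "stationary_shrink":
        # per-cell volume shrinks as the culture saturates
        vol_factor = 1.0 - traj.shrink_fraction * biomass / np.max(biomass)
        n = biomass / vol_factor
        diam = d0 * vol_factor ** (1.0 / 3.0)
    else:  # filamentation
        t1 = traj.pulse_start_hr
        t2 = traj.pulse_end_hr
        b1 = float(np.interp(t1, th, biomass))
        vol_factor = np.ones_like(t)
        in_pulse = (th >= t1) & (th <= t2)
        vol_factor[in_pulse] = np.minimum(biomass[in_pulse] / b1, traj.max_amplification)
        after = th > t2
        v2 = float(np.minimum(np.interp(t2, th, biomass) / b1, traj.max_amplification))
        vol_factor[after] = 1.0 + (v2 - 1.0) * np.exp(-(th[after] - t2) / traj.relax_hr)
        n = biomass / vol_factor
        diam = d0 * vol_factor ** (1.0 / 3.0)

    return GrowthTruth(
        time_s=t,
        n_per_ml=n,
        diameter_um=diam,
        params={
            "model": model,
            "mu_hr": mu_hr,
            "n0_per_ml": n0_per_ml,
            "carrying_capacity_per_ml": carrying_capacity_per_ml,
            "size_trajectory": traj,
        },
    )


def simulate_od_readout(
    truth: GrowthTruth,
    n_particle: float = CELL_REFRACTIVE_INDEX,
    context: OpticalContext = WATER,
    path: Optional[PathConfig] = None,
    params: Optional[MultipleScatteringParams] = None,
    n_reads: int = DEFAULT_N_READS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
) -> GrowthCurve:
    """Plate-reader OD readout of a ground-truth growth trajectory.

    Each reported OD is the mean of ``n_reads`` noisy forward-model
    evaluations (multiplicative Gaussian noise of CV ``noise_cv``) using
    the instantaneous equivalent-volume-sphere diameter. Deterministic
    under ``seed``.
    """
    path = path or PathConfig()
    params = params or MultipleScatteringParams()
    rng = np.random.default_rng(seed)
    # sigma depends only on diameter; cache per unique diameter
    diams = np.asarray(truth.diameter_um, float)
    uniq = np.unique(diams)
    sig_map = {
        float(d): effective_sigma_ext(Scatterer(float(d), n_particle), context)
        for d in uniq
    }
    od_true = np.empty_like(diams)
    for i, (c, d) in enumerate(zip(truth.n_per_ml, diams)):
        tau = turbidity(float(c), sig_map[float(d)], path.path_length_cm)
        od_true[i] = tau - params.quad_coeff * tau * tau
        if tau > params.tau_max:
            raise ValueError(
                "growth scenario drives turbidity beyond the forward model's "
                "monotone branch; reduce concentrations or q"
            )
    rows = []
    for _ in range(n_replicates):
        if noise_cv > 0:
            eps = rng.normal(0.0, noise_cv, size=(n_reads, od_true.size))
            od_rep = (od_true[None, :] * (1.0 + eps)).mean(axis=0)
        else:
            od_rep = od_true.copy()
        rows.append(tuple(float(max(v, 0.0)) for v in od_rep))
    return GrowthCurve(
        time_s=tuple(float(v) for v in truth.time_s),
        od=tuple(rows),
    )


# ---------------------------------------------------------------------------
# microscope counting
# ---------------------------------------------------------------------------


def simulate_counting(
    concentration_per_ml: float,
    setup: Optional[CountingSetup] = None,
    seed: int = 0,
) -> dict:
    """Poisson field-of-view counts and the derived concentration estimate.

    Counts per field are Poisson(C · V_field), independent across fields;
    the estimator is mean count / V_field with its SEM.
    """
    if concentration_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    setup = setup or CountingSetup()
    rng = np.random.default_rng(seed)
    lam = concentration_per_ml * setup.field_volume_ml
    counts = rng.poisson(lam, size=setup.n_fields)
    mean = float(np.mean(counts))
    sem_counts = (
        float(np.std(counts, ddof=1) / np.sqrt(setup.n_fields))
        if setup.n_fields > 1
        else float("nan")
    )
    return {
        "counts": counts,
        "field_volume_ml": setup.field_volume_ml,
        "c_estimate_per_ml": mean / setup.field_volume_ml,
        "c_sem_per_ml": sem_counts / setup.field_volume_ml
        if np.isfinite(sem_counts)
        else float("nan"),
    }
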