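"""Calibration curves: robust fitting, inversion, transfer.

The calibration procedure mirrors standard plate-reader practice: trim
saturated readings, fit OD as a quadratic in the known concentration with
a Tukey-bisquare robust loss (IRLS, tuning constant 4.685, MAD scale), and
later invert the stored polynomial to convert OD readings back to cell or
bead concentrations. Cross-instrument transfer is a proportional rescaling
estimated by least squares, as is the alignment of OD traces with direct
microscope counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "DilutionSeries",
    "CalibrationCurve",
    "CrossCalibration",
    "InsufficientDataError",
    "InversionError",
    "trim_saturated",
    "fit_calibration",
    "select_polynomial_degree",
    "invert_calibration",
    "concentration_table",
    "cross_calibrate",
    "align_od_counts",
    "DEFAULT_OD_SAT",
    "FIG2B_OD_VALUES",
]

DEFAULT_OD_SAT = 3.5
#: ODs at which calibration polynomials are conventionally solved.
FIG2B_OD_VALUES = (0.05, 0.1, 0.5, 1.0, 10.0)

SCHEMA_VERSION = 1
BISQUARE_TUNING = 4.685


class InsufficientDataError(ValueError):
    """Too few points remain to fit the requested polynomial."""


class InversionError(ValueError):
    """OD cannot be mapped back to a concentration.

    ``reason`` is "saturated" (above the invertible/valid range) or
    "below_blank" (below the curve's intercept/valid range).
    """

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DilutionSeries:
    """Known concentrations with replicate OD readings.

    ``od_replicates[i]`` holds the replicate readings at
    ``concentrations_per_ml[i]``; concentrations are sorted ascending on
    construction.
    """

    concentrations_per_ml: tuple[float, ...]
    od_replicates: tuple[tuple[float, ...], ...]
    scatterer: Optional[dict] = None
    instrument_id: str = "unknown"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_per_ml, dtype=float)
        if c.size != len(self.od_replicates):
            raise ValueError("one replicate tuple per concentration required")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if any(len(r) < 1 for r in self.od_replicates):
            raise ValueError("each concentration needs at least one OD replicate")
        order = np.argsort(c, kind="stable")
        if np.any(np.diff(c[order]) == 0):
            raise ValueError("concentrations must be distinct")
        object.__setattr__(
            self, "concentrations_per_ml", tuple(float(c[i]) for i in order)
        )
        object.__setattr__(
            self,
            "od_replicates",
            tuple(tuple(float(v) for v in self.od_replicates[i]) for i in order),
        )

    def __len__(self) -> int:
        return len(self.concentrations_per_ml)

    def mean_od(self) -> np.ndarray:
        return np.array([np.mean(r) for r in self.od_replicates])

    def long_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to per-observation (concentration, od) arrays."""
        c, od = [], []
        for ci, reps in zip(self.concentrations_per_ml, self.od_replicates):
            for v in reps:
                c.append(ci)
                od.append(v)
        return np.asarray(c), np.asarray(od)

    def to_frame(self) -> pd.DataFrame:
        c, od = [], []
        rep = []
        for ci, reps in zip(self.concentrations_per_ml, self.od_replicates):
            for j, v in enumerate(reps):
                c.append(ci)
                od.append(v)
                rep.append(j)
        return pd.DataFrame(
            {"concentration_per_ml": c, "od": od, "replicate_id": rep}
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        scatterer: Optional[dict] = None,
        instrument_id: str = "unknown",
    ) -> "DilutionSeries":
        required = {"concentration_per_ml", "od"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        groups = df.groupby("concentration_per_ml", sort=True)["od"].apply(list)
        return cls(
            concentrations_per_ml=tuple(groups.index.to_list()),
            od_replicates=tuple(tuple(v) for v in groups.to_list()),
            scatterer=scatterer,
            instrument_id=instrument_id,
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic calibration OD(C) = p0 + p1·C + p2·C².

    ``coefficients`` are ascending-order (p0, p1, p2). Validity ranges are
    set from the fitted data; inversion outside them raises unless
    explicitly allowed.
    """

    coefficients: tuple[float, ...]
    od_valid_range: tuple[float, float]
    c_valid_range: tuple[float, float]
    rmse: float
    n_points: int
    n_trimmed: int = 0
    robust_weights: Optional[tuple[float, ...]] = None
    scatterer: Optional[dict] = None
    instrument_id: str = "unknown"
    method: str = "bisquare"

    def __post_init__(self) -> None:
        if len(self.coefficients) < 2:
            raise ValueError("need at least linear coefficients")
        if self.coefficients[1] <= 0:
            raise ValueError("p1 must be > 0: OD must rise with C at low C")

    def __call__(self, c) -> np.ndarray | float:
        c = np.asarray(c, dtype=float)
        out = np.polynomial.polynomial.polyval(c, np.asarray(self.coefficients))
        return float(out) if out.ndim == 0 else out

    def derivative(self, c) -> np.ndarray | float:
        p = np.polynomial.polynomial.Polynomial(self.coefficients)
        out = p.deriv()(np.asarray(c, dtype=float))
        return float(out) if np.ndim(out) == 0 else out

    def is_monotone_increasing(self, n_check: int = 257) -> bool:
        grid = np.linspace(*self.c_valid_range, n_check)
        return bool(np.all(self.derivative(grid) > 0))

    def to_json_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "coefficients": list(self.coefficients),
            "od_valid_range": list(self.od_valid_range),
            "c_valid_range": list(self.c_valid_range),
            "scatterer": self.scatterer,
            "instrument_id": self.instrument_id,
            "fit": {
                "method": self.method,
                "tuning": BISQUARE_TUNING,
                "rmse": self.rmse,
                "n_points": self.n_points,
                "n_trimmed": self.n_trimmed,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json_dict(cls, d: dict) -> "CalibrationCurve":
        major = int(d.get("schema_version", -1))
        if major != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported calibration schema version {major} "
                f"(supported: {SCHEMA_VERSION})"
            )
        fit = d.get("fit", {})
        return cls(
            coefficients=tuple(d["coefficients"]),
            od_valid_range=tuple(d["od_valid_range"]),
            c_valid_range=tuple(d["c_valid_range"]),
            rmse=float(fit.get("rmse", float("nan"))),
            n_points=int(fit.get("n_points", 0)),
            n_trimmed=int(fit.get("n_trimmed", 0)),
            scatterer=d.get("scatterer"),
            instrument_id=d.get("instrument_id", "unknown"),
            method=fit.get("method", "bisquare"),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class CrossCalibration:
    """Proportional map od_B ≈ scale·od_A (+ offset) between instruments."""

    scale: float
    offset: float = 0.0
    rmse: float = float("nan")
    instrument_a: str = "A"
    instrument_b: str = "B"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be > 0")

    def convert(self, od_a) -> np.ndarray | float:
        out = self.scale * np.asarray(od_a, dtype=float) + self.offset
        return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def trim_saturated(
    series: DilutionSeries, od_sat: float = DEFAULT_OD_SAT
) -> tuple[DilutionSeries, int]:
    """Drop points whose mean OD reaches the instrument saturation level.

    Returns the trimmed series and the number of removed points; raises
    :class:`InsufficientDataError` when fewer than 4 points remain.
    """
    if not od_sat > 0:
        raise ValueError("od_sat must be > 0")
    keep = [i for i, m in enumerate(series.mean_od()) if m < od_sat]
    n_removed = len(series) - len(keep)
    if len(keep) < 4:
        raise InsufficientDataError(
            f"only {len(keep)} unsaturated points remain (need >= 4)"
        )
    trimmed = DilutionSeries(
        concentrations_per_ml=tuple(series.concentrations_per_ml[i] for i in keep),
        od_replicates=tuple(series.od_replicates[i] for i in keep),
        scatterer=series.scatterer,
        instrument_id=series.instrument_id,
    )
    return trimmed, n_removed


def _design(c: np.ndarray, degree: int, c_scale: float) -> np.ndarray:
    return np.vander(c / c_scale, degree + 1, increasing=True)


def fit_calibration(
    series: DilutionSeries,
    degree: int = 2,
    n_trimmed: int = 0,
) -> CalibrationCurve:
    """Robust polynomial fit of OD against concentration.

    Replicates enter as individual observations; the loss is the Tukey
    bisquare (tuning 4.685) minimized by iteratively reweighted least
    squares with MAD residual scale — the robust fit plate-reader
    calibrations conventionally use. Concentrations are rescaled
    internally for numerical conditioning; reported coefficients are in
    physical units (OD per (ml⁻¹)ᵏ).
    """
    if len(series) < degree + 2:
        raise InsufficientDataError(
            f"{len(series)} distinct concentrations; need >= {degree + 2} "
            f"for a degree-{degree} fit"
        )
    c, od = series.long_arrays()
    c_scale = float(np.max(np.abs(c)))
    if c_scale == 0:
        raise InsufficientDataError("all concentrations are zero")
    exog = _design(c, degree, c_scale)
    model = sm.RLM(od, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
    res = model.fit(maxiter=50, tol=1e-8, scale_est="mad")
    coef_scaled = np.asarray(res.params)
    coefficients = tuple(
        float(p / c_scale**k) for k, p in enumerate(coef_scaled)
    )
    fitted = exog @ coef_scaled
    rmse = float(np.sqrt(np.mean((od - fitted) ** 2)))
    mean_od = series.mean_od()
    curve = CalibrationCurve(
        coefficients=coefficients,
        od_valid_range=(float(np.min(mean_od)), float(np.max(mean_od))),
        c_valid_range=(
            float(series.concentrations_per_ml[0]),
            float(series.concentrations_per_ml[-1]),
        ),
        rmse=rmse,
        n_points=int(od.size),
        n_trimmed=n_trimmed,
        robust_weights=tuple(float(w) for w in res.weights),
        scatterer=series.scatterer,
        instrument_id=series.instrument_id,
    )
    return curve


def select_polynomial_degree(
    series: DilutionSeries,
    alpha: float = 0.01,
    min_degree: int = 1,
    max_degree: int = 4,
) -> int:
    """Lowest polynomial degree adequate for the series by sequential F-tests.

    Ordinary least-squares polynomials of increasing degree are compared by
    nested-model F-tests; the first degree for which adding the next-order
    term is not significant at ``alpha`` is returned.
    """
    c, od = series.long_arrays()
    n = od.size
    c_scale = float(np.max(np.abs(c)))

    def rss(deg: int) -> float:
        X = _design(c, deg, c_scale)
        beta, *_ = np.linalg.lstsq(X, od, rcond=None)
        r = od - X @ beta
        return float(r @ r)

    for deg in range(min_degree, max_degree):
        rss0, rss1 = rss(deg), rss(deg + 1)
        df_denom = n - (deg + 2)
        if df_denom <= 0:
            return deg
        f_stat = (rss0 - rss1) / (rss1 / df_denom) if rss1 > 0 else np.inf
        p = scipy.stats.f.sf(f_stat, 1, df_denom)
        if p >= alpha:
            return deg
    return max_degree


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def invert_calibration(
    curve: CalibrationCurve, od: float, extrapolate: bool = False
) -> float:
    """Concentration at which the calibration polynomial equals ``od``.

    Solves p2·C² + p1·C + (p0 − od) = 0 and returns the root on the
    increasing branch (the one with smaller |C|). By default ``od`` must
    lie within the curve's fitted OD range; ``extrapolate=True`` lifts the
    range check but still requires the parabola to be invertible.
    """
    od_lo, od_hi = curve.od_valid_range
    if not extrapolate:
        if od > od_hi:
            raise InversionError(
                f"od={od:g} above the calibrated range [{od_lo:g}, {od_hi:g}] "
                "(saturated)",
                reason="saturated",
            )
        if od < od_lo:
            raise InversionError(
                f"od={od:g} below the calibrated range [{od_lo:g}, {od_hi:g}] "
                "(below blank)",
                reason="below_blank",
            )
    p = list(curve.coefficients) + [0.0] * (3 - len(curve.coefficients))
    p0, p1, p2 = p[0], p[1], p[2]
    if p2 == 0.0:
        c_root = (od - p0) / p1
    else:
        disc = p1 * p1 - 4.0 * p2 * (p0 - od)
        if disc < 0:
            # only possible for downward-curving parabola with od above vertex
            raise InversionError(
                f"od={od:g} above the vertex of the calibration parabola "
                "(saturated)",
                reason="saturated",
            )
        sq = float(np.sqrt(disc))
        # stable form of the root (-p1 + sq)/(2 p2): for p2 > 0 this is the
        # sole non-negative root, for p2 < 0 the smaller-|C| root on the
        # increasing branch left of the vertex
        c_root = 2.0 * (od - p0) / (p1 + sq)
    if c_root < 0:
        reason = "below_blank" if od < p0 else "saturated"
        raise InversionError(
            f"od={od:g} maps to negative concentration ({reason})", reason=reason
        )
    return float(c_root)


def concentration_table(
    curves: Sequence[CalibrationCurve],
    od_values: Sequence[float] = FIG2B_OD_VALUES,
    labels: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Invert several calibration curves at a set of ODs.

    Rows are curves (labelled by scatterer diameter when available),
    columns the requested ODs; cells outside a curve's invertible range
    are left missing (NaN), never extrapolated.
    """
    if labels is None:
        labels = []
        for i, cv in enumerate(curves):
            d = (cv.scatterer or {}).get("diameter_um")
            labels.append(d if d is not None else f"curve_{i}")
    rows = []
    for cv in curves:
        row = {}
        for od in od_values:
            try:
                row[od] = invert_calibration(cv, od)
            except InversionError:
                row[od] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(labels, name="diameter_um"))
    df.columns.name = "od"
    return df


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------


def cross_calibrate(
    paired_od: Sequence[tuple[float, float]],
    fit_offset: bool = False,
    instrument_a: str = "A",
    instrument_b: str = "B",
) -> CrossCalibration:
    """Relative scale between two instruments from paired readings.

    The default proportional model ``od_B = scale·od_A`` has the closed-form
    least-squares solution Σ od_A·od_B / Σ od_A²; an affine offset can be
    freed on request.
    """
    pairs = np.asarray(paired_od, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (od_A, od_B) pairs")
    a, b = pairs[:, 0], pairs[:, 1]
    if np.all(a == 0):
        raise ValueError("all od_A readings are zero; scale undefined")
    if fit_offset:
        X = np.column_stack([a, np.ones_like(a)])
        (scale, offset), *_ = np.linalg.lstsq(X, b, rcond=None)
    else:
        scale = float(a @ b / (a @ a))
        offset = 0.0
    resid = b - (scale * a + offset)
    return CrossCalibration(
        scale=float(scale),
        offset=float(offset),
        rmse=float(np.sqrt(np.mean(resid**2))),
        instrument_a=instrument_a,
        instrument_b=instrument_b,
    )


def align_od_counts(
    od_time_s: Sequence[float],
    od: Sequence[float],
    count_time_s: Sequence[float],
    counts_per_ml: Sequence[float],
) -> float:
    """Scale factor c minimizing Σ (od(tᵢ) − c·C(tᵢ))².

    Counts are linearly interpolated onto the OD timepoints within the
    overlapping time support; raises if the supports do not overlap.
    """
    od_t = np.asarray(od_time_s, float)
    od_v = np.asarray(od, float)
    ct = np.asarray(count_time_s, float)
    cv = np.asarray(counts_per_ml, float)
    lo, hi = max(od_t.min(), ct.min()), min(od_t.max(), ct.max())
    mask = (od_t >= lo) & (od_t <= hi)
    if not np.any(mask):
        raise ValueError("OD and count series have no overlapping time support")
    c_interp = np.interp(od_t[mask], ct, cv)
    denom = c_interp @ c_interp
    if denom == 0:
        raise ValueError("counts are zero over the overlap; scale undefined")
    return float(od_v[mask] @ c_interp / denom)
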