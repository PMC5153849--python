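"""Growth-curve analysis on OD and concentration time series.

Converts OD traces to cell concentration through a calibration curve
(with per-point validity flags instead of silent extrapolation) and
extracts the standard growth metrics: maximum specific growth rate from a
sliding-window log-linear fit, its timing, lag time by the tangent
construction, and maximum yield. Rates are reported in hr⁻¹; time is kept
in seconds internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, InversionError, invert_calibration

__all__ = [
    "GrowthCurve",
    "ConcentrationCurve",
    "GrowthMetrics",
    "od_to_concentration",
    "growth_rate_series",
    "growth_metrics",
    "summarize_metrics",
    "compare_rate_estimates",
    "FLAG_OK",
    "FLAG_SATURATED",
    "FLAG_BELOW_BLANK",
]

S_PER_HR = 3600.0

FLAG_OK = "ok"
FLAG_SATURATED = "saturated"
FLAG_BELOW_BLANK = "below_blank"


@dataclass(frozen=True)
class GrowthCurve:
    """OD time series; ``od`` has shape (n_replicates, n_timepoints)."""

    time_s: tuple[float, ...]
    od: tuple[tuple[float, ...], ...]
    replicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing (>= 2 points)")
        od = np.asarray(self.od, float)
        if od.ndim != 2 or od.shape[1] != t.size:
            raise ValueError("od must be (n_replicates, n_timepoints)")
        if np.any(od < 0):
            if np.any(od < -1e-3):
                raise ValueError("od values must be >= 0")
            warnings.warn("clipping small negative ODs to 0", stacklevel=2)
            object.__setattr__(
                self, "od", tuple(tuple(max(v, 0.0) for v in row) for row in self.od)
            )
        if not self.replicate_ids:
            object.__setattr__(
                self,
                "replicate_ids",
                tuple(f"rep{i}" for i in range(od.shape[0])),
            )
        elif len(self.replicate_ids) != od.shape[0]:
            raise ValueError("one replicate id per od row required")

    @property
    def time_hr(self) -> np.ndarray:
        return np.asarray(self.time_s) / S_PER_HR

    def values(self) -> np.ndarray:
        return np.asarray(self.od, float)

    def mean(self) -> np.ndarray:
        return self.values().mean(axis=0)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for rid, row in zip(self.replicate_ids, self.od):
            for t, v in zip(self.time_s, row):
                rows.append((rid, t, v))
        return pd.DataFrame(rows, columns=["well", "time_s", "od"])

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "GrowthCurve":
        missing = {"well", "time_s", "od"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        wide = df.pivot(index="well", columns="time_s", values="od").sort_index()
        wide = wide[sorted(wide.columns)]
        if wide.isna().any().any():
            raise ValueError("replicates do not share a common time grid")
        return cls(
            time_s=tuple(float(t) for t in wide.columns),
            od=tuple(tuple(float(v) for v in row) for row in wide.to_numpy()),
            replicate_ids=tuple(str(w) for w in wide.index),
        )


@dataclass(frozen=True)
class ConcentrationCurve:
    """Concentration time series with per-point validity flags."""

    time_s: tuple[float, ...]
    concentration_per_ml: tuple[tuple[float, ...], ...]
    flags: tuple[tuple[str, ...], ...]
    replicate_ids: tuple[str, ...] = ()

    @property
    def time_hr(self) -> np.ndarray:
        return np.asarray(self.time_s) / S_PER_HR

    def values(self) -> np.ndarray:
        return np.asarray(self.concentration_per_ml, float)

    def fraction_valid(self) -> float:
        f = np.asarray(self.flags)
        return float(np.mean(f == FLAG_OK))


@dataclass(frozen=True)
class GrowthMetrics:
    """Summary metrics of one growth trace.

    ``lag_hr`` is NaN (flagged undefined) for non-growing traces.
    """

    mu_max_hr: float
    t_mu_max_hr: float
    lag_hr: float
    yield_max: float

    @property
    def lag_defined(self) -> bool:
        return bool(np.isfinite(self.lag_hr))


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------


def od_to_concentration(
    curve: GrowthCurve,
    calibration: CalibrationCurve,
    volume_factor: float = 1.0,
) -> ConcentrationCurve:
    """Invert a calibration curve pointwise along an OD time series.

    ``volume_factor`` is an optional fill-volume correction applied to the
    ODs before inversion. Points outside the calibration's valid range are
    flagged ("saturated" / "below_blank") with concentration NaN — never
    silently extrapolated. Below-blank points at the start of growth are
    common (inoculum below the calibrated range) and simply mean the
    calibration cannot resolve them.
    """
    conc_rows, flag_rows = [], []
    for row in curve.values():
        conc, flags = [], []
        for od in row:
            try:
                conc.append(invert_calibration(calibration, od * volume_factor))
                flags.append(FLAG_OK)
            except InversionError as err:
                conc.append(float("nan"))
                flags.append(err.reason)
        conc_rows.append(tuple(conc))
        flag_rows.append(tuple(flags))
    return ConcentrationCurve(
        time_s=curve.time_s,
        concentration_per_ml=tuple(conc_rows),
        flags=tuple(flag_rows),
        replicate_ids=curve.replicate_ids,
    )


# ---------------------------------------------------------------------------
# rates and metrics
# ---------------------------------------------------------------------------


def growth_rate_series(
    time_s: Sequence[float],
    values: Sequence[float],
    window_points: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window specific growth rate d ln(v)/dt in hr⁻¹.

    An ordinary least-squares line is fitted to ln(value) vs time in each
    window of ``window_points`` consecutive samples; the slope is assigned
    to the window's central timepoint. Windows containing non-positive or
    non-finite values are skipped.

    Returns (window-center times in s, rates in hr⁻¹).
    """
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    t = np.asarray(time_s, float)
    v = np.asarray(values, float)
    if t.size != v.size:
        raise ValueError("time and value arrays must have equal length")
    if t.size < window_points:
        raise ValueError(
            f"series of {t.size} points shorter than window ({window_points})"
        )
    centers, rates = [], []
    half = window_points // 2
    skipped = 0
    for i in range(t.size - window_points + 1):
        tw = t[i : i + window_points]
        vw = v[i : i + window_points]
        if np.any(~np.isfinite(vw)) or np.any(vw <= 0):
            skipped += 1
            continue
        slope = np.polyfit(tw / S_PER_HR, np.log(vw), 1)[0]
        centers.append(tw[half])
        rates.append(slope)
    if skipped:
        warnings.warn(
            f"skipped {skipped} windows containing non-positive values",
            stacklevel=2,
        )
    return np.asarray(centers), np.asarray(rates)


def growth_metrics(
    time_s: Sequence[float],
    values: Sequence[float],
    window_points: int = 5,
) -> GrowthMetrics:
    """Growth metrics of a single trace (OD or concentration).

    mu_max is the peak of the sliding-window rate series; the lag time is
    where the tangent at the mu_max point (in log space) intersects the
    initial baseline (mean log of the first 3 points), clipped to
    [0, t_mu_max]. For non-growing traces (mu_max <= 0) the lag is NaN.
    """
    t = np.asarray(time_s, float)
    v = np.asarray(values, float)
    yield_max = float(np.nanmax(v))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centers, rates = growth_rate_series(t, v, window_points)
    if rates.size == 0:
        return GrowthMetrics(float("nan"), float("nan"), float("nan"), yield_max)
    k = int(np.argmax(rates))
    mu_max = float(rates[k])
    t_star_hr = float(centers[k] / S_PER_HR)
    # below ~1e-6 hr^-1 the slope is numerical noise on a flat trace and
    # the tangent construction is meaningless
    if mu_max <= 1e-6:
        return GrowthMetrics(mu_max, t_star_hr, float("nan"), yield_max)
    finite = np.isfinite(v) & (v > 0)
    baseline_idx = np.flatnonzero(finite)[:3]
    baseline_log = float(np.mean(np.log(v[baseline_idx])))
    log_at_star = float(np.interp(centers[k], t[finite], np.log(v[finite])))
    lag_hr = t_star_hr + (baseline_log - log_at_star) / mu_max
    lag_hr = float(np.clip(lag_hr, 0.0, t_star_hr))
    return GrowthMetrics(mu_max, t_star_hr, lag_hr, yield_max)


def summarize_metrics(
    per_replicate: Sequence[GrowthMetrics],
) -> dict:
    """Mean ± SEM summary across replicate metrics."""

    def mean_sem(vals: list[float]) -> tuple[float, float]:
        a = np.asarray([x for x in vals if np.isfinite(x)], float)
        if a.size == 0:
            return float("nan"), float("nan")
        sem = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
        return float(a.mean()), sem

    mu, mu_sem = mean_sem([m.mu_max_hr for m in per_replicate])
    tmu, _ = mean_sem([m.t_mu_max_hr for m in per_replicate])
    lag, lag_sem = mean_sem([m.lag_hr for m in per_replicate])
    yld, yld_sem = mean_sem([m.yield_max for m in per_replicate])
    return {
        "mu_max_hr": mu,
        "mu_max_sem": mu_sem,
        "t_mu_max_hr": tmu,
        "lag_hr": lag,
        "lag_sem": lag_sem,
        "yield": yld,
        "yield_sem": yld_sem,
        "n_replicates": len(per_replicate),
    }


def curve_metrics(
    curve: GrowthCurve | ConcentrationCurve, window_points: int = 5
) -> tuple[list[GrowthMetrics], dict]:
    """Per-replicate metrics plus their mean ± SEM summary."""
    per_rep = [
        growth_metrics(curve.time_s, row, window_points) for row in curve.values()
    ]
    return per_rep, summarize_metrics(per_rep)


def compare_rate_estimates(
    od_curve: GrowthCurve,
    conc_curve: ConcentrationCurve,
    window_points: int = 5,
    on_mean: bool = True,
) -> dict:
    """OD-based vs count-based maximum growth rate.

    Returns the ratio mu_max(OD) / mu_max(concentration) and the peak-time
    difference t_mu_max(OD) − t_mu_max(concentration) in hours. When cell
    size changes during growth (filamentation) the OD-based rate
    overestimates the true rate of cell-number increase.

    With ``on_mean`` (default) each curve's replicates are averaged before
    the metrics are computed — the convention for published plate-reader
    traces, and less biased than averaging per-replicate maxima, since the
    max of a noisy rate series is biased upward. Set it to False to
    compare means of per-replicate metrics instead.
    """
    if on_mean:
        with np.errstate(invalid="ignore"):
            od_summary_m = growth_metrics(od_curve.time_s, od_curve.mean(), window_points)
            conc_mean = np.nanmean(conc_curve.values(), axis=0)
            conc_summary_m = growth_metrics(conc_curve.time_s, conc_mean, window_points)
        mu_od, t_od = od_summary_m.mu_max_hr, od_summary_m.t_mu_max_hr
        mu_c, t_c = conc_summary_m.mu_max_hr, conc_summary_m.t_mu_max_hr
    else:
        _, od_summary = curve_metrics(od_curve, window_points)
        _, conc_summary = curve_metrics(conc_curve, window_points)
        mu_od, t_od = od_summary["mu_max_hr"], od_summary["t_mu_max_hr"]
        mu_c, t_c = conc_summary["mu_max_hr"], conc_summary["t_mu_max_hr"]
    return {
        "mu_max_od_hr": mu_od,
        "mu_max_conc_hr": mu_c,
        "mu_ratio": mu_od / mu_c if mu_c else float("nan"),
        "delta_t_peak_hr": t_od - t_c,
    }
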