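"""Per-cell exposure, morphology deltas, pooled summaries and Hill fits.

Each tracked cell is assigned the concentration interpolated from the
measured dye profile at its position, time-averaged (trapezoid over the
imaged time points) into a mean exposure.  Morphology deltas follow the
sign convention that positive values mean shrinking (area) and rounding
(eccentricity).  Pooling across chambers is done on mean exposure, which
absorbs inter-chamber profile differences.  The threshold-like response is
summarized by fitting delta = emax_eff · cⁿ/(cⁿ + EC50ⁿ) by grid search
plus local refinement, with a cell-resampling bootstrap for confidence
intervals; the fit is exposed statsmodels-style as
:class:`HillThresholdModel` / :class:`HillThresholdResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import kendalltau

from .cytometry import GradientProfile
from .errors import DegenerateDesignError, ExtrapolationError, InsufficientDataError


def concentration_at(x_um: float, profile: GradientProfile, c0: float) -> float:
    """Concentration (μg/ml) at a gradient-axis position, from a % profile.

    Linear interpolation of the profile, scaled by c0/100 and clipped to
    [0, c0].  Positions outside the profiled span (plus half a bin) raise
    :class:`ExtrapolationError`.
    """
    pos = profile.positions_um
    if pos.size < 2:
        raise ExtrapolationError("profile has fewer than 2 bins")
    half_bin = 0.5 * float(np.median(np.diff(pos)))
    if not (pos[0] - half_bin <= x_um <= pos[-1] + half_bin):
        raise ExtrapolationError(
            f"x={x_um:.1f} um outside profiled span [{pos[0]:.1f}, {pos[-1]:.1f}]"
        )
    pct = float(np.interp(x_um, pos, profile.intensity_pct))
    return float(np.clip(pct * c0 / 100.0, 0.0, c0))


@dataclass(frozen=True)
class ExposureRecord:
    track_id: int
    t0_min: float
    t_min: float
    mean_concentration_ug_ml: float


def mean_exposure(
    track_rows: pd.DataFrame,
    profiles: dict[float, GradientProfile],
    c0: float,
    t0_min: float,
    t_min: float,
) -> ExposureRecord:
    """Trapezoidal time-average of the cell's local concentration.

    ``track_rows`` needs columns ``time_min`` and ``x_um``; the local
    concentration is interpolated from the profile measured at each imaged
    time point within [t0, t].
    """
    if t_min <= t0_min:
        raise InsufficientDataError("t must exceed t0")
    rows = track_rows[(track_rows["time_min"] >= t0_min) & (track_rows["time_min"] <= t_min)]
    rows = rows.sort_values("time_min")
    if len(rows) < 2:
        raise InsufficientDataError(
            f"track has {len(rows)} time points in [{t0_min}, {t_min}]; need >= 2"
        )
    times = rows["time_min"].to_numpy(float)
    concs = np.array(
        [
            concentration_at(float(x), profiles[float(t)], c0)
            for t, x in zip(times, rows["x_um"].to_numpy(float))
        ]
    )
    mean_c = float(np.trapezoid(concs, times) / (times[-1] - times[0]))
    return ExposureRecord(
        track_id=int(rows["track_id"].iloc[0]) if "track_id" in rows else -1,
        t0_min=float(times[0]),
        t_min=float(times[-1]),
        mean_concentration_ug_ml=float(np.clip(mean_c, 0.0, c0)),
    )


@dataclass(frozen=True)
class MorphologyDelta:
    track_id: int
    time_min: float
    delta_area: float
    delta_eccentricity: float


def morphology_delta(
    row_t0: pd.Series,
    row_t: pd.Series,
    *,
    eccentricity_mode: str = "absolute",
) -> MorphologyDelta:
    """Morphology change between baseline and a later measurement.

    delta_area = (A(t0) − A(t)) / A(t0): positive = the cell shrank.
    delta_eccentricity = e(t0) − e(t): positive = the cell got rounder
    (absolute difference by default; ``fractional`` divides by e(t0)).
    """
    a0 = float(row_t0["area_px"] if "area_px" in row_t0 else row_t0["area_um2"])
    a1 = float(row_t["area_px"] if "area_px" in row_t else row_t["area_um2"])
    if a0 <= 0:
        raise InsufficientDataError("baseline area must be positive")
    e0 = float(row_t0["eccentricity"])
    e1 = float(row_t["eccentricity"])
    de = e0 - e1
    if eccentricity_mode == "fractional":
        de = de / e0 if e0 > 0 else 0.0
    elif eccentricity_mode != "absolute":
        raise ValueError("eccentricity_mode must be 'absolute' or 'fractional'")
    return MorphologyDelta(
        track_id=int(row_t["track_id"]) if "track_id" in row_t else -1,
        time_min=float(row_t["time_min"]) if "time_min" in row_t else math.nan,
        delta_area=(a0 - a1) / a0,
        delta_eccentricity=de,
    )


def pool_and_bin(
    pooled: pd.DataFrame,
    bin_edges: np.ndarray,
    times_min=None,
    *,
    n_min: int = 5,
) -> pd.DataFrame:
    """Box statistics of deltas per (concentration bin, time point).

    ``pooled`` needs columns ``mean_concentration_ug_ml``, ``time_min`` and
    one or more delta columns.  Whiskers are the most extreme points within
    1.5·IQR of the quartiles.  Bins with fewer than ``n_min`` cells are
    flagged ``low_n``.
    """
    if len(pooled) == 0:
        raise InsufficientDataError("empty pool")
    edges = np.asarray(bin_edges, float)
    if times_min is None:
        times_min = sorted(pooled["time_min"].unique())
    delta_cols = [c for c in pooled.columns if c.startswith("delta_")]
    rows = []
    for t in times_min:
        sub = pooled[pooled["time_min"] == t]
        which = np.clip(np.digitize(sub["mean_concentration_ug_ml"], edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            grp = sub[which == b]
            for col in delta_cols:
                vals = grp[col].to_numpy(float)
                if vals.size:
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    iqr = q3 - q1
                    in_lo = vals[vals >= q1 - 1.5 * iqr]
                    in_hi = vals[vals <= q3 + 1.5 * iqr]
                    lo = float(in_lo.min()) if in_lo.size else float(q1)
                    hi = float(in_hi.max()) if in_hi.size else float(q3)
                else:
                    q1 = med = q3 = lo = hi = math.nan
                rows.append(
                    {
                        "time_min": float(t),
                        "bin_lo_ug_ml": float(edges[b]),
                        "bin_hi_ug_ml": float(edges[b + 1]),
                        "metric": col,
                        "median": float(med),
                        "q1": float(q1),
                        "q3": float(q3),
                        "whisker_lo": lo,
                        "whisker_hi": hi,
                        "n": int(vals.size),
                        "low_n": bool(vals.size < n_min),
                    }
                )
    return pd.DataFrame(rows)


def monotonic_trend(pooled: pd.DataFrame, metric: str = "delta_area") -> pd.DataFrame:
    """Descriptive Kendall-tau trend of a delta vs mean exposure, per time."""
    rows = []
    for t, sub in pooled.groupby("time_min"):
        if len(sub) >= 3 and sub["mean_concentration_ug_ml"].nunique() > 1:
            tau, p = kendalltau(sub["mean_concentration_ug_ml"], sub[metric])
        else:
            tau, p = math.nan, math.nan
        rows.append({"time_min": float(t), "metric": metric, "kendall_tau": tau, "p_value": p, "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hill threshold fit (Model / Results)
# ---------------------------------------------------------------------------


@dataclass
class ThresholdFit:
    """Point estimates and bootstrap CI of the Hill threshold fit."""

    ec50_ug_ml: float
    emax_eff: float
    hill_n: float
    residual_norm: float
    ci_ec50: tuple[float, float]
    ci_emax: tuple[float, float]
    ci_hill_n: tuple[float, float]
    n_cells: int
    flags: list = field(default_factory=list)


def _hill(c: np.ndarray, emax: float, ec50: float, n: float) -> np.ndarray:
    c = np.maximum(c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.where(c > 0, c**n, 0.0)
    return emax * cn / (cn + ec50**n)


def _fit_once(conc: np.ndarray, delta: np.ndarray, ec50_grid, n_grid) -> tuple[float, float, float, float]:
    best = (math.inf, 0.0, float(np.median(ec50_grid)), 1.0)
    for ec50 in ec50_grid:
        for n in n_grid:
            h = _hill(conc, 1.0, ec50, n)
            hh = float(h @ h)
            emax = float(h @ delta) / hh if hh > 0 else 0.0
            r = float(np.sum((delta - emax * h) ** 2))
            if r < best[0]:
                best = (r, emax, float(ec50), float(n))
    _, emax, ec50, n = best

    def resid(p):
        return delta - _hill(conc, p[0], math.exp(p[1]), math.exp(p[2]))

    try:
        sol = least_squares(
            resid,
            x0=[emax, math.log(ec50), math.log(n)],
            bounds=([-2.0, math.log(ec50) - 3.0, math.log(0.2)], [2.0, math.log(ec50) + 3.0, math.log(8.0)]),
            max_nfev=200,
        )
        emax, ec50, n = float(sol.x[0]), math.exp(sol.x[1]), math.exp(sol.x[2])
        rnorm = float(np.sqrt(np.sum(sol.fun**2)))
    except Exception:  # pragma: no cover - refinement is best-effort
        rnorm = math.sqrt(best[0])
    return emax, ec50, n, rnorm


class HillThresholdModel:
    """Hill-occupancy model of a morphology delta vs mean drug exposure.

    delta = emax_eff · cⁿ / (cⁿ + EC50ⁿ).  Requires at least 20 cells
    spanning at least 3 distinct concentration levels; a design with no
    concentration spread raises :class:`DegenerateDesignError`.
    """

    def __init__(self, exposure_ug_ml, delta):
        self.exposure = np.asarray(exposure_ug_ml, float)
        self.delta = np.asarray(delta, float)
        if self.exposure.shape != self.delta.shape or self.exposure.ndim != 1:
            raise ValueError("exposure and delta must be equal-length 1D arrays")
        ok = np.isfinite(self.exposure) & np.isfinite(self.delta)
        self.exposure, self.delta = self.exposure[ok], self.delta[ok]
        if self.exposure.size < 20:
            raise DegenerateDesignError(f"need >= 20 cells, got {self.exposure.size}")
        if np.unique(np.round(self.exposure, 6)).size < 3:
            raise DegenerateDesignError("need >= 3 distinct concentration levels")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric: str = "delta_area") -> "HillThresholdModel":
        return cls(df["mean_concentration_ug_ml"].to_numpy(float), df[metric].to_numpy(float))

    def fit(self, *, n_bootstrap: int = 200, seed: int = 0) -> "HillThresholdResults":
        conc, delta = self.exposure, self.delta
        flags: list[str] = []
        pos = conc[conc > 0]
        lo = float(pos.min()) if pos.size else 1e-3
        hi = float(conc.max())
        ec50_grid = np.geomspace(max(lo, 1e-6), max(hi, lo * 10), 25)
        n_grid = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0])

        if float(np.std(delta)) == 0.0:
            flags.append("degenerate-response")
            fit = ThresholdFit(
                ec50_ug_ml=math.nan,
                emax_eff=0.0,
                hill_n=math.nan,
                residual_norm=0.0,
                ci_ec50=(math.nan, math.nan),
                ci_emax=(0.0, 0.0),
                ci_hill_n=(math.nan, math.nan),
                n_cells=conc.size,
                flags=flags,
            )
            return HillThresholdResults(self, fit)

        emax, ec50, n, rnorm = _fit_once(conc, delta, ec50_grid, n_grid)
        if not (lo <= ec50 <= hi):
            flags.append("extrapolated")

        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            boots = np.empty((n_bootstrap, 3))
            coarse_ec50 = np.geomspace(max(lo, 1e-6), max(hi, lo * 10), 12)
            coarse_n = np.array([0.5, 1.0, 2.0, 4.0])
            for b in range(n_bootstrap):
                idx = rng.integers(0, conc.size, conc.size)
                be, bec, bn, _ = _fit_once(conc[idx], delta[idx], coarse_ec50, coarse_n)
                boots[b] = (be, bec, bn)
            ci = np.percentile(boots, [2.5, 97.5], axis=0)
        else:
            ci = np.full((2, 3), math.nan)
        fit = ThresholdFit(
            ec50_ug_ml=ec50,
            emax_eff=emax,
            hill_n=n,
            residual_norm=rnorm,
            ci_ec50=(float(ci[0, 1]), float(ci[1, 1])),
            ci_emax=(float(ci[0, 0]), float(ci[1, 0])),
            ci_hill_n=(float(ci[0, 2]), float(ci[1, 2])),
            n_cells=conc.size,
            flags=flags,
        )
        return HillThresholdResults(self, fit)


class HillThresholdResults:
    """Fitted Hill threshold parameters with bootstrap uncertainty."""

    def __init__(self, model: HillThresholdModel, fit: ThresholdFit):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> dict:
        return {
            "emax_eff": self._fit.emax_eff,
            "ec50_ug_ml": self._fit.ec50_ug_ml,
            "hill_n": self._fit.hill_n,
        }

    @property
    def fit(self) -> ThresholdFit:
        return self._fit

    def predict(self, conc) -> np.ndarray:
        f = self._fit
        return _hill(np.asarray(conc, float), f.emax_eff, f.ec50_ug_ml, f.hill_n)

    def to_dict(self) -> dict:
        f = self._fit
        return {
            "ec50_ug_ml": f.ec50_ug_ml,
            "emax_eff": f.emax_eff,
            "hill_n": f.hill_n,
            "residual_norm": f.residual_norm,
            "ci_ec50": list(f.ci_ec50),
            "ci_emax": list(f.ci_emax),
            "ci_hill_n": list(f.ci_hill_n),
            "n_cells": f.n_cells,
            "flags": list(f.flags),
        }

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Hill threshold fit (delta = emax_eff * c^n / (c^n + EC50^n))",
            f"  n cells:        {f.n_cells}",
            f"  emax_eff:       {f.emax_eff:.4f}   95% CI [{f.ci_emax[0]:.4f}, {f.ci_emax[1]:.4f}]",
            f"  EC50 (ug/ml):   {f.ec50_ug_ml:.4f}   95% CI [{f.ci_ec50[0]:.4f}, {f.ci_ec50[1]:.4f}]",
            f"  Hill n:         {f.hill_n:.3f}   95% CI [{f.ci_hill_n[0]:.3f}, {f.ci_hill_n[1]:.3f}]",
            f"  residual norm:  {f.residual_norm:.4f}",
        ]
        if f.flags:
            lines.append(f"  flags:          {', '.join(f.flags)}")
        return "\n".join(lines)


def fit_threshold(
    exposure_ug_ml,
    delta,
    *,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> ThresholdFit:
    """Convenience wrapper: fit the Hill threshold and return the estimates."""
    model = HillThresholdModel(exposure_ug_ml, delta)
    return model.fit(n_bootstrap=n_bootstrap, seed=seed).fit
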