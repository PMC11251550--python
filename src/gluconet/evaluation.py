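"""Forecast evaluation: RMSE, time lag, and continuous glucose error grid analysis.

CG-EGA judges a glucose forecast clinically rather than numerically.  Each
evaluated point receives a point-error-grid zone (P-EGA: how far the
predicted glucose value is from the reference, with zone limits that relax
when the reference is changing quickly) and a rate-error-grid zone (R-EGA:
how well the predicted rate of change tracks the reference rate).  The two
zones are then combined, separately for hypoglycemia (< 70 mg/dL),
euglycemia (70-180 mg/dL) and hyperglycemia (> 180 mg/dL), into one of three
categories: accurate, benign error, or erroneous.  A forecast can have a low
RMSE yet be clinically erroneous if it jitters — rate errors are penalized
severely — and conversely a lagged, smooth forecast can score well here.

The zone boundaries and per-region combination matrices follow the published
continuous glucose error grid; they are versioned data in this module and
every boundary is pinned by a unit test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ForecastResult",
    "CGEGAResult",
    "rmse",
    "compute_rates",
    "p_ega",
    "r_ega",
    "cg_ega",
    "time_lag",
    "glycemic_region",
]

#: glycemic region boundaries, mg/dL
HYPO_THRESHOLD = 70.0
HYPER_THRESHOLD = 180.0

#: rates are clamped to this range (mg/dL/min) on the rate grid
RATE_CLAMP = 4.0

P_ZONES = ("A", "B", "C", "D", "E")
R_ZONES = ("A", "B", "uC", "lC", "uD", "lD", "uE", "lE")


@dataclass
class ForecastResult:
    """Aligned reference and predicted glucose with rates of change.

    Rates are finite differences over ``step_minutes`` and are NaN at the
    first point (and anywhere the series is not contiguous).
    """

    times: pd.DatetimeIndex
    reference_glucose: np.ndarray
    predicted_glucose: np.ndarray
    step_minutes: float
    reference_rate: np.ndarray = field(default=None)  # type: ignore[assignment]
    predicted_rate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reference_glucose = np.asarray(self.reference_glucose, dtype=float)
        self.predicted_glucose = np.asarray(self.predicted_glucose, dtype=float)
        n = self.reference_glucose.size
        if self.predicted_glucose.size != n or len(self.times) != n:
            raise ValueError("series lengths differ")
        if self.reference_rate is None:
            self.reference_rate = compute_rates(
                self.reference_glucose, self.step_minutes, self.times)
        if self.predicted_rate is None:
            self.predicted_rate = compute_rates(
                self.predicted_glucose, self.step_minutes, self.times)
        self.reference_rate = np.asarray(self.reference_rate, dtype=float)
        self.predicted_rate = np.asarray(self.predicted_rate, dtype=float)
        if self.reference_rate.size != n or self.predicted_rate.size != n:
            raise ValueError("rate series misaligned with glucose series")

    def __len__(self) -> int:
        return self.reference_glucose.size


@dataclass
class CGEGAResult:
    """Per-region accurate/benign/erroneous counts and overall percentages."""

    counts: dict[str, dict[str, int]]      # region -> category -> count
    n_evaluated: int
    point_detail: pd.DataFrame             # per-point zones and categories

    @property
    def percentages(self) -> dict[str, float]:
        """Overall percentages over all evaluated points; they sum to 100."""
        total = max(self.n_evaluated, 1)
        agg = {c: 0 for c in ("accurate", "benign", "erroneous")}
        for region_counts in self.counts.values():
            for c, k in region_counts.items():
                agg[c] += k
        return {c: 100.0 * k / total for c, k in agg.items()}

    def region_percentages(self, region: str) -> dict[str, float]:
        """Percentages within one glycemic region."""
        counts = self.counts[region]
        total = max(sum(counts.values()), 1)
        return {c: 100.0 * k / total for c, k in counts.items()}

    def to_csv(self, destination: str | Path | IO[str]) -> None:
        """Per-point classification (time, ref, pred, region, zones, category)."""
        self.point_detail.to_csv(destination, index=False)


def rmse(result: ForecastResult | None = None, *,
         reference: np.ndarray | None = None,
         predicted: np.ndarray | None = None) -> float:
    """Root-mean-squared error in mg/dL."""
    if result is not None:
        reference = result.reference_glucose
        predicted = result.predicted_glucose
    reference = np.asarray(reference, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if reference.size == 0:
        raise ValueError("empty forecast")
    return float(np.sqrt(np.mean((predicted - reference) ** 2)))


def compute_rates(series: np.ndarray, step_minutes: float,
                  times: pd.DatetimeIndex | None = None) -> np.ndarray:
    """Backward finite-difference rates in mg/dL per minute.

    The first point is NaN (undefined).  If ``times`` is given, rates are
    also NaN wherever the actual spacing differs from ``step_minutes`` (the
    series is not contiguous there, e.g. across dropped samples).
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need >= 2 points to compute rates")
    rates = np.full(series.size, np.nan)
    rates[1:] = np.diff(series) / step_minutes
    if times is not None:
        dt = np.diff(np.asarray(times).astype("datetime64[s]")).astype(float) / 60.0
        rates[1:][~np.isclose(dt, step_minutes)] = np.nan
    return rates


# ---------------------------------------------------------------------------
# P-EGA

def _expansions(reference_rate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # zone A/B limits relax when the reference is moving: upper limits grow
    # by 10 mg/dL for moderate falls (-2..-1 mg/dL/min) and 20 for rapid
    # falls; lower limits likewise for rises
    r = reference_rate
    up = np.where(r < -2.0, 20.0, np.where(r <= -1.0, 10.0, 0.0))
    lo = np.where(r > 2.0, 20.0, np.where(r >= 1.0, 10.0, 0.0))
    return up, lo


def p_ega(reference: np.ndarray, predicted: np.ndarray,
          reference_rate: np.ndarray) -> np.ndarray:
    """Point-error-grid zone (A..E) per evaluated point.

    Zone A means clinically exact (within 20% of reference, or both
    hypoglycemic); E means a reading on the wrong side of the scale that
    would trigger an opposite treatment.  The A/B limits expand with the
    reference rate of change (see ``_expansions``).
    """
    y = np.atleast_1d(np.asarray(reference, dtype=float))
    p = np.atleast_1d(np.asarray(predicted, dtype=float))
    r = np.atleast_1d(np.asarray(reference_rate, dtype=float))
    if (y <= 0).any() or (p <= 0).any():
        raise ValueError("glucose values must be positive")
    up, lo = _expansions(r)

    zone = np.full(y.shape, "B", dtype=object)
    a = ((y <= 70) & (p <= 70 + up)) | ((p <= 1.2 * y + up) & (p >= 0.8 * y - lo))
    e = ((y <= 70) & (p >= 180)) | ((y >= 180) & (p <= 70))
    c = ((y >= 130) & (y <= 180) & (p <= (7.0 / 5.0) * y - 182 - lo)) \
        | ((y >= 70) & (p >= y + 110 + up))
    d = ((y < 70) & (p > 70 + up) & (p < 180)) \
        | ((y > 240) & (p > 70) & (p < 180 - lo))
    zone[d] = "D"
    zone[c] = "C"
    zone[e] = "E"
    zone[a] = "A"
    return zone if np.asarray(reference).ndim else zone[0]


# ---------------------------------------------------------------------------
# R-EGA

def r_ega(reference_rate: np.ndarray, predicted_rate: np.ndarray) -> np.ndarray:
    """Rate-error-grid zone per evaluated point.

    Zones: A (accurate rate), B (benign deviation), uC/lC (over-prediction
    of rate change while the reference is stable), uD/lD (failure to detect
    a rapid reference change), uE/lE (predicted rate opposite to a rapid
    reference change).  The u/l prefix marks whether the predicted rate errs
    above (upper) or below (lower) the reference rate.  Rates are clamped to
    +-4 mg/dL/min, the extent of the published grid.
    """
    dr = np.atleast_1d(np.asarray(reference_rate, dtype=float))
    dp = np.atleast_1d(np.asarray(predicted_rate, dtype=float))
    if np.isnan(dr).any() or np.isnan(dp).any():
        raise ValueError("rates must be defined (non-NaN)")
    dr = np.clip(dr, -RATE_CLAMP, RATE_CLAMP)
    dp = np.clip(dp, -RATE_CLAMP, RATE_CLAMP)

    diff = dp - dr
    same_sign = dr * dp > 0
    ratio_band = same_sign & (dp >= dr / 2.0) & (dp <= 2.0 * dr)
    ratio_band |= same_sign & (dp <= dr / 2.0) & (dp >= 2.0 * dr)  # negative side
    a = (np.abs(diff) <= 1.0) | ratio_band
    b = np.abs(diff) <= 2.0

    u_e = (dr < -1.0) & (dp > 1.0)
    l_e = (dr > 1.0) & (dp < -1.0)
    u_d = (dp >= -1.0) & (dp <= 1.0) & (diff > 2.0)
    l_d = (dp >= -1.0) & (dp <= 1.0) & (diff < -2.0)

    zone = np.full(dr.shape, "B", dtype=object)
    zone[diff > 2.0] = "uC"
    zone[diff < -2.0] = "lC"
    zone[u_d] = "uD"
    zone[l_d] = "lD"
    zone[u_e] = "uE"
    zone[l_e] = "lE"
    zone[a & ~(u_e | l_e)] = "A"
    zone[b & ~a & ~(u_e | l_e | u_d | l_d)] = "B"
    return zone if np.asarray(reference_rate).ndim else zone[0]


# ---------------------------------------------------------------------------
# combination matrices (region -> set of (P zone, R zone) per category)

def _matrix(accurate: str, benign: str, p_cols: tuple[str, ...]
            ) -> dict[tuple[str, str], str]:
    """Build a (P, R) -> category map from compact row strings.

    ``accurate``/``benign`` hold one row per R zone (order of R_ZONES), one
    character per P column: 'x' marks membership.  Everything else in the
    P columns x R zones grid is erroneous.
    """
    table: dict[tuple[str, str], str] = {}
    acc_rows = accurate.split()
    ben_rows = benign.split()
    for ri, rz in enumerate(R_ZONES):
        for pi, pz in enumerate(p_cols):
            if acc_rows[ri][pi] == "x":
                table[(pz, rz)] = "accurate"
            elif ben_rows[ri][pi] == "x":
                table[(pz, rz)] = "benign"
            else:
                table[(pz, rz)] = "erroneous"
    return table


# hypoglycemia: P columns A, D, E.  Only an exact point reading with a
# no-worse-than-benign rate escapes "erroneous"; any D/E point reading or
# opposite-direction rate is life-threatening here.
_HYPO = _matrix(
    accurate="""
        x..
        x..
        ...
        ...
        ...
        ...
        ...
        ...
    """,
    benign="""
        ...
        ...
        x..
        x..
        x..
        x..
        ...
        ...
    """,
    p_cols=("A", "D", "E"),
)

# euglycemia: P columns A, B, C.  Point zones A/B with tracking rates are
# accurate; rate overshoots/misses (C/D rates) and point zone C are benign
# in the safe band; opposite-direction rates are erroneous.
_EU = _matrix(
    accurate="""
        xx.
        xx.
        ...
        ...
        ...
        ...
        ...
        ...
    """,
    benign="""
        ..x
        ..x
        xxx
        xxx
        xxx
        xxx
        ...
        ...
    """,
    p_cols=("A", "B", "C"),
)

# hyperglycemia: full P columns A..E.  Point zones C/D with benign rates are
# tolerable at high glucose; E points or E rates never are.
_HYPER = _matrix(
    accurate="""
        xx...
        xx...
        .....
        .....
        .....
        .....
        .....
        .....
    """,
    benign="""
        ..xx.
        ..xx.
        xxxx.
        xxxx.
        xxxx.
        xxxx.
        .....
        .....
    """,
    p_cols=("A", "B", "C", "D", "E"),
)

_REGION_MATRICES: dict[str, dict[tuple[str, str], str]] = {
    "hypoglycemia": _HYPO,
    "euglycemia": _EU,
    "hyperglycemia": _HYPER,
}


def glycemic_region(reference: np.ndarray) -> np.ndarray:
    """Region label per point from the reference glucose."""
    y = np.atleast_1d(np.asarray(reference, dtype=float))
    region = np.full(y.shape, "euglycemia", dtype=object)
    region[y < HYPO_THRESHOLD] = "hypoglycemia"
    region[y > HYPER_THRESHOLD] = "hyperglycemia"
    return region if np.asarray(reference).ndim else region[0]


def cg_ega(result: ForecastResult) -> CGEGAResult:
    """Classify every evaluable point as accurate / benign / erroneous.

    Points without defined rates (the first point, or breaks in the series)
    are excluded.  A (P zone, R zone) pair absent from a region's published
    matrix — possible only at region boundaries — counts as erroneous.
    """
    ok = ~np.isnan(result.reference_rate) & ~np.isnan(result.predicted_rate)
    if not ok.any():
        raise ValueError("no evaluable points (rates undefined everywhere)")
    y = result.reference_glucose[ok]
    p = result.predicted_glucose[ok]
    dr = result.reference_rate[ok]
    dp = result.predicted_rate[ok]

    p_zone = p_ega(y, p, dr)
    r_zone = r_ega(dr, dp)
    region = glycemic_region(y)
    category = np.array([
        _REGION_MATRICES[reg].get((pz, rz), "erroneous")
        for reg, pz, rz in zip(region, p_zone, r_zone)
    ], dtype=object)

    counts: dict[str, dict[str, int]] = {
        reg: {c: 0 for c in ("accurate", "benign", "erroneous")}
        for reg in _REGION_MATRICES
    }
    for reg, cat in zip(region, category):
        counts[reg][cat] += 1

    detail = pd.DataFrame({
        "time": np.asarray(result.times)[ok],
        "reference_glucose": y,
        "predicted_glucose": p,
        "region": region,
        "p_zone": p_zone,
        "r_zone": r_zone,
        "category": category,
    })
    return CGEGAResult(counts=counts, n_evaluated=int(ok.sum()),
                       point_detail=detail)


# ---------------------------------------------------------------------------
# time lag

def time_lag(result: ForecastResult, max_shift_minutes: float = 60.0) -> float:
    """Forecast delay in minutes, by cross-correlation argmax.

    Scans non-negative shifts of whole sampling steps up to
    ``max_shift_minutes`` and returns the shift maximizing the Pearson
    correlation between the delayed prediction and the reference.  Constant
    (degenerate) series yield 0 with a warning.
    """
    step = result.step_minutes
    max_shift = int(max_shift_minutes // step)
    n = len(result)
    if n <= max_shift + 1:
        raise ValueError("series too short for the requested maximum shift")
    ref = result.reference_glucose
    pred = result.predicted_glucose
    if np.std(ref) == 0 or np.std(pred) == 0:
        warnings.warn("constant series: time lag undefined, reporting 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    best_shift, best_corr = 0, -np.inf
    for s in range(max_shift + 1):
        a = pred[s:] if s else pred
        b = ref[: n - s] if s else ref
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        corr = float(np.corrcoef(a, b)[0, 1])
        if corr > best_corr:
            best_shift, best_corr = s, corr
    return best_shift * step
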