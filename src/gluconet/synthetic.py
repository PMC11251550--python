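"""Synthetic continuous glucose monitoring (CGM) cohorts and device traces.

Real CGM benchmark data for type-1 diabetes (e.g. the OhioT1DM study cohorts)
is distributed under a data-use agreement, so this module generates series
with the same statistical structure: 5-minute uniform sampling, meal-driven
postprandial excursions, slow circadian drift of the baseline, autocorrelated
sensor noise, device-dropout gaps, and an 8-week duration whose last 10 days
serve as the test split.  It also simulates conductance sweeps of an
electrochemical neuromorphic organic device (ENODe): a "set" ramp of
increasing channel conductance followed by a "reset" ramp back down, the raw
material for discrete network weight states.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

__all__ = [
    "CGMSeries",
    "CGMGenParams",
    "DeviceTrace",
    "generate_cgm_cohort",
    "generate_device_trace",
    "write_ohio_xml",
    "read_ohio_xml",
    "write_cgm_csv",
    "read_cgm_csv",
    "write_device_trace_csv",
    "read_device_trace_csv",
]

#: physiological clipping range of generated glucose, mg/dL
GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 400.0

#: hard validity range for observed readings, mg/dL
VALID_MIN = 20.0
VALID_MAX = 600.0

_OHIO_TS_FORMAT = "%d-%m-%Y %H:%M:%S"


@dataclass
class CGMSeries:
    """One patient's uniformly gridded glucose trace with a missing-value mask.

    Parameters
    ----------
    patient_id : str
        Opaque patient label.
    start_time : pandas.Timestamp
        Time of the first grid point.
    sampling_interval : int
        Minutes between grid points (5 for standard CGM sensors).
    values : ndarray of float
        Glucose in mg/dL on the uniform grid.  Entries where
        ``observed_mask`` is False may be NaN until gap filling.
    observed_mask : ndarray of bool
        True where the sensor actually reported a reading.
    fill_status : ndarray of str, optional
        Set by :func:`gluconet.preprocessing.fill_gaps`; one of
        ``"observed"``, ``"interpolated"``, ``"extrapolated"`` per point.
    """

    patient_id: str
    start_time: pd.Timestamp
    sampling_interval: int
    values: np.ndarray
    observed_mask: np.ndarray
    fill_status: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.start_time = pd.Timestamp(self.start_time)
        if self.values.shape != self.observed_mask.shape or self.values.ndim != 1:
            raise ValueError("values and observed_mask must be aligned 1-D arrays")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive minutes")
        obs = self.values[self.observed_mask]
        if obs.size and (np.isnan(obs).any() or (obs < VALID_MIN).any() or (obs > VALID_MAX).any()):
            raise ValueError(
                f"observed glucose must lie in [{VALID_MIN}, {VALID_MAX}] mg/dL"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> pd.DatetimeIndex:
        """Timestamps of the grid points."""
        return pd.date_range(
            self.start_time, periods=len(self), freq=f"{self.sampling_interval}min"
        )

    def to_frame(self) -> pd.DataFrame:
        """Observed points as a tidy frame (unobserved rows absent)."""
        t = self.times[self.observed_mask]
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "timestamp": t,
                "glucose_mg_dl": self.values[self.observed_mask],
            }
        )


@dataclass(frozen=True)
class CGMGenParams:
    """Generator settings for one synthetic CGM cohort.

    Defaults emulate an adult type-1 cohort on a 5-minute sensor:
    a euglycemic-to-mildly-elevated baseline with a gentle circadian swing,
    three daytime meals with postprandial rises of a few tens of mg/dL,
    strongly autocorrelated sensor noise, and roughly one dropout gap per day.
    """

    baseline: float = 140.0          # mg/dL
    circadian_amplitude: float = 15.0  # mg/dL
    meals_per_day: int = 3
    meal_amplitude_range: tuple[float, float] = (40.0, 120.0)  # mg/dL
    meal_rise_minutes: float = 30.0
    meal_decay_minutes: float = 90.0
    ar_coefficient: float = 0.8      # lag-1 autocorrelation of sensor noise
    noise_sd: float = 5.0            # marginal sd of sensor noise, mg/dL
    gap_rate: float = 1.0            # expected dropout gaps per day
    gap_length_range: tuple[float, float] = (15.0, 120.0)  # minutes
    days: int = 56
    sampling_interval: int = 5       # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        for name in ("circadian_amplitude", "noise_sd", "gap_rate",
                     "meal_rise_minutes", "meal_decay_minutes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.meals_per_day < 0:
            raise ValueError("meals_per_day must be non-negative")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        lo, hi = self.meal_amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("meal_amplitude_range must be 0 <= low <= high")
        lo, hi = self.gap_length_range
        if lo < 0 or hi < lo:
            raise ValueError("gap_length_range must be 0 <= low <= high")
        if self.days < 1 or self.sampling_interval < 1:
            raise ValueError("days and sampling_interval must be >= 1")


@dataclass(frozen=True)
class DeviceTrace:
    """A conductance sweep: (pulse_index, direction, conductance) triples.

    ``direction`` is ``"set"`` while gate pulses potentiate the channel
    (conductance rising) and ``"reset"`` while they depress it.
    Conductances are in siemens.
    """

    entries: tuple[tuple[int, str, float], ...]

    def __post_init__(self) -> None:
        dirs = {d for _, d, _ in self.entries}
        if not dirs <= {"set", "reset"}:
            raise ValueError("direction must be 'set' or 'reset'")
        if "set" not in dirs or "reset" not in dirs:
            raise ValueError("trace needs at least one set and one reset sweep")
        if any(g <= 0 for _, _, g in self.entries):
            raise ValueError("conductance must be positive")

    def conductances(self, direction: Literal["set", "reset"]) -> np.ndarray:
        """Conductance readings of one direction in pulse order."""
        return np.array([g for _, d, g in self.entries if d == direction])


# ---------------------------------------------------------------------------
# CGM generation

def _meal_kernel(minutes: np.ndarray, rise: float, decay: float) -> np.ndarray:
    # log-normal-shaped bump: smooth, positive, asymmetric; peak height 1 at
    # t = rise, width controlled by the decay/rise ratio
    out = np.zeros_like(minutes, dtype=float)
    pos = minutes > 0
    if rise <= 0:
        rise = 1.0
    sigma = 0.5 * np.log1p(decay / rise)
    sigma = max(sigma, 1e-3)
    t = minutes[pos]
    out[pos] = np.exp(-((np.log(t / rise)) ** 2) / (2.0 * sigma**2))
    return out


_MEAL_WINDOWS = ((6.0, 9.0), (11.5, 14.5), (17.5, 20.5))  # hours of day


def _generate_one(params: CGMGenParams, patient_id: str,
                  rng: np.random.Generator) -> CGMSeries:
    per_day = 24 * 60 // params.sampling_interval
    n = per_day * params.days
    minutes = np.arange(n) * float(params.sampling_interval)
    hours = (minutes / 60.0) % 24.0

    # circadian drift: one sinusoid, trough in the early morning (~4 am)
    signal = params.baseline + params.circadian_amplitude * np.sin(
        2 * np.pi * (hours - 10.0) / 24.0
    )

    # meals: per day, one draw per daytime window up to meals_per_day
    for day in range(params.days):
        windows = _MEAL_WINDOWS[: params.meals_per_day]
        extra = max(0, params.meals_per_day - len(_MEAL_WINDOWS))
        starts = [rng.uniform(lo, hi) for lo, hi in windows]
        starts += list(rng.uniform(6.0, 21.0, size=extra))
        for start_h in starts:
            amp = rng.uniform(*params.meal_amplitude_range)
            t0 = day * 24 * 60 + start_h * 60.0
            signal += amp * _meal_kernel(minutes - t0, params.meal_rise_minutes,
                                         params.meal_decay_minutes)

    # AR(1) sensor noise with marginal sd = noise_sd, lag-1 corr = phi
    phi = params.ar_coefficient
    if params.noise_sd > 0:
        innov_sd = params.noise_sd * np.sqrt(1.0 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, params.noise_sd)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + eps[i]
        signal = signal + noise
    else:
        rng.normal(size=n + 1)  # keep stream position stable across settings

    values = np.clip(signal, GLUCOSE_MIN, GLUCOSE_MAX)

    # dropout gaps: Poisson count over the record, uniform starts, uniform
    # lengths in whole sampling intervals
    mask = np.ones(n, dtype=bool)
    n_gaps = rng.poisson(params.gap_rate * params.days)
    lo, hi = params.gap_length_range
    for _ in range(n_gaps):
        length = int(round(rng.uniform(lo, hi) / params.sampling_interval))
        length = max(length, 1)
        start = int(rng.integers(0, n))
        mask[start : start + length] = False

    values = values.copy()
    values[~mask] = np.nan
    return CGMSeries(
        patient_id=patient_id,
        start_time=pd.Timestamp("2021-12-07 00:00:00"),
        sampling_interval=params.sampling_interval,
        values=values,
        observed_mask=mask,
    )


def generate_cgm_cohort(params: CGMGenParams, n_patients: int) -> list[CGMSeries]:
    """Generate a cohort of synthetic CGM series.

    Each series is baseline + circadian sinusoid + meal-response bumps at
    random daytime meal times + AR(1) sensor noise, clipped to
    [40, 400] mg/dL, with dropout gaps marked unobserved.  Patients use
    independent substreams of ``params.seed``, so the cohort is reproducible
    and any prefix of it is unchanged by ``n_patients``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    streams = np.random.SeedSequence(params.seed).spawn(n_patients)
    return [
        _generate_one(params, f"S{1 + i:03d}", np.random.default_rng(s))
        for i, s in enumerate(streams)
    ]


# ---------------------------------------------------------------------------
# Device trace generation

def generate_device_trace(
    n_states: int,
    nonlinearity: float = 0.0,
    noise_sd: float = 0.0,
    g_min: float = 1e-6,
    g_max: float = 1e-4,
    seed: int = 0,
) -> DeviceTrace:
    """Simulate an ENODe-style conductance sweep.

    A set sweep of ``n_states`` conductances rises from ``g_min`` to
    ``g_max``; a reset sweep falls back.  ``nonlinearity`` bends the ramps
    exponentially (0 gives exactly equal spacing; positive values compress
    states near ``g_max`` on set and near ``g_min`` on reset, the saturation
    shape typical of real devices).  Gaussian read noise of ``noise_sd``
    siemens is added per reading.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if not g_min < g_max:
        raise ValueError("g_min must be < g_max")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_states)
    if nonlinearity == 0.0:
        ramp = x
    else:
        ramp = (1.0 - np.exp(-nonlinearity * x)) / (1.0 - np.exp(-nonlinearity))
    set_g = g_min + (g_max - g_min) * ramp
    reset_g = set_g[::-1].copy()
    if noise_sd > 0:
        set_g = set_g + rng.normal(0.0, noise_sd, size=n_states)
        reset_g = reset_g + rng.normal(0.0, noise_sd, size=n_states)
    set_g = np.maximum(set_g, 1e-12)
    reset_g = np.maximum(reset_g, 1e-12)
    entries = [(i, "set", float(g)) for i, g in enumerate(set_g)]
    entries += [(n_states + i, "reset", float(g)) for i, g in enumerate(reset_g)]
    return DeviceTrace(entries=tuple(entries))


# ---------------------------------------------------------------------------
# I/O: OhioT1DM-style XML dialect and CSV

def write_ohio_xml(series: CGMSeries, destination: str | Path | IO[bytes]) -> None:
    """Write one patient's observed readings in the OhioT1DM XML dialect.

    The document is ``<patient id=...><glucose_level><event ts=... value=.../>
    ...</glucose_level></patient>``; timestamps use day-month-year format and
    values are integer mg/dL.  Unobserved grid points are omitted.
    """
    root = ET.Element("patient", id=str(series.patient_id))
    glucose = ET.SubElement(root, "glucose_level")
    times = series.times
    for i in np.flatnonzero(series.observed_mask):
        ET.SubElement(
            glucose,
            "event",
            ts=times[i].strftime(_OHIO_TS_FORMAT),
            value=str(int(round(series.values[i]))),
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    if hasattr(destination, "write"):
        tree.write(destination, encoding="utf-8", xml_declaration=True)
    else:
        with open(destination, "wb") as fh:
            tree.write(fh, encoding="utf-8", xml_declaration=True)


def read_ohio_xml(source: str | Path | IO[bytes],
                  sampling_interval: int = 5) -> CGMSeries:
    """Read a patient document in the OhioT1DM XML dialect onto a uniform grid.

    Events are snapped to the nearest grid point relative to the first event;
    grid points without an event are marked unobserved.
    """
    root = ET.parse(source).getroot()
    pid = root.get("id", "unknown")
    events = root.findall("./glucose_level/event")
    if not events:
        return CGMSeries(pid, pd.Timestamp("1970-01-01"), sampling_interval,
                         np.array([]), np.array([], dtype=bool))
    ts = pd.to_datetime([e.get("ts") for e in events], format=_OHIO_TS_FORMAT)
    vals = np.array([float(e.get("value")) for e in events])
    start = ts[0]
    idx = np.round((ts - start).total_seconds() / 60.0 / sampling_interval
                   ).astype(int)
    n = int(idx.max()) + 1
    values = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    values[idx] = vals
    mask[idx] = True
    return CGMSeries(pid, start, sampling_interval, values, mask)


def write_cgm_csv(cohort: Iterable[CGMSeries],
                  destination: str | Path | IO[str]) -> None:
    """Write observed readings of a cohort as tidy CSV (missing rows absent)."""
    frame = pd.concat([s.to_frame() for s in cohort], ignore_index=True)
    frame.to_csv(destination, index=False)


def read_cgm_csv(source: str | Path | IO[str],
                 sampling_interval: int = 5) -> list[CGMSeries]:
    """Read a tidy CGM CSV back into per-patient gridded series."""
    frame = pd.read_csv(source, parse_dates=["timestamp"])
    out = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        ts = pd.DatetimeIndex(grp["timestamp"])
        start = ts[0]
        idx = np.round((ts - start).total_seconds() / 60.0 / sampling_interval
                       ).astype(int)
        n = int(idx.max()) + 1
        values = np.full(n, np.nan)
        mask = np.zeros(n, dtype=bool)
        values[idx] = grp["glucose_mg_dl"].to_numpy()
        mask[idx] = True
        out.append(CGMSeries(str(pid), start, sampling_interval, values, mask))
    return out


def write_device_trace_csv(trace: DeviceTrace,
                           destination: str | Path | IO[str]) -> None:
    """Write a conductance trace as CSV (pulse_index, direction, conductance_S)."""
    pd.DataFrame(
        trace.entries, columns=["pulse_index", "direction", "conductance_S"]
    ).to_csv(destination, index=False)


def read_device_trace_csv(source: str | Path | IO[str]) -> DeviceTrace:
    """Read a conductance trace CSV written by :func:`write_device_trace_csv`."""
    frame = pd.read_csv(source)
    entries = tuple(
        (int(r.pulse_index), str(r.direction), float(r.conductance_S))
        for r in frame.itertuples()
    )
    return DeviceTrace(entries=entries)
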