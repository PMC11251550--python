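"""GLYFE-style CGM preprocessing.

Gap filling by linear interpolation/extrapolation, supervised sample
construction under sampling- and prediction-frequency configurations,
cohort pooling, chronological cross-validation folds, and standardization
fitted on the training partition only.  Targets are never imputed readings:
samples whose ground truth is unknown are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .synthetic import CGMSeries

__all__ = [
    "SampleConfig",
    "SampleSet",
    "ScalingParams",
    "UnrecoverableSeriesError",
    "fill_gaps",
    "build_samples",
    "combine_cohort",
    "split_folds",
    "standardize",
    "train_test_split_days",
]

logger = logging.getLogger(__name__)

#: days held out at the end of each patient record, matching the benchmark
#: protocol (8 weeks of data, last 10 days as test)
TEST_TAIL_DAYS = 10


class UnrecoverableSeriesError(ValueError):
    """Raised when a series has too few observed points to fill."""


@dataclass(frozen=True)
class SampleConfig:
    """How supervised samples are cut from a glucose series.

    ``sampling_frequency_minutes`` is the spacing of history points ("one
    sample every n minutes"); ``prediction_frequency_minutes`` is the spacing
    of successive supervised samples ("one prediction every n minutes"),
    which thins the training set without changing the input layout.
    """

    history_minutes: int = 180
    sampling_frequency_minutes: int = 5
    prediction_frequency_minutes: int = 5
    horizon_minutes: int = 30
    features: tuple[str, ...] = ("glucose",)

    def __post_init__(self) -> None:
        for name in ("history_minutes", "sampling_frequency_minutes",
                     "prediction_frequency_minutes", "horizon_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.history_minutes < self.sampling_frequency_minutes:
            raise ValueError("history must cover at least one sampling period")
        if tuple(self.features) != ("glucose",):
            raise ValueError("only the glucose feature is supported")

    @classmethod
    def two_point(cls, span_minutes: int, horizon_minutes: int = 30,
                  prediction_frequency_minutes: int = 5) -> "SampleConfig":
        """A two-node history: glucose now and ``span_minutes`` in the past."""
        return cls(
            history_minutes=2 * span_minutes,
            sampling_frequency_minutes=span_minutes,
            prediction_frequency_minutes=prediction_frequency_minutes,
            horizon_minutes=horizon_minutes,
        )

    @property
    def history_points(self) -> int:
        """Number of history points per feature."""
        return self.history_minutes // self.sampling_frequency_minutes

    @property
    def input_nodes(self) -> int:
        """Total input nodes = features x history points."""
        return len(self.features) * self.history_points


@dataclass
class ScalingParams:
    """Standardization parameters fitted on a training sample set."""

    input_mean: np.ndarray
    input_sd: np.ndarray
    target_mean: float
    target_sd: float

    def __post_init__(self) -> None:
        self.input_mean = np.asarray(self.input_mean, dtype=float)
        self.input_sd = np.asarray(self.input_sd, dtype=float)
        if (self.input_sd <= 0).any() or self.target_sd <= 0:
            raise ValueError("standard deviations must be positive")

    def transform_inputs(self, x: np.ndarray) -> np.ndarray:
        return (x - self.input_mean) / self.input_sd

    def inverse_inputs(self, x: np.ndarray) -> np.ndarray:
        return x * self.input_sd + self.input_mean

    def transform_targets(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_mean) / self.target_sd

    def inverse_targets(self, y: np.ndarray) -> np.ndarray:
        """Map standardized predictions back to mg/dL."""
        return y * self.target_sd + self.target_mean

    def to_json(self, destination: str | Path | IO[str]) -> None:
        payload = {
            "input_mean": self.input_mean.tolist(),
            "input_sd": self.input_sd.tolist(),
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
        }
        if hasattr(destination, "write"):
            json.dump(payload, destination)
        else:
            Path(destination).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, source: str | Path | IO[str]) -> "ScalingParams":
        data = json.load(source) if hasattr(source, "read") else json.loads(
            Path(source).read_text())
        return cls(np.array(data["input_mean"]), np.array(data["input_sd"]),
                   data["target_mean"], data["target_sd"])


@dataclass
class SampleSet:
    """Supervised (history -> future glucose) examples.

    ``inputs`` is (n_samples, input_nodes); ``targets`` is future glucose at
    the prediction horizon.  Both are raw mg/dL until :func:`standardize`
    sets ``scaling`` and the ``standardized`` flag.
    """

    inputs: np.ndarray
    targets: np.ndarray
    timestamps: pd.DatetimeIndex
    config: SampleConfig
    patient_ids: np.ndarray
    scaling: ScalingParams | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids)
        n = len(self.targets)
        if self.inputs.shape[0] != n or len(self.timestamps) != n \
                or len(self.patient_ids) != n:
            raise ValueError("inputs, targets, timestamps, patient_ids misaligned")

    def __len__(self) -> int:
        return len(self.targets)

    def subset(self, index: np.ndarray) -> "SampleSet":
        return SampleSet(
            self.inputs[index], self.targets[index], self.timestamps[index],
            self.config, self.patient_ids[index], self.scaling,
            self.standardized,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{i}": self.inputs[:, i] for i in range(self.inputs.shape[1])}
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "timestamp": self.timestamps,
             **cols, "target": self.targets}
        )


# ---------------------------------------------------------------------------
# gap filling

def fill_gaps(series: CGMSeries) -> CGMSeries:
    """Fill unobserved points: linear interpolation inside, extrapolation at edges.

    Interior gaps are filled linearly between the nearest observed
    neighbours.  Leading/trailing gaps, where interpolation is impossible,
    are filled by linear extrapolation from the two nearest observed points.
    The returned series keeps the original ``observed_mask`` and carries a
    per-point ``fill_status`` of observed / interpolated / extrapolated.
    """
    obs_idx = np.flatnonzero(series.observed_mask)
    if obs_idx.size < 2:
        raise UnrecoverableSeriesError(
            f"series {series.patient_id!r}: need >= 2 observed points, "
            f"got {obs_idx.size}"
        )
    n = len(series)
    idx = np.arange(n)
    values = np.interp(idx, obs_idx, series.values[obs_idx])

    first, last = obs_idx[0], obs_idx[-1]
    status = np.where(series.observed_mask, "observed", "interpolated")
    if first > 0:
        x0, x1 = obs_idx[0], obs_idx[1]
        slope = (series.values[x1] - series.values[x0]) / (x1 - x0)
        values[:first] = series.values[x0] + slope * (idx[:first] - x0)
        status[:first] = "extrapolated"
    if last < n - 1:
        x0, x1 = obs_idx[-2], obs_idx[-1]
        slope = (series.values[x1] - series.values[x0]) / (x1 - x0)
        values[last + 1:] = series.values[x1] + slope * (idx[last + 1:] - x1)
        status[last + 1:] = "extrapolated"

    return CGMSeries(
        patient_id=series.patient_id,
        start_time=series.start_time,
        sampling_interval=series.sampling_interval,
        values=values,
        observed_mask=series.observed_mask.copy(),
        fill_status=status,
    )


# ---------------------------------------------------------------------------
# sample construction

def _check_multiple(name: str, minutes: int, interval: int) -> int:
    if minutes % interval:
        raise ValueError(f"{name} ({minutes} min) must be a multiple of the "
                         f"grid interval ({interval} min)")
    return minutes // interval


def build_samples(series: CGMSeries, config: SampleConfig) -> SampleSet:
    """Cut supervised samples from a gap-filled series.

    One sample is emitted per prediction time, stepping by the prediction
    frequency.  The input holds glucose at times t, t-f, t-2f, ... covering
    the configured history; the target is glucose at t + horizon.  Samples
    whose target index is unobserved (imputed) or out of range are dropped,
    as are prediction times whose history would precede the series start.
    """
    if np.isnan(series.values).any():
        raise ValueError("series must be gap-filled before building samples")
    interval = series.sampling_interval
    f = _check_multiple("sampling_frequency_minutes",
                        config.sampling_frequency_minutes, interval)
    p = _check_multiple("prediction_frequency_minutes",
                        config.prediction_frequency_minutes, interval)
    h = _check_multiple("horizon_minutes", config.horizon_minutes, interval)
    m = config.history_points

    n = len(series)
    first_t = (m - 1) * f                      # earliest index with full history
    t_candidates = np.arange(first_t, n, p)
    n_skipped_history = int(np.sum(np.arange(0, n, p) < first_t))
    if n_skipped_history:
        logger.debug("dropped %d prediction times lacking full history",
                     n_skipped_history)

    target_idx = t_candidates + h
    in_range = target_idx < n
    t_candidates, target_idx = t_candidates[in_range], target_idx[in_range]
    ground_truth = series.observed_mask[target_idx]
    t_candidates, target_idx = t_candidates[ground_truth], target_idx[ground_truth]

    # input layout: most recent value first, then progressively older
    hist_idx = t_candidates[:, None] - (np.arange(m) * f)[None, :]
    inputs = series.values[hist_idx]
    targets = series.values[target_idx]
    times = series.times[t_candidates]
    pids = np.repeat(series.patient_id, len(t_candidates))
    return SampleSet(inputs, targets, times, config, pids)


def combine_cohort(training_series: Sequence[CGMSeries],
                   config: SampleConfig) -> SampleSet:
    """Pool several patients' samples into one training set, tagged by patient."""
    if len(training_series) == 0:
        raise ValueError("need at least one series")
    parts = [build_samples(s, config) for s in training_series]
    return SampleSet(
        np.vstack([p.inputs for p in parts]),
        np.concatenate([p.targets for p in parts]),
        pd.DatetimeIndex(np.concatenate([np.asarray(p.timestamps) for p in parts])),
        config,
        np.concatenate([p.patient_ids for p in parts]),
    )


def train_test_split_days(series: CGMSeries,
                          test_days: int = TEST_TAIL_DAYS
                          ) -> tuple[CGMSeries, CGMSeries]:
    """Split one patient record chronologically, last ``test_days`` as test."""
    per_day = 24 * 60 // series.sampling_interval
    cut = len(series) - test_days * per_day
    if cut <= 0:
        raise ValueError("series shorter than the requested test tail")

    def _slice(lo: int, hi: int) -> CGMSeries:
        return CGMSeries(
            series.patient_id,
            series.times[lo],
            series.sampling_interval,
            series.values[lo:hi].copy(),
            series.observed_mask[lo:hi].copy(),
            None if series.fill_status is None else series.fill_status[lo:hi].copy(),
        )

    return _slice(0, cut), _slice(cut, len(series))


# ---------------------------------------------------------------------------
# folds and scaling

def split_folds(samples: SampleSet, k: int, seed: int = 0
                ) -> list[tuple[SampleSet, SampleSet]]:
    """Chronological k-fold split into (train, validation) pairs.

    Validation folds are contiguous blocks of the time-ordered sample index
    (cyclically offset by the seed), which keeps overlapping histories of
    adjacent samples from leaking between train and validation.  Blocks are
    disjoint, cover the set, and each holds 1/k of the samples (+-1).
    """
    n = len(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    offset = int(np.random.default_rng(seed).integers(0, n))
    order = np.argsort(np.asarray(samples.timestamps), kind="stable")
    rotated = np.roll(order, -offset)
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    out = []
    for i in range(k):
        val_idx = rotated[bounds[i]:bounds[i + 1]]
        train_idx = np.concatenate([rotated[:bounds[i]], rotated[bounds[i + 1]:]])
        out.append((samples.subset(train_idx), samples.subset(val_idx)))
    return out


def standardize(train: SampleSet, apply_to: Sequence[SampleSet] = ()
                ) -> tuple[SampleSet, list[SampleSet], ScalingParams]:
    """Fit per-node standardization on ``train``; apply it everywhere.

    Returns the scaled training set, the scaled copies of ``apply_to`` (all
    using the training parameters), and the fitted :class:`ScalingParams`
    whose inverse maps predictions back to mg/dL.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    if train.standardized:
        raise ValueError("training set is already standardized")
    mean = train.inputs.mean(axis=0)
    sd = train.inputs.std(axis=0)
    if (sd <= 1e-12).any():
        bad = np.flatnonzero(sd <= 1e-12)
        raise ValueError(f"zero-variance input node(s) {bad.tolist()}: "
                         "degenerate feature")
    t_sd = float(train.targets.std())
    if t_sd <= 1e-12:
        raise ValueError("zero-variance target: degenerate feature")
    params = ScalingParams(mean, sd, float(train.targets.mean()), t_sd)

    def _apply(s: SampleSet) -> SampleSet:
        return SampleSet(
            params.transform_inputs(s.inputs),
            params.transform_targets(s.targets),
            s.timestamps, s.config, s.patient_ids,
            scaling=params, standardized=True,
        )

    return _apply(train), [_apply(s) for s in apply_to], params
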