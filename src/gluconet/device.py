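"""Bounded, discrete weight spaces derived from neuromorphic device states.

An ENODe (electrochemical neuromorphic organic device) stores a synaptic
weight as a channel conductance that can only take a finite set of stable
states, reached through gate pulses that either potentiate ("set") or
depress ("reset") the channel.  The reachable ladder differs between the two
directions, so a hardware-trained network must round every weight update to
the nearest state of the ladder matching the update's direction.  This
module extracts state ladders from conductance traces, maps them affinely
into a bounded weight interval (preserving the device's spacing exactly),
and provides the direction-dependent nearest-state quantizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Literal, Sequence

import numpy as np

from .synthetic import DeviceTrace

__all__ = [
    "WeightSpace",
    "extract_states",
    "map_to_weightspace",
    "linear_weightspace",
    "nearest_state",
    "tabulated_bounds",
]

Direction = Literal["set", "reset"]

#: weight bounds used in the reference hardware experiments, per architecture;
#: chosen there as the extreme weights of the matching unbounded model
_BOUNDS_TABLE: dict[tuple[int, ...], tuple[float, float]] = {
    (48, 16): (-1.2, 1.2),
    (9, 6): (-1.5, 1.5),
    (6, 3): (-1.7, 1.7),
    (4, 3): (-1.7, 1.7),
    (2, 1): (-2.0, 2.0),
}


@dataclass
class WeightSpace:
    """The discrete values a hardware network parameter may assume.

    ``set_states`` / ``reset_states`` are the ascending ladders reachable by
    potentiation and depression respectively; both span exactly
    [lower_bound, upper_bound].
    """

    lower_bound: float
    upper_bound: float
    set_states: np.ndarray
    reset_states: np.ndarray
    provenance: str = "linear"   # {"linear", "enode"}

    def __post_init__(self) -> None:
        self.set_states = np.asarray(self.set_states, dtype=float)
        self.reset_states = np.asarray(self.reset_states, dtype=float)
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        for name, states in (("set_states", self.set_states),
                             ("reset_states", self.reset_states)):
            if states.size < 2:
                raise ValueError(f"{name} needs >= 2 states")
            if not (np.diff(states) > 0).all():
                raise ValueError(f"{name} must be strictly increasing")
            if not (np.isclose(states[0], self.lower_bound)
                    and np.isclose(states[-1], self.upper_bound)):
                raise ValueError(f"{name} must span exactly the bounds")
            if (states < self.lower_bound - 1e-12).any() \
                    or (states > self.upper_bound + 1e-12).any():
                raise ValueError(f"{name} must lie within the bounds")

    def states(self, direction: Direction) -> np.ndarray:
        if direction == "set":
            return self.set_states
        if direction == "reset":
            return self.reset_states
        raise ValueError(f"unknown direction {direction!r}")

    @property
    def all_states(self) -> np.ndarray:
        """Union of both selections, ascending."""
        return np.unique(np.concatenate([self.set_states, self.reset_states]))

    def to_json(self, destination: str | Path | IO[str]) -> None:
        payload = {
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "set_states": self.set_states.tolist(),
            "reset_states": self.reset_states.tolist(),
            "provenance": self.provenance,
        }
        if hasattr(destination, "write"):
            json.dump(payload, destination)
        else:
            Path(destination).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, source: str | Path | IO[str]) -> "WeightSpace":
        data = json.load(source) if hasattr(source, "read") else json.loads(
            Path(source).read_text())
        return cls(data["lower_bound"], data["upper_bound"],
                   np.array(data["set_states"]), np.array(data["reset_states"]),
                   data["provenance"])


def extract_states(trace: DeviceTrace, n_states: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pick ``n_states`` steady-state conductances per sweep direction.

    The stored state of a pulse is its plateau reading (the retained value
    after the pulse); with one reading per pulse, ``n_states`` evenly spread
    pulses are taken from each sweep.  Both ladders are returned ascending
    (the reset sweep is reversed).
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    out = []
    for direction in ("set", "reset"):
        g = trace.conductances(direction)  # pulse order
        if g.size < n_states:
            raise ValueError(
                f"{direction} sweep has {g.size} readings, need >= {n_states}"
            )
        picks = np.linspace(0, g.size - 1, n_states).round().astype(int)
        states = g[picks]
        if direction == "reset":
            states = states[::-1]
        if not (np.diff(states) > 0).all():
            raise ValueError(f"{direction} sweep is not monotone at the "
                             "selected pulses; cannot extract distinct states")
        out.append(states)
    return out[0], out[1]


def map_to_weightspace(set_g: Sequence[float], reset_g: Sequence[float],
                       lower: float, upper: float) -> WeightSpace:
    """Affinely map conductance ladders into the weight interval [lower, upper].

    Each direction gets its own affine map sending its minimum conductance to
    ``lower`` and its maximum to ``upper``, so the relative spacing of the
    intermediate device states — the device's (non-)linearity — is preserved
    exactly.
    """
    if not lower < upper:
        raise ValueError("lower must be < upper")

    def _map(g: Sequence[float], name: str) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        if g.size < 2 or not (np.diff(g) > 0).all():
            raise ValueError(f"{name} conductances must be strictly increasing "
                             "with >= 2 entries")
        w = lower + (g - g[0]) * (upper - lower) / (g[-1] - g[0])
        w[0], w[-1] = lower, upper  # pin the extremes against rounding
        return w

    return WeightSpace(lower, upper, _map(set_g, "set"), _map(reset_g, "reset"),
                       provenance="enode")


def linear_weightspace(n_states: int, lower: float, upper: float) -> WeightSpace:
    """Equally spaced weight states, identical for both update directions."""
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if not lower < upper:
        raise ValueError("lower must be < upper")
    states = np.linspace(lower, upper, n_states)
    return WeightSpace(lower, upper, states, states.copy(), provenance="linear")


def nearest_state(target: float | np.ndarray, direction: Direction,
                  ws: WeightSpace) -> float | np.ndarray:
    """Round ``target`` to the closest state of the direction's ladder.

    Out-of-bound targets clip to the extreme states.  Exact ties between two
    neighbouring states resolve toward the state of smaller magnitude (and,
    for the symmetric case of equal magnitudes, toward the lower one).
    Vectorized over ``target``.
    """
    states = ws.states(direction)
    t = np.asarray(target, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    pos = np.searchsorted(states, t)
    lo = np.clip(pos - 1, 0, states.size - 1)
    hi = np.clip(pos, 0, states.size - 1)
    d_lo = np.abs(t - states[lo])
    d_hi = np.abs(states[hi] - t)
    take_hi = d_hi < d_lo
    tie = d_hi == d_lo
    # tie: prefer smaller |state|; equal magnitudes fall back to the lower one
    smaller_mag_hi = np.abs(states[hi]) < np.abs(states[lo])
    take_hi = take_hi | (tie & smaller_mag_hi)
    out = np.where(take_hi, states[hi], states[lo])
    return float(out[0]) if scalar else out


def tabulated_bounds(hidden_sizes: Sequence[int]) -> tuple[float, float]:
    """Reference weight bounds for the benchmark hardware architectures.

    Covers hidden sizes [48,16], [9,6], [6,3], [4,3] and [2,1].  For any
    other architecture the caller must supply bounds explicitly — the
    convention is the extreme weight values of the matching unbounded model.
    """
    key = tuple(int(h) for h in hidden_sizes)
    try:
        return _BOUNDS_TABLE[key]
    except KeyError:
        raise KeyError(
            f"no tabulated bounds for architecture {list(key)}; supply bounds "
            "explicitly (e.g. the extreme weights of an unbounded fit)"
        ) from None
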