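"""Sticky state assignment and microscopic rates.

States are discs of radius 3 A (strict inequality) in a 2D coordinate plane.
Assignment is "sticky": once a state is entered the label persists until a
different state's boundary is crossed, which suppresses fast boundary
recrossings.  The microscopic rate from state i to j is k_ij = N_ij / tau_i
(transition count over total dwell time), reported only when the count
exceeds a threshold (default 20) -- below that it is flagged as having
insufficient events, never as zero.

A special exclusion region can be declared (e.g. a weakly-sampled competing
basin): after it is visited, frames are labeled with the exclusion label
until the designated reset state is re-entered, so those excursions do not
contaminate the reset state's dwell statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["State", "StateSet", "RateMatrix", "KineticsError",
           "assign_states", "raw_state_labels", "rates", "arrhenius",
           "UNASSIGNED"]

UNASSIGNED = "unassigned"


class KineticsError(ValueError):
    """Raised for invalid state definitions or rate input."""


@dataclasses.dataclass(frozen=True)
class State:
    label: str
    center: tuple[float, float]
    radius: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise KineticsError(f"state {self.label!r}: radius must be > 0")


@dataclasses.dataclass
class StateSet:
    """Circular state definitions, plus an optional exclusion region.

    ``exclusion`` marks a region whose visits invalidate the dwell of
    ``exclusion_reset`` (frames become ``exclusion_label`` until that state
    is re-entered).
    """

    states: Sequence[State]
    exclusion: State | None = None
    exclusion_reset: str | None = None
    exclusion_label: str = "excluded"

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise KineticsError("duplicate state labels")
        if self.exclusion is not None and self.exclusion_reset not in labels:
            raise KineticsError(
                "exclusion_reset must name one of the states")

    def labels(self) -> list[str]:
        return [s.label for s in self.states]


def _membership(rp: np.ndarray, re_: np.ndarray,
                states: Sequence[State]) -> np.ndarray:
    """(n_frames, n_states) strict-inequality disc membership."""
    rp = np.asarray(rp, dtype=float)
    re_ = np.asarray(re_, dtype=float)
    if rp.shape != re_.shape:
        raise KineticsError("coordinate series have different lengths")
    m = np.empty((len(rp), len(states)), dtype=bool)
    for k, s in enumerate(states):
        m[:, k] = np.hypot(rp - s.center[0], re_ - s.center[1]) < s.radius
    return m


def raw_state_labels(rp, re_, state_set: StateSet) -> np.ndarray:
    """Non-sticky labels: the state whose disc contains the frame, else
    ``UNASSIGNED`` (discs are assumed disjoint; first match wins)."""
    m = _membership(rp, re_, state_set.states)
    labels = np.array([UNASSIGNED] * len(m), dtype=object)
    names = state_set.labels()
    for k in reversed(range(len(names))):
        labels[m[:, k]] = names[k]
    return labels


def assign_states(rp, re_, state_set: StateSet) -> np.ndarray:
    """Sticky assignment of every frame to a state label.

    Frames before the first state entry are ``UNASSIGNED``.  If an exclusion
    region is configured, sampling it relabels frames with the exclusion
    label until the reset state is re-entered.
    """
    m = _membership(rp, re_, state_set.states)
    names = state_set.labels()
    excl = None
    if state_set.exclusion is not None:
        excl = _membership(rp, re_, [state_set.exclusion])[:, 0]

    labels = np.empty(len(m), dtype=object)
    current = UNASSIGNED
    excluded_mode = False
    for t in range(len(m)):
        hit = np.flatnonzero(m[t])
        if hit.size:
            entered = names[int(hit[0])]
            if excluded_mode and entered == state_set.exclusion_reset:
                excluded_mode = False
            if not excluded_mode:
                current = entered
        if excl is not None and excl[t]:
            excluded_mode = True
        labels[t] = (state_set.exclusion_label if excluded_mode
                     else current)
    return labels


@dataclasses.dataclass
class RateMatrix:
    """Transition counts, dwell times and rates k_ij = N_ij / tau_i."""

    counts: dict[tuple[str, str], int]
    dwell: dict[str, float]
    dt: float
    threshold: int = 20

    def rate(self, i: str, j: str) -> float | None:
        """Rate in 1/reduced-time, or None when events are insufficient."""
        n = self.counts.get((i, j), 0)
        if n <= self.threshold:
            return None
        tau = self.dwell.get(i, 0.0)
        return n / tau if tau > 0 else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), n in sorted(self.counts.items()):
            r = self.rate(i, j)
            rows.append({"from": i, "to": j, "n_transitions": n,
                         "dwell_time": self.dwell.get(i, 0.0),
                         "rate": np.nan if r is None else r,
                         "insufficient_events": r is None})
        return pd.DataFrame(rows)


def rates(label_series: Sequence[str], dt: float,
          threshold: int = 20,
          ignore_labels: Sequence[str] = (UNASSIGNED, "excluded"),
          ) -> RateMatrix:
    """Count i->j label changes between assigned states and accumulate
    dwell times (frames with labels in ``ignore_labels`` contribute to
    neither, and break transition continuity)."""
    if dt <= 0:
        raise KineticsError("dt must be positive")
    labels = np.asarray(label_series, dtype=object)
    special = set(ignore_labels)
    counts: dict[tuple[str, str], int] = {}
    dwell: dict[str, float] = {}
    prev = None
    for lab in labels:
        lab = str(lab)
        if lab in special:
            prev = None
            continue
        dwell[lab] = dwell.get(lab, 0.0) + dt
        if prev is not None and lab != prev:
            counts[(prev, lab)] = counts.get((prev, lab), 0) + 1
        prev = lab
    return RateMatrix(counts=counts, dwell=dwell, dt=dt,
                      threshold=threshold)


def arrhenius(barrier: float, prefactor: float) -> tuple[float, float]:
    """Barrier (k_B T) and attempt prefactor (1/time) to (rate, timescale).

    rate = prefactor * exp(-barrier); timescale = 1/rate, in the prefactor's
    time units.
    """
    if prefactor <= 0:
        raise KineticsError("prefactor must be positive")
    rate = prefactor * float(np.exp(-barrier))
    return rate, 1.0 / rate
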