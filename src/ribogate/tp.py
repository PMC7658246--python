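"""Transition-path detection and P(TP|rho) reaction-coordinate scoring.

A transition path (TP) between two designated endpoint states is a maximal
frame interval strictly between leaving one state and first entering the
other; excursions that return to the origin state are not TPs.  For a
diffusive system, a coordinate rho that resolves the transition state will
show a conditional probability P(TP|rho) peaking at 0.5 at the barrier top;
this is the basis for ranking candidate coordinates, together with the
number of apparent 1D transitions along rho that do not correspond to a real
(2D-verified) transition ("false positives").
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .kinetics import UNASSIGNED

__all__ = ["TPResult", "TPError", "transition_paths", "interval_state_labels",
           "p_tp_given_rho", "tp_frame_mask", "count_1d_transitions",
           "rank_coordinates"]


class TPError(ValueError):
    """Raised for invalid transition-path input."""


@dataclasses.dataclass
class TPResult:
    """P(TP|rho) curve and coordinate diagnostics."""

    label: str
    bin_centers: np.ndarray
    p_tp: np.ndarray                 # NaN where the bin is empty
    bin_counts: np.ndarray
    peak: float
    n_transitions: int
    false_positives: int = 0

    def score(self) -> tuple:
        """Ranking key: fewest false positives, then peak closest to 0.5."""
        return (self.false_positives, abs(self.peak - 0.5), self.label)


def transition_paths(raw_labels: Sequence[str], state_a: str, state_b: str
                     ) -> list[tuple[int, int, str, str]]:
    """Detect TP intervals from non-sticky (raw) state labels.

    Returns ``(start_frame, end_frame, from_state, to_state)`` with the
    interval inclusive and strictly between the two states; a direct hop
    yields an empty interval ``(t, t-1, ...)`` that still counts as a
    transition.  Frames inside non-designated states are treated like
    unassigned frames.
    """
    if state_a == state_b:
        raise TPError("endpoint states must differ")
    labels = np.asarray(raw_labels, dtype=object)
    endpoints = {state_a, state_b}
    paths = []
    origin = None          # last endpoint state visited
    exit_frame = -1        # last frame inside the origin state
    for t, lab in enumerate(labels):
        lab = str(lab)
        if lab not in endpoints:
            continue
        if origin is not None and lab != origin:
            paths.append((exit_frame + 1, t - 1, origin, lab))
        origin = lab
        exit_frame = t
    return paths


def interval_state_labels(series: np.ndarray,
                          states: Mapping[str, tuple[float, float]]
                          ) -> np.ndarray:
    """Raw labels for a 1D coordinate: state whose (lo, hi) interval
    contains the value, else ``unassigned``."""
    series = np.asarray(series, dtype=float)
    labels = np.array([UNASSIGNED] * len(series), dtype=object)
    for name, (lo, hi) in states.items():
        labels[(series > lo) & (series < hi)] = name
    return labels


def tp_frame_mask(n_frames: int,
                  tp_intervals: Sequence[tuple]) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for start, end, *_ in tp_intervals:
        if end >= start:
            mask[start:end + 1] = True
    return mask


def p_tp_given_rho(rho_series: np.ndarray,
                   tp_intervals: Sequence[tuple],
                   bin_width: float = 1.0,
                   min_count_for_peak: int = 50,
                   label: str = "rho") -> TPResult:
    """Per-bin probability that a frame lies on a transition path.

    The reported peak is taken over bins holding at least
    ``min_count_for_peak`` frames, so that near-empty bins do not dominate.
    """
    rho = np.asarray(rho_series, dtype=float)
    in_tp = tp_frame_mask(len(rho), tp_intervals)
    lo = np.floor(rho.min() / bin_width) * bin_width
    hi = np.ceil(rho.max() / bin_width) * bin_width
    edges = lo + bin_width * np.arange(int(round((hi - lo) / bin_width)) + 1)
    counts, _ = np.histogram(rho, bins=edges)
    tp_counts, _ = np.histogram(rho[in_tp], bins=edges)
    with np.errstate(invalid="ignore"):
        p = np.where(counts > 0, tp_counts / np.maximum(counts, 1), np.nan)
    eligible = counts >= min_count_for_peak
    peak = float(np.nanmax(p[eligible])) if np.any(eligible) else float("nan")
    return TPResult(label=label,
                    bin_centers=0.5 * (edges[:-1] + edges[1:]),
                    p_tp=p, bin_counts=counts, peak=peak,
                    n_transitions=len(tp_intervals))


def count_1d_transitions(rho: np.ndarray,
                         band_a: tuple[float, float],
                         band_b: tuple[float, float]) -> list[tuple]:
    """Apparent transitions of a 1D coordinate between two value bands
    (same maximal-interval definition as :func:`transition_paths`)."""
    labels = interval_state_labels(rho, {"a": band_a, "b": band_b})
    return transition_paths(labels, "a", "b")


def _percentile_band(values: np.ndarray,
                     lo_pct: float = 5.0, hi_pct: float = 95.0
                     ) -> tuple[float, float]:
    return (float(np.percentile(values, lo_pct)),
            float(np.percentile(values, hi_pct)))


def false_positive_count(rho: np.ndarray,
                         raw_labels: Sequence[str],
                         state_a: str, state_b: str,
                         tp_intervals: Sequence[tuple]) -> int:
    """Apparent 1D transitions along rho with no matching verified TP.

    1D endpoint bands are the 5th-95th percentile range of rho within each
    endpoint ensemble; an apparent transition is matched when its interval
    overlaps (or directly abuts) a verified TP interval.
    """
    labels = np.asarray(raw_labels, dtype=object)
    in_a = labels == state_a
    in_b = labels == state_b
    if not (in_a.any() and in_b.any()):
        raise TPError("both endpoint ensembles must be sampled")
    band_a = _percentile_band(rho[in_a])
    band_b = _percentile_band(rho[in_b])
    apparent = count_1d_transitions(rho, band_a, band_b)
    fp = 0
    for start, end, *_ in apparent:
        hit = False
        for vs, ve, *_ in tp_intervals:
            if start <= ve + 1 and end >= vs - 1:
                hit = True
                break
        if not hit:
            fp += 1
    return fp


def rank_coordinates(candidate_series: Mapping[str, np.ndarray],
                     raw_labels: Sequence[str],
                     state_a: str, state_b: str,
                     bin_width: float = 1.0,
                     min_count_for_peak: int = 50) -> list[TPResult]:
    """Score candidate coordinates against the 2D-verified transitions.

    Candidates are ordered by (false positives ascending, |peak - 0.5|
    ascending, label) -- a good coordinate shows no spurious transitions and
    a diffusive peak of 0.5.
    """
    if len(candidate_series) == 0:
        raise TPError("no candidate coordinates")
    verified = transition_paths(raw_labels, state_a, state_b)
    results = []
    for label, rho in candidate_series.items():
        res = p_tp_given_rho(rho, verified, bin_width=bin_width,
                             min_count_for_peak=min_count_for_peak,
                             label=label)
        res.false_positives = false_positive_count(
            np.asarray(rho, dtype=float), raw_labels, state_a, state_b,
            verified)
        results.append(res)
    return sorted(results, key=lambda r: r.score())
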