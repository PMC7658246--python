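"""Contact-formation statistics and steric-gate identification.

Two complementary observables characterize which interactions shape a
barrier between two binding configurations:

* formation probabilities of the *stabilizing* (native-contact) interactions
  -- a contact counts as formed when the atom pair is within 1.2x its
  endpoint distance; if those probabilities vanish in the transition-state
  window, the barrier is steric rather than energetic;
* per-residue *steric* contact probabilities p_i^j -- residue i touches the
  ligand in ensemble j when any heavy-atom pair is closer than 4 A.  The
  statistic Delta-p_i = p_i^TSE - max(p_i^I1, p_i^I2) singles out residues
  the ligand presses against only while crossing the barrier: the steric
  gate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import _as_selection
from .topology import MultiBasinTopology

__all__ = ["EnsembleWindow", "ContactStatsError",
           "stabilizing_contact_formation", "steric_contact_probability",
           "gate_candidates"]

logger = logging.getLogger(__name__)


class ContactStatsError(ValueError):
    """Raised for empty ensembles or inconsistent input."""


@dataclasses.dataclass
class EnsembleWindow:
    """Open interval on a named coordinate defining one ensemble."""

    label: str
    lower: float
    upper: float
    coordinate: str = "rho"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ContactStatsError(
                f"window {self.label!r}: lower must be < upper")

    def mask(self, series: np.ndarray) -> np.ndarray:
        series = np.asarray(series, dtype=float)
        return (series > self.lower) & (series < self.upper)


def _frames_array(frames) -> np.ndarray:
    arr = np.asarray(getattr(frames, "frames", frames), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def stabilizing_contact_formation(frames, topology: MultiBasinTopology,
                                  tolerance: float = 1.2,
                                  frame_mask: np.ndarray | None = None,
                                  ) -> pd.DataFrame:
    """Formation probability of every native contact over a frame set.

    A contact is formed when the pair distance is at most ``tolerance``
    times the endpoint (native) distance.  Returns one row per contact with
    its basin tag and formation probability.
    """
    arr = _frames_array(frames)
    if frame_mask is not None:
        arr = arr[np.asarray(frame_mask, dtype=bool)]
    if arr.shape[0] == 0:
        raise ContactStatsError("no frames selected")
    i = topology.contacts[:, 0]
    j = topology.contacts[:, 1]
    d = np.linalg.norm(arr[:, i, :] - arr[:, j, :], axis=2)
    formed = d <= tolerance * topology.contact_sigma_native[None, :]
    ref = topology.atoms_ref
    return pd.DataFrame({
        "atom_i": i, "atom_j": j,
        "residue_i": [f"{ref.chain_id[a]}:{ref.res_id[a]}" for a in i],
        "residue_j": [f"{ref.chain_id[a]}:{ref.res_id[a]}" for a in j],
        "basin": topology.contact_tag,
        "sigma_native": topology.contact_sigma_native,
        "p_formed": formed.mean(axis=0),
    })


def _widen(window: EnsembleWindow, series: np.ndarray,
           min_frames: int) -> np.ndarray:
    """Symmetrically widen a window until it holds ``min_frames`` frames."""
    lo, hi = window.lower, window.upper
    mask = window.mask(series)
    step = 0.5 * (hi - lo)
    while mask.sum() < min_frames:
        lo -= step
        hi += step
        mask = (series > lo) & (series < hi)
        if lo < series.min() and hi > series.max():
            break
    if (lo, hi) != (window.lower, window.upper):
        logger.warning(
            "window %r widened from (%g, %g) to (%g, %g) to reach %d frames",
            window.label, window.lower, window.upper, lo, hi,
            int(mask.sum()))
    return mask


def steric_contact_probability(frames, topology: MultiBasinTopology,
                               ligand: "AtomSelection | str",
                               coordinate_series: np.ndarray,
                               windows: Sequence[EnsembleWindow],
                               cutoff: float = 4.0,
                               min_frames: int = 100,
                               widen_windows: bool = True,
                               ) -> pd.DataFrame:
    """p_i^j: probability that scaffold residue i touches the ligand in
    ensemble window j (any heavy-atom pair below ``cutoff``).

    Windows narrower than ``min_frames`` frames are symmetrically widened
    (with a logged warning) when ``widen_windows`` is set.  Returns one row
    per non-ligand residue with a probability column per window label.
    """
    arr = _frames_array(frames)
    series = np.asarray(coordinate_series, dtype=float)
    if len(series) != arr.shape[0]:
        raise ContactStatsError("coordinate series does not match frames")
    masks = {}
    for w in windows:
        mask = w.mask(series)
        if widen_windows and mask.sum() < min_frames:
            mask = _widen(w, series, min_frames)
        if mask.sum() == 0:
            raise ContactStatsError(f"window {w.label!r} contains no frames")
        masks[w.label] = mask

    ref = topology.atoms_ref
    lig = _as_selection(ligand).resolve(ref)
    lig_set = set(lig.tolist())
    residues: dict[tuple[str, int], list[int]] = {}
    for a in range(ref.n_atoms):
        if a in lig_set:
            continue
        residues.setdefault(ref.residue_key(a), []).append(a)

    rows = []
    for (chain, resnum), atom_idx in sorted(residues.items()):
        d = np.linalg.norm(
            arr[:, atom_idx, None, :] - arr[:, None, lig, :], axis=3)
        touch = (d < cutoff).any(axis=(1, 2))
        row = {"chain": chain, "residue": resnum}
        for label, mask in masks.items():
            row[f"p_{label}"] = float(touch[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def gate_candidates(table: pd.DataFrame,
                    tse_label: str = "TSE",
                    endpoint_labels: tuple[str, str] = ("I1", "I2"),
                    delta_threshold: float = 0.35,
                    report_threshold: float = 0.1) -> pd.DataFrame:
    """Rank residues by Delta-p = p^TSE - max over endpoint ensembles.

    Adds boolean flags for the reporting (default 0.1) and gate (default
    0.35) thresholds and sorts by Delta-p descending.
    """
    cols = [f"p_{tse_label}"] + [f"p_{l}" for l in endpoint_labels]
    for c in cols:
        if c not in table.columns:
            raise ContactStatsError(f"probability column {c!r} missing")
    out = table.copy()
    out["delta_p"] = out[cols[0]] - out[cols[1:]].max(axis=1)
    out[f"above_{report_threshold}"] = out["delta_p"] > report_threshold
    out[f"above_{delta_threshold}"] = out["delta_p"] > delta_threshold
    return out.sort_values("delta_p", ascending=False).reset_index(drop=True)
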