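"""Declarative scalar reaction coordinates over trajectories.

Three kinds are supported: the distance between geometric centers of two
selections (``center_distance``), a single atom-pair distance
(``atompair_distance``) and weighted linear combinations of other coordinates
(``linear_combination``).  A coordinate evaluates to one value per frame, in
Angstrom.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .dynamics import Trajectory
from .structures import MolecularStructure, SelectionError, _as_selection

__all__ = ["CoordinateSpec", "evaluate_coordinate", "rho_family"]


@dataclasses.dataclass
class CoordinateSpec:
    """One scalar coordinate.

    * ``center_distance``: distance between the geometric centers of
      ``selections[0]`` and ``selections[1]``.
    * ``atompair_distance``: distance between the single atoms matched by the
      two selections.
    * ``linear_combination``: ``sum_i weights[i] * components[i]``.
    """

    kind: str
    label: str = ""
    selections: tuple = ()
    components: Sequence["CoordinateSpec"] = ()
    weights: Sequence[float] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("center_distance", "atompair_distance",
                             "linear_combination"):
            raise SelectionError(f"unknown coordinate kind {self.kind!r}")
        if self.kind == "linear_combination":
            if len(self.components) < 1:
                raise SelectionError(
                    "linear_combination needs >= 1 component")
            if len(self.weights) != len(self.components):
                raise SelectionError("weights/components length mismatch")
            if not np.all(np.isfinite(np.asarray(self.weights, dtype=float))):
                raise SelectionError("weights must be finite")
        elif len(self.selections) != 2:
            raise SelectionError(f"{self.kind} needs exactly two selections")


def _resolve_pair(spec: CoordinateSpec, reference: MolecularStructure
                  ) -> tuple[np.ndarray, np.ndarray]:
    try:
        a = _as_selection(spec.selections[0]).resolve(reference)
        b = _as_selection(spec.selections[1]).resolve(reference)
    except SelectionError as exc:
        raise SelectionError(
            f"coordinate {spec.label or spec.kind!r}: {exc}") from exc
    if spec.kind == "atompair_distance" and (len(a) != 1 or len(b) != 1):
        raise SelectionError(
            f"coordinate {spec.label!r}: atompair selections must match "
            f"exactly one atom each (got {len(a)}, {len(b)})")
    return a, b


def evaluate_coordinate(spec: CoordinateSpec,
                        trajectory: "Trajectory | np.ndarray",
                        reference: MolecularStructure) -> np.ndarray:
    """Evaluate a coordinate on every frame; returns a (n_frames,) series.

    ``reference`` supplies the atom identities used to resolve selections
    (its coordinates are ignored); frames may be a Trajectory or a bare
    (n_frames, n_atoms, 3) array.
    """
    frames = (trajectory.frames if isinstance(trajectory, Trajectory)
              else np.asarray(trajectory))
    if frames.ndim == 2:
        frames = frames[None]
    if spec.kind == "linear_combination":
        total = np.zeros(frames.shape[0])
        for w, comp in zip(spec.weights, spec.components):
            total += w * evaluate_coordinate(comp, frames, reference)
        return total
    a, b = _resolve_pair(spec, reference)
    ca = frames[:, a, :].mean(axis=1)
    cb = frames[:, b, :].mean(axis=1)
    return np.linalg.norm(ca.astype(np.float64) - cb.astype(np.float64),
                          axis=1)


def rho_family(distances: Sequence[CoordinateSpec],
               weight_grid: Sequence[float]) -> list[CoordinateSpec]:
    """Candidate coordinate pool: every single distance plus every pairwise
    combination ``w * d_i + (1 - w) * d_j`` for w in the grid.

    Grid endpoints 0 and 1 duplicate the single distances and are dropped
    from the pairwise enumeration.
    """
    if len(distances) == 0:
        raise SelectionError("rho_family needs >= 1 distance")
    grid = [float(w) for w in weight_grid]
    if len(grid) == 0:
        raise SelectionError("empty weight grid")
    out = list(distances)
    interior = [w for w in grid if 0.0 < w < 1.0]
    for i in range(len(distances)):
        for j in range(i + 1, len(distances)):
            for w in interior:
                di, dj = distances[i], distances[j]
                out.append(CoordinateSpec(
                    kind="linear_combination",
                    label=f"{w:g}*{di.label or i}+{1-w:g}*{dj.label or j}",
                    components=(di, dj), weights=(w, 1.0 - w)))
    return out
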