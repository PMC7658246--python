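"""Histogram free-energy surfaces F = -k_B T ln P over 1D/2D coordinates.

Free energies are reported in units of k_B T and offset so the lowest
populated bin is zero.  Empty interior bins stay undefined (NaN) -- they are
never interpolated.  Barrier heights are measured along the minimum-free-
energy path between two named minima: the barrier is the highest bin on the
best (minimax) path minus the higher of the two minima.
"""

from __future__ import annotations

import dataclasses
import heapq
from typing import Sequence

import numpy as np

__all__ = ["FreeEnergyProfile", "LandscapeError", "free_energy",
           "barrier_height", "subsample_robustness", "barrier_spread"]


class LandscapeError(ValueError):
    """Raised for empty or inconsistent landscape input."""


@dataclasses.dataclass
class FreeEnergyProfile:
    """Binned free energy: edges per axis, F (k_B T, NaN where empty),
    raw counts, and a human-readable restriction description."""

    edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray
    counts: np.ndarray
    restriction: str = ""

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def bin_index(self, value: float, axis: int = 0) -> int:
        e = self.edges[axis]
        idx = int(np.searchsorted(e, value, side="right") - 1)
        if idx < 0 or idx >= len(e) - 1:
            raise LandscapeError(
                f"value {value} outside binned range [{e[0]}, {e[-1]}]")
        return idx

    def value_at(self, *coords: float) -> float:
        idx = tuple(self.bin_index(c, ax) for ax, c in enumerate(coords))
        return float(self.free_energy[idx])

    def to_tsv(self, path: str, header: str = "") -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            if self.ndim == 1:
                fh.write("# center\tF_kT\tcount\n")
                for c, f, n in zip(self.centers(0), self.free_energy,
                                   self.counts):
                    fh.write(f"{c:.6f}\t{f:.6f}\t{int(n)}\n")
            else:
                fh.write("# center_x\tcenter_y\tF_kT\tcount\n")
                cx, cy = self.centers(0), self.centers(1)
                for i in range(len(cx)):
                    for j in range(len(cy)):
                        fh.write(f"{cx[i]:.6f}\t{cy[j]:.6f}\t"
                                 f"{self.free_energy[i, j]:.6f}\t"
                                 f"{int(self.counts[i, j])}\n")


def _edges(series: np.ndarray, bin_width: float,
           range_: tuple[float, float] | None) -> np.ndarray:
    if range_ is None:
        lo = np.floor(series.min() / bin_width) * bin_width
        hi = np.ceil(series.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = range_
    n = max(1, int(round((hi - lo) / bin_width)))
    return lo + bin_width * np.arange(n + 1)


def free_energy(series, bin_width: float | tuple[float, float] = 0.5,
                restriction: np.ndarray | None = None,
                range_: tuple | None = None,
                restriction_label: str = "") -> FreeEnergyProfile:
    """Histogram free energy of a 1D series or an (x, y) pair of series.

    ``restriction`` is an optional boolean mask selecting the frames to keep
    (e.g. a window in auxiliary coordinates); ``range_`` optionally pins the
    binned interval per axis.  F = -ln(count/total) with min(F) = 0.
    """
    if isinstance(series, (tuple, list)) and len(series) == 2:
        arrs = [np.asarray(s, dtype=float) for s in series]
    else:
        arrs = [np.asarray(series, dtype=float)]
    n_frames = len(arrs[0])
    if restriction is not None:
        restriction = np.asarray(restriction, dtype=bool)
        arrs = [a[restriction] for a in arrs]
    if len(arrs[0]) == 0:
        raise LandscapeError("no samples remain after restriction")

    widths = (bin_width if isinstance(bin_width, (tuple, list))
              else (bin_width,) * len(arrs))
    ranges = (range_ if isinstance(range_, (tuple, list)) and range_
              and isinstance(range_[0], (tuple, list, type(None)))
              else (range_,) * len(arrs))
    edges = tuple(_edges(a, float(w), r)
                  for a, w, r in zip(arrs, widths, ranges))
    counts, _ = np.histogramdd(np.stack(arrs, axis=1), bins=edges)
    total = counts.sum()
    if total == 0:
        raise LandscapeError("no samples fall inside the binned range")
    with np.errstate(divide="ignore"):
        f = -np.log(counts / total)
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    return FreeEnergyProfile(edges=edges, free_energy=f,
                             counts=counts.astype(np.int64),
                             restriction=restriction_label)


def _minimax_path_height(f: np.ndarray, start: tuple, goal: tuple) -> float:
    """Highest F on the path from start to goal that minimizes that maximum
    (4/2-neighbour adjacency; NaN bins are impassable)."""
    shape = f.shape
    ndim = f.ndim
    best = np.full(shape, np.inf)
    h0 = f[start]
    if not np.isfinite(h0) or not np.isfinite(f[goal]):
        raise LandscapeError("minimum bin is empty")
    heap = [(h0, start)]
    best[start] = h0
    while heap:
        height, node = heapq.heappop(heap)
        if node == goal:
            return float(height)
        if height > best[node]:
            continue
        for ax in range(ndim):
            for step in (-1, 1):
                nxt = list(node)
                nxt[ax] += step
                if not (0 <= nxt[ax] < shape[ax]):
                    continue
                nxt = tuple(nxt)
                v = f[nxt]
                if not np.isfinite(v):
                    continue
                cand = max(height, float(v))
                if cand < best[nxt]:
                    best[nxt] = cand
                    heapq.heappush(heap, (cand, nxt))
    raise LandscapeError("minima are not connected through populated bins")


def barrier_height(profile: FreeEnergyProfile,
                   minimum_a: float | tuple,
                   minimum_b: float | tuple) -> float:
    """Barrier (k_B T) between the bins containing two minima.

    Defined as the top of the minimax path minus the higher of the two
    minimum bins, so a downhill profile reports zero.
    """
    a = minimum_a if isinstance(minimum_a, tuple) else (minimum_a,)
    b = minimum_b if isinstance(minimum_b, tuple) else (minimum_b,)
    ia = tuple(profile.bin_index(c, ax) for ax, c in enumerate(a))
    ib = tuple(profile.bin_index(c, ax) for ax, c in enumerate(b))
    top = _minimax_path_height(profile.free_energy, ia, ib)
    ref = max(profile.free_energy[ia], profile.free_energy[ib])
    return float(max(0.0, top - ref))


def subsample_robustness(series, fraction: float = 0.2,
                         n_blocks: int = 5,
                         bin_width: float | tuple = 0.5,
                         restriction: np.ndarray | None = None,
                         range_: tuple | None = None,
                         ) -> list[FreeEnergyProfile]:
    """Free-energy profiles on contiguous data blocks of size
    ``fraction`` * n_frames, for robustness checks."""
    if not (0.0 < fraction <= 1.0):
        raise LandscapeError("fraction must be in (0, 1]")
    if isinstance(series, (tuple, list)) and len(series) == 2:
        arrs = [np.asarray(s, dtype=float) for s in series]
    else:
        arrs = [np.asarray(series, dtype=float)]
    n = len(arrs[0])
    block = int(n * fraction)
    if block < 1 or n_blocks < 1:
        raise LandscapeError("not enough frames for the requested blocks")
    if n_blocks * block > n:
        raise LandscapeError(
            f"{n_blocks} blocks of {block} frames exceed {n} frames")
    if range_ is None:
        # common binning across blocks so barriers are comparable
        range_ = tuple((float(a.min()), float(a.max() + 1e-9)) for a in arrs)
        if len(arrs) == 1:
            range_ = range_[0]
    out = []
    for b in range(n_blocks):
        sl = slice(b * block, (b + 1) * block)
        sub = [a[sl] for a in arrs]
        mask = restriction[sl] if restriction is not None else None
        out.append(free_energy(sub if len(sub) > 1 else sub[0],
                               bin_width=bin_width, restriction=mask,
                               range_=range_,
                               restriction_label=f"block {b}"))
    return out


def barrier_spread(profiles: Sequence[FreeEnergyProfile],
                   minimum_a, minimum_b) -> float:
    """Max pairwise deviation of the barrier over a set of profiles."""
    barriers = [barrier_height(p, minimum_a, minimum_b) for p in profiles]
    return float(max(barriers) - min(barriers))
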