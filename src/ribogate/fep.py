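"""Free-energy perturbation along a binned coordinate.

The change in free energy when the model is modified by an energy term
Delta-U is estimated from unperturbed samples by exponential averaging,
conditioned on a reaction coordinate rho:

    dF(rho) = -k_B T ln < exp(-dU / k_B T) >_rho

Three perturbation families are provided:

* steric inflation -- the r^-12 excluded volume between a ligand and a set of
  scaffold residues is enlarged from sigma_from (default 2.1 A) to sigma_to
  (default 3.0 A) with epsilon = 2 k_B T, so dU >= 0 everywhere;
* hard-sphere clash -- dU = +infinity whenever an external structure, rigidly
  aligned to each frame on a named selection, comes within a clash distance
  (default 2.5 A) of the ligand; the exponential average then reduces exactly
  to -k_B T ln(surviving fraction);
* screened electrostatics -- a Debye-Hueckel potential between ligand and
  scaffold partial charges, truncated (and shifted to zero) at a cutoff.

Averages are accumulated in log space so large dU cannot underflow.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .structures import AtomSelection, MolecularStructure, superpose, \
    _as_selection
from .topology import MultiBasinTopology
from .units import KT

__all__ = [
    "StericInflation", "HardSphereClash", "DebyeHuckel", "PerturbedProfile",
    "FepError", "delta_u", "delta_u_series", "perturbed_free_energy",
    "apply_steric_inflation", "combination_scan", "debye_kappa",
    "bjerrum_length", "fold_hydrogen_charges",
]


class FepError(ValueError):
    """Raised for invalid perturbation input."""


# ---------------------------------------------------------------------------
# Perturbation specifications
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StericInflation:
    """Inflate ligand--residue excluded volume from sigma_from to sigma_to."""

    residues: "AtomSelection | str"
    ligand: "AtomSelection | str"
    sigma_from: float = 2.1       # A
    sigma_to: float = 3.0         # A
    epsilon: float = 2.0 * KT     # epsilon units (2 k_B T)

    def pair_indices(self, topology: MultiBasinTopology
                     ) -> tuple[np.ndarray, np.ndarray]:
        ref = topology.atoms_ref
        lig = _as_selection(self.ligand).resolve(ref)
        res = _as_selection(self.residues).resolve(ref)
        if np.intersect1d(lig, res).size:
            raise FepError("ligand and perturbed residues overlap")
        return lig, res


@dataclasses.dataclass
class HardSphereClash:
    """Reject frames where an aligned external structure clashes with the
    ligand (any inter-atomic distance below ``clash_distance``)."""

    external: MolecularStructure
    alignment: "AtomSelection | str"
    ligand: "AtomSelection | str"
    clash_distance: float = 2.5   # A
    clash_selection: "AtomSelection | str | None" = None

    def __post_init__(self) -> None:
        if self.clash_distance <= 0:
            raise FepError("clash_distance must be positive")


@dataclasses.dataclass
class DebyeHuckel:
    """Screened electrostatics between ligand and scaffold charges.

    Energies use the Bjerrum-length formulation U/kT = l_B q_i q_j
    exp(-kappa r)/r with the aqueous Debye constant at 298.15 K, sharply
    truncated and shifted to zero at ``cutoff``.  Requires per-atom charges
    on the topology.
    """

    ligand: "AtomSelection | str"
    scaffold: "AtomSelection | str"
    ionic_strength: float = 0.1   # mol/L monovalent
    dielectric: float = 80.0
    cutoff: float = 20.0          # A
    kT: float = KT                # reduced thermal energy for unit conversion

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise FepError("cutoff must be positive")

    def energy(self, coords: np.ndarray,
               topology: MultiBasinTopology) -> float:
        """Electrostatic energy of one frame in epsilon (for itemized
        potential-energy reports)."""
        return float(delta_u(coords, topology, self))


#: constants (6 significant figures): e^2/(4 pi eps0) in kcal mol^-1 A and
#: k_B T at 298.15 K in kcal/mol, giving the vacuum Bjerrum prefactor.
_COULOMB_KCAL_A = 332.064
_KT_KCAL_298 = 0.592483
_AVOGADRO_PER_A3 = 6.02214e-4   # (mol/L) -> ions per A^3


def bjerrum_length(dielectric: float = 80.0) -> float:
    """Bjerrum length in A at 298.15 K."""
    return _COULOMB_KCAL_A / (_KT_KCAL_298 * dielectric)


def debye_kappa(ionic_strength: float, dielectric: float = 80.0) -> float:
    """Inverse Debye screening length (1/A) for a monovalent salt."""
    n_per_a3 = 2.0 * ionic_strength * _AVOGADRO_PER_A3
    return float(np.sqrt(4.0 * np.pi * bjerrum_length(dielectric) * n_per_a3))


# ---------------------------------------------------------------------------
# Delta-U evaluation
# ---------------------------------------------------------------------------

def _frames_array(frames) -> np.ndarray:
    arr = np.asarray(getattr(frames, "frames", frames), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def delta_u_series(frames, topology: MultiBasinTopology, spec) -> np.ndarray:
    """Delta-U for every frame, in epsilon (inf marks rejected frames)."""
    arr = _frames_array(frames)
    if isinstance(spec, StericInflation):
        lig, res = spec.pair_indices(topology)
        d = arr[:, lig, None, :] - arr[:, None, res, :]
        r12 = (np.einsum("flrc,flrc->flr", d, d)) ** 6
        coef = spec.epsilon * (spec.sigma_to ** 12 - spec.sigma_from ** 12)
        return coef * (1.0 / r12).sum(axis=(1, 2))

    if isinstance(spec, HardSphereClash):
        return _hard_sphere_series(arr, topology, spec)

    if isinstance(spec, DebyeHuckel):
        return _debye_huckel_series(arr, topology, spec)

    raise FepError(f"unknown perturbation spec {type(spec).__name__}")


def delta_u(frame: np.ndarray, topology: MultiBasinTopology, spec) -> float:
    """Delta-U of a single frame in epsilon."""
    return float(delta_u_series(frame, topology, spec)[0])


def _hard_sphere_series(arr: np.ndarray, topology: MultiBasinTopology,
                        spec: HardSphereClash) -> np.ndarray:
    from scipy.spatial import cKDTree

    ref = topology.atoms_ref
    lig = _as_selection(spec.ligand).resolve(ref)
    ext = spec.external
    if spec.clash_selection is not None:
        clash_idx = _as_selection(spec.clash_selection).resolve(ext)
    else:
        align_mask = _as_selection(spec.alignment).mask(ext)
        clash_idx = np.flatnonzero(~align_mask)
        if clash_idx.size == 0:
            raise FepError("external structure has no clash atoms outside "
                           "the alignment selection")
    out = np.zeros(arr.shape[0])
    for f in range(arr.shape[0]):
        frame_struct = ref.copy(coord=arr[f])
        aligned, _ = superpose(ext, frame_struct, spec.alignment)
        tree = cKDTree(aligned.coord[clash_idx])
        dmin, _ = tree.query(arr[f, lig], k=1)
        if float(np.min(dmin)) < spec.clash_distance:
            out[f] = np.inf
    return out


def _debye_huckel_series(arr: np.ndarray, topology: MultiBasinTopology,
                         spec: DebyeHuckel) -> np.ndarray:
    if topology.charges is None:
        raise FepError("Debye-Hueckel perturbation requires per-atom "
                       "charges on the topology")
    ref = topology.atoms_ref
    lig = _as_selection(spec.ligand).resolve(ref)
    sca = _as_selection(spec.scaffold).resolve(ref)
    q = topology.charges
    kappa = debye_kappa(spec.ionic_strength, spec.dielectric)
    lb = bjerrum_length(spec.dielectric)
    qq = q[lig, None] * q[None, sca]
    d = arr[:, lig, None, :] - arr[:, None, sca, :]
    r = np.sqrt(np.einsum("flsc,flsc->fls", d, d))
    shift = lb * np.exp(-kappa * spec.cutoff) / spec.cutoff
    u_kt = qq[None] * np.where(
        r < spec.cutoff, lb * np.exp(-kappa * r) / r - shift, 0.0)
    return u_kt.sum(axis=(1, 2)) * spec.kT   # kT -> epsilon


# ---------------------------------------------------------------------------
# Exponential averaging
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PerturbedProfile:
    """dF(rho) in k_B T with per-bin frame and survivor counts."""

    bin_centers: np.ndarray
    delta_f: np.ndarray        # k_B T; +inf where no frame survives
    n_frames: np.ndarray
    n_surviving: np.ndarray
    bin_width: float = 1.0

    def value_at(self, rho: float) -> float:
        idx = int(np.argmin(np.abs(self.bin_centers - rho)))
        if abs(self.bin_centers[idx] - rho) > 0.5 * self.bin_width + 1e-9:
            raise FepError(f"rho={rho} outside profile range")
        return float(self.delta_f[idx])

    def to_tsv(self, path: str, header: str = "") -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("# rho_center\tdeltaF_kT\tn_frames\tn_surviving\n")
            for c, f, n, s in zip(self.bin_centers, self.delta_f,
                                  self.n_frames, self.n_surviving):
                fh.write(f"{c:.6f}\t{f:.6f}\t{int(n)}\t{int(s)}\n")


def perturbed_free_energy(rho_series: np.ndarray,
                          du_series: np.ndarray,
                          bin_width: float = 1.0,
                          kT: float = KT,
                          range_: tuple[float, float] | None = None,
                          ) -> PerturbedProfile:
    """Per-bin exponential average of exp(-dU/kT) (log-space).

    ``du_series`` is in epsilon; dF is returned in k_B T.  Bins where every
    frame is rejected (dU = inf) report +inf.
    """
    rho = np.asarray(rho_series, dtype=float)
    du = np.asarray(du_series, dtype=float)
    if rho.shape != du.shape:
        raise FepError("rho and dU series must have equal length")
    if range_ is None:
        lo = np.floor(rho.min() / bin_width) * bin_width
        hi = np.ceil(rho.max() / bin_width) * bin_width
    else:
        lo, hi = range_
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    which = np.clip(np.searchsorted(edges, rho, side="right") - 1,
                    0, n_bins - 1)
    inside = (rho >= edges[0]) & (rho <= edges[-1])

    centers = 0.5 * (edges[:-1] + edges[1:])
    delta_f = np.full(n_bins, np.nan)
    n_frames = np.zeros(n_bins, dtype=np.int64)
    n_surv = np.zeros(n_bins, dtype=np.int64)
    log_boltz = -du / kT     # -inf where rejected
    for b in range(n_bins):
        sel = inside & (which == b)
        n = int(sel.sum())
        if n == 0:
            continue
        n_frames[b] = n
        vals = log_boltz[sel]
        finite = np.isfinite(vals)
        n_surv[b] = int(finite.sum())
        if n_surv[b] == 0:
            delta_f[b] = np.inf
        else:
            delta_f[b] = -(logsumexp(vals[finite]) - np.log(n))
    return PerturbedProfile(bin_centers=centers, delta_f=delta_f,
                            n_frames=n_frames, n_surviving=n_surv,
                            bin_width=float(bin_width))


# ---------------------------------------------------------------------------
# Direct-simulation counterpart and combination scans
# ---------------------------------------------------------------------------

def apply_steric_inflation(topology: MultiBasinTopology,
                           spec: StericInflation) -> MultiBasinTopology:
    """Topology with the inflation Delta-U added as explicit pair terms.

    Because both the original and inflated wall share the r^-12 form, the
    difference is a single r^-12 term with an effective diameter
    (sigma_to^12 - sigma_from^12)^(1/12); simulating this topology directly
    is the independent route against which the exponential-average estimate
    can be checked.
    """
    if spec.sigma_to < spec.sigma_from:
        raise FepError("sigma_to must be >= sigma_from")
    lig, res = spec.pair_indices(topology)
    pairs = [(min(l, p), max(l, p)) for l in lig.tolist()
             for p in res.tolist()]
    sigma_eff = (spec.sigma_to ** 12 - spec.sigma_from ** 12) ** (1.0 / 12.0)
    new_pairs = np.array(pairs, dtype=np.int64).reshape(len(pairs), 2)
    return topology.replace(
        extra_ev=np.vstack([topology.extra_ev, new_pairs]),
        extra_ev_sigma=np.concatenate(
            [topology.extra_ev_sigma, np.full(len(pairs), sigma_eff)]),
        extra_ev_eps=np.concatenate(
            [topology.extra_ev_eps, np.full(len(pairs), spec.epsilon)]),
    )


def combination_scan(frames, topology: MultiBasinTopology,
                     rho_series: np.ndarray,
                     residues: Sequence[tuple[str, int]],
                     ligand: "AtomSelection | str",
                     well_rho: float, barrier_rho: float,
                     n_range: Sequence[int] = (1, 2, 3, 4, 5, 6),
                     bin_width: float = 1.0,
                     sigma_from: float = 2.1, sigma_to: float = 3.0,
                     epsilon: float = 2.0 * KT,
                     kT: float = KT) -> pd.DataFrame:
    """Perturb every residue combination and report barrier increases.

    For each subset size N, every combination of the candidate residues
    (given as (chain, residue_number)) is inflated and the increase of the
    barrier-bin free energy relative to the well bin is recorded; the subset
    maximizing the increase is flagged per N.
    """
    residues = list(residues)
    if max(n_range) > len(residues):
        raise FepError(
            f"subset size {max(n_range)} exceeds {len(residues)} residues")
    arr = _frames_array(frames)
    rho = np.asarray(rho_series, dtype=float)

    # precompute per-residue dU so subsets are sums
    per_res_du = {}
    for chain, resnum in residues:
        spec = StericInflation(
            residues=AtomSelection(chain=chain, residues=[resnum]),
            ligand=ligand, sigma_from=sigma_from, sigma_to=sigma_to,
            epsilon=epsilon)
        per_res_du[(chain, resnum)] = delta_u_series(arr, topology, spec)

    rows = []
    for n in n_range:
        for subset in itertools.combinations(residues, n):
            du = np.sum([per_res_du[r] for r in subset], axis=0)
            prof = perturbed_free_energy(rho, du, bin_width=bin_width, kT=kT)
            dd = prof.value_at(barrier_rho) - prof.value_at(well_rho)
            rows.append({"n": n,
                         "subset": "+".join(f"{c}:{r}" for c, r in subset),
                         "barrier_increase_kT": dd})
    df = pd.DataFrame(rows)
    df["best_for_n"] = False
    for n in n_range:
        sub = df[df["n"] == n]
        df.loc[sub["barrier_increase_kT"].idxmax(), "best_for_n"] = True
    return df


# ---------------------------------------------------------------------------
# Charge utilities
# ---------------------------------------------------------------------------

def fold_hydrogen_charges(charges: Mapping[tuple[str, int, str], float],
                          bonds: Sequence[tuple[tuple[str, int, str],
                                                tuple[str, int, str]]],
                          ) -> dict[tuple[str, int, str], float]:
    """Fold hydrogen partial charges into their bonded heavy atoms.

    ``charges`` maps (chain, residue_number, atom_name) to charge (e) for a
    fully protonated force field; ``bonds`` is the covalent connectivity.
    Hydrogens are recognized by atom name.  Returns a heavy-atom-only table.
    """
    def is_h(key):
        name = key[2].strip().lstrip("0123456789")
        return name[:1].upper() == "H"

    out = {k: float(v) for k, v in charges.items() if not is_h(k)}
    for a, b in bonds:
        ha, hb = is_h(a), is_h(b)
        if ha == hb:
            continue
        h, heavy = (a, b) if ha else (b, a)
        if heavy not in out:
            raise FepError(f"hydrogen {h} bonded to unknown heavy {heavy}")
        out[heavy] += float(charges[h])
    return out
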