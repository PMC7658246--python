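# Methods

## The model

`ribogate` implements an all-heavy-atom, multi-basin structure-based
("Gō-like") force field.  The potential of a configuration is

```
V =  Σ_bonds      (ε_b/2) (r − r_o)²
   + Σ_angles     (ε_θ/2) (θ − θ_o)²
   + Σ_impropers  (ε_χ/2) (χ − χ_o)²
   + Σ_bb-dihed   ε_bb F(φ)  +  Σ_sc-dihed  ε_sc F(φ)
   + Σ_non-contacts  ε_nc (σ_nc / r_ij)¹²
   + Σ_contacts      ε_c_k f(σ_ij,k, r_ij)
```

with `F(φ) = [1 − cos(φ − φ_o)] + ½[1 − cos 3(φ − φ_o)]` and
`f(σ, r) = (σ/r)¹² − 2(σ/r)⁶`.  Defaults (reduced units: energies in ε,
lengths in Å, k_B = 1): ε_b = 100 ε/Å², ε_θ = 80 ε/rad², ε_χ = 40 ε/rad²,
ε_nc = 0.1 ε, σ_nc = 2.5 Å.  Reference values of all bonded terms are
measured from the first endpoint structure.

Native contacts come from a shadow contact map: an atom pair is a contact
when it lies within 6 Å, satisfies the minimum residue separation of its
polymer type (3 for protein, 1 for RNA and for single-bead chemistries;
inter-chain pairs are always eligible), and no third atom lies within the
1 Å shadowing radius of the connecting segment.  Pairs connected through one
or two bonds are excluded from the contact list; pairs within three bonds,
and contact pairs, are excluded from the generic excluded volume.

A dual-basin model merges two single-basin topologies built from the two
endpoint structures.  Bonded terms come from the first (PRE) basin.  The
contact set is the union of all PRE contacts — with σ rescaled by 0.96 to
counteract entropic inflation of effective distances — and the
ligand–scaffold contacts found only in the POST basin.  Relative contact
weights: ligand–scaffold contacts unique to PRE carry 0.15 ε_c, unique to
POST 0.275 ε_c, designated anchor pairs 1.5 ε_c, all others 1 ε_c.  When a
pair appears in both basins with different distances the PRE distance
(rescaled) is kept as a single term.  The overall scale ε_c is fixed either
directly (`set_contact_epsilon`) or by the normalization convention: total
stabilizing energy (contacts + flexible dihedrals) equals N_atoms·ε,
apportioned contact:dihedral = 2:1 and backbone:side-chain dihedral = 2:1
with uniform per-term strengths.  The absolute value of ε_c is therefore
system-dependent by construction; no specific numeric value is claimed for
any particular assembly.

Residue connectivity is template-driven.  Unknown residue chemistry raises
an error instead of being guessed; the built-in table registers only the
single-bead chemistries used by the synthetic systems ("GB" isolated
scaffold bead, "LB" chain-linked ligand bead), and users register
`ResidueTemplate` entries for anything else.

## Sampling

Langevin dynamics in reduced units: temperature T = 0.5 ε/k_B (so
k_B T = 0.5 ε), time step 0.002, friction 1/time by default, all masses 1.
The discretization is BAOAB (kick / drift / Ornstein–Uhlenbeck /
drift / kick), which reduces to velocity Verlet at zero friction and gives
configurational averages accurate to O(dt²).  A fixed seed reproduces a
trajectory bit-for-bit; the output stride only selects which frames are
stored and does not touch the noise stream.  Position restraints are
isotropic harmonic tethers (k/2)|x − x₀|², default k = 0.1 ε/Å², applied to
a named selection (the synthetic gate runs restrain the scaffold at
10 ε/Å² so the pore geometry is rigid while the ligand diffuses).

All interactions are evaluated directly (no neighbor lists): every system
this package targets at desk scale has under a few hundred atoms, where the
exact O(N²) sum is both faster and simpler than list maintenance.  One
reduced time unit corresponds to roughly 1 ns of effective dynamics for
this model class; this constant is used only to label axes, never in a
computation.

## Analysis stack

**Coordinates** are declarative: distances between geometric centers of
selections, single atom-pair distances, and weighted linear combinations
(the ρ-style coordinates).  Candidate pools for coordinate optimization
enumerate all single distances plus all pairwise combinations w·d_i +
(1−w)·d_j over a weight grid (default 0–1 in steps of 0.05).

**Free energies** are histogram estimates F = −k_B T ln(count/total),
offset so the lowest populated bin is zero; empty bins stay undefined and
are never interpolated.  Default bin widths: 0.5 Å for 1D profiles, 1 Å per
axis in 2D.  Barriers are measured on the minimax path between the bins
holding the two minima (Dijkstra-style widest-path search over bin
adjacency), minus the higher of the two minima.  Robustness is assessed on
contiguous 1/5 blocks of the data.

**Kinetics** uses sticky assignment to circular states (radius 3 Å, strict
inequality): once a state is entered the label persists until another
state's boundary is crossed.  Rates are k_ij = N_ij/τ_i with rates reported
only above a transition-count threshold (default 20); below it the pair is
flagged "insufficient events", never zero.  An optional exclusion region
(a weakly-sampled competing basin) relabels frames after its visits until
a designated reset state is re-entered.  Arrhenius conversion:
rate = prefactor·exp(−ΔF/k_B T), timescale = 1/rate.

**Transition paths** are maximal frame intervals strictly between leaving
one endpoint state and first entering the other; returns to the origin are
discarded.  TP detection runs on raw (non-sticky) region labels — sticky
labels contain no between-state frames by construction.  P(TP|ρ) is the
per-bin fraction of frames inside any TP interval; for diffusive dynamics a
coordinate that resolves the transition state peaks at 0.5.  The reported
peak considers only bins with at least 50 frames so near-empty bins cannot
dominate.  Candidate coordinates are ranked by (false positives ascending,
|peak − 0.5| ascending, label); a false positive is an apparent 1D
transition — between the 5th–95th percentile bands of ρ within the two
endpoint ensembles — whose interval overlaps no verified transition.

**FEP.**  ΔF(ρ) = −k_B T ln⟨exp(−ΔU/k_B T)⟩ per ρ-bin, accumulated in log
space (log-sum-exp).  Families: steric inflation (per-pair
ΔU = ε[(σ_to/r)¹² − (σ_from/r)¹²], defaults σ 2.1→3.0 Å, ε = 2 k_B T);
hard-sphere clash against an external structure rigidly superposed on each
frame by a named alignment selection (ΔU = ∞ below 2.5 Å, so ΔF reduces
exactly to −k_B T ln of the surviving fraction); and screened Debye–Hückel
electrostatics, U/k_BT = l_B q_i q_j e^{−κr}/r with the Bjerrum length
l_B = 7.01 Å (ε_r = 80, 298.15 K) and κ from the aqueous Debye relation
(κ⁻¹ = 9.71 Å at 100 mM monovalent salt), sharply truncated and shifted to
zero at 20 Å.  Charge tables are expected hydrogen-folded; a generic
folding utility driven by a connectivity table is provided.  Because the
inflation ΔU shares the r⁻¹² form, it can be added to a topology as exact
pair terms (effective diameter (σ_to¹² − σ_from¹²)^{1/12}), which is how
the exponential-average estimate is cross-checked against direct simulation
of the perturbed model.

**Contact statistics.**  A stabilizing contact is "formed" when the pair
distance is within 1.2× its endpoint value.  Steric contact probabilities
p_i^j use any-heavy-atom minimum distance below 4 Å between residue i and
the ligand, per ensemble window j; Δp_i = p_i^TSE − max(p_i^I1, p_i^I2)
ranks transition-state-specific residues, with reporting thresholds 0.1 and
0.35.  Ensemble windows narrower than 100 frames are symmetrically widened
with a logged warning — narrow literature-style windows are honored as
configuration but cannot be populated at desk-scale sample sizes.

## Synthetic study systems

**Gate system** (`make_gate_system`): a two-bead ligand chain (bond 2.5 Å)
bound in one of two pockets on a rigid scaffold — pocket A (6 beads,
PRE pose) at z = −7 Å and pocket B (2 beads, POST pose) at z = +7 Å —
separated by a 6-bead constriction ring of radius 3.6 Å in the z = 0 plane.
Exchanging pockets requires threading the ring, so the ring beads are a
programmed steric gate: they touch the ligand (< 4 Å) only in transit.
A wide-bore tube (radius 6 Å) plus end caps confines the ligand through
pair-specific soft walls (σ = 5 Å, ε = 1 ε) that keep it farther than the
4 Å contact cutoff at all times, so the confinement cannot register in
Δp; borderline ligand–tube pairs picked up by the shadow maps are removed
from the merged contact set for the same reason.  Contacts carry the
0.15/0.275/1.5 dual-basin weighting with ε_c = 1.2 ε, giving a measured
I1–I2 barrier of roughly 3 k_B T at T = 0.5 and reversible interconversion
within 10⁷ steps.  Scaffold positions get a small seeded jitter (0.1 Å) so
no symmetry is exact.  The progression coordinate is a 0.4/0.6-weighted
combination of the two ligand-bead distances to the bottom cap bead —
monotone along the pore axis — and the I1/TSE/I2 window centers are
computed from the endpoint and ring geometry, never fitted to data.

What the generator does *not* emulate: real nucleotide/amino-acid
chemistry, a deformable scaffold, competing binding modes, solvent or
electrostatic screening (charges are optional and off by default).
Passing tests on this system therefore demonstrate the correctness of the
machinery — map building, weighting, sampling, TP/FEP/Δp statistics — not
biological realism of any particular assembly.

**Analytic double wells** (`brownian_1d`, `brownian_2d`): overdamped
Euler–Maruyama dynamics (β = 1) on U(x) = h((x/a)² − 1)², optionally with
an orthogonal harmonic channel.  Barrier height, Boltzmann distribution and
mean first-passage times are known in closed form or by quadrature, giving
exact oracles for the landscape, transition-path and rate stages.  A
stability guard rejects time steps beyond the explicit-Euler limit
(dt · 23 h D / a² > 1).

## Verification design and problem sizes

The default verification runs use: 1.2×10⁷ steps of 1D Brownian dynamics
(h = 4 k_B T, dt = 10⁻³; ≈ 600–700 barrier crossings) and one 8×10⁶-step
Langevin run of the 82-atom gate system (stride 40, ≈ 2×10⁵ frames) for
the landscape, gate-recovery and inflation analyses; the full 2.1→3.0 Å
inflation of all six ring beads is evaluated through the exponential
average, where it raises the threading barrier by ≈ 2.6 k_B T.

The FEP-versus-direct cross-check needs its own design.  The equivalence
of the exponential average with direct simulation of the perturbed model
is a per-bin identity, but verifying it demands dense sampling of the
barrier-top bin in *both* simulations, and the standard two-pocket system
crosses its barrier only a handful of times per desk-scale run — at that
event count, relative well depths (and even barrier-top densities)
fluctuate by ≈ 0.3–0.5 k_B T between independent runs, swamping any
estimator error.  The cross-check therefore runs on a fast-mixing
instance of the same generator (`make_fep_check_system`): a single-bead
ligand, softer pockets (ε_c = 0.6), and the far pocket blocked by wide
soft walls in both base and perturbed models, leaving one ergodic
component in which the approach to the constriction is sampled
continuously.  With a σ 2.1→2.8 Å inflation (≈ 1.2 k_B T at the barrier
top), a 6×10⁶-step base run and a 10⁷-step perturbed run, the two routes
agree to ≈ 0.1–0.15 k_B T at the pocket-anchored mid-channel and
barrier-top bins (checked against a 0.3 k_B T tolerance).

## Numerical choices and degenerate inputs

* Histogram bins with zero counts are NaN, excluded from barrier paths.
* Microcanonical energy conservation is quantified as the secular trend
  (regression slope) of total energy; the bounded oscillation of the
  symplectic shadow energy (~10⁻⁴ ε at the default time step on a stiff
  bond) is not drift.
* Exponential averages run in log space; fully-rejected bins report +∞.
* Angle forces clamp sin θ at 10⁻⁸; degenerate (collinear) dihedral
  geometries contribute zero force for that term.
* Superposition requires ≥ 3 non-collinear shared fit atoms (singular-value
  check) and matches atoms by (chain, residue, atom-name) identity.
* Alternate PDB locations resolve to the highest-occupancy conformer.
* "Functional group (non-backbone)" means the nucleotide base (sugar and
  phosphate excluded, both primed and starred atom spellings recognized) or
  the amino-acid side chain from CB; for single-bead residues the group
  degenerates to the whole residue.
* Residue numbering follows the source PDB exactly; no renumbering.
* Sticky state discs use strict inequality (< radius), so a frame exactly
  on a boundary does not enter.
* Ties in coordinate ranking break lexicographically by label.

## Known limitations

* The Debye–Hückel prefactor convention (Bjerrum-length form at 298.15 K)
  is one of several in circulation; constants are stated above to the
  precision used, and screened-electrostatics results should be read
  qualitatively.
* The normalization convention fixes ratios, not the per-contact strength
  of any specific published system.
* The hard-sphere route superposes the external structure once per frame;
  for very long trajectories this is the slowest analysis path.
* Production-scale assemblies (10⁶+ atoms, 10⁸+ steps) are out of scope:
  the evaluation kernels are exact but direct-sum, and the trajectory
  container keeps frames in memory.
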