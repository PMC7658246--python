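# ribogate

Multi-basin structure-based ("Gō-like") models and steric-gate analysis of
two-state conformational transitions.

Large conformational rearrangements in molecular machines — the motion of a
tRNA between binding sites on the large ribosomal subunit is the motivating
case — are often rate-limited not by the making and breaking of stabilizing
interactions but by *sterics*: a few residues form a constriction the moving
molecule must thread, and sub-ångström changes to that constriction shift
the kinetics by an order of magnitude.  `ribogate` is a desk-scale pipeline
for studying exactly this situation with simplified, structure-defined
energetics:

* **Model building** — all-heavy-atom structure-based force fields whose
  minima are two endpoint structures (PRE/POST).  Native contacts come from
  a shadow contact map (6 Å cutoff, 1 Å shadowing radius); contacts unique
  to either endpoint are down-weighted (0.15/0.275 ε_c) so the two binding
  modes compete, designated anchor pairs are strengthened (1.5 ε_c), and
  first-basin contact distances are rescaled by 0.96.
* **Sampling** — Langevin dynamics in reduced units (T = 0.5 ε/k_B, step
  0.002, BAOAB discretization), with harmonic position restraints.
* **Analysis** — declarative reaction coordinates (center distances,
  atom-pair distances, weighted combinations ρ = Σ w_i r_i); histogram free
  energies F = −k_BT ln P with minimax-path barriers; sticky-state kinetics
  k_ij = N_ij/τ_i; transition-path conditional probabilities P(TP|ρ) with
  the diffusive 0.5 transition-state diagnostic and coordinate ranking;
  free-energy perturbation ΔF(ρ) = −k_BT ln⟨e^{−ΔU/k_BT}⟩_ρ for steric
  inflation, hard-sphere clashes against aligned external structures, and
  screened (Debye–Hückel) electrostatics; and transition-state contact
  statistics Δp_i = p_i^TSE − max(p_i^I1, p_i^I2) that identify gate
  residues.
* **Synthetic study systems** — a two-pocket "gate" system (a bead ligand
  that must thread a programmed constriction ring) and analytic double
  wells with known barriers, distributions and first-passage times, so
  every stage has an exact or quadrature oracle.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Build the synthetic gate system, sample it, and ask which scaffold residues
the ligand presses against only while crossing the barrier:

```python
import numpy as np
from ribogate import (make_gate_system, simulate_gate, evaluate_coordinate,
                      free_energy, barrier_height,
                      steric_contact_probability, gate_candidates)

system = make_gate_system()                     # 82 atoms, 2 pockets, 1 ring
traj = simulate_gate(system, n_steps=2_000_000, seed=11, output_stride=25)
rho = evaluate_coordinate(system.rho_spec, traj, system.pre)

profile = free_energy(rho, bin_width=0.5)
print("barrier [kT]:",
      round(barrier_height(profile, system.rho_i1, system.rho_i2), 2))

table = steric_contact_probability(traj, system.topology, "chain L",
                                   rho, system.windows(), cutoff=4.0)
ranked = gate_candidates(table)
print(ranked.head(6)[["chain", "residue", "p_TSE", "delta_p"]])
```

Output (seed 11):

```
barrier [kT]: 2.55
  chain  residue     p_TSE   delta_p
0     S        9  0.898863  0.898647
1     S        8  0.897295  0.897295
2     S       11  0.857311  0.857311
3     S       12  0.854567  0.854567
4     S       10  0.779694  0.779694
5     S        7  0.736966  0.736966
```

The six residues with Δp > 0.35 are exactly the constriction-ring beads the
generator programmed (scaffold residues 7–12): the ligand touches them with
high probability in the transition-state window and essentially never in
either pocket.  The ≈ 2.5–3 k_BT barrier (longer runs resolve it more
fully) is what makes pocket exchange a rare, two-state event at T = 0.5.

The same stages are scriptable from a shell:

```bash
ribogate synth --outdir fixtures --seed 0
ribogate build --pre fixtures/gate_pre.pdb --post fixtures/gate_post.pdb \
         --ligand "chain L" --scaffold "chain S" --out merged.top
ribogate simulate --topology merged.top --start fixtures/gate_pre.pdb \
         --steps 200000 --seed 1 --restrain "chain S" \
         --restraint-spring 10 --out traj.npz
```

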