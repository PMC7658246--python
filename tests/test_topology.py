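"""Shadow contact maps, topology building, merging and normalization."""

import numpy as np
import pytest

from ribogate.structures import MolecularStructure
from ribogate.topology import (TopologyError, build_single_basin,
                               load_topology, merge_multibasin,
                               normalize_strengths, save_topology,
                               set_contact_epsilon, shadow_contact_map)
from ribogate.dynamics import total_energy, contact_potential

from conftest import bead_chain


def beads(coords, chains=None, res=None, names=None, resnames=None):
    n = len(coords)
    return MolecularStructure(
        atom_name=names or ["BD"] * n,
        res_id=res if res is not None else np.arange(1, n + 1),
        res_name=resnames or ["GB"] * n,
        chain_id=chains or ["S"] * n,
        coord=np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# shadow contact map
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("b,occluder,expect", [
    ([8.0, 0, 0], None, 0),                 # beyond the 6 A cutoff
    ([4.0, 0, 0], None, 1),                 # plain contact, sigma = 4
    ([5.0, 0, 0], [2.5, 0.4, 0.0], 0),      # occluded: 0.4 A off the segment
    ([5.0, 0, 0], [2.5, 1.4, 0.0], 1),      # occluder misses by > 1 A
])
def test_shadow_map_basic_geometry(b, occluder, expect):
    coords = [[0.0, 0.0, 0.0], b]
    chains = ["S", "T"]
    if occluder is not None:
        coords.append(occluder)
        chains.append("U")
    cm = shadow_contact_map(beads(coords, chains=chains))
    lig_pairs = [p for p in cm.pairs.tolist() if set(p) >= {0, 1}]
    assert len(lig_pairs) == expect
    if expect and occluder is None:
        assert cm.sigma[0] == pytest.approx(np.linalg.norm(np.array(b)))


def test_shadow_map_sequence_separation():
    # same chain, adjacent residues: eligible for bead/rna (sep 1) but a
    # protein pair needs separation >= 3
    s = beads([[0, 0, 0], [4, 0, 0]], chains=["S", "S"], res=[10, 11])
    assert len(shadow_contact_map(s)) == 1
    p = beads([[0, 0, 0], [4, 0, 0]], chains=["A", "A"], res=[10, 11],
              names=["CA", "CA"], resnames=["GLY", "GLY"])
    assert len(shadow_contact_map(p)) == 0
    p2 = beads([[0, 0, 0], [4, 0, 0]], chains=["A", "A"], res=[10, 13],
               names=["CA", "CA"], resnames=["GLY", "GLY"])
    assert len(shadow_contact_map(p2)) == 1


def _oracle_shadow_map(structure, cutoff=6.0, radius=1.0):
    """Independent brute-force triple loop (bead chemistry, seq sep 1)."""
    c = structure.coord
    n = len(c)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if (structure.chain_id[i] == structure.chain_id[j]
                    and abs(int(structure.res_id[i])
                            - int(structure.res_id[j])) < 1):
                continue
            d = np.linalg.norm(c[i] - c[j])
            if d > cutoff:
                continue
            shadowed = False
            for k in range(n):
                if k in (i, j):
                    continue
                seg = c[j] - c[i]
                t = np.clip(np.dot(c[k] - c[i], seg) / np.dot(seg, seg),
                            0, 1)
                if np.linalg.norm(c[k] - (c[i] + t * seg)) < radius:
                    shadowed = True
                    break
            if not shadowed:
                out.add((i, j))
    return out


def test_shadow_map_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for trial in range(5):
        n = int(rng.integers(10, 50))
        coords = rng.uniform(0, 14, (n, 3))
        chains = [str(c) for c in rng.choice(list("STU"), n)]
        s = MolecularStructure(atom_name=["BD"] * n,
                               res_id=np.arange(1, n + 1),
                               res_name=["GB"] * n, chain_id=chains,
                               coord=coords)
        got = set(map(tuple, shadow_contact_map(s).pairs.tolist()))
        assert got == _oracle_shadow_map(s)


# ---------------------------------------------------------------------------
# single-basin builder
# ---------------------------------------------------------------------------

def test_build_single_basin_bonded_enumeration():
    # 3-bead chain: two bonds with measured lengths, one angle, no dihedral
    s = beads([[0, 0, 0], [1.5, 0, 0], [2.0, 1.4, 0]],
              resnames=["LB"] * 3, chains=["L"] * 3)
    topo = build_single_basin(s, shadow_contact_map(s))
    assert len(topo.bonds) == 2
    assert topo.bond_r0 == pytest.approx([1.5, np.hypot(0.5, 1.4)])
    assert len(topo.angles) == 1
    u = s.coord[0] - s.coord[1]
    v = s.coord[2] - s.coord[1]
    expected = np.arccos(u @ v / np.linalg.norm(u) / np.linalg.norm(v))
    assert topo.angle_theta0[0] == pytest.approx(expected)
    assert len(topo.dihedrals) == 0

    s4 = bead_chain(4, seed=7)
    topo4 = build_single_basin(s4, shadow_contact_map(s4))
    assert len(topo4.dihedrals) == 1
    assert np.isfinite(topo4.dihedral_phi0[0])


def test_build_contact_count_consistency():
    rng = np.random.default_rng(9)
    a = np.cumsum(rng.normal(0, 1, (6, 3)) + [2.5, 0, 0], axis=0)
    b = a + [0.0, 4.0, 0.0]
    s = MolecularStructure(
        atom_name=["BD"] * 12,
        res_id=list(range(1, 7)) * 2,
        res_name=["LB"] * 12,
        chain_id=["L"] * 6 + ["M"] * 6,
        coord=np.vstack([a, b]))
    cm = shadow_contact_map(s)
    topo = build_single_basin(s, cm)
    # contacts dropped by the builder must be 1-2/1-3 bonded pairs
    pairs = set(map(tuple, cm.pairs.tolist()))
    got = set(map(tuple, topo.contacts.tolist()))
    assert got <= pairs
    dropped = pairs - got
    for i, j in dropped:
        assert s.chain_id[i] == s.chain_id[j]
        assert abs(int(s.res_id[i]) - int(s.res_id[j])) <= 2


def test_unknown_residue_chemistry_is_refused():
    s = beads([[0, 0, 0], [2, 0, 0]], resnames=["XXX", "XXX"])
    with pytest.raises(TopologyError, match="XXX"):
        build_single_basin(s, shadow_contact_map(s))


# ---------------------------------------------------------------------------
# multi-basin merge
# ---------------------------------------------------------------------------

def _two_pose_system():
    """Ligand bead near scaffold bead A (PRE) or bead B (POST)."""
    scaffold = [[0.0, 0, 0], [10.0, 0, 0], [5.0, 3.0, 0]]
    pre = beads(scaffold + [[3.0, 0, 0]], chains=["S"] * 3 + ["L"],
                res=[1, 2, 3, 1], resnames=["GB"] * 3 + ["LB"])
    post = beads(scaffold + [[7.0, 0, 0]], chains=["S"] * 3 + ["L"],
                 res=[1, 2, 3, 1], resnames=["GB"] * 3 + ["LB"])
    t_pre = build_single_basin(pre, shadow_contact_map(pre))
    t_post = build_single_basin(post, shadow_contact_map(post,
                                                         basin_tag="POST"))
    return pre, post, t_pre, t_post


def test_merge_weights_and_sigma_scaling():
    pre, post, t_pre, t_post = _two_pose_system()
    merged = merge_multibasin(t_pre, t_post, "chain L", "chain S")

    by_pair = {tuple(p): k for k, p in enumerate(merged.contacts.tolist())}
    pre_pairs = set(map(tuple, t_pre.contacts.tolist()))
    post_pairs = set(map(tuple, t_post.contacts.tolist()))

    # contact set = PRE union POST-unique ligand-scaffold pairs
    assert len(merged.contacts) == len(pre_pairs | {
        p for p in post_pairs - pre_pairs
        if 3 in p})   # atom 3 is the ligand
    for pair, k in by_pair.items():
        if pair in pre_pairs and pair in post_pairs:
            assert merged.contact_weight[k] == 1.0
            assert merged.contact_tag[k] == "BOTH"
        if pair in pre_pairs:
            # PRE distances rescaled by 0.96, native values kept
            assert merged.contact_sigma[k] == pytest.approx(
                0.96 * merged.contact_sigma_native[k])
        elif pair in post_pairs:
            assert merged.contact_weight[k] == pytest.approx(0.275)
            assert merged.contact_sigma[k] == pytest.approx(
                merged.contact_sigma_native[k])
    pre_unique_lig = [k for pair, k in by_pair.items()
                      if pair in pre_pairs - post_pairs and 3 in pair]
    assert pre_unique_lig
    for k in pre_unique_lig:
        assert merged.contact_weight[k] == pytest.approx(0.15)


def test_merge_identity_limit():
    pre, post, t_pre, t_post = _two_pose_system()
    merged = merge_multibasin(
        t_pre, t_pre, "chain L", "chain S",
        weights={"pre_unique": 1.0, "post_unique": 1.0, "anchor": 1.0},
        pre_sigma_scale=0.96)
    assert len(merged.contacts) == len(t_pre.contacts)
    assert np.allclose(merged.contact_weight, 1.0)
    assert np.allclose(merged.contact_sigma, 0.96 * t_pre.contact_sigma)


def test_merge_rejects_mismatched_universe(chain6):
    t1 = build_single_basin(chain6, shadow_contact_map(chain6))
    other = bead_chain(5, seed=1)
    t2 = build_single_basin(other, shadow_contact_map(other))
    with pytest.raises(TopologyError, match="universe"):
        merge_multibasin(t1, t2, "chain L", "chain L")


def test_pre_structure_energy_under_merged_topology():
    """Native PRE frame: each PRE contact sits within 1% of its minimum
    depth at sigma scale 1.0 and is compressed (energy above the minimum,
    pushed inward) at the 0.96 rescale."""
    pre, post, t_pre, t_post = _two_pose_system()
    exact = merge_multibasin(t_pre, t_post, "chain L", "chain S",
                             pre_sigma_scale=1.0)
    for k, (i, j) in enumerate(exact.contacts.tolist()):
        if exact.contact_tag[k] == "POST":
            continue
        r = np.linalg.norm(pre.coord[i] - pre.coord[j])
        e = exact.contact_strength[k] * contact_potential(
            exact.contact_sigma[k], r)
        assert e == pytest.approx(-exact.contact_strength[k], rel=0.01)

    scaled = merge_multibasin(t_pre, t_post, "chain L", "chain S",
                              pre_sigma_scale=0.96)
    for k, (i, j) in enumerate(scaled.contacts.tolist()):
        if scaled.contact_tag[k] == "POST":
            continue
        r = np.linalg.norm(pre.coord[i] - pre.coord[j])
        # native distance now lies outside the (inward-shifted) minimum
        assert r > scaled.contact_sigma[k]
        e = contact_potential(scaled.contact_sigma[k], r)
        assert -1.0 < e < 0.0


# ---------------------------------------------------------------------------
# strength normalization
# ---------------------------------------------------------------------------

def _toy_for_normalization(n_atoms=10):
    s = bead_chain(n_atoms, seed=11)
    return build_single_basin(s, shadow_contact_map(s))


def test_normalize_strengths_closed_form():
    topo = _toy_for_normalization(10)
    nc = len(topo.contacts)
    nd = len(topo.dihedrals)
    assert nc >= 1 and nd >= 1
    out = normalize_strengths(topo)
    # hand algebra: total = N_atoms, contacts:dihedrals = 2:1
    total = out.contact_strength.sum() + out.dihedral_strength.sum()
    assert total == pytest.approx(10.0)
    assert out.contact_strength.sum() == pytest.approx(
        2.0 * out.dihedral_strength.sum())
    assert out.eps_c == pytest.approx((2.0 / 3.0) * 10.0 / nc)
    bb = out.dihedral_class == "backbone"
    if bb.any() and (~bb).any():
        assert out.dihedral_strength[bb].sum() == pytest.approx(
            2.0 * out.dihedral_strength[~bb].sum())


def test_normalize_scales_linearly_with_atom_count():
    topo = _toy_for_normalization(10)
    a = normalize_strengths(topo)
    b = normalize_strengths(topo, total_stabilizing=2.0 * topo.n_atoms)
    assert np.allclose(b.contact_strength, 2.0 * a.contact_strength)
    assert np.allclose(b.dihedral_strength, 2.0 * a.dihedral_strength)


def test_normalize_requires_terms():
    s = beads([[0, 0, 0], [1.5, 0, 0]], resnames=["LB"] * 2, chains=["L"] * 2)
    topo = build_single_basin(s, shadow_contact_map(s))
    with pytest.raises(TopologyError):
        normalize_strengths(topo)
    with pytest.raises(TopologyError):
        set_contact_epsilon(topo, -1.0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_topology_text_round_trip(tmp_path, gate_system):
    path = tmp_path / "topo.txt"
    topo = gate_system.topology
    save_topology(topo, path)
    back = load_topology(path)
    assert back.n_atoms == topo.n_atoms
    assert np.array_equal(back.contacts, topo.contacts)
    assert np.allclose(back.contact_sigma, topo.contact_sigma)
    assert np.allclose(back.contact_strength, topo.contact_strength)
    assert np.array_equal(back.contact_tag, topo.contact_tag)
    assert np.allclose(back.bond_r0, topo.bond_r0)
    assert np.allclose(back.extra_ev_sigma, topo.extra_ev_sigma)
    # energies agree between original and reloaded topology
    frame = topo.atoms_ref.coord
    e1, _ = total_energy(topo, frame)
    e2, _ = total_energy(back, frame)
    assert e1 == pytest.approx(e2, abs=1e-6)
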