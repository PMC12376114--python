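"""Independent brute-force oracles used by the test suite.

Everything here is written as plain, slow, loop-based code straight from the
interaction definitions, sharing no implementation with the package's
vectorized energy model or analysis routines.
"""

import math

import numpy as np

COULOMB = 332.0637


def _angle(p0, p1, p2):
    a, b = p0 - p1, p2 - p1
    c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.acos(max(-1.0, min(1.0, c)))


def _dihedral(p0, p1, p2, p3):
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return abs(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))


def brute_force_total_energy(config):
    """O(N^2) double-loop recomputation of the full system energy."""
    p = config.params
    from ligandshell.forcefield import build_topology

    ligs = config.ligands
    e = 0.0
    # bonded + Morse + guard per ligand
    for lid, lig in enumerate(ligs):
        topo = build_topology(lig.ligand_type)
        x = config.ligand_coords(lid)
        names = topo.bead_names
        for i, j in topo.bonds:
            k, r0 = p.bond_params(names[i], names[j])
            r = np.linalg.norm(x[i] - x[j])
            e += k * (r - r0) ** 2
        for i, j, k3 in topo.angles:
            ka, t0 = p.angle_params(names[i], names[j], names[k3])
            e += ka * (_angle(x[i], x[j], x[k3]) - t0) ** 2
        for i, j, k3, l in topo.dihedrals:
            v1, v2, v3, v4 = p.dihedral_params(names[i], names[j], names[k3],
                                               names[l])
            phi = _dihedral(x[i], x[j], x[k3], x[l])
            e += 0.5 * (v1 * (1 + math.cos(phi)) + v2 * (1 - math.cos(2 * phi))
                        + v3 * (1 + math.cos(3 * phi))
                        + v4 * (1 - math.cos(4 * phi)))
        # S-Au Morse to the anchor-site atom
        atom = config.core.anchor_sites[lig.anchor_site_id].position
        r = np.linalg.norm(x[0] - atom)
        e += p.morse_d_e * ((1 - math.exp(-p.morse_alpha * (r - p.morse_r_e))) ** 2 - 1)
        # core guard
        if p.guard_enabled:
            for bead in x:
                d = min(np.linalg.norm(bead - a) for a in config.core.atom_positions)
                if d < p.r_guard:
                    e += p.k_guard * (p.r_guard - d) ** 2
    # nonbonded: all bead pairs, exclusions inside a ligand
    beads = []  # (lid, idx_in_lig, pos, eps, sig, q)
    for lid, lig in enumerate(ligs):
        topo = build_topology(lig.ligand_type)
        x = config.ligand_coords(lid)
        for i, name in enumerate(topo.bead_names):
            spec = p.beads[name]
            beads.append((lid, i, x[i], spec.lj_epsilon, spec.lj_sigma,
                          topo.charges[i]))
    for a in range(len(beads)):
        for b in range(a + 1, len(beads)):
            la, ia, xa, ea, sa, qa = beads[a]
            lb, ib, xb, eb, sb, qb = beads[b]
            if la == lb:
                sep = abs(ia - ib)
                if sep < 3:
                    continue
                scale = p.one_four_scale if sep == 3 else 1.0
            else:
                scale = 1.0
            r = max(np.linalg.norm(xa - xb), 0.1)
            eps = math.sqrt(ea * eb)
            sig = math.sqrt(sa * sb)
            if r <= p.lj_cutoff:
                sr6 = (sig / r) ** 6
                e += scale * 4 * eps * (sr6 * sr6 - sr6)
            if qa * qb != 0.0 and r <= p.coul_cutoff:
                e += scale * COULOMB * qa * qb * math.exp(-r / p.debye_length) / (
                    p.dielectric * r)
    return e


def union_find_patches(positions, types, cutoff):
    """Brute-force O(N^2) union-find connected components of the same-type
    within-cutoff graph.  Returns a set of frozensets of indices."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if types[i] == types[j] and \
                    np.linalg.norm(positions[i] - positions[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def enumerate_fragments(positions, types, cutoff):
    """Exhaustive fragment enumeration: for every seed ligand with >= 3
    neighbours inside the cutoff, the PEG count of {seed + 3 nearest}.
    Returns (comps dict seed->count, eligible set)."""
    n = len(positions)
    comps, eligible = {}, set()
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i:
                continue
            d = np.linalg.norm(positions[i] - positions[j])
            if d <= cutoff:
                cand.append((d, j))
        if len(cand) < 3:
            continue
        cand.sort(key=lambda t: (round(t[0], 9), t[1]))
        chosen = [j for _, j in cand[:3]]
        comps[i] = int(types[i]) + sum(int(types[j]) for j in chosen)
        eligible.add(i)
    return comps, eligible
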