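"""United-atom force field for thiolate ligands on gold.

Ligand models
-------------
DDT (dodecanethiol) is a 13-bead chain: one sulfur anchor plus twelve
carbon united atoms.  The PEG ligand (2-ethoxyethane-1-thiol) is a 6-bead
chain: S, CH2, CH2, ether O, CH2, CH3.  Aliphatic hydrogens are folded into
their carbons (united-atom representation); no explicit hydrogens exist.

Interactions
------------
* harmonic bonds and angles, ``E = k (x - x0)^2``
* OPLS Fourier dihedrals
* 12-6 Lennard-Jones with a 10 A cutoff (geometric mixing)
* Debye-screened Coulomb with a 12 A cutoff, ethanol-like dielectric
* S-Au Morse attachment between each sulfur and its anchor-site gold atom
* a purely repulsive quadratic guard keeping beads out of the rigid core

Intra-ligand nonbonded pairs separated by one or two bonds are excluded,
1-4 pairs are scaled by 0.5, and more distant pairs count fully (OPLS
convention).  Gold interacts only through the S-Au Morse term and the
repulsive guard; the core itself is rigid and contributes no Au-Au energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

__all__ = [
    "BeadSpec",
    "LigandTopology",
    "ParameterSet",
    "build_topology",
    "lj_pair",
    "morse_pair",
    "screened_coulomb_pair",
    "opls_dihedral",
    "bonded_energy",
    "total_energy",
    "delta_energy",
    "EnergyModel",
    "KB_KCAL",
    "COULOMB_KCAL",
]

#: Boltzmann constant, kcal/(mol K)
KB_KCAL = 0.0019872041
#: Coulomb prefactor, kcal A / (mol e^2)
COULOMB_KCAL = 332.0637

_ELEMENT_CLASS = {"S": "S", "CH2": "C", "CH3": "C", "O_ether": "O"}


@dataclass(frozen=True)
class BeadSpec:
    name: str
    mass: float
    lj_epsilon: float
    lj_sigma: float
    charge: float

    def __post_init__(self):
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be positive")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be non-negative")


@dataclass(frozen=True)
class LigandTopology:
    """Unbranched bead chain anchored at sulfur (bead 0)."""

    ligand_type: str  # "PEG" or "DDT"
    bead_names: tuple[str, ...]
    charges: tuple[float, ...]  # per-bead partial charges (e)

    def __post_init__(self):
        if self.bead_names[0] != "S":
            raise ValueError("chain must be anchored at S")
        if len(self.charges) != len(self.bead_names):
            raise ValueError("one charge per bead required")

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def bonds(self) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(self.n_beads - 1)]

    @property
    def angles(self) -> list[tuple[int, int, int]]:
        return [(i, i + 1, i + 2) for i in range(self.n_beads - 2)]

    @property
    def dihedrals(self) -> list[tuple[int, int, int, int]]:
        return [(i, i + 1, i + 2, i + 3) for i in range(self.n_beads - 3)]


def build_topology(ligand_type: str) -> LigandTopology:
    """Standard PEG or DDT united-atom topology.

    PEG carries OPLS ether charges (O -0.5 e, alpha carbons +0.25 e each);
    DDT is apolar.
    """
    lt = ligand_type.upper()
    if lt == "DDT":
        names = ("S",) + ("CH2",) * 11 + ("CH3",)
        charges = (0.0,) * 13
    elif lt == "PEG":
        names = ("S", "CH2", "CH2", "O_ether", "CH2", "CH3")
        charges = (0.0, 0.0, 0.25, -0.5, 0.25, 0.0)
    else:
        raise ValueError(f"unknown ligand type {ligand_type!r}")
    return LigandTopology(lt, names, charges)


class ParameterSet:
    """All force-field constants, cutoffs, temperature and screening.

    Loaded from a versioned YAML file (see ``data/opls_ua.yaml``); any entry
    can be overridden via the ``overrides`` mapping (dotted keys, e.g.
    ``{"morse_s_au.D_e": 9.0, "debye_length": 3.0}``).
    """

    def __init__(self, data: dict):
        self._data = data
        self.temperature = float(data["temperature"])
        self.lj_cutoff = float(data["lj_cutoff"])
        self.coul_cutoff = float(data["coul_cutoff"])
        self.dielectric = float(data["dielectric"])
        self.debye_length = float(data["debye_length"])
        self.one_four_scale = float(data.get("one_four_scale", 0.5))
        self.mixing_rule = data.get("mixing_rule", "geometric")
        guard = data.get("core_guard", {})
        self.guard_enabled = bool(guard.get("enabled", True))
        self.r_guard = float(guard.get("r_guard", 2.5))
        self.k_guard = float(guard.get("k_guard", 50.0))
        m = data["morse_s_au"]
        self.morse_d_e = float(m["D_e"])
        self.morse_alpha = float(m["alpha"])
        self.morse_r_e = float(m["r_e"])
        self.beads = {
            name: BeadSpec(name, **spec) for name, spec in data["beads"].items()
        }
        self._bonds = {k: (v["k"], v["r0"]) for k, v in data["bonds"].items()}
        self._angles = {
            k: (v["k"], math.radians(v["theta0_deg"]))
            for k, v in data["angles"].items()
        }
        self._dihedrals = {k: tuple(v["v"]) for k, v in data["dihedrals"].items()}
        if self.temperature <= 0 or self.lj_cutoff <= 0 or self.coul_cutoff <= 0:
            raise ValueError("temperature and cutoffs must be positive")
        if self.dielectric <= 1:
            raise ValueError("dielectric must exceed 1")

    # -- loading -----------------------------------------------------------
    @classmethod
    def default(cls, overrides: dict | None = None) -> "ParameterSet":
        text = resources.files("ligandshell.data").joinpath("opls_ua.yaml").read_text()
        return cls.from_yaml_text(text, overrides)

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_yaml_text(fh.read(), overrides)

    @classmethod
    def from_yaml_text(cls, text: str, overrides: dict | None = None) -> "ParameterSet":
        data = yaml.safe_load(text)
        for key, val in (overrides or {}).items():
            node = data
            parts = key.split(".")
            for p in parts[:-1]:
                node = node[p]
            node[parts[-1]] = val
        return cls(data)

    # -- derived quantities ------------------------------------------------
    @property
    def kappa(self) -> float:
        """Inverse Debye length (1/A)."""
        return 1.0 / self.debye_length

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KCAL * self.temperature)

    # -- bonded lookups (keys canonicalised by element class) --------------
    @staticmethod
    def _keys(names) -> tuple[str, str]:
        classes = [_ELEMENT_CLASS[n] for n in names]
        return "-".join(classes), "-".join(classes[::-1])

    def _lookup(self, table: dict, names, what: str):
        fwd, bwd = self._keys(names)
        if fwd in table:
            return table[fwd]
        if bwd in table:
            return table[bwd]
        raise KeyError(f"no {what} parameters for {fwd}")

    def bond_params(self, name_i: str, name_j: str) -> tuple[float, float]:
        return self._lookup(self._bonds, (name_i, name_j), "bond")

    def angle_params(self, ni: str, nj: str, nk: str) -> tuple[float, float]:
        return self._lookup(self._angles, (ni, nj, nk), "angle")

    def dihedral_params(self, ni, nj, nk, nl) -> tuple[float, float, float, float]:
        return self._lookup(self._dihedrals, (ni, nj, nk, nl), "dihedral")

    def mix(self, eps_i, sig_i, eps_j, sig_j) -> tuple[float, float]:
        """OPLS geometric mixing for both epsilon and sigma."""
        return math.sqrt(eps_i * eps_j), math.sqrt(sig_i * sig_j)


# ---------------------------------------------------------------------------
# Pair potentials (vectorised over r)
# ---------------------------------------------------------------------------

def lj_pair(r, epsilon, sigma, cutoff):
    """12-6 Lennard-Jones, truncated (not shifted) at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    sr6 = (sigma / r) ** 6
    e = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return np.where(r <= cutoff, e, 0.0)


def morse_pair(r, d_e, alpha, r_e):
    """Morse potential, minimum -D_e at r_e, dissociating to 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    x = 1.0 - np.exp(-alpha * (r - r_e))
    return d_e * (x * x - 1.0)


def screened_coulomb_pair(q1, q2, r, kappa, eps_r, cutoff):
    """Debye-screened Coulomb, truncated at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    e = COULOMB_KCAL * q1 * q2 * np.exp(-kappa * r) / (eps_r * r)
    return np.where(r <= cutoff, e, 0.0)


def opls_dihedral(phi, v1, v2, v3, v4=0.0):
    """OPLS Fourier dihedral; trans (phi = pi) is the zero of every term."""
    phi = np.asarray(phi, dtype=float)
    return 0.5 * (v1 * (1.0 + np.cos(phi))
                  + v2 * (1.0 - np.cos(2.0 * phi))
                  + v3 * (1.0 + np.cos(3.0 * phi))
                  + v4 * (1.0 - np.cos(4.0 * phi)))


def _cross(a, b) -> np.ndarray:
    """Row-wise cross product without np.cross's axis bookkeeping."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _angle(p0, p1, p2) -> float:
    a = p0 - p1
    b = p2 - p1
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.acos(min(1.0, max(-1.0, cosang)))


def _dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle in [0, pi]; cis = 0, trans = pi (sign is irrelevant to
    the even OPLS Fourier form)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return abs(math.atan2(y, x))


# ---------------------------------------------------------------------------
# Energy model over a monolayer configuration
# ---------------------------------------------------------------------------

@dataclass
class _LigandTables:
    """Per-topology cached parameter arrays."""

    bond_k: np.ndarray
    bond_r0: np.ndarray
    angle_k: np.ndarray
    angle_t0: np.ndarray
    dihedral_v: np.ndarray  # (n_dih, 4)
    eps: np.ndarray
    sigma: np.ndarray
    charge: np.ndarray
    # intra nonbonded pairs (separation >= 3) and their scale factors
    nb_pairs: np.ndarray  # (m, 2)
    nb_scale: np.ndarray  # (m,)


def _tables_for(topology: LigandTopology, params: ParameterSet) -> _LigandTables:
    names = topology.bead_names
    bond_k, bond_r0 = [], []
    for i, j in topology.bonds:
        k, r0 = params.bond_params(names[i], names[j])
        bond_k.append(k)
        bond_r0.append(r0)
    angle_k, angle_t0 = [], []
    for i, j, k in topology.angles:
        ka, t0 = params.angle_params(names[i], names[j], names[k])
        angle_k.append(ka)
        angle_t0.append(t0)
    dih_v = []
    for i, j, k, l in topology.dihedrals:
        dih_v.append(params.dihedral_params(names[i], names[j], names[k], names[l]))
    n = topology.n_beads
    pairs, scales = [], []
    for i in range(n):
        for j in range(i + 3, n):
            pairs.append((i, j))
            scales.append(params.one_four_scale if j - i == 3 else 1.0)
    return _LigandTables(
        bond_k=np.array(bond_k),
        bond_r0=np.array(bond_r0),
        angle_k=np.array(angle_k),
        angle_t0=np.array(angle_t0),
        dihedral_v=np.array(dih_v).reshape(-1, 4),
        eps=np.array([params.beads[nm].lj_epsilon for nm in names]),
        sigma=np.array([params.beads[nm].lj_sigma for nm in names]),
        charge=np.array(topology.charges, dtype=float),
        nb_pairs=np.array(pairs, dtype=int).reshape(-1, 2),
        nb_scale=np.array(scales),
    )


#: Bead separation below which a configuration is flagged as overlapping.
OVERLAP_R = 0.1


class EnergyModel:
    """Native energy evaluator for a monolayer configuration.

    Works on the flat bead-coordinate array of a
    :class:`~ligandshell.monolayer.MonolayerConfig`; supports full totals,
    single/two-ligand deltas and the per-bead incremental energies needed by
    configurational-bias regrowth.
    """

    def __init__(self, config):
        self.config = config
        self.params: ParameterSet = config.params
        self._tables: dict[str, _LigandTables] = {}
        for lt in {lig.ligand_type for lig in config.ligands}:
            self._tables[lt] = _tables_for(build_topology(lt), self.params)
        # flat per-bead property arrays
        self.eps = np.concatenate(
            [self._tables[l.ligand_type].eps for l in config.ligands])
        self.sigma = np.concatenate(
            [self._tables[l.ligand_type].sigma for l in config.ligands])
        self.charge = np.concatenate(
            [self._tables[l.ligand_type].charge for l in config.ligands])
        self.bead_lid = np.concatenate(
            [np.full(l.n_beads, i) for i, l in enumerate(config.ligands)])
        self._core_tree = cKDTree(config.core.atom_positions)
        self.overlap_flag = False

    # -- helpers -----------------------------------------------------------
    def _coords(self, lid: int, override) -> np.ndarray:
        if override is not None and lid in override:
            return override[lid]
        return self.config.ligand_coords(lid)

    def _anchor_atom(self, lid: int, site_override) -> np.ndarray:
        if site_override is not None and lid in site_override:
            sid = site_override[lid]
        else:
            sid = self.config.ligands[lid].anchor_site_id
        return self.config.core.anchor_sites[sid].position

    # -- bonded ------------------------------------------------------------
    def bonded_energy(self, lid: int, coords: np.ndarray | None = None) -> float:
        """Bond + angle + dihedral energy of one ligand."""
        lig = self.config.ligands[lid]
        t = self._tables[lig.ligand_type]
        x = coords if coords is not None else self.config.ligand_coords(lid)
        bonds = np.diff(x, axis=0)
        dr = np.linalg.norm(bonds, axis=1)
        e = float(np.sum(t.bond_k * (dr - t.bond_r0) ** 2))
        if len(x) >= 3:
            a = -bonds[:-1]
            b = bonds[1:]
            cosang = np.sum(a * b, axis=1) / (dr[:-1] * dr[1:])
            th = np.arccos(np.clip(cosang, -1.0, 1.0))
            e += float(np.sum(t.angle_k * (th - t.angle_t0) ** 2))
        if len(x) >= 4:
            b1, b2, b3 = bonds[:-2], bonds[1:-1], bonds[2:]
            n1 = _cross(b1, b2)
            n2 = _cross(b2, b3)
            m1 = _cross(n1, b2 / dr[1:-1, None])
            phi = np.abs(np.arctan2(np.sum(m1 * n2, axis=1),
                                    np.sum(n1 * n2, axis=1)))
            v = t.dihedral_v
            e += float(np.sum(
                0.5 * (v[:, 0] * (1.0 + np.cos(phi))
                       + v[:, 1] * (1.0 - np.cos(2.0 * phi))
                       + v[:, 2] * (1.0 + np.cos(3.0 * phi))
                       + v[:, 3] * (1.0 - np.cos(4.0 * phi)))))
        return e

    # -- single-ligand non-pair terms ---------------------------------------
    def morse_energy(self, lid: int, coords=None, site_override=None) -> float:
        x = coords if coords is not None else self.config.ligand_coords(lid)
        r = float(np.linalg.norm(x[0] - self._anchor_atom(lid, site_override)))
        p = self.params
        return float(morse_pair(r, p.morse_d_e, p.morse_alpha, p.morse_r_e))

    def guard_energy(self, coords: np.ndarray) -> float:
        """Repulsive wall: quadratic penalty for beads closer than r_guard
        to any core atom."""
        p = self.params
        if not p.guard_enabled:
            return 0.0
        d, _ = self._core_tree.query(coords, k=1)
        pen = np.clip(p.r_guard - d, 0.0, None)
        return float(p.k_guard * np.sum(pen * pen))

    def intra_nonbonded(self, lid: int, coords=None) -> float:
        """Intra-ligand LJ + screened Coulomb beyond 1-3 (1-4 scaled)."""
        lig = self.config.ligands[lid]
        t = self._tables[lig.ligand_type]
        if len(t.nb_pairs) == 0:
            return 0.0
        x = coords if coords is not None else self.config.ligand_coords(lid)
        i, j = t.nb_pairs[:, 0], t.nb_pairs[:, 1]
        r = np.linalg.norm(x[i] - x[j], axis=1)
        if np.any(r < OVERLAP_R):
            self.overlap_flag = True
            r = np.clip(r, OVERLAP_R, None)
        p = self.params
        eps = np.sqrt(t.eps[i] * t.eps[j])
        sig = np.sqrt(t.sigma[i] * t.sigma[j])
        e = np.sum(t.nb_scale * lj_pair(r, eps, sig, p.lj_cutoff))
        qq = t.charge[i] * t.charge[j]
        if np.any(qq != 0.0):
            e += np.sum(t.nb_scale * np.where(
                r <= p.coul_cutoff,
                COULOMB_KCAL * qq * np.exp(-p.kappa * r) / (p.dielectric * r),
                0.0))
        return float(e)

    # -- interligand --------------------------------------------------------
    def _pair_block(self, xa, ea, sa, qa, xb, eb, sb, qb) -> float:
        """LJ + screened Coulomb between two bead blocks (no exclusions)."""
        p = self.params
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
        if np.any(d < OVERLAP_R):
            self.overlap_flag = True
            d = np.clip(d, OVERLAP_R, None)
        eps = np.sqrt(ea[:, None] * eb[None, :])
        sig = np.sqrt(sa[:, None] * sb[None, :])
        sr6 = (sig / d) ** 6
        e = np.sum(np.where(d <= p.lj_cutoff, 4.0 * eps * (sr6 * sr6 - sr6), 0.0))
        qq = qa[:, None] * qb[None, :]
        if np.any(qq != 0.0):
            e += np.sum(np.where(
                d <= p.coul_cutoff,
                COULOMB_KCAL * qq * np.exp(-p.kappa * d) / (p.dielectric * d),
                0.0))
        return float(e)

    def _ligand_block(self, lid, override):
        x = self._coords(lid, override)
        sl = self.config.ligand_slice(lid)
        return x, self.eps[sl], self.sigma[sl], self.charge[sl]

    def env_block(self, exclude_lids, override=None):
        """Flat (coords, eps, sigma, charge) arrays over every bead whose
        ligand is not excluded, with coordinate overrides applied."""
        excl = set(exclude_lids)
        if override:
            x = self.config.coords.copy()
            for j, c in override.items():
                if j not in excl:
                    x[self.config.ligand_slice(j)] = c
        else:
            x = self.config.coords
        if excl:
            keep = ~np.isin(self.bead_lid, list(excl))
            return x[keep], self.eps[keep], self.sigma[keep], self.charge[keep]
        return x, self.eps, self.sigma, self.charge

    def inter_energy(self, lid: int, coords=None, exclude=frozenset(),
                     override=None) -> float:
        """Nonbonded energy of ligand ``lid`` against all other ligands."""
        ov = dict(override or {})
        if coords is not None:
            ov[lid] = coords
        xa, ea, sa, qa = self._ligand_block(lid, ov)
        env = self.env_block(set(exclude) | {lid}, ov)
        if len(env[0]) == 0:
            return 0.0
        return self._pair_block(xa, ea, sa, qa, *env)

    def pair_inter_energy(self, lid_a: int, lid_b: int, override=None) -> float:
        xa, ea, sa, qa = self._ligand_block(lid_a, override)
        xb, eb, sb, qb = self._ligand_block(lid_b, override)
        return self._pair_block(xa, ea, sa, qa, xb, eb, sb, qb)

    # -- aggregates ---------------------------------------------------------
    def ligand_env_energy(self, lid: int, coords=None, exclude=frozenset(),
                          override=None, site_override=None) -> float:
        """Everything that touches one ligand: bonded, Morse, guard,
        intra-nonbonded, plus its interactions with all non-excluded
        ligands."""
        x = coords if coords is not None else self._coords(lid, override)
        return (self.bonded_energy(lid, x)
                + self.morse_energy(lid, x, site_override)
                + self.guard_energy(x)
                + self.intra_nonbonded(lid, x)
                + self.inter_energy(lid, x, exclude=exclude, override=override))

    def total_energy(self) -> float:
        """Full system energy; deterministic for fixed input."""
        self.overlap_flag = False
        e = 0.0
        n = len(self.config.ligands)
        for lid in range(n):
            x = self.config.ligand_coords(lid)
            e += (self.bonded_energy(lid, x) + self.morse_energy(lid, x)
                  + self.guard_energy(x) + self.intra_nonbonded(lid, x))
        # interligand pairs, each counted once: ligand a vs all beads of
        # ligands with a larger id
        for a in range(n - 1):
            xa, ea, sa, qa = self._ligand_block(a, None)
            keep = self.bead_lid > a
            e += self._pair_block(xa, ea, sa, qa, self.config.coords[keep],
                                  self.eps[keep], self.sigma[keep],
                                  self.charge[keep])
        return e

    def delta_energy(self, moves: dict[int, np.ndarray],
                     site_moves: dict[int, int] | None = None) -> float:
        """Energy change for a proposal replacing the coordinates (and
        optionally anchor sites) of one or two ligands.

        Equals ``total_energy(after) - total_energy(before)`` exactly: only
        terms touching the moved ligands are recomputed.
        """
        if not 1 <= len(moves) <= 2:
            raise ValueError("proposals touch one or two ligands only")
        lids = sorted(moves)
        before = after = 0.0
        for lid in lids:
            others = frozenset(l for l in lids if l != lid)
            before += self.ligand_env_energy(lid, exclude=others)
            after += self.ligand_env_energy(
                lid, coords=moves[lid], exclude=others,
                override=moves, site_override=site_moves)
        if len(lids) == 2:
            a, b = lids
            before += self.pair_inter_energy(a, b)
            after += self.pair_inter_energy(a, b, override=moves)
        return after - before

    def rigid_delta(self, lid: int, new_coords: np.ndarray,
                    new_sid: int | None = None) -> float:
        """Fast delta for a rigid whole-ligand displacement: bonded and
        intra-ligand terms are isometry-invariant, so only Morse, guard and
        interligand energies change."""
        site_ov = {lid: new_sid} if new_sid is not None else None
        before = (self.morse_energy(lid)
                  + self.guard_energy(self.config.ligand_coords(lid))
                  + self.inter_energy(lid))
        after = (self.morse_energy(lid, new_coords, site_ov)
                 + self.guard_energy(new_coords)
                 + self.inter_energy(lid, new_coords))
        return after - before

    # -- CBMC incremental bead energies --------------------------------------
    def incremental_candidates_energy(self, lid: int, bead_i: int,
                                      cands: np.ndarray, placed: np.ndarray,
                                      exclude=frozenset(), override=None,
                                      env=None) -> np.ndarray:
        """Energies that candidate positions for bead ``bead_i`` would add,
        given beads ``0..bead_i-1`` already placed.

        Each candidate's energy includes the bond term to the previous bead,
        the angle and dihedral terms it completes, intra-ligand nonbonded
        pairs against already-placed beads, the core guard, and interactions
        with all non-excluded ligands.  Summed over a regrown chain these
        reproduce the tail's full touching energy.  ``env`` may carry a
        precomputed :meth:`env_block` for the constant environment of one
        regrowth.
        """
        lig = self.config.ligands[lid]
        t = self._tables[lig.ligand_type]
        p = self.params
        cands = np.atleast_2d(cands)
        e = np.zeros(len(cands))
        # bond (i-1, i)
        r = np.linalg.norm(cands - placed[bead_i - 1], axis=1)
        e += t.bond_k[bead_i - 1] * (r - t.bond_r0[bead_i - 1]) ** 2
        if bead_i >= 2:
            a = placed[bead_i - 2] - placed[bead_i - 1]
            b = cands - placed[bead_i - 1]
            cosang = (b @ a) / (np.linalg.norm(a) * np.linalg.norm(b, axis=1))
            th = np.arccos(np.clip(cosang, -1.0, 1.0))
            e += t.angle_k[bead_i - 2] * (th - t.angle_t0[bead_i - 2]) ** 2
        if bead_i >= 3:
            b1 = placed[bead_i - 2] - placed[bead_i - 3]
            b2 = placed[bead_i - 1] - placed[bead_i - 2]
            b3 = cands - placed[bead_i - 1]
            n1 = _cross(b1, b2)[0]
            n2 = _cross(b2, b3)
            m1 = _cross(n1, b2 / np.linalg.norm(b2))[0]
            phi = np.abs(np.arctan2(n2 @ m1, n2 @ n1))
            e += opls_dihedral(phi, *t.dihedral_v[bead_i - 3])
        # intra nonbonded vs placed beads (separation >= 3)
        if bead_i >= 3:
            j = np.arange(0, bead_i - 2)
            d = np.linalg.norm(placed[j][None, :, :] - cands[:, None, :], axis=2)
            d = np.clip(d, OVERLAP_R, None)
            eps = np.sqrt(t.eps[j] * t.eps[bead_i])
            sig = np.sqrt(t.sigma[j] * t.sigma[bead_i])
            scale = np.where(bead_i - j == 3, p.one_four_scale, 1.0)
            sr6 = (sig[None, :] / d) ** 6
            e += np.sum(np.where(d <= p.lj_cutoff,
                                 scale * 4.0 * eps * (sr6 * sr6 - sr6), 0.0),
                        axis=1)
            qq = t.charge[j] * t.charge[bead_i]
            if np.any(qq != 0.0):
                e += np.sum(np.where(
                    d <= p.coul_cutoff,
                    scale * COULOMB_KCAL * qq * np.exp(-p.kappa * d)
                    / (p.dielectric * d), 0.0), axis=1)
        # core guard
        if p.guard_enabled:
            dcore, _ = self._core_tree.query(cands, k=1)
            pen = np.clip(p.r_guard - dcore, 0.0, None)
            e += p.k_guard * pen * pen
        # interligand
        if env is None:
            env = self.env_block(set(exclude) | {lid}, override)
        xe, ee, se, qe = env
        if len(xe):
            d = np.linalg.norm(cands[:, None, :] - xe[None, :, :], axis=2)
            d = np.clip(d, OVERLAP_R, None)
            eps = np.sqrt(ee * t.eps[bead_i])
            sig = np.sqrt(se * t.sigma[bead_i])
            sr6 = (sig[None, :] / d) ** 6
            e += np.sum(np.where(d <= p.lj_cutoff,
                                 4.0 * eps * (sr6 * sr6 - sr6), 0.0), axis=1)
            qq = qe * t.charge[bead_i]
            if np.any(qq != 0.0):
                e += np.sum(np.where(
                    d <= p.coul_cutoff,
                    COULOMB_KCAL * qq * np.exp(-p.kappa * d) / (p.dielectric * d),
                    0.0), axis=1)
        return e

    def incremental_bead_energy(self, lid: int, bead_i: int, pos: np.ndarray,
                                placed: np.ndarray, exclude=frozenset(),
                                override=None, env=None) -> float:
        """Scalar convenience wrapper around
        :meth:`incremental_candidates_energy` for a single position."""
        return float(self.incremental_candidates_energy(
            lid, bead_i, pos[None, :], placed, exclude, override, env)[0])

    def stub_energy(self, lid: int, stub: np.ndarray, exclude=frozenset(),
                    override=None, site_override=None) -> float:
        """Energy of the retained stub (beads 0..len(stub)-1): all bonded
        terms internal to the stub, Morse, guard, and stub-environment
        nonbonded interactions.  Complements the incremental bead energies
        of the regrown tail."""
        lig = self.config.ligands[lid]
        t = self._tables[lig.ligand_type]
        p = self.params
        ns = len(stub)
        e = self.morse_energy(lid, stub, site_override) + self.guard_energy(stub)
        dr = np.linalg.norm(np.diff(stub, axis=0), axis=1)
        e += float(np.sum(t.bond_k[:ns - 1] * (dr - t.bond_r0[:ns - 1]) ** 2))
        for a in range(ns - 2):
            th = _angle(stub[a], stub[a + 1], stub[a + 2])
            e += t.angle_k[a] * (th - t.angle_t0[a]) ** 2
        for a in range(ns - 3):
            phi = _dihedral_angle(stub[a], stub[a + 1], stub[a + 2], stub[a + 3])
            e += float(opls_dihedral(phi, *t.dihedral_v[a]))
        # intra-nb pairs fully inside the stub
        for i in range(ns):
            for j in range(i + 3, ns):
                d = max(float(np.linalg.norm(stub[i] - stub[j])), OVERLAP_R)
                eps, sig = p.mix(t.eps[i], t.sigma[i], t.eps[j], t.sigma[j])
                scale = p.one_four_scale if j - i == 3 else 1.0
                e += scale * float(lj_pair(d, eps, sig, p.lj_cutoff))
                qq = t.charge[i] * t.charge[j]
                if qq != 0.0 and d <= p.coul_cutoff:
                    e += scale * COULOMB_KCAL * qq * math.exp(-p.kappa * d) / (
                        p.dielectric * d)
        # stub vs environment
        env = self.env_block(set(exclude) | {lid}, override)
        if len(env[0]):
            e += self._pair_block(stub, t.eps[:ns], t.sigma[:ns],
                                  t.charge[:ns], *env)
        return float(e)


# ---------------------------------------------------------------------------
# Module-level conveniences matching the operation surface
# ---------------------------------------------------------------------------

def bonded_energy(config, ligand_id: int) -> float:
    """Bond + angle + dihedral energy of one ligand of a configuration."""
    if not 0 <= ligand_id < len(config.ligands):
        raise KeyError(f"unknown ligand {ligand_id}")
    return EnergyModel(config).bonded_energy(ligand_id)


def total_energy(config) -> float:
    """Total system energy (bonded + Morse + guard + nonbonded)."""
    return config.energy_model().total_energy()


def delta_energy(config, ligand_id: int, proposed_coordinates: np.ndarray) -> float:
    """Energy change if one ligand's beads move to the proposed coordinates."""
    return config.energy_model().delta_energy({ligand_id: np.asarray(proposed_coordinates)})
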