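"""Configurational-bias Monte Carlo equilibration of ligand monolayers.

Move set (default proposal weights 10:10:1:1:1):

* **Translation** — rigid tangential displacement of a ligand of up to 4 A,
  with the sulfur re-projected onto the anchor-site surface; Metropolis.
* **Rotation** — rotation of the beads distal to a randomly chosen pivot
  bead about a random axis, up to 0.1745 rad; Metropolis.
* **Regrowth** — the ligand is cut back to the sulfur plus three beads
  (preserving the first dihedral) and regrown bead by bead; each bead
  samples five trial orientations and is chosen with probability
  proportional to its Boltzmann factor.  Accepted on the Rosenbluth ratio
  W_trial / W_initial, where the old chain is retraced with four fresh
  candidates plus its existing position.
* **Swap** — one PEG and one DDT exchange anchor sites and both are rebuilt
  at their new sites (deterministic stub + CBMC regrowth); accepted on the
  product of Rosenbluth ratios times the Metropolis factor of the
  deterministic stub energy change.
* **Jump** — a ligand relocates to a vacant facet anchor site 10-20 A away
  (up to 20 candidate gap sites sampled) and is regrown there; CBMC-accepted
  with the forward/reverse candidate-count correction.

Randomness comes from a single seed expanded into independent sub-streams
(move selection plus one per move type), so runs are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import KB_KCAL, EnergyModel, build_topology
from .monolayer import MonolayerConfig, place_chain

__all__ = [
    "MoveSet",
    "RosenbluthResult",
    "RunRecord",
    "CBMCEngine",
    "metropolis_accept",
    "run",
    "detect_equilibration",
    "MOVE_NAMES",
]

MOVE_NAMES = ("translation", "rotation", "regrowth", "swap", "jump")

#: Number of beads retained during regrowth: the sulfur plus three monomers,
#: which preserves the chain's first dihedral angle.
N_RETAIN = 4


@dataclass(frozen=True)
class MoveSet:
    """Proposal weights and move-specific limits."""

    weights: tuple[float, float, float, float, float] = (10.0, 10.0, 1.0, 1.0, 1.0)
    max_translation: float = 4.0  # A
    max_rotation: float = 0.1745  # rad
    n_trial_orientations: int = 5
    n_jump_candidates: int = 20
    jump_shell: tuple[float, float] = (10.0, 20.0)  # A
    jump_facets_only: bool = True

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(w) != 5 or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("need 5 non-negative weights, at least one positive")
        if (self.max_translation <= 0 or self.max_rotation <= 0
                or self.n_trial_orientations < 1 or self.n_jump_candidates < 1):
            raise ValueError("move limits must be positive")

    @property
    def probabilities(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()


@dataclass
class RosenbluthResult:
    """Log Rosenbluth weights of a regrowth (trial and retraced old chain)."""

    log_w_trial: float
    log_w_initial: float

    @property
    def ratio(self) -> float:
        return math.exp(min(self.log_w_trial - self.log_w_initial, 700.0))


@dataclass
class RunRecord:
    """Bookkeeping of one MC run."""

    seed: int
    n_proposals: int = 0
    proposal_counts: dict = field(default_factory=lambda: {m: 0 for m in MOVE_NAMES})
    accept_counts: dict = field(default_factory=lambda: {m: 0 for m in MOVE_NAMES})
    unavailable_counts: dict = field(default_factory=lambda: {m: 0 for m in MOVE_NAMES})
    energy_series: list = field(default_factory=list)  # (proposal index, kcal/mol)
    snapshot_indices: list = field(default_factory=list)
    snapshot_interval: int = 10_000
    energy_check_max_abs: float = 0.0  # worst |running - recomputed| at snapshots

    def acceptance_rate(self, move: str) -> float:
        n = self.proposal_counts[move]
        return self.accept_counts[move] / n if n else float("nan")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def metropolis_accept(delta_e: float, temperature: float, rng) -> bool:
    """Standard Metropolis criterion: accept with min(1, exp(-dE/kT))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-delta_e / (KB_KCAL * temperature))


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    kx, ky, kz = axis
    k = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


class CBMCEngine:
    """Drives configurational-bias Monte Carlo on one monolayer.

    The running total energy is updated incrementally from accepted
    proposals and cross-checked against a full recomputation at every
    snapshot.
    """

    def __init__(self, config: MonolayerConfig, moveset: MoveSet | None = None,
                 seed: int = 0):
        self.config = config
        self.moveset = moveset or MoveSet()
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(len(MOVE_NAMES) + 1)
        self._rng_select = np.random.default_rng(kids[0])
        self._rng = {m: np.random.default_rng(k)
                     for m, k in zip(MOVE_NAMES, kids[1:])}
        self.model = config.energy_model()
        self.energy = self.model.total_energy()
        self._site_tree = cKDTree(config.core.anchor_positions)
        self._occupied = dict(config.occupied_sites)
        self.beta = config.params.beta

    # ------------------------------------------------------------------
    # Elementary proposals.  Each returns True if accepted and applies the
    # move (coordinates, occupancy, running energy) itself.
    # ------------------------------------------------------------------

    def propose_translation(self, rng=None) -> bool:
        """Rigid surface translation of a random ligand, <= 4 A."""
        rng = rng or self._rng["translation"]
        cfg = self.config
        lid = int(rng.integers(cfg.n_ligands))
        coords = cfg.ligand_coords(lid)
        s_old = coords[0]
        radial = s_old / np.linalg.norm(s_old)
        t = rng.normal(size=3)
        t -= radial * (t @ radial)
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            return False
        t /= norm
        mag = rng.uniform(0.0, self.moveset.max_translation)
        target = s_old + mag * t
        # re-project onto the anchor-site surface: keep the tangential offset
        # but adopt the radius of the nearest site's sulfur shell
        _, sid = self._site_tree.query(target)
        sid = int(sid)
        site = cfg.core.anchor_sites[sid]
        owner = self._occupied.get(sid)
        if owner is not None and owner != lid:
            return False  # site already hosts another ligand
        r_shell = np.linalg.norm(site.position) + cfg.params.morse_r_e
        s_new = target / np.linalg.norm(target) * r_shell
        if np.linalg.norm(s_new - site.position) > cfg.params.morse_r_e + 1.5:
            return False  # sulfur would detach from the binding surface
        new_coords = coords + (s_new - s_old)
        de = self.model.rigid_delta(lid, new_coords, sid)
        if not metropolis_accept(de, cfg.params.temperature, rng):
            return False
        self._apply(lid, new_coords, sid, de)
        return True

    def propose_rotation(self, rng=None) -> bool:
        """Rotate the beads distal to a random pivot bead, <= 0.1745 rad."""
        rng = rng or self._rng["rotation"]
        cfg = self.config
        lid = int(rng.integers(cfg.n_ligands))
        coords = cfg.ligand_coords(lid)
        pivot = int(rng.integers(len(coords)))
        axis = _random_unit(rng)
        angle = rng.uniform(-self.moveset.max_rotation, self.moveset.max_rotation)
        if pivot == len(coords) - 1:
            # no distal beads: identity proposal, dE = 0, always accepted
            return True
        rot = _rotation_matrix(axis, angle)
        new_coords = coords.copy()
        new_coords[pivot + 1:] = (coords[pivot + 1:] - coords[pivot]) @ rot.T + coords[pivot]
        de = self.model.delta_energy({lid: new_coords})
        if not metropolis_accept(de, cfg.params.temperature, rng):
            return False
        self._apply(lid, new_coords, None, de)
        return True

    # -- regrowth machinery ---------------------------------------------

    def _bead_tables(self, lid: int, bead: int):
        """(r0, theta0, k_angle) for the bond and angle completed by a bead."""
        lig = self.config.ligands[lid]
        t = self.model._tables[lig.ligand_type]
        return t.bond_r0[bead - 1], t.angle_t0[bead - 2], t.angle_k[bead - 2]

    def _bonded_directions(self, rng, k: int, d_prev: np.ndarray,
                           theta0: float, k_angle: float):
        """k unit directions drawn from the bond-angle Boltzmann density
        p(theta) ~ sin(theta) exp(-beta k (theta - theta0)^2), torsion
        uniform.  Returns (directions (k,3), thetas (k,))."""
        sigma = 1.0 / math.sqrt(2.0 * self.beta * k_angle)
        thetas = np.empty(k)
        for i in range(k):
            while True:
                th = rng.normal(theta0, sigma)
                if 0.0 < th < math.pi and rng.random() < math.sin(th):
                    thetas[i] = th
                    break
        phis = rng.uniform(0.0, 2.0 * math.pi, size=k)
        e1 = np.zeros(3)
        e1[int(np.argmin(np.abs(d_prev)))] = 1.0
        e1 = np.cross(d_prev, e1)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d_prev, e1)
        dirs = (-np.cos(thetas)[:, None] * d_prev
                + np.sin(thetas)[:, None] * (np.cos(phis)[:, None] * e1
                                             + np.sin(phis)[:, None] * e2))
        return dirs, thetas

    def _grow_chain(self, lid: int, stub: np.ndarray, rng, exclude, override,
                    site_override, trace=None):
        """CBMC growth of beads N_RETAIN.. given a placed stub.

        Trial positions sit at the equilibrium bond length with bond angles
        drawn from their Boltzmann density; the Rosenbluth weight carries
        the external energy only (dihedral + nonbonded + guard), the
        standard split for stiff bonded terms.  Returns (coords, log_W,
        full incremental energy of the grown beads) or None if every
        candidate of some bead is effectively infinite.
        """
        cfg = self.config
        lig = cfg.ligands[lid]
        k_trials = self.moveset.n_trial_orientations
        placed = np.array(stub, dtype=float, copy=True)
        env = self.model.env_block({lid} | set(exclude), override)
        log_w = 0.0
        e_grown = 0.0
        for bead in range(len(stub), lig.n_beads):
            r0, theta0, k_angle = self._bead_tables(lid, bead)
            d_prev = placed[bead - 1] - placed[bead - 2]
            d_prev /= np.linalg.norm(d_prev)
            dirs, thetas = self._bonded_directions(rng, k_trials, d_prev,
                                                   theta0, k_angle)
            cand = placed[bead - 1] + r0 * dirs
            u_full = self.model.incremental_candidates_energy(
                lid, bead, cand, placed, env=env)
            u_ext = u_full - k_angle * (thetas - theta0) ** 2  # bond term is 0
            u_min = u_ext.min()
            if not np.isfinite(u_min) or u_min > 600.0 / self.beta:
                return None  # all candidates overlapping / essentially infinite
            w = np.exp(-self.beta * (u_ext - u_min))
            wsum = w.sum()
            pick = int(rng.choice(k_trials, p=w / wsum))
            log_w += math.log(wsum) - self.beta * u_min
            if trace is not None:
                trace.append({"bead": bead, "candidates": cand.copy(),
                              "energies_ext": u_ext.copy(),
                              "energies_full": u_full.copy(), "picked": pick})
            placed = np.vstack([placed, cand[pick]])
            e_grown += float(u_full[pick])
        return placed, log_w, e_grown

    def _retrace_chain(self, lid: int, old_coords: np.ndarray, n_stub: int,
                       rng, exclude, override, site_override=None):
        """Rosenbluth weight of the existing chain: at each bead, the old
        position plus k-1 fresh Boltzmann-angle candidates."""
        cfg = self.config
        lig = cfg.ligands[lid]
        k_trials = self.moveset.n_trial_orientations
        placed = np.array(old_coords[:n_stub], dtype=float, copy=True)
        env = self.model.env_block({lid} | set(exclude), override)
        log_w = 0.0
        e_old = 0.0
        for bead in range(n_stub, lig.n_beads):
            r0, theta0, k_angle = self._bead_tables(lid, bead)
            d_prev = placed[bead - 1] - placed[bead - 2]
            d_prev /= np.linalg.norm(d_prev)
            old_pos = old_coords[bead]
            b = old_pos - placed[bead - 1]
            cos_old = -(b @ d_prev) / np.linalg.norm(b)
            theta_old = math.acos(min(1.0, max(-1.0, cos_old)))
            if k_trials > 1:
                dirs, thetas = self._bonded_directions(
                    rng, k_trials - 1, d_prev, theta0, k_angle)
                cand = np.vstack([old_pos[None, :], placed[bead - 1] + r0 * dirs])
                thetas = np.concatenate([[theta_old], thetas])
            else:
                cand = old_pos[None, :]
                thetas = np.array([theta_old])
            u_full = self.model.incremental_candidates_energy(
                lid, bead, cand, placed, env=env)
            bond_r = np.linalg.norm(cand - placed[bead - 1], axis=1)
            t = self.model._tables[lig.ligand_type]
            bond_e = t.bond_k[bead - 1] * (bond_r - r0) ** 2
            u_ext = u_full - k_angle * (thetas - theta0) ** 2 - bond_e
            u_min = u_ext.min()
            w = np.exp(-self.beta * (u_ext - u_min))
            log_w += math.log(w.sum()) - self.beta * u_min
            placed = np.vstack([placed, old_pos])
            e_old += float(u_full[0])
        return log_w, e_old

    def propose_regrowth(self, rng=None, trace=None) -> bool:
        """In-place CBMC regrowth of a random ligand beyond its S+3 stub."""
        rng = rng or self._rng["regrowth"]
        cfg = self.config
        lid = int(rng.integers(cfg.n_ligands))
        old = cfg.ligand_coords(lid).copy()
        n_stub = min(N_RETAIN, len(old))
        if n_stub == len(old):
            return True  # nothing to regrow: identity proposal
        grown = self._grow_chain(lid, old[:n_stub], rng, frozenset(), None,
                                 None, trace)
        if grown is None:
            return False
        new_coords, log_w_trial, e_new = grown
        log_w_init, e_old = self._retrace_chain(
            lid, old, n_stub, rng, frozenset(), None, None)
        rb = RosenbluthResult(log_w_trial, log_w_init)
        if rng.random() >= min(1.0, rb.ratio):
            return False
        self._apply(lid, new_coords, None, e_new - e_old)
        return True

    def propose_swap(self, rng=None) -> bool:
        """Exchange the anchor sites of a random PEG/DDT pair; both chains
        are rebuilt at their new sites and CBMC-regrown."""
        rng = rng or self._rng["swap"]
        cfg = self.config
        pegs = [i for i, l in enumerate(cfg.ligands) if l.ligand_type == "PEG"]
        ddts = [i for i, l in enumerate(cfg.ligands) if l.ligand_type == "DDT"]
        if not pegs or not ddts:
            return False  # move unavailable on a homoligand monolayer
        la = pegs[int(rng.integers(len(pegs)))]
        lb = ddts[int(rng.integers(len(ddts)))]
        sa, sb = cfg.ligands[la].anchor_site_id, cfg.ligands[lb].anchor_site_id
        site_moves = {la: sb, lb: sa}
        old_a, old_b = cfg.ligand_coords(la).copy(), cfg.ligand_coords(lb).copy()

        # deterministic all-trans stubs at the new sites
        stub_a = self._fresh_stub(la, sb)
        stub_b = self._fresh_stub(lb, sa)
        exclude_ab = frozenset({la, lb})
        # grow A without B, then B seeing the new A (sequential CBMC);
        # the retrace mirrors that ordering on the old chains.
        grown_a = self._grow_chain(la, stub_a, rng, exclude=frozenset({lb}),
                                   override=None, site_override=site_moves)
        if grown_a is None:
            return False
        new_a, log_wt_a, e_new_a = grown_a
        grown_b = self._grow_chain(lb, stub_b, rng, exclude=frozenset(),
                                   override={la: new_a}, site_override=site_moves)
        if grown_b is None:
            return False
        new_b, log_wt_b, e_new_b = grown_b
        n_stub_a, n_stub_b = len(stub_a), len(stub_b)
        log_wi_a, e_old_a = self._retrace_chain(
            la, old_a, n_stub_a, rng, exclude=frozenset({lb}), override=None,
            site_override=None)
        log_wi_b, e_old_b = self._retrace_chain(
            lb, old_b, n_stub_b, rng, exclude=frozenset(),
            override={la: old_a}, site_override=None)
        # deterministic stub energy change (Metropolis factor)
        e_stub_new = (self.model.stub_energy(la, stub_a, exclude=frozenset({lb}),
                                             site_override=site_moves)
                      + self.model.stub_energy(lb, stub_b, exclude=frozenset(),
                                               override={la: new_a},
                                               site_override=site_moves))
        e_stub_old = (self.model.stub_energy(la, old_a[:n_stub_a],
                                             exclude=frozenset({lb}))
                      + self.model.stub_energy(lb, old_b[:n_stub_b],
                                               override={la: old_a}))
        d_stub = e_stub_new - e_stub_old
        log_acc = (log_wt_a + log_wt_b - log_wi_a - log_wi_b
                   - self.beta * d_stub)
        if math.log(max(rng.random(), 1e-300)) >= min(0.0, log_acc):
            return False
        de = (e_new_a + e_new_b + e_stub_new) - (e_old_a + e_old_b + e_stub_old)
        self._apply_two(la, new_a, sb, lb, new_b, sa, de)
        return True

    def propose_jump(self, rng=None) -> bool:
        """Relocate a random ligand to a vacant facet site 10-20 A away."""
        rng = rng or self._rng["jump"]
        cfg = self.config
        ms = self.moveset
        lid = int(rng.integers(cfg.n_ligands))
        old_sid = cfg.ligands[lid].anchor_site_id
        vac_fwd = self._vacant_in_shell(old_sid, extra_vacant=None)
        if len(vac_fwd) == 0:
            return False
        pool = vac_fwd
        if len(pool) > ms.n_jump_candidates:
            pool = rng.choice(pool, size=ms.n_jump_candidates, replace=False)
        new_sid = int(pool[int(rng.integers(len(pool)))])
        old = cfg.ligand_coords(lid).copy()
        stub = self._fresh_stub(lid, new_sid)
        n_stub = len(stub)
        grown = self._grow_chain(lid, stub, rng, frozenset(), None,
                                 {lid: new_sid})
        if grown is None:
            return False
        new_coords, log_wt, e_new = grown
        log_wi, e_old = self._retrace_chain(lid, old, n_stub, rng,
                                            frozenset(), None, None)
        e_stub_new = self.model.stub_energy(lid, stub,
                                            site_override={lid: new_sid})
        e_stub_old = self.model.stub_energy(lid, old[:n_stub])
        # Forward/reverse candidate-count correction for detailed balance.
        # Sampling <=20 gap sites then choosing uniformly is marginally
        # uniform over all vacancies, so the proposal density is 1/n_vacant.
        n_fwd = len(vac_fwd)
        vac_rev = self._vacant_in_shell(new_sid, extra_vacant=old_sid,
                                        now_occupied=new_sid)
        n_rev = len(vac_rev)
        if n_rev == 0:
            return False
        log_acc = (log_wt - log_wi - self.beta * (e_stub_new - e_stub_old)
                   + math.log(n_fwd) - math.log(n_rev))
        if math.log(max(rng.random(), 1e-300)) >= min(0.0, log_acc):
            return False
        de = (e_new + e_stub_new) - (e_old + e_stub_old)
        self._apply(lid, new_coords, new_sid, de)
        return True

    # -- helpers ----------------------------------------------------------

    def _fresh_stub(self, lid: int, site_id: int) -> np.ndarray:
        topo = build_topology(self.config.ligands[lid].ligand_type)
        chain = place_chain(topo, self.config.core.anchor_sites[site_id],
                            self.config.params)
        return chain[:min(N_RETAIN, len(chain))]

    def _vacant_in_shell(self, around_sid: int, extra_vacant: int | None,
                         now_occupied: int | None = None) -> np.ndarray:
        """Vacant anchor sites whose distance from the reference site lies in
        the jump shell; optionally treating one site as vacant/occupied (for
        the reverse-move count)."""
        cfg = self.config
        ms = self.moveset
        p0 = cfg.core.anchor_sites[around_sid].position
        lo, hi = ms.jump_shell
        idx = self._site_tree.query_ball_point(p0, hi)
        occupied = self._occupied
        out = []
        for sid in idx:
            if sid == now_occupied:
                continue
            if sid in occupied and sid != extra_vacant:
                continue
            if ms.jump_facets_only and cfg.core.anchor_sites[sid].is_vertex:
                continue
            d = np.linalg.norm(cfg.core.anchor_sites[sid].position - p0)
            if lo <= d <= hi:
                out.append(sid)
        return np.array(sorted(out), dtype=int)

    def _apply(self, lid: int, new_coords: np.ndarray, new_sid: int | None,
               de: float) -> None:
        cfg = self.config
        cfg.set_ligand_coords(lid, new_coords)
        if new_sid is not None:
            old_sid = cfg.ligands[lid].anchor_site_id
            if old_sid in self._occupied and self._occupied[old_sid] == lid:
                del self._occupied[old_sid]
            cfg.ligands[lid].anchor_site_id = int(new_sid)
            self._occupied[int(new_sid)] = lid
        self.energy += de

    def _apply_two(self, la, coords_a, sid_a, lb, coords_b, sid_b, de) -> None:
        cfg = self.config
        for sid in (cfg.ligands[la].anchor_site_id, cfg.ligands[lb].anchor_site_id):
            self._occupied.pop(sid, None)
        cfg.set_ligand_coords(la, coords_a)
        cfg.set_ligand_coords(lb, coords_b)
        cfg.ligands[la].anchor_site_id = int(sid_a)
        cfg.ligands[lb].anchor_site_id = int(sid_b)
        self._occupied[int(sid_a)] = la
        self._occupied[int(sid_b)] = lb
        self.energy += de

    # ------------------------------------------------------------------

    def run(self, n_proposals: int, snapshot_interval: int = 10_000,
            energy_log_interval: int = 100,
            collect_snapshots: bool = True):
        """Run the chain; returns ``(RunRecord, trajectory)`` where the
        trajectory is a list of configuration snapshots taken every
        ``snapshot_interval`` proposals."""
        record = RunRecord(seed=self.seed, snapshot_interval=snapshot_interval)
        trajectory: list[MonolayerConfig] = []
        probs = self.moveset.probabilities
        proposers = {
            "translation": self.propose_translation,
            "rotation": self.propose_rotation,
            "regrowth": self.propose_regrowth,
            "swap": self.propose_swap,
            "jump": self.propose_jump,
        }
        pegs = any(l.ligand_type == "PEG" for l in self.config.ligands)
        ddts = any(l.ligand_type == "DDT" for l in self.config.ligands)
        for step in range(1, n_proposals + 1):
            move = MOVE_NAMES[int(self._rng_select.choice(5, p=probs))]
            record.proposal_counts[move] += 1
            if move == "swap" and not (pegs and ddts):
                record.unavailable_counts[move] += 1
            else:
                if proposers[move]():
                    record.accept_counts[move] += 1
            if step % energy_log_interval == 0 or step == n_proposals:
                record.energy_series.append((step, float(self.energy)))
            if step % snapshot_interval == 0:
                full = self.model.total_energy()
                record.energy_check_max_abs = max(
                    record.energy_check_max_abs, abs(full - self.energy))
                self.energy = full  # re-anchor against drift
                record.snapshot_indices.append(step)
                if collect_snapshots:
                    snap = self.config.copy()
                    snap.provenance["proposal_index"] = step
                    trajectory.append(snap)
        record.n_proposals = n_proposals
        return record, trajectory


def _sphere_points(rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]


def run(config: MonolayerConfig, moveset: MoveSet | None, n_proposals: int,
        seed: int, **kwargs):
    """Convenience wrapper: build an engine and run it."""
    engine = CBMCEngine(config, moveset, seed)
    return engine.run(n_proposals, **kwargs)


def detect_equilibration(energy_series, window: int = 50_000,
                         n_consecutive: int = 1) -> int | None:
    """Plateau detection on an energy series.

    The series (energies, or (index, energy) pairs) is split into
    non-overlapping windows; a plateau is declared at the start of the first
    window whose mean differs from the previous window's mean by less than
    one pooled standard error.  Returns the series index where the plateau
    begins, or ``None`` if no plateau (or fewer than two windows) exists.
    Larger windows make the test more conservative.
    """
    e = np.asarray(energy_series, dtype=float)
    if e.ndim == 2:
        e = e[:, 1]
    n_win = len(e) // window
    if n_win < 2:
        return None
    hits = 0
    for w in range(1, n_win):
        a = e[(w - 1) * window: w * window]
        b = e[w * window: (w + 1) * window]
        se = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / window)
        if abs(b.mean() - a.mean()) <= se + 1e-12:
            hits += 1
            if hits >= n_consecutive:
                return (w - hits + 1) * window
        else:
            hits = 0
    return None
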