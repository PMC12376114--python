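"""Monolayer composition plans and initial configurations.

Composition
-----------
The ligand surface density is the composition-weighted average of the alkyl
packing density on gold (4.70 ligands/nm^2) and the interpolated PEG surface
density (6.29 ligands/nm^2):

    sigma(x_PEG) = x_PEG * 6.29 + (1 - x_PEG) * 4.70

Ligand counts follow half-up rounding of ``x_PEG * L_total``.  For the nine
published study compositions the exact (sigma, L_PEG, L_DDT, L_total) rows
are also available verbatim (``TABLE1`` / ``plan_from_table``), because the
printed sigma values at x_PEG >= 0.7 deviate slightly from the linear
weighting and two L_PEG entries differ by one from half-up rounding.

Initial morphologies
--------------------
``init_random``, ``init_striped`` (5 A bands along a random axis) and
``init_janus`` (single boundary plane perpendicular to a random pole) place
all-trans chains along the anchor-site normals.  All initializers are
deterministic under a fixed seed and realize the planned type counts
exactly.  ``make_perfect_janus_ensemble`` builds the unrelaxed perfect-Janus
reference ensemble used to normalize SSR into a Janus character.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import AuCore, build_mackay_core, default_shell_count
from .forcefield import EnergyModel, ParameterSet, build_topology

__all__ = [
    "CompositionPlan",
    "Ligand",
    "MonolayerConfig",
    "PEG_DENSITY",
    "DDT_DENSITY",
    "TABLE1",
    "sigma_of_x",
    "ligand_counts",
    "total_from_area",
    "plan_from_table",
    "make_plan",
    "place_chain",
    "init_random",
    "init_striped",
    "init_janus",
    "make_perfect_janus_ensemble",
    "default_core",
]

#: Interpolated PEG-thiol surface density on gold (ligands/nm^2).
PEG_DENSITY = 6.29
#: Alkanethiol packing density on gold (ligands/nm^2).
DDT_DENSITY = 4.70

#: Published study compositions: x_PEG -> (sigma, L_PEG, L_DDT, L_total).
TABLE1 = {
    0.1: (4.86, 12, 111, 123),
    0.2: (5.02, 25, 102, 127),
    0.3: (5.18, 39, 92, 131),
    0.4: (5.34, 54, 82, 136),
    0.5: (5.50, 70, 70, 140),
    0.6: (5.66, 87, 58, 145),
    0.7: (5.73, 105, 45, 150),
    0.8: (5.84, 123, 30, 153),
    0.9: (6.04, 143, 15, 158),
}


@dataclass(frozen=True)
class CompositionPlan:
    x_peg: float
    sigma: float  # ligands / nm^2
    l_peg: int
    l_ddt: int

    def __post_init__(self):
        if not 0.0 <= self.x_peg <= 1.0:
            raise ValueError("x_peg must lie in [0, 1]")
        if self.l_peg < 0 or self.l_ddt < 0:
            raise ValueError("ligand counts must be non-negative")

    @property
    def l_total(self) -> int:
        return self.l_peg + self.l_ddt


def sigma_of_x(x_peg: float) -> float:
    """Weighted-average ligand surface density (ligands/nm^2)."""
    if not 0.0 <= x_peg <= 1.0:
        raise ValueError(f"x_peg must lie in [0, 1], got {x_peg}")
    return x_peg * PEG_DENSITY + (1.0 - x_peg) * DDT_DENSITY


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ligand_counts(x_peg: float, l_total: int) -> tuple[int, int]:
    """Split a total ligand count into (L_PEG, L_DDT), half-up rounding."""
    if l_total < 1:
        raise ValueError("l_total must be >= 1")
    l_peg = _round_half_up(x_peg * l_total)
    return l_peg, l_total - l_peg


def total_from_area(core: AuCore, sigma: float) -> int:
    """Total ligand count from the core surface area at density sigma.

    Area convention: the sphere of the core's mid-diameter,
    ``A = pi * mid_diameter^2`` (nm^2).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    area = math.pi * core.mid_diameter**2
    return _round_half_up(sigma * area)


def plan_from_table(x_peg: float) -> CompositionPlan:
    """Composition plan pinned verbatim to the published study table."""
    key = round(x_peg, 2)
    if key not in TABLE1:
        raise KeyError(f"x_peg={x_peg} is not a published study composition")
    sigma, l_peg, l_ddt, l_total = TABLE1[key]
    assert l_peg + l_ddt == l_total
    return CompositionPlan(key, sigma, l_peg, l_ddt)


def make_plan(x_peg: float, core: AuCore | None = None,
              l_total: int | None = None, paper_mode: bool = True) -> CompositionPlan:
    """Composition plan for any x_PEG.

    With ``paper_mode`` (default) the nine published compositions are taken
    verbatim from the study table; otherwise (or for other x values) counts
    are recomputed from sigma and the core area (or an explicit ``l_total``).
    """
    if paper_mode and round(x_peg, 2) in TABLE1 and l_total is None:
        return plan_from_table(x_peg)
    sigma = sigma_of_x(x_peg)
    if l_total is None:
        if core is None:
            raise ValueError("need a core or an explicit l_total")
        l_total = total_from_area(core, sigma)
    l_peg, l_ddt = ligand_counts(x_peg, l_total)
    return CompositionPlan(x_peg, sigma, l_peg, l_ddt)


# ---------------------------------------------------------------------------
# Configuration container
# ---------------------------------------------------------------------------

@dataclass
class Ligand:
    ligand_type: str  # "PEG" | "DDT"
    anchor_site_id: int
    n_beads: int


@dataclass
class MonolayerConfig:
    """Core + typed ligand instances with bead coordinates: the simulator's
    state.  Bead coordinates live in one flat ``(B, 3)`` array; per-ligand
    views are exposed through ``ligand_coords`` / ``ligand_slice``."""

    core: AuCore
    params: ParameterSet
    ligands: list[Ligand]
    coords: np.ndarray  # (total beads, 3), A
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self._offsets = np.zeros(len(self.ligands) + 1, dtype=int)
        np.cumsum([l.n_beads for l in self.ligands], out=self._offsets[1:])
        if len(self.coords) != self._offsets[-1]:
            raise ValueError("coordinate array does not match bead counts")
        self._model: EnergyModel | None = None
        self.validate()

    # -- structure ----------------------------------------------------------
    def ligand_slice(self, lid: int) -> slice:
        return slice(self._offsets[lid], self._offsets[lid + 1])

    def ligand_coords(self, lid: int) -> np.ndarray:
        return self.coords[self.ligand_slice(lid)]

    def set_ligand_coords(self, lid: int, new: np.ndarray) -> None:
        self.coords[self.ligand_slice(lid)] = new

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def occupied_sites(self) -> dict[int, int]:
        """anchor site id -> ligand id"""
        return {l.anchor_site_id: i for i, l in enumerate(self.ligands)}

    def sulfur_positions(self) -> np.ndarray:
        return self.coords[self._offsets[:-1]]

    def types_array(self) -> np.ndarray:
        """1 for PEG, 0 for DDT, per ligand."""
        return np.array([1 if l.ligand_type == "PEG" else 0 for l in self.ligands])

    @property
    def x_peg_realized(self) -> float:
        t = self.types_array()
        return float(t.mean()) if len(t) else 0.0

    def energy_model(self) -> EnergyModel:
        if self._model is None:
            self._model = EnergyModel(self)
        return self._model

    def copy(self) -> "MonolayerConfig":
        return MonolayerConfig(
            core=self.core,
            params=self.params,
            ligands=[Ligand(l.ligand_type, l.anchor_site_id, l.n_beads)
                     for l in self.ligands],
            coords=self.coords.copy(),
            provenance=dict(self.provenance),
        )

    # -- invariants ---------------------------------------------------------
    def validate(self, s_bound_extra: float = 1.5) -> None:
        sites = [l.anchor_site_id for l in self.ligands]
        if len(set(sites)) != len(sites):
            raise ValueError("two ligands share an anchor site")
        for l in self.ligands:
            expected = 13 if l.ligand_type == "DDT" else 6 if l.ligand_type == "PEG" else None
            if expected is not None and l.n_beads != expected:
                raise ValueError(
                    f"{l.ligand_type} ligand must have {expected} beads")
        r_e = self.params.morse_r_e
        for i, l in enumerate(self.ligands):
            s = self.ligand_coords(i)[0]
            atom = self.core.anchor_sites[l.anchor_site_id].position
            if np.linalg.norm(s - atom) > r_e + s_bound_extra:
                raise ValueError(
                    f"ligand {i}: sulfur detached from anchor site "
                    f"{l.anchor_site_id}")


# ---------------------------------------------------------------------------
# Chain placement
# ---------------------------------------------------------------------------

def _tangent(normal: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to a normal."""
    a = np.zeros(3)
    a[int(np.argmin(np.abs(normal)))] = 1.0
    t = np.cross(normal, a)
    return t / np.linalg.norm(t)


def place_chain(topology, site, params: ParameterSet) -> np.ndarray:
    """All-trans chain along the site normal.

    The sulfur sits at the Morse equilibrium distance above the anchor gold
    atom; subsequent beads zig-zag in the plane spanned by the normal and a
    deterministic tangent, with equilibrium bond lengths and angles, so all
    backbone dihedrals are trans.
    """
    names = topology.bead_names
    n = topology.n_beads
    normal = site.normal
    t1 = _tangent(normal)
    coords = np.empty((n, 3))
    coords[0] = site.position + params.morse_r_e * normal
    for i in range(1, n):
        _, r0 = params.bond_params(names[i - 1], names[i])
        if i == 1:
            theta0 = params.angle_params(names[0], names[1], names[2])[1] \
                if n >= 3 else math.pi
        else:
            theta0 = params.angle_params(names[i - 2], names[i - 1], names[i])[1]
        delta = 0.5 * (math.pi - theta0)
        sign = 1.0 if i % 2 == 1 else -1.0
        direction = math.cos(delta) * normal + sign * math.sin(delta) * t1
        coords[i] = coords[i - 1] + r0 * direction
    return coords


def _build_config(core, params, chosen_sites, types, provenance) -> MonolayerConfig:
    ligands = []
    blocks = []
    for sid, lt in zip(chosen_sites, types):
        topo = build_topology(lt)
        ligands.append(Ligand(lt, int(sid), topo.n_beads))
        blocks.append(place_chain(topo, core.anchor_sites[sid], params))
    coords = np.vstack(blocks) if blocks else np.zeros((0, 3))
    return MonolayerConfig(core, params, ligands, coords, provenance)


def _choose_sites(plan, core, rng) -> np.ndarray:
    n_sites = len(core.anchor_sites)
    if plan.l_total > n_sites:
        raise ValueError(
            f"plan needs {plan.l_total} sites but the core has {n_sites}")
    return rng.choice(n_sites, size=plan.l_total, replace=False)


def init_random(plan: CompositionPlan, core: AuCore, params: ParameterSet,
                seed: int) -> MonolayerConfig:
    """Uniformly random site choice and type assignment."""
    rng = np.random.default_rng(seed)
    sites = _choose_sites(plan, core, rng)
    types = np.array(["PEG"] * plan.l_peg + ["DDT"] * plan.l_ddt)
    rng.shuffle(types)
    prov = {"init": "random", "seed": int(seed), "x_peg": plan.x_peg,
            "l_peg": plan.l_peg, "l_ddt": plan.l_ddt}
    return _build_config(core, params, sites, types, prov)


def stripe_bands(z: np.ndarray, stripe_width: float) -> np.ndarray:
    """Band parity: True where floor(z / width) is even (PEG band)."""
    return np.floor(z / stripe_width).astype(int) % 2 == 0


def init_striped(plan: CompositionPlan, core: AuCore, params: ParameterSet,
                 seed: int, stripe_width: float = 5.0) -> MonolayerConfig:
    """Alternating 5 A bands of PEG and DDT along a random axis.

    Band assignment generally misses the planned counts; the correction
    reassigns the sites closest to a band boundary until counts match.
    """
    rng = np.random.default_rng(seed)
    sites = _choose_sites(plan, core, rng)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    pos = np.array([core.anchor_sites[s].position for s in sites])
    z = pos @ axis
    is_peg = stripe_bands(z, stripe_width)
    # distance to the nearest band boundary: flip cheapest-to-flip sites
    frac = np.mod(z, stripe_width)
    boundary_dist = np.minimum(frac, stripe_width - frac)
    order = np.argsort(boundary_dist, kind="stable")
    excess = int(is_peg.sum()) - plan.l_peg
    for idx in order:
        if excess == 0:
            break
        if excess > 0 and is_peg[idx]:
            is_peg[idx] = False
            excess -= 1
        elif excess < 0 and not is_peg[idx]:
            is_peg[idx] = True
            excess += 1
    types = np.where(is_peg, "PEG", "DDT")
    prov = {"init": "striped", "seed": int(seed), "x_peg": plan.x_peg,
            "stripe_width": stripe_width, "axis": axis.tolist()}
    return _build_config(core, params, sites, types, prov)


def _janus_types(sites, core, plan, axis) -> np.ndarray:
    pos = np.array([core.anchor_sites[s].position for s in sites])
    proj = pos @ axis
    order = np.argsort(-proj, kind="stable")  # descending polar projection
    types = np.empty(len(sites), dtype=object)
    types[order[:plan.l_peg]] = "PEG"
    types[order[plan.l_peg:]] = "DDT"
    return types


def init_janus(plan: CompositionPlan, core: AuCore, params: ParameterSet,
               seed: int) -> MonolayerConfig:
    """Perfect two-faced split: PEG occupies the cap around a random pole."""
    rng = np.random.default_rng(seed)
    sites = _choose_sites(plan, core, rng)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    types = _janus_types(sites, core, plan, axis)
    prov = {"init": "janus", "seed": int(seed), "x_peg": plan.x_peg,
            "axis": axis.tolist()}
    return _build_config(core, params, sites, types, prov)


def make_perfect_janus_ensemble(x_peg: float, core: AuCore,
                                params: ParameterSet | None = None,
                                n_configs: int = 50, seed: int = 0,
                                l_total: int | None = None,
                                paper_mode: bool = True) -> list[MonolayerConfig]:
    """Unrelaxed, perfectly Janus reference configurations.

    Each draws its own pole axis and site subset from an independent
    sub-seed; used as the upper-bound SSR reference at each composition.
    """
    params = params or ParameterSet.default()
    plan = make_plan(x_peg, core=core, l_total=l_total, paper_mode=paper_mode)
    children = np.random.SeedSequence(seed).spawn(n_configs)
    return [init_janus(plan, core, params,
                       int(child.generate_state(1)[0] % 2**31))
            for child in children]


def random_null_fragment_distribution(plan: CompositionPlan, core: AuCore,
                                      params: ParameterSet | None = None,
                                      n_samples: int = 50_000,
                                      n_configs: int = 50,
                                      cutoff: float = 6.0,
                                      seed: int = 0):
    """Fragment distribution of the randomly mixed null ensemble.

    A single finite shell retains composition structure from its one random
    assignment, so the draws are pooled over ``n_configs`` independent
    random monolayers (the analogue of a mass spectrum, which integrates
    over an enormous particle ensemble).  Total draws = ``n_samples``.
    """
    from .fragments import FRAGMENT_SIZE, sample_fragment_distribution

    params = params or ParameterSet.default()
    ss = np.random.SeedSequence(seed).spawn(n_configs)
    per = [n_samples // n_configs] * n_configs
    for i in range(n_samples - sum(per)):
        per[i] += 1
    counts = np.zeros(FRAGMENT_SIZE + 1)
    for child, n_draw in zip(ss, per):
        s1, s2 = (int(x % 2**31) for x in child.generate_state(2))
        cfg = init_random(plan, core, params, seed=s1)
        dist = sample_fragment_distribution(cfg, n_draw, cutoff, seed=s2)
        counts += dist.theta * n_draw
    from .fragments import FragmentDistribution

    return FragmentDistribution(counts / counts.sum(), n_samples=n_samples,
                                provenance={"source": "random_null",
                                            "n_configs": n_configs,
                                            "seed": seed})


def default_core(lattice_constant: float = 4.08, trim: int | None = 3) -> AuCore:
    """The study core: the Mackay shell count whose mid-diameter best
    matches 2.8 nm (k=5 at a=4.08 A), outer three layers retained."""
    from .core import trim_outer_layers
    k = default_shell_count(lattice_constant)
    core = build_mackay_core(k, lattice_constant)
    if trim is not None and trim < k:
        core = trim_outer_layers(core, trim)
    return core
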