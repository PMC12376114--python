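"""Au4L4 fragment statistics, SSR scores, Janus character and patch sizes.

Laser ablation of a binary thiolate monolayer yields Au4L4 fragments whose
five compositions (i = number of PEG ligands, 0..4) report on local ligand
arrangement.  This module converts monolayer configurations into the
normalized five-bin fragment distribution theta, compares it to the binomial
reference expected for random mixing via the sum-of-squares residual (SSR),
normalizes ensemble SSRs into a Janus character, and measures same-type
ligand patches as connected components of the 6 A sulfur-sulfur graph.

Sampling follows the simulation protocol: a uniformly random ligand is drawn
and grouped with its three nearest neighbours within 6 A (sulfur-sulfur
distance); draws whose seed ligand has fewer than three in-cutoff neighbours
are discarded and redrawn.  Because a seed ligand's fragment is
deterministic, redrawing is equivalent to sampling uniformly over eligible
ligands, which is how it is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import comb

__all__ = [
    "FragmentDistribution",
    "SSRReport",
    "Patch",
    "PatchSet",
    "FRAGMENT_SIZE",
    "theta_from_areas",
    "surface_fraction",
    "binomial_reference",
    "ssr",
    "fragment_composition_per_ligand",
    "sample_fragment_distribution",
    "exhaustive_fragment_distribution",
    "janus_character",
    "find_patches",
    "number_weighted_patch_size",
]

#: Ligands per fragment (Au4L4 family).
FRAGMENT_SIZE = 4


@dataclass(frozen=True)
class FragmentDistribution:
    """Normalized five-bin Au4L4 composition histogram.

    ``theta[i]`` is the probability of a fragment carrying ``i`` PEG
    ligands (PEG is ligand A; the index convention of the composition axis
    x_PEG).
    """

    theta: np.ndarray
    n_samples: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (FRAGMENT_SIZE + 1,):
            raise ValueError("theta must have 5 bins")
        if np.any(th < 0):
            raise ValueError("theta must be non-negative")
        if abs(th.sum() - 1.0) > 1e-12:
            raise ValueError("theta must sum to 1")
        object.__setattr__(self, "theta", th)
        th.setflags(write=False)

    @property
    def x_peg(self) -> float:
        return surface_fraction(self)


@dataclass(frozen=True)
class SSRReport:
    ssr: float
    reference: str  # "binomial" | "distribution"
    x_reference: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.ssr <= 2.0:
            raise ValueError("SSR of two distributions lies in [0, 2]")


def theta_from_areas(areas) -> FragmentDistribution:
    """Normalize five fragment-peak areas C_i into theta_i = C_i / sum C."""
    c = np.asarray(areas, dtype=float)
    if c.shape != (FRAGMENT_SIZE + 1,):
        raise ValueError("need 5 peak areas")
    if np.any(c < 0):
        raise ValueError("areas must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot normalize all-zero areas")
    return FragmentDistribution(c / total, provenance={"source": "areas"})


def _theta_of(dist) -> np.ndarray:
    return dist.theta if isinstance(dist, FragmentDistribution) else np.asarray(dist, float)


def surface_fraction(dist) -> float:
    """Surface fraction of PEG from a fragment distribution:
    x = sum_i i * theta_i / 4.  The DDT fraction is 1 - x (mole balance)."""
    th = _theta_of(dist)
    return float(np.arange(FRAGMENT_SIZE + 1) @ th / FRAGMENT_SIZE)


def binomial_reference(x_peg: float, n: int = FRAGMENT_SIZE) -> FragmentDistribution:
    """Fragment distribution of a randomly mixed monolayer at fraction x:
    theta_i = C(4, i) x^i (1-x)^(4-i)."""
    if not 0.0 <= x_peg <= 1.0:
        raise ValueError("x_peg must lie in [0, 1]")
    i = np.arange(n + 1)
    th = comb(n, i) * x_peg**i * (1.0 - x_peg) ** (n - i)
    th = th / th.sum()  # guard rounding
    return FragmentDistribution(th, provenance={"source": "binomial", "x": x_peg})


def ssr(dist, reference) -> SSRReport:
    """Sum of squared residuals between two fragment distributions."""
    th = _theta_of(dist)
    ref = _theta_of(reference)
    value = float(np.sum((th - ref) ** 2))
    kind = "binomial"
    x_ref = None
    if isinstance(reference, FragmentDistribution):
        if reference.provenance.get("source") == "binomial":
            x_ref = reference.provenance.get("x")
        else:
            kind = "distribution"
    else:
        kind = "distribution"
    return SSRReport(value, kind, x_ref)


# ---------------------------------------------------------------------------
# Fragment sampling from configurations
# ---------------------------------------------------------------------------

def _positions_types(config_or_pair):
    if isinstance(config_or_pair, tuple):
        pos, types = config_or_pair
        return np.asarray(pos, float), np.asarray(types, int)
    cfg = config_or_pair
    return cfg.sulfur_positions(), cfg.types_array()


def fragment_composition_per_ligand(config_or_pair, cutoff: float = 6.0,
                                    neighbor_rule: str = "within_cutoff"):
    """Fragment PEG count for every possible seed ligand.

    For each ligand, its three nearest neighbours by sulfur-sulfur distance
    (ties broken by ligand id) form the 4-ligand fragment.  Under the
    default rule only neighbours within the cutoff qualify and seeds with
    fewer than three are ineligible; ``neighbor_rule="nearest"`` instead
    always takes the three nearest regardless of distance.

    Returns ``(comps, eligible)``: PEG counts (0..4) and eligibility mask.
    """
    pos, types = _positions_types(config_or_pair)
    n = len(pos)
    if n < FRAGMENT_SIZE:
        raise ValueError("need at least 4 ligands")
    tree = cKDTree(pos)
    comps = np.zeros(n, dtype=int)
    eligible = np.zeros(n, dtype=bool)
    k = min(n, FRAGMENT_SIZE + 2)  # a couple extra for tie handling
    dists, idx = tree.query(pos, k=k)
    for i in range(n):
        # exclude self, sort by (distance, id) for deterministic ties
        cand = [(dists[i, j], int(idx[i, j])) for j in range(k)
                if int(idx[i, j]) != i]
        # tree.query already sorts by distance; make ties id-stable
        cand.sort(key=lambda t: (round(t[0], 9), t[1]))
        if neighbor_rule == "nearest":
            chosen = [c[1] for c in cand[:3]]
        else:
            in_cut = [c[1] for c in cand if c[0] <= cutoff]
            if len(in_cut) < 3:
                # k-nearest may have missed in-cutoff neighbours; requery
                ball = sorted(
                    ((np.linalg.norm(pos[j] - pos[i]), j)
                     for j in tree.query_ball_point(pos[i], cutoff) if j != i),
                    key=lambda t: (round(t[0], 9), t[1]))
                in_cut = [j for _, j in ball]
            if len(in_cut) < 3:
                continue
            chosen = in_cut[:3]
        comps[i] = types[i] + int(types[chosen].sum())
        eligible[i] = True
    return comps, eligible


def sample_fragment_distribution(config_or_pair, n_samples: int = 50_000,
                                 cutoff: float = 6.0, seed: int | None = None,
                                 neighbor_rule: str = "within_cutoff",
                                 ) -> FragmentDistribution:
    """Monte Carlo fragment sampling (with replacement).

    Draws ``n_samples`` uniformly random seed ligands, discarding and
    redrawing neighbour-deficient seeds, and bins the 4-ligand fragment
    compositions by PEG count.
    """
    comps, eligible = fragment_composition_per_ligand(
        config_or_pair, cutoff, neighbor_rule)
    if not eligible.any():
        raise ValueError(
            "no ligand has 3 neighbours within the cutoff; sampling infeasible")
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(eligible)
    draws = rng.choice(pool, size=n_samples, replace=True)
    counts = np.bincount(comps[draws], minlength=FRAGMENT_SIZE + 1)
    return FragmentDistribution(
        counts / n_samples, n_samples=n_samples,
        provenance={"source": "sampled", "cutoff": cutoff, "seed": seed,
                    "eligible": int(eligible.sum())})


def exhaustive_fragment_distribution(config_or_pair, cutoff: float = 6.0,
                                     neighbor_rule: str = "within_cutoff",
                                     ) -> FragmentDistribution:
    """Exact expectation of the sampled distribution: the average over all
    eligible seed ligands (the oracle the sampler converges to)."""
    comps, eligible = fragment_composition_per_ligand(
        config_or_pair, cutoff, neighbor_rule)
    if not eligible.any():
        raise ValueError("no eligible seed ligand")
    counts = np.bincount(comps[eligible], minlength=FRAGMENT_SIZE + 1)
    return FragmentDistribution(
        counts / counts.sum(),
        provenance={"source": "exhaustive", "cutoff": cutoff})


def janus_character(ssr_sim_mean: float, ssr_janus_mean: float,
                    ssr_sim_sd: float = 0.0, ssr_janus_sd: float = 0.0,
                    ) -> tuple[float, float]:
    """Janus character: quotient of mean simulated SSR and mean perfect-Janus
    SSR at the same composition, with quotient-rule error propagation.

    Returns ``(ratio, sd)``.
    """
    if ssr_janus_mean <= 0:
        raise ZeroDivisionError("perfect-Janus reference SSR must be positive")
    ratio = ssr_sim_mean / ssr_janus_mean
    if ssr_sim_mean == 0:
        return 0.0, 0.0
    sd = abs(ratio) * np.hypot(ssr_sim_sd / ssr_sim_mean,
                               ssr_janus_sd / ssr_janus_mean)
    return float(ratio), float(sd)


# ---------------------------------------------------------------------------
# Patch analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    ligand_type: str
    members: tuple[int, ...]  # ligand ids

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PatchSet:
    patches: tuple[Patch, ...]
    cutoff: float

    def of_type(self, ligand_type: str) -> list[Patch]:
        return [p for p in self.patches if p.ligand_type == ligand_type]

    def sizes(self, ligand_type: str) -> np.ndarray:
        return np.array([p.size for p in self.of_type(ligand_type)], dtype=int)


def find_patches(config_or_triplet, cutoff: float = 6.0) -> PatchSet:
    """Same-type ligand patches: connected components of the graph linking
    ligands whose anchor sulfurs lie within the cutoff.

    Implemented as the published procedure: a k-d tree supplies in-cutoff
    neighbour pairs and an iterative depth-first search visits every ligand
    exactly once.  Accepts a configuration or a ``(positions, types)`` pair
    (types as strings or ints).
    """
    if isinstance(config_or_triplet, tuple):
        pos, types = config_or_triplet
        pos = np.asarray(pos, float)
        types = np.asarray(types)
    else:
        pos = config_or_triplet.sulfur_positions()
        types = np.array([l.ligand_type for l in config_or_triplet.ligands])
    n = len(pos)
    tree = cKDTree(pos)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in tree.query_pairs(cutoff):
        if types[i] == types[j]:
            adj[i].append(j)
            adj[j].append(i)
    visited = np.zeros(n, dtype=bool)
    patches = []
    for start in range(n):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        members = []
        while stack:
            u = stack.pop()
            members.append(u)
            for v in adj[u]:
                if not visited[v]:
                    visited[v] = True
                    stack.append(v)
        patches.append(Patch(str(types[start]), tuple(sorted(members))))
    return PatchSet(tuple(patches), cutoff)


def number_weighted_patch_size(patchset: PatchSet) -> dict[str, float]:
    """Number-weighted average patch size per ligand type:
    S = sum_i N_i * S_i / sum_i N_i with S_i = N_i, i.e. sum N^2 / sum N."""
    out: dict[str, float] = {}
    for lt in sorted({p.ligand_type for p in patchset.patches}):
        sizes = patchset.sizes(lt).astype(float)
        out[lt] = float(np.sum(sizes**2) / np.sum(sizes))
    return out
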