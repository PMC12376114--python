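"""Icosahedral gold nanoparticle cores.

Builds rigid Mackay-icosahedron gold clusters on an FCC lattice, identifies
the outermost (surface) shell, assigns surface atoms to the 20 triangular
facets, and enumerates thiolate anchor sites (one atop site per surface
atom).

Geometry convention
-------------------
The cluster is built from concentric icosahedral shells.  Shell ``m`` places
atoms on the 20 faces of an icosahedron whose 12 vertices sit at distance
``m * d`` from the origin, where ``d = a / sqrt(2)`` is the FCC
nearest-neighbour distance for lattice constant ``a``.  The radial spacing
``d`` is the minimum interatomic distance; tangential spacings are a factor
``1/sin(2*pi/5) ~ 1.0515`` larger, the usual slight distortion of the Mackay
packing relative to bulk FCC.

A closed ``k``-shell cluster contains ``N(k) = 10k^3/3 + 5k^2 + 11k/3 + 1``
atoms, ``10k^2 + 2`` of them on the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "AuCore",
    "AnchorSite",
    "build_mackay_core",
    "trim_outer_layers",
    "enumerate_anchor_sites",
    "mackay_total_atoms",
    "mackay_surface_atoms",
    "default_shell_count",
    "icosahedral_rotations",
    "write_xyz_core",
    "write_facet_csv",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

#: Norm of a face centroid of an icosahedron with unit circumradius
#: (inradius / circumradius).
_FACE_CENTER_NORM = _GOLDEN**2 / (np.sqrt(3.0) * np.sqrt(_GOLDEN**2 + 1.0))
# ~ 0.794654


def mackay_total_atoms(k: int) -> int:
    """Closed-form atom count of a k-shell Mackay icosahedron."""
    return (10 * k**3 + 15 * k**2 + 11 * k + 3) // 3


def mackay_surface_atoms(k: int) -> int:
    """Atoms on the outermost shell of a k-shell Mackay icosahedron."""
    return 10 * k**2 + 2


def _icosahedron_vertices() -> np.ndarray:
    """12 unit vertices of a regular icosahedron (circumradius 1)."""
    v = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            v.append([0.0, s1, s2 * _GOLDEN])
            v.append([s1, s2 * _GOLDEN, 0.0])
            v.append([s2 * _GOLDEN, 0.0, s1])
    verts = np.array(v)
    return verts / np.linalg.norm(verts[0])


def _icosahedron_faces(verts: np.ndarray) -> list[tuple[int, int, int]]:
    hull = ConvexHull(verts)
    faces = [tuple(sorted(simplex)) for simplex in hull.simplices]
    # Deterministic facet ordering: sort by outward normal, lexicographically.
    normals = [tuple(np.round(verts[list(f)].mean(axis=0), 9)) for f in faces]
    order = sorted(range(len(faces)), key=lambda i: normals[i])
    return [faces[i] for i in order]


@dataclass(frozen=True)
class AnchorSite:
    """One atop thiolate binding site on a surface gold atom."""

    site_id: int
    atom_id: int
    position: np.ndarray  # the surface Au atom position (A)
    normal: np.ndarray  # outward (radial) unit normal
    facet_id: int  # 1..20; ties resolved to the lowest id
    is_vertex: bool  # 5 surface neighbours (icosahedron vertex)


@dataclass(frozen=True)
class AuCore:
    """Rigid icosahedral FCC gold core, centred at the origin.

    Coordinates are read-only (arrays have ``writeable=False``); the core
    never changes after construction.  Atoms are ordered outermost shell
    first so that surface atom ids survive :func:`trim_outer_layers`.
    """

    atom_positions: np.ndarray  # (N, 3) A
    lattice_constant: float  # A
    shell_count: int
    shell_index: np.ndarray  # (N,) shell of each atom, 0 = centre
    surface_atom_ids: np.ndarray  # (n_surf,) row indices into atom_positions
    facet_map: np.ndarray  # (n_surf,) facet id per surface atom (1..20)
    anchor_sites: tuple[AnchorSite, ...] = field(repr=False, default=())

    @property
    def n_atoms(self) -> int:
        return len(self.atom_positions)

    @property
    def nn_distance(self) -> float:
        """FCC nearest-neighbour distance a/sqrt(2) (A)."""
        return self.lattice_constant / np.sqrt(2.0)

    @property
    def mid_diameter(self) -> float:
        """Mean of vertex-to-vertex and face-to-face outer diameters (nm).

        Measured across atom surfaces: one Au atom diameter (= the
        nearest-neighbour distance) is added to the centre-to-centre value,
        matching what electron-microscopy sizing reports.
        """
        d = self.nn_distance
        k = self.shell_count
        vertex = 2.0 * k * d
        face = 2.0 * k * d * _FACE_CENTER_NORM
        return (0.5 * (vertex + face) + d) / 10.0

    @property
    def anchor_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.anchor_sites])


def _build_shell(m: int, d: float, verts: np.ndarray,
                 faces: list[tuple[int, int, int]]) -> np.ndarray:
    """All atom positions on icosahedral shell m (deduplicated)."""
    if m == 0:
        return np.zeros((1, 3))
    pts = []
    for (i, j, k) in faces:
        vi, vj, vk = verts[i], verts[j], verts[k]
        for a in range(m + 1):
            for b in range(m + 1 - a):
                c = m - a - b
                pts.append(d * (c * vi + a * vj + b * vk))
    pts = np.asarray(pts)
    # Deduplicate shared edges/vertices.
    key = np.round(pts / (1e-6), 0).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    return pts[np.sort(idx)]


def build_mackay_core(shell_count: int, lattice_constant: float = 4.08) -> AuCore:
    """Build a closed-shell Mackay icosahedron gold core.

    Parameters
    ----------
    shell_count : int
        Number of closed shells ``k`` (>= 1).
    lattice_constant : float
        FCC lattice constant in Angstrom (default 4.08, bulk gold).
    """
    if shell_count < 1 or int(shell_count) != shell_count:
        raise ValueError(f"shell_count must be a positive integer, got {shell_count}")
    if lattice_constant <= 0:
        raise ValueError(f"lattice_constant must be positive, got {lattice_constant}")
    k = int(shell_count)
    d = lattice_constant / np.sqrt(2.0)
    verts = _icosahedron_vertices()
    faces = _icosahedron_faces(verts)

    positions = []
    shells = []
    for m in range(k, -1, -1):  # outermost shell first: stable surface ids
        shell_pts = _build_shell(m, d, verts, faces)
        # Deterministic in-shell order.
        order = np.lexsort((shell_pts[:, 2], shell_pts[:, 1], shell_pts[:, 0]))
        positions.append(shell_pts[order])
        shells.append(np.full(len(shell_pts), m))
    positions = np.vstack(positions)
    shells = np.concatenate(shells)

    n_surf = mackay_surface_atoms(k)
    surface_ids = np.arange(n_surf)

    facet_map = _assign_facets(positions[surface_ids], verts, faces)
    core = AuCore(
        atom_positions=positions,
        lattice_constant=float(lattice_constant),
        shell_count=k,
        shell_index=shells,
        surface_atom_ids=surface_ids,
        facet_map=facet_map,
    )
    sites = enumerate_anchor_sites(core)
    core = AuCore(
        atom_positions=positions,
        lattice_constant=float(lattice_constant),
        shell_count=k,
        shell_index=shells,
        surface_atom_ids=surface_ids,
        facet_map=facet_map,
        anchor_sites=sites,
    )
    for arr in (core.atom_positions, core.shell_index, core.surface_atom_ids,
                core.facet_map):
        arr.setflags(write=False)
    return core


def _assign_facets(surface_pos: np.ndarray, verts: np.ndarray,
                   faces: list[tuple[int, int, int]]) -> np.ndarray:
    """Facet id (1..20) per surface atom: largest projection onto the 20
    outward face normals; ties go to the lowest facet id."""
    normals = np.array([verts[list(f)].mean(axis=0) for f in faces])
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    proj = surface_pos @ normals.T  # (n_surf, 20)
    # argmax returns the first (lowest) index on exact ties; guard against
    # floating noise by rounding.
    return np.argmax(np.round(proj, 6), axis=1) + 1


def trim_outer_layers(core: AuCore, n_layers: int) -> AuCore:
    """Keep only the outer ``n_layers`` shells of the core.

    The innermost ``shell_count - n_layers`` closed shells (including the
    central atom) are removed; the surface shell and its atom ids are
    untouched because atoms are stored outermost-first.
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    n_layers = int(n_layers)
    if n_layers > core.shell_count:
        raise ValueError(
            f"n_layers ({n_layers}) exceeds shell_count ({core.shell_count})")
    if n_layers == core.shell_count:
        keep = np.ones(core.n_atoms, dtype=bool)  # identity: nothing removed
    else:
        keep = core.shell_index > core.shell_count - n_layers
    positions = core.atom_positions[keep]
    shells = core.shell_index[keep]
    trimmed = AuCore(
        atom_positions=positions,
        lattice_constant=core.lattice_constant,
        shell_count=core.shell_count,
        shell_index=shells,
        surface_atom_ids=core.surface_atom_ids.copy(),
        facet_map=core.facet_map.copy(),
        anchor_sites=core.anchor_sites,
    )
    for arr in (trimmed.atom_positions, trimmed.shell_index,
                trimmed.surface_atom_ids, trimmed.facet_map):
        arr.setflags(write=False)
    return trimmed


def enumerate_anchor_sites(core: AuCore) -> tuple[AnchorSite, ...]:
    """One atop site per surface gold atom.

    The outward normal is the radial unit vector at the atom; the sulfur of
    an adsorbed thiolate is later placed along it at the Morse equilibrium
    distance.  Vertex sites (5 surface neighbours) are flagged so Jump moves
    can restrict targets to facet sites.
    """
    surf = core.atom_positions[core.surface_atom_ids]
    normals = surf / np.linalg.norm(surf, axis=1)[:, None]
    # Surface-neighbour counts: tangential nn spacing is d / sin(2 pi / 5).
    tang = core.nn_distance / np.sin(2.0 * np.pi / 5.0)
    tree = cKDTree(surf)
    n_neigh = np.array([len(tree.query_ball_point(p, 1.2 * tang)) - 1 for p in surf])
    sites = []
    for sid, aid in enumerate(core.surface_atom_ids):
        sites.append(AnchorSite(
            site_id=sid,
            atom_id=int(aid),
            position=surf[sid].copy(),
            normal=normals[sid].copy(),
            facet_id=int(core.facet_map[sid]),
            is_vertex=bool(n_neigh[sid] == 5),
        ))
    for s in sites:
        s.position.setflags(write=False)
        s.normal.setflags(write=False)
    return tuple(sites)


def default_shell_count(lattice_constant: float = 4.08,
                        target_diameter_nm: float = 2.8,
                        k_max: int = 12) -> int:
    """Shell count whose mid-diameter is closest to the target (2.8 nm)."""
    best_k, best_err = 1, np.inf
    d = lattice_constant / np.sqrt(2.0)
    for k in range(1, k_max + 1):
        mid = (k * d * (1.0 + _FACE_CENTER_NORM) + d) / 10.0
        err = abs(mid - target_diameter_nm)
        if err < best_err:
            best_k, best_err = k, err
    return best_k


def icosahedral_rotations() -> np.ndarray:
    """The 60 proper rotations of the icosahedral group as 3x3 matrices.

    Generated by closure from a five-fold rotation about a vertex axis and a
    three-fold rotation about a face axis.
    """
    verts = _icosahedron_vertices()
    faces = _icosahedron_faces(verts)

    def rot(axis, angle):
        axis = axis / np.linalg.norm(axis)
        kx, ky, kz = axis
        kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        return np.eye(3) + np.sin(angle) * kmat + (1 - np.cos(angle)) * (kmat @ kmat)

    g1 = rot(verts[0], 2.0 * np.pi / 5.0)
    g2 = rot(verts[list(faces[0])].mean(axis=0), 2.0 * np.pi / 3.0)
    group = [np.eye(3)]

    def key(m):
        return tuple(np.round(m, 8).ravel())

    seen = {key(np.eye(3))}
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in (g1, g2):
                p = g @ m
                k = key(p)
                if k not in seen:
                    seen.add(k)
                    group.append(p)
                    nxt.append(p)
        frontier = nxt
    assert len(group) == 60, f"expected 60 rotations, got {len(group)}"
    return np.array(group)


def write_xyz_core(core: AuCore, path) -> None:
    """Export the core as an XYZ file (element Au, Angstrom)."""
    with open(path, "w") as fh:
        fh.write(f"{core.n_atoms}\n")
        fh.write(f"Mackay icosahedron k={core.shell_count} "
                 f"a={core.lattice_constant} A\n")
        for p in core.atom_positions:
            fh.write(f"Au {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def write_facet_csv(core: AuCore, path) -> None:
    """Export the surface facet map as CSV (atom_id, facet_id)."""
    with open(path, "w") as fh:
        fh.write("atom_id,facet_id\n")
        for aid, fid in zip(core.surface_atom_ids, core.facet_map):
            fh.write(f"{aid},{fid}\n")
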