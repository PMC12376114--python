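"""Snapshot serialization: XYZ and LAMMPS-data formats.

Both formats carry a JSON metadata record (core construction parameters,
ligand types and anchor sites) so that ``read_snapshot(write_snapshot(c))``
rebuilds a full configuration: coordinates round-trip to 1e-6 A and all
type/anchor metadata exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import build_mackay_core, trim_outer_layers
from .forcefield import ParameterSet, build_topology
from .monolayer import Ligand, MonolayerConfig

__all__ = ["write_snapshot", "read_snapshot", "write_xyz", "read_xyz",
           "write_lammps_data", "read_lammps_data"]

#: Bead name -> chemical element symbol (united atoms map to their heavy atom).
_ELEMENT = {"S": "S", "CH2": "C", "CH3": "C", "O_ether": "O"}

#: Fixed LAMMPS atom-type ids (atom-style full).
_LAMMPS_TYPES = {"Au": 1, "S": 2, "CH2": 3, "CH3": 4, "O_ether": 5}


class SnapshotParseError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


def _metadata(config: MonolayerConfig) -> dict:
    core = config.core
    trim = int(core.shell_count - core.shell_index.min() + 1)
    return {
        "shell_count": int(core.shell_count),
        "lattice_constant": float(core.lattice_constant),
        "trim": trim,
        "ligands": [[l.ligand_type, int(l.anchor_site_id)] for l in config.ligands],
        "provenance": config.provenance,
    }


def _rebuild(meta: dict, coords_beads: np.ndarray,
             params: ParameterSet | None) -> MonolayerConfig:
    core = build_mackay_core(meta["shell_count"], meta["lattice_constant"])
    if meta["trim"] < meta["shell_count"]:
        core = trim_outer_layers(core, meta["trim"])
    params = params or ParameterSet.default()
    ligands = [Ligand(lt, sid, build_topology(lt).n_beads)
               for lt, sid in meta["ligands"]]
    return MonolayerConfig(core, params, ligands, coords_beads,
                           provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(config: MonolayerConfig, path) -> None:
    """XYZ frame: core gold atoms followed by ligand beads; metadata as JSON
    in the comment line."""
    core = config.core
    n = core.n_atoms + len(config.coords)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        fh.write("ligandshell " + json.dumps(_metadata(config)) + "\n")
        # %.17g round-trips doubles exactly, so any analysis recomputed from
        # a stored frame is bit-identical to the in-memory one
        for p in core.atom_positions:
            fh.write(f"Au {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for lid, lig in enumerate(config.ligands):
            names = build_topology(lig.ligand_type).bead_names
            for name, p in zip(names, config.ligand_coords(lid)):
                fh.write(f"{_ELEMENT[name]} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def read_xyz(path, params: ParameterSet | None = None) -> MonolayerConfig:
    with open(path) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise SnapshotParseError(path, 1, "expected atom count") from None
    if not lines[1].startswith("ligandshell "):
        raise SnapshotParseError(path, 2, "missing ligandshell metadata")
    meta = json.loads(lines[1][len("ligandshell "):])
    rows = []
    for i, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) != 4:
            raise SnapshotParseError(path, i, f"malformed atom line: {line!r}")
        rows.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
    if len(rows) != n:
        raise SnapshotParseError(path, len(lines), f"expected {n} atom lines")
    n_core = sum(1 for r in rows if r[0] == "Au")
    coords = np.array([[r[1], r[2], r[3]] for r in rows[n_core:]])
    return _rebuild(meta, coords, params)


# ---------------------------------------------------------------------------
# LAMMPS data (atom_style full)
# ---------------------------------------------------------------------------

def write_lammps_data(config: MonolayerConfig, path) -> None:
    """LAMMPS data file, atom-style ``full`` (id mol type q x y z).

    Molecule id 0 is the rigid gold core; ligand beads carry their ligand id
    plus one.  Bead-type names are mapped in header comments, and the same
    JSON metadata as the XYZ writer rides in a ``#meta`` comment.
    """
    core = config.core
    n_atoms = core.n_atoms + len(config.coords)
    n_bonds = sum(l.n_beads - 1 for l in config.ligands)
    masses = {
        "Au": 196.96657,
        **{name: spec.mass for name, spec in config.params.beads.items()},
    }
    lo = float(np.floor(core.atom_positions.min() - 30.0))
    hi = float(np.ceil(core.atom_positions.max() + 30.0))
    with open(path, "w") as fh:
        fh.write("LAMMPS data file. ligandshell monolayer snapshot\n")
        fh.write("#meta " + json.dumps(_metadata(config)) + "\n")
        fh.write("# types: " + " ".join(
            f"{i}={n}" for n, i in sorted(_LAMMPS_TYPES.items(), key=lambda kv: kv[1]))
            + "\n\n")
        fh.write(f"{n_atoms} atoms\n{n_bonds} bonds\n\n")
        fh.write(f"{len(_LAMMPS_TYPES)} atom types\n1 bond types\n\n")
        for dim in "xyz":
            fh.write(f"{lo:.1f} {hi:.1f} {dim}lo {dim}hi\n")
        fh.write("\nMasses\n\n")
        for name, tid in sorted(_LAMMPS_TYPES.items(), key=lambda kv: kv[1]):
            fh.write(f"{tid} {masses[name]:.5f}\n")
        fh.write("\nAtoms # full\n\n")
        aid = 0
        for p in core.atom_positions:
            aid += 1
            fh.write(f"{aid} 0 {_LAMMPS_TYPES['Au']} 0.000000 "
                     f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        for lid, lig in enumerate(config.ligands):
            topo = build_topology(lig.ligand_type)
            for name, q, p in zip(topo.bead_names, topo.charges,
                                  config.ligand_coords(lid)):
                aid += 1
                fh.write(f"{aid} {lid + 1} {_LAMMPS_TYPES[name]} {q:.6f} "
                         f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write("\nBonds\n\n")
        bid = 0
        offset = core.n_atoms
        for lid, lig in enumerate(config.ligands):
            for b in range(lig.n_beads - 1):
                bid += 1
                fh.write(f"{bid} 1 {offset + b + 1} {offset + b + 2}\n")
            offset += lig.n_beads


def read_lammps_data(path, params: ParameterSet | None = None) -> MonolayerConfig:
    meta = None
    atoms = []
    in_atoms = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#meta "):
                meta = json.loads(line[len("#meta "):])
                continue
            if line.startswith("Atoms"):
                in_atoms = True
                continue
            if in_atoms:
                if not line:
                    if atoms:
                        break
                    continue
                if line[0].isalpha():
                    break
                parts = line.split()
                if len(parts) != 7:
                    raise SnapshotParseError(path, lineno,
                                             f"malformed Atoms line: {line!r}")
                atoms.append((int(parts[0]), int(parts[1]),
                              float(parts[4]), float(parts[5]), float(parts[6])))
    if meta is None:
        raise SnapshotParseError(path, 1, "missing #meta record")
    atoms.sort()
    coords = np.array([[x, y, z] for _, mol, x, y, z in atoms if mol > 0])
    return _rebuild(meta, coords, params)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def write_snapshot(config: MonolayerConfig, path, format: str | None = None) -> None:
    """Write a configuration snapshot (format from extension when omitted:
    ``.xyz`` or ``.data``/``.lmp`` for LAMMPS)."""
    fmt = format or _format_of(path)
    if fmt == "xyz":
        write_xyz(config, path)
    elif fmt == "lammps-data":
        write_lammps_data(config, path)
    else:
        raise ValueError(f"unknown snapshot format {fmt!r}")


def read_snapshot(path, params: ParameterSet | None = None,
                  format: str | None = None) -> MonolayerConfig:
    fmt = format or _format_of(path)
    if fmt == "xyz":
        return read_xyz(path, params)
    if fmt == "lammps-data":
        return read_lammps_data(path, params)
    raise ValueError(f"unknown snapshot format {fmt!r}")


def _format_of(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return "xyz"
    if suffix in (".data", ".lmp"):
        return "lammps-data"
    raise ValueError(f"cannot infer snapshot format from {path!r}")
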