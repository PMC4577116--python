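"""File formats: Abaqus-INP subset, VTK legacy grids, CSV/JSON results, HDF5
network libraries.

Only a deliberately small dialect of each mesh format is supported — enough
to exchange the package's own hexahedral meshes with external tools:

* INP subset: ``*NODE``, ``*ELEMENT, TYPE=C3D8``, ``*ELSET`` (region labels)
  and ``*NSET`` cards; 1-based ids are mapped to internal 0-based ids.
* VTK legacy ASCII unstructured grid: POINTS / CELLS / CELL_TYPES(12), with
  point vectors (displacement) and cell scalars (region, Von Mises stress).

All writers use fixed float formatting and sorted keys so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json

import numpy as np

from .mesh import HexMesh
from .network import FiberNetwork, RveLibrary

_FLOAT = "%.9g"


# ---------------------------------------------------------------------------
# Abaqus INP subset
# ---------------------------------------------------------------------------

def write_inp(mesh: HexMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("*HEADING\npcmech hexahedral mesh\n*NODE\n")
        for i, p in enumerate(mesh.node_coords, start=1):
            fh.write(f"{i}, {_FLOAT % p[0]}, {_FLOAT % p[1]}, {_FLOAT % p[2]}\n")
        fh.write("*ELEMENT, TYPE=C3D8\n")
        for e, conn in enumerate(mesh.elements, start=1):
            fh.write(str(e) + ", " + ", ".join(str(c + 1) for c in conn) + "\n")
        for rid in sorted(set(int(r) for r in mesh.region_ids)):
            name = mesh.region_map[rid]
            ids = np.flatnonzero(mesh.region_ids == rid) + 1
            fh.write(f"*ELSET, ELSET={name}\n")
            _write_id_lines(fh, ids)
        for name in sorted(mesh.node_sets):
            fh.write(f"*NSET, NSET={name}\n")
            _write_id_lines(fh, np.asarray(mesh.node_sets[name]) + 1)


def _write_id_lines(fh, ids, per_line=10):
    ids = list(int(i) for i in ids)
    for k in range(0, len(ids), per_line):
        fh.write(", ".join(str(i) for i in ids[k:k + per_line]) + "\n")


class InpFormatError(ValueError):
    pass


def read_inp(mesh_path) -> HexMesh:
    """Read the INP subset back into a validated HexMesh.

    Unsupported element types are rejected naming the card; malformed lines
    raise with their line number. Node-set order within a set follows the
    file. The 1-based→0-based id mapping is stored in
    ``mesh.geometry_params['inp_node_id_map']``.
    """
    nodes = {}
    elems = []
    elsets: dict[str, list] = {}
    nsets: dict[str, list] = {}
    section = None
    setname = None
    with open(mesh_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                u = line.upper()
                if u.startswith("*HEADING"):
                    section = "heading"
                elif u.startswith("*NODE"):
                    section = "node"
                elif u.startswith("*ELEMENT"):
                    t = _card_param(line, "TYPE")
                    if (t or "").upper() != "C3D8":
                        raise InpFormatError(
                            f"line {ln}: unsupported element card {line!r} "
                            "(only TYPE=C3D8)")
                    section = "element"
                elif u.startswith("*ELSET"):
                    section = "elset"
                    setname = _card_param(line, "ELSET")
                    elsets[setname] = []
                elif u.startswith("*NSET"):
                    section = "nset"
                    setname = _card_param(line, "NSET")
                    nsets[setname] = []
                else:
                    raise InpFormatError(f"line {ln}: unsupported card {line!r}")
                continue
            try:
                parts = [p for p in line.replace(",", " ").split() if p]
                if section == "node":
                    nodes[int(parts[0])] = [float(v) for v in parts[1:4]]
                elif section == "element":
                    conn = [int(v) for v in parts[1:9]]
                    if len(conn) != 8:
                        raise ValueError("need 8 nodes")
                    elems.append(conn)
                elif section == "elset":
                    elsets[setname] += [int(v) for v in parts]
                elif section == "nset":
                    nsets[setname] += [int(v) for v in parts]
                elif section == "heading":
                    pass
                else:
                    raise ValueError("data outside any known card")
            except InpFormatError:
                raise
            except Exception as exc:
                raise InpFormatError(f"line {ln}: {exc}") from exc
    ids = sorted(nodes)
    id_map = {i: k for k, i in enumerate(ids)}
    coords = np.array([nodes[i] for i in ids], dtype=float)
    conn0 = np.array([[id_map[i] for i in c] for c in elems], dtype=np.int64)
    region_ids = np.zeros(len(conn0), dtype=np.int64)
    region_map = {}
    for rid, (name, eids) in enumerate(sorted(elsets.items())):
        region_map[rid] = name
        region_ids[np.asarray(eids, dtype=int) - 1] = rid
    if not region_map:
        region_map = {0: "corpuscle"}
    mesh = HexMesh(
        node_coords=coords,
        elements=conn0,
        region_ids=region_ids,
        region_map=region_map,
        node_sets={k: np.array([id_map[i] for i in v], dtype=np.int64)
                   for k, v in nsets.items()},
        geometry_params={"inp_node_id_map": id_map},
    )
    mesh.validate()
    return mesh


def _card_param(line: str, key: str):
    for part in line.split(",")[1:]:
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip().upper() == key.upper():
                return v.strip()
    return None


# ---------------------------------------------------------------------------
# VTK legacy unstructured grid
# ---------------------------------------------------------------------------

def write_vtk(mesh: HexMesh, path, point_vectors: dict | None = None,
              cell_scalars: dict | None = None) -> None:
    """ASCII VTK legacy file with hexahedron cells (type 12); optional point
    vector fields (e.g. displacement) and cell scalar fields (e.g. Von Mises
    stress), written in sorted name order for byte stability."""
    nn, ne = mesh.n_nodes, mesh.n_elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npcmech results\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {nn} double\n")
        for p in mesh.node_coords:
            fh.write(" ".join(_FLOAT % v for v in p) + "\n")
        fh.write(f"CELLS {ne} {9 * ne}\n")
        for conn in mesh.elements:
            fh.write("8 " + " ".join(str(c) for c in conn) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join(["12"] * ne) + "\n")
        if point_vectors:
            fh.write(f"POINT_DATA {nn}\n")
            for name in sorted(point_vectors):
                fh.write(f"VECTORS {name} double\n")
                for v in np.asarray(point_vectors[name]):
                    fh.write(" ".join(_FLOAT % c for c in v) + "\n")
        if cell_scalars:
            fh.write(f"CELL_DATA {ne}\n")
            for name in sorted(cell_scalars):
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(cell_scalars[name]):
                    fh.write(_FLOAT % v + "\n")


class VtkFormatError(ValueError):
    pass


def read_vtk(path) -> tuple[HexMesh, dict, dict]:
    """Read a legacy-VTK hexahedral grid; returns (mesh, point_vectors,
    cell_scalars). Only cell type 12 (hexahedron) is accepted."""
    with open(path) as fh:
        tokens = fh.read().split()
    t = [tok for tok in tokens]
    pos = 0

    def expect(word):
        nonlocal pos
        while pos < len(t) and t[pos].upper() != word:
            pos += 1
        if pos >= len(t):
            raise VtkFormatError(f"missing {word} section")
        pos += 1

    expect("POINTS")
    nn = int(t[pos]); pos += 2  # skip dtype
    coords = np.array(t[pos:pos + 3 * nn], dtype=float).reshape(nn, 3)
    pos += 3 * nn
    expect("CELLS")
    ne = int(t[pos]); total = int(t[pos + 1]); pos += 2
    raw = np.array(t[pos:pos + total], dtype=int)
    pos += total
    if total != 9 * ne or np.any(raw.reshape(ne, 9)[:, 0] != 8):
        raise VtkFormatError(
            "non-hexahedral cell in CELLS block (only cell type 12 supported)")
    conn = raw.reshape(ne, 9)[:, 1:]
    expect("CELL_TYPES")
    nct = int(t[pos]); pos += 1
    ctypes = np.array(t[pos:pos + nct], dtype=int)
    pos += nct
    if np.any(ctypes != 12):
        raise VtkFormatError("only VTK cell type 12 (hexahedron) is supported")
    point_vectors = {}
    cell_scalars = {}
    rest = t[pos:]
    i = 0
    while i < len(rest):
        tok = rest[i].upper()
        if tok == "VECTORS":
            name = rest[i + 1]
            i += 3
            point_vectors[name] = np.array(rest[i:i + 3 * nn], dtype=float
                                           ).reshape(nn, 3)
            i += 3 * nn
        elif tok == "SCALARS":
            name = rest[i + 1]
            i += 4  # SCALARS name dtype 1
            if rest[i].upper() == "LOOKUP_TABLE":
                i += 2
            cell_scalars[name] = np.array(rest[i:i + ne], dtype=float)
            i += ne
        else:
            i += 1
    regions = cell_scalars.get("region")
    region_ids = regions.astype(np.int64) if regions is not None \
        else np.zeros(ne, dtype=np.int64)
    mesh = HexMesh(coords, conn.astype(np.int64), region_ids,
                   region_map={int(r): f"region{int(r)}"
                               for r in np.unique(region_ids)})
    mesh.validate()
    return mesh, point_vectors, cell_scalars


def read_mesh(path, dialect: str) -> HexMesh:
    """Dispatch reader: ``dialect`` ∈ {'inp_subset', 'vtk_legacy'}."""
    if dialect == "inp_subset":
        return read_inp(path)
    if dialect == "vtk_legacy":
        return read_vtk(path)[0]
    raise ValueError(f"unknown mesh dialect {dialect!r}")


def write_mesh(mesh: HexMesh, path, dialect: str) -> None:
    if dialect == "inp_subset":
        write_inp(mesh, path)
    elif dialect == "vtk_legacy":
        write_vtk(mesh, path,
                  cell_scalars={"region": mesh.region_ids.astype(float)})
    else:
        raise ValueError(f"unknown mesh dialect {dialect!r}")


# ---------------------------------------------------------------------------
# results (CSV / JSON)
# ---------------------------------------------------------------------------

def write_results(obj, path, format: str = "json") -> None:
    """Serialize a result object (anything with ``to_dict``, or a plain dict)
    with stable key order and float formatting."""
    d = obj.to_dict() if hasattr(obj, "to_dict") else dict(obj)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, sort_keys=True, indent=1)
            fh.write("\n")
    elif format == "csv":
        _write_csv(d, path)
    else:
        raise ValueError(f"unknown results format {format!r}")


def _write_csv(d: dict, path) -> None:
    """Tabular CSV for site maps and curves (one row per entry)."""
    if "sites" in d:
        rows = [("x_um", "y_um", "strain")]
        for (x, y), s in zip(d["sites"], d["strains"]):
            rows.append((_FLOAT % x, _FLOAT % y, _FLOAT % s))
    elif "depths" in d:
        rows = [("depth_um", d.get("metric", "value"))]
        for z, v in zip(d["depths"], d["values"]):
            rows.append((_FLOAT % z, _FLOAT % v))
    else:
        rows = [("key", "value")] + [(k, repr(v)) for k, v in sorted(d.items())]
    with open(path, "w") as fh:
        for r in rows:
            fh.write(",".join(str(c) for c in r) + "\n")


def write_gp_stress_csv(state, path) -> None:
    """Per-Gauss-point homogenized Cauchy stress table (kPa).

    One row per (element, gauss) with the six independent components in
    Voigt order (xx, yy, zz, yz, xz, xy).
    """
    S = state.S_gp
    with open(path, "w") as fh:
        fh.write("element,gauss,S_xx,S_yy,S_zz,S_yz,S_xz,S_xy\n")
        for e in range(S.shape[0]):
            for g in range(S.shape[1]):
                s = 0.5 * (S[e, g] + S[e, g].T)
                row = [s[0, 0], s[1, 1], s[2, 2], s[1, 2], s[0, 2], s[0, 1]]
                fh.write(f"{e},{g}," + ",".join(_FLOAT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# HDF5 network libraries
# ---------------------------------------------------------------------------

def save_network_library(lib: RveLibrary, path, state=None) -> None:
    """HDF5 container keyed by (element, gauss index).

    ``state`` may be a PackedLibrary whose current (equilibrated) RVE
    coordinates are dumped alongside the reference networks so a run can be
    restored mid-protocol.
    """
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["global_seed"] = lib.global_seed
        h5.attrs["n_elements"] = lib.n_elements
        h5.attrs["fiber_count_range"] = list(lib.fiber_count_range)
        h5.attrs["policies"] = json.dumps(
            {k: {"kind": v.kind, "stretch_ratio": v.stretch_ratio,
                 "frame_source": v.frame_source}
             for k, v in lib.policies.items()}, sort_keys=True)
        for e in range(lib.n_elements):
            for g in range(8):
                gp = 8 * e + g
                net = lib.network(e, g)
                grp = h5.create_group(f"networks/e{e}_g{g}")
                grp.attrs["seed"] = net.seed
                grp.create_dataset("node_coords", data=net.node_coords)
                grp.create_dataset("fibers", data=net.fibers)
                grp.create_dataset("rest_lengths", data=net.rest_lengths)
                grp.create_dataset("boundary_mask",
                                   data=net.boundary_mask.astype(np.uint8))
                if state is not None:
                    n0, n1 = state.node_off[gp], state.node_off[gp + 1]
                    grp.create_dataset("current_coords",
                                       data=state.xcur[n0:n1])


def load_rve_state(path, packed) -> None:
    """Restore dumped RVE coordinates into a PackedLibrary (in place)."""
    import h5py

    with h5py.File(path, "r") as h5:
        ne = int(h5.attrs["n_elements"])
        for e in range(ne):
            for g in range(8):
                grp = h5[f"networks/e{e}_g{g}"]
                if "current_coords" not in grp:
                    raise ValueError("no RVE state stored in this container")
                gp = 8 * e + g
                n0, n1 = packed.node_off[gp], packed.node_off[gp + 1]
                packed.xcur[n0:n1] = np.asarray(grp["current_coords"])


def load_network_library(path) -> RveLibrary:
    import h5py

    from .network import AlignmentPolicy

    with h5py.File(path, "r") as h5:
        ne = int(h5.attrs["n_elements"])
        nets = []
        for e in range(ne):
            for g in range(8):
                grp = h5[f"networks/e{e}_g{g}"]
                nets.append(FiberNetwork(
                    node_coords=np.asarray(grp["node_coords"]),
                    fibers=np.asarray(grp["fibers"], dtype=np.int32),
                    rest_lengths=np.asarray(grp["rest_lengths"]),
                    boundary_mask=np.asarray(grp["boundary_mask"]).astype(bool),
                    seed=int(grp.attrs["seed"]),
                ))
        policies = {k: AlignmentPolicy(v["kind"], v["stretch_ratio"],
                                       v["frame_source"])
                    for k, v in json.loads(h5.attrs["policies"]).items()}
        return RveLibrary(
            networks=nets, n_elements=ne,
            global_seed=int(h5.attrs["global_seed"]),
            policies=policies,
            fiber_count_range=tuple(int(v)
                                    for v in h5.attrs["fiber_count_range"]),
        )


def save_network_json(net: FiberNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(net.to_dict(), fh, sort_keys=True)
        fh.write("\n")


def load_network_json(path) -> FiberNetwork:
    with open(path) as fh:
        return FiberNetwork.from_dict(json.load(fh))
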