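"""Parametric all-hexahedral meshes: isolated corpuscle and skin-embedded PC.

Three model families are generated natively at a configurable resolution:

* ``mesh_half_ellipsoid`` — the isolated Pacinian corpuscle, a half-ellipsoid
  (major axis along y, flat base at z = 0) meshed by mapping a structured
  half-cube grid through a smooth cube-to-ball map, so every outer node sits
  exactly on the ellipsoid surface.
* ``mesh_embedded`` — a full ellipsoid inside a rectangular skin block at a
  prescribed depth, on a graded tensor-product grid; elements are labeled
  corpuscle/skin by centroid and grid nodes near the ellipsoid are snapped
  onto it for an approximately conforming interface.

Lengths are in μm throughout (geometry inputs in mm, converted once here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

logger = logging.getLogger(__name__)

MM = 1000.0  # μm per mm


@dataclass
class HexMesh:
    """8-node hexahedral mesh with region labels and named node sets."""

    node_coords: np.ndarray                  # (nn, 3) μm
    elements: np.ndarray                     # (ne, 8) int, trilinear ordering
    region_ids: np.ndarray                   # (ne,) int
    region_map: dict = field(default_factory=lambda: {0: "corpuscle"})
    node_sets: dict = field(default_factory=dict)
    geometry_params: dict = field(default_factory=dict)  # center, semi_axes (μm)

    @property
    def n_nodes(self) -> int:
        return int(self.node_coords.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.elements.shape[0])

    def region_name(self, e: int) -> str:
        return self.region_map[int(self.region_ids[e])]

    def region_names(self):
        return set(self.region_map[i] for i in np.unique(self.region_ids))

    def element_centroid(self, e: int) -> np.ndarray:
        return self.node_coords[self.elements[e]].mean(axis=0)

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.elements].mean(axis=1)

    def jacobians(self) -> np.ndarray:
        """det J at all 8 Gauss points of every element."""
        out = np.empty((self.n_elements, 8))
        for e in range(self.n_elements):
            Xe = np.ascontiguousarray(self.node_coords[self.elements[e]],
                                      dtype=float)
            for gi in range(8):
                _, detJ = _kernels.element_gradients(Xe, gi)
                out[e, gi] = detJ
        return out

    def volume(self) -> float:
        return float(self.jacobians().sum())  # 2×2×2 Gauss weights are all 1

    def validate(self) -> None:
        """Positive Jacobians, no duplicate nodes, conformity, valid sets."""
        jac = self.jacobians()
        if np.any(jac <= 0):
            e = int(np.argwhere(jac <= 0)[0, 0])
            raise ValueError(f"non-positive Jacobian in element {e}")
        # duplicate nodes
        key = np.round(self.node_coords / 1e-6).astype(np.int64)
        if len(np.unique(key, axis=0)) != self.n_nodes:
            raise ValueError("duplicate nodes detected")
        # every node-set index valid
        for name, ids in self.node_sets.items():
            ids = np.asarray(ids)
            if len(ids) and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise ValueError(f"node set {name!r} references invalid nodes")
        if len(self.region_ids) != self.n_elements:
            raise ValueError("region labels do not cover all elements")
        self._check_conformity()

    def _check_conformity(self) -> None:
        """Interior faces must be shared by exactly two elements."""
        faces = {}
        FACE = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
                (2, 3, 7, 6), (1, 2, 6, 5), (3, 0, 4, 7)]
        for e in range(self.n_elements):
            for f in FACE:
                k = tuple(sorted(int(self.elements[e, i]) for i in f))
                faces[k] = faces.get(k, 0) + 1
        if any(v > 2 for v in faces.values()):
            raise ValueError("non-conforming mesh: face shared by >2 elements")


# ---------------------------------------------------------------------------
# geometry descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpuscleGeometry:
    """Ellipsoidal corpuscle: major axis along y, equal minor axes (x, z)."""

    major_axis: float = 1.0   # mm (full axis length)
    minor_axes: float = 0.5   # mm
    half: bool = True         # half-ellipsoid for the isolated model

    def __post_init__(self) -> None:
        if not self.major_axis >= self.minor_axes > 0:
            raise ValueError("require major >= minor > 0")

    @property
    def semi_axes_um(self) -> np.ndarray:
        """(ax, ay, az) in μm; long axis along y."""
        a = 0.5 * self.minor_axes * MM
        return np.array([a, 0.5 * self.major_axis * MM, a])


@dataclass(frozen=True)
class EmbeddingGeometry:
    """Rectangular skin block with an embedded corpuscle."""

    domain_dims: tuple = (1.5, 1.5, 0.75)  # mm (x, y, z); z is depth direction
    pc_center_depth: float = 0.375         # mm below the top surface
    orientation: str = "horizontal"        # long axis ∥ skin ('horizontal') or ⊥ ('vertical')

    def __post_init__(self) -> None:
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be 'horizontal' or 'vertical'")

    def semi_axes_um(self, pc: CorpuscleGeometry) -> np.ndarray:
        a = pc.semi_axes_um
        if self.orientation == "vertical":  # rotate 90° about x: y ↔ z
            return np.array([a[0], a[2], a[1]])
        return a

    def center_um(self) -> np.ndarray:
        H = self.domain_dims[2] * MM
        return np.array([0.0, 0.0, H - self.pc_center_depth * MM])

    def check_fit(self, pc: CorpuscleGeometry) -> None:
        semi = self.semi_axes_um(pc)
        W = np.array(self.domain_dims) * MM
        c = self.center_um()
        lo = c - semi
        hi = c + semi
        if (np.any(np.abs([hi[0], hi[1]]) > [W[0] / 2, W[1] / 2])
                or lo[2] < 0 or hi[2] > W[2]):
            raise ValueError("corpuscle does not fit inside the domain")


EPIDERMIS = EmbeddingGeometry((1.5, 1.5, 0.75), 0.375, "horizontal")
DERMIS = EmbeddingGeometry((1.5, 1.5, 2.75), 2.375, "horizontal")
#: vertical variant keeps the horizontal dermis model's 125 μm base clearance
DERMIS_VERTICAL = EmbeddingGeometry((1.5, 1.5, 2.75), 2.125, "vertical")


# ---------------------------------------------------------------------------
# isolated corpuscle (half-ellipsoid)
# ---------------------------------------------------------------------------

def _cube_to_ball(p: np.ndarray) -> np.ndarray:
    """Smooth volumetric map of [−1,1]³ onto the unit ball (cube surface →
    sphere surface exactly)."""
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    out = np.empty_like(p)
    out[:, 0] = x * np.sqrt(np.maximum(1 - y * y / 2 - z * z / 2 + y * y * z * z / 3, 0.0))
    out[:, 1] = y * np.sqrt(np.maximum(1 - z * z / 2 - x * x / 2 + z * z * x * x / 3, 0.0))
    out[:, 2] = z * np.sqrt(np.maximum(1 - x * x / 2 - y * y / 2 + x * x * y * y / 3, 0.0))
    return out


def mesh_half_ellipsoid(geom: CorpuscleGeometry, resolution: int = 4,
                        top_line_depth: float = 100.0) -> HexMesh:
    """Structured all-hex mesh of the isolated half-ellipsoid corpuscle.

    ``resolution`` n gives 4n³ elements (n=4 → 256). Node sets: ``base``
    (z = 0 plane), ``surface`` (curved ellipsoid boundary), ``top_z_line``
    (nodes on the z-axis within ``top_line_depth`` μm of the top pole),
    ``long_axis_pair`` (the two base nodes at y = ±major/2) and
    ``midplane_loop`` (ordered y = 0 cross-section boundary loop).
    """
    n = int(resolution)
    if n < 2:
        raise ValueError("resolution must be >= 2 to form valid hexahedra")
    ax, ay, az = geom.semi_axes_um
    gx = np.arange(-n, n + 1) / n
    gz = np.arange(0, n + 1) / n
    G = np.array([[i, j, k] for k in gz for j in gx for i in gx])
    nx = 2 * n + 1

    def nid(i, j, k):  # grid indices (0-based) into node list
        return (k * nx + j) * nx + i

    mapped = _cube_to_ball(G)
    coords = mapped * np.array([ax, ay, az])

    elems = []
    for k in range(n):
        for j in range(2 * n):
            for i in range(2 * n):
                elems.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    elems = np.array(elems, dtype=np.int64)

    absg = np.abs(G)
    on_base = G[:, 2] == 0.0
    on_surf = (absg[:, 0] == 1.0) | (absg[:, 1] == 1.0) | (G[:, 2] == 1.0)
    on_axis = (G[:, 0] == 0.0) & (G[:, 1] == 0.0)
    sets = {
        "base": np.flatnonzero(on_base),
        "surface": np.flatnonzero(on_surf),
        "top_z_line": np.flatnonzero(on_axis & (coords[:, 2] >= az - top_line_depth)),
        "long_axis_pair": np.array(
            [nid(n, 0, 0), nid(n, 2 * n, 0)], dtype=np.int64),
    }
    # ordered y=0 cross-section boundary: curved arc then base line
    mid = (G[:, 1] == 0.0)
    arc = np.flatnonzero(mid & on_surf & ~on_base)
    arc = arc[np.argsort(-np.arctan2(coords[arc, 2], coords[arc, 0]))]
    baseline = np.flatnonzero(mid & on_base)
    baseline = baseline[np.argsort(coords[baseline, 0])]
    loop = np.concatenate([baseline, arc[::-1]])  # CCW in the x–z plane
    sets["midplane_loop"] = loop

    mesh = HexMesh(
        node_coords=coords,
        elements=elems,
        region_ids=np.zeros(len(elems), dtype=np.int64),
        region_map={0: "corpuscle"},
        node_sets=sets,
        geometry_params={"center": np.zeros(3), "semi_axes": np.array([ax, ay, az])},
    )
    mesh.validate()
    lvl = ((coords / [ax, ay, az]) ** 2).sum(axis=1)
    if np.any(lvl > 1 + 1e-9):
        raise AssertionError("node outside the ellipsoid")
    return mesh


# ---------------------------------------------------------------------------
# embedded corpuscle
# ---------------------------------------------------------------------------

def _segment(a: float, b: float, n: int) -> np.ndarray:
    return np.linspace(a, b, n + 1)[1:]


def _lateral_line(W: float, extent: float, h: float) -> np.ndarray:
    """Symmetric grid line [−W, W]: fine step h on [−E, E], coarse outside."""
    nf = max(1, int(np.ceil(extent / h)))
    E = nf * h
    E = min(E, W)
    fine = np.linspace(-E, E, 2 * nf + 1)
    if E >= W - 1e-9:
        return fine
    nc = max(1, int(round((W - E) / (2.5 * h))))
    right = _segment(E, W, nc)
    left = -right[::-1]
    return np.concatenate([left, fine, right])


def _depth_line(H: float, z0: float, z1: float, h: float) -> np.ndarray:
    """Grid line [0, H]: fine step over the corpuscle band [z0, z1] (with the
    band center a grid plane), graded below, and a refined zone under the
    indented top surface."""
    nf = 2 * max(1, int(np.ceil(0.5 * (z1 - z0) / h)))
    band = np.linspace(z0, z1, nf + 1)
    below = []
    if z0 > 1e-9:
        nb = max(1, int(round(z0 / (2.5 * h))))
        below = list(np.linspace(0.0, z0, nb + 1)[:-1])
    above = []
    if z1 < H - 1e-9:
        top_fine = min(2 * h, H - z1)
        zt = H - top_fine
        if zt > z1 + 1e-9:
            nb = max(1, int(round((zt - z1) / (3.0 * h))))
            above = list(_segment(z1, zt, nb))
        ntf = max(1, int(round(top_fine / h)))
        above += list(_segment(max(zt, z1), H, ntf))
    return np.array(below + list(band) + above)


def _snap_to_surface(coords, center, semi, band, frozen):
    """Project nodes radially onto the ellipsoid when within ``band`` μm of it."""
    x = coords - center
    scaled = x / semi
    r = np.linalg.norm(scaled, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.abs(r - 1.0) * np.linalg.norm(x, axis=1) / np.where(r > 0, r, 1.0)
    move = (~frozen) & (r > 1e-9) & (dist < band)
    out = coords.copy()
    out[move] = center + x[move] / r[move, None]  # radial projection in scaled space
    return out, move


def mesh_embedded(geom: EmbeddingGeometry, pc: CorpuscleGeometry,
                  resolution: float = 1.0) -> HexMesh:
    """Graded conforming hex mesh of a corpuscle embedded in a skin block.

    ``resolution`` sets the fine cell size h = 250/resolution μm around the
    corpuscle. Elements are labeled by whether their centroid lies inside the
    ellipsoid; grid nodes within 0.4 h of the ellipsoid surface are snapped
    onto it (band halved automatically if that inverts an element). Node
    sets: ``surface`` (top face), ``base``, ``sides``, ``surface_center``
    (top node above the PC center) and ``long_axis_pair`` (interface nodes on
    the long axis, the Eq-style strain gauge pair).
    """
    geom.check_fit(pc)
    semi = geom.semi_axes_um(pc)
    center = geom.center_um()
    W = np.array(geom.domain_dims) * MM
    H = W[2]
    h = 250.0 / float(resolution)

    xs = _lateral_line(W[0] / 2, semi[0], h)
    ys = _lateral_line(W[1] / 2, semi[1], h)
    zs = _depth_line(H, center[2] - semi[2], center[2] + semi[2], h)

    nxl, nyl, nzl = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([X.ravel(order="F"), Y.ravel(order="F"),
                              Z.ravel(order="F")])
    # node id: i + nxl*(j + nyl*k) with Fortran ravel of (i,j,k) meshgrid
    def nid(i, j, k):
        return i + nxl * (j + nyl * k)

    elems = []
    for k in range(nzl - 1):
        for j in range(nyl - 1):
            for i in range(nxl - 1):
                elems.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    elems = np.array(elems, dtype=np.int64)

    frozen = (
        (np.abs(coords[:, 0]) > W[0] / 2 - 1e-9)
        | (np.abs(coords[:, 1]) > W[1] / 2 - 1e-9)
        | (coords[:, 2] < 1e-9) | (coords[:, 2] > H - 1e-9)
    )
    band = 0.4 * h
    mesh = None
    for _ in range(6):
        snapped, _moved = _snap_to_surface(coords, center, semi, band, frozen)
        lvl = (((snapped[elems].mean(axis=1) - center) / semi) ** 2).sum(axis=1)
        regions = np.where(lvl < 1.0, 0, 1).astype(np.int64)
        mesh = HexMesh(
            node_coords=snapped,
            elements=elems,
            region_ids=regions,
            region_map={0: "corpuscle", 1: "skin"},
            node_sets={},
            geometry_params={"center": center, "semi_axes": semi},
        )
        if np.all(mesh.jacobians() > 0):
            break
        band *= 0.5
        logger.info("snap band halved to %.1f μm to keep Jacobians positive", band)
    coords = mesh.node_coords

    def nearest(p):
        return int(np.argmin(((coords - p) ** 2).sum(axis=1)))

    if geom.orientation == "horizontal":
        pair = [nearest(center + [0, -semi[1], 0]), nearest(center + [0, semi[1], 0])]
        axis_index = 1
    else:
        pair = [nearest(center + [0, 0, -semi[2]]), nearest(center + [0, 0, semi[2]])]
        axis_index = 2
    mesh.node_sets = {
        "surface": np.flatnonzero(coords[:, 2] > H - 1e-9),
        "base": np.flatnonzero(coords[:, 2] < 1e-9),
        "sides": np.flatnonzero(
            (np.abs(coords[:, 0]) > W[0] / 2 - 1e-9)
            | (np.abs(coords[:, 1]) > W[1] / 2 - 1e-9)),
        "long_axis_pair": np.array(pair, dtype=np.int64),
        "surface_center": np.array([nearest(np.array([0.0, 0.0, H]))],
                                   dtype=np.int64),
    }
    mesh.geometry_params["long_axis_index"] = axis_index
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# resolution ladder
# ---------------------------------------------------------------------------

def resolution_ladder(family: str = "isolated", levels=(2, 3, 4),
                      pc: CorpuscleGeometry | None = None,
                      embedding: EmbeddingGeometry | None = None):
    """Nested refinements for convergence studies.

    Returns a list of (level, mesh); element count grows ≈ 8× per level for
    the isolated family (4n³ with n doubling ≙ one uniform refinement).
    """
    if len(levels) < 2:
        raise ValueError("a ladder needs at least two levels")
    pc = pc or CorpuscleGeometry()
    out = []
    for lv in levels:
        if family == "isolated":
            m = mesh_half_ellipsoid(pc, resolution=int(lv))
        else:
            m = mesh_embedded(embedding or EPIDERMIS, pc, resolution=float(lv))
        logger.info("ladder level %s: %d elements", lv, m.n_elements)
        out.append((lv, m))
    return out
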