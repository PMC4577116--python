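"""Delaunay fiber-network generation, alignment, and characterization.

Every Gauss point of the macroscale mesh carries a representative volume
element (RVE): a unit-cube domain filled with a fiber network whose fibers
are edges of a Delaunay tessellation of random points. Anisotropy — the
model's abstraction of the corpuscle's concentric lamellae and of dermal
collagen sheets — is introduced by stretching an isotropic network and
clipping it back to the unit cube, so that surviving fiber directions tilt
toward the stretched axes.

Networks are dimensionless (unit-cube coordinates); only the fiber force
parameter carries units. Boundary nodes (cross-links lying exactly on a cube
face) are the points through which macroscale deformation enters and through
which the volume-averaged stress is recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)

_FACE_TOL = 1e-9
#: Mean Delaunay edges per point for a 3-D Poisson point set (used only as a
#: first guess; the generator measures and corrects the realized count).
_EDGES_PER_POINT = 6.7
#: Shortest admissible fiber after clipping, in RVE units. Sub-resolution
#: stubs carry no load at rest but make the exponential law blow up under
#: tiny interior motions, so they are removed.
MIN_FIBER_LENGTH = 0.02


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FiberNetwork:
    """A fiber network inside the unit-cube RVE.

    node_coords : (n, 3) positions in [0, 1]^3 (dimensionless)
    fibers      : (m, 2) node-index pairs, i < j, distinct
    rest_lengths: (m,) unloaded fiber lengths (> 0)
    boundary_mask: (n,) True where the node lies on a cube face
    seed        : integer the network was generated from
    """

    node_coords: np.ndarray
    fibers: np.ndarray
    rest_lengths: np.ndarray
    boundary_mask: np.ndarray
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return int(self.node_coords.shape[0])

    @property
    def n_fibers(self) -> int:
        return int(self.fibers.shape[0])

    def validate(self, fiber_count_range: tuple[int, int] | None = None) -> None:
        """Raise ValueError on any violated structural invariant."""
        x, fib, L0 = self.node_coords, self.fibers, self.rest_lengths
        if x.ndim != 2 or x.shape[1] != 3:
            raise ValueError("node_coords must be (n, 3)")
        if np.any(x < -_FACE_TOL) or np.any(x > 1.0 + _FACE_TOL):
            raise ValueError("node coordinates must lie in the unit cube")
        if fib.shape != (len(L0), 2):
            raise ValueError("fibers and rest_lengths are inconsistent")
        if np.any(fib[:, 0] == fib[:, 1]):
            raise ValueError("fiber connects a node to itself")
        if len(L0) and not np.all(L0 > 0):
            raise ValueError("rest lengths must be positive")
        if self.boundary_mask.shape != (len(x),):
            raise ValueError("boundary_mask has wrong shape")
        if fiber_count_range is not None:
            lo, hi = fiber_count_range
            if not lo <= self.n_fibers <= hi:
                raise ValueError(
                    f"fiber count {self.n_fibers} outside configured range [{lo}, {hi}]"
                )
        self._check_interior_connectivity()

    def _check_interior_connectivity(self) -> None:
        """No interior connected component may float free of the boundary.

        Vacuous for raw tessellations without face cross-links (nothing is
        anchored yet); meaningful once a network is clipped to the cube.
        """
        if self.n_fibers == 0 or not self.boundary_mask.any():
            return
        reach = _reachable_from_boundary(
            self.n_nodes, self.fibers, self.boundary_mask
        )
        loose = ~reach & ~self.boundary_mask
        # nodes without any fiber are tolerated only if flagged boundary
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.fibers.ravel(), 1)
        if np.any(loose & (deg > 0)):
            raise ValueError("free-floating interior component detected")

    def to_dict(self) -> dict:
        """Plain-data form of the documented JSON schema."""
        return {
            "schema": "pcmech.fiber_network/1",
            "seed": int(self.seed),
            "node_coords": self.node_coords.tolist(),
            "fibers": self.fibers.tolist(),
            "rest_lengths": self.rest_lengths.tolist(),
            "boundary_mask": self.boundary_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberNetwork":
        return cls(
            node_coords=np.asarray(d["node_coords"], dtype=float),
            fibers=np.asarray(d["fibers"], dtype=np.int32).reshape(-1, 2),
            rest_lengths=np.asarray(d["rest_lengths"], dtype=float),
            boundary_mask=np.asarray(d["boundary_mask"], dtype=bool),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class AlignmentPolicy:
    """How the networks of one mesh region are oriented.

    kind          : 'isotropic' | 'surface_aligned_corpuscle' | 'skin_plane'
    stretch_ratio : in-plane/normal anisotropy magnitude (>= 1)
    frame_source  : 'confocal' (ellipsoidal surface frame) | 'global'
    """

    kind: str = "isotropic"
    stretch_ratio: float = 3.0
    frame_source: str = "confocal"

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic", "surface_aligned_corpuscle", "skin_plane"):
            raise ValueError(f"unknown alignment kind {self.kind!r}")
        if self.stretch_ratio < 1.0:
            raise ValueError("stretch_ratio must be >= 1")
        if self.kind == "isotropic":
            object.__setattr__(self, "stretch_ratio", 1.0)

    @property
    def stretch(self) -> np.ndarray:
        """Principal stretch ratios in the local frame (t1, t2, normal)."""
        r = self.stretch_ratio
        return np.array([r, r, 1.0])


ISOTROPIC = AlignmentPolicy("isotropic")


def _reachable_from_boundary(n_nodes, fibers, boundary_mask) -> np.ndarray:
    """BFS over the fiber graph from all boundary nodes."""
    adj: list[list[int]] = [[] for _ in range(n_nodes)]
    for a, b in fibers:
        adj[a].append(b)
        adj[b].append(a)
    reach = boundary_mask.copy()
    stack = list(np.flatnonzero(boundary_mask))
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if not reach[j]:
                reach[j] = True
                stack.append(j)
    return reach


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique edges (i < j) of the Delaunay tessellation of *points*."""
    tri = Delaunay(points)
    s = tri.simplices
    pairs = np.vstack([
        s[:, [0, 1]], s[:, [0, 2]], s[:, [0, 3]],
        s[:, [1, 2]], s[:, [1, 3]], s[:, [2, 3]],
    ])
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0).astype(np.int32)


def generate_delaunay_network(n_points: int, seed: int) -> FiberNetwork:
    """Delaunay network of ``n_points`` uniform random points in the unit cube.

    Fibers are the tessellation edges; rest lengths are the generated edge
    lengths (the network is unloaded as built). Nodes lying exactly on a cube
    face (rare for random points) are flagged boundary. Degenerate (coplanar)
    point sets are perturbed and retried with a logged warning.
    """
    if n_points < 4:
        raise ValueError("need at least 4 points for a 3-D Delaunay tessellation")
    rng = np.random.default_rng(seed)
    pts = rng.random((n_points, 3))
    for attempt in range(5):
        try:
            fibers = _delaunay_edges(pts)
            break
        except QhullError:
            logger.warning(
                "degenerate point set for seed %d; perturbing (attempt %d)",
                seed, attempt + 1,
            )
            pts = np.clip(pts + rng.normal(0.0, 1e-9, pts.shape), 0.0, 1.0)
    else:  # pragma: no cover
        raise RuntimeError("Delaunay tessellation failed after perturbation")
    d = pts[fibers[:, 1]] - pts[fibers[:, 0]]
    L0 = np.linalg.norm(d, axis=1)
    on_face = np.any((pts < _FACE_TOL) | (pts > 1.0 - _FACE_TOL), axis=1)
    return FiberNetwork(pts, fibers, L0, on_face, seed=seed)


# ---------------------------------------------------------------------------
# affine transform + clip (the alignment mechanism)
# ---------------------------------------------------------------------------

def _clip_segments_to_cube(p0: np.ndarray, p1: np.ndarray):
    """Vectorized Liang–Barsky clip of segments to [0,1]^3.

    Returns (keep, a, b, cut0, cut1): endpoint coordinates of the retained
    portions and flags telling whether each end was created by the clip.
    """
    d = p1 - p0
    u1 = np.zeros(len(p0))
    u2 = np.ones(len(p0))
    ok = np.ones(len(p0), dtype=bool)
    for ax in range(3):
        for p, q in ((-d[:, ax], p0[:, ax]), (d[:, ax], 1.0 - p0[:, ax])):
            par = p == 0.0
            ok &= ~(par & (q < 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(par, 0.0, q / np.where(par, 1.0, p))
            u1 = np.where(~par & (p < 0), np.maximum(u1, t), u1)
            u2 = np.where(~par & (p > 0), np.minimum(u2, t), u2)
    keep = ok & (u1 < u2)
    a = p0 + u1[:, None] * d
    b = p0 + u2[:, None] * d
    return keep, a, b, u1 > 0.0, u2 < 1.0


def _build_clipped(points: np.ndarray, edges: np.ndarray, seed: int,
                   min_len: float = MIN_FIBER_LENGTH) -> FiberNetwork:
    """Assemble a unit-cube network from arbitrary points + edges by clipping.

    Original nodes inside the cube keep their identity; clip intersections
    become new boundary nodes. Fibers shorter than ``min_len`` (clip stubs)
    are dropped, and interior components left unconnected to the boundary
    are pruned.
    """
    p0 = points[edges[:, 0]]
    p1 = points[edges[:, 1]]
    keep, a, b, cut0, cut1 = _clip_segments_to_cube(p0, p1)

    idx = np.flatnonzero(keep)
    inside = np.all((points >= 0.0) & (points <= 1.0), axis=1)
    remap = -np.ones(len(points), dtype=np.int64)

    new_coords: list[np.ndarray] = []
    new_bnd: list[bool] = []

    def _orig(i: int) -> int:
        if remap[i] < 0:
            remap[i] = len(new_coords)
            c = np.clip(points[i], 0.0, 1.0)
            new_coords.append(c)
            new_bnd.append(bool(np.any((c < _FACE_TOL) | (c > 1 - _FACE_TOL))))
        return int(remap[i])

    fib = np.empty((len(idx), 2), dtype=np.int32)
    for k, e in enumerate(idx):
        if cut0[e] or not inside[edges[e, 0]]:
            i0 = len(new_coords)
            new_coords.append(np.clip(a[e], 0.0, 1.0))
            new_bnd.append(True)
        else:
            i0 = _orig(edges[e, 0])
        if cut1[e] or not inside[edges[e, 1]]:
            i1 = len(new_coords)
            new_coords.append(np.clip(b[e], 0.0, 1.0))
            new_bnd.append(True)
        else:
            i1 = _orig(edges[e, 1])
        fib[k] = (i0, i1)

    coords = np.asarray(new_coords) if new_coords else np.zeros((0, 3))
    bnd = np.asarray(new_bnd, dtype=bool)
    L0 = np.linalg.norm(coords[fib[:, 1]] - coords[fib[:, 0]], axis=1) if len(fib) else np.zeros(0)
    good = L0 > min_len
    fib, L0 = fib[good], L0[good]

    # prune components not anchored to the boundary
    reach = _reachable_from_boundary(len(coords), fib, bnd)
    fkeep = reach[fib[:, 0]] & reach[fib[:, 1]]
    fib, L0 = fib[fkeep], L0[fkeep]
    used = np.zeros(len(coords), dtype=bool)
    used[fib.ravel()] = True
    remap2 = np.cumsum(used) - 1
    net = FiberNetwork(
        node_coords=coords[used],
        fibers=remap2[fib].astype(np.int32),
        rest_lengths=L0,
        boundary_mask=bnd[used],
        seed=seed,
    )
    return net


def transform_and_clip(net: FiberNetwork, M: np.ndarray) -> FiberNetwork:
    """Affinely map node positions about the cube center, then clip to the cube.

    The connectivity is kept, so fiber directions rotate/stretch with ``M``;
    fibers crossing a face are cut there and gain boundary cross-links.
    """
    M = np.asarray(M, dtype=float)
    c = np.full(3, 0.5)
    pts = c + (net.node_coords - c) @ M.T
    return _build_clipped(pts, np.asarray(net.fibers), net.seed)


def align_network(net: FiberNetwork, stretch) -> FiberNetwork:
    """Align a network by stretching it by diag(stretch) and re-clipping.

    A fiber population stretched along an axis tilts toward that axis, so the
    orientation-tensor eigenvalue along the largest ratio grows with it.
    stretch = (1, 1, 1) leaves a unit-cube network untouched.
    """
    stretch = np.asarray(stretch, dtype=float)
    if stretch.shape != (3,) or np.any(stretch <= 0):
        raise ValueError("stretch must be three positive ratios")
    return transform_and_clip(net, np.diag(stretch))


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

def orientation_tensor(net: FiberNetwork) -> np.ndarray:
    """Length-weighted second-moment tensor Ω = Σ L d⊗d / Σ L (trace 1)."""
    if net.n_fibers == 0:
        raise ValueError("orientation tensor of an empty network is undefined")
    v = net.node_coords[net.fibers[:, 1]] - net.node_coords[net.fibers[:, 0]]
    L = np.linalg.norm(v, axis=1)
    tot = L.sum()
    if tot <= 0:
        raise ValueError("zero total fiber length")
    d = v / L[:, None]
    return (L[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / tot


# ---------------------------------------------------------------------------
# local frames
# ---------------------------------------------------------------------------

def _confocal_lambda(x: np.ndarray, semi: np.ndarray) -> float:
    """Parameter λ of the confocal ellipsoid Σ x_i²/(a_i²+λ) = 1 through x."""
    active = np.abs(x) > 1e-12 * semi.max()
    if not np.any(active):
        raise ZeroDivisionError("point at the ellipsoid center")
    lo = -np.min(semi[active] ** 2)

    def f(lam):
        return np.sum(x[active] ** 2 / (semi[active] ** 2 + lam)) - 1.0

    eps = 1e-12 * semi.max() ** 2
    a = lo + eps
    while f(a) < 0:  # extremely close to an axis: move bracket down
        eps *= 0.5
        a = lo + eps
        if eps < 1e-300:  # pragma: no cover
            raise ZeroDivisionError("confocal bracket collapsed")
    b = semi.max() ** 2
    while f(b) > 0:
        b *= 2.0
    from scipy.optimize import brentq

    return float(brentq(f, a, b, xtol=1e-14 * semi.max() ** 2, maxiter=200))


def local_frame(element_centroid, region: str, geometry_params: dict) -> np.ndarray:
    """Orthonormal frame (rows = local axes, det +1) at an element centroid.

    Corpuscle elements: third row is the outward normal of the confocal
    ellipsoidal surface through the centroid (the model's proxy for the local
    lamella orientation); the first two rows span the tangent plane. Skin
    elements: identity (skin normal is global z). A centroid at the ellipsoid
    center has no defined normal; the global frame is returned with a log
    message.
    """
    if region != "corpuscle":
        return np.eye(3)
    center = np.asarray(geometry_params["center"], dtype=float)
    semi = np.asarray(geometry_params["semi_axes"], dtype=float)
    x = np.asarray(element_centroid, dtype=float) - center
    try:
        lam = _confocal_lambda(x, semi)
    except ZeroDivisionError:
        logger.info("centroid at ellipsoid center; using global frame")
        return np.eye(3)
    n = x / (semi ** 2 + lam)
    n = n / np.linalg.norm(n)
    helper = np.eye(3)[np.argmin(np.abs(n))]
    t1 = np.cross(helper, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return np.vstack([t1, t2, n])


# ---------------------------------------------------------------------------
# RVE-ready generation and assignment
# ---------------------------------------------------------------------------

def _sample_separated(rng, n: int, h: float) -> np.ndarray:
    """≈n near-uniform points in the cube of half-extent h about the center,
    thinned to a minimum pairwise separation so Delaunay edges cannot be
    arbitrarily short (short edges destabilize the exponential fiber law)."""
    from scipy.spatial import cKDTree

    side = 2.0 * h
    delta = 0.3 * side / max(n, 1) ** (1.0 / 3.0)
    cand = 0.5 + (rng.random((int(n * 1.8) + 8, 3)) - 0.5) * side
    keep = np.ones(len(cand), dtype=bool)
    for i, j in sorted(cKDTree(cand).query_pairs(delta)):
        if keep[i] and keep[j]:
            keep[j] = False
    pts = cand[keep]
    return pts[:n] if len(pts) >= n else pts


def generate_rve_network(
    fiber_count_range: tuple[int, int],
    M: np.ndarray,
    seed: int,
    margin: float = 0.12,
    n_points_hint: int | None = None,
) -> FiberNetwork:
    """Generate a unit-cube RVE network under the affine texture map ``M``.

    Uniform points are sampled on the preimage of the (margin-enlarged) unit
    cube under ``M``, Delaunay-tessellated, mapped through ``M`` about the
    cube center and clipped, so the final network fills the cube, has
    cross-links exactly on the faces, and a fiber count inside
    ``fiber_count_range``. The point count is adjusted iteratively from the
    measured count (``n_points_hint`` seeds the estimate).
    """
    lo, hi = fiber_count_range
    if not 0 < lo <= hi:
        raise ValueError("invalid fiber count range")
    target = 0.5 * (lo + hi)
    M = np.asarray(M, dtype=float)
    detM = abs(np.linalg.det(M))
    if detM <= 0:
        raise ValueError("texture map must be invertible")
    Minv = np.linalg.inv(M)
    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                       dtype=float) - 0.5
    h = np.max(np.abs(corners @ Minv.T)) + margin
    vol_pre = (2.0 * h) ** 3
    if n_points_hint is not None:
        n = max(8, int(n_points_hint))
    else:
        n = max(8, int(round(target / _EDGES_PER_POINT * vol_pre * detM)))
    rng = np.random.default_rng(seed)
    best = None
    best_n = n
    for _ in range(8):
        pts = _sample_separated(rng, n, h)
        edges = _delaunay_edges(pts)
        c = np.full(3, 0.5)
        mapped = c + (pts - c) @ M.T
        net = _build_clipped(mapped, edges, seed)
        if lo <= net.n_fibers <= hi:
            net._n_points_used = n
            return net
        if best is None or abs(net.n_fibers - target) < abs(best.n_fibers - target):
            best, best_n = net, n
        n = max(8, int(round(n * target / max(net.n_fibers, 1))))
    logger.warning(
        "fiber count %d outside range [%d, %d] after retries (seed %d)",
        best.n_fibers, lo, hi, seed,
    )
    best._n_points_used = best_n
    return best


def policy_texture_map(policy: AlignmentPolicy, frame: np.ndarray) -> np.ndarray:
    """Affine texture map M = Q diag(stretch) Qᵀ for a policy in a frame.

    ``frame`` rows are the local axes; stretching happens along the local
    in-plane axes so fibers concentrate in the tangent/skin plane.
    """
    Q = frame.T  # columns = local axes in global coordinates
    return Q @ np.diag(policy.stretch) @ Q.T


@dataclass
class RveLibrary:
    """Per-Gauss-point fiber networks for a mesh, element-major order.

    networks[8*e + g] is the RVE of Gauss point g of element e.
    """

    networks: list
    n_elements: int
    global_seed: int
    policies: dict = field(default_factory=dict)
    fiber_count_range: tuple = (500, 700)

    def network(self, element: int, gauss: int) -> FiberNetwork:
        return self.networks[8 * element + gauss]

    def __len__(self) -> int:
        return len(self.networks)


def matrix_only_library(mesh, seed: int = 0) -> RveLibrary:
    """Library of empty networks: the homogenized response reduces exactly to
    the neo-Hookean matrix. Useful for verification (patch/symmetry tests)
    and as the fiber-free control."""
    empty = FiberNetwork(
        node_coords=np.zeros((0, 3)),
        fibers=np.zeros((0, 2), dtype=np.int32),
        rest_lengths=np.zeros(0),
        boundary_mask=np.zeros(0, dtype=bool),
        seed=seed,
    )
    return RveLibrary(
        networks=[empty] * (8 * mesh.n_elements),
        n_elements=mesh.n_elements,
        global_seed=int(seed),
        policies={},
        fiber_count_range=(0, 0),
    )


def derive_seed(global_seed: int, element: int, gauss: int) -> int:
    """Reproducible 31-bit child seed for one Gauss point."""
    ss = np.random.SeedSequence(entropy=int(global_seed),
                                spawn_key=(int(element), int(gauss)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def assign_networks(
    mesh,
    policy_by_region: dict[str, AlignmentPolicy],
    seed: int,
    fiber_count_range: tuple[int, int] = (500, 700),
) -> RveLibrary:
    """Generate one independent network per Gauss point (8 per element).

    The element's region label selects the alignment policy; the texture map
    is built in the element-centroid local frame and applied in global
    coordinates, so networks rotate with the confocal surface around the
    corpuscle. Seeds derive reproducibly from (seed, element, gauss).
    """
    missing = set(mesh.region_names()) - set(policy_by_region)
    if missing:
        raise ValueError(f"no alignment policy for region(s) {sorted(missing)}")
    geom = mesh.geometry_params
    networks = []
    hints: dict[str, int] = {}
    for e in range(mesh.n_elements):
        region = mesh.region_name(e)
        policy = policy_by_region[region]
        if policy.kind == "isotropic" or policy.frame_source == "global":
            frame = np.eye(3)
        else:
            frame = local_frame(mesh.element_centroid(e), region, geom)
        M = policy_texture_map(policy, frame)
        for g in range(8):
            child = derive_seed(seed, e, g)
            net = generate_rve_network(
                fiber_count_range, M, child,
                n_points_hint=hints.get(region),
            )
            hints[region] = getattr(net, "_n_points_used", None)
            networks.append(net)
    return RveLibrary(
        networks=networks,
        n_elements=mesh.n_elements,
        global_seed=int(seed),
        policies={k: v for k, v in policy_by_region.items()},
        fiber_count_range=tuple(fiber_count_range),
    )
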