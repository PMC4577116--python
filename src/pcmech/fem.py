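"""Nonlinear macroscale finite-element solver with per-Gauss-point RVEs.

Trilinear hexahedra with 2×2×2 Gauss quadrature; at every Gauss point the
constitutive response (Cauchy stress and its tangent) comes from the
fiber-network RVE mixture of ``pcmech.rve``, evaluated through the packed
numba kernels. Equilibrium of the averaged-stress balance is found by Newton
iteration on the free nodal displacements, with indentation applied as
prescribed vertical displacements (no contact mechanics).

Total-Lagrangian formulation: internal forces assemble ∫ (∂N/∂X)ᵀ P dV₀ with
P = J σ F⁻ᵀ, and the tangent uses the central-finite-difference material
tangent dP/dF evaluated kernel-side with warm-started RVE re-solves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels
from .materials import MaterialParams
from .mesh import HexMesh
from .network import RveLibrary

logger = logging.getLogger(__name__)

MACRO_TOL_REL = 1e-4     # residual ∞-norm relative to reaction ∞-norm
MACRO_TOL_ABS = 1e-6     # μN floor
MACRO_MAX_ITER = 30
FD_STEP = 1e-5


class MacroNonConvergence(RuntimeError):
    def __init__(self, increment, history):
        super().__init__(
            f"macroscale Newton failed at increment {increment} "
            f"(residual history {['%.3g' % r for r in history]}); "
            "try smaller depth increments"
        )
        self.increment = increment
        self.history = history


class RveFailure(RuntimeError):
    def __init__(self, element, gauss, code):
        kind = {1: "Newton non-convergence", 2: "fiber-force overflow"}.get(
            code, f"status {code}")
        super().__init__(f"RVE solve failed at element {element}, "
                         f"Gauss point {gauss}: {kind}")
        self.element = element
        self.gauss = gauss


# ---------------------------------------------------------------------------
# protocols and boundary conditions
# ---------------------------------------------------------------------------

@dataclass
class IndentationProtocol:
    """Displacement-controlled indentation schedule.

    kind       : 'cylinder' (flat circular footprint) or 'node' (single node)
    diameter   : footprint diameter, μm (cylinder kind)
    center     : (x, y) surface position of the indenter axis, μm
    increments : depth increments, μm (cumulative depth is their prefix sum)
    fixed      : {node_set_name: mode}, mode ∈ {'clamp','z','normal'};
                 'normal' fixes the outward-normal component of lateral faces
    extra_fixed: [(node_id, component)] pinned to zero (rigid-mode control)
    """

    kind: str = "cylinder"
    diameter: float = 250.0
    center: tuple = (0.0, 0.0)
    increments: tuple = (10.0,)
    fixed: dict = field(default_factory=dict)
    extra_fixed: tuple = ()
    engagement: str = "overlap"

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "node"):
            raise ValueError(f"unknown indenter kind {self.kind!r}")
        if self.engagement not in ("overlap", "uniform"):
            raise ValueError(f"unknown engagement rule {self.engagement!r}")
        if any(d < 0 for d in self.increments):
            raise ValueError("depth increments must be nonnegative")

    @property
    def depths(self) -> np.ndarray:
        """Cumulative depth after each increment (μm, nondecreasing)."""
        return np.cumsum(np.asarray(self.increments, dtype=float))


def footprint_nodes(mesh: HexMesh, protocol: IndentationProtocol) -> np.ndarray:
    """Surface nodes prescribed by the indenter (inclusive radius)."""
    surf = mesh.node_sets["surface"]
    xy = mesh.node_coords[surf, :2] - np.asarray(protocol.center)
    if protocol.kind == "node":
        return surf[[int(np.argmin((xy ** 2).sum(axis=1)))]]
    r = np.sqrt((xy ** 2).sum(axis=1))
    hit = surf[r <= protocol.diameter / 2.0 + 1e-9]
    if len(hit) == 0:
        raise ValueError(
            "no surface node inside the indenter footprint; refine the mesh")
    return hit


def apply_indenter(mesh: HexMesh, protocol: IndentationProtocol,
                   cumulative_depth: float):
    """Dirichlet data at one cumulative depth.

    Returns (mask, values): (n, 3) boolean prescribed-dof mask and the
    prescribed displacement values (μm). Indentation is a downward (−z)
    vertical displacement; clamped/roller sets come from ``protocol.fixed``.
    """
    nn = mesh.n_nodes
    mask = np.zeros((nn, 3), dtype=bool)
    vals = np.zeros((nn, 3))
    for name, mode in protocol.fixed.items():
        ids = mesh.node_sets[name]
        if mode == "clamp":
            mask[ids, :] = True
        elif mode == "z":
            mask[ids, 2] = True
        elif mode == "normal":
            x = mesh.node_coords[ids]
            for axis in (0, 1):
                w = np.max(np.abs(x[:, axis]))
                on = ids[np.abs(np.abs(x[:, axis]) - w) < 1e-9]
                mask[on, axis] = True
        else:
            raise ValueError(f"unknown BC mode {mode!r}")
    for node, comp in protocol.extra_fixed:
        mask[node, comp] = True
    foot = footprint_nodes(mesh, protocol)
    if protocol.kind == "cylinder" and protocol.engagement == "overlap":
        # rigid flat punch: its plane sits at (highest footprint node − depth);
        # a node is engaged once the plane reaches it and is displaced by the
        # geometric overlap, so the curved surface flattens under the indenter
        z0 = mesh.node_coords[foot, 2]
        overlap = float(cumulative_depth) - (z0.max() - z0)
        engaged = foot[overlap > 0]
        mask[engaged, 2] = True
        vals[engaged, 2] = -overlap[overlap > 0]
    else:
        mask[foot, 2] = True
        vals[foot, 2] = -float(cumulative_depth)
    return mask, vals


def isolated_protocol(mesh: HexMesh, increments=(10.0,), diameter=250.0,
                      center=(0.0, 0.0)) -> IndentationProtocol:
    """Standard isolated-corpuscle protocol: cylindrical indenter on the top
    pole, base on vertical rollers with a pin against rigid translation and
    in-plane rotation (the base must stay free to strain along the long
    axis)."""
    c = mesh.node_coords
    base = mesh.node_sets["base"]
    pin = base[int(np.argmin((c[base, :2] ** 2).sum(axis=1)))]
    anti = mesh.node_sets["long_axis_pair"][1]
    return IndentationProtocol(
        kind="cylinder", diameter=diameter, center=center,
        increments=tuple(increments),
        fixed={"base": "z"},
        extra_fixed=((int(pin), 0), (int(pin), 1), (int(anti), 0)),
    )


def embedded_protocol(mesh: HexMesh, site=(0.0, 0.0), increments=(10.0,),
                      kind="node", diameter=250.0,
                      sides: str = "free") -> IndentationProtocol:
    """Embedded-skin protocol: single-node (or cylinder) surface indentation,
    base clamped, lateral faces free by default.

    Free lateral faces let the skin column bulge so indentation stretches a
    horizontal corpuscle along its long axis (positive neurite strain);
    roller walls (``sides='normal'``) confine the column and reverse that
    sign, so they are offered only as an option.
    """
    fixed = {"base": "clamp"}
    if sides == "normal":
        fixed["sides"] = "normal"
    elif sides != "free":
        raise ValueError("sides must be 'free' or 'normal'")
    return IndentationProtocol(
        kind=kind, diameter=diameter, center=tuple(site),
        increments=tuple(increments), fixed=fixed,
    )


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

@dataclass
class PackedLibrary:
    """Flat-array form of an RveLibrary consumed by the assembly kernels."""

    net_ref: np.ndarray
    node_off: np.ndarray
    fib: np.ndarray
    fib_off: np.ndarray
    L0: np.ndarray
    bnd: np.ndarray
    intn: np.ndarray
    int_off: np.ndarray
    xcur: np.ndarray     # mutable per-GP current coordinates (warm starts)

    def copy_state(self) -> np.ndarray:
        return self.xcur.copy()


def pack_library(lib: RveLibrary) -> PackedLibrary:
    nets = lib.networks
    node_off = np.zeros(len(nets) + 1, dtype=np.int64)
    fib_off = np.zeros(len(nets) + 1, dtype=np.int64)
    int_off = np.zeros(len(nets) + 1, dtype=np.int64)
    for g, net in enumerate(nets):
        node_off[g + 1] = node_off[g] + net.n_nodes
        fib_off[g + 1] = fib_off[g] + net.n_fibers
        int_off[g + 1] = int_off[g] + int(np.sum(~net.boundary_mask))
    net_ref = np.zeros((node_off[-1], 3))
    fib = np.zeros((fib_off[-1], 2), dtype=np.int32)
    L0 = np.zeros(fib_off[-1])
    bnd = np.zeros(node_off[-1], dtype=bool)
    intn = np.zeros(int_off[-1], dtype=np.int64)
    for g, net in enumerate(nets):
        net_ref[node_off[g]:node_off[g + 1]] = net.node_coords
        fib[fib_off[g]:fib_off[g + 1]] = net.fibers
        L0[fib_off[g]:fib_off[g + 1]] = net.rest_lengths
        bnd[node_off[g]:node_off[g + 1]] = net.boundary_mask
        intn[int_off[g]:int_off[g + 1]] = np.flatnonzero(~net.boundary_mask)
    return PackedLibrary(net_ref, node_off, fib, fib_off, L0, bnd,
                         intn, int_off, net_ref.copy())


# ---------------------------------------------------------------------------
# assembly and Newton solve
# ---------------------------------------------------------------------------

@dataclass
class MacroState:
    """Converged macroscale state at one cumulative indentation depth."""

    u: np.ndarray                  # (nn, 3) nodal displacements, μm
    F_gp: np.ndarray               # (ne, 8, 3, 3) deformation gradients
    S_gp: np.ndarray               # (ne, 8, 3, 3) homogenized Cauchy stress, kPa
    depth: float                   # cumulative indentation depth, μm
    residual_history: list
    reactions: np.ndarray          # internal forces at prescribed dofs, μN
    rve_coords: np.ndarray | None = None  # packed equilibrated RVE coordinates


def _assemble(mesh, u, packed, params, tol, max_iter, fd_step, need_tangent):
    from .rve import fiber_energy_table

    phi, dlam = fiber_energy_table(params)
    return _kernels.assemble_system(
        np.ascontiguousarray(mesh.node_coords, dtype=float),
        np.ascontiguousarray(mesh.elements, dtype=np.int64),
        np.ascontiguousarray(u, dtype=float),
        packed.net_ref, packed.node_off, packed.fib, packed.fib_off,
        packed.L0, packed.bnd, packed.intn, packed.int_off, packed.xcur,
        params.A, params.B, params.G, params.bulk_modulus,
        tol, max_iter, fd_step, need_tangent,
        phi, dlam,
    )


def assemble_residual(mesh: HexMesh, u: np.ndarray, packed: PackedLibrary,
                      params: MaterialParams,
                      rve_tol: float | None = None) -> np.ndarray:
    """Internal nodal force vector (μN) at displacements ``u``.

    Zero on the stress-free reference state; at equilibrium the entries at
    free dofs vanish and the prescribed-dof entries are the reactions.
    """
    if rve_tol is None:
        rve_tol = 1e-8 * params.A
    fint, _, _, _, status = _assemble(mesh, u, packed, params, rve_tol,
                                      200, FD_STEP, False)
    _raise_on_status(status)
    return fint


def _raise_on_status(status):
    bad = np.argwhere(status > 0)
    if len(bad):
        e, g = map(int, bad[0])
        code = int(status[e, g])
        if code == 3:
            raise ValueError(f"non-positive Jacobian in element {e}")
        raise RveFailure(e, g, code)


def _dof_pattern(mesh: HexMesh):
    elems = mesh.elements
    dof = (3 * elems[:, :, None] + np.arange(3)).reshape(len(elems), 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    return rows, cols


def _newton_increment(mesh, u, mask, vals, packed, params, tol_rel, tol_abs,
                      max_iter, rve_tol, fd_step, rows, cols):
    """Newton iteration on the free dofs at fixed Dirichlet data.

    Mutates ``u`` (and the packed RVE warm-start state); returns
    (fint, Sgp, Fgp, history, converged).
    """
    nn = mesh.n_nodes
    flat_mask = mask.ravel()
    free = ~flat_mask
    u[mask] = vals[mask]
    history: list[float] = []
    fint = Sgp = Fgp = None
    for _it in range(max_iter):
        fint, Ke, Sgp, Fgp, status = _assemble(
            mesh, u, packed, params, rve_tol, 200, fd_step, True)
        _raise_on_status(status)
        r = fint.ravel()
        rnorm = float(np.abs(r[free]).max()) if free.any() else 0.0
        reaction = float(np.abs(r[flat_mask]).max()) if flat_mask.any() else 0.0
        history.append(rnorm)
        tol = max(tol_abs, tol_rel * reaction)
        if rnorm < tol:
            return fint, Sgp, Fgp, history, True
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(3 * nn, 3 * nn)).tocsr()
        freeidx = np.flatnonzero(free)
        Kff = K[freeidx][:, freeidx]
        du = spla.spsolve(Kff.tocsc(), -r[freeidx])
        if not np.all(np.isfinite(du)):
            return fint, Sgp, Fgp, history, False
        alpha = 1.0
        accepted = False
        for _ls in range(7):
            u_try = u.copy()
            u_try.ravel()[freeidx] += alpha * du
            try:
                ft, _, _, _, st = _assemble(mesh, u_try, packed, params,
                                            rve_tol, 200, fd_step, False)
                rt = np.inf if np.any(st > 0) \
                    else float(np.abs(ft.ravel()[free]).max())
            except Exception:  # pragma: no cover
                rt = np.inf
            if rt < rnorm or rt < tol:
                u[:] = u_try
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # accept the smallest step anyway; Newton on the homogenized
            # response is not strictly monotone with warm-started RVEs
            u.ravel()[freeidx] += alpha * du
    return fint, Sgp, Fgp, history, False


def solve_dirichlet(
    mesh: HexMesh,
    mask: np.ndarray,
    vals: np.ndarray,
    rve_library: RveLibrary | PackedLibrary,
    params: MaterialParams,
    tol_rel: float = MACRO_TOL_REL,
    tol_abs: float = MACRO_TOL_ABS,
    max_iter: int = MACRO_MAX_ITER,
    rve_tol: float | None = None,
    fd_step: float = FD_STEP,
    u0: np.ndarray | None = None,
) -> MacroState:
    """Equilibrate the mesh under arbitrary prescribed displacements.

    ``mask``/``vals`` are (n, 3) prescribed-dof flags and values (μm). Used
    directly for patch tests and affine-loading verification; indentation
    protocols go through :func:`newton_solve`.
    """
    packed = rve_library if isinstance(rve_library, PackedLibrary) \
        else pack_library(rve_library)
    if rve_tol is None:
        rve_tol = 1e-8 * params.A
    rows, cols = _dof_pattern(mesh)
    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else np.array(u0)
    fint, Sgp, Fgp, history, ok = _newton_increment(
        mesh, u, mask, vals, packed, params, tol_rel, tol_abs, max_iter,
        rve_tol, fd_step, rows, cols)
    if not ok:
        raise MacroNonConvergence(0, history)
    return MacroState(u=u, F_gp=Fgp, S_gp=Sgp, depth=0.0,
                      residual_history=history,
                      reactions=np.where(mask, fint, 0.0))


def newton_solve(
    mesh: HexMesh,
    protocol: IndentationProtocol,
    rve_library: RveLibrary | PackedLibrary,
    params: MaterialParams,
    tol_rel: float = MACRO_TOL_REL,
    tol_abs: float = MACRO_TOL_ABS,
    max_iter: int = MACRO_MAX_ITER,
    rve_tol: float | None = None,
    fd_step: float = FD_STEP,
    store_rve_coords: bool = False,
    eq4_correction: bool = False,
) -> list[MacroState]:
    """Solve the indentation protocol increment by increment.

    For each cumulative depth the free nodal displacements are iterated until
    the residual ∞-norm falls below max(tol_abs, tol_rel × reaction ∞-norm).
    Deterministic for a fixed mesh, network library and settings. Raises
    MacroNonConvergence (with the residual history) if an increment fails.
    """
    packed = rve_library if isinstance(rve_library, PackedLibrary) \
        else pack_library(rve_library)
    if rve_tol is None:
        rve_tol = 1e-8 * params.A
    nn = mesh.n_nodes
    u = np.zeros((nn, 3))
    rows, cols = _dof_pattern(mesh)

    states: list[MacroState] = []
    du_prev = None
    prev_inc = None
    for inc_idx, depth in enumerate(protocol.depths):
        mask, vals = apply_indenter(mesh, protocol, depth)
        free = ~mask.ravel()
        inc = depth - (protocol.depths[inc_idx - 1] if inc_idx else 0.0)
        if du_prev is not None and prev_inc and inc > 0:
            u.ravel()[free] += (inc / prev_inc) * du_prev[free]
        u_start = u.copy()
        fint, Sgp, Fgp, history, converged = _newton_increment(
            mesh, u, mask, vals, packed, params, tol_rel, tol_abs, max_iter,
            rve_tol, fd_step, rows, cols)
        if not converged:
            raise MacroNonConvergence(inc_idx, history)
        if eq4_correction:
            mag = eq4_correction_magnitude(packed, Fgp, Sgp, params)
            logger.info("increment %d: averaged-stress balance surface-term "
                        "magnitude %.3g kPa/μm (max over GPs)", inc_idx, mag)
        logger.info("increment %d (depth %.3g μm): %d iterations, "
                    "residual %.3g μN", inc_idx, depth, len(history), history[-1])
        states.append(MacroState(
            u=u.copy(), F_gp=Fgp, S_gp=Sgp, depth=float(depth),
            residual_history=history,
            reactions=np.where(mask, fint, 0.0),
            rve_coords=packed.copy_state() if store_rve_coords else None,
        ))
        du_prev = (u - u_start).ravel()
        prev_inc = inc if inc > 0 else prev_inc
    return states


def shape_gradients(mesh: HexMesh, element: int, gauss_index: int):
    """Physical trilinear shape-function gradients at one Gauss point.

    Returns (dN/dX (8×3), det J). Gauss index bits select the 2×2×2 point
    (ξ = bit0, η = bit1, ζ = bit2, 0 → −1/√3). Raises on a non-positive
    Jacobian, naming the element.
    """
    if not 0 <= gauss_index < 8:
        raise ValueError("gauss_index must be in 0..7")
    Xe = np.ascontiguousarray(mesh.node_coords[mesh.elements[element]],
                              dtype=float)
    dNx, detJ = _kernels.element_gradients(Xe, gauss_index)
    if detJ <= 0:
        raise ValueError(f"non-positive Jacobian in element {element}")
    return dNx, float(detJ)


# ---------------------------------------------------------------------------
# averaged-stress-balance surface term (diagnostic estimator)
# ---------------------------------------------------------------------------

def eq4_correction_magnitude(packed: PackedLibrary, Fgp, Sgp,
                             params: MaterialParams | None = None) -> float:
    """Coarse estimate of the micro–macro stress-fluctuation surface term.

    The averaged stress balance carries a right-hand side integrating
    (S_micro − S_macro) u_k,i n_k over the RVE boundary; with affine boundary
    displacements u_k,i is spatially constant, and the micro stress at a
    boundary cross-link is attributed through its reaction–position dyad with
    an equal area share per node. Returns the max over Gauss points of the
    estimator's ∞-norm (kPa per unit RVE length); diagnostic/logging only.
    """
    from .materials import DEFAULT_PARAMS
    params = params or DEFAULT_PARAMS
    ne, ng = Fgp.shape[:2]
    worst = 0.0
    for e in range(ne):
        for g in range(ng):
            gp = 8 * e + g
            n0, n1 = packed.node_off[gp], packed.node_off[gp + 1]
            if n1 == n0:
                continue
            x = packed.xcur[n0:n1]
            ref = packed.net_ref[n0:n1]
            b = packed.bnd[n0:n1]
            if not b.any():
                continue
            F = Fgp[e, g]
            S = Sgp[e, g]
            grad = F - np.eye(3)
            reac = -_node_forces(packed, gp, params)
            V = max(np.linalg.det(F), 1e-12)
            bidx = np.flatnonzero(b)
            w = 1.0 / len(bidx)
            c = np.zeros(3)
            for node in bidx:
                p = ref[node]
                ax = int(np.argmin(np.minimum(p, 1 - p)))
                nrm = np.zeros(3)
                nrm[ax] = -1.0 if p[ax] < 0.5 else 1.0
                ds = np.outer(x[node], reac[node]) / V - w * S
                c += ds.T @ (grad.T @ nrm)
            worst = max(worst, float(np.abs(c).max()))
    return worst


def _node_forces(packed: PackedLibrary, gp: int, params: MaterialParams):
    """Sum of fiber forces acting on every node of one RVE (μN)."""
    n0, n1 = packed.node_off[gp], packed.node_off[gp + 1]
    f0, f1 = packed.fib_off[gp], packed.fib_off[gp + 1]
    x = packed.xcur[n0:n1]
    fib = packed.fib[f0:f1]
    L0 = packed.L0[f0:f1]
    ftot = np.zeros((n1 - n0, 3))
    if len(fib) == 0:
        return ftot
    v = x[fib[:, 1]] - x[fib[:, 0]]
    l = np.linalg.norm(v, axis=1)
    ok = l > 1e-14
    lam = np.where(ok, l / L0, 1.0)
    arg = np.minimum(params.B * 0.5 * (lam ** 2 - 1.0), 60.0)
    fr = (params.A / params.B) * (np.exp(arg) - 1.0)
    coef = np.where(ok, fr / np.where(ok, l, 1.0), 0.0)
    contrib = coef[:, None] * v
    np.add.at(ftot, fib[:, 0], contrib)
    np.add.at(ftot, fib[:, 1], -contrib)
    return ftot
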