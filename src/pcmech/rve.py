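"""RVE micromechanics: fiber law, network equilibrium, homogenized stress.

The constitutive response at each macroscale Gauss point is a constrained
mixture: a Delaunay fiber network equilibrated under affine boundary
displacements, plus a compressible neo-Hookean matrix, both phases seeing
the same macroscopic deformation gradient F. The network contribution is
the volume-averaged Cauchy stress recovered from boundary cross-link
reactions; the total stress is the additive superposition of the two.

Forces are in μN, stresses in kPa (see ``pcmech.materials`` for the unit
bridge), RVE geometry is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .materials import MaterialParams
from .network import FiberNetwork

#: default interior-equilibrium force tolerance, as a fraction of A
RVE_TOL_FRACTION = 1e-8
RVE_MAX_ITER = 200
#: finite-difference step on deformation-gradient components
FD_STEP = 1e-5


@dataclass
class RveState:
    """Equilibrated state of one RVE under a macroscopic deformation."""

    network: FiberNetwork          # deformed copy (node_coords = current)
    macro_F: np.ndarray            # (3,3) deformation gradient
    fiber_stretches: np.ndarray    # λ_f per fiber
    fiber_forces: np.ndarray       # axial force per fiber (μN)
    avg_stress: np.ndarray         # (3,3) volume-averaged network Cauchy stress
    rve_volume: float              # current volume = det(F) × 1

    def residual_norm(self, params: MaterialParams) -> float:
        """Max interior nodal force imbalance (independent re-evaluation)."""
        net = self.network
        imap = np.full(net.n_nodes, -1, dtype=np.int64)
        interior = np.flatnonzero(~net.boundary_mask)
        imap[interior] = np.arange(len(interior))
        R = np.zeros(3 * len(interior))
        rmax, _ = _kernels._residual(
            np.ascontiguousarray(net.node_coords),
            np.ascontiguousarray(net.fibers.astype(np.int32)),
            np.ascontiguousarray(net.rest_lengths),
            imap, params.A, params.B, R,
        )
        return float(rmax) if len(interior) else 0.0


class RveDivergenceError(RuntimeError):
    """Raised when a fiber force overflows or the RVE Newton fails."""

    def __init__(self, msg, residual=None, fiber=None):
        super().__init__(msg)
        self.residual = residual
        self.fiber = fiber


# ---------------------------------------------------------------------------
# fiber law
# ---------------------------------------------------------------------------

def fiber_green_strain(lambda_f):
    """Green strain of a fiber, E_f = ½(λ_f² − 1)."""
    lam = np.asarray(lambda_f, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be positive")
    return 0.5 * (lam * lam - 1.0)


def fiber_force(E_f, params: MaterialParams):
    """Exponential fiber law F = (A/B)(exp(B·E_f) − 1), μN.

    Strictly increasing in E_f with slope A at E_f = 0. Arguments large
    enough to overflow (B·E_f > 700) signal divergence, naming the first
    offending fiber index.
    """
    E = np.asarray(E_f, dtype=float)
    arg = params.B * E
    over = arg > 700.0
    if np.any(over):
        fid = int(np.argmax(over)) if E.ndim else None
        raise RveDivergenceError(
            f"fiber force overflow (B·E_f = {float(np.max(arg)):.3g})",
            fiber=fid,
        )
    return (params.A / params.B) * (np.exp(arg) - 1.0)


# ---------------------------------------------------------------------------
# boundary conditions and equilibrium
# ---------------------------------------------------------------------------

def apply_affine_boundary(net: FiberNetwork, macro_F: np.ndarray) -> np.ndarray:
    """Displacements placing every boundary node at F·X_ref.

    Returns an (n_nodes, 3) array that is (F − I)·X on boundary rows and NaN
    on interior rows (interior nodes are unconstrained).
    """
    F = np.asarray(macro_F, dtype=float)
    if F.shape != (3, 3) or np.linalg.det(F) <= 0:
        raise ValueError("macro_F must be an invertible, orientation-preserving 3×3")
    disp = np.full((net.n_nodes, 3), np.nan)
    b = net.boundary_mask
    disp[b] = net.node_coords[b] @ (F - np.eye(3)).T
    return disp


_PHI_CACHE: dict = {}


def fiber_energy_table(params: MaterialParams, lam_max: float = 3.8,
                       n: int = 4096):
    """Tabulated antiderivative Φ(λ) of the dimensionless fiber force.

    The exponential fiber law has no elementary strain-energy antiderivative
    (it is an erfi-type integral), so the solver's energy line search uses a
    dense trapezoid table of Φ(λ) = ∫₁^λ (e^{B(s²−1)/2} − 1) ds with Φ(1)=0.
    Returns (phi_table, dλ); cached per B.
    """
    key = (round(float(params.B), 12), float(lam_max), int(n))
    if key not in _PHI_CACHE:
        from scipy.integrate import cumulative_trapezoid

        s = np.linspace(0.0, lam_max, n)
        f = np.exp(np.minimum(params.B * 0.5 * (s ** 2 - 1.0), 700.0)) - 1.0
        phi = cumulative_trapezoid(f, s, initial=0.0)
        phi = phi - np.interp(1.0, s, phi)
        _PHI_CACHE[key] = (np.ascontiguousarray(phi), float(s[1] - s[0]))
    return _PHI_CACHE[key]


def _packed(net: FiberNetwork):
    ref = np.ascontiguousarray(net.node_coords, dtype=float)
    fib = np.ascontiguousarray(net.fibers, dtype=np.int32)
    L0 = np.ascontiguousarray(net.rest_lengths, dtype=float)
    bnd = np.ascontiguousarray(net.boundary_mask)
    intn = np.flatnonzero(~net.boundary_mask).astype(np.int64)
    return ref, fib, L0, bnd, intn


def solve_rve_equilibrium(
    net: FiberNetwork,
    boundary_disp: np.ndarray | None,
    params: MaterialParams,
    tol: float | None = None,
    macro_F: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    max_iter: int = RVE_MAX_ITER,
) -> RveState:
    """Equilibrate interior cross-links under prescribed boundary positions.

    Either ``boundary_disp`` (displacements of boundary rows, interior rows
    ignored) or the affine ``macro_F`` must be given. The interior force
    residual is driven below ``tol`` (default 1e-8·A μN) by a damped Newton
    iteration; failure raises RveDivergenceError carrying the last residual.
    """
    if tol is None:
        tol = RVE_TOL_FRACTION * params.A
    ref, fib, L0, bnd, intn = _packed(net)
    x = ref.copy() if x0 is None else np.array(x0, dtype=float)
    if macro_F is not None:
        F = np.asarray(macro_F, dtype=float)
        if np.linalg.det(F) <= 0:
            raise ValueError("non-invertible macro_F")
        _kernels.set_affine_boundary(x, ref, bnd, F)
        if x0 is None:  # affine predictor for interior nodes
            x[~bnd] = ref[~bnd] @ F.T
    else:
        if boundary_disp is None:
            raise ValueError("need boundary_disp or macro_F")
        bd = np.asarray(boundary_disp, dtype=float)
        x[bnd] = ref[bnd] + bd[bnd]
        F = np.eye(3)
    phi, dlam = fiber_energy_table(params)
    st = _kernels.solve_given_boundary(x, fib, L0, intn, params.A, params.B,
                                       tol, max_iter, phi, dlam)
    lam, frc = _kernels.fiber_kinematics(x, fib, L0, params.A, params.B)
    vol = float(np.linalg.det(F)) if macro_F is not None else 1.0
    deformed = FiberNetwork(x, net.fibers.copy(), net.rest_lengths.copy(),
                            net.boundary_mask.copy(), seed=net.seed)
    state = RveState(deformed, np.asarray(F, dtype=float), lam, frc,
                     np.zeros((3, 3)), vol)
    if st == 1:
        raise RveDivergenceError(
            f"RVE Newton did not converge in {max_iter} iterations",
            residual=state.residual_norm(params),
        )
    if st == 2:
        worst = int(np.argmax(lam))
        raise RveDivergenceError(
            f"fiber force overflow during equilibrium (fiber {worst}, "
            f"λ = {lam[worst]:.3g})", fiber=worst,
        )
    state.avg_stress = volume_avg_stress(state, params)
    return state


def volume_avg_stress(state: RveState, params: MaterialParams) -> np.ndarray:
    """Eq-style boundary sum S_ij = (1/V) Σ_bc x_i r_j over face cross-links.

    x is the current boundary-node coordinate and r the reaction transmitted
    to the face (minus the sum of fiber forces on the node).
    """
    if state.rve_volume <= 0:
        raise ValueError("non-positive RVE volume")
    net = state.network
    return _kernels.network_stress(
        np.ascontiguousarray(net.node_coords),
        np.ascontiguousarray(net.fibers.astype(np.int32)),
        np.ascontiguousarray(net.rest_lengths),
        np.ascontiguousarray(net.boundary_mask),
        params.A, params.B, state.rve_volume,
    )


def matrix_stress(macro_F: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Compressible neo-Hookean matrix Cauchy stress (kPa).

    W = G/2 (I₁ − 3 − 2 ln J) + K/2 (ln J)² with K from (G, ν); stress is
    zero at F = I and σ12 ≈ Gγ in small simple shear.
    """
    F = np.asarray(macro_F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("det(F) must be positive")
    sig, _ = _kernels.neo_hookean_cauchy(F, params.G, params.bulk_modulus)
    return sig


_VOIGT = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def rve_total_stress(
    net: FiberNetwork,
    macro_F: np.ndarray,
    params: MaterialParams,
    tol: float | None = None,
    fd_step: float = FD_STEP,
    tangent: bool = True,
):
    """Total (network + matrix) Cauchy stress and small-strain tangent.

    Returns ``(S, C)`` where S is 3×3 and C the 6×6 central-finite-difference
    derivative dσ/dε in Voigt order (xx, yy, zz, yz, xz, xy; tensor shear
    components), each perturbation re-equilibrating the network from the
    converged interior coordinates. With ``tangent=False`` C is None.
    """
    if tol is None:
        tol = RVE_TOL_FRACTION * params.A
    F = np.asarray(macro_F, dtype=float)

    def total(Fv, x0=None):
        if net.n_fibers == 0:
            return matrix_stress(Fv, params), None
        st = solve_rve_equilibrium(net, None, params, tol=tol, macro_F=Fv, x0=x0)
        return st.avg_stress + matrix_stress(Fv, params), st.network.node_coords

    S, xeq = total(F)
    if not tangent:
        return S, None
    C = np.zeros((6, 6))
    for col, (k, l) in enumerate(_VOIGT):
        D = np.zeros((3, 3))
        D[k, l] = D[l, k] = 1.0
        Fp = (np.eye(3) + fd_step * D) @ F
        Fm = (np.eye(3) - fd_step * D) @ F
        Sp, _ = total(Fp, x0=xeq)
        Sm, _ = total(Fm, x0=xeq)
        dS = (Sp - Sm) / (2.0 * fd_step)
        C[:, col] = [dS[i, j] for (i, j) in _VOIGT]
    return S, C
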