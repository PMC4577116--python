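"""Numba kernels: RVE equilibrium, homogenized stress, element assembly.

All heavy numerics live here as nopython-compiled functions operating on
packed flat arrays (one slice per Gauss-point network). The public modules
``pcmech.rve`` and ``pcmech.fem`` wrap these with validated, documented APIs.

Status codes returned by the solvers:
    0  converged
    1  Newton did not converge within max_iter
    2  fiber-force exponent clamped at the accepted state (divergence)
    3  non-positive element Jacobian
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ARG_CLAMP = 60.0  # exp() argument guard for B*E_f


@njit(cache=True)
def _residual(x, fib, L0, imap, A, B, R):
    """Interior nodal force residual; returns (max|R|, clamp_hit)."""
    R[:] = 0.0
    clamped = False
    for f in range(fib.shape[0]):
        p = fib[f, 0]
        q = fib[f, 1]
        vx = x[q, 0] - x[p, 0]
        vy = x[q, 1] - x[p, 1]
        vz = x[q, 2] - x[p, 2]
        l = np.sqrt(vx * vx + vy * vy + vz * vz)
        if l < 1e-14:
            continue
        lam = l / L0[f]
        arg = B * 0.5 * (lam * lam - 1.0)
        if arg > _ARG_CLAMP:
            arg = _ARG_CLAMP
            clamped = True
        fr = (A / B) * (np.exp(arg) - 1.0)
        c = fr / l
        ip = imap[p]
        iq = imap[q]
        if ip >= 0:
            R[3 * ip] += c * vx
            R[3 * ip + 1] += c * vy
            R[3 * ip + 2] += c * vz
        if iq >= 0:
            R[3 * iq] -= c * vx
            R[3 * iq + 1] -= c * vy
            R[3 * iq + 2] -= c * vz
    rmax = 0.0
    for k in range(R.shape[0]):
        a = abs(R[k])
        if a > rmax:
            rmax = a
    return rmax, clamped


@njit(cache=True)
def _residual_stiffness(x, fib, L0, imap, A, B, R, K):
    """Residual plus interior tangent stiffness K = -dR/dx (SPD near stable
    equilibria). Returns (max|R|, clamp_hit)."""
    R[:] = 0.0
    K[:, :] = 0.0
    clamped = False
    for f in range(fib.shape[0]):
        p = fib[f, 0]
        q = fib[f, 1]
        vx = x[q, 0] - x[p, 0]
        vy = x[q, 1] - x[p, 1]
        vz = x[q, 2] - x[p, 2]
        l = np.sqrt(vx * vx + vy * vy + vz * vz)
        if l < 1e-14:
            continue
        lam = l / L0[f]
        arg = B * 0.5 * (lam * lam - 1.0)
        if arg > _ARG_CLAMP:
            arg = _ARG_CLAMP
            clamped = True
        ex = np.exp(arg)
        fr = (A / B) * (ex - 1.0)
        fp = A * lam * ex  # dF/dλ
        ux = vx / l
        uy = vy / l
        uz = vz / l
        c1 = fp / L0[f] - fr / l
        c2 = fr / l
        ip = imap[p]
        iq = imap[q]
        cf = fr / l
        if ip >= 0:
            R[3 * ip] += cf * vx
            R[3 * ip + 1] += cf * vy
            R[3 * ip + 2] += cf * vz
        if iq >= 0:
            R[3 * iq] -= cf * vx
            R[3 * iq + 1] -= cf * vy
            R[3 * iq + 2] -= cf * vz
        u = (ux, uy, uz)
        for a in range(3):
            for b in range(3):
                kab = c1 * u[a] * u[b]
                if a == b:
                    kab += c2
                # stiffness contribution (K = -dR/dx): truss element pattern
                if ip >= 0:
                    K[3 * ip + a, 3 * ip + b] += kab
                if iq >= 0:
                    K[3 * iq + a, 3 * iq + b] += kab
                if ip >= 0 and iq >= 0:
                    K[3 * ip + a, 3 * iq + b] -= kab
                    K[3 * iq + a, 3 * ip + b] -= kab
    rmax = 0.0
    for k in range(R.shape[0]):
        a = abs(R[k])
        if a > rmax:
            rmax = a
    return rmax, clamped


@njit(cache=True)
def _energy(x, fib, L0, A, B, phi, dlam):
    """Total fiber strain energy via the tabulated antiderivative Φ(λ).

    Energy per fiber is (A/B)·L0·Φ(λ) with Φ(1) = 0 and Φ ≥ 0; beyond the
    table the energy is continued linearly with the end slope (steeply
    increasing), which is enough to reject absurd line-search trials.
    """
    n_tab = phi.shape[0]
    lam_max = dlam * (n_tab - 1)
    E = 0.0
    for f in range(fib.shape[0]):
        p = fib[f, 0]
        q = fib[f, 1]
        vx = x[q, 0] - x[p, 0]
        vy = x[q, 1] - x[p, 1]
        vz = x[q, 2] - x[p, 2]
        lam = np.sqrt(vx * vx + vy * vy + vz * vz) / L0[f]
        if lam >= lam_max:
            slope = (phi[n_tab - 1] - phi[n_tab - 2]) / dlam
            w = phi[n_tab - 1] + slope * (lam - lam_max)
        else:
            t = lam / dlam
            i = int(t)
            w = phi[i] + (t - i) * (phi[i + 1] - phi[i])
        E += (A / B) * L0[f] * w
    return E


@njit(cache=True)
def solve_given_boundary(x, fib, L0, intn, A, B, tol, max_iter, phi, dlam):
    """Equilibrate interior nodes by damped-Newton energy minimization.

    The interior problem is the minimization of the network strain energy
    (its gradient is minus the nodal force residual), so a descent method
    with a positive-definite-shifted Hessian always converges to a true
    equilibrium and cannot be trapped at non-root minima of ‖R‖². ``x``
    carries current coordinates (boundary rows already prescribed) and is
    updated in place. Returns a status code.
    """
    ni = intn.shape[0]
    if ni == 0:
        return 0
    nn = x.shape[0]
    imap = np.full(nn, -1, dtype=np.int64)
    for k in range(ni):
        imap[intn[k]] = k
    ndof = 3 * ni
    R = np.empty(ndof)
    Rt = np.empty(ndof)
    K = np.empty((ndof, ndof))
    xt = x.copy()
    mu = 0.0
    dmax = 0.1  # trust cap on the ∞-norm of one Newton step (cube units)
    rnorm, clamped = _residual_stiffness(x, fib, L0, imap, A, B, R, K)
    E0 = _energy(x, fib, L0, A, B, phi, dlam)
    for _ in range(max_iter):
        if rnorm < tol:
            return 2 if clamped else 0
        m0 = 0.0
        for k in range(ndof):
            m0 += R[k] * R[k]
        # ridge keeps the (possibly indefinite) Hessian solve descent-capable;
        # a floor scaled to the diagonal avoids exact singularity (numba's
        # solve raises instead of returning inf)
        tr = 0.0
        for k in range(ndof):
            tr += abs(K[k, k])
        floor = 1e-12 * (tr / ndof + A)
        for k in range(ndof):
            K[k, k] += mu + floor
        dx = np.linalg.solve(K, R)
        bad = False
        dinf = 0.0
        rd = 0.0  # Rᵀd = −∇E·d; must be positive for a descent direction
        for k in range(ndof):
            if not np.isfinite(dx[k]):
                bad = True
                break
            rd += R[k] * dx[k]
            a = abs(dx[k])
            if a > dinf:
                dinf = a
        if bad or rd <= 0.0:
            mu = max(mu * 10.0, 1e-6 * A)
            rnorm, clamped = _residual_stiffness(x, fib, L0, imap, A, B, R, K)
            continue
        # floppy (compressed) modes produce steps far outside the quadratic
        # model's validity; cap the step length before backtracking
        alpha = 1.0 if dinf <= dmax else dmax / dinf
        accepted = False
        for _ls in range(25):
            for k in range(ni):
                i = intn[k]
                xt[i, 0] = x[i, 0] + alpha * dx[3 * k]
                xt[i, 1] = x[i, 1] + alpha * dx[3 * k + 1]
                xt[i, 2] = x[i, 2] + alpha * dx[3 * k + 2]
            # energy (Armijo) acceptance drives the global phase; near the
            # minimum the tabulated energy flattens into interpolation noise,
            # so a plain residual-norm decrease also accepts (Newton phase)
            Et = _energy(xt, fib, L0, A, B, phi, dlam)
            ok = Et <= E0 - 1e-4 * alpha * rd
            if not ok:
                _rn, _cl = _residual(xt, fib, L0, imap, A, B, Rt)
                mt = 0.0
                for k in range(ndof):
                    mt += Rt[k] * Rt[k]
                ok = mt < m0 * (1.0 - 1e-4 * alpha)
            if ok:
                for k in range(ni):
                    i = intn[k]
                    x[i, 0] = xt[i, 0]
                    x[i, 1] = xt[i, 1]
                    x[i, 2] = xt[i, 2]
                E0 = Et
                accepted = True
                mu *= 0.25
                if alpha == 1.0:
                    dmax = min(2.0 * dmax, 0.25)
                break
            alpha *= 0.5
        if not accepted:
            mu = max(mu * 10.0, 1e-6 * A)
            dmax = max(0.5 * dmax, 1e-4)
        rnorm, clamped = _residual_stiffness(x, fib, L0, imap, A, B, R, K)
    return 2 if clamped else 1


@njit(cache=True)
def _pick_start(x, ref, fib, L0, intn, F, A, B, phi, dlam):
    """Overwrite interior coordinates with the affine map F·X_ref when that
    start has a lower strain energy than the warm-started coordinates."""
    ni = intn.shape[0]
    if ni == 0:
        return
    e_warm = _energy(x, fib, L0, A, B, phi, dlam)
    xa = x.copy()
    for k in range(ni):
        i = intn[k]
        for a in range(3):
            xa[i, a] = (F[a, 0] * ref[i, 0] + F[a, 1] * ref[i, 1]
                        + F[a, 2] * ref[i, 2])
    e_aff = _energy(xa, fib, L0, A, B, phi, dlam)
    if e_aff < e_warm:
        for k in range(ni):
            i = intn[k]
            for a in range(3):
                x[i, a] = xa[i, a]


@njit(cache=True)
def set_affine_boundary(x, ref, bnd, F):
    """Place boundary nodes at F·X_ref (interior rows untouched)."""
    for i in range(ref.shape[0]):
        if bnd[i]:
            for a in range(3):
                x[i, a] = (F[a, 0] * ref[i, 0] + F[a, 1] * ref[i, 1]
                           + F[a, 2] * ref[i, 2])


@njit(cache=True)
def network_stress(x, fib, L0, bnd, A, B, volume):
    """Volume-averaged network Cauchy stress S = Σ_bc x ⊗ r / V.

    r is the constraint reaction at each boundary cross-link (the force the
    network transmits to the RVE face), i.e. minus the sum of fiber forces
    acting on that node; this sign makes a fiber in tension contribute
    positive normal stress.
    """
    nn = x.shape[0]
    fnode = np.zeros((nn, 3))
    for f in range(fib.shape[0]):
        p = fib[f, 0]
        q = fib[f, 1]
        vx = x[q, 0] - x[p, 0]
        vy = x[q, 1] - x[p, 1]
        vz = x[q, 2] - x[p, 2]
        l = np.sqrt(vx * vx + vy * vy + vz * vz)
        if l < 1e-14:
            continue
        lam = l / L0[f]
        arg = B * 0.5 * (lam * lam - 1.0)
        if arg > _ARG_CLAMP:
            arg = _ARG_CLAMP
        fr = (A / B) * (np.exp(arg) - 1.0)
        c = fr / l
        fnode[p, 0] += c * vx
        fnode[p, 1] += c * vy
        fnode[p, 2] += c * vz
        fnode[q, 0] -= c * vx
        fnode[q, 1] -= c * vy
        fnode[q, 2] -= c * vz
    S = np.zeros((3, 3))
    for i in range(nn):
        if bnd[i]:
            for a in range(3):
                for b in range(3):
                    S[a, b] += x[i, a] * (-fnode[i, b])
    return S / volume


@njit(cache=True)
def fiber_kinematics(x, fib, L0, A, B):
    """Per-fiber stretches and axial forces at the current coordinates."""
    nf = fib.shape[0]
    lam = np.empty(nf)
    frc = np.empty(nf)
    for f in range(nf):
        p = fib[f, 0]
        q = fib[f, 1]
        vx = x[q, 0] - x[p, 0]
        vy = x[q, 1] - x[p, 1]
        vz = x[q, 2] - x[p, 2]
        l = np.sqrt(vx * vx + vy * vy + vz * vz)
        lam[f] = l / L0[f]
        arg = B * 0.5 * (lam[f] * lam[f] - 1.0)
        if arg > _ARG_CLAMP:
            arg = _ARG_CLAMP
        frc[f] = (A / B) * (np.exp(arg) - 1.0)
    return lam, frc


@njit(cache=True)
def neo_hookean_cauchy(F, G, K):
    """Compressible neo-Hookean Cauchy stress.

    Strain energy W = G/2 (I1 − 3 − 2 ln J) + K/2 (ln J)², giving
    σ = (G/J)(b − I) + (K ln J / J) I;  zero at F = I, σ12 → Gγ in small
    simple shear.
    """
    J = (F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
         - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
         + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]))
    b = F @ F.T
    sig = (G / J) * b
    d = (K * np.log(J) - G) / J
    for a in range(3):
        sig[a, a] += d
    return sig, J


@njit(cache=True)
def gp_total_stress(ref, fib, L0, bnd, intn, x, F, A, B, G, K,
                    tol, max_iter, phi, dlam):
    """Equilibrate the RVE at macro deformation F; total Cauchy stress.

    Returns (sigma, J, status): additive constrained-mixture stress, both
    phases seeing the same F; network stress averaged over the deformed RVE
    volume V = J (unit reference cube).
    """
    sig_m, J = neo_hookean_cauchy(F, G, K)
    if J <= 0.0:
        return sig_m, J, 3
    set_affine_boundary(x, ref, bnd, F)
    _pick_start(x, ref, fib, L0, intn, F, A, B, phi, dlam)
    st = solve_given_boundary(x, fib, L0, intn, A, B, tol, max_iter, phi, dlam)
    if st == 1:
        # merit stagnation at a fold (network snap-through): retry by load
        # continuation from the reference configuration
        for nsub in (4, 16):
            for i in range(ref.shape[0]):
                for a in range(3):
                    x[i, a] = ref[i, a]
            ok = True
            for k in range(1, nsub + 1):
                t = k / nsub
                Ft = np.empty((3, 3))
                for a in range(3):
                    for b in range(3):
                        Ft[a, b] = (1.0 - t) * (1.0 if a == b else 0.0) + t * F[a, b]
                set_affine_boundary(x, ref, bnd, Ft)
                st = solve_given_boundary(x, fib, L0, intn, A, B, tol,
                                          max_iter, phi, dlam)
                if st == 1:
                    ok = False
                    break
            if ok:
                break
    if st == 1:
        # last resort: deterministic interior kick to jump off the fold
        state = np.uint64(0x9E3779B97F4A7C15)
        for _try in range(3):
            set_affine_boundary(x, ref, bnd, F)
            for k in range(intn.shape[0]):
                i = intn[k]
                for a in range(3):
                    state = np.uint64(state * np.uint64(6364136223846793005)
                                      + np.uint64(1442695040888963407))
                    r = (np.float64(state >> np.uint64(11))
                         / 9007199254740992.0) - 0.5
                    x[i, a] += 0.02 * r
            st = solve_given_boundary(x, fib, L0, intn, A, B, tol, max_iter,
                                      phi, dlam)
            if st != 1:
                break
    S = network_stress(x, fib, L0, bnd, A, B, J)
    return S + sig_m, J, st


@njit(cache=True)
def gp_pk1(ref, fib, L0, bnd, intn, x, F, A, B, G, K, tol, max_iter,
           phi, dlam):
    """First Piola–Kirchhoff stress P = J σ F^{-T} at one Gauss point."""
    sig, J, st = gp_total_stress(ref, fib, L0, bnd, intn, x, F, A, B, G, K,
                                 tol, max_iter, phi, dlam)
    Finv = np.linalg.inv(F)
    # P = J σ F^{-T}:  P[i,Jc] = J Σ_k σ[i,k] Finv[Jc,k]
    P2 = np.empty((3, 3))
    for i in range(3):
        for Jc in range(3):
            s = 0.0
            for k in range(3):
                s += sig[i, k] * Finv[Jc, k]
            P2[i, Jc] = J * s
    return P2, sig, st


@njit(cache=True)
def gp_pk1_tangent(ref, fib, L0, bnd, intn, x, F, A, B, G, K,
                   tol, max_iter, h, phi, dlam):
    """P, σ, and the central-FD material tangent A[i,j,k,l] = dP_ij/dF_kl.

    Each perturbed evaluation re-equilibrates the RVE warm-started from the
    converged interior coordinates.
    """
    P0, sig0, st = gp_pk1(ref, fib, L0, bnd, intn, x, F, A, B, G, K,
                          tol, max_iter, phi, dlam)
    A4 = np.zeros((3, 3, 3, 3))
    Fp = np.empty((3, 3))
    for k in range(3):
        for l in range(3):
            for a in range(3):
                for bb in range(3):
                    Fp[a, bb] = F[a, bb]
            Fp[k, l] = F[k, l] + h
            xp = x.copy()
            Pp, _s1, st1 = gp_pk1(ref, fib, L0, bnd, intn, xp, Fp,
                                  A, B, G, K, tol, max_iter, phi, dlam)
            Fp[k, l] = F[k, l] - h
            xm = x.copy()
            Pm, _s2, st2 = gp_pk1(ref, fib, L0, bnd, intn, xm, Fp,
                                  A, B, G, K, tol, max_iter, phi, dlam)
            if st == 0 and (st1 != 0 or st2 != 0):
                st = max(st1, st2)
            for i in range(3):
                for j in range(3):
                    A4[i, j, k, l] = (Pp[i, j] - Pm[i, j]) / (2.0 * h)
    return P0, sig0, A4, st


# ---------------------------------------------------------------------------
# macroscale element kernels
# ---------------------------------------------------------------------------

#: reference corner coordinates of the trilinear hexahedron
_XI = np.array([
    [-1.0, -1.0, -1.0], [1.0, -1.0, -1.0], [1.0, 1.0, -1.0], [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0], [1.0, -1.0, 1.0], [1.0, 1.0, 1.0], [-1.0, 1.0, 1.0],
])

_GP = 1.0 / np.sqrt(3.0)


@njit(cache=True)
def shape_gradients_ref(gi):
    """Trilinear shape-function gradients at Gauss point gi (8 × 3, ref coords).

    Gauss index bits: ξ = bit0, η = bit1, ζ = bit2, each mapping 0 → −1/√3,
    1 → +1/√3.
    """
    xi = -_GP if (gi & 1) == 0 else _GP
    eta = -_GP if (gi & 2) == 0 else _GP
    zeta = -_GP if (gi & 4) == 0 else _GP
    dN = np.empty((8, 3))
    for a in range(8):
        xa = _XI[a, 0]
        ya = _XI[a, 1]
        za = _XI[a, 2]
        dN[a, 0] = 0.125 * xa * (1.0 + ya * eta) * (1.0 + za * zeta)
        dN[a, 1] = 0.125 * (1.0 + xa * xi) * ya * (1.0 + za * zeta)
        dN[a, 2] = 0.125 * (1.0 + xa * xi) * (1.0 + ya * eta) * za
    return dN


@njit(cache=True)
def element_gradients(Xe, gi):
    """Physical shape gradients and Jacobian determinant at Gauss point gi."""
    dNr = shape_gradients_ref(gi)
    Jm = np.zeros((3, 3))
    for a in range(8):
        for i in range(3):
            for j in range(3):
                Jm[i, j] += Xe[a, i] * dNr[a, j]
    detJ = np.linalg.det(Jm)
    if detJ <= 0.0:
        return dNr, detJ  # caller flags the element
    Jinv = np.linalg.inv(Jm)
    dNx = dNr @ Jinv  # dN/dX[a,i] = dN/dξ[a,j] Jinv[j,i]
    return dNx, detJ


@njit(cache=True)
def assemble_system(nodes, elems, u,
                    net_ref, node_off, fib, fib_off, L0, bnd,
                    intn, int_off, xcur,
                    A, B, G, K, tol, max_iter, h, need_tangent,
                    phi, dlam):
    """Internal forces, element tangents and per-GP fields for the whole mesh.

    Sequential element loop with fixed accumulation order (deterministic).
    Returns (fint (nn,3), Ke (ne,24,24), Sgp, Fgp, status (ne,8)).
    """
    nn = nodes.shape[0]
    ne = elems.shape[0]
    fint = np.zeros((nn, 3))
    if need_tangent:
        Ke = np.zeros((ne, 24, 24))
    else:
        Ke = np.zeros((1, 24, 24))
    Sgp = np.zeros((ne, 8, 3, 3))
    Fgp = np.zeros((ne, 8, 3, 3))
    status = np.zeros((ne, 8), dtype=np.int32)
    Xe = np.empty((8, 3))
    ue = np.empty((8, 3))
    for e in range(ne):
        for a in range(8):
            na = elems[e, a]
            for i in range(3):
                Xe[a, i] = nodes[na, i]
                ue[a, i] = u[na, i]
        for gi in range(8):
            dNx, detJ = element_gradients(Xe, gi)
            if detJ <= 0.0:
                status[e, gi] = 3
                continue
            F = np.eye(3)
            for a in range(8):
                for i in range(3):
                    for j in range(3):
                        F[i, j] += ue[a, i] * dNx[a, j]
            g = 8 * e + gi
            n0 = node_off[g]
            n1 = node_off[g + 1]
            f0 = fib_off[g]
            f1 = fib_off[g + 1]
            i0 = int_off[g]
            i1 = int_off[g + 1]
            ref_g = net_ref[n0:n1]
            fib_g = fib[f0:f1]
            L0_g = L0[f0:f1]
            bnd_g = bnd[n0:n1]
            int_g = intn[i0:i1]
            x_g = xcur[n0:n1]
            if need_tangent:
                P, sig, A4, st = gp_pk1_tangent(
                    ref_g, fib_g, L0_g, bnd_g, int_g, x_g, F,
                    A, B, G, K, tol, max_iter, h, phi, dlam)
            else:
                P, sig, st = gp_pk1(
                    ref_g, fib_g, L0_g, bnd_g, int_g, x_g, F,
                    A, B, G, K, tol, max_iter, phi, dlam)
                A4 = np.zeros((3, 3, 3, 3))
            status[e, gi] = st
            Sgp[e, gi] = sig
            Fgp[e, gi] = F
            w = detJ  # all 2×2×2 Gauss weights are 1
            for a in range(8):
                na = elems[e, a]
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += dNx[a, j] * P[i, j]
                    fint[na, i] += w * s
            if need_tangent:
                for a in range(8):
                    for i in range(3):
                        row = 3 * a + i
                        for bb in range(8):
                            for l in range(3):
                                col = 3 * bb + l
                                s = 0.0
                                for j in range(3):
                                    for m in range(3):
                                        s += dNx[a, j] * A4[i, j, l, m] * dNx[bb, m]
                                Ke[e, row, col] += w * s
    return fint, Ke, Sgp, Fgp, status
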