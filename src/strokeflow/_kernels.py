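"""Numba kernels for the 1D pulse-wave solver.

All arrays are flat over the nodes of every active segment, laid out
contiguously segment by segment.  Junctions, the inlet, windkessel outlets
and clot faces are described by index tables prepared in ``solver.py``.

Unit convention: SI throughout (m, m^2, m/s, Pa, s).

Tube law per node:  p = pref + k1 (sqrt(A) - sqrt(A0)),  k1 = beta / A0,
local wave speed    c^2 = k1 sqrt(A) / (2 rho).

Junction unknowns are scaled (a_e = A_e / A0_e; residuals in velocity units)
so the Newton systems stay well conditioned across five orders of magnitude
in vessel calibre.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_JUNCTION_FAIL = 2
STATUS_NEGATIVE_AREA = 3

JUNCTION_TOL = 1e-11
JUNCTION_MAX_ITER = 50
SCALAR_TOL = 1e-10
SCALAR_MAX_ITER = 60


@njit(cache=True, fastmath=False)
def _wave_speed(A, k1, rho):
    return np.sqrt(k1 * np.sqrt(A) / (2.0 * rho))


@njit(cache=True, fastmath=False)
def _pressure(A, k1, sqA0, pref):
    return pref + k1 * (np.sqrt(A) - sqA0)


@njit(cache=True, fastmath=False)
def _gauss_solve(M, b, n):
    """In-place Gaussian elimination with partial pivoting; solution in b."""
    for col in range(n):
        piv = col
        big = abs(M[col, col])
        for r in range(col + 1, n):
            if abs(M[r, col]) > big:
                big = abs(M[r, col])
                piv = r
        if big == 0.0:
            return False
        if piv != col:
            for cc in range(col, n):
                tmp = M[col, cc]
                M[col, cc] = M[piv, cc]
                M[piv, cc] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        inv = 1.0 / M[col, col]
        for r in range(col + 1, n):
            f = M[r, col] * inv
            if f != 0.0:
                for cc in range(col, n):
                    M[r, cc] -= f * M[col, cc]
                b[r] -= f * b[col]
    for col in range(n - 1, -1, -1):
        s = b[col]
        for cc in range(col + 1, n):
            s -= M[col, cc] * b[cc]
        b[col] = s / M[col, col]
    return True


@njit(cache=True, fastmath=False)
def _char_invariant(A, v, k1, sqA0, node, inner, sigma, dx, dt, rho, Kf, pref):
    """Outgoing Riemann invariant W_sigma = v + 4 sigma c at a boundary node.

    First-order extrapolation along the characteristic dx/dt = v + sigma c:
    the foot point lies a distance (sigma v + c) dt inside the domain and the
    state there is linearly interpolated between the boundary node and its
    interior neighbour; the viscous source is accumulated over dt.
    """
    cb = _wave_speed(A[node], k1[node], rho)
    d = (sigma * v[node] + cb) * dt
    th = d / dx
    if th < 0.0:
        th = 0.0
    elif th > 1.0:
        th = 1.0
    Af = (1.0 - th) * A[node] + th * A[inner]
    vf = (1.0 - th) * v[node] + th * v[inner]
    cf = _wave_speed(Af, k1[node], rho)
    return vf + 4.0 * sigma * cf - dt * Kf * vf / Af


@njit(cache=True, fastmath=False)
def _maccormack_segment(A, v, p, An, vn, i0, n, dx, dt, rho, alpha, Kf, k1, sqA0, pref):
    """Predictor-corrector update of the interior nodes of one segment.

    Continuity in conservative form; momentum in the averaged-profile
    non-conservative form with coefficients (2 alpha - 1) and (alpha - 1)
    and viscous drag -Kf v / A, Kf = 2 alpha pi mu / ((alpha - 1) rho).
    """
    lam = dt / dx
    c1 = 2.0 * alpha - 1.0
    c2 = alpha - 1.0
    Ap = np.empty(n)
    vp = np.empty(n)
    pp = np.empty(n)
    # predictor: forward differences, defined on nodes 0..n-2 of the segment
    for j in range(n - 1):
        g = i0 + j
        Ap[j] = A[g] - lam * (A[g + 1] * v[g + 1] - A[g] * v[g])
        adv = (
            c1 * v[g] * (v[g + 1] - v[g])
            + c2 * (v[g] * v[g] / A[g]) * (A[g + 1] - A[g])
            + (p[g + 1] - p[g]) / rho
        )
        vp[j] = v[g] - lam * adv - dt * Kf * v[g] / A[g]
        if Ap[j] <= 0.0:
            return False
        pp[j] = _pressure(Ap[j], k1[g], sqA0[g], pref)
    Ap[n - 1] = A[i0 + n - 1]
    vp[n - 1] = v[i0 + n - 1]
    pp[n - 1] = p[i0 + n - 1]
    # corrector: backward differences on the predicted field, interior nodes
    for j in range(1, n - 1):
        g = i0 + j
        An[g] = 0.5 * (A[g] + Ap[j] - lam * (Ap[j] * vp[j] - Ap[j - 1] * vp[j - 1]))
        adv = (
            c1 * vp[j] * (vp[j] - vp[j - 1])
            + c2 * (vp[j] * vp[j] / Ap[j]) * (Ap[j] - Ap[j - 1])
            + (pp[j] - pp[j - 1]) / rho
        )
        vn[g] = 0.5 * (v[g] + vp[j] - lam * adv - dt * Kf * vp[j] / Ap[j])
        if An[g] <= 0.0:
            return False
    return True


@njit(cache=True, fastmath=False)
def _solve_junction(
    A, v, An, vn, k1, sqA0, beta, ends_node, ends_inner, ends_sigma, ends_dx,
    dt, rho, Kf, pref,
):
    """Newton-Raphson coupling of E segment ends meeting at one junction.

    Constraints: one extrapolated characteristic per end, net mass flux zero,
    and total pressure p + rho v^2 / 2 equal across all ends.  Unknowns are
    (A_e / A0_e, v_e).  Returns True on convergence; writes into An, vn.
    """
    E = ends_node.shape[0]
    m = 2 * E
    W = np.empty(E)
    a = np.empty(E)
    u = np.empty(E)
    A0l = np.empty(E)
    cref = 0.0
    Aref = 0.0
    for e in range(E):
        nd = ends_node[e]
        W[e] = _char_invariant(
            A, v, k1, sqA0, nd, ends_inner[e], ends_sigma[e], ends_dx[e], dt, rho, Kf, pref
        )
        A0l[e] = sqA0[nd] * sqA0[nd]
        a[e] = A[nd] / A0l[e]
        u[e] = v[nd]
        c0 = _wave_speed(A0l[e], k1[nd], rho)
        if c0 > cref:
            cref = c0
        if A0l[e] > Aref:
            Aref = A0l[e]
    R = np.empty(m)
    M = np.empty((m, m))
    for it in range(JUNCTION_MAX_ITER):
        for r in range(m):
            for cc in range(m):
                M[r, cc] = 0.0
        nd0 = ends_node[0]
        Ae0 = a[0] * A0l[0]
        p0 = _pressure(Ae0, k1[nd0], sqA0[nd0], pref)
        pt0 = p0 + 0.5 * rho * u[0] * u[0]
        mass = 0.0
        for e in range(E):
            nd = ends_node[e]
            Ae = a[e] * A0l[e]
            ce = _wave_speed(Ae, k1[nd], rho)
            sg = ends_sigma[e]
            # characteristic rows
            R[e] = u[e] + 4.0 * sg * ce - W[e]
            M[e, e] = sg * ce / a[e]
            M[e, E + e] = 1.0
            mass += sg * Ae * u[e]
            # mass row (index 2E-1)
            M[m - 1, e] = sg * u[e] * A0l[e] / Aref
            M[m - 1, E + e] = sg * Ae / Aref
            # total-pressure rows e=1..E-1 (row E-1+e)
            if e > 0:
                pe = _pressure(Ae, k1[nd], sqA0[nd], pref)
                pte = pe + 0.5 * rho * u[e] * u[e]
                row = E - 1 + e
                R[row] = (pt0 - pte) / (rho * cref)
                M[row, 0] = beta[nd0] / (2.0 * np.sqrt(Ae0) * rho * cref)
                M[row, E] = u[0] / cref
                M[row, e] = -beta[nd] / (2.0 * np.sqrt(Ae) * rho * cref)
                M[row, E + e] = -u[e] / cref
        R[m - 1] = mass / Aref
        nrm = 0.0
        for r in range(m):
            if abs(R[r]) > nrm:
                nrm = abs(R[r])
        if nrm < JUNCTION_TOL:
            break
        if not _gauss_solve(M, R, m):
            return False
        for e in range(E):
            da = R[e]
            # keep areas positive under the Newton update
            if a[e] - da < 0.1 * a[e]:
                a[e] = 0.1 * a[e]
            else:
                a[e] = a[e] - da
            u[e] = u[e] - R[E + e]
    else:
        return False
    if nrm > 1e-8:
        return False
    for e in range(E):
        nd = ends_node[e]
        An[nd] = a[e] * A0l[e]
        vn[nd] = u[e]
    return True


@njit(cache=True, fastmath=False)
def _solve_outlet(
    A, v, An, vn, k1, sqA0, node, inner, sigma, dx, dt, rho, Kf, pref,
    R1, R2, C, pv, pc,
):
    """Three-element windkessel outlet; implicit-Euler capacitor update.

    Solves, for the boundary area A:
      p_tube(A) = pc' + Q R1,   Q = sigma A v,   v = W - 4 sigma c(A),
      pc' = (pc + dt/C (Q + pv/R2)) / (1 + dt/(R2 C)).
    Returns (ok, A, v, pc').
    """
    W = _char_invariant(A, v, k1, sqA0, node, inner, sigma, dx, dt, rho, Kf, pref)
    gam = 1.0 / (1.0 + dt / (R2 * C))
    dpdQ = gam * dt / C
    poff = gam * (pc + dt * pv / (R2 * C))
    Ax = A[node]
    for it in range(SCALAR_MAX_ITER):
        c = _wave_speed(Ax, k1[node], rho)
        vx = W - 4.0 * sigma * c
        Q = sigma * Ax * vx
        F = _pressure(Ax, k1[node], sqA0[node], pref) - poff - Q * (dpdQ + R1)
        dQdA = sigma * vx - c
        dF = k1[node] / (2.0 * np.sqrt(Ax)) - (dpdQ + R1) * dQdA
        step = F / dF
        newA = Ax - step
        if newA < 0.1 * Ax:
            newA = 0.1 * Ax
        Ax = newA
        if abs(F) < SCALAR_TOL * (1.0 + abs(poff)):
            break
    c = _wave_speed(Ax, k1[node], rho)
    vx = W - 4.0 * sigma * c
    Q = sigma * Ax * vx
    An[node] = Ax
    vn[node] = vx
    return poff + dpdQ * Q


@njit(cache=True, fastmath=False)
def _solve_inlet(A, v, An, vn, k1, sqA0, node, inner, dx, dt, rho, Kf, pref, Qt):
    """Prescribed volumetric inflow combined with the outgoing characteristic."""
    W = _char_invariant(A, v, k1, sqA0, node, inner, -1, dx, dt, rho, Kf, pref)
    Ax = A[node]
    for it in range(SCALAR_MAX_ITER):
        c = _wave_speed(Ax, k1[node], rho)
        vx = W + 4.0 * c
        F = Ax * vx - Qt
        dF = vx + c
        Ax = Ax - F / dF
        if Ax <= 0.0:
            Ax = 0.5 * A[node]
        if abs(F) < SCALAR_TOL * (1.0 + abs(Qt)):
            break
    An[node] = Ax
    vn[node] = W + 4.0 * _wave_speed(Ax, k1[node], rho)


@njit(cache=True, fastmath=False)
def advance_cycle(
    A, v, pc,
    t0, period, cfl,
    A0, k1, sqA0, beta, node_dx,
    seg_start, seg_n, seg_dx,
    rho, alpha, Kf, pref,
    inlet_node, inlet_inner, inlet_dx, q_phase, q_vals, q_scale,
    jct_ptr, jend_node, jend_inner, jend_sigma, jend_dx,
    out_node, out_inner, out_sigma, out_dx, out_R1, out_R2, out_C, out_pv,
    clot_node, clot_inner,
    p_snap, v_snap,
    sum_p, sum_v, sum_q,
    p_min, p_max, v_min, v_max,
    err_loc,
):
    """Integrate one cardiac cycle [t0, t0 + period] in place.

    Accumulates exact (stepwise rectangle) time integrals of p, v and Q per
    node, running extrema, and stores state snapshots at n_snap uniformly
    spaced phases.  Returns (status, steps).
    """
    N = A.shape[0]
    S = seg_start.shape[0]
    nJ = jct_ptr.shape[0] - 1
    n_snap = p_snap.shape[0]
    An = np.empty(N)
    vn = np.empty(N)
    p = np.empty(N)
    t = t0
    t_end = t0 + period
    k_snap = 0
    steps = 0
    while t < t_end - 1e-12 * period:
        # CFL time step, clipped to land exactly on snapshot times
        dt = 1e30
        for i in range(N):
            c = _wave_speed(A[i], k1[i], rho)
            lim = node_dx[i] / (abs(v[i]) + c)
            if lim < dt:
                dt = lim
        dt *= cfl
        t_next = t0 + (k_snap + 1) * period / n_snap
        if t + dt >= t_next - 1e-12 * period:
            dt = t_next - t
            hit_snap = True
        else:
            hit_snap = False
        for i in range(N):
            p[i] = _pressure(A[i], k1[i], sqA0[i], pref)
            An[i] = A[i]
            vn[i] = v[i]
        # interior nodes
        for s in range(S):
            ok = _maccormack_segment(
                A, v, p, An, vn, seg_start[s], seg_n[s], seg_dx[s], dt,
                rho, alpha, Kf, k1, sqA0, pref,
            )
            if not ok:
                err_loc[0] = s
                return STATUS_NEGATIVE_AREA, steps
        # inlet
        phase = (t + dt) / period
        phase -= np.floor(phase)
        Qt = q_scale * np.interp(phase, q_phase, q_vals)
        _solve_inlet(
            A, v, An, vn, k1, sqA0, inlet_node, inlet_inner, inlet_dx,
            dt, rho, Kf, pref, Qt,
        )
        # junctions
        for jj in range(nJ):
            lo = jct_ptr[jj]
            hi = jct_ptr[jj + 1]
            ok = _solve_junction(
                A, v, An, vn, k1, sqA0, beta,
                jend_node[lo:hi], jend_inner[lo:hi], jend_sigma[lo:hi], jend_dx[lo:hi],
                dt, rho, Kf, pref,
            )
            if not ok:
                err_loc[0] = jj
                return STATUS_JUNCTION_FAIL, steps
        # windkessel outlets
        for o in range(out_node.shape[0]):
            pc[o] = _solve_outlet(
                A, v, An, vn, k1, sqA0, out_node[o], out_inner[o], out_sigma[o],
                out_dx[o], dt, rho, Kf, pref,
                out_R1[o], out_R2[o], out_C[o], out_pv[o], pc[o],
            )
        # clot faces: reflective wall (zero velocity, zero pressure gradient)
        for cix in range(clot_node.shape[0]):
            An[clot_node[cix]] = An[clot_inner[cix]]
            vn[clot_node[cix]] = 0.0
        # commit + audits + accumulators
        for i in range(N):
            Ai = An[i]
            vi = vn[i]
            if not (np.isfinite(Ai) and np.isfinite(vi)) or Ai <= 0.0:
                err_loc[0] = i
                return STATUS_NONFINITE, steps
            A[i] = Ai
            v[i] = vi
            pi = _pressure(Ai, k1[i], sqA0[i], pref)
            sum_p[i] += pi * dt
            sum_v[i] += vi * dt
            sum_q[i] += Ai * vi * dt
            if pi < p_min[i]:
                p_min[i] = pi
            if pi > p_max[i]:
                p_max[i] = pi
            if vi < v_min[i]:
                v_min[i] = vi
            if vi > v_max[i]:
                v_max[i] = vi
        t += dt
        steps += 1
        if hit_snap:
            for i in range(N):
                p_snap[k_snap, i] = _pressure(A[i], k1[i], sqA0[i], pref)
                v_snap[k_snap, i] = v[i]
            k_snap += 1
            if k_snap >= n_snap:
                break
    return STATUS_OK, steps
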