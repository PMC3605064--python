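"""Independent reference implementations used only by the test suite.

These deliberately re-derive results through different numerical routes
than the package: a dense nodal-pressure solve for network flow, a
finite-difference discretization of the tissue oxygen problem on a padded
fine grid, and the free-space Bessel-K0 kernel for the VEGF balance.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from angioadapt import hemodynamics as hd
from angioadapt import oxygen as oxm
from angioadapt.network import BOUNDARY, Network
from angioadapt.tissue import TissueDomain


# ------------------------------------------------------------- flow oracle
def dense_flow_solve(net: Network, viscosity: dict) -> dict:
    """Nodal pressures from a dense direct solve at fixed viscosities."""
    sids = [s for s in sorted(net.segments) if net.segments[s].flowing]
    nids = sorted({net.segments[s].n_from for s in sids} | {net.segments[s].n_to for s in sids})
    index = {n: k for k, n in enumerate(nids)}
    n = len(nids)
    G = np.zeros((n, n))
    rhs = np.zeros(n)
    fixed = {}
    for nid in nids:
        node = net.nodes[nid]
        if node.kind == BOUNDARY and node.bc_type == "pressure":
            fixed[nid] = float(node.bc_value)
        elif node.kind == BOUNDARY and node.bc_type == "flow":
            rhs[index[nid]] += float(node.bc_value)
    for sid in sids:
        seg = net.segments[sid]
        g = 1.0 / hd.segment_resistance(net.length(sid), seg.diameter, viscosity[sid])
        i, j = index[seg.n_from], index[seg.n_to]
        G[i, i] += g
        G[j, j] += g
        G[i, j] -= g
        G[j, i] -= g
    for nid, p in fixed.items():
        k = index[nid]
        G[k, :] = 0.0
        G[k, k] = 1.0
        rhs[k] = p
        for r in range(n):
            if r != k and G[r, k] != 0.0:
                rhs[r] -= G[r, k] * p
                G[r, k] = 0.0
    P = np.linalg.solve(G, rhs)
    return {nid: float(P[index[nid]]) for nid in nids}


# ----------------------------------------------------------- oxygen oracle
def fd_oxygen_oracle(
    net: Network,
    flow: hd.HemodynamicState,
    dom: TissueDomain,
    params: oxm.OxygenParameters,
    M0: float,
    h: float = 6.25,
    pad: float = 400.0,
    max_iter: int = 120,
):
    """Finite-difference tissue oxygen solution coupled to blood marching.

    Discretizes the steady diffusion/consumption balance on a padded fine
    Cartesian grid (Neumann far boundary approximating free space once the
    net source/sink monopole cancels), with the tissue sinks spread over
    their 50 µm cells, vessel sources distributed along the segment lines,
    Michaelis–Menten consumption linearized per iteration, and wall PO2
    sampled on a lattice-resolvable ring with the analytic cylinder-log
    correction down to the vessel radius. Returns tissue PO2 at the tissue
    points of `dom`.
    """
    x0 = y0 = -pad
    minx, miny, maxx, maxy = dom.boundary.bounds
    W = (maxx - minx) + 2 * pad
    Hh = (maxy - miny) + 2 * pad
    nx = int(round(W / h)) + 1
    ny = int(round(Hh / h)) + 1
    N = nx * ny
    K2 = params.krogh_DOalpha * 60 * (dom.thickness * 1e-4)

    def idx(i, j):
        return i * ny + j

    r_, c_, v_ = [], [], []
    for i in range(nx):
        for j in range(ny):
            k = idx(i, j)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < nx and 0 <= jj < ny:
                    r_.append(k)
                    c_.append(k)
                    v_.append(K2)
                    r_.append(k)
                    c_.append(idx(ii, jj))
                    v_.append(-K2)
    Lap = sparse.csr_matrix((v_, (r_, c_)), shape=(N, N))

    el_seg, A, B, rv, el_len = oxm._discretize(net, flow, params)
    mids = 0.5 * (A + B)
    n_el = len(el_seg)
    K_intra = 1.0 / (params.nusselt * math.pi * (params.blood_DOalpha * 60) * (el_len * 1e-4))
    g_ex = 1.0 / K_intra
    tissue_pts = dom.points
    V = dom.point_volume

    def bw(p):
        fx = (p[0] - (minx + x0)) / h
        fy = (p[1] - (miny + y0)) / h
        i0, j0 = int(fx), int(fy)
        tx, ty = fx - i0, fy - j0
        return [
            (idx(i0, j0), (1 - tx) * (1 - ty)),
            (idx(i0 + 1, j0), tx * (1 - ty)),
            (idx(i0, j0 + 1), (1 - tx) * ty),
            (idx(i0 + 1, j0 + 1), tx * ty),
        ]

    half = dom.spacing / 2
    sub = np.linspace(-half * 0.875, half * 0.875, 8)
    sink_w = []
    for p in tissue_pts:
        acc = {}
        for dx in sub:
            for dy in sub:
                for c, wt in bw((p[0] + dx, p[1] + dy)):
                    acc[c] = acc.get(c, 0) + wt / 64.0
        sink_w.append(list(acc.items()))
    cent_w = [bw(p) for p in tissue_pts]
    src_w = []
    for k in range(n_el):
        acc = {}
        nsub = max(3, int(el_len[k] / 2))
        for t in (np.arange(nsub) + 0.5) / nsub:
            p = A[k] + t * (B[k] - A[k])
            for c, wt in bw(p):
                acc[c] = acc.get(c, 0) + wt / nsub
        src_w.append(list(acc.items()))
    circ = [(math.cos(t), math.sin(t)) for t in np.linspace(0, 2 * np.pi, 8, endpoint=False)]
    R0 = max(2.0 * h, 12.5)
    inv2piK = 1.0 / (2.0 * math.pi * K2)

    def _line_phi_at(p, a, b, rho_min):
        # exact mean potential of a unit-strength uniform line a->b at p
        ab = b - a
        L = math.hypot(ab[0], ab[1])
        ux, uy = ab[0] / L, ab[1] / L
        dx, dy = p[0] - a[0], p[1] - a[1]
        proj = dx * ux + dy * uy
        rho = max(abs(-dx * uy + dy * ux), rho_min)

        def F(s):
            return 0.5 * s * math.log(s * s + rho * rho) - s + rho * math.atan2(s, rho)

        return -(F(L - proj) - F(-proj)) / L

    # near-field correction: the lattice field sampled on the R0 ring misses
    # the sharp variation of nearby elements between the ring and the true
    # wall; replace it with the exact line potentials there
    wall_w = []
    near_corr = {}  # (e, j) -> coefficient on q_j
    for k in range(n_el):
        acc = {}
        ring_pts = [(mids[k][0] + R0 * cx, mids[k][1] + R0 * cy) for cx, cy in circ]
        wallpts = [(mids[k][0] + rv[k] * cx, mids[k][1] + rv[k] * cy) for cx, cy in circ]
        for p in ring_pts:
            for c, wt in bw(p):
                acc[c] = acc.get(c, 0) + wt / 8.0
        wall_w.append(list(acc.items()))
        for j in range(n_el):
            djk = math.hypot(mids[j][0] - mids[k][0], mids[j][1] - mids[k][1])
            if djk > 4.0 * R0 + el_len[j]:
                continue
            phi_wall = np.mean([_line_phi_at(p, A[j], B[j], rv[j]) for p in wallpts])
            phi_ring = np.mean([_line_phi_at(p, A[j], B[j], rv[j]) for p in ring_pts])
            near_corr[(k, j)] = inv2piK * (phi_wall - phi_ring)
    # nearby tissue sinks likewise vary between ring and wall
    sink_corr = {}  # (e, k_sink) -> coefficient on sink strength m_k
    for k in range(n_el):
        ring_pts = [(mids[k][0] + R0 * cx, mids[k][1] + R0 * cy) for cx, cy in circ]
        wallpts = [(mids[k][0] + rv[k] * cx, mids[k][1] + rv[k] * cy) for cx, cy in circ]
        offs = (dom.spacing / 3.0) * np.array([-1.0, 0.0, 1.0])
        for kt, p_t in enumerate(tissue_pts):
            dkt = math.hypot(p_t[0] - mids[k][0], p_t[1] - mids[k][1])
            if dkt > 2.0 * R0 + dom.spacing:
                continue

            def sq_phi(p):
                tot = 0.0
                for ox in offs:
                    for oy in offs:
                        tot -= math.log(max(math.hypot(p[0] - p_t[0] - ox, p[1] - p_t[1] - oy), 1.0))
                return tot / 9.0

            phi_wall = np.mean([sq_phi(p) for p in wallpts])
            phi_ring = np.mean([sq_phi(p) for p in ring_pts])
            sink_corr[(k, kt)] = -inv2piK * (phi_wall - phi_ring)

    Ptis = np.full(len(tissue_pts), 30.0)
    P_b = np.full(n_el, 75.0)
    by_seg = {int(s): np.nonzero(el_seg == s)[0] for s in np.unique(el_seg)}
    M0V = (M0 / 100.0) * V
    q = np.zeros(n_el)
    for it in range(max_iter):
        Pt = np.maximum(Ptis, 0)
        mstar = M0V * Pt / (params.P_half + Pt)
        dmv = M0V * params.P_half / (params.P_half + Pt) ** 2
        aff = mstar - dmv * Pt
        r2, c2, v2 = [], [], []
        rhs = np.zeros(N + n_el)
        for k, swl in enumerate(sink_w):
            for c, wt in swl:
                rhs[c] -= aff[k] * wt
                for c3, wt3 in cent_w[k]:
                    r2.append(c)
                    c2.append(c3)
                    v2.append(dmv[k] * wt * wt3)
        for e, swl in enumerate(src_w):
            for c, wt in swl:
                r2.append(c)
                c2.append(N + e)
                v2.append(-wt)
        for e in range(n_el):
            for c, wt in wall_w[e]:
                r2.append(N + e)
                c2.append(c)
                v2.append(wt)
            r2.append(N + e)
            c2.append(N + e)
            v2.append(K_intra[e])
            rhs[N + e] = P_b[e]
        for (e, j), coef in near_corr.items():
            r2.append(N + e)
            c2.append(N + j)
            v2.append(coef)
        for (e, kt), coef in sink_corr.items():
            rhs[N + e] -= coef * aff[kt]
            for c3, wt3 in cent_w[kt]:
                r2.append(N + e)
                c2.append(c3)
                v2.append(coef * dmv[kt] * wt3)
        Afull = (
            sparse.bmat(
                [
                    [Lap, sparse.csr_matrix((N, n_el))],
                    [sparse.csr_matrix((n_el, N)), sparse.csr_matrix((n_el, n_el))],
                ]
            )
            + sparse.csr_matrix((v2, (r2, c2)), shape=(N + n_el, N + n_el))
        ).tocsc()
        sol = spsolve(Afull, rhs)
        field = sol[:N]
        q = sol[N:]
        w = np.array([sum(field[c] * wt for c, wt in wall_w[e]) for e in range(n_el)])
        for (e, j), coef in near_corr.items():
            w[e] += coef * q[j]
        m_now = mstar + dmv * (
            np.array([sum(field[c] * wt for c, wt in cent_w[k]) for k in range(len(tissue_pts))]) - Pt
        )
        for (e, kt), coef in sink_corr.items():
            w[e] += coef * m_now[kt]
        w = np.clip(w, 0, 75)
        Pb_new = np.zeros(n_el)
        order = sorted(flow.node_pressure, key=lambda n_: -flow.node_pressure[n_])
        nflux = {n_: 0.0 for n_ in order}
        nQ = {n_: 0.0 for n_ in order}
        nH = {n_: 0.0 for n_ in order}
        for nid in order:
            node = net.nodes[nid]
            outs = [s for s in net._adj[nid] if s in by_seg and flow.upstream_node(net, s) == nid]
            if node.kind == BOUNDARY and outs:
                Pn = node.bc_po2
            elif nQ[nid] > 0:
                Pn = float(
                    oxm.blood_po2_from_content(
                        nflux[nid] / (nQ[nid] * 1e-6), nH[nid] / nQ[nid], params
                    )[0]
                )
            else:
                Pn = 0.0
            for s in outs:
                Q = abs(flow.flow[s])
                H = flow.hematocrit[s]
                Qc = Q * 1e-6
                P = Pn
                for e in by_seg[s]:
                    lam = math.exp(-g_ex[e] / (Qc * oxm._dcontent(P, H, params)))
                    Pout = max(w[e] + (P - w[e]) * lam, 0.0)
                    Pb_new[e] = w[e] + (P - w[e]) * math.sqrt(lam)
                    P = Pout
                down = flow.downstream_node(net, s)
                nflux[down] += float(oxm.convective_flux(Q, H, P, params))
                nQ[down] += Q
                nH[down] += Q * H
        db = np.max(np.abs(Pb_new - P_b))
        P_b = P_b + 0.5 * (Pb_new - P_b)
        tis_new = np.array([sum(field[c] * wt for c, wt in cent_w[k]) for k in range(len(tissue_pts))])
        dtis = np.max(np.abs(tis_new - Ptis))
        Ptis = tis_new
        if it > 4 and db < 0.1 and dtis < 0.1:
            break
    return Ptis
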