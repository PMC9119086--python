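"""Independent brute-force / exact oracles used by the test suite only."""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import lil_matrix

from morphoreg.dense_correspondence import FlowParams
from morphoreg.stack_optimization import (
    CorrespondenceSet,
    StackEnergyParams,
    _collect_nodes,
    build_neighbor_graph,
)


def exact_flow_optimum(d1: np.ndarray, d2: np.ndarray, params: FlowParams) -> float:
    """Global optimum of the discrete flow energy via integer programming.

    Standard MAP-as-ILP encoding: binary indicators per (pixel, label) and
    continuous pair variables per (edge, label, label) tied by marginalization
    constraints; with non-negative pairwise costs the LP pair polytope is
    integral once the node variables are binary, so HiGHS returns the exact
    minimum.  Only feasible for tiny instances.
    """
    h, w, _ = d1.shape
    r = params.search_radius
    labels = [(du, dv) for dv in range(-r, r + 1) for du in range(-r, r + 1)]
    n_lab = len(labels)
    n_pix = h * w

    # unary costs: data + magnitude
    unary = np.empty((n_pix, n_lab))
    for li, (du, dv) in enumerate(labels):
        ys, xs = np.mgrid[0:h, 0:w]
        ty, tx = ys + dv, xs + du
        valid = (ty >= 0) & (ty < h) & (tx >= 0) & (tx < w)
        tyc, txc = np.clip(ty, 0, h - 1), np.clip(tx, 0, w - 1)
        l1 = np.abs(d1 - d2[tyc, txc]).sum(axis=2)
        data = np.where(valid, np.minimum(l1, params.t), params.t)
        unary[:, li] = (data + params.eta * (abs(du) + abs(dv))).ravel()

    edges = []
    for y in range(h):
        for x in range(w):
            if x + 1 < w:
                edges.append((y * w + x, y * w + x + 1))
            if y + 1 < h:
                edges.append((y * w + x, (y + 1) * w + x))

    def pair_cost(la, lb):
        (ua, va), (ub, vb) = labels[la], labels[lb]
        return min(params.smooth_weight * abs(ua - ub), params.smooth_trunc) + min(
            params.smooth_weight * abs(va - vb), params.smooth_trunc
        )

    pc = np.array([[pair_cost(a, b) for b in range(n_lab)] for a in range(n_lab)])

    n_node_vars = n_pix * n_lab
    n_pair_vars = len(edges) * n_lab * n_lab
    c = np.concatenate([unary.ravel(), np.tile(pc.ravel(), len(edges))])

    n_rows = n_pix + len(edges) * 2 * n_lab
    A = lil_matrix((n_rows, n_node_vars + n_pair_vars))
    lb = np.empty(n_rows)
    ub = np.empty(n_rows)
    row = 0
    for p in range(n_pix):  # one label per pixel
        A[row, p * n_lab : (p + 1) * n_lab] = 1.0
        lb[row] = ub[row] = 1.0
        row += 1
    for e, (p, q) in enumerate(edges):  # marginalization both ways
        base = n_node_vars + e * n_lab * n_lab
        for la in range(n_lab):
            A[row, base + la * n_lab : base + (la + 1) * n_lab] = 1.0
            A[row, p * n_lab + la] = -1.0
            lb[row] = ub[row] = 0.0
            row += 1
        for lbl in range(n_lab):
            A[row, [base + la * n_lab + lbl for la in range(n_lab)]] = 1.0
            A[row, q * n_lab + lbl] = -1.0
            lb[row] = ub[row] = 0.0
            row += 1

    integrality = np.concatenate(
        [np.ones(n_node_vars), np.zeros(n_pair_vars)]
    )
    res = milp(
        c=c,
        constraints=LinearConstraint(A.tocsr(), lb, ub),
        bounds=(0, 1),
        integrality=integrality,
    )
    if not res.success:
        raise RuntimeError(f"flow ILP failed: {res.message}")
    return float(res.fun)


def kkt_stack_optimum(corrs: CorrespondenceSet, params: StackEnergyParams):
    """Exact constrained minimum of the stack energy via a dense KKT system.

    Unknowns are the raw per-node displacements; the correspondence equality
    constraints enter through Lagrange multipliers.  Independent of the
    union-find elimination used by the solver under test.
    """
    node_section, node_xy, links = _collect_nodes(corrs)
    n = len(node_xy)
    sections = np.array(node_section)
    hess = np.eye(n)
    edge_cache = []
    for s in range(corrs.n_sections):
        nodes = np.nonzero(sections == s)[0]
        edges = build_neighbor_graph(node_xy[nodes], params)
        edge_cache.append((nodes, edges))
        for i, j, wgt in edges:
            a, b = nodes[i], nodes[j]
            hess[a, a] += wgt
            hess[b, b] += wgt
            hess[a, b] -= wgt
            hess[b, a] -= wgt

    cons = np.zeros((len(links), n))
    rhs = np.zeros((len(links), 2))
    for k, (a, b) in enumerate(links):
        cons[k, a] = 1.0
        cons[k, b] = -1.0
        rhs[k] = node_xy[b] - node_xy[a]

    kkt = np.block(
        [[2 * hess, cons.T], [cons, np.zeros((len(links), len(links)))]]
    )
    disp = np.zeros((n, 2))
    for c_idx in range(2):
        vec = np.concatenate([np.zeros(n), rhs[:, c_idx]])
        sol = np.linalg.lstsq(kkt, vec, rcond=None)[0]
        disp[:, c_idx] = sol[:n]

    energy = float(np.sum(disp**2))
    for nodes, edges in edge_cache:
        for i, j, wgt in edges:
            energy += wgt * float(np.sum((disp[nodes[i]] - disp[nodes[j]]) ** 2))
    return energy, disp


def grid_search_translation(ls_points, lt_points, lo=-10.0, hi=10.0, step=0.01):
    """Brute-force minimizer of the landmark cost over a (u, v) grid."""
    grid = np.arange(lo, hi + step / 2, step)
    diff = np.asarray(lt_points) - np.asarray(ls_points)
    # cost(u,v) separates: sum (dx - u)^2 + sum (dy - v)^2
    cost_u = ((diff[:, 0][None, :] - grid[:, None]) ** 2).sum(axis=1)
    cost_v = ((diff[:, 1][None, :] - grid[:, None]) ** 2).sum(axis=1)
    return grid[np.argmin(cost_u)], grid[np.argmin(cost_v)]
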