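"""Simultaneous displacement adjustment across all sections.

Each correspondence (p_i, p_{i+1}) between adjacent sections must end up at
one shared position: p_i + w_i(p_i) = p_{i+1} + w_{i+1}(p_{i+1}).  Subject
to these equality constraints, the displacements of all control points in
all sections are solved at once by minimizing

    E(w) = sum_i sum_p (u(p)^2 + v(p)^2)
         + sum_i sum_{(p,q)} [lambda / dist(p, q)] ((u_p - u_q)^2 + (v_p - v_q)^2)

so no reference section exists and no error accumulates along the stack.
Matched points are eliminated into one shared unknown target position per
constraint chain (chains spanning several sections collapse transitively via
union-find), leaving an unconstrained sparse symmetric positive-definite
system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class StackEnergyParams:
    """Weights of the stack energy and the within-section neighbor rule."""

    lambda_smooth: float = 1.0
    k_neighbors: int = 4
    neighbor_radius: float = 48.0
    #: multiply (not divide) the pairwise weight by dist(p, q) if True
    weight_by_distance: bool = False

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be non-negative")
        if self.k_neighbors < 0:
            raise ValueError("k_neighbors must be non-negative")
        if self.neighbor_radius <= 0:
            raise ValueError("neighbor_radius must be positive")


@dataclass
class CorrespondenceSet:
    """Matched point pairs between every adjacent section pair.

    ``pairs[i]`` holds (src, dst): points in section i and their matches in
    section i + 1, both (K_i, 2) float arrays in (x, y) pixel coordinates.
    """

    pairs: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        cleaned = []
        for src, dst in self.pairs:
            src = np.asarray(src, dtype=float).reshape(-1, 2)
            dst = np.asarray(dst, dtype=float).reshape(-1, 2)
            if src.shape != dst.shape:
                raise ValueError("src and dst point lists must have equal shape")
            if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
                raise ValueError("correspondence coordinates must be finite")
            if len(src) and len(np.unique(src, axis=0)) != len(src):
                raise ValueError("duplicate source points within a section pair")
            cleaned.append((src, dst))
        self.pairs = cleaned

    @property
    def n_sections(self) -> int:
        return len(self.pairs) + 1


@dataclass
class DisplacementSolution:
    """Per-section control points and their solved displacements."""

    points: list[np.ndarray]
    displacements: list[np.ndarray]
    energy: float
    max_constraint_residual: float
    n_groups: int

    def section(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.points[i], self.displacements[i]


# --------------------------------------------------------------------------
# neighbor graph
# --------------------------------------------------------------------------

def build_neighbor_graph(
    points: np.ndarray, params: StackEnergyParams
) -> list[tuple[int, int, float]]:
    """Mutual k-nearest-neighbor edges within a radius for one section.

    Returns undirected edges (i, j, weight) with i < j and weight
    lambda / dist (or lambda * dist when ``weight_by_distance``); coincident
    points are skipped with a warning.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2 or params.k_neighbors == 0 or params.lambda_smooth == 0:
        return []
    k = min(params.k_neighbors + 1, n)
    tree = cKDTree(pts)
    dists, idx = tree.query(pts, k=k)
    knn = []
    for i in range(n):
        # self may appear anywhere among zero-distance ties: filter by index
        near = [
            int(j)
            for d, j in zip(dists[i], idx[i])
            if int(j) != i and np.isfinite(d) and d <= params.neighbor_radius
        ]
        knn.append(set(near[: params.k_neighbors]))
    edges = []
    for i in range(n):
        for j in knn[i]:
            if j <= i or i not in knn[j]:  # mutualized, undirected
                continue
            d = float(np.hypot(*(pts[i] - pts[j])))
            if d == 0.0:
                warnings.warn(f"coincident control points {i}, {j}: edge skipped")
                continue
            w = params.lambda_smooth * d if params.weight_by_distance else params.lambda_smooth / d
            edges.append((i, j, w))
    return edges


def stack_energy(
    solution: DisplacementSolution,
    edges_per_section: list[list[tuple[int, int, float]]],
    params: StackEnergyParams,
) -> float:
    """Recompute the quadratic stack energy of a displacement solution."""
    if len(edges_per_section) != len(solution.points):
        raise ValueError("edge lists do not match the solution's sections")
    total = 0.0
    for pts, w, edges in zip(solution.points, solution.displacements, edges_per_section):
        total += float(np.sum(w**2))
        for i, j, weight in edges:
            total += weight * float(np.sum((w[i] - w[j]) ** 2))
    return total


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _collect_nodes(corrs: CorrespondenceSet):
    """Unique control points per section and node ids; correspondences as node pairs."""
    n_sections = corrs.n_sections
    coords: list[dict[tuple[float, float], int]] = [dict() for _ in range(n_sections)]
    node_section: list[int] = []
    node_xy: list[tuple[float, float]] = []

    def node_id(section: int, xy: np.ndarray) -> int:
        key = (float(xy[0]), float(xy[1]))
        table = coords[section]
        if key not in table:
            table[key] = len(node_xy)
            node_section.append(section)
            node_xy.append(key)
        return table[key]

    links = []
    for i, (src, dst) in enumerate(corrs.pairs):
        for s_xy, d_xy in zip(src, dst):
            links.append((node_id(i, s_xy), node_id(i + 1, d_xy)))
    return node_section, np.array(node_xy, dtype=float).reshape(-1, 2), links


def solve_stack_displacements(
    corrs: CorrespondenceSet, params: StackEnergyParams | None = None
) -> DisplacementSolution:
    """Exact minimizer of the constrained stack energy.

    Every constraint chain shares one unknown target position z; writing
    w(node) = z_g(node) - p(node) turns the problem into an unconstrained
    sparse SPD least-squares system in the group targets, solved per
    coordinate by preconditioned conjugate gradients (dense fallback for
    tiny systems).  The equality constraints hold exactly by construction.
    """
    if params is None:
        params = StackEnergyParams()
    n_sections = corrs.n_sections
    node_section, node_xy, links = _collect_nodes(corrs)
    n_nodes = len(node_section)
    if n_nodes == 0:
        empty = [np.zeros((0, 2)) for _ in range(n_sections)]
        return DisplacementSolution(
            points=empty, displacements=[e.copy() for e in empty],
            energy=0.0, max_constraint_residual=0.0, n_groups=0,
        )

    uf = _UnionFind(n_nodes)
    for a, b in links:
        uf.union(a, b)
    roots = np.array([uf.find(i) for i in range(n_nodes)])
    group_ids, group_of = np.unique(roots, return_inverse=True)
    n_groups = len(group_ids)

    # per-section neighbor graphs over that section's nodes
    section_nodes = [np.nonzero(np.array(node_section) == s)[0] for s in range(n_sections)]
    edge_rows = []  # (node_a, node_b, weight)
    for s in range(n_sections):
        nodes = section_nodes[s]
        for i, j, w in build_neighbor_graph(node_xy[nodes], params):
            edge_rows.append((nodes[i], nodes[j], w))

    # assemble A z = b per coordinate: data term sum_nodes (z_g - x_node)^2
    # plus smoothness sum_edges w ((z_ga - x_a) - (z_gb - x_b))^2
    diag = np.zeros(n_groups)
    b = np.zeros((n_groups, 2))
    np.add.at(diag, group_of, 1.0)
    np.add.at(b, group_of, node_xy)

    rows, cols, vals = [], [], []
    for na, nb, w in edge_rows:
        ga, gb = group_of[na], group_of[nb]
        delta = node_xy[na] - node_xy[nb]
        if ga == gb:
            continue  # difference of displacements is constant: no unknown term
        diag[ga] += w
        diag[gb] += w
        rows += [ga, gb]
        cols += [gb, ga]
        vals += [-w, -w]
        b[ga] += w * delta
        b[gb] -= w * delta

    A = sparse.coo_matrix(
        (np.concatenate([vals, diag]) if vals else diag,
         (np.concatenate([rows, np.arange(n_groups)]) if rows else np.arange(n_groups),
          np.concatenate([cols, np.arange(n_groups)]) if cols else np.arange(n_groups))),
        shape=(n_groups, n_groups),
    ).tocsr()

    z = np.empty((n_groups, 2))
    if n_groups <= 200:
        dense = A.toarray()
        for c in range(2):
            z[:, c] = np.linalg.solve(dense, b[:, c])
    else:
        precond = sparse.diags(1.0 / A.diagonal())
        for c in range(2):
            sol, info = cg(A, b[:, c], rtol=1e-12, atol=0.0, maxiter=20000, M=precond)
            if info != 0:
                sol = spsolve(A.tocsc(), b[:, c])
            z[:, c] = sol

    w_nodes = z[group_of] - node_xy

    points = [node_xy[idx] for idx in section_nodes]
    displacements = [w_nodes[idx] for idx in section_nodes]

    residual = 0.0
    for a, bb in links:
        res = (node_xy[a] + w_nodes[a]) - (node_xy[bb] + w_nodes[bb])
        residual = max(residual, float(np.abs(res).max()))

    edges_per_section = []
    for s in range(n_sections):
        nodes = section_nodes[s]
        edges_per_section.append(build_neighbor_graph(node_xy[nodes], params))
    solution = DisplacementSolution(
        points=points,
        displacements=displacements,
        energy=0.0,
        max_constraint_residual=residual,
        n_groups=n_groups,
    )
    solution.energy = stack_energy(solution, edges_per_section, params)
    return solution
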