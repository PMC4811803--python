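"""Bayesian inference of junction tensions and cell pressures, and the
Batchelor stress of cell patches.

At mechanical equilibrium the geometry of an epithelial junction network
constrains the junction tensions gamma and cell pressures p: at every
interior vertex the tensions pull along the junction chords and the
pressure differences push across them, and the net force vanishes.  These
vertex balance equations are linear and homogeneous in (gamma, p), with
exactly two gauge freedoms (the global tension scale and the pressure
offset).  Tensions and pressures are estimated jointly by maximizing the
marginal likelihood of the balance equations under a prior that tensions
are distributed around a positive value, the hyperparameter being selected
by minimizing the Akaike Bayesian information criterion (ABIC).  Outputs
are normalized to mean tension 1 and mean pressure 0.

The coarse-grained stress of a cell patch follows from the Batchelor
formula:  sigma = (1/A) [ - sum_c p_c A_c 1  + sum_[ck] gamma_ck
(L (x) L)/|L| ], with L the junction chord vectors.  Only tensions enter
the deviator of sigma (the "junctional stress" anisotropy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .tensors import SymTensor2


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class Junction:
    v1: int
    v2: int
    cell_a: int     # cell on the left of v1 -> v2
    cell_b: int     # cell on the right

    @property
    def cells(self) -> tuple[int, int]:
        return self.cell_a, self.cell_b


@dataclass
class JunctionNetwork:
    """Vertices, junction chords and cells of a segmented frame.

    Vertex positions in um.  ``boundary_cells`` are cells at the tissue or
    image edge; vertices incident to them are excluded from the balance
    system (forces there involve unknown external contributions).
    """

    vertices: np.ndarray                   # (V, 2)
    junctions: list[Junction]
    cell_areas: dict[int, float]           # um^2
    boundary_cells: set[int] = field(default_factory=set)
    cell_centroids: dict[int, np.ndarray] = field(default_factory=dict)

    def chord(self, j: Junction) -> np.ndarray:
        return self.vertices[j.v2] - self.vertices[j.v1]

    def interior_vertices(self) -> np.ndarray:
        incident: dict[int, set[int]] = {}
        degree: dict[int, int] = {}
        for j in self.junctions:
            for v in (j.v1, j.v2):
                incident.setdefault(v, set()).update(j.cells)
                degree[v] = degree.get(v, 0) + 1
        keep = [
            v
            for v in sorted(degree)
            if degree[v] >= 3 and not (incident[v] & self.boundary_cells)
        ]
        return np.asarray(keep, dtype=int)


@dataclass
class InferredForces:
    tensions: np.ndarray     # per junction, mean 1
    pressures: dict[int, float]  # per cell, mean 0
    hyperparameter: float
    abic: float
    residual_norm: float
    abic_scan: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# network extraction from label images
# ---------------------------------------------------------------------------

def extract_network(label_image: np.ndarray, pixel_size: float = 1.0
                    ) -> JunctionNetwork:
    """Junction network of a label image (pixel-adjacent or ridge-style).

    Vertices are located at 2x2 pixel corners where at least three regions
    meet; the junction between a cell pair is chorded between its two
    extremal vertices.  Cells touching the image border or the medium
    (label 0) are flagged as boundary cells.
    """
    lab = np.asarray(label_image)
    h, w = lab.shape
    blocks = np.stack(
        [lab[:-1, :-1], lab[:-1, 1:], lab[1:, :-1], lab[1:, 1:]], axis=-1
    )
    ids = np.unique(lab)
    ids = ids[ids != 0]

    # corner (i, j) sits between pixel rows i, i+1 and cols j, j+1
    vertex_pos: list[np.ndarray] = []
    vertex_id: dict[tuple[int, int], int] = {}
    corner_labels: dict[tuple[int, int], set[int]] = {}
    n_distinct = np.array([len(set(b)) for b in blocks.reshape(-1, 4)]).reshape(
        blocks.shape[:2]
    )
    for i, j in zip(*np.nonzero(n_distinct >= 3)):
        key = (int(i), int(j))
        vertex_id[key] = len(vertex_pos)
        vertex_pos.append(pixel_size * np.array([j + 0.5, i + 0.5]))
        corner_labels[key] = set(int(v) for v in blocks[i, j])

    # junction endpoints: for each adjacent cell pair, corners containing both
    pair_corners: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for key, labs in corner_labels.items():
        labs_nz = [v for v in labs if v != 0]
        for a in labs_nz:
            for b in labs_nz:
                if a < b:
                    pair_corners.setdefault((a, b), []).append(key)

    # centroids and areas
    flat = lab.ravel()
    nmax = int(lab.max()) + 1 if len(ids) else 1
    counts = np.bincount(flat, minlength=nmax)
    yy, xx = np.indices(lab.shape)
    sx = np.bincount(flat, weights=xx.ravel(), minlength=nmax)
    sy = np.bincount(flat, weights=yy.ravel(), minlength=nmax)
    centroids = {
        int(i): pixel_size * np.array([sx[i] / counts[i], sy[i] / counts[i]])
        for i in ids
    }
    areas = {int(i): float(counts[i]) * pixel_size**2 for i in ids}

    boundary: set[int] = set()
    for edge in (lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]):
        boundary.update(int(v) for v in np.unique(edge) if v != 0)
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (a == 0) & (b != 0)
        boundary.update(int(v) for v in np.unique(b[m]))
        m = (b == 0) & (a != 0)
        boundary.update(int(v) for v in np.unique(a[m]))

    vertices = (
        np.array(vertex_pos) if vertex_pos else np.zeros((0, 2))
    )
    junctions: list[Junction] = []
    for (a, b), corners in sorted(pair_corners.items()):
        if len(corners) < 2:
            continue
        pts = np.array([vertex_pos[vertex_id[c]] for c in corners])
        # extremal pair = farthest apart (junctions are nearly straight)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        i1, i2 = np.unravel_index(np.argmax(d2), d2.shape)
        if d2[i1, i2] == 0:
            continue
        v1 = vertex_id[corners[i1]]
        v2 = vertex_id[corners[i2]]
        t = vertices[v2] - vertices[v1]
        nleft = np.array([-t[1], t[0]])
        mid = 0.5 * (vertices[v1] + vertices[v2])
        a_left = np.dot(centroids[a] - mid, nleft) >= 0
        ca, cb = (a, b) if a_left else (b, a)
        junctions.append(Junction(v1, v2, ca, cb))
    return JunctionNetwork(vertices, junctions, areas, boundary, centroids)


# ---------------------------------------------------------------------------
# balance system and ABIC inference
# ---------------------------------------------------------------------------

@dataclass
class BalanceSystem:
    matrix: sparse.csr_matrix   # (2 * n_vertices, n_junctions + n_cells)
    junction_index: list[int]   # columns 0..J-1 -> junction list indices
    cell_index: list[int]       # columns J..J+C-1 -> cell ids
    n_vertices: int


def build_balance_system(network: JunctionNetwork) -> BalanceSystem:
    """Force balance at every interior vertex, linear in (gamma, p).

    Each vertex contributes two equations:
    sum_j [ gamma_j t_j  + (p_left - p_right) (L_j / 2) n_j ] = 0,
    with t_j the unit chord direction away from the vertex and n_j the
    corresponding pressure-difference direction.  The system is
    homogeneous; its null space contains the tension scale and the
    pressure offset (per connected component).
    """
    vids = network.interior_vertices()
    vset = set(int(v) for v in vids)
    keep_j = [
        i for i, j in enumerate(network.junctions)
        if j.v1 in vset or j.v2 in vset
    ]
    cells = sorted({c for i in keep_j for c in network.junctions[i].cells})
    jcol = {ji: c for c, ji in enumerate(keep_j)}
    ccol = {cid: len(keep_j) + c for c, cid in enumerate(cells)}
    vrow = {int(v): 2 * r for r, v in enumerate(vids)}

    rows, cols, vals = [], [], []
    for ji in keep_j:
        j = network.junctions[ji]
        chord = network.chord(j)
        length = float(np.hypot(*chord))
        if length == 0:
            continue
        that = chord / length
        nleft = np.array([-that[1], that[0]])  # points into cell_a
        for v, sign in ((j.v1, 1.0), (j.v2, -1.0)):
            if v not in vset:
                continue
            r = vrow[v]
            # tension pulls the vertex toward the other end
            for ax in range(2):
                rows.append(r + ax)
                cols.append(jcol[ji])
                vals.append(sign * that[ax])
            # pressure difference pushes half the chord load onto the vertex:
            # (p_a - p_b) (L/2) * (-nleft) is the force from a onto b side;
            # net force on the junction is (p_a - p_b)(L/2) * (-n_ab), i.e.
            # from the high-pressure side toward the low one.
            for cid, psign in ((j.cell_a, 1.0), (j.cell_b, -1.0)):
                for ax in range(2):
                    rows.append(r + ax)
                    cols.append(ccol[cid])
                    vals.append(psign * 0.5 * length * (-nleft[ax]))
    mat = sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(2 * len(vids), len(keep_j) + len(cells)),
    )
    return BalanceSystem(mat, keep_j, cells, len(vids))


def infer_forces(
    system: BalanceSystem,
    prior_mean: float = 1.0,
    hyper_grid: np.ndarray | None = None,
    pressure_pin: float = 1e-6,
) -> InferredForces:
    """Tensions and pressures by ABIC-minimizing marginal likelihood.

    The balance equations E x = 0 are observed with unknown noise variance;
    the prior gamma ~ Normal(prior_mean, sigma^2/h) encodes that tensions
    cluster around a positive value.  The hyperparameter h is scanned
    logarithmically (default 1e-3..1e3) and chosen by minimizing
    ABIC(h) = dof * log S(h) - K log h + log det A(h) + const.
    A weak zero-mean prior on pressures pins the pressure-offset gauge.
    Deterministic for fixed inputs; warns when the scan minimum is not
    single-welled.
    """
    e = system.matrix.tocsr()
    n_obs, n_x = e.shape
    n_j = len(system.junction_index)
    n_c = len(system.cell_index)
    if n_j == 0 or n_obs == 0:
        raise ValueError("empty balance system")
    if hyper_grid is None:
        hyper_grid = np.logspace(-3, 3, 25)

    ete = (e.T @ e).tocsc()
    bg = sparse.hstack(
        [sparse.identity(n_j, format="csr"),
         sparse.csr_matrix((n_j, n_c))]
    ).tocsr()
    bp = sparse.hstack(
        [sparse.csr_matrix((n_c, n_j)), sparse.identity(n_c, format="csr")]
    ).tocsr()
    btb = (bg.T @ bg).tocsc()
    ptp = (bp.T @ bp).tocsc()
    rhs_base = np.zeros(n_x)
    rhs_base[:n_j] = prior_mean

    dof = n_obs + n_j - n_x  # effective data count after integrating x

    scan = []
    best = None
    for hval in hyper_grid:
        a = (ete + hval * btb + pressure_pin * ptp).tocsc()
        lu = splu(a)
        x = lu.solve(hval * rhs_base)
        r_obs = e @ x
        r_pri = x[:n_j] - prior_mean
        s0 = float(r_obs @ r_obs + hval * (r_pri @ r_pri)
                   + pressure_pin * float(x[n_j:] @ x[n_j:]))
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        abic = max(dof, 1) * np.log(max(s0, 1e-300)) - n_j * np.log(hval) + logdet
        scan.append((hval, abic, s0))
        if best is None or abic < best[1]:
            best = (hval, abic, x, s0)
    scan_df = pd.DataFrame(scan, columns=["h", "abic", "s0"])
    # single-well check: the ABIC sequence should descend then ascend
    # (ignoring wiggles that are negligible against the scan's range)
    a = scan_df["abic"].to_numpy()
    tol = 1e-9 * (np.ptp(a) + 1.0)
    d = np.diff(a)
    d = np.where(np.abs(d) < tol, 0.0, d)
    signs = np.sign(d[d != 0.0])
    if np.sum(np.diff(signs) != 0) > 1:
        warnings.warn("ABIC scan is not single-welled; using its global minimum")

    hstar, abic, x, s0 = best
    gamma = x[:n_j]
    press = x[n_j:]
    gscale = float(np.mean(gamma))
    if gscale == 0:
        raise ValueError("degenerate solution: mean tension is zero")
    gamma = gamma / gscale
    press = (press - float(np.mean(press))) / gscale
    resid = float(np.linalg.norm(e @ x) / max(np.linalg.norm(x), 1e-300))
    return InferredForces(
        tensions=gamma,
        pressures={cid: float(p) for cid, p in zip(system.cell_index, press)},
        hyperparameter=float(hstar),
        abic=float(abic),
        residual_norm=resid,
        abic_scan=scan_df,
    )


# ---------------------------------------------------------------------------
# Batchelor stress
# ---------------------------------------------------------------------------

def batchelor_stress(
    patch_cells: set[int],
    network: JunctionNetwork,
    tensions: dict[int, float] | np.ndarray,
    pressures: dict[int, float],
) -> SymTensor2 | None:
    """Coarse-grained stress of a cell patch from tensions and pressures.

    sigma = (1/A) [ - sum_{c in patch} p_c A_c 1
                    + sum_{[ck]} gamma_ck (L (x) L) / |L| ]
    where the junction sum covers junctions between patch cells (arbitrary
    units; gauge: mean tension 1, mean pressure 0).  Only tensions enter
    the deviator.  Returns None when a required tension, pressure or area
    is missing.
    """
    area = 0.0
    for c in patch_cells:
        if c not in network.cell_areas or c not in pressures:
            return None
        area += network.cell_areas[c]
    if area <= 0:
        return None
    mat = np.zeros((2, 2))
    for c in patch_cells:
        mat -= pressures[c] * network.cell_areas[c] * np.eye(2)
    for i, j in enumerate(network.junctions):
        if not (j.cell_a in patch_cells and j.cell_b in patch_cells):
            continue
        gamma = tensions[i] if not isinstance(tensions, dict) else tensions.get(i)
        if gamma is None:
            return None
        chord = network.chord(j)
        length = float(np.hypot(*chord))
        if length == 0:
            continue
        mat += gamma * np.outer(chord, chord) / length
    return SymTensor2.from_matrix(mat / area)


# ---------------------------------------------------------------------------
# synthetic relaxed foams (ground-truth tension generator)
# ---------------------------------------------------------------------------

def synthetic_foam(
    n_cells: int = 64,
    jitter: float = 0.22,
    seed: int = 0,
) -> tuple[JunctionNetwork, np.ndarray]:
    """Synthetic equilibrium foam with known heterogeneous tensions.

    A Voronoi tessellation of jittered hexagonal seeds is, with straight
    junctions and zero pressures, in *exact* mechanical equilibrium under
    tensions equal to the dual Delaunay edge lengths (each Voronoi edge is
    the 90-degree rotation of its Delaunay edge, so the tension vectors
    around a vertex close into the rotated seed triangle -- the classical
    reciprocal-diagram construction).  Jittering the seeds spreads the
    ground-truth tensions (relative spread roughly proportional to
    ``jitter``).  Returns the network and the true tension array (aligned
    with ``network.junctions``, normalized to mean 1).
    """
    from scipy.spatial import Voronoi

    rng = np.random.default_rng(seed)
    from .morphosim import hex_seeds

    radius = np.sqrt(n_cells / np.pi)
    seeds = hex_seeds(radius + 3.0, 1.0, rng, jitter=jitter)
    vor = Voronoi(seeds)

    keep = []
    for i, s in enumerate(seeds):
        region = vor.regions[vor.point_region[i]]
        if region and -1 not in region and np.hypot(*s) <= radius:
            keep.append(i)
    keep_cells = {i: ci + 1 for ci, i in enumerate(keep)}

    vertices = vor.vertices.copy()
    junctions = []
    gamma_true = []
    for (p1, p2), (rv1, rv2) in zip(vor.ridge_points, vor.ridge_vertices):
        if rv1 == -1 or rv2 == -1:
            continue
        if p1 not in keep_cells or p2 not in keep_cells:
            continue
        a, b = keep_cells[p1], keep_cells[p2]
        t = vertices[rv2] - vertices[rv1]
        nleft = np.array([-t[1], t[0]])
        mid = 0.5 * (vertices[rv1] + vertices[rv2])
        ca, cb = (a, b) if np.dot(seeds[p1] - mid, nleft) >= 0 else (b, a)
        junctions.append(Junction(int(rv1), int(rv2), ca, cb))
        gamma_true.append(float(np.hypot(*(seeds[p1] - seeds[p2]))))

    centroids = {keep_cells[i]: seeds[i] for i in keep}
    boundary = {
        keep_cells[i] for i in keep if np.hypot(*seeds[i]) > radius - 1.5
    }
    areas = {}
    for i in keep:
        region = vor.regions[vor.point_region[i]]
        poly = vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[keep_cells[i]] = 0.5 * abs(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )
    net = JunctionNetwork(vertices, junctions, areas, boundary, centroids)
    gamma_true = np.asarray(gamma_true)
    return net, gamma_true / gamma_true.mean()


def hexagonal_network(n_rings: int = 3, edge: float = 1.0) -> JunctionNetwork:
    """Regular hexagonal honeycomb network (equal tensions, 120-degree
    vertices), for symmetry checks."""
    import networkx as nx

    # hex centers on a triangular lattice
    centers = []
    for q in range(-n_rings, n_rings + 1):
        for r in range(-n_rings, n_rings + 1):
            if abs(q + r) <= n_rings:
                x = edge * np.sqrt(3) * (q + r / 2.0)
                y = edge * 1.5 * r
                centers.append((x, y))
    centers = np.array(centers)

    verts: list[np.ndarray] = []
    vid: dict[tuple[int, int], int] = {}

    def vertex(p):
        key = (round(p[0] * 1e6), round(p[1] * 1e6))
        if key not in vid:
            vid[key] = len(verts)
            verts.append(np.array(p))
        return vid[key]

    g = nx.Graph()
    cell_of_edge: dict[tuple[int, int], list[int]] = {}
    areas = {}
    centroids = {}
    hex_area = 3 * np.sqrt(3) / 2 * edge**2
    for ci, c in enumerate(centers, start=1):
        corners = [
            (c[0] + edge * np.cos(np.pi / 6 + k * np.pi / 3),
             c[1] + edge * np.sin(np.pi / 6 + k * np.pi / 3))
            for k in range(6)
        ]
        ids = [vertex(p) for p in corners]
        areas[ci] = hex_area
        centroids[ci] = np.array(c)
        for k in range(6):
            a, b = ids[k], ids[(k + 1) % 6]
            key = (min(a, b), max(a, b))
            g.add_edge(a, b)
            cell_of_edge.setdefault(key, []).append(ci)

    vertices = np.array(verts)
    junctions = []
    boundary: set[int] = set()
    for (v1, v2), cells in cell_of_edge.items():
        if len(cells) == 2:
            a, b = cells
            t = vertices[v2] - vertices[v1]
            nleft = np.array([-t[1], t[0]])
            mid = 0.5 * (vertices[v1] + vertices[v2])
            ca, cb = (a, b) if np.dot(centroids[a] - mid, nleft) >= 0 else (b, a)
            junctions.append(Junction(v1, v2, ca, cb))
        else:
            boundary.add(cells[0])
    return JunctionNetwork(vertices, junctions, areas, boundary, centroids)
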