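"""Texture-tensor kinematics: per-patch deformation-rate decomposition.

For a Lagrangian patch of cells, the half-link *texture*
``M = (1/N) sum_l l (x) l`` (um^2) encodes mean cell size (trace) and
anisotropy (deviator).  Between two frames separated by ``dt``:

- the tissue deformation rate ``G`` and rotation rate ``Omega`` come from a
  least-squares fit of the displacement gradient over *conserved* links
  (exact for affine motion);
- each topological process P in {D, R, A, N, C, J} contributes
  ``P = -(1/4)(M^-1 T_P + T_P M^-1)`` where ``T_P`` collects the link
  outer-products appearing (at t+dt) minus disappearing (at t) through
  that process, plus the renormalization of the per-link mean caused by
  the process's net link-count change;
- the cell size-and-shape rate ``S`` is measured from the change of the
  total texture M itself (the statistical mean cell size and shape): the
  unique symmetric positive ``F`` with ``F M(t) F = M(t+dt)`` gives
  ``S = (2/dt)(F - 1)(F + 1)^-1``.  This solve is exact for rotation-free
  affine maps, including ones that do not commute with M.

These choices make the balance ``G = S + D + R + A + N + C + J`` hold
identically up to the commutator/discretization error of the least-squares
fit, which the per-patch residual reports.

Signs follow the process semantics: divisions and integrations add links
and carry positive trace, delaminations negative; a T1 elongates the patch
along the *disappearing* link axis, which is where its R deviator points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellgraph import (
    FrameGraph,
    Lineage,
    build_adjacency,
    classify_half_links,
    division_links,
    division_orientation,
)
from .tensors import SymTensor2, tensor_norm

PROCESSES = ("division", "rearrangement", "delamination", "integration",
             "fusion", "flux")
#: tensor symbol per process category
PROCESS_SYMBOL = {
    "division": "D",
    "rearrangement": "R",
    "delamination": "A",
    "integration": "N",
    "fusion": "C",
    "flux": "J",
}

_SINGULAR_RTOL = 1e-12


# ---------------------------------------------------------------------------
# elementary estimators
# ---------------------------------------------------------------------------

def texture(links: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-link average texture matrix M = (1/N) sum l (x) l  (um^2).

    ``links`` is an (N, 2) array of half-link vectors.  Returns (M, N);
    raises on an empty link set (the texture is then undefined).
    """
    links = np.atleast_2d(np.asarray(links, dtype=float))
    n = len(links)
    if n == 0 or links.shape[1] != 2:
        raise ValueError("texture requires at least one 2D link")
    return np.einsum("ni,nj->ij", links, links) / n, n


def reciprocal_condition(m: np.ndarray) -> float:
    """Reciprocal 2-norm condition number of a texture matrix.

    1 for an isotropic link set, 0 when the links are degenerate
    (all parallel, or a single link).
    """
    w = np.linalg.eigvalsh(np.asarray(m, dtype=float))
    hi = float(np.max(np.abs(w)))
    if hi == 0.0:
        return 0.0
    return float(np.min(np.abs(w)) / hi)


def _invertible(m: np.ndarray) -> bool:
    w = np.linalg.eigvalsh(m)
    return float(np.min(w)) > _SINGULAR_RTOL * max(float(np.max(np.abs(w))), 1e-300)


def geometric_rate(
    links_t: np.ndarray, links_t1: np.ndarray, dt: float
) -> tuple[SymTensor2 | None, float | None]:
    """Deformation rate G and rotation rate Omega from conserved links.

    Fits the link displacement gradient L minimizing
    ``sum |dl - L m dt|^2`` over conserved half-links matched row by row,
    with the *midpoint* regressor ``m = (l + l')/2``; G = sym(L),
    Omega = antisym(L).  The midpoint form is unbiased under stationary
    centroid tracking noise (regressing on l(t) alone shares noise with
    dl and produces a spurious contraction) and is a Cayley discretization:
    for an affine map F it returns exactly (2/dt)(F - 1)(F + 1)^-1, which
    equals the generator L of F = exp(L dt) to third order in dt and is
    exactly antisymmetric for a pure rotation.  Returns (None, None) when
    the midpoint texture is singular.
    """
    l0 = np.atleast_2d(np.asarray(links_t, dtype=float))
    l1 = np.atleast_2d(np.asarray(links_t1, dtype=float))
    if l0.shape != l1.shape or l0.size == 0:
        return None, None
    mid = 0.5 * (l0 + l1)
    mc = np.einsum("ni,nj->ij", mid, mid)
    if not _invertible(mc):
        return None, None
    c = np.einsum("ni,nj->ij", l1 - l0, mid)
    L = c @ np.linalg.inv(mc) / dt
    g = SymTensor2.from_matrix(0.5 * (L + L.T))
    omega = 0.5 * (L[1, 0] - L[0, 1])
    return g, float(omega)


def topological_rate(
    appeared: np.ndarray,
    disappeared: np.ndarray,
    n_t: int,
    n_t1: int,
    m_mid: np.ndarray,
    dt: float,
) -> SymTensor2 | None:
    """Deformation rate of one topological process.

    ``appeared`` are the process's link vectors at t+dt, ``disappeared``
    those at t; ``n_t``/``n_t1`` the patch's total half-link counts and
    ``m_mid`` its midframe texture.  The texture change attributed to the
    process is

        T_P = [sum_app l'(x)l' - sum_dis l(x)l - dn_P * M] / (Nbar dt)

    with Nbar the mean link count and dn_P the process's net link-count
    change.  The last term is the renormalization of the per-link mean:
    a process that adds links dilutes the mean cell size (divisions gain
    their positive trace there, delaminations their negative one), while
    count-preserving T1s carry pure orientation exchange.  The rate is the
    texture-normalized symmetrization P = -(1/4)(M^-1 T_P + T_P M^-1);
    None when ``m_mid`` is singular.
    """
    if not _invertible(m_mid):
        return None
    nbar = 0.5 * (n_t + n_t1)
    t = np.zeros((2, 2))
    appeared = np.atleast_2d(np.asarray(appeared, dtype=float))
    disappeared = np.atleast_2d(np.asarray(disappeared, dtype=float))
    dn = 0
    if appeared.size:
        t += np.einsum("ni,nj->ij", appeared, appeared)
        dn += len(appeared)
    if disappeared.size:
        t -= np.einsum("ni,nj->ij", disappeared, disappeared)
        dn -= len(disappeared)
    t -= dn * m_mid
    t /= nbar * dt
    minv = np.linalg.inv(m_mid)
    return SymTensor2.from_matrix(-0.25 * (minv @ t + t @ minv))


def _spd_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return (v * np.sqrt(np.maximum(w, 0.0))) @ v.T


def shape_rate(
    texture_t: np.ndarray,
    texture_t1: np.ndarray,
    dt: float,
) -> SymTensor2 | None:
    """Cell size-and-shape change rate S from the total texture change.

    The per-link texture M is the statistical descriptor of mean cell size
    and shape, so S is the deformation rate carried by the change of M
    itself: the unique symmetric positive F with F M(t) F = M(t+dt) gives
    S = (2/dt)(F - 1)(F + 1)^-1 (the same Cayley discretization as the
    conserved-link fit).  Because M is a *per-link average*, link creation and
    destruction enter S through the renormalization (e.g. divisions halve
    the mean cell size), which is exactly what makes S + sum(P) telescope
    back to the conserved-link deformation rate G.  Exact (S = G) for
    rotation-free affine motion without topological change, even when the
    map does not commute with M.  None if either texture is degenerate.
    """
    a = np.asarray(texture_t, dtype=float)
    b = np.asarray(texture_t1, dtype=float)
    if not (_invertible(a) and _invertible(b)):
        return None
    ra = _spd_sqrt(a)
    ra_inv = np.linalg.inv(ra)
    f = ra_inv @ _spd_sqrt(ra @ b @ ra) @ ra_inv
    # Cayley form (2/dt)(F-1)(F+1)^-1: the same discretization as the
    # conserved-link fit, so S = G exactly on affine fixtures
    s = 2.0 * (f - np.eye(2)) @ np.linalg.inv(f + np.eye(2)) / dt
    return SymTensor2.from_matrix(0.5 * (s + s.T))


# ---------------------------------------------------------------------------
# per-interframe process rates
# ---------------------------------------------------------------------------

@dataclass
class ProcessRates:
    """The decomposition (G; S, D, R, A, N, C, J), rotation rate and
    bookkeeping for one patch and one interframe (or averaging window).

    Missing tensors (undefined measurements) are None.  ``residual`` is
    G - (S + D + R + A + N + C + J) with missing terms treated as zero;
    ``residual_rel`` normalizes its norm by max(|G|, sum |P|).
    """

    G: SymTensor2 | None = None
    S: SymTensor2 | None = None
    D: SymTensor2 | None = None
    R: SymTensor2 | None = None
    A: SymTensor2 | None = None
    N: SymTensor2 | None = None
    C: SymTensor2 | None = None
    J: SymTensor2 | None = None
    omega: float | None = None
    Do: SymTensor2 | None = None
    n_cells: int = 0
    n_links: int = 0
    n_conserved: int = 0
    weight: float = 1.0

    SYMBOLS = ("G", "S", "D", "R", "A", "N", "C", "J")

    @property
    def residual(self) -> SymTensor2 | None:
        if self.G is None:
            return None
        total = SymTensor2.zero()
        for sym in self.SYMBOLS[1:]:
            t = getattr(self, sym)
            if t is not None:
                total = total + t
        return self.G - total

    @property
    def residual_rel(self) -> float:
        res = self.residual
        if res is None:
            return np.nan
        scale = max(
            tensor_norm(self.G),
            sum(tensor_norm(getattr(self, s)) for s in self.SYMBOLS[1:]
                if getattr(self, s) is not None),
        )
        if scale == 0.0:
            return 0.0
        return tensor_norm(res) / scale


def balance_residual(rates: ProcessRates) -> SymTensor2 | None:
    """G - (S + D + R + A + N + C + J); see :class:`ProcessRates`."""
    return rates.residual


def measure_interframe(
    links0: pd.DataFrame,
    links1: pd.DataFrame,
    dt: float,
    sister_links: pd.DataFrame | None = None,
) -> ProcessRates:
    """Process rates from the classified half-links of one patch/interframe.

    ``links0``/``links1`` are classified half-link tables (columns c, k,
    lx, ly, category) restricted to the patch; ``dt`` in hours gives rates
    in h^-1.
    """
    n0, n1 = len(links0), len(links1)
    out = ProcessRates(n_links=n0)
    if n0 == 0 or n1 == 0:
        return out

    v0 = links0[["lx", "ly"]].to_numpy(dtype=float)
    v1 = links1[["lx", "ly"]].to_numpy(dtype=float)
    m0, _ = texture(v0)
    m1, _ = texture(v1)
    m_mid = 0.5 * (m0 + m1)

    # conserved links matched by ordered pair
    c0 = links0[links0["category"] == "conserved"]
    c1 = links1[links1["category"] == "conserved"]
    idx1 = {(c, k): i for i, (c, k) in enumerate(zip(c1["c"], c1["k"]))}
    rows0, rows1 = [], []
    for i, (c, k) in enumerate(zip(c0["c"], c0["k"])):
        j = idx1.get((c, k))
        if j is not None:
            rows0.append(i)
            rows1.append(j)
    lc0 = c0[["lx", "ly"]].to_numpy(dtype=float)[rows0]
    lc1 = c1[["lx", "ly"]].to_numpy(dtype=float)[rows1]
    out.n_conserved = len(lc0)

    out.G, out.omega = geometric_rate(lc0, lc1, dt)
    out.S = shape_rate(m0, m1, dt)

    for cat in PROCESSES:
        app = links1.loc[links1["category"] == cat, ["lx", "ly"]].to_numpy(float)
        dis = links0.loc[links0["category"] == cat, ["lx", "ly"]].to_numpy(float)
        if len(app) == 0 and len(dis) == 0:
            setattr(out, PROCESS_SYMBOL[cat], SymTensor2.zero())
        else:
            setattr(
                out, PROCESS_SYMBOL[cat],
                topological_rate(app, dis, n0, n1, m_mid, dt),
            )

    if sister_links is not None:
        out.Do = division_orientation(sister_links)
    return out


# ---------------------------------------------------------------------------
# Lagrangian patches
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """A Lagrangian cell group: grid id (m, n) and per-frame membership."""

    m: int
    n: int
    members: dict[int, set[int]] = field(default_factory=dict)


def lagrangian_patches(
    g0: FrameGraph,
    lineage: Lineage,
    n_frames: int,
    box_px: float = 128.0,
    overlap: float = 0.5,
) -> list[Patch]:
    """Initial-frame grid boxes with overlapping membership, then tracked.

    Cells are assigned on frame 0 by centroid position to every box of a
    square grid with the given overlap fraction (50% overlap puts each cell
    in up to 4 boxes).  Membership then follows the lineage: daughters
    inherit the patch of their mother; dying/fusing/exiting cells leave.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    stride = box_px * (1.0 - overlap)
    px = g0.pixel_size
    cents = {c: g0.centroids[c] / px for c in g0.valid}  # back to pixels
    if not cents:
        return []
    xy = np.array(list(cents.values()))
    x0, y0 = xy.min(axis=0)

    patches: dict[tuple[int, int], Patch] = {}
    for cell, (x, y) in cents.items():
        # all boxes [m*stride, m*stride + box) containing (x, y)
        m_hi = int(np.floor((x - x0) / stride))
        n_hi = int(np.floor((y - y0) / stride))
        span = int(np.ceil(box_px / stride))
        for m in range(m_hi - span + 1, m_hi + 1):
            if not (m * stride <= x - x0 < m * stride + box_px):
                continue
            for n in range(n_hi - span + 1, n_hi + 1):
                if not (n * stride <= y - y0 < n * stride + box_px):
                    continue
                p = patches.setdefault((m, n), Patch(m, n))
                p.members.setdefault(0, set()).add(cell)

    for p in patches.values():
        for f in range(1, n_frames):
            prev = p.members[f - 1]
            cur = set()
            for cell in prev:
                if lineage.alive(cell, f):
                    cur.add(cell)
                elif lineage.fate(cell) == "divides" and lineage.last_frame(cell) == f - 1:
                    cur.update(lineage.daughters[cell])
            # daughters born later than f would be caught next iteration;
            # verify inherited daughters are actually alive at f
            p.members[f] = {c for c in cur if lineage.alive(c, f)}
    return sorted(patches.values(), key=lambda p: (p.m, p.n))


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def patch_weights(
    a_r: np.ndarray,
    rc: np.ndarray,
    bulk: np.ndarray,
) -> np.ndarray:
    """Per-box weights wa = (a_norm * Rc_norm)^2 at one time point.

    ``a_r`` are relative areas (cell counts normalized to the tissue
    maximum in the Lagrangian description), ``rc`` the reciprocal condition
    numbers of the box textures, ``bulk`` a boolean mask of bulk boxes.
    Normalization references are the bulk minima, so wa = 1 over the bulk
    and decays toward the tissue boundary.  Raises when no box is bulk.
    """
    a_r = np.asarray(a_r, dtype=float)
    rc = np.asarray(rc, dtype=float)
    bulk = np.asarray(bulk, dtype=bool)
    if not bulk.any():
        raise ValueError("no bulk boxes to define weight normalization")
    a_bulk = float(a_r[bulk].min())
    rc_bulk = float(rc[bulk].min())
    a_norm = np.minimum(a_r / a_bulk, 1.0) if a_bulk > 0 else np.zeros_like(a_r)
    rc_norm = np.minimum(rc / rc_bulk, 1.0) if rc_bulk > 0 else np.zeros_like(rc)
    return (a_norm * rc_norm) ** 2


def stress_weights(a_r: np.ndarray, bulk: np.ndarray) -> np.ndarray:
    """Weights for stress maps: (a_norm)^2 only (no texture inversion)."""
    a_r = np.asarray(a_r, dtype=float)
    bulk = np.asarray(bulk, dtype=bool)
    if not bulk.any():
        raise ValueError("no bulk boxes to define weight normalization")
    a_bulk = float(a_r[bulk].min())
    if a_bulk <= 0:
        return np.zeros_like(a_r)
    return np.minimum(a_r / a_bulk, 1.0) ** 2


def bulk_mask(present: dict[tuple[int, int], bool], min_dist: int = 3) -> dict:
    """Bulk = patches at Chebyshev distance >= ``min_dist`` from any grid
    position without cells (Lagrangian definition)."""
    occupied = {mn for mn, ok in present.items() if ok}
    out = {}
    for (m, n) in present:
        if (m, n) not in occupied:
            out[(m, n)] = False
            continue
        d = min_dist
        for dm in range(-min_dist, min_dist + 1):
            for dn in range(-min_dist, min_dist + 1):
                if (m + dm, n + dn) not in occupied:
                    d = min(d, max(abs(dm), abs(dn)))
        out[(m, n)] = d >= min_dist
    return out


# ---------------------------------------------------------------------------
# movie-level driver
# ---------------------------------------------------------------------------

_TENSOR_COLS = ("G", "S", "D", "R", "A", "N", "C", "J", "Do")


def _rates_row(p: Patch, frame: int, rates: ProcessRates, wa: float) -> dict:
    row = {"m": p.m, "n": p.n, "frame": frame, "wa": wa,
           "omega": np.nan if rates.omega is None else rates.omega,
           "n_cells": rates.n_cells, "n_links": rates.n_links,
           "n_conserved": rates.n_conserved}
    for sym in _TENSOR_COLS:
        t = getattr(rates, sym)
        if t is None:
            row[f"{sym}_xx"] = row[f"{sym}_xy"] = row[f"{sym}_yy"] = np.nan
        else:
            row[f"{sym}_xx"], row[f"{sym}_xy"], row[f"{sym}_yy"] = t.xx, t.xy, t.yy
    res = rates.residual
    if res is None:
        row["resid_norm"] = np.nan
        row["resid_rel"] = np.nan
    else:
        row["resid_norm"] = tensor_norm(res)
        row["resid_rel"] = rates.residual_rel
    return row


def measure_movie(
    stack: np.ndarray,
    lineage: Lineage,
    pixel_size: float = 0.32,
    dt_min: float = 5.0,
    box_px: float = 128.0,
    overlap: float = 0.5,
    bulk_mode: str = "auto",
) -> pd.DataFrame:
    """Per-patch, per-interframe process rates for a tracked label stack.

    Returns a long-format table with one row per (m, n, interframe):
    tensor components of G, S, D, R, A, N, C, J, Do (h^-1), rotation rate,
    the balance residual, link counts and the patch weight wa.

    ``bulk_mode='strict'`` raises when no patch qualifies as bulk (three
    patches from the boundary); ``'auto'`` falls back to using the best
    available patch as the normalization reference, which keeps small
    synthetic movies measurable.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (frames, H, W) stack with >= 2 frames")
    n_frames = stack.shape[0]
    dt_h = dt_min / 60.0

    graphs = [
        build_adjacency(stack[f], pixel_size=pixel_size, frame=f)
        for f in range(n_frames)
    ]
    patches = lagrangian_patches(graphs[0], lineage, n_frames, box_px, overlap)
    if not patches:
        raise ValueError("no cells to assign to patches")

    rows = []
    for f in range(n_frames - 1):
        g0, g1 = graphs[f], graphs[f + 1]
        links0, links1 = classify_half_links(g0, g1, lineage)
        sisters = division_links(lineage, g1)

        per_patch = []
        a_r = np.zeros(len(patches))
        rc = np.zeros(len(patches))
        for i, p in enumerate(patches):
            mem0 = p.members.get(f, set()) & g0.valid
            mem1 = p.members.get(f + 1, set()) & g1.valid
            pl0 = links0[links0["c"].isin(mem0)]
            pl1 = links1[links1["c"].isin(mem1)]
            sl = sisters[sisters["mother"].isin(p.members.get(f, set()))]
            rates = measure_interframe(pl0, pl1, dt_h, sister_links=sl)
            rates.n_cells = len(mem0)
            per_patch.append(rates)
            a_r[i] = len(mem0)
            if len(pl0):
                m0, _ = texture(pl0[["lx", "ly"]].to_numpy(float))
                rc[i] = reciprocal_condition(m0)
        if a_r.max() > 0:
            a_r = a_r / a_r.max()

        present = {(p.m, p.n): a_r[i] > 0 for i, p in enumerate(patches)}
        bulk = np.array([bulk_mask(present)[(p.m, p.n)] for p in patches])
        if not bulk.any():
            if bulk_mode == "strict":
                raise ValueError(f"interframe {f}: no bulk patches")
            score = a_r * rc
            bulk = score >= score.max() * (1 - 1e-12)
        wa = patch_weights(a_r, rc, bulk)
        for p, rates, w in zip(patches, per_patch, wa):
            rows.append(_rates_row(p, f, rates, float(w)))
    return pd.DataFrame(rows)


def sliding_time_average(
    rates: pd.DataFrame,
    window_h: float = 2.0,
    dt_min: float = 5.0,
) -> pd.DataFrame:
    """Sliding wa-weighted time average of per-interframe rates.

    Windows of ``window_h`` hours are evaluated at every interframe (the
    standard '2 h every 5 min' convention).  Each tensor component, omega
    and the residual norm are averaged with the instantaneous weights
    wa(tau); the attached mean weight Wa is the plain average of wa over
    the window.  Windows whose weights are all zero yield NaN.
    """
    half = int(round(window_h * 60.0 / dt_min / 2))
    value_cols = [c for c in rates.columns
                  if c not in ("m", "n", "frame", "wa")]
    out_rows = []
    for (m, n), grp in rates.groupby(["m", "n"], sort=True):
        grp = grp.sort_values("frame").reset_index(drop=True)
        f = grp["frame"].to_numpy()
        w = grp["wa"].to_numpy(dtype=float)
        vals = grp[value_cols].to_numpy(dtype=float)
        for i in range(len(grp)):
            sel = (f >= f[i] - half) & (f <= f[i] + half)
            ww = w[sel]
            if ww.sum() == 0:
                avg = np.full(len(value_cols), np.nan)
            else:
                vv = vals[sel]
                avg = np.empty(len(value_cols))
                for j in range(len(value_cols)):
                    col = vv[:, j]
                    ok = ~np.isnan(col)
                    avg[j] = (
                        np.sum(ww[ok] * col[ok]) / np.sum(ww[ok])
                        if ww[ok].sum() > 0 else np.nan
                    )
            row = {"m": m, "n": n, "frame": int(f[i]),
                   "Wa": float(ww.mean()) if len(ww) else 0.0}
            row.update(dict(zip(value_cols, avg)))
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def window_average(rates: pd.DataFrame) -> pd.DataFrame:
    """Single wa-weighted average over the whole movie, per patch."""
    out = []
    value_cols = [c for c in rates.columns if c not in ("m", "n", "frame", "wa")]
    for (m, n), grp in rates.groupby(["m", "n"], sort=True):
        w = grp["wa"].to_numpy(dtype=float)
        row = {"m": m, "n": n, "Wa": float(w.mean())}
        for col in value_cols:
            v = grp[col].to_numpy(dtype=float)
            ok = ~np.isnan(v) & (w > 0)
            row[col] = float(np.sum(w[ok] * v[ok]) / np.sum(w[ok])) if ok.any() else np.nan
        out.append(row)
    return pd.DataFrame(out)


def rates_tensor(row: pd.Series, symbol: str) -> SymTensor2:
    """Extract one tensor from a long-format rates row."""
    return SymTensor2(
        float(row[f"{symbol}_xx"]), float(row[f"{symbol}_xy"]),
        float(row[f"{symbol}_yy"]),
    )
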