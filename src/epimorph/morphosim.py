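"""Synthetic tracked-movie generator: cellular Potts scenarios and exact
affine fixtures.

Each scenario produces a stack of label images with persistent cell ids, a
ground-truth lineage and an event log, emulating what a segmentation and
tracking pipeline would extract from a time-lapse of an epithelial
monolayer in which a *single* cell process dominates:

``divisions``       growing cells under an x-stretching force, each
                    dividing once along its long axis when its target area
                    has doubled (no regrowth afterwards);
``rearrangements``  an x-stretching force with free shape relaxation,
                    driving oriented T1 neighbour exchanges;
``shape_affine``    direct affine manipulation (uniform dilation then pure
                    convergence-extension), with no relaxation and no
                    topological change;
``delamination``    the target areas of half the cells decrease gradually
                    to zero, shrinking the patch to about half its size;
``integration``     the delamination movie played backwards;
``fusion``          random removal of cell-cell junctions (label merges)
                    followed by shape relaxation;
``flux``            gradual removal of successive external cell layers;
``rotation``        rigid anticlockwise rotation by 90 degrees;
``ce_roundtrip``    convergence-extension along x then the inverse along
                    y, returning to the initial pattern.

The Potts dynamics follows a simple energy: uniform interfacial energy per
unlike 8-neighbour pair, a quadratic area constraint toward each cell's
target area, and (where a force is applied) a potential rewarding pixels
far from the patch centre along x.  One Monte-Carlo step visits every
lattice pixel once in random order, proposes copying a random 8-neighbour's
label, accepts energy-decreasing copies and energy-increasing ones with a
constant *fluctuation allowance* probability.  All randomness is pre-drawn
from one seeded generator, so a fixed seed reproduces output bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numba
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree

from .cellgraph import Lineage

SCENARIOS = (
    "divisions",
    "rearrangements",
    "shape_affine",
    "delamination",
    "integration",
    "fusion",
    "flux",
    "rotation",
    "ce_roundtrip",
)


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic movie.

    Defaults mirror the simulation conditions used for validation at full
    scale (241 frames of 800x800 pixels, 50 Monte-Carlo steps between
    successive images); tests run the same scenarios at reduced lattice
    size and frame count.
    """

    scenario: str = "shape_affine"
    frames: int = 241
    steps_per_frame: int = 50
    size: int = 800
    seed: int = 0
    n_cells: int = 100
    # Potts energy parameters, chosen empirically on the energy scale
    # j_cell = 1
    j_cell: float = 1.0
    j_medium: float = 1.6
    lambda_area: float = 0.4
    fluctuation_allowance: float = 0.05
    force_x: float = 1.2
    # affine fixture per-interframe rates (fraction per interframe)
    dilation_rate: float = 8.3e-4
    ce_rate: float = 8.3e-4

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.frames < 2:
            raise ValueError("a movie needs at least 2 frames")


@dataclass
class SimulationResult:
    stack: np.ndarray          # (frames, H, W) uint32 labels, 0 = medium
    lineage: Lineage
    events: pd.DataFrame       # columns: interframe, event, cell, partner, d1, d2
    manifest: dict

    def save(self, outdir) -> None:
        import tifffile
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "labels.tif", self.stack,
                         photometric="minisblack")
        self.lineage.to_csv(out / "lineage.csv")
        self.events.to_csv(out / "events.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


EVENT_COLUMNS = ["interframe", "event", "cell", "partner", "d1", "d2"]


def rate_unit_conversion(
    rate_per_hour: float, interframes: int, duration_hours: float
) -> float:
    """Convert an experimental rate (h^-1) to the per-interframe rate of a
    simulated movie spanning ``duration_hours`` over ``interframes`` steps.

    E.g. 1e-2 h^-1 over a 20 h, 240-interframe movie is 8.3e-4 per
    interframe.
    """
    if interframes < 1 or duration_hours <= 0:
        raise ValueError("need interframes >= 1 and a positive duration")
    return rate_per_hour * duration_hours / interframes


# ---------------------------------------------------------------------------
# initial tilings
# ---------------------------------------------------------------------------

def hex_seeds(radius: float, spacing: float, rng, jitter: float = 0.15):
    """Jittered hexagonal seed points within a disc of the given radius."""
    pts = []
    ny = int(np.ceil(2 * radius / (spacing * np.sqrt(3) / 2))) + 2
    nx = int(np.ceil(2 * radius / spacing)) + 2
    for iy in range(-ny, ny + 1):
        for ix in range(-nx, nx + 1):
            x = ix * spacing + (iy % 2) * spacing / 2
            y = iy * spacing * np.sqrt(3) / 2
            if x * x + y * y <= radius * radius:
                pts.append((x, y))
    pts = np.array(pts, dtype=float)
    pts += rng.uniform(-jitter * spacing, jitter * spacing, size=pts.shape)
    return pts


def voronoi_polygons(seeds: np.ndarray, keep_radius: float):
    """Finite Voronoi polygons for the seeds within ``keep_radius``.

    Seeds outside act as a guard ring so every kept region is bounded.
    Returns (kept seed indices, list of (K, 2) vertex arrays).
    """
    vor = Voronoi(seeds)
    keep, polys = [], []
    for i, s in enumerate(seeds):
        if np.hypot(*s) > keep_radius:
            continue
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        keep.append(i)
        polys.append(vor.vertices[region])
    return keep, polys


def rasterize_polygons(polys, shape, labels=None) -> np.ndarray:
    """Rasterize polygons (x, y vertex arrays in pixel units) to a label
    image; later polygons overwrite earlier ones on shared-edge pixels."""
    from skimage.draw import polygon as draw_polygon

    out = np.zeros(shape, dtype=np.uint32)
    if labels is None:
        labels = range(1, len(polys) + 1)
    for lab, poly in zip(labels, polys):
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
        out[rr, cc] = lab
    return out


def voronoi_labels(seeds: np.ndarray, shape, mask_radius: float, center) -> np.ndarray:
    """Nearest-seed label image inside a disc, medium (0) outside."""
    h, w = shape
    yy, xx = np.indices((h, w))
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    tree = cKDTree(seeds)
    _, idx = tree.query(pts)
    lab = (idx + 1).astype(np.uint32).reshape(h, w)
    rr = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    lab[rr > mask_radius**2] = 0
    return lab


# ---------------------------------------------------------------------------
# Potts Monte-Carlo kernel
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _ring_arcs(ring_is_a):
    """Number of connected arcs of True values in a cyclic 8-ring."""
    arcs = 0
    for i in range(8):
        if ring_is_a[i] and not ring_is_a[i - 1]:
            arcs += 1
    return arcs


@numba.njit(cache=True)
def metropolis_sweep(
    lat, area, target,
    order, nbr_choice, acc_rand,
    j_cell, j_medium, lam, p_acc, fx, cx,
):
    """One Monte-Carlo step: every pixel visited once in random order.

    ``order`` is a permutation of the flat pixel indices, ``nbr_choice``
    a uint8 array picking one of the 8 neighbours per visit, ``acc_rand``
    uniform(0,1) draws for the fluctuation-allowance acceptance.  The
    lattice boundary behaves as medium (the cell patch sits in its
    interior and never reaches it).  Returns the number of accepted
    copies.
    """
    h, w = lat.shape
    dy = np.array([-1, -1, -1, 0, 1, 1, 1, 0], dtype=np.int64)
    dx = np.array([-1, 0, 1, 1, 1, 0, -1, -1], dtype=np.int64)
    scale2 = float(w) * float(w)
    accepted = 0
    for t in range(order.shape[0]):
        p = order[t]
        py = p // w
        px = p - py * w
        k = nbr_choice[t]
        qy = py + dy[k]
        qx = px + dx[k]
        if qy < 0 or qy >= h or qx < 0 or qx >= w:
            continue
        a = lat[py, px]
        b = lat[qy, qx]
        if a == b:
            continue
        # connectivity guard for the losing cell a
        if a != 0:
            if area[a] == 1:
                if target[a] >= 1.0:
                    continue
            else:
                ring = np.empty(8, dtype=numba.boolean)
                for i in range(8):
                    ry = py + dy[i]
                    rx = px + dx[i]
                    if ry < 0 or ry >= h or rx < 0 or rx >= w:
                        ring[i] = False
                    else:
                        ring[i] = lat[ry, rx] == a
                if _ring_arcs(ring) > 1:
                    continue
        # interfacial energy change over the 8-neighbourhood
        de = 0.0
        for i in range(8):
            ry = py + dy[i]
            rx = px + dx[i]
            if ry < 0 or ry >= h or rx < 0 or rx >= w:
                c = numba.uint32(0)
            else:
                c = lat[ry, rx]
            if a != c:
                de -= j_medium if (a == 0 or c == 0) else j_cell
            if b != c:
                de += j_medium if (b == 0 or c == 0) else j_cell
        # area constraint
        if a != 0:
            da = area[a] - target[a]
            de += lam * (-2.0 * da + 1.0)  # (A-1-T)^2 - (A-T)^2
        if b != 0:
            db = area[b] - target[b]
            de += lam * (2.0 * db + 1.0)
        # stretching potential along x (cells only)
        if fx != 0.0:
            pot = -fx * (px - cx) * (px - cx) / scale2
            if a != 0:
                de -= pot
            if b != 0:
                de += pot
        if de < 0.0 or acc_rand[t] < p_acc:
            lat[py, px] = b
            if a != 0:
                area[a] -= 1
            if b != 0:
                area[b] += 1
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# Potts driver
# ---------------------------------------------------------------------------

class PottsTissue:
    """A Potts lattice of labelled cells with target areas and lineage."""

    def __init__(self, cfg: ScenarioConfig, rng: np.random.Generator,
                 n_layers_margin: float = 0.30):
        self.cfg = cfg
        self.rng = rng
        size = cfg.size
        self.center = (size / 2.0, size / 2.0)
        radius = size * n_layers_margin
        spacing = radius * np.sqrt(2 * np.pi / (np.sqrt(3) * cfg.n_cells))
        seeds = hex_seeds(radius - spacing / 2, spacing, rng)
        self.lat = voronoi_labels(
            seeds + np.array(self.center), (size, size), radius, self.center
        )
        n0 = int(self.lat.max())
        cap = 4 * n0 + 8
        self.area = np.zeros(cap, dtype=np.int64)
        counts = np.bincount(self.lat.ravel(), minlength=n0 + 1)
        self.area[: n0 + 1] = counts
        self.init_area = float(np.mean(counts[1:][counts[1:] > 0]))
        self.target = np.zeros(cap, dtype=np.float64)
        self.target[1 : n0 + 1] = counts[1:]
        self.next_label = n0 + 1
        self.records = {
            i: dict(cell_id=i, mother_id=-1, first_frame=0, last_frame=0,
                    fate="survives", fate_partner=-1, origin="initial")
            for i in range(1, n0 + 1)
        }
        self.events: list[dict] = []
        self.force_x = 0.0

    # -- bookkeeping ------------------------------------------------------

    def alive_labels(self):
        return [i for i in range(1, self.next_label) if self.area[i] > 0]

    def log(self, interframe, event, cell, partner=-1, d1=-1, d2=-1):
        self.events.append(dict(interframe=interframe, event=event,
                                cell=cell, partner=partner, d1=d1, d2=d2))

    def sweep(self, n: int = 1):
        cfg = self.cfg
        npix = self.lat.size
        for _ in range(n):
            order = self.rng.permutation(npix).astype(np.int64)
            nbr = self.rng.integers(0, 8, npix, dtype=np.uint8)
            acc = self.rng.random(npix)
            metropolis_sweep(
                self.lat, self.area, self.target, order, nbr, acc,
                cfg.j_cell, cfg.j_medium, cfg.lambda_area,
                cfg.fluctuation_allowance, self.force_x, self.center[0],
            )

    def repair_connectivity(self):
        """Reassign stray 4-disconnected fragments to a neighbouring label."""
        from scipy import ndimage

        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        objects = ndimage.find_objects(self.lat)
        for lab in self.alive_labels():
            sl = objects[lab - 1] if lab - 1 < len(objects) else None
            if sl is None:
                continue
            sl = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in sl)
            sub = self.lat[sl]
            mask = sub == lab
            comp, ncomp = ndimage.label(mask, structure=structure)
            if ncomp <= 1:
                continue
            sizes = ndimage.sum_labels(mask, comp, index=range(1, ncomp + 1))
            keep = int(np.argmax(sizes)) + 1
            for ci in range(1, ncomp + 1):
                if ci == keep:
                    continue
                ys, xs = np.nonzero(comp == ci)
                for y, x in zip(ys, xs):
                    votes = {}
                    for ddy, ddx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        yy, xx = y + ddy, x + ddx
                        if 0 <= yy < sub.shape[0] and 0 <= xx < sub.shape[1]:
                            v = int(sub[yy, xx])
                            if v != lab:
                                votes[v] = votes.get(v, 0) + 1
                    new = max(votes, key=votes.get) if votes else 0
                    sub[y, x] = new
                    self.area[lab] -= 1
                    if new != 0:
                        self.area[new] += 1

    def divide(self, lab: int, interframe: int):
        """Split a cell through its centroid, perpendicular to its long axis."""
        ys, xs = np.nonzero(self.lat == lab)
        if len(ys) < 4:
            return
        cy, cx = ys.mean(), xs.mean()
        dyx = np.stack([xs - cx, ys - cy], axis=1)
        cov = dyx.T @ dyx / len(ys)
        w, v = np.linalg.eigh(cov)
        major = v[:, int(np.argmax(w))]
        side = dyx @ major > 0
        d1, d2 = self.next_label, self.next_label + 1
        self.next_label += 2
        if self.next_label >= len(self.area):
            self.area = np.concatenate([self.area, np.zeros_like(self.area)])
            self.target = np.concatenate([self.target, np.zeros_like(self.target)])
        self.lat[ys[side], xs[side]] = d1
        self.lat[ys[~side], xs[~side]] = d2
        self.area[d1] = int(side.sum())
        self.area[d2] = int((~side).sum())
        self.area[lab] = 0
        half = self.target[lab] / 2.0
        self.target[d1] = half
        self.target[d2] = half
        self.target[lab] = 0.0
        rec = self.records[lab]
        rec["fate"] = "divides"
        rec["last_frame"] = interframe
        for d in (d1, d2):
            self.records[d] = dict(
                cell_id=d, mother_id=lab, first_frame=interframe + 1,
                last_frame=interframe + 1, fate="survives", fate_partner=-1,
                origin="division",
            )
        self.log(interframe, "divides", lab, d1=d1, d2=d2)

    def snapshot(self, frame: int) -> np.ndarray:
        for lab in self.alive_labels():
            rec = self.records[lab]
            if rec["fate"] == "survives":
                rec["last_frame"] = frame
        return self.lat.astype(np.uint32).copy()

    def lineage(self) -> Lineage:
        return Lineage(pd.DataFrame(list(self.records.values())))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _events_frame(events) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.DataFrame(events)[EVENT_COLUMNS]


def _run_potts_scenario(cfg: ScenarioConfig) -> SimulationResult:
    rng = np.random.default_rng(cfg.seed)
    # growing/stretching scenarios need extra margin to the image border
    margin = 0.22 if cfg.scenario == "divisions" else 0.30
    tissue = PottsTissue(cfg, rng, n_layers_margin=margin)
    nif = cfg.frames - 1
    scenario = cfg.scenario

    if scenario in ("divisions", "rearrangements"):
        tissue.force_x = cfg.force_x
    divided: set[int] = set()
    if scenario == "divisions":
        labels0 = tissue.alive_labels()
        async_off = {lab: rng.uniform(0.0, 0.4) for lab in labels0}
        init_target = {lab: tissue.target[lab] for lab in labels0}
        growth_end = 0.75  # fraction of the movie over which targets double
    if scenario == "delamination":
        labels0 = tissue.alive_labels()
        half = rng.permutation(labels0)[: len(labels0) // 2]
        shrink = set(int(v) for v in half)
        init_target = {lab: tissue.target[lab] for lab in shrink}
        # staggered, individually fast shrinkage (a few interframes each),
        # so no single interframe carries a large texture jump
        dur = max(3, nif // 8)
        start = {
            lab: int(v) for lab, v in zip(
                sorted(shrink),
                rng.uniform(0.05 * nif, max(0.75 * nif - dur, 1), len(shrink)),
            )
        }
    if scenario == "fusion":
        n_fusions = max(2, cfg.n_cells // 6)
        fusion_frames = set(
            int(v) for v in np.linspace(1, max(nif - 2, 1), n_fusions).astype(int)
        )
    if scenario == "flux":
        per_frame = max(1, cfg.n_cells // (2 * nif) + 1)

    # brief initial relaxation so frame 0 is an equilibrated pattern
    tissue.sweep(cfg.steps_per_frame)
    tissue.repair_connectivity()

    frames = [tissue.snapshot(0)]
    for f in range(nif):
        phase = (f + 1) / nif
        if scenario == "divisions":
            for lab in list(tissue.alive_labels()):
                if lab not in async_off or lab in divided:
                    continue
                progress = min(phase / growth_end, 1.0) + async_off[lab]
                tissue.target[lab] = init_target[lab] * min(1.0 + progress, 2.0)
                if tissue.target[lab] >= 2.0 * init_target[lab] - 1e-9:
                    tissue.divide(lab, f)
                    divided.add(lab)
        elif scenario == "delamination":
            for lab in shrink:
                if tissue.area[lab] == 0:
                    continue
                frac = np.clip((f - start[lab]) / dur, 0.0, 1.0)
                tissue.target[lab] = init_target[lab] * (1.0 - frac)
        elif scenario == "fusion" and f in fusion_frames:
            pairs = _adjacent_pairs(tissue.lat)
            alivepairs = [
                (c, k) for c, k in pairs
                if tissue.records[c]["fate"] == "survives"
                and tissue.records[k]["fate"] == "survives"
            ]
            if alivepairs:
                c, k = alivepairs[rng.integers(len(alivepairs))]
                tissue.lat[tissue.lat == k] = c
                tissue.area[c] += tissue.area[k]
                tissue.area[k] = 0
                tissue.target[c] += tissue.target[k]
                tissue.target[k] = 0.0
                rec = tissue.records[k]
                rec["fate"] = "fuses"
                rec["fate_partner"] = c
                rec["last_frame"] = f
                tissue.log(f, "fuses", k, partner=c)
        elif scenario == "flux" and f >= 1:
            outer = [
                lab for lab in _medium_adjacent(tissue.lat)
                if tissue.records[lab]["fate"] == "survives"
            ]
            n_alive = len(tissue.alive_labels())
            if n_alive <= max(8, cfg.n_cells // 3):
                outer = []
            for lab in outer[: per_frame]:
                tissue.lat[tissue.lat == lab] = 0
                tissue.area[lab] = 0
                tissue.target[lab] = 0.0
                rec = tissue.records[lab]
                rec["fate"] = "exits"
                rec["last_frame"] = f
                tissue.log(f, "exits", lab)

        tissue.sweep(cfg.steps_per_frame)
        tissue.repair_connectivity()
        if scenario == "delamination":
            for lab in shrink:
                rec = tissue.records[lab]
                if rec["fate"] != "survives":
                    continue
                # a fully shrunk cell lingering at a few pixels has closed
                # its apical surface: remove it outright
                if 0 < tissue.area[lab] <= 4 and tissue.target[lab] == 0.0 \
                        and f > start[lab] + dur:
                    ys, xs = np.nonzero(tissue.lat == lab)
                    for y, x in zip(ys, xs):
                        votes = {}
                        for ddy, ddx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                            v = int(tissue.lat[y + ddy, x + ddx])
                            if v != lab:
                                votes[v] = votes.get(v, 0) + 1
                        new = max(votes, key=votes.get) if votes else 0
                        tissue.lat[y, x] = new
                        if new != 0:
                            tissue.area[new] += 1
                    tissue.area[lab] = 0
                if tissue.area[lab] == 0:
                    rec["fate"] = "delaminates"
                    tissue.log(f, "delaminates", lab)
        frames.append(tissue.snapshot(f + 1))

    stack = np.stack(frames)
    manifest = dict(asdict(cfg), generator="potts")
    return SimulationResult(stack, tissue.lineage(), _events_frame(tissue.events),
                            manifest)


def _adjacent_pairs(lat: np.ndarray):
    pairs = set()
    for a, b in ((lat[:, :-1], lat[:, 1:]), (lat[:-1, :], lat[1:, :])):
        diff = (a != b) & (a != 0) & (b != 0)
        if diff.any():
            for p, q in np.unique(np.stack([a[diff], b[diff]], 1), axis=0):
                pairs.add((int(min(p, q)), int(max(p, q))))
    return sorted(pairs)


def _medium_adjacent(lat: np.ndarray):
    out = set()
    for a, b in ((lat[:, :-1], lat[:, 1:]), (lat[:-1, :], lat[1:, :])):
        edge = (a == 0) & (b != 0)
        out.update(int(v) for v in np.unique(b[edge]))
        edge = (b == 0) & (a != 0)
        out.update(int(v) for v in np.unique(a[edge]))
    return sorted(out)


# ---------------------------------------------------------------------------
# affine fixtures
# ---------------------------------------------------------------------------

def affine_fixture(
    polys: list[np.ndarray],
    interframe_maps: list[np.ndarray],
    shape: tuple[int, int],
    center: tuple[float, float],
) -> np.ndarray:
    """Label stack from exact affine transforms of a polygonal tiling.

    ``interframe_maps[f]`` is the 2x2 matrix applied between frames f and
    f+1 about ``center``; vertices are transformed exactly and only then
    re-rasterized, so no cell shape relaxation and no topological change
    occurs.  Raises on a singular map.
    """
    for m in interframe_maps:
        if abs(np.linalg.det(np.asarray(m, float))) < 1e-12:
            raise ValueError("affine map is not invertible")
    c = np.asarray(center, dtype=float)
    cum = np.eye(2)
    frames = [rasterize_polygons(polys, shape)]
    for m in interframe_maps:
        cum = np.asarray(m, float) @ cum
        moved = [(p - c) @ cum.T + c for p in polys]
        frames.append(rasterize_polygons(moved, shape))
    return np.stack(frames)


def _fixture_tiling(cfg: ScenarioConfig, rng):
    size = cfg.size
    radius = size * 0.30
    spacing = radius * np.sqrt(2 * np.pi / (np.sqrt(3) * cfg.n_cells))
    seeds = hex_seeds(radius + 3 * spacing, spacing, rng)
    _, polys = voronoi_polygons(seeds, radius)
    center = (size / 2.0, size / 2.0)
    return [p + np.asarray(center) for p in polys], center


def _trivial_lineage(stack: np.ndarray) -> Lineage:
    ids = np.unique(stack[0])
    ids = ids[ids != 0]
    last = stack.shape[0] - 1
    return Lineage(pd.DataFrame([
        dict(cell_id=int(i), mother_id=-1, first_frame=0, last_frame=last,
             fate="survives", fate_partner=-1, origin="initial")
        for i in ids
    ]))


def _run_affine_scenario(cfg: ScenarioConfig) -> SimulationResult:
    rng = np.random.default_rng(cfg.seed)
    polys, center = _fixture_tiling(cfg, rng)
    nif = cfg.frames - 1
    g, e = cfg.dilation_rate, cfg.ce_rate
    if cfg.scenario == "shape_affine":
        # constant-rate maps: exp(L) per interframe
        ndil = nif // 2
        maps = [np.eye(2) * np.exp(g)] * ndil
        maps += [np.diag([np.exp(e), np.exp(-e)])] * (nif - ndil)
    elif cfg.scenario == "rotation":
        phi = (np.pi / 2) / nif
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        maps = [rot] * nif
    elif cfg.scenario == "ce_roundtrip":
        nhalf = nif // 2
        fwd = np.diag([1.0 + e, 1.0 / (1.0 + e)])
        maps = [fwd] * nhalf + [np.linalg.inv(fwd)] * (nif - nhalf)
    else:  # pragma: no cover
        raise ValueError(cfg.scenario)
    stack = affine_fixture(polys, maps, (cfg.size, cfg.size), center)
    manifest = dict(asdict(cfg), generator="affine")
    return SimulationResult(stack, _trivial_lineage(stack),
                            _events_frame([]), manifest)


def _run_integration(cfg: ScenarioConfig) -> SimulationResult:
    base = ScenarioConfig(**{**asdict(cfg), "scenario": "delamination"})
    res = _run_potts_scenario(base)
    stack = res.stack[::-1].copy()
    last = stack.shape[0] - 1
    rows = []
    for _, r in res.lineage.table.iterrows():
        first = last - int(r["last_frame"])
        lastf = last - int(r["first_frame"])
        origin = "initial" if first == 0 else "integration"
        rows.append(dict(
            cell_id=int(r["cell_id"]), mother_id=-1, first_frame=first,
            last_frame=lastf, fate="survives", fate_partner=-1, origin=origin,
        ))
    ev = res.events.copy()
    if len(ev):
        ev["interframe"] = last - 1 - ev["interframe"].astype(int)
        ev["event"] = "integrates"
    manifest = dict(asdict(cfg), generator="potts-reversed")
    return SimulationResult(stack, Lineage(pd.DataFrame(rows)), ev, manifest)


def run_scenario(config: ScenarioConfig) -> SimulationResult:
    """Generate one synthetic tracked movie; see module docstring."""
    if config.scenario in ("shape_affine", "rotation", "ce_roundtrip"):
        return _run_affine_scenario(config)
    if config.scenario == "integration":
        return _run_integration(config)
    return _run_potts_scenario(config)
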