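"""Cell adjacency graphs, half-links, and their interframe classification.

A tracked movie is a stack of integer label images (one persistent label per
cell, background 0) plus a lineage table.  From each frame we build the cell
adjacency graph under 4-connectivity and enumerate *half-links*: directed
centroid-to-centroid vectors c -> k, listed independently from k -> c.

Between two consecutive frames every half-link of either frame is assigned
exactly one category:

- ``conserved``     -- same ordered (c, k) pair present in both frames;
- ``division``      -- the base cell divides, or is a newborn daughter
                       (the daughter-daughter link is additionally flagged
                       as a *sister* link);
- ``delamination``  -- the base cell leaves the monolayer apically, or the
                       link appears between former neighbours of a cell
                       that delaminated;
- ``integration``   -- a cell newly joins the monolayer from the basal side;
- ``fusion``        -- two cells merge;
- ``flux``          -- the link crosses the boundary of the field of view
                       (a cell enters or exits the image);
- ``rearrangement`` -- any remaining appearing/disappearing link between
                       persisting cells (T1 neighbour exchanges).

When the base cell and the neighbour each undergo an event, the base cell's
event decides, so c -> k and k -> c may carry different categories.  Ties on
shared-neighbour explanations are resolved by the precedence
division > delamination > fusion > integration > flux > rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

CATEGORIES = (
    "conserved",
    "division",
    "rearrangement",
    "delamination",
    "integration",
    "fusion",
    "flux",
)

#: precedence used when several dead/merged neighbours could explain a link
_EVENT_PRECEDENCE = {"division": 0, "delamination": 1, "fusion": 2,
                     "integration": 3, "flux": 4}

LINK_COLUMNS = ["frame", "c", "k", "lx", "ly", "category", "fourfold", "sister"]


class LineageError(ValueError):
    """Raised when the lineage table contradicts the label images."""


# ---------------------------------------------------------------------------
# lineage table
# ---------------------------------------------------------------------------

class Lineage:
    """Cell life histories: birth/death frames, mothers, fates.

    Wraps a table with columns (cell_id, mother_id, first_frame, last_frame,
    fate, fate_partner) and an optional ``origin`` column distinguishing how
    a cell appeared (initial / division / integration / flux).  Without an
    ``origin`` column, a cell born after frame 0 with no mother is treated
    as an integration event unless it first appears touching the image
    border (then: flux).
    """

    FATES = ("survives", "divides", "delaminates", "fuses", "exits")
    ORIGINS = ("initial", "division", "integration", "flux")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        required = {"cell_id", "first_frame", "last_frame", "fate"}
        missing = required - set(df.columns)
        if missing:
            raise LineageError(f"lineage table lacks columns {sorted(missing)}")
        if "mother_id" not in df:
            df["mother_id"] = -1
        if "fate_partner" not in df:
            df["fate_partner"] = -1
        df["mother_id"] = df["mother_id"].fillna(-1).astype(int)
        df["fate_partner"] = df["fate_partner"].fillna(-1).astype(int)
        bad = set(df["fate"]) - set(self.FATES)
        if bad:
            raise LineageError(f"unknown fates {sorted(bad)}")
        self.table = df.set_index("cell_id", drop=False)
        self._first = df.set_index("cell_id")["first_frame"].to_dict()
        self._last = df.set_index("cell_id")["last_frame"].to_dict()
        self._fate = df.set_index("cell_id")["fate"].to_dict()
        self._mother = df.set_index("cell_id")["mother_id"].to_dict()
        if "origin" in df:
            self._origin = df.set_index("cell_id")["origin"].to_dict()
        else:
            self._origin = {}
        # daughters: mother -> [d1, d2]
        self.daughters: dict[int, list[int]] = {}
        for cid, mid in self._mother.items():
            if mid >= 0:
                self.daughters.setdefault(mid, []).append(cid)
        for mid, ds in self.daughters.items():
            if self._fate.get(mid) != "divides" or len(ds) != 2:
                raise LineageError(
                    f"cell {mid} has daughters {ds} but fate "
                    f"{self._fate.get(mid)!r}; a division needs exactly 2"
                )

    def alive(self, cell: int, frame: int) -> bool:
        return self._first.get(cell, 1 << 30) <= frame <= self._last.get(cell, -1)

    def fate(self, cell: int) -> str:
        return self._fate[cell]

    def mother(self, cell: int) -> int:
        return self._mother.get(cell, -1)

    def origin(self, cell: int, touches_border: bool = False) -> str:
        if cell in self._origin:
            return self._origin[cell]
        if self._mother.get(cell, -1) >= 0:
            return "division"
        if self._first.get(cell, 0) == 0:
            return "initial"
        return "flux" if touches_border else "integration"

    def first_frame(self, cell: int) -> int:
        return self._first[cell]

    def last_frame(self, cell: int) -> int:
        return self._last[cell]

    def sister(self, cell: int) -> int:
        mid = self._mother.get(cell, -1)
        if mid < 0:
            return -1
        ds = self.daughters[mid]
        return ds[1] if ds[0] == cell else ds[0]

    @classmethod
    def from_csv(cls, path) -> "Lineage":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-frame geometry
# ---------------------------------------------------------------------------

@dataclass
class FrameGraph:
    """Adjacency, centroids and areas for one label image.

    Centroids are in um, in image coordinates (x rightward along columns,
    y downward along rows).  ``border`` holds cells touching the image
    border (ill-defined centroids, excluded from all link calculations);
    ``valid`` the remaining cells.  ``dropped_border_links`` counts the
    (valid, border) adjacencies excluded, for flux bookkeeping.
    """

    frame: int
    pixel_size: float
    centroids: dict[int, np.ndarray]
    areas_px: dict[int, int]
    neighbors: dict[int, set[int]]
    border: set[int]
    fourfold: set[frozenset[int]] = field(default_factory=set)
    dropped_border_links: int = 0

    @property
    def cells(self) -> set[int]:
        return set(self.centroids)

    @property
    def valid(self) -> set[int]:
        return self.cells - self.border

    def link_vector(self, c: int, k: int) -> np.ndarray:
        return self.centroids[k] - self.centroids[c]

    def valid_pairs(self) -> set[tuple[int, int]]:
        """Ordered (c, k) pairs with both cells valid."""
        out = set()
        for c, ks in self.neighbors.items():
            if c in self.border:
                continue
            for k in ks:
                if k not in self.border:
                    out.add((c, k))
        return out


def build_adjacency(
    label_image: np.ndarray,
    pixel_size: float = 1.0,
    frame: int = 0,
    check_connected: bool = True,
) -> FrameGraph:
    """Build the cell adjacency graph of one label image.

    Two cells are neighbours iff their regions share at least one boundary
    pixel pair under 4-connectivity; corner-touching cells are not
    neighbours (four-fold vertex configurations are recorded separately).
    Background (0) is no cell.  Rejects frames containing a label split
    into several connected regions.
    """
    lab = np.asarray(label_image)
    if lab.ndim != 2:
        raise ValueError("label image must be 2D")
    ids = np.unique(lab)
    ids = ids[ids != 0]

    if check_connected:
        bad = []
        objects = ndimage.find_objects(lab)
        for i in ids:
            sl = objects[int(i) - 1] if int(i) - 1 < len(objects) else None
            if sl is None:
                continue
            mask = lab[sl] == i
            _, ncomp = ndimage.label(mask, structure=np.array(
                [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
            if ncomp != 1:
                bad.append(int(i))
        if bad:
            raise ValueError(
                f"frame {frame}: labels {bad} are not single connected regions"
            )

    # centroids and areas via bincount
    nmax = int(lab.max()) + 1 if len(ids) else 1
    flat = lab.ravel()
    counts = np.bincount(flat, minlength=nmax)
    yy, xx = np.indices(lab.shape)
    sum_x = np.bincount(flat, weights=xx.ravel(), minlength=nmax)
    sum_y = np.bincount(flat, weights=yy.ravel(), minlength=nmax)
    centroids = {}
    areas = {}
    for i in ids:
        i = int(i)
        a = int(counts[i])
        centroids[i] = pixel_size * np.array([sum_x[i] / a, sum_y[i] / a])
        areas[i] = a

    # 4-connectivity adjacency from horizontal/vertical differing pairs
    neighbors: dict[int, set[int]] = {int(i): set() for i in ids}
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        diff = (a != b) & (a != 0) & (b != 0)
        pairs = np.unique(
            np.stack([a[diff], b[diff]], axis=1), axis=0
        ) if diff.any() else []
        for p, q in pairs:
            neighbors[int(p)].add(int(q))
            neighbors[int(q)].add(int(p))

    # border cells touch the image frame
    border = set()
    for edge in (lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]):
        border.update(int(v) for v in np.unique(edge) if v != 0)

    # four-fold vertices: 2x2 blocks with 4 distinct non-zero labels
    fourfold: set[frozenset[int]] = set()
    blocks = np.stack(
        [lab[:-1, :-1], lab[:-1, 1:], lab[1:, :-1], lab[1:, 1:]], axis=-1
    )
    nz = np.all(blocks != 0, axis=-1)
    if nz.any():
        cand = blocks[nz]
        distinct = (
            (cand[:, 0] != cand[:, 1])
            & (cand[:, 0] != cand[:, 2])
            & (cand[:, 0] != cand[:, 3])
            & (cand[:, 1] != cand[:, 2])
            & (cand[:, 1] != cand[:, 3])
            & (cand[:, 2] != cand[:, 3])
        )
        for row in cand[distinct]:
            fourfold.add(frozenset(int(v) for v in row))

    dropped = sum(
        1
        for c, ks in neighbors.items()
        if c not in border
        for k in ks
        if k in border
    )
    return FrameGraph(
        frame=frame,
        pixel_size=pixel_size,
        centroids=centroids,
        areas_px=areas,
        neighbors=neighbors,
        border=border,
        fourfold=fourfold,
        dropped_border_links=dropped,
    )


def exclude_boundary(graph: FrameGraph) -> set[int]:
    """Valid (non-border) cells of a frame; see :class:`FrameGraph`."""
    return graph.valid


def _is_fourfold(graph: FrameGraph, c: int, k: int) -> bool:
    return any(c in s and k in s for s in graph.fourfold)


def enumerate_half_links(graph: FrameGraph) -> pd.DataFrame:
    """All half-links of a frame between valid cells, vectors in um."""
    rows = []
    for c, k in sorted(graph.valid_pairs()):
        lx, ly = graph.link_vector(c, k)
        rows.append((graph.frame, c, k, lx, ly, "", _is_fourfold(graph, c, k), False))
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


# ---------------------------------------------------------------------------
# interframe classification
# ---------------------------------------------------------------------------

_FATE_CATEGORY = {
    "divides": "division",
    "delaminates": "delamination",
    "fuses": "fusion",
    "exits": "flux",
}

_ORIGIN_CATEGORY = {
    "division": "division",
    "integration": "integration",
    "flux": "flux",
}


def classify_half_links(
    g0: FrameGraph, g1: FrameGraph, lineage: Lineage
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Categorize every half-link of two consecutive frames.

    Returns the two frames' half-link tables with the ``category`` column
    filled (and ``sister`` set on newly created daughter-daughter links).
    Every half-link receives exactly one category; a lineage/image
    contradiction raises :class:`LineageError`.
    """
    t0, t1 = g0.frame, g1.frame
    pairs0 = g0.valid_pairs()
    pairs1 = g1.valid_pairs()

    for g in (g0, g1):
        for c in g.valid:
            if not lineage.alive(c, g.frame):
                raise LineageError(
                    f"cell {c} present in frame {g.frame} but lineage says "
                    f"[{lineage.first_frame(c) if c in lineage._first else '?'}, "
                    f"{lineage.last_frame(c) if c in lineage._last else '?'}]"
                )

    def persists(cell: int) -> bool:
        """Alive and valid (non-border) in both frames."""
        return (
            lineage.alive(cell, t0)
            and lineage.alive(cell, t1)
            and cell in g0.valid
            and cell in g1.valid
        )

    def end_event(cell: int) -> str | None:
        """Event removing `cell` from the valid set during this interframe."""
        if lineage.alive(cell, t0) and not lineage.alive(cell, t1):
            if lineage.last_frame(cell) != t0:
                raise LineageError(
                    f"cell {cell} vanished between frames {t0} and {t1} but "
                    f"lineage last_frame is {lineage.last_frame(cell)}"
                )
            return _FATE_CATEGORY.get(lineage.fate(cell))
        if cell in g0.valid and lineage.alive(cell, t1) and cell not in g1.valid:
            return "flux"  # slipped out to the image border
        return None

    def start_event(cell: int) -> str | None:
        """Event introducing `cell` into the valid set during this interframe."""
        if lineage.alive(cell, t1) and not lineage.alive(cell, t0):
            origin = lineage.origin(cell, touches_border=cell in g1.border)
            return _ORIGIN_CATEGORY.get(origin, "integration")
        if cell in g1.valid and lineage.alive(cell, t0) and cell not in g0.valid:
            return "flux"  # came in from the image border
        return None

    # dead/removed cells at t0 whose disappearance can create new contacts
    removal_events: dict[int, str] = {}
    for c in g0.valid:
        ev = end_event(c)
        if ev is not None:
            removal_events[c] = ev

    # cells absorbing a fusing partner: their centroid jumps at the merge,
    # so all their half-links are fusion-category on both frames (the
    # geometric fit must not see the jump as deformation)
    fusion_survivors = {
        int(lineage.table.loc[cell, "fate_partner"])
        for cell, ev in removal_events.items()
        if ev == "fusion" and int(lineage.table.loc[cell, "fate_partner"]) >= 0
    }

    conserved = {
        p for p in pairs0 & pairs1
        if persists(p[0]) and persists(p[1])
        and p[0] not in fusion_survivors and p[1] not in fusion_survivors
    }

    # newly appearing cells at t1 whose insertion can break old contacts
    insertion_events: dict[int, str] = {}
    for c in g1.valid:
        ev = start_event(c)
        if ev is not None:
            insertion_events[c] = ev

    def explain_by_neighbour_removal(c: int, k: int) -> str | None:
        """Shared t0-neighbour whose removal explains a new (c, k) contact."""
        shared = g0.neighbors.get(c, set()) & g0.neighbors.get(k, set())
        evs = [removal_events[s] for s in shared if s in removal_events]
        if not evs:
            return None
        return min(evs, key=lambda e: _EVENT_PRECEDENCE[e])

    def explain_by_neighbour_insertion(c: int, k: int) -> str | None:
        """Shared t1-neighbour whose insertion explains a lost (c, k)
        contact (a new cell wedged between the pair)."""
        shared = g1.neighbors.get(c, set()) & g1.neighbors.get(k, set())
        evs = [insertion_events[s] for s in shared if s in insertion_events]
        if not evs:
            return None
        return min(evs, key=lambda e: _EVENT_PRECEDENCE.get(e, 9))

    links0 = enumerate_half_links(g0)
    links1 = enumerate_half_links(g1)

    cats0 = []
    for c, k in zip(links0["c"], links0["k"]):
        if (c, k) in conserved:
            cats0.append("conserved")
            continue
        ev = end_event(c) or end_event(k)
        if ev is not None:
            cats0.append(ev)
            continue
        if c in fusion_survivors or k in fusion_survivors:
            cats0.append("fusion")
            continue
        # both cells persist; attribute the lost contact to a removed
        # shared neighbour (delamination/fusion/exit closing the gap) or
        # an inserted one (integration/daughter wedging the pair apart)
        # when one exists, otherwise it is a T1 exchange
        cause = explain_by_neighbour_removal(c, k)
        if cause is None:
            cause = explain_by_neighbour_insertion(c, k)
        cats0.append(cause if cause is not None else "rearrangement")
    links0["category"] = cats0

    cats1 = []
    sisters = []
    for c, k in zip(links1["c"], links1["k"]):
        if (c, k) in conserved:
            cats1.append("conserved")
            sisters.append(False)
            continue
        ev = start_event(c)
        if ev is None:
            ev = start_event(k)
        if ev is not None:
            cats1.append(ev)
            sisters.append(ev == "division" and lineage.sister(c) == k)
            continue
        if c in fusion_survivors or k in fusion_survivors:
            cats1.append("fusion")
            sisters.append(False)
            continue
        cause = explain_by_neighbour_removal(c, k)
        cats1.append(cause if cause is not None else "rearrangement")
        sisters.append(False)
    links1["category"] = cats1
    links1["sister"] = sisters
    return links0, links1


def division_links(lineage: Lineage, g1: FrameGraph) -> pd.DataFrame:
    """Sister links (d1 centroid -> d2 centroid) for divisions completing at
    this frame; the raw material of the division-orientation tensor Do."""
    t1 = g1.frame
    rows = []
    for mother, (d1, d2) in sorted(lineage.daughters.items()):
        if lineage.first_frame(d1) != t1:
            continue
        if d1 in g1.valid and d2 in g1.valid:
            lx, ly = g1.link_vector(d1, d2)
            rows.append((t1, mother, d1, d2, lx, ly))
    return pd.DataFrame(rows, columns=["frame", "mother", "d1", "d2", "lx", "ly"])


def division_orientation(sister_links: pd.DataFrame):
    """Division-orientation deviator Do from unit sister-link directions.

    Returns None when no division occurred in the window.
    """
    from .tensors import SymTensor2, iso_dev_split

    if len(sister_links) == 0:
        return None
    v = sister_links[["lx", "ly"]].to_numpy(dtype=float)
    norms = np.linalg.norm(v, axis=1)
    v = v[norms > 0] / norms[norms > 0, None]
    outer = np.einsum("ni,nj->ij", v, v) / len(v)
    _, dev = iso_dev_split(SymTensor2.from_matrix(outer))
    return dev


# ---------------------------------------------------------------------------
# overlap tracking (for stacks without persistent labels)
# ---------------------------------------------------------------------------

def overlap_tracker(
    stack: np.ndarray,
    min_overlap: float = 0.5,
    division_overlap: float = 0.3,
) -> tuple[np.ndarray, Lineage]:
    """Track a label stack frame-to-frame by greedy maximum overlap.

    Returns a persistently relabelled stack and the inferred lineage.
    A cell with two successors each overlapping >= ``division_overlap`` of
    its area is a division; a vanishing interior cell with a shrinking area
    history is a delamination (at the border: an exit); two cells mapping
    onto one successor are a fusion; an unmatched new cell is an entering
    flux cell at the border, an integration elsewhere.
    """
    stack = np.asarray(stack)
    nframes = stack.shape[0]
    out = np.zeros_like(stack, dtype=np.uint32)

    def border_labels(img):
        s = set()
        for edge in (img[0, :], img[-1, :], img[:, 0], img[:, -1]):
            s.update(int(v) for v in np.unique(edge) if v != 0)
        return s

    next_id = 1
    records: dict[int, dict] = {}
    # map original label -> persistent id in current frame
    cur: dict[int, int] = {}
    for v in np.unique(stack[0]):
        if v == 0:
            continue
        cur[int(v)] = next_id
        records[next_id] = dict(
            cell_id=next_id, mother_id=-1, first_frame=0, last_frame=0,
            fate="survives", fate_partner=-1, origin="initial",
        )
        next_id += 1
    for old, pid in cur.items():
        out[0][stack[0] == old] = pid

    for f in range(1, nframes):
        prev, img = stack[f - 1], stack[f]
        prev_ids = [v for v in np.unique(prev) if v != 0]
        new_ids = [v for v in np.unique(img) if v != 0]
        areas_prev = {int(v): int(np.sum(prev == v)) for v in prev_ids}
        areas_new = {int(v): int(np.sum(img == v)) for v in new_ids}
        # joint histogram of (prev label, new label)
        overlap: dict[tuple[int, int], int] = {}
        both = (prev != 0) & (img != 0)
        if both.any():
            pairs, cnt = np.unique(
                np.stack([prev[both], img[both]], axis=1), axis=0, return_counts=True
            )
            overlap = {(int(p), int(q)): int(n) for (p, q), n in zip(pairs, cnt)}

        succ: dict[int, list[int]] = {int(p): [] for p in prev_ids}
        claimed: dict[int, int] = {}
        for (p, q), n in sorted(overlap.items(), key=lambda kv: -kv[1]):
            if q in claimed:
                continue
            if n >= min_overlap * min(areas_prev[p], areas_new[q]) or (
                n >= division_overlap * areas_prev[p]
            ):
                succ[p].append(q)
                claimed[q] = p

        border_now = border_labels(img)
        new_cur: dict[int, int] = {}
        for p in prev_ids:
            pid = cur[int(p)]
            ss = succ[int(p)]
            if len(ss) == 1:
                new_cur[ss[0]] = pid
                records[pid]["last_frame"] = f
            elif len(ss) >= 2:
                ss2 = sorted(ss, key=lambda q: -overlap.get((int(p), q), 0))[:2]
                good = [q for q in ss2
                        if overlap.get((int(p), q), 0)
                        >= division_overlap * areas_prev[int(p)]]
                if len(good) == 2:
                    records[pid]["fate"] = "divides"
                    for q in good:
                        new_cur[q] = next_id
                        records[next_id] = dict(
                            cell_id=next_id, mother_id=pid, first_frame=f,
                            last_frame=f, fate="survives", fate_partner=-1,
                            origin="division",
                        )
                        next_id += 1
                else:
                    new_cur[ss2[0]] = pid
                    records[pid]["last_frame"] = f
            else:
                # no successor: delamination in the interior, exit at border
                was_border = int(p) in border_labels(prev)
                records[pid]["fate"] = "exits" if was_border else "delaminates"
        # cells claimed twice (fusion) were resolved greedily above; detect
        # unmatched new labels
        for q in new_ids:
            q = int(q)
            if q in new_cur:
                continue
            origin = "flux" if q in border_now else "integration"
            new_cur[q] = next_id
            records[next_id] = dict(
                cell_id=next_id, mother_id=-1, first_frame=f, last_frame=f,
                fate="survives", fate_partner=-1, origin=origin,
            )
            next_id += 1
        for old, pid in new_cur.items():
            out[f][img == old] = pid
        cur = new_cur

    lineage = Lineage(pd.DataFrame(list(records.values())))
    return out, lineage
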