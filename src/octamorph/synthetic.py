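"""Ground-truthed synthetic en-face angiograms.

A capillary plexus is grown as a stochastic bifurcating tree from roots on
the image border; growth deflects around a central avascular disc (the FAZ)
and avoids previously placed vessels, so the stored polyline adjacency is an
exact record of the network topology.  Every junction and terminal is
therefore known by construction, which makes the generator an oracle for
the skeleton, topology and fragmentation stages.

Degradation emulates diabetic-retinopathy-like remodelling: pruning of
terminal branches (fewer branch nodes), flow-dropout gaps cut into vessels
(shorter perfused length, extra terminals) and planted isolated short
fragments.  All randomness is driven by explicit seeds; identical
configurations reproduce identical networks and images bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import (
    DEFAULT_FIELD_MM,
    DEFAULT_SIZE_PX,
    Angiogram,
    ConfigurationError,
    pitch_for,
)

# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------


@dataclass
class Segment:
    """One unbranched vessel polyline.

    ``points`` is an (N, 2) float array of (row, col) pixel coordinates.
    Children (segments with ``parent`` set to this segment's id) start at
    this segment's exact last point, so shared coordinates encode adjacency.
    """

    points: np.ndarray
    width_px: float
    parent: int | None = None
    generation: int = 0
    is_fragment: bool = False

    @property
    def start(self) -> tuple[float, float]:
        return tuple(self.points[0])

    @property
    def end(self) -> tuple[float, float]:
        return tuple(self.points[-1])

    def length_px(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())


def _key(pt) -> tuple[float, float]:
    return (round(float(pt[0]), 4), round(float(pt[1]), 4))


@dataclass
class GroundTruthNetwork:
    """Vector vasculature with exact node / endpoint / fragment annotations."""

    segments: list[Segment]
    size_px: int
    field_mm: float = DEFAULT_FIELD_MM
    faz_center_px: tuple[float, float] = (0.0, 0.0)
    faz_radius_mm: float = 0.3
    nodes: list[tuple[float, float]] = field(default_factory=list)
    endpoints: list[tuple[float, float]] = field(default_factory=list)

    @property
    def pixel_pitch_um(self) -> float:
        return pitch_for(self.size_px, self.field_mm)

    @property
    def faz_radius_px(self) -> float:
        return self.faz_radius_mm * 1000.0 / self.pixel_pitch_um

    @property
    def fragments(self) -> list[int]:
        return [i for i, s in enumerate(self.segments) if s.is_fragment]

    # -- annotation bookkeeping ------------------------------------------

    def end_degrees(self) -> dict[tuple[float, float], int]:
        """Number of segment ends incident to each shared coordinate."""
        deg: dict[tuple[float, float], int] = {}
        for s in self.segments:
            for pt in (s.start, s.end):
                k = _key(pt)
                deg[k] = deg.get(k, 0) + 1
        return deg

    def annotate(self) -> None:
        """Recompute nodes (degree >= 3) and endpoints (degree 1) from the
        stored polyline adjacency."""
        deg = self.end_degrees()
        self.nodes = [k for k, d in deg.items() if d >= 3]
        self.endpoints = [k for k, d in deg.items() if d == 1]

    def total_length_px(self) -> float:
        return sum(s.length_px() for s in self.segments)

    def fragment_length_px(self) -> float:
        return sum(s.length_px() for s in self.segments if s.is_fragment)

    # -- (de)serialization ------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "size_px": self.size_px,
            "field_mm": self.field_mm,
            "faz_center_px": list(self.faz_center_px),
            "faz_radius_mm": self.faz_radius_mm,
            "nodes": [list(p) for p in self.nodes],
            "endpoints": [list(p) for p in self.endpoints],
            "segments": [
                {
                    "points": np.round(s.points, 4).tolist(),
                    "width_px": s.width_px,
                    "parent": s.parent,
                    "generation": s.generation,
                    "is_fragment": s.is_fragment,
                }
                for s in self.segments
            ],
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthNetwork":
        obj = json.loads(text)
        segs = [
            Segment(
                points=np.asarray(d["points"], dtype=float),
                width_px=d["width_px"],
                parent=d["parent"],
                generation=d["generation"],
                is_fragment=d["is_fragment"],
            )
            for d in obj["segments"]
        ]
        net = cls(
            segments=segs,
            size_px=obj["size_px"],
            field_mm=obj["field_mm"],
            faz_center_px=tuple(obj["faz_center_px"]),
            faz_radius_mm=obj["faz_radius_mm"],
        )
        net.nodes = [tuple(p) for p in obj["nodes"]]
        net.endpoints = [tuple(p) for p in obj["endpoints"]]
        return net


@dataclass
class GrowthParams:
    """Branching-process configuration for :func:`grow_network`.

    Pixel-valued defaults refer to the standard 512 px / 3 mm geometry; use
    :meth:`scaled` to keep the physical appearance when rendering smaller
    rasters.
    """

    n_roots: int = 16
    branch_prob: float = 0.85
    max_depth: int = 8
    mean_segment_len_px: float = 30.0
    len_jitter: float = 0.35
    root_width_px: float = 5.0
    width_decay: float = 0.85
    min_width_px: float = 2.0
    branch_angle_deg: float = 32.0
    angle_jitter_deg: float = 10.0
    step_px: float = 2.0
    dir_jitter_deg: float = 7.0
    faz_radius_mm: float = 0.3
    min_clearance_px: float = 4.0
    size_px: int = DEFAULT_SIZE_PX
    field_mm: float = DEFAULT_FIELD_MM
    # perifoveal capillary ring enclosing the FAZ, as in a real macula
    perifoveal_ring: bool = True
    ring_width_px: float = 2.5
    ring_arcs: int = 12
    ring_trees: int = 12
    # seed extra filler trees until no avascular pool rivals the FAZ;
    # the margin leaves room for degradation to widen pools without any of
    # them overtaking the FAZ as the deepest basin
    gap_fill: bool = True
    gap_fill_frac: float = 0.6

    def scaled(self, size_px: int) -> "GrowthParams":
        """Rescale pixel lengths for a different raster size at the same
        physical field; branching depth shrinks with the dyadic scale so
        vessel density (fraction of area covered) is roughly preserved."""
        f = size_px / self.size_px
        depth_drop = int(round(np.log2(1.0 / f))) if f < 1 else 0
        return replace(
            self,
            size_px=size_px,
            mean_segment_len_px=self.mean_segment_len_px * f,
            step_px=max(1.0, self.step_px * f),
            max_depth=max(2, self.max_depth - depth_drop),
        )


def svp_params(**overrides) -> GrowthParams:
    """Preset emulating a superficial plexus: wider calibres."""
    return replace(GrowthParams(), **overrides)


def dvp_params(**overrides) -> GrowthParams:
    """Preset emulating a deep plexus: narrower, denser capillaries."""
    p = GrowthParams(root_width_px=4.0, n_roots=18, branch_angle_deg=38.0)
    return replace(p, **overrides)


@dataclass
class DegradationConfig:
    """Controlled degradation applied by :func:`degrade`.

    ``prune_fraction`` removes that fraction of the removable (non-root)
    segments, leaves first, iterating to a fixpoint at 1.0.
    ``n_dropout_gaps`` cuts flow-dropout gaps of ``dropout_gap_px`` into
    internal segments; with ``balance_endpoints`` additional gaps are cut
    until the truth endpoint count returns to within one of its
    pre-degradation value (each gap adds two terminals), emulating remodelling
    that shortens vessels without changing the terminal count.
    ``n_fragments`` plants isolated short segments away from the network.
    """

    prune_fraction: float = 0.0
    n_fragments: int = 0
    #: planted fragment lengths in px; None scales (12, 36) @ 512 px with
    #: the raster size
    fragment_length_range: tuple[float, float] | None = None
    dropout_gap_px: float = 12.0
    n_dropout_gaps: int = 0
    balance_endpoints: bool = False
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prune_fraction <= 1.0:
            raise ConfigurationError("prune_fraction must be in [0, 1]")
        if self.n_fragments < 0 or self.n_dropout_gaps < 0:
            raise ConfigurationError("counts must be >= 0")
        if (self.fragment_length_range is not None
                and self.fragment_length_range[0] > self.fragment_length_range[1]):
            raise ConfigurationError("fragment_length_range min > max")


# --------------------------------------------------------------------------
# spatial hash for collision avoidance
# --------------------------------------------------------------------------


class _PointHash:
    """Coarse grid hash over placed centerline samples."""

    def __init__(self, cell: float = 8.0):
        self.cell = cell
        self.cells: dict[tuple[int, int], list[tuple[float, float, float, int, int]]] = {}

    def add(self, r: float, c: float, radius: float, seg_id: int, pt_idx: int = 0) -> None:
        k = (int(r // self.cell), int(c // self.cell))
        self.cells.setdefault(k, []).append((r, c, radius, seg_id, pt_idx))

    def near(self, r: float, c: float, dist: float):
        span = int(np.ceil(dist / self.cell))
        kr, kc = int(r // self.cell), int(c // self.cell)
        for i in range(kr - span, kr + span + 1):
            for j in range(kc - span, kc + span + 1):
                yield from self.cells.get((i, j), ())


# --------------------------------------------------------------------------
# growth
# --------------------------------------------------------------------------


def _rot(vec: np.ndarray, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([ca * vec[0] - sa * vec[1], sa * vec[0] + ca * vec[1]])


def grow_network(params: GrowthParams | None = None, seed: int = 0) -> GroundTruthNetwork:
    """Grow a synthetic capillary network with exact topology bookkeeping.

    Roots are spaced around the image border and grow inward; at the end of
    each segment the tip either bifurcates (probability ``branch_prob``,
    always for the root segment when branching is enabled) or terminates.
    Steps that would enter the central avascular disc or collide with an
    unrelated vessel are deflected, or the segment is truncated.
    """
    p = params or GrowthParams()
    if p.n_roots < 1:
        raise ConfigurationError("n_roots must be >= 1")
    size = p.size_px
    pitch = pitch_for(size, p.field_mm)
    faz_r = p.faz_radius_mm * 1000.0 / pitch
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    if faz_r >= size / 2.0:
        raise ConfigurationError("FAZ radius exceeds the field half-width")

    rng = np.random.default_rng(seed)
    hash_ = _PointHash(cell=8.0)
    segments: list[Segment] = []
    margin = 2.0

    def border_point(t: float) -> np.ndarray:
        # parameter t in [0,4) walks the square border, inset past the margin
        lo, e = margin + 0.5, size - 1.0 - 2 * (margin + 0.5)
        side, u = int(t) % 4, lo + (t % 1.0) * e
        if side == 0:
            return np.array([lo, u])
        if side == 1:
            return np.array([u, size - 1.0 - lo])
        if side == 2:
            return np.array([size - 1.0 - lo, size - 1.0 - u + lo])
        return np.array([size - 1.0 - u + lo, lo])

    def blocked(pt: np.ndarray, width: float, seg_id: int, incident: set[int],
                start_pt: np.ndarray, n_own: int) -> bool:
        if not (margin <= pt[0] <= size - 1 - margin and margin <= pt[1] <= size - 1 - margin):
            return True
        if np.linalg.norm(pt - center) < faz_r + width / 2.0 + 1.0:
            return True
        look = width / 2.0 + p.root_width_px / 2.0 + p.min_clearance_px
        exempt_r = 1.5 * width + 5.0
        for (qr, qc, qrad, qid, qidx) in hash_.near(pt[0], pt[1], look):
            d = np.hypot(pt[0] - qr, pt[1] - qc)
            if d >= width / 2.0 + qrad + p.min_clearance_px:
                continue
            if qid == seg_id:
                # recent own points are the trailing path; older ones within
                # touching range mean the segment is about to cross itself
                if qidx < n_own - 3 and d < 1.5:
                    return True
                continue
            if qid in incident \
                    and np.hypot(qr - start_pt[0], qc - start_pt[1]) < exempt_r:
                # junction neighbourhood: segments sharing our start junction
                # (parent, siblings, ring arcs) may sit close by, but actual
                # overlap would create a spurious crossing
                if d < 1.5 and np.hypot(qr - start_pt[0], qc - start_pt[1]) > 0.5:
                    return True
                continue
            return True
        return False

    # queue of (start point, direction, width, generation, parent id)
    queue: list[tuple[np.ndarray, np.ndarray, float, int, int | None]] = []

    if p.perifoveal_ring:
        # closed digital circle just outside the avascular disc, split into
        # arc segments; trees sprout outward from a subset of the joints
        r_ring = faz_r + 1.0 + p.ring_width_px / 2.0
        n_theta = max(64, int(2 * np.pi * r_ring * 4))
        theta0 = rng.uniform(0, 2 * np.pi)
        thetas = theta0 + np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        raw = np.round(
            center[None, :]
            + r_ring * np.stack([np.sin(thetas), np.cos(thetas)], axis=1)
        )
        chain = [raw[0]]
        for q in raw[1:]:
            if not np.array_equal(q, chain[-1]):
                chain.append(q)
        if not np.array_equal(chain[-1], chain[0]):
            chain.append(chain[0].copy())
        chain = np.array(chain)
        cuts = np.linspace(0, len(chain) - 1, p.ring_arcs + 1).astype(int)
        joints: list[tuple[np.ndarray, int]] = []
        for a in range(p.ring_arcs):
            arc_pts = chain[cuts[a]:cuts[a + 1] + 1]
            arc_id = len(segments)
            segments.append(
                Segment(points=arc_pts.copy(), width_px=p.ring_width_px,
                        parent=None, generation=0)
            )
            for idx, q in enumerate(arc_pts[:-1]):
                hash_.add(q[0], q[1], p.ring_width_px / 2.0, arc_id, idx)
            joints.append((arc_pts[-1].copy(), arc_id))
        n_trees = min(p.ring_trees, len(joints))
        pick = np.linspace(0, len(joints) - 1, n_trees).astype(int)
        for j in pick:
            joint, arc_id = joints[j]
            outward = joint - center
            outward = outward / max(np.linalg.norm(outward), 1e-9)
            direction = _rot(outward, rng.uniform(-20, 20))
            queue.append((joint, direction, p.root_width_px * 0.8, 0, arc_id))

    offsets = rng.uniform(0, 4)
    for i in range(p.n_roots):
        t = (offsets + 4.0 * i / p.n_roots + rng.uniform(-0.2, 0.2)) % 4.0
        start = np.round(border_point(t))
        inward = center - start
        inward = inward / np.linalg.norm(inward)
        direction = _rot(inward, rng.uniform(-20, 20))
        queue.append((start, direction, p.root_width_px, 0, None))

    # polylines advance on the pixel lattice: each step rounds the continuous
    # heading to the nearest of the 8 compass offsets, so the stored polyline
    # is an 8-connected chain and its Euclidean length coincides with the
    # lateral-1 / diagonal-sqrt2 geodesic convention of the skeleton metrics
    compass = np.array(
        [[0, 1], [1, 1], [1, 0], [1, -1], [0, -1], [-1, -1], [-1, 0], [-1, 1]],
        dtype=float,
    )

    def compass_step(d: np.ndarray) -> np.ndarray:
        k = int(np.round(np.arctan2(d[0], d[1]) / (np.pi / 4.0))) % 8
        return compass[k]

    def run_queue() -> None:
      while queue:
        start, direction, width, gen, parent = queue.pop(0)
        seg_id = len(segments)
        # segments meeting at our start junction are exempt from clearance
        incident = {
            i for i, s_ in enumerate(segments)
            if np.hypot(s_.points[0][0] - start[0], s_.points[0][1] - start[1]) < 0.5
            or np.hypot(s_.points[-1][0] - start[0], s_.points[-1][1] - start[1]) < 0.5
        }
        if parent is not None:
            incident.add(parent)
        target_len = max(
            4.0 * p.step_px,
            p.mean_segment_len_px * (1.0 + p.len_jitter * rng.uniform(-1, 1)),
        )
        pts = [start.copy()]
        pos, d = start.copy(), direction.copy()
        walked, truncated = 0.0, False
        while walked < target_len:
            d = _rot(d, rng.uniform(-p.dir_jitter_deg, p.dir_jitter_deg))
            off = compass_step(d)
            step = pos + off
            if blocked(step, width, seg_id, incident, start, len(pts)):
                ok = False
                for turn in (45.0, -45.0, 90.0, -90.0):
                    d2 = _rot(d, turn)
                    off2 = compass_step(d2)
                    s2 = pos + off2
                    if not blocked(s2, width, seg_id, incident, start, len(pts)):
                        d, off, step, ok = d2, off2, s2, True
                        break
                if not ok:
                    truncated = True
                    break
            pos = step
            pts.append(pos.copy())
            hash_.add(pos[0], pos[1], width / 2.0, seg_id, len(pts) - 1)
            walked += float(np.hypot(off[0], off[1]))
        # truncated stubs shorter than about two stroke widths would be
        # absorbed by thinning at the junction; drop them so the truth
        # stays measurable
        if len(pts) < 2 or (truncated and walked < max(6.0, 2.0 * width + 2.0)):
            continue
        segments.append(
            Segment(points=np.array(pts), width_px=width, parent=parent, generation=gen)
        )
        if gen >= p.max_depth or p.branch_prob <= 0:
            continue
        # roots of standalone trees always branch so no component is left
        # as a bare unbranched path; truncated tips may still branch (the
        # children deflect or die as stubs)
        do_branch = (gen == 0) or (parent is None) or (rng.uniform() < p.branch_prob)
        if do_branch:
            w_child = max(p.min_width_px, width * p.width_decay)
            for sign in (+1.0, -1.0):
                ang = sign * (p.branch_angle_deg + rng.uniform(-p.angle_jitter_deg, p.angle_jitter_deg))
                queue.append((pos.copy(), _rot(d, ang), w_child, gen + 1, seg_id))

    run_queue()

    def fill_gaps() -> None:
        # gap-filling passes: a healthy plexus has homogeneous capillary
        # spacing, so the FAZ must remain the largest avascular gap; seed
        # small filler trees wherever a pool rivals it
        fill_thresh = p.gap_fill_frac * faz_r
        protect_r = faz_r + p.ring_width_px + 8.0
        rr, cc = np.mgrid[0:size, 0:size]
        protected = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < protect_r**2
        w_fill = max(p.min_width_px, p.root_width_px * p.width_decay**3)
        for _ in range(60):
            occ = np.zeros((size, size), dtype=bool)
            for pts_ in hash_.cells.values():
                for (qr, qc, _rad, _id, _idx) in pts_:
                    occ[int(round(qr)), int(round(qc))] = True
            dist = ndi.distance_transform_edt(~occ)
            dist[protected] = 0.0
            peak = np.unravel_index(int(np.argmax(dist)), dist.shape)
            if dist[peak] <= fill_thresh:
                break
            start = np.array([
                float(np.clip(peak[0], margin + 2, size - 3 - margin)),
                float(np.clip(peak[1], margin + 2, size - 3 - margin)),
            ])
            direction = _rot(np.array([0.0, 1.0]), rng.uniform(0, 360))
            queue.append((start, direction, w_fill, max(0, p.max_depth - 4), None))
            run_queue()

    def build() -> GroundTruthNetwork:
        net = GroundTruthNetwork(
            segments=segments,
            size_px=size,
            field_mm=p.field_mm,
            faz_center_px=tuple(center),
            faz_radius_mm=p.faz_radius_mm,
        )
        net.annotate()
        return net

    if p.branch_prob <= 0:
        return build()

    # alternate gap filling with the unbranched-component cleanup until the
    # kept network itself leaves no rivalling pool
    for _ in range(6):
        if p.gap_fill:
            fill_gaps()
        net = build()
        n_dropped = _drop_unbranched_roots(net)
        if n_dropped == 0 or not p.gap_fill:
            return net
        segments[:] = net.segments
        hash_.cells.clear()
        for i, s_ in enumerate(segments):
            for idx, ptn in enumerate(s_.points):
                hash_.add(ptn[0], ptn[1], s_.width_px / 2.0, i, idx)
    return net


def _drop_unbranched_roots(net: GroundTruthNetwork) -> int:
    """Remove connected components that never established a bifurcation: a
    lone unbranched path would read as an isolated segment downstream, which
    only planted fragments are meant to be.  Components are unions of
    segments sharing end coordinates (union-find)."""
    deg = net.end_degrees()
    n = len(net.segments)
    uf = list(range(n))

    def find(i: int) -> int:
        while uf[i] != i:
            uf[i] = uf[uf[i]]
            i = uf[i]
        return i

    seen: dict[tuple[float, float], int] = {}
    for i, s in enumerate(net.segments):
        for pt in (s.start, s.end):
            k = _key(pt)
            if k in seen:
                uf[find(i)] = find(seen[k])
            else:
                seen[k] = i
    comp_has_node: dict[int, bool] = {}
    for i, s in enumerate(net.segments):
        r = find(i)
        if deg[_key(s.start)] >= 3 or deg[_key(s.end)] >= 3:
            comp_has_node[r] = True
        else:
            comp_has_node.setdefault(r, False)
    keep = [i for i in range(n) if comp_has_node[find(i)]]
    n_dropped = len(net.segments) - len(keep)
    if n_dropped == 0:
        return 0
    remap = {old: new for new, old in enumerate(keep)}
    net.segments = [
        replace(
            net.segments[old],
            parent=None if net.segments[old].parent is None
            else remap[net.segments[old].parent],
        )
        for old in keep
    ]
    net.annotate()
    return n_dropped


# --------------------------------------------------------------------------
# degradation
# --------------------------------------------------------------------------


def _children_map(net: GroundTruthNetwork) -> dict[int, list[int]]:
    ch: dict[int, list[int]] = {}
    for i, s in enumerate(net.segments):
        if s.parent is not None:
            ch.setdefault(s.parent, []).append(i)
    return ch


def _removal_order(net: GroundTruthNetwork, rng: np.random.Generator) -> list[int]:
    """Leaves-first removal order of all non-root, non-fragment segments,
    iterated to the fixpoint where only root segments remain."""
    children = {i: set(c) for i, c in _children_map(net).items()}
    alive = {i for i, s in enumerate(net.segments) if not s.is_fragment}
    order: list[int] = []
    while True:
        leaves = sorted(
            i for i in alive
            if net.segments[i].parent is not None and not children.get(i)
        )
        if not leaves:
            return order
        rng.shuffle(leaves)
        for i in leaves:
            order.append(i)
            alive.discard(i)
            par = net.segments[i].parent
            if par in children:
                children[par].discard(i)


def degrade(net: GroundTruthNetwork, cfg: DegradationConfig) -> GroundTruthNetwork:
    """Apply pruning, flow-dropout gaps and planted fragments; returns a new
    network with annotations recomputed.  Identical (network, config) pairs
    produce identical results."""
    rng = np.random.default_rng(cfg.seed)
    segs = [replace(s, points=s.points.copy()) for s in net.segments]
    work = GroundTruthNetwork(
        segments=segs,
        size_px=net.size_px,
        field_mm=net.field_mm,
        faz_center_px=net.faz_center_px,
        faz_radius_mm=net.faz_radius_mm,
    )
    work.annotate()
    endpoints_before = list(work.endpoints)

    # --- prune terminal branches ---------------------------------------
    order = _removal_order(work, rng)
    quota = int(round(cfg.prune_fraction * len(order)))
    if quota > len(order):  # cannot happen with fraction <= 1, kept for safety
        warnings.warn("requested pruning exceeds available terminals; pruning all")
        quota = len(order)
    removed = set(order[:quota])
    keep_idx = [i for i in range(len(work.segments)) if i not in removed]
    remap = {old: new for new, old in enumerate(keep_idx)}
    pruned: list[Segment] = []
    for old in keep_idx:
        s = work.segments[old]
        par = s.parent if (s.parent is None or s.parent in remap) else None
        pruned.append(replace(s, parent=None if par is None else remap[par]))
    work.segments = pruned
    work.annotate()

    # --- configured flow-dropout gaps -----------------------------------
    _cut_gaps(work, cfg.n_dropout_gaps, cfg.dropout_gap_px, rng)

    # --- planted fragments ----------------------------------------------
    frange = cfg.fragment_length_range
    if frange is None:
        f = net.size_px / DEFAULT_SIZE_PX
        frange = (max(8.0, 12.0 * f), max(14.0, 36.0 * f))
    _plant_fragments(work, cfg.n_fragments, frange, rng)
    work.annotate()

    # --- endpoint balancing ---------------------------------------------
    # restore the terminal count separately inside the fovea-scale zone and
    # outside it, so regional endpoint statistics stay level while vessel
    # length falls (each extra gap adds two terminals in its zone)
    if cfg.balance_endpoints:
        r_zone = 0.75 * 1000.0 / net.pixel_pitch_um
        cr, cc = net.faz_center_px

        def zone_of(pt) -> int:
            return 0 if np.hypot(pt[0] - cr, pt[1] - cc) <= r_zone else 1

        before = [0, 0]
        for pt in endpoints_before:
            before[zone_of(pt)] += 1
        for z in (0, 1):
            now = sum(1 for pt in work.endpoints if zone_of(pt) == z)
            deficit = before[z] - now
            n_gaps = max(0, int(round(deficit / 2.0)))
            if n_gaps:
                _cut_gaps(work, n_gaps, cfg.dropout_gap_px, rng,
                          zone=lambda pt, z=z: zone_of(pt) == z)
        work.annotate()
    return work


def _cut_gaps(net: GroundTruthNetwork, n_gaps: int, gap_px: float,
              rng: np.random.Generator, zone=None) -> None:
    """Cut ``n_gaps`` gaps into internal segments (both ends attached), so
    both halves stay connected to the rest of the network.  ``zone`` is an
    optional predicate on the segment midpoint restricting where gaps go."""
    done = 0
    attempts = 0
    while done < n_gaps:
        attempts += 1
        if attempts > 40 * max(n_gaps, 1):
            warnings.warn(f"only {done} of {n_gaps} dropout gaps could be cut")
            return
        children = _children_map(net)
        candidates = [
            i for i, s in enumerate(net.segments)
            if s.parent is not None and children.get(i)
            and s.length_px() > max(gap_px, s.width_px + 6.0) + 4.0 * 2
            and (zone is None or zone(s.points[len(s.points) // 2]))
        ]
        if not candidates:
            if n_gaps - done > 0:
                warnings.warn(f"only {done} of {n_gaps} dropout gaps could be cut")
            return
        i = int(rng.choice(candidates))
        s = net.segments[i]
        eff_gap = max(gap_px, s.width_px + 6.0)
        d = np.sqrt((np.diff(s.points, axis=0) ** 2).sum(axis=1))
        arclen = np.concatenate([[0.0], np.cumsum(d)])
        total = arclen[-1]
        mid = rng.uniform(0.35, 0.65) * total
        lo, hi = mid - eff_gap / 2.0, mid + eff_gap / 2.0
        a_pts = s.points[arclen <= lo]
        b_pts = s.points[arclen >= hi]
        if len(a_pts) < 2 or len(b_pts) < 2:
            continue
        seg_a = replace(s, points=a_pts)  # keeps parent; free distal end
        seg_b = replace(s, points=b_pts, parent=None)  # keeps the children via end point
        net.segments[i] = seg_a
        b_id = len(net.segments)
        net.segments.append(seg_b)
        for c in children[i]:
            net.segments[c] = replace(net.segments[c], parent=b_id)
        done += 1


def _plant_fragments(net: GroundTruthNetwork, n: int,
                     length_range: tuple[float, float],
                     rng: np.random.Generator) -> None:
    if n == 0:
        return
    size = net.size_px
    center = np.array(net.faz_center_px)
    faz_r = net.faz_radius_px
    hash_ = _PointHash(cell=8.0)
    for i, s in enumerate(net.segments):
        for pt in s.points:
            hash_.add(pt[0], pt[1], s.width_px / 2.0, i)

    planted = 0
    attempts = 0
    max_attempts = 600 * n
    # clearance beyond the stroke radii; relaxed progressively but kept
    # above the raster-disjointness floor
    extra = 4.0
    while planted < n:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                f"could not place {n} isolated fragments (placed {planted}); "
                "network too dense"
            )
        if attempts % (150 * n) == 0:
            extra = max(2.5, extra - 0.75)
        length = rng.uniform(*length_range)
        width = rng.uniform(2.0, 3.0)
        ang = rng.uniform(0, 2 * np.pi)
        d = np.array([np.sin(ang), np.cos(ang)])
        m = 8.0 + length / 2.0
        c0 = np.round(
            [rng.uniform(m, size - 1 - m), rng.uniform(m, size - 1 - m)]
        )
        # digital straight chain: compass-rounded steps until the target
        # arc length is reached, so truth length matches the geodesic metric
        k = int(np.round(np.arctan2(d[0], d[1]) / (np.pi / 4.0))) % 8
        base = np.array(
            [[0, 1], [1, 1], [1, 0], [1, -1], [0, -1], [-1, -1], [-1, 0], [-1, 1]],
            dtype=float,
        )[k]
        frac = abs(np.rad2deg(np.arctan2(d[0], d[1])) % 45.0) / 45.0
        alt = np.array(
            [[0, 1], [1, 1], [1, 0], [1, -1], [0, -1], [-1, -1], [-1, 0], [-1, 1]],
            dtype=float,
        )[(k + 1) % 8]
        pts_list = [np.asarray(c0, dtype=float)]
        walked = 0.0
        while walked < length:
            off = alt if rng.uniform() < frac else base
            nxt = pts_list[-1] + off
            pts_list.append(nxt)
            walked += float(np.hypot(off[0], off[1]))
        pts = np.array(pts_list)
        clearance = width / 2.0 + 3.0
        ok = True
        for pt in pts:
            if np.linalg.norm(pt - center) < faz_r + width / 2.0 + 2.0:
                ok = False
                break
            for (qr, qc, qrad, _qid, _qidx) in hash_.near(pt[0], pt[1], clearance + 5.0):
                if np.hypot(pt[0] - qr, pt[1] - qc) < width / 2.0 + qrad + extra:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        seg_id = len(net.segments)
        net.segments.append(
            Segment(points=pts, width_px=width, parent=None,
                    generation=-1, is_fragment=True)
        )
        for pt in pts:
            hash_.add(pt[0], pt[1], width / 2.0, seg_id)
        planted += 1


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------


@dataclass
class RasterizedAngiogram:
    """An angiogram plus the truth masks it was rendered from."""

    angiogram: Angiogram
    vessel_mask: np.ndarray
    skeleton_mask: np.ndarray
    faz_disc_mask: np.ndarray
    faz_mask: np.ndarray
    network: GroundTruthNetwork


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    rr, cc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = rr**2 + cc**2 <= radius**2 + 1e-9
    return np.stack([rr[keep], cc[keep]], axis=1)


def _resample(points: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    d = np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1))
    arclen = np.concatenate([[0.0], np.cumsum(d)])
    if arclen[-1] <= 0:
        return points[:1]
    t = np.arange(0.0, arclen[-1] + spacing / 2.0, spacing)
    t = np.clip(t, 0, arclen[-1])
    r = np.interp(t, arclen, points[:, 0])
    c = np.interp(t, arclen, points[:, 1])
    return np.stack([r, c], axis=1)


def rasterize(
    net: GroundTruthNetwork,
    noise_sigma: float = 0.0,
    seed: int = 0,
    faz_closing_px: int | None = None,
) -> RasterizedAngiogram:
    """Render a network into an angiogram plus truth masks.

    The vessel mask is the union of the stroked polylines (pixels within
    (width-1)/2 of the centerline, round caps).  Noise affects intensities
    only; the truth masks are identical across noise settings.  The truth
    FAZ mask is the avascular cavity enclosed by the capillary ring
    (morphological closing of the vessel mask, then the cavity containing
    the FAZ center); the bare geometric disc is also returned.
    """
    size = net.size_px
    if size < 64:
        raise ConfigurationError("raster size must be >= 64 px")
    vessel = np.zeros((size, size), dtype=bool)
    skel = np.zeros((size, size), dtype=bool)
    disk_cache: dict[float, np.ndarray] = {}
    for s in net.segments:
        r_eff = max(0.0, (s.width_px - 1.0) / 2.0) + 1e-6
        key = round(r_eff, 2)
        if key not in disk_cache:
            disk_cache[key] = _disk_offsets(r_eff)
        offs = disk_cache[key]
        pts = _resample(s.points, spacing=0.5)
        ctr = np.rint(pts).astype(int)
        skel[np.clip(ctr[:, 0], 0, size - 1), np.clip(ctr[:, 1], 0, size - 1)] = True
        all_px = (ctr[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        np.clip(all_px[:, 0], 0, size - 1, out=all_px[:, 0])
        np.clip(all_px[:, 1], 0, size - 1, out=all_px[:, 1])
        vessel[all_px[:, 0], all_px[:, 1]] = True

    # geometric avascular disc
    rr, cc = np.mgrid[0:size, 0:size]
    cr, ccol = net.faz_center_px
    disc = (rr - cr) ** 2 + (cc - ccol) ** 2 <= net.faz_radius_px**2

    # vessel-bounded truth FAZ: close the plexus, take the cavity holding
    # the FAZ center
    if faz_closing_px is None:
        faz_closing_px = max(4, int(round(8 * size / 512)))
    closed = ndi.binary_closing(
        vessel, structure=_disk_structure(faz_closing_px), border_value=0
    )
    avasc = ~closed
    lbl, _ = ndi.label(avasc)
    center_lbl = lbl[int(round(cr)), int(round(ccol))]
    faz_mask = (lbl == center_lbl) if center_lbl != 0 else disc.copy()

    rng = np.random.default_rng(seed)
    img = np.where(vessel, 0.8, 0.0)
    if noise_sigma > 0:
        tex = ndi.gaussian_filter(rng.standard_normal((size, size)), 12.0)
        tex = (tex - tex.min()) / max(float(np.ptp(tex)), 1e-12)
        img = img + 2.0 * noise_sigma * tex + rng.normal(0.0, noise_sigma, (size, size))
    img = np.clip(img, 0.0, 1.0)

    angio = Angiogram(intensity=img, pixel_pitch_um=net.pixel_pitch_um)
    return RasterizedAngiogram(
        angiogram=angio,
        vessel_mask=vessel,
        skeleton_mask=skel,
        faz_disc_mask=disc,
        faz_mask=faz_mask,
        network=net,
    )


def _disk_structure(radius: int) -> np.ndarray:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return rr**2 + cc**2 <= radius**2


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass
class GroupSpec:
    label: str
    n_eyes: int
    degradation: DegradationConfig = field(default_factory=DegradationConfig)


def default_cohort_groups(n_eyes: int = 20, noise_sigma: float = 0.03,
                          size_px: int = DEFAULT_SIZE_PX) -> list[GroupSpec]:
    """Three-group design emulating healthy controls, diabetics without
    retinopathy, and mild retinopathy: graded terminal-branch pruning and
    fragment planting, with endpoint-count balancing so terminal counts stay
    level while vessel length falls.  Fragment lengths scale with the raster
    so they stay well below the 30 x VAD threshold at any size."""
    del size_px  # fragment lengths auto-scale with the raster at degrade time
    return [
        GroupSpec("HC", n_eyes, DegradationConfig(noise_sigma=noise_sigma)),
        GroupSpec(
            "noDR", n_eyes,
            DegradationConfig(prune_fraction=0.12, n_fragments=4,
                              balance_endpoints=True, noise_sigma=noise_sigma),
        ),
        GroupSpec(
            "mildDR", n_eyes,
            DegradationConfig(prune_fraction=0.25, n_fragments=9,
                              balance_endpoints=True, noise_sigma=noise_sigma),
        ),
    ]


def generate_cohort(
    groups: list[GroupSpec],
    seed: int,
    out_dir: str | Path,
    growth: GrowthParams | None = None,
    layers: tuple[str, ...] = ("DVP",),
) -> pd.DataFrame:
    """Generate a synthetic cohort: per-eye angiogram PNGs, truth JSON +
    masks, and a manifest CSV.  Deterministic under ``seed``."""
    import imageio.v3 as iio

    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate group labels")
    for g in groups:
        if g.n_eyes < 2:
            raise ConfigurationError("each group needs n_eyes >= 2")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    growth = growth or GrowthParams()
    rows = []
    for gi, g in enumerate(groups):
        for ei in range(g.n_eyes):
            for li, layer in enumerate(layers):
                ss = np.random.SeedSequence([int(seed), gi, ei, li])
                s_grow, s_deg, s_noise = ss.generate_state(3) >> np.uint32(1)
                params = growth if layer == "SVP" else replace(
                    growth, root_width_px=growth.root_width_px * 0.8
                )
                net = grow_network(params, seed=int(s_grow))
                cfg = replace(g.degradation, seed=int(s_deg))
                net = degrade(net, cfg)
                ras = rasterize(net, noise_sigma=cfg.noise_sigma, seed=int(s_noise))
                eye_id = f"{g.label}_{ei:03d}"
                stem = f"{eye_id}_{layer}"
                img16 = np.round(ras.angiogram.intensity * 65535).astype(np.uint16)
                iio.imwrite(out / f"{stem}.png", img16)
                (out / f"{stem}_truth.json").write_text(net.to_json())
                iio.imwrite(out / f"{stem}_vessels.png",
                            (ras.vessel_mask * 255).astype(np.uint8))
                iio.imwrite(out / f"{stem}_faz.png",
                            (ras.faz_mask * 255).astype(np.uint8))
                rows.append({
                    "path": f"{stem}.png",
                    "eye_id": eye_id,
                    "group": g.label,
                    "layer": layer,
                    "truth": f"{stem}_truth.json",
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
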