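"""Neuron skeletons, cable trees and compartmental discretization.

A :class:`Morphology` is a rooted tree of 3-D nodes with radii, as stored in
SWC files (units: µm).  Skeletons are "inflated" into cylindrical cables (one
cable per inter-branchpoint path, with the diameter set to twice the mean node
radius along the path) and then remeshed into short isopotential compartments
whose electrotonic length stays below a configurable bound, following the
standard practice for passive cable models of insect central neurons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SWC_SOMA = 1
SWC_NEURITE = 2  # primary neurite / unclassified process
SWC_DENDRITE = 3

#: electrotonic length bounds for a single compartment
DEFAULT_ELEC_UPPER = 0.1
ELEC_LOWER = 1e-4


class MorphologyError(ValueError):
    """Raised on malformed skeletons or SWC files."""


@dataclass
class Morphology:
    """Rooted tree of 3-D nodes with radii.

    Nodes are stored topologically sorted (every parent precedes its
    children); ``parents`` holds 0-based indices with ``-1`` at the root.
    ``ids`` keeps the original SWC identifiers for round-tripping.
    """

    ids: np.ndarray            # (n,) int, original SWC ids
    parents: np.ndarray        # (n,) int, 0-based index into arrays, -1 = root
    xyz: np.ndarray            # (n, 3) float, µm
    radius: np.ndarray         # (n,) float, µm
    labels: np.ndarray         # (n,) int, SWC structure type

    def __post_init__(self) -> None:
        n = len(self.ids)
        if n == 0:
            raise MorphologyError("empty morphology")
        if (self.radius <= 0).any():
            raise MorphologyError("all radii must be positive")
        if not np.isfinite(self.xyz).all():
            raise MorphologyError("coordinates must be finite")
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        if roots[0] != 0:
            raise MorphologyError("root must be the first node")
        if (self.parents[1:] >= np.arange(1, n)).any():
            raise MorphologyError("parents must precede children")

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        return 0

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            kids[self.parents[i]].append(i)
        return kids

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of the edge from each node to its parent (root: 0)."""
        out = np.zeros(self.n_nodes)
        p = self.parents[1:]
        out[1:] = np.linalg.norm(self.xyz[1:] - self.xyz[p], axis=1)
        return out

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "label": self.labels,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "parent_id": np.where(self.parents < 0, -1, self.ids[np.maximum(self.parents, 0)]),
            }
        )


def _toposort(ids, parent_ids, order_of):
    """Return node order such that parents precede children; detect cycles."""
    n = len(ids)
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    root = None
    for i, pid in enumerate(parent_ids):
        if pid == -1:
            if root is not None:
                raise MorphologyError("multiple root nodes (parent -1)")
            root = i
        else:
            children[order_of[pid]].append(i)
    if root is None:
        raise MorphologyError("no root node (parent -1) found")
    order: list[int] = []
    stack = [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children[i]))
    if len(order) != n:
        raise MorphologyError("cyclic parent references in skeleton")
    return order, root


def read_swc(path) -> Morphology:
    """Parse a standard 7-column SWC file (µm units, '#' comments)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0]); typ = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise MorphologyError(f"{path}:{lineno}: unparseable field ({exc})") from None
            rows.append((lineno, nid, typ, x, y, z, r, pid))
    if not rows:
        raise MorphologyError(f"{path}: no nodes")

    ids = [r[1] for r in rows]
    order_of: dict[int, int] = {}
    for r in rows:
        if r[1] in order_of:
            raise MorphologyError(f"{path}:{r[0]}: duplicate node id {r[1]}")
        order_of[r[1]] = len(order_of)
    for r in rows:
        if r[7] != -1 and r[7] not in order_of:
            raise MorphologyError(f"{path}:{r[0]}: node {r[1]} references missing parent {r[7]}")

    parent_ids = [r[7] for r in rows]
    order, _ = _toposort(ids, parent_ids, order_of)
    rank = {old: new for new, old in enumerate(order)}
    rows = [rows[i] for i in order]
    return Morphology(
        ids=np.array([r[1] for r in rows], dtype=int),
        parents=np.array(
            [-1 if r[7] == -1 else rank[order_of[r[7]]] for r in rows], dtype=int
        ),
        xyz=np.array([[r[3], r[4], r[5]] for r in rows], dtype=float),
        radius=np.array([r[6] for r in rows], dtype=float),
        labels=np.array([r[2] for r in rows], dtype=int),
    )


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology as standard SWC (1-based ids, root parent -1)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(morph.n_nodes):
            pid = -1 if morph.parents[i] < 0 else int(morph.ids[morph.parents[i]])
            fh.write(
                f"{int(morph.ids[i])} {int(morph.labels[i])} "
                f"{morph.xyz[i, 0]:.6g} {morph.xyz[i, 1]:.6g} {morph.xyz[i, 2]:.6g} "
                f"{morph.radius[i]:.6g} {pid}\n"
            )


def total_path_length(morph: Morphology, subtree_root: int | None = None) -> float:
    """Sum of Euclidean inter-node distances, optionally below ``subtree_root``."""
    lengths = morph.edge_lengths()
    if subtree_root is None or subtree_root == morph.root:
        return float(lengths.sum())
    keep = np.zeros(morph.n_nodes, dtype=bool)
    keep[subtree_root] = True
    for i in range(subtree_root + 1, morph.n_nodes):
        if morph.parents[i] >= 0 and keep[morph.parents[i]]:
            keep[i] = True
    keep[subtree_root] = False  # edge above the subtree root is upstream
    return float(lengths[keep].sum())


@dataclass
class CableSegment:
    """Uniform cylinder between two branch points of the skeleton."""

    index: int
    parent_cable: int          # -1 if attached to the root/soma
    length: float              # µm
    diameter: float            # µm, 2 × mean node radius along the path
    label: int = SWC_DENDRITE
    node_span: list[int] = field(default_factory=list)  # node indices, proximal→distal

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise MorphologyError("cable length and diameter must be positive")


def inflate(morph: Morphology) -> list[CableSegment]:
    """Convert a wireframe skeleton into cylinder cables.

    One cable per path between branch points (or root/leaf); the cable's
    diameter is twice the mean node radius along the path, emulating the
    caliber-matched cylinder representation of traced neurites.  Soma nodes
    (SWC type 1) are excluded; the soma is modelled separately.
    """
    kids = morph.children()
    lengths = morph.edge_lengths()
    is_soma = morph.labels == SWC_SOMA

    cables: list[CableSegment] = []
    cable_of_node = np.full(morph.n_nodes, -1, dtype=int)
    # starting points: first non-soma child chains hanging off soma/root or branchpoints
    stack: list[tuple[int, int]] = []  # (first node of path, parent cable index)
    for i in range(morph.n_nodes):
        if is_soma[i]:
            for c in kids[i]:
                if not is_soma[c]:
                    stack.append((c, -1))
    if not stack and not is_soma.all():
        # root itself is a neurite node
        stack.append((morph.root, -1))

    while stack:
        start, parent_cable = stack.pop()
        path = [start]
        node = start
        while len(kids[node]) == 1:
            node = kids[node][0]
            path.append(node)
        # include the proximal anchor node radius if it is a neurite node
        anchor = morph.parents[start]
        span = ([anchor] if anchor >= 0 and not is_soma[anchor] else []) + path
        length = float(sum(lengths[j] for j in path))
        radii = morph.radius[span]
        if length <= 0:
            warnings.warn(
                f"zero-length path at node id {morph.ids[start]}; collapsed into parent cable",
                stacklevel=2,
            )
            for c in kids[path[-1]]:
                stack.append((c, parent_cable))
            for j in path:
                cable_of_node[j] = parent_cable
            continue
        cab = CableSegment(
            index=len(cables),
            parent_cable=parent_cable,
            length=length,
            diameter=2.0 * float(radii.mean()),
            label=int(morph.labels[path[-1]]),
            node_span=path,
        )
        cables.append(cab)
        for j in path:
            cable_of_node[j] = cab.index
        for c in kids[path[-1]]:
            stack.append((c, cab.index))
    return cables


def space_constant(diameter_um: float, r_m_kohm_cm2: float, r_a_ohm_cm: float) -> float:
    """Cable space constant λ in µm: sqrt(R_m·d / (4·R_a))."""
    lam_cm = math.sqrt(r_m_kohm_cm2 * 1e3 * diameter_um * 1e-4 / (4.0 * r_a_ohm_cm))
    return lam_cm * 1e4


@dataclass
class CompartmentalModel:
    """Discretized passive electrical tree.

    Compartment 0 is the soma (a cylinder with length = diameter =
    2 × soma radius); cables follow in topological order, proximal to
    distal.  Geometry only — membrane/axial conductances are derived in
    :mod:`glomsim.cablesim` from :class:`~glomsim.cablesim.MembraneParams`.
    """

    parent: np.ndarray         # (n,) int, -1 at soma
    length: np.ndarray         # (n,) µm
    diameter: np.ndarray       # (n,) µm
    area: np.ndarray           # (n,) µm², lateral cylinder area
    cable_index: np.ndarray    # (n,) int, -1 for soma
    soma_index: int
    membrane: "object"         # MembraneParams; typed loosely to avoid an import cycle
    cables: list[CableSegment]
    cable_comp_start: np.ndarray  # (n_cables,) first compartment of each cable
    cable_n_comp: np.ndarray      # (n_cables,)
    merged_cables: list[int] = field(default_factory=list)

    @property
    def n_compartments(self) -> int:
        return len(self.parent)

    def compartments_of_cable(self, cable: int) -> np.ndarray:
        s = self.cable_comp_start[cable]
        return np.arange(s, s + self.cable_n_comp[cable])

    def locate(self, cable: int, arclength: float) -> int:
        """Compartment index containing position ``arclength`` µm along a cable."""
        n = int(self.cable_n_comp[cable])
        if n == 0:  # merged-away cable: bind to the parent's attachment compartment
            parent = self.cables[cable].parent_cable
            if parent < 0:
                return self.soma_index
            return int(self.cable_comp_start[parent] + self.cable_n_comp[parent] - 1)
        L = self.cables[cable].length
        k = min(n - 1, int(arclength / L * n)) if L > 0 else 0
        return int(self.cable_comp_start[cable] + max(0, k))

    def cable_middle_compartments(self) -> np.ndarray:
        """One representative (middle) compartment per cable."""
        out = []
        for c in range(len(self.cables)):
            n = int(self.cable_n_comp[c])
            if n > 0:
                out.append(int(self.cable_comp_start[c] + n // 2))
        return np.array(out, dtype=int)


def remesh(
    cables: list[CableSegment],
    membrane,
    soma_radius: float,
    elec_upper: float = DEFAULT_ELEC_UPPER,
) -> CompartmentalModel:
    """Split cables into compartments of electrotonic length ≤ ``elec_upper``.

    Each cable of electrotonic length L is divided into ``max(1, ceil(L /
    elec_upper))`` equal compartments.  Cables shorter than the lower
    electrotonic bound (1e-4) are merged upward into their parent's distal
    compartment (area-conserving) and reported in ``merged_cables``.
    """
    if membrane.r_m <= 0 or membrane.r_a <= 0 or membrane.c_m <= 0:
        raise ValueError("membrane parameters must be positive")
    if soma_radius <= 0:
        raise ValueError("soma radius must be positive")

    parent = [-1]
    length = [2.0 * soma_radius]
    diameter = [2.0 * soma_radius]
    area = [math.pi * 2.0 * soma_radius * 2.0 * soma_radius]
    cable_index = [-1]
    cable_comp_start = np.zeros(len(cables), dtype=int)
    cable_n_comp = np.zeros(len(cables), dtype=int)
    merged: list[int] = []

    def attachment_comp(cable_idx: int) -> int:
        """Distal compartment of the given cable (following merges upward)."""
        c = cable_idx
        while c >= 0 and cable_n_comp[c] == 0:
            c = cables[c].parent_cable
        if c < 0:
            return 0
        return int(cable_comp_start[c] + cable_n_comp[c] - 1)

    for cab in cables:
        lam = space_constant(cab.diameter, membrane.r_m, membrane.r_a)
        L_elec = cab.length / lam
        if L_elec < ELEC_LOWER:
            # merge into parent's distal compartment, conserving membrane area
            merged.append(cab.index)
            tgt = attachment_comp(cab.parent_cable)
            area[tgt] += math.pi * cab.diameter * cab.length
            continue
        n = max(1, math.ceil(L_elec / elec_upper))
        l_comp = cab.length / n
        first = len(parent)
        cable_comp_start[cab.index] = first
        cable_n_comp[cab.index] = n
        p = attachment_comp(cab.parent_cable)
        for k in range(n):
            parent.append(p)
            length.append(l_comp)
            diameter.append(cab.diameter)
            area.append(math.pi * cab.diameter * l_comp)
            cable_index.append(cab.index)
            p = len(parent) - 1

    if merged:
        warnings.warn(
            f"{len(merged)} cable(s) below electrotonic lower bound merged upward",
            stacklevel=2,
        )
    return CompartmentalModel(
        parent=np.array(parent, dtype=int),
        length=np.array(length),
        diameter=np.array(diameter),
        area=np.array(area),
        cable_index=np.array(cable_index, dtype=int),
        soma_index=0,
        membrane=membrane,
        cables=cables,
        cable_comp_start=cable_comp_start,
        cable_n_comp=cable_n_comp,
        merged_cables=merged,
    )


def build_compartmental_model(
    morph: Morphology,
    membrane,
    elec_upper: float = DEFAULT_ELEC_UPPER,
    soma_radius: float | None = None,
) -> CompartmentalModel:
    """Inflate a skeleton and remesh it in one step.

    The soma radius defaults to the maximum radius among soma-labelled nodes,
    or the root node's radius if no node is labelled as soma.
    """
    if soma_radius is None:
        soma_nodes = morph.labels == SWC_SOMA
        soma_radius = float(
            morph.radius[soma_nodes].max() if soma_nodes.any() else morph.radius[morph.root]
        )
    cables = inflate(morph)
    return remesh(cables, membrane, soma_radius=soma_radius, elec_upper=elec_upper)


def _resample_polyline(morph: Morphology, step: float):
    """Sample every edge at ≤ ``step`` µm spacing.

    Returns (points, seg_mid, seg_len): all sample points, midpoints of the
    sampled sub-intervals and their lengths.
    """
    pts = [morph.xyz[morph.root]]
    mids = []
    lens = []
    for i in range(morph.n_nodes):
        p = morph.parents[i]
        if p < 0:
            continue
        a, b = morph.xyz[p], morph.xyz[i]
        d = float(np.linalg.norm(b - a))
        if d == 0:
            continue
        n = max(1, math.ceil(d / step))
        ts = np.linspace(0.0, 1.0, n + 1)[:, None]
        seg = a + ts * (b - a)
        pts.append(seg[1:])
        mids.append((seg[:-1] + seg[1:]) / 2.0)
        lens.append(np.full(n, d / n))
    points = np.vstack([np.atleast_2d(p) for p in pts])
    if mids:
        return points, np.vstack(mids), np.concatenate(lens)
    return points, np.empty((0, 3)), np.empty(0)


def potential_connection_length(
    dendrite: Morphology,
    axon: Morphology,
    radius: float = 0.5,
    step: float = 0.1,
) -> float:
    """Dendritic path length within ``radius`` µm of the axon (L_d).

    Both skeletons are resampled at ≤ ``step`` µm; a dendritic sub-interval
    counts when its midpoint lies within ``radius`` of any axon sample point.
    Monotone non-decreasing in ``radius`` by construction.
    """
    axon_pts, _, _ = _resample_polyline(axon, step)
    _, mids, lens = _resample_polyline(dendrite, step)
    if len(mids) == 0:
        return 0.0
    tree = cKDTree(axon_pts)
    dist, _ = tree.query(mids, k=1, distance_upper_bound=radius)
    return float(lens[np.isfinite(dist)].sum())
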