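"""Arbor data model, SWC input/output and geometric utilities.

An :class:`Arbor` is a single rooted tree of 3D nodes (coordinates in μm)
holding one axonal reconstruction at one time point.  The module provides

* reading and writing the standard 7-column SWC dialect,
* decomposition into *segments* — maximal paths bordered by two branch
  points or by a branch point and a terminal point,
* arclength resampling to equidistant nodes (default 0.15 μm),
* least-squares rigid (rotation + translation, no scaling/reflection)
  alignment from manually placed landmark pairs.

All coordinates are in μm throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import DegenerateFitError, SWCFormatError

__all__ = [
    "ArborNode",
    "Arbor",
    "Segment",
    "Landmarks",
    "read_swc",
    "write_swc",
    "decompose_segments",
    "resample_arbor",
    "fit_rigid",
    "rigid_align",
]


@dataclass(frozen=True)
class ArborNode:
    """One SWC node: id, structure type, 3D position (μm), radius, parent id."""

    node_id: int
    type_code: int
    position: np.ndarray  # shape (3,), μm
    radius: float
    parent_id: int  # -1 for the root


class Arbor:
    """A rooted tree of 3D nodes with radii; one reconstruction time point.

    Nodes are stored as flat arrays in file/insertion order.  Node ids are
    arbitrary positive integers (1-based in standard exports); ``parent_id``
    -1 marks the single root.  Invariants enforced on construction:

    * node ids unique, exactly one root,
    * every parent id references an existing node,
    * the parent relation is a single connected acyclic tree.
    """

    def __init__(
        self,
        ids: Sequence[int],
        parents: Sequence[int],
        xyz: np.ndarray,
        radius: Sequence[float] | None = None,
        type_code: Sequence[int] | None = None,
        validate: bool = True,
    ):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.parents = np.asarray(parents, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=float).reshape(len(self.ids), 3)
        n = len(self.ids)
        self.radius = (
            np.asarray(radius, dtype=float) if radius is not None else np.full(n, 0.5)
        )
        self.type_code = (
            np.asarray(type_code, dtype=np.int64)
            if type_code is not None
            else np.full(n, 2, dtype=np.int64)
        )
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        if len(self._index) != n:
            raise SWCFormatError("duplicate node ids")
        # parent positions (-1 where root)
        pidx = np.empty(n, dtype=np.int64)
        roots = 0
        for k, p in enumerate(self.parents):
            if p == -1:
                pidx[k] = -1
                roots += 1
            else:
                j = self._index.get(int(p))
                if j is None:
                    raise SWCFormatError(
                        f"dangling parent: node {int(self.ids[k])} references "
                        f"missing parent {int(p)}"
                    )
                pidx[k] = j
        self.parent_index = pidx
        if roots != 1:
            raise SWCFormatError(f"expected exactly one root, found {roots}")
        self.root_index = int(np.nonzero(pidx == -1)[0][0])
        children: list[list[int]] = [[] for _ in range(n)]
        for k, j in enumerate(pidx):
            if j >= 0:
                children[j].append(k)
        self._children = children
        if validate:
            self._check_connected()

    # -- construction / iteration -------------------------------------------------

    @classmethod
    def from_nodes(cls, nodes: Iterable[ArborNode]) -> "Arbor":
        nodes = list(nodes)
        return cls(
            [n.node_id for n in nodes],
            [n.parent_id for n in nodes],
            np.array([n.position for n in nodes], dtype=float).reshape(len(nodes), 3),
            [n.radius for n in nodes],
            [n.type_code for n in nodes],
        )

    def _check_connected(self) -> None:
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [self.root_index]
        seen[self.root_index] = True
        while stack:
            k = stack.pop()
            for c in self._children[k]:
                seen[c] = True
                stack.append(c)
        if not seen.all():
            raise SWCFormatError("tree is disconnected or contains a cycle")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_id(self) -> int:
        return int(self.ids[self.root_index])

    def __iter__(self) -> Iterator[ArborNode]:
        for k in range(self.n_nodes):
            yield ArborNode(
                int(self.ids[k]),
                int(self.type_code[k]),
                self.xyz[k].copy(),
                float(self.radius[k]),
                int(self.parents[k]),
            )

    def node(self, node_id: int) -> ArborNode:
        k = self._index[int(node_id)]
        return ArborNode(
            int(self.ids[k]),
            int(self.type_code[k]),
            self.xyz[k].copy(),
            float(self.radius[k]),
            int(self.parents[k]),
        )

    def children_of(self, node_id: int) -> list[int]:
        return [int(self.ids[c]) for c in self._children[self._index[int(node_id)]]]

    def position_of(self, node_id: int) -> np.ndarray:
        return self.xyz[self._index[int(node_id)]]

    # -- derived geometry ----------------------------------------------------------

    @property
    def edge_lengths(self) -> np.ndarray:
        """Parent–child Euclidean distance per node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        mask = self.parent_index >= 0
        out[mask] = np.linalg.norm(
            self.xyz[mask] - self.xyz[self.parent_index[mask]], axis=1
        )
        return out

    @property
    def total_length(self) -> float:
        """Total cable length: Σ parent–child Euclidean distances (μm)."""
        return float(self.edge_lengths.sum())

    @property
    def terminal_ids(self) -> list[int]:
        """Ids of nodes with no children (the root only if it is the sole node)."""
        return [int(self.ids[k]) for k in range(self.n_nodes) if not self._children[k]]

    @property
    def branch_point_ids(self) -> list[int]:
        """Ids of nodes with ≥ 2 children."""
        return [
            int(self.ids[k]) for k in range(self.n_nodes) if len(self._children[k]) >= 2
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Arbor":
        """Return a copy with positions mapped through x ↦ R·x + t."""
        xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return Arbor(
            self.ids.copy(), self.parents.copy(), xyz, self.radius.copy(),
            self.type_code.copy(), validate=False,
        )

    # -- comparison ----------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Arbor):
            return NotImplemented
        return self.approx_equal(other, tol=0.0)

    def approx_equal(self, other: "Arbor", tol: float = 1e-4) -> bool:
        """Same node set (by id): same parents, types, positions/radii within tol μm."""
        if self.n_nodes != other.n_nodes or set(self._index) != set(other._index):
            return False
        o1 = np.argsort(self.ids)
        o2 = np.argsort(other.ids)
        if not np.array_equal(self.parents[o1], other.parents[o2]):
            return False
        if not np.array_equal(self.type_code[o1], other.type_code[o2]):
            return False
        if tol == 0.0:
            return bool(
                np.array_equal(self.xyz[o1], other.xyz[o2])
                and np.array_equal(self.radius[o1], other.radius[o2])
            )
        return bool(
            np.max(np.abs(self.xyz[o1] - other.xyz[o2])) <= tol
            and np.max(np.abs(self.radius[o1] - other.radius[o2])) <= tol
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Arbor(n_nodes={self.n_nodes}, cable={self.total_length:.2f} μm, "
            f"terminals={len(self.terminal_ids)})"
        )


# -- SWC input / output -----------------------------------------------------------


def read_swc(path: str | Path) -> Arbor:
    """Read an arbor from a standard 7-column SWC file (coordinates in μm).

    Columns: id, type, x, y, z, radius, parent.  Lines starting with ``#``
    and blank lines are ignored.  Node order in the file is preserved.

    Raises
    ------
    SWCFormatError
        On non-numeric fields (with line number), wrong column count,
        duplicate ids, multiple roots, dangling parents, or cycles.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCFormatError(
                    f"{path}:{lineno}: expected 7 columns, found {len(parts)}"
                )
            try:
                ids.append(int(parts[0]))
                types.append(int(parts[1]))
                xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
                radii.append(float(parts[5]))
                parents.append(int(parts[6]))
            except ValueError as exc:
                raise SWCFormatError(f"{path}:{lineno}: non-numeric field ({exc})")
    if not ids:
        raise SWCFormatError(f"{path}: no data lines")
    return Arbor(ids, parents, np.asarray(xyz), radii, types)


def _topological_order(arbor: Arbor) -> list[int]:
    """Node indices with every parent before its children (stable child order)."""
    order: list[int] = []
    stack = [arbor.root_index]
    while stack:
        k = stack.pop()
        order.append(k)
        # reversed so the first child is emitted first
        stack.extend(reversed(arbor._children[k]))
    return order


def write_swc(arbor: Arbor, path: str | Path) -> None:
    """Write an arbor as standard SWC, nodes in topological (parent-first) order.

    Original node ids are kept; only line order changes, so
    ``read_swc(write_swc(a))`` equals ``a`` up to float formatting
    (6 decimal places, ≤ 1e-4 μm).
    """
    with open(path, "w") as fh:
        fh.write("# SWC exported by arbordyn; coordinates in um\n")
        for k in _topological_order(arbor):
            fh.write(
                f"{int(arbor.ids[k])} {int(arbor.type_code[k])} "
                f"{arbor.xyz[k, 0]:.6f} {arbor.xyz[k, 1]:.6f} {arbor.xyz[k, 2]:.6f} "
                f"{arbor.radius[k]:.6f} {int(arbor.parents[k])}\n"
            )


# -- segment decomposition --------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """Maximal unbranched path bordered by two topological landmarks.

    ``node_ids`` runs from the proximal landmark (root or branch point,
    inclusive) to the distal landmark (branch point or terminal point,
    inclusive); interior nodes have exactly one child.  ``length`` includes
    the step from the proximal landmark, so segment lengths sum exactly to
    total cable length.  A branch point is *owned* by the segment it ends
    (its parent-side segment); as the first element of its child segments
    it is a border marker only.
    """

    node_ids: tuple[int, ...]
    kind: str  # "terminal" | "internal"
    length: float  # μm

    @property
    def proximal_id(self) -> int:
        return self.node_ids[0]

    @property
    def distal_id(self) -> int:
        return self.node_ids[-1]

    @property
    def owned_ids(self) -> tuple[int, ...]:
        """Nodes belonging to this segment (excludes the proximal border)."""
        return self.node_ids[1:]


def decompose_segments(arbor: Arbor) -> list[Segment]:
    """Split an arbor into segments bordered by branch/terminal points.

    Returned in breadth-first order from the root (a segment always precedes
    the segments it borders distally).  Every non-root node lies in exactly
    one segment's ``owned_ids``; Σ lengths equals total cable length.
    A single-node arbor yields no segments.
    """
    segments: list[Segment] = []
    idx_children = arbor._children
    queue = [arbor.root_index]
    while queue:
        lm = queue.pop(0)
        for child in idx_children[lm]:
            path = [lm]
            node = child
            while len(idx_children[node]) == 1:
                path.append(node)
                node = idx_children[node][0]
            path.append(node)
            pts = arbor.xyz[path]
            length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            kind = "terminal" if not idx_children[node] else "internal"
            segments.append(
                Segment(tuple(int(arbor.ids[k]) for k in path), kind, length)
            )
            if idx_children[node]:
                queue.append(node)
    return segments


# -- resampling -------------------------------------------------------------------


def resample_arbor(arbor: Arbor, spacing: float = 0.15) -> Arbor:
    """Resample so consecutive nodes are equidistant at ``spacing`` μm.

    Each segment polyline is re-walked at arclength multiples of ``spacing``;
    branch points and terminal points are preserved exactly, so the final
    step of each segment may be shorter than ``spacing``.  Node ids are
    renumbered sequentially from 1 (root first).

    Raises
    ------
    ValueError
        If ``spacing`` ≤ 0 or exceeds the total cable length.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if arbor.n_nodes > 1 and spacing > arbor.total_length:
        raise ValueError(
            f"spacing {spacing} μm exceeds total cable length "
            f"{arbor.total_length:.3f} μm"
        )
    segments = decompose_segments(arbor)
    new_ids: list[int] = [1]
    new_parents: list[int] = [-1]
    new_xyz: list[np.ndarray] = [arbor.xyz[arbor.root_index].copy()]
    new_radius: list[float] = [float(arbor.radius[arbor.root_index])]
    new_type: list[int] = [int(arbor.type_code[arbor.root_index])]
    id_map = {arbor.root_id: 1}
    next_id = 2
    for seg in segments:
        kidx = [arbor._index[i] for i in seg.node_ids]
        pts = arbor.xyz[kidx]
        rad = arbor.radius[kidx]
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        L = cum[-1]
        n_interior = int(np.floor(L / spacing - 1e-9))
        s_vals = np.arange(1, n_interior + 1) * spacing
        s_vals = np.concatenate([s_vals[s_vals < L - 1e-9], [L]])
        px = np.interp(s_vals, cum, pts[:, 0])
        py = np.interp(s_vals, cum, pts[:, 1])
        pz = np.interp(s_vals, cum, pts[:, 2])
        pr = np.interp(s_vals, cum, rad)
        tcode = int(arbor.type_code[kidx[-1]])
        prev = id_map[seg.proximal_id]
        for j in range(len(s_vals)):
            nid = next_id
            next_id += 1
            new_ids.append(nid)
            new_parents.append(prev)
            new_xyz.append(np.array([px[j], py[j], pz[j]]))
            new_radius.append(float(pr[j]))
            new_type.append(tcode)
            prev = nid
        id_map[seg.distal_id] = prev
    return Arbor(new_ids, new_parents, np.asarray(new_xyz), new_radius, new_type)


# -- rigid alignment --------------------------------------------------------------


@dataclass
class Landmarks:
    """Corresponding 3D point pairs (μm): ``dst ≈ R·src + t``."""

    src: np.ndarray  # (n, 3)
    dst: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float).reshape(-1, 3)
        self.dst = np.asarray(self.dst, dtype=float).reshape(-1, 3)
        if self.src.shape != self.dst.shape:
            raise ValueError("landmark src/dst shapes differ")

    def __len__(self) -> int:
        return len(self.src)


def fit_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with ``dst ≈ R·src + t``.

    Closed-form orthogonal Procrustes (Kabsch) with a determinant correction
    so no reflection can occur; no scaling is fitted.

    Raises
    ------
    DegenerateFitError
        Fewer than 3 pairs, or pairs that are collinear (rank < 2), leaving
        the rotation under-determined.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if len(src) < 3:
        raise DegenerateFitError("at least 3 landmark pairs required")
    sc = src - src.mean(axis=0)
    dc = dst - dst.mean(axis=0)
    sv = np.linalg.svd(sc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-30):
        raise DegenerateFitError("landmark pairs are collinear; rotation not unique")
    H = sc.T @ dc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return R, t


def rigid_align(moving: Arbor, landmarks: Landmarks) -> Arbor:
    """Rigidly transform ``moving`` onto the landmark target frame.

    The returned arbor has every node mapped through the least-squares
    rotation + translation; being an isometry, all inter-node distances are
    preserved.
    """
    R, t = fit_rigid(landmarks.src, landmarks.dst)
    return moving.transformed(R, t)


def landmark_rmsd(landmarks: Landmarks, R: np.ndarray, t: np.ndarray) -> float:
    """Root-mean-square landmark residual of a candidate transform (μm)."""
    resid = landmarks.dst - (landmarks.src @ np.asarray(R).T + np.asarray(t))
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
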