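"""Nonconforming quadtree/octree tessellation of a rectangular domain.

Elements are axis-aligned boxes arranged in a 2^d-tree; neighbouring leaves
may differ by at most one refinement level (2:1 balance), so a coarse face
is partitioned by at most 2^(d-1) fine sub-faces (hanging nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

Key = tuple[int, tuple[int, ...]]  # (level, integer index per axis)


@dataclass(frozen=True)
class Face:
    """An (oriented) mesh face used in flux assembly.

    Interior: ``minus``/``plus`` are element ids with the normal +e_axis
    pointing from minus to plus; the face geometry (center, tangential
    half-extents) is that of the *finer* side on nonconforming faces.
    Boundary: ``plus`` is -1 and ``normal_sign`` gives the outward direction.
    """

    minus: int
    plus: int
    axis: int
    center: tuple[float, ...]
    halfwidth: tuple[float, ...]   # tangential half-extents (0 on `axis`)
    normal_sign: int = 1

    @property
    def is_boundary(self) -> bool:
        return self.plus < 0


class Tessellation:
    """Leaves of a 2^d-tree over the box [origin, origin + size]."""

    def __init__(self, origin: Iterable[float], size: Iterable[float],
                 leaves: list[Key]):
        self.origin = np.asarray(tuple(origin), dtype=float)
        self.size = np.asarray(tuple(size), dtype=float)
        self.dim = len(self.origin)
        if np.any(self.size <= 0):
            raise ValueError("domain size must be positive")
        self._set_leaves(leaves)

    # -- construction ------------------------------------------------------

    @classmethod
    def uniform(cls, origin: Iterable[float], size: Iterable[float],
                level: int) -> "Tessellation":
        origin = tuple(origin)
        dim = len(origin)
        if level < 0:
            raise ValueError("level must be nonnegative")
        n = 2 ** level
        leaves = [(level, idx) for idx in np.ndindex(*([n] * dim))]
        return cls(origin, size, leaves)

    @classmethod
    def unit(cls, dim: int, level: int) -> "Tessellation":
        return cls.uniform((0.0,) * dim, (1.0,) * dim, level)

    def _set_leaves(self, leaves: list[Key]) -> None:
        self.leaves = sorted(leaves)
        self.index = {key: i for i, key in enumerate(self.leaves)}
        self.levels = np.array([k[0] for k in self.leaves], dtype=int)
        idx = np.array([k[1] for k in self.leaves], dtype=float)
        scale = self.size[None, :] / (2.0 ** self.levels)[:, None]
        self.widths = scale                                  # (s, d)
        self.corners = self.origin[None, :] + idx * scale    # lower corners
        self.centers = self.corners + 0.5 * scale
        self.measures = np.prod(scale, axis=1)
        # every strict ancestor of a leaf is an interior (split) node
        interior: set[Key] = set()
        for level, idx_t in self.leaves:
            lv, ix = level, idx_t
            while lv > 0:
                lv -= 1
                ix = tuple(i // 2 for i in ix)
                interior.add((lv, ix))
        self._interior = interior
        self._faces: list[Face] | None = None

    @property
    def n_elements(self) -> int:
        return len(self.leaves)

    def element_width(self, e: int) -> np.ndarray:
        return self.widths[e]

    # -- lookup ------------------------------------------------------------

    def covering_leaf(self, level: int, idx: tuple[int, ...]) -> Key | None:
        """The leaf containing cell (level, idx), if it is at level or coarser."""
        lv, ix = level, idx
        while lv >= 0:
            key = (lv, ix)
            if key in self.index:
                return key
            lv -= 1
            ix = tuple(i // 2 for i in ix)
        return None

    def is_split(self, level: int, idx: tuple[int, ...]) -> bool:
        return (level, idx) in self._interior

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Element id containing each physical point (clipped into the domain)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        max_level = int(self.levels.max())
        n = 2 ** max_level
        rel = (points - self.origin) / self.size
        cell = np.clip((rel * n).astype(int), 0, n - 1)
        out = np.empty(len(points), dtype=int)
        for p in range(len(points)):
            key = self.covering_leaf(max_level, tuple(cell[p]))
            if key is None:
                raise ValueError(f"point {points[p]} not covered by the mesh")
            out[p] = self.index[key]
        return out

    # -- refinement --------------------------------------------------------

    def refine(self, flags: np.ndarray) -> "Tessellation":
        """Split flagged leaves once, then restore 2:1 balance by closure."""
        flags = np.asarray(flags, dtype=bool)
        if flags.shape != (self.n_elements,):
            raise ValueError("flags must have one entry per element")
        to_split = {self.leaves[e] for e in np.nonzero(flags)[0]}
        leaves = set(self.leaves)
        while to_split:
            for key in to_split:
                leaves.discard(key)
                level, idx = key
                for child in np.ndindex(*([2] * self.dim)):
                    leaves.add((level + 1,
                                tuple(2 * i + c for i, c in zip(idx, child))))
            mesh = Tessellation(self.origin, self.size, sorted(leaves))
            to_split = mesh._balance_violations()
        return Tessellation(self.origin, self.size, sorted(leaves))

    def _balance_violations(self) -> set[Key]:
        """Leaves whose face neighbour is more than one level finer."""
        bad: set[Key] = set()
        for level, idx in self.leaves:
            if level + 2 > int(self.levels.max()):
                continue
            # probe at level+2: if a (level+2) descendant-neighbour exists,
            # this leaf violates 2:1 balance
            for axis in range(self.dim):
                for direction in (-1, 1):
                    probe = self._neighbor_cell(level, idx, axis, direction)
                    if probe is None:
                        continue
                    if self.is_split(*probe) and any(
                            self.is_split(level + 1, tuple(
                                2 * i + c for i, c in zip(probe[1], child_off)))
                            for child_off in self._face_children(axis, -direction)):
                        bad.add((level, idx))
        return bad

    def _neighbor_cell(self, level: int, idx: tuple[int, ...], axis: int,
                       direction: int) -> Key | None:
        n = 2 ** level
        j = idx[axis] + direction
        if j < 0 or j >= n:
            return None
        return (level, tuple(j if a == axis else i
                             for a, i in enumerate(idx)))

    def _face_children(self, axis: int, direction: int):
        """Child offsets of a cell touching its face in `direction` on `axis`."""
        face_side = 0 if direction < 0 else 1
        for off in np.ndindex(*([2] * self.dim)):
            if off[axis] == face_side:
                yield off

    def refine_where(self, predicate) -> "Tessellation":
        flags = np.array([bool(predicate(e)) for e in range(self.n_elements)])
        return self.refine(flags)

    # -- faces -------------------------------------------------------------

    @property
    def faces(self) -> list[Face]:
        if self._faces is None:
            self._faces = self._build_faces()
        return self._faces

    def _build_faces(self) -> list[Face]:
        faces: list[Face] = []
        for e, (level, idx) in enumerate(self.leaves):
            width = self.widths[e]
            corner = self.corners[e]
            for axis in range(self.dim):
                half = tuple(0.0 if a == axis else 0.5 * width[a]
                             for a in range(self.dim))
                for direction in (-1, 1):
                    nb = self._neighbor_cell(level, idx, axis, direction)
                    if nb is None:
                        # boundary face
                        c = corner + 0.5 * width
                        c[axis] = corner[axis] + (width[axis] if direction > 0
                                                  else 0.0)
                        faces.append(Face(e, -1, axis, tuple(c), half,
                                          normal_sign=direction))
                        continue
                    if self.is_split(*nb):
                        continue  # finer neighbour owns the sub-faces
                    cov = self.covering_leaf(*nb)
                    if cov is None:
                        raise RuntimeError("mesh does not cover its domain")
                    cov_level = cov[0]
                    if cov_level == level and direction < 0:
                        continue  # same-level faces recorded from the minus side
                    if cov_level < level - 1:
                        raise RuntimeError("2:1 balance violated")
                    other = self.index[cov]
                    c = corner + 0.5 * width
                    c[axis] = corner[axis] + (width[axis] if direction > 0
                                              else 0.0)
                    if direction > 0:
                        faces.append(Face(e, other, axis, tuple(c), half))
                    else:
                        faces.append(Face(other, e, axis, tuple(c), half))
        return faces
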