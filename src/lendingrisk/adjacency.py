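"""Symmetric tract neighbor structures.

The spatial backbone of the whole pipeline: the intrinsic CAR prior, the
field simulator and the contiguity builders all consume the same
:class:`Adjacency` object — an immutable, validated neighbor-list graph
over ``n`` census tracts indexed ``0..n-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Adjacency:
    """Symmetric 0/1 neighbor structure over ``n`` tracts.

    Parameters
    ----------
    neighbors
        ``neighbors[i]`` is the sorted tuple of tract indices adjacent to
        tract ``i``. Must be symmetric and free of self-loops.
    """

    neighbors: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.neighbors)
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                if j == i:
                    raise ValueError(f"self-loop at tract {i}")
                if not 0 <= j < n:
                    raise ValueError(f"neighbor index {j} out of range at tract {i}")
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency: {i}->{j} but not {j}->{i}")

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def degree(self) -> np.ndarray:
        return np.array([len(nbrs) for nbrs in self.neighbors], dtype=np.int64)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list with i < j."""
        return [(i, j) for i, nbrs in enumerate(self.neighbors) for j in nbrs if i < j]

    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.neighbors) // 2

    def islands(self) -> list[int]:
        """Tracts with no neighbors."""
        return [i for i, nbrs in enumerate(self.neighbors) if not nbrs]

    def components(self) -> list[list[int]]:
        """Connected components (sorted lists of tract indices)."""
        seen = np.zeros(self.n, dtype=bool)
        comps: list[list[int]] = []
        for start in range(self.n):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                i = stack.pop()
                comp.append(i)
                for j in self.neighbors[i]:
                    if not seen[j]:
                        seen[j] = True
                        stack.append(j)
            comps.append(sorted(comp))
        return comps

    def subgraph(self, keep: Sequence[int]) -> "Adjacency":
        """Induced adjacency on the given tract indices (new 0-based order)."""
        keep = list(keep)
        pos = {old: new for new, old in enumerate(keep)}
        nbrs = tuple(
            tuple(sorted(pos[j] for j in self.neighbors[i] if j in pos)) for i in keep
        )
        return Adjacency(nbrs)

    def structure_matrix(self) -> np.ndarray:
        """Dense ICAR structure matrix ``D - W`` (degree minus adjacency)."""
        n = self.n
        Q = np.zeros((n, n))
        for i, nbrs in enumerate(self.neighbors):
            Q[i, i] = len(nbrs)
            for j in nbrs:
                Q[i, j] = -1.0
        return Q

    def greedy_coloring(self) -> np.ndarray:
        """Proper vertex coloring (no two neighbors share a color).

        Used to block single-site MCMC updates: sites of one color have
        mutually independent full conditionals and can be updated
        simultaneously.
        """
        colors = np.full(self.n, -1, dtype=np.int64)
        for i in range(self.n):
            used = {colors[j] for j in self.neighbors[i] if colors[j] >= 0}
            c = 0
            while c in used:
                c += 1
            colors[i] = c
        return colors

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "Adjacency":
        nbrs: list[set[int]] = [set() for _ in range(n)]
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop edge ({i},{j})")
            nbrs[i].add(j)
            nbrs[j].add(i)
        return cls(tuple(tuple(sorted(s)) for s in nbrs))


def generate_adjacency(n_rows: int, n_cols: int, rule: str = "rook") -> Adjacency:
    """Grid-lattice adjacency: ``rook`` = 4-neighborhood, ``queen`` = 8.

    Tracts are indexed row-major: tract ``r * n_cols + c`` sits at row ``r``,
    column ``c``.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError(f"grid dimensions must be positive, got {n_rows}x{n_cols}")
    if rule not in ("rook", "queen"):
        raise ValueError(f"adjacency rule must be 'rook' or 'queen', got {rule!r}")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if rule == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    j = rr * n_cols + cc
                    if i < j:
                        edges.append((i, j))
    return Adjacency.from_edges(n_rows * n_cols, edges)
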