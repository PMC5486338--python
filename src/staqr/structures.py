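"""Prior precision structures and region adjacency.

Two improper Gaussian Markov random field priors drive the structured
additive terms: a second-order random-walk (RW2) penalty for smooth
functions of continuous covariates, and the intrinsic conditional
autoregressive (ICAR, Besag) precision for district effects built from a
neighbourhood graph. Both are supplied as precision-structure matrices
``K`` with known rank deficiency; identifiability is restored downstream
through sum-to-zero centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, irreflexive neighbourhood structure over labelled regions."""

    labels: tuple[str, ...]
    adjacency: dict[str, tuple[str, ...]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        lset = set(self.labels)
        for a, nbrs in self.adjacency.items():
            if a not in lset:
                raise ValueError(f"unknown region {a!r}")
            for b in nbrs:
                if b == a:
                    raise ValueError(f"self-neighbour at {a!r}")
                if b not in lset:
                    raise ValueError(f"unknown neighbour label {b!r} of {a!r}")
                if a not in self.adjacency.get(b, ()):
                    raise ValueError(f"asymmetric adjacency: {a!r}->{b!r}")

    @classmethod
    def from_edges(cls, labels, edges) -> "AdjacencyGraph":
        """Build from an iterable of (a, b) pairs; duplicates and reversed
        listings collapse to single undirected edges."""
        labels = tuple(labels)
        nbrs: dict[str, set[str]] = {lab: set() for lab in labels}
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-neighbour at {a!r}")
            nbrs[a].add(b)
            nbrs[b].add(a)
        adjacency = {lab: tuple(sorted(nbrs[lab])) for lab in labels}
        return cls(labels, adjacency)

    @property
    def n(self) -> int:
        return len(self.labels)

    def neighbors(self, label: str) -> tuple[str, ...]:
        return self.adjacency[label]

    def degree(self, label: str) -> int:
        return len(self.adjacency[label])

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for a in self.labels:
            for b in self.adjacency[a]:
                if a < b:
                    out.append((a, b))
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges())
        return g

    def components(self) -> list[set[str]]:
        """Connected components, ordered by their first label."""
        comps = list(nx.connected_components(self.to_networkx()))
        order = {lab: i for i, lab in enumerate(self.labels)}
        return sorted(comps, key=lambda c: min(order[x] for x in c))

    # -- file dialects ----------------------------------------------------

    def write_edgelist(self, path: str | Path) -> None:
        """Tab-separated ``regionA<TAB>regionB`` lines, one per edge."""
        lines = [f"{a}\t{b}" for a, b in self.edges()]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_gra(self, path: str | Path) -> None:
        """Label-based .gra dialect: N, then per region its label, its
        neighbour count and the neighbour labels on one line."""
        out = [str(self.n)]
        for lab in self.labels:
            nbrs = self.adjacency[lab]
            out.append(lab)
            out.append(str(len(nbrs)))
            out.append(" ".join(nbrs))
        Path(path).write_text("\n".join(out) + "\n")


def read_graph(path: str | Path, dialect: str = "edgelist") -> AdjacencyGraph:
    """Read an adjacency graph from disk.

    ``edgelist``: one ``A<TAB>B`` pair per line, ``#`` comments ignored,
    symmetrized (an edge listed in both directions is one edge).
    ``gra``: line 1 holds the region count N; then for each region three
    lines — label, neighbour count k, and k space-separated neighbour
    labels (an empty line when k = 0). Asymmetric listings are rejected.
    """
    text = Path(path).read_text()
    if dialect == "edgelist":
        labels: list[str] = []
        edges = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {raw!r}")
            for lab in parts:
                if lab not in labels:
                    labels.append(lab)
            edges.append((parts[0], parts[1]))
        return AdjacencyGraph.from_edges(labels, edges)
    if dialect == "gra":
        lines = text.splitlines()
        if not lines:
            raise ValueError("empty gra file")
        try:
            n = int(lines[0].strip())
        except ValueError as exc:
            raise ValueError(f"malformed region count: {lines[0]!r}") from exc
        body = lines[1:]
        if len(body) < 3 * n:
            raise ValueError("truncated gra file")
        labels = []
        listed: dict[str, tuple[str, ...]] = {}
        for i in range(n):
            lab = body[3 * i].strip()
            try:
                k = int(body[3 * i + 1].strip())
            except ValueError as exc:
                raise ValueError(
                    f"malformed neighbour count for {lab!r}"
                ) from exc
            nbrs = tuple(body[3 * i + 2].split())
            if len(nbrs) != k:
                raise ValueError(
                    f"region {lab!r} announces {k} neighbours, lists {len(nbrs)}"
                )
            labels.append(lab)
            listed[lab] = nbrs
        lset = set(labels)
        for a, nbrs in listed.items():
            for b in nbrs:
                if b not in lset:
                    raise ValueError(f"unknown neighbour label {b!r}")
                if a not in listed[b]:
                    raise ValueError(f"asymmetric gra adjacency: {a!r}->{b!r}")
        return AdjacencyGraph(tuple(labels), listed)
    raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class PenaltyBlock:
    """Precision structure of one improper GMRF prior.

    ``K`` is symmetric positive-semidefinite; the prior precision of the
    block coefficients is ``K / tau2``. ``constraints`` holds the linear
    constraints enforced during sampling (sum-to-zero, one row per
    connected component for ICAR); ``nullity`` is the full null-space
    dimension of ``K`` (2 for RW2 on an equispaced grid: constants and
    linear trends).
    """

    kind: str  # rw2 | icar | iid
    K: np.ndarray = field(repr=False)
    rank: int
    constraints: np.ndarray = field(repr=False)
    nullity: int

    @property
    def size(self) -> int:
        return self.K.shape[0]


def rw2_precision(grid_size: int) -> PenaltyBlock:
    """Second-order random-walk penalty on an equispaced grid.

    ``K = D2' D2`` with ``D2`` the (m-2) x m second-difference operator;
    the quadratic form ``f'Kf`` is the sum of squared second differences.
    """
    m = int(grid_size)
    if m < 3:
        raise ValueError("RW2 penalty needs a grid of at least 3 points")
    d2 = np.diff(np.eye(m), n=2, axis=0)
    K = d2.T @ d2
    constraints = np.ones((1, m)) / m
    return PenaltyBlock(kind="rw2", K=K, rank=m - 2, constraints=constraints,
                        nullity=2)


def icar_precision(graph: AdjacencyGraph) -> PenaltyBlock:
    """Intrinsic CAR (Besag) precision ``K = diag(degree) - adjacency``.

    Rank is n minus the number of connected components; one sum-to-zero
    constraint per component restores propriety.
    """
    if graph.n < 2:
        raise ValueError("ICAR prior needs at least 2 regions")
    idx = {lab: i for i, lab in enumerate(graph.labels)}
    K = np.zeros((graph.n, graph.n))
    for a in graph.labels:
        i = idx[a]
        K[i, i] = graph.degree(a)
        for b in graph.adjacency[a]:
            K[i, idx[b]] = -1.0
    comps = graph.components()
    constraints = np.zeros((len(comps), graph.n))
    for c, comp in enumerate(comps):
        for lab in comp:
            constraints[c, idx[lab]] = 1.0 / len(comp)
    return PenaltyBlock(kind="icar", K=K, rank=graph.n - len(comps),
                        constraints=constraints, nullity=len(comps))


def iid_precision(size: int) -> PenaltyBlock:
    """Exchangeable (unstructured) block: identity precision structure."""
    if size < 1:
        raise ValueError("iid block needs at least 1 unit")
    return PenaltyBlock(kind="iid", K=np.eye(size), rank=size,
                        constraints=np.zeros((0, size)), nullity=0)


def write_precision_txt(block: PenaltyBlock, path: str | Path) -> None:
    """Export K as coordinate-format text: ``row col value`` per nonzero."""
    rows, cols = np.nonzero(block.K)
    lines = [f"{r} {c} {block.K[r, c]:.17g}" for r, c in zip(rows, cols)]
    Path(path).write_text("\n".join(lines) + "\n")
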