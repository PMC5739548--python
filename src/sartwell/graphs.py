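"""Network families for invasion dynamics.

All networks are simple, undirected and connected.  They are stored in
compressed sparse (CSR-like) form — ``indptr``/``indices`` arrays — which
is what the simulation engine consumes; a per-node adjacency-list view is
also exposed.  Construction goes through :mod:`networkx` generators and is
deterministic given ``(family, params, seed)``.

Families
--------
``complete``
    All-to-all mixing (e.g. a well-stirred microbiome); param ``n``.
``star``
    One hub connected to ``spokes`` leaves; ``spokes + 1`` total nodes.
``ring_1d``, ``lattice_2d``, ``lattice_3d``
    Periodic (toroidal) lattices in 1-3 dimensions; params ``n`` for the
    ring, ``shape`` (side lengths) for 2D/3D.  Every node has degree 2d.
``erdos_renyi``
    G(n, rho); params ``n``, ``rho``; resampled until connected.
``small_world``
    Newman-Watts-Strogatz ring with shortcuts; params ``n``, ``rho``
    (shortcut probability) and ``k`` (base ring degree, default 2).
``k_regular``
    Random k-regular graph; params ``n``, ``k``; resampled until connected.
``scale_free``
    Barabasi-Albert preferential attachment; params ``n``, ``m``
    (attachment / minimum degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import networkx as nx
import numpy as np

__all__ = ["Network", "make_network", "FAMILIES"]

FAMILIES = (
    "complete",
    "star",
    "ring_1d",
    "lattice_2d",
    "lattice_3d",
    "erdos_renyi",
    "small_world",
    "k_regular",
    "scale_free",
)

#: families whose generator involves randomness
_RANDOM_FAMILIES = frozenset({"erdos_renyi", "small_world", "k_regular", "scale_free"})

_MAX_RETRIES = 100


@dataclass(frozen=True)
class Network:
    """An undirected, connected, simple graph in CSR form.

    Attributes
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : mapping
        The family-specific construction parameters, as passed in.
    indptr, indices : ndarray of int
        CSR adjacency: the neighbours of node ``i`` are
        ``indices[indptr[i]:indptr[i+1]]``.
    """

    family: str
    params: Mapping[str, object]
    indptr: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)

    @property
    def node_count(self) -> int:
        return len(self.indptr) - 1

    @property
    def edge_count(self) -> int:
        return len(self.indices) // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbour indices of node ``i`` (a read-only view)."""
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def adjacency(self) -> list[np.ndarray]:
        """Per-node neighbour arrays (views into ``indices``)."""
        return [self.neighbors(i) for i in range(self.node_count)]

    def iter_edges(self) -> Iterator[tuple[int, int]]:
        for i in range(self.node_count):
            for j in self.neighbors(i):
                if i < j:
                    yield (i, int(j))

    def to_edgelist(self, path) -> None:
        """Write a plain two-column whitespace edge list (0-based)."""
        with open(path, "w") as fh:
            for i, j in self.iter_edges():
                fh.write(f"{i} {j}\n")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_edges_from(self.iter_edges())
        return g


def _from_networkx(g: nx.Graph, family: str, params: Mapping) -> Network:
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    n = g.number_of_nodes()
    e = np.asarray(g.edges(), dtype=np.int64).reshape(-1, 2)
    src = np.concatenate([e[:, 0], e[:, 1]])
    dst = np.concatenate([e[:, 1], e[:, 0]])
    order = np.argsort(src, kind="stable")
    indices = dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=n), out=indptr[1:])
    return Network(family=family, params=dict(params), indptr=indptr, indices=indices)


def _build(family: str, params: Mapping, seed: int) -> nx.Graph:
    if family == "complete":
        return nx.complete_graph(int(params["n"]))
    if family == "star":
        return nx.star_graph(int(params["spokes"]))
    if family == "ring_1d":
        return nx.cycle_graph(int(params["n"]))
    if family in ("lattice_2d", "lattice_3d"):
        shape = [int(s) for s in params["shape"]]
        want = 2 if family == "lattice_2d" else 3
        if len(shape) != want:
            raise ValueError(f"{family} needs {want} side lengths, got {shape}")
        # periodic in every dimension so each node has degree 2d
        return nx.grid_graph(dim=shape, periodic=True)
    if family == "erdos_renyi":
        rho = float(params["rho"])
        if not 0.0 < rho <= 1.0:
            raise ValueError("edge probability rho must be in (0, 1]")
        return nx.gnp_random_graph(int(params["n"]), rho, seed=seed)
    if family == "small_world":
        rho = float(params["rho"])
        if not 0.0 < rho <= 1.0:
            raise ValueError("shortcut probability rho must be in (0, 1]")
        k = int(params.get("k", 2))
        return nx.newman_watts_strogatz_graph(int(params["n"]), k, rho, seed=seed)
    if family == "k_regular":
        n, k = int(params["n"]), int(params["k"])
        if (n * k) % 2 != 0:
            raise ValueError(f"no {k}-regular graph on {n} nodes (odd degree sum)")
        return nx.random_regular_graph(k, n, seed=seed)
    if family == "scale_free":
        return nx.barabasi_albert_graph(int(params["n"]), int(params["m"]), seed=seed)
    raise ValueError(f"unknown network family {family!r}; known: {FAMILIES}")


def make_network(family: str, params: Mapping | None = None, seed: int = 0, **kwargs) -> Network:
    """Construct a connected network of the given family.

    Parameters may be supplied as a mapping or as keyword arguments, e.g.
    ``make_network("erdos_renyi", n=115, rho=0.5, seed=3)``.  Random
    families that come out disconnected are resampled with an incremented
    seed (fixation is ill-defined across components), up to 100 retries.
    Deterministic given ``(family, params, seed)``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown network family {family!r}; known: {FAMILIES}")
    p = dict(params or {})
    p.update(kwargs)
    _validate_size(family, p)
    for attempt in range(_MAX_RETRIES):
        g = _build(family, p, seed=int(seed) + attempt)
        if nx.is_connected(g):
            return _from_networkx(g, family, p)
        if family not in _RANDOM_FAMILIES:
            raise ValueError(f"{family} with params {p} is disconnected")
    raise RuntimeError(
        f"no connected {family} graph found in {_MAX_RETRIES} attempts (params {p})"
    )


def _validate_size(family: str, p: Mapping) -> None:
    if family == "star":
        if int(p["spokes"]) < 1:
            raise ValueError("star needs at least one spoke")
        return
    if family in ("lattice_2d", "lattice_3d"):
        if int(np.prod([int(s) for s in p["shape"]])) < 2:
            raise ValueError("lattice needs at least 2 nodes")
        return
    if int(p["n"]) < 2:
        raise ValueError("network needs at least 2 nodes")
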