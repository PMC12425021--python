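"""Interactome substrate: graph I/O, shortest-path services, degree
log-binning and degree-matched random sampling.

Every null model in the pipeline (module-size significance, proximity
significance) draws its random gene sets through :func:`sample_degree_matched`,
which preserves the binned degree profile of the reference set exactly.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "gene", "gene1", "gene2", "source", "target", "symbol", "symbol1",
    "symbol2", "node", "node1", "node2", "protein", "protein1", "protein2",
    "gene_a", "gene_b", "from", "to", "interactor_a", "interactor_b",
}


class Interactome:
    """Undirected simple graph over gene symbols.

    Wraps a :class:`networkx.Graph`; self-loops and duplicate edges are
    removed at construction and accounted for in :attr:`load_report`.
    """

    def __init__(self, graph: nx.Graph, load_report: dict | None = None):
        if graph.number_of_nodes() == 0:
            raise ValueError("empty interactome")
        self.graph = graph
        self.load_report = load_report or {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "self_loops_dropped": 0,
            "duplicates_collapsed": 0,
        }
        self._dist_cache: DistanceMatrix | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Interactome":
        """Build from an iterable of symbol pairs, dropping self-loops and
        collapsing duplicate/reversed edges."""
        g = nx.Graph()
        self_loops = 0
        duplicates = 0
        for a, b in edges:
            a, b = str(a).strip(), str(b).strip()
            if not a or not b:
                raise ValueError(f"empty gene symbol in edge ({a!r}, {b!r})")
            if a == b:
                self_loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                duplicates += 1
                continue
            g.add_edge(a, b)
        report = {
            "nodes": g.number_of_nodes(),
            "edges": g.number_of_edges(),
            "self_loops_dropped": self_loops,
            "duplicates_collapsed": duplicates,
        }
        return cls(g, report)

    # -- basic accessors ---------------------------------------------------

    @property
    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def restrict_to_lcc(self) -> "Interactome":
        """Return the interactome restricted to its largest connected
        component (ties broken by lexicographically smallest node set)."""
        comps = sorted(nx.connected_components(self.graph),
                       key=lambda c: (-len(c), sorted(c)))
        sub = self.graph.subgraph(comps[0]).copy()
        rep = dict(self.load_report)
        rep.update(nodes=sub.number_of_nodes(), edges=sub.number_of_edges(),
                   restricted_to_lcc=True)
        return Interactome(sub, rep)

    # -- distances ---------------------------------------------------------

    def distance_matrix(self) -> "DistanceMatrix":
        """All-pairs unweighted shortest-path matrix (cached).

        Practical up to a few thousand nodes; the screening and calibration
        loops use it to turn each proximity evaluation into an array slice.
        """
        if self._dist_cache is None:
            nodes = list(self.graph.nodes)
            adj = nx.to_scipy_sparse_array(self.graph, nodelist=nodes,
                                           format="csr", dtype=np.int8)
            dist = shortest_path(csr_matrix(adj), method="D", unweighted=True)
            self._dist_cache = DistanceMatrix(
                index={n: i for i, n in enumerate(nodes)}, dist=dist)
        return self._dist_cache


@dataclass
class DistanceMatrix:
    """Node index plus dense all-pairs distance matrix (inf = unreachable)."""

    index: dict[str, int]
    dist: np.ndarray

    def set_to_set(self, sources: Sequence[str], targets: Sequence[str]) -> np.ndarray:
        """Submatrix of distances, rows = sources, cols = targets."""
        rows = [self.index[s] for s in sources]
        cols = [self.index[t] for t in targets]
        return self.dist[np.ix_(rows, cols)]


# -- I/O -------------------------------------------------------------------


def load_interactome(path: str | Path, fmt: str = "tsv") -> Interactome:
    """Read an edge list (``tsv``: two symbol columns; ``sif``:
    ``A relation B [C ...]``). '#'-comment and blank lines are skipped;
    a leading header row with recognisable column names is skipped too.
    """
    path = Path(path)
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown interactome format {fmt!r}")
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = [c.strip() for c in line.replace("\t", " ").split()]
            if first_data:
                first_data = False
                if any(c.lower() in _HEADER_TOKENS for c in cols):
                    continue
            if fmt == "sif":
                if len(cols) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF row needs 'source relation "
                        f"target...', got {line!r}")
                edges.extend((cols[0], t) for t in cols[2:])
            else:
                if len(cols) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: edge row needs two symbol "
                        f"columns, got {line!r}")
                edges.append((cols[0], cols[1]))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    net = Interactome.from_edges(edges)
    logger.info("loaded %s: %d nodes, %d edges (%d self-loops dropped, "
                "%d duplicates collapsed)", path, net.n_nodes, net.n_edges,
                net.load_report["self_loops_dropped"],
                net.load_report["duplicates_collapsed"])
    return net


def write_edgelist(net: Interactome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


# -- degree binning --------------------------------------------------------


@dataclass
class DegreeBinning:
    """Partition of the node set into ascending degree intervals.

    Bins start at log2-spaced degree boundaries and are merged upward until
    each holds at least ``min_occupancy`` nodes, so that degree-matched
    sampling has a meaningful candidate pool even in the heavy tail.
    """

    bins: list[tuple[tuple[int, int], list[str]]]
    min_occupancy: int
    node_to_bin: dict[str, int] = field(repr=False)

    def __post_init__(self):
        seen: set[str] = set()
        for _, members in self.bins:
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"bins overlap on {sorted(overlap)[:5]}")
            seen.update(members)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_counts(self, genes: Iterable[str]) -> np.ndarray:
        """How many of `genes` fall in each bin (the binned degree profile)."""
        counts = np.zeros(len(self.bins), dtype=int)
        for g in genes:
            counts[self.node_to_bin[g]] += 1
        return counts


def build_degree_bins(net: Interactome, min_occupancy: int = 100) -> DegreeBinning:
    """Log-spaced degree bins merged upward to ``min_occupancy`` nodes each.

    The last (highest-degree) bin absorbs any short remainder, so every bin
    satisfies the occupancy floor whenever the graph itself does.
    """
    if min_occupancy < 1:
        raise ValueError("min_occupancy must be >= 1")
    degrees = dict(net.graph.degree)
    if min_occupancy > net.n_nodes:
        warnings.warn(
            f"min_occupancy={min_occupancy} exceeds node count "
            f"{net.n_nodes}; using a single bin", stacklevel=2)
    max_deg = max(degrees.values())
    # log2-spaced boundaries: [0,1), [1,2), [2,4), [4,8), ...
    edges = [0, 1]
    while edges[-1] <= max_deg:
        edges.append(edges[-1] * 2)
    raw: list[tuple[tuple[int, int], list[str]]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [n for n, d in degrees.items() if lo <= d < hi]
        if members:
            raw.append(((lo, hi), members))
    # merge upward until each bin reaches min_occupancy
    merged: list[tuple[tuple[int, int], list[str]]] = []
    cur_lo, cur_members = None, []
    for (lo, hi), members in raw:
        if cur_lo is None:
            cur_lo = lo
        cur_members.extend(members)
        cur_hi = hi
        if len(cur_members) >= min_occupancy:
            merged.append(((cur_lo, cur_hi), cur_members))
            cur_lo, cur_members = None, []
    if cur_members:
        if merged:  # short tail absorbed into the last full bin
            (plo, _), prev = merged.pop()
            merged.append(((plo, cur_hi), prev + cur_members))
        else:
            merged.append(((cur_lo, cur_hi), cur_members))
    node_to_bin = {n: i for i, (_, members) in enumerate(merged)
                   for n in members}
    return DegreeBinning(bins=merged, min_occupancy=min_occupancy,
                         node_to_bin=node_to_bin)


# -- degree-matched sampling ----------------------------------------------


@dataclass
class RandomSetSample:
    genes: set[str]
    seed: int | None
    source_set_size: int


class DegreeMatchedSampler:
    """Repeated degree-matched sampling for one reference set.

    Precomputes, per degree bin, the candidate pool (bin members minus the
    reference genes) and the number of reference genes to replace, so that a
    single sample is a handful of `rng.choice` calls. If a bin holds fewer
    non-reference candidates than reference genes, the reference genes
    themselves become eligible in that bin (logged once).
    """

    def __init__(self, bins: DegreeBinning, reference: Iterable[str]):
        reference = set(reference)
        unknown = [g for g in reference if g not in bins.node_to_bin]
        if unknown:
            raise ValueError(
                f"reference genes absent from the binning: {sorted(unknown)[:5]}")
        self.reference = reference
        self.size = len(reference)
        self._plan: list[tuple[np.ndarray, int]] = []
        for idx, (_, members) in enumerate(bins.bins):
            k = sum(1 for g in reference if bins.node_to_bin[g] == idx)
            if k == 0:
                continue
            candidates = [m for m in members if m not in reference]
            if len(candidates) < k:
                logger.info(
                    "degree bin %d exhausted (%d candidates for %d reference "
                    "genes); reference genes made eligible", idx,
                    len(candidates), k)
                candidates = list(members)
            self._plan.append((np.array(sorted(candidates), dtype=object), k))

    def sample(self, rng: np.random.Generator) -> list[str]:
        out: list[str] = []
        for candidates, k in self._plan:
            out.extend(rng.choice(candidates, size=k, replace=False))
        return out


def sample_degree_matched(
    net: Interactome,
    bins: DegreeBinning,
    reference: Iterable[str],
    rng_seed: int | np.random.Generator,
) -> RandomSetSample:
    """One random gene set with the same binned degree profile as `reference`."""
    reference = set(reference)
    missing = reference - net.node_set
    if missing:
        raise ValueError(f"reference genes not in network: {sorted(missing)[:5]}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    seed = rng_seed if isinstance(rng_seed, int) else None
    sampler = DegreeMatchedSampler(bins, reference)
    return RandomSetSample(genes=set(sampler.sample(rng)), seed=seed,
                           source_set_size=len(reference))


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds (< 2**31) from one master seed, so
    any replicate can be reproduced in isolation."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([s.generate_state(1)[0] % (2**31) for s in ss.spawn(n)])


# -- shortest paths --------------------------------------------------------


def min_dist_to_set(net: Interactome, source: str,
                    targets: Iterable[str]) -> float:
    """Unweighted BFS distance from `source` to the nearest member of
    `targets`; 0 if source is a target, inf if unreachable."""
    targets = set(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    usable = targets & net.node_set
    if not usable:
        raise ValueError("no target gene is present in the network")
    if source not in net.graph:
        raise ValueError(f"source {source!r} not in network")
    if source in usable:
        return 0
    g = net.graph
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        node, d = frontier.popleft()
        for nb in g[node]:
            if nb in seen:
                continue
            if nb in usable:
                return d + 1
            seen.add(nb)
            frontier.append((nb, d + 1))
    return float("inf")


def distances_from_set(net: Interactome, sources: Iterable[str]) -> dict[str, int]:
    """Multi-source BFS: distance from every reachable node to the nearest
    member of `sources`."""
    sources = set(sources) & net.node_set
    if not sources:
        raise ValueError("no source gene is present in the network")
    g = net.graph
    dist = {s: 0 for s in sources}
    frontier = deque(sources)
    while frontier:
        node = frontier.popleft()
        d = dist[node]
        for nb in g[node]:
            if nb not in dist:
                dist[nb] = d + 1
                frontier.append(nb)
    return dist
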