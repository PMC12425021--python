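"""Hallmark-of-aging gene sets and their network modules.

Confidence-stratified (cumulative) gene sets per hallmark, largest-connected-
component (LCC) module detection with degree-matched significance, pairwise
separation and Jaccard overlap, and the union "longevity module".
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .netcore import (
    DegreeBinning,
    DegreeMatchedSampler,
    Interactome,
    build_degree_bins,
    min_dist_to_set,
    spawn_seeds,
)

logger = logging.getLogger(__name__)

#: The 11 canonical hallmarks of aging used as gene-set labels.
HALLMARKS = (
    "Genomic instability",
    "Telomere attrition",
    "Epigenetic alterations",
    "Loss of proteostasis",
    "Disabled macroautophagy",
    "Deregulated nutrient sensing",
    "Mitochondrial dysfunction",
    "Cell senescence",
    "Exhaustion of stem cells",
    "Altered intercellular communication",
    "Changes in the extracellular matrix structure",
)

CONFIDENCE_LEVELS = (1, 2, 3, 4, 5)


# -- annotations -----------------------------------------------------------


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read a gene/hallmark/confidence TSV into a validated DataFrame.

    Columns: ``gene``, ``hallmark``, ``confidence`` (1 = highest evidence,
    5 = lowest). A (gene, hallmark) pair may appear only once.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene": str, "hallmark": str})
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "hallmark", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    df = df.copy()
    df["gene"] = df["gene"].str.strip()
    df["hallmark"] = df["hallmark"].str.strip()
    df["confidence"] = df["confidence"].astype(int)
    bad = df.loc[~df["confidence"].isin(CONFIDENCE_LEVELS), "confidence"]
    if len(bad):
        raise ValueError(f"confidence must be in 1-5, got {sorted(bad.unique())}")
    unknown = set(df["hallmark"]) - set(HALLMARKS)
    if unknown:
        raise ValueError(
            f"unknown hallmark name(s) {sorted(unknown)}; valid names are: "
            + "; ".join(HALLMARKS))
    dup = df.duplicated(subset=["gene", "hallmark"])
    if dup.any():
        pairs = df.loc[dup, ["gene", "hallmark"]].head(5).to_records(index=False)
        raise ValueError(f"duplicate (gene, hallmark) annotations: {list(pairs)}")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one gene set per line — name, description, genes...."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            cols = [c.strip() for c in line.rstrip("\n").split("\t")]
            if len(cols) < 3 or not cols[0]:
                continue
            sets[cols[0]] = [g for g in cols[2:] if g]
    return sets


def annotations_from_gmt(paths_by_level: dict[int, str | Path]) -> pd.DataFrame:
    """Assemble an annotation table from one GMT file per confidence level
    (set name = hallmark). A gene listed at several levels keeps the
    strongest (lowest) one."""
    rows = []
    for level in sorted(paths_by_level):
        for hallmark, genes in read_gmt(paths_by_level[level]).items():
            rows.extend({"gene": g, "hallmark": hallmark, "confidence": level}
                        for g in genes)
    df = pd.DataFrame(rows)
    df = (df.sort_values("confidence")
            .drop_duplicates(subset=["gene", "hallmark"], keep="first")
            .reset_index(drop=True))
    return validate_annotations(df)


@dataclass(frozen=True)
class HallmarkGeneSet:
    """Cumulative gene set of one hallmark at one confidence level:
    all genes annotated at confidence <= level, intersected with the
    network. ``absent`` records annotated genes not in the network."""

    hallmark: str
    level: int
    genes: frozenset[str]
    absent: frozenset[str] = frozenset()


def build_hallmark_sets(
    annotations: pd.DataFrame,
    net: Interactome,
    level: int,
) -> dict[str, HallmarkGeneSet]:
    """Per-hallmark cumulative gene sets at one confidence level.

    Level L contains every gene annotated to the hallmark at confidence
    <= L, so the five sets are nested from most stringent (1) to most
    inclusive (5). Genes absent from the network are reported, not
    silently dropped."""
    if level not in CONFIDENCE_LEVELS:
        raise ValueError(f"level must be in 1-5, got {level}")
    annotations = validate_annotations(annotations)
    out: dict[str, HallmarkGeneSet] = {}
    nodes = net.node_set
    for hallmark in HALLMARKS:
        sub = annotations[(annotations["hallmark"] == hallmark)
                          & (annotations["confidence"] <= level)]
        genes = set(sub["gene"])
        absent = genes - nodes
        if absent:
            logger.warning("%s level %d: %d annotated gene(s) absent from "
                           "the network: %s", hallmark, level, len(absent),
                           sorted(absent)[:10])
        kept = genes & nodes
        if not kept and (annotations["hallmark"] == hallmark).any():
            warnings.warn(
                f"{hallmark!r} has no genes at confidence level {level}",
                stacklevel=2)
        out[hallmark] = HallmarkGeneSet(hallmark=hallmark, level=level,
                                        genes=frozenset(kept),
                                        absent=frozenset(absent))
    return out


# -- LCC module detection --------------------------------------------------


def _induced_components(net: Interactome, genes: set[str]):
    """Connected components of the subgraph induced by `genes` (BFS
    restricted to the set; avoids building a networkx subgraph per null
    replicate)."""
    g = net.graph
    unvisited = set(genes)
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        frontier = deque([start])
        while frontier:
            node = frontier.popleft()
            for nb in g[node]:
                if nb in unvisited:
                    unvisited.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        yield comp


def largest_connected_component(net: Interactome, genes) -> set[str]:
    """Node set of the largest connected component of the induced subgraph.

    Ties are broken by the lexicographically smallest sorted member tuple,
    so the result is deterministic."""
    genes = set(genes) & net.node_set
    if not genes:
        return set()
    best: tuple[int, list[str]] | None = None
    for comp in _induced_components(net, genes):
        key = (-len(comp), sorted(comp))
        if best is None or key < best:
            best = key
    return set(best[1])


def _lcc_size(net: Interactome, genes) -> int:
    return max((len(c) for c in _induced_components(net, set(genes))),
               default=0)


@dataclass
class LCCResult:
    """Observed module size vs. the degree-matched null."""

    observed_size: int
    members: set[str]
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_random: int

    @property
    def significance(self) -> str:
        if np.isnan(self.z):
            return "undefined"
        if self.z > 1.96:
            return "significant"
        if self.z > 1.645:
            return "marginal"
        return "ns"


def lcc_significance(
    net: Interactome,
    genes,
    n_random: int = 1000,
    rng_seed: int = 0,
    bins: DegreeBinning | None = None,
) -> LCCResult:
    """Significance of a gene set's largest connected component against
    degree-matched random gene sets of the same size.

    The null resamples the set through the interactome's degree bins
    ``n_random`` times; z is the standardised observed LCC size and the
    empirical p is the (r+1)/(n+1)-smoothed fraction of null LCCs at least
    as large.
    """
    genes = set(genes) & net.node_set
    if len(genes) < 2:
        raise ValueError("need at least 2 network genes for LCC significance")
    if bins is None:
        bins = build_degree_bins(net, min_occupancy=min(100, net.n_nodes))
    members = largest_connected_component(net, genes)
    observed = len(members)
    sampler = DegreeMatchedSampler(bins, genes)
    rng = np.random.default_rng(spawn_seeds(rng_seed, 1)[0])
    null = np.empty(n_random)
    for i in range(n_random):
        null[i] = _lcc_size(net, sampler.sample(rng))
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    # integer LCC sizes make an exactly-constant null common; guard roundoff
    z = float("nan") if sd <= 1e-12 * max(1.0, mean) else (observed - mean) / sd
    p = (int((null >= observed).sum()) + 1) / (n_random + 1)
    return LCCResult(observed_size=observed, members=members, null_mean=mean,
                     null_sd=sd, z=z, empirical_p=p, n_random=n_random)


# -- separation & overlap --------------------------------------------------


@dataclass
class SeparationResult:
    """Topological separation S_AB = d_AB - (d_AA + d_BB)/2.

    Distances are nearest-neighbour shortest paths with the node itself
    excluded from its own target set; negative S_AB means overlapping
    network neighbourhoods. ``n_unreachable`` counts node→set distances
    that were infinite and hence excluded from the means."""

    s_ab: float
    d_ab: float
    d_aa: float
    d_bb: float
    n_unreachable: int = 0


def _mean_nn_dist(net: Interactome, sources, targets) -> tuple[float, int]:
    """Mean over sources of min distance to targets \\ {self}; returns the
    mean (0.0 when no node has any eligible target, inf when all eligible
    distances are unreachable) and the unreachable count."""
    vals, unreachable, had_candidates = [], 0, False
    for s in sources:
        cand = set(targets) - {s}
        if not cand:
            continue
        had_candidates = True
        d = min_dist_to_set(net, s, cand)
        if np.isinf(d):
            unreachable += 1
        else:
            vals.append(d)
    if vals:
        return float(np.mean(vals)), unreachable
    return (float("inf") if had_candidates else 0.0), unreachable


def separation(net: Interactome, set_a, set_b) -> SeparationResult:
    """Network-based separation between two gene sets (symmetric)."""
    a = set(set_a) & net.node_set
    b = set(set_b) & net.node_set
    if not a or not b:
        raise ValueError("both gene sets must be non-empty after "
                         "intersection with the network")
    d_aa, u1 = _mean_nn_dist(net, a, a)
    d_bb, u2 = _mean_nn_dist(net, b, b)
    # cross term: every node of A∪B to the *other* set (self excluded)
    cross_vals, u3, had = [], 0, False
    for s in a | b:
        parts = []
        if s in a:
            parts.append(b - {s})
        if s in b:
            parts.append(a - {s})
        for cand in parts:
            if not cand:
                continue
            had = True
            d = min_dist_to_set(net, s, cand)
            if np.isinf(d):
                u3 += 1
            else:
                cross_vals.append(d)
    if cross_vals:
        d_ab = float(np.mean(cross_vals))
    else:
        d_ab = float("inf") if had else 0.0
    n_unreachable = u1 + u2 + u3
    if n_unreachable:
        logger.info("separation: %d unreachable node-set distances excluded",
                    n_unreachable)
    finite_within = (0.0 if np.isinf(d_aa) else d_aa,
                     0.0 if np.isinf(d_bb) else d_bb)
    s_ab = (float("inf") if np.isinf(d_ab)
            else d_ab - (finite_within[0] + finite_within[1]) / 2)
    return SeparationResult(s_ab=s_ab, d_ab=d_ab, d_aa=d_aa, d_bb=d_bb,
                            n_unreachable=n_unreachable)


@dataclass
class OverlapResult:
    jaccard: float
    p_value: float
    n_common: int


def jaccard_overlap(set_a, set_b, universe, n_random: int = 1000,
                    rng_seed: int = 0) -> OverlapResult:
    """Jaccard index |A∩B|/|A∪B| with a resampling p-value.

    The null redraws both sets uniformly (same sizes) from `universe`;
    degree plays no role in set overlap. p = smoothed fraction of null
    Jaccard values >= observed."""
    a, b, universe = set(set_a), set(set_b), sorted(set(universe))
    if not a <= set(universe) or not b <= set(universe):
        raise ValueError("both sets must be subsets of the universe")
    union = a | b
    jac = len(a & b) / len(union) if union else 0.0
    rng = np.random.default_rng(rng_seed)
    uni = np.array(universe, dtype=object)
    r = 0
    for _ in range(n_random):
        ra = set(rng.choice(uni, size=len(a), replace=False))
        rb = set(rng.choice(uni, size=len(b), replace=False))
        ru = ra | rb
        rj = len(ra & rb) / len(ru) if ru else 0.0
        if rj >= jac:
            r += 1
    return OverlapResult(jaccard=jac, p_value=(r + 1) / (n_random + 1),
                         n_common=len(a & b))


# -- longevity module ------------------------------------------------------


def longevity_module(net: Interactome, hallmark_sets) -> tuple[set[str], Counter]:
    """LCC of the union of all hallmark gene sets, with per-gene hallmark
    membership counts (how many hallmarks each module gene belongs to)."""
    sets = {name: (hs.genes if isinstance(hs, HallmarkGeneSet) else set(hs))
            for name, hs in hallmark_sets.items()}
    if not sets:
        raise ValueError("need at least one hallmark set")
    union = set().union(*sets.values())
    module = largest_connected_component(net, union)
    counts = Counter()
    for genes in sets.values():
        for g in genes & module:
            counts[g] += 1
    return module, counts
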