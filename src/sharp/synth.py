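"""Synthetic inputs with planted, known structure.

Generates every input class the pipeline consumes — an interactome with
planted hallmark modules, confidence-stratified annotations, drugs with
targets at a controlled hop distance from a named module, and
aging/perturbation signature pairs at a controlled sign-concordance — so
each stage is testable against ground truth without external downloads.

The background graph is a configuration model with a power-law degree
sequence (exponent 2.5 by default) so that degree log-binning and the
degree-matched nulls are exercised on a realistic heavy tail.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .hallmarks import HALLMARKS
from .netcore import Interactome, distances_from_set, spawn_seeds, write_edgelist
from .page import Signature, write_gct
from .proximity import DrugTargets


@dataclass
class PlantedModule:
    hallmark: str
    size: int = 20
    density: float = 0.6
    # confidence level -> sampling weight for annotating the module's genes
    confidence_mix: dict[int, float] = field(
        default_factory=lambda: {1: 1, 2: 1, 3: 1, 4: 1, 5: 1})
    genes: list[str] | None = None  # explicit placement overrides sampling


@dataclass
class PlantedDrug:
    drug_id: str
    n_targets: int = 8
    hop: int | str = 0  # 0 | 1 | 2 | "random"
    module: str | None = None  # hallmark name; None only for "random"
    rho: float = 0.0  # sign-concordance of its signature over the module
    has_signature: bool = True
    name: str | None = None


@dataclass
class SignatureSpec:
    n_genes_measured: int | None = None  # None = every network gene
    noise_sd: float = 1.0


@dataclass
class SynthSpec:
    n_nodes: int = 2000
    degree_model: str = "configuration"  # or "erdos-renyi"
    powerlaw_exponent: float = 2.5
    max_degree: int | None = None  # default sqrt(n_nodes)
    er_p: float = 0.004
    modules: list[PlantedModule] = field(default_factory=list)
    drugs: list[PlantedDrug] = field(default_factory=list)
    signatures: SignatureSpec = field(default_factory=SignatureSpec)
    seed: int = 0

    def __post_init__(self):
        for m in self.modules:
            if not (0 < m.density <= 1):
                raise ValueError(
                    f"module {m.hallmark}: density {m.density} infeasible")
            if m.size > self.n_nodes:
                raise ValueError(f"module {m.hallmark}: size exceeds n_nodes")
            if m.hallmark not in HALLMARKS:
                raise ValueError(f"unknown hallmark {m.hallmark!r}")
        for d in self.drugs:
            if d.hop not in (0, 1, 2, "random"):
                raise ValueError(f"drug {d.drug_id}: hop must be 0/1/2/'random'")
            if not (-1 <= d.rho <= 1):
                raise ValueError(f"drug {d.drug_id}: rho outside [-1, 1]")


def truncated_zipf_mean(exponent: float, kmax: int) -> float:
    """Mean of the power-law degree distribution P(k) ~ k^-exponent on
    1..kmax (the generator's target mean degree)."""
    k = np.arange(1, kmax + 1, dtype=float)
    p = k ** -exponent
    p /= p.sum()
    return float((k * p).sum())


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def synth_interactome(spec: SynthSpec) -> tuple[Interactome, dict]:
    """Background graph plus planted modules wired at their internal
    density; returns the interactome and a ground-truth dict (module
    membership and the annotation table)."""
    seeds = spawn_seeds(spec.seed, 4)
    rng = np.random.default_rng(seeds[0])
    names = _gene_names(spec.n_nodes)

    if spec.degree_model == "configuration":
        kmax = spec.max_degree or max(2, int(np.sqrt(spec.n_nodes)))
        k = np.arange(1, kmax + 1, dtype=float)
        p = k ** -spec.powerlaw_exponent
        p /= p.sum()
        degs = rng.choice(np.arange(1, kmax + 1), size=spec.n_nodes, p=p)
        if degs.sum() % 2:
            degs[rng.integers(spec.n_nodes)] += 1
        multi = nx.configuration_model(degs.tolist(),
                                       seed=int(seeds[1]))
        g = nx.Graph(multi)
        g.remove_edges_from(nx.selfloop_edges(g))
        g = nx.relabel_nodes(g, dict(enumerate(names)))
        degree_sequence = degs.tolist()
    elif spec.degree_model == "erdos-renyi":
        g = nx.gnp_random_graph(spec.n_nodes, spec.er_p, seed=int(seeds[1]))
        g = nx.relabel_nodes(g, dict(enumerate(names)))
        degree_sequence = [d for _, d in g.degree]
    else:
        raise ValueError(f"unknown degree model {spec.degree_model!r}")
    g.add_nodes_from(names)

    # plant modules: disjoint random placement unless genes are given
    taken: set[str] = set()
    truth_modules: dict[str, list[str]] = {}
    ann_rows = []
    rng_m = np.random.default_rng(seeds[2])
    for mod in spec.modules:
        if mod.genes is not None:
            members = list(mod.genes)
        else:
            pool = [n for n in names if n not in taken]
            members = list(rng_m.choice(np.array(pool, dtype=object),
                                        size=mod.size, replace=False))
        taken.update(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng_m.random() < mod.density:
                    g.add_edge(members[i], members[j])
        truth_modules[mod.hallmark] = sorted(members)
        levels = sorted(mod.confidence_mix)
        weights = np.array([mod.confidence_mix[l] for l in levels], float)
        weights /= weights.sum()
        for gene in members:
            ann_rows.append({
                "gene": gene, "hallmark": mod.hallmark,
                "confidence": int(rng_m.choice(levels, p=weights))})

    net = Interactome.from_edges(g.edges)
    truth = {
        "modules": truth_modules,
        "annotations": pd.DataFrame(
            ann_rows, columns=["gene", "hallmark", "confidence"]),
        "degree_sequence_mean": float(np.mean(degree_sequence)),
    }
    return net, truth


def synth_drug(
    net: Interactome,
    module_genes,
    n_targets: int,
    hop_distance: int | str,
    rng: np.random.Generator | int,
    drug_id: str = "DRUG",
    name: str | None = None,
) -> DrugTargets:
    """Targets sampled from an exact-distance shell around the module:
    hop 0 inside it, hop 1 its first neighbours, hop 2 the distance-2
    shell, 'random' uniformly outside the module."""
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    module = set(module_genes) & net.node_set
    if not module:
        raise ValueError("module has no genes in the network")
    if hop_distance == "random":
        shell = sorted(net.node_set - module)
    else:
        dmap = distances_from_set(net, module)
        shell = sorted(n for n, d in dmap.items() if d == hop_distance)
    if len(shell) < n_targets:
        raise ValueError(
            f"shell at hop {hop_distance!r} holds {len(shell)} genes, "
            f"cannot draw {n_targets} targets")
    targets = rng.choice(np.array(shell, dtype=object), size=n_targets,
                         replace=False)
    return DrugTargets(drug_id=drug_id, name=name or drug_id,
                       targets=frozenset(targets))


def synth_signatures(
    universe,
    module_genes,
    rho: float,
    rng_seed: int | np.random.Generator,
    noise_sd: float = 1.0,
    aging: Signature | None = None,
) -> tuple[Signature, Signature]:
    """An aging/drug signature pair with expected pAGE = rho over the
    module.

    Aging signs are ±1 uniform (reused if `aging` is passed, so several
    drug signatures can share one aging signature). For module genes the
    drug sign opposes the aging sign with probability (1 + rho)/2; other
    genes are independent. Magnitudes are |N(0, noise_sd)| so that the
    sign-based statistic sees realistic continuous values."""
    if not (-1 <= rho <= 1):
        raise ValueError("rho must be in [-1, 1]")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    genes = sorted(set(universe))
    module = set(module_genes)

    def _mags(n):
        if noise_sd <= 0:
            return np.ones(n)
        return np.clip(np.abs(rng.normal(0, noise_sd, size=n)), 1e-9, None)

    if aging is None:
        a_signs = rng.choice([-1.0, 1.0], size=len(genes))
        aging = Signature(values=pd.Series(a_signs * _mags(len(genes)),
                                           index=genes),
                          kind="aging", provenance="synthetic aging signature")
    a = np.sign(aging.values.reindex(genes).to_numpy())
    flip = rng.random(len(genes))
    d_signs = np.where(
        [g in module for g in genes],
        np.where(flip < (1 + rho) / 2, -a, a),
        rng.choice([-1.0, 1.0], size=len(genes)))
    drug = Signature(values=pd.Series(d_signs * _mags(len(genes)),
                                      index=genes),
                     kind="drug-perturbation",
                     provenance=f"synthetic perturbation, rho={rho}")
    return aging, drug


@dataclass
class SynthData:
    net: Interactome
    annotations: pd.DataFrame
    drugs: list[DrugTargets]
    aging: Signature
    drug_signatures: dict[str, Signature]
    truth: dict


def generate(spec: SynthSpec) -> SynthData:
    """Run the whole generator: graph + modules, drugs, signatures."""
    net, truth = synth_interactome(spec)
    seeds = spawn_seeds(spec.seed, 3 + len(spec.drugs))
    drugs: list[DrugTargets] = []
    for i, pd_ in enumerate(spec.drugs):
        module = (truth["modules"][pd_.module] if pd_.module
                  else next(iter(truth["modules"].values()), None))
        if module is None:
            raise ValueError("planted drugs need at least one planted module")
        drugs.append(synth_drug(net, module, pd_.n_targets, pd_.hop,
                                np.random.default_rng(seeds[3 + i]),
                                drug_id=pd_.drug_id, name=pd_.name))

    n_meas = spec.signatures.n_genes_measured
    universe = sorted(net.node_set)
    if n_meas is not None and n_meas < len(universe):
        rng_u = np.random.default_rng(seeds[1])
        measured = set(rng_u.choice(np.array(universe, dtype=object),
                                    size=n_meas, replace=False))
        # planted module genes stay measured so signatures cover them
        for mod in spec.modules:
            measured.update(truth["modules"][mod.hallmark])
        universe = sorted(measured)

    rng_sig = np.random.default_rng(seeds[2])
    aging: Signature | None = None
    drug_sigs: dict[str, Signature] = {}
    for pd_ in spec.drugs:
        module = truth["modules"][pd_.module] if pd_.module else []
        aging, sig = synth_signatures(universe, module, pd_.rho, rng_sig,
                                      noise_sd=spec.signatures.noise_sd,
                                      aging=aging)
        if pd_.has_signature:
            drug_sigs[pd_.drug_id] = sig
    if aging is None:  # no drugs: still emit an aging signature
        aging, _ = synth_signatures(universe, [], 0.0, rng_sig,
                                    noise_sd=spec.signatures.noise_sd)

    truth = dict(truth)
    truth["spec"] = _spec_to_jsonable(spec)
    truth["drugs"] = {d.drug_id: sorted(d.targets) for d in drugs}
    return SynthData(net=net, annotations=truth["annotations"], drugs=drugs,
                     aging=aging, drug_signatures=drug_sigs, truth=truth)


def _spec_to_jsonable(spec: SynthSpec) -> dict:
    d = asdict(spec)
    for m in d["modules"]:
        m["confidence_mix"] = {str(k): v for k, v in m["confidence_mix"].items()}
    return d


def spec_from_dict(d: dict) -> SynthSpec:
    """Build a SynthSpec from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    d["modules"] = [
        PlantedModule(**{**m, "confidence_mix": {
            int(k): v for k, v in m.get(
                "confidence_mix", {1: 1, 2: 1, 3: 1, 4: 1, 5: 1}).items()}})
        for m in d.get("modules", [])]
    d["drugs"] = [PlantedDrug(**x) for x in d.get("drugs", [])]
    if isinstance(d.get("signatures"), dict):
        d["signatures"] = SignatureSpec(**d["signatures"])
    return SynthSpec(**d)


def write_fixture(data: SynthData, outdir: str | Path) -> dict[str, str]:
    """Write net.tsv, annotations.tsv, drugs.tsv, aging.tsv,
    drug_sigs.gct and truth.json; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: str(outdir / v) for k, v in {
        "net": "net.tsv", "annotations": "annotations.tsv",
        "drugs": "drugs.tsv", "aging": "aging.tsv",
        "drug_signatures": "drug_sigs.gct", "truth": "truth.json"}.items()}
    write_edgelist(data.net, paths["net"])
    data.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    rows = [{"drug_id": d.drug_id, "drug_name": d.name, "target_symbol": t}
            for d in data.drugs for t in sorted(d.targets)]
    pd.DataFrame(rows).to_csv(paths["drugs"], sep="\t", index=False)
    data.aging.values.sort_index().to_csv(paths["aging"], sep="\t",
                                          header=False)
    if data.drug_signatures:
        mat = pd.DataFrame({k: v.values for k, v in
                            sorted(data.drug_signatures.items())}).sort_index()
        write_gct(mat, paths["drug_signatures"])
    else:
        paths.pop("drug_signatures")
    truth = dict(data.truth)
    truth["annotations"] = data.truth["annotations"].to_dict("records")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
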