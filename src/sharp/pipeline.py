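"""End-to-end orchestration of the two-step repurposing screen.

Step 1 ranks every drug by the significance of its network proximity to
each hallmark module across confidence levels; step 2 scores each proximal
drug's pAGE against the aging signature. The pipeline also produces
validation capture accounting, mechanism traces around a drug's targets,
and the extrapolated beneficial-drug count for unprofiled candidates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hallmarks as hm
from . import netcore, page as page_mod, proximity as prox

logger = logging.getLogger(__name__)


@dataclass
class SharpConfig:
    net: str
    annotations: str
    drugs: str
    aging_signature: str | None = None
    drug_signatures: str | None = None  # GCT, columns = drug ids
    out_dir: str = "sharp_out"
    levels: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    n_random: int = 1000
    seed: int = 0
    z_sig: float = -1.96
    z_marg: float = -1.645
    restrict_lcc: bool = False
    weighted_page: bool = False
    fdr_column: bool = False
    resample: str = "both"
    min_occupancy: int = 100
    # dense all-pairs distances are used when the graph is at most this big
    distance_matrix_max_nodes: int = 5000

    def __post_init__(self):
        if not (self.z_sig < self.z_marg < 0):
            raise ValueError("thresholds must satisfy z_sig < z_marg < 0")
        if self.n_random < 100:
            raise ValueError("n_random must be >= 100")
        bad = [l for l in self.levels if l not in hm.CONFIDENCE_LEVELS]
        if bad:
            raise ValueError(f"invalid confidence levels {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SharpConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SharpResult:
    screen: pd.DataFrame
    page_table: pd.DataFrame
    candidates: pd.DataFrame
    manifest: dict


def _write_csv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_sharp(config: SharpConfig) -> SharpResult:
    """Run the full screen from input files to CSV reports.

    pAGE is computed only for drugs with at least one non-ns proximity to
    the hallmark in question and an available perturbation signature;
    proximal drugs without a signature are retained with pAGE = NA
    (``no-signature`` tier). Outputs embed the seed and config hash so a
    rerun with the same config is byte-identical.
    """
    net = netcore.load_interactome(config.net)
    if config.restrict_lcc:
        net = net.restrict_to_lcc()
    annotations = hm.load_annotations(config.annotations)
    drugs = prox.load_drug_targets(config.drugs)

    aging = (page_mod.read_signature_tsv(config.aging_signature, kind="aging")
             if config.aging_signature else None)
    drug_sigs: dict[str, page_mod.Signature] = {}
    if config.drug_signatures:
        drug_sigs = page_mod.signatures_from_gct(
            page_mod.read_gct(config.drug_signatures))

    level_sets = {lvl: hm.build_hallmark_sets(annotations, net, lvl)
                  for lvl in sorted(config.levels)}
    # drop hallmarks with no annotated genes at any requested level
    annotated = set(annotations["hallmark"])
    level_sets = {lvl: {h: s for h, s in sets.items() if h in annotated}
                  for lvl, sets in level_sets.items()}

    bins = netcore.build_degree_bins(
        net, min_occupancy=min(config.min_occupancy, net.n_nodes))
    dist = (net.distance_matrix()
            if net.n_nodes <= config.distance_matrix_max_nodes else None)

    seeds = netcore.spawn_seeds(config.seed, 2)
    screen = prox.screen_drugs(net, drugs, level_sets,
                               n_random=config.n_random,
                               rng_seed=int(seeds[0]), bins=bins, dist=dist,
                               resample=config.resample)
    if config.fdr_column:
        screen = prox.add_fdr_column(screen)

    page_table, candidates = _page_and_candidates(
        config, net, screen, level_sets, drugs, aging, drug_sigs,
        rng_seed=int(seeds[1]))

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "network": dict(net.load_report),
        "n_drugs": len(drugs),
        "n_screen_rows": int(len(screen)),
        "n_candidates": int(len(candidates)),
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]
    _write_csv(screen, out / "screen.csv", header)
    _write_csv(page_table, out / "page.csv", header)
    _write_csv(candidates, out / "candidates.csv", header)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return SharpResult(screen=screen, page_table=page_table,
                       candidates=candidates, manifest=manifest)


def _page_and_candidates(config, net, screen, level_sets, drugs, aging,
                         drug_sigs, rng_seed):
    drugs_by_id = {d.drug_id: d for d in drugs}
    ok = screen[screen["status"].eq("ok")]
    proximal = ok[ok["significance"].ne("ns")]
    pairs = sorted({(r.drug_id, r.hallmark)
                    for r in proximal.itertuples(index=False)})
    seeds = netcore.spawn_seeds(rng_seed, max(1, len(pairs) * len(config.levels)))

    page_rows, cand_rows = [], []
    si = 0
    for drug_id, hallmark in pairs:
        sub = ok[(ok["drug_id"] == drug_id) & (ok["hallmark"] == hallmark)]
        n_avail = len(sub)
        n_sig = int(sub["significance"].eq("significant").sum())
        n_marg = int(sub["significance"].eq("marginal").sum())
        sig = drug_sigs.get(drug_id)
        level_pages: list[page_mod.PAGEResult] = []
        for lvl in sorted(config.levels):
            genes = level_sets.get(lvl, {}).get(hallmark)
            genes = getattr(genes, "genes", genes) or set()
            module = set(genes) & net.node_set
            row = {"drug_id": drug_id, "hallmark": hallmark, "level": lvl,
                   "page": np.nan, "z": np.nan, "n_genes_used": 0,
                   "direction": "undefined"}
            seed = int(seeds[si % len(seeds)])
            si += 1
            if sig is None or aging is None:
                row["status"] = "no-signature"
            elif not module:
                row["status"] = "empty_module"
            else:
                res = page_mod.page_significance(
                    aging, sig, module, n_random=config.n_random,
                    rng_seed=seed, weighted=config.weighted_page)
                row.update(page=res.page, z=res.z,
                           n_genes_used=res.n_genes_used,
                           direction=res.direction, status="ok")
                level_pages.append(res)
            page_rows.append(row)
        defined = [r for r in level_pages if not np.isnan(r.page)]
        direction = (page_mod.classify_direction(defined) if defined
                     else "no-signature")
        if n_sig == n_avail and n_sig > 0:
            tier = "all-level"
        elif n_sig > 0:
            tier = f"{n_sig}-of-{n_avail}"
        else:
            tier = "marginal"
        cand_rows.append({
            "drug_id": drug_id,
            "drug_name": drugs_by_id[drug_id].name,
            "hallmark": hallmark,
            "n_levels_available": n_avail,
            "n_levels_significant": n_sig,
            "n_levels_marginal": n_marg,
            "best_z": float(sub["z"].min()),
            "evidence_tier": tier,
            "page_min": (min(r.page for r in defined) if defined else np.nan),
            "page_max": (max(r.page for r in defined) if defined else np.nan),
            "direction": direction,
        })
    page_table = pd.DataFrame(
        page_rows, columns=["drug_id", "hallmark", "level", "page", "z",
                            "n_genes_used", "direction", "status"])
    candidates = (pd.DataFrame(
        cand_rows, columns=["drug_id", "drug_name", "hallmark",
                            "n_levels_available", "n_levels_significant",
                            "n_levels_marginal", "best_z", "evidence_tier",
                            "page_min", "page_max", "direction"])
        .sort_values(["hallmark", "best_z", "drug_id"])
        .reset_index(drop=True))
    return page_table, candidates


# -- validation capture ----------------------------------------------------


@dataclass
class ValidationSummary:
    """Capture accounting for an external cohort of drugs: a drug counts
    as captured if its best (most negative) proximity z over all
    (hallmark, level) cells is significant or marginal."""

    cohort: str
    n_total: int
    n_significant: int
    n_marginal: int
    capture_fraction: float
    unscreened: list[str] = field(default_factory=list)


def validation_capture(table: pd.DataFrame, cohort: list[str],
                       cohort_name: str = "cohort",
                       z_sig: float = prox.Z_SIGNIFICANT,
                       z_marg: float = prox.Z_MARGINAL) -> ValidationSummary:
    if not cohort:
        raise ValueError("cohort must be non-empty")
    ok = table[table["status"].eq("ok") & table["z"].notna()]
    best = ok.groupby("drug_id")["z"].min()
    n_sig = n_marg = 0
    unscreened = []
    for drug_id in cohort:
        if drug_id not in best.index:
            unscreened.append(drug_id)
            continue
        z = best.loc[drug_id]
        if z < z_sig:
            n_sig += 1
        elif z < z_marg:
            n_marg += 1
    if unscreened:
        logger.warning("validation %s: %d cohort drug(s) not screened: %s",
                       cohort_name, len(unscreened), unscreened[:10])
    return ValidationSummary(
        cohort=cohort_name, n_total=len(cohort), n_significant=n_sig,
        n_marginal=n_marg,
        capture_fraction=(n_sig + n_marg) / len(cohort),
        unscreened=unscreened)


# -- mechanism trace -------------------------------------------------------


@dataclass
class TraceReport:
    nodes: pd.DataFrame
    edges: pd.DataFrame
    relays: pd.DataFrame
    note: str = ""


def mechanism_trace(
    net: netcore.Interactome,
    module_genes,
    drug: prox.DrugTargets,
    drug_sig: page_mod.Signature | None = None,
    max_hops: int = 2,
) -> TraceReport:
    """Subnetwork through which a drug's perturbation reaches the module.

    Emits the induced subgraph over the drug's mapped targets, their first
    neighbours, and module genes within `max_hops` of a target. Each node
    carries in-module/is-target flags, its perturbation z (NA if
    unmeasured) and its distance to the module. Non-module target
    neighbours adjacent to module genes are flagged as relay nodes and
    ranked by |perturbation z|.
    """
    module = set(module_genes) & net.node_set
    targets = set(drug.targets) & net.node_set
    if not targets:
        raise ValueError(f"drug {drug.drug_id} has no network-mapped target")
    d_to_targets = netcore.distances_from_set(net, targets)
    module_near = {g for g in module
                   if d_to_targets.get(g, np.inf) <= max_hops}
    if not module_near:
        return TraceReport(
            nodes=pd.DataFrame(columns=["gene", "in_module", "is_target",
                                        "is_relay", "perturbation_z",
                                        "dist_to_module"]),
            edges=pd.DataFrame(columns=["gene1", "gene2"]),
            relays=pd.DataFrame(columns=["gene", "perturbation_z"]),
            note=(f"no module gene within {max_hops} hops of any target "
                  f"of {drug.drug_id}"))
    neighbors = {nb for t in targets for nb in net.graph[t]}
    keep = targets | neighbors | module_near
    d_to_module = netcore.distances_from_set(net, module)
    # relays carry perturbation from *outside* targets into the module;
    # a target already in the module needs none
    outside_nb = {nb for t in targets - module for nb in net.graph[t]}
    relays = sorted(
        nb for nb in outside_nb - module - targets
        if any(x in module for x in net.graph[nb]))

    def _z(g):
        if drug_sig is None or g not in drug_sig.values.index:
            return np.nan
        return float(drug_sig.values.loc[g])

    nodes = pd.DataFrame([{
        "gene": g,
        "in_module": g in module,
        "is_target": g in targets,
        "is_relay": g in relays,
        "perturbation_z": _z(g),
        "dist_to_module": d_to_module.get(g, np.inf),
    } for g in sorted(keep)])
    edges = pd.DataFrame(
        sorted(tuple(sorted((a, b)))
               for a, b in net.graph.subgraph(keep).edges),
        columns=["gene1", "gene2"])
    relay_df = (nodes[nodes["is_relay"]][["gene", "perturbation_z"]]
                .assign(abs_z=lambda d: d["perturbation_z"].abs())
                .sort_values(["abs_z", "gene"], ascending=[False, True],
                             na_position="last")
                .drop(columns="abs_z")
                .reset_index(drop=True))
    return TraceReport(nodes=nodes, edges=edges, relays=relay_df)


# -- extrapolation ---------------------------------------------------------


@dataclass
class ExtrapolationResult:
    rate: float
    rate_percent: float
    expected: int


def expected_beneficial_extrapolation(
    n_unprofiled: int, n_profiled: int, n_positive: int,
) -> ExtrapolationResult:
    """Extrapolate the profiled cohort's positive-pAGE rate to candidates
    without expression profiles: expected = round(rate * n_unprofiled)."""
    if n_profiled <= 0:
        raise ValueError("n_profiled must be positive")
    rate = n_positive / n_profiled
    return ExtrapolationResult(rate=rate,
                               rate_percent=round(100 * rate, 1),
                               expected=round(rate * n_unprofiled))
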