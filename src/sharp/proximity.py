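"""Drug–module network proximity and the confidence-stratified screen.

Proximity of a drug (target set T) to a module (gene set S) is the mean,
over targets, of each target's shortest-path distance to the nearest module
gene. Significance standardises the observed value against a null in which
both sets are redrawn degree-matched from the interactome; drugs with
z < -1.96 are called significant and -1.96 <= z < -1.645 marginal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .netcore import (
    DegreeBinning,
    DegreeMatchedSampler,
    DistanceMatrix,
    Interactome,
    build_degree_bins,
    distances_from_set,
    spawn_seeds,
)

logger = logging.getLogger(__name__)

Z_SIGNIFICANT = -1.96
Z_MARGINAL = -1.645


@dataclass(frozen=True)
class DrugTargets:
    drug_id: str
    name: str
    targets: frozenset[str]

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"drug {self.drug_id}: target set is empty")


def load_drug_targets(path: str | Path) -> list[DrugTargets]:
    """TSV with columns drug_id, drug_name, target_symbol (one row per
    drug-target pair)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"drug_id", "drug_name", "target_symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: drug table has no rows")
    drugs = []
    for drug_id, grp in df.groupby("drug_id", sort=True):
        drugs.append(DrugTargets(
            drug_id=drug_id,
            name=grp["drug_name"].iloc[0],
            targets=frozenset(t.strip() for t in grp["target_symbol"])))
    return drugs


# -- raw proximity ---------------------------------------------------------


def _proximity_detail(
    net: Interactome,
    module_genes,
    targets,
    dist: DistanceMatrix | None = None,
) -> tuple[float, int, int]:
    """(p_raw, n_targets_used, n_targets_dropped); dropped = unmapped to
    the network plus unreachable from the module."""
    module = set(module_genes) & net.node_set
    targets = set(targets)
    if not module:
        raise ValueError("module has no genes in the network")
    usable = sorted(targets & net.node_set)
    n_unmapped = len(targets) - len(usable)
    if not usable:
        raise ValueError("drug has no network-mapped target")
    if dist is not None:
        d = dist.set_to_set(sorted(module), usable).min(axis=0)
    else:
        dmap = distances_from_set(net, module)
        d = np.array([dmap.get(t, np.inf) for t in usable], dtype=float)
    finite = d[np.isfinite(d)]
    n_unreachable = len(usable) - len(finite)
    if len(finite) == 0:
        raise ValueError("drug has no network-mapped target reachable "
                         "from the module")
    return float(finite.mean()), len(finite), n_unmapped + n_unreachable


def proximity_raw(net: Interactome, module_genes, targets,
                  dist: DistanceMatrix | None = None) -> float:
    """Mean over usable drug targets of the distance to the closest module
    gene; 0 iff every usable target lies inside the module."""
    return _proximity_detail(net, module_genes, targets, dist)[0]


# -- significance ----------------------------------------------------------


def classify_z(z: float, z_sig: float = Z_SIGNIFICANT,
               z_marg: float = Z_MARGINAL) -> str:
    if np.isnan(z):
        return "ns"
    if z < z_sig:
        return "significant"
    if z < z_marg:
        return "marginal"
    return "ns"


@dataclass
class ProximityResult:
    p_raw: float
    null_mean: float
    null_sd: float
    z: float
    n_targets_used: int
    n_targets_dropped: int
    significance: str
    degenerate_null: bool = False
    n_random: int = 0


def proximity_significance(
    net: Interactome,
    module_genes,
    targets,
    n_random: int = 1000,
    rng_seed: int = 0,
    bins: DegreeBinning | None = None,
    dist: DistanceMatrix | None = None,
    resample: str = "both",
) -> ProximityResult:
    """Degree-matched null for drug–module proximity.

    Each replicate redraws the module set S and (by default) the target set
    T through the interactome's degree bins and recomputes the proximity;
    ``resample='targets'`` keeps S fixed for comparison. A precomputed
    :class:`DistanceMatrix` turns every replicate into an array slice and is
    strongly recommended for screens.
    """
    if resample not in ("both", "targets"):
        raise ValueError("resample must be 'both' or 'targets'")
    if bins is None:
        bins = build_degree_bins(net, min_occupancy=min(100, net.n_nodes))
    module = sorted(set(module_genes) & net.node_set)
    usable = sorted(set(targets) & net.node_set)
    p_raw, n_used, n_dropped = _proximity_detail(net, module_genes, targets,
                                                 dist)
    sampler_t = DegreeMatchedSampler(bins, usable)
    sampler_s = DegreeMatchedSampler(bins, module) if resample == "both" else None
    rng = np.random.default_rng(spawn_seeds(rng_seed, 1)[0])
    null = np.empty(n_random)
    for i in range(n_random):
        s = sampler_s.sample(rng) if sampler_s is not None else module
        t = sampler_t.sample(rng)
        if dist is not None:
            d = dist.set_to_set(s, t).min(axis=0)
            finite = d[np.isfinite(d)]
            null[i] = finite.mean() if len(finite) else np.nan
        else:
            dmap = distances_from_set(net, s)
            vals = [dmap[x] for x in t if x in dmap]
            null[i] = np.mean(vals) if vals else np.nan
    null = null[np.isfinite(null)]
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    # roundoff guard: a constant null must yield sd = 0, not ~1e-17
    degenerate = sd <= 1e-12 * max(1.0, abs(mean))
    z = float("nan") if degenerate else (p_raw - mean) / sd
    return ProximityResult(
        p_raw=p_raw, null_mean=mean, null_sd=sd, z=z,
        n_targets_used=n_used, n_targets_dropped=n_dropped,
        significance=classify_z(z), degenerate_null=degenerate,
        n_random=len(null))


# -- screening -------------------------------------------------------------

SCREEN_COLUMNS = [
    "drug_id", "drug_name", "hallmark", "level", "p_raw", "null_mean",
    "null_sd", "z", "significance", "n_targets_used", "n_targets_dropped",
    "status",
]


def screen_drugs(
    net: Interactome,
    drugs: list[DrugTargets],
    hallmark_sets: dict[int, dict[str, object]],
    n_random: int = 1000,
    rng_seed: int = 0,
    bins: DegreeBinning | None = None,
    dist: DistanceMatrix | None = None,
    resample: str = "both",
) -> pd.DataFrame:
    """One proximity row per (drug, hallmark, confidence level).

    `hallmark_sets` maps level -> {hallmark -> gene set (or
    HallmarkGeneSet)}. Empty hallmark-level sets yield NA rows with status
    ``empty_module``; drugs with no network-mapped target yield status
    ``unmapped`` and the screen continues. Re-running with the same master
    seed reproduces every z exactly.
    """
    if not drugs:
        raise ValueError("no drugs to screen")
    if not hallmark_sets:
        raise ValueError("no hallmark sets to screen against")
    if bins is None:
        bins = build_degree_bins(net, min_occupancy=min(100, net.n_nodes))
    cells = [(d, lvl, h) for d in drugs
             for lvl in sorted(hallmark_sets)
             for h in sorted(hallmark_sets[lvl])]
    seeds = spawn_seeds(rng_seed, len(cells))
    rows = []
    for (drug, level, hallmark), seed in zip(cells, seeds):
        genes = hallmark_sets[level][hallmark]
        genes = getattr(genes, "genes", genes)
        row = {"drug_id": drug.drug_id, "drug_name": drug.name,
               "hallmark": hallmark, "level": level,
               "p_raw": np.nan, "null_mean": np.nan, "null_sd": np.nan,
               "z": np.nan, "significance": "ns",
               "n_targets_used": 0, "n_targets_dropped": 0}
        module = set(genes) & net.node_set
        if not module:
            row["status"] = "empty_module"
        elif not (set(drug.targets) & net.node_set):
            row["status"] = "unmapped"
            row["n_targets_dropped"] = len(drug.targets)
        else:
            try:
                res = proximity_significance(
                    net, module, drug.targets, n_random=n_random,
                    rng_seed=int(seed), bins=bins, dist=dist,
                    resample=resample)
            except ValueError as err:  # e.g. no target reachable from module
                logger.warning("screen %s vs %s level %d: %s", drug.drug_id,
                               hallmark, level, err)
                row["status"] = "unreachable"
                row["n_targets_dropped"] = len(drug.targets)
                rows.append(row)
                continue
            row.update(p_raw=res.p_raw, null_mean=res.null_mean,
                       null_sd=res.null_sd, z=res.z,
                       significance=res.significance,
                       n_targets_used=res.n_targets_used,
                       n_targets_dropped=res.n_targets_dropped,
                       status="degenerate_null" if res.degenerate_null else "ok")
        rows.append(row)
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)


def add_fdr_column(table: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini–Hochberg FDR over the one-sided proximity
    p-values implied by z (the screen's default decision rule stays the
    raw z thresholds)."""
    from scipy.stats import norm
    out = table.copy()
    ok = out["status"].eq("ok") & out["z"].notna()
    pvals = norm.cdf(out.loc[ok, "z"].to_numpy())
    ranked = pd.Series(pvals).rank(method="first").to_numpy()
    m = len(pvals)
    q = pvals * m / ranked
    # enforce monotonicity from the largest p downward
    order = np.argsort(pvals)[::-1]
    running = 1.0
    qm = np.empty_like(q)
    for i in order:
        running = min(running, q[i])
        qm[i] = running
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = np.minimum(qm, 1.0)
    return out


def consistency_filter(
    table: pd.DataFrame,
    min_levels: int | None = None,
    rule: str = "all-available",
) -> dict[str, pd.DataFrame]:
    """Per-hallmark drugs whose proximity is significant consistently
    across confidence levels.

    ``all-available``: significant at every level whose hallmark set was
    non-empty (so a hallmark with no level-1 genes is judged on levels
    2–5). ``at-least-k``: significant at >= min_levels levels. Results are
    ranked by best (most negative) z.
    """
    if rule not in ("all-available", "at-least-k"):
        raise ValueError("rule must be 'all-available' or 'at-least-k'")
    if rule == "at-least-k" and not min_levels:
        raise ValueError("at-least-k rule needs min_levels")
    out: dict[str, pd.DataFrame] = {}
    if table.empty:
        return out
    for hallmark, grp in table.groupby("hallmark", sort=True):
        keep = []
        for drug_id, sub in grp.groupby("drug_id", sort=True):
            avail = sub[sub["status"].eq("ok")]
            if avail.empty:
                continue
            n_sig = int(avail["significance"].eq("significant").sum())
            if rule == "all-available":
                passed = n_sig == len(avail) and n_sig > 0
            else:
                passed = n_sig >= min_levels
            if passed:
                keep.append({"drug_id": drug_id,
                             "drug_name": sub["drug_name"].iloc[0],
                             "n_levels_significant": n_sig,
                             "n_levels_available": len(avail),
                             "best_z": float(avail["z"].min())})
        df = pd.DataFrame(keep, columns=["drug_id", "drug_name",
                                         "n_levels_significant",
                                         "n_levels_available", "best_z"])
        out[hallmark] = df.sort_values("best_z").reset_index(drop=True)
    return out
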