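"""The pAGE directional statistic.

pAGE compares a drug's perturbation signature with an aging expression
signature over a hallmark module. Each module gene measured with nonzero
sign in both signatures contributes -sign(aging) * sign(drug): a gene the
drug pushes opposite to its age-associated change contributes +1 (the drug
counteracts aging there), a gene pushed the same way contributes -1. pAGE
is the mean contribution, bounded in [-1, 1]; pAGE > 0 marks a
pro-longevity (beneficial) direction and pAGE < 0 an age-accelerating one.
Significance comes from random gene sets of the same size drawn from the
doubly-measured gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .netcore import spawn_seeds


@dataclass
class Signature:
    """Per-gene signed values: an aging direction-of-change vector or a
    drug perturbation z-score vector (vs. plate reference)."""

    values: pd.Series
    kind: str = "drug-perturbation"  # or "aging"
    provenance: str = ""

    def __post_init__(self):
        v = pd.Series(self.values, dtype=float)
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate genes in signature: {dups}")
        if not np.isfinite(v.to_numpy()).all():
            raise ValueError("signature contains non-finite values")
        self.values = v

    def genes_with_sign(self, min_abs: float = 0.0) -> set[str]:
        """Genes whose value carries a direction (|value| > min_abs)."""
        return set(self.values.index[self.values.abs() > min_abs])


def read_signature_tsv(path: str | Path, kind: str = "drug-perturbation",
                       provenance: str = "") -> Signature:
    """Two-column TSV: gene, signed value."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "value"], dtype={0: str})
    if len(df) and df.iloc[0]["gene"].lower() in ("gene", "symbol", "name"):
        df = df.iloc[1:]
    vals = pd.Series(df["value"].astype(float).to_numpy(),
                     index=df["gene"].str.strip())
    return Signature(values=vals, kind=kind, provenance=provenance or str(path))


# -- GCT 1.2 (text matrix with a 2-line preamble) --------------------------


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 file into a genes x samples DataFrame."""
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"{path}: expected GCT version line '#1.2', "
                             f"got {version!r}")
        nrow, ncol = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore").astype(float)
    if df.shape != (nrow, ncol):
        raise ValueError(f"{path}: header promises {nrow}x{ncol}, "
                         f"file holds {df.shape[0]}x{df.shape[1]}")
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_gct(matrix: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        out = matrix.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t")


def signatures_from_gct(matrix: pd.DataFrame,
                        kind: str = "drug-perturbation") -> dict[str, Signature]:
    """One Signature per column (column name = drug/sample id)."""
    return {col: Signature(values=matrix[col], kind=kind, provenance=col)
            for col in matrix.columns}


# -- CMap instance selection -----------------------------------------------


@dataclass(frozen=True)
class CMapInstanceMeta:
    instance_id: str
    cell_line: str
    dose: str
    exposure_time: str
    distil_cc_q75: float


def load_instance_meta(path: str | Path) -> list[CMapInstanceMeta]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"instance_id", "distil_cc_q75"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"instance table missing columns {sorted(missing)}")
    return [CMapInstanceMeta(
        instance_id=r["instance_id"],
        cell_line=r.get("cell_line", ""),
        dose=r.get("dose", ""),
        exposure_time=r.get("exposure_time", ""),
        distil_cc_q75=float(r["distil_cc_q75"]))
        for r in df.to_dict("records")]


def select_instance(instances: list[CMapInstanceMeta]) -> CMapInstanceMeta:
    """Pick the replicate-consistency winner: highest distil_cc_q75, ties
    broken by lexicographic instance_id."""
    if not instances:
        raise ValueError("no instances to select from")
    for inst in instances:
        if not np.isfinite(inst.distil_cc_q75):
            raise ValueError(f"instance {inst.instance_id}: "
                             "distil_cc_q75 is not finite")
    return min(instances, key=lambda i: (-i.distil_cc_q75, i.instance_id))


# -- the statistic ---------------------------------------------------------


@dataclass
class PAGEResult:
    page: float  # NaN when undefined
    z: float
    n_genes_used: int
    contributions: dict[str, int] = field(repr=False, default_factory=dict)
    direction: str = "undefined"
    n_genes_dropped: int = 0
    n_random: int = 0


def _direction(page: float) -> str:
    if np.isnan(page):
        return "undefined"
    return "beneficial" if page > 0 else ("deficient" if page < 0 else "undefined")


def page_score(
    aging: Signature,
    drug: Signature,
    module_genes,
    weighted: bool = False,
    min_abs: float = 0.0,
) -> PAGEResult:
    """pAGE of one drug over one module.

    G = module genes with |value| > min_abs in both signatures; each
    contributes -sign(aging_g) * sign(drug_g). Unweighted pAGE is the mean
    contribution; the weighted variant weights each gene by |drug_g|
    normalised to sum 1. Genes unmeasured or at exactly zero carry no
    direction and are dropped (counted).
    """
    if len(aging.values) == 0 or len(drug.values) == 0:
        raise ValueError("signatures must be non-empty")
    module = set(module_genes)
    usable = sorted(module & aging.genes_with_sign(min_abs)
                    & drug.genes_with_sign(min_abs))
    dropped = len(module) - len(usable)
    if not usable:
        return PAGEResult(page=float("nan"), z=float("nan"), n_genes_used=0,
                          contributions={}, direction="undefined",
                          n_genes_dropped=dropped)
    a = np.sign(aging.values.loc[usable].to_numpy())
    d = drug.values.loc[usable].to_numpy()
    contrib = (-a * np.sign(d)).astype(int)
    if weighted:
        w = np.abs(d)
        w = w / w.sum()
        page = float(np.sum(w * contrib))
    else:
        page = float(contrib.mean())
    return PAGEResult(page=page, z=float("nan"), n_genes_used=len(usable),
                      contributions=dict(zip(usable, contrib.tolist())),
                      direction=_direction(page), n_genes_dropped=dropped)


def page_significance(
    aging: Signature,
    drug: Signature,
    module_genes,
    n_random: int = 1000,
    rng_seed: int = 0,
    weighted: bool = False,
    min_abs: float = 0.0,
) -> PAGEResult:
    """pAGE with a permutation z-score.

    The null redraws |G| genes uniformly from the genes carrying a sign in
    both signatures (degree is a network property and plays no role in a
    transcriptome permutation) and recomputes pAGE; z standardises the
    observed value. A degenerate null (sd = 0, e.g. module = whole
    measured universe) leaves z = NaN.
    """
    res = page_score(aging, drug, module_genes, weighted=weighted,
                     min_abs=min_abs)
    if np.isnan(res.page):
        return res
    universe = np.array(sorted(aging.genes_with_sign(min_abs)
                               & drug.genes_with_sign(min_abs)), dtype=object)
    rng = np.random.default_rng(spawn_seeds(rng_seed, 1)[0])
    null = np.empty(n_random)
    for i in range(n_random):
        sample = rng.choice(universe, size=res.n_genes_used, replace=False)
        null[i] = page_score(aging, drug, sample, weighted=weighted,
                             min_abs=min_abs).page
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    # guard against roundoff on a constant null (e.g. module = universe)
    degenerate = sd <= 1e-12 * max(1.0, abs(mean))
    res.n_random = n_random
    res.z = float("nan") if degenerate else (res.page - mean) / sd
    return res


def classify_direction(results) -> str:
    """Aggregate per-confidence-level pAGE values into a drug-level call:
    pro-longevity iff positive at every defined level, age-accelerating iff
    negative at every defined level, else inconsistent."""
    pages = [r.page if isinstance(r, PAGEResult) else float(r)
             for r in results]
    defined = [p for p in pages if not np.isnan(p)]
    if not defined:
        raise ValueError("pAGE undefined at every confidence level")
    if all(p > 0 for p in defined):
        return "pro-longevity"
    if all(p < 0 for p in defined):
        return "age-accelerating"
    return "inconsistent"
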