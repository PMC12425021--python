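# Methods

## Scope and model

The package implements a two-step network-medicine screen for
drug-repurposing against the hallmarks of aging, plus the statistics it
rests on.

**Hallmark modules.** Genes annotated to a hallmark of aging (with an
evidence confidence level 1–5, 1 strongest) are mapped onto an undirected
protein–protein interaction network. The hallmark *module* is the largest
connected component (LCC) induced by those genes. Its significance is the
z-score of the observed LCC size against the LCC sizes of random gene sets
of the same size and degree profile: the interactome's nodes are
partitioned into log₂-spaced degree bins merged upward until every bin
holds ≥ 100 nodes, and each random set replaces every module gene with a
uniform draw (without replacement) from the gene's own bin. We call a
module significant at z > 1.96 and marginal at z > 1.645. Empirical
p-values use (r+1)/(n+1) smoothing so that finite replicate counts never
produce p = 0.

**Separation and overlap.** Topological separation between gene sets A and
B is S_AB = d_AB − (d_AA + d_BB)/2 with nearest-neighbour shortest-path
distances. Degenerate cases, which the bare formula leaves open, are fixed
as follows: a node's own-set distance excludes itself (singletons
contribute 0); the cross-set distance also excludes the node itself, so
S(A, A) = 0 exactly; unreachable node→set distances are excluded from the
means and counted in the result. Set overlap uses the Jaccard index with a
uniform-resampling p-value from the annotated universe — degree plays no
role in set overlap, so the overlap null is not degree-matched.

**Proximity (step 1).** A drug with target set T has proximity to module S
P(S, T) = (1/|T|) Σ_{t∈T} min_{s∈S} d(s, t) — the average over targets of
the distance to the closest module gene. The statistic is deliberately
asymmetric (averaged over drug targets) and is never symmetrised. Targets
absent from the network, or unreachable from the module, are dropped from
the mean and counted. Significance resamples, in each of n_random
replicates, degree-matched copies of both S and T (the field's standard
null; a single-sided mode that holds S fixed and resamples only T is
available via `resample="targets"`). Drugs with z < −1.96 are significant
and −1.96 ≤ z < −1.645 marginal; no multiple-testing correction is applied
by default (the raw-z thresholds are the screen's decision rule; an
optional Benjamini–Hochberg column can be added for inspection).

**pAGE (step 2).** For a drug perturbation signature and an aging
expression signature, every module gene g measured with a nonzero sign in
both contributes −sign(aging_g)·sign(drug_g): +1 when the drug pushes the
gene against its age-associated direction, −1 when it reinforces it. pAGE
is the mean contribution, bounded in [−1, 1]; pAGE > 0 is a pro-longevity
(beneficial) direction, pAGE < 0 age-accelerating. A magnitude-weighted
variant (weights |drug_g| normalised to sum 1) sits behind the `weighted`
flag; the unweighted form is the default because the statistic is meant to
be scale-free in both signatures. Genes at exactly zero carry no direction
and are excluded (an optional minimum-|value| threshold generalises this).
Significance redraws |G| genes uniformly from the genes measured with a
sign in both signatures — a transcriptome permutation, hence not
degree-matched. A drug screened at several confidence levels is classified
pro-longevity only if pAGE > 0 at every level where it is defined,
age-accelerating if < 0 at every defined level, else inconsistent.

**Confidence stratification.** Level L of a hallmark contains every gene
annotated at confidence ≤ L, so the five gene sets are nested from most
stringent to most inclusive, and "consistent across levels" statements are
monotone. Hallmarks with empty low-confidence sets are judged on the
levels they have (the `all-available` consistency rule).

**CMap instance selection.** When several perturbation instances exist for
one drug, the instance with the highest distil_cc_q75 (replicate
consistency, 75th percentile of pairwise Spearman correlations over
landmark genes) is kept; ties break lexicographically by instance id.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_occupancy` | 100 nodes | floor for degree-bin size; smaller bins make degree matching exact but pools too small to resample |
| `n_random` | 1000 (pipeline ≥ 100) | null replicates for LCC, proximity, pAGE z-scores |
| `z_sig`, `z_marg` | −1.96, −1.645 | the two evidence tiers of the screen |
| `resample` | `"both"` | proximity null: resample module and targets (field convention) or targets only |
| `weighted` | off | magnitude-weighted pAGE variant |
| `restrict_lcc` | off | restrict all analyses to the interactome's largest component |

All randomness flows from one master seed through deterministic
`SeedSequence` spawning, so any replicate (and any screen cell) is
reproducible in isolation and full runs are byte-identical.

## Synthetic data: what it emulates and what it does not

The generator produces a configuration-model background graph with a
power-law degree sequence (exponent 2.5, degrees capped at √n) so that
degree binning and degree-matched nulls are exercised on a realistic heavy
tail; hallmark modules are planted by wiring a gene set at a chosen
internal density (a G(n, p) block, connected with high probability above
density 2·ln(size)/size); drugs are planted by sampling targets from exact
hop-distance shells around a module (hop 1 gives raw proximity exactly 1);
and signature pairs are planted at a chosen sign-concordance ρ, so the
expected pAGE over the module equals ρ.

What it does not emulate: correlated annotation errors, literature bias in
confidence levels, tissue- or cell-line-specific expression, dose and time
structure in perturbation signatures, and the community structure of real
interactomes. Passing the planted-recovery tests therefore demonstrates
correctness and calibration of the statistics, not biological validity of
any particular screen on real data.

## Calibration of the proximity null

Planting a module by *adding* internal edges makes its genes
inward-pointing near-hubs: degree-matched scattered gene sets reach the
rest of the graph more easily than the module does, so under the
both-sets-resampled null, random drugs score a positively biased z
(measured ≈ +2 mean on the standard testbed). This makes the default
screen conservative for false positives on such modules — uniform-random
drugs are called significant in far under 5% of draws. The calibration
experiment (`benchmarks.proximity_null_calibration`) therefore holds the
planted module fixed and resamples only the target set — the null that is
exchangeable with the experiment's data-generating process — and recovers
z ≈ N(0, 1) (|mean| ≤ 0.15, sd within [0.8, 1.2], lower-tail fraction
≈ 0.025). Power against planted hop-0 drugs is measured under the default
both-sets null.

## Problem sizes

The validation experiments run on 2,000-node graphs with a 20-gene module
at density 0.6 and 8-target drugs; nulls use 500 replicates inside the
calibration and detection loops, 400 simulations for calibration and
false-positive rates, 50 runs for detection and power, and 200 replicates
per ρ for pAGE recovery at |G| = 50 over a 400-gene measured universe.
These sizes give binomial standard errors comfortably inside the asserted
bands while keeping the whole suite fast on one CPU.

## Numerical choices and degenerate inputs

- A constant null (e.g. module = whole network, or module = entire
  measured universe) must give an undefined z; the sd comparison guards
  against float roundoff (sd ≤ 1e−12·max(1, |mean|) counts as zero).
- Component ties in LCC extraction break by lexicographically smallest
  member set, so results are order-independent.
- Degree-matched sampling excludes the reference genes from the candidate
  pools; a bin with fewer non-reference candidates than reference genes
  falls back to making the reference genes eligible (logged), which also
  makes the degenerate reference = whole-node-set case well defined.
- Interactome loading drops self-loops and collapses duplicate/reversed
  edges, reporting both counts; gene symbols are case-sensitive exact
  strings and no aliasing is attempted (a mapping table belongs upstream).
- Mechanism traces look 2 hops out from drug targets by default (the
  target → relay → module pattern); relay nodes are only sought for
  targets outside the module.

## Known limitations

- Proximity variants other than closest-distance (shortest-average,
  kernel, centre) are not implemented.
- The screen applies no multiple-testing correction by default; with
  thousands of drugs × 11 hallmarks × 5 levels the raw thresholds are
  permissive, which is why the consistency-across-levels filter and the
  pAGE direction test exist downstream.
- pAGE ignores magnitudes by default and has no dose/time axis; a drug
  beneficial in one tissue and harmful in another collapses to one call.
- The all-pairs distance matrix used to accelerate screens is dense
  (O(n²) memory) and is enabled automatically only up to 5,000 nodes;
  larger graphs fall back to per-call BFS.
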