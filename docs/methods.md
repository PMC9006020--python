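# Methods

`phylodissect` dissects the phylogenetic signal in concatenated protein
alignments: it builds supermatrices from per-gene alignments, infers
maximum-likelihood (ML) trees under empirical amino-acid models with
discrete-gamma rate heterogeneity, and then perturbs the data — removing
fast-evolving sites, subsampling genes, deleting taxa — to see which
clades are robust and which are artefacts. A two-topology log-likelihood
scan localizes conflicting signal at gene and site resolution. A
synthetic-data generator provides alignments with known truth so every
stage of the pipeline can be validated end to end.

## Substitution model

The engine implements general time-reversible 20-state models
`Q_ij = s_ij π_j` (i ≠ j), with the exchangeabilities `s` taken from the
embedded LG or WAG tables (plain-text data files, PAML order, verified by
SHA-256 checksum at load time) or set uniform (Poisson). `Q` is normalized
to one expected substitution per site per unit branch length
(−Σ_i π_i Q_ii = 1). "+F" replaces the table frequencies with the
alignment's amino-acid proportions; states unobserved in the alignment are
floored at 1e-4 and the vector renormalized, so no state ever has zero
stationary probability.

Among-site rate variation uses the discrete-gamma approximation: `k`
equiprobable categories (default 4), category rates equal to the
conditional mean of each gamma quantile bin (mean-of-bins, the convention
of the mainstream ML engines), so the rates average exactly to 1. The
shape α is the only free model parameter.

Transition matrices come from the symmetric eigendecomposition
`P(t) = Π^{-1/2} U e^{Λt} Uᵀ Π^{1/2}`, computed once per model and reused
for every branch length; tiny negative entries from round-off are clamped
to zero. The unit tests verify `P(t)` against scipy's Padé `expm`, the
20-state Jukes–Cantor closed form for the Poisson model, Chapman–Kolmogorov
products, and detailed balance.

## Likelihood, optimization, tree search

Site likelihoods use Felsenstein pruning over compressed site patterns,
with per-(category, pattern) log-scaling to prevent underflow; characters
outside the 20 amino acids ('-', '?', 'X', 'B', 'Z', 'J', 'U', 'O', '*')
are treated as fully missing and marginalized. The gamma mixture is
averaged with equal weights 1/k. The per-site vector is expanded back from
patterns, and the reported total is the plain sum of that vector, so
site-wise numbers always add up to totals exactly.

Branch lengths are optimized coordinate-wise: inside ("up") and outside
partial vectors are computed once per sweep, each branch is then a 1-D
problem solved by bounded Brent on [1e-8, 20] (the bracket first narrows
around the current length and widens only if the optimum presses against
it). Because the partials go stale as the sweep proceeds, the exact lnL is
re-evaluated after each sweep; in the rare event a sweep lowers it, the
sweep is redone with per-branch refreshed partials. Convergence is a lnL
gain below `tol` (default 1e-4). The shape α is fitted by Brent on ln α ∈
[ln 0.02, ln 50], alternating with branch sweeps.

Tree search: ML pairwise distances (Brent on the two-sequence likelihood
from the 20×20 substitution count matrix) feed neighbour joining
(scikit-bio); the NJ tree's branch lengths are re-fitted and NNI
hill-climbing follows — both rearrangements of every internal edge are
scored, the best improving move is accepted, and branch lengths re-swept,
until no move improves lnL by more than `nni_tol`. Two candidate-scoring
modes exist: full local re-optimization of the five branches around the
focal edge (default), or a prescreen that scores every rearrangement
analytically from one inside/outside pass (each subtree keeps its own
branch length, so the swap-only likelihood is a product of cached
messages) and locally optimizes only the best two
(`SearchSettings.fast()`, used for bootstrap replicates and gene
screening, where thousands of searches run). An optional leaf-SPR pass
(prune each leaf, score reinsertion at every non-adjacent edge from the
pruned tree's partials, fully re-optimize a short list of candidates)
alternates with the NNI loop when enabled; it rescues placements more
than one NNI move away, such as a lineage that must cross an unresolved
region of the tree. The search is deterministic given its inputs.

Site rates are empirical-Bayes posterior means: r̂_s = Σ_m r_m P(m|x_s)
with equal category priors, computed on a supplied (usually ML) tree — the
analog of the per-site rate output of the mainstream ML engines.
The ranking sorts fastest-first and breaks ties toward the lower column
index, so removal sets are reproducible and nested across fractions.
The gamma shape used for ranking is estimated once on the full alignment
and reused for every truncation (a re-rank mode is available but off by
default).

## Supermatrix construction and screening

Genes are aligned FASTA files, one per gene; concatenation records RAxML
style 1-based inclusive partitions in input gene order and pads absent
taxa with '-'. Coverage is the percentage of non-missing cells per taxon.
Taxon deletion removes rows only — columns that become constant or empty
are retained: the convention here is that taxon deletion changes rows
only, so results across deletion schemes stay column-comparable.

Constraint screening rebuilds each gene's quick tree (NJ + NNI under
LG+Γ4) and bootstraps it; a gene is excluded when a split incompatible
with any constraint clade (both restricted to the gene's taxa;
incompatibility = all four pairwise intersections non-empty) reaches
bootstrap support ≥ τ. τ defaults to 0.95 — a deliberately conservative
cutoff, made explicit and configurable because "strong conflict" is
otherwise a subjective call. Genes overlapping fewer than 4 constraint taxa are reported
"unscreenable" rather than failing.

## Perturbation designs

* **Bootstrap support** — standard Felsenstein nonparametric bootstrap:
  resample columns with replacement, re-search each replicate (NJ + NNI,
  fast settings), count the clade's bipartition. This deliberately
  uses the plain bootstrap rather than an ultrafast-bootstrap
  approximation; the monitored quantity (clade support %) is the same
  contract. Replicate i of a run at seed s uses seed s+i, so any single
  replicate is reproducible in isolation. Default 100 replicates
  (large published analyses typically use 1000).
  Replicates can optionally start their searches from the full-data ML
  tree instead of a per-replicate NJ tree — the standard accelerator when
  the tree of interest is hard to reach from distance-based starts.
* **FPR** (fast-evolving position removal) — sites ranked once by
  posterior-mean rate; fraction f removes round(f·L) fastest columns
  (ties to the lower index); each truncation is bootstrapped. Fraction
  index j offsets the seed by 10000·j, making the f=0 row bitwise
  identical to a plain bootstrap run.
* **RGS** (random gene sampling) — subsets of genes drawn without
  replacement (default plan: 50 replicates each of 50- and 100-gene
  subsamples, 10 each of 150 and 200),
  concatenated and bootstrapped; replicate-level support is retained for
  box plots.
* **Taxon deletion** — named removal schemes applied per gene (genes left
  with < 4 taxa are dropped), then any downstream design re-runs;
  monitored clades are restricted to the survivors and reported NaN
  ("not evaluable") when fewer than two members or complement members
  remain.

## Two-topology scans

Given two resolved topologies differing in one lineage's placement, each
gene is scored by ΔlnL = lnL(T1) − lnL(T2), normalized by the gene's
total column count (gap-bearing columns included). The default re-fits
branch lengths (and optionally α) independently per gene under each
topology; a fixed-branch-length mode exists and makes per-gene ΔlnL sum
exactly to the concatenation's ΔlnL. Genes sort ascending (T2-preferring
first), ties by name; outliers are flagged beyond a configurable z-score
(default 3) of the normalized-ΔlnL distribution. The site-wise scan holds
branch lengths at their per-alignment optima under each tree — a per-site
refit would make the comparison meaningless — and its vector sums to the
per-alignment ΔlnL.

## Synthetic data

The generator evolves sites down a tree: root states from π, one gamma
category per site (held across branches), transitions sampled from P(t·r)
edge by edge. Everything is reproducible bit for bit from the seed, and
ground truth (per-site rates, per-site source topology, chimeric segment
coordinates, realized presence masks) is returned alongside.

**LBA fixture.** 14 taxa. One long terminal branch (L1, 1.5
substitutions/site) sits across short internal branches from a clade
whose stem is the second "long branch" — exposed only when its
short-branch breaker neighbour B2 is deleted; B1 is the breaker sister of
L1. Data are simulated under strong heterogeneity (α = 0.3); re-analysing
the breaker-deleted alignment under a rate-homogeneous (k = 1) model is
the mis-specification that elicits an artefactual clade uniting L1 with
the exposed group, displacing the true six-taxon clade. Geometry notes:
the overall tree is long enough that roughly 10–15% of sites are still
variable after removing the 60% fastest — at desk scale (5000 sites,
α = 0.3) a shorter tree leaves the slow tail entirely invariant and
fast-site removal could never recover anything. With the breakers present,
correct-model ML recovers the true topology, and even the mis-specified
analysis does not produce the artefact — the fixture reproduces the
breaker-taxon logic the pipeline is designed to expose. Note that
deleting B1 merges L1's
stem into its terminal branch, so the "long internal branch" control is
defined on the full taxon set.

**Chimera fixture.** Ten taxa. The host tree attaches the query lineage
Cry at an unresolved (degree-6) central polytomy — the situation after
aggressive taxon deletion, when the query's vertical neighbours are
absent from the alignment and vertical sites carry no directional signal
for its placement. The donor tree resolves Cry next to the (Rho1, Rho2) clade
across a subtle 0.03 edge. Chimeric genes take their trailing ⌈c·L⌉
columns from the donor tree (c = 0.3 by default; an interleaved layout is
available). Genes are 100 aa for the detectability experiment — short
enough that a single gene's ~1 expected donor-supporting change drowns in
noise, while 100 concatenated genes accumulate ~90 and resolve the donor
clade with high bootstrap support. Two companion trees serve the
two-topology comparisons: a resolved "tree 1" placing Cry with the
outgroup pair across a weak (0.02) edge (a polytomy nests inside any of
its resolutions, so the comparison needs two resolved alternatives), and
a "whole-gene transfer" tree — the donor topology with a deep (0.15)
shared branch — modelling genes or segments that are unambiguously
donor-derived. Ranking experiments plant one transfer-history gene among
vertical 300-aa genes (the scale of a typical phylogenomic single-gene
alignment); its ΔlnL separates from per-gene noise by several units,
whereas a gene simulated on the subtle-edge donor tree is invisible in a
substantial fraction of 300-site draws — itself an illustration of why
single-gene trees fail to expose weak transferred signal.

**Missingness.** Each (taxon, gene) pair is retained independently with a
per-taxon probability; a gene's mask is redrawn until at least 4 taxa
survive.

## What the synthetic data do not capture

Real transcriptome-derived alignments have alignment error, indels and
ragged ends, compositional heterogeneity across lineages, site-specific
amino-acid profiles (the reason deep phylogenomic analyses reach for
C60-class mixture models), and correlated gene-level missingness. Passing tests show the
pipeline's logic and numerics are sound and that its diagnostics behave
as designed on data satisfying the model assumptions; they do not show
that LG+Γ is adequate for any particular empirical dataset.

## Problem sizes and numerical choices

The validation experiments are desk-scaled by design: 10–14 taxa, 5k-site
LBA alignments, 100-gene sets, 10–20 bootstrap replicates per point, and
10 replicates per gene-subsample size (published deep-phylogeny
supermatrices run to ~10^2 taxa, ~10^5 positions and 1000 bootstrap
replicates). Branch lengths live in
[1e-8, 20]; α in [0.02, 50]; optimizer tolerance 1e-4 lnL units (1e-2 for
the coarse fits inside large resampling loops); likelihood scaling is per
node and per category; ties in site ranking and gene sorting always break
toward the lower index / lexicographically smaller name, which makes every
reported table reproducible bit for bit under a fixed seed.

## Known limitations

Single-threaded; no codon or nucleotide models; no profile-mixture (CAT,
C60) or partitioned models; NNI-only search (no SPR/TBR), so very rugged
likelihood surfaces may need a user-supplied starting tree; the bootstrap
is the plain nonparametric one, so support values on very large matrices
are more expensive than ultrafast-bootstrap approximations; ambiguity
codes are treated as missing rather than partial states.
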