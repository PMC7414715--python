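# Methods

This note documents the models, statistics, algorithms and numerical choices
behind `parafates`, the parameters that matter, and what the synthetic-data
generator does and does not emulate.

## Quartet statistics

A quartet joins the paralog pairs (a, b) of species X and (c, d) of species
Y. A column is *usable* when none of the four residues is a gap or 'X'
(ambiguity codes B, Z, J, U, O, '*', '?' are normalized to 'X' at intake and
treated as missing everywhere). Per usable column the strict two-by-two
patterns are counted:

| pattern | condition | meaning |
|---|---|---|
| Q | a=b, c=d, a≠c | within-species sisters (independent duplications) |
| R | a=c, b=d, a≠b | cross-species matching |
| S | a=d, b=c, a≠b | crossed cross-species matching |
| t (ABAC) | one matched side, the two other residues each distinct | one-sided conservation |
| u (ABCB) | mirror of t on the other side | one-sided conservation |

Degenerate columns such as AAAT or AABC count toward no category; columns
with all four residues identical are usable but uninformative. `l` is the
number of usable columns, not the raw alignment length: gapped columns
cannot produce patterns, so counts and length must share one sample space.
One-sided counts are kept for both candidate pairings and resolved once the
pairing is known (R-pairing if n_R > n_S, S if n_S > n_R, tie otherwise; a
tie emits no fate information).

Fate similarity is F = |n_R − n_S| / (n_Q + n_R + n_S). Modelling each
pattern as a Bernoulli event along the l columns, the variance of
dF = |n_R − n_S| is

    V(dF) = n_R(1 − n_R/l) + n_S(1 − n_S/l) + 2 n_R n_S / l,

which is exactly Var(N_R − N_S) for counts drawn multinomially with
probabilities n_R/l and n_S/l over l trials (the cross term is the unordered
2xy/l total; an ordered 4xy/l reading would overstate the variance — the
unit tests verify the identity symbolically and against 10⁵ multinomial
draws). Z_F = dF/√V, defined as 0 when V = 0. The asymmetry score Z_A is
built identically from (t, u) of the resolved pairing. |Z| > 1.96 is called
significant throughout.

Because real columns are heterogeneous (a mixture of constrained and neutral
classes), the true count-difference variance is Poisson-binomial and smaller
than the Bernoulli expression, so Z_F and Z_A are mildly *conservative*;
the null calibration is exact when columns are exchangeable (measured: 5.3%
|Z_A| > 1.96 on neutral simulated families, 0.8% when frozen diagnostic
columns are present).

## Likelihood engine and the duplication score

Per-site log-likelihoods for the three 4-taxon topologies are computed by
Felsenstein pruning under a reversible amino-acid model: rate matrix
Q = R·diag(π) from the symmetric exchangeabilities R and frequencies π,
scaled to one expected substitution per unit time, diagonalized once via the
√π similarity transform. The default model is LG with 10 equal-probability
discrete-gamma categories (category rate = conditional category mean,
renormalized to mean one); WAG/JTT-style alternatives plug in as data.
Missing residues are marginalized with an all-ones conditional vector, but
the pipeline filters non-usable columns before likelihood computation so
that the D and F paths see the same columns.

Branch lengths (bounds [1e−8, 10], all initialized at 0.1) are optimized by
bounded coordinate ascent in the fixed order a, b, c, d, internal; sweeps
stop when the log-likelihood gain falls below 1e−6 (max 20 sweeps). The
ascent caches the four unchanged tip conditionals during each 1-D search and
collapses repeated alignment columns to unique patterns with multiplicities.
The gamma shape is estimated once per quartet by a bounded 1-D search
([0.05, 20], tolerance 1e−3) on the highest-likelihood topology with branch
lengths fixed, then shared across all three topologies, whose branch lengths
are re-optimized. On rate-homogeneous data the shape profile is nearly flat
above ~2, so the estimate is large but need not sit at the bound; a boundary
solution is flagged with a warning.

Expected likelihood weights use RELL resampling: B replicates (default
1000) draw l sites with replacement, per-topology replicate log-likelihoods
are soft-maxed into weights, and weights are averaged. The duplication score
is D = 1 − w_Q — the support for a *shared* duplication. The parsimony
fallback (w_i = n_i/(n_Q+n_R+n_S)) rank-correlates with ELW-D at Spearman
ρ ≈ 0.88 on graded simulations and is used wherever scoring 66 quartets
per family 100× over would be disproportionate (family-scale end-to-end runs
and the bootstrap default to it; the ELW path is exercised on dedicated
topology-separation experiments).

## Network integration

Duplication network: complete graph over species with D as edge weight;
degenerate quartets (and missing species pairs) receive the neutral weight
θ. Weighted cluster editing uses the signed similarity s = D − θ with
θ = 0.6: pairs above θ attract, below repel, and the partition minimizes
violated similarity (attraction cut across blocks plus repulsion kept within
blocks). For ≤ 10 nodes the optimum is found by exhaustive set-partition
enumeration (restricted growth strings); larger graphs use a deterministic
multi-start heuristic — greedy pivot in two orders plus greedy agglomeration,
each refined by single-node relocation, block-merge and node-swap moves to a
local optimum — which matches the enumeration optimum on ≥ 95% of random
small graphs and can never report a cost below it.

Fate network: per quartet with a resolved pairing, two edges link the
fate-matched genes across species (R: (a,c) and (b,d); S: (a,d) and (b,c)),
weighted by F; repeated observations of a gene pair are averaged so
quartet-rich families do not inflate weights. Markov clustering follows the
canonical algorithm with the stated parameters (expansion 5, inflation 10):
column-stochastic matrix with per-node self-loops (max incident weight,
floor 1e−6), iterate matrix power → entrywise power → renormalize, pruning
entries below 1e−8 *after* renormalization (inflation 10 drives entries far
below any absolute threshold before normalization), until the matrix is
stable (max change < 1e−6, cap 200 iterations). Clusters are read off
attractors (positive diagonal), attractor systems are merged via their
mutual support, and every other node joins the system attracting it most
strongly (ties break lexicographically); edgeless genes stay singletons.

## Bootstrap, robustness, P and Z̄_F

The alignment columns are resampled with replacement to the original length
(default 100 replicates); pattern counting, F, pairing, fate network and MCL
are redone per replicate. The duplication clustering is held from the full
data — only the fate side is bootstrapped, and re-estimating ELW per
replicate would dominate runtime for no inferential gain (a flag recomputes
parsimony-D per replicate instead). Robustness of a baseline fate cluster is
its mean best Jaccard coefficient against each replicate clustering;
clusters are kept greedily by descending robustness, skipping overlaps, and
dropped below 0.5 (with the bootstrap disabled, every baseline cluster
scores 1).

Pervasiveness: for each unordered pair of distinct robust fates, count the
duplication blocks in which *every* member species' pair puts one gene in
each fate; P is the maximum and the prevailing pair the argmax (ties broken
by larger Z̄_F, then lexicographically). A fate containing both genes of one
pair can never cover a block. Z̄_F averages Z_F over quartets whose two
pairs lie in different covered blocks with all four genes inside the
prevailing fates; it is defined only for P ≥ 2 (below that there is no
*recurrent* signal to measure) and reported as null otherwise. Families
where robust fates exist but no fate pair covers a block report P = 0.

## Downstream analyses

Quartet categories: independent iff the two species lie in different
duplication blocks; single-duplication quartets split into WGD vs other via
an external annotation table (species-level ohnolog labels; unannotated
species default to other). Asymmetry summaries report, per category, the
fraction of quartets with |Z_A| > 1.96 among those with |Z_F| > 1.96, with
the proportion standard error √(p(1−p)/n).

Localization configurations compare the four compartments (Mito, Chlo,
Secr, Cyto) under the fate pairing after excluding quartets with any
reliability class ≥ 3 or any gene missing from the table: uniform (all
equal), consistent (fate-matched genes agree and the fates differ),
inconsistent (the crossed genes agree instead), single-distinct (exactly one
gene deviates), other. The labels are mutually exclusive; the full 4⁴ × 2
case table is enforced in the tests against an independently written oracle.

Position coloring: for every pair, over all quartets joining it to pairs in
*other* duplication blocks, each column is classified relative to the
fate-consistent gene matching — full match = symmetric support (yellow),
one-sided match = asymmetric support (red/pink by side), full crossed match
= symmetric contradiction (blue), one-sided crossed = asymmetric
contradiction (cyan/green). A column is colored warm when supports outnumber
contradictions for that pair. Gaps are treated as a shared 21st state here
(only here): an acquired N-terminal extension aligns against gaps in the
non-extended copies, and the shared presence/absence is precisely the
relocalization signal; excluding gaps would blind the coloring to it. The
logo matrix reports, per column, the fraction of pairs carrying each class.
Drift on post-duplication shared branches in two or more blocks produces
genuinely recurrent one-sided patterns at a measurable rate (6–8% of columns
warm beyond the constructed diagnostics at default simulator divergence);
this is an intrinsic false-positive floor of pattern-level recurrence
detection, not a classification error — with drift disabled the warm set is
exactly the diagnostic set at frequency 1.

## The synthetic-data generator

The simulator evolves a root sequence (drawn from the model frequencies)
along a newick species tree under LG (or a Poisson model), optionally with
per-site discrete-gamma rates (10 categories, fixed per site). Duplications
are placed on branches (specified as clades); the lineage forks midway along
the placed branch (fraction 0.5), giving both pre-duplication divergence
between blocks (the Q signal) and shared post-duplication history within
blocks (the R/S signal). Defaults, used as the study conditions everywhere:
12 species in four clades of three, one duplication per clade stem (stem
0.6, terminals 0.08–0.14, inter-clade 0.15), 500 columns, 30 diagnostic
columns per fate, LG, no rate heterogeneity.

Fates are imposed as hard constraints: at each duplication the fate-1 copy
is set to fixed fate-1 residues at the fate-1 diagnostic columns and frozen
there (likewise fate-2), with the *same* residues reused at every
independent duplication — that reuse is the recurrent-evolution signal.
Diagnostic residues are drawn distinct from the root residue at their
column. `one_sided` mode constrains only fate-1 copies (at all diagnostic
columns), producing t ≫ u asymmetry. A soft-constraint mode is deliberately
not the default: hard constraints give sharp, analyzable truth. The optional
N-terminal extension gives fate-2 copies a common ancestral targeting motif
independently re-evolved over each gene's post-duplication path length, with
gaps in all other rows; per-fate compartments and reliability class 1 are
emitted for the localization analyses.

What the generator does not emulate: indels (outside the extension block),
gene loss and >2-copy expansions (the framework ignores such species
anyway), rate variation across lineages, gene conversion, and alignment
error (the true alignment is emitted directly, so no aligner runs in the
loop). Passing tests therefore demonstrate correct inference when the
alignment is right and fates are column-localized; they do not certify
robustness to misalignment or to diffuse, compositional fate signals.

## Problem sizes and determinism

Study-condition experiments: 100 quartets per topology class (300 columns,
B = 1000) for ELW separation; 100 random graphs (n ≤ 7) against the
enumeration oracle; 10 seeds × (signal + null) families for end-to-end
recovery; ≥ 500 quartets for each asymmetry calibration; one relocalization
family. Family-scale runs score quartets with parsimony-D; the ELW path is
validated on the dedicated quartet experiments. Every stochastic step
(simulation, RELL, bootstrap, subsampling) takes an explicit seed, and all
sub-seeds derive from it; repeated runs are bit-identical.

## Known limitations

* The Bernoulli variance is conservative under column heterogeneity (see
  above); site-rate-aware weighting of patterns is out of scope.
* Cluster editing beyond 10 nodes is heuristic (with the guarantees stated
  above), not exact FPT.
* The asymmetry measure is exposed as dA and Z_A only; no normalized
  asymmetry fraction is defined.
* Quartets are formed only from species with exactly two copies; families
  dominated by losses or expansions yield few usable pairs.
* The localization analysis consumes prediction tables as given; prediction
  quality is the caller's responsibility beyond the reliability-class
  filter.
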