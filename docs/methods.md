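# Methods

This note documents the models, rules and numerical choices behind
`beesym`, in the order data flows through the package.

## Synthetic data model (`simdata`)

**Host tree.** The default host phylogeny is a rooted ultrametric
five-taxon tree, depth 1.0 in arbitrary time units, with the two dwarf
honeybees (*A. florea*, *A. andreniformis*) as sisters and *A. dorsata*
sister to the (*A. mellifera*, *A. cerana*) pair. The split depths
(0.4/0.6/0.7 from the root) are round numbers chosen for convenience;
any ultrametric Newick tree with positive branch lengths can be
supplied instead. Downstream statistics only consume patristic
distances, so the absolute time scale is immaterial.

**Symbiont trees.** Symbiont clades evolve along the host tree under a
continuous-time birth–death–switch model with Gillespie exponential
waiting times per lineage:

- *duplication* (rate λ): the lineage splits within its host branch;
- *loss* (rate μ): the lineage dies;
- *host switch* (rate σ): the lineage is copied into a uniformly chosen
  contemporaneous host branch other than its own (the donor persists;
  a `switch_moves` flag turns copies into moves). Copying rather than
  moving reflects that invading a new host does not require losing the
  donor population. When no other branch is alive the event degenerates
  to a duplication.
- at a host split, each lineage follows *both* daughters with
  probability ρ (`cospec_prob`), else one chosen uniformly.

Surviving lineages receive `tips_per_lineage` MAG tips as a star of
length `tip_jitter` (default 0.01), mimicking multiple MAGs assembled
from one bacterial species; the ≥7-tip node filter downstream makes
multi-tip lineages necessary for testability. Branch lengths are host
time × `rate_scale` × a per-branch lognormal multiplier (log-sd
`rate_noise`). `rate_scale` defaults to 0.4: genus-level symbiont
divergence in this system is of the same order as, but smaller than,
host-tree depth, and this scale leaves a fully co-speciating clade
inside the max-tip–tip-distance ≤ 1 filter, which is the regime the
scan is meant to interrogate. In the pure co-speciation limit (ρ=1,
σ=μ=λ=0, one tip per lineage) the symbiont tree equals the host tree
exactly (Robinson–Foulds distance 0), which is tested.

There is no accepted generative model for these communities; rates are
illustrative, and the defaults used in verification (λ=0.2, n0=3,
2 tips/lineage) were chosen once to produce genus-tree sizes (30–50
tips) comparable to real genus-level MAG collections.

**Communities.** Species archetypes carry a per-host prevalence vector
and a lognormal abundance law; samples draw presence Bernoulli(p_host)
and abundance independently. An optional per-(species, location)
lognormal multiplier induces geographic structure. Empirical
prevalences converge to the specified ones (tested at ±3 SE with 500
samples/host).

**Strain mixtures.** A species' strain population is a set of genotypes
over V variant positions. With `host_partition` each host has a private
pool derived from a host-specific consensus (strains deviate from the
consensus at rate `within_strain_div`); without it, all samples share
one pool. Samples mix their pool with symmetric-Dirichlet weights
(concentration 0.5, near-clonal), and observed allele frequencies are
multinomial read draws at Poisson coverage — so the tables carry
realistic binomial sampling noise. Not emulated: linkage between
positions, sequencing error, mapping bias, within-sample strain
replacement over time. Passing tests therefore show the *rules* behave
correctly on well-formed frequency tables, not that the upstream
mapping pipeline is robust.

**Gene tables.** Negative-binomial read counts (dispersion 0.3) around
per-gene lognormal base means; a per-(gene, host) lognormal multiplier
of log-sd `host_effect` creates host-dependent functional profiles
(zero gives an exchangeable null). Fraction of bases covered is the
saturating map 1 − exp(−reads·L_read/length). Recorded per-sample
totals include an unmapped component, so gene reads never exceed them.

## Detection and strain rules (`profiles`)

- Species presence: breadth ≥ 0.5 (inclusive).
- SNV: coverage ≥ 5 and at least two alleles at frequency ≥ 0.05;
  sites with coverage < 1 or in regions failing the read-ANI ≥ 0.92
  mask are excluded from both numerator and covered length. The
  read-ANI mask is consumed as an input column (`read_ani` or
  `read_ani_pass`) since read mapping is out of scope; breadth is
  computed after the mask.
- popANI: a pair of samples is eligible when both have mean coverage
  ≥ 5 and breadth ≥ 0.5; compared positions have ≥ 5× in both; the
  distance is (positions with disjoint allele sets)/(compared
  positions). The denominator counts *all* compared positions — a
  shared fixed allele can never be a substitution, so this matches the
  printed ratio while staying well defined; a `denominator=
  "multiallelic"` flag restricts to positions where either sample is
  polymorphic or the consensi differ, for the narrower reading.
  Ineligible pairs return NaN, distinguishable from 0. Allele
  frequencies are renormalized when within 1e-6 of summing to 1, else
  rejected.
- A species is strain-analyzable when ≥ 5 eligible samples span ≥ 2
  host species.
- ANI clustering: average-linkage agglomerative clustering of 1 − ANI
  cut at 0.05 (95% ANI); representatives maximize completeness −
  5·contamination (the dRep score without the N50 term, which the
  tables here do not model), ties broken by lexicographic MAG id.

## Specificity (`specificity`)

Rohde's index uses the prevalence-rank form with strictly consecutive
ranks 1..H, ties broken by host name, which reproduces the limiting
behaviors the classification relies on (1 for single-host species, the
harmonic bound for uniform generalists). Verified invariances: scale
invariance in overall prevalence, monotonicity under moving mass to the
top-ranked host, and the [0.45667, 1] range for H=5. Classification:
one host → species-specific; shared with strain PERMANOVA p < 0.01 →
strain-specific; otherwise non-specific, flagged "untested" when no
analyzable strain data exist rather than dropped, so category totals
stay well defined.

## Community statistics (`community`)

Beta diversity uses the Baselga partition; β_sor = β_sim + β_sne holds
to 1e-12 by construction and is property-tested. The Sørensen turnover
component β_sim (richness-insensitive) is the phylosymbiosis input.

PERMANOVA computes SS_total = Σ_{i<j} d²/N and SS_within by group,
pseudo-F, R², and Ω² = (SS_b − df_e·MS_w)/(SS_t + MS_w). The null
permutes whole-sample labels freely — no strata; blocking by colony or
location is not modeled. p carries the +1 correction. The pseudo-F
reduces to the classical one-way ANOVA F on univariate Euclidean data
(tested to 1e-10 relative error, plus a cross-check against
scikit-bio's implementation).

Mantel correlation is Spearman by default (Pearson behind a flag); the
null jointly permutes rows/columns of the second matrix. For n ≤ 6 the
full n! permutation set is enumerated (120 permutations at n=5),
removing Monte-Carlo noise from the headline q-values; granularity of
the exact p is 1/n!.

The phylosymbiosis test draws one sample per host species per
iteration, runs the exact 5-object Mantel test against the host
divergence matrix, and BH-adjusts across the `n_iter` p-values of one
run, reporting mean q ± sd. Degenerate draws (zero distance variance)
record p = 1.

PCoA is classical scaling of the Gower-centered −D²/2 with `eigh`;
negative eigenvalues are reported, never silently dropped, and
coordinates span the positive ones.

## Co-phylogeny scan (`cophylo`)

The Hommola statistic is the Pearson correlation, over all unordered
pairs of host–symbiont links, between host and symbiont patristic
distances. The permutation null relabels hosts and symbionts of the
association independently (host-only behind a flag); the observed
statistic is compared with ≥ at tolerance 1e-12 so ties are counted
conservatively, and p carries the +1 correction. Degenerate instances
(zero variance, e.g. all links within one host) return r = NaN, p = 1,
flagged — so shuffled replicates never crash a scan. The implementation
is verified exactly against a brute-force double loop and, on a 4×4
instance, against full 4!×4! enumeration.

Node filters: ≥ 7 tips, ≥ 3 host species, max pairwise patristic
tip–tip distance ≤ 1 in the tree's branch-length units. Every internal
node gets a stable preorder id; per-node permutation RNG streams are
spawned from the master seed and the node id, so results are
independent of scan order. Nodes containing outgroup tips are reported
with their statistics but excluded from significant counts. Outgroup
host labels absent from the host tree are placed at twice the maximal
host distance for filter purposes only. Nested significant nodes both
count (a de-nesting option is deliberately absent: counting follows the
"k of N tested nodes" convention).

The second-order test permutes host assignments uniformly among
non-outgroup tips (topology and branch lengths untouched), re-applies
the filters, re-runs the scan, and compares the observed
tier-significant count with the null distribution over shuffles;
empirical p = (1 + #{null ≥ observed})/(1 + n_shuffles).

## Functional profiles (`funcprof`)

RPKM = reads/((length/1000)·(total/10⁶)). Detection (> 5 reads, > 90%
bases, both strict) precedes aggregation; unannotated genes contribute
to no feature. CAZyme genus shares exclude the GT and AA classes,
require genus prevalence > 0.05 in the host, average per-sample summed
RPKM over *all* of the host's samples (absent counting zero), and
normalize across eligible genera. The robust Aitchison distance is
Euclidean on rclr rows — ln(x) centered by the mean log over *positive*
entries only, zeros kept at 0 with no matrix completion: simple,
reproducible, and a pseudometric (proportional samples are at distance
0), which suffices for ordination and PERMANOVA.

## Verification problem sizes

The verification battery (tests and `scripts/acceptance.py`) uses
problem sizes chosen to make each property measurable with stable
margins on a single CPU: 50 random Hommola instances (≤ 15 links);
co-diversification recovery on ~30–50-tip genus trees with 100
permutations × 100 shuffles, and 20 seeds for the shuffled-label null;
1000 PERMANOVA null replicates (N=24, 199 permutations); 50 seeds per
strain-pipeline condition (2 hosts × 10 samples, 150 variant
positions); 1000 phylosymbiosis iterations with exact 120-permutation
Mantel tests, and 20 independent null runs.

## Known limitations

- The symbiont simulator has no sequence evolution, no sympatry
  structure for switch targets, and star-shaped within-lineage tips;
  it validates the statistics, not phylogenetic inference.
- popANI denominator semantics are implemented under two readings
  (flag); results in this package default to all-compared-positions.
- The PERMANOVA null assumes exchangeable samples; hierarchical
  sampling designs (colonies within locations) would need restricted
  permutations.
- Rohde's index is the prevalence-rank variant; intensity-weighted
  variants are not implemented.
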