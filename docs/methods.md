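# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
numerical contracts of the estimators.

## Expansion census

The census is a genome × functional-role matrix of annotation copy counts.
Genomes absent from the annotation stream contribute zero counts — absence is
information in a copy-number census, so genomes are never dropped.

An expansion event for role *r* and group *g* is called when
`mean_g(r) >= mean_phylum(r) + k · SD_phylum(r)` with `k = 1` by default.
Conventions that the rule's verbal definition leaves open, and how they are
resolved here:

- **Group level.** Means are computed per genus by default (the level at
  which copy numbers are biologically comparable); suborder-level grouping is
  available for pathway-matrix reporting, and the suborder mean is the
  genome-count-weighted combination of its genus means.
- **SD estimator.** The sample (n−1) SD over group means, the conservative
  small-n choice; configurable via `sd_ddof`.
- **Tie rule.** The comparison is inclusive (≥). When all groups are
  identical the SD is zero and every group sits exactly at the threshold, so
  all are flagged; this degenerate case is deliberate and documented rather
  than special-cased.
- **Pathway percentages.** `100 · n_flagged_pairs / (n_genera · pathway
  size)`, an interpretation reverse-engineered from reference percentage
  tables (e.g. 7 flagged pairs over 3 genera × 10 glycolytic enzymes =
  23.3 %); cells with zero flagged pairs are reported as `NE`, and
  percentages are formatted at one decimal.

The copy-number summary reports the full histogram together with its total
rather than forcing any externally stated total, because published category
counts do not always sum to the stated number of genomes; the single-copy
percentage is rounded to the nearest integer for reporting.

## Duplication vs HGT classification

The classifier encodes the visual topology reading used in comparative
studies as a minimal, reconciliation-free rule (no
duplication-transfer-loss model, no parsimony search):

1. Focal-lineage gene copies are partitioned into maximal clades whose tip
   species all belong to the focal lineage; inside each purely-focal region,
   the *minimal* clades covering the full focal membership are the candidate
   paralog clades.
2. If at least two paralog clades exist, their copies are labelled
   **duplication** (the bifurcating duplicated pattern: each paralog clade
   recapitulates the lineage).
3. A focal-species copy whose smallest enclosing clade of ≥ 2 tips contains
   only foreign species besides itself is labelled **HGT**.
4. Everything else is **ambiguous** — the rule prefers abstention to silent
   mislabelling; overlapping or partially retained events therefore surface
   as ambiguous rather than as wrong calls.

Species with a single congruent copy yield no call (there is no expansion to
classify).  Trees are used rooted as written; no midpoint rerooting is
attempted.  Unresolved polytomies are treated as compatible with any
resolution, which again pushes uncertain cases toward ambiguous.

Congruence between two trees is the normalized Robinson–Foulds distance over
*rooted, nontrivial* clades (the unrooted splits variant degenerates on
small rooted trees).  Because the distance needs a tip bijection,
multi-copy species are collapsed to one copy chosen uniformly under a fixed
seed, and both trees are restricted to their shared species set; the number
collapsed is deterministic given the seed.

The 25 % alignment-coverage filter retains records with
`aligned_non_gap_columns / query_length >= 0.25` (inclusive, "at least");
the threshold is a parameter.

## Pairwise dN/dS (Nei–Gojobori with Jukes–Cantor correction)

Site counting assigns each codon position a synonymous fraction
`#synonymous single mutants / #non-stop single mutants`, each position
contributing unit site mass, so `N + S = 3 × n_codons` exactly.  Difference
counting averages synonymous/nonsynonymous step counts over all `k!`
orderings of the `k` differing positions; pathways through stop codons are
excluded and the average renormalised over the survivors.  `pN = Nd/N` and
`pS = Sd/S` are corrected with `d = −(3/4)·ln(1 − 4p/3)` (undefined at
p ≥ 0.75, reported as a saturation error, never silently truncated), and
`ω = dN/dS` with an undefined flag when `dS = 0` (never infinity).

Conventions chosen where the classical description is silent: the standard
genetic code by default (configurable by translation-table id; table 11 is
equivalent for these purposes), pairwise deletion of codons containing
non-ACGT symbols (count reported), and a codon-column bootstrap (1,000
replicates by default) for the standard error of ω — resampling codons, not
nucleotides, because the codon is the unit of selection here.

## Enzyme kinetics

Both rate laws are fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`) on pooled replicates with a deterministic
multi-start grid: Vmax starts at the maximal observed rate, S₀.₅ at the
{10, 25, 50, 75, 90} % quantiles of the observed substrate levels, and the
Hill exponent at {1, 2, 4, 8} bounded to [0.5, 12].  The best residual sum
of squares wins with a first-found tie-break; observations are sorted before
fitting so results are strictly invariant to row order.  Standard errors
come from the Jacobian at the optimum (`(JᵀJ)⁻¹·RSS/dof`).  Tolerances are
set to 1e−14 so that noiseless data are recovered to ≤ 1e−6 relative error —
the fit-consistency contract the tests enforce.

Model selection uses the small-sample corrected information criterion AICc
with an evidence margin (default 2) favouring the simpler hyperbolic model;
"cooperative" is only claimed when the Hill fit earns it.  Designs with only
four distinct substrate levels are flagged low-confidence, not rejected.

Derived quantities: `kcat = Vmax[U/mg] · M[g/mol] / 60000 / sites` (1 U =
1 µmol/min), catalytic efficiency `kcat/S₀.₅` computed from unrounded fit
outputs, and fold changes reported at one decimal.  Published turnover
numbers for the two PK isoforms imply a mass/site convention that is
inconsistent with the standard conversion at a ~50 kDa subunit; the
consistency checker therefore compares printed and recomputed values
without asserting either, and ratio claims (e.g. the ≥ 20-fold turnover
difference) are checked on the printed constants.

Activator dose-response curves are fitted with the same Hill machinery,
reading the concentration column as the activator; a zero-activator baseline,
when present, is subtracted before fitting.

## Fitness, expression and yields

Malthusian rates are `m = ln(Nf/N0)/t` (negative rates allowed — death
phase is data).  Each replicate contributes one relative fitness
`W = m₁/m₂`; replicates are whole assays, not plates, matching triplicate
assay designs.  Summaries report mean and sample SD, a two-sided one-sample
t-test against W = 1, and a Welch two-sample test between assays; the star
thresholds 0.05/0.01/0.001 are used for display only.  Reciprocity
`W(A,B)·W(B,A) = 1` holds exactly per replicate by construction.

ΔΔCt fold changes default to 100 % amplification efficiency (`2^−ΔΔCt`) with
the efficiency exposed as a parameter (`E^−ΔΔCt`).  Specific yields are
AU/mg; negative absorbances from blank over-subtraction are clamped to zero
with a warning, a policy decision in favour of interpretable yields.

## Synthetic data: what it emulates, what it does not

- **Census** (`gen_census`): Poisson copy counts at a base rate per role,
  with planted expansions adding a fixed increment to one group's Poisson
  mean — the simplest count model with a controllable mean shift.  Defaults
  (1.0 copies/role baseline, +3 planted copies, multi-genus taxonomy) give
  clearly separated planted events.  Not emulated: annotation noise,
  phylogenetic correlation between genera, genome-quality artefacts.
- **Gene trees** (`gen_gene_tree`): duplication events replace a clade with
  two species-congruent copies of itself; transfers graft an extra recipient
  copy as sister to the donor tip.  Retained lineages must span a full
  clade — partial retention would require gene-loss modelling, which is out
  of scope.  Not emulated: branch lengths, incomplete lineage sorting.
- **Codon pairs** (`gen_codon_pair`): per-site substitution proposals with
  acceptance probability `ω^Δnd` where Δnd is the pathway-averaged
  nonsynonymous-difference increment the proposal adds between ancestral and
  derived codon (reciprocal damping of synonymous increments when ω > 1).
  This is an approximation adequate for recovery tests, not a full
  codon-matrix CTMC: at ω = 0 it guarantees the pairwise counter finds zero
  nonsynonymous differences, at ω = 1 every non-stop proposal is accepted,
  and the estimated ω is monotone in the target.  Divergence is controlled
  by the expected substitutions per codon (default 0.3, comfortably below
  Jukes–Cantor saturation).
- **Kinetics** (`gen_kinetic_data`): multiplicative Gaussian noise at
  constant CV (default 5 %, matching constant-CV assay error), truncated at
  zero, triplicates.  Substrate grids in the simulation studies are
  geometric over 0.05–5 mM (hyperbolic ADP saturation), linear over 1–20 mM
  (strongly cooperative PEP saturation, where resolution near S₀.₅ matters),
  and geometric over 0.001–1 mM (AMP dose-response); the generating
  parameter sets are the published values for the two PK isoforms, and the
  AMP response is generated hyperbolically (n = 1) since no cooperativity
  value is printed for it.
- **Competition** (`gen_competition`): deterministic exponential growth
  (`Nf = N0·e^{mt}`, default 10⁵ CFU, 68 h) with multiplicative count noise,
  triplicate.  Not emulated: lag phases, resource competition, plating
  stochasticity beyond constant-CV noise.

Passing tests on these generators demonstrate that the estimators recover
known truth under their own model assumptions; they do not validate the
biological assumptions themselves (e.g. Poisson copy counts or constant-CV
assay noise) against real data.

## Reproducibility and problem sizes

Every generator takes an explicit integer seed; the pipeline fans a single
global seed into fixed per-stage substreams (`numpy.random.SeedSequence`
spawn keys), so stage-level reruns reproduce in isolation and the run
summary is byte-identical across repeats.  The simulation studies use 200
seeds per kinetic recovery target, 2,000 resampled null role-columns for
the expansion false-positive calibration, and 2,000 simulated null assays
for the fitness type-I-error check — sizes at which the Monte-Carlo error
of each check is well below its tolerance while the whole suite remains
quick on a single core.

## Known limitations

- The mechanism classifier is topological only; branch-length evidence
  (e.g. unusually long transferred branches) is not used.
- dN/dS is pairwise; no tree-based or maximum-likelihood codon models.
- The expansion rule inherits the census annotation's consistency; roles
  split or merged between annotation systems will shift thresholds.
- Kinetic fits assume independent constant-CV errors; correlated replicate
  effects are not modelled.
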