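# Methods

`paleoeve` re-implements, as a tested pipeline on synthetic data with known
ground truth, the comparative-genomic workflow used to authenticate and date
ancient endogenous viral elements (EVEs) shared across placental mammals:
synteny-anchored orthology, translated homology search with inactivation
annotation, node-calibrated Bayesian molecular dating, and a resampling
neutrality test. This note records the models, the tunable parameters and
their defaults, the numerical choices, and what the synthetic system does and
does not establish about real data.

## The synthetic study system

The generator (`synthsim`) emulates the statistical structure the analysis
assumes rather than any particular genome:

* **Host tree.** A 14-taxon ultrametric mammal-like tree with 12 ingroup
  ("placental") taxa whose crown node sits at 102 My, a marsupial-like
  outgroup at 172 My and a monotreme-like outgroup at 187 My; subclade ages
  loosely follow published mammal timetrees. Trees are parsed from Newick
  (node ages derived from branch lengths) and validated ultrametric to
  1e-6 My; every child must be strictly younger than its parent.
* **Locus.** Three upstream and three downstream landmark protein-coding
  genes (160 aa each by default) flank a multi-gene EVE built from a
  configurable template. The default element carries nine core genes in the
  canonical order POLB → INT → PM → PW → PZ → ATPase → PRO → mCP → MCP on
  the forward strand (90–300 aa each, desk-scale), 60-bp terminal inverted
  repeats that are exact reverse complements at creation, and short
  intergenic spacers. All ORFs are stop-free at creation.
* **Evolution.** GTR+Γ (4 discrete categories, category means normalised to
  mean rate 1) along the tree at a neutral clock of 0.0027
  substitutions/site/My — the pan-genomic mammalian rate the analysis aims
  to recover. Per-site gamma categories are drawn once and inherited.
  Optional uncorrelated-lognormal branch-rate multipliers (mean 1) model a
  relaxed clock. Indel events occur at 0.1× the substitution rate with
  geometric lengths of mean 3 nt, so frameshifts arise naturally in the
  decaying element. The EVE is excised (flanks joined) from every tip
  outside the insertion clade, and carrier tips independently lose the
  element with a configurable probability.
* **Landmark conservation.** Landmark genes evolve under purifying
  constraint: their substitution rate is scaled by `landmark_rate_factor`
  (default 0.25) and indels are rejection-sampled away from them. This is a
  deliberate deviation from whole-locus neutrality: the synteny method's
  premise is that the flanking genes stay recognisable across ~190 My, which
  is true of real conserved coding genes but not of neutral sequence at the
  simulated indel rate. The EVE, spacers, TIRs and noncoding flanks remain
  fully neutral — neutral decay of the element is the object of study.
* **Coordinates and determinism.** 0-based half-open intervals internally;
  1-based inclusive in human-readable hit reports. Every taxon sequence
  carries a per-site map to its ancestral column, which makes features
  liftable through indels, lets the truth record answer presence queries
  exactly, and reconstructs the true alignment (lineage-specific insertions
  dropped). All randomness flows from one explicit seed through
  `numpy.random.default_rng`; per-stage seeds are derived by hashing the
  stage name.

Passing tests on this system show that the *pipeline logic* is correct under
the stated generative model. They do not show robustness to assembly errors,
alignment error in real whole-genome alignments, paralogy among landmark
genes, base-composition heterogeneity, or selection on flanking noncoding
DNA — all held ideal here.

## Translated homology search (`seqsearch`)

Six-frame translation uses the standard codon table; codons containing N
translate to `X`, stops to `*`, and every frame carries an exact coordinate
map back to the forward strand. Alignment is affine-gap Smith–Waterman
against each frame with a BLOSUM45 matrix (gap open 15, extend 2, applied as
`open + g·extend` for a gap of length g). All pairings with `*` score −5:
stops are alignable on purpose, because premature stops are the degeneration
signal being annotated.

The dynamic program is row-vectorised; only the H matrix is stored (E and F
values are recomputed on demand during traceback from their unrolled
definitions, which is exact). Ties prefer diagonal, then gap-in-subject,
then gap-in-query. Multiple subject-disjoint HSPs are extracted from one
matrix by taking candidate endpoint cells in score order and rejecting
tracebacks that merge into an already-reported alignment.

**Seeding.** Candidate windows come from 2-mer word matches scored against
the probe (BLOSUM neighbourhood). Two regimes:

* *Sensitive* (`seed_threshold ≤ 1`, or small subjects): every positive
  word opens a window padded by the probe length. With gap cost
  `open + extend ≥ 17 ≥` the maximal pair score (15), any alignment scoring
  ≥ 16 must contain a positively scoring adjacent pair — if every adjacent
  pair sums ≤ 0, telescoping bounds each gapless segment by 15 and each
  additional segment costs at least one gap — so the seeded search is
  provably identical to exhaustive per-frame Smith–Waterman above the
  default score floor of 16. The acceptance suite verifies this against an
  independent brute-force DP on random pairs.
* *Fast* (default threshold 12): seeds are clustered by diagonal bucket and
  subject position; clusters of ≥ 3 seeds open banded windows. This is the
  usual word-seeding sensitivity/speed trade and is used for locating the
  well-conserved landmark genes.

**Statistics.** Karlin–Altschul λ solves Σ pᵢpⱼ e^{λsᵢⱼ} = 1 (Brent's
method) for a uniform 20-letter background by default; K uses the
lattice-case series over convolution powers of the pair-score distribution.
E = K·m·n·e^{−λS}, bit = (λS − ln K)/ln 2. Gapped statistics are the
ungapped solution scaled by 0.9 (island estimation is out of scope);
E-values carry a regime label. Finite-length edge effects are not corrected,
so absolute E-values are honest to roughly a factor of two (checked by
Monte-Carlo during development); all thresholding in the pipeline is
relative to this one convention.

**Chaining and group significance.** HSPs of one probe are partitioned into
collinear chains by repeatedly extracting the maximum-total-score chain
(strictly advancing in query and subject; ≤ 9 aa overlap; subject gap ≤ 900
nt; opposite strands never chain). Query cover is the union of query
intervals over the probe length. A chained group additionally gets a
*chained E-value*: the summed member scores, charged 20 raw points per
junction, pushed through the same Karlin–Altschul formula. A neutrally
decayed element at the simulated indel rate survives only as ~5–20-codon
in-frame fragments whose individual E-values are weak; the chained
significance captures what a human reader takes from a hit diagram — many
small collinear hits to one protein. This is a deliberately simple group
statistic, not BLAST's sum-P machinery.

**Inactivation annotation.** Within a group's *backbone* (highest-scoring
collinear subset, ≤ 3 aa overlap), every `*` in an HSP's subject translation
is reported as a premature stop at the forward-strand coordinate of its
codon's leftmost nucleotide, and a frameshift is reported at the junction
(left HSP's right edge) between adjacent backbone HSPs whose frames differ.
The planted-case generator (`make_inactivation_case`) rejection-samples
junction contexts so that extensions across the break only lose score, then
verifies by exhaustive alignment that optimal local alignments stop exactly
at the junction — otherwise the "exact breakpoint" is genuinely ill-defined
between diverged sequences.

## Synteny and presence calling (`synteny`)

Landmarks are located by translated search (best group per landmark,
E ≤ 1e-3); the orthologous region is the span between the innermost located
upstream and downstream landmarks (pad 0). With a single anchored side the
region extends 3 × 1,053 codons (the ancestral polymerase length) into the
unanchored direction. Presence requires ≥ 1 core-protein hit group with
(chained or single-HSP) E below 1e-5 inside the region, searched
exhaustively per frame; a stricter multi-probe mode is available. Absence is
only called when the region itself is anchored — unlocated landmarks yield
"ambiguous", never "absent", so assembly gaps cannot masquerade as losses.
Arrangement is consistent when detected genes follow the template order (or
its reverse) and integrase and major capsid share a strand. An independent
alignment-coverage method calls presence from non-gap coverage of the EVE
columns in an alignment slice; the two methods populate one presence matrix
and are compared cell by cell, never silently reconciled.

## Alignment utilities (`alnkit`)

MAF blocks are read via Biopython and clipped to reference regions with
exact per-row coordinate arithmetic; stitching concatenates blocks over a
species set, padding absentees with gaps and refusing overlapping reference
blocks. Alignment merging is global profile–profile Needleman–Wunsch over
intact columns (match 2 / mismatch −1 / gap-vs-base −1, linear gap 2 per
column) — the desk-scale analogue of profile merging of the two locus
subalignments. Trimming removes columns whose gap fraction exceeds 0.8 by
default, keeping a column map; this replaces the published automated
trimming heuristic with a deterministic, testable rule. p-distances use
pairwise deletion over unambiguous A/C/G/T; pairs with no comparable sites
are flagged undefined, not zero.

## Calibrated dating (`clockdate`)

The topology is fixed: each orthologue clade mirrors the host tree
restricted to its carriers, and two clades join at a paralogue root.
Likelihood is Felsenstein pruning under GTR+Γ4 over unique site patterns
(GTR nests the TVM-class model a model-selection step would pick; model
parameters may be fixed or sampled). Gaps and ambiguity codes are missing
data. Partial likelihoods are cached so a single node-age proposal only
recomputes the path to the root.

Priors: normal calibration densities on named MRCA nodes; uncalibrated node
ages are uniform within their order constraints; the root (if uncalibrated)
is uniform between the oldest calibration mean and 500 My; the clock rate is
lognormal with median 0.003 and σ = 1.5 (diffuse); relaxed-clock multipliers
are lognormal with mean 1 and fixed σ. Note the standard consequence of the
flat-within-constraints tree prior: marginals at calibrated nodes match
their normals exactly only when the neighbouring nodes are themselves
calibrated; free intermediate nodes tilt deep calibrated nodes upward
(polytope volume). The prior-recovery check therefore calibrates every
internal node, as the real analysis's densely calibrated tree effectively
does.

Proposals: node-age uniform slides within (oldest child, parent) bounds,
root and rate scale moves, optional α/frequency/exchangeability moves,
per-branch multiplier scales. Step sizes auto-tune toward 20–40% acceptance
during burn-in (25%) and freeze. Defaults are desk-scale (pipeline:
3×10⁴ generations sampled every 20); an ESS ≥ 200 check on every parameter
is applied after the run and failures are surfaced as warnings, exactly as
the convergence criterion of the original analysis. Chain lengths are
configuration, not model.

Summaries: posterior mean, median, shortest-interval 95% HPD (contains
≥ 95% of post-burn-in samples by construction), and ESS
n/(1 + 2Σ|ρₖ|) with the sum truncated when |ρₖ| < 0.05. Summing
autocorrelation *magnitudes* is deliberately conservative: an antithetic
(alternating) chain reports a small ESS rather than a super-efficient one.

The presence-based minimum age is the host-tree age of the MRCA of all taxa
called present (ambiguous excluded); fewer than two carriers is an error,
not a number.

## Neutrality test (`neutrality`)

The observable is the set of pairwise p-distances between carrier taxa over
the EVE region versus pooled distances over noncoding null regions of the
same length. Two inference routes are provided:

* `ks_test_one_tailed`: the classical one-tailed two-sample KS test
  (D⁺ = sup[F_focal − F_null]; asymptotic p = e^{−2mnD²/(m+n)}; exact or
  sampled value-permutation option). This mirrors the published procedure
  but treats distances as exchangeable values, which they are not — the 66
  distances among 12 taxa share the host tree — so its p-value is a
  reference number, not a calibrated error rate.
* `ks_region_rank_test` (used by the pipeline and the acceptance checks):
  the observed D⁺ of the focal region against the pooled others is ranked
  among the D⁺ obtained when each null region plays the focal role;
  p = (1 + #{D_r ≥ D_obs})/(R+1). Under neutrality the focal region is
  exchangeable with the nulls *as a block*, so p is exactly uniform on its
  grid regardless of the within-region dependence structure. With R = 100
  the smallest achievable p is 1/101.

Null regions must be same-length and (near-)disjoint for exchangeability;
the pipeline samples them from a simulated chromosome-scale noncoding
neighbourhood (substitution-only — pairwise-deletion distances are
insensitive to indels) rather than the narrow locus flanks, where 100
windows would overlap almost completely and the rank test loses its
guarantee. The one-tailed direction defaults to "EVE stochastically
smaller" (purifying constraint), configurable. piRNA-cluster overlap is
plain half-open interval intersection; touching intervals do not overlap.

## Pipeline and reproducibility (`pipeline`, `cli`)

Stages (simulate → synteny → date → neutral → report) run in dependency
order; a missing upstream artifact is an error naming the stage. Outputs are
plain text (FASTA, BED, TSV, Newick, YAML config echo, Markdown report).
The dating stage merges the two loci's polymerase subalignments
(profile–profile), trims, calibrates every internal node of each clade at
its host age (σ = max(1 My, 3% of age)), and reports the Table-style block:
root, each locus MRCA, clock rate, with 95% HPDs and ESS. Identical
(config, seed) runs produce identical artifacts.

## Problem sizes and known limitations

Default problem sizes (locus ~11 kb, polymerase 300 aa, chains 10⁴–10⁵
proposals, 100 null regions of the EVE length) are the package's desk-scale
study conditions; every acceptance-level property (oracle equivalence,
prior recovery, ≥ 90% HPD coverage of the true insertion age, ≥ 95% presence
accuracy under 20% loss, calibrated type-I error and ≥ 80% power of the
neutrality test) is computed at these conditions by the test suite and
`scripts/acceptance.py`.

Known limitations: no composition-based score adjustment and no island
statistics (E-values are conventional to a factor of ~2); no topology
inference or model selection; protein-mode dating accepts user-supplied
empirical exchangeabilities only; the root age of the merged paralogue tree
is weakly identified at high divergence (saturation) and is reported with
its full HPD; the generator does not model chromosome-scale context,
transposition, selection on the element, or sequencing/assembly error.
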