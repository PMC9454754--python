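# Methods

`metmap` reconstructs, per patient, how metastatic tumors were seeded: from
multi-sample bulk-sequencing SNV read counts it infers clone genotypes and
frequencies, a rooted clone phylogeny, an anatomical migration map with
per-path posterior support, a progression-model and a seeding-model label,
and cohort-level migration statistics. A paired simulator generates
patients with known clone genealogy and migration history, so every stage
is scored against ground truth. This note records the models, the defaults
and why, the numerical choices, and the known limits.

## Input model and read-count filter

Input is a long-format table of total and variant read counts per SNV per
sample, plus sample metadata (anatomical site label; primary or
metastasis). Patients with fewer than three tumor samples are rejected:
full clone genotypes cannot be deconvolved reliably from one or two
samples. A cell's observation is used only when total reads exceed 40 and
variant reads exceed six, both strictly; failing cells are treated as
missing rather than as zero-VAF evidence, because a low-count cell is
uninformative about presence, and SNVs with no usable cell are dropped. The
filter is applied per cell (whether the original protocols filtered per
cell or per SNV is not documented; per cell discards the least data).

## Clone deconvolution

The mutation model is infinite-sites, copy-number-free and heterozygous
diploid, so an SNV's expected VAF is half the summed frequency of the
clones carrying it. Deconvolution is cluster-then-nest:

1. **Clustering.** SNVs sharing a branch of the clone tree share an exact
   VAF vector across samples, so SNVs are clustered by VAF pattern. On the
   arcsine-square-root scale a binomial VAF estimate has variance
   1/(4·coverage) regardless of its mean, which makes the per-cell noise
   *known*; a Gaussian mixture with fixed per-cell variance is fitted by EM
   (Ward-linkage initialization, deterministic), and the number of clusters
   is chosen by BIC with k·d means and k−1 weights as the only free
   parameters. A soft mixture is essential here: hard data-optimized
   partitions (dendrogram cuts, k-means) reduce the within-cluster sum of
   squares of pure noise by a margin proportional to n and therefore defeat
   any information criterion. Clustering sees the raw (unfiltered)
   variant/total ratios where counts are available — sub-threshold cells
   carry pattern information even though they are excluded from estimation
   — and masked cells are zero-imputed otherwise, since at exome depth an
   unobserved cell means the variant sits below the read filter. With
   VAF-only input (e.g. analytic, noise-free matrices) an effective
   pseudo-coverage of 1e8 sets the resolution scale.
2. **Nesting (pigeonhole rule).** Cluster prevalences are twice the mean
   observed VAF per sample (a sample where the whole cluster is masked
   counts as prevalence 0). Clusters are nested into a tree: placed in
   decreasing order of total prevalence, each attaches beneath the
   containing placed cluster (prevalence at least its own minus a
   containment tolerance in every sample) of smallest total prevalence;
   clusters contained by nothing become sibling branches at the root. Each
   tree node defines one clone, whose genotype is the union of clusters on
   its root path.
3. **Frequencies, purity, presence.** Per sample, clone frequencies solve
   the triangular prevalence system under nonnegativity and a unit-sum
   bound (exact solve, then nonnegative least squares, then an SLSQP
   projection if needed; a degenerate fit returns zeros with a warning).
   Tumor purity is the per-sample frequency sum, clipped to one. A clone is
   present at a site when its frequency exceeds `presence_eps` in any
   sample of that site; clones present nowhere are kept in the phylogeny
   flagged unobserved-ancestral.

Defaults: `containment_tol` 0.05 prevalence units (absorbs binomial noise
at exome coverage; exact, noise-free analyses should use a tight tolerance
such as 1e-6), `presence_eps` 1e-3 ("greater than zero" is numerically
meaningless after least squares), `max_clusters` 15.

**Identifiability.** Two caveats are inherent to the problem, not to the
implementation. First, two nested branches whose expected VAF vectors
differ by less than roughly 0.02 (at coverage 200) cannot be separated by
any method; under symmetric Dirichlet mixing such near-degenerate draws
occur regularly, which caps expected SNV-assignment accuracy near the
low-0.9s at that depth (oracle ceiling ≈0.96 when merging pairs below 0.02
separation, ≈0.94 below 0.03). Second, the tree over clusters is unique
only when no non-ancestor cluster's prevalence dominates another's
elementwise; when a sibling dominates, several perfect phylogenies
reproduce the VAFs exactly and the minimal-containing-parent rule picks one
deterministically. The exact-recovery tests condition on this predicate,
evaluated on the ground truth.

## Clone phylogeny

The clone phylogeny is rooted at the normal (all-reference) genotype, with
integer branch lengths equal to mutation counts. When the binary genotypes
admit a perfect phylogeny (no conflicting character pair) the tree is built
directly from the laminar family of character carrier sets — this is the
only path exercised by the pipeline, since cluster-then-nest genotypes are
perfect by construction. Conflicting inputs fall back to minimum-length
Fitch parsimony: exhaustive enumeration of unrooted topologies up to 8
clones, stepwise addition with NNI refinement beyond. Observed clones
identical to internal nodes sit at zero-length positions; unary unobserved
nodes are suppressed and zero-length internal edges collapsed into
polytomies. MRCA and meta-MRCA (the MRCA of clones found only in
metastases) are located by LCA over observed clones and annotated by where
the MRCA clone itself was detected.

Polytomy resolutions are enumerated exhaustively when the total count (a
product of double factorials, (2c−3)!! per polytomy of c children) is at
most `max_resolutions`, else sampled uniformly without replacement with a
seeded generator. Default 30, overridable per patient (heavily polytomous
phylogenies warrant 100–1000).

## Migration inference

Clone observations become zero-length location leaves on an augmented
tree. Ancestral anatomical sites are reconstructed by minimum-migration
labelings (Sankoff, unit cost per site change along any edge, root fixed to
the primary site); each site change is one clone migration directed
parent-site → child-site. All labelings within `cost_window` (default 2) of
the global minimum are pooled across the polytomy resolutions and weighted
by exp(−λ·(cost−min)) with λ=1; the posterior of a directed site pair is
the weight fraction of labelings containing it. Window and λ are exposed in
the configuration; window 0 restricts to only-optimal labelings, which is
the setting under which exact recovery of an identifiable history is
guaranteed (the wider window deliberately spreads posterior mass over
near-optimal histories to quantify uncertainty).

Map selection: paths with posterior ≥0.5 are retained at high support; if
an occupied site is left without an incoming path, candidates with
posterior >0.15 are pooled and the completion with the fewest added
migrations is chosen at low support (ties: higher posterior, then
lexicographic site order); posteriors ≤0.15 are never used. Clone counts
per path and mapped-variant counts (mutations on the seeding lineage
segment; zero when the identical clone is shared by both sites) come from
the best stored labeling compatible with the selected map. The mean
posterior of retained paths is the map's overall support; maps below 0.3
(strict) are flagged for exclusion from cohort statistics.

When no primary was sampled, a pseudo-primary site holding the MRCA clone
becomes the root and transitions into it are assigned infinite cost, so
metastasis-to-primary paths are structurally impossible in that mode.

A migration history is identifiable only if the true labeling is the
unique cost minimum. Pass-through sites (a founder whose descendants all
emigrate), two migrations sharing a destination, polyclonal companions and
self-seeding all create exact ties; the posterior is precisely the device
that exposes this ambiguity rather than hiding it.

## Classification

Progression labels are decided strictest-first on the located phylogeny:
**linear** (every node has at most one child), **big_bang** (every observed
clone is the MRCA or its direct child), **parallel** (at least two
metastasis-only clones form a branching monophyletic clade containing no
primary-located clone), else **hybrid**; a primary clone nested under
metastasis-only ancestors raises a self-seeding evidence flag. Seeding
labels are decided on the selected map for patients with at least two
metastatic sites: **network** (some site has two or more distinct sources),
**primary_seeds_all**, **metastatic_cascade** (the primary seeds exactly one
metastasis and the metastasis-only edges form a single directed path
covering the rest), else **metastasis_seeds_metastases**.

## Cohort statistics

Every clone migration is tallied as an independent event (co-migration
cannot be distinguished from sequential migration and is not collapsed),
typed P→M / M→M / M→P by site classes. Ordered site pairs are monoclonal or
polyclonal by their clone count; unordered pairs seeded in both directions
are reciprocal exchanges (P↔M or M↔M; polyclonal when a direction carries
two or more clones). Cohort summaries report the distributions of tumors
per patient, clones per patient, clones per tumor, tumors per clone and
purity, pooled path-type and clonality proportions (per-patient tables are
also written), label frequencies, and an ordinary least-squares regression
of total migrations on the number of metastatic sites sampled (flagged
degenerate when the regressor has zero variance).

## Simulator

The simulator provides the ground truth all recovery tests use. A rooted
genealogy (shapes: random attachment, chain, star, fork) carries a
zero-truncated Poisson number of novel SNVs per branch under infinite
sites, default mean 300 per branch — exome cohorts of this kind yield
thousands of SNVs per patient. Migration is one preorder pass with
per-clone probabilities (no time axis): clones are born at their parent's
residence; primary-born clones emigrate with `rate_PM`, metastasis-born
clones move on with `rate_MM` and back-seed the primary with `rate_MP`.
Forward migration relocates the clone (its ancestors mark the source
lineage), back-seeding and polyclonal companions (probability
`polyclonal_prob`) are copies observed in both sites; the MRCA clone never
leaves the primary, which guarantees no site is ever emptied. New sites are
founded until `n_met_sites` exist. Reads: per sample, frequencies of the
clones present are symmetric-Dirichlet (concentration 1, the
least-informative choice) scaled by purity (default 0.6); totals are
Poisson(coverage) floored at one, variants binomial. Defaults — six
clones, primary plus three metastases, purity 0.6, coverage 150 (a
calibration choice, not a reported cohort value), modest rates
(0.5/0.25/0.05) — emulate the clone, tumor and purity scales of the
cohorts this analysis targets.

`simulate_archetype` builds pure seeding-model histories (all-from-primary,
cascade, hub) with a resident subclone anchoring each seeded site, because
per-clone rates alone cannot force an identifiable cascade: with certain
emigration every intermediate site keeps only its founder and the seeding
direction ties in parsimony cost.

What the simulator does not model: copy-number events, sequencing error
beyond binomial sampling, within-tumor spatial structure, clock-like
timing, or multiple samples per site with distinct compositions. Passing
tests therefore demonstrate correct recovery under the stated generative
model, not robustness to CNA-driven VAF distortion or spatial sampling
bias.

## Verification strategy and problem sizes

Unit tests cover each stage; acceptance tests pit the implementation
against independent exhaustive oracles (all site labelings for the
migration minimum and the λ=0 posteriors; all tree topologies for
parsimony length), exact noiseless round-trips on identifiable instances,
calibrated noisy recovery, strict threshold semantics, archetype
classification, and structural guarantees. Problem sizes were chosen to
keep the full suite within a few minutes: 200 oracle instances (≤7 clones,
≤4 sites), 50 noisy patients (5–8 clones, 3–5 sites, coverage 200), 100
archetype seeds, 1000 metastasis-only patients for the missing-primary
guarantee. The migration-edge F1 floor in the test suite (mean ≥0.75) was
calibrated once on the 50-patient setting (measured mean 0.879, sd 0.205)
and then frozen. The SNV-assignment accuracy measured there (mean ≈0.92)
sits at the identifiability ceiling discussed above.

## Known limitations

- Exactness claims require identifiable inputs; the predicates are stated
  above and implemented in the test suite.
- The posterior is per directed site pair, pooled over labelings and
  resolutions with equal prior weight per labeling; it is a transparent
  Boltzmann construction, not a sampled Bayesian posterior.
- Enumeration is capped (10^4 stored labelings, 2·10^5 enumerated); beyond
  the cap posteriors are computed on the enumerated stream and the result
  is flagged truncated.
- Branch lengths count mutations; there is no molecular-clock dating and no
  bootstrap support on the phylogeny.
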