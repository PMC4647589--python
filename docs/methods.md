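# Methods

## The reconstruction model

Each compound class is a binary character (0 = not used as a fertility
signal in that species, 1 = used) evolving independently on a fixed rooted
phylogeny under the symmetric two-state Mk model: rate matrix
`[[-q, q], [q, -q]]`, so gains and losses are equally fast. The transition
kernel over a branch of length *t* has the closed form
stay = (1 + e^(−2qt))/2, switch = (1 − e^(−2qt))/2; the implementation uses
this closed form and the test-suite checks it against the numerical matrix
exponential.

Assumptions worth stating plainly:

* **Fixed tree.** The tree is an input; no topology or branch-length
  inference is done. Composite supertrees with multifurcations are
  supported — the pruning recursion simply takes the product over all
  children.
* **Unit branch lengths.** `set_unit_branch_lengths` overwrites every edge
  with 1 before analysis. This models change per speciation event
  (punctuational change) and makes trees with missing or incommensurable
  branch lengths usable. *q* is therefore "expected changes per branch",
  not per unit time.
* **Flat root prior.** The root state prior is (½, ½), which for this
  symmetric chain equals the stationary distribution, so the choice is
  inert here; it is nonetheless explicit and configurable (`root_prior`)
  because it stops being inert under any asymmetric extension.
* **Independent characters, one rate per character.** Each class gets its
  own MLE of *q*; no rate sharing across characters (a pooled fit across
  characters is available separately as `pooled_rate_mle`, used for
  parameter-recovery checks where a single character is far too noisy).
* **Missing states.** A `?` tip contributes the uninformative conditional
  likelihood (1, 1).

## Likelihood and marginal reconstructions

`tree_log_likelihood` is Felsenstein pruning: post-order conditional
likelihoods, rescaled at every internal node (the per-node scale factors
accumulate in log space), so deep trees at high rates do not underflow — a
200-tip tree at q = 5 is exercised in the tests. Data with probability
exactly zero (e.g. q = 0 with polymorphic tips) return −∞ rather than
raising.

Ancestral states are **marginal proportional likelihoods**: at a node, the
likelihood of all tip data with that node clamped into each state,
normalized across the two states, evaluated at the character's global MLE
of *q* (never re-optimized per clamping). This is the classic node-pie
quantity, distinct from joint (max-product) reconstruction, which answers a
different question and would not reproduce per-node percentage reports.
The implementation is one outside–inside (up-down) pass: with `D_v` the
usual inside conditionals and `U_v` the outside likelihoods (prior at the
root; child updates combine the parent's outside term with sibling
messages), the node marginal is `D_v · U_v` renormalized. The test suite
verifies this pass against the defining clamp-and-renormalize brute force
(explicit enumeration of all ancestral assignments) at every node of a grid
of 2–6-tip topologies, including multifurcations, at three rates, to 1e−10.

**Optimizer.** `fit()` maximizes over *q* by bounded scalar search on
log *q* over [1e−8, 1e3] (`scipy.optimize.minimize_scalar`, xatol 1e−9 on
the log scale, i.e. ~1e−9 relative in *q*). The 1-D profile is empirically
unimodal (asserted on a grid in the tests), so no restarts are used.
Monomorphic characters have likelihood decreasing in *q*; the optimizer
lands on the lower bound and the result carries `at_bound="lower"` so
boundary estimates are never mistaken for interior MLEs.

**Thresholds and ties.** "Likely present" and branch painting use a strict
> 50 % rule; a node at exactly 50 % is ambiguous — not called, not painted.
Report cells are stored unrounded; TSV/printing rounds to one decimal,
half-up. Tip branches are painted by their observed state (their marginals
are degenerate).

## Coding chemical profiles into characters

A compound is *fertility linked* in a species when the fertile group
(queens, or mature egg-laying females in solitary species) overproduces it
relative to the non-fertile group (workers / virgin females). Two routes:

* **Qualitative:** detected in at least half of the fertile individuals and
  absent from every non-fertile individual. This rule is deterministic
  given detection, and it alone can make coding *exact*; the exact-recovery
  tests therefore run with `FertilityCriterion(qualitative_only=True)`.
* **Quantitative (default stand-in, fully configurable):** one-sided
  Mann–Whitney rank-sum (fertile > non-fertile) at α = 0.05 **and** an
  observed fold-change ≥ 2. The fold is the ratio of geometric means —
  the natural location contrast under multiplicative (lognormal) abundance
  noise — falling back to arithmetic means when zeros occur. Published
  studies differ in their exact statistics, which is why literature species
  should be ingested as pre-coded 0/1 rows (TSV or NEXUS) rather than
  re-derived; the default exists so that *new* per-individual tables can be
  coded reproducibly. Single-individual groups trigger the qualitative
  rule only, with a warning. A compound absent from both groups is coded
  not-linked, with a warning. Calls are invariant to global rescaling of
  abundances (unit-free).

A species' row is then: class = 1 if ≥ 1 member compound is fertility
linked, 0 if the species was profiled but no compound of the class
qualified, all-`?` if the species has no measured compounds. Compound →
class assignment tries a trivial-name dictionary, then systematic-name
suffix rules, then structural descriptors; end-group chemistry outranks
hydrocarbon features (an unsaturated acid is a fatty acid, not an alkene;
a methyl-branched alkene is an alkene). Unclassifiable names come back as
`"unknown"` and are logged, never guessed or dropped.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage can be tested with known ground truth:

* `simulate_yule_tree` — pure-birth topologies (each extant lineage equally
  likely to split; exponential waiting times). The analysis is conditional
  on a fixed tree, so only plausible topology *shapes* matter; any other
  generator can be substituted.
* `simulate_character` — forward simulation of the same symmetric chain the
  model assumes: root from (½, ½), per-edge switch probability
  (1 − e^(−2qt))/2, returning both tip states and the true internal states.
* `simulate_chem_profiles` — queen/worker (or mature/virgin) abundance
  tables in which each class's designated compound is overproduced
  `fold_change`-fold in the fertile caste under lognormal noise;
  `fold_change = inf` gives the qualitative regime (compound absent from
  the non-fertile caste).

Generator defaults (in `SimulationConfig`) are the package's reference
study conditions: 16 tips, 12 characters, q_true = 0.1 per unit branch,
12 individuals per caste, 4-fold queen excess, lognormal σ = 1.05 (natural
log; CV ≈ 140 %, typical of per-individual GC–MS peak areas), base
abundance 100 (arbitrary units — the coding is unit-free). The noise level
and group size were calibrated jointly, once, so that the default
quantitative criterion behaves as designed: under these conditions the
significance test rather than the fold filter is the operative gate under
the null (null call rate ≈ 4 %, close to its nominal α = 5 %), while a
4-fold excess is detected in > 90 % of compounds. With quieter data the
fold filter would dominate and the criterion would be conservative —
that trade-off is inherent to any "significant AND ≥ k-fold" rule.

What the generators do **not** emulate: correlated evolution between
classes, detection limits/censoring, chromatographic co-elution,
compositional (relative-abundance) effects, or unequal group sizes.
Passing tests therefore demonstrate correctness of the algorithms under the
model's own assumptions, not robustness of the biology to their violation.

## Validation sizes and numerical tolerances

Oracle checks run on all-pairs grids small enough to enumerate: topologies
with 2–6 tips (three random Yule draws per size plus fixed multifurcating
cases) × rates {0.05, 0.3, 1.0} × 20 random tip vectors, with agreement
required to 1e−10 (likelihood and every node marginal); the transition
kernel is compared with `expm` to 1e−12 over a (q, t) grid. Rate recovery
uses 500 characters on a 64-tip tree (pooled MLE; single-character MLEs on
16 tips are extremely noisy and often boundary-valued, which is expected
behaviour, not failure). Coding calibration uses ~1000 null compounds.
These sizes keep the full suite to a few seconds while leaving the checks
exhaustive where exhaustiveness is the point.

## Design decisions that were genuinely open

* **Newick dialect:** labels are literal (no underscore→space translation;
  quoted labels supported) because the tip names are binomials with spaces.
  Unrooted input (`[&U]`) is rejected rather than auto-rooted — ancestral
  nodes are meaningless without a root. Missing branch lengths are legal
  because the pipeline overwrites them anyway.
* **Polytomies are retained**, not arbitrarily resolved; composite
  supertrees commonly contain them and the likelihood handles them natively.
* **Clade report columns** are ordered most- to least-inclusive (by member
  count); the origins summary exploits this to return the earliest clade
  whose cell clears the threshold.
* **`ChemProfile` bundles both castes** of a species (each a `CasteProfile`
  table), so an overproduction call needs only (profile, compound) — the
  comparison is meaningless for one caste in isolation.
* **Packaged fixtures:** the 16-taxon supertree is a best-effort synthetic
  reconstruction from published clade memberships and relationship
  statements, clearly flagged in `datasets.py`; the published percent table
  ships as data so the origins summary can be run against the real
  analysis' numbers without re-deriving them.

## Known limitations

* Only the symmetric 1-rate binary model: no asymmetric gain/loss rates,
  hidden rate classes, correlated characters, Bayesian or parsimony
  reconstructions.
* The quantitative coding criterion is a reasonable default, not a
  re-implementation of any specific study's statistics.
* Unit branch lengths are an assumption, not an estimate; rate estimates
  are per-branch and not comparable across trees with different depths.
* The packaged supertree should be replaced with an authoritative topology
  for any real analysis; conclusions at shallow nodes are sensitive to the
  placement of sparsely sampled lineages.
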