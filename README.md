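# pherotrace

**pherotrace** reconstructs the evolutionary history of fertility-signal
chemistry in bees. In many social insects the compounds that advertise a
female's fertility — and, in eusocial species, suppress worker reproduction
as *queen pheromones* — are cuticular chemicals drawn from a handful of
biosynthetic families. Given per-caste chemical profiles (queens vs workers,
or egg-laying vs virgin females in solitary species) and a fixed rooted
phylogeny, this package codes each of twelve compound classes (linear and
branched alkanes, alkenes, alkadienes, aldehydes, alcohols, fatty acids,
keto acids, esters, terpenes, terpene alcohols, lactones) as a binary
presence/absence character per species and asks at which ancestral nodes
each class was already in use as a fertility signal.

It is written for chemical ecologists and social-insect biologists who want
the full pipeline — coding rules, likelihood model, clade report — as
scriptable, testable Python rather than a GUI workflow.

## The model

Each character evolves on the rooted tree under the two-state Mk model
("Markov k-state, 1 parameter"): a continuous-time Markov chain on
{0 = absent, 1 = present} with a single symmetric rate *q* for gains and
losses, so over a branch of length *t*

```
P(stay)   = (1 + e^{-2qt}) / 2
P(switch) = (1 - e^{-2qt}) / 2
```

All branch lengths are set to 1 ("punctuational" change, one opportunity
per cladogenetic event), which also sidesteps missing branch-length data in
composite supertrees. Per character, *q* is estimated by maximum likelihood
(Felsenstein pruning with per-node rescaling; bounded 1-D search on log *q*),
with a flat (½, ½) root prior — the stationary distribution of this chain.
Ancestral states are reported as **marginal proportional likelihoods**: for
each internal node, the likelihood of the full data with that node clamped
to each state, renormalized to sum to one, computed in a single
outside–inside pass at the character's global MLE of *q*. A state is called
"likely present" at a node when its proportion strictly exceeds 50 %, the
same rule used to paint branches for plotting.

## Worked example

Evolve twelve compound-class characters along the packaged 16-taxon bee
supertree, then refit the model and build the clade report:

```python
import numpy as np
import pherotrace as pt
from pherotrace.coding import COMPOUND_CLASSES, BinaryCharacterMatrix
from pherotrace.simulate import simulate_character

tree = pt.set_unit_branch_lengths(pt.datasets.load_study_tree())
clades = pt.datasets.load_study_clades()

rng = np.random.default_rng(42)
rows = {sp: {} for sp in tree.tip_labels}
for cls in COMPOUND_CLASSES:
    tips, _ = simulate_character(tree, q_true=0.1, rng=rng)
    for sp, state in tips.items():
        rows[sp][cls] = state
matrix = BinaryCharacterMatrix.from_dict(rows)

report = pt.clade_report(tree, matrix, clades)
print(report.rounded().iloc[:4, [0, 4]])
```

```
                 Apidae sensu lato  Corbiculate bees
linear alkane                  0.9               1.4
branched alkane               99.9             100.0
alkene                        81.9              96.0
alkadiene                     50.0             100.0
```

Each cell is the percent likelihood that the class was present as a
fertility signal at that clade's most recent common ancestor: in this
simulated draw, branched alkanes are confidently ancestral everywhere while
linear alkanes are a recent gain. Per-character fits are available too:

```python
res = report.per_character["linear alkane"]
print(f"q_hat = {res.q:.4f}, logL = {res.llf:.3f}")
print(f"branches painted (>50%): {len(res.paint_branches())} of {len(tree.nodes)}")
```

```
q_hat = 0.0877, logL = -7.703
branches painted (>50%): 6 of 31
```

The packaged published clade-likelihood table for the real 16-species
analysis can be summarized the same way
(`pt.datasets.load_published_clade_likelihoods()` +
`pherotrace.pipeline.summarize_origins`): linear alkanes, alkenes, esters
and fatty acids come out ancestral for all sampled bees, branched alkanes
first become likely in the *Megachile* + Apidae *sensu strictu* ancestor,
and terpenes in the *Centris* + Corbiculate ancestor.

## Command line

```sh
pherotrace simulate --out-dir study/ --n-tips 16 --seed 1   # synthetic study dir
pherotrace code-matrix --profiles study/profiles.tsv --out coded.tsv
pherotrace asr --tree study/tree.nwk --matrix coded.tsv --out-dir results/
pherotrace report --report results/clade_report.tsv
```

`asr` writes the clade report (TSV), one ancestral-state table (JSON) and
one annotated Newick per character, an origins summary, and a manifest with
input hashes for reproducibility.

## Caveats

The packaged supertree topology is a best-effort reconstruction from
published clade memberships (see `pherotrace/datasets.py`); the original
species-level character matrix is not redistributed here, so cell-level
reproduction of the published ancestral-state table requires supplying that
matrix yourself (`pherotrace asr --matrix ...`). See `docs/methods.md` for
the full model description, parameter defaults and known limitations.
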