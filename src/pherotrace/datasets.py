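"""Packaged fixtures for the 16-species bee fertility-signal analysis.

The supertree here is a best-effort reconstruction assembled from the clade
memberships and relationships described with the published analysis (e.g.
stingless bees sister to bumblebees, *Centris* sister to the Corbiculate
bees); it is synthetic in the sense that the exact published figure was not
machine-readable, and it should be replaced by the authoritative topology
where available.  The clade-likelihood table, by contrast, carries the
published percentage values themselves and serves as a reference input for
the origins summary.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .tree import CladeDefinition, PhyloTree, parse_newick

__all__ = [
    "load_study_tree",
    "load_study_clades",
    "load_published_clade_likelihoods",
]


def _data(name: str):
    return resources.files("pherotrace.data").joinpath(name)


def load_study_tree() -> PhyloTree:
    """The 16-taxon composite bee supertree (synthetic best-effort topology).

    Branch lengths are intentionally absent: the analysis sets them to 1.
    """
    return parse_newick(_data("bee_supertree_synthetic.nwk").read_text())


def load_study_clades() -> list[CladeDefinition]:
    """The seven named clades of the study report, most inclusive first."""
    mapping = json.loads(_data("clades.json").read_text())
    return [CladeDefinition(name, tips) for name, tips in mapping.items()]


def load_published_clade_likelihoods() -> pd.DataFrame:
    """Published percent-likelihood-of-presence table (classes x clades)."""
    with _data("published_clade_likelihoods.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
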