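"""Seeded generators for trees, binary characters and chemical profiles.

Everything the pipeline consumes can be generated here with known ground
truth: Yule (pure-birth) topologies, binary traits evolved forward under the
same symmetric two-state Markov chain the reconstruction assumes, and
queen/worker abundance tables in which designated fertility-linked compounds
are overproduced by a configured fold under multiplicative lognormal noise
(GC-MS peak areas are positive and right-skewed, so lognormal is the natural
noise family).  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coding import (
    COMPOUND_CLASSES,
    BinaryCharacterMatrix,
    CasteProfile,
    ChemProfile,
)
from .mk import transition_matrix
from .tree import PhyloNode, PhyloTree

__all__ = [
    "SimulationConfig",
    "DEFAULT_COMPOUND_ROSTER",
    "simulate_yule_tree",
    "simulate_character",
    "simulate_chem_profiles",
]

#: Two representative compounds per biosynthetic class; the first is the one
#: the generator overproduces in fertile castes when the class is "present".
DEFAULT_COMPOUND_ROSTER: dict[str, tuple[str, str]] = {
    "linear alkane": ("pentacosane", "heptacosane"),
    "branched alkane": ("13-methylpentacosane", "3-methylheptacosane"),
    "alkene": ("9-pentacosene", "9-heptacosene"),
    "alkadiene": ("6,9-pentacosadiene", "6,9-heptacosadiene"),
    "aldehyde": ("hexadecanal", "octadecanal"),
    "alcohol": ("hexadecanol", "octadecanol"),
    "fatty acid": ("hexadecanoic acid", "octadecenoic acid"),
    "keto acid": ("9-oxo-2-decenoic acid", "10-oxo-decanoic acid"),
    "ester": ("decyl decanoate", "hexadecanoic acid methyl ester"),
    "terpene": ("farnesene", "squalene"),
    "terpene alcohol": ("geraniol", "farnesol"),
    "lactone": ("hexadecanolide", "gamma-dodecalactone"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for all three generators.

    Defaults mirror the analysed study system: 16 species, 12 binary
    compound-class characters, a per-branch transition probability governed
    by ``q_true`` on unit branches, and GC-MS-like abundance tables with 12
    individuals per caste, a 4-fold queen excess on fertility-linked
    compounds, and lognormal noise of sigma = 1.05 on the natural-log scale
    (a coefficient of variation near 140 %, typical of per-individual GC-MS
    peak areas).
    """

    n_tips: int = 16
    birth_rate: float = 1.0
    q_true: float = 0.1
    n_characters: int = 12
    seed: int = 0
    n_individuals: int = 12
    fold_change: float = 4.0
    sigma: float = 1.05
    base_abundance: float = 100.0
    compound_roster: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOUND_ROSTER)
    )

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_characters < 1 or self.n_individuals < 1:
            raise ValueError("counts must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.q_true < 0 or self.birth_rate <= 0:
            raise ValueError("rates must be nonnegative (birth rate positive)")


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    *,
    seed: Optional[int] = None,
    label_format: str = "t{:02d}",
) -> PhyloTree:
    """A rooted binary pure-birth tree with ``n_tips`` labelled tips.

    Every extant lineage splits at rate ``birth_rate``; the process stops at
    ``n_tips`` lineages and the pending tips are extended by one further
    exponential draw, so terminal branches have positive length.  Tip labels
    are assigned in left-to-right order.  (The analysis overwrites branch
    lengths with 1 anyway; the generator only needs plausible topologies,
    and alternative topology generators can be substituted freely.)
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)

    root = PhyloNode(id=-1)
    birth_time = {id(root): 0.0}
    left = PhyloNode(id=-1, parent=root)
    right = PhyloNode(id=-1, parent=root)
    root.children = [left, right]
    now = 0.0
    active = [left, right]
    for node in active:
        birth_time[id(node)] = now
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active[k]
        parent.length = now - birth_time[id(parent)]
        kids = [PhyloNode(id=-1, parent=parent), PhyloNode(id=-1, parent=parent)]
        parent.children = kids
        for c in kids:
            birth_time[id(c)] = now
        active[k:k + 1] = kids
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = now - birth_time[id(node)]
    counter = [0]

    def label_tips(node: PhyloNode) -> None:
        if not node.children:
            counter[0] += 1
            node.label = label_format.format(counter[0])
        for c in node.children:
            label_tips(c)

    label_tips(root)
    return PhyloTree(root)


def simulate_character(
    tree: PhyloTree,
    q_true: float,
    rng: Optional[np.random.Generator] = None,
    *,
    seed: Optional[int] = None,
) -> tuple[dict[str, int], dict[int, int]]:
    """Evolve one binary character forward along the tree.

    The root state is drawn from the flat (1/2, 1/2) prior; along each edge
    of length t the state switches with probability (1 - exp(-2 q t)) / 2.
    Returns (tip label -> state, internal node id -> true state).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    state: dict[int, int] = {}
    state[tree.root.id] = int(rng.integers(2))
    for node in tree.preorder():
        if node.is_root:
            continue
        t = 1.0 if node.length is None else node.length
        p_switch = transition_matrix(q_true, t)[0, 1]
        parent_state = state[node.parent.id]
        flip = rng.random() < p_switch
        state[node.id] = parent_state ^ int(flip)
    tips = {n.label: state[n.id] for n in tree.tips()}
    internal = {n.id: state[n.id] for n in tree.nodes if not n.is_tip}
    return tips, internal


def simulate_chem_profiles(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    truth: Optional[BinaryCharacterMatrix] = None,
    species: Optional[Sequence[str]] = None,
) -> tuple[list[ChemProfile], BinaryCharacterMatrix]:
    """Abundance tables with a known fertility-linked ground truth.

    For every species and compound class the truth matrix says whether the
    class carries a fertility signal there (supplied, or drawn uniformly).
    The class's designated compound is then overproduced ``fold_change``-fold
    in the fertile caste; all other compounds share the same base abundance
    in both castes.  ``fold_change = inf`` produces the qualitative regime:
    the compound is entirely absent from the non-fertile caste.  Per
    individual, every abundance is multiplied by lognormal noise
    exp(N(0, sigma^2)).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    classes = [c for c in COMPOUND_CLASSES if c in config.compound_roster]
    if species is None:
        if truth is not None:
            species = truth.species
        else:
            species = [f"sp{i:02d}" for i in range(1, config.n_tips + 1)]
    if truth is None:
        cells = rng.integers(2, size=(len(species), len(classes)))
        truth = BinaryCharacterMatrix.from_dict(
            {sp: {cl: int(cells[i, j]) for j, cl in enumerate(classes)}
             for i, sp in enumerate(species)},
            characters=classes,
        )

    compounds: list[str] = []
    linked_of_class: dict[str, str] = {}
    for cl in classes:
        roster = list(config.compound_roster[cl])
        linked_of_class[cl] = roster[0]
        compounds.extend(roster)

    profiles: list[ChemProfile] = []
    n_ind = config.n_individuals
    for i, sp in enumerate(species):
        sociality = "eusocial" if i % 2 == 0 else "solitary"
        fgroup, ngroup = (("queen", "worker") if sociality == "eusocial"
                          else ("mature_female", "virgin_female"))
        tables = {}
        for group, fertile in ((fgroup, True), (ngroup, False)):
            base = np.full((n_ind, len(compounds)), config.base_abundance)
            for j, compound in enumerate(compounds):
                for cl in classes:
                    if compound != linked_of_class[cl]:
                        continue
                    if truth.cell(sp, cl) != "1":
                        continue
                    if fertile:
                        if math.isfinite(config.fold_change):
                            base[:, j] *= config.fold_change
                    else:
                        if not math.isfinite(config.fold_change):
                            base[:, j] = 0.0
            noise = np.exp(rng.normal(0.0, config.sigma, size=base.shape))
            values = base * noise
            values[base == 0.0] = 0.0
            tables[group] = CasteProfile(
                species=sp,
                group=group,
                abundances=pd.DataFrame(
                    values,
                    index=[f"{sp}_{group}_{k + 1}" for k in range(n_ind)],
                    columns=compounds,
                ),
            )
        profiles.append(ChemProfile(species=sp, sociality=sociality,
                                    fertile=tables[fgroup],
                                    nonfertile=tables[ngroup]))
    return profiles, truth
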