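"""Code per-caste cuticular chemistry into a binary species x class matrix.

A compound counts as *fertility linked* in a species when it is overproduced
by the fertile caste — queens versus workers in eusocial species, mature
egg-laying females versus virgin females in solitary ones.  The difference
may be qualitative (present in the fertile caste, absent in the other) or
quantitative (a configurable abundance criterion).  Each species then gets a
presence/absence call for each of twelve broad biosynthetic compound
classes: a class is "present" when at least one of its member compounds is
fertility linked there.  Coding at the level of biosynthetic series, rather
than individual molecules, lets homologous signalling chemistry be tracked
across species even when chain lengths or exact isomers drift.

Literature species whose published coding is already binary bypass this
stage entirely: a pre-coded matrix can be read from TSV or NEXUS.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

__all__ = [
    "COMPOUND_CLASSES",
    "UNKNOWN_CLASS",
    "CompoundRecord",
    "CasteProfile",
    "ChemProfile",
    "FertilityCriterion",
    "BinaryCharacterMatrix",
    "classify_compound",
    "call_fertility_linked",
    "build_character_matrix",
    "read_profiles_tsv",
    "write_profiles_tsv",
]

#: The twelve biosynthetic classes used as binary characters, in report order.
COMPOUND_CLASSES = (
    "linear alkane",
    "branched alkane",
    "alkene",
    "alkadiene",
    "aldehyde",
    "alcohol",
    "fatty acid",
    "keto acid",
    "ester",
    "terpene",
    "terpene alcohol",
    "lactone",
)

UNKNOWN_CLASS = "unknown"

#: Name dictionary for compounds whose class is not recoverable from
#: systematic-name suffixes alone (trivial names, abbreviations).
NAME_DICTIONARY: dict[str, str] = {
    "9-oda": "keto acid",
    "9-oxo-decenoic acid": "keto acid",
    "9-oxo-2-decenoic acid": "keto acid",
    "(e)-9-oxodec-2-enoic acid": "keto acid",
    "9-hda": "fatty acid",
    "9-hydroxy-2-decenoic acid": "fatty acid",
    "geraniol": "terpene alcohol",
    "nerol": "terpene alcohol",
    "farnesol": "terpene alcohol",
    "linalool": "terpene alcohol",
    "citronellol": "terpene alcohol",
    "geranial": "terpene",
    "neral": "terpene",
    "citral": "terpene",
    "farnesene": "terpene",
    "limonene": "terpene",
    "myrcene": "terpene",
    "squalene": "terpene",
    "alpha-pinene": "terpene",
    "beta-ocimene": "terpene",
    "geranyl acetate": "ester",
    "hexadecanolide": "lactone",
    "gamma-dodecalactone": "lactone",
}

# terpene skeleton stems recognised in systematic-ish names
_TERPENE_STEMS = (
    "geran", "neryl", "farnes", "citronell", "limonen", "pinen",
    "myrcen", "squalen", "linalo", "caryophyll", "ocimen", "terpin",
)


@dataclass
class CompoundRecord:
    """A compound as named and/or structurally described.

    ``saturation`` is None, "ene" or "diene"; ``functional_group`` one of
    acid / keto-acid / ester / aldehyde / alcohol / lactone / terpene /
    terpene-alcohol / hydrocarbon.
    """

    name: str = ""
    chain_length: Optional[int] = None
    saturation: Optional[str] = None
    functional_group: Optional[str] = None
    methyl_branches: int = 0

    def __post_init__(self) -> None:
        if not self.name and self.functional_group is None:
            raise ValueError("compound record needs a name or a descriptor")
        if self.chain_length is not None and self.chain_length <= 0:
            raise ValueError("chain length must be positive")


def _classify_name(name: str) -> Optional[str]:
    n = name.strip().lower()
    if not n:
        return None
    if n in NAME_DICTIONARY:
        return NAME_DICTIONARY[n]
    if "lactone" in n or n.endswith("olide"):
        return "lactone"
    if "acid" in n:
        if "oxo" in n or "keto" in n:
            return "keto acid"
        if "ester" in n:  # e.g. "octadecenoic acid methyl ester"
            return "ester"
        return "fatty acid"
    if n.endswith("oate") or re.search(r"\b\w+yl \w+(an|en)?oate\b", n) or n.endswith("ate"):
        return "ester"
    if any(stem in n for stem in _TERPENE_STEMS):
        return "terpene alcohol" if n.endswith("ol") else "terpene"
    if n.endswith("al"):
        return "aldehyde"
    if n.endswith("ol"):
        return "alcohol"
    if "adien" in n:
        return "alkadiene"
    if re.search(r"[a-z]en[e]?\b", n) or n.endswith("ene"):
        return "alkene"
    if n.endswith("ane"):
        return "branched alkane" if "methyl" in n else "linear alkane"
    return None


def _classify_descriptor(rec: CompoundRecord) -> Optional[str]:
    fg = rec.functional_group
    if fg is None:
        return None
    # end-group chemistry takes priority over hydrocarbon features: an
    # unsaturated acid is a fatty acid, not an alkene
    table = {
        "acid": "fatty acid",
        "keto-acid": "keto acid",
        "ester": "ester",
        "aldehyde": "aldehyde",
        "alcohol": "alcohol",
        "lactone": "lactone",
        "terpene": "terpene",
        "terpene-alcohol": "terpene alcohol",
    }
    if fg in table:
        return table[fg]
    if fg == "hydrocarbon":
        # within hydrocarbons, unsaturation beats methyl branching:
        # a methyl-branched alkene is reported as an alkene
        if rec.saturation == "diene":
            return "alkadiene"
        if rec.saturation == "ene":
            return "alkene"
        if rec.methyl_branches > 0:
            return "branched alkane"
        return "linear alkane"
    return None


def classify_compound(record: CompoundRecord) -> str:
    """Assign a compound to one of the twelve biosynthetic classes.

    Name-based lookup (trivial-name dictionary, then systematic-name
    suffixes) is tried first; structural descriptors are the fallback.
    Unclassifiable compounds return ``"unknown"`` and are logged — they are
    surfaced, never silently dropped or guessed.
    """
    cls = _classify_name(record.name)
    if cls is None:
        cls = _classify_descriptor(record)
    if cls is None:
        logger.warning("could not classify compound %r; reporting 'unknown'",
                       record.name or record)
        return UNKNOWN_CLASS
    return cls


# -- profiles -----------------------------------------------------------------

FERTILE_GROUPS = {"queen", "mature_female"}
NONFERTILE_GROUPS = {"worker", "virgin_female"}
_GROUPS_BY_SOCIALITY = {
    "eusocial": ("queen", "worker"),
    "solitary": ("mature_female", "virgin_female"),
}


@dataclass
class CasteProfile:
    """Per-individual abundances for one caste/group of one species.

    ``abundances`` is a DataFrame with individuals as rows and compounds as
    columns; a compound not detected in an individual is 0.
    """

    species: str
    group: str
    abundances: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundances.shape[0] < 1:
            raise ValueError(
                f"{self.species}/{self.group}: at least one individual required"
            )
        if (self.abundances.values < 0).any():
            raise ValueError(f"{self.species}/{self.group}: negative abundance")

    @property
    def n_individuals(self) -> int:
        return self.abundances.shape[0]

    def values(self, compound: str) -> np.ndarray:
        if compound in self.abundances.columns:
            return self.abundances[compound].to_numpy(dtype=float)
        return np.zeros(self.n_individuals)


@dataclass
class ChemProfile:
    """Both caste tables of one species, ready for the overproduction call."""

    species: str
    sociality: str  # "eusocial" or "solitary"
    fertile: CasteProfile
    nonfertile: CasteProfile

    def __post_init__(self) -> None:
        if self.sociality not in _GROUPS_BY_SOCIALITY:
            raise ValueError(f"sociality must be eusocial or solitary, got {self.sociality!r}")
        expect_f, expect_n = _GROUPS_BY_SOCIALITY[self.sociality]
        if self.fertile.group != expect_f or self.nonfertile.group != expect_n:
            raise ValueError(
                f"{self.species}: groups ({self.fertile.group!r}, "
                f"{self.nonfertile.group!r}) inconsistent with {self.sociality} sociality"
            )

    @property
    def compounds(self) -> list[str]:
        cols = list(self.fertile.abundances.columns)
        cols += [c for c in self.nonfertile.abundances.columns if c not in cols]
        return cols


@dataclass(frozen=True)
class FertilityCriterion:
    """The configurable 'overproduced by the fertile caste' rule.

    Qualitative rule: detected in at least ``min_detect_frac`` of fertile
    individuals while absent from every non-fertile individual.  Quantitative
    rule: one-sided rank-sum test (fertile > non-fertile) significant at
    ``alpha`` AND observed fold-change at least ``min_fold``; the fold is the
    ratio of geometric means (abundance noise is multiplicative), falling
    back to arithmetic means when zeros are present.  Either rule suffices.
    The quantitative rule is a stand-in for study-specific statistics and is
    fully configurable.

    ``qualitative_only`` disables the quantitative rule; only with it can
    coding be exact (a significance test, by design, fires on a small
    fraction of null compounds).
    """

    alpha: float = 0.05
    min_fold: float = 2.0
    min_detect_frac: float = 0.5
    qualitative_only: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")


def call_fertility_linked(
    profile: ChemProfile,
    compound: str,
    criterion: FertilityCriterion = FertilityCriterion(),
) -> bool:
    """Is ``compound`` overproduced by the fertile caste of this species?

    Unit-free: multiplying all abundances by a positive constant does not
    change the call.  With a single individual in either caste only the
    qualitative rule applies (flagged with a warning).
    """
    f = profile.fertile.values(compound)
    n = profile.nonfertile.values(compound)
    if f.max(initial=0.0) == 0.0 and n.max(initial=0.0) == 0.0:
        warnings.warn(
            f"{profile.species}: compound {compound!r} absent from both castes",
            stacklevel=2,
        )
        return False

    detect_frac = float((f > 0).mean())
    qualitative = (n.max(initial=0.0) == 0.0
                   and detect_frac >= criterion.min_detect_frac)
    if qualitative:
        return True
    if criterion.qualitative_only:
        return False

    if len(f) < 2 or len(n) < 2:
        warnings.warn(
            f"{profile.species}/{compound}: single-individual caste, "
            "qualitative rule only",
            stacklevel=2,
        )
        return False

    if n.mean() == 0.0:
        # detected too sporadically in the fertile caste for the qualitative
        # rule, and no quantitative baseline to compare against
        return False
    if (f > 0).all() and (n > 0).all():
        fold = math.exp(np.log(f).mean() - np.log(n).mean())
    else:
        fold = f.mean() / n.mean()
    if fold < criterion.min_fold:
        return False
    stat = mannwhitneyu(f, n, alternative="greater")
    return bool(stat.pvalue < criterion.alpha)


# -- the binary matrix --------------------------------------------------------


class BinaryCharacterMatrix:
    """Species x compound-class presence/absence matrix (cells 0, 1 or '?')."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            dupes = sorted(set(frame.index[frame.index.duplicated()]))
            raise ValueError(f"duplicate species: {dupes}")
        frame = frame.astype(str)
        bad = ~frame.isin(["0", "1", "?"])
        if bad.values.any():
            where = [(sp, ch) for sp in frame.index for ch in frame.columns
                     if bad.loc[sp, ch]]
            raise ValueError(f"cells must be 0, 1 or '?'; offending: {where[:5]}")
        self._frame = frame

    @classmethod
    def from_dict(cls, rows: Mapping[str, Mapping[str, object]],
                  characters: Sequence[str] = COMPOUND_CLASSES) -> "BinaryCharacterMatrix":
        frame = pd.DataFrame.from_dict(
            {sp: {ch: str(v) for ch, v in row.items()} for sp, row in rows.items()},
            orient="index",
        ).reindex(columns=list(characters)).fillna("?")
        frame.index.name = "species"
        return cls(frame)

    @classmethod
    def empty(cls, characters: Sequence[str] = COMPOUND_CLASSES) -> "BinaryCharacterMatrix":
        frame = pd.DataFrame(columns=list(characters), dtype=str)
        frame.index.name = "species"
        return cls(frame)

    @property
    def species(self) -> list[str]:
        return list(self._frame.index)

    @property
    def characters(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def cell(self, species: str, character: str) -> str:
        return self._frame.loc[species, character]

    def column(self, character: str) -> dict[str, str]:
        """Tip-state mapping for one character, ready for the Mk model."""
        return {sp: self._frame.loc[sp, character] for sp in self._frame.index}

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def reorder(self, species: Sequence[str]) -> "BinaryCharacterMatrix":
        return BinaryCharacterMatrix(self._frame.loc[list(species)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryCharacterMatrix):
            return NotImplemented
        return self._frame.sort_index().equals(other._frame.sort_index())

    # -- I/O ------------------------------------------------------------------

    def to_tsv(self, path_or_buf=None):
        return self._frame.to_csv(path_or_buf, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "BinaryCharacterMatrix":
        frame = pd.read_csv(path_or_buf, sep="\t", index_col=0, dtype=str)
        return cls(frame)

    def to_nexus(self, path=None) -> str:
        import dendropy

        data = {sp: "".join(self._frame.loc[sp]) for sp in self._frame.index}
        mat = dendropy.StandardCharacterMatrix.from_dict(data)
        text = mat.as_string(schema="nexus")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_nexus(cls, src, characters: Sequence[str] = COMPOUND_CLASSES
                   ) -> "BinaryCharacterMatrix":
        """Read a STANDARD-datatype 0/1 NEXUS matrix.

        NEXUS stores no column names here, so columns are assigned the given
        character labels by position.
        """
        import dendropy

        if hasattr(src, "read"):
            mat = dendropy.StandardCharacterMatrix.get(file=src, schema="nexus")
        elif isinstance(src, str) and src.lstrip().startswith("#"):
            mat = dendropy.StandardCharacterMatrix.get(data=src, schema="nexus")
        else:
            mat = dendropy.StandardCharacterMatrix.get(path=src, schema="nexus")
        rows = {}
        for taxon in mat.taxon_namespace:
            symbols = [str(c.symbol) for c in mat[taxon]]
            if len(symbols) != len(characters):
                raise ValueError(
                    f"matrix has {len(symbols)} characters; expected {len(characters)}"
                )
            rows[taxon.label] = dict(zip(characters, symbols))
        return cls.from_dict(rows, characters)


def build_character_matrix(
    profiles: Sequence[ChemProfile],
    criterion: FertilityCriterion = FertilityCriterion(),
    *,
    characters: Sequence[str] = COMPOUND_CLASSES,
    classifier=None,
) -> BinaryCharacterMatrix:
    """Code one row per species: class present iff >= 1 member compound is
    fertility linked.  Classes of a profiled species with no qualifying
    compound are 0; a species with no measured compounds at all gets an
    all-'?' row (and a warning).  Compound order and profile order do not
    affect the result."""
    classify = classifier or (lambda name: classify_compound(CompoundRecord(name=name)))
    seen: set[str] = set()
    rows: dict[str, dict[str, str]] = {}
    for prof in profiles:
        if prof.species in seen:
            raise ValueError(f"duplicate species in profiles: {prof.species!r}")
        seen.add(prof.species)
        compounds = prof.compounds
        if not compounds:
            warnings.warn(f"{prof.species}: no compounds measured; all-'?' row",
                          stacklevel=2)
            rows[prof.species] = {ch: "?" for ch in characters}
            continue
        row = {ch: "0" for ch in characters}
        for compound in compounds:
            cls = classify(compound)
            if cls not in characters:
                continue  # unknowns surfaced by the classifier's log
            if row[cls] == "1":
                continue
            if call_fertility_linked(prof, compound, criterion):
                row[cls] = "1"
        rows[prof.species] = row
    if not rows:
        return BinaryCharacterMatrix.empty(characters)
    return BinaryCharacterMatrix.from_dict(rows, characters)


# -- long-format TSV I/O ------------------------------------------------------

_PROFILE_COLUMNS = ["species", "sociality", "group", "individual_id",
                    "compound", "abundance"]


def write_profiles_tsv(profiles: Sequence[ChemProfile], path_or_buf=None):
    """Long-format table: one row per (individual, compound) observation."""
    records = []
    for prof in profiles:
        for caste in (prof.fertile, prof.nonfertile):
            for ind in caste.abundances.index:
                for compound in caste.abundances.columns:
                    records.append({
                        "species": prof.species,
                        "sociality": prof.sociality,
                        "group": caste.group,
                        "individual_id": ind,
                        "compound": compound,
                        "abundance": caste.abundances.loc[ind, compound],
                    })
    frame = pd.DataFrame.from_records(records, columns=_PROFILE_COLUMNS)
    return frame.to_csv(path_or_buf, sep="\t", index=False, float_format="%.6g")


def read_profiles_tsv(path_or_buf) -> list[ChemProfile]:
    frame = pd.read_csv(path_or_buf, sep="\t")
    missing = [c for c in _PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"profile TSV missing columns: {missing}")
    profiles = []
    for species, sp_frame in frame.groupby("species", sort=True):
        socialities = sp_frame["sociality"].unique()
        if len(socialities) != 1:
            raise ValueError(f"{species}: inconsistent sociality labels")
        sociality = socialities[0]
        expect_f, expect_n = _GROUPS_BY_SOCIALITY[sociality]
        castes = {}
        for group, g_frame in sp_frame.groupby("group"):
            wide = g_frame.pivot_table(index="individual_id", columns="compound",
                                       values="abundance", fill_value=0.0,
                                       aggfunc="sum")
            castes[group] = CasteProfile(species=species, group=group,
                                         abundances=wide)
        if expect_f not in castes or expect_n not in castes:
            raise ValueError(
                f"{species}: expected groups {expect_f!r} and {expect_n!r}, "
                f"found {sorted(castes)}"
            )
        profiles.append(ChemProfile(species=species, sociality=sociality,
                                    fertile=castes[expect_f],
                                    nonfertile=castes[expect_n]))
    return profiles
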