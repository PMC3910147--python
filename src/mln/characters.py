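"""Presence/absence characters and wordlists.

Characters are binary families — gene families in genome mode, cognate sets in
language mode — scored per taxon as present (1), absent (0) or missing (?).
In language mode each character carries a concept label (the meaning slot),
and characters sharing a concept are synonymous competitors.

The missing convention matters: wordlists are meaning-list *samples*, not
exhaustive inventories.  A taxon with no word at all for a concept is coded
missing for every character of that concept (a sample gap); a taxon that
attests the concept with some other word is a genuine absence for the sets it
does not join.  Genome mode has no missing state by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tree import ReferenceTree

__all__ = [
    "PRESENT",
    "ABSENT",
    "MISSING",
    "Character",
    "CharacterMatrix",
    "Wordlist",
    "WordlistFormatError",
    "MatrixFormatError",
    "read_wordlist",
    "to_character_matrix",
    "read_matrix",
    "classify_detectability",
    "SINGLETON",
    "TREE_COMPATIBLE",
    "PATCHY",
]

PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1

SINGLETON = "singleton"
TREE_COMPATIBLE = "tree_compatible"
PATCHY = "patchy"


class WordlistFormatError(ValueError):
    pass


class MatrixFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Character:
    """One binary character family: a cognate set or gene family."""

    id: str
    concept: str | None = None


class CharacterMatrix:
    """Binary presence/absence matrix, characters x taxa.

    ``states`` holds ``PRESENT``/``ABSENT``/``MISSING`` as int8 with shape
    ``(n_characters, n_taxa)``.  Every character must be present in at least
    one taxon.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[Character],
        states: np.ndarray,
    ):
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.states = np.asarray(states, dtype=np.int8)
        self._validate()
        self._char_index = {c.id: i for i, c in enumerate(self.characters)}

    def _validate(self) -> None:
        n_chars, n_taxa = len(self.characters), len(self.taxa)
        if self.states.shape != (n_chars, n_taxa):
            raise MatrixFormatError(
                f"states shape {self.states.shape} != ({n_chars}, {n_taxa})"
            )
        if len(set(self.taxa)) != n_taxa:
            raise MatrixFormatError("duplicate taxa in matrix")
        ids = [c.id for c in self.characters]
        if len(set(ids)) != n_chars:
            raise MatrixFormatError("duplicate character identifiers")
        bad = ~np.isin(self.states, (PRESENT, ABSENT, MISSING))
        if bad.any():
            raise MatrixFormatError(
                f"undeclared state values: {sorted(set(self.states[bad].tolist()))}"
            )
        if n_chars and not (self.states == PRESENT).any(axis=1).all():
            dead = [
                self.characters[i].id
                for i in np.nonzero(~(self.states == PRESENT).any(axis=1))[0]
            ]
            raise MatrixFormatError(f"characters present in no taxon: {dead}")

    # -- accessors ------------------------------------------------------------

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def character_ids(self) -> list[str]:
        return [c.id for c in self.characters]

    def index_of(self, char_id: str) -> int:
        return self._char_index[char_id]

    def column(self, char_id: str) -> np.ndarray:
        """State vector over taxa for one character."""
        return self.states[self._char_index[char_id]]

    def present_taxa(self, char_id: str) -> frozenset[str]:
        col = self.column(char_id)
        return frozenset(t for t, s in zip(self.taxa, col) if s == PRESENT)

    def concepts(self) -> list[str]:
        """Distinct concept labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.characters:
            if c.concept is not None:
                seen.setdefault(c.concept)
        return list(seen)

    @property
    def has_concepts(self) -> bool:
        return all(c.concept is not None for c in self.characters)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, index=self.character_ids, columns=self.taxa)
        return df

    # -- serialization --------------------------------------------------------

    def write_csv(self, sep: str = ",") -> str:
        """Rows = characters, columns = taxa, cells 0/1/?; a CONCEPT column is
        appended when every character has one."""
        df = self.to_frame().astype(object)
        df[df == MISSING] = "?"
        if self.has_concepts and self.n_characters:
            df.insert(0, "CONCEPT", [c.concept for c in self.characters])
        buf = io.StringIO()
        df.to_csv(buf, sep=sep, index_label="ID")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CharacterMatrix {self.n_characters} characters x {self.n_taxa} taxa>"


def read_matrix(source: str, sep: str | None = None) -> CharacterMatrix:
    """Read a CSV/TSV binary matrix (rows = characters, columns = taxa, cells
    0/1/?; optional CONCEPT column).  ``source`` is a path or literal text;
    the delimiter is sniffed from the header when not given."""
    text = source
    if "\n" not in source and "\t" not in source and "," not in source:
        with open(source) as fh:
            text = fh.read()
    if sep is None:
        header = text.splitlines()[0] if text else ""
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
    concepts: list[str | None]
    if "CONCEPT" in df.columns:
        concepts = df.pop("CONCEPT").tolist()
    else:
        concepts = [None] * len(df)
    decode = {"0": ABSENT, "1": PRESENT, "?": MISSING}
    states = np.empty(df.shape, dtype=np.int8)
    for i, row in enumerate(df.itertuples(index=False)):
        for j, cell in enumerate(row):
            cell = str(cell).strip()
            if cell not in decode:
                raise MatrixFormatError(f"undeclared matrix symbol {cell!r}")
            states[i, j] = decode[cell]
    chars = [
        Character(id=str(cid), concept=con) for cid, con in zip(df.index, concepts)
    ]
    return CharacterMatrix(list(df.columns), chars, states)


# ---------------------------------------------------------------------------
# Wordlists
# ---------------------------------------------------------------------------

#: canonical column names; other spellings are resolved case-insensitively
_WL_REQUIRED = ("DOCULECT", "CONCEPT", "COGID")
_WL_OPTIONAL = ("ID", "FORM", "BORROWED")


class Wordlist:
    """A wordlist table: one row per word with taxon (doculect), concept,
    surface form and cognate-set identifier; optionally a per-word borrowing
    annotation (column BORROWED, values 0/1)."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        missing = [c for c in _WL_REQUIRED if c not in self.table.columns]
        if missing:
            raise WordlistFormatError(f"wordlist missing mandatory columns: {missing}")
        if "ID" not in self.table.columns:
            self.table.insert(0, "ID", [str(i + 1) for i in range(len(self.table))])
        dup = self.table.duplicated(subset=["DOCULECT", "ID"])
        if dup.any():
            pairs = self.table.loc[dup, ["DOCULECT", "ID"]].values.tolist()
            raise WordlistFormatError(f"duplicate (taxon, word id) rows: {pairs}")
        for col in _WL_REQUIRED:
            if self.table[col].isna().any() or (self.table[col] == "").any():
                raise WordlistFormatError(f"empty values in column {col}")

    @property
    def taxa(self) -> list[str]:
        """Doculects in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.table["DOCULECT"]:
            seen.setdefault(t)
        return list(seen)

    @property
    def cognate_sets(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["COGID"]:
            seen.setdefault(c)
        return list(seen)

    @property
    def has_borrowing_annotations(self) -> bool:
        return "BORROWED" in self.table.columns

    def borrowed_cognate_sets(self) -> frozenset[str]:
        """Cognate sets containing at least one word annotated as borrowed."""
        if not self.has_borrowing_annotations:
            return frozenset()
        mask = self.table["BORROWED"].astype(str).isin(("1", "True", "true"))
        return frozenset(self.table.loc[mask, "COGID"])

    def write_tsv(self) -> str:
        buf = io.StringIO()
        self.table.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Wordlist {len(self)} words, {len(self.taxa)} doculects, "
            f"{len(self.cognate_sets)} cognate sets>"
        )


def read_wordlist(source: str) -> Wordlist:
    """Read a tab-separated wordlist with a header row.

    Mandatory columns (matched case-insensitively): DOCULECT, CONCEPT, COGID.
    Optional: ID, FORM, BORROWED.  ``source`` is a path or literal TSV text.
    """
    text = source
    if "\n" not in source and "\t" not in source:
        with open(source) as fh:
            text = fh.read()
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    rename = {}
    known = set(_WL_REQUIRED) | set(_WL_OPTIONAL)
    for col in df.columns:
        canon = col.strip().upper()
        if canon in known:
            rename[col] = canon
    df = df.rename(columns=rename)
    return Wordlist(df)


def to_character_matrix(
    wordlist: Wordlist, taxa: Sequence[str] | None = None
) -> CharacterMatrix:
    """Convert a wordlist into a binary character matrix, one character per
    cognate set.

    A taxon is present for a set iff it has at least one word of that set.  A
    taxon with no word at all for a concept is coded missing for every
    character of that concept; a taxon listed in ``taxa`` but absent from the
    wordlist is all-missing.
    """
    wl_taxa = wordlist.taxa
    if taxa is None:
        taxa = wl_taxa
    else:
        extra = set(wl_taxa) - set(taxa)
        if extra:
            raise WordlistFormatError(
                f"wordlist contains taxa not in the requested taxon list: {sorted(extra)}"
            )
    taxa = list(taxa)
    tindex = {t: j for j, t in enumerate(taxa)}

    concept_of: dict[str, str] = {}
    for cogid, concept in zip(wordlist.table["COGID"], wordlist.table["CONCEPT"]):
        prev = concept_of.setdefault(cogid, concept)
        if prev != concept:
            raise WordlistFormatError(
                f"cognate set {cogid!r} spans concepts {prev!r} and {concept!r}"
            )

    cogids = wordlist.cognate_sets
    characters = [Character(id=c, concept=concept_of[c]) for c in cogids]
    cindex = {c: i for i, c in enumerate(cogids)}

    # which taxa attest which concepts at all (sample-gap detection)
    attested: dict[str, set[str]] = {t: set() for t in taxa}
    for t, con in zip(wordlist.table["DOCULECT"], wordlist.table["CONCEPT"]):
        attested[t].add(con)

    states = np.full((len(cogids), len(taxa)), ABSENT, dtype=np.int8)
    for i, char in enumerate(characters):
        for j, t in enumerate(taxa):
            if char.concept not in attested[t]:
                states[i, j] = MISSING
    for t, cog in zip(wordlist.table["DOCULECT"], wordlist.table["COGID"]):
        states[cindex[cog], tindex[t]] = PRESENT
    return CharacterMatrix(taxa, characters, states)


def classify_detectability(
    matrix: CharacterMatrix, char_id: str, tree: ReferenceTree
) -> str:
    """Classify a character's presence pattern on the reference tree.

    ``singleton``: present in exactly one taxon — a single origin on that
    terminal branch explains it whatever the tree looks like.
    ``tree_compatible``: the present set equals the full clade of one node —
    one gain, zero losses.  ``patchy``: anything else; only patchy characters
    can ever contribute lateral edges under a loss-penalizing selection.
    Missing taxa are ignored.
    """
    present = matrix.present_taxa(char_id)
    if not present:
        raise MatrixFormatError(f"character {char_id!r} is present in no taxon")
    if len(present) == 1:
        return SINGLETON
    for node in tree.preorder():
        if tree.clade(node) == present:
            return TREE_COMPATIBLE
    return PATCHY


def detectability_classes(
    matrix: CharacterMatrix, tree: ReferenceTree
) -> dict[str, str]:
    """Detectability class for every character in the matrix."""
    return {
        c: classify_detectability(matrix, c, tree) for c in matrix.character_ids
    }
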