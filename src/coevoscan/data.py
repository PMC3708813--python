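"""Trees, binary character matrices and organismal trait tables.

This module owns input parsing, validation and the preprocessing rules the
downstream screen relies on: zero-length branches are replaced by a small
epsilon (rate matrices cannot be evaluated along zero-time branches by the
fitting machinery's conventions), trees and matrices are pruned to their
shared taxa, characters without enough presence *and* absence variation are
dropped, and categorical trait annotations are recoded to presence/absence.

Trees are carried as :class:`dendropy.Tree` objects wrapped in
:class:`PhyloTree`; matrices are plain :class:`pandas.DataFrame` objects
(taxa as rows, characters as columns) wrapped in :class:`CharacterMatrix`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError

DEFAULT_EPSILON = 1e-5
DEFAULT_MIN_PRESENT = 5
DEFAULT_MIN_ABSENT = 5


@dataclass
class PhyloTree:
    """A rooted phylogeny with strictly positive branch lengths.

    Parameters
    ----------
    tree:
        The underlying dendropy tree. All non-root edges must carry a
        strictly positive length; leaf taxon labels must be unique.
    """

    tree: dendropy.Tree

    @property
    def taxon_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def validate(self) -> None:
        labels = self.taxon_labels
        if len(labels) < 3:
            raise InsufficientDataError(
                f"tree has {len(labels)} leaves; at least 3 are required"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length
            if length is None:
                raise FormatError("tree has a branch without a length")
            if length <= 0:
                raise ValidationError(f"non-positive branch length {length}")


@dataclass
class CharacterMatrix:
    """Binary presence/absence states, taxa × characters."""

    states: pd.DataFrame  # index: taxa, columns: character ids, values 0/1

    @property
    def taxa(self) -> list[str]:
        return list(self.states.index)

    @property
    def characters(self) -> list[str]:
        return list(self.states.columns)

    def validate(self) -> None:
        values = self.states.to_numpy()
        if pd.isna(values).any():
            raise ValidationError("character matrix contains missing cells")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary state {values[r, c]!r} at taxon "
                f"{self.states.index[r]!r}, character {self.states.columns[c]!r}"
            )
        if self.states.index.has_duplicates:
            raise ValidationError("duplicate taxon labels in matrix")
        if self.states.columns.has_duplicates:
            raise ValidationError("duplicate character ids in matrix")

    def column(self, character: str) -> np.ndarray:
        return self.states[character].to_numpy(dtype=np.int64)


@dataclass
class TraitTable:
    """Categorical organismal traits and their binary recodings.

    ``raw`` holds the annotation strings as read from file (missing cells are
    NaN); ``binary`` is filled by :func:`recode_traits` and uses the pandas
    nullable ``Int64`` dtype so missingness survives the 0/1 recoding.
    ``rules`` records, per recoded trait, a human-readable description of the
    rule that produced it.
    """

    raw: pd.DataFrame
    binary: pd.DataFrame | None = None
    rules: dict[str, str] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.raw.index)

    @property
    def trait_names(self) -> list[str]:
        if self.binary is not None:
            return list(self.binary.columns)
        return list(self.raw.columns)


def load_tree(newick_text: str, epsilon: float = DEFAULT_EPSILON) -> PhyloTree:
    """Parse a newick tree and replace zero-length branches with ``epsilon``.

    Branch lengths are required on every non-root edge; zero lengths are
    replaced by ``epsilon`` (default 1e-5) so that every transition matrix
    along the tree is well defined. Negative lengths are rejected.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length
        if length is None:
            raise FormatError("branch without a length in newick input")
        if length < 0:
            raise ValidationError(f"negative branch length {length}")
        if length == 0:
            node.edge.length = epsilon
    out = PhyloTree(tree)
    out.validate()
    return out


def load_matrix(tsv: str | io.TextIOBase) -> CharacterMatrix:
    """Read a taxa × characters TSV (first column = taxon label, header row =
    character ids, cells 0/1) into a :class:`CharacterMatrix`."""
    if isinstance(tsv, str):
        tsv = io.StringIO(tsv)
    try:
        df = pd.read_csv(tsv, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"could not parse matrix TSV: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    matrix = CharacterMatrix(df)
    matrix.validate()
    return matrix


def load_traits(tsv: str | io.TextIOBase) -> TraitTable:
    """Read a taxa × traits TSV of categorical annotations (blank = missing)."""
    if isinstance(tsv, str):
        tsv = io.StringIO(tsv)
    try:
        df = pd.read_csv(tsv, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"could not parse trait TSV: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    df = df.apply(lambda col: col.str.strip())
    return TraitTable(raw=df)


def align_tree_and_matrix(
    tree: PhyloTree, matrix: CharacterMatrix
) -> tuple[PhyloTree, CharacterMatrix]:
    """Prune tree and matrix to their shared taxa.

    The matrix rows are re-ordered to the pruned tree's leaf order. Raises
    :class:`InsufficientDataError` if fewer than 3 taxa are shared.
    """
    tree_taxa = set(tree.taxon_labels)
    shared = [t for t in matrix.taxa if t in tree_taxa]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} taxa shared between tree and matrix; need >=3"
        )
    pruned = PhyloTree(tree.tree.extract_tree_with_taxa_labels(shared))
    pruned.validate()
    sub = CharacterMatrix(matrix.states.loc[pruned.taxon_labels])
    return pruned, sub


def filter_characters(
    matrix: CharacterMatrix,
    min_present: int = DEFAULT_MIN_PRESENT,
    min_absent: int = DEFAULT_MIN_ABSENT,
) -> tuple[CharacterMatrix, list[str]]:
    """Drop characters with too little presence/absence variation.

    A character is retained iff it has at least ``min_present`` ones and at
    least ``min_absent`` zeros across the taxa (defaults 5 and 5: nearly
    invariant profiles carry no usable gain/loss signal). Returns the filtered
    matrix and the list of dropped character ids.
    """
    ones = matrix.states.sum(axis=0)
    zeros = len(matrix.taxa) - ones
    keep = (ones >= min_present) & (zeros >= min_absent)
    dropped = [c for c, k in keep.items() if not k]
    return CharacterMatrix(matrix.states.loc[:, keep]), dropped


# Default vocabulary for the four standard trait recodings. Token -> 0/1.
# NCBI-style annotations are lower-cased before lookup; the vocabulary is a
# parameter because upstream annotation tokenisation varies between sources.
DEFAULT_TRAIT_VOCAB: dict[str, dict[str, int]] = {
    "pathogenicity": {"pathogenic": 1, "nonpathogenic": 0, "non-pathogenic": 0},
    "thermophilicity": {
        "hyperthermophilic": 1,
        "thermophilic": 1,
        "mesophilic": 0,
        "psychrophilic": 0,
        "psychrotrophic": 0,
    },
    "aerobicity": {
        "anaerobic": 0,
        "aerobic": 1,
        "facultative": 1,
        "microaerophilic": 1,
    },
}

HABITAT_SEPARATOR = ","


def load_trait_vocab(text: str) -> dict[str, dict[str, int]]:
    """Parse a sidecar trait-vocabulary config (YAML mapping trait ->
    {token: 0/1}) as produced alongside a trait table."""
    import yaml

    raw = yaml.safe_load(text) or {}
    vocab: dict[str, dict[str, int]] = {}
    for trait, mapping in raw.items():
        if not isinstance(mapping, dict):
            raise ValidationError(
                f"vocabulary for trait {trait!r} must map tokens to 0/1"
            )
        for token, value in mapping.items():
            if value not in (0, 1):
                raise ValidationError(
                    f"vocabulary value for {trait!r}/{token!r} must be 0 or 1"
                )
        vocab[str(trait)] = {str(k): int(v) for k, v in mapping.items()}
    return vocab


def recode_traits(
    raw: TraitTable,
    vocab: dict[str, dict[str, int]] | None = None,
    habitat_trait: str = "habitat",
    multiple_habitat_name: str = "multiple_habitat",
) -> TraitTable:
    """Recode categorical traits to presence/absence.

    Standard rules: any pathogenicity annotation that is pathogenic toward
    something → 1; thermophilic or hyperthermophilic → 1; anaerobic → 0 and
    every other annotated oxygen requirement → 1. A ``habitat`` column listing
    comma-separated habitat categories is turned into a ``multiple_habitat``
    trait: 1 iff the organism inhabits more than one category. Unannotated
    cells stay missing; unknown tokens raise :class:`ValidationError`.
    """
    if vocab is None:
        vocab = DEFAULT_TRAIT_VOCAB
    out: dict[str, pd.Series] = {}
    rules: dict[str, str] = {}
    for trait in raw.raw.columns:
        col = raw.raw[trait]
        if trait == habitat_trait:
            def n_habitats(v):
                if pd.isna(v) or not str(v).strip():
                    return pd.NA
                return int(
                    len([h for h in str(v).split(HABITAT_SEPARATOR) if h.strip()]) > 1
                )

            out[multiple_habitat_name] = col.map(n_habitats).astype("Int64")
            rules[multiple_habitat_name] = (
                f"1 iff >1 {HABITAT_SEPARATOR!r}-separated habitat category"
            )
            continue
        if trait not in vocab:
            raise ValidationError(
                f"no recoding vocabulary for trait {trait!r}; "
                f"known traits: {sorted(vocab)} + {habitat_trait!r}"
            )
        mapping = {k.lower(): v for k, v in vocab[trait].items()}

        def recode_one(v, _mapping=mapping, _trait=trait):
            if pd.isna(v) or not str(v).strip():
                return pd.NA
            token = str(v).strip().lower()
            if token not in _mapping:
                raise ValidationError(
                    f"unknown category token {token!r} for trait {_trait!r}"
                )
            return _mapping[token]

        out[trait] = col.map(recode_one).astype("Int64")
        rules[trait] = "; ".join(f"{k}->{v}" for k, v in vocab[trait].items())
    binary = pd.DataFrame(out, index=raw.raw.index)
    return TraitTable(raw=raw.raw, binary=binary, rules=rules)


def prune_to_trait(
    tree: PhyloTree, traits: TraitTable, trait_name: str
) -> tuple[PhyloTree, np.ndarray]:
    """Restrict the tree to taxa annotated for one trait.

    Returns the pruned tree and the 0/1 trait states in the pruned tree's
    leaf order. Traits with fewer than 3 annotated taxa on the tree raise
    :class:`InsufficientDataError`.
    """
    if traits.binary is None:
        raise ValidationError("traits have not been recoded; call recode_traits first")
    if trait_name not in traits.binary.columns:
        raise ValidationError(f"unknown trait {trait_name!r}")
    col = traits.binary[trait_name]
    annotated = set(col.dropna().index) & set(tree.taxon_labels)
    if len(annotated) < 3:
        raise InsufficientDataError(
            f"trait {trait_name!r} has {len(annotated)} annotated taxa on the "
            "tree; need >=3"
        )
    pruned = PhyloTree(tree.tree.extract_tree_with_taxa_labels(sorted(annotated)))
    pruned.validate()
    states = col.loc[pruned.taxon_labels].to_numpy(dtype=np.int64)
    return pruned, states
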