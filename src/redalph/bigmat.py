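"""Binary co-membership matrices, alphabet comparison, and consensus matrices.

Every simplified alphabet maps to a 20x20 symmetric 0/1 *binary intra-group*
matrix: cell (i, j) is 1 iff residues i and j share a group. The diagonal is
uninformative (a residue always groups with itself) and is excluded from all
statistics; only the 380 off-diagonal cells count.

Two alphabets are compared by the fraction of the 380 informative cells on
which their binary matrices agree — 1 for identical partitions, 0 for a pair
sharing nothing. A collection is combined into a consensus similarity matrix
whose cell (i, j) is the fraction of input alphabets grouping i with j;
its complement (1 - s) is the consensus distance matrix that drives the
dendrograms. Counts are kept as exact integers and divided only at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet_io import (
    AMINO_ACIDS,
    AlphabetCollection,
    SimplifiedAlphabet,
    WITHIN_PROTEIN_CATEGORIES,
)

#: Number of informative (off-diagonal) cells of a 20x20 matrix.
N_INFORMATIVE: int = 20 * 20 - 20  # = 380

_OFFDIAG = ~np.eye(20, dtype=bool)


@dataclass(frozen=True)
class BIGMatrix:
    """Binary intra-group matrix of one alphabet (20x20, diagonal stored 1)."""

    cells: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        c = self.cells
        if c.shape != (20, 20):
            raise ValueError(f"expected 20x20, got {c.shape}")
        if not np.array_equal(c, c.T):
            raise ValueError("binary intra-group matrix must be symmetric")
        if not np.isin(c, (0, 1)).all():
            raise ValueError("cells must be 0/1")


@dataclass(frozen=True)
class AlphabetSimilarityMatrix:
    """All-against-all alphabet similarity (n x n, diagonal 1)."""

    values: np.ndarray
    ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class ConsensusSimilarityMatrix:
    """Fraction of source alphabets grouping each residue pair (diagonal 1)."""

    values: np.ndarray
    n_sources: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
        )


@dataclass(frozen=True)
class AminoAcidDistanceMatrix:
    """Complement (1 - similarity) of a consensus matrix (diagonal 0)."""

    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
        )


def build_big(alphabet: SimplifiedAlphabet) -> BIGMatrix:
    """Binary intra-group matrix: cell (i, j) = 1 iff i and j share a group."""
    lab = alphabet.labels()
    cells = (lab[:, None] == lab[None, :]).astype(np.int64)
    return BIGMatrix(cells=cells, source_id=alphabet.id)


def compare_alphabets(
    a: BIGMatrix | SimplifiedAlphabet, b: BIGMatrix | SimplifiedAlphabet
) -> float:
    """Fraction of the 380 informative cells on which two alphabets agree."""
    ma = a if isinstance(a, BIGMatrix) else build_big(a)
    mb = b if isinstance(b, BIGMatrix) else build_big(b)
    matches = int((ma.cells[_OFFDIAG] == mb.cells[_OFFDIAG]).sum())
    return matches / N_INFORMATIVE


def build_similarity_matrix(collection: AlphabetCollection) -> AlphabetSimilarityMatrix:
    """All-against-all :func:`compare_alphabets` over a collection."""
    if len(collection) < 2:
        raise ValueError("need at least 2 alphabets to compare")
    bigs = [build_big(a).cells[_OFFDIAG] for a in collection]
    n = len(bigs)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = int((bigs[i] == bigs[j]).sum()) / N_INFORMATIVE
            values[i, j] = values[j, i] = s
    return AlphabetSimilarityMatrix(values=values, ids=tuple(collection.ids))


def build_consensus(collection: AlphabetCollection) -> ConsensusSimilarityMatrix:
    """Cellwise vote fraction: how many alphabets group each residue pair."""
    counts = np.zeros((20, 20), dtype=np.int64)
    for a in collection:
        counts += build_big(a).cells
    values = counts / len(collection)
    np.fill_diagonal(values, 1.0)
    return ConsensusSimilarityMatrix(values=values, n_sources=len(collection))


def similarity_to_distance(m: ConsensusSimilarityMatrix) -> AminoAcidDistanceMatrix:
    """Map similarity s -> distance 1 - s; diagonal stored 0."""
    values = 1.0 - m.values
    np.fill_diagonal(values, 0.0)
    return AminoAcidDistanceMatrix(values=values)


def category_consensus_distances(
    collection: AlphabetCollection,
) -> tuple[AminoAcidDistanceMatrix, AminoAcidDistanceMatrix]:
    """(within-protein, chemistry) consensus distance matrices.

    Splits the collection into alphabets derived from residues within
    protein sequences/structures versus those derived from the
    physico-chemistry of individual amino acids, and returns the two
    category consensus matrices complemented to distances.
    """
    within = collection.by_category(*WITHIN_PROTEIN_CATEGORIES)
    chem = collection.by_category("chemistry")
    return (
        similarity_to_distance(build_consensus(within)),
        similarity_to_distance(build_consensus(chem)),
    )


# ---------------------------------------------------------------------------
# TSV round-trip for labeled matrices (4-decimal rendering)


def write_matrix_tsv(frame_like, path) -> None:
    """Write a labeled matrix as TSV with 4-decimal cells."""
    df = frame_like if isinstance(frame_like, pd.DataFrame) else frame_like.to_frame()
    df.to_csv(path, sep="\t", float_format="%.4f")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
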