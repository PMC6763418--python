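"""Parse, validate, generate and serialize simplified amino-acid alphabets.

A *simplified alphabet* is a partition of the 20 standard amino acids
(one-letter codes) into groups of mutually similar residues. The canonical
residue order ``ACDEFGHIKLMNPQRSTVWY`` indexes every matrix in this package:
row/column ``i`` always refers to letter ``i`` of that string.

File dialect: one alphabet per line, four tab-separated columns
``id``, ``name``, ``category``, ``groups``; the groups column is
comma-delimited strings of uppercase letters, e.g.
``GAVLIMC,FWY,ST,DE,NQ,KRH,P``. Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

#: Canonical residue order shared by every matrix row/column in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Derivation categories. The first five follow the standard split of the
#: reduced-alphabet literature (how each grouping was derived); ``other``
#: is an explicit escape hatch, unknown strings are rejected.
CATEGORIES: frozenset[str] = frozenset(
    {
        "chemistry",
        "sequence_alignment",
        "structure_alignment",
        "protein_blocks",
        "contact_potentials",
        "other",
    }
)

#: Categories counted as "within-protein" derivations, i.e. everything that
#: analyses residues in the context of protein sequences/structures rather
#: than the physico-chemistry of the free amino acid.
WITHIN_PROTEIN_CATEGORIES: frozenset[str] = frozenset(
    {"sequence_alignment", "structure_alignment", "protein_blocks", "contact_potentials"}
)


class AlphabetError(ValueError):
    """Malformed alphabet record or collection."""


class PartitionViolation(AlphabetError):
    """The groups do not form a partition of the 20 standard residues."""


class CategoryError(AlphabetError):
    """Unknown derivation-category token."""


@dataclass(frozen=True)
class SimplifiedAlphabet:
    """A named partition of the 20 amino acids into similarity groups.

    Group identity is a set-of-sets: letter order inside a group and the
    order of the groups carry no meaning (order is preserved for display).
    """

    id: str
    name: str
    category: str
    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CategoryError(
                f"unknown category {self.category!r}; expected one of "
                f"{sorted(CATEGORIES)}"
            )
        validate_partition(self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, letter: str) -> int:
        """Index of the group containing ``letter``."""
        for i, g in enumerate(self.groups):
            if letter in g:
                return i
        raise KeyError(letter)

    def labels(self) -> np.ndarray:
        """Group label per residue in canonical order (length 20)."""
        lab = np.empty(20, dtype=np.int64)
        for i, g in enumerate(self.groups):
            for a in g:
                lab[AA_INDEX[a]] = i
        return lab

    def same_partition(self, other: "SimplifiedAlphabet") -> bool:
        return frozenset(self.groups) == frozenset(other.groups)

    def groups_string(self) -> str:
        """Comma-delimited groups, letters in canonical order within a group."""
        return ",".join(
            "".join(sorted(g, key=AA_INDEX.get)) for g in self.groups
        )

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.id}[{self.n_groups}]: {self.groups_string()}"


def validate_partition(groups: tuple[frozenset[str], ...]) -> None:
    """Raise :class:`PartitionViolation` unless *groups* partition the 20 residues."""
    if not groups or any(len(g) == 0 for g in groups):
        raise PartitionViolation("empty group or empty partition")
    seen: list[str] = []
    for g in groups:
        seen.extend(g)
    unknown = sorted(set(seen) - set(AMINO_ACIDS))
    if unknown:
        raise PartitionViolation(f"unknown letters: {''.join(unknown)}")
    dup = sorted({a for a in seen if seen.count(a) > 1})
    if dup:
        raise PartitionViolation(f"letters in more than one group: {''.join(dup)}")
    missing = sorted(set(AMINO_ACIDS) - set(seen))
    if missing:
        raise PartitionViolation(f"missing letters: {''.join(missing)}")


@dataclass
class AlphabetCollection:
    """Ordered collection of simplified alphabets with unique ids."""

    alphabets: list[SimplifiedAlphabet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.alphabets:
            raise AlphabetError("empty collection")
        ids = [a.id for a in self.alphabets]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise AlphabetError(f"duplicate alphabet ids: {dups}")

    def __len__(self) -> int:
        return len(self.alphabets)

    def __iter__(self):
        return iter(self.alphabets)

    def __getitem__(self, key: int | str) -> SimplifiedAlphabet:
        if isinstance(key, str):
            for a in self.alphabets:
                if a.id == key:
                    return a
            raise KeyError(key)
        return self.alphabets[key]

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.alphabets]

    def subset(self, predicate) -> "AlphabetCollection":
        """New collection of the alphabets for which ``predicate(a)`` is true."""
        return AlphabetCollection([a for a in self.alphabets if predicate(a)])

    def by_category(self, *categories: str) -> "AlphabetCollection":
        cats = set(categories)
        unknown = cats - CATEGORIES
        if unknown:
            raise CategoryError(f"unknown categories: {sorted(unknown)}")
        return self.subset(lambda a: a.category in cats)

    def drop(self, alphabet_id: str) -> "AlphabetCollection":
        """Leave-one-out copy without ``alphabet_id`` (jack-knife helper)."""
        if alphabet_id not in self.ids:
            raise KeyError(alphabet_id)
        return AlphabetCollection([a for a in self.alphabets if a.id != alphabet_id])


# ---------------------------------------------------------------------------
# parsing / serialization


def parse_alphabet(record: str) -> SimplifiedAlphabet:
    """Parse one TSV record ``id<TAB>name<TAB>category<TAB>groups``."""
    parts = record.rstrip("\n").split("\t")
    if len(parts) != 4:
        raise AlphabetError(
            f"expected 4 tab-separated fields (id, name, category, groups), "
            f"got {len(parts)}: {record!r}"
        )
    aid, name, category, groups_field = (p.strip() for p in parts)
    if not aid:
        raise AlphabetError("empty alphabet id")
    tokens = [tok for tok in groups_field.split(",") if tok != ""]
    # detect textual duplicates before frozenset collapses repeats like "AA"
    raw = [ch for tok in tokens for ch in tok]
    dup = sorted({ch for ch in raw if raw.count(ch) > 1})
    if dup:
        raise PartitionViolation(f"letters in more than one group: {''.join(dup)}")
    groups = tuple(frozenset(tok) for tok in tokens)
    return SimplifiedAlphabet(id=aid, name=name, category=category, groups=groups)


def serialize_alphabet(a: SimplifiedAlphabet) -> str:
    return "\t".join([a.id, a.name, a.category, a.groups_string()])


def load_collection(source) -> AlphabetCollection:
    """Load a collection from a path or readable text handle.

    One record per line; ``#`` lines and blank lines are skipped; file order
    is preserved.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            return load_collection(fh)
    alphabets = []
    for lineno, line in enumerate(source, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            alphabets.append(parse_alphabet(line))
        except AlphabetError as exc:
            raise type(exc)(f"line {lineno}: {exc}") from None
    return AlphabetCollection(alphabets)


def dump_collection(collection: AlphabetCollection, dest) -> None:
    """Write a collection in the same TSV dialect ``load_collection`` reads."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w", encoding="utf-8") as fh:
            dump_collection(collection, fh)
        return
    dest.write("# id\tname\tcategory\tgroups\n")
    for a in collection:
        dest.write(serialize_alphabet(a) + "\n")


def loads_collection(text: str) -> AlphabetCollection:
    return load_collection(io.StringIO(text))


# ---------------------------------------------------------------------------
# generators


from functools import lru_cache


@lru_cache(maxsize=None)
def _stirling2(n: int, k: int) -> int:
    """Stirling numbers of the second kind (partitions of n into k blocks)."""
    if k in (0, n):
        return int(n == k)
    if k > n or k < 0:
        return 0
    return k * _stirling2(n - 1, k) + _stirling2(n - 1, k - 1)


def generate_random_alphabet(
    seed: int, n_groups: int, *, aid: str | None = None
) -> SimplifiedAlphabet:
    """Seeded uniform random partition of the 20 residues into exactly
    *n_groups* non-empty groups.

    Distributionally this equals drawing uniform group labels per letter and
    redrawing until all labels occur (uniform surjective labelings induce
    the uniform distribution over k-block partitions); it is sampled exactly
    with Stirling-number weights so the extreme sizes (19, 20 groups) do not
    require astronomically many redraws. Deterministic for a fixed seed.
    """
    if not 1 <= n_groups <= 20:
        raise AlphabetError(f"n_groups must be in 1..20, got {n_groups}")
    rng = np.random.default_rng(seed)
    # top-down decisions: element m (m = 20..1) either opens its own block
    # (weight S(m-1, k-1)) or joins a block of a k-block partition of the
    # remaining m-1 elements (weight k * S(m-1, k))
    decisions: list[bool] = []  # True = singleton/new block
    m, k = 20, n_groups
    while m > 0:
        if k == m:
            decisions.append(True)
            m, k = m - 1, k - 1
        elif k == 1:
            decisions.append(False)
            m -= 1
        else:
            p_new = _stirling2(m - 1, k - 1) / (
                _stirling2(m - 1, k - 1) + k * _stirling2(m - 1, k)
            )
            if rng.random() < p_new:
                decisions.append(True)
                m, k = m - 1, k - 1
            else:
                decisions.append(False)
                m -= 1
    # assemble bottom-up: element 1 first
    blocks: list[list[int]] = []
    for elem, opens_block in zip(range(20), reversed(decisions)):
        if opens_block or not blocks:
            blocks.append([elem])
        else:
            blocks[int(rng.integers(len(blocks)))].append(elem)
    groups = tuple(
        frozenset(AMINO_ACIDS[i] for i in blk) for blk in blocks
    )
    return SimplifiedAlphabet(
        id=aid or f"rand_s{seed}_k{n_groups}",
        name=f"random partition (seed={seed})",
        category="other",
        groups=groups,
    )


def generate_planted_collection(
    base: SimplifiedAlphabet, n: int, noise: float, seed: int
) -> AlphabetCollection:
    """Noisy copies of *base*: a planted-partition test harness.

    Each of the *n* alphabets starts as a copy of *base*; every letter is
    independently reassigned to a uniformly chosen one of the base's groups
    with probability *noise* (so ``noise=0`` reproduces *base* exactly and
    ``noise=1`` assigns labels independently uniformly). Empty groups that
    result from reassignment are dropped. Deterministic for a fixed seed.
    """
    if not 0.0 <= noise <= 1.0:
        raise AlphabetError(f"noise must be in [0, 1], got {noise}")
    if n < 1:
        raise AlphabetError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    k = base.n_groups
    base_labels = base.labels()
    out = []
    for j in range(n):
        labels = base_labels.copy()
        flip = rng.random(20) < noise
        labels[flip] = rng.integers(0, k, size=int(flip.sum()))
        groups = tuple(
            frozenset(AMINO_ACIDS[i] for i in np.flatnonzero(labels == g))
            for g in range(k)
            if np.any(labels == g)
        )
        out.append(
            SimplifiedAlphabet(
                id=f"{base.id}_planted{j}",
                name=f"planted copy {j} of {base.id} (noise={noise})",
                category=base.category,
                groups=groups,
            )
        )
    return AlphabetCollection(out)
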