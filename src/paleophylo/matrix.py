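"""Character matrices, mean character distances, and pattern accounting.

The central container is :class:`DataMatrix`: a taxa x characters table
whose cells are *sets* of states, which uniformly represents categorical
morphology (multistate symbols, polymorphisms like ``{12}``), nucleotide
data (IUPAC ambiguity codes), and missing entries.  Internally each cell is
a bitmask over the character's alphabet plus a ``scored`` flag: a missing
cell carries the full alphabet mask (its likelihood/parsimony semantics)
with ``scored = False`` (its distance/pattern semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Character",
    "DataMatrix",
    "DistanceMatrix",
    "PartitionScheme",
    "mean_distance_matrix",
    "compress_patterns",
    "pattern_share",
    "NUCLEOTIDE_SYMBOLS",
    "IUPAC",
]

NUCLEOTIDE_SYMBOLS = ("A", "C", "G", "T")

#: IUPAC ambiguity codes as sets of fundamental nucleotides. ``N`` (and the
#: full-set codes' degenerate relatives ``X``) convey no information and are
#: handled as missing by the readers.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"), "X": frozenset("ACGT"),
}


@dataclass(frozen=True)
class Character:
    """One column's descriptor: its name, alphabet and broad type."""

    name: str
    symbols: tuple[str, ...] = ("0", "1")
    kind: str = "categorical"  # "categorical" | "nucleotide"

    def __post_init__(self):
        if len(self.symbols) < 1:
            raise ValueError(f"character {self.name!r}: empty alphabet")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"character {self.name!r}: duplicate symbols")

    @property
    def n_states(self) -> int:
        return len(self.symbols)

    @property
    def full_mask(self) -> int:
        return (1 << len(self.symbols)) - 1

    def encode(self, states: Iterable[str]) -> int:
        mask = 0
        for s in states:
            try:
                mask |= 1 << self.symbols.index(s)
            except ValueError:
                raise ValueError(
                    f"state {s!r} not in alphabet of character {self.name!r}"
                ) from None
        return mask

    def decode(self, mask: int) -> frozenset[str]:
        return frozenset(
            s for i, s in enumerate(self.symbols) if mask >> i & 1
        )


class DataMatrix:
    """Taxa x characters table of state sets.

    Parameters
    ----------
    taxa : sequence of str
        Unique row labels.
    characters : sequence of Character
        Column descriptors (alphabet per column).
    cells : sequence of rows
        Each row a sequence of cells; a cell is ``None`` (missing) or an
        iterable of state symbols (singleton = fixed state, larger =
        polymorphic/ambiguous).
    weights : array-like, optional
        Non-negative per-character weights (default all 1).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[Character],
        cells: Sequence[Sequence[Iterable[str] | None]],
        weights: Sequence[float] | None = None,
    ):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise ValueError(f"duplicate taxon labels: {sorted(dupes)}")
        self.characters = list(characters)
        n, k = len(self.taxa), len(self.characters)
        self.masks = np.zeros((n, k), dtype=np.int64)
        self.scored = np.ones((n, k), dtype=bool)
        for i, row in enumerate(cells):
            if len(row) != k:
                raise ValueError(
                    f"row {self.taxa[i]!r} has {len(row)} cells, expected {k}"
                )
            for j, cell in enumerate(row):
                char = self.characters[j]
                if cell is None:
                    self.masks[i, j] = char.full_mask
                    self.scored[i, j] = False
                else:
                    mask = char.encode(cell)
                    if mask == 0:
                        raise ValueError(
                            f"empty state set at ({self.taxa[i]!r}, "
                            f"{char.name!r})"
                        )
                    self.masks[i, j] = mask
        if weights is None:
            self.weights = np.ones(k)
        else:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != (k,) or (self.weights < 0).any():
                raise ValueError("weights must be non-negative, one per character")

    # ------------------------------------------------------------ basics
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_taxa, self.n_characters)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"taxon {label!r} not in matrix") from None

    def cell(self, taxon: int | str, char: int) -> frozenset[str] | None:
        """The state set at a cell, or ``None`` if missing."""
        i = taxon if isinstance(taxon, int) else self.taxon_index(taxon)
        if not self.scored[i, char]:
            return None
        return self.characters[char].decode(int(self.masks[i, char]))

    def row_cells(self, taxon: int | str) -> list[frozenset[str] | None]:
        i = taxon if isinstance(taxon, int) else self.taxon_index(taxon)
        return [self.cell(i, j) for j in range(self.n_characters)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.masks, other.masks)
            and np.array_equal(self.scored, other.scored)
            and np.allclose(self.weights, other.weights)
        )

    # identity hash: likelihood workspaces cache per matrix *object*; the
    # analysis code treats matrices as immutable once handed to it
    def __hash__(self) -> int:
        return id(self)

    # ---------------------------------------------------------- slicing
    def subset_taxa(self, labels: Sequence[str]) -> "DataMatrix":
        idx = [self.taxon_index(t) for t in labels]
        out = DataMatrix.__new__(DataMatrix)
        out.taxa = list(labels)
        out.characters = list(self.characters)
        out.masks = self.masks[idx].copy()
        out.scored = self.scored[idx].copy()
        out.weights = self.weights.copy()
        return out

    def subset_columns(self, columns: Sequence[int]) -> "DataMatrix":
        cols = np.asarray(columns, dtype=int)
        out = DataMatrix.__new__(DataMatrix)
        out.taxa = list(self.taxa)
        out.characters = [self.characters[j] for j in cols]
        out.masks = self.masks[:, cols].copy()
        out.scored = self.scored[:, cols].copy()
        out.weights = self.weights[cols].copy()
        return out

    def drop_taxa(self, labels: Sequence[str]) -> "DataMatrix":
        gone = set(labels)
        keep = [t for t in self.taxa if t not in gone]
        return self.subset_taxa(keep)

    def with_weights(self, weights: Sequence[float]) -> "DataMatrix":
        out = self.subset_taxa(self.taxa)
        w = np.asarray(weights, dtype=float)
        if w.shape != (self.n_characters,) or (w < 0).any():
            raise ValueError("weights must be non-negative, one per character")
        out.weights = w
        return out

    def add_row(
        self, label: str, cells: Sequence[Iterable[str] | None]
    ) -> "DataMatrix":
        if label in self.taxa:
            raise ValueError(f"taxon {label!r} already present")
        if len(cells) != self.n_characters:
            raise ValueError("row length mismatch")
        extra = DataMatrix([label], self.characters, [cells])
        out = DataMatrix.__new__(DataMatrix)
        out.taxa = self.taxa + [label]
        out.characters = list(self.characters)
        out.masks = np.vstack([self.masks, extra.masks])
        out.scored = np.vstack([self.scored, extra.scored])
        out.weights = self.weights.copy()
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<DataMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-site counts.

    ``d[i, j]`` is NaN where no character is scored in both taxa; such
    pairs are flagged in :attr:`undefined_pairs`.
    """

    def __init__(
        self,
        labels: Sequence[str],
        d: np.ndarray,
        comparable: np.ndarray | None = None,
    ):
        self.labels = list(labels)
        self.d = np.asarray(d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        finite = np.isfinite(self.d)
        if not np.allclose(self.d[finite & finite.T], self.d.T[finite & finite.T]):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if (self.d[finite] < 0).any():
            raise ValueError("negative distances")
        self.comparable = (
            np.asarray(comparable, dtype=int)
            if comparable is not None
            else np.full((n, n), -1, dtype=int)
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if not np.isfinite(self.d[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def permuted(self, order: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(t) for t in order]
        return DistanceMatrix(
            order, self.d[np.ix_(idx, idx)], self.comparable[np.ix_(idx, idx)]
        )


@dataclass
class PartitionScheme:
    """Named, pairwise-disjoint column sets; 0-based indices internally.

    ``flags`` carries free-form per-partition annotations, e.g.
    ``{"rbcL": "coding", "trnL-trnF": "spacer"}``.
    """

    partitions: dict[str, np.ndarray]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[int] = set()
        clean = {}
        for name, cols in self.partitions.items():
            arr = np.asarray(cols, dtype=int)
            cols_set = set(arr.tolist())
            if cols_set & seen:
                overlap = sorted(cols_set & seen)[:5]
                raise ValueError(
                    f"partition {name!r} overlaps earlier partitions "
                    f"(columns {overlap}...)"
                )
            seen |= cols_set
            clean[name] = arr
        self.partitions = clean

    @property
    def names(self) -> list[str]:
        return list(self.partitions)

    def columns(self, names: Iterable[str]) -> np.ndarray:
        out: list[np.ndarray] = []
        for name in names:
            if name not in self.partitions:
                raise KeyError(f"unknown partition {name!r}")
            out.append(self.partitions[name])
        if not out:
            return np.array([], dtype=int)
        return np.sort(np.concatenate(out))

    def all_columns(self) -> np.ndarray:
        return self.columns(self.names)

    def __len__(self) -> int:
        return len(self.partitions)


# ---------------------------------------------------------------------------
# operations


def mean_distance_matrix(m: DataMatrix) -> DistanceMatrix:
    """Mean character distance: disjoint-state mismatches over pairwise
    shared scored characters.

    A pair of cells *matches* when their state sets overlap, so a
    polymorphic ``{0,1}`` against a fixed ``1`` scores as a match; the
    mismatch rule is strict set disjointness.  Missing data are handled by
    pairwise deletion, and pairs with no shared scored characters get NaN.
    """
    if m.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    n = m.n_taxa
    d = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=int)
    empty_rows = [t for i, t in enumerate(m.taxa) if not m.scored[i].any()]
    if empty_rows:
        warnings.warn(
            f"taxa with no scored characters: {empty_rows}; their distances "
            "are undefined",
            stacklevel=2,
        )
    for i in range(n):
        for j in range(i + 1, n):
            both = m.scored[i] & m.scored[j]
            nc = int(both.sum())
            comparable[i, j] = comparable[j, i] = nc
            if nc == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            disjoint = (m.masks[i] & m.masks[j]) == 0
            mism = int((disjoint & both).sum())
            d[i, j] = d[j, i] = mism / nc
    return DistanceMatrix(m.taxa, d, comparable)


def _pattern_keys(m: DataMatrix, columns: Sequence[int] | None = None):
    """Hashable per-column keys: two columns share a pattern iff their full
    taxon-state vectors (including missingness) are identical."""
    cols = range(m.n_characters) if columns is None else columns
    keys = []
    for j in cols:
        keys.append(
            (m.masks[:, j].tobytes(), m.scored[:, j].tobytes())
        )
    return keys


def compress_patterns(
    m: DataMatrix,
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Deduplicate identical columns.

    Returns ``(representatives, multiplicities, inverse)`` where
    ``representatives`` are column indices of the first occurrence of each
    distinct pattern, ``multiplicities`` their column counts (summing to
    the total number of columns), and ``inverse`` maps every column to its
    pattern index.
    """
    keys = _pattern_keys(m)
    first: dict = {}
    reps: list[int] = []
    counts: list[int] = []
    inverse = np.zeros(m.n_characters, dtype=int)
    for j, key in enumerate(keys):
        if key in first:
            p = first[key]
            counts[p] += 1
        else:
            p = len(reps)
            first[key] = p
            reps.append(j)
            counts.append(1)
        inverse[j] = p
    return reps, np.asarray(counts), inverse


def pattern_share(
    m: DataMatrix, scheme: PartitionScheme, subset: Iterable[str]
) -> float:
    """Percentage of the matrix's distinct column patterns found within the
    named partitions.

    Patterns are defined on the concatenated matrix, so a pattern occurring
    both inside and outside the subset counts toward the subset.
    """
    subset = list(subset)
    if not subset:
        return 0.0
    all_keys = set(_pattern_keys(m))
    sub_cols = scheme.columns(subset)
    sub_keys = set(_pattern_keys(m, sub_cols.tolist()))
    return 100.0 * len(sub_keys) / len(all_keys)
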