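"""Readers and writers for the formats the pipeline touches.

Formats: NEXUS character blocks (multistate symbols, ``?`` missing, ``-``
gap, ``{..}``/``(..)`` polymorphisms, interleaving), relaxed PHYLIP and
FASTA alignments, RAxML-style partition files, newick / NEXUS tree files
(via dendropy), and the splits-NEXUS block understood by splits-graph
viewers such as SplitsTree.

All readers raise :class:`ParseError` with a located message on malformed
input; every reader/writer pair round-trips losslessly (property-tested).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

from .matrix import (
    IUPAC,
    NUCLEOTIDE_SYMBOLS,
    Character,
    DataMatrix,
    PartitionScheme,
)
from .trees import Tree, TreeSample

__all__ = [
    "FormatDialect",
    "ParseError",
    "read_character_matrix",
    "write_character_matrix",
    "read_alignment",
    "write_alignment",
    "read_partition_scheme",
    "read_trees",
    "write_trees",
    "read_splits_nexus",
    "write_splits_nexus",
]

_KNOWN_FORMATS = {
    "nexus-characters",
    "nexus-trees",
    "newick",
    "relaxed-phylip",
    "fasta",
    "raxml-partitions",
    "splits-nexus",
}


class ParseError(ValueError):
    """Malformed input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class FormatDialect:
    """A format name plus dialect flags (symbols, missing/gap chars...)."""

    format: str
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.format not in _KNOWN_FORMATS:
            raise ValueError(f"unknown format {self.format!r}")
        missing = self.options.get("missing", "?")
        gap = self.options.get("gap", "-")
        if len(missing) != 1 or len(gap) != 1:
            raise ValueError("missing and gap must be single characters")
        if missing == gap:
            raise ValueError("missing and gap symbols must be distinct")
        symbols = self.options.get("symbols")
        if symbols is not None and len(symbols) < 2:
            raise ValueError("categorical data needs >= 2 symbols")

    @property
    def missing(self) -> str:
        return self.options.get("missing", "?")

    @property
    def gap(self) -> str:
        return self.options.get("gap", "-")


# ---------------------------------------------------------------------------
# NEXUS character matrices


def _strip_nexus_comments(text: str) -> str:
    """Blank out [...] comments (nesting supported), preserving newlines."""
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
            out.append(" ")
        elif ch == "]" and depth:
            depth -= 1
            out.append(" ")
        elif depth:
            out.append(ch if ch == "\n" else " ")
        else:
            out.append(ch)
    return "".join(out)


def _parse_row_states(
    seq: str,
    symbols: tuple[str, ...],
    missing: str,
    gap: str,
    gap_as_missing: bool,
    line_no: int,
    taxon: str,
    start_col: int,
) -> list[frozenset | None]:
    cells: list[frozenset | None] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch.isspace():
            i += 1
            continue
        col = start_col + len(cells) + 1
        if ch in "{(":
            closer = "}" if ch == "{" else ")"
            j = seq.find(closer, i)
            if j < 0:
                raise ParseError(
                    f"unclosed polymorphism in row {taxon!r}", line_no
                )
            group = [c for c in seq[i + 1 : j] if not c.isspace() and c != ","]
            for c in group:
                if c not in symbols:
                    raise ParseError(
                        f"symbol {c!r} outside declared SYMBOLS at row "
                        f"{taxon!r}, column {col}",
                        line_no,
                    )
            if not group:
                raise ParseError(
                    f"empty polymorphism in row {taxon!r}, column {col}",
                    line_no,
                )
            cells.append(frozenset(group))
            i = j + 1
        elif ch == missing:
            cells.append(None)
            i += 1
        elif ch == gap:
            cells.append(None if gap_as_missing else frozenset([gap]))
            i += 1
        elif ch in symbols:
            cells.append(frozenset([ch]))
            i += 1
        else:
            raise ParseError(
                f"symbol {ch!r} outside declared SYMBOLS at row {taxon!r}, "
                f"column {col}",
                line_no,
            )
    return cells


_LABEL_RE = re.compile(r"\s*(?:'((?:[^']|'')*)'|(\S+))\s*(.*)")


def read_character_matrix(
    text: str, dialect: FormatDialect | None = None
) -> DataMatrix:
    """Parse a NEXUS DATA/CHARACTERS block into a :class:`DataMatrix`.

    ``?`` cells become missing; gap ``-`` is treated as missing by default
    (option ``gap_as_missing=False`` keeps it as an extra state); ``{..}``
    and ``(..)`` become polymorphic state sets.  Arbitrary single-character
    SYMBOLS lists are accepted.
    """
    dialect = dialect or FormatDialect("nexus-characters")
    gap_as_missing = dialect.options.get("gap_as_missing", True)
    clean = _strip_nexus_comments(text)
    lines = clean.split("\n")
    if not lines or not lines[0].strip().upper().startswith("#NEXUS"):
        raise ParseError("not a NEXUS file (missing #NEXUS header)", 1)

    ntax = nchar = None
    symbols: tuple[str, ...] | None = None
    missing, gap = dialect.missing, dialect.gap
    datatype = "standard"
    interleave = False
    matrix_start = None
    for idx, raw in enumerate(lines):
        line = raw.strip()
        upper = line.upper()
        if upper.startswith("DIMENSIONS"):
            m = re.search(r"NTAX\s*=\s*(\d+)", upper)
            if m:
                ntax = int(m.group(1))
            m = re.search(r"NCHAR\s*=\s*(\d+)", upper)
            if m:
                nchar = int(m.group(1))
        elif upper.startswith("FORMAT"):
            m = re.search(r'SYMBOLS\s*=\s*"([^"]*)"', line, re.I)
            if m:
                symbols = tuple(c for c in m.group(1) if not c.isspace())
            m = re.search(r"MISSING\s*=\s*(\S)", line, re.I)
            if m:
                missing = m.group(1)
            m = re.search(r"GAP\s*=\s*(\S)", line, re.I)
            if m:
                gap = m.group(1)
            m = re.search(r"DATATYPE\s*=\s*(\w+)", line, re.I)
            if m:
                datatype = m.group(1).lower()
            if re.search(r"INTERLEAVE(\s*=\s*YES)?\b", upper):
                interleave = "INTERLEAVE=NO" not in upper.replace(" ", "")
        elif upper.startswith("MATRIX"):
            matrix_start = idx + 1
            break
    if ntax is None or nchar is None:
        raise ParseError("DIMENSIONS with NTAX and NCHAR required")
    if matrix_start is None:
        raise ParseError("MATRIX section not found")
    if missing == gap:
        raise ParseError("MISSING and GAP symbols must be distinct")
    if datatype in ("dna", "rna", "nucleotide"):
        symbols = NUCLEOTIDE_SYMBOLS
    elif symbols is None:
        symbols = tuple("0123456789")

    order: list[str] = []
    rows: dict[str, list] = {}
    row_lines: dict[str, int] = {}
    for idx in range(matrix_start, len(lines)):
        line = lines[idx].strip()
        if not line:
            continue
        if line == ";" or line.upper().startswith("END"):
            break
        terminal = line.endswith(";")
        if terminal:
            line = line[:-1].strip()
        if line:
            m = _LABEL_RE.match(line)
            if not m:
                raise ParseError("cannot parse matrix row", idx + 1)
            label = (m.group(1) or m.group(2)).replace("''", "'")
            seq = m.group(3)
            if label not in rows:
                if not interleave and len(order) == ntax:
                    raise ParseError(
                        f"more than NTAX={ntax} taxa in matrix", idx + 1
                    )
                order.append(label)
                rows[label] = []
                row_lines[label] = idx + 1
            elif not interleave:
                raise ParseError(f"duplicate taxon label {label!r}", idx + 1)
            if datatype in ("dna", "rna", "nucleotide"):
                cells = _parse_dna_states(seq, missing, gap, idx + 1, label,
                                          len(rows[label]))
            else:
                cells = _parse_row_states(
                    seq, symbols, missing, gap, gap_as_missing, idx + 1,
                    label, len(rows[label]),
                )
            rows[label].extend(cells)
        if terminal:
            break

    if len(order) != ntax:
        raise ParseError(f"expected NTAX={ntax} taxa, found {len(order)}")
    for label in order:
        if len(rows[label]) != nchar:
            raise ParseError(
                f"row {label!r} has {len(rows[label])} characters, "
                f"expected NCHAR={nchar}",
                row_lines[label],
            )
    if datatype in ("dna", "rna", "nucleotide"):
        characters = [
            Character(name=str(j + 1), symbols=NUCLEOTIDE_SYMBOLS,
                      kind="nucleotide")
            for j in range(nchar)
        ]
    else:
        if not gap_as_missing:
            symbols = symbols + (gap,)
        characters = [
            Character(name=str(j + 1), symbols=symbols) for j in range(nchar)
        ]
    return DataMatrix(order, characters, [rows[t] for t in order])


def write_character_matrix(m: DataMatrix) -> str:
    """Emit a non-interleaved NEXUS CHARACTERS block."""
    kinds = {c.kind for c in m.characters}
    is_dna = kinds == {"nucleotide"}
    if is_dna:
        fmt = 'FORMAT DATATYPE=DNA MISSING=? GAP=-;'
    else:
        alphabet: list[str] = []
        for c in m.characters:
            for s in c.symbols:
                if s not in alphabet:
                    alphabet.append(s)
        fmt = f'FORMAT DATATYPE=STANDARD SYMBOLS="{"".join(alphabet)}" MISSING=? GAP=-;'
    lines = [
        "#NEXUS",
        "BEGIN CHARACTERS;",
        f"DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};",
        fmt,
        "MATRIX",
    ]
    width = max(len(_quote_label(t)) for t in m.taxa) + 2
    for i, taxon in enumerate(m.taxa):
        cells = []
        for j, char in enumerate(m.characters):
            cell = m.cell(i, j)
            if cell is None:
                cells.append("?")
            elif len(cell) == 1:
                cells.append(next(iter(cell)))
            else:
                cells.append("{" + "".join(sorted(cell, key=char.symbols.index)) + "}")
        lines.append(f"{_quote_label(taxon):<{width}}{''.join(cells)}")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def _quote_label(label: str) -> str:
    if re.search(r"[\s(){}\[\];,'\"=]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# nucleotide alignments


def _parse_dna_states(
    seq: str, missing: str, gap: str, line_no: int, taxon: str, start_col: int
) -> list[frozenset | None]:
    cells: list[frozenset | None] = []
    for ch in seq:
        if ch.isspace():
            continue
        up = ch.upper()
        if ch in (missing, gap) or up in ("N", "X"):
            cells.append(None)
        elif up in IUPAC:
            cells.append(IUPAC[up])
        else:
            raise ParseError(
                f"unknown nucleotide symbol {ch!r} in row {taxon!r}, "
                f"column {start_col + len(cells) + 1}",
                line_no,
            )
    return cells


def _dna_matrix(names: list[str], seqs: list[list[frozenset | None]]) -> DataMatrix:
    nchar = len(seqs[0])
    characters = [
        Character(name=str(j + 1), symbols=NUCLEOTIDE_SYMBOLS, kind="nucleotide")
        for j in range(nchar)
    ]
    return DataMatrix(names, characters, seqs)


def read_alignment(text: str, dialect: FormatDialect) -> DataMatrix:
    """Read a nucleotide alignment (relaxed PHYLIP, FASTA or NEXUS).

    IUPAC ambiguity codes become state sets; ``-``, ``?``, ``N`` and ``X``
    are treated as missing (a full-ambiguity code carries no information
    for distances or patterns).
    """
    fmt = dialect.format
    if fmt == "relaxed-phylip":
        return _read_phylip(text, dialect)
    if fmt == "fasta":
        return _read_fasta(text, dialect)
    if fmt == "nexus-characters":
        return read_character_matrix(text, dialect)
    raise ValueError(f"unsupported alignment format {fmt!r}")


def _read_phylip(text: str, dialect: FormatDialect) -> DataMatrix:
    lines = text.splitlines()
    header = None
    start = 0
    for idx, line in enumerate(lines):
        if line.strip():
            header = line.split()
            start = idx + 1
            break
    if header is None or len(header) != 2:
        raise ParseError("PHYLIP header must be 'ntax nchar'", start or 1)
    try:
        ntax, nchar = int(header[0]), int(header[1])
    except ValueError:
        raise ParseError("PHYLIP header must be two integers", start) from None
    names: list[str] = []
    seqs: list[list[frozenset | None]] = []
    for idx in range(start, len(lines)):
        line = lines[idx].strip()
        if not line:
            continue
        if len(names) == len(seqs):  # expecting a new taxon row
            parts = line.split(None, 1)
            name = parts[0]
            if name in names:
                raise ParseError(f"duplicate taxon label {name!r}", idx + 1)
            names.append(name)
            seqs.append([])
            rest = parts[1] if len(parts) > 1 else ""
        else:
            rest = line
        seqs[-1].extend(
            _parse_dna_states(rest, dialect.missing, dialect.gap, idx + 1,
                              names[-1], len(seqs[-1]))
        )
        if len(seqs[-1]) > nchar:
            raise ParseError(
                f"row {names[-1]!r} longer than declared length {nchar}",
                idx + 1,
            )
    if len(names) != ntax:
        raise ParseError(f"expected {ntax} taxa, found {len(names)}")
    for name, seq in zip(names, seqs):
        if len(seq) != nchar:
            raise ParseError(
                f"row {name!r} has {len(seq)} sites, expected {nchar}"
            )
    return _dna_matrix(names, seqs)


def _read_fasta(text: str, dialect: FormatDialect) -> DataMatrix:
    names: list[str] = []
    seqs: list[list[frozenset | None]] = []
    for idx, raw in enumerate(text.splitlines()):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else ""
            if not name:
                raise ParseError("empty FASTA header", idx + 1)
            if name in names:
                raise ParseError(f"duplicate taxon label {name!r}", idx + 1)
            names.append(name)
            seqs.append([])
        else:
            if not names:
                raise ParseError("sequence data before first header", idx + 1)
            seqs[-1].extend(
                _parse_dna_states(line, dialect.missing, dialect.gap,
                                  idx + 1, names[-1], len(seqs[-1]))
            )
    if not names:
        raise ParseError("no sequences found")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ParseError(f"unequal sequence lengths: {sorted(lengths)}")
    return _dna_matrix(names, seqs)


def write_alignment(m: DataMatrix, fmt: str = "fasta") -> str:
    """Write a nucleotide matrix as FASTA or relaxed PHYLIP."""

    def seq_str(i: int) -> str:
        out = []
        for j in range(m.n_characters):
            cell = m.cell(i, j)
            if cell is None:
                out.append("?")
            elif len(cell) == 1:
                out.append(next(iter(cell)))
            else:
                code = next(
                    (c for c, states in IUPAC.items() if states == cell), None
                )
                if code is None:
                    raise ValueError(f"cell {cell} has no IUPAC code")
                out.append(code)
        return "".join(out)

    if fmt == "fasta":
        return "".join(f">{t}\n{seq_str(i)}\n" for i, t in enumerate(m.taxa))
    if fmt == "relaxed-phylip":
        lines = [f"{m.n_taxa} {m.n_characters}"]
        width = max(len(t) for t in m.taxa) + 2
        for i, t in enumerate(m.taxa):
            lines.append(f"{t:<{width}}{seq_str(i)}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unsupported alignment format {fmt!r}")


# ---------------------------------------------------------------------------
# RAxML-style partition files

_PART_RE = re.compile(r"^\s*([A-Za-z0-9]+)\s*,\s*([^=]+?)\s*=\s*(.+)$")


def read_partition_scheme(text: str, flags: dict | None = None) -> PartitionScheme:
    """Parse RAxML-style lines ``DNA, rbcL = 1-1206`` into a scheme.

    Ranges are 1-based inclusive, comma-separated, with optional strides
    (``1-12\\3`` = every third column); stored 0-based internally.
    """
    partitions: dict[str, list[int]] = {}
    for idx, raw in enumerate(text.splitlines()):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        m = _PART_RE.match(line)
        if not m:
            raise ParseError(f"cannot parse partition line {raw!r}", idx + 1)
        name = m.group(2).strip()
        if name in partitions:
            raise ParseError(f"duplicate partition name {name!r}", idx + 1)
        cols: list[int] = []
        for chunk in m.group(3).split(","):
            chunk = chunk.strip()
            stride = 1
            if "\\" in chunk:
                chunk, stride_s = chunk.split("\\", 1)
                try:
                    stride = int(stride_s)
                except ValueError:
                    raise ParseError(
                        f"bad stride in {chunk!r}", idx + 1
                    ) from None
            if "-" in chunk:
                lo_s, hi_s = chunk.split("-", 1)
            else:
                lo_s = hi_s = chunk
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise ParseError(f"bad range {chunk!r}", idx + 1) from None
            if lo < 1 or hi < lo:
                raise ParseError(f"bad range {chunk!r}", idx + 1)
            cols.extend(range(lo - 1, hi, stride))
        partitions[name] = cols
    try:
        return PartitionScheme(
            {k: sorted(v) for k, v in partitions.items()}, flags or {}
        )
    except ValueError as exc:
        raise ParseError(str(exc)) from None


# ---------------------------------------------------------------------------
# trees


def read_trees(text: str, schema: str = "newick") -> TreeSample:
    """Read one or more trees from newick or NEXUS text."""
    try:
        tlist = dendropy.TreeList.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:
        raise ParseError(f"cannot parse {schema} trees: {exc}") from None
    return TreeSample([Tree.from_dendropy(t) for t in tlist])


def write_trees(sample: TreeSample | list[Tree]) -> str:
    trees = sample.trees if isinstance(sample, TreeSample) else sample
    return "\n".join(t.to_newick() for t in trees) + "\n"


# ---------------------------------------------------------------------------
# splits-NEXUS


def write_splits_nexus(splits: "SplitSystem") -> str:  # noqa: F821
    """Emit a SplitsTree-compatible SPLITS block (weights preserved)."""
    labels = splits.labels
    n = len(labels)
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"DIMENSIONS NTAX={n};",
        "TAXLABELS",
    ]
    lines += [f"[{i + 1}] {_quote_label(t)}" for i, t in enumerate(labels)]
    lines += [";", "END;", "BEGIN SPLITS;"]
    lines.append(f"DIMENSIONS NTAX={n} NSPLITS={len(splits.splits)};")
    lines.append("FORMAT LABELS=NO WEIGHTS=YES;")
    if splits.ordering is not None:
        cycle = " ".join(str(labels.index(t) + 1) for t in splits.ordering)
        lines.append(f"CYCLE {cycle};")
    lines.append("MATRIX")
    for idx, (bip, weight) in enumerate(splits.splits):
        side = [str(i + 1) for i in sorted(bip.side_indices())]
        lines.append(f"[{idx + 1}] {weight:.12g} {' '.join(side)},")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def read_splits_nexus(text: str) -> "SplitSystem":  # noqa: F821
    """Re-import a SPLITS block written by :func:`write_splits_nexus`."""
    from .splits import Bipartition, SplitSystem

    clean = _strip_nexus_comments(text)
    labels: list[str] = []
    lines = clean.split("\n")
    i = 0
    while i < len(lines) and "TAXLABELS" not in lines[i].upper():
        i += 1
    if i == len(lines):
        raise ParseError("TAXLABELS not found")
    i += 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if line.startswith(";") or line.upper().startswith("END"):
            break
        if not line:
            continue
        m = _LABEL_RE.match(line)
        if m:
            labels.append((m.group(1) or m.group(2)).replace("''", "'"))
    ordering = None
    splits: list[tuple] = []
    n = len(labels)
    while i < len(lines):
        line = lines[i].strip()
        upper = line.upper()
        if upper.startswith("CYCLE"):
            body = line.rstrip(";")[5:]
            ordering = [labels[int(tok) - 1] for tok in body.split()]
        elif upper.startswith("MATRIX"):
            i += 1
            while i < len(lines):
                row = lines[i].strip().rstrip(",")
                i += 1
                if row == ";" or row.upper().startswith("END"):
                    break
                if not row:
                    continue
                toks = row.split()
                weight = float(toks[0])
                side = frozenset(int(tok) - 1 for tok in toks[1:])
                bits = 0
                for s in side:
                    bits |= 1 << s
                splits.append((Bipartition.from_side(bits, n), weight))
            break
        i += 1
    return SplitSystem(labels, splits, ordering=ordering)
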