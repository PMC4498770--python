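"""Alignment input and query bookkeeping.

This module covers everything that happens before a tree exists: reading a
multiple sequence alignment of homologs (aligned FASTA or A3M), locating the
alignment columns that carry the query's oxidized cysteines, discarding
homologs whose cysteine count at those columns is odd, and generating the
shuffled-query outgroup sequence used later for rooting.

Coordinates are 0-based everywhere in this package; the CLI converts to and
from the 1-based convention used in biological notation.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GAP_CHARS = frozenset("-.")

OUTGROUP_SUFFIX = "__outgroup"


class AlignmentFormatError(ValueError):
    """Raised when an alignment file violates its declared format."""


@dataclass(frozen=True)
class QueryProtein:
    """A query sequence with known oxidized cysteine positions.

    Parameters
    ----------
    id : str
        Sequence identifier.
    sequence : str
        Ungapped amino-acid sequence.
    oxidized_positions : tuple of int
        0-based positions of the cysteines engaged in disulfide bonds,
        strictly increasing. The count must be even (each bond uses two
        cysteines) and every position must hold a ``C``.
    """

    id: str
    sequence: str
    oxidized_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.oxidized_positions)
        object.__setattr__(self, "oxidized_positions", pos)
        if len(pos) < 2 or len(pos) % 2 != 0:
            raise ValueError(
                f"oxidized cysteine count must be even and >= 2, got {len(pos)}"
            )
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("oxidized positions must be strictly increasing")
        for p in pos:
            if p < 0 or p >= len(self.sequence):
                raise ValueError(f"position {p} outside sequence of length {len(self.sequence)}")
            if self.sequence[p].upper() != "C":
                raise ValueError(
                    f"position {p} of {self.id!r} holds {self.sequence[p]!r}, not a cysteine"
                )

    @property
    def n_cysteines(self) -> int:
        return len(self.oxidized_positions)

    @property
    def n_bonds(self) -> int:
        """d = |C| / 2, the number of disulfide bonds."""
        return len(self.oxidized_positions) // 2


@dataclass(frozen=True)
class AlignedFamily:
    """An MSA of the query's protein family.

    ``rows`` keeps (id, aligned sequence) in file order; all aligned
    sequences share one length. ``oxidized_columns`` is populated by
    :func:`map_oxidized_columns` and maps each oxidized query position to
    its alignment column.
    """

    rows: tuple[tuple[str, str], ...]
    query_row_id: str
    oxidized_columns: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple((str(i), str(s)) for i, s in self.rows))
        object.__setattr__(self, "oxidized_columns", tuple(int(c) for c in self.oxidized_columns))
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"aligned rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.rows)

    def row(self, row_id: str) -> str:
        for i, s in self.rows:
            if i == row_id:
                return s
        raise KeyError(f"row {row_id!r} not in family")

    @property
    def query_row(self) -> str:
        return self.row(self.query_row_id)


def _sanitize_id(raw: str, seen: dict[str, int]) -> str:
    """Newick-safe, unique row identifier.

    Characters with structural meaning in Newick are replaced by ``_``;
    duplicate ids get an ordinal suffix.
    """
    rid = re.sub(r"[\s(),:;'\[\]]", "_", raw) or "row"
    n = seen.get(rid, 0)
    seen[rid] = n + 1
    return rid if n == 0 else f"{rid}.{n + 1}"


def read_alignment(path: str | Path, format: str = "fasta", query_row_id: str | None = None) -> AlignedFamily:
    """Read an alignment from ``path`` in aligned-FASTA or A3M format.

    A3M rows use lowercase letters (and ``.``) for insertion states relative
    to the query/master sequence; these columns are removed so every row
    lands in the master's match-column frame.

    Parameters
    ----------
    path : path-like
        Alignment file.
    format : {"fasta", "a3m"}
        Input dialect.
    query_row_id : str, optional
        Id of the query row; defaults to the first row.
    """
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unknown alignment format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    seen: dict[str, int] = {}
    rows: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq)
        if format == "a3m":
            # lowercase = insertion relative to the master; '.' pads
            # insertions in other rows. Both leave the match frame on removal.
            seq = "".join(ch for ch in seq if not (ch.islower() or ch == "."))
        rows.append((_sanitize_id(rec.id, seen), seq))
    length = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != length:
            raise AlignmentFormatError(
                f"row {rid!r} has aligned length {len(seq)}, expected {length}"
            )
    qid = query_row_id if query_row_id is not None else rows[0][0]
    fam = AlignedFamily(rows=tuple(rows), query_row_id=qid)
    fam.query_row  # raises KeyError if absent
    return fam


def map_oxidized_columns(family: AlignedFamily, query: QueryProtein) -> AlignedFamily:
    """Map the query's oxidized positions onto alignment columns.

    Walks the query row, counting non-gap characters; the column at which
    the running ungapped index hits an oxidized position is recorded.
    Returns a copy of ``family`` with ``oxidized_columns`` filled in.
    """
    qrow = family.row(family.query_row_id)
    wanted = set(query.oxidized_positions)
    col_of: dict[int, int] = {}
    seq_idx = 0
    for col, ch in enumerate(qrow):
        if ch in GAP_CHARS:
            continue
        if seq_idx in wanted:
            col_of[seq_idx] = col
        seq_idx += 1
    ungapped = "".join(ch for ch in qrow if ch not in GAP_CHARS)
    if ungapped.upper() != query.sequence.upper():
        raise ValueError(
            f"query row {family.query_row_id!r} does not reproduce the query sequence when ungapped"
        )
    columns = tuple(col_of[p] for p in query.oxidized_positions)
    for p, c in zip(query.oxidized_positions, columns):
        if qrow[c].upper() != "C":
            raise ValueError(f"column {c} mapped from position {p} holds {qrow[c]!r}, not 'C'")
    return replace(family, oxidized_columns=columns)


def _cysteine_count(seq: str, columns: Iterable[int]) -> int:
    return sum(1 for c in columns if seq[c].upper() == "C")


def filter_even_cysteine_homologs(family: AlignedFamily) -> AlignedFamily:
    """Drop homologs with an odd cysteine count at the oxidized columns.

    An odd count marks a spurious single mutation that would blur the
    tandem-mutation signal. The query row is retained unconditionally (its
    count equals |C|, even by construction), as is a previously appended
    outgroup row (rooting machinery, not a homolog). Zero cysteines is an
    even count: such rows stay. Row order is preserved; the filter is
    idempotent.
    """
    if not family.oxidized_columns:
        raise ValueError("oxidized columns not mapped; call map_oxidized_columns first")
    cols = family.oxidized_columns
    kept = tuple(
        (rid, seq)
        for rid, seq in family.rows
        if rid == family.query_row_id
        or rid.endswith(OUTGROUP_SUFFIX)
        or _cysteine_count(seq, cols) % 2 == 0
    )
    return replace(family, rows=kept)


def make_outgroup(query: QueryProtein, seed: int) -> tuple[str, str]:
    """Shuffle the query sequence into a maximally distant outgroup.

    The shuffle preserves the residue multiset, so composition-based
    distances stay finite while positional similarity is destroyed; the
    resulting sequence branches outside the family and pins the root.
    """
    rng = random.Random(seed)
    chars = list(query.sequence)
    rng.shuffle(chars)
    return query.id + OUTGROUP_SUFFIX, "".join(chars)


def append_outgroup(family: AlignedFamily, query: QueryProtein, seed: int) -> tuple[AlignedFamily, str]:
    """Append the shuffled outgroup as the last alignment row.

    The shuffled residues are laid into the query row's non-gap columns so
    the outgroup shares the alignment frame; gap columns stay gaps.
    Returns the extended family and the outgroup row id.
    """
    og_id, og_seq = make_outgroup(query, seed)
    qrow = family.row(family.query_row_id)
    it = iter(og_seq)
    aligned = "".join(ch if ch in GAP_CHARS else next(it) for ch in qrow)
    return replace(family, rows=family.rows + ((og_id, aligned),)), og_id
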