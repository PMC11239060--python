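"""Core data model for aligned ITS matrices.

Fungal barcode (ITS) alignments from heterokaryotic (n+n) fruit bodies carry
multi-base IUPAC codes with a particular semantics: a ``Y`` in a direct
Sanger read of a heterokaryon is not an ambiguous call (C *or* T) but a
heteromorphic site — both a C allele and a T allele are present in the same
basidioma.  Every downstream operation in this package (polymorphism tables,
diagnostic markers, difference counts) therefore works on *base sets* rather
than single characters.

This module provides:

* :class:`BaseSet` — the expansion of one IUPAC character into a set of
  bases, a gap, or missing data;
* :class:`AlignedMatrix` — samples x alignment-columns of IUPAC characters
  with group (species) labels;
* the two coordinate systems used to report marker positions: raw alignment
  columns, and taxon-local 1-based ungapped positions anchored at the
  conserved ITS start motif ``tygaatt``.

Both coordinate systems are 1-based and inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import AlignmentError, AnchorNotFoundError, CoordinateError, InputError

GAP = "-"
MISSING = "N"

#: Characters accepted after normalisation (uppercase, U -> T).
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: IUPAC expansion for every non-gap, non-N code.
_EXPANSION: dict[str, frozenset[str]] = {
    c: frozenset(ambiguous_dna_values[c]) for c in "ACGTRYSWKMBDHV"
}

#: Conserved motif at the 5' start of the ITS1-5.8S-ITS2 region; local
#: position 1 is the first residue of the first window compatible with it.
ANCHOR_MOTIF = "TYGAATT"


@dataclass(frozen=True)
class BaseSet:
    """State of one sample at one alignment column.

    Exactly one of the following holds: ``bases`` is a non-empty subset of
    {A, C, G, T}; ``is_gap`` (an internal deletion, a real character state);
    or ``is_missing`` (an ``N`` or a terminal gap run, i.e. unsequenced).
    """

    bases: frozenset[str] = frozenset()
    is_gap: bool = False
    is_missing: bool = False

    def __post_init__(self) -> None:
        forms = (bool(self.bases), self.is_gap, self.is_missing)
        if sum(forms) != 1:
            raise ValueError(f"BaseSet must be exactly one of bases/gap/missing: {self!r}")

    @property
    def is_heteromorphic(self) -> bool:
        """Two or more bases co-occur (a heteroallelic site of a heterokaryon)."""
        return len(self.bases) >= 2


GAP_STATE = BaseSet(is_gap=True)
MISSING_STATE = BaseSet(is_missing=True)


def normalize_char(char: str) -> str:
    """Uppercase one character and map U (RNA) to T."""
    c = char.upper()
    return "T" if c == "U" else c


def expand_code(char: str) -> BaseSet:
    """Expand one IUPAC character into its :class:`BaseSet`.

    ``'-'`` expands to a gap state and ``'N'`` to missing data — N is never
    treated as a heteromorphism and never contributes to difference or
    diagnostic counts.
    """
    c = normalize_char(char)
    if c == GAP:
        return GAP_STATE
    if c == MISSING:
        return MISSING_STATE
    try:
        return BaseSet(bases=_EXPANSION[c])
    except KeyError:
        raise InputError(f"illegal nucleotide character {char!r}") from None


def is_heteromorphic(char: str) -> bool:
    """True iff ``char`` encodes two or more co-occurring bases (N excluded)."""
    return expand_code(char).is_heteromorphic


def states_disjoint(a: BaseSet, b: BaseSet) -> bool:
    """Whether two non-missing states share no allele.

    A gap is a distinct character state: gap vs base is disjoint, gap vs gap
    is identity.  Missing states are never disjoint from anything — callers
    are expected to have filtered them out.
    """
    if a.is_missing or b.is_missing:
        return False
    if a.is_gap or b.is_gap:
        return a.is_gap != b.is_gap
    return not (a.bases & b.bases)


@dataclass(frozen=True)
class CoordinateMode:
    """Which coordinate system marker positions are reported in.

    ``alignment``: raw 1-based alignment columns (as used for clade-level
    markers numbered against a reference alignment).  ``local``: 1-based
    ungapped positions of a chosen reference sample, counted from the first
    residue matching :data:`ANCHOR_MOTIF`.
    """

    mode: str
    anchor_motif: str = ANCHOR_MOTIF

    def __post_init__(self) -> None:
        if self.mode not in ("alignment", "local"):
            raise InputError(f"coordinate mode must be 'alignment' or 'local', got {self.mode!r}")


ALIGNMENT_COORDS = CoordinateMode("alignment")
LOCAL_COORDS = CoordinateMode("local")

DEFAULT_GROUP = "ungrouped"


class AlignedMatrix:
    """Samples x alignment columns of IUPAC characters with group labels.

    Rows are normalised (uppercase, U -> T) equal-length strings over the
    IUPAC + gap alphabet.  Terminal gap runs (leading/trailing ``-``) encode
    unsequenced ends and are exposed as *missing* states by :meth:`state`;
    internal gaps are real deletion states.
    """

    def __init__(
        self,
        records: Iterable[tuple[str, str]],
        group_of: Mapping[str, str] | None = None,
        terminal_gaps_missing: bool = True,
    ) -> None:
        self.sample_ids: list[str] = []
        self.rows: dict[str, str] = {}
        self.terminal_gaps_missing = terminal_gaps_missing
        length: int | None = None
        for sample_id, seq in records:
            if sample_id in self.rows:
                raise InputError(f"duplicate sample id {sample_id!r}")
            row = "".join(normalize_char(c) for c in seq)
            for i, c in enumerate(row):
                if c not in ALLOWED_CHARS:
                    raise InputError(
                        f"illegal character {c!r} in sample {sample_id!r} at column {i + 1}"
                    )
            if length is None:
                length = len(row)
            elif len(row) != length:
                raise AlignmentError(
                    f"sample {sample_id!r} has length {len(row)}, expected {length}"
                )
            self.sample_ids.append(sample_id)
            self.rows[sample_id] = row
        if length is None:
            raise InputError("alignment contains no sequences")
        self.column_count: int = length
        group_of = dict(group_of or {})
        unknown = set(group_of) - set(self.sample_ids)
        if unknown:
            raise InputError(f"group map names unknown samples: {sorted(unknown)}")
        self.group_of: dict[str, str] = {
            s: group_of.get(s, DEFAULT_GROUP) for s in self.sample_ids
        }
        # leading/trailing gap run lengths per sample
        self._terminal: dict[str, tuple[int, int]] = {}
        for s, row in self.rows.items():
            lead = len(row) - len(row.lstrip(GAP))
            trail = len(row) - len(row.rstrip(GAP))
            if lead == len(row):  # all-gap row: treat as entirely missing
                trail = 0
            self._terminal[s] = (lead, trail)

    # -- accessors ---------------------------------------------------------

    def char(self, sample: str, column: int) -> str:
        """Raw character of ``sample`` at 1-based alignment ``column``."""
        self._check(sample, column)
        return self.rows[sample][column - 1]

    def is_terminal_gap(self, sample: str, column: int) -> bool:
        self._check(sample, column)
        lead, trail = self._terminal[sample]
        return column <= lead or column > self.column_count - trail

    def state(self, sample: str, column: int) -> BaseSet:
        """State set of ``sample`` at ``column``; terminal gaps are missing."""
        c = self.char(sample, column)
        if c == GAP and self.terminal_gaps_missing and self.is_terminal_gap(sample, column):
            return MISSING_STATE
        return expand_code(c)

    def _check(self, sample: str, column: int) -> None:
        if sample not in self.rows:
            raise InputError(f"unknown sample {sample!r}")
        if not 1 <= column <= self.column_count:
            raise InputError(f"column {column} outside 1..{self.column_count}")

    def samples_in_group(self, group: str) -> list[str]:
        members = [s for s in self.sample_ids if self.group_of[s] == group]
        if not members:
            raise InputError(f"no samples in group {group!r}")
        return members

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.group_of[s], []).append(s)
        return out

    def subset_exists(self, samples: Iterable[str]) -> None:
        for s in samples:
            if s not in self.rows:
                raise InputError(f"unknown sample {s!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)


# -- coordinates -----------------------------------------------------------


def _motif_sets(motif: str = ANCHOR_MOTIF) -> list[frozenset[str]]:
    return [expand_code(c).bases for c in motif]


def locate_anchor(sample_row: str, motif: str = ANCHOR_MOTIF) -> int:
    """Alignment column (1-based) of the first residue of the first ungapped
    window compatible with the ITS start motif.

    Compatibility is by base-set intersection, so the ``y`` of ``tygaatt``
    matches C, T, or any code containing them.  N never matches.
    """
    row = "".join(normalize_char(c) for c in sample_row)
    residues = [(i + 1, c) for i, c in enumerate(row) if c != GAP]
    sets = _motif_sets(motif)
    k = len(sets)
    for start in range(len(residues) - k + 1):
        window = residues[start : start + k]
        if all(expand_code(c).bases & m for (_, c), m in zip(window, sets)):
            return window[0][0]
    raise AnchorNotFoundError(f"no window compatible with motif {motif!r}")


def to_local(matrix: AlignedMatrix, sample: str, alignment_column: int) -> int:
    """Local (ungapped, anchor-relative, 1-based) position of a column.

    Counts non-gap characters of ``sample`` from the anchor residue through
    ``alignment_column`` inclusive.
    """
    row = matrix.rows[sample] if sample in matrix.rows else None
    if row is None:
        raise InputError(f"unknown sample {sample!r}")
    matrix._check(sample, alignment_column)
    anchor_col = locate_anchor(row)
    if row[alignment_column - 1] == GAP:
        raise CoordinateError(
            f"local position undefined: {sample!r} has a gap at column {alignment_column}"
        )
    if alignment_column < anchor_col:
        raise CoordinateError(
            f"column {alignment_column} precedes the anchor at column {anchor_col}"
        )
    return sum(1 for c in row[anchor_col - 1 : alignment_column] if c != GAP)


def local_to_column(matrix: AlignedMatrix, sample: str, local_position: int) -> int:
    """Inverse of :func:`to_local`: alignment column of a local position."""
    if local_position < 1:
        raise CoordinateError(f"local positions are 1-based, got {local_position}")
    row = matrix.rows[sample]
    anchor_col = locate_anchor(row)
    count = 0
    for col in range(anchor_col, matrix.column_count + 1):
        if row[col - 1] != GAP:
            count += 1
            if count == local_position:
                return col
    raise CoordinateError(
        f"local position {local_position} beyond the end of sample {sample!r}"
    )


def local_sequence(matrix: AlignedMatrix, sample: str) -> str:
    """Ungapped sequence of ``sample`` from the anchor residue onward."""
    row = matrix.rows[sample]
    anchor_col = locate_anchor(row)
    return row[anchor_col - 1 :].replace(GAP, "")


# -- I/O -------------------------------------------------------------------


def parse_group_table(text: str) -> dict[str, str]:
    """Parse a two-column (sample_id <TAB> group) table; '#' lines ignored."""
    out: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise InputError(f"group table line {ln} is not two columns: {line!r}")
        sample, group = parts
        if sample in out:
            raise InputError(f"duplicate sample {sample!r} in group table")
        out[sample] = group
    return out


def read_alignment(
    fasta_text: str,
    group_table: str | Mapping[str, str] | None = None,
    terminal_gaps_missing: bool = True,
) -> AlignedMatrix:
    """Read an aligned FASTA string (``-`` gaps) into an :class:`AlignedMatrix`.

    ``group_table`` may be a TSV string (sample_id, group) or a mapping;
    samples it does not name fall into the ``"ungrouped"`` group.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(StringIO(fasta_text), "fasta")]
    groups: Mapping[str, str] | None
    if isinstance(group_table, str):
        groups = parse_group_table(group_table)
    else:
        groups = group_table
    return AlignedMatrix(records, groups, terminal_gaps_missing=terminal_gaps_missing)


def write_alignment(matrix: AlignedMatrix) -> str:
    """Serialise the matrix back to aligned FASTA (row order preserved)."""
    chunks = []
    for s in matrix.sample_ids:
        row = matrix.rows[s]
        body = "\n".join(row[i : i + 70] for i in range(0, len(row), 70))
        chunks.append(f">{s}\n{body}\n")
    return "".join(chunks)


def write_group_table(matrix: AlignedMatrix) -> str:
    return "".join(f"{s}\t{matrix.group_of[s]}\n" for s in matrix.sample_ids)
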