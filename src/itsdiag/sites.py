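"""Per-column classification and polymorphic-position tables.

Reproduces the style of published "polymorphic positions within different
samples" matrices: one row per specimen, one column per variable alignment
position, deletions shown as ``-`` and heteromorphic cells (multi-base IUPAC
codes) flagged.  Since plain TSV cannot carry a colour highlight, a
heteromorphic cell is rendered with a ``*`` suffix and a parallel boolean
flag table is available for machine consumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment import AlignedMatrix, BaseSet, GAP
from .errors import InputError


@dataclass(frozen=True)
class SiteRecord:
    """Classification of one alignment column over a chosen sample set."""

    column: int
    states: dict[str, BaseSet]  # per-sample state sets (insertion order = sample order)
    monomorphic: bool
    polymorphic: bool
    has_heteromorphism: bool
    has_indel: bool
    has_missing: bool


@dataclass
class PolymorphismTable:
    """Samples x variable-positions matrix restricted to polymorphic columns."""

    sample_ids: list[str]
    records: list[SiteRecord]
    display: dict[str, dict[int, str]]  # sample -> column -> display character

    @property
    def columns(self) -> list[int]:
        return [r.column for r in self.records]


def classify_columns(matrix: AlignedMatrix, sample_subset: Sequence[str]) -> list[SiteRecord]:
    """Classify every alignment column over ``sample_subset``.

    A column is monomorphic iff all *non-missing* state sets are identical
    (terminal-gap cells count as missing); it is polymorphic otherwise, so a
    column whose only variation is missing-vs-base is monomorphic — that
    variation reflects sequence length, not polymorphism.
    """
    if not sample_subset:
        raise InputError("sample_subset must be non-empty")
    matrix.subset_exists(sample_subset)
    out: list[SiteRecord] = []
    for col in range(1, matrix.column_count + 1):
        states = {s: matrix.state(s, col) for s in sample_subset}
        present = [st for st in states.values() if not st.is_missing]
        mono = len(set(present)) <= 1
        out.append(
            SiteRecord(
                column=col,
                states=states,
                monomorphic=mono,
                polymorphic=not mono,
                has_heteromorphism=any(st.is_heteromorphic for st in present),
                has_indel=any(st.is_gap for st in present),
                has_missing=any(st.is_missing for st in states.values()),
            )
        )
    return out


def polymorphic_positions(
    matrix: AlignedMatrix, sample_subset: Sequence[str]
) -> PolymorphismTable:
    """Build the polymorphic-position table for the chosen samples."""
    records = [r for r in classify_columns(matrix, sample_subset) if r.polymorphic]
    display = {
        s: {r.column: matrix.char(s, r.column) for r in records} for s in sample_subset
    }
    return PolymorphismTable(list(sample_subset), records, display)


def render_table(table: PolymorphismTable) -> str:
    """Render as TSV: header of positions, one row per sample.

    ``-`` marks deletions (and unsequenced terminal cells), and a ``*``
    suffix marks a heteromorphic cell — the plain-text stand-in for the
    colour highlight used in print.
    """
    cols = table.columns
    lines = ["\t".join(["sample", *(str(c) for c in cols)])]
    for s in table.sample_ids:
        cells = []
        for r in table.records:
            char = table.display[s][r.column]
            if r.states[s].is_heteromorphic:
                char += "*"
            cells.append(char)
        lines.append("\t".join([s, *cells]))
    return "\n".join(lines) + "\n"


def parse_table(text: str) -> tuple[list[str], list[int], dict[str, dict[int, str]]]:
    """Parse :func:`render_table` output back into (samples, columns, cells).

    Cell values keep the ``*`` heteromorphism suffix.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "sample":
        raise InputError("not a polymorphism table: header must start with 'sample'")
    cols = [int(c) for c in header[1:]]
    samples: list[str] = []
    cells: dict[str, dict[int, str]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(cols) + 1:
            raise InputError(f"row {parts[0]!r} has {len(parts) - 1} cells, expected {len(cols)}")
        samples.append(parts[0])
        cells[parts[0]] = dict(zip(cols, parts[1:]))
    return samples, cols, cells


def heteromorphism_flags(table: PolymorphismTable) -> dict[str, dict[int, bool]]:
    """Parallel boolean matrix: which cells are heteromorphic."""
    return {
        s: {r.column: r.states[s].is_heteromorphic for r in table.records}
        for s in table.sample_ids
    }
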