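"""Group-diagnostic columns and capital-letter marker notation.

A diagnostic (species-specific) marker is an alignment column at which the
state sets of every sample of the target taxon are disjoint from those of
every other sample — under heterokaryon semantics, so a target ``Y``
(= C and T) against an outside ``T`` is *not* diagnostic.  Markers are
printed in the field's notation: a fixed-width window of the reference
sequence in lowercase with the diagnostic characters capitalised, followed
by ``@position`` (one position, or ``@p-q`` for a run), in either alignment
or anchored local coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .alignment import (
    AlignedMatrix,
    CoordinateMode,
    GAP,
    LOCAL_COORDS,
    local_sequence,
    states_disjoint,
    to_local,
)
from .errors import InputError

DEFAULT_WINDOW = 13


@dataclass(frozen=True)
class MarkerString:
    """One formatted diagnostic marker.

    ``text`` is the window with lowercase flanks and uppercase diagnostic
    characters (a deletion marker carries the bracketed run instead);
    ``columns`` are the diagnostic alignment columns and ``positions`` the
    printed coordinates (equal to ``columns`` in alignment mode).
    """

    text: str
    columns: tuple[int, ...]
    positions: tuple[int, ...]
    coordinate_mode: str
    window_width: int
    reference_sample: str
    truncated_left: bool = False
    truncated_right: bool = False
    is_indel: bool = False

    @property
    def position_label(self) -> str:
        if len(self.positions) == 1:
            return str(self.positions[0])
        return f"{self.positions[0]}-{self.positions[-1]}"

    def notation(self, dash: str = "-") -> str:
        """The printable ``window@position`` line (``dash`` joins run ends)."""
        if len(self.positions) == 1:
            return f"{self.text}@{self.positions[0]}"
        return f"{self.text}@{self.positions[0]}{dash}{self.positions[-1]}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation()


def find_diagnostic_columns(matrix: AlignedMatrix, target_group: str) -> list[int]:
    """All columns where every target sample's state set is disjoint from
    every non-target sample's.

    Gap counts as a distinct state; missing cells (N, terminal gaps) are
    ignored, and a column where either side becomes empty after dropping
    missing cells is skipped.
    """
    targets = matrix.samples_in_group(target_group)
    others = [s for s in matrix.sample_ids if s not in set(targets)]
    if not others:
        raise InputError(f"group {target_group!r} covers the whole matrix; nothing to contrast")
    out: list[int] = []
    for col in range(1, matrix.column_count + 1):
        t_states = [st for s in targets if not (st := matrix.state(s, col)).is_missing]
        u_states = [st for s in others if not (st := matrix.state(s, col)).is_missing]
        if not t_states or not u_states:
            continue
        if all(states_disjoint(t, u) for t in t_states for u in u_states):
            out.append(col)
    return out


def _flank_widths(window_width: int, k: int) -> tuple[int, int]:
    left = (window_width - k) // 2
    return left, window_width - k - left


def format_marker(
    matrix: AlignedMatrix,
    reference_sample: str,
    diagnostic_columns: Sequence[int],
    coordinate_mode: CoordinateMode | str = LOCAL_COORDS,
    window_width: int = DEFAULT_WINDOW,
) -> MarkerString:
    """Format one marker run in the capital-letter notation.

    The window is ``window_width`` characters wide; for ``k`` diagnostic
    characters the left flank takes ``floor((W-k)/2)`` characters and the
    right flank the remainder, which reproduces the conventional 6+1+6 and
    5+2+6 layouts.  In local mode the flanks come from the reference
    sample's ungapped anchored sequence; in alignment mode from its raw
    alignment row.  A run of columns where the reference is gapped is
    rendered as a bracketed deletion marker (``flank[---]flank``) in
    alignment coordinates, positions = first affected column.
    """
    mode = CoordinateMode(coordinate_mode) if isinstance(coordinate_mode, str) else coordinate_mode
    cols = sorted(int(c) for c in diagnostic_columns)
    if not cols:
        raise InputError("no diagnostic columns given")
    if cols != list(range(cols[0], cols[-1] + 1)):
        raise InputError(f"diagnostic columns must be contiguous, got {cols}")
    matrix.subset_exists([reference_sample])
    row = matrix.rows[reference_sample]
    k = len(cols)
    gapped = [row[c - 1] == GAP for c in cols]
    if any(gapped):
        if not all(gapped):
            raise InputError("diagnostic run mixes gap and base in the reference sample")
        return _format_deletion_marker(matrix, reference_sample, cols, mode, window_width)
    left_w, right_w = _flank_widths(window_width, k)
    diag = "".join(row[c - 1] for c in cols).upper()

    if mode.mode == "local":
        seq = local_sequence(matrix, reference_sample)
        positions = tuple(to_local(matrix, reference_sample, c) for c in cols)
        first = positions[0]  # 1-based index into seq
        lo = first - 1 - left_w
        hi = first - 1 + k + right_w
    else:
        seq = row
        positions = tuple(cols)
        lo = cols[0] - 1 - left_w
        hi = cols[0] - 1 + k + right_w
    trunc_left = lo < 0
    trunc_right = hi > len(seq)
    lflank = seq[max(lo, 0) : positions[0] - 1 if mode.mode == "local" else cols[0] - 1]
    start = (positions[0] - 1 if mode.mode == "local" else cols[0] - 1) + k
    rflank = seq[start : min(hi, len(seq))]
    text = lflank.lower() + diag + rflank.lower()
    return MarkerString(
        text=text,
        columns=tuple(cols),
        positions=positions,
        coordinate_mode=mode.mode,
        window_width=window_width,
        reference_sample=reference_sample,
        truncated_left=trunc_left,
        truncated_right=trunc_right,
    )


def _format_deletion_marker(
    matrix: AlignedMatrix,
    reference_sample: str,
    cols: list[int],
    mode: CoordinateMode,
    window_width: int,
) -> MarkerString:
    if mode.mode == "local":
        raise InputError(
            "local coordinates are undefined where the reference sample is gapped; "
            "use alignment mode for deletion markers"
        )
    row = matrix.rows[reference_sample]
    k = len(cols)
    left_w, right_w = _flank_widths(window_width, k)
    # flanks: nearest non-gap characters of the reference row
    lflank: list[str] = []
    i = cols[0] - 2
    while i >= 0 and len(lflank) < left_w:
        if row[i] != GAP:
            lflank.append(row[i])
        i -= 1
    lflank.reverse()
    rflank: list[str] = []
    i = cols[-1]
    while i < len(row) and len(rflank) < right_w:
        if row[i] != GAP:
            rflank.append(row[i])
        i += 1
    text = "".join(lflank).lower() + "[" + GAP * k + "]" + "".join(rflank).lower()
    # dialect choice: an indel marker's printed position is the first affected column
    return MarkerString(
        text=text,
        columns=tuple(cols),
        positions=(cols[0],),
        coordinate_mode="alignment",
        window_width=window_width,
        reference_sample=reference_sample,
        truncated_left=len(lflank) < left_w,
        truncated_right=len(rflank) < right_w,
        is_indel=True,
    )


def merge_runs(columns: Sequence[int]) -> list[list[int]]:
    """Group sorted columns into maximal runs of consecutive positions."""
    runs: list[list[int]] = []
    for c in sorted(columns):
        if runs and c == runs[-1][-1] + 1:
            runs[-1].append(c)
        else:
            runs.append([c])
    return runs


def discover_and_format(
    matrix: AlignedMatrix,
    group: str,
    coordinate_mode: CoordinateMode | str = LOCAL_COORDS,
    reference_sample: str | None = None,
    window_width: int = DEFAULT_WINDOW,
) -> list[MarkerString]:
    """Find all diagnostic columns of ``group`` and format one marker per
    maximal run of consecutive columns.

    ``reference_sample`` defaults to the first sample of the target group.
    Runs where the reference carries a gap (deletion markers) are split from
    base runs and always formatted in alignment coordinates.
    """
    mode = CoordinateMode(coordinate_mode) if isinstance(coordinate_mode, str) else coordinate_mode
    ref = reference_sample or matrix.samples_in_group(group)[0]
    matrix.subset_exists([ref])
    cols = find_diagnostic_columns(matrix, group)
    row = matrix.rows[ref]
    markers: list[MarkerString] = []
    for run in merge_runs(cols):
        # split the run wherever gap-status of the reference changes
        sub: list[int] = []
        for c in run:
            if sub and (row[c - 1] == GAP) != (row[sub[-1] - 1] == GAP):
                markers.append(_format_run(matrix, ref, sub, mode, window_width))
                sub = []
            sub.append(c)
        if sub:
            markers.append(_format_run(matrix, ref, sub, mode, window_width))
    return markers


def _format_run(matrix, ref, run, mode, window_width):
    if matrix.rows[ref][run[0] - 1] == GAP:
        return _format_deletion_marker(matrix, ref, run, CoordinateMode("alignment"), window_width)
    return format_marker(matrix, ref, run, mode, window_width)


def parse_marker_text(text: str) -> tuple[str, list[int]]:
    """Split a marker window into (lowercase sequence, 0-based uppercase offsets).

    With the position label this recovers the diagnostic positions: the
    i-th uppercase character sits at ``first_position + i``.
    """
    offsets = [i for i, c in enumerate(text) if c.isupper()]
    return text.lower(), offsets
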