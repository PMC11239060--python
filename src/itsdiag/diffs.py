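"""Nucleotide-difference counting between sequences, species and samples.

Implements the counting conventions used in taxonomic Notes sections:
"k nucleotide differences ... excluding heteromorphic sites" and "unique
sites" between two species.  The rules, spelled out:

* a column is excluded from counting when either side is missing there
  (``N`` or a terminal gap run), or — with heteromorphic exclusion on, the
  default — when any compared sample carries a multi-base IUPAC code;
* among counted columns, a difference is scored iff the two state sets are
  disjoint: gap vs base is a difference, gap vs gap is identity;
* indels are scored per column by default (a 3-column deletion = 3
  differences); ``indel_mode="event"`` counts each contiguous gap run as a
  single difference, since published counts rarely state their convention;
* a *unique site* between two species is a counted column at which each
  species is internally invariant and the two are mutually disjoint (the
  fixed-difference reading); columns polymorphic within either species are
  excluded, not averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import (
    AlignedMatrix,
    BaseSet,
    GAP,
    MISSING_STATE,
    expand_code,
    normalize_char,
    states_disjoint,
)
from .errors import InputError

INDEL_MODES = ("column", "event")


@dataclass
class DiffReport:
    """Outcome of one difference count.

    ``differences == len(difference_positions)``; excluded columns are
    disjoint from counted ones.  ``excluded_polymorphic`` is only populated
    by group-level counts (columns variable within a compared group).
    """

    counted_columns: int = 0
    differences: int = 0
    excluded_heteromorphic: int = 0
    excluded_missing: int = 0
    excluded_polymorphic: int = 0
    indel_differences: int = 0
    difference_positions: list[int] = field(default_factory=list)

    def _close(self) -> "DiffReport":
        assert self.differences == len(self.difference_positions)
        assert self.differences <= self.counted_columns
        return self

    def to_dict(self) -> dict:
        return {
            "counted_columns": self.counted_columns,
            "differences": self.differences,
            "excluded_heteromorphic": self.excluded_heteromorphic,
            "excluded_missing": self.excluded_missing,
            "excluded_polymorphic": self.excluded_polymorphic,
            "indel_differences": self.indel_differences,
            "difference_positions": list(self.difference_positions),
        }


def _sequence_states(seq: str) -> list[BaseSet]:
    """Per-column states of a raw aligned sequence; terminal gaps missing."""
    row = "".join(normalize_char(c) for c in seq)
    lead = len(row) - len(row.lstrip(GAP))
    trail = len(row) - len(row.rstrip(GAP))
    if lead == len(row):
        trail = 0
    states = []
    for i, c in enumerate(row):
        if c == GAP and (i < lead or i >= len(row) - trail):
            states.append(MISSING_STATE)
        else:
            states.append(expand_code(c))
    return states


def _tally(
    per_column: list[tuple[BaseSet | None, BaseSet | None, str]],
    exclude_heteromorphic: bool,
    indel_mode: str,
) -> DiffReport:
    """Shared counting core.

    ``per_column`` holds (state_a, state_b, kind) per column, where kind is
    ``"ok"`` / ``"missing"`` / ``"het"`` / ``"poly"`` — the precomputed
    exclusion class (states may be None for excluded columns).
    """
    if indel_mode not in INDEL_MODES:
        raise InputError(f"indel_mode must be one of {INDEL_MODES}, got {indel_mode!r}")
    rep = DiffReport()
    diff_cols: list[tuple[int, bool]] = []  # (column, involves_gap)
    for col, (a, b, kind) in enumerate(per_column, start=1):
        if kind == "missing":
            rep.excluded_missing += 1
        elif kind == "het":
            rep.excluded_heteromorphic += 1
        elif kind == "poly":
            rep.excluded_polymorphic += 1
        else:
            rep.counted_columns += 1
            if states_disjoint(a, b):
                diff_cols.append((col, a.is_gap or b.is_gap))
    if indel_mode == "column":
        rep.difference_positions = [c for c, _ in diff_cols]
        rep.indel_differences = sum(1 for _, g in diff_cols if g)
    else:
        prev_col, prev_gap = None, False
        for col, gap in diff_cols:
            if gap and prev_gap and prev_col == col - 1:
                prev_col = col  # same indel event, not a new difference
                continue
            rep.difference_positions.append(col)
            if gap:
                rep.indel_differences += 1
            prev_col, prev_gap = col, gap
    rep.differences = len(rep.difference_positions)
    return rep._close()


def pairwise_differences(
    seq_a: str,
    seq_b: str,
    exclude_heteromorphic: bool = True,
    indel_mode: str = "column",
) -> DiffReport:
    """Count nucleotide differences between two aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise InputError(f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}")
    states_a = _sequence_states(seq_a)
    states_b = _sequence_states(seq_b)
    per_column = []
    for a, b in zip(states_a, states_b):
        if a.is_missing or b.is_missing:
            per_column.append((None, None, "missing"))
        elif exclude_heteromorphic and (a.is_heteromorphic or b.is_heteromorphic):
            per_column.append((None, None, "het"))
        else:
            per_column.append((a, b, "ok"))
    return _tally(per_column, exclude_heteromorphic, indel_mode)


def _group_states(matrix: AlignedMatrix, samples: list[str], col: int) -> list[BaseSet]:
    return [matrix.state(s, col) for s in samples]


def group_unique_sites(
    matrix: AlignedMatrix,
    group_a: str,
    group_b: str,
    exclude_heteromorphic: bool = True,
    indel_mode: str = "column",
) -> DiffReport:
    """Count unique (fixed) sites between two species/groups.

    A column is excluded when any sample of either group is missing there,
    or (by default) when any is heteromorphic; a counted column is a unique
    site iff all group-A states are identical, all group-B states are
    identical, and the two shared states are disjoint.  Columns variable
    within either group go to ``excluded_polymorphic``.
    """
    a_samples = matrix.samples_in_group(group_a)
    b_samples = matrix.samples_in_group(group_b)
    if set(a_samples) & set(b_samples):
        raise InputError(f"groups {group_a!r} and {group_b!r} overlap")
    per_column = []
    for col in range(1, matrix.column_count + 1):
        sa = _group_states(matrix, a_samples, col)
        sb = _group_states(matrix, b_samples, col)
        if any(st.is_missing for st in sa + sb):
            per_column.append((None, None, "missing"))
        elif exclude_heteromorphic and any(st.is_heteromorphic for st in sa + sb):
            per_column.append((None, None, "het"))
        elif len(set(sa)) > 1 or len(set(sb)) > 1:
            per_column.append((None, None, "poly"))
        else:
            per_column.append((sa[0], sb[0], "ok"))
    return _tally(per_column, exclude_heteromorphic, indel_mode)


def species_vs_sample_differences(
    matrix: AlignedMatrix,
    group: str,
    sample: str,
    exclude_heteromorphic: bool = True,
    indel_mode: str = "column",
) -> DiffReport:
    """Differences between a species (as a consensus of identical states)
    and one outside sample.

    Columns polymorphic within the group are excluded; with a single-member
    group this reduces exactly to :func:`pairwise_differences`.
    """
    members = matrix.samples_in_group(group)
    matrix.subset_exists([sample])
    if sample in members:
        raise InputError(f"sample {sample!r} belongs to group {group!r}")
    per_column = []
    for col in range(1, matrix.column_count + 1):
        sg = _group_states(matrix, members, col)
        ss = matrix.state(sample, col)
        present = [st for st in sg if not st.is_missing]
        if ss.is_missing or not present:
            per_column.append((None, None, "missing"))
        elif exclude_heteromorphic and (
            ss.is_heteromorphic or any(st.is_heteromorphic for st in present)
        ):
            per_column.append((None, None, "het"))
        elif len(set(present)) > 1:
            per_column.append((None, None, "poly"))
        else:
            per_column.append((present[0], ss, "ok"))
    return _tally(per_column, exclude_heteromorphic, indel_mode)
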