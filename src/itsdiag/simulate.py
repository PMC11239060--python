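"""Synthetic heterokaryotic barcode communities and spore measurements.

The generator emulates the data regime of closely related *Agaricus*
species in an ITS alignment: groups of near-identical sequences separated
by a handful of fixed differences, per-sample heteromorphic sites written
as two-base IUPAC codes (two ITS alleles of a heterokaryotic fruit body),
and shared internal deletion blocks.  Every planted feature is recorded in
a truth table so downstream stages can be checked end to end.

Fixed differences use a star design: each species receives
``n_fixed_diffs / 2`` private substitution columns (mutated away from the
shared background), which makes *every* species pair differ at exactly
``n_fixed_diffs`` substitution columns.  With exactly two species an odd
count is split ceil/floor; an odd count with three or more species is
infeasible under this design and rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import ANCHOR_MOTIF, AlignedMatrix, GAP
from .errors import ConfigError
from .morphometry import SporeMeasurementSet

BASES = "ACGT"

#: two-base IUPAC code for each unordered base pair
_PAIR_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass(frozen=True)
class IndelBlock:
    """A shared deletion: ``length`` gap columns starting at ``position``
    (1-based) carried by every sample of ``carrier`` species."""

    position: int
    length: int
    carrier: str


@dataclass
class CommunityConfig:
    """Study conditions for one simulated community.

    Defaults mirror the regime of the two focal sister species in the
    motivating system: a ~718-column ITS alignment, species of 5 and 11
    specimens, four fixed substitution differences plus a one-column
    deletion (five unique sites in all), and about one heteromorphic cell
    per hundred sites per sample.
    """

    species: tuple[tuple[str, int], ...] = (("species_A", 5), ("species_B", 11))
    seq_length: int = 718
    n_fixed_diffs: int = 4
    heteromorphism_rate: float = 0.01
    indel_blocks: tuple[IndelBlock, ...] = (IndelBlock(669, 1, "species_A"),)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigError("at least one species required")
        names = [n for n, _ in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("species names must be unique")
        if any(n_samples < 1 for _, n_samples in self.species):
            raise ConfigError("each species needs at least one sample")
        if not 0.0 <= self.heteromorphism_rate <= 1.0:
            raise ConfigError("heteromorphism_rate must be in [0, 1]")
        if self.n_fixed_diffs < 0:
            raise ConfigError("n_fixed_diffs must be non-negative")
        if self.n_fixed_diffs % 2 and len(self.species) > 2:
            raise ConfigError(
                "an odd n_fixed_diffs is only realisable for exactly two species"
            )
        self.indel_blocks = tuple(
            b if isinstance(b, IndelBlock) else IndelBlock(*b) for b in self.indel_blocks
        )
        for b in self.indel_blocks:
            if b.carrier not in names:
                raise ConfigError(f"indel carrier {b.carrier!r} is not a species")
            # interior only: terminal gaps would read as missing data
            if b.position <= len(ANCHOR_MOTIF) or b.position + b.length - 1 >= self.seq_length:
                raise ConfigError(f"indel block {b} must lie strictly inside the sequence")


@dataclass
class TruthTable:
    """Planted features of one generated community."""

    diagnostic_columns: dict[str, list[int]]  # species -> private substitution columns
    indel_columns: dict[str, list[int]]  # species -> deletion columns it carries
    heteromorphic_cells: list[tuple[str, int, str]]  # (sample, column, code)
    pairwise_fixed_diffs: dict[tuple[str, str], int]  # substitution + indel columns

    def all_diagnostic(self, species: str) -> list[int]:
        """Every column expected to be diagnostic for ``species``.

        With three or more species only the species' own private
        substitution and deletion columns qualify; with exactly two
        species every fixed-difference column separates both groups and
        is therefore diagnostic for either one.
        """
        if len(self.diagnostic_columns) == 2:
            cols = [c for v in self.diagnostic_columns.values() for c in v]
            cols += [c for v in self.indel_columns.values() for c in v]
            return sorted(cols)
        return sorted(self.diagnostic_columns[species] + self.indel_columns[species])

    def to_json(self) -> str:
        return json.dumps(
            {
                "diagnostic_columns": self.diagnostic_columns,
                "indel_columns": self.indel_columns,
                "heteromorphic_cells": [list(c) for c in self.heteromorphic_cells],
                "pairwise_fixed_diffs": {
                    f"{a}|{b}": v for (a, b), v in self.pairwise_fixed_diffs.items()
                },
            },
            indent=2,
            sort_keys=True,
        )


def _allocate_private_counts(config: CommunityConfig) -> dict[str, int]:
    n = config.n_fixed_diffs
    names = [name for name, _ in config.species]
    if len(names) == 2 and n % 2:
        return {names[0]: math.ceil(n / 2), names[1]: n // 2}
    return {name: n // 2 for name in names}


def generate_community(config: CommunityConfig) -> tuple[AlignedMatrix, TruthTable]:
    """Generate an aligned community and its truth table (deterministic in
    ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    names = [name for name, _ in config.species]
    motif = ANCHOR_MOTIF.replace("Y", "T")  # concrete anchor: TTGAATT

    indel_cols: set[int] = set()
    for b in config.indel_blocks:
        indel_cols.update(range(b.position, b.position + b.length))
    counts = _allocate_private_counts(config)
    n_private = sum(counts.values())
    free = [c for c in range(len(motif) + 1, L + 1) if c not in indel_cols]
    if n_private > len(free):
        raise ConfigError(
            f"cannot place {n_private} fixed-difference columns in {len(free)} free columns"
        )
    private_cols = rng.choice(np.array(free), size=n_private, replace=False)
    private_cols = [int(c) for c in private_cols]
    diagnostic: dict[str, list[int]] = {}
    cursor = 0
    for name in names:
        diagnostic[name] = sorted(private_cols[cursor : cursor + counts[name]])
        cursor += counts[name]

    background = motif + "".join(rng.choice(list(BASES), size=L - len(motif)))
    # per-species template rows
    templates: dict[str, list[str]] = {}
    for name in names:
        row = list(background)
        for c in diagnostic[name]:
            old = row[c - 1]
            row[c - 1] = str(rng.choice([b for b in BASES if b != old]))
        for b in config.indel_blocks:
            if b.carrier == name:
                for c in range(b.position, b.position + b.length):
                    row[c - 1] = GAP
        templates[name] = row

    het_forbidden = set(private_cols) | indel_cols | set(range(1, len(motif) + 1))
    records: list[tuple[str, str]] = []
    group_of: dict[str, str] = {}
    het_cells: list[tuple[str, int, str]] = []
    for name, n_samples in config.species:
        for k in range(n_samples):
            sample = f"{name}_{k + 1}"
            row = list(templates[name])
            if config.heteromorphism_rate > 0:
                hits = np.nonzero(rng.random(L) < config.heteromorphism_rate)[0]
                for idx in hits:
                    col = int(idx) + 1
                    if col in het_forbidden or row[idx] == GAP:
                        continue
                    old = row[idx]
                    alt = str(rng.choice([b for b in BASES if b != old]))
                    code = _PAIR_CODE[frozenset((old, alt))]
                    row[idx] = code
                    het_cells.append((sample, col, code))
            records.append((sample, "".join(row)))
            group_of[sample] = name

    indel_by_species = {
        name: sorted(
            c
            for b in config.indel_blocks
            if b.carrier == name
            for c in range(b.position, b.position + b.length)
        )
        for name in names
    }
    pairwise: dict[tuple[str, str], int] = {}
    for i, a in enumerate(names):
        for b_name in names[i + 1 :]:
            subs = counts[a] + counts[b_name]
            indels = sum(
                blk.length
                for blk in config.indel_blocks
                if (blk.carrier == a) != (blk.carrier == b_name)
                and blk.carrier in (a, b_name)
            )
            # an indel carried by a third species distinguishes neither a nor b
            pairwise[(a, b_name)] = subs + indels
    truth = TruthTable(diagnostic, indel_by_species, het_cells, pairwise)
    return AlignedMatrix(records, group_of), truth


def generate_spores(
    mu_len: float = 6.2,
    sd_len: float = 0.67,
    mu_wid: float = 4.6,
    sd_wid: float = 0.45,
    i: int = 20,
    j: int = 10,
    seed: int = 0,
) -> SporeMeasurementSet:
    """Draw ``i`` spore measurements from each of ``j`` collections.

    Lengths and widths are independent normals truncated at zero (redrawn
    while non-positive).  Defaults are the reported spore statistics of the
    motivating brown-squamulose species (μm).
    """
    for v in (mu_len, mu_wid):
        if v <= 0:
            raise ConfigError("means must be positive")
    if sd_len < 0 or sd_wid < 0 or i < 1 or j < 1:
        raise ConfigError("sd must be >= 0 and i, j >= 1")
    rng = np.random.default_rng(seed)

    def draw(mu: float, sd: float) -> float:
        x = rng.normal(mu, sd)
        while x <= 0:
            x = rng.normal(mu, sd)
        return float(x)

    records = []
    for coll in range(1, j + 1):
        for _ in range(i):
            records.append((draw(mu_len, sd_len), draw(mu_wid, sd_wid), f"collection{coll}"))
    return SporeMeasurementSet(tuple(records))
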