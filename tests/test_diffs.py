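"""Nucleotide-difference counting conventions."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_disjoint, oracle_state, terminal_mask
from itsdiag.alignment import AlignedMatrix
from itsdiag.diffs import (
    group_unique_sites,
    pairwise_differences,
    species_vs_sample_differences,
)
from itsdiag.errors import InputError
from itsdiag.simulate import CommunityConfig, IndelBlock, generate_community

ALPHABET = "ACGTACGTACGTYRWN-"

seq_strategy = st.text(alphabet=ALPHABET, min_size=1, max_size=60)


def oracle_pairwise(seq_a, seq_b, exclude_het=True):
    """Independent per-column recount (column indel mode)."""
    ma, mb = terminal_mask(seq_a), terminal_mask(seq_b)
    counted = diffs = ex_het = ex_miss = indels = 0
    positions = []
    for i, (ca, cb) in enumerate(zip(seq_a, seq_b)):
        a = oracle_state(ca, ma[i])
        b = oracle_state(cb, mb[i])
        if a is None or b is None:
            ex_miss += 1
        elif exclude_het and any(
            isinstance(s, frozenset) and len(s) >= 2 for s in (a, b)
        ):
            ex_het += 1
        else:
            counted += 1
            if oracle_disjoint(a, b):
                diffs += 1
                positions.append(i + 1)
                if a == "-" or b == "-":
                    indels += 1
    return counted, diffs, ex_het, ex_miss, indels, positions


class TestPairwise:
    def test_identical_sequences(self):
        rep = pairwise_differences("ACGT", "ACGT")
        assert rep.differences == 0 and rep.counted_columns == 4

    def test_heteromorphic_column_excluded(self):
        rep = pairwise_differences("ACGT", "ACYT")
        assert (rep.counted_columns, rep.differences, rep.excluded_heteromorphic) == (3, 0, 1)

    def test_exclusion_off_compares_sets(self):
        # Y = {C,T} intersects T: no difference even when the column counts
        rep = pairwise_differences("ACTT", "ACYT", exclude_heteromorphic=False)
        assert rep.counted_columns == 4 and rep.differences == 0
        # but Y against G is disjoint, hence a difference
        rep = pairwise_differences("ACGT", "ACYT", exclude_heteromorphic=False)
        assert rep.differences == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            pairwise_differences("ACG", "ACGT")

    def test_gap_vs_base_counts_gap_vs_gap_does_not(self):
        rep = pairwise_differences("A-C-G", "ATC-G")
        assert rep.differences == 1 and rep.indel_differences == 1
        assert rep.difference_positions == [2]

    def test_event_mode_counts_gap_runs_once(self):
        rep = pairwise_differences("A---GA", "ATTTGC", indel_mode="event")
        assert rep.differences == 2  # one deletion event + one substitution
        assert rep.indel_differences == 1
        assert rep.difference_positions == [2, 6]
        col = pairwise_differences("A---GA", "ATTTGC", indel_mode="column")
        assert col.differences == 4 and col.indel_differences == 3

    @pytest.mark.parametrize("seed", range(50))
    def test_random_pairs_match_oracle_recount(self, seed):
        rng = random.Random(seed)
        n = 200
        a = "".join(rng.choice(ALPHABET) for _ in range(n))
        b = "".join(rng.choice(ALPHABET) for _ in range(n))
        for exclude in (True, False):
            rep = pairwise_differences(a, b, exclude_heteromorphic=exclude)
            assert (
                rep.counted_columns,
                rep.differences,
                rep.excluded_heteromorphic,
                rep.excluded_missing,
                rep.indel_differences,
                rep.difference_positions,
            ) == oracle_pairwise(a, b, exclude)

    @given(seq_strategy, seq_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert pairwise_differences(a, b).to_dict() == pairwise_differences(b, a).to_dict()

    @given(seq_strategy, seq_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_exclusion_monotonicity(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        with_excl = pairwise_differences(a, b, exclude_heteromorphic=True)
        without = pairwise_differences(a, b, exclude_heteromorphic=False)
        assert with_excl.differences <= without.differences


class TestGroupUniqueSites:
    def test_sister_species_unique_sites(self, sister_species_matrix):
        """Five fixed differences between the two sister species, at the
        known positions, once heteromorphic columns are excluded."""
        rep = group_unique_sites(
            sister_species_matrix, "A_glabriusculus", "A_badiosquamulosus"
        )
        assert rep.differences == 5
        assert rep.difference_positions == [298, 306, 535, 571, 669]
        assert rep.indel_differences == 1  # the deletion column 669

    def test_duplicate_groups_give_zero(self):
        m = AlignedMatrix(
            [("a1", "ACGT"), ("a2", "ACGT"), ("b1", "ACGT")],
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        assert group_unique_sites(m, "A", "B").differences == 0

    def test_overlapping_groups_rejected(self, sister_species_matrix):
        with pytest.raises(InputError):
            group_unique_sites(sister_species_matrix, "A_glabriusculus", "A_glabriusculus")

    def test_within_group_polymorphism_not_a_unique_site(self):
        # group A split C/T at column 2: excluded as polymorphic, not counted
        m = AlignedMatrix(
            [("a1", "ACG"), ("a2", "ATG"), ("b1", "AGG")],
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        rep = group_unique_sites(m, "A", "B")
        assert rep.differences == 0 and rep.excluded_polymorphic == 1

    def test_unchanged_by_duplicating_members(self, sister_species_matrix):
        m = sister_species_matrix
        rows = [(s, m.rows[s]) for s in m.sample_ids] + [
            ("TS2_dup", m.rows["TS2"]),
            ("M4_dup", m.rows["M4"]),
        ]
        groups = dict(m.group_of, TS2_dup="A_glabriusculus", M4_dup="A_badiosquamulosus")
        rep = group_unique_sites(AlignedMatrix(rows, groups), "A_glabriusculus", "A_badiosquamulosus")
        assert rep.differences == 5
        assert rep.difference_positions == [298, 306, 535, 571, 669]

    @pytest.mark.parametrize("f,h", [(2, 0), (4, 3), (6, 5)])
    def test_planted_fixed_differences_recovered(self, f, h):
        cfg = CommunityConfig(
            species=(("A", 4), ("B", 5)),
            seq_length=300,
            n_fixed_diffs=f,
            heteromorphism_rate=h / 300,
            indel_blocks=(),
            seed=f * 10 + h,
        )
        m, truth = generate_community(cfg)
        rep = group_unique_sites(m, "A", "B")
        assert rep.differences == truth.pairwise_fixed_diffs[("A", "B")] == f


class TestSpeciesVsSample:
    def _matrix(self):
        return AlignedMatrix(
            [("a1", "ACGTA"), ("a2", "ACGTA"), ("x", "ACCTA")],
            {"a1": "A", "a2": "A", "x": "ungrouped"},
        )

    def test_sample_identical_to_group(self):
        m = AlignedMatrix(
            [("a1", "ACGT"), ("a2", "ACGT"), ("x", "ACGT")],
            {"a1": "A", "a2": "A"},
        )
        assert species_vs_sample_differences(m, "A", "x").differences == 0

    def test_counts_consensus_vs_sample(self):
        rep = species_vs_sample_differences(self._matrix(), "A", "x")
        assert rep.differences == 1 and rep.difference_positions == [3]

    def test_sample_inside_group_rejected(self):
        with pytest.raises(InputError):
            species_vs_sample_differences(self._matrix(), "A", "a1")

    def test_single_member_group_reduces_to_pairwise(self):
        rng = random.Random(9)
        a = "".join(rng.choice(ALPHABET) for _ in range(120))
        x = "".join(rng.choice(ALPHABET) for _ in range(120))
        m = AlignedMatrix([("a1", a), ("x", x)], {"a1": "A"})
        rep = species_vs_sample_differences(m, "A", "x")
        pw = pairwise_differences(a, x)
        assert rep.differences == pw.differences
        assert rep.difference_positions == pw.difference_positions
        assert rep.excluded_heteromorphic == pw.excluded_heteromorphic
        assert rep.excluded_missing == pw.excluded_missing

    @pytest.mark.parametrize("d", [0, 3, 7])
    def test_planted_distance_recovered(self, d):
        cfg = CommunityConfig(
            species=(("G", 5), ("S", 1)),
            seq_length=400,
            n_fixed_diffs=d,
            heteromorphism_rate=0.0,
            indel_blocks=(),
            seed=d,
        )
        m, truth = generate_community(cfg)
        sample = m.samples_in_group("S")[0]
        rep = species_vs_sample_differences(m, "G", sample)
        assert rep.differences == d
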